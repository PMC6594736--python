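"""Synthetic metacommunities with known assembly processes and planted labels.

Real activated-sludge surveys give no ground truth: nobody knows which OTUs
truly are core or specialists.  This module builds OTU tables where the truth
is planted, so the partitioning and null-model machinery can be validated
end to end.

The generative model is deliberately minimal.  A regional species pool has
lognormal relative abundances (the canonical species-abundance distribution
for amplicon data).  Under *neutral* assembly every sample is one multinomial
draw from the pool — differences between samples are pure sampling noise.
Under *niche* assembly each OTU has a Gaussian response around an optimum on
a one-dimensional environmental axis, so samples at different environmental
positions draw from systematically different pools — deterministic turnover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables_io import OTUTable


@dataclass
class SyntheticScenario:
    """Full parameterization of one simulated metacommunity.

    Defaults mirror the scale of a multi-plant activated-sludge survey:
    13 samples rarefied to 7,000 reads, a few hundred OTUs, and a strongly
    uneven lognormal regional pool (sigma = 2 on the log scale, which gives
    the usual handful of dominant taxa over a long rare tail and a clearly
    positive abundance-occupancy relationship).
    """

    n_samples: int = 13
    n_otus: int = 500
    reads_per_sample: int = 7000
    sad_log_mean: float = 0.0
    sad_log_sd: float = 2.0
    assembly_mode: str = "neutral"  # {neutral, niche}
    niche_sd: float = 0.15
    env: np.ndarray | None = None  # per-sample environmental value, default linspace(0, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError(f"n_samples must be >= 2, got {self.n_samples}")
        if self.n_otus < 2:
            raise ValueError(f"n_otus must be >= 2, got {self.n_otus}")
        if self.reads_per_sample < 1:
            raise ValueError(f"reads_per_sample must be >= 1, got {self.reads_per_sample}")
        if self.niche_sd <= 0:
            raise ValueError(f"niche_sd must be > 0, got {self.niche_sd}")
        if self.assembly_mode not in {"neutral", "niche"}:
            raise ValueError(f"assembly_mode must be 'neutral' or 'niche', got {self.assembly_mode!r}")
        if self.env is None:
            self.env = np.linspace(0.0, 1.0, self.n_samples)
        self.env = np.asarray(self.env, dtype=float)
        if self.env.shape != (self.n_samples,):
            raise ValueError(f"env must have length n_samples={self.n_samples}")


def sample_probabilities(scenario: SyntheticScenario) -> tuple[np.ndarray, np.ndarray]:
    """Regional pool ``pi`` and the per-sample draw probabilities.

    Returns ``(pi, probs)`` with ``probs`` of shape (n_otus, n_samples).
    Neutral mode uses ``pi`` for every sample; niche mode weights ``pi`` by a
    Gaussian response around each OTU's optimum and renormalizes, so
    ``probs -> pi`` columnwise as ``niche_sd -> infinity``.  Deterministic
    given the scenario seed (optima consume the same stream positions the
    simulator uses).
    """
    rng = np.random.default_rng(scenario.seed)
    pi = rng.lognormal(scenario.sad_log_mean, scenario.sad_log_sd, scenario.n_otus)
    pi /= pi.sum()
    if scenario.assembly_mode == "neutral":
        probs = np.tile(pi[:, None], (1, scenario.n_samples))
    else:
        lo, hi = float(scenario.env.min()), float(scenario.env.max())
        mu = rng.uniform(lo, hi, scenario.n_otus)
        w = pi[:, None] * np.exp(
            -((scenario.env[None, :] - mu[:, None]) ** 2) / (2.0 * scenario.niche_sd**2))
        probs = w / w.sum(axis=0, keepdims=True)
    return pi, probs


def simulate_metacommunity(scenario: SyntheticScenario) -> OTUTable:
    """Simulate one OTU table under the scenario's assembly mode.

    Regional relative abundances pi are lognormal and normalized.  In
    neutral mode each sample is multinomial(reads, pi).  In niche mode OTU
    optima are uniform over the environmental range and sample j draws from
    probabilities proportional to ``pi_i * exp(-(env_j - mu_i)^2 / (2 sd^2))``.
    Byte-identical output for identical (scenario, seed).
    """
    rng = np.random.default_rng(scenario.seed)
    _, probs = sample_probabilities(scenario)
    # keep this rng aligned with sample_probabilities' consumption
    rng.lognormal(scenario.sad_log_mean, scenario.sad_log_sd, scenario.n_otus)
    if scenario.assembly_mode == "niche":
        rng.uniform(0.0, 1.0, scenario.n_otus)
    n, m = scenario.n_otus, scenario.n_samples
    counts = np.zeros((n, m), dtype=np.int64)
    for j in range(m):
        counts[:, j] = rng.multinomial(scenario.reads_per_sample, probs[:, j])
    otu_ids = [f"OTU_{i + 1:05d}" for i in range(n)]
    sample_ids = [f"S{j + 1:02d}" for j in range(m)]
    return OTUTable(otu_ids, sample_ids, counts)


@dataclass
class PlantedStructure:
    """Counts and intensities of planted ecological-group rows.

    Core rows are abundant in every sample with strong multiplicative
    between-sample heterogeneity (locally abundant *and* aggregated, so the
    dispersion test must flag them).  Satellite rows are a few reads confined
    to one or two samples.  Generalist rows spread a modest read total evenly
    over all samples — occupancy saturates while a marginal-preserving null
    leaves gaps.  Specialist rows concentrate a modest total in a small fixed
    sample subset.
    """

    n_core: int = 20
    n_satellite: int = 20
    n_generalist: int = 15
    n_specialist: int = 15
    core_mean: float = 80.0         # per-sample Poisson intensity scale for core rows
    core_log_sd: float = 1.0        # lognormal between-sample heterogeneity of core rows
    satellite_reads: int = 8        # total reads of one satellite row (1-2 samples)
    generalist_reads_per_sample: int = 1
    specialist_reads_per_sample: int = 20
    specialist_samples: tuple[int, ...] = (0, 1)  # column indices hosting specialists


def plant_group_structure(
    table: OTUTable,
    spec: PlantedStructure | None = None,
    seed: int = 0,
) -> tuple[OTUTable, dict[str, str]]:
    """Append planted core/satellite/generalist/specialist rows to ``table``.

    Returns the augmented table and a ground-truth label map covering every
    OTU (background rows are labeled ``"none"``).
    """
    spec = spec or PlantedStructure()
    rng = np.random.default_rng(seed)
    m = table.n_samples
    n_planted = spec.n_core + spec.n_satellite + spec.n_generalist + spec.n_specialist
    if n_planted <= 0:
        raise ValueError("no planted rows requested")
    if max(spec.specialist_samples, default=0) >= m:
        raise ValueError("specialist_samples index out of range")

    rows, ids, labels = [], [], []

    for k in range(spec.n_core):
        lam = spec.core_mean * rng.lognormal(0.0, spec.core_log_sd, m)
        row = np.maximum(rng.poisson(lam), 1)  # occupancy must stay complete
        rows.append(row)
        ids.append(f"CORE_{k + 1:03d}")
        labels.append("core")

    for k in range(spec.n_satellite):
        row = np.zeros(m, dtype=np.int64)
        hosts = rng.choice(m, size=rng.integers(1, 3), replace=False)
        # concentrate all reads in 1-2 samples
        split = rng.multinomial(spec.satellite_reads, np.ones(hosts.size) / hosts.size)
        row[hosts] = np.maximum(split, 0)
        if row.sum() == 0:
            row[hosts[0]] = 1
        rows.append(row)
        ids.append(f"SAT_{k + 1:03d}")
        labels.append("satellite")

    for k in range(spec.n_generalist):
        row = np.full(m, spec.generalist_reads_per_sample, dtype=np.int64)
        rows.append(row)
        ids.append(f"GEN_{k + 1:03d}")
        labels.append("generalist")

    for k in range(spec.n_specialist):
        row = np.zeros(m, dtype=np.int64)
        row[list(spec.specialist_samples)] = spec.specialist_reads_per_sample
        rows.append(row)
        ids.append(f"SPEC_{k + 1:03d}")
        labels.append("specialist")

    counts = np.vstack([table.counts, np.asarray(rows, dtype=np.int64)])
    otu_ids = list(table.otu_ids) + ids
    out = OTUTable(otu_ids, list(table.sample_ids), counts,
                   taxonomy=table.taxonomy, metadata=table.metadata)
    truth = {o: "none" for o in table.otu_ids}
    truth.update(dict(zip(ids, labels)))
    return out, truth


def default_location_metadata(sample_ids: list[str]) -> dict[str, dict]:
    """Two-city metadata split emulating the 8 + 5 sampling design."""
    n = len(sample_ids)
    n_first = max(1, round(n * 8 / 13))
    return {
        s: {"location": "Chongqing" if j < n_first else "Xiamen"}
        for j, s in enumerate(sample_ids)
    }
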