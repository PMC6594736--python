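"""Partition OTUs into ecological groups.

Two orthogonal classifications are computed from a rarefied OTU table:

* **core / satellite** — a chi-squared test of the index of dispersion of each
  OTU's counts across samples.  Counts whose dispersion falls inside the
  central 95% band of the chi-squared distribution (df = n_samples - 1) are
  consistent with random (Poisson) placement; over-dispersed *and* widely
  occupied OTUs are core (widely distributed, locally abundant), while
  randomly-placed or over-dispersed-but-restricted OTUs are satellite.

* **habitat generalist / specialist** — each OTU's observed occurrence
  (number of samples where it is detected) is compared to the occurrence
  distribution over fixed-fixed null tables generated with the quasiswap
  algorithm (row sums, column sums, and matrix fill all preserved).
  Occurrence above the null's upper 95% bound = generalist; below the lower
  bound = specialist.

Two dispersion statistics are offered.  ``paper`` mode is
``(variance / mean) * occupancy``; ``classic`` mode is the textbook Poisson
dispersion statistic ``(n - 1) * variance / mean``, whose null distribution
is exactly chi-squared(n - 1).  Both are compared against the same
chi-squared band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from numba import njit
from scipy import stats

from .tables_io import OTUTable

logger = logging.getLogger("asgroups")

CS_LABELS = ("core", "satellite", "unclassified")
GS_LABELS = ("generalist", "specialist", "nonsignificant")


# ---------------------------------------------------------------------------
# index of dispersion / core-satellite
# ---------------------------------------------------------------------------

@dataclass
class DispersionRecord:
    """Per-OTU dispersion test result."""

    otu_id: str
    mean_abundance: float
    variance: float
    occupancy: int
    dispersion_index: float
    chi2_lower: float = float("nan")
    chi2_upper: float = float("nan")
    cs_label: str | None = None
    testable: bool = True


def dispersion_index(counts_row, otu_id: str = "", mode: str = "paper") -> DispersionRecord:
    """Compute the index of dispersion of one OTU across samples.

    ``paper`` mode: D = (variance / mean) * occupancy.
    ``classic`` mode: D = (n - 1) * variance / mean.
    Variance is the unbiased sample variance over all samples, zeros
    included.  An all-zero row yields an untestable record (D = 0).
    """
    x = np.asarray(counts_row, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("counts_row must be 1-D with at least 2 samples")
    if mode not in {"paper", "classic"}:
        raise ValueError(f"mode must be 'paper' or 'classic', got {mode!r}")
    mean = float(x.mean())
    occupancy = int((x > 0).sum())
    if mean == 0.0:
        return DispersionRecord(otu_id, 0.0, 0.0, 0, 0.0, testable=False)
    variance = float(x.var(ddof=1))
    if mode == "paper":
        d = (variance / mean) * occupancy
    else:
        d = (x.size - 1) * variance / mean
    return DispersionRecord(otu_id, mean, variance, occupancy, d)


def core_satellite(
    table: OTUTable,
    alpha_band: tuple[float, float] = (0.025, 0.975),
    mode: str = "paper",
    core_min_occupancy_frac: float = 0.5,
) -> list[DispersionRecord]:
    """Label every OTU core / satellite / unclassified by the dispersion test.

    Critical values are the chi-squared quantiles at ``alpha_band`` with
    ``n_samples - 1`` degrees of freedom.  Core requires over-dispersion
    (D above the upper quantile) *and* occupancy of at least
    ``core_min_occupancy_frac`` of samples; over-dispersed but restricted
    OTUs, and OTUs inside the band (randomly distributed), are satellite;
    under-dispersed or untestable OTUs are unclassified.
    """
    lo, hi = alpha_band
    if not (0.0 < lo < hi < 1.0):
        raise ValueError(f"invalid alpha_band {alpha_band}: need 0 < lower < upper < 1")
    n = table.n_samples
    if n < 3:
        logger.warning("core_satellite: only %d samples; dispersion test is unreliable", n)
    chi2_lower = float(stats.chi2.ppf(lo, df=n - 1))
    chi2_upper = float(stats.chi2.ppf(hi, df=n - 1))
    min_occ = core_min_occupancy_frac * n

    # vectorized statistics, per-row records
    x = table.counts.astype(float)
    means = x.mean(axis=1)
    variances = x.var(axis=1, ddof=1)
    occs = (x > 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        if mode == "paper":
            ds = np.where(means > 0, variances / means * occs, 0.0)
        elif mode == "classic":
            ds = np.where(means > 0, (n - 1) * variances / means, 0.0)
        else:
            raise ValueError(f"mode must be 'paper' or 'classic', got {mode!r}")

    records = []
    for i, otu in enumerate(table.otu_ids):
        testable = means[i] > 0
        if not testable:
            label = "unclassified"
        elif ds[i] > chi2_upper:
            label = "core" if occs[i] >= min_occ else "satellite"
        elif ds[i] >= chi2_lower:
            label = "satellite"
        else:
            label = "unclassified"
        records.append(
            DispersionRecord(
                otu, float(means[i]), float(variances[i]) if testable else 0.0,
                int(occs[i]), float(ds[i]), chi2_lower, chi2_upper,
                cs_label=label, testable=bool(testable),
            )
        )
    return records


# ---------------------------------------------------------------------------
# fixed-fixed null tables: Patefield initialization + quasiswap fill repair
# ---------------------------------------------------------------------------

def patefield_sample(row_sums, col_sums, seed) -> np.ndarray:
    """One random contingency table with the given margins.

    Sampled from the conditional-uniform (multivariate hypergeometric)
    distribution using Patefield's algorithm via scipy.  Margins with a
    single row or column determine the table uniquely and are returned
    directly.
    """
    r = np.asarray(row_sums, dtype=np.int64)
    c = np.asarray(col_sums, dtype=np.int64)
    if (r < 0).any() or (c < 0).any():
        raise ValueError("margins must be non-negative")
    if r.sum() != c.sum():
        raise ValueError(f"margin totals differ: rows sum to {r.sum()}, columns to {c.sum()}")
    if r.size == 1:
        return c[np.newaxis, :].copy()
    if c.size == 1:
        return r[:, np.newaxis].copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return stats.random_table(r, c).rvs(method="patefield", random_state=rng).astype(np.int64)


@njit(cache=True)
def _quasiswap_fill_adjust(m, target_fill, max_iter, seed):  # pragma: no cover - jitted
    """Drive the fill (nonzero-cell count) of ``m`` to ``target_fill``.

    Random 2x2 submatrices receive margin-preserving diagonal transfers:
    annihilating transfers (subtract min of one diagonal) when fill must
    drop, unit transfers when it must rise; moves in the wrong direction
    are rejected.  Deterministic xorshift64* randomness from ``seed``.
    """
    nr, nc = m.shape
    fill = 0
    for i in range(nr):
        for j in range(nc):
            if m[i, j] != 0:
                fill += 1
    state = np.uint64(seed * 2 + 1)
    it = 0
    while fill != target_fill and it < max_iter:
        it += 1
        # four random indices from one xorshift64* stream
        state ^= state >> np.uint64(12)
        state ^= state << np.uint64(25)
        state ^= state >> np.uint64(27)
        r = state * np.uint64(2685821657736338717)
        i1 = int((r >> np.uint64(33)) % np.uint64(nr))
        state ^= state >> np.uint64(12)
        state ^= state << np.uint64(25)
        state ^= state >> np.uint64(27)
        r = state * np.uint64(2685821657736338717)
        i2 = int((r >> np.uint64(33)) % np.uint64(nr))
        state ^= state >> np.uint64(12)
        state ^= state << np.uint64(25)
        state ^= state >> np.uint64(27)
        r = state * np.uint64(2685821657736338717)
        j1 = int((r >> np.uint64(33)) % np.uint64(nc))
        state ^= state >> np.uint64(12)
        state ^= state << np.uint64(25)
        state ^= state >> np.uint64(27)
        r = state * np.uint64(2685821657736338717)
        j2 = int((r >> np.uint64(33)) % np.uint64(nc))
        flip = (r & np.uint64(1)) == np.uint64(1)
        if i1 == i2 or j1 == j2:
            continue
        if flip:
            j1, j2 = j2, j1
        a = m[i1, j1]
        b = m[i1, j2]
        c = m[i2, j1]
        d = m[i2, j2]
        if fill > target_fill:
            s = a if a < d else d
            if s == 0:
                continue
            delta = (1 if b == 0 else 0) + (1 if c == 0 else 0) \
                - (1 if a == s else 0) - (1 if d == s else 0)
            if delta <= 0:
                m[i1, j1] = a - s
                m[i2, j2] = d - s
                m[i1, j2] = b + s
                m[i2, j1] = c + s
                fill += delta
        else:
            if a == 0 or d == 0:
                continue
            delta = (1 if b == 0 else 0) + (1 if c == 0 else 0) \
                - (1 if a == 1 else 0) - (1 if d == 1 else 0)
            if delta >= 0:
                m[i1, j1] = a - 1
                m[i2, j2] = d - 1
                m[i1, j2] = b + 1
                m[i2, j1] = c + 1
                fill += delta
    return fill


def _subseed(seed: int, index: int) -> np.random.SeedSequence:
    # independent, order-independent sub-stream per null table
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(int(index),))


def quasiswap(table, seed=0, max_iter_factor: int = 100) -> np.ndarray:
    """One fixed-fixed null matrix: same row sums, column sums, and fill.

    A Patefield table with the observed margins is drawn, then its fill is
    repaired to the observed fill with margin-preserving 2x2 transfers.
    """
    counts = table.counts if isinstance(table, OTUTable) else np.asarray(table, dtype=np.int64)
    if counts.size == 0:
        raise ValueError("empty table")
    target_fill = int(np.count_nonzero(counts))
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed))
    rng = np.random.default_rng(ss)
    null = patefield_sample(counts.sum(axis=1), counts.sum(axis=0), rng)
    if null.shape[0] < 2 or null.shape[1] < 2:
        return null  # margins fully determine the table
    max_iter = max_iter_factor * counts.size
    kernel_seed = int(ss.generate_state(1, dtype=np.uint64)[0] >> 1)
    fill = _quasiswap_fill_adjust(null, target_fill, max_iter, kernel_seed)
    if fill != target_fill:
        raise RuntimeError(
            f"quasiswap did not reach target fill {target_fill} (got {fill}, "
            f"gap {fill - target_fill}) within {max_iter} iterations; "
            "increase max_iter_factor"
        )
    return null


# ---------------------------------------------------------------------------
# generalist / specialist
# ---------------------------------------------------------------------------

@dataclass
class OccurrenceNullRecord:
    """Per-OTU occurrence (or niche-breadth) null-model test result."""

    otu_id: str
    observed: float
    null_lower: float
    null_upper: float
    null_mean: float
    null_sd: float
    gs_label: str = "nonsignificant"


def _metric_values(counts: np.ndarray, metric: str) -> np.ndarray:
    if metric == "occurrence":
        return (counts > 0).sum(axis=1).astype(float)
    if metric == "levins_b":
        totals = counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(totals > 0, counts / totals, 0.0)
            ssq = (p**2).sum(axis=1)
            return np.where(ssq > 0, 1.0 / ssq, 0.0)
    raise ValueError(f"metric must be 'occurrence' or 'levins_b', got {metric!r}")


def generalist_specialist(
    table: OTUTable,
    n_null: int = 1000,
    ci: tuple[float, float] = (0.025, 0.975),
    metric: str = "occurrence",
    seed: int = 0,
    ci_method: str = "percentile",
    max_iter_factor: int = 100,
) -> list[OccurrenceNullRecord]:
    """Classify OTUs against a quasiswap (fixed-fixed) occurrence null.

    For each of ``n_null`` null tables the per-OTU metric is recomputed;
    an OTU whose observed metric exceeds the null's upper bound is a habitat
    generalist, one below the lower bound a habitat specialist.  Bounds are
    empirical percentiles of the null by default, or ``mean +/- 1.96 sd``
    with ``ci_method='normal'``.
    """
    if n_null < 100:
        raise ValueError(f"n_null must be >= 100 for a stable CI, got {n_null}")
    if ci_method not in {"percentile", "normal"}:
        raise ValueError(f"ci_method must be 'percentile' or 'normal', got {ci_method!r}")
    observed = _metric_values(table.counts, metric)
    nulls = np.empty((n_null, table.counts.shape[0]))
    for k in range(n_null):
        null = quasiswap(table, seed=_subseed(seed, k), max_iter_factor=max_iter_factor)
        nulls[k] = _metric_values(null, metric)
    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1)
    if ci_method == "percentile":
        lower = np.quantile(nulls, ci[0], axis=0)
        upper = np.quantile(nulls, ci[1], axis=0)
    else:
        z = float(stats.norm.ppf(ci[1]))
        lower, upper = mean - z * sd, mean + z * sd
    records = []
    for i, otu in enumerate(table.otu_ids):
        if observed[i] > upper[i]:
            label = "generalist"
        elif observed[i] < lower[i]:
            label = "specialist"
        else:
            label = "nonsignificant"
        records.append(
            OccurrenceNullRecord(
                otu, float(observed[i]), float(lower[i]), float(upper[i]),
                float(mean[i]), float(sd[i]), label,
            )
        )
    return records


# ---------------------------------------------------------------------------
# group assignment & overlaps
# ---------------------------------------------------------------------------

def pct_round_half_up(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage of ``numerator`` in ``denominator``, rounded half-up."""
    if denominator == 0:
        return 0.0
    q = Decimal(numerator) * 100 / Decimal(denominator)
    return float(q.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))


@dataclass
class GroupAssignment:
    """Per-OTU ecological-group labels with summary counts and read shares."""

    otu_ids: list[str]
    cs_labels: dict[str, str]
    gs_labels: dict[str, str]
    group_members: dict[str, set] = field(default_factory=dict)
    group_counts: dict[str, int] = field(default_factory=dict)
    group_read_fractions: dict[str, float] = field(default_factory=dict)


def assign_groups(
    table: OTUTable,
    dispersion_records: list[DispersionRecord],
    occurrence_records: list[OccurrenceNullRecord],
) -> GroupAssignment:
    """Combine both classifications into one per-OTU assignment."""
    cs = {r.otu_id: r.cs_label for r in dispersion_records}
    gs = {r.otu_id: r.gs_label for r in occurrence_records}
    members = {
        "core": {o for o, l in cs.items() if l == "core"},
        "satellite": {o for o, l in cs.items() if l == "satellite"},
        "generalist": {o for o, l in gs.items() if l == "generalist"},
        "specialist": {o for o, l in gs.items() if l == "specialist"},
    }
    total_reads = float(table.counts.sum())
    row_totals = dict(zip(table.otu_ids, table.counts.sum(axis=1)))
    read_frac = {
        g: (float(sum(row_totals[o] for o in m)) / total_reads if total_reads > 0 else 0.0)
        for g, m in members.items()
    }
    return GroupAssignment(
        otu_ids=list(table.otu_ids),
        cs_labels=cs,
        gs_labels=gs,
        group_members=members,
        group_counts={g: len(m) for g, m in members.items()},
        group_read_fractions=read_frac,
    )


def group_overlap(assignment: GroupAssignment) -> list[dict]:
    """Pairwise shared-OTU counts between groups (the Venn numbers).

    Percentages are of each group's own total, one decimal, half-up.
    """
    groups = ["core", "satellite", "generalist", "specialist"]
    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            a, b = assignment.group_members[ga], assignment.group_members[gb]
            shared = len(a & b)
            rows.append({
                "group_a": ga,
                "group_b": gb,
                "shared": shared,
                "pct_of_a": pct_round_half_up(shared, len(a)),
                "pct_of_b": pct_round_half_up(shared, len(b)),
            })
    return rows
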