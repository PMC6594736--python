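"""Abundance-based beta-diversity null deviations per ecological group.

The deviation of observed Bray-Curtis beta-diversity from the expectation
under a null that preserves each sample's community size and the regional
species-abundance distribution — but randomizes composition — measures the
relative role of deterministic (niche) versus stochastic (neutral) assembly.
Deviations near zero mean the observed turnover is what random draws from a
shared pool would produce (stochastic); deviations away from zero mean
systematic compositional turnover beyond sampling noise (deterministic).

The null metacommunity draws, for every sample, its observed group read
total from a multinomial over the regional relative abundances (group OTU
totals pooled over samples).  An individual-based without-replacement
variant (shuffling the finite regional read pool) is available via
``replace=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .tables_io import OTUTable, subset_table

logger = logging.getLogger("asgroups")


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix over samples."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} does not match {n} sample ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        self.values = v

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in pair order (i < j)."""
        iu = np.triu_indices(len(self.sample_ids), k=1)
        return self.values[iu]

    def pair_ids(self) -> list[tuple[str, str]]:
        return list(combinations(self.sample_ids, 2))


def _bray_curtis_values(x: np.ndarray) -> np.ndarray:
    """Pairwise Bray-Curtis on columns of an (otus x samples) matrix."""
    x = np.asarray(x, dtype=float)
    # |xi - xj| and (xi + xj) summed over OTUs, all pairs at once
    diff = np.abs(x[:, :, None] - x[:, None, :]).sum(axis=0)
    tot = (x[:, :, None] + x[:, None, :]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(tot > 0, diff / np.where(tot > 0, tot, 1.0), 0.0)
    n_empty = int((x.sum(axis=0) == 0).sum())
    if n_empty >= 2:  # off-diagonal zero-total pairs exist
        logger.warning("bray_curtis: pair(s) of all-zero samples set to 0 by convention")
    np.fill_diagonal(d, 0.0)
    return d


def bray_curtis(data) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all sample pairs.

    ``BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i)``; a pair of all-zero
    samples is 0 by convention.  Accepts an :class:`OTUTable`, an
    :class:`~asgroups.tables_io.AbundanceMatrix`, or a plain array with
    samples as columns.
    """
    if isinstance(data, OTUTable):
        ids, mat = list(data.sample_ids), data.counts
    elif hasattr(data, "values") and hasattr(data, "sample_ids"):
        ids, mat = list(data.sample_ids), data.values
    else:
        mat = np.asarray(data, dtype=float)
        ids = [f"S{j + 1}" for j in range(mat.shape[1])]
    if len(ids) < 2:
        raise ValueError("need at least 2 samples")
    return DistanceMatrix(ids, _bray_curtis_values(mat))


def draw_null_metacommunity(
    pool: np.ndarray,
    sample_totals,
    rng: np.random.Generator,
    replace: bool = True,
) -> np.ndarray:
    """One null metacommunity preserving local size and regional SAD.

    Every sample's read total is redrawn from the regional relative
    abundances ``pool / pool.sum()`` — a multinomial by default, or a
    without-replacement draw from the finite pooled reads (``replace=False``,
    in which case ``sum(sample_totals)`` must not exceed the pool).
    """
    pool = np.asarray(pool, dtype=np.int64)
    totals = np.asarray(sample_totals, dtype=np.int64)
    null = np.empty((pool.size, totals.size), dtype=np.int64)
    if replace:
        pi = pool / pool.sum()
        for j, nj in enumerate(totals):
            null[:, j] = rng.multinomial(int(nj), pi)
    else:
        if totals.sum() > pool.sum():
            raise ValueError("sample totals exceed the regional pool")
        remaining = pool.copy()
        for j, nj in enumerate(totals):
            draw = rng.multivariate_hypergeometric(remaining, int(nj), method="marginals")
            null[:, j] = draw
            remaining = remaining - draw
    return null


@dataclass
class BetaNullResult:
    """Observed vs. null-expected Bray-Curtis for one ecological group."""

    group_label: str
    sample_ids: list[str]
    observed_mean_beta: float
    expected_mean_beta: float
    deviation_mean: float
    pairwise_observed: np.ndarray
    pairwise_expected: np.ndarray
    pairwise_deviations: np.ndarray
    n_null: int
    null_sd: float

    def pair_ids(self) -> list[tuple[str, str]]:
        return list(combinations(self.sample_ids, 2))


def beta_null_deviation(
    table: OTUTable,
    group_otus,
    n_null: int = 999,
    seed: int = 0,
    group_label: str = "group",
    replace: bool = True,
) -> BetaNullResult:
    """Beta-null deviation of one OTU group across samples.

    The table is restricted to the group's OTUs; observed pairwise
    Bray-Curtis is computed on the (rarefied) counts; each null iteration
    redraws every sample's observed group read total from the regional
    relative abundances (multinomial by default, or without replacement
    from the pooled read counts with ``replace=False``); the expected
    dissimilarity of a pair is its mean over nulls, and the deviation is
    observed minus expected, per pair and averaged.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    group_otus = list(group_otus)
    if not group_otus:
        raise ValueError("empty OTU group")
    sub = subset_table(table, group_otus)
    totals = sub.sample_totals()
    keep = totals > 0
    if keep.sum() < 2:
        raise ValueError("need at least 2 samples with nonzero group reads")
    if not keep.all():
        excluded = [s for s, k in zip(sub.sample_ids, keep) if not k]
        logger.warning("beta_null_deviation(%s): excluding sample(s) with zero group reads: %s",
                       group_label, ", ".join(excluded))
        sub = OTUTable(list(sub.otu_ids), [s for s, k in zip(sub.sample_ids, keep) if k],
                       sub.counts[:, keep])
        totals = sub.sample_totals()

    counts = sub.counts
    obs = _bray_curtis_values(counts)
    iu = np.triu_indices(counts.shape[1], k=1)
    pair_obs = obs[iu]

    pool = counts.sum(axis=1)  # regional read totals per OTU
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed)))

    pair_sum = np.zeros_like(pair_obs)
    mean_betas = np.empty(n_null)
    for k in range(n_null):
        null = draw_null_metacommunity(pool, totals, rng, replace=replace)
        d = _bray_curtis_values(null)[iu]
        pair_sum += d
        mean_betas[k] = d.mean()
    pair_exp = pair_sum / n_null
    pair_dev = pair_obs - pair_exp
    return BetaNullResult(
        group_label=group_label,
        sample_ids=list(sub.sample_ids),
        observed_mean_beta=float(pair_obs.mean()),
        expected_mean_beta=float(pair_exp.mean()),
        deviation_mean=float(pair_dev.mean()),
        pairwise_observed=pair_obs,
        pairwise_expected=pair_exp,
        pairwise_deviations=pair_dev,
        n_null=n_null,
        null_sd=float(mean_betas.std(ddof=1)) if n_null > 1 else 0.0,
    )


def compare_group_deviations(result_a: BetaNullResult, result_b: BetaNullResult) -> dict:
    """Two-sided Wilcoxon rank-sum test between two groups' pairwise deviations."""
    from .group_stats import wilcoxon

    if set(result_a.sample_ids) != set(result_b.sample_ids):
        raise ValueError(
            f"sample sets differ: {sorted(result_a.sample_ids)} vs {sorted(result_b.sample_ids)}"
        )
    stat, p = wilcoxon(result_a.pairwise_deviations, result_b.pairwise_deviations)
    med_diff = float(np.median(result_a.pairwise_deviations)
                     - np.median(result_b.pairwise_deviations))
    return {
        "group_a": result_a.group_label,
        "group_b": result_b.group_label,
        "statistic": stat,
        "p_value": p,
        "median_difference": med_diff,
        "sign": int(np.sign(med_diff)),
    }
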