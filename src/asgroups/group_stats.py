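"""Permutation and rank statistics for community-structure comparisons.

One-way PERMANOVA (adonis), ANOSIM, MRPP and the Mantel test are computed
directly on a distance matrix with seeded label permutations; p-values use
the Monte-Carlo ``(count + 1) / (n_perm + 1)`` convention, or exact
enumeration of all distinct label arrangements with ``n_perm="exact"``.
PCoA (classical metric MDS via Gower double-centering) displays the
beta-diversity patterns those tests quantify.  The abundance-occupancy
regression and per-group taxon composition summaries support the
ecological-group description of the community.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations as _iter_permutations

import numpy as np
from scipy import stats

from .beta_null import DistanceMatrix
from .tables_io import OTUTable

logger = logging.getLogger("asgroups")


@dataclass
class PermutationTestResult:
    test_name: str
    statistic: float
    p_value: float
    n_permutations: int
    effect_r2: float | None = None


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray        # samples x positive axes
    eigenvalues: np.ndarray        # all eigenvalues, non-increasing
    proportion_explained: np.ndarray  # over positive eigenvalues


@dataclass
class AbundanceOccupancyFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_otus: int


# ---------------------------------------------------------------------------
# shared permutation machinery
# ---------------------------------------------------------------------------

def _check_grouping(dist: DistanceMatrix, grouping: dict) -> np.ndarray:
    missing = [s for s in dist.sample_ids if s not in grouping]
    if missing:
        raise ValueError(f"grouping does not cover sample(s): {missing}")
    labels = np.asarray([grouping[s] for s in dist.sample_ids], dtype=object)
    if len(set(labels.tolist())) < 2:
        raise ValueError("need at least 2 groups")
    return labels


def _distinct_label_arrangements(labels: np.ndarray):
    seen = set()
    for perm in _iter_permutations(labels.tolist()):
        if perm not in seen:
            seen.add(perm)
            yield np.asarray(perm, dtype=object)


def _permutation_p(stat_fn, labels, observed, n_perm, seed, tail: str):
    """Monte-Carlo or exhaustive permutation p for a label statistic."""
    if n_perm == "exact":
        count = total = 0
        for perm in _distinct_label_arrangements(labels):
            s = stat_fn(perm)
            total += 1
            if (tail == "ge" and s >= observed - 1e-12) or \
               (tail == "le" and s <= observed + 1e-12):
                count += 1
        return count / total, total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(int(n_perm)):
        s = stat_fn(rng.permutation(labels))
        if (tail == "ge" and s >= observed - 1e-12) or \
           (tail == "le" and s <= observed + 1e-12):
            count += 1
    return (count + 1) / (int(n_perm) + 1), int(n_perm)


# ---------------------------------------------------------------------------
# PERMANOVA / ANOSIM / MRPP / Mantel
# ---------------------------------------------------------------------------

def adonis(dist: DistanceMatrix, grouping: dict, n_perm=999, seed: int = 0) -> PermutationTestResult:
    """One-way PERMANOVA on a distance matrix.

    ``SS_total = sum_{i<j} d_ij^2 / N``; within-group sums of squares use
    within-group pairs divided by group size; ``F = (SS_b/(a-1)) /
    (SS_w/(N-a))`` and ``R^2 = SS_b / SS_total``.  The p-value permutes
    sample labels (``n_perm="exact"`` enumerates all distinct arrangements).
    """
    labels = _check_grouping(dist, grouping)
    d2 = dist.values**2
    n = len(labels)
    a = len(set(labels.tolist()))
    if a >= n:
        raise ValueError("every sample in its own group: no within-group variance")
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n

    def ss_within(lab):
        total = 0.0
        for g in set(lab.tolist()):
            idx = np.flatnonzero(lab == g)
            if idx.size > 1:
                sub = d2[np.ix_(idx, idx)]
                total += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
        return total

    def f_stat(lab):
        ss_w = ss_within(lab)
        if ss_w == 0.0:
            return np.inf  # all variance between groups
        return ((ss_total - ss_w) / (a - 1)) / (ss_w / (n - a))

    observed = f_stat(labels)
    r2 = 1.0 - ss_within(labels) / ss_total if ss_total > 0 else 0.0
    p, nperm = _permutation_p(f_stat, labels, observed, n_perm, seed, "ge")
    return PermutationTestResult("adonis", float(observed), float(p), nperm, effect_r2=float(r2))


def anosim(dist: DistanceMatrix, grouping: dict, n_perm=999, seed: int = 0) -> PermutationTestResult:
    """ANOSIM R on ranked distances: (mean between-rank - mean within-rank) / (M/2)."""
    labels = _check_grouping(dist, grouping)
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    ranks = stats.rankdata(dist.values[iu])  # average ranks for ties
    m_half = (n * (n - 1) / 2) / 2.0

    def r_stat(lab):
        same = lab[iu[0]] == lab[iu[1]]
        return (ranks[~same].mean() - ranks[same].mean()) / m_half

    observed = r_stat(labels)
    p, nperm = _permutation_p(r_stat, labels, observed, n_perm, seed, "ge")
    return PermutationTestResult("anosim", float(observed), float(p), nperm)


def mrpp(dist: DistanceMatrix, grouping: dict, n_perm=999, seed: int = 0) -> PermutationTestResult:
    """MRPP delta: group-size-weighted mean within-group distance; small delta
    means cohesive groups, so the p-value counts permutations with
    ``delta_perm <= delta_obs``."""
    labels = _check_grouping(dist, grouping)
    n = len(labels)

    def delta_stat(lab):
        delta = 0.0
        for g in set(lab.tolist()):
            idx = np.flatnonzero(lab == g)
            if idx.size > 1:
                sub = dist.values[np.ix_(idx, idx)]
                mean_within = sub[np.triu_indices(idx.size, k=1)].mean()
            else:
                mean_within = 0.0  # singleton group contributes 0
                logger.debug("mrpp: singleton group %r contributes 0", g)
            delta += (idx.size / n) * mean_within
        return delta

    observed = delta_stat(labels)
    p, nperm = _permutation_p(delta_stat, labels, observed, n_perm, seed, "le")
    return PermutationTestResult("mrpp", float(observed), float(p), nperm)


def mantel(
    dist_a: DistanceMatrix,
    dist_b: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Mantel correlation between two distance matrices over the same samples.

    Pearson or Spearman correlation of the upper triangles; the p-value
    permutes rows and columns of the second matrix simultaneously and is
    one-sided (greater), the usual convention for matrix association.
    """
    if dist_a.sample_ids != dist_b.sample_ids:
        raise ValueError("distance matrices must share sample ids and order")
    if method not in {"spearman", "pearson"}:
        raise ValueError(f"method must be 'spearman' or 'pearson', got {method!r}")
    n = len(dist_a.sample_ids)
    iu = np.triu_indices(n, k=1)
    va = dist_a.values[iu]
    if method == "spearman":
        va = stats.rankdata(va)

    def corr(bmat):
        vb = bmat[iu]
        if method == "spearman":
            vb = stats.rankdata(vb)
        return float(np.corrcoef(va, vb)[0, 1])

    observed = corr(dist_b.values)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(int(n_perm)):
        perm = rng.permutation(n)
        if corr(dist_b.values[np.ix_(perm, perm)]) >= observed - 1e-12:
            count += 1
    p = (count + 1) / (int(n_perm) + 1)
    return PermutationTestResult("mantel", observed, float(p), int(n_perm))


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

def pcoa(dist: DistanceMatrix) -> OrdinationResult:
    """Principal coordinate analysis (Gower double-centering).

    Negative eigenvalues (non-Euclidean input) are reported with a warning,
    not corrected; coordinates use positive eigenvalues only and proportions
    explained are over the positive spectrum.
    """
    d = dist.values
    n = d.shape[0]
    b = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ b @ j
    b = (b + b.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-10 * max(1.0, abs(eigvals[0])) if n else 0.0
    if (eigvals < -tol).any():
        logger.warning("pcoa: %d negative eigenvalue(s); input is non-Euclidean",
                       int((eigvals < -tol).sum()))
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    prop = eigvals[pos] / eigvals[pos].sum() if pos.any() else np.zeros(0)
    return OrdinationResult(list(dist.sample_ids), coords, eigvals, prop)


# ---------------------------------------------------------------------------
# rank tests / regressions / composition
# ---------------------------------------------------------------------------

def wilcoxon(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum W of x, p).

    Exact enumeration when both samples are small (nx + ny <= 12) and
    untied, otherwise the normal approximation with continuity correction
    (``mode`` forces either branch).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "exact" if (x.size + y.size <= 12 and not has_ties) else "normal_approx"
    if mode == "exact" and has_ties:
        logger.warning("wilcoxon: ties present, falling back to normal approximation")
        mode = "normal_approx"
    method = "exact" if mode == "exact" else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=(method == "asymptotic"))
    w = float(res.statistic + x.size * (x.size + 1) / 2)  # U -> rank-sum of x
    return w, float(res.pvalue)


def abundance_occupancy(table: OTUTable) -> AbundanceOccupancyFit:
    """OLS of log10(mean abundance) on occupancy across OTUs.

    Mean abundance includes zero samples; OTUs with zero total are excluded
    (their log-abundance is undefined).  A strong positive fit is the
    classic abundance-occupancy relationship.
    """
    means = table.counts.mean(axis=1)
    occ = table.occupancy().astype(float)
    mask = means > 0
    if mask.sum() < 3:
        raise ValueError("need at least 3 OTUs with nonzero totals")
    x, y = occ[mask], np.log10(means[mask])
    if np.unique(x).size < 2:
        raise ValueError("all OTUs share one occupancy value; slope undefined")
    fit = stats.linregress(x, y)
    return AbundanceOccupancyFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n_otus=int(mask.sum()),
    )


def taxon_composition(
    table: OTUTable,
    labels: dict[str, str],
    rank: int = 1,
    min_frac: float = 0.005,
) -> dict[str, dict[str, float]]:
    """Per-group relative abundance of taxa at one taxonomy rank.

    Reads are summed per taxon within each group and normalized by the
    group's total; taxa below ``min_frac`` of a group's reads collapse into
    ``"Other"`` (taxa at exactly the threshold are retained).  ``rank``
    indexes the lineage (0 = domain).
    """
    if table.taxonomy is None:
        raise ValueError("table has no taxonomy")
    groups: dict[str, dict[str, float]] = {}
    totals = dict(zip(table.otu_ids, table.counts.sum(axis=1)))
    for otu, group in labels.items():
        if group in (None, "none", "nonsignificant", "unclassified"):
            continue
        lineage = table.taxonomy.get(otu, [])
        taxon = lineage[rank] if len(lineage) > rank else "Unassigned"
        groups.setdefault(group, {})
        groups[group][taxon] = groups[group].get(taxon, 0.0) + float(totals.get(otu, 0))
    out = {}
    for group, taxa in groups.items():
        total = sum(taxa.values())
        if total == 0:
            out[group] = {}
            continue
        fracs = {t: v / total for t, v in taxa.items()}
        kept = {t: f for t, f in fracs.items() if f >= min_frac}
        other = sum(f for t, f in fracs.items() if t not in kept)
        if other > 0:
            kept["Other"] = other
        out[group] = kept
    return out
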