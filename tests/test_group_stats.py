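from itertools import permutations

import numpy as np
import pytest
from scipy import stats

import asgroups as ag
from asgroups.beta_null import DistanceMatrix


def _dist_from_points(points):
    pts = np.asarray(points, dtype=float)
    d = np.abs(pts[:, None] - pts[None, :])
    ids = [f"s{i}" for i in range(len(pts))]
    return DistanceMatrix(ids, d)


def _two_groups(n_a, n_b):
    return {f"s{i}": ("A" if i < n_a else "B") for i in range(n_a + n_b)}


@pytest.fixture
def toy_six():
    """6 samples in 1-D, two groups of 3, with some separation."""
    rng = np.random.default_rng(3)
    pts = np.concatenate([rng.normal(0, 1, 3), rng.normal(2, 1, 3)])
    return _dist_from_points(pts), _two_groups(3, 3), pts


def _brute_force_permanova(d, labels):
    """Independent exhaustive PERMANOVA oracle (direct SS bookkeeping)."""
    n = len(labels)
    a = len(set(labels))

    def f_of(lab):
        sst = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
        ssw = 0.0
        for g in set(lab):
            idx = [i for i, l in enumerate(lab) if l == g]
            ssw += sum(d[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
        return ((sst - ssw) / (a - 1)) / (ssw / (n - a))

    f_obs = f_of(labels)
    arrangements = set(permutations(labels))
    count = sum(f_of(lab) >= f_obs - 1e-12 for lab in arrangements)
    return f_obs, count / len(arrangements)


def _brute_force_mrpp(d, labels):
    n = len(labels)

    def delta_of(lab):
        total = 0.0
        for g in set(lab):
            idx = [i for i, l in enumerate(lab) if l == g]
            if len(idx) > 1:
                pairs = [(i, j) for i in idx for j in idx if i < j]
                total += (len(idx) / n) * np.mean([d[i, j] for i, j in pairs])
        return total

    obs = delta_of(labels)
    arrangements = set(permutations(labels))
    count = sum(delta_of(lab) <= obs + 1e-12 for lab in arrangements)
    return obs, count / len(arrangements)


class TestAdonis:
    def test_exhaustive_p_matches_brute_force_oracle(self, toy_six):
        dist, grouping, _ = toy_six
        res = ag.adonis(dist, grouping, n_perm="exact")
        labels = tuple(grouping[s] for s in dist.sample_ids)
        f_oracle, p_oracle = _brute_force_permanova(dist.values, labels)
        assert res.statistic == pytest.approx(f_oracle, rel=1e-12)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)
        assert res.n_permutations == 20

    def test_fully_separated_identical_points(self):
        # two clusters of identical points: all variance is between groups
        dist = _dist_from_points([0, 0, 0, 5, 5, 5])
        res = ag.adonis(dist, _two_groups(3, 3), n_perm="exact")
        assert res.effect_r2 == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 10)  # 2 of 20 arrangements tie at F=inf

    def test_equals_classical_anova_f_on_euclidean_1d(self):
        pts = np.array([1.0, 2.0, 1.5, 4.0, 5.0, 4.5, 5.5])
        grouping = _two_groups(3, 4)
        res = ag.adonis(_dist_from_points(pts), grouping, n_perm=99, seed=0)
        f_anova = stats.f_oneway(pts[:3], pts[3:]).statistic
        assert res.statistic == pytest.approx(f_anova, rel=1e-10)

    def test_matches_scikit_bio(self, toy_six):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova

        dist, grouping, _ = toy_six
        dm = skbio.DistanceMatrix(dist.values, ids=dist.sample_ids)
        ref = permanova(dm, [grouping[s] for s in dist.sample_ids], permutations=99)
        assert ag.adonis(dist, grouping, n_perm=99, seed=0).statistic == \
            pytest.approx(ref["test statistic"], rel=1e-10)

    def test_invariant_to_sample_reordering(self, toy_six):
        dist, grouping, pts = toy_six
        order = [4, 2, 0, 5, 1, 3]
        shuffled = DistanceMatrix([dist.sample_ids[i] for i in order],
                                  dist.values[np.ix_(order, order)])
        a = ag.adonis(dist, grouping, n_perm="exact")
        b = ag.adonis(shuffled, grouping, n_perm="exact")
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)
        assert a.p_value == b.p_value

    def test_single_group_rejected(self, toy_six):
        dist, _, _ = toy_six
        with pytest.raises(ValueError, match="2 groups"):
            ag.adonis(dist, {s: "A" for s in dist.sample_ids}, n_perm=9)

    def test_type_one_error_is_nominal(self):
        # random labels on random distances: P(p <= 0.05) must be ~0.05;
        # 12 samples give enough distinct arrangements (924) that permutation
        # ties with the observed labeling are negligible
        rng = np.random.default_rng(99)
        rejections = 0
        n_trials = 1000
        grouping = _two_groups(6, 6)
        for _ in range(n_trials):
            pts = rng.normal(size=12)
            dist = _dist_from_points(pts)
            res = ag.adonis(dist, grouping, n_perm=99,
                            seed=int(rng.integers(2**31)))
            rejections += res.p_value <= 0.05
        assert abs(rejections / n_trials - 0.05) < 0.015


class TestAnosim:
    def test_perfect_separation_gives_r_one(self):
        dist = _dist_from_points([0.0, 0.1, 0.2, 10.0, 10.1, 10.2])
        res = ag.anosim(dist, _two_groups(3, 3), n_perm=99, seed=1)
        assert res.statistic == pytest.approx(1.0)
        # permutations recreating the same split (prob 2/20) tie at R = 1
        assert res.p_value < 0.25

    def test_five_sample_hand_rank_case(self):
        # distances small within A={s0,s1} and B={s2,s3,s4}, large between;
        # R computed from an independently hand-built rank table
        pts = [0.0, 1.0, 10.0, 11.0, 12.0]
        dist = _dist_from_points(pts)
        grouping = _two_groups(2, 3)
        d = dist.values
        iu = np.triu_indices(5, k=1)
        ranks = stats.rankdata(d[iu])
        same = np.array([grouping[f"s{i}"] == grouping[f"s{j}"]
                         for i, j in zip(*iu)])
        r_expected = (ranks[~same].mean() - ranks[same].mean()) / (10 / 2)
        res = ag.anosim(dist, grouping, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(r_expected, abs=1e-12)

    def test_matches_scikit_bio(self, toy_six):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import anosim as sk_anosim

        dist, grouping, _ = toy_six
        dm = skbio.DistanceMatrix(dist.values, ids=dist.sample_ids)
        ref = sk_anosim(dm, [grouping[s] for s in dist.sample_ids], permutations=99)
        res = ag.anosim(dist, grouping, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_null_symmetry_mean_r_near_zero(self):
        rng = np.random.default_rng(7)
        rs = []
        for _ in range(200):
            dist = _dist_from_points(rng.normal(size=8))
            rs.append(ag.anosim(dist, _two_groups(4, 4), n_perm=1, seed=0).statistic)
        assert abs(np.mean(rs)) < 0.05


class TestMrpp:
    def test_identical_points_give_zero_delta(self):
        dist = _dist_from_points([2.0, 2.0, 2.0, 2.0])
        res = ag.mrpp(dist, _two_groups(2, 2), n_perm=9, seed=0)
        assert res.statistic == 0.0

    def test_constant_distances_give_delta_d(self):
        d = np.full((5, 5), 0.7)
        np.fill_diagonal(d, 0.0)
        dist = DistanceMatrix([f"s{i}" for i in range(5)], d)
        res = ag.mrpp(dist, _two_groups(2, 3), n_perm=9, seed=0)
        assert res.statistic == pytest.approx(0.7)

    def test_exhaustive_p_matches_brute_force_oracle(self, toy_six):
        dist, grouping, _ = toy_six
        res = ag.mrpp(dist, grouping, n_perm="exact")
        labels = tuple(grouping[s] for s in dist.sample_ids)
        delta_oracle, p_oracle = _brute_force_mrpp(dist.values, labels)
        assert res.statistic == pytest.approx(delta_oracle, rel=1e-12)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)


class TestMantel:
    def test_self_correlation_is_one(self, toy_six):
        dist, _, _ = toy_six
        assert ag.mantel(dist, dist, n_perm=99, seed=0).statistic == pytest.approx(1.0)

    def test_affine_invariance_pearson(self, toy_six):
        dist, _, _ = toy_six
        scaled = DistanceMatrix(dist.sample_ids, 3.0 * dist.values)
        res = ag.mantel(dist, scaled, method="pearson", n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_dimension_mismatch_rejected(self, toy_six):
        dist, _, _ = toy_six
        other = _dist_from_points([0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="sample ids"):
            ag.mantel(dist, other)

    def test_type_one_error_is_nominal(self):
        rng = np.random.default_rng(13)
        rejections = 0
        n_trials = 1000
        for _ in range(n_trials):
            a = _dist_from_points(rng.normal(size=8))
            b = _dist_from_points(rng.normal(size=8))
            res = ag.mantel(a, b, method="pearson", n_perm=99,
                            seed=int(rng.integers(2**31)))
            rejections += res.p_value <= 0.05
        assert abs(rejections / n_trials - 0.05) < 0.015


class TestPcoa:
    def test_reconstructs_1d_configuration(self):
        dist = _dist_from_points([0.0, 1.0, 3.0])
        res = ag.pcoa(dist)
        coords = res.coordinates
        rec = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        np.testing.assert_allclose(rec, dist.values, atol=1e-9)

    def test_equilateral_distances_give_two_equal_eigenvalues(self):
        d = np.full((3, 3), 1.0)
        np.fill_diagonal(d, 0.0)
        res = ag.pcoa(DistanceMatrix(["a", "b", "c"], d))
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert pos.size == 2
        assert pos[0] == pytest.approx(pos[1], rel=1e-9)

    def test_zero_distances_give_zero_spectrum(self):
        res = ag.pcoa(DistanceMatrix(["a", "b", "c"], np.zeros((3, 3))))
        np.testing.assert_allclose(res.eigenvalues, 0.0, atol=1e-12)
        assert res.coordinates.shape[1] == 0

    def test_eigenvalues_non_increasing_and_proportions(self, toy_six):
        dist, _, _ = toy_six
        res = ag.pcoa(dist)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        assert res.proportion_explained.sum() == pytest.approx(1.0)

    def test_matches_scikit_bio_coordinates(self, toy_six):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa as sk_pcoa

        dist, _, _ = toy_six
        ref = sk_pcoa(skbio.DistanceMatrix(dist.values, ids=dist.sample_ids),
                      number_of_dimensions=2)
        res = ag.pcoa(dist)
        np.testing.assert_allclose(np.abs(res.coordinates[:, 0]),
                                   np.abs(ref.samples.values[:, 0]), atol=1e-8)


class TestWilcoxon:
    def test_exact_enumeration_small_samples(self):
        # C(6,3)=20 arrangements; [1,2,3] vs [4,5,6] is the most extreme
        w, p = ag.wilcoxon([1, 2, 3], [4, 5, 6])
        assert w == 6.0  # minimal rank sum
        assert p == pytest.approx(2 / 20)

    def test_identical_samples_give_p_one(self):
        _, p = ag.wilcoxon([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_power_on_shifted_normals(self):
        rng = np.random.default_rng(21)
        x = rng.normal(0, 1, 200)
        y = rng.normal(1, 1, 200)
        _, p = ag.wilcoxon(x, y)
        assert p < 1e-10

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            ag.wilcoxon([], [1.0])


class TestAbundanceOccupancy:
    def test_perfect_log_linear_relationship(self):
        # occupancy k OTUs with mean abundance 10^k lie exactly on a line
        n_samples = 5
        rows, occs = [], []
        for k in range(1, n_samples + 1):
            mean = 10.0**k
            row = np.zeros(n_samples)
            row[:k] = mean * n_samples / k
            rows.append(row)
            occs.append(k)
        t = ag.OTUTable([f"o{k}" for k in occs], [f"s{j}" for j in range(n_samples)],
                        np.array(rows, dtype=np.int64))
        fit = ag.abundance_occupancy(t)
        # integer truncation of the planted counts perturbs the fit slightly
        assert fit.r_squared == pytest.approx(1.0, abs=1e-6)
        assert fit.slope == pytest.approx(1.0, abs=1e-3)

    def test_neutral_synthetic_table_is_strongly_positive(self):
        scen = ag.SyntheticScenario(n_otus=500, n_samples=13, reads_per_sample=7000, seed=10)
        fit = ag.abundance_occupancy(ag.simulate_metacommunity(scen))
        assert fit.slope > 0
        assert fit.r_squared > 0.5

    def test_shuffled_abundances_have_no_relationship(self):
        # break the coupling: occupancy patterns from one OTU, totals from
        # another; R^2 should average near zero
        rng = np.random.default_rng(12)
        r2 = []
        for _ in range(100):
            occ = rng.integers(1, 14, size=60)
            means = 10 ** rng.uniform(0, 3, size=60)
            rows = np.zeros((60, 13), dtype=np.int64)
            for i, (k, m) in enumerate(zip(occ, means)):
                cols = rng.choice(13, size=k, replace=False)
                rows[i, cols] = max(1, round(m * 13 / k))
            t = ag.OTUTable([f"o{i}" for i in range(60)],
                            [f"s{j}" for j in range(13)], rows)
            r2.append(ag.abundance_occupancy(t).r_squared)
        assert np.mean(r2) < 0.05

    def test_uniform_occupancy_rejected(self):
        t = ag.OTUTable(["a", "b", "c"], ["s1", "s2"],
                        np.array([[1, 1], [2, 2], [3, 3]]))
        with pytest.raises(ValueError, match="occupancy"):
            ag.abundance_occupancy(t)


class TestTaxonComposition:
    @pytest.fixture
    def taxed_table(self):
        counts = np.array([[500], [300], [199], [1]])
        return ag.OTUTable(
            ["a", "b", "c", "d"], ["s1"], counts,
            taxonomy={
                "a": ["Bacteria", "Proteobacteria"],
                "b": ["Bacteria", "Actinobacteria"],
                "c": ["Bacteria", "Chloroflexi"],
                "d": ["Bacteria", "Verrucomicrobia"],
            },
        )

    def test_group_fractions_sum_to_one(self, taxed_table):
        labels = {o: "core" for o in taxed_table.otu_ids}
        comp = ag.taxon_composition(taxed_table, labels, rank=1)
        assert sum(comp["core"].values()) == pytest.approx(1.0, abs=1e-9)

    def test_rare_taxa_collapse_into_other(self, taxed_table):
        labels = {o: "core" for o in taxed_table.otu_ids}
        comp = ag.taxon_composition(taxed_table, labels, rank=1)
        assert "Verrucomicrobia" not in comp["core"]  # 0.1% < 0.5%
        assert comp["core"]["Other"] == pytest.approx(0.001)

    def test_taxon_exactly_at_threshold_is_retained(self):
        counts = np.array([[995], [5]])  # second taxon exactly 0.5%
        t = ag.OTUTable(["a", "b"], ["s1"], counts,
                        taxonomy={"a": ["Bacteria", "X"], "b": ["Bacteria", "Y"]})
        comp = ag.taxon_composition(t, {"a": "core", "b": "core"}, rank=1)
        assert "Y" in comp["core"]

    def test_single_taxon_is_everything(self):
        t = ag.OTUTable(["a"], ["s1", "s2"], np.array([[3, 4]]),
                        taxonomy={"a": ["Bacteria", "Nitrospirae"]})
        comp = ag.taxon_composition(t, {"a": "satellite"}, rank=1)
        assert comp["satellite"] == {"Nitrospirae": 1.0}

    def test_missing_taxonomy_rejected(self, tiny_table):
        tiny_table.taxonomy = None
        with pytest.raises(ValueError, match="taxonomy"):
            ag.taxon_composition(tiny_table, {"OTU_1": "core"})
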