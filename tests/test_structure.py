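"""FST, PCoA, bitwise distances, RDA outlier scan and locus partitioning."""

import numpy as np
import pytest
from scipy import stats as sps

from kelppopgen import (
    MISSING,
    bitwise_distance,
    pairwise_fst,
    partition_loci,
    pcoa,
    rda_scan,
    wc_theta,
)

from conftest import make_gm


def wc_theta_literal(calls_a, calls_b):
    """Independent Weir & Cockerham (1984) reference: explicit per-locus loops
    over genotype counts, r = 2 populations, ratio-of-sums combination."""
    a_sum = t_sum = 0.0
    for locus in range(calls_a.shape[1]):
        groups = []
        for calls in (calls_a, calls_b):
            col = [c for c in calls[:, locus] if c != MISSING]
            if len(col) < 2:
                break
            n = len(col)
            p = sum(col) / (2 * n)
            h = sum(1 for c in col if c == 1) / n
            groups.append((n, p, h))
        if len(groups) < 2:
            continue
        (n1, p1, h1), (n2, p2, h2) = groups
        r = 2
        nbar = (n1 + n2) / r
        nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 / 2 - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        a_sum += a
        t_sum += a + b + c
    return a_sum / t_sum


class TestWcTheta:
    def test_fixed_difference_is_one(self):
        gm = make_gm(
            np.array([[0, 0], [0, 0], [2, 2], [2, 2]], dtype=np.int8),
            populations=["warm", "warm", "cool", "cool"],
        )
        comp = wc_theta(gm, gm.select_individuals(population="warm"),
                        gm.select_individuals(population="cool"))
        assert comp.theta == pytest.approx(1.0)

    def test_null_two_thousand_loci_near_zero(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.95, 2000)
        calls = rng.binomial(2, np.broadcast_to(p, (200, 2000))).astype(np.int8)
        gm = make_gm(calls, populations=["warm"] * 100 + ["cool"] * 100)
        comp = wc_theta(gm, gm.select_individuals(population="warm"),
                        gm.select_individuals(population="cool"))
        assert abs(comp.theta) < 0.01

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_literal_reference_implementation(self, seed):
        rng = np.random.default_rng(seed)
        calls = rng.choice([0, 1, 2, MISSING], size=(8, 2), p=[0.35, 0.3, 0.3, 0.05])
        gm = make_gm(calls, populations=["warm"] * 4 + ["cool"] * 4)
        try:
            comp = wc_theta(gm, gm.select_individuals(population="warm"),
                            gm.select_individuals(population="cool"))
        except ValueError:
            pytest.skip("degenerate draw: too few valid calls")
        expected = wc_theta_literal(calls[:4], calls[4:])
        assert comp.theta == pytest.approx(expected, abs=1e-10)

    def test_invariance_to_relabelling_and_group_order(self):
        rng = np.random.default_rng(1)
        calls = rng.choice([0, 1, 2], size=(20, 50))
        gm = make_gm(calls, populations=["warm"] * 10 + ["cool"] * 10)
        w = gm.select_individuals(population="warm")
        c = gm.select_individuals(population="cool")
        theta = wc_theta(gm, w, c).theta
        assert wc_theta(gm, c, w).theta == pytest.approx(theta, abs=1e-12)
        gm_flip = make_gm((2 - calls).astype(np.int8),
                          populations=["warm"] * 10 + ["cool"] * 10)
        assert wc_theta(gm_flip, w, c).theta == pytest.approx(theta, abs=1e-12)

    def test_ratio_of_sums_on_replicated_locus(self):
        rng = np.random.default_rng(2)
        col = rng.choice([0, 1, 2], size=(20, 1))
        gm1 = make_gm(col, populations=["warm"] * 10 + ["cool"] * 10)
        gm5 = make_gm(np.tile(col, (1, 5)), populations=["warm"] * 10 + ["cool"] * 10)
        w = gm1.select_individuals(population="warm")
        c = gm1.select_individuals(population="cool")
        assert wc_theta(gm5, w, c).theta == pytest.approx(
            wc_theta(gm1, w, c).theta, abs=1e-12
        )


class TestPairwiseFst:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(3)
        half = rng.choice([0, 1, 2], size=(30, 100))
        calls = np.vstack([half, half])
        gm = make_gm(calls, populations=["warm"] * 30 + ["cool"] * 30)
        (res,) = pairwise_fst(gm, "population", n_boot=199, seed=0)
        assert res.p_value > 0.05
        assert res.p_adjusted >= res.p_value

    def test_fixed_difference_bootstrap_distribution(self):
        gm = make_gm(
            np.array([[0] * 5, [0] * 5, [2] * 5, [2] * 5], dtype=np.int8),
            populations=["warm", "warm", "cool", "cool"],
        )
        (res,) = pairwise_fst(gm, "population", n_boot=199, seed=0)
        assert res.theta == pytest.approx(1.0)
        assert res.ci_low == pytest.approx(1.0)  # every bootstrap theta = 1
        assert res.p_value == pytest.approx(1 / 200)

    def test_three_groups_bh_monotonic(self):
        rng = np.random.default_rng(4)
        p = np.stack([rng.uniform(0.2, 0.8, 80) for _ in range(3)])
        p[1] = np.clip(p[0] + 0.2, 0, 1)
        calls = np.vstack(
            [rng.binomial(2, np.broadcast_to(pi, (15, 80))) for pi in p]
        ).astype(np.int8)
        pops = ["warm"] * 15 + ["cool"] * 30
        gm = make_gm(calls, populations=pops, cohorts=["wild"] * 15 + ["wild"] * 15 + ["hatchery"] * 15)
        keys = gm.individuals[["population", "cohort"]].agg("/".join, axis=1)
        grouping = {k: (keys == k).to_numpy() for k in keys.unique()}
        results = pairwise_fst(gm, grouping, n_boot=99, seed=0)
        assert len(results) == 3
        by_p = sorted(results, key=lambda r: r.p_value)
        adj = [r.p_adjusted for r in by_p]
        assert all(a <= b + 1e-12 for a, b in zip(adj, adj[1:]))


class TestBitwiseDistance:
    def test_reference_values(self):
        calls = np.array([[0, 1, 2], [0, 1, 2], [2, 1, 0]], dtype=np.int8)
        d = bitwise_distance(make_gm(calls))
        assert d[0, 1] == pytest.approx(0.0)
        assert d[0, 2] == pytest.approx(2 / 3)

    def test_opposite_homozygotes_are_maximal(self):
        calls = np.vstack([np.zeros(10), np.full(10, 2)]).astype(np.int8)
        d = bitwise_distance(make_gm(calls))
        assert d[0, 1] == pytest.approx(1.0)

    def test_all_missing_individual_named(self):
        calls = np.array([[0, 1], [MISSING, MISSING]], dtype=np.int8)
        with pytest.raises(ValueError, match="ind001"):
            bitwise_distance(make_gm(calls))

    def test_missing_handled_pairwise(self):
        calls = np.array([[0, 1, MISSING], [2, 1, 0]], dtype=np.int8)
        d = bitwise_distance(make_gm(calls))
        assert d[0, 1] == pytest.approx((2 + 0) / (2 * 2))


class TestPcoa:
    def test_three_collinear_points(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        res = pcoa(d)
        axis1 = np.sort(res.coordinates[:, 0])
        gaps = np.diff(axis1)
        np.testing.assert_allclose(gaps, [1.0, 1.0], atol=1e-8)

    def test_zero_distances_give_zero_coordinates(self):
        res = pcoa(np.zeros((4, 4)))
        assert res.coordinates.shape[1] == 0 or np.allclose(res.coordinates, 0)

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(12, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = pcoa(d)
        x = res.coordinates[:, :2]
        # Procrustes alignment: centred configurations match up to rotation
        a = pts - pts.mean(0)
        u, _, vt = np.linalg.svd(x.T @ a)
        rot = u @ vt
        assert np.sqrt(((x @ rot - a) ** 2).mean()) < 1e-8

    def test_matches_pca_eigenvalues_on_euclidean_data(self):
        rng = np.random.default_rng(6)
        data = rng.normal(size=(15, 4))
        d = np.linalg.norm(data[:, None] - data[None, :], axis=-1)
        res = pcoa(d)
        centred = data - data.mean(0)
        pca_eig = np.sort(np.linalg.eigvalsh(centred @ centred.T))[::-1][:4]
        np.testing.assert_allclose(res.eigenvalues[:4], pca_eig, atol=1e-8)

    def test_matches_skbio_reference(self):
        skbio_pcoa = pytest.importorskip("skbio.stats.ordination").pcoa
        from skbio import DistanceMatrix

        rng = np.random.default_rng(7)
        pts = rng.normal(size=(10, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ours = pcoa(d)
        ref = skbio_pcoa(DistanceMatrix(d))
        np.testing.assert_allclose(
            np.abs(ours.coordinates[:, :3]),
            np.abs(ref.samples.to_numpy()[:, :3]),
            atol=1e-6,
        )

    def test_asymmetric_input_rejected(self):
        d = np.array([[0, 1], [2, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(d)


class TestRdaScan:
    @staticmethod
    def null_matrix(rng, n=100, n_loci=500):
        p = rng.uniform(0.1, 0.9, n_loci)
        return rng.binomial(2, np.broadcast_to(p, (n, n_loci))).astype(np.int8)

    def test_planted_locus_flagged(self):
        rng = np.random.default_rng(0)
        calls = self.null_matrix(rng)
        predictor = np.repeat(["wild", "hatchery"], 50)
        calls[:, 0] = np.where(predictor == "wild", 0, 2)  # perfect association
        gm = make_gm(calls, cohorts=predictor)
        res = rda_scan(gm, "cohort")
        assert res.outlier[0]
        assert abs(res.z_scores[0]) == np.abs(res.z_scores).max()

    def test_permuted_predictor_unflags_planted_locus(self):
        rng = np.random.default_rng(1)
        calls = self.null_matrix(rng)
        predictor = np.repeat(["wild", "hatchery"], 50)
        calls[:, 0] = np.where(predictor == "wild", 0, 2)
        gm = make_gm(calls, cohorts=predictor)
        permuted = rng.permutation(predictor)
        res = rda_scan(gm, permuted)
        assert not res.outlier[0]
        # null outlier count stays near loci x 2*Phi(-3)
        expect = 500 * 2 * sps.norm.cdf(-3)
        assert res.outlier.sum() <= expect + 3 * np.sqrt(expect) + 1

    def test_loading_rank_matches_point_biserial_when_scaled(self):
        rng = np.random.default_rng(2)
        calls = self.null_matrix(rng, n=80, n_loci=60)
        predictor = np.repeat(["wild", "hatchery"], 40)
        gm = make_gm(calls, cohorts=predictor)
        res = rda_scan(gm, "cohort", scale=True)
        dummy = (predictor == "hatchery").astype(float)
        pb = np.array(
            [abs(np.corrcoef(calls[:, j], dummy)[0, 1]) for j in range(60)]
        )
        # loadings are proportional to |point-biserial r|, hence same ranking
        np.testing.assert_allclose(
            np.abs(res.loadings) / np.abs(res.loadings).max(), pb / pb.max(),
            atol=1e-9,
        )

    def test_constant_predictor_rejected(self):
        gm = make_gm(self.null_matrix(np.random.default_rng(3), n=10, n_loci=5))
        with pytest.raises(ValueError, match="binary"):
            rda_scan(gm, "cohort")  # all wild

    def test_variance_explained_in_unit_interval(self):
        rng = np.random.default_rng(4)
        gm = make_gm(self.null_matrix(rng), cohorts=np.repeat(["wild", "hatchery"], 50))
        res = rda_scan(gm, "cohort")
        assert 0 <= res.variance_explained <= 1


class TestPartition:
    def test_no_outliers_means_all_neutral(self):
        rng = np.random.default_rng(5)
        calls = TestRdaScan.null_matrix(rng, n=60, n_loci=40)
        gm = make_gm(calls, cohorts=np.repeat(["wild", "hatchery"], 30),
                     populations=np.tile(np.repeat(["warm", "cool"], 15), 2))
        a = rda_scan(gm, "population", sd_threshold=50.0)
        b = rda_scan(gm, "cohort", sd_threshold=50.0)
        part = partition_loci(a, b)
        assert len(part.neutral) == 40
        assert not part.provenance and not part.hatchery

    def test_overlap_recorded_and_excluded_from_neutral(self):
        rng = np.random.default_rng(6)
        calls = TestRdaScan.null_matrix(rng, n=60, n_loci=40)
        pops = np.tile(np.repeat(["warm", "cool"], 15), 2)
        cohorts = np.repeat(["wild", "hatchery"], 30)
        # locus 0 perfectly tracks both predictors' first halves
        calls[:, 0] = np.where(pops == "warm", 0, 2)
        calls[:, 1] = np.where(cohorts == "wild", 0, 2)
        gm = make_gm(calls, populations=pops, cohorts=cohorts)
        a = rda_scan(gm, "population")
        b = rda_scan(gm, "cohort")
        part = partition_loci(a, b)
        ids = gm.locus_ids
        assert ids[0] in part.provenance
        assert ids[1] in part.hatchery
        assert set(part.overlap) == set(part.provenance) & set(part.hatchery)
        assert not (set(part.neutral) & (set(part.provenance) | set(part.hatchery)))
        assert len(set(part.neutral) | set(part.provenance) | set(part.hatchery)) == 40

    def test_mismatched_loci_rejected(self):
        rng = np.random.default_rng(7)
        calls = TestRdaScan.null_matrix(rng, n=20, n_loci=10)
        gm = make_gm(calls, cohorts=np.repeat(["wild", "hatchery"], 10))
        a = rda_scan(gm, "cohort")
        b = rda_scan(gm.take_loci(np.arange(5)), "cohort")
        with pytest.raises(ValueError, match="different loci"):
            partition_loci(a, b)
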