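"""Forward breeding simulator: Mendelian transmission, drift decay, sweep."""

import numpy as np
import pytest
from scipy import stats as sps

from kelppopgen import (
    SimulationConfig,
    assign_sexes,
    donor_sweep,
    expected_he_decay,
    mate_randomly,
    simulate_generations,
)
from kelppopgen.simulate import impute_missing
from kelppopgen.genotypes import MISSING

from conftest import make_gm


class TestAssignSexes:
    @pytest.mark.parametrize("n, n_dams, n_sires", [(4, 2, 2), (5, 3, 2), (2, 1, 1)])
    def test_split_counts(self, n, n_dams, n_sires):
        dams, sires = assign_sexes(n, np.random.default_rng(0))
        assert len(dams) == n_dams and len(sires) == n_sires
        assert sorted(np.concatenate([dams, sires])) == list(range(n))

    def test_seeded_determinism(self):
        a = assign_sexes(9, np.random.default_rng(7))
        b = assign_sexes(9, np.random.default_rng(7))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_rejects_single_parent(self):
        with pytest.raises(ValueError):
            assign_sexes(1, np.random.default_rng(0))


class TestMateRandomly:
    def test_fixation_persists(self):
        dams = np.zeros((3, 10), dtype=np.int8)
        sires = np.zeros((3, 10), dtype=np.int8)
        off = mate_randomly(dams, sires, 50, np.random.default_rng(0))
        assert (off == 0).all()

    def test_het_cross_gives_mendelian_ratios(self):
        dams = np.ones((1, 1), dtype=np.int8)
        sires = np.ones((1, 1), dtype=np.int8)
        off = mate_randomly(dams, sires, 10000, np.random.default_rng(1)).ravel()
        counts = np.bincount(off, minlength=3)
        _, p = sps.chisquare(counts, 10000 * np.array([0.25, 0.5, 0.25]))
        assert p > 0.001

    def test_transmission_unbiased(self):
        rng = np.random.default_rng(2)
        parents = rng.binomial(2, 0.4, size=(20, 50)).astype(np.int8)
        dams, sires = parents[:10], parents[10:]
        off = mate_randomly(dams, sires, 1000, np.random.default_rng(3))
        p_par = (dams.mean(0) + sires.mean(0)) / 4.0
        p_off = off.mean(0) / 2.0
        se = np.sqrt(p_par * (1 - p_par) / (2 * 1000))
        assert np.mean(np.abs(p_off - p_par) <= 3 * se) > 0.9


class TestImputation:
    def test_fills_from_pool_frequency(self):
        calls = np.array([[2, MISSING], [2, 0], [2, 0]], dtype=np.int8)
        out = impute_missing(calls, np.random.default_rng(0))
        assert (out != MISSING).all()
        assert out[0, 1] == 0  # pool frequency is 0 at locus 1
        assert (out[:, 0] == 2).all()


class TestSimulateGenerations:
    def test_monomorphic_pool_stays_empty(self):
        donors = np.full((4, 20), 2, dtype=np.int8)
        out = simulate_generations(donors, 100, 10, [1, 5, 10],
                                   np.random.default_rng(0))
        assert all(rec["he"] == 0 and rec["pl"] == 0 for rec in out.values())

    def test_fixed_locus_never_repolymorphises(self):
        rng = np.random.default_rng(1)
        donors = rng.binomial(2, 0.5, size=(10, 30)).astype(np.int8)
        donors[:, 0] = 0
        out = simulate_generations(donors, 200, 20, [20], rng,
                                   keep_genotypes=True)
        assert (out[20]["dosages"][:, 0] == 0).all()

    def test_checkpoint_beyond_horizon_rejected(self):
        donors = np.zeros((4, 5), dtype=np.int8)
        with pytest.raises(ValueError, match="horizon"):
            simulate_generations(donors, 10, 5, [6], np.random.default_rng(0))

    @staticmethod
    def _he(pool):
        p = pool.mean(0) / 2.0
        return np.mean(2 * p * (1 - p))

    def _decay_ratio(self, n, t, reps, seed, sexed):
        """Mean He_t / He_0 over replicate constant-size closed lines,
        aggregated as a ratio of means (mean-of-ratios is Jensen-biased for
        tiny pools); returns (ratio, jackknife SE)."""
        pairs = []
        for ss in np.random.SeedSequence(seed).spawn(reps):
            rng = np.random.default_rng(ss)
            p0 = rng.uniform(0.2, 0.5, 100)
            pool = rng.binomial(2, np.broadcast_to(p0, (n, 100))).astype(np.int8)
            he0 = self._he(pool)
            if sexed:
                out = simulate_generations(pool, n, t, [t], rng,
                                           keep_genotypes=True)
                pool = out[t]["dosages"]
            else:
                for _ in range(t):  # monoecious: both gametes from one pool
                    pool = mate_randomly(pool, pool, n, rng)
            pairs.append((self._he(pool), he0))
        pairs = np.asarray(pairs)
        ratio = pairs[:, 0].sum() / pairs[:, 1].sum()
        leave = (pairs[:, 0].sum() - pairs[:, 0]) / (pairs[:, 1].sum() - pairs[:, 1])
        se = np.sqrt((reps - 1) / reps * ((leave - leave.mean()) ** 2).sum())
        return ratio, se

    @pytest.mark.parametrize("n, t", [(2, 1), (2, 5), (10, 1), (10, 5)])
    def test_monoecious_decay_tracks_closed_form(self, n, t):
        """Constant-size monoecious WF lines follow He0 (1 - 1/(2Ne))^t
        exactly; this isolates Mendelian-transmission drift from the
        separate-sex correction."""
        ratio, se = self._decay_ratio(n, t, reps=100, seed=1234 + n * 10 + t,
                                      sexed=False)
        expected = expected_he_decay(1.0, n // 2, n // 2, t)  # Ne = n
        assert ratio == pytest.approx(expected, abs=3 * se + 0.005)

    @pytest.mark.parametrize(
        "n, expected",
        [(2, 5 / 6), (10, 0.905 / 0.95)],
        ids=["sib-line", "ten-parents"],
    )
    def test_sexed_scheme_first_generation_exact(self, n, expected):
        """Separate sexes without selfing lose less heterozygosity in the
        first generation than 1 - 1/(2Ne): the exact expectation is
        [(1 - 1/(2N)) - (2 - 1/(2Nd) - 1/(2Ns))/(2N)] / (1 - 1/(2N))."""
        ratio, se = self._decay_ratio(n, 1, reps=150, seed=431 + n, sexed=True)
        assert ratio == pytest.approx(expected, abs=3 * se + 0.005)

    def test_large_offspring_cohorts_decay_at_census_rate(self):
        """With 500 offspring per generation the per-generation 2pq loss is
        ~1/(2*500) for any donor count: the founder bottleneck enters
        through donor sampling (He0), not through later frequency drift."""
        n_off, n_loci, reps, t = 500, 100, 60, 5
        ratios = []
        root = np.random.SeedSequence(99)
        for ss in root.spawn(reps):
            rng = np.random.default_rng(ss)
            p0 = rng.uniform(0.2, 0.5, n_loci)
            donors = rng.binomial(2, np.broadcast_to(p0, (4, n_loci))).astype(np.int8)
            he0 = np.mean(2 * donors.mean(0) / 2 * (1 - donors.mean(0) / 2))
            out = simulate_generations(donors, n_off, t, [t], rng)
            ratios.append(out[t]["he"] / he0)
        expected = (1 - 1 / (2 * n_off)) ** t
        se = np.std(ratios, ddof=1) / np.sqrt(reps)
        assert np.mean(ratios) == pytest.approx(expected, abs=3 * se + 0.005)

    def test_allele_frequency_martingale(self):
        # mean frequency at t = 10 stays at its initial value (200 replicates)
        reps, n_loci = 200, 40
        p0 = np.linspace(0.1, 0.9, n_loci)
        finals = []
        root = np.random.SeedSequence(77)
        for ss in root.spawn(reps):
            rng = np.random.default_rng(ss)
            donors = rng.binomial(2, np.broadcast_to(p0, (20, n_loci))).astype(np.int8)
            out = simulate_generations(donors, 100, 10, [10], rng,
                                       keep_genotypes=True)
            finals.append(out[10]["dosages"].mean(0) / 2.0)
        finals = np.asarray(finals)
        se = finals.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.mean(np.abs(finals.mean(0) - p0) <= 3 * se) > 0.9


class TestExpectedHeDecay:
    def test_identity_at_t_zero(self):
        assert expected_he_decay(0.3, 5, 5, 0) == pytest.approx(0.3)

    def test_single_pair_one_generation(self):
        # Ne = 2 for one dam x one sire: factor 1 - 1/4
        assert expected_he_decay(0.4, 1, 1, 1) == pytest.approx(0.3)

    def test_infinite_ne_limit(self):
        assert expected_he_decay(0.25, 10**6, 10**6, 50) == pytest.approx(0.25, rel=1e-4)

    def test_rejects_zero_parents(self):
        with pytest.raises(ValueError):
            expected_he_decay(0.3, 0, 1, 1)


class TestDonorSweep:
    @staticmethod
    def pool(seed=0, n=60, n_loci=120):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.05, 0.5, n_loci)
        return rng.binomial(2, np.broadcast_to(p, (n, n_loci))).astype(np.int8)

    @pytest.fixture(scope="class")
    def sweep(self):
        cfg = SimulationConfig(donor_counts=(2, 4, 10, 20, 60), n_offspring=100,
                               generations=40, checkpoints=(1, 3, 40), n_boot=30,
                               seed=5)
        return donor_sweep(self.pool(), cfg)

    def test_f1_he_nondecreasing_in_donor_count(self, sweep):
        he = sweep.table.query("metric == 'He' and checkpoint == 1").sort_values(
            "donor_count"
        )
        diffs = np.diff(he["mean"].to_numpy())
        slack = 2 * np.sqrt(he["se"].to_numpy()[1:] ** 2 + he["se"].to_numpy()[:-1] ** 2)
        assert (diffs >= -slack).all()

    def test_drift_erodes_polymorphism_by_final_generation(self, sweep):
        t = sweep.table
        for n in t["donor_count"].unique():
            pl1 = t.query("metric=='PL' and checkpoint==1 and donor_count==@n")["mean"]
            pl_last = t.query(
                "metric=='PL' and checkpoint==40 and donor_count==@n"
            )["mean"]
            assert pl_last.item() < pl1.item()

    def test_full_pool_f1_matches_pool_he(self, sweep):
        pool = self.pool()
        p = pool.mean(0) / 2
        pool_he = np.mean(2 * p * (1 - p))
        f1 = sweep.table.query(
            "metric=='He' and checkpoint==1 and donor_count==60"
        )
        assert f1["mean"].item() == pytest.approx(pool_he, abs=5 * f1["se"].item() + 0.005)

    def test_determinism(self):
        cfg = SimulationConfig(donor_counts=(2, 6), n_offspring=50, generations=5,
                               checkpoints=(1, 5), n_boot=5, seed=9)
        a = donor_sweep(self.pool(), cfg)
        b = donor_sweep(self.pool(), cfg)
        assert a.table.equals(b.table)

    def test_donor_count_exceeding_pool_rejected(self):
        cfg = SimulationConfig(donor_counts=(2, 500), n_boot=1)
        with pytest.raises(ValueError, match="exceeds"):
            donor_sweep(self.pool(), cfg)
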