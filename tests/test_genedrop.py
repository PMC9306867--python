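import numpy as np
import pytest

from haplodrop import (
    GeneDropConfig,
    HaplotypeSet,
    drop_once,
    expected_frequency_trajectory,
    observed_standing_frequencies,
    run_genedrop,
    sample_offspring_haplotype,
)
from haplodrop.genedrop import DropEngine, cohort_frequencies

from conftest import make_pedigree
from _oracles import exact_drop_distribution

CFG = GeneDropConfig(founder_years=(1989, 1992), simulated_years=(1993, 1995), n_sim=10, seed=0)


class TestObservedFrequencies:
    def test_direct_count(self, toy_hs):
        ped = make_pedigree(
            [("x", None, None, None, 1990, 1995),
             ("y", None, None, None, 1990, 1995),
             ("z", None, None, None, 1990, 1995)]
        )
        dips = {"x": ("A", "A"), "y": ("A", "B"), "z": ("B", "B")}
        table = observed_standing_frequencies(ped, dips, [1993], toy_hs)
        assert table.freq[0, 0] == pytest.approx(0.5)
        assert table.freq[0, 1] == pytest.approx(0.5)
        assert table.n_individuals[0] == 3

    def test_single_homozygote(self, toy_hs):
        ped = make_pedigree([("x", None, None, None, 1990, 1995)])
        table = observed_standing_frequencies(ped, {"x": ("A", "A")}, [1993], toy_hs)
        assert table.freq[0, 0] == 1.0

    def test_empty_year_flagged_undefined(self, toy_hs):
        ped = make_pedigree([("x", None, None, None, 1990, 1991)])
        table = observed_standing_frequencies(ped, {"x": ("A", "A")}, [1994], toy_hs)
        assert not table.defined[0]
        assert np.isnan(table.freq[0]).all()


class TestConfig:
    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError, match="n_sim"):
            GeneDropConfig(n_sim=0)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="precede"):
            GeneDropConfig(founder_years=(1989, 1993), simulated_years=(1993, 2000))


class TestMendelianSampling:
    def test_homozygous_parent(self):
        rng = np.random.default_rng(0)
        assert all(
            sample_offspring_haplotype(("A", "A"), rng) == "A" for _ in range(50)
        )

    def test_heterozygous_parent_is_fair(self):
        rng = np.random.default_rng(1)
        n = 100_000
        draws = sum(sample_offspring_haplotype(("A", "B"), rng) == "A" for _ in range(n))
        se = np.sqrt(0.25 / n)
        assert abs(draws / n - 0.5) < 3 * se

    def test_sibling_draws_independent(self, three_generation, toy_hs):
        """Joint diplotype frequencies of two sibs factor into the marginals."""
        rows = [
            ("F1", None, None, "M", 1989, 1996),
            ("F2", None, None, "F", 1989, 1996),
            ("S1", "F1", "F2", "M", 1993, 1996),
            ("S2", "F1", "F2", "F", 1993, 1996),
        ]
        ped = make_pedigree(rows)
        observed = {"F1": ("A", "B"), "F2": ("C", "D")}
        engine = DropEngine(ped, observed, toy_hs, CFG)
        assigned = engine.run(20_000, seed=3)
        pos = {iid: k for k, iid in enumerate(engine.ids)}
        pairs1 = [tuple(sorted(row)) for row in assigned[:, pos["S1"], :]]
        pairs2 = [tuple(sorted(row)) for row in assigned[:, pos["S2"], :]]
        from collections import Counter

        joint = Counter(zip(pairs1, pairs2))
        m1, m2 = Counter(pairs1), Counter(pairs2)
        n = len(pairs1)
        from scipy import stats

        table = np.array(
            [[joint[(a, b)] for b in m2] for a in m1], dtype=float
        )
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.001  # no evidence against independence


class TestFounderAssignment:
    def test_observed_founders_kept_verbatim(self, three_generation, toy_hs):
        pedigree, observed = three_generation
        engine = DropEngine(pedigree, observed, toy_hs, CFG)
        assigned = engine.run(200, seed=1)
        pos = {iid: k for k, iid in enumerate(engine.ids)}
        for iid, pair in observed.items():
            codes = {toy_hs.index()[h] for h in pair}
            got = set(np.unique(assigned[:, pos[iid], :]))
            assert got == codes

    def test_degenerate_cohort_frequency(self, toy_hs):
        ped = make_pedigree(
            [("g", None, None, None, 1990, 1995),
             ("u", None, None, None, 1990, 1995)]
        )
        observed = {"g": ("A", "A")}
        engine = DropEngine(ped, observed, toy_hs, CFG)
        assigned = engine.run(100, seed=2)
        pos = {iid: k for k, iid in enumerate(engine.ids)}
        assert (assigned[:, pos["u"], :] == 0).all()  # only A available

    def test_half_known_parent_exact_enumeration(self, toy_hs):
        """Known sire (A,B) + unknown dam with cohort all-C: offspring is
        (A,C) or (B,C) with probability 1/2 each."""
        rows = [
            ("sire", None, None, "M", 1989, 1995),
            ("cc1", None, None, "F", 1990, 1995),
            ("x", "sire", None, None, 1990, 1995),
        ]
        individuals = [
            {"id": r[0], "sire": r[1], "dam": r[2], "birth": r[4]} for r in rows
        ]
        observed = {"sire": ("A", "B"), "cc1": ("C", "C")}
        exact = exact_drop_distribution(individuals, observed, 1992, toy_hs.names, "x")
        assert exact == {("A", "C"): pytest.approx(0.5), ("B", "C"): pytest.approx(0.5)}

        ped = make_pedigree(rows)
        engine = DropEngine(ped, observed, toy_hs, CFG)
        assigned = engine.run(10_000, seed=5)
        pos = {iid: k for k, iid in enumerate(engine.ids)}
        from collections import Counter

        pairs = Counter(tuple(sorted(toy_hs.names[c] for c in row))
                        for row in assigned[:, pos["x"], :])
        for pair, p in exact.items():
            se = np.sqrt(p * (1 - p) / 10_000)
            assert abs(pairs[pair] / 10_000 - p) < 3 * se


class TestDropOnce:
    def test_three_generation_enumeration(self, three_generation, toy_hs):
        pedigree, observed = three_generation
        engine = DropEngine(pedigree, observed, toy_hs, CFG)
        assigned = engine.run(10_000, seed=9)
        pos = {iid: k for k, iid in enumerate(engine.ids)}
        b = toy_hs.index()["B"]
        # child of (A,A) x (B,B) is always (A,B)
        child = assigned[:, pos["C1"], :]
        assert set(map(tuple, np.sort(child, axis=1))) == {(0, 1)}
        # grandchild B-dosage is 1 or 2 with probability 1/2 each
        gdose = (assigned[:, pos["G1"], :] == b).sum(axis=1)
        frac2 = (gdose == 2).mean()
        assert set(np.unique(gdose)) == {1, 2}
        assert abs(frac2 - 0.5) < 3 * np.sqrt(0.25 / 10_000)

    def test_founders_only_pedigree_reproduces_observed(self, toy_hs):
        ped = make_pedigree(
            [("a", None, None, None, 1990, 1995), ("b", None, None, None, 1991, 1995)]
        )
        observed = {"a": ("A", "B"), "b": ("C", "C")}
        assignment = drop_once(ped, observed, toy_hs, CFG, np.random.default_rng(0))
        assert assignment.pairs == observed
        assert set(assignment.flags.values()) == {"observed"}

    def test_post_founder_observed_never_copied(self, toy_hs):
        rows = [
            ("f1", None, None, "M", 1989, 1995),
            ("f2", None, None, "F", 1989, 1995),
            ("kid", "f1", "f2", None, 1994, 1995),
        ]
        ped = make_pedigree(rows)
        observed = {"f1": ("A", "A"), "f2": ("B", "B"), "kid": ("C", "C")}
        assignment = drop_once(ped, observed, toy_hs, CFG, np.random.default_rng(0))
        assert assignment.flags["kid"] == "mendelian"
        assert assignment.pairs["kid"] == ("A", "B")  # never the observed (C,C)

    def test_scalar_and_vectorised_paths_identical(self, neutral_population, eight_hap_hs):
        cfg_s, sim = neutral_population
        cfg = GeneDropConfig(n_sim=3, seed=123)
        engine = DropEngine(sim.pedigree, sim.diplotypes, eight_hap_hs, cfg)
        assigned = engine.run(3, seed=123)
        child0 = np.random.SeedSequence(123).spawn(3)[0]
        scalar = engine.drop_once(np.random.default_rng(child0))
        idx = eight_hap_hs.index()
        for k, iid in enumerate(engine.ids):
            assert tuple(idx[h] for h in scalar.pairs[iid]) == tuple(assigned[0, k, :])


class TestRunGeneDrop:
    def test_bit_identical_reruns(self, three_generation, toy_hs):
        pedigree, observed = three_generation
        cfg = GeneDropConfig(founder_years=(1989, 1992), simulated_years=(1993, 1995),
                             n_sim=50, seed=77)
        a = run_genedrop(pedigree, observed, toy_hs, cfg)
        b = run_genedrop(pedigree, observed, toy_hs, cfg)
        np.testing.assert_array_equal(a.sim_freq, b.sim_freq)

    def test_frequency_rows_sum_to_one(self, neutral_population, eight_hap_hs):
        _, sim = neutral_population
        cfg = GeneDropConfig(n_sim=20, seed=5)
        run = run_genedrop(sim.pedigree, sim.diplotypes, eight_hap_hs, cfg)
        sums = run.sim_freq.sum(axis=2)
        defined = run.sim_n > 0
        assert np.allclose(sums[:, defined], 1.0, atol=1e-12)
        obs_sums = run.observed.freq[run.observed.defined].sum(axis=1)
        assert np.allclose(obs_sums, 1.0, atol=1e-12)

    def test_expectation_conservation_toy(self, toy_hs):
        """Replicate means converge to the exact propagated expectation."""
        rows = [
            ("f1", None, None, "M", 1989, 1996),
            ("f2", None, None, "F", 1989, 1996),
            ("f3", None, None, "F", 1990, 1996),
            ("k1", "f1", "f2", "M", 1993, 1996),
            ("k2", "f1", "f3", "F", 1994, 1996),
            ("g1", "k1", "k2", None, 1995, 1996),
        ]
        ped = make_pedigree(rows)
        observed = {"f1": ("A", "B"), "f2": ("B", "C"), "f3": ("A", "A")}
        cfg = GeneDropConfig(founder_years=(1989, 1992), simulated_years=(1993, 1996),
                             n_sim=4000, seed=3, frequency_individuals="all")
        run = run_genedrop(ped, observed, toy_hs, cfg)
        expected = expected_frequency_trajectory(ped, observed, toy_hs, cfg)
        mean = run.sim_freq.mean(axis=0)
        se = run.sim_freq.std(axis=0, ddof=1) / np.sqrt(cfg.n_sim)
        diff = np.abs(mean - expected.freq)
        assert (diff <= 3 * se + 1e-12).all()

    def test_replicate_table_round_trip(self, three_generation, toy_hs):
        pedigree, observed = three_generation
        cfg = GeneDropConfig(founder_years=(1989, 1992), simulated_years=(1993, 1995),
                             n_sim=4, seed=1)
        run = run_genedrop(pedigree, observed, toy_hs, cfg)
        tables = list(run.replicates())
        assert len(tables) == 4
        long = run.to_long_frame()
        assert set(long["replicate"]) == {"observed", "0", "1", "2", "3"}


class TestCohortFrequencies:
    def test_fallback_to_nearest_cohort(self, toy_hs):
        ped = make_pedigree(
            [("a", None, None, None, 1989, 1995),
             ("b", None, None, None, 1991, 1995)]
        )
        freqs = cohort_frequencies(ped, {"a": ("A", "B")}, toy_hs)
        np.testing.assert_allclose(freqs[1991], freqs[1989])

    def test_no_genotypes_anywhere_rejected(self, toy_hs):
        ped = make_pedigree([("a", None, None, None, 1989, 1995)])
        with pytest.raises(ValueError, match="no genotyped"):
            cohort_frequencies(ped, {}, toy_hs)
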