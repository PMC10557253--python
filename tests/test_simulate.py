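"""Generator validity: coalescent closed forms, neutral SFS law, msprime
cross-check, forward-engine neutrality, mosaic admixture properties."""

import numpy as np
import pytest
from scipy import stats

from lactotrail.simulate import (DemographicModel, SampleConfig, SweepConfig,
                                 branch_spectrum, simulate_admixed,
                                 simulate_coalescent, simulate_sweep,
                                 tibetan_dog_model)


def one_pop(ne=1000.0, gen_time=1.0):
    return DemographicModel(populations=["A"], splits=[],
                            sizes={"A": [(0.0, ne)]}, gen_time=gen_time)


class TestCoalescentClosedForms:
    def test_pairwise_tmrca_is_2n(self):
        B, total = branch_spectrum(one_pop(), SampleConfig({"A": 2}), ["A"],
                                   100_000, seed=1)
        assert total / 2 == pytest.approx(2000.0, rel=0.01)

    def test_total_branch_length_n4(self):
        _, total = branch_spectrum(one_pop(), SampleConfig({"A": 4}), ["A"],
                                   100_000, seed=2)
        assert total == pytest.approx(4 * 1000 * (1 + 0.5 + 1 / 3), rel=0.01)

    def test_branch_lengths_follow_1_over_i(self):
        B, _ = branch_spectrum(one_pop(), SampleConfig({"A": 6}), ["A"],
                               60_000, seed=3)
        lens = np.array([B[i, 0, 0] for i in range(1, 6)])
        expect = 2 * 2 * 1000 / np.arange(1, 6)
        assert np.allclose(lens, expect, rtol=0.03)

    def test_unreachable_ancestor_errors(self):
        model = DemographicModel(populations=["A", "B"],
                                 splits=[(100.0, "B", "A")],
                                 sizes={"A": [(0.0, 100.0)],
                                        "B": [(0.0, 100.0)]}, gen_time=1.0)
        # sabotage: remove the merge event after validation
        model.splits = []
        with pytest.raises(RuntimeError, match="common ancestor"):
            branch_spectrum(model, SampleConfig({"A": 2, "B": 2}),
                            ["A", "B"], 100, seed=1)


class TestNeutralSfsLaw:
    def test_chi2_one_over_i(self):
        """Single population: observed i-ton counts fit count ∝ 1/i."""
        hm = simulate_coalescent(one_pop(ne=5000.0), SampleConfig({"A": 8}),
                                 n_loci=100_000, locus_len=50.0, seed=11)
        d, n = hm.derived_counts()
        counts = np.bincount(d, minlength=9)[1:8]
        expect = counts.sum() * (1 / np.arange(1, 8)) / np.sum(1 / np.arange(1, 8))
        chi2 = ((counts - expect) ** 2 / expect).sum()
        p = stats.chi2.sf(chi2, df=6)
        assert p > 0.01

    def test_pulse_p1_equals_split(self):
        """A pulse with p=1 at time t is a split at t (same joint SFS)."""
        base = dict(populations=["A", "B"], sizes={"A": [(0.0, 1000.0)],
                                                   "B": [(0.0, 1000.0)]},
                    gen_time=1.0)
        as_split = DemographicModel(splits=[(500.0, "B", "A")], **base)
        as_pulse = DemographicModel(splits=[(4000.0, "B", "A")],
                                    pulses=[(500.0, "A", "B", 1.0)], **base)
        cfg = SampleConfig({"A": 4, "B": 4})
        B1, _ = branch_spectrum(as_split, cfg, ["A", "B"], 40_000, seed=5)
        B2, _ = branch_spectrum(as_pulse, cfg, ["A", "B"], 40_000, seed=6)
        p1, p2 = B1 / B1.sum(), B2 / B2.sum()
        tv = 0.5 * np.abs(p1 - p2).sum()
        assert tv < 0.01

    def test_exchangeability_within_population(self):
        """Permuting sample labels within a population leaves the SFS alone."""
        hm = simulate_coalescent(tibetan_dog_model(),
                                 SampleConfig({"EUR": 4, "TIB_DOG": 4,
                                               "SEAID": 4}),
                                 n_loci=300, locus_len=10_000.0, seed=9)
        d_before, _ = hm.derived_counts("TIB_DOG")
        rows = hm.haplotype_rows("TIB_DOG")
        perm = np.random.default_rng(0).permutation(len(rows))
        hm.H[rows] = hm.H[rows[perm]]
        d_after, _ = hm.derived_counts("TIB_DOG")
        assert np.array_equal(np.sort(d_before), np.sort(d_after))
        assert np.array_equal(d_before, d_after)


class TestMsprimeCrossCheck:
    def test_two_pulse_model_joint_sfs(self):
        """Joint SFS agrees with an independent coalescent implementation."""
        msprime = pytest.importorskip("msprime")
        model = tibetan_dog_model()
        cfg = SampleConfig({"EUR": 4, "TIB_DOG": 4, "SEAID": 4})
        B, _ = branch_spectrum(model, cfg, ["EUR", "TIB_DOG", "SEAID"],
                               100_000, seed=21)
        mine = B / B.sum()

        dem = msprime.Demography()
        g = model.gen_time
        for pop in model.populations:
            dem.add_population(name=pop, initial_size=20_000)
        dem.add_mass_migration(time=3600 / g, source="TIB_DOG", dest="EUR",
                               proportion=0.3)
        dem.add_mass_migration(time=3700 / g, source="SEAID", dest="EUR",
                               proportion=0.3)
        dem.add_mass_migration(time=4500 / g, source="TIB_DOG", dest="SEAID",
                               proportion=1.0)
        dem.add_mass_migration(time=20_000 / g, source="SEAID", dest="EUR",
                               proportion=1.0)
        dem.sort_events()
        other = np.zeros_like(mine)
        reps = msprime.sim_ancestry(
            samples={"EUR": 2, "TIB_DOG": 2, "SEAID": 2}, demography=dem,
            ploidy=2, num_replicates=100_000, random_seed=99)
        for ts in reps:
            t = ts.first()
            sets = [ts.samples(population=i) for i in range(3)]
            for node in t.nodes():
                if t.parent(node) == -1:
                    continue
                leaves = set(t.leaves(node))
                cfg_idx = tuple(len(leaves & set(s)) for s in sets)
                other[cfg_idx] += t.branch_length(node)
        other /= other.sum()
        tv = 0.5 * np.abs(mine - other).sum()
        assert tv < 0.01


class TestSimulateCoalescent:
    def test_deterministic_replay(self):
        model = tibetan_dog_model()
        cfg = SampleConfig({"EUR": 2, "TIB_DOG": 2, "SEAID": 2})
        a = simulate_coalescent(model, cfg, 200, 10_000.0, seed=4)
        b = simulate_coalescent(model, cfg, 200, 10_000.0, seed=4)
        assert np.array_equal(a.H, b.H)
        assert np.array_equal(a.positions, b.positions)

    def test_positions_strictly_increasing(self):
        hm = simulate_coalescent(one_pop(), SampleConfig({"A": 4}), 500,
                                 1000.0, seed=8)
        assert np.all(np.diff(hm.positions) > 0)

    def test_output_is_polarized_binary(self):
        hm = simulate_coalescent(one_pop(), SampleConfig({"A": 4}), 100,
                                 1000.0, seed=8)
        assert hm.polarized
        assert set(np.unique(hm.H)) <= {0, 1}


class TestForwardEngine:
    def test_same_seed_identical(self):
        cfg = SweepConfig(N=40, s=0.1, f0=0.2, duration=30, seed=5,
                          m_sites=50, burn_in=20)
        a, b = simulate_sweep(cfg), simulate_sweep(cfg)
        assert np.array_equal(a.hm.H, b.hm.H)
        assert np.array_equal(a.trajectory, b.trajectory)

    def test_neutral_fixation_probability(self):
        """P(fix) of a neutral allele equals its starting frequency."""
        f0, n_rep = 0.25, 600
        fixed = 0
        absorbed = 0
        for rep in range(n_rep):
            res = simulate_sweep(SweepConfig(
                N=20, L=1e4, r=0.0, mu=0.0, s=0.0, f0=f0, duration=800,
                seed=10_000 + rep, m_sites=4, burn_in=0,
                stop_on_absorption=True))
            if res.fixed or res.lost:
                absorbed += 1
                fixed += res.fixed
        assert absorbed / n_rep > 0.99
        ci = 1.96 * np.sqrt(f0 * (1 - f0) / n_rep)
        assert abs(fixed / n_rep - f0) < ci + 0.01

    def test_heterozygosity_decay(self):
        """Mean heterozygosity decays by 1 - 1/(2N) per generation."""
        N = 100
        # high recombination decorrelates the site genealogies, so the mean
        # over sites tracks the expectation tightly
        res = simulate_sweep(SweepConfig(
            N=N, L=1e5, r=2e-3, mu=0.0, s=0.0, f0=0.0, duration=200,
            seed=3, m_sites=2000, burn_in=0, init="random", record_het=True))
        h = res.het_trajectory
        gens = np.arange(len(h))
        slope = np.polyfit(gens, np.log(h), 1)[0]
        expect = np.log(1 - 1 / (2 * N))
        assert slope == pytest.approx(expect, rel=0.05)

    def test_retry_cap_errors(self):
        with pytest.raises(RuntimeError, match="condition"):
            simulate_sweep(SweepConfig(N=20, s=0.0, f0=1 / 40, duration=5,
                                       seed=1, m_sites=10, burn_in=0,
                                       condition_min_freq=0.99, retry_cap=3))

    def test_two_population_mode_labels(self):
        res = simulate_sweep(SweepConfig(N=30, s=0.2, f0=0.2, duration=20,
                                         split_gen=5, seed=2, m_sites=40,
                                         burn_in=10))
        assert res.hm.n_haplotypes == 120
        assert set(res.hm.pop_of.values()) == {"POP1", "POP2"}


@pytest.fixture(scope="module")
def panels():
    res = simulate_sweep(SweepConfig(N=40, s=0.0, duration=60,
                                     split_gen=0, seed=6, m_sites=300,
                                     burn_in=160, mu=5e-8,
                                     pop_labels=("PA", "PB")))
    return (res.hm.subset_pops(["PA"]), res.hm.subset_pops(["PB"]))


class TestSimulateAdmixed:

    def test_q_zero_paints_all_b(self, panels):
        pa, pb = panels
        hm, truth = simulate_admixed(pa, pb, q=0.0, generations=50.0,
                                     r=1e-8, n_targets=10, seed=3)
        assert (truth.donor == 1).all()
        assert truth.donor_fraction_a() == 0.0

    def test_breakpoint_poisson_mean(self, panels):
        pa, pb = panels
        hm, truth = simulate_admixed(pa, pb, q=0.5, generations=100.0,
                                     r=1e-8, n_targets=500, seed=4)
        span = pa.positions[-1] - pa.positions[0]
        expect = 100.0 * 1e-8 * span
        mean_bp = np.mean([len(b) for b in truth.breakpoints])
        se = np.sqrt(expect / 500)
        assert abs(mean_bp - expect) < 4 * se

    def test_donor_fraction_law_of_large_numbers(self, panels):
        pa, pb = panels
        hm, truth = simulate_admixed(pa, pb, q=0.3, generations=100.0,
                                     r=1e-8, n_targets=500, seed=5)
        assert truth.donor_fraction_a() == pytest.approx(0.30, abs=0.02)

    def test_bad_q_rejected(self, panels):
        pa, pb = panels
        with pytest.raises(ValueError):
            simulate_admixed(pa, pb, q=1.5, generations=10.0, r=1e-8,
                             n_targets=2, seed=1)

    def test_mismatched_positions_rejected(self, panels):
        pa, pb = panels
        pb2 = pb.subset_pops(["PB"])
        pb2.positions = pb2.positions + 1
        with pytest.raises(ValueError, match="positions"):
            simulate_admixed(pa, pb2, q=0.5, generations=10.0, r=1e-8,
                             n_targets=2, seed=1)
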