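"""Joint SFS construction, MC expected SFS, composite likelihood identities,
model selection and block bootstrap."""

import numpy as np
import pytest
from scipy import stats

from lactotrail import sfs as sfsmod
from lactotrail.sfs import (FitResult, JointSFS, build_joint_sfs,
                            composite_loglik, dog_model_template, expected_sfs,
                            fit_model, read_sfs_tsv, select_model,
                            write_sfs_tsv)
from lactotrail.simulate import (DemographicModel, SampleConfig,
                                 simulate_coalescent, tibetan_dog_model)

from conftest import make_hm


def one_pop(ne=1000.0):
    return DemographicModel(populations=["A"], splits=[],
                            sizes={"A": [(0.0, ne)]}, gen_time=1.0)


POPS3 = ("EUR", "TIB_DOG", "SEAID")


@pytest.fixture(scope="module")
def small_sim_sfs():
    hm = simulate_coalescent(tibetan_dog_model(),
                             SampleConfig({p: 4 for p in POPS3}),
                             n_loci=400, locus_len=10_000.0, seed=77)
    return build_joint_sfs(hm, POPS3)


class TestBuildJointSfs:
    def test_hand_tally(self):
        # 3 pops x 1 diploid, 4 sites
        H = [[1, 0, 1, 0],   # EUR
             [1, 0, 0, 0],
             [0, 1, 1, 1],   # TIB_DOG
             [0, 1, 1, 0],
             [0, 0, 1, 1],   # SEAID
             [0, 0, 1, 1]]
        hm = make_hm(H, pops={"S0": "EUR", "S1": "TIB_DOG", "S2": "SEAID"})
        sfs = build_joint_sfs(hm, POPS3)
        xi = sfs.counts()
        assert sfs.S == 4
        assert xi[2, 0, 0] == 1   # site 0
        assert xi[0, 2, 0] == 1   # site 1
        assert xi[1, 2, 2] == 1   # site 2
        assert xi[0, 1, 2] == 1   # site 3
        assert xi.sum() == sfs.S

    def test_monomorphic_only_gives_empty(self):
        H = np.zeros((6, 3), dtype=np.int8)
        H[:, 1] = 1  # fixed derived in all three pops -> excluded
        hm = make_hm(H, pops={"S0": "EUR", "S1": "TIB_DOG", "S2": "SEAID"})
        sfs = build_joint_sfs(hm, POPS3)
        assert sfs.S == 0

    def test_unpolarized_rejected(self):
        hm = make_hm([[0, 1]] * 6, pops={"S0": "EUR", "S1": "TIB_DOG",
                                         "S2": "SEAID"}, polarized=False)
        with pytest.raises(ValueError, match="polarized"):
            build_joint_sfs(hm, POPS3)

    def test_tsv_round_trip(self, small_sim_sfs, tmp_path):
        p = tmp_path / "sfs.tsv"
        write_sfs_tsv(small_sim_sfs, str(p))
        back = read_sfs_tsv(str(p))
        assert back.sample_sizes == small_sim_sfs.sample_sizes
        assert np.array_equal(back.counts(), small_sim_sfs.counts())


class TestExpectedSfs:
    def test_one_over_i_law_n3(self):
        model = DemographicModel(populations=["A"], splits=[],
                                 sizes={"A": [(0.0, 500.0)]}, gen_time=1.0)
        p, se = expected_sfs(model, SampleConfig({"A": 3}), ("A",),
                             20_000, seed=1)
        assert p[1].sum() == pytest.approx(2 / 3, abs=0.02)
        assert p[2].sum() == pytest.approx(1 / 3, abs=0.02)
        assert p.sum() == pytest.approx(1.0)
        assert np.all(se >= 0)

    def test_merged_at_zero_equals_pooled(self):
        """Two populations merged at (almost) time zero behave as one pool."""
        merged = DemographicModel(
            populations=["A", "B"], splits=[(1e-6, "B", "A")],
            sizes={"A": [(0.0, 800.0)], "B": [(0.0, 800.0)]}, gen_time=1.0)
        pool = one_pop(800.0)
        pm, _ = expected_sfs(merged, SampleConfig({"A": 2, "B": 2}),
                             ("A", "B"), 30_000, seed=2)
        pp, _ = expected_sfs(pool, SampleConfig({"A": 4}), ("A",),
                             30_000, seed=3)
        # total-derived-count marginal of the merged model = pooled spectrum
        marg = np.zeros(5)
        for i in range(3):
            for j in range(3):
                marg[i + j] += pm[i, j, 0]
        assert np.allclose(marg[1:4], pp[1:4, 0, 0], atol=0.02)

    def test_too_few_genealogies_rejected(self):
        with pytest.raises(ValueError, match="noisy"):
            expected_sfs(one_pop(), SampleConfig({"A": 3}), ("A",), 500, 1)

    def test_label_permutation_invariance(self):
        model = tibetan_dog_model()
        cfg = SampleConfig({p: 2 for p in POPS3})
        pa, _ = expected_sfs(model, cfg, ("EUR", "TIB_DOG", "SEAID"),
                             20_000, seed=4)
        pb, _ = expected_sfs(model, cfg, ("SEAID", "EUR", "TIB_DOG"),
                             20_000, seed=4)
        assert np.allclose(pa, np.moveaxis(pb, (0, 1, 2), (2, 0, 1)),
                           atol=1e-12)


class TestCompositeLoglik:
    def test_concentrated_spectrum_ll_zero(self):
        """If the model puts all mass on the observed cell, ll = 0."""
        # n=2: the only segregating cells are (1,) and (2,); a star-like
        # tally on one cell with p=1 gives ll = count * log 1 = 0
        sfs = JointSFS(("A", "B", "C"), (2, 2, 2),
                       np.array([[1, 0, 0]] * 5), np.arange(5) + 1)
        xi = sfs.counts()
        p = np.zeros_like(xi, dtype=float)
        p[1, 0, 0] = 1.0
        ll = np.sum(xi[xi > 0] * np.log(p[xi > 0]))
        assert ll == 0.0

    def test_nesting_identity_pulse_zero(self, small_sim_sfs):
        """M1 with pulse proportion 0 equals M0 at identical parameters."""
        shared = {"N_EUR": 2e4, "N_TIB": 2e4, "N_SEA": 2e4, "N_ANC": 2e4,
                  "N_ROOT": 2e4, "T_EURASIA": 2e4, "T_TIBSEA_FRAC": 0.225}
        m0 = dog_model_template("M0").build(shared)
        m1 = dog_model_template("M1").build(
            dict(shared, P1=0.0, T_PULSE1_FRAC=0.5))
        cfg = SampleConfig(dict(zip(POPS3, small_sim_sfs.sample_sizes)))
        ll0 = composite_loglik(small_sim_sfs, m0, cfg, 5000, seed=9)
        ll1 = composite_loglik(small_sim_sfs, m1, cfg, 5000, seed=9)
        assert ll0 == ll1

    def test_grid_recovery_of_split_time(self, small_sim_sfs):
        """ll over a split-time grid peaks near the generating value."""
        cfg = SampleConfig(dict(zip(POPS3, small_sim_sfs.sample_sizes)))
        lls = []
        grid = [5e3, 1e4, 2e4, 3.2e4]
        for t_eur in grid:
            model = tibetan_dog_model(t_eurasia=t_eur)
            lls.append(composite_loglik(small_sim_sfs, model, cfg,
                                        20_000, seed=11))
        assert grid[int(np.argmax(lls))] == 2e4


class TestFitModel:
    def test_degenerate_sfs_rejected(self):
        empty = JointSFS(POPS3, (4, 4, 4), np.empty((0, 3), dtype=np.int64),
                         np.empty(0, dtype=np.int64))
        with pytest.raises(ValueError, match="degenerate"):
            fit_model(empty, dog_model_template("M0"), n_starts=1, seed=0)

    def test_m0_recovers_ne(self):
        """True Ne lies inside the spread of M0 estimates on M0 data."""
        truth = tibetan_dog_model(pulse_tib=None, pulse_sea=None)
        hm = simulate_coalescent(truth, SampleConfig({p: 4 for p in POPS3}),
                                 1500, 10_000.0, seed=13)
        sfs = build_joint_sfs(hm, POPS3)
        tpl = dog_model_template(
            "M0", fixed={"N_ANC": 2e4, "N_ROOT": 2e4, "T_EURASIA": 2e4,
                         "T_TIBSEA_FRAC": 0.225})
        fits = fit_model(sfs, tpl, n_starts=3, seed=1, n_genealogies=4000,
                         max_evals=200)
        best = max(fits, key=lambda r: r.loglik)
        for key in ("N_EUR", "N_TIB", "N_SEA"):
            assert 0.4 * 2e4 < best.params[key] < 2.5 * 2e4

    def test_deterministic_replay(self, small_sim_sfs):
        tpl = dog_model_template(
            "M0", fixed={"N_ANC": 2e4, "N_ROOT": 2e4, "T_EURASIA": 2e4})
        kw = dict(n_starts=2, seed=5, n_genealogies=2000, max_evals=60,
                  reeval_genealogies=None)
        a = fit_model(small_sim_sfs, tpl, **kw)
        b = fit_model(small_sim_sfs, tpl, **kw)
        for ra, rb in zip(a, b):
            assert ra.loglik == rb.loglik
            assert ra.params == rb.params


class TestSelectModel:
    def _fits(self, name, lls):
        return [FitResult(name, {}, ll, i, True, 1)
                for i, ll in enumerate(lls)]

    def test_identical_vectors_tie_to_simpler(self):
        fits = {"M1": self._fits("M1", [-10.0, -11.0, -9.0]),
                "M0": self._fits("M0", [-10.0, -11.0, -9.0])}
        cmp = select_model(fits)
        assert cmp.selected == "M0"
        assert cmp.table[0]["p"] == 1.0

    def test_welch_formula(self):
        a, b = [-100.0, -101.0, -99.0], [-90.0, -91.0, -89.0]
        cmp = select_model({"M0": self._fits("M0", a),
                            "M1": self._fits("M1", b)})
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=False)
        row = cmp.table[0]
        assert row["t"] == pytest.approx(t_ref)
        assert row["p"] == pytest.approx(p_ref)
        # hand Welch: diff=-10, se = sqrt(1/3 + 1/3)
        assert row["t"] == pytest.approx(-10 / np.sqrt(2 / 3))
        assert cmp.selected == "M1"

    def test_significantly_better_complex_model_wins(self):
        fits = {"M0": self._fits("M0", [-100.0, -101.0, -99.0]),
                "M2": self._fits("M2", [-90.0, -91.0, -89.0])}
        assert select_model(fits).selected == "M2"

    def test_single_model_rejected(self):
        with pytest.raises(ValueError):
            select_model({"M0": self._fits("M0", [-1.0, -2.0])})


class TestBootstrap:
    def test_duplicated_blocks_zero_width(self, small_sim_sfs):
        """Degenerate resampling (every draw = same layout) -> near-zero CI."""
        tpl = dog_model_template(
            "M0", fixed={"N_ANC": 2e4, "N_ROOT": 2e4, "T_EURASIA": 2e4,
                         "T_TIBSEA_FRAC": 0.225, "N_EUR": 2e4, "N_SEA": 2e4})
        # single free parameter, identical data every replicate
        dup = JointSFS(small_sim_sfs.pops, small_sim_sfs.sample_sizes,
                       np.tile(small_sim_sfs.site_configs[:50], (2, 1)),
                       np.arange(100) + 1)
        boot = sfsmod.bootstrap_ci(dup, tpl, B=3, K=1, seed=1, n_starts=1,
                                   n_genealogies=2000, max_evals=40,
                                   init={"N_TIB": 2e4})
        est = boot.estimates[:, boot.params.index("N_TIB")]
        assert np.ptp(est) == pytest.approx(0.0, abs=1e-9)

    def test_k_larger_than_sites_rejected(self, small_sim_sfs):
        tpl = dog_model_template("M0")
        with pytest.raises(ValueError, match="exceeds"):
            sfsmod.bootstrap_ci(small_sim_sfs, tpl, B=1,
                                K=small_sim_sfs.S + 1, seed=1)

    def test_resample_blocks_conserves_sites(self, small_sim_sfs):
        ids = np.zeros(100, dtype=np.int64)  # block 0 drawn 100 times
        boot = small_sim_sfs.resample_blocks(ids, 100)
        block0 = np.array_split(np.arange(small_sim_sfs.S), 100)[0]
        assert boot.S == 100 * len(block0)
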