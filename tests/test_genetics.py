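"""GRM construction, REML heritability, permutation null, metabolite h2."""
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import seedcourse as sc
from seedcourse import gcoe, genetics


class TestGRM:
    def test_identical_genotype_rows_look_like_clones(self):
        rng = np.random.default_rng(1)
        geno = rng.integers(0, 3, size=(5, 200)).astype(float)
        geno[1] = geno[0]
        K = sc.grm_vanraden(pd.DataFrame(geno)).to_numpy()
        assert K[0, 1] == pytest.approx(K[0, 0])
        assert K[0, 1] == pytest.approx(K[1, 1])

    def test_symmetric_to_machine_precision(self):
        g = sc.simulate.simulate_markers(10, 60, seed=2)
        K = sc.grm_vanraden(g).to_numpy()
        assert np.array_equal(K, K.T)

    def test_unrelated_lines_have_near_zero_mean_relationship(self):
        g = sc.simulate.simulate_markers(22, 5000, seed=3)
        K = sc.grm_vanraden(g).to_numpy()
        assert abs(K[~np.eye(22, dtype=bool)].mean()) < 0.05
        assert np.diag(K).mean() == pytest.approx(1.0, abs=0.15)


def _dense_reml_oracle(y, Km):
    """Brute-force REML (no eigendecomposition shortcut)."""
    n = len(y)
    X = np.ones((n, 1))

    def ll(lam):
        H = lam * Km + np.eye(n)
        Hinv = np.linalg.inv(H)
        XHX = X.T @ Hinv @ X
        P = Hinv - Hinv @ X @ np.linalg.inv(XHX) @ X.T @ Hinv
        s2 = float(y @ P @ y) / (n - 1)
        return -0.5 * ((n - 1) * (np.log(2 * np.pi * s2) + 1)
                       + np.linalg.slogdet(H)[1] + np.log(XHX[0, 0]))

    res = optimize.minimize_scalar(lambda t: -ll(10.0 ** t), bounds=(-6, 6),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    lam = 10.0 ** res.x
    if ll(0.0) >= -res.fun:
        lam = 0.0
    return lam / (1 + lam)


class TestEstimateH2:
    def test_constant_trait_degenerates_to_zero_with_warning(self,
                                                             marker_grm22):
        with pytest.warns(UserWarning, match="constant"):
            est = genetics.estimate_h2(np.full(22, 3.0), marker_grm22)
        assert est.h2 == 0.0 and est.p == 1.0

    def test_invariant_to_shift_and_positive_scaling(self, structured_grm22):
        rng = np.random.default_rng(4)
        y = rng.standard_normal(22)
        a = genetics.estimate_h2(y, structured_grm22)
        b = genetics.estimate_h2(5.0 * y + 11.0, structured_grm22)
        assert a.h2 == pytest.approx(b.h2, abs=1e-6)
        assert a.lrt_stat == pytest.approx(b.lrt_stat, abs=1e-6)

    def test_lrt_never_negative_and_boundary_p_convention(self,
                                                          structured_grm22):
        rng = np.random.default_rng(5)
        for _ in range(20):
            est = genetics.estimate_h2(rng.standard_normal(22),
                                       structured_grm22)
            assert est.lrt_stat >= 0.0
            assert (est.p == 1.0) == (est.lrt_stat == 0.0)

    def test_matches_dense_reml_oracle_on_random_instances(self):
        rng = np.random.default_rng(6)
        n = 12
        mismatches = 0
        for rep in range(50):
            A = rng.standard_normal((n, n + 5))
            Km = A @ A.T / (n + 5)
            Km = Km / np.diag(Km).mean()
            K = pd.DataFrame(Km)
            y = rng.standard_normal(n)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = genetics.estimate_h2(y, K)
            oracle = _dense_reml_oracle(y, Km)
            if abs(est.h2 - oracle) > 1e-4:
                mismatches += 1
        assert mismatches == 0

    def test_identity_grm_is_the_flat_likelihood_degenerate_case(self):
        # with one observation per line and K = I, sigma_u2 and
        # sigma_e2 enter only through their sum: REML is exactly flat
        # and the fit collapses to the no-genetics boundary.
        rng = np.random.default_rng(7)
        K = pd.DataFrame(np.eye(22))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = genetics.estimate_h2(rng.standard_normal(22), K)
        assert est.lrt_stat == pytest.approx(0.0, abs=1e-6)
        assert est.h2 < 0.05 or est.p == 1.0

    def test_null_p_is_subuniform_under_boundary_mixture(self,
                                                         structured_grm22):
        rng = np.random.default_rng(8)
        ps = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(300):
                ps.append(genetics.estimate_h2(rng.standard_normal(22),
                                               structured_grm22).p)
        ps = np.asarray(ps)
        # P(p <= t) ~ t for t <= 0.5 plus an atom at 1
        assert (ps <= 0.05).mean() == pytest.approx(0.05, abs=0.04)
        assert (ps <= 0.25).mean() == pytest.approx(0.25, abs=0.07)
        assert (ps == 1.0).mean() > 0.3

    def test_structured_signal_typically_detected(self, structured_grm22):
        # one realized trait can be an unlucky draw at n=22; the typical
        # (median) behaviour over draws must show strong heritability
        Km = structured_grm22.to_numpy()
        L = np.linalg.cholesky(Km + 1e-8 * np.eye(22))
        rng = np.random.default_rng(9)
        h2s = []
        for _ in range(10):
            y = L @ rng.standard_normal(22) * np.sqrt(0.9) \
                + rng.standard_normal(22) * np.sqrt(0.1)
            h2s.append(genetics.estimate_h2(y, structured_grm22).h2)
        assert np.median(h2s) > 0.5


class TestH2PermutationNull:
    def test_fixed_seed_reproduces_null_draws(self, structured_grm22):
        rng = np.random.default_rng(10)
        lsm = pd.DataFrame(rng.standard_normal((22, 30)),
                           index=structured_grm22.index,
                           columns=[f"T{j}" for j in range(30)])
        sets = {"setA": (list(lsm.columns), 2)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = genetics.h2_permutation_null(lsm, sets, structured_grm22,
                                             n_perm=5, seed=3)
            b = genetics.h2_permutation_null(lsm, sets, structured_grm22,
                                             n_perm=5, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_exchangeable_data_indistinguishable_from_null(self,
                                                           structured_grm22):
        # data with no genetic structure: real h2 and permuted h2 come
        # from the same distribution
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(11)
        lsm = pd.DataFrame(rng.standard_normal((22, 40)),
                           index=structured_grm22.index,
                           columns=[f"T{j}" for j in range(40)])
        sets = {"setA": (list(lsm.columns), 3)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null = genetics.h2_permutation_null(lsm, sets, structured_grm22,
                                                n_perm=40, seed=4)
            real = []
            labels = gcoe.subcluster(lsm, lsm.columns, 3)
            for g in sorted(labels.unique()):
                scr, _ = gcoe.pc1_scores(lsm, labels.index[labels == g])
                real.append(genetics.estimate_h2(scr, structured_grm22).h2)
        stat = mannwhitneyu(real, null["h2"].to_numpy())
        assert stat.pvalue > 0.01


class TestMetaboliteH2:
    def _balanced(self, s_line, s_loc_line, s_e, seed, n_lines=22):
        rng = np.random.default_rng(seed)
        aL = rng.normal(0, np.sqrt(s_line), n_lines)
        rows = []
        for j, loc in enumerate(["S1", "S2"]):
            bS = rng.normal(0, 0.3)
            bLS = rng.normal(0, np.sqrt(s_loc_line), n_lines)
            for rep in (1, 2):
                bR = rng.normal(0, 0.3)
                e = rng.normal(0, np.sqrt(s_e), n_lines)
                for i in range(n_lines):
                    rows.append((f"L{i:02d}", loc, rep,
                                 aL[i] + bS + bLS[i] + bR + e[i]))
        return pd.DataFrame(rows, columns=["line", "location", "replicate",
                                           "value"])

    def test_no_line_variance_gives_near_zero_typical_h2(self):
        # the line component is truncated at zero, so single null draws
        # at 22 lines can show h2 ~ 0.4 (verified against lme4); the
        # typical (median) estimate must be near zero and the mean well
        # below the heritable regime
        vals = [genetics.metabolite_h2(
            self._balanced(0.0, 0.5, 2.0, seed=200 + r)).h2
            for r in range(15)]
        assert np.median(vals) < 0.15
        assert np.mean(vals) < 0.3

    def test_generative_check_of_h2_formula(self):
        # sigma_L2=4, sigma_LS2=2, sigma_e2=4 -> h2 = 4/(4+1+1) = 2/3
        vals = [genetics.metabolite_h2(
            self._balanced(4.0, 2.0, 4.0, seed=100 + r)).h2
            for r in range(12)]
        assert np.mean(vals) == pytest.approx(2 / 3, abs=0.08)

    def test_scale_invariance_of_h2(self):
        df = self._balanced(4.0, 2.0, 4.0, seed=13)
        a = genetics.metabolite_h2(df)
        df2 = df.assign(value=2.0 * df["value"])
        b = genetics.metabolite_h2(df2)
        assert b.h2 == pytest.approx(a.h2, abs=1e-4)
        assert b.components["line"] == pytest.approx(
            4 * a.components["line"], rel=1e-3, abs=1e-8)

    def test_reml_matches_ems_oracle_on_balanced_interior_fixture(self):
        df = self._balanced(6.0, 3.0, 2.0, seed=14)
        ems = genetics.ems_components(df)
        reml = genetics.metabolite_h2(df).components
        for k in ("line", "loc_line", "residual"):
            assert reml[k] == pytest.approx(ems[k], rel=0.15, abs=0.3)

    def test_single_location_is_rejected(self):
        df = self._balanced(1.0, 1.0, 1.0, seed=15)
        with pytest.raises(ValueError, match="location"):
            genetics.metabolite_h2(df[df["location"] == "S1"])
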