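"""Statistical engines: symmetry, oracle agreement, FDR and direction."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from dasekit.ase_counts import nested_design
from dasekit.dase_model import (
    adjust_fdr,
    betabin_loglik,
    classify_direction,
    fit_dase_betabin,
    fit_dase_glm_batch,
)


def stacked_counts(high_pairs, low_pairs):
    """(ref, alt) per sample -> observation vector in design row order."""
    y = []
    for ref, alt in list(high_pairs) + list(low_pairs):
        y.extend([ref, alt])
    return np.array([y], dtype=float)


def glm_fit(high_pairs, low_pairs):
    X, ih, il = nested_design(len(high_pairs), len(low_pairs))
    return fit_dase_glm_batch(stacked_counts(high_pairs, low_pairs), X, ih, il)


class TestGlmEngine:
    def test_perfectly_balanced_counts_are_null(self):
        res = glm_fit([(20, 20)] * 4, [(20, 20)] * 4)
        assert res["delta_high"][0] == pytest.approx(0.0, abs=1e-6)
        assert res["delta_low"][0] == pytest.approx(0.0, abs=1e-6)
        assert res["log2fc"][0] == pytest.approx(0.0, abs=1e-6)
        assert res["p_diff"][0] > 0.99

    def test_imbalanced_high_gives_positive_log2fc(self):
        # High imbalance toward ref, Low balanced: larger imbalance in High,
        # positive log2 fold-change by convention
        res = glm_fit([(30, 10)] * 4, [(20, 20)] * 4)
        assert res["log2fc"][0] > 0
        assert res["p_diff"][0] < 0.05

    def test_label_swap_negates_log2fc(self):
        high = [(30, 10), (28, 12), (33, 9), (25, 14)]
        low = [(20, 20), (21, 19), (18, 22), (22, 20)]
        a = glm_fit(high, low)
        b = glm_fit(low, high)
        assert a["log2fc"][0] == pytest.approx(-b["log2fc"][0], abs=1e-4)
        assert a["p_diff"][0] == pytest.approx(b["p_diff"][0], abs=1e-6)

    def test_wald_ranks_agree_with_brute_force_lrt(self):
        # independent oracle: numeric ML of the same NB model with and
        # without a common allele effect, p from chi-square(1)
        rng = np.random.default_rng(4)
        scenarios = []
        for shift in (0.0, 0.1, 0.2, 0.3):
            d = rng.poisson(60, size=8) + 1
            pi = 0.5 + shift
            alt = rng.binomial(d, [pi] * 4 + [0.5] * 4)
            scenarios.append(([(r, a) for r, a in zip(d[:4] - alt[:4], alt[:4])],
                              [(r, a) for r, a in zip(d[4:] - alt[4:], alt[4:])]))

        def nb_ll(y, mu, alpha):
            k = 1 / max(alpha, 1e-8)
            return np.sum(
                special.gammaln(y + k) - special.gammaln(k) - special.gammaln(y + 1)
                + y * np.log(mu / (mu + k)) + k * np.log(k / (k + mu))
            )

        def brute_lrt(high, low):
            X, ih, il = nested_design(len(high), len(low))
            y = stacked_counts(high, low)[0]
            Xr = X.copy()  # common allele effect: collapse the two columns
            Xr[:, il] = Xr[:, il] + Xr[:, ih]
            Xr = np.delete(Xr, ih, axis=1)

            def fit(M):
                p = M.shape[1]

                def negll(t):
                    return -nb_ll(y, np.exp(np.clip(M @ t[:p], -25, 25)), np.exp(t[p]))

                t0 = np.append(np.linalg.lstsq(M, np.log(y + 0.5), rcond=None)[0], np.log(0.05))
                return -optimize.minimize(negll, t0, method="Nelder-Mead",
                                          options={"maxiter": 20000, "xatol": 1e-8, "fatol": 1e-10}).fun

            return 2 * (fit(X) - fit(Xr))

        wald_p = [glm_fit(h, l)["p_diff"][0] for h, l in scenarios]
        lrt_p = [stats.chi2.sf(max(brute_lrt(h, l), 0), 1) for h, l in scenarios]
        assert list(np.argsort(wald_p)) == list(np.argsort(lrt_p))

    def test_zero_alt_in_group_flagged_boundary(self):
        res = glm_fit([(20, 0)] * 3, [(10, 10)] * 3)
        assert res["boundary"][0]
        assert not res["converged"][0]
        assert np.isnan(res["p_diff"][0])


class TestBetabinEngine:
    def test_null_data_estimates_half(self):
        alt = np.full(30, 50)
        n = np.full(30, 100)
        fit, res = fit_dase_betabin((alt, n), (alt, n))
        assert fit.coefficients["pi_high"] == pytest.approx(0.5, abs=1e-3)
        assert res.p_high > 0.9
        assert res.p_diff > 0.9
        assert res.log2fc == pytest.approx(0.0, abs=1e-6)

    def test_loglik_matches_dense_grid_oracle(self):
        high = (np.array([80, 75, 85]), np.array([100, 100, 100]))
        low = (np.array([50, 55, 45]), np.array([100, 100, 100]))
        fit, _ = fit_dase_betabin(high, low)
        pis = np.linspace(0.02, 0.98, 50)
        rhos = np.linspace(0.0, 0.4, 20)
        # per-group grids over (pi, rho); samples broadcast on the last axis
        ll_h = betabin_loglik(high[0], high[1], pis[:, None, None], rhos[None, :, None])
        ll_l = betabin_loglik(low[0], low[1], pis[:, None, None], rhos[None, :, None])
        # combine on the shared rho axis: (pi_high, pi_low, rho)
        ll = ll_h[:, None, :] + ll_l[None, :, :]
        assert fit.loglik >= ll.max() - 1e-4

    def test_identical_groups_are_null(self):
        alt = np.array([60, 40, 55, 48])
        n = np.array([100, 90, 110, 95])
        _, res = fit_dase_betabin((alt, n), (alt, n))
        assert res.p_diff > 0.9
        assert res.log2fc == pytest.approx(0.0, abs=1e-6)

    def test_label_swap_antisymmetry_exact(self):
        high = (np.array([70, 66, 74]), np.array([100, 100, 100]))
        low = (np.array([52, 49, 50]), np.array([100, 100, 100]))
        _, a = fit_dase_betabin(high, low)
        _, b = fit_dase_betabin(low, high)
        assert a.log2fc == pytest.approx(-b.log2fc, abs=1e-6)
        assert a.p_diff == pytest.approx(b.p_diff, abs=1e-6)

    def test_parameter_recovery(self):
        from dasekit.synthetic_data import simulate_group_counts

        ah, nh, al, nl = simulate_group_counts(
            1, 200, 200, 0.7, 0.5, rho=0.05, mean_depth=100, seed=9
        )
        fit, _ = fit_dase_betabin((ah[0], nh[0]), (al[0], nl[0]))
        assert fit.coefficients["pi_high"] == pytest.approx(0.7, abs=0.03)
        assert fit.coefficients["pi_low"] == pytest.approx(0.5, abs=0.03)
        assert fit.dispersion == pytest.approx(0.05, abs=0.01)

    def test_rho_zero_boundary_flagged(self):
        # underdispersed data: identical alt counts at identical depths
        alt = np.full(6, 50)
        n = np.full(6, 100)
        fit, res = fit_dase_betabin((alt, n), (alt, n))
        assert fit.boundary
        assert fit.dispersion == 0.0

    def test_engine_agreement_on_mixed_regimes(self):
        from dasekit.synthetic_data import simulate_group_counts

        rng = np.random.default_rng(12)
        p_glm, p_bb = [], []
        for shift in (0.0, 0.0, 0.15, 0.3):
            ah, nh, al, nl = simulate_group_counts(
                30, 5, 5, 0.5 + shift, 0.5, rho=0.02, mean_depth=60, seed=rng
            )
            X, ih, il = nested_design(5, 5)
            Y = np.zeros((30, 20))
            Y[:, 0:10:2] = nh - ah
            Y[:, 1:10:2] = ah
            Y[:, 10:20:2] = nl - al
            Y[:, 11:20:2] = al
            res = fit_dase_glm_batch(Y, X, ih, il)
            p_glm.extend(res["p_diff"])
            for s in range(30):
                _, r = fit_dase_betabin((ah[s], nh[s]), (al[s], nl[s]), which=("diff",))
                p_bb.append(r.p_diff)
        rho = stats.spearmanr(p_glm, p_bb).statistic
        assert rho >= 0.9


class TestFdrAndDirection:
    def test_bh_hand_computation(self):
        res = pd.DataFrame(
            {
                "trait": "T",
                "snp_id": list("abcd"),
                "p_diff": [0.01, 0.02, 0.03, 0.04],
                "converged": True,
            }
        )
        out = adjust_fdr(res)
        assert np.allclose(out["fdr"], [0.04, 0.04, 0.04, 0.04])

    def test_single_test_fdr_is_p(self):
        res = pd.DataFrame({"trait": ["T"], "snp_id": ["a"], "p_diff": [0.2], "converged": [True]})
        assert adjust_fdr(res)["fdr"].iloc[0] == pytest.approx(0.2)

    def test_all_ones_stay_one(self):
        res = pd.DataFrame(
            {"trait": "T", "snp_id": list("abc"), "p_diff": [1.0] * 3, "converged": True}
        )
        assert (adjust_fdr(res)["fdr"] == 1.0).all()

    def test_strata_are_per_trait(self):
        res = pd.DataFrame(
            {
                "trait": ["T1"] * 2 + ["T2"] * 2,
                "snp_id": list("abab"),
                "p_diff": [0.01, 0.04, 0.5, 0.9],
                "converged": True,
            }
        )
        out = adjust_fdr(res).set_index(["trait", "snp_id"])
        assert out.loc[("T1", "a"), "fdr"] == pytest.approx(0.02)
        assert out.loc[("T2", "b"), "fdr"] == pytest.approx(0.9)

    def test_unconverged_excluded_from_stratum(self):
        res = pd.DataFrame(
            {
                "trait": "T",
                "snp_id": list("abc"),
                "p_diff": [0.01, 0.02, 0.03],
                "converged": [True, False, True],
            }
        )
        out = adjust_fdr(res)
        assert np.isnan(out.loc[1, "fdr"])
        # m = 2, not 3, in the BH stratum
        assert out.loc[0, "fdr"] == pytest.approx(0.02)

    @pytest.mark.parametrize(
        "fc,expected", [(-2.0, "Low"), (2.0, "High"), (0.0, "undirected")]
    )
    def test_direction_convention(self, fc, expected):
        assert classify_direction(fc) == expected
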