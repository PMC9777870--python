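"""Statistical engines for differential allele-specific expression (DASE).

Two interchangeable engines test, for each SNP, (a) allelic imbalance within
the High group, (b) within the Low group, and (c) a *difference* in imbalance
between the groups:

``glm``
    A negative-binomial log-linear model on the duplicated-sample count
    matrix, log mu = intercept + group + sample(group) + allele(group), fit by
    maximum likelihood with a per-SNP dispersion profiled on a Cox-Reid
    adjusted likelihood (the small-sample bias correction used by the
    standard RNA-seq count-model packages).  Wald tests on the
    allele-within-group coefficients delta_High, delta_Low and their
    difference are referred to a t distribution with the residual degrees of
    freedom, which keeps the test calibrated at the 3-20 samples per group
    this analysis typically retains.

``betabin``
    Per group g, alt_i ~ BetaBinomial(n_i, pi_g, rho) with a dispersion rho
    shared between groups; likelihood-ratio tests of pi_High = 1/2,
    pi_Low = 1/2 and pi_High = pi_Low against chi-square(1).

The reported log2 fold-change contrasts the *magnitude* of allelic imbalance:
positive values mean the imbalance is larger in the High group, negative
values larger in the Low group.  Benjamini-Hochberg FDR is applied to the
between-group p-value within each trait.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .ase_counts import DesignMatrix

__all__ = [
    "DaseResult",
    "ModelFit",
    "fit_dase_glm",
    "fit_dase_glm_batch",
    "fit_dase_betabin",
    "betabin_loglik",
    "adjust_fdr",
    "classify_direction",
]

_LN2 = np.log(2.0)


@dataclass
class ModelFit:
    """Fitted model parameters for one SNP."""

    coefficients: dict[str, float]
    dispersion: float
    loglik: float
    vcov: np.ndarray | None = None
    boundary: bool = False


@dataclass
class DaseResult:
    """Per SNP x trait test result."""

    snp_id: str
    trait: str
    p_high: float
    p_low: float
    p_diff: float
    log2fc: float
    n_high: int
    n_low: int
    engine: str
    converged: bool
    fdr: float = float("nan")
    boundary: bool = False

    @property
    def direction(self) -> str:
        return classify_direction(self.log2fc)


# ---------------------------------------------------------------------------
# Negative-binomial GLM engine
# ---------------------------------------------------------------------------


def _nb_loglik(Y: np.ndarray, mu: np.ndarray, alpha: np.ndarray | float) -> np.ndarray:
    """NB2 log-likelihood summed over observations; Poisson in the alpha->0 limit."""
    alpha = np.asarray(alpha, dtype=float)
    small = alpha < 1e-8
    with np.errstate(divide="ignore", invalid="ignore"):
        k = 1.0 / np.where(small, 1.0, alpha)
        nb = (
            special.gammaln(Y + k)
            - special.gammaln(k)
            - special.gammaln(Y + 1.0)
            + Y * np.log(mu / (mu + k))
            + k * np.log(k / (k + mu))
        )
        pois = Y * np.log(mu) - mu - special.gammaln(Y + 1.0)
    out = np.where(np.broadcast_to(small, nb.shape), pois, nb)
    return out.sum(axis=-1)


def _irls(
    Y: np.ndarray,
    X: np.ndarray,
    alpha: np.ndarray | float,
    eta0: np.ndarray,
    max_iter: int = 25,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Batched IRLS for the NB log-linear model (shared design ``X``).

    ``Y``: (S, m) counts; ``alpha``: scalar or (S, 1).  Returns
    (beta (S,p), eta (S,m), W (S,m), converged (S,)).
    """
    S, m = Y.shape
    p = X.shape[1]
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float).reshape(-1, 1), (S, 1)).copy()
    eta = eta0.copy()
    beta = np.zeros((S, p))
    ll_prev = np.full(S, -np.inf)
    converged = np.zeros(S, dtype=bool)
    for _ in range(max_iter):
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        W = mu / (1.0 + alpha * mu)
        z = eta + (Y - mu) / mu
        WX = W[:, :, None] * X[None, :, :]
        A = np.matmul(X.T[None, :, :], WX)
        A += 1e-10 * np.eye(p)  # numerical guard; design is full rank
        b = np.matmul(WX.transpose(0, 2, 1), z[:, :, None])
        beta = np.linalg.solve(A, b)[:, :, 0]
        eta = beta @ X.T
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        ll = _nb_loglik(Y, mu, alpha)
        converged = np.abs(ll - ll_prev) < tol * (np.abs(ll) + 1.0)
        if converged.all():
            break
        ll_prev = ll
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    W = mu / (1.0 + alpha * mu)
    return beta, eta, W, converged


def _cr_criterion(Y, X, eta, W, alpha) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood for the dispersion."""
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    ll = _nb_loglik(Y, mu, np.asarray(alpha).reshape(-1, 1))
    A = np.matmul(X.T[None, :, :], W[:, :, None] * X[None, :, :])
    sign, logdet = np.linalg.slogdet(A + 1e-10 * np.eye(X.shape[1]))
    return ll - 0.5 * logdet


_ALPHA_GRID = np.concatenate([[1e-9], np.geomspace(1e-4, 4.0, 17)])


def _nb_profile_fit(
    Y: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit the NB GLM per SNP with dispersion profiled over a CR-adjusted grid.

    Returns (beta, cov, alpha, loglik, converged).
    """
    S, m = Y.shape
    p = X.shape[1]
    eta0 = np.log(Y + 0.5)
    # Poisson start
    beta, eta, W, _ = _irls(Y, X, 0.0, eta0, max_iter=25)

    best_crit = np.full(S, -np.inf)
    best_alpha = np.full(S, _ALPHA_GRID[0])
    warm = eta
    for a in _ALPHA_GRID:
        _, eta_a, W_a, _ = _irls(Y, X, a, warm, max_iter=6)
        crit = _cr_criterion(Y, X, eta_a, W_a, a)
        better = crit > best_crit
        best_crit = np.where(better, crit, best_crit)
        best_alpha = np.where(better, a, best_alpha)
        warm = eta_a

    # final fit at the per-SNP selected dispersion
    beta, eta, W, converged = _irls(Y, X, best_alpha.reshape(-1, 1), np.log(Y + 0.5), max_iter=40)
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    ll = _nb_loglik(Y, mu, best_alpha.reshape(-1, 1))
    A = np.matmul(X.T[None, :, :], W[:, :, None] * X[None, :, :])
    cov = np.linalg.inv(A + 1e-10 * np.eye(p))
    ok = np.isfinite(ll) & np.isfinite(beta).all(axis=1)
    if not ok.all():  # method-of-moments fallback for pathological fits
        for s in np.where(~ok)[0]:
            y = Y[s : s + 1]
            b0, e0, w0, _ = _irls(y, X, 0.0, np.log(y + 0.5))
            mu0 = np.exp(np.clip(e0, -30.0, 30.0))
            resid = ((y - mu0) ** 2 - mu0) / mu0**2
            a_mom = float(np.clip(resid.sum() / max(m - p, 1), 1e-9, 10.0))
            b1, e1, w1, c1 = _irls(y, X, a_mom, e0)
            beta[s], best_alpha[s] = b1[0], a_mom
            mu1 = np.exp(np.clip(e1, -30.0, 30.0))
            ll[s] = _nb_loglik(y, mu1, a_mom)[0]
            A1 = X.T @ (w1[0][:, None] * X)
            cov[s] = np.linalg.inv(A1 + 1e-10 * np.eye(p))
            converged[s] = bool(c1[0]) and np.isfinite(ll[s])
    return beta, cov, best_alpha, ll, converged


def fit_dase_glm_batch(
    Y: np.ndarray,
    X: np.ndarray,
    idx_alt_high: int,
    idx_alt_low: int,
) -> dict[str, np.ndarray]:
    """Vectorised GLM engine for many SNPs sharing one design shape.

    ``Y`` rows must follow the :class:`~dasekit.ase_counts.DesignMatrix`
    observation order (High samples then Low, a ref row then an alt row per
    sample).  Returns per-SNP arrays: p_high, p_low, p_diff, log2fc,
    delta_high, delta_low, alpha, loglik, converged, boundary.
    """
    Y = np.asarray(Y, dtype=float)
    S, m = Y.shape
    p = X.shape[1]
    df = max(m - p, 1)

    # boundary: a group with all-zero counts for one allele has an infinite
    # allele coefficient; flagged, not fit
    high_rows = X[:, 1] == 1.0
    alt_rows = (X[:, idx_alt_high] == 1.0) | (X[:, idx_alt_low] == 1.0)
    zero_tot = np.zeros(S, dtype=bool)
    for g_rows in (high_rows, ~high_rows):
        for a_rows in (alt_rows, ~alt_rows):
            zero_tot |= Y[:, g_rows & a_rows].sum(axis=1) == 0

    out = {
        k: np.full(S, np.nan)
        for k in ("p_high", "p_low", "p_diff", "log2fc", "delta_high", "delta_low", "alpha", "loglik")
    }
    out["converged"] = np.zeros(S, dtype=bool)
    out["boundary"] = zero_tot.copy()

    fit_idx = np.where(~zero_tot)[0]
    if fit_idx.size == 0:
        return out
    beta, cov, alpha, ll, converged = _nb_profile_fit(Y[fit_idx], X)

    dh = beta[:, idx_alt_high]
    dl = beta[:, idx_alt_low]
    se_h = np.sqrt(np.maximum(cov[:, idx_alt_high, idx_alt_high], 0.0))
    se_l = np.sqrt(np.maximum(cov[:, idx_alt_low, idx_alt_low], 0.0))
    var_d = (
        cov[:, idx_alt_high, idx_alt_high]
        + cov[:, idx_alt_low, idx_alt_low]
        - 2.0 * cov[:, idx_alt_high, idx_alt_low]
    )
    se_d = np.sqrt(np.maximum(var_d, 1e-300))
    with np.errstate(divide="ignore", invalid="ignore"):
        out["p_high"][fit_idx] = 2.0 * stats.t.sf(np.abs(dh) / np.maximum(se_h, 1e-300), df)
        out["p_low"][fit_idx] = 2.0 * stats.t.sf(np.abs(dl) / np.maximum(se_l, 1e-300), df)
        out["p_diff"][fit_idx] = 2.0 * stats.t.sf(np.abs(dh - dl) / se_d, df)
    out["log2fc"][fit_idx] = (np.abs(dh) - np.abs(dl)) / _LN2
    out["delta_high"][fit_idx] = dh
    out["delta_low"][fit_idx] = dl
    out["alpha"][fit_idx] = alpha
    out["loglik"][fit_idx] = ll
    out["converged"][fit_idx] = converged
    return out


def fit_dase_glm(design: DesignMatrix) -> tuple[ModelFit, DaseResult]:
    """Fit the NB interaction GLM for one testable SNP.

    Wald tests: ``p_high`` for delta_High = 0 (allelic imbalance within the
    High group), ``p_low`` for delta_Low = 0, ``p_diff`` for
    delta_High = delta_Low (differential imbalance).  The log2 fold-change is
    (|delta_High| - |delta_Low|) / ln 2, so positive values mean more
    imbalance in the High group.
    """
    res = fit_dase_glm_batch(
        design.y[None, :], design.X, design.idx_alt_high, design.idx_alt_low
    )
    s = 0
    beta_full = np.full(len(design.colnames), np.nan)
    fit = ModelFit(
        coefficients={},
        dispersion=float(res["alpha"][s]),
        loglik=float(res["loglik"][s]),
        boundary=bool(res["boundary"][s]),
    )
    if not res["boundary"][s]:
        # refit bookkeeping for the coefficient map / vcov
        beta, cov, alpha, ll, conv = _nb_profile_fit(design.y[None, :], design.X)
        fit.coefficients = dict(zip(design.colnames, beta[0]))
        fit.vcov = cov[0]
    result = DaseResult(
        snp_id=design.snp_id,
        trait=design.trait,
        p_high=float(res["p_high"][s]),
        p_low=float(res["p_low"][s]),
        p_diff=float(res["p_diff"][s]),
        log2fc=float(res["log2fc"][s]),
        n_high=design.n_high,
        n_low=design.n_low,
        engine="glm",
        converged=bool(res["converged"][s]),
        boundary=bool(res["boundary"][s]),
    )
    return fit, result


# ---------------------------------------------------------------------------
# Beta-binomial engine
# ---------------------------------------------------------------------------


def betabin_loglik(
    alt: np.ndarray, n: np.ndarray, pi: float | np.ndarray, rho: float | np.ndarray
) -> np.ndarray:
    """Beta-binomial log-likelihood (binomial at rho = 0), summed over samples.

    Broadcasts over trailing grid dimensions of ``pi``/``rho``; the sample
    axis of ``alt``/``n`` must be the last axis of the broadcast inputs.
    """
    alt = np.asarray(alt, dtype=float)
    n = np.asarray(n, dtype=float)
    pi = np.asarray(pi, dtype=float)
    rho = np.asarray(rho, dtype=float)
    binom_term = special.gammaln(n + 1) - special.gammaln(alt + 1) - special.gammaln(n - alt + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = (1.0 - rho) / np.where(rho > 0, rho, 1.0)
        a = pi * c
        b = (1.0 - pi) * c
        bb = (
            binom_term
            + special.betaln(alt + a, n - alt + b)
            - special.betaln(a, b)
        )
        bi = binom_term + special.xlogy(alt, pi) + special.xlog1py(n - alt, -pi)
    out = np.where(np.broadcast_to(rho, bb.shape) < 1e-12, bi, bb)
    return out.sum(axis=-1)


def _bb_mle(
    groups: Sequence[tuple[np.ndarray, np.ndarray]],
    fixed_pi: Sequence[float | None],
    tie_pi: bool,
    rho_max: float = 0.95,
) -> tuple[list[float], float, float, bool]:
    """Maximise the joint beta-binomial likelihood over free pi's and shared rho.

    ``groups``: [(alt, n), ...]; ``fixed_pi[i]`` pins group i's pi; ``tie_pi``
    forces a single common pi.  Returns (pi per group, rho, loglik,
    rho_at_zero_boundary).
    """
    k = len(groups)

    def pis_from(x: np.ndarray) -> list[float]:
        if tie_pi:
            return [x[0]] * k
        out, j = [], 0
        for f in fixed_pi:
            if f is None:
                out.append(x[j])
                j += 1
            else:
                out.append(f)
        return out

    n_free = 1 if tie_pi else sum(f is None for f in fixed_pi)

    def negll(x: np.ndarray) -> float:
        pis, rho = pis_from(x[:n_free]), x[n_free]
        total = 0.0
        for (alt, n), pi in zip(groups, pis):
            total += betabin_loglik(alt, n, pi, rho)
        return -float(total)

    # moment starts
    if tie_pi:
        alt_all = np.concatenate([g[0] for g in groups])
        n_all = np.concatenate([g[1] for g in groups])
        starts_pi = [np.clip(alt_all.sum() / n_all.sum(), 1e-3, 1 - 1e-3)]
    else:
        starts_pi = [
            np.clip(alt.sum() / n.sum(), 1e-3, 1 - 1e-3)
            for (alt, n), f in zip(groups, fixed_pi)
            if f is None
        ]
    eps = 1e-4
    bounds = [(eps, 1 - eps)] * n_free + [(1e-6, rho_max)]
    best = None
    for rho0 in (0.02, 0.15):
        x0 = np.array(starts_pi + [rho0])
        try:
            r = optimize.minimize(negll, x0, method="L-BFGS-B", bounds=bounds)
        except (ValueError, FloatingPointError):  # pragma: no cover
            continue
        if best is None or r.fun < best.fun:
            best = r
    if best is None:  # pragma: no cover
        raise RuntimeError("beta-binomial optimisation failed")

    # exact rho = 0 (pure binomial) profile: closed-form pi MLEs
    if tie_pi:
        alt_all = np.concatenate([g[0] for g in groups])
        n_all = np.concatenate([g[1] for g in groups])
        pis0 = [float(np.clip(alt_all.sum() / max(n_all.sum(), 1.0), eps, 1 - eps))] * k
    else:
        pis0 = [
            f
            if f is not None
            else float(np.clip(alt.sum() / max(n.sum(), 1.0), eps, 1 - eps))
            for (alt, n), f in zip(groups, fixed_pi)
        ]
    ll0 = sum(float(betabin_loglik(alt, n, pi, 0.0)) for (alt, n), pi in zip(groups, pis0))

    if ll0 >= -best.fun:
        return pis0, 0.0, ll0, True
    pis = pis_from(best.x[:n_free])
    return [float(p) for p in pis], float(best.x[n_free]), float(-best.fun), False


def fit_dase_betabin(
    high: tuple[np.ndarray, np.ndarray],
    low: tuple[np.ndarray, np.ndarray],
    snp_id: str = "",
    trait: str = "",
    which: Iterable[str] = ("high", "low", "diff"),
) -> tuple[ModelFit, DaseResult]:
    """Beta-binomial likelihood-ratio engine for one SNP.

    Parameters
    ----------
    high, low
        Per-group count pairs ``(alt, total)`` as equal-length arrays; zero
        total depths must have been excluded upstream.
    which
        Which of the three tests to compute (the others are NaN); restricting
        to ``("diff",)`` roughly halves the work in large simulations.

    Notes
    -----
    The shared overdispersion rho is estimated jointly with (pi_High, pi_Low);
    when the rho MLE sits on the zero boundary the fit degrades gracefully to
    binomial likelihoods and the boundary flag is set.
    """
    alt_h = np.asarray(high[0], dtype=float)
    n_h = np.asarray(high[1], dtype=float)
    alt_l = np.asarray(low[0], dtype=float)
    n_l = np.asarray(low[1], dtype=float)
    if alt_h.size < 1 or alt_l.size < 1:
        raise ValueError("both groups need at least one sample")
    if (n_h <= 0).any() or (n_l <= 0).any():
        raise ValueError("zero-depth samples must be excluded upstream")
    which = set(which)

    groups = [(alt_h, n_h), (alt_l, n_l)]
    pis, rho, ll_full, at_zero = _bb_mle(groups, [None, None], tie_pi=False)
    pi_h, pi_l = pis

    # Small-sample reference: the 1-df LRT is referred to F(1, n - 2) (the
    # t-squared analogue with the two-sample residual df) instead of
    # chi-square(1); with the handful of samples these tests retain, the
    # estimated dispersion makes the chi-square reference anticonservative.
    # F(1, n - 2) -> chi-square(1) as n grows.
    df_ref = max(alt_h.size + alt_l.size - 2, 1)

    def lrt(ll_null: float) -> float:
        return float(stats.f.sf(max(2.0 * (ll_full - ll_null), 0.0), 1, df_ref))

    p_high = p_low = p_diff = float("nan")
    if "high" in which:
        _, _, ll0, _ = _bb_mle(groups, [0.5, None], tie_pi=False)
        p_high = lrt(ll0)
    if "low" in which:
        _, _, ll0, _ = _bb_mle(groups, [None, 0.5], tie_pi=False)
        p_low = lrt(ll0)
    if "diff" in which:
        _, _, ll0, _ = _bb_mle(groups, [None, None], tie_pi=True)
        p_diff = lrt(ll0)

    eps = 1e-6
    odds = lambda p: np.log2(np.clip(p, eps, 1 - eps) / (1 - np.clip(p, eps, 1 - eps)))
    log2fc = float(np.abs(odds(pi_h)) - np.abs(odds(pi_l)))

    fit = ModelFit(
        coefficients={"pi_high": pi_h, "pi_low": pi_l},
        dispersion=rho,
        loglik=ll_full,
        boundary=at_zero,
    )
    result = DaseResult(
        snp_id=snp_id,
        trait=trait,
        p_high=p_high,
        p_low=p_low,
        p_diff=p_diff,
        log2fc=log2fc,
        n_high=int(alt_h.size),
        n_low=int(alt_l.size),
        engine="betabin",
        converged=True,
        boundary=at_zero,
    )
    return fit, result


# ---------------------------------------------------------------------------
# Multiple testing and direction
# ---------------------------------------------------------------------------


def adjust_fdr(
    results: pd.DataFrame,
    by: str | Sequence[str] = "trait",
    per_gene: bool = False,
) -> pd.DataFrame:
    """Benjamini-Hochberg adjustment of ``p_diff`` within each trait stratum.

    Unconverged tests (or tests without a p-value) are excluded from the
    strata and keep ``fdr = NaN``.  With ``per_gene=True`` the strata are
    trait x gene cells (requires a ``gene_id`` column).
    """
    if isinstance(by, str):
        by = [by]
    by = list(by)
    if per_gene:
        if "gene_id" not in results.columns:
            raise ValueError("per_gene FDR requires a 'gene_id' column")
        by = by + ["gene_id"]
    out = results.copy()
    out["fdr"] = np.nan
    usable = out["p_diff"].notna()
    if "converged" in out.columns:
        usable &= out["converged"].astype(bool)
    for _, block in out[usable].groupby(by, sort=False):
        _, fdr, _, _ = multipletests(block["p_diff"].to_numpy(), method="fdr_bh")
        out.loc[block.index, "fdr"] = fdr
    return out


def classify_direction(log2fc: float) -> str:
    """Which group shows the larger allelic imbalance.

    Negative log2 fold-changes mean the imbalance is larger in the Low group,
    positive in the High group, zero is undirected.
    """
    if np.isnan(log2fc):
        return "undirected"
    if log2fc < 0:
        return "Low"
    if log2fc > 0:
        return "High"
    return "undirected"
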