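"""Calibration and validation studies for the DASE engines.

Each function simulates data at stated study conditions with a known ground
truth, runs the package's own machinery, and reports an operating
characteristic: type-I error, power, false-discovery proportion, parameter
recovery, oracle agreement, permutation-null calibration and full-pipeline
determinism.  These are the quantities a user should inspect before trusting
the engines on real data; they are also what the repository's acceptance
checks recompute.
"""

from __future__ import annotations

import filecmp
from pathlib import Path
import numpy as np
import pandas as pd

from . import integration, pipeline
from .ase_counts import nested_design
from .dase_model import adjust_fdr, betabin_loglik, fit_dase_betabin, fit_dase_glm_batch
from .synthetic_data import SimConfig, simulate_group_counts

__all__ = [
    "glm_pvalues_from_counts",
    "type1_error_study",
    "power_study",
    "recovery_study",
    "fdr_control_study",
    "betabin_grid_gap",
    "overlap_oracle_mismatches",
    "permutation_calibration_study",
    "pipeline_determinism_check",
]


def glm_pvalues_from_counts(
    alt_h: np.ndarray, dep_h: np.ndarray, alt_l: np.ndarray, dep_l: np.ndarray
) -> dict[str, np.ndarray]:
    """Run the batched GLM engine on (n_snps x n_group) count matrices."""
    S, nh = alt_h.shape
    nl = alt_l.shape[1]
    X, ih, il = nested_design(nh, nl)
    Y = np.zeros((S, 2 * (nh + nl)))
    Y[:, 0 : 2 * nh : 2] = dep_h - alt_h
    Y[:, 1 : 2 * nh : 2] = alt_h
    Y[:, 2 * nh :: 2] = dep_l - alt_l
    Y[:, 2 * nh + 1 :: 2] = alt_l
    return fit_dase_glm_batch(Y, X, ih, il)


def _betabin_pdiff(alt_h, dep_h, alt_l, dep_l) -> np.ndarray:
    out = np.empty(alt_h.shape[0])
    for s in range(alt_h.shape[0]):
        _, r = fit_dase_betabin(
            (alt_h[s], dep_h[s]), (alt_l[s], dep_l[s]), which=("diff",)
        )
        out[s] = r.p_diff
    return out


def type1_error_study(
    engine: str = "glm",
    n_snps: int = 2000,
    n_per_group: int = 6,
    mean_depth: float = 50.0,
    rho: float = 0.02,
    pi: float = 0.5,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Empirical type-I error of the between-group test on null SNPs."""
    ah, dh, al, dl = simulate_group_counts(
        n_snps, n_per_group, n_per_group, pi, pi, rho, mean_depth, seed=seed
    )
    if engine == "glm":
        p = glm_pvalues_from_counts(ah, dh, al, dl)["p_diff"]
    elif engine == "betabin":
        p = _betabin_pdiff(ah, dh, al, dl)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    p = p[np.isfinite(p)]
    return {"rate": float(np.mean(p < alpha)), "n": int(p.size), "alpha": alpha}


def power_study(
    pi_shift: float,
    engine: str = "glm",
    n_snps: int = 500,
    n_per_group: int = 10,
    mean_depth: float = 100.0,
    rho: float = 0.02,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Empirical power at a given allelic-ratio shift in the High group."""
    ah, dh, al, dl = simulate_group_counts(
        n_snps, n_per_group, n_per_group, 0.5 + pi_shift, 0.5, rho, mean_depth, seed=seed
    )
    if engine == "glm":
        p = glm_pvalues_from_counts(ah, dh, al, dl)["p_diff"]
    else:
        p = _betabin_pdiff(ah, dh, al, dl)
    p = p[np.isfinite(p)]
    return {"power": float(np.mean(p < alpha)), "n": int(p.size), "shift": pi_shift}


def recovery_study(
    pi_high: float = 0.7,
    pi_low: float = 0.5,
    rho: float = 0.05,
    n_per_group: int = 200,
    mean_depth: float = 100.0,
    seed: int = 0,
) -> dict[str, float]:
    """Beta-binomial MLE error against the generating (pi_High, pi_Low, rho)."""
    ah, dh, al, dl = simulate_group_counts(
        1, n_per_group, n_per_group, pi_high, pi_low, rho, mean_depth, seed=seed
    )
    fit, _ = fit_dase_betabin((ah[0], dh[0]), (al[0], dl[0]), which=())
    return {
        "pi_high_hat": fit.coefficients["pi_high"],
        "pi_low_hat": fit.coefficients["pi_low"],
        "rho_hat": fit.dispersion,
        "pi_high_err": abs(fit.coefficients["pi_high"] - pi_high),
        "pi_low_err": abs(fit.coefficients["pi_low"] - pi_low),
        "rho_err": abs(fit.dispersion - rho),
    }


def fdr_control_study(
    n_snps: int = 5000,
    dase_fraction: float = 0.1,
    pi_shift: float = 0.25,
    n_seeds: int = 20,
    n_per_group: int = 6,
    mean_depth: float = 50.0,
    rho: float = 0.02,
    min_depth: int = 10,
    min_animals: int = 3,
    fdr_alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """False-discovery proportion of BH-adjusted calls in mixed simulations.

    Each replicate simulates ``n_snps`` SNPs of which ``dase_fraction`` carry
    a genuine shift of ``pi_shift`` in the High group; the study's depth and
    group-size filters are applied before testing; BH is applied per
    replicate and the false-discovery proportion of fdr <= ``fdr_alpha``
    calls is averaged over replicates (replicates without calls contribute
    power only).
    """
    rng = np.random.default_rng(seed)
    fdps: list[float] = []
    powers: list[float] = []
    n_calls_total = 0
    for _ in range(n_seeds):
        is_dase = rng.random(n_snps) < dase_fraction
        pi_h = np.where(is_dase, 0.5 + pi_shift, 0.5)
        ah, dh, al, dl = simulate_group_counts(
            n_snps, n_per_group, n_per_group, 0.5, 0.5, rho, mean_depth, seed=rng
        )
        # re-draw High alt counts at the per-SNP ratio (vectorised truth mix)
        c = (1.0 - rho) / rho
        a_par = np.broadcast_to(pi_h[:, None] * c, dh.shape)
        b_par = np.broadcast_to((1.0 - pi_h[:, None]) * c, dh.shape)
        pp = rng.beta(a_par, b_par)
        ah = rng.binomial(dh, pp)

        keep_h = dh >= min_depth
        keep_l = dl >= min_depth
        testable = (keep_h.sum(axis=1) >= min_animals) & (keep_l.sum(axis=1) >= min_animals)
        # batch by inclusion counts; samples are exchangeable so order is free
        frames = []
        kh, kl = keep_h.sum(axis=1), keep_l.sum(axis=1)
        for nh in range(min_animals, n_per_group + 1):
            for nl in range(min_animals, n_per_group + 1):
                snps = np.where(testable & (kh == nh) & (kl == nl))[0]
                if snps.size == 0:
                    continue
                A_h = np.zeros((snps.size, nh), dtype=np.int64)
                D_h = np.zeros_like(A_h)
                A_l = np.zeros((snps.size, nl), dtype=np.int64)
                D_l = np.zeros_like(A_l)
                for i, s in enumerate(snps):
                    hs = np.where(keep_h[s])[0]
                    ls = np.where(keep_l[s])[0]
                    A_h[i], D_h[i] = ah[s, hs], dh[s, hs]
                    A_l[i], D_l[i] = al[s, ls], dl[s, ls]
                res = glm_pvalues_from_counts(A_h, D_h, A_l, D_l)
                frames.append(
                    pd.DataFrame(
                        {
                            "snp": snps,
                            "p_diff": res["p_diff"],
                            "converged": res["converged"],
                            "is_dase": is_dase[snps],
                        }
                    )
                )
        results = pd.concat(frames, ignore_index=True)
        results["trait"] = "sim"
        results = adjust_fdr(results)
        called = results["fdr"] <= fdr_alpha
        n_calls = int(called.sum())
        n_calls_total += n_calls
        if n_calls:
            fdps.append(float((called & ~results["is_dase"]).sum() / n_calls))
        n_true = int(results["is_dase"].sum())
        if n_true:
            powers.append(float((called & results["is_dase"]).sum() / n_true))
    return {
        "mean_fdp": float(np.mean(fdps)) if fdps else 0.0,
        "mean_power": float(np.mean(powers)) if powers else float("nan"),
        "n_seeds": n_seeds,
        "n_calls": n_calls_total,
    }


def betabin_grid_gap(n_instances: int = 50, n_per_group: int = 4, seed: int = 0) -> float:
    """Worst gap between the engine's maximised log-likelihood and a dense grid.

    The oracle maximises over a 50 x 50 x 20 grid on (pi_High, pi_Low, rho);
    a correct optimiser is never below the grid maximum (up to tolerance).
    Returns max(grid_max - loglik_hat) over instances (negative = engine wins
    everywhere).
    """
    rng = np.random.default_rng(seed)
    pis = np.linspace(0.02, 0.98, 50)
    rhos = np.linspace(0.0, 0.4, 20)
    worst = -np.inf
    for _ in range(n_instances):
        shift = rng.choice([0.0, 0.15, 0.3])
        ah, dh, al, dl = simulate_group_counts(
            1, n_per_group, n_per_group, 0.5 + shift, 0.5, 0.05, 60.0, seed=rng
        )
        fit, _ = fit_dase_betabin((ah[0], dh[0]), (al[0], dl[0]), which=())
        ll_h = betabin_loglik(ah[0], dh[0], pis[:, None, None], rhos[None, :, None])
        ll_l = betabin_loglik(al[0], dl[0], pis[:, None, None], rhos[None, :, None])
        grid_max = float((ll_h[:, None, :] + ll_l[None, :, :]).max())
        worst = max(worst, grid_max - fit.loglik)
    return worst


def overlap_oracle_mismatches(n_tracks: int = 100, n_intervals: int = 60, seed: int = 0) -> int:
    """Count disagreements between find_overlaps and the all-pairs oracle."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_tracks):
        def rand_track():
            contig = rng.choice(["1", "2"], size=n_intervals)
            start = rng.integers(0, 50_000, size=n_intervals)
            length = rng.integers(1, 2_000, size=n_intervals)
            return pd.DataFrame({"contig": contig, "start": start, "end": start + length})

        q, r = rand_track(), rand_track()
        got = integration.find_overlaps(q, r)
        got_pairs = set(zip(got["query_index"], got["ref_index"]))
        brute = {
            (qi, ri)
            for qi in q.index
            for ri in r.index
            if q.at[qi, "contig"] == r.at[ri, "contig"]
            and q.at[qi, "start"] < r.at[ri, "end"]
            and r.at[ri, "start"] < q.at[qi, "end"]
        }
        mismatches += got_pairs != brute
    return mismatches


def permutation_calibration_study(
    n_reps: int = 100, n_perm: int = 200, alpha: float = 0.05, seed: int = 0
) -> dict[str, float]:
    """Permutation p-values on independent uniform tracks are super-uniform."""
    rng = np.random.default_rng(seed)
    genome = {"1": 2_000_000}
    n_sig = 0
    for _ in range(n_reps):
        qs = rng.integers(0, genome["1"] - 200, size=30)
        rs = rng.integers(0, genome["1"] - 2000, size=40)
        q = pd.DataFrame({"contig": "1", "start": qs, "end": qs + 200})
        ref = pd.DataFrame({"contig": "1", "start": rs, "end": rs + 2000})
        r = integration.permutation_overlap_test(
            q, ref, genome, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        n_sig += r.p_value < alpha
    # self-overlap sanity: maximal enrichment reaches the permutation floor
    q = pd.DataFrame({"contig": "1", "start": np.arange(10) * 150_000, "end": np.arange(10) * 150_000 + 100})
    self_p = integration.permutation_overlap_test(q, q, genome, n_perm=n_perm, seed=seed).p_value
    return {
        "frac_significant": n_sig / n_reps,
        "n_reps": n_reps,
        "self_overlap_p": self_p,
        "perm_floor": 1.0 / (n_perm + 1),
    }


def pipeline_determinism_check(tmpdir: str | Path, seed: int = 0) -> bool:
    """Run the packaged synthetic pipeline twice; outputs must be byte-identical."""
    cfg = SimConfig(
        n_animals=60, n_sires=30, traits=("T1", "T2"), n_snps=60, het_prob=0.6,
        dase_fraction=0.2, seed=seed,
    )
    tmpdir = Path(tmpdir)
    dirs = [tmpdir / "run1", tmpdir / "run2"]
    for d in dirs:
        pipeline.run_pipeline(cfg, outdir=d, n_per_group=10, n_perm=100)
    names = sorted(p.name for p in dirs[0].iterdir())
    if names != sorted(p.name for p in dirs[1].iterdir()):
        return False
    return all(
        filecmp.cmp(dirs[0] / name, dirs[1] / name, shallow=False) for name in names
    )
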