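"""End-to-end orchestration of the DASE analysis.

`test_trait` runs the testability filters and the chosen statistical engine
over all SNPs for one trait; `run_dase` does so across traits and applies the
per-trait FDR; `run_pipeline` wires the synthetic generators, group
selection, testing, feature integration and reporting into one deterministic
run.  The GLM engine is batched across SNPs that retain the same number of
qualifying samples per group (those share a design matrix), which is what
makes simulation studies with tens of thousands of SNPs tractable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import ase_counts, dase_model, group_selection, integration, reporting, synthetic_data
from .group_selection import ContrastGroups
from .synthetic_data import Population, SimConfig

__all__ = ["test_trait", "run_dase", "run_pipeline", "PipelineResult"]


def _snp_meta(counts: pd.DataFrame) -> pd.DataFrame:
    return counts[["variantID", "contig", "position"]].drop_duplicates("variantID").set_index(
        "variantID"
    )


def test_trait(
    counts: pd.DataFrame,
    groups: ContrastGroups,
    engine: str = "glm",
    min_depth: int = 10,
    min_animals: int = 3,
    which: Sequence[str] = ("high", "low", "diff"),
) -> pd.DataFrame:
    """Test every testable SNP for one trait's contrasting groups.

    Returns one row per testable SNP with the three p-values, log2 fold
    change, group sizes and convergence flags (no FDR yet — that is applied
    across traits by :func:`run_dase`).
    """
    testable = ase_counts.filter_testable(counts, groups, min_depth, min_animals)
    if not testable:
        return pd.DataFrame(
            columns=[
                "snp_id", "trait", "contig", "position", "n_high", "n_low",
                "p_high", "p_low", "p_diff", "log2fc", "direction", "engine",
                "converged", "boundary",
            ]
        )
    meta = _snp_meta(counts)
    sub = counts[counts["variantID"].isin(testable)]
    tot = {}
    for (snp, sample), block in sub.groupby(["variantID", "sample_id"], sort=False):
        rec = block.iloc[0]
        tot[(snp, sample)] = (int(rec["altCount"]), int(rec["refCount"]) + int(rec["altCount"]))

    rows: list[dict] = []
    if engine == "glm":
        # batch SNPs by (n_high, n_low): identical design shape
        by_shape: dict[tuple[int, int], list[str]] = {}
        for snp_id, inc in testable.items():
            by_shape.setdefault((len(inc["high"]), len(inc["low"])), []).append(snp_id)
        for (nh, nl), snp_ids in sorted(by_shape.items()):
            X, ih, il = ase_counts.nested_design(nh, nl)
            Y = np.zeros((len(snp_ids), 2 * (nh + nl)))
            for s, snp_id in enumerate(snp_ids):
                inc = testable[snp_id]
                r = 0
                for sample in inc["high"] + inc["low"]:
                    alt, total = tot[(snp_id, sample)]
                    Y[s, r] = total - alt
                    Y[s, r + 1] = alt
                    r += 2
            res = dase_model.fit_dase_glm_batch(Y, X, ih, il)
            for s, snp_id in enumerate(snp_ids):
                rows.append(
                    {
                        "snp_id": snp_id,
                        "n_high": nh,
                        "n_low": nl,
                        "p_high": res["p_high"][s],
                        "p_low": res["p_low"][s],
                        "p_diff": res["p_diff"][s],
                        "log2fc": res["log2fc"][s],
                        "converged": bool(res["converged"][s]),
                        "boundary": bool(res["boundary"][s]),
                    }
                )
    elif engine == "betabin":
        for snp_id, inc in sorted(testable.items()):
            ah, nh_tot = zip(*(tot[(snp_id, s)] for s in inc["high"]))
            al, nl_tot = zip(*(tot[(snp_id, s)] for s in inc["low"]))
            _, r = dase_model.fit_dase_betabin(
                (np.array(ah), np.array(nh_tot)),
                (np.array(al), np.array(nl_tot)),
                snp_id=snp_id,
                trait=groups.trait,
                which=which,
            )
            rows.append(
                {
                    "snp_id": snp_id,
                    "n_high": r.n_high,
                    "n_low": r.n_low,
                    "p_high": r.p_high,
                    "p_low": r.p_low,
                    "p_diff": r.p_diff,
                    "log2fc": r.log2fc,
                    "converged": r.converged,
                    "boundary": r.boundary,
                }
            )
    else:
        raise ValueError(f"unknown engine {engine!r} (expected 'glm' or 'betabin')")

    out = pd.DataFrame(rows)
    out["trait"] = groups.trait
    out["engine"] = engine
    out["contig"] = out["snp_id"].map(meta["contig"])
    out["position"] = out["snp_id"].map(meta["position"])
    out["direction"] = [dase_model.classify_direction(fc) for fc in out["log2fc"]]
    return out.sort_values("snp_id", kind="stable").reset_index(drop=True)


def run_dase(
    counts: pd.DataFrame,
    groups_by_trait: Mapping[str, ContrastGroups],
    engine: str = "glm",
    min_depth: int = 10,
    min_animals: int = 3,
    fdr_alpha: float = 0.05,
    per_gene_fdr: bool = False,
) -> pd.DataFrame:
    """Run the DASE test for every trait and apply BH FDR within trait."""
    frames = [
        test_trait(counts, groups, engine=engine, min_depth=min_depth, min_animals=min_animals)
        for trait, groups in sorted(groups_by_trait.items())
    ]
    frames = [f for f in frames if not f.empty]
    if not frames:
        return pd.DataFrame()
    results = pd.concat(frames, ignore_index=True)
    return dase_model.adjust_fdr(results, by="trait", per_gene=per_gene_fdr)


@dataclass
class PipelineResult:
    population: Population
    groups: dict[str, ContrastGroups]
    counts: pd.DataFrame
    truth: pd.DataFrame
    results: pd.DataFrame
    summary: pd.DataFrame
    tracks: dict[str, pd.DataFrame]
    overlap_tests: dict[str, integration.OverlapTestResult]
    annotated: pd.DataFrame
    per_gene: pd.DataFrame


def run_pipeline(
    config: SimConfig,
    outdir: str | Path | None = None,
    engine: str = "glm",
    n_per_group: int = 20,
    max_per_sire: int = 1,
    min_depth: int = 10,
    min_animals: int = 3,
    fdr_alpha: float = 0.05,
    window: int = 200_000,
    n_perm: int = 1000,
    genome_sizes: Mapping[str, int] | None = None,
    n_track_regions: int = 200,
    track_mean_length: float = 5_000.0,
) -> PipelineResult:
    """Full synthetic study: simulate, select groups, test, integrate, report.

    Everything derives from ``config.seed``; two runs with the same config
    produce byte-identical output tables.  When ``outdir`` is given the
    standard TSV/JSON outputs are written there.
    """
    genome = dict(genome_sizes or synthetic_data.DEFAULT_GENOME)
    population = synthetic_data.simulate_population(config)
    groups = {
        trait: group_selection.select_contrast_groups(
            population.animals, trait, n_per_group=n_per_group, max_per_sire=max_per_sire
        )
        for trait in config.traits
    }
    counts, truth = synthetic_data.simulate_allele_counts(
        population, config, groups, genome_sizes=genome
    )
    results = run_dase(
        counts,
        groups,
        engine=engine,
        min_depth=min_depth,
        min_animals=min_animals,
        fdr_alpha=fdr_alpha,
    )
    summary = reporting.summarize_per_trait(results, truth=truth, fdr_alpha=fdr_alpha)

    # synthetic regulatory track + gene map for the integration stage
    track = synthetic_data.simulate_feature_tracks(
        genome, n_track_regions, track_mean_length, seed=config.seed, label="reg"
    )
    gene_map = synthetic_data.simulate_feature_tracks(
        genome, n_track_regions, 10 * track_mean_length, seed=config.seed + 1, label="gene"
    ).rename(columns={"name": "gene_id"})
    tracks = {"regulatory": track}

    sig = results[results["fdr"] <= fdr_alpha] if len(results) else results
    overlap_tests: dict[str, integration.OverlapTestResult] = {}
    if len(sig):
        query = pd.DataFrame(
            {
                "contig": sig["contig"].astype(str),
                "start": sig["position"].astype(np.int64) - 1,
                "end": sig["position"].astype(np.int64),
            }
        ).drop_duplicates()
        for name, t in tracks.items():
            overlap_tests[name] = integration.permutation_overlap_test(
                query, t, genome, n_perm=n_perm, seed=config.seed
            )
    annotated, per_gene = (
        integration.annotate_dase(
            results, gene_map=gene_map, tracks=tracks, genome_sizes=genome, width=window
        )
        if len(results)
        else (results, pd.DataFrame(columns=["gene_id", "n_dase_snps"]))
    )

    result = PipelineResult(
        population=population,
        groups=groups,
        counts=counts,
        truth=truth,
        results=results,
        summary=summary,
        tracks=tracks,
        overlap_tests=overlap_tests,
        annotated=annotated,
        per_gene=per_gene,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        synthetic_data.write_gebv_tsv(population.gebv, outdir / "gebv.tsv")
        synthetic_data.write_pedigree_tsv(population.pedigree, outdir / "pedigree.tsv")
        synthetic_data.write_ase_counts_tsv(counts, outdir / "ase_counts.tsv")
        synthetic_data.write_bed(track, outdir / "regulatory.bed")
        for trait, grp in groups.items():
            group_selection.write_groups_tsv(grp, outdir / f"groups_{trait}.tsv")
        results.to_csv(outdir / "dase_results.tsv", sep="\t", index=False)
        summary.to_csv(outdir / "trait_summary.tsv", sep="\t", index=False)
        annotated.to_csv(outdir / "dase_annotated.tsv", sep="\t", index=False)
        per_gene.to_csv(outdir / "per_gene_counts.tsv", sep="\t", index=False)
        if overlap_tests:
            pd.DataFrame(
                [{"track": k, **vars(v)} for k, v in overlap_tests.items()]
            ).to_csv(outdir / "overlap_tests.tsv", sep="\t", index=False)
        reporting.write_manifest(
            outdir / "manifest.json",
            inputs={
                "gebv": outdir / "gebv.tsv",
                "pedigree": outdir / "pedigree.tsv",
                "ase_counts": outdir / "ase_counts.tsv",
            },
            params={
                "engine": engine,
                "n_per_group": n_per_group,
                "max_per_sire": max_per_sire,
                "min_depth": min_depth,
                "min_animals": min_animals,
                "fdr_alpha": fdr_alpha,
                "window": window,
                "n_perm": n_perm,
            },
            seeds={"master": config.seed},
            engine=engine,
        )
    return result
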