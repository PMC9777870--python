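"""Windowed integration of DASE SNPs with genomic feature tracks.

SNP tables are 1-based (VCF/ASEReadCounter convention); interval tracks are
BED-style 0-based half-open.  Conversion between the two happens in exactly
one place (:func:`snp_to_interval`).  Enrichment of observed overlaps is
assessed with a permutation test that re-places the query features uniformly
at random within their own chromosomes, preserving lengths — the standard
region-randomisation null for genomic interval sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "OverlapTestResult",
    "snp_to_interval",
    "window_around",
    "find_overlaps",
    "permutation_overlap_test",
    "annotate_dase",
    "read_bed",
    "read_genome_sizes",
]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    contig: str
    start: int
    end: int
    label: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class OverlapTestResult:
    observed: int
    perm_mean: float
    perm_sd: float
    z: float
    p_value: float
    n_perm: int
    seed: int


def snp_to_interval(contig: str, position: int) -> GenomicInterval:
    """Single-base interval for a 1-based SNP position."""
    if position < 1:
        raise ValueError(f"1-based position must be >= 1, got {position}")
    return GenomicInterval(contig, position - 1, position)


def window_around(
    contig: str,
    position: int,
    genome_sizes: Mapping[str, int],
    width: int = 200_000,
) -> GenomicInterval:
    """Interval covering ``width`` bp up- and downstream of a 1-based SNP.

    The window is clamped to the chromosome bounds; ``width=0`` returns the
    single SNP base.
    """
    if contig not in genome_sizes:
        raise KeyError(f"unknown chromosome {contig!r}")
    if position < 1 or position > genome_sizes[contig]:
        raise ValueError(f"position {position} outside chromosome {contig!r}")
    start = max(0, position - 1 - width)
    end = min(int(genome_sizes[contig]), position + width)
    return GenomicInterval(contig, start, end)


def _as_track(track: pd.DataFrame) -> pd.DataFrame:
    missing = {"contig", "start", "end"} - set(track.columns)
    if missing:
        raise ValueError(f"track is missing columns {sorted(missing)}")
    bad = track["start"] >= track["end"]
    if bad.any():
        raise ValueError(f"{int(bad.sum())} interval(s) with start >= end")
    return track


def find_overlaps(query: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """All (query, reference) pairs sharing at least one base.

    Half-open semantics: intervals touching end-to-start do not overlap.
    Returns a DataFrame with the original index labels of both tracks
    (``query_index``, ``ref_index``); per-query overlap counts follow from a
    groupby on ``query_index``.
    """
    if len(query) == 0 or len(reference) == 0:
        return pd.DataFrame(columns=["query_index", "ref_index"])
    query = _as_track(query)
    reference = _as_track(reference)
    pairs_q: list = []
    pairs_r: list = []
    for contig, q in query.groupby("contig", sort=False):
        r = reference[reference["contig"] == contig]
        if r.empty:
            continue
        # sweep: sort reference by start; candidates via searchsorted window,
        # then filter on end > query start
        r = r.sort_values("start")
        r_start = r["start"].to_numpy()
        r_end = r["end"].to_numpy()
        r_idx = r.index.to_numpy()
        # prefix max of ends lets us bound how far left a candidate can sit
        for qi, qs, qe in zip(q.index.to_numpy(), q["start"].to_numpy(), q["end"].to_numpy()):
            hi = np.searchsorted(r_start, qe, side="left")  # start < q.end
            if hi == 0:
                continue
            sel = r_end[:hi] > qs
            hits = r_idx[:hi][sel]
            pairs_q.extend([qi] * len(hits))
            pairs_r.extend(hits)
    return pd.DataFrame({"query_index": pairs_q, "ref_index": pairs_r})


def _merged_by_contig(track: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merge intervals per contig into sorted disjoint (starts, ends)."""
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for contig, block in track.groupby("contig", sort=False):
        b = block.sort_values("start")
        starts = b["start"].to_numpy(dtype=np.int64)
        ends = b["end"].to_numpy(dtype=np.int64)
        ms, me = [], []
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                ms.append(cur_s)
                me.append(cur_e)
                cur_s, cur_e = s, e
        ms.append(cur_s)
        me.append(cur_e)
        merged[contig] = (np.asarray(ms), np.asarray(me))
    return merged


def _hits_any(
    starts: np.ndarray, lengths: np.ndarray, ref: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    """Whether intervals [s, s+L) overlap any merged reference interval."""
    r_start, r_end = ref
    lengths = np.broadcast_to(lengths, starts.shape)
    idx = np.searchsorted(r_end, starts, side="right")  # first ref with end > s
    ok = idx < len(r_start)
    hit = np.zeros(starts.shape, dtype=bool)
    hit[ok] = r_start[np.minimum(idx[ok], len(r_start) - 1)] < starts[ok] + lengths[ok]
    return hit


def permutation_overlap_test(
    query: pd.DataFrame,
    reference: pd.DataFrame,
    genome_sizes: Mapping[str, int],
    n_perm: int = 1000,
    seed: int = 0,
) -> OverlapTestResult:
    """Permutation test for enrichment of query/reference overlaps.

    The statistic is the number of query features overlapping at least one
    reference feature.  Under the null, query features are re-placed
    uniformly at random within their own chromosome, preserving their
    lengths.  ``p = (1 + #{perm >= observed}) / (n_perm + 1)`` (never zero);
    ``z = (observed - mean) / sd`` of the permutation distribution (NaN when
    the permutation distribution is degenerate).
    """
    query = _as_track(query)
    reference = _as_track(reference)
    for contig in query["contig"].unique():
        if contig not in genome_sizes:
            raise KeyError(f"genome sizes missing contig {contig!r}")
    lengths_ok = query["end"] - query["start"] <= query["contig"].map(genome_sizes)
    if not lengths_ok.all():
        bad = query[~lengths_ok]
        raise ValueError(
            "query feature(s) longer than their chromosome: "
            + ", ".join(f"{r.contig}:[{r.start},{r.end})" for r in bad.itertuples())
        )

    merged = _merged_by_contig(reference) if len(reference) else {}
    rng = np.random.default_rng(seed)

    observed = 0
    perm_counts = np.zeros(n_perm, dtype=np.int64)
    for contig, q in query.groupby("contig", sort=False):
        L = (q["end"] - q["start"]).to_numpy(dtype=np.int64)
        s_obs = q["start"].to_numpy(dtype=np.int64)
        ref = merged.get(contig)
        if ref is None:
            continue
        observed += int(_hits_any(s_obs, L, ref).sum())
        max_start = genome_sizes[contig] - L  # inclusive upper bound
        u = rng.random((n_perm, L.size))
        s_perm = (u * (max_start + 1)).astype(np.int64)
        perm_counts += _hits_any(s_perm, L[None, :], ref).sum(axis=1)

    perm_mean = float(perm_counts.mean())
    perm_sd = float(perm_counts.std(ddof=1)) if n_perm > 1 else 0.0
    z = (observed - perm_mean) / perm_sd if perm_sd > 0 else float("nan")
    p = (1.0 + float((perm_counts >= observed).sum())) / (n_perm + 1.0)
    return OverlapTestResult(
        observed=observed,
        perm_mean=perm_mean,
        perm_sd=perm_sd,
        z=z,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
    )


def _check_contigs(
    snp_contigs: set[str], track: pd.DataFrame, track_name: str
) -> None:
    if len(track) == 0 or not snp_contigs:
        return
    track_contigs = set(track["contig"].astype(str))
    if not (snp_contigs & track_contigs):
        raise ValueError(
            f"contig names of track {track_name!r} share nothing with the SNP "
            f"table: SNPs use {sorted(snp_contigs)}, track uses "
            f"{sorted(track_contigs)} (no silent chr-prefix coercion)"
        )


def annotate_dase(
    results: pd.DataFrame,
    gene_map: pd.DataFrame | None = None,
    tracks: Mapping[str, pd.DataFrame] | None = None,
    qtl: pd.DataFrame | None = None,
    genome_sizes: Mapping[str, int] | None = None,
    width: int = 200_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Integrate DASE results with genes, feature tracks and QTL lists.

    Per SNP: the overlapping gene(s), a ``<track>_snp_in_feature`` flag (the
    SNP base falls inside a feature), a ``<track>_feature_in_window`` flag (a
    feature lies within ``width`` bp of the SNP), and the trait names of QTLs
    within the window.  Also returns per-gene counts of DASE-significant SNPs.

    ``results`` needs ``snp_id``, ``contig``, ``position`` (1-based) columns;
    ``genome_sizes`` is required for windowed lookups (clamping needs the
    chromosome lengths).
    """
    required = {"snp_id", "contig", "position"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table is missing columns {sorted(missing)}")
    tracks = dict(tracks or {})
    out = results.copy()
    snp_contigs = set(out["contig"].astype(str))

    snps = out[["snp_id", "contig", "position"]].drop_duplicates("snp_id").reset_index(drop=True)
    base = pd.DataFrame(
        {
            "contig": snps["contig"].astype(str),
            "start": snps["position"].astype(np.int64) - 1,
            "end": snps["position"].astype(np.int64),
        }
    )
    if genome_sizes is not None:
        windows = pd.DataFrame(
            [
                window_around(c, int(p), genome_sizes, width).__dict__
                for c, p in zip(base["contig"], snps["position"])
            ]
        )[["contig", "start", "end"]]
    else:
        windows = pd.DataFrame(
            {
                "contig": base["contig"],
                "start": np.maximum(base["start"] - width, 0),
                "end": base["end"] + width,
            }
        )

    # gene assignment
    gene_of: dict[str, str] = {}
    if gene_map is not None and len(gene_map):
        _check_contigs(snp_contigs, gene_map, "gene_map")
        pairs = find_overlaps(base, gene_map.reset_index(drop=True))
        for qi, block in pairs.groupby("query_index"):
            genes = sorted(gene_map.reset_index(drop=True).loc[block["ref_index"], "gene_id"].astype(str))
            gene_of[snps.loc[qi, "snp_id"]] = ",".join(genes)
    if "gene_id" not in out.columns:
        out["gene_id"] = out["snp_id"].map(gene_of)
    else:
        out["gene_id"] = out["gene_id"].fillna(out["snp_id"].map(gene_of))

    # per-track flags
    for name, track in tracks.items():
        _check_contigs(snp_contigs, track, name)
        in_feat = np.zeros(len(snps), dtype=bool)
        in_win = np.zeros(len(snps), dtype=bool)
        if len(track):
            t = track.reset_index(drop=True)
            hits = find_overlaps(base, t)
            if len(hits):
                in_feat[hits["query_index"].to_numpy(dtype=np.int64)] = True
            hits = find_overlaps(windows, t)
            if len(hits):
                in_win[hits["query_index"].to_numpy(dtype=np.int64)] = True
        out[f"{name}_snp_in_feature"] = out["snp_id"].map(dict(zip(snps["snp_id"], in_feat)))
        out[f"{name}_feature_in_window"] = out["snp_id"].map(dict(zip(snps["snp_id"], in_win)))

    # QTL trait names within the window
    if qtl is not None and len(qtl):
        _check_contigs(snp_contigs, qtl, "qtl")
        if "trait" not in qtl.columns:
            raise ValueError("qtl table needs a 'trait' column")
        q = qtl.reset_index(drop=True)
        qtl_traits: dict[str, str] = {}
        pairs = find_overlaps(windows, q)
        for qi, block in pairs.groupby("query_index"):
            names = sorted(set(q.loc[block["ref_index"], "trait"].astype(str)))
            qtl_traits[snps.loc[qi, "snp_id"]] = ",".join(names)
        out["qtl_traits"] = out["snp_id"].map(qtl_traits)
    elif qtl is not None:
        out["qtl_traits"] = pd.Series(np.nan, index=out.index, dtype=object)

    # per-gene DASE SNP counts (significant calls when an fdr column exists)
    sig = out
    if "fdr" in out.columns:
        sig = out[out["fdr"] <= 0.05]
    per_gene = (
        sig.dropna(subset=["gene_id"])
        .groupby("gene_id")["snp_id"]
        .nunique()
        .rename("n_dase_snps")
        .reset_index()
        .sort_values(["n_dase_snps", "gene_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return out, per_gene


def read_bed(path, source: str | None = None) -> pd.DataFrame:
    """Read a BED3+ track (0-based half-open)."""
    raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if raw.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    track = raw.iloc[:, :4] if raw.shape[1] >= 4 else raw.iloc[:, :3]
    track.columns = ["contig", "start", "end", "name"][: track.shape[1]]
    track = track.copy()
    track["start"] = track["start"].astype(np.int64)
    track["end"] = track["end"].astype(np.int64)
    if source:
        track["source"] = source
    return _as_track(track)


def read_genome_sizes(path) -> dict[str, int]:
    sizes = pd.read_csv(path, sep="\t", header=None, names=["contig", "length"], dtype={0: str})
    return dict(zip(sizes["contig"], sizes["length"].astype(int)))
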