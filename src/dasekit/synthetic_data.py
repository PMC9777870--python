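"""Synthetic data generation for the DASE pipeline.

Emulates the inputs of a differential allele-specific expression study on a
half-sib cattle population: genomic estimated breeding values (GEBVs) with a
sire-level genetic component, heterozygous SNP panels with overdispersed
allelic read counts, and genomic feature tracks.  Every generator is
deterministic under a fixed master seed; each stage draws from its own named
substream so that, e.g., regenerating feature tracks does not perturb the
allelic counts.

Ground truth (which SNPs carry a genuine group-dependent allelic imbalance,
and in which direction) is returned alongside the counts so downstream tests
can measure power and false-discovery rates against known labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "Population",
    "DEFAULT_GENOME",
    "simulate_population",
    "simulate_allele_counts",
    "simulate_feature_tracks",
    "simulate_group_counts",
    "write_gebv_tsv",
    "write_pedigree_tsv",
    "write_ase_counts_tsv",
    "write_bed",
]

# Two-chromosome toy genome used when the caller does not supply sizes.
DEFAULT_GENOME: dict[str, int] = {"1": 50_000_000, "2": 30_000_000}

# Named substreams: every stage derives its generator from the master seed
# plus a fixed spawn key, so stages are independently reproducible.
_STAGES = {"population": 0, "gebv": 1, "snps": 2, "truth": 3, "counts": 4, "tracks": 5}

_BASES = np.array(list("ACGT"))


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGES[stage],)))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the structure of the emulated experiment: 190 steers from
    34 sires, allelic counts at mean depth 50 with mild beta-binomial
    overdispersion (rho = 0.02), a balanced baseline allelic ratio of 0.5 and
    an additive shift of 0.25 for truly differential SNPs in one contrasting
    group.
    """

    n_animals: int = 190
    n_sires: int = 34
    traits: tuple[str, ...] = ("WBSF0", "REA", "BFT")
    n_snps: int = 1000
    mean_depth: float = 50.0
    depth_dispersion: float = 5.0
    het_prob: float = 0.3
    rho: float = 0.02
    dase_fraction: float = 0.1
    pi_null: float = 0.5
    pi_shift: float = 0.25
    seed: int = 0
    # GEBV variance components: half-sib correlation = sire_sd^2/(sire_sd^2+resid_sd^2)
    sire_sd: float = 0.5
    resid_sd: float = 1.0

    def validate(self) -> None:
        if self.n_animals < 1:
            raise ValueError(f"n_animals must be >= 1, got {self.n_animals}")
        if not 1 <= self.n_sires <= self.n_animals:
            raise ValueError(
                f"n_sires must be in [1, n_animals={self.n_animals}], got {self.n_sires}"
            )
        if len(self.traits) == 0:
            raise ValueError("traits must be non-empty")
        if self.n_snps < 0:
            raise ValueError(f"n_snps must be >= 0, got {self.n_snps}")
        if self.mean_depth <= 0:
            raise ValueError(f"mean_depth must be > 0, got {self.mean_depth}")
        if self.depth_dispersion <= 0:
            raise ValueError(f"depth_dispersion must be > 0, got {self.depth_dispersion}")
        for name in ("het_prob", "dase_fraction", "pi_null"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if not 0.0 < self.pi_null + self.pi_shift < 1.0:
            raise ValueError(
                f"pi_null + pi_shift must be in (0, 1), got {self.pi_null + self.pi_shift}"
            )
        if self.sire_sd < 0 or self.resid_sd < 0:
            raise ValueError("sire_sd and resid_sd must be >= 0")


class Population(NamedTuple):
    """Animals with sires and GEBVs, plus the two on-disk table views."""

    animals: pd.DataFrame  # animal_id, sire_id, one column per trait
    gebv: pd.DataFrame  # animal_id + trait columns
    pedigree: pd.DataFrame  # animal_id, sire_id


def simulate_population(config: SimConfig) -> Population:
    """Draw a half-sib population and per-trait GEBVs.

    Each animal is assigned exactly one of ``n_sires`` sires (each sire is
    guaranteed at least one progeny).  GEBVs are the sum of a Gaussian sire
    effect and an individual Gaussian residual, so paternal half-sibs are
    positively correlated.
    """
    config.validate()
    rng = _rng(config.seed, "population")

    sire_ids = np.array([f"S{i + 1:03d}" for i in range(config.n_sires)])
    animal_ids = np.array([f"A{i + 1:04d}" for i in range(config.n_animals)])
    # First pass guarantees every sire appears; remaining dams drawn uniformly.
    assignment = np.concatenate(
        [
            np.arange(config.n_sires),
            rng.integers(0, config.n_sires, size=config.n_animals - config.n_sires),
        ]
    )
    assignment = rng.permutation(assignment)

    grng = _rng(config.seed, "gebv")
    gebv = {}
    for trait in config.traits:
        sire_eff = grng.normal(0.0, config.sire_sd, size=config.n_sires)
        resid = grng.normal(0.0, config.resid_sd, size=config.n_animals)
        gebv[trait] = sire_eff[assignment] + resid

    animals = pd.DataFrame({"animal_id": animal_ids, "sire_id": sire_ids[assignment], **gebv})
    gebv_table = animals.drop(columns="sire_id")
    pedigree = animals[["animal_id", "sire_id"]].copy()
    return Population(animals, gebv_table, pedigree)


def _draw_depths(rng: np.random.Generator, size: int, mean: float, dispersion: float) -> np.ndarray:
    """Zero-truncated gamma-Poisson (negative binomial) read depths."""
    p = dispersion / (dispersion + mean)
    d = rng.negative_binomial(dispersion, p, size=size)
    zero = d == 0
    # redraw zeros: a zero-depth site carries no allelic signal
    while zero.any():
        d[zero] = rng.negative_binomial(dispersion, p, size=int(zero.sum()))
        zero = d == 0
    return d


def _draw_beta_binomial(
    rng: np.random.Generator, n: np.ndarray, pi: np.ndarray, rho: float
) -> np.ndarray:
    """Alt-allele counts: binomial at rho=0, beta-binomial otherwise."""
    if rho == 0.0:
        return rng.binomial(n, pi)
    c = (1.0 - rho) / rho
    p = rng.beta(pi * c, (1.0 - pi) * c)
    return rng.binomial(n, p)


def simulate_allele_counts(
    population: Population,
    config: SimConfig,
    contrast_groups: Mapping[str, object] | None = None,
    genome_sizes: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-sample allelic read counts at heterozygous SNPs.

    Parameters
    ----------
    population
        Output of :func:`simulate_population`.
    config
        Simulation parameters; ``dase_fraction`` controls the proportion of
        SNPs with a genuine between-group difference in allelic imbalance.
    contrast_groups
        Mapping trait -> object with ``high`` and ``low`` sample-id
        collections (e.g. :class:`dasekit.group_selection.ContrastGroups`).
        Required when ``dase_fraction > 0``: a true-DASE SNP shifts the
        alternate-allele ratio by ``pi_shift`` for the members of one
        (randomly designated) contrasting group of one randomly assigned
        trait.
    genome_sizes
        Chromosome lengths for SNP placement; defaults to a small
        two-chromosome genome.

    Returns
    -------
    counts, truth
        ``counts`` is a long-format ASEReadCounter-style table (one row per
        sample x heterozygous SNP, 1-based positions).  ``truth`` has one row
        per (snp, trait) with ``is_dase`` and the generating allelic ratios
        ``pi_high`` / ``pi_low``.
    """
    config.validate()
    if population.animals.empty:
        raise ValueError("population is empty")
    genome = dict(genome_sizes or DEFAULT_GENOME)

    animal_ids = population.animals["animal_id"].to_numpy()
    animal_index = {a: i for i, a in enumerate(animal_ids)}

    groups = dict(contrast_groups or {})
    if config.dase_fraction > 0 and config.n_snps > 0 and not groups:
        raise ValueError("contrast_groups are required when dase_fraction > 0")
    for trait, grp in groups.items():
        for side in ("high", "low"):
            unknown = [a for a in getattr(grp, side) if a not in animal_index]
            if unknown:
                raise ValueError(f"group '{trait}'/{side} references unknown animals: {unknown}")

    # --- SNP panel ---------------------------------------------------------
    srng = _rng(config.seed, "snps")
    contigs = np.array(sorted(genome))
    lengths = np.array([genome[c] for c in contigs], dtype=float)
    chrom_idx = srng.choice(len(contigs), size=config.n_snps, p=lengths / lengths.sum())
    positions = (srng.random(config.n_snps) * lengths[chrom_idx]).astype(np.int64) + 1
    order = np.lexsort((positions, chrom_idx))
    chrom_idx, positions = chrom_idx[order], positions[order]
    snp_ids = np.array([f"snp{i + 1:05d}" for i in range(config.n_snps)])
    ref_alleles = _BASES[srng.integers(0, 4, size=config.n_snps)]
    alt_alleles = _BASES[
        (srng.integers(1, 4, size=config.n_snps) + np.searchsorted(_BASES, ref_alleles)) % 4
    ]

    # --- ground truth ------------------------------------------------------
    trng = _rng(config.seed, "truth")
    trait_names = [t for t in config.traits if t in groups] or list(config.traits)
    is_dase_snp = trng.random(config.n_snps) < (config.dase_fraction if groups else 0.0)
    assigned_trait = trng.integers(0, max(len(trait_names), 1), size=config.n_snps)
    shifted_high = trng.random(config.n_snps) < 0.5  # which group carries the shift

    truth_rows = []
    pi_alt = config.pi_null + config.pi_shift
    for trait in config.traits:
        pi_high = np.full(config.n_snps, config.pi_null)
        pi_low = np.full(config.n_snps, config.pi_null)
        if trait in trait_names:
            t_idx = trait_names.index(trait)
            mask = is_dase_snp & (assigned_trait == t_idx)
            pi_high[mask & shifted_high] = pi_alt
            pi_low[mask & ~shifted_high] = pi_alt
        else:
            mask = np.zeros(config.n_snps, dtype=bool)
        truth_rows.append(
            pd.DataFrame(
                {
                    "snp_id": snp_ids,
                    "trait": trait,
                    "is_dase": mask,
                    "pi_high": pi_high,
                    "pi_low": pi_low,
                }
            )
        )
    truth = pd.concat(truth_rows, ignore_index=True)

    # --- per-animal allelic ratios ----------------------------------------
    # pi matrix (snp x animal); conflicts cannot arise because each true-DASE
    # SNP is tied to exactly one trait.
    pi = np.full((config.n_snps, len(animal_ids)), config.pi_null)
    for t_idx, trait in enumerate(trait_names):
        grp = groups.get(trait)
        if grp is None:
            continue
        high_cols = [animal_index[a] for a in grp.high]
        low_cols = [animal_index[a] for a in grp.low]
        mask = is_dase_snp & (assigned_trait == t_idx)
        rows_high = np.where(mask & shifted_high)[0]
        rows_low = np.where(mask & ~shifted_high)[0]
        if rows_high.size and high_cols:
            pi[np.ix_(rows_high, high_cols)] = pi_alt
        if rows_low.size and low_cols:
            pi[np.ix_(rows_low, low_cols)] = pi_alt

    # --- counts ------------------------------------------------------------
    crng = _rng(config.seed, "counts")
    het = crng.random((config.n_snps, len(animal_ids))) < config.het_prob
    snp_row, animal_col = np.nonzero(het)
    depths = _draw_depths(crng, snp_row.size, config.mean_depth, config.depth_dispersion)
    alt = _draw_beta_binomial(crng, depths, pi[snp_row, animal_col], config.rho)

    counts = pd.DataFrame(
        {
            "sample_id": animal_ids[animal_col],
            "contig": contigs[chrom_idx[snp_row]],
            "position": positions[snp_row],
            "variantID": snp_ids[snp_row],
            "refAllele": ref_alleles[snp_row],
            "altAllele": alt_alleles[snp_row],
            "refCount": depths - alt,
            "altCount": alt,
        }
    )
    return counts, truth


def simulate_feature_tracks(
    genome_sizes: Mapping[str, int],
    n_regions: int,
    mean_length: float,
    seed: int,
    label: str = "feature",
) -> pd.DataFrame:
    """Place ``n_regions`` intervals uniformly at random across the genome.

    Chromosomes are chosen with probability proportional to their length;
    interval lengths are geometric with the given mean (minimum 1 bp).
    Coordinates are 0-based half-open and clipped inside the chromosome.
    """
    if not genome_sizes:
        raise ValueError("genome_sizes must be non-empty")
    if any(length <= 0 for length in genome_sizes.values()):
        raise ValueError("genome sizes must be positive")
    shortest = min(genome_sizes.values())
    if mean_length >= shortest:
        raise ValueError(
            f"mean_length ({mean_length}) must be smaller than the shortest "
            f"chromosome ({shortest})"
        )
    if n_regions < 0:
        raise ValueError(f"n_regions must be >= 0, got {n_regions}")

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGES["tracks"],)))
    contigs = np.array(sorted(genome_sizes))
    lengths = np.array([genome_sizes[c] for c in contigs], dtype=np.int64)
    if n_regions == 0:
        return pd.DataFrame(columns=["contig", "start", "end", "name"])

    chrom_idx = rng.choice(len(contigs), size=n_regions, p=lengths / lengths.sum())
    feat_len = rng.geometric(min(1.0, 1.0 / mean_length), size=n_regions)
    feat_len = np.minimum(feat_len, lengths[chrom_idx])
    start = (rng.random(n_regions) * (lengths[chrom_idx] - feat_len + 1)).astype(np.int64)
    return pd.DataFrame(
        {
            "contig": contigs[chrom_idx],
            "start": start,
            "end": start + feat_len,
            "name": [f"{label}{i + 1:05d}" for i in range(n_regions)],
        }
    )


def simulate_group_counts(
    n_snps: int,
    n_high: int,
    n_low: int,
    pi_high: float,
    pi_low: float,
    rho: float,
    mean_depth: float,
    depth_dispersion: float = 5.0,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Directly simulate allelic counts for two groups at many SNPs.

    A convenience generator for calibration studies that bypasses the
    population layer: depths are zero-truncated negative binomial, alternate
    counts beta-binomial with group-specific ratios.  Returns
    ``(alt_high, depth_high, alt_low, depth_low)``, each ``(n_snps, n_group)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for n_g, pi in ((n_high, pi_high), (n_low, pi_low)):
        d = _draw_depths(rng, n_snps * n_g, mean_depth, depth_dispersion).reshape(n_snps, n_g)
        alt = _draw_beta_binomial(rng, d, np.full((n_snps, n_g), pi), rho)
        out.extend([alt, d])
    return out[0], out[1], out[2], out[3]


# --- writers (TSV/BED dialects used by the rest of the pipeline) -----------


def write_gebv_tsv(gebv: pd.DataFrame, path) -> None:
    gebv.to_csv(path, sep="\t", index=False)


def write_pedigree_tsv(pedigree: pd.DataFrame, path) -> None:
    pedigree.to_csv(path, sep="\t", index=False)


def write_ase_counts_tsv(counts: pd.DataFrame, path) -> None:
    """Write the long-format multi-sample ASEReadCounter-dialect table."""
    counts.to_csv(path, sep="\t", index=False)


def write_bed(track: pd.DataFrame, path) -> None:
    cols = [c for c in ("contig", "start", "end", "name") if c in track.columns]
    track[cols].to_csv(path, sep="\t", index=False, header=False)
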