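"""Selection of phenotypically contrasting groups from breeding values.

Animals are ranked by their genomic estimated breeding value (GEBV) for a
trait; the top and bottom ``n_per_group`` form the High and Low groups,
subject to a sire-diversity constraint that caps how many progeny of one sire
may enter the same group (half-sibs share genetics, so stacking a single
sire's offspring into one group would confound family and group effects).
Group separation is verified with a two-sample Student's t-test, and the
trait-by-trait relationship of the GEBVs is summarised as a Pearson
correlogram.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnimalRecord",
    "ContrastGroups",
    "GroupSelectionError",
    "select_contrast_groups",
    "verify_group_separation",
    "gebv_correlation_matrix",
    "classify_correlation_signs",
    "read_gebv_tsv",
    "read_pedigree_tsv",
    "write_groups_tsv",
]


class GroupSelectionError(ValueError):
    """Raised when the contrasting groups cannot be filled as requested."""


@dataclass(frozen=True)
class AnimalRecord:
    animal_id: str
    sire_id: str
    gebv: Mapping[str, float]


@dataclass
class ContrastGroups:
    """High/Low contrasting groups for one trait."""

    trait: str
    high: tuple[str, ...]
    low: tuple[str, ...]
    t_pvalue: float = float("nan")
    n_per_group: int = 0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if set(self.high) & set(self.low):
            raise ValueError("high and low groups overlap")
        if self.n_per_group == 0:
            self.n_per_group = len(self.high)

    def members(self) -> set[str]:
        return set(self.high) | set(self.low)


def _greedy_pick(
    ordered: pd.DataFrame, n: int, max_per_sire: int, taken: set[str]
) -> list[str]:
    """Scan animals in rank order, skipping over-represented sires."""
    picked: list[str] = []
    per_sire: dict[str, int] = {}
    for row in ordered.itertuples(index=False):
        if len(picked) == n:
            break
        if row.animal_id in taken:
            continue
        if per_sire.get(row.sire_id, 0) >= max_per_sire:
            continue
        picked.append(row.animal_id)
        per_sire[row.sire_id] = per_sire.get(row.sire_id, 0) + 1
    return picked


def select_contrast_groups(
    animals: pd.DataFrame,
    trait: str,
    n_per_group: int = 20,
    max_per_sire: int = 1,
) -> ContrastGroups:
    """Build High/Low groups of size ``n_per_group`` for ``trait``.

    The High group is filled by a greedy scan from the highest GEBV downwards;
    an animal is skipped if its sire already has ``max_per_sire`` members in
    that group.  The Low group is then filled symmetrically from the bottom,
    excluding animals already allocated to High.  GEBV ties are broken by
    ascending animal id.

    Parameters
    ----------
    animals
        Table with columns ``animal_id``, ``sire_id`` and one column per
        trait (``NaN`` GEBVs are treated as missing).

    Raises
    ------
    GroupSelectionError
        If either group cannot be filled; the message reports how many slots
        could be filled.
    """
    if trait not in animals.columns:
        raise KeyError(f"trait {trait!r} not found in animal table")
    if n_per_group < 1:
        raise ValueError(f"n_per_group must be >= 1, got {n_per_group}")
    if max_per_sire < 1:
        raise ValueError(f"max_per_sire must be >= 1, got {max_per_sire}")

    eligible = animals.loc[animals[trait].notna(), ["animal_id", "sire_id", trait]]
    if len(eligible) < 2 * n_per_group:
        raise GroupSelectionError(
            f"trait {trait!r}: need {2 * n_per_group} animals with a GEBV, "
            f"have {len(eligible)}"
        )

    desc = eligible.sort_values([trait, "animal_id"], ascending=[False, True])
    asc = eligible.sort_values([trait, "animal_id"], ascending=[True, True])

    high = _greedy_pick(desc, n_per_group, max_per_sire, taken=set())
    low = _greedy_pick(asc, n_per_group, max_per_sire, taken=set(high))
    if len(high) < n_per_group or len(low) < n_per_group:
        raise GroupSelectionError(
            f"trait {trait!r}: sire constraint (max_per_sire={max_per_sire}) "
            f"infeasible; filled {len(high)}/{n_per_group} High and "
            f"{len(low)}/{n_per_group} Low slots"
        )

    groups = ContrastGroups(trait=trait, high=tuple(high), low=tuple(low), n_per_group=n_per_group)
    gebv = eligible.set_index("animal_id")[trait]
    p, degenerate = verify_group_separation(gebv.loc[list(high)], gebv.loc[list(low)])
    groups.t_pvalue = p
    groups.degenerate = degenerate
    return groups


def verify_group_separation(
    high: Sequence[float], low: Sequence[float], welch: bool = False
) -> tuple[float, bool]:
    """Two-sided two-sample t-test p-value on High vs Low GEBVs.

    The classical pooled-variance Student's test is the default; Welch's
    unequal-variance variant is available via ``welch=True``.  Degenerate
    zero-variance inputs follow the convention p = 1 for identical means and
    p = 0 otherwise, with the degenerate flag set.

    Returns
    -------
    (p_value, degenerate)
    """
    a = np.asarray(high, dtype=float)
    b = np.asarray(low, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 members")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return (1.0, False) if a.mean() == b.mean() else (0.0, True)
    t = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t.pvalue), False


def gebv_correlation_matrix(gebv: pd.DataFrame, min_animals: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between trait GEBVs.

    Pairs with fewer than ``min_animals`` complete observations, and traits
    with zero variance, are reported as missing (NaN) rather than zero.
    """
    traits = [c for c in gebv.columns if c != "animal_id"]
    corr = gebv[traits].corr(method="pearson", min_periods=min_animals)
    # enforce exact symmetry and a unit diagonal for non-constant traits
    vals = corr.to_numpy()
    vals = (vals + vals.T) / 2.0
    corr = pd.DataFrame(vals, index=corr.index, columns=corr.columns)
    return corr


def classify_correlation_signs(corr: pd.DataFrame, tol: float = 0.0) -> pd.DataFrame:
    """Map a correlation matrix to 'negative'/'zero'/'positive'/'missing'."""

    def cls(v: float) -> str:
        if np.isnan(v):
            return "missing"
        if v > tol:
            return "positive"
        if v < -tol:
            return "negative"
        return "zero"

    return corr.map(cls)


def read_gebv_tsv(path) -> pd.DataFrame:
    gebv = pd.read_csv(path, sep="\t")
    if "animal_id" not in gebv.columns:
        raise ValueError(f"{path}: GEBV table must have an 'animal_id' column")
    return gebv


def read_pedigree_tsv(path) -> pd.DataFrame:
    ped = pd.read_csv(path, sep="\t")
    missing = {"animal_id", "sire_id"} - set(ped.columns)
    if missing:
        raise ValueError(f"{path}: pedigree is missing columns {sorted(missing)}")
    return ped


def merge_population(gebv: pd.DataFrame, pedigree: pd.DataFrame) -> pd.DataFrame:
    """Join GEBVs with the pedigree into the animal table used for selection."""
    merged = pedigree.merge(gebv, on="animal_id", how="inner", validate="one_to_one")
    return merged


def read_groups_tsv(path) -> dict[str, ContrastGroups]:
    """Read group-membership TSV (trait, group, animal_id) back into objects."""
    df = pd.read_csv(path, sep="\t")
    missing = {"trait", "group", "animal_id"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: groups table is missing columns {sorted(missing)}")
    out: dict[str, ContrastGroups] = {}
    for trait, block in df.groupby("trait", sort=True):
        high = tuple(block.loc[block["group"] == "High", "animal_id"].astype(str))
        low = tuple(block.loc[block["group"] == "Low", "animal_id"].astype(str))
        out[str(trait)] = ContrastGroups(trait=str(trait), high=high, low=low)
    return out


def write_groups_tsv(groups: ContrastGroups, path) -> None:
    rows = [(groups.trait, "High", a) for a in groups.high] + [
        (groups.trait, "Low", a) for a in groups.low
    ]
    pd.DataFrame(rows, columns=["trait", "group", "animal_id"]).to_csv(
        path, sep="\t", index=False
    )
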