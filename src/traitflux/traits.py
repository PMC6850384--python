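"""Fuzzy-coded trait tables and Gower dissimilarity with Podani's extension.

Traits are discrete: each trait (block) is a set of categories, and every
taxon carries an affinity in [0, 1] to each category, the affinities of one
block summing to 1 (fuzzy coding).  A taxon expressing a single category
has affinity 1 there; a taxon splitting its habit across categories has
fractions.  Blocks are typed nominal, ordinal (categories carry an order)
or fuzzy; ordinal blocks enter the Gower dissimilarity through Podani's
tied-rank formula, all other blocks as range-normalised quantitative
columns with equal total weight per trait.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from skbio import DistanceMatrix

__all__ = [
    "TraitBlock",
    "TraitMatrix",
    "validate_trait_matrix",
    "gower_distance",
    "read_trait_csv",
    "write_trait_csv",
]

VALID_TYPES = ("nominal", "ordinal", "fuzzy")


@dataclass(frozen=True)
class TraitBlock:
    """One trait: its name, ordered category labels, and coding type."""

    name: str
    categories: tuple
    kind: str = "fuzzy"

    def __post_init__(self):
        if self.kind not in VALID_TYPES:
            raise ValueError(f"trait type must be one of {VALID_TYPES}, got {self.kind!r}")
        if len(self.categories) < 2:
            raise ValueError(f"trait {self.name!r} needs >= 2 categories")
        object.__setattr__(self, "categories", tuple(self.categories))


@dataclass(frozen=True)
class TraitMatrix:
    """Taxa x trait-category affinity matrix organised in trait blocks.

    ``affinity`` is indexed by taxon with a (trait, category) column
    MultiIndex; within each block a taxon's affinities sum to 1.
    """

    affinity: pd.DataFrame
    blocks: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.affinity.index.has_duplicates:
            raise ValueError("duplicate taxa in trait matrix")
        if not isinstance(self.affinity.columns, pd.MultiIndex):
            raise ValueError("affinity columns must be a (trait, category) MultiIndex")
        blocks = tuple(self.blocks)
        declared = {b.name: b for b in blocks}
        traits_in_cols = list(dict.fromkeys(self.affinity.columns.get_level_values(0)))
        if set(declared) != set(traits_in_cols):
            raise ValueError("trait blocks do not match affinity columns")
        for b in blocks:
            cols = tuple(self.affinity[b.name].columns)
            if cols != b.categories:
                raise ValueError(
                    f"category labels/order mismatch for trait {b.name!r}: "
                    f"{cols} vs declared {b.categories}"
                )
        object.__setattr__(self, "blocks", blocks)

    @property
    def taxa(self) -> list:
        return list(self.affinity.index)

    @property
    def categories(self) -> list:
        """Flat (trait, category) column labels in block order."""
        return list(self.affinity.columns)

    def block(self, name: str) -> pd.DataFrame:
        return self.affinity[name]

    def subset(self, taxa) -> "TraitMatrix":
        missing = [t for t in taxa if t not in self.affinity.index]
        if missing:
            raise KeyError(f"taxa absent from trait matrix: {missing}")
        return TraitMatrix(affinity=self.affinity.loc[list(taxa)], blocks=self.blocks)


def validate_trait_matrix(tm: TraitMatrix, tol: float = 1e-9) -> list:
    """Check fuzzy-coding constraints; return a list of violation strings.

    A well-formed matrix yields an empty list.  Reported problems:
    out-of-range affinities, per-taxon block sums deviating from 1 by more
    than ``tol``, and empty (all-zero) blocks.
    """
    report = []
    vals = tm.affinity.to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)):
        report.append("non-finite affinities present")
    bad = np.argwhere((vals < 0) | (vals > 1))
    for i, j in bad:
        report.append(
            f"affinity out of [0,1]: taxon {tm.affinity.index[i]!r}, "
            f"column {tm.affinity.columns[j]} = {vals[i, j]:g}"
        )
    for b in tm.blocks:
        blk = tm.block(b.name).to_numpy(dtype=float)
        if not blk.any():
            report.append(f"trait block {b.name!r} is all-zero")
        sums = blk.sum(axis=1)
        for i in np.nonzero(np.abs(sums - 1.0) > tol)[0]:
            report.append(
                f"block sum != 1: taxon {tm.affinity.index[i]!r}, "
                f"trait {b.name!r}, sum = {sums[i]:.6g}"
            )
    return report


def _ordinal_contribution(block: pd.DataFrame) -> np.ndarray | None:
    """Podani's tied-rank dissimilarity for one ordinal trait block.

    The (possibly fuzzy) affinities over ordered categories are collapsed
    to an affinity-weighted mean category score per taxon, ranked with
    ties, and compared with Podani's correction that discounts tie-group
    sizes from both the numerator and the range.  Returns an n x n
    contribution matrix in [0, 1], or None if all taxa tie (zero range).
    """
    scores = block.to_numpy(dtype=float) @ np.arange(block.shape[1], dtype=float)
    r = rankdata(scores, method="average")
    # tie-group size for each taxon's rank value
    _, inv, counts = np.unique(r, return_inverse=True, return_counts=True)
    tie = counts[inv].astype(float)
    rmax_i, rmin_i = np.argmax(r), np.argmin(r)
    denom = (r[rmax_i] - r[rmin_i]) - (tie[rmax_i] - 1) / 2.0 - (tie[rmin_i] - 1) / 2.0
    if denom <= 0:
        return None
    num = np.abs(r[:, None] - r[None, :]) - (tie[:, None] - 1) / 2.0 - (tie[None, :] - 1) / 2.0
    return np.clip(num / denom, 0.0, 1.0)


def gower_distance(tm: TraitMatrix) -> DistanceMatrix:
    """Pairwise Gower dissimilarity over the taxon pool, Podani extension.

    Nominal and fuzzy blocks contribute per category column
    ``|a_i - a_j| / range``, the range taken over the taxon pool; each
    block's columns share weight 1/(block size) so that every trait
    carries equal total weight.  Ordinal blocks contribute one tied-rank
    Podani term with weight 1.  Zero-range columns (and all-tied ordinal
    blocks) are dropped from both numerator and denominator.  The result
    is symmetric with zero diagonal, values in [0, 1].
    """
    n = len(tm.taxa)
    if n < 2:
        raise ValueError("Gower distance needs at least 2 taxa")
    problems = [p for p in validate_trait_matrix(tm) if "all-zero" in p]
    if problems:
        raise ValueError("; ".join(problems))
    num = np.zeros((n, n))
    wsum = 0.0
    for b in tm.blocks:
        block = tm.block(b.name)
        if b.kind == "ordinal":
            contrib = _ordinal_contribution(block)
            if contrib is not None:
                num += contrib
                wsum += 1.0
        else:
            a = block.to_numpy(dtype=float)
            w_col = 1.0 / a.shape[1]
            for c in range(a.shape[1]):
                col = a[:, c]
                rng = col.max() - col.min()
                if rng <= 0:
                    continue
                num += w_col * np.abs(col[:, None] - col[None, :]) / rng
                wsum += w_col
    if wsum == 0:
        d = np.zeros((n, n))
    else:
        d = num / wsum
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=[str(t) for t in tm.taxa])


def write_trait_csv(tm: TraitMatrix, path) -> None:
    """Write the long trait table: taxon, trait, category, affinity, trait_type."""
    kind = {b.name: b.kind for b in tm.blocks}
    long = (
        tm.affinity.stack([0, 1], future_stack=True)
        .rename("affinity")
        .rename_axis(["taxon", "trait", "category"])
        .reset_index()
    )
    long["trait_type"] = long["trait"].map(kind)
    long.to_csv(path, index=False)


def read_trait_csv(path) -> TraitMatrix:
    """Read the long trait table written by :func:`write_trait_csv`.

    Category order within each trait follows first appearance in the file,
    which for ordinal traits must therefore be their declared order.
    """
    df = pd.read_csv(path)
    required = {"taxon", "trait", "category", "affinity"}
    if not required.issubset(df.columns):
        raise ValueError(f"trait CSV must have columns {sorted(required)}")
    blocks = []
    for trait, sub in df.groupby("trait", sort=False):
        cats = tuple(dict.fromkeys(sub["category"]))
        kind = str(sub["trait_type"].iloc[0]) if "trait_type" in df.columns else "fuzzy"
        blocks.append(TraitBlock(name=str(trait), categories=cats, kind=kind))
    taxa = list(dict.fromkeys(df["taxon"]))
    cols = pd.MultiIndex.from_tuples(
        [(b.name, c) for b in blocks for c in b.categories], names=["trait", "category"]
    )
    wide = df.pivot_table(
        index="taxon", columns=["trait", "category"], values="affinity", aggfunc="first"
    ).reindex(index=taxa, columns=cols)
    if wide.isna().any().any():
        raise ValueError("trait CSV is missing taxon x category affinities")
    return TraitMatrix(affinity=wide, blocks=tuple(blocks))
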