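"""Per-year taxonomic and functional diversity indices.

Four complementary indices per sampled year:

* SRic — species (taxon) richness, the number of taxa present.
* TRic — trait richness, the number of trait categories expressed by at
  least one present taxon (non-weighted).
* FEve — functional evenness: how evenly density is distributed along
  the minimum spanning tree of the community in trait space (in [0, 1];
  defined only for communities of at least three taxa).
* FDis — functional dispersion: the density-weighted mean distance of
  taxa to the community's weighted centroid in trait space.

FEve and FDis operate on the Gower–Podani dissimilarity of the taxon
pool: FEve in its additively corrected principal-coordinate embedding,
FDis through the signed real/imaginary decomposition so that squared
centroid distances honour the original (possibly non-Euclidean)
dissimilarities, floored at zero.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform, pdist
from skbio import DistanceMatrix

from .community import CommunityTimeSeries
from .ordination import pcoa_embed, dual_embedding
from .traits import TraitMatrix, gower_distance

__all__ = [
    "species_richness",
    "trait_richness",
    "functional_evenness",
    "functional_dispersion",
    "diversity_series",
]


def species_richness(densities) -> int:
    """Number of taxa with density > 0."""
    arr = np.asarray(densities, dtype=float)
    if (arr < 0).any():
        raise ValueError("densities must be non-negative")
    return int((arr > 0).sum())


def trait_richness(densities, tm: TraitMatrix) -> int:
    """Number of trait categories with positive summed affinity over present taxa."""
    arr = np.asarray(densities, dtype=float)
    if arr.shape[0] != len(tm.taxa):
        raise ValueError("densities and trait matrix are misaligned")
    present = arr > 0
    if not present.any():
        return 0
    expressed = tm.affinity.to_numpy(dtype=float)[present].sum(axis=0) > 0
    return int(expressed.sum())


def functional_evenness(coords: np.ndarray, weights) -> float:
    """MST-based evenness of density distribution in trait space.

    ``coords`` are coordinates for all taxa in the pool (one row each);
    ``weights`` the per-taxon relative densities for one year.  Taxa with
    zero weight are excluded; with fewer than three present taxa the
    index is undefined (NaN, with a warning).  For each MST edge joining
    taxa i and j, the weighted evenness EW = dist(i,j)/(w_i + w_j) is
    computed, normalised to partial weights PEW = EW/sum(EW), and

        FEve = (sum min(PEW, 1/(S-1)) - 1/(S-1)) / (1 - 1/(S-1)).
    """
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != coords.shape[0]:
        raise ValueError("weights and coordinates are misaligned")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    present = w > 0
    s = int(present.sum())
    if s < 3:
        warnings.warn(f"FEve undefined for {s} < 3 present taxa", stacklevel=2)
        return float("nan")
    x = coords[present]
    wp = w[present]
    wp = wp / wp.sum()
    d = squareform(pdist(x))
    mst = minimum_spanning_tree(d).tocoo()
    ew = mst.data / (wp[mst.row] + wp[mst.col])
    pew = ew / ew.sum()
    thresh = 1.0 / (s - 1)
    return float((np.minimum(pew, thresh).sum() - thresh) / (1.0 - thresh))


def functional_dispersion(dm: DistanceMatrix, weights) -> float:
    """Density-weighted mean distance to the weighted centroid in trait space.

    Uses the real/imaginary eigen-decomposition of the dissimilarity
    matrix: squared centroid distances are the real-block squared
    distance minus the imaginary-block squared distance, floored at 0.
    Invariant to rescaling all weights by a positive constant.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != dm.shape[0]:
        raise ValueError("weights and distance matrix are misaligned")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("at least one weight must be positive")
    real, imag = dual_embedding(dm)
    wn = w / total
    c_real = wn @ real
    z2 = ((real - c_real) ** 2).sum(axis=1)
    if imag.size:
        c_imag = wn @ imag
        z2 = z2 - ((imag - c_imag) ** 2).sum(axis=1)
    z = np.sqrt(np.maximum(z2, 0.0))
    return float(wn @ z)


def diversity_series(
    cts: CommunityTimeSeries,
    tm: TraitMatrix,
    dm: DistanceMatrix | None = None,
) -> pd.DataFrame:
    """Compute SRic, TRic, FEve and FDis for every sampled year.

    ``cts.density`` supplies the per-year weights (pass an already
    ln-transformed community if ln weights are wanted, the study
    convention).  The trait matrix is aligned to the community's taxa;
    the Gower–Podani matrix is recomputed on that pool unless supplied.
    """
    tm = tm.subset(cts.taxa)
    if dm is None:
        dm = gower_distance(tm)
    emb = pcoa_embed(dm)
    rows = []
    for year in cts.density.index:
        dens = cts.density.loc[year].to_numpy(dtype=float)
        sric = species_richness(dens)
        tric = trait_richness(dens, tm)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            feve = functional_evenness(emb.coords, dens) if sric >= 3 else float("nan")
        fdis = functional_dispersion(dm, dens) if sric >= 1 else float("nan")
        rows.append(
            {"area": cts.area, "group": cts.group, "year": int(year),
             "SRic": sric, "TRic": tric, "FEve": feve, "FDis": fdis}
        )
    return pd.DataFrame(rows)
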