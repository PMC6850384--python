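"""Community-weighted mean (CWM) trait profiles and functional turnover.

The CWM combines trait scores with the density of individuals: for each
trait category c and year t,

    CWM_tc = sum_j w_jt * a_jc / sum_j w_jt,

with w_jt the (by default ln(x+1)-transformed) density of taxon j.  The
per-block fuzzy-coding identity (affinities of one trait summing to 1)
carries over exactly to the CWM whenever total weight is positive.

Functional turnover (Fturn) is the Euclidean distance between the CWM
vectors of subsequent sampled years — a density-and-identity sensitive
rate of multi-trait compositional change.  Pairs of adjacent sampled
years separated by a missing sampling year are reported but flagged.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .community import CommunityTimeSeries
from .traits import TraitMatrix

__all__ = ["community_weighted_mean", "cwm_series", "trait_turnover"]


def community_weighted_mean(densities, tm: TraitMatrix) -> np.ndarray:
    """CWM vector over all trait categories for one year's densities.

    Raises if total density is zero (the year is undefined and must be
    flagged by the caller).
    """
    w = np.asarray(densities, dtype=float)
    if w.shape[0] != len(tm.taxa):
        raise ValueError("densities and trait matrix are misaligned")
    if (w < 0).any():
        raise ValueError("densities must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total density: CWM undefined for this year")
    return (w @ tm.affinity.to_numpy(dtype=float)) / total


def cwm_series(cts: CommunityTimeSeries, tm: TraitMatrix) -> pd.DataFrame:
    """Per-year CWM matrix (years x trait categories).

    Pass an ln-transformed community for the study's ln weighting.
    Years with zero total density yield NaN rows.
    """
    tm = tm.subset(cts.taxa)
    out = np.full((len(cts.density.index), len(tm.categories)), np.nan)
    for i, year in enumerate(cts.density.index):
        dens = cts.density.loc[year].to_numpy(dtype=float)
        if dens.sum() > 0:
            out[i] = community_weighted_mean(dens, tm)
    return pd.DataFrame(out, index=cts.density.index.copy(), columns=tm.affinity.columns.copy())


def trait_turnover(cwm: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance between CWM vectors of subsequent sampled years.

    Returns a frame with columns ``year_from``, ``year_to``, ``Fturn``
    and ``spans_gap`` (True when the pair straddles at least one missing
    sampling year).  Only adjacent sampled years are compared.
    """
    defined = cwm.dropna(how="any")
    if len(defined) < 2:
        raise ValueError("turnover needs at least 2 years with defined CWM")
    years = defined.index.to_numpy()
    vals = defined.to_numpy(dtype=float)
    diffs = np.sqrt(((vals[1:] - vals[:-1]) ** 2).sum(axis=1))
    return pd.DataFrame(
        {
            "year_from": years[:-1].astype(int),
            "year_to": years[1:].astype(int),
            "Fturn": diffs,
            "spans_gap": (np.diff(years) > 1),
        }
    )
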