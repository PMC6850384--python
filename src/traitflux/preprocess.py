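"""Data-inclusion rules and transformations applied before any index.

Four operations mirror the study protocol for long-term coastal
monitoring series: removal of non-established rare taxa, the cumulative
96%-of-abundance inclusion rule for zoobenthos, ln(x+1) transformation,
neighbour-average imputation of missing sampling years, and anomaly
standardisation (zero mean, unit sample variance).
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .community import CommunityTimeSeries

__all__ = [
    "filter_rare_taxa",
    "filter_cumulative_abundance",
    "ln_transform",
    "impute_missing_years",
    "standardize_anomaly",
]


def filter_rare_taxa(
    cts: CommunityTimeSeries, min_occurrence_fraction: float = 0.05
) -> CommunityTimeSeries:
    """Drop taxa occurring in <5% of sampled years and never in consecutive years.

    A taxon is removed iff its frequency of occurrence (years with
    density > 0 divided by sampled years) does not exceed the threshold
    AND it never occurs in two calendar-consecutive sampled years.  Such
    taxa are not considered established in the area.  The boundary counts
    as rare: "occurring only once or twice" in a 40-year series means
    2/40 = 5% falls under the default 5% rule.  Retained densities are
    unchanged; the operation is idempotent.
    """
    if not (0 < min_occurrence_fraction < 1):
        raise ValueError("min_occurrence_fraction must be in (0,1)")
    dens = cts.density
    n_years = len(dens.index)
    present = dens.to_numpy(dtype=float) > 0
    years = dens.index.to_numpy()
    keep = []
    for j, taxon in enumerate(dens.columns):
        occ_years = years[present[:, j]]
        frac = len(occ_years) / n_years
        consecutive = np.any(np.diff(occ_years) == 1) if len(occ_years) > 1 else False
        if frac <= min_occurrence_fraction + 1e-12 and not consecutive:
            continue
        keep.append(taxon)
    if not keep:
        warnings.warn("all taxa removed by rare-taxon filter", stacklevel=2)
    return cts.with_density(dens[keep])


def filter_cumulative_abundance(
    cts: CommunityTimeSeries, threshold: float = 0.96
) -> CommunityTimeSeries:
    """Keep the most abundant taxa making up at least ``threshold`` of total abundance.

    Taxa are ranked by all-years summed density (descending, ties broken
    by taxon identifier); the smallest prefix whose cumulative share
    reaches the threshold is retained, in the original column order.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0,1]")
    totals = cts.density.sum(axis=0)
    grand = float(totals.sum())
    if grand <= 0:
        raise ValueError("cannot apply abundance filter to an all-zero community")
    order = sorted(totals.index, key=lambda t: (-totals[t], str(t)))
    cum = 0.0
    chosen = set()
    for t in order:
        chosen.add(t)
        cum += float(totals[t])
        if cum / grand >= threshold - 1e-12:
            break
    keep = [t for t in cts.density.columns if t in chosen]
    return cts.with_density(cts.density[keep])


def ln_transform(cts: CommunityTimeSeries) -> CommunityTimeSeries:
    """ln(x + 1) transform of all densities (zeros map to zero)."""
    vals = cts.density.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("densities must be non-negative")
    return cts.with_density(pd.DataFrame(
        np.log1p(vals), index=cts.density.index, columns=cts.density.columns
    ))


def impute_missing_years(series: pd.Series) -> pd.Series:
    """Fill missing years with the average of the neighbouring two years.

    ``series`` is indexed by consecutive calendar years with NaN at
    missing years (or with missing years absent from the index, in which
    case the index is completed first).  Interior gaps take the mean of
    the nearest observed value on each side — for an isolated gap this is
    the average of the two neighbouring years; boundary gaps copy the
    nearest single observed value.
    """
    s = series.astype(float)
    full = pd.RangeIndex(int(s.index.min()), int(s.index.max()) + 1)
    s = s.reindex(full)
    if s.notna().sum() == 0:
        raise ValueError("cannot impute an all-missing series")
    fwd = s.ffill()
    bwd = s.bfill()
    both = (fwd + bwd) / 2.0
    out = both.where(fwd.notna() & bwd.notna(), fwd.fillna(bwd))
    out.index = full
    out.name = series.name
    return out


def standardize_anomaly(series) -> pd.Series | np.ndarray:
    """Standardise to zero mean and unit sample (n-1) standard deviation."""
    arr = np.asarray(series, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values to standardise")
    obs = arr[np.isfinite(arr)]
    sd = obs.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardise a zero-variance series")
    out = (arr - obs.mean()) / sd
    if isinstance(series, pd.Series):
        return pd.Series(out, index=series.index, name=series.name)
    return out
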