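"""Synthetic community and trait data with the structure the analysis assumes.

The generator emulates multi-decadal coastal monitoring series: 20-60
taxa observed over ~34-43 annual samples with a few missing years,
log-normal densities whose log-scale means are driven by a small number
of shared latent random-walk trends through taxon-specific loadings,
optional AR1 observation noise, an optional multiplicative step change,
and a constructed set of rare "non-established" taxa (one or two
occurrence years, never consecutive).  Trait tables are fuzzy-coded per
block (affinities summing to 1).  The returned truth record stores the
latent structure so downstream recovery tests (DFA, change-point, trend)
can score estimates against it without re-running the generator.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .community import CommunityTimeSeries
from .traits import TraitBlock, TraitMatrix

__all__ = [
    "StepChange",
    "SyntheticConfig",
    "generate_latent_trends",
    "generate_trait_matrix",
    "generate_community",
    "expected_log_density",
    "expected_cwm",
    "write_truth_json",
]

DEFAULT_TRAIT_BLOCKS = (
    ("size", 3, "ordinal"),
    ("feeding", 4, "fuzzy"),
    ("mobility", 3, "nominal"),
    ("reproduction", 3, "fuzzy"),
    ("lifespan", 3, "ordinal"),
    ("habitat", 2, "nominal"),
)


@dataclass(frozen=True)
class StepChange:
    """Multiplicative density shift from ``year_index`` on, for some taxa."""

    year_index: int
    taxa: tuple          # taxon indices (0-based)
    effect: float        # multiplicative, e.g. 5.0 or 0.2

    def __post_init__(self):
        object.__setattr__(self, "taxa", tuple(int(i) for i in self.taxa))
        if self.effect <= 0:
            raise ValueError("step-change effect must be positive (multiplicative)")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the synthetic community generator.

    Defaults mirror the monitoring setting the analysis targets: a
    40-year annual series of ~30 established taxa plus a 10% fraction of
    constructed rare taxa, two latent common trends acting on
    log-density, moderate log-scale observation noise, and six
    fuzzy-coded traits.
    """

    n_years: int = 40
    n_taxa: int = 30
    trait_blocks: tuple = DEFAULT_TRAIT_BLOCKS
    n_latent_trends: int = 2
    trend_loading_scale: float = 0.5
    obs_noise_sd: float = 0.3
    ar1_phi: float = 0.0
    step_change: StepChange | None = None
    rare_taxon_fraction: float = 0.1
    missing_years: tuple = field(default_factory=tuple)
    start_year: int = 1974
    baseline_log_mean: float = 2.0
    baseline_log_sd: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_years < 10:
            raise ValueError("n_years must be >= 10")
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.n_latent_trends < 0:
            raise ValueError("n_latent_trends must be >= 0")
        if not (0 <= self.rare_taxon_fraction < 1):
            raise ValueError("rare_taxon_fraction must be in [0,1)")
        if not (-1 < self.ar1_phi < 1):
            raise ValueError("ar1_phi must be in (-1,1)")
        if self.obs_noise_sd < 0:
            raise ValueError("obs_noise_sd must be >= 0")
        for name, k, kind in self.trait_blocks:
            if k < 2:
                raise ValueError(f"trait {name!r} needs >= 2 categories")
        object.__setattr__(self, "trait_blocks", tuple(
            (str(n), int(k), str(t)) for n, k, t in self.trait_blocks))
        object.__setattr__(self, "missing_years", tuple(int(i) for i in self.missing_years))
        for idx in self.missing_years:
            if not (0 <= idx < self.n_years):
                raise ValueError("missing_years indices out of range")


def generate_latent_trends(m: int, T: int, seed=None, rng=None, steps=None) -> np.ndarray:
    """m latent random-walk trends of length T, each centred to zero mean.

    Each trend is the cumulative sum of unit-variance Gaussian steps
    (mirroring the state equation of dynamic factor analysis), then
    centred.  ``steps`` (m x T) overrides the random draws, for
    deterministic construction in tests.
    """
    if m < 0 or T < 2:
        raise ValueError("need m >= 0 and T >= 2")
    if m == 0:
        return np.empty((0, T))
    if steps is None:
        if rng is None:
            rng = np.random.default_rng(seed)
        steps = rng.standard_normal((m, T))
    else:
        steps = np.asarray(steps, dtype=float).reshape(m, T)
    trends = np.cumsum(steps, axis=1)
    return trends - trends.mean(axis=1, keepdims=True)


def generate_trait_matrix(config: SyntheticConfig, rng) -> TraitMatrix:
    """Fuzzy-coded trait table: Dirichlet rows for fuzzy blocks, one-hot
    for nominal and ordinal blocks (per-block sums exactly 1)."""
    taxa = [f"sp{j:03d}" for j in range(config.n_taxa)]
    blocks = []
    cols = {}
    for name, k, kind in config.trait_blocks:
        cats = tuple(f"{name}_{c}" for c in range(k))
        blocks.append(TraitBlock(name=name, categories=cats, kind=kind))
        if kind == "fuzzy":
            a = rng.dirichlet(np.ones(k), size=config.n_taxa)
            a = a / a.sum(axis=1, keepdims=True)
        else:
            a = np.zeros((config.n_taxa, k))
            a[np.arange(config.n_taxa), rng.integers(0, k, size=config.n_taxa)] = 1.0
        for c_i, cat in enumerate(cats):
            cols[(name, cat)] = a[:, c_i]
    columns = pd.MultiIndex.from_tuples(list(cols), names=["trait", "category"])
    affinity = pd.DataFrame(cols, index=taxa)
    affinity.columns = columns
    return TraitMatrix(affinity=affinity, blocks=tuple(blocks))


def _rare_occurrence_years(sampled_idx: np.ndarray, rng) -> np.ndarray:
    """Choose 1 or 2 sampled-year indices, never calendar-consecutive."""
    k = int(rng.integers(1, 3))
    first = int(rng.choice(sampled_idx))
    if k == 1:
        return np.array([first])
    allowed = sampled_idx[np.abs(sampled_idx - first) >= 2]
    if len(allowed) == 0:
        return np.array([first])
    return np.sort(np.array([first, int(rng.choice(allowed))]))


def generate_community(config: SyntheticConfig):
    """Generate (CommunityTimeSeries, TraitMatrix, truth record).

    Log-density of taxon j in year t is baseline_j + (loadings @
    trends)_jt + step_jt + AR1 noise; density is its exponential, hence
    log-normal and positive.  Rare taxa are constructed deterministically
    from the seeded stream: their density is zero except in one or two
    non-consecutive sampled years.  Missing years are dropped rows.
    """
    rng = np.random.default_rng(config.seed)
    T, n = config.n_years, config.n_taxa
    tm = generate_trait_matrix(config, rng)
    taxa = tm.taxa
    years = np.arange(config.start_year, config.start_year + T)

    trends = generate_latent_trends(config.n_latent_trends, T, rng=rng)
    loadings = (
        rng.normal(0.0, config.trend_loading_scale, size=(n, config.n_latent_trends))
        if config.n_latent_trends
        else np.zeros((n, 0))
    )
    baselines = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n)

    noise = np.zeros((n, T))
    if config.obs_noise_sd > 0:
        z = rng.standard_normal((n, T)) * config.obs_noise_sd
        phi = config.ar1_phi
        noise[:, 0] = z[:, 0]
        for t in range(1, T):
            noise[:, t] = phi * noise[:, t - 1] + np.sqrt(1.0 - phi**2) * z[:, t]

    log_dens = baselines[:, None] + loadings @ trends + noise
    step = config.step_change
    if step is not None:
        log_dens[list(step.taxa), step.year_index:] += np.log(step.effect)

    density = np.exp(log_dens)

    sampled_mask = np.ones(T, dtype=bool)
    sampled_mask[list(config.missing_years)] = False
    sampled_idx = np.flatnonzero(sampled_mask)

    n_rare = int(round(config.rare_taxon_fraction * n))
    rare_taxa = list(range(n - n_rare, n))
    rare_years = {}
    for j in rare_taxa:
        occ = _rare_occurrence_years(sampled_idx, rng)
        kept = density[j, occ].copy()
        density[j, :] = 0.0
        density[j, occ] = kept
        rare_years[taxa[j]] = [int(years[i]) for i in occ]

    frame = pd.DataFrame(density.T, index=pd.Index(years, name="year"), columns=taxa)
    frame = frame.loc[years[sampled_mask]]
    cts = CommunityTimeSeries(
        density=frame,
        area="synthetic",
        group="community",
        missing_years=tuple(int(years[i]) for i in config.missing_years),
    )
    truth = {
        "seed": config.seed,
        "years": [int(y) for y in years],
        "taxa": list(taxa),
        "trends": trends.tolist(),
        "loadings": loadings.tolist(),
        "baselines": baselines.tolist(),
        "rare_taxa": [taxa[j] for j in rare_taxa],
        "rare_occurrence_years": rare_years,
        "step_change": None if step is None else {
            "year": int(years[step.year_index]),
            "year_index": step.year_index,
            "taxa": [taxa[j] for j in step.taxa],
            "effect": step.effect,
        },
        "ar1_phi": config.ar1_phi,
        "obs_noise_sd": config.obs_noise_sd,
        "missing_years": [int(years[i]) for i in config.missing_years],
    }
    return cts, tm, truth


def expected_log_density(truth: dict) -> pd.DataFrame:
    """Noise-free log-density (years x taxa) implied by the truth record.

    baseline + loadings @ trends + step effect; rare taxa excluded from
    the latent structure are reported as NaN columns.
    """
    trends = np.asarray(truth["trends"], dtype=float)
    loadings = np.asarray(truth["loadings"], dtype=float)
    baselines = np.asarray(truth["baselines"], dtype=float)
    log_dens = np.tile(baselines[:, None], (1, len(truth["years"])))
    if trends.size:
        log_dens = log_dens + loadings @ trends
    step = truth.get("step_change")
    taxa = truth["taxa"]
    if step is not None:
        idx = [taxa.index(t) for t in step["taxa"]]
        log_dens[idx, step["year_index"]:] += np.log(step["effect"])
    out = pd.DataFrame(log_dens.T, index=pd.Index(truth["years"], name="year"), columns=taxa)
    out[truth["rare_taxa"]] = np.nan
    return out


def expected_cwm(truth: dict, tm: TraitMatrix, ln_weights: bool = True) -> pd.DataFrame:
    """Noise-free CWM trajectory implied by loadings and trends.

    Weights are the expected densities (exp of the noise-free
    log-density), ln(x+1)-transformed by default; rare taxa carry zero
    expected weight.  Used by DFA recovery tests as the target the
    estimated trends should span.
    """
    logd = expected_log_density(truth)
    dens = np.exp(logd.to_numpy(dtype=float))
    dens[np.isnan(dens)] = 0.0
    w = np.log1p(dens) if ln_weights else dens
    a = tm.subset(truth["taxa"]).affinity.to_numpy(dtype=float)
    cwm = (w @ a) / w.sum(axis=1, keepdims=True)
    return pd.DataFrame(cwm, index=logd.index.copy(), columns=tm.affinity.columns.copy())


def write_truth_json(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)
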