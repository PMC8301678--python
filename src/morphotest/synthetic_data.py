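"""Synthetic hybrid-zone mussel samples.

Generates individual-level tables with the statistical structure the
downstream analyses assume:

* **q-values** come from a three-component mixture: purebred edulis on
  [0, 0.2], purebred trossulus on [0.8, 1] (scaled Beta(1, c), concentration
  ``c`` a free dispersion knob) and hybrids on (0.2, 0.8).  Hybrid q-values
  fall on the trossulus side of 0.5 with probability equal to the target
  prevalence, so the expected fraction of q > 0.5 genotypes equals the target
  prevalence exactly for every point of the grid, hybrids or not.  The
  ``bimodal`` regime (default, <15% intermediates) mirrors most contact
  zones; the ``flattened`` regime (30-40% intermediates) mirrors zones with
  extensive hybridization.
* **Morphotypes** are Bernoulli draws on the logit scale with per-species
  intercepts and optional per-species slopes on prevalence - the generative
  counterpart of the prevalence drift of the test's operating
  characteristics.  Hybrids use the midpoint of the two species' linear
  predictors (intermediate morphotype frequencies).
* **Shell lengths** are log-normal, with an optional morphotype-size effect
  (zero by default: no systematic size difference between morphotypes).

A single integer seed governs the whole study through spawned per-sample
substreams, so any one sample can be regenerated without the rest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .metrics import EDULIS, TROSSULUS

HYBRID = "hybrid"
SPECIES_LABELS = (EDULIS, TROSSULUS, HYBRID)

__all__ = [
    "HYBRID",
    "QMixtureConfig",
    "MorphotypeModel",
    "SizeModel",
    "SimulationConfig",
    "wsbl_like_config",
    "generate_individual",
    "generate_sample",
    "generate_study",
]


@dataclass(frozen=True)
class QMixtureConfig:
    """Mixture shaping the admixture-proportion (q) distribution.

    ``intermediate_fraction`` is the expected share of hybrids (q strictly in
    (0.2, 0.8)).  ``purebred_concentration`` c controls purebred dispersion:
    purebred edulis q = 0.2*Beta(1, c), trossulus mirrored.  ``hybrid_spread``
    are the Beta parameters of the hybrid half-width draw.
    """

    intermediate_fraction: float = 0.10
    purebred_concentration: float = 5.0
    hybrid_spread: tuple[float, float] = (1.2, 1.2)

    def __post_init__(self) -> None:
        if not 0.0 <= self.intermediate_fraction <= 1.0:
            raise ValueError("intermediate_fraction must lie in [0, 1]")
        if self.purebred_concentration <= 0:
            raise ValueError("purebred_concentration must be positive")

    @classmethod
    def bimodal(cls) -> "QMixtureConfig":
        """Pronouncedly bimodal regime: 10% intermediates."""
        return cls(intermediate_fraction=0.10)

    @classmethod
    def flattened(cls) -> "QMixtureConfig":
        """Flattened regime typical of heavily introgressed zones: 35%."""
        return cls(intermediate_fraction=0.35)


@dataclass(frozen=True)
class MorphotypeModel:
    """Per-species morphotype probabilities on the logit scale.

    P(T | species, prevalence p) = invlogit(intercept_species +
    slope_species * p).  The defaults reproduce the White Sea pooled
    operating characteristics (sensitivity 0.74, false-positive rate 0.04)
    with no prevalence drift.
    """

    intercept_tros: float = logit(0.74)
    slope_tros: float = 0.0
    intercept_edu: float = logit(0.04)
    slope_edu: float = 0.0

    def linpred(self, species: np.ndarray, ptros: float) -> np.ndarray:
        eta_t = self.intercept_tros + self.slope_tros * ptros
        eta_e = self.intercept_edu + self.slope_edu * ptros
        eta = np.where(species == TROSSULUS, eta_t, eta_e)
        # hybrids sit midway between the species on the logit scale
        return np.where(species == HYBRID, 0.5 * (eta_t + eta_e), eta)


@dataclass(frozen=True)
class SizeModel:
    """Log-normal shell lengths (mm) and an optional morphotype-size link.

    ``morph_effect_per_mm`` shifts the morphotype logit by that amount per mm
    of deviation from ``reference_mm``; the default 0 encodes the null of no
    systematic size effect.
    """

    log_mean: float = math.log(35.0)
    log_sd: float = 0.30
    morph_effect_per_mm: float = 0.0
    reference_mm: float = 35.0


def _default_grid() -> tuple[float, ...]:
    return tuple(np.round(np.linspace(0.0, 1.0, 36), 6))


@dataclass(frozen=True)
class SimulationConfig:
    """Full study configuration: one sample per prevalence-grid point."""

    prevalence_grid: tuple[float, ...] = field(default_factory=_default_grid)
    sample_size_range: tuple[int, int] = (18, 173)
    q_mixture: QMixtureConfig = field(default_factory=QMixtureConfig.bimodal)
    morph_model: MorphotypeModel = field(default_factory=MorphotypeModel)
    size_model: SizeModel = field(default_factory=SizeModel)
    set_label: str = "SIM"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.prevalence_grid) == 0:
            raise ValueError("prevalence_grid must be non-empty")
        grid = np.asarray(self.prevalence_grid, dtype=float)
        if np.any(grid < 0.0) or np.any(grid > 1.0):
            raise ValueError("prevalence grid values must lie in [0, 1]")
        lo, hi = self.sample_size_range
        if not (1 <= lo <= hi):
            raise ValueError("sample_size_range must satisfy 1 <= lo <= hi")


def wsbl_like_grid() -> tuple[float, ...]:
    """Sample prevalences of a mosaic contact zone, 36 samples.

    A recently invaded, mostly edulis-dominated region: many pure-edulis
    sites, a block of pure-trossulus patches, and a band of mixing-front
    populations leaning towards the resident species.
    """
    lows = np.linspace(0.0, 0.10, 18)
    mids = np.linspace(0.28, 0.47, 10)
    highs = np.linspace(0.93, 1.0, 8)
    return tuple(np.round(np.concatenate([lows, mids, highs]), 4))


def wsbl_like_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study conditions emulating the White Sea / brackish Barents Sea set.

    36 samples with the bimodal prevalence structure of a mosaic hybrid
    zone, bimodal within-sample q distributions, and prevalence-drifting
    morphotype probabilities: both species' T-morphotype frequencies rise
    with the trossulus share of the population.  The drift is calibrated so
    that the effective operating characteristics of well-mixed populations
    match the published regional predictive-value formulas (sensitivity
    ~0.73, false-positive rate ~0.05 at a balanced mix, rising to ~0.85 /
    falling to ~0.02 in pure populations).
    """
    morph = MorphotypeModel(
        intercept_tros=0.41,
        slope_tros=1.7,
        intercept_edu=-4.5,
        slope_edu=2.3,
    )
    cfg = SimulationConfig(
        prevalence_grid=wsbl_like_grid(),
        q_mixture=QMixtureConfig.bimodal(),
        morph_model=morph,
        set_label="WSBL_SIM",
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def _draw_q(
    species: np.ndarray, ptros: float, mix: QMixtureConfig, rng: np.random.Generator
) -> np.ndarray:
    n = species.shape[0]
    q = np.empty(n)
    c = mix.purebred_concentration
    edu = species == EDULIS
    tro = species == TROSSULUS
    hyb = species == HYBRID
    q[edu] = 0.2 * rng.beta(1.0, c, size=int(edu.sum()))
    q[tro] = 1.0 - 0.2 * rng.beta(1.0, c, size=int(tro.sum()))
    n_h = int(hyb.sum())
    if n_h:
        a, b = mix.hybrid_spread
        half = 0.3 * rng.beta(a, b, size=n_h)
        side = np.where(rng.random(n_h) < ptros, 1.0, -1.0)
        q[hyb] = 0.5 + side * half
    return q


def _draw_species(
    ptros: float, n: int, mix: QMixtureConfig, rng: np.random.Generator
) -> np.ndarray:
    u = rng.random(n)
    hybrid = u < mix.intermediate_fraction
    tros = rng.random(n) < ptros
    species = np.where(tros, TROSSULUS, EDULIS)
    species[hybrid] = HYBRID
    return species


def generate_individual(
    species: str,
    ptros: float,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> dict:
    """Draw one individual of a given class at a given population prevalence."""
    if species not in SPECIES_LABELS:
        raise ValueError(f"unknown species label {species!r}; expected one of {SPECIES_LABELS}")
    if not 0.0 <= ptros <= 1.0:
        raise ValueError(f"ptros must lie in [0, 1], got {ptros!r}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    arr = np.array([species], dtype=object)
    q = float(_draw_q(arr, ptros, cfg.q_mixture, rng)[0])
    sz = cfg.size_model
    length = float(rng.lognormal(sz.log_mean, sz.log_sd))
    eta = float(cfg.morph_model.linpred(arr, ptros)[0])
    eta += sz.morph_effect_per_mm * (length - sz.reference_mm)
    morph = "T" if rng.random() < expit(eta) else "E"
    return {"species": species, "q": q, "morphotype": morph, "length_mm": length}


def generate_sample(
    ptros: float,
    n: int,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    sample_id: str = "S00",
    set_label: Optional[str] = None,
) -> pd.DataFrame:
    """Draw one sample of ``n`` individuals at target prevalence ``ptros``.

    The expected fraction of q > 0.5 genotypes equals ``ptros`` (hybrids are
    side-biased towards the dominant species), and the expected fraction of
    intermediate q-values equals the configured hybrid share.
    """
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    if not 0.0 <= ptros <= 1.0:
        raise ValueError(f"ptros must lie in [0, 1], got {ptros!r}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    species = _draw_species(ptros, n, cfg.q_mixture, rng)
    q = _draw_q(species, ptros, cfg.q_mixture, rng)
    sz = cfg.size_model
    length = rng.lognormal(sz.log_mean, sz.log_sd, size=n)
    eta = cfg.morph_model.linpred(species, ptros)
    eta = eta + sz.morph_effect_per_mm * (length - sz.reference_mm)
    morph = np.where(rng.random(n) < expit(eta), "T", "E")
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "set": cfg.set_label if set_label is None else set_label,
            "species": species,
            "q": q,
            "morphotype": morph,
            "length_mm": np.round(length, 1),
        }
    )


def generate_study(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one sample per prevalence-grid point.

    Returns ``(individuals, metadata)``: the individual-level table and the
    sample metadata (sample_id, set, true prevalence, size).  Reproducible:
    the same config yields byte-identical tables.  Per-sample substreams are
    spawned from the study seed keyed by sample index.
    """
    grid = list(cfg.prevalence_grid)
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(len(grid) + 1)
    size_rng = np.random.default_rng(children[0])
    lo, hi = cfg.sample_size_range
    sizes = size_rng.integers(lo, hi + 1, size=len(grid))
    width = max(2, len(str(len(grid) - 1)))
    frames = []
    meta = []
    for i, (p, n) in enumerate(zip(grid, sizes)):
        sid = f"S{i:0{width}d}"
        rng = np.random.default_rng(children[i + 1])
        frames.append(generate_sample(float(p), int(n), cfg, rng=rng, sample_id=sid))
        meta.append(
            {
                "sample_id": sid,
                "set": cfg.set_label,
                "salinity_class": "unknown",
                "true_ptros": float(p),
                "n": int(n),
            }
        )
    individuals = pd.concat(frames, ignore_index=True)
    return individuals, pd.DataFrame(meta)
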