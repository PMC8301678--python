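"""Probability calculators for the morphotype test.

Three closed-form relations tie the test's operating characteristics
(sensitivity P(T|tros), false-positive rate P(T|edu)) to the species
composition of a mixed population:

* positive predictive value
  ``PPV(p) = p*sens / (p*sens + (1-p)*fpr)``
* negative predictive value (Bayes form)
  ``NPV(p) = (1-p)*(1-fpr) / ((1-p)*(1-fpr) + p*(1-sens))``
* prevalence from the observed morphotype frequency
  ``Ptros = (PT - fpr) / (sens - fpr)``

where ``p`` is the prevalence of trossulus genotypes.  The NPV relation is
implemented in the Bayes-consistent form throughout; see docs/methods.md for
the typographic variant it replaces.

The module also ships the published region-specific logistic formulas
(intercept/slope on the logit scale, to the printed one-decimal precision)
for the five regional sample sets, and the "lazy" calibration shortcut that
takes the extreme morphotype frequencies of a regional set as stand-ins for
the pure-species frequencies.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit

from .metrics import SampleSummary, diagnostic_indices

ArrayLike = Union[float, Sequence[float], np.ndarray]

PUBLISHED_SETS = ("WSBL", "BH", "GOM", "BALT", "NORW")
PUBLISHED_TARGETS = ("Ptros_from_PT", "NPV_from_Ptros", "PPV_from_Ptros")

__all__ = [
    "CalculatorParams",
    "PublishedModel",
    "PUBLISHED_SETS",
    "PUBLISHED_TARGETS",
    "ppv",
    "npv",
    "prevalence_from_pt",
    "expected_pt",
    "params_from_summary",
    "params_from_pooled",
    "lazy_params",
    "published_models",
    "get_published",
    "published_predict",
]


@dataclass(frozen=True)
class CalculatorParams:
    """Operating characteristics of the test plus their provenance.

    ``p_t_tros`` is the sensitivity P(T|tros) and ``p_t_edu`` the
    false-positive rate P(T|edu).  ``provenance`` records where the pair came
    from (a calibration sample pair, a pooled stratum, or the lazy min/max
    shortcut).
    """

    p_t_tros: float
    p_t_edu: float
    provenance: str = ""

    def __post_init__(self) -> None:
        for name in ("p_t_tros", "p_t_edu"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0.0 or v > 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")

    @property
    def sens(self) -> float:
        return self.p_t_tros

    @property
    def fpr(self) -> float:
        return self.p_t_edu

    @property
    def invertible(self) -> bool:
        """Whether the prevalence equation is solvable (sens > fpr)."""
        return self.p_t_tros > self.p_t_edu


def _check_unit(x: ArrayLike, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.size and (np.any(arr < 0.0) | np.any(arr > 1.0) | np.any(~np.isfinite(arr))):
        raise ValueError(f"{name} must lie in [0, 1]")
    return arr


def _maybe_scalar(arr: np.ndarray, like: ArrayLike):
    return float(arr) if np.isscalar(like) or np.ndim(like) == 0 else arr


def ppv(params: CalculatorParams, ptros: ArrayLike) -> ArrayLike:
    """P(tros|T) at the given prevalence; NaN where undefined (0/0)."""
    p = _check_unit(ptros, "ptros")
    num = p * params.sens
    den = num + (1.0 - p) * params.fpr
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), np.nan)
    return _maybe_scalar(out, ptros)


def npv(params: CalculatorParams, ptros: ArrayLike) -> ArrayLike:
    """P(edu|E) at the given prevalence; NaN where undefined (0/0)."""
    p = _check_unit(ptros, "ptros")
    num = (1.0 - p) * (1.0 - params.fpr)
    den = num + p * (1.0 - params.sens)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), np.nan)
    return _maybe_scalar(out, ptros)


def expected_pt(params: CalculatorParams, ptros: ArrayLike) -> ArrayLike:
    """Expected T-morphotype frequency ``p*sens + (1-p)*fpr`` (the inverse of
    the prevalence equation)."""
    p = _check_unit(ptros, "ptros")
    out = p * params.sens + (1.0 - p) * params.fpr
    return _maybe_scalar(out, ptros)


def prevalence_from_pt(
    params: CalculatorParams, pt: ArrayLike, clamp: bool = True
) -> ArrayLike:
    """Prevalence from the observed morphotype frequency.

    Requires an informative marker (sens > fpr).  With ``clamp=True`` (the
    default) values are truncated to [0, 1]: a PT outside the attainable band
    ``[fpr, sens]`` maps to the nearest pure population.  Pass ``clamp=False``
    to obtain the raw linear solution and detect truncation yourself.
    """
    if not params.invertible:
        raise ValueError(
            "non-informative marker: P(T|tros) must exceed P(T|edu) "
            f"(got sens={params.sens}, fpr={params.fpr})"
        )
    x = _check_unit(pt, "pt")
    raw = (x - params.fpr) / (params.sens - params.fpr)
    out = np.clip(raw, 0.0, 1.0) if clamp else raw
    return _maybe_scalar(out, pt)


def params_from_summary(summary: SampleSummary, provenance: str = "") -> CalculatorParams:
    """Operating characteristics counted from one (possibly pooled) summary."""
    d = diagnostic_indices(summary)
    if d.sens is None or d.fpr is None:
        missing = "trossulus" if d.sens is None else "edulis"
        raise ValueError(
            f"cannot estimate operating characteristics from sample "
            f"'{summary.sample_id}': no {missing} genotypes"
        )
    return CalculatorParams(d.sens, d.fpr, provenance or f"sample:{summary.sample_id}")


def params_from_pooled(
    summaries: Iterable[SampleSummary], provenance: str = ""
) -> CalculatorParams:
    from .metrics import pool_summaries

    pooled = pool_summaries(summaries, sample_id="pooled")
    return params_from_summary(pooled, provenance or "pooled")


def lazy_params(summaries: Sequence[SampleSummary]) -> CalculatorParams:
    """The "lazy" calibration: extreme PT samples stand in for pure species.

    The sample with the highest T-morphotype frequency is treated as pure
    trossulus (its PT becomes the sensitivity) and the one with the lowest as
    pure edulis (its PT becomes the false-positive rate).  Ties are broken by
    sample id for determinism.
    """
    if len(summaries) < 2:
        raise ValueError("lazy calibration needs at least two samples")
    pts = [s.pt for s in summaries]
    if max(pts) == min(pts):
        raise ValueError("all samples have identical PT; lazy calibration undefined")
    hi = max(summaries, key=lambda s: (s.pt, s.sample_id))
    lo = min(summaries, key=lambda s: (s.pt, s.sample_id))
    return CalculatorParams(
        hi.pt, lo.pt, provenance=f"lazy:max={hi.sample_id},min={lo.sample_id}"
    )


@dataclass(frozen=True)
class PublishedModel:
    """A published logistic formula: inverse-logit(intercept + slope * x)."""

    set: str
    target: str
    intercept: float
    slope: float


@lru_cache(maxsize=1)
def published_models() -> dict[tuple[str, str], PublishedModel]:
    """Published region-specific logistic coefficients, keyed (set, target)."""
    path = importlib.resources.files("morphotest").joinpath("data/published_models.csv")
    with importlib.resources.as_file(path) as p:
        df = pd.read_csv(p)
    out = {}
    for row in df.itertuples(index=False):
        m = PublishedModel(row.set, row.target, float(row.intercept), float(row.slope))
        out[(m.set, m.target)] = m
    return out


def get_published(set_label: str, target: str) -> PublishedModel:
    models = published_models()
    key = (set_label, target)
    if key not in models:
        raise KeyError(
            f"no published model for set={set_label!r}, target={target!r}; "
            f"sets: {PUBLISHED_SETS}, targets: {PUBLISHED_TARGETS}"
        )
    return models[key]


def published_predict(model: PublishedModel, x: ArrayLike) -> ArrayLike:
    """Evaluate a published logistic formula at ``x`` (a frequency in [0, 1])."""
    arr = _check_unit(x, "x")
    out = expit(model.intercept + model.slope * arr)
    return _maybe_scalar(out, x)
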