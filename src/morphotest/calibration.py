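"""Calibration-sample selection for the probability calculators.

To apply the calculators in an unstudied contact zone one needs the test's
operating characteristics from a few genotyped "calibration" samples.  This
module implements the pair-search experiment that identifies which samples
calibrate well:

* ``delta(p1, p2) = p1(1-p2) + p2(1-p1)`` - a symmetric taxonomic
  dissimilarity index for a pair of samples (0 for two pure conspecific
  samples, 0.5 for two balanced mixtures, 1 for a pure-trossulus /
  pure-edulis pair).
* every unordered pair of samples is pooled into candidate calculator
  parameters, and the calculator curves are compared with a reference
  regression over a fixed frequency grid ([0, 1], step 0.01, endpoints
  included) by ``Goodness = 1 / MSS`` (mean squared difference; a perfect
  match yields the infinity sentinel);
* a LOESS curve of goodness against delta summarises the search, and simple
  prevalence strata implement the resulting selection rules (most-dissimilar
  pairs for the prevalence calculator, most-mixed samples for the
  predictive-value calculator).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .calculators import (
    CalculatorParams,
    PublishedModel,
    npv,
    ppv,
    prevalence_from_pt,
    published_predict,
)
from .loess import loess
from .metrics import SampleSummary, pool_summaries
from .regression import ModelFit, predict_with_ci

Curve = Callable[[np.ndarray], np.ndarray]

__all__ = [
    "PairEvaluation",
    "delta",
    "enumerate_pairs",
    "goodness_prevalence",
    "goodness_predictive",
    "evaluate_pairs",
    "pairs_frame",
    "loess_summary",
    "select_calibrators",
    "prevalence_reference",
    "predictive_reference",
]


def delta(ptros1: float, ptros2: float) -> float:
    """Taxonomic dissimilarity of a sample pair; symmetric, in [0, 1]."""
    p1 = np.asarray(ptros1, dtype=float)
    p2 = np.asarray(ptros2, dtype=float)
    if np.any((p1 < 0) | (p1 > 1)) or np.any((p2 < 0) | (p2 > 1)):
        raise ValueError("prevalences must lie in [0, 1]")
    out = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    return float(out) if out.ndim == 0 else out


@dataclass
class PairEvaluation:
    """One candidate calibration pair and its agreement with the reference."""

    sample_ids: tuple[str, str]
    delta: float
    params: Optional[CalculatorParams] = None
    failed: bool = False
    reason: str = ""
    mss_prevalence: Optional[float] = None
    goodness_prevalence: Optional[float] = None
    mss_predictive: Optional[float] = None
    goodness_predictive: Optional[float] = None


def _pair_shell(s1: SampleSummary, s2: SampleSummary) -> PairEvaluation:
    d = delta(s1.ptros, s2.ptros)
    ids = (s1.sample_id, s2.sample_id)
    try:
        from .calculators import params_from_pooled

        params = params_from_pooled([s1, s2], provenance=f"pair:{ids[0]}+{ids[1]}")
    except ValueError as exc:
        return PairEvaluation(ids, d, failed=True, reason=str(exc))
    if not params.invertible:
        return PairEvaluation(
            ids, d, params=params, failed=True,
            reason="non-informative pooled marker (sens <= fpr)",
        )
    return PairEvaluation(ids, d, params=params)


def enumerate_pairs(summaries: Sequence[SampleSummary]) -> list[PairEvaluation]:
    """All n(n-1)/2 unordered sample pairs, with pooled parameters attached.

    Pairs whose pooled counts cannot supply usable operating characteristics
    (a missing species, or sens <= fpr) are returned flagged as failed rather
    than dropped.
    """
    if len(summaries) < 2:
        raise ValueError("pair enumeration needs at least two samples")
    out = []
    for i in range(len(summaries)):
        for j in range(i + 1, len(summaries)):
            out.append(_pair_shell(summaries[i], summaries[j]))
    return out


def _grid(step: float) -> np.ndarray:
    if not 0.0 < step <= 0.5:
        raise ValueError("grid step must lie in (0, 0.5]")
    n = int(round(1.0 / step))
    return np.linspace(0.0, 1.0, n + 1)


def _as_curve(reference, target_x: str) -> Curve:
    """Normalise a reference (callable / published model / ModelFit) to a curve."""
    if callable(reference) and not isinstance(reference, (PublishedModel, ModelFit)):
        return reference
    if isinstance(reference, PublishedModel):
        return lambda g: np.asarray(published_predict(reference, g))
    if isinstance(reference, ModelFit):
        def curve(g: np.ndarray) -> np.ndarray:
            newdata = pd.DataFrame({target_x: g})
            return predict_with_ci(reference, newdata, level=0.0)["fit"].to_numpy()

        return curve
    raise TypeError(f"unsupported reference type: {type(reference)!r}")


def prevalence_reference(reference) -> Curve:
    """Reference curve PT -> Ptros (a fitted M4, published formula or callable)."""
    return _as_curve(reference, "pt")


def predictive_reference(fit: ModelFit) -> tuple[Curve, Curve]:
    """PPV and NPV reference curves from a fitted correctness model (M6 type).

    The model predicts P(correct | prevalence, morphotype); the T-morphotype
    curve is the PPV reference and the E-morphotype curve the NPV reference.
    """

    def curve_for(morph: str) -> Curve:
        def curve(g: np.ndarray) -> np.ndarray:
            newdata = pd.DataFrame({"ptros": g, "morphotype": morph})
            return predict_with_ci(fit, newdata, level=0.0)["fit"].to_numpy()

        return curve

    return curve_for("T"), curve_for("E")


def _goodness_from_mss(mss: float) -> float:
    return np.inf if mss == 0.0 else 1.0 / mss


def goodness_prevalence(
    params: CalculatorParams, reference, grid_step: float = 0.01
) -> tuple[float, float]:
    """(MSS, Goodness) of the prevalence calculator against the reference.

    The calculator's prevalence predictions (clamped to [0, 1]) and the
    reference curve are compared over the PT grid.
    """
    grid = _grid(grid_step)
    pred = np.asarray(prevalence_from_pt(params, grid, clamp=True))
    ref = np.asarray(prevalence_reference(reference)(grid))
    mss = float(np.mean((pred - ref) ** 2))
    return mss, _goodness_from_mss(mss)


def goodness_predictive(
    params: CalculatorParams,
    reference_ppv,
    reference_npv,
    grid_step: float = 0.01,
) -> tuple[float, float]:
    """(MSS, Goodness) of the predictive-value calculator against references.

    Squared differences of the PPV and NPV curves over the prevalence grid
    are pooled with equal weight into one mean.
    """
    grid = _grid(grid_step)
    ref_p = np.asarray(_as_curve(reference_ppv, "ptros")(grid))
    ref_n = np.asarray(_as_curve(reference_npv, "ptros")(grid))
    pred_p = np.asarray(ppv(params, grid))
    pred_n = np.asarray(npv(params, grid))
    diffs = np.concatenate([pred_p - ref_p, pred_n - ref_n])
    if np.any(~np.isfinite(diffs)):
        raise ValueError("predictive calculator undefined on the grid (degenerate params)")
    mss = float(np.mean(diffs**2))
    return mss, _goodness_from_mss(mss)


def evaluate_pairs(
    summaries: Sequence[SampleSummary],
    reference_prevalence=None,
    reference_ppv=None,
    reference_npv=None,
    grid_step: float = 0.01,
) -> list[PairEvaluation]:
    """Run the full pair search against the supplied references."""
    pairs = enumerate_pairs(summaries)
    for pe in pairs:
        if pe.failed:
            continue
        try:
            if reference_prevalence is not None:
                pe.mss_prevalence, pe.goodness_prevalence = goodness_prevalence(
                    pe.params, reference_prevalence, grid_step
                )
            if reference_ppv is not None and reference_npv is not None:
                pe.mss_predictive, pe.goodness_predictive = goodness_predictive(
                    pe.params, reference_ppv, reference_npv, grid_step
                )
        except ValueError as exc:
            pe.failed = True
            pe.reason = str(exc)
    return pairs


def pairs_frame(pairs: Iterable[PairEvaluation]) -> pd.DataFrame:
    """Tabular view of a pair search (one row per pair, NaN where absent)."""
    rows = []
    for pe in pairs:
        rows.append(
            {
                "sample_1": pe.sample_ids[0],
                "sample_2": pe.sample_ids[1],
                "delta": pe.delta,
                "p_t_tros": np.nan if pe.params is None else pe.params.p_t_tros,
                "p_t_edu": np.nan if pe.params is None else pe.params.p_t_edu,
                "failed": pe.failed,
                "reason": pe.reason,
                "mss_prevalence": np.nan if pe.mss_prevalence is None else pe.mss_prevalence,
                "goodness_prevalence": np.nan
                if pe.goodness_prevalence is None
                else pe.goodness_prevalence,
                "mss_predictive": np.nan if pe.mss_predictive is None else pe.mss_predictive,
                "goodness_predictive": np.nan
                if pe.goodness_predictive is None
                else pe.goodness_predictive,
            }
        )
    return pd.DataFrame(rows)


def loess_summary(
    pairs: Iterable[PairEvaluation],
    target: str = "prevalence",
    span: float = 0.75,
    degree: int = 2,
    grid: Optional[Sequence[float]] = None,
    min_points: int = 10,
) -> pd.DataFrame:
    """LOESS curve of goodness against delta over the finite, non-failed pairs.

    Infinity sentinels (perfect agreement) never enter the smoother.
    """
    if target not in ("prevalence", "predictive"):
        raise ValueError("target must be 'prevalence' or 'predictive'")
    attr = f"goodness_{target}"
    xs, ys = [], []
    for pe in pairs:
        g = getattr(pe, attr)
        if pe.failed or g is None or not np.isfinite(g):
            continue
        xs.append(pe.delta)
        ys.append(g)
    if len(xs) < min_points:
        raise ValueError(
            f"need at least {min_points} finite pair evaluations, got {len(xs)}"
        )
    xg = np.asarray(sorted(set(xs)) if grid is None else grid, dtype=float)
    yg = loess(xs, ys, x_eval=xg, span=span, degree=degree)
    return pd.DataFrame({"delta": xg, f"goodness_{target}_smooth": yg})


def select_calibrators(
    summaries: Sequence[SampleSummary],
    purpose: str,
    pure_bounds: tuple[float, float] = (0.1, 0.8),
    mixed_bounds: tuple[float, float] = (0.45, 0.65),
) -> CalculatorParams:
    """Pool the calibration stratum dictated by the selection rules.

    ``purpose='prevalence'`` pools the near-pure samples (prevalence below
    ``pure_bounds[0]`` or above ``pure_bounds[1]``); ``purpose='predictive'``
    pools the well-mixed samples (prevalence strictly inside
    ``mixed_bounds``).  An empty stratum is an error naming the stratum, the
    cue to fall back to pooling everything in data-poor regions.
    """
    from .calculators import params_from_summary

    if purpose == "prevalence":
        lo, hi = pure_bounds
        chosen = [s for s in summaries if s.ptros < lo or s.ptros > hi]
        low_stratum = [s for s in summaries if s.ptros < lo]
        high_stratum = [s for s in summaries if s.ptros > hi]
        if not low_stratum:
            raise ValueError(f"empty calibration stratum: no samples with Ptros < {lo}")
        if not high_stratum:
            raise ValueError(f"empty calibration stratum: no samples with Ptros > {hi}")
        label = f"pooled:Ptros<{lo}|>{hi}"
    elif purpose == "predictive":
        lo, hi = mixed_bounds
        chosen = [s for s in summaries if lo < s.ptros < hi]
        if not chosen:
            raise ValueError(
                f"empty calibration stratum: no samples with {lo} < Ptros < {hi}"
            )
        label = f"pooled:{lo}<Ptros<{hi}"
    else:
        raise ValueError("purpose must be 'prevalence' or 'predictive'")
    pooled = pool_summaries(chosen, sample_id=label)
    return params_from_summary(pooled, provenance=label)
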