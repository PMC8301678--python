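"""Morphotype-size association screen.

Shell size is a potential confounder of the morphotype test: if the
prismatic strip appeared or vanished with age, morphotype frequencies would
track the size structure of a sample rather than its species composition.
Two checks are implemented:

* a per-cell logistic screen - one fit of morphotype against shell length
  for every (sample x species-genotype) cell that is *informative* (both
  morphotypes present), with Hochberg's step-up correction applied within
  each species' family of informative cells;
* a residual check of a fitted correctness model (M6 type): deviance
  residuals regressed on length, flagging any systematic trend.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import fit_logistic_glm
from .metrics import classify_genotypes
from .regression import ModelFit

__all__ = ["hochberg_adjust", "size_screen", "residual_size_check", "SizeResidualCheck"]


def hochberg_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Hochberg step-up adjusted p-values, returned in the input order.

    Sort ascending; the i-th smallest (1-based) gets the running minimum of
    ``(m - i + 1) * p_(i)`` taken from the largest rank downwards, capped at 1.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):  # 1-based rank from largest p down
        bound = (m - rank + 1) * p[order[rank - 1]]
        running = min(running, bound)
        adj_sorted[rank - 1] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def size_screen(
    data: pd.DataFrame, q_threshold: float = 0.5, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-(sample x species) logistic screen of morphotype against length.

    Returns one row per cell with the slope (logit per mm), raw and
    Hochberg-adjusted p-values (families formed within species), and an
    ``informative`` flag; non-informative cells (a single morphotype, or no
    length variation) carry NaN statistics and never enter the correction.
    """
    if "length_mm" not in data.columns or data["length_mm"].isna().all():
        raise ValueError("size screen requires a length_mm column with data")
    frame = data.copy()
    frame["species"] = classify_genotypes(frame["q"].to_numpy(), q_threshold)
    frame["morph_T"] = (frame["morphotype"].astype(str) == "T").astype(int)
    rows = []
    for (sid, sp), cell in frame.groupby(["sample_id", "species"], sort=True):
        cell = cell.dropna(subset=["length_mm"])
        n = len(cell)
        y = cell["morph_T"].to_numpy(dtype=float)
        length = cell["length_mm"].to_numpy(dtype=float)
        informative = (
            n >= 3 and 0 < y.sum() < n and np.ptp(length) > 0.0
        )
        row = {
            "sample_id": str(sid),
            "species": sp,
            "n": n,
            "n_T": int(y.sum()),
            "slope": np.nan,
            "se": np.nan,
            "p_raw": np.nan,
            "informative": informative,
            "method": "",
        }
        if informative:
            X = np.column_stack([np.ones(n), length])
            fit = fit_logistic_glm(y, X, names=["Intercept", "length_mm"])
            z = fit.beta[1] / fit.bse[1] if fit.bse[1] > 0 else 0.0
            row.update(
                slope=fit.beta[1],
                se=fit.bse[1],
                p_raw=float(2.0 * stats.norm.sf(abs(z))),
                method=fit.method,
            )
        rows.append(row)
    result = pd.DataFrame(rows)
    result["p_adjusted"] = np.nan
    for sp, idx in result.groupby("species").groups.items():
        mask = result.loc[idx, "informative"].to_numpy()
        fam = result.loc[idx].loc[mask]
        if len(fam):
            result.loc[fam.index, "p_adjusted"] = hochberg_adjust(fam["p_raw"].to_numpy())
    result["significant"] = result["p_adjusted"] < alpha
    return result


@dataclass(frozen=True)
class SizeResidualCheck:
    """Linear trend of correctness-model deviance residuals against length."""

    slope: float
    pvalue: float
    no_pattern: bool
    n: int


def residual_size_check(
    fit: ModelFit, data: pd.DataFrame, alpha: float = 0.05
) -> SizeResidualCheck:
    """Regress deviance residuals of a fitted model on shell length.

    Residuals use the fixed-effect fitted probabilities.  ``no_pattern`` is
    True when the slope is not significant at ``alpha`` - the expected
    outcome when morphotype expression is size-independent.
    """
    if not fit.converged:
        raise ValueError("residual check requires a converged fit")
    if "length_mm" not in data.columns:
        raise ValueError("residual check requires a length_mm column")
    length = data["length_mm"].reindex(fit.row_index).to_numpy(dtype=float)
    ok = np.isfinite(length)
    if not ok.any():
        raise ValueError("no finite lengths aligned with the fitted rows")
    y = fit.response[ok]
    p = np.clip(fit.fitted[ok], 1e-12, 1.0 - 1e-12)
    length = length[ok]
    if np.ptp(length) == 0.0:
        raise ValueError("degenerate predictor: length is constant")
    dev = np.sign(y - p) * np.sqrt(-2.0 * (y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
    res = stats.linregress(length, dev)
    return SizeResidualCheck(
        slope=float(res.slope),
        pvalue=float(res.pvalue),
        no_pattern=bool(res.pvalue >= alpha),
        n=int(length.size),
    )
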