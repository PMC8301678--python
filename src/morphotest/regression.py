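"""Regression layer: the six binomial GL(M)M model structures.

All models are individual-level logistic regressions:

* **M1** - T-morphotype (1/0) against sample prevalence ``ptros`` (and Set).
* **M4** - trossulus genotype (1/0) against sample morphotype frequency
  ``pt`` (and Set); the reference for the prevalence calculator.
* **M2 / M5** - T-morphotype against ``ptros`` x Species (x Set), with a
  sample-level random intercept: the species-conditional drift of the
  operating characteristics.
* **M3 / M6** - correct identification (trossulus-as-T or edulis-as-E = 1)
  against ``ptros`` x Morphotype (x Set), with a sample-level random
  intercept: the predictive-value curves.

M2/M3 and M5/M6 share a structure and differ only in which geographic sets
enter; both ids are accepted.  Goodness of fit is summarised by
marginal/conditional pseudo-R2 (theoretical logit residual variance
``pi^2/3``), and candidate poolings of the geographic sets are compared by
AIC refits of the M3 structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy.special import expit
from scipy.stats import norm

from .glmm import LogisticFit, fit_logistic_glm, fit_logistic_glmm
from .metrics import TROSSULUS, classify_genotypes

MODEL_IDS = ("M1", "M2", "M3", "M4", "M5", "M6")
_RANDOM_MODELS = {"M2", "M3", "M5", "M6"}
LOGIT_RESIDUAL_VAR = np.pi**2 / 3.0

__all__ = [
    "MODEL_IDS",
    "ModelFit",
    "PoolingResult",
    "prepare_model_frame",
    "model_formula",
    "fit_model",
    "pseudo_r2",
    "predict_with_ci",
    "pooling_test",
]


@dataclass
class ModelFit:
    """A fitted model with everything needed for prediction and diagnostics."""

    model_id: str
    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    sigma2_alpha: float
    loglik: float
    aic: float
    converged: bool
    separation: bool
    method: str
    n_obs: int
    formula: str
    design_info: object
    eta_fixed: np.ndarray = field(repr=False)
    response: np.ndarray = field(repr=False)
    row_index: pd.Index = field(repr=False)

    @property
    def fitted(self) -> np.ndarray:
        """Fixed-effect fitted probabilities (population-averaged curve)."""
        return expit(self.eta_fixed)


def prepare_model_frame(
    data: pd.DataFrame,
    q_threshold: float = 0.5,
    covariates: str = "empirical",
) -> pd.DataFrame:
    """Derive the modelling columns from an individual-level table.

    Adds ``species`` (q-threshold rule), the binary responses ``morph_T``,
    ``tros`` and ``correct``, and the sample-level covariates ``ptros`` and
    ``pt``.  With ``covariates='empirical'`` (what one does with field data)
    these are the observed per-sample frequencies; with ``'provided'`` the
    input must already carry ``ptros``/``pt`` columns (e.g. the design values
    of a simulation, for parameter-recovery work).
    """
    frame = data.copy()
    frame["species"] = classify_genotypes(frame["q"].to_numpy(), q_threshold)
    frame["morph_T"] = (frame["morphotype"].astype(str) == "T").astype(int)
    frame["tros"] = (frame["species"] == TROSSULUS).astype(int)
    frame["correct"] = (frame["tros"] == frame["morph_T"]).astype(int)
    if covariates == "empirical":
        grp = frame.groupby("sample_id")
        frame["ptros"] = grp["tros"].transform("mean")
        frame["pt"] = grp["morph_T"].transform("mean")
    elif covariates == "provided":
        missing = {"ptros", "pt"} - set(frame.columns)
        if missing:
            raise ValueError(f"covariates='provided' but columns missing: {sorted(missing)}")
    else:
        raise ValueError("covariates must be 'empirical' or 'provided'")
    if "set" not in frame.columns:
        frame["set"] = "ALL"
    return frame


def model_formula(
    model_id: str, frame: pd.DataFrame, parametrization: str = "interaction"
) -> str:
    """Patsy formula for a model id; Set terms drop out with a single level.

    ``parametrization='by_level'`` recodes M2/M3/M5/M6 (single-set data) as
    separate intercept and prevalence slope per factor level, which makes the
    coefficients directly comparable with the published per-morphotype
    formulas.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model id {model_id!r}; expected one of {MODEL_IDS}")
    multi_set = frame["set"].nunique() > 1
    if model_id == "M1":
        rhs = "ptros * C(set)" if multi_set else "ptros"
        return f"morph_T ~ {rhs}"
    if model_id == "M4":
        rhs = "pt * C(set)" if multi_set else "pt"
        return f"tros ~ {rhs}"
    if model_id in ("M2", "M5"):
        core, resp = "C(species)", "morph_T"
    else:  # M3 / M6
        core, resp = "C(morphotype)", "correct"
    if parametrization == "by_level":
        if multi_set:
            raise ValueError("by_level parametrization expects a single set")
        return f"{resp} ~ 0 + {core} + ptros:{core}"
    rhs = f"ptros * {core} * C(set)" if multi_set else f"ptros * {core}"
    return f"{resp} ~ {rhs}"


def fit_model(
    model_id: str,
    data: pd.DataFrame,
    q_threshold: float = 0.5,
    covariates: str = "empirical",
    formula: Optional[str] = None,
    parametrization: str = "interaction",
    n_quad: int = 15,
) -> ModelFit:
    """Fit one of the six model structures to an individual-level table.

    Models with a random term use the adaptive-quadrature GLMM engine
    (sample as the random intercept); the rest use a binomial GLM with a
    bias-reduced fallback under separation.
    """
    frame = prepare_model_frame(data, q_threshold, covariates)
    fml = formula or model_formula(model_id, frame, parametrization)
    y_dm, X_dm = patsy.dmatrices(fml, frame, return_type="dataframe")
    y = y_dm.to_numpy().ravel()
    if np.unique(y).size < 2:
        raise ValueError(f"degenerate response for {model_id}: only one outcome value")
    X = X_dm.to_numpy()
    names = list(X_dm.columns)
    if model_id in _RANDOM_MODELS:
        groups = frame.loc[X_dm.index, "sample_id"].to_numpy()
        fit = fit_logistic_glmm(y, X, groups, n_quad=n_quad, names=names)
    else:
        fit = fit_logistic_glm(y, X, names=names)
    eta_fixed = X @ fit.beta
    return ModelFit(
        model_id=model_id,
        params=pd.Series(fit.beta, index=names),
        bse=pd.Series(fit.bse, index=names),
        cov=pd.DataFrame(fit.cov, index=names, columns=names),
        sigma2_alpha=fit.sigma2,
        loglik=fit.loglik,
        aic=fit.aic,
        converged=fit.converged,
        separation=fit.separation,
        method=fit.method,
        n_obs=fit.n_obs,
        formula=fml,
        design_info=X_dm.design_info,
        eta_fixed=eta_fixed,
        response=y,
        row_index=X_dm.index,
    )


def pseudo_r2(fit: ModelFit) -> tuple[float, float]:
    """Marginal and conditional pseudo-R2 on the logit scale.

    marginal = var_f / (var_f + sigma2_alpha + pi^2/3);
    conditional adds the random-intercept variance to the numerator.
    ``var_f`` is the variance of the fixed-effect linear predictor over the
    fitted data.
    """
    if not fit.converged:
        raise ValueError("pseudo-R2 requires a converged fit")
    var_f = float(np.var(fit.eta_fixed))
    denom = var_f + fit.sigma2_alpha + LOGIT_RESIDUAL_VAR
    return var_f / denom, (var_f + fit.sigma2_alpha) / denom


def predict_with_ci(
    fit: ModelFit, newdata: pd.DataFrame, level: float = 0.95
) -> pd.DataFrame:
    """Population-averaged predictions with a Wald interval on the logit scale.

    The interval is built on the linear predictor and mapped through the
    inverse logit, so the bounds always stay inside [0, 1]; ``level=0``
    degenerates to the point estimate.
    """
    if not fit.converged:
        raise ValueError("prediction requires a converged fit")
    if not 0.0 <= level < 1.0:
        raise ValueError("level must lie in [0, 1)")
    (X_dm,) = patsy.build_design_matrices([fit.design_info], newdata, return_type="dataframe")
    X = X_dm.to_numpy()
    eta = X @ fit.params.to_numpy()
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, fit.cov.to_numpy(), X), 0.0))
    z = norm.ppf(0.5 + level / 2.0)
    return pd.DataFrame(
        {
            "fit": expit(eta),
            "lower": expit(eta - z * se),
            "upper": expit(eta + z * se),
            "eta": eta,
            "se_eta": se,
        },
        index=newdata.index,
    )


@dataclass
class PoolingResult:
    """AIC comparison of candidate poolings of the geographic sets."""

    table: pd.DataFrame
    best: tuple[tuple[str, ...], ...]
    fits: dict


def _partition_label(partition: Sequence[Sequence[str]]) -> str:
    return " + ".join("(" + "".join(sorted(g)) + ")" for g in partition)


def pooling_test(
    data: pd.DataFrame,
    partitions: Iterable[Sequence[Sequence[str]]],
    model_id: str = "M3",
    keep_fits: bool = False,
    **fit_kwargs,
) -> PoolingResult:
    """Refit the correctness model under each candidate set pooling.

    Each partition is a grouping of the set labels (e.g.
    ``[["WS","BL"],["BH"]]``); every partition must cover all sets present in
    the data exactly once.  Models are compared by AIC on the identical
    response vector; the minimum-AIC grouping is selected.
    """
    sets = set(map(str, data["set"].unique()))
    rows = []
    fits = {}
    parts = [tuple(tuple(map(str, g)) for g in p) for p in partitions]
    if not parts:
        raise ValueError("no candidate partitions supplied")
    for part in parts:
        labels = [s for g in part for s in g]
        if sorted(labels) != sorted(sets):
            raise ValueError(
                f"partition {_partition_label(part)} does not cover sets {sorted(sets)}"
            )
        mapping = {s: "".join(sorted(g)) for g in part for s in g}
        pooled = data.copy()
        pooled["set"] = pooled["set"].astype(str).map(mapping)
        fit = fit_model(model_id, pooled, **fit_kwargs)
        rows.append(
            {
                "partition": _partition_label(part),
                "n_groups": len(part),
                "aic": fit.aic,
                "converged": fit.converged,
            }
        )
        if keep_fits:
            fits[part] = fit
    table = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    best = parts[int(np.argmin([r["aic"] for r in rows]))]
    return PoolingResult(table=table, best=best, fits=fits)
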