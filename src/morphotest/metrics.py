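"""Observed-data layer of the morphotype test.

Individuals carry an admixture proportion ``q`` (estimated fraction of
*M. trossulus* genes) and a binary shell morphotype (T = uninterrupted
prismatic strip under the ligament present, E = absent).  This module
classifies individuals into the two genotype groups by the q = 0.5 rule,
builds per-sample 2x2 genotype-by-morphotype tables, and computes the four
diagnostic indices of the test in clinical-test terminology:

* sensitivity  P(T|tros) - T-morphotype frequency among trossulus genotypes
* false-positive rate  P(T|edu) = 1 - specificity
* positive predictive value  P(tros|T)
* negative predictive value  P(edu|E)

Indices with a zero denominator (e.g. PPV in a sample without T-morphotypes)
are *undefined* and carried as ``None`` - never silently coerced to 0 - so
that degenerate samples contribute no spurious rows to pooled analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

TROSSULUS = "trossulus"
EDULIS = "edulis"
Q_THRESHOLD = 0.5

__all__ = [
    "TROSSULUS",
    "EDULIS",
    "Q_THRESHOLD",
    "classify_genotype",
    "classify_genotypes",
    "SampleSummary",
    "DiagnosticIndices",
    "summarize_sample",
    "summarize_study",
    "pool_summaries",
    "diagnostic_indices",
    "summaries_frame",
]


def classify_genotype(q: float, threshold: float = Q_THRESHOLD) -> str:
    """Assign a genotype group from the admixture proportion.

    ``trossulus`` iff ``q > threshold``; the boundary is inclusive to
    ``edulis`` (a q-value of exactly 0.5 is an edulis-dominated genotype).
    """
    if not np.isfinite(q) or q < 0.0 or q > 1.0:
        raise ValueError(f"q must lie in [0, 1], got {q!r}")
    return TROSSULUS if q > threshold else EDULIS


def classify_genotypes(q: Sequence[float], threshold: float = Q_THRESHOLD) -> np.ndarray:
    """Vectorised :func:`classify_genotype`; returns an object array of labels."""
    arr = np.asarray(q, dtype=float)
    if arr.size and (np.nanmin(arr) < 0.0 or np.nanmax(arr) > 1.0 or np.isnan(arr).any()):
        bad = np.flatnonzero(~((arr >= 0.0) & (arr <= 1.0)))
        raise ValueError(f"q values outside [0, 1] at positions {bad[:10].tolist()}")
    return np.where(arr > threshold, TROSSULUS, EDULIS)


@dataclass(frozen=True)
class SampleSummary:
    """Per-sample 2x2 genotype-by-morphotype counts.

    ``n_T_tros`` counts trossulus genotypes with the T-morphotype, and so on.
    ``ptros`` is the prevalence (trossulus-genotype frequency), ``pt`` the
    T-morphotype frequency.
    """

    sample_id: str
    n_T_tros: int
    n_E_tros: int
    n_T_edu: int
    n_E_edu: int

    def __post_init__(self) -> None:
        for name in ("n_T_tros", "n_E_tros", "n_T_edu", "n_E_edu"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.n == 0:
            raise ValueError("sample summary must contain at least one individual")

    @property
    def n(self) -> int:
        return self.n_T_tros + self.n_E_tros + self.n_T_edu + self.n_E_edu

    @property
    def n_tros(self) -> int:
        return self.n_T_tros + self.n_E_tros

    @property
    def n_edu(self) -> int:
        return self.n_T_edu + self.n_E_edu

    @property
    def n_T(self) -> int:
        return self.n_T_tros + self.n_T_edu

    @property
    def n_E(self) -> int:
        return self.n_E_tros + self.n_E_edu

    @property
    def ptros(self) -> float:
        return self.n_tros / self.n

    @property
    def pt(self) -> float:
        return self.n_T / self.n


@dataclass(frozen=True)
class DiagnosticIndices:
    """The four diagnostic indices; ``None`` marks an undefined value."""

    sens: Optional[float]  # P(T|tros)
    fpr: Optional[float]   # P(T|edu) = 1 - specificity
    ppv: Optional[float]   # P(tros|T)
    npv: Optional[float]   # P(edu|E)

    @property
    def specificity(self) -> Optional[float]:
        return None if self.fpr is None else 1.0 - self.fpr


def _check_individuals(df: pd.DataFrame) -> pd.DataFrame:
    if len(df) == 0:
        raise ValueError("empty individual table")
    required = {"sample_id", "q", "morphotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"individual table missing columns: {sorted(missing)}")
    morph = df["morphotype"].astype(str)
    bad = ~morph.isin(["T", "E"])
    if bad.any():
        raise ValueError(
            f"morphotype must be 'T' or 'E'; offending values: "
            f"{sorted(morph[bad].unique())[:5]}"
        )
    return df


def summarize_sample(
    individuals: pd.DataFrame,
    sample_id: Optional[str] = None,
    threshold: float = Q_THRESHOLD,
) -> SampleSummary:
    """Count one sample's 2x2 genotype-by-morphotype table.

    All rows must share a single ``sample_id`` (passed explicitly or taken
    from the table); mixed samples are rejected.
    """
    df = _check_individuals(individuals)
    ids = df["sample_id"].unique()
    if len(ids) > 1:
        raise ValueError(f"individuals from multiple samples: {sorted(map(str, ids))[:5]}")
    sid = str(ids[0]) if sample_id is None else str(sample_id)
    species = classify_genotypes(df["q"].to_numpy(), threshold)
    morph_T = df["morphotype"].astype(str).to_numpy() == "T"
    tros = species == TROSSULUS
    return SampleSummary(
        sample_id=sid,
        n_T_tros=int(np.sum(tros & morph_T)),
        n_E_tros=int(np.sum(tros & ~morph_T)),
        n_T_edu=int(np.sum(~tros & morph_T)),
        n_E_edu=int(np.sum(~tros & ~morph_T)),
    )


def summarize_study(
    individuals: pd.DataFrame, threshold: float = Q_THRESHOLD
) -> list[SampleSummary]:
    """Per-sample summaries for a whole individual table, ordered by sample id."""
    df = _check_individuals(individuals)
    out = []
    for sid, grp in df.groupby("sample_id", sort=True):
        out.append(summarize_sample(grp, sample_id=str(sid), threshold=threshold))
    return out


def pool_summaries(
    summaries: Iterable[SampleSummary], sample_id: str = "pooled"
) -> SampleSummary:
    """Pool samples by summing the 2x2 counts (direct-count pooling)."""
    sums = [0, 0, 0, 0]
    k = 0
    for s in summaries:
        sums[0] += s.n_T_tros
        sums[1] += s.n_E_tros
        sums[2] += s.n_T_edu
        sums[3] += s.n_E_edu
        k += 1
    if k == 0:
        raise ValueError("no summaries to pool")
    return SampleSummary(sample_id, *sums)


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def diagnostic_indices(s: SampleSummary) -> DiagnosticIndices:
    """Diagnostic indices from a sample's counts; zero denominators yield None."""
    return DiagnosticIndices(
        sens=_ratio(s.n_T_tros, s.n_tros),
        fpr=_ratio(s.n_T_edu, s.n_edu),
        ppv=_ratio(s.n_T_tros, s.n_T),
        npv=_ratio(s.n_E_edu, s.n_E),
    )


def summaries_frame(summaries: Iterable[SampleSummary]) -> pd.DataFrame:
    """One row per sample: counts, frequencies, indices and defined-ness flags.

    Undefined indices appear as NaN with the matching ``*_defined`` flag False;
    this is the on-disk representation of the ``None`` sentinels.
    """
    rows = []
    for s in summaries:
        d = diagnostic_indices(s)
        rows.append(
            {
                "sample_id": s.sample_id,
                "n": s.n,
                "n_T_tros": s.n_T_tros,
                "n_E_tros": s.n_E_tros,
                "n_T_edu": s.n_T_edu,
                "n_E_edu": s.n_E_edu,
                "ptros": s.ptros,
                "pt": s.pt,
                "sens": np.nan if d.sens is None else d.sens,
                "fpr": np.nan if d.fpr is None else d.fpr,
                "ppv": np.nan if d.ppv is None else d.ppv,
                "npv": np.nan if d.npv is None else d.npv,
                "sens_defined": d.sens is not None,
                "fpr_defined": d.fpr is not None,
                "ppv_defined": d.ppv is not None,
                "npv_defined": d.npv is not None,
            }
        )
    return pd.DataFrame(rows)
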