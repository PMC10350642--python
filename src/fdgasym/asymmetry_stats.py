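"""Asymmetry index, cohort statistics, and inter-rater agreement.

The asymmetry index between the epileptogenic zone (EZ) and its
contralateral mirror region is

    AI = 100 * 2 * (SUVmean_contra - SUVmean_EZ) / (SUVmean_contra + SUVmean_EZ)

positive when the EZ side is hypometabolic.  AI1 and AI2 denote the
index at the early and delayed acquisitions; dAI = AI2 - AI1 is the
change between time points, the study's headline quantity.

Diagnostic banding follows the conventional reading that an AI between
10 and 15 is suggestive of an EZ and an AI above 15 diagnostic; the
interval is implemented closed, [10, 15], since boundary behavior is a
convention.  Cohort summaries report mean +/- sample SD of AI1/AI2/dAI
overall and by MRI status, increased/decreased counts, and a paired
t-test per stratum.  Observer concordance on a 3-category visual rating
is scored with Cohen's kappa; kappa bands are half-open [lo, hi) with
"very good" closed at 1.00.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "AIRecord",
    "CohortSummary",
    "RatingPair",
    "KappaResult",
    "asymmetry_index",
    "delta_ai",
    "classify_ai",
    "paired_t_test",
    "cohen_kappa",
    "kappa_band",
    "summarize_cohort",
    "simulate_observers",
    "ratings_contingency",
    "ai_records_from_suvmeans",
]

RATING_CATEGORIES = ("early_better", "same", "delayed_better")


def asymmetry_index(suv_ez: float, suv_contra: float) -> float:
    """AI = 200 * (contra - ez) / (contra + ez); positive when EZ hypometabolic."""
    if suv_ez < 0 or suv_contra < 0:
        raise ValueError("SUV values must be non-negative")
    denom = suv_contra + suv_ez
    if denom <= 0:
        raise ValueError("SUV sum must be positive")
    return 100.0 * 2.0 * (suv_contra - suv_ez) / denom


def delta_ai(ai1: float, ai2: float) -> float:
    """Change of asymmetry between time points, dAI = AI2 - AI1."""
    if not (math.isfinite(ai1) and math.isfinite(ai2)):
        raise ValueError("AI values must be finite")
    return ai2 - ai1


def classify_ai(ai: float) -> str:
    """Diagnostic band: <10 sub_threshold, [10, 15] suggestive, >15 diagnostic."""
    if not math.isfinite(ai):
        raise ValueError("AI must be finite")
    if ai < 10.0:
        return "sub_threshold"
    if ai <= 15.0:
        return "suggestive"
    return "diagnostic"


def paired_t_test(x_early: Sequence[float], x_delayed: Sequence[float]) -> Tuple[float, int, float]:
    """Two-sided paired t-test of delayed vs early values.

    Returns (t, df, p) with d = delayed - early, t = mean(d)/(sd(d)/sqrt(n)),
    sample (n-1) SD, df = n - 1, and p from the regularized incomplete
    beta function I_{df/(df+t^2)}(df/2, 1/2).
    """
    x_early = np.asarray(x_early, dtype=float)
    x_delayed = np.asarray(x_delayed, dtype=float)
    if x_early.shape != x_delayed.shape or x_early.ndim != 1:
        raise ValueError("inputs must be 1-D of equal length")
    n = x_early.size
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    d = x_delayed - x_early
    sd = d.std(ddof=1)
    # sd that vanishes to rounding (constant differences) is degenerate
    if sd <= 1e-12 * max(1e-300, abs(d.mean())):
        if d.mean() == 0 and sd == 0:
            return 0.0, n - 1, 1.0
        raise ZeroDivisionError("all differences identical and nonzero: t undefined")
    t = d.mean() / (sd / math.sqrt(n))
    df = n - 1
    p = float(special.betainc(df / 2.0, 0.5, df / (df + t * t)))
    return float(t), df, p


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    p_observed: float
    p_expected: float
    band: str


def cohen_kappa(contingency) -> KappaResult:
    """Cohen's kappa from a square rater-by-rater contingency table."""
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise ValueError("contingency table must be square")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    total = table.sum()
    if total <= 0:
        raise ValueError("contingency table is empty")
    p_o = np.trace(table) / total
    p_e = float((table.sum(axis=1) * table.sum(axis=0)).sum()) / total**2
    if p_e >= 1.0:
        raise ZeroDivisionError("expected agreement is 1: kappa undefined")
    kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(kappa=float(kappa), p_observed=float(p_o), p_expected=p_e, band=kappa_band(kappa))


def kappa_band(kappa: float) -> str:
    """Agreement band: <0.20 poor, [0.20,0.40) fair, [0.40,0.60) moderate,
    [0.60,0.80) good, [0.80,1.00] very good."""
    if kappa > 1.0:
        raise ValueError("kappa cannot exceed 1")
    if kappa < 0.20:
        return "poor consistency"
    if kappa < 0.40:
        return "fair agreement"
    if kappa < 0.60:
        return "moderate agreement"
    if kappa < 0.80:
        return "good agreement"
    return "very good agreement"


@dataclass(frozen=True)
class AIRecord:
    """Per-patient SUVmean pairs and derived asymmetry quantities."""

    patient_id: str
    suv_ez_early: float
    suv_contra_early: float
    suv_ez_delayed: float
    suv_contra_delayed: float
    mri_status: str
    ai1: float = field(init=False)
    ai2: float = field(init=False)
    dai: float = field(init=False)
    band1: str = field(init=False)
    band2: str = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "ai1", asymmetry_index(self.suv_ez_early, self.suv_contra_early))
        object.__setattr__(self, "ai2", asymmetry_index(self.suv_ez_delayed, self.suv_contra_delayed))
        object.__setattr__(self, "dai", delta_ai(self.ai1, self.ai2))
        object.__setattr__(self, "band1", classify_ai(self.ai1))
        object.__setattr__(self, "band2", classify_ai(self.ai2))


@dataclass(frozen=True)
class StratumStats:
    n: int
    ai1_mean: float
    ai1_sd: Optional[float]
    ai2_mean: float
    ai2_sd: Optional[float]
    dai_mean: float
    dai_sd: Optional[float]
    t: Optional[float]
    df: Optional[int]
    p: Optional[float]
    note: str = ""


@dataclass(frozen=True)
class CohortSummary:
    """Stratified cohort statistics (overall, MRI-positive, MRI-negative)."""

    strata: Dict[str, StratumStats]
    n_increased: int
    n_decreased: int
    n_unchanged: int

    @property
    def n(self) -> int:
        return self.strata["all"].n

    def pct_increased(self) -> float:
        return 100.0 * self.n_increased / self.n

    def pct_decreased(self) -> float:
        return 100.0 * self.n_decreased / self.n

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, s in self.strata.items():
            rows.append(dict(stratum=name, n=s.n, AI1_mean=s.ai1_mean, AI1_sd=s.ai1_sd,
                             AI2_mean=s.ai2_mean, AI2_sd=s.ai2_sd, dAI_mean=s.dai_mean,
                             dAI_sd=s.dai_sd, t=s.t, df=s.df, p=s.p, note=s.note))
        return pd.DataFrame(rows)


def _stratum(records: List[AIRecord]) -> StratumStats:
    n = len(records)
    ai1 = np.array([r.ai1 for r in records])
    ai2 = np.array([r.ai2 for r in records])
    dai = ai2 - ai1
    if n < 2:
        return StratumStats(
            n=n,
            ai1_mean=float(ai1.mean()) if n else float("nan"),
            ai1_sd=None, ai2_mean=float(ai2.mean()) if n else float("nan"),
            ai2_sd=None, dai_mean=float(dai.mean()) if n else float("nan"),
            dai_sd=None, t=None, df=None, p=None,
            note="n < 2: dispersion and test unavailable",
        )
    try:
        t, df, p = paired_t_test(ai1, ai2)
        note = ""
    except ZeroDivisionError:
        t = df = p = None
        note = "degenerate variance: paired t unavailable"
    return StratumStats(
        n=n,
        ai1_mean=float(ai1.mean()), ai1_sd=float(ai1.std(ddof=1)),
        ai2_mean=float(ai2.mean()), ai2_sd=float(ai2.std(ddof=1)),
        dai_mean=float(dai.mean()), dai_sd=float(dai.std(ddof=1)),
        t=t, df=None if df is None else int(df), p=p, note=note,
    )


def summarize_cohort(records: Sequence[AIRecord]) -> CohortSummary:
    """Table-style cohort summary with MRI-status stratification.

    dAI == 0 ties are counted in their own category, not folded into
    increased or decreased.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    for r in records:
        if r.mri_status not in ("positive", "negative"):
            raise ValueError(f"record {r.patient_id} lacks a valid MRI status")
    strata = {
        "all": _stratum(records),
        "mri_positive": _stratum([r for r in records if r.mri_status == "positive"]),
        "mri_negative": _stratum([r for r in records if r.mri_status == "negative"]),
    }
    dai = np.array([r.dai for r in records])
    return CohortSummary(
        strata=strata,
        n_increased=int((dai > 0).sum()),
        n_decreased=int((dai < 0).sum()),
        n_unchanged=int((dai == 0).sum()),
    )


@dataclass(frozen=True)
class RatingPair:
    patient_id: str
    obs1: str
    obs2: str

    def __post_init__(self):
        for r in (self.obs1, self.obs2):
            if r not in RATING_CATEGORIES:
                raise ValueError(f"rating {r!r} not in {RATING_CATEGORIES}")


def simulate_observers(
    records: Sequence[AIRecord],
    noise_sd: float,
    same_threshold: float,
    seed: int,
) -> List[RatingPair]:
    """Synthetic stand-in for two blinded readers of the paired images.

    Each observer perceives the patient's dAI corrupted by independent
    Normal(0, noise_sd^2) noise and rates ``delayed_better`` above
    ``+same_threshold``, ``early_better`` below ``-same_threshold``,
    otherwise ``same``.  Deterministic given ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    if same_threshold <= 0:
        raise ValueError("same-band threshold must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for r in records:
        ratings = []
        for _ in range(2):
            perceived = r.dai + (rng.standard_normal() * noise_sd if noise_sd > 0 else 0.0)
            if perceived > same_threshold:
                ratings.append("delayed_better")
            elif perceived < -same_threshold:
                ratings.append("early_better")
            else:
                ratings.append("same")
        out.append(RatingPair(patient_id=r.patient_id, obs1=ratings[0], obs2=ratings[1]))
    return out


def ratings_contingency(pairs: Sequence[RatingPair]) -> np.ndarray:
    """3x3 contingency table (observer 1 rows, observer 2 columns)."""
    table = np.zeros((3, 3), dtype=int)
    for p in pairs:
        table[RATING_CATEGORIES.index(p.obs1), RATING_CATEGORIES.index(p.obs2)] += 1
    return table


def ai_records_from_suvmeans(df: pd.DataFrame) -> List[AIRecord]:
    """Build AIRecords from a per-patient SUVmean table.

    Expects columns patient_id, suv_ez_early, suv_contra_early,
    suv_ez_delayed, suv_contra_delayed, mri_status (as produced by the
    quantification step joined with the cohort sidecar).
    """
    needed = {"patient_id", "suv_ez_early", "suv_contra_early",
              "suv_ez_delayed", "suv_contra_delayed", "mri_status"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    return [
        AIRecord(
            patient_id=str(row.patient_id),
            suv_ez_early=float(row.suv_ez_early),
            suv_contra_early=float(row.suv_contra_early),
            suv_ez_delayed=float(row.suv_ez_delayed),
            suv_contra_delayed=float(row.suv_contra_delayed),
            mri_status=str(row.mri_status),
        )
        for row in df.itertuples(index=False)
    ]
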