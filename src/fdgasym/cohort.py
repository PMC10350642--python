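"""Clinical-table handling: the 52-patient TLE cohort and its demographics.

Ships the demographic and clinical table of the 52-patient temporal-lobe
-epilepsy cohort as a packaged CSV fixture, transcribed exactly as
printed (including its internal tensions — e.g. the count of rows with
a literally "Negative" MRI field differs from the stated MRI-negative
group size of 18).  The fixture is never corrected; demographics are
recomputed from what the rows contain.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["PatientRow", "Demographics", "table1_path", "load_table1", "demographics"]

_COLUMNS = ["patient", "gender", "age", "veeg", "mri", "pet", "mdt_ez"]


@dataclass(frozen=True)
class PatientRow:
    patient: int
    gender: str  # M | F
    age: int
    veeg: str  # L | R | Negative
    mri: str  # "Negative" or side/region/etiology
    pet: str
    mdt_ez: str

    def __post_init__(self):
        if self.gender not in ("M", "F"):
            raise ValueError(f"patient {self.patient}: unknown gender token {self.gender!r}")
        if not (10 <= self.age <= 65):
            raise ValueError(f"patient {self.patient}: age {self.age} outside [10, 65]")


@dataclass(frozen=True)
class Demographics:
    n: int
    male_count: int
    male_pct: float
    age_mean: float
    age_sd: Optional[float]  # None when n < 2
    veeg_negative: int
    mri_negative: int
    pet_negative: int
    side_counts: Dict[str, Dict[str, int]]  # modality -> {"L": ..., "R": ...}


def table1_path():
    """Path-like handle to the packaged cohort table fixture."""
    return importlib.resources.files("fdgasym") / "data" / "table1.csv"


def load_table1(path=None) -> List[PatientRow]:
    """Load and validate the clinical table (the packaged fixture by default)."""
    source = table1_path() if path is None else path
    with importlib.resources.as_file(source) if path is None else _nullctx(source) as p:
        try:
            df = pd.read_csv(p, dtype=str)
        except pd.errors.EmptyDataError as exc:
            raise ValueError(f"{source}: empty or unparseable table") from exc
    if list(df.columns) != _COLUMNS:
        raise ValueError(f"expected columns {_COLUMNS}, found {list(df.columns)}")
    if df.empty:
        raise ValueError(f"{source}: table has no rows")
    rows = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        try:
            rows.append(
                PatientRow(
                    patient=int(rec.patient),
                    gender=str(rec.gender),
                    age=int(rec.age),
                    veeg=str(rec.veeg),
                    mri=str(rec.mri),
                    pet=str(rec.pet),
                    mdt_ez=str(rec.mdt_ez),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    return rows


class _nullctx:
    def __init__(self, value):
        self.value = value

    def __enter__(self):
        return self.value

    def __exit__(self, *exc):
        return False


def write_table(rows: Sequence[PatientRow], path) -> None:
    pd.DataFrame([r.__dict__ for r in rows], columns=_COLUMNS).to_csv(path, index=False)


def _side_counts(values: Sequence[str]) -> Dict[str, int]:
    out = {"L": 0, "R": 0}
    for v in values:
        side = v.split("/")[0]
        if side in out:
            out[side] += 1
    return out


def demographics(rows: Sequence[PatientRow]) -> Demographics:
    """Recompute cohort demographics from the clinical rows.

    MRI/PET/VEEG-negative counts are rows whose field equals "Negative"
    literally; side counts take the leading L/R token of each finding.
    Percentages are 100*count/n rounded to 2 decimals; age SD is the
    sample (n-1) SD and unavailable for a single row.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("need at least one row")
    n = len(rows)
    ages = np.array([r.age for r in rows], dtype=float)
    male = sum(1 for r in rows if r.gender == "M")
    return Demographics(
        n=n,
        male_count=male,
        male_pct=round(100.0 * male / n, 2),
        age_mean=float(ages.mean()),
        age_sd=float(ages.std(ddof=1)) if n >= 2 else None,
        veeg_negative=sum(1 for r in rows if r.veeg == "Negative"),
        mri_negative=sum(1 for r in rows if r.mri == "Negative"),
        pet_negative=sum(1 for r in rows if r.pet == "Negative"),
        side_counts={
            "veeg": _side_counts([r.veeg for r in rows]),
            "mri": _side_counts([r.mri for r in rows]),
            "pet": _side_counts([r.pet for r in rows]),
            "mdt_ez": _side_counts([r.mdt_ez for r in rows]),
        },
    )
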