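"""Health-expenditure impoverishment and the HFGT poverty index family.

A household is *health-expenditure impoverished* when its pre-expenditure
income is at or above the poverty line z but its income net of
out-of-pocket (OOP) health spending falls below z. The HFGT index adapts
the Foster–Greer–Thorbecke family to this population:

    HFGT_alpha = (1/n) * sum_{i impoverished} ((z - y_i) / z) ** alpha

where n counts all households in the group (including the already poor),
y_i is post-expenditure income floored at 0, and alpha in {0, 1, 2} gives
the *breadth* (headcount ratio), *depth* (poverty gap) and *strength*
(squared poverty gap) of health-expenditure poverty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HouseholdRecord",
    "PovertyLine",
    "RegionalPovertyProfile",
    "CleaningReport",
    "HOUSEHOLD_COLUMNS",
    "out_of_pocket",
    "classify_impoverished",
    "hfgt",
    "regional_profiles",
    "adjust_poverty_line",
    "clean_records",
]

logger = logging.getLogger(__name__)

HOUSEHOLD_COLUMNS = ("region_id", "income", "health_exp_total",
                     "reimbursed", "expected_reimbursed")

IMPOVERISHED = "impoverished"
ALREADY_POOR = "already_poor"
NON_POOR = "non_poor"


@dataclass(frozen=True)
class HouseholdRecord:
    """One surveyed household: income, health spending, reimbursement, region."""

    region_id: object
    income: float
    health_exp_total: float
    reimbursed: float
    expected_reimbursed: float

    def __post_init__(self) -> None:
        for name in ("income", "health_exp_total", "reimbursed", "expected_reimbursed"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")


@dataclass(frozen=True)
class PovertyLine:
    """An annual income threshold z in RMB/year."""

    z: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.z > 0):
            raise ValueError(f"poverty line must be positive, got {self.z}")


@dataclass(frozen=True)
class RegionalPovertyProfile:
    region_id: object
    n: int
    q: int
    breadth: float
    depth: float
    strength: float


def _as_frame(records) -> pd.DataFrame:
    """Canonicalize records (DataFrame or iterable of HouseholdRecord)."""
    if isinstance(records, pd.DataFrame):
        missing = [c for c in HOUSEHOLD_COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"household table missing columns: {missing}")
        return records
    rows = list(records)
    if rows and isinstance(rows[0], HouseholdRecord):
        return pd.DataFrame([r.__dict__ for r in rows])
    return pd.DataFrame(rows, columns=list(HOUSEHOLD_COLUMNS))


def out_of_pocket(record: HouseholdRecord) -> float:
    """Out-of-pocket health spending: total minus (expected-)reimbursed.

    A negative raw difference (over-reimbursement) is clamped to 0 and
    logged; the clamp-and-flag policy keeps such records usable.
    """
    raw = record.health_exp_total - record.reimbursed - record.expected_reimbursed
    if raw < 0:
        logger.warning("household in region %s: reimbursement exceeds health expenditure "
                       "(%.2f); out-of-pocket clamped to 0", record.region_id, raw)
        return 0.0
    return raw


def _oop_vector(frame: pd.DataFrame) -> np.ndarray:
    raw = (frame["health_exp_total"] - frame["reimbursed"]
           - frame["expected_reimbursed"]).to_numpy(dtype=float)
    n_clamped = int(np.count_nonzero(raw < 0))
    if n_clamped:
        logger.warning("%d households with reimbursement exceeding expenditure; "
                       "out-of-pocket clamped to 0", n_clamped)
    return np.maximum(raw, 0.0)


def classify_impoverished(record: HouseholdRecord, line: PovertyLine) -> str:
    """Classify one household against the poverty line.

    ``already_poor`` if pre-expenditure income is below z (excluded from q);
    ``impoverished`` if income >= z but income net of OOP drops below z;
    ``non_poor`` otherwise.
    """
    if record.income < line.z:
        return ALREADY_POOR
    if record.income - out_of_pocket(record) < line.z:
        return IMPOVERISHED
    return NON_POOR


def _classify_vector(frame: pd.DataFrame, line: PovertyLine) -> np.ndarray:
    income = frame["income"].to_numpy(dtype=float)
    post = income - _oop_vector(frame)
    out = np.full(len(frame), NON_POOR, dtype=object)
    out[income < line.z] = ALREADY_POOR
    out[(income >= line.z) & (post < line.z)] = IMPOVERISHED
    return out


def hfgt(records, line: PovertyLine, alpha: int) -> float:
    """HFGT index at poverty-aversion coefficient alpha in {0, 1, 2}.

    y_i is post-expenditure income of the impoverished, floored at 0, so
    each gap ratio (z - y_i)/z lies in (0, 1]. With 0**0 = 1, alpha = 0
    yields the headcount ratio q/n.
    """
    if alpha not in (0, 1, 2):
        raise ValueError(f"alpha must be 0, 1 or 2, got {alpha}")
    frame = _as_frame(records)
    if len(frame) == 0:
        raise ValueError("hfgt requires at least one record")
    status = _classify_vector(frame, line)
    poor = status == IMPOVERISHED
    if not poor.any():
        return 0.0
    income = frame["income"].to_numpy(dtype=float)[poor]
    post = np.maximum(income - _oop_vector(frame)[poor], 0.0)
    gap = (line.z - post) / line.z
    return float(np.sum(gap ** alpha) / len(frame))


def regional_profiles(records, line: PovertyLine) -> pd.DataFrame:
    """Per-region n, q and HFGT at alpha = 0, 1, 2, ordered by region_id.

    Returns a DataFrame with columns
    (region_id, n, q, breadth, depth, strength); regions with zero records
    simply do not appear.
    """
    frame = _as_frame(records)
    if len(frame) == 0:
        raise ValueError("regional_profiles requires at least one record")
    status = _classify_vector(frame, line)
    post = np.maximum(frame["income"].to_numpy(dtype=float) - _oop_vector(frame), 0.0)
    gap = np.where(status == IMPOVERISHED, (line.z - post) / line.z, 0.0)
    aux = pd.DataFrame({
        "region_id": frame["region_id"].to_numpy(),
        "poor": (status == IMPOVERISHED).astype(float),
        "gap": gap,
        "gap2": gap ** 2,
    })
    g = aux.groupby("region_id", sort=True)
    out = pd.DataFrame({
        "n": g.size(),
        "q": g["poor"].sum().astype(int),
        "breadth": g["poor"].mean(),
        "depth": g["gap"].mean(),
        "strength": g["gap2"].mean(),
    }).reset_index()
    return out


def profiles_as_records(profiles: pd.DataFrame) -> list[RegionalPovertyProfile]:
    """Typed view of :func:`regional_profiles` output."""
    return [RegionalPovertyProfile(**row) for row in profiles.to_dict("records")]


def adjust_poverty_line(base: PovertyLine, cpi_yoy_percent: Sequence[float]) -> PovertyLine:
    """Chain the line forward through year-over-year CPI percent changes.

    z_new = z * prod_t (1 + rate_t / 100); the label records the chain.
    """
    rates = [float(r) for r in cpi_yoy_percent]
    if any(r <= -100 for r in rates):
        raise ValueError("CPI rates must exceed -100 percent")
    factor = float(np.prod([1.0 + r / 100.0 for r in rates])) if rates else 1.0
    label = (f"{base.label or base.z} chained through CPI "
             f"{'% , '.join(f'{r:g}' for r in rates)}%" if rates else base.label)
    return PovertyLine(z=base.z * factor, label=label)


@dataclass
class CleaningReport:
    """Counts of rows kept and dropped, by reason."""

    n_input: int
    n_kept: int
    dropped: dict = field(default_factory=dict)  # reason -> count


def clean_records(
    raw: pd.DataFrame,
    income_trim: float | None = None,
    expenditure_trim: float | None = None,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Drop unusable rows from a raw household table.

    Rows are dropped when any required field is missing or when income or
    health expenditure is negative. ``income_trim`` / ``expenditure_trim``
    optionally drop rows above an absolute upper bound (default: no trim).
    """
    missing_cols = [c for c in HOUSEHOLD_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"household table missing columns: {missing_cols}")
    df = raw.copy()
    report = CleaningReport(n_input=len(df), n_kept=0)

    monetary = list(HOUSEHOLD_COLUMNS[1:])
    mask_missing = df[list(HOUSEHOLD_COLUMNS)].isna().any(axis=1)
    report.dropped["missing"] = int(mask_missing.sum())
    df = df[~mask_missing]

    mask_negative = (df[monetary] < 0).any(axis=1)
    report.dropped["negative"] = int(mask_negative.sum())
    df = df[~mask_negative]

    if income_trim is not None:
        mask = df["income"] > income_trim
        report.dropped["income_trim"] = int(mask.sum())
        df = df[~mask]
    if expenditure_trim is not None:
        mask = df["health_exp_total"] > expenditure_trim
        report.dropped["expenditure_trim"] = int(mask.sum())
        df = df[~mask]

    report.n_kept = len(df)
    if report.n_kept == 0:
        raise ValueError("no rows survive cleaning")
    return df.reset_index(drop=True), report
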