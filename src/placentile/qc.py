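"""Segmentation and volumetry quality control.

Two QC operators on an assembled cohort:

* Dice-similarity triage — each case carries the Dice agreement between two
  independent segmentations of the placenta and of the amniotic fluid;
  cases falling below review thresholds are flagged in three sequential
  rounds (placenta < 0.60; placenta < 0.75 and fluid < 0.40; fluid < 0.40).

* per-gestational-day Tukey-fence outlier detection on placental volume —
  within each day of gestation, values strictly outside
  [Q1 - 1.5*IQR, Q3 + 1.5*IQR] are flagged, quartiles by the
  linear-interpolation sample-quantile convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: triage thresholds: (placenta round 1, placenta round 2, fluid rounds 2-3)
TRIAGE_THRESHOLDS = {"placenta_r1": 0.60, "placenta_r2": 0.75, "fluid": 0.40}

#: fewer observations than this in a gestational-day group exempts the group
#: from fence computation (quartiles would be meaningless)
MIN_GROUP_SIZE = 4

IQR_MULTIPLIER = 1.5


@dataclass
class SegmentationPair:
    """Dice agreement between two segmentations of the same case."""

    case_id: object
    dice_placenta: float | None
    dice_fluid: float | None

    def __post_init__(self):
        for v in (self.dice_placenta, self.dice_fluid):
            if v is not None and not np.isnan(v) and not 0.0 <= v <= 1.0:
                raise ValueError(f"Dice value {v} outside [0, 1]")


@dataclass
class QCReport:
    """Triage decisions and volume-outlier flags with their fences."""

    triage: pd.DataFrame = field(default_factory=pd.DataFrame)
    outliers: pd.DataFrame = field(default_factory=pd.DataFrame)

    def excluded_ids(self) -> set:
        ids = set()
        if len(self.triage):
            ids |= set(self.triage.loc[self.triage["round"] > 0, "case_id"])
        if len(self.outliers):
            ids |= set(self.outliers.loc[self.outliers["outlier"], "case_id"])
        return ids


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A^B| / (|A| + |B|) of two binary masks.

    Defined as 1.0 when both masks are empty (identical-by-vacuity; logged).
    """
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    size_a, size_b = int(a.sum()), int(b.sum())
    if size_a + size_b == 0:
        log.info("dice: both masks empty, returning 1.0")
        return 1.0
    inter = int(np.logical_and(a, b).sum())
    return 2.0 * inter / (size_a + size_b)


def triage_rounds(pairs) -> pd.DataFrame:
    """Assign each segmentation pair its review round (or 0 = pass).

    Rounds are evaluated sequentially with first-match-wins:
    1. placental Dice < 0.60, irrespective of fluid agreement;
    2. placental Dice < 0.75 and fluid Dice < 0.40;
    3. fluid Dice < 0.40, irrespective of placental agreement.
    A case with a missing Dice value is marked unresolvable (round -1).
    """
    rows = []
    for pair in pairs:
        dp, df_ = pair.dice_placenta, pair.dice_fluid
        missing = any(v is None or (isinstance(v, float) and np.isnan(v)) for v in (dp, df_))
        if missing:
            rows.append({"case_id": pair.case_id, "round": -1, "reason": "missing Dice value"})
            continue
        if dp < TRIAGE_THRESHOLDS["placenta_r1"]:
            rnd, why = 1, f"placenta Dice {dp:.3f} < {TRIAGE_THRESHOLDS['placenta_r1']}"
        elif dp < TRIAGE_THRESHOLDS["placenta_r2"] and df_ < TRIAGE_THRESHOLDS["fluid"]:
            rnd, why = 2, (
                f"placenta Dice {dp:.3f} < {TRIAGE_THRESHOLDS['placenta_r2']} "
                f"and fluid Dice {df_:.3f} < {TRIAGE_THRESHOLDS['fluid']}"
            )
        elif df_ < TRIAGE_THRESHOLDS["fluid"]:
            rnd, why = 3, f"fluid Dice {df_:.3f} < {TRIAGE_THRESHOLDS['fluid']}"
        else:
            rnd, why = 0, "pass"
        rows.append({"case_id": pair.case_id, "round": rnd, "reason": why})
    return pd.DataFrame(rows, columns=["case_id", "round", "reason"])


def iqr_outliers(volumes, ga_days, case_ids=None) -> pd.DataFrame:
    """Per-gestational-day Tukey-fence outlier flags on placental volume.

    Within each day group of at least ``MIN_GROUP_SIZE`` observations,
    Q1/Q3 are linear-interpolation sample quantiles and values strictly
    outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR] are flagged.  Smaller groups are
    exempt (flag False, fences NaN) and logged.
    """
    volumes = np.asarray(volumes, float)
    ga_days = np.asarray(ga_days)
    if volumes.size == 0:
        raise ValueError("empty input")
    if case_ids is None:
        case_ids = np.arange(volumes.size)
    df = pd.DataFrame({"case_id": case_ids, "ga_days": ga_days, "volume": volumes})
    df["q1"] = np.nan
    df["q3"] = np.nan
    df["fence_low"] = np.nan
    df["fence_high"] = np.nan
    df["outlier"] = False
    for day, idx in df.groupby("ga_days").groups.items():
        vals = df.loc[idx, "volume"].to_numpy()
        if vals.size < MIN_GROUP_SIZE:
            log.info("iqr_outliers: day %s has %d < %d cases, exempt", day, vals.size, MIN_GROUP_SIZE)
            continue
        q1, q3 = np.quantile(vals, [0.25, 0.75])  # linear interpolation default
        iqr = q3 - q1
        lo, hi = q1 - IQR_MULTIPLIER * iqr, q3 + IQR_MULTIPLIER * iqr
        df.loc[idx, ["q1", "q3", "fence_low", "fence_high"]] = [q1, q3, lo, hi]
        df.loc[idx, "outlier"] = (vals < lo) | (vals > hi)
    return df


def qc_report(cohort: pd.DataFrame) -> QCReport:
    """Run both QC stages on a cohort table.

    Expects columns ``case_id``, ``dice_placenta``, ``dice_fluid``,
    ``placental_volume``, ``ga_days``.
    """
    pairs = [
        SegmentationPair(r.case_id, r.dice_placenta, r.dice_fluid)
        for r in cohort.itertuples(index=False)
    ]
    triage = triage_rounds(pairs)
    passing = cohort[cohort["case_id"].isin(triage.loc[triage["round"] == 0, "case_id"])]
    outliers = iqr_outliers(
        passing["placental_volume"].to_numpy(),
        passing["ga_days"].to_numpy(),
        passing["case_id"].to_numpy(),
    )
    return QCReport(triage=triage, outliers=outliers)
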