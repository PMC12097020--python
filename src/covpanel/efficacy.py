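"""Scalar efficacy and culture-health quantifications.

Killing fractions from dual-stain co-culture tables (tumor nuclear label x
PI death stain), AO/PI viability percentages, organoid growth curves
relative to baseline, a power-law diameter-to-cell-count calibration,
culture success rates, and the five-criterion GvHD composite welfare score.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import InputError

GVHD_CRITERIA = (
    "weight_loss",
    "activity",
    "posture",
    "fur_texture",
    "skin_integrity",
)


def _round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def killing_fraction(
    labels: pd.DataFrame, condition: str, timepoint_h: float
) -> float:
    """Percent of tumor cells that are death-stain positive in one stratum.

    The stratum is condition x timepoint. Only tumor-stain-positive cells
    enter numerator and denominator; bystander (non-tumor) cells in the
    table never affect the result.
    """
    required = {"tumor_stain", "death_stain", "condition", "timepoint_h"}
    missing = required - set(labels.columns)
    if missing:
        raise InputError(f"label table missing columns: {sorted(missing)}")
    stratum = labels[
        (labels["condition"] == condition) & (labels["timepoint_h"] == timepoint_h)
    ]
    tumor = stratum[stratum["tumor_stain"].astype(bool)]
    if tumor.empty:
        raise InputError(
            f"no tumor-stain-positive cells in stratum "
            f"(condition={condition!r}, timepoint={timepoint_h} h)"
        )
    return 100.0 * tumor["death_stain"].astype(bool).mean()


def viability_percent(live_count: int, dead_count: int) -> tuple[float, float]:
    """(percent dead, percent live) from AO/PI live/dead counts."""
    if live_count < 0 or dead_count < 0:
        raise InputError("counts must be non-negative")
    total = live_count + dead_count
    if total == 0:
        raise InputError("live + dead counts are zero")
    dead = 100.0 * dead_count / total
    return dead, 100.0 - dead


def growth_curve(observations: pd.DataFrame) -> pd.DataFrame:
    """Per-spheroid relative size over time.

    Relative size = diameter(day) / diameter(earliest day per spheroid);
    the earliest observation maps to exactly 1.0. Input days may be
    unordered; rows are sorted per spheroid before ratioing.
    """
    required = {"spheroid_id", "day", "diameter_um"}
    missing = required - set(observations.columns)
    if missing:
        raise InputError(f"observation table missing columns: {sorted(missing)}")
    if (observations["diameter_um"] <= 0).any():
        raise InputError("diameters must be positive")
    if (observations["day"] < 0).any():
        raise InputError("days must be non-negative")
    df = observations.sort_values(["spheroid_id", "day"], kind="stable").copy()
    baseline = df.groupby("spheroid_id")["diameter_um"].transform("first")
    df["relative_size"] = df["diameter_um"] / baseline
    return df.reset_index(drop=True)


@dataclass
class PowerLawFit:
    """count(d) = a * d**b, fit by least squares on the log-log scale."""

    a: float
    b: float
    r_squared: float

    def predict(self, diameter_um) -> np.ndarray:
        return self.a * np.asarray(diameter_um, dtype=float) ** self.b


def diameter_count_fit(diameters_um, counts) -> PowerLawFit:
    """Calibrate a spheroid diameter -> dissociated-cell-count power law.

    Fits log(count) = log(a) + b*log(d) by ordinary least squares; on
    noiseless power-law data the exponent is recovered exactly. Requires
    >= 3 pairs with distinct, positive diameters and positive counts.
    """
    d = np.asarray(diameters_um, dtype=float)
    c = np.asarray(counts, dtype=float)
    if d.size != c.size or d.size < 3:
        raise InputError("need >= 3 paired (diameter, count) observations")
    if np.any(d <= 0) or np.any(c <= 0):
        raise InputError("diameters and counts must be positive")
    if np.unique(d).size < d.size:
        raise InputError("diameters must be distinct")
    logd, logc = np.log(d), np.log(c)
    b, loga = np.polyfit(logd, logc, 1)
    resid = logc - (loga + b * logd)
    ss_tot = np.sum((logc - logc.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2) / ss_tot)
    return PowerLawFit(a=float(np.exp(loga)), b=float(b), r_squared=r2)


def success_rate(n_success: int, n_total: int) -> float:
    """Culture success percentage, rounded half-up to 2 decimals."""
    if n_total <= 0:
        raise InputError("n_total must be positive")
    if not 0 <= n_success <= n_total:
        raise InputError("need 0 <= n_success <= n_total")
    return _round_half_up(100.0 * n_success / n_total, 2)


@dataclass
class GvhdScore:
    """Five-criterion composite welfare score, each 0 (normal), 1 (mild) or
    2 (moderate/severe); total ranges 0-10."""

    sub_scores: dict[str, int]
    total: int


def gvhd_score(sub_scores) -> GvhdScore:
    """Compose the GvHD score from the five criterion sub-scores.

    Accepts a sequence of five values (criterion order: weight loss,
    activity, posture, fur texture, skin integrity) or a mapping from
    criterion name to value.
    """
    if isinstance(sub_scores, dict):
        missing = set(GVHD_CRITERIA) - set(sub_scores)
        extra = set(sub_scores) - set(GVHD_CRITERIA)
        if missing or extra:
            raise InputError(
                f"sub-scores must be exactly {GVHD_CRITERIA}; "
                f"missing={sorted(missing)}, unknown={sorted(extra)}"
            )
        values = {k: sub_scores[k] for k in GVHD_CRITERIA}
    else:
        seq = list(sub_scores)
        if len(seq) != len(GVHD_CRITERIA):
            raise InputError(f"expected {len(GVHD_CRITERIA)} sub-scores, got {len(seq)}")
        values = dict(zip(GVHD_CRITERIA, seq))
    for k, v in values.items():
        if v not in (0, 1, 2):
            raise InputError(f"sub-score {k}={v!r} outside {{0, 1, 2}}")
    return GvhdScore(sub_scores=values, total=int(sum(values.values())))
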