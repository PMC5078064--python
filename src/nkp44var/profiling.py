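"""Splice-variant fraction computation and sample profile classification.

Each NKp46-positive sample is assigned one of three splice-variant
profiles from the expression of the three NCR2/NKp44 isoforms:

* ``NKP44_1`` — solitary NKp44-1 expression (NKp44-2 and -3 both at or
  below threshold, NKp44-1 above);
* ``NKP44_2_3`` — any expression of NKp44-2 and/or NKp44-3, with or
  without NKp44-1;
* ``NKP44_NEG`` — no isoform above threshold.

Samples that fail the NKp46/NCR1 positivity filter are excluded as
``EXCLUDED_NKP46_NEG``. The NKp44-1 profile group is further split at the
median of NKp44-1 expression normalized to NCR1 into HIGH and LOW
subgroups.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProfileLabel",
    "Subgroup",
    "Nkp44Fractions",
    "SampleClassification",
    "call_positive",
    "isoform_fractions",
    "classify_profile",
    "classify_sample",
    "split_high_low",
    "cohort_summary",
    "classification_frame",
    "positive_share",
]


class ProfileLabel(str, Enum):
    NKP44_1 = "NKP44_1"
    NKP44_2_3 = "NKP44_2_3"
    NKP44_NEG = "NKP44_NEG"
    EXCLUDED_NKP46_NEG = "EXCLUDED_NKP46_NEG"


class Subgroup(str, Enum):
    HIGH = "HIGH"
    LOW = "LOW"
    NA = "NA"


@dataclass(frozen=True)
class Nkp44Fractions:
    """Percent of total NKp44 mRNA attributed to each splice variant.

    All three are NaN when the isoform total is zero (fractions of
    nothing are undefined, not zero).
    """

    f1: float
    f2: float
    f3: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.f1)


@dataclass(frozen=True)
class SampleClassification:
    barcode: str
    ncr1_value: float
    ncr2_total: float
    v1: float
    v2: float
    v3: float
    fractions: Nkp44Fractions
    label: ProfileLabel
    nkp44_1_norm: float = float("nan")
    subgroup: Subgroup = Subgroup.NA


def call_positive(value: float, threshold: float = 0.0) -> bool:
    """Positivity call on a normalized expression value: value > threshold.

    Strict inequality, so with the default threshold 0 a value reported
    as exactly 0 is negative and any strictly positive value is positive.
    """
    if not np.isfinite(value):
        raise ValueError(f"expression value must be finite, got {value}")
    if value < 0:
        raise ValueError(f"expression value must be >= 0, got {value}")
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    return value > threshold


def isoform_fractions(v1: float, v2: float, v3: float) -> Nkp44Fractions:
    """Percent of each splice variant out of the summed isoform expression.

    The denominator is v1+v2+v3; a zero total yields all-NaN fractions.
    """
    vals = (v1, v2, v3)
    if any(not np.isfinite(v) or v < 0 for v in vals):
        raise ValueError(f"isoform values must be finite and >= 0, got {vals}")
    total = v1 + v2 + v3
    if total == 0:
        nan = float("nan")
        return Nkp44Fractions(nan, nan, nan)
    return Nkp44Fractions(100.0 * v1 / total, 100.0 * v2 / total, 100.0 * v3 / total)


def classify_profile(
    ncr1: float,
    v1: float,
    v2: float,
    v3: float,
    tau_ncr1: float = 0.0,
    tau_isoform: float = 0.0,
) -> ProfileLabel:
    """Assign the splice-variant profile label from raw expression values.

    NKp46-negative samples are excluded; otherwise NKP44_1 requires
    NKp44-1 positive with both other variants non-positive, NKP44_2_3 any
    NKp44-2/-3 positivity, NKP44_NEG none. A sample whose isoforms are all
    at threshold is NKp44-negative even if the gene-level NCR2 total is
    positive.
    """
    if not call_positive(ncr1, tau_ncr1):
        return ProfileLabel.EXCLUDED_NKP46_NEG
    p1 = call_positive(v1, tau_isoform)
    p2 = call_positive(v2, tau_isoform)
    p3 = call_positive(v3, tau_isoform)
    if not (p1 or p2 or p3):
        return ProfileLabel.NKP44_NEG
    if p1 and not (p2 or p3):
        return ProfileLabel.NKP44_1
    return ProfileLabel.NKP44_2_3


def classify_sample(
    barcode: str,
    ncr1: float,
    v1: float,
    v2: float,
    v3: float,
    *,
    ncr2_total: float | None = None,
    tau_ncr1: float = 0.0,
    tau_isoform: float = 0.0,
) -> SampleClassification:
    """Full per-sample classification record (fractions + profile label)."""
    label = classify_profile(ncr1, v1, v2, v3, tau_ncr1, tau_isoform)
    return SampleClassification(
        barcode=barcode,
        ncr1_value=ncr1,
        ncr2_total=(v1 + v2 + v3) if ncr2_total is None else ncr2_total,
        v1=v1,
        v2=v2,
        v3=v3,
        fractions=isoform_fractions(v1, v2, v3),
        label=label,
    )


def split_high_low(classified: Sequence[SampleClassification]) -> list[SampleClassification]:
    """Median-split the NKp44-1 profile group on NKp44-1/NCR1 into HIGH and LOW.

    Input must contain only NKP44_1-labelled samples with NCR1 > 0. The
    ratio v1/ncr1 is sorted descending (ties broken by barcode, ascending)
    and the top half becomes HIGH; for odd n the middle sample goes to LOW.
    """
    for c in classified:
        if c.label is not ProfileLabel.NKP44_1:
            raise ValueError(
                f"split_high_low expects only NKP44_1 samples, got {c.label} "
                f"for {c.barcode}"
            )
        if c.ncr1_value <= 0:
            raise ValueError(
                f"NCR1 value must be > 0 to normalize NKp44-1 ({c.barcode})"
            )
    ranked = sorted(classified, key=lambda c: (-(c.v1 / c.ncr1_value), c.barcode))
    n = len(ranked)
    n_high = n // 2
    out = []
    for i, c in enumerate(ranked):
        out.append(
            replace(
                c,
                nkp44_1_norm=c.v1 / c.ncr1_value,
                subgroup=Subgroup.HIGH if i < n_high else Subgroup.LOW,
            )
        )
    return out


def cohort_summary(classified: Sequence[SampleClassification]) -> pd.DataFrame:
    """Per-profile counts and mean/SD of the splice-variant percentages."""
    rows = []
    for label in ProfileLabel:
        members = [c for c in classified if c.label is label]
        fr = np.array(
            [(c.fractions.f1, c.fractions.f2, c.fractions.f3) for c in members]
            or np.empty((0, 3))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            means = np.nanmean(fr, axis=0) if len(fr) else np.full(3, np.nan)
            sds = np.nanstd(fr, axis=0, ddof=1) if len(fr) > 1 else np.full(3, np.nan)
        rows.append(
            {
                "label": label.value,
                "n": len(members),
                "mean_f1": means[0], "mean_f2": means[1], "mean_f3": means[2],
                "sd_f1": sds[0], "sd_f2": sds[1], "sd_f3": sds[2],
            }
        )
    return pd.DataFrame(rows).set_index("label")


def classification_frame(classified: Sequence[SampleClassification]) -> pd.DataFrame:
    """Flat classification table (one row per sample) for TSV export."""
    return pd.DataFrame(
        {
            "barcode": [c.barcode for c in classified],
            "ncr1": [c.ncr1_value for c in classified],
            "v1": [c.v1 for c in classified],
            "v2": [c.v2 for c in classified],
            "v3": [c.v3 for c in classified],
            "f1": [c.fractions.f1 for c in classified],
            "f2": [c.fractions.f2 for c in classified],
            "f3": [c.fractions.f3 for c in classified],
            "label": [c.label.value for c in classified],
            "nkp44_1_norm": [c.nkp44_1_norm for c in classified],
            "subgroup": [c.subgroup.value for c in classified],
        }
    )


def positive_share(n_positive: int, n_total: int) -> float:
    """Percentage share of positive calls, rounded to whole percent.

    The cohort-level incidence figure reported alongside the positivity
    filter (e.g. the share of NKp44+ samples among NKp46+ cases).
    """
    if n_total <= 0 or n_positive < 0 or n_positive > n_total:
        raise ValueError(f"invalid counts {n_positive}/{n_total}")
    return round(100.0 * n_positive / n_total)
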