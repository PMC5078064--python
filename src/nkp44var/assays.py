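"""Wet-lab assay arithmetic: qPCR quantification and functional readouts.

Covers relative expression by the 2^-dCt method against a reference gene
(GAPDH role), splice-variant percentages from qPCR signals, primer
amplification efficiency from a dilution-curve slope, specific
cytotoxicity from a release assay, normalization to a control condition,
and the immune-synapse F-actin MFI ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .profiling import Nkp44Fractions

__all__ = [
    "CtMeasurement",
    "VariantExpressionSet",
    "LysisAssay",
    "delta_ct_expression",
    "qpcr_variant_percentages",
    "amplification_efficiency",
    "efficiency_to_slope",
    "specific_cytotoxicity",
    "relative_to_control",
    "synapse_factin_ratio",
    "ratio_percent_change",
]


@dataclass(frozen=True)
class CtMeasurement:
    """Threshold cycles of a target and the reference gene for one sample."""

    target_ct: float
    reference_ct: float

    def __post_init__(self):
        for name in ("target_ct", "reference_ct"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
            if not (0.0 <= v <= 45.0):
                warnings.warn(
                    f"{name}={v} outside the typical 0-45 cycle range",
                    stacklevel=3,
                )


@dataclass(frozen=True)
class VariantExpressionSet:
    """2^-dCt expression of the three NKp44 splice variants.

    ``e_total`` is the optional signal from the total-NKp44 primer set,
    used when percentages are taken over the measured total rather than
    the variant sum.
    """

    e1: float
    e2: float
    e3: float
    e_total: float | None = None

    def __post_init__(self):
        vals = [self.e1, self.e2, self.e3]
        if self.e_total is not None:
            vals.append(self.e_total)
        if any(not math.isfinite(v) or v < 0 for v in vals):
            raise ValueError("expression values must be finite and >= 0")


@dataclass(frozen=True)
class LysisAssay:
    """Release-assay readouts (same units for all three wells)."""

    experimental: float
    spontaneous: float
    maximum: float

    def __post_init__(self):
        if any(v < 0 for v in (self.experimental, self.spontaneous, self.maximum)):
            raise ValueError("lysis readouts must be >= 0")
        if not self.maximum > self.spontaneous:
            raise ValueError(
                f"maximum ({self.maximum}) must exceed spontaneous "
                f"({self.spontaneous})"
            )


def delta_ct_expression(m: CtMeasurement) -> float:
    """Relative expression 2^-(target_ct - reference_ct).

    One extra cycle on the target halves the value; equal cycles give 1.
    """
    return float(2.0 ** -(m.target_ct - m.reference_ct))


def qpcr_variant_percentages(
    v: VariantExpressionSet, denominator: str = "sum_of_variants"
) -> Nkp44Fractions:
    """Splice-variant percentages from qPCR 2^-dCt signals.

    With ``denominator="sum_of_variants"`` the three percentages total 100
    by construction; with ``"measured_total"`` each variant is taken over
    the total-NKp44 primer signal and the percentages need not sum to 100.
    """
    if denominator == "sum_of_variants":
        denom = v.e1 + v.e2 + v.e3
    elif denominator == "measured_total":
        if v.e_total is None:
            raise ValueError("measured_total denominator requires e_total")
        denom = v.e_total
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom <= 0:
        raise ValueError(f"denominator must be > 0, got {denom}")
    return Nkp44Fractions(
        100.0 * v.e1 / denom, 100.0 * v.e2 / denom, 100.0 * v.e3 / denom
    )


def amplification_efficiency(slope: float) -> float:
    """Primer amplification efficiency (%) from a dilution-curve slope.

    The standard relation (10^(-1/slope) - 1) x 100: a slope of
    -1/log10(2) = -3.3219 is perfect per-cycle doubling, 100%.
    """
    if not math.isfinite(slope) or slope >= 0:
        raise ValueError(f"dilution-curve slope must be negative, got {slope}")
    return float((10.0 ** (-1.0 / slope) - 1.0) * 100.0)


def efficiency_to_slope(efficiency_percent: float) -> float:
    """Inverse of :func:`amplification_efficiency` (slope from percent)."""
    if efficiency_percent <= -100.0:
        raise ValueError("efficiency must exceed -100%")
    return float(-1.0 / math.log10(1.0 + efficiency_percent / 100.0))


def specific_cytotoxicity(a: LysisAssay) -> float:
    """Specific lysis (%): (experimental - spontaneous)/(maximum - spontaneous) x 100.

    Values below 0% or above 100% are reported as-is with a warning —
    clipping would silently bias averaged replicates.
    """
    pct = 100.0 * (a.experimental - a.spontaneous) / (a.maximum - a.spontaneous)
    if not (0.0 <= pct <= 100.0):
        warnings.warn(
            f"specific cytotoxicity {pct:.1f}% outside [0, 100]; reported unclipped",
            stacklevel=2,
        )
    return float(pct)


def relative_to_control(sample: float, control: float) -> float:
    """Readout as a percentage of the control condition (control = 100%)."""
    if sample < 0:
        raise ValueError(f"sample readout must be >= 0, got {sample}")
    if not control > 0:
        raise ValueError(f"control readout must be > 0, got {control}")
    return float(100.0 * sample / control)


def synapse_factin_ratio(synapse_mfi: float, conjugate_mfi: float) -> float:
    """Gated synapse F-actin MFI over total conjugation MFI.

    Normalizes synapse-localized F-actin signal to the whole
    effector-target conjugate, cancelling staining-intensity variation.
    """
    if synapse_mfi < 0:
        raise ValueError(f"synapse MFI must be >= 0, got {synapse_mfi}")
    if not conjugate_mfi > 0:
        raise ValueError(f"conjugate MFI must be > 0, got {conjugate_mfi}")
    return float(synapse_mfi / conjugate_mfi)


def ratio_percent_change(
    condition_ratios: Sequence[float], control_ratios: Sequence[float]
) -> float:
    """Percent change of the mean MFI ratio in a condition vs its control.

    A condition mean of 0.774 against a control mean of 1.0 is a -22.6%
    change in synapse F-actin accumulation.
    """
    cond = np.asarray(condition_ratios, dtype=float)
    ctrl = np.asarray(control_ratios, dtype=float)
    if cond.size == 0 or ctrl.size == 0:
        raise ValueError("both conditions need at least one ratio")
    ctrl_mean = ctrl.mean()
    if not ctrl_mean > 0:
        raise ValueError(f"control mean ratio must be > 0, got {ctrl_mean}")
    return float(100.0 * (cond.mean() - ctrl_mean) / ctrl_mean)
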