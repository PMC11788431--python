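"""Closed-form assay quantifications.

Small formulas used around a screen's validation experiments:

* **percent input** (ChIP-qPCR): the input aliquot is a fraction of the
  chromatin, so its Ct is first adjusted by ``log2(1 / input_fraction)``;
  recovery is ``100 * 2**(adjusted_input_ct - ip_ct)``.
* **2^-ddCt relative expression**: target Ct normalized to a reference
  gene (dCt), then to the control group's mean dCt; the control group has
  geometric-mean fold change 1 by construction.
* **tumor volume** from caliper length/width: ``L * W**2 / 2`` (mm^3).
* **protein half-life** from a cycloheximide chase: levels normalized to
  100% at time 0, fit log-linearly; ``t_half = ln 2 / (-slope)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError


def percent_input(
    ct_ip: float, ct_input: float, input_fraction: float = 0.01
) -> float:
    """ChIP recovery as percent of input chromatin.

    ``input_fraction`` is the fraction of chromatin used for the input
    qPCR (default 1%, a documented assumption).
    """
    if not 0 < input_fraction <= 1:
        raise InputError("input_fraction must be in (0, 1]")
    adjusted = ct_input - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (adjusted - ct_ip)


def delta_ct(ct_target, ct_reference) -> np.ndarray:
    """Per-sample dCt = Ct(target) - Ct(reference)."""
    t = np.asarray(ct_target, dtype=float)
    r = np.asarray(ct_reference, dtype=float)
    if t.shape != r.shape:
        raise InputError("target and reference Ct arrays must align")
    if np.isnan(r).any():
        raise InputError("missing reference Ct")
    return t - r


def relative_expression_ddct(
    ct_target, ct_reference, control_mean_dct: float | None = None
) -> np.ndarray:
    """Fold changes ``2**-(dCt - control_mean_dct)`` (Livak method).

    When ``control_mean_dct`` is None the mean dCt of the given samples is
    used, i.e. the samples ARE the control group and their geometric-mean
    fold is exactly 1.
    """
    dct = delta_ct(ct_target, ct_reference)
    if control_mean_dct is None:
        control_mean_dct = float(np.mean(dct))
    return 2.0 ** (-(dct - control_mean_dct))


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper tumor volume ``L * W**2 / 2`` in mm^3."""
    if length_mm < 0 or width_mm < 0:
        raise InputError("caliper measurements must be non-negative")
    return length_mm * width_mm**2 / 2.0


@dataclass(frozen=True)
class HalfLifeFit:
    half_life: float  # hours; NaN when undefined
    slope: float  # per hour, on ln(level)
    intercept: float
    r_squared: float
    defined: bool


def normalize_to_time_zero(times, levels) -> tuple[np.ndarray, np.ndarray]:
    """Rescale a decay series so the earliest time point reads 100%."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(levels, dtype=float)
    if t.size != y.size or t.size < 2:
        raise InputError("need >= 2 aligned (time, level) points")
    order = np.argsort(t, kind="stable")
    t, y = t[order], y[order]
    if y[0] <= 0:
        raise InputError("level at the first time point must be positive")
    return t, 100.0 * y / y[0]


def decay_half_life(times, levels) -> HalfLifeFit:
    """Half-life from a first-order decay series via log-linear least squares.

    Fits ``ln(level) = intercept + slope * time``; the half-life is
    ``ln 2 / (-slope)``. A non-negative slope (no decay) is flagged
    undefined rather than reported as a negative half-life.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(levels, dtype=float)
    if t.size != y.size or t.size < 2:
        raise InputError("need >= 2 aligned (time, level) points")
    if (y <= 0).any():
        raise InputError("levels must be positive for a log-linear fit")
    logy = np.log(y)
    slope, intercept = np.polyfit(t, logy, 1)
    fitted = intercept + slope * t
    ss_res = float(np.sum((logy - fitted) ** 2))
    ss_tot = float(np.sum((logy - logy.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    if slope >= -1e-12:  # no decay within numerical precision
        return HalfLifeFit(float("nan"), float(slope), float(intercept), r2, False)
    return HalfLifeFit(
        math.log(2) / (-float(slope)), float(slope), float(intercept), r2, True
    )
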