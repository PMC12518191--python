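"""Closed-form EANM SOP single-time-point TIA estimators.

The EANM standard operating procedure for pre-therapy :sup:`131`\\ I
dosimetry gives two closed-form estimates of the time-integrated activity
from one retention measurement ``A(t)``:

early window (1 d <= t <= 3 d):
    ``hTIA = 0.97 * A(t) * 2^(t / 5.5 d) * 5.5 d / ln 2``

late window (4 d <= t <= 8 d):
    ``hTIA = A(t) * t / 0.357``

The early form back-extrapolates the measurement assuming an effective
half-life of 5.5 d; the late form exploits that ``lambda_eff * t *
exp(-lambda_eff * t)`` is nearly flat (about 0.357) around one effective
half-life, making late measurements almost proportional to the TIA.  The
gap (3 d, 4 d) and anything outside [1 d, 8 d] are undefined by the SOP and
raise :class:`OutOfWindowError`.  No physical-decay correction is applied
here: the measured activity already includes decay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["SOPConstants", "OutOfWindowError", "htia", "HTIA_TIMES_H"]

#: Measurement times (h) at which the study computes hTIA.
HTIA_TIMES_H = (24.0, 48.0, 96.0, 120.0)


@dataclass(frozen=True)
class SOPConstants:
    """Constants of the EANM SOP closed-form estimators (immutable)."""

    scale_early: float = 0.97
    halflife_early_days: float = 5.5
    denom_late: float = 0.357
    early_window_days: tuple[float, float] = (1.0, 3.0)
    late_window_days: tuple[float, float] = (4.0, 8.0)


class OutOfWindowError(ValueError):
    """Measurement time lies where the SOP defines no formula."""


def htia(activity: float, time_h: float, constants: SOPConstants = SOPConstants()) -> float:
    """EANM SOP single-time-point TIA estimate, in hours.

    Parameters
    ----------
    activity
        Measured retention fraction ``A(t)`` (dimensionless, >= 0).
    time_h
        Measurement time after administration in hours; must fall in the
        SOP windows [24 h, 72 h] or [96 h, 192 h] (1-3 d or 4-8 d,
        boundaries inclusive).

    Returns
    -------
    float
        TIA in (fraction of administered activity) x hours.
    """
    if not activity >= 0.0:
        raise ValueError(f"activity must be >= 0, got {activity}")
    if not time_h > 0.0:
        raise ValueError(f"time_h must be > 0, got {time_h}")
    t_d = time_h / 24.0
    lo_e, hi_e = constants.early_window_days
    lo_l, hi_l = constants.late_window_days
    if lo_e <= t_d <= hi_e:
        return (
            constants.scale_early
            * activity
            * 2.0 ** (t_d / constants.halflife_early_days)
            * constants.halflife_early_days
            * 24.0
            / math.log(2.0)
        )
    if lo_l <= t_d <= hi_l:
        return activity * time_h / constants.denom_late
    raise OutOfWindowError(
        f"t = {t_d:g} d is outside the SOP windows [{lo_e}, {hi_e}] d and "
        f"[{lo_l}, {hi_l}] d"
    )
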