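"""Voltage-to-pixel calibration from fiducial bead stacks.

Fluorescent beads immobilized on the coverslip are imaged while the galvo
mirror is driven at several amplitudes; each bead renders as N spots whose
first-to-last distance L grows linearly with the drive voltage.  Fitting
L(V) through the origin yields the slope in pixel/mV used by
:class:`~smsweep.sweep.SweepConfig`.
"""

from __future__ import annotations

import numpy as np

from .decode import detect_spots
from .errors import CalibrationError, InsufficientDataError
from .simulate import FrameStack


def measure_sweep_length(stack: FrameStack, detect_threshold: float | None = None,
                         row_tolerance_px: float = 3.0) -> float:
    """Mean first-to-last spot distance (px) of the bead streaks in a stack.

    Spots are detected on the time-averaged image and grouped by row (same
    bead, different sub-exposures); L is the max-min x within each group,
    averaged over beads.  A single spot per group (V = 0) gives L = 0.
    """
    img = np.asarray(stack.frames, dtype=float).mean(axis=0)
    if stack.layout is not None:
        img = img[:, stack.layout.split:]
    if detect_threshold is None:
        detect_threshold = float(np.median(img) + 5.0 * img.std())
    peaks = detect_spots(img, min_separation_px=0.0, intensity_threshold=detect_threshold)
    if not peaks:
        raise CalibrationError("no bead spots detected")
    peaks = sorted(peaks, key=lambda p: p.y)
    groups: list[list] = [[peaks[0]]]
    for p in peaks[1:]:
        if abs(p.y - groups[-1][-1].y) <= row_tolerance_px:
            groups[-1].append(p)
        else:
            groups.append([p])
    lengths = [max(p.x for p in g) - min(p.x for p in g) for g in groups]
    return float(np.mean(lengths))


def calibrate_sweep(bead_stacks: dict[float, FrameStack],
                    residual_tol_px: float = 1.0,
                    detect_threshold: float | None = None) -> tuple[float, dict]:
    """Fit the voltage->pixel slope from bead stacks at several amplitudes.

    ``bead_stacks`` maps drive voltage (mV) to a bead FrameStack; at least
    three voltages including 0 are required.  Returns ``(slope_px_per_mV,
    report)`` where the report carries per-voltage measured lengths and
    residuals of the through-origin linear fit.  Residuals above
    ``residual_tol_px`` raise :class:`CalibrationError` (nonlinear galvo
    response or failed detection).
    """
    if len(bead_stacks) < 3:
        raise InsufficientDataError("need bead stacks at >= 3 voltages")
    if not any(v == 0 for v in bead_stacks):
        raise InsufficientDataError("a 0 mV (unswept) bead stack is required")
    volts = np.array(sorted(bead_stacks), dtype=float)
    lengths = np.array([measure_sweep_length(bead_stacks[v], detect_threshold)
                        for v in volts])
    denom = float(np.sum(volts ** 2))
    slope = float(np.sum(volts * lengths) / denom) if denom > 0 else 0.0
    residuals = lengths - slope * volts
    if np.max(np.abs(residuals)) > residual_tol_px:
        raise CalibrationError(
            f"calibration residuals up to {np.max(np.abs(residuals)):.2f} px exceed "
            f"{residual_tol_px} px")
    report = {"voltages_mV": volts.tolist(), "lengths_px": lengths.tolist(),
              "residuals_px": residuals.tolist()}
    return slope, report
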