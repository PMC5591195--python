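"""Geometry and timing of the galvo-mirror sweep encoding.

One camera exposure of duration ``exposure_ms`` is split into ``n_steps``
sub-exposures.  Between sub-exposures a galvo mirror in the detection path
steps the image sideways, so a single molecule appears as ``n_steps``
laterally offset spots in one frame: temporal information is encoded in the
spatial domain.  The mirror displacement is linear in the drive voltage with
a fixed calibration slope (pixel/mV), and the drive waveform is a staircase
from 0 to the full amplitude in equal increments.

Everything here is pure arithmetic shared by the simulator and the decoder;
both must agree on the sweep direction convention (positive x, i.e.
increasing column index, first sub-exposure at the unswept position).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from .errors import InvalidArgumentError

#: relative tolerance applied at the spot-separation boundary
SEPARATION_RTOL = 1e-9


@dataclass(frozen=True)
class SweepConfig:
    """Geometry and timing of the sweep encoding.

    Parameters
    ----------
    n_steps:
        Number of sub-exposures N per frame (N >= 1; N = 1 is conventional
        imaging).
    voltage_mV:
        Drive amplitude V of the final step, in millivolts.
    slope_px_per_mV:
        Calibration slope converting drive voltage to image displacement.
    exposure_ms:
        Camera exposure time per frame.
    frame_lag_ms:
        Dead time between consecutive exposures (camera readout); photons
        arriving during the lag are not collected.
    sweep_axis:
        Only ``"x"`` (increasing column index) is supported.
    """

    n_steps: int
    voltage_mV: float
    slope_px_per_mV: float
    exposure_ms: float
    frame_lag_ms: float = 0.0
    sweep_axis: str = "x"

    def __post_init__(self) -> None:
        if int(self.n_steps) != self.n_steps or self.n_steps < 1:
            raise InvalidArgumentError(f"n_steps must be an integer >= 1, got {self.n_steps}")
        for name in ("voltage_mV", "slope_px_per_mV", "frame_lag_ms"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.exposure_ms <= 0:
            raise InvalidArgumentError(f"exposure_ms must be > 0, got {self.exposure_ms}")
        if self.sweep_axis != "x":
            raise InvalidArgumentError(f"only sweep_axis='x' is supported, got {self.sweep_axis!r}")

    # ---- derived quantities -------------------------------------------------

    @property
    def substep_ms(self) -> float:
        """Sub-frame time resolution Δt/N."""
        return self.exposure_ms / self.n_steps

    @property
    def frame_period_ms(self) -> float:
        """Exposure plus inter-frame dead time."""
        return self.exposure_ms + self.frame_lag_ms

    @property
    def sample_interval_ms(self) -> float:
        """Mean time between consecutive substep samples of a decoded trace.

        Within a frame samples are ``substep_ms`` apart, but across a frame
        boundary the inter-frame lag adds dead time; averaged over a long
        trace each substep advance is (exposure + lag)/N.  Autocorrelation
        lags of decoded traces should use this spacing.
        """
        return self.frame_period_ms / self.n_steps

    @property
    def sweep_length_px(self) -> float:
        """Total displacement L between first and last spot."""
        return self.slope_px_per_mV * self.voltage_mV

    @property
    def spacing_px(self) -> float:
        """Distance between adjacent spots, L/(N-1); 0 for a single step."""
        if self.n_steps == 1:
            return 0.0
        return self.sweep_length_px / (self.n_steps - 1)

    # ---- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SweepConfig":
        known = {"n_steps", "voltage_mV", "slope_px_per_mV", "exposure_ms",
                 "frame_lag_ms", "sweep_axis"}
        unknown = set(d) - known
        if unknown:
            raise InvalidArgumentError(f"unknown SweepConfig keys: {sorted(unknown)}")
        return cls(**d)


def make_step_waveform(n_steps: int, voltage_mV: float) -> list[float]:
    """Staircase drive voltages: 0 to ``voltage_mV`` in V/(N-1) increments.

    For ``n_steps == 1`` the mirror never moves and the waveform is ``[0]``.
    """
    if int(n_steps) != n_steps or n_steps < 1:
        raise InvalidArgumentError(f"n_steps must be an integer >= 1, got {n_steps}")
    if voltage_mV < 0:
        raise InvalidArgumentError(f"voltage_mV must be >= 0, got {voltage_mV}")
    if n_steps == 1:
        return [0.0]
    return [voltage_mV * s / (n_steps - 1) for s in range(n_steps)]


def voltage_to_sweep_px(voltage_mV: float, slope_px_per_mV: float) -> float:
    """Total sweep length L in pixels for a given drive amplitude."""
    if voltage_mV < 0 or slope_px_per_mV < 0:
        raise InvalidArgumentError("voltage_mV and slope_px_per_mV must be >= 0")
    return voltage_mV * slope_px_per_mV


def substep_resolution_ms(exposure_ms: float, n_steps: int) -> float:
    """Sub-frame time resolution Δt/N in milliseconds."""
    if exposure_ms <= 0:
        raise InvalidArgumentError(f"exposure_ms must be > 0, got {exposure_ms}")
    if int(n_steps) != n_steps or n_steps < 1:
        raise InvalidArgumentError(f"n_steps must be an integer >= 1, got {n_steps}")
    return exposure_ms / n_steps


def separation_ok(config: SweepConfig, fwhm_px: float, factor: float = 2.0) -> bool:
    """Check the unambiguous-decoding criterion: spacing >= factor x FWHM.

    Adjacent swept spots must be separated by roughly twice the point-spread
    function FWHM for the sub-exposures to be read out independently.  The
    comparison allows a small relative tolerance at the boundary so that
    exact-equality configurations count as separated.
    """
    if fwhm_px <= 0:
        raise InvalidArgumentError(f"fwhm_px must be > 0, got {fwhm_px}")
    if config.n_steps < 2:
        raise InvalidArgumentError("separation is undefined for n_steps < 2")
    required = factor * fwhm_px
    return config.spacing_px >= required * (1.0 - SEPARATION_RTOL)


def fwhm_px_to_nm(fwhm_px: float, pixel_size_um: float) -> float:
    """Convert a FWHM in pixels to nanometres given the pixel pitch in µm."""
    if fwhm_px < 0 or pixel_size_um <= 0:
        raise InvalidArgumentError("fwhm_px must be >= 0 and pixel_size_um > 0")
    return fwhm_px * pixel_size_um * 1000.0


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian sigma for a given FWHM (fwhm / (2 sqrt(2 ln 2)))."""
    return fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
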