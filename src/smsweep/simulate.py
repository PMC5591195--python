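"""Synthetic swept single-molecule EMCCD movies.

Generates image stacks in which each immobilized molecule follows a two-state
continuous-time Markov (telegraph) process — bright/dark photoblinking,
bound/unbound hybridization, or two-conformation FRET — while a galvo mirror
steps the image N times per exposure.  Each frame therefore contains N
laterally offset Gaussian spots per molecule, one per sub-exposure.

The state process is simulated exactly (event-driven, exponential dwells),
so per-substep expected photon counts are exact time integrals, not
discretized approximations.  Camera noise follows the standard EMCCD chain:
Poisson photon shot noise, Gamma electron-multiplication noise
(``n`` photons -> Gamma(shape=n, scale=gain) counts), additive Gaussian read
noise, and a constant baseline offset.

A dual-channel chip layout is supported: for blinking/binding experiments a
30:70 beam splitter sends 30% of the light to a conventional (unswept) image
on the left half and 70% to the swept image on the right; for FRET the light
is split by color into swept donor (left) and acceptor (right) images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import ndtr

from .errors import InvalidArgumentError
from .sweep import SweepConfig, fwhm_to_sigma

#: iXon-style chip: 512 px across 68 µm
DEFAULT_PIXEL_SIZE_UM = 68.0 / 512.0

#: PSF rendering window half-width in units of sigma.  The pixel-mass patch
#: is renormalized to unit mass so rendering conserves photons exactly.
PSF_WINDOW_SIGMA = 5.0


# --------------------------------------------------------------------------
# models
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticModel:
    """Two-state telegraph process driving a molecule's brightness.

    ``k_on`` is the dark->bright (or unbound->bound) rate and ``k_off`` the
    bright->dark rate, both in s^-1, so the expected bright dwell is
    1/k_off and the expected dark dwell 1/k_on.  Photon detection rates are
    in photons/ms.
    """

    k_on: float
    k_off: float
    bright_rate: float
    dark_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_off < 0:
            raise InvalidArgumentError("rates must be >= 0")
        if not (self.bright_rate > self.dark_rate >= 0):
            raise InvalidArgumentError("need bright_rate > dark_rate >= 0")

    @property
    def rate_to_high(self) -> float:
        return self.k_on

    @property
    def rate_to_low(self) -> float:
        return self.k_off

    def emission_rates(self) -> tuple[float, float]:
        """(low-state, high-state) photon rates in photons/ms."""
        return (self.dark_rate, self.bright_rate)

    @property
    def stationary_high(self) -> float:
        """Long-run probability of the bright state."""
        tot = self.k_on + self.k_off
        return 0.5 if tot == 0 else self.k_on / tot


@dataclass(frozen=True)
class FretModel:
    """Two-conformation FRET process (e.g. Holliday-junction isomerization).

    States 1 and 2 have true FRET efficiencies ``E_1`` and ``E_2``;
    ``k_12``/``k_21`` are the interconversion rates in s^-1.  ``total_rate``
    is the summed donor+acceptor photon detection rate (photons/ms), assumed
    state-independent; ``leakage`` is the donor->acceptor spectral crosstalk
    fraction.
    """

    k_12: float
    k_21: float
    E_1: float
    E_2: float
    total_rate: float
    leakage: float = 0.0

    def __post_init__(self) -> None:
        if self.k_12 < 0 or self.k_21 < 0:
            raise InvalidArgumentError("rates must be >= 0")
        for e in (self.E_1, self.E_2):
            if not 0.0 <= e <= 1.0:
                raise InvalidArgumentError("FRET efficiencies must lie in [0, 1]")
        if self.E_1 == self.E_2:
            raise InvalidArgumentError("E_1 must differ from E_2")
        if self.total_rate <= 0:
            raise InvalidArgumentError("total_rate must be > 0")
        if not 0.0 <= self.leakage < 1.0:
            raise InvalidArgumentError("leakage must lie in [0, 1)")

    # state 2 plays the role of the 'high' state in the trajectory machinery
    @property
    def rate_to_high(self) -> float:
        return self.k_12

    @property
    def rate_to_low(self) -> float:
        return self.k_21

    def emission_rates(self) -> tuple[float, float]:
        return (self.total_rate, self.total_rate)

    @property
    def stationary_high(self) -> float:
        tot = self.k_12 + self.k_21
        return 0.5 if tot == 0 else self.k_12 / tot


@dataclass(frozen=True)
class CameraModel:
    """EMCCD readout parameters."""

    em_gain: float = 300.0
    read_noise_sd: float = 50.0
    baseline: float = 100.0
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if self.em_gain <= 0:
            raise InvalidArgumentError("em_gain must be > 0")
        if self.read_noise_sd < 0:
            raise InvalidArgumentError("read_noise_sd must be >= 0")
        if self.pixel_size_um <= 0:
            raise InvalidArgumentError("pixel_size_um must be > 0")


@dataclass(frozen=True)
class ChannelLayout:
    """Left/right split of the chip and the role of each half.

    ``left_fraction``/``right_fraction`` are the photon fractions routed to
    each half.  For an amplitude beam splitter (conventional + swept imaging)
    they sum to 1; for a dichroic (donor + acceptor) each channel receives
    all photons of its color and both fractions are 1.
    """

    height: int
    width: int
    split: int
    left_role: str = "conventional"
    right_role: str = "swept"
    left_fraction: float = 0.3
    right_fraction: float = 0.7

    def __post_init__(self) -> None:
        if not (0 < self.split < self.width):
            raise InvalidArgumentError("split column must lie inside the frame")

    @property
    def left_shape(self) -> tuple[int, int]:
        return (self.height, self.split)

    @property
    def right_shape(self) -> tuple[int, int]:
        return (self.height, self.width - self.split)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelLayout":
        return cls(**d)


def dual_channel_layout(height: int = 128, channel_width: int = 64,
                        reflect: float = 0.3) -> ChannelLayout:
    """Conventional (left) + swept (right) layout with an R:T beam split."""
    return ChannelLayout(height=height, width=2 * channel_width, split=channel_width,
                         left_role="conventional", right_role="swept",
                         left_fraction=reflect, right_fraction=1.0 - reflect)


def fret_layout(height: int = 128, channel_width: int = 64) -> ChannelLayout:
    """Swept donor (left) + swept acceptor (right) dichroic layout."""
    return ChannelLayout(height=height, width=2 * channel_width, split=channel_width,
                         left_role="donor", right_role="acceptor",
                         left_fraction=1.0, right_fraction=1.0)


@dataclass
class FrameStack:
    """A time-ordered stack of 2-D images plus acquisition metadata."""

    frames: np.ndarray            # (n_frames, height, width), float or uint16
    pixel_size_um: float
    exposure_ms: float
    layout: ChannelLayout | None = None
    sweep: SweepConfig | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise InvalidArgumentError("frames must be a (n_frames, h, w) array with n_frames >= 1")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def channel(self, side: str) -> np.ndarray:
        """View of the left or right channel, (n_frames, h, w_half)."""
        if self.layout is None:
            raise InvalidArgumentError("stack has no channel layout")
        if side == "left":
            return self.frames[:, :, : self.layout.split]
        if side == "right":
            return self.frames[:, :, self.layout.split:]
        raise InvalidArgumentError(f"side must be 'left' or 'right', got {side!r}")


@dataclass
class StateTrajectory:
    """Exact event list of a two-state process.

    ``switch_times_ms`` are the strictly increasing switch instants within
    [0, duration_ms); the state alternates starting from ``initial_state``
    (0 = low/dark/state-1, 1 = high/bright/state-2).
    """

    switch_times_ms: np.ndarray
    initial_state: int
    duration_ms: float
    emission_rates: tuple[float, float] = (0.0, 1.0)

    def state_at(self, t_ms: np.ndarray | float) -> np.ndarray:
        n = np.searchsorted(self.switch_times_ms, np.asarray(t_ms), side="right")
        return (self.initial_state + n) % 2

    def high_time_knots(self) -> tuple[np.ndarray, np.ndarray]:
        """Knots (t, H(t)) of the cumulative high-state occupancy time."""
        t = np.concatenate(([0.0], self.switch_times_ms, [self.duration_ms]))
        seg = np.diff(t)
        states = (self.initial_state + np.arange(seg.size)) % 2
        H = np.concatenate(([0.0], np.cumsum(seg * states)))
        return t, H


@dataclass
class GroundTruth:
    """Per-molecule truth for recovery tests.

    ``occupancy`` holds the exact fraction of each substep spent in the high
    state; ``states`` the majority state per substep; ``expected_photons``
    the expected photon count per substep before any beam split.  All arrays
    are (n_molecules, n_frames * n_steps).
    """

    positions: np.ndarray
    occupancy: np.ndarray
    expected_photons: np.ndarray
    states: np.ndarray
    trajectories: list[StateTrajectory]
    expected_donor: np.ndarray | None = None
    expected_acceptor: np.ndarray | None = None


# --------------------------------------------------------------------------
# state-process simulation
# --------------------------------------------------------------------------

def simulate_state_trajectory(model: KineticModel | FretModel, duration_ms: float,
                              seed: int | np.random.Generator,
                              initial_state: int | None = None) -> StateTrajectory:
    """Exact (event-driven) simulation of the two-state process.

    Dwell times are exponential with the model's rates; with both rates zero
    the process stays in its initial state for the whole duration.  When
    ``initial_state`` is None it is drawn from the stationary distribution.
    """
    if duration_ms <= 0:
        raise InvalidArgumentError("duration_ms must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rates = (model.rate_to_high, model.rate_to_low)  # exit rate of (low, high), s^-1
    if initial_state is None:
        initial_state = int(rng.random() < model.stationary_high)

    times = []
    t = 0.0
    state = initial_state
    while True:
        k = rates[state]  # s^-1
        if k <= 0:
            break
        t += rng.exponential(1000.0 / k)  # ms
        if t >= duration_ms:
            break
        times.append(t)
        state = 1 - state
    return StateTrajectory(np.asarray(times, dtype=float), int(initial_state),
                           float(duration_ms), model.emission_rates())


def _substep_windows(config: SweepConfig, n_frames: int) -> tuple[np.ndarray, np.ndarray]:
    """Start/end times (ms) of every exposed substep, frame-major order."""
    frames = np.arange(n_frames) * config.frame_period_ms
    sub = np.arange(config.n_steps) * config.substep_ms
    starts = (frames[:, None] + sub[None, :]).ravel()
    return starts, starts + config.substep_ms


def substep_occupancy(traj: StateTrajectory, config: SweepConfig,
                      n_frames: int) -> np.ndarray:
    """Exact fraction of each substep spent in the high state.

    Shape (n_frames, n_steps).  Photons arriving during the inter-frame lag
    belong to no substep and are discarded.
    """
    starts, ends = _substep_windows(config, n_frames)
    if traj.duration_ms < ends[-1] - 1e-9:
        raise InvalidArgumentError(
            f"trajectory ({traj.duration_ms} ms) shorter than required span ({ends[-1]} ms)")
    t, H = traj.high_time_knots()
    occ = (np.interp(ends, t, H) - np.interp(starts, t, H)) / config.substep_ms
    return occ.reshape(n_frames, config.n_steps)


def integrate_substeps(traj: StateTrajectory, config: SweepConfig,
                       n_frames: int) -> np.ndarray:
    """Expected photon count per substep, shape (n_frames, n_steps).

    Integrates the trajectory's emission rate (photons/ms) over each substep
    window exactly, using the event list.
    """
    occ = substep_occupancy(traj, config, n_frames)
    low, high = traj.emission_rates
    return config.substep_ms * (low + (high - low) * occ)


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def gaussian_patch(x0: float, y0: float, sigma: float,
                   shape: tuple[int, int]) -> tuple[np.ndarray, int, int]:
    """Unit-mass pixel-integrated Gaussian at (x0, y0) clipped to ``shape``.

    Pixel (r, c) covers [c-0.5, c+0.5] x [r-0.5, r+0.5] so integer
    coordinates are pixel centers.  Returns (patch, r0, c0) where the patch
    is to be added at ``frame[r0:r0+ph, c0:c0+pw]``.  The patch is
    renormalized to unit mass so photon budgets are conserved exactly.
    """
    h, w = shape
    r = PSF_WINDOW_SIGMA * sigma
    c0, c1 = max(0, int(np.floor(x0 - r))), min(w - 1, int(np.ceil(x0 + r)))
    r0, r1 = max(0, int(np.floor(y0 - r))), min(h - 1, int(np.ceil(y0 + r)))
    if c1 < c0 or r1 < r0:
        raise InvalidArgumentError(f"spot at ({x0}, {y0}) lies outside the image")
    cols = np.arange(c0, c1 + 1)
    rows = np.arange(r0, r1 + 1)
    mx = ndtr((cols + 0.5 - x0) / sigma) - ndtr((cols - 0.5 - x0) / sigma)
    my = ndtr((rows + 0.5 - y0) / sigma) - ndtr((rows - 0.5 - y0) / sigma)
    patch = my[:, None] * mx[None, :]
    patch /= patch.sum()
    return patch, r0, c0


def apply_camera_noise(expected_photons: np.ndarray, camera: CameraModel,
                       rng: np.random.Generator) -> np.ndarray:
    """EMCCD noise chain: Poisson -> Gamma EM multiplication -> read noise -> baseline."""
    n = rng.poisson(expected_photons).astype(np.float64)
    if camera.em_gain != 1.0:
        counts = rng.standard_gamma(n) * camera.em_gain  # Gamma(n, gain); n=0 -> 0
    else:
        counts = n
    if camera.read_noise_sd > 0:
        counts = counts + rng.normal(0.0, camera.read_noise_sd, size=counts.shape)
    counts += camera.baseline
    return np.maximum(counts, 0.0)


def _check_sweep_fits(x: float, y: float, config: SweepConfig, layout: ChannelLayout,
                      sigma: float, idx: int) -> None:
    w = layout.right_shape[1]
    margin = 0.0  # PSF tails are clipped at the border; center + L must stay inside
    if not (0 <= x and x + config.sweep_length_px <= w - 1 - margin):
        raise InvalidArgumentError(
            f"molecule {idx}: sweep range [{x}, {x + config.sweep_length_px}] exits "
            f"the swept sub-region (width {w})")
    if not (0 <= y <= layout.height - 1):
        raise InvalidArgumentError(f"molecule {idx}: y={y} outside the sub-region")


def render_swept_stack(molecules, config: SweepConfig, camera: CameraModel,
                       layout: ChannelLayout, n_frames: int, seed: int,
                       fwhm_px: float = 2.56, background_rate: float = 0.0,
                       noise: bool = True) -> tuple[FrameStack, GroundTruth]:
    """Render a dual-channel (conventional + swept) movie.

    ``molecules`` is a list of ``((x, y), KineticModel)`` with positions in
    channel-local pixel coordinates (x = column); the conventional channel
    shows one spot per molecule at the same local position.  Expected spot
    intensities come from exact substep integration of each molecule's
    telegraph trajectory, scaled by the layout's photon fractions.
    ``background_rate`` is in photons/ms/pixel, collected only during the
    exposure.  With ``noise=False`` the returned pixel values are expected
    photon counts (no Poisson/EM/read noise, no baseline).
    """
    rng = np.random.default_rng(seed)
    sigma = fwhm_to_sigma(fwhm_px)
    spacing = config.spacing_px
    duration = n_frames * config.frame_period_ms

    expected = np.zeros((n_frames, layout.height, layout.width), dtype=np.float64)
    bg = background_rate * config.exposure_ms
    if bg:
        expected += bg

    positions, occs, photons, states, trajs = [], [], [], [], []
    split = layout.split
    for idx, ((x, y), model) in enumerate(molecules):
        _check_sweep_fits(x, y, config, layout, sigma, idx)
        traj = simulate_state_trajectory(model, duration, rng)
        occ = substep_occupancy(traj, config, n_frames)
        counts = integrate_substeps(traj, config, n_frames)  # (n_frames, N)
        # swept channel: one spot per substep at x + s*spacing
        for s in range(config.n_steps):
            patch, r0, c0 = gaussian_patch(x + s * spacing, y, sigma, layout.right_shape)
            expected[:, r0:r0 + patch.shape[0], split + c0: split + c0 + patch.shape[1]] += (
                layout.right_fraction * counts[:, s, None, None] * patch)
        # conventional channel: full-exposure integral at the unswept position
        patch, r0, c0 = gaussian_patch(x, y, sigma, layout.left_shape)
        expected[:, r0:r0 + patch.shape[0], c0:c0 + patch.shape[1]] += (
            layout.left_fraction * counts.sum(axis=1)[:, None, None] * patch)

        positions.append((x, y))
        occs.append(occ.ravel())
        photons.append(counts.ravel())
        states.append((occ.ravel() >= 0.5).astype(np.int8))
        trajs.append(traj)

    frames = apply_camera_noise(expected, camera, rng).astype(np.float32) \
        if noise else expected
    stack = FrameStack(frames, camera.pixel_size_um,
                       config.exposure_ms, layout, config,
                       meta={"seed": seed, "fwhm_px": fwhm_px,
                             "background_rate": background_rate, "noise": noise,
                             "n_frames": n_frames})
    truth = GroundTruth(np.asarray(positions, dtype=float),
                        np.asarray(occs), np.asarray(photons),
                        np.asarray(states), trajs)
    return stack, truth


def render_fret_stack(molecules, config: SweepConfig, camera: CameraModel,
                      n_frames: int, n_unswept_lead_frames: int, seed: int,
                      fwhm_px: float = 2.56, background_rate: float = 0.0,
                      noise: bool = True,
                      layout: ChannelLayout | None = None) -> tuple[FrameStack, GroundTruth]:
    """Render a swept donor/acceptor FRET movie.

    ``molecules`` is a list of ``((x, y), FretModel)`` in channel-local
    coordinates; the acceptor image of each molecule sits at the same local
    position in the right channel (pure-translation channel map).  Per
    substep the total photon budget is split as donor fraction (1-E) and
    acceptor fraction E of the occupancy-averaged efficiency, then the
    leakage fraction of donor photons is moved to the acceptor channel.
    The first ``n_unswept_lead_frames`` frames are rendered without sweeping
    (N = 1) for spot selection and channel mapping, as in real acquisitions.
    """
    if layout is None:
        layout = fret_layout()
    if not (0 <= n_unswept_lead_frames <= n_frames):
        raise InvalidArgumentError("need 0 <= n_unswept_lead_frames <= n_frames")
    rng = np.random.default_rng(seed)
    sigma = fwhm_to_sigma(fwhm_px)
    spacing = config.spacing_px
    duration = n_frames * config.frame_period_ms
    n_lead, n_swept = n_unswept_lead_frames, n_frames - n_unswept_lead_frames

    expected = np.zeros((n_frames, layout.height, layout.width), dtype=np.float64)
    bg = background_rate * config.exposure_ms
    if bg:
        expected += bg

    positions, occs, photons, states, trajs = [], [], [], [], []
    e_don, e_acc = [], []
    split = layout.split
    for idx, ((x, y), model) in enumerate(molecules):
        _check_sweep_fits(x, y, config, layout, sigma, idx)
        traj = simulate_state_trajectory(model, duration, rng)
        occ = substep_occupancy(traj, config, n_frames)      # (n_frames, N)
        counts = integrate_substeps(traj, config, n_frames)  # total photons per substep
        eff = model.E_1 + (model.E_2 - model.E_1) * occ      # occupancy-averaged E
        donor = counts * (1.0 - eff) * (1.0 - model.leakage)
        acceptor = counts * eff + counts * (1.0 - eff) * model.leakage

        patch_d, rd, cd = gaussian_patch(x, y, sigma, layout.left_shape)
        patch_a, ra, ca = gaussian_patch(x, y, sigma, layout.right_shape)
        # lead frames: no sweep, whole-frame integral in one spot
        if n_lead:
            expected[:n_lead, rd:rd + patch_d.shape[0], cd:cd + patch_d.shape[1]] += (
                donor[:n_lead].sum(axis=1)[:, None, None] * patch_d)
            expected[:n_lead, ra:ra + patch_a.shape[0],
                     split + ca: split + ca + patch_a.shape[1]] += (
                acceptor[:n_lead].sum(axis=1)[:, None, None] * patch_a)
        for s in range(config.n_steps):
            pd, rd, cd = gaussian_patch(x + s * spacing, y, sigma, layout.left_shape)
            pa, ra, ca = gaussian_patch(x + s * spacing, y, sigma, layout.right_shape)
            expected[n_lead:, rd:rd + pd.shape[0], cd:cd + pd.shape[1]] += (
                donor[n_lead:, s, None, None] * pd)
            expected[n_lead:, ra:ra + pa.shape[0],
                     split + ca: split + ca + pa.shape[1]] += (
                acceptor[n_lead:, s, None, None] * pa)

        positions.append((x, y))
        occs.append(occ.ravel())
        photons.append(counts.ravel())
        states.append((occ.ravel() >= 0.5).astype(np.int8))
        e_don.append(donor.ravel())
        e_acc.append(acceptor.ravel())
        trajs.append(traj)

    frames = apply_camera_noise(expected, camera, rng).astype(np.float32) \
        if noise else expected
    stack = FrameStack(frames, camera.pixel_size_um,
                       config.exposure_ms, layout, config,
                       meta={"seed": seed, "fwhm_px": fwhm_px,
                             "background_rate": background_rate, "noise": noise,
                             "n_frames": n_frames,
                             "n_unswept_lead_frames": n_unswept_lead_frames})
    truth = GroundTruth(np.asarray(positions, dtype=float),
                        np.asarray(occs), np.asarray(photons),
                        np.asarray(states), trajs,
                        expected_donor=np.asarray(e_don),
                        expected_acceptor=np.asarray(e_acc))
    return stack, truth


# --------------------------------------------------------------------------
# scenario presets
# --------------------------------------------------------------------------

def blinking_preset() -> dict:
    """Dye photoblinking at low reducer concentration.

    Off-time 4.6 ms (k_on = 217.4 s^-1) and on-time 12.5 ms (k_off = 80 s^-1);
    sweep: 5 steps, 96 mV, 0.25 px/mV, 20 ms exposure, 1.7 ms lag -> 4 ms
    substeps spaced 6 px.
    """
    return {
        "sweep": SweepConfig(n_steps=5, voltage_mV=96.0, slope_px_per_mV=0.25,
                             exposure_ms=20.0, frame_lag_ms=1.7),
        "kinetics": KineticModel(k_on=1000.0 / 4.6, k_off=80.0, bright_rate=60.0),
        "camera": CameraModel(),
        "fwhm_px": 2.56,
        "background_rate": 0.2,
    }


def binding_preset() -> dict:
    """Transient hybridization of a short DNA duplex (7 bp with 1 mismatch).

    On-time 7.7 ms (k_off = 129.9 s^-1); per-site binding rate 2 s^-1; sweep:
    5 steps, 112 mV -> 28 px total, 7 px spacing, 4 ms substeps.
    """
    return {
        "sweep": SweepConfig(n_steps=5, voltage_mV=112.0, slope_px_per_mV=0.25,
                             exposure_ms=20.0, frame_lag_ms=1.7),
        "kinetics": KineticModel(k_on=2.0, k_off=1000.0 / 7.7, bright_rate=60.0),
        "camera": CameraModel(),
        "fwhm_px": 2.56,
        "background_rate": 0.2,
    }


def fret_preset() -> dict:
    """Holliday-junction conformational dynamics at low Mg2+.

    Combined interconversion rate 61.1 s^-1 split evenly (k_12 = k_21 =
    30.55 s^-1); E = 0.3 / 0.7; sweep: 4 steps, 96 mV -> 5 ms substeps spaced
    8 px; 10 unswept lead frames for mapping and selection.
    """
    return {
        "sweep": SweepConfig(n_steps=4, voltage_mV=96.0, slope_px_per_mV=0.25,
                             exposure_ms=20.0, frame_lag_ms=1.7),
        "kinetics": FretModel(k_12=61.1 / 2, k_21=61.1 / 2, E_1=0.3, E_2=0.7,
                              total_rate=50.0, leakage=0.05),
        "camera": CameraModel(),
        "fwhm_px": 2.56,
        "background_rate": 0.2,
        "n_unswept_lead_frames": 10,
    }


SCENARIOS = {"blinking": blinking_preset, "binding": binding_preset, "fret": fret_preset}


def grid_positions(layout: ChannelLayout, config: SweepConfig, box_px: int = 7,
                   max_molecules: int | None = None) -> list[tuple[float, float]]:
    """Non-overlapping molecule positions on a vertical grid.

    Rows are spaced ``box_px + 2`` apart so swept footprints never interact;
    x is fixed near the left edge of the channel with room for the sweep.
    """
    half = box_px // 2 + 1
    x = float(half + 1)
    w = layout.right_shape[1]
    if x + config.sweep_length_px > w - half - 1:
        raise InvalidArgumentError("channel too narrow for the sweep length")
    ys = np.arange(half + 1, layout.height - half - 1, box_px + 2, dtype=float)
    pos = [(x, float(y)) for y in ys]
    return pos if max_molecules is None else pos[:max_molecules]
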