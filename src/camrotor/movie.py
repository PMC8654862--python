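"""Synthetic single-particle TIRF movie generation.

Emulates wide-field movies of surface-anchored rotary nanomechanisms whose
camshaft carries a ~290 nm fluorescent lever arm: each rotary particle is a
diffraction-limited spot circling a fixed anchor, sampled at 20 frames/s
with a 5 ms laser-on time.  Angle traces come either from the
coarse-grained mechanism simulator (:func:`trace_from_trajectory`) or from
a direct three-state hopping model (:func:`make_hopping_trace`).

Image convention (shared with the tracker): x = column, y = row, origin at
the pixel grid, angles measured from +x towards +y (y increases downward),
tip position = anchor + (R / pixel_size) * (cos theta, sin theta).

Noise model: expected photon image (integrated Gaussian PSF per pixel plus
flat background) -> Poisson -> camera gain -> additive Gaussian read noise
-> offset -> clipped integer counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

from .mechanics import wrap360, wrapdiff
from .traces import AngleTrace

__all__ = [
    "OpticsModel",
    "CameraModel",
    "ParticleSpec",
    "DriftSpec",
    "SceneSpec",
    "HopModel",
    "MovieStack",
    "make_hopping_trace",
    "trace_from_trajectory",
    "render_movie",
]


@dataclass(frozen=True)
class OpticsModel:
    """Acquisition optics.  Frame rate and exposure follow the experiment
    (20 frames/s, 5 ms laser-on); pixel size, PSF width and photon budget
    are stated assumptions typical of objective-type TIRF with a sCMOS/EMCCD
    detector."""

    psf_sigma: float = 130.0          # nm
    pixel_size: float = 100.0         # nm/px
    photons_per_frame: float = 5000.0  # expected photons per spot per frame
    exposure: float = 0.005           # s
    frame_interval: float = 0.05      # s
    background: float = 20.0          # photons/px/frame

    def __post_init__(self):
        if (min(self.psf_sigma, self.pixel_size, self.exposure,
                self.frame_interval) <= 0
                or self.photons_per_frame < 0 or self.background < 0):
            raise ValueError("optics parameters must be positive")
        if self.exposure > self.frame_interval:
            raise ValueError("exposure cannot exceed the frame interval")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma / self.pixel_size


@dataclass(frozen=True)
class CameraModel:
    gain: float = 2.0          # counts/photon
    read_noise: float = 3.0    # counts, Gaussian std
    offset: float = 100.0      # counts
    bit_depth: int = 16

    def __post_init__(self):
        if self.gain <= 0 or self.read_noise < 0 or self.offset < 0:
            raise ValueError("invalid camera parameters")

    @property
    def max_count(self) -> int:
        return 2 ** self.bit_depth - 1


@dataclass(frozen=True)
class ParticleSpec:
    """One particle: ``kind`` is 'rotary' (tip circles the anchor),
    'stationary' (fixed spot) or 'defective' (fixed spot blinking with the
    given on-fraction)."""

    anchor: tuple               # (x, y) px
    kind: str = "rotary"
    lever_radius: float = 290.0  # nm
    on_fraction: float = 0.2     # used by 'defective'
    blink_dwell_frames: float = 5.0

    def __post_init__(self):
        if self.kind not in ("rotary", "stationary", "defective"):
            raise ValueError(f"unknown particle kind: {self.kind!r}")
        if not 0.0 < self.on_fraction <= 1.0:
            raise ValueError("on_fraction must be in (0, 1]")


@dataclass(frozen=True)
class DriftSpec:
    velocity: tuple = (0.0, 0.0)   # px/s, applied to all positions
    random_walk_std: float = 0.0   # px per sqrt(frame)


@dataclass(frozen=True)
class SceneSpec:
    field_size: tuple = (32, 32)   # (height, width) px
    particles: tuple = ()
    reference_spot: tuple | None = None   # stator-fixed pointer position
    drift: DriftSpec | None = None

    def __post_init__(self):
        object.__setattr__(self, "particles", tuple(self.particles))

    def validate(self, optics: OpticsModel):
        H, W = self.field_size
        margin = 4.0 * optics.psf_sigma_px
        for p in self.particles:
            x, y = p.anchor
            if not (margin <= x <= W - 1 - margin and margin <= y <= H - 1 - margin):
                raise ValueError(
                    f"anchor {p.anchor} closer than {margin:.1f} px to the field edge")


@dataclass(frozen=True)
class HopModel:
    """Three-state continuous-time Markov hopping among orientations 120
    degrees apart with a mean-reverting intra-state wiggle.

    The default rate matrix gives symmetric hopping with a mean dwell of
    1.5 s; the wiggle emulates the restricted rotary motion seen for a
    docked camshaft (std 7 deg, relaxing within a couple of frames).
    """

    state_angles: tuple = (0.0, 120.0, 240.0)
    rate_matrix: tuple = None       # 1/s, rows sum to zero
    wiggle_sigma: float = 7.0       # deg
    wiggle_tau: float = 0.1         # s

    def __post_init__(self):
        if self.rate_matrix is None:
            k = 1.0 / 3.0
            n = len(self.state_angles)
            Q = np.full((n, n), k)
            np.fill_diagonal(Q, -(n - 1) * k)
            object.__setattr__(self, "rate_matrix", tuple(map(tuple, Q)))
        Q = np.asarray(self.rate_matrix, dtype=float)
        n = len(self.state_angles)
        if Q.shape != (n, n):
            raise ValueError("rate matrix shape must match state_angles")
        off = Q[~np.eye(n, dtype=bool)]
        if np.any(off < 0) or not np.allclose(Q.sum(axis=1), 0.0, atol=1e-10):
            raise ValueError("rate matrix rows must sum to 0 with non-negative "
                             "off-diagonal rates")
        if self.wiggle_sigma < 0 or self.wiggle_tau <= 0:
            raise ValueError("invalid wiggle parameters")

    @property
    def Q(self) -> np.ndarray:
        return np.asarray(self.rate_matrix, dtype=float)


@dataclass
class MovieStack:
    """Grayscale frame stack with acquisition metadata and, for synthetic
    movies, the pre-noise ground truth (one row per particle per frame)."""

    frames: np.ndarray             # (T, H, W) integer counts
    pixel_size: float              # nm/px
    frame_interval: float          # s
    ground_truth: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape


# --------------------------------------------------------------------------


def make_hopping_trace(model: HopModel, duration: float, dt: float = 0.05,
                       seed: int = 0):
    """Simulate the hopping model on a uniform frame grid.

    The state path is drawn by Gillespie sampling of the embedded jump
    chain and discretized to the grid; the wiggle is an exact
    Ornstein-Uhlenbeck update.  Returns (AngleTrace, labels).
    """
    Q = model.Q
    exit_rates = -np.diag(Q)
    if dt > 0.1 / max(exit_rates.max(), 1e-12):
        raise ValueError("dt too coarse for the fastest hopping rate")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration / dt)) + 1
    times = np.arange(n_frames) * dt

    # Gillespie path
    state = int(rng.integers(len(model.state_angles)))
    jump_times = [0.0]
    states = [state]
    t = 0.0
    while t < duration:
        rate = exit_rates[state]
        if rate <= 0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            break
        probs = Q[state].copy()
        probs[state] = 0.0
        probs = probs / probs.sum()
        state = int(rng.choice(len(probs), p=probs))
        jump_times.append(t)
        states.append(state)

    labels = np.asarray(states)[np.searchsorted(jump_times, times, side="right") - 1]

    # unwrapped center path: each hop takes the minimal angular step
    angles = np.asarray(model.state_angles, dtype=float)
    center = np.empty(n_frames)
    center[0] = angles[labels[0]]
    steps = wrapdiff(angles[labels[1:]] - angles[labels[:-1]])
    center[1:] = center[0] + np.cumsum(steps)

    # OU wiggle, exact discretization
    wig = np.zeros(n_frames)
    if model.wiggle_sigma > 0:
        a = np.exp(-dt / model.wiggle_tau)
        sig = model.wiggle_sigma * np.sqrt(1.0 - a * a)
        wig[0] = rng.normal(0.0, model.wiggle_sigma)
        noise = rng.normal(0.0, sig, n_frames - 1)
        for i in range(1, n_frames):
            wig[i] = a * wig[i - 1] + noise[i - 1]

    trace = AngleTrace(times, center + wig, dt,
                       meta={"source": "hop_model", "seed": seed})
    return trace, labels


def trace_from_trajectory(traj, frame_interval: float = 0.05,
                          exposure: float | None = None) -> AngleTrace:
    """Subsample a mechanism trajectory onto the camera frame grid.

    With ``exposure`` set, the angle is averaged over the laser-on window
    at the start of each frame (motion blur on the angular coordinate).
    """
    rec_dt = traj.record_dt
    stride = frame_interval / rec_dt
    if abs(stride - round(stride)) > 1e-9:
        raise ValueError("trajectory recording interval must divide frame_interval")
    stride = int(round(stride))
    idx = np.arange(0, len(traj.theta), stride)
    if exposure is None:
        theta = traj.theta[idx]
    else:
        n_win = max(1, int(round(exposure / rec_dt)))
        theta = np.array([traj.theta[i:i + n_win].mean() for i in idx])
    times = traj.times[idx]
    return AngleTrace(times - times[0], theta, frame_interval,
                      meta={"source": "mechanism", **traj.meta})


def _integrated_gaussian(x0, y0, sigma_px, H, W, radius_px):
    """Expected fraction of a unit-intensity spot in each pixel, computed
    on a local window; returns (window, (y_slice, x_slice))."""
    r = int(np.ceil(radius_px))
    x_lo, x_hi = int(np.floor(x0)) - r, int(np.floor(x0)) + r + 1
    y_lo, y_hi = int(np.floor(y0)) - r, int(np.floor(y0)) + r + 1
    x_lo, x_hi = max(x_lo, 0), min(x_hi, W)
    y_lo, y_hi = max(y_lo, 0), min(y_hi, H)
    if x_lo >= x_hi or y_lo >= y_hi:
        return None, None
    xs = np.arange(x_lo, x_hi)
    ys = np.arange(y_lo, y_hi)
    s = sigma_px * np.sqrt(2.0)
    fx = 0.5 * (erf((xs + 0.5 - x0) / s) - erf((xs - 0.5 - x0) / s))
    fy = 0.5 * (erf((ys + 0.5 - y0) / s) - erf((ys - 0.5 - y0) / s))
    return np.outer(fy, fx), (slice(y_lo, y_hi), slice(x_lo, x_hi))


def _telegraph(n, on_fraction, dwell_frames, rng):
    """Two-state blinking with the requested stationary on-fraction and
    mean on-dwell in frames."""
    k_off = 1.0 / dwell_frames
    k_on = k_off * on_fraction / (1.0 - on_fraction)
    state = rng.random() < on_fraction
    out = np.empty(n, dtype=bool)
    for i in range(n):
        out[i] = state
        p_flip = k_off if state else k_on
        if rng.random() < min(p_flip, 1.0):
            state = not state
    return out


def render_movie(traces, scene: SceneSpec, optics: OpticsModel | None = None,
                 camera: CameraModel | None = None, seed: int = 0,
                 noise: bool = True, n_frames: int | None = None) -> MovieStack:
    """Render a movie of the scene.

    ``traces`` supplies one :class:`AngleTrace` per rotary particle (in
    scene order); all traces must share the frame grid.  Ground truth
    (pre-noise positions, angles, state of the blinkers, applied drift) is
    recorded per particle per frame.  With ``noise=False`` the expected
    photon image is converted directly to counts (no shot or read noise),
    which is strictly deterministic.
    """
    optics = optics or OpticsModel()
    camera = camera or CameraModel()
    scene.validate(optics)
    rng = np.random.default_rng(seed)

    rotary = [p for p in scene.particles if p.kind == "rotary"]
    if len(traces) != len(rotary):
        raise ValueError(f"need one trace per rotary particle "
                         f"({len(rotary)} rotary, {len(traces)} traces)")
    if traces:
        n_frames = len(traces[0])
        for tr in traces:
            if len(tr) != n_frames or abs(tr.dt - traces[0].dt) > 1e-12:
                raise ValueError("all traces must share the frame grid")
    else:
        n_frames = n_frames or 100

    H, W = scene.field_size
    frames = np.empty((n_frames, H, W), dtype=np.uint16)
    radius_px = 6.0 * optics.psf_sigma_px

    # drift path
    drift = np.zeros((n_frames, 2))
    if scene.drift is not None:
        tgrid = np.arange(n_frames) * optics.frame_interval
        drift += np.asarray(scene.drift.velocity)[None, :] * tgrid[:, None]
        if scene.drift.random_walk_std > 0:
            steps = rng.normal(0.0, scene.drift.random_walk_std, (n_frames, 2))
            steps[0] = 0.0
            drift += np.cumsum(steps, axis=0)

    # blinking schedules for defective particles
    blink = {}
    for i, p in enumerate(scene.particles):
        if p.kind == "defective":
            blink[i] = _telegraph(n_frames, p.on_fraction,
                                  p.blink_dwell_frames, rng)

    records = []
    clipped_frames = []
    trace_iter = iter(traces)
    tip_theta = {}
    for i, p in enumerate(scene.particles):
        if p.kind == "rotary":
            tip_theta[i] = next(trace_iter).theta

    for t in range(n_frames):
        photons = np.full((H, W), float(optics.background))
        for i, p in enumerate(scene.particles):
            ax, ay = p.anchor
            if p.kind == "rotary":
                th = tip_theta[i][t]
                r_px = p.lever_radius / optics.pixel_size
                x = ax + r_px * np.cos(np.radians(th))
                y = ay + r_px * np.sin(np.radians(th))
                state = np.nan
            else:
                x, y = float(ax), float(ay)
                th = np.nan
                state = 1.0
                if p.kind == "defective":
                    state = float(blink[i][t])
            x += drift[t, 0]
            y += drift[t, 1]
            on = state != 0.0
            if on:
                win, sl = _integrated_gaussian(x, y, optics.psf_sigma_px,
                                               H, W, radius_px)
                if win is not None:
                    photons[sl] += optics.photons_per_frame * win
                elif p.kind == "rotary":
                    clipped_frames.append((t, i))
            records.append((t, i, x, y,
                            wrap360(th) if np.isfinite(th) else np.nan,
                            state, drift[t, 0], drift[t, 1]))
        if scene.reference_spot is not None:
            x = scene.reference_spot[0] + drift[t, 0]
            y = scene.reference_spot[1] + drift[t, 1]
            win, sl = _integrated_gaussian(x, y, optics.psf_sigma_px, H, W, radius_px)
            if win is not None:
                photons[sl] += optics.photons_per_frame * win

        if noise:
            counts = camera.gain * rng.poisson(photons)
            if camera.read_noise > 0:
                counts = counts + rng.normal(0.0, camera.read_noise, counts.shape)
        else:
            counts = camera.gain * photons
        counts = np.clip(np.round(counts + camera.offset), 0, camera.max_count)
        frames[t] = counts.astype(np.uint16)

    gt = pd.DataFrame(records, columns=["frame", "particle_id", "x_px", "y_px",
                                        "theta_deg", "state", "drift_x", "drift_y"])
    meta = {"seed": seed, "optics": optics, "camera": camera, "scene": scene}
    if clipped_frames:
        meta["tip_out_of_field"] = clipped_frames
    return MovieStack(frames, optics.pixel_size, optics.frame_interval, gt, meta)
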