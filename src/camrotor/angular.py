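"""Angular statistics of rotary single-particle tracks.

Converts sub-pixel centroid tracks into angle traces about a fitted center
of motion and computes the standard observables of rotary Brownian motion:

* orientation clustering into k preferred states (circular k-means),
* single-origin angular RMSD, ``RMSD = sqrt(sum_i (theta_i - theta_0)^2 / N)``,
* ensemble RMSD(t) over sliding time origins with the ``RMSD = A sqrt(t)``
  fit expected for normal rotary diffusion,
* frame-to-frame angular velocities ``Omega_i = (theta_i - theta_{i-1}) / dt``,
* tip-to-center radius distribution,
* dwell-time and transition statistics,
* a rotary/stationary motion classifier.

All angles are degrees; velocities deg/s (rev/s as convenience).  Angle
convention: measured from +x towards +y with y increasing downward (image
coordinates), matching the movie generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .mechanics import wrap360, wrapdiff
from .traces import AngleTrace

__all__ = [
    "CircleFit",
    "StateAssignment",
    "DiffusionSummary",
    "VelocitySummary",
    "DwellSummary",
    "fit_center",
    "to_angle_trace",
    "cluster_states",
    "rmsd_single",
    "rmsd_ensemble",
    "angular_velocities",
    "radius_distribution",
    "dwell_analysis",
    "classify_motion",
]


@dataclass
class CircleFit:
    cx: float
    cy: float
    radius: float
    rms_residual: float


def _track_xy(track, only_converged=True):
    if hasattr(track, "positions"):
        return track.positions(only_converged)
    x, y = np.asarray(track[0], float), np.asarray(track[1], float)
    return x, y


def fit_center(track, min_points: int = 10, min_arc: float = 90.0) -> CircleFit:
    """Fit the center of motion: algebraic (Kasa) circle fit refined by
    geometric least squares on the orthogonal residuals.

    Requires >= ``min_points`` converged positions spanning >= ``min_arc``
    degrees of arc around the provisional center; raises ValueError
    ('degenerate arc') otherwise.
    """
    x, y = _track_xy(track)
    if len(x) < max(min_points, 3):
        raise ValueError("degenerate arc: too few converged positions")

    A = np.column_stack([x, y, np.ones_like(x)])
    b = x * x + y * y
    sol, res, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3 or sv[-1] < 1e-10 * sv[0]:
        raise ValueError("degenerate arc: collinear positions")
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r = float(np.sqrt(sol[2] + cx * cx + cy * cy))

    ang = np.degrees(np.arctan2(y - cy, x - cx))
    spread = _circular_span(ang)
    if spread < min_arc:
        raise ValueError(f"degenerate arc: angular span {spread:.1f} deg < {min_arc}")

    def resid(p):
        return np.hypot(x - p[0], y - p[1]) - p[2]

    fit = least_squares(resid, [cx, cy, r])
    cx, cy, r = fit.x
    rms = float(np.sqrt(np.mean(resid(fit.x) ** 2)))
    return CircleFit(float(cx), float(cy), float(r), rms)


def _circular_span(angles_deg):
    """Smallest arc containing all angles (degrees)."""
    a = np.sort(wrap360(np.asarray(angles_deg)))
    if len(a) < 2:
        return 0.0
    gaps = np.diff(np.concatenate([a, [a[0] + 360.0]]))
    return float(360.0 - gaps.max())


def to_angle_trace(track, fit: CircleFit, frame_interval: float,
                   max_gap: int = 10):
    """Angles about the fitted center, unwrapped by the minimal-step rule.

    Each increment between consecutive *converged* frames is mapped into
    (-180, 180]; gaps of up to ``max_gap`` frames are bridged by the same
    rule, longer gaps split the trace.  Returns a list of
    :class:`AngleTrace` segments (one element when the track has no long
    gaps)."""
    conv = np.asarray(track.converged, bool) if hasattr(track, "converged") \
        else np.ones(len(track.x), bool)
    if not conv.any():
        raise ValueError("no converged frames in track")
    idx = np.flatnonzero(conv)
    theta_w = np.degrees(np.arctan2(track.y[idx] - fit.cy, track.x[idx] - fit.cx))
    theta_w = wrap360(theta_w)

    segments = []
    seg_start = 0
    for i in range(1, len(idx) + 1):
        gap_exceeded = i < len(idx) and (idx[i] - idx[i - 1] - 1) > max_gap
        if i == len(idx) or gap_exceeded:
            sel = slice(seg_start, i)
            w = theta_w[sel]
            unwrapped = np.concatenate([[w[0]], w[0] + np.cumsum(wrapdiff(np.diff(w)))])
            segments.append(AngleTrace(idx[sel] * frame_interval, unwrapped,
                                       frame_interval,
                                       meta={"frames": idx[sel]}))
            seg_start = i
    return segments


# --------------------------------------------------------------------------
# circular clustering


@dataclass
class StateAssignment:
    k: int
    centers: np.ndarray          # deg in [0, 360), sorted
    labels: np.ndarray           # per frame, -1 = unassigned
    occupancies: np.ndarray      # fractions over assigned frames
    inertia: float               # mean squared circular distance


def _circmean(a):
    rad = np.radians(a)
    return float(wrap360(np.degrees(np.arctan2(np.sin(rad).mean(),
                                               np.cos(rad).mean()))))


def cluster_states(trace, k: int = 3, n_init: int = 10, seed: int = 0,
                   reject_angle: float | None = None) -> StateAssignment:
    """Circular k-means on wrapped angles (distance = circular difference,
    centers = circular means), best of ``n_init`` seeded restarts.

    Frames farther than ``reject_angle`` from every center are labeled -1
    (unassigned).  Raises on persistent empty clusters.
    """
    angles = trace.theta_wrapped if isinstance(trace, AngleTrace) \
        else wrap360(np.asarray(trace, float))
    if len(angles) < 10 * k:
        raise ValueError(f"need at least {10 * k} angles to cluster")
    rng = np.random.default_rng(seed)

    best = None
    for _ in range(n_init):
        centers = angles[rng.choice(len(angles), k, replace=False)]
        for _ in range(200):
            dist = np.abs(wrapdiff(angles[:, None] - centers[None, :]))
            labels = np.argmin(dist, axis=1)
            new = centers.copy()
            for j in range(k):
                members = angles[labels == j]
                if len(members) == 0:
                    far = np.argmax(np.min(dist, axis=1))
                    new[j] = angles[far]
                else:
                    new[j] = _circmean(members)
            if np.allclose(np.abs(wrapdiff(new - centers)), 0.0, atol=1e-10):
                centers = new
                break
            centers = new
        dist = np.abs(wrapdiff(angles[:, None] - centers[None, :]))
        labels = np.argmin(dist, axis=1)
        if len(np.unique(labels)) < k:
            continue
        inertia = float(np.mean(np.min(dist, axis=1) ** 2))
        if best is None or inertia < best[2]:
            best = (centers, labels, inertia)
    if best is None:
        raise RuntimeError("circular k-means failed: persistent empty clusters")
    centers, labels, inertia = best

    order = np.argsort(wrap360(centers))
    centers = wrap360(centers[order])
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = remap[labels]

    if reject_angle is not None:
        d = np.abs(wrapdiff(angles - centers[labels]))
        labels = np.where(d > reject_angle, -1, labels)
    assigned = labels >= 0
    occ = np.bincount(labels[assigned], minlength=k).astype(float)
    occ /= occ.sum()
    return StateAssignment(k, centers, labels, occ, inertia)


# --------------------------------------------------------------------------
# diffusion statistics


@dataclass
class DiffusionSummary:
    lags: np.ndarray             # s
    rmsd: np.ndarray             # deg, sliding-origin ensemble RMSD(t)
    A: float                     # deg / sqrt(s), fit of RMSD = A sqrt(t)
    fit_residual: float
    loglog_slope: float
    per_trace_rmsd: np.ndarray   # single-origin RMSD per trace


def rmsd_single(trace: AngleTrace) -> float:
    """Single-origin RMSD over the whole trace: the reference angle is the
    first frame and every frame (including the first) enters the mean."""
    th = trace.theta
    if len(th) == 0:
        raise ValueError("empty trace")
    return float(np.sqrt(np.mean((th - th[0]) ** 2)))


def rmsd_ensemble(traces, lags=None, fit_range=None) -> DiffusionSummary:
    """Ensemble angular RMSD over time with the sqrt(t) fit.

    ``RMSD(t)`` averages ``(theta(t0 + t) - theta(t0))^2`` over all traces
    and all sliding origins t0 (unwrapped angles).  ``A`` is the least-
    squares coefficient of ``RMSD = A sqrt(t)`` over ``fit_range`` (s),
    defaulting to all computed lags.
    """
    traces = list(traces)
    if len(traces) < 1:
        raise ValueError("need at least one trace")
    dt = traces[0].dt
    n_min = min(len(t) for t in traces)
    if lags is None:
        lag_idx = np.unique(np.linspace(1, max(n_min // 4, 1), 30).astype(int))
    else:
        lag_idx = np.unique(np.asarray(
            [int(round(l / dt)) for l in np.atleast_1d(lags)], dtype=int))
        lag_idx = lag_idx[(lag_idx >= 1) & (lag_idx < n_min)]
        if len(lag_idx) == 0:
            raise ValueError("no usable lags within the shortest trace")

    msd = np.zeros(len(lag_idx))
    for i, l in enumerate(lag_idx):
        acc, cnt = 0.0, 0
        for tr in traces:
            th = tr.theta
            if len(th) > l:
                dth = th[l:] - th[:-l]
                acc += np.sum(dth * dth)
                cnt += len(dth)
        msd[i] = acc / cnt
    lags_s = lag_idx * dt
    rmsd = np.sqrt(msd)

    mask = np.ones(len(lags_s), bool)
    if fit_range is not None:
        mask = (lags_s >= fit_range[0]) & (lags_s <= fit_range[1])
        if not mask.any():
            mask = np.ones(len(lags_s), bool)
    sq = np.sqrt(lags_s[mask])
    A = float(np.dot(sq, rmsd[mask]) / np.dot(sq, sq))
    resid = float(np.sqrt(np.mean((rmsd[mask] - A * sq) ** 2)))

    pos = rmsd > 0
    if pos.sum() >= 2:
        slope = float(np.polyfit(np.log(lags_s[pos]), np.log(rmsd[pos]), 1)[0])
    else:
        slope = np.nan
    per_trace = np.array([rmsd_single(t) for t in traces])
    return DiffusionSummary(lags_s, rmsd, A, resid, slope, per_trace)


@dataclass
class VelocitySummary:
    omega: np.ndarray            # deg/s, concatenated over traces
    weights: np.ndarray          # trace length (frames) per velocity sample
    hist_edges: np.ndarray
    hist_density: np.ndarray
    weighted_mean: float         # deg/s, trace-length weighted
    weighted_sem: float          # standard error of the weighted mean

    @property
    def omega_rev(self) -> np.ndarray:
        return self.omega / 360.0

    @property
    def weighted_mean_rev(self) -> float:
        return self.weighted_mean / 360.0


def angular_velocities(traces, bins=61, vmax=None) -> VelocitySummary:
    """Frame-to-frame angular velocities on unwrapped angles.

    Accepts one trace or a list.  The mean is weighted by trace length
    (each trace contributes its mean velocity weighted by its number of
    velocity samples, equivalent to pooling all samples)."""
    if isinstance(traces, AngleTrace):
        traces = [traces]
    omega, w = [], []
    for tr in traces:
        if len(tr) < 2:
            continue
        om = np.diff(tr.theta) / tr.dt
        omega.append(om)
        w.append(np.full(len(om), len(om), dtype=float))
    if not omega:
        raise ValueError("need at least one trace with two frames")
    omega = np.concatenate(omega)
    w = np.concatenate(w)
    if vmax is None:
        vmax = max(np.abs(omega).max(), 1e-9)
    edges = np.linspace(-vmax, vmax, bins + 1)
    density, _ = np.histogram(omega, bins=edges, density=True)
    mean = float(np.mean(omega))
    sem = float(np.std(omega, ddof=1) / np.sqrt(len(omega))) if len(omega) > 1 else np.inf
    return VelocitySummary(omega, w, edges, density, mean, sem)


def radius_distribution(track, fit: CircleFit, pixel_size: float):
    """Per-frame tip-to-center distance in nm (converged frames) and its
    mean; returns (distances, mean_nm)."""
    x, y = _track_xy(track)
    dist = np.hypot(x - fit.cx, y - fit.cy) * pixel_size
    return dist, float(dist.mean())


# --------------------------------------------------------------------------
# dwell / transition statistics


@dataclass
class DwellSummary:
    dwells: dict                 # state -> array of dwell times (s)
    mean_dwell: np.ndarray       # per state, s (nan if no samples)
    transitions: np.ndarray      # (k, k) counts, zero diagonal
    net_cycles: float            # signed completed cycles


def dwell_analysis(assignment: StateAssignment, frame_interval: float,
                   min_dwell: int = 1) -> DwellSummary:
    """Run-length dwell and transition statistics from state labels.

    Runs shorter than ``min_dwell`` frames are merged into the preceding
    run (a leading short run merges forward).  The first and last runs are
    censored and excluded from the dwell samples.  Net cycles counts the
    signed number of completed revolutions through the cyclic state order
    (k states of ``2 pi / k`` each).
    """
    labels = np.asarray(assignment.labels)
    labels = labels[labels >= 0]
    k = assignment.k
    if len(labels) == 0:
        raise ValueError("no assigned frames")

    runs = []
    for lab in labels:
        if runs and runs[-1][0] == lab:
            runs[-1][1] += 1
        else:
            runs.append([int(lab), 1])
    # absorb short runs into the preceding run (first run is kept as is:
    # it is censored and never enters the dwell samples)
    merged = []
    for lab, length in runs:
        if merged and length < min_dwell:
            merged[-1][1] += length
        elif merged and merged[-1][0] == lab:
            merged[-1][1] += length
        else:
            merged.append([lab, length])
    # collapse neighbors that became equal after merging
    runs = []
    for lab, length in merged:
        if runs and runs[-1][0] == lab:
            runs[-1][1] += length
        else:
            runs.append([lab, length])

    dwells = {j: [] for j in range(k)}
    for lab, length in runs[1:-1]:
        dwells[lab].append(length * frame_interval)
    dwells = {j: np.asarray(v) for j, v in dwells.items()}
    mean_dwell = np.array([dwells[j].mean() if len(dwells[j]) else np.nan
                           for j in range(k)])

    trans = np.zeros((k, k), dtype=int)
    signed = 0
    for (a, _), (b, _) in zip(runs[:-1], runs[1:]):
        trans[a, b] += 1
        step = (b - a) % k
        signed += step if step <= k / 2 else step - k
    return DwellSummary(dwells, mean_dwell, trans, signed / float(k))


def classify_motion(trace: AngleTrace, span_threshold: float = 200.0,
                    min_transitions: int = 2,
                    assignment: StateAssignment | None = None,
                    frame_interval: float | None = None) -> str:
    """'rotary' iff the unwrapped angular span strictly exceeds
    ``span_threshold`` and at least ``min_transitions`` inter-state
    transitions occur; otherwise 'stationary'.  A span exactly at the
    threshold classifies as stationary."""
    span = float(trace.theta.max() - trace.theta.min())
    if span <= span_threshold:
        return "stationary"
    if assignment is None:
        try:
            assignment = cluster_states(trace, k=3)
        except (ValueError, RuntimeError):
            return "stationary"
    dw = dwell_analysis(assignment, frame_interval or trace.dt)
    if dw.transitions.sum() < min_transitions:
        return "stationary"
    return "rotary"
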