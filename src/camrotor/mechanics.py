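"""Coarse-grained mechanics of the camshaft-in-stator rotary mechanism.

The mechanism is a trimeric DNA-origami stator (three units, each with a
rigid bearing block and two flexible pawls) enclosing a camshaft whose
off-axis cam sterically pushes the pawls outwards as it rotates.  The model
collapses the device onto seven coordinates: the camshaft angle ``theta``
(degrees) and six outward radial pawl deflections ``d_1..d_6`` (nm).

Internal units: thermal energy k_BT at ``MechanicalParams.temperature``,
nm, degrees, seconds.

The potential energy is

``U = sum_j 1/2 k_pawl (d_j - rest_j)^2            pawl bending
    + sum_j 1/2 k_steric (c_j(theta) - d_j)^2      cam/pawl contact, d_j < c_j
    + sum_pairs 1/2 k_pair (d_j - d_k)^2           inter-pawl couplings
    + strut terms                                  rigid links spanning a slot
    - stack_depth sum_j exp(-(d_j/stack_range)^2)  blunt-end stacking well``

where the required clearance ``c_j(theta) = h * g(theta - phi_j; w)`` uses a
smooth cosine taper ``g`` (g(0)=1, g(+-w)=0), so forces are C^1 and safe for
Euler-Maruyama integration.

Six design variants alter the pawl couplings:

1. independent pawls, stacking on (reference design)
2. independent pawls, stacking off (extra-flexible pawls)
3. the two pawls of each unit rigidly cross-linked (removes the three
   intra-unit slots)
4. pawls rigidly cross-linked across the unit interfaces (removes the three
   inter-unit slots; stalls)
5. as 4 but with long flexible spacer linkages that push the pawls slightly
   apart (fastest variant)
6. all adjacent pawls rigidly cross-linked (fully locked)

A rigid cross-link is modeled both as a stiff difference spring and as a
steric strut spanning the slot between the linked pawls.  A strut between
the two pawls of one unit rides on those pawls (it deflects with them); a
strut bridging the inter-unit interface is backed by the rigid bearing
blocks and is treated as immobile, which is what blocks the inter-unit
slots and stalls variants 4 and 6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from . import _kernels

__all__ = [
    "KCAL_PER_MOL_IN_KBT",
    "MechanismGeometry",
    "MechanicalParams",
    "VariantSpec",
    "MechanismState",
    "SteeredProtocol",
    "BDTrajectory",
    "MechanismModel",
    "RotationCycleSummary",
    "LandscapeProfile",
    "MobilityResult",
    "build_mechanism",
    "simulate_equilibrium",
    "simulate_steered",
    "cycle_average",
    "effective_landscape",
    "mobility",
    "wrap360",
    "wrapdiff",
]

#: 1 kcal/mol expressed in k_BT at 295 K (R*T = 8.314 J/mol/K * 295 K).
KCAL_PER_MOL_IN_KBT = 4184.0 / (8.314462618 * 295.0)


def wrap360(x):
    """Wrap angles (degrees) into [0, 360)."""
    x = np.asarray(x, dtype=float)
    return x - 360.0 * np.floor(x / 360.0)


def wrapdiff(x):
    """Map angle differences (degrees) into (-180, 180]."""
    x = np.asarray(x, dtype=float)
    y = x - 360.0 * np.floor(x / 360.0)
    return np.where(y > 180.0, y - 360.0, y)


# --------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class MechanismGeometry:
    """Angular layout of the stator and the cam dimensions.

    Defaults: three units centered at 0/120/240 deg, pawls at the unit
    center +-25 deg, cam steric half-width 30 deg, cam protrusion 5 nm past
    a 10 nm bearing bore, and a 290 nm fluorescent lever arm.  The cam
    height and bore radius are calibration choices that reproduce ~5 nm
    pawl deflections during forced rotation.
    """

    n_units: int = 3
    pawls_per_unit: int = 2
    pawl_offset: float = 25.0        # deg from the unit center
    cam_halfwidth: float = 30.0      # deg
    cam_height: float = 5.0          # nm
    bore_radius: float = 10.0        # nm
    lever_radius: float = 290.0      # nm
    pawl_angles: tuple = None        # override; else derived from offsets

    def __post_init__(self):
        if self.pawl_angles is None:
            centers = self.unit_centers
            ang = np.sort(wrap360(np.concatenate(
                [centers - self.pawl_offset, centers + self.pawl_offset])))
            object.__setattr__(self, "pawl_angles", tuple(float(a) for a in ang))
        ang = np.asarray(self.pawl_angles, dtype=float)
        if ang.ndim != 1 or len(ang) != self.n_units * self.pawls_per_unit:
            raise ValueError("pawl_angles must list one angle per pawl")
        if np.any(ang < 0) or np.any(ang >= 360) or np.any(np.diff(ang) <= 0):
            raise ValueError("pawl_angles must be sorted, strictly increasing, in [0, 360)")
        gaps = np.diff(np.concatenate([ang, [ang[0] + 360.0]]))
        if self.cam_halfwidth >= gaps.min():
            raise ValueError("cam_halfwidth must be smaller than the minimum pawl gap")
        if self.cam_height <= 0:
            raise ValueError("cam_height must be positive")

    @property
    def n_pawls(self) -> int:
        return self.n_units * self.pawls_per_unit

    @property
    def unit_centers(self) -> np.ndarray:
        return np.arange(self.n_units) * (360.0 / self.n_units)

    @property
    def pawl_unit(self) -> np.ndarray:
        """Unit index of each pawl (nearest unit center)."""
        ang = np.asarray(self.pawl_angles)
        diffs = np.abs(wrapdiff(ang[:, None] - self.unit_centers[None, :]))
        return np.argmin(diffs, axis=1)

    @property
    def slot_angles(self) -> np.ndarray:
        """The six slots: circular midpoints between adjacent pawls
        (alternating intra-unit and inter-unit)."""
        ang = np.asarray(self.pawl_angles)
        nxt = np.roll(ang, -1).copy()
        nxt[-1] += 360.0
        return wrap360(0.5 * (ang + nxt))

    @property
    def intra_slot_angles(self) -> np.ndarray:
        return self.slot_angles[self._slot_is_intra()]

    @property
    def inter_slot_angles(self) -> np.ndarray:
        return self.slot_angles[~self._slot_is_intra()]

    def _slot_is_intra(self) -> np.ndarray:
        u = self.pawl_unit
        return u == np.roll(u, -1)

    def adjacent_pairs(self, kind: str = "all"):
        """Adjacent pawl index pairs: 'intra' (same unit), 'inter'
        (across a unit interface) or 'all'."""
        u = self.pawl_unit
        n = self.n_pawls
        pairs = []
        for j in range(n):
            k = (j + 1) % n
            same = u[j] == u[k]
            if kind == "all" or (kind == "intra" and same) or (kind == "inter" and not same):
                pairs.append((j, k))
        return pairs


@dataclass(frozen=True)
class MechanicalParams:
    """Stiffnesses, diffusion coefficients and thermodynamic parameters.

    All energies in k_BT.  The defaults are calibrated so that (i) forced
    rotation deflects pawls by ~5 nm, (ii) disabling stacking roughly
    doubles the rotary mobility, and (iii) slot-to-slot hopping occurs on
    the ~0.1-1 s scale so that state visits are resolvable at 20 frames/s.
    """

    k_pawl: float = 0.12          # kBT/nm^2, radial pawl stiffness
    k_steric_factor: float = 10.0  # steric contact stiffness, units of k_pawl
    k_rigid_factor: float = 100.0  # rigid-link difference stiffness, units of k_pawl
    k_couple: float = 0.05        # kBT/nm^2, soft (spring/spacer) coupling
    couple_rest: float = 4.0      # nm, outward rest offset of spacer-linked pawls
    stack_depth: float = 0.7      # kBT, blunt-end stacking well at d = 0
    stack_range: float = 1.5      # nm
    D_theta: float = 2.0e4        # deg^2/s, bare camshaft rotational diffusion
    D_pawl: float = 5.0e3         # nm^2/s, pawl deflection diffusion
    temperature: float = 295.0    # K

    def __post_init__(self):
        for name in ("k_pawl", "k_steric_factor", "k_rigid_factor", "k_couple",
                     "stack_depth", "stack_range", "D_theta", "D_pawl"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.couple_rest < 0:
            raise ValueError("couple_rest must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def k_steric(self) -> float:
        return self.k_steric_factor * self.k_pawl

    @property
    def k_rigid(self) -> float:
        return self.k_rigid_factor * self.k_pawl


@dataclass(frozen=True)
class VariantSpec:
    """Coupling topology of one design variant.

    ``coupled_pairs`` lists (pawl j, pawl k, kind) with kind in
    {'spring', 'rigid', 'spacer'}.
    """

    id: int
    coupled_pairs: tuple = ()
    stacking_enabled: bool = True

    @classmethod
    def preset(cls, variant_id: int, geometry: MechanismGeometry | None = None) -> "VariantSpec":
        geo = geometry or MechanismGeometry()
        if variant_id == 1:
            return cls(1, (), True)
        if variant_id == 2:
            return cls(2, (), False)
        if variant_id == 3:
            pairs = tuple((j, k, "rigid") for j, k in geo.adjacent_pairs("intra"))
            return cls(3, pairs, True)
        if variant_id == 4:
            pairs = tuple((j, k, "rigid") for j, k in geo.adjacent_pairs("inter"))
            return cls(4, pairs, True)
        if variant_id == 5:
            pairs = tuple((j, k, "spacer") for j, k in geo.adjacent_pairs("inter"))
            return cls(5, pairs, True)
        if variant_id == 6:
            pairs = tuple((j, k, "rigid") for j, k in geo.adjacent_pairs("all"))
            return cls(6, pairs, True)
        raise ValueError(f"unknown variant id: {variant_id}")


@dataclass
class MechanismState:
    """Instantaneous configuration: camshaft angle (deg, wrapped) and the
    six pawl deflections (nm)."""

    theta: float
    d: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.theta = float(wrap360(self.theta))
        self.d = np.asarray(self.d, dtype=float)
        if not np.all(np.isfinite(self.d)):
            raise ValueError("pawl deflections must be finite")


@dataclass(frozen=True)
class SteeredProtocol:
    """Harmonic bias on the camshaft angle with a rest angle advancing at a
    constant rate; run for n_turns full revolutions in each direction.

    The default stiffness is 0.5 kcal/mol/deg^2 expressed in k_BT at 295 K
    (~0.853 kBT/deg^2)."""

    k_spring: float = 0.5 * KCAL_PER_MOL_IN_KBT   # kBT/deg^2
    rate: float = 90.0                            # deg/s
    n_turns: int = 3
    bin_width: float = 10.0                       # deg

    def __post_init__(self):
        if self.k_spring <= 0 or self.rate <= 0:
            raise ValueError("k_spring and rate must be positive")
        if self.n_turns < 3:
            raise ValueError("at least three revolutions per direction are required")
        if 360.0 % self.bin_width:
            raise ValueError("bin_width must divide 360")


@dataclass
class BDTrajectory:
    """Recorded Brownian-dynamics trajectory.

    ``theta`` is the unwrapped camshaft angle at the recording grid (every
    ``record_every`` integrator steps of size ``dt``); ``d`` the pawl
    deflections.  ``theta_rest`` is the bias rest angle for steered runs.
    """

    times: np.ndarray
    theta: np.ndarray
    d: np.ndarray
    seed: int
    dt: float
    record_every: int
    meta: dict = field(default_factory=dict)
    theta_rest: np.ndarray | None = None

    @property
    def theta_wrapped(self) -> np.ndarray:
        return wrap360(self.theta)

    @property
    def record_dt(self) -> float:
        return self.dt * self.record_every

    def __len__(self) -> int:
        return len(self.times)

    def state(self, i: int) -> MechanismState:
        return MechanismState(self.theta[i], self.d[i], self.times[i])

    def to_dataframe(self):
        import pandas as pd

        cols = {"t": self.times, "theta_deg": self.theta}
        for j in range(self.d.shape[1]):
            cols[f"d{j + 1}"] = self.d[:, j]
        if self.theta_rest is not None:
            cols["theta_rest_deg"] = self.theta_rest
        return pd.DataFrame(cols)


# --------------------------------------------------------------------------
# model


class MechanismModel:
    """Energy model of one variant; exposes the potential, its gradient and
    the steric clearance profile, and packs arrays for the numba kernels."""

    def __init__(self, variant: VariantSpec, geometry: MechanismGeometry,
                 params: MechanicalParams):
        self.variant = variant
        self.geometry = geometry
        self.params = params

        n = geometry.n_pawls
        phi = np.asarray(geometry.pawl_angles, dtype=float)
        unit = geometry.pawl_unit
        h_eff = np.full(n, float(geometry.cam_height))
        steric_on = np.ones(n, dtype=np.int64)
        pair_idx, pair_k = [], []
        mwall_idx, mwall_span, fwall_span = [], [], []

        for (j, k, kind) in variant.coupled_pairs:
            if not (0 <= j < n and 0 <= k < n) or j == k:
                raise ValueError(f"coupling pair ({j}, {k}) references a nonexistent pawl")
            if kind not in ("spring", "rigid", "spacer"):
                raise ValueError(f"unknown coupling kind: {kind!r}")
            pair_idx.append((j, k))
            if kind == "rigid":
                pair_k.append(params.k_rigid)
                a, arc = self._gap_span(phi, j, k)
                if unit[j] == unit[k]:
                    mwall_idx.append((j, k))
                    mwall_span.append((a, arc))
                    steric_on[j] = 0
                    steric_on[k] = 0
                else:
                    fwall_span.append((a, arc))
            else:
                pair_k.append(params.k_couple)
                if kind == "spacer":
                    # the bulky linker pushes the pawls apart, reducing the
                    # cam/pawl radial overlap
                    h_eff[j] = max(geometry.cam_height - params.couple_rest, 0.0)
                    h_eff[k] = max(geometry.cam_height - params.couple_rest, 0.0)

        self._phi = phi
        self._h_eff = h_eff
        self._steric_on = steric_on
        self._pair_idx = (np.asarray(pair_idx, dtype=np.int64).reshape(-1, 2)
                          if pair_idx else np.empty((0, 2), dtype=np.int64))
        self._pair_k = np.asarray(pair_k, dtype=float)
        self._mwall_idx = (np.asarray(mwall_idx, dtype=np.int64).reshape(-1, 2)
                           if mwall_idx else np.empty((0, 2), dtype=np.int64))
        self._mwall_span = (np.asarray(mwall_span, dtype=float).reshape(-1, 2)
                            if mwall_span else np.empty((0, 2)))
        self._fwall_span = (np.asarray(fwall_span, dtype=float).reshape(-1, 2)
                            if fwall_span else np.empty((0, 2)))

    @staticmethod
    def _gap_span(phi, j, k):
        """Start angle and arc length of the (short) gap from pawl j to k."""
        arc = wrap360(phi[k] - phi[j])
        if arc <= 180.0:
            return float(phi[j]), float(arc)
        return float(phi[k]), float(wrap360(phi[j] - phi[k]))

    @property
    def n_dof(self) -> int:
        return 1 + self.geometry.n_pawls

    def _kernel_args(self):
        p = self.params
        return (self._phi, self._h_eff, self._steric_on, p.k_pawl, p.k_steric,
                self.geometry.cam_height, self.geometry.cam_halfwidth,
                1 if self.variant.stacking_enabled else 0,
                p.stack_depth, p.stack_range,
                self._pair_idx, self._pair_k,
                self._mwall_idx, self._mwall_span, self._fwall_span)

    def clearance(self, theta: float) -> np.ndarray:
        """Required outward clearance c_j(theta) of each pawl, nm."""
        geo = self.geometry
        delta = wrapdiff(theta - self._phi)
        g = np.where(np.abs(delta) < geo.cam_halfwidth,
                     0.5 * (1 + np.cos(np.pi * delta / geo.cam_halfwidth)), 0.0)
        return self._h_eff * g

    def potential_energy(self, state: MechanismState) -> float:
        """Total potential energy, k_BT."""
        grad_d = np.empty(self.geometry.n_pawls)
        U, _ = _kernels.energy_gradient(float(state.theta), np.asarray(state.d, float),
                                        *self._kernel_args(), grad_d)
        return float(U)

    def energy_gradient(self, state: MechanismState):
        """(dU/dtheta [kBT/deg], dU/dd [kBT/nm])."""
        grad_d = np.empty(self.geometry.n_pawls)
        _, gt = _kernels.energy_gradient(float(state.theta), np.asarray(state.d, float),
                                         *self._kernel_args(), grad_d)
        return float(gt), grad_d

    def energy_at(self, theta: float, d: np.ndarray) -> float:
        grad_d = np.empty(self.geometry.n_pawls)
        U, _ = _kernels.energy_gradient(float(theta), np.asarray(d, float),
                                        *self._kernel_args(), grad_d)
        return float(U)

    def minimize_pawls(self, theta: float, d0: np.ndarray | None = None):
        """Minimize U over the pawl deflections at fixed theta.

        Returns (d_min, U_min)."""

        def fun(d):
            grad_d = np.empty(self.geometry.n_pawls)
            U, _ = _kernels.energy_gradient(float(theta), d, *self._kernel_args(), grad_d)
            return U, grad_d

        starts = []
        if d0 is not None:
            starts.append(np.asarray(d0, float))
        starts.append(np.zeros(self.geometry.n_pawls))
        starts.append(self.clearance(theta))
        best = None
        for s in starts:
            res = minimize(fun, s, jac=True, method="L-BFGS-B")
            if best is None or res.fun < best.fun:
                best = res
        if not best.success and not np.isfinite(best.fun):
            raise RuntimeError(f"pawl minimization failed at theta={theta}")
        return best.x, float(best.fun)


def build_mechanism(variant: VariantSpec | int,
                    geometry: MechanismGeometry | None = None,
                    params: MechanicalParams | None = None) -> MechanismModel:
    """Assemble the energy model for a design variant.

    ``variant`` may be a :class:`VariantSpec` or a preset id 1..6.
    """
    geometry = geometry or MechanismGeometry()
    params = params or MechanicalParams()
    if isinstance(variant, (int, np.integer)):
        variant = VariantSpec.preset(int(variant), geometry)
    return MechanismModel(variant, geometry, params)


# --------------------------------------------------------------------------
# simulation


DEFAULT_DT = 2.0e-6          # s
DEFAULT_RECORD_DT = 1.0e-3   # s


def docked_angle(model: MechanismModel) -> float:
    """Slot angle with the lowest adiabatic energy: where a released
    camshaft would start (the docked orientation)."""
    slots = model.geometry.slot_angles
    U = [model.minimize_pawls(th)[1] for th in slots]
    return float(slots[int(np.argmin(U))])


def _check_dt(model: MechanismModel, dt: float):
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = model.params
    geo = model.geometry
    # typical force scales: full steric compression over the cam height plus
    # a thermal-amplitude stretch of the stiffest coupling spring
    f_d = p.k_steric * geo.cam_height + np.sqrt(2.0 * p.k_rigid)  # kBT/nm
    f_t = p.k_steric * geo.cam_height * geo.cam_height * np.pi / (2 * geo.cam_halfwidth)
    drift_d = p.D_pawl * f_d * dt
    drift_t = p.D_theta * f_t * dt
    if drift_d > 0.1 * max(geo.cam_height, 1.0) or drift_t > 0.1 * geo.cam_halfwidth:
        warnings.warn(
            f"dt={dt:g} s may be too large: worst-case drift per step is "
            f"{drift_d:.3g} nm / {drift_t:.3g} deg", stacklevel=3)


def _run(model, duration, dt, seed, record_every, theta0, d0,
         bias_on=False, k_spring=0.0, rest0=0.0, rate=0.0):
    _check_dt(model, dt)
    n_steps = int(round(duration / dt))
    if record_every is None:
        record_every = max(1, int(round(DEFAULT_RECORD_DT / dt)))
    n_steps = (n_steps // record_every) * record_every
    if n_steps <= 0:
        raise ValueError("duration too short for one recording interval")
    if d0 is None:
        d0, _ = model.minimize_pawls(theta0)
    seed = int(seed) % (2 ** 31)
    theta_rec, d_rec, rest_rec, status = _kernels.integrate(
        float(theta0), np.asarray(d0, float), n_steps, dt, record_every,
        model.params.D_theta, model.params.D_pawl,
        bias_on, k_spring, rest0, rate, seed, *model._kernel_args())
    if status >= 0:
        raise FloatingPointError(
            f"non-finite state encountered at integration step {status}")
    times = np.arange(len(theta_rec)) * dt * record_every
    meta = {"variant": model.variant.id, "seed": seed, "dt": dt,
            "record_every": record_every, "steered": bool(bias_on)}
    return BDTrajectory(times, theta_rec, d_rec, seed, dt, record_every, meta,
                        theta_rest=rest_rec if bias_on else None)


def simulate_equilibrium(model: MechanismModel, duration: float,
                         dt: float = DEFAULT_DT, seed: int = 0,
                         record_every: int | None = None,
                         theta0: float | None = None) -> BDTrajectory:
    """Equilibrium overdamped Langevin dynamics (Euler-Maruyama).

    Per coordinate: ``x <- x - D * dU/dx * dt + sqrt(2 D dt) * xi`` with
    D = D_theta for theta (deg^2/s) and D_pawl for the deflections (nm^2/s);
    energies are in k_BT so no explicit temperature factor appears.
    Bit-reproducible for a given seed.
    """
    if theta0 is None:
        theta0 = docked_angle(model)
    return _run(model, duration, dt, seed, record_every, theta0, None)


def simulate_steered(model: MechanismModel, protocol: SteeredProtocol,
                     seed: int = 0, dt: float = DEFAULT_DT,
                     record_every: int | None = None,
                     theta0: float | None = None):
    """Steered rotation: a harmonic bias 1/2 k_spring wrapdiff(theta -
    theta_rest(t))^2 whose rest angle advances at ``protocol.rate``.

    Runs ``n_turns`` full revolutions in the + direction and again in the -
    direction; returns (forward, backward) trajectories.
    """
    if theta0 is None:
        theta0 = docked_angle(model)
    duration = protocol.n_turns * 360.0 / protocol.rate
    fwd = _run(model, duration, dt, seed, record_every, theta0, None,
               bias_on=True, k_spring=protocol.k_spring, rest0=theta0,
               rate=protocol.rate)
    bwd = _run(model, duration, dt, int(seed) + 1, record_every, theta0, None,
               bias_on=True, k_spring=protocol.k_spring, rest0=theta0,
               rate=-protocol.rate)
    return fwd, bwd


# --------------------------------------------------------------------------
# analysis of mechanism trajectories


@dataclass
class RotationCycleSummary:
    """Rotation-cycle averages: cam-to-subunit distances and pawl
    deflections binned by camshaft angle, with first-harmonic fits."""

    bin_centers: np.ndarray        # deg, 360/bin_width bins
    cam_unit_distance: np.ndarray  # (n_bins, n_units) nm
    pawl_deflection: np.ndarray    # (n_bins, n_pawls) nm
    amplitude: np.ndarray          # (n_units,) nm, first-harmonic amplitude
    phase: np.ndarray              # (n_units,) deg, angle of closest approach
    phase_offsets: np.ndarray      # (n_units,) deg, circular diff of adjacent units
    counts: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        cols = {"bin_center_deg": self.bin_centers}
        for u in range(self.cam_unit_distance.shape[1]):
            cols[f"dist_u{u + 1}"] = self.cam_unit_distance[:, u]
        for j in range(self.pawl_deflection.shape[1]):
            cols[f"defl_p{j + 1}"] = self.pawl_deflection[:, j]
        return pd.DataFrame(cols)


def _first_harmonic(theta_deg, y):
    """Least-squares fit y ~ a0 + a cos(theta) + b sin(theta); returns
    (amplitude, phase of minimum in degrees)."""
    th = np.radians(theta_deg)
    X = np.column_stack([np.ones_like(th), np.cos(th), np.sin(th)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    a, b = coef[1], coef[2]
    amp = float(np.hypot(a, b))
    # y is maximal at atan2(b, a); the cam is closest where y is minimal
    phase_min = wrap360(np.degrees(np.arctan2(b, a)) + 180.0)
    return amp, float(phase_min)


def cycle_average(traj, geometry: MechanismGeometry,
                  bin_width: float = 10.0) -> RotationCycleSummary:
    """Bin steered-rotation configurations by wrapped camshaft angle.

    ``traj`` may be one trajectory or a list (e.g. both steering
    directions).  Per bin, the Euclidean distance between the cam tip (at
    radius r0 + h, angle theta) and each unit's pawl midpoint (at radius
    r0 + mean pawl deflection, angle = unit center) is averaged, along with
    each pawl's deflection.  A first circular harmonic is fitted per unit;
    phase offsets are circular differences between adjacent units.
    """
    if 360.0 % bin_width:
        raise ValueError("bin_width must divide 360")
    trajs = traj if isinstance(traj, (list, tuple)) else [traj]
    theta = np.concatenate([t.theta_wrapped for t in trajs])
    d = np.concatenate([t.d for t in trajs], axis=0)

    n_bins = int(round(360.0 / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip((theta // bin_width).astype(int), 0, n_bins - 1)

    unit = geometry.pawl_unit
    r0, h = geometry.bore_radius, geometry.cam_height
    ucent = geometry.unit_centers

    n_units = geometry.n_units
    counts = np.bincount(idx, minlength=n_bins)
    defl = np.full((n_bins, geometry.n_pawls), np.nan)
    dist = np.full((n_bins, n_units), np.nan)

    cam_xy = (r0 + h) * np.column_stack([np.cos(np.radians(theta)),
                                         np.sin(np.radians(theta))])
    for u in range(n_units):
        du = d[:, unit == u].mean(axis=1)
        pw = np.column_stack([(r0 + du) * np.cos(np.radians(ucent[u])),
                              (r0 + du) * np.sin(np.radians(ucent[u]))])
        dd = np.hypot(*(cam_xy - pw).T)
        dist[:, u] = _binned_mean(idx, dd, n_bins)
    for j in range(geometry.n_pawls):
        defl[:, j] = _binned_mean(idx, d[:, j], n_bins)

    empty = counts == 0
    if empty.any():
        warnings.warn(f"{empty.sum()} empty angle bins; interpolating", stacklevel=2)
        for arr in (dist, defl):
            for c in range(arr.shape[1]):
                arr[empty, c] = np.interp(centers[empty], centers[~empty],
                                          arr[~empty, c], period=360.0)

    amp = np.empty(n_units)
    phase = np.empty(n_units)
    for u in range(n_units):
        amp[u], phase[u] = _first_harmonic(centers, dist[:, u])
    offsets = np.abs(wrapdiff(np.roll(phase, -1) - phase))
    return RotationCycleSummary(centers, dist, defl, amp, phase, offsets, counts)


def _binned_mean(idx, values, n_bins):
    s = np.bincount(idx, weights=values, minlength=n_bins)
    c = np.bincount(idx, minlength=n_bins).astype(float)
    with np.errstate(invalid="ignore"):
        return s / np.where(c > 0, c, np.nan)


@dataclass
class LandscapeProfile:
    """Adiabatic landscape U_eff(theta) = min_d U(theta, d)."""

    theta: np.ndarray
    U: np.ndarray            # kBT, shifted so min(U) = 0
    d_min: np.ndarray        # (n, n_pawls) minimizing deflections
    minima: np.ndarray       # deg, local minima positions
    barriers: np.ndarray     # kBT, barrier height after each minimum (circular)


def effective_landscape(model: MechanismModel, grid: float = 2.0) -> LandscapeProfile:
    """Minimize the potential over the pawl coordinates on a theta grid and
    locate wells and barriers."""
    if grid > 5.0:
        raise ValueError("grid resolution must be <= 5 degrees")
    thetas = np.arange(0.0, 360.0, grid)
    n = len(thetas)
    U = np.empty(n)
    dmin = np.empty((n, model.geometry.n_pawls))
    d_prev = None
    for i, th in enumerate(thetas):
        d_prev, U[i] = model.minimize_pawls(th, d_prev)
        dmin[i] = d_prev
    U = U - U.min()

    # local minima on the periodic profile: find basins with a minimum
    # prominence (ignores numerical ripple on plateaus), then place each
    # minimum at the circular midpoint of its flat bottom
    from scipy.signal import find_peaks

    tiled = np.concatenate([U, U, U])
    peaks, _ = find_peaks(-tiled, prominence=0.1)
    peaks = peaks[(peaks >= n) & (peaks < 2 * n)] - n
    minima = []
    for p in peaks:
        floor = U[p]
        lo = p
        while U[(lo - 1) % n] <= floor + 0.02 and (p - lo) < n:
            lo -= 1
        hi = p
        while U[(hi + 1) % n] <= floor + 0.02 and (hi - p) < n:
            hi += 1
        minima.append(wrap360(thetas[0] + 0.5 * (lo + hi) * grid))
    minima = np.unique(np.round(minima, 6))

    barriers = []
    if len(minima) >= 2:
        pos = np.searchsorted(thetas, minima)
        for a, b in zip(pos, np.roll(pos, -1)):
            seg = U[a:b] if a < b else np.concatenate([U[a:], U[:b]])
            floor = min(U[a], U[b % n])
            barriers.append(seg.max() - floor)
    return LandscapeProfile(thetas, U, dmin, minima, np.asarray(barriers))


@dataclass
class MobilityResult:
    """Effective rotational diffusion coefficient from the angular MSD."""

    D_eff: float             # deg^2/s
    ci: tuple                # bootstrap 95% interval
    stalled: bool
    n_hops: int
    lags: np.ndarray
    msd: np.ndarray


def count_slot_hops(theta_wrapped, slot_angles, capture: float = 15.0,
                    persist: int = 3):
    """Count transitions between slot basins with hysteresis: a hop is
    registered only when the angle stays within ``capture`` degrees of a
    new slot center for ``persist`` consecutive records."""
    slots = np.asarray(slot_angles)
    diffs = np.abs(wrapdiff(theta_wrapped[:, None] - slots[None, :]))
    nearest = np.argmin(diffs, axis=1)
    captured = diffs[np.arange(len(nearest)), nearest] < capture
    hops = 0
    current = None
    streak_lab = None
    streak = 0
    for lab, ok in zip(nearest, captured):
        if not ok:
            streak = 0
            streak_lab = None
            continue
        if lab == streak_lab:
            streak += 1
        else:
            streak_lab = lab
            streak = 1
        if streak >= persist and lab != current:
            if current is not None:
                hops += 1
            current = lab
    return hops


def mobility(model: MechanismModel, duration: float, seed: int = 0,
             dt: float = DEFAULT_DT, min_hops: int = 5,
             n_boot: int = 100, lag_range: tuple = (0.05, 0.5)) -> MobilityResult:
    """Effective rotational diffusion from an equilibrium run.

    Computes the time-lag MSD of the unwrapped angle and fits
    ``MSD = 2 D_eff t + b`` over lags in ``lag_range`` seconds (clipped to
    duration/20 so every lag averages many independent stretches; the
    intercept absorbs the intra-well plateau).  A block bootstrap over
    angular increments gives the confidence interval.  If fewer than
    ``min_hops`` inter-slot hops are observed the result is flagged
    'stalled' and D_eff is an upper bound.
    """
    traj = simulate_equilibrium(model, duration, dt=dt, seed=seed)
    theta = traj.theta
    rec_dt = traj.record_dt

    n = len(theta)
    hi = min(lag_range[1], duration / 20.0)
    lo = min(lag_range[0], hi / 4.0)
    lag_idx = np.unique(np.clip(
        np.linspace(lo / rec_dt, hi / rec_dt, 25).astype(int), 1, n - 2))
    msd = np.array([np.mean((theta[l:] - theta[:-l]) ** 2) for l in lag_idx])
    lags = lag_idx * rec_dt

    fit_mask = np.ones_like(lag_idx, dtype=bool)

    def fit_D(th):
        m = np.array([np.mean((th[l:] - th[:-l]) ** 2) for l in lag_idx[fit_mask]])
        A = np.column_stack([2.0 * lag_idx[fit_mask] * rec_dt, np.ones(fit_mask.sum())])
        coef, *_ = np.linalg.lstsq(A, m, rcond=None)
        return max(coef[0], 0.0)

    D = fit_D(theta)

    # block bootstrap over increments
    rng = np.random.default_rng(seed + 987654)
    n_blocks = 10
    block = (n - 1) // n_blocks
    incs = np.diff(theta)[: n_blocks * block].reshape(n_blocks, block)
    Ds = []
    for _ in range(n_boot):
        pick = rng.integers(0, n_blocks, n_blocks)
        th_b = np.concatenate([[0.0], np.cumsum(incs[pick].ravel())])
        Ds.append(fit_D(th_b))
    ci = (float(np.percentile(Ds, 2.5)), float(np.percentile(Ds, 97.5)))

    hops = count_slot_hops(traj.theta_wrapped, model.geometry.slot_angles)
    return MobilityResult(float(D), ci, hops < min_hops, hops, lags, msd)
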