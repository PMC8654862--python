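"""Numba kernels for the mechanism energy model and the Langevin integrator.

All energies are in units of k_BT, lengths in nm, angles in degrees and time
in seconds.  The kernels are deliberately free of Python objects: the model
is passed as a flat tuple of arrays assembled by :class:`camrotor.mechanics.
MechanismModel`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_PI = np.pi


@njit(cache=True, inline="always")
def _wrap360(x):
    return x - 360.0 * np.floor(x / 360.0)


@njit(cache=True, inline="always")
def _wrapdiff(x):
    """Map an angle difference into (-180, 180]."""
    y = x - 360.0 * np.floor(x / 360.0)
    if y > 180.0:
        y -= 360.0
    return y


@njit(cache=True, inline="always")
def _taper(x, w):
    """Cosine taper g with g(0)=1, g(+-w)=0, C1; returns (g, dg/dx)."""
    ax = abs(x)
    if ax >= w:
        return 0.0, 0.0
    s = _PI / w
    g = 0.5 * (1.0 + np.cos(s * x))
    dg = -0.5 * s * np.sin(s * x)
    return g, dg


@njit(cache=True, inline="always")
def _span(theta, a, arc, w):
    """Plateau of height 1 over the arc [a, a+arc] with cosine tapers of
    width w on either side; returns (S, dS/dtheta)."""
    v = _wrap360(theta - a)
    if v <= arc:
        return 1.0, 0.0
    e_end = v - arc          # distance past the end of the arc
    e_start = 360.0 - v      # distance before the start of the arc
    if e_end < e_start:
        if e_end >= w:
            return 0.0, 0.0
        s = _PI / w
        return 0.5 * (1.0 + np.cos(s * e_end)), -0.5 * s * np.sin(s * e_end)
    else:
        if e_start >= w:
            return 0.0, 0.0
        s = _PI / w
        return 0.5 * (1.0 + np.cos(s * e_start)), 0.5 * s * np.sin(s * e_start)


@njit(cache=True)
def energy_gradient(theta, d, phi, h_eff, steric_on, k_pawl, k_steric,
                    cam_h, cam_w, stack_on, stack_depth, stack_range,
                    pair_idx, pair_k, mwall_idx, mwall_span, fwall_span,
                    grad_d):
    """Potential energy and gradient of the camshaft/stator model.

    Returns (U, dU/dtheta) and fills grad_d (length 6) in place.
    """
    n = phi.shape[0]
    U = 0.0
    gt = 0.0
    for j in range(n):
        grad_d[j] = 0.0

    # pawl restoring springs + optional stacking well at d = 0
    inv_sr2 = 1.0 / (stack_range * stack_range) if stack_range > 0.0 else 0.0
    for j in range(n):
        U += 0.5 * k_pawl * d[j] * d[j]
        grad_d[j] += k_pawl * d[j]
        if stack_on and stack_depth > 0.0:
            e = np.exp(-d[j] * d[j] * inv_sr2)
            U -= stack_depth * e
            grad_d[j] += 2.0 * stack_depth * d[j] * inv_sr2 * e

    # per-pawl steric clearance (cam pushes the pawl outwards); spacer
    # linkages reduce the effective cam overlap h_eff for their pawls
    for j in range(n):
        if steric_on[j] == 0 or h_eff[j] <= 0.0:
            continue
        delta = _wrapdiff(theta - phi[j])
        g, dg = _taper(delta, cam_w)
        c = h_eff[j] * g
        if d[j] < c:
            r = c - d[j]
            U += 0.5 * k_steric * r * r
            grad_d[j] -= k_steric * r
            gt += k_steric * r * h_eff[j] * dg

    # pairwise difference couplings
    for p in range(pair_idx.shape[0]):
        j = pair_idx[p, 0]
        k = pair_idx[p, 1]
        r = d[j] - d[k]
        U += 0.5 * pair_k[p] * r * r
        grad_d[j] += pair_k[p] * r
        grad_d[k] -= pair_k[p] * r

    # movable struts spanning the gap of an intra-unit rigid pair:
    # the strut rides on the mean deflection of its two pawls
    for p in range(mwall_idx.shape[0]):
        j = mwall_idx[p, 0]
        k = mwall_idx[p, 1]
        S, dS = _span(theta, mwall_span[p, 0], mwall_span[p, 1], cam_w)
        c = cam_h * S
        m = 0.5 * (d[j] + d[k])
        if m < c:
            r = c - m
            U += 0.5 * k_steric * r * r
            grad_d[j] -= 0.5 * k_steric * r
            grad_d[k] -= 0.5 * k_steric * r
            gt += k_steric * r * cam_h * dS

    # immobile struts bridging the inter-unit interface (anchored to the
    # rigid bearing frame): pure theta-dependent barrier
    for p in range(fwall_span.shape[0]):
        S, dS = _span(theta, fwall_span[p, 0], fwall_span[p, 1], cam_w)
        c = cam_h * S
        U += 0.5 * k_steric * c * c
        gt += k_steric * c * cam_h * dS

    return U, gt


@njit(cache=True)
def integrate(theta0, d0, n_steps, dt, record_every, D_theta, D_pawl,
              bias_on, k_spring, rest0, rate, seed,
              phi, h_eff, steric_on, k_pawl, k_steric, cam_h, cam_w,
              stack_on, stack_depth, stack_range,
              pair_idx, pair_k, mwall_idx, mwall_span, fwall_span):
    """Euler-Maruyama integration of the overdamped Langevin dynamics.

    theta is evolved unwrapped.  Records every `record_every` steps
    (including step 0 and the final step).  Returns (theta_rec, d_rec,
    rest_rec, status) where status is -1 on success or the index of the
    first step at which a non-finite energy/force was found.
    """
    np.random.seed(seed)
    n = d0.shape[0]
    n_rec = n_steps // record_every + 1
    theta_rec = np.empty(n_rec)
    d_rec = np.empty((n_rec, n))
    rest_rec = np.empty(n_rec)

    theta = theta0
    d = d0.copy()
    grad_d = np.empty(n)

    amp_t = np.sqrt(2.0 * D_theta * dt)
    amp_d = np.sqrt(2.0 * D_pawl * dt)

    r = 0
    status = -1
    for step in range(n_steps + 1):
        t = step * dt
        theta_rest = rest0 + rate * t
        if step % record_every == 0:
            theta_rec[r] = theta
            d_rec[r, :] = d
            rest_rec[r] = theta_rest
            if not (np.isfinite(theta) and np.isfinite(d).all()):
                status = step
                break
            r += 1
        if step == n_steps:
            break

        U, gt = energy_gradient(theta, d, phi, h_eff, steric_on, k_pawl,
                                k_steric, cam_h, cam_w, stack_on,
                                stack_depth, stack_range, pair_idx, pair_k,
                                mwall_idx, mwall_span, fwall_span, grad_d)
        if bias_on:
            gt += k_spring * _wrapdiff(theta - theta_rest)

        theta += -D_theta * gt * dt + amp_t * np.random.normal()
        for j in range(n):
            d[j] += -D_pawl * grad_d[j] * dt + amp_d * np.random.normal()

    return theta_rec, d_rec, rest_rec, status
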