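"""End-to-end pipelines over synthetic data.

:func:`run_rotation_assay` reproduces the single-particle imaging analysis
(simulate rotors or hopping traces, render movies, screen std images,
track with VWCM, compute the angular statistics) and writes the summary
tables: orientation clusters, radius distribution, velocity histogram and
the ensemble RMSD(t) with its ``A sqrt(t)`` fit, together with
recovery-vs-ground-truth deltas.

:func:`run_variant_comparison` contrasts the six stator designs: the
equilibrium rotary mobility of each variant (with stall detection) and the
steered-rotation cycle summary (cam-to-subunit distance curves, pawl
deflections, first-harmonic amplitudes and adjacent-subunit phase
offsets).
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import angular as ang
from . import io as cio
from . import mechanics as mech
from . import movie as mv
from . import tracking as tk
from .config import RunConfig, substream_seed

__all__ = ["RunReport", "run_rotation_assay", "run_variant_comparison",
           "simulate_and_track_particles"]


@dataclass
class RunReport:
    config: dict
    timings: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    results: dict = field(default_factory=dict)

    def save(self, path):
        return cio.save_json(
            {"config": self.config, "timings": self.timings,
             "warnings": self.warnings, "results": self.results}, path)


def _particle_traces(cfg: RunConfig, n, duration):
    """Ground-truth angle traces for n rotary particles, either from the
    3-state hopping generator or from equilibrium mechanism runs."""
    traces = []
    if cfg.trace_source == "hopping":
        for i in range(n):
            tr, labels = mv.make_hopping_trace(
                cfg.hop_model, duration, cfg.optics.frame_interval,
                seed=substream_seed(cfg.seed, f"hop/{i}"))
            tr.meta["labels"] = labels
            traces.append(tr)
    elif cfg.trace_source == "mechanism":
        model = mech.build_mechanism(cfg.variant, cfg.geometry, cfg.params)
        for i in range(n):
            traj = mech.simulate_equilibrium(
                model, duration, seed=substream_seed(cfg.seed, f"bd/{i}"))
            traces.append(mv.trace_from_trajectory(traj, cfg.optics.frame_interval))
    else:
        raise ValueError(f"unknown trace_source: {cfg.trace_source!r}")
    return traces


def simulate_and_track_particles(cfg: RunConfig, n=None, duration=None,
                                 outdir=None):
    """Render one per-particle movie per trace, screen and track it.

    Returns a list of dicts with the trace, movie, candidate, and track of
    every particle whose std image yielded an accepted rotary candidate.
    """
    n = n or cfg.n_particles
    duration = duration or cfg.movie_duration
    traces = _particle_traces(cfg, n, duration)
    c = cfg.crop_size
    anchor = ((c - 1) / 2.0, (c - 1) / 2.0)
    out = []
    for i, tr in enumerate(traces):
        scene = mv.SceneSpec(field_size=(c, c),
                             particles=[mv.ParticleSpec(anchor)])
        stack = mv.render_movie([tr], scene, cfg.optics, cfg.camera,
                                seed=substream_seed(cfg.seed, f"render/{i}"))
        if outdir is not None:
            cio.save_movie(stack, Path(outdir) / f"particle_{i:03d}.tif")
        std = tk.std_image(stack)
        cands = tk.detect_and_classify(std, stack, cfg.detection)
        rotary = [cd for cd in cands if cd.accepted]
        if not rotary:
            out.append({"particle": i, "trace": tr, "movie": stack,
                        "candidate": None, "track": None})
            continue
        track = tk.track_particle(stack, rotary[0], cfg.tracking)
        track.particle_id = i
        out.append({"particle": i, "trace": tr, "movie": stack,
                    "candidate": rotary[0], "track": track})
    return out


def run_rotation_assay(cfg: RunConfig, outdir=None) -> RunReport:
    """Full imaging pipeline on synthetic rotary particles."""
    t0 = time.time()
    outdir = Path(outdir or cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=cfg.to_dict())

    tracked = simulate_and_track_particles(
        cfg, outdir=outdir if cfg.save_movies else None)
    report.timings["simulate_render_track"] = time.time() - t0
    ok = [r for r in tracked if r["track"] is not None]
    if not ok:
        report.warnings.append("no rotary particles detected")
        report.results["n_particles"] = 0
        report.save(outdir / "report.json")
        return report

    rows = []
    angle_traces = []
    radii_nm = []
    radii_weights = []
    all_wrapped = []
    for r in ok:
        track, trace = r["track"], r["trace"]
        try:
            fit = ang.fit_center(track)
        except ValueError as e:
            report.warnings.append(f"particle {r['particle']}: {e}")
            continue
        segs = ang.to_angle_trace(track, fit, cfg.optics.frame_interval)
        seg = max(segs, key=len)
        dist, mean_nm = ang.radius_distribution(track, fit, cfg.optics.pixel_size)
        cls = ang.classify_motion(seg, cfg.span_threshold, cfg.min_transitions)
        row = {"particle": r["particle"], "cx": fit.cx, "cy": fit.cy,
               "radius_px": fit.radius, "radius_nm": mean_nm,
               "classification": cls, "n_frames": len(track),
               "converged_fraction": float(track.converged.mean()),
               "rmsd_single_deg": ang.rmsd_single(seg)}
        try:
            sa = ang.cluster_states(seg, k=cfg.n_states,
                                    seed=substream_seed(cfg.seed, "cluster"))
            for j, (cc, occ) in enumerate(zip(sa.centers, sa.occupancies)):
                row[f"center_{j + 1}_deg"] = cc
                row[f"occupancy_{j + 1}"] = occ
        except (ValueError, RuntimeError) as e:
            report.warnings.append(f"particle {r['particle']}: clustering: {e}")
        # recovery deltas vs ground truth
        gt = r["movie"].ground_truth
        err = np.hypot(track.x - gt.x_px.values[: len(track)],
                       track.y - gt.y_px.values[: len(track)])[track.converged]
        row["median_tracking_error_px"] = float(np.median(err))
        row["radius_error_nm"] = mean_nm - r["movie"].meta["scene"].particles[0].lever_radius
        rows.append(row)
        angle_traces.append(seg)
        radii_nm.append(dist)
        radii_weights.append(len(dist))
        all_wrapped.append(seg.theta_wrapped)

    summary = pd.DataFrame(rows)
    summary.to_csv(outdir / "particles.csv", index=False)

    # ensemble statistics
    diff = ang.rmsd_ensemble(angle_traces)
    pd.DataFrame({"lag_s": diff.lags, "rmsd_deg": diff.rmsd}).to_csv(
        outdir / "rmsd_curve.csv", index=False)
    vel = ang.angular_velocities(angle_traces)
    pd.DataFrame({"omega_lo": vel.hist_edges[:-1], "omega_hi": vel.hist_edges[1:],
                  "density": vel.hist_density}).to_csv(
        outdir / "velocity_hist.csv", index=False)
    pooled = np.concatenate(all_wrapped)
    dens, edges = np.histogram(pooled, bins=72, range=(0, 360), density=True)
    pd.DataFrame({"theta_lo": edges[:-1], "theta_hi": edges[1:],
                  "density": dens}).to_csv(outdir / "orientation_density.csv",
                                           index=False)
    rad = np.concatenate(radii_nm)
    rdens, redges = np.histogram(rad, bins=60, density=True)
    pd.DataFrame({"radius_lo": redges[:-1], "radius_hi": redges[1:],
                  "density": rdens}).to_csv(outdir / "radius_hist.csv", index=False)

    pooled_sa = ang.cluster_states(pooled, k=cfg.n_states,
                                   seed=substream_seed(cfg.seed, "cluster/pooled"))
    seps = np.sort(mech.wrap360(np.diff(
        np.concatenate([pooled_sa.centers, [pooled_sa.centers[0] + 360]]))))

    w = np.asarray(radii_weights, float)
    weighted_radius = float(np.sum([d.sum() for d in radii_nm]) / w.sum())
    report.results = {
        "n_particles": len(rows),
        "n_rotary": int((summary.classification == "rotary").sum()),
        "weighted_mean_radius_nm": weighted_radius,
        "weighted_mean_omega_deg_s": vel.weighted_mean,
        "weighted_mean_omega_sem": vel.weighted_sem,
        "rmsd_A_deg_per_sqrt_s": diff.A,
        "rmsd_loglog_slope": diff.loglog_slope,
        "orientation_centers_deg": pooled_sa.centers.tolist(),
        "adjacent_separations_deg": seps.tolist(),
        "median_tracking_error_px": float(summary.median_tracking_error_px.median()),
    }
    report.timings["total"] = time.time() - t0
    report.save(outdir / "report.json")
    return report


def run_variant_comparison(cfg: RunConfig, outdir=None,
                           steered_variants=(1,)) -> RunReport:
    """Mobility of each design variant plus steered-rotation cycle
    summaries for ``steered_variants``."""
    t0 = time.time()
    outdir = Path(outdir or cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=cfg.to_dict())

    mob_rows = []
    for v in cfg.variants:
        model = mech.build_mechanism(v, cfg.geometry, cfg.params)
        res = mech.mobility(model, cfg.mobility_duration,
                            seed=substream_seed(cfg.seed, f"mobility/{v}"))
        mob_rows.append({"variant": v, "D_eff_deg2_s": res.D_eff,
                         "ci_lo": res.ci[0], "ci_hi": res.ci[1],
                         "n_hops": res.n_hops, "stalled": res.stalled})
        # RMSD(t) analog of the experimental per-variant curves
        traj = mech.simulate_equilibrium(
            model, cfg.mobility_duration,
            seed=substream_seed(cfg.seed, f"rmsdtrace/{v}"))
        trace = mv.trace_from_trajectory(traj, cfg.optics.frame_interval)
        diff = ang.rmsd_ensemble([trace])
        pd.DataFrame({"lag_s": diff.lags, "rmsd_deg": diff.rmsd}).to_csv(
            outdir / f"rmsd_variant_{v}.csv", index=False)
    mob = pd.DataFrame(mob_rows)
    mob.to_csv(outdir / "mobility.csv", index=False)
    report.timings["mobility"] = time.time() - t0

    cycles = {}
    for v in steered_variants:
        model = mech.build_mechanism(v, cfg.geometry, cfg.params)
        fwd, bwd = mech.simulate_steered(
            model, cfg.protocol, seed=substream_seed(cfg.seed, f"steer/{v}"))
        summary = mech.cycle_average([fwd, bwd], cfg.geometry,
                                     cfg.protocol.bin_width)
        summary.to_dataframe().to_csv(outdir / f"cycle_variant_{v}.csv",
                                      index=False)
        cycles[v] = {"amplitude_nm": summary.amplitude.tolist(),
                     "phase_deg": summary.phase.tolist(),
                     "phase_offsets_deg": summary.phase_offsets.tolist(),
                     "max_pawl_deflection_nm": float(np.nanmax(summary.pawl_deflection))}
    report.results = {
        "mobility": mob.to_dict(orient="records"),
        "stalled_variants": mob.loc[mob.stalled, "variant"].tolist(),
        "steered_cycles": cycles,
    }
    report.timings["total"] = time.time() - t0
    report.save(outdir / "report.json")
    return report
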