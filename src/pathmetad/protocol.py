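"""Run configuration and the end-to-end protocol driver.

The driver chains the whole workflow on a bead host--guest system:

    unbiased run -> harvest start states -> steered replicas along each
    channel -> pathway statistics and ranking -> reference path from the
    lowest-work replica of the preferred channel -> well-tempered
    metadynamics on the path CVs -> FES, 1D projection, binding free
    energy -> basins, per-basin GROMOS clusters, representative frames.

Configuration is a flat INI file (key = value sections) that round-trips
losslessly; defaults follow standard practice for path-CV unbinding runs
(hill height 1 kJ/mol, bias factor 10, deposition every 500 steps, sigma_s
0.05, sigma_z 0.007 nm^2, walls at s < 12 and z < 0.2 nm^2, pulling spring
10 kcal/mol/A^2).  Every applied value is logged so a run can be
reconstructed from its log.
"""

from __future__ import annotations

import configparser
import json
import logging
import math
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
import numpy as np

from . import io as pmio
from .units import NM2_TO_A2
from .toy_systems import (
    LangevinParams,
    harvest_start_states,
    make_host_guest,
    run_langevin,
)
from .smd import (
    AnchorDistanceCV,
    SMDProtocol,
    compare_pathways,
    pathway_stats,
    run_smd_replicas,
)
from .pathcv import (
    PathCVMapping,
    build_reference_path,
    rmsd_matrix,
)
from .wtmetad import (
    WallSpec,
    WTParams,
    binding_free_energy,
    convergence_series,
    project_fes_1d,
    reconstruct_fes,
    run_wt_metad,
    sigma_from_unbiased,
)
from .fes_analysis import (
    assign_frames,
    find_minima,
    gromos_cluster,
    representative_structure,
)

log = logging.getLogger("pathmetad")


@dataclass
class RunConfig:
    """Flat configuration for one protocol run (internal units unless the
    field name says otherwise)."""

    # system
    barrier_channel1: float = 6.0
    barrier_channel2: float = 10.0
    cavity_depth: float = 8.0
    ring_radius: float = 6.0

    # dynamics
    dt: float = 0.005
    friction: float = 1.0
    temperature: float = 300.0

    # unbiased run + start-state harvesting
    unbiased_steps: int = 200_000
    n_starts: int = 10
    harvest_stride_time: float = 5.0
    harvest_tail_fraction: float = 0.5

    # steered replicas
    spring_k: float = 10.0
    pull_distance: float = 8.0    # radial distance the guest is pulled outward, A
    smd_duration: float = 50.0
    smd_sample_stride: int = 10

    # reference path
    path_spacing: float = 1.2
    n_smd_frames: int = 6
    n_interp: int = 5

    # metadynamics
    metad_steps: int = 1_200_000
    w0_kj: float = 4.0
    bias_factor: float = 10.0
    deposition_stride: int = 500
    sigma_s: float = 0.05
    sigma_z_nm2: float = 0.007
    sigma_mode: str = "unbiased"     # "config" | "unbiased" (1/3-sd rule)
    s_max: float = 12.0
    z_max_nm2: float = 0.1
    kappa_z_nm4: float = 5000.0

    # analysis
    bound_s_min: float = 1.0
    bound_s_max: float = 3.0
    unbound_s_min: float = 7.0
    min_basin_depth: float = 1.5
    cluster_cutoff: float = 2.0
    frame_stride_ps: float = 10.0

    # bookkeeping
    seed: int = 1
    outdir: str = "runs/protocol"

    _SECTIONS = {
        "system": ["barrier_channel1", "barrier_channel2", "cavity_depth", "ring_radius"],
        "dynamics": ["dt", "friction", "temperature"],
        "unbiased": ["unbiased_steps", "n_starts", "harvest_stride_time",
                     "harvest_tail_fraction"],
        "smd": ["spring_k", "pull_distance", "smd_duration", "smd_sample_stride"],
        "path": ["path_spacing", "n_smd_frames", "n_interp"],
        "metad": ["metad_steps", "w0_kj", "bias_factor", "deposition_stride",
                  "sigma_s", "sigma_z_nm2", "sigma_mode", "s_max", "z_max_nm2",
                  "kappa_z_nm4"],
        "analysis": ["bound_s_min", "bound_s_max", "unbound_s_min",
                     "min_basin_depth", "cluster_cutoff", "frame_stride_ps"],
        "run": ["seed", "outdir"],
    }

    def to_file(self, path):
        cp = configparser.ConfigParser()
        for section, keys in self._SECTIONS.items():
            cp[section] = {k: repr(getattr(self, k)) if not isinstance(getattr(self, k), str)
                           else getattr(self, k) for k in keys}
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        cp = configparser.ConfigParser()
        read = cp.read(path)
        if not read:
            raise FileNotFoundError(path)
        types = {f.name: f.type for f in dc_fields(cls)}
        kwargs = {}
        for section in cp.sections():
            for key, raw in cp[section].items():
                if key not in types:
                    raise ValueError(f"unknown config key '{key}' in [{section}]")
                t = types[key]
                kwargs[key] = raw if t == "str" or t is str else (
                    int(raw) if t in ("int", int) else float(raw))
        return cls(**kwargs)

    def log_all(self):
        for section, keys in self._SECTIONS.items():
            for k in keys:
                log.info("config [%s] %s = %s", section, k, getattr(self, k))


class StageError(RuntimeError):
    """A protocol stage failed; the message names the stage."""


@dataclass
class ProtocolReport:
    config: RunConfig
    pathway_table: dict              # channel -> PathwayStats
    comparison: object
    preferred_channel: str
    path_n_frames: int
    path_lambda: float
    gullwing_ok: bool
    n_hills: int
    delta_f_bind: float
    plateau_sd: float
    convergence_times: np.ndarray
    convergence_df: np.ndarray
    basin_table: list                # (label, s, z, depth, n_frames, n_clusters)

    def to_dict(self) -> dict:
        d = {
            "preferred_channel": self.preferred_channel,
            "pathways": {
                name: {
                    "W_min": round(s.w_min, 6), "W_max": round(s.w_max, 6),
                    "F_max_pN": round(s.f_max_pN, 6),
                    "dF_unbind": round(s.df_unbind, 6),
                    "work_sd": round(s.work_sd, 6), "n": s.n_replicas,
                }
                for name, s in self.pathway_table.items()
            },
            "path": {"n_frames": self.path_n_frames,
                     "lambda_A-2": round(self.path_lambda, 6),
                     "gullwing_ok": bool(self.gullwing_ok)},
            "metad": {"n_hills": self.n_hills},
            "delta_f_bind": round(self.delta_f_bind, 6),
            "plateau_sd": round(self.plateau_sd, 6),
            "basins": [
                {"label": b[0], "s": round(b[1], 4), "z_A2": round(b[2], 4),
                 "depth": round(b[3], 4), "n_frames": b[4], "n_clusters": b[5]}
                for b in self.basin_table
            ],
        }
        return d

    def to_text(self) -> str:
        lines = [self.comparison.to_text(), ""]
        lines.append(f"preferred channel: {self.preferred_channel}")
        lines.append(
            f"reference path: {self.path_n_frames} frames, "
            f"lambda = {self.path_lambda:.4f} A^-2, "
            f"gull-wing diagnostic {'passed' if self.gullwing_ok else 'FAILED'}"
        )
        lines.append(f"hills deposited: {self.n_hills}")
        lines.append(
            f"dF_bind = {self.delta_f_bind:.2f} kcal/mol "
            f"(unbound plateau sd {self.plateau_sd:.2f})"
        )
        lines.append("basins:")
        for label, s, z, depth, nf, nc in self.basin_table:
            lines.append(
                f"  {label}: s = {s:.2f}, z = {z:.2f} A^2, "
                f"F = {depth:.2f} kcal/mol, frames = {nf}, clusters = {nc}"
            )
        return "\n".join(lines)


def run_protocol(config: RunConfig, write_outputs: bool = True) -> ProtocolReport:
    """Execute the full steered-MD + path-CV metadynamics protocol."""
    cfg = config
    cfg.log_all()
    outdir = Path(cfg.outdir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
        cfg.to_file(outdir / "config.ini")

    stage = "build system"
    try:
        system = make_host_guest(
            cfg.barrier_channel1, cfg.barrier_channel2, cfg.cavity_depth,
            ring_radius=cfg.ring_radius,
        )
        names = pmio.frame_names_for_system(system)

        stage = "unbiased run"
        lp = LangevinParams(dt=cfg.dt, friction=cfg.friction,
                            temperature=cfg.temperature, seed=cfg.seed)
        unbiased = run_langevin(system, lp, cfg.unbiased_steps, sample_stride=10)
        starts = harvest_start_states(
            unbiased, cfg.n_starts, cfg.harvest_stride_time,
            cfg.harvest_tail_fraction,
        )

        stage = "steered replicas"
        stats, lowest_work_traj = {}, {}
        for ci, channel in enumerate(sorted(system.channel_definitions)):
            anchor = system.channel_anchor(channel)
            cv = AnchorDistanceCV(anchor)
            cv0 = float(np.linalg.norm(np.zeros(2) - anchor))
            prot = SMDProtocol(
                cv=cv, cv_start=cv0, cv_end=cv0 + cfg.pull_distance,
                duration=cfg.smd_duration, spring_k=cfg.spring_k,
                n_replicas=cfg.n_starts,
            )
            rp = LangevinParams(dt=cfg.dt, friction=cfg.friction,
                                temperature=cfg.temperature,
                                seed=cfg.seed + 1000 * (ci + 1))
            trajs, profiles = run_smd_replicas(
                system, prot, starts, rp, sample_stride=cfg.smd_sample_stride)
            stats[channel] = pathway_stats(profiles, cfg.temperature)
            best = int(np.argmin([p.final_work for p in profiles]))
            lowest_work_traj[channel] = trajs[best]
            if write_outputs:
                for i, p in enumerate(profiles):
                    pmio.write_work_profile(outdir / f"COLVAR_smd_{channel}_{i}", p)

        stage = "pathway comparison"
        comparison = compare_pathways(stats)
        preferred = comparison.preferred or min(
            stats, key=lambda n: stats[n].w_min)

        stage = "reference path"
        seed_traj = lowest_work_traj[preferred]
        direction = system.channel_definitions[preferred].direction
        bulk = direction * (cfg.ring_radius + 4.0)
        end_frame = seed_traj.frame_coords(len(seed_traj) - 1).copy()
        n_host = len(system.host_coords)
        end_frame[n_host] = [bulk[0], bulk[1], 0.0]
        align_sel = np.arange(n_host)
        dist_sel = np.array([n_host])
        # keep only snapshots that advance the unbinding progress (new record
        # of the pulling distance) up to just outside the cavity mouth, and
        # smooth lightly, so thermal wobble does not contaminate the frame set
        anchor = system.channel_anchor(preferred)
        guests = []
        best_cv = -math.inf
        for i in range(len(seed_traj)):
            g = seed_traj.positions[i][:2]
            d = float(np.linalg.norm(g - anchor))
            if d > best_cv:
                best_cv = d
                guests.append(g)
                if float(np.linalg.norm(g)) > cfg.ring_radius + 2.0:
                    break
        guests = np.asarray(guests)
        w = 5
        smoothed = np.array([guests[max(0, i - w // 2): i + w // 2 + 1].mean(axis=0)
                             for i in range(len(guests))])
        base = seed_traj.frame_coords(0)
        seed_frames = []
        for g in smoothed:
            f = base.copy()
            f[n_host] = [g[0], g[1], 0.0]
            seed_frames.append(f)
        path = build_reference_path(
            seed_frames, cfg.path_spacing, cfg.n_smd_frames, end_frame,
            cfg.n_interp, align_sel, dist_sel,
        )
        matrix, gullwing_ok = rmsd_matrix(path, tolerance=0.2)
        if write_outputs:
            pmio.write_xyz(outdir / "reference_path.xyz", path.frames, names)
            pmio.write_pdb(outdir / "reference_path.pdb", path.frames, names)
            np.savetxt(outdir / "rmsd_matrix.csv", matrix, delimiter=",")
            (outdir / "reference_path.json").write_text(json.dumps({
                "n_frames": path.n_frames,
                "n_smd_frames": path.n_smd_frames,
                "spacing_target_A": path.spacing_target,
                "lambda_A-2": path.lambda_,
                "align_selection": path.align_selection.tolist(),
                "distance_selection": path.distance_selection.tolist(),
            }, indent=2) + "\n")

        stage = "metadynamics"
        sigma_s, sigma_z = cfg.sigma_s, cfg.sigma_z_nm2 * NM2_TO_A2
        if cfg.sigma_mode == "unbiased":
            mapping = PathCVMapping(path, system)
            sub = unbiased.positions[len(unbiased) // 2::5]
            series = np.array([mapping.evaluate(x)[:2] for x in sub])
            sigma_s, sigma_z = sigma_from_unbiased(series)
            log.info("widths from unbiased run: sigma_s=%.4f sigma_z=%.4f A^2",
                     sigma_s, sigma_z)
        wt = WTParams(
            w0=cfg.w0_kj * 0.239005736, bias_factor=cfg.bias_factor,
            deposition_stride=cfg.deposition_stride,
            sigma_s=sigma_s, sigma_z=sigma_z, temperature=cfg.temperature,
        )
        walls = WallSpec(s_max=cfg.s_max, z_max=cfg.z_max_nm2 * NM2_TO_A2,
                         kappa_z=cfg.kappa_z_nm4 / NM2_TO_A2**2)
        mp = LangevinParams(dt=cfg.dt, friction=cfg.friction,
                            temperature=cfg.temperature, seed=cfg.seed + 9000)
        run = run_wt_metad(system, path, wt, walls, mp, cfg.metad_steps)
        if not run.hills:
            raise StageError("metadynamics deposited no hills")
        if write_outputs:
            pmio.write_hills(outdir / "HILLS", run.hills, cfg.bias_factor)
            pmio.write_colvar(outdir / "COLVAR", run.colvar)

        stage = "free-energy surface"
        z_floor = -math.log(path.n_frames) / path.lambda_
        grid = (np.linspace(1.0, min(cfg.s_max, path.n_frames), 200),
                np.linspace(z_floor, 1.2 * walls.z_max, 200))
        fes = reconstruct_fes(run.hills, grid, cfg.temperature, cfg.bias_factor)
        profile = project_fes_1d(fes)
        bfe = binding_free_energy(
            profile,
            bound_region=(cfg.bound_s_min, cfg.bound_s_max),
            unbound_region=(cfg.unbound_s_min, math.inf),
        )
        ck_t, ck_df, hill_t, hill_h = convergence_series(
            run.hills, max(1, len(run.hills) // 40), grid,
            cfg.temperature, cfg.bias_factor,
            (cfg.bound_s_min, cfg.bound_s_max), (cfg.unbound_s_min, math.inf),
        )

        stage = "basins and clusters"
        basins = find_minima(fes, cfg.min_basin_depth)
        basins = assign_frames(run.colvar, basins, fes, stride=cfg.frame_stride_ps)
        basin_table = []
        for b in basins:
            n_clusters = 0
            if b.member_frames:
                frames = [system.frame_coords(run.positions[i])
                          for i in b.member_frames]
                clusters = gromos_cluster(
                    frames, cfg.cluster_cutoff,
                    distance_selection=[n_host],
                )
                n_clusters = len(clusters)
                if write_outputs:
                    idx, rep = representative_structure(b, clusters, frames)
                    pmio.write_xyz(
                        outdir / f"representative_{b.label}.xyz", [rep], names)
            basin_table.append((
                b.label, b.location[0], b.location[1], b.depth,
                len(b.member_frames), n_clusters,
            ))
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"protocol stage '{stage}' failed: {exc}") from exc

    report = ProtocolReport(
        config=cfg,
        pathway_table=stats,
        comparison=comparison,
        preferred_channel=preferred,
        path_n_frames=path.n_frames,
        path_lambda=path.lambda_,
        gullwing_ok=gullwing_ok,
        n_hills=len(run.hills),
        delta_f_bind=bfe.value,
        plateau_sd=bfe.plateau_sd,
        convergence_times=ck_t,
        convergence_df=ck_df,
        basin_table=basin_table,
    )
    if write_outputs:
        (outdir / "report.txt").write_text(report.to_text() + "\n")
        (outdir / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2) + "\n")
    return report
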