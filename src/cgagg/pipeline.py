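"""End-to-end analysis pipeline and fixture builder.

``run_pipeline`` chains the analysis stages — cluster detection, residue
contact map, lateral diffusion, ΔSASA, lipid-domain statistics — over one
trajectory and emits a machine-readable JSON report plus TSV artifacts.
All randomness flows from the single config seed; two runs with the same
config produce byte-identical reports.

``make_fixture`` materializes a self-contained synthetic dataset (GRO
trajectory + topology TSV + ground-truth JSON) at a CI-friendly ("tiny")
or reference-system ("paper_scale") size.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import clustering, contacts, dynamics, sasa as sasa_mod, synth
from .core import (
    AnalysisWindow,
    Topology,
    Trajectory,
    TrajectoryFrame,
    read_gro,
    read_topology_table,
    write_gro,
    write_topology_table,
)

__all__ = ["RunConfig", "run_pipeline", "make_fixture", "load_config",
           "validate_report", "REPORT_SCHEMA_VERSION"]

log = logging.getLogger("cgagg.pipeline")

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Pipeline configuration: either input files or generator settings."""

    outdir: str = "cgagg_out"
    seed: int = 0
    # input files; when absent, a synthetic trajectory is generated
    traj_path: str | None = None
    topo_path: str | None = None
    # generator settings (used when no input files are given)
    n_proteins: int = 8
    n_residues: int = 186
    n_frames: int = 200
    n_lipid_beads: int = 2000
    d_free: float = 10.5
    dt: float = 4.0
    box_xy: tuple[float, float] = (22.0, 23.0)
    bind_radius: float = 2.3
    # analysis settings
    cutoff: float = clustering.DEFAULT_CONTACT_CUTOFF_NM
    dwell: int = 5
    probe: float = sasa_mod.DEFAULT_PROBE_NM
    burial_threshold: float = sasa_mod.DEFAULT_BURIAL_THRESHOLD_NM2
    sasa_points: int = 240
    sasa_frames_per_window: int = 2
    contact_window_frames: int = 50
    msd_fit: tuple[float, float] | None = None

    def validate(self) -> "RunConfig":
        for p in (self.traj_path, self.topo_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input path {p} does not exist")
        if (self.traj_path is None) != (self.topo_path is None):
            raise ValueError("traj_path and topo_path must be given together")
        return self


def load_config(path) -> RunConfig:
    """Read a flat TOML config; unknown keys are rejected."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "msd_fit" in data and data["msd_fit"] is not None:
        data["msd_fit"] = tuple(data["msd_fit"])
    return RunConfig(**data)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def _build_synthetic(n_proteins: int, n_residues: int, n_frames: int,
                     n_lipid_beads: int, d_free: float, dt: float,
                     seed: int, box_xy: tuple[float, float] = (44.0, 46.0),
                     bind_radius: float = 2.3,
                     ) -> tuple[Trajectory, Topology, synth.GroundTruth]:
    """Sticky-aggregation proteins over a progressively de-mixing lipid field.

    The default sticking radius (2.3 nm center-to-center) is blob-aware:
    at that separation the discrete bead shells of two 1-nm-radius blobs
    are reliably within the 0.75 nm bead contact criterion, so detected
    clusters track the generator's merges.
    """
    sim_cfg = synth.StickySimConfig(
        n_proteins=n_proteins, n_residues=n_residues, d_free=d_free,
        dt=dt, n_steps=n_frames - 1, seed=seed, box_xy=tuple(box_xy),
        bind_radius=bind_radius)
    traj, truth = synth.simulate_sticky_brownian(sim_cfg)

    total = max(n_lipid_beads, 0)
    n_dppc = int(round(total * 3480 / 7320))
    n_dlipc = int(round(total * 2304 / 7320))
    n_chol = total - n_dppc - n_dlipc
    frames = []
    topo = traj.topology
    lipid_topo = None
    for k, fr in enumerate(traj):
        if total:
            lip_cfg = synth.DomainFieldConfig(
                n_dppc=n_dppc, n_dlipc=n_dlipc, n_chol=n_chol,
                box_xy=tuple(box_xy), seed=seed + 10_000 + k)
            progress = k / max(n_frames - 1, 1)
            lip_frame, lipid_topo = synth.generate_domain_field(
                lip_cfg, progress, first_molecule_id=n_proteins)
            pos = np.vstack([fr.positions, lip_frame.positions])
        else:
            pos = fr.positions
        frames.append(TrajectoryFrame(time=fr.time, box=fr.box, positions=pos))
    full_topo = Topology.concatenate([topo, lipid_topo]) if lipid_topo \
        else topo
    return Trajectory(frames, full_topo), full_topo, truth


FIXTURE_PROFILES = {
    "tiny": dict(n_proteins=8, n_residues=186, n_frames=200,
                 n_lipid_beads=2000, box_xy=(22.0, 23.0)),
    "paper_scale": dict(n_proteins=32, n_residues=186, n_frames=250,
                        n_lipid_beads=7320, box_xy=(44.0, 46.0)),
}


def make_fixture(profile: str, outdir, seed: int = 0) -> Path:
    """Write a synthetic dataset (traj.gro, topology.tsv, truth.json)."""
    if profile not in FIXTURE_PROFILES:
        raise ValueError(f"unknown fixture profile {profile!r}; "
                         f"choose from {sorted(FIXTURE_PROFILES)}")
    params = FIXTURE_PROFILES[profile]
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    traj, topo, truth = _build_synthetic(
        d_free=10.5, dt=4.0, seed=seed, **params)
    write_gro(out / "traj.gro", traj.frames,
              resid=topo.molecule_id + 1,
              resname=np.char.add(
                  np.where(topo.is_protein, "PRO", ""),
                  np.where(topo.is_protein, "", topo.molecule_type)),
              atomname=np.where(topo.is_backbone, "BB", "CG"))
    write_topology_table(topo, out / "topology.tsv")
    truth.to_json(out / "truth.json")
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _stage(report: dict, manifest: list, name: str):
    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is None:
                manifest.append({"stage": name, "status": "ok"})
                log.info("stage %s: done", name)
            else:
                manifest.append({"stage": name, "status": "failed",
                                 "error": str(exc)})
            return False
    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Run every analysis stage on one trajectory; return the report dict.

    Writes ``report.json``, per-stage TSVs and a MANIFEST to the configured
    output directory.  A stage failure aborts the run with the stage named
    in the exception; partial outputs stay on disk with the MANIFEST
    recording the incomplete state.
    """
    cfg = config.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": cfg.seed,
        "parameters": {k: v for k, v in asdict(cfg).items()},
    }

    try:
        with _stage(report, manifest, "load"):
            if cfg.traj_path is not None:
                topo = read_topology_table(cfg.topo_path)
                _, frames = read_gro(cfg.traj_path)
                traj = Trajectory(frames, topo)
            else:
                traj, topo, _ = _build_synthetic(
                    cfg.n_proteins, cfg.n_residues, cfg.n_frames,
                    cfg.n_lipid_beads, cfg.d_free, cfg.dt, cfg.seed,
                    box_xy=cfg.box_xy, bind_radius=cfg.bind_radius)
            times = traj.times
            report["n_frames"] = len(traj)
            report["n_beads"] = topo.n_beads

        crit = clustering.ContactCriterion(cutoff=cfg.cutoff)
        with _stage(report, manifest, "clusters"):
            series = clustering.cluster_timeseries(traj, topo, crit)
            agg_t = clustering.aggregation_time(series, dwell=cfg.dwell)
            _write_tsv(out / "clusters.tsv",
                       ["time_ns", "n_clusters", "largest_size"],
                       zip(series.times, series.n_clusters,
                           series.largest_size))
            report["clusters"] = {
                "n_clusters": series.n_clusters.tolist(),
                "final_count": int(series.n_clusters[-1]),
                "aggregation_time_ns":
                    agg_t if isinstance(agg_t, str) else float(agg_t),
            }

        with _stage(report, manifest, "contacts"):
            k0 = max(0, len(traj) - cfg.contact_window_frames)
            win = AnalysisWindow(times[k0], times[-1]) if len(traj) > 1 \
                else None
            acc = contacts.accumulate_residue_contacts(traj, topo, crit,
                                                       window=win)
            pmap = contacts.contact_probability(acc, window=win,
                                                criterion=crit)
            top = contacts.high_contact_pairs(pmap)
            _write_tsv(out / "high_p_pairs.tsv", ["res_i", "res_j", "P"], top)
            report["contacts"] = {
                "n_frames": acc.F,
                "total_per_frame": acc.total_per_frame(),
                "max_P": float(pmap.P.max()),
                "n_high_P_pairs": len(top),
            }

        with _stage(report, manifest, "diffusion"):
            tracks = dynamics.unwrap_trajectory(traj, topo, "protein")
            half = times[0] + (times[-1] - times[0]) / 2
            results = {}
            for name, win in (("early", AnalysisWindow(times[0], half)),
                              ("late", AnalysisWindow(half, times[-1]))):
                prof = dynamics.msd_profile(tracks, window=win)
                est = dynamics.fit_diffusion(prof, cfg.msd_fit,
                                             tracks=tracks.window(win))
                results[name] = {"D_1e-8_cm2_s": est.D, "stderr": est.stderr}
            prof_full = dynamics.msd_profile(tracks)
            _write_tsv(out / "msd.tsv", ["lag_ns", "msd_nm2", "n_origins"],
                       zip(prof_full.lag_times, prof_full.msd,
                           prof_full.n_origins))
            report["diffusion"] = results

        with _stage(report, manifest, "sasa"):
            dt = traj.spacing if len(traj) > 1 else cfg.dt
            span = dt * (cfg.sasa_frames_per_window - 1) if \
                cfg.sasa_frames_per_window > 1 else dt / 2
            early_w = AnalysisWindow(times[0], times[0] + span)
            late_w = AnalysisWindow(times[-1] - span, times[-1])
            early = sasa_mod.residue_sasa_window(
                traj, topo, early_w, probe=cfg.probe, spacing=dt,
                n_points=cfg.sasa_points)
            late = sasa_mod.residue_sasa_window(
                traj, topo, late_w, probe=cfg.probe, spacing=dt,
                n_points=cfg.sasa_points)
            delta = sasa_mod.delta_sasa(early, late,
                                        burial_threshold=cfg.burial_threshold)
            buried = sasa_mod.buried_residues(delta)
            _write_tsv(out / "dsasa.tsv",
                       ["residue", "sasa_early", "sasa_late", "delta",
                        "buried_flag"],
                       zip(delta.residues, early.values, late.values,
                           delta.delta,
                           (delta.burial > cfg.burial_threshold).astype(int)))
            report["sasa"] = {
                "n_buried": len(buried),
                "buried_residues": [r for r, _ in buried],
                "mean_delta": float(delta.delta.mean()),
            }

        with _stage(report, manifest, "domains"):
            has_lipids = bool(np.any(topo.lipid_mask()))
            if has_lipids and len(traj) >= 2:
                k0 = max(0, len(traj) - cfg.contact_window_frames)
                win = AnalysisWindow(times[k0], times[-1])
                stats = contacts.domain_preference_ratio(
                    traj, topo, window=win, cutoff=cfg.cutoff)
                demix = contacts.demixing_contact_ratio(traj, topo,
                                                        cutoff=cfg.cutoff)
                demix.to_csv(out / "demixing.tsv", sep="\t", index=False)
                first = demix[demix.time == demix.time.min()]["ratio"].mean()
                last = demix[demix.time == demix.time.max()]["ratio"].mean()
                report["domains"] = {
                    "ratio_dppc_dlipc": stats.ratio_dppc_dlipc,
                    "stderr": stats.stderr,
                    "mean_counts": stats.mean_counts,
                    "demix_ratio_first": float(first),
                    "demix_ratio_last": float(last),
                }
            else:
                report["domains"] = None
    finally:
        with open(out / "MANIFEST.json", "w") as fh:
            json.dump({"complete": all(s["status"] == "ok" for s in manifest)
                       and len(manifest) == 6,
                       "stages": manifest}, fh, indent=1, sort_keys=True)

    validate_report(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, allow_nan=True)
    return report


def _write_tsv(path, header, rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# report schema
# ---------------------------------------------------------------------------

def _schema_path() -> Path:
    return Path(__file__).resolve().parent / "report.schema.json"


def validate_report(report: dict, schema: dict | None = None) -> None:
    """Structural check of a pipeline report against the packaged schema.

    Supports the subset of JSON-schema used there: type, properties,
    required, items.  Raises ValueError on the first violation.
    """
    if schema is None:
        with open(_schema_path()) as fh:
            schema = json.load(fh)

    def check(node, sch, path="$"):
        t = sch.get("type")
        type_map = {"object": dict, "array": list, "string": str,
                    "integer": int, "number": (int, float),
                    "boolean": bool}
        if t is not None:
            if t == "null":
                if node is not None:
                    raise ValueError(f"{path}: expected null")
            elif isinstance(t, list):
                ok = any(node is None if x == "null"
                         else isinstance(node, type_map[x]) for x in t)
                if not ok:
                    raise ValueError(f"{path}: expected one of {t}")
            elif not isinstance(node, type_map[t]) or (
                    t in ("integer",) and isinstance(node, bool)):
                raise ValueError(f"{path}: expected {t}, got "
                                 f"{type(node).__name__}")
        for key in sch.get("required", []):
            if not isinstance(node, dict) or key not in node:
                raise ValueError(f"{path}: missing required key {key!r}")
        for key, sub in sch.get("properties", {}).items():
            if isinstance(node, dict) and key in node and node[key] is not None:
                check(node[key], sub, f"{path}.{key}")
        if "items" in sch and isinstance(node, list):
            for i, item in enumerate(node):
                check(item, sch["items"], f"{path}[{i}]")

    check(report, schema)
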