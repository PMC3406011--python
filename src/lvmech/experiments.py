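"""Experiment orchestration: configured end-to-end runs and run comparison.

A run executes: mesh construction -> initial fiber field -> passive
inflation to the venous filling pressure -> fixed-fiber cardiac cycles to
hemodynamic steady state -> adaptation cycles with per-cycle fiber
reorientation -> postprocessing.  Outputs under the run directory:

    manifest.json       full configuration echo + provenance summary
    hemodynamics.csv    per-step hemodynamic state of every simulated cycle
    adaptation.csv      per-cycle local/global function metrics
    torsion.csv         section torsion traces before/after adaptation
    fibers.csv          nodal (u, v, alpha_h, alpha_t), initial and final
    solver_log.csv      per-cycle Newton iteration statistics
    checkpoint.json     full state after every cycle (run_experiment(...,
                        resume=True) continues an interrupted run from it)
    fields/*.vtu        optional mesh/fiber/displacement snapshots
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np
import pandas as pd

from . import __version__
from .circulation import CirculationState
from .config import RunConfig, preset, to_dict
from .fibers import build_fiber_field
from .geometry import build_mesh
from .postprocess import TorsionTrace, default_slice_levels, torsion, write_torsion_csv
from .reorientation import AdaptationHistory, run_adaptation
from .solver import CycleState, FEModel, initialize_diastolic_state, run_cardiac_cycle


class ExperimentError(RuntimeError):
    pass


@dataclasses.dataclass
class RunResult:
    config: RunConfig
    outdir: pathlib.Path
    history: AdaptationHistory
    hemo_cycles: list[CycleState]
    torsion_before: TorsionTrace
    torsion_after: TorsionTrace
    model: FEModel
    circulation: CirculationState


def _hemo_frame(cycles: list[CycleState], labels: list[str]) -> pd.DataFrame:
    frames = []
    for lab, cyc in zip(labels, cycles):
        n = cyc.t.size
        frames.append(pd.DataFrame({
            "cycle": lab, "t_ms": cyc.t, "p_lv_kpa": cyc.p_lv, "v_lv_ml": cyc.V_lv,
            "p_art_kpa": cyc.p_art, "p_ven_kpa": cyc.p_ven,
            "q_mitral_ml_ms": np.concatenate([[0.0], cyc.q_mitral]),
            "q_aortic_ml_ms": np.concatenate([[0.0], cyc.q_aortic]),
            "phase": ["-"] + [p.value for p in cyc.phase],
        }))
    return pd.concat(frames, ignore_index=True)


def _adaptation_frame(history: AdaptationHistory) -> pd.DataFrame:
    rows = []
    for r in history.records:
        rows.append({"cycle": r.cycle,
                     "eps_ic_mean": r.eps_ic_mean, "eps_ic_sd": r.eps_ic_sd,
                     "eps_ej_mean": r.eps_ej_mean, "eps_ej_sd": r.eps_ej_sd,
                     "eps_ir_mean": r.eps_ir_mean, "eps_ir_sd": r.eps_ir_sd,
                     "wf_mean": r.wf_mean, "wf_sd": r.wf_sd,
                     "p_lv_max": r.p_lv_max, "stroke_volume": r.stroke_volume})
    return pd.DataFrame(rows)


def _serialize_record(r) -> dict:
    d = {k: float(getattr(r, k)) for k in [
        "eps_ic_mean", "eps_ic_sd", "eps_ej_mean", "eps_ej_sd",
        "eps_ir_mean", "eps_ir_sd", "wf_mean", "wf_sd",
        "p_lv_max", "stroke_volume"]}
    d["cycle"] = int(r.cycle)
    d["alpha_h"] = np.asarray(r.alpha_h).tolist()
    d["alpha_t"] = np.asarray(r.alpha_t).tolist()
    return d


def _deserialize_record(d: dict):
    from .reorientation import AdaptationRecord

    kw = dict(d)
    kw["alpha_h"] = np.array(kw["alpha_h"])
    kw["alpha_t"] = np.array(kw["alpha_t"])
    return AdaptationRecord(**kw)


def _serialize_trace(tr: TorsionTrace) -> dict:
    return {"t": tr.t.tolist(), "levels": tr.levels.tolist(),
            "torsion": tr.torsion.tolist(), "reference_index": int(tr.reference_index)}


def _deserialize_trace(d: dict) -> TorsionTrace:
    return TorsionTrace(t=np.array(d["t"]), levels=np.array(d["levels"]),
                        torsion=np.array(d["torsion"]),
                        reference_index=d["reference_index"])


def run_experiment(config: RunConfig | str, outdir, resume: bool = False) -> RunResult:
    """Execute a configured simulation and write the run directory.

    A ``checkpoint.json`` is written after every completed cycle; with
    ``resume=True`` an interrupted run continues from it (the configuration
    must match).  On resume, the per-step hemodynamics CSV covers only the
    cycles simulated in the resumed session; the per-cycle metrics cover the
    whole run.
    """
    if isinstance(config, str):
        config = preset(config)
    config.validate()
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ckpt_path = outdir / "checkpoint.json"

    ck = None
    if resume and ckpt_path.exists():
        ck = json.loads(ckpt_path.read_text())
        if ck["config"] != to_dict(config):
            raise ExperimentError("checkpoint configuration does not match")

    mesh = build_mesh(config.geometry, config.subdivisions)
    field = build_fiber_field(mesh, config.fiber.kind, config.fiber.ss,
                              config.fiber.transition if config.fiber.kind == "sit" else None)
    model = FEModel(mesh.cross_section, field, config.passive, config.active,
                    config.solver)
    ah0, at0 = field.angles()

    from .fibers import FiberField
    from .materials import SarcomereState

    if ck is None:
        circ = initialize_diastolic_state(model, config.circulation)
    else:
        vecs = np.array(ck["model"]["fiber_vectors"])
        model.set_fiber_field(FiberField(vectors=vecs, basis=field.basis,
                                         provenance=ck["model"]["fiber_provenance"]))
        model.U = np.array(ck["model"]["U"])
        model.p_lv = ck["model"]["p_lv"]
        nel, nqp = model.cs.n_elems, model.cs.nqp
        model.sarcomere = SarcomereState(
            l_c=np.array(ck["model"]["l_c"]).reshape(nel, nqp),
            l_s=np.array(ck["model"]["l_s"]).reshape(nel, nqp), t_a=-1.0)
        circ = CirculationState(V_art=ck["circ"]["V_art"], V_ven=ck["circ"]["V_ven"],
                                V_lv=ck["circ"]["V_lv"], params=config.circulation)

    z_levels = default_slice_levels(model.cs, config.postprocess.n_sections,
                                    config.postprocess.slice_margin)

    ck_records: list[dict] = list(ck["records"]) if ck else []
    tor0: TorsionTrace | None = (_deserialize_trace(ck["torsion_before"])
                                 if ck and ck.get("torsion_before") else None)
    solver_log: list[dict] = []

    def save_checkpoint(stage: str, hemo_done: int, adapt_done: int,
                        F_samples: np.ndarray | None) -> None:
        data = {
            "config": to_dict(config), "stage": stage,
            "hemo_done": hemo_done, "adapt_done": adapt_done,
            "model": {"U": model.U.tolist(), "p_lv": float(model.p_lv),
                      "l_c": model.sarcomere.l_c.ravel().tolist(),
                      "l_s": model.sarcomere.l_s.ravel().tolist(),
                      "fiber_vectors": model.fiber_field.vectors.tolist(),
                      "fiber_provenance": model.fiber_field.provenance},
            "circ": {"V_art": float(circ.V_art), "V_ven": float(circ.V_ven),
                     "V_lv": float(circ.V_lv)},
            "records": ck_records,
            "torsion_before": _serialize_trace(tor0) if tor0 is not None else None,
            "F_samples": None if F_samples is None else F_samples.tolist(),
        }
        ckpt_path.write_text(json.dumps(data))

    hemo_cycles: list[CycleState] = []
    labels: list[str] = []
    error: str | None = None
    hemo_start = ck["hemo_done"] if ck else 0
    try:
        for i in range(hemo_start, config.n_hemodynamic_cycles):
            cyc, circ = run_cardiac_cycle(model, circ)
            hemo_cycles.append(cyc)
            labels.append(f"hemo_{i}")
            solver_log.append({"cycle": f"hemo_{i}",
                               "newton_mean": float(cyc.newton_iters.mean()),
                               "newton_max": int(cyc.newton_iters.max())})
            save_checkpoint("hemo", i + 1, -1, None)
    except Exception as exc:
        error = f"{type(exc).__name__}: {exc}"
        (outdir / "error.json").write_text(json.dumps({"error": error}, indent=2))
        if hemo_cycles:
            _hemo_frame(hemo_cycles, labels).to_csv(outdir / "hemodynamics.csv", index=False)
        raise ExperimentError(error) from exc

    adapt_start = ck["adapt_done"] if ck and ck["stage"] == "adapt" else 0
    resume_F = (np.array(ck["F_samples"]) if ck and ck.get("F_samples") else None)
    if adapt_start >= config.adaptation.n_cycles and ck is not None:
        raise ExperimentError("run already complete; nothing to resume")

    def on_cycle(record, cycle, model_, circ_, F_prev):
        nonlocal tor0, circ
        circ = circ_  # the adaptation loop advances its own state copy
        if record.cycle == 0:
            tor0 = torsion(model.cs, cycle.psi, cycle.t,
                           cycle.begin_ejection_index, z_levels)
        ck_records.append(_serialize_record(record))
        solver_log.append({"cycle": f"adapt_{record.cycle}",
                           "newton_mean": float(cycle.newton_iters.mean()),
                           "newton_max": int(cycle.newton_iters.max())})
        save_checkpoint("adapt", config.n_hemodynamic_cycles, record.cycle, F_prev)

    history, circ = run_adaptation(model, circ, config.adaptation,
                                   on_cycle=on_cycle, start_cycle=adapt_start,
                                   resume_F_samples=resume_F)
    if history.error:
        error = history.error
        (outdir / "error.json").write_text(json.dumps({"error": error}, indent=2))
    if adapt_start > 0:
        prev = [_deserialize_record(d) for d in ck["records"]]
        history = AdaptationHistory(records=prev + history.records,
                                    cycles=history.cycles,
                                    steady_state_cycle=history.steady_state_cycle,
                                    error=history.error)

    cycN = history.cycles[-1]
    torN = torsion(model.cs, cycN.psi, cycN.t, cycN.begin_ejection_index, z_levels)
    if tor0 is None:
        raise ExperimentError("missing pre-adaptation torsion reference")

    # outputs
    all_cycles = hemo_cycles + history.cycles
    first_adapt = 0 if adapt_start == 0 else adapt_start + 1
    cycle_labels = labels + [f"adapt_{i}" for i in
                             range(first_adapt, first_adapt + len(history.cycles))]
    _hemo_frame(all_cycles, cycle_labels).to_csv(outdir / "hemodynamics.csv", index=False)
    _adaptation_frame(history).to_csv(outdir / "adaptation.csv", index=False)
    pd.DataFrame(solver_log).to_csv(outdir / "solver_log.csv", index=False)

    tor_rows = []
    for tag, tr in [("before", tor0), ("after", torN)]:
        for s in range(tr.torsion.shape[0]):
            for k in range(tr.t.size):
                tor_rows.append((tag, tr.t[k], s, tr.torsion[s, k]))
    pd.DataFrame(tor_rows, columns=["stage", "time_ms", "section_id", "torsion_rad"]
                 ).to_csv(outdir / "torsion.csv", index=False)

    ahN, atN = model.fiber_field.angles()
    cs = model.cs
    pd.DataFrame({"node_id": np.arange(cs.n_nodes), "u": cs.u, "v": cs.v,
                  "alpha_h_initial": ah0, "alpha_t_initial": at0,
                  "alpha_h_final": ahN, "alpha_t_final": atN}
                 ).to_csv(outdir / "fibers.csv", index=False)

    manifest = {
        "package": "lvmech", "version": __version__,
        "config": to_dict(config),
        "mesh": {"n_elements": mesh.n_elems, "n_nodes": mesh.n_nodes,
                 "wall_volume_ml": mesh.wall_volume(),
                 "cavity_volume_ml": mesh.cavity_volume()},
        "steady_state_cycle": history.steady_state_cycle,
        "final": {"stroke_volume_ml": history.records[-1].stroke_volume,
                  "p_lv_max_kpa": history.records[-1].p_lv_max,
                  "wf_mean_kpa": history.records[-1].wf_mean,
                  "wf_sd_kpa": history.records[-1].wf_sd},
        "error": error,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    if config.write_fields:
        from .vtkio import write_cross_section_vtu, write_mesh_vtu
        fields_dir = outdir / "fields"
        fields_dir.mkdir(exist_ok=True)
        write_mesh_vtu(fields_dir / "mesh.vtu", mesh)
        write_cross_section_vtu(fields_dir / "fibers_final.vtu", cs,
                                {"alpha_h": ahN, "alpha_t": atN,
                                 "fiber": model.fiber_field.vectors})
        # thinned per-cycle fiber-angle snapshots
        for r in history.records[::5]:
            write_cross_section_vtu(fields_dir / f"fibers_cycle_{r.cycle:03d}.vtu",
                                    cs, {"alpha_h": r.alpha_h, "alpha_t": r.alpha_t})
        # displacement snapshots of the final cycle: end-diastole,
        # mid-ejection, end-ejection
        pb = cycN.phase_bounds.get("ejection")
        snaps = {"ed": 0}
        if pb:
            snaps["midej"] = (pb[0] + pb[1]) // 2
            snaps["endej"] = pb[1]
        for tag, k in snaps.items():
            write_cross_section_vtu(
                fields_dir / f"displacement_{tag}.vtu", cs,
                {"u_r": cycN.ur[k], "psi": cycN.psi[k], "u_z": cycN.uz[k]})

    write_torsion_csv(torN, outdir / "torsion_after.csv")
    return RunResult(config=config, outdir=outdir, history=history,
                     hemo_cycles=hemo_cycles, torsion_before=tor0,
                     torsion_after=torN, model=model, circulation=circ)


def compare_runs(run_dirs: list) -> pd.DataFrame:
    """Before/after comparison table of local and global function metrics."""
    rows = []
    for d in run_dirs:
        d = pathlib.Path(d)
        try:
            adf = pd.read_csv(d / "adaptation.csv")
            manifest = json.loads((d / "manifest.json").read_text())
        except FileNotFoundError:
            rows.append({"run": d.name, "status": "incomplete"})
            continue
        first, last = adf.iloc[0], adf.iloc[-1]
        for stage, rec in [("before", first), ("after", last)]:
            rows.append({
                "run": d.name, "status": "ok", "stage": stage,
                "eps_ic": rec["eps_ic_mean"], "eps_ic_sd": rec["eps_ic_sd"],
                "eps_ej": rec["eps_ej_mean"], "eps_ej_sd": rec["eps_ej_sd"],
                "eps_ir": rec["eps_ir_mean"], "eps_ir_sd": rec["eps_ir_sd"],
                "wf": rec["wf_mean"], "wf_sd": rec["wf_sd"],
                "p_max": rec["p_lv_max"], "sv": rec["stroke_volume"],
                "n_elements": manifest["mesh"]["n_elements"],
            })
    return pd.DataFrame(rows)
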