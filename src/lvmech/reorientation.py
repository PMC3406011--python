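"""Shear-induced adaptive myofiber reorientation.

The remodelling hypothesis: fiber cross-fiber shear during the cycle damages
fiber-matrix connections, and newly formed connections fix the *current*
fiber direction in the tissue.  Mathematically, the unloaded fiber direction
e_f0 at each node evolves towards the deformed fiber direction mapped back
to the unloaded state with the rigid-body rotation removed,

    target = U e_f0 / |U e_f0|,     F = R U  (right polar decomposition).

If e_f0 is an eigenvector of U (no fiber cross-fiber shear) the target
coincides with e_f0 and no reorientation occurs.  One update is applied per
cardiac cycle: the per-node target is aggregated over sampling instants
spanning diastole and systole (end-diastole plus ejection samples, weighted
by the gap angle), and e_f0 is rotated towards it along the great circle by
the fraction 1/kappa (kappa = adaptation rate constant in cycles).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .fibers import FiberField
from .solver import FEModel, CycleState, run_cardiac_cycle
from .circulation import CirculationState


class ReorientationError(RuntimeError):
    pass


@dataclasses.dataclass(frozen=True)
class AdaptationConfig:
    kappa: float = 5.0              # rate constant, cycles (fraction 1/kappa per cycle)
    n_cycles: int = 15              # adaptation cycles to run
    n_ejection_samples: int = 5     # sampling instants during ejection
    steady_threshold: float = 0.01  # relative metric change per cycle

    def validate(self) -> None:
        if self.kappa <= 0 or self.steady_threshold <= 0:
            raise ReorientationError("kappa and steady threshold must be positive")


def right_stretch(F: np.ndarray) -> np.ndarray:
    """Right stretch tensor U = sqrt(F^T F), batched; requires det F > 0."""
    F = np.asarray(F, dtype=float)
    if np.any(np.linalg.det(F) <= 0.0):
        raise ReorientationError("polar decomposition failed: det F <= 0")
    C = np.einsum("...ki,...kj->...ij", F, F)
    w, V = np.linalg.eigh(C)
    return np.einsum("...ik,...k,...jk->...ij", V, np.sqrt(w), V)


def target_direction(F: np.ndarray, e_f0: np.ndarray) -> np.ndarray:
    """Rotation-free image of the fiber direction, normalized and sign-aligned
    with e_f0 (fibers are directionless)."""
    U = right_stretch(F)
    t = np.einsum("...ij,...j->...i", U, e_f0)
    t = t / np.linalg.norm(t, axis=-1, keepdims=True)
    sign = np.sign(np.einsum("...i,...i->...", t, e_f0))
    return t * np.where(sign == 0.0, 1.0, sign)[..., None]


def _slerp(a: np.ndarray, b: np.ndarray, frac: float) -> np.ndarray:
    """Rotate unit vectors a towards b by ``frac`` of the angular gap."""
    dot = np.clip(np.einsum("...i,...i->...", a, b), -1.0, 1.0)
    theta = np.arccos(dot)
    small = theta < 1e-12
    st = np.where(small, 1.0, np.sin(np.where(small, 1.0, theta)))
    wa = np.where(small, 1.0 - frac, np.sin((1.0 - frac) * theta) / st)
    wb = np.where(small, frac, np.sin(frac * theta) / st)
    out = wa[..., None] * a + wb[..., None] * b
    return out / np.linalg.norm(out, axis=-1, keepdims=True)


def aggregate_target(e_f0: np.ndarray, F_samples: np.ndarray) -> np.ndarray:
    """Gap-angle-weighted mean target over sampling instants.

    ``F_samples`` has shape (n_samples, n_nodes, 3, 3).  Nodes whose gap is
    zero at every instant keep their current direction.
    """
    n_s = F_samples.shape[0]
    if n_s == 0:
        raise ReorientationError("at least one deformation sample per cycle is required")
    # non-invertible recovered samples (coarse-mesh corner artifacts) carry
    # no reorientation drive: their target is the current direction
    dets = np.linalg.det(F_samples)
    F_safe = np.where(dets[..., None, None] > 0.0, F_samples, np.eye(3))
    targets = np.stack([target_direction(F_safe[s], e_f0) for s in range(n_s)])
    dots = np.clip(np.einsum("sni,ni->sn", targets, e_f0), -1.0, 1.0)
    gaps = np.arccos(dots)                      # (n_s, n_nodes)
    wsum = gaps.sum(axis=0)
    w = np.where(wsum[None] > 1e-14, gaps / np.maximum(wsum[None], 1e-300), 1.0 / n_s)
    agg = np.einsum("sn,sni->ni", w, targets)
    nrm = np.linalg.norm(agg, axis=-1, keepdims=True)
    agg = np.where(nrm > 1e-14, agg / np.maximum(nrm, 1e-300), e_f0)
    return agg


def adapt_fibers(field: FiberField, F_samples: np.ndarray,
                 cfg: AdaptationConfig = AdaptationConfig()) -> FiberField:
    """One per-cycle reorientation update of the nodal fiber field."""
    cfg.validate()
    target = aggregate_target(field.vectors, F_samples)
    frac = min(1.0, 1.0 / cfg.kappa)
    new = _slerp(field.vectors, target, frac)
    return FiberField(vectors=new, basis=field.basis, provenance="adapted")


@dataclasses.dataclass
class AdaptationRecord:
    cycle: int
    eps_ic_mean: float
    eps_ic_sd: float
    eps_ej_mean: float
    eps_ej_sd: float
    eps_ir_mean: float
    eps_ir_sd: float
    wf_mean: float
    wf_sd: float
    p_lv_max: float
    stroke_volume: float
    alpha_h: np.ndarray      # nodal helix angles after this cycle's update
    alpha_t: np.ndarray


@dataclasses.dataclass
class AdaptationHistory:
    records: list[AdaptationRecord]
    cycles: list[CycleState]
    steady_state_cycle: int | None
    error: str | None = None

    def metric_table(self) -> dict[str, np.ndarray]:
        keys = ["eps_ic_mean", "eps_ic_sd", "eps_ej_mean", "eps_ej_sd",
                "eps_ir_mean", "eps_ir_sd", "wf_mean", "wf_sd",
                "p_lv_max", "stroke_volume"]
        return {k: np.array([getattr(r, k) for r in self.records]) for k in keys}


def run_adaptation(model: FEModel, circ: CirculationState,
                   cfg: AdaptationConfig = AdaptationConfig(),
                   keep_cycles: bool = True, on_cycle=None,
                   start_cycle: int = 0, resume_F_samples: np.ndarray | None = None
                   ) -> tuple[AdaptationHistory, CirculationState]:
    """Alternate cardiac-cycle simulation and fiber reorientation.

    The model should already be at hemodynamic steady state with frozen
    fibers.  Record 0 is the pre-adaptation cycle (fibers unchanged); each
    subsequent record follows one reorientation update.  On a solver failure
    the history up to the failure is returned with the error recorded.

    ``on_cycle(record, cycle, model, circ)`` is invoked after every completed
    cycle (checkpointing hook).  ``start_cycle > 0`` resumes mid-loop: the
    model/circulation state must already be the end state of that cycle, and
    the pre-adaptation record is skipped.
    """
    from .postprocess import local_function, region_mask

    cfg.validate()
    mask = region_mask(model.cs)
    records: list[AdaptationRecord] = []
    cycles: list[CycleState] = []
    steady: int | None = None

    def record_from(cycle: CycleState, idx: int) -> AdaptationRecord:
        lf = local_function(model, cycle, mask)
        ah, at = model.fiber_field.angles()
        return AdaptationRecord(cycle=idx, p_lv_max=cycle.p_lv_max,
                                stroke_volume=cycle.stroke_volume,
                                alpha_h=ah, alpha_t=at, **lf)

    error = None
    try:
        if start_cycle == 0:
            cycle, circ = run_cardiac_cycle(model, circ,
                                            n_ejection_samples=cfg.n_ejection_samples)
            records.append(record_from(cycle, 0))
            if keep_cycles:
                cycles.append(cycle)
            F_prev = np.concatenate([cycle.F_nodal_ed[None], cycle.F_nodal_ej])
            if on_cycle is not None:
                on_cycle(records[-1], cycle, model, circ, F_prev)
        else:
            if resume_F_samples is None:
                raise ReorientationError("resuming requires the deformation "
                                         "samples of the checkpointed cycle")
            F_prev = resume_F_samples
        for i in range(start_cycle + 1, cfg.n_cycles + 1):
            model.set_fiber_field(adapt_fibers(model.fiber_field, F_prev, cfg))
            cycle, circ = run_cardiac_cycle(model, circ,
                                            n_ejection_samples=cfg.n_ejection_samples)
            F_prev = np.concatenate([cycle.F_nodal_ed[None], cycle.F_nodal_ej])
            records.append(record_from(cycle, i))
            if keep_cycles:
                cycles.append(cycle)
            if on_cycle is not None:
                on_cycle(records[-1], cycle, model, circ, F_prev)
            if (steady is None and len(records) >= 2
                    and _is_steady(records[-2], records[-1], cfg.steady_threshold)):
                steady = i
    except Exception as exc:  # preserve partial history
        error = f"{type(exc).__name__}: {exc}"
        if not records:
            raise
    return AdaptationHistory(records=records, cycles=cycles,
                             steady_state_cycle=steady, error=error), circ


def _is_steady(prev: AdaptationRecord, cur: AdaptationRecord, threshold: float) -> bool:
    for key in ["eps_ic_mean", "eps_ej_mean", "eps_ir_mean", "wf_mean",
                "p_lv_max", "stroke_volume"]:
        a, b = getattr(prev, key), getattr(cur, key)
        scale = max(abs(a), abs(b), 1e-9)
        if abs(b - a) / scale > threshold:
            return False
    return True
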