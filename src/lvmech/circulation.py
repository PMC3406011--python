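"""Lumped-parameter systemic circulation.

A two-compartment windkessel (arterial, venous) closes the loop around the
LV: the aortic valve feeds the arterial compartment through resistance
R_art, blood returns through the peripheral resistance R_per, and the mitral
valve fills the LV from the venous compartment through R_ven.  Compartment
pressures are linear in stored volume, p = (V - V0)/C; valves are ideal
diodes.  Units: kPa, mL, ms (resistance kPa*ms/mL, compliance mL/kPa).

Parameter defaults are tuned once so the converged normal-geometry run
operates in the physiological ~5 L/min cardiac output regime; they are model
choices, not literature constants.
"""

from __future__ import annotations

import dataclasses
import enum

class CirculationError(RuntimeError):
    pass


@dataclasses.dataclass(frozen=True)
class CirculationParams:
    R_art: float = 5.0      # aortic/arterial inflow resistance
    R_per: float = 140.0    # peripheral resistance
    R_ven: float = 2.0      # venous return (mitral) resistance
    C_art: float = 12.0     # arterial compliance
    C_ven: float = 60.0     # venous compliance
    V_art0: float = 600.0   # zero-pressure arterial volume
    V_ven0: float = 2900.0  # zero-pressure venous volume
    p_art_init: float = 11.5  # initial arterial pressure, kPa
    p_ven_init: float = 1.4   # initial venous (filling) pressure, kPa

    def validate(self) -> None:
        vals = dataclasses.astuple(self)
        if any(x <= 0 for x in vals):
            raise CirculationError("all circulation parameters must be positive")


@dataclasses.dataclass
class CirculationState:
    V_art: float
    V_ven: float
    V_lv: float
    params: CirculationParams

    @classmethod
    def initial(cls, params: CirculationParams, V_lv: float) -> "CirculationState":
        params.validate()
        return cls(V_art=params.V_art0 + params.C_art * params.p_art_init,
                   V_ven=params.V_ven0 + params.C_ven * params.p_ven_init,
                   V_lv=V_lv, params=params)

    @property
    def p_art(self) -> float:
        return (self.V_art - self.params.V_art0) / self.params.C_art

    @property
    def p_ven(self) -> float:
        return (self.V_ven - self.params.V_ven0) / self.params.C_ven

    @property
    def total_volume(self) -> float:
        return self.V_art + self.V_ven + self.V_lv

    def valve_states(self, p_lv: float) -> dict[str, bool]:
        return {"mitral": self.p_ven > p_lv, "aortic": p_lv > self.p_art}

    def copy(self) -> "CirculationState":
        return CirculationState(self.V_art, self.V_ven, self.V_lv, self.params)


def circulation_step(state: CirculationState, p_lv: float, dt: float
                     ) -> tuple[CirculationState, float, float]:
    """Advance compartments by one step at LV pressure ``p_lv``.

    Valves are ideal diodes: the mitral valve conducts iff p_ven > p_lv, the
    aortic valve iff p_lv > p_art.  Returns (new state, q_mitral, q_aortic)
    with flows in mL/ms.  Volume is conserved exactly by construction.
    """
    if dt <= 0:
        raise CirculationError("dt must be positive")
    p = state.params
    q_mit = max(state.p_ven - p_lv, 0.0) / p.R_ven
    q_ao = max(p_lv - state.p_art, 0.0) / p.R_art
    q_per = (state.p_art - state.p_ven) / p.R_per
    new = state.copy()
    new.V_art += dt * (q_ao - q_per)
    new.V_ven += dt * (q_per - q_mit)
    new.V_lv += dt * (q_mit - q_ao)
    if new.V_art <= 0 or new.V_ven <= 0 or new.V_lv <= 0:
        raise CirculationError(f"negative compartment volume: {new}")
    return new, q_mit, q_ao


def apply_valve_flows(state: CirculationState, q_mit: float, q_ao: float,
                      dt: float) -> CirculationState:
    """Compartment update with externally determined valve flows (used by the
    coupled FE scheme, which solves the valve flow implicitly with the LV).
    The peripheral path is advanced with the same step."""
    p = state.params
    q_per = (state.p_art - state.p_ven) / p.R_per
    new = state.copy()
    new.V_art += dt * (q_ao - q_per)
    new.V_ven += dt * (q_per - q_mit)
    new.V_lv += dt * (q_mit - q_ao)
    return new


class PhaseLabel(str, enum.Enum):
    FILLING = "filling"
    IC = "isovolumic_contraction"
    EJECTION = "ejection"
    IR = "isovolumic_relaxation"


_CANONICAL_NEXT = {
    PhaseLabel.FILLING: PhaseLabel.IC,
    PhaseLabel.IC: PhaseLabel.EJECTION,
    PhaseLabel.EJECTION: PhaseLabel.IR,
    PhaseLabel.IR: PhaseLabel.FILLING,
}


@dataclasses.dataclass
class Phase:
    label: PhaseLabel
    t_begin: float
    t_end: float | None = None


def detect_phase(prev: PhaseLabel, p_lv: float, p_art: float, p_ven: float,
                 at_activation_onset: bool) -> PhaseLabel:
    """Deterministic phase transitions of the cardiac cycle.

    filling -> IC at activation onset; IC -> ejection when the aortic valve
    opens (p_lv >= p_art); ejection -> IR when it closes; IR -> filling when
    the mitral valve opens (p_lv <= p_ven).  Any other transition indicates a
    solver failure and raises.
    """
    nxt = prev
    if prev is PhaseLabel.FILLING and at_activation_onset:
        nxt = PhaseLabel.IC
    elif prev is PhaseLabel.IC and p_lv >= p_art:
        nxt = PhaseLabel.EJECTION
    elif prev is PhaseLabel.EJECTION and p_lv < p_art:
        nxt = PhaseLabel.IR
    elif prev is PhaseLabel.IR and p_lv <= p_ven:
        nxt = PhaseLabel.FILLING
    if nxt is not prev and _CANONICAL_NEXT[prev] is not nxt:
        raise CirculationError(f"out-of-order phase transition {prev} -> {nxt}")
    return nxt


def phase_flow(phase: PhaseLabel, p_lv: float, p_art: float, p_ven: float,
               params: CirculationParams) -> tuple[float, float]:
    """Net LV inflow q (mL/ms) and dq/dp_lv for the current phase."""
    if phase is PhaseLabel.FILLING:
        return (p_ven - p_lv) / params.R_ven, -1.0 / params.R_ven
    if phase is PhaseLabel.EJECTION:
        return -(p_lv - p_art) / params.R_art, -1.0 / params.R_art
    return 0.0, 0.0
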