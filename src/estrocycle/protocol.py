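"""In-silico replication of the culture / knockdown / starvation / exposure protocol.

The wet-lab protocol that the simulations mirror is: cells proliferate in
complete medium (which carries estrogenic activity equivalent to an effective
E2 concentration of 0.156), are optionally transfected with siRNA for 24 h,
starved for 24 h in estrogen-free medium, and finally exposed to an E2 dose
whose effective concentration is applied as an instantaneous spike that then
depletes freely through complex formation.

Cell-to-cell variability comes exclusively from the cell cycle phase at the
start of the protocol: the population is seeded with states drawn uniformly
along one period of the culture limit cycle.  The signaling layer is shared
by all cells (one-way coupling), so it is integrated once and the
two-variable oscillator is driven per cell by the interpolated signaling
inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Collection, Sequence

import numpy as np
import pandas as pd
import yaml

from .params import (
    CellCycleParams,
    SignalingParams,
    COMPLETE_MEDIUM_E2,
)
from .signaling import (
    E2Input,
    STATE_VARS,
    Trajectory,
    model_rhs,
    simulate_signaling,
    steady_state,
)
from .cellcycle import (
    classify_phases,
    cycle_rhs,
    detect_oscillation,
    find_limit_cycle,
    phase_durations_insilico,
    sample_initial_states,
    simulate_cycle,
)

__all__ = [
    "Phase",
    "Protocol",
    "ProtocolResult",
    "run_protocol",
    "degradation_rhs",
    "degradation_solution",
    "estimate_e2_equivalent",
    "bracket_midpoint",
]

PHASE_ORDER = ("culture", "knockdown", "starvation", "exposure")


@dataclass(frozen=True)
class Phase:
    """One protocol phase: a name, a duration and an E2 input mode."""

    name: str
    duration_h: float
    e2: E2Input
    knockdown_targets: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.name not in PHASE_ORDER:
            raise ValueError(f"unknown phase name {self.name!r}")
        if self.duration_h <= 0:
            raise ValueError("phase duration must be positive")


@dataclass(frozen=True)
class Protocol:
    """Ordered experimental phases.

    Culture must precede starvation, starvation must precede exposure, and a
    knockdown phase (if any) sits between culture and starvation; its targets
    persist through every later phase.
    """

    phases: tuple[Phase, ...]

    def __post_init__(self) -> None:
        order = [PHASE_ORDER.index(p.name) for p in self.phases]
        if sorted(order) != order or len(set(order)) != len(order):
            raise ValueError("phases must follow culture < knockdown < starvation < exposure")
        for required in ("culture", "starvation", "exposure"):
            if required not in [p.name for p in self.phases]:
                raise ValueError(f"protocol is missing the {required} phase")

    def __iter__(self):
        return iter(self.phases)

    def __getitem__(self, name: str) -> Phase:
        for p in self.phases:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def knockdown_targets(self) -> frozenset:
        for p in self.phases:
            if p.name == "knockdown":
                return p.knockdown_targets
        return frozenset()

    @classmethod
    def standard(
        cls,
        exposure_effective: float,
        knockdown: Collection[str] = (),
        culture_e2: float = COMPLETE_MEDIUM_E2,
        culture_h: float = 48.0,
        knockdown_h: float = 24.0,
        starvation_h: float = 24.0,
        exposure_h: float = 100.0,
    ) -> "Protocol":
        """The default protocol; the culture duration is nominal because the
        culture phase is always run to steady state / limit cycle."""
        phases = [Phase("culture", culture_h, E2Input.clamp(culture_e2))]
        if knockdown:
            # transfection happens in complete medium, so E2 stays clamped
            phases.append(Phase("knockdown", knockdown_h, E2Input.clamp(culture_e2),
                                frozenset(knockdown)))
        phases.append(Phase("starvation", starvation_h, E2Input.clamp(0.0)))
        phases.append(Phase("exposure", exposure_h, E2Input.free(exposure_effective)))
        return cls(tuple(phases))

    @classmethod
    def load(cls, path: str | Path) -> "Protocol":
        path = Path(path)
        doc = (yaml.safe_load if path.suffix in (".yaml", ".yml") else json.loads)(
            path.read_text()
        )
        phases = []
        for ph in doc["phases"]:
            mode, value = ph["e2_mode"], float(ph["e2_value"])
            phases.append(Phase(
                ph["name"], float(ph["duration_h"]), E2Input(mode, value),
                frozenset(ph.get("knockdown_targets", ())),
            ))
        return cls(tuple(phases))


@dataclass
class ProtocolResult:
    """Everything a protocol simulation produced.

    ``signaling`` covers the post-culture phases on a common clock whose zero
    is the start of the first post-culture phase; ``exposure_start`` marks
    where the exposure phase begins on that clock.  Per-cell CDK1/APC
    trajectories share the same clock.
    """

    protocol: Protocol
    signaling: Trajectory
    exposure_start: float
    times: np.ndarray
    cdk1: np.ndarray  # (n_cells, n_times)
    apc: np.ndarray
    culture_period: float | None
    arrest_in_culture: bool
    durations: pd.DataFrame
    n_divisions: np.ndarray  # per cell, exposure window only
    meta: dict = field(default_factory=dict)

    def to_frame(self, stride: int = 1) -> pd.DataFrame:
        """Long-format per-cell activities (cell_id, time_h, CDK1, APC),
        optionally strided for compact CSV export."""
        sel = np.arange(0, len(self.times), stride)
        frames = [
            pd.DataFrame({
                "cell_id": i, "time_h": self.times[sel],
                "CDK1": self.cdk1[i, sel], "APC": self.apc[i, sel],
            })
            for i in range(self.cdk1.shape[0])
        ]
        return pd.concat(frames, ignore_index=True)

    def cells_cycling(self, min_divisions: int = 2) -> np.ndarray:
        return self.n_divisions >= min_divisions

    def cdk1_pinned_low(self, tail_h: float = 25.0, level: float = 0.25) -> np.ndarray:
        """Per-cell flag: mean CDK1 over the final ``tail_h`` stays below
        ``level`` (sustained low activity; the arrest signature)."""
        sel = self.times >= self.times[-1] - tail_h
        return self.cdk1[:, sel].mean(axis=1) < level


def run_protocol(
    protocol: Protocol,
    sig_params: SignalingParams | None = None,
    cyc_params: CellCycleParams | None = None,
    model_id: str = "III",
    n_cells: int = 100,
    seed: int = 0,
    grid_dt: float = 0.1,
    couple_totals: bool = False,
) -> ProtocolResult:
    """Simulate the full protocol for ``n_cells`` unsynchronized cells.

    The culture phase is run to signaling steady state under its E2 clamp and
    to a stable limit cycle of the driven oscillator; initial (CDK1, APC)
    states are sampled uniformly along one period.  If culture produces no
    oscillation the result carries an explicit arrest report instead of
    failing.  Deterministic for a fixed seed and configuration.
    """
    sig_params = sig_params or SignalingParams()
    cyc_params = cyc_params or CellCycleParams.default()
    names = STATE_VARS[model_id]
    culture = protocol["culture"]

    # --- culture: steady state + limit cycle ------------------------------
    sig_ss = steady_state(model_id, sig_params, culture.e2.value)
    d = dict(zip(names, sig_ss))
    inputs = (d["GREB1"], d["E2_ER"], d["PR"])
    if couple_totals:
        inputs = (
            d["GREB1"] + d.get("E2_ER_PR_GREB1", d.get("E2_ER_GREB1", 0.0)),
            d["E2_ER"],
            d["PR"] + d.get("E2_ER_PR", 0.0) + d.get("E2_ER_PR_GREB1", 0.0),
        )
    try:
        cyc_traj, period = find_limit_cycle(cyc_params, inputs=inputs)
        arrest_in_culture = False
        init_states = sample_initial_states(cyc_traj, period, n_cells, seed)
    except RuntimeError:
        period = None
        arrest_in_culture = True
        init_states = np.tile([0.05, 0.95], (n_cells, 1))

    # --- post-culture signaling (shared by all cells) ---------------------
    post = [p for p in protocol if p.name != "culture"]
    kd: frozenset = frozenset()
    t_offset = 0.0
    seg_t: list[np.ndarray] = []
    seg_y: list[np.ndarray] = []
    y = sig_ss.copy()
    for ph in post:
        if ph.name == "knockdown":
            kd = kd | ph.knockdown_targets
        n_pts = max(int(round(ph.duration_h / grid_dt)) + 1, 2)
        grid = np.linspace(0.0, ph.duration_h, n_pts)
        traj = simulate_signaling(model_id, sig_params, ph.e2, grid, y0=y, knockdown=kd)
        y = traj.final.copy()
        if ph.e2.mode == "clamp":
            y[0] = ph.e2.value
        seg_t.append(traj.times + t_offset)
        seg_y.append(traj.states)
        if ph.name == "starvation":
            exposure_start = t_offset + ph.duration_h
        t_offset += ph.duration_h
    times = np.concatenate([s[:-1] for s in seg_t[:-1]] + [seg_t[-1]])
    states = np.concatenate([s[:-1] for s in seg_y[:-1]] + [seg_y[-1]])
    sig_traj = Trajectory(times, states, names, model_id,
                          meta={"knockdown": sorted(kd)})

    i_g, i_c1, i_p = names.index("GREB1"), names.index("E2_ER"), names.index("PR")
    g_t = states[:, i_g].copy()
    p_t = states[:, i_p].copy()
    if couple_totals:
        if model_id == "III":
            g_t += states[:, names.index("E2_ER_PR_GREB1")]
            p_t += states[:, names.index("E2_ER_PR")] + states[:, names.index("E2_ER_PR_GREB1")]
        else:
            g_t += states[:, names.index("E2_ER_GREB1")]
    c1_t = states[:, i_c1]

    def drive(t: float) -> tuple[float, float, float]:
        return (
            float(np.interp(t, times, g_t)),
            float(np.interp(t, times, c1_t)),
            float(np.interp(t, times, p_t)),
        )

    # --- per-cell oscillator ----------------------------------------------
    cdk1 = np.empty((n_cells, len(times)))
    apc = np.empty((n_cells, len(times)))
    for i in range(n_cells):
        tr = simulate_cycle(cyc_params, times, y0=init_states[i], inputs=drive)
        cdk1[i] = tr["CDK1"]
        apc[i] = tr["APC"]

    # --- phase durations in the exposure window ---------------------------
    exp_sel = times >= exposure_start
    rows = []
    n_div = np.zeros(n_cells, dtype=int)
    for i in range(n_cells):
        seq = classify_phases(times[exp_sel], cdk1[i, exp_sel], apc[i, exp_sel])
        n_div[i] = sum(k == "division" for k in seq.transition_kinds)
        for rec in phase_durations_insilico(seq):
            rows.append({
                "cell_id": i, "cycle_index": rec.cycle_index, "phase": rec.phase,
                "duration_h": rec.duration_h, "complete": True,
            })
    durations = pd.DataFrame(rows, columns=["cell_id", "cycle_index", "phase",
                                            "duration_h", "complete"])

    return ProtocolResult(
        protocol=protocol, signaling=sig_traj, exposure_start=exposure_start,
        times=times, cdk1=cdk1, apc=apc, culture_period=period,
        arrest_in_culture=arrest_in_culture, durations=durations,
        n_divisions=n_div,
        meta={"seed": seed, "n_cells": n_cells, "model": model_id,
              "knockdown": sorted(protocol.knockdown_targets),
              "coupling": "totals" if couple_totals else "free"},
    )


# ---------------------------------------------------------------------------
# elementary starvation degradation model
# ---------------------------------------------------------------------------

def degradation_rhs(state: Sequence[float], d_rates: Sequence[float]) -> np.ndarray:
    """First-order decay: ``dX/dt = -d_X * X`` for GREB1, PR, TFF1."""
    state = np.asarray(state, float)
    d_rates = np.asarray(d_rates, float)
    if np.any(state < 0) or np.any(d_rates < 0):
        raise ValueError("degradation model requires non-negative inputs")
    return -d_rates * state


def degradation_solution(x0: float, d: float, t) -> np.ndarray:
    """Closed form ``x0 * exp(-d t)`` of the elementary degradation model."""
    return x0 * np.exp(-d * np.asarray(t, float))


def bracket_midpoint(lo_nm: float, hi_nm: float) -> float:
    """Arithmetic midpoint of the nominal dose bracket (nM), e.g. the
    0.01–0.1 nM bracket around the starvation-medium E2 equivalent."""
    return 0.5 * (lo_nm + hi_nm)


def estimate_e2_equivalent(
    effective_at_bracket_mid: float, complete_to_starved_ratio: float
) -> float:
    """E2-equivalent concentration of complete medium.

    The starved-medium equivalent is the effective concentration at the
    bracketing nominal midpoint; complete medium carries
    ``complete_to_starved_ratio`` times as much estrogenic activity
    (0.104 * 1.5 = 0.156 with the calibrated dose scale).
    """
    if effective_at_bracket_mid <= 0 or complete_to_starved_ratio <= 0:
        raise ValueError("inputs must be positive")
    return effective_at_bracket_mid * complete_to_starved_ratio
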