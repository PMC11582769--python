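"""ODE right-hand sides, knockdowns and observables for the E2 signaling models.

Three nested model variants describe how 17β-estradiol (E2) binding to ERα
drives expression of the target proteins GREB1, PR and TFF1:

* **Model I** — E2-ERα binds GREB1; the E2-ERα/GREB1 complex stimulates
  synthesis of all three targets.
* **Model II** — as Model I, but GREB1 stimulation additionally requires PR
  and TFF1 is stimulated by E2-ERα and PR jointly (independent of GREB1).
* **Model III** — PR binds E2-ERα first (E2-ERα/PR), GREB1 joins afterwards
  (E2-ERα/PR/GREB1); the quaternary complex stimulates GREB1 and PR while
  TFF1 is stimulated by E2-ERα and PR jointly.

Every bimolecular interaction uses the saturating form ``p*X*Y/(1+X+Y)`` so
no species can accumulate without bound, and complexes only degrade (no
dissociation).  Synthesis rates are derived from degradation and initial
states, so each model starts in steady state when E2 is absent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Collection, Literal

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import SignalingParams

__all__ = [
    "MODEL_IDS",
    "STATE_VARS",
    "TARGET_PROTEINS",
    "E2Input",
    "Trajectory",
    "saturating_rate",
    "derive_synthesis",
    "model_rhs",
    "apply_knockdown",
    "observable_totals",
    "simulate_signaling",
    "steady_state",
]

ModelId = Literal["I", "II", "III"]
MODEL_IDS: tuple[ModelId, ...] = ("I", "II", "III")

STATE_VARS: dict[str, tuple[str, ...]] = {
    "I": ("E2", "ER", "E2_ER", "E2_ER_GREB1", "GREB1", "PR", "TFF1"),
    "II": ("E2", "ER", "E2_ER", "E2_ER_GREB1", "GREB1", "PR", "TFF1"),
    "III": ("E2", "ER", "E2_ER", "E2_ER_PR", "E2_ER_PR_GREB1", "GREB1", "PR", "TFF1"),
}

TARGET_PROTEINS = frozenset({"GREB1", "PR", "TFF1"})


def saturating_rate(p: float, X, Y):
    """Saturating interaction flux ``p*X*Y/(1+X+Y)`` (a.u./h).

    Bounded above by ``p*min(X, Y)``, which prevents unlimited accumulation
    of the product species.  Negative inputs are rejected.
    """
    if p < 0 or np.any(np.asarray(X) < 0) or np.any(np.asarray(Y) < 0):
        raise ValueError("saturating_rate requires non-negative inputs")
    return p * X * Y / (1.0 + X + Y)


def derive_synthesis(params: SignalingParams) -> dict[str, float]:
    """Synthesis rates that place the E2-free system exactly at steady state."""
    return params.synthesis()


@dataclass(frozen=True)
class E2Input:
    """E2 input mode for a simulation phase.

    ``clamp``: E2 held constant at ``value`` (derivative forced to zero).
    ``free``: E2 initialized at ``value`` and depleted by complex formation
    only (it has no synthesis term), which produces the biphasic decay after
    an exposure spike.
    """

    mode: Literal["clamp", "free"]
    value: float

    def __post_init__(self) -> None:
        if self.mode not in ("clamp", "free"):
            raise ValueError(f"unknown E2 input mode {self.mode!r}")
        if self.value < 0:
            raise ValueError("E2 level must be non-negative")

    @classmethod
    def clamp(cls, value: float) -> "E2Input":
        return cls("clamp", value)

    @classmethod
    def free(cls, value: float) -> "E2Input":
        return cls("free", value)


def _validate_targets(targets: Collection[str]) -> frozenset:
    targets = frozenset(targets)
    unknown = targets - TARGET_PROTEINS
    if unknown:
        raise ValueError(f"unknown knockdown targets: {sorted(unknown)}")
    return targets


def model_rhs(
    model_id: ModelId,
    params: SignalingParams,
    knockdown: Collection[str] = (),
    strict_printed: bool = False,
    clamp_e2: bool = False,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Vector right-hand side ``f(t, y)`` for one model variant.

    ``knockdown`` removes all positive (synthesis/stimulation) terms from the
    listed target proteins' equations; degradation and consumption fluxes are
    retained.  ``strict_printed`` reproduces the Model I/II GREB1 equation
    without the flux consuming GREB1 into the E2-ERα/GREB1 complex (the
    mass-consistent consumption term is included by default).  ``clamp_e2``
    zeroes the E2 derivative.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model {model_id!r}")
    kd = _validate_targets(knockdown)
    p = params
    syn = p.synthesis()
    s_ER, s_G, s_P, s_T = syn["s_ER"], syn["s_GREB1"], syn["s_PR"], syn["s_TFF1"]
    g_on = "GREB1" not in kd
    p_on = "PR" not in kd
    t_on = "TFF1" not in kd

    if model_id in ("I", "II"):
        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            E2, ER, C1, C2, G, P, T = y
            E2 = max(E2, 0.0); ER = max(ER, 0.0); C1 = max(C1, 0.0)
            C2 = max(C2, 0.0); G = max(G, 0.0); P = max(P, 0.0); T = max(T, 0.0)
            B1 = p.b_E2_ER * E2 * ER / (1.0 + E2 + ER)
            B2 = p.b_E2_ER_GREB1 * C1 * G / (1.0 + C1 + G)
            if model_id == "I":
                stim_g = p.stim_GREB1 * C2 / (1.0 + C2)
                stim_t = p.stim_TFF1 * C2 / (1.0 + C2)
            else:  # Model II: GREB1 needs PR too; TFF1 from E2-ER and PR
                stim_g = p.stim_GREB1 * C2 * P / (1.0 + C2 + P)
                stim_t = p.stim_TFF1 * C1 * P / (1.0 + C1 + P)
            stim_p = p.stim_PR * C2 / (1.0 + C2)
            dG = -p.d_GREB1 * G
            if not strict_printed:
                dG -= B2
            if g_on:
                dG += s_G + stim_g
            dP = -p.d_PR * P + (s_P + stim_p if p_on else 0.0)
            dT = -p.d_TFF1 * T + (s_T + stim_t if t_on else 0.0)
            return np.array([
                0.0 if clamp_e2 else -B1,
                s_ER - B1 - p.d_ER * ER,
                B1 - B2 - p.d_E2_ER * C1,
                B2 - p.d_E2_ER_GREB1 * C2,
                dG, dP, dT,
            ])
        return rhs

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        E2, ER, C1, C2, C3, G, P, T = y
        E2 = max(E2, 0.0); ER = max(ER, 0.0); C1 = max(C1, 0.0)
        C2 = max(C2, 0.0); C3 = max(C3, 0.0)
        G = max(G, 0.0); P = max(P, 0.0); T = max(T, 0.0)
        B1 = p.b_E2_ER * E2 * ER / (1.0 + E2 + ER)
        B2 = p.b_E2_ER_PR * C1 * P / (1.0 + C1 + P)
        B3 = p.b_E2_ER_PR_GREB1 * C2 * G / (1.0 + C2 + G)
        stim_g = p.stim_GREB1 * C3 / (1.0 + C3)
        stim_p = p.stim_PR * C3 / (1.0 + C3)
        stim_t = p.stim_TFF1 * C1 * P / (1.0 + C1 + P)
        dG = -B3 - p.d_GREB1 * G + (s_G + stim_g if g_on else 0.0)
        dP = -B2 - p.d_PR * P + (s_P + stim_p if p_on else 0.0)
        dT = -p.d_TFF1 * T + (s_T + stim_t if t_on else 0.0)
        return np.array([
            0.0 if clamp_e2 else -B1,
            s_ER - B1 - p.d_ER * ER,
            B1 - B2 - p.d_E2_ER * C1,
            B2 - B3 - p.d_E2_ER_PR * C2,
            B3 - p.d_E2_ER_PR_GREB1 * C3,
            dG, dP, dT,
        ])
    return rhs


def apply_knockdown(
    model_id: ModelId,
    targets: Collection[str],
    params: SignalingParams,
    **kwargs,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """RHS with all positive terms removed from the knocked-down proteins.

    An siRNA knockdown is modeled as complete loss of the target's synthesis
    and stimulated production; degradation and consumption into complexes
    continue, so the knocked-down protein (and everything depending on it)
    decays from the moment the knockdown is applied.
    """
    return model_rhs(model_id, params, knockdown=targets, **kwargs)


@dataclass
class Trajectory:
    """Time-gridded solution of one signaling (or coupled) simulation."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, n_vars)
    var_names: tuple[str, ...]
    model_id: str
    meta: dict | None = None

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self.var_names.index(name)]

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self, long: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.var_names))
        df.insert(0, "time_h", self.times)
        if long:
            df = df.melt(id_vars="time_h", var_name="variable", value_name="value")
            df["model"] = self.model_id
        return df


def initial_state(
    model_id: ModelId, params: SignalingParams, e2_input: E2Input
) -> np.ndarray:
    """Initial state vector: free proteins at their initial concentrations,
    every E2-containing complex at zero."""
    names = STATE_VARS[model_id]
    init = {
        "E2": e2_input.value,
        "ER": params.ER_init,
        "GREB1": params.GREB1_init,
        "PR": params.PR_init,
        "TFF1": params.TFF1_init,
    }
    return np.array([init.get(n, 0.0) for n in names])


def simulate_signaling(
    model_id: ModelId,
    params: SignalingParams,
    e2_input: E2Input,
    t_grid: np.ndarray,
    y0: np.ndarray | None = None,
    knockdown: Collection[str] = (),
    strict_printed: bool = False,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate one signaling model on ``t_grid`` with LSODA.

    Under ``clamp`` the E2 derivative is zeroed (never reset step-wise) and
    the E2 entry of the initial state is overwritten with the clamp value.
    ``y0`` continues from a previous phase; by default the model starts at
    its derived steady state with the complexes empty.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    if y0 is None:
        y0 = initial_state(model_id, params, e2_input)
    else:
        y0 = np.asarray(y0, dtype=float).copy()
        y0[0] = e2_input.value
    rhs = model_rhs(
        model_id, params, knockdown=knockdown,
        strict_printed=strict_printed, clamp_e2=e2_input.mode == "clamp",
    )
    sol = solve_ivp(
        rhs, (t_grid[0], t_grid[-1]), y0, t_eval=t_grid,
        method="LSODA", rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"signaling integration failed: {sol.message}; "
            f"last state {dict(zip(STATE_VARS[model_id], sol.y[:, -1]))}"
        )
    return Trajectory(
        times=sol.t, states=sol.y.T, var_names=STATE_VARS[model_id],
        model_id=model_id,
        meta={"e2_mode": e2_input.mode, "e2_value": e2_input.value,
              "knockdown": sorted(_validate_targets(knockdown))},
    )


def steady_state(
    model_id: ModelId,
    params: SignalingParams,
    e2_clamp: float,
    knockdown: Collection[str] = (),
    t_max: float = 20000.0,
    residual_tol: float = 1e-8,
) -> np.ndarray:
    """Steady state under a clamped E2 level, found by long integration.

    Integration horizon doubles until the RHS residual (relative to the state
    scale) falls below ``residual_tol``.
    """
    e2 = E2Input.clamp(e2_clamp)
    y = initial_state(model_id, params, e2)
    rhs = model_rhs(model_id, params, knockdown=knockdown, clamp_e2=True)
    t_span = 2000.0
    while True:
        traj = simulate_signaling(
            model_id, params, e2, np.linspace(0, t_span, 50), y0=y,
            knockdown=knockdown,
        )
        y = traj.final.copy()
        scale = max(1.0, float(np.max(np.abs(y))))
        if float(np.max(np.abs(rhs(0.0, y)))) / scale < residual_tol:
            return y
        t_span *= 2
        if t_span > t_max:
            raise RuntimeError(
                f"no steady state reached within {t_max} h under clamp {e2_clamp}"
            )


def observable_totals(traj: Trajectory, model_id: ModelId | None = None) -> pd.DataFrame:
    """Experimentally observed totals: free protein plus protein in complexes.

    GFP-tagged GREB1 and PR are visible whether free or bound, so the
    measured intensity corresponds to ``GREB1 + E2_ER_GREB1`` (Models I/II)
    or ``GREB1 + E2_ER_PR_GREB1`` and ``PR + E2_ER_PR + E2_ER_PR_GREB1``
    (Model III).  TFF1 never enters a complex.
    """
    mid = model_id or traj.model_id
    if mid in ("I", "II"):
        g = traj["GREB1"] + traj["E2_ER_GREB1"]
        p = traj["PR"]
    elif mid == "III":
        g = traj["GREB1"] + traj["E2_ER_PR_GREB1"]
        p = traj["PR"] + traj["E2_ER_PR"] + traj["E2_ER_PR_GREB1"]
    else:
        raise ValueError(f"unknown model {mid!r}")
    return pd.DataFrame(
        {"time_h": traj.times, "GREB1_total": g, "PR_total": p, "TFF1": traj["TFF1"]}
    )
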