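"""CDK1/APC relaxation oscillator, signaling coupling and phase calling.

The cell cycle is represented by the active fractions of CDK1 and APC.  CDK1
is produced at a basal rate, inactivated by active APC, and auto-activates
through a Cdc25-mediated positive feedback; APC is activated by CDK1 and
inactivated at a basal rate.  All regulations are steep Hill functions, which
puts the system in a relaxation-oscillation regime: CDK1 spikes trigger APC
activation, APC destroys CDK1 activity, and the cycle restarts.

Estrogen signaling enters in two places: GREB1 adds a linear CDK1 activation
flux (rate ``k_GREB1``; GREB1 acts through Akt-mediated p21 inactivation) and
the availability of the E2-ERα complex together with PR scales the APC
inactivation term (factor ``r``; both stimulate cyclin D1 production and
thereby G1 exit).  Without E2 the APC inactivation flux vanishes, APC
saturates, CDK1 stays pinned low and the cell arrests in G1.

Phases are read off the two activities: the interior minima of CDK1 mark
mitotic exit (S-G2-M → G1) and an APC threshold — the first APC minimum plus
5 % of the climb to the following maximum — separates G1 (above, falling),
the G1/S transition (below) and S-G2-M (above, rising).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Collection, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .params import CellCycleParams, SignalingParams
from .signaling import (
    E2Input,
    STATE_VARS,
    Trajectory,
    model_rhs,
    initial_state,
)

__all__ = [
    "cycle_rhs",
    "simulate_cycle",
    "coupled_rhs",
    "simulate_coupled",
    "detect_oscillation",
    "OscillationResult",
    "find_limit_cycle",
    "sample_initial_states",
    "classify_phases",
    "PhaseSequence",
    "phase_durations_insilico",
    "PhaseRecord",
]

PHASES = ("G1", "G1S", "SG2M")


def cycle_rhs(
    state: Sequence[float],
    params: CellCycleParams,
    GREB1: float = 0.0,
    E2_ER: float = 0.0,
    PR: float = 1.0,
) -> np.ndarray:
    """Time derivative of (CDK1, APC) given the instantaneous signaling inputs.

    With ``k_GREB1 = 0`` and ``r * E2_ER * PR = 1`` this is exactly the
    uncoupled base oscillator.
    """
    c, a = state
    cc = max(c, 0.0)
    aa = min(max(a, 0.0), 1.0)
    p = params
    hill_a = aa ** p.n1 / (p.K1 ** p.n1 + aa ** p.n1)
    hill_c2 = cc ** p.n2 / (p.K2 ** p.n2 + cc ** p.n2)
    hill_c3 = cc ** p.n3 / (p.K3 ** p.n3 + cc ** p.n3)
    dc = p.a1 - p.b1 * cc * hill_a + p.a3 * (1.0 - cc) * hill_c3 + p.k_GREB1 * GREB1
    da = p.a2 * (1.0 - aa) * hill_c2 - p.r * p.b2 * aa * E2_ER * PR
    return np.array([dc, da])


def simulate_cycle(
    params: CellCycleParams,
    t_grid: np.ndarray,
    y0: Sequence[float] = (0.2, 0.1),
    inputs: tuple[float, float, float] | Callable[[float], tuple[float, float, float]] = (0.0, 1.0, 1.0),
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the two-variable oscillator on ``t_grid``.

    ``inputs`` supplies (GREB1, E2_ER, PR) either as constants or as a
    callable of time (used when the oscillator is driven by a pre-computed
    signaling trajectory).  The default inputs reduce the model to the base
    oscillator.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if callable(inputs):
        def rhs(t, y):
            g, c1, pr = inputs(t)
            return cycle_rhs(y, params, g, c1, pr)
    else:
        g, c1, pr = inputs

        def rhs(t, y):
            return cycle_rhs(y, params, g, c1, pr)

    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), list(y0), t_eval=t_grid,
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"cell cycle integration failed: {sol.message}")
    return Trajectory(sol.t, sol.y.T, ("CDK1", "APC"), "cycle")


def coupled_rhs(
    sig_params: SignalingParams,
    cyc_params: CellCycleParams,
    model_id: str = "III",
    knockdown: Collection[str] = (),
    clamp_e2: bool = False,
    couple_totals: bool = False,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Joint RHS over (signaling state, CDK1, APC); one-way coupling.

    The signaling derivatives never see the cell cycle state; the oscillator
    is fed the instantaneous free-form GREB1, E2_ER and PR (the literal
    coupling variables) or, with ``couple_totals``, the observable totals.
    """
    sig_rhs = model_rhs(model_id, sig_params, knockdown=knockdown, clamp_e2=clamp_e2)
    names = STATE_VARS[model_id]
    i_g, i_c1, i_p = names.index("GREB1"), names.index("E2_ER"), names.index("PR")
    extra: list[tuple[int, ...]] = []
    if couple_totals:
        if model_id == "III":
            extra = [(names.index("E2_ER_PR_GREB1"),),
                     (names.index("E2_ER_PR"), names.index("E2_ER_PR_GREB1"))]
        else:
            extra = [(names.index("E2_ER_GREB1"),), ()]
    n_sig = len(names)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        ys = y[:n_sig]
        g, c1, pr = ys[i_g], ys[i_c1], ys[i_p]
        if couple_totals:
            g = g + sum(ys[i] for i in extra[0])
            pr = pr + sum(ys[i] for i in extra[1])
        dsig = sig_rhs(t, ys)
        dcyc = cycle_rhs(y[n_sig:], cyc_params, max(g, 0.0), max(c1, 0.0), max(pr, 0.0))
        return np.concatenate([dsig, dcyc])

    return rhs


def simulate_coupled(
    sig_params: SignalingParams,
    cyc_params: CellCycleParams,
    e2_input: E2Input,
    t_grid: np.ndarray,
    model_id: str = "III",
    y0_sig: np.ndarray | None = None,
    y0_cyc: Sequence[float] = (0.2, 0.1),
    knockdown: Collection[str] = (),
    couple_totals: bool = False,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the one-way coupled signaling + cell cycle system.

    The coupling is exploited structurally: the signaling layer is integrated
    on its own (so it is bit-identical regardless of the cell cycle state)
    and the oscillator is then driven by the interpolated signaling inputs on
    a dense internal grid.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    from .signaling import simulate_signaling  # local import to avoid cycle

    span = t_grid[-1] - t_grid[0]
    dense = np.unique(np.concatenate([
        t_grid, np.linspace(t_grid[0], t_grid[-1], max(int(span * 10), 2))
    ]))
    sig = simulate_signaling(
        model_id, sig_params, e2_input, dense, y0=y0_sig,
        knockdown=knockdown, rtol=rtol, atol=atol,
    )
    names = STATE_VARS[model_id]
    g = sig["GREB1"].copy()
    pr = sig["PR"].copy()
    if couple_totals:
        if model_id == "III":
            g = g + sig["E2_ER_PR_GREB1"]
            pr = pr + sig["E2_ER_PR"] + sig["E2_ER_PR_GREB1"]
        else:
            g = g + sig["E2_ER_GREB1"]
    c1 = sig["E2_ER"]

    def drive(t: float) -> tuple[float, float, float]:
        return (
            float(np.interp(t, sig.times, g)),
            float(np.interp(t, sig.times, c1)),
            float(np.interp(t, sig.times, pr)),
        )

    cyc = simulate_cycle(cyc_params, t_grid, y0=y0_cyc, inputs=drive,
                         rtol=rtol, atol=atol)
    keep = np.isin(sig.times, t_grid)
    states = np.column_stack([sig.states[keep], cyc.states])
    return Trajectory(
        t_grid, states, tuple(names) + ("CDK1", "APC"), model_id,
        meta={"coupling": "totals" if couple_totals else "free",
              "knockdown": sorted(knockdown), "e2_mode": e2_input.mode},
    )


# ---------------------------------------------------------------------------
# oscillation detection and phase classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OscillationResult:
    oscillates: bool
    period: float | None
    peak_times: np.ndarray

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.oscillates


def detect_oscillation(
    times: np.ndarray,
    values: np.ndarray,
    t_tail: float | None = None,
    amplitude_tol: float = 0.05,
    period_tol: float = 0.10,
    min_peaks: int = 3,
) -> OscillationResult:
    """Decide whether a series shows sustained oscillations in its tail.

    Requires >= ``min_peaks`` maxima in the analysis tail whose peak-to-trough
    amplitude exceeds ``amplitude_tol`` times the observed range and whose
    spacing varies by less than ``period_tol`` relative; the period is the
    mean spacing of those maxima.
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if len(times) < 10:
        raise ValueError("trajectory too short for oscillation analysis")
    if t_tail is None:
        t_tail = (times[-1] - times[0]) / 2.0
    sel = times >= times[-1] - t_tail
    t, v = times[sel], values[sel]
    vrange = float(values.max() - values.min())
    if vrange <= 0:
        return OscillationResult(False, None, np.array([]))
    prom = amplitude_tol * vrange
    peaks, _ = find_peaks(v, prominence=prom)
    peak_times = np.array([_refine_extremum(t, v, int(i)) for i in peaks])
    if len(peaks) < min_peaks:
        return OscillationResult(False, None, peak_times)
    spacing = np.diff(peak_times)
    mean_sp = float(spacing.mean())
    if mean_sp <= 0 or float(np.max(np.abs(spacing - mean_sp))) / mean_sp > period_tol:
        return OscillationResult(False, None, peak_times)
    return OscillationResult(True, mean_sp, peak_times)


def find_limit_cycle(
    cyc_params: CellCycleParams,
    inputs: tuple[float, float, float] = (0.0, 1.0, 1.0),
    y0: Sequence[float] = (0.2, 0.1),
    period_guess: float = 50.0,
    period_agreement: float = 1e-3,
    max_cycles: int = 120,
) -> tuple[Trajectory, float]:
    """Integrate with constant inputs until a stable limit cycle is found.

    A cycle counts as stable once the last two inter-peak spacings agree to
    ``period_agreement`` relative.  Returns the trajectory (whose tail lies on
    the cycle) and the period.  Raises ``RuntimeError`` if no sustained
    oscillation appears (arrest regime).
    """
    n_cyc = 20
    while True:
        horizon = n_cyc * period_guess
        t = np.linspace(0.0, horizon, max(int(horizon * 20), 1000))
        traj = simulate_cycle(cyc_params, t, y0=y0, inputs=inputs)
        osc = detect_oscillation(traj.times, traj["CDK1"], t_tail=horizon * 0.6)
        if osc.oscillates and len(osc.peak_times) >= 4:
            sp = np.diff(osc.peak_times)
            if abs(sp[-1] - sp[-2]) / sp[-1] < period_agreement:
                return traj, float(sp[-1])
        n_cyc *= 2
        if n_cyc > max_cycles:
            raise RuntimeError(
                "no stable limit cycle: the oscillator is in an arrest regime "
                f"for inputs {inputs}"
            )


def sample_initial_states(
    traj: Trajectory,
    period: float,
    n: int,
    seed: int | np.random.Generator,
    var_names: Sequence[str] = ("CDK1", "APC"),
) -> np.ndarray:
    """Sample ``n`` states uniformly along one period of a limit cycle.

    Interpolates the final full period of ``traj`` at uniform random phases,
    emulating an unsynchronized population of cells.
    """
    if period is None or period <= 0:
        raise ValueError("no limit cycle available to sample from")
    t_end = traj.times[-1]
    t0 = t_end - period
    if t0 < traj.times[0]:
        raise ValueError("trajectory shorter than one period")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    offsets = t0 + rng.uniform(0.0, period, size=n)
    cols = []
    for name in var_names:
        cols.append(np.interp(offsets, traj.times, traj[name]))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# phase classification
# ---------------------------------------------------------------------------

@dataclass
class PhaseSequence:
    """Per-timepoint phase labels with the transition bookkeeping."""

    times: np.ndarray
    phases: np.ndarray  # array of {"G1","G1S","SG2M"} strings
    transition_indices: list[int]
    transition_times: list[float]
    transition_kinds: list[str]  # "division" | "g1_to_g1s" | "g1s_to_sg2m"
    apc_threshold: float | None
    arrest: bool = False

    def __len__(self) -> int:
        return len(self.times)


def _refine_extremum(t: np.ndarray, v: np.ndarray, i: int) -> float:
    """Quadratic refinement of an interior extremum around grid index ``i``."""
    if i <= 0 or i >= len(t) - 1:
        return float(t[i])
    t0, t1, t2 = t[i - 1], t[i], t[i + 1]
    v0, v1, v2 = v[i - 1], v[i], v[i + 1]
    denom = (v0 - 2 * v1 + v2)
    if denom == 0:
        return float(t1)
    # vertex of the parabola through three equally/unequally spaced points
    dt = 0.5 * ((v0 - v2) / denom) * ((t2 - t0) / 2.0)
    lo, hi = min(t0, t2), max(t0, t2)
    return float(min(max(t1 + dt, lo), hi))


def _cross_time(t0, t1, v0, v1, thr) -> float:
    if v1 == v0:
        return float(t0)
    return float(t0 + (thr - v0) * (t1 - t0) / (v1 - v0))


def classify_phases(
    times: np.ndarray,
    cdk1: np.ndarray,
    apc: np.ndarray,
    prominence_frac: float = 0.05,
) -> PhaseSequence:
    """Assign G1 / G1S / SG2M per timepoint from the CDK1 and APC activities.

    Interior CDK1 minima mark mitotic exit (S-G2-M → G1).  The APC threshold
    is frozen once, at the first interior APC minimum plus 5 % of the rise to
    the following APC maximum; a downward APC crossing starts the G1/S
    transition and an upward crossing starts S-G2-M.  Without interior
    extrema the cell is reported as arrested (single-phase sequence).
    """
    times = np.asarray(times, float)
    cdk1 = np.asarray(cdk1, float)
    apc = np.asarray(apc, float)
    n = len(times)
    c_prom = prominence_frac * max(float(cdk1.max() - cdk1.min()), 1e-12)
    a_prom = prominence_frac * max(float(apc.max() - apc.min()), 1e-12)
    cdk1_minima, _ = find_peaks(-cdk1, prominence=c_prom)
    apc_minima, _ = find_peaks(-apc, prominence=a_prom)
    apc_maxima, _ = find_peaks(apc, prominence=a_prom)

    if len(apc_minima) == 0 or len(apc_maxima) == 0:
        # arrest: no complete G1->G1S->SG2M machinery visible; sustained low
        # CDK1 activity is the G1-arrest signature
        phase = "G1" if cdk1[-1] < 0.5 else "SG2M"
        return PhaseSequence(times, np.array([phase] * n), [], [], [], None, arrest=True)

    i_min = int(apc_minima[0])
    later_max = apc_maxima[apc_maxima > i_min]
    if len(later_max) == 0:
        return PhaseSequence(times, np.array(["G1"] * n), [], [], [], None, arrest=True)
    i_max = int(later_max[0])
    threshold = float(apc[i_min] + 0.05 * (apc[i_max] - apc[i_min]))

    events: list[tuple[float, int, str]] = []
    for i in cdk1_minima:
        events.append((_refine_extremum(times, cdk1, int(i)), int(i), "division"))
    below = apc < threshold
    for i in range(1, n):
        if below[i] and not below[i - 1]:
            events.append((_cross_time(times[i - 1], times[i], apc[i - 1], apc[i], threshold), i, "g1_to_g1s"))
        elif not below[i] and below[i - 1]:
            events.append((_cross_time(times[i - 1], times[i], apc[i - 1], apc[i], threshold), i, "g1s_to_sg2m"))
    events.sort(key=lambda e: e[0])
    if not events:
        return PhaseSequence(times, np.array(["G1"] * n), [], [], [], threshold, arrest=True)

    before = {"division": "SG2M", "g1_to_g1s": "G1", "g1s_to_sg2m": "G1S"}
    after = {"division": "G1", "g1_to_g1s": "G1S", "g1s_to_sg2m": "SG2M"}
    phases = np.empty(n, dtype=object)
    cur = before[events[0][2]]
    ev_iter = iter(events)
    nxt = next(ev_iter)
    for i in range(n):
        while nxt is not None and times[i] >= nxt[0]:
            cur = after[nxt[2]]
            nxt = next(ev_iter, None)
        phases[i] = cur
    return PhaseSequence(
        times, phases.astype(str),
        transition_indices=[e[1] for e in events],
        transition_times=[e[0] for e in events],
        transition_kinds=[e[2] for e in events],
        apc_threshold=threshold,
    )


@dataclass(frozen=True)
class PhaseRecord:
    cycle_index: int
    phase: str
    start_h: float
    end_h: float

    @property
    def duration_h(self) -> float:
        return self.end_h - self.start_h


def phase_durations_insilico(seq: PhaseSequence) -> list[PhaseRecord]:
    """Durations of the phases whose start and end both lie in the window.

    Phases are delimited by consecutive transition events; the leading and
    trailing (censored) stretches of the simulation are not reported.  Cycle
    indexing advances at each division event.
    """
    after = {"division": "G1", "g1_to_g1s": "G1S", "g1s_to_sg2m": "SG2M"}
    records: list[PhaseRecord] = []
    cycle = 0
    evs = list(zip(seq.transition_times, seq.transition_kinds))
    for (t0, k0), (t1, _k1) in zip(evs, evs[1:]):
        if k0 == "division":
            cycle += 1
        records.append(PhaseRecord(cycle, after[k0], float(t0), float(t1)))
    return records
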