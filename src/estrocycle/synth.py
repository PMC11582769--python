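"""Seeded generators for every input class the analysis consumes.

Three generators produce (a) population-level dose–time expression tables
with multiplicative replicate noise, (b) single-cell FUCCI tracking tables
with scripted divisions and phase-dependent Cdt1/Geminin expression, and
(c) label-image movies of drifting elliptical nuclei with known lineage.
Each generator is bit-reproducible under its seed and returns the ground
truth needed to score the downstream module without any external data.

The FUCCI intensity shapes are piecewise-linear templates keyed to the
scripted phase, not a mechanistic Cdt1/Geminin model: Cdt1 is high through
G1 and decays across the G1/S transition, Geminin rises from the G1/S entry
through S-G2-M and crashes at division (the drop that the division detector
keys on), and the cell is colorless for one frame after mitosis.  The
template levels near each phase boundary are calibrated so that the
pipeline's centered 10-sample smoothing leaves the recovered boundary within
one frame of the scripted one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.draw import ellipse

from .params import SignalingParams
from .signaling import E2Input, observable_totals, simulate_signaling

__all__ = [
    "SynthConfig",
    "gen_expression_data",
    "gen_fucci_tracks",
    "gen_label_movie",
    "FUCCI_TEMPLATE",
]


@dataclass(frozen=True)
class SynthConfig:
    """Shared generator configuration (all generators are seeded)."""

    seed: int = 0
    # expression tables
    doses_nm: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0)
    timepoints_h: tuple[float, ...] = tuple(float(t) for t in range(0, 56))
    replicates: int = 3
    noise_sigma: float = 0.1  # multiplicative lognormal sigma
    # FUCCI tracks
    frame_interval_h: float = 0.5
    n_frames: int = 96  # 48 h imaging window
    n_founders: int = 6
    g1_frames: int = 32
    g1s_frames: int = 16
    sg2m_frames: int = 48
    fucci_noise_sigma: float = 0.0
    intensity_scale: float = 1000.0
    # label movies
    field_shape: tuple[int, int] = (128, 128)
    n_nuclei: int = 3
    radii_px: tuple[float, float] = (7.0, 10.0)
    drift_px: float = 2.0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0 or self.fucci_noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if any(d < 0 for d in self.doses_nm):
            raise ValueError("doses must be >= 0")


# ---------------------------------------------------------------------------
# (a) population expression tables
# ---------------------------------------------------------------------------

def gen_expression_data(
    model_id: str,
    params: SignalingParams | None = None,
    config: SynthConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Dose–time observable-intensity table with lognormal replicate noise.

    Each dose is simulated as an exposure experiment (steady-state start, E2
    spiked to the effective dose, free depletion); the observable totals are
    multiplied per replicate by ``exp(sigma * z)`` noise.  Returns the long
    table and the ground truth (parameters and noiseless trajectories).
    """
    params = params or SignalingParams()
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    t_grid = np.asarray(config.timepoints_h, float)
    rows = []
    truth_curves = {}
    for dose in config.doses_nm:
        eff = params.dose_map.get(float(dose), None)
        if eff is None:
            eff = params.effective_dose(float(dose))
        traj = simulate_signaling(model_id, params, E2Input.free(eff), t_grid)
        obs = observable_totals(traj, model_id)
        truth_curves[float(dose)] = obs
        for reporter, col in (("GREB1", "GREB1_total"), ("PR", "PR_total"), ("TFF1", "TFF1")):
            clean = obs[col].to_numpy()
            for rep in range(1, config.replicates + 1):
                noise = (
                    np.exp(rng.normal(0.0, config.noise_sigma, size=len(clean)))
                    if config.noise_sigma > 0 else 1.0
                )
                vals = clean * noise
                rows.extend(
                    {"time_h": float(t), "nominal_dose_nM": float(dose),
                     "replicate": rep, "reporter": reporter, "value": float(v)}
                    for t, v in zip(t_grid, vals)
                )
    table = pd.DataFrame(rows)
    truth = {"params": params, "model_id": model_id, "curves": truth_curves,
             "noise_sigma": config.noise_sigma}
    return table, truth


# ---------------------------------------------------------------------------
# (b) FUCCI tracks
# ---------------------------------------------------------------------------

#: Piecewise-linear template levels (normalized intensity units).  The
#: boundary-adjacent constants are calibrated against the pipeline's
#: centered-window smoothing (see module docstring):
#:  * ``g1_gem`` sets how far below the co-expression band G1 sits,
#:  * ``g1s_cdt1_end`` / ``sg2m_cdt1`` bracket the upward ratio crossing,
#:  * ``cdt1_rise_frames`` delays the daughter's Cdt1 accumulation so the
#:    post-mitotic blend resolves within a frame of the scripted division.
FUCCI_TEMPLATE: dict[str, float] = {
    "g1_cdt1": 0.55,
    "g1_gem": 0.0030,
    "g1s_gem_start": 0.0060,
    "g1s_gem_mid": 0.025,    # level after the slow entry ramp
    "g1s_gem_knee": 0.3,     # fraction of G1/S where the slow entry ends
    "g1s_gem_end": 0.35,
    "g1s_cdt1_mid": 0.004,   # level after the fast early decay
    "g1s_cdt1_knee": 0.6,    # fraction of G1/S where the fast decay ends
    "g1s_cdt1_end": 0.003,
    "sg2m_gem_end": 0.80,
    "sg2m_cdt1": 0.0018,
    "grey_level": 0.0005,
    "cdt1_delay_frames": 4,  # colorless lag before the daughter's Cdt1 rise
    "cdt1_rise_frames": 8,
    "hoechst_base": 0.4,
    "area_base": 0.5,
}


def _fucci_intensity(phase: str, u: float, frames_since_birth: int,
                     tpl: dict[str, float]) -> tuple[float, float]:
    """(cdt1, geminin) template value at fraction ``u`` through ``phase``."""
    if phase == "grey":
        return tpl["grey_level"], tpl["grey_level"]
    if phase == "G1":
        k = frames_since_birth - tpl["cdt1_delay_frames"]
        rise = min(max(k, 0) / max(tpl["cdt1_rise_frames"], 1), 1.0)
        cdt1 = tpl["grey_level"] + (tpl["g1_cdt1"] - tpl["grey_level"]) * rise
        return cdt1, tpl["g1_gem"]
    if phase == "G1S":
        gk = tpl["g1s_gem_knee"]
        if u < gk:  # slow entry so the smoothed ratio crossing stays put
            gem = tpl["g1s_gem_start"] + (tpl["g1s_gem_mid"] - tpl["g1s_gem_start"]) * (u / gk)
        else:
            gem = tpl["g1s_gem_mid"] + (tpl["g1s_gem_end"] - tpl["g1s_gem_mid"]) * ((u - gk) / (1 - gk))
        knee = tpl["g1s_cdt1_knee"]
        if u < knee:  # fast decay, finished well before the S-G2-M boundary
            cdt1 = tpl["g1_cdt1"] + (tpl["g1s_cdt1_mid"] - tpl["g1_cdt1"]) * (u / knee)
        else:  # slow taper across the upward ratio crossing
            v = (u - knee) / (1.0 - knee)
            cdt1 = tpl["g1s_cdt1_mid"] + (tpl["g1s_cdt1_end"] - tpl["g1s_cdt1_mid"]) * v
        return cdt1, gem
    if phase == "SG2M":
        gem = tpl["g1s_gem_end"] + (tpl["sg2m_gem_end"] - tpl["g1s_gem_end"]) * u
        return tpl["sg2m_cdt1"], gem
    raise ValueError(phase)


def gen_fucci_tracks(
    config: SynthConfig | None = None,
    template: dict[str, float] | None = None,
    founder_offsets: tuple[int, ...] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scripted FUCCI tracking table plus per-sample ground truth.

    Each founder runs the G1 → G1/S → S-G2-M cycle from a (seeded or given)
    starting offset; at the end of S-G2-M the Geminin signal crashes and two
    daughters continue, each colorless for one frame.  Returns ``(tracks,
    truth)`` where ``tracks`` has the tracker-export schema (``track_id,
    parent_id, frame, time_h, cdt1, geminin, hoechst, area``; raw intensity
    scale) and ``truth`` adds the scripted ``true_phase`` per sample (the
    colorless frame carries the G1 label of the following sample).
    """
    config = config or SynthConfig()
    tpl = dict(FUCCI_TEMPLATE)
    if template:
        tpl.update(template)
    rng = np.random.default_rng(config.seed)
    cycle = config.g1_frames + config.g1s_frames + config.sg2m_frames
    if founder_offsets is None:
        # founders divided before imaging started: skip the post-mitotic
        # Cdt1 accumulation window so the first frame shows a settled readout
        lo = int(tpl["cdt1_delay_frames"] + tpl["cdt1_rise_frames"])
        founder_offsets = tuple(int(v) for v in rng.integers(min(lo, cycle - 1), cycle, config.n_founders))

    def pos_to_phase(pos: int) -> tuple[str, float]:
        if pos < config.g1_frames:
            return "G1", pos / config.g1_frames
        pos -= config.g1_frames
        if pos < config.g1s_frames:
            return "G1S", pos / config.g1s_frames
        pos -= config.g1s_frames
        return "SG2M", pos / config.sg2m_frames

    rows = []
    next_id = [1]

    def emit(track_id, parent_id, start_frame, cycle_pos, frames_since_birth, grey_first):
        """March one track segment forward; spawn daughters at division."""
        f = start_frame
        pos = cycle_pos
        fsb = frames_since_birth
        first = grey_first
        while f < config.n_frames:
            if first:
                phase, u, true_phase = "grey", 0.0, "G1"
                first = False
            else:
                phase, u = pos_to_phase(pos)
                true_phase = phase
                pos += 1
            cdt1, gem = _fucci_intensity(phase, u, fsb, tpl)
            hoechst = tpl["hoechst_base"] + 0.3 * (pos / cycle)
            area = tpl["area_base"] + 0.3 * (pos / cycle)
            if config.fucci_noise_sigma > 0:
                cdt1 *= float(np.exp(rng.normal(0, config.fucci_noise_sigma)))
                gem *= float(np.exp(rng.normal(0, config.fucci_noise_sigma)))
            rows.append({
                "track_id": track_id, "parent_id": parent_id, "frame": f,
                "time_h": f * config.frame_interval_h,
                "cdt1": cdt1 * config.intensity_scale,
                "geminin": gem * config.intensity_scale,
                "hoechst": hoechst * config.intensity_scale,
                "area": 100.0 + 100.0 * area,
                "true_phase": true_phase,
            })
            f += 1
            fsb += 1
            if pos >= cycle:  # division: two daughters, colorless first frame
                for _ in range(2):
                    did = next_id[0]
                    next_id[0] += 1
                    emit(did, track_id, f, 0, 0, True)
                return

    for _ in range(config.n_founders):
        fid = next_id[0]
        next_id[0] += 1
    founder_ids = list(range(1, config.n_founders + 1))
    for fid, off in zip(founder_ids, founder_offsets):
        emit(fid, np.nan, 0, int(off), int(off), False)

    truth = pd.DataFrame(rows).sort_values(["track_id", "frame"]).reset_index(drop=True)
    tracks = truth.drop(columns=["true_phase"])
    return tracks, truth


# ---------------------------------------------------------------------------
# (c) label movies
# ---------------------------------------------------------------------------

def gen_label_movie(
    config: SynthConfig | None = None,
    splits: tuple[tuple[int, int], ...] = (),
    drift_px: float | None = None,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Label-image sequence of drifting elliptical nuclei with known lineage.

    ``splits`` lists ``(nucleus_index, frame)`` events: at that frame the
    nucleus is replaced by two daughters that separate along x.  Nuclei are
    placed on a grid with random jitter; a configuration whose ellipses would
    overlap raises instead of silently merging.  Returns the frame stack and
    the ground-truth table (frame, nucleus_id, parent, y, x).
    """
    config = config or SynthConfig()
    drift = config.drift_px if drift_px is None else drift_px
    rng = np.random.default_rng(config.seed)
    h, w = config.field_shape
    ry, rx = config.radii_px
    n = config.n_nuclei
    # grid placement with jitter, margins generous enough for drift
    grid = int(np.ceil(np.sqrt(n)))
    ys = np.linspace(h * 0.25, h * 0.75, grid)
    xs = np.linspace(w * 0.25, w * 0.75, grid)
    centers = [(float(ys[i // grid]), float(xs[i % grid])) for i in range(n)]
    centers = [
        (y + float(rng.uniform(-3, 3)), x + float(rng.uniform(-3, 3)))
        for y, x in centers
    ]
    velocities = [
        (float(rng.uniform(-drift, drift)), float(rng.uniform(-drift, drift)))
        for _ in range(n)
    ]
    split_at = {idx: frame for idx, frame in splits}

    # nucleus registry: id -> dict(center, vel, parent, born, alive)
    nuclei = {
        i + 1: {"c": centers[i], "v": velocities[i], "parent": None, "alive": True}
        for i in range(n)
    }
    next_id = n + 1
    stack: list[np.ndarray] = []
    rows = []
    for f in range(config.n_frames):
        # apply scripted splits
        for idx, frame in list(split_at.items()):
            if frame == f and idx in nuclei and nuclei[idx]["alive"]:
                mother = nuclei[idx]
                mother["alive"] = False
                cy, cx = mother["c"]
                for sgn in (-1.0, 1.0):
                    nuclei[next_id] = {
                        "c": (cy, cx + sgn * (rx + 2.0)),
                        "v": (mother["v"][0], mother["v"][1] + sgn * 0.5),
                        "parent": idx, "alive": True,
                    }
                    next_id += 1
        img = np.zeros((h, w), dtype=np.int32)
        for nid, nu in nuclei.items():
            if not nu["alive"]:
                continue
            cy, cx = nu["c"]
            rr, cc = ellipse(cy, cx, ry, rx, shape=(h, w))
            if np.any(img[rr, cc] != 0):
                raise ValueError(
                    f"nuclei overlap at frame {f}: geometry too dense for the field"
                )
            img[rr, cc] = nid
            rows.append({"frame": f, "nucleus_id": nid, "parent": nu["parent"],
                         "y": cy, "x": cx})
            nu["c"] = (cy + nu["v"][0], cx + nu["v"][1])
        stack.append(img)
    return stack, pd.DataFrame(rows)
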