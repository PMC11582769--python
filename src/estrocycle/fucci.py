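"""Single-cell FUCCI track processing: lineages, phase calls and durations.

FUCCI reporter cells carry red-tagged Cdt1 (present in G1) and green-tagged
Geminin (present through S/G2/M); co-expression marks the G1/S transition and
a colorless frame follows mitosis.  This module turns raw tracker output into
per-timepoint cell cycle phases and censoring-aware phase durations:

1.  lineage relabeling (dotted IDs: mother ``1`` → daughters ``1.1``/``1.2``)
    and construction of one "family" track per final-generation descendant;
2.  track filtering (short childless tracks, short families, families with
    implausibly many divisions);
3.  min-max normalization per channel, rolling-mean smoothing, division
    detection from sharp Geminin drops;
4.  phase assignment from the log10 Geminin:Cdt1 ratio with sentinel values
    for degenerate intensities, plus two rule-based corrections (transient
    flips, forbidden mitotic G1/S);
5.  duration quantification with parental-duplicate removal and censoring of
    phases that touch the observation window;
6.  condition comparison with Welch's ANOVA and Games–Howell post-hoc tests.

Tables are long-format pandas DataFrames throughout; a track segment is
identified by ``track_id`` (+ ``parent_id``), a relabeled segment by its
dotted ``lineage_id`` and a family by the dotted ID of its leaf.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "relabel_lineages",
    "build_family_tracks",
    "filter_tracks",
    "minmax_normalize",
    "normalize_channels",
    "rolling_mean",
    "detect_divisions",
    "compute_log_ratio",
    "assign_phases",
    "correct_transient_flips",
    "correct_mitotic_g1s",
    "call_phases",
    "quantify_phase_durations",
    "compare_conditions",
    "link_tracks",
    "process_tracks",
    "LOG_RATIO_SENTINEL",
    "INTENSITY_EPS",
]

LOG_RATIO_SENTINEL = 100.0
INTENSITY_EPS = 1e-4  # degenerate-intensity cutoff on min-max normalized scale
PHASES = ("G1", "G1S", "SG2M")


# ---------------------------------------------------------------------------
# lineage relabeling and family tracks
# ---------------------------------------------------------------------------

def relabel_lineages(tracks: pd.DataFrame) -> pd.DataFrame:
    """Assign dotted lineage IDs from ``track_id``/``parent_id`` links.

    Roots keep their integer ID as a string; the k-th daughter of lineage
    ``L`` becomes ``L.k`` (daughters ordered by first frame, then track id).
    Raises on cyclic parent links.
    """
    req = {"track_id", "parent_id", "frame"}
    if not req <= set(tracks.columns):
        raise ValueError(f"tracks table lacks columns: {sorted(req - set(tracks.columns))}")
    first_frame = tracks.groupby("track_id")["frame"].min()
    parent_of: dict = (
        tracks.dropna(subset=["parent_id"])
        .groupby("track_id")["parent_id"].first().to_dict()
    )
    children: dict = {}
    for tid, pid in parent_of.items():
        children.setdefault(pid, []).append(tid)
    for pid in children:
        children[pid].sort(key=lambda t: (first_frame.get(t, np.inf), str(t)))

    lineage: dict = {}

    def resolve(tid, stack=()):
        if tid in lineage:
            return lineage[tid]
        if tid in stack:
            raise ValueError(f"cyclic parent links involving track {tid!r}")
        pid = parent_of.get(tid)
        if pid is None or pd.isna(pid):
            name = str(int(tid)) if float(tid) == int(tid) else str(tid)
        else:
            k = children[pid].index(tid) + 1
            name = f"{resolve(pid, stack + (tid,))}.{k}"
        lineage[tid] = name
        return name

    out = tracks.copy()
    out["lineage_id"] = [resolve(t) for t in out["track_id"]]
    return out


def _ancestor_chain(lineage_id: str) -> list[str]:
    parts = lineage_id.split(".")
    return [".".join(parts[: i + 1]) for i in range(len(parts))]


def build_family_tracks(relabeled: pd.DataFrame) -> pd.DataFrame:
    """One family track per final-generation descendant.

    A family contains the samples of every ancestor followed by the leaf's
    own, time-ordered; ancestor samples are therefore repeated across the
    families of sibling leaves.
    """
    present = set(relabeled["lineage_id"].unique())
    parents_with_children = {lid.rsplit(".", 1)[0] for lid in present if "." in lid}
    leaves = sorted(present - parents_with_children)
    groups = {lid: grp for lid, grp in relabeled.groupby("lineage_id")}
    frames = []
    for leaf in leaves:
        chain = [lid for lid in _ancestor_chain(leaf) if lid in groups]
        fam = pd.concat([groups[lid] for lid in chain], ignore_index=True)
        fam = fam.sort_values("frame").reset_index(drop=True)
        fam["family_id"] = leaf
        frames.append(fam)
    if not frames:
        return relabeled.iloc[0:0].assign(family_id=pd.Series(dtype=str))
    return pd.concat(frames, ignore_index=True)


def filter_tracks(
    relabeled: pd.DataFrame,
    min_track_len: int = 5,
    min_family_len: int = 31,
    max_divisions: int = 4,
) -> tuple[pd.DataFrame, dict]:
    """Apply the three track-quality rules in order; returns families + audit.

    1. drop track segments shorter than ``min_track_len`` samples that have
       no descendants (appear-and-vanish objects);
    2. build family tracks and drop those with fewer than ``min_family_len``
       samples (i.e. 30 timepoints or less with the defaults);
    3. drop families whose Geminin trace shows more than ``max_divisions``
       divisions.
    """
    audit = {}
    present = set(relabeled["lineage_id"].unique())
    parents_with_children = {lid.rsplit(".", 1)[0] for lid in present if "." in lid}
    sizes = relabeled.groupby("lineage_id").size()
    short_childless = {
        lid for lid, n in sizes.items()
        if n < min_track_len and lid not in parents_with_children
    }
    step1 = relabeled[~relabeled["lineage_id"].isin(short_childless)]
    audit["removed_short_childless"] = len(short_childless)

    families = build_family_tracks(step1)
    fam_sizes = families.groupby("family_id").size()
    short_families = set(fam_sizes[fam_sizes < min_family_len].index)
    families = families[~families["family_id"].isin(short_families)]
    audit["removed_short_families"] = len(short_families)

    too_many = set()
    for fid, grp in families.groupby("family_id"):
        n_div = len(detect_divisions(grp.sort_values("frame")["geminin"].to_numpy()))
        if n_div > max_divisions:
            too_many.add(fid)
    families = families[~families["family_id"].isin(too_many)].reset_index(drop=True)
    audit["removed_many_divisions"] = len(too_many)
    audit["n_families_retained"] = families["family_id"].nunique()
    return families, audit


# ---------------------------------------------------------------------------
# normalization, smoothing, divisions
# ---------------------------------------------------------------------------

def minmax_normalize(values) -> np.ndarray:
    """Min-max normalization to [0, 1]; rejects constant input."""
    x = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi <= lo:
        raise ValueError("constant channel: min-max normalization is degenerate")
    return (x - lo) / (hi - lo)


def normalize_channels(
    df: pd.DataFrame, channels=("cdt1", "geminin", "hoechst", "area")
) -> pd.DataFrame:
    """Min-max normalize each readout channel over the whole experiment."""
    out = df.copy()
    for ch in channels:
        if ch in out.columns:
            out[ch] = minmax_normalize(out[ch].to_numpy())
    return out


def rolling_mean(series, window: int, mode: str = "centered") -> np.ndarray:
    """Rolling mean with partial windows at the edges.

    ``centered`` places an even window with ``window//2`` samples to the left
    and ``window//2 - 1`` to the right of the focal sample; ``trailing`` uses
    the current and previous ``window - 1`` samples.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    s = pd.Series(np.asarray(series, dtype=float))
    if mode == "centered":
        out = s.rolling(window, center=True, min_periods=1).mean()
    elif mode == "trailing":
        out = s.rolling(window, min_periods=1).mean()
    else:
        raise ValueError(f"unknown rolling mode {mode!r}")
    return out.to_numpy()


def detect_divisions(geminin, sd_factor: float = 0.5) -> np.ndarray:
    """Indices of division events from sharp Geminin drops.

    Geminin is smoothed with a trailing window of 2; a division is flagged at
    sample ``i+1`` whenever the consecutive difference drops below
    ``-sd_factor`` times the standard deviation of the smoothed trace
    (computed over the whole track).
    """
    g = np.asarray(geminin, dtype=float)
    if len(g) < 3:
        return np.array([], dtype=int)
    sm = rolling_mean(g, 2, mode="trailing")
    d = np.diff(sm)
    sd = float(np.std(sm))
    if sd == 0:
        return np.array([], dtype=int)
    flags = np.where(d < -sd_factor * sd)[0] + 1
    if len(flags) == 0:
        return flags
    # the 2-sample smoothing spreads one crash over consecutive differences;
    # adjacent flags belong to the same division event
    keep = np.concatenate([[True], np.diff(flags) > 1])
    return flags[keep]


# ---------------------------------------------------------------------------
# phase assignment
# ---------------------------------------------------------------------------

def compute_log_ratio(geminin, cdt1) -> np.ndarray:
    """log10(Geminin/Cdt1) with sentinels for degenerate intensities.

    -100 when Geminin is zero, or both readouts sit below the 1e-4 detection
    floor; +100 when Cdt1 is zero while Geminin is measurable.  (A zero Cdt1
    with Geminin at or below the floor is treated as colorless, -100.)
    """
    g = np.asarray(geminin, dtype=float)
    c = np.asarray(cdt1, dtype=float)
    r = np.empty_like(g)
    neg = (g == 0) | ((g < INTENSITY_EPS) & (c < INTENSITY_EPS))
    pos = ~neg & (c == 0)
    rest = ~neg & ~pos
    r[neg] = -LOG_RATIO_SENTINEL
    r[pos] = LOG_RATIO_SENTINEL
    with np.errstate(divide="ignore"):
        r[rest] = np.log10(g[rest] / c[rest])
    return r


def assign_phases(log_ratio, cdt1, geminin) -> np.ndarray:
    """Per-sample phase from the log ratio and the smoothed readouts.

    G1/S takes precedence whenever |r| < 2 and r is not a sentinel (the
    yellow co-expression state); otherwise the dominant readout decides, with
    the sentinels mapping to pure G1 (red) or pure S-G2-M (green).  An
    unassignable sample carries the previous phase forward.
    """
    r = np.asarray(log_ratio, dtype=float)
    c = np.asarray(cdt1, dtype=float)
    g = np.asarray(geminin, dtype=float)
    n = len(r)
    phases = np.empty(n, dtype=object)
    prev = "G1"
    n_carried = 0
    for i in range(n):
        if r[i] == -LOG_RATIO_SENTINEL:
            phases[i] = "G1"
        elif r[i] == LOG_RATIO_SENTINEL:
            phases[i] = "SG2M"
        elif abs(r[i]) < 2.0:
            phases[i] = "G1S"
        elif c[i] > g[i]:
            phases[i] = "G1"
        elif g[i] > c[i]:
            phases[i] = "SG2M"
        else:
            phases[i] = prev
            n_carried += 1
        prev = phases[i]
    if n_carried:
        warnings.warn(f"{n_carried} unassignable samples carried the previous phase")
    return phases.astype(str)


def correct_transient_flips(phases, max_len: int = 4) -> np.ndarray:
    """Overwrite phase excursions that revert within ``max_len`` samples.

    A departure from a stable phase that returns to the same phase within at
    most ``max_len`` samples (possibly visiting several phases on the way) is
    replaced by the flanking phase; applied left-to-right until fixpoint.
    """
    ph = np.asarray(phases, dtype=object).copy()
    n = len(ph)
    changed = True
    while changed:
        changed = False
        i = 1
        while i < n:
            if ph[i] != ph[i - 1]:
                base = ph[i - 1]
                for j in range(i + 1, min(i + max_len, n - 1) + 1):
                    if ph[j] == base:
                        ph[i:j] = base
                        changed = True
                        break
                i = max(i, 1)
            i += 1
    return ph.astype(str)


def correct_mitotic_g1s(phases) -> tuple[np.ndarray, int]:
    """Forbid the S-G2-M → G1/S → G1 path across mitosis.

    A G1/S run immediately after S-G2-M that resolves into G1 is an artifact
    of the ratio passing through the co-expression band during mitosis and is
    relabeled G1.  A direct S-G2-M → G1/S → S-G2-M excursion is legal and a
    trailing (unresolved) G1/S at the end of a track is left as-is; the count
    of unresolved runs is returned alongside.
    """
    ph = np.asarray(phases, dtype=object).copy()
    n = len(ph)
    unresolved = 0
    i = 1
    while i < n:
        if ph[i] == "G1S" and ph[i - 1] == "SG2M":
            j = i
            while j < n and ph[j] == "G1S":
                j += 1
            if j < n and ph[j] == "G1":
                ph[i:j] = "G1"
            elif j >= n:
                unresolved += 1
            i = j
        else:
            i += 1
    return ph.astype(str), unresolved


def call_phases(
    family: pd.DataFrame,
    smooth_window: int = 10,
) -> pd.DataFrame:
    """Full phase calling for one (already normalized) family track.

    Readouts are smoothed with a centered window of ``smooth_window``, the
    log Geminin:Cdt1 ratio is computed, phases assigned and both corrections
    applied; division events come from the raw (trailing-2 smoothed) Geminin
    trace.  Returns the family table with ``cdt1_s, geminin_s, log_ratio,
    phase, division`` columns added.
    """
    fam = family.sort_values("frame").reset_index(drop=True).copy()
    cs = rolling_mean(fam["cdt1"].to_numpy(), smooth_window, "centered")
    gs = rolling_mean(fam["geminin"].to_numpy(), smooth_window, "centered")
    r = compute_log_ratio(gs, cs)
    ph = assign_phases(r, cs, gs)
    ph = correct_transient_flips(ph)
    ph, _ = correct_mitotic_g1s(ph)
    div = np.zeros(len(fam), dtype=bool)
    div[detect_divisions(fam["geminin"].to_numpy())] = True
    fam["cdt1_s"] = cs
    fam["geminin_s"] = gs
    fam["log_ratio"] = r
    fam["phase"] = ph
    fam["division"] = div
    return fam


# ---------------------------------------------------------------------------
# durations and statistics
# ---------------------------------------------------------------------------

def quantify_phase_durations(
    called_families: pd.DataFrame,
    frame_interval_h: float,
    min_subtrack_len: int = 6,
) -> tuple[pd.DataFrame, dict]:
    """Phase durations per family with duplicate removal and censoring.

    Ancestor samples repeat across sibling families; each track segment is
    counted once (assigned to the lexicographically first family that
    contains it) and the remaining subtracks of 5 or fewer samples are
    dropped.  A run of ``k`` samples lasts ``k * frame_interval_h``; runs
    touching a subtrack boundary are censored and excluded from summaries but
    retained with ``censored=True``.
    """
    rows = []
    used: set = set()
    n_short = 0
    for fid in sorted(called_families["family_id"].unique()):
        fam = called_families[called_families["family_id"] == fid].sort_values("frame")
        fresh = fam[~fam["lineage_id"].isin(used)]
        used |= set(fam["lineage_id"].unique())
        if len(fresh) == 0:
            continue
        if len(fresh) < min_subtrack_len:
            n_short += 1
            continue
        ph = fresh["phase"].to_numpy()
        # run-length encode
        change = np.flatnonzero(ph[1:] != ph[:-1]) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(ph)]])
        for s, e in zip(starts, ends):
            censored = (s == 0) or (e == len(ph))
            rows.append({
                "family_id": fid,
                "phase": ph[s],
                "n_samples": int(e - s),
                "duration_h": float((e - s) * frame_interval_h),
                "censored": bool(censored),
            })
    durations = pd.DataFrame(
        rows, columns=["family_id", "phase", "n_samples", "duration_h", "censored"]
    )
    audit = {
        "n_subtracks_too_short": n_short,
        "n_records": len(durations),
        "n_complete": int((~durations["censored"]).sum()) if len(durations) else 0,
    }
    return durations, audit


def compare_conditions(
    durations: pd.DataFrame,
    condition_col: str = "condition",
    min_records: int = 2,
) -> dict:
    """Welch one-way ANOVA + Games–Howell pairwise tests per phase.

    Only complete (non-censored) durations enter; conditions with fewer than
    ``min_records`` complete records for a phase are skipped with a notice.
    """
    import pingouin as pg

    data = durations[~durations["censored"]] if "censored" in durations.columns else durations
    report: dict = {"phases": {}, "notices": []}
    for phase in sorted(data["phase"].unique()):
        sub = data[data["phase"] == phase]
        counts = sub.groupby(condition_col).size()
        keep = counts[counts >= min_records].index
        dropped = sorted(set(counts.index) - set(keep))
        if dropped:
            report["notices"].append(
                f"{phase}: conditions {dropped} skipped (< {min_records} records)"
            )
        sub = sub[sub[condition_col].isin(keep)]
        entry: dict = {"n_per_condition": counts.to_dict()}
        if sub[condition_col].nunique() >= 2:
            if sub.groupby(condition_col)["duration_h"].var().max() == 0:
                # identical values within conditions: tests are degenerate
                means = sub.groupby(condition_col)["duration_h"].mean()
                p = 1.0 if means.nunique() == 1 else 0.0
                entry["welch_anova_p"] = p
                entry["games_howell"] = []
            else:
                aov = pg.welch_anova(data=sub, dv="duration_h", between=condition_col)
                pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
                entry["welch_anova_p"] = float(aov[pcol].iloc[0])
                gh = pg.pairwise_gameshowell(data=sub, dv="duration_h", between=condition_col)
                entry["games_howell"] = gh[["A", "B", "diff", "pval"]].to_dict("records")
        else:
            entry["welch_anova_p"] = None
            entry["games_howell"] = []
            report["notices"].append(f"{phase}: fewer than two eligible conditions")
        report["phases"][phase] = entry
    return report


def process_tracks(
    tracks: pd.DataFrame,
    frame_interval_h: float = 0.5,
    smooth_window: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """End-to-end pipeline: raw tracker table → phase calls + durations.

    ``tracks`` needs columns ``track_id, parent_id, frame, cdt1, geminin``
    (+ optional ``hoechst, area``).  Returns (phase calls per family sample,
    duration records, audit log).
    """
    relabeled = relabel_lineages(tracks)
    families, audit = filter_tracks(relabeled)
    if len(families) == 0:
        return families, pd.DataFrame(), audit
    families = normalize_channels(families, channels=("cdt1", "geminin"))
    called = pd.concat(
        [call_phases(grp, smooth_window) for _, grp in families.groupby("family_id")],
        ignore_index=True,
    )
    durations, dur_audit = quantify_phase_durations(called, frame_interval_h)
    audit.update(dur_audit)
    return called, durations, audit


# ---------------------------------------------------------------------------
# label-image tracking (stand-in linker honoring the 40 px rule)
# ---------------------------------------------------------------------------

def link_tracks(label_stack, max_distance_px: float = 40.0) -> pd.DataFrame:
    """Greedy maximum-overlap linking of label images into raw tracks.

    Objects in consecutive frames are linked to the previous object they
    overlap most; links whose centroid displacement exceeds
    ``max_distance_px`` are rejected.  When two objects claim the same
    predecessor, both open new tracks with the predecessor as parent (a
    division).  Returns a table (frame, label, track_id, parent_id, x, y).
    """
    rows = []
    next_id = itertools.count(1)
    prev_tracks: dict[int, int] = {}  # label in prev frame -> track_id
    prev_cent: dict[int, tuple[float, float]] = {}
    prev_labels = None
    for f, lab in enumerate(label_stack):
        lab = np.asarray(lab)
        ids = [int(v) for v in np.unique(lab) if v != 0]
        cents = {
            i: c for i, c in zip(
                ids, ndimage.center_of_mass(np.ones_like(lab), lab, ids)
            )
        }
        links: dict[int, list[int]] = {}
        candidates: dict[int, int | None] = {}
        if prev_labels is not None:
            for i in ids:
                mask = lab == i
                overlap = prev_labels[mask]
                overlap = overlap[overlap != 0]
                best = None
                if len(overlap):
                    vals, cnts = np.unique(overlap, return_counts=True)
                    best = int(vals[np.argmax(cnts)])
                    dy = cents[i][0] - prev_cent[best][0]
                    dx = cents[i][1] - prev_cent[best][1]
                    if np.hypot(dx, dy) > max_distance_px:
                        best = None
                candidates[i] = best
                if best is not None:
                    links.setdefault(best, []).append(i)
        cur_tracks: dict[int, int] = {}
        for i in ids:
            best = candidates.get(i)
            if best is None:
                tid, pid = next(next_id), None
            elif len(links[best]) == 1:
                tid, pid = prev_tracks[best], None
            else:  # division: each sibling opens a new track
                tid, pid = next(next_id), prev_tracks[best]
            cur_tracks[i] = tid
            rows.append({
                "frame": f, "label": i, "track_id": tid,
                "parent_id": pid if pid is not None else np.nan,
                "y": cents[i][0], "x": cents[i][1],
            })
        prev_tracks, prev_cent, prev_labels = cur_tracks, cents, lab
    df = pd.DataFrame(rows, columns=["frame", "label", "track_id", "parent_id", "x", "y"])
    # parent is recorded on the first sample of a daughter; propagate per track
    parent = df.dropna(subset=["parent_id"]).groupby("track_id")["parent_id"].first()
    df["parent_id"] = df["track_id"].map(parent)
    return df
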