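"""Sliding-window Delta(SNP-index) profiles, permutation thresholds and
candidate-region calling.

Markers are averaged (unweighted) in windows of ``window_bp`` advanced by
``step_bp`` (study defaults 20 kb / 2 kb); windows with fewer than
``min_markers`` markers are masked.  Significance thresholds come from a
read-level permutation null: at every marker the reads of the two bulks
are pooled and re-split at random preserving each bulk's depth
(hypergeometric draw), the windowed delta is recomputed, and two-sided
percentile thresholds are taken from the pooled null, stratified by window
marker-count class because window precision depends on marker density.
Overlapping or abutting significant windows merge into candidate regions.

Coordinates are 1-based inclusive externally (VCF/GFF convention); BED
export converts to 0-based half-open.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "MARKER_CLASS_BOUNDS",
    "window_profile",
    "delta_profile",
    "permutation_threshold",
    "call_candidate_regions",
]

#: marker-count strata for threshold pooling: 3-5, 6-10, 11-20, >20.
MARKER_CLASS_BOUNDS = (5, 10, 20)

PROFILE_COLUMNS = [
    "chrom", "start", "end", "n_markers",
    "mean_index_high", "mean_index_low", "mean_delta",
    "threshold_lo", "threshold_hi", "significant",
]


def _marker_class(n_markers: np.ndarray) -> np.ndarray:
    return np.searchsorted(np.asarray(MARKER_CLASS_BOUNDS), n_markers, side="left")


def _window_assignment(
    track: pd.DataFrame, window_bp: int, step_bp: int
) -> tuple[pd.DataFrame, sparse.csr_matrix]:
    """Window skeleton plus a windows x markers membership matrix.

    A marker belongs to a window iff start <= pos <= end.  Window starts run
    1, 1+step, ... up to the last observed marker position per chromosome.
    """
    rows = []
    w_idx, m_idx = [], []
    offset = 0
    for chrom, sub in track.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy(np.int64)
        max_pos = int(pos.max())
        starts = np.arange(1, max_pos + 1, step_bp, dtype=np.int64)
        ends = starts + window_bp - 1
        base = len(rows)
        for s, e in zip(starts, ends):
            rows.append((chrom, int(s), int(e)))
        # marker pos covered by window starts in (pos-window, pos]
        first = np.ceil((pos - window_bp - 1 + 1) / step_bp).astype(np.int64)
        first = np.maximum(first, 0)  # index of first covering start
        last = (pos - 1) // step_bp   # index of last covering start
        counts = last - first + 1
        m_rep = np.repeat(np.arange(pos.size) + offset, counts)
        w_rep = np.concatenate(
            [np.arange(f, l + 1) for f, l in zip(first, last)]
        ) + base if pos.size else np.empty(0, dtype=np.int64)
        w_idx.append(w_rep)
        m_idx.append(m_rep)
        offset += pos.size
    profile = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    n_windows = len(rows)
    n_markers = len(track)
    if n_windows and n_markers:
        w_all = np.concatenate(w_idx)
        m_all = np.concatenate(m_idx)
        a = sparse.csr_matrix(
            (np.ones(w_all.size), (w_all, m_all)), shape=(n_windows, n_markers)
        )
    else:
        a = sparse.csr_matrix((n_windows, n_markers))
    return profile, a


def window_profile(
    track: pd.DataFrame,
    window_bp: int = 20_000,
    step_bp: int = 2_000,
    min_markers: int = 3,
) -> pd.DataFrame:
    """Windowed unweighted means of the per-bulk indices and of delta.

    Windows with fewer than ``min_markers`` member markers have NaN means
    (masked), never zero.
    """
    if step_bp > window_bp:
        raise ValueError("step_bp must not exceed window_bp (markers would be skipped)")
    if step_bp < 1 or window_bp < 1:
        raise ValueError("window_bp and step_bp must be positive")
    profile, a = _window_assignment(track, window_bp, step_bp)
    counts = np.asarray(a.sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_h = np.asarray(a @ track["index_high"].to_numpy(float)).ravel() / counts
        mean_l = np.asarray(a @ track["index_low"].to_numpy(float)).ravel() / counts
    masked = counts < min_markers
    mean_h[masked] = np.nan
    mean_l[masked] = np.nan
    profile["n_markers"] = counts.astype(np.int64)
    profile["mean_index_high"] = mean_h
    profile["mean_index_low"] = mean_l
    profile.attrs["window_bp"] = window_bp
    profile.attrs["step_bp"] = step_bp
    profile.attrs["min_markers"] = min_markers
    return delta_profile(track, profile)


def delta_profile(track: pd.DataFrame, profile: pd.DataFrame) -> pd.DataFrame:
    """Fill ``mean_delta`` = windowed mean of per-marker (high - low) index."""
    _, a = _window_assignment(
        track, profile.attrs["window_bp"], profile.attrs["step_bp"]
    )
    counts = np.asarray(a.sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = np.asarray(a @ track["delta"].to_numpy(float)).ravel() / counts
    delta[counts < profile.attrs["min_markers"]] = np.nan
    out = profile.copy()
    out.attrs.update(profile.attrs)
    out["mean_delta"] = delta
    return out


def permutation_threshold(
    track: pd.DataFrame,
    profile: pd.DataFrame,
    n_perm: int = 1000,
    level: float = 0.95,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Two-sided permutation thresholds on the windowed delta.

    Each replicate pools, per marker, the two bulks' reads and re-splits
    them at random preserving each bulk's depth (hypergeometric), then
    recomputes all windowed deltas.  Null deltas are pooled within window
    marker-count classes and the (1-level)/2 and (1+level)/2 percentiles
    become that class's thresholds.  Windows below ``min_markers`` get NaN
    thresholds and are never significant.
    """
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} < 100 gives unstable (wide) thresholds",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    _, a = _window_assignment(
        track, profile.attrs["window_bp"], profile.attrs["step_bp"]
    )
    counts = np.asarray(a.sum(axis=1)).ravel()
    dh = track["depth_high"].to_numpy(np.int64)
    dl = track["depth_low"].to_numpy(np.int64)
    dwarf_total = track["dwarf_high"].to_numpy(np.int64) + track["dwarf_low"].to_numpy(np.int64)
    other_total = dh + dl - dwarf_total
    m = len(track)
    # null dwarf reads landing in the high bulk, (markers x n_perm)
    alt_h = rng.hypergeometric(
        dwarf_total[:, None], other_total[:, None], dh[:, None], size=(m, n_perm)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        null_delta = alt_h / dh[:, None] - (dwarf_total[:, None] - alt_h) / dl[:, None]
        null_win = (a @ null_delta) / counts[:, None]
    classes = _marker_class(counts)
    lo = np.full(len(profile), np.nan)
    hi = np.full(len(profile), np.nan)
    usable = counts >= profile.attrs["min_markers"]
    q_lo, q_hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    for cls in np.unique(classes[usable]):
        sel = usable & (classes == cls)
        pool = null_win[sel].ravel()
        pool = pool[np.isfinite(pool)]
        if pool.size == 0:
            continue
        lo[sel], hi[sel] = np.percentile(pool, [q_lo, q_hi])
    out = profile.copy()
    out.attrs.update(profile.attrs)
    out["threshold_lo"] = lo
    out["threshold_hi"] = hi
    out["significant"] = (
        np.isfinite(out["mean_delta"])
        & np.isfinite(lo)
        & ((out["mean_delta"] < lo) | (out["mean_delta"] > hi))
    )
    out.attrs["n_perm"] = n_perm
    out.attrs["level"] = level
    out.attrs["threshold_scheme"] = (
        "read re-splitting per marker; two-sided percentiles pooled by "
        "window marker-count class, per-window assignment"
    )
    return out


def call_candidate_regions(
    profile: pd.DataFrame, track: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Merge overlapping/abutting significant windows into regions.

    Region coordinates span min(start)..max(end) of their member windows.
    When ``track`` is given, member marker ids ("chrom:pos") are attached
    and region bounds are clipped to the chromosome's observed marker
    extent (windows may overhang the last marker).
    """
    sig = profile.loc[profile.get("significant", pd.Series(dtype=bool)) == True]  # noqa: E712
    regions = []
    for chrom, sub in sig.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        cur_s = cur_e = None
        n_win = 0
        for w in sub.itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e, n_win = w.start, w.end, 1
            elif w.start <= cur_e + 1:
                cur_e = max(cur_e, w.end)
                n_win += 1
            else:
                regions.append((chrom, cur_s, cur_e, n_win))
                cur_s, cur_e, n_win = w.start, w.end, 1
        if cur_s is not None:
            regions.append((chrom, cur_s, cur_e, n_win))
    out = pd.DataFrame(
        regions, columns=["chrom", "start", "end", "n_significant_windows"]
    )
    out.insert(0, "region_id", [f"region_{i + 1}" for i in range(len(out))])
    if track is not None and len(out):
        extent = track.groupby("chrom")["pos"].agg(["min", "max"])
        lo = out["chrom"].map(extent["min"])
        hi = out["chrom"].map(extent["max"])
        out["start"] = np.maximum(out["start"], lo.fillna(out["start"]))
        out["end"] = np.minimum(out["end"], hi.fillna(out["end"]))
    if track is not None:
        members = []
        for reg in out.itertuples(index=False):
            inside = track[
                (track["chrom"] == reg.chrom)
                & (track["pos"] >= reg.start)
                & (track["pos"] <= reg.end)
            ]
            members.append(
                [f"{c}:{p}" for c, p in zip(inside["chrom"], inside["pos"])]
            )
        out["member_variants"] = members
    return out
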