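"""Downstream conditioning statistics.

Implements the full data-analysis toolchain: per-bin valid-object
filtering, behaviour-fraction time bins with exact (Clopper–Pearson)
binomial intervals and Fisher exact tests under Bonferroni correction,
PRE/ON/OFF percentage-bending differences, 200 ms bend-event smoothing,
per-bin bend rates and their stimulated-minus-unstimulated differences,
and the rank tests (Mann–Whitney U with CLES, Wilcoxon signed-rank).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import BehaviorEvent

BONFERRONI_M = 24
BEND_SMOOTH_GAP_S = 0.2     # merge same-side bends separated by < 200 ms
BEND_MIN_DURATION_S = 0.2   # drop bends shorter than 200 ms


# ---------------------------------------------------------------------------
# valid-object filtering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidObjectFilter:
    """Per-bin inclusion criteria for tracked objects.

    ``proof``: detected every frame of the bin, first detection at least
    15 s before the bin starts, and mean smoothed centroid speed of at
    least 0.5 mm/s.  ``operant``: detected every frame, first detection at
    least 20 s before the bin, smoothed speed never above 1.5 mm/s, and
    mean speed at least 0.5 mm/s.  ``single`` applies no speed criteria.
    """

    variant: str = "operant"
    min_mean_speed: float = 0.5        # mm/s
    max_speed: float = 1.5             # mm/s (operant only)
    min_track_age_s: float = 20.0      # before bin start

    @classmethod
    def proof(cls) -> "ValidObjectFilter":
        return cls(variant="proof", min_track_age_s=15.0)

    @classmethod
    def operant(cls) -> "ValidObjectFilter":
        return cls(variant="operant", min_track_age_s=20.0)

    @classmethod
    def single(cls) -> "ValidObjectFilter":
        return cls(variant="single", min_mean_speed=0.0, max_speed=np.inf,
                   min_track_age_s=0.0)


def smoothed_centroid_speed(track: pd.DataFrame, frame_dt: float = 0.05,
                            tau: float = 0.25) -> pd.DataFrame:
    """Per-frame smoothed centroid speed (mm/s) per id, appended as a column."""
    alpha = frame_dt / tau
    out = []
    for lid, sub in track.sort_values("frame").groupby("id"):
        x = sub["x_mm"].to_numpy()
        y = sub["y_mm"].to_numpy()
        sp = np.zeros(len(sub))
        sp[1:] = np.hypot(np.diff(x), np.diff(y)) / frame_dt
        sm = np.empty_like(sp)
        acc = sp[0]
        for i, v in enumerate(sp):
            acc = (1 - alpha) * acc + alpha * v
            sm[i] = acc
        s = sub.copy()
        s["speed_mm_s"] = sm
        out.append(s)
    return pd.concat(out, ignore_index=True) if out else track.assign(speed_mm_s=[])


def filter_valid_objects(track: pd.DataFrame, bin_s: float,
                         filt: ValidObjectFilter,
                         duration_s: float | None = None,
                         frame_dt: float = 0.05) -> dict[int, set[int]]:
    """Per-bin sets of valid object ids.

    Bins are contiguous equal-length intervals from time 0.  ``track``
    needs columns (frame, time_s, id, x_mm, y_mm).
    """
    if track.empty:
        return {}
    tr = smoothed_centroid_speed(track, frame_dt)
    t_end = duration_s if duration_s is not None else tr["time_s"].max() + frame_dt
    n_bins = int(np.ceil(round(t_end / bin_s, 9)))
    frames_per_bin = int(round(bin_s / frame_dt))
    first_seen = tr.groupby("id")["time_s"].min()
    out: dict[int, set[int]] = {}
    for b in range(n_bins):
        t0, t1 = b * bin_s, (b + 1) * bin_s
        sub = tr[(tr["time_s"] >= t0 - 1e-9) & (tr["time_s"] < t1 - 1e-9)]
        valid: set[int] = set()
        for lid, rows in sub.groupby("id"):
            if len(rows) < frames_per_bin:
                continue  # not detected in every frame of the bin
            if first_seen[lid] > t0 - filt.min_track_age_s + 1e-9:
                continue
            sp = rows["speed_mm_s"].to_numpy()
            if filt.variant == "operant" and sp.max() > filt.max_speed:
                continue
            if sp.mean() < filt.min_mean_speed:
                continue
            valid.add(int(lid))
        out[b] = valid
    return out


# ---------------------------------------------------------------------------
# behaviour fractions with exact intervals and Fisher tests
# ---------------------------------------------------------------------------


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval via beta quantiles."""
    if n == 0:
        return (np.nan, np.nan)
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def behavior_fraction_bins(behavior: pd.DataFrame, valid: dict[int, set[int]],
                           channel: str, bin_s: float,
                           frame_dt: float = 0.05) -> pd.DataFrame:
    """Fraction of valid larvae showing ``channel`` at least once per bin.

    Returns one row per bin with the Clopper–Pearson 95% interval; empty
    valid sets yield NaN fractions (reported as missing).
    """
    rows = []
    for b in sorted(valid):
        ids = valid[b]
        t0, t1 = b * bin_s, (b + 1) * bin_s
        sub = behavior[(behavior["time_s"] >= t0 - 1e-9)
                       & (behavior["time_s"] < t1 - 1e-9)
                       & (behavior["id"].isin(ids))]
        n = len(ids)
        k = int(sub[sub[channel]].groupby("id").ngroups) if n else 0
        frac = k / n if n else np.nan
        lo, hi = clopper_pearson(k, n)
        rows.append({"bin": b, "t0": t0, "t1": t1, "n": n, "k": k,
                     "fraction": frac, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def fisher_bins(frac_a: pd.DataFrame, frac_b: pd.DataFrame,
                m: int = BONFERRONI_M) -> pd.DataFrame:
    """Two-sided Fisher exact test per bin between two groups, with the
    Bonferroni-corrected significance flag (p < .05/m)."""
    rows = []
    for (_, ra), (_, rb) in zip(frac_a.iterrows(), frac_b.iterrows()):
        table = [[ra["k"], ra["n"] - ra["k"]], [rb["k"], rb["n"] - rb["k"]]]
        if ra["n"] == 0 or rb["n"] == 0:
            p = np.nan
        else:
            _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({"bin": ra["bin"], "p": p,
                     "significant": bool(p < 0.05 / m) if np.isfinite(p) else False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# classical conditioning: PRE/ON/OFF percentage bending
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TestWindows:
    """Per-round analysis windows relative to test-light onset/offset (s)."""

    pre: tuple[float, float] = (-10.0, 0.0)     # before onset
    on: tuple[float, float] = (0.0, 20.0)       # after onset
    off: tuple[float, float] = (0.0, 20.0)      # after offset


def percentage_bending_difference(behavior: pd.DataFrame,
                                  light_onsets: list[float],
                                  light_offsets: list[float],
                                  windows: TestWindows = TestWindows(),
                                  frame_dt: float = 0.05) -> pd.Series:
    """Per-larva ON-OFF percentage-bending difference over the test rounds.

    ON percentages are pooled across all rounds before differencing.  Only
    larvae tracked for every ON and OFF window are retained.
    """
    if not light_onsets:
        raise ValueError("no testing rounds identified")
    result = {}
    ids = behavior["id"].unique()
    for lid in ids:
        sub = behavior[behavior["id"] == lid]
        on_flags, off_flags = [], []
        complete = True
        for onset, offset in zip(light_onsets, light_offsets):
            for (w0, w1), store, anchor in (
                    (windows.on, on_flags, onset),
                    (windows.off, off_flags, offset)):
                t0, t1 = anchor + w0, anchor + w1
                w = sub[(sub["time_s"] >= t0 - 1e-9) & (sub["time_s"] < t1 - 1e-9)]
                expected = int(round((t1 - t0) / frame_dt))
                if len(w) < expected:
                    complete = False
                    break
                store.append(w["bend"].to_numpy(dtype=bool))
            if not complete:
                break
        if not complete:
            continue
        pct_on = 100.0 * np.concatenate(on_flags).mean()
        pct_off = 100.0 * np.concatenate(off_flags).mean()
        result[lid] = pct_on - pct_off
    return pd.Series(result, name="on_minus_off_pct", dtype=float)


# ---------------------------------------------------------------------------
# operant conditioning: bend smoothing, rates, differences
# ---------------------------------------------------------------------------


def smooth_bend_events(events: list[BehaviorEvent]) -> list[BehaviorEvent]:
    """Merge same-side bends separated by < 200 ms, then drop bends
    shorter than 200 ms (in that order)."""
    bends = sorted((e for e in events if e.behavior == "bend"),
                   key=lambda e: e.t_start)
    for a, b in zip(bends, bends[1:]):
        if b.t_start < a.t_end - 1e-9:
            raise ValueError("overlapping bend events")
    merged: list[BehaviorEvent] = []
    for e in bends:
        if (merged and merged[-1].side == e.side
                and e.t_start - merged[-1].t_end < BEND_SMOOTH_GAP_S - 1e-9):
            prev = merged.pop()
            e = BehaviorEvent("bend", e.side, prev.t_start, e.t_end)
        merged.append(e)
    return [e for e in merged if e.duration >= BEND_MIN_DURATION_S - 1e-9]


def bend_rates(events_by_larva: dict[int, list[BehaviorEvent]],
               valid: dict[int, set[int]],
               side_assignment: dict[int, str] | None,
               bin_s: float = 60.0) -> pd.DataFrame:
    """Per-larva per-bin left/right bend rates (bends/min) and difference.

    A bend counts in the bin where it initiates.  With a side assignment
    the difference is stimulated minus unstimulated; without one (the
    uncorrelated control) it is left minus right.
    """
    rows = []
    scale = 60.0 / bin_s
    for b, ids in sorted(valid.items()):
        t0, t1 = b * bin_s, (b + 1) * bin_s
        for lid in sorted(ids):
            evs = [e for e in events_by_larva.get(lid, [])
                   if t0 - 1e-9 <= e.t_start < t1 - 1e-9]
            left = sum(1 for e in evs if e.side == "left") * scale
            right = sum(1 for e in evs if e.side == "right") * scale
            if side_assignment is not None:
                side = side_assignment.get(lid)
                if side is None:
                    continue
                stim = left if side == "left" else right
                unstim = right if side == "left" else left
            else:
                stim, unstim = left, right
            rows.append({"bin": b, "id": lid, "left_rate": left,
                         "right_rate": right, "stim_rate": stim,
                         "unstim_rate": unstim, "difference": stim - unstim})
    return pd.DataFrame(rows, columns=["bin", "id", "left_rate", "right_rate",
                                       "stim_rate", "unstim_rate", "difference"])


# ---------------------------------------------------------------------------
# rank tests and CLES
# ---------------------------------------------------------------------------


def cles(a: np.ndarray, b: np.ndarray) -> float:
    """Common-language effect size: P(a > b) with half weight for ties."""
    a = np.asarray(a, float)[:, None]
    b = np.asarray(b, float)[None, :]
    greater = (a > b).sum()
    ties = (a == b).sum()
    return float((greater + 0.5 * ties) / (a.size * b.size))


def rank_tests(a, b=None, mode: str = "mann_whitney") -> dict:
    """Two-sided rank tests used throughout the conditioning analyses.

    ``mann_whitney``: independent samples, exact for n <= 25 without ties,
    returns CLES.  ``wilcoxon_signed``: paired; ``wilcoxon_vs_zero``: one
    sample against zero.  Zero differences are discarded (classic
    convention); all-zero differences return p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    if a.size == 0:
        raise ValueError("empty sample")
    if mode == "mann_whitney":
        b = np.asarray(b, dtype=float)
        if b.size == 0:
            raise ValueError("empty sample")
        exact = (a.size <= 25 and b.size <= 25
                 and len(np.unique(np.concatenate([a, b]))) == a.size + b.size)
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="exact" if exact else "asymptotic")
        return {"statistic": float(res.statistic), "p": float(res.pvalue),
                "cles": cles(a, b)}
    if mode == "wilcoxon_signed":
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("paired samples must have equal length")
        d = a - b
    elif mode == "wilcoxon_vs_zero":
        d = a
    else:
        raise ValueError(f"unknown mode {mode!r}")
    d_nz = d[d != 0]
    if d_nz.size == 0:
        warnings.warn("all paired differences are zero; returning p = 1")
        return {"statistic": 0.0, "p": 1.0}
    mthd = "exact" if (d_nz.size <= 25
                       and len(np.unique(np.abs(d_nz))) == d_nz.size) else "approx"
    res = stats.wilcoxon(d_nz, zero_method="wilcox", alternative="two-sided",
                         method=mthd)
    return {"statistic": float(res.statistic), "p": float(res.pvalue)}


# ---------------------------------------------------------------------------
# external source-data tables
# ---------------------------------------------------------------------------

#: documented column mapping for externally supplied behaviour tables
SOURCE_DATA_COLUMNS = {
    "larva_id": "id", "id": "id",
    "time": "time_s", "time_s": "time_s",
    "bend": "bend", "left": "left", "right": "right", "roll": "roll",
    "back": "back", "forward": "forward",
    "forward_peristaltic": "forward_peristaltic",
    "side": "side", "bend_side": "side",
    "stimulus": "stimulus", "stimulus_state": "stimulus",
    "x_mm": "x_mm", "y_mm": "y_mm",
}


def read_source_data(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read an external per-larva behaviour time-series CSV.

    Columns are renamed through :data:`SOURCE_DATA_COLUMNS` (overridable);
    the result is sorted by (id, time_s) and boolean behaviour flags are
    coerced.
    """
    df = pd.read_csv(path)
    mapping = {**SOURCE_DATA_COLUMNS, **(column_map or {})}
    df = df.rename(columns={c: mapping[c] for c in df.columns if c in mapping})
    if "id" not in df.columns or "time_s" not in df.columns:
        raise ValueError("source data needs larva id and time columns")
    for c in ("bend", "left", "right", "roll", "back", "forward",
              "forward_peristaltic"):
        if c in df.columns:
            df[c] = df[c].astype(bool)
    return df.sort_values(["id", "time_s"]).reset_index(drop=True)
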