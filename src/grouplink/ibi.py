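"""Beat streams -> per-minute mean IBI -> baseline-referenced reactivity.

Processing follows the conventional psychophysiology pipeline: flag
artifactual beats, segment into one-minute windows requiring at least
30 contiguous seconds of readable data, take each person's reference as
the final readable baseline minute, and subtract it from every session
minute to obtain reactivity in ms.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# absolute physiological bounds on a credible interbeat interval
IBI_MIN_MS = 300.0
IBI_MAX_MS = 2000.0

#: a minute counts only if it contains this much contiguous readable data
MIN_CONTIGUOUS_S = 30.0

BEAT_COLUMNS = ["person_id", "cohort_id", "session", "window",
                "beat_time_s", "ibi_ms"]


def flag_artifacts(
    stream: pd.DataFrame, rel_tol: float = 0.3, window: int = 5
) -> pd.DataFrame:
    """Set ``artifact_flag`` on implausible beats.

    A beat is flagged iff its IBI lies outside the absolute
    [300, 2000] ms physiological bounds, or deviates from the running
    median of the prior ``window`` in-bounds beats by more than
    ``rel_tol`` times that median.  The median is taken over beats
    passing the absolute bound only, so the flagged set shrinks
    monotonically as ``rel_tol`` grows.

    Operates per (person, session, window) group; beats must already be
    time-ordered within each group.  Empty input passes through.
    """
    out = stream.copy()
    if out.empty:
        out["artifact_flag"] = pd.Series(dtype=bool)
        return out

    flags = np.zeros(len(out), dtype=bool)
    group_cols = [c for c in ("person_id", "session", "window") if c in out.columns]
    grouped = out.groupby(group_cols, sort=False) if group_cols else [(None, out)]
    for _, grp in grouped:
        ibi = grp["ibi_ms"].to_numpy(float)
        idx = grp.index.to_numpy()
        in_bounds = (ibi >= IBI_MIN_MS) & (ibi <= IBI_MAX_MS)
        history: list[float] = []
        for i in range(len(ibi)):
            f = not in_bounds[i]
            if not f and history:
                med = float(np.median(history[-window:]))
                f = abs(ibi[i] - med) > rel_tol * med
            if in_bounds[i]:
                history.append(ibi[i])
            flags[out.index.get_loc(idx[i])] = f
    out["artifact_flag"] = flags
    return out


def _minute_of(beat_time_s: np.ndarray) -> np.ndarray:
    """1-based minute index; a beat exactly on a boundary closes that minute."""
    return np.maximum(1, np.ceil(np.asarray(beat_time_s, float) / 60.0)).astype(int)


def _longest_contiguous_s(ibi_ms: np.ndarray, flagged: np.ndarray) -> float:
    """Longest run of consecutive unflagged beats, measured as summed IBI."""
    best = run = 0.0
    for v, f in zip(ibi_ms, flagged):
        if f:
            run = 0.0
        else:
            run += v / 1000.0
            best = max(best, run)
    return best


def segment_minutes(
    stream: pd.DataFrame, window_length_min: int
) -> pd.DataFrame:
    """Per-minute mean IBI with the 30-s contiguity readability rule.

    Beats are assigned to 1-based minutes by event time; within each
    minute, readable spans are maximal runs of unflagged beats (span
    length = the sum of their IBIs, truncated at minute boundaries by
    construction).  A minute's mean is the mean IBI over all unflagged
    beats in it if its longest readable span is at least 30 s, else
    missing.  Minutes with no beats at all are emitted as missing.

    Returns person_id, session, window, minute_index, mean_ibi_ms,
    n_readable_s.
    """
    if window_length_min <= 0:
        raise ValueError("window_length_min must be positive")
    if "artifact_flag" not in stream.columns:
        raise ValueError("run flag_artifacts before segment_minutes")

    rows = []
    group_cols = [c for c in ("person_id", "cohort_id", "session", "window")
                  if c in stream.columns]
    for key, grp in stream.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        meta = dict(zip(group_cols, key))
        minute = _minute_of(grp["beat_time_s"].to_numpy())
        for m in range(1, window_length_min + 1):
            sel = minute == m
            ibi = grp.loc[sel, "ibi_ms"].to_numpy(float)
            flg = grp.loc[sel, "artifact_flag"].to_numpy(bool)
            readable_s = _longest_contiguous_s(ibi, flg)
            clean = ibi[~flg]
            if readable_s >= MIN_CONTIGUOUS_S and clean.size:
                mean = float(clean.mean())
            else:
                mean = np.nan
            rows.append({**meta, "minute_index": m, "mean_ibi_ms": mean,
                         "n_readable_s": readable_s})
    cols = group_cols + ["minute_index", "mean_ibi_ms", "n_readable_s"]
    return pd.DataFrame(rows, columns=cols)


def baseline_reference(
    baseline_minutes: pd.DataFrame, strict: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-person baseline reference from the final readable baseline minute.

    The reference is the last baseline minute's mean IBI; if that minute
    is unreadable and ``strict`` is False, the latest readable baseline
    minute is used instead and the fallback is recorded.  People with no
    readable baseline minute are excluded with a reason.

    Grouping is per person, and additionally per session when a session
    column is present (one baseline recording before each session).

    Returns ``(references, exclusions)``: references with columns
    [group cols..., baseline_reference_ms, reference_minute, fallback],
    exclusions with [group cols..., reason].
    """
    group_cols = [c for c in ("person_id", "cohort_id", "session")
                  if c in baseline_minutes.columns]
    refs, excl = [], []
    for key, grp in baseline_minutes.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        meta = dict(zip(group_cols, key))
        grp = grp.sort_values("minute_index")
        readable = grp[np.isfinite(grp["mean_ibi_ms"])]
        if readable.empty:
            excl.append({**meta, "reason": "no_readable_baseline"})
            continue
        last_idx = int(grp["minute_index"].max())
        chosen = readable.iloc[-1]
        fallback = int(chosen["minute_index"]) != last_idx
        if fallback and strict:
            excl.append({**meta, "reason": "final_baseline_minute_unreadable"})
            continue
        refs.append(
            {
                **meta,
                "baseline_reference_ms": float(chosen["mean_ibi_ms"]),
                "reference_minute": int(chosen["minute_index"]),
                "fallback": fallback,
            }
        )
    ref_cols = group_cols + ["baseline_reference_ms", "reference_minute", "fallback"]
    exc_cols = group_cols + ["reason"]
    return (
        pd.DataFrame(refs, columns=ref_cols),
        pd.DataFrame(excl, columns=exc_cols),
    )


def compute_reactivity(
    session_minutes: pd.DataFrame, references: pd.DataFrame
) -> pd.DataFrame:
    """Reactivity = session minute mean IBI − baseline reference, in ms.

    Missing minutes stay missing; people without a reference drop out
    (they were already excluded upstream with a reason).
    """
    join_cols = [c for c in ("person_id", "cohort_id", "session")
                 if c in references.columns and c in session_minutes.columns]
    merged = session_minutes.merge(
        references[join_cols + ["baseline_reference_ms"]],
        on=join_cols, how="inner",
    )
    merged["reactivity_ms"] = (
        merged["mean_ibi_ms"] - merged["baseline_reference_ms"]
    )
    return merged


def read_beat_csv(path) -> pd.DataFrame:
    """Read a beat stream CSV; header order free, units must be ms / s."""
    df = pd.read_csv(path)
    missing = [c for c in ("person_id", "session", "beat_time_s", "ibi_ms")
               if c not in df.columns]
    if missing:
        raise ValueError(f"beat CSV missing required columns: {missing}")
    if (df["ibi_ms"] <= 0).any():
        raise ValueError("ibi_ms must be positive (milliseconds)")
    order = df.groupby(
        [c for c in ("person_id", "session", "window") if c in df.columns]
    )["beat_time_s"].apply(lambda s: bool(s.is_monotonic_increasing))
    if not order.all():
        raise ValueError("beat_time_s must be strictly increasing per window")
    return df
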