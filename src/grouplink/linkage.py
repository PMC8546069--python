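"""Directed linkage estimation: per-dyad lagged regression plus inclusion rules.

For every ordered (receiver, sender) pair present in a session, the
receiver's reactivity at minute t+1 is regressed on the sender's
reactivity at minute t (coupling, b1) and the receiver's own reactivity
at minute t (stability, b2) by ordinary least squares:

    Y_{t+1} = b0 + b1 * S_t + b2 * R_t + e_{t+1}

b1 is the directed linkage score.  Estimates built from fewer than half
of the possible lagged minutes are excluded, as are study-wide outliers
(a 3-SD screen followed by an extreme-value screen).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

LINKAGE_COLUMNS = [
    "cohort_id", "session", "receiver_id", "sender_id", "dyad_id",
    "receiver_role", "sender_role", "drug_condition",
    "b0", "b1", "b2", "se_b1", "n_triples", "n_possible",
    "included", "exclusion_reason",
]

#: an intercept + two slopes need a few spare observations to be estimable
MIN_TRIPLES = 4


def dyad_key(a: str, b: str) -> str:
    """Unordered pair label shared by both directed estimates."""
    return "--".join(sorted((str(a), str(b))))


def enumerate_directed_pairs(members: list[str]) -> list[tuple[str, str]]:
    """All ordered (receiver, sender) pairs among attending members.

    n attendees yield n(n-1) directed pairs; each unordered dyad
    contributes two, one per direction.
    """
    if len(members) < 2:
        raise ValueError("need at least 2 attending members for dyads")
    return [(r, s) for r, s in itertools.permutations(members, 2)]


def build_lagged_triples(
    receiver: np.ndarray, sender: np.ndarray
) -> tuple[np.ndarray, int]:
    """Lagged (S_t, R_t, Y_{t+1}) triples from two aligned minute series.

    Inputs are the two members' reactivity series over the same session
    minutes (NaN = missing).  A triple exists at minute t only when the
    sender's and receiver's minute-t values and the receiver's minute-t+1
    value are all observed.  Returns ``(triples, n_possible)`` where
    triples has columns [S_t, R_t, Y_{t+1}] and ``n_possible`` is the
    number of lagged slots (series length − 1).
    """
    receiver = np.asarray(receiver, float)
    sender = np.asarray(sender, float)
    if receiver.shape != sender.shape:
        raise ValueError("receiver and sender series must align minute-for-minute")
    n_possible = len(receiver) - 1
    s_t = sender[:-1]
    r_t = receiver[:-1]
    y_next = receiver[1:]
    ok = np.isfinite(s_t) & np.isfinite(r_t) & np.isfinite(y_next)
    return np.column_stack([s_t[ok], r_t[ok], y_next[ok]]), n_possible


@dataclass
class StabilityInfluenceFit:
    b0: float
    b1: float
    b2: float
    se_b0: float
    se_b1: float
    se_b2: float
    n: int


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix not full rank (e.g. a constant sender series)."""


def fit_stability_influence(triples: np.ndarray) -> StabilityInfluenceFit:
    """OLS fit of Y_{t+1} on [1, S_t, R_t].

    Coefficient standard errors use the usual residual-variance
    estimator s² (X'X)⁻¹ with n − 3 degrees of freedom.  Raises
    :class:`RankDeficientError` when the design matrix is rank
    deficient and ``ValueError`` with fewer than 4 triples.
    """
    triples = np.asarray(triples, float)
    n = len(triples)
    if n < MIN_TRIPLES:
        raise ValueError(f"need at least {MIN_TRIPLES} triples, got {n}")
    X = np.column_stack([np.ones(n), triples[:, 0], triples[:, 1]])
    y = triples[:, 2]
    if np.linalg.matrix_rank(X) < 3:
        raise RankDeficientError("design matrix rank deficient")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - 3
    s2 = float(resid @ resid) / dof if dof > 0 else np.nan
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    return StabilityInfluenceFit(
        b0=float(beta[0]), b1=float(beta[1]), b2=float(beta[2]),
        se_b0=float(se[0]), se_b1=float(se[1]), se_b2=float(se[2]), n=n,
    )


def completeness_threshold(n_possible: int) -> int:
    """Minimum triples for inclusion: half of all possible lagged slots.

    90-minute sessions have 89 slots -> threshold 45; the 60-minute
    session has 59 -> 30.
    """
    return int(np.ceil(0.5 * n_possible))


def apply_completeness_rule(n_triples: int, n_possible: int) -> bool:
    return n_triples >= completeness_threshold(n_possible)


def estimate_linkage_table(
    reactivity: pd.DataFrame,
    roster: pd.DataFrame,
    session_lengths: dict | None = None,
) -> pd.DataFrame:
    """All directed linkage estimates for a study, before outlier screening.

    ``reactivity`` needs columns person_id, cohort_id, session,
    minute_index, reactivity_ms (missing minutes NaN or absent rows).
    People appear in a session if they contribute any reactivity row for
    it.  Completeness is applied here; outlier screening is a separate
    study-wide pass (:func:`screen_outliers`).
    """
    roles = roster.set_index(["person_id", "cohort_id"])["role"]
    conds = roster.drop_duplicates("cohort_id").set_index("cohort_id")[
        "drug_condition"
    ]
    rows = []
    for (cohort_id, session), grp in reactivity.groupby(
        ["cohort_id", "session"], sort=True
    ):
        if session_lengths is not None:
            n_minutes = int(session_lengths[session])
        else:
            n_minutes = int(grp["minute_index"].max())
        series = {}
        for pid, pgrp in grp.groupby("person_id"):
            v = np.full(n_minutes, np.nan)
            idx = pgrp["minute_index"].to_numpy(int) - 1
            v[idx] = pgrp["reactivity_ms"].to_numpy(float)
            series[pid] = v
        attending = sorted(series)
        if len(attending) < 2:
            continue
        for receiver, sender in enumerate_directed_pairs(attending):
            triples, n_possible = build_lagged_triples(
                series[receiver], series[sender]
            )
            rec = {
                "cohort_id": cohort_id,
                "session": session,
                "receiver_id": receiver,
                "sender_id": sender,
                "dyad_id": dyad_key(receiver, sender),
                "receiver_role": roles.get((receiver, cohort_id), "participant"),
                "sender_role": roles.get((sender, cohort_id), "participant"),
                "drug_condition": conds.get(cohort_id, ""),
                "b0": np.nan, "b1": np.nan, "b2": np.nan, "se_b1": np.nan,
                "n_triples": len(triples), "n_possible": n_possible,
                "included": False, "exclusion_reason": "none",
            }
            try:
                if len(triples) >= MIN_TRIPLES:
                    fit = fit_stability_influence(triples)
                    rec.update(b0=fit.b0, b1=fit.b1, b2=fit.b2, se_b1=fit.se_b1)
                if not apply_completeness_rule(len(triples), n_possible):
                    rec["exclusion_reason"] = "too_few_obs"
                elif len(triples) < MIN_TRIPLES:
                    rec["exclusion_reason"] = "too_few_obs"
                else:
                    rec["included"] = True
            except RankDeficientError:
                rec["exclusion_reason"] = "rank_deficient"
            rows.append(rec)
    return pd.DataFrame(rows, columns=LINKAGE_COLUMNS)


def screen_outliers(
    table: pd.DataFrame,
    sd_limit: float = 3.0,
    extreme_sd: float = 8.0,
    isolation_sd: float = 2.5,
    mode: str = "exclude",
) -> pd.DataFrame:
    """Study-wide outlier screen on included b1 estimates, two passes.

    Pass 1 excludes estimates more than ``sd_limit`` SDs from the pooled
    mean (mean and SD over all currently included b1).  Pass 2, on the
    recomputed pool, excludes estimates that are both more than
    ``extreme_sd`` SDs from the mean and more than ``isolation_sd`` SDs
    away from the nearest other estimate.  A pool SD of zero makes both
    passes no-ops.  ``mode="winsorize"`` clips at the pass-1 bounds
    instead of excluding (sensitivity option); pass 2 still excludes.
    """
    if mode not in ("exclude", "winsorize"):
        raise ValueError("mode must be 'exclude' or 'winsorize'")
    out = table.copy()
    pool = out["included"] & np.isfinite(out["b1"])

    mean = out.loc[pool, "b1"].mean()
    sd = out.loc[pool, "b1"].std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return out
    dev = np.abs(out["b1"] - mean)
    hit1 = pool & (dev > sd_limit * sd)
    if mode == "exclude":
        out.loc[hit1, "included"] = False
        out.loc[hit1, "exclusion_reason"] = "sd_outlier"
        pool = pool & ~hit1
    else:
        lo, hi = mean - sd_limit * sd, mean + sd_limit * sd
        out.loc[pool, "b1"] = out.loc[pool, "b1"].clip(lo, hi)

    b = out.loc[pool, "b1"].to_numpy(float)
    if len(b) < 2:
        return out
    mean2, sd2 = b.mean(), b.std(ddof=1)
    if sd2 == 0:
        return out
    order = np.sort(b)
    for idx in out.index[pool]:
        v = out.at[idx, "b1"]
        others = order[order != v] if (order == v).sum() == 1 else order
        if (order == v).sum() > 1:
            nearest = 0.0
        else:
            nearest = np.min(np.abs(others - v)) if others.size else np.inf
        if abs(v - mean2) > extreme_sd * sd2 and nearest > isolation_sd * sd2:
            out.at[idx, "included"] = False
            out.at[idx, "exclusion_reason"] = "extreme_outlier"
    return out
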