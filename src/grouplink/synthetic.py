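"""Synthetic-cohort generator with known ground truth.

Generates complete studies — rosters, attendance, baseline and session
IBI series — from a coupled "stability and influence" process: each
person's next-minute reactivity is their own current reactivity times a
stability coefficient, plus each cohort-mate's current reactivity times
a directed coupling coefficient, plus Gaussian innovation.  Observed
minute-mean IBI is baseline level + reactivity + measurement noise.
Because the coupling coefficients are known, every downstream stage
(segmentation, linkage regression, mixed model) can be checked against
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    ConfigurationError,
    SimulationTruth,
    StudyConfig,
    check_stationary,
)

# stream tags for per-(cohort, session) derived substreams
_TAG_TRUTH = 0
_TAG_REACTIVITY = 1
_TAG_MEASUREMENT = 2
_TAG_MISSINGNESS = 3
_TAG_BEATS = 4


def _rng(seed: int, *path: int) -> np.random.Generator:
    """Derived random substream: reproducible for any subset of the study."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, path)]))


def generate_roster(config: StudyConfig) -> pd.DataFrame:
    """Build the member table: one row per member per cohort.

    Each cohort gets exactly 2 facilitators drawn round-robin from a
    shared pool (facilitators recur across cohorts; participants never
    do) and ``cohort_size - 2`` participants with globally unique ids.

    Returns a DataFrame with columns person_id, cohort_id, role,
    drug_condition; deterministic given ``config.seed``.
    """
    rows = []
    next_participant = 1
    fac_ids = [f"F{i + 1:02d}" for i in range(config.n_facilitator_pool)]
    fac_cursor = 0
    for c_idx, (size, cond) in enumerate(
        zip(config.cohort_sizes, config.drug_assignment)
    ):
        cohort_id = f"C{c_idx + 1:02d}"
        for _ in range(2):
            rows.append((fac_ids[fac_cursor % len(fac_ids)], cohort_id,
                         "facilitator", cond))
            fac_cursor += 1
        for _ in range(size - 2):
            rows.append((f"P{next_participant:03d}", cohort_id,
                         "participant", cond))
            next_participant += 1
    return pd.DataFrame(
        rows, columns=["person_id", "cohort_id", "role", "drug_condition"]
    )


def default_truth(
    config: StudyConfig,
    roster: pd.DataFrame,
    *,
    oxytocin_coupling_start: float = 0.08,
    oxytocin_coupling_decline: float = 0.02,
    placebo_coupling: float = 0.0,
    stability_range: tuple[float, float] = (0.2, 0.4),
    innovation_sd: float = 20.0,
    baseline_mean: float = 850.0,
    baseline_sd: float = 70.0,
    measurement_sd: float = 5.0,
    attendance_prob_later: float = 0.75,
    missing_targets: dict | None = None,
) -> SimulationTruth:
    """Default ground truth emulating the study conditions.

    Oxytocin cohorts couple at ``oxytocin_coupling_start`` in session 1,
    declining linearly per session and floored at zero; placebo cohorts
    couple at ``placebo_coupling``.  Everyone attends session 1 and
    facilitators attend all sessions; participants attend later sessions
    with probability ``attendance_prob_later``.  ``missing_targets`` are
    the per-condition *overall* missing fractions (missed sessions count
    as missing) used to derive the per-minute mask rate.
    """
    rng = _rng(config.seed, _TAG_TRUTH)
    truth = SimulationTruth(
        innovation_sd=innovation_sd, measurement_sd=measurement_sd
    )
    if missing_targets is not None:
        truth.segment_missing_prob = dict(missing_targets)

    for pid in roster["person_id"].unique():
        truth.stability[pid] = float(rng.uniform(*stability_range))
        truth.baseline_level[pid] = float(
            max(400.0, rng.normal(baseline_mean, baseline_sd))
        )

    for cohort_id, grp in roster.groupby("cohort_id", sort=True):
        cond = grp["drug_condition"].iloc[0]
        members = list(grp["person_id"])
        for session in range(1, config.n_sessions + 1):
            if cond == "oxytocin":
                c = max(
                    0.0,
                    oxytocin_coupling_start
                    - oxytocin_coupling_decline * (session - 1),
                )
            else:
                c = placebo_coupling
            for sender in members:
                for receiver in members:
                    if sender != receiver:
                        truth.coupling[(cohort_id, session, sender, receiver)] = c
            for _, row in grp.iterrows():
                if row["role"] == "facilitator" or session == 1:
                    present = True
                else:
                    present = bool(rng.random() < attendance_prob_later)
                truth.attendance[(row["person_id"], cohort_id, session)] = present

    truth.validate()
    return truth


def simulate_reactivity_series(
    members: list[str],
    transition: np.ndarray,
    n_minutes: int,
    innovation_sd: float,
    rng: np.random.Generator,
    initial_state: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate the coupled VAR(1) reactivity process for one window.

    ``transition[r, s]`` is the weight of member s's reactivity at minute
    t in member r's reactivity at minute t+1 (diagonal = stability).  The
    process starts at the stationary mean (zero) unless ``initial_state``
    is given.  Returns an array of shape ``(n_minutes, n_members)`` in ms.

    Raises :class:`ConfigurationError` before simulating if the
    transition matrix is nonstationary (spectral radius >= 1).
    """
    n = len(members)
    if transition.shape != (n, n):
        raise ValueError("transition matrix shape does not match members")
    check_stationary(transition)
    x = np.zeros(n) if initial_state is None else np.asarray(initial_state, float)
    out = np.empty((n_minutes, n))
    for t in range(n_minutes):
        eps = rng.normal(0.0, innovation_sd, size=n) if innovation_sd > 0 else 0.0
        x = transition @ x + eps
        out[t] = x
    return out


def render_minute_ibi(
    reactivity: np.ndarray,
    members: list[str],
    baseline_levels: dict,
    measurement_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Observed session minute means: baseline level + reactivity + noise.

    Returns an array shaped like ``reactivity``.  Raises
    :class:`ConfigurationError` if any rendered IBI is non-positive
    (parameters implausible for real interbeat intervals).
    """
    base = np.array([baseline_levels[m] for m in members], float)
    if np.any(base <= 0):
        raise ConfigurationError("baseline_level must be positive")
    noise = (
        rng.normal(0.0, measurement_sd, size=reactivity.shape)
        if measurement_sd > 0
        else 0.0
    )
    obs = base[None, :] + reactivity + noise
    if np.any(obs <= 0):
        raise ConfigurationError(
            "rendered IBI <= 0 ms; reactivity/noise parameters implausible"
        )
    return obs


def apply_missingness(
    minutes: pd.DataFrame,
    attendance: dict,
    minute_missing_prob: float | dict,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Mask observations: absent sessions entirely, present minutes i.i.d.

    ``minute_missing_prob`` is either a scalar or a mapping from drug
    condition to the per-present-minute mask probability.  Masked cells
    get NaN ``mean_ibi_ms``; rows are kept so accounting can see them.
    """
    out = minutes.copy()
    absent = np.array(
        [
            not attendance.get((p, c, s), True)
            for p, c, s in zip(
                out["person_id"], out["cohort_id"], out["session"]
            )
        ]
    )
    if isinstance(minute_missing_prob, dict):
        probs = out["drug_condition"].map(minute_missing_prob).to_numpy(float)
    else:
        probs = np.full(len(out), float(minute_missing_prob))
    if np.any((probs < 0) | (probs > 1)):
        raise ConfigurationError("minute_missing_prob must lie in [0, 1]")
    masked = absent | (rng.random(len(out)) < probs)
    out.loc[masked, "mean_ibi_ms"] = np.nan
    return out


def render_beats(
    minutes: pd.DataFrame,
    artifact_rate: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Emit a beat stream whose clean minute means equal the input means.

    Within each non-missing minute, beats are laid down at the constant
    minute-mean IBI from the minute's start; with probability
    ``artifact_rate`` a beat's recorded IBI is corrupted to a
    physiologically impossible short value (mimicking a misdetected R
    peak) without moving the beat, so artifact flagging and the 30-s
    contiguity rule can be exercised downstream.

    Returns columns person_id, cohort_id, session, window, beat_time_s,
    ibi_ms, true_artifact.
    """
    rows = []
    for _, r in minutes.iterrows():
        m = r["mean_ibi_ms"]
        if not np.isfinite(m):
            continue
        if m <= 0:
            raise ConfigurationError("minute mean IBI must be positive")
        n_beats = int(np.floor(60_000.0 / m))
        start = 60.0 * (r["minute_index"] - 1)
        for j in range(1, n_beats + 1):
            ibi = m
            corrupt = artifact_rate > 0 and rng.random() < artifact_rate
            if corrupt:
                ibi = float(rng.uniform(80.0, 240.0))
            rows.append(
                (
                    r["person_id"],
                    r.get("cohort_id", ""),
                    r["session"],
                    r.get("window", "session"),
                    start + j * m / 1000.0,
                    ibi,
                    corrupt,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "person_id",
            "cohort_id",
            "session",
            "window",
            "beat_time_s",
            "ibi_ms",
            "true_artifact",
        ],
    )


@dataclass
class SimulatedStudy:
    """Everything one synthetic run produces, with its ground truth."""

    config: StudyConfig
    roster: pd.DataFrame
    truth: SimulationTruth
    latent: pd.DataFrame  # true reactivity per present person-minute
    minutes: pd.DataFrame  # observed minute means with missingness applied


def _absent_fraction(
    config: StudyConfig, roster: pd.DataFrame, truth: SimulationTruth
) -> dict:
    """Fraction of session member-minutes lost to missed sessions, by condition."""
    tot: dict[str, float] = {}
    absent: dict[str, float] = {}
    for _, row in roster.iterrows():
        cond = row["drug_condition"]
        for session in range(1, config.n_sessions + 1):
            mins = config.session_lengths_min[session - 1]
            tot[cond] = tot.get(cond, 0.0) + mins
            if not truth.attendance.get(
                (row["person_id"], row["cohort_id"], session), True
            ):
                absent[cond] = absent.get(cond, 0.0) + mins
    return {c: absent.get(c, 0.0) / tot[c] for c in tot}


def derive_session_dropout_prob(
    config: StudyConfig, roster: pd.DataFrame, truth: SimulationTruth
) -> tuple[dict, dict]:
    """Per-condition whole-session dropout and scattered-minute rates.

    The per-condition missing-data targets are marginal rates over all
    session member-minutes, and missed sessions count toward them.  Real
    IBI missingness is blocky — a sensor that fails tends to fail for
    most of a session — so the generator delivers the target as
    whole-session dropout plus a low scattered per-minute rate
    (``truth.scatter_missing_prob``), rather than masking minutes i.i.d.
    at the full target rate, which would push nearly every surviving
    dyad below the 50% completeness rule.  Solving

        target = absent + (1-absent) * (q + (1-q) * scatter)

    for q gives the dropout probability among attended sessions; the
    scattered rate is capped at the condition's marginal rate so a zero
    target yields no masking at all.  Returns ``(dropout, scatter)``
    mappings keyed by condition.
    """
    p_abs = _absent_fraction(config, roster, truth)
    dropout, scatter = {}, {}
    for cond, target in truth.segment_missing_prob.items():
        a = p_abs.get(cond, 0.0)
        cond_rate = 0.0 if a >= 1.0 else max(0.0, (target - a) / (1.0 - a))
        p0 = min(truth.scatter_missing_prob, cond_rate)
        q = 0.0 if p0 >= 1.0 else max(0.0, (cond_rate - p0) / (1.0 - p0))
        dropout[cond] = min(1.0, q)
        scatter[cond] = p0
    return dropout, scatter


def simulate_study(
    config: StudyConfig,
    truth: SimulationTruth | None = None,
    roster: pd.DataFrame | None = None,
) -> SimulatedStudy:
    """Generate a full synthetic study at the configured conditions.

    Produces, per cohort and session, a baseline window (reactivity zero
    by construction) and a session window driven by the coupled process,
    renders observed minute means, and applies attendance plus
    minute-level missingness at the condition-calibrated rates.
    """
    if roster is None:
        roster = generate_roster(config)
    if truth is None:
        truth = default_truth(config, roster)
    truth.validate()

    dropout_prob, scatter_prob = derive_session_dropout_prob(
        config, roster, truth
    )
    rng_drop = _rng(config.seed, _TAG_MISSINGNESS, 1)
    # recorded = attended and the device held up for the session.  Dropout
    # is a fixed-count random subset of attended person-sessions per
    # condition (weighted draw is unnecessary: session lengths are equal
    # within a condition to good approximation), which keeps the marginal
    # missing rate at its calibrated value for every seed.
    attended: dict[str, list] = {}
    for _, row in roster.iterrows():
        cond = row["drug_condition"]
        for session in range(1, config.n_sessions + 1):
            key = (row["person_id"], row["cohort_id"], session)
            if truth.attendance.get(key, True):
                attended.setdefault(cond, []).append(key)
    recorded = {}
    for cond, keys in attended.items():
        n_drop = int(round(dropout_prob.get(cond, 0.0) * len(keys)))
        drop_idx = set(
            rng_drop.choice(len(keys), size=n_drop, replace=False)
        ) if n_drop else set()
        for i, key in enumerate(keys):
            recorded[key] = i not in drop_idx
    latent_rows = []
    minute_rows = []
    cohort_ids = sorted(roster["cohort_id"].unique())
    for c_idx, cohort_id in enumerate(cohort_ids):
        grp = roster[roster["cohort_id"] == cohort_id]
        cond = grp["drug_condition"].iloc[0]
        members = list(grp["person_id"])
        for session in range(1, config.n_sessions + 1):
            present = [
                m
                for m in members
                if truth.attendance.get((m, cohort_id, session), True)
            ]
            n_min = config.session_lengths_min[session - 1]
            rng_r = _rng(config.seed, c_idx, session, _TAG_REACTIVITY)
            rng_m = _rng(config.seed, c_idx, session, _TAG_MEASUREMENT)
            # baseline window: reactivity is zero by definition
            n_base = config.baseline_length_min
            if present:
                base_react = np.zeros((n_base, len(present)))
                base_obs = render_minute_ibi(
                    base_react, present, truth.baseline_level,
                    truth.measurement_sd, rng_m,
                )
                A = truth.transition_matrix(cohort_id, session, present)
                react = simulate_reactivity_series(
                    present, A, n_min, truth.innovation_sd, rng_r
                )
                sess_obs = render_minute_ibi(
                    react, present, truth.baseline_level,
                    truth.measurement_sd, rng_m,
                )
            for p_i, pid in enumerate(members):
                if pid not in present:
                    # keep rows for accounting; all observations missing
                    for w, n_w in (("baseline", n_base), ("session", n_min)):
                        for t in range(1, n_w + 1):
                            minute_rows.append(
                                (pid, cohort_id, cond, session, w, t, np.nan)
                            )
                    continue
                j = present.index(pid)
                for t in range(1, n_base + 1):
                    minute_rows.append(
                        (pid, cohort_id, cond, session, "baseline", t,
                         base_obs[t - 1, j])
                    )
                for t in range(1, n_min + 1):
                    latent_rows.append(
                        (pid, cohort_id, cond, session, t, react[t - 1, j])
                    )
                    minute_rows.append(
                        (pid, cohort_id, cond, session, "session", t,
                         sess_obs[t - 1, j])
                    )

    latent = pd.DataFrame(
        latent_rows,
        columns=["person_id", "cohort_id", "drug_condition", "session",
                 "minute_index", "reactivity_ms"],
    )
    minutes = pd.DataFrame(
        minute_rows,
        columns=["person_id", "cohort_id", "drug_condition", "session",
                 "window", "minute_index", "mean_ibi_ms"],
    )
    rng_miss = _rng(config.seed, _TAG_MISSINGNESS, 2)
    minutes = apply_missingness(minutes, recorded, scatter_prob, rng_miss)
    return SimulatedStudy(config, roster, truth, latent, minutes)
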