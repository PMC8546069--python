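"""Replicated scaled-down studies for calibration and power checks.

Monte-Carlo replication of the full analysis chain at the study's design
(10 cohorts, six sessions, half oxytocin) but at reduced per-cohort size
and session length, feeding the latent reactivity directly to the
estimator.  These problem sizes keep hundreds of replicates tractable on
one CPU while preserving the crossed structure the mixed model has to
absorb; they are the package's standing choice for calibration runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import StudyConfig
from .linkage import estimate_linkage_table, screen_outliers
from .mixedmodel import (
    LinkageModelFit,
    build_model_frame,
    fit_crossclassified,
    simple_effects_by_session,
    test_effect,
)
from .synthetic import generate_roster, simulate_reactivity_series

#: scaled-down replicate design: 10 cohorts of 4 (2 facilitators + 2
#: participants, the smallest size occupying every role cell of the
#: factorial), six sessions at the study's 90-minute length so the
#: per-estimate sampling error matches the real design
SCALED_CONFIG = dict(
    n_cohorts=10,
    cohort_sizes=(4,) * 10,
    n_sessions=6,
    session_lengths_min=(90,) * 6,
)


def simulate_scaled_study_fit(
    seed: int,
    coupling_by_session: dict | None = None,
    stability: float = 0.3,
    innovation_sd: float = 20.0,
    session_length: int | None = None,
    base_coupling_mean: float = 0.0,
    cohort_coupling_sd: float = 0.0,
    dyad_coupling_sd: float = 0.0,
) -> LinkageModelFit:
    """One replicate: simulate, estimate linkage, screen, fit the model.

    ``coupling_by_session`` maps condition -> per-session coupling added
    on top of a heterogeneous base: each cohort draws a mean coupling
    N(base_coupling_mean, cohort_coupling_sd²) and each ordered pair
    scatters around it with SD ``dyad_coupling_sd`` (constant over
    sessions, identical in distribution for both conditions).  With all
    three base parameters zero the study is the degenerate
    no-heterogeneity null.  The latent reactivity is analyzed directly —
    measurement rendering and missingness are exercised elsewhere and
    only dilute the quantity being calibrated here.
    """
    cfg = StudyConfig(**{**SCALED_CONFIG, "seed": int(seed)})
    if session_length is not None:
        cfg = StudyConfig(
            **{
                **SCALED_CONFIG,
                "session_lengths_min": (session_length,) * 6,
                "seed": int(seed),
            }
        )
    coupling_by_session = coupling_by_session or {}
    roster = generate_roster(cfg)
    rows = []
    for c_idx, (cohort_id, grp) in enumerate(
        roster.groupby("cohort_id", sort=True)
    ):
        cond = grp["drug_condition"].iloc[0]
        members = list(grp["person_id"])
        n = len(members)
        per_session = coupling_by_session.get(cond, {})
        rng_base = np.random.default_rng(
            np.random.SeedSequence([int(seed), c_idx, 777])
        )
        mu_c = rng_base.normal(base_coupling_mean, cohort_coupling_sd)
        base = np.clip(
            rng_base.normal(mu_c, dyad_coupling_sd, (n, n)), -0.1, 0.15
        )
        for session in range(1, cfg.n_sessions + 1):
            c = float(per_session.get(session, 0.0))
            A = base + c
            np.fill_diagonal(A, stability)
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), c_idx, session])
            )
            n_min = cfg.session_lengths_min[session - 1]
            x = simulate_reactivity_series(
                members, A, n_min, innovation_sd, rng
            )
            for j, pid in enumerate(members):
                for t in range(n_min):
                    rows.append(
                        (pid, cohort_id, session, t + 1, x[t, j])
                    )
    react = pd.DataFrame(
        rows,
        columns=["person_id", "cohort_id", "session", "minute_index",
                 "reactivity_ms"],
    )
    lengths = {
        s + 1: cfg.session_lengths_min[s] for s in range(cfg.n_sessions)
    }
    table = screen_outliers(estimate_linkage_table(react, roster, lengths))
    return fit_crossclassified(build_model_frame(table))


def type_one_error_rate(
    n_replicates: int,
    seed: int,
    alpha: float = 0.05,
    base_coupling_mean: float = 0.04,
    cohort_coupling_sd: float = 0.02,
    dyad_coupling_sd: float = 0.02,
) -> float:
    """Rejection rate of the drug main effect under the null study.

    The null keeps the population's linkage heterogeneity — cohorts and
    dyads couple at different levels, drawn from the same distribution
    in both conditions — and removes only the condition effect.  (With
    every random variance truly zero instead, the nonnegativity
    constraint truncates the component estimates at the boundary, the
    contrast SE picks up only the upward half of their sampling noise,
    and the test runs conservative; that degenerate case is reachable by
    zeroing the three coupling parameters.)
    """
    hits = 0
    for i in range(n_replicates):
        fit = simulate_scaled_study_fit(
            seed * 1_000_003 % (2**31) + i,
            base_coupling_mean=base_coupling_mean,
            cohort_coupling_sd=cohort_coupling_sd,
            dyad_coupling_sd=dyad_coupling_sd,
        )
        if test_effect(fit, "drug").p < alpha:
            hits += 1
    return hits / n_replicates


def session1_difference_detection(
    n_replicates: int,
    seed: int,
    oxytocin_coupling: float = 0.08,
    decline: float = 0.02,
    session_length: int = 90,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Power probe: oxytocin coupling declining from session 1, placebo null.

    Returns (detection rate of the session-1 condition difference, mean
    estimated session-1 difference).
    """
    coupling = {
        "oxytocin": {
            s: max(0.0, oxytocin_coupling - decline * (s - 1))
            for s in range(1, 7)
        }
    }
    hits, diffs = 0, []
    for i in range(n_replicates):
        fit = simulate_scaled_study_fit(
            seed * 2_000_003 % (2**31) + i,
            coupling_by_session=coupling,
            session_length=session_length,
        )
        diff = simple_effects_by_session(fit, 1)[2]
        diffs.append(diff.estimate)
        if diff.p < alpha:
            hits += 1
    return hits / n_replicates, float(np.mean(diffs))
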