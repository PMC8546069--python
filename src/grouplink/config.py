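"""Study-level configuration and ground-truth containers.

``StudyConfig`` describes the design of a (synthetic or real) study:
how many cohorts, their sizes, session count and lengths, and the
drug-condition assignment.  ``SimulationTruth`` carries everything the
generator needs to produce one cohort-session of coupled reactivity:
the directed coupling coefficients, per-person stability, noise scales,
attendance, and the per-condition missingness targets.  Both are plain
dataclasses so they serialize cleanly to YAML/JSON.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence
import json

import numpy as np
import yaml


class ConfigurationError(ValueError):
    """Raised when a study configuration violates a design invariant."""


#: Cohort sizes (participants + 2 facilitators) matching the study design:
#: four cohorts of 6, four of 7, two of 8 -> 48 participants total.
DEFAULT_COHORT_SIZES: tuple[int, ...] = (6, 6, 6, 6, 7, 7, 7, 7, 8, 8)

DEFAULT_SESSION_LENGTHS: tuple[int, ...] = (90, 90, 90, 90, 90, 60)

#: Overall per-condition missing fractions for IBI observations, counting
#: minutes lost to missed sessions as missing.
DEFAULT_MISSING_TARGETS: dict[str, float] = {"placebo": 0.494, "oxytocin": 0.387}


@dataclass(frozen=True)
class StudyConfig:
    """Design of one study: cohorts, sessions, drug assignment.

    Parameters
    ----------
    n_cohorts : int
        Number of therapy cohorts; half receive oxytocin, half placebo.
    cohort_sizes : sequence of int
        Total members per cohort (participants plus 2 facilitators).
    n_sessions : int
        Weekly sessions per cohort.
    session_lengths_min : sequence of int
        Length of each session in minutes.
    baseline_length_min : int
        Length of the pre-session resting baseline recording in minutes.
    n_facilitator_pool : int
        Size of the shared facilitator pool; facilitators recur across
        cohorts, participants never do.
    seed : int
        Master seed; every random stream is derived from it.
    """

    n_cohorts: int = 10
    cohort_sizes: tuple[int, ...] = DEFAULT_COHORT_SIZES
    n_sessions: int = 6
    session_lengths_min: tuple[int, ...] = DEFAULT_SESSION_LENGTHS
    baseline_length_min: int = 5
    n_facilitator_pool: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cohorts < 1:
            raise ConfigurationError("need at least one cohort")
        if len(self.cohort_sizes) != self.n_cohorts:
            raise ConfigurationError(
                f"cohort_sizes has {len(self.cohort_sizes)} entries "
                f"for n_cohorts={self.n_cohorts}"
            )
        if any(s < 3 for s in self.cohort_sizes):
            raise ConfigurationError("every cohort needs at least 3 members")
        if len(self.session_lengths_min) != self.n_sessions:
            raise ConfigurationError(
                f"session_lengths_min has {len(self.session_lengths_min)} "
                f"entries for n_sessions={self.n_sessions}"
            )
        if any(m < 2 for m in self.session_lengths_min):
            raise ConfigurationError("session lengths must be >= 2 minutes")
        if self.baseline_length_min < 1:
            raise ConfigurationError("baseline must be >= 1 minute")
        if self.n_facilitator_pool < 2:
            raise ConfigurationError("facilitator pool must hold >= 2 people")

    @property
    def drug_assignment(self) -> tuple[str, ...]:
        """Condition per cohort: alternating, so half the cohorts (and a
        balanced share of each cohort size) receive each drug."""
        return tuple(
            "oxytocin" if i % 2 == 0 else "placebo"
            for i in range(self.n_cohorts)
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort_sizes"] = list(self.cohort_sizes)
        d["session_lengths_min"] = list(self.session_lengths_min)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        d = dict(d)
        for key in ("cohort_sizes", "session_lengths_min"):
            if key in d:
                d[key] = tuple(int(v) for v in d[key])
        return cls(**d)


@dataclass
class SimulationTruth:
    """Ground truth for one simulated study.

    coupling maps ``(cohort_id, session, sender_id, receiver_id)`` to the
    directed coupling coefficient (the expected linkage b1); ``stability``
    maps person to the autoregressive coefficient on their own reactivity
    (expected b2).  ``attendance`` maps ``(person_id, cohort_id, session)``
    to presence.  ``segment_missing_prob`` holds the per-condition overall
    missing-data targets (missed sessions included); the study generator
    derives from them the conditional mask rate for present minutes.
    """

    coupling: dict = field(default_factory=dict)
    stability: dict = field(default_factory=dict)
    innovation_sd: float = 20.0
    baseline_level: dict = field(default_factory=dict)
    measurement_sd: float = 5.0
    attendance: dict = field(default_factory=dict)
    segment_missing_prob: dict = field(
        default_factory=lambda: dict(DEFAULT_MISSING_TARGETS)
    )
    #: per-minute scattered signal-loss rate among otherwise-recorded
    #: sessions; the remainder of the missing-data target is delivered as
    #: whole-session device dropout so that most surviving estimates still
    #: clear the 50% completeness rule, as in real recordings
    scatter_missing_prob: float = 0.15

    def validate(self) -> None:
        for pid, b2 in self.stability.items():
            if not abs(b2) < 1:
                raise ConfigurationError(f"|stability| must be < 1 for {pid}")
        for cond, p in self.segment_missing_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"missing prob for {cond} not in [0,1]")
        if not 0.0 <= self.scatter_missing_prob <= 1.0:
            raise ConfigurationError("scatter_missing_prob not in [0,1]")
        for lvl in self.baseline_level.values():
            if lvl <= 0:
                raise ConfigurationError("baseline_level must be positive")

    def transition_matrix(
        self, cohort_id: str, session: int, members: Sequence[str]
    ) -> np.ndarray:
        """Per-cohort-session VAR(1) transition matrix A.

        Row r, column s holds the influence of member s's reactivity at
        minute t on member r's at t+1; the diagonal holds stability.
        """
        n = len(members)
        A = np.zeros((n, n))
        for i, pid in enumerate(members):
            A[i, i] = self.stability.get(pid, 0.0)
        for j, sender in enumerate(members):
            for i, receiver in enumerate(members):
                if i == j:
                    continue
                key = (cohort_id, session, sender, receiver)
                A[i, j] = self.coupling.get(key, 0.0)
        return A

    def to_json(self) -> str:
        def _keyed(d: Mapping) -> dict:
            return {
                "|".join(str(p) for p in k) if isinstance(k, tuple) else str(k): v
                for k, v in d.items()
            }

        return json.dumps(
            {
                "coupling": _keyed(self.coupling),
                "stability": dict(self.stability),
                "innovation_sd": self.innovation_sd,
                "baseline_level": dict(self.baseline_level),
                "measurement_sd": self.measurement_sd,
                "attendance": _keyed(self.attendance),
                "segment_missing_prob": dict(self.segment_missing_prob),
                "scatter_missing_prob": self.scatter_missing_prob,
            },
            indent=1,
            sort_keys=True,
        )


def spectral_radius(A: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(A)))) if A.size else 0.0


def check_stationary(A: np.ndarray) -> None:
    """Reject transition matrices whose spectral radius is >= 1."""
    rho = spectral_radius(A)
    if rho >= 1.0:
        raise ConfigurationError(
            f"transition matrix is nonstationary (spectral radius {rho:.3f} >= 1)"
        )


def load_config(path) -> dict:
    """Read a flat YAML config; returns the raw mapping (may be empty)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return raw or {}


def study_config_from_yaml(path) -> StudyConfig:
    raw = load_config(path)
    cfg_keys = {f for f in StudyConfig.__dataclass_fields__}
    return StudyConfig.from_dict({k: v for k, v in raw.items() if k in cfg_keys})
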