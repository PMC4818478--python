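"""Seeded generators emulating the vignette study and the request cohort.

Two study arms are simulated.

**Vignette arm.**  A panel of raters evaluates a set of clinical vignettes.
Each vignette has a latent questionnaire answer set drawn uniformly from the
decision-table combinations that classify to its target priority, so the
reference priority holds by construction (default: 40 vignettes distributed
7/13/10/10 over priorities 1-4).  Each rater reads the vignette through a
noisy channel: per question, the latent answer is reproduced with probability
``question_fidelity``, otherwise an adjacent category is substituted
(reflecting at the scale ends; the binary request-type question flips).  The
rater's algorithm-based priority is always the decision rule applied to the
rater's answers.  In parallel, each rater's *intuitive* priority is the
reference priority passed through an ordinal confusion kernel: with
probability ``intuition_noise`` it moves to an adjacent priority.  Raters also
judge appropriateness of admission: a 4-level Likert answer and a yes/no
last-ICU-bed answer drawn from priority-indexed probabilities.

**Cohort arm.**  Admission requests with fixed per-priority counts (default
265/155/102/61 prioritized records plus 20 with missing priority, totalling
603) receive independent Bernoulli outcomes — ICU admission, in-hospital
death, palliative-care consultation — at per-priority configured rates.

All randomness flows from one seed through named child streams, so identical
configurations give bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from functools import cached_property
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    PriorityClass,
    TriageAssessment,
    classify_priority,
    enumerate_decision_table,
)

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "generate_reference_vignettes",
    "simulate_raters",
    "simulate_cohort",
    "simulate_study",
]

_QUESTIONS = ("request_type", "comorbidity", "functionality", "prognosis")
_CATEGORY_COUNTS = (2, 4, 3, 3)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with the study's sizes as defaults.

    ``question_fidelity`` may be a single probability applied to all four
    questions or a 4-tuple (Q1..Q4).  ``intuition_noise`` is the probability
    that a rater's intuitive priority slips to a neighboring class.  Outcome
    and appropriateness probabilities are indexed by priority 1-4;
    ``unclassified_outcome_probs`` covers the records with missing priority
    (defaults are the cohort-wide admission/mortality/palliative rates).
    """

    seed: int = 0
    n_vignettes: int = 40
    n_raters: int = 9
    reference_distribution: tuple[int, int, int, int] = (7, 13, 10, 10)
    question_fidelity: float | tuple[float, float, float, float] = 0.9
    intuition_noise: float = 0.4
    cohort_n: int = 603
    cohort_priority_counts: tuple[int, int, int, int] = (265, 155, 102, 61)
    admission_probs: tuple[float, float, float, float] = (0.652, 0.632, 0.569, 0.525)
    mortality_probs: tuple[float, float, float, float] = (0.355, 0.276, 0.461, 0.661)
    palliative_probs: tuple[float, float, float, float] = (0.079, 0.045, 0.118, 0.164)
    last_bed_probs: tuple[float, float, float, float] = (0.837, 0.612, 0.452, 0.168)
    appropriate_probs: tuple[float, float, float, float] = (1.0, 0.94, 0.952, 0.671)
    unclassified_outcome_probs: dict[str, float] = field(
        default_factory=lambda: {"admitted": 0.620, "died": 0.378, "palliative": 0.085}
    )
    discussion_variant: bool = False
    n_bootstrap: int = 2000

    def fidelities(self) -> tuple[float, float, float, float]:
        f = self.question_fidelity
        if isinstance(f, (int, float)):
            return (float(f),) * 4
        if len(f) != 4:
            raise ValueError("question_fidelity must be a scalar or a 4-tuple")
        return tuple(float(v) for v in f)

    def validate(self) -> "SimulationConfig":
        if sum(self.reference_distribution) != self.n_vignettes:
            raise ValueError(
                "reference_distribution must sum to n_vignettes "
                f"({sum(self.reference_distribution)} != {self.n_vignettes})"
            )
        if sum(self.cohort_priority_counts) > self.cohort_n:
            raise ValueError("cohort_priority_counts exceed cohort_n")
        probs = (
            list(self.fidelities())
            + [self.intuition_noise]
            + list(self.admission_probs)
            + list(self.mortality_probs)
            + list(self.palliative_probs)
            + list(self.last_bed_probs)
            + list(self.appropriate_probs)
            + list(self.unclassified_outcome_probs.values())
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.n_raters < 2 or self.n_vignettes < 2:
            raise ValueError("need at least 2 raters and 2 vignettes")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["question_fidelity"] = list(self.fidelities())
        for key, value in d.items():
            if isinstance(value, tuple):
                d[key] = list(value)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in (
            "reference_distribution",
            "cohort_priority_counts",
            "admission_probs",
            "mortality_probs",
            "palliative_probs",
            "last_bed_probs",
            "appropriate_probs",
        ):
            if key in kwargs and isinstance(kwargs[key], (list, tuple)):
                kwargs[key] = tuple(kwargs[key])
        if "question_fidelity" in kwargs and isinstance(kwargs["question_fidelity"], list):
            kwargs["question_fidelity"] = tuple(kwargs["question_fidelity"])
        return cls(**kwargs).validate()

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    """Named independent child streams derived from the one run seed."""
    root = np.random.SeedSequence(seed)
    names = ("vignettes", "raters", "intuition", "judgments", "cohort")
    children = root.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def generate_reference_vignettes(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[TriageAssessment], np.ndarray]:
    """Latent assessments whose decision-rule class equals the target priority.

    For each priority stratum in ``reference_distribution``, draws uniformly
    (with replacement) among the decision-table combinations classifying to
    that priority.  Returns the assessments and the reference priorities; the
    identity ``classify_priority(latent) == reference`` holds by construction.
    """
    cfg.validate()
    rng = rng if rng is not None else _streams(cfg.seed)["vignettes"]
    by_priority: dict[int, list[TriageAssessment]] = {1: [], 2: [], 3: [], 4: []}
    for assessment, priority in enumerate_decision_table(
        discussion_variant=cfg.discussion_variant
    ):
        by_priority[priority.value].append(assessment)
    latent: list[TriageAssessment] = []
    reference: list[int] = []
    for priority, count in zip((1, 2, 3, 4), cfg.reference_distribution):
        pool = by_priority[priority]
        picks = rng.integers(0, len(pool), size=count)
        latent.extend(pool[i] for i in picks)
        reference.extend([priority] * count)
    return latent, np.array(reference, dtype=int)


def _perturb_answer(code: int, k: int, fidelity: float, rng: np.random.Generator) -> int:
    """Reproduce the latent code with probability ``fidelity``, else slip.

    Binary questions flip; ordinal questions move to a uniformly chosen
    adjacent category, reflecting at the scale ends.
    """
    if rng.random() < fidelity:
        return code
    if k == 2:
        return 3 - code
    if code == 1:
        return 2
    if code == k:
        return k - 1
    return code + (1 if rng.random() < 0.5 else -1)


@dataclass
class SimulatedStudy:
    """One realization of the synthetic study.

    ``rater_answers[r][v]`` is rater ``r``'s questionnaire for vignette ``v``;
    algorithm-based priorities are always derived from those answers by the
    decision rule, never stored independently.
    """

    config: SimulationConfig
    latent_assessments: list[TriageAssessment]
    reference_priorities: np.ndarray
    rater_answers: list[list[TriageAssessment]]
    intuitive_priorities: np.ndarray  # raters x vignettes
    judgments: pd.DataFrame  # vignette_id, rater_id, likert, last_bed
    cohort: pd.DataFrame  # patient_id, priority, admitted, died, palliative

    @cached_property
    def algorithm_priorities(self) -> np.ndarray:
        """Raters x vignettes grid of decision-rule priorities."""
        return np.array(
            [
                [
                    classify_priority(
                        a, discussion_variant=self.config.discussion_variant
                    ).value
                    for a in answers
                ]
                for answers in self.rater_answers
            ],
            dtype=int,
        )

    def rating_matrix(self, track: str = "algorithm"):
        """The ratings grid of one track as a :class:`~icutriage.agreement.RatingMatrix`."""
        from .agreement import RatingMatrix

        if track == "algorithm":
            grid = self.algorithm_priorities
        elif track == "intuitive":
            grid = self.intuitive_priorities
        else:
            raise ValueError("track must be 'algorithm' or 'intuitive'")
        ratings = pd.DataFrame(
            grid.T,
            index=pd.Index(range(1, grid.shape[1] + 1), name="vignette_id"),
            columns=[f"rater{r + 1}" for r in range(grid.shape[0])],
        )
        reference = pd.Series(self.reference_priorities, index=ratings.index)
        return RatingMatrix(ratings, reference=reference, category_count=4)


def simulate_raters(
    latent: Sequence[TriageAssessment],
    reference: np.ndarray,
    cfg: SimulationConfig,
    rngs: dict[str, np.random.Generator] | None = None,
) -> tuple[list[list[TriageAssessment]], np.ndarray, pd.DataFrame]:
    """Simulate the rater panel: noisy questionnaires, intuition, judgments."""
    cfg.validate()
    rngs = rngs if rngs is not None else _streams(cfg.seed)
    fid = cfg.fidelities()
    rng_a, rng_i, rng_j = rngs["raters"], rngs["intuition"], rngs["judgments"]

    rater_answers: list[list[TriageAssessment]] = []
    for _ in range(cfg.n_raters):
        answers = []
        for a in latent:
            codes = [
                _perturb_answer(code, k, f, rng_a)
                for code, k, f in zip(a.codes(), _CATEGORY_COUNTS, fid)
            ]
            answers.append(TriageAssessment(*codes))
        rater_answers.append(answers)

    intuitive = np.empty((cfg.n_raters, len(latent)), dtype=int)
    for r in range(cfg.n_raters):
        for v, ref in enumerate(reference):
            intuitive[r, v] = _perturb_answer(int(ref), 4, 1.0 - cfg.intuition_noise, rng_i)

    rows = []
    for r in range(cfg.n_raters):
        for v, ref in enumerate(reference):
            p = int(ref) - 1
            appropriate = rng_j.random() < cfg.appropriate_probs[p]
            likert = int(rng_j.integers(1, 3)) if appropriate else int(rng_j.integers(3, 5))
            last_bed = bool(rng_j.random() < cfg.last_bed_probs[p])
            rows.append(
                {
                    "vignette_id": v + 1,
                    "rater_id": f"rater{r + 1}",
                    "likert": likert,
                    "last_bed": last_bed,
                }
            )
    judgments = pd.DataFrame(rows)
    return rater_answers, intuitive, judgments


def simulate_cohort(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Cohort of admission requests with Bernoulli outcomes per stratum.

    Emits ``sum(cohort_priority_counts)`` prioritized records plus enough
    missing-priority records to reach ``cohort_n``; outcomes are independent
    Bernoulli draws at the stratum's configured probability.
    """
    cfg.validate()
    rng = rng if rng is not None else _streams(cfg.seed)["cohort"]
    records = []
    pid = 0
    for priority, count in zip((1, 2, 3, 4), cfg.cohort_priority_counts):
        p = priority - 1
        for _ in range(count):
            pid += 1
            records.append(
                {
                    "patient_id": pid,
                    "priority": priority,
                    "admitted": bool(rng.random() < cfg.admission_probs[p]),
                    "died": bool(rng.random() < cfg.mortality_probs[p]),
                    "palliative": bool(rng.random() < cfg.palliative_probs[p]),
                }
            )
    probs = cfg.unclassified_outcome_probs
    for _ in range(cfg.cohort_n - sum(cfg.cohort_priority_counts)):
        pid += 1
        records.append(
            {
                "patient_id": pid,
                "priority": None,
                "admitted": bool(rng.random() < probs["admitted"]),
                "died": bool(rng.random() < probs["died"]),
                "palliative": bool(rng.random() < probs["palliative"]),
            }
        )
    return pd.DataFrame(records)


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Run both study arms from one seed and return the full realization."""
    cfg.validate()
    rngs = _streams(cfg.seed)
    latent, reference = generate_reference_vignettes(cfg, rngs["vignettes"])
    rater_answers, intuitive, judgments = simulate_raters(latent, reference, cfg, rngs)
    cohort = simulate_cohort(cfg, rngs["cohort"])
    return SimulatedStudy(
        config=cfg,
        latent_assessments=latent,
        reference_priorities=reference,
        rater_answers=rater_answers,
        intuitive_priorities=intuitive,
        judgments=judgments,
        cohort=cohort,
    )
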