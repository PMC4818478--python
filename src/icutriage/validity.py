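"""Construct- and criterion-validity analyses for triage priorities.

Construct validity: how strongly do the algorithm's priority classes track
clinicians' judgment of the appropriateness of ICU admission?  Appropriateness
is elicited per vignette on a 4-level Likert scale (1 = completely agree with
admission ... 4 = completely disagree), dichotomized as appropriate (1-2) vs
inappropriate (3-4) for the non-scarcity setting, and as a yes/no "would you
admit this patient to the last ICU bed" question for the scarcity setting.

Criterion validity: in a cohort of admission requests, the per-priority rates
of actual ICU admission, in-hospital death, and palliative-care consultation,
with a one-degree-of-freedom chi-square test for linear trend across the four
ordered priority strata (Cochran-Armitage, equally spaced scores).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "Appropriateness",
    "RateByPriority",
    "dichotomize_likert",
    "appropriateness_by_priority",
    "outcome_rates_by_priority",
    "cochran_armitage_trend",
    "chi_square_association",
    "format_percent",
]

OUTCOME_COLUMNS = {
    "MORTALITY": "died",
    "ADMISSION": "admitted",
    "PALLIATIVE": "palliative",
}


class Appropriateness(enum.Enum):
    APPROPRIATE = "APPROPRIATE"
    INAPPROPRIATE = "INAPPROPRIATE"


def dichotomize_likert(likert: int) -> Appropriateness:
    """Collapse the 4-level appropriateness scale: 1-2 appropriate, 3-4 not."""
    if likert not in (1, 2, 3, 4):
        raise ValueError(f"likert value must be in 1..4, got {likert!r}")
    return Appropriateness.APPROPRIATE if likert <= 2 else Appropriateness.INAPPROPRIATE


def format_percent(numerator: int, denominator: int) -> str:
    """Percentage with one decimal, rounding half up (e.g. 47/102 -> '46.1')."""
    if denominator == 0:
        raise ZeroDivisionError("empty stratum has no defined proportion")
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return str(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class RateByPriority:
    """Per-priority event counts and proportions with a trend test.

    ``rates`` maps priority level to ``(numerator, denominator, proportion)``;
    proportions are exact fractions of the stored counts.  Strata listed in
    ``undefined_strata`` had no records and are excluded from the trend test.
    """

    outcome: str
    rates: dict[int, tuple[int, int, float]]
    trend_statistic: float
    trend_p: float
    undefined_strata: list[int]
    n_excluded: int = 0

    def formatted(self) -> dict[int, str]:
        """Printed-style percentages (one decimal, round half up) by priority."""
        return {p: format_percent(n, d) for p, (n, d, _) in self.rates.items()}

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "rates": {
                str(p): {
                    "events": n,
                    "total": d,
                    "proportion": prop,
                    "percent": format_percent(n, d),
                }
                for p, (n, d, prop) in self.rates.items()
            },
            "trend_statistic": self.trend_statistic,
            "trend_p": self.trend_p,
            "undefined_strata": self.undefined_strata,
            "n_excluded": self.n_excluded,
        }


def cochran_armitage_trend(
    table: Sequence[Sequence[int]] | np.ndarray,
    scores: Sequence[float] | None = None,
) -> tuple[float, float]:
    """Chi-square test for linear trend in proportions across ordered strata.

    ``table`` holds one row per stratum as ``(events, non-events)`` counts.
    The statistic is the squared score test for a linear trend with the given
    stratum scores (default equally spaced 1..r), referred to a chi-square
    distribution with one degree of freedom; no continuity correction.  It is
    invariant under affine rescaling of the scores, and with two strata it
    equals the square of the pooled two-proportion z statistic.  If every
    stratum has the same outcome for all records, the statistic is 0 and p is 1.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 2:
        raise ValueError("table must be r x 2 (events, non-events)")
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be nonnegative integers")
    totals = counts.sum(axis=1)
    keep = totals > 0
    counts, totals = counts[keep], totals[keep]
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 strata with nonzero totals")
    s = np.arange(1, counts.shape[0] + 1, dtype=float) if scores is None else np.asarray(
        [sc for sc, k in zip(scores, keep) if k], dtype=float
    )
    if s.shape[0] != counts.shape[0]:
        raise ValueError("scores must match the number of strata")
    events = counts[:, 0]
    n_total = totals.sum()
    p_bar = events.sum() / n_total
    if p_bar in (0.0, 1.0):
        return 0.0, 1.0
    t = float((s * events).sum() - p_bar * (s * totals).sum())
    var = p_bar * (1 - p_bar) * ((totals * s**2).sum() - (totals * s).sum() ** 2 / n_total)
    if var <= 0:
        return 0.0, 1.0
    statistic = t**2 / var
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


def chi_square_association(
    table: Sequence[Sequence[int]] | np.ndarray,
) -> tuple[float, int, float]:
    """Pearson chi-square of independence, no continuity correction.

    Rows or columns with a zero margin are dropped with a warning; returns
    ``(statistic, df, p)`` with ``df = (r-1)(c-1)`` on the retained table.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    row_ok = counts.sum(axis=1) > 0
    col_ok = counts.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        logger.warning(
            "chi-square: dropping %d zero-margin row(s) and %d column(s)",
            int((~row_ok).sum()),
            int((~col_ok).sum()),
        )
        counts = counts[row_ok][:, col_ok]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least 2 non-empty rows and columns")
    result = stats.chi2_contingency(counts, correction=False)
    return float(result.statistic), int(result.dof), float(result.pvalue)


def _rates_with_trend(
    outcome: str,
    counts: Mapping[int, tuple[int, int]],
    n_excluded: int = 0,
) -> RateByPriority:
    rates: dict[int, tuple[int, int, float]] = {}
    undefined: list[int] = []
    trend_rows = []
    for priority in (1, 2, 3, 4):
        num, den = counts.get(priority, (0, 0))
        if den == 0:
            undefined.append(priority)
            logger.warning("%s: priority-%d stratum empty, excluded from trend", outcome, priority)
            continue
        rates[priority] = (num, den, float(Fraction(num, den)))
        trend_rows.append((num, den - num))
    if len(trend_rows) >= 2:
        statistic, p = cochran_armitage_trend(trend_rows)
    else:
        statistic, p = float("nan"), float("nan")
    return RateByPriority(
        outcome=outcome,
        rates=rates,
        trend_statistic=statistic,
        trend_p=p,
        undefined_strata=undefined,
        n_excluded=n_excluded,
    )


def appropriateness_by_priority(
    judgments: pd.DataFrame,
    priorities: Mapping[object, int] | pd.Series,
    setting: str = "SCARCITY",
) -> RateByPriority:
    """Per-priority appropriateness proportions with a trend test.

    ``judgments`` needs columns ``vignette_id``, ``likert``, ``last_bed``;
    ``priorities`` maps each vignette id to its priority class.  In the
    NONSCARCITY setting the event is a dichotomized-appropriate Likert answer
    (1 or 2); in the SCARCITY setting it is a yes to the last-ICU-bed
    question.
    """
    setting = setting.upper()
    if setting not in ("SCARCITY", "NONSCARCITY"):
        raise ValueError("setting must be SCARCITY or NONSCARCITY")
    judgments = pd.DataFrame(judgments)
    priorities = pd.Series(dict(priorities) if not isinstance(priorities, pd.Series) else priorities)
    unmatched = sorted(set(judgments["vignette_id"]) - set(priorities.index))
    if unmatched:
        raise ValueError(f"judgments reference unknown vignette ids: {unmatched}")
    bad = ~judgments["likert"].isin([1, 2, 3, 4])
    if bad.any():
        raise ValueError(
            f"likert values outside 1..4 at rows {list(judgments.index[bad])}"
        )
    if setting == "NONSCARCITY":
        event = judgments["likert"] <= 2
    else:
        event = judgments["last_bed"].astype(bool)
    priority = judgments["vignette_id"].map(priorities).astype(int)
    counts = {
        int(p): (int(event[priority == p].sum()), int((priority == p).sum()))
        for p in sorted(priority.unique())
    }
    return _rates_with_trend(f"APPROPRIATENESS_{setting}", counts)


def outcome_rates_by_priority(
    cohort: pd.DataFrame, outcome: str
) -> RateByPriority:
    """Per-priority rate of a binary cohort outcome with a trend test.

    ``outcome`` is one of MORTALITY, ADMISSION, PALLIATIVE, mapping to the
    cohort columns ``died``, ``admitted``, ``palliative``.  Records with a
    missing priority are excluded from the stratified rates (their count is
    reported in ``n_excluded``).
    """
    outcome = outcome.upper()
    if outcome not in OUTCOME_COLUMNS:
        raise ValueError(f"outcome must be one of {sorted(OUTCOME_COLUMNS)}")
    cohort = pd.DataFrame(cohort)
    if cohort.empty:
        raise ValueError("cohort is empty")
    col = OUTCOME_COLUMNS[outcome]
    priority = pd.to_numeric(cohort["priority"], errors="coerce")
    known = priority.notna()
    n_excluded = int((~known).sum())
    if n_excluded:
        logger.info("%s: excluding %d record(s) with missing priority", outcome, n_excluded)
    event = cohort[col].astype(bool)
    counts = {}
    for p in (1, 2, 3, 4):
        mask = known & (priority == p)
        counts[p] = (int(event[mask].sum()), int(mask.sum()))
    return _rates_with_trend(outcome, counts, n_excluded=n_excluded)
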