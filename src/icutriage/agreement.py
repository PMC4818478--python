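"""Inter-rater reliability statistics for ordinal priority ratings.

Implements the reliability toolkit for a vignettes-by-raters grid of ordinal
ratings in ``1..k``: quadratic-weighted Cohen's kappa, raw percent agreement,
pairwise aggregation with a vignette-level bootstrap confidence interval,
per-rater agreement against a reference standard, and the average-measures
intraclass correlation coefficient (ICC).

The quadratic weighting scheme scores partial credit for near-misses:
``w_ij = 1 - (i - j)^2 / (k - 1)^2``, so adjacent categories disagree mildly
and opposite extremes disagree completely.  Kappa corrects the weighted
observed agreement for the agreement expected by chance from the two raters'
marginal distributions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RatingMatrix",
    "AgreementSummary",
    "UndefinedKappaError",
    "quadratic_weights",
    "weighted_kappa",
    "percent_agreement",
    "pairwise_summary",
    "kappa_vs_reference",
    "icc_average",
    "landis_koch_label",
]


class UndefinedKappaError(ValueError):
    """Chance agreement is 1 (both raters constant) and the vectors differ."""


@dataclass
class RatingMatrix:
    """A vignettes x raters grid of ordinal ratings with an optional reference.

    Parameters
    ----------
    ratings:
        DataFrame indexed by vignette id, one column per rater; cells hold
        ordinal values in ``1..category_count`` or NaN for missing.
    reference:
        Optional per-vignette reference-standard rating, aligned on the index.
    category_count:
        Number of ordinal categories ``k`` (default 4).  Explicit so that
        unobserved categories still shape the quadratic weights.
    """

    ratings: pd.DataFrame
    reference: pd.Series | None = None
    category_count: int = 4

    def __post_init__(self) -> None:
        self.ratings = pd.DataFrame(self.ratings).astype(float)
        values = self.ratings.to_numpy()
        finite = values[np.isfinite(values)]
        if finite.size and (
            (finite < 1).any()
            or (finite > self.category_count).any()
            or (finite != np.round(finite)).any()
        ):
            raise ValueError(
                f"ratings must be integers in 1..{self.category_count} or missing"
            )
        if self.reference is not None:
            self.reference = pd.Series(self.reference).astype(float)
            self.reference = self.reference.reindex(self.ratings.index)
            ref = self.reference.to_numpy()
            ok = np.isfinite(ref)
            if ((ref[ok] < 1) | (ref[ok] > self.category_count)).any():
                raise ValueError(
                    f"reference must lie in 1..{self.category_count}"
                )

    @property
    def n_vignettes(self) -> int:
        return self.ratings.shape[0]

    @property
    def n_raters(self) -> int:
        return self.ratings.shape[1]

    @property
    def raters(self) -> list[str]:
        return [str(c) for c in self.ratings.columns]


@dataclass
class AgreementSummary:
    """Aggregate of an agreement statistic over rater pairs (or raters).

    ``pairwise_values`` maps the pair (or rater) label to its statistic;
    ``overall`` is the mean of those values; ``ci95`` is a bootstrap interval
    for the overall value when one was computed.
    """

    statistic: str
    pairwise_values: dict[tuple[str, ...] | str, float]
    median: float
    iqr: tuple[float, float]
    overall: float
    ci95: tuple[float, float] | None = None
    dropped_pairs: list[tuple[str, ...] | str] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairwise_values)

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "n_pairs": self.n_pairs,
            "overall": self.overall,
            "ci95": list(self.ci95) if self.ci95 is not None else None,
            "median": self.median,
            "iqr": list(self.iqr),
            "pairwise_values": {
                "/".join(k) if isinstance(k, tuple) else str(k): v
                for k, v in self.pairwise_values.items()
            },
            "dropped_pairs": [
                "/".join(k) if isinstance(k, tuple) else str(k)
                for k in self.dropped_pairs
            ],
        }


def quadratic_weights(k: int) -> np.ndarray:
    """The k x k quadratic agreement-weight grid ``1 - (i-j)^2/(k-1)^2``.

    Symmetric, 1 on the diagonal, 0 at the extreme-disagreement corners.
    For ``k = 2`` it reduces to the identity, i.e. unweighted agreement.
    """
    if k < 2:
        raise ValueError("category count k must be >= 2")
    idx = np.arange(k)
    return 1.0 - np.subtract.outer(idx, idx) ** 2 / (k - 1) ** 2


def _paired(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("rating vectors must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def confusion_proportions(
    x: Sequence[float], y: Sequence[float], k: int
) -> np.ndarray:
    """k x k joint proportion table of two paired rating vectors."""
    x, y = _paired(x, y)
    table = np.zeros((k, k))
    np.add.at(table, (x.astype(int) - 1, y.astype(int) - 1), 1.0)
    return table / table.sum()


def weighted_kappa(
    x: Sequence[float], y: Sequence[float], k: int = 4
) -> float:
    """Quadratic-weighted Cohen's kappa between two ordinal rating vectors.

    Positions where either rating is missing are dropped pairwise; at least
    two retained positions are required.  Defined as
    ``(P_o(w) - P_e(w)) / (1 - P_e(w))`` with weighted observed agreement
    ``P_o(w) = sum(W * P)`` over the joint proportion table and chance
    agreement ``P_e(w)`` from the product of the marginals.  Identical vectors
    give 1 even when both raters are constant.  Chance agreement of 1 — which
    leaves kappa undefined — only arises when both raters are constant on the
    same category; should that ever coincide with a discrepancy,
    :class:`UndefinedKappaError` is raised rather than dividing by zero.
    """
    x, y = _paired(x, y)
    if x.size < 2:
        raise ValueError("need at least 2 overlapping ratings")
    if ((x < 1) | (x > k) | (y < 1) | (y > k)).any():
        raise ValueError(f"ratings must lie in 1..{k}")
    weights = quadratic_weights(k)
    joint = confusion_proportions(x, y, k)
    p_obs = float((weights * joint).sum())
    expected = np.outer(joint.sum(axis=1), joint.sum(axis=0))
    p_exp = float((weights * expected).sum())
    if np.isclose(p_exp, 1.0):
        if np.array_equal(x, y):
            return 1.0
        raise UndefinedKappaError(
            "undefined kappa: chance agreement is 1 but raters disagree"
        )
    return (p_obs - p_exp) / (1.0 - p_exp)


def percent_agreement(x: Sequence[float], y: Sequence[float]) -> float:
    """Fraction of retained (pairwise non-missing) positions with exact equality."""
    x, y = _paired(x, y)
    if x.size == 0:
        raise ValueError("no overlapping ratings")
    return float(np.mean(x == y))


def _iqr(values: np.ndarray) -> tuple[float, float]:
    # 25th/75th percentiles by linear interpolation
    lo, hi = np.percentile(values, [25, 75])
    return float(lo), float(hi)


def _pair_stat(stat: str, x, y, k: int) -> float:
    if stat == "kappa":
        return weighted_kappa(x, y, k)
    if stat == "percent":
        return percent_agreement(x, y)
    raise ValueError(f"unknown statistic {stat!r}; expected 'kappa' or 'percent'")


def pairwise_summary(
    m: RatingMatrix,
    stat: Literal["kappa", "percent"] = "kappa",
    *,
    n_bootstrap: int = 2000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> AgreementSummary:
    """Agreement statistic over every unordered rater pair, with summary.

    Computes the statistic for all ``r(r-1)/2`` pairs (36 pairs for a 9-rater
    panel), the median and IQR across pairs, the overall value (mean of
    pairwise values), and — when ``n_bootstrap > 0`` — a seeded nonparametric
    bootstrap percentile CI obtained by resampling vignettes.  Pairs with no
    overlapping ratings, or with undefined kappa, are dropped and logged.
    """
    if m.n_raters < 2:
        raise ValueError("need at least 2 raters")
    if m.n_vignettes < 2:
        raise ValueError("need at least 2 vignettes")
    values: dict[tuple[str, ...], float] = {}
    dropped: list[tuple[str, ...]] = []
    cols = list(m.ratings.columns)
    for a, b in combinations(cols, 2):
        key = (str(a), str(b))
        try:
            values[key] = _pair_stat(stat, m.ratings[a], m.ratings[b], m.category_count)
        except (ValueError, UndefinedKappaError) as exc:
            logger.warning("dropping rater pair %s: %s", key, exc)
            dropped.append(key)
    if not values:
        raise ValueError("no rater pair had enough overlapping ratings")
    arr = np.array(list(values.values()))
    overall = float(arr.mean())

    ci = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        grid = m.ratings.to_numpy()
        n = grid.shape[0]
        pair_idx = [
            (cols.index(a), cols.index(b)) for a, b in combinations(cols, 2)
        ]
        boot = np.empty(n_bootstrap)
        for i in range(n_bootstrap):
            rows = rng.integers(0, n, size=n)
            sample = grid[rows]
            vals = []
            for ia, ib in pair_idx:
                try:
                    vals.append(
                        _pair_stat(stat, sample[:, ia], sample[:, ib], m.category_count)
                    )
                except (ValueError, UndefinedKappaError):
                    continue
            boot[i] = np.mean(vals) if vals else np.nan
        alpha = (1.0 - ci_level) / 2.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lo, hi = np.nanpercentile(boot, [100 * alpha, 100 * (1 - alpha)])
        ci = (float(lo), float(hi))

    return AgreementSummary(
        statistic=stat,
        pairwise_values=values,
        median=float(np.median(arr)),
        iqr=_iqr(arr),
        overall=overall,
        ci95=ci,
        dropped_pairs=dropped,
    )


def kappa_vs_reference(
    m: RatingMatrix, stat: Literal["kappa", "percent"] = "kappa"
) -> AgreementSummary:
    """Per-rater agreement against the reference-standard column.

    Returns the per-rater quadratic-weighted kappa (or percent agreement)
    against the reference, with the median and IQR taken across raters.
    """
    if m.reference is None:
        raise ValueError("rating matrix has no reference standard")
    values: dict[str, float] = {}
    dropped: list[str] = []
    for col in m.ratings.columns:
        try:
            values[str(col)] = _pair_stat(
                stat, m.ratings[col], m.reference, m.category_count
            )
        except (ValueError, UndefinedKappaError) as exc:
            logger.warning("dropping rater %s vs reference: %s", col, exc)
            dropped.append(str(col))
    if not values:
        raise ValueError("no rater overlapped the reference standard")
    arr = np.array(list(values.values()))
    return AgreementSummary(
        statistic=f"{stat}_vs_reference",
        pairwise_values=values,
        median=float(np.median(arr)),
        iqr=_iqr(arr),
        overall=float(arr.mean()),
        ci95=None,
        dropped_pairs=dropped,
    )


def icc_average(
    m: RatingMatrix,
    *,
    model: Literal["consistency", "agreement"] = "consistency",
    ci_level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Average-measures intraclass correlation of the rating panel.

    Ratings are treated as interval-scaled in a two-way model (vignettes x
    raters); the default is the consistency-type average-measures coefficient
    (ICC3k in the Shrout-Fleiss taxonomy), with the absolute-agreement
    variant (ICC2k) available via ``model="agreement"``.  Vignettes with any
    missing rating are dropped listwise (and logged).  Returns the ICC and an
    F-based confidence interval.
    """
    import pingouin as pg

    if m.n_raters < 2:
        raise ValueError("need at least 2 raters")
    complete = m.ratings.dropna(axis=0, how="any")
    n_dropped = m.n_vignettes - complete.shape[0]
    if n_dropped:
        logger.info("icc: dropped %d vignette(s) with missing ratings", n_dropped)
    if complete.shape[0] < 3:
        raise ValueError("need at least 3 complete-case vignettes")
    if np.allclose(complete.mean(axis=1).var(ddof=1), 0.0):
        raise ValueError("no subject variance: between-vignette variance is zero")
    long = complete.reset_index(names="vignette").melt(
        id_vars="vignette", var_name="rater", value_name="rating"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(
            data=long,
            targets="vignette",
            raters="rater",
            ratings="rating",
            nan_policy="omit",
        ).set_index("Type")
    # row/column labels differ across pingouin versions
    labels = ("ICC3k", "ICC(C,k)") if model == "consistency" else ("ICC2k", "ICC(A,k)")
    label = next(l for l in labels if l in table.index)
    row = table.loc[label]
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    icc = float(row["ICC"])
    lo, hi = (float(v) for v in row[ci_col])
    return icc, (lo, hi)


_LANDIS_KOCH_BANDS = (
    (0.0, "slight"),
    (0.21, "fair"),
    (0.41, "moderate"),
    (0.61, "substantial"),
    (0.81, "almost perfect"),
)


def landis_koch_label(kappa: float) -> str:
    """Conventional verbal interpretation of a kappa value.

    Bands: <0 poor, 0-0.20 slight, 0.21-0.40 fair, 0.41-0.60 moderate,
    0.61-0.80 substantial, 0.81-1.00 almost perfect; a boundary value belongs
    to the upper band.
    """
    if not -1.0 <= kappa <= 1.0:
        raise ValueError("kappa must lie in [-1, 1]")
    if kappa < 0:
        return "poor"
    label = "slight"
    for edge, name in _LANDIS_KOCH_BANDS:
        if kappa >= edge:
            label = name
    return label
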