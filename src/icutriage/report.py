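"""End-to-end synthetic replication of the study's analysis tables.

``run_replication`` simulates one study realization, then runs the full
analysis: construct validity (agreement with the reference standard and
between the two rating tracks, appropriateness by priority in both scarcity
settings), reliability (pairwise weighted kappa and percent agreement for the
algorithm and intuitive tracks, plus the average-measures ICC), and criterion
validity (admission, mortality, palliative-consultation rates by priority
with trend tests).  The report carries the config hash and seed so every
number is recomputable from the archived inputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import __version__
from .agreement import icc_average, kappa_vs_reference, pairwise_summary, weighted_kappa
from .simulate import SimulatedStudy, SimulationConfig, simulate_study
from .validity import appropriateness_by_priority, outcome_rates_by_priority

logger = logging.getLogger(__name__)

__all__ = ["run_replication", "write_report"]


def _track_reliability(study: SimulatedStudy, track: str, seed: int, n_bootstrap: int) -> dict:
    m = study.rating_matrix(track)
    kappa = pairwise_summary(m, "kappa", n_bootstrap=n_bootstrap, seed=seed)
    percent = pairwise_summary(m, "percent", n_bootstrap=0)
    icc, icc_ci = icc_average(m)
    return {
        "pairwise_kappa": kappa.to_dict(),
        "pairwise_percent_agreement": percent.to_dict(),
        "icc_average": {"value": icc, "ci95": list(icc_ci)},
    }


def run_replication(cfg: SimulationConfig) -> dict:
    """Simulate one study and compute every analysis table as a JSON-able dict."""
    cfg = cfg.validate()
    study = simulate_study(cfg)
    logger.info(
        "simulated %d vignettes x %d raters and a cohort of %d records",
        cfg.n_vignettes,
        cfg.n_raters,
        len(study.cohort),
    )

    algo = study.rating_matrix("algorithm")
    intuitive = study.rating_matrix("intuitive")

    construct = {
        "algorithm_vs_reference": kappa_vs_reference(algo).to_dict(),
        "intuitive_vs_reference": kappa_vs_reference(intuitive).to_dict(),
        "algorithm_vs_intuitive": {
            str(col): float(
                weighted_kappa(
                    algo.ratings[col], intuitive.ratings[col], algo.category_count
                )
            )
            for col in algo.ratings.columns
        },
        "appropriateness": {
            setting.lower(): appropriateness_by_priority(
                study.judgments,
                _scenario_priorities(study),
                setting,
            ).to_dict()
            for setting in ("NONSCARCITY", "SCARCITY")
        },
    }

    reliability = {
        track: _track_reliability(study, track, cfg.seed, cfg.n_bootstrap)
        for track in ("algorithm", "intuitive")
    }

    criterion = {
        outcome.lower(): outcome_rates_by_priority(study.cohort, outcome).to_dict()
        for outcome in ("ADMISSION", "MORTALITY", "PALLIATIVE")
    }

    return {
        "provenance": {
            "package_version": __version__,
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "config": cfg.to_dict(),
        },
        "construct_validity": construct,
        "reliability": reliability,
        "criterion_validity": criterion,
    }


def _scenario_priorities(study: SimulatedStudy) -> dict[int, int]:
    # judgments attach to vignettes; the scenario priority is the reference class
    return {
        v + 1: int(p) for v, p in enumerate(study.reference_priorities)
    }


def write_report(report: dict, out_dir: str | Path) -> Path:
    """Write the JSON report plus per-outcome CSV count tables; returns the JSON path."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / "study_report.json"
    json_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    for outcome, table in report["criterion_validity"].items():
        rows = [
            {
                "priority": p,
                "events": cell["events"],
                "total": cell["total"],
                "percent": cell["percent"],
            }
            for p, cell in sorted(table["rates"].items())
        ]
        pd.DataFrame(rows).to_csv(out_dir / f"rates_{outcome}.csv", index=False)
    for setting, table in report["construct_validity"]["appropriateness"].items():
        rows = [
            {
                "priority": p,
                "events": cell["events"],
                "total": cell["total"],
                "percent": cell["percent"],
            }
            for p, cell in sorted(table["rates"].items())
        ]
        pd.DataFrame(rows).to_csv(out_dir / f"appropriateness_{setting}.csv", index=False)
    return json_path
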