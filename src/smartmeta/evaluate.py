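"""Sensitivity and precision of classifications against known truth.

Definitions (per taxonomy level):

* sensitivity = correct classifications / total reads in the dataset;
* precision  = correct classifications / reads attempted, where a read is
  *attempted* at a level when it received a unique taxon verdict there
  (AMBIGUOUS and UNMATCHED reads stay in the sensitivity denominator but
  drop out of the precision denominator — the reading under which precision
  can exceed sensitivity).  The alternative convention, counting ambiguous
  reads as attempted-but-incorrect, is available via
  ``ambiguous_counts_as_attempted``.

A verdict is correct iff it equals the truth lineage's taxon at that exact
level.  Metrics carry Wilson-score 95% confidence intervals.  Host (truth
mammalian) and microbial reads are also scored separately, so host-rich
samples do not dilute the microbial metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from statsmodels.stats.proportion import proportion_confint

from .classify import AMBIGUOUS, LEVELS, UNMATCHED, ReadClassification
from .errors import EvaluationError
from .taxonomy import TaxonomyTable

__all__ = ["LevelMetrics", "EvalMetrics", "evaluate"]


@dataclass(frozen=True)
class LevelMetrics:
    """Counts and rates at one taxonomy level."""

    level: str
    n_total: int
    n_attempted: int
    n_correct: int
    sensitivity: float
    precision: float | None
    sensitivity_ci: tuple[float, float]
    precision_ci: tuple[float, float] | None

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "n_total": self.n_total,
            "n_attempted": self.n_attempted,
            "n_correct": self.n_correct,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "sensitivity_ci": list(self.sensitivity_ci),
            "precision_ci": (
                list(self.precision_ci) if self.precision_ci else None
            ),
        }


@dataclass
class EvalMetrics:
    """Per-level metrics, overall and split by truth host/microbial."""

    overall: dict[str, LevelMetrics]
    microbial: dict[str, LevelMetrics]
    host: dict[str, LevelMetrics]

    def to_dict(self) -> dict:
        return {
            group: {lvl: m.to_dict() for lvl, m in metrics.items()}
            for group, metrics in (
                ("overall", self.overall),
                ("microbial", self.microbial),
                ("host", self.host),
            )
        }


def _wilson(successes: int, trials: int) -> tuple[float, float]:
    if trials == 0:
        return (0.0, 1.0)
    lo, hi = proportion_confint(successes, trials, alpha=0.05, method="wilson")
    return (float(lo), float(hi))


def _level_metrics(
    level: str,
    verdicts: Sequence[str],
    truths: Sequence[str],
    ambiguous_counts_as_attempted: bool,
) -> LevelMetrics:
    n_total = len(verdicts)
    n_attempted = 0
    n_correct = 0
    for verdict, truth in zip(verdicts, truths):
        if verdict == UNMATCHED:
            continue
        if verdict == AMBIGUOUS:
            if ambiguous_counts_as_attempted:
                n_attempted += 1
            continue
        n_attempted += 1
        if verdict == truth:
            n_correct += 1
    sensitivity = n_correct / n_total if n_total else 0.0
    precision = n_correct / n_attempted if n_attempted else None
    return LevelMetrics(
        level=level,
        n_total=n_total,
        n_attempted=n_attempted,
        n_correct=n_correct,
        sensitivity=sensitivity,
        precision=precision,
        sensitivity_ci=_wilson(n_correct, n_total),
        precision_ci=_wilson(n_correct, n_attempted) if n_attempted else None,
    )


def evaluate(
    classifications: Sequence[ReadClassification],
    truth: Mapping[str, Mapping],
    taxonomy: TaxonomyTable,
    ambiguous_counts_as_attempted: bool = False,
) -> EvalMetrics:
    """Score classifications against a truth table.

    ``truth`` maps read_id to a row with at least a ``species`` field (the
    :func:`smartmeta.simdata.load_truth_tsv` output).  Every classified
    read must have a truth row and every truth species a lineage in the
    taxonomy; orphans on either side raise :class:`EvaluationError`.
    """
    classified_ids = {rc.read_id for rc in classifications}
    orphans = sorted(classified_ids - set(truth))
    missing = sorted(set(truth) - classified_ids)
    if orphans or missing:
        raise EvaluationError(
            f"read universe mismatch: {len(orphans)} classified without "
            f"truth (e.g. {orphans[:3]}), {len(missing)} truth rows never "
            f"classified (e.g. {missing[:3]})"
        )
    species_index = taxonomy.species_index()

    groups: dict[str, list[ReadClassification]] = {
        "overall": [],
        "microbial": [],
        "host": [],
    }
    truth_lineage: dict[str, Mapping] = {}
    for rc in classifications:
        sp = truth[rc.read_id]["species"]
        lineage = species_index.get(sp)
        if lineage is None:
            raise EvaluationError(
                f"truth species {sp!r} absent from the taxonomy"
            )
        truth_lineage[rc.read_id] = lineage
        groups["overall"].append(rc)
        groups["host" if lineage.is_mammalian else "microbial"].append(rc)

    def score(members: list[ReadClassification]) -> dict[str, LevelMetrics]:
        out = {}
        for level in LEVELS:
            verdicts = [rc.verdict_per_level[level] for rc in members]
            truths = [
                truth_lineage[rc.read_id].label_at(level) for rc in members
            ]
            out[level] = _level_metrics(
                level, verdicts, truths, ambiguous_counts_as_attempted
            )
        return out

    return EvalMetrics(
        overall=score(groups["overall"]),
        microbial=score(groups["microbial"]),
        host=score(groups["host"]),
    )
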