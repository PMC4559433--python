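"""Metrics, aggregation, and curation filters for stability-ΔΔG and
alanine-scanning benchmarks.

Sign convention throughout: positive ΔΔG = destabilizing (or weaker binding).
Experimental values are in kcal/mol; predicted values are in the scoring
method's own units (the metrics that compare them are either scale-invariant,
like Pearson's r, or explicitly scale-sensitive, like MAE).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import UndefinedMetricError, ValidationError
from .io_formats import BindingDecomposition, DdgRecord, ScoredModelSet


class StabilityClass(enum.Enum):
    STABILIZING = "stabilizing"
    NEUTRAL = "neutral"
    DESTABILIZING = "destabilizing"


class RejectReason(enum.Enum):
    """Machine-readable curation-rejection codes."""

    RESOLUTION = "resolution"          # not X-ray, or resolution worse than cutoff
    DISCREPANCY = "discrepancy"        # replicate ΔΔG values disagree too much
    TRANSMEMBRANE = "transmembrane"    # mutated protein is transmembrane


@dataclass
class CurationConfig:
    """Thresholds for the thermostability-dataset curation filters.

    ``max_resolution``: worst acceptable crystal resolution in Å.
    ``max_ddg_discrepancy``: largest tolerated spread (max − min, kcal/mol)
    among replicate experimental measurements of one mutation.
    """

    max_resolution: float = 2.5
    max_ddg_discrepancy: float = 2.5
    exclude_transmembrane: bool = True

    def __post_init__(self):
        if self.max_resolution <= 0 or self.max_ddg_discrepancy <= 0:
            raise ValidationError("curation thresholds must be > 0")


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation between experimental and predicted values.

    Raises :class:`UndefinedMetricError` when either input has zero variance
    (rather than propagating NaN into reports).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValidationError("pearson requires at least 2 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("zero variance in input")
    return float(stats.pearsonr(x, y).statistic)


def mean_absolute_error(x: Sequence[float], y: Sequence[float]) -> float:
    """Mean of |x_i − y_i|; on the kcal/mol scale when both inputs are."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise ValidationError("empty input")
    return float(np.mean(np.abs(x - y)))


def _classify_interval(ddg: float, lower: float, upper: float) -> StabilityClass:
    if ddg < lower:
        return StabilityClass.STABILIZING
    if ddg > upper:
        return StabilityClass.DESTABILIZING
    return StabilityClass.NEUTRAL


def classify_stability(ddg: float, neutral_halfwidth: float = 1.0) -> StabilityClass:
    """Classify a ΔΔG as stabilizing / neutral / destabilizing.

    The neutral band is the closed interval [−halfwidth, +halfwidth]; the
    boundaries themselves classify as neutral.
    """
    if not math.isfinite(ddg):
        raise ValidationError(f"non-finite ΔΔG {ddg!r}")
    return _classify_interval(ddg, -neutral_halfwidth, neutral_halfwidth)


def fraction_correct(exp: Sequence[float], pred: Sequence[float],
                     exp_halfwidth: float = 1.0,
                     pred_halfwidth: float = 1.0,
                     pred_bounds: Optional[Tuple[float, float]] = None) -> float:
    """Fraction of mutations whose predicted stability class matches experiment.

    The predicted neutral band defaults to the symmetric ±``pred_halfwidth``
    score units; pass ``pred_bounds=(lower, upper)`` for an asymmetric band
    (e.g. the historical [-3, 1.1] convention).
    """
    exp = np.asarray(exp, float)
    pred = np.asarray(pred, float)
    if exp.shape != pred.shape:
        raise ValidationError(f"length mismatch: {exp.shape} vs {pred.shape}")
    if exp.size == 0:
        raise ValidationError("empty input")
    lo, hi = pred_bounds if pred_bounds is not None else (-pred_halfwidth, pred_halfwidth)
    matches = sum(
        classify_stability(e, exp_halfwidth) == _classify_interval(p, lo, hi)
        for e, p in zip(exp, pred)
    )
    return matches / exp.size


def aggregate_ensemble_ddg(s: ScoredModelSet, n_best: int = 3) -> float:
    """Predicted ΔΔG from a model ensemble: mean of the ``n_best`` lowest
    (best) mutant scores minus mean of the ``n_best`` lowest wild-type scores.

    The mean (not the sum) keeps the result on the per-model score scale.
    """
    for label, scores in (("wildtype", s.wildtype_scores), ("mutant", s.mutant_scores)):
        if len(scores) < n_best:
            raise ValidationError(
                f"case {s.case_id!r}: {label} has {len(scores)} models, "
                f"needs at least {n_best}"
            )
    wt = np.sort(np.asarray(s.wildtype_scores, float))[:n_best]
    mut = np.sort(np.asarray(s.mutant_scores, float))[:n_best]
    return float(mut.mean() - wt.mean())


def alanine_ddg_bind(d: BindingDecomposition) -> float:
    """ΔΔG of binding upon mutation to alanine from six ΔG-of-folding terms:

    (ΔG_complex^MUT − ΔG_A^MUT − ΔG_B^MUT) − (ΔG_complex^WT − ΔG_A^WT − ΔG_B^WT)
    """
    mut = d.dG_complex_mut - d.dG_partnerA_mut - d.dG_partnerB_mut
    wt = d.dG_complex_wt - d.dG_partnerA_wt - d.dG_partnerB_wt
    return float(mut - wt)


def curate_dataset(records: Sequence[DdgRecord],
                   cfg: Optional[CurationConfig] = None):
    """Apply the three thermostability-dataset curation filters.

    Rejects (i) records without an X-ray structure of resolution ≤
    ``max_resolution`` Å (missing resolution counts as unverifiable and is
    rejected); (ii) *all* records of any mutation whose replicate experimental
    ΔΔG values span more than ``max_ddg_discrepancy`` kcal/mol (max − min);
    (iii) transmembrane-flagged records.  Returns ``(kept, rejected)`` with
    ``rejected`` a list of ``(record, RejectReason)``; kept ∪ rejected = input,
    and the filter is idempotent.
    """
    cfg = cfg or CurationConfig()

    # Discrepancy groups over the full input: whole groups are rejected
    # together, so re-curating the kept set changes nothing.
    spans: dict = {}
    for r in records:
        spans.setdefault(r.mutation_key, []).append(r.ddg_experimental)
    discrepant = {key for key, vals in spans.items()
                  if max(vals) - min(vals) > cfg.max_ddg_discrepancy}

    kept, rejected = [], []
    for r in records:
        if r.method != "xray" or r.resolution is None or r.resolution > cfg.max_resolution:
            rejected.append((r, RejectReason.RESOLUTION))
        elif r.mutation_key in discrepant:
            rejected.append((r, RejectReason.DISCREPANCY))
        elif cfg.exclude_transmembrane and r.is_transmembrane:
            rejected.append((r, RejectReason.TRANSMEMBRANE))
        else:
            kept.append(r)
    return kept, rejected
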