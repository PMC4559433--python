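"""Recognition-specificity evaluation: Boltzmann-weighted predicted PWMs from
scored designed sequences, and the four PWM-comparison metrics (AAD,
Frobenius distance, AUC, rank-top).

The predicted PWM weights each scored sequence by exp(−E/kT) so that
low-energy (favorable) sequences dominate; at kT → 0 the PWM collapses onto
the single best sequence and at kT → ∞ it converges to unweighted
frequencies.  E is the experimentally determined frequency vector and P the
predicted one throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .core import (
    AA_ALPHABET,
    AA_INDEX,
    N_AA,
    UndefinedMetricError,
    ValidationError,
)
from .io_formats import Pwm


@dataclass
class ScoredSequence:
    """One designed sequence (restricted to the designed positions) and its
    energy in score units (lower = better)."""

    sequence: str
    energy: float

    def __post_init__(self):
        if not self.sequence:
            raise ValidationError("empty sequence")
        bad = set(self.sequence.upper()) - set(AA_ALPHABET)
        if bad:
            raise ValidationError(f"invalid residues {sorted(bad)} in {self.sequence!r}")
        if not math.isfinite(self.energy):
            raise ValidationError(f"non-finite energy for {self.sequence!r}")
        self.sequence = self.sequence.upper()


def boltzmann_pwm(seqs: Sequence[ScoredSequence], kT: float = 1.0,
                  positions: Optional[Sequence[str]] = None) -> Pwm:
    """Boltzmann-weighted position weight matrix from scored sequences.

    Each sequence carries weight ∝ exp(−E/kT); the minimum energy is
    subtracted before exponentiation as an overflow guard (which leaves the
    normalized weights unchanged, making the PWM invariant to a common energy
    shift).
    """
    if kT <= 0:
        raise ValidationError(f"kT must be > 0, got {kT}")
    if not seqs:
        raise ValidationError("at least one scored sequence is required")
    length = len(seqs[0].sequence)
    if any(len(s.sequence) != length for s in seqs):
        raise ValidationError("scored sequences must all have equal length")
    energies = np.array([s.energy for s in seqs], float)
    weights = np.exp(-(energies - energies.min()) / kT)
    total = weights.sum()
    matrix = np.zeros((N_AA, length))
    for s, w in zip(seqs, weights):
        for i, aa in enumerate(s.sequence):
            matrix[AA_INDEX[aa], i] += w
    matrix /= total
    if positions is None:
        positions = [str(i + 1) for i in range(length)]
    elif len(positions) != length:
        raise ValidationError("positions must match sequence length")
    return Pwm(list(positions), matrix)


def _as_array(x) -> np.ndarray:
    if isinstance(x, Pwm):
        return x.matrix.ravel()
    return np.asarray(x, float).ravel()


def aad(E, P) -> float:
    """Average absolute deviation (1/N) Σ |E_i − P_i| between an experimental
    and a predicted frequency vector/matrix of the same shape."""
    e, p = _as_array(E), _as_array(P)
    if e.shape != p.shape:
        raise ValidationError(f"shape mismatch: {e.shape} vs {p.shape}")
    return float(np.mean(np.abs(e - p)))


def frobenius_distance(E, P) -> float:
    """Frobenius (Euclidean) distance sqrt(Σ (E_i − P_i)²)."""
    e, p = _as_array(E), _as_array(P)
    if e.shape != p.shape:
        raise ValidationError(f"shape mismatch: {e.shape} vs {p.shape}")
    return float(np.sqrt(((e - p) ** 2).sum()))


def profile_auc(E_col, P_col, positive_threshold: float = 0.1) -> float:
    """Rank-based AUC of the predicted column as a score for recovering the
    experimentally frequent amino acids.

    Amino acids with experimental frequency ≥ ``positive_threshold`` are the
    positive class; the AUC is the probability that a random positive outranks
    a random negative under P, with ties counting 0.5 (Wilcoxon/Mann–Whitney
    form, computed from midranks).  Undefined when the thresholding leaves no
    positives or no negatives.
    """
    e, p = _as_array(E_col), _as_array(P_col)
    if e.shape != p.shape:
        raise ValidationError(f"shape mismatch: {e.shape} vs {p.shape}")
    labels = e >= positive_threshold
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            f"degenerate labels at threshold {positive_threshold} "
            f"({n_pos} positives, {n_neg} negatives)"
        )
    ranks = rankdata(p)  # midranks handle ties
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def rank_top(E_col, P_col) -> int:
    """Competition rank (1 = highest P) of the experimentally most frequent
    amino acid within the predicted column.  Ties in E resolve to the first
    amino acid in alphabet order; ties in P share the best rank."""
    e, p = _as_array(E_col), _as_array(P_col)
    if e.shape != p.shape:
        raise ValidationError(f"shape mismatch: {e.shape} vs {p.shape}")
    target = int(np.argmax(e))
    return 1 + int((p > p[target]).sum())


@dataclass
class PwmComparison:
    """Per-position and macro-averaged PWM comparison metrics."""

    aad_per_position: list
    frobenius_per_position: list
    auc_per_position: list       # None where undefined (degenerate labels)
    rank_top_per_position: list
    aad_mean: float
    frobenius_mean: float
    auc_mean: Optional[float]
    rank_top_mean: float
    aad_flat: float
    frobenius_flat: float


def compare_pwms(E: Pwm, P: Pwm, auc_threshold: float = 0.1) -> PwmComparison:
    """All four specificity metrics between an experimental and predicted PWM,
    computed per designed position and macro-averaged."""
    if E.n_positions != P.n_positions:
        raise ValidationError(
            f"PWMs differ in positions: {E.n_positions} vs {P.n_positions}"
        )
    aads, frobs, aucs, ranks = [], [], [], []
    for i in range(E.n_positions):
        e, p = E.column(i), P.column(i)
        aads.append(aad(e, p))
        frobs.append(frobenius_distance(e, p))
        try:
            aucs.append(profile_auc(e, p, auc_threshold))
        except UndefinedMetricError:
            aucs.append(None)
        ranks.append(rank_top(e, p))
    defined_aucs = [a for a in aucs if a is not None]
    return PwmComparison(
        aad_per_position=aads,
        frobenius_per_position=frobs,
        auc_per_position=aucs,
        rank_top_per_position=ranks,
        aad_mean=float(np.mean(aads)),
        frobenius_mean=float(np.mean(frobs)),
        auc_mean=float(np.mean(defined_aucs)) if defined_aucs else None,
        rank_top_mean=float(np.mean(ranks)),
        aad_flat=aad(E, P),
        frobenius_flat=frobenius_distance(E, P),
    )
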