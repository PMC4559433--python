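"""Shared alphabet constants, error types, and the amino-acid distribution container.

Every profile-level metric in this package operates on normalized frequency
vectors over the 20 standard amino acids in the fixed order
``ACDEFGHIKLMNPQRSTVWY``.  That ordering is part of the on-disk PWM format and
must never change.
"""

from __future__ import annotations

import math

import numpy as np

#: The 20 standard amino acids, fixed ordering used for every vector/matrix.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
N_AA = len(AA_ALPHABET)

#: Characters treated as gaps in alignments ('.' is normalized to '-' on read).
GAP_CHARS = frozenset({"-", "."})
#: Unknown residue; excluded from frequency counts like a gap.
UNKNOWN_CHAR = "X"

_SUM_TOL = 1e-9


class MacrobenchError(Exception):
    """Base class for all package errors."""


class FormatError(MacrobenchError):
    """A file or table does not conform to its expected format."""


class ValidationError(MacrobenchError):
    """An in-memory record or argument violates a domain invariant."""


class EmptyStructureError(FormatError):
    """A coordinate file yielded no usable ATOM records."""


class UndefinedMetricError(MacrobenchError):
    """A metric is mathematically undefined on this input (e.g. zero variance).

    Carries a machine-readable ``reason`` so report assembly can record an
    explicit null-with-reason entry instead of silently dropping the metric.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class AminoAcidDistribution:
    """A normalized frequency vector over the 20 amino acids.

    Parameters
    ----------
    probs : array-like of shape (20,)
        Nonnegative frequencies summing to 1 (within 1e-9).
    is_empty : bool
        Flags a distribution derived from an all-gap alignment column; such
        distributions carry a zero vector and are excluded from averages.
    """

    __slots__ = ("probs", "is_empty")

    def __init__(self, probs, *, is_empty: bool = False):
        p = np.asarray(probs, dtype=float)
        if p.shape != (N_AA,):
            raise ValidationError(
                f"amino-acid distribution must have {N_AA} entries, got shape {p.shape}"
            )
        if is_empty:
            if np.any(p != 0.0):
                raise ValidationError("empty-flagged distribution must be all zeros")
        else:
            if np.any(p < 0) or not np.all(np.isfinite(p)):
                raise ValidationError("distribution entries must be finite and >= 0")
            total = float(p.sum())
            if abs(total - 1.0) > _SUM_TOL:
                raise ValidationError(
                    f"distribution must sum to 1 within {_SUM_TOL}, got {total!r}"
                )
        self.probs = p
        self.is_empty = bool(is_empty)

    @classmethod
    def from_counts(cls, counts) -> "AminoAcidDistribution":
        """Normalize a raw count vector; all-zero counts yield an empty flag."""
        c = np.asarray(counts, dtype=float)
        total = c.sum()
        if total <= 0:
            return cls.empty()
        return cls(c / total)

    @classmethod
    def empty(cls) -> "AminoAcidDistribution":
        return cls(np.zeros(N_AA), is_empty=True)

    @classmethod
    def uniform(cls) -> "AminoAcidDistribution":
        return cls(np.full(N_AA, 1.0 / N_AA))

    @classmethod
    def one_hot(cls, aa: str) -> "AminoAcidDistribution":
        if aa not in AA_INDEX:
            raise ValidationError(f"unknown amino acid {aa!r}")
        p = np.zeros(N_AA)
        p[AA_INDEX[aa]] = 1.0
        return cls(p)

    def __getitem__(self, aa: str) -> float:
        return float(self.probs[AA_INDEX[aa]])

    def __len__(self) -> int:
        return N_AA

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_empty:
            return "AminoAcidDistribution(<empty>)"
        top = AA_ALPHABET[int(np.argmax(self.probs))]
        return f"AminoAcidDistribution(mode={top}, H={self.entropy():.3f} bits)"

    def entropy(self) -> float:
        """Shannon entropy in bits, with 0*log(0) = 0."""
        p = self.probs[self.probs > 0]
        return float(-(p * np.log2(p)).sum()) if p.size else 0.0


def as_prob_vector(d) -> np.ndarray:
    """Coerce a distribution-like object to a plain probability ndarray."""
    if isinstance(d, AminoAcidDistribution):
        return d.probs
    p = np.asarray(d, dtype=float)
    if np.any(p < 0):
        raise ValidationError("probability vector has negative entries")
    total = p.sum()
    if not math.isfinite(total) or total <= 0:
        raise ValidationError("probability vector must have a positive finite sum")
    if abs(total - 1.0) > _SUM_TOL:
        raise ValidationError(f"probability vector must sum to 1, got {total!r}")
    return p
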