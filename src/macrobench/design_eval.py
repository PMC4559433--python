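"""Sequence-level design evaluation: native sequence recovery, sequence
profiles and Jensen–Shannon profile similarity, amino-acid covariation
(MI / MIp / Zpx), high-covariation overlap, residue burial, and composition
breakdowns by polarity.

Covariation model
-----------------
Mutual information between alignment columns i and j is the plug-in estimate

    MI_ij = H_i + H_j − H_ij          (entropies in bits)

computed from the rows that are non-gap at *both* columns (so the three
entropies share one sample space).  The average-product correction removes
background signal from noise and shared ancestry:

    MIp_ij = MI_ij − (MĪ_i · MĪ_j) / MĪ

with MĪ_i the mean MI of column i with all other columns and MĪ the grand
off-diagonal mean.  MIp is then standardized against each column's
off-diagonal mean and standard deviation and the two z-scores multiplied,

    Z_ij = z_i(MIp_ij) · z_j(MIp_ij),      Zpx_ij = sign(Z_ij) · sqrt(|Z_ij|).

Pairs scoring more than two standard deviations above the mean of the
off-diagonal Zpx entries are considered highly covarying; the similarity of
two alignments' covariation structure is the percent of one alignment's
highly-covarying pairs recovered by the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Set, Tuple

import numpy as np

from .core import (
    AA_ALPHABET,
    AA_INDEX,
    AminoAcidDistribution,
    GAP_CHARS,
    N_AA,
    UNKNOWN_CHAR,
    UndefinedMetricError,
    ValidationError,
    as_prob_vector,
)
from .io_formats import Msa, StructureCoords

#: Polarity categories (each string partitions the 20-letter alphabet).
POLARITY_CATEGORIES: Dict[str, str] = {
    "nonpolar": "CGAVLIMFWP",
    "polar": "STYNQ",
    "charged": "HRKDE",
}

_SKIP = GAP_CHARS | {UNKNOWN_CHAR}


# ---------------------------------------------------------------------------
# Recovery, profiles, entropy
# ---------------------------------------------------------------------------

def sequence_recovery(native: str, designed: str,
                      positions: Optional[Iterable[int]] = None) -> float:
    """Percent identity of a designed sequence to the native sequence.

    ``positions`` restricts scoring to a subset of 0-based indices.  A gap or
    unknown residue never counts as a match but still counts as a scored
    position.
    """
    if len(native) != len(designed):
        raise ValidationError(
            f"length mismatch: native {len(native)} vs designed {len(designed)}"
        )
    idx = sorted(positions) if positions is not None else range(len(native))
    idx = list(idx)
    if not idx:
        raise ValidationError("no positions to score")
    if idx and (idx[0] < 0 or idx[-1] >= len(native)):
        raise ValidationError("positions out of range")
    matches = sum(
        1 for i in idx
        if native[i].upper() == designed[i].upper() and native[i].upper() in AA_INDEX
    )
    return 100.0 * matches / len(idx)


def column_distribution(msa: Msa, col: int,
                        gap_policy: str = "exclude") -> AminoAcidDistribution:
    """Amino-acid distribution of one alignment column.

    Default policy excludes gaps and unknowns and renormalizes over the
    observed residues; an all-gap column yields an empty-flagged distribution.
    """
    if gap_policy != "exclude":
        raise ValidationError(f"unknown gap policy {gap_policy!r}")
    counts = np.zeros(N_AA)
    for c in msa.column(col):
        if c in _SKIP:
            continue
        counts[AA_INDEX[c]] += 1
    return AminoAcidDistribution.from_counts(counts)


def shannon_entropy(d) -> float:
    """Shannon entropy of a distribution in bits; in [0, log2 20] for residues."""
    p = as_prob_vector(d) if not isinstance(d, AminoAcidDistribution) else d.probs
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


def _kl_bits(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    return float((p[mask] * np.log2(p[mask] / q[mask])).sum())


def js_divergence(p, q) -> float:
    """Jensen–Shannon divergence (base 2) between two distributions: in [0, 1],
    symmetric, 0 iff p == q, 1 iff the supports are disjoint."""
    p = as_prob_vector(p)
    q = as_prob_vector(q)
    if p.shape != q.shape:
        raise ValidationError("distributions differ in length")
    m = 0.5 * (p + q)
    return 0.5 * _kl_bits(p, m) + 0.5 * _kl_bits(q, m)


def profile_similarity(p, q, background=None) -> float:
    """Similarity of two per-position amino-acid distributions.

    ``½ (1 − D_JS[p‖q]) (1 + D_JS[r‖P₀])`` with r = (p+q)/2 and P₀ the
    background distribution (uniform by default).  The first factor rewards
    agreement between the two profiles; the second rewards their joint
    divergence from background, so an uninformative match scores only 0.5.
    """
    p = as_prob_vector(p)
    q = as_prob_vector(q)
    bg = (AminoAcidDistribution.uniform().probs if background is None
          else as_prob_vector(background))
    if not (p.shape == q.shape == bg.shape):
        raise ValidationError("distributions differ in length")
    r = 0.5 * (p + q)
    return 0.5 * (1.0 - js_divergence(p, q)) * (1.0 + js_divergence(r, bg))


def average_profile_similarity(natural: Msa, designed: Msa, background=None):
    """Mean per-column profile similarity between two alignments of equal length.

    Returns ``(mean, per_column)``; columns that are all-gap in either
    alignment contribute ``None`` and are excluded from the mean.
    """
    if natural.length != designed.length:
        raise ValidationError(
            f"alignment lengths differ: {natural.length} vs {designed.length}"
        )
    per_column = []
    for i in range(natural.length):
        p = column_distribution(natural, i)
        q = column_distribution(designed, i)
        if p.is_empty or q.is_empty:
            per_column.append(None)
        else:
            per_column.append(profile_similarity(p, q, background))
    defined = [v for v in per_column if v is not None]
    if not defined:
        raise UndefinedMetricError("every column is all-gap in one alignment")
    return float(np.mean(defined)), per_column


# ---------------------------------------------------------------------------
# Covariation
# ---------------------------------------------------------------------------

@dataclass
class CovariationMatrices:
    """MI, MIp, and Zpx matrices for one alignment (diagonals set to 0 and
    excluded from all means/SDs)."""

    mi: np.ndarray
    mip: np.ndarray
    zpx: np.ndarray
    column_means: np.ndarray   # MĪ_i
    grand_mean: float          # MĪ


def _encode(msa: Msa) -> np.ndarray:
    """Integer codes: 0..19 residues, -1 gap/unknown; shape (depth, length)."""
    codes = np.full((msa.depth, msa.length), -1, dtype=np.int64)
    for r, seq in enumerate(msa.sequences):
        for c, ch in enumerate(seq):
            if ch in AA_INDEX:
                codes[r, c] = AA_INDEX[ch]
    return codes


def _entropy_from_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def mutual_information(msa: Msa) -> np.ndarray:
    """Pairwise column mutual information in bits (plug-in estimator).

    For each pair only rows that are non-gap at both columns contribute; the
    diagonal is set to 0.  Entries are clipped at 0 against −1e-12 rounding.
    """
    if msa.depth < 2:
        raise ValidationError("mutual information requires alignment depth >= 2")
    codes = _encode(msa)
    L = msa.length
    mi = np.zeros((L, L))
    for i in range(L):
        ci = codes[:, i]
        for j in range(i + 1, L):
            cj = codes[:, j]
            ok = (ci >= 0) & (cj >= 0)
            if not ok.any():
                continue
            joint = np.bincount(ci[ok] * N_AA + cj[ok], minlength=N_AA * N_AA)
            joint = joint.reshape(N_AA, N_AA)
            h_i = _entropy_from_counts(joint.sum(axis=1))
            h_j = _entropy_from_counts(joint.sum(axis=0))
            h_ij = _entropy_from_counts(joint.ravel())
            mi[i, j] = mi[j, i] = max(0.0, h_i + h_j - h_ij)
    return mi


def _offdiag_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


def mip_correction(mi: np.ndarray) -> np.ndarray:
    """Average-product correction: MIp_ij = MI_ij − MĪ_i·MĪ_j / MĪ.

    Column means and the grand mean exclude the diagonal.  When the grand mean
    is 0 (an MI matrix of exact zeros) the correction term vanishes and
    MIp = MI by definition.
    """
    mi = np.asarray(mi, float)
    n = mi.shape[0]
    if mi.shape != (n, n) or n < 3:
        raise ValidationError("MIp needs a square matrix with >= 3 columns")
    if not np.allclose(mi, mi.T, atol=1e-10):
        raise ValidationError("MI matrix must be symmetric")
    off = _offdiag_mask(n)
    col_means = (mi * off).sum(axis=1) / (n - 1)
    grand = mi[off].mean()
    if grand == 0.0:
        mip = mi.copy()
    else:
        mip = mi - np.outer(col_means, col_means) / grand
    np.fill_diagonal(mip, 0.0)
    return mip


def zpx_scores(mip: np.ndarray) -> np.ndarray:
    """Zpx covariation scores from an MIp matrix.

    Each entry is standardized against the off-diagonal mean/SD of its row
    column and of its column column; the two z-scores are multiplied and the
    signed square root taken:

        Z_ij = z_i · z_j,   Zpx_ij = sign(Z_ij)·sqrt(|Z_ij|).

    A column whose off-diagonal MIp values have zero spread has no defined
    z-score; its pairs are returned as NaN with a warning.
    """
    mip = np.asarray(mip, float)
    n = mip.shape[0]
    if mip.shape != (n, n) or n < 3:
        raise ValidationError("Zpx needs a square matrix with >= 3 columns")
    off = _offdiag_mask(n)
    means = np.empty(n)
    sds = np.empty(n)
    for k in range(n):
        vals = mip[k][off[k]]
        means[k] = vals.mean()
        sds[k] = vals.std()  # population SD over the n-1 off-diagonal entries
    degenerate = sds == 0.0
    if degenerate.any():
        warnings.warn(
            f"zero off-diagonal MIp spread for column(s) {np.where(degenerate)[0].tolist()}; "
            "their Zpx entries are undefined (NaN)",
            RuntimeWarning, stacklevel=2,
        )
    sds_safe = np.where(degenerate, np.nan, sds)
    zi = (mip - means[:, None]) / sds_safe[:, None]
    zj = (mip - means[None, :]) / sds_safe[None, :]
    z = zi * zj
    zpx = np.sign(z) * np.sqrt(np.abs(z))
    np.fill_diagonal(zpx, 0.0)
    return zpx


def covariation_matrices(msa: Msa) -> CovariationMatrices:
    """Full covariation pipeline: MI → MIp → Zpx for one alignment."""
    mi = mutual_information(msa)
    n = mi.shape[0]
    off = _offdiag_mask(n)
    col_means = (mi * off).sum(axis=1) / (n - 1)
    grand = float(mi[off].mean())
    mip = mip_correction(mi)
    zpx = zpx_scores(mip)
    return CovariationMatrices(mi=mi, mip=mip, zpx=zpx,
                               column_means=col_means, grand_mean=grand)


def high_covariation_pairs(scores: np.ndarray, z: float = 2.0) -> Set[Tuple[int, int]]:
    """Pairs scoring more than ``z`` standard deviations above the mean.

    Mean and SD are taken over the finite off-diagonal upper-triangle entries;
    the threshold is strict (>).  Zero SD yields an empty set with a warning.
    """
    scores = np.asarray(scores, float)
    n = scores.shape[0]
    if scores.shape != (n, n):
        raise ValidationError("scores must be a square matrix")
    iu, ju = np.triu_indices(n, k=1)
    vals = scores[iu, ju]
    finite = np.isfinite(vals)
    if not finite.any():
        return set()
    mean = vals[finite].mean()
    sd = vals[finite].std()
    # constant inputs can leave an SD of ~1e-17 from rounding; treat as zero
    if sd <= 1e-12 * max(1.0, abs(mean)):
        warnings.warn("zero spread in covariation scores; no pairs selected",
                      RuntimeWarning, stacklevel=2)
        return set()
    threshold = mean + z * sd
    sel = finite & (vals > threshold)
    return {(int(i), int(j)) for i, j in zip(iu[sel], ju[sel])}


def covariation_overlap(natural: np.ndarray, designed: np.ndarray,
                        z: float = 2.0, denominator: str = "natural") -> float:
    """Percent overlap of highly-covarying pairs between two score matrices.

    Default is recovery semantics: 100 · |HC(nat) ∩ HC(des)| / |HC(nat)|.
    ``denominator="jaccard"`` uses the union instead.  Undefined when the
    natural set (or union) is empty.
    """
    natural = np.asarray(natural, float)
    designed = np.asarray(designed, float)
    if natural.shape != designed.shape:
        raise ValidationError(
            f"matrix dimensions differ: {natural.shape} vs {designed.shape}"
        )
    hc_nat = high_covariation_pairs(natural, z)
    hc_des = high_covariation_pairs(designed, z)
    if denominator == "natural":
        denom = len(hc_nat)
    elif denominator == "jaccard":
        denom = len(hc_nat | hc_des)
    else:
        raise ValidationError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise UndefinedMetricError("no highly covarying pairs in the reference set")
    return 100.0 * len(hc_nat & hc_des) / denom


# ---------------------------------------------------------------------------
# Burial and composition
# ---------------------------------------------------------------------------

class Burial:
    BURIED = "buried"
    INTERMEDIATE = "intermediate"
    EXPOSED = "exposed"


@dataclass
class BurialConfig:
    """Neighbor-count burial classification parameters.

    A residue's neighbors are the other residues whose Cβ atom (Cα for
    glycine, or when Cβ is absent) lies within ``radius`` Å of its own.
    Buried: count > ``buried_min_neighbors``; exposed: count ≤
    ``exposed_max_neighbors``; intermediate otherwise.
    """

    neighbor_atom: str = "CB"
    fallback_atom: str = "CA"
    radius: float = 8.0
    buried_min_neighbors: int = 14
    exposed_max_neighbors: int = 8

    def __post_init__(self):
        if self.radius <= 0:
            raise ValidationError("radius must be > 0")
        if self.exposed_max_neighbors >= self.buried_min_neighbors:
            raise ValidationError("exposed_max_neighbors must be < buried_min_neighbors")


def classify_burial(structure: StructureCoords,
                    cfg: Optional[BurialConfig] = None) -> Dict[Tuple[str, str], Tuple[str, int]]:
    """Classify every residue as buried / intermediate / exposed by neighbor count.

    Returns ``{(chain, residue_id): (class, neighbor_count)}``.  Residues
    missing both the neighbor atom and its fallback are skipped with a warning.
    """
    cfg = cfg or BurialConfig()
    points, keys = [], []
    for chain, residue_id, resname in structure.residues():
        atom = structure.get_atom(chain, residue_id, cfg.neighbor_atom)
        if atom is None or resname == "GLY":
            atom = structure.get_atom(chain, residue_id, cfg.fallback_atom) or atom
        if atom is None:
            warnings.warn(
                f"residue {chain}/{residue_id} ({resname}) lacks both "
                f"{cfg.neighbor_atom} and {cfg.fallback_atom}; skipped",
                RuntimeWarning, stacklevel=2,
            )
            continue
        points.append([atom.x, atom.y, atom.z])
        keys.append((chain, residue_id))
    result: Dict[Tuple[str, str], Tuple[str, int]] = {}
    if not points:
        return result
    pts = np.asarray(points)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
    within = d2 <= cfg.radius ** 2
    np.fill_diagonal(within, False)
    for k, key in enumerate(keys):
        count = int(within[k].sum())
        if count > cfg.buried_min_neighbors:
            label = Burial.BURIED
        elif count <= cfg.exposed_max_neighbors:
            label = Burial.EXPOSED
        else:
            label = Burial.INTERMEDIATE
        result[key] = (label, count)
    return result


def residue_frequencies(msa: Msa,
                        positions: Optional[Iterable[int]] = None) -> Dict[str, float]:
    """Percent occurrence of each amino acid at the given positions across all
    sequences (gaps and unknowns excluded)."""
    cols = sorted(positions) if positions is not None else range(msa.length)
    counts = np.zeros(N_AA)
    for c in cols:
        for ch in msa.column(c):
            if ch in AA_INDEX:
                counts[AA_INDEX[ch]] += 1
    total = counts.sum()
    if total == 0:
        raise UndefinedMetricError("no residues at the requested positions")
    return {aa: 100.0 * counts[AA_INDEX[aa]] / total for aa in AA_ALPHABET}


def composition_by_category(msa: Msa,
                            positions: Optional[Iterable[int]] = None,
                            categories: Optional[Mapping[str, str]] = None) -> Dict[str, float]:
    """Percent occurrence per residue category (default: nonpolar / polar /
    charged polarity classes) at the given positions across all sequences.

    ``categories`` must partition the 20-letter alphabet; the returned
    percentages sum to 100.
    """
    categories = dict(categories) if categories is not None else dict(POLARITY_CATEGORIES)
    assigned = "".join(categories.values())
    if sorted(assigned) != sorted(AA_ALPHABET):
        raise ValidationError("categories must partition the 20-letter alphabet")
    per_aa = residue_frequencies(msa, positions)
    return {name: sum(per_aa[aa] for aa in members)
            for name, members in categories.items()}
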