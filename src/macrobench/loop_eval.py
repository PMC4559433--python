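"""Loop-reconstruction benchmark metrics.

A loop model is scored by (1) least-squares superposition of the model onto
the native structure using the backbone atoms of all *non*-loop residues (the
frame), then (2) RMSD over the loop backbone heavy atoms (N, CA, C, O by
default) without further fitting.  Per-case summaries take the RMSD of the
lowest-energy model (or the best of the 5 lowest-energy models) and the
percentage of sub-angstrom models; benchmark-level summaries are medians over
cases.  A crystal-contact filter flags loops with too many residues near
symmetry mates, whose native conformation may be a lattice artifact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .core import ValidationError
from .io_formats import StructureCoords

#: Loop backbone heavy atoms used for RMSD (carbonyl O included; pass
#: ("N", "CA", "C") for the three-atom variant).
BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class LoopCase:
    """One benchmark case: native structure, loop residue list, and an
    ensemble of (model, energy) pairs."""

    case_id: str
    native: StructureCoords
    loop_residues: List[Tuple[str, str]]  # (chain, residue_id) in loop order
    models: List[Tuple[StructureCoords, float]]


@dataclass
class LoopCaseMetrics:
    case_id: str
    rmsd_lowest_energy: float
    rmsd_best_of_5_lowest: Optional[float]  # None when fewer than 5 models
    pct_subangstrom: float
    n_models: int


@dataclass
class BenchmarkMetrics:
    median_rmsd_lowest_energy: float
    median_rmsd_best_of_5: Optional[float]
    median_pct_subangstrom: float
    n_cases: int


@dataclass
class ContactFilterResult:
    passed: bool
    contact_count: int
    contact_residues: List[Tuple[str, str]]


def kabsch_superpose(mobile, reference):
    """Optimal least-squares rigid superposition of ``mobile`` onto
    ``reference`` (paired point sets, shape (N, 3), N ≥ 3).

    Returns ``(rotation, translation, rmsd)`` with a proper rotation
    (det = +1) such that ``R @ x + t`` maps mobile points onto the reference
    frame.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValidationError("point sets must be paired arrays of shape (N, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValidationError("superposition requires at least 3 points")
    mob_center = mobile.mean(axis=0)
    ref_center = reference.mean(axis=0)
    a = mobile - mob_center
    b = reference - ref_center
    if np.linalg.matrix_rank(a, tol=1e-8) < 2 or np.linalg.matrix_rank(b, tol=1e-8) < 2:
        raise ValidationError("degenerate (collinear or coincident) point set")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = ref_center - rotation @ mob_center
    fitted = a @ rotation.T
    rmsd = float(np.sqrt(((fitted - b) ** 2).sum() / n))
    return rotation, translation, rmsd


def _backbone_coords(structure: StructureCoords,
                     residues: Sequence[Tuple[str, str]],
                     atoms: Sequence[str],
                     strict: bool) -> np.ndarray:
    coords = []
    for chain, residue_id in residues:
        for name in atoms:
            atom = structure.get_atom(chain, residue_id, name)
            if atom is None:
                if strict:
                    raise ValidationError(
                        f"missing backbone atom {name} for residue {chain}/{residue_id}"
                    )
                continue
            coords.append([atom.x, atom.y, atom.z])
    return np.asarray(coords)


def loop_rmsd(model: StructureCoords, native: StructureCoords,
              loop: Sequence[Tuple[str, str]],
              backbone_atoms: Sequence[str] = BACKBONE_ATOMS) -> float:
    """Loop backbone heavy-atom RMSD of a model to the native conformation.

    The model is superposed onto the native using the backbone atoms of all
    non-loop residues present in both structures (side chains are excluded:
    repacking near the loop would contaminate the frame); the RMSD is then
    measured over the loop backbone atoms without further fitting.
    """
    loop = [(c, str(r)) for c, r in loop]
    loop_set = set(loop)
    frame_residues = [(c, r) for c, r, _ in native.residues() if (c, r) not in loop_set]
    frame_residues = [(c, r) for c, r in frame_residues
                      if any(model.get_atom(c, r, a) for a in backbone_atoms)]
    if len(frame_residues) < 3:
        raise ValidationError("need at least 3 non-loop residues for the frame superposition")
    # paired frame atoms: only positions present in both structures
    native_frame, model_frame = [], []
    for chain, residue_id in frame_residues:
        for name in backbone_atoms:
            nat = native.get_atom(chain, residue_id, name)
            mod = model.get_atom(chain, residue_id, name)
            if nat is not None and mod is not None:
                native_frame.append([nat.x, nat.y, nat.z])
                model_frame.append([mod.x, mod.y, mod.z])
    native_frame = np.asarray(native_frame)
    model_frame = np.asarray(model_frame)
    rotation, translation, _ = kabsch_superpose(model_frame, native_frame)

    native_loop = _backbone_coords(native, loop, backbone_atoms, strict=True)
    model_loop = _backbone_coords(model, loop, backbone_atoms, strict=True)
    fitted = model_loop @ rotation.T + translation
    return float(np.sqrt(((fitted - native_loop) ** 2).sum() / len(native_loop)))


def case_metrics(case: LoopCase,
                 backbone_atoms: Sequence[str] = BACKBONE_ATOMS,
                 subangstrom_cutoff: float = 1.0) -> LoopCaseMetrics:
    """Per-case summary of a model ensemble.

    ``rmsd_lowest_energy``: RMSD of the single lowest-energy model (energy
    ties broken by model input order).  ``rmsd_best_of_5_lowest``: minimum
    RMSD among the 5 lowest-energy models (None when fewer than 5).
    ``pct_subangstrom``: percent of all models with RMSD strictly below 1 Å.
    """
    if not case.models:
        raise ValidationError(f"case {case.case_id!r} has no models")
    energies = np.array([e for _, e in case.models], float)
    rmsds = np.array([
        loop_rmsd(m, case.native, case.loop_residues, backbone_atoms)
        for m, _ in case.models
    ])
    order = np.argsort(energies, kind="stable")  # ties keep input order
    rmsd_lowest = float(rmsds[order[0]])
    best5 = float(rmsds[order[:5]].min()) if len(order) >= 5 else None
    pct = 100.0 * float((rmsds < subangstrom_cutoff).sum()) / len(rmsds)
    return LoopCaseMetrics(case.case_id, rmsd_lowest, best5, pct, len(rmsds))


def benchmark_metrics(cases: Sequence[LoopCaseMetrics]) -> BenchmarkMetrics:
    """Benchmark-level medians over per-case metrics (even-length median =
    mean of the two central values).  Cases lacking the best-of-5 metric are
    excluded from that median only."""
    if not cases:
        raise ValidationError("no cases")
    best5 = [c.rmsd_best_of_5_lowest for c in cases if c.rmsd_best_of_5_lowest is not None]
    return BenchmarkMetrics(
        median_rmsd_lowest_energy=float(np.median([c.rmsd_lowest_energy for c in cases])),
        median_rmsd_best_of_5=float(np.median(best5)) if best5 else None,
        median_pct_subangstrom=float(np.median([c.pct_subangstrom for c in cases])),
        n_cases=len(cases),
    )


def _heavy_atoms(structure: StructureCoords):
    # Hydrogens start with H (or digit-H in some naming schemes); everything
    # else in an ATOM record is a heavy atom.
    return [a for a in structure.atoms
            if not a.atom_name.lstrip("0123456789").startswith("H")]


def crystal_contact_filter(loop: Sequence[Tuple[str, str]],
                           native: StructureCoords,
                           symmetry_mates: Optional[StructureCoords],
                           cutoff: float = 6.0,
                           max_contact_residues: int = 5) -> ContactFilterResult:
    """Curation rule for long-loop cases: a loop residue is a crystal contact
    when ANY of its heavy atoms lies within ``cutoff`` Å (inclusive) of ANY
    symmetry-mate heavy atom; the case passes when at most
    ``max_contact_residues`` loop residues are contacts.
    """
    loop = [(c, str(r)) for c, r in loop]
    if symmetry_mates is None or len(symmetry_mates) == 0:
        warnings.warn("no symmetry-mate atoms supplied; contact filter passes trivially",
                      RuntimeWarning, stacklevel=2)
        return ContactFilterResult(True, 0, [])
    mate_atoms = _heavy_atoms(symmetry_mates)
    if not mate_atoms:
        warnings.warn("symmetry mates contain no heavy atoms; contact filter passes trivially",
                      RuntimeWarning, stacklevel=2)
        return ContactFilterResult(True, 0, [])
    tree = cKDTree(np.array([[a.x, a.y, a.z] for a in mate_atoms]))
    contacts = []
    for chain, residue_id in loop:
        atoms = [a for a in native.residue_atoms(chain, residue_id)
                 if not a.atom_name.lstrip("0123456789").startswith("H")]
        if not atoms:
            raise ValidationError(f"loop residue {chain}/{residue_id} not found in native")
        dists, _ = tree.query(np.array([[a.x, a.y, a.z] for a in atoms]))
        if float(np.min(dists)) <= cutoff:
            contacts.append((chain, residue_id))
    return ContactFilterResult(len(contacts) <= max_contact_residues,
                               len(contacts), contacts)
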