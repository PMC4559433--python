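"""Seeded generators producing benchmark inputs with known ground truth.

Every generator takes an explicit integer seed and draws from its own
``numpy.random.Generator`` — never from process-global state — so the same
seed always yields bit-identical output.  Noise models are Gaussian
throughout, chosen for their closed-form expectations: each generator's
ground truth is recoverable by the corresponding metric module, which is what
the parameter-recovery test suite checks.
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import AA_ALPHABET, N_AA, ValidationError
from .io_formats import Atom, DdgRecord, Msa, Pwm, StructureCoords
from .loop_eval import LoopCase
from .specificity_eval import ScoredSequence

_EXP_MEAN = 1.0   # kcal/mol, mean of simulated experimental ΔΔG
_EXP_SD = 2.0     # kcal/mol, spread of simulated experimental ΔΔG


def noise_sd_for_correlation(target_correlation: float,
                             exp_sd: float = _EXP_SD) -> float:
    """Additive-noise SD giving the requested population correlation between
    x and x + noise: corr = sd_x / sqrt(sd_x² + sd_noise²)."""
    r = abs(target_correlation)
    if not 0 < r <= 1:
        raise ValidationError("correlation must satisfy 0 < |r| <= 1 for the additive model")
    if r == 1:
        return 0.0
    return exp_sd * math.sqrt(1.0 / r**2 - 1.0)


def expected_mae(target_correlation: float, exp_sd: float = _EXP_SD) -> float:
    """Closed-form expected MAE between experimental and predicted values
    under the additive Gaussian noise model of :func:`simulate_ddg_dataset`.

    For 0 < |r| < 1 the prediction is x + N(0, σ²) so MAE = σ·sqrt(2/π); for
    r = ±1 it is 0; for r = 0 the prediction is an independent N(mean, sd²)
    draw, giving MAE = sd·sqrt(2)·sqrt(2/π).
    """
    r = target_correlation
    if abs(r) == 1:
        return 0.0
    if r == 0:
        return exp_sd * math.sqrt(2.0) * math.sqrt(2.0 / math.pi)
    return noise_sd_for_correlation(r, exp_sd) * math.sqrt(2.0 / math.pi)


def simulate_ddg_dataset(n: int, target_correlation: float, seed: int,
                         exp_mean: float = _EXP_MEAN, exp_sd: float = _EXP_SD,
                         plant_violations: bool = False) -> List[DdgRecord]:
    """Simulate a ΔΔG benchmark dataset with a controlled exp/pred correlation.

    Experimental values are N(``exp_mean``, ``exp_sd``²) kcal/mol; predictions
    are the experimental value plus Gaussian noise calibrated so the
    *population* correlation equals ``target_correlation`` (negative targets
    negate the prediction; target 0 draws an independent prediction).

    With ``plant_violations`` the last four records carry one curation
    violation each: one non-X-ray/poor-resolution record, one transmembrane
    record, and one replicate pair whose experimental ΔΔG values differ by
    4 kcal/mol (requires n ≥ 8 so a majority of records stay clean).
    """
    if n < 2:
        raise ValidationError("n must be >= 2")
    if abs(target_correlation) > 1:
        raise ValidationError("|target_correlation| must be <= 1")
    if plant_violations and n < 8:
        raise ValidationError("plant_violations requires n >= 8")
    rng = np.random.default_rng(seed)
    exp = rng.normal(exp_mean, exp_sd, size=n)
    r = target_correlation
    if r == 0:
        pred = rng.normal(exp_mean, exp_sd, size=n)
    else:
        noise_sd = noise_sd_for_correlation(r, exp_sd)
        pred = exp + rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else exp.copy()
        if r < 0:
            pred = 2 * exp_mean - pred  # reflect: flips the correlation sign
    aas = list(AA_ALPHABET)
    records = []
    for k in range(n):
        wt = aas[k % N_AA]
        mut = aas[(k + 7) % N_AA]  # 7 and 20 coprime: mut != wt always
        records.append(DdgRecord(
            record_id=f"SIM{k:05d}",
            pdb_id="1XYZ",
            chain="A",
            residue_id=str(k + 1),
            wildtype_aa=wt,
            mutant_aa=mut,
            ddg_experimental=float(exp[k]),
            ddg_predicted=float(pred[k]),
            resolution=float(rng.uniform(1.0, 2.4)),
            method="xray",
        ))
    if plant_violations:
        records[-4].resolution = 3.0                       # filter (i)
        records[-3].is_transmembrane = True                # filter (iii)
        # filter (ii): make the last two records replicates of one mutation
        # with experimental values 4 kcal/mol apart
        pair_key = records[-2]
        records[-1] = DdgRecord(
            record_id=records[-1].record_id,
            pdb_id=pair_key.pdb_id, chain=pair_key.chain,
            residue_id=pair_key.residue_id,
            wildtype_aa=pair_key.wildtype_aa, mutant_aa=pair_key.mutant_aa,
            ddg_experimental=pair_key.ddg_experimental + 4.0,
            ddg_predicted=records[-1].ddg_predicted,
            resolution=records[-1].resolution, method="xray",
        )
    return records


def simulate_msa(n_seqs: int, length: int,
                 planted_pairs: Sequence[Tuple[int, int]] = (),
                 coupling_strength: float = 0.0,
                 seed: int = 0,
                 background: Optional[np.ndarray] = None) -> Msa:
    """Simulate an alignment with planted covarying column pairs.

    Background columns are i.i.d. draws from ``background`` (uniform over the
    20 amino acids by default).  For each planted pair (i, j), column i is a
    background draw and column j copies it with probability
    ``coupling_strength`` (identical-symbol coupling), otherwise redraws
    independently — so at coupling 1 the pair's mutual information equals the
    column entropy exactly, and at coupling 0 the pair is indistinguishable
    from background.
    """
    if n_seqs < 1 or length < 1:
        raise ValidationError("n_seqs and length must be >= 1")
    if not 0 <= coupling_strength <= 1:
        raise ValidationError("coupling_strength must be in [0, 1]")
    used: set = set()
    for i, j in planted_pairs:
        if i == j or not (0 <= i < length and 0 <= j < length):
            raise ValidationError(f"invalid planted pair ({i}, {j})")
        if i in used or j in used:
            raise ValidationError("planted pairs must be disjoint")
        used.update((i, j))
    rng = np.random.default_rng(seed)
    p = (np.full(N_AA, 1.0 / N_AA) if background is None
         else np.asarray(background, float) / np.sum(background))
    codes = rng.choice(N_AA, size=(n_seqs, length), p=p)
    for i, j in planted_pairs:
        coupled = rng.random(n_seqs) < coupling_strength
        codes[coupled, j] = codes[coupled, i]
    sequences = ["".join(AA_ALPHABET[c] for c in row) for row in codes]
    return Msa([f"seq{k}" for k in range(n_seqs)], sequences)


def simulate_scored_sequences(pwm_truth: Pwm, n: int, kT: float = 1.0,
                              seed: int = 0) -> List[ScoredSequence]:
    """Simulate scored designed sequences whose Boltzmann-weighted PWM
    recovers ``pwm_truth`` in expectation at the same kT.

    Sequences are sampled uniformly over the alphabet at every position and
    assigned energy E = −kT · Σ_i log p_truth(s_i).  The Boltzmann weight
    exp(−E/kT) then equals Π p_truth(s_i), and the importance identity
    E_uniform[w · 1(s_i = a)] ∝ p_truth(a) makes the weighted column
    frequencies an unbiased estimate of the truth.  The truth must be
    strictly positive (a zero-probability symbol would need infinite energy).
    """
    if kT <= 0:
        raise ValidationError("kT must be > 0")
    if n < 1:
        raise ValidationError("n must be >= 1")
    matrix = pwm_truth.matrix
    if np.any(matrix <= 0):
        raise ValidationError(
            "pwm_truth must be strictly positive (zero-probability symbol requested)"
        )
    rng = np.random.default_rng(seed)
    length = pwm_truth.n_positions
    codes = rng.integers(0, N_AA, size=(n, length))
    log_p = np.log(matrix)
    out = []
    for row in codes:
        energy = -kT * float(log_p[row, np.arange(length)].sum())
        out.append(ScoredSequence("".join(AA_ALPHABET[c] for c in row), energy))
    return out


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

def simulate_structure(n_residues: int, packing: str = "cluster",
                       seed: int = 0, spacing: float = 10.0,
                       cluster_radius: float = 3.0) -> StructureCoords:
    """Pseudo-atom scaffold with analytically known pairwise distances.

    ``line`` places residues ``spacing`` Å apart along x (no neighbors at the
    8 Å burial radius when spacing > 8); ``cluster`` scatters residues inside
    a ball of radius ``cluster_radius`` Å (every residue neighbors every other
    when 2·cluster_radius < 8).  Each residue gets a CB pseudo-atom and a CA
    0.5 Å away.
    """
    if n_residues < 1:
        raise ValidationError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)
    if packing == "line":
        centers = np.zeros((n_residues, 3))
        centers[:, 0] = np.arange(n_residues) * spacing
    elif packing == "cluster":
        # uniform in a ball: scale gaussian directions by radius * u^(1/3)
        directions = rng.normal(size=(n_residues, 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        radii = cluster_radius * rng.random(n_residues) ** (1 / 3)
        centers = directions * radii[:, None]
    else:
        raise ValidationError(f"unknown packing {packing!r}")
    atoms = []
    for k, (x, y, z) in enumerate(centers):
        rid = str(k + 1)
        atoms.append(Atom("A", rid, "ALA", "CA", float(x) + 0.5, float(y), float(z)))
        atoms.append(Atom("A", rid, "ALA", "CB", float(x), float(y), float(z)))
    return StructureCoords(atoms)


def simulate_backbone_structure(n_residues: int, seed: int = 0,
                                chain: str = "A") -> StructureCoords:
    """A synthetic single-chain backbone (N, CA, C, O per residue) laid out as
    a gently perturbed extended chain with ~3.8 Å CA spacing.

    Not physically realistic geometry — a labeled coordinate scaffold for
    superposition/RMSD testing with every backbone atom present.
    """
    if n_residues < 1:
        raise ValidationError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)
    atoms = []
    for k in range(n_residues):
        ca = np.array([3.8 * k, 2.0 * math.sin(0.6 * k), 2.0 * math.cos(0.6 * k)])
        ca = ca + rng.normal(0.0, 0.05, size=3)
        rid = str(k + 1)
        offsets = {"N": np.array([-1.2, 0.6, 0.0]),
                   "CA": np.zeros(3),
                   "C": np.array([1.2, 0.5, 0.3]),
                   "O": np.array([1.4, 1.6, 0.5])}
        for name, off in offsets.items():
            x, y, z = ca + off
            atoms.append(Atom(chain, rid, "ALA", name, float(x), float(y), float(z)))
    return StructureCoords(atoms)


def simulate_loop_ensemble(native: StructureCoords,
                           loop: Sequence[Tuple[str, str]],
                           n_models: int,
                           perturbation_scale: float,
                           energy_rmsd_correlation: float = 1.0,
                           seed: int = 0,
                           case_id: str = "sim_loop") -> Tuple[LoopCase, np.ndarray]:
    """Simulate a loop-model ensemble around a native structure.

    Each model copies the native and displaces every loop atom by an i.i.d.
    Gaussian offset of per-coordinate SD ``perturbation_scale`` Å (frame atoms
    untouched, so the superposition is the identity and the true loop RMSD is
    the root-mean-square displacement, recorded as ground truth).
    Pseudo-energies correlate with the true RMSD at the stated level
    (correlation 1 makes energy a monotone function of RMSD).

    Returns ``(case, true_rmsds)``.
    """
    if perturbation_scale < 0:
        raise ValidationError("perturbation_scale must be >= 0")
    if not -1 <= energy_rmsd_correlation <= 1:
        raise ValidationError("|energy_rmsd_correlation| must be <= 1")
    loop = [(c, str(r)) for c, r in loop]
    native_keys = {(c, r) for c, r, _ in native.residues()}
    missing = [lr for lr in loop if lr not in native_keys]
    if missing:
        raise ValidationError(f"loop residues not in native structure: {missing}")
    loop_set = set(loop)
    rng = np.random.default_rng(seed)
    models = []
    true_rmsds = np.empty(n_models)
    for m in range(n_models):
        new_atoms = []
        sq_sum, n_loop_atoms = 0.0, 0
        for a in native.atoms:
            if (a.chain, a.residue_id) in loop_set:
                d = rng.normal(0.0, perturbation_scale, size=3) if perturbation_scale > 0 else np.zeros(3)
                sq_sum += float(d @ d)
                n_loop_atoms += 1
                new_atoms.append(a._replace(x=a.x + d[0], y=a.y + d[1], z=a.z + d[2]))
            else:
                new_atoms.append(a)
        true_rmsds[m] = math.sqrt(sq_sum / n_loop_atoms) if n_loop_atoms else 0.0
        models.append(StructureCoords(new_atoms))
    rho = energy_rmsd_correlation
    sd = true_rmsds.std()
    z = (true_rmsds - true_rmsds.mean()) / sd if sd > 0 else np.zeros(n_models)
    noise = rng.normal(size=n_models)
    energies = rho * z + math.sqrt(max(0.0, 1 - rho**2)) * noise
    case = LoopCase(case_id, native, list(loop),
                    [(m, float(e)) for m, e in zip(models, energies)])
    return case, true_rmsds
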