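"""Readers and writers for every external representation the toolkit touches.

Formats supported: the standardized ΔΔG record schema (CSV/JSON), FASTA
multiple sequence alignments, PDB coordinates (ATOM records), PWM tables
(CSV, rows = amino acids in the fixed ``ACDEFGHIKLMNPQRSTVWY`` order,
columns = positions), score tables (``case_id, variant, score``), and JSON/CSV
metric reports.

Residue identifiers use *author* numbering taken verbatim from the PDB file
(string with optional insertion code) and are never renumbered: the benchmark
datasets cross-reference author numbering.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser

from .core import (
    AA_ALPHABET,
    EmptyStructureError,
    FormatError,
    GAP_CHARS,
    N_AA,
    UNKNOWN_CHAR,
    ValidationError,
)

_DDG_REQUIRED = (
    "record_id",
    "pdb_id",
    "chain",
    "residue_id",
    "wildtype_aa",
    "mutant_aa",
    "ddg_experimental",
)
_DDG_OPTIONAL = (
    "ddg_predicted",
    "resolution",
    "method",
    "is_transmembrane",
    "references",
)
_METHODS = ("xray", "nmr", "other")


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass
class DdgRecord:
    """One point mutation with experimental (and optionally predicted) ΔΔG.

    ``ddg_experimental`` is in kcal/mol; ``ddg_predicted`` is in the scoring
    method's own units.  Positive ΔΔG = destabilizing.
    """

    record_id: str
    pdb_id: str
    chain: str
    residue_id: str
    wildtype_aa: str
    mutant_aa: str
    ddg_experimental: float
    ddg_predicted: Optional[float] = None
    resolution: Optional[float] = None
    method: str = "xray"
    is_transmembrane: bool = False
    references: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.wildtype_aa not in AA_ALPHABET:
            raise ValidationError(
                f"{self.record_id}: wildtype_aa {self.wildtype_aa!r} not a standard amino acid"
            )
        if self.mutant_aa not in AA_ALPHABET:
            raise ValidationError(
                f"{self.record_id}: mutant_aa {self.mutant_aa!r} not a standard amino acid"
            )
        if self.wildtype_aa == self.mutant_aa:
            raise ValidationError(
                f"{self.record_id}: wildtype and mutant amino acid are identical "
                f"({self.wildtype_aa})"
            )
        if not math.isfinite(self.ddg_experimental):
            raise ValidationError(f"{self.record_id}: ddg_experimental is not finite")
        if self.method not in _METHODS:
            raise ValidationError(
                f"{self.record_id}: method must be one of {_METHODS}, got {self.method!r}"
            )

    @property
    def mutation_key(self) -> tuple:
        """Identity of the mutation, used to group replicate measurements."""
        return (self.pdb_id, self.chain, self.residue_id,
                self.wildtype_aa, self.mutant_aa)


@dataclass
class ScoredModelSet:
    """Per-case score lists for an ensemble of wild-type and mutant models.

    Lower score = more favorable.
    """

    case_id: str
    wildtype_scores: list
    mutant_scores: list


@dataclass
class BindingDecomposition:
    """The six folding free-energy terms of the alanine-scanning equation."""

    case_id: str
    dG_complex_mut: float
    dG_partnerA_mut: float
    dG_partnerB_mut: float
    dG_complex_wt: float
    dG_partnerA_wt: float
    dG_partnerB_wt: float

    def __post_init__(self):
        for name in ("dG_complex_mut", "dG_partnerA_mut", "dG_partnerB_mut",
                     "dG_complex_wt", "dG_partnerA_wt", "dG_partnerB_wt"):
            v = getattr(self, name)
            if v is None or not math.isfinite(float(v)):
                raise ValidationError(f"{self.case_id}: term {name} missing or non-finite")


class Msa:
    """An aligned set of sequences over {20 amino acids, '-', 'X'}."""

    def __init__(self, ids: Sequence[str], sequences: Sequence[str]):
        if len(ids) != len(sequences):
            raise ValidationError("ids and sequences differ in length")
        if len(sequences) < 1:
            raise ValidationError("alignment must contain at least one sequence")
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            bad = [i for i, s in zip(ids, sequences)
                   if len(s) != len(sequences[0])]
            raise FormatError(
                f"ragged alignment: sequences {bad} differ in length from {ids[0]!r}"
            )
        self.ids = list(ids)
        self.sequences = [s.upper().replace(".", "-") for s in sequences]
        allowed = set(AA_ALPHABET) | GAP_CHARS | {UNKNOWN_CHAR}
        for sid, s in zip(self.ids, self.sequences):
            bad_chars = set(s) - allowed
            if bad_chars:
                raise FormatError(f"sequence {sid!r} has invalid characters {sorted(bad_chars)}")

    @property
    def depth(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def column(self, i: int) -> str:
        """The i-th alignment column (0-based) as a string of length ``depth``."""
        if not 0 <= i < self.length:
            raise IndexError(f"column {i} out of range for alignment of length {self.length}")
        return "".join(s[i] for s in self.sequences)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Msa(depth={self.depth}, length={self.length})"


class Atom(NamedTuple):
    chain: str
    residue_id: str  # author number + optional insertion code, e.g. "153" or "100A"
    residue_name: str
    atom_name: str
    x: float
    y: float
    z: float

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


class StructureCoords:
    """Labeled atomic coordinates keyed by (chain, residue_id, atom_name)."""

    def __init__(self, atoms: Iterable[Atom]):
        self.atoms = list(atoms)
        self._index = {}
        for a in self.atoms:
            key = (a.chain, a.residue_id, a.atom_name)
            if key in self._index:
                raise ValidationError(f"duplicate atom key {key}")
            if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                raise ValidationError(f"non-finite coordinates for atom {key}")
            self._index[key] = a

    def __len__(self) -> int:
        return len(self.atoms)

    def get_atom(self, chain: str, residue_id: str, atom_name: str) -> Optional[Atom]:
        return self._index.get((chain, residue_id, atom_name))

    def residues(self) -> list:
        """Unique (chain, residue_id, residue_name) triples in file order."""
        seen, out = set(), []
        for a in self.atoms:
            key = (a.chain, a.residue_id)
            if key not in seen:
                seen.add(key)
                out.append((a.chain, a.residue_id, a.residue_name))
        return out

    def residue_atoms(self, chain: str, residue_id: str) -> list:
        return [a for a in self.atoms if a.chain == chain and a.residue_id == residue_id]

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureCoords":
        """A copy with ``x' = R x + t`` applied to every atom."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        new = []
        for a in self.atoms:
            x, y, z = R @ np.array([a.x, a.y, a.z]) + t
            new.append(a._replace(x=float(x), y=float(y), z=float(z)))
        return StructureCoords(new)


@dataclass
class Pwm:
    """A position weight matrix: per-position amino-acid frequency columns.

    ``matrix`` has shape (20, n_positions) with rows in the fixed amino-acid
    order; every column sums to 1.
    """

    positions: list
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (N_AA, len(self.positions)):
            raise ValidationError(
                f"PWM matrix shape {self.matrix.shape} does not match "
                f"(20, {len(self.positions)})"
            )
        if np.any(self.matrix < -1e-12):
            raise ValidationError("PWM entries must be >= 0")
        sums = self.matrix.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValidationError("every PWM column must sum to 1 within 1e-9")

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def column(self, i: int) -> np.ndarray:
        return self.matrix[:, i]


@dataclass
class MetricReport:
    """A keyed collection of metric values plus provenance, serializable to JSON/CSV.

    Every metric maps to ``{value, units, n, notes}``.  An undefined metric is
    recorded with ``value=None`` and the reason in ``notes`` rather than being
    omitted: benchmark tables need visible gaps.
    """

    benchmark: str
    metrics: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def add(self, name: str, value, units: str = "", n: Optional[int] = None,
            notes: str = ""):
        if value is not None:
            value = float(value)
            if not math.isfinite(value):
                raise ValidationError(f"metric {name!r} has non-finite value {value}")
        self.metrics[name] = {"value": value, "units": units, "n": n, "notes": notes}

    def add_undefined(self, name: str, reason: str, units: str = "",
                      n: Optional[int] = None):
        self.metrics[name] = {"value": None, "units": units, "n": n,
                              "notes": f"undefined: {reason}"}


# ---------------------------------------------------------------------------
# ΔΔG dataset I/O
# ---------------------------------------------------------------------------

def _parse_float(value, field_name, record_id):
    if value is None or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise FormatError(
            f"record {record_id!r}: cannot parse {field_name} value {value!r}"
        ) from None


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("true", "1", "yes")


def _record_from_mapping(row: dict) -> DdgRecord:
    rid = str(row.get("record_id", "<missing id>"))
    ddg = _parse_float(row.get("ddg_experimental"), "ddg_experimental", rid)
    if ddg is None:
        raise FormatError(f"record {rid!r}: ddg_experimental is missing")
    refs = row.get("references") or []
    if isinstance(refs, str):
        refs = [r for r in refs.split(";") if r]
    extra = {k: v for k, v in row.items()
             if k not in _DDG_REQUIRED and k not in _DDG_OPTIONAL}
    return DdgRecord(
        record_id=rid,
        pdb_id=str(row["pdb_id"]),
        chain=str(row["chain"]),
        residue_id=str(row["residue_id"]),
        wildtype_aa=str(row["wildtype_aa"]).upper(),
        mutant_aa=str(row["mutant_aa"]).upper(),
        ddg_experimental=ddg,
        ddg_predicted=_parse_float(row.get("ddg_predicted"), "ddg_predicted", rid),
        resolution=_parse_float(row.get("resolution"), "resolution", rid),
        method=str(row.get("method") or "xray"),
        is_transmembrane=_parse_bool(row.get("is_transmembrane", False)),
        references=list(refs),
        extra=extra,
    )


def read_ddg_dataset(path, format: Optional[str] = None) -> list:
    """Read a ΔΔG benchmark dataset from CSV or JSON into ``DdgRecord`` objects.

    ``format`` defaults to the file extension.  Unknown optional columns are
    preserved in each record's ``extra`` bag.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            missing = [c for c in _DDG_REQUIRED if c not in header]
            if missing:
                raise FormatError(f"missing required column(s): {', '.join(missing)}")
            rows = list(reader)
    elif fmt == "json":
        with open(path, encoding="utf-8") as fh:
            rows = json.load(fh)
        if not isinstance(rows, list):
            raise FormatError("JSON ΔΔG dataset must be a list of objects")
        for row in rows:
            missing = [c for c in _DDG_REQUIRED if c not in row]
            if missing:
                raise FormatError(
                    f"record {row.get('record_id', '?')!r} missing required "
                    f"field(s): {', '.join(missing)}"
                )
    else:
        raise FormatError(f"unknown ΔΔG dataset format {fmt!r}")
    return [_record_from_mapping(row) for row in rows]


def _record_to_mapping(r: DdgRecord) -> dict:
    d = {
        "record_id": r.record_id,
        "pdb_id": r.pdb_id,
        "chain": r.chain,
        "residue_id": r.residue_id,
        "wildtype_aa": r.wildtype_aa,
        "mutant_aa": r.mutant_aa,
        "ddg_experimental": r.ddg_experimental,
        "ddg_predicted": r.ddg_predicted,
        "resolution": r.resolution,
        "method": r.method,
        "is_transmembrane": r.is_transmembrane,
        "references": list(r.references),
    }
    d.update(r.extra)
    return d


def write_ddg_dataset(records: Sequence[DdgRecord], path,
                      format: Optional[str] = None) -> None:
    """Write ``DdgRecord`` objects to CSV or JSON (round-trip safe)."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    rows = [_record_to_mapping(r) for r in records]
    if fmt == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(rows, fh, indent=1)
    elif fmt == "csv":
        fields = list(_DDG_REQUIRED) + list(_DDG_OPTIONAL)
        extra_fields = sorted({k for row in rows for k in row} - set(fields))
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields + extra_fields)
            writer.writeheader()
            for row in rows:
                row = dict(row)
                row["references"] = ";".join(row["references"])
                writer.writerow({k: ("" if row.get(k) is None else row.get(k))
                                 for k in fields + extra_fields})
    else:
        raise FormatError(f"unknown ΔΔG dataset format {fmt!r}")


# ---------------------------------------------------------------------------
# Score tables / binding decompositions
# ---------------------------------------------------------------------------

def read_score_table(path) -> list:
    """Read a ``case_id, variant, score`` CSV into ``ScoredModelSet`` objects.

    ``variant`` is ``wt`` or ``mut``; each case yields one set, in first-seen
    order, with scores in file order.
    """
    cases: dict = {}
    order = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for col in ("case_id", "variant", "score"):
            if col not in (reader.fieldnames or []):
                raise FormatError(f"missing required column(s): {col}")
        for row in reader:
            cid = row["case_id"]
            variant = row["variant"].strip().lower()
            if variant not in ("wt", "mut"):
                raise FormatError(f"case {cid!r}: variant must be 'wt' or 'mut', "
                                  f"got {row['variant']!r}")
            if cid not in cases:
                cases[cid] = {"wt": [], "mut": []}
                order.append(cid)
            cases[cid][variant].append(float(row["score"]))
    return [ScoredModelSet(cid, cases[cid]["wt"], cases[cid]["mut"]) for cid in order]


_DECOMP_COLS = ("dG_complex_mut", "dG_partnerA_mut", "dG_partnerB_mut",
                "dG_complex_wt", "dG_partnerA_wt", "dG_partnerB_wt")


def read_binding_decompositions(path, format: Optional[str] = None) -> list:
    """Read six-term binding energy decompositions from CSV or JSON."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            missing = [c for c in ("case_id",) + _DECOMP_COLS
                       if c not in (reader.fieldnames or [])]
            if missing:
                raise FormatError(f"missing required column(s): {', '.join(missing)}")
            rows = list(reader)
    elif fmt == "json":
        with open(path, encoding="utf-8") as fh:
            rows = json.load(fh)
    else:
        raise FormatError(f"unknown decomposition format {fmt!r}")
    return [BindingDecomposition(
        case_id=str(row["case_id"]),
        **{c: float(row[c]) for c in _DECOMP_COLS}) for row in rows]


# ---------------------------------------------------------------------------
# FASTA alignments
# ---------------------------------------------------------------------------

def read_fasta_msa(path) -> Msa:
    """Read a FASTA alignment; sequences are upper-cased, '.' becomes '-'."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return Msa([r.id for r in records], [str(r.seq) for r in records])


def write_fasta_msa(msa: Msa, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, seq in zip(msa.ids, msa.sequences):
            fh.write(f">{sid}\n{seq}\n")


# ---------------------------------------------------------------------------
# PDB coordinates
# ---------------------------------------------------------------------------

def read_pdb_coords(path, model_index: int = 1) -> StructureCoords:
    """Read ATOM coordinates from a PDB file.

    Only standard-residue ATOM records are retained (HETATM dropped).  For
    alternate locations, altloc ' ' or 'A' is kept and all others dropped,
    yielding a deterministic single-conformer structure.  ``model_index`` is
    1-based over MODEL blocks.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    models = list(structure)
    if not models:
        raise EmptyStructureError(f"no coordinate models in {path}")
    if not 1 <= model_index <= len(models):
        raise FormatError(
            f"model_index {model_index} out of range (file has {len(models)} model(s))"
        )
    model = models[model_index - 1]
    atoms = []
    for chain in model:
        for residue in chain:
            hetflag, resseq, icode = residue.id
            if hetflag != " ":
                continue  # HETATM / water
            residue_id = f"{resseq}{icode}".strip()
            for atom in residue.get_unpacked_list():
                if atom.get_altloc() not in (" ", "A"):
                    continue
                x, y, z = atom.coord
                atoms.append(Atom(chain.id, residue_id, residue.get_resname().strip(),
                                  atom.get_name(), float(x), float(y), float(z)))
    if not atoms:
        raise EmptyStructureError(f"no ATOM records retained from {path}")
    return StructureCoords(atoms)


# ---------------------------------------------------------------------------
# PWM CSV
# ---------------------------------------------------------------------------

def read_pwm_csv(path) -> Pwm:
    """Read a PWM table: first column 'aa' (rows in ACDEFGHIKLMNPQRSTVWY order),
    remaining columns one per position."""
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows or rows[0][0] != "aa":
        raise FormatError("PWM CSV must start with header column 'aa'")
    positions = rows[0][1:]
    if len(rows) != N_AA + 1:
        raise FormatError(f"PWM CSV must have exactly {N_AA} amino-acid rows")
    matrix = np.zeros((N_AA, len(positions)))
    for i, row in enumerate(rows[1:]):
        if row[0] != AA_ALPHABET[i]:
            raise FormatError(
                f"PWM rows must be in fixed order {AA_ALPHABET}; row {i + 1} is {row[0]!r}"
            )
        matrix[i] = [float(v) for v in row[1:]]
    return Pwm(positions, matrix)


def write_pwm_csv(pwm: Pwm, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["aa"] + [str(p) for p in pwm.positions])
        for i, aa in enumerate(AA_ALPHABET):
            writer.writerow([aa] + [repr(float(v)) for v in pwm.matrix[i]])


# ---------------------------------------------------------------------------
# Metric reports
# ---------------------------------------------------------------------------

def _sig6(x):
    """Round a float to 6 significant digits for stable serialization."""
    if x is None or x == 0:
        return x
    return float(f"{x:.6g}")


def write_report(report: MetricReport, path, format: str = "json") -> None:
    """Serialize a MetricReport with stable key ordering and 6-significant-digit
    floats.  The write is atomic (temp file + rename)."""
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    if format == "json":
        payload = {
            "benchmark": report.benchmark,
            "metrics": {
                name: {"value": _sig6(m["value"]), "units": m["units"],
                       "n": m["n"], "notes": m["notes"]}
                for name, m in sorted(report.metrics.items())
            },
            "provenance": {k: report.provenance[k] for k in sorted(report.provenance)},
        }
        with open(tmp, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif format == "csv":
        with open(tmp, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["benchmark", "metric", "value", "units", "n", "notes"])
            for name in sorted(report.metrics):
                m = report.metrics[name]
                v = _sig6(m["value"])
                writer.writerow([report.benchmark, name,
                                 "" if v is None else v,
                                 m["units"], "" if m["n"] is None else m["n"],
                                 m["notes"]])
    else:
        raise FormatError(f"unknown report format {format!r}")
    tmp.replace(path)


def read_report(path) -> MetricReport:
    """Read back a JSON metric report (round-trip counterpart of write_report)."""
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    report = MetricReport(benchmark=payload["benchmark"],
                          provenance=payload.get("provenance", {}))
    report.metrics = payload["metrics"]
    return report
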