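"""Readers/writers for the external formats the pipeline touches, plus the
canonical in-memory data model.

Positions are 1-based everywhere in the public API, matching mutation
nomenclature such as R175H; 0-based indexing is used only internally.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._aminoacids import (
    AA20,
    AA_SET,
    AA_WITH_X,
    FOLD_TO_X,
    PSSM_COLUMNS,
    THREE_TO_ONE,
)

LABELS = ("driver", "passenger", "unknown")


class FormatError(ValueError):
    """Raised when an input file violates its dialect or an invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence over the 20-letter alphabet (X permitted, flagged)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise FormatError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - AA_WITH_X
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.residues):
            raise IndexError(
                f"position {position} outside sequence {self.id!r} "
                f"(length {len(self.residues)})"
            )
        return self.residues[position - 1]

    @property
    def has_unknown(self) -> bool:
        return "X" in self.residues


@dataclass(frozen=True)
class MutationRecord:
    """One missense substitution observed in a cancer type.

    ``label`` is ``driver``, ``passenger`` or ``unknown``; recurrence-based
    labelling (``label_by_recurrence``) promotes ``unknown`` records with
    sufficient sample support to drivers.
    """

    protein_id: str
    position: int
    wt: str
    mut: str
    cancer_type: str
    sample_count: int = 0
    label: str = "unknown"

    def __post_init__(self) -> None:
        if self.wt == self.mut:
            raise FormatError(
                f"{self.protein_id} position {self.position}: wt == mut ({self.wt})"
            )
        for res, name in ((self.wt, "wt"), (self.mut, "mut")):
            if res not in AA_WITH_X:
                raise FormatError(
                    f"{self.protein_id} position {self.position}: "
                    f"unknown {name} residue {res!r}"
                )
        if self.position < 1:
            raise FormatError(f"position must be >= 1, got {self.position}")
        if self.sample_count < 0:
            raise FormatError(f"sample_count must be >= 0, got {self.sample_count}")
        if self.label not in LABELS:
            raise FormatError(f"label must be one of {LABELS}, got {self.label!r}")

    def check_against(self, sequence: ProteinSequence) -> None:
        """Verify the wild-type residue matches the attached sequence."""
        if self.position > len(sequence):
            raise FormatError(
                f"{self.protein_id}: position {self.position} beyond "
                f"sequence length {len(sequence)}"
            )
        found = sequence.residue(self.position)
        if found != self.wt:
            raise FormatError(
                f"{self.protein_id} position {self.position}: sequence has "
                f"{found}, record claims wt {self.wt}"
            )


@dataclass(frozen=True)
class PSSMProfile:
    """Per-position log-odds scores in PSI-BLAST column order (ARNDCQEGHILKMFPSTWYV)."""

    protein_id: str
    scores: np.ndarray  # shape (L, 20), integer log-odds
    residues: str | None = None  # per-position native residue, if known

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise FormatError(
                f"PSSM for {self.protein_id!r} must be (L, 20), got {scores.shape}"
            )
        object.__setattr__(self, "scores", scores)
        if self.residues is not None and len(self.residues) != scores.shape[0]:
            raise FormatError(
                f"PSSM for {self.protein_id!r}: residue string length "
                f"{len(self.residues)} != {scores.shape[0]} rows"
            )

    def __len__(self) -> int:
        return self.scores.shape[0]

    def score(self, position: int, residue: str) -> float:
        """Log-odds score at a 1-based position for a residue column."""
        col = PSSM_COLUMNS.index(residue)
        return float(self.scores[position - 1, col])


@dataclass
class StructureModel:
    """Per-residue atom coordinates with B-factor (pLDDT for AlphaFold models).

    ``residues`` is an ordered list of (residue_number, residue_name, atoms)
    where atoms are (atom_name, x, y, z, bfactor) tuples in angstroms.
    """

    protein_id: str
    model_id: str
    residues: list[tuple[int, str, list[tuple[str, float, float, float, float]]]]

    def __post_init__(self) -> None:
        numbers = [r[0] for r in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise FormatError(
                f"{self.protein_id}/{self.model_id}: residue numbers not "
                "strictly increasing"
            )
        for _, _, atoms in self.residues:
            for name, x, y, z, b in atoms:
                if not all(math.isfinite(v) for v in (x, y, z)):
                    raise FormatError(
                        f"{self.protein_id}/{self.model_id}: non-finite "
                        f"coordinate on atom {name}"
                    )

    def residue_numbers(self) -> list[int]:
        return [r[0] for r in self.residues]

    def atoms_of(self, residue_number: int) -> list[tuple[str, float, float, float, float]]:
        for num, _, atoms in self.residues:
            if num == residue_number:
                return atoms
        raise KeyError(f"residue {residue_number} not in model {self.model_id}")

    def coords(self) -> np.ndarray:
        """All atom coordinates, shape (n_atoms, 3)."""
        return np.array(
            [[x, y, z] for _, _, atoms in self.residues for _, x, y, z, _ in atoms]
        )


@dataclass(frozen=True)
class ResidueTrack:
    """A per-residue score track (conservation, disorder, ...).

    Missing values are ``nan`` — explicitly encoded, never silently zero.
    """

    protein_id: str
    track_name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)

    def value(self, position: int) -> float:
        return float(self.values[position - 1])


@dataclass
class AAindexEntry:
    """One AAindex entry: 20 per-residue values (index1) or a 20x20 table
    (index2 mutation matrices, index3 contact potentials).

    Missing ("NA") cells are stored as nan; looking one up raises KeyError at
    use time, never at parse time.
    """

    accession: str
    kind: str  # index1 | index2 | index3
    values: dict = field(default_factory=dict)
    description: str = ""

    def lookup(self, a: str, b: str | None = None) -> float:
        if self.kind == "index1":
            if b is not None:
                raise ValueError(f"{self.accession} is index1; one residue expected")
            v = self.values.get(a)
        else:
            if b is None:
                raise ValueError(f"{self.accession} is {self.kind}; pair expected")
            v = self.values.get((a, b))
            if v is None or (isinstance(v, float) and math.isnan(v)):
                v = self.values.get((b, a)) if self.kind == "index3" else v
        if v is None:
            raise KeyError(f"{self.accession}: no cell for {(a, b) if b else a}")
        if isinstance(v, float) and math.isnan(v):
            raise KeyError(f"{self.accession}: cell {(a, b) if b else a} is NA")
        return float(v)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a FASTA file; ids from header up to first whitespace, sequences
    uppercased, non-standard letters (U/B/Z/J/O) folded to X with a warning."""
    path = Path(path)
    records: list[ProteinSequence] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks).upper()
        folded = "".join(FOLD_TO_X.get(c, c) for c in seq)
        if folded != seq:
            warnings.warn(
                f"{header}: non-standard residues mapped to X", stacklevel=3
            )
        records.append(ProteinSequence(id=header, residues=folded))
        header, chunks = None, []

    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FormatError(f"{path}: empty FASTA header")
                if header in seen:
                    raise FormatError(f"{path}: duplicate sequence id {header!r}")
                seen.add(header)
            else:
                if header is None:
                    raise FormatError(f"{path}: sequence data before first header")
                chunks.append(line)
        flush()
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(sequences: Iterable[ProteinSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# mutation tables
# ---------------------------------------------------------------------------

DEFAULT_COLUMNS = {
    "protein_id": "protein_id",
    "position": "position",
    "wt": "wt",
    "mut": "mut",
    "cancer_type": "cancer_type",
    "sample_count": "sample_count",
    "label": "label",
}


def read_mutation_table(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> list[MutationRecord]:
    """Read a mutation CSV. ``columns`` remaps this package's canonical column
    names to the file's header; the ``label`` column is optional."""
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    records: list[MutationRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty mutation table")
        required = ["protein_id", "position", "wt", "mut", "cancer_type", "sample_count"]
        missing = [colmap[c] for c in required if colmap[c] not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        has_label = colmap["label"] in reader.fieldnames
        for i, row in enumerate(reader, start=2):  # 1-based, header is row 1
            try:
                position = int(row[colmap["position"]])
            except ValueError:
                raise FormatError(
                    f"{path} row {i}: malformed position "
                    f"{row[colmap['position']]!r}"
                ) from None
            try:
                sample_count = int(row[colmap["sample_count"]])
            except ValueError:
                raise FormatError(
                    f"{path} row {i}: malformed sample_count "
                    f"{row[colmap['sample_count']]!r}"
                ) from None
            label = "unknown"
            if has_label and row[colmap["label"]]:
                label = row[colmap["label"]].strip().lower()
            try:
                records.append(
                    MutationRecord(
                        protein_id=row[colmap["protein_id"]].strip(),
                        position=position,
                        wt=row[colmap["wt"]].strip().upper(),
                        mut=row[colmap["mut"]].strip().upper(),
                        cancer_type=row[colmap["cancer_type"]].strip(),
                        sample_count=sample_count,
                        label=label,
                    )
                )
            except FormatError as exc:
                raise FormatError(f"{path} row {i}: {exc}") from None
    return records


def write_mutation_table(records: Iterable[MutationRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["protein_id", "position", "wt", "mut", "cancer_type", "sample_count", "label"]
        )
        for r in records:
            writer.writerow(
                [r.protein_id, r.position, r.wt, r.mut, r.cancer_type, r.sample_count, r.label]
            )


def label_by_recurrence(
    records: Sequence[MutationRecord], threshold: int = 3
) -> list[MutationRecord]:
    """Promote ``unknown`` records with sample_count >= threshold to drivers.

    Existing driver/passenger labels are never overwritten.
    """
    out = []
    for r in records:
        if r.label == "unknown" and r.sample_count >= threshold:
            out.append(
                MutationRecord(
                    protein_id=r.protein_id,
                    position=r.position,
                    wt=r.wt,
                    mut=r.mut,
                    cancer_type=r.cancer_type,
                    sample_count=r.sample_count,
                    label="driver",
                )
            )
        else:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# PSI-BLAST ascii PSSM
# ---------------------------------------------------------------------------

def read_pssm_ascii(
    path: str | Path, sequence: ProteinSequence | None = None
) -> PSSMProfile:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    Only the first 20-column log-odds block is read; the weighted-percentage
    block and trailing statistics are ignored. If ``sequence`` is given, each
    row's residue letter is checked against it.
    """
    path = Path(path)
    rows: list[list[int]] = []
    letters: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 22:
                continue
            if not parts[0].isdigit():
                continue
            if len(parts[1]) != 1 or not parts[1].isalpha():
                continue
            try:
                scores = [int(tok) for tok in parts[2:22]]
            except ValueError:
                continue
            rows.append(scores)
            letters.append(parts[1].upper())
    if not rows:
        raise FormatError(f"{path}: no PSSM rows found")
    protein_id = path.stem
    if sequence is not None:
        protein_id = sequence.id
        if len(rows) != len(sequence):
            raise FormatError(
                f"{path}: {len(rows)} PSSM rows but sequence length {len(sequence)}"
            )
        for i, letter in enumerate(letters):
            expected = sequence.residues[i]
            if expected != "X" and letter != expected:
                raise FormatError(
                    f"{path} position {i + 1}: PSSM residue {letter} does not "
                    f"match sequence residue {expected}"
                )
    return PSSMProfile(
        protein_id=protein_id,
        scores=np.array(rows, dtype=int),
        residues="".join(letters),
    )


# ---------------------------------------------------------------------------
# structures (PDB / mmCIF)
# ---------------------------------------------------------------------------

def read_structure(path: str | Path, protein_id: str | None = None) -> list[StructureModel]:
    """Read a PDB or mmCIF file into one StructureModel per MODEL block.

    HETATM records and waters are ignored; only the first chain is kept
    (AlphaFold monomer assumption).
    """
    from Bio.PDB import MMCIFParser, PDBParser

    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    parser = (
        MMCIFParser(QUIET=True)
        if path.suffix.lower() in {".cif", ".mmcif"}
        else PDBParser(QUIET=True)
    )
    structure = parser.get_structure(protein_id, str(path))
    models: list[StructureModel] = []
    for model in structure:
        chains = list(model)
        if not chains:
            continue
        chain = chains[0]
        residues = []
        for res in chain:
            hetflag, resnum, _ = res.id
            if hetflag.strip():  # HETATM / water
                continue
            atoms = [
                (
                    atom.get_name(),
                    float(atom.coord[0]),
                    float(atom.coord[1]),
                    float(atom.coord[2]),
                    float(atom.get_bfactor()),
                )
                for atom in res
            ]
            if atoms:
                residues.append((resnum, res.get_resname(), atoms))
        if residues:
            models.append(
                StructureModel(
                    protein_id=protein_id, model_id=str(model.id), residues=residues
                )
            )
    if not models:
        raise FormatError(f"{path}: no ATOM records")
    return models


def model_sequence(model: StructureModel) -> str:
    """One-letter sequence of a structure model (X for non-standard residues)."""
    return "".join(THREE_TO_ONE.get(name, "X") for _, name, _ in model.residues)


# ---------------------------------------------------------------------------
# DSSP output
# ---------------------------------------------------------------------------

SS8_TO_SS3 = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}


def collapse_ss8(code: str) -> str:
    """Collapse an 8-state DSSP code to 3 states: {H,G,I}->H, {E,B}->E, else C."""
    return SS8_TO_SS3.get(code, "C")


def read_dssp(path: str | Path) -> list[tuple[int, str, float]]:
    """Parse classic DSSP output into (residue_number, ss3, acc) tuples.

    Uses the fixed-column residue section following the ``#  RESIDUE`` header;
    chain-break ``!`` rows are skipped with a warning.
    """
    path = Path(path)
    out: list[tuple[int, str, float]] = []
    in_body = False
    with open(path) as fh:
        for line in fh:
            if not in_body:
                if line.lstrip().startswith("#") and "RESIDUE" in line:
                    in_body = True
                continue
            if len(line) < 38:
                continue
            aa = line[13]
            if aa == "!":
                warnings.warn(f"{path}: chain break row skipped", stacklevel=2)
                continue
            resnum_field = line[5:10].strip()
            if not resnum_field:
                continue
            ss = collapse_ss8(line[16].strip())
            acc = float(line[34:38].strip() or 0)
            out.append((int(resnum_field), ss, acc))
    if not out:
        raise FormatError(f"{path}: no residue rows (is this DSSP output?)")
    return out


# ---------------------------------------------------------------------------
# residue tracks (TSV)
# ---------------------------------------------------------------------------

def read_tracks(path: str | Path, protein_id: str | None = None) -> list[ResidueTrack]:
    """Read a per-residue track TSV: first column ``position`` (1-based),
    one column per track; empty cells / 'NA' become nan."""
    import pandas as pd

    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""])
    if "position" not in df.columns:
        raise FormatError(f"{path}: missing 'position' column")
    df = df.sort_values("position")
    positions = df["position"].to_numpy()
    if not np.array_equal(positions, np.arange(1, len(df) + 1)):
        raise FormatError(f"{path}: positions must be contiguous from 1")
    return [
        ResidueTrack(
            protein_id=protein_id,
            track_name=col,
            values=df[col].to_numpy(dtype=float),
        )
        for col in df.columns
        if col != "position"
    ]


# ---------------------------------------------------------------------------
# AAindex flat files
# ---------------------------------------------------------------------------

def _parse_float(tok: str) -> float:
    if tok.upper() in {"NA", "NA.", "-"}:
        return math.nan
    return float(tok)


def read_aaindex(path: str | Path, kind: str) -> list[AAindexEntry]:
    """Parse an AAindex flat file (``//``-terminated entries).

    kind='index1': ``I`` blocks of 20 values. kind='index2'/'index3':
    ``M rows = ..., cols = ...`` blocks; lower-triangular matrices are
    mirrored (index3 contact potentials are symmetric by construction).
    """
    if kind not in {"index1", "index2", "index3"}:
        raise ValueError(f"kind must be index1|index2|index3, got {kind!r}")
    entries: list[AAindexEntry] = []
    accession = ""
    description = ""
    mode: str | None = None
    rows_order = cols_order = ""
    matrix_rows: list[list[float]] = []
    index1_vals: list[float] = []
    index1_cols: list[str] = []

    def finish() -> None:
        nonlocal accession, description, mode, matrix_rows, index1_vals, index1_cols
        nonlocal rows_order, cols_order
        if not accession:
            return
        if kind == "index1":
            if len(index1_vals) != 20 or len(index1_cols) != 20:
                raise FormatError(
                    f"{accession}: index1 entry needs exactly 20 values, "
                    f"got {len(index1_vals)}"
                )
            values = dict(zip(index1_cols, index1_vals))
        else:
            values = {}
            for i, row in enumerate(matrix_rows):
                r = rows_order[i]
                if len(row) == len(cols_order):  # full square
                    for j, v in enumerate(row):
                        values[(r, cols_order[j])] = v
                elif len(row) == i + 1:  # lower triangle, mirror
                    for j, v in enumerate(row):
                        c = cols_order[j]
                        values[(r, c)] = v
                        values[(c, r)] = v
                else:
                    raise FormatError(
                        f"{accession}: matrix row {i + 1} has {len(row)} values"
                    )
        entries.append(
            AAindexEntry(
                accession=accession, kind=kind, values=values, description=description
            )
        )
        accession, description, mode = "", "", None
        matrix_rows, index1_vals, index1_cols = [], [], []
        rows_order = cols_order = ""

    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("//"):
                finish()
                continue
            if line.startswith("H "):
                accession = line[2:].strip()
                mode = None
            elif line.startswith("D "):
                description = line[2:].strip()
            elif line.startswith("I ") and kind == "index1":
                # header like "I    A/L     R/K ..." -> first-letter order, then second
                pairs = [tok.split("/") for tok in line[2:].split()]
                index1_cols = [p[0] for p in pairs] + [p[1] for p in pairs]
                mode = "index1"
            elif line.startswith("M ") and kind != "index1":
                spec_part = line[2:]
                rows_order = cols_order = ""
                for piece in spec_part.split(","):
                    piece = piece.strip()
                    if piece.startswith("rows ="):
                        rows_order = piece.split("=")[1].strip()
                    elif piece.startswith("cols ="):
                        cols_order = piece.split("=")[1].strip()
                mode = "matrix"
            elif mode == "index1" and line[:1] == " ":
                index1_vals.extend(_parse_float(t) for t in line.split())
            elif mode == "matrix" and line[:1] == " ":
                toks = line.split()
                if toks:
                    matrix_rows.append([_parse_float(t) for t in toks])
    finish()
    if not entries:
        raise FormatError(f"{path}: no AAindex entries parsed")
    return entries
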