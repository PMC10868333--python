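"""Readers and writers for the formats the evaluation system touches.

FASTA goes through Biopython, indicator tables through pandas.  PDB ATOM
records are parsed directly from their fixed-width columns because the
model kept here is deliberately coarse: one chain, backbone/Cα coordinates
per residue, first altloc, HETATM ignored.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    ConfigError,
    DimensionMismatchError,
    FormatError,
    InputTooSmallError,
)

logger = logging.getLogger(__name__)

#: Canonical one-letter amino-acid alphabet, alphabetical by letter.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Missing-value markers accepted in indicator tables (the published
#: tables print an en dash for an unavailable design time).
MISSING_MARKERS = ["", "-", "–", "NA"]

#: Allowed per-indicator orientation tags.
ORIENTATIONS = ("benefit", "cost-linear", "cost-reciprocal")

#: Three-letter -> one-letter residue code map for PDB parsing.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """One amino-acid sequence with optional provenance tags."""

    id: str
    sequence: str
    method: str | None = None
    protein: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS + "X")
        if bad:
            raise FormatError(
                f"record {self.id!r}: illegal residue characters "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Residue:
    """A residue with Cα and optional further backbone coordinates (Å)."""

    number: int
    code: str
    ca: np.ndarray
    n: np.ndarray | None = None
    c: np.ndarray | None = None
    o: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        if self.ca.shape != (3,) or not np.all(np.isfinite(self.ca)):
            raise FormatError(
                f"residue {self.number}: Cα coordinate must be a finite 3-vector"
            )


@dataclass
class StructureModel:
    """An ordered single-chain backbone model."""

    id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        numbers = [r.number for r in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise FormatError(
                f"structure {self.id!r}: residue numbers must be strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.code for r in self.residues)

    @property
    def ca_coords(self) -> np.ndarray:
        """(n, 3) array of Cα coordinates in residue order."""
        return np.array([r.ca for r in self.residues], dtype=float)


@dataclass
class IndicatorTable:
    """A methods × indicators matrix with per-indicator orientation tags.

    ``data`` is indexed by method name; ``orientation`` maps every column
    to one of :data:`ORIENTATIONS`.  Missing cells are NaN.
    """

    data: pd.DataFrame
    orientation: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in self.data.columns:
            if col not in self.orientation:
                raise ConfigError(f"indicator {col!r} has no orientation tag")
            if self.orientation[col] not in ORIENTATIONS:
                raise ConfigError(
                    f"indicator {col!r}: unknown orientation "
                    f"{self.orientation[col]!r}"
                )
            n_missing = int(self.data[col].isna().sum())
            if n_missing > 1:
                raise FormatError(
                    f"indicator {col!r}: {n_missing} missing values "
                    "(at most one per column is tolerated)"
                )

    @property
    def method_names(self) -> list[str]:
        return list(self.data.index)

    @property
    def indicator_names(self) -> list[str]:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, allow_x: bool = False) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into :class:`SequenceRecord` objects.

    Sequences are upper-cased and order is preserved.  Residue letters
    outside the canonical alphabet raise :class:`FormatError`; ``X`` is
    accepted only when *allow_x* is set.
    """
    path = Path(path)
    records = []
    with path.open() as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            allowed = set(AMINO_ACIDS) | ({"X"} if allow_x else set())
            bad = set(seq) - allowed
            if bad:
                raise FormatError(
                    f"{path.name}, record {rec.id!r}: illegal characters "
                    f"{sorted(bad)}"
                )
            records.append(SequenceRecord(id=rec.id, sequence=seq))
    if not records:
        raise FormatError(f"{path.name}: no FASTA records found")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_structure(path: str | Path) -> StructureModel:
    """Parse the first chain of a PDB file into a :class:`StructureModel`.

    Only ATOM records are considered; the first altloc wins; residues
    without a Cα atom are dropped with a warning.  Files with no ATOM
    records raise :class:`FormatError`; models with fewer than three Cα
    atoms raise :class:`InputTooSmallError`.
    """
    path = Path(path)
    chain_id: str | None = None
    per_residue: dict[int, dict] = {}
    order: list[int] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.startswith("ATOM"):
                continue
            try:
                atom_name = line[12:16].strip()
                altloc = line[16]
                resname = line[17:20].strip()
                chain = line[21]
                resseq = int(line[22:26])
                xyz = np.array(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
            except ValueError as exc:
                raise FormatError(f"{path.name}, line {lineno}: {exc}") from exc
            if chain_id is None:
                chain_id = chain
            if chain != chain_id:
                continue
            if altloc not in (" ", "A"):
                continue
            if resname not in THREE_TO_ONE:
                continue
            entry = per_residue.setdefault(resseq, {"code": THREE_TO_ONE[resname]})
            if resseq not in order:
                order.append(resseq)
            key = atom_name.lower()
            if key in ("ca", "n", "c", "o") and key not in entry:
                entry[key] = xyz
    if chain_id is None:
        raise FormatError(f"{path.name}: no ATOM records")

    residues = []
    for num in sorted(order):
        entry = per_residue[num]
        if "ca" not in entry:
            warnings.warn(
                f"{path.name}: residue {num} has no Cα atom and was dropped",
                stacklevel=2,
            )
            continue
        residues.append(
            Residue(number=num, code=entry["code"], ca=entry["ca"],
                    n=entry.get("n"), c=entry.get("c"), o=entry.get("o"))
        )
    if len(residues) < 3:
        raise InputTooSmallError(
            f"{path.name}: {len(residues)} residues with Cα "
            "(at least 3 required for superposition)"
        )
    return StructureModel(id=path.stem, residues=residues)


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a model as minimal PDB ATOM records (chain A, Cα + backbone)."""
    path = Path(path)
    serial = 1
    with path.open("w") as fh:
        for res in model.residues:
            three = ONE_TO_THREE.get(res.code, "UNK")
            for name, coord in (("N", res.n), ("CA", res.ca),
                                ("C", res.c), ("O", res.o)):
                if coord is None:
                    continue
                fh.write(
                    f"ATOM  {serial:5d} {name:^4s}{three:>4s} A{res.number:4d}    "
                    f"{coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}"
                    f"{1.0:6.2f}{0.0:6.2f}           {name[0]:>1s}\n"
                )
                serial += 1
        fh.write("END\n")


# ---------------------------------------------------------------------------
# indicator tables and reports
# ---------------------------------------------------------------------------

def read_indicator_table(path: str | Path,
                         orientation_config: Mapping[str, str]) -> IndicatorTable:
    """Read a CSV/TSV indicator table (methods in the first column).

    Each column must appear in *orientation_config*; cells equal to one of
    :data:`MISSING_MARKERS` become NaN; any other non-numeric cell raises
    :class:`FormatError`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", index_col=0,
                     na_values=MISSING_MARKERS, keep_default_na=False,
                     skipinitialspace=True)
    for col in df.columns:
        if col not in orientation_config:
            raise ConfigError(
                f"indicator {col!r} in {path.name} is absent from the "
                "orientation config"
            )
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise FormatError(
                f"{path.name}, column {col!r}: non-numeric cell ({exc})"
            ) from exc
    orientation = {col: orientation_config[col] for col in df.columns}
    return IndicatorTable(data=df, orientation=orientation)


def write_indicator_table(table: IndicatorTable, path: str | Path) -> None:
    table.data.to_csv(path)


def write_report(result, weights: Mapping[str, "object"],
                 path: str | Path, table: IndicatorTable | None = None) -> None:
    """Write a CSV ranking report.

    One row per method (raw indicator values when *table* is given, Ci to
    three decimals, rank), followed by the subjective / objective / combined
    weight rows labelled the way the published tables label them.

    *weights* maps ``subjective`` / ``objective`` / ``combined`` to
    WeightVector-like objects sharing the result's indicator set.
    """
    path = Path(path)
    indicator_names = list(weights["combined"].indicator_names)
    for role, wv in weights.items():
        if list(wv.indicator_names) != indicator_names:
            raise DimensionMismatchError(
                f"{role} weights do not share the indicator set of the report"
            )
    columns = indicator_names + ["Ci", "Rank"]
    rows = {}
    for i, method in enumerate(result.method_names):
        vals: list = [""] * len(indicator_names)
        if table is not None:
            if list(table.indicator_names) != indicator_names:
                raise DimensionMismatchError(
                    "indicator table does not share the report's indicator set"
                )
            vals = [table.data.loc[method, c] for c in indicator_names]
        rows[method] = vals + [round(float(result.ci[i]), 3),
                               int(result.ranks[i])]
    label = {"subjective": "AHP weight", "objective": "CRITIC weight",
             "combined": "Final weight"}
    for role in ("subjective", "objective", "combined"):
        wv = weights[role]
        rows[label[role]] = [round(float(w), 3) for w in wv.weights] + ["", ""]
    report = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    report.index.name = "Method and weight"
    try:
        report.to_csv(path)
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# JSON config
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict:
    """Read a JSON config (orientation map, weights, judgment matrix...)."""
    path = Path(path)
    try:
        with path.open() as fh:
            return json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path.name}: invalid JSON ({exc})") from exc
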