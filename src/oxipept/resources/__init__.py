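"""Lookup tables the peptide encoders depend on.

Three tables are exposed through validating loaders:

* :func:`load_aaindex` — a 566-property amino-acid physicochemical index
  table.  The bundled default is a deterministic SYNTHETIC stand-in (see
  :func:`_synthetic_property_table`); users holding the real AAindex1
  flat file can pass its path to consume the genuine database.
* :func:`load_blosum62` — the published BLOSUM62 log-odds substitution
  matrix (via Biopython's bundled NCBI copy), extended with one all-zero
  21st column so every residue row has a uniform 21-wide layout.
* :func:`load_ctd_groups` — the 13-attribute three-group residue
  partition table behind CTD descriptors.

All loaders are pure: repeated calls return equal objects.

Amino-acid ordering everywhere is the alphabetical one-letter order
``ACDEFGHIKLMNPQRSTVWY``; it fixes the feature layout of the BLOSUM62 and
skip-dipeptide encoders and is deliberately never configurable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources as _ilres
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from ..sequence_io import AMINO_ACIDS

__all__ = [
    "PropertyTable",
    "SubstitutionMatrix",
    "CtdGroupingTable",
    "load_aaindex",
    "load_blosum62",
    "load_ctd_groups",
    "N_AAINDEX_PROPERTIES",
]

#: Cardinality of the AAindex1 physicochemical-property collection.
N_AAINDEX_PROPERTIES = 566

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


class ResourceError(ValueError):
    """A bundled or user-supplied resource failed validation."""


@dataclass(frozen=True)
class PropertyTable:
    """566 physicochemical properties, one value per canonical residue.

    ``values[j, a]`` is property ``properties[j]`` for amino acid
    ``AMINO_ACIDS[a]``.  ``imputed`` flags cells that were missing in the
    source and filled with the property's mean over available residues.
    """

    properties: tuple[str, ...]
    values: np.ndarray  # (566, 20) float
    imputed: np.ndarray  # (566, 20) bool
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if len(self.properties) != N_AAINDEX_PROPERTIES:
            raise ResourceError(
                f"expected {N_AAINDEX_PROPERTIES} properties, got {len(self.properties)}"
            )
        if self.values.shape != (N_AAINDEX_PROPERTIES, 20):
            raise ResourceError(f"bad value matrix shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ResourceError("property table contains non-finite values")

    def value(self, prop: str, aa: str) -> float:
        return float(self.values[self.properties.index(prop), _AA_INDEX[aa]])


@dataclass(frozen=True)
class SubstitutionMatrix:
    """BLOSUM62 as a 20 x 21 integer score matrix.

    Rows/columns 0..19 follow alphabetical residue order; column 20 is the
    appended all-zero column.  The 20 x 20 block is symmetric.
    """

    scores: np.ndarray  # (20, 21) int

    def __post_init__(self) -> None:
        if self.scores.shape != (20, 21):
            raise ResourceError(f"bad matrix shape {self.scores.shape}")
        block = self.scores[:, :20]
        if not np.array_equal(block, block.T):
            raise ResourceError("20x20 substitution block is not symmetric")
        if np.any(self.scores[:, 20] != 0):
            raise ResourceError("column 21 must be identically zero")

    def row(self, aa: str) -> np.ndarray:
        return self.scores[_AA_INDEX[aa]]

    def score(self, x: str, y: str) -> int:
        return int(self.scores[_AA_INDEX[x], _AA_INDEX[y]])


@dataclass(frozen=True)
class CtdGroupingTable:
    """13 physicochemical attributes, each a 3-group partition of the 20 residues."""

    properties: tuple[str, ...]
    grouping: dict[str, dict[str, int]]  # property -> residue -> group in {1,2,3}

    def __post_init__(self) -> None:
        if len(self.properties) != 13:
            raise ResourceError(f"expected 13 CTD properties, got {len(self.properties)}")
        for prop in self.properties:
            assign = self.grouping[prop]
            if sorted(assign) != sorted(AMINO_ACIDS):
                raise ResourceError(f"{prop}: residues not a partition of the 20")
            groups = set(assign.values())
            if groups != {1, 2, 3}:
                raise ResourceError(f"{prop}: groups {sorted(groups)} != {{1,2,3}}")

    def group_of(self, prop: str, aa: str) -> int:
        return self.grouping[prop][aa]


def _data_path(name: str) -> Path:
    return Path(_ilres.files("oxipept.resources") / "data" / name)


# ---------------------------------------------------------------------------
# AAindex


def _synthetic_property_table(seed: int = 20250606) -> PropertyTable:
    """Deterministic synthetic stand-in for the 566-property AAindex table.

    Each synthetic property assigns every residue a value drawn from a
    property-specific normal distribution (seeded once, identical on every
    load).  The table reproduces the real database's *shape* and the
    encoder contract (566 finite values per residue) but none of its
    measured physicochemistry; results that depend on genuine AAindex
    values require the real flat file via ``load_aaindex(path=...)``.
    A small fraction of cells are masked and mean-imputed so the
    imputation path is exercised by default.
    """
    rng = np.random.default_rng(seed)
    scale = rng.lognormal(mean=0.0, sigma=1.5, size=N_AAINDEX_PROPERTIES)
    loc = rng.normal(0.0, 2.0, size=N_AAINDEX_PROPERTIES)
    values = loc[:, None] + scale[:, None] * rng.standard_normal(
        (N_AAINDEX_PROPERTIES, 20)
    )
    # mask ~1% of cells (never a full row) to exercise mean imputation
    imputed = rng.random((N_AAINDEX_PROPERTIES, 20)) < 0.01
    imputed[:, 0] &= ~imputed[:, 1:].all(axis=1)
    for j in range(N_AAINDEX_PROPERTIES):
        if imputed[j].any():
            mean = values[j, ~imputed[j]].mean()
            values[j, imputed[j]] = mean
    props = tuple(f"SYNTH{j:03d}" for j in range(N_AAINDEX_PROPERTIES))
    return PropertyTable(props, values, imputed, source="synthetic")


_AAINDEX_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"  # row order in aaindex1 'I' blocks


def _parse_aaindex1(path: str | Path) -> PropertyTable:
    """Parse the AAindex1 flat-file format (H/I record blocks).

    Missing entries (``NA``) are imputed with the property's mean over the
    available residues and flagged.
    """
    entries: list[tuple[str, dict[str, float | None]]] = []
    accession = None
    with open(path, encoding="utf-8", errors="replace") as fh:
        lines = iter(fh)
        for line in lines:
            if line.startswith("H "):
                accession = line[2:].strip()
            elif line.startswith("I "):
                row1 = next(lines).split()
                row2 = next(lines).split()
                vals = row1 + row2
                if len(vals) != 20:
                    raise ResourceError(f"{accession}: expected 20 values, got {len(vals)}")
                parsed: dict[str, float | None] = {}
                for aa, v in zip(_AAINDEX_AA_ORDER, vals):
                    parsed[aa] = None if v in ("NA", "NA.") else float(v)
                entries.append((accession or f"PROP{len(entries)}", parsed))
    if len(entries) != N_AAINDEX_PROPERTIES:
        raise ResourceError(
            f"AAindex file has {len(entries)} properties, expected {N_AAINDEX_PROPERTIES}"
        )
    values = np.empty((N_AAINDEX_PROPERTIES, 20))
    imputed = np.zeros((N_AAINDEX_PROPERTIES, 20), dtype=bool)
    for j, (_, parsed) in enumerate(entries):
        avail = [v for v in parsed.values() if v is not None]
        if not avail:
            raise ResourceError(f"{entries[j][0]}: all values missing")
        mean = float(np.mean(avail))
        for aa, v in parsed.items():
            a = _AA_INDEX[aa]
            if v is None:
                values[j, a] = mean
                imputed[j, a] = True
            else:
                values[j, a] = v
    return PropertyTable(
        tuple(acc for acc, _ in entries), values, imputed, source=str(path)
    )


def load_aaindex(path: str | Path | None = None) -> PropertyTable:
    """Load the 566-property table.

    With ``path=None`` returns the bundled deterministic synthetic
    stand-in; with a path, parses a real AAindex1 flat file, mean-imputing
    ``NA`` cells per property and flagging them.
    """
    if path is None:
        return _synthetic_property_table()
    return _parse_aaindex1(path)


# ---------------------------------------------------------------------------
# BLOSUM62


def load_blosum62(path: str | Path | None = None) -> SubstitutionMatrix:
    """Load BLOSUM62 and append the all-zero 21st column.

    Default source is Biopython's bundled NCBI matrix; ``path`` accepts a
    matrix in the standard NCBI text format.
    """
    if path is None:
        mat = substitution_matrices.load("BLOSUM62")
    else:
        mat = substitution_matrices.read(str(path))
    scores = np.zeros((20, 21), dtype=np.int64)
    for i, x in enumerate(AMINO_ACIDS):
        for j, y in enumerate(AMINO_ACIDS):
            scores[i, j] = int(mat[x, y])
    return SubstitutionMatrix(scores)


# ---------------------------------------------------------------------------
# CTD groupings


def load_ctd_groups(path: str | Path | None = None) -> CtdGroupingTable:
    """Load the 13-attribute three-group partition table from TSV."""
    src = Path(path) if path is not None else _data_path("ctd_groups.tsv")
    props: list[str] = []
    grouping: dict[str, dict[str, int]] = {}
    with open(src, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("property\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ResourceError(f"bad CTD grouping row: {line!r}")
            prop, *groups = parts
            assign: dict[str, int] = {}
            for g, residues in enumerate(groups, start=1):
                if not residues:
                    raise ResourceError(f"{prop}: group {g} is empty")
                for aa in residues:
                    if aa in assign:
                        raise ResourceError(f"{prop}: residue {aa} assigned twice")
                    assign[aa] = g
            props.append(prop)
            grouping[prop] = assign
    return CtdGroupingTable(tuple(props), grouping)


@dataclass(frozen=True)
class ResourceBundle:
    """The three tables the encoders need, loaded together."""

    aaindex: PropertyTable
    blosum62: SubstitutionMatrix
    ctd_groups: CtdGroupingTable

    @classmethod
    def default(cls) -> "ResourceBundle":
        return cls(load_aaindex(), load_blosum62(), load_ctd_groups())
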