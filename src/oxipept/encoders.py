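"""Peptide descriptor encoders and fusion features.

Four descriptor families map a peptide to a fixed-length numeric vector:

* **AAindex** (566-D) — the mean of each physicochemical property over the
  peptide's residues: ``F_j = (1/L) * sum_i v_j(residue_i)``.
* **CTD** (273-D) — for each of 13 physicochemical attributes whose
  three-group residue partition is tabulated in :mod:`oxipept.resources`:
  3 group-composition fractions, 3 adjacent-transition frequencies
  (unordered group pairs, divided by L-1), and 15 distribution values (the
  normalized positions at which each group reaches its first, 25%, 50%,
  75% and last occurrence).
* **ASDC** (400-D) — adaptive skip dipeptide composition: the frequency of
  every ordered residue pair over *all* index pairs i < j, at any
  separation, normalized by L(L-1)/2 so the vector is a probability
  distribution over the 400 ordered amino-acid pairs.
* **BLOSUM62** (420-D) — for each residue type in alphabetical order, its
  in-peptide frequency times its 21-wide row of the zero-column-extended
  substitution matrix, concatenated.

Fusions concatenate member blocks in the canonical order
(aaindex, asdc, blosum62, ctd), so feature indices are stable no matter
how the user spells the combination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .resources import (
    CtdGroupingTable,
    PropertyTable,
    ResourceBundle,
    SubstitutionMatrix,
)
from .sequence_io import AMINO_ACIDS, LabeledDataset, PeptideRecord

__all__ = [
    "FeatureBlock",
    "FeatureSetSpec",
    "ENCODER_NAMES",
    "ENCODER_DIMS",
    "encode_aaindex",
    "encode_ctd",
    "encode_asdc",
    "encode_blosum62",
    "encode_fusion",
    "encode_dataset",
    "enumerate_feature_sets",
]

#: Canonical encoder order; fixes fusion concatenation order.
ENCODER_NAMES = ("aaindex", "asdc", "blosum62", "ctd")
ENCODER_DIMS = {"aaindex": 566, "asdc": 400, "blosum62": 420, "ctd": 273}

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class FeatureBlock:
    """A named fixed-dimension feature vector with per-dimension labels."""

    name: str
    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.values.ndim != 1 or len(self.labels) != self.values.size:
            raise ValueError(
                f"{self.name}: {self.values.shape} values vs {len(self.labels)} labels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.name}: non-finite feature values")

    @property
    def dim(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class FeatureSetSpec:
    """An ordered, duplicate-free subset of the four encoders."""

    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("feature set must have at least one member")
        unknown = [m for m in self.members if m not in ENCODER_NAMES]
        if unknown:
            raise ValueError(
                f"unknown encoder(s) {unknown}; valid names: {list(ENCODER_NAMES)}"
            )
        canonical = tuple(m for m in ENCODER_NAMES if m in self.members)
        if self.members != canonical or len(set(self.members)) != len(self.members):
            raise ValueError(
                f"members must be duplicate-free in canonical order {canonical}"
            )

    @classmethod
    def of(cls, *names: str) -> "FeatureSetSpec":
        """Build a spec from names in any order/case."""
        wanted = {n.lower() for n in names}
        unknown = sorted(wanted - set(ENCODER_NAMES))
        if unknown:
            raise ValueError(
                f"unknown encoder(s) {unknown}; valid names: {list(ENCODER_NAMES)}"
            )
        return cls(tuple(m for m in ENCODER_NAMES if m in wanted))

    @property
    def dim(self) -> int:
        return sum(ENCODER_DIMS[m] for m in self.members)

    @property
    def name(self) -> str:
        return "+".join(self.members)


def encode_aaindex(p: PeptideRecord, table: PropertyTable) -> FeatureBlock:
    """566-D mean physicochemical property profile of the peptide."""
    idx = np.fromiter((_AA_INDEX[aa] for aa in p.residues), dtype=np.intp)
    values = table.values[:, idx].mean(axis=1)
    return FeatureBlock("aaindex", values, tuple(table.properties))


_CTD_PREFIXES = (
    "C.g1", "C.g2", "C.g3",
    "T.g1g2", "T.g1g3", "T.g2g3",
    "D.g1.first", "D.g1.25", "D.g1.50", "D.g1.75", "D.g1.last",
    "D.g2.first", "D.g2.25", "D.g2.50", "D.g2.75", "D.g2.last",
    "D.g3.first", "D.g3.25", "D.g3.50", "D.g3.75", "D.g3.last",
)


def encode_ctd(
    p: PeptideRecord,
    groups: CtdGroupingTable,
    *,
    d_variant: str = "milestone",
) -> FeatureBlock:
    """273-D composition/transition/distribution descriptor.

    ``d_variant="milestone"`` (default) reports distribution as normalized
    milestone positions — where along the sequence each group attains its
    1st, 25%, 50%, 75% and final occurrence.  ``d_variant="ratio"``
    instead reports the fraction of each group's residues falling in the
    first k% of positions (k in 0, 25, 50, 75, 100), a variant retained
    for auditability; it is nearly constant by construction and not
    recommended.
    """
    if d_variant not in ("milestone", "ratio"):
        raise ValueError(f"unknown d_variant {d_variant!r}")
    L = p.length
    out = np.zeros(273)
    labels: list[str] = []
    col = 0
    for prop in groups.properties:
        assign = groups.grouping[prop]
        seq_groups = [assign[aa] for aa in p.residues]
        counts = [seq_groups.count(g) for g in (1, 2, 3)]
        # composition
        for g in range(3):
            out[col + g] = counts[g] / L
        # transitions over unordered group pairs {1,2},{1,3},{2,3}
        trans = {(1, 2): 0, (1, 3): 0, (2, 3): 0}
        for a, b in zip(seq_groups, seq_groups[1:]):
            if a != b:
                trans[(min(a, b), max(a, b))] += 1
        out[col + 3] = trans[(1, 2)] / (L - 1)
        out[col + 4] = trans[(1, 3)] / (L - 1)
        out[col + 5] = trans[(2, 3)] / (L - 1)
        # distribution, 5 milestones per group
        d = col + 6
        for gi, g in enumerate((1, 2, 3)):
            positions = [i + 1 for i, x in enumerate(seq_groups) if x == g]  # 1-based
            if not positions:
                d += 5
                continue
            n = len(positions)
            if d_variant == "milestone":
                marks = (
                    positions[0],
                    positions[max(math.ceil(0.25 * n), 1) - 1],
                    positions[max(math.ceil(0.50 * n), 1) - 1],
                    positions[max(math.ceil(0.75 * n), 1) - 1],
                    positions[-1],
                )
                for m in marks:
                    out[d] = m / L
                    d += 1
            else:  # ratio: N_ik / N_i with k% of sequence positions
                for k in (0, 25, 50, 75, 100):
                    cutoff = math.floor(k / 100 * L)
                    out[d] = sum(1 for pos in positions if pos <= cutoff) / n
                    d += 1
        labels.extend(f"{prop}.{suffix}" for suffix in _CTD_PREFIXES)
        col += 21
    return FeatureBlock("ctd", out, tuple(labels))


_ASDC_LABELS = tuple(f"{a}{b}" for a in AMINO_ACIDS for b in AMINO_ACIDS)


def encode_asdc(p: PeptideRecord) -> FeatureBlock:
    """400-D adaptive skip dipeptide composition (probability vector).

    Counts the ordered residue pair at every index pair i < j — adjacent
    dipeptides and all skip distances alike — and divides by the total
    number of pairs L(L-1)/2.
    """
    L = p.length
    counts = np.zeros((20, 20))
    idx = [_AA_INDEX[aa] for aa in p.residues]
    for i in range(L - 1):
        for j in range(i + 1, L):
            counts[idx[i], idx[j]] += 1
    values = counts.ravel() / (L * (L - 1) / 2)
    return FeatureBlock("asdc", values, _ASDC_LABELS)


_B62_LABELS = tuple(
    f"{a}.{col}"
    for a in AMINO_ACIDS
    for col in list(AMINO_ACIDS) + ["gap"]
)


def encode_blosum62(p: PeptideRecord, matrix: SubstitutionMatrix) -> FeatureBlock:
    """420-D frequency-weighted substitution profile.

    Block *a* is the peptide frequency of residue *a* times row *a* of the
    20 x 21 extended matrix; residues absent from the peptide contribute a
    zero block.
    """
    freqs = np.zeros(20)
    for aa in p.residues:
        freqs[_AA_INDEX[aa]] += 1
    freqs /= p.length
    values = (freqs[:, None] * matrix.scores).ravel()
    return FeatureBlock("blosum62", values, _B62_LABELS)


def encode_fusion(
    p: PeptideRecord,
    spec: FeatureSetSpec,
    resources: ResourceBundle,
    *,
    ctd_d_variant: str = "milestone",
) -> FeatureBlock:
    """Concatenate the spec's member blocks in canonical order."""
    blocks: list[FeatureBlock] = []
    for member in spec.members:
        if member == "aaindex":
            blocks.append(encode_aaindex(p, resources.aaindex))
        elif member == "asdc":
            blocks.append(encode_asdc(p))
        elif member == "blosum62":
            blocks.append(encode_blosum62(p, resources.blosum62))
        else:
            blocks.append(encode_ctd(p, resources.ctd_groups, d_variant=ctd_d_variant))
    values = np.concatenate([b.values for b in blocks])
    labels = tuple(f"{b.name}.{lab}" for b in blocks for lab in b.labels)
    return FeatureBlock(spec.name, values, labels)


def encode_dataset(
    records: Sequence[PeptideRecord] | LabeledDataset,
    spec: FeatureSetSpec,
    resources: ResourceBundle,
    *,
    ctd_d_variant: str = "milestone",
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Encode many peptides into an (n, dim) matrix plus column labels."""
    if isinstance(records, LabeledDataset):
        records = records.records
    rows = [
        encode_fusion(p, spec, resources, ctd_d_variant=ctd_d_variant)
        for p in records
    ]
    if not rows:
        return np.empty((0, spec.dim)), tuple()
    return np.vstack([b.values for b in rows]), rows[0].labels


def enumerate_feature_sets(
    base: Sequence[str] = ENCODER_NAMES,
) -> list[FeatureSetSpec]:
    """All non-empty encoder subsets: singletons first, then by size.

    Four base encoders give 15 specs (4 singles + 11 true fusions).
    """
    base = tuple(base)
    if not base:
        raise ValueError("base encoder list must be non-empty")
    if len(set(base)) != len(base):
        raise ValueError("base encoder list has duplicates")
    canonical = tuple(m for m in ENCODER_NAMES if m in base)
    specs: list[FeatureSetSpec] = []
    for size in range(1, len(canonical) + 1):
        for combo in combinations(canonical, size):
            specs.append(FeatureSetSpec(combo))
    return specs
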