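"""Clone-consensus SNP calling and cDNA haplotype analysis.

Full-length cDNA alleles of a gene are cloned from several independent
PCR amplifications and Sanger sequenced.  Because Taq errors and
singleton sequencing miscalls are common, a variant is accepted as a
real SNP only under a consensus rule: it must be observed in at least
three clones originating from at least two independent amplifications.
The accepted SNPs define a haplotype matrix (SNP positions x cDNA
variants) on which this module provides distinct-variant counting,
pattern matching, pairwise Hamming distances, marker-correspondence
concordance, and ORF coordinate arithmetic (position 1 = A of the ATG
start codon; residue index = floor((pos-1)/3) + 1).

The package ships the 15-SNP x 9-variant haplotype matrix of the
potato plastidic starch phosphorylase PHO1a cDNA alleles as an example
dataset (``load_pho1a_haplotypes``); variant 1 is the reference allele
H_R and variant 5 the starch-associated allele H_A.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CloneTable",
    "HaplotypeMatrix",
    "MarkerCorrespondence",
    "consensus_snps",
    "distinct_variants",
    "match_haplotype",
    "haplotype_distance",
    "concordance",
    "residue_of",
    "third_position_snps",
    "check_annotations",
    "haplotype_matrix_from_fasta",
    "load_pho1a_haplotypes",
]

_META_COLS = ("cultivar", "tissue", "batch")


class CloneTable:
    """Base calls of sequenced cDNA clones with amplification metadata.

    Wraps a DataFrame indexed by clone id with the metadata columns
    ``cultivar``, ``tissue``, ``batch`` followed by one column per
    scored cDNA position (integer 1-based ORF coordinates).
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        missing = [c for c in _META_COLS if c not in frame.columns]
        if missing:
            raise ValueError(f"clone table lacks metadata columns {missing}")
        if frame["batch"].isna().any():
            raise ValueError("clones with missing amplification batch id")
        self._frame = frame

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def positions(self) -> list[int]:
        return [int(c) for c in self._frame.columns if c not in _META_COLS]

    @property
    def calls(self) -> pd.DataFrame:
        """Clone x position base calls (metadata columns dropped)."""
        cols = [c for c in self._frame.columns if c not in _META_COLS]
        return self._frame[cols]

    @property
    def batches(self) -> pd.Series:
        return self._frame["batch"]

    def __len__(self) -> int:
        return len(self._frame)


class HaplotypeMatrix:
    """SNP positions x cDNA variants base matrix.

    Rows are strictly increasing 1-based ORF positions; columns are
    variant ids; cells are single nucleotides.  ``annotations`` maps a
    position to its amino-acid-change label (e.g. ``His8Tyr``) when
    the substitution is nonsynonymous.
    """

    def __init__(self, values: pd.DataFrame, annotations: Mapping[int, str] | None = None) -> None:
        positions = [int(p) for p in values.index]
        if any(b - a <= 0 for a, b in zip(positions, positions[1:])):
            raise ValueError("positions must be strictly increasing")
        if positions and positions[0] < 1:
            raise ValueError("ORF positions are 1-based")
        bad = values.map(lambda b: not (isinstance(b, str) and len(b) == 1))
        if bad.to_numpy().any():
            raise ValueError("haplotype matrix cells must be single bases")
        self._values = values.copy()
        self._values.index = pd.Index(positions, name="position")
        self.annotations = dict(annotations or {})

    @property
    def values(self) -> pd.DataFrame:
        return self._values

    @property
    def positions(self) -> list[int]:
        return list(self._values.index)

    @property
    def variant_ids(self) -> list[str]:
        return [str(c) for c in self._values.columns]

    def column(self, variant_id: str) -> pd.Series:
        return self._values[variant_id]

    def __repr__(self) -> str:  # pragma: no cover
        return f"HaplotypeMatrix({len(self.positions)} positions x {len(self.variant_ids)} variants)"


@dataclass(frozen=True)
class MarkerCorrespondence:
    """Agreement between two marker scorings of the same individuals."""

    marker_a: str
    marker_b: str
    concordance: float
    n_compared: int


def consensus_snps(
    clones: CloneTable,
    reference: Mapping[int, str],
    min_clones: int = 3,
    min_batches: int = 2,
) -> list[tuple[int, str]]:
    """Call consensus SNPs from a clone table.

    A variant (position, base != reference) is accepted iff it is
    carried by at least ``min_clones`` clones spanning at least
    ``min_batches`` distinct amplification batches — the rule that
    separates real cDNA polymorphisms from PCR/sequencing artifacts.
    """
    if len(clones) < min_clones:
        raise ValueError(f"need at least {min_clones} clones")
    if clones.batches.nunique() < 2:
        raise ValueError("need clones from at least two amplification batches")
    out: list[tuple[int, str]] = []
    calls = clones.calls
    for col, pos in zip(calls.columns, clones.positions):
        ref_base = reference[pos]
        column = calls[col]
        for base in sorted(column.dropna().unique()):
            if base == ref_base:
                continue
            carriers = column == base
            if carriers.sum() >= min_clones and clones.batches[carriers].nunique() >= min_batches:
                out.append((pos, base))
    return out


def distinct_variants(matrix: HaplotypeMatrix) -> tuple[int, list[str]]:
    """Count pairwise-distinct haplotype columns.

    Duplicate columns are merged; the first-seen variant id represents
    each distinct haplotype.  Returns (count, representative ids).
    """
    if not matrix.variant_ids:
        raise ValueError("empty haplotype matrix")
    seen: dict[tuple, str] = {}
    for vid in matrix.variant_ids:
        key = tuple(matrix.column(vid))
        seen.setdefault(key, vid)
    reps = list(seen.values())
    return len(reps), reps


def match_haplotype(matrix: HaplotypeMatrix, pattern: Mapping[int, str]) -> list[str]:
    """Variant ids matching ``pattern`` (position -> base) at every position."""
    missing = [p for p in pattern if p not in matrix.positions]
    if missing:
        raise KeyError(f"pattern positions not in matrix: {missing}")
    hits = []
    for vid in matrix.variant_ids:
        col = matrix.column(vid)
        if all(col.loc[pos] == base for pos, base in pattern.items()):
            hits.append(vid)
    return hits


def haplotype_distance(matrix: HaplotypeMatrix, id_a: str, id_b: str) -> int:
    """Hamming distance between two variants over the scored positions."""
    a, b = matrix.column(id_a), matrix.column(id_b)
    return int((a.to_numpy() != b.to_numpy()).sum())


def concordance(calls_a: pd.Series, calls_b: pd.Series) -> MarkerCorrespondence:
    """Fraction of individuals on which two marker scorings agree.

    Used to establish that two markers (e.g. an SSCP band pattern and
    a SNP haplotype) diagnose the same allele.  Missing calls are
    excluded, not counted as mismatches.
    """
    joined = pd.concat([calls_a, calls_b], axis=1, join="inner").dropna()
    if joined.empty:
        raise ValueError("no non-missing overlapping individuals")
    equal = (joined.iloc[:, 0] == joined.iloc[:, 1]).sum()
    return MarkerCorrespondence(
        marker_a=str(calls_a.name),
        marker_b=str(calls_b.name),
        concordance=float(equal) / len(joined),
        n_compared=len(joined),
    )


def residue_of(cdna_position: int) -> tuple[int, int]:
    """Map a 1-based ORF position to (residue index, codon offset 1..3)."""
    if cdna_position < 1:
        raise ValueError("ORF positions are 1-based")
    return (cdna_position - 1) // 3 + 1, (cdna_position - 1) % 3 + 1


def third_position_snps(matrix: HaplotypeMatrix) -> tuple[list[int], list[int]]:
    """Partition the scored positions into (third-codon, non-third).

    Third-codon-position substitutions are synonymous for most codons,
    so the non-third set closely tracks the amino-acid-changing SNPs.
    """
    third = [p for p in matrix.positions if residue_of(p)[1] == 3]
    other = [p for p in matrix.positions if residue_of(p)[1] != 3]
    return third, other


_ANNOT_RE = re.compile(r"^([A-Za-z]{3})(\d+)([A-Za-z]{3})$")


def check_annotations(matrix: HaplotypeMatrix) -> list[tuple[int, str, int]]:
    """Verify amino-acid-change labels against coordinate arithmetic.

    For each annotated position, the residue index embedded in the
    label (e.g. 108 in ``Ala108Thr``) is compared with the index
    recomputed as floor((pos-1)/3)+1.  Disagreements are returned as
    (position, annotation, computed residue) and left uncorrected:
    they indicate an inconsistency in the input labels, and guessing
    the intended numbering is not this package's call to make.
    """
    flagged = []
    for pos, annot in matrix.annotations.items():
        m = _ANNOT_RE.match(annot)
        if m is None:
            continue
        claimed = int(m.group(2))
        computed = residue_of(pos)[0]
        if claimed != computed:
            flagged.append((pos, annot, computed))
    return flagged


def haplotype_matrix_from_fasta(path) -> HaplotypeMatrix:
    """Build a haplotype matrix from pre-aligned full-length cDNA alleles.

    All records must have equal length; the first record is the
    reference.  Positions where any sequence differs from the
    reference become matrix rows.
    """
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise ValueError("need at least two sequences")
    length = len(records[0].seq)
    if any(len(r.seq) != length for r in records):
        raise ValueError("sequences must be pre-aligned to equal length")
    seqs = [str(r.seq).upper() for r in records]
    variable = [i for i in range(length) if len({s[i] for s in seqs}) > 1]
    data = {r.id: [s[i] for i in variable] for r, s in zip(records, seqs)}
    frame = pd.DataFrame(data, index=[i + 1 for i in variable])
    return HaplotypeMatrix(frame)


def load_pho1a_haplotypes() -> HaplotypeMatrix:
    """The bundled PHO1a cDNA example: 15 consensus SNPs x 9 variants."""
    from .io import read_haplotype_tsv

    with resources.as_file(
        resources.files("tetrasnp.data") / "pho1a_cdna_haplotypes.tsv"
    ) as path:
        return read_haplotype_tsv(path)
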