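"""Tetraploid allele-dosage genotyping.

An autotetraploid individual carries four homologous copies of each
chromosome, so a biallelic SNP has five possible genotype classes
(AAAA, AAAB, AABB, ABBB, BBBB), i.e. minor-allele dosages 0-4.  In
Sanger amplicon sequencing the dosage of a heterozygous individual
(1:3, 2:2 or 3:1) is estimated from the relative heights of the
overlapping base-calling peaks.  This module converts peak signals (or
class strings) into dosage genotypes, computes allele frequencies from
dosage columns, and applies carrier-count frequency filters.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnpMarker",
    "PeakSignal",
    "GenotypeClass",
    "DosageMatrix",
    "call_dosage",
    "call_dosage_triallelic",
    "minor_allele_frequency",
    "mfa_dosage",
    "presence_absence_frequency",
    "apply_mfa_filter",
    "PLOIDY",
    "CLASS_LETTERS",
]

PLOIDY = 4
CLASS_LETTERS = "ABC"

#: Expected minor-allele peak-height fractions for dosages 0..4.
DOSAGE_CENTROIDS = np.array([0.0, 0.25, 0.5, 0.75, 1.0])

_ID_RE = re.compile(r"^(?P<locus>.+)-(?P<ref>[ACGT]+)_(?P<pos>\d+)_(?P<alt>[ACGT]+(?:/[ACGT]+)?)$")


@dataclass(frozen=True)
class SnpMarker:
    """A scored SNP or indel.

    Marker ids follow the ``Locus-REF_position_ALT`` convention
    (e.g. ``GWD-A_3452_G``); a triallelic marker joins its two
    alternate alleles with ``/`` (``PGM-3-T_441_A/C``).  ``position``
    is 1-based in the marker's coordinate system: ``cDNA_orf``
    (position 1 = A of the ATG start codon) or ``genomic_dm``
    (reference genome numbering).
    """

    locus: str
    position: int
    alleles: tuple[str, ...]
    coordinate_system: str = "cDNA_orf"
    scoring_mode: str = "dosage"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not 2 <= len(self.alleles) <= 3:
            raise ValueError(f"expected 2 or 3 alleles, got {self.alleles!r}")
        if self.coordinate_system not in {"cDNA_orf", "genomic_dm"}:
            raise ValueError(f"unknown coordinate system {self.coordinate_system!r}")
        if self.scoring_mode not in {"dosage", "presence_absence"}:
            raise ValueError(f"unknown scoring mode {self.scoring_mode!r}")

    @property
    def id(self) -> str:
        ref = self.alleles[0]
        alt = "/".join(self.alleles[1:])
        return f"{self.locus}-{ref}_{self.position}_{alt}"

    @property
    def is_triallelic(self) -> bool:
        return len(self.alleles) == 3

    @classmethod
    def from_id(cls, marker_id: str, **kwargs) -> "SnpMarker":
        """Parse a ``Locus-REF_position_ALT`` id back into a marker.

        The locus acronym may itself contain hyphens (``INV-8/2``,
        ``PGM-3``); the last hyphen before the REF_pos_ALT block is the
        separator.
        """
        m = _ID_RE.match(marker_id)
        if m is None:
            raise ValueError(f"cannot parse marker id {marker_id!r}")
        alleles = (m.group("ref"), *m.group("alt").split("/"))
        return cls(locus=m.group("locus"), position=int(m.group("pos")), alleles=alleles, **kwargs)


@dataclass(frozen=True)
class PeakSignal:
    """Per-allele peak heights at one marker in one individual."""

    heights: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(h < 0 for h in self.heights):
            raise ValueError("peak heights must be nonnegative")
        if not any(h > 0 for h in self.heights):
            raise ValueError("all-zero peak signal")


@dataclass(frozen=True)
class GenotypeClass:
    """A tetraploid genotype class such as AABB or AABC.

    ``dosage_vector`` counts copies of each marker allele (reference
    first) and sums to the ploidy; ``label`` is the canonical sorted
    letter string.  ``confidence`` is the distance from the observed
    height fraction(s) to the assigned class centroid (0 = exact) and
    supports an optional no-call band.
    """

    dosage_vector: tuple[int, ...]
    confidence: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if sum(self.dosage_vector) != PLOIDY:
            raise ValueError(f"dosage vector {self.dosage_vector} does not sum to {PLOIDY}")
        if any(d < 0 for d in self.dosage_vector):
            raise ValueError("negative allele count")

    @property
    def label(self) -> str:
        return "".join(
            CLASS_LETTERS[i] * d for i, d in enumerate(self.dosage_vector)
        )

    @property
    def alt_dosage(self) -> int:
        """Copies of the first alternate allele (biallelic dosage 0-4)."""
        return self.dosage_vector[1]

    @classmethod
    def from_label(cls, label: str) -> "GenotypeClass":
        label = label.upper()
        if len(label) != PLOIDY or any(c not in CLASS_LETTERS for c in label):
            raise ValueError(f"invalid genotype class label {label!r}")
        n_alleles = 3 if "C" in label else 2
        counts = tuple(label.count(CLASS_LETTERS[i]) for i in range(n_alleles))
        return cls(dosage_vector=counts)


def call_dosage(signal: PeakSignal, marker: SnpMarker) -> GenotypeClass:
    """Call a biallelic dosage genotype from two peak heights.

    The minor(alt)-allele height fraction ``f = h_alt / (h_ref + h_alt)``
    is mapped to the nearest of the five expected fractions
    {0, 1/4, 1/2, 3/4, 1}; ties break toward the lower dosage.
    """
    if marker.is_triallelic:
        return call_dosage_triallelic(signal, marker)
    if len(signal.heights) != 2:
        raise ValueError(f"expected 2 peak heights for biallelic marker, got {len(signal.heights)}")
    h_ref, h_alt = signal.heights
    f = h_alt / (h_ref + h_alt)
    dosage = int(np.argmin(np.abs(DOSAGE_CENTROIDS - f)))
    conf = abs(f - DOSAGE_CENTROIDS[dosage])
    return GenotypeClass(dosage_vector=(PLOIDY - dosage, dosage), confidence=conf)


def _compositions_of_ploidy(k: int) -> list[tuple[int, ...]]:
    """All ways of distributing 4 allele copies over k alleles."""
    out = []
    for bars in itertools.combinations_with_replacement(range(k), PLOIDY):
        counts = [0] * k
        for b in bars:
            counts[b] += 1
        out.append(tuple(counts))
    return out


def call_dosage_triallelic(signal: PeakSignal, marker: SnpMarker) -> GenotypeClass:
    """Call a triallelic genotype class (AAAC, AABC, ...) from three peaks.

    The observed height fractions are matched to the nearest of the 15
    integer compositions (d1, d2, d3) with d1+d2+d3 = 4 by Euclidean
    distance on the fraction simplex; ties break toward the
    lexicographically smallest class label.
    """
    if len(signal.heights) != 3:
        raise ValueError("triallelic call needs three peak heights")
    h = np.asarray(signal.heights, dtype=float)
    f = h / h.sum()
    best: tuple[float, str, tuple[int, ...]] | None = None
    for counts in _compositions_of_ploidy(3):
        d = np.linalg.norm(f - np.asarray(counts) / PLOIDY)
        label = "".join(CLASS_LETTERS[i] * c for i, c in enumerate(counts))
        key = (d, label)
        if best is None or key < (best[0], best[1]):
            best = (d, label, counts)
    assert best is not None
    return GenotypeClass(dosage_vector=best[2], confidence=best[0])


class DosageMatrix:
    """Individuals x markers genotype matrix.

    Values are minor(alt)-allele copy counts 0-4 for dosage-scored
    markers, class codes 0..N-1 for triallelic markers, or 0/1 for
    presence/absence-scored markers; ``NaN`` marks missing calls.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        markers: Mapping[str, SnpMarker] | None = None,
        modes: Mapping[str, str] | None = None,
    ) -> None:
        values = values.astype(float)
        if values.index.has_duplicates:
            raise ValueError("duplicate individual ids")
        if values.columns.has_duplicates:
            raise ValueError("duplicate marker ids")
        self._values = values
        self.markers = dict(markers) if markers else {}
        self._modes = dict(modes) if modes else {}
        for mid, marker in self.markers.items():
            self._modes.setdefault(mid, marker.scoring_mode)
        for mid in values.columns:
            self._modes.setdefault(mid, "dosage")
        self._validate()

    def _validate(self) -> None:
        for mid in self._values.columns:
            col = self._values[mid].dropna()
            if (col != col.round()).any():
                raise ValueError(f"non-integer genotype values in column {mid!r}")
            mode = self._modes[mid]
            marker = self.markers.get(mid)
            if mode == "presence_absence":
                hi = 1
            elif marker is not None and marker.is_triallelic:
                hi = 14  # class codes 0..N-1, at most 15 classes
            else:
                hi = PLOIDY
            if len(col) and (col.min() < 0 or col.max() > hi):
                raise ValueError(f"genotype values out of range in column {mid!r}")

    @property
    def values(self) -> pd.DataFrame:
        return self._values

    @property
    def individuals(self) -> pd.Index:
        return self._values.index

    @property
    def marker_ids(self) -> list[str]:
        return list(self._values.columns)

    def scoring_mode(self, marker_id: str) -> str:
        return self._modes[marker_id]

    def column(self, marker_id: str) -> pd.Series:
        return self._values[marker_id]

    def high_missing_markers(self, threshold: float = 0.2) -> list[str]:
        """Marker ids whose missing fraction exceeds ``threshold``."""
        frac = self._values.isna().mean()
        return list(frac.index[frac > threshold])

    def __repr__(self) -> str:  # pragma: no cover
        n, m = self._values.shape
        return f"DosageMatrix({n} individuals x {m} markers)"


def minor_allele_frequency(column: pd.Series, marker: SnpMarker | None = None) -> tuple[str, float]:
    """Minor-frequency-allele (MFA) identity and copy frequency.

    The alternate-allele frequency is ``sum(dosage) / (4 * n)`` over
    non-missing individuals; the MFA is whichever allele has frequency
    <= 0.5 (tie goes to the alternate allele).  Returns the MFA's
    nucleotide (or ``"B"``/``"A"`` when no marker is supplied) and its
    frequency in [0, 0.5].
    """
    col = column.dropna()
    if col.empty:
        raise ValueError(f"all genotypes missing for marker {column.name!r}")
    alt_freq = float(col.sum()) / (PLOIDY * len(col))
    ref_name, alt_name = ("A", "B") if marker is None else (marker.alleles[0], marker.alleles[1])
    if alt_freq <= 0.5:
        return alt_name, alt_freq
    return ref_name, 1.0 - alt_freq


def mfa_dosage(column: pd.Series, marker: SnpMarker | None = None) -> tuple[str, float, pd.Series]:
    """MFA identity, frequency, and per-individual MFA copy counts.

    When the alternate allele is the MFA the copy counts equal the
    stored dosages; otherwise they are ``4 - dosage``.
    """
    allele, freq = minor_allele_frequency(column, marker)
    col = column.dropna()
    alt_freq = float(col.sum()) / (PLOIDY * len(col))
    if alt_freq <= 0.5:
        return allele, freq, column
    return allele, freq, PLOIDY - column


def presence_absence_frequency(column: pd.Series) -> tuple[float, float]:
    """Frequency summaries for a presence/absence-scored marker.

    Without dosage information a copy frequency cannot be computed, so
    two quantities are returned: the carrier fraction (carriers / n)
    and the copy frequency under the assumption that every carrier is
    simplex (carriers / 4n).  The two are not commensurable with the
    dosage-based copy frequency and are both reported.
    """
    col = column.dropna()
    if col.empty:
        raise ValueError(f"all calls missing for marker {column.name!r}")
    carriers = int((col == 1).sum())
    return carriers / len(col), carriers / (PLOIDY * len(col))


def _mfa_carriers(column: pd.Series, mode: str) -> int:
    """Number of genotypes carrying at least one copy of the MFA."""
    col = column.dropna()
    if col.empty:
        return 0
    if mode == "presence_absence":
        present = int((col == 1).sum())
        # carriers of the minority call
        return min(present, len(col) - present)
    alt_freq = float(col.sum()) / (PLOIDY * len(col))
    if alt_freq <= 0.5:
        return int((col >= 1).sum())
    return int((col <= PLOIDY - 1).sum())


def apply_mfa_filter(matrix: DosageMatrix, min_carrier_genotypes: int) -> list[str]:
    """Retain markers whose MFA is carried by enough genotypes.

    Mirrors the study's frequency filters: markers whose minor allele
    was present (in simplex) in fewer than 8 genotypes of the n=208
    discovery population (MFA < 1%), or fewer than 3 genotypes of the
    n=40 validation panel (MFA < 2%), are excluded.  A marker is
    retained iff the number of genotypes carrying >= 1 MFA copy is
    >= ``min_carrier_genotypes``.
    """
    if min_carrier_genotypes < 0:
        raise ValueError("min_carrier_genotypes must be >= 0")
    retained = []
    for mid in matrix.marker_ids:
        col = matrix.column(mid).dropna()
        if col.empty:
            continue
        carriers = _mfa_carriers(matrix.column(mid), matrix.scoring_mode(mid))
        if carriers >= min_carrier_genotypes:
            retained.append(mid)
    return retained
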