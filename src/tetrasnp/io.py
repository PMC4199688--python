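"""File formats for the pipeline.

Plain-text formats throughout: tab-separated genotype and trait
tables with an explicit ``NA`` missing token, comma-separated peak
and clone tables, a Table-layout haplotype matrix TSV, and VCF import
for polyploid GT fields.  Genotype cells may be numeric dosages
(0-4), presence/absence 0/1, or human-friendly class strings (AABB);
mixed conventions within one column are rejected.  Writers emit a
``# modes:`` header comment so that a write/read round trip restores
scoring modes exactly; readers fall back to inference (class strings
imply dosage scoring, a {0,1}-only column is presence/absence) when
the comment is absent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .association import AssociationResult, TraitSpecMeta, TraitTable, DIRECTION_GLYPHS
from .genotyping import PLOIDY, DosageMatrix, GenotypeClass, SnpMarker
from .haplotypes import CloneTable, HaplotypeMatrix
from .ld import LdResult

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_trait_tsv",
    "write_trait_tsv",
    "read_peak_csv",
    "write_peak_csv",
    "read_clone_csv",
    "write_clone_csv",
    "read_haplotype_tsv",
    "write_haplotype_tsv",
    "read_vcf_polyploid",
    "write_association_long",
    "write_association_wide",
    "write_ld_pairs",
    "write_ld_matrix",
    "write_ld_blocks",
    "write_truth_sidecar",
    "read_config",
]

NA_TOKEN = "NA"


@dataclass
class RunConfig:
    """Pipeline configuration; all randomness flows from ``seed``."""

    mode: str = "discovery"
    alpha_report: float = 0.01
    mfa_min_carriers: int | None = None  # defaults to 8 (discovery) / 3 (validation)
    correction: str = "bh"
    ld_q_threshold: float = 0.05
    ld_max_span_bp: int = 700
    seed: int = 0
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in {"discovery", "validation"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        for name, v in {"alpha_report": self.alpha_report, "ld_q_threshold": self.ld_q_threshold}.items():
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


def read_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


# ---------------------------------------------------------------------------
# genotype TSV

def _parse_genotype_column(name: str, raw: pd.Series) -> tuple[pd.Series, str]:
    """Convert one raw string column to numeric codes + scoring mode."""
    vals = raw.astype("string")
    present = vals.dropna()
    is_alpha = present.str.fullmatch(r"[A-Ca-c]{4}")
    is_num = present.str.fullmatch(r"\d+")
    if is_alpha.any() and is_num.any():
        raise ValueError(f"column {name!r} mixes class strings and numeric codes")
    if is_alpha.all() and len(present):
        labels = present.str.upper()
        if labels.str.contains("C").any():
            # triallelic: numeric code is the rank of the canonical class
            # label among the classes observed in the population (0..N-1)
            classes = sorted({"".join(sorted(lab)) for lab in labels})
            code = {c: i for i, c in enumerate(classes)}
            numeric = labels.map(lambda lab: code["".join(sorted(lab))]).astype(float)
        else:
            numeric = labels.map(lambda lab: GenotypeClass.from_label(lab).alt_dosage).astype(float)
        return numeric.reindex(raw.index).astype(float), "dosage"
    if not is_num.all():
        bad = present[~is_num].iloc[0]
        raise ValueError(f"column {name!r}: cannot parse cell {bad!r}")
    numeric = present.astype(float)
    if len(numeric) and numeric.max() > PLOIDY:
        raise ValueError(f"column {name!r}: dosage {int(numeric.max())} exceeds ploidy {PLOIDY}")
    mode = "presence_absence" if len(numeric) and set(numeric.unique()) <= {0.0, 1.0} else "dosage"
    return numeric.reindex(raw.index).astype(float), mode


def read_genotype_tsv(path, modes: Mapping[str, str] | None = None) -> DosageMatrix:
    """Read a genotype TSV (individuals x markers) into a DosageMatrix.

    First column: individual ids; header: marker ids; cells: dosages
    0-4, presence/absence 0/1, class strings (AABB, AABC), or ``NA``.
    An optional leading ``# modes: marker=mode,...`` comment (written
    by :func:`write_genotype_tsv`) pins scoring modes; ``modes``
    overrides both the comment and inference.
    """
    path = Path(path)
    header_modes: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# modes:"):
            for item in first[len("# modes:"):].strip().split(","):
                if item:
                    mid, _, mval = item.partition("=")
                    header_modes[mid.strip()] = mval.strip()
            raw = pd.read_csv(fh, sep="\t", index_col=0, dtype=str, na_values=[NA_TOKEN], keep_default_na=False)
        else:
            raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, na_values=[NA_TOKEN], keep_default_na=False)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate individual id {dup!r}")
    if raw.columns.has_duplicates:
        dup = raw.columns[raw.columns.duplicated()][0]
        raise ValueError(f"duplicate marker id {dup!r}")
    values = {}
    inferred: dict[str, str] = {}
    for col in raw.columns:
        numeric, mode = _parse_genotype_column(col, raw[col])
        values[col] = numeric
        inferred[col] = mode
    inferred.update(header_modes)
    if modes:
        inferred.update(modes)
    markers = {}
    for col in raw.columns:
        try:
            markers[col] = SnpMarker.from_id(col, scoring_mode=inferred[col])
        except ValueError:
            pass  # opaque marker ids are allowed
    return DosageMatrix(pd.DataFrame(values, index=raw.index), markers=markers, modes=inferred)


def write_genotype_tsv(matrix: DosageMatrix, path) -> None:
    with open(path, "w") as fh:
        mode_items = ",".join(f"{m}={matrix.scoring_mode(m)}" for m in matrix.marker_ids)
        fh.write(f"# modes: {mode_items}\n")
        out = matrix.values.map(lambda v: NA_TOKEN if pd.isna(v) else str(int(v)))
        out.index.name = "individual"
        out.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# trait TSV

def read_trait_tsv(path) -> TraitTable:
    """Read a trait TSV; ``# trait`` comments carry column metadata."""
    path = Path(path)
    metadata: dict[str, TraitSpecMeta] = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            if line.startswith("# trait "):
                parts = line[len("# trait "):].strip().split("\t")
                name = parts[0]
                kv = dict(p.split("=", 1) for p in parts[1:] if "=" in p)
                metadata[name] = TraitSpecMeta(
                    scale=kv.get("scale", "continuous"),
                    units=kv.get("units", ""),
                    transform=kv.get("transform", "none"),
                )
    values = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip,
                         na_values=[NA_TOKEN], keep_default_na=False)
    return TraitTable(values, metadata=metadata)


def write_trait_tsv(traits: TraitTable, path) -> None:
    with open(path, "w") as fh:
        for name in traits.trait_names:
            meta = traits.metadata[name]
            fh.write(f"# trait {name}\tscale={meta.scale}\tunits={meta.units}\ttransform={meta.transform}\n")
        out = traits.values.copy()
        out.index.name = "individual"
        out.to_csv(fh, sep="\t", na_rep=NA_TOKEN)


# ---------------------------------------------------------------------------
# peak CSV

def read_peak_csv(path) -> pd.DataFrame:
    """Long-format peak heights: individual, marker, height_allele1..3."""
    df = pd.read_csv(path)
    required = {"individual", "marker", "height_allele1", "height_allele2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peak CSV lacks columns {sorted(missing)}")
    return df


def write_peak_csv(peaks: pd.DataFrame, path) -> None:
    peaks.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# clone CSV

def read_clone_csv(path) -> CloneTable:
    df = pd.read_csv(path, index_col=0, dtype={"batch": str})
    df.columns = [c if c in ("cultivar", "tissue", "batch") else int(c) for c in df.columns]
    return CloneTable(df)


def write_clone_csv(clones: CloneTable, path) -> None:
    clones.frame.to_csv(path)


# ---------------------------------------------------------------------------
# haplotype matrix TSV

def read_haplotype_tsv(path) -> HaplotypeMatrix:
    """Positions as rows, variants as columns; an optional
    ``amino_acid_change`` column carries substitution labels (``-``
    marks synonymous sites)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    annotations = {}
    if "amino_acid_change" in df.columns:
        for pos, label in df["amino_acid_change"].items():
            if isinstance(label, str) and label not in ("-", ""):
                annotations[int(pos)] = label
        df = df.drop(columns=["amino_acid_change"])
    df.index = [int(p) for p in df.index]
    return HaplotypeMatrix(df, annotations=annotations)


def write_haplotype_tsv(matrix: HaplotypeMatrix, path) -> None:
    out = matrix.values.copy()
    out.insert(0, "amino_acid_change", [matrix.annotations.get(p, "-") for p in matrix.positions])
    out.index.name = "position"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# VCF import

def read_vcf_polyploid(path) -> DosageMatrix:
    """Import tetraploid genotypes from a VCF.

    Biallelic records map GT to the ALT-allele count (0/0/0/1 -> 1);
    records with two ALT alleles become triallelic markers coded by
    the rank of the canonical genotype-class label among the classes
    observed (0..N-1).  Genotypes of ploidy other than 4 are set to
    missing with a warning.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        columns: dict[str, pd.Series] = {}
        markers: dict[str, SnpMarker] = {}
        for rec in vcf:
            alts = rec.alts or ()
            if not 1 <= len(alts) <= 2:
                logger.warning("skipping record %s:%s with %d ALT alleles", rec.chrom, rec.pos, len(alts))
                continue
            alleles = (rec.ref, *alts)
            marker = SnpMarker(locus=rec.chrom, position=rec.pos, alleles=alleles,
                               coordinate_system="genomic_dm")
            labels: list[str | None] = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    labels.append(None)
                    continue
                if len(gt) != PLOIDY:
                    warnings.warn(
                        f"{marker.id}: sample {s} has ploidy {len(gt)}, expected {PLOIDY}; set to missing",
                        stacklevel=2,
                    )
                    labels.append(None)
                    continue
                counts = [gt.count(i) for i in range(len(alleles))]
                labels.append("".join("ABC"[i] * c for i, c in enumerate(counts)))
            if len(alleles) == 2:
                vals = [None if lab is None else float(lab.count("B")) for lab in labels]
            else:
                observed = sorted({lab for lab in labels if lab is not None})
                code = {lab: float(i) for i, lab in enumerate(observed)}
                vals = [None if lab is None else code[lab] for lab in labels]
            columns[marker.id] = pd.Series(vals, index=samples, dtype=float)
            markers[marker.id] = marker
    if not columns:
        raise ValueError(f"no usable records in {path}")
    return DosageMatrix(pd.DataFrame(columns), markers=markers)


# ---------------------------------------------------------------------------
# result writers

def write_association_long(results: Sequence[AssociationResult], path) -> None:
    pd.DataFrame([r.__dict__ for r in results]).to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


def write_association_wide(results: Sequence[AssociationResult], path) -> None:
    """Table-2/5-shaped report: one row per marker, one percent-variance
    + tier + direction-glyph cell per trait."""
    rows: dict[str, dict] = {}
    traits: list[str] = []
    for r in results:
        row = rows.setdefault(r.marker_id, {
            "marker": r.marker_id,
            "mfa_allele": r.mfa_allele,
            "mfa_frequency_percent": round(r.mfa_frequency_percent, 1),
        })
        if r.trait not in traits:
            traits.append(r.trait)
        if not r.testable:
            cell = "nt"
        elif r.tier == "ns":
            cell = "ns"
        else:
            cell = f"{r.percent_variance:.1f}{r.tier} {DIRECTION_GLYPHS[r.direction]}"
        row[r.trait] = cell
    frame = pd.DataFrame(rows.values(), columns=["marker", "mfa_allele", "mfa_frequency_percent", *traits])
    frame.to_csv(path, sep="\t", index=False)


def write_ld_pairs(results: Sequence[LdResult], path) -> None:
    pd.DataFrame([r.__dict__ for r in results]).to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


def write_ld_matrix(results: Sequence[LdResult], path) -> None:
    """Square marker x marker matrix of q-values."""
    ids = sorted({r.marker_i for r in results} | {r.marker_j for r in results})
    mat = pd.DataFrame(np.nan, index=ids, columns=ids)
    for r in results:
        if r.q_value is not None:
            mat.loc[r.marker_i, r.marker_j] = r.q_value
            mat.loc[r.marker_j, r.marker_i] = r.q_value
    mat.index.name = "marker"
    mat.to_csv(path, sep="\t", na_rep=NA_TOKEN)


def write_ld_blocks(blocks: Sequence[tuple[str, list[str]]], path) -> None:
    with open(path, "w") as fh:
        fh.write("representative\tn_markers\tmembers\n")
        for rep, members in blocks:
            fh.write(f"{rep}\t{len(members)}\t{','.join(members)}\n")


def write_truth_sidecar(truth: Mapping, path) -> None:
    """Flat key=value sidecar recording simulation ground truth."""
    with open(path, "w") as fh:
        def emit(prefix: str, obj) -> None:
            if isinstance(obj, Mapping):
                for k, v in obj.items():
                    emit(f"{prefix}.{k}" if prefix else str(k), v)
            elif isinstance(obj, (list, tuple, np.ndarray)):
                fh.write(f"{prefix}={','.join(str(x) for x in obj)}\n")
            else:
                fh.write(f"{prefix}={obj}\n")
        emit("", truth)
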