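"""Read/write genotype panels (PLINK text, VCF) and quality-control filtering.

The PLINK text dialect understood here is the classic PED/MAP pair: MAP has
four whitespace-separated columns (chromosome, SNP id, genetic position in
cM, physical position in bp); PED has six leading columns (family id,
individual id, father, mother, sex, phenotype) followed by two allele
characters per variant, with ``0`` marking a missing allele.  The family-id
column carries the breed code.

Quality control mirrors routine SNP-chip filtering: drop non-autosomal
variants, then variants with a missing-call rate of 10% or more, then
variants whose pooled minor-allele frequency is 5% or less (both boundaries
strict: a variant exactly at a threshold is removed).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel, SampleRecord, VariantRecord, genotype_counts

logger = logging.getLogger(__name__)

#: Allele characters accepted in PED files.
VALID_PED_ALLELES = frozenset("ACGT012")

#: Default autosome labels (chicken: autosomes 1..28; Z/W are excluded).
CHICKEN_AUTOSOMES = frozenset(str(i) for i in range(1, 29))


class FormatError(ValueError):
    """Malformed input file."""


# ----------------------------------------------------------------------
# breed table
# ----------------------------------------------------------------------

def read_breed_table(path: str | Path) -> dict[str, SampleRecord]:
    """Read a sample -> breed assignment TSV.

    Columns: ``sample_id``, ``breed_code`` and optionally ``fao_class`` and
    ``origin``.  A header row is detected by the literal ``sample_id`` in
    the first field; ``NA``/empty mark unknown class/origin.
    """
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            rows.append(line.split("\t"))
    if rows and rows[0][0].strip().lower() == "sample_id":
        rows = rows[1:]
    out: dict[str, SampleRecord] = {}
    for r in rows:
        if len(r) < 2:
            raise FormatError(f"breed table row needs >= 2 columns: {r!r}")
        sid, breed = r[0].strip(), r[1].strip()
        fao = r[2].strip().lower() if len(r) > 2 and r[2].strip() else None
        origin = r[3].strip().lower() if len(r) > 3 and r[3].strip() else None
        if fao in (None, "na", "n/a"):
            fao = None
        if origin in (None, "na", "n/a"):
            origin = None
        out[sid] = SampleRecord(sid, breed, fao, origin)
    return out


# ----------------------------------------------------------------------
# PLINK text
# ----------------------------------------------------------------------

def read_plink(
    ped_path: str | Path,
    map_path: str | Path,
    breed_table: Mapping[str, SampleRecord] | str | Path | None = None,
) -> GenotypePanel:
    """Read a PED/MAP pair into a :class:`GenotypePanel`.

    The coding reference ``allele_a`` of each variant is the first
    non-missing allele observed in file order; the second distinct allele
    becomes ``allele_b``.  For a variant with only one observed allele,
    ``allele_b`` is recorded as ``"0"`` (placeholder).  The PED family-id
    column is used as the breed code; an optional ``breed_table`` attaches
    FAO class and origin metadata by sample id.
    """
    if isinstance(breed_table, (str, Path)):
        breed_table = read_breed_table(breed_table)

    map_rows: list[tuple[str, str, int]] = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{map_path}:{ln}: MAP line must have 4 columns")
            chrom, snp_id, _cm, bp = parts
            map_rows.append((chrom, snp_id, int(bp)))
    n_var = len(map_rows)

    sample_meta: list[tuple[str, str]] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_var:
                raise FormatError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_var} fields "
                    f"(6 + 2 x {n_var} variants), got {len(parts)}"
                )
            fam, iid = parts[0], parts[1]
            alleles = parts[6:]
            for a in alleles:
                if a not in VALID_PED_ALLELES:
                    raise FormatError(
                        f"{ped_path}:{ln}: allele character {a!r} outside "
                        f"{{A,C,G,T,0,1,2}}"
                    )
            sample_meta.append((fam, iid))
            allele_rows.append(alleles)

    n_samp = len(sample_meta)
    calls = np.full((n_samp, n_var), MISSING, dtype=np.int8)
    allele_a = ["0"] * n_var
    allele_b = ["0"] * n_var
    for j in range(n_var):
        for i in range(n_samp):
            a1 = allele_rows[i][2 * j]
            a2 = allele_rows[i][2 * j + 1]
            if a1 == "0" and a2 == "0":
                continue
            if a1 == "0" or a2 == "0":
                raise FormatError(
                    f"half-missing genotype ({a1} {a2}) for sample "
                    f"{sample_meta[i][1]} at variant {map_rows[j][1]}"
                )
            for a in (a1, a2):
                if allele_a[j] == "0":
                    allele_a[j] = a
                elif a != allele_a[j] and allele_b[j] == "0":
                    allele_b[j] = a
                elif a != allele_a[j] and a != allele_b[j]:
                    raise FormatError(
                        f"variant {map_rows[j][1]} has more than two alleles"
                    )
            calls[i, j] = (a1 != allele_a[j]) + (a2 != allele_a[j])

    variants = []
    for j, (chrom, snp_id, bp) in enumerate(map_rows):
        b = allele_b[j]
        if allele_a[j] == "0":
            # all calls missing at this variant: keep placeholder alleles
            allele_a[j], b = "A", "0"
        variants.append(VariantRecord(snp_id, chrom, bp, allele_a[j], b))

    samples = []
    for fam, iid in sample_meta:
        meta = breed_table.get(iid) if breed_table else None
        samples.append(
            SampleRecord(
                iid,
                fam,
                meta.fao_class if meta else None,
                meta.origin if meta else None,
            )
        )
    return GenotypePanel(samples, variants, calls)


def reader_oriented(panel: GenotypePanel) -> GenotypePanel:
    """Re-orient allele coding to the :func:`read_plink` convention.

    Flips every variant whose first non-missing call is homozygous for
    ``allele_b``, so that ``allele_a`` is the first allele a reader would
    observe in file order.  On the result, ``read_plink(write_plink(...))``
    is an exact identity.
    """
    to_flip = []
    for j in range(panel.n_variants):
        col = panel.calls[:, j]
        called = col[col != MISSING]
        if called.size and called[0] == 2:
            to_flip.append(j)
    return panel.flipped(to_flip) if to_flip else panel


def write_plink(panel: GenotypePanel, ped_path: str | Path, map_path: str | Path) -> None:
    """Write a panel as a PED/MAP pair re-readable by :func:`read_plink`.

    Round trip note: :func:`read_plink` orients ``allele_a`` as the first
    non-missing allele in file order, so a written panel reads back with an
    identical call matrix whenever the panel itself satisfies that
    convention (always true for panels produced by :func:`read_plink`);
    otherwise it reads back with some variants coding-flipped, which leaves
    every statistic unchanged.
    """
    if panel.n_samples == 0 or panel.n_variants == 0:
        raise ValueError("refusing to write an empty panel")
    with open(map_path, "w") as fh:
        for v in panel.variants:
            fh.write(f"{v.chromosome}\t{v.snp_id}\t0\t{v.position_bp}\n")
    with open(ped_path, "w") as fh:
        for i, s in enumerate(panel.samples):
            fields = [s.breed_code, s.sample_id, "0", "0", "0", "-9"]
            for j, v in enumerate(panel.variants):
                g = panel.calls[i, j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [v.allele_a, v.allele_a]
                elif g == 1:
                    fields += [v.allele_a, v.allele_b]
                else:
                    fields += [v.allele_b, v.allele_b]
            fh.write(" ".join(fields) + "\n")


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------

@dataclass
class VcfReadStats:
    """Records skipped while reading a VCF."""

    n_multiallelic: int = 0
    n_non_snp: int = 0


def read_vcf_with_stats(
    vcf_path: str | Path,
    breed_table: Mapping[str, SampleRecord] | str | Path,
) -> tuple[GenotypePanel, VcfReadStats]:
    """Read a VCF (GT field) plus a breed table; also return skip counters.

    REF maps to ``allele_a`` and ALT to ``allele_b``.  Multi-allelic records
    and non-SNP records (REF/ALT longer than one base) are skipped and
    counted.  Every VCF sample must appear in the breed table.
    """
    from cyvcf2 import VCF  # deferred: needs htslib at import time

    if isinstance(breed_table, (str, Path)):
        breed_table = read_breed_table(breed_table)

    vcf = VCF(str(vcf_path), gts012=False)
    vcf_samples = list(vcf.samples)
    unknown = [s for s in vcf_samples if s not in breed_table]
    if unknown:
        raise ValueError(
            f"samples present in VCF but absent from breed table: {', '.join(unknown)}"
        )

    stats = VcfReadStats()
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    # cyvcf2 gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
    code_map = {0: 0, 1: 1, 2: MISSING, 3: 2}
    for rec in vcf:
        if len(rec.ALT) != 1:
            stats.n_multiallelic += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            stats.n_non_snp += 1
            continue
        snp_id = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}"
        variants.append(VariantRecord(snp_id, rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        columns.append(np.array([code_map[g] for g in rec.gt_types], dtype=np.int8))
    vcf.close()

    if stats.n_multiallelic or stats.n_non_snp:
        logger.info(
            "read_vcf: skipped %d multi-allelic and %d non-SNP records",
            stats.n_multiallelic,
            stats.n_non_snp,
        )
    calls = (
        np.column_stack(columns)
        if columns
        else np.empty((len(vcf_samples), 0), dtype=np.int8)
    )
    samples = [breed_table[s] for s in vcf_samples]
    return GenotypePanel(samples, variants, calls), stats


def read_vcf(
    vcf_path: str | Path,
    breed_table: Mapping[str, SampleRecord] | str | Path,
) -> GenotypePanel:
    """Read a VCF into a panel (see :func:`read_vcf_with_stats`)."""
    panel, _ = read_vcf_with_stats(vcf_path, breed_table)
    return panel


# ----------------------------------------------------------------------
# quality control
# ----------------------------------------------------------------------

@dataclass
class QCReport:
    """Per-filter variant counts; each removed variant is counted once, at
    the first rule it fails (autosome -> missingness -> MAF)."""

    n_input_variants: int
    n_removed_nonautosomal: int
    n_removed_missingness: int
    n_removed_maf: int
    n_retained: int
    max_missing_rate: float
    min_maf: float
    autosome_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        removed = (
            self.n_removed_nonautosomal + self.n_removed_missingness + self.n_removed_maf
        )
        if self.n_retained != self.n_input_variants - removed:
            raise ValueError("QCReport counts are not conserved")

    def to_dict(self) -> dict:
        return asdict(self)


def apply_qc(
    panel: GenotypePanel,
    max_missing_rate: float = 0.10,
    min_maf: float = 0.05,
    autosome_labels: frozenset[str] | set[str] | None = None,
) -> tuple[GenotypePanel, QCReport]:
    """Filter variants: autosomes only, missing rate < ``max_missing_rate``,
    pooled MAF > ``min_maf`` (strict boundaries on both thresholds).

    MAF is computed on the pooled panel (all breeds together).  Raises if no
    variant survives.
    """
    if not (0 <= max_missing_rate <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    autosomes = CHICKEN_AUTOSOMES if autosome_labels is None else frozenset(autosome_labels)

    chrom = np.array([v.chromosome for v in panel.variants])
    is_autosomal = np.isin(chrom, list(autosomes))

    n_aa, n_ab, n_bb, n_missing = genotype_counts(panel.calls)
    n_called = n_aa + n_ab + n_bb
    with np.errstate(invalid="ignore", divide="ignore"):
        miss_rate = np.where(
            panel.n_samples > 0, n_missing / max(panel.n_samples, 1), 1.0
        )
        p = np.where(n_called > 0, (2 * n_bb + n_ab) / np.maximum(2 * n_called, 1), np.nan)
    maf = np.fmin(p, 1 - p)

    fail_auto = ~is_autosomal
    fail_miss = is_autosomal & (miss_rate >= max_missing_rate)
    keep_so_far = is_autosomal & ~fail_miss
    fail_maf = keep_so_far & ~(maf > min_maf)  # NaN MAF (no calls) also fails
    keep = keep_so_far & ~fail_maf

    report = QCReport(
        n_input_variants=panel.n_variants,
        n_removed_nonautosomal=int(fail_auto.sum()),
        n_removed_missingness=int(fail_miss.sum()),
        n_removed_maf=int(fail_maf.sum()),
        n_retained=int(keep.sum()),
        max_missing_rate=max_missing_rate,
        min_maf=min_maf,
        autosome_labels=sorted(autosomes),
    )
    if report.n_retained == 0:
        raise ValueError(
            "quality control removed every variant; review the thresholds "
            f"(max_missing_rate={max_missing_rate}, min_maf={min_maf}) and the "
            "autosome label set"
        )
    return panel.subset(variant_idx=np.flatnonzero(keep)), report
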