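"""Readers and writers for the on-disk formats the pipeline consumes.

Allelic counts and results travel as TSV, genotypes as VCF 4.x (via
pysam), TADs as BED3+.  All readers transparently accept
gzip-compressed files.
"""

from __future__ import annotations

import gzip
import io as _io
import math
from typing import IO, Iterable, Optional, Union

import numpy as np
import pandas as pd
import pysam

from .errors import FormatError, ValidationError
from .types import MISSING, AllelicCountRecord, GenotypeMatrix, TADSet, VariantInfo

PathLike = Union[str, "os.PathLike[str]"]

COUNT_COLUMNS = ["sample_id", "variant_id", "chrom", "pos", "ref_count", "alt_count"]
RESULT_COLUMNS = ["variant_id", "n_samples", "Z", "p_perm", "p_tail", "direction", "q_value"]


def _open_text(path: PathLike, mode: str = "rt") -> IO[str]:
    """Open a possibly gzip-compressed text file."""
    path = str(path)
    if "r" in mode:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(path, mode)
    elif path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# allelic count tables


def read_allelic_counts(path: PathLike) -> list[AllelicCountRecord]:
    """Read a per-(sample, variant) allele-specific read-count table.

    The file must carry a header with the columns
    ``sample_id variant_id chrom pos ref_count alt_count`` (extra
    columns are ignored).  Counts must be non-negative integers; the
    first offending row is reported by its 1-based data-row number.
    """
    with _open_text(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path}: empty file, expected a header line")
        header = header_line.rstrip("\n").split("\t")
        for col in COUNT_COLUMNS:
            if col not in header:
                raise FormatError(f"{path}: missing required column {col!r}")
        idx = {col: header.index(col) for col in COUNT_COLUMNS}
        records: list[AllelicCountRecord] = []
        seen: set[tuple[str, str]] = set()
        for rowno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < len(header):
                raise FormatError(f"{path}: row {rowno}: expected {len(header)} fields")
            try:
                pos = int(fields[idx["pos"]])
                ref_count = int(fields[idx["ref_count"]])
                alt_count = int(fields[idx["alt_count"]])
            except ValueError as exc:
                raise ValidationError(f"{path}: row {rowno}: non-integer value ({exc})") from None
            if ref_count < 0 or alt_count < 0:
                raise ValidationError(f"{path}: row {rowno}: negative read count")
            key = (fields[idx["sample_id"]], fields[idx["variant_id"]])
            if key in seen:
                raise ValidationError(
                    f"{path}: row {rowno}: duplicate (sample_id, variant_id) pair {key}"
                )
            seen.add(key)
            records.append(
                AllelicCountRecord(
                    sample_id=fields[idx["sample_id"]],
                    variant_id=fields[idx["variant_id"]],
                    chrom=fields[idx["chrom"]],
                    pos=pos,
                    ref_count=ref_count,
                    alt_count=alt_count,
                )
            )
    return records


def write_allelic_counts(records: Iterable[AllelicCountRecord], path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(COUNT_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.sample_id}\t{r.variant_id}\t{r.chrom}\t{r.pos}\t{r.ref_count}\t{r.alt_count}\n"
            )


# ---------------------------------------------------------------------------
# genotypes (VCF)


def _parse_region(region: str) -> tuple[str, int, int]:
    chrom, _, span = region.partition(":")
    if span:
        start, _, end = span.partition("-")
        return chrom, int(start), int(end)
    return chrom, 1, 2**62


def read_genotypes_vcf(
    path: PathLike,
    region: Optional[str] = None,
    multiallelic: str = "error",
) -> tuple[GenotypeMatrix, list[VariantInfo]]:
    """Read sample genotypes from a VCF into a dosage matrix.

    ``0/1``, ``1/0`` and ``0|1`` all map to dosage 1; ``./.`` maps to
    :data:`~casekit.types.MISSING`.  The matrix is flagged phased only
    when every genotype in the file uses the ``|`` separator.
    Multi-allelic sites are rejected unless ``multiallelic="split"``,
    which emits one biallelic pseudo-variant per alternative allele.

    ``region`` (``chrom`` or ``chrom:start-end``, 1-based inclusive)
    restricts the variants returned; a region containing no variants
    yields an empty matrix.
    """
    if multiallelic not in ("error", "split"):
        raise ValueError("multiallelic must be 'error' or 'split'")
    want = _parse_region(region) if region else None
    with pysam.VariantFile(str(path)) as vcf:
        if "GT" not in vcf.header.formats:
            raise FormatError(f"{path}: VCF has no GT FORMAT field")
        sample_ids = list(vcf.header.samples)
        variants: list[VariantInfo] = []
        columns: list[np.ndarray] = []
        hap_cols: list[np.ndarray] = []
        phased = True
        for rec in vcf:
            if want is not None:
                chrom, start, end = want
                if rec.chrom != chrom or not (start <= rec.pos <= end):
                    continue
            alts = rec.alts or ()
            if len(alts) == 0:
                continue
            if len(alts) > 1 and multiallelic == "error":
                raise FormatError(
                    f"{path}: multi-allelic site {rec.chrom}:{rec.pos} "
                    "(pass multiallelic='split' to decompose)"
                )
            base_id = rec.id or f"{rec.chrom}:{rec.pos}"
            for ai, alt in enumerate(alts, start=1):
                vid = base_id if len(alts) == 1 else f"{base_id}_alt{ai}"
                dos = np.full(len(sample_ids), MISSING, dtype=np.int8)
                haps = np.full((len(sample_ids), 2), MISSING, dtype=np.int8)
                for si, sample in enumerate(rec.samples.values()):
                    gt = sample["GT"]
                    if not sample.phased:
                        phased = False
                    if gt is None or any(a is None for a in gt) or len(gt) != 2:
                        continue
                    alleles = [1 if a == ai else 0 for a in gt]
                    dos[si] = sum(alleles)
                    haps[si] = alleles
                variants.append(VariantInfo(vid, rec.chrom, rec.pos, rec.ref, alt))
                columns.append(dos)
                hap_cols.append(haps)
    if not variants:
        gm = GenotypeMatrix(sample_ids, [], np.zeros((len(sample_ids), 0), dtype=np.int8))
        return gm, []
    dosage = np.stack(columns, axis=1)
    haplotypes = np.stack(hap_cols, axis=2) if phased else None
    gm = GenotypeMatrix(
        sample_ids,
        [v.variant_id for v in variants],
        dosage,
        phased=phased,
        haplotypes=haplotypes,
    )
    return gm, variants


def write_genotypes_vcf(
    genotypes: GenotypeMatrix, variants: list[VariantInfo], path: PathLike
) -> None:
    """Write a dosage/haplotype matrix as a minimal VCF 4.2 file."""
    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"), ("Description", "Genotype")])
    for chrom in dict.fromkeys(v.chrom for v in variants):
        header.contigs.add(chrom)
    for s in genotypes.sample_ids:
        header.add_sample(s)
    phased = genotypes.phased and genotypes.haplotypes is not None
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, v in enumerate(variants):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos, alleles=(v.ref, v.alt), id=v.variant_id
            )
            for i in range(genotypes.n_samples):
                d = int(genotypes.dosage[i, j])
                if d == MISSING:
                    gt = (None, None)
                elif phased:
                    gt = tuple(int(a) for a in genotypes.haplotypes[i, :, j])
                else:
                    gt = (0, 0) if d == 0 else ((0, 1) if d == 1 else (1, 1))
                sample = rec.samples[genotypes.sample_ids[i]]
                sample["GT"] = gt
                sample.phased = phased
            out.write(rec)


# ---------------------------------------------------------------------------
# TAD intervals (BED)


def read_tads_bed(path: PathLike) -> TADSet:
    """Read TAD intervals from a BED3+ file (0-based, half-open)."""
    intervals: list[tuple[str, int, int]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: BED needs >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates") from None
            if start >= end:
                raise ValidationError(f"{path}: line {lineno}: start >= end ({start} >= {end})")
            intervals.append((fields[0], start, end))
    return TADSet(intervals)


def write_tads_bed(tads: TADSet, path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        for chrom, start, end in tads.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# reporter results


def write_reporter_results(results: Iterable["ReporterResult"], path: PathLike) -> None:
    """Write per-reporter cASE results as TSV.

    Z is printed to 2 decimals with its sign preserved; p-values and q
    in scientific notation.  An empty result list yields a header-only
    file.
    """
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results:
            z = "NA" if r.Z is None or math.isnan(r.Z) else f"{r.Z:.2f}"
            fh.write(
                f"{r.variant_id}\t{r.n_samples}\t{z}\t{r.p_perm:.6e}\t"
                f"{r.p_tail:.6e}\t{r.direction}\t{r.q_value:.6e}\n"
            )


def read_reporter_results(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing result columns {missing}")
    return df
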