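"""Core domain containers.

Coordinate conventions used throughout the package:

* variant positions are 1-based (VCF convention);
* TAD intervals are 0-based half-open (BED convention);
* a variant at position ``p`` lies inside a BED interval ``(s, e)``
  iff ``s < p <= e``.  The conversion is done explicitly in
  :meth:`TADSet.tads_containing` and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from intervaltree import IntervalTree

#: Dosage code for a missing genotype call (``./.`` in VCF).
MISSING: int = -1


@dataclass(frozen=True)
class AllelicCountRecord:
    """One heterozygous-reporter observation in one RNA-seq sample."""

    sample_id: str
    variant_id: str
    chrom: str
    pos: int  # 1-based
    ref_count: int
    alt_count: int

    @property
    def coverage(self) -> int:
        return self.ref_count + self.alt_count


@dataclass(frozen=True)
class VariantInfo:
    """Minimal variant description (1-based position, ref/alt alleles)."""

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix, optionally with phased haplotypes.

    ``dosage[i, j]`` is 0 (hom-ref), 1 (het), 2 (hom-alt) or
    :data:`MISSING` for sample ``i`` at variant ``j``.  When ``phased``,
    ``haplotypes[i, k, j]`` holds allele 0/1 carried by haplotype
    ``k in {0, 1}`` and the dosage equals the haplotype sum.
    """

    sample_ids: list[str]
    variant_ids: list[str]
    dosage: np.ndarray  # (n_samples, n_variants) int8
    phased: bool = False
    haplotypes: Optional[np.ndarray] = None  # (n_samples, 2, n_variants)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError("dosage shape inconsistent with id lists")
        if self.phased and self.haplotypes is not None:
            hap_sum = self.haplotypes.sum(axis=1)
            ok = self.dosage == MISSING
            if not np.array_equal(np.where(ok, hap_sum, self.dosage), hap_sum):
                raise ValueError("dosage does not equal haplotype sum")
        self._vidx = {v: j for j, v in enumerate(self.variant_ids)}
        self._sidx = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def variant_index(self, variant_id: str) -> int:
        try:
            return self._vidx[variant_id]
        except KeyError:
            raise LookupError(f"variant {variant_id!r} not in genotype matrix") from None

    def dosage_of(self, variant_id: str) -> np.ndarray:
        """Dosage vector across samples for one variant."""
        return self.dosage[:, self.variant_index(variant_id)]

    def dosage_for(self, sample_id: str, variant_id: str) -> int:
        return int(self.dosage[self._sidx[sample_id], self.variant_index(variant_id)])

    def has_sample(self, sample_id: str) -> bool:
        return sample_id in self._sidx


@dataclass
class TADSet:
    """Topologically associating domains as 0-based half-open intervals."""

    intervals: list[tuple[str, int, int]]
    _trees: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"empty TAD interval {chrom}:{start}-{end}")
        self.intervals = sorted(self.intervals)
        self._trees = {}
        for chrom, start, end in self.intervals:
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end)

    def tads_containing(self, chrom: str, pos: int) -> list[tuple[str, int, int]]:
        """TADs containing a 1-based variant position.

        A variant at 1-based ``pos`` occupies 0-based coordinate
        ``pos - 1``, hence membership is ``start <= pos - 1 < end``,
        i.e. ``start < pos <= end``.
        """
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((chrom, iv.begin, iv.end) for iv in tree.at(pos - 1))

    def __len__(self) -> int:
        return len(self.intervals)
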