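"""Candidate-regulatory-variant assessment within TADs.

Every variant sharing a topologically associating domain with a
significant reporter is a potential mediator of its allelic imbalance.
Samples heterozygous at the reporter are split by their genotype at
the candidate: heterozygous carriers (who can transmit a cis effect)
versus homozygous ones (who cannot).  A candidate is proposed when the
combined Z of the heterozygous subgroup (C.Z) is strictly stronger
than the all-sample reporter Z (R.Z) while the homozygous subgroup
shows no significant bias — the signature expected if the candidate,
not the reporter itself, drives the imbalance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .case import DEFAULT_ALPHA, DEFAULT_MIN_COV, combine_weighted_z, sample_z_table
from .types import MISSING, AllelicCountRecord, GenotypeMatrix, TADSet, VariantInfo

DEFAULT_MIN_SUBGROUP = 3


@dataclass
class CandidateAssessment:
    """Mediation verdict for one (reporter, candidate) pair."""

    reporter_id: str
    candidate_id: str
    R_Z: float  # reporter Z over all samples
    C_Z: float  # Z over candidate-heterozygous subgroup
    hom_Z: float  # Z over candidate-homozygous subgroup
    hom_p: float  # standard-normal tail p of hom_Z
    n_het: int
    n_hom: int
    is_candidate: bool
    reason: str


@dataclass(frozen=True)
class LDResult:
    """Squared dosage correlation between two variants."""

    variant_a: str
    variant_b: str
    r2: Optional[float]  # None when undefined (monomorphic)
    n_samples: int


def variants_in_tad(
    reporter: VariantInfo, variants: Iterable[VariantInfo], tads: TADSet
) -> list[VariantInfo]:
    """Variants sharing at least one TAD with the reporter (reporter excluded).

    A reporter falling in several overlapping TADs collects the union
    of their residents.  A reporter outside every TAD yields an empty
    list with a warning.
    """
    reporter_tads = tads.tads_containing(reporter.chrom, reporter.pos)
    if not reporter_tads:
        warnings.warn(
            f"reporter {reporter.variant_id} at {reporter.chrom}:{reporter.pos} "
            "falls in no TAD; no candidates assessed",
            stacklevel=2,
        )
        return []
    out = []
    for v in variants:
        if v.variant_id == reporter.variant_id:
            continue
        v_tads = tads.tads_containing(v.chrom, v.pos)
        if any(t in reporter_tads for t in v_tads):
            out.append(v)
    return out


def split_by_candidate_genotype(
    reporter_records: Sequence[AllelicCountRecord],
    genotypes: GenotypeMatrix,
    candidate_id: str,
) -> tuple[list[AllelicCountRecord], list[AllelicCountRecord]]:
    """Partition reporter records by candidate genotype.

    Heterozygous (dosage 1) versus homozygous (dosage 0 or 2, pooled).
    Samples with a missing call at the candidate, or absent from the
    genotype matrix, are dropped from both subgroups.
    """
    j = genotypes.variant_index(candidate_id)  # raises LookupError if absent
    het, hom = [], []
    for r in reporter_records:
        if not genotypes.has_sample(r.sample_id):
            continue
        d = genotypes.dosage_for(r.sample_id, candidate_id)
        if d == MISSING:
            continue
        (het if d == 1 else hom).append(r)
    return het, hom


def assess_candidate(
    reporter_id: str,
    candidate_id: str,
    R_Z: float,
    het_records: Sequence[AllelicCountRecord],
    hom_records: Sequence[AllelicCountRecord],
    alpha: float = DEFAULT_ALPHA,
    min_subgroup: int = DEFAULT_MIN_SUBGROUP,
    min_cov: int = 0,
) -> CandidateAssessment:
    """Apply the C.Z / R.Z decision rule to one candidate.

    ``is_candidate`` requires |C.Z| > |R.Z| strictly, a non-significant
    homozygous subgroup (standard-normal tail p >= alpha; the combined
    Z is unit-variance under the null), and both subgroups of at least
    ``min_subgroup`` samples.  ``reason`` records the first failing
    clause.
    """
    het_samples = sample_z_table(het_records, min_cov=min_cov)
    hom_samples = sample_z_table(hom_records, min_cov=min_cov)
    n_het, n_hom = len(het_samples), len(hom_samples)
    C_Z = combine_weighted_z(het_samples) if het_samples else float("nan")
    hom_Z = combine_weighted_z(hom_samples) if hom_samples else float("nan")
    hom_p = float(2.0 * stats.norm.sf(abs(hom_Z))) if hom_samples else float("nan")

    if n_het == 0:
        ok, reason = False, "no heterozygous carriers"
    elif n_het < min_subgroup:
        ok, reason = False, "heterozygous subgroup below minimum size"
    elif n_hom < min_subgroup:
        ok, reason = False, "homozygous subgroup below minimum size"
    elif not abs(C_Z) > abs(R_Z):
        ok, reason = False, "candidate Z not stronger than reporter Z"
    elif not hom_p >= alpha:
        ok, reason = False, "homozygous subgroup significant"
    else:
        ok, reason = True, "ok"
    return CandidateAssessment(
        reporter_id, candidate_id, R_Z, C_Z, hom_Z, hom_p, n_het, n_hom, ok, reason
    )


def ld_r2(
    geno_a: np.ndarray,
    geno_b: np.ndarray,
    variant_a: str = "a",
    variant_b: str = "b",
) -> LDResult:
    """Composite LD r-squared from unphased dosage vectors.

    Squared Pearson correlation over pairwise-complete samples.  A
    variant monomorphic in the intersection makes r-squared undefined,
    reported as ``None`` (never coerced to 0).
    """
    a = np.asarray(geno_a, dtype=float)
    b = np.asarray(geno_b, dtype=float)
    keep = (np.asarray(geno_a) != MISSING) & (np.asarray(geno_b) != MISSING)
    a, b = a[keep], b[keep]
    n = int(keep.sum())
    if n < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return LDResult(variant_a, variant_b, None, n)
    r = np.corrcoef(a, b)[0, 1]
    return LDResult(variant_a, variant_b, float(r * r), n)


def run_mediation(
    reporter_records: Sequence[AllelicCountRecord],
    R_Z: float,
    reporter: VariantInfo,
    variants: Iterable[VariantInfo],
    genotypes: GenotypeMatrix,
    tads: TADSet,
    alpha: float = DEFAULT_ALPHA,
    min_subgroup: int = DEFAULT_MIN_SUBGROUP,
    min_cov: int = DEFAULT_MIN_COV,
) -> list[tuple[CandidateAssessment, LDResult]]:
    """Assess every TAD-resident candidate of one reporter.

    Returns one (assessment, LD-vs-reporter) pair per candidate, in
    genomic order.  ``min_cov`` must match the filter used when R.Z was
    computed so the subgroup Zs are comparable.
    """
    out = []
    reporter_dos = (
        genotypes.dosage_of(reporter.variant_id)
        if reporter.variant_id in genotypes.variant_ids
        else None
    )
    for cand in variants_in_tad(reporter, variants, tads):
        het, hom = split_by_candidate_genotype(reporter_records, genotypes, cand.variant_id)
        assessment = assess_candidate(
            reporter.variant_id,
            cand.variant_id,
            R_Z,
            het,
            hom,
            alpha=alpha,
            min_subgroup=min_subgroup,
            min_cov=min_cov,
        )
        if reporter_dos is not None:
            ld = ld_r2(
                reporter_dos,
                genotypes.dosage_of(cand.variant_id),
                reporter.variant_id,
                cand.variant_id,
            )
        else:
            ld = LDResult(reporter.variant_id, cand.variant_id, None, 0)
        out.append((assessment, ld))
    return out
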