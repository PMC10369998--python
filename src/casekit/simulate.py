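"""Synthetic genotypes, TADs and allele-specific read counts.

The generator reproduces the statistical structure the cASE analysis
assumes, so every downstream stage is testable without external data:

* diploid genotypes under Hardy-Weinberg equilibrium, built from two
  independent haplotypes per sample;
* linkage disequilibrium by first-order copying within blocks: the
  first variant of a block is Bernoulli(MAF), each subsequent variant
  copies the previous variant's allele with a configurable probability
  (for equal MAFs the copy probability equals the haplotype allele
  correlation r, so a target r-squared is reached directly);
* overdispersed per-sample read depth (gamma-Poisson mixture, i.e.
  negative-binomial with variance mu + d*mu^2, floored at 1 read);
* a causal cis-regulatory variant that skews the reference-allele read
  fraction at the reporter away from 0.5 only on haplotypes carrying
  its risk allele: the fraction is theta when the reporter's reference
  allele is in phase with the risk allele, 1 - theta when anti-phased,
  and exactly 0.5 in samples homozygous at the causal variant.

Only samples heterozygous at the reporter emit a count record, since
only they can reveal which gene copy is more expressed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import yaml

from .types import AllelicCountRecord, GenotypeMatrix, TADSet, VariantInfo


@dataclass(frozen=True)
class SimVariant:
    """One simulated variant: identity, frequency and LD-block placement.

    ``copy_prob`` overrides the config-wide ``ld_copy_prob`` for the
    adjacency between this variant and the previous one in its block,
    which lets a single block mix tightly and loosely linked variants.
    """

    variant_id: str
    chrom: str
    pos: int
    maf: float
    block: int = 0
    copy_prob: Optional[float] = None


@dataclass
class SimConfig:
    """Study conditions for one simulated reporter locus."""

    n_samples: int
    variants: list[SimVariant]
    reporter_variant_id: str
    causal_variant_id: str
    theta: float = 0.5  # ref-allele expression fraction on risk haplotypes
    coverage_mean: float = 50.0
    coverage_dispersion: float = 0.3  # var = mu + d * mu^2
    ld_copy_prob: float = 1.0
    risk_allele: str = "ref"  # which causal allele carries the expression skew
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must lie in (0, 1)")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage parameters must be positive")
        if not 0.0 <= self.ld_copy_prob <= 1.0:
            raise ValueError("ld_copy_prob must lie in [0, 1]")
        if self.risk_allele not in ("ref", "alt"):
            raise ValueError("risk_allele must be 'ref' or 'alt'")
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids")
        for v in self.variants:
            if not 0.0 < v.maf <= 0.5:
                raise ValueError(f"{v.variant_id}: MAF must lie in (0, 0.5]")
        for vid in (self.reporter_variant_id, self.causal_variant_id):
            if vid not in ids:
                raise ValueError(f"variant {vid!r} not among simulated variants")

    @property
    def variant_infos(self) -> list[VariantInfo]:
        # minor allele is the alternative by construction
        return [VariantInfo(v.variant_id, v.chrom, v.pos, "A", "G") for v in self.variants]


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    sample_ids: list[str]
    haplotypes: np.ndarray  # (n_samples, 2, n_variants) alleles 0/1
    ref_fraction: dict[str, float]  # true reporter ref fraction, emitted samples
    causal_variant_id: str


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=[int(seed), stream]))


def simulate_haplotypes(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw phased genotypes for all samples under HWE with block LD.

    Each of the two haplotypes per sample is drawn independently; the
    genotype is their sum, which yields Hardy-Weinberg proportions.
    Deterministic given ``config.seed``.
    """
    rng = _rng(config.seed, 1)
    n, m = config.n_samples, len(config.variants)
    haps = np.zeros((n, 2, m), dtype=np.int8)
    prev_in_block: dict[int, int] = {}
    for j, v in enumerate(config.variants):
        cp = config.ld_copy_prob if v.copy_prob is None else v.copy_prob
        fresh = (rng.random(size=(n, 2)) < v.maf).astype(np.int8)
        if v.block in prev_in_block:
            copy = rng.random(size=(n, 2)) < cp
            haps[:, :, j] = np.where(copy, haps[:, :, prev_in_block[v.block]], fresh)
        else:
            haps[:, :, j] = fresh
        prev_in_block[v.block] = j
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    gm = GenotypeMatrix(
        sample_ids,
        [v.variant_id for v in config.variants],
        haps.sum(axis=1),
        phased=True,
        haplotypes=haps,
    )
    truth = SimTruth(sample_ids, haps, {}, config.causal_variant_id)
    return gm, truth


def true_ref_fraction(config: SimConfig, hap_pair: np.ndarray) -> float:
    """Expected reporter reference-read fraction for one sample.

    ``hap_pair`` is the (2, n_variants) allele matrix of the sample.
    Requires heterozygosity at the reporter.  0.5 when the sample is
    homozygous at the causal variant; otherwise theta or 1 - theta
    depending on whether the reporter's reference allele shares a
    haplotype with the causal risk allele.
    """
    vids = [v.variant_id for v in config.variants]
    jr, jc = vids.index(config.reporter_variant_id), vids.index(config.causal_variant_id)
    if hap_pair[0, jc] == hap_pair[1, jc]:
        return 0.5
    risk = 0 if config.risk_allele == "ref" else 1
    ref_hap = 0 if hap_pair[0, jr] == 0 else 1  # haplotype carrying reporter ref
    return config.theta if hap_pair[ref_hap, jc] == risk else 1.0 - config.theta


def simulate_allelic_counts(
    genotypes: GenotypeMatrix, config: SimConfig
) -> tuple[list[AllelicCountRecord], SimTruth]:
    """Emit one allelic count record per reporter-heterozygous sample.

    Total coverage is gamma-Poisson (mean ``coverage_mean``, variance
    ``mu + d*mu^2``) floored at one read; the reference-read count is
    binomial with the phase-determined success probability.
    Deterministic given ``config.seed``.
    """
    if genotypes.haplotypes is None or not genotypes.phased:
        raise ValueError("phased haplotypes required to simulate allelic counts")
    rng = _rng(config.seed, 2)
    vids = [v.variant_id for v in config.variants]
    jr = vids.index(config.reporter_variant_id)
    reporter = next(v for v in config.variants if v.variant_id == config.reporter_variant_id)
    shape = 1.0 / config.coverage_dispersion
    scale = config.coverage_mean * config.coverage_dispersion

    records: list[AllelicCountRecord] = []
    fractions: dict[str, float] = {}
    for i, sample_id in enumerate(genotypes.sample_ids):
        if genotypes.dosage[i, jr] != 1:
            continue
        p_i = true_ref_fraction(config, genotypes.haplotypes[i])
        cov = max(1, int(rng.poisson(rng.gamma(shape, scale))))
        ref = int(rng.binomial(cov, p_i))
        records.append(
            AllelicCountRecord(sample_id, reporter.variant_id, reporter.chrom, reporter.pos, ref, cov - ref)
        )
        fractions[sample_id] = p_i
    if not records:
        warnings.warn(
            f"no sample heterozygous at reporter {config.reporter_variant_id}", stacklevel=2
        )
    truth = SimTruth(
        list(genotypes.sample_ids), genotypes.haplotypes, fractions, config.causal_variant_id
    )
    return records, truth


def simulate_dataset(config: SimConfig) -> tuple[GenotypeMatrix, list[AllelicCountRecord], SimTruth]:
    """Haplotypes plus allelic counts in one call."""
    gm, _ = simulate_haplotypes(config)
    records, truth = simulate_allelic_counts(gm, config)
    return gm, records, truth


# ---------------------------------------------------------------------------
# packaged scenarios


@dataclass
class Scenario:
    """A simulation config together with the TAD context it lives in."""

    config: SimConfig
    tads: TADSet


def mediation_scenario(seed: int = 1, n_samples: int = 60, theta: float = 0.75) -> Scenario:
    """Default mediation setup: a causal enhancer variant in moderate LD.

    One transcribed reporter, a causal regulatory variant at haplotype
    r ~ 0.7 (r-squared ~ 0.5) with it, and two unlinked variants in the
    same TAD that serve as negative controls for the candidate rule.
    """
    variants = [
        SimVariant("reporter_1", "chr8", 118_185_000, 0.4, block=0),
        SimVariant("causal_enh", "chr8", 118_120_000, 0.4, block=0, copy_prob=0.7),
        SimVariant("unlinked_1", "chr8", 118_300_000, 0.4, block=1),
        SimVariant("unlinked_2", "chr8", 118_420_000, 0.3, block=2),
    ]
    config = SimConfig(
        n_samples=n_samples,
        variants=variants,
        reporter_variant_id="reporter_1",
        causal_variant_id="causal_enh",
        theta=theta,
        coverage_mean=50.0,
        coverage_dispersion=0.3,
        seed=seed,
    )
    tads = TADSet([("chr8", 118_000_000, 118_500_000), ("chr8", 118_500_000, 119_200_000)])
    return Scenario(config, tads)


def tag_ld_scenario(seed: int = 1, n_samples: int = 60, theta: float = 0.7) -> Scenario:
    """Tag-SNP setup mirroring a GWAS locus with one coding tag.

    A transcribed reporter, a coding tag variant in near-perfect LD
    with it (haplotype r ~ 0.98, r-squared ~ 0.96) and two weakly
    linked variants (r-squared ~ 0.05 with the reporter).  The causal
    effect is placed on the reporter itself, so the risk (reference)
    allele is the preferentially transcribed one.
    """
    # chain order chosen so both weak candidates sit at r ~ 0.224 from
    # the reporter while staying essentially unlinked from each other
    variants = [
        SimVariant("cand_weak1", "chr8", 118_050_000, 0.35, block=0),
        SimVariant("reporter_1", "chr8", 118_185_000, 0.35, block=0, copy_prob=0.2236),
        SimVariant("tag_coding", "chr8", 118_184_000, 0.35, block=0, copy_prob=0.9798),
        SimVariant("cand_weak2", "chr8", 118_350_000, 0.35, block=0, copy_prob=0.2282),
    ]
    config = SimConfig(
        n_samples=n_samples,
        variants=variants,
        reporter_variant_id="reporter_1",
        causal_variant_id="reporter_1",
        theta=theta,
        coverage_mean=50.0,
        coverage_dispersion=0.3,
        seed=seed,
    )
    tads = TADSet([("chr8", 118_000_000, 118_500_000)])
    return Scenario(config, tads)


def null_scenario(
    seed: int = 1, n_samples: int = 20, coverage_mean: float = 30.0
) -> Scenario:
    """A no-effect reporter (theta = 0.5) for calibration studies."""
    variants = [SimVariant("reporter_1", "chr8", 118_185_000, 0.5, block=0)]
    config = SimConfig(
        n_samples=n_samples,
        variants=variants,
        reporter_variant_id="reporter_1",
        causal_variant_id="reporter_1",
        theta=0.5,
        coverage_mean=coverage_mean,
        coverage_dispersion=0.3,
        seed=seed,
    )
    return Scenario(config, TADSet([("chr8", 118_000_000, 118_500_000)]))


SCENARIOS = {
    "mediation": mediation_scenario,
    "tag-ld": tag_ld_scenario,
    "null": null_scenario,
}


def scenario_from_yaml(path) -> Scenario:
    """Load a scenario from a YAML file mirroring :class:`SimConfig`.

    Expected keys: the SimConfig fields, with ``variants`` as a list of
    mappings (variant_id, chrom, pos, maf, block, copy_prob) and an
    optional ``tads`` list of (chrom, start, end) triples.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    tads = TADSet([tuple(t) for t in raw.pop("tads", [])])
    variants = [SimVariant(**v) for v in raw.pop("variants")]
    config = SimConfig(variants=variants, **raw)
    return Scenario(config, tads)


def write_scenario(scenario: Scenario, out_dir) -> dict[str, str]:
    """Simulate a scenario and write counts.tsv, geno.vcf, tads.bed, truth.tsv."""
    import os

    from . import io as ckio

    os.makedirs(out_dir, exist_ok=True)
    gm, records, truth = simulate_dataset(scenario.config)
    paths = {
        "counts": os.path.join(out_dir, "counts.tsv"),
        "vcf": os.path.join(out_dir, "geno.vcf"),
        "tads": os.path.join(out_dir, "tads.bed"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    ckio.write_allelic_counts(records, paths["counts"])
    ckio.write_genotypes_vcf(gm, scenario.config.variant_infos, paths["vcf"])
    ckio.write_tads_bed(scenario.tads, paths["tads"])
    with open(paths["truth"], "w") as fh:
        fh.write("sample_id\ttrue_ref_fraction\tcausal_variant_id\n")
        for sid in sorted(truth.ref_fraction):
            fh.write(f"{sid}\t{truth.ref_fraction[sid]:.6f}\t{truth.causal_variant_id}\n")
    return paths
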