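"""The combined allele-specific expression (cASE) statistic.

For every sample heterozygous at a transcribed reporter variant, the
reference/alternative read counts give an exact two-sided binomial
p-value against a balanced (0.5) expectation.  Each p-value is turned
into a signed standard-normal deviate (positive = reference-allele
excess) and the deviates are combined across samples with a weighted
Stouffer rule,

    Z = sum_i(w_i * z_i) / sqrt(sum_i(w_i^2)),    w_i = n_i (read coverage),

which is unit-variance under the null.  Significance is assessed both
against a permutation null (per-sample allele-label flips of the same
read counts) and against a Gaussian fitted to that null, whose
analytic tail resolves p-values below the permutation floor
1/(N_perm + 1).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateNullError, UndefinedResultError
from .types import AllelicCountRecord

#: Cap on |z_i|: the probit of the smallest positive double is ~38.5,
#: so larger deviates are numerically indistinguishable from infinity.
Z_CAP = 38.0

DEFAULT_N_PERM = 1000
DEFAULT_MIN_COV = 10
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class SampleZ:
    """Per-sample allelic-bias evidence entering the combination."""

    sample_id: str
    n_i: int  # total coverage (ref + alt)
    p_i: float  # exact two-sided binomial p vs 0.5
    z_i: float  # signed probit; positive = reference excess
    w_i: float  # Stouffer weight = n_i


@dataclass
class PermutationNull:
    """Combined-Z draws under per-sample allele-label flips."""

    z_values: np.ndarray
    n_perm: int
    seed: int


@dataclass
class ReporterResult:
    """cASE outcome for one reporter variant."""

    variant_id: str
    n_samples: int
    Z: float
    p_perm: float
    p_tail: float
    direction: str  # ref-biased | alt-biased | none
    q_value: float = float("nan")
    low_coverage: bool = False


# ---------------------------------------------------------------------------
# per-sample statistics


def binomial_two_sided_p(ref_count: int, alt_count: int) -> float:
    """Exact two-sided binomial p-value against p=0.5.

    P(|X - n/2| >= |x - n/2|) for X ~ Binomial(n, 0.5).  By symmetry
    this equals 2*P(X <= min(x, n-x)) except at perfect balance, where
    it is 1.
    """
    n = ref_count + alt_count
    if n < 1:
        raise ValueError("zero total coverage")
    k = min(ref_count, alt_count)
    if 2 * k == n:
        return 1.0
    return min(1.0, 2.0 * stats.binom.cdf(k, n, 0.5))


def binomial_signed_z(ref_count: int, alt_count: int) -> tuple[float, float]:
    """Exact binomial p and signed probit deviate for one sample.

    Returns ``(p_i, z_i)`` with ``z_i = sign(ref - alt) *
    Phi^-1(1 - p_i/2)``, capped at +/-38.  ``z_i`` is zero exactly when
    the counts balance.
    """
    p = binomial_two_sided_p(ref_count, alt_count)
    if ref_count == alt_count:
        return p, 0.0
    z = float(min(stats.norm.isf(p / 2.0), Z_CAP))
    return p, z if ref_count > alt_count else -z


def sample_z_table(
    records: Iterable[AllelicCountRecord], min_cov: int = 0
) -> list[SampleZ]:
    """Per-sample z for a reporter's records, dropping low/zero coverage.

    Records with coverage below ``min_cov`` (and the degenerate
    zero-coverage case) are silently excluded, matching the batch
    contract of the pipeline.
    """
    out = []
    for r in records:
        n = r.coverage
        if n < max(min_cov, 1):
            continue
        p, z = binomial_signed_z(r.ref_count, r.alt_count)
        out.append(SampleZ(r.sample_id, n, p, z, float(n)))
    return out


# ---------------------------------------------------------------------------
# combination and null


def combine_weighted_z(samples: Sequence[SampleZ]) -> float:
    """Coverage-weighted Stouffer combination of per-sample deviates.

    Z = sum(w_i z_i) / sqrt(sum(w_i^2)); order-invariant and
    unit-variance under the null when the z_i are standard normal.
    """
    if len(samples) == 0:
        raise UndefinedResultError("cannot combine an empty sample list")
    w = np.array([s.w_i for s in samples])
    z = np.array([s.z_i for s in samples])
    return float(np.dot(w, z) / np.sqrt(np.dot(w, w)))


def _reporter_seed(seed: int, variant_id: str) -> np.random.SeedSequence:
    # crc32 keys the stream to the reporter id (stable across processes),
    # so the null is independent of sample or reporter ordering.
    return np.random.SeedSequence(entropy=[int(seed), zlib.crc32(variant_id.encode())])


def permutation_null(
    records: Sequence[AllelicCountRecord],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 1,
    min_cov: int = 0,
) -> PermutationNull:
    """Null distribution of Z under random per-sample allele flips.

    Each draw independently swaps the (ref, alt) assignment of every
    sample's counts with probability 0.5 and recomputes the combined Z.
    Because the two-sided binomial p is symmetric in its arguments, a
    swap negates z_i and leaves w_i unchanged, so the draw reduces to a
    sign flip of the per-sample deviates.  The random stream is keyed
    to sorted sample ids, making the null invariant to record order.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not records:
        raise UndefinedResultError("no records for permutation null")
    variant_id = records[0].variant_id
    samples = sample_z_table(sorted(records, key=lambda r: r.sample_id), min_cov=min_cov)
    if not samples:
        raise UndefinedResultError("no records surviving the coverage filter")
    z = np.array([s.z_i for s in samples])
    w = np.array([s.w_i for s in samples])
    rng = np.random.default_rng(_reporter_seed(seed, variant_id))
    signs = rng.integers(0, 2, size=(n_perm, len(samples))) * 2 - 1
    z_values = (signs * z) @ w / np.sqrt(np.dot(w, w))
    return PermutationNull(z_values=z_values, n_perm=n_perm, seed=seed)


def empirical_p(z_obs: float, null: PermutationNull) -> float:
    """Add-one two-sided empirical p: (1 + #{|Z_k| >= |Z_obs|}) / (1 + N)."""
    if null.z_values.size == 0:
        raise UndefinedResultError("empty permutation null")
    hits = int(np.sum(np.abs(null.z_values) >= abs(z_obs)))
    return (1 + hits) / (1 + null.n_perm)


def tail_p(z_obs: float, null: PermutationNull) -> float:
    """Gaussian-tail p from a normal fitted to the permutation null.

    Resolves significance below the 1/(N_perm+1) floor of the empirical
    estimator.  Raises :class:`DegenerateNullError` when the null has
    zero spread.
    """
    if null.n_perm < 30:
        raise ValueError("need at least 30 permutations to fit a tail")
    mu = float(np.mean(null.z_values))
    sigma = float(np.std(null.z_values, ddof=1))
    if sigma == 0.0:
        raise DegenerateNullError("permutation null has zero standard deviation")
    return float(2.0 * stats.norm.sf(abs(z_obs - mu) / sigma))


# ---------------------------------------------------------------------------
# pipeline


def _direction(z: float) -> str:
    if np.isnan(z) or z == 0.0:
        return "none"
    return "ref-biased" if z > 0 else "alt-biased"


def run_case(
    records: Iterable[AllelicCountRecord],
    min_cov: int = DEFAULT_MIN_COV,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 1,
    alpha: float = DEFAULT_ALPHA,
) -> list[ReporterResult]:
    """Full cASE scan over all reporter variants in a count table.

    Per reporter: samples below ``min_cov`` reads are dropped; the
    coverage-weighted Z, permutation p and Gaussian-tail p are computed
    on the survivors.  Reporters with no surviving sample are emitted
    with direction "none" and p = 1, flagged ``low_coverage``.
    Benjamini-Hochberg FDR across reporters is applied to the tail
    p-values; results are sorted by tail p ascending.
    """
    by_reporter: dict[str, list[AllelicCountRecord]] = {}
    for r in records:
        by_reporter.setdefault(r.variant_id, []).append(r)

    results: list[ReporterResult] = []
    for variant_id in sorted(by_reporter):
        recs = by_reporter[variant_id]
        samples = sample_z_table(recs, min_cov=min_cov)
        if not samples:
            results.append(
                ReporterResult(variant_id, 0, float("nan"), 1.0, 1.0, "none", low_coverage=True)
            )
            continue
        z_obs = combine_weighted_z(samples)
        null = permutation_null(recs, n_perm=n_perm, seed=seed, min_cov=min_cov)
        p_perm = empirical_p(z_obs, null)
        try:
            p_t = tail_p(z_obs, null)
        except DegenerateNullError:
            # all-balanced reporter: the null is a point mass at 0
            p_t = 1.0 if z_obs == float(np.mean(null.z_values)) else p_perm
        results.append(
            ReporterResult(variant_id, len(samples), z_obs, p_perm, p_t, _direction(z_obs))
        )

    if results:
        _, q, _, _ = multipletests([r.p_tail for r in results], alpha=alpha, method="fdr_bh")
        for r, qv in zip(results, q):
            r.q_value = float(qv)
    results.sort(key=lambda r: (r.p_tail, r.variant_id))
    return results
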