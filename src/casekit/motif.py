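"""Position-weight-matrix relative scoring around variants.

A JASPAR position frequency matrix is converted to log-odds against a
uniform background with a pseudocount, and sequence windows are scored
on the JASPAR relative scale:

    relative = (raw - min_possible) / (max_possible - min_possible)

where min/max are the column-wise worst/best log-odds sums, so the
consensus scores exactly 1 and the anti-consensus exactly 0.  A
variant is scanned by scoring, on both strands, every matrix-length
window overlapping the variant site in the reference and alternative
sequences; an allele "binds" when its best relative score reaches the
threshold (0.80 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Union

import numpy as np
from Bio import motifs as bio_motifs

from .errors import FormatError, ValidationError

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

DEFAULT_PSEUDOCOUNT = 0.8
DEFAULT_THRESHOLD = 0.80


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """A position frequency matrix with derived log-odds.

    ``counts`` has one row per base (A, C, G, T order) and one column
    per motif position.  Counts are first normalized to column
    frequencies, then a pseudocount split by the background (uniform,
    0.25 per base) is mixed in before the log-odds are taken:

        p = (count/colsum + pseudocount * bg) / (1 + pseudocount)

    which makes the score invariant to rescaling all counts by a
    positive constant (a matrix built from twice the sites says the
    same thing about the motif).
    """

    matrix_id: str
    counts: np.ndarray  # (4, L) non-negative
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    log_odds: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4 or self.counts.shape[1] < 1:
            raise ValidationError("PWM counts must be a 4 x L matrix with L >= 1")
        if np.any(self.counts < 0):
            raise ValidationError("PWM counts must be non-negative")
        colsum = self.counts.sum(axis=0)
        if np.any(colsum <= 0):
            raise ValidationError("every PWM column needs a positive count sum")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")
        bg = 0.25
        probs = (self.counts / colsum + self.pseudocount * bg) / (1.0 + self.pseudocount)
        self.log_odds = np.log2(probs / bg)

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def reverse_complement(self) -> "PWM":
        """The PWM binding the reverse-complement site."""
        return PWM(self.matrix_id, self.counts[::-1, ::-1], self.pseudocount)


def read_jaspar_pfm(source: Union[str, IO[str]]) -> PWM:
    """Read a JASPAR-format position frequency matrix.

    Accepts both the bracketed, base-labelled JASPAR dialect and the
    plain four-row PFM dialect, with or without a ``>`` header line.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    matrix_id = "PFM"
    if lines and lines[0].startswith(">"):
        matrix_id = lines[0][1:].split()[0] if lines[0][1:].split() else "PFM"
        body = lines[1:]
    else:
        body = lines
    if len(body) != 4:
        raise FormatError(f"expected 4 matrix rows (A, C, G, T), found {len(body)}")
    labelled = all(ln.lstrip()[:1].upper() in set(BASES) for ln in body)
    from io import StringIO

    try:
        if labelled:
            motif = bio_motifs.read(StringIO(f">{matrix_id}\n" + "\n".join(body)), "jaspar")
        else:
            motif = bio_motifs.read(StringIO("\n".join(body)), "pfm")
    except Exception as exc:
        raise FormatError(f"could not parse PFM: {exc}") from exc
    counts = np.array([motif.counts[b] for b in BASES], dtype=float)
    if counts.shape[1] < 1:
        raise FormatError("empty matrix")
    return PWM(matrix_id, counts)


def write_jaspar_pfm(pwm: PWM, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pwm.matrix_id}\n")
        for i, b in enumerate(BASES):
            vals = " ".join(f"{v:g}" for v in pwm.counts[i])
            fh.write(f"{b} [ {vals} ]\n")


def _encode(window: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in window.upper()])
    except KeyError:
        bad = sorted(set(window.upper()) - set(BASES))
        raise ValidationError(f"non-ACGT characters in sequence: {bad}") from None


def _relative_one_strand(pwm: PWM, window: str) -> float:
    idx = _encode(window)
    if idx.size != pwm.length:
        raise ValidationError(f"window length {idx.size} != matrix length {pwm.length}")
    cols = np.arange(pwm.length)
    raw = pwm.log_odds[idx, cols].sum()
    lo = pwm.log_odds.min(axis=0).sum()
    hi = pwm.log_odds.max(axis=0).sum()
    if hi == lo:  # completely uninformative matrix
        return 1.0
    return float((raw - lo) / (hi - lo))


def relative_score(pwm: PWM, window: str, strand: str = "best") -> float:
    """Relative profile score of one window in [0, 1].

    ``strand`` "+" scores the window as given, "-" scores its reverse
    complement, "best" returns the larger of the two.
    """
    if strand == "+":
        return _relative_one_strand(pwm, window)
    if strand == "-":
        return _relative_one_strand(pwm, reverse_complement(window))
    if strand == "best":
        return max(
            _relative_one_strand(pwm, window),
            _relative_one_strand(pwm, reverse_complement(window)),
        )
    raise ValueError("strand must be '+', '-' or 'best'")


@dataclass(frozen=True)
class VariantWindowPair:
    """Reference and alternative sequence windows around a variant.

    Equal-length ACGT strings differing at (at least) the variant
    site, located ``variant_offset`` bases into each string.
    """

    seq_ref: str
    seq_alt: str
    variant_offset: int

    def __post_init__(self) -> None:
        if len(self.seq_ref) != len(self.seq_alt):
            raise ValidationError("ref and alt windows must have equal length")
        if not 0 <= self.variant_offset < len(self.seq_ref):
            raise ValidationError("variant offset outside the window")
        _encode(self.seq_ref)
        _encode(self.seq_alt)


@dataclass(frozen=True)
class DifferentialBindingCall:
    """Best per-allele relative scores and the threshold call."""

    matrix_id: str
    best_ref: float
    best_alt: float
    threshold: float
    call: str  # both | ref_only | alt_only | neither


def _best_overlapping(pwm: PWM, seq: str, offset: int) -> float:
    """Best stranded score over all L-windows covering the variant site."""
    L = pwm.length
    if len(seq) < L:
        raise ValidationError(f"sequence shorter than matrix length {L}")
    lo = max(0, offset - L + 1)
    hi = min(len(seq) - L, offset)
    return max(relative_score(pwm, seq[s : s + L], "best") for s in range(lo, hi + 1))


def scan_variant(
    pwm: PWM, pair: VariantWindowPair, threshold: float = DEFAULT_THRESHOLD
) -> DifferentialBindingCall:
    """Differential-binding call for a variant under one motif.

    Scans both strands of every matrix-length window overlapping the
    variant in each allele's sequence; each allele's best relative
    score is compared against ``threshold``.
    """
    best_ref = _best_overlapping(pwm, pair.seq_ref, pair.variant_offset)
    best_alt = _best_overlapping(pwm, pair.seq_alt, pair.variant_offset)
    ref_hit, alt_hit = best_ref >= threshold, best_alt >= threshold
    call = {
        (True, True): "both",
        (True, False): "ref_only",
        (False, True): "alt_only",
        (False, False): "neither",
    }[(ref_hit, alt_hit)]
    return DifferentialBindingCall(pwm.matrix_id, best_ref, best_alt, threshold, call)
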