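"""Targeted amplicon CMC-seq quantification of pseudouridine stoichiometry.

The procedure: reads are collapsed along UMI keeping the first occurrence
of each 10-mer, then only sequences with perfect 8-mer anchor matches
flanking the target NΨN window are considered.  The deletion rate is the
fraction of anchor-matched sequences with 2 nt between the anchors (the
CMC adduct on Ψ terminates/skips reverse transcription, deleting the
central base); the mutation rate is the fraction with 3 nt between the
anchors and no T at the Ψ position.  Effective pseudouridylation is the
sample deletion rate normalized to a 100 % ΨTP in-vitro-transcribed
standard run through identical chemistry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .targets import AmpliconTarget

__all__ = [
    "ReadRecord",
    "AnchorMatch",
    "LocusCounts",
    "PsiQuantResult",
    "NoDataError",
    "read_fastq",
    "extract_umi",
    "collapse_by_umi",
    "match_anchors",
    "count_locus",
    "signature_rates",
    "effective_psi",
    "quantify_reads",
    "quantify_locus",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class NoDataError(ValueError):
    """No usable reads survive filtering at a locus."""


@dataclass(frozen=True)
class ReadRecord:
    """A read after UMI extraction: identifier, UMI and remaining payload."""

    read_id: str
    umi: str
    payload: str
    quality: str | None = None


@dataclass(frozen=True)
class AnchorMatch:
    """Result of perfect two-anchor matching on one payload.

    ``gap_length`` counts the bases strictly between the end of the
    anchor_up match and the start of the anchor_down match;
    ``gap_sequence`` is always reported in the sense orientation of the
    amplicon reference.
    """

    gap_length: int
    gap_sequence: str
    orientation: str  # "sense" | "revcomp"

    def __post_init__(self) -> None:
        if len(self.gap_sequence) != self.gap_length:
            raise ValueError("gap_sequence length disagrees with gap_length")


@dataclass
class LocusCounts:
    """Classified read tallies at one locus.

    The four classification buckets partition the anchor-matched reads:
    ``n_del`` (gap 2), ``n_ret_T`` (gap 3, middle base T), ``n_ret_nonT``
    (gap 3, middle base ≠ T), ``n_other_gap`` (any other gap ≤ max_gap).
    """

    locus_name: str
    n_input_reads: int = 0
    n_after_umi: int = 0
    n_anchor_matched: int = 0
    n_del: int = 0
    n_ret_T: int = 0
    n_ret_nonT: int = 0
    n_other_gap: int = 0

    def validate(self) -> None:
        if self.n_del + self.n_ret_T + self.n_ret_nonT + self.n_other_gap != self.n_anchor_matched:
            raise AssertionError(f"count buckets do not partition matches at {self.locus_name}")
        if not (self.n_anchor_matched <= self.n_after_umi <= self.n_input_reads):
            raise AssertionError(f"filtering stages not monotone at {self.locus_name}")


@dataclass
class PsiQuantResult:
    """Raw signature rates plus standard-normalized effective Ψ fraction."""

    locus_name: str
    deletion_rate: float
    mutation_rate: float
    standard_deletion_rate: float
    effective_psi: float
    clamped: bool = False
    sample_counts: LocusCounts | None = None
    standard_counts: LocusCounts | None = None


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality) from FASTQ in file order.

    Order preservation is contractual: downstream UMI collapse keeps the
    first occurrence of each UMI.  Truncated records and sequence/quality
    length mismatches raise ``ValueError`` (Biopython's parser enforces
    both).
    """
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq, qual


def extract_umi(read: tuple[str, str, str] | tuple[str, str], umi_length: int = 10,
                umi_offset: int = 0) -> ReadRecord:
    """Extract the UMI at ``[umi_offset, umi_offset + umi_length)``.

    The payload is the read with the UMI sliced out; bases before the UMI
    (when ``umi_offset`` > 0) are retained at the payload head.
    """
    read_id, seq = read[0], read[1]
    qual = read[2] if len(read) > 2 else None
    if len(seq) < umi_offset + umi_length:
        raise ValueError(
            f"read {read_id!r} of length {len(seq)} too short for UMI at "
            f"offset {umi_offset}, length {umi_length}"
        )
    umi = seq[umi_offset : umi_offset + umi_length]
    payload = seq[:umi_offset] + seq[umi_offset + umi_length :]
    pqual = None
    if qual is not None:
        pqual = qual[:umi_offset] + qual[umi_offset + umi_length :]
    return ReadRecord(read_id=read_id, umi=umi, payload=payload, quality=pqual)


def collapse_by_umi(reads: Iterable[ReadRecord]) -> list[ReadRecord]:
    """Keep exactly the first-encountered read per distinct UMI.

    Exact string identity, no mismatch tolerance; original relative order
    is preserved.  Idempotent by construction.
    """
    seen: set[str] = set()
    kept: list[ReadRecord] = []
    for rec in reads:
        if rec.umi not in seen:
            seen.add(rec.umi)
            kept.append(rec)
    return kept


def _match_one_orientation(payload: str, up: str, down: str,
                           max_gap: int) -> tuple[int, str] | None:
    i = payload.find(up)
    if i < 0:
        return None
    j = payload.find(down, i + len(up))
    if j < 0:
        return None
    gap = j - (i + len(up))
    if gap > max_gap:
        return None
    return gap, payload[i + len(up) : j]


def _match_single_anchor(payload: str, up: str, down: str,
                         max_gap: int) -> tuple[int, str] | None:
    """Permissive mode: one perfect anchor; the other located by best
    Hamming fit over candidate gaps (ties broken toward the smaller gap)."""
    def hamming(a: str, b: str) -> int:
        return sum(x != y for x, y in zip(a, b)) + abs(len(a) - len(b)) * len(up)

    i = payload.find(up)
    if i >= 0:
        best = None
        for gap in range(max_gap + 1):
            start = i + len(up) + gap
            cand = payload[start : start + len(down)]
            if len(cand) < len(down):
                break
            d = hamming(cand, down)
            if best is None or d < best[0]:
                best = (d, gap, payload[i + len(up) : start])
        if best is not None:
            return best[1], best[2]
        return None
    j = payload.find(down)
    if j >= 0:
        best = None
        for gap in range(min(max_gap, j) + 1):
            start = j - gap - len(up)
            if start < 0:
                break
            cand = payload[start : start + len(up)]
            d = hamming(cand, up)
            if best is None or d < best[0]:
                best = (d, gap, payload[j - gap : j])
        if best is not None:
            return best[1], best[2]
    return None


def match_anchors(payload: str, target: AmpliconTarget, max_gap: int = 10,
                  single_anchor: bool = False) -> AnchorMatch | None:
    """Locate the NΨN window by perfect 8-mer anchor matching.

    Finds the leftmost exact occurrence of ``anchor_up``, then the leftmost
    exact occurrence of ``anchor_down`` after it; reports the gap between
    them when it does not exceed ``max_gap``.  If the sense strand yields
    no match the reverse complement is tried, and the gap sequence is then
    reported in sense orientation.  Any mismatch disqualifies an
    occurrence; ``single_anchor=True`` enables a permissive mode that
    accepts one perfect anchor and infers the gap from the best inexact
    placement of the other.

    Returns ``None`` when neither orientation matches (no-match is a value,
    not an error).
    """
    if not payload:
        raise ValueError("empty payload")
    matcher = _match_single_anchor if single_anchor else _match_one_orientation
    hit = matcher(payload, target.anchor_up, target.anchor_down, max_gap)
    if hit is not None:
        return AnchorMatch(gap_length=hit[0], gap_sequence=hit[1], orientation="sense")
    rc = revcomp(payload)
    hit = matcher(rc, target.anchor_up, target.anchor_down, max_gap)
    if hit is not None:
        return AnchorMatch(gap_length=hit[0], gap_sequence=hit[1], orientation="revcomp")
    return None


def count_locus(reads: Sequence[ReadRecord], target: AmpliconTarget,
                max_gap: int = 10, single_anchor: bool = False,
                n_input_reads: int | None = None) -> LocusCounts:
    """Classify collapsed reads at a locus into the signature buckets.

    gap 2 → deletion signature; gap 3 with T at the central gap base
    (sense orientation) → retained unmodified; gap 3 with non-T middle →
    retained-mutated; any other gap ≤ max_gap stays in the denominator but
    in no signature numerator.  Reads failing anchor matching are excluded
    from ``n_anchor_matched``.
    """
    counts = LocusCounts(
        locus_name=target.locus_name,
        n_input_reads=len(reads) if n_input_reads is None else n_input_reads,
        n_after_umi=len(reads),
    )
    for rec in reads:
        m = match_anchors(rec.payload, target, max_gap=max_gap,
                          single_anchor=single_anchor)
        if m is None:
            continue
        counts.n_anchor_matched += 1
        if m.gap_length == 2:
            counts.n_del += 1
        elif m.gap_length == 3:
            if m.gap_sequence[1] == "T":
                counts.n_ret_T += 1
            else:
                counts.n_ret_nonT += 1
        else:
            counts.n_other_gap += 1
    counts.validate()
    return counts


def signature_rates(counts: LocusCounts) -> tuple[float, float]:
    """Deletion and mutation rates as fractions of anchor-matched reads."""
    if counts.n_anchor_matched == 0:
        raise NoDataError(f"no anchor-matched reads at locus {counts.locus_name!r}")
    n = counts.n_anchor_matched
    return counts.n_del / n, counts.n_ret_nonT / n


def effective_psi(sample_rate: float, standard_rate: float,
                  clamp: bool = False) -> tuple[float, bool]:
    """Normalize a sample deletion rate to the 100 % ΨTP standard.

    Returns ``(effective, clamped)``.  Values above 1 indicate the sample
    signature exceeded the standard's; by default they are reported as-is
    with a logged warning so calibration bias stays visible, and are capped
    at 1 only when ``clamp`` is requested.
    """
    if standard_rate <= 0:
        raise ValueError(f"standard deletion rate {standard_rate} <= 0: standard failed")
    value = sample_rate / standard_rate
    clamped = False
    if value > 1.0:
        logger.warning("effective pseudouridylation %.4f exceeds 1.0", value)
        if clamp:
            value, clamped = 1.0, True
    return value, clamped


def quantify_reads(
    sample_reads: Iterable[tuple[str, str]] | Iterable[tuple[str, str, str]],
    standard_reads: Iterable[tuple[str, str]] | Iterable[tuple[str, str, str]],
    target: AmpliconTarget,
    umi_length: int = 10,
    umi_offset: int = 0,
    max_gap: int = 10,
    clamp: bool = False,
    single_anchor: bool = False,
) -> PsiQuantResult:
    """Full in-memory quantification: UMI collapse → anchor counting →
    signature rates → standard normalization."""

    def process(raw) -> LocusCounts:
        records = []
        n_input = 0
        for read in raw:
            n_input += 1
            records.append(extract_umi(read, umi_length=umi_length, umi_offset=umi_offset))
        collapsed = collapse_by_umi(records)
        logger.info(
            "%s: %d input reads, %d after UMI collapse",
            target.locus_name, n_input, len(collapsed),
        )
        return count_locus(collapsed, target, max_gap=max_gap,
                           single_anchor=single_anchor, n_input_reads=n_input)

    sample_counts = process(sample_reads)
    standard_counts = process(standard_reads)
    del_rate, mut_rate = signature_rates(sample_counts)
    std_del_rate, _ = signature_rates(standard_counts)
    eff, clamped = effective_psi(del_rate, std_del_rate, clamp=clamp)
    return PsiQuantResult(
        locus_name=target.locus_name,
        deletion_rate=del_rate,
        mutation_rate=mut_rate,
        standard_deletion_rate=std_del_rate,
        effective_psi=eff,
        clamped=clamped,
        sample_counts=sample_counts,
        standard_counts=standard_counts,
    )


def quantify_locus(sample_fastq: str | Path, standard_fastq: str | Path,
                   target: AmpliconTarget, **kwargs) -> PsiQuantResult:
    """File-based entry point: quantify one locus from sample and 100 %-ΨTP
    standard FASTQ files.  Keyword arguments as in :func:`quantify_reads`."""
    return quantify_reads(
        read_fastq(sample_fastq), read_fastq(standard_fastq), target, **kwargs
    )
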