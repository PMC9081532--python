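"""96-channel mutation spectra.

Single-base substitutions are classified into the 96 canonical
substitution-in-trinucleotide-context channels: six pyrimidine-referenced
substitution classes (C>A, C>G, C>T, T>A, T>C, T>G), each split by the 16
combinations of 5' and 3' flanking bases.  Purine-referenced mutations are
reverse-complemented onto the pyrimidine strand before lookup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .records import MutationRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

SUBSTITUTION_CLASSES: tuple[tuple[str, str], ...] = (
    ("C", "A"), ("C", "G"), ("C", "T"),
    ("T", "A"), ("T", "C"), ("T", "G"),
)

#: canonical channel labels, COSMIC v2 order: classes as above, contexts by
#: 5' base then 3' base alphabetically within each class.
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{ref}>{alt}]{three}"
    for ref, alt in SUBSTITUTION_CLASSES
    for five in "ACGT"
    for three in "ACGT"
)

_CHANNEL_INDEX = {label: i for i, label in enumerate(CHANNELS)}


class ChannelError(ValueError):
    """Raised when a (ref, alt, context) triple cannot be classified."""


def reverse_complement(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise ChannelError(f"ambiguous base {exc.args[0]!r} in {seq!r}") from None


def classify_channel(ref: str, alt: str, context: str) -> int:
    """Map a substitution with its trinucleotide context to a channel index.

    Purine-referenced mutations (ref in {A, G}) are reverse-complemented so
    that every channel carries a pyrimidine reference base.

    Raises
    ------
    ChannelError
        on ambiguous bases (N etc.), ref == alt, or context[1] != ref.
    """
    if len(context) != 3:
        raise ChannelError(f"context must be a 3-mer, got {context!r}")
    for b in (ref, alt, *context):
        if b not in "ACGT":
            raise ChannelError(f"ambiguous base {b!r}")
    if ref == alt:
        raise ChannelError(f"ref == alt ({ref!r})")
    if context[1] != ref:
        raise ChannelError(f"context {context!r} middle base != ref {ref!r}")
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        context = reverse_complement(context)
    return _CHANNEL_INDEX[f"{context[0]}[{ref}>{alt}]{context[2]}"]


@dataclass
class Spectrum96:
    """Per-sample counts over the 96 canonical channels."""

    sample_id: str
    counts: np.ndarray  # shape (96,), non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (96,):
            raise ValueError(f"expected 96 channels, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("negative channel count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def normalized(self) -> np.ndarray:
        """Channel proportions; raises on an empty spectrum."""
        t = self.total
        if t == 0:
            raise ValueError(f"sample {self.sample_id}: empty spectrum")
        return self.counts / t


def _fetch_context(genome, chrom: str, pos: int) -> str | None:
    """1-based inclusive slice genome[chrom][pos-1 .. pos+1], or None."""
    for name in (chrom, f"chr{chrom}"):
        try:
            seq = genome[name]
        except KeyError:
            continue
        piece = seq[pos - 2 : pos + 1]
        piece = str(getattr(piece, "seq", piece)).upper()
        if len(piece) == 3:
            return piece
        return None
    return None


@dataclass
class ContextReport:
    """Reconciliation of annotate_context: what was kept and why rows fell out."""

    annotated: int = 0
    ref_mismatch: int = 0
    missing_chrom: int = 0
    edge: int = 0
    dropped_records: list = field(default_factory=list)


def annotate_context(
    records: list[MutationRecord], genome
) -> tuple[list[MutationRecord], ContextReport]:
    """Attach trinucleotide contexts from a reference genome accessor.

    ``genome`` is anything supporting ``genome[chrom]`` returning a
    0-based-sliceable sequence (a dict of strings, a pyfaidx.Fasta, ...).
    Chromosome names are tried verbatim and with a "chr" prefix.  Records
    whose reference base disagrees with the genome are dropped and counted.
    """
    report = ContextReport()
    out: list[MutationRecord] = []
    for rec in records:
        ctx = _fetch_context(genome, rec.chrom, rec.pos)
        if ctx is None:
            has_chrom = any(
                _chrom_present(genome, c) for c in (rec.chrom, f"chr{rec.chrom}")
            )
            if has_chrom:
                report.edge += 1
            else:
                report.missing_chrom += 1
            report.dropped_records.append(rec)
            continue
        if ctx[1] != rec.ref:
            report.ref_mismatch += 1
            report.dropped_records.append(rec)
            continue
        out.append(rec.with_context(ctx))
        report.annotated += 1
    if report.dropped_records:
        logger.warning(
            "annotate_context dropped %d records (%d ref mismatch, %d missing "
            "chromosome, %d contig edge)",
            len(report.dropped_records),
            report.ref_mismatch,
            report.missing_chrom,
            report.edge,
        )
    return out, report


def _chrom_present(genome, chrom: str) -> bool:
    try:
        genome[chrom]
    except KeyError:
        return False
    return True


def build_spectra(records: list[MutationRecord]) -> tuple[list[Spectrum96], int]:
    """Aggregate records into one spectrum per sample.

    Records without a context, or with N-containing/unclassifiable contexts,
    are skipped and counted (second return value), so that
    sum of totals + skipped == len(records).
    Samples appear in order of first occurrence.
    """
    counts: dict[str, np.ndarray] = {}
    skipped = 0
    for rec in records:
        if rec.context is None:
            skipped += 1
            continue
        try:
            ch = classify_channel(rec.ref, rec.alt, rec.context)
        except ChannelError:
            skipped += 1
            continue
        if rec.sample_id not in counts:
            counts[rec.sample_id] = np.zeros(96, dtype=np.int64)
        counts[rec.sample_id][ch] += 1
    if skipped:
        logger.info("build_spectra skipped %d unclassifiable records", skipped)
    return [Spectrum96(sid, c) for sid, c in counts.items()], skipped
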