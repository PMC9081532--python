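"""Core record type shared by the I/O and spectrum layers."""

from __future__ import annotations

from dataclasses import dataclass, replace

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class MutationRecord:
    """One somatic single-nucleotide variant.

    Coordinates are 1-based inclusive (MAF convention).  ``context``, when
    set, is the genome 3-mer centered on the variant with the reference base
    in the middle.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    context: str | None = None

    def __post_init__(self) -> None:
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"ref/alt must be single bases, got {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.context is not None:
            if len(self.context) != 3:
                raise ValueError(f"context must be a 3-mer, got {self.context!r}")
            if self.context[1] != self.ref:
                raise ValueError(
                    f"context {self.context!r} middle base != ref {self.ref!r}"
                )

    def with_context(self, context: str) -> "MutationRecord":
        return replace(self, context=context)
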