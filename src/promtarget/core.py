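"""Core domain types and coordinate conventions.

All genomic intervals are 0-based half-open. Strand affects only
TSS-relative transforms: offsets upstream of the transcription start
site are negative on both strands.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger("promtarget")

DEFAULT_UPSTREAM = 2200
DEFAULT_DOWNSTREAM = 500
PROBE_LENGTH_BOUNDS = (50, 75)


class PromtargetError(Exception):
    """Base class for package errors."""


class ValidationError(PromtargetError):
    """A record violates a domain invariant."""


class ParseError(PromtargetError):
    """A file could not be parsed; the message names the offending line."""


class ConfigError(PromtargetError):
    """An invalid parameter combination."""


def promoter_span(
    tss: int,
    strand: str,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    clip_low: int | None = 0,
) -> tuple[int, int]:
    """Half-open promoter interval around a TSS, strand-aware.

    On the + strand the interval is [tss - upstream, tss + downstream);
    on the - strand it is mirrored to [tss - downstream, tss + upstream).
    Intervals extending past the chromosome start are clipped at
    ``clip_low`` (pass None to disable) and the clip is logged.
    """
    if strand == "+":
        start, end = tss - upstream, tss + downstream
    elif strand == "-":
        start, end = tss - downstream, tss + upstream
    else:
        raise ValidationError(f"strand must be '+' or '-', got {strand!r}")
    if clip_low is not None and start < clip_low:
        logger.warning("promoter interval clipped at %d (tss=%d)", clip_low, tss)
        start = clip_low
    if not start <= tss < end:
        raise ValidationError(f"TSS {tss} outside promoter interval [{start}, {end})")
    return start, end


@dataclass(frozen=True)
class PromoterModel:
    """One promoter record: a gene's TSS and its tiled interval.

    ``n_tss`` counts the annotated transcription start sites of the gene;
    positional analyses restricted to unambiguous promoters filter on
    ``n_tss == 1``.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    start: int
    end: int
    n_tss: int = 1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.start < self.end:
            raise ValidationError(f"{self.gene_id}: empty interval [{self.start}, {self.end})")
        if not self.start <= self.tss < self.end:
            raise ValidationError(
                f"{self.gene_id}: TSS {self.tss} outside [{self.start}, {self.end})"
            )
        if self.n_tss < 1:
            raise ValidationError(f"{self.gene_id}: n_tss must be >= 1")

    @classmethod
    def from_tss(
        cls,
        gene_id: str,
        chrom: str,
        strand: str,
        tss: int,
        upstream: int = DEFAULT_UPSTREAM,
        downstream: int = DEFAULT_DOWNSTREAM,
        n_tss: int = 1,
    ) -> "PromoterModel":
        start, end = promoter_span(tss, strand, upstream, downstream)
        return cls(gene_id, chrom, strand, tss, start, end, n_tss)

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end

    def tss_offset(self, position: float) -> float:
        """Signed TSS-relative offset of a genomic position (upstream < 0)."""
        if self.strand == "+":
            return position - self.tss
        return self.tss - position


@dataclass(frozen=True)
class TilingProbe:
    """One tiling-array probe; controls carry no promoter assignment."""

    probe_id: str
    chrom: str
    start: int
    end: int
    promoter_id: str | None = None
    is_control: bool = False

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(f"{self.probe_id}: empty interval")
        if not self.is_control and self.promoter_id is None:
            raise ValidationError(f"{self.probe_id}: non-control probe lacks promoter")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class Max400Record:
    """Per-promoter, per-replicate windowed-median maximum (binding score)."""

    promoter_id: str
    replicate_id: str
    max400: float
    peak_probe_id: str
    peak_position: float


@dataclass(frozen=True)
class ConsensusCall:
    """Replicate-consensus membership for one promoter."""

    promoter_id: str
    n_support: int
    member: bool


@dataclass(frozen=True)
class PeakCall:
    """A cross-replicate concordant binding peak for one promoter."""

    promoter_id: str
    chrom: str
    consensus_position: float
    tss_offset: float
    support: int
    peak_probe_id: str | None = None
    sequence: str | None = None


@dataclass(frozen=True)
class CNSegment:
    """A constant-state copy-number segment in one sample."""

    sample_id: str
    chrom: str
    start: int
    end: int
    state: str  # loss_hom | loss_het | neutral | gain

    def __post_init__(self) -> None:
        if self.state not in ("loss_hom", "loss_het", "neutral", "gain"):
            raise ValidationError(f"bad CN state {self.state!r}")
        if not self.start < self.end:
            raise ValidationError("empty CN segment")
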