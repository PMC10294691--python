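"""Core domain types shared across the pipeline.

All coordinates are 0-based, half-open, on the forward strand of a named
contig. File dialects that use other conventions (1-based peak tables, GFF3)
are converted at the I/O boundary, never inside analysis code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

VALID_STRANDS = ("+", "-", ".")
DNA_ALPHABET = frozenset("ACGT")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic region ``[start, end)`` with optional strand."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty/inverted interval: [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"bad strand {self.strand!r}; expected one of {VALID_STRANDS}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        """True if ``start <= position < end``."""
        return self.start <= position < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.contig == other.contig and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class Gene:
    """An annotated gene: a named, mandatory-strand interval."""

    name: str
    body: GenomicInterval

    def __post_init__(self) -> None:
        if self.body.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name!r} requires an explicit strand")

    @property
    def start_coord(self) -> int:
        """Transcription-polarity start: left edge on '+', right edge on '-'."""
        return self.body.start if self.body.strand == "+" else self.body.end - 1


@dataclass(frozen=True)
class BindingSite:
    """A motif instance: fixed-width sequence with optional placement/score."""

    sequence: str
    position: Optional[int] = None
    strand: str = "+"
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty binding-site sequence")
        bad = set(self.sequence.upper()) - DNA_ALPHABET
        if bad:
            raise ValueError(f"non-ACGT characters in site: {sorted(bad)}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad site strand {self.strand!r}")
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def width(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneLink:
    """A gene associated with a peak in a curated table.

    ``intragenic`` marks genes whose body contains the peak center (the
    parenthesized entries of the packaged binding-region table); other
    linked genes lie downstream of an intergenic or near-start peak.
    """

    name: str
    intragenic: bool = False


@dataclass(frozen=True)
class Peak:
    """A ChIP peak summarized by a single center coordinate and score."""

    id: str
    contig: str
    center: int
    score: float
    hns_flag: bool = False
    site: Optional[BindingSite] = None
    chipchip_flag: bool = False
    genes: tuple = ()

    def __post_init__(self) -> None:
        if self.score <= 0:
            raise ValueError(f"peak {self.id}: score must be > 0, got {self.score}")
        if self.center < 0:
            raise ValueError(f"peak {self.id}: negative center {self.center}")

    @property
    def intragenic_curated(self) -> Optional[bool]:
        """Curated context from the source table: True if the first linked
        gene is marked intragenic, None when no genes are linked."""
        if not self.genes:
            return None
        return self.genes[0].intragenic

    def with_site(self, site: Optional[BindingSite]) -> "Peak":
        return replace(self, site=site)


@dataclass(frozen=True)
class ExpressionRecord:
    """Relative RNA level of one gene in two conditions.

    ``expr_a``/``expr_b`` are arbitrary-unit relative abundances (condition A
    = wild type, condition B = regulator deletion in the packaged table);
    ``None`` encodes a not-determined measurement. ``significant`` is the
    upstream differential-expression call (q < 0.01)."""

    gene: str
    expr_a: Optional[float]
    expr_b: Optional[float]
    significant: bool = False

    def __post_init__(self) -> None:
        for v in (self.expr_a, self.expr_b):
            if v is not None and v < 0:
                raise ValueError(f"{self.gene}: negative expression {v}")

    @property
    def complete(self) -> bool:
        return self.expr_a is not None and self.expr_b is not None


@dataclass(frozen=True)
class QPCRSummary:
    """Mean/SD summary of replicate qPCR occupancy measurements."""

    amplicon: str
    mean: float
    sd: float
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"{self.amplicon}: negative sd")
        if self.n_replicates < 1:
            raise ValueError(f"{self.amplicon}: n_replicates must be >= 1")


def merge_intervals(regions: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals per contig, returned sorted and non-overlapping."""
    by_contig: dict[str, list[GenomicInterval]] = {}
    for r in regions:
        by_contig.setdefault(r.contig, []).append(r)
    merged: list[GenomicInterval] = []
    for contig in sorted(by_contig):
        ivs = sorted(by_contig[contig], key=lambda r: (r.start, r.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for r in ivs[1:]:
            if r.start <= cur_e:
                cur_e = max(cur_e, r.end)
            else:
                merged.append(GenomicInterval(contig, cur_s, cur_e))
                cur_s, cur_e = r.start, r.end
        merged.append(GenomicInterval(contig, cur_s, cur_e))
    return merged
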