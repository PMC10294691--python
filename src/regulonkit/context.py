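"""Genomic-context classification of ChIP peaks and peak-set matching.

A peak center is *intragenic* when it lies inside at least one annotated gene
body, and is upgraded to *intragenic and upstream* when it additionally sits
within 200 bp 5' (strand-aware) of some gene's annotated start — close enough
that promoter-proximal regulation of that downstream gene remains plausible.
Everything else is *intergenic*, annotated with the nearest downstream gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .model import Gene, Peak

INTERGENIC = "intergenic"
INTRAGENIC = "intragenic"
INTRAGENIC_AND_UPSTREAM = "intragenic_and_upstream"

UPSTREAM_RULE_BP = 200  # "<200 bp upstream of an annotated gene start"


@dataclass(frozen=True)
class ContextCall:
    """Context classification of one peak.

    ``distance_to_start`` is the strand-aware distance from the peak center
    to the start of ``nearest_downstream_gene`` (positive = peak upstream).
    """

    peak_id: str
    category: str
    container_gene: Optional[str] = None
    nearest_downstream_gene: Optional[str] = None
    distance_to_start: Optional[int] = None


@dataclass(frozen=True)
class MatchedPair:
    peak_a: str
    peak_b: str
    distance: int


@dataclass(frozen=True)
class PeakSetMatch:
    pairs: list
    unmatched_a: list
    unmatched_b: list


def _upstream_distance(gene: Gene, position: int) -> Optional[int]:
    """Distance from position to the gene start, if the position is 5' of it.

    Returns a positive bp count when the peak lies upstream of the gene's
    start on the gene's own strand, else None.
    """
    if gene.body.strand == "+":
        d = gene.body.start - position
    else:
        d = position - (gene.body.end - 1)
    return d if d > 0 else None


def classify_peak(peak: Peak, annotation: Sequence[Gene]) -> ContextCall:
    """Classify one peak against a gene annotation.

    Containment is ``start <= center < end``; the 200-bp upstream rule is a
    strict inequality. When several genes contain the peak, the one whose
    start is nearest is reported (ties: leftmost start).
    """
    if not annotation:
        raise ValueError("annotation must be non-empty")
    genes = [g for g in annotation if g.body.contig == peak.contig]
    containers = [g for g in genes if g.body.contains(peak.center)]

    # nearest downstream gene: smallest strict upstream distance
    best_gene: Optional[Gene] = None
    best_dist: Optional[int] = None
    for g in genes:
        d = _upstream_distance(g, peak.center)
        if d is not None and (best_dist is None or d < best_dist):
            best_gene, best_dist = g, d

    if containers:
        containers.sort(key=lambda g: (abs(g.start_coord - peak.center), g.body.start))
        container = containers[0]
        if best_dist is not None and best_dist < UPSTREAM_RULE_BP:
            return ContextCall(
                peak.id,
                INTRAGENIC_AND_UPSTREAM,
                container_gene=container.name,
                nearest_downstream_gene=best_gene.name,
                distance_to_start=best_dist,
            )
        return ContextCall(
            peak.id,
            INTRAGENIC,
            container_gene=container.name,
            nearest_downstream_gene=best_gene.name if best_gene else None,
            distance_to_start=best_dist,
        )
    return ContextCall(
        peak.id,
        INTERGENIC,
        nearest_downstream_gene=best_gene.name if best_gene else None,
        distance_to_start=best_dist,
    )


def classify_all(
    peaks: Sequence[Peak], annotation: Sequence[Gene]
) -> tuple[list[ContextCall], dict[str, int]]:
    """Classify every peak; return calls plus per-category counts.

    With an empty annotation every peak is intergenic (degenerate but
    well-defined: there are no genes to be inside of).
    """
    if not annotation:
        calls = [ContextCall(p.id, INTERGENIC) for p in peaks]
    else:
        calls = [classify_peak(p, annotation) for p in peaks]
    counts = {INTERGENIC: 0, INTRAGENIC: 0, INTRAGENIC_AND_UPSTREAM: 0}
    for c in calls:
        counts[c.category] += 1
    return calls, counts


def match_peak_sets(
    set_a: Sequence[Peak], set_b: Sequence[Peak], max_dist: int
) -> PeakSetMatch:
    """Match peaks of A to their nearest B peak within ``max_dist`` (strict).

    A peak in A is matched iff some same-contig B peak center lies strictly
    closer than ``max_dist``; the nearest such peak is reported.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be > 0")
    pairs = []
    unmatched_a = []
    matched_b = set()
    for pa in set_a:
        best: Optional[Peak] = None
        best_d: Optional[int] = None
        for pb in set_b:
            if pb.contig != pa.contig:
                continue
            d = abs(pa.center - pb.center)
            if best_d is None or d < best_d:
                best, best_d = pb, d
        if best is not None and best_d < max_dist:
            pairs.append(MatchedPair(pa.id, best.id, best_d))
            matched_b.add(best.id)
        else:
            unmatched_a.append(pa.id)
    unmatched_b = [pb.id for pb in set_b if pb.id not in matched_b]
    return PeakSetMatch(pairs, unmatched_a, unmatched_b)
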