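"""Integration of binding context and differential expression into regulon
calls.

A gene is a *direct* regulon member when it has promoter-proximal binding
evidence (an intergenic peak with the gene as nearest downstream neighbor, or
an intragenic-and-upstream peak within 200 bp of its start) AND its RNA level
responds to loss of the regulator (significant, above the fold threshold). A
responding gene without promoter-proximal binding is an *indirect* target —
this includes genes whose only binding evidence is a promoter-distal
intragenic site, since occupancy and roadblock analyses of such cases show
the response is not site-mediated. Bound but non-responding genes are
*binding-only inert*;
everything else is *unaffected*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .context import INTERGENIC, INTRAGENIC, INTRAGENIC_AND_UPSTREAM, ContextCall
from .model import ExpressionRecord

BINDING_NONE = "none"
BINDING_UPSTREAM = "upstream"

DIRECT_MEMBER = "direct_member"
INDIRECT_TARGET = "indirect_target"
BINDING_ONLY_INERT = "binding_only_inert"
UNAFFECTED = "unaffected"

_MEMBERSHIP_BINDING = {BINDING_UPSTREAM, INTRAGENIC_AND_UPSTREAM}


@dataclass(frozen=True)
class RegulonCall:
    gene: str
    binding: str  # upstream | intragenic | intragenic_and_upstream | none
    de_significant: bool
    fold_change: float  # expr_a over expr_b, floored ratio (>= 0)
    direction: str  # activated | repressed | none
    label: str  # direct_member | indirect_target | binding_only_inert | unaffected


def binding_by_gene(context_calls: Sequence[ContextCall]) -> dict[str, str]:
    """Reduce context calls to the strongest binding evidence per gene.

    Intergenic peaks credit their nearest downstream gene with 'upstream'
    binding; intragenic-and-upstream peaks credit the downstream gene with
    'intragenic_and_upstream' and the container with 'intragenic'; plain
    intragenic peaks credit only the container. Upstream-type evidence
    outranks intragenic.
    """
    rank = {
        BINDING_UPSTREAM: 3,
        INTRAGENIC_AND_UPSTREAM: 2,
        INTRAGENIC: 1,
        BINDING_NONE: 0,
    }
    out: dict[str, str] = {}

    def credit(gene: Optional[str], kind: str) -> None:
        if gene and rank[kind] > rank.get(out.get(gene, BINDING_NONE), 0):
            out[gene] = kind

    for c in context_calls:
        if c.category == INTERGENIC:
            credit(c.nearest_downstream_gene, BINDING_UPSTREAM)
        elif c.category == INTRAGENIC_AND_UPSTREAM:
            credit(c.container_gene, INTRAGENIC)
            credit(c.nearest_downstream_gene, INTRAGENIC_AND_UPSTREAM)
        elif c.category == INTRAGENIC:
            credit(c.container_gene, INTRAGENIC)
    return out


def fixture_binding_map(peaks) -> dict[str, str]:
    """Binding evidence per gene from a curated peak table's gene links.

    Parenthesized (intragenic) links count as 'intragenic' except when the
    same row also lists a downstream gene, which is credited 'upstream'-type
    evidence exactly as the curated table intends.
    """
    rank = {BINDING_UPSTREAM: 3, INTRAGENIC: 1, BINDING_NONE: 0}
    out: dict[str, str] = {}
    for p in peaks:
        for link in p.genes:
            kind = INTRAGENIC if link.intragenic else BINDING_UPSTREAM
            if rank[kind] > rank.get(out.get(link.name, BINDING_NONE), 0):
                out[link.name] = kind
    return out


def _fold_and_direction(rec: ExpressionRecord, floor: float) -> tuple[float, str]:
    a = (rec.expr_a or 0.0) + floor
    b = (rec.expr_b or 0.0) + floor
    fold = a / b
    if fold > 1:
        direction = "activated"  # wild type higher: regulator activates
    elif fold < 1:
        direction = "repressed"
    else:
        direction = "none"
    return fold, direction


def count_de_genes(
    de_table: Sequence[ExpressionRecord], fold_threshold: float = 2.0, floor: float = 1.0
) -> int:
    """Number of genes flagged significant with |fold| >= threshold.

    Records with missing expression are excluded.
    """
    n = 0
    for rec in de_table:
        if not rec.complete or not rec.significant:
            continue
        fold, _ = _fold_and_direction(rec, floor)
        if max(fold, 1.0 / fold) >= fold_threshold:
            n += 1
    return n


def call_regulon(
    binding: Mapping[str, str],
    de_table: Sequence[ExpressionRecord],
    fold_threshold: float = 2.0,
    floor: float = 1.0,
    operons: Optional[Sequence[Sequence[str]]] = None,
) -> tuple[list[RegulonCall], list[str]]:
    """Classify every gene in the union of binding and expression evidence.

    ``binding`` maps gene -> binding category (from :func:`binding_by_gene`
    or :func:`fixture_binding_map`). ``operons`` optionally propagates
    membership-eligible binding from any operon member to all members.
    Returns (calls, genes excluded for missing expression).
    """
    seen: set[str] = set()
    for rec in de_table:
        if rec.gene in seen:
            raise ValueError(f"duplicate gene row: {rec.gene}")
        seen.add(rec.gene)

    binding = dict(binding)
    if operons:
        for operon in operons:
            kinds = [binding.get(g, BINDING_NONE) for g in operon]
            eligible = [k for k in kinds if k in _MEMBERSHIP_BINDING]
            if eligible:
                best = max(eligible, key=lambda k: k == BINDING_UPSTREAM)
                for g in operon:
                    if binding.get(g, BINDING_NONE) not in _MEMBERSHIP_BINDING:
                        binding[g] = best

    records = {rec.gene: rec for rec in de_table}
    excluded = [g for g, rec in records.items() if not rec.complete]
    calls: list[RegulonCall] = []
    for gene in sorted(set(binding) | set(records)):
        rec = records.get(gene)
        bind = binding.get(gene, BINDING_NONE)
        if rec is None or not rec.complete:
            # no usable expression: binding evidence alone cannot make a member
            label = BINDING_ONLY_INERT if bind != BINDING_NONE else UNAFFECTED
            calls.append(RegulonCall(gene, bind, False, 0.0, "none", label))
            continue
        fold, direction = _fold_and_direction(rec, floor)
        responsive = rec.significant and max(fold, 1.0 / fold) >= fold_threshold
        if responsive and bind in _MEMBERSHIP_BINDING:
            label = DIRECT_MEMBER
        elif responsive:
            label = INDIRECT_TARGET
        elif bind != BINDING_NONE:
            label = BINDING_ONLY_INERT
        else:
            label = UNAFFECTED
        calls.append(
            RegulonCall(gene, bind, rec.significant, fold, direction if responsive else direction, label)
        )
    return calls, excluded
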