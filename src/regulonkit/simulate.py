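"""Synthetic study generator with planted, machine-readable ground truth.

Emulates the statistical structure the analysis assumes: a genome of tunable
GC content carrying AT-rich silencer domains over a target fraction (0.17 by
default, the genome share of nucleoid-silencer-bound DNA in the system this
package models); an annotation of non-overlapping genes; binding peaks split
between intragenic and intergenic contexts (36/65 by default) with an AT-rich
direct-repeat motif instance planted at each center; two-genotype occupancy
tracks with Poisson noise and factor-dependent promoters; a differential-
expression table with planted direct, indirect, and inert genes; and qPCR
summaries with a controllable roadblock effect.

What it deliberately does not model: read-level artifacts (GC bias, mapping
ambiguity), operon structure, overlapping genes, or sequence evolution — so
recovery tests certify the pipeline's logic, not its robustness to every
property of real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import BindingSite, ExpressionRecord, Gene, GenomicInterval, Peak, QPCRSummary
from .motif import ALPHABET, reverse_complement
from .occupancy import CoverageTrack

SIM_CONTIG = "sim"

# pho-box-like AT-rich direct repeat used as the default planted motif
DEFAULT_CONSENSUS = "TGTCATAAAACTGTCATA"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic study."""

    genome_length: int = 200_000
    gc_content: float = 0.50
    silencer_fraction: float = 0.17
    silencer_gc: float = 0.30
    silencer_domain_length: int = 2_000
    n_genes: int = 100
    n_peaks: int = 65
    intragenic_fraction: float = 36 / 65
    consensus: str = DEFAULT_CONSENSUS
    site_mutation_rate: float = 0.10
    promoter_strength: float = 5.0
    base_depth: float = 20.0
    n_replicates: int = 2
    de_effect: float = 2.0  # log2 fold change planted for direct members
    n_indirect: int = 5
    expression_noise_sigma: float = 0.05  # log-normal jitter between conditions
    qpcr_cv: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc_content", "silencer_fraction", "silencer_gc", "intragenic_fraction"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.silencer_gc >= self.gc_content:
            raise ValueError("silencer_gc must be below gc_content")
        if self.genome_length < self.n_genes * 600:
            raise ValueError("genome too short for requested gene count")
        if self.n_genes < self.n_peaks:
            raise ValueError("need at least one gene per peak (n_genes >= n_peaks)")


@dataclass
class SimulatedStudy:
    """A generated genome plus every derived truth the tests consume."""

    config: SimConfig
    genome: str
    silencers: list
    genes: list
    peaks: list
    truth: pd.DataFrame  # one row per peak

    def write(self, outdir) -> None:
        from . import io

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_fasta({SIM_CONTIG: self.genome}, outdir / "genome.fasta")
        io.write_bed(self.silencers, outdir / "silencers.bed")
        io.write_genes_gff3(self.genes, outdir / "genes.gff3")
        io.write_peak_table(self.peaks, outdir / "peaks.tsv")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=probs)


def _mutate(rng: np.random.Generator, consensus: str, rate: float) -> str:
    out = []
    for c in consensus:
        if rng.random() < rate:
            out.append(ALPHABET[rng.integers(4)])
        else:
            out.append(c)
    return "".join(out)


def simulate_genome(config: SimConfig) -> SimulatedStudy:
    """Generate the genome, silencer domains, annotation, and planted peaks.

    Reproducible: the same config (including seed) yields byte-identical
    output. Realized silencer coverage is within 2% of the target fraction.
    """
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    codes = _random_sequence(rng, L, config.gc_content)

    # silencer domains: one per equal segment, so they never overlap and the
    # realized fraction is n * domain_length / L (within 2% of target)
    dlen = config.silencer_domain_length
    n_domains = max(1, round(config.silencer_fraction * L / dlen))
    silencers = []
    seg = L // n_domains
    for i in range(n_domains):
        lo = i * seg
        start = int(rng.integers(lo, lo + seg - dlen))
        silencers.append(GenomicInterval(SIM_CONTIG, start, start + dlen))
        codes[start : start + dlen] = _random_sequence(rng, dlen, config.silencer_gc)

    # non-overlapping genes tiled left to right with intergenic gaps
    genes = []
    pos = 600
    while len(genes) < config.n_genes:
        glen = int(rng.integers(900, 1500))
        gap = int(rng.integers(250, 450))
        if pos + glen + 300 > L:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Gene(f"g{len(genes):04d}", GenomicInterval(SIM_CONTIG, pos, pos + glen, strand)))
        pos += glen + gap

    n_intra = round(config.n_peaks * config.intragenic_fraction)
    n_inter = config.n_peaks - n_intra
    width = len(config.consensus)

    rows = []
    peaks = []
    # one distinct gene per peak so planted signals never stack
    gene_order = rng.permutation(len(genes))
    if len(genes) < n_intra + n_inter:
        raise ValueError("not enough genes generated for the requested peaks")
    # intragenic peaks: centered deep inside a gene body (>200 bp from starts)
    for i in range(n_intra):
        g = genes[gene_order[i]]
        b = g.body
        center = int(rng.integers(b.start + 250, b.end - 250))
        rows.append(("intra", g.name, center))
    # intergenic peaks: in the gap 5' of a gene start, <200 bp away and closer
    # to this gene's start than to any neighbor's
    for i in range(n_inter):
        g = genes[gene_order[n_intra + i]]
        d = int(rng.integers(60, 120))
        if g.body.strand == "+":
            center = g.body.start - d
        else:
            center = g.body.end - 1 + d
        rows.append(("inter", g.name, center))

    # factor-dependent promoters: every other intergenic peak
    truth_rows = []
    n_factor = 0
    for idx, (kind, gene_name, center) in enumerate(rows):
        site_seq = _mutate(rng, config.consensus, config.site_mutation_rate)
        strand = "+" if rng.random() < 0.5 else "-"
        start = center - width // 2
        planted = site_seq if strand == "+" else reverse_complement(site_seq)
        for j, c in enumerate(planted):
            codes[start + j] = ALPHABET.index(c)
        factor_dependent = kind == "inter" and idx % 2 == 0
        n_factor += factor_dependent
        in_silencer = any(s.contains(center) for s in silencers)
        pid = f"p{idx:03d}"
        peaks.append(
            Peak(
                id=pid,
                contig=SIM_CONTIG,
                center=center,
                score=float(rng.integers(1, 40)),
                site=BindingSite(site_seq, position=start, strand=strand),
            )
        )
        truth_rows.append(
            {
                "peak_id": pid,
                "center": center,
                "context": "intragenic" if kind == "intra" else "intergenic",
                "gene": gene_name,
                "site": site_seq,
                "site_strand": strand,
                "in_silencer": in_silencer,
                "factor_dependent": factor_dependent,
            }
        )

    genome = "".join(ALPHABET[c] for c in codes)
    truth = pd.DataFrame(truth_rows)
    return SimulatedStudy(config, genome, silencers, genes, peaks, truth)


def simulate_tracks(
    config: SimConfig, study: SimulatedStudy, conditions: Sequence[str] = ("wt", "mut")
) -> dict:
    """Poisson coverage tracks per condition and replicate.

    Factor-dependent promoter windows (200 bp around the peak) are elevated
    ``promoter_strength``-fold in the first condition only; every gene start
    carries a modest factor-independent promoter in both conditions.
    """
    rng = np.random.default_rng(config.seed + 1)
    L = config.genome_length
    lam_base = np.full(L, config.base_depth)
    for g in study.genes:
        s = g.start_coord
        lo, hi = max(0, s - 100), min(L, s + 100)
        lam_base[lo:hi] *= 2.0  # constitutive promoter signal
    factor_centers = study.truth.loc[study.truth.factor_dependent, "center"].to_numpy()

    tracks: dict = {}
    for ci, cond in enumerate(conditions):
        lam = lam_base.copy()
        if ci == 0:
            # elevate a full 400-bp window (mask, so overlapping windows can
            # never compound) so the windowed fold equals the planted strength
            mask = np.zeros(L, dtype=bool)
            for c in factor_centers:
                mask[max(0, c - 200) : min(L, c + 200)] = True
            lam[mask] *= config.promoter_strength
        tracks[cond] = [
            CoverageTrack(SIM_CONTIG, rng.poisson(lam).astype(float))
            for _ in range(config.n_replicates)
        ]
    return tracks


def simulate_de_table(
    config: SimConfig, study: SimulatedStudy
) -> tuple[list[ExpressionRecord], dict[str, str]]:
    """Expression table with planted regulon classes.

    Returns the records plus the truth mapping gene -> expected class
    ('direct_member', 'indirect_target', 'binding_only_inert', 'unaffected').
    """
    rng = np.random.default_rng(config.seed + 2)
    direct = set(study.truth.loc[study.truth.factor_dependent, "gene"])
    intragenic_bound = set(
        study.truth.loc[study.truth.context == "intragenic", "gene"]
    ) - direct
    upstream_bound = set(study.truth.loc[study.truth.context == "intergenic", "gene"]) - direct
    unbound = [g.name for g in study.genes if g.name not in direct | intragenic_bound | upstream_bound]
    indirect = set(unbound[: config.n_indirect]) if config.de_effect != 0 else set()

    records = []
    classes: dict[str, str] = {}
    shift = 2.0 ** config.de_effect
    for g in study.genes:
        base = float(rng.lognormal(mean=5.0, sigma=1.0))
        jitter = float(rng.lognormal(mean=0.0, sigma=config.expression_noise_sigma))
        if g.name in direct or g.name in indirect:
            expr_a, expr_b = base * shift, base * jitter
            significant = config.de_effect != 0
            classes[g.name] = "direct_member" if g.name in direct else "indirect_target"
        else:
            expr_a, expr_b = base, base * jitter
            significant = False
            if g.name in intragenic_bound or g.name in upstream_bound:
                classes[g.name] = "binding_only_inert"
            else:
                classes[g.name] = "unaffected"
        records.append(ExpressionRecord(g.name, expr_a, expr_b, significant))
    return records, classes


def simulate_qpcr(
    config: SimConfig,
    effect: float = 1.0,
    up_mean: float = 10.0,
    ratio_wt: float = 0.5,
) -> tuple[QPCRSummary, QPCRSummary, QPCRSummary, QPCRSummary]:
    """Occupancy summaries with a planted roadblock effect.

    ``effect`` multiplies the downstream/upstream occupancy ratio in the
    deletion strain: 1.0 is the no-roadblock null, >1 mimics roadblock
    relief. SDs are ``qpcr_cv * mean`` (cv 0 gives deterministic draws).
    """
    cv = config.qpcr_cv
    down_wt = up_mean * ratio_wt
    down_mut = up_mean * ratio_wt * effect
    return (
        QPCRSummary("up_wt", up_mean, cv * up_mean),
        QPCRSummary("down_wt", down_wt, cv * down_wt),
        QPCRSummary("up_mut", up_mean, cv * up_mean),
        QPCRSummary("down_mut", down_mut, cv * down_mut),
    )
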