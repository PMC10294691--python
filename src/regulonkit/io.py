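"""Readers and writers for the flat-file formats the pipeline consumes.

Dialect conventions handled here, once:

* peak tables and gene TSV/GFF3 are 1-based inclusive on disk,
* BED and bedGraph are 0-based half-open,
* everything in memory is 0-based half-open (:mod:`regulonkit.model`).

The packaged binding-region table (``data/table1.tsv``) transcribes a
published set of 65 PhoB-bound regions mapped by ChIP-seq in E. coli:
coordinate, H-NS co-occupancy flag, ChIP enrichment score, associated genes
(parentheses = intragenic), the 18-bp pho-box site call (NA when absent), and
relative RNA levels in wild-type vs regulator-deletion cells (asterisk =
significant difference, parentheses mirror the gene markup, ND = not
determined).
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    BindingSite,
    ExpressionRecord,
    Gene,
    GeneLink,
    GenomicInterval,
    Peak,
)
from .occupancy import CoverageTrack

PathLike = Union[str, Path]

_MISSING = {"", "NA", "ND", "nan", "None"}


# ---------------------------------------------------------------------------
# peak tables
# ---------------------------------------------------------------------------

def _parse_gene_field(field: str) -> tuple[GeneLink, ...]:
    links = []
    for token in str(field).split("/"):
        token = token.strip()
        if not token or token in _MISSING:
            continue
        intragenic = token.startswith("(") and token.endswith(")")
        links.append(GeneLink(token.strip("()"), intragenic=intragenic))
    return tuple(links)


def _format_gene_field(links: Sequence[GeneLink]) -> str:
    return "/".join(f"({g.name})" if g.intragenic else g.name for g in links)


def _parse_expression_token(token: str) -> tuple[Optional[float], bool]:
    """One expression cell -> (value or None, significance asterisk seen)."""
    token = str(token).strip().strip("()")
    significant = token.endswith("*")
    token = token.rstrip("*").replace(",", "")
    if token in _MISSING:
        return None, significant
    return float(token), significant


def read_peak_table(path: PathLike, contig: str = "genome") -> list[Peak]:
    """Read a TSV peak table (1-based ``coordinate`` column) into peaks.

    Required columns: ``coordinate``, ``chip_score``. Recognized optional
    columns: ``contig``, ``hns``, ``chipchip``, ``genes``, ``site``.
    Site cells of ``NA`` yield peaks without a binding site.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("coordinate", "chip_score"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    peaks: list[Peak] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        row = row._asdict()
        try:
            center = int(str(row["coordinate"]).replace(",", "")) - 1
            score = float(row["chip_score"])
            site_seq = str(row.get("site", "")).strip()
            site = None
            if site_seq and site_seq not in _MISSING:
                site = BindingSite(site_seq)
            peaks.append(
                Peak(
                    id=str(row["coordinate"]),
                    contig=str(row.get("contig", "") or contig),
                    center=center,
                    score=score,
                    hns_flag=str(row.get("hns", "")).strip().lower() in {"x", "1", "true", "yes"},
                    chipchip_flag=str(row.get("chipchip", "")).strip().lower()
                    in {"x", "1", "true", "yes"},
                    site=site,
                    genes=_parse_gene_field(row.get("genes", "")),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: malformed row at line {i}: {exc}") from exc
    return peaks


def write_peak_table(peaks: Sequence[Peak], path: PathLike) -> None:
    """Write peaks back to TSV with 1-based coordinates (inverse of read)."""
    rows = []
    for p in peaks:
        rows.append(
            {
                "coordinate": p.center + 1,
                "contig": p.contig,
                "chipchip": "x" if p.chipchip_flag else "",
                "hns": "x" if p.hns_flag else "",
                "chip_score": p.score,
                "genes": _format_gene_field(p.genes),
                "site": p.site.sequence if p.site else "NA",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def read_expression_table(path: PathLike) -> list[ExpressionRecord]:
    """Read a per-gene expression TSV: gene, expr_a, expr_b, significant."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene", "expr_a", "expr_b"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            a, sig_a = _parse_expression_token(row["expr_a"])
            b, sig_b = _parse_expression_token(row["expr_b"])
            flag = str(row.get("significant", "")).strip().lower() in {"x", "1", "true", "yes"}
            records.append(ExpressionRecord(str(row["gene"]), a, b, flag or sig_a or sig_b))
        except ValueError as exc:
            raise ValueError(f"{path}: malformed row at line {i}: {exc}") from exc
    return records


def write_expression_table(records: Sequence[ExpressionRecord], path: PathLike) -> None:
    pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "expr_a": ["ND" if r.expr_a is None else r.expr_a for r in records],
            "expr_b": ["ND" if r.expr_b is None else r.expr_b for r in records],
            "significant": [int(r.significant) for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# coverage (bedGraph)
# ---------------------------------------------------------------------------

def read_coverage(path: PathLike, contig_length: Optional[int] = None) -> CoverageTrack:
    """Read a bedGraph file into a dense per-position coverage track.

    Intervals are 0-based half-open and must not overlap; positions not
    covered by any record are 0.
    """
    recs = []
    contig = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 bedGraph columns")
            c, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if contig is None:
                contig = c
            elif c != contig:
                raise ValueError(f"{path}: multiple contigs not supported ({contig} vs {c})")
            recs.append((s, e, v))
    recs.sort()
    for (s1, e1, _), (s2, _, _) in zip(recs, recs[1:]):
        if s2 < e1:
            raise ValueError(f"{path}: overlapping bedGraph intervals at {s2}")
    length = contig_length if contig_length is not None else (recs[-1][1] if recs else 0)
    import numpy as np

    values = np.zeros(length, dtype=float)
    for s, e, v in recs:
        values[s:e] = v
    return CoverageTrack(contig=contig or "genome", values=values)


def write_coverage(track: CoverageTrack, path: PathLike) -> None:
    """Write a coverage track as bedGraph, run-length encoding non-zero runs."""
    import numpy as np

    vals = track.values
    with open(path, "w") as fh:
        if len(vals) == 0:
            return
        breaks = np.flatnonzero(np.diff(vals)) + 1
        starts = np.concatenate(([0], breaks))
        ends = np.concatenate((breaks, [len(vals)]))
        for s, e in zip(starts, ends):
            v = vals[s]
            if v != 0:
                fh.write(f"{track.contig}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# sequences, annotation, regions
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> dict[str, str]:
    """FASTA file -> {record id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


_GFF_ATTR = re.compile(r"(?:^|;)\s*(?:Name|gene|locus_tag|ID)=([^;]+)")


def read_genes(path: PathLike) -> list[Gene]:
    """Read gene annotation from GFF3 or a minimal TSV.

    GFF3 (detected by ``##gff`` header or 9 tab columns): features of type
    ``gene`` are used, named from Name/gene/locus_tag/ID attributes.
    TSV: header columns gene, start, end, strand [, contig], 1-based
    inclusive coordinates.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##gff") or (first.count("\t") >= 8 and not first.startswith("gene")):
        return _read_gff3(path)
    return _read_gene_tsv(path)


def _read_gff3(path: Path) -> list[Gene]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            contig, start, end, strand, attrs = parts[0], int(parts[3]), int(parts[4]), parts[6], parts[8]
            m = _GFF_ATTR.search(attrs)
            name = m.group(1) if m else f"{contig}:{start}-{end}"
            genes.append(Gene(name, GenomicInterval(contig, start - 1, end, strand)))
    _check_unique([g.name for g in genes], path)
    return genes


def _read_gene_tsv(path: Path) -> list[Gene]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene", "start", "end", "strand"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    genes = []
    for row in df.itertuples(index=False):
        row = row._asdict()
        contig = str(row.get("contig", "") or "genome")
        genes.append(
            Gene(
                str(row["gene"]),
                GenomicInterval(contig, int(row["start"]) - 1, int(row["end"]), str(row["strand"])),
            )
        )
    _check_unique([g.name for g in genes], path)
    return genes


def _check_unique(names: Sequence[str], path: Path) -> None:
    seen = set()
    for n in names:
        if n in seen:
            raise ValueError(f"{path}: duplicate gene name {n!r}")
        seen.add(n)


def write_genes_gff3(genes: Sequence[Gene], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            b = g.body
            fh.write(
                f"{b.contig}\tregulonkit\tgene\t{b.start + 1}\t{b.end}\t.\t{b.strand}\t.\tName={g.name}\n"
            )


def read_bed(path: PathLike) -> list[GenomicInterval]:
    """BED file (0-based half-open) -> intervals."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            regions.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
    return regions


def write_bed(regions: Sequence[GenomicInterval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\n")


# ---------------------------------------------------------------------------
# packaged fixture
# ---------------------------------------------------------------------------

TABLE1_CONTIG = "NC_000913.3"


def load_table1_fixture() -> tuple[list[Peak], list[BindingSite], list[ExpressionRecord]]:
    """Load the packaged 65-region PhoB binding table.

    Returns the peaks (with curated gene links, H-NS flags, and site calls),
    the 59 pho-box site sequences, and one expression record per associated
    gene (deduplicated; ND entries carried as missing values).
    """
    ref = resources.files("regulonkit.data").joinpath("table1.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        peaks = read_peak_table(path, contig=TABLE1_CONTIG)
    sites = [p.site for p in peaks if p.site is not None]
    records: dict[str, ExpressionRecord] = {}
    for row in df.itertuples(index=False):
        row = row._asdict()
        links = _parse_gene_field(row["genes"])
        wt_tokens = str(row["expr_wt"]).split("/")
        mut_tokens = str(row["expr_mut"]).split("/")
        if not (len(links) == len(wt_tokens) == len(mut_tokens)):
            raise ValueError(f"fixture row {row['coordinate']}: gene/expression arity mismatch")
        for link, wt_tok, mut_tok in zip(links, wt_tokens, mut_tokens):
            a, sig_a = _parse_expression_token(wt_tok)
            b, sig_b = _parse_expression_token(mut_tok)
            rec = ExpressionRecord(link.name, a, b, sig_a or sig_b)
            if link.name in records and records[link.name] != rec:
                raise ValueError(f"fixture: conflicting duplicate records for {link.name}")
            records[link.name] = rec
    return peaks, sites, list(records.values())
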