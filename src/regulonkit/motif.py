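"""Position weight matrices: construction, scanning, and scrambled nulls.

A PWM is built from aligned fixed-width binding sites: per-position counts,
probabilities after a pseudocount, and base-2 log-odds against a background
nucleotide distribution. Scores are therefore in bits and additive over
positions; the expected score of background-distributed sequence is the
negative Kullback-Leibler divergence, hence <= 0.

The scrambled-site null asks how much of a motif's genome-wide signal is
explained by nucleotide composition alone: each site is individually letter-
permuted, a PWM is rebuilt from the scrambled set, the genome is scanned for
the top-k matches, and the fraction of match midpoints falling in a region
set (e.g. nucleoid-silencer domains) is reported. An AT-rich motif keeps
finding AT-rich regions even after scrambling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .model import BindingSite, GenomicInterval, Peak, merge_intervals

ALPHABET = "ACGT"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

UNIFORM_BACKGROUND = np.full(4, 0.25)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """DNA string -> int array over {A:0, C:1, G:2, T:3}."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = np.full(256, -1, dtype=np.int8)
    for c, i in _INDEX.items():
        codes[ord(c)] = i
    out = codes[arr]
    if (out < 0).any():
        bad = sorted({seq[i] for i in np.flatnonzero(out < 0)})
        raise ValueError(f"non-ACGT characters in sequence: {bad}")
    return out.astype(np.intp)


def genome_background(genome: str) -> np.ndarray:
    """Mononucleotide frequencies of a genome sequence."""
    counts = np.bincount(encode(genome), minlength=4).astype(float)
    return counts / counts.sum()


@dataclass(frozen=True)
class ScanHit:
    """One PWM match: leftmost base of the window, strand, score in bits."""

    position: int
    strand: str
    score: float

    def midpoint(self, width: int) -> int:
        return self.position + width // 2


@dataclass(frozen=True)
class CentralityProfile:
    """Binding-site coverage at signed offsets from ChIP peak centers."""

    offsets: np.ndarray
    coverage: np.ndarray
    n_skipped: int = 0

    def peak_offset(self) -> int:
        """Offset of maximum coverage (ties -> closest to zero)."""
        m = self.coverage.max()
        candidates = self.offsets[self.coverage == m]
        return int(candidates[np.argmin(np.abs(candidates))])


class PWM:
    """A position weight matrix with counts, probabilities, and log-odds.

    Parameters
    ----------
    counts : (width, 4) array of per-position nucleotide counts.
    background : length-4 nucleotide distribution (default uniform).
    pseudocount : count added to every cell before normalization.
    """

    def __init__(
        self,
        counts: np.ndarray,
        background: Optional[np.ndarray] = None,
        pseudocount: float = 0.5,
    ) -> None:
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError(f"counts must be (width, 4), got {counts.shape}")
        if counts.shape[0] < 1:
            raise ValueError("width must be >= 1")
        if pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be a length-4 distribution summing to 1")
        self.counts = counts
        self.background = bg
        self.pseudocount = float(pseudocount)
        totals = counts.sum(axis=1, keepdims=True) + 4 * pseudocount
        self.probabilities = (counts + pseudocount) / totals
        with np.errstate(divide="ignore"):
            self.log_odds = np.log2(self.probabilities / bg)

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probabilities.argmax(axis=1))

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def reverse_complement(self) -> "PWM":
        rc = PWM.__new__(PWM)
        rc.counts = self.counts[::-1, ::-1].copy()
        rc.background = self.background
        rc.pseudocount = self.pseudocount
        rc.probabilities = self.probabilities[::-1, ::-1].copy()
        rc.log_odds = self.log_odds[::-1, ::-1].copy()
        return rc

    def score(self, seq: str) -> float:
        """Log-odds score (bits) of one width-length sequence."""
        if len(seq) != self.width:
            raise ValueError(f"sequence length {len(seq)} != PWM width {self.width}")
        idx = encode(seq)
        return float(self.log_odds[np.arange(self.width), idx].sum())

    def score_all(self, genome: Union[str, np.ndarray]) -> np.ndarray:
        """Scores of every forward-strand window of an encoded genome."""
        codes = genome if isinstance(genome, np.ndarray) else encode(genome)
        n = len(codes) - self.width + 1
        if n < 1:
            raise ValueError("genome shorter than PWM width")
        scores = np.zeros(n)
        for j in range(self.width):
            scores += self.log_odds[j, codes[j : j + n]]
        return scores

    def to_meme(self, name: str = "motif") -> str:
        """Serialize in MEME minimal motif format."""
        n_sites = int(round(self.counts.sum(axis=1).max())) or 1
        lines = [
            "MEME version 4",
            "",
            "ALPHABET= ACGT",
            "",
            "Background letter frequencies",
            " ".join(f"{c} {f:.6f}" for c, f in zip(ALPHABET, self.background)),
            "",
            f"MOTIF {name}",
            f"letter-probability matrix: alength= 4 w= {self.width} nsites= {n_sites}",
        ]
        for row in self.probabilities:
            lines.append(" ".join(f"{p:.6f}" for p in row))
        return "\n".join(lines) + "\n"


def build_pwm(
    sites: Sequence[Union[str, BindingSite]],
    background: Optional[np.ndarray] = None,
    pseudocount: float = 0.5,
) -> PWM:
    """Build a PWM from aligned same-length binding sites.

    Requires at least two sites; mixed lengths or non-ACGT characters raise.
    """
    seqs = [s.sequence if isinstance(s, BindingSite) else str(s).upper() for s in sites]
    if len(seqs) < 2:
        raise ValueError(f"need >= 2 sites to build a PWM, got {len(seqs)}")
    widths = {len(s) for s in seqs}
    if len(widths) != 1:
        raise ValueError(f"sites have mixed lengths: {sorted(widths)}")
    (width,) = widths
    counts = np.zeros((width, 4))
    for s in seqs:
        idx = encode(s)
        np.add.at(counts, (np.arange(width), idx), 1)
    return PWM(counts, background=background, pseudocount=pseudocount)


def scan_genome(pwm: PWM, genome: str, top_k: int = 1000) -> list[ScanHit]:
    """Top-k PWM matches on both strands of a genome.

    Hits are sorted by descending score, ties broken by (position, strand)
    ascending. Reverse-strand hits are reported at the forward coordinate of
    the window's leftmost base. Overlapping hits are not masked.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    codes = encode(genome)
    fwd = pwm.score_all(codes)
    rev = pwm.reverse_complement().score_all(codes)
    n = len(fwd)
    scores = np.concatenate([fwd, rev])
    positions = np.concatenate([np.arange(n), np.arange(n)])
    strands = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
    # round for ordering only, so float summation order cannot scramble ties
    order = np.lexsort((strands, positions, -np.round(scores, 9)))
    k = min(top_k, 2 * n)
    return [
        ScanHit(int(positions[i]), "+-"[strands[i]], float(scores[i]))
        for i in order[:k]
    ]


def scramble_sites(
    sites: Sequence[Union[str, BindingSite]],
    seed: Union[int, np.random.Generator, None] = None,
) -> list[str]:
    """Independently letter-permute each site (composition-preserving null)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for s in sites:
        seq = s.sequence if isinstance(s, BindingSite) else str(s).upper()
        out.append("".join(rng.permutation(list(seq))))
    return out


def scrambled_null_overlap(
    sites: Sequence[Union[str, BindingSite]],
    genome: str,
    regions: Sequence[GenomicInterval],
    top_k: int = 1000,
    seed: Union[int, np.random.Generator, None] = None,
    background: Optional[np.ndarray] = None,
    pseudocount: float = 0.5,
) -> float:
    """Fraction of top-k scrambled-PWM hit midpoints inside a region union.

    Pipeline: scramble each site, rebuild the PWM from the scrambled set,
    scan both genome strands for the top-k matches, and count the fraction of
    match-window midpoints that fall within the union of ``regions``.
    """
    scrambled = scramble_sites(sites, seed)
    pwm = build_pwm(scrambled, background=background, pseudocount=pseudocount)
    hits = scan_genome(pwm, genome, top_k=top_k)
    if not hits:
        return 0.0
    merged = merge_intervals(regions) if regions else []
    starts = np.array([r.start for r in merged])
    ends = np.array([r.end for r in merged])
    inside = 0
    for h in hits:
        mid = h.midpoint(pwm.width)
        if len(starts):
            i = np.searchsorted(starts, mid, side="right") - 1
            if i >= 0 and mid < ends[i]:
                inside += 1
    return inside / len(hits)


def centrality_profile(
    peaks: Sequence[Peak], half_range: int = 50
) -> CentralityProfile:
    """Coverage of binding sites at offsets relative to their peak centers.

    Each peak whose site has a genomic position contributes +1 coverage on
    offsets ``[site_start - center, site_start - center + width)``. Peaks
    without a placed site are skipped and counted in ``n_skipped``.
    """
    offsets = np.arange(-half_range, half_range + 1)
    coverage = np.zeros_like(offsets)
    skipped = 0
    for p in peaks:
        if p.site is None or p.site.position is None:
            skipped += 1
            continue
        lo = p.site.position - p.center
        for off in range(lo, lo + p.site.width):
            j = off + half_range
            if 0 <= j < len(coverage):
                coverage[j] += 1
    return CentralityProfile(offsets, coverage, n_skipped=skipped)
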