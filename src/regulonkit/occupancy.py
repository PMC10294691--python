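"""Windowed occupancy extraction and cross-condition fold classification.

A :class:`CoverageTrack` is dense per-position coverage on one contig,
normalized to reads-per-million-equivalent units so tracks of different
sequencing depth are comparable. Occupancy around a binding site is the mean
coverage in a fixed-width window centered on the ChIP peak coordinate
(400 bp is the convention for sigma-factor occupancy analyses); regulator
dependence is the ratio of those means between genotypes, guarded by a small
floor pseudovalue so near-zero windows do not produce unstable folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from statistics import mean as _pymean
from typing import Optional, Sequence

import numpy as np

from .model import GenomicInterval, merge_intervals

DEFAULT_FLOOR = 1.0  # reads-per-million units added to both window means


@dataclass
class CoverageTrack:
    """Per-position read coverage for one contig."""

    contig: str
    values: np.ndarray
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("coverage values must be one-dimensional")
        if len(self.values) and self.values.min() < 0:
            raise ValueError("negative coverage values")

    def __len__(self) -> int:
        return len(self.values)

    def value_at(self, position: int) -> float:
        if 0 <= position < len(self.values):
            return float(self.values[position])
        return 0.0

    def normalized(self, per: float = 1e6) -> "CoverageTrack":
        """Scale so the track total equals ``per`` (reads-per-million units)."""
        total = self.values.sum()
        if total == 0:
            return CoverageTrack(self.contig, self.values.copy(), self.strand)
        return CoverageTrack(self.contig, self.values * (per / total), self.strand)

    def __add__(self, other: "CoverageTrack") -> "CoverageTrack":
        if self.contig != other.contig or len(self) != len(other):
            raise ValueError("cannot add tracks of different contigs/lengths")
        return CoverageTrack(self.contig, self.values + other.values)


@dataclass(frozen=True)
class OccupancyWindow:
    """Mean coverage per condition/replicate in one peak-centered window."""

    peak_id: str
    center: int
    half_width: int
    means: dict  # condition -> tuple of replicate window means
    truncated: bool = False


@dataclass(frozen=True)
class FoldCall:
    """Cross-condition occupancy comparison for one peak/window."""

    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    fold: float  # (mean_a + floor) / (mean_b + floor)
    direction: str  # 'up' (A higher), 'down' (B higher), 'unchanged'

    def exceeds(self, threshold: float) -> bool:
        """True if occupancy differs more than ``threshold``-fold either way."""
        return max(self.fold, 1.0 / self.fold) > threshold


def window_occupancy(track: CoverageTrack, center: int, width: int) -> float:
    """Mean coverage on ``[center - width/2, center + width/2)``.

    Windows extending beyond the contig are truncated to the available
    positions with a warning.
    """
    if width < 2 or width % 2:
        raise ValueError(f"width must be even and >= 2, got {width}")
    lo, hi = center - width // 2, center + width // 2
    clo, chi = max(lo, 0), min(hi, len(track))
    if clo >= chi:
        raise ValueError(f"window [{lo}, {hi}) lies entirely outside the contig")
    if (clo, chi) != (lo, hi):
        warnings.warn(
            f"window [{lo}, {hi}) truncated to [{clo}, {chi}) at contig edge",
            stacklevel=2,
        )
    return float(track.values[clo:chi].mean())


def window_table(
    tracks: dict, peaks: Sequence, width: int
) -> list[OccupancyWindow]:
    """Window means for every peak under every (condition, replicate) track.

    ``tracks`` maps condition name -> sequence of replicate CoverageTracks.
    Stranded replicate pairs should be summed into one track beforehand
    (or passed through ``CoverageTrack.__add__``).
    """
    out = []
    for p in peaks:
        means = {
            cond: tuple(window_occupancy(t, p.center, width) for t in reps)
            for cond, reps in tracks.items()
        }
        truncated = p.center - width // 2 < 0 or any(
            p.center + width // 2 > len(reps[0]) for reps in tracks.values() if reps
        )
        out.append(OccupancyWindow(p.id, p.center, width // 2, means, truncated))
    return out


def compare_conditions(
    reps_a: Sequence[float],
    reps_b: Sequence[float],
    floor: float = DEFAULT_FLOOR,
    unchanged_threshold: float = 1.0,
) -> FoldCall:
    """Fold change of condition A over condition B from replicate window means."""
    if not reps_a or not reps_b:
        raise ValueError("at least one replicate required per condition")
    ma, mb = _pymean(reps_a), _pymean(reps_b)
    sa = float(np.std(reps_a, ddof=1)) if len(reps_a) > 1 else 0.0
    sb = float(np.std(reps_b, ddof=1)) if len(reps_b) > 1 else 0.0
    fold = (ma + floor) / (mb + floor)
    if max(fold, 1.0 / fold) <= unchanged_threshold:
        direction = "unchanged"
    else:
        direction = "up" if fold > 1 else ("unchanged" if fold == 1 else "down")
    return FoldCall(ma, mb, sa, sb, fold, direction)


def classify_fold(fold: float, thresholds: Sequence[float] = (1.5, 2.0, 5.0, 19.0)) -> Optional[float]:
    """Largest threshold exceeded by the fold change (either direction), or None."""
    magnitude = max(fold, 1.0 / fold)
    passed = [t for t in sorted(thresholds) if magnitude > t]
    return passed[-1] if passed else None


def region_occupancy(tracks: Sequence[CoverageTrack], region: GenomicInterval) -> float:
    """Mean over tracks of the mean coverage across a region's positions."""
    if not tracks:
        raise ValueError("at least one track required")
    per_track = [float(t.values[region.start : region.end].mean()) for t in tracks]
    return float(np.mean(per_track))


def genome_fraction(regions: Sequence[GenomicInterval], genome_length: int) -> float:
    """Fraction of the genome covered by the union of ``regions``."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if not regions:
        return 0.0
    for r in regions:
        if r.start < 0 or r.end > genome_length:
            raise ValueError(f"region [{r.start}, {r.end}) outside [0, {genome_length})")
    covered = sum(len(r) for r in merge_intervals(regions))
    return covered / genome_length
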