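"""Inferential procedures: overlap enrichment, rank comparison, the
Monte-Carlo roadblock test, and qPCR arithmetic.

* Binomial enrichment: are k of n binding sites inside a region class that
  covers a fraction p0 of the genome more often than chance? Upper-tail
  exact binomial by default (the hypothesis is directional).
* Mann-Whitney U: do two groups of ChIP scores differ in location? Exact
  p when the samples are tie-free and small, otherwise a tie-corrected
  normal approximation; one-sided and two-sided p-values are both reported.
* Roadblock test: given mean/SD summaries of polymerase occupancy upstream
  and downstream of an intragenic binding site in two genotypes, simulate
  occupancy draws and ask how often the downstream/upstream ratio is higher
  with the regulator deleted. Frequent increases indicate the bound factor
  was obstructing elongation (roadblock relief).
* Occupancy units and relative expression follow standard qPCR double-delta
  cycle-threshold arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats as sps

from .model import QPCRSummary


@dataclass(frozen=True)
class EnrichmentResult:
    """Binomial overlap-enrichment summary."""

    k: int
    n: int
    p0: float
    p_value: float
    enrichment: float  # observed/expected = k / (n * p0)
    alternative: str = "greater"


@dataclass(frozen=True)
class MannWhitneyResult:
    u_x: float
    u_y: float
    p_two_sided: float
    p_less: float  # P under H1: x stochastically smaller than y
    p_greater: float
    method: str  # 'exact' or 'asymptotic'

    @property
    def p_value(self) -> float:
        return self.p_two_sided


@dataclass(frozen=True)
class RoadblockResult:
    """Monte-Carlo roadblock-relief test result.

    ``per_repeat_p`` holds one p estimate per simulation repeat: the fraction
    of draws in which the downstream/upstream occupancy ratio did NOT rise in
    the deletion strain (orientation 'relief': small p = strong evidence the
    factor was roadblocking). ``p_estimate`` is their mean.
    """

    per_repeat_p: tuple
    n_draws: int
    orientation: str = "relief"

    @property
    def p_estimate(self) -> float:
        return float(np.mean(self.per_repeat_p))

    @property
    def fraction_mut_higher(self) -> float:
        return 1.0 - self.p_estimate


def binomial_enrichment(
    k: int, n: int, p0: float, alternative: str = "greater"
) -> EnrichmentResult:
    """Exact binomial test of k successes in n trials against rate p0.

    With ``alternative='greater'`` (default) the p-value is the upper tail
    P(X >= k) for X ~ Binomial(n, p0).
    """
    if not (0 < p0 < 1):
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    if not (0 <= k <= n):
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if alternative == "greater":
        p = float(sps.binom.sf(k - 1, n, p0))
    elif alternative == "less":
        p = float(sps.binom.cdf(k, n, p0))
    elif alternative == "two-sided":
        p = float(sps.binomtest(k, n, p0, alternative="two-sided").pvalue)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return EnrichmentResult(k, n, p0, min(p, 1.0), k / (n * p0), alternative)


_EXACT_LIMIT = 2000  # n*m at or below which a tie-free exact p is computed


def mann_whitney(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> MannWhitneyResult:
    """Mann-Whitney U comparison of two score samples.

    ``method='auto'`` uses the exact null distribution when both samples are
    tie-free and n*m <= 2000, else the normal approximation with midranks and
    tie-corrected variance. One-sided p-values for both directions and the
    two-sided p are all reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if method == "auto":
        method = "exact" if (not has_ties and len(x) * len(y) <= _EXACT_LIMIT) else "asymptotic"
    if method == "exact" and has_ties:
        raise ValueError("exact method is only defined for tie-free samples")
    res_two = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    res_less = sps.mannwhitneyu(x, y, alternative="less", method=method)
    res_greater = sps.mannwhitneyu(x, y, alternative="greater", method=method)
    u_x = float(res_two.statistic)
    return MannWhitneyResult(
        u_x=u_x,
        u_y=len(x) * len(y) - u_x,
        p_two_sided=float(res_two.pvalue),
        p_less=float(res_less.pvalue),
        p_greater=float(res_greater.pvalue),
        method=method,
    )


def _draw_truncated(
    rng: np.random.Generator, summary: QPCRSummary, size: int, floor: float
) -> np.ndarray:
    draws = rng.normal(summary.mean, summary.sd, size=size)
    return np.maximum(draws, floor)


def roadblock_test(
    up_wt: QPCRSummary,
    down_wt: QPCRSummary,
    up_mut: QPCRSummary,
    down_mut: QPCRSummary,
    n_draws: int = 1000,
    n_repeats: int = 10,
    seed: Union[int, np.random.Generator, None] = None,
    floor: float = 1e-6,
) -> RoadblockResult:
    """Monte-Carlo test for roadblock relief at an intragenic binding site.

    Per repeat, ``n_draws`` occupancy quadruples are drawn from normal
    distributions (mean/SD from the qPCR summaries, truncated below at
    ``floor``); the per-draw comparison is whether down/up is higher in the
    deletion strain than in the wild type. The reported p (orientation
    'relief') is the fraction of draws where it is NOT higher, averaged over
    repeats — small p means the deletion reproducibly raised downstream
    occupancy, as expected if the factor had been blocking elongation.
    """
    for s in (up_wt, down_wt, up_mut, down_mut):
        if s.mean <= 0:
            raise ValueError(f"{s.amplicon}: mean occupancy must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    per_repeat = []
    for _ in range(n_repeats):
        uw = _draw_truncated(rng, up_wt, n_draws, floor)
        dw = _draw_truncated(rng, down_wt, n_draws, floor)
        um = _draw_truncated(rng, up_mut, n_draws, floor)
        dm = _draw_truncated(rng, down_mut, n_draws, floor)
        frac_higher = float(np.mean((dm / um) > (dw / uw)))
        per_repeat.append(1.0 - frac_higher)
    return RoadblockResult(tuple(per_repeat), n_draws)


def occupancy_units(
    ct_chip_target: float,
    ct_input_target: float,
    ct_chip_ctrl: float,
    ct_input_ctrl: float,
) -> float:
    """Background-subtracted fold enrichment over a silent control region.

    ``2**((ct_chip_ctrl - ct_input_ctrl) - (ct_chip_target - ct_input_target)) - 1``:
    fold enrichment of the target amplicon relative to the control, minus one
    so a target indistinguishable from background scores 0.
    """
    fold = 2.0 ** ((ct_chip_ctrl - ct_input_ctrl) - (ct_chip_target - ct_input_target))
    return fold - 1.0


def delta_ct_expression(ct_target: float, ct_reference: float) -> float:
    """Relative expression by the delta-CT method: 2**(ct_ref - ct_target)."""
    return 2.0 ** (ct_reference - ct_target)
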