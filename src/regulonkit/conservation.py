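"""Cross-species binding-site conservation scoring.

Each E. coli binding site has, in some other species, a homologous region
(provided by an upstream orthology mapping, as FASTA keyed ``species|site``).
The conservation score of a (site, species) cell is the best PWM log-odds
match anywhere in that region, on either strand; a missing or too-short
region leaves the cell masked. Assembled over sites x species this gives the
conservation heat-map of the motif: functional promoter-proximal sites keep
strong matches across the clade, drifting intragenic sites do not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .motif import PWM


@dataclass
class ConservationMatrix:
    """Best-match scores per site (columns) and species (rows)."""

    scores: pd.DataFrame  # float scores, NaN where region missing
    groups: Optional[dict] = None  # site_id -> column group label

    @property
    def site_ids(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def species(self) -> list[str]:
        return list(self.scores.index)

    @property
    def missing(self) -> pd.DataFrame:
        return self.scores.isna()

    def normalized(self) -> pd.DataFrame:
        """Min-max normalization of present scores to [0, 1] for plotting."""
        vals = self.scores.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if finite.size == 0:
            return self.scores.copy()
        lo, hi = finite.min(), finite.max()
        if hi == lo:
            return self.scores * 0 + 1.0
        return (self.scores - lo) / (hi - lo)

    def group_mean(self, group: str) -> float:
        """Mean present score over all columns labeled ``group``."""
        if not self.groups:
            raise ValueError("no column groups defined")
        cols = [s for s, g in self.groups.items() if g == group]
        if not cols:
            raise ValueError(f"no sites in group {group!r}")
        return float(np.nanmean(self.scores[cols].to_numpy(dtype=float)))

    def to_tsv(self, path) -> None:
        self.scores.to_csv(path, sep="\t", na_rep="NA")

    def plot(self, ax=None):
        """Heat-map of min-max-normalized scores (white = missing region)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(max(6, len(self.site_ids) * 0.3), max(4, len(self.species) * 0.25)))
        norm = self.normalized().to_numpy(dtype=float)
        masked = np.ma.masked_invalid(norm)
        cmap = plt.get_cmap("cividis").copy()
        cmap.set_bad("white")
        im = ax.imshow(masked, aspect="auto", cmap=cmap, vmin=0, vmax=1)
        ax.set_xticks(range(len(self.site_ids)), self.site_ids, rotation=90, fontsize=6)
        ax.set_yticks(range(len(self.species)), self.species, fontsize=6)
        ax.figure.colorbar(im, ax=ax, label="normalized best match")
        return ax


def best_match(pwm: PWM, region: str) -> Optional[float]:
    """Maximum log-odds score over all windows of a region, both strands.

    Returns None when the region is shorter than the PWM width (a missing
    cell, not an error).
    """
    if region is None or len(region) < pwm.width:
        return None
    fwd = pwm.score_all(region)
    rev = pwm.reverse_complement().score_all(region)
    return float(max(fwd.max(), rev.max()))


def build_matrix(
    pwm: PWM,
    homolog_regions: Mapping[str, Mapping[str, Optional[str]]],
    site_ids: Optional[Sequence[str]] = None,
    groups: Optional[Mapping[str, str]] = None,
) -> ConservationMatrix:
    """Assemble the sites x species best-match matrix.

    ``homolog_regions`` maps species -> {site_id -> region sequence or None}.
    ``site_ids`` fixes column order (default: sorted union over species,
    grouped by ``groups`` label order when given); unknown site ids in any
    species mapping raise.
    """
    all_sites: set[str] = set()
    for mapping in homolog_regions.values():
        all_sites.update(mapping.keys())
    if site_ids is None:
        if groups:
            order = {g: i for i, g in enumerate(dict.fromkeys(groups.values()))}
            site_ids = sorted(all_sites, key=lambda s: (order.get(groups.get(s, ""), 99), s))
        else:
            site_ids = sorted(all_sites)
    else:
        unknown = all_sites - set(site_ids)
        if unknown:
            raise ValueError(f"unknown site ids in species mappings: {sorted(unknown)}")
    data = {}
    for species, mapping in homolog_regions.items():
        row = []
        for sid in site_ids:
            region = mapping.get(sid)
            score = best_match(pwm, region) if region else None
            row.append(np.nan if score is None else score)
        data[species] = row
    frame = pd.DataFrame.from_dict(data, orient="index", columns=list(site_ids))
    return ConservationMatrix(frame, groups=dict(groups) if groups else None)


def parse_homolog_fasta(sequences: Mapping[str, str]) -> dict[str, dict[str, str]]:
    """Regroup ``species|site_id`` FASTA records into the build_matrix input."""
    out: dict[str, dict[str, str]] = {}
    for header, seq in sequences.items():
        if "|" not in header:
            raise ValueError(f"homolog FASTA header {header!r} lacks 'species|site_id'")
        species, site_id = header.split("|", 1)
        out.setdefault(species, {})[site_id] = seq
    return out
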