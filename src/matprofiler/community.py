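"""Absolute-abundance scaling of layered mat communities.

Relative 16S amplicon abundances per mat layer are converted to absolute
cell densities by multiplying with total cell counts from fluorescence
microscopy:

    (cells/g)_taxon = (relative sequence abundance)_taxon * (total cells/g).

Taxa are then grouped into functional guilds (oxygenic photoautotrophs,
sulfate reducers, sulfur oxidizers) and contrasted between layer groups.
Taxonomy strings are opaque labels; no database lookups are performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical mat layers, surface to bottom
LAYER_ORDER: tuple[str, ...] = ("orange", "green", "brown", "black", "gray")

#: controlled guild vocabulary
GUILDS: tuple[str, ...] = ("cyanobacteria", "SRB", "SOB", "other")

_SUM_TOL = 1e-3


@dataclass
class LayerCommunity:
    """Relative taxon abundances plus the total cell count of one mat layer."""

    patch_id: str
    layer: str
    layer_index: int
    taxon_abundances: dict[str, float]
    total_cells_per_g: float

    def __post_init__(self) -> None:
        if self.total_cells_per_g < 0:
            raise ValueError("total_cells_per_g must be >= 0")
        vals = np.array(list(self.taxon_abundances.values()), dtype=float)
        if len(vals) == 0 or np.any(vals < 0):
            raise ValueError("taxon abundances must be non-empty and >= 0")
        if abs(vals.sum() - 1.0) > _SUM_TOL:
            raise ValueError(
                f"taxon abundances sum to {vals.sum():.6f}, not 1 "
                f"(layer {self.layer!r}, patch {self.patch_id!r})"
            )
        if self.layer in LAYER_ORDER and LAYER_ORDER.index(self.layer) != self.layer_index:
            raise ValueError(
                f"layer_index {self.layer_index} does not match layer {self.layer!r} "
                f"(expected {LAYER_ORDER.index(self.layer)})"
            )

    @property
    def sample_name(self) -> str:
        """``<patch>_<layerIndex>`` naming, e.g. ``I_0`` for the surface layer."""
        return f"{self.patch_id}_{self.layer_index}"


@dataclass
class GuildMap:
    """Taxon-to-guild assignment with a provenance note for the rule set."""

    mapping: dict[str, str]
    note: str = ""

    def __post_init__(self) -> None:
        bad = {g for g in self.mapping.values() if g not in GUILDS}
        if bad:
            raise ValueError(f"guild labels {sorted(bad)} not in the vocabulary {GUILDS}")

    def guild_of(self, taxon: str) -> str:
        return self.mapping.get(taxon, "other")


def scale_abundances(layer: LayerCommunity, renormalize: bool = False) -> dict[str, float]:
    """Absolute cell densities (cells per g) per taxon for one layer.

    The abundance vector must sum to 1 within 1e-3 unless ``renormalize``
    is set, in which case it is divided by its sum first.  The output sums
    to ``total_cells_per_g`` to floating tolerance.
    """
    vals = np.array(list(layer.taxon_abundances.values()), dtype=float)
    total = vals.sum()
    if abs(total - 1.0) > _SUM_TOL and not renormalize:
        raise ValueError(
            f"abundances sum to {total:.6f}; pass renormalize=True to rescale explicitly"
        )
    scale = layer.total_cells_per_g / total if renormalize else layer.total_cells_per_g
    return {t: a * scale for t, a in layer.taxon_abundances.items()}


def guild_summary(
    layers: Iterable[LayerCommunity],
    guilds: GuildMap,
    order: str = "scale_then_average",
) -> pd.DataFrame:
    """Layer x guild cell-density table, replicate layers averaged.

    ``order`` controls replicate handling: ``"scale_then_average"``
    (default) scales each replicate with its own total cell count and then
    averages the densities; ``"average_then_scale"`` averages abundances
    and totals per layer first.  The replicate count per layer is reported
    in the ``n`` column.  Unmapped taxa are binned as ``"other"`` and their
    count is logged.
    """
    layers = list(layers)
    if not layers:
        raise ValueError("no layers given")
    if order not in ("scale_then_average", "average_then_scale"):
        raise ValueError(f"unknown replicate order {order!r}")
    unmapped = {t for l in layers for t in l.taxon_abundances if t not in guilds.mapping}
    if unmapped:
        logger.info("%d taxa without guild assignment binned as 'other'", len(unmapped))

    by_layer: dict[str, list[LayerCommunity]] = {}
    for l in layers:
        by_layer.setdefault(l.layer, []).append(l)

    rows = {}
    for label, reps in by_layer.items():
        if order == "scale_then_average":
            per_rep = []
            for rep in reps:
                scaled = scale_abundances(rep)
                sums = dict.fromkeys(GUILDS, 0.0)
                for taxon, cells in scaled.items():
                    sums[guilds.guild_of(taxon)] += cells
                per_rep.append(sums)
            row = {g: float(np.mean([r[g] for r in per_rep])) for g in GUILDS}
        else:
            taxa = sorted({t for rep in reps for t in rep.taxon_abundances})
            mean_ab = {
                t: float(np.mean([rep.taxon_abundances.get(t, 0.0) for rep in reps]))
                for t in taxa
            }
            mean_total = float(np.mean([rep.total_cells_per_g for rep in reps]))
            row = dict.fromkeys(GUILDS, 0.0)
            for taxon, ab in mean_ab.items():
                row[guilds.guild_of(taxon)] += ab * mean_total
        row["n"] = len(reps)
        rows[label] = row

    index = [l for l in LAYER_ORDER if l in rows] + sorted(set(rows) - set(LAYER_ORDER))
    table = pd.DataFrame.from_dict(rows, orient="index").loc[index]
    table.index.name = "layer"
    return table[list(GUILDS) + ["n"]]


def layer_contrast(
    layers: Iterable[LayerCommunity],
    group_a: Sequence[str],
    group_b: Sequence[str],
    statistic: str = "midpoint_ratio",
) -> float:
    """Fold difference in total cell counts between two layer groups.

    ``midpoint_ratio`` compares the midpoints of each group's min-max
    range; ``mean_ratio`` compares group means.  Render the result with
    :func:`matprofiler.rates.format_fold`.
    """
    layers = list(layers)
    a = [l.total_cells_per_g for l in layers if l.layer in set(group_a)]
    b = [l.total_cells_per_g for l in layers if l.layer in set(group_b)]
    if not a or not b:
        raise ValueError("both layer groups must match at least one layer")
    if statistic == "midpoint_ratio":
        num = 0.5 * (min(a) + max(a))
        den = 0.5 * (min(b) + max(b))
    elif statistic == "mean_ratio":
        num, den = float(np.mean(a)), float(np.mean(b))
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    if den <= 0:
        raise ValueError("denominator group has non-positive cell counts")
    return num / den
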