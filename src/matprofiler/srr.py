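"""Sulfate reduction rates from 35S radiotracer syringe-core sections.

Each core section yields the activity recovered in the total reducible
inorganic sulfur pool (TRIS, ``a``) and the residual sulfate activity
(``A``).  The standard single-step radiotracer rate equation

    SRR = [SO4^2-] * phi * (a / (a + A)) * 1.06 / t

converts the turned-over tracer fraction into a sulfate reduction rate in
mol m^-3 sediment s^-1 ([SO4^2-] is the porewater concentration; the
porosity factor phi converts to a whole-sediment volume basis; 1.06 is the
isotope fractionation correction; t the incubation time in seconds).

Blanks, killed immediately after tracer addition, carry the instrument and
chemistry background; the minimum detection limit (MDL) is the mean plus
three standard deviations of the blank-derived apparent rates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

#: isotope fractionation correction for 35S sulfate reduction
ISOTOPE_FRACTIONATION = 1.06

_TILING_TOL_MM = 1e-6


@dataclass
class TracerSample:
    """One 35S syringe-core section with activities and incubation context."""

    core_id: str
    section_top_mm: float
    section_bottom_mm: float
    section_volume_ml: float
    tris_activity_kbq: float
    residual_sulfate_activity_kbq: float
    sulfate_mol_m3: float
    porosity: float
    incubation_time_s: float
    is_blank: bool = False

    def __post_init__(self) -> None:
        if self.tris_activity_kbq < 0 or self.residual_sulfate_activity_kbq < 0:
            raise ValueError("activities must be >= 0")
        if self.section_bottom_mm <= self.section_top_mm:
            raise ValueError("section_bottom_mm must exceed section_top_mm")
        if not self.is_blank:
            if self.incubation_time_s <= 0:
                raise ValueError("incubation_time_s must be > 0 for non-blank samples")
            if self.tris_activity_kbq + self.residual_sulfate_activity_kbq <= 0:
                raise ValueError("a + A must be > 0 for non-blank samples")
        if not (0 < self.porosity <= 1):
            raise ValueError("porosity must lie in (0, 1]")

    @property
    def depth_mid_mm(self) -> float:
        return 0.5 * (self.section_top_mm + self.section_bottom_mm)


@dataclass
class SRRResult:
    """Sulfate reduction rate of one section (mol m^-3 sediment s^-1)."""

    core_id: str
    section_top_mm: float
    section_bottom_mm: float
    rate: float
    below_mdl: bool = False

    @property
    def depth_mid_mm(self) -> float:
        return 0.5 * (self.section_top_mm + self.section_bottom_mm)


def compute_srr(sample: TracerSample, fractionation: float = ISOTOPE_FRACTIONATION) -> SRRResult:
    """Sulfate reduction rate of one tracer section.

    Raises if the sample is a blank (use :func:`detection_limit`) or if no
    activity was recovered at all.
    """
    if sample.is_blank:
        raise ValueError("sample is a blank; blanks enter detection_limit, not compute_srr")
    a = sample.tris_activity_kbq
    total = a + sample.residual_sulfate_activity_kbq
    if total <= 0:
        raise ValueError("no recovered activity (a + A = 0)")
    rate = (
        sample.sulfate_mol_m3
        * sample.porosity
        * (a / total)
        * fractionation
        / sample.incubation_time_s
    )
    return SRRResult(sample.core_id, sample.section_top_mm, sample.section_bottom_mm, rate)


def detection_limit(
    blanks: Iterable[TracerSample],
    sulfate_mol_m3: float,
    porosity: float,
    incubation_time_s: float,
    multiplier: float = 3.0,
    fractionation: float = ISOTOPE_FRACTIONATION,
) -> float:
    """Minimum detection limit from blank samples (mol m^-3 s^-1).

    Apparent rates are computed for every blank with the same rate equation
    and the supplied context parameters; the MDL is their mean plus
    ``multiplier`` (default 3) sample standard deviations.
    """
    blanks = list(blanks)
    if len(blanks) < 2:
        raise ValueError("at least 2 blanks are required to estimate the MDL")
    apparent = []
    for b in blanks:
        total = b.tris_activity_kbq + b.residual_sulfate_activity_kbq
        if total <= 0:
            raise ValueError("blank with no recovered activity (a + A = 0)")
        apparent.append(
            sulfate_mol_m3
            * porosity
            * (b.tris_activity_kbq / total)
            * fractionation
            / incubation_time_s
        )
    apparent = np.asarray(apparent)
    return float(apparent.mean() + multiplier * apparent.std(ddof=1))


def censor_rates(results: Iterable[SRRResult], mdl: float) -> list[SRRResult]:
    """Flag rates below the MDL; censored values are retained, not zeroed.

    The number of censored sections is ``sum(r.below_mdl for r in out)``.
    """
    if mdl < 0:
        raise ValueError("mdl must be >= 0")
    return [replace(r, below_mdl=bool(r.rate < mdl)) for r in results]


def _validate_tiling(sections: list[SRRResult], horizon_mm: float) -> None:
    offenders = []
    if abs(sections[0].section_top_mm) > _TILING_TOL_MM:
        offenders.append(f"first section starts at {sections[0].section_top_mm} mm, not 0")
    for prev, nxt in zip(sections, sections[1:]):
        gap = nxt.section_top_mm - prev.section_bottom_mm
        if abs(gap) > _TILING_TOL_MM:
            kind = "gap" if gap > 0 else "overlap"
            offenders.append(
                f"{kind} of {abs(gap):g} mm between sections ending {prev.section_bottom_mm} "
                f"and starting {nxt.section_top_mm}"
            )
    if sections[-1].section_bottom_mm < horizon_mm - _TILING_TOL_MM:
        offenders.append(
            f"sections end at {sections[-1].section_bottom_mm} mm, "
            f"short of the {horizon_mm} mm horizon"
        )
    if offenders:
        raise ValueError("invalid core sectioning: " + "; ".join(offenders))


def _weighted_avg(sections: list[SRRResult], lo: float, hi: float) -> float:
    w = np.array(
        [
            max(0.0, min(s.section_bottom_mm, hi) - max(s.section_top_mm, lo))
            for s in sections
        ]
    )
    r = np.array([s.rate for s in sections])
    if w.sum() <= 0:
        raise ValueError(f"no section overlaps the interval [{lo}, {hi}] mm")
    return float(np.sum(r * w) / np.sum(w))


def depth_aggregate(
    results: Iterable[SRRResult],
    mat_bottom_mm: float,
    horizon_mm: float = 30.0,
) -> dict[str, float]:
    """Average SRR over the mat and over the full horizon (default 3 cm).

    Sections of each core must tile ``[0, horizon]`` without gaps or
    overlaps (the canonical layout is a 3.2-mm top slice followed by 8-mm
    slices, but any tiling is accepted).  Averages are weighted by the
    overlap length of each section with the target interval; with multiple
    cores, per-core averages are combined with an unweighted mean.
    """
    results = list(results)
    if not results:
        raise ValueError("no SRR results to aggregate")
    cores: dict[str, list[SRRResult]] = {}
    for r in results:
        cores.setdefault(r.core_id, []).append(r)
    mat_avgs, horizon_avgs = [], []
    for sections in cores.values():
        sections = sorted(sections, key=lambda s: s.section_top_mm)
        _validate_tiling(sections, horizon_mm)
        mat_avgs.append(_weighted_avg(sections, 0.0, mat_bottom_mm))
        horizon_avgs.append(_weighted_avg(sections, 0.0, horizon_mm))
    return {
        "mat_avg": float(np.mean(mat_avgs)),
        "horizon_avg": float(np.mean(horizon_avgs)),
        "n_cores": len(cores),
    }
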