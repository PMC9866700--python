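"""Targeted MS2 screening of DDA runs against the compound library.

A spectrum is annotated as a library compound only if it passes four
gates simultaneously:

1. precursor mass: |observed - target| below 15 ppm, with an absolute
   tolerance floor of 0.0010 Da;
2. retention time: |observed - target| below 2% of the target RT, clamped
   to the [0.05, 0.15] min band;
3. fragment recall: more than 2/3 of the reference fragments (those with
   relative intensity >= 1% of base peak) found within the fragment mass
   tolerance;
4. fragment intensity: for every matched fragment, the base-peak
   normalized percentages differ by fewer than 15 percentage points.

Reference spectra are renormalized to their own base peak before the
intensity comparison (a few published fragment lists top out below 100%).
Scans matching the same compound within one chromatographic peak are then
grouped: intensities are summed and each merged fragment m/z is the
intensity-weighted mean of its members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .formula import ppm_error
from .io import MS2Scan, read_mgf
from .library import CompoundLibrary, CompoundRecord

__all__ = [
    "ScreeningConfig",
    "SpectrumMatch",
    "GroupedSpectrum",
    "mass_tolerance",
    "rt_tolerance",
    "match_spectrum",
    "screen_run",
    "group_scans",
]


@dataclass(frozen=True)
class ScreeningConfig:
    """Gate thresholds; defaults are the published screening criteria."""

    precursor_ppm_max: float = 15.0
    precursor_da_floor: float = 0.0010
    rt_rel_max: float = 0.02
    rt_abs_floor_min: float = 0.05
    rt_abs_ceiling_min: float = 0.15
    fragment_match_min_fraction: float = 2.0 / 3.0
    intensity_err_max: float = 15.0
    fragment_ppm_max: float = 15.0
    fragment_da_floor: float = 0.0010
    #: reference fragments below this relative intensity (percent) are
    #: ignored as trace ions when computing the matched fraction
    ref_intensity_floor: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.fragment_match_min_fraction <= 1):
            raise ValueError("fragment_match_min_fraction must be in (0, 1]")
        for name in ("precursor_ppm_max", "precursor_da_floor", "rt_rel_max",
                     "rt_abs_floor_min", "rt_abs_ceiling_min",
                     "intensity_err_max", "fragment_ppm_max", "fragment_da_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def scaled(self, factor: float) -> "ScreeningConfig":
        """All thresholds multiplied by ``factor`` (>1 loosens every gate)."""
        return ScreeningConfig(
            precursor_ppm_max=self.precursor_ppm_max * factor,
            precursor_da_floor=self.precursor_da_floor * factor,
            rt_rel_max=self.rt_rel_max * factor,
            rt_abs_floor_min=self.rt_abs_floor_min * factor,
            rt_abs_ceiling_min=self.rt_abs_ceiling_min * factor,
            fragment_match_min_fraction=min(1.0, self.fragment_match_min_fraction / factor),
            intensity_err_max=self.intensity_err_max * factor,
            fragment_ppm_max=self.fragment_ppm_max * factor,
            fragment_da_floor=self.fragment_da_floor * factor,
            ref_intensity_floor=self.ref_intensity_floor,
        )


def mass_tolerance(mz: float, ppm: float, da_floor: float) -> float:
    """Absolute mass tolerance: ppm-scaled with a Da floor."""
    return max(ppm * 1e-6 * mz, da_floor)


def rt_tolerance(target_rt: float, config: ScreeningConfig) -> float:
    """RT tolerance in minutes: 2% of target RT clamped to [floor, ceiling]."""
    return min(max(config.rt_rel_max * target_rt, config.rt_abs_floor_min),
               config.rt_abs_ceiling_min)


@dataclass(frozen=True)
class SpectrumMatch:
    """Screening verdict for one (scan, target) pair with per-gate diagnostics."""

    compound_id: int
    scan: MS2Scan
    precursor_ppm: float
    rt_error_min: float
    matched_fraction: float
    max_intensity_err: float
    passed: bool


@dataclass
class GroupedSpectrum:
    """Scans merged within one chromatographic peak.

    ``fragments`` holds (intensity-weighted mean m/z, summed intensity)
    clusters pooled across the member scans; ``apex_rt`` is the RT of the
    most intense member scan.
    """

    compound_id: int
    members: list[SpectrumMatch]
    fragments: list[tuple[float, float]]
    apex_rt: float


def _normalized_reference(target: CompoundRecord, floor: float) -> list[tuple[float, float]]:
    """Reference fragments above the trace floor, rescaled to base peak 100."""
    if not target.fragments:
        raise ValueError(f"compound {target.id} has an empty fragment list")
    top = max(rel for _mz, rel in target.fragments)
    ref = [(mz, rel * 100.0 / top) for mz, rel in target.fragments]
    return [(mz, rel) for mz, rel in ref if rel >= floor]


def match_spectrum(
    scan: MS2Scan, target: CompoundRecord, config: ScreeningConfig | None = None
) -> SpectrumMatch:
    """Evaluate the four screening gates for one scan against one target."""
    config = config or ScreeningConfig()
    if scan.mz.size == 0:
        raise ValueError("scan has no fragments")

    prec_ppm = ppm_error(scan.precursor_mz, target.exact_mz)
    prec_tol = mass_tolerance(target.exact_mz, config.precursor_ppm_max,
                              config.precursor_da_floor)
    prec_ok = abs(scan.precursor_mz - target.exact_mz) < prec_tol

    rt_err = abs(scan.rt_min - target.rt_min)
    rt_ok = rt_err < rt_tolerance(target.rt_min, config)

    ref = _normalized_reference(target, config.ref_intensity_floor)
    query_rel = scan.relative_intensities()
    matched_pairs: list[tuple[float, float]] = []  # (ref %, query %)
    for rmz, rrel in ref:
        tol = mass_tolerance(rmz, config.fragment_ppm_max, config.fragment_da_floor)
        close = np.abs(scan.mz - rmz) < tol
        if close.any():
            matched_pairs.append((rrel, float(query_rel[close].max())))
    frac = len(matched_pairs) / len(ref)
    frac_ok = frac > config.fragment_match_min_fraction

    max_int_err = max((abs(q - r) for r, q in matched_pairs), default=math.nan)
    int_ok = bool(matched_pairs) and max_int_err < config.intensity_err_max

    return SpectrumMatch(
        compound_id=target.id,
        scan=scan,
        precursor_ppm=prec_ppm,
        rt_error_min=rt_err,
        matched_fraction=frac,
        max_intensity_err=max_int_err,
        passed=prec_ok and rt_ok and frac_ok and int_ok,
    )


def screen_run(
    scans: Iterable[MS2Scan] | str | Path,
    library: CompoundLibrary,
    config: ScreeningConfig | None = None,
) -> list[SpectrumMatch]:
    """Screen every MS2 scan against every library compound.

    ``scans`` may be a path to an MGF file or an iterable of scans.
    Returns passed matches only, ordered by (compound id, scan RT); a scan
    that satisfies all gates for several targets is reported for each.
    """
    config = config or ScreeningConfig()
    if isinstance(scans, (str, Path)):
        scans = read_mgf(scans)
    hits = []
    for scan in scans:
        if scan.mz.size == 0:
            continue
        for rec in library:
            # cheap precursor prefilter before the full gate evaluation
            if abs(scan.precursor_mz - rec.exact_mz) > 1.0:
                continue
            m = match_spectrum(scan, rec, config)
            if m.passed:
                hits.append(m)
    hits.sort(key=lambda m: (m.compound_id, m.scan.rt_min, m.scan.precursor_mz))
    return hits


def _cluster_fragments(
    peaks: Sequence[tuple[float, float]], config: ScreeningConfig
) -> list[tuple[float, float]]:
    """Greedy m/z clustering of pooled fragment peaks.

    Peaks sorted by m/z join the current cluster while they stay within
    the fragment tolerance of its running intensity-weighted mean.
    """
    merged: list[tuple[float, float]] = []
    cur_wsum = cur_isum = 0.0
    for mz, inten in sorted(peaks):
        if cur_isum > 0:
            mean = cur_wsum / cur_isum
            tol = mass_tolerance(mean, config.fragment_ppm_max, config.fragment_da_floor)
            if abs(mz - mean) >= tol:
                merged.append((mean, cur_isum))
                cur_wsum = cur_isum = 0.0
        cur_wsum += mz * inten
        cur_isum += inten
    if cur_isum > 0:
        merged.append((cur_wsum / cur_isum, cur_isum))
    return merged


def group_scans(
    matches: Sequence[SpectrumMatch],
    rt_window: float = 0.1,
    config: ScreeningConfig | None = None,
) -> GroupedSpectrum:
    """Merge passed matches of one compound found in the same peak.

    The best match (highest matched fraction, then smallest precursor
    error) anchors the group; members within ``rt_window`` minutes of it
    are summed, with merged fragment m/z values recomputed as
    intensity-weighted means sum(int_i * mz_i) / sum(int_i).
    """
    config = config or ScreeningConfig()
    if not matches:
        raise ValueError("group_scans requires at least one match")
    ids = {m.compound_id for m in matches}
    if len(ids) != 1:
        raise ValueError(f"matches must share one compound id, got {sorted(ids)}")

    best = max(matches, key=lambda m: (m.matched_fraction, -abs(m.precursor_ppm)))
    members = [m for m in matches if abs(m.scan.rt_min - best.scan.rt_min) <= rt_window]
    pooled = [
        (float(mz), float(inten))
        for m in members
        for mz, inten in zip(m.scan.mz, m.scan.intensity)
    ]
    apex = max(members, key=lambda m: m.scan.base_peak).scan.rt_min
    return GroupedSpectrum(
        compound_id=best.compound_id,
        members=members,
        fragments=_cluster_fragments(pooled, config),
        apex_rt=apex,
    )
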