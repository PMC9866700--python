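"""Seeded generator of negative-mode DDA LC-MS runs with known ground truth.

Emulates the acquisition used for the Senecioneae extracts -- full scans
over m/z 100-1000 in negative mode with data-dependent MS2 of the library
compounds at their library retention times -- so the screening and
quantification stages can be exercised against a planted answer.

Each planted compound contributes a Gaussian chromatographic peak whose
area equals its ground-truth abundance; MS2 scans near each peak apex
carry the library fragment list with multiplicative intensity noise and
ppm-scale m/z jitter. Decoy precursors (kept >=25 ppm away from every
library mass) exercise the false-positive side of the screen.

Generation is a pure function of (library, truth, settings, species,
seed): the same inputs give byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import MS2Scan, read_mgf, read_ms1, read_truth, write_mgf, write_ms1, write_truth
from .library import SPECIES_ORDER, CompoundLibrary, load_table2

__all__ = [
    "PEAK_SIGMA_MIN",
    "AcquisitionSettings",
    "GroundTruth",
    "SyntheticRun",
    "generate_run",
    "write_run",
    "read_run",
]

#: Chromatographic peak width (Gaussian sigma, minutes). A typical UHPLC
#: peak; narrow enough to resolve the closest same-mass isomer pair in the
#: library (0.09 min apart), as the published chromatography did.
PEAK_SIGMA_MIN = 0.015

#: Decoy precursors are kept at least this many ppm from every library mass,
#: so any decoy passing the screen would indicate a logic error, not bad luck.
DECOY_MIN_PPM = 25.0


@dataclass(frozen=True)
class AcquisitionSettings:
    """Instrument-level constants of the emulated acquisition."""

    mz_range: tuple[float, float] = (100.0, 1000.0)
    scan_interval_s: float = 0.3
    rt_span_min: tuple[float, float] = (0.0, 13.0)
    peak_sigma_min: float = PEAK_SIGMA_MIN

    def __post_init__(self) -> None:
        if self.mz_range[0] >= self.mz_range[1]:
            raise ValueError("mz_range low must be below high")
        if self.scan_interval_s <= 0:
            raise ValueError("scan_interval_s must be positive")

    def rt_grid(self) -> np.ndarray:
        lo, hi = self.rt_span_min
        step = self.scan_interval_s / 60.0
        return np.arange(lo, hi + step / 2, step)


@dataclass(frozen=True)
class GroundTruth:
    """Planted per-species abundances plus noise magnitudes.

    ``abundance`` is a compound x species DataFrame of true peak areas
    (arbitrary units, >= 0); zero means the compound is absent from that
    extract. Noise defaults are package choices documented in the methods
    note; the paper reports none.
    """

    abundance: pd.DataFrame
    rt_shift_sd: float = 0.02
    mz_jitter_ppm: float = 3.0
    fragment_intensity_cv: float = 0.10
    decoy_count: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.abundance.empty or not len(self.abundance.columns):
            raise ValueError("abundance matrix must be non-empty")
        if (self.abundance.values < 0).any():
            raise ValueError("abundances must be non-negative")

    @property
    def species(self) -> list[str]:
        return list(self.abundance.columns)

    @classmethod
    def from_table2(cls, scale: float = 1000.0, seed: int = 0, **kw) -> "GroundTruth":
        """Ground truth with areas = published normalized AUC x ``scale``.

        Preserves the published zero pattern, so pipeline recovery can be
        checked cell-by-cell against the printed matrix.
        """
        t2 = load_table2()
        abundance = t2[SPECIES_ORDER].astype(float) * scale
        return cls(abundance=abundance, seed=seed, **kw)

    def low_noise(self) -> "GroundTruth":
        """Variant with noise magnitudes small enough that every screening
        gate is comfortably inside its threshold (used for recovery tests)."""
        return replace(
            self, rt_shift_sd=0.005, mz_jitter_ppm=1.0, fragment_intensity_cv=0.02
        )


@dataclass
class SyntheticRun:
    """One simulated LC-MS run (a single species extract)."""

    label: str
    ms1_scans: list[tuple[float, np.ndarray, np.ndarray]]
    ms2_scans: list[MS2Scan]
    truth: dict[int, float]  # compound id -> planted area
    settings: AcquisitionSettings = field(default_factory=AcquisitionSettings)
    seed: int = 0


def _gaussian(rt: np.ndarray, apex: float, sigma: float, area: float) -> np.ndarray:
    return area / (sigma * math.sqrt(2 * math.pi)) * np.exp(-0.5 * ((rt - apex) / sigma) ** 2)


def _species_rng(seed: int, species_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(species_index,)))


def generate_run(
    library: CompoundLibrary,
    truth: GroundTruth,
    settings: AcquisitionSettings,
    species: str,
) -> SyntheticRun:
    """Simulate one run for ``species`` from the planted abundance column."""
    if species not in truth.species:
        raise ValueError(f"species {species!r} not in ground truth columns {truth.species}")
    col = truth.abundance[species]
    unknown = [cid for cid in col.index if cid not in library.by_id]
    if unknown:
        raise ValueError(f"abundance rows refer to unknown compound ids: {unknown}")

    rng = _species_rng(truth.seed, truth.species.index(species))
    sigma = settings.peak_sigma_min
    rt_grid = settings.rt_grid()
    lo_mz, hi_mz = settings.mz_range

    # retention drift is mostly a run-level offset (the whole gradient moves);
    # a smaller per-compound jitter perturbs the spacing between peaks
    run_shift = rng.normal(0.0, truth.rt_shift_sd)
    planted: list[tuple[int, float, float]] = []  # (id, apex rt, area)
    for cid, area in col.items():
        if area <= 0:
            continue
        rec = library[int(cid)]
        apex = rec.rt_min + run_shift + rng.normal(0.0, truth.rt_shift_sd / 5.0)
        planted.append((int(cid), apex, float(area)))

    # --- MS1: per-scan stick spectra sampling each compound's Gaussian ---
    ms1_scans: list[tuple[float, np.ndarray, np.ndarray]] = []
    profiles = {
        cid: _gaussian(rt_grid, apex, sigma, area) for cid, apex, area in planted
    }
    for i, rt in enumerate(rt_grid):
        mzs, ints = [], []
        for cid, apex, _area in planted:
            inten = profiles[cid][i]
            if inten < 1e-3 or abs(rt - apex) > 6 * sigma:
                continue
            mz = library[cid].exact_mz
            mz *= 1.0 + rng.normal(0.0, truth.mz_jitter_ppm) * 1e-6
            if lo_mz <= mz <= hi_mz:
                mzs.append(mz)
                ints.append(inten)
        if not mzs:
            continue  # empty scans carry no information and would not round-trip
        order = np.argsort(mzs, kind="stable")
        ms1_scans.append(
            (float(rt), np.asarray(mzs, dtype=float)[order], np.asarray(ints, dtype=float)[order])
        )

    # --- MS2: one scan at each planted apex plus up to two within +/-1 sigma ---
    ms2_scans: list[MS2Scan] = []
    for cid, apex, area in planted:
        rec = library[cid]
        n_extra = int(rng.integers(0, 3))
        offsets = [0.0] + [float(rng.uniform(-sigma, sigma)) for _ in range(n_extra)]
        for k, off in enumerate(offsets):
            rt = apex + off
            height = _gaussian(np.array([rt]), apex, sigma, area)[0]
            frag_mz, frag_int = [], []
            for mz, rel in rec.fragments:
                jmz = mz * (1.0 + rng.normal(0.0, truth.mz_jitter_ppm) * 1e-6)
                noise = max(1e-3, 1.0 + rng.normal(0.0, truth.fragment_intensity_cv))
                frag_mz.append(jmz)
                frag_int.append(rel / 100.0 * height * noise)
            prec = rec.exact_mz * (1.0 + rng.normal(0.0, truth.mz_jitter_ppm) * 1e-6)
            ms2_scans.append(
                MS2Scan(
                    rt_min=rt,
                    precursor_mz=prec,
                    mz=np.asarray(frag_mz),
                    intensity=np.asarray(frag_int),
                    title=f"run={species} compound={cid} sub={k}",
                )
            )

    # --- decoys: random precursors kept away from every library mass ---
    lib_mz = np.array([r.exact_mz for r in library])
    for d in range(truth.decoy_count):
        while True:
            prec = float(rng.uniform(lo_mz, hi_mz))
            if np.min(np.abs(prec - lib_mz) / lib_mz) * 1e6 >= DECOY_MIN_PPM:
                break
        rt = float(rng.uniform(*settings.rt_span_min))
        n_frag = int(rng.integers(5, 11))
        fmz = np.sort(rng.uniform(lo_mz, max(prec, lo_mz + 1.0), n_frag))
        fint = rng.uniform(1.0, 80.0, n_frag)
        fint[int(rng.integers(0, n_frag))] = 100.0
        fint *= float(rng.uniform(1e3, 1e5)) / 100.0
        ms2_scans.append(
            MS2Scan(rt_min=rt, precursor_mz=prec, mz=fmz, intensity=fint,
                    title=f"run={species} decoy={d}")
        )

    ms2_scans.sort(key=lambda s: (s.rt_min, s.precursor_mz))
    return SyntheticRun(
        label=species,
        ms1_scans=ms1_scans,
        ms2_scans=ms2_scans,
        truth={cid: area for cid, _apex, area in planted},
        settings=settings,
        seed=truth.seed,
    )


def write_run(run: SyntheticRun, outdir: str | Path) -> dict[str, Path]:
    """Write ``<label>.mgf``, ``<label>.ms1.tsv`` and ``<label>.truth.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mgf": write_mgf(run.ms2_scans, outdir / f"{run.label}.mgf"),
        "ms1": write_ms1(run.ms1_scans, outdir / f"{run.label}.ms1.tsv"),
        "truth": write_truth(
            {
                "label": run.label,
                "seed": run.seed,
                "areas": {str(k): v for k, v in run.truth.items()},
            },
            outdir / f"{run.label}.truth.json",
        ),
    }
    return paths


def read_run(outdir: str | Path, label: str) -> SyntheticRun:
    """Read a run written by :func:`write_run` back into memory."""
    outdir = Path(outdir)
    ms2 = read_mgf(outdir / f"{label}.mgf")
    df = read_ms1(outdir / f"{label}.ms1.tsv")
    ms1 = [
        (float(g["rt_min"].iloc[0]), g["mz"].to_numpy(), g["intensity"].to_numpy())
        for _scan, g in df.groupby("scan", sort=True)
    ]
    truth = read_truth(outdir / f"{label}.truth.json")
    return SyntheticRun(
        label=label,
        ms1_scans=ms1,
        ms2_scans=ms2,
        truth={int(k): v for k, v in truth["areas"].items()},
        seed=int(truth["seed"]),
    )
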