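"""Run file formats: MGF for MS2 spectra, a plain TSV for MS1 scans.

The MGF writer emits a deterministic byte layout (fixed float formatting,
scans in ascending retention time) so identically-seeded simulations
produce identical files; reading goes through pyteomics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

__all__ = ["MS2Scan", "write_mgf", "read_mgf", "write_ms1", "read_ms1"]


@dataclass
class MS2Scan:
    """One data-dependent MS2 spectrum (singly deprotonated precursor)."""

    rt_min: float
    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray
    title: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("fragment m/z and intensity arrays differ in length")

    @property
    def base_peak(self) -> float:
        return float(self.intensity.max()) if self.intensity.size else 0.0

    def relative_intensities(self) -> np.ndarray:
        """Intensities as percent of the base peak."""
        bp = self.base_peak
        return self.intensity * (100.0 / bp) if bp > 0 else self.intensity


def write_mgf(scans: list[MS2Scan], path: str | Path) -> Path:
    """Write MS2 scans to MGF (TITLE, RTINSECONDS, PEPMASS, CHARGE=1-)."""
    path = Path(path)
    with open(path, "w") as fh:
        for scan in sorted(scans, key=lambda s: (s.rt_min, s.precursor_mz)):
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={scan.title}\n")
            fh.write(f"RTINSECONDS={scan.rt_min * 60.0:.4f}\n")
            fh.write(f"PEPMASS={scan.precursor_mz:.5f}\n")
            fh.write("CHARGE=1-\n")
            for mz, inten in zip(scan.mz, scan.intensity):
                fh.write(f"{mz:.5f} {inten:.3f}\n")
            fh.write("END IONS\n")
    return path


def read_mgf(path: str | Path) -> list[MS2Scan]:
    """Read an MGF file via pyteomics into :class:`MS2Scan` objects."""
    scans = []
    with _mgf.MGF(str(path)) as reader:
        for idx, spec in enumerate(reader):
            params = spec["params"]
            try:
                rt = float(params["rtinseconds"]) / 60.0
                prec = float(params["pepmass"][0])
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"corrupt MGF scan at index {idx} in {path}") from exc
            scans.append(
                MS2Scan(
                    rt_min=rt,
                    precursor_mz=prec,
                    mz=spec["m/z array"],
                    intensity=spec["intensity array"],
                    title=str(params.get("title", "")),
                )
            )
    return scans


def write_ms1(scans: list[tuple[float, np.ndarray, np.ndarray]], path: str | Path) -> Path:
    """Write MS1 scans as TSV with columns scan, rt_min, mz, intensity.

    ``scans`` is a list of (rt_min, mz array, intensity array), one entry
    per full scan; empty scans are recorded with no rows.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("scan\trt_min\tmz\tintensity\n")
        for i, (rt, mz, inten) in enumerate(scans):
            for m, x in zip(mz, inten):
                fh.write(f"{i}\t{rt:.4f}\t{m:.5f}\t{x:.3f}\n")
    return path


def read_ms1(path: str | Path) -> pd.DataFrame:
    """Read the MS1 TSV into a DataFrame sorted by (scan, mz)."""
    df = pd.read_csv(path, sep="\t")
    expected = ["scan", "rt_min", "mz", "intensity"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, found {list(df.columns)}")
    return df.sort_values(["scan", "mz"], kind="stable").reset_index(drop=True)


def write_truth(truth: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return path


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
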