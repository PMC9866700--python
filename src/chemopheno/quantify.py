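"""XIC integration and assembly of the compound x species abundance matrix.

For every screened compound the MS1 trace within a narrow m/z tolerance
is extracted around the annotated peak apex and integrated by the
trapezoidal rule. Raw areas are normalized per compound (row) to a 0-100
scale -- 100 marks the species with the highest signal, 0 marks
non-detection -- mirroring the published relative-abundance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import read_ms1
from .library import SPECIES_BY_LETTER, CompoundLibrary
from .screening import ScreeningConfig, group_scans, mass_tolerance, screen_run

__all__ = [
    "XIC",
    "AbundanceMatrix",
    "extract_xic",
    "integrate_auc",
    "normalize_rows",
    "filter_min_species",
    "distribution_letters",
    "quantify_runs",
]

#: Default integration half-window (min): 2 x the generator's peak sigma.
#: Narrow enough that the closest same-mass neighbours in the library RT
#: ladder (0.06 min apart) do not bleed into each other's window; the
#: uniform truncation of the Gaussian tails cancels in row normalization.
DEFAULT_RT_HALF_WINDOW = 0.030


@dataclass
class XIC:
    """Extracted ion chromatogram for one target m/z."""

    compound_id: int
    rt: np.ndarray
    intensity: np.ndarray
    tol_da: float

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.size and (np.diff(self.rt) <= 0).any():
            raise ValueError("XIC retention times must be strictly increasing")
        if (self.intensity < 0).any():
            raise ValueError("XIC intensities must be non-negative")


def extract_xic(
    ms1: pd.DataFrame,
    target_mz: float,
    apex_rt: float,
    compound_id: int = 0,
    ppm: float = 15.0,
    da_floor: float = 0.0010,
    rt_half_window: float = DEFAULT_RT_HALF_WINDOW,
) -> XIC:
    """Per-scan summed intensity within tolerance of ``target_mz``.

    ``ms1`` is the scan table from :func:`chemopheno.io.read_ms1`
    (columns scan, rt_min, mz, intensity). Scans inside the RT window with
    no peak near the target contribute explicit zeros so the trace
    integrates over a complete grid.
    """
    if ms1.empty:
        raise ValueError("empty MS1 scan table")
    tol = mass_tolerance(target_mz, ppm, da_floor)
    window = ms1[np.abs(ms1["rt_min"] - apex_rt) <= rt_half_window]
    rts, values = [], []
    for _scan, g in window.groupby("scan", sort=True):
        sel = np.abs(g["mz"].to_numpy() - target_mz) < tol
        rts.append(float(g["rt_min"].iloc[0]))
        values.append(float(g["intensity"].to_numpy()[sel].sum()))
    order = np.argsort(rts)
    return XIC(
        compound_id=compound_id,
        rt=np.asarray(rts)[order],
        intensity=np.asarray(values)[order],
        tol_da=tol,
    )


def integrate_auc(xic: XIC, subtract_baseline: bool = False) -> float:
    """Trapezoidal area under the XIC (RT in minutes x intensity).

    ``subtract_baseline`` removes the minimum intensity inside the window
    first (useful on data with a nonzero baseline offset).
    """
    if xic.rt.size < 2:
        raise ValueError("integration requires at least 2 XIC points")
    y = xic.intensity
    if subtract_baseline:
        y = y - y.min()
    return float(max(np.trapezoid(y, xic.rt), 0.0))


@dataclass
class AbundanceMatrix:
    """Compound x species AUC matrix with raw, detection and 0-100 views."""

    raw: pd.DataFrame
    detected: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if (self.raw.values < 0).any():
            raise ValueError("raw AUC values must be non-negative")
        if self.detected is None:
            self.detected = self.raw > 0
        self.detected = self.detected.astype(bool)
        if not self.detected.shape == self.raw.shape:
            raise ValueError("detection mask shape mismatch")

    @property
    def species(self) -> list[str]:
        return list(self.raw.columns)

    @property
    def normalized(self) -> pd.DataFrame:
        return normalize_rows(self)

    def filter_min_species(self, k: int = 2) -> "AbundanceMatrix":
        return filter_min_species(self, k)


def normalize_rows(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Scale each compound row by 100 / row maximum.

    Cells where the detection mask is false are exactly 0; all-zero rows
    stay all-zero. Every row with at least one detection has max 100.
    """
    raw = matrix.raw.where(matrix.detected, 0.0).astype(float)
    row_max = raw.max(axis=1)
    scale = row_max.where(row_max > 0, 1.0)
    # divide before scaling: v/vmax <= 1 exactly in floating point, so the
    # row maximum is exactly 100 and nothing exceeds it
    return raw.div(scale, axis=0).mul(100.0)


def filter_min_species(matrix: AbundanceMatrix, k: int = 2) -> AbundanceMatrix:
    """Keep compounds detected in at least ``k`` species; column order kept."""
    if k < 1:
        raise ValueError("k must be >= 1")
    keep = matrix.detected.sum(axis=1) >= k
    return AbundanceMatrix(raw=matrix.raw[keep].copy(), detected=matrix.detected[keep].copy())


def distribution_letters(matrix: AbundanceMatrix) -> dict[int, frozenset[str]]:
    """Species letter set (A..E) per compound, from the detection mask."""
    label_to_letter = {v: k for k, v in SPECIES_BY_LETTER.items()}
    out: dict[int, frozenset[str]] = {}
    for cid, row in matrix.detected.iterrows():
        out[int(cid)] = frozenset(
            label_to_letter.get(col, "?") for col, det in row.items() if det
        )
    return out


def quantify_runs(
    run_dir: str | Path,
    species: list[str],
    library: CompoundLibrary,
    config: ScreeningConfig | None = None,
    rt_group_window: float = 0.1,
    rt_half_window: float = DEFAULT_RT_HALF_WINDOW,
) -> AbundanceMatrix:
    """Screen + integrate every run in ``run_dir`` into an abundance matrix.

    Expects ``<species>.mgf`` and ``<species>.ms1.tsv`` per species label.
    A compound counts as detected in a species iff it has at least one
    passed screening match there and its integrated AUC is positive.
    """
    run_dir = Path(run_dir)
    config = config or ScreeningConfig()
    all_ids = [r.id for r in library]
    raw = pd.DataFrame(0.0, index=all_ids, columns=species)
    det = pd.DataFrame(False, index=all_ids, columns=species)

    for label in species:
        mgf = run_dir / f"{label}.mgf"
        ms1_path = run_dir / f"{label}.ms1.tsv"
        for p in (mgf, ms1_path):
            if not p.exists():
                raise FileNotFoundError(f"missing run input: {p}")
        hits = screen_run(mgf, library, config)
        if not hits:
            continue
        ms1 = read_ms1(ms1_path)
        by_compound: dict[int, list] = {}
        for h in hits:
            by_compound.setdefault(h.compound_id, []).append(h)
        for cid, matches in by_compound.items():
            grouped = group_scans(matches, rt_window=rt_group_window, config=config)
            xic = extract_xic(
                ms1,
                target_mz=library[cid].exact_mz,
                apex_rt=grouped.apex_rt,
                compound_id=cid,
                ppm=config.precursor_ppm_max,
                da_floor=config.precursor_da_floor,
                rt_half_window=rt_half_window,
            )
            auc = integrate_auc(xic) if xic.rt.size >= 2 else 0.0
            raw.loc[cid, label] = auc
            det.loc[cid, label] = auc > 0

    keep = det.any(axis=1)
    return AbundanceMatrix(raw=raw[keep], detected=det[keep])
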