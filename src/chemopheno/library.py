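"""Phenolic compound library for the five Senecioneae species.

The packaged fixtures hold the 68 annotated phenolic metabolites (name,
molecular formula, deprotonated exact mass, MS2 fragment list, retention
time, species distribution, reference-standard flag) and the 51-compound
x 5-species normalized AUC matrix used by the clustering stage.

Species letter codes: A = S. hercynicus, B = S. ovatus, C = S. rupestris,
D = J. pancicii, E = J. maritima.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .formula import ChemicalFormula, monoisotopic_mz, parse_formula, ppm_error

__all__ = [
    "SPECIES_BY_LETTER",
    "SPECIES_ORDER",
    "CompoundRecord",
    "CompoundLibrary",
    "load_library",
    "load_table2",
    "class_counts",
]

SPECIES_BY_LETTER: dict[str, str] = {
    "A": "S_hercynicus",
    "B": "S_ovatus",
    "C": "S_rupestris",
    "D": "J_pancicii",
    "E": "J_maritima",
}
#: Column order used throughout the pipeline (letter order A..E).
SPECIES_ORDER: list[str] = list(SPECIES_BY_LETTER.values())

COMPOUND_CLASSES = ("phenolic_acid_or_derivative", "coumarin", "flavonoid")


@dataclass(frozen=True)
class CompoundRecord:
    """One library entry.

    ``exact_mz`` is the published deprotonated monoisotopic m/z; for one
    compound (id 18) the published value disagrees with its formula, so
    ``theoretical_mz`` (recomputed from the formula) is kept alongside.
    ``fragments`` are (m/z, relative intensity in percent of base peak).
    """

    id: int
    name: str
    formula: ChemicalFormula
    exact_mz: float
    theoretical_mz: float
    fragments: tuple[tuple[float, float], ...]
    rt_min: float
    compound_class: str
    has_standard: bool
    distribution: frozenset[str]

    def __post_init__(self) -> None:
        if self.rt_min <= 0:
            raise ValueError(f"compound {self.id}: rt_min must be positive")
        if self.compound_class not in COMPOUND_CLASSES:
            raise ValueError(f"compound {self.id}: unknown class {self.compound_class!r}")
        for mz, rel in self.fragments:
            if not (0 < rel <= 100):
                raise ValueError(f"compound {self.id}: fragment intensity {rel} outside (0, 100]")
            if mz <= 0:
                raise ValueError(f"compound {self.id}: non-positive fragment m/z")
        if not self.distribution <= set("ABCDE"):
            raise ValueError(f"compound {self.id}: bad distribution letters")

    @property
    def species(self) -> list[str]:
        """Species labels (column names) this compound was reported in."""
        return [SPECIES_BY_LETTER[c] for c in sorted(self.distribution)]


class CompoundLibrary:
    """Ordered collection of :class:`CompoundRecord` with id lookup."""

    def __init__(self, records: list[CompoundRecord]):
        self.records = list(records)
        self.by_id = {r.id: r for r in self.records}
        if len(self.by_id) != len(self.records):
            raise ValueError("duplicate compound ids in library")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, cid: int) -> CompoundRecord:
        return self.by_id[cid]

    def validate(self, max_abs_ppm: float = 3.0) -> list[str]:
        """Check fixture invariants; return a list of human-readable problems.

        Published exact masses are 4-decimal roundings, so they must agree
        with the formula-derived value to <3 ppm -- except the known
        misprinted compound 18, which is reported, not failed.
        """
        problems: list[str] = []
        if len(self) != 68:
            problems.append(f"expected 68 records, found {len(self)}")
        n_std = sum(r.has_standard for r in self)
        if n_std != 24:
            problems.append(f"expected 24 reference-standard compounds, found {n_std}")
        for r in self:
            err = ppm_error(r.exact_mz, r.theoretical_mz)
            if abs(err) >= max_abs_ppm and r.id != 18:
                problems.append(f"compound {r.id}: printed mass off by {err:.1f} ppm")
        return problems


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("chemopheno").joinpath("data", name)))


def _parse_fragments(text: str) -> tuple[tuple[float, float], ...]:
    out = []
    for pair in text.split(";"):
        if pair:
            mz, rel = pair.split(":")
            out.append((float(mz), float(rel)))
    return tuple(out)


def load_library(path: str | Path | None = None) -> CompoundLibrary:
    """Load the packaged 68-compound library (or a compatible TSV)."""
    path = _fixture_path("table1.tsv") if path is None else Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            CompoundRecord(
                id=int(row.id),
                name=row.name,
                formula=parse_formula(row.formula),
                exact_mz=float(row.exact_mz),
                theoretical_mz=float(row.theoretical_mz),
                fragments=_parse_fragments(row.fragments),
                rt_min=float(row.rt_min),
                compound_class=row.compound_class,
                has_standard=row.has_standard == "true",
                distribution=frozenset(row.distribution),
            )
        )
    return CompoundLibrary(records)


def load_table2(path: str | Path | None = None) -> pd.DataFrame:
    """Published normalized AUC matrix: 51 compounds x 5 species, 0-100 by rows.

    Indexed by compound id; columns are :data:`SPECIES_ORDER` (a ``name``
    column is kept as metadata). Zeros mark non-detection.
    """
    path = _fixture_path("table2.tsv") if path is None else Path(path)
    df = pd.read_csv(path, sep="\t", index_col="id")
    return df[["name"] + SPECIES_ORDER]


def class_counts(library: CompoundLibrary) -> dict[str, int]:
    """Number of compounds per class; keys cover all classes (zero-filled)."""
    counts = Counter(r.compound_class for r in library)
    return {c: counts.get(c, 0) for c in COMPOUND_CLASSES}
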