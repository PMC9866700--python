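"""End-to-end orchestration: simulate -> screen -> quantify -> cluster.

A run manifest (seeds, configuration hash, package version, output
checksums) is written next to the artifacts so a rerun with the same
configuration can be verified byte-for-byte on the TSV outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .cluster import cut_tree, euclidean_distances, heatmap_export, pca, ward_d2_cluster
from .library import SPECIES_ORDER, load_library
from .quantify import quantify_runs
from .screening import ScreeningConfig
from .simulate import AcquisitionSettings, GroundTruth, generate_run, write_run

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """One source of truth for an end-to-end run."""

    outdir: str = "results"
    seed: int = 0
    simulate: bool = True
    run_dir: str | None = None  # where run files live (defaults to outdir/runs)
    low_noise: bool = False
    truth_scale: float = 1000.0
    decoy_count: int = 20
    min_species: int = 2
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    acquisition: AcquisitionSettings = field(default_factory=AcquisitionSettings)
    pca_center: bool = True
    pca_scale: bool = False

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output paths excluded)."""
        d = asdict(self)
        d.pop("outdir", None)
        d.pop("run_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_dir = Path(config.run_dir) if config.run_dir else outdir / "runs"
    library = load_library()

    stage = "simulate"
    try:
        if config.simulate:
            truth = GroundTruth.from_table2(
                scale=config.truth_scale, seed=config.seed,
                decoy_count=config.decoy_count,
            )
            if config.low_noise:
                truth = truth.low_noise()
            for species in SPECIES_ORDER:
                run = generate_run(library, truth, config.acquisition, species)
                write_run(run, run_dir)
        else:
            missing = [
                str(run_dir / f"{s}{ext}")
                for s in SPECIES_ORDER
                for ext in (".mgf", ".ms1.tsv")
                if not (run_dir / f"{s}{ext}").exists()
            ]
            if missing:
                raise FileNotFoundError(
                    f"simulation skipped but run inputs are missing: {missing}"
                )

        stage = "quantify"
        matrix = quantify_runs(run_dir, SPECIES_ORDER, library, config.screening)
        stage = "normalize_filter"
        filtered = matrix.filter_min_species(config.min_species)
        norm = filtered.normalized
        matrix.raw.to_csv(outdir / "matrix_raw.tsv", sep="\t")
        norm.to_csv(outdir / "matrix_normalized.tsv", sep="\t")

        stage = "cluster"
        species_matrix = norm.T  # species rows x compound columns
        dist = euclidean_distances(species_matrix)
        dend_species = ward_d2_cluster(dist)
        dend_compounds = ward_d2_cluster(euclidean_distances(norm))
        import pandas as pd

        pd.DataFrame(dist.matrix, index=dist.labels, columns=dist.labels).to_csv(
            outdir / "distances.tsv", sep="\t"
        )
        pd.DataFrame(
            dend_species.merges, columns=["node_a", "node_b", "height", "size"]
        ).to_csv(outdir / "species_merges.tsv", sep="\t", index=False)
        clusters = cut_tree(dend_species, 2)
        pca_res = pca(species_matrix, center=config.pca_center, scale=config.pca_scale)
        pca_res.scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
        pca_res.cos2.to_csv(outdir / "pca_cos2.tsv", sep="\t")
        heatmap_export(species_matrix, dend_species, dend_compounds, outdir / "heatmap")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "species_clusters_k2": clusters,
        "n_compounds_detected": int(len(matrix.raw)),
        "n_compounds_min_species": int(len(norm)),
        "outputs": {
            p.name: _sha256(p) for p in sorted(outdir.glob("*.tsv"))
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
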