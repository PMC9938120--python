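"""End-to-end orchestration: normalize -> fit -> dss -> (sdss, tas, cohort,
synergy), with a flat-text run manifest recording config digest, seed and
per-stage row counts plus output digests for byte-reproducibility checks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .config import DSSConfig, TASConfig, config_digest
from .cohort import (differential_sensitivity, hierarchical_clustering,
                     pairwise_subtype_correlation, pca_projection,
                     subtype_group_stats)
from .curves import fit_screen
from .dss import (ScreenMatrix, compute_selective_dss, effectiveness_calls,
                  score_screen)
from .normalize import assemble_series, normalize_plates
from .synergy import CombinationMatrix, hsa_excess, score_matrices
from .tas import build_membership, tas_profile

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    wells: str
    library: str
    samples: str
    outdir: str
    targets: str | None = None
    controls: str | None = None
    combo_matrices: list[str] = field(default_factory=list)
    dss: DSSConfig = field(default_factory=DSSConfig)
    tas: TASConfig = field(default_factory=TASConfig)
    effectiveness_threshold: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("wells", "library", "samples"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"missing {name} input: {path}")
        for name in ("targets", "controls"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"missing {name} input: {path}")
        for path in self.combo_matrices:
            if not Path(path).exists():
                raise FileNotFoundError(f"missing combination matrix: {path}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: PipelineConfig) -> Path:
    """Execute all stages; returns the output directory.

    Every artifact is a CSV under ``outdir``; ``manifest.txt`` holds flat
    ``key=value`` lines (sorted) so two runs with identical inputs and seed
    produce identical manifests.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    digest_fields = dataclasses.asdict(config)
    digest_fields.pop("outdir")  # manifests must not depend on where outputs land
    manifest: dict[str, str] = {
        "version": __version__,
        "seed": str(config.seed),
        "config_sha256": config_digest(digest_fields),
    }

    def _stage(name):
        logger.info("stage: %s", name)

    def _emit(name: str, df: pd.DataFrame) -> Path:
        path = io.write_csv(df, outdir / f"{name}.csv")
        manifest[f"rows_{name}"] = str(len(df))
        manifest[f"sha256_{name}"] = _sha256(path)
        return path

    _stage("normalize")
    wells = io.read_wells(config.wells)
    library = io.read_library(config.library)
    samples = io.read_samples(config.samples)
    try:
        normalized, qc = normalize_plates(wells)
        series, excluded = assemble_series(normalized)
    except Exception as err:
        raise RuntimeError(f"stage normalize failed: {err}") from err
    series = series.rename(columns={})
    _emit("qc", qc)
    _emit("series", series[["sample_id", "drug_id", "conc_nM",
                            "inhibition_pct"]])
    _emit("excluded_series", excluded)

    _stage("fit")
    fits = fit_screen(series)
    _emit("fits", fits)

    _stage("dss")
    dss_df = score_screen(fits, config.dss)
    _emit("dss", dss_df)
    matrix = ScreenMatrix.from_long(dss_df, samples, library)
    eff = effectiveness_calls(matrix, threshold=config.effectiveness_threshold)
    frac = eff.fractions.reset_index().rename(columns={"index": "sample_id"})
    _emit("effective_fractions", frac)
    manifest["pooled_quantile85"] = f"{eff.pooled_quantile85:.10g}"

    if config.controls:
        _stage("sdss")
        controls = io.read_controls(config.controls)
        controls = controls.rename(columns={"donor_id": "donor_id"})
        sdss = compute_selective_dss(dss_df, controls)
        _emit("sdss", sdss)

    if config.targets:
        _stage("tas")
        targets = io.read_targets(config.targets)
        membership = build_membership(
            targets, potency_cutoff_nM=config.tas.potency_cutoff_nM,
            min_drugs_per_target=config.tas.min_drugs_per_target)
        tas_df = tas_profile(dss_df, membership, config.tas, seed=config.seed)
        _emit("tas", tas_df)

    _stage("cohort")
    group_stats = subtype_group_stats(matrix, level="class",
                                      threshold=config.effectiveness_threshold)
    _emit("group_stats", group_stats)
    corr = pairwise_subtype_correlation(matrix)
    _emit("subtype_correlations", corr)
    clust = hierarchical_clustering(matrix, k=len(set(matrix.subtypes)))
    linkage_df = pd.DataFrame(clust.linkage_matrix,
                              columns=["child_a", "child_b", "height", "size"])
    _emit("linkage", linkage_df)
    if clust.labels is not None:
        _emit("clusters", clust.labels.reset_index())
    pca = pca_projection(matrix)
    scores = pca.scores.reset_index()
    _emit("pca_scores", scores)
    manifest["pca_explained"] = ",".join(
        f"{v:.10g}" for v in pca.explained_fraction)
    subtypes = matrix.subtypes
    lgs = list(subtypes[subtypes == "LGSOC"].index)
    rest = list(subtypes[subtypes != "LGSOC"].index)
    if len(lgs) >= 2 and len(rest) >= 2:
        volcano = differential_sensitivity(
            matrix, lgs, rest, threshold=config.effectiveness_threshold)
        _emit("volcano", volcano)

    if config.combo_matrices:
        _stage("synergy")
        matrices = []
        for path in config.combo_matrices:
            df = pd.read_csv(path)
            name = Path(path).stem
            matrices.append(CombinationMatrix.from_long(
                df, drugA_id=f"{name}:A", drugB_id=f"{name}:B"))
        _emit("synergy_summary", score_matrices(matrices))
        for m in matrices:
            res = hsa_excess(m)
            excess_long = m.to_long()
            excess_long["hsa_excess"] = res.excess.ravel()
            _emit(f"synergy_excess_{m.drugA_id.split(':')[0]}", excess_long)

    manifest_path = outdir / "manifest.txt"
    manifest_path.write_text(
        "".join(f"{k}={manifest[k]}\n" for k in sorted(manifest)))
    return outdir
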