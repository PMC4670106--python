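"""End-to-end pipeline driver and run manifest.

Stages: preprocess -> differential expression (or an externally supplied DE
table) -> DES scoring and ranked-list descriptives -> nested-subset
enrichment sweep with integrated clustering -> clinical-covariate
association. All artifacts are TSVs with sidecar schema comments; a
manifest.json records the configuration hash, seed, per-stage row counts
and the SHA-256 of every output, so identical configuration and inputs
yield a byte-identical manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import covariates, dge, enrich, io, preprocess, score
from .errors import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds and paths for a pipeline run.

    The analysis constants: subset step 25, top 15 sets per collection,
    5 cluster groups, FDR<0.05 DE call, p<0.05 display mask, 100-gene
    sliding window, Tukey fence k=3, DES padj floor 1e-300.
    """

    counts: str = ""
    meta: str = ""
    gmt: list[str] = field(default_factory=list)
    biotypes: str = ""
    hierarchy: str = ""          # optional child-TAB-parent edges for first GMT
    external_de: str = ""
    step: int = 25
    top_k: int = 15
    n_groups: int = 5
    de_alpha: float = 0.05
    mask_alpha: float = 0.05
    window: int = 100
    trim_k: float = 3.0
    padj_floor: float = 1e-300
    seed: int = 0

    def __post_init__(self):
        for name in ("step", "top_k", "n_groups", "window"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        for name in ("de_alpha", "mask_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1), got {v}")
        if self.trim_k <= 0:
            raise ConfigurationError("trim_k must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for path in [config.counts, config.meta, *config.gmt]:
        if path and not Path(path).exists():
            raise ConfigurationError(f"input does not exist: {path}")
    if not config.counts or not config.meta:
        raise ConfigurationError("counts and meta inputs are required")

    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }

    counts = io.read_counts(config.counts)
    samples = io.read_sample_table(config.meta)
    samples = samples.loc[counts.columns]
    groups = samples["condition"]

    # --- preprocess ---------------------------------------------------
    filtered, removed = preprocess.filter_low_signal(counts, groups)
    trimmed = preprocess.trim_outlier_counts(filtered, groups, k=config.trim_k)
    factors = preprocess.size_factors(trimmed)
    norm = preprocess.normalize(trimmed, factors)
    alpha_hat = preprocess.estimate_dispersion(norm, groups)
    vst_mat = preprocess.vst(norm, alpha_hat)
    manifest["stages"]["preprocess"] = {
        "genes_in": int(counts.shape[0]),
        "genes_removed": len(removed),
        "genes_out": int(filtered.shape[0]),
        "shared_dispersion": float(alpha_hat),
    }
    io.write_table(factors.to_frame(), outdir / "size_factors.tsv", index=True)
    io.write_table(vst_mat.round(6), outdir / "vst.tsv", index=True)

    # --- differential expression --------------------------------------
    if config.external_de:
        de_table = io.read_table(config.external_de, index_col=0)
    else:
        de_table = dge.nb_wald_test(trimmed, samples, factors=factors)
    de_genes = dge.call_de(de_table, threshold=config.de_alpha)
    manifest["stages"]["dge"] = {
        "genes_tested": int(de_table["p"].notna().sum()),
        "de_genes": len(de_genes),
    }

    # --- DES scoring and descriptives ---------------------------------
    scored = score.add_des(de_table, padj_floor=config.padj_floor)
    ranked_des = score.rank_by_des(scored)
    io.write_table(ranked_des.round(6), outdir / "de_table.tsv", index=True)
    ranked_sig = dge.call_de(scored, threshold=config.de_alpha)
    if ranked_sig:
        lfc_ranked = scored.loc[ranked_sig, "lfc"].to_numpy()
        window = min(config.window, len(ranked_sig))
        profile = score.updown_profile(lfc_ranked, window=window)
        io.write_table(profile, outdir / "updown_profile.tsv")
        io.write_table(score.lfc_histogram(lfc_ranked),
                       outdir / "lfc_histogram.tsv")
        top10 = ranked_sig[:10]
        io.write_table(score.rowmax_normalize(norm.loc[top10]).round(6),
                       outdir / "top_genes_rowmax.tsv", index=True)
    if config.biotypes:
        bios = io.read_biotypes(config.biotypes)
        comp = score.biotype_composition(ranked_sig, bios)
        io.write_table(comp.rename("proportion").to_frame(),
                       outdir / "biotype_composition.tsv", index=True)
    manifest["stages"]["score"] = {"scored_genes": int(len(scored))}

    # --- enrichment sweep ---------------------------------------------
    universe = set(filtered.index)
    if ranked_sig and config.gmt:
        profiles = []
        for i, gmt_path in enumerate(config.gmt):
            sets = io.read_gmt(gmt_path)
            hier = (io.read_hierarchy(config.hierarchy)
                    if (i == 0 and config.hierarchy) else [])
            coll = enrich.GeneSetCollection(Path(gmt_path).stem, sets, hier)
            prof = enrich.enrichment_profile(coll, ranked_sig, universe,
                                             step=config.step,
                                             mask_alpha=config.mask_alpha)
            profiles.append(prof)
            io.write_table(prof.neglog10p.round(6),
                           outdir / f"profile_{coll.name}.tsv", index=True)
            io.write_table(prof.mask.astype(int),
                           outdir / f"mask_{coll.name}.tsv", index=True)
        gram = enrich.integrate_and_cluster(profiles, top_k=config.top_k,
                                            n_groups=config.n_groups)
        io.write_table(gram.matrix.round(6), outdir / "clustergram.tsv",
                       index=True)
        io.write_table(gram.groups.to_frame(), outdir / "cluster_groups.tsv",
                       index=True)
        pd.DataFrame(gram.linkage_matrix,
                     columns=["left", "right", "height", "size"]).round(6).to_csv(
            outdir / "linkage.tsv", sep="\t", index=False)
        (outdir / "row_order.txt").write_text("\n".join(gram.row_order) + "\n")
        manifest["stages"]["enrichsweep"] = {
            "collections": len(profiles),
            "clustered_rows": int(gram.matrix.shape[0]),
        }
    else:
        logger.warning("enrichment sweep skipped (no DE genes or no GMT inputs)")
        manifest["stages"]["enrichsweep"] = {"skipped": True}

    # --- clinical covariate association -------------------------------
    cases = samples[groups == preprocess.CASE_LABEL]
    assoc_stage: dict = {}
    clinical = [c for c in ("cag", "hv_striatal", "hv_cortical")
                if c in cases.columns and cases[c].notna().sum() > 3]
    case_vst = pd.DataFrame(vst_mat, index=norm.index,
                            columns=norm.columns)[cases.index]
    for cov in clinical:
        table = covariates.covariate_regression(case_vst, cases[cov],
                                                cases["rin"])
        io.write_table(table.round(6), outdir / f"assoc_{cov}.tsv", index=True)
        assoc_stage[cov] = int(table["p"].notna().sum())
    if {"age_of_onset", "cag"} <= set(cases.columns) and \
            cases["age_of_onset"].notna().sum() > 3:
        model = covariates.fit_onset_model(cases["age_of_onset"], cases["cag"])
        resid = covariates.residual_onset(cases["age_of_onset"], cases["cag"],
                                          model)
        table = covariates.covariate_regression(case_vst, resid, cases["rin"])
        io.write_table(table.round(6), outdir / "assoc_onset_residual.tsv",
                       index=True)
        assoc_stage["onset_residual"] = int(table["p"].notna().sum())
    if "hv_cortical" in clinical and de_genes:
        table, confounded = covariates.confound_check(
            filtered[cases.index], de_genes, cases["hv_cortical"],
            cases["rin"], size_factors=factors.loc[cases.index],
            dispersion=alpha_hat, alpha=config.de_alpha)
        io.write_table(table.round(6), outdir / "confound_check.tsv",
                       index=True)
        assoc_stage["confounded_by_cortical_score"] = confounded
    manifest["stages"]["covassoc"] = assoc_stage or {"skipped": True}

    # --- manifest ------------------------------------------------------
    for path in sorted(outdir.iterdir()):
        if path.name != "manifest.json" and path.is_file():
            manifest["outputs"][path.name] = _sha256(path)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1) + "\n")
    return manifest
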