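"""End-to-end orchestration: simulate -> anatomy -> field model -> scan
-> haplotypes -> BWB -> multivariate reports.

Each stage reads its inputs from files or from the outputs of earlier
stages, writes plain-text outputs into the run directory, and records
row counts and seeds in a JSON manifest.  A stage failure stops
downstream stages but preserves what was already written.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import ConfigError
from . import anatomy as anat
from . import field_model as fm
from . import gas_exchange as gx
from . import gwas_scan as gws
from . import haplotypes as hap
from . import io_formats as io
from . import stats_multivariate as smv
from . import synthetic_data as synth

logger = logging.getLogger(__name__)

STAGES = ("simulate", "anatomy", "fieldmodel", "gwas", "haplotypes", "bwb", "stats")

FARMCPU_NOTICE = (
    "association scan: single-marker OLS with PC covariates "
    "(FarmCPU not reimplemented)"
)


@dataclass
class PipelineConfig:
    """Parameters of a full run.  ``simulation`` drives the generator;
    stage toggles select what runs; file paths override simulated inputs."""

    output_dir: str = "sorgwue_run"
    seed: int = 1
    stages: tuple[str, ...] = STAGES
    simulation: synth.SimulationConfig = field(default_factory=synth.SimulationConfig)
    alpha: float = 0.05
    maf_cutoff: float = 0.03
    k_pcs: int = 3
    window_bp: int = 75_000
    focal_marker_ids: tuple[str, ...] = tuple(m[0] for m in synth.CAUSAL_MARKERS)
    anchor_haplotype_order: tuple[str, ...] | None = synth.FOCAL_HAPLOTYPE_ORDER
    k_trait_clusters: int = 3
    genotype_vcf: str | None = None  # real-data entry points
    phenotype_csv: str | None = None
    gff3: str | None = None
    gas_exchange_csv: str | None = None

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ConfigError(f"unknown stages: {unknown}")
        self.simulation.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulation" in raw:
            raw["simulation"] = synth.SimulationConfig.from_dict(raw["simulation"])
        for f_ in ("stages", "focal_marker_ids", "anchor_haplotype_order"):
            if f_ in raw and isinstance(raw[f_], list):
                raw[f_] = tuple(raw[f_])
        cfg = cls(**raw)
        if "seed" in raw and "simulation" not in raw:
            cfg.simulation.seed = cfg.seed
        return cfg


def _config_hash(config: PipelineConfig) -> str:
    from dataclasses import asdict

    d = asdict(config)
    d.pop("output_dir", None)  # hash covers analysis parameters, not paths
    blob = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order; return the manifest."""
    config.validate()
    config.simulation.seed = config.seed
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"seed={config.seed} config={_config_hash(config)}"
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "notices": [FARMCPU_NOTICE],
        "stages": {},
    }

    G = truth = pheno = None
    gas_records = None
    predictions = None

    def record(stage: str, **counts) -> None:
        manifest["stages"][stage] = {"status": "completed", **counts}

    try:
        if "simulate" in config.stages:
            G, truth = synth.simulate_genotypes(config.simulation)
            pheno, truth = synth.simulate_field_phenotypes(G, truth, config.simulation)
            io.write_vcf(G, out / "genotypes.vcf", header_comment=stamp)
            io.write_phenotype_csv(pheno, out / "phenotypes.csv", header_comment=stamp)
            panel = synth.representative_panel(truth)
            gas_records = synth.simulate_gas_exchange_panel(config.simulation, panel)
            io.write_gas_exchange_csv(gas_records, out / "gas_exchange.csv",
                                      header_comment=stamp)
            record("simulate", n_accessions=G.n_accessions, n_markers=G.n_markers,
                   n_plots=len(pheno.data), n_gas_records=len(gas_records))

        if config.genotype_vcf:
            G = io.read_vcf_lite(config.genotype_vcf)
        if config.phenotype_csv:
            pheno = io.read_phenotype_csv(config.phenotype_csv)
        if config.gas_exchange_csv:
            gas_records = io.read_gas_exchange_csv(config.gas_exchange_csv)

        if "anatomy" in config.stages:
            if truth is None:
                raise ConfigError("anatomy stage requires simulated impressions")
            # adaxial density means derived from the simulated SD_total truth
            dens = truth.accession_values["SD_total"] / (
                1.0 + config.simulation.impressions.abaxial_density_factor
            )
            impressions = synth.simulate_impressions(dens, config.simulation)
            rows = []
            for acc, recs in impressions.items():
                plants = sorted({r.plant_id for r in recs})
                for pid in plants:
                    t = anat.derive_plant_traits([r for r in recs if r.plant_id == pid])
                    rows.append(
                        {"accession": acc, "plant_id": pid,
                         "SD_total": t.SD_total, "SPALA_total": t.SPALA_total,
                         "g_total": t.g_total, "SS_mean": t.SS_mean,
                         "PAmax_mean": t.PAmax_mean}
                    )
            anat_df = pd.DataFrame(rows)
            with open(out / "anatomy_traits.csv", "w", encoding="utf-8",
                      newline="\n") as fh:
                fh.write(f"# {stamp}\n")
                anat_df.to_csv(fh, index=False, lineterminator="\n")
            record("anatomy", n_plants=len(anat_df))

        if "fieldmodel" in config.stages:
            if pheno is None:
                raise ConfigError("fieldmodel stage has no phenotype input")
            fits, predictions = fm.fit_all_traits(pheno)
            with open(out / "accession_predictions.csv", "w", encoding="utf-8",
                      newline="\n") as fh:
                fh.write(f"# {stamp}\n")
                predictions.to_csv(fh, index_label="accession", lineterminator="\n")
            record(
                "fieldmodel",
                n_traits=len(fits),
                n_accessions=len(predictions),
                variance_components={
                    t: {"sigma2_accession": f.sigma2_accession,
                        "sigma2_residual": f.sigma2_residual}
                    for t, f in fits.items()
                },
            )

        scan_results: dict[str, gws.GWASResult] = {}
        if "gwas" in config.stages:
            if G is None or predictions is None:
                raise ConfigError("gwas stage requires genotypes and predictions")
            Gf = gws.maf_filter(G, config.maf_cutoff)
            pcs, _ = gws.genotype_pcs(Gf, k=config.k_pcs)
            n_sig = {}
            for trait in predictions.columns:
                result = gws.single_marker_scan(
                    Gf, predictions[trait], pcs, alpha=config.alpha, trait=trait
                )
                scan_results[trait] = result
                io.write_gwas_tsv(result, out / f"gwas_{trait}.tsv")
                gws.qq_table(result.table["p"]).to_csv(
                    out / f"qq_{trait}.tsv", sep="\t", index=False,
                    lineterminator="\n",
                )
                n_sig[trait] = int(len(result.significant()))
            if config.gff3:
                genes = io.read_gff3_genes(config.gff3)
                cand_rows = []
                for trait, result in scan_results.items():
                    for _, r in result.significant().iterrows():
                        hits = gws.candidate_window(
                            genes, r["chromosome"], int(r["position"]),
                            config.window_bp,
                        )
                        for _, g in hits.iterrows():
                            cand_rows.append(
                                {"trait": trait, "marker_id": r["marker_id"],
                                 "gene_id": g["gene_id"], "distance": g["distance"]}
                            )
                pd.DataFrame(cand_rows).to_csv(
                    out / "candidate_genes.tsv", sep="\t", index=False,
                    lineterminator="\n",
                )
            record("gwas", n_markers_tested=Gf.n_markers,
                   n_significant=n_sig, threshold=gws.bonferroni_threshold(
                       config.alpha, Gf.n_markers))

        if "haplotypes" in config.stages:
            if G is None:
                raise ConfigError("haplotypes stage requires genotypes")
            table = hap.build_haplotypes(
                G, list(config.focal_marker_ids),
                anchor_order=config.anchor_haplotype_order,
            )
            table.assignments.to_csv(out / "haplotype_assignments.csv",
                                     index=False, lineterminator="\n")
            stats_rows = []
            if predictions is not None:
                for trait in predictions.columns:
                    gstats = hap.haplotype_group_stats(table, predictions[trait])
                    groups = {
                        row["class_label"]: predictions[trait][
                            table.assignments.set_index("accession")["class_label"]
                            .reindex(predictions.index) == row["class_label"]
                        ].dropna().to_numpy()
                        for _, row in gstats.iterrows()
                        if row["n"] >= 2
                    }
                    letters = {}
                    if len(groups) >= 2:
                        letters = hap.anova_tukey_letters(groups).letters
                    gstats["trait"] = trait
                    gstats["letters"] = gstats["class_label"].map(letters).fillna("")
                    stats_rows.append(gstats)
                pd.concat(stats_rows).to_csv(
                    out / "haplotype_stats.csv", index=False, lineterminator="\n"
                )
            record("haplotypes", n_classes=table.n_classes,
                   n_assigned=len(table.assignments), n_excluded=table.n_excluded)

        if "bwb" in config.stages:
            if gas_records is None:
                raise ConfigError("bwb stage has no gas-exchange input")
            fits = gx.fit_bwb_by_curve(gas_records)
            fit_df = pd.DataFrame(
                [{"accession": f.accession_id, "treatment": f.treatment,
                  "replicate": f.replicate, "m": f.m, "g0": f.g0,
                  "r2": f.r2, "n": f.n_points} for f in fits]
            )
            fit_df.to_csv(out / "bwb_fits.csv", index=False, lineterminator="\n")
            ww = [f for f in fits if f.treatment == "WW"]
            ws = [f for f in fits if f.treatment == "WS"]
            contrast = gx.compare_slopes(ww, ws)
            contrast.per_accession.to_csv(
                out / "bwb_contrast.csv", index=False, lineterminator="\n"
            )
            record("bwb", n_fits=len(fits),
                   interaction_p=contrast.interaction_p,
                   treatment_p=contrast.treatment_p)

        if "stats" in config.stages:
            if predictions is None:
                raise ConfigError("stats stage requires accession predictions")
            tm = smv.TraitMatrix(predictions)
            r, p = smv.correlation_matrix(tm)
            r.to_csv(out / "correlations_r.csv", lineterminator="\n")
            p.to_csv(out / "correlations_p.csv", lineterminator="\n")
            pca = smv.pca_traits(tm)
            pca.scores.to_csv(out / "pca_scores.csv", lineterminator="\n")
            pca.loadings.to_csv(out / "pca_loadings.csv", lineterminator="\n")
            desc = {
                t: smv.descriptive_stats(predictions[t]).__dict__
                for t in predictions.columns
            }
            k = min(config.k_trait_clusters, len(predictions.columns))
            clusters = smv.cluster_traits(pca, k=k) if k >= 2 else {}
            pd.Series(clusters, name="cluster").to_csv(
                out / "trait_clusters.csv", index_label="trait", lineterminator="\n"
            )
            record("stats", n_traits=len(predictions.columns),
                   pc1_percent=float(pca.percent_variance[0]),
                   descriptives=desc)
    except Exception as exc:
        failed = next((s for s in config.stages if s not in manifest["stages"]), "?")
        manifest["stages"][failed] = {"status": "failed", "error": str(exc)}
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str) + "\n", encoding="utf-8"
        )
        raise

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n", encoding="utf-8"
    )
    return manifest
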