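"""Packaged reference fixtures, run configuration and the combined
pipeline report.

The fixtures (a 22-row published DAP table, questionnaire group
summaries, small mitochondrial and CD gene lists) let every stage run and
be tested fully offline. :func:`run_pipeline` orchestrates the stages on
either simulated or user-supplied inputs and writes a JSON report plus a
MANIFEST with content hashes so a rerun under the same config and seed is
verifiably bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

logger = logging.getLogger("mecfs_omics")


def _data_path(name: str):
    return resources.files("mecfs_omics.data").joinpath(name)


def load_published_dap_table() -> pd.DataFrame:
    """Published 22-row differential-protein table: accession, description,
    gene, fold change (patient/control) and raw t-test p."""
    with resources.as_file(_data_path("published_dap_table.tsv")) as path:
        df = pd.read_csv(path, sep="\t")
    return df.rename(columns={"p": "raw_p"})


def load_questionnaire_reference() -> pd.DataFrame:
    """Questionnaire group summaries (instrument, group means and SDs)."""
    with resources.as_file(_data_path("questionnaire_reference.csv")) as path:
        return pd.read_csv(path)


def _load_list(name: str) -> list[str]:
    with resources.as_file(_data_path(name)) as path:
        lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]


def load_mito_list() -> list[str]:
    """Packaged curated subset of mitochondrial gene symbols (tests/demo);
    real analyses should pass a full inventory file."""
    return _load_list("mito_genes_subset.txt")


def load_cd_list() -> list[str]:
    return _load_list("cd_markers.txt")


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything one pipeline run needs; serialised into every sidecar."""

    outdir: str
    seed: int = 0
    stages: list = field(
        default_factory=lambda: ["simulate", "flux", "proteomics", "metabolomics", "clinical"]
    )
    # stage inputs; filled from the simulate stage when absent
    flux_traces: str | None = None
    flux_layout: str | None = None
    protein_table: str | None = None
    protein_groups: str | None = None
    metabolite_panel: str | None = None
    metabolite_groups: str | None = None
    cohort_table: str | None = None
    # stage parameters
    simulate_params: dict = field(default_factory=dict)
    summary_policy: dict | None = None
    welch: bool = False
    alpha: float = 0.05
    max_qc_cv: float = 0.25
    max_missing: float = 0.3
    glog_a: float | None = None
    met_fc_upper: float = 1.3
    met_fc_lower: float = 0.77
    mito_list: str | None = None
    pathway_map: str | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        needs = {
            "flux": ("flux_traces", "flux_layout"),
            "proteomics": ("protein_table", "protein_groups"),
            "metabolomics": ("metabolite_panel", "metabolite_groups"),
            "clinical": ("cohort_table",),
        }
        simulating = "simulate" in self.stages
        for stage in self.stages:
            for key in needs.get(stage, ()):
                value = getattr(self, key)
                if value is None and not simulating:
                    raise ValueError(f"stage {stage!r} requires config key {key!r}")
                if value is not None and not Path(value).exists():
                    raise ValueError(f"input path for {key!r} does not exist: {value}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and write report + MANIFEST.

    Returns the report dict. On stage failure the exception propagates
    after the MANIFEST (with completion state) is written, so partial
    outputs remain inspectable.
    """
    from . import clinical, flux, metabolomics, proteomics, synthetic

    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}, "config": dataclasses.asdict(config)}
    completed: list[str] = []

    def finish(status: str) -> None:
        manifest = {
            "status": status,
            "completed_stages": completed,
            "artifacts": {
                p.name: _sha256(p)
                for p in sorted(outdir.iterdir())
                if p.is_file() and p.name != "MANIFEST.json"
            },
        }
        (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))

    try:
        if "simulate" in config.stages:
            spec = synthetic.CohortSpec(seed=config.seed, **config.simulate_params)
            paths = synthetic.write_cohort(spec, outdir / "simulated")
            for key in (
                "flux_traces",
                "flux_layout",
                "protein_table",
                "protein_groups",
                "metabolite_panel",
                "metabolite_groups",
                "cohort_table",
            ):
                if getattr(config, key) is None:
                    setattr(config, key, str(paths[key]))
            report["stages"]["simulate"] = {"spec": spec.to_dict()}
            completed.append("simulate")

        if "flux" in config.stages:
            plate = flux.read_flux_plate(config.flux_traces, config.flux_layout)
            policy = (
                flux.SummaryPolicy.from_mapping(config.summary_policy)
                if config.summary_policy
                else None
            )
            profiles, comparison = flux.profile_plate(plate, policy)
            comparison = flux.compare_groups(profiles, welch=config.welch)
            profiles.to_csv(outdir / "bioenergetic_profiles.csv", index=False)
            comparison.to_csv(outdir / "bioenergetic_comparison.csv", index=False)
            report["stages"]["flux"] = {
                "n_subjects": int(profiles["subject"].nunique()),
                "comparisons": comparison.to_dict(orient="records"),
            }
            completed.append("flux")

        if "proteomics" in config.stages:
            table = proteomics.read_protein_table(config.protein_table)
            groups = proteomics.read_groups(config.protein_groups)
            filtered = proteomics.filter_quantifiable(table)
            thresholds = proteomics.derive_fc_thresholds(filtered, groups)
            results = proteomics.screen_proteins(
                filtered, groups, thresholds, alpha=config.alpha
            )
            summary = proteomics.classify_daps(results)
            mito_genes = (
                proteomics.read_gene_list(config.mito_list)
                if config.mito_list
                else load_mito_list()
            )
            mito = proteomics.mito_summary(results, mito_genes)
            cd = proteomics.cd_marker_check(filtered, groups, load_cd_list())
            results.to_csv(outdir / "protein_screen.tsv", sep="\t", index=False)
            summary["daps"].to_csv(outdir / "daps.tsv", sep="\t", index=False)
            stage = {
                "n_input": int(len(table)),
                "n_quantifiable": int(len(filtered)),
                "fc_threshold_upper": thresholds.upper,
                "fc_threshold_lower": thresholds.lower,
                "median_control_cv": thresholds.source_median_cv,
                "n_daps": summary["n_total"],
                "n_up": summary["n_up"],
                "n_down": summary["n_down"],
                "mito_n": mito["n_mito"],
                "mito_median_fc": mito["median_fc"],
                "cd_markers": cd.to_dict(orient="records"),
            }
            if config.pathway_map:
                pathways = proteomics.read_pathway_map(config.pathway_map)
                ptab = proteomics.pathway_group_test(results, pathways)
                ptab.to_csv(outdir / "pathway_tests.tsv", sep="\t", index=False)
                stage["pathways"] = ptab.to_dict(orient="records")
            report["stages"]["proteomics"] = stage
            completed.append("proteomics")

        if "metabolomics" in config.stages:
            panel = metabolomics.read_panel(config.metabolite_panel)
            groups = pd.read_csv(config.metabolite_groups)
            raw, scaled, prep = metabolomics.preprocess(
                panel,
                max_qc_cv=config.max_qc_cv,
                max_missing=config.max_missing,
                glog_a=config.glog_a,
            )
            fc = metabolomics.fc_screen(
                raw, groups, upper=config.met_fc_upper, lower=config.met_fc_lower
            )
            tests = metabolomics.t_fdr_screen(scaled, groups)
            screened = fc.merge(tests, on="compound")
            screened.to_csv(outdir / "metabolite_screen.tsv", sep="\t", index=False)
            components = metabolomics.pca(scaled, k=min(2, len(scaled.sample_cols) - 1))
            components["scores"].to_csv(outdir / "metabolite_pca_scores.csv")
            report["stages"]["metabolomics"] = {
                "preprocess": prep.to_dict(),
                "n_fc_flagged": int(fc["flagged"].sum()),
                "n_fdr_significant": int(tests["significant"].sum()),
                "n_nominal_only": int(tests["nominal_only"].sum()),
            }
            completed.append("metabolomics")

        if "clinical" in config.stages:
            cohort = pd.read_csv(config.cohort_table)
            corr_all = clinical.correlation_matrix(cohort, clinical.DEFAULT_PAIRS, "all")
            corr_pat = clinical.correlation_matrix(cohort, clinical.DEFAULT_PAIRS, "patients")
            corr = pd.concat([corr_all, corr_pat], ignore_index=True)
            corr.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
            report["stages"]["clinical"] = {"correlations": corr.to_dict(orient="records")}
            completed.append("clinical")
    except Exception:
        finish("failed")
        raise

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    finish("complete")
    return report
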