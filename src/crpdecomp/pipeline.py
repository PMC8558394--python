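"""End-to-end pipeline: generate -> ancestry -> models -> importance -> PheWAS.

One configuration file (generator block plus analysis thresholds) drives the
whole chain; a :class:`RunManifest` records stage outputs, row counts, the
configuration hash and the seed so reruns can be verified byte-for-byte on
their numeric artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .ancestry import (
    apply_ancestry_filter,
    harmonize_variants,
    infer_ancestry_nnls,
    ld_prune,
    run_pca,
    selfid_probability_curve,
)
from .config import GeneratorConfig, load_preset
from .crpmodels import (
    BASE_TERMS,
    FULLY_ADJUSTED_TERMS,
    INTERACTION_TERMS,
    CRPLinearModel,
    cohort_summary,
    likelihood_ratio_test,
    prepare_analysis_table,
    sensitivity_exclude_acute,
)
from .exceptions import ConfigurationError
from .phewas import (
    bonferroni_flags,
    disease_scan,
    load_phecode_map,
    load_toy_map,
    manhattan_frame,
    rank_sum_disparity,
)
from .relimp import importance_ranks, lmg_shares, table2_grouping
from .synthgen import (
    simulate_admixed_cohort,
    simulate_cohort_table,
    simulate_reference_panel,
    write_truth_files,
)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisParams:
    """All analysis thresholds in one block (defaults are the study's values)."""

    maf_min: float = 0.01
    miss_max: float = 0.05
    n_pcs: int = 10
    ld_window: int = 50
    ld_step: int = 5
    ld_r2_max: float = 0.1
    max_other_ancestry: float = 0.05
    elevated_threshold: float = 3.0
    acute_threshold: float = 10.0
    alpha: float = 0.05
    min_cases: int = 20
    top_k: int = 20
    n_bins: int = 100
    loess_span: float = 0.75
    scan_mode: str = "joint"
    run_phewas: bool = True
    run_genotypes: bool = True
    phecode_map: str | None = None   # path; bundled toy map when None


REQUIRED_GENERATOR_FIELDS = (
    "n_participants", "n_variants", "fst", "group_proportions", "group_theta",
    "covariate_params", "crp_effects", "crp_sigma", "seed",
)


@dataclass
class PipelineConfig:
    generator: GeneratorConfig
    analysis: AnalysisParams = field(default_factory=AnalysisParams)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        if "generator" not in raw:
            raise ConfigurationError("config missing the 'generator' block")
        gen_raw = raw["generator"]
        for f in REQUIRED_GENERATOR_FIELDS:
            if f not in gen_raw:
                raise ConfigurationError(f"schema error: generator.{f} is missing")
        generator = GeneratorConfig.from_dict(gen_raw)
        ana_raw = dict(raw.get("analysis", {}))
        known = {f.name for f in dataclasses.fields(AnalysisParams)}
        unknown = set(ana_raw) - known
        if unknown:
            raise ConfigurationError(
                f"schema error: unknown analysis fields {sorted(unknown)}")
        return cls(generator=generator, analysis=AnalysisParams(**ana_raw))

    def to_yaml(self, path=None) -> str:
        d = {"generator": self.generator.to_dict(),
             "analysis": dataclasses.asdict(self.analysis)}
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_preset(cls, name: str, seed: int | None = None,
                    n: int | None = None) -> "PipelineConfig":
        return cls(generator=load_preset(name, n_participants=n, seed=seed))


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    package_version: str
    stages: list = field(default_factory=list)
    started: str = ""
    finished: str = ""
    out_dir: str = ""

    def add_stage(self, name: str, outputs: dict) -> None:
        self.stages.append({"stage": name, "outputs": outputs})

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))

    def verify(self) -> list:
        """Return a list of problems (missing outputs / row-count mismatches)."""
        problems = []
        for st in self.stages:
            for name, meta in st["outputs"].items():
                path = os.path.join(self.out_dir, meta["path"])
                if not os.path.exists(path):
                    problems.append(f"{st['stage']}/{name}: missing {meta['path']}")
                    continue
                if "rows" in meta and meta["path"].endswith(".tsv"):
                    with open(path) as fh:
                        nrows = sum(1 for _ in fh) - 1
                    if nrows != meta["rows"]:
                        problems.append(
                            f"{st['stage']}/{name}: {nrows} rows on disk, "
                            f"manifest says {meta['rows']}")
        return problems


def _write(df: pd.DataFrame, out_dir: str, rel: str) -> dict:
    df.to_csv(os.path.join(out_dir, rel), sep="\t", index=False)
    return {"path": rel, "rows": int(len(df))}


def run_pipeline(config, out_dir, log_level: str = "INFO") -> RunManifest:
    """Execute the full chain and write all stage artifacts to ``out_dir``.

    ``config`` is a :class:`PipelineConfig`, a preset name, or a YAML path.
    Any stage failure propagates after a partial manifest is written.
    """
    if isinstance(config, str):
        if os.path.exists(config):
            config = PipelineConfig.from_yaml(config)
        else:
            config = PipelineConfig.from_preset(config)
    os.makedirs(out_dir, exist_ok=True)
    logging.basicConfig(level=getattr(logging, log_level.upper(), logging.INFO))
    gen, ana = config.generator, config.analysis
    manifest = RunManifest(
        config_hash=gen.config_hash(),
        seed=gen.seed,
        package_version=__version__,
        out_dir=str(out_dir),
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest_path = os.path.join(out_dir, "manifest.json")
    config.to_yaml(os.path.join(out_dir, "config.yaml"))
    pmap = load_phecode_map(ana.phecode_map) if ana.phecode_map else load_toy_map()
    try:
        # -- stage 1: synthetic genotypes + cohort --------------------------
        table = simulate_cohort_table(gen, phemap=pmap if ana.run_phewas else None)
        outputs = {}
        if ana.run_genotypes:
            panel = simulate_reference_panel(gen)
            study, truth = simulate_admixed_cohort(gen, panel)
            table["participant_id"] = study.sample_ids
            write_truth_files(gen, truth, out_dir)
            outputs["truth_theta"] = {"path": "truth_theta.tsv",
                                      "rows": len(truth.theta_afr)}
        outputs["phenotypes"] = _write(table, out_dir, "phenotypes.tsv")
        manifest.add_stage("synthgen", outputs)

        # -- stage 2: ancestry ---------------------------------------------
        if ana.run_genotypes:
            merged = harmonize_variants([study, panel.genotypes],
                                        maf_min=ana.maf_min, miss_max=ana.miss_max)
            pruned = ld_prune(merged, window=ana.ld_window, step=ana.ld_step,
                              r2_max=ana.ld_r2_max)
            pd.DataFrame({"id": pruned.variants["id"]}).to_csv(
                os.path.join(out_dir, "pruned_variants.tsv"), sep="\t", index=False)
            pcs = run_pca(pruned, n_components=min(ana.n_pcs, pruned.n_samples - 1),
                          random_state=gen.seed)
            ref_labels = pd.Series(
                [panel.ancestry_groups[p] for p in panel.population_labels],
                index=panel.genotypes.sample_ids)
            est = infer_ancestry_nnls(pcs, ref_labels)
            included = apply_ancestry_filter(
                est, {"African", "European"}, ana.max_other_ancestry)
            afr = est.fractions["African"].to_numpy()
            frac_map = dict(zip(est.sample_ids, afr))
            table["african_fraction"] = table["participant_id"].map(frac_map)
            study_scores = pcs.frame().set_index("sample_id")
            table["pc1"] = table["participant_id"].map(study_scores["PC1"])
            table["pc2"] = table["participant_id"].map(study_scores["PC2"])
            curve = selfid_probability_curve(
                table["african_fraction"], table["ethnicity"],
                n_bins=ana.n_bins, span=ana.loess_span)
            manifest.add_stage("ancestry", {
                "pc_scores": _write(pcs.frame(), out_dir, "pc_scores.tsv"),
                "fractions": _write(est.frame(), out_dir, "ancestry_fractions.tsv"),
                "included": _write(pd.DataFrame({"participant_id": included}),
                                   out_dir, "included_samples.tsv"),
                "selfid_curve": _write(curve.frame(), out_dir, "selfid_curve.tsv"),
                "pruned_variants": {"path": "pruned_variants.tsv",
                                    "rows": pruned.n_variants},
            })
            table = table[table["participant_id"].isin(set(included))]

        # -- stage 3: CRP models ---------------------------------------------
        atab = prepare_analysis_table(table)
        base = CRPLinearModel.from_dataframe(atab, BASE_TERMS).fit()
        inter = CRPLinearModel.from_dataframe(atab, INTERACTION_TERMS).fit()
        lrt = likelihood_ratio_test(base, inter)
        full_terms = list(FULLY_ADJUSTED_TERMS)
        full = CRPLinearModel.from_dataframe(atab, full_terms).fit()
        sens = CRPLinearModel.from_dataframe(
            prepare_analysis_table(sensitivity_exclude_acute(atab, ana.acute_threshold)),
            BASE_TERMS).fit()
        summary = cohort_summary(atab)
        lrt_df = pd.DataFrame([{"statistic": lrt.statistic, "df": lrt.df,
                                "p_value": lrt.p_value}])
        manifest.add_stage("crpmodels", {
            "base_model": _write(base.to_frame(), out_dir, "model_base.tsv"),
            "interaction_model": _write(inter.to_frame(), out_dir,
                                        "model_interaction.tsv"),
            "lrt": _write(lrt_df, out_dir, "lrt.tsv"),
            "full_model": _write(full.to_frame(), out_dir, "model_full.tsv"),
            "sensitivity_model": _write(sens.to_frame(), out_dir,
                                        "model_sensitivity.tsv"),
            "cohort_summary": _write(summary["summary"], out_dir,
                                     "cohort_summary.tsv"),
            "cohort_tests": _write(summary["tests"], out_dir, "cohort_tests.tsv"),
        })

        # -- stage 4: relative importance ------------------------------------
        design = build_full_design(atab, full_terms)
        grouping = table2_grouping(design)
        imp = lmg_shares(design, grouping)
        ranked = importance_ranks(imp)
        manifest.add_stage("relimp", {
            "importance": _write(ranked, out_dir, "importance.tsv"),
        })

        # -- stage 5: PheWAS -------------------------------------------------
        if ana.run_phewas and gen.disease_params:
            scan = disease_scan(atab, pmap, min_cases=ana.min_cases,
                                mode=ana.scan_mode)
            scan = bonferroni_flags(scan, alpha=ana.alpha)
            top = rank_sum_disparity(scan, top_k=ana.top_k)
            manifest.add_stage("phewas", {
                "scan": _write(scan, out_dir, "disease_scan.tsv"),
                "disparity": _write(top, out_dir, "disparity_top.tsv"),
                "manhattan_crp": _write(manhattan_frame(scan, "crp"), out_dir,
                                        "manhattan_crp.tsv"),
                "manhattan_eth": _write(manhattan_frame(scan, "eth"), out_dir,
                                        "manhattan_eth.tsv"),
            })
    finally:
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest.to_json(manifest_path)
    return manifest


def build_full_design(atab: pd.DataFrame, terms) -> pd.DataFrame:
    """Design-plus-outcome frame consumed by the importance decomposition."""
    from .crpmodels import build_design

    design = build_design(atab, terms)
    design = design.drop(columns=["const"])
    design["log_crp"] = atab["log_crp"].to_numpy()
    return design


_REPORT_SECTIONS = [
    ("Cohort summary", "cohort_summary.tsv"),
    ("Base model (log CRP ~ ethnicity + age + sex)", "model_base.tsv"),
    ("Fully adjusted model", "model_full.tsv"),
    ("Relative importance (LMG)", "importance.tsv"),
    ("Top disparity-ranked diseases", "disparity_top.tsv"),
]


def export_report(manifest: RunManifest, path=None) -> str:
    """Render the run's headline tables as one deterministic markdown report."""
    lines = [
        "# crpdecomp pipeline report",
        "",
        f"- config hash: `{manifest.config_hash}`",
        f"- seed: {manifest.seed}",
        f"- package version: {manifest.package_version}",
        "",
    ]
    for title, rel in _REPORT_SECTIONS:
        lines.append(f"## {title}")
        lines.append("")
        fpath = os.path.join(manifest.out_dir, rel)
        if not os.path.exists(fpath):
            lines.append("_Section unavailable (stage output missing)._")
        else:
            df = pd.read_csv(fpath, sep="\t")
            lines.append("```")
            lines.append(df.round(4).to_string(index=False))
            lines.append("```")
        lines.append("")
    text = "\n".join(lines)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
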