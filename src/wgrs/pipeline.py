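"""End-to-end orchestration: simulate -> score -> impute -> associate -> meta.

A run is fully described by a :class:`PipelineConfig` (one structured file,
one master seed) and writes every intermediate artifact as headed TSV/CSV
plus a JSON sidecar naming the stage, its inputs and the seed.  Runs are
deterministic: the same config and seed reproduce every output byte for
byte (no timestamps are written anywhere).

In simulation mode the configured cohorts are first written in the exact
external file formats and then read back, so the analysis path exercised is
identical to an analysis of user-supplied files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import (
    DIATHESIS_FEATURES,
    diathesis_by_category,
    diathesis_count_analysis,
    per_unit_association,
    recurrence_by_category,
)
from .errors import ConfigError
from .io_formats import (
    GenotypeMatrix,
    PhenotypeTable,
    WeightPanel,
    read_dosage_matrix,
    read_genotypes_vcf,
    read_phenotypes,
    read_weight_table,
    write_dosage_matrix,
    write_phenotypes,
    write_weight_table,
)
from .meta import StudyEstimate, fixed_effect_meta
from .mice import ImputedStack, default_plan, mice_impute
from .rng import child_seed
from .score import (
    categorize_scores,
    category_thresholds,
    filter_low_genotyping,
    score_distribution_report,
    score_matrix,
)
from .simulate import SimulatedCohort, default_two_cohort_configs, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "read_imputed_long", "FLOAT_FORMAT"]

FLOAT_FORMAT = "%.10g"


@dataclass(frozen=True)
class PipelineConfig:
    """One reproducible run: either input file paths or a simulation recipe."""

    out_dir: str
    seed: int = 0
    # files mode (single cohort): all three paths, or none of them
    weights_path: str | None = None
    genotypes_path: str | None = None
    phenotypes_path: str | None = None
    # simulation mode (two cohorts)
    simulate: bool = False
    n_cases_a: int = 6126
    n_controls_a: int = 6126
    n_cases_b: int = 1730
    n_controls_b: int = 1000
    # scoring
    min_genotyped: int = 2
    # imputation (defaults scaled for a desk-size demo; the study-scale
    # configuration is m=75, cycles=100)
    mice_m: int = 5
    mice_cycles: int = 10
    # analyses to run
    analyses: tuple[str, ...] = (
        "distribution", "per_unit", "category", "diathesis_count", "diathesis_multinomial"
    )
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        paths = (self.weights_path, self.genotypes_path, self.phenotypes_path)
        has_paths = all(p is not None for p in paths)
        some_paths = any(p is not None for p in paths)
        if some_paths and not has_paths:
            raise ConfigError("files mode needs weights, genotypes and phenotypes paths")
        if self.simulate and some_paths:
            raise ConfigError("provide either input paths or a simulation recipe, not both")
        if not self.simulate and not has_paths:
            raise ConfigError("provide either input paths or a simulation recipe")
        unknown = set(self.analyses) - {
            "distribution", "per_unit", "category", "diathesis_count", "diathesis_multinomial"
        }
        if unknown:
            raise ConfigError(f"unknown analyses: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path}: expected a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"config {path}: unknown keys {sorted(unknown)}")
        if "analyses" in raw:
            raw["analyses"] = tuple(raw["analyses"])
        return cls(**raw)

    def to_dict(self, portable: bool = False) -> dict:
        """Config as a plain dict; ``portable`` records out_dir as '.' so
        identical runs into different directories serialise identically."""
        d = dataclasses.asdict(self)
        d["analyses"] = list(self.analyses)
        if portable:
            d["out_dir"] = "."
        return d


def _write_tsv(df: pd.DataFrame, path: Path, *, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def _sidecar(path: Path, stage: str, inputs: list[str], seed: int) -> None:
    meta = {"stage": stage, "inputs": inputs, "seed": seed, "version": __version__}
    Path(str(path) + ".sidecar.json").write_text(json.dumps(meta, sort_keys=True, indent=1) + "\n")


def read_imputed_long(path: str | Path) -> list[pd.DataFrame]:
    """Split a long-format imputed TSV back into per-dataset frames."""
    long = pd.read_csv(path, sep="\t")
    if "dataset_index" not in long.columns or "sample_id" not in long.columns:
        raise ConfigError(f"{path}: not a long-format imputed stack")
    out = []
    for _, g in long.groupby("dataset_index", sort=True):
        out.append(g.drop(columns=["dataset_index"]).set_index("sample_id"))
    return out


def _write_simulated_inputs(
    cohort: SimulatedCohort, cohort_dir: Path, seed: int, root: Path | None = None
) -> dict:
    """Write one cohort's inputs; recorded paths are relative to ``root``."""
    root = root or cohort_dir
    cohort_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "weights": cohort_dir / "weights.tsv",
        "genotypes": cohort_dir / "genotypes.tsv",
        "phenotypes": cohort_dir / "phenotypes.csv",
        "provenance": cohort_dir / "simulation.json",
    }
    write_weight_table(cohort.config.true_panel, paths["weights"])
    write_dosage_matrix(cohort.genotypes, paths["genotypes"])
    write_phenotypes(cohort.phenotypes, paths["phenotypes"])
    paths["provenance"].write_text(
        json.dumps(cohort.config.to_dict(), sort_keys=True, indent=1) + "\n"
    )
    rel = {k: str(v.relative_to(root)) for k, v in paths.items()}
    for key in ("weights", "genotypes", "phenotypes"):
        _sidecar(paths[key], "simulate", [rel["provenance"]], seed)
    return rel


def _load_genotypes(path: str, panel: WeightPanel) -> GenotypeMatrix:
    if str(path).endswith(".vcf"):
        return read_genotypes_vcf(path, panel)
    return read_dosage_matrix(path, panel)


def _analyze_cohort(
    label: str,
    panel: WeightPanel,
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    config: PipelineConfig,
    out_dir: Path,
    root: Path,
) -> dict:
    """Score, impute and associate one cohort; returns a manifest fragment."""
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = child_seed(config.seed, label)
    summary: dict = {"label": label, "n_input_samples": len(genotypes.sample_ids)}

    retained, excluded = filter_low_genotyping(genotypes, config.min_genotyped)
    summary["n_excluded_low_genotyping"] = len(excluded)
    (out_dir / "excluded_samples.txt").write_text("".join(f"{s}\n" for s in excluded))
    logger.info("%s: excluded %d samples genotyped at < %d SNPs", label, len(excluded), config.min_genotyped)

    pheno = phenotypes.data.loc[retained.sample_ids]
    scores = score_matrix(retained, panel)
    is_case = pheno["is_case"] == 1
    case_scores = scores.loc[is_case, "scaled_score"]
    assignments = categorize_scores(scores["scaled_score"], case_scores.to_numpy())
    scores_out = scores.copy()
    scores_out["category"] = [a.category for a in assignments]
    scores_out.insert(0, "sample_id", scores_out.index)
    scores_path = out_dir / "scores.tsv"
    scores_rel = str(scores_path.relative_to(root))
    _write_tsv(scores_out, scores_path)
    _sidecar(scores_path, "score", ["genotypes", "weights"], seed)
    summary["n_cases"] = int(is_case.sum())
    summary["n_controls"] = int((~is_case).sum())
    summary["case_mean_wgrs"] = float(case_scores.mean())
    summary["category_thresholds"] = list(category_thresholds(case_scores.to_numpy()))

    if "distribution" in config.analyses and (~is_case).sum() >= 2:
        report = score_distribution_report(
            case_scores.to_numpy(), scores.loc[~is_case, "scaled_score"].to_numpy()
        )
        dist = pd.DataFrame(
            [
                {
                    "mean": report.mean,
                    "sd": report.sd,
                    "min": report.min,
                    "max": report.max,
                    "mean_cases": report.mean_a,
                    "mean_controls": report.mean_b,
                    "levene_stat": report.levene_stat,
                    "levene_p": report.levene_p,
                    "t_stat": report.t_stat,
                    "t_p": report.t_p,
                    "equal_var": report.equal_var,
                }
            ]
        )
        _write_tsv(dist, out_dir / "distribution.tsv")
        _sidecar(out_dir / "distribution.tsv", "distribution", [scores_rel], seed)
        _write_tsv(report.qq_frame(), out_dir / "qq.tsv")
        _sidecar(out_dir / "qq.tsv", "distribution", [scores_rel], seed)
        summary["control_mean_wgrs"] = report.mean_b

    # case-only analysis table: scaled score joined to the clinical variables
    cases = pheno[is_case].copy()
    cases["wgrs"] = scores.loc[is_case.index[is_case], "scaled_score"]
    chain_cols = ["recurrence", "wgrs", "family_history", "early_onset", "ectopic", "bilateral", "sex"]
    case_table = cases[chain_cols]
    impute_ectopic = bool(case_table["ectopic"].isna().any())
    plan = default_plan(
        m=config.mice_m,
        cycles=config.mice_cycles,
        seed=child_seed(config.seed, label, "mice"),
        impute_ectopic=impute_ectopic,
    )
    stack = mice_impute(case_table, plan)
    long = stack.to_long_frame()
    imputed_path = out_dir / "imputed.tsv"
    imputed_rel = str(imputed_path.relative_to(root))
    _write_tsv(long, imputed_path)
    _sidecar(imputed_path, "impute", [scores_rel], plan.seed)
    summary["mice"] = {"m": plan.m, "cycles": plan.cycles, "impute_ectopic": impute_ectopic}

    # per-dataset score categories against that dataset's own case scores
    datasets = []
    for df in stack.datasets:
        df = df.copy()
        thr = category_thresholds(df["wgrs"].to_numpy())
        cats = categorize_scores(df["wgrs"], df["wgrs"].to_numpy())
        df["wgrs_category"] = [c.category for c in cats]
        datasets.append(df)
    data = ImputedStack(
        datasets=tuple(datasets), plan=plan, chain_seeds=stack.chain_seeds,
        diagnostics=stack.diagnostics,
    )

    estimates: dict = {}
    if "per_unit" in config.analyses:
        rows = []
        for model, adjust in (("unadjusted", ()), ("adjusted", tuple(DIATHESIS_FEATURES))):
            res = per_unit_association(data, adjust=adjust).iloc[0].to_dict()
            res["model"] = model
            rows.append(res)
            estimates[model] = {"log_or": res["estimate"], "se": res["se"]}
        per_unit = pd.DataFrame(rows)
        _write_tsv(per_unit, out_dir / "per_unit.tsv")
        _sidecar(out_dir / "per_unit.tsv", "associate", [imputed_rel], seed)
        summary["per_unit"] = {
            m: {k: float(v) for k, v in e.items()} for m, e in estimates.items()
        }
    if "category" in config.analyses:
        cat_table = recurrence_by_category(data)
        _write_tsv(cat_table, out_dir / "recurrence_by_category.tsv")
        _sidecar(out_dir / "recurrence_by_category.tsv", "associate", [imputed_rel], seed)
        top = cat_table[(cat_table["category"] == 4) & (cat_table["model"] == "adjusted")]
        summary["top_category_adjusted_or"] = float(top["or"].iloc[0])
    if "diathesis_count" in config.analyses:
        cnt_table = diathesis_count_analysis(data)
        _write_tsv(cnt_table, out_dir / "diathesis_count.tsv")
        _sidecar(out_dir / "diathesis_count.tsv", "associate", [imputed_rel], seed)
    if "diathesis_multinomial" in config.analyses:
        dbc = diathesis_by_category(data)
        _write_tsv(dbc, out_dir / "diathesis_by_category.tsv")
        _sidecar(out_dir / "diathesis_by_category.tsv", "associate", [imputed_rel], seed)

    summary["estimates"] = estimates
    return summary


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(portable=True), sort_keys=True))
    manifest: dict = {"version": __version__, "seed": config.seed, "config": config.to_dict(portable=True)}

    cohorts: list[tuple[str, WeightPanel, GenotypeMatrix, PhenotypeTable]] = []
    if config.simulate:
        cfg_a, cfg_b = default_two_cohort_configs(
            seed=config.seed,
            n_cases_a=config.n_cases_a,
            n_controls_a=config.n_controls_a,
            n_cases_b=config.n_cases_b,
            n_controls_b=config.n_controls_b,
        )
        manifest["simulated_inputs"] = {}
        for cfg in (cfg_a, cfg_b):
            cohort = simulate_cohort(cfg)
            paths = _write_simulated_inputs(cohort, out / "inputs" / cfg.label, config.seed, root=out)
            manifest["simulated_inputs"][cfg.label] = paths
            # read back through the standard readers: the analysis path is
            # identical to a run on user-supplied files
            panel = read_weight_table(out / paths["weights"])
            genotypes = read_dosage_matrix(out / paths["genotypes"], panel)
            phenotypes = read_phenotypes(out / paths["phenotypes"])
            cohorts.append((cfg.label, panel, genotypes, phenotypes))
    else:
        panel = read_weight_table(config.weights_path)
        genotypes = _load_genotypes(config.genotypes_path, panel)
        phenotypes = read_phenotypes(config.phenotypes_path)
        cohorts.append(("cohort", panel, genotypes, phenotypes))

    manifest["cohorts"] = []
    for label, panel, genotypes, phenotypes in cohorts:
        summary = _analyze_cohort(label, panel, genotypes, phenotypes, config, out / label, out)
        manifest["cohorts"].append(summary)

    if len(cohorts) >= 2 and "per_unit" in config.analyses:
        meta_rows = []
        for model in ("unadjusted", "adjusted"):
            studies = [
                StudyEstimate(
                    label=c["label"],
                    log_or=c["estimates"][model]["log_or"],
                    se=c["estimates"][model]["se"],
                )
                for c in manifest["cohorts"]
            ]
            res = fixed_effect_meta(studies)
            row = res.to_frame().iloc[0].to_dict()
            row["model"] = model
            meta_rows.append(row)
        meta_df = pd.DataFrame(meta_rows)
        _write_tsv(meta_df, out / "meta_per_unit.tsv")
        _sidecar(out / "meta_per_unit.tsv", "meta", ["per_unit.tsv per cohort"], config.seed)
        manifest["meta_per_unit"] = {
            r["model"]: {"or": float(r["or"]), "ci_low": float(r["ci_low"]), "ci_high": float(r["ci_high"]), "p": float(r["p"])}
            for r in meta_rows
        }

    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1) + "\n")
    return manifest
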