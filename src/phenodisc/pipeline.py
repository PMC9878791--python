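"""End-to-end orchestration of the three-model discrimination analysis.

Stage order is fixed: read -> anonymize -> low-information filter ->
imputation (group mean, then PMM) -> scaling -> correlation filter ->
MFA on the decorrelated set -> 30%-contribution selection -> per model
(full / decorrelated / sel30): MFA, four classifiers, accuracy, cumulative
variance, plots.  Every table written is listed in the manifest with a
checksum, so reruns are verifiable bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from phenodisc._random import substream_seed
from phenodisc.classify import (
    assess_accuracy,
    fit_glm_importance,
    fit_glmnet_importance,
    fit_multiglm_importance,
    fit_rf_importance,
    group_summaries,
)
from phenodisc.errors import PhenodiscError, StageError
from phenodisc.factor_core import FactorInput, cumulative_variance, mfamix
from phenodisc.preprocess import (
    ImputationSpec,
    drop_low_information,
    impute_group_mean,
    impute_pmm,
    scale_features,
)
from phenodisc.report_viz import StyleSpec, render_all
from phenodisc.selection import (
    contribution_table,
    correlation_matrix,
    remove_correlated,
    select_contributing,
)
from phenodisc.tabular_io import (
    PhenoTable,
    RunConfig,
    TYPE_QUAL,
    TYPE_QUANT,
    anonymize_ids,
    read_pheno_table,
    write_pheno_table,
)

MODELS = ("full", "decorrelated", "sel30")


@dataclass
class RunManifest:
    config: dict
    input_checksum: str = ""
    software_version: str = "0.1.0"
    timings: dict[str, float] = field(default_factory=dict)
    model_sets: dict[str, list[str]] = field(default_factory=dict)
    accuracies: dict[str, dict[str, list[float]]] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True, default=str)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _register(manifest: RunManifest, path: Path) -> None:
    manifest.outputs[str(path)] = _sha256(path)


def _write_tsv(frame: pd.DataFrame, path: Path, manifest: RunManifest) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t")
    _register(manifest, path)


def factor_input_for(table: PhenoTable, predictors: list[str], include_dependent: bool = True) -> FactorInput:
    """Assemble the factor-analysis block for a predictor set.

    The dependent variable joins as a qualitative variable (its levels are
    plotted in the component maps) but is never part of any classifier's
    predictor matrix.
    """
    quant = [c for c in predictors if table.var_types[c] == TYPE_QUANT]
    qual = [c for c in predictors if table.var_types[c] == TYPE_QUAL]
    if include_dependent:
        qual = qual + [table.dependent]
    groups = {}
    for var in quant + qual:
        groups[var] = table.var_groups.get(var) or var
    return FactorInput(
        quantitative=table.values[quant].astype(float),
        qualitative=table.values[qual].astype(str),
        groups=groups,
    )


def run_pipeline(
    source: str | Path | PhenoTable,
    config: RunConfig,
    outdir: str | Path,
    style: StyleSpec | None = None,
    render_plots: bool = True,
) -> RunManifest:
    """Run the whole three-model analysis; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    style = style or StyleSpec()
    manifest = RunManifest(config=json.loads(config.to_json()))
    clock = time.perf_counter
    state = {"stage": "init", "start": clock()}

    def _stage(name):
        state["stage"], state["start"] = name, clock()

    def _done(name):
        manifest.timings[name] = clock() - state["start"]

    try:
        _stage("read")
        if isinstance(source, PhenoTable):
            table = source.copy()
        else:
            source = Path(source)
            table = read_pheno_table(source, config)
            manifest.input_checksum = _sha256(source)
        _done("read")

        _stage("anonymize")
        if config.anonymize:
            table, mapping = anonymize_ids(table)
            map_path = outdir / "anonymization_mapping.tsv"
            mapping.to_csv(map_path, sep="\t", index=False)
            _register(manifest, map_path)
        _done("anonymize")

        _stage("filter")
        table, removed_low = drop_low_information(table)
        _done("filter")

        _stage("impute")
        table = impute_group_mean(table)
        if table.values.isna().any().any():
            table = impute_pmm(
                table,
                ImputationSpec(
                    k_donors=config.pmm_k_donors,
                    n_bootstrap=config.pmm_n_bootstrap,
                    seed=config.seed,
                ),
            )
            log = getattr(table, "imputation_log", None)
            if log is not None and len(log):
                log_path = outdir / "imputation_log.tsv"
                log.to_csv(log_path, sep="\t", index=False)
                _register(manifest, log_path)
        raw_table = table.copy()  # imputed, unscaled — for summaries
        _done("impute")

        _stage("scale")
        table = scale_features(table)
        write_pheno_table(table, outdir / "normalized_table.tsv")
        _register(manifest, outdir / "normalized_table.tsv")
        _done("scale")

        _stage("correlation")
        report = correlation_matrix(table)
        kept = remove_correlated(
            report, config.correlation_threshold, protected=tuple(table.conditioning)
        )
        _write_tsv(report.correlation, outdir / "correlation_matrix.tsv", manifest)
        _write_tsv(report.flagged_pairs, outdir / "flagged_pairs.tsv", manifest)
        _done("correlation")

        _stage("selection")
        predictors = table.predictors
        mfa_decor = mfamix(factor_input_for(table, kept))
        sel30 = select_contributing(
            mfa_decor,
            config.contribution_threshold,
            config.n_dims_selection,
            exclude=(table.dependent,),
        )
        sel30 = [v for v in kept if v in sel30]  # enforce nesting + column order
        report.model_sets = {
            "full": list(predictors),
            "decorrelated": list(kept),
            "sel30": sel30,
        }
        report.contributions = contribution_table(mfa_decor, config.n_dims_selection)
        manifest.model_sets = {k: list(v) for k, v in report.model_sets.items()}
        _write_tsv(report.to_selection_frame().set_index("variable"),
                   outdir / "selection.tsv", manifest)
        _write_tsv(report.contributions.set_index("variable"),
                   outdir / "contributions.tsv", manifest)
        _done("selection")

        summaries_raw = group_summaries(raw_table)
        summaries_scaled = group_summaries(table)
        _write_tsv(summaries_raw.frame, outdir / "group_summaries.tsv", manifest)

        y = table.values[table.dependent].astype(str)
        for model in MODELS:
            _stage(f"model:{model}")
            members = report.model_sets[model]
            model_dir = outdir / model
            mfa = mfamix(factor_input_for(table, members))
            _write_tsv(
                pd.DataFrame({"eigenvalue": mfa.eigenvalues,
                              "variance_pct": mfa.variance_pct,
                              "cumulative_pct": mfa.cumulative_pct}),
                model_dir / "eigenvalues.tsv", manifest)
            _write_tsv(mfa.squared_loadings, model_dir / "squared_loadings.tsv", manifest)
            _write_tsv(mfa.quant_correlations, model_dir / "quant_correlations.tsv", manifest)
            _write_tsv(mfa.level_coordinates, model_dir / "level_coordinates.tsv", manifest)
            _write_tsv(mfa.group_contributions, model_dir / "group_contributions.tsv", manifest)
            _write_tsv(mfa.partial_axes, model_dir / "partial_axes.tsv", manifest)
            _write_tsv(mfa.scores, model_dir / "individual_coordinates.tsv", manifest)
            _write_tsv(cumulative_variance(mfa, config.n_dims_variance).set_index("dimension"),
                       model_dir / "cumulative_variance.tsv", manifest)

            X = table.values[members]
            seed = config.seed
            glm_imp = fit_glm_importance(X, y, max_iter=config.max_iter)
            glm_imp.classifier = "glm"  # keep the slot name when routed to multinomial
            imps = [
                glm_imp,
                fit_multiglm_importance(X, y, max_iter=config.max_iter),
                fit_glmnet_importance(
                    X, y, alphas=config.alpha_grid,
                    lambdas=None if config.n_lambda >= 50 else tuple(
                        np.logspace(-4, 1, config.n_lambda)),
                    seed=seed),
                fit_rf_importance(X, y, n_trees=config.n_trees,
                                  mtry=config.rf_mtry, seed=seed),
            ]
            manifest.accuracies[model] = {}
            factories = {
                "multiglm": lambda: LogisticRegression(max_iter=config.max_iter),
                "rf": lambda: RandomForestClassifier(
                    n_estimators=min(config.n_trees, 200),
                    random_state=substream_seed(seed, f"acc/{model}/rf")),
            }
            for name, factory in factories.items():
                mean, sd = assess_accuracy(
                    factory, X, y, resampling=("bootstrap", config.n_resamples), seed=seed)
                manifest.accuracies[model][name] = [mean, sd]
            long = pd.concat(
                [t.frame.assign(classifier=t.classifier) for t in imps], ignore_index=True)
            _write_tsv(long.set_index(["classifier", "class", "variable"]),
                       model_dir / "importances.tsv", manifest)

            if render_plots:
                viz = render_all(
                    mfa, report, imps, summaries_raw, style, model_dir,
                    class_labels=y, summaries_scaled=summaries_scaled,
                )
                for f in viz["files"]:
                    _register(manifest, Path(f))
            _done(f"model:{model}")

        manifest_path = outdir / "run_manifest.json"
        manifest_path.write_text(manifest.to_json())
        return manifest
    except PhenodiscError:
        raise
    except Exception as exc:  # noqa: BLE001 - partial outputs stay on disk
        raise StageError(state["stage"], str(exc)) from exc
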