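"""End-to-end orchestration: generate -> fit -> rank -> classify -> intersect.

Given a :class:`~grnsets.config.RunConfig`, the pipeline generates synthetic
datasets for the wild-type and knock-out experiments from a chosen
ground-truth structure (or loads supplied CSVs), fits the corresponding
structure family to each experiment, draws the acceptability threshold on
each cost curve, trains the wild-type acceptability classifier when the full
three-gene family is in play, and intersects the per-experiment model sets.
Every stage writes plain-text artifacts into the output directory, fitting is
resumable through per-model checkpoints, and a manifest records the seeds,
configuration and input hashes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as gio
from .config import RunConfig, derive_seed
from .fitting import FitOptions, fit_family
from .modelsets import (
    ModelSet,
    extract_model_set,
    feature_matrix,
    intersect_model_sets,
    train_acceptability_classifier,
)
from .sweep import cost_curve, select_acceptance_threshold
from .synth import (
    KNOCKOUT_OF_EXPERIMENT,
    NoiseSpec,
    experimental_design,
    generate_dataset,
    max_scale,
)
from .terms import GENES, build_family, named_models, reduce_for_knockout


class PipelineError(RuntimeError):
    pass


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _fit_options(config: RunConfig) -> FitOptions:
    return FitOptions(
        maxiter=config.maxiter,
        maxfun=config.maxfun,
        rtol=config.rtol,
        atol=config.atol,
        sigma_floor=config.sigma_floor,
        preset_protein_ic=config.preset_protein_ic,
    )


def run_pipeline(
    config: RunConfig, outdir, datasets: Optional[dict] = None
) -> Path:
    """Execute the full analysis and return the artifact directory.

    ``datasets`` may supply pre-loaded :class:`ExpressionDataset` objects per
    experiment label; otherwise synthetic data are generated from the
    configured ground-truth structure under each experiment's design.
    A stage failure halts with the stage name; finished fit checkpoints
    survive and are reused on the next invocation.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "master_seed": config.master_seed,
        "stage_seeds": {},
        "inputs": {},
    }
    wt_label = "WT"
    options = _fit_options(config)

    stage = "generate"
    try:
        if datasets is None:
            if config.true_model not in named_models():
                raise PipelineError(f"unknown ground-truth model {config.true_model!r}")
            truth = named_models()[config.true_model]
        else:
            truth = None
        base_family = build_family(config.regulators, config.genes)
        prepared = {}
        for experiment in config.experiments:
            if datasets is not None and experiment in datasets:
                dataset = datasets[experiment]
                manifest["inputs"][experiment] = "supplied"
            else:
                times, replicates = experimental_design(experiment)
                ko_gene = KNOCKOUT_OF_EXPERIMENT.get(experiment)
                model = truth if ko_gene is None else reduce_for_knockout(truth, ko_gene)
                data_seed = derive_seed(config.master_seed, "generate", experiment)
                manifest["stage_seeds"][f"generate/{experiment}"] = data_seed
                dataset = generate_dataset(
                    model,
                    _true_params_for(model),
                    np.asarray(times),
                    replicates,
                    NoiseSpec(cv=config.noise_cv, seed=data_seed),
                    experiment=experiment,
                )
            dataset = max_scale(dataset, config.scaling_scope)
            path = outdir / f"data_{experiment}.csv"
            gio.write_expression_csv(dataset, path)
            manifest["inputs"].setdefault(experiment, _file_hash(path))
            prepared[experiment] = dataset

        stage = "fit"
        fits = {}
        families = {}
        for experiment, dataset in prepared.items():
            ko_gene = KNOCKOUT_OF_EXPERIMENT.get(experiment)
            if ko_gene is None:
                family = base_family
                model_indices = config.model_indices
            else:
                if ko_gene not in base_family.target_genes:
                    continue
                family = reduce_for_knockout(base_family, ko_gene)
                model_indices = None
            fit_seed = derive_seed(config.master_seed, "fit", experiment)
            manifest["stage_seeds"][f"fit/{experiment}"] = fit_seed
            table = fit_family(
                family,
                dataset,
                n_starts=config.n_starts,
                seed=fit_seed,
                workers=config.workers,
                options=options,
                model_indices=model_indices,
                checkpoint_dir=outdir / f"checkpoints_{experiment}",
            )
            gio.write_table_tsv(table, outdir / f"fits_{experiment}.tsv")
            fits[experiment] = table
            families[experiment] = family

        stage = "rank"
        model_sets = {}
        for experiment, table in fits.items():
            curve = cost_curve(table)
            if experiment == wt_label:
                k = min(config.acceptable_rank, max(1, len(curve.table) - 1))
                curve = select_acceptance_threshold(curve, "rank_k", k=k)
            else:
                curve = select_acceptance_threshold(curve, config.ko_threshold_mode,
                                                    k=min(config.acceptable_rank, max(1, len(curve.table) - 1)))
            gio.write_table_tsv(curve.table, outdir / f"curve_{experiment}.tsv")
            acceptable = curve.table.loc[curve.table["acceptable"], "model_index"]
            model_sets[experiment] = ModelSet(
                experiment=experiment,
                indices=frozenset(int(i) for i in acceptable),
                family=families[experiment],
                description="acceptability-thresholded cost curve",
            )

        stage = "classify"
        classify = (
            wt_label in fits
            and tuple(base_family.target_genes) == GENES
            and len(base_family.available_regulators) == 3
        )
        if classify:
            table = fits[wt_label]
            indices = table["model_index"].to_numpy()
            labels = np.isin(indices, list(model_sets[wt_label].indices))
            features = feature_matrix(base_family, model_indices=indices)
            tree_seed = derive_seed(config.master_seed, "classify")
            manifest["stage_seeds"]["classify"] = tree_seed
            tree, accuracy = train_acceptability_classifier(
                features,
                labels,
                max_depth=config.classifier_max_depth,
                criterion=config.classifier_criterion,
                k_folds=config.classifier_folds,
                upsample_minority=config.upsample_minority,
                seed=tree_seed,
            )
            manifest["classifier_cv_accuracy"] = accuracy
            if hasattr(tree, "tree_"):
                predicted = extract_model_set(
                    tree, base_family, experiment=wt_label, description="decision-tree prediction"
                )
                gio.write_json(predicted.to_json_dict(), outdir / "model_set_WT_predicted.json")

        stage = "intersect"
        for experiment, model_set in model_sets.items():
            gio.write_json(model_set.to_json_dict(), outdir / f"model_set_{experiment}.json")
        ko_sets = {
            KNOCKOUT_OF_EXPERIMENT[exp]: ms
            for exp, ms in model_sets.items()
            if exp in KNOCKOUT_OF_EXPERIMENT
        }
        if wt_label in model_sets:
            intersection = intersect_model_sets(model_sets[wt_label], ko_sets)
            gio.write_json(intersection.to_json_dict(), outdir / "model_set_intersection.json")
            manifest["intersection_size"] = len(intersection)

        stage = "manifest"
        import grnsets

        manifest["version"] = getattr(grnsets, "__version__", "unknown")
        gio.write_json(manifest, outdir / "manifest.json")
    except Exception as exc:
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outdir


def _true_params_for(model):
    from .synth import default_true_params

    params = default_true_params()
    genes = model.genes
    return type(params)(
        alpha={g: params.alpha[g] for g in genes},
        k_tx={g: params.k_tx[g] for g in genes},
        k_m=params.k_m,
        k_p=params.k_p,
        K=params.K,
        m0={g: params.m0[g] for g in genes},
        p0={p: params.p0[p] for p in model.proteins},
        translation_rate=params.translation_rate,
    )
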