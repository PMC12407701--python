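"""Structural featurization, acceptability classification and model sets.

A *model set* is the collection of network structures that achieve an
acceptable fit to one experiment and share regulatory features.  For the
wild-type family the set is characterised by binarizing 21 structural
features of every structure and training a shallow decision tree to predict
acceptability; knock-out families are small enough to threshold directly.
Model sets from different experiments are intersected by projecting each
wild-type structure through its knock-out reductions.

The 21-feature schema (this package's documented convention; 9 + 3 + 3 + 3
+ 3): for each target gene in order (eud-1, nhr-40, sult-1) — regulated by
E, by N, by S (9 features); then per gene: any activating factor (3), any
repressing factor (3), autoregulated, i.e. the gene's own protein appears in
its term (3), cooperative/squared term (3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.tree import DecisionTreeClassifier

from .terms import (
    ACTIVATION,
    GENES,
    PROTEIN_OF_GENE,
    REGULATORS,
    REPRESSION,
    ModelFamily,
    RegulatoryModel,
    model_from_index,
    reduce_for_knockout,
    index_of_model,
)


class ModelSetError(ValueError):
    pass


def _gene_tag(gene: str) -> str:
    return gene.replace("-", "")


FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"{_gene_tag(g)}_regulated_by_{r}" for g in GENES for r in REGULATORS]
    + [f"{_gene_tag(g)}_any_activation" for g in GENES]
    + [f"{_gene_tag(g)}_any_repression" for g in GENES]
    + [f"{_gene_tag(g)}_autoregulated" for g in GENES]
    + [f"{_gene_tag(g)}_cooperative" for g in GENES]
)
assert len(FEATURE_NAMES) == 21


def featurize(model: RegulatoryModel) -> np.ndarray:
    """21 binary structural features of a wild-type (3-gene) structure."""
    if model.knockout is not None or set(model.genes) != set(GENES):
        raise ModelSetError("featurization is defined on the full wild-type family")
    values = []
    terms = [model.terms[g] for g in GENES]
    for term in terms:
        regs = term.regulators
        values.extend(int(r in regs) for r in REGULATORS)
    for sign in (ACTIVATION, REPRESSION):
        for term in terms:
            values.append(int(any(s == sign for _, s in term.factors)))
    for gene, term in zip(GENES, terms):
        values.append(int(PROTEIN_OF_GENE[gene] in term.regulators))
    for term in terms:
        values.append(int(term.exponent == 2))
    return np.array(values, dtype=np.int8)


def feature_matrix(family: ModelFamily, model_indices=None) -> pd.DataFrame:
    """Feature vectors for a family (or index subset), indexed by model index."""
    indices = range(family.size) if model_indices is None else model_indices
    rows = [featurize(model_from_index(family, i)) for i in indices]
    frame = pd.DataFrame(rows, columns=FEATURE_NAMES, index=list(indices))
    frame.index.name = "model_index"
    return frame


@dataclass
class MajorityClassifier:
    """Degenerate fallback when the labels contain a single class."""

    label: bool

    def predict(self, X) -> np.ndarray:
        return np.full(np.asarray(X).shape[0], self.label)


def train_acceptability_classifier(
    features: pd.DataFrame,
    labels,
    max_depth: int = 5,
    criterion: str = "gini",
    k_folds: int = 5,
    upsample_minority: bool = False,
    seed: int = 0,
):
    """Fit a shallow decision tree predicting fit acceptability from structure.

    Returns ``(classifier, mean_cv_accuracy)`` using stratified K-fold
    cross-validation.  With single-class labels a majority classifier and its
    (trivial) accuracy are returned instead of a tree.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if X.shape[0] != y.shape[0]:
        raise ModelSetError("features and labels must have the same length")
    classes = np.unique(y)
    if classes.size == 1:
        return MajorityClassifier(bool(classes[0])), 1.0 if y.all() or not y.any() else 0.0
    if upsample_minority:
        rng = np.random.default_rng(seed)
        minority = classes[np.argmin([np.sum(y == c) for c in classes])]
        idx = np.flatnonzero(y == minority)
        extra = rng.choice(idx, size=np.sum(y != minority) - idx.size, replace=True)
        X = np.vstack([X, X[extra]])
        y = np.concatenate([y, y[extra]])
    tree = DecisionTreeClassifier(max_depth=max_depth, criterion=criterion, random_state=seed)
    cv = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    accuracy = float(np.mean(cross_val_score(tree, X, y, cv=cv, scoring="accuracy")))
    tree.fit(X, y)
    return tree, accuracy


def depth_sweep(features, labels, depths=range(1, 11), **kwargs) -> pd.DataFrame:
    """Cross-validated accuracy as a function of maximum tree depth."""
    rows = [
        {"max_depth": d, "cv_accuracy": train_acceptability_classifier(features, labels, max_depth=d, **kwargs)[1]}
        for d in depths
    ]
    return pd.DataFrame(rows)


def null_accuracy(family_size: int, n_acceptable: int) -> float:
    """Accuracy of labelling everything unacceptable (the majority baseline)."""
    return (family_size - n_acceptable) / family_size


@dataclass
class ModelSet:
    """A set of structure indices within one family, for one experiment."""

    experiment: str
    indices: frozenset[int]
    family: ModelFamily
    description: str = ""

    def __post_init__(self) -> None:
        bad = [i for i in self.indices if not 0 <= i < self.family.size]
        if bad:
            raise ModelSetError(f"indices outside the family: {sorted(bad)[:5]}")

    def __len__(self) -> int:
        return len(self.indices)

    def to_json_dict(self) -> dict:
        return {
            "experiment": self.experiment,
            "knockout": self.family.knockout,
            "indices": sorted(self.indices),
            "description": self.description,
        }


def extract_model_set(
    predictor: Union[Callable[[np.ndarray], bool], DecisionTreeClassifier, MajorityClassifier],
    family: ModelFamily,
    experiment: str = "",
    description: str = "",
) -> ModelSet:
    """All structures of a family predicted acceptable.

    ``predictor`` is either a fitted classifier (``predict`` over feature
    rows) or a boolean predicate on a single feature vector.  Enumerates the
    family exhaustively.
    """
    features = feature_matrix(family)
    if hasattr(predictor, "predict"):
        mask = np.asarray(predictor.predict(features.to_numpy(dtype=float)), dtype=bool)
    else:
        mask = np.array([bool(predictor(row)) for row in features.to_numpy()], dtype=bool)
    indices = frozenset(int(i) for i in features.index[mask])
    return ModelSet(experiment=experiment, indices=indices, family=family, description=description)


def leaf_class_counts(tree: DecisionTreeClassifier, family: ModelFamily) -> pd.DataFrame:
    """Per-leaf counts of family structures routed to each decision-tree leaf."""
    features = feature_matrix(family)
    leaves = tree.apply(features.to_numpy(dtype=float))
    predictions = tree.predict(features.to_numpy(dtype=float)).astype(bool)
    frame = pd.DataFrame({"leaf": leaves, "acceptable": predictions})
    return frame.groupby(["leaf", "acceptable"]).size().rename("count").reset_index()


def project_to_knockout(
    model: RegulatoryModel, ko_gene: str, ko_family: ModelFamily
) -> Optional[int]:
    """Index of a wild-type structure's knock-out reduction, if it is a family member.

    A reduction whose term collapsed to basal-only production (no factors
    left) has no counterpart in the knock-out term library and maps to None.
    """
    reduced = reduce_for_knockout(model, ko_gene)
    try:
        return index_of_model(ko_family, reduced)
    except Exception:
        return None


def intersect_model_sets(
    wt_set: ModelSet, ko_sets: dict[str, ModelSet]
) -> ModelSet:
    """Wild-type structures whose knock-out reductions lie in every knock-out set.

    ``ko_sets`` maps the knocked-out gene to that experiment's model set; the
    projection rule is structural reduction followed by re-indexing in the
    knock-out family.  With an empty ``ko_sets`` this is the wild-type set
    itself; sets over the same family intersect directly via their indices.
    """
    for gene, ko_set in ko_sets.items():
        if ko_set.family.knockout != gene:
            raise ModelSetError(
                f"model set for {gene} knock-out has family knockout {ko_set.family.knockout!r}"
            )
    kept = []
    for index in sorted(wt_set.indices):
        model = model_from_index(wt_set.family, index)
        ok = True
        for gene, ko_set in ko_sets.items():
            projected = project_to_knockout(model, gene, ko_set.family)
            if projected is None or projected not in ko_set.indices:
                ok = False
                break
        if ok:
            kept.append(index)
    description = "intersection: " + ", ".join([wt_set.experiment, *ko_sets])
    return ModelSet(
        experiment="intersection",
        indices=frozenset(kept),
        family=wt_set.family,
        description=description,
    )
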