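"""Random-forest classification of samples into aggressiveness classes.

Each sample is a feature vector over the selected genes: the gene's
interactome connection count if the gene is upregulated in that sample, zero
otherwise. A forest of Gini-impurity trees (defaults mtry = 8 candidate
features per split, ntree = 50) is evaluated purely by its out-of-bag (OOB)
predictions — each sample classified by the trees whose bootstrap missed it —
so no train/test split is needed. Feature importance is the mean decrease in
Gini impurity attributable to splits on each gene.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .interactome import Interactome
from .synthcohort import SampleProfile

__all__ = [
    "SampleFeatureMatrix",
    "RFCResult",
    "build_sample_features",
    "train_rfc",
    "confusion_error_rates",
    "importance_ranking",
]

logger = logging.getLogger(__name__)

CLASS_ORDER = ("H", "L")


@dataclass
class SampleFeatureMatrix:
    X: pd.DataFrame  # samples x genes; degree if upregulated else 0
    y: pd.Series  # H/L label per sample

    def __post_init__(self):
        if not set(self.y.unique()) <= set(CLASS_ORDER):
            raise ValueError("labels must be H or L")
        if (self.X.to_numpy() < 0).any():
            raise ValueError("feature values must be non-negative")


@dataclass
class RFCResult:
    confusion: pd.DataFrame  # rows true class, columns OOB-predicted class
    class_errors: dict[str, float]
    oob_error: float
    importances: pd.Series  # per-gene mean decrease in Gini (normalized)
    mtry: int
    ntree: int
    seed: int
    n_never_oob: int = 0  # samples in every bootstrap (majority-class fallback)


def build_sample_features(
    profiles: Sequence[SampleProfile],
    interactome: Interactome | Mapping[str, int],
    genes: Sequence[str],
) -> SampleFeatureMatrix:
    """Sample x gene connection-count features.

    Genes missing from the interactome are dropped (with a warning) rather
    than given an arbitrary value.
    """
    degrees = (
        interactome.degrees() if isinstance(interactome, Interactome) else dict(interactome)
    )
    kept = [g for g in genes if g in degrees]
    if len(kept) < len(genes):
        logger.warning(
            "%d feature genes missing from interactome were dropped",
            len(genes) - len(kept),
        )
    rows = np.zeros((len(profiles), len(kept)))
    col = {g: j for j, g in enumerate(kept)}
    for i, p in enumerate(profiles):
        for g in p.genes:
            j = col.get(g)
            if j is not None:
                rows[i, j] = degrees[g]
    X = pd.DataFrame(rows, index=[p.sample_id for p in profiles], columns=kept)
    y = pd.Series([p.class_label for p in profiles], index=X.index, name="class")
    return SampleFeatureMatrix(X=X, y=y)


def train_rfc(
    features: SampleFeatureMatrix,
    mtry: int = 8,
    ntree: int = 50,
    seed: int = 0,
) -> RFCResult:
    """Fit the forest and evaluate by out-of-bag prediction.

    Each tree is grown on a bootstrap resample with ``mtry`` candidate
    features per split; each sample's OOB prediction aggregates only the
    trees that never saw it. The rare sample present in every bootstrap is
    assigned the majority class and counted in ``n_never_oob``.
    """
    classes = sorted(features.y.unique())
    if len(classes) < 2:
        raise ValueError("both classes must be represented")
    if mtry > features.X.shape[1]:
        raise ValueError(
            f"mtry={mtry} exceeds the {features.X.shape[1]} available features"
        )
    clf = RandomForestClassifier(
        n_estimators=ntree,
        max_features=mtry,
        criterion="gini",
        bootstrap=True,
        oob_score=True,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # small forests can leave a sample in every bootstrap; handled below
        warnings.filterwarnings("ignore", message=".*out-of-bag.*")
        clf.fit(features.X.to_numpy(), features.y.to_numpy())
    proba = clf.oob_decision_function_
    never = np.isnan(proba).any(axis=1) | (np.nansum(proba, axis=1) == 0)
    majority = features.y.value_counts().idxmax()
    pred = np.empty(len(features.y), dtype=object)
    pred[~never] = clf.classes_[np.argmax(proba[~never], axis=1)]
    pred[never] = majority
    confusion = pd.DataFrame(
        0, index=list(CLASS_ORDER), columns=list(CLASS_ORDER), dtype=int
    )
    for true, hat in zip(features.y, pred):
        confusion.loc[true, hat] += 1
    class_errors, oob = confusion_error_rates(confusion)
    importances = pd.Series(
        clf.feature_importances_, index=features.X.columns, name="mean_decrease_gini"
    )
    return RFCResult(
        confusion=confusion,
        class_errors=class_errors,
        oob_error=oob,
        importances=importances,
        mtry=mtry,
        ntree=ntree,
        seed=seed,
        n_never_oob=int(never.sum()),
    )


def confusion_error_rates(
    confusion: pd.DataFrame | np.ndarray,
) -> tuple[dict[str, float], float]:
    """Per-class and overall error rates from a 2x2 confusion matrix.

    Rows are true classes; per-class error is the off-diagonal fraction of
    the row, overall error the off-diagonal fraction of all samples.
    """
    mat = pd.DataFrame(confusion)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError("confusion matrix must be square")
    arr = mat.to_numpy()
    if (arr < 0).any() or not np.issubdtype(arr.dtype, np.number):
        raise ValueError("confusion entries must be non-negative numbers")
    row_sums = arr.sum(axis=1)
    if (row_sums == 0).any():
        raise ValueError("every true class needs at least one sample")
    diag = np.diag(arr)
    class_errors = {
        str(mat.index[i]): float((row_sums[i] - diag[i]) / row_sums[i])
        for i in range(len(row_sums))
    }
    overall = float((arr.sum() - diag.sum()) / arr.sum())
    return class_errors, overall


def importance_ranking(result: RFCResult, top_k: int | None = None) -> pd.DataFrame:
    """Genes by decreasing Gini importance; ties broken lexicographically."""
    df = result.importances.rename_axis("gene").reset_index()
    df = df.sort_values(
        ["mean_decrease_gini", "gene"], ascending=[False, True]
    ).reset_index(drop=True)
    if top_k is not None:
        if top_k < 0:
            raise ValueError("top_k must be non-negative")
        if top_k > len(df):
            logger.warning("top_k=%d exceeds %d genes; truncating", top_k, len(df))
        df = df.head(top_k)
    return df
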