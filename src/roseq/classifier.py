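"""Linear-SVM protocol classification with leave-one-out cross-validation.

Each gene contributes one 2-D feature per sample — its (PC1, PC2)
scores from the wavelet detail-coefficient PCA.  For every gene, each
sample is held out once while a linear-kernel SVM is trained on the
rest; per-gene accuracy is the fraction of correctly predicted folds.
A majority-rules vote across genes then calls the protocol of each
held-out sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .errors import ValidationError

__all__ = ["LOOCVResult", "loocv_per_gene", "loocv_per_gene_refit",
           "majority_vote", "classify_cohort", "ClassificationReport"]

logger = logging.getLogger(__name__)


@dataclass
class LOOCVResult:
    """Fold-level predictions plus per-gene accuracy.

    ``predictions`` has one row per (gene, held-out sample) with columns
    ``gene_id, sample_id, truth, predicted, decision`` where ``decision``
    is the signed SVM decision value (positive for the alphabetically
    later class).
    """

    predictions: pd.DataFrame
    per_gene_accuracy: pd.Series
    n_folds: int
    skipped_genes: list[str] = field(default_factory=list)
    skipped_folds: int = 0


def _standardize(X_train: np.ndarray, X_test: np.ndarray):
    """Per-feature z-scaling fitted on the training fold only.

    Mirrors the scale-by-default behaviour of standard SVM front ends;
    without it the soft margin is meaningless when PC scores are tiny.
    Constant features are left unscaled.
    """
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X_train - mu) / sd, (X_test - mu) / sd


def loocv_per_gene(
    features: pd.DataFrame,
    labels: Mapping[str, str],
    C: float = 1.0,
) -> LOOCVResult:
    """Leave-one-out SVM evaluation of every gene's (PC1, PC2) features.

    ``features`` is tidy with columns ``gene_id, sample_id, pc1, pc2``.
    Each of the n samples is held out once (n folds).  Features are
    z-scaled within each training fold.  Folds whose training set
    collapses to one class are skipped with a warning; genes with
    constant features are skipped and logged.
    """
    required = {"gene_id", "sample_id", "pc1", "pc2"}
    if not required.issubset(features.columns):
        raise ValidationError(f"features needs columns {sorted(required)}")
    sample_ids = sorted(features["sample_id"].unique())
    n = len(sample_ids)
    if n < 3:
        raise ValidationError("LOOCV needs at least 3 samples")
    y_all = np.array([labels[s] for s in sample_ids])
    classes = np.unique(y_all)
    if len(classes) != 2:
        raise ValidationError("need exactly two protocol labels")

    rows = []
    accs = {}
    skipped_genes: list[str] = []
    skipped_folds = 0
    for gene_id, sub in features.groupby("gene_id", sort=True):
        sub = sub.set_index("sample_id").loc[sample_ids]
        X = sub[["pc1", "pc2"]].to_numpy(dtype=float)
        if np.allclose(X, X[0]):
            skipped_genes.append(str(gene_id))
            logger.info("loocv: gene %s has constant scores, skipped", gene_id)
            continue
        correct = evaluated = 0
        for i in range(n):
            train = np.delete(np.arange(n), i)
            y_train = y_all[train]
            if len(np.unique(y_train)) < 2:
                skipped_folds += 1
                warnings.warn(
                    f"fold holding out {sample_ids[i]} has single-class training; skipped",
                    stacklevel=2,
                )
                continue
            X_train, X_test = _standardize(X[train], X[[i]])
            model = SVC(kernel="linear", C=C)
            model.fit(X_train, y_train)
            pred = model.predict(X_test)[0]
            decision = float(model.decision_function(X_test)[0])
            rows.append((gene_id, sample_ids[i], y_all[i], pred, decision))
            evaluated += 1
            correct += int(pred == y_all[i])
        if evaluated:
            accs[gene_id] = correct / evaluated
    if not rows:
        raise ValidationError("no evaluable folds (degenerate cohort)")
    predictions = pd.DataFrame(
        rows, columns=["gene_id", "sample_id", "truth", "predicted", "decision"]
    )
    return LOOCVResult(
        predictions=predictions,
        per_gene_accuracy=pd.Series(accs, dtype=float).sort_index(),
        n_folds=n,
        skipped_genes=skipped_genes,
        skipped_folds=skipped_folds,
    )


def loocv_per_gene_refit(
    detail_matrices: Mapping[str, tuple[np.ndarray, list[str]]],
    labels: Mapping[str, str],
    C: float = 1.0,
) -> LOOCVResult:
    """Leave-one-out evaluation with the PCA basis re-fit per fold.

    ``detail_matrices`` maps gene id -> (samples x coefficients matrix,
    sample ids).  For every fold the top-2 principal axes are estimated
    from the training samples only and the held-out sample is projected
    onto them, so no information from the held-out sample enters the
    score basis.  Otherwise identical to :func:`loocv_per_gene`.
    """
    from .wavelet import per_gene_pca

    first = next(iter(detail_matrices.values()), None)
    if first is None:
        raise ValidationError("no genes supplied")
    sample_ids = list(first[1])
    n = len(sample_ids)
    if n < 3:
        raise ValidationError("LOOCV needs at least 3 samples")
    y_all = np.array([labels[s] for s in sample_ids])
    if len(np.unique(y_all)) != 2:
        raise ValidationError("need exactly two protocol labels")

    rows = []
    accs = {}
    skipped_genes: list[str] = []
    skipped_folds = 0
    for gene_id in sorted(detail_matrices):
        M, ids = detail_matrices[gene_id]
        if list(ids) != sample_ids:
            raise ValidationError("inconsistent sample order across genes")
        M = np.asarray(M, dtype=float)
        correct = evaluated = 0
        try:
            for i in range(n):
                train = np.delete(np.arange(n), i)
                y_train = y_all[train]
                if len(np.unique(y_train)) < 2:
                    skipped_folds += 1
                    warnings.warn(
                        f"fold holding out {sample_ids[i]} has single-class "
                        "training; skipped", stacklevel=2,
                    )
                    continue
                pcs = per_gene_pca(M[train], [sample_ids[j] for j in train],
                                   gene_id)
                X_tr = pcs.scores
                X_te = ((M[i] - pcs.mean) @ pcs.components.T)[None, :]
                X_tr, X_te = _standardize(X_tr, X_te)
                model = SVC(kernel="linear", C=C)
                model.fit(X_tr, y_train)
                pred = model.predict(X_te)[0]
                decision = float(model.decision_function(X_te)[0])
                rows.append((gene_id, sample_ids[i], y_all[i], pred, decision))
                evaluated += 1
                correct += int(pred == y_all[i])
        except ValidationError:
            skipped_genes.append(str(gene_id))
            logger.info("loocv_refit: gene %s degenerate, skipped", gene_id)
            continue
        if evaluated:
            accs[gene_id] = correct / evaluated
    if not rows:
        raise ValidationError("no evaluable folds (degenerate cohort)")
    predictions = pd.DataFrame(
        rows, columns=["gene_id", "sample_id", "truth", "predicted", "decision"]
    )
    return LOOCVResult(
        predictions=predictions,
        per_gene_accuracy=pd.Series(accs, dtype=float).sort_index(),
        n_folds=n,
        skipped_genes=skipped_genes,
        skipped_folds=skipped_folds,
    )


def majority_vote(result: LOOCVResult) -> pd.DataFrame:
    """Modal predicted protocol per held-out sample.

    Returns a frame indexed by sample with columns ``call, truth,
    margin, tie`` where ``margin`` is the winning vote share.  Exact
    ties are broken by the sign of the summed SVM decision values and
    flagged.
    """
    out = []
    preds = result.predictions
    for sample_id, sub in preds.groupby("sample_id", sort=True):
        counts = sub["predicted"].value_counts()
        top = counts.max()
        winners = sorted(counts[counts == top].index)
        tie = len(winners) > 1
        if tie:
            # decision > 0 favours the lexicographically later class
            # (sklearn orders classes that way)
            call = winners[-1] if sub["decision"].sum() > 0 else winners[0]
        else:
            call = winners[0]
        out.append(
            {
                "sample_id": sample_id,
                "call": call,
                "truth": sub["truth"].iloc[0],
                "margin": top / len(sub),
                "tie": tie,
            }
        )
    return pd.DataFrame(out).set_index("sample_id")


@dataclass
class ClassificationReport:
    """Aggregate LOOCV + majority-vote output for a cohort."""

    loocv: LOOCVResult
    sample_calls: pd.DataFrame
    mean_gene_accuracy: float
    majority_accuracy: float


def classify_cohort(
    features: pd.DataFrame,
    labels: Mapping[str, str],
    C: float = 1.0,
) -> ClassificationReport:
    """Run per-gene LOOCV then majority voting; deterministic given inputs."""
    if features.empty:
        raise ValidationError("empty gene set")
    loocv = loocv_per_gene(features, labels, C=C)
    calls = majority_vote(loocv)
    return ClassificationReport(
        loocv=loocv,
        sample_calls=calls,
        mean_gene_accuracy=float(loocv.per_gene_accuracy.mean()),
        majority_accuracy=float((calls["call"] == calls["truth"]).mean()),
    )
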