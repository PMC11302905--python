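"""Cross-validation, ensembling and evaluation metrics.

The training recipe fits one model per cross-validation fold and predicts
with the ensemble mean of the member sigmoid outputs.  Evaluation reports
PR-AUC (the primary metric on imbalanced candidate sets), ROC-AUC, and the
Top-(n+i) success rate: for a protein with n bound ligands, a ligand is a
hit when some pocket ranked in the top n+i lies within 4 A (DCA) of it; the
rate aggregates hits over all ligands in the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import EnsembleError, MetricError
from .estimator import GraphTransformerSiteClassifier, lr_schedule  # re-export
from .graphs import PocketGraph
from .pockets import DCA_THRESHOLD

__all__ = [
    "Prediction", "EvalReport", "lr_schedule", "train_fold", "cross_validate",
    "ensemble_predict", "pr_roc_auc", "success_rate", "success_rates",
    "predictions_to_frame",
]


@dataclass(frozen=True)
class Prediction:
    """A scored pocket with its within-protein rank (1-based, best first)."""

    protein_id: str
    pocket_id: str
    score: float
    rank: int


@dataclass(frozen=True)
class EvalReport:
    pr_auc: float
    roc_auc: float
    success_rate: dict[int, float] | None
    n_proteins: int
    n_pockets: int
    n_ligands: int

    def to_dict(self) -> dict:
        return {
            "pr_auc": self.pr_auc,
            "roc_auc": self.roc_auc,
            "success_rate": None
            if self.success_rate is None
            else {str(k): v for k, v in self.success_rate.items()},
            "counts": {
                "proteins": self.n_proteins,
                "pockets": self.n_pockets,
                "ligands": self.n_ligands,
            },
        }


def train_fold(
    train_graphs: list[PocketGraph],
    valid_graphs: list[PocketGraph],
    **estimator_params,
) -> GraphTransformerSiteClassifier:
    """Fit one fold: train on ``train_graphs``, checkpoint on ``valid_graphs``."""
    est = GraphTransformerSiteClassifier(**estimator_params)
    return est.fit(train_graphs, validation_data=(valid_graphs, None))


def cross_validate(
    graphs: list[PocketGraph],
    n_folds: int = 5,
    seed: int = 0,
    **estimator_params,
) -> tuple[list[GraphTransformerSiteClassifier], np.ndarray]:
    """Seeded random pocket-level K-fold; returns fitted members and fold ids."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if len(graphs) < n_folds:
        raise ValueError("dataset smaller than the number of folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(graphs))
    fold_of = np.empty(len(graphs), dtype=int)
    for f, chunk in enumerate(np.array_split(order, n_folds)):
        fold_of[chunk] = f
    members = []
    for f in range(n_folds):
        train = [g for g, fo in zip(graphs, fold_of) if fo != f]
        valid = [g for g, fo in zip(graphs, fold_of) if fo == f]
        params = dict(estimator_params)
        params.setdefault("random_state", seed + f)
        members.append(train_fold(train, valid, **params))
    return members, fold_of


def _rank_within_protein(rows: list[tuple[str, str, float]]) -> list[Prediction]:
    by_protein: dict[str, list[tuple[str, float]]] = {}
    for protein_id, pocket_id, score in rows:
        by_protein.setdefault(protein_id, []).append((pocket_id, score))
    out = []
    for protein_id, items in by_protein.items():
        items.sort(key=lambda t: (-t[1], t[0]))  # descending score, pocket_id tiebreak
        for rank, (pocket_id, score) in enumerate(items, start=1):
            out.append(Prediction(protein_id, pocket_id, float(score), rank))
    return out


def ensemble_predict(
    members: list[GraphTransformerSiteClassifier],
    graphs: list[PocketGraph],
) -> list[Prediction]:
    """Mean member score per pocket, ranked per protein by descending score."""
    if not members:
        raise EnsembleError("an ensemble needs at least one member")
    configs = {m.config_ for m in members}
    if len(configs) > 1:
        raise EnsembleError("ensemble members have mismatched model configs")
    scores = np.mean([m.decision_function(graphs) for m in members], axis=0)
    rows = [(g.protein_id, g.pocket_id, s) for g, s in zip(graphs, scores)]
    return _rank_within_protein(rows)


def pr_roc_auc(scores, labels) -> tuple[float, float]:
    """PR-AUC (step-wise interpolated precision-recall) and ROC-AUC (trapezoid)."""
    labels = np.asarray([int(l) for l in labels])
    scores = np.asarray(scores, dtype=float)
    if len(set(labels)) < 2:
        raise MetricError("PR/ROC AUC are undefined for single-class labels")
    return (
        float(average_precision_score(labels, scores)),
        float(roc_auc_score(labels, scores)),
    )


def success_rate(
    predictions: list[Prediction],
    barycenters: dict[tuple[str, str], np.ndarray],
    protein_ligands: dict[str, list[np.ndarray]],
    i: int = 0,
    dca_threshold: float = DCA_THRESHOLD,
) -> float:
    """Top-(n+i) success rate over all ligands.

    ``barycenters`` maps ``(protein_id, pocket_id)`` to the pocket
    barycenter; ``protein_ligands`` maps each protein to its ligand atom
    coordinate arrays (n = number of ligands).  A ligand is a hit when any
    pocket ranked in the top n+i has DCA to it strictly below the
    threshold.  Proteins without ranked pockets count as all-miss.
    """
    preds_by_protein: dict[str, list[Prediction]] = {}
    for p in predictions:
        preds_by_protein.setdefault(p.protein_id, []).append(p)
    hits = 0
    total = 0
    for protein_id, ligands in protein_ligands.items():
        n = len(ligands)
        if n == 0:
            continue
        total += n
        preds = sorted(preds_by_protein.get(protein_id, []), key=lambda p: p.rank)
        if not preds:
            import warnings

            warnings.warn(f"protein {protein_id} has no ranked pockets; counted as missed")
            continue
        top = preds[: n + i]
        for ligand in ligands:
            ligand = np.asarray(ligand, float).reshape(-1, 3)
            for p in top:
                bc = np.asarray(barycenters[(protein_id, p.pocket_id)], float)
                if np.linalg.norm(ligand - bc, axis=1).min() < dca_threshold:
                    hits += 1
                    break
    if total == 0:
        raise MetricError("success rate needs at least one ligand")
    return hits / total


def success_rates(
    predictions: list[Prediction],
    barycenters: dict[tuple[str, str], np.ndarray],
    protein_ligands: dict[str, list[np.ndarray]],
    max_extra: int = 6,
) -> dict[int, float]:
    """Top-(n+i) success rates for i = 0..max_extra (non-decreasing in i)."""
    return {
        i: success_rate(predictions, barycenters, protein_ligands, i)
        for i in range(max_extra + 1)
    }


def evaluate(
    predictions: list[Prediction],
    labels: dict[tuple[str, str], bool],
    barycenters: dict[tuple[str, str], np.ndarray] | None = None,
    protein_ligands: dict[str, list[np.ndarray]] | None = None,
) -> EvalReport:
    """Full evaluation report; success rates only when geometry is supplied."""
    scores, y = [], []
    for p in predictions:
        key = (p.protein_id, p.pocket_id)
        if key in labels:
            scores.append(p.score)
            y.append(int(labels[key]))
    pr, roc = pr_roc_auc(scores, y)
    rates = None
    n_ligands = 0
    if barycenters is not None and protein_ligands is not None:
        rates = success_rates(predictions, barycenters, protein_ligands)
        n_ligands = sum(len(v) for v in protein_ligands.values())
    return EvalReport(
        pr_auc=pr,
        roc_auc=roc,
        success_rate=rates,
        n_proteins=len({p.protein_id for p in predictions}),
        n_pockets=len(predictions),
        n_ligands=n_ligands,
    )


def predictions_to_frame(predictions: list[Prediction]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.protein_id, p.pocket_id, p.score, p.rank) for p in predictions],
        columns=["protein_id", "pocket_id", "score", "rank"],
    )
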