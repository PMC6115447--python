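"""Classification and gene-selection metrics, and the replicated comparison.

Gene selection is scored on support recovery: NC is the number of true signal
genes with a nonzero fitted coefficient, NS the total number of nonzero
coefficients, and sensitivity/specificity are the gene-level rates
``NC / n_true`` and ``TN / (TN + FP)``.  Classification is scored on the
originally-unlabeled samples: accuracy at the 0.5 threshold and the ROC / AUC
of the final model's probabilities against the hidden truth.

``run_experiment`` drives the paired comparison: per replicate it simulates
each group once, tunes the lasso penalty once on the labeled subset, then runs
every requested variant on the identical dataset, mask and penalty, so
between-variant differences are not confounded by the draw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .core import ModelState, predict_prob, tune_penalty
from .simulate import SyntheticDataset, group_config, simulate_dataset
from .trainer import SampleStatus, TrainerConfig, Variant, run_variant
from .windows import Schedule

__all__ = [
    "GeneSelectionReport",
    "ClassificationReport",
    "ExperimentResult",
    "gene_selection_metrics",
    "classification_metrics",
    "evaluate_run",
    "run_experiment",
    "ALL_VARIANTS",
]

logger = logging.getLogger(__name__)

ALL_VARIANTS: tuple[Variant, ...] = tuple(Variant)


@dataclass(frozen=True)
class GeneSelectionReport:
    """Support-recovery counts and rates for one fitted model."""

    nc: int
    ns: int
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class ClassificationReport:
    """Accuracy, ROC points and AUC on a held-out set."""

    accuracy: float
    roc_points: np.ndarray  # (n_thresholds, 2) array of (FPR, TPR)
    auc: float


def gene_selection_metrics(
    model: ModelState, true_support: np.ndarray, p: int
) -> GeneSelectionReport:
    """Score the nonzero pattern of the coefficients against the true support."""
    true_support = np.asarray(true_support, dtype=int)
    selected = model.support
    n_true = len(true_support)
    nc = int(np.isin(selected, true_support).sum())
    ns = int(len(selected))
    fp = ns - nc
    tn = (p - n_true) - fp
    sensitivity = nc / n_true if n_true else 0.0
    specificity = tn / (p - n_true) if p > n_true else 1.0
    return GeneSelectionReport(nc, ns, sensitivity, specificity)


def classification_metrics(probs: np.ndarray, truth: np.ndarray) -> ClassificationReport:
    """Accuracy at the 0.5 threshold plus ROC / AUC (midrank tie handling)."""
    probs = np.asarray(probs, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if probs.shape != truth.shape:
        raise ValueError("probability and truth vectors differ in length")
    if len(np.unique(truth)) < 2:
        raise ValueError("AUC undefined: truth contains a single class")
    predicted = (probs > 0.5).astype(int)
    accuracy = float((predicted == truth).mean())
    fpr, tpr, _ = roc_curve(truth, probs, drop_intermediate=False)
    auc = float(roc_auc_score(truth, probs))
    return ClassificationReport(accuracy, np.column_stack([fpr, tpr]), auc)


def evaluate_run(
    model: ModelState,
    dataset: SyntheticDataset,
    final_status: np.ndarray | None = None,
) -> dict:
    """Evaluate one trained model on its dataset's originally-unlabeled samples.

    The reported accuracy scores the model's predictions on all n2 masked
    samples; ``accuracy_excl_oracle`` additionally drops samples whose true
    label was revealed by the oracle during training.
    """
    unl = ~dataset.observed_status
    probs = predict_prob(model, dataset.X.values[unl])
    cls = classification_metrics(probs, dataset.truth_labels[unl])
    gene = gene_selection_metrics(model, dataset.true_support, dataset.config.p)
    out = {
        "accuracy": cls.accuracy,
        "auc": cls.auc,
        "nc": gene.nc,
        "ns": gene.ns,
        "sensitivity": gene.sensitivity,
        "specificity": gene.specificity,
        "_roc_points": cls.roc_points,
    }
    if final_status is not None:
        not_oracle = unl & (np.asarray(final_status) != SampleStatus.ORACLE_LABELED)
        if not_oracle.sum() and len(np.unique(dataset.truth_labels[not_oracle])) == 2:
            probs2 = predict_prob(model, dataset.X.values[not_oracle])
            cls2 = classification_metrics(probs2, dataset.truth_labels[not_oracle])
            out["accuracy_excl_oracle"] = cls2.accuracy
        else:
            out["accuracy_excl_oracle"] = np.nan
    else:
        out["accuracy_excl_oracle"] = out["accuracy"]
    return out


@dataclass
class ExperimentResult:
    """Raw per-replicate rows plus replicate-averaged summary tables."""

    raw: pd.DataFrame
    roc_points: pd.DataFrame

    @property
    def summary(self) -> pd.DataFrame:
        metrics = ["nc", "ns", "sensitivity", "specificity", "accuracy", "auc"]
        g = self.raw.groupby(["group", "variant"], sort=False)[metrics]
        out = g.agg(["mean", "std"])
        out.columns = [f"{m}_{'sd' if s == 'std' else s}" for m, s in out.columns]
        out["n_replicates"] = g.size()
        return out.reset_index()

    def mean(self, group: str, variant: Variant | str, metric: str) -> float:
        v = Variant(variant).value
        rows = self.raw[(self.raw["group"] == group) & (self.raw["variant"] == v)]
        return float(rows[metric].mean())


def run_experiment(
    groups: Sequence[str] = ("A", "B"),
    variants: Sequence[Variant | str] = ALL_VARIANTS,
    replicates: int = 20,
    master_seed: int = 0,
    *,
    schedule=None,
    sim_overrides: dict | None = None,
    keep_roc_for: tuple[str, Variant | str] | None = None,
) -> ExperimentResult:
    """Run the paired multi-variant comparison over seeded replicates.

    A failed replicate is logged and dropped (the summary records the
    effective replicate count).  Identical ``master_seed`` gives identical
    tables.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    variants = [Variant(v) for v in variants]
    schedule = schedule or Schedule()
    rows = []
    roc_rows = []
    ss = np.random.SeedSequence(master_seed)
    child_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(replicates)]
    for r, rseed in enumerate(child_seeds):
        try:
            for group in groups:
                cfg = group_config(group, seed=rseed, **(sim_overrides or {}))
                dataset = simulate_dataset(cfg)
                pool0 = dataset.to_pool()
                lab = np.flatnonzero(dataset.observed_status)
                lam = tune_penalty(
                    dataset.X.values[lab],
                    dataset.truth_labels[lab],
                    seed=rseed,
                )
                for variant in variants:
                    tc = TrainerConfig(
                        variant=variant, schedule=schedule, seed=rseed, penalty=lam
                    )
                    pool = pool0.copy()
                    model, log, _records = run_variant(pool, tc)
                    ev = evaluate_run(model, dataset, final_status=pool.status)
                    roc = ev.pop("_roc_points")
                    rows.append(
                        {
                            "replicate": r,
                            "seed": rseed,
                            "group": group,
                            "variant": variant.value,
                            "penalty": lam,
                            **ev,
                        }
                    )
                    if (
                        keep_roc_for is not None
                        and r == 0
                        and group == keep_roc_for[0]
                        and variant == Variant(keep_roc_for[1])
                    ):
                        for fpr, tpr in roc:
                            roc_rows.append(
                                {"group": group, "variant": variant.value, "fpr": fpr, "tpr": tpr}
                            )
        except Exception:  # pragma: no cover - defensive
            logger.warning("replicate %d failed; dropping it", r, exc_info=True)
            rows = [row for row in rows if row["replicate"] != r]
    return ExperimentResult(pd.DataFrame(rows), pd.DataFrame(roc_rows))
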