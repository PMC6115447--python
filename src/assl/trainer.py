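"""The select-retrain-update training loop and its six variants.

Starting from a small labeled set and a pool of unlabeled samples, every
variant except the plain lasso-logistic baseline repeats, for up to ``C``
iterations:

1. score the pool with the current classifier;
2. select pool samples through the iteration's SSL (high-confidence) and/or
   AL (uncertain) probability windows and move them into the training set,
   either with a pseudo-label from the classifier or, for the manually-labeled
   baselines, with their hidden true label up to an oracle budget;
3. refit the lasso-logistic model on the enlarged training set;
4. (update mechanism only) find pseudo-labeled samples whose predicted class
   has flipped under the new model: SSL-selected flips go back to the pool,
   AL-selected flips have their label revised in place.

The loop ends early when the pool empties; because the windows cover all of
(0, 1) at the final iteration, fully self-labeling variants always drain the
pool.

Variants
--------
``logistic``     single fit on the labeled samples, no loop.
``al-lo``        AL window only; selections receive their true label from the
                 oracle, up to a budget (default 40% of the pool).
``ssl-lo``       SSL window only; selections are pseudo-labeled, no update.
``assl-lo``      both windows; AL selections oracle-labeled up to the budget,
                 SSL selections pseudo-labeled.
``auto-assl-a``  both windows, everything pseudo-labeled, no update mechanism.
``auto-assl-b``  as A plus the flip-detection update mechanism.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, ModelState, fit_l1_logistic, predict_prob, tune_penalty
from .windows import (
    Schedule,
    assign_pseudo_labels,
    select_confident,
    select_uncertain,
    windows_at,
)

__all__ = [
    "SampleStatus",
    "Variant",
    "LabeledPool",
    "PseudoLabelRecord",
    "TrainerConfig",
    "TrainLog",
    "detect_flips",
    "apply_update_mechanism",
    "oracle_label",
    "run_variant",
]


class SampleStatus(enum.IntEnum):
    LABELED = 0          # originally labeled; never changes
    UNLABELED = 1        # in the pool
    PSEUDO_SSL = 2       # pseudo-labeled, entered via the SSL window
    PSEUDO_AL = 3        # pseudo-labeled, entered via the AL window
    ORACLE_LABELED = 4   # true label revealed by the oracle (AL-lo / ASSL-lo)


class Variant(str, enum.Enum):
    LOGISTIC = "logistic"
    AL_LO = "al-lo"
    SSL_LO = "ssl-lo"
    ASSL_LO = "assl-lo"
    AUTO_ASSL_A = "auto-assl-a"
    AUTO_ASSL_B = "auto-assl-b"


_USES_SSL = {Variant.SSL_LO, Variant.ASSL_LO, Variant.AUTO_ASSL_A, Variant.AUTO_ASSL_B}
_USES_AL = {Variant.AL_LO, Variant.ASSL_LO, Variant.AUTO_ASSL_A, Variant.AUTO_ASSL_B}
_ORACLE_VARIANTS = {Variant.AL_LO, Variant.ASSL_LO}


@dataclass
class LabeledPool:
    """Expression matrix with per-sample status, working label and hidden truth.

    ``label`` is NaN exactly when a sample is unlabeled.  ``truth`` carries the
    hidden true labels in simulations (used only by the oracle and by
    evaluation); it is ``None`` for real data.
    """

    X: ExpressionMatrix
    status: np.ndarray
    label: np.ndarray
    truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.X.n_samples
        self.status = np.asarray(self.status, dtype=int)
        self.label = np.asarray(self.label, dtype=float)
        if self.status.shape != (n,) or self.label.shape != (n,):
            raise ValueError("status/label length must match the matrix")
        unlabeled = self.status == SampleStatus.UNLABELED
        if np.isnan(self.label[~unlabeled]).any():
            raise ValueError("every non-unlabeled sample must carry a label")
        if not np.isnan(self.label[unlabeled]).all():
            raise ValueError("unlabeled samples must not carry a label")
        if self.truth is not None:
            self.truth = np.asarray(self.truth, dtype=int)
            if self.truth.shape != (n,):
                raise ValueError("truth length must match the matrix")

    @classmethod
    def from_labels(
        cls,
        X: ExpressionMatrix,
        labels: np.ndarray,
        labeled_mask: np.ndarray,
        truth: np.ndarray | None = None,
    ) -> "LabeledPool":
        """Build an initial pool: ``labeled_mask`` marks the labeled samples."""
        labeled_mask = np.asarray(labeled_mask, dtype=bool)
        status = np.where(labeled_mask, int(SampleStatus.LABELED), int(SampleStatus.UNLABELED))
        label = np.where(labeled_mask, np.asarray(labels, dtype=float), np.nan)
        return cls(X, status, label, truth)

    def copy(self) -> "LabeledPool":
        return LabeledPool(
            self.X,
            self.status.copy(),
            self.label.copy(),
            None if self.truth is None else self.truth.copy(),
        )

    @property
    def n(self) -> int:
        return self.X.n_samples

    @property
    def pool_indices(self) -> np.ndarray:
        return np.flatnonzero(self.status == SampleStatus.UNLABELED)

    @property
    def training_indices(self) -> np.ndarray:
        return np.flatnonzero(self.status != SampleStatus.UNLABELED)

    @property
    def n_labeled(self) -> int:
        return int((self.status == SampleStatus.LABELED).sum())


@dataclass
class PseudoLabelRecord:
    """Provenance of one pseudo-label: who selected it, when, at what probability."""

    sample_index: int
    selector: str  # "SSL" or "AL"
    iteration_assigned: int
    prob_at_assignment: float
    current_label: int
    revision_count: int = 0
    retired: bool = False


@dataclass
class TrainerConfig:
    """Configuration of one training run."""

    variant: Variant | str = Variant.AUTO_ASSL_B
    schedule: Schedule = field(default_factory=Schedule)
    oracle_budget_fraction: float = 0.4
    seed: int = 0
    penalty: float | None = None  # None -> 5-fold CV tuning on the labeled set
    cv_folds: int = 5
    tune_scoring: str = "loglik"
    tune_one_se: bool = False
    # flip_margin > 0 only overturns a pseudo-label when the new prediction is
    # confidently on the other side; max_revisions caps in-place revisions per
    # record.  Both default to the plain boundary-crossing rule.
    flip_margin: float = 0.0
    max_revisions: int | None = None
    fit_tol: float = 1e-7

    def __post_init__(self) -> None:
        self.variant = Variant(self.variant)
        if not (0 <= self.oracle_budget_fraction <= 1):
            raise ValueError("oracle_budget_fraction must lie in [0, 1]")

    @property
    def update_mechanism(self) -> bool:
        return self.variant is Variant.AUTO_ASSL_B


@dataclass
class IterationRecord:
    iteration: int
    train_size: int
    pool_size: int
    n_ssl_selected: int
    n_al_selected: int
    n_oracle_labeled: int
    n_flips: int
    n_flips_revised: int
    n_flips_returned: int


@dataclass
class TrainLog:
    """Per-iteration bookkeeping of the training loop."""

    penalty: float = 0.0
    rows: list[IterationRecord] = field(default_factory=list)

    def append(self, row: IterationRecord) -> None:
        self.rows.append(row)

    def __len__(self) -> int:
        return len(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])


def detect_flips(
    model: ModelState,
    records: list[PseudoLabelRecord],
    X: ExpressionMatrix,
    *,
    margin: float = 0.0,
) -> list[PseudoLabelRecord]:
    """Records whose classifier-implied label now differs from their current label.

    With a positive ``margin`` a disagreement only counts as a flip when the
    new prediction is confidently on the other side (``|prob - 0.5| > margin``);
    ``margin=0`` flips on any crossing of the decision boundary.
    """
    live = [r for r in records if not r.retired]
    if not live:
        return []
    idx = np.array([r.sample_index for r in live])
    probs = predict_prob(model, X.values[idx])
    implied = assign_pseudo_labels(probs, np.arange(len(idx)))
    return [
        r
        for r, lab, p in zip(live, implied, probs)
        if lab != r.current_label and abs(p - 0.5) > margin
    ]


def apply_update_mechanism(pool: LabeledPool, flips: list[PseudoLabelRecord]) -> LabeledPool:
    """Route flipped pseudo-labels: SSL flips back to the pool, AL flips revised.

    Mutates and returns ``pool``.  SSL-selected flips lose their label and
    record (``retired`` set); AL-selected flips have their label negated in
    place and their revision count incremented.
    """
    for rec in flips:
        i = rec.sample_index
        if pool.status[i] not in (SampleStatus.PSEUDO_SSL, SampleStatus.PSEUDO_AL):
            raise ValueError(
                f"flip for sample {i} with status {SampleStatus(pool.status[i]).name}; "
                "only pseudo-labeled samples can flip"
            )
        if rec.selector == "SSL":
            pool.status[i] = SampleStatus.UNLABELED
            pool.label[i] = np.nan
            rec.retired = True
        else:
            new = 1 - rec.current_label
            rec.current_label = new
            rec.revision_count += 1
            pool.label[i] = new
    return pool


def oracle_label(
    pool: LabeledPool,
    indices: np.ndarray,
    probs: np.ndarray,
    budget_remaining: int,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Reveal true labels for up to ``budget_remaining`` samples.

    ``probs`` are the current class probabilities of ``indices``; samples
    closest to 0.5 are labeled first (the natural uncertainty-sampling rank).
    Returns ``(chosen_indices, labels, new_budget)``; indices beyond the
    budget are skipped and stay in the pool.
    """
    if pool.truth is None:
        raise ValueError(
            "oracle labels require hidden truth (simulation); for real data "
            "supply manual labels instead"
        )
    indices = np.asarray(indices, dtype=int)
    if budget_remaining <= 0 or indices.size == 0:
        return np.array([], dtype=int), np.array([], dtype=int), budget_remaining
    probs = np.asarray(probs, dtype=float)
    # distance ties broken toward the lower probability, then input order
    order = np.lexsort((probs, np.abs(probs - 0.5)))
    chosen = indices[order[:budget_remaining]]
    return chosen, pool.truth[chosen].astype(int), budget_remaining - len(chosen)


def _fit_training_set(pool: LabeledPool, penalty_per_sample: float, tol: float) -> ModelState:
    # The penalty is held fixed on the mean-loss scale across iterations: as the
    # training set grows the sum-loss penalty scales with it, keeping the
    # per-sample regularization strength constant.  (With a constant sum-loss
    # penalty the relative regularization vanishes as pseudo-labels accumulate,
    # the model interpolates its own pseudo-labels, and no flip can ever occur.)
    idx = pool.training_indices
    return fit_l1_logistic(
        pool.X.values[idx],
        pool.label[idx].astype(int),
        penalty=penalty_per_sample * len(idx),
        tol=tol,
    )


def run_variant(
    pool: LabeledPool,
    config: TrainerConfig,
) -> tuple[ModelState, TrainLog, list[PseudoLabelRecord]]:
    """Run one training variant to completion.

    The penalty is tuned once on the initial labeled set (unless fixed in the
    config) and held constant across iterations.  Deterministic given the
    config seed.  Returns the final model, the per-iteration log, and all
    pseudo-label records (including retired ones).

    ``pool`` is updated in place: on return its statuses and labels reflect
    the final training state (callers wanting to reuse the initial pool should
    pass ``pool.copy()``).
    """
    variant = config.variant
    n = pool.n
    lab_idx = np.flatnonzero(pool.status == SampleStatus.LABELED)
    if len(lab_idx) == 0 or len(np.unique(pool.label[lab_idx])) < 2:
        raise ValueError("initial labeled set must contain both classes")

    if config.penalty is not None:
        lam = float(config.penalty)
    else:
        lam = tune_penalty(
            pool.X.values[lab_idx],
            pool.label[lab_idx].astype(int),
            folds=config.cv_folds,
            seed=config.seed,
            scoring=config.tune_scoring,
            one_se=config.tune_one_se,
        )
    lam_per_sample = lam / len(lab_idx)
    log = TrainLog(penalty=lam)
    model = _fit_training_set(pool, lam_per_sample, config.fit_tol)

    if variant is Variant.LOGISTIC:
        log.append(IterationRecord(0, len(lab_idx), n - len(lab_idx), 0, 0, 0, 0, 0, 0))
        return model, log, []

    n_pool0 = n - len(lab_idx)
    budget = round(config.oracle_budget_fraction * n_pool0) if variant in _ORACLE_VARIANTS else 0
    records: dict[int, PseudoLabelRecord] = {}
    all_records: list[PseudoLabelRecord] = []

    for t in range(1, config.schedule.max_iterations + 1):
        pool_idx = pool.pool_indices
        if pool_idx.size == 0:
            break
        probs = predict_prob(model, pool.X.values[pool_idx])
        wp = windows_at(config.schedule, t)

        ssl_local = (
            select_confident(probs, wp.ssl_halfwidth) if variant in _USES_SSL else np.array([], int)
        )
        al_local = (
            select_uncertain(probs, wp.al_halfwidth) if variant in _USES_AL else np.array([], int)
        )

        n_oracle = 0
        if variant in _ORACLE_VARIANTS and al_local.size:
            chosen, labels, budget = oracle_label(
                pool, pool_idx[al_local], probs[al_local], budget
            )
            pool.status[chosen] = SampleStatus.ORACLE_LABELED
            pool.label[chosen] = labels
            n_oracle = len(chosen)
            n_al_sel = len(chosen)
        elif al_local.size:
            al_idx = pool_idx[al_local]
            labels = assign_pseudo_labels(probs, al_local)
            pool.status[al_idx] = SampleStatus.PSEUDO_AL
            pool.label[al_idx] = labels
            for i, pr, lab in zip(al_idx, probs[al_local], labels):
                rec = PseudoLabelRecord(int(i), "AL", t, float(pr), int(lab))
                records[int(i)] = rec
                all_records.append(rec)
            n_al_sel = len(al_idx)
        else:
            n_al_sel = 0

        if ssl_local.size:
            ssl_idx = pool_idx[ssl_local]
            labels = assign_pseudo_labels(probs, ssl_local)
            pool.status[ssl_idx] = SampleStatus.PSEUDO_SSL
            pool.label[ssl_idx] = labels
            for i, pr, lab in zip(ssl_idx, probs[ssl_local], labels):
                rec = PseudoLabelRecord(int(i), "SSL", t, float(pr), int(lab))
                records[int(i)] = rec
                all_records.append(rec)

        model = _fit_training_set(pool, lam_per_sample, config.fit_tol)

        n_flips = n_rev = n_ret = 0
        if config.update_mechanism:
            flips = detect_flips(
                model, list(records.values()), pool.X, margin=config.flip_margin
            )
            if config.max_revisions is not None:
                flips = [
                    r
                    for r in flips
                    if r.selector == "SSL" or r.revision_count < config.max_revisions
                ]
            n_flips = len(flips)
            apply_update_mechanism(pool, flips)
            for rec in flips:
                if rec.retired:
                    n_ret += 1
                    del records[rec.sample_index]
                else:
                    n_rev += 1

        log.append(
            IterationRecord(
                t,
                len(pool.training_indices),
                len(pool.pool_indices),
                int(ssl_local.size),
                n_al_sel,
                n_oracle,
                n_flips,
                n_rev,
                n_ret,
            )
        )

        if variant is Variant.AL_LO and budget == 0:
            # oracle budget exhausted: nothing further can enter the training set
            break

    return model, log, all_records
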