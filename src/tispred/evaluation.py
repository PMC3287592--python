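"""Performance metrics, 10-fold cross-validation, and ROC point emission.

Five measures summarise a confusion matrix, all reported as percentages:
accuracy (Ac), precision (Pr), sensitivity (Se), specificity (Sp), and
adjusted accuracy (Adj), the mean of sensitivity and specificity.  Adjusted
accuracy is the headline number for imbalanced problems, where plain accuracy
is dominated by the majority class.

Cross-validation splits by *molecule* — every candidate of one mRNA shares a
fold — and balances (and, when enabled, runs the acquired-knowledge
procedure on) the training folds only; the held-out fold is evaluated
imbalanced and untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.metrics import roc_curve

from .balancing import BalancerSpec
from .classifier import SvmSpec, decision_values, make_layout, predict
from .features import FeatureComboSpec, encode_candidates
from .inaknow import InaknowResult, inaknow_train, plain_train
from .seqmodel import MrnaRecord, Region, WindowSpec, extract_window

METRIC_NAMES = ("Ac", "Pr", "Se", "Sp", "Adj")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred must align")
        return cls(
            TP=int(((y_true == 1) & (y_pred == 1)).sum()),
            FP=int(((y_true == -1) & (y_pred == 1)).sum()),
            TN=int(((y_true == -1) & (y_pred == -1)).sum()),
            FN=int(((y_true == 1) & (y_pred == -1)).sum()),
        )


@dataclass(frozen=True)
class MetricSet:
    """The five measures as percentages; ``None`` marks a zero denominator."""

    Ac: float | None
    Pr: float | None
    Se: float | None
    Sp: float | None
    Adj: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _ratio(num: int, den: int) -> float | None:
    return 100.0 * num / den if den > 0 else None


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Ac, Pr, Se, Sp and Adj from raw counts.

    Ac = (TP+TN)/total, Pr = TP/(TP+FP), Se = TP/(TP+FN), Sp = TN/(TN+FP),
    Adj = (Se+Sp)/2.  Full precision is retained; rounding is a display
    concern (:func:`format_metric`).
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    se = _ratio(c.TP, c.TP + c.FN)
    sp = _ratio(c.TN, c.TN + c.FP)
    adj = (se + sp) / 2 if se is not None and sp is not None else None
    return MetricSet(
        Ac=_ratio(c.TP + c.TN, c.total),
        Pr=_ratio(c.TP, c.TP + c.FP),
        Se=se,
        Sp=sp,
        Adj=adj,
    )


def format_metric(value: float | None, decimals: int = 2) -> str:
    """Half-up rounding to two decimals; a dash for undefined values."""
    if value is None:
        return "-"
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Ordered (FPR, TPR) pairs from a threshold sweep over the scores.

    Both endpoints (0,0) and (1,1) are always present and both coordinates
    are monotone non-decreasing.
    """
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(labels, np.asarray(scores, dtype=float),
                            pos_label=1, drop_intermediate=False)
    return np.column_stack([fpr, tpr])


@dataclass
class FoldResult:
    counts: ConfusionCounts
    metrics: MetricSet
    roc: np.ndarray
    n_test_molecules: int
    n_test_samples: int
    inaknow: InaknowResult | None = None


@dataclass
class CvReport:
    folds: list[FoldResult] = field(default_factory=list)

    def mean(self, name: str) -> float | None:
        vals = [getattr(f.metrics, name) for f in self.folds
                if getattr(f.metrics, name) is not None]
        return float(np.mean(vals)) if vals else None

    def std(self, name: str) -> float | None:
        vals = [getattr(f.metrics, name) for f in self.folds
                if getattr(f.metrics, name) is not None]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else None

    def summary(self) -> dict[str, dict[str, float | None]]:
        return {name: {"mean": self.mean(name), "std": self.std(name)}
                for name in METRIC_NAMES}


def assign_folds(
    records: list[MrnaRecord], window: WindowSpec, n_folds: int, seed: int
) -> np.ndarray:
    """Molecule-level fold labels, stratified on positive extractability.

    Molecules whose TIS window is extractable are dealt round-robin first so
    that every fold receives positives; fold sizes differ by at most one.
    """
    has_pos = np.array(
        [extract_window(r, r.tis_pos, window) is not None for r in records]
    )
    n_pos = int(has_pos.sum())
    if n_pos < n_folds:
        raise ValueError(
            f"only {n_pos} molecules with extractable positives; "
            f"use at most {max(n_pos, 1)} folds"
        )
    rng = np.random.default_rng(seed)
    order = np.concatenate([
        rng.permutation(np.nonzero(has_pos)[0]),
        rng.permutation(np.nonzero(~has_pos)[0]),
    ])
    folds = np.empty(len(records), dtype=int)
    folds[order] = np.arange(len(records)) % n_folds
    return folds


def _split_arrays(samples):
    """Stack sample vectors into (X, y, regions, ids) arrays."""
    if not samples:
        return (np.zeros((0, 0)), np.zeros(0, dtype=int), [], [])
    X = np.vstack([s.vector for s in samples])
    y = np.array([s.label for s in samples], dtype=int)
    regions = [s.site.region for s in samples]
    ids = [s.site.record_id for s in samples]
    return X, y, regions, ids


def cross_validate(
    records: list[MrnaRecord],
    window: WindowSpec,
    combo: FeatureComboSpec,
    balancer: BalancerSpec,
    svm: SvmSpec,
    inaknow: bool = False,
    n_folds: int = 10,
    seed: int = 0,
    include_in_frame_negatives: bool = False,
) -> CvReport:
    """K-fold cross-validation with in-fold balancing (and InAKnow).

    Folds partition molecules.  Training candidates come exclusively from
    training-fold molecules; a leakage audit asserts that no held-out
    molecule contributes any sample to training.  The held-out fold is
    evaluated with its natural imbalance: positives against (out-of-frame)
    negatives, upstream and downstream alike.

    Under InAKnow the downstream candidates of the held-out fold are not
    assumed negative either: their evaluation labels are assigned by the
    training fold's Level-1 model, mirroring the procedure's premise that
    downstream sequences join the data only after that classification.
    Plain-mode evaluation labels every non-TIS candidate negative.
    """
    fold_of = assign_folds(records, window, n_folds, seed)
    layout = make_layout(window, combo)
    report = CvReport()
    for fold in range(n_folds):
        train_recs = [r for r, f in zip(records, fold_of) if f != fold]
        test_recs = [r for r, f in zip(records, fold_of) if f == fold]
        test_ids = {r.id for r in test_recs}

        mode = "inaknow" if inaknow else "plain"
        tr = encode_candidates(train_recs, window, combo, mode=mode,
                               include_in_frame_negatives=include_in_frame_negatives)
        X, y, regions, ids = _split_arrays(tr)
        # leakage audit: no held-out molecule may feed training
        leaked = set(ids) & test_ids
        assert not leaked, f"fold {fold}: held-out molecules in training: {leaked}"

        fold_balancer = BalancerSpec(
            method=balancer.method, m=balancer.m, sbc_k=balancer.sbc_k,
            mclus_take=balancer.mclus_take,
            seed=balancer.seed + 1000 * fold,
            sbc_selection=balancer.sbc_selection,
        )
        ik: InaknowResult | None = None
        if inaknow:
            ik = inaknow_train(
                X[y == 1], X[y == -1], X[y == 0],
                fold_balancer, svm, layout=layout,
            )
            model = ik.final_model
        else:
            model = plain_train(X[y == 1], X[y == -1],
                                fold_balancer, svm, layout=layout)

        te = encode_candidates(test_recs, window, combo, mode="plain",
                               include_in_frame_negatives=include_in_frame_negatives)
        X_te, y_te, te_regions, _ = _split_arrays(te)
        if len(X_te) == 0:
            raise ValueError(f"fold {fold}: no evaluable candidates in test fold")
        if ik is not None and ik.downstream_total > 0:
            down_mask = np.array([r is Region.downstream for r in te_regions])
            if down_mask.any():
                y_te = y_te.copy()
                y_te[down_mask] = predict(ik.level1_model, X_te[down_mask])
        y_hat = predict(model, X_te)
        scores = decision_values(model, X_te)
        counts = ConfusionCounts.from_predictions(y_te, y_hat)
        roc = (roc_points(scores, y_te)
               if len(set(y_te.tolist())) == 2 else np.zeros((0, 2)))
        report.folds.append(FoldResult(
            counts=counts,
            metrics=compute_metrics(counts),
            roc=roc,
            n_test_molecules=len(test_recs),
            n_test_samples=len(X_te),
            inaknow=ik,
        ))
    return report
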