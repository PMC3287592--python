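"""The three-level acquired-knowledge (InAKnow) training procedure.

Under the ribosome scanning model only the candidate ATGs upstream of the
annotated start, and the start itself, have a defensible class: the ribosome
never evaluates downstream ATGs, so calling them negatives is an assumption,
not an observation.  InAKnow treats them as unlabeled and lets the classifier
supply their labels:

1. **Level 1** — train on the positives and the out-of-frame upstream
   negatives (balanced).
2. **Level 2** — score every downstream candidate with the Level-1 model and
   adopt its hard prediction as the candidate's label.
3. **Level 3** — pool positives with relabeled-positive downstream candidates
   (class +1) and upstream negatives with relabeled-negative ones (class -1),
   re-balance with the same balancer, and train the final model.

Relabeling moves context-strong downstream candidates out of the negative
pool, which both reduces the class imbalance entering Level 3 and removes
would-be false positives — the mechanism behind the method's precision gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .balancing import BalancerSpec, balance
from .classifier import SvmSpec, TrainedModel, predict, train


@dataclass
class InaknowResult:
    """Models and bookkeeping from one InAKnow run."""

    level1_model: TrainedModel
    final_model: TrainedModel
    downstream_total: int
    downstream_relabeled_positive: int
    post_balance_ratio: float  # majority:minority entering the final fit

    @property
    def relabel_fraction(self) -> float:
        """Share of downstream candidates the Level-1 model called positive.

        Reported as 0 when there were no downstream candidates.
        """
        if self.downstream_total == 0:
            return 0.0
        return self.downstream_relabeled_positive / self.downstream_total


def _balanced_fit(
    X_pos: np.ndarray,
    X_neg: np.ndarray,
    balancer: BalancerSpec,
    svm: SvmSpec,
    layout: str | None,
) -> tuple[TrainedModel, float]:
    """Balance the majority class down and fit; returns (model, maj:min ratio).

    Whichever class is larger is treated as the majority for balancing.
    """
    if len(X_pos) == 0:
        raise ValueError("no positive samples")
    if len(X_neg) == 0:
        raise ValueError("no negative samples")
    if len(X_neg) >= len(X_pos):
        keep = balance(X_neg, X_pos, balancer)
        X_neg = X_neg[keep]
    else:
        keep = balance(X_pos, X_neg, balancer)
        X_pos = X_pos[keep]
    ratio = len(X_neg) / len(X_pos)
    X = np.vstack([X_pos, X_neg])
    y = np.concatenate([np.ones(len(X_pos), dtype=int),
                        -np.ones(len(X_neg), dtype=int)])
    return train(X, y, svm, layout=layout), ratio


def plain_train(
    X_pos: np.ndarray,
    X_neg: np.ndarray,
    balancer: BalancerSpec,
    svm: SvmSpec,
    layout: str | None = None,
) -> TrainedModel:
    """The non-InAKnow baseline: one balanced fit on positives vs negatives."""
    model, _ = _balanced_fit(X_pos, X_neg, balancer, svm, layout)
    return model


def inaknow_train(
    X_pos: np.ndarray,
    X_neg_upstream: np.ndarray,
    X_downstream: np.ndarray,
    balancer: BalancerSpec,
    svm: SvmSpec,
    layout: str | None = None,
) -> InaknowResult:
    """Run the three-level procedure; see the module docstring.

    ``X_downstream`` holds the unlabeled downstream candidates; it may be
    empty, in which case the procedure degenerates to plain training and the
    relabel fraction is reported as 0 of 0.
    """
    X_pos = np.asarray(X_pos, dtype=float)
    X_neg_upstream = np.asarray(X_neg_upstream, dtype=float)
    X_downstream = np.asarray(X_downstream, dtype=float)
    if len(X_pos) == 0:
        raise ValueError("no positive samples")

    level1, _ = _balanced_fit(X_pos, X_neg_upstream, balancer, svm, layout)

    if len(X_downstream) > 0:
        down_labels = predict(level1, X_downstream)
        pos_pool = np.vstack([X_pos, X_downstream[down_labels == 1]])
        neg_pool = np.vstack([X_neg_upstream, X_downstream[down_labels == -1]])
        n_relabeled = int((down_labels == 1).sum())
    else:
        pos_pool, neg_pool, n_relabeled = X_pos, X_neg_upstream, 0

    final, ratio = _balanced_fit(pos_pool, neg_pool, balancer, svm, layout)
    return InaknowResult(
        level1_model=level1,
        final_model=final,
        downstream_total=len(X_downstream),
        downstream_relabeled_positive=n_relabeled,
        post_balance_ratio=ratio,
    )
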