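"""Per-epitope CDR3 beta specificity classifiers with background calibration.

A random-forest classifier is trained per epitope on epitope-specific CDR3s
(positives) versus CDR3s sampled from a bulk background pool (negatives).
Raw scores (positive-class vote fractions) are interpreted through a frozen
score distribution of ``n_background`` background TCRs: the baseline
prediction rate (BPR) of a query is the fraction of background TCRs scoring
greater than or equal to it. A query is called epitope-specific when its BPR
is at or below the threshold (default 0.01%, i.e. at most 10 of 100,000
background TCRs score as high).

The estimators follow scikit-learn conventions (``fit``/``predict``,
``get_params``/``set_params``, trailing-underscore fitted attributes) and a
:class:`TcrSpecificityClassifier` drops into sklearn pipelines and model
selection, taking raw CDR3 strings as ``X``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    average_precision_score,
    balanced_accuracy_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .io import Clonotype
from .resources import AMINO_ACIDS, standardized_descriptor_matrix

#: Default number of background TCRs scored for BPR calibration.
N_BACKGROUND = 100_000
#: Default BPR pass threshold (0.01%).
BPR_THRESHOLD = 1e-4
MIN_POSITIVES = 20
MIN_CDR3_LENGTH = 5


class EncodingError(ValueError):
    """A CDR3 sequence cannot be embedded in the fixed feature frame."""


class Cdr3Encoder(TransformerMixin, BaseEstimator):
    """Fixed-width physicochemical embedding of CDR3 amino-acid sequences.

    The conserved anchor residues (first and last position) are dropped and
    the inner sequence is placed into a frame of ``frame_length`` slots:
    the left half fills from the N-terminal side, the right half from the
    C-terminal side, and unused middle slots stay zero (a gap). Each slot
    carries four z-scored residue descriptors (hydrophobicity, charge,
    volume, polarity); one extra feature encodes sequence length. The
    encoding is stateless and deterministic: dimension ``4*frame_length + 1``
    for every input length in 5..frame_length+2.
    """

    #: bump when the feature layout changes; stored in model metadata
    ENCODING_VERSION = "anchored-physchem-1"

    def __init__(self, frame_length: int = 18):
        self.frame_length = frame_length

    def fit(self, X, y=None):  # stateless; sklearn API compliance
        self.n_features_in_ = 1
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        desc = standardized_descriptor_matrix()
        index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
        n_desc = desc.shape[1]
        out = np.zeros((len(X), n_desc * self.frame_length + 1))
        for row, seq in enumerate(X):
            if len(seq) < MIN_CDR3_LENGTH:
                raise EncodingError(f"CDR3 {seq!r} shorter than {MIN_CDR3_LENGTH}")
            inner = seq[1:-1]
            if len(inner) > self.frame_length:
                # center-truncate: keep both anchor-proximal ends
                half = self.frame_length - self.frame_length // 2
                inner = inner[:half] + inner[-(self.frame_length // 2):]
            k = len(inner)
            left = k - k // 2
            slots = list(range(left)) + list(
                range(self.frame_length - (k - left), self.frame_length)
            )
            for slot, aa in zip(slots, inner):
                if aa not in index:
                    raise EncodingError(f"non-standard residue {aa!r} in {seq!r}")
                start = slot * n_desc
                out[row, start : start + n_desc] = desc[index[aa]]
            out[row, -1] = len(seq)
        return out


@dataclass
class CvMetrics:
    """5-fold cross-validation metrics (mean +/- SD) plus curve points."""

    balanced_accuracy: tuple[float, float]
    auroc: tuple[float, float]
    average_precision: tuple[float, float]
    per_fold: pd.DataFrame = field(repr=False, default=None)
    roc_points: pd.DataFrame = field(repr=False, default=None)
    pr_points: pd.DataFrame = field(repr=False, default=None)


class TcrSpecificityClassifier(ClassifierMixin, BaseEstimator):
    """Random-forest CDR3 specificity classifier with BPR calibration.

    ``X`` is an array-like of CDR3 amino-acid strings; ``y`` is binary
    (1 = epitope-specific). After :meth:`fit`, :meth:`calibrate_background`
    freezes the sorted score distribution of a background TCR sample, after
    which :meth:`bpr` and :meth:`predict_bpr` are available.

    Parameters
    ----------
    epitope : label attached to predictions.
    n_estimators, random_state : forwarded to the random forest.
    bpr_threshold : pass threshold on the baseline prediction rate.
    frame_length : encoder frame width.
    """

    def __init__(
        self,
        epitope: Optional[str] = None,
        n_estimators: int = 100,
        random_state: Optional[int] = None,
        bpr_threshold: float = BPR_THRESHOLD,
        frame_length: int = 18,
    ):
        self.epitope = epitope
        self.n_estimators = n_estimators
        self.random_state = random_state
        self.bpr_threshold = bpr_threshold
        self.frame_length = frame_length

    def fit(self, X: Sequence[str], y):
        y = np.asarray(y)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("y must be binary 0/1")
        self.encoder_ = Cdr3Encoder(frame_length=self.frame_length).fit(X)
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=self.random_state
        )
        self.forest_.fit(self.encoder_.transform(X), y)
        self.classes_ = self.forest_.classes_
        self.n_features_in_ = 1
        return self

    def specificity_scores(self, X: Sequence[str]) -> np.ndarray:
        """Positive-class vote fraction per sequence."""
        check_is_fitted(self, "forest_")
        proba = self.forest_.predict_proba(self.encoder_.transform(X))
        return proba[:, list(self.forest_.classes_).index(1)]

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(self.encoder_.transform(X))

    def predict(self, X) -> np.ndarray:
        """Class labels at the 0.5 vote threshold (uncalibrated)."""
        check_is_fitted(self, "forest_")
        return self.forest_.predict(self.encoder_.transform(X))

    # -- background calibration -------------------------------------------

    def calibrate_background(self, X_background: Sequence[str]):
        """Freeze the sorted background score distribution for BPR."""
        self.background_scores_ = np.sort(self.specificity_scores(X_background))
        return self

    def bpr(self, scores) -> np.ndarray:
        """Baseline prediction rate of raw scores (inclusive >= comparison).

        ``bpr(s) = #{background score >= s} / n_background``; monotone
        non-increasing in ``s``.
        """
        check_is_fitted(self, "background_scores_")
        scores = np.atleast_1d(np.asarray(scores, dtype=float))
        n = self.background_scores_.size
        n_ge = n - np.searchsorted(self.background_scores_, scores, side="left")
        return n_ge / n

    def predict_bpr(self, clonotypes: Sequence[Clonotype] | Sequence[str],
                    threshold: Optional[float] = None) -> pd.DataFrame:
        """Score clonotypes and flag the BPR-passing subset.

        Accepts Clonotype records or bare CDR3 strings; returns one row per
        input with ``score``, ``bpr`` and ``passes`` (bpr <= threshold).
        """
        threshold = self.bpr_threshold if threshold is None else threshold
        seqs = [c.cdr3_aa if isinstance(c, Clonotype) else c for c in clonotypes]
        if not seqs:
            return pd.DataFrame(
                columns=["cdr3_aa", "epitope", "score", "bpr", "passes"]
            )
        scores = self.specificity_scores(seqs)
        rates = self.bpr(scores)
        return pd.DataFrame(
            {
                "cdr3_aa": seqs,
                "epitope": self.epitope,
                "score": scores,
                "bpr": rates,
                "passes": rates <= threshold,
            }
        )


def train_model(
    positives: Sequence[Clonotype],
    background_pool: Sequence[Clonotype],
    epitope: Optional[str] = None,
    neg_ratio: float = 5.0,
    n_background: int = N_BACKGROUND,
    seed: Optional[int] = None,
    n_estimators: int = 100,
    n_folds: int = 5,
) -> tuple[TcrSpecificityClassifier, CvMetrics]:
    """Train and cross-validate a per-epitope specificity model.

    Positives must be CDR3-deduplicated; pool entries whose CDR3 matches a
    positive are excluded. Negatives are sampled without replacement at
    ``neg_ratio`` per positive; metrics come from stratified ``n_folds``-fold
    CV (balanced accuracy at the 0.5 vote threshold, AUROC, average
    precision); the returned model is refit on all data and calibrated on
    ``n_background`` pool TCRs, drawn outside the training negatives when
    the pool is large enough.
    """
    pos_seqs = sorted({p.cdr3_aa for p in positives})
    if len(pos_seqs) < MIN_POSITIVES:
        raise ValueError(
            f"need at least {MIN_POSITIVES} unique positive CDR3s, got {len(pos_seqs)}"
        )
    pos_set = set(pos_seqs)
    pool_seqs = sorted({c.cdr3_aa if isinstance(c, Clonotype) else c
                        for c in background_pool} - pos_set)
    n_neg = int(round(neg_ratio * len(pos_seqs)))
    if len(pool_seqs) < n_neg:
        raise ValueError(f"background pool too small: {len(pool_seqs)} < {n_neg}")
    if len(pool_seqs) < n_background:
        raise ValueError(
            f"background pool too small for calibration: {len(pool_seqs)} < {n_background}"
        )
    rng = np.random.default_rng(seed)
    neg_idx = rng.choice(len(pool_seqs), size=n_neg, replace=False)
    neg_seqs = [pool_seqs[i] for i in neg_idx]

    X = np.array(pos_seqs + neg_seqs, dtype=object)
    y = np.concatenate([np.ones(len(pos_seqs), int), np.zeros(n_neg, int)])

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=int(rng.integers(2**31)))
    fold_rows, oof_scores, oof_y = [], [], []
    forest_seed = int(rng.integers(2**31))
    for k, (tr, te) in enumerate(skf.split(X, y)):
        clf = TcrSpecificityClassifier(
            epitope=epitope, n_estimators=n_estimators, random_state=forest_seed
        ).fit(X[tr], y[tr])
        scores = clf.specificity_scores(X[te])
        fold_rows.append(
            {
                "fold": k,
                "balanced_accuracy": balanced_accuracy_score(y[te], scores >= 0.5),
                "auroc": roc_auc_score(y[te], scores),
                "average_precision": average_precision_score(y[te], scores),
            }
        )
        oof_scores.append(scores)
        oof_y.append(y[te])
    per_fold = pd.DataFrame(fold_rows)
    oof_scores = np.concatenate(oof_scores)
    oof_y = np.concatenate(oof_y)
    fpr, tpr, _ = roc_curve(oof_y, oof_scores)
    prec, rec, _ = precision_recall_curve(oof_y, oof_scores)
    metrics = CvMetrics(
        balanced_accuracy=(per_fold.balanced_accuracy.mean(), per_fold.balanced_accuracy.std(ddof=0)),
        auroc=(per_fold.auroc.mean(), per_fold.auroc.std(ddof=0)),
        average_precision=(per_fold.average_precision.mean(), per_fold.average_precision.std(ddof=0)),
        per_fold=per_fold,
        roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        pr_points=pd.DataFrame({"precision": prec, "recall": rec}),
    )

    model = TcrSpecificityClassifier(
        epitope=epitope, n_estimators=n_estimators, random_state=forest_seed
    ).fit(X, y)
    remaining = sorted(set(pool_seqs) - set(neg_seqs))
    calib_pool = remaining if len(remaining) >= n_background else pool_seqs
    calib_idx = rng.choice(len(calib_pool), size=n_background, replace=False)
    model.calibrate_background([calib_pool[i] for i in calib_idx])
    model.training_meta_ = {
        "epitope": epitope,
        "n_positives": len(pos_seqs),
        "n_negatives": n_neg,
        "neg_ratio": neg_ratio,
        "n_background": n_background,
        "seed": seed,
        "n_estimators": n_estimators,
        "encoding": Cdr3Encoder.ENCODING_VERSION,
    }
    return model, metrics


def predict_repertoire(
    model: TcrSpecificityClassifier,
    repertoire: Sequence[Clonotype],
    threshold: float = BPR_THRESHOLD,
) -> pd.DataFrame:
    """Score every clonotype of a repertoire; BPR-passing subset flagged."""
    return model.predict_bpr(repertoire, threshold=threshold)
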