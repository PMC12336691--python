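"""HLA carrier imputation from repertoires and HLA assignment of
discovered sequences.

Carrier status of an HLA allele leaves a detectable footprint in a TRB
repertoire: a set of public, allele-associated clonotypes occurs far
more often in carriers. The imputation model is a two-covariate
logistic regression on (i) the number of allele-associated marker
clonotypes present in a sample and (ii) the natural log of the
sample's unique productive rearrangement count (deeper repertoires
contain more of everything, so the count must be conditioned on
depth). Marker clonotypes are selected by one-sided Fisher exact
carrier enrichment on the training folds.

Once every sample carries an HLA label (molecularly typed where
available — typed labels always override imputed ones — otherwise
imputed), each discovered Enhanced Sequence is tested against each
allele label with a one-sided FET and assigned the most significant
allele; assignments are categorized as ``assigned`` (p < 1e-4),
``uncertain`` (1e-4 <= p < 1e-3), or ``unassigned``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .discovery import EnhancedSequence, fet_enrichment, presence_matrix, _fet_vector
from .io import Repertoire, SequenceKey
from .motifs import MotifKey

__all__ = [
    "HLACarrierClassifier",
    "HLAAssignment",
    "train_hla_model",
    "impute_hla",
    "assign_hla",
    "merge_labels",
]

P_ASSIGNED = 1e-4
P_UNCERTAIN = 1e-3


class HLACarrierClassifier(BaseEstimator, ClassifierMixin):
    """Two-covariate logistic HLA carrier imputation.

    Parameters
    ----------
    allele : str or None
        Name of the modelled allele (informational).
    feature_p : float
        One-sided FET threshold for selecting marker clonotypes on the
        training data.
    min_presence : int
        A clonotype must be present in at least this many training
        samples to be considered as a marker candidate.
    cv : int
        Number of stratified folds for the reported cross-validated
        AUROC (the final model is refit on all training data).
    candidate_keys : sequence of SequenceKey, optional
        Restrict marker selection to these clonotypes; by default every
        clonotype observed in the training samples is a candidate.
    random_state : int

    Attributes
    ----------
    feature_keys_ : list of SequenceKey — selected marker clonotypes.
    intercept_, coef_count_, coef_logr_ : fitted coefficients.
    cv_auroc_ : out-of-fold AUROC on the training data.
    classes_ : array([False, True]).
    """

    def __init__(
        self,
        allele: str | None = None,
        feature_p: float = 1e-4,
        min_presence: int = 2,
        cv: int = 5,
        candidate_keys: Sequence[SequenceKey] | None = None,
        random_state: int = 0,
    ):
        self.allele = allele
        self.feature_p = feature_p
        self.min_presence = min_presence
        self.cv = cv
        self.candidate_keys = candidate_keys
        self.random_state = random_state

    # -- internals ---------------------------------------------------

    @staticmethod
    def _log_r(reps: Sequence[Repertoire]) -> np.ndarray:
        r = np.array([rep.r_unique for rep in reps], dtype=float)
        if (r == 0).any():
            bad = [rep.sample_id for rep, ri in zip(reps, r) if ri == 0]
            raise ValueError(f"imputation undefined for empty repertoire(s): {bad}")
        return np.log(r)

    def _select(self, pres: np.ndarray, y: np.ndarray, columns) -> np.ndarray:
        """Indices of carrier-enriched marker clonotypes."""
        n_car = int(y.sum())
        n_non = int((~y).sum())
        a = pres[y].sum(axis=0)
        c = pres[~y].sum(axis=0)
        keep = (a + c) >= self.min_presence
        p = np.ones(pres.shape[1])
        p[keep] = _fet_vector(a[keep], n_car, c[keep], n_non)
        return np.flatnonzero(p < self.feature_p)

    @staticmethod
    def _fit_logistic(count: np.ndarray, log_r: np.ndarray, y: np.ndarray):
        X = np.column_stack([count, log_r])
        # C=inf: unpenalized maximum likelihood
        clf = LogisticRegression(C=np.inf, max_iter=1000)
        clf.fit(X, y)
        return clf

    # -- sklearn API -------------------------------------------------

    def fit(self, X: Sequence[Repertoire], y):
        y = np.asarray(y, dtype=bool)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        if y.all() or not y.any():
            raise ValueError("training labels must contain carriers and non-carriers")
        pres_df = presence_matrix(X, min_samples=self.min_presence)
        if self.candidate_keys is not None:
            cols = [k for k in self.candidate_keys if k in pres_df.columns]
            pres_df = pres_df[cols]
        pres = pres_df.to_numpy()
        log_r = self._log_r(X)

        # out-of-fold AUROC with per-fold marker selection (selection is
        # part of the pipeline, so it happens inside each fold)
        skf = StratifiedKFold(n_splits=self.cv, shuffle=True, random_state=self.random_state)
        oof = np.full(len(y), np.nan)
        for tr, va in skf.split(pres, y):
            idx = self._select(pres[tr], y[tr], pres_df.columns)
            count_tr = pres[tr][:, idx].sum(axis=1)
            count_va = pres[va][:, idx].sum(axis=1)
            clf = self._fit_logistic(count_tr, log_r[tr], y[tr])
            oof[va] = clf.predict_proba(np.column_stack([count_va, log_r[va]]))[:, 1]
        self.cv_auroc_ = float(roc_auc_score(y, oof))

        idx = self._select(pres, y, pres_df.columns)
        self.feature_keys_ = [pres_df.columns[i] for i in idx]
        count = pres[:, idx].sum(axis=1)
        clf = self._fit_logistic(count, log_r, y)
        self.intercept_ = float(clf.intercept_[0])
        self.coef_count_ = float(clf.coef_[0][0])
        self.coef_logr_ = float(clf.coef_[0][1])
        self.classes_ = np.array([False, True])
        return self

    def _features(self, X: Sequence[Repertoire]) -> np.ndarray:
        keys = set(self.feature_keys_)
        count = np.array([len(keys & rep.productive_keys()) for rep in X], dtype=float)
        return np.column_stack([count, self._log_r(X)])

    def decision_function(self, X: Sequence[Repertoire]) -> np.ndarray:
        check_is_fitted(self, "feature_keys_")
        f = self._features(X)
        return self.intercept_ + self.coef_count_ * f[:, 0] + self.coef_logr_ * f[:, 1]

    def predict_proba(self, X: Sequence[Repertoire]) -> np.ndarray:
        z = self.decision_function(X)
        p = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1 - p, p])

    def predict(self, X: Sequence[Repertoire], threshold: float = 0.5) -> np.ndarray:
        return self.predict_proba(X)[:, 1] >= threshold

    def to_json_dict(self) -> dict:
        check_is_fitted(self, "feature_keys_")
        return {
            "allele": self.allele,
            "feature_keys": [list(k) for k in self.feature_keys_],
            "intercept": self.intercept_,
            "coef_count": self.coef_count_,
            "coef_logr": self.coef_logr_,
            "cv_auroc": self.cv_auroc_,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "HLACarrierClassifier":
        model = cls(allele=d["allele"])
        model.feature_keys_ = [SequenceKey(*k) for k in d["feature_keys"]]
        model.intercept_ = float(d["intercept"])
        model.coef_count_ = float(d["coef_count"])
        model.coef_logr_ = float(d["coef_logr"])
        model.cv_auroc_ = float(d.get("cv_auroc", np.nan))
        model.classes_ = np.array([False, True])
        return model


def train_hla_model(
    reps: Sequence[Repertoire],
    labels: Sequence[bool],
    allele: str,
    candidate_keys: Sequence[SequenceKey] | None = None,
    folds: int = 5,
    seed: int = 0,
    feature_p: float = 1e-4,
) -> HLACarrierClassifier:
    """Fit an :class:`HLACarrierClassifier` on labelled repertoires."""
    return HLACarrierClassifier(
        allele=allele,
        feature_p=feature_p,
        cv=folds,
        candidate_keys=candidate_keys,
        random_state=seed,
    ).fit(reps, labels)


def impute_hla(
    model: HLACarrierClassifier, rep: Repertoire, threshold: float = 0.5
) -> tuple[bool, float]:
    """Carrier label and probability for one repertoire."""
    p = float(model.predict_proba([rep])[0, 1])
    return p >= threshold, p


def merge_labels(typed: pd.DataFrame, imputed: pd.DataFrame) -> pd.DataFrame:
    """Combine typed and imputed allele labels; typed wins where known.

    Both frames are samples x alleles with boolean/NaN entries; a NaN
    in ``typed`` means genotype unknown for that sample/allele.
    """
    merged = imputed.copy().astype("boolean")
    typed = typed.reindex(index=merged.index, columns=merged.columns)
    mask = typed.notna()
    merged[mask] = typed[mask].astype("boolean")
    return merged.astype(bool)


@dataclass(frozen=True)
class HLAAssignment:
    """HLA assignment of one Enhanced Sequence.

    ``alleles`` has length > 1 only when the minimal p-value is tied
    across alleles; ties are reported, never broken silently, and a tie
    downgrades the category to ``uncertain``.
    """

    target: SequenceKey | MotifKey
    alleles: tuple[str, ...]
    p_value: float
    category: str  # assigned | uncertain | unassigned


def _categorize(p: float, tied: bool) -> str:
    if p >= P_UNCERTAIN:
        return "unassigned"
    if tied or p >= P_ASSIGNED:
        return "uncertain"
    return "assigned"


def assign_hla(
    es_list: Sequence[EnhancedSequence | SequenceKey | MotifKey],
    reps: Sequence[Repertoire],
    labels: pd.DataFrame,
) -> list[HLAAssignment]:
    """Assign each discovered sequence/motif to its most associated allele.

    ``labels`` is a boolean samples x alleles frame covering every
    sample in ``reps`` (typed or imputed). For an exact clonotype the
    test is presence vs carrier label per allele; for a motif, every
    member clonotype is tested and the most significant (member,
    allele) pair determines the assignment.
    """
    ids = [r.sample_id for r in reps]
    missing = [i for i in ids if i not in labels.index]
    if missing:
        raise ValueError(f"unlabelled sample(s): {missing}")
    labels = labels.loc[ids].astype(bool)
    pres = presence_matrix(reps)
    col = {k: j for j, k in enumerate(pres.columns)}
    mat = pres.to_numpy()

    def key_vs_allele(key: SequenceKey, allele: str) -> float:
        j = col.get(key)
        present = mat[:, j] if j is not None else np.zeros(len(ids), dtype=bool)
        car = labels[allele].to_numpy()
        a = int(present[car].sum())
        c = int(present[~car].sum())
        return fet_enrichment(a, int(car.sum()) - a, c, int((~car).sum()) - c)

    out = []
    for es in es_list:
        target = es.target if isinstance(es, EnhancedSequence) else es
        if isinstance(target, MotifKey):
            members = list(target.members) or []
            pairs = [
                (key_vs_allele(k, allele), allele) for k in members for allele in labels.columns
            ]
        else:
            pairs = [(key_vs_allele(target, allele), allele) for allele in labels.columns]
        if not pairs:
            out.append(HLAAssignment(target, (), 1.0, "unassigned"))
            continue
        p_min = min(p for p, _ in pairs)
        best = tuple(sorted({allele for p, allele in pairs if p == p_min}))
        out.append(HLAAssignment(target, best, p_min, _categorize(p_min, len(best) > 1)))
    return out
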