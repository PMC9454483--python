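"""Housekeeping normalization and log2 transform.

NanoString nCounter counts are made comparable across samples by scaling
each sample so the geometric mean of its housekeeping genes (here GAPDH,
ACTB, TUBB) matches the cohort average: for sample *j*,

    factor_j = mean_k(geomean(HK counts, sample k)) / geomean(HK counts, sample j)

and every count in sample *j* is multiplied by ``factor_j``. After scaling,
housekeeping geometric means are equal across samples. Counts are then
log2-transformed with a small offset to keep zeros finite.

The scaling and the transform are exposed both as sklearn-style
transformers operating on samples × genes arrays and as functions on
:class:`~crcpanel.matrix.ExpressionMatrix`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .matrix import NORMALIZED_LOG2, RAW_COUNTS, ExpressionMatrix


class HousekeepingNormalizer(TransformerMixin, BaseEstimator):
    """Scale samples so housekeeping geometric means are equalized.

    Parameters
    ----------
    housekeeping_index : array-like of int or bool
        Columns of X (samples × genes orientation) that are housekeeping
        genes.
    reference : {"mean", float}
        Target geometric mean. ``"mean"`` (default) uses the arithmetic mean
        of the per-sample housekeeping geometric means of the data passed to
        :meth:`fit`; a float pins an explicit target, letting new cohorts be
        scaled against a frozen reference.

    Attributes
    ----------
    reference_ : float
        The target housekeeping geometric mean.
    """

    def __init__(self, housekeeping_index=None, reference="mean"):
        self.housekeeping_index = housekeeping_index
        self.reference = reference

    def _hk_geomeans(self, X: np.ndarray) -> np.ndarray:
        idx = np.asarray(self.housekeeping_index)
        hk = X[:, idx]
        if hk.shape[1] == 0:
            raise ValueError("no housekeeping genes selected")
        if np.any(hk <= 0):
            bad = np.argwhere(hk <= 0)[0, 0]
            raise ValueError(
                f"housekeeping count <= 0 in sample index {bad}: "
                "geometric mean undefined"
            )
        return np.exp(np.mean(np.log(hk), axis=1))

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if self.housekeeping_index is None:
            raise ValueError("housekeeping_index is required")
        geo = self._hk_geomeans(X)
        self.reference_ = (
            float(np.mean(geo)) if self.reference == "mean" else float(self.reference)
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_")
        X = check_array(X, dtype=float)
        geo = self._hk_geomeans(X)
        factors = self.reference_ / geo
        return X * factors[:, None]


class Log2Transformer(TransformerMixin, BaseEstimator):
    """Elementwise ``log2(x + offset)``; stateless."""

    def __init__(self, offset: float = 1.0):
        self.offset = offset

    def fit(self, X, y=None):
        self.n_features_in_ = check_array(X, dtype=float).shape[1]
        return self

    def transform(self, X):
        X = check_array(X, dtype=float)
        if self.offset <= 0 and np.any(X <= 0):
            raise ValueError("offset must be > 0 when zero counts are present")
        if np.any(X + self.offset <= 0):
            raise ValueError("log2 undefined: value + offset <= 0")
        return np.log2(X + self.offset)


def normalize_housekeeping(m: ExpressionMatrix) -> ExpressionMatrix:
    """Housekeeping-normalize a raw-count matrix (scale stays raw_counts)."""
    if m.scale != RAW_COUNTS:
        raise ValueError("normalize_housekeeping expects raw counts")
    hk = m.housekeeping_index
    if not hk.any():
        raise ValueError("matrix has no housekeeping genes")
    # estimator works in samples × genes orientation
    X = m.values.T
    idx_hk = np.where(hk)[0]
    for j in idx_hk:
        zero = np.where(m.values[j] <= 0)[0]
        if zero.size:
            raise ValueError(
                f"housekeeping gene {m.genes[j].transcript_id} has count <= 0 "
                f"in sample {m.samples[zero[0]]!r}: geometric mean undefined"
            )
    norm = HousekeepingNormalizer(housekeeping_index=hk).fit(X)
    out = norm.transform(X).T
    return ExpressionMatrix(
        values=out,
        genes=list(m.genes),
        samples=list(m.samples),
        sample_class=list(m.sample_class),
        scale=RAW_COUNTS,
    )


def log2_transform(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """log2(count + offset); marks the matrix as normalized_log2."""
    if m.scale != RAW_COUNTS:
        raise ValueError("log2_transform expects raw counts")
    values = Log2Transformer(offset=offset).fit_transform(m.values.T).T
    return ExpressionMatrix(
        values=values,
        genes=list(m.genes),
        samples=list(m.samples),
        sample_class=list(m.sample_class),
        scale=NORMALIZED_LOG2,
    )


def preprocess(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Housekeeping normalization followed by log2 transform."""
    return log2_transform(normalize_housekeeping(m), offset=offset)
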