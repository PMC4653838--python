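"""Two-stage correlation feature extraction for multi-omics integration.

Given K patient x feature matrices X(1)..X(K) measured on the same M
patients, the method builds, for each data type, the M x M Pearson
similarity matrix P(k) and/or Spearman similarity matrix S(k) of patient
rows (Step I), concatenates them column-wise into a feature matrix
Y = [P(1) S(1) ... P(K) S(K)] (Step II), and finally computes the Pearson
correlation of the rows of Y to obtain the integrated patient-similarity
matrix Z (Step III).  Because every extracted feature is a correlation
coefficient in [-1, 1], data types with wildly different measurement
scales enter Step II on an equal footing, and no tuning parameter is
involved at any stage.

Three variants are provided: ``ibfe1`` uses both Pearson and Spearman
similarities, ``ibfe2`` Pearson only, ``ibfe3`` Spearman only.  The
Spearman-only variant is invariant under strictly increasing elementwise
transforms of each data type, which is the mechanism behind its
robustness to scale distortions.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

__all__ = [
    "VARIANTS",
    "IBFE",
    "correlation_similarity",
    "stack_features",
    "integrate",
    "ibfe",
    "direct_concatenate",
]

#: correlation kinds used by each variant, in stacking order
VARIANTS: dict[str, tuple[str, ...]] = {
    "ibfe1": ("pearson", "spearman"),
    "ibfe2": ("pearson",),
    "ibfe3": ("spearman",),
}

# numerical tolerance for symmetry/diagonal checks on similarity matrices
_SYM_TOL = 1e-10


def _as_frame(X, what: str = "matrix") -> pd.DataFrame:
    """Coerce ``X`` to a DataFrame with string patient ids, validating it."""
    if isinstance(X, pd.DataFrame):
        df = X
    else:
        arr = np.asarray(X)
        if arr.ndim != 2:
            raise ValueError(f"{what} must be 2-dimensional, got shape {arr.shape}")
        df = pd.DataFrame(arr)
        df.index = [f"p{i}" for i in range(arr.shape[0])]
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate patient ids in {what}: {dupes}")
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        n_bad = int((~np.isfinite(values)).sum())
        raise ValueError(f"{what} contains {n_bad} non-finite entries")
    return df


def _validate_omics(X, what: str = "dataset") -> pd.DataFrame:
    df = _as_frame(X, what)
    if df.shape[0] < 3:
        raise ValueError(f"{what} needs at least 3 patients, got {df.shape[0]}")
    if df.shape[1] < 2:
        raise ValueError(f"{what} needs at least 2 feature columns, got {df.shape[1]}")
    return df


def _row_correlation(values: np.ndarray) -> np.ndarray:
    """Pearson correlation of matrix rows, well defined for constant rows.

    Rows with zero variance cannot be correlated; any pair involving one
    gets similarity 0 while its diagonal entry stays 1, and a warning is
    emitted.  The result is symmetrized and clipped to [-1, 1] to remove
    floating-point round-off.
    """
    values = np.asarray(values, dtype=float)
    m = values.shape[0]
    sd = values.std(axis=1)
    ok = sd > 0
    C = np.zeros((m, m))
    n_ok = int(ok.sum())
    if n_ok == 1:
        C[np.ix_(ok, ok)] = 1.0
    elif n_ok > 1:
        C[np.ix_(ok, ok)] = np.corrcoef(values[ok])
    if n_ok < m:
        warnings.warn(
            f"{m - n_ok} constant row(s): correlation undefined, similarity set to 0",
            RuntimeWarning,
            stacklevel=3,
        )
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return C


def correlation_similarity(X, method: str = "pearson") -> pd.DataFrame:
    """Patient x patient correlation similarity of one data type (Step I).

    Parameters
    ----------
    X : DataFrame or array of shape (n_patients, n_features)
        One data type, patients as rows.  Entries must be finite.
    method : {"pearson", "spearman"}
        Spearman ranks each patient row with midranks (average ranks for
        ties) and applies Pearson to the ranks.

    Returns
    -------
    DataFrame of shape (n_patients, n_patients)
        Symmetric, unit diagonal, entries in [-1, 1].
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    df = _validate_omics(X)
    values = df.to_numpy(dtype=float)
    if method == "spearman":
        values = rankdata(values, axis=1)
    C = _row_correlation(values)
    return pd.DataFrame(C, index=df.index, columns=df.index)


def _check_aligned(frames: Sequence[pd.DataFrame], what: str) -> pd.Index:
    index = frames[0].index
    for i, f in enumerate(frames[1:], start=2):
        if len(f.index) != len(index) or not (f.index == index).all():
            raise ValueError(
                f"{what} {i} has different or reordered patient ids; "
                "align datasets first (see ibfe.io.align_patients)"
            )
    return index


def stack_features(sims: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate similarity matrices column-wise into Y (Step II).

    The result has one row per patient and ``M * len(sims)`` columns with a
    two-level column index ``(block, patient)`` recording which similarity
    matrix each column came from.  No rescaling is applied: correlation
    coefficients are already on a common [-1, 1] scale.
    """
    if len(sims) == 0:
        raise ValueError("need at least one similarity matrix to stack")
    frames = [_as_frame(s, f"similarity matrix {i + 1}") for i, s in enumerate(sims)]
    index = _check_aligned(frames, "similarity matrix")
    blocks = {}
    for i, f in enumerate(frames):
        name = f.columns.name if isinstance(f.columns.name, str) and f.columns.name else f"block{i + 1}"
        # de-duplicate block labels so column provenance stays unambiguous
        label, j = name, 1
        while label in blocks:
            j += 1
            label = f"{name}.{j}"
        blocks[label] = f
    Y = pd.concat(blocks, axis=1)
    Y.columns.names = ["block", "patient"]
    Y.index = index
    return Y


def integrate(Y) -> pd.DataFrame:
    """Pearson correlation of the rows of the stacked features Y (Step III)."""
    df = _as_frame(Y, "stacked feature matrix")
    if df.shape[1] < 2:
        raise ValueError("stacked feature matrix needs at least 2 columns")
    Z = _row_correlation(df.to_numpy(dtype=float))
    return pd.DataFrame(Z, index=df.index, columns=df.index)


def _block_name(kind: str, label: str) -> str:
    return f"{kind[0].upper()}:{label}"


def ibfe(datasets: Sequence, variant: str = "ibfe1", labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Integrated patient-similarity matrix Z from multiple data types.

    Composition of the three stages: per-type correlation similarities,
    column-wise stacking, and row-wise Pearson correlation of the stack.

    Parameters
    ----------
    datasets : sequence of DataFrame or array
        Patient x feature matrices sharing the same patients in the same
        order.  DataFrames must carry identical indexes.
    variant : {"ibfe1", "ibfe2", "ibfe3"}
        Which correlation kinds to extract: both, Pearson only, or
        Spearman only.
    labels : sequence of str, optional
        Data-type names used for column bookkeeping; defaults to
        ``data1, data2, ...``.

    Returns
    -------
    DataFrame of shape (n_patients, n_patients)
        Symmetric with unit diagonal; entries in [-1, 1].
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {sorted(VARIANTS)}, got {variant!r}")
    if len(datasets) == 0:
        raise ValueError("need at least one dataset")
    frames = [_validate_omics(d, f"dataset {i + 1}") for i, d in enumerate(datasets)]
    _check_aligned(frames, "dataset")
    if labels is None:
        labels = [f"data{i + 1}" for i in range(len(frames))]
    sims = []
    for frame, label in zip(frames, labels):
        for kind in VARIANTS[variant]:
            s = correlation_similarity(frame, kind)
            s.columns.name = _block_name(kind, label)
            sims.append(s)
    return integrate(stack_features(sims))


def direct_concatenate(datasets: Sequence, labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Column-wise concatenation of raw feature matrices (the baseline).

    Feature ids are prefixed with their data-type label so that the
    concatenated columns stay unique.
    """
    if len(datasets) == 0:
        raise ValueError("need at least one dataset")
    frames = [_as_frame(d, f"dataset {i + 1}") for i, d in enumerate(datasets)]
    _check_aligned(frames, "dataset")
    if labels is None:
        labels = [f"data{i + 1}" for i in range(len(frames))]
    renamed = [
        f.set_axis([f"{label}:{c}" for c in f.columns], axis=1)
        for f, label in zip(frames, labels)
    ]
    return pd.concat(renamed, axis=1)


class IBFE(BaseEstimator):
    """Parameter-free multi-view integration into a patient-similarity space.

    Fitting computes the integrated similarity matrix Z for the supplied
    views; ``fit_transform`` returns the rows of Z, which serve as the
    integrated per-patient feature vectors for downstream clustering or
    classification.  The estimator is transductive (the similarity is
    defined jointly over the fitted patients), so there is no
    out-of-sample ``transform``.

    Parameters
    ----------
    variant : {"ibfe1", "ibfe2", "ibfe3"}, default="ibfe1"
        Correlation kinds extracted per view: Pearson and Spearman, Pearson
        only, or Spearman only.

    Attributes
    ----------
    similarity_ : DataFrame of shape (n_patients, n_patients)
        The integrated patient-similarity matrix Z.
    stacked_ : DataFrame of shape (n_patients, n_patients * n_blocks)
        The intermediate stacked correlation features Y.
    embedding_ : ndarray of shape (n_patients, n_patients)
        Rows of Z as a plain array.
    patient_ids_ : Index
        Patient identifiers, in input order.
    n_views_ : int
        Number of data types integrated.

    Examples
    --------
    >>> import numpy as np
    >>> rng = np.random.default_rng(0)
    >>> views = [rng.normal(size=(20, 30)), rng.normal(size=(20, 15))]
    >>> Z = IBFE(variant="ibfe1").fit(views).similarity_
    >>> Z.shape
    (20, 20)
    """

    def __init__(self, variant: str = "ibfe1"):
        self.variant = variant

    def fit(self, X, y=None):
        """Compute the integrated similarity for a list of views.

        ``X`` may be a single matrix or a sequence of matrices sharing
        patients (rows) in identical order.
        """
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {sorted(VARIANTS)}, got {self.variant!r}")
        views = X if isinstance(X, (list, tuple)) else [X]
        frames = [_validate_omics(v, f"view {i + 1}") for i, v in enumerate(views)]
        _check_aligned(frames, "view")
        labels = [f"data{i + 1}" for i in range(len(frames))]
        sims = []
        for frame, label in zip(frames, labels):
            for kind in VARIANTS[self.variant]:
                s = correlation_similarity(frame, kind)
                s.columns.name = _block_name(kind, label)
                sims.append(s)
        self.stacked_ = stack_features(sims)
        self.similarity_ = integrate(self.stacked_)
        self.embedding_ = self.similarity_.to_numpy()
        self.patient_ids_ = self.similarity_.index
        self.n_views_ = len(frames)
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        """Fit and return the integrated per-patient feature vectors (rows of Z)."""
        return self.fit(X).embedding_
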