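"""Morphospace PCA and RDA variation partitioning with permutation tests.

Redundancy analysis (RDA) here is multivariate least squares of a
column-centred response matrix Y (cell morphologies) on an ordered list of
design terms, followed by a decomposition of the explained sum of squares.
Sequential (type-I-like) attribution credits each term with the fitted SS
it adds given all earlier terms; a marginal mode credits each term with the
SS lost when it alone is removed from the full model.  For each term,

    R^2_k = SS_k / SS_total,
    F_k   = (SS_k / df_k) / (SS_res / df_res),

and significance comes from an ANOVA-like permutation test: rows of Y are
freely permuted, F recomputed, and

    p_k = (1 + #{F* >= F}) / (1 + n_perm),

so the smallest attainable p is 1/(n_perm + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class DesignTerm:
    """One explanatory term: named block of encoded predictor columns."""

    name: str
    kind: str  # categorical | continuous | interaction
    columns: np.ndarray  # (n, k) float

    @property
    def ncol(self) -> int:
        return self.columns.shape[1]


@dataclass
class RDATerm:
    """One term's share of a variation partitioning."""

    name: str
    df: int
    variance: float  # SS / (n - 1)
    F: float
    r2: float
    p: float


@dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray  # columns are components
    explained_variance: np.ndarray
    mean: np.ndarray


def pca_morphospace(X) -> PCAResult:
    """Column-centred PCA with a deterministic sign convention.

    Components are ordered by decreasing variance; each loading vector is
    flipped so its largest-magnitude entry is positive.  Constant columns
    simply contribute zero-variance axes.
    """
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2-D matrix with at least 3 rows")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    ev = s**2 / (X.shape[0] - 1)
    loadings = Vt.T
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
    scores = Xc @ loadings
    return PCAResult(scores, loadings, ev, mean)


# ---------------------------------------------------------------------------
# design construction


def _dummies(series: pd.Series) -> np.ndarray:
    """Treatment-contrast (drop-first) encoding of a categorical."""
    d = pd.get_dummies(series.astype("category"), drop_first=True, dtype=float)
    return d.to_numpy()


def _interact(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise products: (n,p) x (n,q) -> (n, p*q)."""
    return (a[:, :, None] * b[:, None, :]).reshape(len(a), -1)


#: Term order of the fluctuating-regime partitioning.
FLUCTUATING_TERMS = (
    "strain", "growth_rate", "day", "salinity", "predictability",
    "salinity:predictability", "day:salinity", "day:predictability",
    "day:salinity:predictability",
)
#: Term order of the constant-regime partitioning.
CONSTANT_TERMS = ("strain", "growth_rate", "day", "salinity", "day:salinity")


def build_design(metadata: pd.DataFrame, regime: str = "fluctuating",
                 terms=None) -> list[DesignTerm]:
    """Encode the ordered explanatory terms of the variation partitioning.

    ``metadata`` carries one row per cell with columns ``strain``,
    ``growth_rate``, ``day``, ``salinity_M`` and (fluctuating regime)
    ``predictability``.  Day and salinity are treatment-contrast
    categoricals, growth rate and predictability continuous; interactions
    are column products of their parents.
    """
    if terms is None:
        terms = FLUCTUATING_TERMS if regime == "fluctuating" else CONSTANT_TERMS
    base_cols = {"strain": "strain", "day": "day", "salinity": "salinity_M",
                 "growth_rate": "growth_rate", "predictability": "predictability"}
    needed = {base_cols[p] for t in terms for p in t.split(":")}
    missing = needed - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    for col in needed:
        if metadata[col].isna().any():
            raise ValueError(f"metadata column {col!r} has missing values")

    encoded: dict[str, np.ndarray] = {}

    def encode(name: str) -> np.ndarray:
        if name not in encoded:
            col = base_cols[name]
            if name in ("day", "salinity", "strain"):
                encoded[name] = _dummies(metadata[col])
            else:
                encoded[name] = metadata[col].to_numpy(float)[:, None]
        return encoded[name]

    out = []
    for term in terms:
        parents = term.split(":")
        block = encode(parents[0])
        for p in parents[1:]:
            block = _interact(block, encode(p))
        kind = ("interaction" if len(parents) > 1
                else ("categorical" if parents[0] in ("day", "salinity", "strain") else "continuous"))
        out.append(DesignTerm(term, kind, np.asarray(block, float)))
    return out


# ---------------------------------------------------------------------------
# partitioning


def _orthonormal_blocks(term_mats, n, scale):
    """Incrementally orthonormalise centred term blocks.

    Returns (Q, slices) where Q stacks the accepted orthonormal columns and
    slices[k] selects term k's columns.  Columns numerically inside the
    span of earlier terms are dropped (rank deficiency).
    """
    tol = scale * 1e-9
    Q = np.empty((n, 0))
    slices = []
    for C in term_mats:
        C = C - C.mean(axis=0)
        for _ in range(2):  # re-orthogonalise for stability
            if Q.shape[1]:
                C = C - Q @ (Q.T @ C)
        if C.size:
            U, s, _ = np.linalg.svd(C, full_matrices=False)
            r = int(np.sum(s > tol))
            B = U[:, :r]
        else:
            B = np.empty((n, 0))
        start = Q.shape[1]
        Q = np.hstack([Q, B])
        slices.append(slice(start, Q.shape[1]))
    return Q, slices


def _term_ss(Q, slices, Y):
    A = Q.T @ Y
    return np.array([(A[sl] ** 2).sum() for sl in slices])


def rda_partition(
    Y,
    terms: list[DesignTerm],
    n_perm: int = 999,
    seed: int | None = None,
    method: str = "sequential",
) -> list[RDATerm]:
    """Partition multivariate variation over ordered design terms.

    Returns one :class:`RDATerm` per design term, in order, plus a final
    ``Residual`` row (F and p are NaN there).  ``method`` is
    ``"sequential"`` (each term given the previous ones, in order) or
    ``"marginal"`` (each term given all others; R^2 values then need not
    sum with the residual to 1).
    """
    Y = np.asarray(Y, float)
    n = len(Y)
    Yc = Y - Y.mean(axis=0)
    ss_total = float((Yc**2).sum())
    if ss_total == 0:
        raise ValueError("response matrix has zero variance")
    mats = [t.columns for t in terms]
    scale = max(float(np.abs(m - m.mean(0)).max(initial=0.0)) for m in mats) * np.sqrt(n)
    Q, slices = _orthonormal_blocks(mats, n, scale or 1.0)
    dfs = np.array([sl.stop - sl.start for sl in slices])
    for t, df, m in zip(terms, dfs, mats):
        if df < m.shape[1]:
            warnings.warn(f"term {t.name!r}: rank-deficient, df reduced to {df}")
    df_model = int(dfs.sum())
    if df_model >= n - 1:
        raise ValueError("total encoded df must be < number of rows - 1")
    df_res = n - 1 - df_model

    drop_bases = None
    if method == "sequential":
        ss = _term_ss(Q, slices, Yc)
    elif method == "marginal":
        drop_bases = [
            _orthonormal_blocks(mats[:k] + mats[k + 1:], n, scale or 1.0)
            for k in range(len(terms))
        ]
        ss_full = float(_term_ss(Q, slices, Yc).sum())
        ss = np.array(
            [ss_full - float(_term_ss(Qk, sk, Yc).sum()) for Qk, sk in drop_bases]
        )
    else:
        raise ValueError("method must be 'sequential' or 'marginal'")

    ss_res = ss_total - float(_term_ss(Q, slices, Yc).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (ss / np.maximum(dfs, 1)) / (ss_res / df_res)

    # permutation test: freely permute rows of Y
    exceed = np.zeros(len(terms))
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            Yp = Yc[rng.permutation(n)]
            if method == "sequential":
                ss_p = _term_ss(Q, slices, Yp)
                ss_res_p = ss_total - float(ss_p.sum())
            else:
                full_p = float(_term_ss(Q, slices, Yp).sum())
                ss_res_p = ss_total - full_p
                ss_p = np.array(
                    [full_p - float(_term_ss(Qk, sk, Yp).sum()) for Qk, sk in drop_bases]
                )
            with np.errstate(invalid="ignore", divide="ignore"):
                F_p = (ss_p / np.maximum(dfs, 1)) / (ss_res_p / df_res)
            exceed += F_p >= F
    p = (1.0 + exceed) / (1.0 + n_perm) if n_perm > 0 else np.full(len(terms), np.nan)

    out = [
        RDATerm(t.name, int(d), float(s) / (n - 1), float(f) if d > 0 else np.nan,
                float(s) / ss_total, float(pk) if d > 0 else np.nan)
        for t, d, s, f, pk in zip(terms, dfs, ss, F, p)
    ]
    out.append(RDATerm("Residual", df_res, ss_res / (n - 1), np.nan, ss_res / ss_total, np.nan))
    return out


def partition_frame(parts: list[RDATerm]) -> pd.DataFrame:
    """Tabulate a partitioning (term, df, variance, F, R2, p)."""
    return pd.DataFrame(
        {
            "term": [t.name for t in parts],
            "df": [t.df for t in parts],
            "variance": [t.variance for t in parts],
            "F": [t.F for t in parts],
            "R2": [t.r2 for t in parts],
            "p": [t.p for t in parts],
        }
    )


# ---------------------------------------------------------------------------
# centroids


def condition_centroids(
    scores: pd.DataFrame,
    value_cols,
    treatment_of_line: pd.Series | dict | None = None,
):
    """Per-condition centroids and treatment-level means with SE.

    ``scores`` has one row per cell with ``line_id, salinity_M, day`` plus
    the score columns.  Returns ``(condition, treatment)`` frames: the
    first averages cells within (line, salinity, day); the second, present
    only when a line -> treatment mapping is given, averages the line
    centroids within (treatment, salinity, day) and reports the standard
    error across lines (NaN for a single line).
    """
    value_cols = list(value_cols)
    cond = (
        scores.groupby(["line_id", "salinity_M", "day"], sort=True)[value_cols]
        .mean()
        .reset_index()
    )
    if treatment_of_line is None:
        return cond, None
    tmap = pd.Series(treatment_of_line)
    cond2 = cond.assign(treatment=cond["line_id"].map(tmap))
    grp = cond2.groupby(["treatment", "salinity_M", "day"], sort=True, dropna=False)[value_cols]
    mean = grp.mean()
    se = grp.sem(ddof=1)
    treat = mean.join(se, rsuffix="_se").reset_index()
    return cond, treat
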