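"""Metagene expression analysis by non-negative matrix factorization.

A gene × condition transcript matrix T (column-normalized so every condition
sums to 1, optionally after a log(1+c) transform that keeps highly expressed
genes from dominating the variance) is decomposed into T ≈ W·S with W, S ≥ 0:
W holds the gene weights of each metagene expression type, S the score
(contribution) of each growth condition.  The number of components m is
chosen as the smallest rank whose reconstruction explains at least a given
share (default 90%) of the condition-wise variance for *every* condition;
variance is uncentered (squared-norm) since the factorization has no
intercept.

The factorization minimizes the Frobenius residual with Lee–Seung
multiplicative updates, keeping the best of several random restarts; results
are deterministic given (seed, restarts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_EPS = 1e-12


class TranscriptError(ValueError):
    pass


@dataclass
class TranscriptMatrix:
    genes: list[str]
    conditions: list[str]
    counts: np.ndarray  # genes × conditions, >= 0
    scale: str = "raw"  # raw | linear-normalized | log-normalized

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.genes), len(self.conditions)):
            raise TranscriptError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes × {len(self.conditions)} conditions"
            )
        if np.any(self.counts < 0):
            raise TranscriptError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.conditions)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scale: str = "raw") -> "TranscriptMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), scale)


def prepare_matrix(
    tm: TranscriptMatrix,
    mode: str = "linear",
    count_floor: float = 0.0,
) -> TranscriptMatrix:
    """Floor, optionally log-transform, then column-normalize to sum 1.

    ``mode="log"`` applies T = log(1+c) entrywise *before* normalizing, so
    the normalized columns still sum to 1.  ``count_floor`` zeroes entries
    below a raw-count cutoff (RNA-seq pipelines often discard counts below
    ~50 upstream; exposed here as an option, default off).
    """
    if mode not in ("linear", "log"):
        raise TranscriptError(f"unknown mode {mode!r}")
    x = tm.counts.copy()
    if count_floor > 0:
        x[x < count_floor] = 0.0
    if mode == "log":
        x = np.log1p(x)
    colsums = x.sum(axis=0)
    zero = np.nonzero(colsums == 0)[0]
    if zero.size:
        raise TranscriptError(
            f"all-zero condition column(s): {[tm.conditions[i] for i in zero]}"
        )
    x = x / colsums
    return TranscriptMatrix(
        list(tm.genes), list(tm.conditions), x,
        scale="log-normalized" if mode == "log" else "linear-normalized",
    )


@dataclass
class MetageneDecomposition:
    W: np.ndarray  # genes × m
    S: np.ndarray  # m × conditions
    m: int
    loss: float  # squared Frobenius residual of the best restart
    seed: int
    restarts: int
    converged: bool
    n_iter: int
    loss_trace: np.ndarray = field(repr=False, default=None)

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.S


def _mu_nmf(T: np.ndarray, m: int, rng: np.random.Generator,
            max_iter: int, tol: float) -> tuple[np.ndarray, np.ndarray, bool, int, np.ndarray]:
    n, M = T.shape
    scale = np.sqrt(T.mean() / m) if T.mean() > 0 else 1.0
    W = rng.uniform(0.1, 1.0, size=(n, m)) * scale
    S = rng.uniform(0.1, 1.0, size=(m, M)) * scale
    prev = float(np.linalg.norm(T - W @ S) ** 2)
    trace = [prev]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # Lee–Seung multiplicative updates for the Frobenius objective
        S *= (W.T @ T) / (W.T @ W @ S + _EPS)
        W *= (T @ S.T) / (W @ (S @ S.T) + _EPS)
        loss = float(np.linalg.norm(T - W @ S) ** 2)
        trace.append(loss)
        if prev - loss <= tol * max(prev, _EPS):
            converged = True
            break
        prev = loss
    return W, S, converged, it, np.array(trace)


def fit_nmf(
    tm: TranscriptMatrix,
    m: int,
    seed: int = 0,
    restarts: int = 10,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> MetageneDecomposition:
    """Best-of-restarts multiplicative-update NMF at rank *m*.

    Deterministic for fixed (seed, restarts).  Non-convergence within
    ``max_iter`` is reported through the ``converged`` flag, never hidden.
    """
    T = tm.counts
    if m < 1:
        raise TranscriptError("m must be >= 1")
    if m > min(T.shape):
        raise TranscriptError(f"m={m} exceeds min(genes, conditions)={min(T.shape)}")
    best = None
    for k in range(restarts):
        rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
        W, S, converged, n_iter, trace = _mu_nmf(T, m, rng, max_iter, tol)
        loss = trace[-1]
        if best is None or loss < best[0]:
            best = (loss, W, S, converged, n_iter, trace)
    loss, W, S, converged, n_iter, trace = best
    return MetageneDecomposition(
        W=W, S=S, m=m, loss=float(loss), seed=seed, restarts=restarts,
        converged=converged, n_iter=n_iter, loss_trace=trace,
    )


@dataclass
class VarianceReport:
    total: float  # fraction of total (uncentered) variance explained
    per_condition: dict[str, float]
    cumulative: list[float] | None = None  # by rank 1..m, from nested refits
    clipped: bool = False  # True when a pathological fit was clipped at 0

    @property
    def min_condition(self) -> float:
        return min(self.per_condition.values())


def _ev(T: np.ndarray, R: np.ndarray) -> tuple[float, np.ndarray, bool]:
    col_norm = np.sum(T**2, axis=0)
    if np.any(col_norm == 0):
        raise TranscriptError("zero-norm condition column; explained variance undefined")
    resid = np.sum((T - R) ** 2, axis=0)
    per_col = 1.0 - resid / col_norm
    clipped = bool(np.any(per_col < 0))
    per_col = np.clip(per_col, 0.0, None)
    total = 1.0 - float(np.sum((T - R) ** 2)) / float(np.sum(T**2))
    return max(total, 0.0), per_col, clipped


def explained_variance(
    tm: TranscriptMatrix,
    dec: MetageneDecomposition,
    *,
    cumulative: bool = False,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> VarianceReport:
    """Uncentered explained variance, per condition and overall.

    EV_j = 1 − ‖T_·j − (WS)_·j‖² / ‖T_·j‖².  With ``cumulative=True`` the
    report also carries total EV at every rank 1..m, each from a fresh fit
    with the decomposition's own seed/restarts (nested reporting).
    """
    T = tm.counts
    if dec.W.shape[0] != T.shape[0] or dec.S.shape[1] != T.shape[1]:
        raise TranscriptError("decomposition shape does not match matrix")
    total, per_col, clipped = _ev(T, dec.reconstruction())
    cum = None
    if cumulative:
        cum = []
        for rank in range(1, dec.m + 1):
            if rank == dec.m:
                sub = dec
            else:
                sub = fit_nmf(tm, rank, seed=dec.seed, restarts=dec.restarts,
                              max_iter=max_iter, tol=tol)
            cum.append(_ev(T, sub.reconstruction())[0])
    return VarianceReport(
        total=total,
        per_condition=dict(zip(tm.conditions, (float(v) for v in per_col))),
        cumulative=cum,
        clipped=clipped,
    )


class ComponentSelectionError(ValueError):
    def __init__(self, m_max: int, best_min_ev: float):
        self.m_max = m_max
        self.best_min_ev = best_min_ev
        super().__init__(
            f"no m <= {m_max} reaches the threshold; best attained "
            f"min condition-wise EV = {best_min_ev:.4f}"
        )


def select_components(
    tm: TranscriptMatrix,
    threshold: float = 0.9,
    m_max: int = 10,
    seed: int = 0,
    restarts: int = 10,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> tuple[int, MetageneDecomposition, VarianceReport]:
    """Smallest m whose fit explains ≥ threshold of every condition's variance.

    Scans m = 1..m_max reusing the same seed for comparability; the first m
    meeting the criterion wins.
    """
    if not 0.0 < threshold < 1.0:
        raise TranscriptError("threshold must be in (0, 1)")
    if m_max < 1:
        raise TranscriptError("m_max must be >= 1")
    best_min = -np.inf
    for m in range(1, min(m_max, min(tm.counts.shape)) + 1):
        dec = fit_nmf(tm, m, seed=seed, restarts=restarts, max_iter=max_iter, tol=tol)
        report = explained_variance(tm, dec)
        if report.min_condition >= threshold:
            return m, dec, report
        best_min = max(best_min, report.min_condition)
    raise ComponentSelectionError(m_max, best_min)


def metagene_report(
    dec: MetageneDecomposition,
    gene_ids: list[str],
    top_n: int = 10,
    annotations: dict[str, str] | None = None,
) -> tuple[dict[int, list[tuple[str, float, str]]], pd.DataFrame]:
    """Ranked gene lists per metagene plus the transposed score table.

    Returns ({metagene index: [(gene, weight, annotation), ...]},
    conditions × metagenes score DataFrame ready for heat-mapping).
    """
    if len(gene_ids) != dec.W.shape[0]:
        raise TranscriptError("gene id list does not match W")
    annotations = annotations or {}
    ranked: dict[int, list[tuple[str, float, str]]] = {}
    k_top = min(top_n, len(gene_ids))
    for k in range(dec.m):
        order = np.argsort(-dec.W[:, k])[:k_top]
        ranked[k] = [
            (gene_ids[i], float(dec.W[i, k]), annotations.get(gene_ids[i], ""))
            for i in order
        ]
    scores = pd.DataFrame(
        dec.S.T, columns=[f"metagene_{k + 1}" for k in range(dec.m)]
    )
    return ranked, scores


def match_components(
    W_fit: np.ndarray, W_true: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Best one-to-one matching of fitted to true components (Hungarian).

    Returns (permutation p with fitted k ↔ true p[k], cosine similarities).
    """
    from scipy.optimize import linear_sum_assignment

    def _unit(A):
        return A / (np.linalg.norm(A, axis=0, keepdims=True) + _EPS)

    C = _unit(W_fit).T @ _unit(W_true)  # m_fit × m_true cosine matrix
    rows, cols = linear_sum_assignment(-C)
    perm = np.empty(len(rows), dtype=int)
    sims = np.empty(len(rows))
    for r, c in zip(rows, cols):
        perm[r] = c
        sims[r] = C[r, c]
    return perm, sims
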