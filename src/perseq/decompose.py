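"""Signature comparison and NNLS decomposition into an SBS catalog.

A measured 96-channel error signature ``d`` is reconstructed as a
nonnegative linear combination ``C x`` of catalog signatures (columns of
``C``, each a PDF).  For each subset size K, every size-K subset of the
catalog is fitted by non-negative least squares and the subset with the
lowest squared reconstruction error ``||C x - d||^2`` is kept; K grows
while the best error improves by at least the improvement threshold
(default 20%), which guards against overfitting.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.optimize

from ._channels import CHANNELS_96


@dataclass
class SignatureCatalog:
    """A matrix of reference SBS signatures: 96 rows x S columns, each
    column a PDF over the COSMIC channel order."""

    names: List[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 96:
            raise ValueError("catalog matrix must be 96 x S")
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("number of names must match number of columns")
        if np.any(self.matrix < 0):
            raise ValueError("catalog columns must be nonnegative")
        sums = self.matrix.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("catalog columns must each sum to 1")

    @property
    def n_signatures(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_tsv(cls, path) -> "SignatureCatalog":
        """Read a catalog TSV: first column = channel labels in COSMIC
        dialect (``A[C>A]A`` or ``ACA>A``), remaining columns signatures."""
        df = pd.read_csv(path, sep="\t")
        labels = df.iloc[:, 0].astype(str)
        order = _channel_order(labels)
        mat = df.iloc[:, 1:].to_numpy(dtype=float)[order]
        mat = mat / mat.sum(axis=0, keepdims=True)
        return cls(names=list(df.columns[1:]), matrix=mat)

    def to_tsv(self, path) -> None:
        labels = [f"{t[0]}[{t[1]}>{a}]{t[2]}" for t, a in CHANNELS_96]
        df = pd.DataFrame(self.matrix, columns=self.names)
        df.insert(0, "Type", labels)
        df.to_csv(path, sep="\t", index=False)


def _channel_order(labels) -> np.ndarray:
    """Map channel labels to the canonical COSMIC row order."""
    want = {f"{t[0]}[{t[1]}>{a}]{t[2]}": i for i, (t, a) in enumerate(CHANNELS_96)}
    want.update({f"{t}>{a}": i for i, (t, a) in enumerate(CHANNELS_96)})
    idx = np.empty(96, dtype=np.int64)
    seen = set()
    for row, lab in enumerate(labels):
        if lab not in want:
            raise ValueError(f"unrecognized channel label {lab!r}")
        idx[want[lab]] = row
        seen.add(lab)
    if len(seen) != 96:
        raise ValueError("catalog must contain all 96 channels exactly once")
    return idx


@dataclass
class DecompositionResult:
    selected_names: List[str]
    exposures: np.ndarray
    reconstruction: np.ndarray
    reconstruction_error: float
    cosine_to_target: float
    k_trace: List[Tuple[int, float]]  # (K, best error at K)

    def to_dict(self) -> dict:
        return {
            "selected_signatures": list(self.selected_names),
            "exposures": {n: float(x) for n, x in
                          zip(self.selected_names, self.exposures)},
            "reconstruction_error": float(self.reconstruction_error),
            "cosine_to_target": float(self.cosine_to_target),
            "k_trace": [{"K": k, "best_error": e} for k, e in self.k_trace],
        }


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity between two nonnegative signature vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def nnls_fit(C: np.ndarray, d: np.ndarray) -> Tuple[np.ndarray, float]:
    """Solve ``min_{x>=0} ||C x - d||^2``; returns (x, squared error)."""
    C = np.atleast_2d(np.asarray(C, dtype=float))
    d = np.asarray(d, dtype=float)
    x, rnorm = scipy.optimize.nnls(C, d)
    return x, float(rnorm**2)


def select_signature_subset(
    catalog: SignatureCatalog,
    d: np.ndarray,
    improvement_threshold: float = 0.20,
    k_max: int = 6,
    stop_at_first_drop: bool = False,
) -> DecompositionResult:
    """Exhaustive-subset NNLS decomposition with the 20%-improvement rule.

    For K = 1, 2, ... the best size-K subset (lowest NNLS error, ties
    broken by lexicographically smallest name set) is found by exhaustive
    search.  By default K keeps growing while
    ``bestError(K) <= (1 - improvement_threshold) * bestError(K-1)``;
    with ``stop_at_first_drop=True`` the first K whose best error drops by
    at least the threshold relative to K-1 is returned immediately
    (the alternative reading of the stopping rule).  K=1 is always
    accepted.
    """
    d = np.asarray(d, dtype=float)
    S = catalog.n_signatures
    if S < 1:
        raise ValueError("catalog must contain at least one signature")
    k_max = min(k_max, S)
    if S > 30:
        import warnings

        warnings.warn(
            f"exhaustive subset search over {S} signatures is combinatorial; "
            f"bounded by k_max={k_max}",
            stacklevel=2,
        )
    # search in sorted-name order so strict '<' yields the lexicographically
    # smallest tied subset
    name_order = sorted(range(S), key=lambda i: catalog.names[i])

    def best_at(k: int):
        best_err = np.inf
        best = None
        for combo in combinations(name_order, k):
            cols = list(combo)
            x, err = nnls_fit(catalog.matrix[:, cols], d)
            if err < best_err - 1e-12:
                best_err = err
                best = (cols, x)
        return best[0], best[1], best_err

    k_trace: List[Tuple[int, float]] = []
    cols, x, err = best_at(1)
    k_trace.append((1, err))
    chosen = (cols, x, err)
    for k in range(2, k_max + 1):
        if err <= 1e-15:
            break
        cols_k, x_k, err_k = best_at(k)
        k_trace.append((k, err_k))
        improved = err_k <= (1.0 - improvement_threshold) * err
        if improved:
            chosen = (cols_k, x_k, err_k)
            err = err_k
            if stop_at_first_drop:
                break
        else:
            break

    cols, x, err = chosen
    recon = catalog.matrix[:, cols] @ x
    cos = cosine_similarity(recon, d) if recon.any() else 0.0
    names = [catalog.names[i] for i in cols]
    order = np.argsort(names)
    return DecompositionResult(
        selected_names=[names[i] for i in order],
        exposures=x[order],
        reconstruction=recon,
        reconstruction_error=err,
        cosine_to_target=cos,
        k_trace=k_trace,
    )
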