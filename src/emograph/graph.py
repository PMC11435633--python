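"""Channel connectivity graph and spectral filtering machinery.

The functional-connectivity graph has one node per EEG channel and edge
weights given by the absolute Pearson correlation between channel time
series, sparsified by a threshold.  On that graph:

* unnormalized Laplacian ``L = D - W`` with degree ``D_ii = sum_j W_ij``;
* graph Fourier transform ``q_hat = U^T q`` from the symmetric
  eigendecomposition ``L = U diag(lambda) U^T``;
* exact spectral filtering ``y = U g(Lambda) U^T x``;
* Chebyshev-polynomial filtering ``y = sum_k theta_k T_k(L~) x`` with the
  rescaled Laplacian ``L~ = 2 L / lambda_max - I`` — the polynomial form the
  trainable layers use, which never touches the eigendecomposition.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChannelGraph", "correlation_adjacency", "sparsify", "laplacian",
    "gft", "igft", "spectral_filter", "cheb_filter", "cheb_t_stack",
    "build_graph", "graph_to_json", "graph_from_json",
]


@dataclass
class ChannelGraph:
    """Adjacency / degree / Laplacian / eigensystem bundle."""

    W: np.ndarray
    tau: float = 0.0
    Ddeg: np.ndarray | None = None
    L: np.ndarray | None = None
    U: np.ndarray | None = None
    lam: np.ndarray | None = None
    normalized: bool = False

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    @property
    def lambda_max(self) -> float:
        if self.lam is None:
            raise ValueError("eigensystem not computed; call laplacian() first")
        lmax = float(self.lam[-1])
        return lmax if lmax > 0 else 2.0   # isolated-graph fallback


def correlation_adjacency(signal: np.ndarray) -> ChannelGraph:
    """Absolute Pearson correlation between channels, zero diagonal.

    Constant channels have undefined correlation; their entries are set to 0
    with a warning.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 2:
        raise ValueError("signal must be [channels, samples]")
    N, T = x.shape
    if T < 2:
        raise ValueError("need at least 2 samples to correlate")
    sd = x.std(axis=1)
    dead = sd == 0
    if dead.any():
        warnings.warn("constant channel(s); correlations set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(x)
    W = np.abs(C)
    W[np.isnan(W)] = 0.0
    W[dead, :] = 0.0
    W[:, dead] = 0.0
    np.fill_diagonal(W, 0.0)
    W = np.clip((W + W.T) / 2.0, 0.0, 1.0)
    return ChannelGraph(W=W)


def sparsify(W: np.ndarray, tau: float) -> np.ndarray:
    """Zero out edges below the threshold; idempotent, symmetry-preserving."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    Wp = np.where(W < tau, 0.0, W)
    deg = Wp.sum(axis=1)
    if W.shape[0] > 1 and np.any(deg == 0):
        warnings.warn(f"sparsify(tau={tau}) isolated {int((deg == 0).sum())} node(s)")
    return Wp


def laplacian(graph_or_W, normalized: bool = False) -> ChannelGraph:
    """Fill degree matrix, Laplacian and sorted eigensystem.

    Eigenvalues ascend; each eigenvector's sign is fixed so its
    largest-magnitude entry is positive.
    """
    if isinstance(graph_or_W, ChannelGraph):
        g = graph_or_W
        W = g.W
        tau = g.tau
    else:
        W = np.asarray(graph_or_W, dtype=float)
        tau = 0.0
    if np.abs(W - W.T).max() > 1e-9:
        raise ValueError("adjacency must be symmetric")
    if np.any(W < 0):
        raise ValueError("adjacency must be nonnegative")
    deg = W.sum(axis=1)
    Ddeg = np.diag(deg)
    if normalized:
        dinv = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
        connected = (deg > 0).astype(float)
        # isolated nodes get an all-zero row/column (their normalized degree
        # is undefined; zero keeps L PSD with a 0 eigenvalue on them)
        L = np.diag(connected) - dinv[:, None] * W * dinv[None, :]
    else:
        L = Ddeg - W
    lam, U = np.linalg.eigh((L + L.T) / 2.0)
    for k in range(U.shape[1]):
        j = np.argmax(np.abs(U[:, k]))
        if U[j, k] < 0:
            U[:, k] = -U[:, k]
    return ChannelGraph(W=W, tau=tau, Ddeg=Ddeg, L=L, U=U, lam=lam,
                        normalized=normalized)


def gft(q: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Graph Fourier transform q_hat = U^T q for [N] or [N, F] signals."""
    q = np.asarray(q)
    if q.shape[0] != U.shape[0]:
        raise ValueError(f"signal has {q.shape[0]} nodes, graph has {U.shape[0]}")
    return U.T @ q


def igft(q_hat: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Inverse transform q = U q_hat."""
    q_hat = np.asarray(q_hat)
    if q_hat.shape[0] != U.shape[1]:
        raise ValueError("spectral coefficients do not match the graph")
    return U @ q_hat


def spectral_filter(x: np.ndarray, response, graph: ChannelGraph) -> np.ndarray:
    """Exact filtering y = U diag(g(lambda)) U^T x."""
    if graph.U is None or graph.lam is None:
        raise ValueError("graph eigensystem missing; call laplacian() first")
    g = np.asarray([response(l) for l in graph.lam], dtype=float)
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return graph.U @ (g * (graph.U.T @ x))
    return graph.U @ (g[:, None] * (graph.U.T @ x))


def cheb_t_stack(graph: ChannelGraph, K: int) -> np.ndarray:
    """Chebyshev matrices [T_0(L~), ..., T_{K-1}(L~)], each [N, N].

    Uses the recurrence T_k = 2 L~ T_{k-1} - T_{k-2}; no eigendecomposition.
    """
    if K < 1:
        raise ValueError("Chebyshev order K must be >= 1")
    if graph.L is None:
        raise ValueError("graph Laplacian missing; call laplacian() first")
    N = graph.n_nodes
    Lt = 2.0 * graph.L / graph.lambda_max - np.eye(N)
    T = np.empty((K, N, N))
    T[0] = np.eye(N)
    if K > 1:
        T[1] = Lt
    for k in range(2, K):
        T[k] = 2.0 * Lt @ T[k - 1] - T[k - 2]
    return T


def cheb_filter(x: np.ndarray, theta, graph: ChannelGraph) -> np.ndarray:
    """Polynomial filtering y = sum_k theta_k T_k(L~) x via the recurrence.

    Cost O(K * nnz(L) * F); the eigensystem is never used.
    """
    theta = np.asarray(theta, dtype=float)
    K = theta.shape[0]
    if K < 1:
        raise ValueError("need at least one Chebyshev coefficient")
    if graph.L is None:
        raise ValueError("graph Laplacian missing; call laplacian() first")
    N = graph.n_nodes
    Lt = 2.0 * graph.L / graph.lambda_max - np.eye(N)
    x = np.asarray(x, dtype=float)
    t_prev = x
    y = theta[0] * t_prev
    if K > 1:
        t_cur = Lt @ x
        y = y + theta[1] * t_cur
        for k in range(2, K):
            t_prev, t_cur = t_cur, 2.0 * Lt @ t_cur - t_prev
            y = y + theta[k] * t_cur
    return y


def build_graph(signal: np.ndarray, tau: float = 0.3,
                normalized: bool = False) -> ChannelGraph:
    """Correlation adjacency -> threshold sparsification -> Laplacian.

    Build from pooled *training* data only, then freeze, to keep the graph
    free of test-set information.
    """
    g = correlation_adjacency(signal)
    Wp = sparsify(g.W, tau)
    out = laplacian(Wp, normalized=normalized)
    out.tau = tau
    return out


# ---------------------------------------------------------------------------
# serialization (bit-exact float round-trip via hex encoding)

def _mat_to_hex(M: np.ndarray) -> list:
    return [[float.hex(float(v)) for v in row] for row in np.asarray(M)]


def _mat_from_hex(rows) -> np.ndarray:
    return np.array([[float.fromhex(v) for v in row] for row in rows])


def graph_to_json(graph: ChannelGraph, path=None) -> str:
    doc = {"W": _mat_to_hex(graph.W), "tau": graph.tau,
           "normalized": graph.normalized}
    s = json.dumps(doc)
    if path is not None:
        with open(path, "w") as f:
            f.write(s)
    return s


def graph_from_json(source) -> ChannelGraph:
    if not (isinstance(source, (str, bytes))
            and str(source).lstrip().startswith("{")):
        with open(source) as f:
            source = f.read()
    doc = json.loads(source)
    g = laplacian(_mat_from_hex(doc["W"]), normalized=doc.get("normalized", False))
    g.tau = doc["tau"]
    return g
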