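"""Consensus non-negative matrix factorization with cophenetic rank selection.

Class discovery follows the metagene approach: factorize the non-negative
expression matrix V (features x samples) as V ~ W H with W >= 0 (metagene
basis) and H >= 0 (per-sample metagene expression), assign each sample to
its dominant metagene, repeat from many random starts, and summarize
co-assignment stability in a consensus matrix per candidate rank k.  The
rank whose consensus matrix is closest to a perfect block structure —
measured by the cophenetic correlation of its induced distances — is
selected as the number of subgroups.

The factorization minimizes the generalized Kullback-Leibler divergence

    D(V || WH) = sum_ij [ V_ij log(V_ij / (WH)_ij) - V_ij + (WH)_ij ]

by the classical multiplicative updates, which decrease D monotonically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform

_EPS = 1e-12


@dataclass
class NMFFactors:
    W: np.ndarray            # features x k, columns scaled to unit sum
    H: np.ndarray            # k x samples
    objective_trace: np.ndarray
    seed: int
    converged: bool


def kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    """Generalized KL divergence D(V || WH), with 0 log 0 = 0."""
    mask = V > 0
    div = np.sum(WH) - np.sum(V)
    div += np.sum(V[mask] * np.log(V[mask] / np.maximum(WH[mask], _EPS)))
    return float(div)


def nmf_factorize(V: np.ndarray, k: int, seed: int = 0,
                  max_iter: int = 2000, tol: float = 1e-6,
                  trace_every: int = 1) -> NMFFactors:
    """Rank-k KL-divergence NMF by multiplicative updates.

    Stops at ``max_iter`` or when the relative objective decrease over a
    10-iteration window falls below ``tol``.  W columns are rescaled to unit
    sum (compensated in H) so metagene magnitudes live in H.

    ``trace_every`` evaluates the objective only every that many iterations
    (the divergence evaluation costs as much as an update); the default
    records the full per-iteration trace.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be 2-D")
    if np.any(V < 0) or not np.all(np.isfinite(V)):
        raise ValueError("V must be non-negative and finite")
    if not (2 <= k < min(V.shape)):
        raise ValueError(f"k={k} out of range [2, {min(V.shape) - 1}]")
    if trace_every < 1:
        raise ValueError("trace_every must be >= 1")

    # broad uniform random init: restart diversity is what the consensus
    # matrix aggregates over
    rng = np.random.default_rng(seed)
    scale = max(V.mean(), _EPS)
    W = rng.random(size=(V.shape[0], k)) * np.sqrt(scale / k) * 2.0
    H = rng.random(size=(k, V.shape[1])) * np.sqrt(scale / k) * 2.0

    # constant part of D(V||WH): sum V log V - sum V
    mask = V > 0
    vm = V[mask]
    const = float(np.sum(vm * np.log(vm)) - np.sum(V))

    def objective() -> float:
        WH = W @ H
        return const + float(np.sum(WH) - np.sum(vm * np.log(np.maximum(WH[mask], _EPS))))

    trace = []
    converged = False
    window = max(1, 10 // trace_every)  # ~10-iteration comparison window
    for it in range(max_iter):
        WH = W @ H + _EPS
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = W @ H + _EPS
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        if (it + 1) % trace_every == 0 or it == max_iter - 1:
            trace.append(objective())
            if len(trace) > window:
                prev, cur = trace[-window - 1], trace[-1]
                denom = abs(prev) if prev != 0 else 1.0
                if (prev - cur) / denom < tol:
                    converged = True
                    break

    col_sums = np.maximum(W.sum(axis=0), _EPS)
    W = W / col_sums
    H = H * col_sums[:, None]
    return NMFFactors(W=W, H=H, objective_trace=np.asarray(trace),
                      seed=seed, converged=converged)


def metagene_labels(f: NMFFactors) -> np.ndarray:
    """Dominant metagene per sample (argmax over H column; ties -> lowest index)."""
    return np.argmax(f.H, axis=0)


def connectivity_matrix(f: NMFFactors) -> np.ndarray:
    """Binary sample x sample co-assignment indicator for one factorization."""
    labels = metagene_labels(f)
    return (labels[:, None] == labels[None, :]).astype(float)


def nonneg_fold(X: np.ndarray) -> np.ndarray:
    """Split each signed feature into its positive and negative half-features.

    Standardized (signed) data cannot feed NMF directly; stacking max(X, 0)
    over max(-X, 0) preserves all information in a non-negative encoding.
    """
    X = np.asarray(X, dtype=float)
    return np.vstack([np.maximum(X, 0.0), np.maximum(-X, 0.0)])


@dataclass
class ConsensusResult:
    """Per-rank consensus matrices, cophenetic coefficients, and labels.

    ``cophenetic[k]`` is ``None`` when the consensus matrix is degenerate
    (all off-diagonal entries equal), in which case no stability estimate
    exists at that rank.  ``labels[k]`` are 1-based cluster labels from
    cutting the average-linkage tree of ``1 - C_k`` into k clusters.
    """

    k_range: tuple
    consensus: dict
    cophenetic: dict
    labels: dict
    n_runs: int
    seed: int


def _run_seed(master_seed: int, k: int, run: int) -> np.random.SeedSequence:
    # documented counter scheme: child seed sequence keyed by (master, k, run)
    return np.random.SeedSequence([master_seed, k, run])


def consensus_cluster(V: np.ndarray, k_range=range(2, 11), n_runs: int = 50,
                      seed: int = 0, max_iter: int = 2000,
                      tol: float = 1e-6, trace_every: int = 10,
                      subsample: float = 0.8) -> ConsensusResult:
    """Consensus NMF over a range of ranks.

    For each k, ``n_runs`` factorizations from seeds derived deterministically
    from the master seed are reduced to connectivity matrices and combined
    into the consensus matrix C_k.  Each run perturbs the problem by a random
    restart *and* a random subsample of ``subsample`` of the samples
    (perturbed-input consensus in the Monti et al. sense); C_k entries are
    co-assignment counts normalized by co-occurrence counts.  Genuine cluster
    structure survives resampling, whereas splits fitted to one realization
    of the noise do not, so over-clusterings lose stability.  Set
    ``subsample=1.0`` for plain random restarts.

    The cophenetic coefficient rho_k is the Pearson correlation between the
    off-diagonal distances 1 - C_k and the cophenetic distances of their
    average-linkage hierarchical clustering; final labels at rank k cut that
    tree into k clusters.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if not (0.0 < subsample <= 1.0):
        raise ValueError("subsample must be in (0, 1]")
    V = np.asarray(V, dtype=float)
    n_samples = V.shape[1]
    n_sub = max(3, int(round(subsample * n_samples)))
    k_range = tuple(k_range)
    consensus, coph, labels = {}, {}, {}
    for k in k_range:
        C = np.zeros((n_samples, n_samples))
        count = np.zeros((n_samples, n_samples))
        for run in range(n_runs):
            run_seed = _run_seed(seed, k, run)
            if n_sub < n_samples:
                cols = np.sort(np.random.default_rng(run_seed.spawn(1)[0]).choice(
                    n_samples, size=n_sub, replace=False))
            else:
                cols = np.arange(n_samples)
            f = nmf_factorize(V[:, cols], k, seed=run_seed, max_iter=max_iter,
                              tol=tol, trace_every=trace_every)
            conn = connectivity_matrix(f)
            C[np.ix_(cols, cols)] += conn
            count[np.ix_(cols, cols)] += 1.0
        C /= np.maximum(count, 1.0)
        np.fill_diagonal(C, 1.0)
        consensus[k] = C

        dist = squareform(1.0 - C, checks=False)
        Z = average(dist)
        labels[k] = fcluster(Z, t=k, criterion="maxclust")
        if np.allclose(dist, dist[0]):
            coph[k] = None  # degenerate consensus: stability undefined
        else:
            c, _ = cophenet(Z, dist)
            coph[k] = None if not np.isfinite(c) else float(c)
    return ConsensusResult(k_range=k_range, consensus=consensus,
                           cophenetic=coph, labels=labels,
                           n_runs=n_runs, seed=seed)


def select_k(result: ConsensusResult) -> int:
    """Rank with the highest cophenetic coefficient (ties -> smallest k)."""
    defined = {k: r for k, r in result.cophenetic.items() if r is not None}
    if not defined:
        raise ValueError("no rank has a defined cophenetic coefficient")
    best = max(defined.items(), key=lambda kr: (kr[1], -kr[0]))
    return best[0]
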