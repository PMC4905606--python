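"""Synthetic benchmark generator: scale-free mixed networks and Gibbs samples.

The generator emulates the benchmark conditions used throughout this package:
undirected scale-free graphs grown by degree-proportional attachment, mixed
node types (continuous nodes first, categorical nodes last), edge weights
drawn uniformly from ``[.5, .8]``, and either "linear" or "non-linear"
assignments of the categorical interaction parameters.  Samples are drawn
from the resulting mixed graphical model by a block Gibbs sampler that draws
the full continuous vector exactly from its joint Gaussian conditional and
scans the categorical variables one at a time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import cholesky, solve_triangular

from .core import MGMParameters, MixedDataset

__all__ = [
    "ScaleFreeGraph",
    "GroundTruthModel",
    "SimulationConfig",
    "generate_scale_free_network",
    "assign_parameters",
    "sample_dataset",
    "true_adjacency",
    "simulate_benchmark",
]


@dataclass
class ScaleFreeGraph:
    """Undirected graph with nodes 0..num_nodes-1; the first ``p`` nodes are
    continuous and the remaining ``q`` categorical."""

    num_nodes: int
    edges: list  # sorted (i, j) tuples, i < j

    def degree(self) -> np.ndarray:
        deg = np.zeros(self.num_nodes, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def adjacency(self) -> np.ndarray:
        A = np.zeros((self.num_nodes, self.num_nodes), dtype=bool)
        for i, j in self.edges:
            A[i, j] = A[j, i] = True
        return A


@dataclass
class GroundTruthModel:
    graph: ScaleFreeGraph
    params: MGMParameters
    weights: dict  # (i, j) -> w drawn from the weight range
    linear: bool
    p: int
    q: int


@dataclass
class SimulationConfig:
    """Benchmark conditions: 100-node scale-free networks split into 50
    continuous and 50 four-level categorical variables, 500 samples each, one
    linear and one non-linear parameterization per network."""

    p: int = 50
    q: int = 50
    levels: int = 4
    n_samples: int = 500
    n_networks: int = 20
    weight_low: float = 0.5
    weight_high: float = 0.8
    prob_old_old: float = 0.3  # attachment between two already-connected nodes
    burn_in: int = 200
    thin: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.prob_old_old < 1:
            raise ValueError("attachment probability must be in (0, 1)")
        if not 0 < self.weight_low <= self.weight_high:
            raise ValueError("invalid weight range")


def generate_scale_free_network(num_nodes: int, seed=None) -> ScaleFreeGraph:
    """Grow an undirected scale-free graph by degree-proportional attachment.

    Starting from a single edge between two random nodes, edges are added
    until every node has degree >= 1.  Each addition either joins two
    already-connected nodes (probability .3) or attaches a still-isolated
    node to a connected one (probability .7); connected endpoints are chosen
    with probability proportional to their degree.  Draws that would
    duplicate an existing edge are rejected and redrawn a bounded number of
    times, after which the step is skipped.
    """
    if num_nodes < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(seed)
    deg = np.zeros(num_nodes, dtype=int)
    edges: set = set()

    first = rng.choice(num_nodes, size=2, replace=False)
    i, j = int(first.min()), int(first.max())
    edges.add((i, j))
    deg[i] += 1
    deg[j] += 1

    while np.any(deg == 0):
        if rng.random() < 0.3:
            for _ in range(100):  # reject duplicate edges, bounded redraw
                probs = deg / deg.sum()
                a = int(rng.choice(num_nodes, p=probs))
                probs_b = probs.copy()
                probs_b[a] = 0.0
                probs_b /= probs_b.sum()
                b = int(rng.choice(num_nodes, p=probs_b))
                e = (min(a, b), max(a, b))
                if e not in edges:
                    edges.add(e)
                    deg[a] += 1
                    deg[b] += 1
                    break
        else:
            zero = np.flatnonzero(deg == 0)
            a = int(rng.choice(zero))
            probs = deg / deg.sum()
            b = int(rng.choice(num_nodes, p=probs))
            e = (min(a, b), max(a, b))
            edges.add(e)
            deg[a] += 1
            deg[b] += 1
    return ScaleFreeGraph(num_nodes, sorted(edges))


def assign_parameters(graph: ScaleFreeGraph, config: SimulationConfig,
                      linear: bool = True, seed=None,
                      diag_mode: str = "per_node") -> GroundTruthModel:
    """Draw edge weights and populate the generating MGM parameters.

    Every edge gets a weight ``w ~ U[weight_low, weight_high]``.  cc edges set
    ``beta_st = +/-w`` with even sign probability; cd edges set
    ``rho = (-w, -.5w, .5w, w)`` (a random permutation of it in the
    non-linear variant); dd edges set the block diagonal to ``w`` and the
    rest to ``-w`` (non-linear: ``+w`` on a random permutation-matrix
    pattern).  The beta diagonal of each continuous node is its sum of
    absolute incident edge weights (all edge types) plus a margin of 1,
    which makes beta strictly diagonally dominant and hence positive
    definite.  ``diag_mode`` selects alternative readings of that rule:
    ``"per_node_cc"`` sums only the cc weights, and ``"global"`` gives every
    node the largest cc row sum in the network (plus the same margin).
    """
    rng = np.random.default_rng(seed)
    p, q = config.p, config.q
    L = config.levels
    if graph.num_nodes != p + q:
        raise ValueError("graph size must equal p + q")
    levels = (L,) * q
    params = MGMParameters.zeros(p, levels)
    params.beta[:] = 0.0
    offs = params.offsets
    weights = {}
    for (i, j) in graph.edges:
        w = float(rng.uniform(config.weight_low, config.weight_high))
        weights[(i, j)] = w
        if j < p:  # cc
            sgn = 1.0 if rng.random() < 0.5 else -1.0
            params.beta[i, j] = params.beta[j, i] = sgn * w
        elif i < p:  # cd: continuous i, categorical j - p
            base = np.array([-w, -0.5 * w, 0.5 * w, w]) if L == 4 else \
                w * np.linspace(-1.0, 1.0, L)
            if not linear:
                base = rng.permutation(base)
            jj = j - p
            params.rho[i, offs[jj]:offs[jj + 1]] = base
        else:  # dd
            r, jj = i - p, j - p
            blk = np.full((L, L), -w)
            if linear:
                np.fill_diagonal(blk, w)
            else:
                perm = rng.permutation(L)
                blk[np.arange(L), perm] = w
            params.phi[offs[r]:offs[r + 1], offs[jj]:offs[jj + 1]] = blk
            params.phi[offs[jj]:offs[jj + 1], offs[r]:offs[r + 1]] = blk.T
    if p:
        cc_row_sums = np.abs(params.beta).sum(axis=1)
        if diag_mode == "per_node":
            all_sums = np.zeros(p + q)
            for (i, j), w in weights.items():
                all_sums[i] += abs(w)
                all_sums[j] += abs(w)
            np.fill_diagonal(params.beta, all_sums[:p] + 1.0)
        elif diag_mode == "per_node_cc":
            np.fill_diagonal(params.beta, cc_row_sums + 1.0)
        elif diag_mode == "global":
            np.fill_diagonal(params.beta, float(cc_row_sums.max()) + 1.0)
        else:
            raise ValueError(
                "diag_mode must be 'per_node', 'per_node_cc' or 'global'")
    return GroundTruthModel(graph, params, weights, linear, p, q)


def true_adjacency(model: GroundTruthModel) -> np.ndarray:
    return model.graph.adjacency()


def sample_dataset(model: GroundTruthModel, n: int, burn_in: int = 200,
                   thin: int = 10, seed=None) -> MixedDataset:
    """Draw ``n`` samples from the model by block Gibbs sampling.

    The continuous block is drawn exactly from its joint Gaussian conditional
    ``x | y ~ N(beta^{-1}(alpha + rho d_y), beta^{-1})`` (one Cholesky factor,
    computed once); the categorical variables are then updated one at a time
    from their softmax conditionals.  The chain starts at ``x = 0`` and every
    categorical variable at its first level, discards ``burn_in`` sweeps and
    keeps one sample every ``thin`` sweeps.
    """
    rng = np.random.default_rng(seed)
    params = model.params
    p, q = params.p, params.q
    offs = params.offsets
    levels = params.levels
    beta = params.beta
    if p:
        # beta = Lo Lo^T ; x = mean + Lo^{-T} z has covariance beta^{-1}
        Lo = cholesky(beta, lower=True)
    rho = params.rho
    phi = params.phi
    alpha = params.alpha
    phidiag_blocks = [np.diag(phi[offs[r]:offs[r + 1], offs[r]:offs[r + 1]])
                      for r in range(q)]

    x = np.zeros(p)
    y = np.zeros(q, dtype=int)
    X_out = np.empty((n, p))
    Y_out = np.empty((n, q), dtype=int)

    total_sweeps = burn_in + (n - 1) * thin + 1 if n else 0
    kept = 0
    for sweep in range(total_sweeps):
        if p:
            idx = offs[:-1] + y
            m = alpha + (rho[:, idx].sum(axis=1) if q else 0.0)
            mean = solve_triangular(
                Lo.T, solve_triangular(Lo, m, lower=True), lower=False)
            z = rng.standard_normal(p)
            x = mean + solve_triangular(Lo.T, z, lower=False)
        for r in range(q):
            sl = slice(offs[r], offs[r + 1])
            idx = offs[:-1] + y
            cross = phi[sl][:, idx].sum(axis=1) - phi[sl][:, idx[r]]
            logits = cross + phidiag_blocks[r]
            if p:
                logits = logits + x @ rho[:, sl]
            logits -= logits.max()
            w = np.exp(logits)
            w /= w.sum()
            y[r] = rng.choice(levels[r], p=w)
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            X_out[kept] = x
            Y_out[kept] = y
            kept += 1
    assert kept == n
    return MixedDataset(X_out, Y_out, levels)


def simulate_benchmark(config: SimulationConfig):
    """Generate the full benchmark: for each network, one linear and one
    non-linear dataset sharing the same graph.

    Returns a list of dicts with keys ``network`` (index), ``linear`` (bool),
    ``data``, ``model`` and ``adjacency``.
    """
    master = np.random.SeedSequence(config.seed)
    out = []
    for k in range(config.n_networks):
        net_seq, lin_seq, nonlin_seq = master.spawn(3)
        graph = generate_scale_free_network(config.p + config.q, seed=net_seq)
        for linear, seq in ((True, lin_seq), (False, nonlin_seq)):
            par_seed, samp_seed = seq.spawn(2)
            model = assign_parameters(graph, config, linear=linear, seed=par_seed)
            data = sample_dataset(model, config.n_samples,
                                  burn_in=config.burn_in, thin=config.thin,
                                  seed=samp_seed)
            out.append({
                "network": k,
                "linear": linear,
                "data": data,
                "model": model,
                "adjacency": true_adjacency(model),
            })
    return out
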