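"""Stability-based penalty selection: StARS, StEPS and the cubic search.

StARS draws ``N`` subsamples of size ``b`` without replacement, learns one
network per (subsample, lambda), and summarizes how often any two subsample
networks disagree about each edge: with ``theta_st(lam)`` the fraction of
subsample networks containing edge (s, t), the edge instability is
``xi_st = 2 theta (1 - theta)`` and the total instability ``D(lam)`` is the
average of ``xi`` over all unordered pairs.  After monotonizing
(``Dbar(lam) = sup_{t >= lam} D(t)``), the smallest lambda with
``Dbar <= gamma`` is selected and the model refit on all samples.

StEPS computes the same quantities separately for cc, cd and dd edge
positions *from the same single-lambda ensemble* and thresholds each curve
independently, giving three edge-type-specific penalties in linear time
(``N * |grid|`` fits).  The cubic search fits the full triple grid
(``N * |grid|^3`` fits) and serves as the validity check for StEPS's
independence assumption: among settings whose monotonized instability
(pooled, or the max over the three per-type curves) stays below gamma, it
picks the one whose subsample networks carry the most predicted edges.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (FitConfig, MGMParameters, MixedDataset, PenaltyWeights,
                   adjacency_from_parameters, edge_type_masks, fit_mgm)
from .selection import LambdaGrid, fit_path

__all__ = [
    "SubsampleEnsemble",
    "InstabilityProfile",
    "default_subsample_size",
    "draw_subsamples",
    "subsample_adjacencies",
    "edge_frequency",
    "edge_instability",
    "total_instability",
    "monotonize",
    "stars_select_lambda",
    "instability_profile",
    "stars_select",
    "steps_select",
    "cubic_stability_select",
    "StabilityResult",
]

EDGE_TYPES = ("all", "cc", "cd", "dd")


def default_subsample_size(n: int) -> int:
    """``b = floor(10 * sqrt(n))``, capped at ``n``."""
    return min(n, int(math.floor(10.0 * math.sqrt(n))))


@dataclass
class SubsampleEnsemble:
    """Subsample index sets and the adjacency of every (subsample, candidate)
    fit."""

    indices: np.ndarray        # (N, b) sample indices
    candidates: list           # PenaltyWeights, warm-start order
    adjacencies: np.ndarray    # (N, C, P, P) bool

    @property
    def N(self) -> int:
        return self.indices.shape[0]


@dataclass
class InstabilityProfile:
    """Per-lambda edge frequencies and instabilities from a single-lambda
    subsample ensemble, with per-edge-type totals and their monotonizations."""

    lambdas: tuple             # descending
    theta: np.ndarray          # (G, P, P) subsample edge frequencies
    xi: np.ndarray             # (G, P, P) edge instabilities
    d_hat: dict                # edge type -> (G,) total instability
    d_bar: dict                # edge type -> (G,) monotonized
    edge_counts: np.ndarray    # (N, G) predicted edges per subsample network


@dataclass
class StabilityResult:
    method: str
    chosen: PenaltyWeights
    profile: object = None
    params: Optional[MGMParameters] = None
    warnings: list = field(default_factory=list)


def draw_subsamples(n: int, N: int = 20, b: Optional[int] = None,
                    seed=None) -> np.ndarray:
    """Draw ``N`` subsamples of ``b`` distinct indices without replacement,
    reproducibly from ``seed``."""
    if b is None:
        b = default_subsample_size(n)
    if b > n:
        raise ValueError("subsample size b exceeds n")
    if N < 2:
        raise ValueError("need at least 2 subsamples")
    rng = np.random.default_rng(seed)
    return np.stack([rng.choice(n, size=b, replace=False) for _ in range(N)])


def subsample_adjacencies(data: MixedDataset, candidates: Sequence[PenaltyWeights],
                          indices: np.ndarray,
                          config: Optional[FitConfig] = None) -> SubsampleEnsemble:
    """Fit every (subsample, candidate) model and record its adjacency.

    Candidates are fit in the given order with warm starts within each
    subsample; exactly ``N * len(candidates)`` fits are performed.
    """
    P = data.p + data.q
    N = indices.shape[0]
    adj = np.zeros((N, len(candidates), P, P), dtype=bool)
    for i in range(N):
        sub = data.subset(indices[i])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fits = fit_path(sub, candidates, config)
        for c, f in enumerate(fits):
            adj[i, c] = adjacency_from_parameters(f)
    return SubsampleEnsemble(np.asarray(indices), list(candidates), adj)


def edge_frequency(adjacencies: np.ndarray) -> np.ndarray:
    """Element-wise mean of a stack of binary adjacencies (first axis =
    subsamples)."""
    adjacencies = np.asarray(adjacencies)
    if adjacencies.ndim < 3 or adjacencies.shape[0] < 1:
        raise ValueError("need at least one subsample adjacency")
    return adjacencies.mean(axis=0)


def edge_instability(theta: np.ndarray) -> np.ndarray:
    """``xi = 2 * theta * (1 - theta)``: the probability that two subsample
    networks disagree about each edge."""
    theta = np.asarray(theta, dtype=float)
    return 2.0 * theta * (1.0 - theta)


def total_instability(xi: np.ndarray, edge_type: str, p: int, q: int) -> float:
    """Mean instability over the unordered-pair positions of one edge type
    (denominators C(p+q,2), C(p,2), p*q, C(q,2) for all/cc/cd/dd)."""
    mask = edge_type_masks(p, q)[edge_type]
    cnt = int(mask.sum())
    if cnt == 0:
        raise ValueError(f"no {edge_type} edge positions with p={p}, q={q}")
    return float(np.asarray(xi)[mask].sum()) / cnt


def monotonize(d_hat: np.ndarray, axis: int = 0) -> np.ndarray:
    """Running maximum over larger penalties: with the grid ordered by
    descending lambda, ``Dbar(lam) = max_{t >= lam} Dhat(t)``."""
    return np.maximum.accumulate(np.asarray(d_hat, dtype=float), axis=axis)


def stars_select_lambda(lambdas: Sequence[float], d_bar: np.ndarray,
                        gamma: float = 0.05):
    """Smallest lambda whose monotonized instability stays within gamma.

    Scans from the largest lambda down; if even the largest violates the
    threshold, the largest lambda is returned with a warning flag.
    """
    lambdas = tuple(lambdas)
    d_bar = np.asarray(d_bar, dtype=float)
    feasible = np.flatnonzero(d_bar <= gamma)
    if feasible.size == 0:
        return lambdas[0], 0, True
    # Dbar is non-decreasing along the descending grid, so the feasible set
    # is a prefix; its last element is the smallest feasible lambda.
    idx = int(feasible[-1])
    return lambdas[idx], idx, False


def instability_profile(data: MixedDataset, grid: LambdaGrid,
                        N: int = 20, b: Optional[int] = None,
                        config: Optional[FitConfig] = None, seed=None
                        ) -> InstabilityProfile:
    """Build the per-lambda, per-edge-type instability profile from a
    single-lambda subsample ensemble (``N * |grid|`` fits)."""
    if grid.mode != "single":
        raise ValueError("instability_profile requires a single-lambda grid")
    indices = draw_subsamples(data.n, N=N, b=b, seed=seed)
    ens = subsample_adjacencies(data, grid.candidates(), indices, config)
    return profile_from_ensemble(ens, grid.values, data.p, data.q)


def profile_from_ensemble(ens: SubsampleEnsemble, lambdas: Sequence[float],
                          p: int, q: int) -> InstabilityProfile:
    theta = edge_frequency(ens.adjacencies)           # (G, P, P)
    xi = edge_instability(theta)
    masks = edge_type_masks(p, q)
    d_hat, d_bar = {}, {}
    for et in EDGE_TYPES:
        if masks[et].sum() == 0:
            continue
        d = np.array([total_instability(x, et, p, q) for x in xi])
        d_hat[et] = d
        d_bar[et] = monotonize(d)
    upper = masks["all"]
    edge_counts = ens.adjacencies[:, :, upper].sum(axis=2)  # (N, G)
    return InstabilityProfile(tuple(lambdas), theta, xi, d_hat, d_bar, edge_counts)


def stars_select(data: MixedDataset, grid: LambdaGrid, N: int = 20,
                 b: Optional[int] = None, gamma: float = 0.05,
                 config: Optional[FitConfig] = None, seed=None,
                 profile: Optional[InstabilityProfile] = None) -> StabilityResult:
    """Single-penalty StARS: threshold the pooled instability curve, then
    refit on all samples at the selected lambda."""
    if profile is None:
        profile = instability_profile(data, grid, N=N, b=b, config=config, seed=seed)
    lam, _, warned = stars_select_lambda(profile.lambdas, profile.d_bar["all"], gamma)
    notes = []
    if warned:
        notes.append("instability threshold never met; returning largest lambda")
        warnings.warn(notes[-1], RuntimeWarning)
    chosen = PenaltyWeights.single(lam)
    params = fit_mgm(data, chosen, config)
    return StabilityResult("stars", chosen, profile, params, notes)


def steps_select(data: MixedDataset, grid: LambdaGrid, N: int = 20,
                 b: Optional[int] = None, gamma: float = 0.05,
                 config: Optional[FitConfig] = None, seed=None,
                 profile: Optional[InstabilityProfile] = None) -> StabilityResult:
    """Stable Edge-specific Penalty Selection.

    Learns one single-lambda MGM per (subsample, lambda) — ``N * |grid|``
    subsample fits in total — computes the per-edge-type instability curves
    from that one ensemble, thresholds each curve independently, and refits
    on all samples with the three selected penalties.
    """
    if profile is None:
        profile = instability_profile(data, grid, N=N, b=b, config=config, seed=seed)
    notes = []
    sel = {}
    for et in ("cc", "cd", "dd"):
        if et not in profile.d_bar:
            raise ValueError(f"edge type {et} has no positions in this dataset")
        lam, _, warned = stars_select_lambda(profile.lambdas, profile.d_bar[et], gamma)
        if warned:
            notes.append(f"{et}: instability threshold never met; using largest lambda")
            warnings.warn(notes[-1], RuntimeWarning)
        sel[et] = lam
    chosen = PenaltyWeights(sel["cc"], sel["cd"], sel["dd"])
    params = fit_mgm(data, chosen, config)
    return StabilityResult("steps", chosen, profile, params, notes)


def cubic_stability_select(data: MixedDataset, grid: LambdaGrid, N: int = 20,
                           b: Optional[int] = None, gamma: float = 0.05,
                           rule: str = "per_type_max",
                           config: Optional[FitConfig] = None, seed=None,
                           ensemble: Optional[SubsampleEnsemble] = None
                           ) -> StabilityResult:
    """Three-dimensional stability search over the full triple grid.

    Fits ``N * |grid|^3`` subsample models, monotonizes each per-type (or
    pooled) instability array across each of its three dimensions, and among
    settings meeting the gamma threshold selects the one whose subsample
    networks carry the most predicted edges in total (ties toward sparser
    penalties).  If no setting is feasible, the most stable one is returned
    with a warning.
    """
    if rule not in ("pooled", "per_type_max"):
        raise ValueError("rule must be 'pooled' or 'per_type_max'")
    G = len(grid.values)
    triple = LambdaGrid(grid.values, mode="triple")
    candidates = triple.candidates()
    if ensemble is None:
        indices = draw_subsamples(data.n, N=N, b=b, seed=seed)
        ensemble = subsample_adjacencies(data, candidates, indices, config)
    p, q = data.p, data.q
    masks = edge_type_masks(p, q)
    theta = edge_frequency(ensemble.adjacencies)   # (C, P, P)
    xi = edge_instability(theta)
    idx_of = {v: i for i, v in enumerate(grid.values)}
    pos = np.array([[idx_of[c.lambda_cc], idx_of[c.lambda_cd],
                     idx_of[c.lambda_dd]] for c in candidates])

    def dcube(et):
        mask = masks[et]
        d = np.empty((G, G, G))
        d[pos[:, 0], pos[:, 1], pos[:, 2]] = xi[:, mask].mean(axis=1)
        for ax in range(3):  # dimension-wise running maxima reach the sup
            d = monotonize(d, axis=ax)
        return d

    if rule == "pooled":
        stat = dcube("all")
    else:
        stat = np.maximum.reduce([dcube(et) for et in ("cc", "cd", "dd")
                                  if masks[et].sum()])
    stat_flat = stat[pos[:, 0], pos[:, 1], pos[:, 2]]  # per candidate
    upper = masks["all"]
    counts = ensemble.adjacencies[:, :, upper].sum(axis=(0, 2))  # per candidate
    feasible = stat_flat <= gamma
    notes = []
    if not feasible.any():
        notes.append("no setting met the instability threshold; "
                     "returning the most stable one")
        warnings.warn(notes[-1], RuntimeWarning)
        best = int(np.lexsort((np.arange(len(candidates)), stat_flat))[0])
    else:
        idx = np.flatnonzero(feasible)
        key = sorted(idx, key=lambda i: (
            -counts[i],
            -candidates[i].lambda_dd, -candidates[i].lambda_cd,
            -candidates[i].lambda_cc))
        best = int(key[0])
    chosen = candidates[best]
    params = fit_mgm(data, chosen, config)
    counts_cube = np.empty((G, G, G), dtype=int)
    counts_cube[pos[:, 0], pos[:, 1], pos[:, 2]] = counts
    result = StabilityResult(f"cubic_{rule}", chosen, None, params, notes)
    result.profile = {"stat": stat, "edge_counts": counts_cube,
                      "candidates": candidates}
    return result
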