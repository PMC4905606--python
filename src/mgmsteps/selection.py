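"""Classical penalty selection: AIC, BIC, K-fold CV and oracle selection.

All methods score candidate penalty triples ``(lambda_cc, lambda_cd,
lambda_dd)`` from a grid — either a shared single value or the full cubic
Cartesian product — and refit the winning candidate on all samples.  AIC and
BIC substitute the (sample-summed) negative log-pseudolikelihood for the
likelihood, with network degrees of freedom of 1 per cc edge, ``L - 1`` per
cd edge and ``(L_i - 1)(L_j - 1)`` per dd edge.  The oracle picks the
candidate minimizing false positives plus false negatives against the known
generating graph; it is an upper bound on selection performance, not a
practical method.  Ties are always broken toward sparser models
(lexicographically larger ``(lambda_dd, lambda_cd, lambda_cc)``).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (FitConfig, MGMParameters, MixedDataset, PenaltyWeights,
                   adjacency_from_parameters, degrees_of_freedom, fit_mgm,
                   negative_log_pseudolikelihood)

__all__ = [
    "LambdaGrid",
    "SelectionResult",
    "fit_path",
    "aic_score",
    "bic_score",
    "select_information_criterion",
    "cross_validate",
    "oracle_select",
]

DEFAULT_GRID = (0.64, 0.32, 0.16, 0.08, 0.04)
#: 13 values evenly spaced on a log scale from .64 down to .08
LOG13_GRID = tuple(float(v) for v in np.geomspace(0.64, 0.08, 13))


@dataclass
class LambdaGrid:
    """Ordered, strictly decreasing positive penalty values.

    ``mode="single"`` shares one value across all three edge types;
    ``mode="triple"`` enumerates the full cubic Cartesian product.
    """

    values: tuple
    mode: str = "single"

    def __post_init__(self):
        self.values = tuple(float(v) for v in self.values)
        if any(v <= 0 for v in self.values):
            raise ValueError("grid values must be strictly positive")
        if any(a >= b for a, b in zip(self.values[1:], self.values[:-1])):
            raise ValueError("grid values must be strictly decreasing")
        if self.mode not in ("single", "triple"):
            raise ValueError("mode must be 'single' or 'triple'")

    def candidates(self) -> list:
        """Candidate penalty settings in warm-start order.

        Single mode descends the grid; triple mode walks the cube
        boustrophedon-style so consecutive candidates differ in exactly one
        coordinate by one grid step, which keeps warm starts close.
        """
        if self.mode == "single":
            return [PenaltyWeights.single(v) for v in self.values]
        G = len(self.values)
        out = []
        for i in range(G):
            js = range(G) if i % 2 == 0 else range(G - 1, -1, -1)
            for nj, j in enumerate(js):
                ks = range(G) if (i + nj) % 2 == 0 else range(G - 1, -1, -1)
                for k in ks:
                    out.append(PenaltyWeights(self.values[i], self.values[j],
                                              self.values[k]))
        return out


@dataclass
class SelectionResult:
    method: str
    chosen: PenaltyWeights
    table: pd.DataFrame  # one row per candidate with its score
    params: Optional[MGMParameters] = None  # refit on all samples


def _sparser_key(pw: PenaltyWeights):
    return (-pw.lambda_dd, -pw.lambda_cd, -pw.lambda_cc)


def fit_path(data: MixedDataset, candidates: Sequence[PenaltyWeights],
             config: Optional[FitConfig] = None, warm_start: bool = True) -> list:
    """Fit one MGM per candidate, warm-starting each fit from the previous
    candidate's solution (candidates should be ordered large-to-small)."""
    fits = []
    prev = None
    for pw in candidates:
        prev = fit_mgm(data, pw, config, init=prev if warm_start else None)
        fits.append(prev)
    return fits


def aic_score(params: MGMParameters, data: MixedDataset) -> float:
    """``2 * NLPL + 2 * dof`` with the pseudolikelihood summed over samples."""
    return 2.0 * float(negative_log_pseudolikelihood(params, data)) \
        + 2.0 * degrees_of_freedom(params)


def bic_score(params: MGMParameters, data: MixedDataset) -> float:
    """``2 * NLPL + log(n) * dof`` with the pseudolikelihood summed over samples."""
    return 2.0 * float(negative_log_pseudolikelihood(params, data)) \
        + math.log(data.n) * degrees_of_freedom(params)


def _result_table(candidates, scores) -> pd.DataFrame:
    return pd.DataFrame({
        "lambda_cc": [c.lambda_cc for c in candidates],
        "lambda_cd": [c.lambda_cd for c in candidates],
        "lambda_dd": [c.lambda_dd for c in candidates],
        "score": scores,
    })


def _pick(candidates, scores) -> PenaltyWeights:
    order = sorted(range(len(candidates)),
                   key=lambda i: (scores[i],) + _sparser_key(candidates[i]))
    return candidates[order[0]]


def select_information_criterion(data: MixedDataset, grid: LambdaGrid,
                                 criterion: str = "aic",
                                 config: Optional[FitConfig] = None,
                                 fits: Optional[Sequence[MGMParameters]] = None
                                 ) -> SelectionResult:
    """AIC or BIC selection over the grid; ``fits`` may supply cached
    full-data fits aligned with ``grid.candidates()``."""
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    candidates = grid.candidates()
    if fits is None:
        fits = fit_path(data, candidates, config)
    score_fn = aic_score if criterion == "aic" else bic_score
    scores = [score_fn(f, data) for f in fits]
    chosen = _pick(candidates, scores)
    params = fits[candidates.index(chosen)]
    return SelectionResult(criterion, chosen, _result_table(candidates, scores), params)


def cross_validate(data: MixedDataset, grid: LambdaGrid, K: int = 5,
                   config: Optional[FitConfig] = None, seed: int = 0
                   ) -> SelectionResult:
    """K-fold cross-validation on held-out per-sample pseudolikelihood.

    Folds are a deterministic random partition given ``seed``.  For each
    candidate the held-out negative log-pseudolikelihood per sample is
    averaged across folds; the minimizer is refit on all samples.
    """
    if data.n < K:
        raise ValueError("need at least K samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(data.n)
    folds = np.array_split(perm, K)
    candidates = grid.candidates()
    fold_scores = np.zeros((K, len(candidates)))
    for k, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(perm, test_idx)
        train = data.subset(train_idx)
        test = data.subset(test_idx)
        for j, L in enumerate(train.levels):
            if len(np.unique(train.Y[:, j])) < L:
                warnings.warn(
                    f"fold {k}: categorical variable {train.cat_names[j]} lost "
                    "a level; keeping it with zero count", RuntimeWarning)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fits = fit_path(train, candidates, config)
        for i, f in enumerate(fits):
            fold_scores[k, i] = float(
                negative_log_pseudolikelihood(f, test)) / test.n
    scores = fold_scores.mean(axis=0).tolist()
    chosen = _pick(candidates, scores)
    params = fit_mgm(data, chosen, config)
    return SelectionResult("cv", chosen, _result_table(candidates, scores), params)


def oracle_select(data: MixedDataset, grid: LambdaGrid,
                  true_adjacency: np.ndarray,
                  config: Optional[FitConfig] = None,
                  fits: Optional[Sequence[MGMParameters]] = None
                  ) -> SelectionResult:
    """Select the candidate minimizing FP + FN against the true graph."""
    true_adjacency = np.asarray(true_adjacency, dtype=bool)
    if true_adjacency.shape != (data.p + data.q,) * 2:
        raise ValueError("true adjacency does not match data dimensions")
    candidates = grid.candidates()
    if fits is None:
        fits = fit_path(data, candidates, config)
    upper = np.triu_indices(data.p + data.q, 1)
    scores = []
    for f in fits:
        A = adjacency_from_parameters(f)
        scores.append(int(np.sum(A[upper] != true_adjacency[upper])))
    chosen = _pick(candidates, scores)
    params = fits[candidates.index(chosen)]
    return SelectionResult("oracle", chosen, _result_table(candidates, scores), params)
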