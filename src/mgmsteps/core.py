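"""Pairwise mixed graphical models over continuous and categorical variables.

The model is a pairwise Markov random field with joint density proportional to

    exp( sum_{s,t} -1/2 beta_st x_s x_t + sum_s alpha_s x_s
         + sum_{s,j} rho_sj(y_j) x_s + sum_{j <= r} phi_rj(y_r, y_j) )

where the quadratic continuous form runs over all index pairs (cross terms
appear twice, halved) while each categorical pair potential is counted once.  ``beta`` couples pairs of
continuous variables, ``rho_sj`` is a per-level vector coupling continuous
variable ``s`` to categorical variable ``j``, and ``phi_rj`` is a per-level
matrix coupling two categorical variables.  Structure learning minimizes the
negative log-pseudolikelihood (sum of each variable's conditional given the
rest) plus edge-type-specific sparsity penalties:

    lambda_cc * sum_{t<s} |beta_st|
  + lambda_cd * sum_{s,j} ||rho_sj||_2
  + lambda_dd * sum_{r<j} ||phi_rj||_F

solved with an accelerated proximal-gradient (FISTA) scheme with backtracking
line search and monotone restarts.  Categorical variables use L indicator
columns per variable; the group penalty structure keeps each rho vector
sum-to-zero and each phi block doubly centered (zero row and column sums),
which this implementation enforces exactly by projecting gradients onto the
centered subspace (block soft-thresholding is radial, so iterates stay
centered).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MixedDataset",
    "MGMParameters",
    "PenaltyWeights",
    "FitConfig",
    "FitDivergenceError",
    "log_unnormalized_density",
    "continuous_conditional",
    "categorical_conditional",
    "negative_log_pseudolikelihood",
    "penalty_value",
    "proximal_step",
    "fit_mgm",
    "adjacency_from_parameters",
    "degrees_of_freedom",
    "edge_type_masks",
    "fit_call_count",
    "reset_fit_counter",
]

_BETA_DIAG_FLOOR = 1e-6

# global fit-call accounting, used to verify the linear-vs-cubic cost claims
_FIT_CALLS = 0


def fit_call_count() -> int:
    """Number of calls to :func:`fit_mgm` since the last counter reset."""
    return _FIT_CALLS


def reset_fit_counter() -> None:
    global _FIT_CALLS
    _FIT_CALLS = 0


class FitDivergenceError(RuntimeError):
    """Raised when the penalized objective becomes non-finite during a fit."""


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class MixedDataset:
    """A sample-by-variable table of continuous and categorical observations.

    Parameters
    ----------
    X
        ``(n, p)`` float matrix of continuous observations.
    Y
        ``(n, q)`` integer matrix of 0-based category indices.
    levels
        Number of categories ``L_j >= 2`` for each categorical variable.
    cont_names, cat_names
        Variable names; generated automatically when omitted.
    level_labels
        For each categorical variable, the external labels of its levels in
        index order (defaults to ``"1" .. "L"``).
    """

    X: np.ndarray
    Y: np.ndarray
    levels: tuple
    cont_names: list = field(default_factory=list)
    cat_names: list = field(default_factory=list)
    level_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=int)
        if self.X.ndim != 2 or self.Y.ndim != 2:
            raise ValueError("X and Y must be 2-D arrays")
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y must have the same number of rows")
        self.levels = tuple(int(L) for L in self.levels)
        if len(self.levels) != self.Y.shape[1]:
            raise ValueError("levels must have one entry per categorical variable")
        if any(L < 2 for L in self.levels):
            raise ValueError("every categorical variable needs at least 2 levels")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")
        for j, L in enumerate(self.levels):
            col = self.Y[:, j]
            if col.size and (col.min() < 0 or col.max() >= L):
                raise ValueError(f"category index out of range in column {j}")
        if not self.cont_names:
            self.cont_names = [f"x{s+1}" for s in range(self.p)]
        if not self.cat_names:
            self.cat_names = [f"y{j+1}" for j in range(self.q)]
        if not self.level_labels:
            self.level_labels = [[str(k + 1) for k in range(L)] for L in self.levels]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Y.shape[1]

    @property
    def names(self) -> list:
        return list(self.cont_names) + list(self.cat_names)

    def indicator(self) -> np.ndarray:
        """One-hot encoding of ``Y`` with ``sum(levels)`` columns."""
        offs = np.concatenate([[0], np.cumsum(self.levels)]).astype(int)
        D = np.zeros((self.n, offs[-1]))
        rows = np.arange(self.n)
        for j in range(self.q):
            D[rows, offs[j] + self.Y[:, j]] = 1.0
        return D

    def subset(self, idx) -> "MixedDataset":
        idx = np.asarray(idx)
        return MixedDataset(
            self.X[idx], self.Y[idx], self.levels,
            list(self.cont_names), list(self.cat_names),
            [list(ll) for ll in self.level_labels],
        )


@dataclass
class PenaltyWeights:
    """Edge-type-specific sparsity penalties (all non-negative)."""

    lambda_cc: float
    lambda_cd: float
    lambda_dd: float

    def __post_init__(self):
        if min(self.lambda_cc, self.lambda_cd, self.lambda_dd) < 0:
            raise ValueError("penalty weights must be non-negative")

    @classmethod
    def single(cls, lam: float) -> "PenaltyWeights":
        return cls(lam, lam, lam)

    def astuple(self):
        return (self.lambda_cc, self.lambda_cd, self.lambda_dd)


@dataclass
class FitConfig:
    """Optimizer settings for :func:`fit_mgm`."""

    max_iter: int = 500
    tol: float = 1e-6
    step0: float = 1.0
    backtrack: float = 0.5
    accelerate: bool = True
    standardize: bool = True
    seed: Optional[int] = None  # reserved; the fit itself is deterministic

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")


@dataclass
class MGMParameters:
    """Parameters of a pairwise mixed graphical model.

    ``beta`` is the symmetric ``(p, p)`` continuous interaction matrix with a
    strictly positive diagonal, ``alpha`` the ``(p,)`` continuous intercepts,
    ``rho`` a ``(p, Q)`` matrix whose column block ``j`` holds the vectors
    ``rho_sj`` (``Q = sum(levels)``), and ``phi`` a symmetric ``(Q, Q)``
    block matrix of categorical interactions.  ``x_mean`` / ``x_sd`` record
    the standardization applied to the continuous columns during fitting
    (``None`` when the model lives on the raw scale).
    """

    beta: np.ndarray
    alpha: np.ndarray
    rho: np.ndarray
    phi: np.ndarray
    levels: tuple
    x_mean: Optional[np.ndarray] = None
    x_sd: Optional[np.ndarray] = None
    fit_info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.levels = tuple(int(L) for L in self.levels)

    @property
    def p(self) -> int:
        return self.beta.shape[0]

    @property
    def q(self) -> int:
        return len(self.levels)

    @property
    def offsets(self) -> np.ndarray:
        return np.concatenate([[0], np.cumsum(self.levels)]).astype(int)

    @classmethod
    def zeros(cls, p: int, levels: Sequence[int]) -> "MGMParameters":
        Q = int(sum(levels))
        return cls(np.eye(p), np.zeros(p), np.zeros((p, Q)), np.zeros((Q, Q)), tuple(levels))

    def rho_block(self, s: int, j: int) -> np.ndarray:
        o = self.offsets
        return self.rho[s, o[j]:o[j + 1]]

    def phi_block(self, r: int, j: int) -> np.ndarray:
        o = self.offsets
        return self.phi[o[r]:o[r + 1], o[j]:o[j + 1]]

    def copy(self) -> "MGMParameters":
        return MGMParameters(
            self.beta.copy(), self.alpha.copy(), self.rho.copy(), self.phi.copy(),
            self.levels,
            None if self.x_mean is None else self.x_mean.copy(),
            None if self.x_sd is None else self.x_sd.copy(),
            dict(self.fit_info),
        )


# ---------------------------------------------------------------------------
# flat parameterization used by the optimizer
# ---------------------------------------------------------------------------


class _Layout:
    """Index bookkeeping between MGMParameters and a flat free-parameter vector.

    Each free parameter appears exactly once in the vector: the beta diagonal,
    the strict upper triangle of beta, alpha, the full rho matrix, the upper
    off-diagonal phi blocks, and the diagonals of the within-variable phi
    blocks (the only part of phi_rr the conditionals use).
    """

    def __init__(self, p: int, levels: Sequence[int]):
        self.p = int(p)
        self.levels = tuple(int(L) for L in levels)
        self.q = len(self.levels)
        self.Q = int(sum(self.levels))
        self.offs = np.concatenate([[0], np.cumsum(self.levels)]).astype(int)
        self.tr, self.tc = np.triu_indices(self.p, 1)

        self.pairs = [(r, j) for r in range(self.q) for j in range(r + 1, self.q)]
        sizes = [self.levels[r] * self.levels[j] for (r, j) in self.pairs]
        self.phi_sizes = np.asarray(sizes, dtype=int)
        self.phi_bounds = np.concatenate([[0], np.cumsum(sizes)]).astype(int)

        # flat indices into a (Q, Q) matrix for the upper blocks (row-major
        # within each block) and their transposes
        up, lo = [], []
        for (r, j) in self.pairs:
            a = np.arange(self.offs[r], self.offs[r + 1])
            b = np.arange(self.offs[j], self.offs[j + 1])
            A, B = np.meshgrid(a, b, indexing="ij")
            up.append((A * self.Q + B).ravel())
            lo.append((B * self.Q + A).ravel())
        self.phi_up_idx = np.concatenate(up) if up else np.zeros(0, dtype=int)
        self.phi_lo_idx = np.concatenate(lo) if lo else np.zeros(0, dtype=int)
        self.phi_diag_idx = (np.arange(self.Q) * self.Q + np.arange(self.Q))

        n_bdiag = self.p
        n_boff = self.p * (self.p - 1) // 2
        n_alpha = self.p
        n_rho = self.p * self.Q
        n_phioff = int(self.phi_sizes.sum()) if sizes else 0
        n_phidiag = self.Q
        cuts = np.cumsum([0, n_bdiag, n_boff, n_alpha, n_rho, n_phioff, n_phidiag])
        (self.s_bdiag, self.s_boff, self.s_alpha,
         self.s_rho, self.s_phioff, self.s_phidiag) = (
            slice(cuts[i], cuts[i + 1]) for i in range(6))
        self.size = int(cuts[-1])
        self.uniform_L = len(set(self.levels)) <= 1

    # -- conversions -------------------------------------------------------
    def pack(self, params: MGMParameters) -> np.ndarray:
        v = np.zeros(self.size)
        v[self.s_bdiag] = np.diag(params.beta)
        v[self.s_boff] = params.beta[self.tr, self.tc]
        v[self.s_alpha] = params.alpha
        v[self.s_rho] = params.rho.ravel()
        if self.phi_up_idx.size:
            v[self.s_phioff] = params.phi.ravel()[self.phi_up_idx]
        v[self.s_phidiag] = params.phi.ravel()[self.phi_diag_idx]
        return v

    def unpack(self, v: np.ndarray) -> tuple:
        """Return (beta, alpha, R, Phi_off, phidiag) as full matrices."""
        beta = np.zeros((self.p, self.p))
        beta[self.tr, self.tc] = v[self.s_boff]
        beta += beta.T
        np.fill_diagonal(beta, v[self.s_bdiag])
        alpha = v[self.s_alpha].copy()
        R = v[self.s_rho].reshape(self.p, self.Q)
        Phi_off = np.zeros((self.Q, self.Q))
        if self.phi_up_idx.size:
            Phi_off.ravel()[self.phi_up_idx] = v[self.s_phioff]
            Phi_off.ravel()[self.phi_lo_idx] = v[self.s_phioff]
        phidiag = v[self.s_phidiag].copy()
        return beta, alpha, R, Phi_off, phidiag

    def to_params(self, v: np.ndarray, **kw) -> MGMParameters:
        beta, alpha, R, Phi_off, phidiag = self.unpack(v)
        Phi = Phi_off.copy()
        Phi.ravel()[self.phi_diag_idx] = phidiag
        return MGMParameters(beta, alpha, R, Phi, self.levels, **kw)

    # -- group geometry ----------------------------------------------------
    def rho_group_norms(self, rho_flat: np.ndarray) -> np.ndarray:
        R2 = (rho_flat.reshape(self.p, self.Q)) ** 2
        if self.q == 0:
            return np.zeros((self.p, 0))
        return np.sqrt(np.add.reduceat(R2, self.offs[:-1], axis=1))

    def phi_group_norms(self, phi_flat: np.ndarray) -> np.ndarray:
        if not len(self.pairs):
            return np.zeros(0)
        return np.sqrt(np.add.reduceat(phi_flat ** 2, self.phi_bounds[:-1]))

    def center_rho(self, rho_flat: np.ndarray) -> np.ndarray:
        """Project each rho_sj block onto sum-to-zero."""
        if self.q == 0:
            return rho_flat
        R = rho_flat.reshape(self.p, self.Q).copy()
        means = np.add.reduceat(R, self.offs[:-1], axis=1) / np.asarray(self.levels)
        R -= np.repeat(means, self.levels, axis=1)
        return R.ravel()

    def center_phi(self, phi_flat: np.ndarray) -> np.ndarray:
        """Project each off-diagonal phi block onto zero row and column sums."""
        if not len(self.pairs):
            return phi_flat
        out = phi_flat.copy()
        if self.uniform_L:
            L = self.levels[0]
            blocks = out.reshape(-1, L, L)
            rm = blocks.mean(axis=2, keepdims=True)
            cm = blocks.mean(axis=1, keepdims=True)
            gm = blocks.mean(axis=(1, 2), keepdims=True)
            blocks -= rm + cm - gm
            return blocks.ravel()
        for k, (r, j) in enumerate(self.pairs):
            blk = out[self.phi_bounds[k]:self.phi_bounds[k + 1]].reshape(
                self.levels[r], self.levels[j])
            blk -= blk.mean(axis=1, keepdims=True)
            blk -= blk.mean(axis=0, keepdims=True)
            out[self.phi_bounds[k]:self.phi_bounds[k + 1]] = blk.ravel()
        return out


_LAYOUT_CACHE: dict = {}


def _layout_for(p: int, levels: Sequence[int]) -> _Layout:
    key = (int(p), tuple(int(L) for L in levels))
    if key not in _LAYOUT_CACHE:
        _LAYOUT_CACHE[key] = _Layout(p, levels)
    return _LAYOUT_CACHE[key]


# ---------------------------------------------------------------------------
# density and conditionals
# ---------------------------------------------------------------------------


def _check_xy(params: MGMParameters, x, y):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=int).ravel()
    if x.size != params.p or y.size != params.q:
        raise ValueError("dimension mismatch between parameters and (x, y)")
    for j, L in enumerate(params.levels):
        if y.size and not (0 <= y[j] < L):
            raise ValueError(f"level index out of range for categorical variable {j}")
    return x, y


def log_unnormalized_density(params: MGMParameters, x, y) -> float:
    """Exponent of the joint density at a single configuration ``(x, y)``.

    The continuous quadratic form runs over all index pairs (so each cross
    term ``-1/2 beta_st x_s x_t`` appears twice); each categorical pair
    potential ``phi_rj(y_r, y_j)`` is counted once, including ``r = j``.
    """
    x, y = _check_xy(params, x, y)
    offs = params.offsets
    idx = offs[:-1] + y if params.q else np.zeros(0, dtype=int)
    val = -0.5 * float(x @ params.beta @ x) + float(params.alpha @ x)
    if params.q:
        d = np.zeros(offs[-1])
        d[idx] = 1.0
        val += float(x @ (params.rho @ d))
        # off-diagonal blocks are stored symmetrically: halve the double count
        Phi = params.phi
        val += 0.5 * float(d @ Phi @ d)
        val += 0.5 * float(sum(Phi[offs[r] + y[r], offs[r] + y[r]]
                               for r in range(params.q)))
    return val


def continuous_conditional(params: MGMParameters, s: int, x, y):
    """Gaussian conditional of ``x_s`` given all other variables.

    Returns ``(mean, variance)`` with ``variance = 1/beta_ss`` and
    ``mean = (alpha_s + sum_j rho_sj(y_j) - sum_{t != s} beta_st x_t) / beta_ss``.
    """
    x, y = _check_xy(params, x, y)
    d = params.beta[s, s]
    if d <= 0:
        raise ValueError("conditional variance undefined: beta diagonal not positive")
    offs = params.offsets
    num = params.alpha[s]
    if params.q:
        idx = offs[:-1] + y
        num += params.rho[s, idx].sum()
    num -= params.beta[s] @ x - params.beta[s, s] * x[s]
    return num / d, 1.0 / d


def categorical_conditional(params: MGMParameters, r: int, x, y) -> np.ndarray:
    """Probability vector of ``y_r`` given all other variables.

    Derived by renormalizing the joint density over the levels of ``y_r``:
    the logit of level ``k`` is
    ``sum_s rho_sr(k) x_s + sum_{j != r} phi_rj(k, y_j) + phi_rr(k, k)``.
    """
    x, y = _check_xy(params, x, y)
    offs = params.offsets
    sl = slice(offs[r], offs[r + 1])
    logits = params.rho[:, sl].T @ x if params.p else np.zeros(params.levels[r])
    idx = offs[:-1] + y
    cross = params.phi[sl][:, idx].sum(axis=1) - params.phi[sl][:, idx[r]]
    logits = logits + cross + np.diag(params.phi[sl, sl])
    logits -= logits.max()
    w = np.exp(logits)
    return w / w.sum()


# ---------------------------------------------------------------------------
# pseudolikelihood objective
# ---------------------------------------------------------------------------


def _apply_standardizer(params: MGMParameters, data: MixedDataset):
    """Return (X, jacobian_term): data on the scale the parameters live on."""
    if params.x_mean is None:
        return data.X, 0.0
    X = (data.X - params.x_mean) / params.x_sd
    return X, float(data.n * np.sum(np.log(params.x_sd)))


def _nlpl_arrays(beta, alpha, R, Phi_off, phidiag, X, D, Yidx, offs,
                 want_grad=False, per_sample=False):
    """Negative log-pseudolikelihood (summed over samples) and its gradient.

    Operates on full matrices; ``Phi_off`` must have zero diagonal blocks and
    ``phidiag`` holds the diagonals of the within-variable blocks.
    """
    n = X.shape[0]
    p = X.shape[1]
    q = Yidx.shape[1]
    d = np.diag(beta).copy()
    if np.any(d <= 0):
        raise ValueError("nonpositive conditional variance: beta diagonal <= 0")

    persample = np.zeros(n) if per_sample else None
    if p:
        B_off = beta - np.diag(d)
        Mnum = alpha[None, :] + D @ R.T - X @ B_off if q else alpha[None, :] - X @ B_off
        mu = Mnum / d[None, :]
        E = X - mu
        sq = E * E
        val_cont = n * 0.5 * float(np.sum(np.log(2 * np.pi / d)))
        val_cont += 0.5 * float((d[None, :] * sq).sum())
        if per_sample:
            persample += 0.5 * (d[None, :] * sq).sum(axis=1)
            persample += 0.5 * np.sum(np.log(2 * np.pi / d))
    else:
        E = np.zeros((n, 0))
        mu = E
        val_cont = 0.0

    val_cat = 0.0
    G = np.empty((n, Phi_off.shape[0])) if (q and want_grad) else None
    if q:
        logits = (X @ R if p else 0.0) + (D @ Phi_off) + phidiag[None, :]
        rows = np.arange(n)
        for r in range(q):
            sl = slice(offs[r], offs[r + 1])
            Lg = logits[:, sl]
            m = Lg.max(axis=1)
            ex = np.exp(Lg - m[:, None])
            Z = ex.sum(axis=1)
            lse = m + np.log(Z)
            obs = Lg[rows, Yidx[:, r]]
            val_cat += float((lse - obs).sum())
            if per_sample:
                persample += lse - obs
            if want_grad:
                P = ex / Z[:, None]
                P[rows, Yidx[:, r]] -= 1.0
                G[:, sl] = P

    value = val_cont + val_cat
    if not want_grad:
        return (value, persample) if per_sample else value

    grads = {}
    if p:
        A = E.T @ X
        grads["boff_u"] = A + A.T  # u-space gradient of strict-upper beta
        grads["bdiag"] = 0.5 * np.sum(X * X, axis=0) - 0.5 * np.sum(mu * mu, axis=0) \
            - n / (2.0 * d)
        grads["alpha"] = -E.sum(axis=0)
    if q:
        gR = (X.T @ G) if p else np.zeros((0, Phi_off.shape[0]))
        if p:
            gR = gR - E.T @ D
        grads["rho"] = gR
        M = D.T @ G
        grads["phi_sym2"] = M + M.T  # gather upper blocks for u-gradient
        grads["phidiag"] = G.sum(axis=0)
    return value, grads


def negative_log_pseudolikelihood(params: MGMParameters, data: MixedDataset,
                                  per_sample: bool = False):
    """Negative log-pseudolikelihood of ``data`` under ``params``.

    Summed over samples; set ``per_sample=True`` for the ``(n,)`` vector of
    per-sample contributions.  If the parameters carry a standardizer the
    continuous columns are transformed first and the log-Jacobian of the
    transform is included, so values remain comparable across models fit with
    different scalings.
    """
    if params.p != data.p or params.q != data.q or params.levels != data.levels:
        raise ValueError("parameter/data dimension mismatch")
    layout = _layout_for(params.p, params.levels)
    X, jac = _apply_standardizer(params, data)
    D = data.indicator()
    Phi_off = params.phi.copy()
    offs = layout.offs
    for r in range(params.q):
        Phi_off[offs[r]:offs[r + 1], offs[r]:offs[r + 1]] = 0.0
    phidiag = params.phi.ravel()[layout.phi_diag_idx].copy()
    out = _nlpl_arrays(params.beta, params.alpha, params.rho, Phi_off, phidiag,
                       X, D, data.Y, offs, want_grad=False, per_sample=per_sample)
    if per_sample:
        value, vec = out
        return vec + jac / max(data.n, 1)
    return out + jac


def penalty_value(params: MGMParameters, penalties: PenaltyWeights) -> float:
    """Edge-type penalty: counts each symmetric pair once, never the
    beta diagonal or within-variable phi blocks."""
    layout = _layout_for(params.p, params.levels)
    v = layout.pack(params)
    val = penalties.lambda_cc * float(np.abs(v[layout.s_boff]).sum())
    val += penalties.lambda_cd * float(layout.rho_group_norms(v[layout.s_rho]).sum())
    val += penalties.lambda_dd * float(layout.phi_group_norms(v[layout.s_phioff]).sum())
    return val


# ---------------------------------------------------------------------------
# proximal operator and fit
# ---------------------------------------------------------------------------


def _prox_vec(v: np.ndarray, step: float, pw: PenaltyWeights, layout: _Layout) -> np.ndarray:
    out = v.copy()
    b = out[layout.s_boff]
    t = step * pw.lambda_cc
    out[layout.s_boff] = np.sign(b) * np.maximum(np.abs(b) - t, 0.0)
    out[layout.s_bdiag] = np.maximum(out[layout.s_bdiag], _BETA_DIAG_FLOOR)
    if layout.q:
        norms = layout.rho_group_norms(out[layout.s_rho])
        t = step * pw.lambda_cd
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(norms > t, 1.0 - t / np.where(norms > 0, norms, 1.0), 0.0)
        out[layout.s_rho] = (out[layout.s_rho].reshape(layout.p, layout.Q)
                             * np.repeat(scale, layout.levels, axis=1)).ravel()
    if len(layout.pairs):
        norms = layout.phi_group_norms(out[layout.s_phioff])
        t = step * pw.lambda_dd
        scale = np.where(norms > t, 1.0 - t / np.where(norms > 0, norms, 1.0), 0.0)
        out[layout.s_phioff] = out[layout.s_phioff] * np.repeat(scale, layout.phi_sizes)
    return out


def proximal_step(params: MGMParameters, gradient: MGMParameters, step: float,
                  penalties: PenaltyWeights) -> MGMParameters:
    """One proximal-gradient update of the penalized objective.

    Takes a gradient step, soft-thresholds off-diagonal beta entries at
    ``step*lambda_cc``, group-thresholds rho vectors at ``step*lambda_cd`` and
    off-diagonal phi blocks at ``step*lambda_dd`` (a group whose post-gradient
    norm falls inside its threshold becomes exactly zero), restores symmetry,
    and re-projects the penalized groups onto their sum-to-zero subspaces.
    The beta diagonal, alpha, and within-variable phi blocks are unpenalized.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    layout = _layout_for(params.p, params.levels)
    v = layout.pack(params) - step * layout.pack(gradient)
    v = _prox_vec(v, step, penalties, layout)
    v[layout.s_rho] = layout.center_rho(v[layout.s_rho])
    v[layout.s_phioff] = layout.center_phi(v[layout.s_phioff])
    return layout.to_params(v, x_mean=params.x_mean, x_sd=params.x_sd)


def _grad_to_vec(grads: dict, layout: _Layout, n: int) -> np.ndarray:
    g = np.zeros(layout.size)
    if layout.p:
        g[layout.s_bdiag] = grads["bdiag"] / n
        g[layout.s_boff] = grads["boff_u"][layout.tr, layout.tc] / n
        g[layout.s_alpha] = grads["alpha"] / n
    if layout.q:
        g[layout.s_rho] = grads["rho"].ravel() / n
        if layout.phi_up_idx.size:
            g[layout.s_phioff] = grads["phi_sym2"].ravel()[layout.phi_up_idx] / n
        g[layout.s_phidiag] = grads["phidiag"] / n
    # project onto the sum-to-zero subspace so proximal iterates stay centered
    g[layout.s_rho] = layout.center_rho(g[layout.s_rho])
    g[layout.s_phioff] = layout.center_phi(g[layout.s_phioff])
    return g


def fit_mgm(data: MixedDataset, penalties: PenaltyWeights,
            config: Optional[FitConfig] = None,
            init: Optional[MGMParameters] = None) -> MGMParameters:
    """Fit a sparse MGM by accelerated proximal gradient (FISTA).

    Minimizes ``negative_log_pseudolikelihood / n + penalty_value`` with
    backtracking line search; a monotone restart drops the momentum whenever
    acceleration would increase the objective, so the reported per-iterate
    objective sequence is non-increasing.  Continuous columns are standardized
    first by default and the parameters are reported on that scale (recorded
    in ``x_mean`` / ``x_sd``).
    """
    global _FIT_CALLS
    if config is None:
        config = FitConfig()
    if data.n < 2:
        raise ValueError("need at least 2 samples to fit")
    layout = _layout_for(data.p, data.levels)

    if config.standardize and data.p:
        x_mean = data.X.mean(axis=0)
        x_sd = data.X.std(axis=0)
        x_sd = np.where(x_sd > 1e-12, x_sd, 1.0)
        X = (data.X - x_mean) / x_sd
    else:
        x_mean = x_sd = None
        X = data.X
    D = data.indicator()
    n = data.n
    offs = layout.offs

    for j in range(data.q):
        counts = D[:, offs[j]:offs[j + 1]].sum(axis=0)
        if np.any(counts == 0):
            warnings.warn(
                f"categorical variable {data.cat_names[j]} has unobserved levels; "
                "they are kept but contribute no likelihood", RuntimeWarning)

    if init is not None:
        x0 = layout.pack(init)
        x0[layout.s_bdiag] = np.maximum(x0[layout.s_bdiag], _BETA_DIAG_FLOOR)
        x0[layout.s_rho] = layout.center_rho(x0[layout.s_rho])
        x0[layout.s_phioff] = layout.center_phi(x0[layout.s_phioff])
    else:
        x0 = np.zeros(layout.size)
        x0[layout.s_bdiag] = 1.0

    def smooth(v, want_grad=True):
        beta, alpha, R, Phi_off, phidiag = layout.unpack(v)
        out = _nlpl_arrays(beta, alpha, R, Phi_off, phidiag, X, D, data.Y, offs,
                           want_grad=want_grad)
        if want_grad:
            val, grads = out
            return val / n, _grad_to_vec(grads, layout, n)
        return out / n

    def pen(v):
        return (penalties.lambda_cc * float(np.abs(v[layout.s_boff]).sum())
                + penalties.lambda_cd * float(layout.rho_group_norms(v[layout.s_rho]).sum())
                + penalties.lambda_dd * float(layout.phi_group_norms(v[layout.s_phioff]).sum()))

    def backtracked_step(point, g_val, grad, step):
        while True:
            w = _prox_vec(point - step * grad, step, penalties, layout)
            delta = w - point
            g_w = smooth(w, want_grad=False)
            if not np.isfinite(g_w):
                step *= config.backtrack
                if step < 1e-16:
                    raise FitDivergenceError("objective became non-finite during line search")
                continue
            bound = g_val + float(grad @ delta) + float(delta @ delta) / (2.0 * step)
            if g_w <= bound + 1e-12:
                return w, g_w, step
            step *= config.backtrack
            if step < 1e-16:
                return point, g_val, step

    x = x0
    g_x, grad_x = smooth(x)
    F_x = g_x + pen(x)
    if not np.isfinite(F_x):
        raise FitDivergenceError("objective non-finite at initialization")
    z = x.copy()
    z_is_x = True
    t = 1.0
    step = config.step0
    status = "max_iter"
    it = 0
    def ensure_grad_x():
        nonlocal g_x, grad_x
        if grad_x is None:
            g_x, grad_x = smooth(x)

    for it in range(1, config.max_iter + 1):
        if z_is_x:
            ensure_grad_x()
            g_z, grad_z = g_x, grad_x
        else:
            g_z, grad_z = smooth(z)
            if not np.isfinite(g_z):
                # momentum flung the iterate into a bad region: restart
                ensure_grad_x()
                z, g_z, grad_z, t = x.copy(), g_x, grad_x, 1.0
        w, g_w, step = backtracked_step(z, g_z, grad_z, step)
        F_w = g_w + pen(w)
        if F_w > F_x + 1e-12 and config.accelerate and not z_is_x:
            # monotone restart: plain proximal step from the current iterate
            t = 1.0
            ensure_grad_x()
            w, g_w, step = backtracked_step(x, g_x, grad_x, step)
            F_w = g_w + pen(w)
        if not np.isfinite(F_w):
            raise FitDivergenceError(f"objective non-finite at iteration {it}")
        if F_w > F_x + 1e-12:
            status = "stalled"
            break
        rel = abs(F_x - F_w) / max(1.0, abs(F_x))
        if config.accelerate:
            t_new = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * t * t))
            z = w + ((t - 1.0) / t_new) * (w - x)
            t = t_new
            z_is_x = False
        else:
            z = w.copy()
            z_is_x = True
        x, F_x, g_x, grad_x = w, F_w, g_w, None
        if rel < config.tol:
            status = "converged"
            break
        if it % 10 == 0:
            step /= config.backtrack  # occasionally let the step grow back

    _FIT_CALLS += 1
    return layout.to_params(
        x, x_mean=x_mean, x_sd=x_sd,
        fit_info={"iterations": it, "status": status, "objective": float(F_x),
                  "penalties": penalties.astuple()})


# ---------------------------------------------------------------------------
# graph extraction
# ---------------------------------------------------------------------------


def adjacency_from_parameters(params: MGMParameters, threshold: float = 0.0) -> np.ndarray:
    """Binary ``(p+q, p+q)`` adjacency: an edge is present when any parameter
    of its block exceeds ``threshold`` in absolute value (default: non-zero).
    Node order is continuous variables first, then categorical."""
    p, q = params.p, params.q
    P = p + q
    A = np.zeros((P, P), dtype=bool)
    if p:
        cc = np.abs(params.beta) > threshold
        np.fill_diagonal(cc, False)
        A[:p, :p] = cc
    offs = params.offsets
    if p and q:
        absr = np.abs(params.rho)
        cd = np.vstack([
            absr[:, offs[j]:offs[j + 1]].max(axis=1) for j in range(q)
        ]).T > threshold
        A[:p, p:] = cd
        A[p:, :p] = cd.T
    if q > 1:
        for r in range(q):
            for j in range(r + 1, q):
                present = np.abs(params.phi_block(r, j)).max() > threshold
                A[p + r, p + j] = A[p + j, p + r] = present
    return A


def edge_type_masks(p: int, q: int) -> dict:
    """Boolean ``(p+q, p+q)`` masks selecting the unordered-pair positions of
    each edge type (upper triangle only)."""
    P = p + q
    upper = np.triu(np.ones((P, P), dtype=bool), k=1)
    is_cont = np.zeros(P, dtype=bool)
    is_cont[:p] = True
    cc = upper & is_cont[:, None] & is_cont[None, :]
    dd = upper & ~is_cont[:, None] & ~is_cont[None, :]
    cd = upper & (is_cont[:, None] ^ is_cont[None, :])
    return {"all": upper, "cc": cc, "cd": cd, "dd": dd}


def degrees_of_freedom(params: MGMParameters) -> int:
    """Model degrees of freedom: 1 per cc edge, ``L_j - 1`` per cd edge and
    ``(L_r - 1)(L_j - 1)`` per dd edge present at threshold 0."""
    A = adjacency_from_parameters(params, 0.0)
    p, q = params.p, params.q
    L = np.asarray(params.levels, dtype=int)
    dof = int(np.triu(A[:p, :p], 1).sum())
    if p and q:
        dof += int((A[:p, p:].sum(axis=0) * (L - 1)).sum())
    for r in range(q):
        for j in range(r + 1, q):
            if A[p + r, p + j]:
                dof += int((L[r] - 1) * (L[j] - 1))
    return dof
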