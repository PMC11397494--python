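"""Two-state (conserved / nonconserved) phylogenetic HMM over alignment columns.

The parameterisation follows the phastCons convention: the user supplies the
expected conserved-segment length ``omega`` (in columns) and the target
coverage ``gamma``; the switch probabilities are then forced to
``mu = 1/omega`` (conserved -> nonconserved) and ``nu = mu*gamma/(1-gamma)``,
which makes the stationary probability of the conserved state exactly
``gamma``.  Emissions are pruning likelihoods with every branch scaled by
``rho`` (conserved state) or unscaled (nonconserved state).  Segments are
maximal conserved runs on the Viterbi path, with backtracking ties resolved
toward the nonconserved state so that calls are conservative and
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .likelihood import TreeLikelihood
from .substitution import HKYModel
from .trees import Phylogeny

__all__ = [
    "HmmParams",
    "ConservedSegment",
    "derive_transitions",
    "emission_logliks",
    "forward_loglik",
    "forward_backward",
    "viterbi_path",
    "viterbi_segments",
    "estimate_rho",
]

CONSERVED, NONCONSERVED = 0, 1


def derive_transitions(omega: float, gamma: float) -> tuple[float, float]:
    """Switch probabilities (mu, nu) from expected length and target coverage."""
    if not omega > 1:
        raise ValueError("expected conserved length omega must exceed 1 column")
    if not 0 < gamma < 1:
        raise ValueError("target coverage gamma must lie in (0, 1)")
    mu = 1.0 / omega
    nu = mu * gamma / (1.0 - gamma)
    if not 0 < nu < 1:
        raise ValueError(f"derived nu={nu} outside (0,1); omega/gamma incompatible")
    return mu, nu


@dataclass(frozen=True)
class HmmParams:
    """phastCons-style parameters: expected length, coverage, conserved scale."""

    omega: float = 12.0
    gamma: float = 0.3
    rho: float = 0.3

    def __post_init__(self):
        derive_transitions(self.omega, self.gamma)
        if not 0 < self.rho <= 1:
            raise ValueError("rho must lie in (0, 1]")

    @property
    def mu(self) -> float:
        return derive_transitions(self.omega, self.gamma)[0]

    @property
    def nu(self) -> float:
        return derive_transitions(self.omega, self.gamma)[1]


@dataclass(frozen=True)
class ConservedSegment:
    """A conserved run in reference coordinates (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    mean_posterior: float
    score: float  # summed conserved-minus-nonconserved emission log-odds

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")


def emission_logliks(
    data: dict, tree: Phylogeny, model: HKYModel, rho: float
) -> np.ndarray:
    """(L, 2) emission log-likelihoods: column 0 conserved, column 1 nonconserved."""
    if not 0 < rho <= 1:
        raise ValueError("rho must lie in (0, 1]")
    engine = TreeLikelihood(tree, model)
    noncons = engine.column_logliks(data)
    cons = engine.column_logliks(data, np.full(tree.n_nodes, rho)) if rho != 1 else noncons
    return np.column_stack([cons, noncons])


def _log_transition(mu: float, nu: float) -> np.ndarray:
    return np.log(np.array([[1 - mu, mu], [nu, 1 - nu]]))


def _log_initial(mu: float, nu: float) -> np.ndarray:
    gamma = nu / (mu + nu)
    return np.log(np.array([gamma, 1 - gamma]))


def forward_loglik(emissions: np.ndarray, mu: float, nu: float) -> float:
    """Total log-likelihood of the column sequence under the two-state chain."""
    em = np.asarray(emissions, dtype=float)
    if em.ndim != 2 or em.shape[1] != 2 or em.shape[0] < 1:
        raise ValueError("emissions must be a non-empty (L, 2) array")
    logt = _log_transition(mu, nu)
    alpha = _log_initial(mu, nu) + em[0]
    for i in range(1, len(em)):
        alpha = logsumexp(alpha[:, None] + logt, axis=0) + em[i]
    return float(logsumexp(alpha))


def forward_backward(emissions: np.ndarray, mu: float, nu: float):
    """Posterior state probabilities per column and the total log-likelihood."""
    em = np.asarray(emissions, dtype=float)
    L = len(em)
    logt = _log_transition(mu, nu)
    alpha = np.empty((L, 2))
    alpha[0] = _log_initial(mu, nu) + em[0]
    for i in range(1, L):
        alpha[i] = logsumexp(alpha[i - 1][:, None] + logt, axis=0) + em[i]
    beta = np.zeros((L, 2))
    for i in range(L - 2, -1, -1):
        beta[i] = logsumexp(logt + (em[i + 1] + beta[i + 1])[None, :], axis=1)
    total = logsumexp(alpha[-1])
    post = np.exp(alpha + beta - total)
    post /= post.sum(axis=1, keepdims=True)
    return post, float(total)


def viterbi_path(emissions: np.ndarray, mu: float, nu: float) -> np.ndarray:
    """Most probable state path; ties broken toward the nonconserved state."""
    em = np.asarray(emissions, dtype=float)
    L = len(em)
    if L < 1:
        raise ValueError("need at least one column")
    logt = _log_transition(mu, nu)
    delta = _log_initial(mu, nu) + em[0]
    ptr = np.empty((L, 2), dtype=np.int8)
    for i in range(1, L):
        cand = delta[:, None] + logt  # cand[prev, cur]
        # strict > keeps the nonconserved predecessor on ties
        choose_cons = cand[CONSERVED] > cand[NONCONSERVED]
        ptr[i] = np.where(choose_cons, CONSERVED, NONCONSERVED)
        delta = np.where(choose_cons, cand[CONSERVED], cand[NONCONSERVED]) + em[i]
    state = CONSERVED if delta[CONSERVED] > delta[NONCONSERVED] else NONCONSERVED
    path = np.empty(L, dtype=np.int8)
    path[-1] = state
    for i in range(L - 1, 0, -1):
        state = ptr[i, state]
        path[i - 1] = state
    return path


def viterbi_segments(
    emissions: np.ndarray,
    mu: float,
    nu: float,
    coord_map: np.ndarray,
    chrom: str = "chr",
) -> list[ConservedSegment]:
    """Conserved segments from the Viterbi path, mapped to reference coordinates.

    ``coord_map`` gives the reference position of each column, with -1 for
    columns where the reference has a gap; a segment spans the reference
    positions its run covers.
    """
    em = np.asarray(emissions, dtype=float)
    path = viterbi_path(em, mu, nu)
    post, _ = forward_backward(em, mu, nu)
    coord = np.asarray(coord_map)
    segments = []
    i = 0
    L = len(path)
    while i < L:
        if path[i] != CONSERVED:
            i += 1
            continue
        j = i
        while j < L and path[j] == CONSERVED:
            j += 1
        pos = coord[i:j]
        pos = pos[pos >= 0]
        if len(pos):
            segments.append(
                ConservedSegment(
                    chrom=chrom,
                    start=int(pos.min()),
                    end=int(pos.max()) + 1,
                    mean_posterior=float(post[i:j, CONSERVED].mean()),
                    score=float((em[i:j, CONSERVED] - em[i:j, NONCONSERVED]).sum()),
                )
            )
        i = j
    return segments


def estimate_rho(
    blocks: list[dict],
    tree: Phylogeny,
    model: HKYModel,
    mu: float,
    nu: float,
    grid=None,
    xatol: float = 1e-3,
) -> float:
    """Maximum-likelihood conserved-state scale over a grid refined by
    bounded scalar optimisation; deterministic given inputs."""
    if not blocks:
        raise ValueError("need at least one alignment block")
    engine = TreeLikelihood(tree, model)
    noncons = [engine.column_logliks(b) for b in blocks]
    if all(not np.isfinite(nc).any() or np.allclose(nc, 0.0) for nc in noncons):
        raise ValueError("cannot estimate rho from entirely missing data")

    def total(rho: float) -> float:
        out = 0.0
        for b, nc in zip(blocks, noncons):
            cons = engine.column_logliks(b, np.full(tree.n_nodes, rho))
            out += forward_loglik(np.column_stack([cons, nc]), mu, nu)
        return out

    if grid is None:
        grid = np.geomspace(0.02, 1.0, 12)
    grid = np.asarray(grid, dtype=float)
    if len(grid) == 1:
        return float(grid[0])
    vals = np.array([total(r) for r in grid])
    i = int(vals.argmax())
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(lambda r: -total(r), bounds=(lo, hi), method="bounded",
                          options={"xatol": xatol})
    if -res.fun > vals[i]:
        return float(res.x)
    return float(grid[i])
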