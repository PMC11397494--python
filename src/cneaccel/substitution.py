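"""HKY85 nucleotide substitution model.

The rate matrix distinguishes transitions (A<->G, C<->T) from transversions by
the ratio ``kappa`` and is normalised so one time unit equals one expected
substitution per site at stationarity.  Transition-probability matrices are
computed from the spectral decomposition of the similarity-transformed
(symmetric) rate matrix, which is exact for any reversible model and avoids a
hand-derived closed form.
"""

from __future__ import annotations

import numpy as np

__all__ = ["HKYModel", "BASES", "transition_matrix"]

BASES = "ACGT"
_TRANSITION_PAIRS = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T


class HKYModel:
    """HKY85 model with base frequencies ``pi`` (A,C,G,T order) and ``kappa``."""

    def __init__(self, freqs, kappa: float = 2.0):
        freqs = np.asarray(freqs, dtype=float)
        if freqs.shape != (4,):
            raise ValueError("freqs must have four entries (A,C,G,T)")
        if np.any(freqs <= 0):
            raise ValueError("all base frequencies must be > 0")
        if abs(freqs.sum() - 1.0) > 1e-8:
            raise ValueError("base frequencies must sum to 1")
        if not np.isfinite(kappa) or kappa <= 0:
            raise ValueError("kappa must be a positive real")
        self.freqs = freqs / freqs.sum()
        self.kappa = float(kappa)
        self.Q = self._rate_matrix()
        self._decompose()

    def _rate_matrix(self) -> np.ndarray:
        q = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                rate = self.freqs[j]
                if (i, j) in _TRANSITION_PAIRS:
                    rate *= self.kappa
                q[i, j] = rate
        np.fill_diagonal(q, -q.sum(axis=1))
        # normalise: expected rate at stationarity = -sum_i pi_i q_ii = 1
        mu = -np.dot(self.freqs, np.diag(q))
        return q / mu

    def _decompose(self) -> None:
        # pi^{1/2} Q pi^{-1/2} is symmetric for a reversible model
        sq = np.sqrt(self.freqs)
        sym = self.Q * sq[:, None] / sq[None, :]
        w, v = np.linalg.eigh((sym + sym.T) / 2.0)
        self._eigvals = w
        self._left = v / sq[:, None]       # pi^{-1/2} V
        self._right = v.T * sq[None, :]    # V^T pi^{1/2}

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows index the ancestral base, columns the descendant."""
        if not np.isfinite(t) or t < 0:
            raise ValueError(f"branch length must be finite and >= 0, got {t}")
        p = (self._left * np.exp(self._eigvals * t)) @ self._right
        np.clip(p, 0.0, 1.0, out=p)
        return p

    # -- convenience ---------------------------------------------------------
    @classmethod
    def jc69(cls) -> "HKYModel":
        """Jukes-Cantor special case: equal frequencies, kappa = 1."""
        return cls(np.full(4, 0.25), kappa=1.0)

    def to_dict(self) -> dict:
        return {"freqs": [float(x) for x in self.freqs], "kappa": self.kappa}

    @classmethod
    def from_dict(cls, d: dict) -> "HKYModel":
        return cls(np.asarray(d["freqs"], dtype=float), float(d.get("kappa", 2.0)))

    def __repr__(self) -> str:
        f = ", ".join(f"{x:.4f}" for x in self.freqs)
        return f"HKYModel(freqs=[{f}], kappa={self.kappa:.4f})"


def transition_matrix(model: HKYModel, t: float) -> np.ndarray:
    """Functional alias for :meth:`HKYModel.transition_matrix`."""
    return model.transition_matrix(t)
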