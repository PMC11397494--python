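"""Column log-likelihoods on a phylogeny via Felsenstein pruning.

All computation is vectorised across alignment columns: leaf observations are
encoded as small integers (A=0, C=1, G=2, T=3, missing=4, where ``N`` and gaps
are missing and marginalised with a partial vector of ones).  Per-node scaling
of partial likelihoods with accumulated log-scalers keeps long elements exact
in log space.
"""

from __future__ import annotations

import numpy as np

from .substitution import HKYModel
from .trees import Phylogeny

__all__ = [
    "MISSING",
    "encode_sequence",
    "TreeLikelihood",
    "column_loglik",
    "alignment_loglik",
    "fit_neutral_model",
]

MISSING = 4

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
for _b in "Nn-.?":
    _CODE[ord(_b)] = MISSING

# leaf partial vectors by code: identity rows, plus all-ones for missing
_LEAF_PARTIALS = np.vstack([np.eye(4), np.ones(4)])


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes; unknown symbols are an error."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if np.any(arr == 255):
        bad = sorted({seq[i] for i in np.nonzero(arr == 255)[0]})
        raise ValueError(f"unknown alignment symbols: {bad}")
    return arr


class TreeLikelihood:
    """Pruning engine bound to one tree and one substitution model.

    Leaf data are supplied as ``{species: uint8 code array}``; species missing
    from the mapping are treated as entirely unobserved.
    """

    def __init__(self, tree: Phylogeny, model: HKYModel):
        self.tree = tree
        self.model = model
        self._leafset = set(tree.leaf_labels())

    def _leaf_codes(self, data: dict, length: int) -> dict[int, np.ndarray]:
        unknown = set(data) - self._leafset
        if unknown:
            raise ValueError(f"species not in tree: {sorted(unknown)}")
        out = {}
        for node in self.tree.leaf_nodes():
            codes = data.get(self.tree.names[node])
            if codes is None:
                codes = np.full(length, MISSING, dtype=np.uint8)
            elif len(codes) != length:
                raise ValueError("all leaf sequences must have equal length")
            out[node] = codes
        return out

    def column_logliks(self, data: dict, scales=None) -> np.ndarray:
        """Per-column log-likelihood array.

        Parameters
        ----------
        data : mapping species -> uint8 codes (equal lengths)
        scales : per-branch multipliers; a ``{name: factor}`` map, a per-node
            array, or None for all ones.
        """
        lengths = {len(v) for v in data.values()}
        if len(lengths) > 1:
            raise ValueError("all leaf sequences must have equal length")
        ncol = lengths.pop() if lengths else 0
        if ncol == 0:
            raise ValueError("empty alignment block")
        tree = self.tree
        if scales is None:
            scale_arr = np.ones(tree.n_nodes)
        elif isinstance(scales, dict):
            scale_arr = tree.scale_array(scales)
        else:
            scale_arr = np.asarray(scales, dtype=float)
        leaf_codes = self._leaf_codes(data, ncol)

        partials: dict[int, np.ndarray] = {}
        logscale = np.zeros(ncol)
        for node in tree.postorder:
            node = int(node)
            if tree.is_leaf(node):
                partials[node] = _LEAF_PARTIALS[leaf_codes[node]]
                continue
            prod = np.ones((ncol, 4))
            for child in tree.children[node]:
                p = self.model.transition_matrix(
                    float(tree.lengths[child]) * float(scale_arr[child])
                )
                prod *= partials.pop(child) @ p.T
            mx = prod.max(axis=1)
            safe = np.where(mx > 0, mx, 1.0)
            prod /= safe[:, None]
            with np.errstate(divide="ignore"):
                logscale += np.where(mx > 0, np.log(safe), -np.inf)
            partials[node] = prod
        root_like = partials[tree.root] @ self.model.freqs
        with np.errstate(divide="ignore"):
            out = np.log(root_like) + logscale
        # all-missing columns marginalise to probability 1: pin to exactly 0
        all_missing = np.ones(ncol, dtype=bool)
        for codes in leaf_codes.values():
            all_missing &= codes == MISSING
        out[all_missing] = 0.0
        return out

    def loglik(self, data: dict, scales=None) -> float:
        return float(self.column_logliks(data, scales).sum())


def column_loglik(tree: Phylogeny, model: HKYModel, column: dict, scales=None) -> float:
    """Log-probability of a single alignment column (``{species: symbol}``)."""
    data = {sp: encode_sequence(sym) for sp, sym in column.items()}
    return float(TreeLikelihood(tree, model).column_logliks(data, scales)[0])


def alignment_loglik(tree: Phylogeny, model: HKYModel, data: dict, scales=None) -> float:
    """Sum of per-column log-likelihoods over a reference-anchored block."""
    return TreeLikelihood(tree, model).loglik(data, scales)


def fit_neutral_model(
    tree: Phylogeny,
    data: dict,
    kappa_grid=(0.5, 1.0, 2.0, 4.0, 8.0, 16.0),
) -> HKYModel:
    """Fit the neutral HKY model from presumed-neutral alignment columns.

    Base frequencies are empirical over all non-missing symbols (with a +1
    pseudocount); kappa maximises the pruning likelihood over a coarse grid
    refined by bounded scalar minimisation.
    """
    from scipy.optimize import minimize_scalar

    counts = np.ones(4)
    for codes in data.values():
        counts += np.bincount(codes[codes < 4], minlength=4)
    freqs = counts / counts.sum()

    def negll(kappa: float) -> float:
        return -TreeLikelihood(tree, HKYModel(freqs, kappa)).loglik(data)

    grid = np.asarray(kappa_grid, dtype=float)
    vals = np.array([negll(k) for k in grid])
    i = int(vals.argmin())
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi > lo:
        res = minimize_scalar(negll, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-3})
        kappa = float(res.x) if res.fun < vals[i] else float(grid[i])
    else:
        kappa = float(grid[i])
    return HKYModel(freqs, kappa)
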