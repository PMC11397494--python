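"""Branch-targeted likelihood-ratio tests for accelerated element evolution.

For each element the null model fits one global branch-scale ``r`` (absorbing
element-wide rate variation, lambda fixed at 1); the alternative additionally
fits one shared scale ``lambda >= 1`` applied multiplicatively to every target
branch — jointly to the three hermaphrodite terminals, or to a single terminal
per species.  Because lambda is tested at its boundary, the LRT statistic is
referred to the one-sided mixture ``0.5*chi2_0 + 0.5*chi2_1``.  Optimisation
is a coarse geometric grid refined by bounded scalar minimisation with no
randomness, so results are fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .likelihood import TreeLikelihood
from .substitution import HKYModel
from .trees import Phylogeny

__all__ = [
    "TargetSpec",
    "AccelResult",
    "AccelerationTest",
    "lrt_pvalue",
    "call_ha_cnes",
    "per_species_accel",
    "convergent_orthogroups",
]

logger = logging.getLogger(__name__)

JOINT = "joint_shared_scale"
SINGLE = "single_branch"


@dataclass(frozen=True)
class TargetSpec:
    """Branches under test, each named by the node below it."""

    branches: frozenset
    mode: str = JOINT

    def __post_init__(self):
        if not self.branches:
            raise ValueError("target branch set must be non-empty")
        if self.mode not in (JOINT, SINGLE):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == SINGLE and len(self.branches) != 1:
            raise ValueError("single_branch mode takes exactly one branch")


@dataclass(frozen=True)
class AccelResult:
    cne_id: str
    target: TargetSpec
    lnl0: float
    lnl1: float
    r_hat: float
    lam_hat: float
    stat: float
    p: float
    q: float = np.nan


def lrt_pvalue(stat: float, lam_hat: float) -> float:
    """One-sided boundary-corrected p-value for the acceleration LRT."""
    if stat < 0:
        if stat < -1e-8:
            raise ValueError("LRT statistic must be non-negative")
        stat = 0.0
    if lam_hat <= 1.0 or stat == 0.0:
        return 1.0
    return float(0.5 * chi2.sf(stat, df=1))


def _refine(f, grid: np.ndarray, xatol: float):
    """Maximise ``f`` over a grid, then golden-section inside the bracket."""
    vals = np.array([f(x) for x in grid])
    i = int(vals.argmax())
    best_x, best_v = float(grid[i]), float(vals[i])
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    if hi > lo:
        res = minimize_scalar(lambda x: -f(x), bounds=(lo, hi), method="bounded",
                              options={"xatol": xatol})
        if -res.fun > best_v:
            best_x, best_v = float(res.x), float(-res.fun)
    return best_x, best_v


class AccelerationTest:
    """LRT machinery bound to one tree and neutral model."""

    def __init__(
        self,
        tree: Phylogeny,
        model: HKYModel,
        r_bounds: tuple[float, float] = (1e-3, 10.0),
        lam_max: float = 100.0,
        xatol: float = 1e-4,
        n_rounds: int = 3,
    ):
        self.tree = tree
        self.engine = TreeLikelihood(tree, model)
        self.r_bounds = r_bounds
        self.lam_max = lam_max
        self.xatol = xatol
        self.n_rounds = n_rounds
        self._r_grid = np.geomspace(r_bounds[0], r_bounds[1], 13)
        self._lam_grid = np.geomspace(1.0, lam_max, 9)

    def _scales(self, r: float, lam: float, target_nodes: np.ndarray) -> np.ndarray:
        arr = np.full(self.tree.n_nodes, r)
        arr[target_nodes] *= lam
        return arr

    def _target_nodes(self, targets: TargetSpec) -> np.ndarray:
        return np.array([self.tree.node_by_name(b) for b in sorted(targets.branches)])

    def fit_null(self, data: dict) -> tuple[float, float]:
        """(lnL0, r_hat): one free global scale, no target acceleration."""
        f = lambda r: self.engine.loglik(data, np.full(self.tree.n_nodes, r))
        r_hat, lnl0 = _refine(f, self._r_grid, self.xatol)
        return lnl0, r_hat

    def fit_acceleration(
        self, data: dict, targets: TargetSpec, null_fit: tuple[float, float] | None = None
    ) -> tuple[float, float, float]:
        """(lnL1, r_hat, lam_hat) by coordinate ascent over (r, lambda >= 1)."""
        if null_fit is None:
            null_fit = self.fit_null(data)
        lnl0, r0 = null_fit
        tnodes = self._target_nodes(targets)
        r, lam, lnl1 = r0, 1.0, lnl0
        for _ in range(self.n_rounds):
            lam, lnl1 = _refine(
                lambda l: self.engine.loglik(data, self._scales(r, l, tnodes)),
                self._lam_grid, self.xatol,
            )
            r, lnl1 = _refine(
                lambda rr: self.engine.loglik(data, self._scales(rr, lam, tnodes)),
                self._r_grid, self.xatol,
            )
        if lnl1 < lnl0:  # nested models: never report a worse alternative fit
            return lnl0, r0, 1.0
        return lnl1, r, lam

    def test_element(self, cne_id: str, data: dict, targets: TargetSpec) -> AccelResult:
        lnl0, r0 = self.fit_null(data)
        lnl1, r1, lam = self.fit_acceleration(data, targets, null_fit=(lnl0, r0))
        stat = max(0.0, 2.0 * (lnl1 - lnl0))
        return AccelResult(
            cne_id=cne_id,
            target=targets,
            lnl0=lnl0,
            lnl1=lnl1,
            r_hat=r1,
            lam_hat=lam,
            stat=stat,
            p=lrt_pvalue(stat, lam),
        )

    def run(self, elements: dict, targets: TargetSpec) -> list[AccelResult]:
        """Test every element and BH-adjust p-values within this run."""
        results = [self.test_element(cid, data, targets) for cid, data in elements.items()]
        if results:
            qs = multipletests([r.p for r in results], method="fdr_bh")[1]
            results = [replace(r, q=float(q)) for r, q in zip(results, qs)]
        return results


def call_ha_cnes(results: list[AccelResult], alpha: float = 0.05) -> set:
    """Element ids significant at BH q < alpha (joint-run results)."""
    if results and np.all(np.isnan([r.q for r in results])):
        qs = multipletests([r.p for r in results], method="fdr_bh")[1]
        results = [replace(r, q=float(q)) for r, q in zip(results, qs)]
    return {r.cne_id for r in results if r.q < alpha}


def per_species_accel(results_by_species: dict, alpha: float = 0.05):
    """Per-species accelerated sets plus the pairwise/triple intersection counts."""
    sets = {sp: call_ha_cnes(res, alpha) for sp, res in results_by_species.items()}
    species = sorted(sets)
    intersections = {}
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            intersections[(a, b)] = len(sets[a] & sets[b])
    if len(species) >= 3:
        intersections[tuple(species)] = len(
            set.intersection(*(sets[s] for s in species))
        )
    return sets, intersections


def convergent_orthogroups(
    accel_sets: dict,
    nearest_map: dict,
    orthogroup_map: dict,
) -> dict:
    """Orthogroups hit by *different* accelerated CNEs in >= 2 species.

    Parameters
    ----------
    accel_sets : species -> set of accelerated cne ids
    nearest_map : species -> {cne id: nearest gene id}
    orthogroup_map : gene id -> orthogroup id; genes absent from the map are
        treated as singleton groups (logged).

    Returns
    -------
    {orthogroup id: {species: set of contributing cne ids}} restricted to
    groups where two species contribute distinct CNEs.
    """
    contributions: dict[str, dict[str, set]] = {}
    for sp, cnes in accel_sets.items():
        for cid in cnes:
            gene = nearest_map.get(sp, {}).get(cid)
            if gene is None:
                continue
            og = orthogroup_map.get(gene)
            if og is None:
                og = f"singleton:{gene}"
                logger.info("gene %s missing from orthogroup map; singleton group", gene)
            contributions.setdefault(og, {}).setdefault(sp, set()).add(cid)
    out = {}
    for og, per_sp in contributions.items():
        species = sorted(per_sp)
        # require some pair of species contributing distinct CNEs
        qualifies = any(
            c1 != c2
            for i, a in enumerate(species)
            for b in species[i + 1:]
            for c1 in per_sp[a]
            for c2 in per_sp[b]
        )
        if len(species) >= 2 and qualifies:
            out[og] = per_sp
    return out
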