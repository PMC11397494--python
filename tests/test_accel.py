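import numpy as np
import pytest

from cneaccel.accel import (
    JOINT,
    SINGLE,
    AccelResult,
    AccelerationTest,
    TargetSpec,
    call_ha_cnes,
    convergent_orthogroups,
    lrt_pvalue,
    per_species_accel,
)
from cneaccel.pipeline import element_codes
from cneaccel.simulate import HERMAPHRODITE_BRANCHES, SimConfig, simulate_alignment


@pytest.fixture(scope="module")
def sim_elements():
    """Simulated conserved elements, 12 of 30 accelerated on C_elegans."""
    cfg = SimConfig(seed=51, chrom_length=8000, n_conserved=30, n_accelerated=12,
                    n_genes=0, element_length_range=(60, 60),
                    target_branches=("C_elegans",))
    sim = simulate_alignment(cfg)
    elements = {
        f"e{i}": element_codes(sim.block, iv) for i, iv in enumerate(sim.conserved_truth)
    }
    accel_ids = {
        f"e{i}"
        for i, iv in enumerate(sim.conserved_truth)
        if (iv.start, iv.end) in {(a.start, a.end) for a in sim.accelerated_truth}
    }
    return sim, elements, accel_ids


class TestLrtPvalue:
    def test_zero_statistic_gives_one(self):
        assert lrt_pvalue(0.0, 2.0) == 1.0
        assert lrt_pvalue(5.0, 1.0) == 1.0

    def test_halved_chi2_table_value(self):
        assert np.isclose(lrt_pvalue(2.706, 1.5), 0.05, atol=1e-3)
        from scipy.stats import chi2

        assert lrt_pvalue(3.3, 2.0) == 0.5 * chi2.sf(3.3, 1)

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            lrt_pvalue(-0.5, 2.0)


class TestTargetSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            TargetSpec(frozenset())
        with pytest.raises(ValueError):
            TargetSpec(frozenset({"a", "b"}), SINGLE)


class TestFits:
    def test_null_recovers_global_scale(self, eleven_taxon):
        cfg = SimConfig(seed=53, chrom_length=9000, n_conserved=10, n_accelerated=0,
                        n_genes=0, element_length_range=(200, 200), rho_conserved=0.5)
        sim = simulate_alignment(cfg)
        tester = AccelerationTest(sim.tree, sim.model)
        r_hats = []
        for iv in sim.conserved_truth[:10]:
            _, r_hat = tester.fit_null(element_codes(sim.block, iv))
            r_hats.append(r_hat)
        hits = sum(0.35 <= r <= 0.65 for r in r_hats)
        assert hits >= 9

    def test_invariant_column_drives_r_to_lower_bound(self, eleven_taxon, hky):
        tester = AccelerationTest(eleven_taxon, hky)
        data = {sp: np.zeros(5, dtype=np.uint8) for sp in eleven_taxon.leaf_labels()}
        _, r_hat = tester.fit_null(data)
        assert r_hat <= tester.r_bounds[0] * 1.5

    def test_nestedness(self, sim_elements):
        sim, elements, _ = sim_elements
        tester = AccelerationTest(sim.tree, sim.model)
        targets = TargetSpec(frozenset({"C_elegans"}), SINGLE)
        for data in list(elements.values())[:10]:
            lnl0, r0 = tester.fit_null(data)
            lnl1, _, lam = tester.fit_acceleration(data, targets, null_fit=(lnl0, r0))
            assert lnl1 >= lnl0 - 1e-8

    def test_joint_single_target_equals_single_mode(self, sim_elements):
        sim, elements, _ = sim_elements
        tester = AccelerationTest(sim.tree, sim.model)
        data = next(iter(elements.values()))
        r_joint = tester.test_element("x", data, TargetSpec(frozenset({"C_elegans"}), JOINT))
        r_single = tester.test_element("x", data, TargetSpec(frozenset({"C_elegans"}), SINGLE))
        assert r_joint.stat == r_single.stat and r_joint.p == r_single.p

    def test_planted_acceleration_detected(self, sim_elements):
        sim, elements, accel_ids = sim_elements
        tester = AccelerationTest(sim.tree, sim.model)
        results = tester.run(elements, TargetSpec(frozenset({"C_elegans"}), SINGLE))
        hits = {r.cne_id for r in results if r.q < 0.05}
        recall = len(hits & accel_ids) / len(accel_ids)
        fdr = len(hits - accel_ids) / max(1, len(hits))
        assert recall >= 0.8 and fdr <= 0.1
        by_id = {r.cne_id: r for r in results}
        assert all(by_id[i].lam_hat > 1 for i in hits)


class TestCalling:
    def _res(self, pvals):
        return [
            AccelResult(f"c{i}", TargetSpec(frozenset({"C_elegans"})), 0, 0, 1, 2, 1, p)
            for i, p in enumerate(pvals)
        ]

    def test_all_p_one_empty(self):
        assert call_ha_cnes(self._res([1.0] * 5)) == set()

    def test_bh_by_hand_ten_elements(self):
        from statsmodels.stats.multitest import multipletests

        ps = [0.001, 0.002, 0.004, 0.01, 0.03, 0.2, 0.4, 0.6, 0.8, 1.0]
        got = multipletests(ps, method="fdr_bh")[1]
        # hand step-up: q_i = min_{j>=i} p_j * n / j
        n = len(ps)
        hand = [min(ps[j] * n / (j + 1) for j in range(i, n)) for i in range(n)]
        assert np.allclose(got, hand)
        # q for p=0.03 at rank 5 is 0.06, so only the first four pass 0.05
        assert call_ha_cnes(self._res(ps)) == {"c0", "c1", "c2", "c3"}

    def test_per_species_sets_and_intersections(self):
        by_sp = {
            "C_elegans": self._res([0.001, 1, 1]),
            "C_briggsae": self._res([1, 0.001, 1]),
            "C_tropicalis": self._res([0.001, 0.001, 1]),
        }
        sets, inter = per_species_accel(by_sp)
        assert sets["C_elegans"] == {"c0"}
        assert inter[("C_briggsae", "C_elegans")] == 0
        assert inter[("C_elegans", "C_tropicalis")] == 1
        assert inter[("C_briggsae", "C_elegans", "C_tropicalis")] == 0
        union = set.union(*sets.values())
        assert all(s <= union for s in sets.values())


class TestConvergence:
    def test_different_cnes_same_orthogroup_reported(self):
        out = convergent_orthogroups(
            {"sp1": {"c1"}, "sp2": {"c2"}},
            {"sp1": {"c1": "geneA1"}, "sp2": {"c2": "geneA2"}},
            {"geneA1": "OG1", "geneA2": "OG1"},
        )
        assert set(out) == {"OG1"}

    def test_same_cne_in_both_species_excluded(self):
        out = convergent_orthogroups(
            {"sp1": {"c1"}, "sp2": {"c1"}},
            {"sp1": {"c1": "geneA1"}, "sp2": {"c1": "geneA2"}},
            {"geneA1": "OG1", "geneA2": "OG1"},
        )
        assert out == {}

    def test_planted_convergent_groups_exactly_recovered(self):
        rng = np.random.default_rng(13)
        orthomap = {}
        nearest = {"sp1": {}, "sp2": {}, "sp3": {}}
        accel = {"sp1": set(), "sp2": set(), "sp3": set()}
        planted = set()
        for g in range(20):
            og = f"OG{g:02d}"
            for sp in nearest:
                gene = f"{sp}_gene{g}"
                orthomap[gene] = og
            if g < 5:  # convergent: two species, different cnes
                planted.add(og)
                for sp in ("sp1", "sp2"):
                    cid = f"{sp}_cne{g}"
                    accel[sp].add(cid)
                    nearest[sp][cid] = f"{sp}_gene{g}"
            elif g < 10:  # hit in one species only
                cid = f"sp3_cne{g}"
                accel["sp3"].add(cid)
                nearest["sp3"][cid] = f"sp3_gene{g}"
        out = convergent_orthogroups(accel, nearest, orthomap)
        assert set(out) == planted

    def test_gene_missing_from_map_becomes_singleton(self):
        out = convergent_orthogroups(
            {"sp1": {"c1"}, "sp2": {"c2"}},
            {"sp1": {"c1": "gX"}, "sp2": {"c2": "gY"}},
            {},
        )
        assert out == {}  # two different singleton groups never pair
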