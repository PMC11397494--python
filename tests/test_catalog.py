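import numpy as np
import pytest
from scipy.stats import hypergeom

from cneaccel.catalog import (
    DROPPED_LENGTH_RATIO,
    DROPPED_REDUNDANT,
    KEPT,
    UNALIGNED,
    AnnotationSet,
    CneRecord,
    annotation_enrichment,
    filter_min_length,
    filter_species_cnes,
    nearest_gene,
    project_to_species,
    subtract_coding,
)
from cneaccel.intervals import GenomicInterval as GI
from cneaccel.io import AlignmentBlock, MafRow


def ann_with(ftype, triples):
    ann = AnnotationSet()
    for chrom, s, e, *rest in triples:
        ann.add(ftype, GI(chrom, s, e), rest[0] if rest else None)
    return ann


class TestSubtractCoding:
    def test_half_overlap_split(self):
        ann = ann_with("CDS", [("c", 120, 200)])
        out = subtract_coding([GI("c", 100, 140)], ann)
        assert out == [GI("c", 100, 120)]

    def test_fully_inside_removed(self):
        ann = ann_with("CDS", [("c", 50, 300)])
        assert subtract_coding([GI("c", 100, 140)], ann) == []

    def test_multi_hole_matches_per_base_oracle(self):
        ann = ann_with("CDS", [("c", 20, 30), ("c", 60, 70)])
        seg = GI("c", 0, 100)
        out = subtract_coding([seg], ann)
        assert out == [GI("c", 0, 20), GI("c", 30, 60), GI("c", 70, 100)]
        # per-base membership oracle
        covered = set()
        for iv in out:
            covered |= set(range(iv.start, iv.end))
        cds = set(range(20, 30)) | set(range(60, 70))
        assert covered == set(range(0, 100)) - cds

    def test_random_against_per_base_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            cds = []
            for _ in range(rng.integers(0, 5)):
                s = int(rng.integers(0, 180))
                cds.append(("c", s, s + int(rng.integers(1, 30))))
            ann = ann_with("CDS", cds)
            s = int(rng.integers(0, 150))
            seg = GI("c", s, s + int(rng.integers(10, 60)))
            out = subtract_coding([seg], ann)
            got = set()
            for iv in out:
                got |= set(range(iv.start, iv.end))
            cdsbases = set()
            for _, a, b in cds:
                cdsbases |= set(range(a, b))
            assert got == set(range(seg.start, seg.end)) - cdsbases

    def test_chrom_mismatch_warns_and_keeps(self, caplog):
        ann = ann_with("CDS", [("other", 0, 10)])
        with caplog.at_level("WARNING"):
            out = subtract_coding([GI("c", 5, 25)], ann)
        assert out == [GI("c", 5, 25)]
        assert any("absent" in r.message for r in caplog.records)


class TestMinLength:
    def test_boundary_cases(self):
        lens = (5, 10, 11, 12, 50, 8)
        segs = [GI("c", 0 + 100 * i, 100 * i + l) for i, l in enumerate(lens)]
        kept = filter_min_length(segs)
        assert [s.length for s in kept] == [11, 12, 50]


def _block(rows, ref="R"):
    b = AlignmentBlock(ref_species=ref)
    for sp, chrom, start, text in rows:
        size = len(text.replace("-", ""))
        b.rows[sp] = MafRow(species=sp, chrom=chrom, start=start, size=size,
                            strand="+", src_size=10000, text=text)
    return b


class TestProjection:
    def test_ungapped_identical_length(self):
        b = _block([("R", "c", 100, "ACGTACGTAC"), ("S", "x", 500, "ACGTACGTAC")])
        proj = project_to_species(GI("c", 102, 108), [b])
        assert proj["S"] == [GI("x", 502, 508)]

    def test_deletion_shrinks_projection(self):
        b = _block([("R", "c", 0, "ACGTACGTAC"), ("S", "x", 0, "AC-----TAC")])
        proj = project_to_species(GI("c", 1, 9), [b])
        # columns 1..8: S has bases at cols 1,7,8 -> positions 1,2,3
        assert proj["S"] == [GI("x", 1, 4)]
        # per-column walk oracle
        spos = []
        p = 0
        for col, ch in enumerate("AC-----TAC"):
            if ch != "-":
                if 1 <= col < 9:
                    spos.append(p)
                p += 1
        assert proj["S"][0].start == min(spos) and proj["S"][0].end == max(spos) + 1

    def test_split_across_chromosomes_gives_two_intervals(self):
        b1 = _block([("R", "c", 0, "ACGTA"), ("S", "x", 0, "ACGTA")])
        b2 = _block([("R", "c", 5, "CGTAC"), ("S", "y", 100, "CGTAC")])
        proj = project_to_species(GI("c", 2, 8), [b1, b2])
        assert len(proj["S"]) == 2

    def test_insertion_lengthens_projection(self):
        b = _block([("R", "c", 0, "ACG---TAC"), ("S", "x", 0, "ACGTTTTAC")])
        proj = project_to_species(GI("c", 1, 5), [b])
        # ref positions 1..4 span columns 1..7; S covers 7 bases
        assert proj["S"] == [GI("x", 1, 8)]

    def test_unaligned_species(self):
        b = _block([("R", "c", 0, "ACGTA"), ("S", "x", 0, "-----")])
        proj = project_to_species(GI("c", 1, 4), [b])
        assert proj["S"] == []


class TestSpeciesFilters:
    def _rec(self, projections, ref_len=12):
        rec = CneRecord(cne_id="e", ref=GI("c", 0, ref_len))
        rec.projections = projections
        return rec

    @pytest.mark.parametrize(
        "length,expected",
        [(25, DROPPED_LENGTH_RATIO), (24, KEPT), (12, KEPT)],
    )
    def test_length_ratio_boundary(self, length, expected):
        rec = self._rec({"S": [GI("x", 0, length)]})
        filter_species_cnes([rec])
        assert rec.status["S"] == expected

    def test_redundant_and_unaligned(self):
        rec = self._rec({"S": [GI("x", 0, 5), GI("y", 0, 5)], "T": []})
        filter_species_cnes([rec])
        assert rec.status["S"] == DROPPED_REDUNDANT
        assert rec.status["T"] == UNALIGNED

    def test_reference_never_dropped(self):
        rec = self._rec({"R": [GI("c", 0, 100)]})
        filter_species_cnes([rec], ref_species="R")
        assert rec.status["R"] == KEPT


class TestNearestGene:
    def test_downstream_gene_wins(self):
        genes = ann_with("gene", [("c", 0, 50, "g1"), ("c", 130, 200, "g2")])
        assert nearest_gene(GI("c", 100, 120), genes) == ("g2", 10)

    def test_overlap_gives_zero(self):
        genes = ann_with("gene", [("c", 0, 500, "g1")])
        assert nearest_gene(GI("c", 100, 120), genes) == ("g1", 0)

    def test_no_gene_on_chromosome(self):
        genes = ann_with("gene", [("other", 0, 50, "g1")])
        assert nearest_gene(GI("c", 100, 120), genes) is None

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(2)
        genes = []
        for i in range(30):
            s = int(rng.integers(0, 5000))
            genes.append(("c", s, s + int(rng.integers(50, 300)), f"g{i:02d}"))
        ann = ann_with("gene", genes)
        for _ in range(200):
            s = int(rng.integers(0, 5000))
            cne = GI("c", s, s + int(rng.integers(10, 100)))
            gid, dist = nearest_gene(cne, ann)
            # brute force minimal absolute gap
            def gap(g):
                _, gs, ge, _ = g
                if gs < cne.end and cne.start < ge:
                    return 0
                return gs - cne.end if gs >= cne.end else cne.start - ge
            best = min(abs(gap(g)) for g in genes)
            assert abs(dist) == best


class TestEnrichment:
    def test_hand_hypergeometric_table(self):
        # accelerated CNEs a,b,c,d; feature overlaps a,b,c and one non-accel
        cnes = {f"c{i}": GI("c", 100 * i, 100 * i + 10) for i in range(8)}
        accel = {"c0", "c1", "c2", "c3"}
        ann = AnnotationSet()
        for cid in ("c0", "c1", "c2", "c4"):
            ann.add("enhancer", cnes[cid])
        df = annotation_enrichment(accel, set(cnes), cnes, ann)
        # table [[3,1],[1,3]] -> one-sided p = (16+1)/70
        assert np.isclose(df.loc[0, "p"], 17 / 70)
        assert np.isclose(df.loc[0, "p"], hypergeom.sf(2, 8, 4, 4))

    def test_accelerated_equals_universe_gives_p_one(self):
        cnes = {f"c{i}": GI("c", 100 * i, 100 * i + 10) for i in range(4)}
        ann = AnnotationSet()
        ann.add("enhancer", cnes["c0"])
        df = annotation_enrichment(set(cnes), set(cnes), cnes, ann)
        assert (df["p"] == 1.0).all()

    def test_empty_accelerated_gives_p_one(self):
        cnes = {f"c{i}": GI("c", 100 * i, 100 * i + 10) for i in range(4)}
        ann = AnnotationSet()
        ann.add("enhancer", cnes["c0"])
        df = annotation_enrichment(set(), set(cnes), cnes, ann)
        assert (df["p"] == 1.0).all()

    def test_bh_step_up_by_hand(self):
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(q, 0.04)

    def test_fisher_matches_hypergeom_for_all_small_tables(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(4, 61))
            k = int(rng.integers(1, n))      # row-1 margin
            m = int(rng.integers(1, n))      # col-1 margin
            a = int(rng.integers(max(0, k + m - n), min(k, m) + 1))
            table = [[a, k - a], [m - a, n - k - (m - a)]]
            p = fisher_exact(table, alternative="greater")[1]
            assert np.isclose(p, hypergeom.sf(a - 1, n, m, k), atol=1e-12)
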