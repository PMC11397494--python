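"""A hand-sized, fully deterministic end-to-end fixture dataset.

Everything here is constructed, synthetic data: planted conserved stretches
are literally identical across species, the single accelerated element has
its three hermaphrodite terminals mutated at a strongly elevated rate, the
divergent background is evolved once from a fixed generator state, and the
columns flanking every planted stretch are set to a fixed maximally divergent
pattern so segment boundaries are exact by construction.  The variant and
expression tables are written out by hand so that every downstream number
(filter outcomes, nearest genes, per-element pi, the transition table) can be
checked with pencil-and-paper arithmetic; the frozen expectations live in
``tests/data/fixture``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import AnnotationSet
from .intervals import GenomicInterval
from .io import AlignmentBlock, MafRow
from .diversity import VariantMatrix
from .hmm import HmmParams
from .simulate import DEFAULT_TREE_NEWICK, HERMAPHRODITE_BRANCHES
from .substitution import HKYModel
from .trees import Phylogeny

__all__ = ["FixtureBundle", "make_fixture", "run_fixture_pipeline"]

CHROM = "chrI"
REF_LENGTH = 2000
REF_SPECIES = "C_niphades"
INSERTION_SPECIES = "C_latens"
REDUNDANT_SPECIES = "C_brenneri"

# planted conserved stretches in reference coordinates (half-open)
CONSERVED_STRETCHES = [
    (70, 130),     # overlaps CDS of gene g0001 -> trimmed to [70,100)
    (300, 360),    # the accelerated element
    (500, 540),
    (850, 862),
    (900, 910),    # length 10: removed by the "longer than 10 bp" rule
    (1000, 1060),  # C_latens carries a 70-column insertion inside
    (1200, 1260),  # C_brenneri aligns redundantly (second block, chrB)
    (1600, 1700),
]
ACCELERATED_STRETCH = (300, 360)
INSERTION_AFTER_REF_POS = 1030   # 70 gap columns follow this reference position
INSERTION_LENGTH = 70

GENES = [  # (gene id, body start, body end, cds start, cds end)
    ("g0001", 80, 240, 100, 220),
    ("g0002", 600, 800, 620, 780),
    ("g0003", 1400, 1500, 1410, 1490),
    ("g0004", 1750, 1900, 1760, 1890),
]

# population variants: (ref position, derived-allele carrier haplotypes,
# missing haplotypes) over 8 haplotypes
VARIANT_SPEC = [
    (110, (0, 1, 2, 3), ()),
    (150, (0, 1, 2), ()),
    (200, (4, 5, 6, 7), ()),
    (320, (4, 5, 6, 7), ()),
    (650, (0, 2, 4, 6), ()),
    (700, (1, 3, 5, 7), ()),
    (1230, (0,), (7,)),
    (1450, (2, 5), ()),
    (1620, (3,), ()),
    (1650, (0, 4), ()),
]
N_HAPLOTYPES = 8


@dataclass
class FixtureBundle:
    tree: Phylogeny
    model: HKYModel
    hmm_params: HmmParams
    primary_block: AlignmentBlock        # the HMM runs on this block only
    projection_blocks: list              # primary + the duplicated-region block
    annotations: AnnotationSet
    variants: VariantMatrix
    counts: dict                         # species -> genes x samples DataFrame
    metadata: pd.DataFrame
    orthologs: list
    neighbor_genes: set
    truth_conserved: list
    truth_accelerated_id: str = "CNE00002"


def _divergent_pattern(species: list) -> dict:
    return {sp: "ACGT"[i % 4] for i, sp in enumerate(sorted(species))}


def _build_alignment(tree: Phylogeny, model: HKYModel) -> tuple[AlignmentBlock, AlignmentBlock, str]:
    rng = np.random.default_rng(987654321)
    species = tree.leaf_labels()
    L = REF_LENGTH
    cls = np.zeros(L, dtype=np.int8)
    for s, e in CONSERVED_STRETCHES:
        cls[s:e] = 1
    a_s, a_e = ACCELERATED_STRETCH

    ref_seq = rng.choice(4, size=L, p=model.freqs)
    seqs = {sp: ref_seq.copy() for sp in species}
    # background: evolve each leaf independently from the reference at an
    # inflated divergence so nonconserved columns are unambiguous
    for sp in species:
        if sp == REF_SPECIES:
            continue
        t = 2.5 * _leaf_depth(tree, sp)
        P = model.transition_matrix(t)
        bg = np.nonzero(cls == 0)[0]
        for b in range(4):
            m = bg[ref_seq[bg] == b]
            seqs[sp][m] = rng.choice(4, size=len(m), p=P[b])
    # accelerated element: hermaphrodite terminals mutate at rho*lambda
    for sp in HERMAPHRODITE_BRANCHES:
        t = float(tree.lengths[tree.node_by_name(sp)])
        P = model.transition_matrix(t * 0.3 * 8.0)
        idx = np.arange(a_s, a_e)
        for b in range(4):
            m = idx[ref_seq[idx] == b]
            seqs[sp][m] = rng.choice(4, size=len(m), p=P[b])
    # fixed maximally divergent flanking columns pin segment boundaries
    pattern = _divergent_pattern(species)
    for s, e in CONSERVED_STRETCHES:
        for col in (s - 1, e):
            if 0 <= col < L:
                for sp in species:
                    seqs[sp][col] = "ACGT".index(pattern[sp])

    texts = {sp: "".join("ACGT"[b] for b in seqs[sp]) for sp in species}
    # insert a 70-column C_latens-only block inside the [1000,1060) element
    cut = INSERTION_AFTER_REF_POS + 1
    ins = ("ACGT" * (INSERTION_LENGTH // 4 + 1))[:INSERTION_LENGTH]
    gapped = {}
    for sp in species:
        filler = ins if sp == INSERTION_SPECIES else "-" * INSERTION_LENGTH
        gapped[sp] = texts[sp][:cut] + filler + texts[sp][cut:]

    block = AlignmentBlock(ref_species=REF_SPECIES)
    for sp in species:
        size = L + (INSERTION_LENGTH if sp == INSERTION_SPECIES else 0)
        block.rows[sp] = MafRow(
            species=sp, chrom=CHROM, start=0, size=size, strand="+",
            src_size=size, text=gapped[sp],
        )
    # second block: the [1200,1260) region of C_brenneri also aligns on chrB
    dup = AlignmentBlock(ref_species=REF_SPECIES)
    s, e = 1200, 1260
    dup.rows[REF_SPECIES] = MafRow(
        species=REF_SPECIES, chrom=CHROM, start=s, size=e - s, strand="+",
        src_size=L, text=texts[REF_SPECIES][s:e],
    )
    dup.rows[REDUNDANT_SPECIES] = MafRow(
        species=REDUNDANT_SPECIES, chrom="chrB", start=5000, size=e - s,
        strand="+", src_size=8000, text=texts[REF_SPECIES][s:e],
    )
    return block, dup, texts[REF_SPECIES]


def _leaf_depth(tree: Phylogeny, name: str) -> float:
    node = tree.node_by_name(name)
    depth = 0.0
    while node != tree.root:
        depth += float(tree.lengths[node])
        node = int(tree.parent[node])
    return depth


def _build_variants(ref_text: str) -> VariantMatrix:
    chroms, poss, refs, alts, rows = [], [], [], [], []
    for pos, carriers, missing in VARIANT_SPEC:
        refb = ref_text[pos]
        alt = "ACGT"[("ACGT".index(refb) + 1) % 4]
        g = np.zeros(N_HAPLOTYPES, dtype=np.int8)
        g[list(carriers)] = 1
        for m in missing:
            g[m] = -1
        chroms.append(CHROM)
        poss.append(pos)
        refs.append(refb)
        alts.append(alt)
        rows.append(g)
    return VariantMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        haplotypes=np.array(rows, dtype=np.int8),
    )


def _build_expression():
    """Hand-written counts: class-defining means 800 vs 100, Non flat 200."""
    class_a = {1: "XX", 2: "XX", 3: "XO", 4: "XO"}          # rest Non
    class_b = {1: "XX", 3: "XO", 4: "XX", 5: "XX"}          # rest Non
    neighbor = {"gA04", "gA05", "gA07"}
    counts = {}
    meta_rows = []
    orthologs = []
    for species, classes in (("A", class_a), ("B", class_b)):
        cols = {}
        genes = [f"g{species}{i:02d}" for i in range(1, 13)]
        for stage in ("L4", "young_adult"):
            for sex in ("XX", "XO"):
                for rep in range(1, 4):
                    name = f"{species}_{stage}_{sex}_r{rep}"
                    vals = []
                    for i in range(1, 13):
                        cls = classes.get(i)
                        if cls is None:
                            vals.append(200)
                        elif cls == sex:
                            vals.append(800)
                        else:
                            vals.append(100)
                    # small fixed replicate jitter keeps dispersions finite
                    cols[name] = [v + 2 * (rep - 2) for v in vals]
                    meta_rows.append(dict(sample=name, species=species,
                                          sex=sex, stage=stage, replicate=rep))
        counts[species] = pd.DataFrame(cols, index=genes)
    orthologs = [(f"gA{i:02d}", f"gB{i:02d}") for i in range(1, 13)]
    return counts, pd.DataFrame(meta_rows), orthologs, neighbor


def make_fixture() -> FixtureBundle:
    """Build the deterministic bundle; identical output on every call."""
    tree = Phylogeny.from_newick(DEFAULT_TREE_NEWICK)
    model = HKYModel(np.array([0.3, 0.2, 0.2, 0.3]), kappa=2.0)
    block, dup, ref_text = _build_alignment(tree, model)
    ann = AnnotationSet()
    for gid, gs, ge, cs, ce in GENES:
        ann.add("gene", GenomicInterval(CHROM, gs, ge), gid)
        ann.add("CDS", GenomicInterval(CHROM, cs, ce), f"{gid}.cds")
    counts, metadata, orthologs, neighbor = _build_expression()
    return FixtureBundle(
        tree=tree,
        model=model,
        hmm_params=HmmParams(omega=12.0, gamma=0.3, rho=0.3),
        primary_block=block,
        projection_blocks=[block, dup],
        annotations=ann,
        variants=_build_variants(ref_text),
        counts=counts,
        metadata=metadata,
        orthologs=orthologs,
        neighbor_genes=neighbor,
        truth_conserved=[GenomicInterval(CHROM, s, e) for s, e in CONSERVED_STRETCHES],
    )


def run_fixture_pipeline(bundle: FixtureBundle | None = None) -> dict:
    """Execute every stage on the fixture; returns canonical TSV strings.

    Keys: ``catalog``, ``pi_per_element``, ``pi_summary``, ``transitions``,
    plus the in-memory ``records`` and acceleration ``results``.
    """
    from .accel import JOINT, AccelerationTest, TargetSpec
    from .catalog import KEPT, catalog_to_frame
    from .diversity import pi_per_element, summarize_by_class
    from .expression import classify_sex_bias, de_test, transition_association
    from .pipeline import build_catalog, detect_conserved_segments, element_codes

    if bundle is None:
        bundle = make_fixture()
    segments = detect_conserved_segments(
        [bundle.primary_block], bundle.tree, bundle.model, bundle.hmm_params
    )
    records = build_catalog(
        segments, bundle.projection_blocks, bundle.annotations, REF_SPECIES
    )
    catalog = catalog_to_frame(records, species_order=sorted(bundle.tree.leaf_labels()))

    # nucleotide diversity over kept elements and CDS
    cnes = [r.ref for r in records]
    cds = bundle.annotations.intervals("CDS", CHROM)
    summary, per_element = summarize_by_class(
        {"CNE": cnes, "CDS": cds}, bundle.variants
    )

    # acceleration: joint test on the three hermaphrodite terminals
    targets = TargetSpec(frozenset(HERMAPHRODITE_BRANCHES), mode=JOINT)
    tester = AccelerationTest(bundle.tree, bundle.model)
    elements = {
        r.cne_id: element_codes(bundle.primary_block, r.ref) for r in records
    }
    results = tester.run(elements, targets)

    # expression: young-adult XX-vs-XO calls per species, then the 3x3 table
    calls = {}
    for sp in ("A", "B"):
        meta = bundle.metadata.query("species == @sp and stage == 'young_adult'")
        xx = meta.query("sex == 'XX'")["sample"].tolist()
        xo = meta.query("sex == 'XO'")["sample"].tolist()
        calls[sp] = classify_sex_bias(de_test(bundle.counts[sp], xx, xo))
    table = transition_association(
        calls["A"], calls["B"], bundle.orthologs, bundle.neighbor_genes
    )

    def tsv(df: pd.DataFrame) -> str:
        return df.to_csv(sep="\t", index=False, float_format="%.10g")

    return {
        "catalog": tsv(catalog),
        "pi_per_element": tsv(per_element),
        "pi_summary": tsv(summary),
        "transitions": tsv(table.cells),
        "records": records,
        "results": results,
        "segments": segments,
        "bundle": bundle,
    }
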