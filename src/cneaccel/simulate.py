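"""Seeded generators for every input the pipeline consumes, with ground truth.

The alignment generator evolves a root sequence down the packaged 11-taxon
tree under the same HKY machinery the inference uses; planted conserved
stretches scale every branch by ``rho`` and planted accelerated stretches
additionally scale the target (hermaphrodite terminal) branches by
``lambda``.  The population generator places segregating sites independently
with per-site density proportional to a local theta that is reduced inside
conserved elements, drawing allele counts from the neutral 1/k frequency
spectrum (no linkage — a documented simplification).  The expression
generator emits negative-binomial count matrices for two species with planted
sex-bias classes and neighbor flags enriched in configured transition cells
at a configured odds ratio.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .catalog import AnnotationSet
from .intervals import GenomicInterval
from .io import AlignmentBlock, MafRow
from .diversity import VariantMatrix
from .substitution import HKYModel
from .trees import Phylogeny

__all__ = [
    "DEFAULT_TREE_NEWICK",
    "HERMAPHRODITE_BRANCHES",
    "SimConfig",
    "AlignmentSim",
    "simulate_alignment",
    "simulate_population",
    "simulate_expression",
    "write_bundle",
]

# Packaged 11-taxon Caenorhabditis-style topology: three hermaphrodite
# (androdioecious) terminals, C_niphades as the high-quality outgroup used as
# the alignment reference.  Branch lengths are round numbers chosen to give
# the test suite realistic divergence, not estimates for the real genus.
DEFAULT_TREE_NEWICK = (
    "(((((C_elegans:0.18,C_inopinata:0.18):0.05,"
    "((C_briggsae:0.18,C_nigoni:0.18):0.05,"
    "(C_tropicalis:0.18,C_wallacei:0.18):0.05):0.03):0.03,"
    "(C_remanei:0.18,C_latens:0.18):0.06):0.03,"
    "(C_brenneri:0.2,C_sinica:0.2):0.05):0.08,"
    "C_niphades:0.35);"
)

HERMAPHRODITE_BRANCHES = ("C_elegans", "C_briggsae", "C_tropicalis")

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

NEUTRAL, CONSERVED_CLASS, ACCEL_CLASS = 0, 1, 2


@dataclass
class SimConfig:
    """Study conditions for the synthetic data (all generators)."""

    seed: int = 0
    tree_newick: str = DEFAULT_TREE_NEWICK
    ref_species: str = "C_niphades"
    target_branches: tuple = HERMAPHRODITE_BRANCHES
    # alignment / element layout
    chrom: str = "chrI"
    chrom_length: int = 20000
    n_conserved: int = 40
    n_accelerated: int = 8
    element_length_range: tuple = (30, 120)
    rho_conserved: float = 0.3
    lam_accelerated: float = 5.0
    n_genes: int = 20
    cds_fraction: float = 0.25
    base_freqs: tuple = (0.3, 0.2, 0.2, 0.3)
    kappa: float = 2.0
    # population haplotypes
    n_haplotypes: int = 48
    theta_neutral: float = 0.004
    cne_theta_reduction: float = 5.0
    # expression
    n_orthologs: int = 2000
    nb_dispersion: float = 0.1
    mean_gamma_shape: float = 2.0
    mean_gamma_scale: float = 50.0
    bias_fraction_xx: float = 0.1
    bias_fraction_xo: float = 0.1
    bias_fold: float = 4.0
    n_replicates: int = 4
    neighbor_base_rate: float = 0.1
    neighbor_or: float = 3.0
    neighbor_target_cells: tuple = (("Non", "XX-biased"),)
    stages: tuple = ("L4", "young_adult")

    def tree(self) -> Phylogeny:
        return Phylogeny.from_newick(self.tree_newick)

    def model(self) -> HKYModel:
        return HKYModel(np.asarray(self.base_freqs), self.kappa)


@dataclass
class AlignmentSim:
    """Output bundle of :func:`simulate_alignment`."""

    config: SimConfig
    tree: Phylogeny
    model: HKYModel
    block: AlignmentBlock
    sequences: dict                      # species -> ungapped string
    annotations: AnnotationSet           # gene + CDS features on the reference
    conserved_truth: list                # planted conserved GenomicIntervals
    accelerated_truth: list              # subset additionally accelerated
    neutral_controls: list               # matched neutral intergenic intervals
    column_class: np.ndarray = field(repr=False, default=None)


def _evolve_branch(parent: np.ndarray, pmats: dict, column_class: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    child = np.empty_like(parent)
    for cls, P in pmats.items():
        cls_mask = column_class == cls
        for b in range(4):
            m = cls_mask & (parent == b)
            k = int(m.sum())
            if k:
                child[m] = rng.choice(4, size=k, p=P[b])
    return child


def _layout(cfg: SimConfig, rng: np.random.Generator):
    """Place genes, conserved elements and neutral controls without overlap."""
    lens_elem = rng.integers(cfg.element_length_range[0],
                             cfg.element_length_range[1] + 1, cfg.n_conserved)
    lens_ctrl = rng.integers(cfg.element_length_range[0],
                             cfg.element_length_range[1] + 1, cfg.n_conserved)
    gene_len = max(60, int(cfg.cds_fraction * cfg.chrom_length / max(cfg.n_genes, 1)))
    features = (
        [("gene", gene_len)] * cfg.n_genes
        + [("cne", int(l)) for l in lens_elem]
        + [("ctrl", int(l)) for l in lens_ctrl]
    )
    order = rng.permutation(len(features))
    features = [features[i] for i in order]
    used = sum(l for _, l in features)
    free = cfg.chrom_length - used
    if free < len(features) + 1:
        raise ValueError("element layout exceeds chromosome length")
    cuts = np.sort(rng.choice(free, size=len(features), replace=False))
    gaps = np.diff(np.concatenate([[0], cuts, [free]]))
    cursor = 0
    genes, cnes, ctrls = [], [], []
    for (kind, length), gap in zip(features, gaps[:-1]):
        cursor += int(gap)
        iv = GenomicInterval(cfg.chrom, cursor, cursor + length)
        {"gene": genes, "cne": cnes, "ctrl": ctrls}[kind].append(iv)
        cursor += length
    return genes, cnes, ctrls


def simulate_alignment(cfg: SimConfig, rng: np.random.Generator | None = None) -> AlignmentSim:
    """Evolve the multi-species alignment with planted conserved/accelerated
    elements; returns the alignment block, annotation and truth sets."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    tree = cfg.tree()
    model = cfg.model()
    genes, cnes, ctrls = _layout(cfg, rng)
    accel_idx = set(
        rng.choice(len(cnes), size=cfg.n_accelerated, replace=False).tolist()
    ) if cfg.n_accelerated else set()
    column_class = np.zeros(cfg.chrom_length, dtype=np.int8)
    for i, iv in enumerate(cnes):
        column_class[iv.start:iv.end] = ACCEL_CLASS if i in accel_idx else CONSERVED_CLASS

    target_nodes = {tree.node_by_name(b) for b in cfg.target_branches}
    root_seq = rng.choice(4, size=cfg.chrom_length, p=model.freqs)
    seqs = {tree.root: root_seq}
    preorder = list(tree.postorder[::-1])
    for node in preorder:
        node = int(node)
        if node == tree.root:
            continue
        t = float(tree.lengths[node])
        scale_accel = cfg.rho_conserved * (
            cfg.lam_accelerated if node in target_nodes else 1.0
        )
        pmats = {
            NEUTRAL: model.transition_matrix(t),
            CONSERVED_CLASS: model.transition_matrix(t * cfg.rho_conserved),
            ACCEL_CLASS: model.transition_matrix(t * scale_accel),
        }
        seqs[node] = _evolve_branch(seqs[int(tree.parent[node])], pmats, column_class, rng)

    leaf_seqs = {
        tree.names[n]: "".join("ACGT"[b] for b in seqs[n]) for n in tree.leaf_nodes()
    }
    block = AlignmentBlock(ref_species=cfg.ref_species)
    for sp, s in leaf_seqs.items():
        block.rows[sp] = MafRow(
            species=sp, chrom=cfg.chrom, start=0, size=cfg.chrom_length,
            strand="+", src_size=cfg.chrom_length, text=s,
        )

    ann = AnnotationSet()
    for i, iv in enumerate(genes):
        gid = f"gene{i + 1:04d}"
        ann.add("gene", iv, gid)
        # CDS inset by 10 bp on each side (UTR-like margins)
        ann.add("CDS", GenomicInterval(iv.chrom, iv.start + 10, iv.end - 10), f"{gid}.cds")
    return AlignmentSim(
        config=cfg,
        tree=tree,
        model=model,
        block=block,
        sequences=leaf_seqs,
        annotations=ann,
        conserved_truth=list(cnes),
        accelerated_truth=[iv for i, iv in enumerate(cnes) if i in accel_idx],
        neutral_controls=ctrls,
        column_class=column_class,
    )


# ---------------------------------------------------------------------------
# population haplotypes


def simulate_population(
    cfg: SimConfig,
    ref_sequence: str,
    conserved: list,
    rng: np.random.Generator | None = None,
    chrom: str | None = None,
) -> VariantMatrix:
    """Site-independent segregating variants with reduced theta inside CNEs.

    A site segregates with probability ``theta * a_n`` (Watterson's harmonic
    factor), and its derived-allele count k is drawn from the neutral 1/k
    spectrum, so expected per-site pi equals the local theta.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    chrom = chrom or cfg.chrom
    n = cfg.n_haplotypes
    L = len(ref_sequence)
    theta = np.full(L, cfg.theta_neutral)
    for iv in conserved:
        theta[iv.start:iv.end] = cfg.theta_neutral / cfg.cne_theta_reduction
    a_n = np.sum(1.0 / np.arange(1, n))
    p_seg = np.clip(theta * a_n, 0, 0.9)
    seg_pos = np.nonzero(rng.random(L) < p_seg)[0]
    ks = np.arange(1, n)
    k_probs = (1.0 / ks) / np.sum(1.0 / ks)
    chroms, poss, refs, alts, rows = [], [], [], [], []
    for pos in seg_pos:
        refb = ref_sequence[pos]
        if refb not in "ACGT":
            continue
        alt = rng.choice([b for b in "ACGT" if b != refb])
        k = int(rng.choice(ks, p=k_probs))
        carriers = rng.choice(n, size=k, replace=False)
        g = np.zeros(n, dtype=np.int8)
        g[carriers] = 1
        chroms.append(chrom)
        poss.append(int(pos))
        refs.append(refb)
        alts.append(str(alt))
        rows.append(g)
    return VariantMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        haplotypes=(np.array(rows, dtype=np.int8)
                    if rows else np.empty((0, n), np.int8)),
    )


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionSim:
    counts: dict                 # species -> genes x samples DataFrame
    metadata: pd.DataFrame       # sample, species, sex, stage, replicate
    orthologs: list              # (gene_a, gene_b) one-to-one pairs
    truth_class: dict            # species -> per-gene planted class Series
    neighbor_genes: set          # species-A gene ids flagged as CNE neighbors
    config: SimConfig


def _planted_class(rng, n, p_xx, p_xo):
    u = rng.random(n)
    cls = np.where(u < p_xx, "XX-biased", np.where(u < p_xx + p_xo, "XO-biased", "Non"))
    return cls


def simulate_expression(cfg: SimConfig, rng: np.random.Generator | None = None) -> ExpressionSim:
    """NB count matrices for two species with planted sex-bias classes and
    neighbor flags enriched in the configured transition cells."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    n = cfg.n_orthologs
    genes_a = [f"gA{i + 1:05d}" for i in range(n)]
    genes_b = [f"gB{i + 1:05d}" for i in range(n)]
    mu = rng.gamma(cfg.mean_gamma_shape, cfg.mean_gamma_scale, size=n) + 1.0
    cls_a = _planted_class(rng, n, cfg.bias_fraction_xx, cfg.bias_fraction_xo)
    cls_b = _planted_class(rng, n, cfg.bias_fraction_xx, cfg.bias_fraction_xo)

    # neighbor flags: base rate everywhere, odds-ratio bump in target cells
    base_odds = cfg.neighbor_base_rate / (1 - cfg.neighbor_base_rate)
    p_target = cfg.neighbor_or * base_odds / (1 + cfg.neighbor_or * base_odds)
    if not 0 < p_target < 1:
        raise ValueError(
            f"neighbor odds ratio {cfg.neighbor_or} infeasible with base rate "
            f"{cfg.neighbor_base_rate}"
        )
    target_cells = {tuple(c) for c in cfg.neighbor_target_cells}
    in_target = np.array([(a, b) in target_cells for a, b in zip(cls_a, cls_b)])
    p_neigh = np.where(in_target, p_target, cfg.neighbor_base_rate)
    neighbor = rng.random(n) < p_neigh

    size = 1.0 / cfg.nb_dispersion
    counts = {}
    meta_rows = []
    for species, cls, gene_ids in (("A", cls_a, genes_a), ("B", cls_b, genes_b)):
        cols = {}
        for stage in cfg.stages:
            for sex in ("XX", "XO"):
                boost = np.where(
                    (cls == f"{sex}-biased"), cfg.bias_fold, 1.0
                )
                mean = mu * boost
                for rep in range(1, cfg.n_replicates + 1):
                    name = f"{species}_{stage}_{sex}_r{rep}"
                    p = size / (size + mean)
                    cols[name] = rng.negative_binomial(size, p)
                    meta_rows.append(
                        dict(sample=name, species=species, sex=sex,
                             stage=stage, replicate=rep)
                    )
        counts[species] = pd.DataFrame(cols, index=gene_ids)
    return ExpressionSim(
        counts=counts,
        metadata=pd.DataFrame(meta_rows),
        orthologs=list(zip(genes_a, genes_b)),
        truth_class={
            "A": pd.Series(cls_a, index=genes_a),
            "B": pd.Series(cls_b, index=genes_b),
        },
        neighbor_genes={g for g, f in zip(genes_a, neighbor) if f},
        config=cfg,
    )


# ---------------------------------------------------------------------------
# file output


def write_bundle(sim: AlignmentSim, outdir, variants: VariantMatrix | None = None,
                 expression: ExpressionSim | None = None) -> None:
    """Write a simulated dataset plus truth files and a manifest."""
    import hashlib
    import json
    from pathlib import Path

    from . import io as cio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cio.write_maf(out / "alignment.maf", [sim.block])
    cio.write_fasta(out / "reference.fa",
                    {f"{sim.config.chrom}": sim.sequences[sim.config.ref_species]})
    feats = []
    for iv, gid in sim.annotations.features("gene", sim.config.chrom):
        feats.append((sim.config.chrom, "cneaccel_sim", "gene", iv, gid, None))
    for iv, cid in sim.annotations.features("CDS", sim.config.chrom):
        feats.append((sim.config.chrom, "cneaccel_sim", "CDS", iv, cid,
                      cid.rsplit(".", 1)[0]))
    cio.write_gff3(out / "annotation.gff3", feats)
    cio.write_bed(out / "truth_conserved.bed", sim.conserved_truth,
                  names=[f"cons{i}" for i in range(len(sim.conserved_truth))])
    cio.write_bed(out / "truth_accelerated.bed", sim.accelerated_truth,
                  names=[f"accel{i}" for i in range(len(sim.accelerated_truth))])
    cio.write_bed(out / "truth_neutral_controls.bed", sim.neutral_controls,
                  names=[f"ctrl{i}" for i in range(len(sim.neutral_controls))])
    if variants is not None:
        cio.write_vcf(
            out / "population.vcf",
            list(zip(variants.chrom, variants.pos, variants.ref, variants.alt)),
            variants.haplotypes,
            [f"hap{i + 1:03d}" for i in range(variants.n_haplotypes)],
        )
    if expression is not None:
        for sp, df in expression.counts.items():
            df.to_csv(out / f"counts_{sp}.tsv", sep="\t")
        expression.metadata.to_csv(out / "samples.tsv", sep="\t", index=False)
        pd.DataFrame(expression.orthologs, columns=["gene_a", "gene_b"]).to_csv(
            out / "orthologs.tsv", sep="\t", index=False
        )
        with open(out / "neighbor_genes.txt", "w") as fh:
            for g in sorted(expression.neighbor_genes):
                fh.write(g + "\n")
    cfg = asdict(sim.config)
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump({"seed": sim.config.seed, "config": cfg,
                   "config_sha256": digest}, fh, indent=2, default=str)
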