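"""End-to-end glue: alignment blocks -> conserved segments -> CNE catalog."""

from __future__ import annotations

import numpy as np

from .catalog import (
    AnnotationSet,
    CneRecord,
    filter_min_length,
    filter_species_cnes,
    nearest_gene,
    project_to_species,
    subtract_coding,
)
from .hmm import HmmParams, ConservedSegment, emission_logliks, viterbi_segments
from .intervals import GenomicInterval
from .substitution import HKYModel
from .trees import Phylogeny

__all__ = ["detect_conserved_segments", "build_catalog", "element_codes"]


def detect_conserved_segments(
    blocks, tree: Phylogeny, model: HKYModel, params: HmmParams
) -> list[ConservedSegment]:
    """Run the two-state phylo-HMM over every block; segments in ref coords."""
    segments = []
    for block in blocks:
        em = emission_logliks(block.codes(), tree, model, params.rho)
        segments.extend(
            viterbi_segments(
                em, params.mu, params.nu,
                block.ref_positions(), chrom=block.ref_row.chrom,
            )
        )
    return sorted(segments, key=lambda s: (s.chrom, s.start))


def build_catalog(
    segments,
    blocks,
    annotations: AnnotationSet,
    ref_species: str,
    id_prefix: str = "CNE",
) -> list[CneRecord]:
    """Conserved segments -> filtered, projected, gene-annotated CNE records."""
    intervals = [GenomicInterval(s.chrom, s.start, s.end) for s in segments]
    noncoding = subtract_coding(intervals, annotations)
    kept = filter_min_length(noncoding)
    records = []
    for i, iv in enumerate(sorted(kept, key=lambda x: (x.chrom, x.start))):
        rec = CneRecord(cne_id=f"{id_prefix}{i + 1:05d}", ref=iv)
        rec.projections = project_to_species(iv, blocks)
        records.append(rec)
    filter_species_cnes(records, ref_species=ref_species)
    for rec in records:
        hit = nearest_gene(rec.ref, annotations)
        if hit is not None:
            rec.nearest[ref_species] = hit
    return records


def element_codes(block, interval: GenomicInterval) -> dict[str, np.ndarray]:
    """Per-species observation codes for the columns spanning a ref interval."""
    refpos = block.ref_positions()
    inside = (refpos >= interval.start) & (refpos < interval.end)
    if not inside.any():
        raise ValueError(f"{interval} not covered by block")
    cols = np.nonzero(inside)[0]
    lo, hi = int(cols.min()), int(cols.max()) + 1
    codes = block.codes()
    return {sp: arr[lo:hi] for sp, arr in codes.items()}
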