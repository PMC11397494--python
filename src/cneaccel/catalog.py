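"""Building the CNE catalog from conserved segments.

The pipeline here mirrors the standard comparative-genomics recipe: subtract
protein-coding sequence from the conserved segments, keep pieces longer than
10 bp on the reference genome, project each element through the alignment to
every subject species, and drop per-species projections that align redundantly
(split into two or more genomic intervals) or are more than twice as long as
the reference element.  Nearest-gene assignment and annotation-overlap
enrichment (one-sided Fisher with Benjamini-Hochberg correction across
feature types) complete the catalog.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, merge_intervals, subtract_intervals, total_length

__all__ = [
    "AnnotationSet",
    "CneRecord",
    "subtract_coding",
    "filter_min_length",
    "project_to_species",
    "filter_species_cnes",
    "nearest_gene",
    "annotation_enrichment",
    "catalog_to_frame",
]

logger = logging.getLogger(__name__)

KEPT = "kept"
DROPPED_REDUNDANT = "dropped_redundant"
DROPPED_LENGTH_RATIO = "dropped_length_ratio"
UNALIGNED = "unaligned"

MIN_CNE_LENGTH = 10       # elements must be strictly longer than this
MAX_LENGTH_RATIO = 2.0    # projections strictly longer than ratio*ref are dropped


class AnnotationSet:
    """Typed interval collections (CDS, gene, UTRs, enhancer, ...) per chromosome.

    Gene features carry ids; other feature types are anonymous intervals.
    """

    def __init__(self):
        self._features: dict[str, dict[str, list]] = {}

    def add(self, ftype: str, interval: GenomicInterval, feature_id: str | None = None):
        self._features.setdefault(ftype, {}).setdefault(interval.chrom, []).append(
            (interval, feature_id)
        )

    @property
    def feature_types(self) -> list[str]:
        return sorted(self._features)

    def chromosomes(self, ftype: str) -> set[str]:
        return set(self._features.get(ftype, {}))

    def intervals(self, ftype: str, chrom: str | None = None) -> list[GenomicInterval]:
        chroms = self._features.get(ftype, {})
        keys = [chrom] if chrom is not None else sorted(chroms)
        return [iv for c in keys for iv, _ in sorted(chroms.get(c, []))]

    def features(self, ftype: str, chrom: str) -> list[tuple[GenomicInterval, str]]:
        return sorted(self._features.get(ftype, {}).get(chrom, []))

    def overlaps(self, ftype: str, query: GenomicInterval) -> bool:
        for iv, _ in self._features.get(ftype, {}).get(query.chrom, []):
            if iv.overlaps(query):
                return True
        return False

    @classmethod
    def from_gff3(cls, path, types: set[str] | None = None) -> "AnnotationSet":
        """Load a GFF3 file (coordinates converted to 0-based half-open)."""
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        out = cls()
        for feat in db.all_features():
            if types is not None and feat.featuretype not in types:
                continue
            fid = feat.attributes.get("ID", [feat.id])[0]
            out.add(
                feat.featuretype,
                GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand or "."),
                fid,
            )
        return out


@dataclass
class CneRecord:
    """One conserved noncoding element with its per-species projections."""

    cne_id: str
    ref: GenomicInterval
    projections: dict = field(default_factory=dict)  # species -> [GenomicInterval]
    status: dict = field(default_factory=dict)       # species -> status flag
    nearest: dict = field(default_factory=dict)      # species -> (gene_id, signed dist)


# ---------------------------------------------------------------------------
# segment -> element steps


def subtract_coding(segments, cds: AnnotationSet) -> list[GenomicInterval]:
    """Remove every CDS-overlapping base from the conserved segments."""
    cds_chroms = cds.chromosomes("CDS")
    out = []
    warned = set()
    for seg in segments:
        if seg.chrom not in cds_chroms:
            if seg.chrom not in warned:
                logger.warning(
                    "chromosome %s absent from CDS annotation; nothing subtracted",
                    seg.chrom,
                )
                warned.add(seg.chrom)
            out.append(seg)
            continue
        out.extend(subtract_intervals(seg, cds.intervals("CDS", seg.chrom)))
    return out


def filter_min_length(segments, min_length: int = MIN_CNE_LENGTH) -> list[GenomicInterval]:
    """Keep only segments strictly longer than ``min_length`` bp."""
    return [s for s in segments if s.length > min_length]


def project_to_species(cne: GenomicInterval, blocks) -> dict[str, list[GenomicInterval]]:
    """Map a reference element through the alignment into each subject species.

    For every block covering part of the element, the columns from the first
    to the last reference position inside the element (inclusive of any
    interior reference-gap columns, i.e. insertions in subject species) are
    projected; per species the non-gap positions of that column range form one
    contiguous source interval.  Unions across blocks are merged; a species
    with no aligned base is reported with an empty list (unaligned).
    """
    per_species: dict[str, list[GenomicInterval]] = {}
    for block in blocks:
        refpos = block.ref_positions()
        if block.ref_row.chrom != cne.chrom:
            continue
        inside = (refpos >= cne.start) & (refpos < cne.end)
        if not inside.any():
            continue
        cols = np.nonzero(inside)[0]
        lo, hi = int(cols.min()), int(cols.max()) + 1
        for sp in block.rows:
            pos = block.column_positions(sp)[lo:hi]
            pos = pos[pos >= 0]
            if len(pos) == 0:
                per_species.setdefault(sp, [])
                continue
            iv = GenomicInterval(
                block.rows[sp].chrom, int(pos.min()), int(pos.max()) + 1
            )
            per_species.setdefault(sp, []).append(iv)
    merged = {}
    for sp, ivs in per_species.items():
        merged[sp] = merge_intervals(ivs) if ivs else []
    return merged


def filter_species_cnes(records: list[CneRecord], ref_species: str | None = None) -> list[CneRecord]:
    """Assign per-species keep/drop status flags on each record (in place).

    A projection splitting into >= 2 disjoint genomic intervals is flagged
    redundant; a single projection strictly longer than twice the reference
    element is flagged for length ratio; otherwise the species is kept.  The
    reference itself is never dropped.
    """
    for rec in records:
        for sp, ivs in rec.projections.items():
            if sp == ref_species:
                rec.status[sp] = KEPT
                continue
            if not ivs:
                rec.status[sp] = UNALIGNED
            elif len(ivs) >= 2:
                rec.status[sp] = DROPPED_REDUNDANT
            elif total_length(ivs) > MAX_LENGTH_RATIO * rec.ref.length:
                rec.status[sp] = DROPPED_LENGTH_RATIO
            else:
                rec.status[sp] = KEPT
    return records


def nearest_gene(cne: GenomicInterval, genes: AnnotationSet) -> tuple[str, int] | None:
    """Closest gene body and signed distance (0 on overlap, + downstream).

    Ties on absolute distance are broken by leftmost gene start, then by
    lexicographic gene id, making the assignment deterministic.
    """
    candidates = genes.features("gene", cne.chrom)
    if not candidates:
        logger.warning("no gene on chromosome %s for %s", cne.chrom, cne)
        return None
    best = None
    for iv, gid in candidates:
        if iv.overlaps(cne):
            dist = 0
        elif iv.start >= cne.end:
            dist = iv.start - cne.end
        else:
            dist = -(cne.start - iv.end)  # gene upstream: negative gap
        key = (abs(dist), iv.start, gid or "")
        if best is None or key < best[0]:
            best = (key, gid, dist)
    return best[1], best[2]


def annotation_enrichment(
    accelerated: set,
    universe: set,
    cne_intervals: dict,
    annotations: AnnotationSet,
    feature_types=None,
) -> pd.DataFrame:
    """Per-feature-type 2x2 enrichment of annotation overlap in accelerated CNEs.

    Table: {accelerated, non-accelerated} x {overlaps feature, does not};
    one-sided Fisher's exact test in the enrichment direction, BH-corrected
    across feature types.
    """
    if not accelerated <= universe:
        raise ValueError("accelerated set must be a subset of the universe")
    if feature_types is None:
        feature_types = annotations.feature_types
    rows = []
    others = universe - accelerated
    for ftype in feature_types:
        hit_acc = sum(
            1 for cid in accelerated if annotations.overlaps(ftype, cne_intervals[cid])
        )
        hit_other = sum(
            1 for cid in others if annotations.overlaps(ftype, cne_intervals[cid])
        )
        table = [
            [hit_acc, len(accelerated) - hit_acc],
            [hit_other, len(others) - hit_other],
        ]
        if len(accelerated) == 0:
            p = 1.0
            odds = np.nan
        else:
            odds, p = fisher_exact(table, alternative="greater")
        rows.append(
            dict(
                feature=ftype,
                accel_overlap=table[0][0],
                accel_no_overlap=table[0][1],
                other_overlap=table[1][0],
                other_no_overlap=table[1][1],
                odds_ratio=odds,
                p=p,
            )
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def catalog_to_frame(records: list[CneRecord], species_order=None) -> pd.DataFrame:
    """Flatten the catalog into a TSV-ready table, one row per element."""
    if species_order is None:
        species_order = sorted({sp for r in records for sp in r.projections})
    rows = []
    for rec in records:
        row = {
            "cne_id": rec.cne_id,
            "ref_chrom": rec.ref.chrom,
            "ref_start": rec.ref.start,
            "ref_end": rec.ref.end,
        }
        for sp in species_order:
            ivs = rec.projections.get(sp, [])
            row[f"{sp}_coords"] = ";".join(str(iv) for iv in ivs) if ivs else "."
            row[f"{sp}_status"] = rec.status.get(sp, UNALIGNED)
        for sp, hit in sorted(rec.nearest.items()):
            row[f"{sp}_nearest_gene"] = hit[0] if hit else "."
            row[f"{sp}_gene_distance"] = hit[1] if hit else "."
        rows.append(row)
    return pd.DataFrame(rows)
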