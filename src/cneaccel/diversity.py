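"""Nucleotide diversity (pi) per genomic element from population haplotypes.

Per segregating site the unbiased estimator ``2*p*(1-p)*n/(n-1)`` is used,
with ``p`` the alternate-allele frequency among the ``n`` non-missing
haplotypes at that site; this equals the mean pairwise difference among the
haplotypes.  Element pi divides the site sum by the full element length by
default (a callable-length denominator can be supplied where callability is
known).  Only biallelic SNPs are used; others are dropped with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

__all__ = ["VariantMatrix", "pi_per_element", "summarize_by_class"]

logger = logging.getLogger(__name__)

MIN_SUMMARY_LENGTH = 50   # elements must be strictly longer to enter summaries
LOW_COUNT_N = 10          # classes with <= this many elements are flagged


@dataclass
class VariantMatrix:
    """Biallelic SNP haplotype calls: positions are 0-based internally."""

    chrom: np.ndarray       # per-site chromosome name
    pos: np.ndarray         # per-site 0-based position, strictly increasing per chrom
    ref: np.ndarray
    alt: np.ndarray
    haplotypes: np.ndarray  # (n_sites, n_haplotypes) int8; -1 = missing
    n_dropped: int = 0
    _index: dict = field(default_factory=dict, init=False, repr=False)

    def __post_init__(self):
        for c in np.unique(self.chrom):
            sel = np.nonzero(self.chrom == c)[0]
            p = self.pos[sel]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions must be strictly increasing on {c}")
            self._index[str(c)] = (sel, p)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[1]

    def sites_in(self, element: GenomicInterval) -> np.ndarray:
        """Row indices of sites inside the element."""
        if element.chrom not in self._index:
            return np.array([], dtype=np.intp)
        sel, p = self._index[element.chrom]
        lo = np.searchsorted(p, element.start, side="left")
        hi = np.searchsorted(p, element.end, side="left")
        return sel[lo:hi]

    @classmethod
    def from_vcf(cls, path, samples=None) -> "VariantMatrix":
        """Read haplotypes from a VCF via pysam.

        Haploid calls contribute one haplotype each; diploid calls contribute
        both alleles.  Non-biallelic or non-SNP records are dropped (counted).
        """
        import pysam

        vf = pysam.VariantFile(str(path))
        use = list(samples) if samples is not None else list(vf.header.samples)
        chroms, poss, refs, alts, rows = [], [], [], [], []
        dropped = 0
        for rec in vf:
            if (
                rec.alts is None
                or len(rec.alts) != 1
                or len(rec.ref) != 1
                or len(rec.alts[0]) != 1
                or rec.ref not in "ACGT"
                or rec.alts[0] not in "ACGT"
            ):
                dropped += 1
                continue
            calls = []
            for s in use:
                alleles = rec.samples[s].get("GT", (None,))
                if not isinstance(alleles, tuple):
                    alleles = (alleles,)
                for a in alleles:
                    calls.append(-1 if a is None else int(a))
            chroms.append(rec.chrom)
            poss.append(rec.pos - 1)
            refs.append(rec.ref)
            alts.append(rec.alts[0])
            rows.append(calls)
        if dropped:
            logger.info("dropped %d non-biallelic/non-SNP records", dropped)
        return cls(
            chrom=np.array(chroms, dtype=object),
            pos=np.array(poss, dtype=np.int64),
            ref=np.array(refs, dtype=object),
            alt=np.array(alts, dtype=object),
            haplotypes=np.array(rows, dtype=np.int8) if rows else np.empty((0, 0), np.int8),
            n_dropped=dropped,
        )


def pi_per_element(
    variants: VariantMatrix,
    element: GenomicInterval,
    callable_length: int | None = None,
) -> float:
    """Nucleotide diversity of one element (site sum over element length)."""
    idx = variants.sites_in(element)
    denom = callable_length if callable_length is not None else element.length
    if denom <= 0:
        raise ValueError("element must have positive length")
    if len(idx) == 0:
        return 0.0
    g = variants.haplotypes[idx]
    obs = g >= 0
    ns = obs.sum(axis=1)
    ok = ns >= 2
    if not ok.all():
        logger.info("skipped %d sites with fewer than 2 called haplotypes", (~ok).sum())
    g = g[ok]
    obs = obs[ok]
    ns = ns[ok].astype(float)
    if len(g) == 0:
        return 0.0
    p = np.where(obs, g, 0).sum(axis=1) / ns
    het = 2.0 * p * (1.0 - p) * ns / (ns - 1.0)
    return float(het.sum() / denom)


def summarize_by_class(
    elements_by_class: dict,
    variants: VariantMatrix,
    min_length: int = MIN_SUMMARY_LENGTH,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class median pi over elements strictly longer than ``min_length`` bp.

    Returns (summary, per-element table).  Classes left empty after the length
    filter are absent from the summary (logged); classes with few elements are
    flagged rather than removed.
    """
    per_rows = []
    summary_rows = []
    for cls_name, elements in elements_by_class.items():
        usable = [e for e in elements if e.length > min_length]
        if not usable:
            logger.info("class %s has no element longer than %d bp", cls_name, min_length)
            continue
        pis = [pi_per_element(variants, e) for e in usable]
        for e, v in zip(usable, pis):
            per_rows.append(
                dict(element_class=cls_name, chrom=e.chrom, start=e.start,
                     end=e.end, length=e.length, pi=v)
            )
        summary_rows.append(
            dict(
                element_class=cls_name,
                n=len(usable),
                median_pi=float(np.median(pis)),
                low_count=len(usable) <= LOW_COUNT_N,
            )
        )
    return pd.DataFrame(summary_rows), pd.DataFrame(per_rows)
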