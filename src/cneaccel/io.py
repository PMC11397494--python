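"""Readers and writers for the pipeline's interchange formats.

MAF blocks go through Bio.AlignIO's maf support; the in-memory
:class:`AlignmentBlock` keeps per-species source coordinates so elements can
be projected between genomes.  GFF3 is read with gffutils.  BED, GFF3, VCF and
FASTA writing are plain-text formatting of records this package produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval
from .likelihood import encode_sequence

__all__ = [
    "MafRow",
    "AlignmentBlock",
    "read_maf",
    "write_maf",
    "write_fasta",
    "write_bed",
    "read_bed",
    "write_gff3",
    "write_vcf",
]


@dataclass
class MafRow:
    """One 's' line of a MAF block (``src`` split into species and chromosome)."""

    species: str
    chrom: str
    start: int          # 0-based on the + strand source sequence
    size: int           # ungapped length
    strand: str
    src_size: int
    text: str           # gapped sequence

    @property
    def src(self) -> str:
        return f"{self.species}.{self.chrom}"


@dataclass
class AlignmentBlock:
    """A reference-anchored gapped alignment block over one reference interval."""

    ref_species: str
    rows: dict = field(default_factory=dict)  # species -> MafRow

    @property
    def ncols(self) -> int:
        return len(next(iter(self.rows.values())).text)

    @property
    def ref_row(self) -> MafRow:
        return self.rows[self.ref_species]

    def codes(self) -> dict[str, np.ndarray]:
        """Leaf observation codes per species for the likelihood engine."""
        return {sp: encode_sequence(r.text) for sp, r in self.rows.items()}

    def column_positions(self, species: str) -> np.ndarray:
        """Source position of each column for ``species`` (-1 at gap columns).

        Only + strand rows are supported; the synthetic alignments and the
        reference anchoring used here are all forward strand.
        """
        row = self.rows[species]
        if row.strand != "+":
            raise ValueError("only + strand MAF rows are supported")
        arr = np.frombuffer(row.text.encode("ascii"), dtype=np.uint8)
        nongap = arr != ord("-")
        pos = np.full(len(arr), -1, dtype=np.int64)
        pos[nongap] = row.start + np.arange(nongap.sum())
        return pos

    def ref_positions(self) -> np.ndarray:
        return self.column_positions(self.ref_species)


def _split_src(src: str) -> tuple[str, str]:
    if "." in src:
        sp, chrom = src.split(".", 1)
        return sp, chrom
    return src, src


def read_maf(path, ref_species: str) -> list[AlignmentBlock]:
    blocks = []
    for msa in AlignIO.parse(str(path), "maf"):
        block = AlignmentBlock(ref_species=ref_species)
        for rec in msa:
            sp, chrom = _split_src(rec.id)
            ann = rec.annotations
            block.rows[sp] = MafRow(
                species=sp,
                chrom=chrom,
                start=int(ann["start"]),
                size=int(ann["size"]),
                strand="+" if ann.get("strand", 1) in (1, "+") else "-",
                src_size=int(ann["srcSize"]),
                text=str(rec.seq),
            )
        if ref_species not in block.rows:
            raise ValueError(f"block lacks reference species {ref_species!r}")
        blocks.append(block)
    return blocks


def write_maf(path, blocks: list[AlignmentBlock]) -> None:
    msas = []
    for block in blocks:
        recs = []
        order = [block.ref_species] + [s for s in block.rows if s != block.ref_species]
        for sp in order:
            r = block.rows[sp]
            rec = SeqRecord(Seq(r.text), id=r.src)
            rec.annotations.update(
                start=r.start,
                size=r.size,
                strand=1 if r.strand == "+" else -1,
                srcSize=r.src_size,
            )
            recs.append(rec)
        msas.append(MultipleSeqAlignment(recs))
    with open(path, "w") as fh:
        AlignIO.write(msas, fh, "maf")


def write_fasta(path, sequences: dict[str, str]) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


def write_bed(path, intervals, names=None, scores=None) -> None:
    """BED6 writer (strand from each interval; '.' allowed)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"elem{i}"
            score = scores[i] if scores is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n")


def read_bed(path) -> list[tuple[GenomicInterval, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            strand = f[5] if len(f) > 5 else "."
            name = f[3] if len(f) > 3 else ""
            out.append((GenomicInterval(f[0], int(f[1]), int(f[2]), strand), name))
    return out


def write_gff3(path, features) -> None:
    """Write (seqid, source, type, interval, feature_id, parent) tuples as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, source, ftype, iv, fid, parent in features:
            attrs = f"ID={fid}"
            if parent:
                attrs += f";Parent={parent}"
            strand = iv.strand if iv.strand in "+-" else "."
            fh.write(
                f"{seqid}\t{source}\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t{strand}\t.\t{attrs}\n"
            )


def write_vcf(path, chrom_pos_ref_alt, genotypes: np.ndarray, sample_names) -> None:
    """Minimal haploid VCF: ``genotypes`` is (n_sites, n_samples) of 0/1/-1."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = sorted({c for c, *_ in chrom_pos_ref_alt})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        for (chrom, pos, ref, alt), row in zip(chrom_pos_ref_alt, genotypes):
            gts = "\t".join("." if g < 0 else str(int(g)) for g in row)
            fh.write(f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")
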