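"""Gene models (genePred-style), spliced CDS extraction and codon lookup.

Gene records follow the UCSC genePred column convention:
``name chrom strand txStart txEnd cdsStart cdsEnd exonCount exonStarts exonEnds``
with comma-separated exon coordinate lists.  Noncoding transcripts carry an
empty CDS (``cdsStart == cdsEnd``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .genome import GenomeSequence, revcomp

log = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "FrameError",
    "read_genepred",
    "write_genepred",
    "cds_intervals",
    "spliced_cds",
    "codon_at",
    "collapse_by_name",
]


class FrameError(ValueError):
    """CDS length not divisible by 3 (gene should be skipped with a warning)."""


@dataclass
class GeneModel:
    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.name}: strand must be + or -, got {self.strand!r}")
        if not self.exons:
            self.exons = [(self.tx_start, self.tx_end)]
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.name}: empty exon ({s},{e})")
            if s < self.tx_start or e > self.tx_end:
                raise ValueError(f"{self.name}: exon ({s},{e}) outside tx bounds")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.name}: overlapping exons")
            prev_end = e
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(f"{self.name}: CDS bounds outside tx bounds")

    @property
    def is_coding(self) -> bool:
        return self.cds_end > self.cds_start

    @property
    def tss(self) -> int:
        """Strand-aware transcription start: tx_start on +, tx_end - 1 on -."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1


def read_genepred(path: str) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ValueError(f"{path}:{lineno}: expected >=10 genePred columns")
            name, chrom, strand = fields[0], fields[1], fields[2]
            tx_s, tx_e, cds_s, cds_e, n_ex = map(int, fields[3:8])
            starts = [int(x) for x in fields[8].rstrip(",").split(",") if x]
            ends = [int(x) for x in fields[9].rstrip(",").split(",") if x]
            if len(starts) != n_ex or len(ends) != n_ex:
                raise ValueError(f"{path}:{lineno}: exon count mismatch")
            genes.append(
                GeneModel(name, chrom, strand, tx_s, tx_e, cds_s, cds_e, list(zip(starts, ends)))
            )
    return genes


def write_genepred(genes: list[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            starts = ",".join(str(s) for s, _ in g.exons) + ","
            ends = ",".join(str(e) for _, e in g.exons) + ","
            fh.write(
                f"{g.name}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}"
                f"\t{g.cds_start}\t{g.cds_end}\t{len(g.exons)}\t{starts}\t{ends}\n"
            )


def collapse_by_name(genes: list[GeneModel]) -> list[GeneModel]:
    """Collapse transcript-level records sharing one gene name.

    Isoforms of a gene typically share a TSS; classifying CpG islands against
    every isoform separately would misbrand shared-promoter islands as
    multi-label.  The collapse takes the union transcript span and calls the
    gene coding if any isoform is.
    """
    by_name: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_name.setdefault(g.name, []).append(g)
    out: list[GeneModel] = []
    for name, grp in by_name.items():
        if len(grp) == 1:
            out.append(grp[0])
            continue
        chrom = grp[0].chrom
        strand = grp[0].strand
        tx_s = min(g.tx_start for g in grp)
        tx_e = max(g.tx_end for g in grp)
        coding = [g for g in grp if g.is_coding]
        cds_s = min((g.cds_start for g in coding), default=tx_s)
        cds_e = max((g.cds_end for g in coding), default=tx_s)
        out.append(GeneModel(name, chrom, strand, tx_s, tx_e, cds_s, cds_e, [(tx_s, tx_e)]))
    return sorted(out, key=lambda g: (g.chrom, g.tx_start))


def cds_intervals(gene: GeneModel) -> list[tuple[int, int]]:
    """Exon pieces clipped to the CDS bounds, in genomic order."""
    if not gene.is_coding:
        return []
    out = []
    for s, e in gene.exons:
        s2, e2 = max(s, gene.cds_start), min(e, gene.cds_end)
        if s2 < e2:
            out.append((s2, e2))
    return out


def spliced_cds(genome: GenomeSequence, gene: GeneModel) -> str:
    """Coding sequence in transcript orientation (reverse-complemented on -)."""
    parts = [genome.fetch(gene.chrom, s, e) for s, e in cds_intervals(gene)]
    seq = "".join(parts)
    return revcomp(seq) if gene.strand == "-" else seq


def cds_index_of(gene: GeneModel, genomic_pos: int) -> int:
    """Transcript-oriented CDS index of a genomic position inside the CDS."""
    offset = 0
    ivs = cds_intervals(gene)
    for s, e in ivs:
        if s <= genomic_pos < e:
            plus_index = offset + (genomic_pos - s)
            total = sum(e2 - s2 for s2, e2 in ivs)
            return plus_index if gene.strand == "+" else total - 1 - plus_index
        offset += e - s
    raise ValueError(f"position {gene.chrom}:{genomic_pos} outside CDS of {gene.name}")


def codon_at(
    genome: GenomeSequence, gene: GeneModel, genomic_pos: int
) -> tuple[str, int]:
    """Codon (transcript orientation, read across exon junctions) covering a CDS base.

    Returns ``(codon, offset_in_codon)`` with offset 0..2.  Raises
    :class:`FrameError` when the CDS length is not a multiple of 3, and
    ``ValueError`` when the position is outside the CDS.
    """
    cds = spliced_cds(genome, gene)
    if len(cds) % 3 != 0:
        raise FrameError(f"{gene.name}: CDS length {len(cds)} not divisible by 3")
    i = cds_index_of(gene, genomic_pos)
    start = 3 * (i // 3)
    return cds[start : start + 3], i % 3
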