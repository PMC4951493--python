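"""Annotated-genome data model, GFF3/FASTA I/O and promoter arithmetic.

Coordinates are 0-based half-open throughout the package; GFF3 I/O converts
from and to the 1-based inclusive convention of the format. The translational
start site (TLS) of a gene is its first coding base in reading orientation:
``start`` for a + strand gene and ``end - 1`` for a - strand gene. Promoter
windows are defined relative to the TLS and returned in reading orientation
(reverse-complemented for - strand genes).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.FastaIO import FastaWriter

from ._dna import reverse_complement

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Gene:
    """A CDS feature on a contig, 0-based half-open interval."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein: str | None = None

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.protein is not None:
            prot = self.protein.rstrip("*")
            bad = set(prot) - CANONICAL_AA
            if bad:
                raise ValueError(f"gene {self.gene_id}: non-canonical residues {sorted(bad)}")
            object.__setattr__(self, "protein", prot)

    @property
    def tls(self) -> int:
        """Translational start site: first coding base in reading orientation."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PromoterRegion:
    """A promoter window in reading orientation toward its gene/operon."""

    region_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    sequence: str
    offset_of_tls: int

    def __post_init__(self):
        if len(self.sequence) != self.end - self.start:
            raise ValueError("promoter sequence length must equal its interval length")


@dataclass
class AnnotatedGenome:
    """Contigs plus strand-aware gene annotations; the unit the pipeline scans."""

    genome_id: str
    contigs: list[tuple[str, str]]
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self):
        lengths = {cid: len(seq) for cid, seq in self.contigs}
        seen = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.contig_id not in lengths:
                raise ValueError(f"gene {g.gene_id}: unknown contig {g.contig_id!r}")
            if g.end > lengths[g.contig_id]:
                raise ValueError(f"gene {g.gene_id}: interval exceeds contig {g.contig_id!r}")
        self.genes = sorted(self.genes, key=lambda g: (g.contig_id, g.start))
        self._by_id = {g.gene_id: g for g in self.genes}
        self._contig_seq = dict(self.contigs)

    def gene(self, gene_id: str) -> Gene:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None

    def contig_sequence(self, contig_id: str) -> str:
        return self._contig_seq[contig_id]

    def genes_on(self, contig_id: str) -> list[Gene]:
        return [g for g in self.genes if g.contig_id == contig_id]

    @property
    def proteins(self) -> dict[str, str]:
        return {g.gene_id: g.protein for g in self.genes if g.protein}


def _translate_cds(dna: str, feature_id: str) -> str:
    if len(dna) % 3 != 0:
        raise ValueError(f"CDS length of feature {feature_id!r} is not divisible by 3")
    prot = str(Seq(dna).translate(table=11)).rstrip("*")
    if "*" in prot:
        raise ValueError(f"internal stop codon translating feature {feature_id!r}")
    return prot


def read_genome(fasta_path: str | os.PathLike, gff3_path: str | os.PathLike,
                genome_id: str | None = None) -> AnnotatedGenome:
    """Read a FASTA + GFF3 pair into an :class:`AnnotatedGenome`.

    Only ``CDS`` features are kept. GFF3 1-based inclusive coordinates are
    converted to 0-based half-open. The protein is taken from the
    ``translation`` attribute when present, otherwise translated from the CDS
    with the bacterial code (table 11).
    """
    contigs = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(fasta_path), "fasta")]
    contig_seq = dict(contigs)
    db = gffutils.create_db(str(gff3_path), dbfn=":memory:", keep_order=True,
                            merge_strategy="error")
    genes = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        if feat.seqid not in contig_seq:
            raise ValueError(f"GFF3 feature on contig {feat.seqid!r} absent from FASTA")
        if "ID" not in feat.attributes:
            raise ValueError(f"CDS feature at {feat.seqid}:{feat.start} lacks an ID attribute")
        gid = feat.attributes["ID"][0]
        start, end = feat.start - 1, feat.end  # 1-based inclusive -> 0-based half-open
        if "translation" in feat.attributes:
            prot = feat.attributes["translation"][0]
        else:
            dna = contig_seq[feat.seqid][start:end]
            if feat.strand == "-":
                dna = reverse_complement(dna)
            prot = _translate_cds(dna, gid)
        genes.append(Gene(gid, feat.seqid, start, end, feat.strand, prot))
    if genome_id is None:
        genome_id = os.path.splitext(os.path.basename(str(fasta_path)))[0]
    return AnnotatedGenome(genome_id, contigs, genes)


def write_genome(genome: AnnotatedGenome, fasta_path: str | os.PathLike,
                 gff3_path: str | os.PathLike) -> None:
    """Write FASTA (70-column wrap) and a GFF3 CDS table; inverse of read_genome."""
    with open(fasta_path, "w") as fh:
        writer = FastaWriter(fh, wrap=70)
        writer.write_file(SeqRecord(Seq(seq), id=cid, description="")
                          for cid, seq in genome.contigs)
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genome.genes:
            attrs = f"ID={g.gene_id}"
            if g.protein:
                attrs += f";translation={g.protein}"
            fh.write(f"{g.contig_id}\tregulonscout\tCDS\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t0\t{attrs}\n")


def extract_promoter(genome: AnnotatedGenome, gene_or_id: Gene | str,
                     upstream: int = 250, downstream: int = 50,
                     region_id: str | None = None) -> PromoterRegion:
    """Extract the ``(-upstream, +downstream)`` window around a gene's TLS.

    The window is clamped at contig edges and the sequence is returned in
    reading orientation (reverse-complemented for - strand genes). The - strand
    window mirrors the + strand definition relative to the TLS.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be non-negative")
    gene = genome.gene(gene_or_id) if isinstance(gene_or_id, str) else gene_or_id
    contig = genome.contig_sequence(gene.contig_id)
    t = gene.tls
    if gene.strand == "+":
        lo, hi = t - upstream, t + downstream
    else:
        lo, hi = t - downstream + 1, t + upstream + 1
    lo, hi = max(lo, 0), min(hi, len(contig))
    seq = contig[lo:hi]
    if gene.strand == "+":
        offset = t - lo
    else:
        seq = reverse_complement(seq)
        offset = (hi - 1) - t
    return PromoterRegion(region_id or gene.gene_id, gene.contig_id, lo, hi,
                          gene.strand, seq, offset)


def intergenic_distances(genome: AnnotatedGenome) -> list[tuple[tuple[str, str], int]]:
    """Distances ``start(next) - end(prev)`` for consecutive genes per contig.

    Computed over all adjacent pairs regardless of strand; overlaps yield
    negative distances and are kept. Pairs never span contigs.
    """
    out = []
    for cid, _ in genome.contigs:
        genes = genome.genes_on(cid)
        for prev, nxt in zip(genes, genes[1:]):
            out.append(((prev.gene_id, nxt.gene_id), nxt.start - prev.end))
    return out


def mean_intergenic_distance(genome: AnnotatedGenome) -> float | None:
    """Genome-wide mean intergenic distance, or None if no adjacent pairs exist."""
    dists = [d for _, d in intergenic_distances(genome)]
    if not dists:
        return None
    return sum(dists) / len(dists)


def write_promoters_fasta(promoters: list[PromoterRegion], path: str | os.PathLike) -> None:
    """Export promoter windows as FASTA with locus-tagged headers."""
    with open(path, "w") as fh:
        for p in promoters:
            fh.write(f">{p.region_id}|{p.contig_id}:{p.start}-{p.end}({p.strand})\n")
            for i in range(0, len(p.sequence), 70):
                fh.write(p.sequence[i:i + 70] + "\n")
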