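"""Comparative regulon pipeline: operons, promoter site search, regulon matrix.

Operons are predicted from directons (maximal runs of consecutive same-strand
genes on a contig): adjacent genes merge when their intergenic distance is
strictly below the genome-wide mean intergenic distance. The promoter of an
operon is the window upstream of its lead gene (5'-most in reading
orientation); the best site found there is inherited by every operon member.
A high-scoring site inside an operon, upstream of a non-lead member, triggers
an operon split (revision). The cross-species summary is a matrix of
ortholog groups x species holding the normalised best promoter score, with
species columns ordered by a distance-based TF tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome_model import (AnnotatedGenome, Gene, PromoterRegion, extract_promoter,
                           mean_intergenic_distance)
from .motif_model import BindingMotif, SiteHit, scan_sequence
from .orthology import build_ortholog_groups, newick_leaf_order, reciprocal_best_hits, \
    tf_distance_tree

ABSENT = "absent"


@dataclass
class Operon:
    """A predicted transcription unit; genes listed lead-first (reading order)."""

    operon_id: str
    genome_id: str
    contig_id: str
    strand: str
    gene_ids: list[str]
    promoter: PromoterRegion | None = None
    best_hit: SiteHit | None = None

    @property
    def lead_gene_id(self) -> str:
        return self.gene_ids[0]


def predict_operons(genome: AnnotatedGenome) -> list[Operon]:
    """Merge same-strand neighbours closer than the genome mean intergenic distance.

    Strand switches always split (directon rule); with fewer than two genes in
    the genome the mean is undefined and every gene is its own operon.
    """
    mean = mean_intergenic_distance(genome)
    operons: list[list[Gene]] = []
    for cid, _ in genome.contigs:
        genes = genome.genes_on(cid)
        current: list[Gene] = []
        for g in genes:
            if current and g.strand == current[-1].strand and mean is not None \
                    and (g.start - current[-1].end) < mean:
                current.append(g)
            else:
                if current:
                    operons.append(current)
                current = [g]
        if current:
            operons.append(current)
    out = []
    for i, members in enumerate(operons):
        ordered = members if members[0].strand == "+" else members[::-1]
        out.append(Operon(f"{genome.genome_id}_op{i:04d}", genome.genome_id,
                          members[0].contig_id, members[0].strand,
                          [g.gene_id for g in ordered]))
    return out


def _map_promoter_hits(prom: PromoterRegion, hits: list[SiteHit],
                       width: int, context: str) -> list[SiteHit]:
    """Rewrite promoter-local hits into genomic coordinates plus a TLS offset."""
    mapped = []
    for h in hits:
        if prom.strand == "+":
            gpos, gstrand = prom.start + h.position, h.strand
        else:
            gpos = prom.end - h.position - width
            gstrand = "-" if h.strand == "+" else "+"
        mapped.append(SiteHit(prom.contig_id, gpos, gstrand, h.sequence, h.score,
                              context, offset=h.position - prom.offset_of_tls))
    return mapped


def _best_hit_in_window(genome: AnnotatedGenome, gene: Gene, motif: BindingMotif,
                        upstream: int, downstream: int, context: str) -> SiteHit | None:
    prom = extract_promoter(genome, gene, upstream, downstream, region_id=context)
    hits = scan_sequence(motif, prom.sequence, threshold=-math.inf)
    if not hits:
        return None
    best_local = max(hits, key=lambda h: (h.score, -h.position))
    return _map_promoter_hits(prom, [best_local], motif.width, context)[0]


def search_operon_promoters(genome: AnnotatedGenome, operons: list[Operon],
                            motif: BindingMotif, upstream: int = 250,
                            downstream: int = 50,
                            threshold: float | None = None) -> list[Operon]:
    """Fill each operon's promoter and best site from its lead gene's window.

    The best hit is the maximum-scoring position (ties resolved 5'-most in
    reading orientation); with ``threshold`` set, weaker best hits are dropped.
    Every member gene inherits the operon-level hit by construction.
    """
    out = []
    for op in operons:
        lead = genome.gene(op.lead_gene_id)
        prom = extract_promoter(genome, lead, upstream, downstream, region_id=op.operon_id)
        best = None
        if len(prom.sequence) >= motif.width:
            best = _best_hit_in_window(genome, lead, motif, upstream, downstream,
                                       op.operon_id)
        if best is not None and threshold is not None and best.score < threshold:
            best = None
        out.append(replace(op, promoter=prom, best_hit=best))
    return out


def revise_operons(genome: AnnotatedGenome, operons: list[Operon],
                   motif: BindingMotif, revision_threshold: float | None = None,
                   upstream: int = 250, downstream: int = 50) -> list[Operon]:
    """Split operons before internal genes owning a high-scoring site.

    A non-lead member whose own promoter window contains a hit scoring at
    least ``revision_threshold`` (default 0.75 x the maximum achievable motif
    score) becomes the lead of a new operon. Splits are applied left to right,
    one per operon per pass, and passes repeat until a fixpoint; the result is
    idempotent under re-revision.
    """
    if revision_threshold is None:
        revision_threshold = 0.75 * motif.max_score
    current = [replace(op) for op in operons]
    changed = True
    while changed:
        changed = False
        nxt: list[Operon] = []
        for op in current:
            split_at = None
            for idx, gid in enumerate(op.gene_ids[1:], start=1):
                hit = _best_hit_in_window(genome, genome.gene(gid), motif,
                                          upstream, downstream, op.operon_id)
                if hit is not None and hit.score >= revision_threshold:
                    split_at = idx
                    break
            if split_at is None:
                nxt.append(op)
            else:
                changed = True
                nxt.append(replace(op, gene_ids=op.gene_ids[:split_at],
                                   promoter=None, best_hit=None))
                nxt.append(replace(op, operon_id=op.operon_id + "r",
                                   gene_ids=op.gene_ids[split_at:],
                                   promoter=None, best_hit=None))
        current = nxt
    return search_operon_promoters(genome, current, motif, upstream, downstream)


@dataclass
class RegulonMatrix:
    """Species x ortholog-group grid of best promoter scores plus the TF tree."""

    species: list[str]                  # ordered by TF tree leaf order
    group_ids: list[str]                # reference-genome gene order
    raw_scores: pd.DataFrame            # rows=groups, cols=species; NaN = no site/window
    absent: pd.DataFrame                # boolean: no ortholog in that species
    tf_tree_newick: str
    excluded_species: list[str] = field(default_factory=list)
    normalized: pd.DataFrame = field(init=False)

    def __post_init__(self):
        vals = self.raw_scores.values[~self.absent.values]
        vals = vals[~np.isnan(vals.astype(float))]
        lo, hi = (float(vals.min()), float(vals.max())) if len(vals) else (0.0, 0.0)
        span = hi - lo
        if span > 0:
            self.normalized = (self.raw_scores - lo) / span
        else:
            self.normalized = self.raw_scores.notna().astype(float)
            self.normalized[self.raw_scores.isna()] = np.nan
        self.normalized[self.absent] = np.nan

    def cell(self, group_id: str, species: str):
        """ABSENT, a normalised score in [0, 1], or NaN (ortholog but no window)."""
        if bool(self.absent.loc[group_id, species]):
            return ABSENT
        return float(self.normalized.loc[group_id, species])

    def to_tsv(self) -> str:
        lines = ["group_id\t" + "\t".join(self.species)]
        for gid in self.group_ids:
            row = []
            for sp in self.species:
                v = self.cell(gid, sp)
                row.append(ABSENT if v == ABSENT else
                           ("no_site" if isinstance(v, float) and math.isnan(v)
                            else f"{v:.4f}"))
            lines.append(gid + "\t" + "\t".join(row))
        return "\n".join(lines) + "\n"

    def regulated_pairs(self, min_score_bits: float) -> set[tuple[str, str]]:
        """(species, group) pairs whose best raw promoter score reaches the cutoff."""
        pairs = set()
        for gid in self.group_ids:
            for sp in self.species:
                if bool(self.absent.loc[gid, sp]):
                    continue
                raw = float(self.raw_scores.loc[gid, sp])
                if not math.isnan(raw) and raw >= min_score_bits:
                    pairs.add((sp, gid))
        return pairs


def build_regulon_matrix(genomes: list[AnnotatedGenome], reference: AnnotatedGenome,
                         motif: BindingMotif, tf_gene_id: str,
                         reference_genes: list[str] | None = None,
                         upstream: int = 250, downstream: int = 50,
                         revision_threshold: float | None = None,
                         e_threshold: float = 1e-20) -> RegulonMatrix:
    """Run the full comparative analysis and summarise it as a matrix.

    Species lacking a TF ortholog are excluded from the tree and the matrix
    and reported in ``excluded_species``. Cells hold the best promoter score
    of the operon containing each ortholog, min-max normalised over all
    non-absent cells of the analysis.
    """
    if tf_gene_id not in {g.gene_id for g in reference.genes}:
        raise ValueError(f"TF gene {tf_gene_id!r} not found in the reference genome")
    # TF presence screen
    kept, excluded, tf_proteins = [], [], {}
    rbh_cache: dict[str, dict[str, str]] = {}
    for genome in genomes:
        if genome is reference:
            kept.append(genome)
            tf_proteins[genome.genome_id] = reference.gene(tf_gene_id).protein
            continue
        pairs = dict(reciprocal_best_hits(reference, genome, e_threshold))
        rbh_cache[genome.genome_id] = pairs
        if tf_gene_id in pairs:
            kept.append(genome)
            tf_proteins[genome.genome_id] = genome.gene(pairs[tf_gene_id]).protein
        else:
            excluded.append(genome.genome_id)

    group_ids = reference_genes if reference_genes is not None \
        else [g.gene_id for g in reference.genes if g.protein]
    member_of: dict[tuple[str, str], str] = {}
    for genome in kept:
        if genome is reference:
            for gid in group_ids:
                member_of[genome.genome_id, gid] = gid
        else:
            pairs = rbh_cache[genome.genome_id]
            for gid in group_ids:
                if gid in pairs:
                    member_of[genome.genome_id, gid] = pairs[gid]

    # per-species operon analysis
    gene_to_score: dict[tuple[str, str], float] = {}
    for genome in kept:
        operons = predict_operons(genome)
        operons = revise_operons(genome, operons, motif, revision_threshold,
                                 upstream, downstream)
        for op in operons:
            score = op.best_hit.score if op.best_hit is not None else math.nan
            for gid in op.gene_ids:
                gene_to_score[genome.genome_id, gid] = score

    tree = tf_distance_tree(tf_proteins) if len(tf_proteins) >= 2 \
        else f"({next(iter(tf_proteins))});"
    species = [s for s in newick_leaf_order(tree) if s in tf_proteins] \
        if len(tf_proteins) >= 2 else list(tf_proteins)

    raw = pd.DataFrame(math.nan, index=group_ids, columns=species, dtype=float)
    absent = pd.DataFrame(True, index=group_ids, columns=species, dtype=bool)
    for sp in species:
        for gid in group_ids:
            member = member_of.get((sp, gid))
            if member is None:
                continue
            absent.loc[gid, sp] = False
            raw.loc[gid, sp] = gene_to_score.get((sp, member), math.nan)
    return RegulonMatrix(species, group_ids, raw, absent, tree, excluded)


def operons_to_tsv(operons: list[Operon]) -> str:
    lines = ["operon_id\tcontig\tstrand\tgenes\tbest_site_score\tbest_site_offset"]
    for op in operons:
        score = f"{op.best_hit.score:.3f}" if op.best_hit else "NA"
        offset = str(op.best_hit.offset) if op.best_hit and op.best_hit.offset is not None \
            else "NA"
        lines.append(f"{op.operon_id}\t{op.contig_id}\t{op.strand}\t"
                     f"{','.join(op.gene_ids)}\t{score}\t{offset}")
    return "\n".join(lines) + "\n"


def plot_regulon_heatmap(matrix: RegulonMatrix, path: str) -> None:
    """Render the matrix as a green/red heatmap with absent cells in blue."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import colors

    data = matrix.normalized.values.astype(float).copy()
    fig, ax = plt.subplots(figsize=(1 + 0.5 * len(matrix.species),
                                    1 + 0.3 * len(matrix.group_ids)))
    cmap = colors.LinearSegmentedColormap.from_list("regulon", ["red", "yellow", "green"])
    cmap.set_bad("blue")
    masked = np.ma.masked_invalid(data)
    masked = np.ma.masked_where(matrix.absent.values, masked)
    ax.imshow(masked, cmap=cmap, vmin=0, vmax=1, aspect="auto")
    ax.set_xticks(range(len(matrix.species)), matrix.species, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.group_ids)), matrix.group_ids, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
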