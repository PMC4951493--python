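"""Pairwise protein comparison, reciprocal-best-hit orthology and the TF tree.

Local alignments use Smith-Waterman with BLOSUM62 and affine gaps (open 11,
extend 1, so a gap of length g costs 11 + g). Expect values follow the
Karlin-Altschul formula E = K * m * n * exp(-lambda * S) with the standard
gapped BLOSUM62-11-1 constants (lambda = 0.267, K = 0.041). Orthologs between
two proteomes are unique reciprocal best hits at an E-value cutoff; groups
across many genomes are anchored on a reference proteome (star topology). The
TF tree is neighbour joining on pairwise identity distances.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from math import exp

from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix
from skbio.tree import nj

GAPPED_LAMBDA = 0.267
GAPPED_K = 0.041
GAP_OPEN = 11
GAP_EXTEND = 1

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYBZX*")


def _make_aligner(matrix: str = "BLOSUM62", gap_open: int = GAP_OPEN,
                  gap_extend: int = GAP_EXTEND) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # Biopython charges open+extend for the first gap position; BLAST-style
    # "open 11, extend 1" means a length-g gap costs 11 + g.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


_DEFAULT_ALIGNER = _make_aligner()


@dataclass(frozen=True)
class AlignmentResult:
    query_id: str
    subject_id: str
    score: float
    bit_score: float
    evalue: float
    identity: float       # percent over alignment columns
    alignment_length: int


def _check_protein(seq: str, label: str) -> str:
    if not seq:
        raise ValueError(f"empty protein sequence for {label}")
    seq = seq.upper().rstrip("*")
    bad = set(seq) - _VALID_AA
    if bad:
        raise ValueError(f"unknown residues {sorted(bad)} in {label}")
    return seq


def evalue_from_score(score: float, m: int, n: int,
                      lam: float = GAPPED_LAMBDA, k: float = GAPPED_K) -> float:
    return k * m * n * exp(-lam * score)


def align_pair(protein_a: str, protein_b: str, query_id: str = "a",
               subject_id: str = "b", aligner: Align.PairwiseAligner | None = None,
               search_space: tuple[int, int] | None = None) -> AlignmentResult:
    """Optimal local alignment of two proteins with identity and E-value."""
    a = _check_protein(protein_a, query_id)
    b = _check_protein(protein_b, subject_id)
    al = aligner or _DEFAULT_ALIGNER
    alignment = al.align(a, b)[0]
    score = float(alignment.score)
    counts = alignment.counts()
    length = alignment.length
    identity = 100.0 * counts.identities / length if length else 0.0
    m, n = search_space if search_space else (len(a), len(b))
    ev = evalue_from_score(score, m, n)
    from math import log
    bits = (GAPPED_LAMBDA * score - log(GAPPED_K)) / log(2.0)
    return AlignmentResult(query_id, subject_id, score, bits, ev, identity, length)


def _score_matrix(prots_a: dict[str, str], prots_b: dict[str, str],
                  aligner: Align.PairwiseAligner):
    """Raw SW scores for all pairs; ids in sorted order for determinism."""
    ids_a, ids_b = sorted(prots_a), sorted(prots_b)
    scores = {}
    for ia in ids_a:
        sa = prots_a[ia].upper().rstrip("*")
        for ib in ids_b:
            scores[ia, ib] = float(aligner.score(sa, prots_b[ib].upper().rstrip("*")))
    return ids_a, ids_b, scores


def _unique_best(ids_from, ids_to, scores, transpose=False):
    best = {}
    for i in ids_from:
        ranked = sorted(ids_to,
                        key=lambda j: -(scores[j, i] if transpose else scores[i, j]))
        top = ranked[0]
        top_score = scores[top, i] if transpose else scores[i, top]
        runner = (scores[ranked[1], i] if transpose else scores[i, ranked[1]]) \
            if len(ranked) > 1 else None
        # ties on the best score are conservative: no hit
        if runner is not None and runner == top_score:
            best[i] = None
        else:
            best[i] = (top, top_score)
    return best


def reciprocal_best_hits(genome_a, genome_b, e_threshold: float = 1e-20,
                         aligner: Align.PairwiseAligner | None = None
                         ) -> list[tuple[str, str]]:
    """Unique reciprocal best hits between two proteomes at an E-value cutoff.

    ``genome_a``/``genome_b`` are :class:`AnnotatedGenome` objects or plain
    ``{gene_id: protein}`` mappings. A pair (a, b) is reported iff b is a's
    unique best hit, a is b's unique best hit, and both E-values pass.
    """
    prots_a = genome_a if isinstance(genome_a, dict) else genome_a.proteins
    prots_b = genome_b if isinstance(genome_b, dict) else genome_b.proteins
    if not prots_a or not prots_b:
        return []
    al = aligner or _DEFAULT_ALIGNER
    ids_a, ids_b, scores = _score_matrix(prots_a, prots_b, al)
    best_ab = _unique_best(ids_a, ids_b, scores)
    best_ba = _unique_best(ids_b, ids_a, scores, transpose=True)
    pairs = []
    for a in ids_a:
        hit = best_ab[a]
        if hit is None:
            continue
        b, score = hit
        back = best_ba[b]
        if back is None or back[0] != a:
            continue
        ev = evalue_from_score(score, len(prots_a[a]), len(prots_b[b]))
        if ev <= e_threshold:
            pairs.append((a, b))
    return pairs


@dataclass
class OrthologGroup:
    """Reference-anchored ortholog group: at most one member per species."""

    group_id: str                    # the reference gene id
    anchor_species: str
    members: dict[str, str]          # species -> gene_id (anchor included)

    def __post_init__(self):
        if self.members.get(self.anchor_species) != self.group_id:
            raise ValueError("anchor gene must be a member of its own group")


def build_ortholog_groups(genomes: list, reference, e_threshold: float = 1e-20,
                          reference_genes: list[str] | None = None,
                          aligner: Align.PairwiseAligner | None = None
                          ) -> list[OrthologGroup]:
    """One group per reference gene; members are RBH partners of the anchor.

    Star topology (no transitive closure), mirroring a reference-query
    comparative design. A non-reference gene with no reference RBH partner
    appears in no group.
    """
    if reference not in genomes:
        raise ValueError("reference genome must be among the analysed genomes")
    ref_ids = reference_genes if reference_genes is not None \
        else [g.gene_id for g in reference.genes if g.protein]
    groups = {rid: OrthologGroup(rid, reference.genome_id, {reference.genome_id: rid})
              for rid in ref_ids}
    for genome in genomes:
        if genome is reference:
            continue
        for ref_gene, other_gene in reciprocal_best_hits(reference, genome,
                                                         e_threshold, aligner):
            if ref_gene in groups:
                groups[ref_gene].members[genome.genome_id] = other_gene
    return [groups[rid] for rid in ref_ids]


def groups_to_tsv(groups: list[OrthologGroup]) -> str:
    lines = ["group_id\tspecies\tgene_id"]
    for g in groups:
        for sp in sorted(g.members):
            lines.append(f"{g.group_id}\t{sp}\t{g.members[sp]}")
    return "\n".join(lines) + "\n"


def tf_distance_tree(tf_proteins: dict[str, str],
                     aligner: Align.PairwiseAligner | None = None) -> str:
    """Neighbour-joining tree over TF proteins, as a newick string.

    Pairwise distance is 1 - identity/100 from the optimal local alignment.
    Negative NJ branch lengths are clamped to zero; species are fed in
    lexicographic order so ties resolve deterministically.
    """
    species = sorted(tf_proteins)
    if len(species) < 2:
        raise ValueError("at least two species are required for a TF tree")
    if len(species) == 2:
        a, b = species
        d = 1.0 - align_pair(tf_proteins[a], tf_proteins[b]).identity / 100.0
        return f"({a}:{d / 2:.6f},{b}:{d / 2:.6f});"
    n = len(species)
    dm = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            res = align_pair(tf_proteins[species[i]], tf_proteins[species[j]])
            dm[i][j] = dm[j][i] = 1.0 - res.identity / 100.0
    tree = nj(DistanceMatrix(dm, ids=species), neg_as_zero=True)
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def newick_leaf_order(newick: str) -> list[str]:
    """Leaf names in the order they appear in a newick string."""
    import re
    names = re.findall(r"[(,]([^(),:;]+)", newick.replace(" ", ""))
    return [n for n in names if n]
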