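"""Synthetic multi-species annotated genomes with planted regulatory ground truth.

The generator emulates the statistical structure the pipeline assumes: ortholog
protein families diverged along a species tree, genes organised into operons
with a bimodal intergenic-distance distribution (short within-operon gaps, long
between-operon gaps with a minimum separation), and TF-binding sites sampled
from a motif model planted in the promoter window of regulated lead genes,
optionally with a tandem secondary site at a short gap. Everything is
deterministic given the seed, and every genome round-trips through the
FASTA/GFF3 readers.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from ._dna import BASES, reverse_complement
from .genome_model import AnnotatedGenome, Gene, write_genome
from .motif_model import BindingMotif, motif_from_consensus

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Default regulated operons: the shared SOS core (lexA, recA and the
#: imuA-imuB-dnaE2 translesion-synthesis cassette) plus commonly co-regulated
#: DNA-repair genes (photolyase, excinuclease subunits, a RecQ helicase and an
#: error-prone polymerase), giving a moderately sized regulon.
DEFAULT_REGULON_OPERONS: tuple[tuple[str, ...], ...] = (
    ("lexA",), ("recA",), ("imuA", "imuB", "dnaE2"),
    ("splB",), ("uvrA",), ("uvrB",), ("recQ",), ("dinP",),
)


@dataclass
class CommunityConfig:
    """Study conditions for one synthetic community."""

    n_species: int = 3
    species_tree: str = "random"              # "random" or a newick topology
    divergence: float = 0.15                  # expected substitutions/site per branch
    n_genes: int = 30                         # per genome, regulated families included
    operon_size_probs: tuple[float, ...] = (0.5, 0.25, 0.15, 0.10)  # sizes 1..k
    within_operon_gap_mean: float = 20.0      # geometric, bp
    between_operon_gap_mean: float = 200.0    # min separation + geometric tail, bp
    between_operon_gap_min: int = 160
    gc_content: float = 0.60
    motif_consensus: str = "TGTTC-N4-GAACA"
    arm_information_bits: float = 1.95
    regulon_operons: tuple[tuple[str, ...], ...] = DEFAULT_REGULON_OPERONS
    regulon_presence: dict[str, set[str]] | None = None   # operon lead family -> species
    family_absence: dict[str, set[str]] | None = None     # species -> deleted families
    site_window: tuple[int, int] = (-200, -20)            # site span relative to TLS
    tandem_fraction: float = 0.25
    tandem_gaps: tuple[int, ...] = (1, 2, 3)
    protein_length_range: tuple[int, int] = (120, 300)
    margin: int = 300                         # bare DNA at contig ends
    seed: int = 0

    def validate(self) -> None:
        tail = self.between_operon_gap_mean - self.between_operon_gap_min
        if not self.within_operon_gap_mean < self.between_operon_gap_mean:
            raise ValueError("within-operon mean gap must be below the between-operon "
                             "mean, otherwise the operon distance rule is untestable")
        if tail <= 0:
            raise ValueError("between-operon mean must exceed the minimum separation")
        if abs(sum(self.operon_size_probs) - 1.0) > 1e-9 or \
                any(not 0 <= p <= 1 for p in self.operon_size_probs):
            raise ValueError("operon size probabilities must be in [0,1] and sum to 1")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie in (0, 1)")
        if not 0.0 <= self.tandem_fraction <= 1.0:
            raise ValueError("tandem_fraction must lie in [0, 1]")
        lo, hi = self.site_window
        width = len(self.motif().consensus)
        need = 2 * width + max(self.tandem_gaps) if self.tandem_fraction > 0 else width
        if hi - lo < need:
            raise ValueError("site placement window is too narrow for the motif")
        if hi > 0 or lo >= 0:
            raise ValueError("site window must lie upstream of the TLS (negative offsets)")
        n_regulated = sum(len(op) for op in self.regulon_operons)
        if self.n_genes < n_regulated:
            raise ValueError("n_genes must accommodate every regulated family")

    def motif(self) -> BindingMotif:
        bg = np.array([(1 - self.gc_content) / 2, self.gc_content / 2,
                       self.gc_content / 2, (1 - self.gc_content) / 2])
        return motif_from_consensus(self.motif_consensus, self.arm_information_bits,
                                    background=bg)

    @property
    def species_names(self) -> list[str]:
        return [f"sp{i + 1:02d}" for i in range(self.n_species)]


@dataclass
class TruthTable:
    """Ground truth of one generated community."""

    sites: pd.DataFrame       # species, operon_id, lead_gene, contig, start, strand, sequence, role, gap
    operons: pd.DataFrame     # species, operon_id, gene_id, position_in_operon
    families: pd.DataFrame    # species, gene_id, family
    regulon: pd.DataFrame     # species, family, regulated
    species_tree_newick: str = ""

    def regulated_pairs(self) -> set[tuple[str, str]]:
        sel = self.regulon[self.regulon.regulated]
        return set(zip(sel.species, sel.family))

    def family_of(self) -> dict[tuple[str, str], str]:
        return {(r.species, r.gene_id): r.family for r in self.families.itertuples()}


# ---------------------------------------------------------------------------
# protein evolution

_BLOSUM = substitution_matrices.load("BLOSUM62")


def _conditional_substitution_matrix() -> np.ndarray:
    """P(replacement b | original a), b != a, proportional to 2**(S[a,b]/2)."""
    n = len(AMINO_ACIDS)
    mat = np.zeros((n, n))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            if i != j:
                mat[i, j] = 2.0 ** (_BLOSUM[a, b] / 2.0)
        mat[i] /= mat[i].sum()
    return mat


_COND_SUB = _conditional_substitution_matrix()
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def evolve_protein(sequence: str, expected_subs_per_site: float,
                   seed: int | np.random.Generator = 0) -> str:
    """Evolve a protein by per-site substitution with BLOSUM62-conditional replacement.

    Each site substitutes with probability 1 - exp(-rate); the replacement is
    drawn from the BLOSUM62-conditional distribution and always differs from
    the original residue. Length is preserved.
    """
    if expected_subs_per_site < 0:
        raise ValueError("substitution rate must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    try:
        idx = np.array([_AA_INDEX[a] for a in sequence])
    except KeyError as exc:
        raise ValueError(f"invalid residue {exc.args[0]!r}") from None
    p_sub = 1.0 - math.exp(-expected_subs_per_site)
    hit = rng.random(len(idx)) < p_sub
    out = list(sequence)
    for pos in np.nonzero(hit)[0]:
        out[pos] = AMINO_ACIDS[rng.choice(len(AMINO_ACIDS), p=_COND_SUB[idx[pos]])]
    return "".join(out)


# ---------------------------------------------------------------------------
# species tree

def _random_topology(names: list[str], rng: np.random.Generator):
    nodes: list = list(names)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        nodes.append((left, right))
    return nodes[0]


def _parse_newick_topology(newick: str):
    """Parse a topology-only newick string into nested tuples (lengths ignored)."""
    text = newick.strip().rstrip(";")

    def parse(s: str, i: int):
        if s[i] == "(":
            children = []
            i += 1
            while True:
                child, i = parse(s, i)
                children.append(child)
                if s[i] == ",":
                    i += 1
                    continue
                if s[i] == ")":
                    i += 1
                    break
            while i < len(s) and s[i] not in ",()":
                i += 1
            node = tuple(children) if len(children) > 1 else children[0]
            return node, i
        j = i
        while j < len(s) and s[j] not in ",():":
            j += 1
        name = s[i:j]
        while j < len(s) and s[j] not in ",()":
            j += 1
        return name, j

    node, _ = parse(text, 0)
    return node


def _topology_to_newick(node, length: float) -> str:
    if isinstance(node, str):
        return f"{node}:{length}"
    inner = ",".join(_topology_to_newick(c, length) for c in node)
    return f"({inner}):{length}"


def _evolve_down(node, seq: str, rate: float, rng: np.random.Generator,
                 out: dict[str, str]) -> None:
    if isinstance(node, str):
        out[node] = seq
        return
    for child in node:
        _evolve_down(child, evolve_protein(seq, rate, rng), rate, rng, out)


# ---------------------------------------------------------------------------
# site sampling and promoter sets

def sample_site(motif: BindingMotif, rng: np.random.Generator) -> str:
    cols = [rng.choice(4, p=motif.frequencies[:, l] / motif.frequencies[:, l].sum())
            for l in range(motif.width)]
    return "".join(BASES[c] for c in cols)


def _random_dna(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def planted_promoter_set(n_promoters: int, length: int, gc: float,
                         motif: BindingMotif, window: tuple[int, int] = (-200, -20),
                         seed: int | np.random.Generator = 0
                         ) -> tuple[list[str], list[int]]:
    """Promoter-like sequences each carrying one sampled site in the window.

    Sequences represent ``[-length, 0)`` windows upstream of a TLS; the site
    span falls inside ``window`` (offsets relative to the TLS). Returns the
    sequences and the planted site start index within each sequence.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = window
    W = motif.width
    if hi - lo < W or length + lo < 0:
        raise ValueError("placement window does not fit the promoter length/motif width")
    seqs, positions = [], []
    for _ in range(n_promoters):
        arr = _random_dna(length, gc, rng)
        d = int(rng.integers(lo, hi - W + 2))   # site span within [lo, hi]
        pos = length + d
        site = sample_site(motif, rng)
        for k, b in enumerate(site):
            arr[pos + k] = BASES.index(b)
        seqs.append("".join(BASES[i] for i in arr))
        positions.append(pos)
    return seqs, positions


# ---------------------------------------------------------------------------
# community generation

def _codons_for(protein: str, rng: np.random.Generator) -> str:
    table = CodonTable.unambiguous_dna_by_id[11]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        by_aa.setdefault(aa, []).append(codon)
    parts = [by_aa[a][rng.integers(len(by_aa[a]))] for a in protein]
    parts.append("TAA")
    return "".join(parts)


def generate_community(config: CommunityConfig
                       ) -> tuple[list[AnnotatedGenome], TruthTable]:
    """Generate the annotated genomes and ground truth of one community."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    species = config.species_names
    motif = config.motif()
    W = motif.width
    win_lo, win_hi = config.site_window

    # --- protein families along the species tree
    regulated_families = [f for op in config.regulon_operons for f in op]
    n_background = config.n_genes - len(regulated_families)
    families = regulated_families + [f"fam{i + 1:03d}" for i in range(n_background)]
    topology = _random_topology(list(species), rng) if config.species_tree == "random" \
        else _parse_newick_topology(config.species_tree)
    tree_newick = _topology_to_newick(topology, config.divergence)
    tree_newick = tree_newick.rsplit(":", 1)[0] + ";"

    lo_len, hi_len = config.protein_length_range
    proteins: dict[str, dict[str, str]] = {}
    for fam in families:
        length = int(rng.integers(lo_len, hi_len + 1))
        ancestor = "M" + "".join(AMINO_ACIDS[i]
                                 for i in rng.integers(0, 20, size=length - 1))
        leaves: dict[str, str] = {}
        _evolve_down(topology, ancestor, config.divergence, rng, leaves)
        proteins[fam] = leaves

    # --- operon composition (shared across species, order shuffled per species)
    background_ops: list[tuple[str, ...]] = []
    remaining = list(families[len(regulated_families):])
    while remaining:
        size = int(rng.choice(len(config.operon_size_probs),
                              p=config.operon_size_probs)) + 1
        background_ops.append(tuple(remaining[:size]))
        remaining = remaining[size:]
    all_ops = [(op, True) for op in config.regulon_operons] + \
              [(op, False) for op in background_ops]

    absence = config.family_absence or {}
    presence = config.regulon_presence
    tail_mean = config.between_operon_gap_mean - config.between_operon_gap_min
    clearance = -win_lo + 5   # intergenic bases needed upstream of a regulated lead

    genomes: list[AnnotatedGenome] = []
    site_rows, operon_rows, family_rows, regulon_rows = [], [], [], []

    for sp in species:
        dropped = absence.get(sp, set())
        order = [all_ops[i] for i in rng.permutation(len(all_ops))]
        contig_id = f"{sp}_c1"
        layout = []   # (operon families, regulated?, strand, [(gene, start, end)])
        pos = config.margin
        pending_clearance = 0
        prev_strand = None
        forbid_plus = False   # previous regulated '-' operon owns the shared gap
        for op_families, regulated in order:
            kept_fams = [f for f in op_families if f not in dropped]
            if not kept_fams:
                continue
            is_regulated = regulated and (presence is None or
                                          sp in presence.get(op_families[0], set()))
            strand = "+" if rng.random() < 0.5 else "-"
            # a regulated promoter gap must not double as another operon's
            # promoter: head-to-head arrangements around a planted site would
            # put that site inside the neighbour's search window too
            if forbid_plus and strand == "+":
                strand = "-"
            elif is_regulated and strand == "+" and prev_strand == "-":
                strand = "-"
            forbid_plus = is_regulated and strand == "-"
            prev_strand = strand
            gap = config.between_operon_gap_min + int(rng.geometric(1.0 / tail_mean))
            if is_regulated and strand == "+":
                gap = max(gap, clearance)
            gap = max(gap, pending_clearance)
            pending_clearance = clearance if (is_regulated and strand == "-") else 0
            pos += gap if layout else 0
            genomic_order = kept_fams if strand == "+" else kept_fams[::-1]
            placements = []
            for k, fam in enumerate(genomic_order):
                if k > 0:
                    pos += int(rng.geometric(1.0 / config.within_operon_gap_mean))
                prot = proteins[fam][sp]
                glen = 3 * (len(prot) + 1)
                placements.append((fam, pos, pos + glen))
                pos = pos + glen
            layout.append((kept_fams, is_regulated, strand, placements))
        total_len = pos + max(config.margin, pending_clearance)

        arr = _random_dna(total_len, config.gc_content, rng)
        genes: list[Gene] = []
        gene_intervals = []
        for kept_fams, is_regulated, strand, placements in layout:
            for fam, start, end in placements:
                cds = _codons_for(proteins[fam][sp], rng)
                if strand == "-":
                    cds = reverse_complement(cds)
                arr[start:end] = [BASES.index(b) for b in cds]
                genes.append(Gene(f"{sp}_{fam}", contig_id, start, end, strand,
                                  proteins[fam][sp]))
                gene_intervals.append((start, end))

        # --- plant sites in regulated lead-gene promoter windows
        op_counter = 0
        for kept_fams, is_regulated, strand, placements in layout:
            operon_id = f"{sp}_true_op{op_counter:03d}"
            op_counter += 1
            reading = kept_fams  # lead first by construction
            for rank, fam in enumerate(reading):
                operon_rows.append((sp, operon_id, f"{sp}_{fam}", rank))
            for fam in reading:
                regulon_rows.append((sp, fam, bool(is_regulated)))
            if not is_regulated:
                continue
            lead_fam = reading[0]
            lead = next(p for p in placements if p[0] == lead_fam)
            tls = lead[1] if strand == "+" else lead[2] - 1
            tandem = rng.random() < config.tandem_fraction
            gap = int(rng.choice(config.tandem_gaps)) if tandem else 0
            span = 2 * W + gap if tandem else W
            d = int(rng.integers(win_lo, win_hi - span + 2))
            placed = [(d, sample_site(motif, rng), "primary", gap if tandem else None)]
            if tandem:
                placed.append((d + W + gap, sample_site(motif, rng), "secondary", gap))
            for offset, site, role, site_gap in placed:
                if strand == "+":
                    gstart = tls + offset
                    ins = site
                else:
                    gstart = tls - offset - W + 1
                    ins = reverse_complement(site)
                if any(s < gstart + W and gstart < e for s, e in gene_intervals):
                    raise AssertionError("planted site overlaps a CDS; "
                                         "increase the between-operon separation")
                arr[gstart:gstart + W] = [BASES.index(b) for b in ins]
                site_rows.append((sp, operon_id, f"{sp}_{lead_fam}", contig_id,
                                  gstart, strand, site, role,
                                  site_gap if site_gap is not None else np.nan))
        for fam in families:
            if fam not in dropped:
                family_rows.append((sp, f"{sp}_{fam}", fam))

        contig_seq = "".join(BASES[i] for i in arr)
        genomes.append(AnnotatedGenome(sp, [(contig_id, contig_seq)], genes))

    truth = TruthTable(
        sites=pd.DataFrame(site_rows, columns=["species", "operon_id", "lead_gene",
                                               "contig", "start", "strand",
                                               "sequence", "role", "gap"]),
        operons=pd.DataFrame(operon_rows, columns=["species", "operon_id", "gene_id",
                                                   "position_in_operon"]),
        families=pd.DataFrame(family_rows, columns=["species", "gene_id", "family"]),
        regulon=pd.DataFrame(regulon_rows, columns=["species", "family", "regulated"]),
        species_tree_newick=tree_newick,
    )
    return genomes, truth


def write_community(genomes: list[AnnotatedGenome], truth: TruthTable,
                    outdir: str | os.PathLike) -> None:
    """Write per-species FASTA + GFF3 plus the truth tables as TSV."""
    os.makedirs(outdir, exist_ok=True)
    for genome in genomes:
        write_genome(genome, os.path.join(outdir, f"{genome.genome_id}.fasta"),
                     os.path.join(outdir, f"{genome.genome_id}.gff3"))
    for name in ("sites", "operons", "families", "regulon"):
        getattr(truth, name).to_csv(os.path.join(outdir, f"truth_{name}.tsv"),
                                    sep="\t", index=False)
    with open(os.path.join(outdir, "species_tree.nwk"), "w") as fh:
        fh.write(truth.species_tree_newick + "\n")


# ---------------------------------------------------------------------------
# recovery scoring

@dataclass
class RecoveryScore:
    precision: float | None
    recall: float | None
    confusion: pd.DataFrame    # per family: tp, fp, fn

    @property
    def f1(self) -> float | None:
        if self.precision is None or self.recall is None or \
                (self.precision + self.recall) == 0:
            return None
        return 2 * self.precision * self.recall / (self.precision + self.recall)


def evaluate_recovery(predicted: set[tuple[str, str]], truth: TruthTable
                      ) -> RecoveryScore:
    """Score predicted (species, family) regulated pairs against the truth.

    Undefined denominators are reported as None (NA), never as zero.
    """
    true_pairs = truth.regulated_pairs()
    known_species = set(truth.regulon.species)
    bad = {sp for sp, _ in predicted} - known_species
    if bad:
        raise ValueError(f"predicted species not present in the truth table: {sorted(bad)}")
    tp = predicted & true_pairs
    fp = predicted - true_pairs
    fn = true_pairs - predicted
    precision = len(tp) / len(predicted) if predicted else None
    recall = len(tp) / len(true_pairs) if true_pairs else None
    fams = sorted({f for _, f in true_pairs | predicted})
    confusion = pd.DataFrame(
        [(f, sum(1 for _, x in tp if x == f), sum(1 for _, x in fp if x == f),
          sum(1 for _, x in fn if x == f)) for f in fams],
        columns=["family", "tp", "fp", "fn"])
    return RecoveryScore(precision, recall, confusion)
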