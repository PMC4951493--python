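"""Binding-motif models and sequence-information (Ri) site scoring.

A motif is summarised as per-column base frequencies f(b,l) estimated from a
collection of aligned sites with a background-weighted pseudocount. Each
column contributes an individual-information weight

    Riw(b, l) = 2 + log2 f(b, l)   [bits]

and a candidate site scores the sum of its per-position weights. The
consensus sequence attains the maximum achievable score. Degenerate (N)
positions in scanned sequences score the column-average weight, so draft
assemblies with ambiguity characters remain scannable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._dna import (BASES, BASE_INDEX, SET_TO_IUPAC, encode, expand_iupac_pattern,
                   reverse_complement)

UNIFORM_BACKGROUND = np.full(4, 0.25)


def _revcomp_matrix(m: np.ndarray) -> np.ndarray:
    """Reverse complement of a 4 x W column matrix (A<->T, C<->G, columns reversed)."""
    return m[::-1, ::-1]


def _consensus_from_frequencies(freqs: np.ndarray, tol: float = 1e-9) -> str:
    letters = []
    for col in freqs.T:
        best = col.max()
        tied = frozenset(BASES[i] for i in range(4) if col[i] >= best - tol)
        letters.append(SET_TO_IUPAC[tied])
    return "".join(letters)


@dataclass
class BindingMotif:
    """A TF-binding motif: counts, frequencies and Ri weights over W columns."""

    counts: np.ndarray          # 4 x W, rows in ACGT order
    site_count: float
    background: np.ndarray      # length-4 base probabilities
    pseudocount: float
    frequencies: np.ndarray = field(init=False)
    weights: np.ndarray = field(init=False)       # Riw(b,l) in bits
    consensus: str = field(init=False)
    is_palindromic: bool = field(init=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.shape[0] != 4:
            raise ValueError("count matrix must have 4 rows (ACGT)")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background probabilities must sum to 1")
        denom = self.site_count + self.pseudocount
        self.frequencies = (self.counts + self.pseudocount * self.background[:, None]) / denom
        self.weights = 2.0 + np.log2(self.frequencies)
        self.consensus = _consensus_from_frequencies(self.frequencies)
        self.is_palindromic = bool(np.allclose(self.counts, _revcomp_matrix(self.counts)))
        # N scores the column-average weight
        self._weights_ext = np.vstack([self.weights, self.weights.mean(axis=0)])

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def max_score(self) -> float:
        """Maximum achievable Ri score (attained by the consensus)."""
        return float(self.weights.max(axis=0).sum())

    @property
    def information_content(self) -> np.ndarray:
        """Per-column expected information 2 + sum_b f log2 f, in bits."""
        f = self.frequencies
        return 2.0 + (f * np.log2(f)).sum(axis=0)

    @classmethod
    def from_frequencies(cls, frequencies: np.ndarray, site_count: float = 100.0,
                         background: np.ndarray = UNIFORM_BACKGROUND,
                         pseudocount: float = 0.0) -> "BindingMotif":
        """Build a motif directly from a 4 x W frequency matrix."""
        f = np.asarray(frequencies, dtype=float)
        if not np.allclose(f.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("frequency columns must sum to 1")
        return cls(f * site_count, site_count, background, pseudocount)


@dataclass(frozen=True)
class SiteHit:
    """A scored motif occurrence on a scanned sequence or contig."""

    contig_id: str
    position: int           # 0-based start on + strand coordinates of the scanned axis
    strand: str
    sequence: str           # W-mer in match orientation
    score: float            # Ri, bits
    context: str | None = None  # owning promoter/operon id
    offset: int | None = None   # start relative to the TLS, reading orientation


def build_motif(sites: list[str], pseudocount: float = 1.0,
                background: np.ndarray = UNIFORM_BACKGROUND) -> BindingMotif:
    """Build a :class:`BindingMotif` from equal-length aligned ACGT sites."""
    if not sites:
        raise ValueError("at least one site is required")
    width = len(sites[0])
    counts = np.zeros((4, width))
    for s in sites:
        if len(s) != width:
            raise ValueError("all sites must have equal length")
        enc = encode(s)
        if (enc > 3).any():
            raise ValueError(f"site {s!r} contains non-ACGT characters")
        counts[enc, np.arange(width)] += 1
    return BindingMotif(counts, len(sites), np.asarray(background, float), pseudocount)


def motif_from_consensus(pattern: str, information_bits: float = 1.95,
                         site_count: float = 100.0,
                         background: np.ndarray = UNIFORM_BACKGROUND) -> BindingMotif:
    """Idealised motif from a consensus pattern such as ``TGTTC-N4-GAACA``.

    Specified positions get the stated individual information (bits) on the
    consensus base, i.e. f(cons) = 2**(bits - 2), with the remainder split
    evenly; ``N`` positions are uniform.
    """
    expanded = expand_iupac_pattern(pattern)
    if not 0.0 < information_bits <= 2.0:
        raise ValueError("information_bits must lie in (0, 2]")
    f_cons = 2.0 ** (information_bits - 2.0)
    freqs = np.empty((4, len(expanded)))
    for l, ch in enumerate(expanded):
        if ch == "N":
            freqs[:, l] = 0.25
        elif ch in BASE_INDEX:
            freqs[:, l] = (1.0 - f_cons) / 3.0
            freqs[BASE_INDEX[ch], l] = f_cons
        else:
            raise ValueError(f"consensus pattern may only contain ACGT and N runs, got {ch!r}")
    return BindingMotif.from_frequencies(freqs, site_count=site_count, background=background)


def score_site(motif: BindingMotif, seq: str) -> float:
    """Ri score (bits) of a single W-mer: sum of per-position weights."""
    if len(seq) != motif.width:
        raise ValueError(f"sequence length {len(seq)} != motif width {motif.width}")
    enc = encode(seq)
    return float(motif._weights_ext[enc, np.arange(motif.width)].sum())


def _score_all_positions(motif: BindingMotif, enc: np.ndarray) -> np.ndarray:
    """Ri score at every start position of an encoded sequence (vectorised)."""
    W = motif.width
    n = len(enc) - W + 1
    if n <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(enc, W)
    return motif._weights_ext[windows, np.arange(W)].sum(axis=1)


def scan_sequence(motif: BindingMotif, seq: str, threshold: float = 0.0,
                  both_strands: bool = True, contig_id: str = "",
                  context: str | None = None) -> list[SiteHit]:
    """Report every position/strand scoring at least ``threshold``, by position.

    For a palindromic motif the + and - strand scores of one physical site are
    identical, so each site is reported once with a + strand representative.
    """
    seq = seq.upper()
    W = motif.width
    if len(seq) < W:
        return []
    enc = encode(seq)
    hits = []
    fwd = _score_all_positions(motif, enc)
    for pos in np.nonzero(fwd >= threshold)[0]:
        hits.append(SiteHit(contig_id, int(pos), "+", seq[pos:pos + W],
                            float(fwd[pos]), context))
    if both_strands and not motif.is_palindromic:
        rc = reverse_complement(seq)
        rev = _score_all_positions(motif, encode(rc))
        L = len(seq)
        for rpos in np.nonzero(rev >= threshold)[0]:
            pos = L - int(rpos) - W  # start on the + strand axis
            hits.append(SiteHit(contig_id, pos, "-", rc[rpos:rpos + W],
                                float(rev[rpos]), context))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


@dataclass
class SaturationScan:
    """In-silico saturation mutagenesis of one site under a motif."""

    site: str
    deltas: np.ndarray        # W x 4, score(site) - score(mutant); 0 at the site's own base
    tolerance_bits: float
    classification: list[str] = field(init=False)  # per position: tolerant | essential

    def __post_init__(self):
        self.classification = ["tolerant" if d <= self.tolerance_bits else "essential"
                               for d in self.deltas.max(axis=1)]

    def tolerant_positions(self) -> list[int]:
        return [i for i, c in enumerate(self.classification) if c == "tolerant"]


def saturation_scan(motif: BindingMotif, site: str,
                    tolerance_bits: float = 1e-9) -> SaturationScan:
    """Score change of every single-nucleotide substitution of ``site``.

    deltas[l, b] = score(site) - score(site with position l set to base b);
    positive values mean the substitution lowers the score. A position is
    classified tolerant when no substitution changes the score by more than
    ``tolerance_bits``.
    """
    if len(site) != motif.width:
        raise ValueError(f"site length {len(site)} != motif width {motif.width}")
    enc = encode(site.upper())
    if (enc > 3).any():
        raise ValueError("saturation scan requires an ACGT site")
    own = motif.weights[enc, np.arange(motif.width)]
    deltas = (own[None, :] - motif.weights).T  # W x 4
    return SaturationScan(site.upper(), deltas, tolerance_bits)


@dataclass(frozen=True)
class KnownMotif:
    name: str
    pattern: str            # dashed shorthand, e.g. "GAAC-N4-GTTC"
    geometry: str           # "inverted" | "direct"

    @property
    def expanded(self) -> str:
        return expand_iupac_pattern(self.pattern)


#: Experimentally characterised LexA-binding motifs across bacterial phyla.
KNOWN_MOTIF_LIBRARY: tuple[KnownMotif, ...] = (
    KnownMotif("Firmicutes/Actinobacteria", "GAAC-N4-GTTC", "inverted"),
    KnownMotif("Gammaproteobacteria", "CTGT-N8-ACAG", "inverted"),
    KnownMotif("Alphaproteobacteria", "GTTC-N7-GTTC", "direct"),
    KnownMotif("Verrucomicrobia", "TGTTC-N4-GAACA", "inverted"),
)


def read_sites(path: str) -> list[str]:
    """Read aligned sites from FASTA or a plain one-site-per-line list."""
    sites, current = [], []
    with open(path) as fh:
        text = fh.read()
    if text.lstrip().startswith(">"):
        for line in text.splitlines():
            if line.startswith(">"):
                if current:
                    sites.append("".join(current))
                    current = []
            elif line.strip():
                current.append(line.strip().upper())
        if current:
            sites.append("".join(current))
    else:
        sites = [ln.strip().upper() for ln in text.splitlines() if ln.strip()]
    return sites


def hits_to_bed(hits: list[SiteHit], motif_width: int | None = None) -> str:
    """Render hits as BED6 text (0-based half-open; score = Ri bits x 100, rounded)."""
    lines = []
    for h in hits:
        w = motif_width or len(h.sequence)
        name = h.context or h.sequence
        lines.append(f"{h.contig_id}\t{h.position}\t{h.position + w}\t{name}\t"
                     f"{round(h.score * 100)}\t{h.strand}")
    return "\n".join(lines) + ("\n" if lines else "")


def frequencies_to_tsv(motif: BindingMotif) -> str:
    """Per-position frequencies and information content as TSV (logo data)."""
    ic = motif.information_content
    lines = ["pos\tA\tC\tG\tT\tinformation_bits"]
    for l in range(motif.width):
        f = motif.frequencies[:, l]
        lines.append(f"{l}\t" + "\t".join(f"{x:.6f}" for x in f) + f"\t{ic[l]:.6f}")
    return "\n".join(lines) + "\n"
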