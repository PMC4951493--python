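"""De novo discovery of (optionally palindromic) motifs by ZOOPS EM.

The model is zero-or-one occurrence per sequence: each sequence carries a
motif occurrence with probability gamma, uniformly placed, against a 0-order
background estimated from the input. EM alternates posterior site
responsibilities (E) with count re-estimation (M); in palindromic mode the
expected count matrix is averaged with its reverse complement after every
M-step, which is the exact maximiser under the strand-symmetry constraint, so
the (MAP-penalised) log likelihood remains monotone. Model selection across
widths uses a BIC-penalised log-likelihood ratio (lower is better).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._dna import encode
from .motif_model import BindingMotif, build_motif

_PSEUDOCOUNT = 0.5


@dataclass
class DiscoveryResult:
    """Outcome of one EM run or of a full width scan."""

    motif: BindingMotif
    site_assignments: list[tuple[int, str] | None]   # per sequence: (position, strand) | None
    llr: float                                       # log-likelihood ratio vs background, nats
    significance: float                              # BIC-penalised LLR; lower is better
    gamma: float                                     # estimated fraction of sequences with a site
    objective_trace: list[float] = field(default_factory=list)
    width_scan_table: list[tuple[int, float, float]] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        """True when the motif beats the background model under the BIC criterion."""
        return self.significance < 0.0


def _n_parameters(width: int, palindromic: bool) -> int:
    # free column frequencies (3 per column orbit) + gamma
    cols = -(-width // 2) if palindromic else width
    return 3 * cols + 1


def _symmetrize(counts: np.ndarray) -> np.ndarray:
    return 0.5 * (counts + counts[::-1, ::-1])


def _prepare(seqs: list[str], width: int):
    encs = []
    for i, s in enumerate(seqs):
        if len(s) < width:
            raise ValueError(f"sequence {i} is shorter than the motif width {width}")
        encs.append(encode(s.upper()))
        if (encs[-1] > 3).any():
            raise ValueError(f"sequence {i} contains non-ACGT characters")
    windows = [np.lib.stride_tricks.sliding_window_view(e, width) for e in encs]
    return encs, windows


def _background(encs: list[np.ndarray], symmetric: bool) -> np.ndarray:
    counts = np.bincount(np.concatenate(encs), minlength=4).astype(float) + 1.0
    q = counts / counts.sum()
    if symmetric:
        q = 0.5 * (q + q[::-1])
    return q


def run_em_zoops(seqs: list[str], width: int, palindromic: bool = True,
                 seed_sites: list[tuple[int, int]] | None = None,
                 max_iter: int = 200, tol: float = 1e-6) -> DiscoveryResult:
    """Fit the ZOOPS motif model by EM from the given seed occurrences.

    ``seed_sites`` is a list of (sequence index, position) pairs whose W-mers
    initialise the frequency matrix (MEME-style: 0.5 mass on the seed base).
    The per-iteration penalised objective is recorded and is non-decreasing.
    """
    if width < 4:
        raise ValueError("motif width must be at least 4")
    encs, windows = _prepare(seqs, width)
    q = _background(encs, symmetric=palindromic)
    log_q = np.log(q)
    cols = np.arange(width)
    n_windows = sum(w.shape[0] for w in windows)

    # --- initial frequencies from seeds
    f = np.tile(q[:, None], (1, width))
    if seed_sites:
        seed_counts = np.zeros((4, width))
        for s_idx, pos in seed_sites:
            wmer = encs[s_idx][pos:pos + width]
            seed_counts[wmer, cols] += 1.0
        seed_f = seed_counts / seed_counts.sum(axis=0, keepdims=True)
        f = 0.5 * seed_f + 0.5 * q[:, None]
    if palindromic:
        f = _symmetrize(f)
    gamma = 0.5

    objective_trace: list[float] = []
    prev_obj = -np.inf
    Z_list: list[np.ndarray] = []
    z0_list: list[float] = []
    llr = 0.0
    for _ in range(max_iter):
        log_f = np.log(f)
        logodds = log_f - log_q[:, None]
        llr = 0.0
        Z_list, z0_list = [], []
        for w in windows:
            m = w.shape[0]
            site_ll = logodds[w, cols].sum(axis=1)
            r = np.exp(site_ll)
            denom = (1.0 - gamma) + (gamma / m) * r.sum()
            Z_list.append((gamma / m) * r / denom)
            z0_list.append((1.0 - gamma) / denom)
            llr += np.log(denom)
        prior = _PSEUDOCOUNT * (q[:, None] * log_f).sum()
        obj = llr + prior
        objective_trace.append(float(obj))
        if obj - prev_obj < tol and len(objective_trace) > 1:
            break
        prev_obj = obj
        # --- M-step
        counts = np.zeros((4, width))
        for w, Z in zip(windows, Z_list):
            for l in range(width):
                np.add.at(counts[:, l], w[:, l], Z)
        if palindromic:
            counts = _symmetrize(counts)
        counts += _PSEUDOCOUNT * q[:, None]
        f = counts / counts.sum(axis=0, keepdims=True)
        gamma = float(np.clip(np.mean([1.0 - z0 for z0 in z0_list]), 1e-6, 1.0 - 1e-6))

    # --- hard site assignments and final motif
    assignments: list[tuple[int, str] | None] = []
    assigned_sites: list[str] = []
    for s, Z, z0 in zip(seqs, Z_list, z0_list):
        if 1.0 - z0 > 0.5 and Z.size:
            pos = int(np.argmax(Z))
            assignments.append((pos, "+"))
            assigned_sites.append(s.upper()[pos:pos + width])
        else:
            assignments.append(None)
    if assigned_sites:
        motif = build_motif(assigned_sites, pseudocount=1.0, background=q)
        if palindromic:
            motif = BindingMotif(_symmetrize(motif.counts), motif.site_count, q, 1.0)
    else:
        motif = BindingMotif.from_frequencies(f, site_count=max(gamma * len(seqs), 1.0),
                                              background=q)
    significance = -2.0 * llr + _n_parameters(width, palindromic) * np.log(n_windows)
    return DiscoveryResult(motif, assignments, float(llr), float(significance), gamma,
                           objective_trace)


def _seed_positions(encs: list[np.ndarray], width: int, n_seeds: int,
                    rng: np.random.Generator) -> list[tuple[int, int]]:
    """Deterministic over-represented-k-mer seeds plus random restarts.

    The heuristic counts exact k-mers (k = min(5, width)), ranks them by the
    ratio of observed to background-expected counts, and proposes W-mers whose
    window starts or ends on an occurrence of a top k-mer — an arm of a spaced
    dyad sits at one of the two window edges.
    """
    k = min(5, width)
    q = _background(encs, symmetric=False)
    counts: dict[tuple, list[tuple[int, int]]] = {}
    for s_idx, enc in enumerate(encs):
        kmers = np.lib.stride_tricks.sliding_window_view(enc, k)
        for pos in range(kmers.shape[0]):
            key = tuple(kmers[pos])
            counts.setdefault(key, []).append((s_idx, pos))
    def enrichment(item):
        key, occ = item
        expected = np.prod(q[list(key)]) * sum(len(e) - k + 1 for e in encs)
        return len(occ) / max(expected, 1e-12)
    ranked = sorted(counts.items(), key=enrichment, reverse=True)

    seeds: list[tuple[int, int]] = []
    seen = set()
    n_heuristic = max(n_seeds // 2, 1)
    for _, occurrences in ranked[:3]:
        for s_idx, pos in occurrences:
            for start in (pos, pos - (width - k)):
                if 0 <= start <= len(encs[s_idx]) - width and (s_idx, start) not in seen:
                    seen.add((s_idx, start))
                    seeds.append((s_idx, start))
        if len(seeds) >= n_heuristic:
            break
    seeds = seeds[:n_heuristic]
    while len(seeds) < n_seeds:
        s_idx = int(rng.integers(len(encs)))
        start = int(rng.integers(len(encs[s_idx]) - width + 1))
        if (s_idx, start) not in seen:
            seen.add((s_idx, start))
            seeds.append((s_idx, start))
    return seeds


def discover_motifs(seqs: list[str], w_min: int = 8, w_max: int = 20,
                    palindromic: bool = True, n_seeds: int = 20,
                    seed: int = 0, max_iter: int = 200,
                    tol: float = 1e-6, n_refine: int = 3) -> DiscoveryResult:
    """Scan widths ``w_min..w_max`` and return the best-significance motif.

    For each width, ``n_seeds`` seed occurrences (over-represented-k-mer
    heuristic plus random restarts from ``seed``) get a short trial EM; the
    ``n_refine`` most promising are run to convergence. The winner across all
    widths minimises the BIC-penalised significance. Identical inputs and seed
    give identical results.
    """
    if w_min > w_max:
        raise ValueError("w_min must not exceed w_max")
    if len(seqs) < 2:
        raise ValueError("at least two sequences are required")
    rng = np.random.default_rng(seed)
    best: DiscoveryResult | None = None
    table: list[tuple[int, float, float]] = []
    for width in range(w_min, w_max + 1):
        if any(len(s) < width for s in seqs):
            break
        encs, _ = _prepare(seqs, width)
        seeds = _seed_positions(encs, width, n_seeds, rng)
        trials = [(run_em_zoops(seqs, width, palindromic, [sd], max_iter=3, tol=0.0), sd)
                  for sd in seeds]
        trials.sort(key=lambda t: t[0].significance)
        width_best: DiscoveryResult | None = None
        for _, sd in trials[:n_refine]:
            res = run_em_zoops(seqs, width, palindromic, [sd], max_iter=max_iter, tol=tol)
            if width_best is None or res.significance < width_best.significance:
                width_best = res
        assert width_best is not None
        table.append((width, width_best.llr, width_best.significance))
        if best is None or width_best.significance < best.significance:
            best = width_best
    if best is None:
        raise ValueError("no width in the requested range fits the input sequences")
    best.width_scan_table = table
    return best


def consensus_compatible(pattern: str, consensus: str,
                         max_mismatches: int = 0) -> bool:
    """Does a discovered consensus match a reference pattern (N = free)?

    Positions where the reference has ``N`` are ignored; elsewhere the
    discovered IUPAC letter must intersect the reference base. Up to
    ``max_mismatches`` disagreements are allowed.
    """
    from ._dna import IUPAC_SETS, expand_iupac_pattern
    ref = expand_iupac_pattern(pattern)
    if len(ref) != len(consensus):
        return False
    mism = sum(1 for r, c in zip(ref, consensus.upper())
               if r != "N" and not (IUPAC_SETS[c] & IUPAC_SETS[r]))
    return mism <= max_mismatches


def to_meme_text(motif: BindingMotif, name: str = "MOTIF_1") -> str:
    """Render a motif as a MEME minimal-format text block for interoperability."""
    q = motif.background
    lines = [
        "MEME version 4", "",
        "ALPHABET= ACGT", "",
        "Background letter frequencies",
        f"A {q[0]:.4f} C {q[1]:.4f} G {q[2]:.4f} T {q[3]:.4f}", "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= 4 w= {motif.width} "
        f"nsites= {motif.site_count:.0f}",
    ]
    for l in range(motif.width):
        lines.append(" ".join(f"{x:.6f}" for x in motif.frequencies[:, l]))
    return "\n".join(lines) + "\n"
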