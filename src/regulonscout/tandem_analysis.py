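"""Tandem binding-site arrangements and emergent junction motifs.

Two same-orientation sites a few base pairs apart in one promoter form a
tandem arrangement; the DNA spanning both sites (the junction) can itself
contain an instance of a *different* dyad motif. For inverted-repeat sites
with arms ...GAACA / TGTTC... the inner arms of consecutive sites read
GAACA-(gap)-TGTTC, so a GAAC-Nk-GTTC instance appears exactly when
k = gap + 2: the emergent spacer covers the final A of the upstream site, the
gap, and the initial T of the downstream site.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._dna import expand_iupac_pattern, iupac_guaranteed_match, reverse_complement
from .motif_model import KNOWN_MOTIF_LIBRARY, KnownMotif, SiteHit


@dataclass(frozen=True)
class TandemArrangement:
    """Two same-orientation sites in one promoter plus their junction DNA."""

    site1: SiteHit
    site2: SiteHit
    gap: int
    junction: str

    def __post_init__(self):
        if self.gap < 0:
            raise ValueError("tandem gap must be non-negative")
        if len(self.junction) != len(self.site1.sequence) + len(self.site2.sequence) + self.gap:
            raise ValueError("junction length must equal 2W + gap")


@dataclass(frozen=True)
class JunctionInstance:
    """An occurrence of a known motif inside a tandem junction."""

    motif_name: str
    offset: int
    strand: str
    matched: str


def find_tandem_sites(hits: list[SiteHit], sequence: str, max_gap: int = 10,
                      min_secondary_score: float | None = None
                      ) -> list[TandemArrangement]:
    """All ordered same-orientation site pairs separated by 0..max_gap bp.

    ``hits`` carry positions within ``sequence`` (one promoter). The
    secondary-site score filter is deliberately permissive by default
    (``None``): degenerate downstream sites are biologically meaningful.
    Results are sorted by gap.
    """
    sequence = sequence.upper()
    out = []
    ordered = sorted(hits, key=lambda h: h.position)
    for i, h1 in enumerate(ordered):
        for h2 in ordered[i + 1:]:
            if h1.strand != h2.strand:
                continue
            gap = h2.position - (h1.position + len(h1.sequence))
            if gap < 0 or gap > max_gap:
                continue
            if min_secondary_score is not None and h2.score < min_secondary_score:
                continue
            junction = sequence[h1.position:h2.position + len(h2.sequence)]
            out.append(TandemArrangement(h1, h2, gap, junction))
    out.sort(key=lambda t: t.gap)
    return out


def junction_instances(arrangement: TandemArrangement | str,
                       library: tuple[KnownMotif, ...] = KNOWN_MOTIF_LIBRARY
                       ) -> list[JunctionInstance]:
    """Occurrences of library motifs at any offset of a junction, both strands.

    Matching uses guaranteed-match semantics: an ambiguous junction position
    (e.g. an ``N`` spacer of a consensus-built junction) only matches a
    pattern position that admits every base it could be. On concrete DNA this
    is ordinary IUPAC matching.
    """
    junction = arrangement if isinstance(arrangement, str) else arrangement.junction
    junction = junction.upper()
    rc = reverse_complement(junction)
    out = []
    for entry in library:
        pat = entry.expanded
        w = len(pat)
        for offset in range(len(junction) - w + 1):
            if iupac_guaranteed_match(pat, junction[offset:offset + w]):
                out.append(JunctionInstance(entry.name, offset, "+",
                                            junction[offset:offset + w]))
            if iupac_guaranteed_match(pat, rc[offset:offset + w]):
                rev_offset = len(junction) - offset - w
                out.append(JunctionInstance(entry.name, rev_offset, "-",
                                            rc[offset:offset + w]))
    # palindromic patterns match both strands at the same place; keep one
    seen = set()
    unique = []
    for inst in sorted(out, key=lambda x: (x.motif_name, x.offset, x.strand)):
        key = (inst.motif_name, inst.offset, inst.matched)
        if key not in seen:
            seen.add(key)
            unique.append(inst)
    return unique


def emergence_spacing(site_consensus: str, emergent_pattern: str,
                      gaps: range | list[int] = range(0, 11)) -> list[int]:
    """Gaps at which two tandem consensus sites generate the emergent motif.

    For each gap g the junction ``site + N*g + site`` is built and searched
    for a guaranteed instance of ``emergent_pattern``; the gaps with at least
    one instance are returned in increasing order.
    """
    site = expand_iupac_pattern(site_consensus)
    entry = KnownMotif("emergent", emergent_pattern, "inverted")
    found = []
    for g in sorted(gaps):
        if g < 0:
            raise ValueError("gaps must be non-negative")
        junction = site + "N" * g + site
        if junction_instances(junction, (entry,)):
            found.append(g)
    return found


def tandem_report_tsv(promoter_id: str, arrangements: list[TandemArrangement],
                      library: tuple[KnownMotif, ...] = KNOWN_MOTIF_LIBRARY) -> str:
    lines = ["promoter_id\tsite1_pos\tsite2_pos\tgap\temergent_motifs"]
    for arr in arrangements:
        names = sorted({i.motif_name for i in junction_instances(arr, library)})
        lines.append(f"{promoter_id}\t{arr.site1.position}\t{arr.site2.position}\t"
                     f"{arr.gap}\t{','.join(names) if names else 'none'}")
    return "\n".join(lines) + "\n"
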