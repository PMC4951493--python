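"""Low-level DNA/IUPAC helpers shared across modules."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# IUPAC ambiguity codes -> set of concrete bases
IUPAC_SETS = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
# concrete base-set -> IUPAC code
SET_TO_IUPAC = {v: k for k, v in IUPAC_SETS.items()}

_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes allowed)."""
    try:
        return "".join(_IUPAC_COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid DNA character {exc.args[0]!r} in sequence") from None


def encode(seq: str) -> np.ndarray:
    """Encode ACGT(N) into integers 0..3, N -> 4."""
    table = np.full(256, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    table[ord("N")] = 4
    table[ord("n")] = 4
    out = table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (out < 0).any():
        bad = seq[int(np.argmax(out < 0))]
        raise ValueError(f"invalid DNA character {bad!r} in sequence")
    return out.astype(np.int64)


def expand_iupac_pattern(pattern: str) -> str:
    """Expand shorthand like ``GAAC-N4-GTTC`` into ``GAACNNNNGTTC``.

    Accepts plain IUPAC strings (returned upper-cased) and the dashed
    spacer notation used for spaced-dyad consensus patterns, where ``Nk``
    denotes a run of k unspecified positions.
    """
    out = []
    for part in pattern.upper().split("-"):
        if not part:
            continue
        if part.startswith("N") and part[1:].isdigit():
            out.append("N" * int(part[1:]))
        else:
            for ch in part:
                if ch not in IUPAC_SETS:
                    raise ValueError(f"invalid IUPAC character {ch!r} in pattern {pattern!r}")
            out.append(part)
    expanded = "".join(out)
    if not expanded:
        raise ValueError(f"empty IUPAC pattern {pattern!r}")
    return expanded


def iupac_guaranteed_match(pattern: str, subject: str) -> bool:
    """True if every sequence consistent with ``subject`` matches ``pattern``.

    Each subject position may itself be ambiguous (e.g. an ``N`` spacer in a
    consensus); the match is *guaranteed* when the subject's allowed bases are
    a subset of the pattern's at every position. On concrete ACGT subjects
    this reduces to ordinary IUPAC pattern matching.
    """
    if len(pattern) != len(subject):
        return False
    for p, s in zip(pattern, subject):
        if not IUPAC_SETS[s] <= IUPAC_SETS[p]:
            return False
    return True


def gc_fraction(seq: str) -> float:
    s = seq.upper()
    return (s.count("G") + s.count("C")) / max(len(s), 1)
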