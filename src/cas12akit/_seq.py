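"""Low-level DNA string helpers shared across modules."""

from __future__ import annotations

import re

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# IUPAC nucleotide codes -> the set of plain bases they stand for.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N preserved)."""
    return seq.translate(_COMP)[::-1]


def gc_percent(seq: str) -> float:
    """GC content of *seq* in percent (0-100)."""
    if not seq:
        return 0.0
    gc = sum(1 for b in seq if b in "GCgc")
    return 100.0 * gc / len(seq)


def iupac_regex(pattern: str) -> str:
    """Translate an IUPAC motif into a plain regex character-class string."""
    parts = []
    for code in pattern.upper():
        try:
            bases = IUPAC[code]
        except KeyError:  # pragma: no cover - guarded by config validation
            raise ValueError(f"invalid IUPAC code {code!r} in pattern {pattern!r}")
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


def compile_motifs(patterns) -> "re.Pattern[str]":
    """Compile IUPAC motifs into one overlap-aware (lookahead) regex."""
    alts = "|".join(iupac_regex(p) for p in patterns)
    return re.compile(f"(?=({alts}))")


def find_motif_positions(seq: str, compiled: "re.Pattern[str]"):
    """Yield every start position (overlaps included) of the motif in *seq*."""
    for m in compiled.finditer(seq):
        yield m.start()


def hamming(a: str, b: str, limit: int | None = None) -> int:
    """Hamming distance between equal-length strings, optionally early-exiting
    once *limit* is exceeded (returns limit+1 in that case)."""
    if len(a) != len(b):
        raise ValueError("hamming: length mismatch")
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if limit is not None and d > limit:
                return d
    return d


def has_run(seq: str, base: str, min_run: int) -> bool:
    """True if *seq* contains >= min_run consecutive copies of *base*."""
    return base * min_run in seq


def max_homopolymer(seq: str) -> int:
    """Length of the longest single-base run in *seq*."""
    best = run = 0
    prev = ""
    for b in seq:
        run = run + 1 if b == prev else 1
        prev = b
        best = max(best, run)
    return best
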