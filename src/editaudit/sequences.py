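"""Small sequence utilities: complements, IUPAC matching, PAM handling."""

from __future__ import annotations

import re

import numpy as np

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def check_dna(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    if not seq or any(b not in "ACGT" for b in seq):
        raise ValueError(f"{what} must be non-empty over A/C/G/T, got {seq!r}")
    return seq


def iupac_matches(base: str, code: str) -> bool:
    """True if a concrete genome base satisfies an IUPAC pattern code."""
    return base in IUPAC.get(code, "")


def iupac_regex(pattern: str) -> str:
    """Translate an IUPAC pattern into a character-class regex."""
    parts = []
    for code in pattern.upper():
        opts = IUPAC.get(code)
        if not opts:
            raise ValueError(f"bad IUPAC code {code!r} in pattern {pattern!r}")
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return "".join(parts)


def find_pattern_positions(seq: str, pattern: str) -> list[int]:
    """0-based start positions of all (overlapping) IUPAC pattern matches."""
    rx = re.compile(f"(?=({iupac_regex(pattern)}))")
    return [m.start() for m in rx.finditer(seq)]


def pam_concrete(pattern: str, rng: np.random.Generator) -> str:
    """Draw one concrete PAM satisfying an IUPAC pattern."""
    out = []
    for code in pattern.upper():
        opts = IUPAC.get(code)
        if not opts:
            raise ValueError(f"bad IUPAC code {code!r} in PAM {pattern!r}")
        out.append(opts[int(rng.integers(len(opts)))])
    return "".join(out)
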