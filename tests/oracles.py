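"""Independent brute-force oracles used to validate the fast paths.

These deliberately share no code with the package internals: the scanner
oracle enumerates every window of every length and explores alignments by
plain recursion from the PAM-distal end; the distance oracle walks both
arcs; the Marascuilo oracle scans an alpha grid.
"""

from __future__ import annotations

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"},
    "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}


def rc(seq: str) -> str:
    return "".join(_RC.get(b, "N") for b in reversed(seq))


def _get(s: str, start: int, length: int, circular: bool):
    """``length`` bases beginning at 0-based ``start`` (may be negative or
    run off the end when circular); None if out of bounds on a linear
    sequence."""
    n = len(s)
    if circular:
        return "".join(s[(start + k) % n] for k in range(length))
    if start < 0 or start + length > n:
        return None
    return s[start: start + length]


def best_alignment_bruteforce(spacer: str, window: str, max_total: int,
                              max_gaps: int):
    """Minimal (mismatch+gaps, gaps) global alignment by exhaustive
    recursion; gaps are counted per bulged base.  None if out of bounds."""
    la, lb = len(spacer), len(window)
    best = [None]

    def walk(i, j, mm, gaps):
        if mm + gaps > max_total or gaps > max_gaps:
            return
        if abs((la - i) - (lb - j)) > max_gaps - gaps:
            return
        if i == la and j == lb:
            cand = (mm + gaps, gaps, mm)
            if best[0] is None or cand < best[0]:
                best[0] = cand
            return
        if i < la and j < lb:
            walk(i + 1, j + 1, mm + (spacer[i] != window[j]), gaps)
        if i < la:
            walk(i + 1, j, mm, gaps + 1)  # unpaired spacer base (RNA bulge)
        if j < lb:
            walk(i, j + 1, mm, gaps + 1)  # extra genome base (DNA bulge)

    walk(0, 0, 0, 0)
    return best[0]


def oracle_scan(sequence: str, circular: bool, spacer: str, pam: str = "NGG",
                max_total: int = 6, max_gaps: int = 2):
    """Every PAM-adjacent window on either strand within the bounds.

    Returns {(position_1based_forward, strand): (n_mismatch, n_gap)} keyed
    by the PAM-proximal protospacer end, minimal (cost, gaps) per key.
    """
    n = len(sequence)
    ls = len(spacer)
    hits = {}
    for strand in "+-":
        s = sequence if strand == "+" else rc(sequence)
        for e0 in range(n):
            pam_seq = _get(s, e0 + 1, len(pam), circular)
            if pam_seq is None or any(
                b not in IUPAC_SETS[c] for b, c in zip(pam_seq, pam)
            ):
                continue
            best = None
            for w in range(ls - max_gaps, ls + max_gaps + 1):
                window = _get(s, e0 - w + 1, w, circular)
                if window is None:
                    continue
                r = best_alignment_bruteforce(spacer, window, max_total, max_gaps)
                if r is not None and (best is None or r < best):
                    best = r
            if best is None:
                continue
            total, gaps, mm = best
            pos = e0 + 1 if strand == "+" else n - e0
            hits[(pos, strand)] = (mm, gaps)
    return hits


def circular_distance_bruteforce(a: int, b: int, n: int) -> int:
    """Walk both arcs step by step and take the shorter."""
    forward = 0
    p = a
    while p != b:
        p = p % n + 1
        forward += 1
    backward = 0
    p = a
    while p != b:
        p = (p - 2) % n + 1
        backward += 1
    return min(forward, backward)


def marascuilo_min_alpha_grid(p1, n1, p2, n2, k, grid_size=20000):
    """Smallest alpha on a uniform grid at which |p1-p2| exceeds the
    Marascuilo critical range (independent of the bisection path)."""
    import math

    from scipy.stats import chi2

    diff = abs(p1 - p2)
    var = p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2
    for i in range(1, grid_size):
        alpha = i / grid_size
        cr = math.sqrt(chi2.ppf(1 - alpha, k - 1)) * math.sqrt(var)
        if diff > cr:
            return alpha
    return 1.0
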