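"""PAM-anchored enumeration of candidate nuclease off-target sites.

Cas9 tolerates imperfect spacer/protospacer pairing, so any genomic window
next to a PAM whose best alignment to the 20-nt spacer stays within a
mismatch-plus-bulge budget is a candidate cleavage site.  The scanner
enumerates every such window on both strands of a circular genome and
reports, per PAM-anchored window, the minimal alignment under a
(mismatches + bulged bases, bulged bases) lexicographic objective:

* a substitution costs 1 mismatch;
* a DNA bulge (extra genomic base) or RNA bulge (unpaired spacer base)
  costs 1 per bulged base toward both the gap count and the total budget
  (the additive reading of a "mismatches plus gaps" filter, matching the
  Cas-OFFinder-bulge convention of reporting bulge sizes);
* the PAM itself is anchored and never costs anything.

An alternative convention counting bulge *events* (a contiguous bulge run
costs 1 toward the gap count regardless of length) is available as
``gap_mode="events"`` for comparison.

The alignment is anchored at the PAM-proximal end (the biologically rigid
seed side of the heteroduplex); the PAM-distal end is free, so windows of
20 +/- max_gaps genomic bases are considered implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .records import Genome, OffTargetHit
from .sequences import check_dna, find_pattern_positions, reverse_complement

#: the most-used spacer in the audited experiments (targets mCherry)
MCHERRY_SPACER = "CTGTCCCCTCAGTTCATGTA"
#: canonical 18-bp I-SceI recognition site
ISCEI_SITE = "TAGGGATAACAGGGTAAT"

_INF = 10 ** 9


@dataclass(frozen=True)
class SpacerQuery:
    """A spacer plus scan bounds.

    ``spacer`` is written 5'->3' as on the protospacer strand, PAM 3' of it.
    ``max_mismatch_plus_gap`` bounds mismatches + gap cost; ``max_gaps``
    bounds the gap count alone (bulged bases, or bulge events under
    ``gap_mode="events"``).
    """

    spacer: str
    pam_pattern: str = "NGG"
    max_mismatch_plus_gap: int = 6
    max_gaps: int = 2
    gap_mode: str = "bases"

    def __post_init__(self) -> None:
        object.__setattr__(self, "spacer", check_dna(self.spacer, "spacer"))
        if self.max_mismatch_plus_gap < 0 or self.max_gaps < 0:
            raise ValueError("scan bounds must be non-negative")
        if self.gap_mode not in ("bases", "events"):
            raise ValueError(f"gap_mode must be 'bases' or 'events', not {self.gap_mode!r}")


def _align_anchored(spacer_r: str, site_r: str, max_total: int, max_gaps: int):
    """Best anchored alignment of a reversed spacer against reversed genomic
    context (both starting at the PAM-proximal base).

    Returns (n_mismatch, n_gap, span, ops) or None if no alignment satisfies
    the bounds.  ``ops`` is the PAM-proximal->distal operation string over
    {M, X, D, R} (match, mismatch, DNA bulge, RNA bulge) reversed back to
    5'->3' spacer orientation by the caller.  Bulged *bases* are counted.
    """
    ls, lg = len(spacer_r), len(site_r)
    # D[g][i][j]: min mismatches with g bulged bases, i spacer and j genome
    # bases consumed.  Band |i - j| <= g keeps the table tiny.
    D = [[[_INF] * (lg + 1) for _ in range(ls + 1)] for _ in range(max_gaps + 1)]
    D[0][0][0] = 0
    for g in range(max_gaps + 1):
        for i in range(ls + 1):
            lo = max(0, i - max_gaps)
            hi = min(lg, i + max_gaps)
            for j in range(lo, hi + 1):
                v = D[g][i][j]
                if v >= _INF:
                    continue
                if i < ls and j < lg:
                    cost = 0 if spacer_r[i] == site_r[j] else 1
                    if v + cost < D[g][i + 1][j + 1]:
                        D[g][i + 1][j + 1] = v + cost
                if g < max_gaps:
                    if i < ls and v < D[g + 1][i + 1][j]:  # RNA bulge
                        D[g + 1][i + 1][j] = v
                    if j < lg and v < D[g + 1][i][j + 1]:  # DNA bulge
                        D[g + 1][i][j + 1] = v
    best = None
    for g in range(max_gaps + 1):
        for j in range(max(0, ls - max_gaps), min(lg, ls + max_gaps) + 1):
            mm = D[g][ls][j]
            if mm >= _INF or mm + g > max_total:
                continue
            cand = (mm + g, g, mm, j)
            if best is None or cand < best:
                best = cand
    if best is None:
        return None
    _, g, mm, j_end = best
    # deterministic traceback preferring diagonal, then DNA, then RNA bulge
    ops = []
    i, j, gg, v = ls, j_end, g, mm
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            cost = 0 if spacer_r[i - 1] == site_r[j - 1] else 1
            if D[gg][i - 1][j - 1] == v - cost:
                ops.append("M" if cost == 0 else "X")
                i, j, v = i - 1, j - 1, v - cost
                continue
        if gg > 0 and j > 0 and D[gg - 1][i][j - 1] == v:
            ops.append("D")
            j, gg = j - 1, gg - 1
            continue
        if gg > 0 and i > 0 and D[gg - 1][i - 1][j] == v:
            ops.append("R")
            i, gg = i - 1, gg - 1
            continue
        raise AssertionError("traceback failed")  # pragma: no cover
    return mm, g, j_end, "".join(reversed(ops))


def _align_anchored_events(spacer_r: str, site_r: str, max_total: int,
                           max_gaps: int, max_bulge_len: int = 2):
    """Variant counting bulge *events*: a contiguous run of bulged bases on
    one side costs 1 gap regardless of length (runs capped at
    ``max_bulge_len`` bases).  Returns like :func:`_align_anchored` with
    n_gap = number of events."""
    ls, lg = len(spacer_r), len(site_r)
    width = max_gaps * max_bulge_len
    # state: (events, last op 0=diag 1=D 2=R, i, j) -> min mismatches
    D = {}
    D[(0, 0, 0, 0)] = 0
    order = sorted(
        ((i, j) for i in range(ls + 1) for j in range(lg + 1) if abs(i - j) <= width),
        key=lambda t: (t[0] + t[1], t[0]),
    )
    run_len: dict[tuple, int] = {(0, 0, 0, 0): 0}
    for (i, j) in order:
        for e in range(max_gaps + 1):
            for last in (0, 1, 2):
                key = (e, last, i, j)
                v = D.get(key, _INF)
                if v >= _INF:
                    continue
                rl = run_len.get(key, 0)
                if i < ls and j < lg:
                    cost = 0 if spacer_r[i] == site_r[j] else 1
                    nk = (e, 0, i + 1, j + 1)
                    if v + cost < D.get(nk, _INF):
                        D[nk] = v + cost
                        run_len[nk] = 0
                # DNA bulge (consume genome)
                if j < lg:
                    if last == 1 and rl < max_bulge_len:
                        nk = (e, 1, i, j + 1)
                        if v < D.get(nk, _INF):
                            D[nk] = v
                            run_len[nk] = rl + 1
                    if e < max_gaps:
                        nk = (e + 1, 1, i, j + 1)
                        if v < D.get(nk, _INF):
                            D[nk] = v
                            run_len[nk] = 1
                # RNA bulge (consume spacer)
                if i < ls:
                    if last == 2 and rl < max_bulge_len:
                        nk = (e, 2, i + 1, j)
                        if v < D.get(nk, _INF):
                            D[nk] = v
                            run_len[nk] = rl + 1
                    if e < max_gaps:
                        nk = (e + 1, 2, i + 1, j)
                        if v < D.get(nk, _INF):
                            D[nk] = v
                            run_len[nk] = 1
    best = None
    for (e, last, i, j), mm in D.items():
        if i != ls or mm + e > max_total:
            continue
        cand = (mm + e, e, mm, j)
        if best is None or cand < best:
            best = cand
    if best is None:
        return None
    total, e, mm, j_end = best
    return mm, e, j_end, ""


def _scan_strand(seq: str, n: int, circular: bool, query: SpacerQuery):
    """Scan one strand in local coordinates.

    Yields (e0_canonical, n_mismatch, n_gap, span, ops) where e0 is the
    0-based local position of the PAM-proximal protospacer end.
    """
    spacer = query.spacer
    pam = query.pam_pattern
    ls, lp = len(spacer), len(pam)
    maxw = ls + query.max_gaps if query.gap_mode == "bases" else ls + 2 * query.max_gaps
    if n <= ls + lp:
        raise ValueError("genome shorter than spacer plus PAM")
    pad = maxw + lp
    t = seq + seq[:pad] if circular else seq
    spacer_r = spacer[::-1]
    max_total = query.max_mismatch_plus_gap
    best: dict[int, tuple] = {}
    for i in find_pattern_positions(t, pam):
        e0 = i - 1  # protospacer end, 0-based in t
        if e0 < 0:
            continue
        if circular:
            if e0 < maxw - 1:
                continue  # its wrapped representative lies at e0 + n
            if e0 >= n + maxw - 1:
                continue
        avail = min(maxw, e0 + 1)
        region_r = t[e0 - avail + 1: e0 + 1][::-1]
        # admissible prefilter: unconstrained edit distance never exceeds the
        # constrained mismatch+gap cost
        d = edlib.align(spacer_r, region_r, mode="SHW", task="distance")["editDistance"]
        if d > max_total:
            continue
        if query.gap_mode == "bases":
            res = _align_anchored(spacer_r, region_r, max_total, query.max_gaps)
        else:
            res = _align_anchored_events(spacer_r, region_r, max_total, query.max_gaps)
        if res is None:
            continue
        mm, gap, span, ops = res
        key = e0 % n
        cand = (mm + gap, gap, mm, span, ops)
        if key not in best or cand < best[key]:
            best[key] = cand
    for key, (_, gap, mm, span, ops) in sorted(best.items()):
        yield key, mm, gap, span, ops


def _ops_to_hit(spacer: str, region: str, ops: str) -> tuple[str, str, str]:
    """Render gapped alignment strings (PAM-distal -> PAM-proximal, 5'->3' of
    the spacer) and classify the gap kind."""
    i = j = 0
    a_sp, a_si = [], []
    for op in ops:
        if op in "MX":
            a_sp.append(spacer[i]); a_si.append(region[j]); i += 1; j += 1
        elif op == "D":  # DNA bulge: extra genome base, gap in spacer
            a_sp.append("-"); a_si.append(region[j]); j += 1
        elif op == "R":  # RNA bulge: unpaired spacer base, gap in genome
            a_sp.append(spacer[i]); a_si.append("-"); i += 1
    has_d, has_r = "D" in ops, "R" in ops
    kind = ("mixed" if has_d and has_r else "dna_bulge" if has_d
            else "rna_bulge" if has_r else "none")
    return "".join(a_si), "".join(a_sp), kind


def scan_cas9(genome: Genome, query: SpacerQuery) -> list[OffTargetHit]:
    """Enumerate candidate Cas9 off-target sites on both strands.

    Every PAM-adjacent window whose best anchored alignment to the spacer
    satisfies both bounds is reported exactly once, with the minimal
    (mismatch+gap, gap) alignment.  Circular genomes include origin-spanning
    windows; positions are canonical 1-based forward-strand coordinates of
    the PAM-proximal protospacer end.
    """
    n = len(genome)
    seq = genome.sequence
    hits: list[OffTargetHit] = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for e0, mm, gap, span, ops in _scan_strand(s, n, genome.circular, query):
            # recover the matched local window for alignment rendering
            if strand == "+":
                pos = e0 + 1
            else:
                pos = ((n - e0 - 1) % n) + 1
            start_local = (e0 - span + 1) % n
            window = (s + s)[start_local: start_local + span]
            aligned_site, aligned_spacer, kind = (
                _ops_to_hit(query.spacer, window, ops) if ops else ("", "", "none")
            )
            if ops and gap == 0:
                kind = "none"
            hits.append(
                OffTargetHit(
                    position=pos,
                    strand=strand,
                    n_mismatch=mm,
                    n_gap=gap,
                    gap_kind=kind,
                    aligned_site=aligned_site,
                    aligned_spacer=aligned_spacer,
                    span=span,
                )
            )
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def scan_fixed_site(genome: Genome, site: str, max_mismatch: int = 0) -> list[OffTargetHit]:
    """All windows within ``max_mismatch`` substitutions of a fixed
    recognition site (no gaps), both strands.

    Positions are the 1-based forward-strand start of the matched window.
    """
    import numpy as np

    site = check_dna(site, "site")
    L = len(site)
    n = len(genome)
    if n < L:
        return []
    s = genome.sequence + (genome.sequence[: L - 1] if genome.circular else "")
    arr = np.frombuffer(s.encode(), dtype="S1")
    n_windows = (n if genome.circular else n - L + 1)
    hits: list[OffTargetHit] = []
    for strand, probe in (("+", site), ("-", reverse_complement(site))):
        mm = np.zeros(n_windows, dtype=np.int32)
        for k, b in enumerate(probe):
            mm += arr[k: k + n_windows] != b.encode()
        for start0 in np.nonzero(mm <= max_mismatch)[0]:
            hits.append(
                OffTargetHit(
                    position=int(start0) + 1,
                    strand=strand,
                    n_mismatch=int(mm[start0]),
                    n_gap=0,
                    span=L,
                )
            )
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


# ---------------------------------------------------------------------------
# reporting


def write_hits_bed(hits, genome: Genome, path, name: str = "offtarget") -> None:
    """BED6 export: 0-based half-open protospacer intervals, score = mm+gap."""
    n = len(genome)
    with open(path, "w") as fh:
        for h in hits:
            start, end = h.interval(n)
            fh.write(
                f"{genome.name}\t{start - 1}\t{end}\t{name}\t{h.total}\t{h.strand}\n"
            )


def write_hits_tsv(hits, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "position\tstrand\tn_mismatch\tn_gap\tgap_kind\taligned_site\t"
            "aligned_spacer\n"
        )
        for h in hits:
            fh.write(
                f"{h.position}\t{h.strand}\t{h.n_mismatch}\t{h.n_gap}\t"
                f"{h.gap_kind}\t{h.aligned_site}\t{h.aligned_spacer}\n"
            )
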