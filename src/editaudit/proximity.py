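"""Circular-genome distances from mutations to off-target sites and edits.

Distances are measured on the circle (the shorter of the two arcs) from the
mutation position to the nearest *edge* of a site's occupied interval; a
mutation inside the interval is at distance 0.  Summaries report the
arithmetic mean and the count of mutations within a threshold (default
2 kb), plus 1-kb histogram bins.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .records import MutationRecord, OffTargetHit, ProximityResult


def circular_distance(a: int, b: int, genome_length: int) -> int:
    """Shorter-arc distance between two 1-based positions on the circle."""
    if not 1 <= a <= genome_length or not 1 <= b <= genome_length:
        raise ValueError(
            f"positions ({a}, {b}) outside [1, {genome_length}]"
        )
    d = abs(a - b)
    return min(d, genome_length - d)


def _distance_to_interval(pos: int, start: int, end: int, n: int) -> int:
    """Circular distance from a position to an inclusive interval (which may
    extend past n when wrapping the origin)."""
    s, e = start, end
    p = pos
    if e > n:  # wrapped interval: test both unwrapped representations
        if p <= e - n or p >= s:
            return 0
    elif s <= p <= e:
        return 0
    return min(
        circular_distance(p, ((s - 1) % n) + 1, n),
        circular_distance(p, ((e - 1) % n) + 1, n),
    )


def nearest_offtarget(
    mutations: Sequence[MutationRecord],
    hits: Sequence[OffTargetHit],
    genome_length: int,
    within: int = 2000,
    intended_edit_positions: Optional[dict[str, int]] = None,
) -> tuple[list[ProximityResult], float, int]:
    """Per-mutation distance to the nearest off-target site.

    Returns (results, mean distance, count with distance <= ``within``).
    An empty hit list is an error: widen the scan bounds instead of
    reporting vacuous distances.
    """
    if not hits:
        raise ValueError(
            "no off-target sites supplied; widen the scan bounds "
            "(max mismatches+gaps / max gaps) and rescan"
        )
    intervals = [(h, h.interval(genome_length)) for h in hits]
    results = []
    for m in mutations:
        best = None
        for h, (s, e) in intervals:
            d = _distance_to_interval(m.position, s, e, genome_length)
            if best is None or d < best[0]:
                best = (d, h)
        d, h = best
        edit_pos = (intended_edit_positions or {}).get(m.sample_id)
        results.append(
            ProximityResult(
                mutation_key=m.key,
                nearest_site_position=h.position,
                distance=d,
                distance_to_intended_edit=(
                    None
                    if edit_pos is None
                    else circular_distance(m.position, edit_pos, genome_length)
                ),
            )
        )
    distances = np.array([r.distance for r in results], dtype=float)
    mean = float(distances.mean()) if len(distances) else float("nan")
    n_within = int((distances <= within).sum())
    return results, mean, n_within


def histogram_1kb(results: Sequence[ProximityResult]) -> dict[int, int]:
    """Counts of mutations per 1-kb distance bin (bin i covers
    [1000*i, 1000*i + 999] bp)."""
    out: dict[int, int] = {}
    for r in results:
        out[r.bin_index] = out.get(r.bin_index, 0) + 1
    return dict(sorted(out.items()))


def mean_distance_kb(mean_bp: float) -> int:
    """Means are reported rounded to whole kilobases."""
    return round(mean_bp / 1000)


def write_proximity_tsv(results: Sequence[ProximityResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "position\tref\talt\tnearest_site\tdistance_bp\tbin_1kb\t"
            "distance_to_intended_edit\n"
        )
        for r in results:
            pos, ref, alt = r.mutation_key
            d_int = (
                "" if r.distance_to_intended_edit is None
                else r.distance_to_intended_edit
            )
            fh.write(
                f"{pos}\t{ref}\t{alt}\t{r.nearest_site_position}\t{r.distance}\t"
                f"{r.bin_index}\t{d_int}\n"
            )


def write_summary_json(
    path: str | Path,
    mean_bp: float,
    n_within: int,
    within: int,
    n_mutations: int,
    histogram: dict[int, int],
) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "n_mutations": n_mutations,
                "mean_distance_bp": mean_bp,
                "mean_distance_kb": mean_distance_kb(mean_bp),
                "within_bp": within,
                "n_within": n_within,
                "histogram_1kb": {str(k): v for k, v in histogram.items()},
            },
            indent=1,
        )
        + "\n"
    )


def circular_coordinates(
    genome_length: int,
    mutations: Sequence[MutationRecord] = (),
    hits: Sequence[OffTargetHit] = (),
    intended_edits: Sequence[int] = (),
) -> dict:
    """Ring coordinates (fraction of the circle per item) for circular
    plotting: inner ring intended edits, middle ring mutations, outer ring
    off-target sites."""
    frac = lambda p: (p - 1) / genome_length
    return {
        "genome_length": genome_length,
        "intended_edits": [frac(p) for p in intended_edits],
        "mutations": [frac(m.position) for m in mutations],
        "offtarget_sites": [frac(h.position) for h in hits],
    }
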