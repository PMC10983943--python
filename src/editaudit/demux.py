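"""Ascribe mutations in a pooled sample to member clones.

Clones are pooled at distinct designed fractions (typically 18/32/50%), so
the read fraction of a clone-private mutation estimates its clone's pool
fraction.  Each pooled call is matched against the designed fractions in
*relative* terms (binomial sampling noise scales with the fraction):

* nearest single designed fraction within tolerance  -> ``assigned``;
* else nearest 2-subset sum of designed fractions or 1.0, whichever is
  relatively closer, within tolerance -> ``shared`` / ``parental_like``;
* otherwise ``unassigned``.

Ties between equally distant designed fractions go to the smaller one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .records import MutationRecord, PoolDesign

CATEGORIES = ("assigned", "shared", "parental_like", "unassigned")


@dataclass(frozen=True)
class Assignment:
    record: MutationRecord
    category: str
    clone_id: Optional[str] = None
    clone_ids: tuple[str, ...] = ()  # members of a shared match
    relative_distance: Optional[float] = None


def _rel(observed: float, designed: float) -> float:
    return abs(observed - designed) / designed


def assign_mutations(
    pooled_records: Sequence[MutationRecord], design: PoolDesign
) -> list[Assignment]:
    """Assign each pooled mutation to a clone (or flag it).

    Deterministic given input order; no mutation is both assigned and
    shared (single-clone matches take precedence).
    """
    if not design.members:
        raise ValueError("empty pool design")
    tol = design.tolerance
    singles = sorted(design.members, key=lambda m: (m[1], m[0]))
    pairs = [
        (a, b)
        for idx, a in enumerate(singles)
        for b in singles[idx + 1:]
    ]
    out: list[Assignment] = []
    for rec in pooled_records:
        f = rec.read_fraction
        cands = [
            (_rel(f, frac), frac, cid)
            for cid, frac in singles
            if _rel(f, frac) <= tol
        ]
        if cands:
            d, _, cid = min(cands)  # ties -> smaller designed fraction
            out.append(Assignment(rec, "assigned", clone_id=cid, relative_distance=d))
            continue
        others: list[tuple[float, float, str, tuple[str, ...]]] = []
        for (ca, fa), (cb, fb) in pairs:
            s = fa + fb
            if s <= 1.0 and _rel(f, s) <= tol:
                others.append((_rel(f, s), s, "shared", (ca, cb)))
        if _rel(f, 1.0) <= tol:
            others.append((_rel(f, 1.0), 1.0, "parental_like", ()))
        if others:
            d, _, category, members = min(others)
            out.append(
                Assignment(
                    rec, category, clone_ids=members, relative_distance=d
                )
            )
        else:
            out.append(Assignment(rec, "unassigned"))
    return out


def recovery_rate(
    assignments: Sequence[Assignment], truth: dict[tuple, str]
) -> float:
    """Fraction of truth mutations assigned to their true clone.

    ``truth`` maps (position, ref, alt) of clone-private planted mutations
    to the owning clone id; planted mutations that were never observed in
    the pool count as unrecovered.
    """
    if not truth:
        raise ValueError("empty truth set")
    by_key = {a.record.key: a for a in assignments}
    ok = sum(
        1
        for key, clone_id in truth.items()
        if key in by_key
        and by_key[key].category == "assigned"
        and by_key[key].clone_id == clone_id
    )
    return ok / len(truth)


def write_assignment_report(
    assignments: Sequence[Assignment], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "sample_id\tposition\tref\talt\tread_fraction\tflag\tclone_id\t"
            "shared_with\trelative_distance\n"
        )
        for a in assignments:
            r = a.record
            rd = "" if a.relative_distance is None else f"{a.relative_distance:.4f}"
            fh.write(
                f"{r.sample_id}\t{r.position}\t{r.ref}\t{r.alt}\t"
                f"{r.read_fraction:.6g}\t{a.category}\t{a.clone_id or ''}\t"
                f"{','.join(a.clone_ids)}\t{rd}\n"
            )
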