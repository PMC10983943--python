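"""Synthetic cohorts with the statistical structure the audit assumes.

The generator emulates the study design of a strain-verification experiment:
clones accumulate unintended mutations as a Poisson process over the cell
divisions of an editing protocol, the mutation spectrum is dominated by
single-base substitutions, genomic DNA of several clones is pooled at
designed percentages before sequencing, and the genome may carry planted
degenerate protospacer copies so that an off-target scanner can be scored
against known truth.

Everything is driven by explicit seeds; identical seeds give byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .records import CloneRecord, Genome, MutationRecord, PoolDesign
from .sequences import reverse_complement, pam_concrete

#: per-genome mutation rate per generation for E. coli K-12
#: (2.0e-10 per nt per generation on a 4,641,652-bp chromosome)
DEFAULT_GENOME_RATE = 2.0e-10 * 4_641_652
#: cell divisions from single colony to sequenced culture in one-step editing
DEFAULT_GENERATIONS = 80
#: share of unintended mutations that are single-base substitutions
DEFAULT_SNV_FRACTION = 0.9
#: designed pooling percentages used for pooled gDNA submissions
DEFAULT_POOL_FRACTIONS = (0.18, 0.32, 0.50)

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


@dataclass
class PlantedOffTarget:
    position: int  # 1-based start of the protospacer body on the forward strand
    strand: str
    n_mismatch: int
    n_gap: int
    span: int  # genomic bases occupied by protospacer body (without PAM)

    @property
    def pam_proximal_position(self) -> int:
        """Coordinate a scanner reports for this site (PAM-proximal end)."""
        return self.position + self.span - 1 if self.strand == "+" else self.position


@dataclass
class SyntheticTruth:
    """Ground truth for a generated cohort, written alongside every output."""

    genome_length: int
    planted_offtargets: list[PlantedOffTarget] = field(default_factory=list)
    clone_mutations: dict[str, list[MutationRecord]] = field(default_factory=dict)
    pool_fractions: dict[str, float] = field(default_factory=dict)
    seed: Optional[int] = None

    def validate(self) -> None:
        if sum(self.pool_fractions.values()) > 1.0 + 1e-9:
            raise ValueError("pool fractions sum to more than 1")
        for muts in self.clone_mutations.values():
            for m in muts:
                if m.position > self.genome_length:
                    raise ValueError(
                        f"planted mutation at {m.position} beyond genome end"
                    )


def generate_genome(
    length: int, gc_fraction: float = 0.508, seed: int = 0, name: str = "synthetic"
) -> Genome:
    """Random circular genome with the requested G+C content.

    The default G+C matches the E. coli K-12 chromosome.
    """
    if length <= 0:
        raise ValueError(f"genome length must be positive, got {length}")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError(f"gc_fraction must be within [0, 1], got {gc_fraction}")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    seq = "".join(rng.choice(_BASES, size=length, p=p))
    return Genome(sequence=seq, circular=True, name=name)


def _apply_edits(spacer: str, edits: Sequence[tuple], rng: np.random.Generator):
    """Build a degenerate protospacer body from a spacer and edit specs.

    Edit specs (0-based offsets into the spacer):
      ("sub", i)            substitute position i with a random different base
      ("sub", i, base)      substitute position i with the given base
      ("dna_bulge", i, base) insert a base into the genomic copy before spacer[i]
      ("rna_bulge", i)      delete spacer position i from the genomic copy
    Returns (site_sequence, n_mismatch, n_gap).
    """
    if len(edits) > len(spacer):
        raise ValueError("more edits than spacer positions")
    chars: list[Optional[str]] = list(spacer)
    inserts: dict[int, str] = {}
    n_mm = n_gap = 0
    for spec in edits:
        kind = spec[0]
        i = spec[1]
        if not 0 <= i < len(spacer):
            raise ValueError(f"edit offset {i} outside spacer")
        if kind == "sub":
            base = spec[2] if len(spec) > 2 else None
            if base is None:
                others = [b for b in "ACGT" if b != spacer[i]]
                base = others[rng.integers(len(others))]
            if chars[i] is None:
                raise ValueError(f"conflicting edits at spacer offset {i}")
            if base == spacer[i]:
                raise ValueError(f"substitution at offset {i} must change the base")
            chars[i] = base
            n_mm += 1
        elif kind == "dna_bulge":
            base = spec[2] if len(spec) > 2 else "ACGT"[rng.integers(4)]
            inserts[i] = inserts.get(i, "") + base
            n_gap += 1
        elif kind == "rna_bulge":
            if chars[i] is None:
                raise ValueError(f"duplicate rna_bulge at spacer offset {i}")
            chars[i] = None
            n_gap += 1
        else:
            raise ValueError(f"unknown edit kind {kind!r}")
    out = []
    for i in range(len(spacer) + 1):
        if i in inserts:
            out.append(inserts[i])
        if i < len(spacer) and chars[i] is not None:
            out.append(chars[i])
    return "".join(out), n_mm, n_gap


def plant_protospacer(
    genome: Genome,
    spacer: str,
    position: int,
    strand: str = "+",
    edits: Sequence[tuple] = (),
    pam_pattern: str = "NGG",
    seed: int = 0,
    existing: Optional[list[PlantedOffTarget]] = None,
) -> tuple[Genome, PlantedOffTarget]:
    """Overwrite genome bases with a degenerate protospacer copy plus PAM.

    ``position`` is the 1-based start of the protospacer body on the forward
    strand.  On the + strand the PAM is written immediately 3' of the body;
    on the - strand the forward sequence carries the reverse complement with
    the PAM 5' of it.  Planted sites may not overlap previously planted ones
    (pass the accumulating truth list via ``existing``).

    The returned truth entry stores the *intended* mismatch/bulge counts; a
    scanner may legitimately report a cheaper alternative alignment.
    """
    rng = np.random.default_rng(seed)
    site, n_mm, n_gap = _apply_edits(spacer, edits, rng)
    pam = pam_concrete(pam_pattern, rng)
    # the protospacer body occupies [position, position+span-1] on the
    # forward strand for both orientations; the PAM sits 3' of the body in
    # protospacer orientation (downstream for +, upstream-as-revcomp for -)
    if strand == "+":
        block = site + pam
        block_start0 = position - 1
    else:
        block = reverse_complement(site + pam)
        block_start0 = position - 1 - len(pam)
    start0 = block_start0
    end0 = start0 + len(block)  # half-open, forward strand
    if not genome.circular and (end0 > len(genome) or start0 < 0):
        raise ValueError("protospacer+PAM does not fit at this position")
    if existing:
        for prev in existing:
            if prev.strand == "+":
                ps = prev.position - 1
                pe = ps + prev.span + len(pam)
            else:
                ps = prev.position - 1 - len(pam)
                pe = prev.position - 1 + prev.span
            if start0 < pe and ps < end0:
                raise ValueError(
                    f"planted site at {position} overlaps existing plant at "
                    f"{prev.position}"
                )
    n = len(genome)
    arr = list(genome.sequence)
    for k, b in enumerate(block):
        arr[(start0 + k) % n] = b
    new_seq = "".join(arr)
    truth = PlantedOffTarget(
        position=position, strand=strand, n_mismatch=n_mm, n_gap=n_gap, span=len(site)
    )
    if existing is not None:
        existing.append(truth)
    return Genome(new_seq, circular=genome.circular, name=genome.name), truth


def simulate_clones(
    n_clones: int,
    genome: Genome,
    genome_rate: float = DEFAULT_GENOME_RATE,
    generations: int = DEFAULT_GENERATIONS,
    snv_fraction: float = DEFAULT_SNV_FRACTION,
    seed: int = 0,
    group_label: str = "control",
    clone_prefix: str = "clone",
    intended_edit_position: Optional[int] = None,
    spacer_id: Optional[str] = None,
) -> tuple[list[CloneRecord], SyntheticTruth]:
    """Simulate a roster of clones carrying Poisson mutation loads.

    Per-clone unintended-mutation counts are Poisson(genome_rate x
    generations); positions are uniform on the circle; each mutation is a
    single-base substitution with probability ``snv_fraction`` and otherwise
    a 1-bp insertion or deletion (equally likely).
    """
    if genome_rate < 0 or generations < 0:
        raise ValueError("genome_rate and generations must be non-negative")
    if not 0.0 <= snv_fraction <= 1.0:
        raise ValueError("snv_fraction must be within [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(genome)
    counts = rng.poisson(genome_rate * generations, size=n_clones)
    clones: list[CloneRecord] = []
    truth = SyntheticTruth(genome_length=n, seed=seed)
    for i, c in enumerate(counts):
        clone_id = f"{clone_prefix}_{i:05d}"
        muts: list[MutationRecord] = []
        for _ in range(int(c)):
            pos = int(rng.integers(1, n + 1))
            ref = genome.base(pos)
            if rng.random() < snv_fraction:
                alt = "ACGT"[(("ACGT".index(ref)) + int(rng.integers(1, 4))) % 4]
                muts.append(
                    MutationRecord(clone_id, pos, ref, alt, "SNV", 1.0)
                )
            elif rng.random() < 0.5:
                base = "ACGT"[rng.integers(4)]
                muts.append(
                    MutationRecord(clone_id, pos, "", base, "insertion", 1.0)
                )
            else:
                muts.append(
                    MutationRecord(clone_id, pos, ref, "", "deletion", 1.0)
                )
        muts.sort(key=lambda m: m.position)
        clones.append(
            CloneRecord(
                clone_id=clone_id,
                group_label=group_label,
                intended_edit_position=(
                    None if group_label == "control" else intended_edit_position
                ),
                spacer_id=spacer_id,
                unintended_mutations=muts,
            )
        )
        truth.clone_mutations[clone_id] = muts
    truth.validate()
    return clones, truth


def simulate_pools(
    clones: Sequence[CloneRecord],
    design: PoolDesign,
    depth: int = 100,
    seed: int = 0,
) -> list[MutationRecord]:
    """Pool clone gDNA at designed fractions and emit one mutation table.

    Each mutation's observed read fraction is Binomial(depth, f)/depth where
    f is the summed designed fraction of the clones that carry it; mutations
    drawing zero reads are unobserved and omitted.  Designed fractions not
    covered by the roster are treated as unsequenced carrier.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    roster = {c.clone_id: c for c in clones}
    for clone_id, _ in design.members:
        if clone_id not in roster:
            raise ValueError(f"clone {clone_id!r} in pool design but not in roster")
    rng = np.random.default_rng(seed)
    fractions = design.fractions
    by_key: dict[tuple, float] = {}
    classes: dict[tuple, tuple[str, str, str]] = {}
    for clone_id, frac in design.members:
        for m in roster[clone_id].unintended_mutations:
            by_key[m.key] = by_key.get(m.key, 0.0) + frac
            classes[m.key] = (m.ref, m.alt, m.mut_class)
    records: list[MutationRecord] = []
    for key in sorted(by_key):
        f = min(by_key[key], 1.0)
        reads = int(rng.binomial(depth, f))
        if reads == 0:
            continue
        ref, alt, mut_class = classes[key]
        records.append(
            MutationRecord(
                sample_id=design.pool_id,
                position=key[0],
                ref=ref,
                alt=alt,
                mut_class=mut_class,
                read_fraction=reads / depth,
            )
        )
    return records


# ---------------------------------------------------------------------------
# truth / parameter round-tripping


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Serialize a SyntheticTruth to JSON (mutations as plain tuples)."""
    payload = {
        "genome_length": truth.genome_length,
        "seed": truth.seed,
        "planted_offtargets": [dataclasses.asdict(p) for p in truth.planted_offtargets],
        "pool_fractions": truth.pool_fractions,
        "clone_mutations": {
            cid: [
                [m.position, m.ref, m.alt, m.mut_class]
                for m in muts
            ]
            for cid, muts in truth.clone_mutations.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_truth(path: str | Path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    truth = SyntheticTruth(
        genome_length=payload["genome_length"],
        seed=payload["seed"],
        planted_offtargets=[
            PlantedOffTarget(**p) for p in payload["planted_offtargets"]
        ],
        pool_fractions=dict(payload["pool_fractions"]),
        clone_mutations={
            cid: [
                MutationRecord(cid, pos, ref, alt, mut_class, 1.0)
                for pos, ref, alt, mut_class in muts
            ]
            for cid, muts in payload["clone_mutations"].items()
        },
    )
    truth.validate()
    return truth


def write_run_sidecar(path: str | Path, seed: int, **params) -> None:
    """Echo the seed and generator parameters next to every synthetic output."""
    Path(path).write_text(
        json.dumps({"seed": seed, **params}, indent=1, sort_keys=True, default=str)
        + "\n"
    )
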