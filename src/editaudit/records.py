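"""Core record types shared across the audit pipeline.

Coordinates are 1-based on the forward strand of the (circular) reference,
matching Breseq/GenomeDiff convention.  Internal arithmetic that needs
0-based half-open intervals converts at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

MUT_CLASSES = ("SNV", "insertion", "deletion", "MOB", "other")
GROUP_LABELS = ("cas9", "lambda_red", "isceI", "control")


@dataclass(frozen=True)
class Genome:
    """A reference sequence with a circularity flag."""

    sequence: str
    circular: bool = True
    name: str = "genome"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based position (wraps if circular)."""
        n = len(self.sequence)
        if self.circular:
            return self.sequence[(position - 1) % n]
        if not 1 <= position <= n:
            raise ValueError(f"position {position} outside linear genome of {n} bp")
        return self.sequence[position - 1]


@dataclass(frozen=True)
class MutationRecord:
    """One called variant from a (possibly pooled) sequenced sample.

    ``ref`` is empty for a pure insertion, ``alt`` empty for a deletion.
    ``read_fraction`` is the fraction of aligned reads supporting the call.
    """

    sample_id: str
    position: int
    ref: str
    alt: str
    mut_class: str
    read_fraction: float
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.mut_class not in MUT_CLASSES:
            raise ValueError(
                f"mut_class {self.mut_class!r} not one of {MUT_CLASSES}"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.position}")
        if not 0.0 < self.read_fraction <= 1.0:
            raise ValueError(
                f"read_fraction must be in (0, 1], got {self.read_fraction}"
            )

    @property
    def key(self) -> tuple[int, str, str]:
        """Identity key used for parental/intended subtraction."""
        return (self.position, self.ref, self.alt)

    def with_flag(self, flag: str) -> "MutationRecord":
        if flag in self.flags:
            return self
        return replace(self, flags=tuple(sorted((*self.flags, flag))))


@dataclass
class CloneRecord:
    """An edited (or control) clone and its unintended-mutation set."""

    clone_id: str
    group_label: str
    intended_edit_position: Optional[int] = None
    spacer_id: Optional[str] = None
    unintended_mutations: list[MutationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group_label == "control" and self.intended_edit_position is not None:
            raise ValueError("control clones carry no intended edit")

    @property
    def has_unintended(self) -> bool:
        return len(self.unintended_mutations) > 0


@dataclass(frozen=True)
class GeneFeature:
    """One gene/CDS feature. ``start`` <= ``end`` 1-based inclusive; strand +/-."""

    feature_id: str
    start: int
    end: int
    strand: str
    frame: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad feature interval [{self.start}, {self.end}]")

    @property
    def start_codon_position(self) -> int:
        """1-based genomic position of the first base of the start codon."""
        return self.start if self.strand == "+" else self.end

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class GenomeAnnotation:
    features: list[GeneFeature]
    genome_length: int
    circular: bool = True

    def __post_init__(self) -> None:
        for f in self.features:
            if f.end > self.genome_length:
                raise ValueError(
                    f"feature {f.feature_id} extends beyond genome "
                    f"({f.end} > {self.genome_length})"
                )

    def overlapping(self, position: int) -> list[GeneFeature]:
        return [f for f in self.features if f.contains(position)]


@dataclass(frozen=True)
class OffTargetHit:
    """A genomic locus resembling the spacer (or fixed site).

    ``position`` is the 1-based coordinate of the PAM-proximal end of the
    matched protospacer on the forward strand; for fixed-site hits it is the
    1-based start of the matched window.  ``span`` is the number of genomic
    bases the alignment consumed, so the occupied forward-strand interval is
    recoverable for either strand.
    """

    position: int
    strand: str
    n_mismatch: int
    n_gap: int
    gap_kind: str = "none"
    aligned_site: str = ""
    aligned_spacer: str = ""
    span: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.gap_kind not in ("none", "dna_bulge", "rna_bulge", "mixed"):
            raise ValueError(f"bad gap_kind {self.gap_kind!r}")
        if self.aligned_site and len(self.aligned_site) != len(self.aligned_spacer):
            raise ValueError("aligned strings must have equal length")

    @property
    def total(self) -> int:
        return self.n_mismatch + self.n_gap

    def interval(self, genome_length: int) -> tuple[int, int]:
        """1-based inclusive (start, end) of the occupied forward-strand
        interval; end may exceed genome_length on a circular wrap."""
        span = self.span or len(self.aligned_site.replace("-", ""))
        if self.strand == "+":
            end = self.position
            start = end - span + 1
        else:
            start = self.position
            end = start + span - 1
        if start < 1:
            start += genome_length
            end += genome_length
        return start, end


@dataclass
class PoolDesign:
    """Designed mixing fractions of clones within one pooled gDNA sample."""

    pool_id: str
    members: list[tuple[str, float]]
    tolerance: float = 0.25

    def __post_init__(self) -> None:
        import warnings

        if not self.members:
            raise ValueError("pool design must contain at least one clone")
        total = sum(f for _, f in self.members)
        if total > 1.0 + 1e-9:
            raise ValueError(f"pool fractions sum to {total:.3f} > 1")
        if not 0 < self.tolerance < 1:
            raise ValueError("tolerance must be in (0, 1)")
        for _, f in self.members:
            if not 0 < f <= 1:
                raise ValueError(f"designed fraction {f} outside (0, 1]")
        fracs = sorted(f for _, f in self.members)
        for lo, hi in zip(fracs, fracs[1:]):
            if (hi - lo) / lo <= 2 * self.tolerance:
                warnings.warn(
                    f"pool {self.pool_id}: fractions {lo:.3f} and {hi:.3f} are "
                    f"separated by less than twice the tolerance "
                    f"({self.tolerance:.0%}); assignments may be ambiguous",
                    stacklevel=2,
                )

    @property
    def fractions(self) -> dict[str, float]:
        return dict(self.members)


@dataclass(frozen=True)
class GroupCounts:
    """Clones-with->=1-unintended-mutation count within one protocol group."""

    label: str
    n_clones: int
    n_with_mutation: int

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ValueError(f"group {self.label!r} has no clones")
        if not 0 <= self.n_with_mutation <= self.n_clones:
            raise ValueError(
                f"group {self.label!r}: {self.n_with_mutation} of {self.n_clones}"
            )

    @property
    def proportion(self) -> float:
        return self.n_with_mutation / self.n_clones

    @property
    def percent(self) -> int:
        """Proportion rounded to a whole percent, as reported."""
        return round(100 * self.proportion)


@dataclass(frozen=True)
class ProximityResult:
    mutation_key: tuple
    nearest_site_position: int
    distance: int
    distance_to_intended_edit: Optional[int] = None

    @property
    def bin_index(self) -> int:
        """1-kb histogram bin."""
        return self.distance // 1000
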