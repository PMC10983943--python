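"""Functional-context classification of unintended mutations.

Substitutions inside a CDS are translated under the bacterial codon table
(NCBI table 11) with strand awareness and classed as synonymous,
nonsynonymous or nonsense; length-changing variants whose net length change
is not a multiple of 3 are frameshifts.  Intergenic mutations get the
circular distance to the nearest annotated start codon on either strand,
with a flag for the within-100-bp promoter-proxy window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .proximity import circular_distance
from .records import GeneFeature, Genome, GenomeAnnotation, MutationRecord
from .sequences import reverse_complement

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_STARTS = set(_TABLE11.start_codons)

CODING_EFFECTS = ("synonymous", "nonsynonymous", "nonsense", "frameshift", "none")
_SEVERITY = {e: i for i, e in enumerate(
    ("none", "synonymous", "nonsynonymous", "nonsense", "frameshift")
)}


@dataclass(frozen=True)
class MutationAnnotation:
    context: str  # coding | intergenic
    coding_effect: str
    gene_ids: tuple[str, ...] = ()
    distance_to_nearest_start_codon: Optional[int] = None
    within_100bp_of_start: bool = False
    multi: bool = False  # position fell inside overlapping CDSs

    def __post_init__(self) -> None:
        if (self.coding_effect == "none") != (self.context == "intergenic"):
            raise ValueError("coding_effect is 'none' iff context is intergenic")


def _translate_codon(codon: str, at_gene_start: bool) -> str:
    if at_gene_start and codon in _STARTS:
        return "M"  # alternative initiators read as Met at position 1
    return str(Seq(codon).translate(table=11))


def _snv_effect(record: MutationRecord, feature: GeneFeature, genome: Genome) -> str:
    if feature.strand == "+":
        offset = record.position - feature.start - feature.frame
        coding_alt = record.alt
    else:
        offset = feature.end - record.position - feature.frame
        coding_alt = reverse_complement(record.alt)
    if offset < 0:
        return "nonsynonymous"  # upstream of the reading frame start; rare
    codon_index, within = divmod(offset, 3)
    codon_start_genomic = (
        feature.start + feature.frame + 3 * codon_index
        if feature.strand == "+"
        else feature.end - feature.frame - 3 * codon_index
    )
    if feature.strand == "+":
        codon = "".join(genome.base(codon_start_genomic + k) for k in range(3))
    else:
        codon = reverse_complement(
            "".join(genome.base(codon_start_genomic - 2 + k) for k in range(3))
        )
    alt_codon = codon[:within] + coding_alt + codon[within + 1:]
    at_start = codon_index == 0
    ref_aa = _translate_codon(codon, at_start)
    alt_aa = _translate_codon(alt_codon, at_start)
    if alt_aa == "*" and ref_aa != "*":
        return "nonsense"
    return "synonymous" if ref_aa == alt_aa else "nonsynonymous"


def _start_distance(
    position: int, annotation: GenomeAnnotation
) -> Optional[int]:
    starts = [f.start_codon_position for f in annotation.features]
    if not starts:
        return None
    return min(
        circular_distance(position, s, annotation.genome_length) for s in starts
    )


def classify_mutation(
    record: MutationRecord,
    annotation: GenomeAnnotation,
    genome: Genome,
) -> MutationAnnotation:
    """Classify one mutation against gene annotation.

    A position inside overlapping CDSs is annotated against each and the
    most severe effect is reported with ``multi=True``.
    """
    features = annotation.overlapping(record.position)
    if not features:
        d = _start_distance(record.position, annotation)
        return MutationAnnotation(
            context="intergenic",
            coding_effect="none",
            distance_to_nearest_start_codon=d,
            within_100bp_of_start=(d is not None and d <= 100),
        )
    effects = []
    for f in features:
        if record.mut_class == "SNV":
            effects.append(_snv_effect(record, f, genome))
        else:
            shift = abs(len(record.alt) - len(record.ref))
            # in-frame indels still change the protein; out-of-frame shift it
            effects.append(
                "frameshift"
                if record.mut_class == "MOB" or shift % 3 != 0
                else "nonsynonymous"
            )
    worst = max(effects, key=lambda e: _SEVERITY[e])
    return MutationAnnotation(
        context="coding",
        coding_effect=worst,
        gene_ids=tuple(f.feature_id for f in features),
        multi=len(features) > 1,
    )


def spectrum_summary(
    records: Sequence[MutationRecord],
    annotations: Optional[Sequence[MutationAnnotation]] = None,
) -> dict:
    """Fractions by mutation class, and by context/effect when annotations
    are supplied.  Fractions sum to 1 within each partition."""
    if not records:
        raise ValueError("no mutations to summarize")
    n = len(records)
    by_class: dict[str, int] = {}
    for r in records:
        by_class[r.mut_class] = by_class.get(r.mut_class, 0) + 1
    out = {
        "n": n,
        "class_fractions": {k: v / n for k, v in sorted(by_class.items())},
    }
    if annotations is not None:
        if len(annotations) != n:
            raise ValueError("annotations must parallel records")
        coding = [a for a in annotations if a.context == "coding"]
        intergenic = [a for a in annotations if a.context == "intergenic"]
        out["context_fractions"] = {
            "coding": len(coding) / n,
            "intergenic": len(intergenic) / n,
        }
        if coding:
            eff: dict[str, int] = {}
            for a in coding:
                eff[a.coding_effect] = eff.get(a.coding_effect, 0) + 1
            out["coding_effect_fractions"] = {
                k: v / len(coding) for k, v in sorted(eff.items())
            }
        if intergenic:
            out["intergenic_within_100bp_of_start"] = sum(
                a.within_100bp_of_start for a in intergenic
            ) / len(intergenic)
    return out


def write_annotated_tsv(
    records: Sequence[MutationRecord],
    annotations: Sequence[MutationAnnotation],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "sample_id\tposition\tref\talt\tmut_class\tcontext\tcoding_effect\t"
            "gene_ids\tdistance_to_start\twithin_100bp_of_start\tmulti\n"
        )
        for r, a in zip(records, annotations):
            d = (
                "" if a.distance_to_nearest_start_codon is None
                else a.distance_to_nearest_start_codon
            )
            fh.write(
                f"{r.sample_id}\t{r.position}\t{r.ref}\t{r.alt}\t{r.mut_class}\t"
                f"{a.context}\t{a.coding_effect}\t{','.join(a.gene_ids)}\t{d}\t"
                f"{int(a.within_100bp_of_start)}\t{int(a.multi)}\n"
            )
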