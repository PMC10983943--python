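#!/usr/bin/env python
"""Annotate unintended mutations and summarize the mutation spectrum.

Classifies every unintended mutation from the synthetic cohort against the
tiled gene annotation: coding mutations are translated (bacterial codon
table) into synonymous/nonsynonymous/nonsense/frameshift classes, and
intergenic mutations get their distance to the nearest start codon with a
within-100-bp flag.  The class spectrum (SNV vs 1-bp indels) reflects the
generator's 90% single-base-substitution share.

Writes results/spectrum/annotations.tsv and spectrum.json.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "synthetic_cohort"
OUT = ROOT / "results" / "spectrum"

from editaudit.annotate import classify_mutation, spectrum_summary, \
    write_annotated_tsv
from editaudit.ingest import (
    read_annotation_gff3,
    read_genome,
    read_mutation_table,
    subtract_known,
)


def main() -> None:
    if not COHORT.exists():
        print("run analysis/01_simulate_cohort.py first", file=sys.stderr)
        return 1
    OUT.mkdir(parents=True, exist_ok=True)
    params = json.loads((COHORT / "params.json").read_text())
    genome, _ = read_genome(COHORT / "genome.fasta")
    annotation = read_annotation_gff3(COHORT / "genes.gff3", len(genome))

    parental = []
    for pp in params["parental_positions"]:
        ref = genome.base(pp)
        parental.append((pp, ref, "A" if ref != "A" else "G"))
    edit_pos = params["intended_edit_position"]
    ref = genome.base(edit_pos)
    intended = [(edit_pos, ref, "T" if ref != "T" else "C")]

    muts = []
    for group_dir in sorted(p for p in COHORT.iterdir()
                            if p.is_dir() and p.name != "pools"):
        for table in sorted(group_dir.glob("*.tsv")):
            records = read_mutation_table(table)
            muts.extend(m for m in subtract_known(records, parental, intended)
                        if "near_intended" not in m.flags)
    annotations = [classify_mutation(m, annotation, genome) for m in muts]
    write_annotated_tsv(muts, annotations, OUT / "annotations.tsv")
    summary = spectrum_summary(muts, annotations)
    (OUT / "spectrum.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n")

    print(f"{summary['n']} unintended mutations across all arms")
    snv = summary["class_fractions"].get("SNV", 0.0)
    print(f"  single-base substitutions: {snv:.0%} of all unintended "
          f"mutations (generator plants 90%)")
    ctx = summary["context_fractions"]
    print(f"  coding {ctx['coding']:.0%} / intergenic {ctx['intergenic']:.0%}")
    for effect, frac in summary.get("coding_effect_fractions", {}).items():
        print(f"    {effect:>14}: {frac:.0%} of coding mutations")
    if "intergenic_within_100bp_of_start" in summary:
        print(f"  {summary['intergenic_within_100bp_of_start']:.0%} of "
              f"intergenic mutations lie within 100 bp of a start codon")
    print(f"wrote {OUT}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
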