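#!/usr/bin/env python
"""Simulate the audited editing study on a synthetic genome.

Builds a 200-kb circular genome carrying planted degenerate protospacer
copies of the mCherry spacer, then four clone cohorts at the study's sample
sizes (117 Cas9, 52 control, 48 lambda-Red, 19 I-SceI).  The control and
lambda-Red arms accumulate mutations at the literature baseline rate
(mu_g = 9.28e-4 per genome per generation over 80 divisions); the Cas9 and
I-SceI arms use elevated rates solved from the observed 26% mutated-clone
proportions (the I-SceI protocol runs ~30 extra divisions).  Edited clones
additionally carry their intended edit and every clone carries two parental
markers, so the downstream audit has something to subtract.  Three-clone
pools at 18/32/50% with 100x read depth emulate the pooled sequencing
submissions.

Writes genome, per-clone mutation tables, pooled tables, a GFF3 annotation,
and ground truth under results/synthetic_cohort/.
"""

import json
import math
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "synthetic_cohort"

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from editaudit.ingest import write_mutation_table
from editaudit.offtargets import MCHERRY_SPACER
from editaudit.records import MutationRecord, PoolDesign
from editaudit.stats import per_genome_rate
from editaudit.synthetic import (
    generate_genome,
    plant_protospacer,
    simulate_clones,
    simulate_pools,
    write_run_sidecar,
    write_truth,
)

SEED = 2024
GENOME_LENGTH = 200_000
BASELINE_MU_G = per_genome_rate(2.0e-10, 4_641_652)  # 9.28e-4
INTENDED_EDIT_POS = 100_000
PARENTAL_POSITIONS = (20_000, 150_000)

# observed mutated-clone proportions the edited arms are solved to reproduce
GROUP_DESIGN = {
    # label: (n_clones, observed proportion, generations)
    "cas9": (117, 31 / 117, 80),
    "control": (52, None, 80),        # baseline rate
    "lambda_red": (48, None, 80),     # baseline rate
    "isceI": (19, 5 / 19, 110),       # ~30 extra divisions
}

PLANTS = [
    # (position, strand, edits) - intended mismatch/bulge structure
    (15_000, "+", [("sub", 1), ("sub", 6), ("sub", 11), ("sub", 16), ("sub", 19)]),
    (42_000, "-", [("sub", 0), ("sub", 5), ("sub", 9), ("sub", 13),
                   ("dna_bulge", 15, "A")]),
    (71_000, "+", [("sub", 2), ("sub", 8), ("rna_bulge", 12), ("sub", 17),
                   ("sub", 19)]),
    (99_000, "-", [("sub", 3), ("sub", 7), ("sub", 10), ("sub", 14),
                   ("sub", 18), ("sub", 1)]),
    (130_000, "+", [("dna_bulge", 5, "G"), ("rna_bulge", 14), ("sub", 2),
                    ("sub", 9), ("sub", 18)]),
    # too degenerate: seven substitutions, should stay below the filter
    (160_000, "+", [("sub", i) for i in (0, 3, 6, 9, 12, 15, 18)]),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(GENOME_LENGTH, gc_fraction=0.508, seed=SEED)
    planted = []
    for i, (pos, strand, edits) in enumerate(PLANTS):
        genome, truth_entry = plant_protospacer(
            genome, MCHERRY_SPACER, pos, strand, edits=edits,
            seed=SEED + 10 + i, existing=planted,
        )
    SeqIO.write(
        [SeqRecord(Seq(genome.sequence), id="synthetic_chr",
                   description="synthetic circular genome")],
        str(OUT / "genome.fasta"), "fasta",
    )
    import dataclasses

    (OUT / "planted_offtargets.json").write_text(json.dumps(
        [dataclasses.asdict(p) | {"pam_proximal_position":
                                  p.pam_proximal_position}
         for p in planted], indent=1) + "\n")
    print(f"genome: {GENOME_LENGTH:,} bp, {len(planted)} planted "
          f"protospacer copies (one beyond the 6 mismatch+gap filter)")

    # simple tiled annotation: 900-bp genes, 150-bp gaps, alternating strands
    with open(OUT / "genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        start, i = 201, 0
        while start + 900 < GENOME_LENGTH - 200:
            strand = "+" if i % 2 == 0 else "-"
            fh.write(
                f"synthetic_chr\tsim\tCDS\t{start}\t{start + 899}\t.\t{strand}"
                f"\t0\tID=gene{i:04d}\n"
            )
            start += 1050
            i += 1
    print(f"annotation: {i} tiled CDS features")

    clone_tables = {}
    all_clones = {}
    full_rows = {}  # unintended + parental markers + intended edit
    for gi, (label, (n, p_obs, gens)) in enumerate(GROUP_DESIGN.items()):
        rate = (BASELINE_MU_G if p_obs is None
                else -math.log(1 - p_obs) / gens)
        clones, truth = simulate_clones(
            n, genome, genome_rate=rate, generations=gens,
            seed=SEED + 100 + gi, group_label=label, clone_prefix=label,
            intended_edit_position=(None if label == "control"
                                    else INTENDED_EDIT_POS),
            spacer_id=None if label in ("control", "lambda_red") else "mcherry",
        )
        write_truth(truth, OUT / f"truth_{label}.json")
        group_dir = OUT / label
        group_dir.mkdir(exist_ok=True)
        for c in clones:
            rows = list(c.unintended_mutations)
            for pp in PARENTAL_POSITIONS:  # parental markers in every clone
                rows.append(MutationRecord(
                    c.clone_id, pp, genome.base(pp),
                    "A" if genome.base(pp) != "A" else "G", "SNV", 1.0))
            if c.intended_edit_position:  # the intended edit itself
                ref = genome.base(INTENDED_EDIT_POS)
                rows.append(MutationRecord(
                    c.clone_id, INTENDED_EDIT_POS, ref,
                    "T" if ref != "T" else "C", "SNV", 1.0))
            rows.sort(key=lambda m: m.position)
            write_mutation_table(rows, group_dir / f"{c.clone_id}.tsv")
            clone_tables[c.clone_id] = str(group_dir / f"{c.clone_id}.tsv")
            full_rows[c.clone_id] = rows
            all_clones[c.clone_id] = c
        frac = sum(c.has_unintended for c in clones) / n
        print(f"  {label:>10}: {n} clones at mu_g={rate:.2e}/gen x {gens} "
              f"generations -> {frac:.0%} with >=1 unintended mutation")

    # pooled submissions: consecutive triples of cas9 clones at 18/32/50%
    cas9 = [c for c in all_clones.values() if c.group_label == "cas9"]
    pool_truth = {}
    pools_dir = OUT / "pools"
    pools_dir.mkdir(exist_ok=True)
    n_pools = 0
    from editaudit.records import CloneRecord

    for k in range(0, len(cas9) - 2, 3):
        members = cas9[k: k + 3]
        design = PoolDesign(
            f"pool{k // 3:02d}",
            [(c.clone_id, f) for c, f in zip(members, (0.18, 0.32, 0.50))],
        )
        # pool the full gDNA content: unintended mutations plus the shared
        # parental markers and intended edit (these sum to ~100% of reads)
        pool_input = [
            CloneRecord(c.clone_id, c.group_label,
                        intended_edit_position=c.intended_edit_position,
                        spacer_id=c.spacer_id,
                        unintended_mutations=full_rows[c.clone_id])
            for c in members
        ]
        pooled = simulate_pools(pool_input, design, depth=100,
                                seed=SEED + 500 + k)
        write_mutation_table(pooled, pools_dir / f"{design.pool_id}.tsv")
        pool_truth[design.pool_id] = {
            "members": design.members,
            "private_mutations": {
                f"{m.position}:{m.ref}:{m.alt}": c.clone_id
                for c in members for m in c.unintended_mutations
            },
        }
        n_pools += 1
    (OUT / "pool_truth.json").write_text(
        json.dumps(pool_truth, indent=1, sort_keys=True) + "\n")
    print(f"  pools: {n_pools} three-clone pools at 18/32/50%, depth 100x")

    write_run_sidecar(
        OUT / "params.json", seed=SEED, genome_length=GENOME_LENGTH,
        baseline_mu_g=BASELINE_MU_G, group_design=GROUP_DESIGN,
        intended_edit_position=INTENDED_EDIT_POS,
        parental_positions=PARENTAL_POSITIONS,
        pool_fractions=(0.18, 0.32, 0.50), pool_depth=100,
    )
    print(f"wrote cohort under {OUT}")


if __name__ == "__main__":
    sys.exit(main())
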