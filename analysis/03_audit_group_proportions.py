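#!/usr/bin/env python
"""Audit unintended-mutation frequencies per editing protocol.

Ingests every clone's mutation table from the synthetic cohort, removes the
parental markers and intended edits, counts clones with at least one
unintended mutation per protocol group, and tests the proportions: a
four-group chi-square followed by the Marascuilo pairwise procedure, plus
the Poisson null expectation for the control arm.

The same statistics are also computed for the study's printed counts
(31/117 Cas9, 5/52 control, 4/48 lambda-Red, 5/19 I-SceI).

Writes results/audit/synthetic_stats.json and printed_stats.json.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "synthetic_cohort"
OUT = ROOT / "results" / "audit"

from editaudit.ingest import (
    flag_recurrent,
    read_genome,
    read_mutation_table,
    subtract_known,
)
from editaudit.records import CloneRecord, GroupCounts
from editaudit.stats import NullModel, group_summary, marascuilo

PRINTED = [("cas9", 31, 117), ("control", 5, 52),
           ("lambda_red", 4, 48), ("isceI", 5, 19)]


def stats_payload(groups, alpha=0.05):
    result = marascuilo(sorted(groups, key=lambda g: g.label), alpha=alpha)
    return {
        "groups": {g.label: {"n": g.n_clones, "mutated": g.n_with_mutation,
                             "percent": g.percent} for g in groups},
        "chi2": result.chi2, "df": result.df, "p_value": result.p_value,
        "pairs": [
            {"pair": [p.label_i, p.label_j],
             "abs_difference": round(p.abs_difference, 4),
             "significant_at_0.05": p.significant,
             "min_adjusted_alpha": round(p.min_alpha, 4)}
            for p in result.pairs
        ],
    }


def main() -> None:
    if not COHORT.exists():
        print("run analysis/01_simulate_cohort.py first", file=sys.stderr)
        return 1
    OUT.mkdir(parents=True, exist_ok=True)
    params = json.loads((COHORT / "params.json").read_text())
    genome, _ = read_genome(COHORT / "genome.fasta")

    parental = []
    for pp in params["parental_positions"]:
        ref = genome.base(pp)
        parental.append((pp, ref, "A" if ref != "A" else "G"))
    edit_pos = params["intended_edit_position"]
    ref = genome.base(edit_pos)
    intended = [(edit_pos, ref, "T" if ref != "T" else "C")]

    clones = []
    for group_dir in sorted(p for p in COHORT.iterdir() if p.is_dir()
                            and p.name != "pools"):
        for table in sorted(group_dir.glob("*.tsv")):
            records = read_mutation_table(table)
            unintended = subtract_known(records, parental, intended,
                                        positional_tolerance=20)
            unintended = [m for m in unintended
                          if "near_intended" not in m.flags]
            clones.append(CloneRecord(
                table.stem, group_dir.name,
                intended_edit_position=(None if group_dir.name == "control"
                                        else edit_pos),
                unintended_mutations=list(unintended),
            ))
    flag_recurrent(clones)
    groups = list(group_summary(clones).values())
    synthetic = stats_payload(groups)
    print("synthetic cohort after subtracting parental/intended mutations:")
    for label, g in sorted(synthetic["groups"].items()):
        print(f"  {label:>10}: {g['mutated']}/{g['n']} clones mutated "
              f"({g['percent']}%)")
    print(f"  chi-square {synthetic['chi2']:.2f} (df={synthetic['df']}), "
          f"p = {synthetic['p_value']:.4f}")
    for p in synthetic["pairs"]:
        mark = "*" if p["significant_at_0.05"] else " "
        print(f"  {mark} {p['pair'][0]} vs {p['pair'][1]}: min adjusted "
              f"alpha {p['min_adjusted_alpha']}")

    null = NullModel(mu_nt=2.0e-10, genome_length=4_641_652)
    expected = null.expected_fraction(80)
    synthetic["null_model"] = {
        "mu_genome": null.mu_genome, "generations": 80,
        "expected_fraction": expected,
    }
    print(f"Poisson null: mu_g = {null.mu_genome:.2e}/generation -> "
          f"{expected:.1%} of clones expected mutated after 80 divisions")
    (OUT / "synthetic_stats.json").write_text(
        json.dumps(synthetic, indent=1, sort_keys=True) + "\n")

    printed = stats_payload(
        [GroupCounts(l, n, x) for l, x, n in PRINTED])
    printed["null_model"] = synthetic["null_model"]
    (OUT / "printed_stats.json").write_text(
        json.dumps(printed, indent=1, sort_keys=True) + "\n")
    print("\nstudy's printed counts:")
    for label, g in sorted(printed["groups"].items()):
        print(f"  {label:>10}: {g['mutated']}/{g['n']} ({g['percent']}%)")
    print(f"  chi-square {printed['chi2']:.2f} (df={printed['df']}), "
          f"p = {printed['p_value']:.4f}")
    for p in printed["pairs"]:
        mark = "*" if p["significant_at_0.05"] else " "
        print(f"  {mark} {p['pair'][0]} vs {p['pair'][1]}: min adjusted "
              f"alpha {p['min_adjusted_alpha']}")
    print(f"wrote {OUT}/synthetic_stats.json and printed_stats.json")
    return 0


if __name__ == "__main__":
    sys.exit(main())
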