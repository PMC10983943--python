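#!/usr/bin/env python
"""Demultiplex the pooled sequencing submissions back to clones.

Reads the pooled mutation tables written by 01_simulate_cohort.py, assigns
each pooled call to a clone by matching its read fraction to the designed
18/32/50% pool fractions, and scores the assignments against ground truth.
Parental markers and the shared intended edit appear at ~100% of reads and
are flagged parental-like rather than assigned.

Also reruns the assignment on a dense calibration pool to measure the
recovery ceiling at 100x depth.

Writes per-pool assignment reports and results/demux/summary.json.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "synthetic_cohort"
OUT = ROOT / "results" / "demux"

from editaudit.demux import assign_mutations, recovery_rate, \
    write_assignment_report
from editaudit.ingest import read_mutation_table
from editaudit.records import PoolDesign
from editaudit.synthetic import generate_genome, simulate_clones, simulate_pools


def main() -> None:
    if not COHORT.exists():
        print("run analysis/01_simulate_cohort.py first", file=sys.stderr)
        return 1
    OUT.mkdir(parents=True, exist_ok=True)
    pool_truth = json.loads((COHORT / "pool_truth.json").read_text())

    n_private = n_recovered = n_parental_like = 0
    for pool_id, info in sorted(pool_truth.items()):
        design = PoolDesign(pool_id,
                            [tuple(m) for m in info["members"]])
        records = read_mutation_table(COHORT / "pools" / f"{pool_id}.tsv")
        assignments = assign_mutations(records, design)
        write_assignment_report(assignments, OUT / f"{pool_id}.tsv")
        truth = {
            tuple([int(k.split(":")[0]), k.split(":")[1], k.split(":")[2]]): v
            for k, v in info["private_mutations"].items()
        }
        by_key = {a.record.key: a for a in assignments}
        for key, clone in truth.items():
            n_private += 1
            a = by_key.get(key)
            if a and a.category == "assigned" and a.clone_id == clone:
                n_recovered += 1
        n_parental_like += sum(
            a.category == "parental_like" for a in assignments)

    print(f"cohort pools: {n_recovered}/{n_private} private unintended "
          f"mutations assigned to the correct clone")
    print(f"  {n_parental_like} calls at ~100% reads flagged parental-like "
          f"(parental markers and the shared intended edit)")

    # calibration: a dense pool quantifies recovery at 100x depth
    genome = generate_genome(200_000, 0.5, seed=5)
    clones, _ = simulate_clones(3, genome, genome_rate=5.0, generations=40,
                                seed=12, clone_prefix="cal")
    design = PoolDesign("calibration", [
        (c.clone_id, f) for c, f in zip(clones, (0.18, 0.32, 0.50))])
    carriers = {}
    for c in clones:
        for m in c.unintended_mutations:
            carriers.setdefault(m.key, []).append(c.clone_id)
    truth = {k: v[0] for k, v in carriers.items() if len(v) == 1}
    pooled = simulate_pools(clones, design, depth=100, seed=13)
    cal_rate = recovery_rate(assign_mutations(pooled, design), truth)
    print(f"calibration pool ({len(truth)} private mutations, depth 100x): "
          f"{cal_rate:.1%} recovered")
    print("  note: binomial read sampling at this depth caps even "
          "likelihood-optimal assignment at ~94.5% for 18/32/50% fractions")

    (OUT / "summary.json").write_text(json.dumps({
        "cohort_private_mutations": n_private,
        "cohort_recovered": n_recovered,
        "cohort_parental_like_calls": n_parental_like,
        "calibration_recovery": cal_rate,
        "pool_fractions": [0.18, 0.32, 0.50],
        "depth": 100,
    }, indent=1) + "\n")
    print(f"wrote {OUT}/summary.json")
    return 0


if __name__ == "__main__":
    sys.exit(main())
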