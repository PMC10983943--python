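#!/usr/bin/env python
"""Scan for off-target sites and measure mutation-to-site distances.

Scans the synthetic genome for the mCherry spacer (<=6 mismatches+gaps,
<=2 gaps, NGG PAM, both strands), checks the planted degenerate protospacer
copies are recovered (and the seven-substitution plant is not), then
computes the circular distance from every Cas9-arm unintended mutation to
the nearest candidate site and to the intended edit.

Writes BED/TSV site lists, per-mutation distances, a 1-kb histogram and a
summary under results/offtargets/; a histogram figure goes to scratch/.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "synthetic_cohort"
OUT = ROOT / "results" / "offtargets"

from editaudit.ingest import read_genome, read_mutation_table, subtract_known
from editaudit.offtargets import MCHERRY_SPACER, SpacerQuery, scan_cas9, \
    write_hits_bed, write_hits_tsv
from editaudit.proximity import (
    circular_coordinates,
    histogram_1kb,
    mean_distance_kb,
    nearest_offtarget,
    write_proximity_tsv,
    write_summary_json,
)


def main() -> None:
    if not COHORT.exists():
        print("run analysis/01_simulate_cohort.py first", file=sys.stderr)
        return 1
    OUT.mkdir(parents=True, exist_ok=True)
    params = json.loads((COHORT / "params.json").read_text())
    genome, _ = read_genome(COHORT / "genome.fasta")

    query = SpacerQuery(MCHERRY_SPACER)
    hits = scan_cas9(genome, query)
    write_hits_bed(hits, genome, OUT / "mcherry_sites.bed", name="mcherry")
    write_hits_tsv(hits, OUT / "mcherry_sites.tsv")
    print(f"{len(hits)} candidate off-target sites for the mCherry spacer "
          f"(<= {query.max_mismatch_plus_gap} mismatches+gaps, "
          f"<= {query.max_gaps} gaps)")

    planted = json.loads((COHORT / "planted_offtargets.json").read_text())
    hit_keys = {(h.position, h.strand): h for h in hits}
    n_found = 0
    for p in planted:
        key = (p["pam_proximal_position"], p["strand"])
        intended = p["n_mismatch"] + p["n_gap"]
        h = hit_keys.get(key)
        if h is not None:
            n_found += 1
            note = ("" if h.total == intended
                    else f" (cheaper alternative alignment: {h.total})")
            print(f"  planted site at {key[0]}{key[1]} recovered with "
                  f"{h.n_mismatch} mm + {h.n_gap} gaps{note}")
        else:
            print(f"  planted site at {key[0]}{key[1]} with {intended} "
                  f"intended edits is beyond the filter (expected for >6)")
    print(f"recovered {n_found}/{len(planted)} planted sites")

    # proximity: unintended mutations of the cas9 arm
    edit_pos = params["intended_edit_position"]
    genome_ref = genome
    parental = []
    for pp in params["parental_positions"]:
        ref = genome_ref.base(pp)
        parental.append((pp, ref, "A" if ref != "A" else "G"))
    ref = genome_ref.base(edit_pos)
    intended = [(edit_pos, ref, "T" if ref != "T" else "C")]
    muts = []
    for table in sorted((COHORT / "cas9").glob("*.tsv")):
        records = read_mutation_table(table)
        muts.extend(m for m in subtract_known(records, parental, intended)
                    if "near_intended" not in m.flags)
    results, mean_bp, n_within = nearest_offtarget(
        muts, hits, len(genome), within=2000,
        intended_edit_positions={m.sample_id: edit_pos for m in muts},
    )
    hist = histogram_1kb(results)
    write_proximity_tsv(results, OUT / "proximity.tsv")
    write_summary_json(OUT / "proximity_summary.json", mean_bp, n_within,
                       2000, len(muts), hist)
    (OUT / "circos_coordinates.json").write_text(json.dumps(
        circular_coordinates(len(genome), muts, hits, [edit_pos]), indent=1
    ) + "\n")
    print(f"{len(muts)} unintended mutations in the Cas9 arm: mean distance "
          f"{mean_distance_kb(mean_bp)} kb to the nearest site; "
          f"{n_within} within 2 kb")
    far_edit = sum(
        1 for r in results
        if r.distance_to_intended_edit and r.distance_to_intended_edit > 10_000
    )
    print(f"  {far_edit}/{len(muts)} are >10 kb from the intended edit")

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig_dir = ROOT / "scratch" / "figures"
        fig_dir.mkdir(parents=True, exist_ok=True)
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.bar([k + 0.5 for k in hist], hist.values(), width=0.9)
        ax.set_xlabel("distance to nearest off-target site (kb)")
        ax.set_ylabel("unintended mutations")
        fig.tight_layout()
        fig.savefig(fig_dir / "proximity_histogram.png", dpi=120)
        print(f"  histogram figure -> {fig_dir}/proximity_histogram.png")
    except Exception as exc:  # plotting is never load-bearing
        print(f"  (skipped figure: {exc})")
    print(f"wrote {OUT}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
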