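"""Off-target scanner: planted-site recovery, invariants, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from editaudit.offtargets import (
    ISCEI_SITE,
    MCHERRY_SPACER,
    SpacerQuery,
    scan_cas9,
    scan_fixed_site,
)
from editaudit.records import Genome
from editaudit.sequences import reverse_complement
from editaudit.synthetic import generate_genome, plant_protospacer

from oracles import oracle_scan


def hit_map(hits):
    return {(h.position, h.strand): (h.n_mismatch, h.n_gap) for h in hits}


class TestPlantedSites:
    def test_exact_plant_reported_with_zero_cost(self, small_genome):
        planted = []
        g, truth = plant_protospacer(
            small_genome, MCHERRY_SPACER, 700, "+", seed=3, existing=planted
        )
        hits = hit_map(scan_cas9(g, SpacerQuery(MCHERRY_SPACER)))
        assert hits[(truth.pam_proximal_position, "+")] == (0, 0)

    def test_minus_strand_plant_reported(self, small_genome):
        g, truth = plant_protospacer(small_genome, MCHERRY_SPACER, 1500, "-", seed=4)
        hits = hit_map(scan_cas9(g, SpacerQuery(MCHERRY_SPACER)))
        assert hits[(truth.pam_proximal_position, "-")] == (0, 0)

    @pytest.mark.parametrize("edits,expected", [
        ([("sub", 2), ("sub", 9), ("sub", 15)], (3, 0)),
        ([("sub", 4), ("dna_bulge", 10, "A")], (1, 1)),
        ([("rna_bulge", 11), ("sub", 3)], (1, 1)),
    ])
    def test_degenerate_plants_cost_at_most_intended(self, small_genome, edits,
                                                     expected):
        """The scanner reports the planted cost unless a cheaper alternative
        alignment exists, in which case it must agree with the oracle."""
        g, truth = plant_protospacer(
            small_genome, MCHERRY_SPACER, 900, "+", edits=edits, seed=5
        )
        hits = hit_map(scan_cas9(g, SpacerQuery(MCHERRY_SPACER)))
        got = hits[(truth.pam_proximal_position, "+")]
        assert sum(got) <= sum(expected)
        oracle = oracle_scan(g.sequence, True, MCHERRY_SPACER)
        assert got == oracle[(truth.pam_proximal_position, "+")]

    def test_seven_substitutions_not_reported(self, small_genome):
        g, truth = plant_protospacer(
            small_genome, MCHERRY_SPACER, 2000, "+",
            edits=[("sub", i) for i in (0, 3, 6, 9, 12, 15, 18)], seed=6,
        )
        hits = hit_map(scan_cas9(g, SpacerQuery(MCHERRY_SPACER)))
        key = (truth.pam_proximal_position, "+")
        if key in hits:  # only reachable if random edits created a cheap alignment
            assert sum(hits[key]) <= 6
            oracle = oracle_scan(g.sequence, True, MCHERRY_SPACER)
            assert hits[key] == oracle[key]

    def test_wraparound_site_found_on_circle(self):
        genome = generate_genome(2000, 0.5, seed=11)
        # body starts 10 bp before the origin so protospacer+PAM wraps
        g, truth = plant_protospacer(genome, MCHERRY_SPACER, 1991, "+", seed=7)
        hits = hit_map(scan_cas9(g, SpacerQuery(MCHERRY_SPACER)))
        assert (truth.pam_proximal_position % 2000, "+") in hits

    def test_overlapping_plants_rejected(self, small_genome):
        planted = []
        g, _ = plant_protospacer(small_genome, MCHERRY_SPACER, 700, "+",
                                 seed=1, existing=planted)
        with pytest.raises(ValueError, match="overlap"):
            plant_protospacer(g, MCHERRY_SPACER, 710, "+", seed=2,
                              existing=planted)


class TestQueryValidation:
    def test_invalid_spacer_alphabet_rejected(self):
        with pytest.raises(ValueError, match="spacer"):
            SpacerQuery("CTGUCCCCTCAGTTCATGTA")

    def test_genome_shorter_than_query_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            scan_cas9(Genome("ACGTACGT"), SpacerQuery(MCHERRY_SPACER))


class TestInvariants:
    def test_bounds_respected_by_every_hit(self, small_genome):
        q = SpacerQuery(MCHERRY_SPACER, max_mismatch_plus_gap=6, max_gaps=2)
        for h in scan_cas9(small_genome, q):
            assert h.n_mismatch + h.n_gap <= 6
            assert h.n_gap <= 2
            assert len(h.aligned_site) == len(h.aligned_spacer)

    def test_loosening_bounds_never_removes_hits(self, small_genome):
        tight = hit_map(scan_cas9(small_genome, SpacerQuery(
            MCHERRY_SPACER, max_mismatch_plus_gap=5, max_gaps=1)))
        loose = hit_map(scan_cas9(small_genome, SpacerQuery(
            MCHERRY_SPACER, max_mismatch_plus_gap=6, max_gaps=2)))
        assert set(tight) <= set(loose)

    def test_strand_symmetry(self):
        genome = generate_genome(1200, 0.5, seed=21)
        flipped = Genome(reverse_complement(genome.sequence), circular=True)
        n = len(genome)
        fwd = hit_map(scan_cas9(genome, SpacerQuery(MCHERRY_SPACER)))
        rev = hit_map(scan_cas9(flipped, SpacerQuery(MCHERRY_SPACER)))
        mirrored = {
            (n + 1 - pos, "+" if strand == "-" else "-"): cost
            for (pos, strand), cost in rev.items()
        }
        assert fwd == mirrored


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed,length,gc", [
        (1, 400, 0.5), (2, 700, 0.65), (3, 1000, 0.4), (4, 1500, 0.55),
    ])
    def test_random_genomes_match_bruteforce(self, seed, length, gc):
        genome = generate_genome(length, gc, seed=seed)
        got = hit_map(scan_cas9(genome, SpacerQuery(MCHERRY_SPACER)))
        want = oracle_scan(genome.sequence, True, MCHERRY_SPACER)
        assert got == want

    def test_linear_genome_matches_bruteforce(self):
        genome = Genome(generate_genome(800, 0.5, seed=31).sequence,
                        circular=False)
        got = hit_map(scan_cas9(genome, SpacerQuery(MCHERRY_SPACER)))
        want = oracle_scan(genome.sequence, False, MCHERRY_SPACER)
        assert got == want

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10 ** 6))
    def test_planted_degenerate_sites_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        genome = generate_genome(350, 0.5, seed=seed)
        n_sub = int(rng.integers(0, 6))
        n_bulge = int(rng.integers(0, 3))
        offsets = rng.choice(20, size=n_sub + n_bulge, replace=False)
        edits = [("sub", int(o)) for o in offsets[:n_sub]]
        for o in offsets[n_sub:]:
            kind = "dna_bulge" if rng.random() < 0.5 else "rna_bulge"
            edits.append((kind, int(o)) if kind == "rna_bulge"
                         else (kind, int(o), "ACGT"[rng.integers(4)]))
        strand = "+" if rng.random() < 0.5 else "-"
        g, _ = plant_protospacer(genome, MCHERRY_SPACER, 120, strand,
                                 edits=edits, seed=seed + 1)
        got = hit_map(scan_cas9(g, SpacerQuery(MCHERRY_SPACER)))
        want = oracle_scan(g.sequence, True, MCHERRY_SPACER)
        assert got == want


class TestGapConventions:
    def test_event_counting_is_never_stricter_on_single_base_bulges(self):
        """A single 1-bp bulge costs the same under both conventions; the
        conventions may diverge only for multi-base bulge runs."""
        genome = generate_genome(600, 0.5, seed=41)
        g, truth = plant_protospacer(
            genome, MCHERRY_SPACER, 200, "+",
            edits=[("dna_bulge", 8, "T"), ("sub", 3)], seed=8,
        )
        key = (truth.pam_proximal_position, "+")
        bases = hit_map(scan_cas9(g, SpacerQuery(MCHERRY_SPACER, gap_mode="bases")))
        events = hit_map(scan_cas9(g, SpacerQuery(MCHERRY_SPACER, gap_mode="events")))
        assert bases[key] == events[key] == (1, 1)

    def test_event_counting_admits_two_base_bulge_runs(self):
        """Under base counting a 2-bp bulge exhausts the gap budget; under
        event counting it costs a single gap, so hit sets can differ."""
        genome = generate_genome(600, 0.5, seed=42)
        g, truth = plant_protospacer(
            genome, MCHERRY_SPACER, 200, "+",
            edits=[("dna_bulge", 8, "T"), ("dna_bulge", 8, "G"),
                   ("dna_bulge", 14, "A")],
            seed=9,
        )
        key = (truth.pam_proximal_position, "+")
        bases = hit_map(scan_cas9(g, SpacerQuery(MCHERRY_SPACER, gap_mode="bases")))
        events = hit_map(scan_cas9(g, SpacerQuery(MCHERRY_SPACER, gap_mode="events")))
        # three bulged bases exceed the 2-base budget...
        assert key not in bases or sum(bases[key]) <= 6
        # ...but only two runs, within the 2-event budget
        assert key in events
        assert events[key][1] <= 2


class TestFixedSite:
    def test_planted_recognition_site_found_once_per_strand(self, small_genome):
        seq = small_genome.sequence
        g = Genome(seq[:500] + ISCEI_SITE + seq[500 + 18:], circular=True)
        hits = [h for h in scan_fixed_site(g, ISCEI_SITE, 0)]
        plus = [h for h in hits if h.strand == "+"]
        assert [h.position for h in plus] == [501]
        assert plus[0].n_mismatch == 0

    def test_absent_site_gives_empty_list(self, small_genome):
        assert scan_fixed_site(small_genome, ISCEI_SITE, 0) == []

    def test_mismatch_tolerance_counts_correctly(self, small_genome):
        site = ISCEI_SITE[:9] + "G" + ISCEI_SITE[10:]  # one substitution
        assert site != ISCEI_SITE
        g = Genome(small_genome.sequence[:500] + site +
                   small_genome.sequence[518:], circular=True)
        exact = {h.position for h in scan_fixed_site(g, ISCEI_SITE, 0)}
        fuzzy = {h.position: h.n_mismatch
                 for h in scan_fixed_site(g, ISCEI_SITE, 1) if h.strand == "+"}
        assert 501 not in exact
        assert fuzzy[501] == 1

    def test_minus_strand_occurrence_found(self, small_genome):
        probe = reverse_complement(ISCEI_SITE)
        g = Genome(small_genome.sequence[:900] + probe +
                   small_genome.sequence[918:], circular=True)
        minus = [h for h in scan_fixed_site(g, ISCEI_SITE, 0) if h.strand == "-"]
        assert [h.position for h in minus] == [901]
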