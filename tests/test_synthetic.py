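"""Generator statistics: Poisson clone loads, pooling noise, reproducibility."""

import math

import numpy as np
import pytest

from editaudit.records import PoolDesign
from editaudit.synthetic import (
    generate_genome,
    read_truth,
    simulate_clones,
    simulate_pools,
    write_truth,
)


class TestGenerateGenome:
    def test_length_contract(self):
        assert len(generate_genome(1000, 0.5, seed=7)) == 1000

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            generate_genome(0)

    def test_gc_content_within_binomial_bound(self):
        n, gc = 100_000, 0.7
        g = generate_genome(n, gc, seed=1)
        observed = sum(g.sequence.count(b) for b in "GC")
        sd = math.sqrt(n * gc * (1 - gc))
        assert abs(observed - n * gc) < 4 * sd

    def test_identical_seed_identical_sequence(self):
        assert generate_genome(5000, 0.5, seed=3).sequence == \
            generate_genome(5000, 0.5, seed=3).sequence


class TestSimulateClones:
    def test_zero_rate_means_no_mutations(self, small_genome):
        clones, _ = simulate_clones(50, small_genome, genome_rate=0.0, seed=2)
        assert all(not c.unintended_mutations for c in clones)

    def test_poisson_load_mean_and_variance(self, small_genome):
        mu_g, g = 9.3e-4, 80
        lam = mu_g * g
        clones, _ = simulate_clones(
            10_000, small_genome, genome_rate=mu_g, generations=g, seed=5
        )
        counts = np.array([len(c.unintended_mutations) for c in clones])
        se_mean = math.sqrt(lam / len(counts))
        assert abs(counts.mean() - lam) < 4 * se_mean
        # Poisson: variance equals the mean
        assert abs(counts.var() - lam) < 5 * se_mean

    def test_mutated_fraction_matches_closed_form(self, small_genome):
        mu_g, g, n = 9.3e-4, 80, 10_000
        expected = 1 - math.exp(-mu_g * g)
        clones, _ = simulate_clones(
            n, small_genome, genome_rate=mu_g, generations=g, seed=6
        )
        frac = sum(c.has_unintended for c in clones) / n
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * se

    def test_snv_share_within_binomial_ci(self, small_genome):
        clones, _ = simulate_clones(
            2000, small_genome, genome_rate=0.05, generations=20,
            snv_fraction=0.9, seed=7,
        )
        muts = [m for c in clones for m in c.unintended_mutations]
        share = sum(m.mut_class == "SNV" for m in muts) / len(muts)
        se = math.sqrt(0.9 * 0.1 / len(muts))
        assert abs(share - 0.9) < 4 * se

    def test_ref_base_matches_genome(self, small_genome):
        clones, _ = simulate_clones(
            200, small_genome, genome_rate=0.05, generations=20, seed=8
        )
        for c in clones:
            for m in c.unintended_mutations:
                if m.mut_class in ("SNV", "deletion"):
                    assert m.ref == small_genome.base(m.position)


class TestSimulatePools:
    def _roster(self, genome, seed=9):
        clones, _ = simulate_clones(
            3, genome, genome_rate=0.2, generations=40, seed=seed,
            clone_prefix="cl",
        )
        return clones

    def test_high_depth_fraction_near_design(self, small_genome):
        clones = self._roster(small_genome)
        design = PoolDesign("pool1", [(clones[0].clone_id, 0.18),
                                      (clones[1].clone_id, 0.32),
                                      (clones[2].clone_id, 0.50)])
        pooled = simulate_pools(clones, design, depth=10 ** 6, seed=1)
        private = {
            m.key: frac
            for c, frac in zip(clones, (0.18, 0.32, 0.50))
            for m in c.unintended_mutations
        }
        for rec in pooled:
            if rec.key in private:
                assert rec.read_fraction == pytest.approx(private[rec.key],
                                                          abs=0.005)

    def test_shared_mutations_sum_their_fractions(self, small_genome):
        clones = self._roster(small_genome)
        shared = clones[0].unintended_mutations[0]
        clones[1].unintended_mutations.append(
            type(shared)(clones[1].clone_id, shared.position, shared.ref,
                         shared.alt, shared.mut_class, 1.0)
        )
        design = PoolDesign("pool1", [(clones[0].clone_id, 0.18),
                                      (clones[1].clone_id, 0.32),
                                      (clones[2].clone_id, 0.50)])
        pooled = simulate_pools(clones, design, depth=10 ** 6, seed=2)
        by_key = {m.key: m.read_fraction for m in pooled}
        assert by_key[shared.key] == pytest.approx(0.50, abs=0.005)

    def test_mean_fraction_converges_to_design(self, small_genome):
        clones = self._roster(small_genome)
        key = clones[2].unintended_mutations[0].key
        design = PoolDesign("pool1", [(c.clone_id, f) for c, f in
                                      zip(clones, (0.18, 0.32, 0.50))])
        obs = []
        for rep in range(400):
            pooled = simulate_pools(clones, design, depth=100, seed=rep)
            for m in pooled:
                if m.key == key:
                    obs.append(m.read_fraction)
        se = math.sqrt(0.5 * 0.5 / 100) / math.sqrt(len(obs))
        assert abs(np.mean(obs) - 0.50) < 4 * se

    def test_unknown_clone_in_design_rejected(self, small_genome):
        clones = self._roster(small_genome)
        design = PoolDesign("pool1", [("ghost", 0.5)])
        with pytest.raises(ValueError, match="ghost"):
            simulate_pools(clones, design, depth=100, seed=1)

    def test_identical_seed_identical_pool(self, small_genome):
        clones = self._roster(small_genome)
        design = PoolDesign("p", [(c.clone_id, f) for c, f in
                                  zip(clones, (0.18, 0.32, 0.50))])
        a = simulate_pools(clones, design, depth=100, seed=33)
        b = simulate_pools(clones, design, depth=100, seed=33)
        assert a == b


class TestTruthRoundTrip:
    def test_truth_files_round_trip(self, small_genome, tmp_path):
        clones, truth = simulate_clones(
            20, small_genome, genome_rate=0.05, generations=40, seed=10
        )
        truth.pool_fractions = {clones[0].clone_id: 0.18,
                                clones[1].clone_id: 0.32}
        path = tmp_path / "truth.json"
        write_truth(truth, path)
        back = read_truth(path)
        assert back.genome_length == truth.genome_length
        assert back.pool_fractions == truth.pool_fractions
        assert {
            cid: [(m.position, m.ref, m.alt, m.mut_class) for m in muts]
            for cid, muts in back.clone_mutations.items()
        } == {
            cid: [(m.position, m.ref, m.alt, m.mut_class) for m in muts]
            for cid, muts in truth.clone_mutations.items()
        }
        # byte-identical on rewrite
        path2 = tmp_path / "truth2.json"
        write_truth(back, path2)
        assert path.read_bytes() == path2.read_bytes()
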