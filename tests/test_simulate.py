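"""Generator contracts: determinism, planted structure, codon calibration."""

import filecmp

import numpy as np
import pytest

from syntepoch.divergence import STOP_CODONS, ng86_kaks
from syntepoch.errors import ConfigError
from syntepoch.simulate import (
    EpochSpec,
    SimulationConfig,
    evolve_codon_pair,
    mutate_cds,
    simulate_dataset,
)


def full_retention_config(n=120, seed=7):
    epochs = {
        "recent": EpochSpec(depth=0.53, n_tracks=3, block_survival=1.0,
                            gene_retention=1.0, block_length=30),
        "young": EpochSpec(depth=1.17, n_tracks=3, block_survival=1.0,
                           gene_retention=1.0, block_length=30),
        "old": EpochSpec(depth=2.19, n_tracks=6, block_survival=1.0,
                         gene_retention=1.0, block_length=30),
    }
    return SimulationConfig(n_ancestral_genes=n, epochs=epochs, emit_cds=False,
                            rng_seed=seed)


class TestGenerator:
    def test_full_retention_gives_twelve_copies_and_index_four(self):
        # 3 x 2 x 2 lineages survive per ancestral gene without fractionation
        ds = simulate_dataset(full_retention_config())
        per_subject: dict[str, int] = {}
        for q, s in ds.truth.pair_ks:
            per_subject[s] = per_subject.get(s, 0) + 1
        assert set(per_subject.values()) == {12}
        assert set(ds.truth.retention_index.values()) == {4}

    def test_same_seed_is_byte_identical(self, tmp_path):
        for d in ("a", "b"):
            config = SimulationConfig(n_ancestral_genes=200, rng_seed=13,
                                      cds_codons=40)
            simulate_dataset(config).write(tmp_path / d)
        files = sorted(p.name for p in (tmp_path / "a").iterdir())
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", files, shallow=False)
        assert mismatch == [] and errors == []
        assert len(match) == len(files)

    def test_different_seeds_differ(self):
        a = simulate_dataset(SimulationConfig(n_ancestral_genes=200, emit_cds=False,
                                              rng_seed=1))
        b = simulate_dataset(SimulationConfig(n_ancestral_genes=200, emit_cds=False,
                                              rng_seed=2))
        assert a.truth.pair_ks != b.truth.pair_ks

    def test_truth_genes_all_exist_in_emitted_genomes(self, small_dataset):
        ds = small_dataset
        qids = {g.gene_id for g in ds.genes_query}
        sids = {g.gene_id for g in ds.genes_subject}
        for q, s in ds.truth.pair_ks:
            assert q in qids and s in sids
        assert set(ds.truth.retention_index) == sids

    def test_epoch_depth_ordering_reflected_in_planted_ks(self, small_dataset):
        ds = small_dataset
        by_epoch: dict[str, list[float]] = {}
        for pair, epoch in ds.truth.pair_epoch.items():
            if pair not in ds.truth.fast_pairs:
                by_epoch.setdefault(epoch, []).append(ds.truth.pair_ks[pair])
        means = {e: np.mean(v) for e, v in by_epoch.items()}
        assert means["recent"] < means["young"] < means["old"]
        assert means["recent"] == pytest.approx(0.53, abs=0.05)

    def test_impossible_config_rejected(self):
        with pytest.raises(ConfigError, match="fast_inflation"):
            SimulationConfig(fast_inflation=0.9).validate()
        bad = SimulationConfig()
        bad.epochs = {**bad.epochs,
                      "old": EpochSpec(0.4, 6, 0.02, 0.5, 30)}  # not increasing
        with pytest.raises(ConfigError, match="increasing"):
            bad.validate()

    def test_fate_mixture_must_sum_to_one(self):
        bad = SimulationConfig()
        bad.fate_mixture = {"dead": 0.5, "neutral": 0.2}
        with pytest.raises(ConfigError, match="sum to 1"):
            bad.validate()

    def test_zero_fast_fraction_plants_no_fast_genes(self):
        config = SimulationConfig(n_ancestral_genes=400, emit_cds=False,
                                  rng_seed=3, fast_fraction=0.0)
        ds = simulate_dataset(config)
        assert ds.truth.fast_pairs == set()

    def test_dead_groups_have_all_zero_expression(self, small_dataset):
        ds = small_dataset
        seen = 0
        for s, rec in ds.truth.fates.items():
            if rec["fate"] == "dead":
                for c in rec["copies"]:
                    assert (ds.expression.row(c) == 0).all()
                seen += 1
        assert seen > 0

    def test_spurious_anchors_are_added_on_request(self):
        config = SimulationConfig(n_ancestral_genes=300, emit_cds=False,
                                  rng_seed=5, spurious_anchor_rate=0.1)
        ds = simulate_dataset(config)
        true_pairs = set(ds.truth.pair_ks)
        extras = [a for a in ds.anchors
                  if (a.query_gene, a.subject_gene) not in true_pairs]
        assert len(extras) == round(0.1 * len(true_pairs))


class TestCodonEvolution:
    def test_zero_targets_give_identical_sequences(self):
        rng = np.random.default_rng(0)
        a, b = evolve_codon_pair(60, 0.0, 0.0, rng)
        assert a == b

    def test_no_stop_codons_ever_introduced(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a, b = evolve_codon_pair(50, 0.8, 0.2, rng)
            for seq in (a, b):
                codons = {seq[i:i + 3] for i in range(0, len(seq), 3)}
                assert not (codons & STOP_CODONS)

    def test_sequences_differ_only_by_point_substitutions(self):
        rng = np.random.default_rng(2)
        a, b = evolve_codon_pair(80, 0.3, 0.05, rng)
        assert len(a) == len(b)
        assert any(x != y for x, y in zip(a, b))

    def test_monte_carlo_calibration_at_moderate_divergence(self):
        # estimates from the counting estimator recover the planted targets
        rng = np.random.default_rng(42)
        ks_values, ka_values = [], []
        for _ in range(200):
            a, b = evolve_codon_pair(300, 0.3, 0.03, rng)
            pair = ng86_kaks(a, b)
            ks_values.append(pair.ks)
            ka_values.append(pair.ka)
        assert 0.27 <= float(np.mean(ks_values)) <= 0.33
        assert 0.027 <= float(np.mean(ka_values)) <= 0.033

    def test_single_replicate_agrees_with_independent_hand_count(self):
        # one replicate checked against a from-scratch proportion count
        from test_divergence import oracle_counts

        rng = np.random.default_rng(9)
        a, b = evolve_codon_pair(100, 0.2, 0.02, rng)
        pair = ng86_kaks(a, b)
        s, n, sd, nd = oracle_counts(a, b)
        assert pair.s_diffs == pytest.approx(sd, abs=1e-9)
        assert pair.n_diffs == pytest.approx(nd, abs=1e-9)

    def test_short_sequence_with_tiny_target_warns(self):
        rng = np.random.default_rng(3)
        with pytest.warns(UserWarning, match="barely resolvable"):
            evolve_codon_pair(30, 0.001, 0.0, rng)

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ConfigError, match=">= 30"):
            evolve_codon_pair(10, 0.1, 0.01, np.random.default_rng(0))

    def test_mutate_cds_applies_requested_event_counts(self):
        rng = np.random.default_rng(4)
        cds = "ATGGCTAAAGATCCTGGT" * 10
        mutated = mutate_cds(cds, 5, 0, rng)
        from Bio.Seq import Seq
        assert str(Seq(mutated).translate()) == str(Seq(cds).translate())
        diffs = sum(x != y for x, y in zip(cds, mutated))
        assert 1 <= diffs <= 5  # repeated hits may collapse
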