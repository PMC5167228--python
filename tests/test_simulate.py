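"""Synthetic barcode generator: determinism, calibration, truth structure."""

import numpy as np
import pytest

import barcodelim as bl
from barcodelim.core_io import ValidationError


class TestConfig:
    def test_infeasible_rejected(self):
        with pytest.raises(ValidationError):
            bl.SimConfig(n_species=5, singleton_fraction=1.5)
        with pytest.raises(ValidationError):
            bl.SimConfig(n_species=2, n_clades=5)
        with pytest.raises(ValidationError):
            bl.SimConfig(n_species=5, mean_specimens_per_species=1.0,
                         singleton_fraction=0.1)

    def test_profile_validates(self):
        cfg = bl.paper_scale_profile()
        assert cfg.n_species == 124
        assert cfg.seq_length == 633
        assert cfg.n_clades == 5


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        cfg = bl.SimConfig(n_species=6, n_clades=2, seed=5)
        a1, t1 = bl.simulate_dataset(cfg)
        a2, t2 = bl.simulate_dataset(cfg)
        assert a1.records == a2.records
        assert t1.species_partition.assignment == \
            t2.species_partition.assignment
        assert t1.true_tree.newick() == t2.true_tree.newick()

    def test_different_seed_differs(self):
        a1, _ = bl.simulate_dataset(bl.SimConfig(n_species=6, n_clades=2, seed=5))
        a2, _ = bl.simulate_dataset(bl.SimConfig(n_species=6, n_clades=2, seed=6))
        assert a1.records != a2.records


class TestStructure:
    def test_zero_mutation_scale_identical_sequences(self):
        aln, _ = bl.simulate_dataset(
            bl.SimConfig(n_species=4, n_clades=1, mutation_scale=0.0, seed=1)
        )
        seqs = {s for _, s in aln.records}
        assert len(seqs) == 1
        dm = bl.pairwise_k2p(aln)
        assert np.allclose(dm.d, 0.0)

    def test_true_tree_ultrametric_with_branching_times(self):
        _, truth = bl.simulate_dataset(
            bl.SimConfig(n_species=8, n_clades=2, seed=3)
        )
        assert truth.true_tree.is_ultrametric
        times = bl.branching_times(truth.true_tree)
        n_leaves = len(truth.true_tree.leaf_labels)
        assert len(times) == n_leaves - 1

    def test_partition_covers_all_specimens(self):
        aln, truth = bl.simulate_dataset(
            bl.SimConfig(n_species=8, n_clades=2, seed=3)
        )
        assert set(truth.species_partition.assignment) == set(aln.ids)
        assert truth.species_partition.n_clusters == 8
        clades = {truth.clade_labels[s]
                  for s in truth.species_partition.assignment.values()}
        assert clades == {"clade1", "clade2"}

    def test_duplicate_haplotypes_injected(self):
        cfg = bl.SimConfig(n_species=6, n_clades=1, seed=2,
                           mean_specimens_per_species=8.0,
                           duplicate_haplotype_rate=0.8)
        aln, _ = bl.simulate_dataset(cfg)
        collapsed, _ = bl.collapse_haplotypes(aln)
        assert len(collapsed) < len(aln)

    def test_n_masking(self):
        cfg = bl.SimConfig(n_species=3, n_clades=1, seed=2, n_mask_rate=0.1)
        aln, _ = bl.simulate_dataset(cfg)
        assert any("N" in s for _, s in aln.records)


class TestCalibration:
    def test_distance_targets_over_seeds(self):
        """Monte-Carlo check of the K2P calibration: realized mean
        within-species and between-clade distances near the targets."""
        within, between = [], []
        for seed in range(6):
            cfg = bl.SimConfig(n_species=20, seed=seed)
            aln, truth = bl.simulate_dataset(cfg)
            dm = bl.pairwise_k2p(aln)
            clades = {
                s: truth.clade_labels[m.nominal_species]
                for s, m in aln.metadata.items()
            }
            summ = bl.distance_summaries(dm, truth.species_partition, clades)
            if summ.mean_within is not None:
                within.append(summ.mean_within)
            cm = summ.clade_matrix
            vals = [
                cm.iloc[j, i]
                for i in range(len(cm)) for j in range(i + 1, len(cm))
                if not np.isnan(cm.iloc[j, i])
            ]
            between.append(np.mean(vals))
        assert 0.002 <= np.mean(within) <= 0.008
        assert 0.13 <= np.mean(between) <= 0.25

    def test_inter_target_monotone(self):
        means = []
        for target in (0.12, 0.188, 0.26):
            cfg = bl.SimConfig(n_species=12, n_clades=3, seed=7,
                               target_inter=target,
                               min_species_split=0.05)
            aln, truth = bl.simulate_dataset(cfg)
            dm = bl.pairwise_k2p(aln)
            idx = {s: k for k, s in enumerate(dm.ids)}
            clade = {s: truth.clade_labels[m.nominal_species]
                     for s, m in aln.metadata.items()}
            vals = [
                dm.d[idx[a], idx[b]]
                for i, a in enumerate(dm.ids) for b in dm.ids[i + 1:]
                if clade[a] != clade[b]
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestPaperProfile:
    def test_truth_counts(self):
        for seed in (0, 1):
            cfg = bl.paper_scale_profile(seed=seed)
            aln, truth = bl.simulate_dataset(cfg)
            assert truth.species_partition.n_clusters == 124
            assert len(truth.species_partition.singletons()) >= 25
            assert aln.length == 633
            assert len({truth.clade_labels[s]
                        for s in truth.clade_labels}) == 5
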