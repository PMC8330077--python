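"""Generators: determinism, motif exactness, calibration, forward models."""

import re

import numpy as np
import pytest

from methylatlas import cpg_profile as cp
from methylatlas import repertoire as rp
from methylatlas import restriction_luma as rl
from methylatlas import synthdata as sd


class TestTranscriptome:
    @pytest.mark.parametrize("target", [0.3, 0.55, 1.0])
    def test_mean_oe_calibrated_to_target(self, target):
        seqs = sd.simulate_transcriptome(
            n=5000, length_range=(500, 1500), gc=0.4, target_oe=target, seed=42
        )
        mean_oe = np.mean([cp.cpg_oe(s).oe for s in seqs])
        assert abs(mean_oe - target) < 0.03

    def test_deterministic_under_seed(self):
        a = sd.simulate_transcriptome(20, (100, 200), 0.4, 0.6, seed=7)
        b = sd.simulate_transcriptome(20, (100, 200), 0.4, 0.6, seed=7)
        assert [r.residues for r in a] == [r.residues for r in b]
        c = sd.simulate_transcriptome(20, (100, 200), 0.4, 0.6, seed=8)
        assert [r.residues for r in a] != [r.residues for r in c]

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n=0, length_range=(100, 200), gc=0.4, target_oe=0.5),
            dict(n=5, length_range=(100, 200), gc=0.4, target_oe=0.0),
            dict(n=5, length_range=(100, 200), gc=0.4, target_oe=6.0),  # CG prob > 1
            dict(n=5, length_range=(200, 100), gc=0.4, target_oe=0.5),
        ],
    )
    def test_invalid_parameters_raise(self, kwargs):
        with pytest.raises(ValueError):
            sd.simulate_transcriptome(seed=0, **kwargs)


class TestGenomeWithSites:
    def test_declared_counts_match_independent_scan(self):
        genome = sd.simulate_genome_with_sites(20_000, 60, 30, gc=0.4, seed=3)
        seq = genome.record.residues
        # oracle: regex lookahead scan, independent of find_sites
        ccgg = [m.start() for m in re.finditer("(?=CCGG)", seq)]
        ecori = [m.start() for m in re.finditer("(?=GAATTC)", seq)]
        assert len(ccgg) == genome.declared_ccgg_count == 60
        assert len(ecori) == genome.declared_ecori_count == 30
        assert tuple(ccgg) == genome.ccgg_positions
        assert tuple(ecori) == genome.ecori_positions

    def test_zero_sites_genome_is_motif_free(self):
        genome = sd.simulate_genome_with_sites(5_000, 0, 0, gc=0.5, seed=1)
        assert "CCGG" not in genome.record.residues
        assert "GAATTC" not in genome.record.residues

    def test_overfull_genome_raises_placement_error(self):
        with pytest.raises(sd.PlacementError):
            sd.simulate_genome_with_sites(10, 3, 0, gc=0.5, seed=0)

    def test_deterministic_under_seed(self):
        a = sd.simulate_genome_with_sites(3_000, 10, 5, gc=0.4, seed=9)
        b = sd.simulate_genome_with_sites(3_000, 10, 5, gc=0.4, seed=9)
        assert a.record.residues == b.record.residues


class TestMethylomeAssignment:
    def test_exact_count_of_flagged_sites(self):
        genome = sd.simulate_genome_with_sites(5_000, 30, 0, gc=0.4, seed=2)
        track = sd.assign_ccgg_methylation(genome, 0.8, seed=5)
        assert track.n_methylated == round(0.8 * 30) == 24
        assert track.site_positions == genome.ccgg_positions

    @pytest.mark.parametrize("fraction,expected", [(0.0, 0), (1.0, 30)])
    def test_boundary_fractions(self, fraction, expected):
        genome = sd.simulate_genome_with_sites(5_000, 30, 0, gc=0.4, seed=2)
        track = sd.assign_ccgg_methylation(genome, fraction, seed=5)
        assert track.n_methylated == expected

    def test_fraction_outside_unit_interval_raises(self):
        genome = sd.simulate_genome_with_sites(1_000, 5, 0, gc=0.4, seed=2)
        with pytest.raises(ValueError):
            sd.assign_ccgg_methylation(genome, 1.2, seed=0)


class TestBisulfiteReads:
    def test_fully_methylated_cpg_always_reads_c(self):
        locus = sd.SequenceRecord("l", "AACGTT")
        reads = sd.simulate_bisulfite_reads(locus, [1.0], 50, 0.98, 0.0, seed=1)
        assert all(r[2] == "C" for r in reads.reads)

    def test_unmethylated_fully_converted_reads_t(self):
        locus = sd.SequenceRecord("l", "AACGTT")
        reads = sd.simulate_bisulfite_reads(locus, [0.0], 50, 1.0, 0.0, seed=1)
        assert all(r[2] == "T" for r in reads.reads)

    def test_partial_conversion_leaves_closed_form_c_fraction(self):
        # (1-m)(1-c) + m with m=0, c=0.98 -> 2% C
        locus = sd.SequenceRecord("l", "AACGTT")
        reads = sd.simulate_bisulfite_reads(locus, [0.0], 20_000, 0.98, 0.0, seed=1)
        c_frac = sum(r[2] == "C" for r in reads.reads) / len(reads.reads)
        assert abs(c_frac - 0.02) < 0.005

    def test_invalid_inputs_raise(self):
        locus = sd.SequenceRecord("l", "AACGTT")
        with pytest.raises(ValueError):
            sd.simulate_bisulfite_reads(locus, [0.5], 0, 1.0, 0.0, seed=1)
        with pytest.raises(ValueError):
            sd.simulate_bisulfite_reads(locus, [0.5, 0.5], 5, 1.0, 0.0, seed=1)


class TestPyrogramNoise:
    def _pyro(self):
        return rl.Pyrogram(reaction="HpaII+EcoRI", peaks=(2.0, 4.0, 2.0, 0.0, 4.0, 2.0, 2.0))

    def test_zero_cv_is_identity(self):
        p = self._pyro()
        assert sd.add_pyrogram_noise(p, 0.0, seed=1).peaks == p.peaks

    def test_same_seed_same_noise(self):
        p = self._pyro()
        a = sd.add_pyrogram_noise(p, 0.1, seed=3)
        b = sd.add_pyrogram_noise(p, 0.1, seed=3)
        assert a.peaks == b.peaks

    def test_peaks_never_negative(self):
        p = self._pyro()
        noisy = sd.add_pyrogram_noise(p, 2.0, seed=4)  # huge cv forces clamping
        assert all(x >= 0 for x in noisy.peaks)


class TestRepertoireEvolution:
    def test_zero_rates_copy_root_everywhere(self):
        tree = rp.load_tree("((A,B),(C,D));", is_path=False)
        mat = sd.simulate_repertoire_evolution(
            tree, ["f1", "f2"], [1, 3], loss_rate=0.0, dup_rate=0.0, seed=1
        )
        assert (mat.counts["f1"] == 1).all()
        assert (mat.counts["f2"] == 3).all()

    def test_deterministic_under_seed(self):
        tree = rp.load_tree("((A,B),(C,D));", is_path=False)
        a = sd.simulate_repertoire_evolution(tree, ["f"], [2], 0.3, 0.3, seed=5)
        b = sd.simulate_repertoire_evolution(tree, ["f"], [2], 0.3, 0.3, seed=5)
        assert a.counts.equals(b.counts)

    def test_losses_only_dollo_recovers_root_when_survivors_span_clades(self):
        # with pure loss, reconstruction is exact whenever possessors span
        # at least two child clades of the root (the origin then maps to it)
        tree = rp.load_tree("((A,B),(C,D),(E,F));", is_path=False)
        recovered = checked = 0
        for seed in range(30):
            mat = sd.simulate_repertoire_evolution(
                tree, ["f"], [1], loss_rate=0.25, dup_rate=0.0, seed=seed
            )
            pres = {s: bool(mat.counts.loc[s, "f"] >= 1) for s in mat.species}
            clades = [{"A", "B"}, {"C", "D"}, {"E", "F"}]
            spanning = sum(any(pres[x] for x in c) for c in clades) >= 2
            if spanning:
                checked += 1
                rec = rp.dollo_reconstruct(tree, pres)
                root_id = next(iter(tree_root_id(tree)))
                recovered += rec.node_states[root_id]
        assert checked > 0 and recovered == checked

    def test_unrooted_tree_rejected(self):
        import dendropy

        tree = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        tree.is_rooted = False
        with pytest.raises(ValueError):
            sd.simulate_repertoire_evolution(tree, ["f"], [1], 0.1, 0.1, seed=1)


def tree_root_id(tree):
    from methylatlas.repertoire import _indexed_nodes

    ids = _indexed_nodes(tree)
    return [ids[id(tree.seed_node)]]
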