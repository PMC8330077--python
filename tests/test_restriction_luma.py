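"""Digestion model, virtual gel, pyrogram arithmetic and LUMA estimator."""

import numpy as np
import pytest

from methylatlas import restriction_luma as rl
from methylatlas import synthdata as sd


def genome_from_string(s: str) -> sd.Genome:
    ccgg = tuple(rl.find_sites(s, "CCGG"))
    ecori = tuple(rl.find_sites(s, "GAATTC"))
    return sd.Genome(
        record=sd.SequenceRecord("g", s),
        declared_ccgg_count=len(ccgg),
        declared_ecori_count=len(ecori),
        ccgg_positions=ccgg,
        ecori_positions=ecori,
    )


class TestFindSites:
    @pytest.mark.parametrize(
        "seq,motif,expected",
        [
            ("AAACCGGTT", "CCGG", [3]),
            ("CCGGCCGG", "CCGG", [0, 4]),
            ("ATATAT", "CCGG", []),
            ("AAAA", "AA", [0, 1, 2]),  # overlapping occurrences
        ],
    )
    def test_hand_scanned_positions(self, seq, motif, expected):
        assert rl.find_sites(seq, motif) == expected

    def test_motif_with_n_rejected(self):
        with pytest.raises(ValueError):
            rl.find_sites("ACGT", "CNG")


class TestDigest:
    SEQ = "AAACCGGAAACCGGAAA"  # CCGG at 3 and 10, L=17

    def test_mspi_cuts_every_ccgg(self):
        res = rl.digest(genome_from_string(self.SEQ), "MspI")
        assert res.cut_positions == (4, 11)
        assert res.fragment_lengths == (4, 7, 6)

    def test_hpaii_blocked_by_methylation(self):
        g = genome_from_string(self.SEQ)
        track = sd.MethylomeTrack(site_positions=(3, 10), methylated=(True, False))
        res = rl.digest(g, "HpaII", track)
        assert res.cut_positions == (11,)
        assert res.fragment_lengths == (11, 6)

    def test_no_sites_single_fragment(self):
        g = genome_from_string("ATATATATAT")
        res = rl.digest(g, "MspI")
        assert res.cut_positions == ()
        assert res.fragment_lengths == (10,)

    def test_combined_reaction_unions_cut_sets(self):
        g = genome_from_string("AAACCGGAAAGAATTCAAA")  # CCGG@3, GAATTC@10
        res = rl.digest(g, "MspI+EcoRI")
        assert res.cut_positions == (4, 11)
        assert res.ccgg_cuts == 1 and res.ecori_cuts == 1

    def test_inconsistent_methylome_rejected(self):
        g = genome_from_string(self.SEQ)
        bad = sd.MethylomeTrack(site_positions=(5,), methylated=(True,))
        with pytest.raises(ValueError, match="not a CCGG site"):
            rl.digest(g, "HpaII", bad)

    def test_mass_conserved_and_hpaii_nested_in_mspi(self, rng):
        for i in range(40):
            g = sd.simulate_genome_with_sites(4_000, 12, 6, gc=0.4, seed=1000 + i)
            f = float(rng.uniform(0, 1))
            track = sd.assign_ccgg_methylation(g, f, seed=i)
            for enzyme in ("HpaII", "MspI", "EcoRI", "HpaII+EcoRI", "MspI+EcoRI"):
                res = rl.digest(g, enzyme, track)
                assert sum(res.fragment_lengths) == g.record.length
                assert len(res.fragment_lengths) == len(res.cut_positions) + 1
            h = set(rl.digest(g, "HpaII", track).cut_positions)
            m = set(rl.digest(g, "MspI", track).cut_positions)
            assert h <= m
            if track.n_methylated == 0:
                assert h == m


class TestVirtualGel:
    def test_single_fragment_in_one_bin(self):
        res = rl.digest(genome_from_string("ATATATATAT"), "MspI")
        gel = rl.virtual_gel(res, n_bins=10, frag_range=(1, 100))
        assert np.count_nonzero(gel.mass_per_bin) == 1
        assert gel.mass_per_bin.sum() == 10

    def test_total_mass_equals_genome_length(self):
        res = rl.digest(genome_from_string("AAACCGGAAACCGGAAA"), "MspI")
        gel = rl.virtual_gel(res, n_bins=8, frag_range=(1, 100))
        assert gel.mass_per_bin.sum() == 17

    def test_fully_methylated_hpaii_lane_runs_high(self):
        g = sd.simulate_genome_with_sites(50_000, 80, 0, gc=0.4, seed=4)
        track = sd.assign_ccgg_methylation(g, 1.0, seed=0)
        gel_h = rl.virtual_gel(rl.digest(g, "HpaII", track), 20, (50, 100_000))
        gel_m = rl.virtual_gel(rl.digest(g, "MspI", track), 20, (50, 100_000))
        centers = np.sqrt(gel_h.bin_edges[:-1] * gel_h.bin_edges[1:])

        def mass_weighted_size(gel):
            return (gel.mass_per_bin * centers).sum() / gel.mass_per_bin.sum()

        assert mass_weighted_size(gel_h) > 10 * mass_weighted_size(gel_m)

    def test_invalid_bin_count_raises(self):
        res = rl.digest(genome_from_string("ATAT"), "MspI")
        with pytest.raises(ValueError):
            rl.virtual_gel(res, n_bins=0)


class TestPyrogram:
    def _digest_result(self, ccgg, ecori):
        return rl.DigestResult(
            enzyme="MspI+EcoRI",
            cut_positions=(),
            fragment_lengths=(1,),
            ccgg_cuts=ccgg,
            ecori_cuts=ecori,
        )

    def test_fill_in_stoichiometry(self):
        pyro = rl.pyrogram_from_digest(self._digest_result(2, 1))
        p = pyro.peaks
        assert p[1] + p[4] == 8  # dGTP+dCTP
        assert p[0] + p[5] == 4  # dATP
        assert p[2] + p[6] == 4  # dTTP
        assert p[3] == 0  # H2O control

    def test_no_ccgg_cuts_means_zero_gc_peaks(self):
        pyro = rl.pyrogram_from_digest(self._digest_result(0, 3))
        assert pyro.peaks[1] == 0 and pyro.peaks[4] == 0

    def test_single_enzyme_digest_rejected(self):
        res = rl.DigestResult("MspI", (), (1,), 1, 0)
        with pytest.raises(ValueError):
            rl.pyrogram_from_digest(res)

    def test_ratio_equals_ccgg_over_ecori_cuts(self):
        pyro = rl.pyrogram_from_digest(self._digest_result(2, 1))
        assert rl.luma_ratio(pyro) == pytest.approx(2.0)

    def test_zero_ecori_cuts_is_a_control_failure(self):
        pyro = rl.pyrogram_from_digest(self._digest_result(2, 0))
        with pytest.raises(rl.LumaError, match="EcoRI"):
            rl.luma_ratio(pyro)


class TestLumaEstimator:
    def _pyro(self, ccgg, ecori, reaction):
        return rl.pyrogram_from_digest(
            rl.DigestResult(reaction, (), (1,), ccgg, ecori)
        )

    def test_equal_ratios_mean_zero_percent(self):
        h = self._pyro(10, 5, "HpaII+EcoRI")
        m = self._pyro(10, 5, "MspI+EcoRI")
        assert rl.luma_percent_methylation(h, m).percent_methylation == 0.0

    def test_zero_hpaii_ratio_means_fully_methylated(self):
        h = self._pyro(0, 5, "HpaII+EcoRI")
        m = self._pyro(10, 5, "MspI+EcoRI")
        assert rl.luma_percent_methylation(h, m).percent_methylation == 100.0

    def test_printed_formula_arithmetic(self):
        # HpaII/EcoRI = 0.4, MspI/EcoRI = 2.0 -> 100 x (1 - 0.2) = 80%
        h = self._pyro(2, 5, "HpaII+EcoRI")
        m = self._pyro(10, 5, "MspI+EcoRI")
        res = rl.luma_percent_methylation(h, m)
        assert res.ratio_hpaii == pytest.approx(0.4)
        assert res.ratio_mspi == pytest.approx(2.0)
        assert res.percent_methylation == pytest.approx(80.0)

    def test_zero_mspi_ratio_raises(self):
        h = self._pyro(0, 5, "HpaII+EcoRI")
        m = self._pyro(0, 5, "MspI+EcoRI")
        with pytest.raises(rl.LumaError):
            rl.luma_percent_methylation(h, m)

    def test_negative_raw_percent_clamped_and_flagged(self):
        h = rl.Pyrogram("HpaII+EcoRI", (2.0, 12.0, 2.0, 0.0, 12.0, 2.0, 2.0))
        m = rl.Pyrogram("MspI+EcoRI", (2.0, 8.0, 2.0, 0.0, 8.0, 2.0, 2.0))
        res = rl.luma_percent_methylation(h, m)
        assert res.raw_percent < 0
        assert res.percent_methylation == 0.0 and res.clamped

    @pytest.mark.parametrize("fraction", [0.0, 0.25, 0.5, 0.8, 1.0])
    def test_noise_free_chain_recovers_exact_fraction(self, fraction):
        g = sd.simulate_genome_with_sites(10_000, 40, 20, gc=0.4, seed=6)
        track = sd.assign_ccgg_methylation(g, fraction, seed=7)
        pct, _ = rl.estimate_percent_methylation(g, track)
        assert pct == pytest.approx(100.0 * track.n_methylated / 40, abs=1e-9)

    @pytest.mark.parametrize("n_ecori", [10, 150, 1000])
    def test_estimator_invariant_to_ecori_count(self, n_ecori):
        g = sd.simulate_genome_with_sites(60_000, 40, n_ecori, gc=0.4, seed=8)
        track = sd.assign_ccgg_methylation(g, 0.8, seed=9)
        pct, _ = rl.estimate_percent_methylation(g, track)
        assert pct == pytest.approx(80.0, abs=1e-9)
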