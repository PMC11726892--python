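"""Synthetic-study generator: digest, truth, reads, lesion track."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rremtools import simulate as sim

DNA = st.text(alphabet="ACGT", min_size=0, max_size=2000)


# ---------------------------------------------------------------------------
# MspI digest
# ---------------------------------------------------------------------------

class TestDigest:
    def test_hand_worked_fragments(self):
        # brute-force oracle: CCGG at 2 and 10 -> cuts at 3 and 11
        seq = "TTCCGGAATTCCGGTT"
        assert sim.mspi_fragments(seq) == [(0, 3), (3, 11), (11, 16)]
        assert sim.digest_mspi(seq, 4, 10) == [(3, 11), (11, 16)]
        assert sim.digest_mspi(seq, 6, 8) == [(3, 11)]

    def test_no_site_yields_whole_contig(self):
        assert sim.digest_mspi("ATATATAT", 1, 10**9) == [(0, 8)]

    def test_size_window_inclusive(self):
        seq = "A" * 3 + "CCGG" + "A" * 10  # cuts at 4 -> fragments 4 and 13
        assert sim.digest_mspi(seq, 4, 13) == [(0, 4), (4, 17)]
        assert sim.digest_mspi(seq, 5, 12) == []

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sim.digest_mspi("ACGT", 10, 5)
        with pytest.raises(ValueError):
            sim.digest_mspi("acgt", 1, 10)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(DNA)
    def test_fragments_tile_sequence(self, seq):
        frags = sim.mspi_fragments(seq)
        assert "".join(seq[s:e] for s, e in frags) == seq
        for s, e in frags[1:]:
            assert seq[s - 1:s + 3] == "CCGG"
        retained = sim.digest_mspi(seq, 2, 50)
        assert set(retained) <= set(frags)
        assert all(2 <= e - s <= 50 for s, e in retained)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

class TestGenome:
    def test_deterministic_per_seed(self):
        a = sim.generate_genome(1, 1, 20_000, island_count=2)
        b = sim.generate_genome(1, 1, 20_000, island_count=2)
        assert a.contigs == b.contigs
        assert a.annotation == b.annotation

    def test_seed_changes_sequence_not_shape(self):
        a = sim.generate_genome(1, 2, 20_000, island_count=0)
        b = sim.generate_genome(2, 2, 20_000, island_count=0)
        assert list(a.contigs) == list(b.contigs)
        assert {k: len(v) for k, v in a.contigs.items()} == \
               {k: len(v) for k, v in b.contigs.items()}
        assert a.contigs["chr1"] != b.contigs["chr1"]

    def test_zero_islands(self):
        g = sim.generate_genome(3, 1, 20_000, island_count=0)
        assert g.annotation["CpG_island"] == []

    def test_ccgg_density_invariant(self, genome_small):
        for name, seq in genome_small.contigs.items():
            per5kb = seq.count("CCGG") / (len(seq) / 5000)
            assert per5kb >= 1.0

    def test_annotation_within_bounds(self, genome_small):
        lengths = {c: len(s) for c, s in genome_small.contigs.items()}
        for cat, ivals in genome_small.annotation.items():
            for contig, s, e in ivals:
                assert contig not in sim.SPIKE_CONTIGS
                assert 0 <= s < e <= lengths[contig]

    def test_spikes_fixed_and_cpg_rich(self):
        lam = sim.lambda_spike_sequence()
        puc = sim.puc19_spike_sequence()
        assert lam == sim.lambda_spike_sequence()
        assert len(lam) >= 2000 and len(puc) >= 2000
        assert sim.find_cpg_sites(lam).size >= 50
        assert sim.find_cpg_sites(puc).size >= 50
        # MspI digestion of the spikes keeps usable fragments
        assert len(sim.digest_mspi(lam)) >= 5

    def test_bad_args_rejected(self):
        with pytest.raises(ValueError):
            sim.generate_genome(1, 0, 20_000)
        with pytest.raises(ValueError):
            sim.generate_genome(1, 1, 500)


# ---------------------------------------------------------------------------
# modification truth
# ---------------------------------------------------------------------------

class TestTruth:
    def test_marginal_mostly_low_methylation(self, study_small):
        t = study_small["truths"]["WT"]
        main = t[~t["contig"].isin(sim.SPIKE_CONTIGS)]
        assert (main["p_m"] <= 0.10).mean() >= 0.60
        assert ((main["p_m"] + main["p_h"]) <= 1.0 + 1e-12).all()

    def test_spike_truth_idealized(self, study_small):
        t = study_small["truths"]["WT"]
        lam = t[t["contig"] == sim.LAMBDA_SPIKE]
        puc = t[t["contig"] == sim.PUC19_SPIKE]
        assert (lam[["p_m", "p_h"]] == 0).all().all()
        assert (puc["p_m"] == 1).all() and (puc["p_h"] == 0).all()

    def test_zero_effects_share_baseline(self, genome_small):
        design = sim.StudyDesign(groups=("A", "B"), effects={}, seed=3)
        truths, ledger = sim.generate_truth(genome_small, design)
        pd.testing.assert_frame_equal(truths["A"], truths["B"])
        assert ledger.empty

    def test_effect_ledger_exact_count(self, study_small):
        t = study_small["truths"]["WT"]
        n_main = int((~t["contig"].isin(sim.SPIKE_CONTIGS)).sum())
        led = study_small["ledger"]
        dko = led[(led["group"] == "DKO") & (led["target"] == "p_h")]
        assert len(dko) == round(0.02 * n_main)
        # effects keep probabilities valid
        dko_truth = study_small["truths"]["DKO"]
        assert ((dko_truth["p_m"] + dko_truth["p_h"]) <= 1.0 + 1e-12).all()


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _one_site_setup(p_m, p_h, depth):
    truth = pd.DataFrame({"contig": ["c"], "pos": [10],
                          "p_m": [p_m], "p_h": [p_h]})
    frags = {"c": [(0, 50)]}
    design = sim.StudyDesign(groups=("G",), effects={}, mean_depth=depth,
                             e_fail=0.0, e_over=0.0, e_seq=0.0, seed=0)
    return truth, frags, design


class TestReads:
    def test_unknown_assay_rejected(self):
        truth, frags, design = _one_site_setup(0.5, 0.0, 10)
        with pytest.raises(ValueError, match="assay"):
            sim.simulate_reads(frags, truth, "BS", design)

    def test_protection_rule_forced(self):
        truth, frags, design = _one_site_setup(1.0, 0.0, 200)
        rng = np.random.default_rng(0)
        hm = sim.simulate_reads(frags, truth, "RREhM", design, rng=rng)
        assert (hm["observed_state"] == "T").all()  # 5mC unprotected in RREhM
        m = sim.simulate_reads(frags, truth, "RREM", design,
                               rng=np.random.default_rng(0))
        assert (m["observed_state"] == "C").all()

    def test_error_free_levels_binomial(self):
        truth, frags, design = _one_site_setup(0.4, 0.3, 5000)
        for assay, expect in (("RREM", 0.7), ("RREhM", 0.3)):
            calls = sim.simulate_reads(frags, truth, assay, design,
                                       rng=np.random.default_rng(11))
            freq = (calls["observed_state"] == "C").mean()
            se = np.sqrt(expect * (1 - expect) / len(calls))
            assert abs(freq - expect) <= 3 * se

    def test_expected_level_with_errors(self):
        truth = pd.DataFrame({"contig": "c", "pos": np.arange(5) * 10,
                              "p_m": [0.0, 0.2, 0.5, 0.9, 1.0],
                              "p_h": [0.0, 0.1, 0.2, 0.05, 0.0]})
        frags = {"c": [(0, 60)]}
        design = sim.StudyDesign(groups=("G",), effects={}, mean_depth=4000,
                                 e_fail=0.01, e_over=0.02, e_seq=0.005, seed=0)
        calls = sim.simulate_reads(frags, truth, "RREM", design,
                                   rng=np.random.default_rng(5))
        freqs = (calls.assign(c=calls["observed_state"].eq("C"))
                      .groupby("cpg_position")["c"].agg(["mean", "size"]))
        exp = sim.expected_level(truth["p_m"], truth["p_h"], "RREM", design)
        for pos, e in zip(truth["pos"], exp):
            row = freqs.loc[pos]
            se = np.sqrt(max(e * (1 - e), 1e-9) / row["size"])
            assert abs(row["mean"] - e) <= 4 * se

    def test_depth_poisson_and_spike_multiplier(self, study_small):
        calls = sim.simulate_reads(study_small["fragments"],
                                   study_small["truths"]["WT"], "RREM",
                                   study_small["design"],
                                   rng=np.random.default_rng(2))
        by = calls.groupby("contig")["read_id"].size()
        n_lam_sites = calls[calls["contig"] == sim.LAMBDA_SPIKE]["cpg_position"].nunique()
        mean_lam_depth = by[sim.LAMBDA_SPIKE] / n_lam_sites
        assert mean_lam_depth > 5 * study_small["design"].mean_depth


# ---------------------------------------------------------------------------
# lesion track
# ---------------------------------------------------------------------------

class TestLesionTrack:
    def test_zero_noise_zero_effect(self, genome_small):
        tr = sim.simulate_lesion_track(genome_small, noise_sd=0.0)
        assert (tr.data["value"] == 0).all()
        widths = tr.data["end"] - tr.data["start"]
        assert widths.max() == 100

    def test_effect_hits_exactly_overlapping_bins(self, genome_small):
        region = [("chr1", 150, 250)]
        tr = sim.simulate_lesion_track(genome_small, bin_width=100,
                                       enriched_regions=region, effect=1.0,
                                       noise_sd=0.0)
        sub = tr.data[tr.data["contig"] == "chr1"]
        hot = sub[sub["value"] == 1.0]
        assert hot["start"].tolist() == [100, 200]
        assert (sub["value"] != 0).sum() == 2

    def test_noise_mean_near_zero(self, genome_small):
        tr = sim.simulate_lesion_track(genome_small, bin_width=10,
                                       noise_sd=0.3, seed=4)
        assert len(tr.data) >= 10_000
        assert abs(tr.data["value"].mean()) <= 0.01

    def test_bad_bin_width(self, genome_small):
        with pytest.raises(ValueError):
            sim.simulate_lesion_track(genome_small, bin_width=0)
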