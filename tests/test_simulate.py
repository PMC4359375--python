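"""Simulator contracts: capacity, determinism, loading, emission, recovery."""

import numpy as np
import pandas as pd
import pytest

from polyribo.features import mean_conservation
from polyribo.profiles import coverage_fraction, frame_distribution
from polyribo.simulate import (
    LARGE_POLYSOME, SMALL_POLYSOME, SUB_POLYSOMAL, SimulationConfig,
    ribosome_capacity, simulate_conservation, simulate_experiment,
    simulate_mrna_fragments, simulate_polysome_loading, simulate_transcriptome,
    write_simulation)
from polyribo.transcripts import OrfDiscoveryParams, find_orfs, load_transcripts
from polyribo.features import conservation_threshold

SMALL_CFG = SimulationConfig(seed=7, n_canonical=30, n_smorf=20, n_ncrna=8,
                             library_size={SMALL_POLYSOME: 20000, LARGE_POLYSOME: 20000},
                             mrna_library_size=20000, n_intergenic=500)


@pytest.fixture(scope="module")
def small_sim():
    return simulate_experiment(SMALL_CFG)


class TestRibosomeCapacity:
    def test_smorf_holds_five(self):
        assert ribosome_capacity(303, 80) == 5

    def test_one_spacing_interval(self):
        assert ribosome_capacity(80, 80) == 2

    def test_two_spacing_intervals(self):
        assert ribosome_capacity(160, 80) == 3

    def test_strict_packing_gives_four_on_smorf(self):
        assert ribosome_capacity(303, 80, mode="strict") == 4

    def test_errors(self):
        with pytest.raises(ValueError):
            ribosome_capacity(2, 80)
        with pytest.raises(ValueError):
            ribosome_capacity(100, 0)


class TestTranscriptome:
    def test_fixed_seed_bitwise_deterministic(self):
        a = simulate_experiment(SMALL_CFG)
        b = simulate_experiment(SMALL_CFG)
        assert [t.sequence for t in a.transcripts] == [t.sequence for t in b.transcripts]
        assert a.truth.orfs.equals(b.truth.orfs)
        for k in a.footprints:
            assert a.footprints[k].equals(b.footprints[k])
        assert a.mrna.equals(b.mrna)
        assert np.array_equal(a.intergenic_scores, b.intergenic_scores)

    def test_no_ncrnas_when_disabled(self):
        cfg = SimulationConfig(seed=2, n_canonical=5, n_smorf=5, n_ncrna=0)
        transcripts, _ = simulate_transcriptome(cfg)
        assert all(t.coding for t in transcripts)

    def test_truth_orfs_rediscovered_by_finder(self, small_sim):
        by_id = {t.transcript_id: t for t in small_sim.transcripts}
        params = OrfDiscoveryParams(min_aa=11, report_mode="all_starts")
        for row in small_sim.truth.orfs.itertuples():
            t = by_id[row.transcript_id]
            hits = find_orfs(t.sequence, params)
            assert (row.start, row.end) in hits

    def test_class_sizes_respect_smorf_boundary(self, small_sim):
        truth = small_sim.truth.orfs
        smorf_len = truth.loc[truth.category == "smorf_cds", "end"] - \
            truth.loc[truth.category == "smorf_cds", "start"]
        canon_len = truth.loc[truth.category == "canonical_cds", "end"] - \
            truth.loc[truth.category == "canonical_cds", "start"]
        assert (smorf_len <= 303).all()
        assert (canon_len > 303).all()


class TestLoading:
    def test_labels_match_ribosome_ranges(self, small_sim):
        copies = small_sim.truth.copies
        sub = copies[copies["fraction_label"] == SUB_POLYSOMAL]["ribosomes"]
        small = copies[copies["fraction_label"] == SMALL_POLYSOME]["ribosomes"]
        large = copies[copies["fraction_label"] == LARGE_POLYSOME]["ribosomes"]
        assert (sub <= 1).all()
        assert small.between(2, 6).all()
        assert (large >= 7).all()

    def test_smorf_only_transcripts_never_in_large_polysomes(self, small_sim):
        truth = small_sim.truth.orfs
        translated = truth[truth["translated"]]
        cap_by_tx = translated.groupby("transcript_id")["capacity"].max()
        capped = set(cap_by_tx[cap_by_tx <= 6].index)
        large = small_sim.truth.copies.query("fraction_label == @LARGE_POLYSOME")
        assert not set(large["transcript_id"]) & capped

    def test_no_translation_no_polysomes(self):
        cfg = SimulationConfig(seed=3, n_canonical=10, n_smorf=10, n_ncrna=2,
                               translated_prob_canonical=0.0, translated_prob_smorf=0.0,
                               uorf_translated_prob=0.0, ncorf_translated_prob=0.0)
        transcripts, truth = simulate_transcriptome(cfg)
        rng = np.random.default_rng(0)
        loading = simulate_polysome_loading(transcripts, truth, cfg, rng)
        assert (loading["fraction_label"] == SUB_POLYSOMAL).all()


class TestFootprints:
    def test_alignments_within_bounds_and_length_range(self, small_sim):
        by_id = {t.transcript_id: t for t in small_sim.transcripts}
        for frame in small_sim.footprints.values():
            assert frame["length"].between(28, 34).all()
            ends = frame["start"] + frame["length"]
            lengths = frame["transcript_id"].map(lambda i: by_id[i].length)
            assert (frame["start"] >= 0).all()
            assert (ends <= lengths).all()

    def test_perfect_fidelity_no_background_pure_frame0(self):
        cfg = SimulationConfig(seed=9, n_canonical=10, n_smorf=10, n_ncrna=0,
                               frame_fidelity=1.0, background_rate=0.0,
                               library_size={SMALL_POLYSOME: 30000},
                               mrna_library_size=1000)
        sim = simulate_experiment(cfg)
        fp = sim.footprints[SMALL_POLYSOME]
        by_tx = {t: g for t, g in fp.groupby("transcript_id")}
        checked = 0
        for row in sim.truth.orfs[sim.truth.orfs["translated"]].itertuples():
            g = by_tx.get(row.transcript_id)
            if g is None:
                continue
            fs = frame_distribution((row.start, row.end), g)
            if fs.total >= 50:
                assert fs.fractions[0] == 1.0
                checked += 1
        assert checked > 0

    def test_no_background_means_zero_utr3_coverage(self):
        cfg = SimulationConfig(seed=9, n_canonical=10, n_smorf=10, n_ncrna=0,
                               background_rate=0.0,
                               library_size={SMALL_POLYSOME: 30000},
                               mrna_library_size=1000)
        sim = simulate_experiment(cfg)
        fp = sim.footprints[SMALL_POLYSOME]
        by_tx = {t: g for t, g in fp.groupby("transcript_id")}
        for t in sim.transcripts:
            g = by_tx.get(t.transcript_id)
            if g is None or t.utr3[1] <= t.utr3[0]:
                continue
            # full extents may poke a few nt past the stop codon; P-site anchors may not
            from polyribo.profiles import feature_read_count
            assert feature_read_count(t.utr3, g) == 0

    def test_phasing_fidelity_recovered_within_tolerance(self, small_sim):
        pooled = pd.concat(small_sim.footprints.values(), ignore_index=True)
        by_tx = {t: g for t, g in pooled.groupby("transcript_id")}
        phi = small_sim.config.frame_fidelity
        checked = 0
        for row in small_sim.truth.orfs[small_sim.truth.orfs["translated"]].itertuples():
            g = by_tx.get(row.transcript_id)
            if g is None:
                continue
            fs = frame_distribution((row.start, row.end), g)
            if fs.total >= 2000:
                assert abs(fs.fractions[0] - phi) < 0.05
                checked += 1
        assert checked > 0


class TestMrnaFragments:
    def test_lengths_in_range_and_deterministic(self, small_sim):
        assert small_sim.mrna["length"].between(50, 80).all()
        rng = np.random.default_rng(4)
        a = simulate_mrna_fragments(small_sim.transcripts, small_sim.truth.abundance,
                                    SMALL_CFG, np.random.default_rng(4))
        b = simulate_mrna_fragments(small_sim.transcripts, small_sim.truth.abundance,
                                    SMALL_CFG, np.random.default_rng(4))
        assert a.equals(b)

    def test_flat_coverage_on_long_transcript(self):
        from conftest import make_coding
        t = make_coding("big", utr5=100, cds_aa=599, utr3=100)  # 2000 nt
        cfg = SimulationConfig(seed=1, mrna_library_size=4000)  # ~130x depth
        frame = simulate_mrna_fragments([t], pd.Series({"big": 10.0}), cfg,
                                        np.random.default_rng(5))
        depth = np.zeros(t.length)
        for r in frame.itertuples():
            depth[r.start:r.start + r.length] += 1
        # interior windows: the first/last ~80 nt ramp because fragments
        # cannot start before the 5' end or run past the 3' end
        interior = depth[80:-80]
        means = [interior[i:i + 100].mean() for i in range(0, len(interior) - 100, 50)]
        overall = interior.mean()
        assert all(abs(m - overall) / overall < 0.25 for m in means)

    def test_short_transcript_skipped_with_warning(self):
        from polyribo.transcripts import NONCODING, Transcript
        short = Transcript("tiny", "g", NONCODING, "ACGT" * 10, (0, 0), (0, 0), (0, 0))
        with pytest.warns(UserWarning, match="tiny"):
            frame = simulate_mrna_fragments([short], pd.Series({"tiny": 5.0}),
                                            SimulationConfig(seed=1),
                                            np.random.default_rng(0))
        assert len(frame) == 0


class TestConservation:
    def test_scores_in_unit_interval_and_deterministic(self, small_sim):
        scores = [b.score for b in small_sim.conservation]
        assert all(0.0 <= s <= 1.0 for s in scores)
        blocks2, inter2 = simulate_conservation(
            small_sim.transcripts, small_sim.truth, SMALL_CFG,
            np.random.default_rng(99))
        blocks3, inter3 = simulate_conservation(
            small_sim.transcripts, small_sim.truth, SMALL_CFG,
            np.random.default_rng(99))
        assert np.array_equal(inter2, inter3)
        assert [(b.start, b.end, b.score) for b in blocks2] == \
            [(b.start, b.end, b.score) for b in blocks3]

    def test_translated_orfs_clear_intergenic_cutoff(self):
        """High/low score separation holds across seeds."""
        hits = total = 0
        for seed in range(10):
            cfg = SimulationConfig(seed=seed, n_canonical=10, n_smorf=10, n_ncrna=3,
                                   n_intergenic=500)
            transcripts, truth = simulate_transcriptome(cfg)
            rng = np.random.default_rng(seed + 1000)
            blocks, intergenic = simulate_conservation(transcripts, truth, cfg, rng)
            cutoff = conservation_threshold(intergenic)
            by_space = {}
            for b in blocks:
                by_space.setdefault(b.space_id, []).append(b)
            for row in truth.orfs[truth.orfs["translated"]].itertuples():
                score = mean_conservation((row.start, row.end),
                                          by_space[row.transcript_id])
                hits += score >= cutoff
                total += 1
        assert total > 50
        assert hits / total >= 0.8


def test_write_simulation_round_trips_transcriptome(tmp_path, small_sim):
    paths = write_simulation(small_sim, tmp_path / "sim")
    loaded = load_transcripts(paths["fasta"], paths["structure"])
    assert loaded == small_sim.transcripts
    from polyribo.profiles import read_bed6
    got = read_bed6(paths[f"footprints_{SMALL_POLYSOME}"])
    pd.testing.assert_frame_equal(got, small_sim.footprints[SMALL_POLYSOME])
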