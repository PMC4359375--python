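"""Transcript validation, ORF discovery against brute-force oracles, masking."""

import numpy as np
import pandas as pd
import pytest

from polyribo.transcripts import (
    CODING, NONCODING, STOP_CODONS, MissingSequenceError, NoAnnotatedCdsError,
    OrfDiscoveryParams, OrfFeature, Transcript, TranscriptValidationError,
    annotated_cds_feature, classify_annotated_cds, discover_ncorfs,
    discover_uorfs, find_orfs, load_transcripts, load_transcripts_from_gtf,
    mask_uorfs_from_utr5, write_transcript_fasta, write_transcript_table)

from conftest import make_coding, make_noncoding, random_sequence


def orf_oracle(seq, min_aa=11, all_starts=False):
    """Brute force: test every position for ATG, scan in-frame for the first stop."""
    seq = seq.upper()
    hits = []
    for i in range(len(seq) - 2):
        if seq[i:i + 3] != "ATG":
            continue
        for j in range(i + 3, len(seq) - 2, 3):
            if seq[j:j + 3] in STOP_CODONS:
                if (j + 3 - i) // 3 - 1 >= min_aa:
                    hits.append((i, j + 3))
                break
    if not all_starts:
        best = {}
        for s, e in hits:  # 5'-most ATG per (frame, stop)
            key = (e, s % 3)
            if key not in best or s < best[key][0]:
                best[key] = (s, e)
        hits = list(best.values())
    return sorted(hits)


class TestFindOrfs:
    def test_minimal_passing_length(self):
        seq = "ATG" + "GCT" * 10 + "TAA"
        assert find_orfs(seq, OrfDiscoveryParams(min_aa=11)) == [(0, 36)]

    def test_length_filter_excludes_short(self):
        seq = "ATG" + "GCT" * 10 + "TAA"
        assert find_orfs(seq, OrfDiscoveryParams(min_aa=12)) == []

    def test_n_codons_never_match(self):
        # the only potential start/stop codons are broken by Ns
        seq = "ANG" + "GCT" * 12 + "TAN"
        assert find_orfs(seq, OrfDiscoveryParams(min_aa=1)) == []

    @pytest.mark.parametrize("mode", ["all_starts", "longest_per_stop"])
    def test_matches_brute_force_oracle(self, mode):
        rng = np.random.default_rng(42)
        for _ in range(100):
            seq = random_sequence(rng, 500, "ACGTN" if rng.random() < 0.3 else "ACGT")
            got = find_orfs(seq, OrfDiscoveryParams(min_aa=5, report_mode=mode))
            want = orf_oracle(seq, min_aa=5, all_starts=(mode == "all_starts"))
            assert got == want

    def test_all_starts_superset_of_longest_per_stop(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            seq = random_sequence(rng, 400)
            all_s = set(find_orfs(seq, OrfDiscoveryParams(min_aa=3, report_mode="all_starts")))
            longest = set(find_orfs(seq, OrfDiscoveryParams(min_aa=3)))
            assert longest <= all_s


class TestClassify:
    def test_boundary_100aa_is_smorf(self):
        t = make_coding(cds_aa=100)  # 303 nt including stop
        assert t.cds[1] - t.cds[0] == 303
        assert classify_annotated_cds(t) == "smorf_cds"

    def test_101aa_is_canonical(self):
        t = make_coding(cds_aa=101)
        assert classify_annotated_cds(t) == "canonical_cds"

    def test_short_cds_is_smorf(self):
        t = make_coding(cds_aa=19)  # 60 nt
        assert classify_annotated_cds(t) == "smorf_cds"

    def test_noncoding_raises(self):
        with pytest.raises(NoAnnotatedCdsError, match="no annotated CDS"):
            classify_annotated_cds(make_noncoding())


class TestDiscoverUorfs:
    def test_embedded_uorf_found(self):
        u_orf = "ATG" + "AAA" * 10 + "TAA"
        utr5 = u_orf + "C" * (60 - len(u_orf))
        cds = "ATG" + "GGG" * 120 + "TAA"
        seq = utr5 + cds + "C" * 30
        t = Transcript("t", "g", CODING, seq, (0, 60), (60, 60 + len(cds)),
                       (60 + len(cds), len(seq)))
        feats = discover_uorfs(t)
        assert [(f.start, f.end) for f in feats] == [(0, 36)]
        assert feats[0].category == "uorf" and feats[0].aa_length == 11

    def test_orf_reading_into_cds_excluded(self):
        # ATG in the UTR whose first in-frame stop lies inside the CDS
        utr5 = "ATG" + "AAA" * 19  # 60 nt, no stop within the UTR
        cds = "TAATAA" + "GGG" * 38  # in-frame stop immediately downstream
        seq = utr5 + cds + "C" * 30
        t = Transcript("t", "g", CODING, seq, (0, 60), (60, 60 + len(cds)),
                       (60 + len(cds), len(seq)))
        assert discover_uorfs(t) == []

    def test_noncoding_input_empty_not_error(self):
        assert discover_uorfs(make_noncoding()) == []

    def test_equals_find_orfs_restricted_to_utr5(self):
        rng = np.random.default_rng(11)
        for i in range(50):
            t = make_coding(tid=f"t{i}", utr5=int(rng.integers(30, 200)),
                            cds_aa=int(rng.integers(12, 60)), seed=int(rng.integers(1 << 30)))
            got = [(f.start, f.end) for f in discover_uorfs(t, OrfDiscoveryParams(min_aa=3))]
            sub = t.sequence[t.utr5[0]:t.utr5[1]]
            want = [(s, e) for s, e in find_orfs(sub, OrfDiscoveryParams(min_aa=3))]
            assert got == want
            # never overlapping the CDS
            for s, e in got:
                assert e <= t.cds[0]


class TestDiscoverNcorfs:
    def test_two_orfs_numbered_in_order(self):
        a = "ATG" + "CCC" * 11 + "TAA"
        b = "ATG" + "GGG" * 12 + "TAG"
        seq = "CCCC" + a + "TTTT" + b + "CC"
        t = make_noncoding(sequence=seq)
        feats = discover_ncorfs(t)
        assert [f.feature_id for f in feats] == ["nc1:ORF1", "nc1:ORF2"]
        assert feats[0].start < feats[1].start

    def test_all_a_sequence_empty(self):
        assert discover_ncorfs(make_noncoding(sequence="A" * 300)) == []

    def test_coding_input_raises(self):
        with pytest.raises(NoAnnotatedCdsError, match="expected noncoding"):
            discover_ncorfs(make_coding())

    def test_matches_oracle_on_random_ncrnas(self):
        rng = np.random.default_rng(23)
        for i in range(50):
            t = make_noncoding(tid=f"n{i}", sequence=random_sequence(rng, 400))
            got = [(f.start, f.end) for f in discover_ncorfs(t, OrfDiscoveryParams(min_aa=5))]
            assert got == orf_oracle(t.sequence, min_aa=5)


class TestMask:
    def _t(self, utr5_len=100):
        return make_coding(utr5=utr5_len, cds_aa=30, utr3=30)

    def _uorf(self, t, s, e):
        return OrfFeature("u", t.transcript_id, s, e, "uorf")

    def test_single_uorf_subtracted(self):
        t = self._t()
        assert mask_uorfs_from_utr5(t, [self._uorf(t, 10, 43)]) == [(0, 10), (43, 100)]

    def test_no_uorfs_identity(self):
        t = self._t()
        assert mask_uorfs_from_utr5(t, []) == [(0, 100)]

    def test_overlapping_uorfs_unioned(self):
        t = self._t()
        got = mask_uorfs_from_utr5(t, [self._uorf(t, 10, 43), self._uorf(t, 40, 76)])
        assert got == [(0, 10), (76, 100)]

    def test_uorf_outside_utr5_raises(self):
        t = self._t()
        with pytest.raises(ValueError, match="outside utr5"):
            mask_uorfs_from_utr5(t, [self._uorf(t, 90, 123)])

    def test_mask_plus_union_length_identity(self):
        rng = np.random.default_rng(3)
        t = self._t(200)
        for _ in range(100):
            n = rng.integers(0, 5)
            uorfs = []
            for _ in range(n):
                s = int(rng.integers(0, 160))
                e = s + 3 * int(rng.integers(2, 13))
                if e <= 200:
                    uorfs.append(self._uorf(t, s, e))
            masks = mask_uorfs_from_utr5(t, uorfs)
            from polyribo._util import total_length
            union = total_length([u.interval for u in uorfs])
            assert sum(e - s for s, e in masks) + union == 200
            assert masks == sorted(masks)


class TestLoadTranscripts:
    def _write(self, tmp_path, transcripts):
        fa, tsv = tmp_path / "t.fa", tmp_path / "t.tsv"
        write_transcript_fasta(transcripts, fa)
        write_transcript_table(transcripts, tsv)
        return fa, tsv

    def test_identity_round_trip(self, tmp_path):
        t = make_coding(utr5=30, cds_aa=19, utr3=30)
        fa, tsv = self._write(tmp_path, [t])
        (got,) = load_transcripts(fa, tsv)
        assert got == t

    def test_cds_not_multiple_of_3(self, tmp_path):
        t = make_coding()
        fa, _ = self._write(tmp_path, [t])
        tsv = tmp_path / "bad.tsv"
        tsv.write_text("transcript_id\tgene_id\tbiotype\tutr5_end\tcds_end\n"
                       f"{t.transcript_id}\t{t.gene_id}\tcoding\t30\t91\n")
        with pytest.raises(TranscriptValidationError, match="CDS length not multiple of 3"):
            load_transcripts(fa, tsv)

    def test_missing_sequence(self, tmp_path):
        t = make_coding()
        fa, _ = self._write(tmp_path, [t])
        tsv = tmp_path / "bad.tsv"
        tsv.write_text("transcript_id\tgene_id\tbiotype\tutr5_end\tcds_end\n"
                       "ghost\tg\tcoding\t30\t90\n")
        with pytest.raises(MissingSequenceError, match="ghost"):
            load_transcripts(fa, tsv)

    def test_50_random_transcripts_byte_identical_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        ts = []
        for i in range(50):
            if rng.random() < 0.3:
                ts.append(make_noncoding(f"nc{i}", random_sequence(rng, int(rng.integers(60, 400)))))
            else:
                ts.append(make_coding(f"tx{i}", utr5=int(rng.integers(0, 100)),
                                      cds_aa=int(rng.integers(5, 200)),
                                      utr3=int(rng.integers(0, 100)),
                                      seed=int(rng.integers(1 << 30))))
        fa, tsv = self._write(tmp_path, ts)
        loaded = load_transcripts(fa, tsv)
        assert loaded == ts
        tsv2 = tmp_path / "again.tsv"
        write_transcript_table(loaded, tsv2)
        assert tsv.read_bytes() == tsv2.read_bytes()

    def test_row_order_reversal_changes_nothing_per_transcript(self, tmp_path):
        ts = [make_coding(f"t{i}", seed=i) for i in range(5)]
        fa, tsv = self._write(tmp_path, ts)
        table = pd.read_csv(tsv, sep="\t")
        rev = tmp_path / "rev.tsv"
        table.iloc[::-1].to_csv(rev, sep="\t", index=False)
        a = {t.transcript_id: t for t in load_transcripts(fa, tsv)}
        b = {t.transcript_id: t for t in load_transcripts(fa, rev)}
        assert a == b


class TestGtfImport:
    def test_plus_and_minus_strand(self, tmp_path):
        genome = tmp_path / "genome.fa"
        chrom = ("ACGTACGTAA" "ATGAAACCCGGGTTTTAA" "GGGCCCTTTA" * 2)
        genome.write_text(f">chr1\n{chrom}\n")
        # plus-strand: exon 0..48 (1-based 1..48), CDS 11..28
        # minus-strand transcript over the same exon span
        gtf = tmp_path / "x.gtf"
        attrs_p = 'gene_id "gA"; transcript_id "txP";'
        attrs_m = 'gene_id "gB"; transcript_id "txM";'
        gtf.write_text(
            f'chr1\tsrc\texon\t1\t48\t.\t+\t.\t{attrs_p}\n'
            f'chr1\tsrc\tCDS\t11\t28\t.\t+\t.\t{attrs_p}\n'
            f'chr1\tsrc\texon\t1\t48\t.\t-\t.\t{attrs_m}\n')
        got = {t.transcript_id: t for t in load_transcripts_from_gtf(gtf, genome)}
        p = got["txP"]
        assert p.coding and p.cds == (10, 28)
        assert p.sequence == chrom[:48]
        assert p.sequence[p.cds[0]:p.cds[0] + 3] == "ATG"
        m = got["txM"]
        from Bio.Seq import Seq
        assert m.biotype == NONCODING
        assert m.sequence == str(Seq(chrom[:48]).reverse_complement())
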