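"""Transcriptome model and ORF discovery.

Everything here lives in 0-based, half-open transcript coordinates on the
sense strand; strand handling ends at ingestion (the GTF importer flips
minus-strand transcripts). ORF intervals always include the stop codon, so
a peptide of ``a`` amino acids occupies ``3 * (a + 1)`` nt.

The discovery rules mirror classic AUG-anchored ORF finders: an ORF is an
ATG followed by an in-frame stop with no earlier in-frame stop, with a
minimum peptide length (default 11 aa). Annotated coding sequences are
classified as smORFs when their peptide is at most 100 aa (303 nt with the
stop codon), canonical otherwise.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import Interval, merge_intervals, subtract_intervals

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: Peptide-length boundary between smORFs and canonical CDSs (inclusive).
SMORF_MAX_AA = 100
#: Nucleotide bound for a smORF including its stop codon: 100 codons + stop.
SMORF_MAX_NT = 3 * (SMORF_MAX_AA + 1)

CODING = "coding"
NONCODING = "noncoding"

ORF_CATEGORIES = ("canonical_cds", "smorf_cds", "uorf", "ncorf")
FEATURE_CATEGORIES = ORF_CATEGORIES + ("utr5_mask", "utr3_background", "custom")


class TranscriptValidationError(ValueError):
    """Raised when a transcript record violates a structural invariant."""

    def __init__(self, transcript_id: str, message: str):
        self.transcript_id = transcript_id
        super().__init__(f"{transcript_id}: {message}")


class MissingSequenceError(TranscriptValidationError):
    """Structure table references a transcript absent from the FASTA."""


class NoAnnotatedCdsError(ValueError):
    """Raised when a coding-only operation receives a noncoding transcript."""


@dataclass(frozen=True)
class Transcript:
    """A sense-strand transcript with 5'UTR / CDS / 3'UTR structure.

    Intervals are contiguous: ``utr5 = [0, cds.start)``, ``utr3 =
    [cds.end, len)``. Noncoding transcripts carry empty intervals.
    """

    transcript_id: str
    gene_id: str
    biotype: str
    sequence: str
    utr5: Interval
    cds: Interval
    utr3: Interval

    def __post_init__(self):
        tid = self.transcript_id
        if self.biotype not in (CODING, NONCODING):
            raise TranscriptValidationError(tid, f"unknown biotype {self.biotype!r}")
        seq = self.sequence
        if set(seq) - set("ACGTN"):
            bad = sorted(set(seq) - set("ACGTN"))
            raise TranscriptValidationError(tid, f"non-ACGTN characters {bad}")
        n = len(seq)
        for name, (s, e) in (("utr5", self.utr5), ("cds", self.cds), ("utr3", self.utr3)):
            if not (0 <= s <= e <= n):
                raise TranscriptValidationError(tid, f"{name} interval {s, e} outside [0, {n}]")
        if self.biotype == NONCODING:
            if any(e > s for s, e in (self.utr5, self.cds, self.utr3)):
                raise TranscriptValidationError(tid, "noncoding transcript with non-empty UTR/CDS")
            return
        s5, e5 = self.utr5
        sc, ec = self.cds
        s3, e3 = self.utr3
        if ec <= sc:
            raise TranscriptValidationError(tid, "coding transcript with empty CDS")
        if s5 != 0 or e5 != sc:
            raise TranscriptValidationError(tid, "utr5 must span [0, cds.start)")
        if s3 != ec or e3 != n:
            raise TranscriptValidationError(tid, "utr3 must span [cds.end, length)")
        if (ec - sc) % 3 != 0:
            raise TranscriptValidationError(tid, "CDS length not multiple of 3")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def coding(self) -> bool:
        return self.biotype == CODING

    @property
    def cds_aa_length(self) -> int:
        """Peptide length of the annotated CDS (stop codon not counted)."""
        if not self.coding:
            raise NoAnnotatedCdsError(f"{self.transcript_id}: no annotated CDS")
        return (self.cds[1] - self.cds[0]) // 3 - 1


@dataclass(frozen=True)
class OrfFeature:
    """A feature interval on a transcript (ORF, mask, or background region).

    For ORF categories the interval includes the stop codon and
    ``aa_length == length/3 - 1``.
    """

    feature_id: str
    transcript_id: str
    start: int
    end: int
    category: str

    def __post_init__(self):
        if self.category not in FEATURE_CATEGORIES:
            raise ValueError(f"unknown feature category {self.category!r}")
        if self.end <= self.start:
            raise ValueError(f"{self.feature_id}: empty interval")
        if self.category in ORF_CATEGORIES:
            n = self.end - self.start
            if n % 3 != 0 or n < 6:
                raise ValueError(f"{self.feature_id}: ORF length {n} not a multiple of 3 >= 6")

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def aa_length(self) -> int:
        return (self.end - self.start) // 3 - 1


@dataclass(frozen=True)
class OrfDiscoveryParams:
    """Parameters for AUG-anchored ORF discovery.

    min_aa : minimum peptide length; "longer than 10 aa" is read as >= 11.
    report_mode : ``longest_per_stop`` keeps the 5'-most qualifying ATG per
        (frame, stop); ``all_starts`` reports every qualifying ATG.
    """

    min_aa: int = 11
    require_atg: bool = True
    report_mode: str = "longest_per_stop"

    def __post_init__(self):
        if self.min_aa < 1:
            raise ValueError("min_aa must be >= 1")
        if self.report_mode not in ("all_starts", "longest_per_stop"):
            raise ValueError(f"unknown report_mode {self.report_mode!r}")


def find_orfs(sequence: str, params: OrfDiscoveryParams | None = None) -> list[Interval]:
    """AUG-to-stop ORF intervals (stop included), sorted by start.

    Codons containing N never match ATG or a stop. In ``longest_per_stop``
    mode at most one ORF is reported per (frame, stop), anchored at the
    5'-most ATG whose peptide meets ``min_aa``.
    """
    params = params or OrfDiscoveryParams()
    seq = sequence.upper()
    min_nt = 3 * (params.min_aa + 1)
    out: list[Interval] = []
    for frame in range(3):
        starts: list[int] = []
        stops: list[int] = []
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i:i + 3]
            if codon in STOP_CODONS:
                stops.append(i)
            if codon == START_CODON:
                starts.append(i)
            elif not params.require_atg and codon not in STOP_CODONS:
                starts.append(i)
        claimed: set[int] = set()
        for s in starts:
            j = bisect.bisect_right(stops, s)
            if j == len(stops):
                continue
            stop = stops[j]
            end = stop + 3
            if end - s < min_nt:
                continue
            if params.report_mode == "longest_per_stop":
                if stop in claimed:
                    continue
                claimed.add(stop)
            out.append((s, end))
    out.sort()
    return out


def classify_annotated_cds(transcript: Transcript) -> str:
    """``smorf_cds`` iff the annotated peptide is <= 100 aa, else ``canonical_cds``."""
    if not transcript.coding:
        raise NoAnnotatedCdsError(f"{transcript.transcript_id}: no annotated CDS")
    return "smorf_cds" if transcript.cds_aa_length <= SMORF_MAX_AA else "canonical_cds"


def annotated_cds_feature(transcript: Transcript) -> OrfFeature:
    """The annotated CDS as an OrfFeature (id ``<transcript>:CDS``)."""
    return OrfFeature(
        feature_id=f"{transcript.transcript_id}:CDS",
        transcript_id=transcript.transcript_id,
        start=transcript.cds[0],
        end=transcript.cds[1],
        category=classify_annotated_cds(transcript),
    )


def discover_uorfs(transcript: Transcript,
                   params: OrfDiscoveryParams | None = None) -> list[OrfFeature]:
    """AUG-ORFs fully contained in the 5'-UTR, stop codon included.

    ORFs whose stop would fall at or past ``cds.start`` are excluded by
    construction (discovery runs on the 5'-UTR subsequence only), keeping
    uORF metrics independent of CDS signal. Noncoding or UTR-less input
    yields an empty list.
    """
    if not transcript.coding:
        return []
    s5, e5 = transcript.utr5
    if e5 <= s5:
        return []
    sub = transcript.sequence[s5:e5]
    feats = []
    for i, (s, e) in enumerate(find_orfs(sub, params), start=1):
        feats.append(OrfFeature(
            feature_id=f"{transcript.transcript_id}:uORF{i}",
            transcript_id=transcript.transcript_id,
            start=s5 + s, end=s5 + e, category="uorf"))
    return feats


def discover_ncorfs(transcript: Transcript,
                    params: OrfDiscoveryParams | None = None) -> list[OrfFeature]:
    """AUG-ORFs anywhere in a noncoding transcript, numbered 5' to 3'."""
    if transcript.coding:
        raise NoAnnotatedCdsError(
            f"{transcript.transcript_id}: expected noncoding transcript")
    feats = []
    for i, (s, e) in enumerate(find_orfs(transcript.sequence, params), start=1):
        feats.append(OrfFeature(
            feature_id=f"{transcript.transcript_id}:ORF{i}",
            transcript_id=transcript.transcript_id,
            start=s, end=e, category="ncorf"))
    return feats


def mask_uorfs_from_utr5(transcript: Transcript,
                         uorfs: Sequence[OrfFeature]) -> list[Interval]:
    """5'-UTR minus the union of uORF intervals (disjoint, sorted).

    This is the "modified 5'-UTR" used so that UTR occupancy metrics are
    not driven by ribosomes sitting on upstream ORFs.
    """
    s5, e5 = transcript.utr5
    for u in uorfs:
        if u.start < s5 or u.end > e5:
            raise ValueError(
                f"{u.feature_id}: uORF {u.interval} outside utr5 {transcript.utr5}")
    return subtract_intervals((s5, e5), [u.interval for u in uorfs])


# ---------------------------------------------------------------------------
# I/O: FASTA + structure table, optional GTF

TABLE_COLUMNS = ["transcript_id", "gene_id", "biotype", "utr5_end", "cds_end"]


def load_transcripts(fasta: str | Path, structure: str | Path) -> list[Transcript]:
    """Build validated Transcripts from a FASTA and a structure TSV.

    The TSV has columns ``transcript_id gene_id biotype utr5_end cds_end``;
    noncoding rows leave both boundary fields empty.
    """
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq).upper().replace("U", "T")
            for rec in SeqIO.parse(str(fasta), "fasta")}
    table = pd.read_csv(structure, sep="\t", dtype={"transcript_id": str, "gene_id": str,
                                                    "biotype": str})
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"structure table missing columns {missing}")
    out: list[Transcript] = []
    for row in table.itertuples(index=False):
        tid = row.transcript_id
        if tid not in seqs:
            raise MissingSequenceError(tid, "no sequence in FASTA")
        seq = seqs[tid]
        n = len(seq)
        if row.biotype == NONCODING:
            if not (pd.isna(row.utr5_end) and pd.isna(row.cds_end)):
                raise TranscriptValidationError(tid, "noncoding row with CDS boundaries")
            out.append(Transcript(tid, row.gene_id, NONCODING, seq,
                                  (0, 0), (0, 0), (0, 0)))
            continue
        if pd.isna(row.utr5_end) or pd.isna(row.cds_end):
            raise TranscriptValidationError(tid, "coding row with empty CDS boundaries")
        u5, ce = int(row.utr5_end), int(row.cds_end)
        out.append(Transcript(tid, row.gene_id, CODING, seq,
                              (0, u5), (u5, ce), (ce, n)))
    return out


def write_transcript_table(transcripts: Iterable[Transcript], path: str | Path) -> None:
    rows = []
    for t in transcripts:
        if t.coding:
            rows.append((t.transcript_id, t.gene_id, t.biotype, t.cds[0], t.cds[1]))
        else:
            rows.append((t.transcript_id, t.gene_id, t.biotype, "", ""))
    pd.DataFrame(rows, columns=TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_transcript_fasta(transcripts: Iterable[Transcript], path: str | Path,
                           width: int = 60) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.transcript_id}\n")
            for i in range(0, len(t.sequence), width):
                fh.write(t.sequence[i:i + width] + "\n")


def load_transcripts_from_gtf(gtf: str | Path, genome_fasta: str | Path) -> list[Transcript]:
    """Import transcripts from a genomic GTF plus a genome FASTA.

    Recognises exon / CDS / five_prime_utr / three_prime_utr features keyed
    by ``transcript_id``. GTF coordinates (1-based closed) are converted at
    the boundary; minus-strand transcripts are reverse-complemented so the
    result is sense-strand transcript space.
    """
    import gffutils
    from Bio import SeqIO
    from Bio.Seq import Seq

    db = gffutils.create_db(str(gtf), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique",
                            disable_infer_genes=True, disable_infer_transcripts=True)
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_fasta), "fasta")}

    by_tx: dict[str, dict[str, list]] = {}
    meta: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS", "five_prime_utr", "three_prime_utr"):
            continue
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            continue
        rec = by_tx.setdefault(tid, {"exon": [], "CDS": []})
        rec.setdefault(feat.featuretype, []).append((feat.start - 1, feat.end))
        meta.setdefault(tid, {
            "gene_id": feat.attributes.get("gene_id", [tid])[0],
            "chrom": feat.seqid, "strand": feat.strand})

    out: list[Transcript] = []
    for tid, rec in by_tx.items():
        info = meta[tid]
        strand = info["strand"]
        exons = sorted(rec["exon"])
        if not exons:
            raise TranscriptValidationError(tid, "no exon features in GTF")
        chrom_seq = genome[info["chrom"]]
        seq = "".join(chrom_seq[s:e] for s, e in exons)
        # genomic -> transcript coordinate lookup for exon-contained positions
        def to_tx(gpos: int) -> int:
            off = 0
            for s, e in exons:
                if s <= gpos <= e:
                    return off + (gpos - s)
                off += e - s
            raise TranscriptValidationError(tid, f"position {gpos} outside exons")
        cds_iv = sorted(rec.get("CDS", []))
        if strand == "-":
            seq = str(Seq(seq).reverse_complement())
            n = len(seq)
            flip = lambda p: n - p  # noqa: E731 - boundary flip for half-open coords
            if cds_iv:
                cs = flip(to_tx(cds_iv[-1][1] - 1) + 1)
                ce = flip(to_tx(cds_iv[0][0]))
            biotype = CODING if cds_iv else NONCODING
        else:
            biotype = CODING if cds_iv else NONCODING
            if cds_iv:
                cs = to_tx(cds_iv[0][0])
                ce = to_tx(cds_iv[-1][1] - 1) + 1
        n = len(seq)
        if biotype == CODING:
            out.append(Transcript(tid, info["gene_id"], CODING, seq,
                                  (0, cs), (cs, ce), (ce, n)))
        else:
            out.append(Transcript(tid, info["gene_id"], NONCODING, seq,
                                  (0, 0), (0, 0), (0, 0)))
    out.sort(key=lambda t: t.transcript_id)
    return out


# ---------------------------------------------------------------------------
# Feature-set assembly and export

def build_features(transcripts: Sequence[Transcript],
                   params: OrfDiscoveryParams | None = None) -> list[OrfFeature]:
    """The full analysis feature set for a transcriptome.

    Annotated CDSs (classified), discovered uORFs and ncORFs, masked
    5'-UTR intervals (UTR minus uORFs), and 3'-UTR background features.
    """
    params = params or OrfDiscoveryParams()
    feats: list[OrfFeature] = []
    for t in transcripts:
        if t.coding:
            feats.append(annotated_cds_feature(t))
            uorfs = discover_uorfs(t, params)
            feats.extend(uorfs)
            for i, (s, e) in enumerate(mask_uorfs_from_utr5(t, uorfs), start=1):
                feats.append(OrfFeature(f"{t.transcript_id}:utr5_mask{i}",
                                        t.transcript_id, s, e, "utr5_mask"))
            s3, e3 = t.utr3
            if e3 > s3:
                feats.append(OrfFeature(f"{t.transcript_id}:utr3",
                                        t.transcript_id, s3, e3, "utr3_background"))
        else:
            feats.extend(discover_ncorfs(t, params))
    return feats


def features_to_frame(features: Sequence[OrfFeature]) -> pd.DataFrame:
    return pd.DataFrame(
        [(f.feature_id, f.transcript_id, f.start, f.end, f.category, f.length)
         for f in features],
        columns=["feature_id", "transcript_id", "start", "end", "category", "length"])


def write_orf_bed(features: Sequence[OrfFeature], path: str | Path) -> None:
    """ORFs as BED6 in transcript coordinates (score = peptide length)."""
    with open(path, "w") as fh:
        for f in features:
            score = f.aa_length if f.category in ORF_CATEGORIES else 0
            fh.write(f"{f.transcript_id}\t{f.start}\t{f.end}\t{f.feature_id}\t{score}\t+\n")


def write_orf_table(features: Sequence[OrfFeature],
                    transcripts: Mapping[str, Transcript],
                    path: str | Path) -> None:
    """TSV of ORF features with category and peptide sequence."""
    from Bio.Seq import Seq

    rows = []
    for f in features:
        if f.category in ORF_CATEGORIES:
            nt = transcripts[f.transcript_id].sequence[f.start:f.end - 3]
            pep = str(Seq(nt).translate())
            rows.append((f.feature_id, f.transcript_id, f.start, f.end,
                         f.category, f.aa_length, pep))
        else:
            rows.append((f.feature_id, f.transcript_id, f.start, f.end,
                         f.category, "", ""))
    pd.DataFrame(rows, columns=["feature_id", "transcript_id", "start", "end",
                                "category", "aa_length", "peptide"]
                 ).to_csv(path, sep="\t", index=False)
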