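"""Footprint signal: length filtering, P-sites, coverage, counts, composites.

Alignments are read placements in transcript coordinates: a 5'-end start,
a length, and a collapsed-duplicate multiplicity. Internally most
operations run on a pandas DataFrame with columns ``transcript_id, start,
length, multiplicity``; ``to_frame`` converts lists of
:class:`FootprintAlignment` on the way in.

Two deliberately different placement rules coexist:

* **counting** anchors each read at a single point (the P-site for mapped
  footprint lengths, the midpoint otherwise) so that adjacent features
  never double-count a read;
* **coverage** uses full read extents, reproducing the convention where a
  single 32-nt footprint covers 32/57 of a 57-nt ORF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import Interval
from .transcripts import OrfFeature, Transcript

ALIGNMENT_COLUMNS = ["transcript_id", "start", "length", "multiplicity"]

#: Read-length -> P-site offset. Lengths absent from the map are excluded
#: from framing: footprints are gel-purified at 28-34 nt but only 28-32 nt
#: reads carry a calibrated offset (+12 for 28-29, +13 for 30-31, +14 for 32).
DEFAULT_PSITE_OFFSETS: dict[int, int] = {28: 12, 29: 12, 30: 13, 31: 13, 32: 14}

FOOTPRINT_MIN_LEN = 28
FOOTPRINT_MAX_LEN = 34


@dataclass(frozen=True)
class FootprintAlignment:
    transcript_id: str
    start: int
    length: int
    multiplicity: int = 1

    def __post_init__(self):
        if self.start < 0 or self.length < 1 or self.multiplicity < 1:
            raise ValueError(f"invalid alignment {self!r}")


@dataclass(frozen=True)
class PsiteOffsets:
    """Mapping from read length to P-site offset (nt from the read 5' end)."""

    offsets: Mapping[int, int] = field(default_factory=lambda: dict(DEFAULT_PSITE_OFFSETS))

    def __post_init__(self):
        for length, off in self.offsets.items():
            if not 0 <= off < length:
                raise ValueError(f"offset {off} out of range for length {length}")

    def get(self, length: int) -> int | None:
        return self.offsets.get(length)

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(sorted(self.offsets))


@dataclass(frozen=True)
class FrameStats:
    """P-site counts per codon frame relative to an ORF start."""

    counts: tuple[float, float, float]

    @property
    def total(self) -> float:
        return sum(self.counts)

    @property
    def defined(self) -> bool:
        return self.total > 0

    @property
    def fractions(self) -> tuple[float, float, float] | None:
        t = self.total
        if t == 0:
            return None
        return tuple(c / t for c in self.counts)


def to_frame(alignments) -> pd.DataFrame:
    """Normalise list-of-FootprintAlignment or DataFrame input."""
    if isinstance(alignments, pd.DataFrame):
        missing = [c for c in ALIGNMENT_COLUMNS if c not in alignments.columns]
        if missing:
            raise ValueError(f"alignment frame missing columns {missing}")
        return alignments
    rows = [(a.transcript_id, a.start, a.length, a.multiplicity) for a in alignments]
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


def total_mapped(alignments) -> int:
    frame = to_frame(alignments)
    return int(frame["multiplicity"].sum()) if len(frame) else 0


def filter_by_length(alignments, min_len: int = FOOTPRINT_MIN_LEN,
                     max_len: int = FOOTPRINT_MAX_LEN) -> pd.DataFrame:
    """Keep reads with min_len <= length <= max_len (order preserved)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    frame = to_frame(alignments)
    return frame[(frame["length"] >= min_len) & (frame["length"] <= max_len)].reset_index(drop=True)


def assign_psite(alignment: FootprintAlignment,
                 offsets: PsiteOffsets | None = None,
                 transcript_length: int | None = None) -> int | None:
    """P-site position of one read, or None for lengths outside the map."""
    offsets = offsets or PsiteOffsets()
    off = offsets.get(alignment.length)
    if off is None:
        return None
    p = alignment.start + off
    if transcript_length is not None and p >= transcript_length:
        raise ValueError(f"P-site {p} beyond transcript end {transcript_length}")
    return p


def anchor_positions(frame: pd.DataFrame, mode: str = "psite",
                     offsets: PsiteOffsets | None = None) -> np.ndarray:
    """Single-point anchors for counting.

    ``psite`` mode anchors mapped lengths at their P-site and falls back to
    the midpoint for unmapped lengths; ``midpoint`` mode (mRNA fragments)
    uses midpoints throughout.
    """
    if mode not in ("psite", "midpoint"):
        raise ValueError(f"unknown anchor mode {mode!r}")
    starts = frame["start"].to_numpy()
    lengths = frame["length"].to_numpy()
    if mode == "midpoint":
        return starts + lengths // 2
    offsets = offsets or PsiteOffsets()
    offs = np.array([offsets.get(l) if offsets.get(l) is not None else l // 2
                     for l in lengths], dtype=np.int64) if len(lengths) else np.array([], dtype=np.int64)
    return starts + offs


def _interval_of(feature) -> Interval:
    if isinstance(feature, OrfFeature):
        return feature.interval
    return (int(feature[0]), int(feature[1]))


def coverage_fraction(feature, alignments) -> float:
    """Fraction of feature bases overlapped by at least one read.

    Uses full read extents; reads partially overlapping contribute only
    their overlapping bases. Multiplicity does not matter.
    """
    s, e = _interval_of(feature)
    if e <= s:
        raise ValueError(f"zero-length feature {s, e}")
    frame = to_frame(alignments)
    if isinstance(feature, OrfFeature) and "transcript_id" in frame.columns:
        frame = frame[frame["transcript_id"] == feature.transcript_id]
    starts = np.maximum(frame["start"].to_numpy(), s)
    ends = np.minimum((frame["start"] + frame["length"]).to_numpy(), e)
    keep = ends > starts
    starts, ends = starts[keep], ends[keep]
    if starts.size == 0:
        return 0.0
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    covered = 0
    cur_s, cur_e = int(starts[0]), int(ends[0])
    for i in range(1, starts.size):
        if starts[i] <= cur_e:
            cur_e = max(cur_e, int(ends[i]))
        else:
            covered += cur_e - cur_s
            cur_s, cur_e = int(starts[i]), int(ends[i])
    covered += cur_e - cur_s
    return covered / (e - s)


def feature_read_count(feature, alignments, mode: str = "psite",
                       offsets: PsiteOffsets | None = None) -> int:
    """Summed multiplicity of reads whose anchor lies in [start, end)."""
    s, e = _interval_of(feature)
    frame = to_frame(alignments)
    if isinstance(feature, OrfFeature) and "transcript_id" in frame.columns:
        frame = frame[frame["transcript_id"] == feature.transcript_id]
    if len(frame) == 0:
        return 0
    anchors = anchor_positions(frame, mode, offsets)
    inside = (anchors >= s) & (anchors < e)
    return int(frame["multiplicity"].to_numpy()[inside].sum())


DEFAULT_START_WINDOW = (-50, 100)
DEFAULT_STOP_WINDOW = (-100, 50)


def metagene_composite(transcripts: Sequence[Transcript], alignments,
                       anchor: str = "start",
                       window: tuple[int, int] | None = None) -> pd.Series:
    """Read 5'-end counts summed over transcripts at offsets from an anchor.

    The anchor is the first base of the start codon (``anchor="start"``) or
    of the stop codon (``anchor="stop"``). Offsets outside a transcript
    contribute nothing. Returns a Series indexed by offset.
    """
    if anchor not in ("start", "stop"):
        raise ValueError(f"unknown anchor {anchor!r}")
    coding = [t for t in transcripts if t.coding]
    if not coding:
        raise ValueError("metagene requires at least one coding transcript")
    if window is None:
        window = DEFAULT_START_WINDOW if anchor == "start" else DEFAULT_STOP_WINDOW
    lo, hi = window
    if lo >= hi:
        raise ValueError(f"bad window {window}")
    frame = to_frame(alignments)
    counts = np.zeros(hi - lo + 1, dtype=float)
    by_tx = dict(tuple(frame.groupby("transcript_id", sort=False)))
    for t in coding:
        sub = by_tx.get(t.transcript_id)
        if sub is None or len(sub) == 0:
            continue
        pos = t.cds[0] if anchor == "start" else t.cds[1] - 3
        offs = sub["start"].to_numpy() - pos
        inside = (offs >= lo) & (offs <= hi)
        np.add.at(counts, offs[inside] - lo, sub["multiplicity"].to_numpy()[inside])
    return pd.Series(counts, index=np.arange(lo, hi + 1), name="count")


def frame_distribution(orf, alignments,
                       offsets: PsiteOffsets | None = None) -> FrameStats:
    """P-site frame distribution relative to the ORF start.

    Only reads whose length is in the offset map contribute. With zero
    included reads the result is a defined-false FrameStats, not an error.
    """
    offsets = offsets or PsiteOffsets()
    s, e = _interval_of(orf)
    frame = to_frame(alignments)
    if isinstance(orf, OrfFeature) and "transcript_id" in frame.columns:
        frame = frame[frame["transcript_id"] == orf.transcript_id]
    mapped = frame[frame["length"].isin(offsets.lengths)]
    if len(mapped) == 0:
        return FrameStats((0.0, 0.0, 0.0))
    offs = np.array([offsets.get(l) for l in mapped["length"].to_numpy()], dtype=np.int64)
    psites = mapped["start"].to_numpy() + offs
    inside = (psites >= s) & (psites < e)
    mult = mapped["multiplicity"].to_numpy()[inside]
    frames = (psites[inside] - s) % 3
    counts = tuple(float(mult[frames == k].sum()) for k in range(3))
    return FrameStats(counts)


# ---------------------------------------------------------------------------
# I/O

def read_bed6(path: str | Path) -> pd.DataFrame:
    """Alignments from BED6 in transcript coordinates (score = multiplicity)."""
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name", "score", "strand"])
    return pd.DataFrame({
        "transcript_id": bed["chrom"].astype(str),
        "start": bed["start"].astype(int),
        "length": (bed["end"] - bed["start"]).astype(int),
        "multiplicity": bed["score"].astype(int),
    })


def write_bed6(alignments, path: str | Path, name: str = ".") -> None:
    frame = to_frame(alignments)
    with open(path, "w") as fh:
        for row in frame.itertuples(index=False):
            fh.write(f"{row.transcript_id}\t{row.start}\t{row.start + row.length}"
                     f"\t{name}\t{row.multiplicity}\t+\n")


def read_sam(path: str | Path) -> pd.DataFrame:
    """Alignments from SAM mapped against the transcript FASTA as reference."""
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            rows.append((rec.reference_name, rec.reference_start,
                         rec.query_length or rec.infer_query_length() or 0, 1))
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


def write_profile_tsv(series: pd.Series, path: str | Path,
                      index_name: str = "offset") -> None:
    df = series.rename_axis(index_name).reset_index()
    df.to_csv(path, sep="\t", index=False)
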