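"""Conservation scoring and amino-acid composition of called ORFs.

Conservation comes as scored alignment blocks (phastCons-style, scores in
[0, 1]); a feature's score is the overlap-length-weighted mean over its
bases, with uncovered bases contributing zero by default. The conserved /
unconserved boundary is the 90th percentile of scores measured on
intergenic features, computed with the same quantile convention as the
translation cut-offs.

Composition compares observed per-residue frequencies against the random
expectation implied by nucleotide composition: each codon's probability is
the product of its base frequencies, summed over synonymous codons and
renormalised over the 61 sense codons.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from ._util import quantile

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ConservationBlock:
    """A scored alignment block in some coordinate space (0-based half-open)."""

    space_id: str
    start: int
    end: int
    score: float

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty block {self.space_id}:{self.start}-{self.end}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"block score {self.score} outside [0, 1]")


def mean_conservation(feature, blocks: Sequence[ConservationBlock],
                      uncovered: str = "zero") -> float:
    """Overlap-weighted mean block score over a feature interval.

    ``uncovered="zero"`` (default) counts bases under no block as score 0;
    ``uncovered="exclude"`` averages over covered bases only (NaN if none).
    Overlapping blocks are a validation error.
    """
    if uncovered not in ("zero", "exclude"):
        raise ValueError(f"unknown uncovered mode {uncovered!r}")
    if hasattr(feature, "interval"):
        s, e = feature.interval
        space = feature.transcript_id
        blocks = [b for b in blocks if b.space_id == space]
    else:
        s, e = int(feature[0]), int(feature[1])
    if e <= s:
        raise ValueError("empty feature interval")
    ordered = sorted(blocks, key=lambda b: b.start)
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start < prev.end:
            raise ValueError(
                f"overlapping conservation blocks at {prev.start}-{prev.end} "
                f"and {cur.start}-{cur.end}")
    weighted = 0.0
    covered = 0
    for b in ordered:
        ov = min(b.end, e) - max(b.start, s)
        if ov > 0:
            weighted += ov * b.score
            covered += ov
    if uncovered == "zero":
        return weighted / (e - s)
    if covered == 0:
        return float("nan")
    return weighted / covered


def conservation_threshold(intergenic_scores: Iterable[float],
                           percentile: float = 90.0) -> float:
    """Cut-off separating conserved features from the intergenic baseline."""
    return quantile(intergenic_scores, percentile)


def flag_conserved(scores: Iterable[float], cutoff: float) -> np.ndarray:
    """Features at or above the cutoff are flagged conserved."""
    return np.asarray(list(scores), dtype=float) >= cutoff


def aa_frequencies(peptides: Sequence[str]) -> dict[str, float]:
    """Pooled residue frequencies over all peptides (sum to 1)."""
    counts = dict.fromkeys(AMINO_ACIDS, 0)
    total = 0
    for pep in peptides:
        for aa in pep.upper():
            if aa not in counts:
                raise ValueError(f"unknown amino-acid letter {aa!r}")
            counts[aa] += 1
            total += 1
    if total == 0:
        raise ValueError("empty peptide pool")
    return {aa: c / total for aa, c in counts.items()}


def random_expected_frequencies(nucleotide_freqs: Mapping[str, float]) -> dict[str, float]:
    """Amino-acid usage expected from nucleotide composition alone.

    Codon probability is the product of its three base frequencies;
    amino-acid probability sums synonymous codons and is renormalised over
    the 61 sense codons (stops excluded).
    """
    p = {b: float(nucleotide_freqs[b]) for b in "ACGT"}
    if any(v < 0 for v in p.values()):
        raise ValueError("negative nucleotide frequency")
    tot = sum(p.values())
    if tot <= 0:
        raise ValueError("nucleotide frequencies sum to zero")
    p = {b: v / tot for b, v in p.items()}
    table = CodonTable.unambiguous_dna_by_id[1]
    probs = dict.fromkeys(AMINO_ACIDS, 0.0)
    sense_total = 0.0
    for b1 in "ACGT":
        for b2 in "ACGT":
            for b3 in "ACGT":
                codon = b1 + b2 + b3
                if codon in table.stop_codons:
                    continue
                pc = p[b1] * p[b2] * p[b3]
                probs[table.forward_table[codon]] += pc
                sense_total += pc
    if sense_total <= 0:
        raise ValueError("all sense codons have zero probability")
    return {aa: v / sense_total for aa, v in probs.items()}


def nucleotide_frequencies(sequences: Iterable[str]) -> dict[str, float]:
    """Pooled A/C/G/T frequencies (N ignored)."""
    counts = dict.fromkeys("ACGT", 0)
    for seq in sequences:
        for b in seq.upper():
            if b in counts:
                counts[b] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no A/C/G/T bases in input")
    return {b: c / total for b, c in counts.items()}


def composition_table(sets: Mapping[str, Mapping[str, float]],
                      ratio_to: str | None = "random_expected") -> pd.DataFrame:
    """Per-amino-acid frequency table across peptide sets.

    One column per set; optionally a ``<set>_vs_<ratio_to>`` ratio column
    for each non-reference set.
    """
    df = pd.DataFrame({name: [freqs.get(aa, 0.0) for aa in AMINO_ACIDS]
                       for name, freqs in sets.items()}, index=list(AMINO_ACIDS))
    df.index.name = "aa"
    for name in list(df.columns):
        total = df[name].sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"frequencies for set {name!r} sum to {total}, not 1")
    if ratio_to is not None and ratio_to in df.columns:
        ref = df[ratio_to]
        for name in list(df.columns):
            if name != ratio_to:
                with np.errstate(divide="ignore", invalid="ignore"):
                    df[f"{name}_vs_{ratio_to}"] = np.where(ref > 0, df[name] / ref, np.nan)
    return df


# ---------------------------------------------------------------------------
# I/O

def read_scored_bed(path: str | Path) -> list[ConservationBlock]:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name", "score"],
                      usecols=[0, 1, 2, 3, 4])
    return [ConservationBlock(str(r.chrom), int(r.start), int(r.end), float(r.score))
            for r in bed.itertuples(index=False)]


def write_scored_bed(blocks: Sequence[ConservationBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"{b.space_id}\t{b.start}\t{b.end}\t.\t{b.score:.6g}\n")
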