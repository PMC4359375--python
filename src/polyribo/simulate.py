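"""Synthetic polysome-fractionated footprinting with known translation truth.

The generator emulates the experimental design end to end: a transcriptome
with canonical genes (>100 aa), smORF genes (<=100 aa), ncRNAs seeded with
AUG-ORFs, and uORFs embedded in a fraction of 5'-UTRs; per-mRNA-copy
ribosome loading capped by ORF capacity (one ribosome at the start codon
plus one per 80 nt); sucrose-gradient fractionation by ribosome count
(sub-polysomal <=1, small 2-6, large >=7); footprints of 28-34 nt whose
P-sites sit in frame 0 with probability ``frame_fidelity`` (else +/-1 nt);
unphased background reads on UTRs and untranslated RNAs; 50-80 nt mRNA
fragments from total cytoplasmic RNA; and phastCons-style conservation
blocks, high over translated ORFs and low elsewhere.

Background footprints are emitted in clusters around sparse "sticky
sites" (roughly one per 100 nt) rather than base-uniformly: experimental
UTR background comes from sporadic single-ribosome binding, which gives
low per-feature coverage even where background density is appreciable.

Every random draw flows from the single config seed, so identical configs
give identical outputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from ._util import subtract_intervals
from .transcripts import (CODING, NONCODING, STOP_CODONS, OrfFeature, Transcript,
                          write_transcript_fasta, write_transcript_table)

SUB_POLYSOMAL = "sub_polysomal"
SMALL_POLYSOME = "small_polysome"
LARGE_POLYSOME = "large_polysome"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_SENSE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in STOP_CODONS]
_STOPS = sorted(STOP_CODONS)


def ribosome_capacity(orf_length: int, spacing: int = 80, mode: str = "start_plus_ceil",
                      footprint: int = 30) -> int:
    """Maximum ribosomes on an ORF of ``orf_length`` nt.

    Default rule: one ribosome at the start codon plus one per (possibly
    partial) spacing interval, ``1 + ceil(L / spacing)`` - the convention
    under which a 303-nt smORF holds five ribosomes. ``mode="strict"``
    instead packs by position, ``1 + floor((L - footprint) / spacing)``,
    for sensitivity analysis of tighter packing.
    """
    if orf_length < 3:
        raise ValueError("orf_length must be >= 3")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if mode == "start_plus_ceil":
        return 1 + math.ceil(orf_length / spacing)
    if mode == "strict":
        return 1 + max(0, (orf_length - footprint) // spacing)
    raise ValueError(f"unknown capacity mode {mode!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; defaults are the package's standard study conditions."""

    seed: int = 1
    n_canonical: int = 300
    n_smorf: int = 150
    n_ncrna: int = 50
    # transcript architecture (aa lengths exclude the stop codon)
    canonical_aa: tuple[int, int] = (150, 600)
    smorf_aa: tuple[int, int] = (11, 100)
    uorf_aa: tuple[int, int] = (11, 30)
    ncorf_aa: tuple[int, int] = (11, 60)
    utr5_len: tuple[int, int] = (40, 150)
    utr3_len: tuple[int, int] = (60, 250)
    ncrna_pad: tuple[int, int] = (30, 120)
    p_uorf: float = 0.4
    ncorf_per_ncrna: tuple[int, int] = (1, 3)
    # expression and translation truth
    transcribed_prob: float = 0.6
    translated_prob_canonical: float = 0.81
    translated_prob_smorf: float = 0.83
    uorf_translated_prob: float = 0.3
    ncorf_translated_prob: float = 0.3
    abundance_mean: float = 20.0
    abundance_sigma: float = 0.75
    occupancy: tuple[float, float] = (0.3, 0.9)
    sub_binding_prob: float = 0.1
    # ribosome loading / fractionation
    ribosome_spacing: int = 80
    capacity_mode: str = "start_plus_ceil"
    small_range: tuple[int, int] = (2, 6)
    large_min: int = 7
    # footprint emission
    frame_fidelity: float = 0.85
    footprint_length_probs: Mapping[int, float] = field(default_factory=lambda: {
        28: 0.18, 29: 0.22, 30: 0.22, 31: 0.15, 32: 0.13, 33: 0.06, 34: 0.04})
    psite_emission_offsets: Mapping[int, int] = field(default_factory=lambda: {
        28: 12, 29: 12, 30: 13, 31: 13, 32: 14, 33: 14, 34: 14})
    background_rate: float = 3e-4
    utr5_background_multiplier: float = 2.5
    background_site_spacing: int = 100
    background_jitter: int = 10
    library_size: Mapping[str, int] = field(default_factory=lambda: {
        SMALL_POLYSOME: 200_000, LARGE_POLYSOME: 200_000})
    # mRNA fragments
    mrna_library_size: int = 200_000
    mrna_fragment_length: tuple[int, int] = (50, 80)
    # conservation
    conserved_score_beta: tuple[float, float] = (6.6, 3.4)
    intergenic_score_beta: tuple[float, float] = (3.0, 7.0)
    intergenic_q90: float = 0.55
    n_intergenic: int = 2000
    conservation_block_len: tuple[int, int] = (20, 60)

    def __post_init__(self):
        probs = sum(self.footprint_length_probs.values())
        if not math.isclose(probs, 1.0, abs_tol=1e-9):
            raise ValueError(f"footprint_length_probs sum to {probs}, not 1")
        if not 0.0 <= self.frame_fidelity <= 1.0:
            raise ValueError("frame_fidelity must be in [0, 1]")
        if self.small_range[0] > self.small_range[1] or self.large_min <= self.small_range[1]:
            raise ValueError("fraction ranges must be ordered")
        if self.ribosome_spacing <= 0:
            raise ValueError("ribosome_spacing must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        kwargs = dict(d)
        for k, v in kwargs.items():
            if isinstance(v, list):
                kwargs[k] = tuple(v)
            elif isinstance(v, dict) and k in ("footprint_length_probs",
                                               "psite_emission_offsets", "library_size"):
                kwargs[k] = {int(i) if str(i).isdigit() else i: w for i, w in v.items()}
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Per-ORF truth and per-copy polysome loading used for recovery tests."""

    orfs: pd.DataFrame          # feature_id, transcript_id, start, end, category,
                                # translated, rate, capacity
    abundance: pd.Series        # transcript_id -> expected copy number (0 = off)
    copies: pd.DataFrame | None = None  # transcript_id, ribosomes, fraction_label


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    transcripts: list[Transcript]
    truth: GroundTruth
    footprints: dict[str, pd.DataFrame]
    mrna: pd.DataFrame
    conservation: list
    intergenic_scores: np.ndarray


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _rand_cds(rng: np.random.Generator, aa: int) -> str:
    """ATG + (aa-1) sense codons + stop: no internal in-frame stop."""
    idx = rng.integers(0, len(_SENSE_CODONS), aa - 1)
    body = "".join(_SENSE_CODONS[i] for i in idx)
    stop = _STOPS[rng.integers(0, 3)]
    return "ATG" + body + stop


def simulate_transcriptome(config: SimulationConfig,
                           rng: np.random.Generator | None = None
                           ) -> tuple[list[Transcript], GroundTruth]:
    """Transcripts plus ground-truth ORFs with translated flags and rates.

    Embedded ORFs are preceded by an in-frame TAA so that AUG-anchored
    discovery recovers exactly the embedded interval (no 5' extension
    through chance upstream ATGs sharing the stop).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    transcripts: list[Transcript] = []
    orf_rows: list[tuple] = []
    abundances: dict[str, float] = {}

    def draw_rate(translated: bool) -> float:
        return float(rng.uniform(*config.occupancy)) if translated else 0.0

    def draw_abundance(transcribed: bool) -> float:
        if not transcribed:
            return 0.0
        return float(rng.lognormal(math.log(config.abundance_mean),
                                   config.abundance_sigma))

    def coding_transcript(tid: str, aa_range: tuple[int, int],
                          translated_prob: float, category: str) -> None:
        aa = int(rng.integers(aa_range[0], aa_range[1] + 1))
        cds = _rand_cds(rng, aa)
        has_uorf = rng.random() < config.p_uorf
        if has_uorf:
            u_aa = int(rng.integers(config.uorf_aa[0], config.uorf_aa[1] + 1))
            front = int(rng.integers(15, 41))
            back = int(rng.integers(12, 41))
            u_cds = _rand_cds(rng, u_aa)
            utr5 = _rand_seq(rng, front) + "TAA" + u_cds + _rand_seq(rng, back)
            u_iv = (front + 3, front + 3 + len(u_cds))
        else:
            utr5 = _rand_seq(rng, int(rng.integers(*_plus1(config.utr5_len))))
            u_iv = None
        utr3 = _rand_seq(rng, int(rng.integers(*_plus1(config.utr3_len))))
        seq = utr5 + cds + utr3
        t = Transcript(tid, f"g_{tid}", CODING, seq,
                       (0, len(utr5)), (len(utr5), len(utr5) + len(cds)),
                       (len(utr5) + len(cds), len(seq)))
        transcripts.append(t)
        transcribed = rng.random() < config.transcribed_prob
        abundances[tid] = draw_abundance(transcribed)
        cds_translated = transcribed and rng.random() < translated_prob
        orf_rows.append((f"{tid}:CDS", tid, t.cds[0], t.cds[1], category,
                         cds_translated, draw_rate(cds_translated),
                         ribosome_capacity(t.cds[1] - t.cds[0], config.ribosome_spacing,
                                           config.capacity_mode)))
        if u_iv is not None:
            u_translated = transcribed and rng.random() < config.uorf_translated_prob
            orf_rows.append((f"{tid}:uORF_true", tid, u_iv[0], u_iv[1], "uorf",
                             u_translated, draw_rate(u_translated),
                             ribosome_capacity(u_iv[1] - u_iv[0], config.ribosome_spacing,
                                               config.capacity_mode)))

    for i in range(config.n_canonical):
        coding_transcript(f"can{i:04d}", config.canonical_aa,
                          config.translated_prob_canonical, "canonical_cds")
    for i in range(config.n_smorf):
        coding_transcript(f"smo{i:04d}", config.smorf_aa,
                          config.translated_prob_smorf, "smorf_cds")

    for i in range(config.n_ncrna):
        tid = f"ncr{i:04d}"
        n_orfs = int(rng.integers(config.ncorf_per_ncrna[0],
                                  config.ncorf_per_ncrna[1] + 1))
        parts = [_rand_seq(rng, int(rng.integers(*_plus1(config.ncrna_pad))))]
        pos = len(parts[0])
        ivs = []
        for _ in range(n_orfs):
            o_aa = int(rng.integers(config.ncorf_aa[0], config.ncorf_aa[1] + 1))
            o_cds = _rand_cds(rng, o_aa)
            parts.append("TAA" + o_cds)
            ivs.append((pos + 3, pos + 3 + len(o_cds)))
            pos += 3 + len(o_cds)
            gap = _rand_seq(rng, int(rng.integers(12, 61)))
            parts.append(gap)
            pos += len(gap)
        parts.append(_rand_seq(rng, int(rng.integers(*_plus1(config.ncrna_pad)))))
        seq = "".join(parts)
        t = Transcript(tid, f"g_{tid}", NONCODING, seq, (0, 0), (0, 0), (0, 0))
        transcripts.append(t)
        transcribed = rng.random() < config.transcribed_prob
        abundances[tid] = draw_abundance(transcribed)
        for j, (s, e) in enumerate(ivs, start=1):
            translated = transcribed and rng.random() < config.ncorf_translated_prob
            orf_rows.append((f"{tid}:ORF_true{j}", tid, s, e, "ncorf",
                             translated, draw_rate(translated),
                             ribosome_capacity(e - s, config.ribosome_spacing,
                                               config.capacity_mode)))

    orfs = pd.DataFrame(orf_rows, columns=[
        "feature_id", "transcript_id", "start", "end", "category",
        "translated", "rate", "capacity"])
    abundance = pd.Series(abundances, name="abundance")
    return transcripts, GroundTruth(orfs=orfs, abundance=abundance)


def _plus1(rng_pair: tuple[int, int]) -> tuple[int, int]:
    return (rng_pair[0], rng_pair[1] + 1)


def simulate_polysome_loading(transcripts: Sequence[Transcript], truth: GroundTruth,
                              config: SimulationConfig,
                              rng: np.random.Generator) -> pd.DataFrame:
    """Per-copy ribosome counts and fraction labels.

    Copies of a transcript with at least one translated ORF draw
    ``min(capacity, 1 + Poisson(rate * capacity))`` ribosomes using the
    dominant (highest-capacity) translated ORF; untranslated copies carry
    0 or 1 sporadically bound ribosomes and stay sub-polysomal.
    """
    lo, hi = config.small_range
    rows_tx, rows_ribo = [], []
    translated = truth.orfs[truth.orfs["translated"]]
    dominant = (translated.sort_values(["capacity", "rate"])
                .groupby("transcript_id").last())
    for t in transcripts:
        k = int(rng.poisson(truth.abundance.get(t.transcript_id, 0.0)))
        if k == 0:
            continue
        if t.transcript_id in dominant.index:
            dom = dominant.loc[t.transcript_id]
            cap = int(dom["capacity"])
            lam = float(dom["rate"]) * cap
            counts = np.minimum(cap, 1 + rng.poisson(lam, k))
        else:
            counts = (rng.random(k) < config.sub_binding_prob).astype(int)
        rows_tx.append(np.repeat(t.transcript_id, k))
        rows_ribo.append(counts)
    if not rows_tx:
        return pd.DataFrame(columns=["transcript_id", "ribosomes", "fraction_label"])
    tx = np.concatenate(rows_tx)
    ribo = np.concatenate(rows_ribo)
    label = np.where(ribo <= 1, SUB_POLYSOMAL,
                     np.where(ribo <= hi, SMALL_POLYSOME, LARGE_POLYSOME))
    label[(ribo >= lo) & (ribo <= hi)] = SMALL_POLYSOME
    return pd.DataFrame({"transcript_id": tx, "ribosomes": ribo,
                         "fraction_label": label})


def _fraction_mass(loading: pd.DataFrame, fraction: str) -> pd.DataFrame:
    sub = loading[loading["fraction_label"] == fraction]
    if len(sub) == 0:
        return pd.DataFrame(columns=["mass", "copies"])
    g = sub.groupby("transcript_id")["ribosomes"]
    return pd.DataFrame({"mass": g.sum(), "copies": g.size()})


def simulate_footprints(transcripts: Sequence[Transcript], loading: pd.DataFrame,
                        truth: GroundTruth, config: SimulationConfig,
                        rng: np.random.Generator,
                        fraction: str = SMALL_POLYSOME) -> pd.DataFrame:
    """Footprint alignments for one polysome fraction.

    Reads come only from mRNA copies in the requested fraction. Translated
    ORFs emit reads in proportion to their copies' ribosome load (split
    between co-translated ORFs by rate x length); UTRs and other
    untranslated stretches of fraction-resident transcripts emit clustered
    background at ``background_rate`` per nt per copy (5'-UTRs scaled by
    ``utr5_background_multiplier``).
    """
    mass = _fraction_mass(loading, fraction)
    by_id = {t.transcript_id: t for t in transcripts}
    orfs_by_tx = {tid: g for tid, g in
                  truth.orfs[truth.orfs["translated"]].groupby("transcript_id")}

    units: list[tuple] = []   # (kind, transcript, payload, weight)
    for tid in mass.index:
        t = by_id[tid]
        m = float(mass.loc[tid, "mass"])
        copies = float(mass.loc[tid, "copies"])
        sub = orfs_by_tx.get(tid)
        ivs = []
        if sub is not None and len(sub):
            w = (sub["rate"] * (sub["end"] - sub["start"])).to_numpy(dtype=float)
            w = w / w.sum()
            for (s, e), share in zip(zip(sub["start"], sub["end"]), w):
                units.append(("orf", t, (int(s), int(e)), m * share))
                ivs.append((int(s), int(e)))
        for (s, e) in subtract_intervals((0, t.length), ivs):
            pieces = [(s, e)]
            if t.coding and t.utr5[1] > 0:
                pieces = [(ps, pe) for ps, pe in
                          ((max(s, 0), min(e, t.utr5[1])), (max(s, t.utr5[1]), e))
                          if pe > ps]
            for ps, pe in pieces:
                mult = (config.utr5_background_multiplier
                        if t.coding and pe <= t.utr5[1] else 1.0)
                weight = config.background_rate * (pe - ps) * copies * mult
                if weight > 0:
                    units.append(("bg", t, (ps, pe), weight))

    n_reads = int(config.library_size.get(fraction, 0))
    weights = np.array([u[3] for u in units], dtype=float)
    if n_reads == 0 or weights.sum() <= 0:
        return pd.DataFrame(columns=["transcript_id", "start", "length", "multiplicity"])
    per_unit = rng.multinomial(n_reads, weights / weights.sum())

    lens = np.array(sorted(config.footprint_length_probs), dtype=np.int64)
    lprobs = np.array([config.footprint_length_probs[l] for l in lens], dtype=float)
    offs = np.array([config.psite_emission_offsets[l] for l in lens], dtype=np.int64)
    phi = config.frame_fidelity

    tx_out, start_out, len_out = [], [], []
    for (kind, t, payload, _), k in zip(units, per_unit):
        if k == 0:
            continue
        li = rng.choice(len(lens), size=k, p=lprobs)
        lengths = lens[li]
        if kind == "orf":
            # P-sites over sense codons (elongating ribosomes); the stop
            # codon itself is not an emission site, so counting anchors
            # stay inside the ORF even after +/-1 nt jitter.
            s, e = payload
            codons = rng.integers(0, max(1, (e - s) // 3 - 1), k)
            r = rng.random(k)
            jitter = np.where(r < phi, 0, np.where(r < phi + (1 - phi) / 2, -1, 1))
            psite = s + 3 * codons + jitter
            starts = psite - offs[li]
        else:
            ps, pe = payload
            n_sites = max(1, (pe - ps) // config.background_site_spacing)
            sites = rng.integers(ps, pe, n_sites)
            j = config.background_jitter
            starts = sites[rng.integers(0, n_sites, k)] + rng.integers(-j, j + 1, k)
        starts = np.clip(starts, 0, t.length - lengths)
        tx_out.append(np.repeat(t.transcript_id, k))
        start_out.append(starts.astype(np.int64))
        len_out.append(lengths)
    out = pd.DataFrame({
        "transcript_id": np.concatenate(tx_out),
        "start": np.concatenate(start_out),
        "length": np.concatenate(len_out),
    })
    out["multiplicity"] = 1
    return out.sort_values(["transcript_id", "start", "length"],
                           kind="stable").reset_index(drop=True)


def simulate_mrna_fragments(transcripts: Sequence[Transcript], abundances: pd.Series,
                            config: SimulationConfig,
                            rng: np.random.Generator) -> pd.DataFrame:
    """Total-cytoplasmic mRNA fragments: 50-80 nt, uniform placement.

    Fragment counts are proportional to abundance x transcript length
    (fragmentation yield); transcripts shorter than the minimum fragment
    length are skipped with a warning.
    """
    lo, hi = config.mrna_fragment_length
    usable, weights = [], []
    for t in transcripts:
        a = float(abundances.get(t.transcript_id, 0.0))
        if a <= 0:
            continue
        if t.length < lo:
            warnings.warn(f"{t.transcript_id}: shorter than minimum fragment "
                          f"length {lo}; skipped")
            continue
        usable.append(t)
        weights.append(a * t.length)
    if not usable or config.mrna_library_size == 0:
        return pd.DataFrame(columns=["transcript_id", "start", "length", "multiplicity"])
    w = np.array(weights, dtype=float)
    per_tx = rng.multinomial(config.mrna_library_size, w / w.sum())
    tx_out, start_out, len_out = [], [], []
    for t, k in zip(usable, per_tx):
        if k == 0:
            continue
        lengths = np.minimum(rng.integers(lo, hi + 1, k), t.length)
        starts = rng.integers(0, t.length - lengths + 1)
        tx_out.append(np.repeat(t.transcript_id, k))
        start_out.append(starts.astype(np.int64))
        len_out.append(lengths)
    out = pd.DataFrame({
        "transcript_id": np.concatenate(tx_out),
        "start": np.concatenate(start_out),
        "length": np.concatenate(len_out),
    })
    out["multiplicity"] = 1
    return out.sort_values(["transcript_id", "start", "length"],
                           kind="stable").reset_index(drop=True)


def simulate_conservation(transcripts: Sequence[Transcript], truth: GroundTruth,
                          config: SimulationConfig, rng: np.random.Generator):
    """Conservation blocks plus an intergenic score sample.

    Translated ORFs are tiled with blocks drawn from a high Beta
    distribution; the rest of each transcript and the intergenic sample
    use a low distribution scaled so its 90th percentile sits at
    ``intergenic_q90``.
    """
    from .features import ConservationBlock

    a_hi, b_hi = config.conserved_score_beta
    a_lo, b_lo = config.intergenic_score_beta
    scale = config.intergenic_q90 / _stats.beta.ppf(0.9, a_lo, b_lo)
    bl_lo, bl_hi = config.conservation_block_len

    orfs_by_tx = {tid: list(zip(g["start"], g["end"])) for tid, g in
                  truth.orfs[truth.orfs["translated"]].groupby("transcript_id")}
    blocks: list[ConservationBlock] = []
    for t in transcripts:
        ivs = orfs_by_tx.get(t.transcript_id, [])
        regions = [(s, e, True) for s, e in ivs]
        regions += [(s, e, False) for s, e in subtract_intervals((0, t.length), ivs)]
        for s, e, high in sorted(regions):
            pos = s
            while pos < e:
                bl = int(min(rng.integers(bl_lo, bl_hi + 1), e - pos))
                if high:
                    score = float(rng.beta(a_hi, b_hi))
                else:
                    score = float(min(1.0, rng.beta(a_lo, b_lo) * scale))
                blocks.append(ConservationBlock(t.transcript_id, pos, pos + bl, score))
                pos += bl
    intergenic = np.minimum(1.0, rng.beta(a_lo, b_lo, config.n_intergenic) * scale)
    return blocks, intergenic


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Run the whole generator from one seed."""
    rng = np.random.default_rng(config.seed)
    transcripts, truth = simulate_transcriptome(config, rng)
    loading = simulate_polysome_loading(transcripts, truth, config, rng)
    truth.copies = loading
    footprints = {}
    for fraction in sorted(config.library_size):
        footprints[fraction] = simulate_footprints(
            transcripts, loading, truth, config, rng, fraction)
    mrna = simulate_mrna_fragments(transcripts, truth.abundance, config, rng)
    conservation, intergenic = simulate_conservation(transcripts, truth, config, rng)
    return SimulatedExperiment(config, transcripts, truth, footprints, mrna,
                               conservation, intergenic)


def write_simulation(sim: SimulatedExperiment, outdir: str | Path) -> dict[str, Path]:
    """Write the generator's outputs in the formats the pipeline reads."""
    import yaml

    from .features import write_scored_bed
    from .profiles import write_bed6

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["fasta"] = outdir / "transcripts.fa"
    write_transcript_fasta(sim.transcripts, paths["fasta"])
    paths["structure"] = outdir / "transcripts.tsv"
    write_transcript_table(sim.transcripts, paths["structure"])
    for fraction, frame in sim.footprints.items():
        p = outdir / f"footprints_{fraction}.bed"
        write_bed6(frame, p)
        paths[f"footprints_{fraction}"] = p
    paths["mrna"] = outdir / "mrna_fragments.bed"
    write_bed6(sim.mrna, paths["mrna"])
    paths["conservation"] = outdir / "conservation.bed"
    write_scored_bed(sim.conservation, paths["conservation"])
    paths["intergenic"] = outdir / "intergenic_scores.tsv"
    pd.Series(sim.intergenic_scores, name="score").to_csv(
        paths["intergenic"], sep="\t", index=False)
    paths["truth"] = outdir / "truth_orfs.tsv"
    sim.truth.orfs.to_csv(paths["truth"], sep="\t", index=False)
    paths["abundance"] = outdir / "truth_abundance.tsv"
    sim.truth.abundance.rename_axis("transcript_id").reset_index().to_csv(
        paths["abundance"], sep="\t", index=False)
    if sim.truth.copies is not None:
        paths["copies"] = outdir / "truth_copies.tsv"
        sim.truth.copies.to_csv(paths["copies"], sep="\t", index=False)
    paths["config"] = outdir / "config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(sim.config.to_dict(), fh, sort_keys=True)
    return paths
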