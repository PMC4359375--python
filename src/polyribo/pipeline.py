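"""End-to-end analysis: load -> discover ORFs -> metrics -> thresholds ->
calls -> combine -> conservation & composition -> report.

``analyze`` is the in-memory core; ``run_pipeline`` wraps it with file I/O,
logging, and overwrite protection for the command-line interface.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .calling import (ExpressionBackground, ThresholdSet, call_table,
                      combine_calls, compute_metrics, derive_thresholds)
from .features import (ConservationBlock, aa_frequencies, composition_table,
                       conservation_threshold, flag_conserved, mean_conservation,
                       nucleotide_frequencies, random_expected_frequencies)
from .profiles import PsiteOffsets, frame_distribution, metagene_composite, to_frame
from .transcripts import (ORF_CATEGORIES, OrfDiscoveryParams, Transcript,
                          build_features, features_to_frame)

SMALL = "small_polysome"
TOTAL = "total"


@dataclass
class PipelineConfig:
    """File-level configuration for ``run_pipeline`` (paths + parameters)."""

    fasta: str
    structure: str
    footprints: Mapping[str, str]          # fraction label -> BED6 path
    mrna: str
    outdir: str
    conservation: str | None = None
    intergenic_scores: str | None = None
    min_aa: int = 11
    report_mode: str = "longest_per_stop"
    psite_offsets: Mapping[int, int] | None = None
    thresholds: Mapping[str, float] | str = "derive"
    background_percentile: float = 90.0
    coverage_floor: float = 0.57
    min_reads: int = 5
    alpha: float = 0.01
    n_expression_samples: int = 1000
    seed: int = 0
    force: bool = False


@dataclass
class AnalysisResult:
    features: pd.DataFrame
    metrics: pd.DataFrame              # all fractions + pooled "total"
    thresholds: ThresholdSet
    calls: pd.DataFrame
    combined: dict[str, tuple[str, ...]]
    metagene: pd.DataFrame
    frames: pd.DataFrame
    report: pd.DataFrame
    conservation: pd.DataFrame | None = None
    composition: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = [f"polyribo {__version__} analysis",
                 f"features: {len(self.features)}",
                 f"thresholds: rpkm >= {self.thresholds.rpkm_cutoff:.3g}, "
                 f"coverage >= {self.thresholds.coverage_cutoff:.3g}, "
                 f"reads >= {self.thresholds.min_reads}",
                 f"translated features (any fraction): {len(self.combined)}"]
        return "\n".join(lines)


def select_background(metrics: pd.DataFrame, features: pd.DataFrame,
                      alpha: float = 0.01) -> pd.DataFrame:
    """3'-UTR rows of transcribed canonical (>100 aa) mRNAs.

    "Transcribed" uses the same gate as TE: mRNA RPKM above zero with
    expression p below alpha.
    """
    canonical_tx = set(features.loc[features["category"] == "canonical_cds",
                                    "transcript_id"])
    sub = metrics[(metrics["category"] == "utr3_background")
                  & metrics["transcript_id"].isin(canonical_tx)
                  & (metrics["mrna_rpkm"] > 0)
                  & (metrics["expression_p"] < alpha)]
    return sub


def analyze(transcripts: Sequence[Transcript],
            fp_by_fraction: Mapping[str, pd.DataFrame],
            mrna_alignments,
            orf_params: OrfDiscoveryParams | None = None,
            offsets: PsiteOffsets | None = None,
            thresholds: ThresholdSet | None = None,
            background_percentile: float = 90.0,
            coverage_floor: float = 0.57,
            min_reads: int = 5,
            alpha: float = 0.01,
            n_expression_samples: int = 1000,
            seed: int = 0,
            conservation_blocks: Sequence[ConservationBlock] | None = None,
            intergenic_scores=None,
            conservation_percentile: float = 90.0) -> AnalysisResult:
    """Run the full analysis on in-memory inputs.

    Thresholds are derived from the small-polysome 3'-UTR background unless
    an explicit ThresholdSet is supplied; calls are made per fraction and
    combined by union across fractions.
    """
    offsets = offsets or PsiteOffsets()
    feats = build_features(transcripts, orf_params)
    fdf = features_to_frame(feats)
    mrna = to_frame(mrna_alignments)
    expression_bg = ExpressionBackground(transcripts, mrna,
                                         n_samples=n_expression_samples, seed=seed)

    fractions = dict(fp_by_fraction)
    if len(fractions) > 1 and TOTAL not in fractions:
        fractions[TOTAL] = pd.concat([to_frame(v) for v in fp_by_fraction.values()],
                                     ignore_index=True)
    metrics_by_fraction = {
        label: compute_metrics(fdf, transcripts, frame, mrna, label,
                               offsets=offsets, expression_bg=expression_bg,
                               alpha=alpha)
        for label, frame in fractions.items()}
    metrics = pd.concat(metrics_by_fraction.values(), ignore_index=True)

    if thresholds is None:
        bg_label = SMALL if SMALL in metrics_by_fraction else next(iter(metrics_by_fraction))
        background = select_background(metrics_by_fraction[bg_label], fdf, alpha)
        thresholds = derive_thresholds(background, percentile=background_percentile,
                                       coverage_floor=coverage_floor,
                                       min_reads=min_reads, alpha=alpha)

    call_frames = []
    per_experiment_sets = {}
    for label in fp_by_fraction:
        called = call_table(metrics_by_fraction[label], thresholds)
        call_frames.append(called)
        per_experiment_sets[label] = set(called.loc[called["translated"], "feature_id"])
    calls = pd.concat(call_frames, ignore_index=True)
    combined = combine_calls(per_experiment_sets)

    metagene_rows = []
    for label, frame in fractions.items():
        for anchor in ("start", "stop"):
            series = metagene_composite(transcripts, frame, anchor=anchor)
            metagene_rows.append(pd.DataFrame({
                "fraction_label": label, "anchor": anchor,
                "offset": series.index, "count": series.to_numpy()}))
    metagene = pd.concat(metagene_rows, ignore_index=True)

    frames = _frame_table(fdf, fractions, offsets)
    report = export_report(metrics, calls, alpha=alpha)

    conservation = None
    if conservation_blocks is not None and intergenic_scores is not None:
        conservation = _conservation_table(
            fdf, feats, conservation_blocks, intergenic_scores, conservation_percentile)

    composition = _composition_table(transcripts, feats, combined)

    return AnalysisResult(features=fdf, metrics=metrics, thresholds=thresholds,
                          calls=calls, combined=combined, metagene=metagene,
                          frames=frames, report=report, conservation=conservation,
                          composition=composition)


def _frame_table(fdf: pd.DataFrame, fractions: Mapping[str, pd.DataFrame],
                 offsets: PsiteOffsets) -> pd.DataFrame:
    rows = []
    orfs = fdf[fdf["category"].isin(ORF_CATEGORIES)]
    for label, frame in fractions.items():
        by_tx = {tid: g for tid, g in to_frame(frame).groupby("transcript_id", sort=False)}
        for row in orfs.itertuples(index=False):
            sub = by_tx.get(row.transcript_id)
            if sub is None:
                stats = None
            else:
                fs = frame_distribution((row.start, row.end), sub, offsets)
                stats = fs.fractions
                total = fs.total
            if stats is None:
                rows.append((row.feature_id, label, 0.0, np.nan, np.nan, np.nan))
            else:
                rows.append((row.feature_id, label, total, *stats))
    return pd.DataFrame(rows, columns=["feature_id", "fraction_label",
                                       "psite_total", "frame0", "frame1", "frame2"])


def _conservation_table(fdf, feats, blocks, intergenic_scores, percentile):
    by_space: dict[str, list[ConservationBlock]] = {}
    for b in blocks:
        by_space.setdefault(b.space_id, []).append(b)
    cutoff = conservation_threshold(np.asarray(intergenic_scores, dtype=float),
                                    percentile)
    rows = []
    for f in feats:
        if f.category not in ORF_CATEGORIES:
            continue
        score = mean_conservation((f.start, f.end),
                                  by_space.get(f.transcript_id, []))
        rows.append((f.feature_id, score))
    out = pd.DataFrame(rows, columns=["feature_id", "mean_conservation"])
    out["conserved"] = flag_conserved(out["mean_conservation"], cutoff)
    out.attrs["cutoff"] = cutoff
    return out


def _composition_table(transcripts, feats, combined):
    from Bio.Seq import Seq

    seqs = {t.transcript_id: t.sequence for t in transcripts}

    def peptides(selected):
        peps = []
        for f in selected:
            nt = seqs[f.transcript_id][f.start:f.end - 3]
            pep = str(Seq(nt).translate())
            if pep and "*" not in pep and "X" not in pep:
                peps.append(pep)
        return peps

    cds = [f for f in feats if f.category in ("canonical_cds", "smorf_cds")]
    smorfs = [f for f in feats if f.category == "smorf_cds"]
    translated_smorfs = [f for f in smorfs if f.feature_id in combined]
    sets = {"random_expected":
            random_expected_frequencies(nucleotide_frequencies(seqs.values()))}
    for name, group in (("all_cds", cds), ("all_smorfs", smorfs),
                        ("translated_smorfs", translated_smorfs)):
        peps = peptides(group)
        if peps:
            sets[name] = aa_frequencies(peps)
    return composition_table(sets)


def export_report(metrics: pd.DataFrame, calls: pd.DataFrame,
                  alpha: float = 0.01) -> pd.DataFrame:
    """Per-category, per-fraction translated/untranslated tallies and median TE.

    Counts are restricted to transcribed features (mRNA expression gate),
    so translated + untranslated == transcribed in every row. Median TE
    excludes undefined TEs; a category with none is reported NA.
    """
    call_flags = calls[["feature_id", "fraction_label", "translated"]]
    merged = metrics.merge(call_flags, on=["feature_id", "fraction_label"], how="left")
    merged["translated"] = merged["translated"].eq(True)
    merged["transcribed"] = (merged["mrna_rpkm"] > 0) & (merged["expression_p"] < alpha)
    rows = []
    for (label, category), g in merged.groupby(["fraction_label", "category"],
                                               sort=True):
        tr = g[g["transcribed"]]
        tes = pd.to_numeric(tr["te"], errors="coerce").dropna()
        rows.append((label, category, len(g), len(tr),
                     int((tr["translated"]).sum()),
                     int((~tr["translated"]).sum()),
                     float(tes.median()) if len(tes) else np.nan,
                     len(tes)))
    return pd.DataFrame(rows, columns=["fraction_label", "category", "n_features",
                                       "n_transcribed", "n_translated",
                                       "n_untranslated", "median_te", "n_te_defined"])


# ---------------------------------------------------------------------------
# File-level driver

class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


OUTPUT_FILES = ("metrics.tsv", "calls.tsv", "combined_calls.tsv", "report.tsv",
                "metagene.tsv", "frames.tsv", "composition.tsv",
                "conservation.tsv", "thresholds.yaml", "run.log")


def run_pipeline(config: PipelineConfig) -> AnalysisResult:
    """Execute the full pipeline from files and write the report bundle."""
    import yaml

    from .features import read_scored_bed
    from .profiles import read_bed6
    from .transcripts import load_transcripts

    outdir = Path(config.outdir)
    if outdir.exists() and not config.force:
        existing = [f for f in OUTPUT_FILES if (outdir / f).exists()]
        if existing:
            raise PipelineError("setup", f"output files already exist in {outdir} "
                                f"({existing[0]}, ...); use force to overwrite")
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc

    transcripts = stage("load_transcripts", load_transcripts,
                        config.fasta, config.structure)
    fp_by_fraction = {label: stage("load_footprints", read_bed6, path)
                      for label, path in config.footprints.items()}
    mrna = stage("load_mrna", read_bed6, config.mrna)
    blocks = (stage("load_conservation", read_scored_bed, config.conservation)
              if config.conservation else None)
    intergenic = (stage("load_intergenic", pd.read_csv, config.intergenic_scores,
                        sep="\t")["score"].to_numpy()
                  if config.intergenic_scores else None)

    thresholds = None
    if isinstance(config.thresholds, Mapping):
        thresholds = ThresholdSet(**config.thresholds)
    offsets = PsiteOffsets(dict(config.psite_offsets)) if config.psite_offsets else None

    result = stage("analyze", analyze, transcripts, fp_by_fraction, mrna,
                   orf_params=OrfDiscoveryParams(min_aa=config.min_aa,
                                                 report_mode=config.report_mode),
                   offsets=offsets, thresholds=thresholds,
                   background_percentile=config.background_percentile,
                   coverage_floor=config.coverage_floor,
                   min_reads=config.min_reads, alpha=config.alpha,
                   n_expression_samples=config.n_expression_samples,
                   seed=config.seed, conservation_blocks=blocks,
                   intergenic_scores=intergenic)

    header = (f"# polyribo {__version__} seed={config.seed} "
              f"rpkm_cutoff={result.thresholds.rpkm_cutoff:.6g} "
              f"coverage_cutoff={result.thresholds.coverage_cutoff:.6g} "
              f"min_reads={result.thresholds.min_reads}")

    def write(df: pd.DataFrame, name: str):
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(header + "\n")
            df.to_csv(fh, sep="\t", index=False)

    write(result.metrics, "metrics.tsv")
    write(result.calls, "calls.tsv")
    combined = pd.DataFrame(
        [(fid, ",".join(labels)) for fid, labels in result.combined.items()],
        columns=["feature_id", "experiments"])
    write(combined, "combined_calls.tsv")
    write(result.report, "report.tsv")
    write(result.metagene, "metagene.tsv")
    write(result.frames, "frames.tsv")
    if result.composition is not None:
        write(result.composition.reset_index(), "composition.tsv")
    if result.conservation is not None:
        write(result.conservation, "conservation.tsv")
    with open(outdir / "thresholds.yaml", "w") as fh:
        yaml.safe_dump({"rpkm_cutoff": float(result.thresholds.rpkm_cutoff),
                        "coverage_cutoff": float(result.thresholds.coverage_cutoff),
                        "min_reads": int(result.thresholds.min_reads),
                        "background_percentile": float(result.thresholds.background_percentile),
                        "alpha": float(result.thresholds.alpha)}, fh)
    with open(outdir / "run.log", "w") as fh:
        fh.write(f"{_dt.datetime.now().isoformat(timespec='seconds')} "
                 f"polyribo {__version__}\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write(result.summary() + "\n")
    return result
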