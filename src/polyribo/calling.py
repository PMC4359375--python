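"""Translation metrics, background-derived cut-offs, and translation calls.

A feature is called translated when it clears three filters at once:
footprint density (RPKM) at least the background-derived cut-off, footprint
coverage at least the coverage cut-off, and at least ``min_reads`` raw
reads in the experiment. The RPKM and coverage cut-offs are the 90th
percentiles of the same metrics measured on 3'-UTRs of transcribed
canonical mRNAs (the non-coding background of lowly translated messages),
with the coverage cut-off floored at 0.57 - the coverage a single 32-nt
footprint produces on a 57-nt dwarf ORF - and the read floor guarding
against RPKM inflation on very short features.

Translational efficiency (footprint RPKM / mRNA RPKM) is computed only for
features whose mRNA signal is significant against a randomised background,
since the ratio is unstable at low expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import quantile
from .profiles import PsiteOffsets, anchor_positions, coverage_fraction, to_frame
from .transcripts import Transcript

FRACTION_LABELS = ("small_polysome", "large_polysome", "total")


@dataclass(frozen=True)
class ThresholdSet:
    """Cut-offs that turn per-feature metrics into translation calls."""

    rpkm_cutoff: float
    coverage_cutoff: float
    min_reads: int = 5
    background_percentile: float = 90.0
    alpha: float = 0.01

    def __post_init__(self):
        if not 0.0 <= self.coverage_cutoff <= 1.0:
            raise ValueError("coverage_cutoff must be in [0, 1]")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")


#: The published cut-offs, for use when no background set is available.
PAPER_THRESHOLDS = ThresholdSet(rpkm_cutoff=11.8, coverage_cutoff=0.57, min_reads=5)

#: Coverage floor: a single 32-nt footprint on a 57-nt dwarf ORF covers
#: 32/57 = 0.56, so the cut-off is raised just above it.
COVERAGE_FLOOR = 0.57


@dataclass(frozen=True)
class TranslationCall:
    feature_id: str
    translated: bool
    rpkm_pass: bool
    coverage_pass: bool
    min_reads_pass: bool


def rpkm(count: float, feature_length: int, total_mapped: int) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if feature_length <= 0:
        raise ValueError("feature_length must be positive")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return count / (feature_length / 1e3) / (total_mapped / 1e6)


def translational_efficiency(fp_rpkm: float, mrna_rpkm: float,
                             expression_p: float, alpha: float = 0.01) -> float | None:
    """fp_rpkm / mrna_rpkm, or None when mRNA expression is not significant."""
    if fp_rpkm < 0 or mrna_rpkm < 0:
        raise ValueError("RPKM inputs must be non-negative")
    if expression_p >= alpha or mrna_rpkm <= 0:
        return None
    return fp_rpkm / mrna_rpkm


class ExpressionBackground:
    """Empirical mRNA-expression test against a randomised read background.

    The null scatters the library's read anchors uniformly over the
    concatenated transcript space (one seeded randomisation per instance);
    for each feature, ``n_samples`` length-matched intervals are placed
    uniformly over that space and the add-one empirical p-value is the
    fraction of null intervals whose randomised-read count reaches the
    feature's observed count (identical lengths make count and RPKM
    comparisons equivalent).
    """

    def __init__(self, transcripts: Sequence[Transcript], mrna_alignments,
                 n_samples: int = 1000, seed: int = 0):
        if n_samples < 100:
            raise ValueError("n_samples must be >= 100")
        self.n_samples = n_samples
        frame = to_frame(mrna_alignments)
        self._offsets: dict[str, int] = {}
        off = 0
        for t in transcripts:
            self._offsets[t.transcript_id] = off
            off += t.length
        self.space = off
        if self.space <= 0:
            raise ValueError("empty transcript space")
        tx_off = frame["transcript_id"].map(self._offsets)
        if tx_off.isna().any():
            bad = frame.loc[tx_off.isna(), "transcript_id"].iloc[0]
            raise ValueError(f"mRNA alignment on unknown transcript {bad!r}")
        anchors = tx_off.to_numpy(dtype=np.int64) + anchor_positions(frame, "midpoint")
        mult = frame["multiplicity"].to_numpy()
        self._obs = np.sort(np.repeat(anchors, mult))
        rng = np.random.default_rng(seed)
        self._null = np.sort(rng.integers(0, self.space, size=self._obs.size))
        self._rng = rng

    def observed_count(self, transcript_id: str, interval) -> int:
        off = self._offsets[transcript_id]
        s, e = off + int(interval[0]), off + int(interval[1])
        return int(np.searchsorted(self._obs, e) - np.searchsorted(self._obs, s))

    def pvalues(self, transcript_ids: Sequence[str],
                intervals: Sequence[tuple[int, int]]) -> np.ndarray:
        lengths = np.array([e - s for s, e in intervals], dtype=np.int64)
        if np.any(lengths > self.space):
            raise ValueError("feature longer than total transcript space")
        obs = np.array([self.observed_count(t, iv)
                        for t, iv in zip(transcript_ids, intervals)], dtype=np.int64)
        n = self.n_samples
        starts = self._rng.integers(0, self.space - lengths[:, None] + 1,
                                    size=(len(lengths), n))
        lo = np.searchsorted(self._null, starts)
        hi = np.searchsorted(self._null, starts + lengths[:, None])
        null_counts = hi - lo
        ge = (null_counts >= obs[:, None]).sum(axis=1)
        return (1 + ge) / (n + 1)


def expression_significance(feature, mrna_alignments, transcripts: Sequence[Transcript],
                            n_samples: int = 1000, seed: int = 0) -> float:
    """Empirical p for one feature's mRNA expression (see ExpressionBackground)."""
    bg = ExpressionBackground(transcripts, mrna_alignments, n_samples, seed)
    if hasattr(feature, "transcript_id"):
        tid, iv = feature.transcript_id, feature.interval
    else:
        tid, iv = feature
    return float(bg.pvalues([tid], [iv])[0])


def derive_thresholds(utr3_metrics: pd.DataFrame, percentile: float = 90.0,
                      coverage_floor: float = COVERAGE_FLOOR,
                      min_reads: int = 5, alpha: float = 0.01) -> ThresholdSet:
    """Cut-offs from the 3'-UTR background of transcribed canonical mRNAs.

    ``rpkm_cutoff`` is the chosen percentile of background footprint RPKM;
    ``coverage_cutoff`` is the same percentile of background coverage but
    never below ``coverage_floor`` (the dwarf-smORF correction).
    """
    if len(utr3_metrics) == 0:
        raise ValueError(
            "empty 3'-UTR background; supply background metrics or use the "
            "published default PAPER_THRESHOLDS (11.8 RPKM, 0.57 coverage, 5 reads)")
    rpkm_cut = quantile(utr3_metrics["fp_rpkm"].to_numpy(), percentile)
    cov_cut = max(quantile(utr3_metrics["coverage"].to_numpy(), percentile),
                  coverage_floor)
    return ThresholdSet(rpkm_cutoff=rpkm_cut, coverage_cutoff=min(cov_cut, 1.0),
                        min_reads=min_reads, background_percentile=percentile,
                        alpha=alpha)


def call_translation(metrics, thresholds: ThresholdSet) -> TranslationCall:
    """Apply the three filters ("at least" is inclusive on every boundary)."""
    fid = metrics["feature_id"] if isinstance(metrics, (dict, pd.Series)) else metrics.feature_id
    get = (lambda k: metrics[k]) if isinstance(metrics, (dict, pd.Series)) else (
        lambda k: getattr(metrics, k))
    rpkm_pass = get("fp_rpkm") >= thresholds.rpkm_cutoff
    cov_pass = get("coverage") >= thresholds.coverage_cutoff
    reads_pass = get("fp_count") >= thresholds.min_reads
    return TranslationCall(fid, bool(rpkm_pass and cov_pass and reads_pass),
                           bool(rpkm_pass), bool(cov_pass), bool(reads_pass))


def call_table(metrics: pd.DataFrame, thresholds: ThresholdSet) -> pd.DataFrame:
    """Vectorised call_translation over a metrics table."""
    out = metrics.copy()
    out["rpkm_pass"] = out["fp_rpkm"] >= thresholds.rpkm_cutoff
    out["coverage_pass"] = out["coverage"] >= thresholds.coverage_cutoff
    out["min_reads_pass"] = out["fp_count"] >= thresholds.min_reads
    out["translated"] = out["rpkm_pass"] & out["coverage_pass"] & out["min_reads_pass"]
    return out


def combine_calls(call_sets: Mapping[str, Iterable[str]] | Sequence[Iterable[str]]
                  ) -> dict[str, tuple[str, ...]]:
    """Union of per-experiment translated-ID sets with provenance.

    Returns ``{feature_id: (experiments that called it, ...)}``.
    """
    if isinstance(call_sets, Mapping):
        items = list(call_sets.items())
    else:
        items = [(f"experiment_{i + 1}", s) for i, s in enumerate(call_sets)]
    if not items:
        raise ValueError("at least one call set required")
    out: dict[str, list[str]] = {}
    for label, ids in items:
        for fid in ids:
            out.setdefault(fid, []).append(label)
    return {fid: tuple(labels) for fid, labels in sorted(out.items())}


def replicate_correlation(metrics_a, metrics_b) -> float:
    """Squared Pearson correlation of per-feature densities over shared features."""
    sa = _as_series(metrics_a)
    sb = _as_series(metrics_b)
    shared = sa.index.intersection(sb.index)
    a = sa.loc[shared].to_numpy(dtype=float)
    b = sb.loc[shared].to_numpy(dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValueError("need at least 3 shared features with finite densities")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in one replicate")
    r, _ = stats.pearsonr(a, b)
    return float(r ** 2)


def _as_series(metrics) -> pd.Series:
    if isinstance(metrics, pd.Series):
        return metrics
    if isinstance(metrics, pd.DataFrame):
        return metrics.set_index("feature_id")["fp_rpkm"]
    if isinstance(metrics, Mapping):
        return pd.Series(metrics)
    raise TypeError(f"cannot interpret metrics of type {type(metrics)}")


# ---------------------------------------------------------------------------
# Metrics assembly

def compute_metrics(features: pd.DataFrame, transcripts: Sequence[Transcript],
                    fp_alignments, mrna_alignments,
                    fraction_label: str,
                    offsets: PsiteOffsets | None = None,
                    expression_bg: ExpressionBackground | None = None,
                    n_samples: int = 1000, seed: int = 0,
                    alpha: float = 0.01) -> pd.DataFrame:
    """Per-feature metrics table for one polysome fraction.

    Columns: feature_id, category, fraction_label, length, fp_count,
    fp_rpkm, coverage, mrna_count, mrna_rpkm, expression_p, te.
    """
    offsets = offsets or PsiteOffsets()
    fp = to_frame(fp_alignments)
    mrna = to_frame(mrna_alignments)
    total_fp = int(fp["multiplicity"].sum()) if len(fp) else 0
    total_mrna = int(mrna["multiplicity"].sum()) if len(mrna) else 0
    if expression_bg is None:
        expression_bg = ExpressionBackground(transcripts, mrna, n_samples, seed)

    fp_by_tx = {tid: g for tid, g in fp.groupby("transcript_id", sort=False)}
    fp_anchor_by_tx = {}
    fp_mult_by_tx = {}
    for tid, g in fp_by_tx.items():
        anchors = anchor_positions(g, "psite", offsets)
        order = np.argsort(anchors, kind="stable")
        fp_anchor_by_tx[tid] = anchors[order]
        fp_mult_by_tx[tid] = np.cumsum(np.concatenate([[0], g["multiplicity"].to_numpy()[order]]))
    mrna_by_tx = {tid: g for tid, g in mrna.groupby("transcript_id", sort=False)}
    mrna_anchor_by_tx = {}
    mrna_mult_by_tx = {}
    for tid, g in mrna_by_tx.items():
        anchors = anchor_positions(g, "midpoint")
        order = np.argsort(anchors, kind="stable")
        mrna_anchor_by_tx[tid] = anchors[order]
        mrna_mult_by_tx[tid] = np.cumsum(np.concatenate([[0], g["multiplicity"].to_numpy()[order]]))

    def anchored_count(anchor_by_tx, cum_by_tx, tid, s, e):
        a = anchor_by_tx.get(tid)
        if a is None:
            return 0
        cum = cum_by_tx[tid]
        lo = np.searchsorted(a, s)
        hi = np.searchsorted(a, e)
        return int(cum[hi] - cum[lo])

    rows = []
    for row in features.itertuples(index=False):
        s, e = int(row.start), int(row.end)
        length = e - s
        fp_count = anchored_count(fp_anchor_by_tx, fp_mult_by_tx, row.transcript_id, s, e)
        mrna_count = anchored_count(mrna_anchor_by_tx, mrna_mult_by_tx, row.transcript_id, s, e)
        sub = fp_by_tx.get(row.transcript_id)
        cov = coverage_fraction((s, e), sub) if sub is not None and len(sub) else 0.0
        fp_density = rpkm(fp_count, length, total_fp) if total_fp > 0 else 0.0
        mrna_density = rpkm(mrna_count, length, total_mrna) if total_mrna > 0 else 0.0
        rows.append((row.feature_id, row.transcript_id, row.category, fraction_label,
                     length, fp_count, fp_density, cov, mrna_count, mrna_density))
    out = pd.DataFrame(rows, columns=[
        "feature_id", "transcript_id", "category", "fraction_label", "length",
        "fp_count", "fp_rpkm", "coverage", "mrna_count", "mrna_rpkm"])
    out["expression_p"] = expression_bg.pvalues(
        features["transcript_id"].tolist(),
        list(zip(features["start"], features["end"])))
    out["te"] = [
        translational_efficiency(f, m, p, alpha) if m > 0 else None
        for f, m, p in zip(out["fp_rpkm"], out["mrna_rpkm"], out["expression_p"])]
    return out
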