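"""Promoter/enhancer discovery by chromatin-mark vs expression correlation.

For a transcript with no annotated TSS, the promoter is located by
correlating, across a cohort of cell types, the expression of the target
feature with the binned enrichment of activating histone marks over the
surrounding window. Significance comes from an empirical null: the same
per-bin correlations computed over decoy windows around genes with no
expected relationship to the target (classically ACTB, HOTAIR, FOXO4).
Per mark, the threshold r* is the (1 - q) quantile of the pooled decoy
correlations, so a fraction q of null bins exceeds it (default q = 0.005).

Region calls combine marks: a promoter is a maximal run of bins significant
for both H3K4me3 and H3K27ac; an enhancer, for both H3K4me1 and H3K27ac
(and not already inside a promoter call). Thresholding is one-sided — only
strong positive correlation is called; repressive-mark anticorrelation is
descriptive only.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chip_binning import BinEnrichmentMatrix, GenomicBin
from .expression_quant import ExpressionVector

logger = logging.getLogger(__name__)

MIN_SAMPLES = 3


@dataclass
class ScanConfig:
    """Scan parameters; the mark signatures define the region-call rules."""

    bin_size: int = 500            # bp
    flank: int = 50_000            # bp either side of the annotated locus
    q: float = 0.005               # empirical FDR level
    marks: tuple[str, ...] = ("H3K4me1", "H3K4me3", "H3K27ac", "H3K27me3")
    promoter_rule: frozenset[str] = frozenset({"H3K4me3", "H3K27ac"})
    enhancer_rule: frozenset[str] = frozenset({"H3K4me1", "H3K27ac"})

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError(f"q must be in (0, 1), got {self.q}")


@dataclass
class CorrelationTrack:
    """Per-bin Pearson r of one mark's enrichment against target expression.

    Bins whose enrichment (or the expression vector) has zero variance have
    no defined correlation and carry NaN; they are never significant and
    never enter a null pool.
    """

    mark: str
    bins: list[GenomicBin]
    r: np.ndarray          # NaN = undefined
    n: int                 # matched samples used per bin

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        defined = self.r[~np.isnan(self.r)]
        if ((defined < -1 - 1e-12) | (defined > 1 + 1e-12)).any():
            raise ValueError("defined correlations must lie in [-1, 1]")

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.r)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_id": [b.bin_id for b in self.bins],
            "r": self.r,
            "n": self.n,
        })


@dataclass
class EmpiricalNull:
    """Pooled decoy-bin correlations for one mark."""

    mark: str
    values: np.ndarray
    decoy_labels: list[str] = field(default_factory=list)
    n_undefined_excluded: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError(f"{self.mark}: empty null pool after exclusions")
        if np.isnan(self.values).any():
            raise ValueError(f"{self.mark}: null pool contains undefined correlations")
        if ((self.values < -1 - 1e-12) | (self.values > 1 + 1e-12)).any():
            raise ValueError(f"{self.mark}: null correlations must lie in [-1, 1]")


@dataclass(frozen=True)
class RegionCall:
    """A maximal run of co-significant bins, called promoter or enhancer."""

    kind: str                        # "promoter" | "enhancer"
    bins: tuple[GenomicBin, ...]
    mark_r: Mapping[str, tuple[float, ...]]   # per rule mark, member-bin r values
    thresholds: Mapping[str, float]

    @property
    def start(self) -> int:
        return self.bins[0].start

    @property
    def end(self) -> int:
        return self.bins[-1].end

    @property
    def bin_indices(self) -> tuple[int, ...]:
        return tuple(b.index for b in self.bins)


def _match_samples(matrix: BinEnrichmentMatrix, expr: ExpressionVector) -> list[str]:
    mat, ex = set(matrix.samples), set(expr.samples)
    common = [s for s in matrix.samples if s in ex]
    if mat != ex:
        unmatched = sorted((mat - ex) | (ex - mat))
        raise ValueError(f"sample labels do not match; unmatched: {unmatched}")
    if len(common) < MIN_SAMPLES:
        raise ValueError(f"need >= {MIN_SAMPLES} matched samples, got {len(common)}")
    return common


def _rowwise_pearson(values: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``values`` against ``y``; NaN where undefined."""
    x = values - values.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((x ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x @ yc) / (sx * sy)
    r[(sx == 0)] = np.nan
    if sy == 0:
        r[:] = np.nan
    return np.clip(r, -1.0, 1.0, out=r, where=~np.isnan(r))


def correlate_bins(matrix: BinEnrichmentMatrix, expr: ExpressionVector) -> CorrelationTrack:
    """Per-bin Pearson correlation of mark enrichment with target expression."""
    samples = _match_samples(matrix, expr)
    order = [matrix.samples.index(s) for s in samples]
    values = matrix.values[:, order]
    y = expr.values.loc[samples].to_numpy(dtype=float)
    r = _rowwise_pearson(values, y)
    return CorrelationTrack(mark=matrix.mark, bins=list(matrix.bins), r=r, n=len(samples))


def build_empirical_null(decoy_matrices: Sequence[BinEnrichmentMatrix],
                         expr: ExpressionVector,
                         decoy_labels: Sequence[str] | None = None) -> EmpiricalNull:
    """Pool decoy-window bin correlations for one mark into an empirical null."""
    marks = {m.mark for m in decoy_matrices}
    if len(marks) != 1:
        raise ValueError(f"decoy matrices must share one mark, got {sorted(marks)}")
    pools, n_undef = [], 0
    for m in decoy_matrices:
        track = correlate_bins(m, expr)
        defined = track.r[track.defined]
        n_undef += int((~track.defined).sum())
        pools.append(defined)
    values = np.concatenate(pools) if pools else np.zeros(0)
    if n_undef:
        logger.info("%s: excluded %d zero-variance decoy bins from null pool",
                    decoy_matrices[0].mark, n_undef)
    if values.size == 0:
        raise ValueError(
            f"{decoy_matrices[0].mark}: empty null pool after excluding undefined bins"
        )
    return EmpiricalNull(mark=decoy_matrices[0].mark, values=values,
                         decoy_labels=list(decoy_labels or []),
                         n_undefined_excluded=n_undef)


def fdr_threshold(null: EmpiricalNull, q: float) -> float:
    """The correlation above which a fraction q of the pooled null falls.

    Uses the Weibull plotting position ((n+1)p, linear interpolation between
    order statistics): with it, a fresh draw from the null exceeds the
    returned r* with probability q, so the empirical FDR is calibrated even
    for modest pools. Non-increasing in q; ties at r == r* are not
    significant (strict inequality downstream).
    """
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0, 1), got {q}")
    return float(np.quantile(null.values, 1.0 - q, method="weibull"))


def significant_bins(track: CorrelationTrack, r_star: float) -> np.ndarray:
    """Boolean mask: defined r strictly greater than the threshold."""
    with np.errstate(invalid="ignore"):
        return np.where(track.defined, track.r > r_star, False)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as [start, stop) index pairs."""
    runs, start = [], None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def call_regions(tracks: Mapping[str, CorrelationTrack],
                 thresholds: Mapping[str, float],
                 config: ScanConfig) -> list[RegionCall]:
    """Call promoters and enhancers from per-mark significance.

    Promoter = maximal run of bins significant for every promoter-rule mark;
    enhancer = maximal run significant for every enhancer-rule mark, minus
    bins already inside a promoter call. A single significant bin is a valid
    region.
    """
    for rule in (config.promoter_rule, config.enhancer_rule):
        missing = rule - set(tracks)
        if missing:
            raise ValueError(f"missing required mark track(s): {sorted(missing)}")
    ref_bins = next(iter(tracks.values())).bins
    for t in tracks.values():
        if [b.bin_id for b in t.bins] != [b.bin_id for b in ref_bins]:
            raise ValueError("correlation tracks must share the same bin list")

    sig = {mark: significant_bins(tracks[mark], thresholds[mark])
           for mark in set(config.promoter_rule) | set(config.enhancer_rule)}

    def co_sig(rule: frozenset[str]) -> np.ndarray:
        mask = np.ones(len(ref_bins), dtype=bool)
        for mark in rule:
            mask &= sig[mark]
        return mask

    prom_mask = co_sig(config.promoter_rule)
    enh_mask = co_sig(config.enhancer_rule) & ~prom_mask

    calls: list[RegionCall] = []
    for kind, mask, rule in (("promoter", prom_mask, config.promoter_rule),
                             ("enhancer", enh_mask, config.enhancer_rule)):
        for start, stop in _runs(mask):
            member = tuple(ref_bins[start:stop])
            calls.append(RegionCall(
                kind=kind,
                bins=member,
                mark_r={m: tuple(float(x) for x in tracks[m].r[start:stop]) for m in sorted(rule)},
                thresholds={m: float(thresholds[m]) for m in sorted(rule)},
            ))
    calls.sort(key=lambda c: c.start)
    return calls


def model_check_decoys(target_expr: ExpressionVector,
                       decoy_gene_exprs: Sequence[ExpressionVector]) -> pd.DataFrame:
    """Check that decoy-gene expression is unrelated to the target.

    Per decoy gene: Pearson r with the target across matched cell types and
    its two-sided p-value (t approximation). A decoy significantly (anti-)
    correlated with the target could distort the empirical null, so p < 0.05
    raises a warning.
    """
    rows = []
    for decoy in decoy_gene_exprs:
        common = [s for s in target_expr.samples if s in set(decoy.samples)]
        if len(common) < MIN_SAMPLES:
            raise ValueError(
                f"decoy {decoy.feature_id}: need >= {MIN_SAMPLES} matched samples"
            )
        x = target_expr.values.loc[common].to_numpy(float)
        y = decoy.values.loc[common].to_numpy(float)
        res = stats.pearsonr(x, y)
        rows.append({"gene": decoy.feature_id, "r": float(res.statistic),
                     "p": float(res.pvalue), "n": len(common)})
        if res.pvalue < 0.05:
            warnings.warn(
                f"decoy gene {decoy.feature_id} correlates with the target "
                f"(r={res.statistic:.2f}, p={res.pvalue:.3g}); this could distort the null model",
                stacklevel=2,
            )
    return pd.DataFrame(rows)


@dataclass
class ScanResult:
    tracks: dict[str, CorrelationTrack]
    nulls: dict[str, EmpiricalNull]
    thresholds: dict[str, float]
    calls: list[RegionCall]
    config: ScanConfig


def scan(target_matrices: Mapping[str, BinEnrichmentMatrix],
         decoy_matrices: Mapping[str, Sequence[BinEnrichmentMatrix]],
         expr: ExpressionVector,
         config: ScanConfig | None = None) -> ScanResult:
    """Full promoter scan: tracks, per-mark empirical nulls, thresholds, calls.

    ``target_matrices``/``decoy_matrices`` map mark -> matrix/matrices. Marks
    without a decoy pool (e.g. repressive marks kept for description only)
    get correlation tracks but no threshold and never contribute calls.
    """
    config = config or ScanConfig()
    tracks = {mark: correlate_bins(m, expr) for mark, m in target_matrices.items()}
    nulls = {mark: build_empirical_null(list(ms), expr)
             for mark, ms in decoy_matrices.items()}
    thresholds = {mark: fdr_threshold(null, config.q) for mark, null in nulls.items()}
    rule_marks = set(config.promoter_rule) | set(config.enhancer_rule)
    calls = call_regions({m: tracks[m] for m in rule_marks if m in tracks},
                         thresholds, config)
    return ScanResult(tracks=tracks, nulls=nulls, thresholds=thresholds,
                      calls=calls, config=config)


def write_scan_outputs(result: ScanResult, out_dir: str | Path) -> None:
    """Write tracks, null pools, thresholds, BED calls and a long-format table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for mark, track in result.tracks.items():
        track.to_frame().to_csv(out / f"track_{mark}.tsv", sep="\t", index=False)
    for mark, null in result.nulls.items():
        pd.DataFrame({"r": null.values}).to_csv(out / f"null_{mark}.tsv", sep="\t", index=False)
    meta = {"q": result.config.q, "quantile_method": "weibull",
            "thresholds": result.thresholds}
    (out / "thresholds.json").write_text(json.dumps(meta, indent=2))
    with open(out / "calls.bed", "w") as bed:
        for call in result.calls:
            chrom = call.bins[0].window.chrom
            bed.write(f"{chrom}\t{call.start}\t{call.end}\t{call.kind}\n")
    long_rows = [
        {"mark": mark, "bin_id": b.bin_id, "bin_index": b.index, "r": float(r)}
        for mark, track in result.tracks.items()
        for b, r in zip(track.bins, track.r)
    ]
    pd.DataFrame(long_rows).to_csv(out / "heatmap_long.tsv", sep="\t", index=False)
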