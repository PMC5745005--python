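"""Synthetic fixtures: correlated-chromatin cohorts and spliced-read sets.

Two generators, both fully deterministic under a seed:

* ``simulate_cohort`` emulates the promoter-scan study design — a cohort of
  34 cell types with per-bin chromatin-mark fold-enrichment over a 175-kb
  target window (500-bp bins) and three 100-kb decoy windows. Enrichment is
  zero-inflated log-normal: a latent standard normal per bin/sample is
  censored to 0 below its zero-inflation quantile, else mapped through
  exp(loc + scale*z). "Planted" promoter/enhancer bins share a Gaussian
  copula with the log-expression latent at population correlation rho;
  decoy and background bins are independent of expression. Censoring is
  tied to the same latent, mimicking peak calls dropping out exactly in the
  low-signal samples.

* ``simulate_locus_reads`` emulates the unaligned-read input of junction
  discovery: a random toy locus with a focal (circularizable) exon, reads
  of fixed length drawn either contiguously or across planted forward/back
  splice junctions with the breakpoint uniform inside the read, plus i.i.d.
  substitution errors. Truth labels record, per read, the class, junction,
  breakpoint, and whether the breakpoint falls in the pseudo-pair-observable
  interval [k, O].
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .chip_binning import BinEnrichmentMatrix, GenomicWindow, bin_window
from .expression_quant import ExpressionVector
from .junction_discovery import KnownJunction, LocusIndex


@dataclass(frozen=True)
class PlantedBlock:
    """A run of bins whose enrichment covaries with target expression."""

    bin_start: int
    bin_stop: int          # half-open bin-index range
    marks: tuple[str, ...]
    rho: float             # latent (copula) population correlation

    def __post_init__(self) -> None:
        if not 0 <= self.rho <= 1:
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")
        if self.bin_start >= self.bin_stop:
            raise ValueError("empty planted block")


@dataclass
class SyntheticCohortSpec:
    """Study-design parameters for the cohort generator.

    Defaults mirror the design the scan targets: 34 cell types, a 175-kb
    window in 500-bp bins (350 bins), three 100-kb decoy windows (200 bins
    each), and one 4-bin promoter block at latent correlation 0.8 for the
    promoter-signature marks.
    """

    n_samples: int = 34
    window: GenomicWindow = field(
        default_factory=lambda: GenomicWindow("chrX", 140_660_000, 140_835_000, "target"))
    bin_size: int = 500
    decoy_windows: tuple[GenomicWindow, ...] = field(default_factory=lambda: (
        GenomicWindow("chr7", 5_480_000, 5_580_000, "decoyA"),
        GenomicWindow("chr12", 54_310_000, 54_410_000, "decoyB"),
        GenomicWindow("chrX", 71_050_000, 71_150_000, "decoyC"),
    ))
    planted_blocks: tuple[PlantedBlock, ...] = field(default_factory=lambda: (
        PlantedBlock(100, 104, ("H3K4me3", "H3K27ac"), 0.8),
    ))
    marks: tuple[str, ...] = ("H3K4me1", "H3K4me3", "H3K27ac")
    zero_inflation: float = 0.3
    enrich_loc: float = 1.5     # log fold-enrichment location -> median ~4.5x
    enrich_scale: float = 0.5
    expr_loc: float = 2.0       # log expression; scale 1.0 spans ~2 orders of magnitude
    expr_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation must be in [0, 1)")
        n_bins = len(bin_window(self.window, self.bin_size))
        for block in self.planted_blocks:
            if block.bin_stop > n_bins:
                raise ValueError(f"planted block {block} exceeds {n_bins} target bins")
            if block.rho > 0 and self.zero_inflation >= 0.95:
                raise ValueError(
                    "rho > 0 is infeasible when zero-inflation censors nearly all mass"
                )


@dataclass
class SyntheticCohort:
    target: dict[str, BinEnrichmentMatrix]            # mark -> matrix
    decoys: dict[str, list[BinEnrichmentMatrix]]      # mark -> one matrix per decoy window
    expr: ExpressionVector
    truth: pd.DataFrame                               # planted (bin_index, mark, rho)
    spec: SyntheticCohortSpec


def _to_plain(obj):
    """Recursively convert dataclass/tuple structure to YAML-safe builtins."""
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _censored_lognormal(z: np.ndarray, pi: float, loc: float, scale: float) -> np.ndarray:
    """Map latent normals to zero-inflated positive fold-enrichments."""
    values = np.exp(loc + scale * z)
    if pi > 0:
        values = np.where(z < stats.norm.ppf(pi), 0.0, values)
    return values


def simulate_cohort(spec: SyntheticCohortSpec | None = None) -> SyntheticCohort:
    spec = spec or SyntheticCohortSpec()
    rng = np.random.default_rng(spec.seed)
    samples = [f"CT{i:02d}" for i in range(spec.n_samples)]

    z_expr = rng.standard_normal(spec.n_samples)
    expr = ExpressionVector(
        feature_id="target",
        values=pd.Series(np.exp(spec.expr_loc + spec.expr_scale * z_expr), index=samples),
        normalization="length_scaled_tpm",
    )

    target_bins = bin_window(spec.window, spec.bin_size)
    planted = {}  # (mark, bin index) -> rho
    truth_rows = []
    for block in spec.planted_blocks:
        for mark in block.marks:
            for i in range(block.bin_start, block.bin_stop):
                planted[(mark, i)] = block.rho
                truth_rows.append({"mark": mark, "bin_index": i, "rho": block.rho})

    target = {}
    for mark in spec.marks:
        eps = rng.standard_normal((len(target_bins), spec.n_samples))
        z = eps.copy()
        for (m, i), rho in planted.items():
            if m == mark:
                z[i] = rho * z_expr + np.sqrt(1 - rho ** 2) * eps[i]
        target[mark] = BinEnrichmentMatrix(
            mark=mark, bins=target_bins, samples=list(samples),
            values=_censored_lognormal(z, spec.zero_inflation,
                                       spec.enrich_loc, spec.enrich_scale))

    decoys: dict[str, list[BinEnrichmentMatrix]] = {mark: [] for mark in spec.marks}
    for dw in spec.decoy_windows:
        dbins = bin_window(dw, spec.bin_size)
        for mark in spec.marks:
            z = rng.standard_normal((len(dbins), spec.n_samples))
            decoys[mark].append(BinEnrichmentMatrix(
                mark=mark, bins=dbins, samples=list(samples),
                values=_censored_lognormal(z, spec.zero_inflation,
                                           spec.enrich_loc, spec.enrich_scale)))

    truth = pd.DataFrame(truth_rows, columns=["mark", "bin_index", "rho"])
    return SyntheticCohort(target=target, decoys=decoys, expr=expr, truth=truth, spec=spec)


@dataclass
class SyntheticLocusSpec:
    """Toy-locus read-simulation parameters.

    The default locus is 5 kb with a 1350-nt focal exon at [2000, 3350) and
    three planted junctions: a cryptic upstream donor into the focal
    acceptor, the focal donor into a cryptic downstream acceptor, and the
    focal exon's own back-splice (circle) junction. Reads are 76 nt — the
    geometry the default pseudo-pair offsets (k=20, O=50) were set for.
    """

    window_length: int = 5000
    exon_start: int = 2000
    exon_end: int = 3350
    planted_junctions: tuple[tuple[int, int, str], ...] = (
        (1000, 2000, "forward"),    # (donor, acceptor, kind) in window coords
        (3350, 4000, "forward"),
        (3350, 2000, "back"),       # the circle junction
    )
    read_length: int = 76
    n_reads: int = 2000
    class_mixture: tuple[float, float, float] = (0.5, 0.25, 0.25)  # contiguous/forward/back
    error_rate: float = 0.002
    k: int = 20
    O: int = 50
    min_mate: int = 19
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mixture) - 1.0) > 1e-9:
            raise ValueError("class mixture fractions must sum to 1")
        if self.read_length < self.O + self.min_mate:
            raise ValueError(
                f"read length {self.read_length} < O + min_mate = "
                f"{self.O + self.min_mate}: pseudo-pairing impossible"
            )
        for don, acc, kind in self.planted_junctions:
            if not (0 <= don <= self.window_length and 0 <= acc <= self.window_length):
                raise ValueError(f"junction ({don}, {acc}) outside window")
            if kind not in ("forward", "back"):
                raise ValueError(f"unknown junction kind {kind!r}")


@dataclass
class SyntheticLocusReads:
    index: LocusIndex
    reads: list[tuple[str, str]]      # (read id, sequence)
    truth: pd.DataFrame
    known_junctions: list[KnownJunction]
    spec: SyntheticLocusSpec


def _draw_junction_read(rng: np.random.Generator, seq: str, don: int, acc: int,
                        L: int) -> tuple[str, int] | None:
    """A read crossing donor->acceptor with the breakpoint uniform in [1, L-1]."""
    lo, hi = 1, L - 1
    # clip so both sides stay inside the window
    lo = max(lo, L - (len(seq) - acc))
    hi = min(hi, don)
    if lo > hi:
        return None
    b = int(rng.integers(lo, hi + 1))
    return seq[don - b:don] + seq[acc:acc + (L - b)], b


def simulate_locus_reads(spec: SyntheticLocusSpec | None = None) -> SyntheticLocusReads:
    spec = spec or SyntheticLocusSpec()
    rng = np.random.default_rng(spec.seed)
    seq = "".join(rng.choice(list("ACGT"), size=spec.window_length))
    index = LocusIndex(sequence=seq, target_strand="+",
                       exon_start=spec.exon_start, exon_end=spec.exon_end,
                       label="synthetic_locus")

    forward = [(d, a) for d, a, kind in spec.planted_junctions if kind == "forward"]
    back = [(d, a) for d, a, kind in spec.planted_junctions if kind == "back"]
    known = [KnownJunction(name=f"{kind}_{d}_{a}",
                           donor_t=index.to_transcript(d, 0, "+"),
                           acceptor_t=index.to_transcript(a, 0, "+"),
                           kind=kind)
             for d, a, kind in spec.planted_junctions]

    L = spec.read_length
    classes = rng.choice(3, size=spec.n_reads, p=list(spec.class_mixture))
    reads, rows = [], []
    for i, cls_idx in enumerate(classes):
        read_id = f"sim{i:06d}"
        if cls_idx == 0 or not (forward if cls_idx == 1 else back):
            start = int(rng.integers(0, spec.window_length - L + 1))
            read, cls, junction, b = seq[start:start + L], "contiguous", "", -1
        else:
            pool = forward if cls_idx == 1 else back
            don, acc = pool[int(rng.integers(len(pool)))]
            drawn = _draw_junction_read(rng, seq, don, acc, L)
            if drawn is None:
                start = int(rng.integers(0, spec.window_length - L + 1))
                read, cls, junction, b = seq[start:start + L], "contiguous", "", -1
            else:
                read, b = drawn
                cls = "forward_splice" if cls_idx == 1 else "back_splice"
                junction = f"{'forward' if cls_idx == 1 else 'back'}_{don}_{acc}"
        if spec.error_rate > 0:
            arr = np.frombuffer(read.encode(), dtype="S1").copy()
            hits = np.flatnonzero(rng.random(L) < spec.error_rate)
            for pos in hits:
                base = arr[pos].decode()
                arr[pos] = rng.choice([c for c in "ACGT" if c != base]).encode()
            read = arr.tobytes().decode()
            n_err = len(hits)
        else:
            n_err = 0
        observable = cls != "contiguous" and spec.k <= b <= spec.O
        reads.append((read_id, read))
        rows.append({"read_id": read_id, "class": cls, "junction": junction,
                     "breakpoint": b, "observable": observable, "n_errors": n_err})

    truth = pd.DataFrame(rows, columns=["read_id", "class", "junction",
                                        "breakpoint", "observable", "n_errors"])
    return SyntheticLocusReads(index=index, reads=reads, truth=truth,
                               known_junctions=known, spec=spec)


def write_locus_reads(sim: SyntheticLocusReads, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA reference, FASTQ reads (constant quality 'I'), truth TSV, spec YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "locus.fa",
        "fastq": out / "reads.fastq",
        "truth": out / "truth.tsv",
        "spec": out / "spec.yaml",
    }
    with open(paths["fasta"], "w") as fa:
        fa.write(f">{sim.index.label}\n")
        s = sim.index.sequence
        for i in range(0, len(s), 70):
            fa.write(s[i:i + 70] + "\n")
    with open(paths["fastq"], "w") as fq:
        for read_id, read in sim.reads:
            fq.write(f"@{read_id}\n{read}\n+\n{'I' * len(read)}\n")
    sim.truth.to_csv(paths["truth"], sep="\t", index=False)
    spec_dict = _to_plain(asdict(sim.spec))
    paths["spec"].write_text(yaml.safe_dump(spec_dict, sort_keys=False))
    return paths


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write target/decoy matrices and the expression vector as TSV, spec as YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for mark, matrix in cohort.target.items():
        p = out / f"target_{mark}.tsv"
        matrix.to_tsv(p)
        paths[f"target_{mark}"] = p
    for mark, matrices in cohort.decoys.items():
        for matrix in matrices:
            label = matrix.bins[0].window.label or matrix.bins[0].window.chrom
            p = out / f"decoy_{label}_{mark}.tsv"
            matrix.to_tsv(p)
            paths[f"decoy_{label}_{mark}"] = p
    cohort.expr.to_tsv(out / "expression.tsv")
    paths["expression"] = out / "expression.tsv"
    cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    paths["truth"] = out / "truth.tsv"
    spec = _to_plain(asdict(cohort.spec))
    (out / "spec.yaml").write_text(yaml.safe_dump(spec, sort_keys=False, default_flow_style=None))
    paths["spec"] = out / "spec.yaml"
    return paths
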