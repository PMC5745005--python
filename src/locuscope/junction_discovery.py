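"""Pseudo-paired split-read discovery of un-annotated splice junctions.

Single-end reads that failed a prior genome/transcriptome alignment are cut
into two k-mers ("pseudo-pairs"): the first k nt of the read and the k-mer
starting at in-read offset O (clipped to the read end). Both mates are
placed on a locus window — the +/- 100 kb neighbourhood of the focal exon —
by exact (optionally 1-mismatch) matching, and the displacement d between
the mates' transcript-oriented 5' ends encodes the splicing geometry:

* d == O     the read is contiguous on the genome (no junction between mates);
* d >  O     a forward splice, skipping an intron of d - O nt;
* d <  O     reversed geometry — the hallmark of a back-splice (circRNA
             junction), where the second mate lands upstream of the first.

The placement does not pinpoint the breakpoint at base resolution; instead,
each read whose pseudo-mates both place is reported with its geometry and
its relation to the focal exon's acceptor and donor. Junctions in the read
interval outside [k, O] fall inside one of the mates and are invisible to
this geometry — a documented blind spot.

All geometry is computed in transcript orientation of the target strand, so
"upstream"/"downstream" follow the transcript for both + and - strand loci.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Default locus windows from the human (hg38, + strand) and mouse (mm10,
# - strand) focal-exon neighbourhoods this method was designed around.
DEFAULT_WINDOWS = {
    "hg38": {"chrom": "chrX", "start": 140_683_176, "end": 140_884_660, "strand": "+"},
    "mm10": {"chrom": "chrX", "start": 61_083_246, "end": 61_285_558, "strand": "-"},
}


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SplitConfig:
    """Pseudo-pair geometry and placement parameters.

    k: first-mate length. O: in-read start of the second mate — 50 for
    ~76-nt+ reads, 30 for 50-nt reads, so the second mate is the k-mer at
    [O, min(O+k, L)). min_mate: both mates must exceed 18 nt. max_placements
    caps same-strand hit combinations per read (guards low-complexity
    mates). known_tol: +/- nt within which a placement's geometry matches a
    known junction.
    """

    k: int = 20
    O: int = 50
    min_mate: int = 19
    max_placements: int = 10
    mismatch: str = "exact"  # or "one_mismatch"
    known_tol: int = 2

    def __post_init__(self) -> None:
        if self.k < self.min_mate:
            raise ValueError(f"k={self.k} below minimum mate length {self.min_mate}")
        if self.O < self.k:
            raise ValueError(f"O={self.O} must be >= k={self.k} (mates must not overlap)")
        if self.mismatch not in ("exact", "one_mismatch"):
            raise ValueError(f"unknown mismatch mode {self.mismatch!r}")


@dataclass
class LocusIndex:
    """The locus window sequence plus the focal exon's boundaries.

    ``exon_start``/``exon_end`` are window coordinates (0-based half-open on
    the + strand of the window sequence). In transcript orientation the
    acceptor is the exon's 5' boundary and the donor its 3' boundary.
    """

    sequence: str
    target_strand: str = "+"
    exon_start: int = 0
    exon_end: int = 0
    label: str = "locus"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.target_strand not in "+-":
            raise ValueError(f"target_strand must be '+' or '-', got {self.target_strand!r}")
        if not 0 <= self.exon_start <= self.exon_end <= len(self.sequence):
            raise ValueError("focal exon must lie inside the window")

    def __len__(self) -> int:
        return len(self.sequence)

    # transcript-oriented coordinates: position of a mate's 5' end measured
    # along the target transcript's direction of transcription
    def to_transcript(self, pos: int, length: int, strand: str) -> int:
        if strand == "+":
            return pos
        return len(self.sequence) - (pos + length)

    @property
    def acceptor_t(self) -> int:
        """Focal exon 5' boundary in transcript orientation."""
        if self.target_strand == "+":
            return self.exon_start
        return len(self.sequence) - self.exon_end

    @property
    def donor_t(self) -> int:
        """Focal exon 3' boundary in transcript orientation."""
        if self.target_strand == "+":
            return self.exon_end
        return len(self.sequence) - self.exon_start

    @classmethod
    def from_fasta(cls, path: str | Path, target_strand: str = "+",
                   exon_start: int = 0, exon_end: int = 0) -> "LocusIndex":
        from Bio import SeqIO
        record = next(SeqIO.parse(str(path), "fasta"))
        return cls(sequence=str(record.seq), target_strand=target_strand,
                   exon_start=exon_start, exon_end=exon_end, label=record.id)


@dataclass(frozen=True)
class PseudoPair:
    read_id: str
    mate1: str  # read[0, k)
    mate2: str  # read[O, min(O+k, L))
    O: int


@dataclass(frozen=True)
class PairPlacement:
    """Both mates placed on the same strand; positions are transcript-oriented 5' ends."""

    p1: int
    p2: int
    strand: str

    @property
    def d(self) -> int:
        return self.p2 - self.p1


@dataclass(frozen=True)
class JunctionCall:
    read_id: str
    cls: str        # contiguous | forward_splice | back_splice | internal_other
    relation: str   # upstream_of_acceptor | downstream_of_donor | spans_circle_junction | internal | other
    d: int | None = None
    intron_span: int | None = None
    placement: PairPlacement | None = None
    antisense: bool = False


@dataclass(frozen=True)
class KnownJunction:
    """A known splice, transcript-oriented: donor then acceptor positions.

    For a forward splice acceptor_t > donor_t; for a back-splice (circle
    junction) acceptor_t < donor_t. ``delta`` is the displacement shift the
    junction imposes on a pseudo-pair spanning it: d - O == acceptor_t - donor_t.
    """

    name: str
    donor_t: int
    acceptor_t: int
    kind: str = "forward"  # or "back"

    @property
    def delta(self) -> int:
        return self.acceptor_t - self.donor_t


def split_read(read_id: str, seq: str, cfg: SplitConfig) -> PseudoPair | None:
    """Cut a read into its two pseudo-mates; None (reject) if either is too short."""
    seq = seq.upper()
    mate1 = seq[:cfg.k]
    mate2 = seq[cfg.O:cfg.O + cfg.k]
    if len(mate1) < cfg.min_mate or len(mate2) < cfg.min_mate:
        return None
    return PseudoPair(read_id=read_id, mate1=mate1, mate2=mate2, O=cfg.O)


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, start = [], haystack.find(needle)
    while start != -1:
        hits.append(start)
        start = haystack.find(needle, start + 1)
    return hits


def _find_one_mismatch(haystack: str, needle: str) -> list[int]:
    """Positions matching ``needle`` with <= 1 substitution (includes exact)."""
    k = len(needle)
    hits = set(_find_all(haystack, needle))
    # anchor on the exact half that must be error-free under one substitution
    half = k // 2
    for pos in _find_all(haystack, needle[:half]):
        window = haystack[pos:pos + k]
        if len(window) == k and sum(a != b for a, b in zip(window, needle)) <= 1:
            hits.add(pos)
    for pos in _find_all(haystack, needle[half:]):
        start = pos - half
        if start < 0:
            continue
        window = haystack[start:start + k]
        if len(window) == k and sum(a != b for a, b in zip(window, needle)) <= 1:
            hits.add(start)
    return sorted(hits)


def locate_mate(mate: str, index: LocusIndex, cfg: SplitConfig) -> list[tuple[int, str]]:
    """All placements of a mate on the window: (window position, strand).

    + strand hits are exact occurrences of the mate in the window sequence;
    - strand hits are occurrences of its reverse complement. In exact mode
    an N anywhere in the mate yields no hits.
    """
    finder = _find_all if cfg.mismatch == "exact" else _find_one_mismatch
    if cfg.mismatch == "exact" and "N" in mate:
        return []
    hits = [(pos, "+") for pos in finder(index.sequence, mate)]
    hits += [(pos, "-") for pos in finder(index.sequence, reverse_complement(mate))]
    return hits


def place_pair(pair: PseudoPair, index: LocusIndex, cfg: SplitConfig) -> PairPlacement | None:
    """Select the best same-strand joint placement of the two mates.

    Among all same-strand hit combinations, the one minimizing |d - O| wins
    (the most parsimonious, contiguous-like explanation); ties break to the
    smallest p1. Returns None when no same-strand combination exists or the
    number of combinations exceeds ``max_placements``.
    """
    hits1 = locate_mate(pair.mate1, index, cfg)
    hits2 = locate_mate(pair.mate2, index, cfg)
    combos: list[PairPlacement] = []
    for pos1, s1 in hits1:
        for pos2, s2 in hits2:
            if s1 != s2:
                continue
            combos.append(PairPlacement(
                p1=index.to_transcript(pos1, len(pair.mate1), s1),
                p2=index.to_transcript(pos2, len(pair.mate2), s2),
                strand=s1,
            ))
    if not combos or len(combos) > cfg.max_placements:
        return None
    return min(combos, key=lambda pl: (abs(pl.d - pair.O), pl.p1))


def classify_placement(pl: PairPlacement, index: LocusIndex, cfg: SplitConfig,
                       read_id: str = "", mate2_len: int | None = None) -> JunctionCall:
    """Interpret a placement's geometry relative to the focal exon."""
    if pl.strand != index.target_strand:
        return JunctionCall(read_id=read_id, cls="internal_other", relation="other",
                            d=pl.d, placement=pl, antisense=True)
    mate2_len = mate2_len if mate2_len is not None else cfg.k
    acc, don = index.acceptor_t, index.donor_t
    d = pl.d
    mate1_end = pl.p1 + cfg.k
    mate2_end = pl.p2 + mate2_len

    if d == cfg.O:
        return JunctionCall(read_id=read_id, cls="contiguous", relation="internal",
                            d=d, placement=pl)
    if d > cfg.O:
        # forward splice: mate1 upstream of the junction, mate2 downstream
        if mate1_end <= acc and pl.p2 >= acc - cfg.known_tol and pl.p2 < don:
            relation = "upstream_of_acceptor"
        elif pl.p1 >= acc and mate1_end <= don + cfg.known_tol and pl.p2 >= don:
            relation = "downstream_of_donor"
        elif pl.p1 >= acc and mate2_end <= don:
            relation = "internal"
        else:
            relation = "other"
        return JunctionCall(read_id=read_id, cls="forward_splice", relation=relation,
                            d=d, intron_span=d - cfg.O, placement=pl)
    # d < O: reversed geometry, back-splice candidate — mate1 sits toward the
    # exon's donor end, mate2 toward its acceptor end
    if pl.p1 >= acc and mate1_end <= don + cfg.known_tol \
            and pl.p2 >= acc - cfg.known_tol and mate2_end <= don:
        relation = "spans_circle_junction"
    else:
        relation = "other"
    return JunctionCall(read_id=read_id, cls="back_splice", relation=relation,
                        d=d, placement=pl)


def matches_known(call: JunctionCall, known: KnownJunction, cfg: SplitConfig) -> bool:
    """Does a splice call's geometry fit a known junction within tolerance?

    A pseudo-pair spanning junction (donor_t, acceptor_t) shows
    d - O == acceptor_t - donor_t, mate1 ending at or before the donor and
    mate2 starting at or after the acceptor.
    """
    if call.cls not in ("forward_splice", "back_splice") or call.placement is None:
        return False
    pl = call.placement
    if abs((call.d - cfg.O) - known.delta) > cfg.known_tol:
        return False
    return (pl.p1 + cfg.k <= known.donor_t + cfg.known_tol
            and pl.p2 >= known.acceptor_t - cfg.known_tol)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read id, sequence) from FASTQ, transparently handling gzip."""
    from Bio import SeqIO
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for record in SeqIO.parse(fh, "fastq"):
            yield record.id, str(record.seq)


@dataclass
class DiscoveryReport:
    calls: pd.DataFrame           # one row per placed read
    counts: dict[str, int]        # per-class tallies
    explained: int                # splice calls matching a known junction
    novel: int                    # splice calls matching none
    rejected: int                 # reads with a pseudo-mate below min_mate
    unplaced: int                 # pairs with no acceptable same-strand placement
    total_reads: int

    def to_json(self) -> str:
        return json.dumps({
            "total_reads": self.total_reads,
            "rejected": self.rejected,
            "unplaced": self.unplaced,
            "counts": self.counts,
            "splice_evidence_reads": self.explained + self.novel,
            "explained_by_known": self.explained,
            "novel": self.novel,
        }, indent=2)


def discover(reads: Iterable[tuple[str, str]] | str | Path,
             index: LocusIndex,
             cfg: SplitConfig | None = None,
             known_junctions: Sequence[KnownJunction] = ()) -> DiscoveryReport:
    """Run the pseudo-pair pipeline over an unaligned-read stream.

    ``reads`` is a FASTQ path or an iterable of (id, sequence). Every placed
    read yields a JunctionCall row; splice calls whose geometry fits a
    junction in ``known_junctions`` (within ``cfg.known_tol`` nt) are
    counted as explained, the rest as novel. Deterministic given
    (reads, index, cfg).
    """
    cfg = cfg or SplitConfig()
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    rows = []
    counts = {"contiguous": 0, "forward_splice": 0, "back_splice": 0, "internal_other": 0}
    explained = novel = rejected = unplaced = total = 0
    for read_id, seq in reads:
        total += 1
        pair = split_read(read_id, seq, cfg)
        if pair is None:
            rejected += 1
            continue
        pl = place_pair(pair, index, cfg)
        if pl is None:
            unplaced += 1
            continue
        call = classify_placement(pl, index, cfg, read_id=read_id,
                                  mate2_len=len(pair.mate2))
        counts[call.cls] += 1
        known_name = ""
        if call.cls in ("forward_splice", "back_splice"):
            hit = next((kj for kj in known_junctions if matches_known(call, kj, cfg)), None)
            if hit is not None:
                explained += 1
                known_name = hit.name
            else:
                novel += 1
        rows.append({
            "read_id": read_id, "class": call.cls, "d": call.d,
            "intron_span": call.intron_span if call.intron_span is not None else "",
            "relation": call.relation, "p1": pl.p1, "p2": pl.p2,
            "strand": pl.strand, "known_junction": known_name,
        })
    calls = pd.DataFrame(rows, columns=["read_id", "class", "d", "intron_span",
                                        "relation", "p1", "p2", "strand", "known_junction"])
    return DiscoveryReport(calls=calls, counts=counts, explained=explained,
                           novel=novel, rejected=rejected, unplaced=unplaced,
                           total_reads=total)


def write_discovery_outputs(report: DiscoveryReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.calls.to_csv(out / "junction_calls.tsv", sep="\t", index=False)
    (out / "report.json").write_text(report.to_json())
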