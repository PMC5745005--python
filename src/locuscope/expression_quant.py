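"""Expression normalization and junction-reference construction.

Ingests kallisto-style per-transcript abundance tables and produces the
normalized expression measures used elsewhere in the package:

* length-scaled expression ``1000 * tpm / transcript_length`` (an RPKM-like
  per-nucleotide measure) for the target feature correlated against
  chromatin marks;
* gene-level TPM as the sum of member-transcript TPMs;
* junction counts-per-million against a custom splice-junction reference,
  depth-normalized by the reads quantified against the companion reference
  transcriptome and averaged across replicates.

Also builds the 40-bp junction reference (20 nt either side of each splice
site) used for junction-level quantification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

JUNCTION_FLANK_DEFAULT = 20  # nt on each side -> 40-bp junction entries


@dataclass(frozen=True)
class TranscriptQuant:
    transcript_id: str
    length: int
    tpm: float
    est_counts: float = 0.0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.transcript_id}: transcript length must be > 0")
        if self.tpm < 0 or self.est_counts < 0:
            raise ValueError(f"{self.transcript_id}: tpm/est_counts must be >= 0")


@dataclass
class ExpressionVector:
    """Per-cell-type normalized expression of one feature."""

    feature_id: str
    values: pd.Series  # index = cell-type labels, one value per cell type
    normalization: str = "length_scaled_tpm"  # or "tpm", "junction_cpm"

    def __post_init__(self) -> None:
        self.values = pd.Series(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError(f"{self.feature_id}: expression values must be >= 0")
        if self.values.index.has_duplicates:
            raise ValueError(f"{self.feature_id}: duplicate cell-type labels")

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.values.index]

    def to_tsv(self, path: str | Path) -> None:
        df = self.values.rename(self.feature_id).rename_axis("cell_type").reset_index()
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, normalization: str = "length_scaled_tpm") -> "ExpressionVector":
        df = pd.read_csv(path, sep="\t")
        feature = df.columns[1]
        return cls(feature_id=str(feature),
                   values=pd.Series(df[feature].to_numpy(float), index=df["cell_type"].astype(str)),
                   normalization=normalization)


@dataclass(frozen=True)
class JunctionReferenceEntry:
    """A donor-flank + acceptor-flank concatenation naming one splice junction."""

    junction_id: str
    sequence: str
    donor_flank: int
    acceptor_flank: int

    def __post_init__(self) -> None:
        if len(self.sequence) != self.donor_flank + self.acceptor_flank:
            raise ValueError(
                f"{self.junction_id}: sequence length {len(self.sequence)} != "
                f"{self.donor_flank} + {self.acceptor_flank}"
            )


def read_abundance(path: str | Path) -> pd.DataFrame:
    """Read a kallisto-style abundance table (target_id, length, [eff_length,] est_counts, tpm)."""
    df = pd.read_csv(path, sep="\t")
    required = {"target_id", "length", "est_counts", "tpm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing abundance columns {sorted(missing)}")
    return df


def length_scaled_expression(tpm, length):
    """1000 * tpm / transcript length — per-nucleotide expression density.

    Accepts scalars or aligned arrays; linear in tpm at fixed length.
    """
    length = np.asarray(length, dtype=float)
    if (length <= 0).any():
        raise ValueError("transcript length must be > 0")
    out = 1000.0 * np.asarray(tpm, dtype=float) / length
    return float(out) if out.ndim == 0 else out


def gene_level_sum(quants: Iterable[TranscriptQuant],
                   gene_map: Mapping[str, str]) -> pd.Series:
    """Sum member-transcript TPMs to gene level.

    Transcripts absent from ``gene_map`` are excluded with a logged warning
    rather than aborting the run.
    """
    totals: dict[str, float] = {}
    for q in quants:
        gene = gene_map.get(q.transcript_id)
        if gene is None:
            logger.warning("transcript %s has no gene assignment; excluded", q.transcript_id)
            continue
        totals[gene] = totals.get(gene, 0.0) + q.tpm
    # genes with no surviving transcripts still report 0
    for gene in gene_map.values():
        totals.setdefault(gene, 0.0)
    return pd.Series(totals, dtype=float).sort_index()


def junction_cpm(est_counts: pd.DataFrame,
                 depth: Mapping[str, float],
                 replicate_groups: Mapping[str, Sequence[str]] | None = None) -> pd.DataFrame:
    """Depth-normalize junction counts to counts-per-million and average replicates.

    ``est_counts`` is junctions x samples; ``depth`` gives, per sample, the
    total reads quantified against the reference transcriptome (total
    est_counts over the reference index). ``replicate_groups`` maps cell-type
    label -> member sample names; without it each sample is its own group.
    Junctions with no supporting read in any sample are dropped.
    """
    cpm = est_counts.astype(float).copy()
    for sample in cpm.columns:
        d = float(depth[sample])
        if d <= 0:
            raise ValueError(f"sample {sample}: sequencing depth must be > 0")
        cpm[sample] = cpm[sample] * 1e6 / d
    if replicate_groups is not None:
        cpm = pd.DataFrame({
            cell_type: cpm[list(members)].mean(axis=1)
            for cell_type, members in replicate_groups.items()
        })
    supported = (est_counts.to_numpy(float) > 0).any(axis=1)
    return cpm.loc[supported]


def build_junction_reference(splice_sites: Sequence[tuple[str, str, str]],
                             flank: int = JUNCTION_FLANK_DEFAULT) -> list[JunctionReferenceEntry]:
    """Concatenate donor/acceptor flanks into junction reference entries.

    ``splice_sites`` holds (junction_id, upstream_seq, downstream_seq); each
    entry takes the last ``flank`` nt of the upstream (donor-side) sequence
    and the first ``flank`` nt of the downstream (acceptor-side) sequence.
    For a back-splice the donor side is the exon end and the acceptor side
    the same exon's start.
    """
    entries = []
    for junction_id, upstream, downstream in splice_sites:
        if len(upstream) < flank or len(downstream) < flank:
            raise ValueError(
                f"junction {junction_id}: flank sequences shorter than {flank} nt "
                f"({len(upstream)}/{len(downstream)})"
            )
        entries.append(JunctionReferenceEntry(
            junction_id=junction_id,
            sequence=upstream[-flank:] + downstream[:flank],
            donor_flank=flank,
            acceptor_flank=flank,
        ))
    return entries


def write_junction_fasta(entries: Iterable[JunctionReferenceEntry], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(e.sequence), id=e.junction_id, description="") for e in entries]
    seqio_write(records, str(path), "fasta")


def target_expression_vector(abundances: Mapping[str, pd.DataFrame],
                             feature_ids: Sequence[str],
                             replicate_groups: Mapping[str, Sequence[str]] | None = None,
                             normalization: str = "length_scaled_tpm",
                             feature_label: str | None = None) -> ExpressionVector:
    """Build the per-cell-type expression vector for one feature.

    ``abundances`` maps sample name -> abundance table. The feature's value
    per sample is the sum over ``feature_ids`` rows of length-scaled TPM (or
    raw TPM); replicate samples in the same cell type are then averaged,
    matching the replicate handling of the ChIP matrices.
    """
    per_sample = {}
    for sample, df in abundances.items():
        rows = df[df["target_id"].isin(feature_ids)]
        if rows.empty:
            raise ValueError(f"sample {sample}: none of {list(feature_ids)} in abundance table")
        if normalization == "length_scaled_tpm":
            per_sample[sample] = float(np.sum(length_scaled_expression(rows["tpm"], rows["length"])))
        elif normalization == "tpm":
            per_sample[sample] = float(rows["tpm"].sum())
        else:
            raise ValueError(f"unknown normalization {normalization!r}")
    series = pd.Series(per_sample, dtype=float)
    if replicate_groups is not None:
        series = pd.Series({
            cell_type: series[list(members)].mean()
            for cell_type, members in replicate_groups.items()
        })
    return ExpressionVector(feature_id=feature_label or "+".join(feature_ids),
                            values=series, normalization=normalization)
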