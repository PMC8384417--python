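"""Per-codon A-site pause scores.

The pause score of one codon occurrence is the ribosome density at the first
nucleotide of the codon, with the codon in the ribosomal A site, divided by
the mean per-nucleotide density of the gene it occurs in.  Scores are averaged
(unweighted) over every transcriptome occurrence of each of the 61 sense
codons.  Three filters from the field's standard protocol apply: reads within
a length window, genes with more than ``min_reads_per_codon`` reads per codon
on average (strict inequality), and removal of the first and last
``trim_codons`` codons of each ORF from both the instance set and the
gene-mean denominator.

Because 3'-end-assigned density sits ``asite_offset`` nt downstream of the
A-site codon's first nt, the track is shifted upstream by that offset before
scoring.  Scores are scale invariant, so raw counts and rpm give identical
tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import ORFRecord, Transcriptome, amino_acid, normalize_codon, STOP_CODONS
from .tracks import DensityTrack, coding_profile

log = logging.getLogger(__name__)

DEFAULT_ASITE_OFFSET = 15
DEFAULT_TRIM_CODONS = 7
DEFAULT_MIN_READS_PER_CODON = 0.1


@dataclass(frozen=True)
class CodonInstance:
    """One occurrence of a codon type within one ORF."""

    gene_id: str
    codon_index: int
    triplet: str
    first_nt: int  # genomic coordinate of the codon's first nt
    ref_name: str
    strand: str


@dataclass
class CodonStats:
    mean_score: float
    n_instances: int
    instance_scores: np.ndarray


@dataclass
class PauseScoreTable:
    """Aggregated pause scores per codon type and per amino acid."""

    per_codon: Dict[str, CodonStats]
    per_amino_acid: Dict[str, CodonStats]
    asite_offset: int
    filters: Dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [(t, amino_acid(t), s.mean_score, s.n_instances)
                for t, s in sorted(self.per_codon.items())]
        return pd.DataFrame(rows, columns=["triplet", "amino_acid", "mean_score", "n_instances"])

    def aa_frame(self) -> pd.DataFrame:
        rows = [(aa, s.mean_score, s.n_instances)
                for aa, s in sorted(self.per_amino_acid.items())]
        return pd.DataFrame(rows, columns=["amino_acid", "mean_score", "n_instances"])

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# asite_offset={self.asite_offset}")
            for k, v in self.filters.items():
                fh.write(f"; {k}={v}")
            fh.write("\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.6g")


def shift_to_asite(track: DensityTrack, offset: int) -> DensityTrack:
    """Reattribute 3'-end density at position p to the A-site first nt p − offset
    (strand-aware: p + offset on the minus strand).  Counts are conserved except
    for positions shifted off the reference, which are logged."""
    if offset < 0:
        raise ValueError("offset must be >= 0")
    if offset == 0:
        return track.copy()
    out = DensityTrack(track.ref_lengths, units=track.units)
    out.total_mapped = track.total_mapped
    lost = 0.0
    for (ref, strand), vec in track.values.items():
        dst = out.values[(ref, strand)]
        if strand == "+":
            dst[:-offset] = vec[offset:]
            lost += vec[:offset].sum()
        else:
            dst[offset:] = vec[:-offset]
            lost += vec[-offset:].sum()
    if lost:
        log.warning("shift_to_asite: %g units shifted off the reference", lost)
    return out


def gene_mean_density(track: DensityTrack, orf: ORFRecord,
                      trim_codons: int = DEFAULT_TRIM_CODONS) -> float:
    """Mean per-nt density over the ORF excluding the first/last trim_codons codons."""
    if trim_codons < 0:
        raise ValueError("trim_codons must be >= 0")
    if orf.n_codons <= 2 * trim_codons:
        raise ValueError(f"{orf.gene_id}: no interior left after trimming {trim_codons} codons per edge")
    prof = coding_profile(track, orf)
    interior = prof[3 * trim_codons: len(prof) - 3 * trim_codons]
    return float(interior.mean())


def gene_passes_filter(track: DensityTrack, orf: ORFRecord,
                       min_reads_per_codon: float = DEFAULT_MIN_READS_PER_CODON) -> bool:
    """True iff the gene has strictly more than min_reads_per_codon reads per codon."""
    total = float(coding_profile(track, orf).sum())
    return total / orf.n_codons > min_reads_per_codon


def instance_pause_score(track: DensityTrack, instance: CodonInstance, gene_mean: float) -> float:
    """Density at the instance's first nt divided by the gene mean (0 is legal)."""
    if gene_mean <= 0:
        raise ValueError("gene_mean must be positive")
    dens = track.values[(instance.ref_name, instance.strand)][instance.first_nt]
    return float(dens) / gene_mean


def collect_instances(orf: ORFRecord, trim_codons: int = DEFAULT_TRIM_CODONS,
                      codons: Optional[Sequence[str]] = None) -> List[CodonInstance]:
    """Interior sense-codon occurrences of an ORF, optionally restricted to
    the given codon types (DNA or RNA alphabet)."""
    wanted = {normalize_codon(c) for c in codons} if codons else None
    out: List[CodonInstance] = []
    for i in range(trim_codons, orf.n_codons - trim_codons):
        t = orf.codon(i)
        if t in STOP_CODONS:
            continue
        if wanted is not None and t not in wanted:
            continue
        out.append(CodonInstance(orf.gene_id, i, t, orf.codon_first_nt(i),
                                 orf.ref_name, orf.strand))
    return out


def pause_scores(track: DensityTrack, transcriptome: Transcriptome, *,
                 asite_offset: int = DEFAULT_ASITE_OFFSET,
                 trim_codons: int = DEFAULT_TRIM_CODONS,
                 min_reads_per_codon: float = DEFAULT_MIN_READS_PER_CODON,
                 exclude_overlaps: bool = False,
                 shifted: bool = False) -> PauseScoreTable:
    """Compute the transcriptome-wide pause score table.

    ``shifted=True`` declares that ``track`` is already A-site shifted.
    Genes failing the coverage filter, shorter than the trimmed window, or
    (optionally) overlapping another ORF are excluded whole; stop codons are
    excluded from the statistics.
    """
    work = track if shifted else shift_to_asite(track, asite_offset)
    scores: Dict[str, List[np.ndarray]] = {}
    aa_scores: Dict[str, List[np.ndarray]] = {}
    n_genes_used = 0
    for orf in transcriptome:
        if exclude_overlaps and orf.gene_id in transcriptome.overlapping:
            continue
        if orf.n_codons <= 2 * trim_codons:
            continue
        if not gene_passes_filter(work, orf, min_reads_per_codon):
            continue
        prof = coding_profile(work, orf)
        interior = prof[3 * trim_codons: len(prof) - 3 * trim_codons]
        gmean = float(interior.mean())
        if gmean <= 0:
            continue
        n_genes_used += 1
        idx = np.arange(trim_codons, orf.n_codons - trim_codons)
        vals = prof[3 * idx] / gmean
        for i, s in zip(idx, vals):
            t = orf.sequence[3 * i: 3 * i + 3]
            if t in STOP_CODONS:
                continue
            scores.setdefault(t, []).append(s)
            aa_scores.setdefault(amino_acid(t), []).append(s)

    def _aggregate(d: Dict[str, List[float]]) -> Dict[str, CodonStats]:
        out = {}
        for key, vals in d.items():
            arr = np.asarray(vals, dtype=float)
            out[key] = CodonStats(float(arr.mean()), len(arr), arr)
        return out

    log.info("pause_scores: %d genes used", n_genes_used)
    return PauseScoreTable(
        per_codon=_aggregate(scores),
        per_amino_acid=_aggregate(aa_scores),
        asite_offset=asite_offset,
        filters={"trim_codons": trim_codons, "min_reads_per_codon": min_reads_per_codon,
                 "exclude_overlaps": float(exclude_overlaps)},
    )


def aggregate_pause_scores(instances: Iterable[CodonInstance],
                           instance_scores: Iterable[float],
                           asite_offset: int = DEFAULT_ASITE_OFFSET) -> PauseScoreTable:
    """Aggregate externally scored instances into a table (unweighted means)."""
    scores: Dict[str, List[float]] = {}
    aa_scores: Dict[str, List[float]] = {}
    for inst, s in zip(instances, instance_scores):
        if inst.triplet in STOP_CODONS:
            continue
        scores.setdefault(inst.triplet, []).append(s)
        aa_scores.setdefault(amino_acid(inst.triplet), []).append(s)

    def _aggregate(d):
        return {k: CodonStats(float(np.mean(v)), len(v), np.asarray(v, dtype=float))
                for k, v in d.items()}

    return PauseScoreTable(_aggregate(scores), _aggregate(aa_scores), asite_offset)
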