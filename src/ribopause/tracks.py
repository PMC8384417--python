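"""Aligned-read ingestion, 3'-end position assignment, and density tracks.

The ribosome's position is anchored at the 3' end of each footprint, which in
bacterial MNase libraries is better defined than the 5' end.  A
:class:`DensityTrack` holds one per-nucleotide vector per (reference, strand)
pair, in raw counts or rpm (reads per million mapped reads).  Tracks are
written as variableStep WIG (1-based) or bedGraph.

Reads come from SAM/BAM (via pysam) or from a plain four-column TSV
(``ref  strand  five_prime_0based  length``) so that simulators and tests
need no binary dependencies.  ``five_prime_0based`` is the biological 5' end:
the leftmost genomic coordinate on ``+``, the rightmost on ``-``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, Mapping, Tuple, Union

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger(__name__)

READ_COLUMNS = ["ref", "strand", "five_prime", "length"]


@dataclass(frozen=True)
class AlignedRead:
    """One uniquely mapped read.  ``five_prime`` is the biological 5'-end
    genomic coordinate (0-based); ``length`` the aligned span on the
    reference."""

    ref_name: str
    strand: str
    five_prime: int
    length: int

    @property
    def three_prime(self) -> int:
        if self.strand == "+":
            return self.five_prime + self.length - 1
        return self.five_prime - self.length + 1

    @property
    def left(self) -> int:
        """Leftmost genomic coordinate."""
        return min(self.five_prime, self.three_prime)


def assign_position(read: AlignedRead, mode: str = "three_prime") -> int:
    """Ribosome position of a read: the 3'-terminal nt on the read's strand."""
    if mode != "three_prime":
        raise ValueError(f"unsupported assignment mode {mode!r}")
    return read.three_prime


def _frame_from_sam(path: Path) -> pd.DataFrame:
    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            left = aln.reference_start
            # aligned span on the reference, so soft-clips/indels do not move the 3' end
            span = aln.reference_length
            if span is None or span <= 0:
                log.warning("skipping unparseable record %s", aln.query_name)
                continue
            if aln.is_reverse:
                rows.append((aln.reference_name, "-", left + span - 1, span))
            else:
                rows.append((aln.reference_name, "+", left, span))
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def _frame_from_tsv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None, names=READ_COLUMNS,
                         dtype={"ref": str, "strand": str, "five_prime": np.int64, "length": np.int64})
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty alignment file") from None
    bad = ~df.strand.isin(["+", "-"])
    if bad.any():
        log.warning("skipping %d TSV records with invalid strand", int(bad.sum()))
        df = df[~bad]
    return df.reset_index(drop=True)


def read_alignments(path: Union[str, Path], min_len: int, max_len: int) -> pd.DataFrame:
    """Read alignments from SAM/BAM or TSV, keeping lengths in [min_len, max_len].

    Returns a DataFrame with columns ``ref, strand, five_prime, length``.
    Raises if no read survives the filter.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    path = Path(path)
    if path.suffix.lower() in {".sam", ".bam"}:
        df = _frame_from_sam(path)
    else:
        df = _frame_from_tsv(path)
    kept = df[(df.length >= min_len) & (df.length <= max_len)].reset_index(drop=True)
    log.info("%s: %d reads kept, %d dropped by length window [%d, %d]",
             path.name, len(kept), len(df) - len(kept), min_len, max_len)
    if kept.empty:
        raise ValueError(f"{path}: no reads in length window [{min_len}, {max_len}]")
    return kept


def iter_alignments(path: Union[str, Path], min_len: int, max_len: int) -> Iterator[AlignedRead]:
    """Stream view of :func:`read_alignments`."""
    for row in read_alignments(path, min_len, max_len).itertuples(index=False):
        yield AlignedRead(row.ref, row.strand, int(row.five_prime), int(row.length))


class DensityTrack:
    """Per-nucleotide read density over each (reference, strand).

    In ``raw`` units the track sum equals the number of retained reads; the
    ``rpm`` track is the raw track scaled by 1e6 / total_mapped.
    """

    def __init__(self, ref_lengths: Mapping[str, int], units: str = "raw"):
        self.ref_lengths: Dict[str, int] = dict(ref_lengths)
        self.units = units
        self.total_mapped: int = 0
        self.values: Dict[Tuple[str, str], np.ndarray] = {
            (ref, strand): np.zeros(length, dtype=float)
            for ref, length in self.ref_lengths.items() for strand in "+-"
        }

    def get(self, ref: str, strand: str) -> np.ndarray:
        return self.values[(ref, strand)]

    def sum(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def to_rpm(self) -> "DensityTrack":
        if self.units == "rpm":
            return self
        if self.total_mapped == 0:
            raise ValueError("cannot convert an empty track to rpm")
        out = DensityTrack(self.ref_lengths, units="rpm")
        out.total_mapped = self.total_mapped
        factor = 1e6 / self.total_mapped
        for key, vec in self.values.items():
            out.values[key] = vec * factor
        return out

    def copy(self) -> "DensityTrack":
        out = DensityTrack(self.ref_lengths, units=self.units)
        out.total_mapped = self.total_mapped
        for key, vec in self.values.items():
            out.values[key] = vec.copy()
        return out


def _as_frame(reads) -> pd.DataFrame:
    if isinstance(reads, pd.DataFrame):
        return reads
    rows = [(r.ref_name, r.strand, r.five_prime, r.length) for r in reads]
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def build_track(reads: Union[pd.DataFrame, Iterable[AlignedRead]],
                ref_lengths: Mapping[str, int],
                normalize: str = "raw") -> DensityTrack:
    """Accumulate assigned 3'-end positions into a density track.

    Out-of-bounds positions and unknown references are skipped with a
    warning; ``total_mapped`` counts the reads actually deposited (this is
    the rpm denominator).
    """
    if normalize not in {"raw", "rpm"}:
        raise ValueError(f"normalize must be 'raw' or 'rpm', got {normalize!r}")
    df = _as_frame(reads)
    track = DensityTrack(ref_lengths, units="raw")
    n_skipped = 0
    plus = df.strand == "+"
    pos = np.where(plus, df.five_prime + df.length - 1, df.five_prime - df.length + 1)
    for (ref, strand), idx in df.groupby(["ref", "strand"], sort=False).groups.items():
        if ref not in ref_lengths:
            log.warning("skipping %d reads on unknown reference %r", len(idx), ref)
            n_skipped += len(idx)
            continue
        p = pos[df.index.get_indexer(idx)]
        ok = (p >= 0) & (p < ref_lengths[ref])
        n_skipped += int((~ok).sum())
        np.add.at(track.values[(ref, strand)], p[ok], 1.0)
    if n_skipped:
        log.warning("%d reads skipped (out of bounds or unknown reference)", n_skipped)
    track.total_mapped = int(round(track.sum()))
    if track.total_mapped == 0:
        raise ValueError("no reads fell inside the reference bounds")
    return track.to_rpm() if normalize == "rpm" else track


# -- WIG / bedGraph ----------------------------------------------------------
# No pre-installed library emits text WIG (pyBigWig is binary), so the
# variableStep dialect used by GEO-style processed tracks is written here.
# One `track` line per (reference, strand); positions are 1-based.

def _fmt(value: float) -> str:
    return format(value, ".10g")


def write_wig(track: DensityTrack, path: Union[str, Path]) -> None:
    """Write non-zero positions as variableStep WIG, one block per (ref, strand)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# ribopause density track; units={track.units}; total_mapped={track.total_mapped}\n")
        for ref in track.ref_lengths:
            for strand in "+-":
                vec = track.values[(ref, strand)]
                nz = np.flatnonzero(vec)
                fh.write(f'track type=wiggle_0 name="{ref}_{"plus" if strand == "+" else "minus"}"\n')
                fh.write(f"variableStep chrom={ref}\n")
                for i in nz:
                    fh.write(f"{i + 1} {_fmt(vec[i])}\n")


def read_wig(path: Union[str, Path], ref_lengths: Mapping[str, int]) -> DensityTrack:
    """Read back the WIG dialect produced by :func:`write_wig`."""
    path = Path(path)
    units, total = "raw", 0
    track = None
    key = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                for part in line[1:].split(";"):
                    part = part.strip()
                    if part.startswith("units="):
                        units = part[6:]
                    elif part.startswith("total_mapped="):
                        total = int(part[13:])
                track = DensityTrack(ref_lengths, units=units)
                track.total_mapped = total
            elif line.startswith("track"):
                name = line.split('name="', 1)[1].rstrip('"')
                ref, suffix = name.rsplit("_", 1)
                key = (ref, "+" if suffix == "plus" else "-")
            elif line.startswith("variableStep"):
                continue
            elif line:
                if track is None or key is None:
                    raise ValueError(f"{path}: malformed WIG (data before headers)")
                pos_s, val_s = line.split()
                track.values[key][int(pos_s) - 1] = float(val_s)
    if track is None:
        raise ValueError(f"{path}: empty WIG file")
    return track


def write_bedgraph(track: DensityTrack, path: Union[str, Path], strand: str = "+") -> None:
    """Write one strand of the track as bedGraph (0-based half-open runs)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="ribopause_{ "plus" if strand == "+" else "minus"}"\n')
        for ref in track.ref_lengths:
            vec = track.values[(ref, strand)]
            if not vec.any():
                continue
            change = np.flatnonzero(np.diff(vec) != 0)
            starts = np.concatenate(([0], change + 1))
            ends = np.concatenate((change + 1, [len(vec)]))
            for s, e in zip(starts, ends):
                if vec[s] != 0:
                    fh.write(f"{ref}\t{s}\t{e}\t{_fmt(vec[s])}\n")


def coding_profile(track: DensityTrack, orf) -> np.ndarray:
    """Per-nt density over an ORF in coding orientation (codon i at [3i, 3i+3))."""
    vec = track.values[(orf.ref_name, orf.strand)][orf.start:orf.end]
    return vec if orf.strand == "+" else vec[::-1]
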