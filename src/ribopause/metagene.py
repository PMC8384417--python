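"""Codon-aligned metagene profiles and peak calling.

For every qualifying occurrence of a codon type, a window of A-site-shifted,
gene-mean-normalized per-nt density is extracted around the codon's first nt
(offset 0).  Positive offsets run downstream in the coding direction.
Occurrences closer than the window to an ORF edge contribute masked partial
windows with per-offset denominators, so short genes are not discarded.

On such profiles an A-site pause appears as a peak at offset 0; post-lysis
run-on elongation spreads it into shoulders at +3 and +6 (the affected codon
having moved into the P and E sites), and a queued (collided) upstream
ribosome adds density near offset −25, roughly one footprint length upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import scipy.signal

from .genome import Transcriptome, normalize_codon
from .pause import (DEFAULT_ASITE_OFFSET, DEFAULT_MIN_READS_PER_CODON,
                    DEFAULT_TRIM_CODONS, gene_passes_filter, shift_to_asite)
from .tracks import DensityTrack, coding_profile

log = logging.getLogger(__name__)


@dataclass
class MetageneProfile:
    offsets: np.ndarray          # -window .. +window, nt
    mean_density: np.ndarray     # gene-mean-normalized, averaged over instances
    coverage: np.ndarray         # instances covering each offset
    n_instances: int
    peaks: List[Tuple[int, float]] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"offset": self.offsets, "mean_density": self.mean_density,
                             "n_covering": self.coverage})


def codon_metagene(track: DensityTrack, transcriptome: Transcriptome,
                   codons: Sequence[str] | str, window: int = 50, *,
                   asite_offset: int = DEFAULT_ASITE_OFFSET,
                   trim_codons: int = DEFAULT_TRIM_CODONS,
                   min_reads_per_codon: float = DEFAULT_MIN_READS_PER_CODON,
                   exclude_overlaps: bool = False,
                   shifted: bool = False) -> MetageneProfile:
    """Average normalized density aligned at all occurrences of the codon(s).

    Gene inclusion and edge trimming follow the pause-score filters exactly.
    Raises if no occurrence qualifies.
    """
    if isinstance(codons, str):
        codons = codons.split(",")
    wanted = {normalize_codon(c) for c in codons}
    if window < 1:
        raise ValueError("window must be >= 1")
    work = track if shifted else shift_to_asite(track, asite_offset)

    width = 2 * window + 1
    total = np.zeros(width)
    count = np.zeros(width, dtype=int)
    n_instances = 0
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
        norm = prof / gmean
        L = len(prof)
        for i in range(trim_codons, orf.n_codons - trim_codons):
            if orf.sequence[3 * i: 3 * i + 3] not in wanted:
                continue
            x0 = 3 * i
            lo, hi = x0 - window, x0 + window + 1
            a, b = max(lo, 0), min(hi, L)
            total[a - lo: width - (hi - b)] += norm[a:b]
            count[a - lo: width - (hi - b)] += 1
            n_instances += 1
    if n_instances == 0:
        raise ValueError(f"no qualifying occurrence of {sorted(wanted)}")
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return MetageneProfile(np.arange(-window, window + 1), mean, count, n_instances)


def find_peaks(profile: MetageneProfile, min_height: float = 1.5,
               min_separation: int = 2) -> List[Tuple[int, float]]:
    """Local maxima above min_height, greedily spaced by min_separation nt.

    Heights are normalized densities (no background subtraction).  The peak
    list is also stored on the profile.
    """
    y = np.nan_to_num(profile.mean_density, nan=0.0)
    idx, props = scipy.signal.find_peaks(y, height=min_height,
                                         distance=max(1, min_separation))
    order = np.argsort(props["peak_heights"])[::-1]
    peaks = [(int(profile.offsets[idx[j]]), float(y[idx[j]])) for j in order]
    profile.peaks = peaks
    return peaks
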