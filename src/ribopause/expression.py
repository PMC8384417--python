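"""Gene-level quantification, ribosome occupancy, attenuation ratios, and
gene-set shift comparisons.

RPKM = counts × 10⁹ / (total_mapped × length_nt); ribosome occupancy
RO = Ribo-seq RPKM / RNA-seq RPKM, a translational-efficiency proxy.

Transcriptional attenuation at amino-acid-operon leaders (e.g. *leuL* ahead
of *leuABCD*, *ilvL* ahead of *ilvGMEDA*) is read out as the fold-decrease of
length-adjusted RNA-seq density from the leader region to a downstream-gene
region: efficient termination gives a large fold-decrease, stalling-induced
read-through collapses it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats

from .genome import Transcriptome
from .tracks import DensityTrack, coding_profile

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Region:
    ref_name: str
    strand: str
    start: int  # 0-based inclusive
    end: int    # exclusive

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AttenuationResult:
    leader_region: Region
    downstream_region: Region
    leader_density: float      # track units per nt
    downstream_density: float
    fold_decrease: float       # leader / downstream; inf when downstream is empty


@dataclass
class GeneSetShift:
    set_label: str
    log2_ratios: np.ndarray
    median_log2: float
    p_t: float        # one-sample t-test of the ratios vs 0
    p_mw: float       # Mann-Whitney vs all quantified genes outside the set
    n_genes: int
    n_excluded: int   # zero-count genes dropped (or none if pseudocount used)


def quantify(track_rna: DensityTrack, track_ribo: DensityTrack,
             transcriptome: Transcriptome) -> pd.DataFrame:
    """Per-gene counts, RPKM, and ribosome occupancy.

    Both tracks must be in raw counts with a recorded total_mapped.  RO is
    NaN where the RNA RPKM is zero (flagged, not fatal).
    """
    for name, tr in (("rna", track_rna), ("ribo", track_ribo)):
        if tr.units != "raw":
            raise ValueError(f"{name} track must be in raw counts for RPKM")
        if tr.total_mapped == 0:
            raise ValueError(f"{name} track has zero mapped reads")
    rows = []
    for orf in transcriptome:
        n_rna = float(coding_profile(track_rna, orf).sum())
        n_ribo = float(coding_profile(track_ribo, orf).sum())
        length = orf.end - orf.start
        rna_rpkm = n_rna * 1e9 / (track_rna.total_mapped * length)
        ribo_rpkm = n_ribo * 1e9 / (track_ribo.total_mapped * length)
        ro = ribo_rpkm / rna_rpkm if rna_rpkm > 0 else math.nan
        rows.append((orf.gene_id, length, n_rna, n_ribo, rna_rpkm, ribo_rpkm, ro))
    df = pd.DataFrame(rows, columns=["gene_id", "length_nt", "rna_counts", "ribo_counts",
                                     "rna_rpkm", "ribo_rpkm", "ro"])
    return df.set_index("gene_id")


def region_density(track: DensityTrack, region: Region) -> float:
    """Region read signal divided by region length (track units per nt)."""
    if region.length <= 0:
        raise ValueError("empty region")
    vec = track.values[(region.ref_name, region.strand)]
    return float(vec[region.start:region.end].sum()) / region.length


def attenuation_ratio(track_rna: DensityTrack, leader_region: Region,
                      downstream_region: Region) -> AttenuationResult:
    """Length-adjusted RNA density fold-decrease from leader to downstream gene."""
    if leader_region.strand != downstream_region.strand:
        raise ValueError("leader and downstream regions must share a strand")
    if (leader_region.ref_name == downstream_region.ref_name
            and leader_region.start < downstream_region.end
            and downstream_region.start < leader_region.end):
        raise ValueError("leader and downstream regions must be disjoint")
    d_leader = region_density(track_rna, leader_region)
    d_down = region_density(track_rna, downstream_region)
    fold = d_leader / d_down if d_down > 0 else math.inf
    if not math.isfinite(fold):
        log.warning("downstream region has zero density; fold_decrease = inf")
    return AttenuationResult(leader_region, downstream_region, d_leader, d_down, fold)


def read_regions_bed(path) -> Dict[str, Region]:
    """Read named regions from BED6 (name column required, strand required)."""
    import pyranges as pr
    df = pr.read_bed(str(path)).df
    for col in ("Name", "Strand"):
        if col not in df.columns:
            raise ValueError(f"{path}: BED6 with name and strand columns required")
    return {str(r.Name): Region(str(r.Chromosome), str(r.Strand), int(r.Start), int(r.End))
            for r in df.itertuples(index=False)}


def compare_gene_sets(expr_mutant: pd.DataFrame, expr_control: pd.DataFrame,
                      gene_sets: Mapping[str, Sequence[str]],
                      value: str = "rna_rpkm",
                      pseudocount: float | None = None,
                      min_set_size: int = 3) -> list[GeneSetShift]:
    """Per-gene-set log2(mutant/control) shifts with t and Mann-Whitney tests.

    Genes with a zero value in either condition are excluded unless a
    ``pseudocount`` is given (added to both sides); missing genes are logged.
    The Mann-Whitney compares each set's ratios with those of all quantified
    genes outside the set.  Statistics are suppressed (NaN) below
    ``min_set_size``.
    """
    common = expr_mutant.index.intersection(expr_control.index)
    m = expr_mutant.loc[common, value].to_numpy(dtype=float)
    c = expr_control.loc[common, value].to_numpy(dtype=float)
    if pseudocount is not None:
        m, c = m + pseudocount, c + pseudocount
    ok = (m > 0) & (c > 0) & np.isfinite(m) & np.isfinite(c)
    ratios = pd.Series(np.log2(m[ok] / c[ok]), index=common[ok])

    results = []
    for label, genes in gene_sets.items():
        genes = list(dict.fromkeys(genes))
        missing = [g for g in genes if g not in common]
        if missing:
            log.warning("set %r: %d genes not quantified", label, len(missing))
        in_set = ratios.index.isin(genes)
        vals = ratios[in_set].to_numpy()
        n_excluded = len(genes) - len(missing) - len(vals)
        if len(vals) < min_set_size:
            log.warning("set %r: only %d usable genes; statistics suppressed", label, len(vals))
            results.append(GeneSetShift(label, vals, math.nan, math.nan, math.nan,
                                        len(vals), n_excluded))
            continue
        rest = ratios[~in_set].to_numpy()
        p_t = float(scipy.stats.ttest_1samp(vals, 0.0).pvalue)
        p_mw = (float(scipy.stats.mannwhitneyu(vals, rest).pvalue)
                if len(rest) >= min_set_size else math.nan)
        results.append(GeneSetShift(label, vals, float(np.median(vals)), p_t, p_mw,
                                    len(vals), n_excluded))
    return results


def shifts_frame(shifts: Sequence[GeneSetShift]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.set_label, s.n_genes, s.n_excluded, s.median_log2, s.p_t, s.p_mw) for s in shifts],
        columns=["set", "n_genes", "n_zero_excluded", "median_log2", "p_t", "p_mannwhitney"])


def read_gene_set(path) -> list[str]:
    """Plain-text gene list, one id per line, '#' comments allowed."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
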