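"""Synthetic ribosome-footprint and RNA-seq generator.

The generator is the statistical inverse of the analysis: per-gene transcript
abundances follow a log-normal law; ribosome positions are drawn per
nucleotide with a dwell weight of 1 everywhere except at the first nt of
codons carrying a dwell enrichment; each footprint's 3' end is placed
``asite_offset`` nt downstream of the sampled A-site first nt, with the read
length drawn independently (3'-end anchoring).  Optional switches add
post-lysis run-on blurring (a geometric number of extra codons translated
after lysis) and ribosome-collision reads one footprint length (~25 nt,
±2 nt jitter) upstream of paused positions.  RNA-seq reads are uniform within
each transcript; an attenuated operon scales the downstream gene's abundance
by a read-through probability.

Named scenario presets encode the strain conditions of a TrmD-depletion
(m¹G37-deficiency) experiment as *target* recovered pause scores per codon
family and *target* leader→downstream fold-decreases.  Because a pause score
is internally normalized by the gene mean, the dwell factor that yields a
target score s at a codon with k interior occurrences in a gene of L interior
nt is not s itself: the factors solve the coupled system
``s_t = f_t · L / (L + Σ_u k_u (f_u − 1))``, giving
``f_t = s_t (L − Σk) / (L − Σ k_u s_u)`` per gene.  With that correction the
expected recovered score equals the target exactly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq

from .expression import Region
from .genome import ORFRecord, SENSE_CODONS, Transcriptome, normalize_codon
from .tracks import READ_COLUMNS

log = logging.getLogger(__name__)

REFERENCE_NAME = "chrSim"
PADDING = 200          # nt of intergenic sequence flanking every ORF
STOPS = ("TAA", "TGA", "TAG")


@dataclass
class AttenuationSpec:
    """A two-gene attenuated operon: a short leader ORF and a downstream
    biosynthetic gene whose abundance is leader × readthrough."""

    leader_id: str = "leuL"
    downstream_id: str = "leuA"
    leader_codons: int = 29        # leuL: 28 aa + stop = 87 nt
    downstream_codons: int = 524   # leuA: 1572 nt
    readthrough: float = 1.0 / 29.0
    downstream_window: str = "full"   # "full" (leu geometry) or "half5" (ilv)
    leader_log_expression: float = 3.0  # ln-scale offset above the expression law mean


@dataclass
class ScenarioConfig:
    """Full parameterization of the generator; ``seed`` determines all output."""

    n_genes: int = 200
    orf_length_codons: Tuple[int, int] = (100, 500)   # uniform, incl. start+stop
    codon_usage: Optional[Dict[str, float]] = None    # default: uniform over 61
    expression_mu: float = 0.0      # log-normal (ln-scale) transcript abundance
    expression_sigma: float = 1.0
    dwell_enrichment: Dict[str, float] = field(default_factory=dict)  # target pause scores
    read_length: Tuple[int, int] = (10, 40)           # uniform footprint lengths
    rnaseq_read_length: int = 50
    asite_offset: int = 15
    runon_blur: Optional[float] = None  # geometric continuation probability, or None
    collision_prob: float = 0.0
    attenuation: Optional[AttenuationSpec] = None
    depth: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        self.dwell_enrichment = {normalize_codon(k): float(v)
                                 for k, v in self.dwell_enrichment.items()}
        if self.codon_usage is not None:
            usage = {normalize_codon(k): float(v) for k, v in self.codon_usage.items()}
            total = sum(usage.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"codon_usage sums to {total}, expected 1")
            if any(v < 0 for v in usage.values()):
                raise ValueError("codon_usage probabilities must be non-negative")
            if set(usage) - set(SENSE_CODONS):
                raise ValueError("codon_usage may only name sense codons")
            self.codon_usage = usage
        lo, hi = self.orf_length_codons
        if lo < 16 or hi < lo:
            raise ValueError("orf_length_codons must satisfy 16 <= min <= max")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


# --- scenario presets -------------------------------------------------------
# One versioned table holds every preset's targets; the closed-form k-correction
# in _dwell_factors turns targets into per-gene dwell factors at simulation time.

PRESET_TABLE_VERSION = 1

#: Target mean A-site pause scores per codon family (DNA alphabet).
PAUSE_TARGETS: Dict[str, Dict[str, float]] = {
    "uniform": {},
    "trmD_cont": {"CCA": 1.4, "CCC": 1.4, "CCG": 1.4, "CCT": 1.4, "CGG": 1.0, "CTA": 1.0},
    "trmD_deg": {"CCA": 3.5, "CCC": 3.5, "CCG": 3.5, "CCT": 3.5, "CGG": 3.0, "CTA": 1.4},
    "trmD_WT_trm5minus": {"CCA": 1.2, "CCC": 1.2, "CCG": 1.2, "CCT": 1.2, "CGG": 1.0, "CTA": 1.0},
    "trmD_KO_trm5minus": {"CCA": 2.5, "CCC": 2.5, "CCG": 2.5, "CCT": 2.5, "CGG": 3.0, "CTA": 1.4},
}

#: Footprint length windows: high-Mg²⁺ arrest libraries resolve only 24–40 nt.
READ_LENGTH_LAWS: Dict[str, Tuple[int, int]] = {
    "uniform": (10, 40),
    "trmD_cont": (10, 40),
    "trmD_deg": (10, 40),
    "trmD_WT_trm5minus": (24, 40),
    "trmD_KO_trm5minus": (24, 40),
}

#: Target leader→downstream RNA-density fold-decreases per operon geometry.
ATTENUATION_TARGETS: Dict[Tuple[str, str], float] = {
    ("attenuation_control", "leuL"): 29.0,
    ("attenuation_deg", "leuL"): 4.0,
    ("attenuation_control", "ilvL"): 45.0,
    ("attenuation_deg", "ilvL"): 9.0,
}

ATTENUATION_GEOMETRIES: Dict[str, dict] = {
    # leu: leader compared with the whole first structural gene
    "leuL": dict(leader_id="leuL", downstream_id="leuA", leader_codons=29,
                 downstream_codons=524, downstream_window="full"),
    # ilv: leader compared with the 5' half of the downstream gene
    "ilvL": dict(leader_id="ilvL", downstream_id="ilvG", leader_codons=33,
                 downstream_codons=548, downstream_window="half5"),
}

PRESETS = tuple(PAUSE_TARGETS) + ("attenuation_control", "attenuation_deg")


def preset(name: str, geometry: str = "leuL", **overrides) -> ScenarioConfig:
    """Build the ScenarioConfig for a named preset.

    ``geometry`` selects the operon for the attenuation presets ("leuL" or
    "ilvL"); keyword overrides are applied last.
    """
    if name in PAUSE_TARGETS:
        cfg = ScenarioConfig(dwell_enrichment=dict(PAUSE_TARGETS[name]),
                             read_length=READ_LENGTH_LAWS[name])
    elif name in {"attenuation_control", "attenuation_deg"}:
        if geometry not in ATTENUATION_GEOMETRIES:
            raise ValueError(f"unknown operon geometry {geometry!r}")
        fold = ATTENUATION_TARGETS[(name, geometry)]
        spec = AttenuationSpec(readthrough=1.0 / fold, **ATTENUATION_GEOMETRIES[geometry])
        cfg = ScenarioConfig(n_genes=20, attenuation=spec)
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    return replace(cfg, **overrides) if overrides else cfg


# --- transcriptome ----------------------------------------------------------

def _rng(cfg: ScenarioConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed) % (2**31), stream])


def _draw_codons(rng: np.random.Generator, n: int, usage: Optional[Dict[str, float]]) -> list[str]:
    codons = np.array(SENSE_CODONS)
    if usage is None:
        p = None
    else:
        p = np.array([usage.get(c, 0.0) for c in SENSE_CODONS])
    return list(rng.choice(codons, size=n, p=p))


def simulate_transcriptome(cfg: ScenarioConfig) -> Tuple[Transcriptome, Dict[str, str]]:
    """Generate ORFs laid head-to-tail (alternating strands) on one reference.

    Returns the transcriptome and the genome as {ref_name: sequence}.  With an
    attenuation spec the operon's two genes are appended on the + strand after
    the background genes.
    """
    rng = _rng(cfg, 0)
    lo, hi = cfg.orf_length_codons
    plan: list[Tuple[str, int, str]] = []  # (gene_id, n_codons, strand)
    for i in range(cfg.n_genes):
        n = int(rng.integers(lo, hi + 1))
        plan.append((f"g{i:04d}", n, "+" if i % 2 == 0 else "-"))
    if cfg.attenuation is not None:
        att = cfg.attenuation
        plan.append((att.leader_id, att.leader_codons, "+"))
        plan.append((att.downstream_id, att.downstream_codons, "+"))

    orfs: Dict[str, ORFRecord] = {}
    chunks: list[str] = []
    cursor = 0

    def _gap(n: int) -> None:
        nonlocal cursor
        chunks.append("".join(rng.choice(list("ACGT"), size=n)))
        cursor += n

    _gap(PADDING)
    for gene_id, n_codons, strand in plan:
        body = _draw_codons(rng, n_codons - 2, cfg.codon_usage)
        seq = "ATG" + "".join(body) + str(rng.choice(np.array(STOPS)))
        start, end = cursor, cursor + 3 * n_codons
        genomic = seq if strand == "+" else str(Seq(seq).reverse_complement())
        chunks.append(genomic)
        cursor = end
        orfs[gene_id] = ORFRecord(gene_id, REFERENCE_NAME, strand, start, end, seq)
        _gap(PADDING)

    genome = {REFERENCE_NAME: "".join(chunks)}
    tx = Transcriptome(orfs=orfs, ref_lengths={REFERENCE_NAME: cursor})
    tx.validate()
    return tx, genome


def write_reference(transcriptome: Transcriptome, genome: Mapping[str, str],
                    fasta_path, bed_path) -> None:
    with open(fasta_path, "w") as fh:
        for ref, seq in genome.items():
            fh.write(f">{ref}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    with open(bed_path, "w") as fh:
        for orf in transcriptome:
            fh.write(f"{orf.ref_name}\t{orf.start}\t{orf.end}\t{orf.gene_id}\t0\t{orf.strand}\n")


# --- footprints -------------------------------------------------------------

def _dwell_factors(orf: ORFRecord, targets: Mapping[str, float],
                   trim_codons: int = 7) -> Dict[str, float]:
    """Per-gene dwell factors whose expected recovered pause scores equal the
    targets (closed-form correction; see module docstring)."""
    if not targets:
        return {}
    n = orf.n_codons
    L = 3 * (n - 2 * trim_codons)
    if L <= 0:
        return {}
    counts = {t: 0 for t in targets}
    for i in range(trim_codons, n - trim_codons):
        t = orf.codon(i)
        if t in counts:
            counts[t] += 1
    sum_k = sum(counts.values())
    sum_ks = sum(counts[t] * targets[t] for t in counts)
    if L - sum_ks <= 0:
        raise ValueError(f"{orf.gene_id}: targets infeasible (L={L}, sum k*s={sum_ks})")
    scale = (L - sum_k) / (L - sum_ks)
    return {t: targets[t] * scale for t in targets}


def _gene_dwell(orf: ORFRecord, factors: Mapping[str, float]) -> np.ndarray:
    w = np.ones(3 * orf.n_codons)
    if factors:
        for i in range(orf.n_codons):
            f = factors.get(orf.codon(i))
            if f is not None:
                w[3 * i] = f
    return w


def _expression(cfg: ScenarioConfig, transcriptome: Transcriptome) -> Dict[str, float]:
    # dedicated stream so footprints and RNA-seq share one abundance vector
    rng = _rng(cfg, 3)
    expr: Dict[str, float] = {}
    for orf in transcriptome:
        expr[orf.gene_id] = float(rng.lognormal(cfg.expression_mu, cfg.expression_sigma))
    if cfg.attenuation is not None:
        att = cfg.attenuation
        leader = float(np.exp(cfg.expression_mu + att.leader_log_expression))
        expr[att.leader_id] = leader
        expr[att.downstream_id] = leader * att.readthrough
    return expr


def simulate_footprints(transcriptome: Transcriptome, cfg: ScenarioConfig) -> pd.DataFrame:
    """Draw ``cfg.depth`` footprints; returns a read table (tracks.READ_COLUMNS).

    Genes are sampled proportional to expression × total dwell; A-site first
    nts proportional to per-nt dwell.  Collision reads (if enabled) are extra
    reads on top of the configured depth.
    """
    rng = _rng(cfg, 1)
    orfs = list(transcriptome)
    expr = _expression(cfg, transcriptome)

    weights, starts, gene_of = [], [], []
    dwells = []
    offset = 0
    for gi, orf in enumerate(orfs):
        factors = _dwell_factors(orf, cfg.dwell_enrichment)
        w = _gene_dwell(orf, factors)
        dwells.append(w)
        weights.append(w * expr[orf.gene_id])
        starts.append(offset)
        offset += len(w)
    p = np.concatenate(weights)
    p /= p.sum()
    counts = rng.multinomial(cfg.depth, p)
    flat = np.repeat(np.arange(len(p)), counts)

    gene_starts = np.array(starts + [offset])
    gi = np.searchsorted(gene_starts, flat, side="right") - 1
    x = flat - gene_starts[gi]  # coding-space nt position of the A-site first nt

    n_codons = np.array([o.n_codons for o in orfs])
    if cfg.runon_blur is not None:
        pcont = float(cfg.runon_blur)
        if not 0 <= pcont < 1:
            raise ValueError("runon_blur must be a probability in [0, 1)")
        extra = rng.geometric(1 - pcont, size=len(x)) - 1
        x = x + 3 * extra
        keep = x < 3 * n_codons[gi]
        x, gi = x[keep], gi[keep]

    if cfg.collision_prob > 0:
        paused = np.zeros(len(x), dtype=bool)
        for j, w in enumerate(dwells):
            sel = gi == j
            paused[sel] = w[x[sel]] > 1.0
        hit = paused & (rng.random(len(x)) < cfg.collision_prob)
        xc = x[hit] - 25 + rng.integers(-2, 3, size=int(hit.sum()))
        gc = gi[hit]
        ok = xc >= 0
        x = np.concatenate([x, xc[ok]])
        gi = np.concatenate([gi, gc[ok]])

    o_start = np.array([o.start for o in orfs])
    o_end = np.array([o.end for o in orfs])
    plus = np.array([o.strand == "+" for o in orfs])[gi]
    g = np.where(plus, o_start[gi] + x, o_end[gi] - 1 - x)
    three = np.where(plus, g + cfg.asite_offset, g - cfg.asite_offset)
    lmin, lmax = cfg.read_length
    length = rng.integers(lmin, lmax + 1, size=len(g))
    five = np.where(plus, three - (length - 1), three + (length - 1))

    return pd.DataFrame({
        "ref": np.array([o.ref_name for o in orfs])[gi],
        "strand": np.where(plus, "+", "-"),
        "five_prime": five.astype(np.int64),
        "length": length.astype(np.int64),
    }, columns=READ_COLUMNS)


def simulate_rnaseq(transcriptome: Transcriptome, cfg: ScenarioConfig) -> pd.DataFrame:
    """Draw RNA-seq reads with 3' ends uniform within each transcript,
    genes sampled proportional to abundance × length."""
    rng = _rng(cfg, 2)
    orfs = list(transcriptome)
    expr = _expression(cfg, transcriptome)
    lengths = np.array([3 * o.n_codons for o in orfs], dtype=float)
    w = np.array([expr[o.gene_id] for o in orfs]) * lengths
    counts = rng.multinomial(cfg.depth, w / w.sum())

    frames = []
    for orf, n in zip(orfs, counts):
        if n == 0:
            continue
        x = rng.integers(0, 3 * orf.n_codons, size=n)
        if orf.strand == "+":
            three = orf.start + x
        else:
            three = orf.end - 1 - x
        length = np.full(n, cfg.rnaseq_read_length, dtype=np.int64)
        five = np.where(orf.strand == "+", three - (length - 1), three + (length - 1))
        frames.append(pd.DataFrame({"ref": orf.ref_name, "strand": orf.strand,
                                    "five_prime": five.astype(np.int64), "length": length},
                                   columns=READ_COLUMNS))
    return pd.concat(frames, ignore_index=True)


def attenuation_regions(transcriptome: Transcriptome,
                        spec: AttenuationSpec) -> Tuple[Region, Region]:
    """Default leader/downstream regions: the leader ORF and either the full
    downstream ORF (leu geometry) or its 5' half (ilv geometry)."""
    leader = transcriptome[spec.leader_id]
    down = transcriptome[spec.downstream_id]
    leader_region = Region(leader.ref_name, leader.strand, leader.start, leader.end)
    if spec.downstream_window == "full":
        down_region = Region(down.ref_name, down.strand, down.start, down.end)
    elif spec.downstream_window == "half5":
        half = (down.end - down.start) // 2
        if down.strand == "+":
            down_region = Region(down.ref_name, down.strand, down.start, down.start + half)
        else:
            down_region = Region(down.ref_name, down.strand, down.end - half, down.end)
    else:
        raise ValueError(f"unknown downstream_window {spec.downstream_window!r}")
    return leader_region, down_region


def write_reads_tsv(reads: pd.DataFrame, path) -> None:
    reads.to_csv(path, sep="\t", header=False, index=False)


def write_scenario(cfg: ScenarioConfig, path) -> None:
    doc = cfg.to_dict()
    doc["preset_table_version"] = PRESET_TABLE_VERSION
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
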