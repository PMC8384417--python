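"""Reference sequences, ORF annotations, and codon-level coordinate arithmetic.

A bacterial transcriptome is modeled as a set of single-exon protein-coding
regions (ORFs) on one or more reference sequences.  Coordinates are 0-based,
half-open throughout the package; the WIG writer converts to 1-based on
output.  Sequences are stored on the coding strand using the DNA alphabet
(``U`` is normalized to ``T`` at load time); codon selectors elsewhere in the
package accept either alphabet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, Mapping, Optional, Set

import pyranges as pr
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

#: NCBI translation table 11 (bacterial); maps the 61 sense codons to amino acids.
CODON_TABLE = CodonTable.unambiguous_dna_by_id[11]
STOP_CODONS = frozenset(CODON_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(CODON_TABLE.forward_table))

_ONE_TO_THREE = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}


def normalize_codon(triplet: str) -> str:
    """Return the canonical DNA form of a codon given in DNA or RNA alphabet."""
    t = triplet.strip().upper().replace("U", "T")
    if len(t) != 3 or any(b not in "ACGT" for b in t):
        raise ValueError(f"not a codon: {triplet!r}")
    return t


def amino_acid(triplet: str) -> Optional[str]:
    """Three-letter amino acid for a sense codon, or None for a stop codon."""
    t = normalize_codon(triplet)
    if t in STOP_CODONS:
        return None
    return _ONE_TO_THREE[CODON_TABLE.forward_table[t]]


@dataclass(frozen=True)
class ORFRecord:
    """A protein-coding region: the unit over which densities and pause
    scores are computed.

    ``sequence`` is the coding-strand nucleotide sequence from the start
    codon through the stop codon; codon ``i`` occupies coding-strand offsets
    ``[3i, 3i+3)``.
    """

    gene_id: str
    ref_name: str
    strand: str
    start: int  # 0-based inclusive genomic coordinate
    end: int    # exclusive
    sequence: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if self.end - self.start != len(seq):
            raise ValueError(f"{self.gene_id}: span {self.end - self.start} != sequence length {len(seq)}")
        if len(seq) % 3 != 0 or len(seq) < 9:
            raise ValueError(f"{self.gene_id}: length {len(seq)} nt is not >= 3 codons and a multiple of 3")
        if any(b not in "ACGT" for b in seq):
            raise ValueError(f"{self.gene_id}: non-ACGT characters in sequence")

    @property
    def n_codons(self) -> int:
        return len(self.sequence) // 3

    def codon(self, codon_index: int) -> str:
        self._check_index(codon_index)
        return self.sequence[3 * codon_index: 3 * codon_index + 3]

    def codon_first_nt(self, codon_index: int) -> int:
        """Genomic coordinate of the first (5'-most in coding sense) nt of a codon."""
        self._check_index(codon_index)
        if self.strand == "+":
            return self.start + 3 * codon_index
        return self.end - 1 - 3 * codon_index

    def genomic_to_codon(self, position: int) -> tuple[int, int]:
        """Inverse of codon coordinates: (codon_index, offset within codon)."""
        if not self.start <= position < self.end:
            raise ValueError(f"{self.gene_id}: position {position} outside [{self.start}, {self.end})")
        x = position - self.start if self.strand == "+" else self.end - 1 - position
        return x // 3, x % 3

    def _check_index(self, codon_index: int) -> None:
        if not 0 <= codon_index < self.n_codons:
            raise IndexError(f"{self.gene_id}: codon index {codon_index} out of range [0, {self.n_codons})")


@dataclass
class Transcriptome:
    """ORFs keyed by gene_id plus reference lengths; overlapping ORFs are
    permitted but flagged in ``overlapping``."""

    orfs: Dict[str, ORFRecord]
    ref_lengths: Dict[str, int]
    overlapping: Set[str] = field(default_factory=set)

    def __iter__(self) -> Iterator[ORFRecord]:
        return iter(self.orfs.values())

    def __len__(self) -> int:
        return len(self.orfs)

    def __getitem__(self, gene_id: str) -> ORFRecord:
        return self.orfs[gene_id]

    def validate(self) -> None:
        for orf in self:
            if orf.ref_name not in self.ref_lengths:
                raise ValueError(f"{orf.gene_id}: unknown reference {orf.ref_name!r}")
            if not (0 <= orf.start < orf.end <= self.ref_lengths[orf.ref_name]):
                raise ValueError(f"{orf.gene_id}: [{orf.start}, {orf.end}) outside reference")


def _flag_overlaps(orfs: Mapping[str, ORFRecord]) -> Set[str]:
    trees: Dict[str, IntervalTree] = {}
    for orf in orfs.values():
        trees.setdefault(orf.ref_name, IntervalTree()).addi(orf.start, orf.end, orf.gene_id)
    flagged: Set[str] = set()
    for orf in orfs.values():
        hits = trees[orf.ref_name].overlap(orf.start, orf.end)
        if len(hits) > 1:
            flagged.add(orf.gene_id)
    return flagged


def _annotation_frame(path: Path):
    suffix = path.suffix.lower()
    if suffix in {".bed", ".bed6", ".bed12"}:
        df = pr.read_bed(str(path)).df
        if "Name" not in df.columns:
            raise ValueError(f"{path}: BED file needs at least 4 columns (name required)")
        return df[["Chromosome", "Start", "End", "Name", "Strand"]]
    if suffix in {".gff", ".gff3"}:
        df = pr.read_gff3(str(path)).df
        df = df[df.Feature == "CDS"].copy()
        if df.empty:
            raise ValueError(f"{path}: no CDS features found")
        name_col = "gene_id" if "gene_id" in df.columns else "ID"
        df = df.rename(columns={name_col: "Name"})
        return df[["Chromosome", "Start", "End", "Name", "Strand"]]
    raise ValueError(f"{path}: unrecognized annotation format (use .bed or .gff3)")


def load_annotation(annotation_file: str | Path, fasta_file: str | Path) -> Transcriptome:
    """Load an ORF annotation (BED6/BED12 or GFF3 CDS) against reference FASTA.

    ORFs violating the coding-region invariants (length not a multiple of 3,
    fewer than 3 codons, undeclared strand) are dropped with a warning; a
    reference named in the annotation but missing from the FASTA is fatal.
    """
    annotation_file, fasta_file = Path(annotation_file), Path(fasta_file)
    refs = {rec.id: str(rec.seq).upper().replace("U", "T")
            for rec in SeqIO.parse(str(fasta_file), "fasta")}
    if not refs:
        raise ValueError(f"{fasta_file}: no FASTA records")
    df = _annotation_frame(annotation_file)

    orfs: Dict[str, ORFRecord] = {}
    n_dropped = 0
    for row in df.itertuples(index=False):
        ref, start, end = str(row.Chromosome), int(row.Start), int(row.End)
        name, strand = str(row.Name), str(row.Strand)
        if ref not in refs:
            raise ValueError(f"{annotation_file}: reference {ref!r} missing from {fasta_file}")
        if strand not in "+-":
            log.warning("dropping %s: undeclared strand %r", name, strand)
            n_dropped += 1
            continue
        if name in orfs:
            raise ValueError(f"{annotation_file}: duplicate gene_id {name!r}")
        genomic = refs[ref][start:end]
        seq = genomic if strand == "+" else str(Seq(genomic).reverse_complement())
        try:
            orfs[name] = ORFRecord(name, ref, strand, start, end, seq)
        except ValueError as exc:
            log.warning("dropping %s: %s", name, exc)
            n_dropped += 1
    log.info("loaded %d ORFs (%d dropped) from %s", len(orfs), n_dropped, annotation_file)

    tx = Transcriptome(orfs=orfs, ref_lengths={r: len(s) for r, s in refs.items()},
                       overlapping=_flag_overlaps(orfs))
    tx.validate()
    return tx
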