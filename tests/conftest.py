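import numpy as np
import pytest

from ribopause import DensityTrack, ORFRecord, Transcriptome


def make_orf(gene_id="geneA", ref="chr1", strand="+", start=30, codons=None, seq=None):
    """Small ORF helper; `codons` is a list of triplets (start/stop added)."""
    if seq is None:
        body = "".join(codons or ["AAA"] * 8)
        seq = "ATG" + body + "TAA"
    return ORFRecord(gene_id, ref, strand, start, start + len(seq), seq)


@pytest.fixture
def toy_transcriptome():
    """Two genes on opposite strands of a 600-nt reference."""
    plus = make_orf("gPlus", strand="+", start=50,
                    codons=["CCG", "AAA", "GGC", "CCG", "TTT", "GCA", "AAA", "CGG",
                            "CTA", "AAA", "CCG", "GAT", "AAA", "TTC", "GGA", "ACG"])
    minus = make_orf("gMinus", strand="-", start=300,
                     codons=["CCG", "GGC", "AAA", "CGG", "TTT", "AAA", "CCG", "GCA",
                             "AAA", "CTA", "GAT", "AAA", "TTC", "AAA", "GGA", "ACG"])
    tx = Transcriptome(orfs={o.gene_id: o for o in (plus, minus)},
                       ref_lengths={"chr1": 600})
    tx.validate()
    return tx


def uniform_track(tx, value=2.0, units="raw"):
    """Track with constant per-nt density over every ORF (zero elsewhere)."""
    track = DensityTrack(tx.ref_lengths, units=units)
    for orf in tx:
        track.values[(orf.ref_name, orf.strand)][orf.start:orf.end] = value
    track.total_mapped = int(round(track.sum()))
    return track


def genome_string(tx, fill="A"):
    """Reference sequences consistent with the ORFs (minus-strand revcomp)."""
    comp = str.maketrans("ACGT", "TGCA")
    refs = {}
    for ref, length in tx.ref_lengths.items():
        arr = [fill] * length
        for orf in tx:
            if orf.ref_name != ref:
                continue
            genomic = (orf.sequence if orf.strand == "+"
                       else orf.sequence.translate(comp)[::-1])
            arr[orf.start:orf.end] = list(genomic)
        refs[ref] = "".join(arr)
    return refs


def write_reference_files(tx, tmp_path, name="ref"):
    fasta = tmp_path / f"{name}.fa"
    bed = tmp_path / f"{name}.bed"
    refs = genome_string(tx)
    with open(fasta, "w") as fh:
        for ref, seq in refs.items():
            fh.write(f">{ref}\n{seq}\n")
    with open(bed, "w") as fh:
        for orf in tx:
            fh.write(f"{orf.ref_name}\t{orf.start}\t{orf.end}\t{orf.gene_id}\t0\t{orf.strand}\n")
    return fasta, bed


@pytest.fixture
def rng():
    return np.random.default_rng(170)
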