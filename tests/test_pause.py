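"""A-site pause scores: filters, normalization, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from ribopause import (CodonInstance, DensityTrack, collect_instances,
                       gene_mean_density, gene_passes_filter,
                       instance_pause_score, pause_scores, shift_to_asite)
from ribopause.genome import STOP_CODONS

from conftest import make_orf, uniform_track


def brute_force_pause_table(track, tx, offset, trim, min_density):
    """Independent per-codon recomputation straight from genomic coordinates.

    Avoids shift_to_asite and coding_profile entirely: the A-site density of
    a coding-strand position g is looked up at the raw 3'-end position
    g + offset (plus strand) or g − offset (minus strand).
    """
    def asite_density(orf, g):
        vec = track.values[(orf.ref_name, orf.strand)]
        p = g + offset if orf.strand == "+" else g - offset
        return vec[p] if 0 <= p < len(vec) else 0.0

    out = {}
    for orf in tx:
        coding = [orf.codon_first_nt(i // 3) + (1 if orf.strand == "+" else -1) * (i % 3)
                  for i in range(3 * orf.n_codons)]
        total = sum(asite_density(orf, g) for g in coding)
        if not total / orf.n_codons > min_density:
            continue
        interior = coding[3 * trim: len(coding) - 3 * trim]
        mean = sum(asite_density(orf, g) for g in interior) / len(interior)
        if mean <= 0:
            continue
        for i in range(trim, orf.n_codons - trim):
            t = orf.codon(i)
            if t in STOP_CODONS:
                continue
            s = asite_density(orf, orf.codon_first_nt(i)) / mean
            out.setdefault(t, []).append(s)
    return {t: (float(np.mean(v)), len(v)) for t, v in out.items()}


class TestShiftToAsite:
    def test_zero_offset_identity(self, toy_transcriptome):
        track = uniform_track(toy_transcriptome)
        shifted = shift_to_asite(track, 0)
        for key in track.values:
            np.testing.assert_array_equal(shifted.values[key], track.values[key])

    def test_plus_strand_shift_arithmetic(self):
        track = DensityTrack({"chr1": 200})
        track.values[("chr1", "+")][115] = 4
        shifted = shift_to_asite(track, 15)
        assert shifted.values[("chr1", "+")][100] == 4

    def test_minus_strand_shift_arithmetic(self):
        track = DensityTrack({"chr1": 200})
        track.values[("chr1", "-")][100] = 4
        shifted = shift_to_asite(track, 15)
        assert shifted.values[("chr1", "-")][115] == 4

    def test_interior_counts_conserved(self, rng):
        track = DensityTrack({"chr1": 300})
        track.values[("chr1", "+")][50:250] = rng.poisson(3, 200)
        total = track.sum()
        assert shift_to_asite(track, 15).sum() == total


class TestGeneMeanAndFilter:
    def test_uniform_density_mean(self, toy_transcriptome):
        track = uniform_track(toy_transcriptome, value=2.0)
        for orf in toy_transcriptome:
            assert gene_mean_density(track, orf, trim_codons=0) == 2.0
            assert gene_mean_density(track, orf, trim_codons=3) == 2.0

    def test_trimmed_mean_spec_example(self):
        # 30-codon ORF, 60 reads all inside codon 10, trim 7 -> 60 / 48 nt
        orf = make_orf(strand="+", start=0, codons=["GCA"] * 28)
        track = DensityTrack({"chr1": 200})
        track.values[("chr1", "+")][30:33] = [20, 20, 20]
        assert gene_mean_density(track, orf, trim_codons=7) == pytest.approx(60 / 48)

    def test_empty_track_mean_is_zero(self):
        orf = make_orf(strand="+", start=0, codons=["GCA"] * 28)
        assert gene_mean_density(DensityTrack({"chr1": 200}), orf) == 0.0

    def test_no_interior_after_trim_errors(self):
        orf = make_orf(codons=["GCA"] * 8)  # 10 codons
        with pytest.raises(ValueError, match="interior"):
            gene_mean_density(DensityTrack({"chr1": 600}), orf, trim_codons=5)

    @pytest.mark.parametrize("reads,included", [(5, False), (6, False), (7, True)])
    def test_coverage_threshold_is_strict(self, reads, included):
        # 60-codon gene: 6 reads is exactly 0.1/codon and must be excluded
        orf = make_orf(strand="+", start=0, codons=["GCA"] * 58)
        track = DensityTrack({"chr1": 300})
        track.values[("chr1", "+")][30] = reads
        assert gene_passes_filter(track, orf, 0.1) is included


class TestInstanceScore:
    def test_score_arithmetic(self):
        orf = make_orf(strand="+", start=0, codons=["CCG"] + ["GCA"] * 27)
        track = DensityTrack({"chr1": 200})
        inst = collect_instances(orf, trim_codons=0, codons=["CCG"])[0]
        track.values[("chr1", "+")][inst.first_nt] = 10
        assert instance_pause_score(track, inst, gene_mean=2.0) == 5.0
        track.values[("chr1", "+")][inst.first_nt] = 0
        assert instance_pause_score(track, inst, gene_mean=2.0) == 0.0

    def test_edge_codons_excluded_from_instances(self):
        orf = make_orf(codons=["CCG"] * 28)  # 30 codons
        instances = collect_instances(orf, trim_codons=7)
        indices = {i.codon_index for i in instances}
        assert indices == set(range(7, 23))

    def test_stop_codons_never_instances(self):
        orf = make_orf(codons=["TAA" if i % 2 else "GCA" for i in range(20)])
        assert all(i.triplet not in STOP_CODONS
                   for i in collect_instances(orf, trim_codons=0))


class TestPauseTable:
    def test_uniform_track_scores_exactly_one(self, toy_transcriptome):
        track = uniform_track(toy_transcriptome, value=3.0)
        table = pause_scores(track, toy_transcriptome, asite_offset=0,
                             trim_codons=2, min_reads_per_codon=0.1, shifted=True)
        for stats in table.per_codon.values():
            np.testing.assert_array_equal(stats.instance_scores, 1.0)

    @settings(derandomize=True, max_examples=25,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(c=st.floats(min_value=1e-3, max_value=1e3, allow_nan=False))
    def test_scale_invariance(self, toy_transcriptome, rng, c):
        track = DensityTrack(toy_transcriptome.ref_lengths)
        for orf in toy_transcriptome:
            track.values[(orf.ref_name, orf.strand)][orf.start:orf.end] = \
                rng.poisson(5, orf.end - orf.start) + 1.0
        base = pause_scores(track, toy_transcriptome, asite_offset=0,
                            trim_codons=2, min_reads_per_codon=0.0, shifted=True)
        scaled_track = track.copy()
        for key in scaled_track.values:
            scaled_track.values[key] *= c
        scaled = pause_scores(scaled_track, toy_transcriptome, asite_offset=0,
                              trim_codons=2, min_reads_per_codon=0.0, shifted=True)
        for t in base.per_codon:
            np.testing.assert_allclose(scaled.per_codon[t].instance_scores,
                                       base.per_codon[t].instance_scores, rtol=1e-9)

    def test_equals_brute_force_on_toy_transcriptome(self, toy_transcriptome, rng):
        offset = 5
        track = DensityTrack(toy_transcriptome.ref_lengths)
        for key in track.values:
            track.values[key][:] = rng.poisson(4, 600)
        table = pause_scores(track, toy_transcriptome, asite_offset=offset,
                             trim_codons=2, min_reads_per_codon=0.1)
        oracle = brute_force_pause_table(track, toy_transcriptome, offset,
                                         trim=2, min_density=0.1)
        assert set(table.per_codon) == set(oracle)
        for t, (mean, n) in oracle.items():
            assert table.per_codon[t].n_instances == n
            assert table.per_codon[t].mean_score == pytest.approx(mean)

    def test_mean_is_mean_of_instances(self, toy_transcriptome, rng):
        track = DensityTrack(toy_transcriptome.ref_lengths)
        for key in track.values:
            track.values[key][:] = rng.poisson(4, 600)
        table = pause_scores(track, toy_transcriptome, asite_offset=0,
                             trim_codons=2, shifted=True)
        for stats in table.per_codon.values():
            assert stats.mean_score == pytest.approx(float(stats.instance_scores.mean()))
            assert stats.n_instances == len(stats.instance_scores) > 0

    def test_amino_acid_groups_pool_instances(self, toy_transcriptome, rng):
        track = DensityTrack(toy_transcriptome.ref_lengths)
        for key in track.values:
            track.values[key][:] = rng.poisson(4, 600)
        table = pause_scores(track, toy_transcriptome, asite_offset=0,
                             trim_codons=2, shifted=True)
        from ribopause import amino_acid
        pro = np.concatenate([table.per_codon[t].instance_scores
                              for t in table.per_codon if amino_acid(t) == "Pro"])
        assert table.per_amino_acid["Pro"].n_instances == len(pro)
        assert table.per_amino_acid["Pro"].mean_score == pytest.approx(float(pro.mean()))
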