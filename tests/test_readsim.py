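"""Read simulation: allocation, in-silico PCR, pairing, errors, FASTQ."""

import numpy as np
import pytest

from vmbench._errors import InvalidParameterError, VmbenchError
from vmbench.readsim import (
    PrimerPair,
    ReadSimConfig,
    V3V4_PRIMERS,
    _draw_error_positions,
    _error_probabilities,
    allocate_reads,
    apply_poly4_errors,
    in_silico_pcr,
    make_pair,
    read_fastq,
    redistribute_failed,
    reverse_complement,
    sample_fragment,
    simulate_reads,
    write_fastq,
)
from vmbench.refdb import SeqRecord


class TestAllocate:
    def test_single_species_takes_all(self):
        assert allocate_reads(np.array([1.0]), 100_000).tolist() == [100_000]

    def test_even_split(self):
        assert allocate_reads(np.array([0.5, 0.5]), 10).tolist() == [5, 5]

    def test_largest_remainder_by_hand(self):
        # quotas 6.1, 2.6, 1.3 -> floors (6,2,1), one leftover to largest
        # remainder 0.6
        assert allocate_reads(np.array([0.61, 0.26, 0.13]), 10).tolist() == [6, 3, 1]

    def test_total_conserved(self, rng):
        ab = rng.dirichlet(np.ones(77))
        assert allocate_reads(ab, 12_345).sum() == 12_345

    def test_multinomial_needs_rng_and_conserves(self, rng):
        ab = np.array([0.9, 0.1])
        with pytest.raises(InvalidParameterError):
            allocate_reads(ab, 10, method="multinomial")
        assert allocate_reads(ab, 1000, method="multinomial", rng=rng).sum() == 1000

    def test_empty_vector_rejected(self):
        with pytest.raises(InvalidParameterError):
            allocate_reads(np.array([]), 10)


def _gene_with_sites(fwd_at=10, var_len=430, rng_seed=0):
    """Random gene with concrete V3V4 primer sites at known coordinates."""
    rng = np.random.default_rng(rng_seed)
    bases = "ACGT"
    fwd = "CCTACGGGAGGCAGCAG"  # concrete realization of the forward primer
    rev_rc = reverse_complement("GGACTACAGGGGTATCTAATCC")  # concrete reverse
    head = "".join(bases[i] for i in rng.integers(0, 4, fwd_at))
    var = "".join(bases[i] for i in rng.integers(0, 4, var_len))
    tail = "".join(bases[i] for i in rng.integers(0, 4, 200))
    seq = head + fwd + var + rev_rc + tail
    end = fwd_at + len(fwd) + var_len + len(rev_rc)
    return seq, (fwd_at, end)


class TestInSilicoPCR:
    def test_finds_designed_interval(self):
        seq, interval = _gene_with_sites()
        assert in_silico_pcr(seq, V3V4_PRIMERS) == interval

    def test_missing_forward_site_fails(self):
        rng = np.random.default_rng(1)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 600))
        assert in_silico_pcr(seq, V3V4_PRIMERS) is None

    def test_primer_n_matches_any_base(self):
        # forward primer position 8 is N: every base there must amplify
        for base in "ACGT":
            fwd = "CCTACGGG" + base + "GGCAGCAG"
            seq = "TTTT" + fwd + "A" * 100 + reverse_complement(
                "GGACTACAGGGGTATCTAATCC") + "TTTT"
            assert in_silico_pcr(seq, V3V4_PRIMERS) is not None

    def test_mismatch_tolerance(self):
        seq, _ = _gene_with_sites()
        broken = seq[:12] + ("A" if seq[12] != "A" else "G") + seq[13:]
        assert in_silico_pcr(broken, V3V4_PRIMERS, max_mismatches=0) is None
        assert in_silico_pcr(broken, V3V4_PRIMERS, max_mismatches=1) is not None


class TestRedistribute:
    def test_all_amplifiable_identity(self):
        counts = np.array([60, 40])
        out = redistribute_failed(counts, np.array([0.6, 0.4]),
                                  np.array([True, True]))
        assert out.tolist() == [60, 40]

    def test_single_recipient(self):
        out = redistribute_failed(np.array([60, 40]), np.array([0.6, 0.4]),
                                  np.array([True, False]))
        assert out.tolist() == [100, 0]

    def test_proportional_split_by_hand(self):
        # 20 failed reads split 5/8 vs 3/8 over abundances (0.5, 0.3):
        # quotas 62.5 and 37.5, largest-remainder tie -> lower index
        out = redistribute_failed(np.array([50, 30, 20]),
                                  np.array([0.5, 0.3, 0.2]),
                                  np.array([True, True, False]))
        assert out.tolist() == [63, 37, 0]

    def test_no_amplifiable_species_is_error(self):
        with pytest.raises(VmbenchError):
            redistribute_failed(np.array([10]), np.array([1.0]),
                                np.array([False]))

    def test_total_conserved(self, rng):
        counts = rng.integers(0, 50, 30)
        ab = rng.dirichlet(np.ones(30))
        ok = rng.random(30) > 0.3
        ok[0] = True
        out = redistribute_failed(counts, ab, ok)
        assert out.sum() == counts.sum()
        assert (out[~ok] == 0).all()


def _record(seq):
    return SeqRecord("rec0", seq, "16S", "spX", "geX", "faX")


class TestFragments:
    def test_zero_sd_insert_covers_whole_region(self, rng):
        config = ReadSimConfig.amplicon(insert_mean=100, insert_sd=0,
                                        read_length=50)
        rec = _record("A" * 100)
        start, end, strand = sample_fragment(rec, config, (0, 100), rng)
        assert (start, end, strand) == (0, 100, "+")

    def test_unidirectional_is_all_forward(self, rng):
        config = ReadSimConfig.amplicon(insert_mean=60, insert_sd=10,
                                        read_length=40)
        rec = _record("ACGT" * 50)
        strands = {sample_fragment(rec, config, None, rng)[2]
                   for _ in range(50)}
        assert strands == {"+"}

    def test_insert_clamped_to_region(self, rng):
        config = ReadSimConfig.amplicon(insert_mean=700, insert_sd=0,
                                        read_length=300)
        rec = _record("A" * 480)
        start, end, _ = sample_fragment(rec, config, (0, 480), rng)
        assert end - start == 480

    def test_mate_overlap_at_design_point(self):
        frag = "".join("ACGT"[i] for i in
                       np.random.default_rng(2).integers(0, 4, 550))
        config = ReadSimConfig.amplicon()
        m1, m2 = make_pair(frag, config)
        assert len(m1) == len(m2) == 300
        # 2*300 - 550 = 50 bp overlap: mate1's tail equals the start of
        # mate2's template strand
        assert m1[250:] == reverse_complement(m2)[:50]

    def test_inner_gap_for_wgs_geometry(self):
        frag = "".join("ACGT"[i] for i in
                       np.random.default_rng(3).integers(0, 4, 400))
        config = ReadSimConfig.wgs()
        m1, m2 = make_pair(frag, config)
        # 2*150 - 400 = -100: mates leave a 100 bp inner gap
        assert reverse_complement(m2) == frag[250:]
        assert m1 == frag[:150]

    def test_equal_lengths_mate2_is_revcomp_of_mate1(self):
        frag = "ACGTTGCA" * 10
        config = ReadSimConfig(mode="wgs", read_length=80, insert_mean=80,
                               insert_sd=0, orientation="bidirectional")
        m1, m2 = make_pair(frag, config)
        assert m2 == reverse_complement(m1)


class TestErrors:
    def test_zero_rate_leaves_read_intact(self, rng):
        config = ReadSimConfig.amplicon(error_a=0.0, error_b=0.0,
                                        read_length=20)
        seq, qual = apply_poly4_errors("ACGTACGTACGTACGTACGT", config, rng)
        assert seq == "ACGTACGTACGTACGTACGT"
        assert qual == chr(30 + 33) * 20

    def test_certain_substitution_changes_every_base(self, rng):
        config = ReadSimConfig.amplicon(error_a=100.0, error_b=0.0,
                                        error_ratio=(1.0, 0.0, 0.0),
                                        read_length=30)
        template = "A" * 30
        seq, qual = apply_poly4_errors(template, config, rng)
        assert all(b != "A" for b in seq)
        assert qual == chr(10 + 33) * 30

    def test_error_count_matches_poisson_binomial_mean(self):
        # oracle: expected errors per read = sum_i min(1, p(i)); empirical
        # mean over n reads must fall within 3 sigma of it
        rng = np.random.default_rng(5)
        config = ReadSimConfig.amplicon()
        p = _error_probabilities(300, config)
        n = 2000
        counts = [len(_draw_error_positions(300, config, rng))
                  for _ in range(n)]
        sigma_mean = np.sqrt((p * (1 - p)).sum() / n)
        assert abs(np.mean(counts) - p.sum()) < 3 * sigma_mean

    def test_length_restored_after_indels(self, rng):
        config = ReadSimConfig.amplicon(error_a=20.0, error_b=0.0,
                                        error_ratio=(0.0, 0.5, 0.5),
                                        read_length=100)
        seq, qual = apply_poly4_errors("ACGT" * 25, config, rng)
        assert len(seq) == len(qual) == 100


class TestSimulate:
    def test_exact_pair_count_and_truth_labels(self, clean_reads):
        assert len(clean_reads) == 2000
        for p in clean_reads.pairs[:20]:
            assert p.species and p.record_id
            assert len(p.seq1) == len(p.seq2) == 300

    def test_zero_error_reads_are_substrings(self, clean_reads,
                                             small_universe):
        _, db_16s, _, _ = small_universe
        by_id = {r.record_id: r.sequence for r in db_16s.records}
        for p in clean_reads.pairs[:100]:
            source = by_id[p.record_id]
            assert p.seq1 in source
            assert reverse_complement(p.seq2) in source

    def test_amplicon_reads_stay_inside_amplicons(self, clean_reads,
                                                  small_universe):
        spec, db_16s, _, _ = small_universe
        a_start, a_end = spec.amplicon_interval
        for p in clean_reads.pairs:
            assert p.start >= a_start and p.end <= a_end

    def test_unidirectional_mode_yields_no_reverse_fragments(self, clean_reads):
        assert {p.strand for p in clean_reads.pairs} == {"+"}

    def test_seeded_reproducibility(self, bound_vm, small_universe):
        _, db_16s, _, _ = small_universe
        config = ReadSimConfig.amplicon(total_reads=300, seed=99)
        a = simulate_reads(bound_vm, 0, db_16s, config)
        b = simulate_reads(bound_vm, 0, db_16s, config)
        assert [(p.pair_id, p.seq1, p.seq2) for p in a.pairs] == \
               [(p.pair_id, p.seq1, p.seq2) for p in b.pairs]

    def test_wgs_mode_runs_and_uses_whole_genome(self, bound_vm,
                                                 small_universe):
        _, _, db_genome, _ = small_universe
        config = ReadSimConfig.wgs(total_reads=500, seed=17,
                                   error_a=0.0, error_b=0.0)
        rs = simulate_reads(bound_vm, 0, db_genome, config)
        assert len(rs) == 500
        strands = {p.strand for p in rs.pairs}
        assert strands == {"+", "-"}

    def test_record_choice_uniform_among_duplicates(self, rng):
        from vmbench.ecology import EcologyParams, generate_ecology
        from vmbench.universe import (UniverseSpec, generate_universe,
                                      bind_ecology_to_universe)
        vm = generate_ecology(EcologyParams(
            n_species=1, n_genera=1, n_families=1, n_communities=1, seed=6))
        spec = UniverseSpec(n_species=1, n_genera=1, n_families=1,
                            genome_length=2000, records_per_species=2,
                            primer_fail_prob=0.0, seed=7)
        db_16s, _, tax = generate_universe(spec)
        vm = bind_ecology_to_universe(vm, tax)
        config = ReadSimConfig.amplicon(total_reads=10_000, seed=8,
                                        error_a=0.0, error_b=0.0)
        rs = simulate_reads(vm, 0, db_16s, config)
        share = np.mean([p.record_id.endswith("r0") for p in rs.pairs])
        # binomial(10000, 0.5): 4 sigma is 0.02
        assert abs(share - 0.5) < 0.02


class TestFastq:
    def test_roundtrip(self, clean_reads, tmp_path):
        r1, r2 = tmp_path / "R1.fastq", tmp_path / "R2.fastq"
        write_fastq(clean_reads, r1, r2)
        back = read_fastq(r1, r2)
        assert len(back) == len(clean_reads)
        for a, b in zip(back.pairs[:50], clean_reads.pairs[:50]):
            assert (a.pair_id, a.seq1, a.qual1, a.seq2, a.qual2,
                    a.species, a.record_id) == \
                   (b.pair_id, b.seq1, b.qual1, b.seq2, b.qual2,
                    b.species, b.record_id)

    def test_phred33_encoding_in_files(self, clean_reads, tmp_path):
        # error-free run: every written quality symbol is Q30 -> '?'
        r1 = tmp_path / "R1.fastq"
        write_fastq(clean_reads, r1, tmp_path / "R2.fastq")
        lines = r1.read_text().splitlines()
        assert set(lines[3]) == {"?"}

    def test_empty_readset_roundtrip(self, tmp_path):
        from vmbench.readsim import ReadSet
        r1, r2 = tmp_path / "R1.fastq", tmp_path / "R2.fastq"
        write_fastq(ReadSet([]), r1, r2)
        assert len(read_fastq(r1, r2)) == 0

    def test_malformed_fastq_reports_line(self, tmp_path):
        (tmp_path / "R1.fastq").write_text("@x\nACGT\n+\n!!\n")
        (tmp_path / "R2.fastq").write_text("@x\nACGT\n+\n!!!!\n")
        with pytest.raises(VmbenchError, match="line"):
            read_fastq(tmp_path / "R1.fastq", tmp_path / "R2.fastq")


def test_primer_pair_validation():
    with pytest.raises(InvalidParameterError):
        PrimerPair(forward="", reverse="ACGT")
    with pytest.raises(InvalidParameterError):
        PrimerPair(forward="ACGX", reverse="ACGT")
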