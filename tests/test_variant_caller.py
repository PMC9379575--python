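import math

import numpy as np
import pytest
from scipy.stats import binom, chi2

from vntrcall.catalog import decompose_reference
from vntrcall.simulate import (SimConfig, generate_locus, hap_region,
                               inject_indel, revcomp, simulate_reads)
from vntrcall.variant_caller import (CallerConfig, IndelEvidence, LocusParser,
                                     aggregate_evidence, call_indels,
                                     calls_from_evidence, detect_mutations,
                                     genotype_motif_count, iter_fastq,
                                     lr_statistic, realign_labels,
                                     recruit_reads, write_alignment_report,
                                     write_calls, write_genotypes)


class TestLRStatistic:
    def test_matches_binomial_pmf_ratio_oracle(self):
        """Closed form equals -2 log of the directly evaluated binomial
        pmf ratio for the full grid d <= 50, u in {1, 2, 5}."""
        eps = 0.01
        for u in (1, 2, 5):
            q = 1.0 / (2 * u)
            for d in range(1, 51):
                for i in range(0, d + 1):
                    expect = -2.0 * (binom.logpmf(i, d, eps)
                                     - binom.logpmf(i, d, q))
                    stat, _ = lr_statistic(i, d, u, eps)
                    assert stat == pytest.approx(expect, abs=1e-9)

    def test_zero_support_favours_null(self):
        stat, p = lr_statistic(0, 30, 1, 0.01)
        assert stat < 0
        assert p == 1.0

    def test_strong_signal_example(self):
        stat, p = lr_statistic(15, 30, 1, 0.01)
        expect = -2.0 * (binom.logpmf(15, 30, 0.01)
                         - binom.logpmf(15, 30, 0.5))
        assert stat == pytest.approx(expect, abs=1e-9)
        assert stat == pytest.approx(96.87, abs=0.01)
        assert p < 1e-10

    def test_equal_hypotheses_give_zero(self):
        # epsilon == 1/(2u): likelihoods identical for every i
        for i in range(0, 21):
            stat, p = lr_statistic(i, 20, 50, 0.01)
            assert stat == pytest.approx(0.0, abs=1e-9)
            assert p == 1.0

    def test_p_value_is_chi2_upper_tail(self):
        stat, p = lr_statistic(10, 40, 1, 0.01)
        assert p == pytest.approx(float(chi2.sf(stat, 1)), rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            lr_statistic(1, 0, 1, 0.01)
        with pytest.raises(ValueError):
            lr_statistic(5, 3, 1, 0.01)


class TestRecruitment:
    def test_error_free_read_recruited_both_strands(self, small_locus):
        parser = LocusParser(small_locus)
        read = small_locus.region_seq[100:250]
        fwd = parser.parse_read(read)
        rev = parser.parse_read(revcomp(read))
        assert fwd is not None and fwd.strand == "+"
        assert rev is not None and rev.strand == "-"
        assert fwd.log_score == pytest.approx(rev.log_score, abs=1e-9)

    def test_random_reads_not_recruited(self, small_locus, rng):
        parser = LocusParser(small_locus)
        bases = np.array(list("ACGT"))
        n_recruited = sum(
            parser.parse_read("".join(rng.choice(bases, size=150)))
            is not None
            for _ in range(1000))
        assert n_recruited == 0

    def test_read_with_excess_indels_rejected(self, small_locus, rng):
        """More indels than the banding budget tolerates -> no alignment."""
        parser = LocusParser(small_locus)
        delta = parser.delta
        region = small_locus.region_seq
        read = list(region[100:250])
        # scatter far more single-base deletions than delta across the read
        drop = rng.choice(len(read), size=min(len(read) // 2, 4 * delta + 40),
                          replace=False)
        mangled = "".join(b for i, b in enumerate(read) if i not in set(drop))
        tail = region[250:250 + 150 - len(mangled)]
        assert parser.parse_read(mangled + tail) is None

    def test_recruit_reads_accepts_pairs_and_objects(self, small_locus):
        read = small_locus.region_seq[50:200]
        parses = recruit_reads([("r1", read)], small_locus)
        assert len(parses) == 1


class TestCallingThresholds:
    def _ev(self, **kw):
        base = dict(locus_id="L", motif_label=1, state_offset=3,
                    event="deletion", i=15, d=30, u_occ=1, sizes=[2] * 15)
        base.update(kw)
        return IndelEvidence(**base)

    def test_supported_significant_event_called(self):
        calls = calls_from_evidence([self._ev()])
        assert len(calls) == 1
        assert calls[0].size == 2
        assert calls[0].p_value < 0.001

    def test_min_support_suppresses(self):
        ev = self._ev(i=4, sizes=[2] * 4)
        assert calls_from_evidence([ev]) == []

    def test_insignificant_p_suppressed(self):
        ev = self._ev(i=5, d=300, u_occ=9, sizes=[1] * 5)
        assert calls_from_evidence([ev]) == []

    def test_hyper_variable_segments_excluded(self, small_locus):
        """Segments with more than four substitutions against their motif
        contribute no indel evidence."""
        from vntrcall.motif_hmm import IndelEvent
        parser = LocusParser(small_locus)
        read = small_locus.region_seq[120:270]
        parse = parser.parse_read(read)
        for seg in parse.segments:
            if seg.is_motif:
                seg.n_subs = 5
                seg.events = [IndelEvent("del", 2, 1)]
        ev = aggregate_evidence([parse], small_locus)
        assert ev == []


class TestEndToEndCalling:
    def test_het_insertion_called(self):
        rng = np.random.default_rng(77)
        cfg = SimConfig(total_len_range=(300, 360), seed=77)
        locus = decompose_reference(generate_locus(cfg, rng, "e2e"))
        w = len(locus.consensus_motif)
        pos = locus.total_length // 2
        insert = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 3)])
        mutated = locus.ref_vntr_seq[:pos] + insert + locus.ref_vntr_seq[pos:]
        reads = simulate_reads([hap_region(locus), hap_region(locus, mutated)],
                               cfg, rng)
        calls, parses = detect_mutations(locus, reads)
        assert calls, "heterozygous 3 bp insertion should be detected"
        assert any(c.event == "insertion" for c in calls)
        best = max(calls, key=lambda c: c.i)
        assert best.i >= 5
        assert best.p_value < 0.001

    def test_clean_locus_yields_no_calls(self):
        rng = np.random.default_rng(78)
        cfg = SimConfig(total_len_range=(300, 360), seed=78)
        locus = decompose_reference(generate_locus(cfg, rng, "clean"))
        reads = simulate_reads([hap_region(locus), hap_region(locus)],
                               cfg, rng)
        calls, _ = detect_mutations(locus, reads)
        assert calls == []


class TestGenotyping:
    def _spanning_parses(self, locus, haps, cfg, rng):
        reads = simulate_reads([hap_region(locus, h) for h in haps], cfg, rng)
        return recruit_reads(reads, locus)

    def test_homozygous_counts(self):
        rng = np.random.default_rng(21)
        cfg = SimConfig.short_preset(seed=21)
        locus = decompose_reference(generate_locus(cfg, rng, "hom"))
        c = len(locus.motif_occurrences)
        parses = self._spanning_parses(
            locus, [locus.ref_vntr_seq] * 2, cfg, rng)
        gt = genotype_motif_count(parses, locus)
        assert gt is not None
        assert gt.alleles == (c, c)

    def test_heterozygous_counts(self):
        from vntrcall.simulate import inject_motif_count_change
        rng = np.random.default_rng(22)
        cfg = SimConfig.short_preset(seed=22)
        locus = decompose_reference(generate_locus(cfg, rng, "het"))
        c = len(locus.motif_occurrences)
        mutated, rec = inject_motif_count_change(locus, rng)
        parses = self._spanning_parses(
            locus, [locus.ref_vntr_seq, mutated], cfg, rng)
        gt = genotype_motif_count(parses, locus)
        assert gt is not None
        assert gt.alleles == tuple(sorted((c, c + rec.size)))

    def test_exhaustive_pair_enumeration_oracle(self):
        """The reported pair maximises the mixture likelihood over all
        pairs, checked by independent enumeration on the histogram."""
        rng = np.random.default_rng(23)
        cfg = SimConfig.short_preset(seed=23)
        locus = decompose_reference(generate_locus(cfg, rng, "orc"))
        parses = self._spanning_parses(locus, [locus.ref_vntr_seq] * 2,
                                       cfg, rng)
        gt = genotype_motif_count(parses, locus)
        cfg_c = CallerConfig()
        w_hat = locus.total_length / len(locus.motif_occurrences)

        def loglik(pair):
            def pc(c, a):
                if c == a:
                    return 1 - 2 * cfg_c.slippage_rate
                if abs(c - a) == 1:
                    return cfg_c.slippage_rate
                return 1e-4

            def win(a):
                return max(1.0, 150 - a * w_hat - 2 * cfg_c.flank_anchor)

            f1 = win(pair[0]) / (win(pair[0]) + win(pair[1]))
            return sum(n * math.log(f1 * pc(c, pair[0])
                                    + (1 - f1) * pc(c, pair[1]))
                       for c, n in gt.histogram.items())

        lo = max(1, min(gt.histogram) - 1)
        hi = max(gt.histogram) + 1
        pairs = [(a, b) for a in range(lo, hi + 1)
                 for b in range(a, hi + 1)]
        best = max(pairs, key=loglik)
        assert loglik(gt.alleles) == pytest.approx(loglik(best))

    def test_too_few_spanning_reads_no_call(self, small_locus):
        parser = LocusParser(small_locus)
        region = small_locus.region_seq
        read = region[:150]  # anchored on the left only
        parse = parser.parse_read(read)
        assert genotype_motif_count([parse], small_locus) is None


class TestOutputs:
    def test_empty_vcf_is_valid(self, tmp_path, small_locus):
        out = tmp_path / "calls.vcf"
        write_calls([], [], out, [small_locus])
        import pysam
        with pysam.VariantFile(str(out)) as vcf:
            assert list(vcf) == []

    def test_call_record_round_trips_through_pysam(self, tmp_path,
                                                   small_locus):
        from vntrcall.variant_caller import VariantCall
        call = VariantCall(locus_id=small_locus.locus_id, motif_label=2,
                           state_offset=7, event="insertion", size=3,
                           i=12, d=28, lr_stat=50.0, p_value=1e-8)
        out = tmp_path / "calls.vcf"
        write_calls([call], [], out, [small_locus])
        import pysam
        with pysam.VariantFile(str(out)) as vcf:
            records = list(vcf)
        assert len(records) == 1
        rec = records[0]
        assert rec.pos == small_locus.start + 1
        assert rec.info["MOTIF"] == 2
        assert rec.info["OFFSET"] == 7
        assert rec.info["SUPPORT"] == 12
        assert rec.info["P"] == pytest.approx(1e-8)

    def test_alignment_report_lists_read_substrings(self, tmp_path,
                                                    small_locus):
        parser = LocusParser(small_locus)
        reads = [small_locus.region_seq[i:i + 150] for i in (60, 120, 180)]
        parses = [parser.parse_read(r) for r in reads]
        out = tmp_path / "report.txt"
        write_alignment_report(parses, small_locus, out)
        text = out.read_text()
        assert f"# locus {small_locus.locus_id}" in text
        assert text.count(">motif") >= 1
        some_seg = next(s for p in parses for s in p.segments if s.is_motif)
        assert some_seg.text in text

    def test_genotype_table(self, tmp_path):
        from vntrcall.variant_caller import GenotypeCall
        gt = GenotypeCall("L1", (3, 4), {3: 8, 4: 7}, 15)
        out = tmp_path / "gt.tsv"
        write_genotypes([gt], out)
        lines = out.read_text().splitlines()
        assert lines[1].split("\t")[:3] == ["L1", "3", "4"]


def test_iter_fastq_round_trip(tmp_path):
    from vntrcall.simulate import SimRead, write_fastq
    reads = [SimRead(f"r{i}", "ACGT" * 10, "?" * 40) for i in range(3)]
    path = tmp_path / "reads.fastq"
    write_fastq(reads, path)
    got = list(iter_fastq(path))
    assert got == [(r.name, r.seq) for r in reads]
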