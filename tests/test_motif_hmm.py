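import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vntrcall.motif_hmm import (DELETE, HMMParams, INSERT, MATCH, UNIT_END,
                                UNIT_START, build_multi_motif_hmm,
                                build_profile_hmm, compute_tau, default_delta,
                                viterbi_banded, viterbi_full,
                                worst_indel_penalty)
from vntrcall.simulate import SimConfig, generate_locus
from vntrcall.catalog import decompose_reference

from conftest import make_locus, reference_viterbi


def _norm_ok(hmm):
    sums = hmm.transition_sums()
    return np.allclose(np.delete(sums, hmm.end), 1.0, atol=1e-9)


class TestProfileHMM:
    def test_match_chain_probability(self, params):
        hmm = build_profile_hmm("ACGT", params)
        m_states = [q for q in range(hmm.n_states) if hmm.kind[q] == MATCH]
        assert len(m_states) == 4
        # Match_j -> Match_{j+1} carries the canonical continue probability
        for j in range(len(m_states) - 1):
            sel = (hmm.e_src == m_states[j]) & (hmm.e_dst == m_states[j + 1])
            assert sel.sum() == 1
            assert hmm.e_logp[sel][0] == pytest.approx(math.log(0.9975))

    def test_reference_emission_split(self, params):
        hmm = build_profile_hmm("ACGT", params)
        q = next(q for q in range(hmm.n_states)
                 if hmm.kind[q] == MATCH and hmm.ref_base[q] == 0)
        probs = np.exp(hmm.emis[q])
        assert probs[0] == pytest.approx(0.996)
        assert probs[1:] == pytest.approx([(1 - 0.996) / 3] * 3)
        assert probs.sum() == pytest.approx(1.0)

    def test_empty_motif_rejected(self, params):
        with pytest.raises(ValueError):
            build_profile_hmm("", params)

    def test_non_acgt_rejected(self, params):
        with pytest.raises(ValueError):
            build_profile_hmm("ACGN", params)

    @pytest.mark.parametrize("motif", ["ACGT", "AACCGGTT", "ACGTACGTAA"])
    def test_transition_normalisation(self, motif, params):
        assert _norm_ok(build_profile_hmm(motif, params))


class TestMultiMotifHMM:
    def test_motif_entry_mass_uniform(self, params):
        locus = make_locus(["ACGTAA", "ACGTCA", "AGGTAA", "TCGTAA"],
                           [1, 2, 3, 4, 1, 2])
        hmm = build_multi_motif_hmm(locus, params)
        assert _norm_ok(hmm)
        # Start spreads half its mass equally over the four motif units
        shares = {}
        for src, dst, lp in zip(hmm.s_src, hmm.s_dst, hmm.s_logp):
            if src == hmm.start and hmm.kind[dst] == UNIT_START:
                shares[int(hmm.unit[dst])] = math.exp(lp)
        for src, dst, lp in zip(hmm.e_src, hmm.e_dst, hmm.e_logp):
            if src == hmm.start:
                shares[int(hmm.unit[dst])] = \
                    shares.get(int(hmm.unit[dst]), 0) + math.exp(lp)
        motif_units = hmm.motif_units
        vals = [shares[t] for t in motif_units]
        assert vals == pytest.approx([0.5 / len(motif_units)] * len(vals))
        assert shares[0] == pytest.approx(0.5)  # prefix flank

    def test_every_motif_end_reaches_every_motif_start(self, params):
        locus = make_locus(["ACGTAA", "ACGTCA", "AGGTAA"], [1, 2, 3, 1])
        hmm = build_multi_motif_hmm(locus, params)
        ue = {int(hmm.unit[q]) for q in range(hmm.n_states)
              if hmm.kind[q] == UNIT_END and hmm.unit_is_motif[hmm.unit[q]]}
        pairs = set()
        for src, dst in zip(hmm.s_src, hmm.s_dst):
            if hmm.kind[src] == UNIT_END and hmm.kind[dst] == UNIT_START \
                    and hmm.unit_is_motif[hmm.unit[src]] \
                    and hmm.unit_is_motif[hmm.unit[dst]]:
                pairs.add((int(hmm.unit[src]), int(hmm.unit[dst])))
        assert pairs == {(a, b) for a in ue for b in ue}

    def test_state_count_scales_with_distinct_motif_length(self, params):
        locus = make_locus(["A" * 84, "C" * 84], [1, 2, 1, 2])
        hmm = build_multi_motif_hmm(locus, params)
        # per unit: UnitStart + w Match + (w+1) Insert + w Delete + UnitEnd
        expect_motifs = 2 * (3 * 84 + 3)
        expect_flanks = 2 * (3 * 150 + 3)
        assert hmm.n_states == 2 + expect_motifs + expect_flanks

    def test_undecomposed_locus_rejected(self, params):
        import dataclasses
        locus = dataclasses.replace(make_locus(["ACGTAA"], [1, 1]),
                                    motif_occurrences=())
        with pytest.raises(ValueError):
            build_multi_motif_hmm(locus, params)

    def test_motif_end_fed_before_back_transitions(self, params):
        """Canonical silent order: each Motif-End receives its
        emission-fed value before any of its back-transitions to a
        Motif-Start is relaxed, so one cross-unit hop per column is
        possible and degenerate cycles are not."""
        locus = make_locus(["ACGTAA", "ACGTCA"], [1, 2, 1])
        hmm = build_multi_motif_hmm(locus, params)
        is_motif = lambda q: hmm.unit_is_motif[hmm.unit[q]]
        fed_at = {}
        for pos, (src, dst) in enumerate(zip(hmm.s_src, hmm.s_dst)):
            if hmm.kind[dst] == UNIT_END and is_motif(dst) \
                    and not hmm.is_silent(src):
                fed_at.setdefault(int(dst), pos)
        for pos, (src, dst) in enumerate(zip(hmm.s_src, hmm.s_dst)):
            if hmm.kind[src] == UNIT_END and is_motif(src) \
                    and hmm.kind[dst] == UNIT_START and is_motif(dst):
                assert fed_at[int(src)] < pos


class TestViterbiFull:
    def test_exact_tandem_repeat_path(self, params):
        hmm = build_profile_hmm("ACGT", params)
        parse = viterbi_full(hmm, "ACGTACGT")
        assert parse.status == "aligned"
        assert parse.motif_count == 2
        assert [s.text for s in parse.segments] == ["ACGT", "ACGT"]
        assert all(not s.events for s in parse.segments)
        # closed-form score: entry 1, two clean traversals, one
        # back-transition (1/2), exit to End (1/2)
        p = params
        per_unit = 4 * math.log(p.ref_emission) \
            + 3 * math.log(p.match_to_match) + math.log(p.match_to_match) \
            + math.log(1 - p.alt_event)
        expect = 2 * per_unit + 2 * math.log(0.5)
        assert parse.log_score == pytest.approx(expect, abs=1e-9)

    def test_single_motif_partition(self, params):
        hmm = build_profile_hmm("ACGTAA", params)
        parse = viterbi_full(hmm, "ACGTAA")
        assert len(parse.segments) == 1
        assert parse.segments[0].text == "ACGTAA"

    def test_extra_base_uses_one_insert(self, params):
        hmm = build_profile_hmm("ACGT", params)
        parse = viterbi_full(hmm, "ACGGT")
        events = [e for s in parse.segments for e in s.events]
        assert [(e.kind, e.size) for e in events] == [("ins", 1)]
        n_ins = sum(1 for q in parse.state_path if hmm.kind[q] == INSERT)
        assert n_ins == 1

    def test_missing_base_uses_one_delete(self, params):
        hmm = build_profile_hmm("ACGT", params)
        parse = viterbi_full(hmm, "ACTACGT")
        events = [e for s in parse.segments for e in s.events]
        assert ("del", 1) in [(e.kind, e.size) for e in events]

    def test_emitted_symbols_reproduce_read(self, params, small_locus):
        hmm = build_multi_motif_hmm(small_locus, params)
        region = small_locus.region_seq
        for start in (0, 100, 200, len(region) - 150):
            read = region[start:start + 150]
            parse = viterbi_full(hmm, read)
            assert parse.emitted() == read
            assert parse.explored_cells == parse.total_cells

    def test_matches_independent_oracle(self, params):
        rng = np.random.default_rng(11)
        cfg = SimConfig(total_len_range=(300, 400), seed=11)
        for trial in range(6):
            locus = decompose_reference(
                generate_locus(cfg, rng, locus_id=f"orc{trial}"))
            hmm = build_multi_motif_hmm(locus, params)
            region = locus.region_seq
            start = int(rng.integers(0, len(region) - 60))
            read = list(region[start:start + 60])
            for _ in range(2):  # sprinkle substitutions
                pos = int(rng.integers(len(read)))
                read[pos] = "ACGT"[int(rng.integers(4))]
            read = "".join(read)
            got = viterbi_full(hmm, read).log_score
            expect = reference_viterbi(hmm, read)
            assert got == pytest.approx(expect, abs=1e-9)


class TestBanding:
    def test_tau_monotone_in_delta(self, params, small_locus):
        hmm = build_multi_motif_hmm(small_locus, params)
        taus = [compute_tau(hmm, 150, d) for d in (0, 2, 5, 10, 30)]
        assert all(a > b for a, b in zip(taus, taus[1:]))
        assert taus[0] <= 150 * (math.log(params.match_to_match)
                                 + math.log(params.ref_emission))

    def test_default_delta_half_motif(self):
        locus = make_locus(["A" * 60, "C" * 60], [1, 2])
        assert default_delta(locus) == 30

    def test_worst_indel_penalty_negative(self, params):
        assert worst_indel_penalty(params) < 0

    def test_banded_equals_full_above_tau(self, params, small_locus):
        hmm = build_multi_motif_hmm(small_locus, params)
        region = small_locus.region_seq
        delta = default_delta(small_locus)
        rng = np.random.default_rng(5)
        for _ in range(20):
            start = int(rng.integers(0, len(region) - 150))
            read = region[start:start + 150]
            tau = compute_tau(hmm, len(read), delta)
            full = viterbi_full(hmm, read)
            banded = viterbi_banded(hmm, read, tau)
            assert full.log_score > tau
            assert banded.status == "aligned"
            assert banded.log_score == pytest.approx(full.log_score, abs=1e-9)
            assert banded.emitted() == read

    def test_random_read_no_alignment(self, params, small_locus):
        hmm = build_multi_motif_hmm(small_locus, params)
        rng = np.random.default_rng(6)
        read = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 150)])
        tau = compute_tau(hmm, 150, default_delta(small_locus))
        parse = viterbi_banded(hmm, read, tau)
        assert parse.status == "no_alignment"
        assert parse.log_score == -np.inf

    def test_pruning_occurs_on_near_exact_read(self, params, small_locus):
        hmm = build_multi_motif_hmm(small_locus, params)
        region = small_locus.region_seq
        read = region[180:330]
        tau = compute_tau(hmm, 150, default_delta(small_locus))
        parse = viterbi_banded(hmm, read, tau)
        assert parse.status == "aligned"
        assert parse.explored_cells < parse.total_cells
        assert parse.total_cells == hmm.n_states * 151

    def test_no_state_repeats_without_emission(self, params, small_locus):
        hmm = build_multi_motif_hmm(small_locus, params)
        read = small_locus.region_seq[120:270]
        parse = viterbi_full(hmm, read)
        silent_run: list[int] = []
        for q in parse.state_path:
            if hmm.is_silent(q):
                assert q not in silent_run
                silent_run.append(q)
            else:
                silent_run = []


@settings(deadline=None, max_examples=15, derandomize=True)
@given(st.integers(min_value=0, max_value=10 ** 6))
def test_parse_reproduces_read_property(seed):
    """Any recruited-quality read is reproduced exactly by its parse."""
    rng = np.random.default_rng(seed)
    cfg = SimConfig(total_len_range=(300, 400), seed=int(seed) % 997)
    locus = decompose_reference(generate_locus(cfg, rng, locus_id="prop"))
    hmm = build_multi_motif_hmm(locus)
    region = locus.region_seq
    start = int(rng.integers(0, len(region) - 100))
    read = region[start:start + 100]
    parse = viterbi_full(hmm, read)
    assert parse.emitted() == read
    assert "".join(t for _, t, _ in parse.unit_partition) == read
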