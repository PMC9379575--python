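import numpy as np
import pytest

from vntrcall.catalog import VNTRLocus, decompose_reference
from vntrcall.motif_hmm import HMMParams
from vntrcall.simulate import SimConfig, generate_locus


@pytest.fixture(scope="session")
def params():
    return HMMParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_locus(motifs, arrangement, seed=0, flank=150):
    """Assemble a decomposed locus from explicit motifs and label order."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    occurrences = tuple((lab, motifs[lab - 1]) for lab in arrangement)
    vntr = "".join(seq for _, seq in occurrences)
    return VNTRLocus(
        locus_id="toy",
        chrom="toy",
        start=flank,
        end=flank + len(vntr),
        consensus_motif=motifs[0],
        ref_vntr_seq=vntr,
        left_flank="".join(rng.choice(bases, size=flank)),
        right_flank="".join(rng.choice(bases, size=flank)),
        motif_occurrences=occurrences,
    )


@pytest.fixture(scope="session")
def small_locus():
    """A decomposed synthetic long locus shared across read-level tests."""
    cfg = SimConfig(total_len_range=(300, 360), seed=7)
    rng = np.random.default_rng(7)
    return decompose_reference(generate_locus(cfg, rng, locus_id="shared"))


def reference_viterbi(hmm, read):
    """Independent scalar Viterbi oracle.

    Dense dynamic program over Eq-style recurrences with the silent
    states relaxed to a fixed point within each column (iterated until
    no value changes), written without any of the production kernel's
    edge-ordering machinery.  Because all silent cycles have negative
    weight the iteration converges; paths that revisit a state without
    emitting cannot improve the score.
    """
    from vntrcall.motif_hmm import BASE_INDEX

    n = hmm.n_states
    m = len(read)
    codes = [BASE_INDEX[b] for b in read]
    silent_edges = list(zip(hmm.s_src, hmm.s_dst, hmm.s_logp))
    emit_edges = list(zip(hmm.e_src, hmm.e_dst, hmm.e_logp))
    NEG = float("-inf")
    V = [[NEG] * (m + 1) for _ in range(n)]
    V[hmm.start][0] = 0.0
    for j in range(m + 1):
        changed = True
        iters = 0
        while changed:
            changed = False
            iters += 1
            if iters > n + 2:  # pragma: no cover - cycle guard
                raise RuntimeError("silent relaxation failed to converge")
            for s, d, w in silent_edges:
                if V[s][j] == NEG:
                    continue
                v = V[s][j] + w
                if v > V[d][j] + 1e-12:
                    V[d][j] = v
                    changed = True
        if j < m:
            c = codes[j]
            for s, d, w in emit_edges:
                if V[s][j] == NEG:
                    continue
                v = V[s][j] + w + hmm.emis[d, c]
                if v > V[d][j + 1]:
                    V[d][j + 1] = v
    return V[hmm.end][m]
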