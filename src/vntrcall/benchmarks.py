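"""Self-contained evaluation harnesses over the synthetic pipeline.

Each harness regenerates its loci and reads from a seed, runs the full
caller, and reports a summary statistic: indel-detection accuracy over
replicated heterozygous mutations, the search-space fraction explored
by the banded parser, the false-call rate on mutation-free loci, and
motif-count genotype recovery.  They are used both by the test suite
and by the results-reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import VNTRLocus, decompose_reference
from .motif_hmm import viterbi_banded, viterbi_full
from .simulate import (SimConfig, generate_locus, hap_region, inject_indel,
                       inject_motif_count_change, revcomp, simulate_reads)
from .variant_caller import (CallerConfig, LocusParser, detect_mutations,
                             genotype_motif_count, realign_labels,
                             recruit_reads)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2 ** 31), stream])


@dataclass
class DetectionResult:
    n_replicates: int
    n_detected: int

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.n_detected / self.n_replicates


def indel_detection_accuracy(n_loci: int = 30, n_reps: int = 10,
                             seed: int = 0,
                             cfg: SimConfig | None = None,
                             caller: CallerConfig | None = None,
                             ) -> DetectionResult:
    """Heterozygous-indel detection over synthetic long loci.

    For each locus and replicate, one random indel of size below half
    the motif length is planted on one haplotype, 30x reads are
    simulated, and the replicate scores as detected when the mutation
    caller reports any indel at the locus.
    """
    cfg = cfg or SimConfig(seed=seed)
    caller = caller or CallerConfig()
    detected = total = 0
    for li in range(n_loci):
        rng = _rng(seed, 1000 + li)
        locus = decompose_reference(
            generate_locus(cfg, rng, locus_id=f"acc{li:03d}"))
        parser = LocusParser(locus, caller)
        for rep in range(n_reps):
            mutated, _truth = inject_indel(locus, rng)
            reads = simulate_reads(
                [hap_region(locus), hap_region(locus, mutated)], cfg, rng)
            calls, _ = detect_mutations(locus, reads, caller, parser=parser)
            total += 1
            detected += bool(calls)
    return DetectionResult(n_replicates=total, n_detected=detected)


def muc1_detection_accuracy(n_reps: int = 10, seed: int = 0,
                            caller: CallerConfig | None = None,
                            ) -> DetectionResult:
    """Detection on a MUC1-like preset (60 bp GC-rich motifs, 25 copies)."""
    cfg = SimConfig.muc1_preset(seed=seed)
    rng = _rng(seed, 77)
    locus = decompose_reference(generate_locus(cfg, rng, locus_id="muc1like"))
    caller = caller or CallerConfig()
    parser = LocusParser(locus, caller)
    detected = 0
    for rep in range(n_reps):
        mutated, _truth = inject_indel(locus, rng)
        reads = simulate_reads(
            [hap_region(locus), hap_region(locus, mutated)], cfg, rng)
        calls, _ = detect_mutations(locus, reads, caller, parser=parser)
        detected += bool(calls)
    return DetectionResult(n_replicates=n_reps, n_detected=detected)


@dataclass
class PruningResult:
    n_reads: int
    mean_explored_fraction: float     # banded explored / full table size

    @property
    def explored_pct(self) -> float:
        return 100.0 * self.mean_explored_fraction


def pruning_fraction(n_loci: int = 20, n_reads_total: int = 500,
                     seed: int = 0, check_full: bool = False,
                     cfg: SimConfig | None = None) -> PruningResult:
    """Mean fraction of DP cells the banded parser explores.

    Loci carry at least three distinct motifs; reads are low-error reads
    from the VNTR region, parsed with the default banding budget
    (delta = half the consensus motif length).  With ``check_full`` the
    banded score is also verified against the full-table optimum.
    """
    cfg = cfg or SimConfig(n_distinct_motifs_range=(3, 5), seed=seed)
    per_locus = -(-n_reads_total // n_loci)
    fractions: list[float] = []
    for li in range(n_loci):
        rng = _rng(seed, 2000 + li)
        locus = decompose_reference(
            generate_locus(cfg, rng, locus_id=f"band{li:03d}"))
        parser = LocusParser(locus)
        reads = simulate_reads([hap_region(locus)], cfg, rng)
        rng.shuffle(reads)
        for read in reads[:per_locus]:
            parse = parser.parse_read(read.seq)
            if parse is None:
                continue
            fractions.append(parse.explored_cells / parse.total_cells)
            if check_full:
                oriented = read.seq if parse.strand == "+" else revcomp(read.seq)
                full = viterbi_full(parser.hmm, oriented)
                assert abs(full.log_score - parse.log_score) < 1e-9
    return PruningResult(n_reads=len(fractions),
                         mean_explored_fraction=float(np.mean(fractions)))


def null_call_rate(n_loci: int = 500, seed: int = 0,
                   indel_error_rate: float = 0.005,
                   caller: CallerConfig | None = None) -> float:
    """Fraction of mutation-free loci yielding any indel call.

    Reads carry sequencing indel errors at a rate below the caller's
    epsilon, so any call is a false positive.
    """
    caller = caller or CallerConfig()
    n_called = 0
    for li in range(n_loci):
        rng = _rng(seed, 3000 + li)
        cfg = SimConfig(total_len_range=(300, 450),
                        indel_error_rate=indel_error_rate, seed=seed)
        locus = decompose_reference(
            generate_locus(cfg, rng, locus_id=f"null{li:03d}"))
        reads = simulate_reads([hap_region(locus), hap_region(locus)],
                               cfg, rng)
        calls, _ = detect_mutations(locus, reads, caller)
        n_called += bool(calls)
    return n_called / n_loci


def genotype_recovery(n_loci: int = 40, seed: int = 0,
                      caller: CallerConfig | None = None) -> float:
    """Fraction of short loci whose planted diploid motif-count pair is
    recovered from 30x reads (half with a heterozygous copy change)."""
    caller = caller or CallerConfig()
    cfg = SimConfig.short_preset(seed=seed)
    n_correct = 0
    for li in range(n_loci):
        rng = _rng(seed, 4000 + li)
        locus = decompose_reference(
            generate_locus(cfg, rng, locus_id=f"gt{li:03d}"))
        c_ref = len(locus.motif_occurrences)
        if li % 2 == 0:
            truth = (c_ref, c_ref)
            haps = [locus.ref_vntr_seq, locus.ref_vntr_seq]
        else:
            mutated, rec = inject_motif_count_change(locus, rng)
            truth = tuple(sorted((c_ref, c_ref + rec.size)))
            haps = [locus.ref_vntr_seq, mutated]
        reads = simulate_reads([hap_region(locus, h) for h in haps],
                               cfg, rng)
        parses = recruit_reads(reads, locus, caller)
        gt = genotype_motif_count(parses, locus, caller)
        n_correct += (gt is not None and gt.alleles == truth)
    return n_correct / n_loci
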