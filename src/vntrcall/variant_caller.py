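"""Read recruitment, indel evidence aggregation, and variant calling.

Mutation mode (long VNTRs).  Reads recruited to a locus are parsed by
the banded Viterbi decoder of the multi-motif HMM; each read's Viterbi
path partitions it into motif substrings carrying insert/delete
transitions.  At a motif state covered by ``d`` reads with ``i``
observed indel transitions, a true heterozygous mutation in one of the
``u`` reference occurrences of that motif is expected in a fraction
``1/(2u)`` of covering reads, whereas sequencing error produces indel
transitions at a per-nucleotide rate ``epsilon``.  The test statistic

    stat = -2 * ln[ Binom(d, i, epsilon) / Binom(d, i, 1/(2u)) ]

is referred to a chi-squared distribution with one degree of freedom;
a mutation is reported when the nominal p-value falls below the cutoff
and at least ``min_support`` reads support it.

Genotype mode (short VNTRs).  Reads spanning both flanks each yield a
motif count (number of Motif-End traversals); the diploid count pair
maximising a binomial mixture likelihood over the count histogram is
reported.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import chi2

from .catalog import VNTRLocus
from .label_align import (MotifReparser, align_labels, align_labels_at,
                          anchored_offsets, read_label_string,
                          reassign_substrings)
from .motif_hmm import (HMMParams, MultiMotifHMM, ScoredParse,
                        build_multi_motif_hmm, compute_tau, default_delta,
                        viterbi_banded)
from .simulate import revcomp


@dataclass
class CallerConfig:
    """Tunable thresholds of the mutation/genotype callers."""

    epsilon: float = 0.01          # per-nucleotide erroneous-indel rate
    p_cutoff: float = 0.001        # nominal significance level
    min_support: int = 5           # minimum supporting reads
    max_motif_mismatches: int = 4  # hyper-variability mask per motif copy
    delta: int | None = None       # banding indel budget; None = w/2
    kmer_size: int = 15
    min_shared_kmers: int = 2
    min_spanning_reads: int = 3    # genotype mode coverage floor
    flank_anchor: int = 10         # bp of flank a spanning read must emit
    slippage_rate: float = 0.01    # +-1 copy miscount rate in genotyping
    read_edge_margin: int = 12    # bp near read ends masked for indel evidence

    def __post_init__(self) -> None:
        if not (0 < self.epsilon < 0.5):
            raise ValueError("epsilon must lie in (0, 0.5)")
        if self.p_cutoff <= 0 or self.min_support <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class IndelEvidence:
    """Aggregated indel-transition counts at one motif state."""

    locus_id: str
    motif_label: int
    state_offset: int      # profile column within the motif
    event: str             # "insertion" | "deletion"
    i: int                 # supporting reads (indel transitions observed)
    d: int                 # covering reads at that state
    u_occ: int             # occurrences of this motif in the reference
    sizes: list[int] = field(default_factory=list)
    n_cols: int = 1        # DP columns pooled into this evidence group

    @property
    def size(self) -> int:
        """Modal event size in bp across supporting reads."""
        vals, counts = np.unique(np.array(self.sizes), return_counts=True)
        return int(vals[np.argmax(counts)])


@dataclass
class VariantCall:
    locus_id: str
    motif_label: int
    state_offset: int
    event: str
    size: int
    i: int
    d: int
    lr_stat: float
    p_value: float


@dataclass
class GenotypeCall:
    locus_id: str
    alleles: tuple[int, int]            # motif counts, c1 <= c2
    histogram: dict[int, int]
    n_spanning: int


# ---------------------------------------------------------------------------
# statistic
# ---------------------------------------------------------------------------


def lr_statistic(i: int, d: int, u_occ: int, epsilon: float,
                 ) -> tuple[float, float]:
    """Likelihood-ratio statistic and chi-squared (1 df) p-value.

    The binomial coefficients cancel, leaving
    ``stat = -2 * [i ln(eps/q) + (d-i) ln((1-eps)/(1-q))]`` with
    ``q = 1/(2 u_occ)``.  When the error hypothesis fits at least as
    well (stat <= 0) the p-value is 1.
    """
    if d <= 0:
        raise ValueError("d must be >= 1")
    if not (0 <= i <= d):
        raise ValueError("need 0 <= i <= d")
    if u_occ < 1:
        raise ValueError("u_occ must be >= 1")
    q = 1.0 / (2.0 * u_occ)
    stat = -2.0 * (i * math.log(epsilon / q)
                   + (d - i) * math.log((1.0 - epsilon) / (1.0 - q)))
    if stat <= 0:
        return stat, 1.0
    return stat, float(chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# recruitment and parsing
# ---------------------------------------------------------------------------


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _shared_kmers(read: str, ref_kmers: set[str], k: int) -> int:
    return sum(1 for i in range(len(read) - k + 1) if read[i:i + k] in ref_kmers)


class LocusParser:
    """Per-locus parsing context: HMM, banding threshold, k-mer filter."""

    def __init__(self, locus: VNTRLocus, config: CallerConfig | None = None,
                 params: HMMParams | None = None):
        if not locus.motif_occurrences:
            raise ValueError(f"locus {locus.locus_id} is not decomposed")
        self.locus = locus
        self.config = config or CallerConfig()
        self.params = params or HMMParams()
        self.hmm = build_multi_motif_hmm(locus, self.params)
        self.delta = (self.config.delta if self.config.delta is not None
                      else default_delta(locus))
        self._kmers = _kmer_set(locus.region_seq, self.config.kmer_size)
        self._tau_cache: dict[int, float] = {}

    def tau(self, m: int) -> float:
        if m not in self._tau_cache:
            self._tau_cache[m] = compute_tau(self.hmm, m, self.delta)
        return self._tau_cache[m]

    def parse_read(self, seq: str) -> ScoredParse | None:
        """k-mer prefilter + banded parse of the better-scoring strand."""
        cfg = self.config
        seq = seq.upper()
        if len(seq) < cfg.kmer_size or any(b not in "ACGT" for b in seq):
            return None
        best: ScoredParse | None = None
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            if _shared_kmers(oriented, self._kmers, cfg.kmer_size) \
                    < cfg.min_shared_kmers:
                continue
            parse = viterbi_banded(self.hmm, oriented, self.tau(len(oriented)))
            if parse.status != "aligned":
                continue
            parse.strand = strand
            if best is None or parse.log_score > best.log_score:
                best = parse
        return best


def recruit_reads(reads: Iterable, locus: VNTRLocus,
                  config: CallerConfig | None = None,
                  params: HMMParams | None = None,
                  parser: LocusParser | None = None) -> list[ScoredParse]:
    """Recruit and parse reads for one locus.

    A read (or its reverse complement) is recruited when it shares at
    least ``min_shared_kmers`` exact k-mers with the locus region and
    its banded-Viterbi score clears the threshold tau; the better
    scoring strand is kept.  ``reads`` may be sequences, ``(name, seq)``
    pairs, or objects with a ``seq`` attribute.
    """
    parser = parser or LocusParser(locus, config, params)
    out: list[ScoredParse] = []
    for read in reads:
        seq = _read_seq(read)
        parse = parser.parse_read(seq)
        if parse is not None:
            out.append(parse)
    return out


def _read_seq(read) -> str:
    if isinstance(read, str):
        return read
    if isinstance(read, tuple):
        return read[1]
    return str(getattr(read, "seq"))


def realign_labels(parses: Sequence[ScoredParse], locus: VNTRLocus,
                   config: CallerConfig | None = None,
                   params: HMMParams | None = None) -> list[ScoredParse]:
    """Apply reference label-order guidance to every parse.

    The label string (complete motif segments plus sufficiently long
    boundary fragments) is aligned against the reference label order;
    when several offsets tie, a read emitting flank sequence is pinned
    to the offset its flank anchor dictates.
    """
    config = config or CallerConfig()
    reparser = MotifReparser(locus, params)
    ref_labels = locus.ref_labels
    out = []
    for parse in parses:
        labels = read_label_string(parse, locus)
        if not labels:
            parse.label_status = "none"
            out.append(parse)
            continue
        alignment = align_labels(labels, ref_labels)
        if alignment.status != "aligned":
            forced = anchored_offsets(parse, locus, len(labels),
                                      config.flank_anchor)
            for off in forced:
                cand = align_labels_at(labels, ref_labels, off)
                if cand.status == "aligned":
                    alignment = cand
                    break
        realigned = reassign_substrings(
            parse, alignment, locus, reparser,
            max_motif_mismatches=config.max_motif_mismatches)
        realigned.label_status = alignment.status
        out.append(realigned)
    return out


# ---------------------------------------------------------------------------
# evidence aggregation and calling
# ---------------------------------------------------------------------------


def aggregate_evidence(parses: Sequence[ScoredParse], locus: VNTRLocus,
                       config: CallerConfig | None = None,
                       ) -> list[IndelEvidence]:
    """Pool per-read indel transitions into per-state evidence.

    Runs of adjacent indel columns within one read are already merged
    into single multi-bp events during path segmentation; here events
    are grouped by (motif label, event type, column) across reads, and
    coverage ``d`` counts motif-copy traversals whose column span
    includes the state.  Hyper-variable segments (more substitutions
    than ``max_motif_mismatches`` against their assigned motif)
    contribute neither support nor coverage.  Complete motif copies
    carry enough sequence to identify their label on their own, but a
    boundary fragment of an ambiguously placed read cannot distinguish
    similar motifs and its tie-broken label would systematically
    distort the coverage counts -- so on multi-motif loci partial
    fragments count only when their parse aligned to the reference
    label order (which corrects their labels positionally).
    """
    config = config or CallerConfig()
    u_occ = locus.label_occurrence_counts()
    widths = {lab: len(seq) for lab, seq in locus.distinct_motifs().items()}
    cover: dict[tuple[int, int], int] = {}
    # per-segment geometry: (first_col, last_col, read context before/after)
    spans: dict[int, list[tuple[int, int, int, int]]] = {}
    groups: dict[tuple[int, str, int], list[int]] = {}
    confident = locus.u <= 1
    first_label = locus.ref_labels[0] if locus.ref_labels else 1
    last_label = locus.ref_labels[-1] if locus.ref_labels else 1
    flank_len = {0: len(locus.left_flank), -1: len(locus.right_flank)}
    for parse in parses:
        frag_ok = confident or parse.label_status in ("aligned", "")
        emitted = [len(s.text) for s in parse.segments]
        total_emitted = sum(emitted)
        before = 0
        for seg_i, seg in enumerate(parse.segments):
            left_ctx = before
            right_ctx = total_emitted - before - emitted[seg_i]
            before += emitted[seg_i]
            if not seg.is_motif:
                # an insertion between the flank and the bordering motif
                # copy is an intra-VNTR event at the copy's edge
                for ev in seg.events:
                    if ev.kind != "ins":
                        continue
                    if seg.label == 0 and ev.col == flank_len[0]:
                        groups.setdefault(
                            (first_label, "insertion", 0), []).append(ev.size)
                    elif seg.label == -1 and ev.col == 0:
                        w_last = widths.get(last_label, 1)
                        groups.setdefault(
                            (last_label, "insertion", w_last), []).append(ev.size)
                continue
            if seg.partial and not frag_ok \
                    and len(seg.text) < 0.5 * widths.get(seg.label, 1):
                continue
            if seg.hyper_variable or seg.n_subs > config.max_motif_mismatches:
                continue
            for col in range(seg.first_col, seg.last_col + 1):
                cover[(seg.label, col)] = cover.get((seg.label, col), 0) + 1
            spans.setdefault(seg.label, []).append(
                (seg.first_col, seg.last_col, left_ctx, right_ctx))
            for ev in seg.events:
                # single-base indels aligned within a read-end margin are
                # unreliable (boundary re-synchronisation artifacts);
                # larger events need one event-length of context
                margin = config.read_edge_margin if ev.size == 1 else ev.size
                off = max(0, ev.col - seg.first_col)
                pos = left_ctx + off
                end_dist = len(seg.text) - off + right_ctx
                if min(pos, end_dist) < margin:
                    continue
                kind = "insertion" if ev.kind == "ins" else "deletion"
                groups.setdefault((seg.label, kind, ev.col), []).append(ev.size)

    def modal(sizes: list[int]) -> int:
        vals, counts = np.unique(np.array(sizes), return_counts=True)
        return int(vals[np.argmax(counts)])

    # read frames place the same event at slightly different columns in
    # different reads; pool groups of the same label/type/size within a
    # two-column window into one event, anchored at the best-supported
    # column of the cluster
    clusters: list[dict] = []
    for (label, kind, col), sizes in sorted(groups.items()):
        size = modal(sizes)
        cur = clusters[-1] if clusters else None
        if cur is not None and cur["label"] == label and cur["kind"] == kind \
                and cur["size"] == size \
                and col - cur["last_col"] <= (2 if size >= 2 else 1):
            cur["sizes"].extend(sizes)
            cur["last_col"] = col
            cur["n_cols"] += 1
            cur["col_counts"][col] = len(sizes)
            if len(sizes) > cur["anchor_n"]:
                cur["anchor_col"], cur["anchor_n"] = col, len(sizes)
        else:
            clusters.append(dict(label=label, kind=kind, size=size,
                                 last_col=col, anchor_col=col, n_cols=1,
                                 anchor_n=len(sizes), sizes=list(sizes),
                                 col_counts={col: len(sizes)}))
    # the same multi-bp event can additionally be attributed to different
    # (similar) motif labels by different reads; clusters of identical
    # type and size (>= 3 bp, so independent error indels never merge)
    # at the same column are pooled under the best-supported label
    clusters.sort(key=lambda c: (-len(c["sizes"]), -c["size"]))
    pooled: list[dict] = []
    for c in clusters:
        host = None
        if c["size"] >= 3:
            # the same event attributed to different (similar) labels
            host = next(
                (p for p in pooled
                 if p["kind"] == c["kind"] and p["size"] == c["size"] >= 3
                 and abs(p["anchor_col"] - c["anchor_col"]) <= 2
                 and p["label"] != c["label"]), None)
        if host is None and c["kind"] == "insertion":
            # a long insertion fragments into nearby runs of varying
            # length in different reads; pool onto a >= 3 bp anchor
            host = next(
                (p for p in pooled
                 if p["kind"] == "insertion" and p["label"] == c["label"]
                 and max(p["size"], c["size"]) >= 3
                 and abs(p["anchor_col"] - c["anchor_col"]) <= 3), None)
        if host is not None:
            host["sizes"].extend(c["sizes"])
            host["size"] = max(host["size"], c["size"])
            host["n_cols"] += c["n_cols"]
            continue
        pooled.append(c)

    # a deletion crossing a copy boundary is represented as two runs --
    # one touching the end of a copy, one the start of the next copy.
    # Each read carries both runs, so the merged event's support is the
    # larger of the two, with the summed size.
    tails = [c for c in pooled if c["kind"] == "deletion" and c["size"] >= 2
             and c["anchor_col"] + c["size"] - 1
             >= widths.get(c["label"], 1) - 1]
    heads = [c for c in pooled if c["kind"] == "deletion" and c["size"] >= 2
             and c["anchor_col"] <= 2]
    boundary_merged = []
    for tail in tails:
        for head in heads:
            if head is tail:
                continue
            n = min(len(tail["sizes"]), len(head["sizes"]))
            if n < 2:
                continue
            i_merged = max(len(tail["sizes"]), len(head["sizes"]))
            boundary_merged.append((tail, head, i_merged))

    # physical depth bound: coverage of one motif state cannot exceed the
    # read depth summed over the motif's occurrences; any surplus in the
    # observed counts is label misattribution, not real coverage
    region_len = max(1, len(locus.region_seq))
    depth_hat = sum(len(p.read) for p in parses) / region_len

    def informative_d(label: int, kind: str, col: int, size: int,
                      margin: int | None = None) -> int:
        # informative coverage: a read can express an event only when it
        # both spans the event's columns and carries matching context on
        # each side (read-edge margin for single-base events, one
        # event-length otherwise)
        if margin is None:
            margin = config.read_edge_margin if size == 1 else size
        w_lab = widths.get(label, 1)
        if kind == "deletion":
            lo, hi = col, min(w_lab, col + size - 1)
        else:
            lo, hi = max(1, col - 1), min(w_lab, max(1, col))
        d = sum(1 for a, b, lc, rc in spans.get(label, ())
                if a <= lo and b >= hi
                and lc + (lo - a) >= margin and rc + (b - hi) >= margin)
        d_cap = math.ceil(u_occ.get(label, 1) * depth_hat)
        return min(d, d_cap) if d_cap > 0 else d

    for tail, head, i_merged in boundary_merged:
        size = tail["size"] + head["size"]
        d = min(informative_d(tail["label"], "deletion",
                              tail["anchor_col"], tail["size"], margin=size),
                informative_d(head["label"], "deletion",
                              head["anchor_col"], head["size"], margin=size))
        pooled.append(dict(label=head["label"], kind="deletion", size=size,
                           anchor_col=head["anchor_col"], n_cols=1,
                           anchor_n=i_merged, sizes=[size] * i_merged,
                           d_fixed=d))

    # for pooled single-base clusters the best single column is also
    # evaluated on its own: pooling is only worthwhile when the extra
    # support outweighs the proportionally larger error-rate null
    for c in list(pooled):
        if c["size"] == 1 and c["n_cols"] > 1:
            pooled.append(dict(label=c["label"], kind=c["kind"], size=1,
                               anchor_col=c["anchor_col"], n_cols=1,
                               anchor_n=c["anchor_n"],
                               sizes=[1] * c["anchor_n"]))

    out = []
    for c in sorted(pooled, key=lambda c: (c["label"], c["kind"],
                                           c["anchor_col"])):
        label, kind, col, sizes = c["label"], c["kind"], c["anchor_col"], c["sizes"]
        size = c["size"]
        if "d_fixed" in c:
            d = c["d_fixed"]
        else:
            d = informative_d(label, kind, col, size)
        d = max(d, len(sizes))
        out.append(IndelEvidence(
            locus_id=locus.locus_id, motif_label=label, state_offset=col,
            event=kind, i=len(sizes), d=d, u_occ=u_occ.get(label, 1),
            sizes=sizes, n_cols=c["n_cols"]))
    return out


def calls_from_evidence(evidence: Sequence[IndelEvidence],
                        config: CallerConfig | None = None,
                        ) -> list[VariantCall]:
    """Apply the likelihood-ratio test and reporting thresholds."""
    config = config or CallerConfig()
    calls = []
    for ev in evidence:
        if ev.i < config.min_support:
            continue
        # single-base evidence pooled over several DP columns accumulates
        # error indels from each of them; the null error rate scales to
        # match (multi-base error indels are not an i.i.d. error class)
        n_err_cols = max(1, ev.n_cols) if ev.size == 1 else 1
        eps = min(config.epsilon * n_err_cols, 0.49)
        if ev.i / ev.d <= eps:
            continue
        stat, p = lr_statistic(ev.i, ev.d, ev.u_occ, eps)
        if stat <= 0 or p >= config.p_cutoff:
            continue
        calls.append(VariantCall(
            locus_id=ev.locus_id, motif_label=ev.motif_label,
            state_offset=ev.state_offset, event=ev.event, size=ev.size,
            i=ev.i, d=ev.d, lr_stat=stat, p_value=p))
    return calls


def call_indels(parses: Sequence[ScoredParse], locus: VNTRLocus,
                config: CallerConfig | None = None) -> list[VariantCall]:
    """Evidence aggregation + likelihood-ratio test on realigned parses."""
    config = config or CallerConfig()
    return calls_from_evidence(aggregate_evidence(parses, locus, config),
                               config)


def detect_mutations(locus: VNTRLocus, reads: Iterable,
                     config: CallerConfig | None = None,
                     params: HMMParams | None = None,
                     parser: LocusParser | None = None,
                     ) -> tuple[list[VariantCall], list[ScoredParse]]:
    """Full mutation-mode pipeline for one long locus."""
    config = config or CallerConfig()
    parses = recruit_reads(reads, locus, config, params, parser=parser)
    parses = realign_labels(parses, locus, config, params)
    return call_indels(parses, locus, config), parses


# ---------------------------------------------------------------------------
# motif-count genotyping (short loci)
# ---------------------------------------------------------------------------


def _count_loglik(count: int, allele: int, slip: float) -> float:
    if count == allele:
        return math.log(1.0 - 2.0 * slip)
    if abs(count - allele) == 1:
        return math.log(slip)
    return math.log(1e-4)


def genotype_motif_count(parses: Sequence[ScoredParse], locus: VNTRLocus,
                         config: CallerConfig | None = None,
                         read_len: int | None = None,
                         ) -> GenotypeCall | None:
    """Maximum-likelihood diploid motif-count genotype from spanning reads.

    Only reads anchored in both flanks (>= ``flank_anchor`` emitted bp
    each) carry a complete motif count.  Each spanning read's count is
    modelled as a mixture over the two alleles with a symmetric +-1
    slippage error; because a longer allele leaves a narrower window of
    read start positions that span it, the mixture weights are
    proportional to each allele's spanning window rather than 1/2.
    Returns the best pair ``(c1 <= c2)`` under a uniform prior, or None
    when fewer than ``min_spanning_reads`` spanning reads exist.
    """
    config = config or CallerConfig()
    counts = []
    for parse in parses:
        pre = sum(len(s.text) for s in parse.segments if s.label == 0)
        suf = sum(len(s.text) for s in parse.segments if s.label == -1)
        if pre >= config.flank_anchor and suf >= config.flank_anchor:
            counts.append(parse.motif_count)
    if len(counts) < config.min_spanning_reads:
        return None
    if read_len is None:
        read_len = max((len(p.read) for p in parses), default=150)
    w_hat = locus.total_length / max(1, len(locus.motif_occurrences))
    hist: dict[int, int] = {}
    for c in counts:
        hist[c] = hist.get(c, 0) + 1

    def window(c: int) -> float:
        return max(1.0, read_len - c * w_hat - 2 * config.flank_anchor)

    lo = max(1, min(counts) - 1)
    hi = max(counts) + 1
    best_pair, best_ll = None, -math.inf
    for c1 in range(lo, hi + 1):
        for c2 in range(c1, hi + 1):
            w1, w2 = window(c1), window(c2)
            f1 = w1 / (w1 + w2)
            ll = sum(n * math.log(
                f1 * math.exp(_count_loglik(c, c1, config.slippage_rate))
                + (1 - f1) * math.exp(_count_loglik(c, c2,
                                                    config.slippage_rate)))
                for c, n in hist.items())
            if ll > best_ll:
                best_ll, best_pair = ll, (c1, c2)
    return GenotypeCall(locus_id=locus.locus_id, alleles=best_pair,
                        histogram=dict(sorted(hist.items())),
                        n_spanning=len(counts))


def genotype_locus(locus: VNTRLocus, reads: Iterable,
                   config: CallerConfig | None = None,
                   params: HMMParams | None = None,
                   parser: LocusParser | None = None) -> GenotypeCall | None:
    """Full genotype-mode pipeline for one short locus."""
    config = config or CallerConfig()
    parses = recruit_reads(reads, locus, config, params, parser=parser)
    return genotype_motif_count(parses, locus, config)


# ---------------------------------------------------------------------------
# input/output
# ---------------------------------------------------------------------------


def iter_fastq(path) -> Iterable[tuple[str, str]]:
    """Yield (name, sequence) from a plain or gzipped FASTQ file."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            yield header[1:].split()[0], seq


def iter_bam(path, chrom: str | None = None, start: int | None = None,
             end: int | None = None) -> Iterable[tuple[str, str]]:
    """Yield (name, sequence) from a BAM/SAM file, optionally by region."""
    import pysam

    mode = "r" if str(path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(str(path), mode) as bam:
        it = bam.fetch(chrom, start, end) if chrom else bam.fetch(until_eof=True)
        for aln in it:
            if aln.query_sequence:
                yield aln.query_name, aln.query_sequence


def write_calls(calls: Sequence[VariantCall],
                genotypes: Sequence[GenotypeCall],
                out_path, loci: Sequence[VNTRLocus]) -> None:
    """Write indel calls as VCF 4.2; motif-count genotypes as INFO=GTMC rows.

    POS is the locus start (1-based); the intra-VNTR position is
    deliberately reported only as a motif label and state offset in the
    INFO field, since the method localises variants relative to a motif
    rather than to genomic coordinates.
    """
    by_id = {l.locus_id: l for l in loci}
    lines = [
        "##fileformat=VCFv4.2",
        "##source=vntrcall",
        '##INFO=<ID=MOTIF,Number=1,Type=Integer,Description="Motif label">',
        '##INFO=<ID=OFFSET,Number=1,Type=Integer,Description="State offset within motif">',
        '##INFO=<ID=SIZE,Number=1,Type=Integer,Description="Indel size in bp">',
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting reads">',
        '##INFO=<ID=DEPTH,Number=1,Type=Integer,Description="Covering reads">',
        '##INFO=<ID=P,Number=1,Type=Float,Description="Nominal chi-squared p-value">',
        '##INFO=<ID=GTMC,Number=2,Type=Integer,Description="Diploid motif-count genotype">',
        '##ALT=<ID=INS,Description="Insertion within VNTR motif">',
        '##ALT=<ID=DEL,Description="Deletion within VNTR motif">',
    ]
    for chrom in dict.fromkeys(l.chrom for l in loci):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for call in calls:
        loc = by_id[call.locus_id]
        alt = "<INS>" if call.event == "insertion" else "<DEL>"
        ref_base = loc.ref_vntr_seq[0] if loc.ref_vntr_seq else "N"
        info = (f"MOTIF={call.motif_label};OFFSET={call.state_offset};"
                f"SIZE={call.size};SUPPORT={call.i};DEPTH={call.d};"
                f"P={call.p_value:.3g}")
        lines.append(f"{loc.chrom}\t{loc.start + 1}\t{call.locus_id}\t"
                     f"{ref_base}\t{alt}\t.\tPASS\t{info}")
    for gt in genotypes:
        loc = by_id[gt.locus_id]
        ref_base = loc.ref_vntr_seq[0] if loc.ref_vntr_seq else "N"
        lines.append(f"{loc.chrom}\t{loc.start + 1}\t{gt.locus_id}\t"
                     f"{ref_base}\t.\t.\tPASS\t"
                     f"GTMC={gt.alleles[0]},{gt.alleles[1]}")
    with open(out_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_genotypes(genotypes: Sequence[GenotypeCall], out_path) -> None:
    with open(out_path, "w") as fh:
        fh.write("locus_id\tallele1\tallele2\tn_spanning\thistogram\n")
        for gt in genotypes:
            hist = ",".join(f"{c}:{n}" for c, n in gt.histogram.items())
            fh.write(f"{gt.locus_id}\t{gt.alleles[0]}\t{gt.alleles[1]}\t"
                     f"{gt.n_spanning}\t{hist}\n")


def write_alignment_report(parses: Sequence[ScoredParse], locus: VNTRLocus,
                           out_path) -> None:
    """Plain-text report of read substrings stacked under their motifs."""
    motifs = locus.distinct_motifs()
    by_label: dict[int, list] = {}
    for parse in parses:
        for seg in parse.segments:
            if seg.is_motif:
                by_label.setdefault(seg.label, []).append(seg)
    with open(out_path, "w") as fh:
        fh.write(f"# locus {locus.locus_id}  motifs={len(motifs)}  "
                 f"reads={len(parses)}\n")
        for label in sorted(by_label):
            fh.write(f"\n>motif {label}  {motifs.get(label, '?')}\n")
            for seg in by_label[label]:
                marks = "".join(
                    f" {e.kind}@{e.col}x{e.size}" for e in seg.events)
                flag = " partial" if seg.partial else ""
                hv = " hyper" if seg.hyper_variable else ""
                fh.write(f"  {seg.text}{marks}{flag}{hv}\n")
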