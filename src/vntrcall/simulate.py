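"""Synthetic VNTR loci, truth-known mutations, and Illumina-like reads.

The generator emulates the structure of coding VNTRs: a random
consensus motif (6-100 bp), a handful of distinct motif variants
produced by point substitutions, tandem copies concatenated to a target
total length, and unique random flanks one read-length long.  Mutations
are injected heterozygously -- an indel of random size strictly below
half the motif length at a uniform position for long loci, or a
whole-copy gain/loss for short loci.  Reads are single-end, fixed
length, drawn uniformly from both haplotypes at a target total depth,
with i.i.d. substitution and (rare) single-base indel errors and
constant Q30 qualities.

All randomness flows through a :class:`numpy.random.Generator`; a fixed
seed reproduces loci, truth records, and reads byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .catalog import (LONG_MIN_LEN, SHORT_MAX_LEN, VNTRLocus)

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for one simulation batch."""

    n_loci: int = 1
    motif_len_range: tuple[int, int] = (6, 100)
    total_len_class: str = "long"          # "short" (<=140) | "long" (>=300)
    total_len_range: tuple[int, int] = (300, 600)
    # None: number of distinct motifs scales with copy number (each
    # distinct motif recurring ~1.5-3x, as in substitution-scarred
    # coding repeats); a (lo, hi) tuple fixes the range explicitly.
    n_distinct_motifs_range: tuple[int, int] | None = None
    gc_content: float | None = None
    coverage: float = 30.0
    read_len: int = 150
    sub_error_rate: float = 0.001
    indel_error_rate: float = 0.0001
    flank_len: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        for rate in (self.sub_error_rate, self.indel_error_rate):
            if not (0 <= rate <= 0.05):
                raise ValueError("error rates must lie in [0, 0.05]")
        if self.total_len_class not in ("short", "long"):
            raise ValueError("total_len_class must be 'short' or 'long'")

    @classmethod
    def short_preset(cls, **kw) -> "SimConfig":
        kw.setdefault("motif_len_range", (6, 20))
        # short coding VNTRs cluster well below the 140 bp class bound
        # (median near 54 bp); staying <= 96 bp also keeps both alleles
        # of a copy-number heterozygote spannable by a 150 bp read
        kw.setdefault("total_len_range", (36, 96))
        kw.setdefault("n_distinct_motifs_range", (1, 3))
        return cls(total_len_class="short", **kw)

    @classmethod
    def muc1_preset(cls, **kw) -> "SimConfig":
        """MUC1-like locus: ~60 bp GC-rich motifs, 25 copies.

        The number of distinct motifs follows the generator's standard
        substitution-scarring rule (about one distinct variant per 1.5-3
        copies, hence well above five distinct labels at 25 copies).
        """
        kw.setdefault("motif_len_range", (60, 60))
        kw.setdefault("total_len_range", (1500, 1500))
        kw.setdefault("gc_content", 0.7)
        return cls(total_len_class="long", **kw)


@dataclass
class TruthRecord:
    """Ground truth for one injected mutation."""

    locus_id: str
    event: str            # insertion | deletion | motif_count_change
    size: int             # bp for indels, signed copy delta for count changes
    position: int         # offset within the VNTR (0-based)
    zygosity: str = "het"


@dataclass
class SimRead:
    name: str
    seq: str
    qual: str

    def to_fastq(self) -> str:
        return f"@{self.name}\n{self.seq}\n+\n{self.qual}\n"


def _random_seq(rng: np.random.Generator, length: int,
                gc: float | None = None) -> str:
    if gc is None:
        probs = None
    else:
        probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=probs))


def _mutate_motif(rng: np.random.Generator, motif: str, n_subs: int) -> str:
    seq = list(motif)
    for pos in rng.choice(len(seq), size=min(n_subs, len(seq)), replace=False):
        alts = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = alts[rng.integers(3)]
    return "".join(seq)


def generate_locus(cfg: SimConfig, rng: np.random.Generator,
                   locus_id: str = "sim_locus") -> VNTRLocus:
    """Generate one decomposed synthetic locus on a virtual contig.

    Distinct motifs are the consensus plus copies carrying 1-3 random
    substitutions; copies of the motifs are concatenated to the target
    length and labelled by order of first appearance, so the planted
    decomposition satisfies the catalog invariants directly.
    """
    w_lo, w_hi = cfg.motif_len_range
    if w_lo == w_hi:
        w = w_lo
    else:
        # motif lengths of catalogued VNTRs are heavily skewed towards the
        # short end; draw log-uniformly over the admissible range
        w = int(round(math.exp(rng.uniform(math.log(w_lo), math.log(w_hi)))))
        w = min(max(w, w_lo), w_hi)
    lo, hi = cfg.total_len_range
    target = int(rng.integers(lo, hi + 1))
    copies = max(2, round(target / w))
    if cfg.total_len_class == "long":
        copies = max(copies, math.ceil(LONG_MIN_LEN / w))
        if copies * w < LONG_MIN_LEN:
            copies += 1
    else:
        while copies * w > SHORT_MAX_LEN and copies > 2:
            copies -= 1
        if copies * w > SHORT_MAX_LEN:
            raise ValueError(
                f"cannot satisfy short-class length bound with motif {w} bp")

    consensus = _random_seq(rng, w, cfg.gc_content)
    if cfg.n_distinct_motifs_range is None:
        u = max(1, round(copies / rng.uniform(1.5, 3.0)))
    else:
        u = int(rng.integers(cfg.n_distinct_motifs_range[0],
                             cfg.n_distinct_motifs_range[1] + 1))
    u = min(u, copies)
    motifs = [consensus]
    attempts = 0
    while len(motifs) < u and attempts < 50 * u:
        variant = _mutate_motif(rng, consensus, int(rng.integers(1, 4)))
        if variant not in motifs:
            motifs.append(variant)
        attempts += 1
    u = len(motifs)

    # arrangement: every distinct motif appears at least once
    arrangement = list(rng.integers(0, u, size=copies))
    for k in range(u):
        if k not in arrangement:
            arrangement[int(rng.integers(copies))] = k
    # relabel by order of first appearance
    order: dict[int, int] = {}
    occurrences = []
    for k in arrangement:
        lab = order.setdefault(k, len(order) + 1)
        occurrences.append((lab, motifs[k]))

    vntr = "".join(seq for _, seq in occurrences)
    left = _random_seq(rng, cfg.flank_len)
    right = _random_seq(rng, cfg.flank_len)
    locus = VNTRLocus(
        locus_id=locus_id,
        chrom=locus_id,
        start=cfg.flank_len,
        end=cfg.flank_len + len(vntr),
        consensus_motif=consensus,
        ref_vntr_seq=vntr,
        left_flank=left,
        right_flank=right,
        motif_occurrences=tuple(occurrences),
    )
    locus.validate()
    return locus


def inject_indel(locus: VNTRLocus, rng: np.random.Generator,
                 ) -> tuple[str, TruthRecord]:
    """Plant one heterozygous indel in the VNTR of a long-class locus.

    The size is uniform on ``1 .. ceil(w/2)-1`` (strictly below half the
    consensus motif length) and the position uniform over the VNTR.
    Returns the mutated haplotype's VNTR sequence and the truth record;
    the other haplotype keeps the reference sequence.
    """
    w = len(locus.consensus_motif)
    smax = math.ceil(w / 2) - 1
    if smax < 1:
        raise ValueError("motif too short to host an indel below w/2")
    size = int(rng.integers(1, smax + 1))
    seq = locus.ref_vntr_seq
    if rng.random() < 0.5:
        pos = int(rng.integers(0, len(seq) + 1))
        insert = _random_seq(rng, size)
        mutated = seq[:pos] + insert + seq[pos:]
        event = "insertion"
    else:
        pos = int(rng.integers(0, len(seq) - size + 1))
        mutated = seq[:pos] + seq[pos + size:]
        event = "deletion"
    return mutated, TruthRecord(locus.locus_id, event, size, pos)


def inject_motif_count_change(locus: VNTRLocus, rng: np.random.Generator,
                              ) -> tuple[str, TruthRecord]:
    """Duplicate or drop one motif copy (heterozygous) on a short locus."""
    occ = list(locus.motif_occurrences)
    if len(occ) < 2:
        raise ValueError("need >= 2 copies to change the motif count")
    idx = int(rng.integers(len(occ)))
    gain = bool(rng.random() < 0.5)
    if gain:
        occ.insert(idx, occ[idx])
        delta = +1
    else:
        occ.pop(idx)
        delta = -1
    pos = sum(len(s) for _, s in locus.motif_occurrences[:idx])
    mutated = "".join(seq for _, seq in occ)
    return mutated, TruthRecord(locus.locus_id, "motif_count_change",
                                delta, pos)


def _apply_errors(rng: np.random.Generator, template: str, read_len: int,
                  sub_rate: float, indel_rate: float) -> str:
    out: list[str] = []
    i = 0
    while len(out) < read_len and i < len(template):
        b = template[i]
        r = rng.random()
        if r < indel_rate:
            if rng.random() < 0.5:       # insertion error before this base
                out.append(str(rng.choice(_BASES)))
                continue                 # same template base next round
            i += 1                       # deletion error: skip base
            continue
        if r < indel_rate + sub_rate:
            alts = [x for x in "ACGT" if x != b]
            out.append(alts[rng.integers(3)])
        else:
            out.append(b)
        i += 1
    while len(out) < read_len:           # pad if deletions ran off the end
        out.append(str(rng.choice(_BASES)))
    return "".join(out[:read_len])


_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def simulate_reads(haplotypes: Sequence[str], cfg: SimConfig,
                   rng: np.random.Generator,
                   name_prefix: str = "read") -> list[SimRead]:
    """Sample single-end reads uniformly from each haplotype region.

    ``haplotypes`` are full region sequences (flank + VNTR + flank).
    Each haplotype receives ``round((coverage / n_hap) * len / read_len)``
    reads; strand is random.  Reads carry i.i.d. substitution errors at
    ``sub_error_rate`` and single-base indel errors at
    ``indel_error_rate``; qualities are constant Q30.
    """
    reads: list[SimRead] = []
    per_hap_cov = cfg.coverage / max(1, len(haplotypes))
    for h, hap in enumerate(haplotypes):
        if len(hap) < cfg.read_len:
            raise ValueError("haplotype region shorter than the read length")
        n_reads = int(round(per_hap_cov * len(hap) / cfg.read_len))
        for r in range(n_reads):
            start = int(rng.integers(0, len(hap) - cfg.read_len + 1))
            template = hap[start:start + cfg.read_len + 16]
            seq = _apply_errors(rng, template, cfg.read_len,
                                cfg.sub_error_rate, cfg.indel_error_rate)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            reads.append(SimRead(f"{name_prefix}_h{h}_{r}", seq,
                                 "?" * len(seq)))
    return reads


def hap_region(locus: VNTRLocus, vntr_seq: str | None = None) -> str:
    """Full haplotype region: left flank + (possibly mutated) VNTR + right."""
    return locus.left_flank + (vntr_seq or locus.ref_vntr_seq) + locus.right_flank


def write_fastq(reads: Sequence[SimRead], path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(read.to_fastq())


def write_truth(records: Sequence[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tevent\tsize\tposition\tzygosity\n")
        for t in records:
            fh.write(f"{t.locus_id}\t{t.event}\t{t.size}\t{t.position}"
                     f"\t{t.zygosity}\n")
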