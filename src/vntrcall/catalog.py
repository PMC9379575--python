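"""VNTR target catalog: loading, target selection, reference decomposition.

A catalog row describes one tandem-repeat locus by genomic interval and
consensus motif; the locus sequence and its flanks are pulled from a
reference FASTA.  Before any read parsing, each reference VNTR is
decomposed into an ordered list of motif occurrences by running a
single-motif profile HMM over it; occurrences with identical sequences
share an integer label, numbered by order of first appearance.  The
distinct labelled motifs are the building blocks of the multi-motif HMM
and the reference label order drives the read label-alignment step.

Coordinates are 0-based half-open throughout; catalog sequences are on
the + strand.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import pandas as pd
from pyfaidx import Fasta

from .motif_hmm import HMMParams, MATCH, build_profile_hmm, viterbi_full

log = logging.getLogger(__name__)

CATALOG_COLUMNS = ["locus_id", "chrom", "start", "end", "consensus_motif"]

MIN_MOTIF_LEN = 6
MAX_MOTIF_LEN = 100
MIN_REPEAT_COUNT = 2
MAX_TOTAL_LEN = 30_000
SHORT_MAX_LEN = 140
LONG_MIN_LEN = 300
DEFAULT_FLANK = 150


@dataclass(frozen=True)
class VNTRLocus:
    """One catalogued tandem-repeat locus.

    ``motif_occurrences`` is empty until :func:`decompose_reference` has
    been run; afterwards it lists ``(label, sequence)`` pairs whose
    concatenation equals ``ref_vntr_seq``, with labels in ``1..u``
    assigned so that two occurrences share a label iff their sequences
    are identical.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    consensus_motif: str
    ref_vntr_seq: str
    left_flank: str
    right_flank: str
    motif_occurrences: tuple[tuple[int, str], ...] = ()
    gene_name: str = ""
    coding: bool = True

    @property
    def total_length(self) -> int:
        return len(self.ref_vntr_seq)

    @property
    def u(self) -> int:
        """Number of distinct motifs."""
        return max((lab for lab, _ in self.motif_occurrences), default=0)

    @property
    def ref_labels(self) -> list[int]:
        return [lab for lab, _ in self.motif_occurrences]

    def distinct_motifs(self) -> dict[int, str]:
        """Map label -> motif sequence."""
        out: dict[int, str] = {}
        for lab, seq in self.motif_occurrences:
            out.setdefault(lab, seq)
        return out

    def label_occurrence_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for lab, _ in self.motif_occurrences:
            counts[lab] = counts.get(lab, 0) + 1
        return counts

    @property
    def region_seq(self) -> str:
        return self.left_flank + self.ref_vntr_seq + self.right_flank

    def validate(self) -> None:
        if self.motif_occurrences:
            joined = "".join(seq for _, seq in self.motif_occurrences)
            if joined != self.ref_vntr_seq:
                raise ValueError(
                    f"locus {self.locus_id}: motif occurrences do not "
                    f"re-concatenate to the reference VNTR sequence")


def passes_catalog_filters(motif: str, total_len: int) -> bool:
    """Size filters defining a usable VNTR target."""
    w = len(motif)
    return (MIN_MOTIF_LEN <= w <= MAX_MOTIF_LEN
            and total_len >= MIN_REPEAT_COUNT * w
            and total_len <= MAX_TOTAL_LEN)


def load_catalog(catalog_path, reference, flank: int = DEFAULT_FLANK,
                 ) -> list[VNTRLocus]:
    """Load a TSV catalog against an indexed reference FASTA.

    Required columns: locus_id, chrom, start, end, consensus_motif;
    optional: gene, region_class ("coding" marks coding loci).  Rows
    failing the motif-length / repeat-count / total-length filters are
    dropped with a log message; a missing chromosome or out-of-contig
    coordinates are hard errors naming the locus.
    """
    df = pd.read_csv(catalog_path, sep="\t", dtype={"chrom": str})
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"catalog is missing columns: {missing}")
    ref = reference if isinstance(reference, Fasta) else Fasta(str(reference))
    loci: list[VNTRLocus] = []
    for row in df.itertuples(index=False):
        locus_id = str(row.locus_id)
        chrom = str(row.chrom)
        start, end = int(row.start), int(row.end)
        if chrom not in ref:
            raise ValueError(f"locus {locus_id}: chromosome {chrom!r} "
                             f"not present in reference")
        contig_len = len(ref[chrom])
        if not (0 <= start < end <= contig_len):
            raise ValueError(f"locus {locus_id}: interval [{start},{end}) "
                             f"outside contig {chrom} (length {contig_len})")
        motif = str(row.consensus_motif).upper()
        if not passes_catalog_filters(motif, end - start):
            log.info("locus %s filtered out (motif %d bp, length %d bp)",
                     locus_id, len(motif), end - start)
            continue
        lf_start = max(0, start - flank)
        rf_end = min(contig_len, end + flank)
        loci.append(VNTRLocus(
            locus_id=locus_id,
            chrom=chrom,
            start=start,
            end=end,
            consensus_motif=motif,
            ref_vntr_seq=str(ref[chrom][start:end]).upper(),
            left_flank=str(ref[chrom][lf_start:start]).upper(),
            right_flank=str(ref[chrom][end:rf_end]).upper(),
            gene_name=str(getattr(row, "gene", "")) if hasattr(row, "gene") else "",
            coding=(str(getattr(row, "region_class", "coding")) == "coding"),
        ))
    return loci


def select_targets(loci: Iterable[VNTRLocus],
                   ) -> tuple[list[VNTRLocus], list[VNTRLocus]]:
    """Split loci into short (<= 140 bp) and long (>= 300 bp) target sets.

    Loci of intermediate length belong to neither set.  Within each set,
    overlapping loci on the same chromosome are resolved greedily by
    earliest end position (interval scheduling); equal end positions are
    broken towards the lexicographically smaller locus_id.
    """
    loci = list(loci)
    short = [l for l in loci if l.total_length <= SHORT_MAX_LEN]
    long_ = [l for l in loci if l.total_length >= LONG_MIN_LEN]

    def greedy(group: list[VNTRLocus]) -> list[VNTRLocus]:
        kept: list[VNTRLocus] = []
        last_end: dict[str, int] = {}
        for loc in sorted(group, key=lambda l: (l.chrom, l.end, l.locus_id)):
            if loc.start >= last_end.get(loc.chrom, -1):
                kept.append(loc)
                last_end[loc.chrom] = loc.end
        return kept

    return greedy(short), greedy(long_)


def decompose_reference(locus: VNTRLocus,
                        hmm_params: HMMParams | None = None) -> VNTRLocus:
    """Partition the reference VNTR into labelled motif occurrences.

    The Viterbi path of a single-motif profile HMM built on the
    consensus motif is run over the full reference VNTR sequence; each
    pass through the motif unit yields one occurrence.  Identical
    occurrence sequences receive identical labels, numbered by order of
    first appearance.  The result is a pure function of
    ``(ref_vntr_seq, consensus_motif, hmm_params)``.
    """
    hmm_params = hmm_params or HMMParams()
    hmm = build_profile_hmm(locus.consensus_motif, hmm_params)
    parse = viterbi_full(hmm, locus.ref_vntr_seq)
    texts = [seg.text for seg in parse.segments]
    if len(texts) < MIN_REPEAT_COUNT:
        raise ValueError(f"locus {locus.locus_id}: not a tandem repeat "
                         f"({len(texts)} motif unit(s) in reference parse)")
    labels: dict[str, int] = {}
    occurrences = []
    for text in texts:
        lab = labels.setdefault(text, len(labels) + 1)
        occurrences.append((lab, text))
    out = replace(locus, motif_occurrences=tuple(occurrences))
    out.validate()
    return out
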