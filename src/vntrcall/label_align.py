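"""Align a read's motif-label sequence to the reference label order.

A mutation can turn one motif into (a copy of) another distinct motif of
the same VNTR, in which case the HMM parse assigns the wrong label and
the mutation is invisible at the sequence level.  Positionally aligning
the read's label string against the reference label order -- a gap-free
local alignment over the label alphabet allowing at most one label
mismatch -- recovers the reference label each read substring should be
compared against.  At a mismatch position the substring is re-parsed
against the reference label's own single-motif profile HMM so that the
underlying substitution or indel resurfaces as emission/transition
evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .catalog import VNTRLocus
from .motif_hmm import (HMMParams, MultiMotifHMM, ScoredParse,
                        build_profile_hmm, viterbi_full)

MATCH_SCORE = 1
MISMATCH_SCORE = -1
MAX_LABEL_MISMATCHES = 1


@dataclass
class LabelAlignment:
    """Best gap-free placement of a read label string on the reference.

    ``ref_offset`` may be negative (left overhang) and overhanging
    positions are ignored; ``mismatches`` lists
    ``(read_position, read_label, ref_label)`` tuples.
    """

    read_labels: list[int]
    ref_offset: int
    mismatches: list[tuple[int, int, int]]
    status: str   # "aligned" | "ambiguous" | "unaligned"


@dataclass
class LabelTable:
    """Admissible contiguous label windows of the reference, by window."""

    windows: dict[tuple[int, ...], list[int]]
    max_window: int

    def offsets(self, window: Sequence[int]) -> list[int]:
        return self.windows.get(tuple(window), [])


def build_label_table(locus: VNTRLocus, read_len: int) -> LabelTable:
    """Index every contiguous reference label window a read could span.

    A read of length ``r`` over motifs of minimum length ``w`` can cover
    at most ``ceil(r / w)`` full motifs plus one extra partial motif, so
    windows up to that length are admissible.
    """
    labels = locus.ref_labels
    if read_len <= 0 or not labels:
        return LabelTable(windows={}, max_window=0)
    w_min = min(len(seq) for _, seq in locus.motif_occurrences)
    max_window = min(len(labels), -(-read_len // w_min) + 1)
    windows: dict[tuple[int, ...], list[int]] = {}
    for size in range(1, max_window + 1):
        for off in range(len(labels) - size + 1):
            windows.setdefault(tuple(labels[off:off + size]), []).append(off)
    return LabelTable(windows=windows, max_window=max_window)


def align_labels(read_labels: Sequence[int], ref_labels: Sequence[int],
                 max_mismatches: int = MAX_LABEL_MISMATCHES) -> LabelAlignment:
    """Gap-free local alignment of label strings, <= 1 mismatch.

    Every offset (including partial overlaps at the VNTR boundaries) is
    scored +1 per label match and -1 per mismatch over the overlapping
    positions; offsets with more than ``max_mismatches`` mismatches are
    disqualified.  Equal scores are broken towards the larger overlap
    (the maximal local alignment); a unique best offset aligns, while
    two or more offsets tying on both score and overlap are reported as
    ambiguous rather than guessed.
    """
    read_labels = list(read_labels)
    ref_labels = list(ref_labels)
    n, r = len(read_labels), len(ref_labels)
    if n == 0 or r == 0:
        return LabelAlignment(read_labels, 0, [], "unaligned")
    best_key = None
    best: list[tuple[int, list[tuple[int, int, int]]]] = []
    for off in range(-(n - 1), r):
        mism: list[tuple[int, int, int]] = []
        score = 0
        overlap = 0
        for i, lab in enumerate(read_labels):
            j = off + i
            if 0 <= j < r:
                overlap += 1
                if lab == ref_labels[j]:
                    score += MATCH_SCORE
                else:
                    score += MISMATCH_SCORE
                    mism.append((i, lab, ref_labels[j]))
        if overlap == 0 or len(mism) > max_mismatches:
            continue
        key = (score, overlap)
        if best_key is None or key > best_key:
            best_key = key
            best = [(off, mism)]
        elif key == best_key:
            best.append((off, mism))
    if not best:
        return LabelAlignment(read_labels, 0, [], "unaligned")
    if len(best) > 1:
        return LabelAlignment(read_labels, best[0][0], [], "ambiguous")
    off, mism = best[0]
    return LabelAlignment(read_labels, off, mism, "aligned")


# -- substring re-assignment -------------------------------------------------


class MotifReparser:
    """Caches single-motif profile HMMs per reference label.

    Two flavours per label: start-anchored (substring begins at the
    motif start) and mid-entry (substring may be a suffix of the motif,
    as for a read's leading boundary fragment).
    """

    def __init__(self, locus: VNTRLocus, params: HMMParams | None = None):
        self.locus = locus
        self.params = params or HMMParams()
        self._hmms: dict[tuple[int, bool], MultiMotifHMM] = {}

    def hmm_for(self, label: int, mid_entry: bool = False) -> MultiMotifHMM:
        key = (label, mid_entry)
        if key not in self._hmms:
            motif = self.locus.distinct_motifs()[label]
            self._hmms[key] = build_profile_hmm(motif, self.params,
                                                mid_entry=mid_entry)
        return self._hmms[key]

    def reparse(self, text: str, label: int, mid_entry: bool = False):
        """Parse ``text`` against motif ``label``.

        Returns (events, n_subs, first_col, last_col) pooled over the
        re-parse segments.
        """
        parse = viterbi_full(self.hmm_for(label, mid_entry), text)
        events = [e for seg in parse.segments for e in seg.events]
        n_subs = sum(seg.n_subs for seg in parse.segments)
        first = min((s.first_col for s in parse.segments), default=0)
        last = max((s.last_col for s in parse.segments), default=0)
        return events, n_subs, first, last


def reassign_substrings(parse: ScoredParse, alignment: LabelAlignment,
                        locus: VNTRLocus,
                        reparser: MotifReparser | None = None,
                        max_motif_mismatches: int = 4) -> ScoredParse:
    """Replace HMM motif labels with reference labels along the alignment.

    The complete (non-partial) motif segments carry the read's label
    string; where a read label disagrees with the reference label the
    substring is re-parsed against the reference label's single-motif
    HMM, replacing the segment's indel/substitution evidence.  Boundary
    partial segments (the read's leading/trailing motif fragments) are
    then re-assigned to the reference label adjacent to the aligned
    window and re-parsed likewise -- the position guidance is what makes
    evidence from truncated junction fragments usable.  Any re-parse
    showing more than ``max_motif_mismatches`` substitutions marks its
    segment hyper-variable, excluding it from indel evidence.  Ambiguous
    or unaligned alignments leave the parse unchanged.  Partition
    boundaries (the read substrings) are never altered.
    """
    if alignment.status != "aligned":
        return parse
    reparser = reparser or MotifReparser(locus)
    ref_labels = locus.ref_labels
    segs = [replace(s, events=list(s.events)) for s in parse.segments]
    motif_idx = [i for i, s in enumerate(segs) if s.is_motif]
    part = participating_segments(parse, locus)
    if len(part) != len(alignment.read_labels):
        return parse

    def apply(seg, ref_lab: int, mid_entry: bool) -> None:
        events, n_subs, first, last = reparser.reparse(seg.text, ref_lab,
                                                       mid_entry=mid_entry)
        seg.label = ref_lab
        seg.events = events
        seg.n_subs = n_subs
        if seg.partial:
            seg.first_col, seg.last_col = first, last
        seg.hyper_variable = n_subs > max_motif_mismatches

    for i, si in enumerate(part):
        j = alignment.ref_offset + i
        if not (0 <= j < len(ref_labels)):
            continue
        seg = segs[si]
        ref_lab = ref_labels[j]
        if seg.partial or ref_lab != seg.label:
            mid = seg.partial and si == motif_idx[0]
            apply(seg, ref_lab, mid_entry=mid)
    # short boundary fragments excluded from the label string still get
    # position guidance from the reference label adjacent to the window
    if motif_idx and motif_idx[0] not in part:
        j = alignment.ref_offset - 1
        if 0 <= j < len(ref_labels):
            apply(segs[motif_idx[0]], ref_labels[j], mid_entry=True)
    if len(motif_idx) > 1 and motif_idx[-1] not in part:
        j = alignment.ref_offset + len(alignment.read_labels)
        if 0 <= j < len(ref_labels):
            apply(segs[motif_idx[-1]], ref_labels[j], mid_entry=False)
    return replace(parse, segments=segs)


def participating_segments(parse: ScoredParse, locus: VNTRLocus,
                           min_fraction: float = 0.5) -> list[int]:
    """Indices of motif segments that carry a usable label.

    Complete segments always participate; boundary partial fragments
    participate when they cover at least half their motif's length
    (shorter fragments have unreliable labels).
    """
    widths = {lab: len(seq) for lab, seq in locus.distinct_motifs().items()}
    out = []
    for i, seg in enumerate(parse.segments):
        if not seg.is_motif:
            continue
        if not seg.partial or \
                len(seg.text) >= min_fraction * widths.get(seg.label, 1):
            out.append(i)
    return out


def read_label_string(parse: ScoredParse, locus: VNTRLocus | None = None,
                      ) -> list[int]:
    """Label string of a parse, in read order.

    With a locus, labels follow :func:`participating_segments`
    (complete segments plus long boundary fragments); without one, only
    complete segments contribute.
    """
    if locus is None:
        return [s.label for s in parse.segments
                if s.is_motif and not s.partial]
    return [parse.segments[i].label
            for i in participating_segments(parse, locus)]


def anchored_offsets(parse: ScoredParse, locus: VNTRLocus,
                     n_labels: int, flank_anchor: int = 10) -> list[int]:
    """Offsets forced by flank anchoring, when the read emits flank bases.

    A read anchored in the left flank must start at reference label 0;
    one anchored in the right flank must end at the last label.
    """
    offsets = []
    pre = sum(len(s.text) for s in parse.segments if s.label == 0)
    suf = sum(len(s.text) for s in parse.segments if s.label == -1)
    if pre >= flank_anchor:
        first = next((s for s in parse.segments if s.is_motif), None)
        # a short excluded leading fragment occupies position 0 itself
        lead_extra = 0
        if first is not None and first.partial:
            part = participating_segments(parse, locus)
            idx = [i for i, s in enumerate(parse.segments) if s.is_motif]
            if idx and idx[0] not in part:
                lead_extra = 1
        offsets.append(lead_extra)
    if suf >= flank_anchor:
        last_extra = 0
        last = next((s for s in reversed(parse.segments) if s.is_motif), None)
        if last is not None and last.partial:
            part = participating_segments(parse, locus)
            idx = [i for i, s in enumerate(parse.segments) if s.is_motif]
            if idx and idx[-1] not in part:
                last_extra = 1
        offsets.append(len(locus.ref_labels) - n_labels - last_extra)
    return sorted(set(offsets))


def align_labels_at(read_labels: Sequence[int], ref_labels: Sequence[int],
                    offset: int,
                    max_mismatches: int = MAX_LABEL_MISMATCHES,
                    ) -> LabelAlignment:
    """Alignment at one forced offset (flank-anchored reads)."""
    mism = [(i, lab, ref_labels[offset + i])
            for i, lab in enumerate(read_labels)
            if 0 <= offset + i < len(ref_labels)
            and lab != ref_labels[offset + i]]
    if len(mism) > max_mismatches:
        return LabelAlignment(list(read_labels), offset, [], "unaligned")
    return LabelAlignment(list(read_labels), offset, mism, "aligned")
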