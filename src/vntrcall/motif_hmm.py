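"""Multi-motif profile HMMs and Viterbi parsing of short reads.

A VNTR composed of ``u`` distinct motifs is modelled as a union of ``u``
profile HMMs (one per distinct motif) plus profile HMMs for the two
flanking sequences, joined through silent Motif-Start/Motif-End states.
Back-transitions from every Motif-End to every Motif-Start let a single
read traverse several (possibly different) motif copies, so the Viterbi
path simultaneously partitions the read into motif occurrences and
records substitutions and indels relative to each motif.

Two decoders are provided:

* :func:`viterbi_full` -- the exact dynamic program over the complete
  ``n x (m+1)`` table; used as the correctness oracle.
* :func:`viterbi_banded` -- a thresholded decoder that only expands
  cells whose running score stays above a cutoff ``tau`` derived from a
  per-read indel budget ``delta``; returns the same optimum whenever the
  optimum itself clears ``tau``, and ``no_alignment`` otherwise.

Scores are natural-log probabilities throughout; unreachable cells hold
``-inf``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from numba import njit

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .catalog import VNTRLocus

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# State kinds.
START, END, UNIT_START, MATCH, INSERT, DELETE, UNIT_END = range(7)
KIND_NAMES = {
    START: "Start",
    END: "End",
    UNIT_START: "UnitStart",
    MATCH: "M",
    INSERT: "I",
    DELETE: "D",
    UNIT_END: "UnitEnd",
}

#: unit index reserved for the left-flank (prefix) profile HMM
PREFIX_UNIT = 0


@dataclass(frozen=True)
class HMMParams:
    """Fixed transition/emission probabilities of the repeat profile HMMs.

    The defaults encode the strong conservation of coding repeats: a
    Match state continues to the next Match with probability 0.9975 and
    emits the reference residue with probability 0.996; insertions,
    deletions and non-reference residues are rare alternative events.

    match_to_match : Match->Match transition probability.
    ref_emission   : probability that a Match state emits its reference base.
    alt_event      : total probability of each alternative transition
                     (into an Insert state, or out of a Match towards a
                     Delete state / direct read-end exit, which split it).
    gap_extend     : probability of extending an open gap (Insert->Insert
                     and Delete->Delete); entering a gap stays governed
                     by ``alt_event``, so gaps are affine -- rare to
                     open, geometric in length once open.
    """

    match_to_match: float = 0.9975
    ref_emission: float = 0.996
    alt_event: float = 0.00125
    gap_extend: float = 0.15

    def __post_init__(self) -> None:
        if not (0 < self.match_to_match < 1 and 0 < self.ref_emission < 1):
            raise ValueError("probabilities must lie in (0, 1)")
        if self.match_to_match + 2 * self.alt_event > 1 + 1e-12:
            raise ValueError("match_to_match + 2*alt_event must not exceed 1")
        if not (0 < self.gap_extend < 1 - self.alt_event):
            raise ValueError("gap_extend must lie in (0, 1 - alt_event)")


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as int8 codes; raises on other characters."""
    try:
        return np.fromiter((BASE_INDEX[b] for b in seq.upper()), dtype=np.int8,
                           count=len(seq))
    except KeyError as exc:  # pragma: no cover - message detail
        raise ValueError(f"non-ACGT character {exc} in sequence") from None


# ---------------------------------------------------------------------------
# model container and construction
# ---------------------------------------------------------------------------


class _Builder:
    def __init__(self) -> None:
        self.kind: list[int] = []
        self.unit: list[int] = []
        self.col: list[int] = []
        self.ref: list[int] = []

    def state(self, kind: int, unit: int, col: int, ref: int = -1) -> int:
        self.kind.append(kind)
        self.unit.append(unit)
        self.col.append(col)
        self.ref.append(ref)
        return len(self.kind) - 1


@dataclass
class MultiMotifHMM:
    """Flattened state-space representation of a (multi-)motif HMM.

    Transitions are stored as two edge lists: edges into *emitting*
    states (Match/Insert, consume one read symbol) and edges into
    *silent* states (everything else, consume nothing).  The silent list
    is stored in a canonical relaxation order that realises the
    topological ordering of silent states: within one read column, every
    edge is relaxed exactly once in this order, which permits a single
    Motif-End -> Motif-Start hop per unit pair and forbids degenerate
    zero-emission cycles.
    """

    params: HMMParams
    kind: np.ndarray          # int8 (n,)
    unit: np.ndarray          # int16 (n,) unit index, -1 for Start/End
    col: np.ndarray           # int16 (n,) column within unit, -1 if n/a
    ref_base: np.ndarray      # int8 (n,) reference base of Match states, -1 else
    emis: np.ndarray          # float64 (n, 4) log emission; -inf rows for silent
    s_src: np.ndarray         # silent-destination edges, canonical order
    s_dst: np.ndarray
    s_logp: np.ndarray
    e_src: np.ndarray         # emitting-destination edges
    e_dst: np.ndarray
    e_logp: np.ndarray
    unit_seqs: tuple[str, ...]      # per-unit reference sequence
    unit_is_motif: tuple[bool, ...]  # False for flank units
    start: int = 0
    end: int = 1

    # -- basic properties ---------------------------------------------------

    @property
    def n_states(self) -> int:
        return self.kind.shape[0]

    @property
    def n_units(self) -> int:
        return len(self.unit_seqs)

    @property
    def motif_units(self) -> list[int]:
        return [t for t, m in enumerate(self.unit_is_motif) if m]

    @property
    def silent_topo_order(self) -> list[int]:
        """Silent states in first-relaxation order (Start first)."""
        seen: list[int] = [self.start]
        mark = {self.start}
        for d in self.s_dst:
            if int(d) not in mark:
                mark.add(int(d))
                seen.append(int(d))
        return seen

    def is_silent(self, q: int) -> bool:
        return self.kind[q] not in (MATCH, INSERT)

    def state_name(self, q: int) -> str:
        k = int(self.kind[q])
        if k in (START, END):
            return KIND_NAMES[k]
        return f"{KIND_NAMES[k]}[u{int(self.unit[q])},{int(self.col[q])}]"

    # -- normalisation check and debug serialisation ------------------------

    def transition_sums(self) -> np.ndarray:
        """Total outgoing probability per state (End has none)."""
        out = np.zeros(self.n_states)
        for src, logp in ((self.s_src, self.s_logp), (self.e_src, self.e_logp)):
            np.add.at(out, src, np.exp(logp))
        return out

    def to_json(self, path=None) -> str:
        """Serialise states/transitions/emissions to a debug JSON text."""
        obj = {
            "n_states": int(self.n_states),
            "states": [
                {
                    "index": q,
                    "name": self.state_name(q),
                    "silent": bool(self.is_silent(q)),
                    "emission": None if self.is_silent(q) else {
                        b: float(np.exp(self.emis[q, i]))
                        for i, b in enumerate(BASES)
                    },
                }
                for q in range(self.n_states)
            ],
            "transitions": [
                {"from": int(s), "to": int(d), "p": float(np.exp(w)),
                 "silent_dst": bool(sil)}
                for s, d, w, sil in self._edge_iter()
            ],
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def _edge_iter(self):
        for s, d, w in zip(self.s_src, self.s_dst, self.s_logp):
            yield s, d, w, True
        for s, d, w in zip(self.e_src, self.e_dst, self.e_logp):
            yield s, d, w, False


@dataclass
class _UnitIdx:
    """State indices of one profile-HMM unit of length w."""

    us: int
    ue: int
    m: list[int]    # m[1..w] (index 0 unused)
    i: list[int]    # i[0..w]
    d: list[int]    # d[1..w] (index 0 unused)
    w: int


def _add_unit(b: _Builder, seq: str, unit: int) -> _UnitIdx:
    w = len(seq)
    codes = encode(seq)
    us = b.state(UNIT_START, unit, 0)
    m = [-1] + [b.state(MATCH, unit, j + 1, int(codes[j])) for j in range(w)]
    i = [b.state(INSERT, unit, j) for j in range(w + 1)]
    d = [-1] + [b.state(DELETE, unit, j + 1) for j in range(w)]
    ue = b.state(UNIT_END, unit, w + 1)
    return _UnitIdx(us=us, ue=ue, m=m, i=i, d=d, w=w)


def _unit_edges(u: _UnitIdx, p: HMMParams):
    """Internal profile-HMM edges of one unit.

    Returns (emit_edges, delete_chain_edges, unit_end_pass1, unit_end_pass2,
    end_exits) where end_exits are Match -> End hooks filled by the caller.
    The Match alternative mass ``alt_event`` towards deletions is split
    evenly between Delete entry and a direct read-end exit so that reads
    ending inside a motif pay a single bounded exit penalty instead of a
    full delete-chain traversal.
    """
    a, t, g = p.match_to_match, p.alt_event, p.gap_extend
    half = t / 2.0
    la, lt, lh, lg = math.log(a), math.log(t), math.log(half), math.log(g)
    l_last = math.log(1.0 - t)      # final column: continue mass to UnitEnd
    l_close = math.log(1.0 - g - t)  # gap close back to Match
    l_lastg = math.log(1.0 - g)      # final-column gap close to UnitEnd

    emit, dchain, ue1, ue2, ends = [], [], [], [], []
    w = u.w
    # UnitStart behaves like a Match in column 0.
    emit.append((u.us, u.m[1], la))
    emit.append((u.us, u.i[0], lt))
    dchain.append((u.us, u.d[1], lt))
    if w > 0:
        emit.append((u.i[0], u.m[1], l_close))
        emit.append((u.i[0], u.i[0], lg))
        dchain.append((u.i[0], u.d[1], lt))
    for j in range(1, w + 1):
        mj, ij = u.m[j], u.i[j]
        if j < w:
            emit.append((mj, u.m[j + 1], la))
            emit.append((mj, ij, lt))
            dchain.append((mj, u.d[j + 1], lh))
            ends.append((mj, lh))
            emit.append((ij, u.m[j + 1], l_close))
            emit.append((ij, ij, lg))
            dchain.append((ij, u.d[j + 1], lt))
            dj = u.d[j]
            emit.append((dj, u.m[j + 1], l_close))
            emit.append((dj, ij, lt))
            dchain.append((dj, u.d[j + 1], lg))
        else:
            ue1.append((mj, u.ue, l_last))
            emit.append((mj, ij, lt))
            ue1.append((ij, u.ue, l_lastg))
            emit.append((ij, ij, lg))
            ue2.append((u.d[w], u.ue, l_last))
            emit.append((u.d[w], ij, lt))
    # order delete-chain edges by destination column
    dchain.sort(key=lambda e: (e[1], e[0]))
    return emit, dchain, ue1, ue2, ends


def _emission_matrix(b: _Builder, p: HMMParams) -> np.ndarray:
    n = len(b.kind)
    emis = np.full((n, 4), -np.inf)
    l_ref = math.log(p.ref_emission)
    l_alt = math.log((1.0 - p.ref_emission) / 3.0)
    l_uni = math.log(0.25)
    for q in range(n):
        if b.kind[q] == MATCH:
            emis[q, :] = l_alt
            emis[q, b.ref[q]] = l_ref
        elif b.kind[q] == INSERT:
            emis[q, :] = l_uni
    return emis


def _finalise(b: _Builder, p: HMMParams, silent_edges, emit_edges,
              unit_seqs, unit_is_motif) -> MultiMotifHMM:
    emit_edges = sorted(emit_edges, key=lambda e: (e[1], e[0]))
    s_src = np.array([e[0] for e in silent_edges], dtype=np.int32)
    s_dst = np.array([e[1] for e in silent_edges], dtype=np.int32)
    s_logp = np.array([e[2] for e in silent_edges], dtype=np.float64)
    e_src = np.array([e[0] for e in emit_edges], dtype=np.int32)
    e_dst = np.array([e[1] for e in emit_edges], dtype=np.int32)
    e_logp = np.array([e[2] for e in emit_edges], dtype=np.float64)
    return MultiMotifHMM(
        params=p,
        kind=np.array(b.kind, dtype=np.int8),
        unit=np.array(b.unit, dtype=np.int16),
        col=np.array(b.col, dtype=np.int16),
        ref_base=np.array(b.ref, dtype=np.int8),
        emis=_emission_matrix(b, p),
        s_src=s_src, s_dst=s_dst, s_logp=s_logp,
        e_src=e_src, e_dst=e_dst, e_logp=e_logp,
        unit_seqs=tuple(unit_seqs),
        unit_is_motif=tuple(unit_is_motif),
    )


def build_profile_hmm(motif: str, params: HMMParams | None = None,
                      mid_entry: bool = False) -> MultiMotifHMM:
    """Single-motif profile HMM with a Motif-End -> Motif-Start back edge.

    Used to decompose a reference VNTR into motif occurrences and to
    re-parse individual read substrings against one motif.  By default
    entry is at the motif start only; with ``mid_entry`` half the entry
    mass is spread over the match columns so that a substring that is a
    suffix of the motif (a read's leading boundary fragment) can be
    aligned.  After each traversal the model either cycles back (p=1/2)
    or exits to End (p=1/2).
    """
    params = params or HMMParams()
    if len(motif) == 0:
        raise ValueError("empty motif")
    b = _Builder()
    start = b.state(START, -1, -1)
    end = b.state(END, -1, -1)
    u = _add_unit(b, motif, 1)
    emit, dchain, ue1, ue2, ends = _unit_edges(u, params)

    lhalf = math.log(0.5)
    silent: list[tuple[int, int, float]] = []
    if mid_entry:
        silent.append((start, u.us, lhalf))
        per_col = 0.5 / u.w
        emit.extend((start, u.m[j], math.log(per_col))
                    for j in range(1, u.w + 1))
    else:
        silent.append((start, u.us, 0.0))       # sole entry
    silent.extend(ue1)                          # UnitEnd pass 1 (from M_w/I_w)
    silent.append((u.ue, u.us, lhalf))          # back-transition
    silent.extend(dchain)                       # delete chain
    silent.extend(ue2)                          # UnitEnd pass 2 (from D_w)
    silent.extend((m, end, w) for m, w in ends)  # mid-motif read-end exits
    silent.append((u.ue, end, lhalf))
    # unit_seqs is indexed by unit id; id 0 (flank slot) is unused here
    return _finalise(b, params, silent, emit, ["", motif], [False, True])


def build_multi_motif_hmm(locus: "VNTRLocus",
                          params: HMMParams | None = None) -> MultiMotifHMM:
    """Combine per-motif profile HMMs and flank HMMs into one model.

    Unit 0 is the left flank, units ``1..u`` the distinct motifs in
    label order, unit ``u+1`` the right flank.  Start splits its mass
    half to the prefix flank and half across the motif units; within a
    unit, entry mass is split between the unit start and every match
    column so that reads beginning anywhere inside the VNTR (or flank)
    remain representable.  Every Motif-End fans out to all Motif-Starts,
    the suffix flank, and End.  Flank units have no back-transition.
    """
    params = params or HMMParams()
    motifs = locus.distinct_motifs()
    u_cnt = len(motifs)
    if u_cnt == 0:
        raise ValueError(f"locus {locus.locus_id}: no motifs; run decompose_reference first")
    b = _Builder()
    start = b.state(START, -1, -1)
    end = b.state(END, -1, -1)

    prefix = _add_unit(b, locus.left_flank, PREFIX_UNIT)
    units = [_add_unit(b, motifs[lab], lab) for lab in range(1, u_cnt + 1)]
    suffix = _add_unit(b, locus.right_flank, u_cnt + 1)

    emit: list[tuple[int, int, float]] = []
    parts = {}
    for key, unit in [("p", prefix), ("s", suffix)] + [(k, u) for k, u in enumerate(units)]:
        parts[key] = _unit_edges(unit, params)
        emit.extend(parts[key][0])

    # Start fan-out: 1/2 to prefix, 1/2 shared by motif units; within a
    # unit, half the share enters at UnitStart and half is spread over
    # the match columns (mid-sequence read starts).
    def entry(unit: _UnitIdx, share: float):
        edges_sil = [(start, unit.us, math.log(share / 2.0))]
        per_col = share / (2.0 * unit.w)
        edges_emit = [(start, unit.m[j], math.log(per_col))
                      for j in range(1, unit.w + 1)]
        return edges_sil, edges_emit

    silent: list[tuple[int, int, float]] = []
    pre_sil, pre_emit = entry(prefix, 0.5)
    silent.extend(pre_sil)
    emit.extend(pre_emit)
    motif_share = 0.5 / u_cnt
    motif_entry_sil = []
    for unit in units:
        es, ee = entry(unit, motif_share)
        motif_entry_sil.extend(es)
        emit.extend(ee)
    silent.extend(motif_entry_sil)

    # prefix chain, then prefix UnitEnd, then prefix -> motif starts
    p_emit, p_dchain, p_ue1, p_ue2, p_ends = parts["p"]
    silent.extend(p_ue1)
    silent.extend(p_dchain)
    silent.extend(p_ue2)
    l_fan = math.log(1.0 / u_cnt)
    silent.extend((prefix.ue, unit.us, l_fan) for unit in units)

    # motif UnitEnd pass 1 (values via emissions into M_w / I_w)
    for k, unit in enumerate(units):
        silent.extend(parts[k][2])
    # back-transitions: every Motif-End to every Motif-Start (pass-1 values)
    l_back = math.log(0.5 / u_cnt)
    for src_u in units:
        silent.extend((src_u.ue, dst_u.us, l_back) for dst_u in units)
    # motif delete chains, then UnitEnd pass 2 (whole-motif deletion; the
    # updated value does not re-enter other motif starts in this column)
    for k, unit in enumerate(units):
        silent.extend(parts[k][1])
        silent.extend(parts[k][3])
    # motif ends -> suffix flank (post pass-2), suffix chain, suffix end
    l_quart = math.log(0.25)
    silent.extend((unit.ue, suffix.us, l_quart) for unit in units)
    s_emit, s_dchain, s_ue1, s_ue2, s_ends = parts["s"]
    silent.extend(s_ue1)
    silent.extend(s_dchain)
    silent.extend(s_ue2)
    # terminal hooks into End
    for key in ["p"] + list(range(u_cnt)) + ["s"]:
        unit = {"p": prefix, "s": suffix}.get(key, units[key] if isinstance(key, int) else None)
        silent.extend((m, end, w) for m, w in parts[key][4])
    silent.extend((unit.ue, end, l_quart) for unit in units)
    silent.append((suffix.ue, end, 0.0))

    unit_seqs = [locus.left_flank] + [motifs[lab] for lab in range(1, u_cnt + 1)] \
        + [locus.right_flank]
    unit_is_motif = [False] + [True] * u_cnt + [False]
    return _finalise(b, params, silent, emit, unit_seqs, unit_is_motif)


# ---------------------------------------------------------------------------
# decoding kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _full_kernel(n, m, read, s_src, s_dst, s_logp, e_src, e_dst, e_logp,
                 emis, start):
    V = np.full((n, m + 1), -np.inf)
    ptr = np.full((n, m + 1), -1, np.int32)
    ptyp = np.zeros((n, m + 1), np.uint8)
    V[start, 0] = 0.0
    for j in range(m + 1):
        for t in range(s_src.size):
            s = s_src[t]
            vs = V[s, j]
            if vs == -np.inf:
                continue
            v = vs + s_logp[t]
            d = s_dst[t]
            if v > V[d, j]:
                V[d, j] = v
                ptr[d, j] = s
                ptyp[d, j] = 0
        if j < m:
            c = read[j]
            for t in range(e_src.size):
                s = e_src[t]
                vs = V[s, j]
                if vs == -np.inf:
                    continue
                d = e_dst[t]
                v = vs + e_logp[t] + emis[d, c]
                if v > V[d, j + 1]:
                    V[d, j + 1] = v
                    ptr[d, j + 1] = s
                    ptyp[d, j + 1] = 1
    return V, ptr, ptyp


@njit(cache=True)
def _banded_kernel(n, m, read, s_src, s_dst, s_logp, e_src, e_dst, e_logp,
                   emis, start, tau):
    V = np.full((n, m + 1), -np.inf)
    ptr = np.full((n, m + 1), -1, np.int32)
    ptyp = np.zeros((n, m + 1), np.uint8)
    explored = np.zeros((n, m + 1), np.bool_)
    V[start, 0] = 0.0
    explored[start, 0] = True
    for j in range(m + 1):
        for t in range(s_src.size):
            s = s_src[t]
            vs = V[s, j]
            if vs == -np.inf:
                continue
            v = vs + s_logp[t]
            d = s_dst[t]
            if v >= tau and v > V[d, j]:
                V[d, j] = v
                ptr[d, j] = s
                ptyp[d, j] = 0
                explored[d, j] = True
        if j < m:
            c = read[j]
            for t in range(e_src.size):
                s = e_src[t]
                vs = V[s, j]
                if vs == -np.inf:
                    continue
                d = e_dst[t]
                v = vs + e_logp[t] + emis[d, c]
                if v >= tau and v > V[d, j + 1]:
                    V[d, j + 1] = v
                    ptr[d, j + 1] = s
                    ptyp[d, j + 1] = 1
                    explored[d, j + 1] = True
    n_explored = 0
    for q in range(n):
        for j in range(m + 1):
            if explored[q, j]:
                n_explored += 1
    return V, ptr, ptyp, n_explored


# ---------------------------------------------------------------------------
# parse containers
# ---------------------------------------------------------------------------


@dataclass
class IndelEvent:
    """One merged indel run in a unit segment of a Viterbi path.

    ``col`` is the profile column: for deletions the first deleted match
    column (1-based); for insertions the match column after which the
    inserted bases sit (0 = before the first match column).
    """

    kind: str   # "ins" | "del"
    col: int
    size: int


@dataclass
class UnitSegment:
    """A maximal stretch of one Viterbi path spent inside one unit."""

    unit: int                 # unit index in the HMM (0=prefix, u+1=suffix)
    label: int                # motif label (after any reassignment); 0/-1 flanks
    text: str                 # read substring emitted in this unit
    first_col: int            # first match/delete column covered
    last_col: int             # last match/delete column covered
    events: list[IndelEvent] = field(default_factory=list)
    n_subs: int = 0
    partial: bool = False     # does not span the full unit
    hyper_variable: bool = False

    @property
    def is_motif(self) -> bool:
        return self.label >= 1


@dataclass
class ScoredParse:
    """Viterbi result for one read."""

    log_score: float
    state_path: list[int]
    segments: list[UnitSegment]
    explored_cells: int
    total_cells: int
    status: str                      # "aligned" | "no_alignment"
    strand: str = "+"
    read: str = ""
    label_status: str = ""           # set by label realignment

    @property
    def unit_partition(self) -> list[tuple[int, str, list[tuple[str, int]]]]:
        return [(s.label, s.text, [(e.kind, e.col) for e in s.events])
                for s in self.segments]

    @property
    def motif_count(self) -> int:
        """Number of motif-unit traversals (Motif-End transitions)."""
        return sum(1 for s in self.segments if s.is_motif)

    def emitted(self) -> str:
        return "".join(s.text for s in self.segments)


def _backtrack(hmm: MultiMotifHMM, ptr: np.ndarray, ptyp: np.ndarray,
               m: int) -> list[tuple[int, int]]:
    """Trace the optimal path back from (End, m).

    Returns [(state, read_index)] in forward order; read_index is the
    0-based index of the symbol emitted on arrival at the state, or -1
    for silent states.
    """
    path: list[tuple[int, int]] = []
    q, j = hmm.end, m
    limit = hmm.n_states * (m + 2) + 10
    while not (q == hmm.start and j == 0):
        if len(path) > limit:  # pragma: no cover - defensive
            raise RuntimeError("backtracking did not terminate")
        p = ptr[q, j]
        if p < 0:  # pragma: no cover - defensive
            raise RuntimeError("broken backpointer chain")
        if ptyp[q, j] == 1:
            path.append((q, j - 1))
            j -= 1
        else:
            path.append((q, -1))
        q = p
    path.append((hmm.start, -1))
    path.reverse()
    return path


def _segments_from_path(hmm: MultiMotifHMM, path: list[tuple[int, int]],
                        read: str) -> list[UnitSegment]:
    segs: list[UnitSegment] = []
    cur: UnitSegment | None = None
    open_ins: IndelEvent | None = None
    open_del: IndelEvent | None = None
    saw_entry = False  # entered unit at UnitStart (or column 1)

    def close(unit_len: int):
        nonlocal cur, open_ins, open_del, saw_entry
        if cur is not None:
            if cur.first_col > cur.last_col:   # no match/delete column touched
                cur.first_col = cur.last_col = 0
            cur.partial = not (saw_entry and cur.last_col >= unit_len)
            segs.append(cur)
        cur = None
        open_ins = None
        open_del = None
        saw_entry = False

    for q, ridx in path:
        k = int(hmm.kind[q])
        if k in (START, END):
            if cur is not None:
                close(len(hmm.unit_seqs[cur.unit]))
            continue
        t = int(hmm.unit[q])
        if cur is None or cur.unit != t or k == UNIT_START:
            if cur is not None:
                close(len(hmm.unit_seqs[cur.unit]))
            label = t if hmm.unit_is_motif[t] else (0 if t == PREFIX_UNIT else -1)
            cur = UnitSegment(unit=t, label=label, text="",
                              first_col=10 ** 9, last_col=-1)
            saw_entry = False
        c = int(hmm.col[q])
        if k == UNIT_START:
            saw_entry = True
        elif k == MATCH:
            if c == 1:
                saw_entry = True
            cur.text += read[ridx]
            cur.first_col = min(cur.first_col, c)
            cur.last_col = max(cur.last_col, c)
            if BASE_INDEX[read[ridx]] != int(hmm.ref_base[q]):
                cur.n_subs += 1
            open_ins = None
            open_del = None
        elif k == INSERT:
            cur.text += read[ridx]
            if open_ins is not None and open_ins.col == c:
                open_ins.size += 1
            else:
                open_ins = IndelEvent("ins", c, 1)
                cur.events.append(open_ins)
            open_del = None
        elif k == DELETE:
            cur.first_col = min(cur.first_col, c)
            cur.last_col = max(cur.last_col, c)
            if open_del is not None and open_del.col + open_del.size == c:
                open_del.size += 1
            else:
                open_del = IndelEvent("del", c, 1)
                cur.events.append(open_del)
            open_ins = None
        # UNIT_END closes on next unit change / End
    if cur is not None:  # pragma: no cover - End always terminates the path
        close(len(hmm.unit_seqs[cur.unit]))
    return segs


def _decode(hmm: MultiMotifHMM, read: str, tau: float | None) -> ScoredParse:
    codes = encode(read)
    m = len(read)
    if m < 1:
        raise ValueError("empty read")
    args = (hmm.n_states, m, codes, hmm.s_src, hmm.s_dst, hmm.s_logp,
            hmm.e_src, hmm.e_dst, hmm.e_logp, hmm.emis, hmm.start)
    total = hmm.n_states * (m + 1)
    if tau is None:
        V, ptr, ptyp = _full_kernel(*args)
        explored = total
        score = float(V[hmm.end, m])
        ok = np.isfinite(score)
    else:
        V, ptr, ptyp, explored = _banded_kernel(*args, tau)
        score = float(V[hmm.end, m])
        ok = np.isfinite(score) and score > tau
    if not ok:
        return ScoredParse(log_score=-np.inf, state_path=[], segments=[],
                           explored_cells=int(explored), total_cells=total,
                           status="no_alignment", read=read)
    path = _backtrack(hmm, ptr, ptyp, m)
    segs = _segments_from_path(hmm, path, read)
    return ScoredParse(log_score=score, state_path=[q for q, _ in path],
                       segments=segs, explored_cells=int(explored),
                       total_cells=total, status="aligned", read=read)


def viterbi_full(hmm: MultiMotifHMM, read: str) -> ScoredParse:
    """Exact Viterbi optimum over the complete DP table."""
    return _decode(hmm, read, None)


def viterbi_banded(hmm: MultiMotifHMM, read: str, tau: float) -> ScoredParse:
    """Score-thresholded Viterbi; identical optimum whenever it exceeds tau.

    Cells are expanded only when reached with a running score >= tau;
    if the End state's final score does not clear tau the read is
    reported as ``no_alignment``.
    """
    return _decode(hmm, read, float(tau))


# ---------------------------------------------------------------------------
# banding threshold
# ---------------------------------------------------------------------------


def worst_indel_penalty(params: HMMParams) -> float:
    """Most severe per-indel log-score drop relative to the match path.

    Insertion: swap a Match transition+reference emission for an Insert
    transition+uniform emission.  Deletion: swap a Match transition for
    the (split) Delete entry.  The minimum (most negative) of the two is
    the budget cost charged per allowed indel in :func:`compute_tau`.
    """
    per_match = math.log(params.match_to_match) + math.log(params.ref_emission)
    ins = math.log(params.alt_event) + math.log(0.25) - per_match
    dele = math.log(params.alt_event / 2.0) - math.log(params.match_to_match)
    return min(ins, dele)


def compute_tau(hmm: MultiMotifHMM, m: int, delta: int) -> float:
    """Score cutoff for banded parsing of a read of length ``m``.

    ``tau`` is the score of an idealised error-free parse minus a budget
    of ``delta`` worst-case indel penalties.  The idealised score
    accounts for the structural costs every real parse must pay -- entry
    into the model, one Motif-End -> Motif-Start transition per motif
    copy spanned, and the read-end exit -- so that any read within the
    indel budget is guaranteed not to be pruned.  tau is monotonically
    decreasing in ``delta``.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    p = hmm.params
    per_match = math.log(p.match_to_match) + math.log(p.ref_emission)
    # worst entry cost: cheapest guaranteed way into the model
    entry = float(np.min(np.concatenate([
        hmm.s_logp[hmm.s_src == hmm.start],
        hmm.e_logp[hmm.e_src == hmm.start],
    ])))
    # per-copy cycling cost and number of copies a read can span
    is_ue = hmm.kind[hmm.s_src] == UNIT_END
    is_us = hmm.kind[hmm.s_dst] == UNIT_START
    cyc_edges = hmm.s_logp[is_ue & is_us]
    cycle = float(np.min(cyc_edges)) if cyc_edges.size else 0.0
    w_min = min(len(hmm.unit_seqs[t]) for t in hmm.motif_units)
    n_cycles = math.ceil(m / w_min) + 1
    # worst proper read-end exit (direct Match -> End hook)
    into_end = hmm.s_logp[hmm.s_dst == hmm.end]
    exit_cost = float(np.min(into_end)) if into_end.size else 0.0
    best = m * per_match + entry + n_cycles * cycle + exit_cost
    return best + delta * worst_indel_penalty(p)


def default_delta(locus: "VNTRLocus") -> int:
    """Default indel budget: half the consensus motif length."""
    return max(1, math.ceil(len(locus.consensus_motif) / 2))
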