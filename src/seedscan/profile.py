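"""Motif-profile construction: exact seeding, mismatch extension, scoring and
overlap filtering.

A *motif* is an ungapped, mismatch-containing matched region between query and
target, grown from a perfect k-mer seed.  Its score is
``(p*s_p + q*s_q) * (p + q)`` where ``p``/``q`` count matching/mismatching
positions — long near-perfect regions are rewarded super-linearly.

Conventions:

- ``N`` never seeds and always counts as a mismatch during extension.
- Soft-masked positions never seed but match/mismatch by identity during
  extension.
- Reverse-orientation motifs are stored in forward target coordinates; query
  offset ``i`` of a reverse motif aligns to target position
  ``t_start + length - 1 - i``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Dict, List, Literal, Optional, Tuple

import numpy as np

from .sequence_io import Sequence, reverse_complement

__all__ = [
    "ScoringParams",
    "Seed",
    "Motif",
    "MotifProfile",
    "score_motif",
    "noise_threshold",
    "find_seeds",
    "extend_seed",
    "build_raw_profile",
    "filter_overlaps",
    "filter_overlaps_motifs",
]

Axis = Literal["target", "query"]
Orientation = Literal["forward", "reverse"]


@dataclass(frozen=True)
class ScoringParams:
    """All tunables of the scanner, with their defaults.

    ``s_p``/``s_q`` are per-nucleotide match/mismatch scores; ``k`` the minimum
    seed size; ``noise_word_len`` the perfect-word length defining the noise
    threshold; the remaining fields control windowing, pattern geometry,
    region calling and ranking.
    """

    s_p: float = 1.0
    s_q: float = -1.0
    k: int = 8
    noise_word_len: int = 12
    window_step_fraction: float = 0.25
    max_distance: int = 200
    max_shift: int = 25
    mad_multiplier: float = 3.0
    top_n: int = 25

    def __post_init__(self) -> None:
        if not (self.s_p > 0 > self.s_q):
            raise ValueError("require s_p > 0 > s_q")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.noise_word_len < self.k:
            raise ValueError("noise_word_len must be >= k")
        if not (0 < self.window_step_fraction <= 1):
            raise ValueError("window_step_fraction must be in (0, 1]")
        if self.max_distance <= 0 or self.max_shift <= 0:
            raise ValueError("max_distance and max_shift must be positive")
        if self.mad_multiplier < 0:
            raise ValueError("mad_multiplier must be >= 0")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


@dataclass(frozen=True)
class Seed:
    """A perfect k-mer match between query and the working-strand target."""

    q_start: int
    t_start: int
    length: int
    orientation: Orientation = "forward"


def score_motif(p: int, q: int, params: ScoringParams) -> float:
    """Score of a motif with ``p`` matches and ``q`` mismatches."""
    if p < 0 or q < 0 or p + q < 1:
        raise ValueError("require p >= 0, q >= 0, p + q >= 1")
    return (p * params.s_p + q * params.s_q) * (p + q)


def noise_threshold(params: ScoringParams) -> float:
    """Score of a perfect noise_word_len-mer; motifs below it are noise."""
    return score_motif(params.noise_word_len, 0, params)


def _longest_true_run(mask: np.ndarray) -> int:
    best = run = 0
    for v in mask:
        run = run + 1 if v else 0
        if run > best:
            best = run
    return best


@dataclass(frozen=True, eq=False)  # identity equality: match is an ndarray
class Motif:
    """Extended match region; see module docstring for coordinate conventions."""

    q_start: int
    t_start: int
    length: int
    orientation: Orientation
    match: np.ndarray  # bool per query offset
    p: int
    q: int
    score: float
    core_len: int

    @classmethod
    def build(
        cls,
        q_start: int,
        t_start: int,
        orientation: Orientation,
        match: np.ndarray,
        params: ScoringParams,
    ) -> "Motif":
        match = np.asarray(match, dtype=bool)
        p = int(match.sum())
        q = int(len(match) - p)
        return cls(
            q_start=q_start,
            t_start=t_start,
            length=len(match),
            orientation=orientation,
            match=match,
            p=p,
            q=q,
            score=score_motif(p, q, params),
            core_len=_longest_true_run(match),
        )

    # -- axis geometry -------------------------------------------------
    @property
    def q_end(self) -> int:
        return self.q_start + self.length

    @property
    def t_end(self) -> int:
        return self.t_start + self.length

    def axis_span(self, axis: Axis) -> Tuple[int, int]:
        if axis == "query":
            return self.q_start, self.q_end
        return self.t_start, self.t_end

    def target_pos_of_offset(self, i: int) -> int:
        if self.orientation == "forward":
            return self.t_start + i
        return self.t_start + self.length - 1 - i

    def key(self) -> Tuple[int, int, int, str]:
        return (self.q_start, self.t_start, self.length, self.orientation)

    def subset(self, lo: int, hi: int, params: ScoringParams) -> "Motif":
        """New motif restricted to query offsets ``[lo, hi)`` of this one."""
        if not (0 <= lo < hi <= self.length):
            raise ValueError("invalid offset range")
        if self.orientation == "forward":
            new_t = self.t_start + lo
        else:
            new_t = self.t_start + self.length - hi
        return Motif.build(
            self.q_start + lo, new_t, self.orientation, self.match[lo:hi], params
        )


@dataclass
class MotifProfile:
    """The motif set for one (query, target record) comparison."""

    motifs: List[Motif]
    query_len: int
    target_id: str = "target"
    query_id: str = "query"


# ---------------------------------------------------------------------------
# Seeding and extension
# ---------------------------------------------------------------------------

def _valid_kmer_starts(seq: Sequence, k: int) -> np.ndarray:
    """Boolean array over start positions: k-mer free of N and soft-masking."""
    n = len(seq)
    if n < k:
        return np.zeros(0, dtype=bool)
    arr = np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)
    invalid = (arr == ord("N")) | seq.mask
    c = np.concatenate(([0], np.cumsum(invalid, dtype=np.int64)))
    return (c[k:] - c[:-k]) == 0


def find_seeds(
    query: Sequence,
    target: Sequence,
    params: ScoringParams,
    orientation: Orientation = "forward",
) -> List[Seed]:
    """All perfect, N-free, unmasked shared k-mers, ascending (q_start, t_start)."""
    k = params.k
    if len(query) < k or len(target) < k:
        return []
    t_valid = _valid_kmer_starts(target, k)
    index: Dict[str, List[int]] = {}
    tres = target.residues
    for j in np.flatnonzero(t_valid):
        index.setdefault(tres[j : j + k], []).append(int(j))
    q_valid = _valid_kmer_starts(query, k)
    qres = query.residues
    seeds: List[Seed] = []
    for i in np.flatnonzero(q_valid):
        hits = index.get(qres[i : i + k])
        if hits:
            seeds.extend(Seed(int(i), j, k, orientation) for j in hits)
    return seeds


def _extend_direction(
    query: Sequence,
    target: Sequence,
    q0: int,
    t0: int,
    step: int,
    seed_score: float,
    params: ScoringParams,
) -> List[bool]:
    """Grow one direction; return the kept extension's match flags (seed-outward).

    The running score starts at the seed score and advances per base; growth
    stops when it drops below 0 or a sequence end is hit, then the extension is
    truncated to the shortest prefix achieving the maximal running score.
    """
    qres, tres = query.residues, target.residues
    qn, tn = len(query), len(target)
    run = seed_score
    best, best_len = seed_score, 0
    flags: List[bool] = []
    d = 1
    while True:
        qi, ti = q0 + step * d, t0 + step * d
        if not (0 <= qi < qn and 0 <= ti < tn):
            break
        is_match = qres[qi] == tres[ti] and qres[qi] != "N"
        run += params.s_p if is_match else params.s_q
        flags.append(is_match)
        if run > best:
            best, best_len = run, d
        if run < 0:
            break
        d += 1
    return flags[:best_len]


def extend_seed(
    query: Sequence, target: Sequence, seed: Seed, params: ScoringParams
) -> Motif:
    """Bidirectional mismatch extension of one seed (working-strand coords)."""
    seed_score = seed.length * params.s_p
    down = _extend_direction(
        query, target, seed.q_start + seed.length - 1, seed.t_start + seed.length - 1,
        +1, seed_score, params,
    )
    up = _extend_direction(
        query, target, seed.q_start, seed.t_start, -1, seed_score, params
    )
    match = np.array(up[::-1] + [True] * seed.length + down, dtype=bool)
    return Motif.build(
        seed.q_start - len(up), seed.t_start - len(up), seed.orientation, match, params
    )


def build_raw_profile(
    query: Sequence, target: Sequence, params: ScoringParams
) -> MotifProfile:
    """Seed and extend on both target strands; map reverse hits to forward
    coordinates; collapse exact duplicates."""
    seen = {}
    for seed in find_seeds(query, target, params, "forward"):
        m = extend_seed(query, target, seed, params)
        seen.setdefault(m.key(), m)
    rc = reverse_complement(target)
    tlen = len(target)
    for seed in find_seeds(query, rc, params, "reverse"):
        m = extend_seed(query, rc, seed, params)
        m = replace(m, t_start=tlen - (m.t_start + m.length))
        seen.setdefault(m.key(), m)
    motifs = sorted(seen.values(), key=lambda m: (m.t_start, m.q_start, m.orientation))
    return MotifProfile(motifs, len(query), target.id, query.id)


# ---------------------------------------------------------------------------
# Overlap filtering
# ---------------------------------------------------------------------------

def _rank_key(m: Motif, axis: Axis):
    # score desc, length desc, axis coordinate asc, forward before reverse
    return (-m.score, -m.length, m.axis_span(axis)[0], 0 if m.orientation == "forward" else 1)


def _axis_to_offsets(m: Motif, axis: Axis, a_lo: int, a_hi: int) -> Tuple[int, int]:
    """Map an axis sub-interval of the motif to query-offset range [lo, hi)."""
    s, _ = m.axis_span(axis)
    if axis == "query" or m.orientation == "forward":
        return a_lo - s, a_hi - s
    # reverse motif on the target axis: coordinates run opposite to offsets
    return (s + m.length) - a_hi, (s + m.length) - a_lo


def _truncate_against(
    m: Motif, axis: Axis, o_lo: int, o_hi: int, params: ScoringParams
) -> Optional[Motif]:
    """Cut ``m`` on the side(s) where it overlaps axis interval [o_lo, o_hi),
    then pull the cut edge in to the next matching nucleotide.  Returns None
    when nothing survives."""
    s, e = m.axis_span(axis)
    left = (s, min(o_lo, e)) if o_lo > s else None       # retained left part
    right = (max(o_hi, s), e) if o_hi < e else None      # retained right part
    if left is None and right is None:
        return None
    if left is not None and right is not None:
        # placed motif strictly inside: keep the larger side, ties keep left
        keep = left if (left[1] - left[0]) >= (right[1] - right[0]) else right
        edge_is_high = keep is left
    elif left is not None:
        keep, edge_is_high = left, True    # cut on the high-coordinate side
    else:
        keep, edge_is_high = right, False  # cut on the low-coordinate side
    lo, hi = _axis_to_offsets(m, axis, keep[0], keep[1])
    # which offset-side sits against the overlap boundary
    trim_high = edge_is_high if (axis == "query" or m.orientation == "forward") else not edge_is_high
    if trim_high:
        while hi > lo and not m.match[hi - 1]:
            hi -= 1
    else:
        while lo < hi and not m.match[lo]:
            lo += 1
    if hi <= lo:
        return None
    return m.subset(lo, hi, params)


def filter_overlaps_motifs(
    motifs: List[Motif], axis: Axis, params: ScoringParams
) -> List[Motif]:
    """Greedy rank-and-place overlap resolution on one axis.

    Motifs are placed in rank order (score desc, length desc, coordinate asc,
    forward first).  A lower-ranked motif overlapping an already-placed one of
    *different* score is truncated on the overlapping side to the next matching
    nucleotide and rescored; equal-score overlaps are allowed untouched.
    Motifs whose perfect-match core drops below ``k`` are discarded.
    """
    ranked = sorted(motifs, key=lambda m: _rank_key(m, axis))
    placed: List[Motif] = []
    starts: List[int] = []  # placed axis starts, kept sorted for bisect pruning

    def overlapping_placed(lo: int, hi: int) -> List[Motif]:
        out = []
        idx = bisect.bisect_left(starts, hi)
        for j in range(idx):
            pm = placed[j]
            ps, pe = pm.axis_span(axis)
            if pe > lo:
                out.append(pm)
        return out

    kept: List[Motif] = []
    for m in ranked:
        entry_score = m.score
        cur: Optional[Motif] = m
        while cur is not None:
            lo, hi = cur.axis_span(axis)
            conflict = None
            for pm in overlapping_placed(lo, hi):
                if pm.score != entry_score:
                    conflict = pm
                    break
            if conflict is None:
                break
            o_lo, o_hi = conflict.axis_span(axis)
            cur = _truncate_against(cur, axis, o_lo, o_hi, params)
            if cur is not None and cur.core_len < params.k:
                cur = None
        if cur is None:
            continue
        kept.append(cur)
        s = cur.axis_span(axis)[0]
        j = bisect.bisect_left(starts, s)
        starts.insert(j, s)
        placed.insert(j, cur)
    kept.sort(key=lambda m: (m.t_start, m.q_start, m.orientation))
    return kept


def filter_overlaps(
    profile: MotifProfile, axis: Axis, params: ScoringParams
) -> MotifProfile:
    return MotifProfile(
        filter_overlaps_motifs(profile.motifs, axis, params),
        profile.query_len,
        profile.target_id,
        profile.query_id,
    )


def profile_to_tsv(profile: MotifProfile, path) -> None:
    """Debug dump; fixed column order."""
    with open(path, "w") as fh:
        fh.write(
            "query_id\ttarget_id\tq_start\tq_end\tt_start\tt_end\t"
            "orientation\tp\tq\tscore\tcore_len\n"
        )
        for m in profile.motifs:
            fh.write(
                f"{profile.query_id}\t{profile.target_id}\t{m.q_start}\t{m.q_end}\t"
                f"{m.t_start}\t{m.t_end}\t{m.orientation}\t{m.p}\t{m.q}\t"
                f"{m.score!r}\t{m.core_len}\n"
            )
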