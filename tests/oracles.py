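"""Independent brute-force references for the scanner's operations.

Everything here is a literal, unoptimised transcription of the stated rules:
nested loops, position sets and the focal-distance definition of an ellipse.
None of it shares code paths with the package implementation.
"""

from __future__ import annotations

import math
from itertools import groupby
from typing import List, Optional, Tuple


def brute_seeds(query, target, k: int) -> List[Tuple[int, int]]:
    """All (q, t) offset pairs with identical, N-free, unmasked k-mers."""
    out = []
    for i in range(len(query.residues) - k + 1):
        qw = query.residues[i : i + k]
        if "N" in qw or any(query.mask[i : i + k]):
            continue
        for j in range(len(target.residues) - k + 1):
            tw = target.residues[j : j + k]
            if "N" in tw or any(target.mask[j : j + k]):
                continue
            if qw == tw:
                out.append((i, j))
    return out


def _is_match(a: str, b: str) -> bool:
    return a == b and a != "N"


def brute_extend(query, target, q0: int, t0: int, k: int, s_p: float, s_q: float):
    """Reference extension: per direction enumerate every reachable extension
    length, score it as seed + plain running sum, keep max score then min
    length.  Returns (q_start, t_start, length, match_flags)."""
    seed_score = k * s_p

    def direction(step: int, qe: int, te: int) -> int:
        # candidate scores by extension length, stopping past the first run < 0
        scores = {0: seed_score}
        run = seed_score
        d = 1
        while 0 <= qe + step * d < len(query.residues) and 0 <= te + step * d < len(
            target.residues
        ):
            run += s_p if _is_match(query.residues[qe + step * d], target.residues[te + step * d]) else s_q
            scores[d] = run
            if run < 0:
                break
            d += 1
        best = max(scores.values())
        return min(l for l, s in scores.items() if s == best)

    up = direction(-1, q0, t0)
    down = direction(+1, q0 + k - 1, t0 + k - 1)
    qs = q0 - up
    length = up + k + down
    flags = [
        _is_match(query.residues[qs + i], target.residues[t0 - up + i])
        for i in range(length)
    ]
    return qs, t0 - up, length, flags


def brute_score(p: int, q: int, s_p: float, s_q: float) -> float:
    return (p * s_p + q * s_q) * (p + q)


class RefMotif:
    """Plain record used by the reference filters: query offsets <-> axis
    positions kept as explicit position lists."""

    def __init__(self, q_start, t_start, length, orientation, flags, s_p, s_q):
        self.q_start = q_start
        self.t_start = t_start
        self.length = length
        self.orientation = orientation
        self.flags = list(flags)
        self.s_p, self.s_q = s_p, s_q

    @property
    def score(self) -> float:
        p = sum(self.flags)
        return brute_score(p, self.length - p, self.s_p, self.s_q)

    @property
    def core(self) -> int:
        best = run = 0
        for f in self.flags:
            run = run + 1 if f else 0
            best = max(best, run)
        return best

    def axis_positions(self, axis: str) -> List[int]:
        if axis == "query":
            return list(range(self.q_start, self.q_start + self.length))
        return list(range(self.t_start, self.t_start + self.length))

    def offset_of_axis_pos(self, axis: str, pos: int) -> int:
        if axis == "query":
            return pos - self.q_start
        if self.orientation == "forward":
            return pos - self.t_start
        return (self.t_start + self.length - 1) - pos

    def restricted_to_axis_positions(self, axis: str, keep: List[int]) -> Optional["RefMotif"]:
        """Sub-motif over a contiguous run of axis positions."""
        if not keep:
            return None
        offs = sorted(self.offset_of_axis_pos(axis, p) for p in keep)
        lo, hi = offs[0], offs[-1] + 1
        new_q = self.q_start + lo
        if self.orientation == "forward":
            new_t = self.t_start + lo
        else:
            new_t = self.t_start + self.length - hi
        return RefMotif(
            new_q, new_t, hi - lo, self.orientation, self.flags[lo:hi], self.s_p, self.s_q
        )

    def signature(self):
        return (self.q_start, self.t_start, self.length, self.orientation,
                tuple(self.flags))


def brute_filter_overlaps(motifs: List[RefMotif], axis: str, k: int) -> List[RefMotif]:
    """Literal rank-and-place filtering using axis position sets."""
    def rank_key(m: RefMotif):
        return (-m.score, -m.length, m.axis_positions(axis)[0],
                0 if m.orientation == "forward" else 1)

    placed: List[RefMotif] = []
    for m in sorted(motifs, key=rank_key):
        entry_score = m.score
        cur: Optional[RefMotif] = m
        while cur is not None:
            cur_pos = set(cur.axis_positions(axis))
            conflict = None
            for pm in placed:
                if pm.score != entry_score and cur_pos & set(pm.axis_positions(axis)):
                    conflict = pm
                    break
            if conflict is None:
                break
            over = set(conflict.axis_positions(axis))
            s, e = min(cur_pos), max(cur_pos) + 1
            o_s, o_e = min(over), max(over) + 1
            left = [p for p in range(s, min(o_s, e))]
            right = [p for p in range(max(o_e, s), e)]
            if not left and not right:
                cur = None
                break
            if left and right:
                keep, edge_high = (left, True) if len(left) >= len(right) else (right, False)
            elif left:
                keep, edge_high = left, True
            else:
                keep, edge_high = right, False
            # pull the cut edge in to the next matching nucleotide
            while keep:
                edge = keep[-1] if edge_high else keep[0]
                if cur.flags[cur.offset_of_axis_pos(axis, edge)]:
                    break
                keep = keep[:-1] if edge_high else keep[1:]
            cur = cur.restricted_to_axis_positions(axis, keep)
            if cur is not None and cur.core < k:
                cur = None
        if cur is not None:
            placed.append(cur)
    return placed


def brute_in_ellipse(
    anchor_xy: Tuple[float, float],
    cand_xy: Tuple[float, float],
    window_len: float,
    max_shift: float,
) -> bool:
    """Focal-distance definition: inside iff the summed distances to the two
    foci do not exceed 2a, for either of the two ellipses sharing the anchor
    focus."""
    b = max_shift
    c = window_len / 2.0
    a = math.hypot(c, b)
    x0, y0 = anchor_xy
    x, y = cand_xy
    for other_focus_x in (x0 + window_len, x0 - window_len):
        d = math.hypot(x - x0, y - y0) + math.hypot(x - other_focus_x, y - y0)
        if d <= 2 * a + 1e-12:
            return True
    return False


def brute_assemble_patterns(
    members: List[dict], window_start: int, window_len: int,
    max_distance: int, max_shift: int, threshold: float,
):
    """Reference pattern partition over plain dict motifs with keys
    q_start/q_end/t_start/t_end/score/orientation.  Returns a list of member
    index lists."""
    def center(m):
        return (
            (m["q_start"] + m["q_end"]) / 2.0,
            ((m["t_start"] + m["t_end"]) / 2.0 - window_start)
            - (m["q_start"] + m["q_end"]) / 2.0,
        )

    idx_pool = [i for i, m in enumerate(members) if m["orientation"] == "forward"]
    anchors = sorted(
        (i for i in idx_pool if members[i]["score"] >= threshold),
        key=lambda i: (
            -members[i]["score"],
            -(members[i]["q_end"] - members[i]["q_start"]),
            members[i]["q_start"],
        ),
    )
    assigned = set()
    patterns = []
    for ai in anchors:
        if ai in assigned:
            continue
        cands = [
            i
            for i in idx_pool
            if i not in assigned
            and brute_in_ellipse(center(members[ai]), center(members[i]),
                                 window_len, max_shift)
        ]
        cands.sort(key=lambda i: (members[i]["q_start"], members[i]["t_start"]))
        pos = cands.index(ai)

        def ok(prev_i, next_i):
            return (
                members[next_i]["q_start"] - members[prev_i]["q_end"] <= max_distance
                and members[next_i]["t_start"] - members[prev_i]["t_end"] <= max_distance
            )

        chain = [ai]
        for i in cands[pos + 1 :]:
            if ok(chain[-1], i):
                chain.append(i)
        for i in reversed(cands[:pos]):
            if ok(i, chain[0]):
                chain.insert(0, i)
        n_above = sum(1 for i in chain if members[i]["score"] >= threshold)
        if len(chain) >= 3 and n_above >= 2:
            patterns.append(chain)
            assigned.update(chain)
    return patterns


def brute_median(values: List[float]) -> float:
    """Sort-based median, independent of numpy."""
    vs = sorted(values)
    n = len(vs)
    mid = n // 2
    return vs[mid] if n % 2 else (vs[mid - 1] + vs[mid]) / 2.0


def brute_mad_threshold(values: List[float], mult: float) -> float:
    med = brute_median(values)
    return med + mult * brute_median([abs(v - med) for v in values])


def brute_call_regions(scores: List[float], threshold: float):
    """Run-length encoding of the strict-above mask; returns a list of
    (first_index, last_index, max_score) runs."""
    out = []
    i = 0
    for above, grp in groupby(scores, key=lambda s: s > threshold):
        block = list(grp)
        if above:
            out.append((i, i + len(block) - 1, max(block)))
        i += len(block)
    return out
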