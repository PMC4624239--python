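"""Co-linear pattern detection inside a window's filtered motif profile.

A pattern is a chain of motifs sharing approximately one query-target diagonal.
Membership is decided by an elliptical search space around an anchor motif in
(query-center, shift) coordinates: two ellipses sharing the anchor's position
as a common focus, extending one window length up- and downstream along the
anchor's diagonal, with semi-minor axis ``max_shift`` across it.  Chains are
grown greedily from the strongest motif outward; a valid pattern needs at
least three members of which at least two score at or above the noise
threshold, so sub-threshold motifs can be rescued by context.  Each pattern is
scored as a weighted sum of member scores, with weights derived from the mean
inter-motif gap and per-member shift deviation from the weighted pattern
midline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

from .profile import Motif, ScoringParams, noise_threshold
from .sequence_io import GenomicInterval

__all__ = [
    "Pattern",
    "motif_shift",
    "in_motif_space",
    "assemble_patterns",
    "pattern_metrics",
    "pattern_weights",
    "factor_distance",
    "factor_shift",
    "weighted_pattern_score",
    "score_comb",
]


@dataclass
class Pattern:
    """A co-linear motif cluster; members ordered by query start."""

    members: List[Motif]
    shifts: List[float] = field(default_factory=list)  # window-local, per member
    mean_distance: Optional[float] = None
    pattern_shift: Optional[float] = None
    weights: List[float] = field(default_factory=list)
    pattern_score: Optional[float] = None


def motif_shift(m: Motif, window: GenomicInterval) -> float:
    """Signed diagonal offset: window-local target center minus query center."""
    t_center = (m.t_start + m.t_end) / 2.0 - window.start
    q_center = (m.q_start + m.q_end) / 2.0
    return t_center - q_center


def in_motif_space(
    anchor: Motif,
    candidate: Motif,
    window: GenomicInterval,
    params: ScoringParams,
    window_len: Optional[int] = None,
) -> bool:
    """Candidate center inside either ellipse anchored at the anchor's center.

    In (query-center, shift) coordinates both ellipses are axis-aligned: foci
    separated by the window length along the anchor's diagonal (constant
    shift), semi-minor axis ``b = max_shift``, semi-major axis
    ``a = sqrt((window_len/2)^2 + b^2)``; the anchor occupies the shared focus.
    """
    if window_len is None:
        window_len = window.length()
    b = float(params.max_shift)
    c = window_len / 2.0
    a = math.sqrt(c * c + b * b)
    x0 = (anchor.q_start + anchor.q_end) / 2.0
    y0 = motif_shift(anchor, window)
    x = (candidate.q_start + candidate.q_end) / 2.0
    y = motif_shift(candidate, window)
    dy2 = ((y - y0) / b) ** 2
    for xc in (x0 + c, x0 - c):
        if ((x - xc) / a) ** 2 + dy2 <= 1.0:
            return True
    return False


def _gap_ok(prev: Motif, nxt: Motif, params: ScoringParams) -> bool:
    """Consecutive inter-motif gap (end to start) within bounds on both axes."""
    return (
        nxt.q_start - prev.q_end <= params.max_distance
        and nxt.t_start - prev.t_end <= params.max_distance
    )


def _anchor_rank_key(m: Motif):
    return (-m.score, -m.length, m.q_start, 0 if m.orientation == "forward" else 1)


def assemble_patterns(
    motifs: Sequence[Motif], window: GenomicInterval, params: ScoringParams
) -> List[Pattern]:
    """Ranked-greedy pattern partition of a window's filtered selection.

    Input is the target- and query-filtered selection *before* noise-threshold
    removal.  Only forward-orientation motifs participate (the diagonal is
    ill-defined across orientations).  Anchors must score at or above the
    noise threshold; candidates in the anchor's motif space are chained
    outward from the anchor by query order under the inter-motif gap limit.
    Patterns failing the >=3 member / >=2 above-threshold rule dissolve and
    release their members.
    """
    thr = noise_threshold(params)
    pool = [m for m in motifs if m.orientation == "forward"]
    anchors = sorted((m for m in pool if m.score >= thr), key=_anchor_rank_key)
    assigned: set = set()
    patterns: List[Pattern] = []
    for anchor in anchors:
        if id(anchor) in assigned:
            continue
        cands = [
            m
            for m in pool
            if id(m) not in assigned
            and in_motif_space(anchor, m, window, params)
        ]
        cands.sort(key=lambda m: (m.q_start, m.t_start))
        ai = next(i for i, m in enumerate(cands) if m is anchor)
        chain = [anchor]
        for m in cands[ai + 1 :]:  # grow downstream of the anchor
            if _gap_ok(chain[-1], m, params):
                chain.append(m)
        head = [anchor]
        for m in reversed(cands[:ai]):  # grow upstream
            if _gap_ok(m, head[0], params):
                head.insert(0, m)
        members = head[:-1] + chain
        n_above = sum(1 for m in members if m.score >= thr)
        if len(members) >= 3 and n_above >= 2:
            pat = Pattern(members=members)
            pattern_metrics(pat, params, window)
            pattern_weights(pat, params)
            patterns.append(pat)
            assigned.update(id(m) for m in members)
    return patterns


def pattern_metrics(
    p: Pattern, params: ScoringParams, window: GenomicInterval
) -> Pattern:
    """Mean inter-motif gap (target axis) and length-weighted mean shift."""
    if len(p.members) < 2:
        raise ValueError("pattern metrics need at least two members")
    gaps = [
        p.members[i + 1].t_start - p.members[i].t_end
        for i in range(len(p.members) - 1)
    ]
    p.mean_distance = sum(gaps) / len(gaps)
    p.shifts = [motif_shift(m, window) for m in p.members]
    total_len = sum(m.length for m in p.members)
    p.pattern_shift = (
        sum(m.length * s for m, s in zip(p.members, p.shifts)) / total_len
    )
    return p


def factor_distance(mean_distance: float, params: ScoringParams) -> float:
    """Pattern-wide compactness factor: 1 at zero mean gap, 0 at the limit."""
    return 1.0 - mean_distance / params.max_distance


def factor_shift(shift: float, pattern_shift: float, params: ScoringParams) -> float:
    """Per-member diagonal-agreement factor relative to the pattern midline."""
    return 1.0 - abs(shift - pattern_shift) / (2.0 * params.max_shift)


def weighted_pattern_score(
    scores: Sequence[float], weights: Sequence[float]
) -> float:
    """Weighted sum of member scores — the bonus one pattern contributes."""
    return sum(s * w for s, w in zip(scores, weights, strict=True))


def pattern_weights(p: Pattern, params: ScoringParams) -> Pattern:
    """Per-member weights from the distance and shift correction factors,
    clamped to [0, 1]; also fills in the weighted pattern score."""
    if p.mean_distance is None or p.pattern_shift is None:
        raise ValueError("call pattern_metrics first")
    f_dist = factor_distance(p.mean_distance, params)
    p.weights = [
        min(1.0, max(0.0, (f_dist + factor_shift(s, p.pattern_shift, params)) / 2.0))
        for s in p.shifts
    ]
    p.pattern_score = weighted_pattern_score(
        [m.score for m in p.members], p.weights
    )
    return p


def score_comb(
    pure: float, patterns: Sequence[Pattern], params: ScoringParams
) -> float:
    """Basic score plus the weighted score of every detected pattern."""
    return pure + sum(p.pattern_score for p in patterns)
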