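"""Sliding-window scoring: window grid, motif selection and the basic
(pattern-free) window similarity score."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .profile import Motif, MotifProfile, ScoringParams, filter_overlaps_motifs, noise_threshold
from .sequence_io import GenomicInterval

__all__ = ["WindowScore", "iter_windows", "select_window_motifs", "score_pure"]


@dataclass
class WindowScore:
    """One window's interval plus its basic and pattern-augmented scores."""

    window: GenomicInterval
    score_pure: float
    score_comb: float
    patterns: list = field(default_factory=list)
    n_motifs_valid: int = 0


def iter_windows(
    target_len: int, query_len: int, params: ScoringParams, seq_id: str = "target"
) -> List[GenomicInterval]:
    """Window grid over the target: size = min(query, target) length, stepping
    by ``window_step_fraction`` of the window size (nearest integer, min 1).
    A flush-right window is appended when the regular grid stops short."""
    if target_len < 1 or query_len < 1:
        raise ValueError("lengths must be >= 1")
    size = min(query_len, target_len)
    step = max(1, round(size * params.window_step_fraction))
    windows = []
    start = 0
    while start + size <= target_len:
        windows.append(GenomicInterval(seq_id, start, start + size))
        start += step
    if windows[-1].end < target_len:
        windows.append(GenomicInterval(seq_id, target_len - size, target_len))
    return windows


def select_window_motifs(
    profile: MotifProfile, window: GenomicInterval
) -> List[Motif]:
    """All motifs whose target interval intersects the window, including
    partial boundary overlaps, unmodified (they virtually extend the window)."""
    return [
        m
        for m in profile.motifs
        if m.t_start < window.end and m.t_end > window.start
    ]


class _WindowIndex:
    """Vectorised window->motif selection used by the scan loop."""

    def __init__(self, profile: MotifProfile):
        self.motifs = profile.motifs
        self.starts = np.array([m.t_start for m in profile.motifs], dtype=np.int64)
        self.ends = np.array([m.t_end for m in profile.motifs], dtype=np.int64)

    def select(self, window: GenomicInterval) -> List[Motif]:
        if len(self.motifs) == 0:
            return []
        hit = (self.starts < window.end) & (self.ends > window.start)
        return [self.motifs[i] for i in np.flatnonzero(hit)]


def score_pure(
    motifs: List[Motif], window: GenomicInterval, params: ScoringParams
) -> Tuple[float, List[Motif]]:
    """Query-axis overlap filtering of the window's selection, then noise
    filtering; returns (sum of surviving scores, survivors)."""
    filtered = filter_overlaps_motifs(motifs, "query", params)
    thr = noise_threshold(params)
    valid = [m for m in filtered if m.score >= thr]
    return float(sum(m.score for m in valid)), valid
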