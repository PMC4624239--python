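"""End-to-end scan of one query against a (multi-record) target.

Per target record: raw profile -> target-axis overlap filter -> window grid;
per window: motif selection, query-axis filter, noise filter, basic score,
pattern detection, combined score.  Thresholds are computed per scan (pooled
over all records of the target) and regions called and ranked per score type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence as PySequence

from .patterns import assemble_patterns, score_comb
from .profile import (
    MotifProfile,
    ScoringParams,
    build_raw_profile,
    filter_overlaps,
    filter_overlaps_motifs,
    noise_threshold,
)
from .regions import PredictedRegion, call_regions, mad_threshold, rank_predictions
from .sequence_io import Sequence
from .windows import WindowScore, _WindowIndex, iter_windows

__all__ = ["ScanResult", "scan"]

SCORE_TYPES = ("PURE", "COMB")


@dataclass
class ScanResult:
    query_id: str
    params: ScoringParams
    window_scores: Dict[str, List[WindowScore]] = field(default_factory=dict)
    profiles: Dict[str, MotifProfile] = field(default_factory=dict)
    thresholds: Dict[str, float] = field(default_factory=dict)
    regions: Dict[str, List[PredictedRegion]] = field(default_factory=dict)

    def all_windows(self) -> List[WindowScore]:
        out: List[WindowScore] = []
        for ws in self.window_scores.values():
            out.extend(ws)
        return out


def score_windows(
    query: Sequence, target: Sequence, params: ScoringParams
) -> tuple[List[WindowScore], MotifProfile]:
    """Window scores for one target record plus its target-filtered profile."""
    profile = filter_overlaps(build_raw_profile(query, target, params), "target", params)
    index = _WindowIndex(profile)
    thr = noise_threshold(params)
    out: List[WindowScore] = []
    for window in iter_windows(len(target), len(query), params, seq_id=target.id):
        selected = index.select(window)
        filtered = filter_overlaps_motifs(selected, "query", params)
        valid = [m for m in filtered if m.score >= thr]
        pure = float(sum(m.score for m in valid))
        pats = assemble_patterns(filtered, window, params)
        comb = score_comb(pure, pats, params)
        out.append(
            WindowScore(
                window=window,
                score_pure=pure,
                score_comb=comb,
                patterns=pats,
                n_motifs_valid=len(valid),
            )
        )
    return out, profile


def scan(
    query: Sequence,
    targets: PySequence[Sequence],
    params: ScoringParams | None = None,
) -> ScanResult:
    """Scan ``query`` against every target record independently; no window
    crosses a record boundary."""
    params = params or ScoringParams()
    result = ScanResult(query_id=query.id, params=params)
    for target in targets:
        ws, profile = score_windows(query, target, params)
        result.window_scores[target.id] = ws
        result.profiles[target.id] = profile
    pooled = result.all_windows()
    for score_type in SCORE_TYPES:
        attr = "score_pure" if score_type == "PURE" else "score_comb"
        threshold = mad_threshold([getattr(w, attr) for w in pooled], params)
        result.thresholds[score_type] = threshold
        regions: List[PredictedRegion] = []
        for target in targets:
            regions.extend(
                call_regions(
                    result.window_scores[target.id], score_type, threshold, query.id
                )
            )
        result.regions[score_type] = rank_predictions(regions, params)
    return result
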