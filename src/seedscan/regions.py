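"""Region calling: robust score threshold, run merging and ranking."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .profile import ScoringParams
from .sequence_io import GenomicInterval
from .windows import WindowScore

__all__ = ["PredictedRegion", "mad_threshold", "call_regions", "rank_predictions"]


@dataclass
class PredictedRegion:
    """A maximal run of above-threshold windows merged into one interval."""

    interval: GenomicInterval
    score_type: str  # "PURE" or "COMB"
    region_score: float
    peak_window: GenomicInterval
    query_id: str = "query"
    rank: int = 0


def mad_threshold(scores: Sequence[float], params: ScoringParams) -> float:
    """median + mad_multiplier * raw MAD (no consistency constant)."""
    if len(scores) == 0:
        raise ValueError("cannot compute a threshold from zero window scores")
    arr = np.asarray(scores, dtype=float)
    med = float(np.median(arr))
    mad = float(np.median(np.abs(arr - med)))
    return med + params.mad_multiplier * mad


def _score_of(ws: WindowScore, score_type: str) -> float:
    if score_type == "PURE":
        return ws.score_pure
    if score_type == "COMB":
        return ws.score_comb
    raise ValueError(f"unknown score type {score_type!r}")


def call_regions(
    window_scores: Sequence[WindowScore],
    score_type: str,
    threshold: float,
    query_id: str = "query",
) -> List[PredictedRegion]:
    """Merge maximal runs of consecutive windows scoring strictly above the
    threshold; region score is the maximum window score of the run."""
    regions: List[PredictedRegion] = []
    run: List[WindowScore] = []

    def flush():
        if not run:
            return
        peak = max(run, key=lambda w: _score_of(w, score_type))
        regions.append(
            PredictedRegion(
                interval=GenomicInterval(
                    run[0].window.seq_id, run[0].window.start, run[-1].window.end
                ),
                score_type=score_type,
                region_score=_score_of(peak, score_type),
                peak_window=peak.window,
                query_id=query_id,
            )
        )
        run.clear()

    for ws in window_scores:
        if _score_of(ws, score_type) > threshold:
            run.append(ws)
        else:
            flush()
    flush()
    return regions


def rank_predictions(
    regions: Sequence[PredictedRegion], params: ScoringParams
) -> List[PredictedRegion]:
    """Top-N regions by score; ties go to the longer interval, then ascending
    (seq_id, start).  Ranks are assigned 1..N."""
    ordered = sorted(
        regions,
        key=lambda r: (
            -r.region_score,
            -r.interval.length(),
            r.interval.seq_id,
            r.interval.start,
        ),
    )[: params.top_n]
    for i, r in enumerate(ordered, start=1):
        r.rank = i
    return ordered
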