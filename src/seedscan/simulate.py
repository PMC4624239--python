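"""Synthetic-evolution fixtures: enhancer pairs with conserved motif blocks,
fast-evolving spacers, optional block permutation, and embedding into a random
background genome — everything the scanner and the annotation stages consume,
generated deterministically from one seed.

The model is substitution-only: spacer turnover vs motif conservation is the
mechanism under test, and indels would only shift the truth coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence as PySequence, Tuple, Union

import numpy as np

from .annotation import GeneRecord, OrthologMap
from .sequence_io import GenomicInterval, Sequence

__all__ = [
    "EvolutionConfig",
    "PlantedTruth",
    "make_ancestor",
    "evolve",
    "permute_motifs",
    "embed_in_background",
    "make_annotation_fixture",
    "make_conservation_track_lines",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class EvolutionConfig:
    n_motifs: int = 8
    motif_len_range: Tuple[int, int] = (15, 25)
    spacer_len_range: Tuple[int, int] = (30, 60)
    motif_subst_rate: float = 0.05
    spacer_subst_rate: float = 0.4
    permute: bool = False
    background_len: int = 100_000
    gc_content: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("motif_subst_rate", "spacer_subst_rate", "gc_content"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("motif_len_range", "spacer_len_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or lo > hi:
                raise ValueError(f"degenerate {name}: ({lo}, {hi})")
        if self.n_motifs < 0:
            raise ValueError("n_motifs must be >= 0")
        if self.background_len < 1:
            raise ValueError("background_len must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


@dataclass
class PlantedTruth:
    """Ground truth of an embedded synthetic enhancer."""

    enhancer_interval: GenomicInterval
    motif_intervals: List[GenomicInterval] = field(default_factory=list)
    permutation: Optional[List[int]] = None


def _random_bases(n: int, gc: float, rng: np.random.Generator) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(_BASES, size=n, p=probs).tobytes().decode("ascii")


def make_ancestor(
    cfg: EvolutionConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[Sequence, List[Tuple[int, int]]]:
    """Alternating spacer/motif blocks; returns the sequence and the motif
    coordinates (0-based half-open), disjoint and in order."""
    rng = rng if rng is not None else cfg.rng()
    parts: List[str] = []
    coords: List[Tuple[int, int]] = []
    pos = 0

    def spacer() -> None:
        nonlocal pos
        n = int(rng.integers(cfg.spacer_len_range[0], cfg.spacer_len_range[1] + 1))
        parts.append(_random_bases(n, cfg.gc_content, rng))
        pos += n

    spacer()
    for _ in range(cfg.n_motifs):
        n = int(rng.integers(cfg.motif_len_range[0], cfg.motif_len_range[1] + 1))
        parts.append(_random_bases(n, cfg.gc_content, rng))
        coords.append((pos, pos + n))
        pos += n
        spacer()
    return Sequence(id="ancestor", residues="".join(parts)), coords


def evolve(
    seq: Sequence,
    motifs: PySequence[Tuple[int, int]],
    cfg: EvolutionConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Sequence, List[Tuple[int, int]]]:
    """Independent per-base substitution to a uniformly chosen *different*
    base: motif bases at ``motif_subst_rate``, spacer bases at
    ``spacer_subst_rate``.  Coordinates are unchanged (no indels)."""
    rng = rng if rng is not None else cfg.rng()
    n = len(seq)
    in_motif = np.zeros(n, dtype=bool)
    for s, e in motifs:
        if not (0 <= s < e <= n):
            raise ValueError(f"motif coordinates ({s}, {e}) outside sequence")
        in_motif[s:e] = True
    rate = np.where(in_motif, cfg.motif_subst_rate, cfg.spacer_subst_rate)
    hit = rng.random(n) < rate
    arr = np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8).copy()
    idx = np.flatnonzero(hit & (arr != ord("N")))
    if idx.size:
        # pick one of the 3 alternative bases per hit position
        cur = np.searchsorted(_BASES, arr[idx])
        offset = rng.integers(1, 4, size=idx.size)
        arr[idx] = _BASES[(cur + offset) % 4]
    return (
        Sequence(id=seq.id, residues=arr.tobytes().decode("ascii"), mask=seq.mask.copy()),
        list(motifs),
    )


def permute_motifs(
    seq: Sequence,
    motifs: PySequence[Tuple[int, int]],
    order: PySequence[int],
    rng_seed: Union[int, np.random.Generator, None] = None,
    resample_spacers: bool = True,
    gc_content: float = 0.5,
) -> Tuple[Sequence, List[Tuple[int, int]]]:
    """Reorder motif blocks per ``order``; spacers keep their lengths and are
    freshly resampled (unless disabled) so block junctions carry no residual
    seeds.  Returns the rebuilt sequence and the new motif coordinates, listed
    in the order of ``order`` (i.e. entry i is the new home of motif order[i]).
    """
    if sorted(order) != list(range(len(motifs))):
        raise ValueError("order must be a permutation of motif indices")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    bounds = [0] + [x for s, e in motifs for x in (s, e)] + [len(seq)]
    spacers = [
        seq.residues[bounds[2 * i] : bounds[2 * i + 1]]
        for i in range(len(motifs) + 1)
    ]
    if resample_spacers:
        spacers = [_random_bases(len(sp), gc_content, rng) for sp in spacers]
    blocks = [seq.residues[s:e] for s, e in motifs]
    parts: List[str] = []
    coords: List[Tuple[int, int]] = []
    pos = 0
    for i, src in enumerate(order):
        parts.append(spacers[i])
        pos += len(spacers[i])
        parts.append(blocks[src])
        coords.append((pos, pos + len(blocks[src])))
        pos += len(blocks[src])
    parts.append(spacers[-1])
    return Sequence(id=seq.id, residues="".join(parts)), coords


def embed_in_background(
    region: Sequence,
    cfg: EvolutionConfig,
    position: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    motif_coords: PySequence[Tuple[int, int]] = (),
    seq_id: str = "chr_sim",
) -> Tuple[Sequence, PlantedTruth]:
    """Insert the region into an i.i.d. random background of
    ``background_len`` total length at a given or random offset."""
    rng = rng if rng is not None else cfg.rng()
    if len(region) > cfg.background_len:
        raise ValueError("region longer than the requested background")
    max_off = cfg.background_len - len(region)
    if position is None:
        position = int(rng.integers(0, max_off + 1))
    if not (0 <= position <= max_off):
        raise ValueError("embedding offset outside the background")
    left = _random_bases(position, cfg.gc_content, rng)
    right = _random_bases(max_off - position, cfg.gc_content, rng)
    genome = Sequence(id=seq_id, residues=left + region.residues + right)
    truth = PlantedTruth(
        enhancer_interval=GenomicInterval(seq_id, position, position + len(region)),
        motif_intervals=[
            GenomicInterval(seq_id, position + s, position + e)
            for s, e in motif_coords
        ],
    )
    return genome, truth


def make_conservation_track_lines(
    truth: PlantedTruth, seq_len: int, high: float = 0.9, low: float = 0.05
) -> List[str]:
    """bedGraph lines: high scores inside motif truth intervals, low outside."""
    chrom = truth.enhancer_interval.seq_id
    lines = []
    pos = 0
    for iv in sorted(truth.motif_intervals, key=lambda i: i.start):
        if iv.start > pos:
            lines.append(f"{chrom}\t{pos}\t{iv.start}\t{low}")
        lines.append(f"{chrom}\t{iv.start}\t{iv.end}\t{high}")
        pos = iv.end
    if pos < seq_len:
        lines.append(f"{chrom}\t{pos}\t{seq_len}\t{low}")
    return lines


# ---------------------------------------------------------------------------
# Annotation fixtures
# ---------------------------------------------------------------------------

def make_annotation_fixture(
    rng_seed: int = 0,
    margin: int = 1_500_000,
    gene_spacing: int = 200_000,
):
    """Paired synthetic gene layouts realizing each flank-status class by
    construction.

    Returns ``(query_genes, target_genes, OrthologMap, cases)`` where each
    case is ``(label, query_anchor, target_prediction)``; one case per class,
    each on its own chromosome pair so the scenarios cannot interact.
    """
    query_genes: List[GeneRecord] = []
    target_genes: List[GeneRecord] = []
    omap = OrthologMap()
    cases = []

    n_side = 6
    anchor_start = n_side * gene_spacing + gene_spacing // 2
    anchor = lambda chrom: GenomicInterval(chrom, anchor_start, anchor_start + 1_000)

    def layout(chrom: str, prefix: str, out: List[GeneRecord]) -> List[str]:
        """n_side genes on each side of the anchor; returns ids, upstream ones
        first (nearest-to-anchor ordering: index 0 = nearest upstream)."""
        ids = []
        for i in range(n_side):  # upstream, nearest first
            tss = anchor_start - (i + 1) * gene_spacing
            gid = f"{prefix}_up{i}"
            out.append(GeneRecord(gid, chrom, tss))
            ids.append(gid)
        for i in range(n_side):  # downstream, nearest first
            tss = anchor_start + 1_000 + (i + 1) * gene_spacing
            gid = f"{prefix}_dn{i}"
            out.append(GeneRecord(gid, chrom, tss))
            ids.append(gid)
        return ids

    scenarios = [
        ("double_flanked", "df"),
        ("single_flanked", "sf"),
        ("near_flank", "nf"),
        ("not_flanked", "nfl"),
        ("not_orthologous", "no"),
    ]
    for label, tag in scenarios:
        qchrom, tchrom = f"qchr_{tag}", f"tchr_{tag}"
        q_ids = layout(qchrom, f"q{tag}", query_genes)
        t_ids = layout(tchrom, f"t{tag}", target_genes)
        q_up0, q_dn0 = q_ids[0], q_ids[n_side]
        t_up0, t_dn0 = t_ids[0], t_ids[n_side]
        if label == "double_flanked":
            omap.add(q_up0, t_up0)
            omap.add(q_dn0, t_dn0)
        elif label == "single_flanked":
            omap.add(q_up0, t_up0)  # the other flanker's ortholog is absent
        elif label == "near_flank":
            omap.add(q_up0, t_ids[2])  # in the environment, not flanking
        elif label == "not_flanked":
            omap.add(q_ids[3], t_ids[2])  # non-flanking env gene's ortholog
        # not_orthologous: no pairs at all
        cases.append((label, anchor(qchrom), anchor(tchrom)))
    return query_genes, target_genes, omap, cases
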