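"""Candidate assessment: gene environments, orthologous-flank classification,
random motif sets and motif-conservation comparison.

Distances between genes and an anchor interval are measured TSS to nearest
anchor boundary.  A "flanking gene" is the gene with the nearest TSS strictly
on each side of the anchor; genes whose TSS falls inside the anchor count for
the nearer side.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
from scipy import stats

from .sequence_io import GenomicInterval

__all__ = [
    "GeneRecord",
    "OrthologMap",
    "FlankStatus",
    "ConservationTrack",
    "gene_environment",
    "flanking_genes",
    "classify_flanking",
    "random_motif_sets",
    "motif_conservation",
    "compare_conservation",
    "read_genes_bed",
    "read_genes_gff3",
    "read_ortholog_tsv",
    "read_bedgraph",
    "read_wiggle",
]

DEFAULT_MARGIN = 1_500_000
DEFAULT_MIN_PER_SIDE = 5

# classification labels, most specific first
DOUBLE_FLANKED = "double_flanked"
SINGLE_FLANKED = "single_flanked"
NEAR_FLANK = "near_flank"
NOT_FLANKED = "not_flanked"
NOT_ORTHOLOGOUS = "not_orthologous"
FLANK_STATUSES = (
    DOUBLE_FLANKED,
    SINGLE_FLANKED,
    NEAR_FLANK,
    NOT_FLANKED,
    NOT_ORTHOLOGOUS,
)


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    seq_id: str
    tss: int  # 0-based
    strand: str = "+"


class OrthologMap:
    """Query-gene -> target-gene pairs; paralogs are simply absent."""

    def __init__(self, pairs: Iterable[Tuple[str, str]] = ()):  # noqa: D401
        self._fwd: Dict[str, Set[str]] = {}
        self._rev: Dict[str, Set[str]] = {}
        for a, b in pairs:
            self.add(a, b)

    def add(self, query_gene: str, target_gene: str) -> None:
        self._fwd.setdefault(query_gene, set()).add(target_gene)
        self._rev.setdefault(target_gene, set()).add(query_gene)

    def targets_of(self, query_gene: str) -> Set[str]:
        return self._fwd.get(query_gene, set())

    def queries_of(self, target_gene: str) -> Set[str]:
        return self._rev.get(target_gene, set())

    def __len__(self) -> int:
        return sum(len(v) for v in self._fwd.values())


# ---------------------------------------------------------------------------
# Gene environments and flank classification
# ---------------------------------------------------------------------------

def _split_sides(
    anchor: GenomicInterval, genes: Sequence[GeneRecord]
) -> Tuple[List[GeneRecord], List[GeneRecord]]:
    """Partition one chromosome's genes into upstream/downstream of the anchor;
    genes with TSS inside the anchor go to the nearer boundary."""
    up: List[GeneRecord] = []
    down: List[GeneRecord] = []
    for g in genes:
        if g.seq_id != anchor.seq_id:
            continue
        if g.tss < anchor.start:
            up.append(g)
        elif g.tss >= anchor.end:
            down.append(g)
        else:
            if g.tss - anchor.start <= anchor.end - 1 - g.tss:
                up.append(g)
            else:
                down.append(g)
    up.sort(key=lambda g: g.tss)
    down.sort(key=lambda g: g.tss)
    return up, down


def _side_distance(anchor: GenomicInterval, g: GeneRecord, side: str) -> int:
    if side == "up":
        return max(0, anchor.start - g.tss)
    return max(0, g.tss - (anchor.end - 1))


def gene_environment(
    anchor: GenomicInterval,
    genes: Sequence[GeneRecord],
    margin: int = DEFAULT_MARGIN,
    min_per_side: int = DEFAULT_MIN_PER_SIDE,
) -> Tuple[List[GeneRecord], List[GeneRecord]]:
    """Genes within ``margin`` of the anchor boundaries, split by side; a side
    with fewer than ``min_per_side`` genes is extended to the nearest TSSs
    until the minimum is met or the chromosome is exhausted."""
    up, down = _split_sides(anchor, genes)
    out = []
    for side, pool in (("up", up), ("down", down)):
        within = [g for g in pool if _side_distance(anchor, g, side) <= margin]
        if len(within) < min_per_side:
            ranked = sorted(pool, key=lambda g: _side_distance(anchor, g, side))
            within = ranked[:min_per_side]
            within.sort(key=lambda g: g.tss)
        out.append(within)
    return out[0], out[1]


def flanking_genes(
    anchor: GenomicInterval, genes: Sequence[GeneRecord]
) -> Tuple[Optional[GeneRecord], Optional[GeneRecord]]:
    """Nearest-TSS gene on each side of the anchor (may be None at chr ends)."""
    up, down = _split_sides(anchor, genes)
    up_flank = max(up, key=lambda g: g.tss) if up else None
    down_flank = min(down, key=lambda g: g.tss) if down else None
    return up_flank, down_flank


def classify_flanking(
    query_anchor: GenomicInterval,
    query_genes: Sequence[GeneRecord],
    target_prediction: GenomicInterval,
    target_genes: Sequence[GeneRecord],
    orthologs: OrthologMap,
    margin: int = DEFAULT_MARGIN,
    min_per_side: int = DEFAULT_MIN_PER_SIDE,
) -> str:
    """Classify a target prediction by where orthologs of the query's
    environment genes land relative to the prediction.

    Classes, most specific first: both query flankers have orthologs flanking
    the prediction (double), exactly one does (single), a flanker's ortholog is
    in the target environment but not flanking (near_flank), an ortholog of a
    non-flanking environment gene is in the target environment (not_flanked),
    nothing orthologous nearby (not_orthologous).
    """
    if not any(g.seq_id == target_prediction.seq_id for g in target_genes):
        warnings.warn(
            f"prediction chromosome {target_prediction.seq_id!r} absent from "
            "target annotation; classifying as not_orthologous",
            stacklevel=2,
        )
        return NOT_ORTHOLOGOUS

    q_up, q_down = flanking_genes(query_anchor, query_genes)
    t_up, t_down = flanking_genes(target_prediction, target_genes)
    t_flank_ids = {g.gene_id for g in (t_up, t_down) if g is not None}

    q_env_up, q_env_down = gene_environment(
        query_anchor, query_genes, margin, min_per_side
    )
    t_env_up, t_env_down = gene_environment(
        target_prediction, target_genes, margin, min_per_side
    )
    t_env_ids = {g.gene_id for g in t_env_up + t_env_down}

    q_flankers = [g for g in (q_up, q_down) if g is not None]
    n_flanking_orth = sum(
        1 for g in q_flankers if orthologs.targets_of(g.gene_id) & t_flank_ids
    )
    if n_flanking_orth >= 2:
        return DOUBLE_FLANKED
    if n_flanking_orth == 1:
        return SINGLE_FLANKED
    if any(orthologs.targets_of(g.gene_id) & t_env_ids for g in q_flankers):
        return NEAR_FLANK
    flanker_ids = {g.gene_id for g in q_flankers}
    non_flanking_env = [
        g for g in q_env_up + q_env_down if g.gene_id not in flanker_ids
    ]
    if any(orthologs.targets_of(g.gene_id) & t_env_ids for g in non_flanking_env):
        return NOT_FLANKED
    return NOT_ORTHOLOGOUS


# ---------------------------------------------------------------------------
# Random motif sets and conservation
# ---------------------------------------------------------------------------

def random_motif_sets(
    region: GenomicInterval,
    motif_lengths: Sequence[int],
    n_sets: int = 10,
    rng_seed: Union[int, np.random.Generator, None] = None,
    max_tries: int = 10_000,
) -> List[List[GenomicInterval]]:
    """``n_sets`` independent placements of non-overlapping segments matching
    the requested lengths, uniform inside the region (rejection sampling)."""
    if any(l < 1 for l in motif_lengths):
        raise ValueError("motif lengths must be positive")
    if sum(motif_lengths) > region.length():
        raise ValueError("segments cannot fit in the region without overlap")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    sets: List[List[GenomicInterval]] = []
    for _ in range(n_sets):
        for _attempt in range(max_tries):
            placed: List[Tuple[int, int]] = []
            for length in motif_lengths:
                start = int(rng.integers(region.start, region.end - length + 1))
                placed.append((start, start + length))
            placed_sorted = sorted(placed)
            if all(
                placed_sorted[i][1] <= placed_sorted[i + 1][0]
                for i in range(len(placed_sorted) - 1)
            ):
                sets.append(
                    [GenomicInterval(region.seq_id, s, e) for s, e in placed]
                )
                break
        else:
            raise RuntimeError(
                "could not place non-overlapping segments within attempt budget"
            )
    return sets


class ConservationTrack:
    """Sparse per-base [0, 1] scores keyed by (seq_id, position)."""

    def __init__(self) -> None:
        self._data: Dict[str, Dict[int, float]] = {}

    def set_score(self, seq_id: str, pos: int, score: float) -> None:
        if not (0.0 <= score <= 1.0):
            raise ValueError(f"conservation score {score} outside [0, 1]")
        self._data.setdefault(seq_id, {})[pos] = score

    def get(self, seq_id: str, pos: int) -> Optional[float]:
        return self._data.get(seq_id, {}).get(pos)

    def has_chrom(self, seq_id: str) -> bool:
        return seq_id in self._data


def motif_conservation(
    intervals: Sequence[GenomicInterval], track: ConservationTrack
) -> List[float]:
    """Mean of available per-base scores per interval; NaN when uncovered."""
    means: List[float] = []
    for iv in intervals:
        vals = [
            s
            for pos in range(iv.start, iv.end)
            if (s := track.get(iv.seq_id, pos)) is not None
        ]
        means.append(float(np.mean(vals)) if vals else math.nan)
    return means


def compare_conservation(
    real_means: Sequence[float], random_means: Sequence[float]
) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) of real vs random
    per-motif conservation means; missing values are dropped first."""
    real = [v for v in real_means if not math.isnan(v)]
    rand = [v for v in random_means if not math.isnan(v)]
    if not real or not rand:
        raise ValueError("need non-missing values on both sides")
    res = stats.mannwhitneyu(real, rand, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# File readers (plain-text formats only)
# ---------------------------------------------------------------------------

def read_genes_bed(path: Union[str, Path]) -> List[GeneRecord]:
    """BED with >= 4 columns; TSS = start on '+', end-1 on '-'."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"BED line {lineno}: need at least 4 columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if len(parts) >= 6 else "+"
            tss = start if strand == "+" else end - 1
            genes.append(GeneRecord(name, chrom, tss, strand))
    return genes


def _gff3_attr(attrs: str, key: str) -> Optional[str]:
    for item in attrs.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return None


def read_genes_gff3(path: Union[str, Path]) -> List[GeneRecord]:
    """Gene-typed GFF3 lines; 1-based inclusive coordinates."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            chrom, start, end, strand, attrs = (
                parts[0],
                int(parts[3]),
                int(parts[4]),
                parts[6],
                parts[8],
            )
            gene_id = _gff3_attr(attrs, "ID") or _gff3_attr(attrs, "gene_id")
            if gene_id is None:
                raise ValueError(f"GFF3 gene line without ID attribute: {line!r}")
            tss = start - 1 if strand == "+" else end - 1
            genes.append(GeneRecord(gene_id, chrom, tss, strand))
    return genes


def read_ortholog_tsv(path: Union[str, Path]) -> OrthologMap:
    omap = OrthologMap()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"ortholog TSV line {lineno}: need 2 columns")
            omap.add(parts[0], parts[1])
    return omap


def read_bedgraph(path: Union[str, Path]) -> ConservationTrack:
    track = ConservationTrack()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            v = float(value)
            for pos in range(int(start), int(end)):
                track.set_score(chrom, pos, v)
    return track


def read_wiggle(path: Union[str, Path]) -> ConservationTrack:
    """Fixed-step wiggle (1-based start) into a sparse track."""
    track = ConservationTrack()
    chrom, pos, step = None, None, 1
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(
                    kv.split("=") for kv in line.split()[1:] if "=" in kv
                )
                chrom = fields["chrom"]
                pos = int(fields["start"]) - 1
                step = int(fields.get("step", 1))
            else:
                if chrom is None:
                    raise ValueError("wiggle data before fixedStep declaration")
                track.set_score(chrom, pos, float(line))
                pos += step
    return track
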