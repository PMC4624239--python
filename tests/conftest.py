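import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from seedscan import ScoringParams, Sequence

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int, seq_id: str = "s") -> Sequence:
    return Sequence(id=seq_id, residues="".join(rng.choice(list(BASES), size=n)))


def random_word(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


@pytest.fixture
def params() -> ScoringParams:
    return ScoringParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def planted_pair(rng, n_motifs=4, motif_len=20, spacer_len=30, order=None):
    """Query with N spacers and a target with random spacers sharing the same
    motif blocks; junction-safe by construction (query N never seeds or
    matches).  Returns (query, target, motif_blocks, target_coords)."""
    blocks = [random_word(rng, motif_len) for _ in range(n_motifs)]
    if order is None:
        order = list(range(n_motifs))
    q_parts, t_parts = [], []
    t_coords = []
    pos = 0
    for i in range(n_motifs):
        q_parts.append("N" * spacer_len)
        q_parts.append(blocks[i])
        t_parts.append(random_word(rng, spacer_len))
        pos += spacer_len
        t_coords.append((pos, pos + motif_len))
        t_parts.append(blocks[order[i]])
        pos += motif_len
    q_parts.append("N" * spacer_len)
    t_parts.append(random_word(rng, spacer_len))
    query = Sequence(id="query", residues="".join(q_parts))
    target = Sequence(id="target", residues="".join(t_parts))
    return query, target, blocks, t_coords
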