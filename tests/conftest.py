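import numpy as np
import pytest

from brickseq.design import Design, Segment, Strand


def make_strand(sid: str, seq: str, role: str = "brick",
                row: int = 0, col: int = 0, shapes=()) -> Strand:
    return Strand(
        strand_id=sid,
        sequence=seq,
        role=role,
        segments=(Segment(row, col, 0, len(seq)),),
        shapes=frozenset(shapes),
    )


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def small_design(rng):
    """Six distinct-prefix bricks on a 2x3 grid, two tagged as shape 'L'."""
    strands = {}
    for i in range(6):
        seq = random_seq(rng, 32)
        shapes = ("L",) if i < 2 else ()
        strands[f"s{i}"] = make_strand(f"s{i}", seq, row=i // 3, col=i % 3,
                                       shapes=shapes)
    return Design(name="toy", strands=strands)
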