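import numpy as np
import pytest

from polfid import MutantRead, ReferenceTarget

REF64 = "ATGCCGCGTTACGCATCAGGCTAGTTGACGCAGATCCGTAACTGGATTCCATGAGTCTAGCTAC"

BASES = "ACGT"


@pytest.fixture
def reference64() -> ReferenceTarget:
    return ReferenceTarget(id="target", sequence=REF64)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def mutate_sequence(
    rng: np.random.Generator,
    sequence: str,
    n_sub: int = 0,
    n_ins: int = 0,
    n_del: int = 0,
) -> str:
    """Apply random point edits to a sequence (for round-trip tests)."""
    seq = list(sequence)
    for _ in range(n_sub):
        i = int(rng.integers(0, len(seq)))
        alts = [b for b in BASES if b != seq[i]]
        seq[i] = alts[int(rng.integers(0, 3))]
    for _ in range(n_ins):
        i = int(rng.integers(0, len(seq) + 1))
        seq.insert(i, BASES[int(rng.integers(0, 4))])
    for _ in range(n_del):
        if len(seq) > 1:
            seq.pop(int(rng.integers(0, len(seq))))
    return "".join(seq)


def read_of(sequence: str, rid: str = "read") -> MutantRead:
    return MutantRead(id=rid, sequence=sequence)
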