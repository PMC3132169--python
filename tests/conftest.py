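"""Shared fixtures: deterministic RNG and small synthetic read factories."""

from __future__ import annotations

import numpy as np
import pytest

from oakbes.bes_io import BesRead


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_260_923)


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


@pytest.fixture
def reads_with_element(rng):
    """Factory: reads of random background with a shared element planted.

    Returns (reads, element); each read carries the identical element at
    a random offset, so every read should self-match every other.
    """

    def make(n_reads: int, read_len: int = 400, elem_len: int = 150, divergence: float = 0.0,
             clone_prefix: str = "E"):
        element = random_seq(rng, elem_len)
        reads = []
        for i in range(n_reads):
            bg = random_seq(rng, read_len)
            pos = int(rng.integers(0, read_len - elem_len + 1))
            payload = mutate(rng, element, divergence)
            seq = bg[:pos] + payload + bg[pos + elem_len:]
            reads.append(BesRead(f"{clone_prefix}{i:03d}.F", f"{clone_prefix}{i:03d}", "F", seq))
        return reads, element

    return make


@pytest.fixture
def background_reads(rng):
    """Factory: i.i.d. random reads (no planted structure)."""

    def make(n_reads: int, read_len: int = 400, clone_prefix: str = "B"):
        return [
            BesRead(
                f"{clone_prefix}{i:03d}.F",
                f"{clone_prefix}{i:03d}",
                "F",
                random_seq(rng, read_len),
            )
            for i in range(n_reads)
        ]

    return make
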