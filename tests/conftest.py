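"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import pr77kit as pk

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def mutate_at(seq: str, positions, rng: np.random.Generator) -> str:
    s = list(seq)
    for p in positions:
        s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
    return "".join(s)


# -- independent exhaustive local-alignment oracle ---------------------------
# A deliberately naive full-matrix Smith-Waterman, written separately from the
# package's seed-and-extend scanner, used to verify hit intervals and scores.

def sw_oracle(query: str, target: str, match=1, mismatch=-1, gap=-2):
    """Return (score, t_start, t_end, matches, columns) of the best local
    alignment, or None when no positive-scoring alignment exists."""
    n, m = len(query), len(target)
    H = np.zeros((n + 1, m + 1), dtype=int)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if query[i - 1] == target[j - 1] else mismatch
            H[i, j] = max(0, H[i - 1, j - 1] + s, H[i - 1, j] + gap, H[i, j - 1] + gap)
    score = int(H.max())
    if score <= 0:
        return None
    i, j = np.unravel_index(np.argmax(H), H.shape)
    i, j = int(i), int(j)
    end_j = j
    matches = columns = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        s = match if query[i - 1] == target[j - 1] else mismatch
        if H[i, j] == H[i - 1, j - 1] + s:
            matches += query[i - 1] == target[j - 1]
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
        columns += 1
    return score, j, end_j, matches, columns


# -- shared expensive fixtures ------------------------------------------------

TWELVE_ELEMENT_SPECS = (
    [pk.PlantSpec("SIDER1", "+")] * 2
    + [pk.PlantSpec("SIDER1", "-")] * 2
    + [pk.PlantSpec("SIDER2", "+")] * 2
    + [pk.PlantSpec("SIDER2", "-")] * 2
    + [pk.PlantSpec("LINE_DIRE", "+"), pk.PlantSpec("LINE_DIRE", "-")]
    + [pk.PlantSpec("SIDER1", "+", pk.ElementOptions(with_tsd=False))] * 2
)


@pytest.fixture(scope="session")
def planted_200kb():
    """The reference recovery scenario: 200 kb, 12 planted elements
    (4 SIDER1, 4 SIDER2, 2 LINE_DIRE, 2 TSD-less decoys), seed 42."""
    return pk.plant_genome(1, 200_000, list(TWELVE_ELEMENT_SPECS), rng_seed=42)


@pytest.fixture(scope="session")
def annotations_200kb(planted_200kb):
    return pk.annotate_genome(planted_200kb.genomes[0], [planted_200kb.query])


@pytest.fixture(scope="session")
def ribozyme7():
    """A descriptor-satisfying 77-nt hallmark with its truth fold."""
    return pk.sample_ribozyme(rng_seed=7, length=77)
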