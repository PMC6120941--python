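"""Shared fixtures: the worked-example cluster and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from umishift import UmiAlignment, write_sam

# The worked example: one UMI, five consecutive coordinates on Chr03 centred
# at 591516 with per-coordinate read counts 1, 10, 796, 3, 1.
FIG1_UMI = "AAAGGAGTGG"
FIG1_COUNTS = {591514: 1, 591515: 10, 591516: 796, 591517: 3, 591518: 1}
FIG1_REFERENCE = "Chr03"


def make_fig1_alignments(sequence: str = "AC" * 18) -> list[UmiAlignment]:
    alignments = []
    i = 0
    for coord, n in sorted(FIG1_COUNTS.items()):
        for _ in range(n):
            alignments.append(
                UmiAlignment(
                    read_id=f"read{i:04d}",
                    umi=FIG1_UMI,
                    reference=FIG1_REFERENCE,
                    strand="+",
                    coordinate=coord,
                    sequence=sequence,
                )
            )
            i += 1
    return alignments


@pytest.fixture
def fig1_alignments() -> list[UmiAlignment]:
    return make_fig1_alignments()


@pytest.fixture
def fig1_sam(tmp_path, fig1_alignments):
    path = tmp_path / "fig1.sam"
    write_sam(fig1_alignments, path, {FIG1_REFERENCE: 1_000_000})
    return path


def brute_force_levenshtein(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance, independent of edlib."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = cur
    return prev[-1]


def brute_force_components(coords: list[int], max_gap: int) -> list[list[int]]:
    """Connected components of the graph joining coordinates within max_gap,
    by explicit all-pairs edge enumeration (independent of the chaining code)."""
    coords = sorted(coords)
    n = len(coords)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if abs(coords[i] - coords[j]) <= max_gap:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(coords[i])
    return sorted(sorted(g) for g in groups.values())


def random_coordinate_instance(rng: np.random.Generator, max_n: int = 200):
    """Random sorted (coordinate, count) instance for clustering oracles."""
    n = int(rng.integers(1, max_n + 1))
    coords = np.unique(rng.integers(1, 5 * max_n, size=n))
    counts = rng.integers(1, 20, size=len(coords))
    return [(int(c), int(k)) for c, k in zip(coords, counts)]
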