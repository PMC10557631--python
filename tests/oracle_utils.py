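"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the library's own code paths: hex distance via the
closed-form axial formula, BFS via a plain dict/queue over explicitly listed
offsets, dilation via an explicit neighborhood sweep, and tallies via python
loops.
"""

from __future__ import annotations

from collections import deque

import numpy as np

OFFSETS = [(-1, -1), (-1, 1), (1, -1), (1, 1), (0, -2), (0, 2)]


def axial_hex_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Closed-form hex distance for Visium array coords (row+col even)."""
    (r1, c1), (r2, c2) = a, b
    q1, q2 = (c1 - r1) // 2, (c2 - r2) // 2
    dq, dr = q2 - q1, r2 - r1
    return (abs(dq) + abs(dr) + abs(dq + dr)) // 2


def naive_multisource_bfs(coords: set[tuple[int, int]],
                          sources: set[tuple[int, int]]) -> dict[tuple[int, int], int]:
    dist = {s: 0 for s in sources}
    queue = deque(sources)
    while queue:
        r, c = queue.popleft()
        for dr, dc in OFFSETS:
            nb = (r + dr, c + dc)
            if nb in coords and nb not in dist:
                dist[nb] = dist[(r, c)] + 1
                queue.append(nb)
    return dist


def naive_dilate(mask: np.ndarray, rounds: int) -> np.ndarray:
    out = mask.astype(bool).copy()
    h, w = out.shape
    for _ in range(rounds):
        nxt = out.copy()
        for i in range(h):
            for j in range(w):
                if out[i, j]:
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            ii, jj = i + di, j + dj
                            if 0 <= ii < h and 0 <= jj < w:
                                nxt[ii, jj] = True
        out = nxt
    return out


def naive_composition(calls: dict[str, str], regions: dict[str, str]) -> dict:
    """{region: {label: proportion}} by explicit counting."""
    counts: dict[str, dict[str, int]] = {}
    for unit, label in calls.items():
        region = regions[unit]
        counts.setdefault(region, {}).setdefault(label, 0)
        counts[region][label] += 1
    out = {}
    for region, tab in counts.items():
        total = sum(tab.values())
        out[region] = {lab: n / total for lab, n in tab.items()}
    return out


def naive_encounter(rescaled, genes: list[str], me: dict[str, str],
                    threshold: float) -> dict[str, tuple[int, int]]:
    """{ME: (n_subspots, full_overlap)} by explicit per-subspot looping."""
    out: dict[str, list[int]] = {}
    for unit in rescaled.columns:
        label = me[unit]
        out.setdefault(label, [0, 0])
        out[label][0] += 1
        if all(rescaled.at[g, unit] > threshold for g in genes):
            out[label][1] += 1
    return {k: (v[0], v[1]) for k, v in out.items()}
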