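"""Independent brute-force oracles, written before and apart from the package.

These deliberately use plain loops and the definitions spelled out as prose,
so they share no code path with the vectorized implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_amova(
    codes: np.ndarray, labels: list[str], rescale: bool = True
) -> dict[str, float]:
    """One-level AMOVA on the allele-count scale, by explicit enumeration.

    codes: lines x markers, values in {0(missing), 1, 2, 3}.
    """
    n, L = codes.shape
    x = [[None if codes[i][j] == 0 else 3 - int(codes[i][j]) for j in range(L)] for i in range(n)]

    def d2(i, k):
        tot, valid = 0.0, 0
        for j in range(L):
            if x[i][j] is not None and x[k][j] is not None:
                tot += (x[i][j] - x[k][j]) ** 2
                valid += 1
        if valid == 0:
            return None
        return tot * (L / valid) if rescale else tot

    groups = list(dict.fromkeys(labels))
    K = len(groups)
    ss_total = 0.0
    for i, k in itertools.combinations(range(n), 2):
        ss_total += d2(i, k)
    ss_total /= n
    ss_within = 0.0
    for gname in groups:
        idx = [i for i in range(n) if labels[i] == gname]
        s = 0.0
        for i, k in itertools.combinations(idx, 2):
            s += d2(i, k)
        ss_within += s / len(idx)
    ss_among = ss_total - ss_within
    df_among, df_within = K - 1, n - K
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    sizes = [labels.count(gname) for gname in groups]
    n0 = (n - sum(s * s for s in sizes) / n) / (K - 1)
    va = (ms_among - ms_within) / n0
    vw = ms_within
    return {
        "ss_total": ss_total,
        "ss_among": ss_among,
        "ss_within": ss_within,
        "va": va,
        "vw": vw,
        "phi_st": va / (va + vw),
    }


def four_point_split(d: np.ndarray, ids: list[str]):
    """Quartet pairing by direct four-point minimisation; None on a tie.

    Returns the split as a frozenset of two frozensets, or None for a star.
    """
    a, b, c, e = range(4)
    sums = {
        frozenset({frozenset({ids[a], ids[b]}), frozenset({ids[c], ids[e]})}): d[a, b] + d[c, e],
        frozenset({frozenset({ids[a], ids[c]}), frozenset({ids[b], ids[e]})}): d[a, c] + d[b, e],
        frozenset({frozenset({ids[a], ids[e]}), frozenset({ids[b], ids[c]})}): d[a, e] + d[b, c],
    }
    best = min(sums.values())
    winners = [k for k, v in sums.items() if abs(v - best) <= 1e-12]
    return winners[0] if len(winners) == 1 else None


def random_additive_tree(ids: list[str], rng: np.random.Generator):
    """Random additive distance matrix and the generating tree's splits."""
    clusters = [{t: 0.0} for t in ids]
    dist: dict[tuple[str, str], float] = {}
    splits: set[frozenset] = set()
    n = len(ids)
    taxa = frozenset(ids)
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        la, lb = rng.uniform(0.1, 1.0, size=2)
        A, B = clusters[i], clusters[j]
        for xx, dx in A.items():
            for yy, dy in B.items():
                dist[(xx, yy)] = dist[(yy, xx)] = dx + la + dy + lb
        merged = {xx: dx + la for xx, dx in A.items()}
        merged.update({yy: dy + lb for yy, dy in B.items()})
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
        side = set(merged)
        if 2 <= len(side) <= n - 2 and len(clusters) > 1:
            splits.add(frozenset({frozenset(side), frozenset(taxa - side)}))
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if a != b:
                d[a, b] = dist[(ids[a], ids[b])]
    return d, frozenset(splits)
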