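"""Simple-matching distances, neighbor-joining, and unrooted-topology equality.

Genetic relationships are inferred from the simple matching coefficient:
for two lines, S = (# co-observed loci with identical genotype codes) /
(# co-observed loci), and the dissimilarity is D = 1 − S.  Trees are built
with Saitou–Nei neighbor-joining (Q-criterion minimization, standard branch
length and distance updates) with deterministic tie-breaking by the lowest
pair of taxon indices.  For four-taxon inputs a tie between two pairings of
the four-point criterion yields a star topology rather than an arbitrary
resolution, so topology-accuracy counting never credits coin flips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import MISSING, GenotypeMatrix

__all__ = ["DistanceMatrix", "TreeTopology", "smc_distance", "nj_tree", "same_topology"]


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray
    valid_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")


@dataclass(frozen=True)
class TreeTopology:
    """Unrooted tree as its leaf set, nontrivial splits, and a newick string.

    Each split is a frozenset of the two leaf-label frozensets it separates.
    A star tree (no internal edge) has an empty split set.
    """

    taxa: frozenset[str]
    splits: frozenset[frozenset[frozenset[str]]]
    newick: str

    def is_star(self) -> bool:
        return len(self.splits) == 0


def smc_distance(
    g: GenotypeMatrix, undefined_pair_fallback: bool = False
) -> DistanceMatrix:
    """Pairwise D = 1 − simple-matching similarity over co-observed loci."""
    if g.n_lines < 2:
        raise ValueError("need at least 2 lines")
    codes = g.codes
    obs = (codes != MISSING).astype(float)
    matches = np.zeros((g.n_lines, g.n_lines))
    for c in (1, 2, 3):
        ind = (codes == c).astype(float)
        matches += ind @ ind.T
    valid = obs @ obs.T
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(valid > 0, 1.0 - matches / np.maximum(valid, 1), np.nan)
    np.fill_diagonal(d, 0.0)
    iu = np.triu_indices(g.n_lines, k=1)
    if np.isnan(d[iu]).any():
        n_undef = int(np.isnan(d[iu]).sum())
        if not undefined_pair_fallback:
            raise ValueError(
                f"{n_undef} line pair(s) share no co-observed locus; enable "
                "undefined_pair_fallback to substitute the mean distance"
            )
        fill = float(np.nanmean(d[iu]))
        warnings.warn(f"{n_undef} undefined pair distance(s) set to the mean", stacklevel=2)
        d = np.where(np.isnan(d), fill, d)
    return DistanceMatrix(list(g.line_ids), d, valid.astype(int))


def _canonical_split(side: set[str], taxa: frozenset[str]) -> frozenset:
    return frozenset({frozenset(side), frozenset(taxa - side)})


def _star(ids: list[str]) -> TreeTopology:
    return TreeTopology(frozenset(ids), frozenset(), "(" + ",".join(ids) + ");")


def nj_tree(dm: DistanceMatrix) -> TreeTopology:
    """Neighbor-joining topology from a distance matrix.

    Deterministic: Q-ties are broken by the lexicographically lowest pair of
    active-node indices; a four-taxon input whose four-point criterion ties
    returns a star.
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    D = np.asarray(dm.d, dtype=float).copy()
    if not np.isfinite(D).all():
        raise ValueError("non-finite distance")
    taxa = frozenset(ids)
    if n == 3:
        return _star(ids)

    members: list[set[str]] = [{t} for t in ids]
    newick: list[str] = list(ids)
    active = list(range(n))
    splits: set[frozenset] = set()
    first_join = True

    while len(active) > 3:
        na = len(active)
        sub = D[np.ix_(active, active)]
        if first_join and n == 4:
            # four-point criterion: a tie between pairings yields a star
            s = [sub[0, 1] + sub[2, 3], sub[0, 2] + sub[1, 3], sub[0, 3] + sub[1, 2]]
            order = np.argsort(s)
            if abs(s[order[0]] - s[order[1]]) <= 1e-12:
                return _star(ids)
        r = sub.sum(axis=1)
        q = (na - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(np.isclose(q, qmin, rtol=0.0, atol=1e-12))
        pairs = sorted({(min(a, b), max(a, b)) for a, b in ties})
        ai, aj = pairs[0]
        first_join = False
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (na - 2))
        lj = dij - li
        # new node
        new = len(members)
        members.append(members[i] | members[j])
        newick.append(f"({newick[i]}:{li:.10g},{newick[j]}:{lj:.10g})")
        duk = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[new, :-1] = duk
        D[:-1, new] = duk
        D[new, new] = 0.0
        active = [k for k in active if k not in (i, j)] + [new]
        side = members[new]
        if 2 <= len(side) <= n - 2:
            splits.add(_canonical_split(side, taxa))

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    nwk = f"({newick[a]}:{la:.10g},{newick[b]}:{lb:.10g},{newick[c]}:{lc:.10g});"
    return TreeTopology(taxa, frozenset(splits), nwk)


def same_topology(t1: TreeTopology, t2: TreeTopology) -> bool:
    """True iff the unrooted split sets coincide (a star matches only a star)."""
    if t1.taxa != t2.taxa:
        raise ValueError("trees have different leaf sets")
    return t1.splits == t2.splits
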