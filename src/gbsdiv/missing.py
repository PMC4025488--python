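"""Random-missingness simulation and the subsampling step of the assessment.

"Missing level" m counts cells drawn, not the final missing fraction:
exactly round(m·N) distinct cells are drawn uniformly from all N cells of
the matrix, ignoring pre-existing missingness, lines and markers.  On a
complete matrix the drawn count and the realized missing fraction coincide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import MISSING, GenotypeMatrix, GroupAssignment

logger = logging.getLogger(__name__)

__all__ = ["MissingMask", "SubsampleIndex", "apply_random_missing", "subsample"]


@dataclass
class MissingMask:
    """Cells newly designated missing, as parallel (line, marker) index arrays."""

    line_idx: np.ndarray
    marker_idx: np.ndarray
    missing_level: float

    def __len__(self) -> int:
        return len(self.line_idx)

    def as_set(self) -> set[tuple[int, int]]:
        return set(zip(self.line_idx.tolist(), self.marker_idx.tolist()))


@dataclass
class SubsampleIndex:
    """Positional indices that extract the same cells from any aligned matrix."""

    line_idx: np.ndarray
    marker_idx: np.ndarray

    def apply(self, g: GenotypeMatrix) -> GenotypeMatrix:
        return g.take(self.line_idx, self.marker_idx)


def apply_random_missing(
    g: GenotypeMatrix, m: float, rng: np.random.Generator
) -> tuple[GenotypeMatrix, MissingMask]:
    """Set round(m·N) uniformly drawn cells to MISSING; all others unchanged.

    Cells already missing may be drawn and simply remain missing.
    """
    if not (0.0 <= m <= 1.0):
        raise ValueError("missing level must be in [0, 1]")
    n_cells = g.codes.size
    n_draw = int(round(m * n_cells))
    out = g.copy()
    if n_draw == 0:
        empty = np.empty(0, dtype=int)
        return out, MissingMask(empty, empty, m)
    flat = rng.choice(n_cells, size=n_draw, replace=False)
    li, mi = np.unravel_index(flat, g.codes.shape)
    out.codes[li, mi] = MISSING
    return out, MissingMask(li, mi, m)


def subsample(
    g: GenotypeMatrix,
    groups: GroupAssignment,
    n_lines: int,
    n_markers: int,
    rng: np.random.Generator,
    require_all_groups: bool = True,
    max_retries: int = 100,
) -> tuple[GenotypeMatrix, GroupAssignment, SubsampleIndex]:
    """Simple random sample of lines and markers without replacement.

    When ``require_all_groups`` is set, line draws are retried (bounded,
    logged) until every group keeps at least one representative, so the
    downstream four-representative quartet is always defined.
    """
    if n_lines > g.n_lines or n_markers > g.n_markers:
        raise ValueError("subsample larger than the matrix")
    labels = groups.labels_for(g.line_ids)
    all_groups = set(groups.subset(g.line_ids).groups)

    line_idx = None
    for attempt in range(max_retries):
        cand = np.sort(rng.choice(g.n_lines, size=n_lines, replace=False))
        if not require_all_groups or set(labels[cand]) == all_groups:
            line_idx = cand
            if attempt:
                logger.info("subsample: %d retries to represent all groups", attempt)
            break
    if line_idx is None:
        raise ValueError(
            f"could not represent all {len(all_groups)} groups in a "
            f"{n_lines}-line subsample after {max_retries} retries"
        )
    marker_idx = np.sort(rng.choice(g.n_markers, size=n_markers, replace=False))
    idx = SubsampleIndex(line_idx, marker_idx)
    sub = idx.apply(g)
    return sub, groups.subset(sub.line_ids), idx
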