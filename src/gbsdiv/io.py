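"""Reading and writing genotype matrices, group assignments, and VCF import.

The package's universal currency is the :class:`GenotypeMatrix`: a lines ×
markers grid of diploid biallelic genotypes coded ``1`` (homozygote AA),
``2`` (heterozygote Aa), ``3`` (the other homozygote aa), with ``MISSING``
(internally 0) for absent observations.  The allele-count view used by AMOVA
and PCA centering is ``x = 3 - code`` (so x counts copies of allele A:
2, 1, 0); :func:`allele_count_view` is the one documented bijection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Internal sentinel for a missing genotype cell.
MISSING: int = 0

#: Missing tokens accepted on input; "NA" is written on output.
_MISSING_TOKENS = {"NA", "-", ""}

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "GroupAssignment",
    "GenotypeFormatError",
    "GenotypeParseError",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_groups",
    "vcf_to_matrix",
    "allele_count_view",
]


class GenotypeFormatError(ValueError):
    """Structural problem in an input file (duplicates, empty, bad shape)."""


class GenotypeParseError(GenotypeFormatError):
    """A cell value outside the genotype alphabet; names its coordinates."""


@dataclass
class GenotypeMatrix:
    """Lines × markers integer-coded genotype grid.

    Parameters
    ----------
    line_ids : sequence of str
        Ordered, unique row identifiers.
    marker_ids : sequence of str
        Ordered, unique column identifiers.
    codes : ndarray of int8, shape (n_lines, n_markers)
        Values in {1, 2, 3, MISSING}.
    """

    line_ids: list[str]
    marker_ids: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = [str(x) for x in self.line_ids]
        self.marker_ids = [str(x) for x in self.marker_ids]
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise GenotypeFormatError("codes must be a 2-D grid")
        if self.codes.shape != (len(self.line_ids), len(self.marker_ids)):
            raise GenotypeFormatError(
                f"grid shape {self.codes.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        if len(set(self.line_ids)) != len(self.line_ids):
            raise GenotypeFormatError("duplicate line ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise GenotypeFormatError("duplicate marker ids")
        bad = ~np.isin(self.codes, (MISSING, 1, 2, 3))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeParseError(
                f"invalid genotype code {self.codes[i, j]} at "
                f"line {self.line_ids[i]!r}, marker {self.marker_ids[j]!r}"
            )

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean grid, True where the genotype is missing."""
        return self.codes == MISSING

    def missing_fraction(self) -> float:
        return float(self.missing_mask.mean()) if self.codes.size else 0.0

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.line_ids), list(self.marker_ids), self.codes.copy())

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.line_ids == other.line_ids
            and self.marker_ids == other.marker_ids
            and np.array_equal(self.codes, other.codes)
        )

    def take(self, line_idx: np.ndarray | list[int], marker_idx: np.ndarray | list[int]) -> "GenotypeMatrix":
        """Subset by positional indices, preserving the given order."""
        line_idx = np.asarray(line_idx, dtype=int)
        marker_idx = np.asarray(marker_idx, dtype=int)
        return GenotypeMatrix(
            [self.line_ids[i] for i in line_idx],
            [self.marker_ids[j] for j in marker_idx],
            self.codes[np.ix_(line_idx, marker_idx)],
        )


def allele_count_view(codes: np.ndarray) -> np.ndarray:
    """Map genotype codes to counts of allele A (1→2, 2→1, 3→0) as float.

    Missing cells become NaN.
    """
    x = 3.0 - np.asarray(codes, dtype=float)
    x[np.asarray(codes) == MISSING] = np.nan
    return x


@dataclass
class GroupAssignment:
    """Mapping from line id to group label."""

    mapping: dict[str, str]

    @property
    def groups(self) -> list[str]:
        """Group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.mapping.values():
            seen.setdefault(g, None)
        return list(seen)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {g: 0 for g in self.groups}
        for g in self.mapping.values():
            out[g] += 1
        return out

    def labels_for(self, line_ids: list[str]) -> np.ndarray:
        """Group label per line, raising if any line is unassigned."""
        missing = [x for x in line_ids if x not in self.mapping]
        if missing:
            raise GenotypeFormatError(
                f"{len(missing)} line(s) have no group assignment, e.g. {missing[0]!r}"
            )
        return np.array([self.mapping[x] for x in line_ids])

    def subset(self, line_ids: list[str]) -> "GroupAssignment":
        return GroupAssignment({x: self.mapping[x] for x in line_ids})


def _parse_cell(tok: str, line_id: str, marker_id: str) -> int:
    tok = tok.strip()
    if tok in _MISSING_TOKENS:
        return MISSING
    if tok in ("1", "2", "3"):
        return int(tok)
    raise GenotypeParseError(
        f"unparseable genotype {tok!r} at line {line_id!r}, marker {marker_id!r}"
    )


def read_genotype_matrix(path: str | Path, dialect: str = "tsv") -> GenotypeMatrix:
    """Read a genotype TSV: header ``line_id<TAB>m1<TAB>...``, one row per line.

    Cells must be 1/2/3 or a missing token ("NA", "-", empty).
    """
    if dialect != "tsv":
        raise ValueError(f"unsupported dialect {dialect!r}")
    path = Path(path)
    text = path.read_text()
    rows = [line.split("\t") for line in text.splitlines() if line.strip() != ""]
    if not rows:
        raise GenotypeFormatError(f"{path}: empty genotype file")
    header = rows[0]
    marker_ids = [h.strip() for h in header[1:]]
    if not marker_ids:
        raise GenotypeFormatError(f"{path}: no marker columns in header")
    line_ids: list[str] = []
    grid = np.empty((len(rows) - 1, len(marker_ids)), dtype=np.int8)
    for r, row in enumerate(rows[1:]):
        lid = row[0].strip()
        if len(row) != len(marker_ids) + 1:
            raise GenotypeFormatError(
                f"{path}: row for line {lid!r} has {len(row) - 1} cells, "
                f"expected {len(marker_ids)}"
            )
        line_ids.append(lid)
        for c, tok in enumerate(row[1:]):
            grid[r, c] = _parse_cell(tok, lid, marker_ids[c])
    return GenotypeMatrix(line_ids, marker_ids, grid)


def write_genotype_matrix(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the TSV dialect read by :func:`read_genotype_matrix` (missing → "NA")."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("line_id\t" + "\t".join(g.marker_ids) + "\n")
        for i, lid in enumerate(g.line_ids):
            cells = ["NA" if c == MISSING else str(c) for c in g.codes[i]]
            fh.write(lid + "\t" + "\t".join(cells) + "\n")


def read_groups(path: str | Path) -> GroupAssignment:
    """Read a two-column ``line_id<TAB>group`` table; header auto-detected."""
    path = Path(path)
    rows = [ln.split("\t") for ln in path.read_text().splitlines() if ln.strip()]
    if not rows:
        raise GenotypeFormatError(f"{path}: empty group file")
    first = [t.strip().lower() for t in rows[0]]
    if first[:2] == ["line_id", "group"]:
        rows = rows[1:]
    mapping: dict[str, str] = {}
    for row in rows:
        if len(row) < 2:
            raise GenotypeFormatError(f"{path}: malformed group row {row!r}")
        lid, grp = row[0].strip(), row[1].strip()
        if lid in mapping:
            raise GenotypeFormatError(f"{path}: duplicated line id {lid!r}")
        mapping[lid] = grp
    ga = GroupAssignment(mapping)
    logger.info("read %d lines in %d groups: %s", len(mapping), ga.n_groups, ga.sizes())
    return ga


def write_groups(groups: GroupAssignment, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("line_id\tgroup\n")
        for lid, grp in groups.mapping.items():
            fh.write(f"{lid}\t{grp}\n")


def vcf_to_matrix(path: str | Path) -> GenotypeMatrix:
    """Import biallelic SNP records from a VCF (GT fields only).

    GT 0/0 → 1, 0/1 or 1/0 → 2, 1/1 → 3, ./. → MISSING.  Multiallelic
    records are skipped with a logged count.
    """
    import pysam

    path = Path(path)
    skipped = 0
    marker_ids: list[str] = []
    columns: list[np.ndarray] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf.fetch() if vf.index is not None else vf:
            if rec.alts is None or len(rec.alts) != 1:
                skipped += 1
                continue
            col = np.empty(len(samples), dtype=np.int8)
            for k, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    col[k] = MISSING
                else:
                    n_alt = sum(1 for a in gt if a == 1)
                    col[k] = (1, 2, 3)[n_alt]
            marker_ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            columns.append(col)
    if not columns:
        raise GenotypeFormatError(f"{path}: no parsable biallelic records")
    if skipped:
        logger.warning("%s: skipped %d multiallelic record(s)", path, skipped)
    return GenotypeMatrix(samples, marker_ids, np.column_stack(columns))
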