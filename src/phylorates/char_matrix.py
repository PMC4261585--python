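"""Character matrices of nonnegative integer states and site-pattern
compression."""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CharacterMatrix",
    "PatternSet",
    "read_character_matrix",
    "write_character_matrix",
    "simplify_to_binary",
    "compress_patterns",
]


@dataclass
class CharacterMatrix:
    """Taxa x sites grid of integer states ``0..a-1``.

    ``a`` is the number of character states modelled; it may exceed the
    largest observed state (states present in the model but unobserved in the
    data are legal).
    """

    taxa: list[str]
    states: np.ndarray  # shape (n_taxa, n_sites), integer dtype
    a: int
    site_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states)
        if self.states.ndim != 2:
            raise ValueError("states must be a 2-D taxa x sites array")
        if not np.issubdtype(self.states.dtype, np.integer):
            raise ValueError("states must be integers")
        if len(self.taxa) != self.states.shape[0]:
            raise ValueError("taxa labels do not match the number of rows")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        if self.states.size and self.states.min() < 0:
            raise ValueError("negative character state")
        if self.a < 2:
            raise ValueError("need at least 2 character states (a >= 2)")
        if self.states.size and self.states.max() >= self.a:
            raise ValueError(
                f"state {self.states.max()} out of range for a={self.a}")
        if self.site_ids is not None and len(self.site_ids) != self.n_sites:
            raise ValueError("site_ids length mismatch")

    @property
    def n_taxa(self) -> int:
        return self.states.shape[0]

    @property
    def n_sites(self) -> int:
        return self.states.shape[1]

    def reorder(self, taxa: Sequence[str]) -> "CharacterMatrix":
        """Return a copy with rows arranged to the given taxon order."""
        missing = set(taxa) - set(self.taxa)
        extra = set(self.taxa) - set(taxa)
        if missing or extra:
            raise ValueError(
                "taxa do not match: "
                + (f"missing {sorted(missing)} " if missing else "")
                + (f"unexpected {sorted(extra)}" if extra else ""))
        idx = [self.taxa.index(t) for t in taxa]
        return CharacterMatrix(list(taxa), self.states[idx].copy(), self.a,
                               self.site_ids)


@dataclass
class PatternSet:
    """Distinct site columns with multiplicities (likelihood speedup)."""

    patterns: np.ndarray  # shape (n_patterns, n_taxa)
    weights: np.ndarray  # positive ints, shape (n_patterns,)
    site_index: np.ndarray = field(default=None)  # site -> pattern row
    taxa: Optional[list[str]] = None  # column labels, one per taxon

    def __post_init__(self) -> None:
        if (self.weights <= 0).any():
            raise ValueError("pattern weights must be positive")

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_sites(self) -> int:
        return int(self.weights.sum())


_INT_RE = re.compile(r"[+-]?\d+$")


def _tokenize(line: str) -> list[str]:
    line = line.strip()
    if "," in line:
        return [t.strip() for t in line.split(",")]
    return line.split()


def read_character_matrix(path, orientation: str = "taxa_in_rows",
                          a: Optional[int] = None) -> CharacterMatrix:
    """Read a delimited integer table as a taxa x sites matrix.

    ``orientation`` declares the layout of the file (``taxa_in_rows`` or
    ``taxa_in_columns``); the result is always taxa x sites.  An optional
    leading header row and/or first column of non-integer tokens provide
    labels for whichever axis they belong to.  ``a`` defaults to
    ``max(observed state) + 1`` and may only be overridden upward.
    """
    orientation = orientation.replace("-", "_")
    if orientation not in ("taxa_in_rows", "taxa_in_columns"):
        raise ValueError(f"unknown orientation {orientation!r}")

    with open(path) as fh:
        rows = [_tokenize(ln) for ln in fh if ln.strip()]
    if not rows:
        raise ValueError(f"{path}: empty matrix file")

    header: Optional[list[str]] = None
    if all(not _INT_RE.match(tok) for tok in rows[0]):
        header = rows[0]
        rows = rows[1:]
        if not rows:
            raise ValueError(f"{path}: header but no data rows")

    row_labels: Optional[list[str]] = None
    if rows and not _INT_RE.match(rows[0][0]):
        row_labels = [r[0] for r in rows]
        rows = [r[1:] for r in rows]
        if header is not None and len(header) == len(rows[0]) + 1:
            header = header[1:]  # header had a stub over the label column

    width = len(rows[0])
    grid = np.empty((len(rows), width), dtype=np.int64)
    for i, row in enumerate(rows):
        if len(row) != width:
            raise ValueError(f"{path}: ragged row {i + 1} "
                             f"({len(row)} fields, expected {width})")
        for j, tok in enumerate(row):
            if not _INT_RE.match(tok):
                raise ValueError(f"{path}: non-integer token {tok!r} "
                                 f"at row {i + 1}, column {j + 1}")
            val = int(tok)
            if val < 0:
                raise ValueError(f"{path}: negative state {val} "
                                 f"at row {i + 1}, column {j + 1}")
            grid[i, j] = val

    if orientation == "taxa_in_rows":
        taxa_labels, site_labels = row_labels, header
    else:
        grid = grid.T
        taxa_labels, site_labels = header, row_labels

    n_taxa, n_sites = grid.shape
    taxa = list(taxa_labels) if taxa_labels else [f"t{i + 1}" for i in range(n_taxa)]
    if len(taxa) != n_taxa:
        raise ValueError(f"{path}: {len(taxa)} taxa labels for {n_taxa} taxa")
    observed_a = int(grid.max()) + 1 if grid.size else 2
    if a is None:
        a = max(observed_a, 2)
    elif a < observed_a:
        raise ValueError(f"a={a} is smaller than required by the data "
                         f"(max state {observed_a - 1})")
    return CharacterMatrix(taxa, grid, a,
                           list(site_labels) if site_labels else None)


def write_character_matrix(m: CharacterMatrix, path,
                           orientation: str = "taxa_in_rows") -> None:
    """Write a tab-delimited matrix readable by :func:`read_character_matrix`."""
    orientation = orientation.replace("-", "_")
    with open(path, "w") as fh:
        if orientation == "taxa_in_rows":
            for name, row in zip(m.taxa, m.states):
                fh.write(name + "\t" + "\t".join(map(str, row)) + "\n")
        elif orientation == "taxa_in_columns":
            fh.write("\t".join(m.taxa) + "\n")
            for col in m.states.T:
                fh.write("\t".join(map(str, col)) + "\n")
        else:
            raise ValueError(f"unknown orientation {orientation!r}")


def simplify_to_binary(m: CharacterMatrix) -> CharacterMatrix:
    """Map every state ``x`` to ``min(x, 1)``; the result has ``a = 2``."""
    return CharacterMatrix(list(m.taxa), np.minimum(m.states, 1), 2, m.site_ids)


def compress_patterns(m: CharacterMatrix) -> PatternSet:
    """Collapse identical site columns into weighted patterns."""
    cols = m.states.T  # (n_sites, n_taxa)
    patterns, site_index, counts = np.unique(
        cols, axis=0, return_inverse=True, return_counts=True)
    return PatternSet(patterns=patterns, weights=counts,
                      site_index=np.asarray(site_index).ravel(),
                      taxa=list(m.taxa))
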