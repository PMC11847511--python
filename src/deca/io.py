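"""Readers and writers for the external text formats the tool touches.

Peaks travel as BED (0-based half-open), chromatin contacts as BEDPE-like
text, matrices as labelled TSV/CSV or MatrixMarket triplets with sidecar
label files.  All coordinates are normalised to 0-based half-open at this
boundary and kept that way internally.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "PeakSet",
    "ContactList",
    "LabeledMatrix",
    "read_peaks",
    "write_peaks",
    "read_matrix",
    "write_matrix",
    "read_contacts",
    "write_contacts",
    "natural_chrom_key",
]

_CANONICAL = {f"chr{i}": i for i in range(1, 23)}
_CANONICAL.update({"chrX": 23, "chrY": 24, "chrM": 25})


def natural_chrom_key(chrom: str) -> tuple:
    """Sort key placing chr1..chr22, chrX, chrY first, then lexicographic."""
    if chrom in _CANONICAL:
        return (0, _CANONICAL[chrom], "")
    m = re.fullmatch(r"chr(\d+)", chrom)
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, chrom)


@dataclass(frozen=True)
class PeakSet:
    """Ordered genomic intervals defining the shared feature space.

    Records are (chrom, start, end, peak_id) with 0-based half-open
    coordinates, sorted by (chrom, start, end) under the natural
    chromosome order; peak ids are unique.
    """

    records: tuple = ()

    def __post_init__(self):
        seen = set()
        for chrom, start, end, pid in self.records:
            if start >= end:
                raise ValueError(f"peak {pid}: start {start} >= end {end}")
            if start < 0:
                raise ValueError(f"peak {pid}: negative start {start}")
            if pid in seen:
                raise ValueError(f"duplicate peak_id {pid!r}")
            seen.add(pid)
        key = [(natural_chrom_key(c), s, e) for c, s, e, _ in self.records]
        if key != sorted(key):
            raise ValueError("peaks are not sorted by (chrom, start, end)")

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "PeakSet":
        """Build a PeakSet, sorting records and synthesising missing ids."""
        recs = []
        for rec in records:
            chrom, start, end = rec[0], int(rec[1]), int(rec[2])
            pid = rec[3] if len(rec) > 3 and rec[3] else f"{chrom}:{start}-{end}"
            recs.append((chrom, start, end, pid))
        recs.sort(key=lambda r: (natural_chrom_key(r[0]), r[1], r[2]))
        return cls(records=tuple(recs))

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __iter__(self):
        return iter(self.records)

    @property
    def peak_ids(self) -> list[str]:
        return [r[3] for r in self.records]

    @property
    def chroms(self) -> list[str]:
        """Distinct chromosomes in natural order."""
        out, seen = [], set()
        for c, *_ in self.records:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out


@dataclass(frozen=True)
class ContactList:
    """Intra-chromosomal pairwise contacts (chrom, pos1, pos2, strength)."""

    pairs: tuple = ()

    def __post_init__(self):
        for chrom, p1, p2, s in self.pairs:
            if s < 0:
                raise ValueError(f"negative contact strength {s} on {chrom}")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


@dataclass
class LabeledMatrix:
    """A numeric matrix with row and column identifiers attached."""

    values: np.ndarray | sp.spmatrix
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        n, m = self.values.shape
        if len(self.row_labels) != n or len(self.col_labels) != m:
            raise ValueError(
                f"label count ({len(self.row_labels)}, {len(self.col_labels)}) "
                f"does not match matrix shape {self.values.shape}"
            )
        dense = self.values.toarray() if sp.issparse(self.values) else self.values
        if not np.all(np.isfinite(dense)):
            raise ValueError("matrix contains NaN or infinite entries")

    def toarray(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)


def read_peaks(path: str | Path) -> PeakSet:
    """Read a 3+-column BED file into a validated :class:`PeakSet`.

    A fourth column, when present, supplies peak ids; otherwise ids are
    synthesised as ``chrom:start-end``.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}, line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}, line {lineno}: non-integer coordinate"
                ) from exc
            if start >= end:
                raise ValueError(
                    f"{path}, line {lineno}: start {start} >= end {end}"
                )
            pid = fields[3] if len(fields) > 3 else None
            records.append((chrom, start, end, pid))
    return PeakSet.from_records(records)


def write_peaks(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, pid in peaks:
            fh.write(f"{chrom}\t{start}\t{end}\t{pid}\n")


def read_matrix(
    path: str | Path,
    orientation: Literal["features_by_samples", "cells_by_features"] = "features_by_samples",
) -> LabeledMatrix:
    """Read a labelled matrix from TSV/CSV or a MatrixMarket triplet.

    For a ``.mtx`` file, row and column labels are read from sidecar files
    ``<path>.rows`` and ``<path>.cols`` (one label per line).  The
    ``orientation`` argument is declarative: it records which axis the
    caller expects on rows and is attached to error messages only.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path).tocsr()
        rows = Path(str(path) + ".rows").read_text().splitlines()
        cols = Path(str(path) + ".cols").read_text().splitlines()
        return LabeledMatrix(mat, rows, cols)
    sep = "," if path.suffix == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: matrix contains NaN or infinite entries")
    return LabeledMatrix(values, [str(i) for i in df.index], [str(c) for c in df.columns])


def write_matrix(mat: LabeledMatrix, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".mtx":
        scipy.io.mmwrite(str(path), sp.coo_matrix(mat.values))
        Path(str(path) + ".rows").write_text("\n".join(mat.row_labels) + "\n")
        Path(str(path) + ".cols").write_text("\n".join(mat.col_labels) + "\n")
        return
    sep = "," if path.suffix == ".csv" else "\t"
    df = pd.DataFrame(mat.toarray(), index=mat.row_labels, columns=mat.col_labels)
    df.to_csv(path, sep=sep, float_format="%.17g")


def read_contacts(path: str | Path) -> ContactList:
    """Read a BEDPE-like contact dump into a :class:`ContactList`.

    Columns: chrom1, start1, end1, chrom2, start2, end2, strength.  Each
    anchor is reduced to its midpoint; inter-chromosomal rows are dropped
    with a logged count.
    """
    pairs = []
    n_inter = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) == 1:
                f = line.split()
            if len(f) < 7:
                raise ValueError(f"{path}, line {lineno}: fewer than 7 columns")
            c1, s1, e1, c2, s2, e2 = f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5])
            strength = float(f[6])
            if strength < 0:
                raise ValueError(f"{path}, line {lineno}: negative strength {strength}")
            if c1 != c2:
                n_inter += 1
                continue
            pairs.append((c1, (s1 + e1) // 2, (s2 + e2) // 2, strength))
    if n_inter:
        logger.info("read_contacts: dropped %d inter-chromosomal rows", n_inter)
    return ContactList(pairs=tuple(pairs))


def write_contacts(contacts: ContactList, path: str | Path) -> None:
    """Write contacts as BEDPE with 1-bp anchors at the stored midpoints."""
    with open(path, "w") as fh:
        for chrom, p1, p2, s in contacts:
            fh.write(f"{chrom}\t{p1}\t{p1 + 1}\t{chrom}\t{p2}\t{p2 + 1}\t{s:.17g}\n")
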