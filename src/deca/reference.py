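"""Synthetic labelled single-cell chromatin-accessibility references.

The generator emulates an annotated scATAC atlas: per-cell-type
accessibility signatures with disjoint marker-peak blocks, sparse
Poisson counts, and peaks laid out along several chromosomes.  It gives
every downstream stage (pseudo-bulk simulation, training, evaluation,
interpretability) a fully known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io import PeakSet

__all__ = ["ReferenceAtlas", "SignatureMatrix", "generate_reference", "true_signatures"]

PEAK_WIDTH = 500
PEAK_SPACING = 5_000


@dataclass
class SignatureMatrix:
    """Cell-type-by-peak matrix of characteristic accessibility (rows in [0,1])."""

    values: np.ndarray
    celltypes: list[str]
    peak_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("signature matrix must be 2-D")
        if self.values.shape != (len(self.celltypes), len(self.peak_ids)):
            raise ValueError("signature labels do not match matrix shape")
        if np.any(self.values < 0):
            raise ValueError("signature entries must be non-negative")


@dataclass
class ReferenceAtlas:
    """Labelled cell-by-peak count matrix plus its peak interval table."""

    counts: sp.csr_matrix
    labels: list[str]
    peaks: PeakSet
    celltypes: list[str]
    marker_blocks: dict | None = None  # celltype -> (start, stop) peak-index slice

    def __post_init__(self):
        if self.counts.shape != (len(self.labels), len(self.peaks)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.labels)} cells x {len(self.peaks)} peaks"
            )
        known = set(self.celltypes)
        for lab in self.labels:
            if lab not in known:
                raise ValueError(f"cell label {lab!r} not in celltypes")
        present = set(self.labels)
        for ct in self.celltypes:
            if ct not in present:
                raise ValueError(f"celltype {ct!r} has no cells")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_peaks(self) -> int:
        return self.counts.shape[1]

    def cells_of_type(self, celltype: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.labels) == celltype)


def _tiled_peaks(n_peaks: int, n_chroms: int) -> PeakSet:
    """Lay peaks round-robin across chromosomes, fixed width and spacing."""
    per_chrom = [0] * n_chroms
    assignment = [i % n_chroms for i in range(n_peaks)]
    records = []
    for i, c in enumerate(assignment):
        start = per_chrom[c] * PEAK_SPACING
        records.append((f"chr{c + 1}", start, start + PEAK_WIDTH, f"peak_{i:05d}"))
        per_chrom[c] += 1
    return PeakSet.from_records(records)


def generate_reference(
    n_celltypes: int,
    n_peaks: int,
    cells_per_type: int,
    n_chroms: int = 3,
    marker_fraction: float = 0.2,
    marker_fold: float = 10.0,
    base_rate: float = 0.1,
    seed: int = 0,
) -> ReferenceAtlas:
    """Generate a labelled synthetic single-cell accessibility atlas.

    Each cell type owns a disjoint, contiguous block of marker peaks
    (``floor(marker_fraction * n_peaks / n_celltypes)`` peaks) whose
    Poisson rate is ``base_rate * marker_fold``; every other peak has rate
    ``base_rate``.  Counts are drawn independently per cell and are
    reproducible for a fixed seed.
    """
    if n_celltypes < 1 or n_peaks < 1 or cells_per_type < 1 or n_chroms < 1:
        raise ValueError("n_celltypes, n_peaks, cells_per_type, n_chroms must be >= 1")
    if not 0 < marker_fraction < 1:
        raise ValueError("marker_fraction must lie in (0, 1)")
    if marker_fold <= 1:
        raise ValueError("marker_fold must exceed 1")
    if base_rate <= 0:
        raise ValueError("base_rate must be positive")
    block = int(marker_fraction * n_peaks / n_celltypes)
    if block < 1:
        raise ValueError(
            f"marker_fraction * n_peaks = {marker_fraction * n_peaks:.1f} leaves no "
            f"room for one marker peak per each of {n_celltypes} cell types"
        )

    rng = np.random.default_rng(seed)
    celltypes = [f"type_{chr(ord('A') + t)}" if t < 26 else f"type_{t}" for t in range(n_celltypes)]
    # marker blocks are contiguous in peak order: type t owns [t*block, (t+1)*block)
    marker_blocks = {ct: (t * block, (t + 1) * block) for t, ct in enumerate(celltypes)}

    rates = np.full((n_celltypes, n_peaks), base_rate)
    for t, ct in enumerate(celltypes):
        lo, hi = marker_blocks[ct]
        rates[t, lo:hi] = base_rate * marker_fold

    labels = []
    rows = []
    for t, ct in enumerate(celltypes):
        counts_t = rng.poisson(rates[t], size=(cells_per_type, n_peaks))
        rows.append(counts_t)
        labels.extend([ct] * cells_per_type)
    counts = sp.csr_matrix(np.vstack(rows))

    return ReferenceAtlas(
        counts=counts,
        labels=labels,
        peaks=_tiled_peaks(n_peaks, n_chroms),
        celltypes=celltypes,
        marker_blocks=marker_blocks,
    )


def minmax_rows(x: np.ndarray) -> np.ndarray:
    """Row-wise min-max scaling to [0,1]; constant rows map to all zeros."""
    x = np.asarray(x, dtype=float)
    lo = x.min(axis=-1, keepdims=True)
    rng = x.max(axis=-1, keepdims=True) - lo
    out = np.zeros_like(x)
    np.divide(x - lo, rng, out=out, where=rng > 0)
    return out


def true_signatures(atlas: ReferenceAtlas) -> SignatureMatrix:
    """Ground-truth signature matrix: per-type mean profile, min-max scaled.

    Row t is the mean count profile over cells labelled t, rescaled per
    row to [0,1] so signatures live on the same scale as min-max
    normalised bulk inputs.  A constant profile maps to all zeros.
    """
    labels = np.asarray(atlas.labels)
    profiles = np.vstack(
        [
            np.asarray(atlas.counts[labels == ct].mean(axis=0)).ravel()
            for ct in atlas.celltypes
        ]
    )
    return SignatureMatrix(minmax_rows(profiles), list(atlas.celltypes), atlas.peaks.peak_ids)
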