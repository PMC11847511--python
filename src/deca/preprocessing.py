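"""Feature-space alignment and per-chromosome patch layout.

Bulk and reference peak sets are intersected (any-overlap, largest
overlap wins), profiles are min-max normalised per sample, and the
shared peaks are chunked into fixed-size patches that never span a
chromosome boundary — each chromosome is its own input channel for the
transformer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import PeakSet, natural_chrom_key
from .reference import minmax_rows

__all__ = ["PatchLayout", "intersect_peaks", "minmax_normalize", "build_patches"]

DEFAULT_PATCH_SIZE = 50


@dataclass
class PatchLayout:
    """Partition of a peak set into per-chromosome patches of size <= s.

    ``patches`` is an ordered list of (chrom, patch_index_within_chrom,
    peak_ids); ``peak_to_patch`` maps each peak id to its (global patch
    index, offset) address.  Every patch except possibly the last per
    chromosome holds exactly ``patch_size`` peaks.
    """

    patch_size: int
    patches: list = field(default_factory=list)
    peak_to_patch: dict = field(default_factory=dict)
    peaks: PeakSet | None = None

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    def chrom_patch_indices(self, chrom: str) -> list[int]:
        """Global patch indices belonging to one chromosome, in order."""
        return [i for i, (c, _, _) in enumerate(self.patches) if c == chrom]

    @property
    def chroms(self) -> list[str]:
        out, seen = [], set()
        for c, _, _ in self.patches:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out

    def patch_lengths(self) -> np.ndarray:
        return np.array([len(ids) for _, _, ids in self.patches])


def intersect_peaks(bulk_peaks: PeakSet, ref_peaks: PeakSet):
    """Intersect bulk and reference peak sets on any-overlap.

    Every reference peak overlapping at least one bulk peak (by >= 1 bp)
    is kept with its reference coordinates; when several bulk peaks
    overlap it, the one with the largest overlap wins (ties to the
    smaller bulk start).  Returns the shared :class:`PeakSet` plus index
    maps peak_id -> column position into the original reference and bulk
    matrices.
    """
    bulk_by_chrom: dict[str, list] = {}
    for j, (chrom, start, end, pid) in enumerate(bulk_peaks):
        bulk_by_chrom.setdefault(chrom, []).append((start, end, pid, j))

    shared_records = []
    ref_index: dict[str, int] = {}
    bulk_index: dict[str, int] = {}
    for i, (chrom, rstart, rend, rpid) in enumerate(ref_peaks):
        best = None  # (overlap, -start) maximised
        for bstart, bend, bpid, j in bulk_by_chrom.get(chrom, ()):
            if bstart >= rend:
                break  # bulk peaks sorted; no later peak can overlap
            overlap = min(rend, bend) - max(rstart, bstart)
            if overlap >= 1:
                key = (overlap, -bstart)
                if best is None or key > best[0]:
                    best = (key, j)
        if best is not None:
            shared_records.append((chrom, rstart, rend, rpid))
            ref_index[rpid] = i
            bulk_index[rpid] = best[1]
    if not shared_records:
        raise ValueError(
            "bulk and reference peak sets share no overlapping regions; "
            "harmonize peak sets (same genome build and chromosome naming) first"
        )
    return PeakSet.from_records(shared_records), bulk_index, ref_index


def minmax_normalize(matrix: np.ndarray) -> np.ndarray:
    """Per-sample (row) min-max scaling to [0,1]; constant rows -> zeros.

    Applied per sample because its purpose is to remove sample-level
    sequencing-depth differences between bulk and pseudo-bulk profiles.
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if not np.all(np.isfinite(matrix)):
        raise ValueError("matrix contains non-finite entries")
    return minmax_rows(matrix)


def build_patches(peaks: PeakSet, patch_size: int = DEFAULT_PATCH_SIZE) -> PatchLayout:
    """Chunk peaks into consecutive per-chromosome windows of ``patch_size``.

    The final short window on each chromosome is kept (it is zero-padded
    at model-input time rather than dropped, so no peak ever leaves the
    model's output space).  Global patch indices run chromosome by
    chromosome in natural chromosome order.
    """
    if patch_size < 1:
        raise ValueError("patch_size must be >= 1")
    if len(peaks) == 0:
        raise ValueError("cannot build patches from an empty peak set")

    by_chrom: dict[str, list[str]] = {}
    for chrom, _, _, pid in peaks:
        by_chrom.setdefault(chrom, []).append(pid)

    layout = PatchLayout(patch_size=patch_size, peaks=peaks)
    for chrom in sorted(by_chrom, key=natural_chrom_key):
        ids = by_chrom[chrom]
        for pi, lo in enumerate(range(0, len(ids), patch_size)):
            chunk = ids[lo : lo + patch_size]
            gidx = len(layout.patches)
            layout.patches.append((chrom, pi, chunk))
            for off, pid in enumerate(chunk):
                layout.peak_to_patch[pid] = (gidx, off)
    return layout
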