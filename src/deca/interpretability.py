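"""Patch-attention interpretability and chromatin-contact overlap testing.

The encoder's attention weights between patches on the same chromosome
are extracted, categorised into High/Median/Low tertiles, and compared
with an external chromatin-interaction map (e.g. a Hi-C dump): the top
fraction of patch pairs by |attention| is intersected with the top
pairs by contact strength, and significance is assessed by a genomic
permutation test in which contact-pair positions are circularly shifted
along the patch axis — a distance-preserving null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import ContactList
from .model import DecaModel, forward
from .preprocessing import PatchLayout

logger = logging.getLogger(__name__)

__all__ = [
    "AttentionMap",
    "OverlapResult",
    "extract_attention",
    "categorize_attention",
    "contacts_to_patch_pairs",
    "overlap_permutation_test",
]

AGGREGATIONS = ("mean_heads_last_layer", "mean_heads_all_layers")


@dataclass
class AttentionMap:
    """Per-chromosome symmetric patch-by-patch attention weights."""

    per_chrom: dict = field(default_factory=dict)  # chrom -> (patch_ids, W)
    layer: int = -1
    aggregation: str = "mean_heads_last_layer"

    def __post_init__(self):
        for chrom, (ids, W) in self.per_chrom.items():
            W = np.asarray(W)
            if W.shape != (len(ids), len(ids)):
                raise ValueError(f"{chrom}: weight matrix does not match patch ids")
            if not np.all(np.isfinite(W)):
                raise ValueError(f"{chrom}: non-finite attention weights")
            if not np.allclose(W, W.T, atol=1e-9):
                raise ValueError(f"{chrom}: attention matrix not symmetric")


@dataclass
class OverlapResult:
    n_attention_selected: int
    n_contact_selected: int
    n_overlap: int
    p_value: float
    n_permutations: int

    def __post_init__(self):
        if self.n_overlap > min(self.n_attention_selected, self.n_contact_selected):
            raise ValueError("overlap exceeds the smaller selected set")
        if not 0 < self.p_value <= 1:
            raise ValueError("p_value must lie in (0, 1]")


def extract_attention(
    model: DecaModel,
    x: np.ndarray,
    layout: PatchLayout,
    aggregation: str = "mean_heads_last_layer",
) -> AttentionMap:
    """Harvest patch-patch attention from a forward pass on one profile.

    Per-layer, per-head attention is captured, averaged over heads (and
    over layers for ``mean_heads_all_layers``), the class-token row and
    column are dropped, the map is restricted to within-chromosome
    blocks, and each block is symmetrised W <- (W + W^T)/2.
    """
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if model.config.L == 0:
        raise ValueError("cannot extract attention from a depth-0 encoder")
    out = forward(model, np.atleast_2d(x)[:1], capture_attention=True)
    atts = out["attentions"]  # list of (1, h, T, T)
    if aggregation == "mean_heads_last_layer":
        A = atts[-1][0].mean(axis=0)  # (T, T)
        layer = len(atts) - 1
    else:
        A = np.mean([a[0].mean(axis=0) for a in atts], axis=0)
        layer = -1
    A = A[1:, 1:]  # drop class token row/column

    per_chrom = {}
    for chrom in layout.chroms:
        idx = np.asarray(layout.chrom_patch_indices(chrom))
        W = A[np.ix_(idx, idx)]
        W = 0.5 * (W + W.T)
        per_chrom[chrom] = (idx.tolist(), W)
    return AttentionMap(per_chrom=per_chrom, layer=layer, aggregation=aggregation)


def categorize_attention(att_map: AttentionMap) -> dict:
    """Split each chromosome's off-diagonal |weights| at empirical tertiles.

    Returns chrom -> string matrix with 'High'/'Median'/'Low' off the
    diagonal and '' on it.  Ties at a tertile boundary fall into the
    lower category; fewer than 3 distinct off-diagonal values yields all
    'Median' with a warning.
    """
    out = {}
    for chrom, (ids, W) in att_map.per_chrom.items():
        p = len(ids)
        labels = np.full((p, p), "", dtype=object)
        if p < 2:
            out[chrom] = labels
            continue
        off_mask = ~np.eye(p, dtype=bool)
        vals = np.abs(W[off_mask])
        if len(np.unique(vals)) < 3:
            logger.warning("%s: fewer than 3 distinct attention values; all Median", chrom)
            labels[off_mask] = "Median"
            out[chrom] = labels
            continue
        # tertile cuts over unique pair values (upper triangle), remainder
        # assigned Low, Median, High in that order
        iu = np.triu_indices(p, k=1)
        pair_vals = np.sort(np.abs(W[iu]))
        npairs = len(pair_vals)
        base, rem = divmod(npairs, 3)
        n_low = base + (1 if rem >= 1 else 0)
        n_med = base + (1 if rem >= 2 else 0)
        low_cut = pair_vals[n_low - 1]
        med_cut = pair_vals[n_low + n_med - 1]
        absW = np.abs(W)
        cat = np.where(absW <= low_cut, "Low", np.where(absW <= med_cut, "Median", "High"))
        labels[off_mask] = cat[off_mask]
        out[chrom] = labels
    return out


def contacts_to_patch_pairs(contacts: ContactList, layout: PatchLayout) -> dict:
    """Accumulate contact strengths onto symmetric patch-pair matrices.

    Each contact's two positions are mapped to the patch whose peak
    contains them (or the nearest peak, when the position falls inside
    the chromosome's peak span); contacts outside any chromosome span or
    on chromosomes absent from the layout are dropped with a logged
    count.  Patch indices in the output are chromosome-local (0..p-1).
    """
    if layout.peaks is None:
        raise ValueError("layout carries no peak coordinates")
    # per-chrom peak interval arrays + peak -> local patch index
    chrom_peaks: dict[str, list] = {}
    for chrom, start, end, pid in layout.peaks:
        gidx, _ = layout.peak_to_patch[pid]
        chrom_peaks.setdefault(chrom, []).append((start, end, gidx))
    chrom_arrays = {}
    for chrom, lst in chrom_peaks.items():
        starts = np.array([t[0] for t in lst])
        ends = np.array([t[1] for t in lst])
        gidx = np.array([t[2] for t in lst])
        local = {g: i for i, g in enumerate(layout.chrom_patch_indices(chrom))}
        chrom_arrays[chrom] = (starts, ends, np.array([local[g] for g in gidx]))

    matrices = {
        chrom: np.zeros((len(layout.chrom_patch_indices(chrom)),) * 2)
        for chrom in layout.chroms
    }
    n_dropped = 0

    def locate(chrom: str, pos: int):
        starts, ends, patch_of_peak = chrom_arrays[chrom]
        if pos < starts[0] or pos >= ends[-1]:
            return None  # outside the chromosome's peak span
        i = np.searchsorted(starts, pos, side="right") - 1
        if i >= 0 and starts[i] <= pos < ends[i]:
            return patch_of_peak[i]
        # between peaks: nearest by distance to interval edge
        right = min(i + 1, len(starts) - 1)
        d_left = pos - ends[i] if i >= 0 else np.inf
        d_right = starts[right] - pos
        return patch_of_peak[i if d_left <= d_right else right]

    for chrom, p1, p2, strength in contacts:
        if chrom not in chrom_arrays:
            n_dropped += 1
            continue
        a, b = locate(chrom, p1), locate(chrom, p2)
        if a is None or b is None:
            n_dropped += 1
            continue
        matrices[chrom][a, b] += strength
        if a != b:
            matrices[chrom][b, a] += strength
    if n_dropped:
        logger.info("contacts_to_patch_pairs: dropped %d unmappable contacts", n_dropped)
    return matrices


def _top_pairs(W: np.ndarray, n_select: int) -> set:
    """Top n unordered off-diagonal pairs (i<j) by |value|, deterministic."""
    p = W.shape[0]
    iu, ju = np.triu_indices(p, k=1)
    vals = np.abs(W[iu, ju])
    order = np.lexsort((iu, ju, -vals))  # value desc, then (j, i) for stable ties
    return {(int(iu[o]), int(ju[o])) for o in order[:n_select]}


def overlap_permutation_test(
    attention: AttentionMap,
    contact_matrix: dict,
    top_fraction: float = 0.05,
    n_permutations: int = 50_000,
    seed: int = 0,
) -> OverlapResult:
    """Test whether high-attention patch pairs coincide with strong contacts.

    Per chromosome, the top ``top_fraction`` of off-diagonal pairs by
    |attention| and, separately, by contact strength are selected; the
    observed statistic is the total intersection size.  The null shifts
    each chromosome's selected contact pairs by a uniformly random
    non-zero circular offset along the patch axis (preserving the
    pair-distance structure) and recomputes the overlap; the add-one
    estimator p = (1 + #{null >= obs}) / (1 + n_permutations) never
    returns 0.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must lie in (0, 1)")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1 (p undefined otherwise)")

    rng = np.random.default_rng(seed)
    per_chrom = []
    n_att_total = n_con_total = observed = 0
    for chrom, (ids, W) in attention.per_chrom.items():
        p = len(ids)
        n_pairs = p * (p - 1) // 2
        if n_pairs == 0:
            continue
        C = np.asarray(contact_matrix[chrom])
        if C.shape != (p, p):
            raise ValueError(f"{chrom}: contact matrix shape {C.shape} != ({p}, {p})")
        n_select = int(np.ceil(top_fraction * n_pairs))
        att_top = _top_pairs(W, n_select)
        # zero-strength pairs are absent contacts, not weak ones: never select them
        iu_, ju_ = np.triu_indices(p, k=1)
        n_nonzero = int(np.count_nonzero(C[iu_, ju_]))
        con_top = _top_pairs(C, min(n_select, n_nonzero))
        n_att_total += len(att_top)
        n_con_total += len(con_top)
        observed += len(att_top & con_top)
        per_chrom.append((p, att_top, con_top))
    if n_att_total == 0:
        raise ValueError("top_fraction selects zero pairs on every chromosome")

    null_ge = 0
    for _ in range(n_permutations):
        stat = 0
        for p, att_top, con_top in per_chrom:
            if p < 2:
                continue
            offset = int(rng.integers(1, p)) if p > 2 else 1
            shifted = set()
            for i, j in con_top:
                a, b = (i + offset) % p, (j + offset) % p
                shifted.add((a, b) if a < b else (b, a))
            stat += len(att_top & shifted)
        if stat >= observed:
            null_ge += 1
    p_value = (1 + null_ge) / (1 + n_permutations)
    return OverlapResult(
        n_attention_selected=n_att_total,
        n_contact_selected=n_con_total,
        n_overlap=observed,
        p_value=p_value,
        n_permutations=n_permutations,
    )
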