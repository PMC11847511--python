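"""Pseudo-bulk simulation with known cell-type proportions.

Proportion vectors are drawn from a Dirichlet under four regimes —
Random, Rare (one type below 5%), Dominant (one type above 50%) and
Average (all types nearly equal) — then labelled single cells are mixed
at those proportions and the summed profile is min-max normalised per
sample, mirroring how real bulk inputs are normalised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reference import ReferenceAtlas, SignatureMatrix, minmax_rows, true_signatures

__all__ = [
    "REGIMES",
    "ProportionVector",
    "PseudoBulkBatch",
    "simulate_proportions",
    "largest_remainder_counts",
    "make_pseudobulk",
]

REGIMES = ("random", "rare", "dominant", "average")

_AVG_SPREAD = 0.049  # target max-min for the Average regime (< 0.05 invariant)


@dataclass(frozen=True)
class ProportionVector:
    """A point on the k-simplex plus the regime that produced it."""

    p: np.ndarray
    regime: str

    def __post_init__(self):
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if np.any(self.p < 0):
            raise ValueError("proportions must be non-negative")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {self.p.sum()}, not 1")
        k = len(self.p)
        if k > 1:
            if self.regime == "dominant" and self.p.max() <= 0.5:
                raise ValueError("dominant regime requires max(p) > 0.5")
            if self.regime == "rare" and self.p.min() >= 0.05:
                raise ValueError("rare regime requires min(p) < 0.05")
            if self.regime == "average" and self.p.max() - self.p.min() >= 0.05:
                raise ValueError("average regime requires max(p) - min(p) < 0.05")


@dataclass
class PseudoBulkBatch:
    """Mixed bulk profiles with their generating ground truth."""

    bulk: np.ndarray  # samples x peaks, min-max normalised per sample
    P_true: np.ndarray  # samples x k realised proportions
    M_true: SignatureMatrix
    n_cells_per_sample: int
    regimes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if np.any(np.abs(self.P_true.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each P_true row must sum to 1")
        if self.bulk.min() < 0 or self.bulk.max() > 1:
            raise ValueError("bulk entries must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.bulk.shape[0]


def _average_vector(k: int, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """1/k plus Dirichlet jitter shrunk until max - min < 0.05."""
    d = rng.dirichlet(np.full(k, alpha))
    dev = d - 1.0 / k
    spread = dev.max() - dev.min()
    scale = 1.0 if spread == 0 else min(1.0, _AVG_SPREAD / spread)
    if dev.min() < 0:  # keep entries non-negative for very large k
        scale = min(scale, (1.0 / k) / -dev.min())
    return 1.0 / k + scale * dev


def simulate_proportions(
    k: int,
    n_samples: int,
    regime: str,
    alpha: float = 1.0,
    seed: int = 0,
) -> list[ProportionVector]:
    """Draw ``n_samples`` proportion vectors for ``k`` cell types.

    Random draws Dirichlet(alpha * 1_k).  Dominant rescales one uniformly
    chosen coordinate to U(0.5, 0.9] and renormalises the rest; Rare
    rescales one coordinate to U(0, 0.05); Average centres all entries at
    1/k with Dirichlet jitter shrunk below the 0.05 spread bound.  The
    post-hoc rescaling guarantees the regime thresholds deterministically
    rather than by rejection.
    """
    regime = regime.lower()
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_samples):
        if k == 1:
            out.append(ProportionVector(np.array([1.0]), regime))
            continue
        if regime == "average":
            p = _average_vector(k, alpha, rng)
        else:
            p = rng.dirichlet(np.full(k, alpha))
            if regime in ("dominant", "rare"):
                i = rng.integers(k)
                if regime == "dominant":
                    target = rng.uniform(0.5, 0.9)
                    target = np.nextafter(target, 1.0)  # open at 0.5, closed at 0.9
                else:
                    target = rng.uniform(0.0, 0.05)
                rest = p.sum() - p[i]
                if rest <= 0:  # degenerate one-hot draw: spread remainder evenly
                    p = np.full(k, (1.0 - target) / (k - 1))
                else:
                    p = p * (1.0 - target) / rest
                p[i] = target
        p = p / p.sum()
        out.append(ProportionVector(p, regime))
    return out


def largest_remainder_counts(p: np.ndarray, n: int) -> np.ndarray:
    """Integer cell counts summing to ``n`` with proportions closest to ``p``.

    Floor each quota, then hand out the remaining units by descending
    fractional remainder; ties go to the lower type index.
    """
    quota = np.asarray(p, dtype=float) * n
    counts = np.floor(quota).astype(int)
    short = n - counts.sum()
    if short > 0:
        remainder = quota - counts
        # stable argsort on negated remainders: ties broken by type order
        order = np.argsort(-remainder, kind="stable")
        counts[order[:short]] += 1
    return counts


def make_pseudobulk(
    atlas: ReferenceAtlas,
    proportions: list[ProportionVector],
    n_cells_per_sample: int = 500,
    seed: int = 0,
) -> PseudoBulkBatch:
    """Mix reference cells at the given proportions into pseudo-bulk samples.

    For each sample, ``round(p_t * n_cells)`` cells of type t (largest-
    remainder rounding, so counts sum exactly) are drawn with replacement
    and their count rows summed; the sum is min-max normalised.  P_true
    stores the realised post-rounding proportions; M_true the atlas's
    ground-truth signatures.
    """
    k = len(atlas.celltypes)
    counts = atlas.counts.tocsr()
    type_indices = {ct: atlas.cells_of_type(ct) for ct in atlas.celltypes}
    rng = np.random.default_rng(seed)

    bulk_rows, p_rows, regimes = [], [], []
    for pv in proportions:
        if len(pv.p) != k:
            raise ValueError(f"proportion vector has {len(pv.p)} entries, atlas has {k} types")
        n_per_type = largest_remainder_counts(pv.p, n_cells_per_sample)
        profile = np.zeros(atlas.n_peaks)
        for t, ct in enumerate(atlas.celltypes):
            if n_per_type[t] == 0:
                continue
            pool = type_indices[ct]
            if len(pool) == 0:
                raise ValueError(f"cell type {ct!r} has no reference cells but nonzero proportion")
            chosen = rng.choice(pool, size=n_per_type[t], replace=True)
            profile += np.asarray(counts[chosen].sum(axis=0)).ravel()
        bulk_rows.append(profile)
        p_rows.append(n_per_type / n_cells_per_sample)
        regimes.append(pv.regime)

    bulk = minmax_rows(np.vstack(bulk_rows)) if bulk_rows else np.zeros((0, atlas.n_peaks))
    P_true = np.vstack(p_rows) if p_rows else np.zeros((0, k))
    return PseudoBulkBatch(
        bulk=bulk,
        P_true=P_true,
        M_true=true_signatures(atlas),
        n_cells_per_sample=n_cells_per_sample,
        regimes=regimes,
    )
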