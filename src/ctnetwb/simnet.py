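"""Per-subject morphological similarity networks from cortical thickness.

For every unordered pair of parcels the two thickness distributions are
binned into 30 equal-width bins spanning the *pooled* min-max of the pair
(a shared support, so bin-wise frequencies compare like with like), and the
Pearson correlation of the two 30-bin frequency vectors measures how similar
the two distribution shapes are. The absolute correlation becomes the edge
weight: negative correlations (anti-correlated distribution curves) are a
small minority and enter by magnitude. The result is one symmetric
parcel-by-parcel similarity matrix per subject with zero diagonal.

Frequencies are raw vertex counts; Pearson correlation is invariant to the
counts-versus-proportions choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .thickness import ParcelTable, SubjectThickness

__all__ = [
    "DegeneratePairError",
    "PairHistograms",
    "SimilarityMatrix",
    "pair_histograms",
    "histogram_similarity",
    "build_similarity_matrix",
    "write_similarity_matrix",
    "read_similarity_matrix",
]

logger = logging.getLogger(__name__)


class DegeneratePairError(ValueError):
    """A pair of parcels carries no usable distribution-shape information."""


@dataclass(frozen=True)
class PairHistograms:
    """Shared-support histograms for one pair of parcels."""

    bin_edges: np.ndarray  # n_bins + 1 strictly increasing thickness values (mm)
    freq_x: np.ndarray  # vertex counts per bin
    freq_y: np.ndarray


@dataclass
class SimilarityMatrix:
    subject_id: str
    names: list[str]
    values: np.ndarray = field(repr=False)
    n_degenerate_pairs: int = 0
    frac_negative: float = 0.0

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.names)
        if v.shape != (n, n):
            raise ValueError("similarity matrix shape does not match node list")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("similarity matrix diagonal must be zero")
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("similarity entries must lie in [0, 1]")


def _bin_counts(values: np.ndarray, lo: float, hi: float, n_bins: int) -> np.ndarray:
    # equal-width bins on [lo, hi], last bin right-closed
    scale = n_bins / (hi - lo)
    idx = np.clip(((values - lo) * scale).astype(np.int64), 0, n_bins - 1)
    return np.bincount(idx, minlength=n_bins)


def pair_histograms(x, y, n_bins: int = 30) -> PairHistograms:
    """Histogram a pair of thickness vectors over their pooled range."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("thickness vectors must be nonempty")
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    if hi == lo:
        raise DegeneratePairError("pooled thickness range is zero")
    edges = np.linspace(lo, hi, n_bins + 1)
    return PairHistograms(
        bin_edges=edges,
        freq_x=_bin_counts(x, lo, hi, n_bins),
        freq_y=_bin_counts(y, lo, hi, n_bins),
    )


def histogram_similarity(h: PairHistograms) -> float:
    """Pearson correlation of the two frequency vectors, in [-1, 1]."""
    fx = h.freq_x.astype(float)
    fy = h.freq_y.astype(float)
    fx = fx - fx.mean()
    fy = fy - fy.mean()
    denom = np.sqrt((fx @ fx) * (fy @ fy))
    if denom == 0:
        raise DegeneratePairError("zero-variance frequency vector")
    return float(np.clip((fx @ fy) / denom, -1.0, 1.0))


def build_similarity_matrix(
    subject: SubjectThickness,
    table: ParcelTable,
    n_bins: int = 30,
    max_degenerate_frac: float = 0.10,
) -> SimilarityMatrix:
    """Absolute histogram-similarity matrix over all parcel pairs.

    Degenerate pairs (zero pooled range or zero-variance histogram) get
    similarity 0 with a logged warning; more than ``max_degenerate_frac`` of
    degenerate pairs is treated as a data pathology and raises.
    """
    subject.validate(table)
    names = table.names
    n = len(names)
    vecs = [np.asarray(subject.values[name], dtype=float) for name in names]
    mins = np.array([v.min() for v in vecs])
    maxs = np.array([v.max() for v in vecs])

    S = np.zeros((n, n))
    n_degenerate = 0
    n_negative = 0
    n_pairs = n * (n - 1) // 2
    for i in range(n):
        for j in range(i + 1, n):
            lo = min(mins[i], mins[j])
            hi = max(maxs[i], maxs[j])
            if hi == lo:
                n_degenerate += 1
                continue
            fx = _bin_counts(vecs[i], lo, hi, n_bins).astype(float)
            fy = _bin_counts(vecs[j], lo, hi, n_bins).astype(float)
            fx -= fx.mean()
            fy -= fy.mean()
            denom = np.sqrt((fx @ fx) * (fy @ fy))
            if denom == 0:
                n_degenerate += 1
                continue
            r = float(np.clip((fx @ fy) / denom, -1.0, 1.0))
            if r < 0:
                n_negative += 1
            S[i, j] = S[j, i] = abs(r)

    if n_degenerate:
        logger.warning(
            "subject %s: %d/%d degenerate parcel pairs set to similarity 0",
            subject.subject_id,
            n_degenerate,
            n_pairs,
        )
    if n_degenerate > max_degenerate_frac * n_pairs:
        raise ValueError(
            f"subject {subject.subject_id}: {n_degenerate}/{n_pairs} degenerate "
            "pairs -- inspect input data"
        )
    frac_negative = n_negative / n_pairs
    logger.debug(
        "subject %s: %.1f%% negative raw correlations",
        subject.subject_id,
        100 * frac_negative,
    )
    return SimilarityMatrix(
        subject_id=subject.subject_id,
        names=list(names),
        values=S,
        n_degenerate_pairs=n_degenerate,
        frac_negative=frac_negative,
    )


def write_similarity_matrix(sim: SimilarityMatrix, path) -> None:
    pd.DataFrame(sim.values, index=sim.names, columns=sim.names).to_csv(path, sep="\t")


def read_similarity_matrix(path, subject_id: str | None = None) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if subject_id is None:
        import os

        subject_id = os.path.splitext(os.path.basename(str(path)))[0]
    return SimilarityMatrix(
        subject_id=subject_id, names=[str(c) for c in df.columns], values=df.to_numpy()
    )
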