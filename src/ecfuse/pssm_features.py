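"""Mutation-histogram feature map XL from a position-specific score matrix.

Pipeline: optionally build a PSSM from an alignment profile and a
substitution-rate matrix; group PSSM rows by the residue type carried at
each position; histogram every target-type column over [-12, 13] with 25
unit-width bins; smooth each histogram with a short 1D Gaussian kernel; and
stack everything into the fixed-shape [20 x 20 x 25] tensor XL.

Histograms are normalized to probability mass 1 per (source, target) pair so
XL is independent of sequence length; residue types absent from the sequence
yield all-zero slices.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_formats import AA1_ORDER, PSSMProfile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MutationHistogramSpec:
    """Binning/smoothing parameters for the XL histograms."""

    vmin: float = -12.0
    vmax: float = 13.0
    nbins: int = 25
    sigma: float = 0.5  # bins

    def __post_init__(self) -> None:
        if self.nbins < 1:
            raise ValueError("nbins must be >= 1")
        if not self.vmax > self.vmin:
            raise ValueError("vmax must exceed vmin")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def bin_width(self) -> float:
        return (self.vmax - self.vmin) / self.nbins

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.vmin, self.vmax, self.nbins + 1)


def gaussian_kernel_1d(sigma: float, radius: int = 2) -> np.ndarray:
    """Discrete Gaussian kernel on integer offsets [-radius, radius], sum 1."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def compute_pssm_from_msa(
    gamma: np.ndarray, w: np.ndarray, sequence: str | None = None
) -> PSSMProfile:
    """Build a PSSM as the profile/substitution-matrix product.

    ``scores[i, j] = sum_k gamma[i, k] * w[k, j]`` where ``gamma`` is the
    L x 20 per-position frequency-ratio profile and ``w`` a 20 x 20
    substitution-rate (Dayhoff-style) matrix, both in :data:`AA1_ORDER`.

    If ``sequence`` is omitted it is taken as the per-position argmax of
    ``gamma`` (the dominant residue of the alignment column).
    """
    gamma = np.asarray(gamma, dtype=float)
    w = np.asarray(w, dtype=float)
    if gamma.ndim != 2 or gamma.shape[1] != 20:
        raise ValueError(f"gamma must be L x 20, got {gamma.shape}")
    if w.shape != (20, 20):
        raise ValueError(f"w must be 20 x 20, got {w.shape}")
    if not (np.all(np.isfinite(gamma)) and np.all(np.isfinite(w))):
        raise ValueError("non-finite input")
    scores = gamma @ w
    if sequence is None:
        sequence = "".join(AA1_ORDER[k] for k in np.argmax(gamma, axis=1))
    return PSSMProfile(sequence=sequence, scores=scores)


def load_mutation_matrix(path: str | os.PathLike) -> np.ndarray:
    """Load a whitespace-delimited 20 x 20 substitution-rate matrix."""
    w = np.loadtxt(Path(path), dtype=float)
    if w.shape != (20, 20):
        raise ValueError(f"{path}: expected 20 x 20 matrix, got {w.shape}")
    return w


def group_rows_by_residue_type(pssm: PSSMProfile) -> dict[str, np.ndarray]:
    """Split PSSM rows by the residue type at each position.

    Returns a map from one-letter code to the (count x 20) stack of that
    type's rows, original position order preserved.  Positions whose code is
    not one of the standard 20 are skipped with a warning.
    """
    buckets: dict[str, list[np.ndarray]] = {}
    for i, aa in enumerate(pssm.sequence):
        if aa not in AA1_ORDER:
            logger.warning("position %d: nonstandard code %r skipped", i, aa)
            continue
        buckets.setdefault(aa, []).append(pssm.scores[i])
    return {aa: np.vstack(rows) for aa, rows in buckets.items()}


def mutation_histogram(
    Y: np.ndarray, spec: MutationHistogramSpec = MutationHistogramSpec()
) -> np.ndarray:
    """Per-target-type histograms of one residue type's PSSM rows.

    Row ``j`` of the (20 x nbins) result is the histogram of column ``j`` of
    ``Y`` over [vmin, vmax] (left-closed equal bins, last bin closed;
    out-of-range values clipped into the end bins), normalized to sum 1.
    An empty ``Y`` yields the zero matrix.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != 20:
        raise ValueError(f"Y must have 20 columns, got {Y.shape}")
    out = np.zeros((20, spec.nbins))
    if Y.shape[0] == 0:
        return out
    clipped = np.clip(Y, spec.vmin, spec.vmax)
    for j in range(20):
        counts, _ = np.histogram(
            clipped[:, j], bins=spec.nbins, range=(spec.vmin, spec.vmax)
        )
        out[j] = counts / Y.shape[0]
    return out


def smooth_histogram_1d(h: np.ndarray, sigma: float = 0.5) -> np.ndarray:
    """Smooth a histogram with a truncated Gaussian kernel, conserving mass.

    The kernel spans +-2 bins and is renormalized to sum 1; the input is
    extended by symmetric (mirror) padding so total mass is conserved
    exactly for any input length.
    """
    h = np.asarray(h, dtype=float)
    if h.ndim != 1:
        raise ValueError("h must be 1-D")
    kernel = gaussian_kernel_1d(sigma, radius=2)
    padded = np.pad(h, 2, mode="symmetric")
    return np.convolve(padded, kernel, mode="valid")


def build_xl(
    pssm: PSSMProfile, spec: MutationHistogramSpec = MutationHistogramSpec()
) -> np.ndarray:
    """Assemble the [20 x 20 x nbins] mutation feature map XL.

    ``XL[n, j, :]`` is the smoothed, normalized histogram of scores toward
    target type ``j`` over all positions carrying source type ``n`` (both
    axes in :data:`AA1_ORDER`).  Source types absent from the sequence give
    all-zero slices.
    """
    groups = group_rows_by_residue_type(pssm)
    xl = np.zeros((20, 20, spec.nbins))
    for aa, Y in groups.items():
        n = AA1_ORDER.index(aa)
        hist = mutation_histogram(Y, spec)
        for j in range(20):
            xl[n, j] = smooth_histogram_1d(hist[j], spec.sigma)
    return xl
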