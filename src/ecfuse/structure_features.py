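"""Backbone-geometry feature maps: torsion angles (XA) and Ca distances (XD).

XA is a [19 x 19 x 23] tensor: per residue-type channel, the 2D histogram of
(phi, psi) backbone dihedrals over [-180, 180] x [-180, 180], smoothed with a
2D Gaussian kernel.  XD is a [23 x 23 x 8] tensor: per ordered residue-type
pair, the histogram of pairwise Ca-Ca distances over [5, 40] Angstrom,
smoothed along the bin axis.  Both are normalized per channel/slice so the
maps are independent of protein length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import EXTENDED23, STANDARD20, ProteinStructure
from .pssm_features import gaussian_kernel_1d, smooth_histogram_1d

_STD_INDEX = {code: i for i, code in enumerate(STANDARD20)}


def map_to_extended23(code: str) -> int:
    """Map a residue code to its channel in the 23-type extended alphabet.

    Standard codes keep their alphabetical index 0-19; ASX -> 20, GLX -> 21;
    every other (modified/nonstandard) code falls into the catch-all
    channel 22.  The mapping is total: it never fails for a nonempty code.
    """
    if not code:
        raise ValueError("empty residue code")
    code = code.upper()
    if code in _STD_INDEX:
        return _STD_INDEX[code]
    if code == "ASX":
        return 20
    if code == "GLX":
        return 21
    return 22


@dataclass(frozen=True)
class AngleHistogramSpec:
    """19 equal bins per axis on [-180, 180] degrees, Gaussian-smoothed."""

    nbins: int = 19
    sigma: float = 0.5  # bins

    def __post_init__(self) -> None:
        if self.nbins < 1:
            raise ValueError("nbins must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def bin_width(self) -> float:
        return 360.0 / self.nbins


@dataclass(frozen=True)
class DistanceHistogramSpec:
    """8 equal bins on [5, 40] Angstrom; d > 40 clipped into the last bin,
    d < 5 discarded; optional minimum sequence separation between pairs."""

    vmin: float = 5.0
    vmax: float = 40.0
    nbins: int = 8
    sigma: float = 0.5  # bins
    min_separation: int = 0

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


@dataclass
class TorsionAngles:
    """Per-residue phi/psi in degrees, NaN where undefined."""

    phi: np.ndarray
    psi: np.ndarray

    def __len__(self) -> int:
        return len(self.phi)


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral of four points, IUPAC convention, in [-180, 180)."""
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    ang = np.degrees(np.arctan2(y, x))
    return -180.0 if ang >= 180.0 else float(ang)


def compute_torsion_angles(structure: ProteinStructure) -> TorsionAngles:
    """Backbone phi/psi per residue; NaN wherever a defining atom is absent.

    ``phi[i]`` uses C(i-1), N(i), CA(i), C(i); ``psi[i]`` uses N(i), CA(i),
    C(i), N(i+1).  The first residue has no phi, the last no psi.
    """
    L = len(structure.residues)
    phi = np.full(L, np.nan)
    psi = np.full(L, np.nan)
    res = structure.residues
    for i in range(L):
        if i > 0 and all(
            p is not None for p in (res[i - 1].c, res[i].n, res[i].ca, res[i].c)
        ):
            phi[i] = dihedral(res[i - 1].c, res[i].n, res[i].ca, res[i].c)
        if i < L - 1 and all(
            p is not None for p in (res[i].n, res[i].ca, res[i].c, res[i + 1].n)
        ):
            psi[i] = dihedral(res[i].n, res[i].ca, res[i].c, res[i + 1].n)
    return TorsionAngles(phi=phi, psi=psi)


def _bin_index(value: float, vmin: float, width: float, nbins: int) -> int:
    """Left-closed equal bins; ties at internal edges go right; last bin closed."""
    idx = int(np.floor((value - vmin) / width))
    return min(max(idx, 0), nbins - 1)


def smooth_histogram_2d(H: np.ndarray, sigma: float = 0.5) -> np.ndarray:
    """Separable 2D Gaussian smoothing (+-2 bin kernel, symmetric padding).

    Conserves total mass exactly, matching :func:`smooth_histogram_1d`
    applied along each axis.
    """
    out = np.apply_along_axis(smooth_histogram_1d, 0, np.asarray(H, float), sigma)
    return np.apply_along_axis(smooth_histogram_1d, 1, out, sigma)


def build_xa(
    structure: ProteinStructure,
    torsions: TorsionAngles | None = None,
    spec: AngleHistogramSpec = AngleHistogramSpec(),
    normalize: bool = True,
    smooth: bool = True,
) -> np.ndarray:
    """Assemble the [nbins x nbins x 23] torsion-angle feature map XA.

    Each residue with both dihedrals defined adds one count at its
    (phi-bin, psi-bin) cell in the channel of its residue type; channels are
    then normalized to mass 1 and smoothed with a 2D Gaussian kernel.
    """
    if torsions is None:
        torsions = compute_torsion_angles(structure)
    xa = np.zeros((spec.nbins, spec.nbins, 23))
    w = spec.bin_width
    for res, phi, psi in zip(structure.residues, torsions.phi, torsions.psi):
        if np.isnan(phi) or np.isnan(psi):
            continue
        a = _bin_index(phi, -180.0, w, spec.nbins)
        b = _bin_index(psi, -180.0, w, spec.nbins)
        xa[a, b, map_to_extended23(res.name)] += 1.0
    for ch in range(23):
        total = xa[:, :, ch].sum()
        if total > 0 and normalize:
            xa[:, :, ch] /= total
        if smooth:
            xa[:, :, ch] = smooth_histogram_2d(xa[:, :, ch], spec.sigma)
    return xa


def pairwise_ca_distances(
    structure: ProteinStructure, min_separation: int = 0
) -> list[tuple[str, str, float]]:
    """Euclidean Ca-Ca distances for all unordered residue pairs i < j.

    Residues lacking a CA atom are skipped.  ``min_separation`` requires
    ``j - i > min_separation`` in sequence positions (0 keeps all pairs).
    """
    entries = [
        (i, r.name, r.ca) for i, r in enumerate(structure.residues) if r.ca is not None
    ]
    out: list[tuple[str, str, float]] = []
    if len(entries) < 2:
        return out
    coords = np.vstack([e[2] for e in entries])
    for a in range(len(entries)):
        for b in range(a + 1, len(entries)):
            if entries[b][0] - entries[a][0] <= min_separation and min_separation > 0:
                continue
            d = float(np.linalg.norm(coords[a] - coords[b]))
            out.append((entries[a][1], entries[b][1], d))
    return out


def build_xd(
    pairs: Iterable[tuple[str, str, float]],
    spec: DistanceHistogramSpec = DistanceHistogramSpec(),
    normalize: bool = True,
    smooth: bool = True,
) -> np.ndarray:
    """Assemble the [23 x 23 x nbins] Ca-distance feature map XD.

    Every pair contributes one count to both ordered type cells (i, j) and
    (j, i), so XD is symmetric in its first two axes by construction.
    Distances below ``vmin`` are discarded; those above ``vmax`` are clipped
    into the last bin.  Slices are normalized to mass 1 and smoothed along
    the distance-bin axis.
    """
    xd = np.zeros((23, 23, spec.nbins))
    w = spec.bin_width
    for code_i, code_j, d in pairs:
        if d < spec.vmin:
            continue
        k = _bin_index(d, spec.vmin, w, spec.nbins)
        ci, cj = map_to_extended23(code_i), map_to_extended23(code_j)
        xd[ci, cj, k] += 1.0
        if cj != ci:
            xd[cj, ci, k] += 1.0
    for i in range(23):
        for j in range(23):
            total = xd[i, j].sum()
            if total == 0:
                continue
            if normalize:
                xd[i, j] /= total
            if smooth:
                xd[i, j] = smooth_histogram_1d(xd[i, j], spec.sigma)
    return xd


def build_structure_maps(
    structure: ProteinStructure,
    angle_spec: AngleHistogramSpec = AngleHistogramSpec(),
    dist_spec: DistanceHistogramSpec = DistanceHistogramSpec(),
) -> tuple[np.ndarray, np.ndarray]:
    """Convenience: (XA, XD) for one structure with default specs."""
    torsions = compute_torsion_angles(structure)
    xa = build_xa(structure, torsions, angle_spec)
    xd = build_xd(
        pairwise_ca_distances(structure, dist_spec.min_separation), dist_spec
    )
    return xa, xd
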