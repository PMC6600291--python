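"""Seeded, class-structured synthetic datasets: PDB backbones + PSSM files.

Structures are built by sequential internal-coordinate placement from
sampled (phi, psi) torsions with ideal backbone bond geometry, so the
generating torsions can be recovered exactly by dihedral measurement.
PSSM scores are class-conditional integer patterns written in the
PSI-BLAST ASCII dialect.  Class signal is injected through both geometry
(torsion regimes) and sequence (conservation profiles) so each of the
XA/XD/XL maps carries discriminative information.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    AA1_ORDER,
    DatasetManifest,
    ManifestEntry,
    ONE_TO_THREE,
    PSSMProfile,
    ProteinStructure,
    Residue,
    write_manifest,
    write_pdb,
    write_pssm,
)

# ideal backbone geometry (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA = 180.0

#: Nonstandard residue codes occasionally mixed into synthetic sequences.
NONSTANDARD_CODES = ("ASE", "THP", "MSE")

SCORE_MIN, SCORE_MAX = -12, 13


@dataclass(frozen=True)
class TorsionRegime:
    """Mixture of (phi, psi) modes with angular noise, one per class."""

    modes: tuple[tuple[float, float], ...]
    weights: tuple[float, ...] = ()
    noise_sd: float = 6.0

    def __post_init__(self) -> None:
        weights = self.weights or tuple(1.0 / len(self.modes) for _ in self.modes)
        object.__setattr__(self, "weights", weights)
        if len(weights) != len(self.modes):
            raise ValueError("one weight per mode required")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    n_classes: int = 6
    n_per_class: int = 10
    length_range: tuple[int, int] = (30, 60)
    regimes: tuple[TorsionRegime, ...] = ()
    conservation: tuple[np.ndarray, ...] = ()  # one 20x20 mean matrix per class
    pssm_noise_sd: float = 1.0
    nonstandard_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_classes <= 6:
            raise ValueError("n_classes must be in 1..6")
        if self.length_range[0] < 5:
            raise ValueError("minimum length is 5 residues")
        if len(self.regimes) != self.n_classes:
            raise ValueError("one torsion regime per class required")
        if len(self.conservation) != self.n_classes:
            raise ValueError("one conservation profile per class required")
        for m in self.conservation:
            if np.asarray(m).shape != (20, 20):
                raise ValueError("conservation profiles must be 20 x 20")
            if np.min(m) < SCORE_MIN or np.max(m) > SCORE_MAX:
                raise ValueError(
                    f"conservation means must lie in [{SCORE_MIN}, {SCORE_MAX}]"
                )
        if not 0.0 <= self.nonstandard_fraction < 1.0:
            raise ValueError("nonstandard_fraction must be in [0, 1)")


def well_separated_config(
    n_per_class: int = 10,
    n_classes: int = 6,
    seed: int = 0,
    length_range: tuple[int, int] = (30, 60),
    noise_sd: float = 6.0,
    pssm_noise_sd: float = 1.0,
) -> SimulationConfig:
    """Config with disjoint per-class torsion modes and conservation patterns."""
    all_modes = (
        (-57.0, -47.0),    # alpha helix
        (-120.0, 130.0),   # beta strand
        (60.0, 45.0),      # left-handed helix
        (-150.0, -60.0),
        (40.0, -120.0),
        (140.0, 60.0),
    )
    regimes = tuple(
        TorsionRegime(modes=(all_modes[c],), noise_sd=noise_sd)
        for c in range(n_classes)
    )
    conservation = []
    for c in range(n_classes):
        m = np.full((20, 20), -8.0)
        for k in range(20):
            m[k, (k + 3 * c) % 20] = 10.0
            m[k, (k + 3 * c + 1) % 20] = 6.0
        conservation.append(m)
    return SimulationConfig(
        n_classes=n_classes,
        n_per_class=n_per_class,
        length_range=length_range,
        regimes=regimes,
        conservation=tuple(conservation),
        pssm_noise_sd=pssm_noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# backbone construction
# ---------------------------------------------------------------------------

def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Position atom D from A-B-C with given C-D bond, B-C-D angle and
    A-B-C-D torsion (standard internal-coordinate / NeRF placement)."""
    theta = np.radians(angle_deg)
    tau = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(tau), np.sin(theta) * np.sin(tau)]
    )
    return c + bond * (d[0] * bc + d[1] * m + d[2] * n)


def _wrap(angle: float) -> float:
    a = (angle + 180.0) % 360.0 - 180.0
    return float(a)


def sample_torsions(
    length: int, regime: TorsionRegime, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample per-residue (phi, psi) from the regime's mixture."""
    modes = np.asarray(regime.modes, dtype=float)
    idx = rng.choice(len(modes), size=length, p=np.asarray(regime.weights))
    phi = modes[idx, 0] + rng.normal(0.0, regime.noise_sd, size=length)
    psi = modes[idx, 1] + rng.normal(0.0, regime.noise_sd, size=length)
    return (
        np.array([_wrap(v) for v in phi]),
        np.array([_wrap(v) for v in psi]),
    )


def sample_sequence(
    length: int, rng: np.random.Generator, nonstandard_fraction: float = 0.0
) -> list[str]:
    """Random three-letter residue codes, optionally mixing nonstandard ones."""
    codes: list[str] = []
    for _ in range(length):
        if nonstandard_fraction > 0 and rng.random() < nonstandard_fraction:
            codes.append(NONSTANDARD_CODES[rng.integers(len(NONSTANDARD_CODES))])
        else:
            codes.append(ONE_TO_THREE[AA1_ORDER[rng.integers(20)]])
    return codes


def generate_structure(
    length: int,
    regime: TorsionRegime,
    seed: int | np.random.Generator = 0,
    sequence: list[str] | None = None,
    nonstandard_fraction: float = 0.0,
    structure_id: str = "synthetic",
) -> tuple[ProteinStructure, np.ndarray, np.ndarray]:
    """Build a backbone from sampled torsions; return ground truth too.

    Returns ``(structure, phi, psi)`` where ``phi[0]`` and ``psi[-1]`` are
    NaN (undefined at the chain ends).  With ``noise_sd=0`` the dihedrals
    measured on the structure equal the regime's modes exactly.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    phi, psi = sample_torsions(length, regime, rng)
    if sequence is None:
        sequence = sample_sequence(length, rng, nonstandard_fraction)
    if len(sequence) != length:
        raise ValueError("sequence length mismatch")

    n0 = np.zeros(3)
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    a = np.radians(180.0 - ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([np.cos(a), np.sin(a), 0.0])
    ns, cas, cs = [n0], [ca0], [c0]
    for i in range(length - 1):
        n_next = place_atom(ns[i], cas[i], cs[i], BOND_C_N, ANGLE_CA_C_N, psi[i])
        ca_next = place_atom(cas[i], cs[i], n_next, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_next = place_atom(cs[i], n_next, ca_next, BOND_CA_C, ANGLE_N_CA_C, phi[i + 1])
        ns.append(n_next)
        cas.append(ca_next)
        cs.append(c_next)

    residues = [
        Residue(name=sequence[i], n=ns[i], ca=cas[i], c=cs[i]) for i in range(length)
    ]
    phi_out = phi.copy()
    psi_out = psi.copy()
    phi_out[0] = np.nan
    psi_out[-1] = np.nan
    return ProteinStructure(id=structure_id, residues=residues), phi_out, psi_out


# ---------------------------------------------------------------------------
# PSSM generation
# ---------------------------------------------------------------------------

def generate_pssm(
    sequence: str | list[str],
    conservation: np.ndarray,
    seed: int | np.random.Generator = 0,
    noise_sd: float = 1.0,
) -> PSSMProfile:
    """Integer PSSM: class-profile mean + rounded noise, clipped to [-12, 13].

    ``conservation`` is a 20x20 matrix: row k is the mean score vector for
    positions carrying residue type k (:data:`AA1_ORDER` order).  Positions
    with nonstandard codes get the column-averaged profile and sequence
    letter ``X``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    conservation = np.asarray(conservation, dtype=float)
    if conservation.shape != (20, 20):
        raise ValueError("conservation must be 20 x 20")
    if isinstance(sequence, str):
        letters = list(sequence)
    else:
        from .io_formats import THREE_TO_ONE

        letters = [THREE_TO_ONE.get(code, "X") for code in sequence]
    mean_profile = conservation.mean(axis=0)
    rows = []
    for aa in letters:
        mu = conservation[AA1_ORDER.index(aa)] if aa in AA1_ORDER else mean_profile
        noise = rng.normal(0.0, noise_sd, size=20) if noise_sd > 0 else 0.0
        rows.append(np.clip(np.rint(mu + noise), SCORE_MIN, SCORE_MAX))
    return PSSMProfile(sequence="".join(letters), scores=np.vstack(rows))


# ---------------------------------------------------------------------------
# whole datasets
# ---------------------------------------------------------------------------

def generate_dataset(
    config: SimulationConfig, outdir: str | os.PathLike
) -> tuple[DatasetManifest, Path]:
    """Write PDB + PSSM files and a manifest; fully reproducible by seed.

    Returns the manifest and the path of the written ``manifest.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    entries: list[ManifestEntry] = []
    for c in range(config.n_classes):
        for i in range(config.n_per_class):
            pid = f"C{c + 1}_{i:03d}"
            length = int(
                rng.integers(config.length_range[0], config.length_range[1] + 1)
            )
            structure, _, _ = generate_structure(
                length,
                config.regimes[c],
                seed=rng,
                nonstandard_fraction=config.nonstandard_fraction,
                structure_id=pid,
            )
            pssm = generate_pssm(
                [r.name for r in structure.residues],
                config.conservation[c],
                seed=rng,
                noise_sd=config.pssm_noise_sd,
            )
            write_pdb(structure, outdir / f"{pid}.pdb")
            write_pssm(pssm, outdir / f"{pid}.pssm")
            entries.append(ManifestEntry(pid, f"{pid}.pdb", f"{pid}.pssm", c + 1))
    manifest = DatasetManifest(entries)
    manifest_path = outdir / "manifest.tsv"
    write_manifest(manifest, manifest_path)
    return manifest, manifest_path
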