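"""Readers/writers for the on-disk formats used by the pipeline.

Formats handled here:

* PDB structure files (``ATOM`` records, fixed columns; backbone N/CA/C only),
* PSI-BLAST ASCII PSSM profiles (the ``-out_ascii_pssm`` dialect),
* tab-separated dataset manifests (``id<TAB>pdb<TAB>pssm<TAB>ec``),
* an HDF5 feature container with per-protein ``XA``/``XD``/``XL`` tensors.

The residue alphabets that fix the tensor axis order for the whole package
are defined at the top of this module.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical by three-letter code.  This
#: ordering defines axis 0/1 of the XL tensor and the PSSM column order.
STANDARD20: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

#: 23-type extended alphabet used for the XA/XD channel axes: the standard
#: 20 (alphabetical) followed by the two ambiguity codes and a catch-all
#: channel for every other (modified/nonstandard) residue code.
EXTENDED23: tuple[str, ...] = STANDARD20 + ("ASX", "GLX", "OTHER")

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

#: One-letter codes in the canonical column order (identical to the
#: alphabetical-by-three-letter order above, and to the PSI-BLAST header
#: order "A R N D C Q E G H I L K M F P S T W Y V").
AA1_ORDER: str = "".join(THREE_TO_ONE[c] for c in STANDARD20)

FEATURE_SHAPES: dict[str, tuple[int, ...]] = {
    "XA": (19, 19, 23),
    "XD": (23, 23, 8),
    "XL": (20, 20, 25),
}


class FormatError(ValueError):
    """Raised when an on-disk file violates its expected layout."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Residue:
    """One residue's backbone atoms; any coordinate may be ``None``."""

    name: str
    n: np.ndarray | None = None
    ca: np.ndarray | None = None
    c: np.ndarray | None = None

    @property
    def has_ca(self) -> bool:
        return self.ca is not None


@dataclass
class ProteinStructure:
    """Parsed backbone (residues in file order) with an optional EC label."""

    id: str
    residues: list[Residue]
    ec_label: int | None = None

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        """One-letter sequence; nonstandard residues become ``X``."""
        return "".join(THREE_TO_ONE.get(r.name, "X") for r in self.residues)


@dataclass
class PSSMProfile:
    """Sequence plus L x 20 position-specific score matrix.

    Columns follow :data:`AA1_ORDER`.
    """

    sequence: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(f"scores must be L x 20, got {self.scores.shape}")
        if self.scores.shape[0] != len(self.sequence):
            raise ValueError(
                f"sequence length {len(self.sequence)} != score rows "
                f"{self.scores.shape[0]}"
            )
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores contain non-finite entries")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ManifestEntry:
    id: str
    pdb_path: str
    pssm_path: str
    ec_label: int


@dataclass
class DatasetManifest:
    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.id in seen:
                raise FormatError(f"duplicate manifest id {e.id!r}")
            seen.add(e.id)
            if not 1 <= e.ec_label <= 6:
                raise FormatError(
                    f"manifest id {e.id!r}: EC label {e.ec_label} outside 1..6"
                )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.entries]

    @property
    def labels(self) -> np.ndarray:
        return np.array([e.ec_label for e in self.entries], dtype=int)


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

_BACKBONE = {"N": "n", "CA": "ca", "C": "c"}


def read_pdb(
    path: str | os.PathLike,
    model_policy: str = "first",
    chain_policy: str = "all",
) -> ProteinStructure:
    """Read backbone N/CA/C atoms from a PDB file, residues in file order.

    Parameters
    ----------
    path:
        PDB file with at least one ``ATOM`` record.
    model_policy:
        ``"first"`` keeps only the first MODEL encountered; ``"all"``
        concatenates every model in file order.
    chain_policy:
        ``"all"`` concatenates all chains in file order; otherwise the
        single chain identifier to keep.

    Residues lacking their CA atom are retained (coordinate ``None``) and a
    warning is logged.  Nonstandard residue codes are preserved verbatim.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if model_policy not in ("first", "all"):
        raise ValueError(f"unknown model_policy {model_policy!r}")

    residues: list[Residue] = []
    current_key: tuple | None = None
    model = 1
    first_model: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                try:
                    model = int(line[10:14])
                except ValueError:
                    model += 1
                continue
            if rec != "ATOM  ":
                continue
            if first_model is None:
                first_model = model
            if model_policy == "first" and model != first_model:
                continue
            chain = line[21]
            if chain_policy != "all" and chain != chain_policy:
                continue
            name = line[12:16].strip()
            if name not in _BACKBONE:
                continue
            altloc = line[16]
            if altloc not in (" ", "A"):
                continue
            resname = line[17:20].strip()
            try:
                xyz = np.array(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
            except ValueError as exc:
                raise FormatError(
                    f"{path}: unparseable coordinate field at line {lineno}"
                ) from exc
            key = (model, chain, line[22:26], line[26], resname)
            if key != current_key:
                residues.append(Residue(name=resname))
                current_key = key
            res = residues[-1]
            if getattr(res, _BACKBONE[name]) is None:
                setattr(res, _BACKBONE[name], xyz)

    if not residues:
        raise FormatError(f"{path}: no ATOM records")
    for i, res in enumerate(residues):
        if res.ca is None:
            logger.warning("%s: residue %d (%s) has no CA atom", path.name, i, res.name)
    return ProteinStructure(id=path.stem, residues=residues)


def write_pdb(structure: ProteinStructure, path: str | os.PathLike) -> None:
    """Write backbone atoms as fixed-column ``ATOM`` records (one chain A)."""
    lines: list[str] = []
    serial = 1
    for ires, res in enumerate(structure.residues, start=1):
        for atom_name, attr in (("N", "n"), ("CA", "ca"), ("C", "c")):
            xyz = getattr(res, attr)
            if xyz is None:
                continue
            name_field = atom_name.center(3).rjust(4)[:4]
            # PDB convention: 1-2 char names start in column 14
            name_field = f" {atom_name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name_field}{'':1s}{res.name:>3s} A"
                f"{ires:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {atom_name[0]:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

def read_pssm(path: str | os.PathLike) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM; keep only the 20 log-odds columns.

    The residue column supplies the sequence.  Columns are reordered to the
    canonical :data:`AA1_ORDER` using the file's own header letters.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = path.read_text().splitlines()

    header_cols: list[str] | None = None
    header_idx = -1
    for i, line in enumerate(lines):
        toks = line.split()
        if len(toks) >= 20 and all(len(t) == 1 and t.isalpha() for t in toks[:20]):
            header_cols = toks[:20]
            header_idx = i
            break
    if header_cols is None:
        raise FormatError(f"{path}: no PSSM column header found (truncated file?)")
    if sorted(header_cols) != sorted(AA1_ORDER):
        raise FormatError(f"{path}: header columns are not the 20 amino acids")

    seq: list[str] = []
    rows: list[list[float]] = []
    prev_pos = 0
    for lineno, line in enumerate(lines[header_idx + 1:], start=header_idx + 2):
        toks = line.split()
        if not toks:
            if rows:
                break
            continue
        if not toks[0].lstrip("-").isdigit():
            break
        try:
            pos = int(toks[0])
        except ValueError as exc:
            raise FormatError(f"{path}: bad position index at line {lineno}") from exc
        if pos != prev_pos + 1:
            raise FormatError(
                f"{path}: non-monotone position index {pos} at line {lineno}"
            )
        prev_pos = pos
        if len(toks) < 22:
            raise FormatError(
                f"{path}: row with fewer than 20 score fields at line {lineno}"
            )
        try:
            scores = [float(t) for t in toks[2:22]]
        except ValueError as exc:
            raise FormatError(
                f"{path}: unparseable score field at line {lineno}"
            ) from exc
        seq.append(toks[1])
        rows.append(scores)

    if not rows:
        raise FormatError(f"{path}: no PSSM rows found (truncated file?)")

    raw = np.asarray(rows, dtype=float)
    perm = [header_cols.index(a) for a in AA1_ORDER]
    return PSSMProfile(sequence="".join(seq), scores=raw[:, perm])


def write_pssm(profile: PSSMProfile, path: str | os.PathLike) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect read by :func:`read_pssm`."""
    out = [
        "",
        "Last position-specific scoring matrix computed, weighted observed"
        " percentages rounded down, information per position, and relative"
        " weight of gapless real matches to pseudocounts",
        "            " + "  ".join(AA1_ORDER) + "   " + "  ".join(AA1_ORDER),
    ]
    for i, (aa, row) in enumerate(zip(profile.sequence, profile.scores), start=1):
        cells = " ".join(f"{int(round(v)):3d}" for v in row)
        pct = " ".join(f"{0:3d}" for _ in row)
        out.append(f"{i:5d} {aa} {cells}  {pct}  0.00 0.00")
    out.append("")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def read_manifest(path: str | os.PathLike, check_files: bool = False) -> DatasetManifest:
    """Read a 4-column TSV manifest (``id pdb pssm ec``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    entries: list[ManifestEntry] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 4:
            raise FormatError(f"{path}: expected 4 tab-separated fields at line {lineno}")
        pid, pdb, pssm, ec = fields
        try:
            ec_label = int(ec)
        except ValueError as exc:
            raise FormatError(f"{path}: bad EC label at line {lineno}") from exc
        entries.append(ManifestEntry(pid, pdb, pssm, ec_label))
    manifest = DatasetManifest(entries)
    if check_files:
        base = path.parent
        for e in manifest.entries:
            for p in (e.pdb_path, e.pssm_path):
                full = Path(p) if os.path.isabs(p) else base / p
                if not full.exists():
                    raise FormatError(f"{path}: missing file {p} for id {e.id}")
    return manifest


def write_manifest(manifest: DatasetManifest, path: str | os.PathLike) -> None:
    lines = [f"{e.id}\t{e.pdb_path}\t{e.pssm_path}\t{e.ec_label}" for e in manifest.entries]
    Path(path).write_text("\n".join(lines) + "\n")


def resolve_manifest_paths(
    manifest: DatasetManifest, manifest_path: str | os.PathLike
) -> list[tuple[str, Path, Path, int]]:
    """Resolve relative manifest paths against the manifest's directory."""
    base = Path(manifest_path).parent
    out = []
    for e in manifest.entries:
        pdb = Path(e.pdb_path) if os.path.isabs(e.pdb_path) else base / e.pdb_path
        pssm = Path(e.pssm_path) if os.path.isabs(e.pssm_path) else base / e.pssm_path
        out.append((e.id, pdb, pssm, e.ec_label))
    return out


# ---------------------------------------------------------------------------
# HDF5 feature container
# ---------------------------------------------------------------------------

def save_features(
    features: Mapping[str, Mapping[str, object]], path: str | os.PathLike
) -> None:
    """Save per-protein feature tensors to an HDF5 container.

    ``features`` maps protein id to a dict with keys ``XA``, ``XD``, ``XL``
    (float tensors) and ``label`` (int, optional).
    """
    with h5py.File(path, "w") as fh:
        for pid, maps in features.items():
            grp = fh.create_group(pid)
            for key in ("XA", "XD", "XL"):
                if key in maps:
                    grp.create_dataset(key, data=np.asarray(maps[key], dtype=np.float64))
            if maps.get("label") is not None:
                grp.attrs["label"] = int(maps["label"])  # type: ignore[arg-type]


def load_features(path: str | os.PathLike) -> dict[str, dict[str, object]]:
    """Load a feature container written by :func:`save_features`.

    Raises :class:`FormatError` if a stored tensor does not have its
    documented fixed shape.
    """
    if not Path(path).exists():
        raise FileNotFoundError(path)
    out: dict[str, dict[str, object]] = {}
    with h5py.File(path, "r") as fh:
        for pid in fh:
            grp = fh[pid]
            maps: dict[str, object] = {}
            for key in ("XA", "XD", "XL"):
                if key in grp:
                    arr = np.asarray(grp[key])
                    if arr.shape != FEATURE_SHAPES[key]:
                        raise FormatError(
                            f"{path}: {pid}/{key} has shape {arr.shape}, "
                            f"expected {FEATURE_SHAPES[key]}"
                        )
                    maps[key] = arr
            maps["label"] = int(grp.attrs["label"]) if "label" in grp.attrs else None
            out[pid] = maps
    return out
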