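"""Glue: manifest -> feature maps -> stacked training arrays."""

from __future__ import annotations

import os
from pathlib import Path
from typing import Mapping

import numpy as np

from .io_formats import DatasetManifest, read_manifest, read_pdb, read_pssm, resolve_manifest_paths
from .pssm_features import MutationHistogramSpec, build_xl
from .structure_features import (
    AngleHistogramSpec,
    DistanceHistogramSpec,
    build_structure_maps,
)


def features_from_manifest(
    manifest: DatasetManifest,
    manifest_path: str | os.PathLike,
    angle_spec: AngleHistogramSpec = AngleHistogramSpec(),
    dist_spec: DistanceHistogramSpec = DistanceHistogramSpec(),
    mut_spec: MutationHistogramSpec = MutationHistogramSpec(),
) -> dict[str, dict[str, object]]:
    """Compute XA/XD/XL + label for every manifest entry."""
    out: dict[str, dict[str, object]] = {}
    for pid, pdb_path, pssm_path, label in resolve_manifest_paths(manifest, manifest_path):
        structure = read_pdb(pdb_path)
        pssm = read_pssm(pssm_path)
        xa, xd = build_structure_maps(structure, angle_spec, dist_spec)
        xl = build_xl(pssm, mut_spec)
        out[pid] = {"XA": xa, "XD": xd, "XL": xl, "label": label}
    return out


def stack_features(
    features: Mapping[str, Mapping[str, object]], ids: list[str] | None = None
) -> tuple[dict[str, np.ndarray], np.ndarray, list[str]]:
    """Stack per-protein maps into (maps, labels, ids) training arrays."""
    if ids is None:
        ids = list(features.keys())
    maps = {
        key: np.stack([np.asarray(features[i][key]) for i in ids])
        for key in ("XA", "XD", "XL")
    }
    labels = np.array([features[i]["label"] for i in ids], dtype=int)
    return maps, labels, ids
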