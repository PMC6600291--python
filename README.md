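# ecfuse

Enzyme EC-class (1–6) prediction from three fixed-shape histogram feature
maps, parallel small CNNs, late fusion and a correlation-distance KNN.

Each protein is summarized by three tensors whose shapes do not depend on
sequence length:

| Map | Shape | Content |
|-----|-------|---------|
| `XL` | 20×20×25 | per residue-type histograms of PSSM mutation scores over [−12, 13] (25 unit bins), Gaussian-smoothed (σ=0.5) |
| `XA` | 19×19×23 | per residue-type 2D histograms of backbone (φ, ψ) torsion angles over [−180, 180]² |
| `XD` | 23×23×8 | per residue-type-pair histograms of Cα–Cα distances over [5, 40] Å |

Each map (Architecture 1) or each channel of each map (Architecture 2,
23+8+25 = 56 streams) is fed to a small CNN
(conv5→BN→ReLU→pool2→conv5→BN→ReLU→conv2→BN→ReLU→dropout→FC→softmax).
The per-stream class probabilities are concatenated into a fused vector
(length 18 for Architecture 1, 336 for Architecture 2 at 6 classes) and
classified by KNN (k=12) under the correlation distance (1 − Pearson r).

The CNN is implemented in pure NumPy (seeded, single-threaded,
bit-reproducible); no deep-learning framework is required.

## CLI

```sh
# seeded synthetic dataset: PDB backbones + PSI-BLAST-dialect PSSMs + manifest
ecfuse simulate --classes 6 --n-per-class 10 --seed 1 --out data/

# feature extraction into an HDF5 container
ecfuse extract --manifest data/manifest.tsv --out features.h5

# 80/20 split, parallel CNNs + fusion + KNN; --profile paper uses the
# full-size hyperparameters (filters 20/50/500, lr 0.001, epochs 300/150),
# --profile scaled the desk-scale profile (filters 8/16/64, 20 epochs)
ecfuse train --features features.h5 --arch 1 --seed 0 --profile scaled \
    --model-out model.npz --history-out history.csv

# JSON report: accuracy, row-percent confusion matrix, per-class ROC AUC
ecfuse evaluate --model model.npz --features features.h5 --report report.json
```

## Library

```python
from ecfuse import (read_pdb, read_pssm, build_xl, build_xa, build_xd,
                    compute_torsion_angles, FusionPipeline)
```

Key modules: `io_formats` (PDB / ASCII-PSSM / manifest / HDF5 container),
`pssm_features` (XL), `structure_features` (XA, XD), `network` (NumPy CNN),
`fusion_classify` (fusion + KNN + pipeline), `evaluation` (split, confusion
matrix, ROC/AUC), `synthetic_data` (seeded class-structured datasets built
from torsion-angle internal coordinates).

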