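"""File formats: point-annotation CSVs, map TIFFs, datasets, checkpoints.

Point annotations travel as CSV with header ``image,row,col`` (0-based pixel
coordinates, one row per point).  Location/count maps persist as single-channel
TIFF.  A simulated dataset directory holds PNG images, ``full.csv`` (all
centers), ``labeled.csv`` (the sparse subset shown to the learner) and a JSON
manifest with the generation seeds.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import AnnotatedImage
from .train import Checkpoint, TrainConfig

__all__ = [
    "read_annotations",
    "write_annotations",
    "save_map",
    "load_map",
    "write_dataset",
    "read_dataset",
    "save_checkpoint",
    "load_checkpoint",
]


def read_annotations(path) -> dict[str, np.ndarray]:
    """CSV ``image,row,col`` → {image id: (n, 2) array of (row, col)}."""
    df = pd.read_csv(path)
    required = {"image", "row", "col"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation CSV needs columns {sorted(required)}, got {list(df.columns)}")
    return {
        str(img): g[["row", "col"]].to_numpy(dtype=float)
        for img, g in df.groupby("image", sort=True)
    }


def write_annotations(path, annotations: dict[str, np.ndarray]) -> None:
    rows = [
        {"image": img, "row": r, "col": c}
        for img, pts in annotations.items()
        for r, c in np.asarray(pts, dtype=float).reshape(-1, 2)
    ]
    pd.DataFrame(rows, columns=["image", "row", "col"]).to_csv(path, index=False)


def save_map(path, values: np.ndarray) -> None:
    """Persist a location/count map as a single-channel float32 TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(values, dtype=np.float32))


def load_map(path) -> np.ndarray:
    import tifffile

    return np.asarray(tifffile.imread(path), dtype=float)


def write_dataset(outdir, images: list[AnnotatedImage], prefix: str = "img") -> None:
    """Write scenes as 16-bit PNGs plus full/labeled annotation CSVs and a manifest."""
    import imageio.v3 as iio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    full: dict[str, np.ndarray] = {}
    labeled: dict[str, np.ndarray] = {}
    manifest = []
    for i, im in enumerate(images):
        name = f"{prefix}_{i:04d}"
        iio.imwrite(
            out / f"{name}.png",
            (np.clip(im.image, 0, 1) * 65535).astype(np.uint16),
        )
        full[name] = im.centers
        labeled[name] = im.labeled
        manifest.append({"image": name, "seed": im.seed, "n_objects": im.n_objects,
                         "n_labeled": len(im.labeled)})
    write_annotations(out / "full.csv", full)
    write_annotations(out / "labeled.csv", labeled)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_dataset(path) -> list[AnnotatedImage]:
    """Load a dataset directory written by :func:`write_dataset`."""
    import imageio.v3 as iio

    root = Path(path)
    manifest = json.loads((root / "manifest.json").read_text())
    full = read_annotations(root / "full.csv")
    labeled = read_annotations(root / "labeled.csv")
    images = []
    for entry in manifest:
        name = entry["image"]
        arr = np.asarray(iio.imread(root / f"{name}.png"), dtype=float)
        arr /= 65535.0 if arr.max() > 1.5 else 1.0
        images.append(
            AnnotatedImage(
                image=arr,
                centers=full.get(name, np.empty((0, 2))),
                labeled=labeled.get(name, np.empty((0, 2))),
                seed=int(entry.get("seed", 0)),
            )
        )
    return images


def save_checkpoint(path, ckpt: Checkpoint) -> None:
    """Weights to ``<path>.npz``; stage/epoch/score metadata to ``<path>.json``."""
    base = Path(path)
    np.savez(base.with_suffix(".npz"), **ckpt.state)
    meta = {
        "stage": ckpt.stage,
        "epoch": ckpt.epoch,
        "val_f1": ckpt.val_f1,
        "kernel_size": ckpt.config.kernel.kernel_size,
        "class_prior": ckpt.config.class_prior,
        "seed": ckpt.config.seed,
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    ckpt.history.to_csv(base.with_suffix(".history.csv"), index=False)


def load_checkpoint(path, config: TrainConfig) -> Checkpoint:
    base = Path(path)
    with np.load(base.with_suffix(".npz")) as data:
        state = {k: data[k] for k in data.files}
    meta = json.loads(base.with_suffix(".json").read_text())
    hist_path = base.with_suffix(".history.csv")
    history = pd.read_csv(hist_path) if hist_path.exists() else pd.DataFrame()
    return Checkpoint(
        stage=meta["stage"], state=state, epoch=meta["epoch"],
        val_f1=meta["val_f1"], config=config, history=history,
    )
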