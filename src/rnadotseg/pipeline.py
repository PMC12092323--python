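"""Dataset and run plumbing: image/CSV I/O, run configs, tiled prediction.

Images are stored on disk as ordinary RGB PNG/TIFF and converted to the
package's internal BGR layout on read; dot annotations are CSV files with an
``x,y,type`` header in 0-based integer pixels; probability maps are 8-bit
greyscale PNGs so the 0-255 grey-threshold convention applies directly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import synthgen, trainer
from .netarch import DotSegNet, NetworkConfig
from .trainer import LossConfig, OptimizerConfig, PhaseSpec
from .dotcall import DotCallConfig
from .evalmatch import MatchConfig

__all__ = [
    "PatchRecord", "RunConfig", "save_image", "load_image", "save_map",
    "load_map", "write_coords_csv", "read_coords_csv", "generate_dataset",
    "load_dataset", "predict_patch",
]


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def save_image(path, image_bgr: np.ndarray) -> None:
    """Write an internal BGR uint8 image as a conventional RGB file."""
    iio.imwrite(path, np.ascontiguousarray(image_bgr[:, :, ::-1]))


def load_image(path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    return np.ascontiguousarray(img[:, :, :3][:, :, ::-1])


def save_map(path, prob_map: np.ndarray) -> None:
    """Probability map in [0, 1] (or 8-bit) -> 8-bit greyscale PNG."""
    m = np.asarray(prob_map)
    if np.issubdtype(m.dtype, np.floating):
        m = np.clip(np.rint(m * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(path, m.astype(np.uint8))


def load_map(path) -> np.ndarray:
    m = iio.imread(path)
    if m.ndim == 3:
        m = m[:, :, 0]
    return m


def write_coords_csv(path, dots) -> None:
    rows = [{"x": int(d[0]), "y": int(d[1]),
             "type": d[2] if len(d) > 2 else "primary"} for d in dots]
    pd.DataFrame(rows, columns=["x", "y", "type"]).to_csv(path, index=False)


def read_coords_csv(path) -> list[tuple[int, int, str]]:
    df = pd.read_csv(path)
    if df.empty:
        return []
    types = df["type"] if "type" in df else ["primary"] * len(df)
    return [(int(x), int(y), str(t)) for x, y, t in zip(df["x"], df["y"], types)]


# ---------------------------------------------------------------------------
# records and run configuration
# ---------------------------------------------------------------------------

@dataclass
class PatchRecord:
    image_path: str
    coords_path: str
    split: str = "train"            # train | val
    patient_id: str = ""


@dataclass
class RunConfig:
    seed: int = 0
    network: NetworkConfig = field(default_factory=NetworkConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    schedule: list[PhaseSpec] = field(default_factory=trainer.default_schedule)
    dotcall: DotCallConfig = field(default_factory=DotCallConfig)
    match: MatchConfig = field(default_factory=MatchConfig)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        return cls(
            seed=d.get("seed", 0),
            network=NetworkConfig(**d.get("network", {})),
            loss=LossConfig(**d.get("loss", {})),
            optimizer=OptimizerConfig(**d.get("optimizer", {})),
            schedule=[PhaseSpec(**row) for row in d.get("schedule", [])]
            or trainer.default_schedule(),
            dotcall=DotCallConfig(**d.get("dotcall", {})),
            match=MatchConfig(**d.get("match", {})),
        )


# ---------------------------------------------------------------------------
# dataset generation / loading
# ---------------------------------------------------------------------------

def generate_dataset(out_dir, count: int, shape: tuple[int, int] = (480, 480),
                     seed: int = 0) -> Path:
    """Write `count` synthetic patches (PNG + CSV) plus a manifest listing the
    per-patch seeds; the same call regenerates byte-identical files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(count):
        patch_seed = seed * 100_000 + i
        patch = synthgen.generate_patch(shape=shape, seed=patch_seed)
        img_name, csv_name = f"patch_{i:04d}.png", f"patch_{i:04d}.csv"
        save_image(out / img_name, patch.image)
        write_coords_csv(out / csv_name, patch.dots)
        rows.append({"image": img_name, "coords": csv_name, "split": "train",
                     "patient_id": f"synthetic_{i:04d}", "seed": patch_seed})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows, columns=["image", "coords", "split", "patient_id",
                                "seed"]).to_csv(manifest, index=False)
    return manifest


def load_dataset(manifest_path) -> list[tuple[np.ndarray, list, PatchRecord]]:
    """Load (image, dots, record) triples; enforces patient-disjoint splits."""
    manifest = Path(manifest_path)
    df = pd.read_csv(manifest)
    if not df.empty:
        by_split = df.groupby("split")["patient_id"].apply(set)
        if len(by_split) > 1:
            overlap = set.intersection(*by_split.tolist())
            if overlap:
                raise ValueError(f"patients present in multiple splits: {sorted(overlap)}")
    out = []
    for _, row in df.iterrows():
        rec = PatchRecord(image_path=str(manifest.parent / row["image"]),
                          coords_path=str(manifest.parent / row["coords"]),
                          split=row.get("split", "train"),
                          patient_id=str(row.get("patient_id", "")))
        out.append((load_image(rec.image_path), read_coords_csv(rec.coords_path), rec))
    return out


# ---------------------------------------------------------------------------
# tiled prediction
# ---------------------------------------------------------------------------

def predict_patch(model: DotSegNet, image: np.ndarray, tile: int | None = None,
                  stride: int = 128) -> np.ndarray:
    """Predict a probability map for an arbitrarily sized patch by tiling it
    into network-sized windows and stitching by per-pixel maximum."""
    tile = tile or model.config.input_size
    H, W = image.shape[:2]
    if H == tile and W == tile:
        return trainer.predict_map(model, image)
    tiles = trainer.subdivide_patch(image, [], "eval", tile=tile, stride=stride)
    out = np.zeros((H, W))
    for t in tiles:
        pm = trainer.predict_map(model, t.image)
        x0, y0 = t.origin
        region = out[y0:y0 + tile, x0:x0 + tile]
        np.maximum(region, pm, out=region)
    return out
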