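"""Image/mask I/O, manifests and flat key-value configuration files."""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .network import NetworkConfig
from .training import MMLMConfig

__all__ = [
    "read_image",
    "read_mask",
    "write_mask",
    "write_image",
    "load_manifest",
    "save_manifest",
    "load_configs",
    "save_configs",
]


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG image as an (H, W, 3) uint8 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def read_mask(path) -> np.ndarray:
    """Read a single-channel mask PNG as uint8 {0, 1}.

    Any value above half the dtype range maps to 1 (so both 8-bit
    {0, 255} and 16-bit {0, 65535} masks load correctly).  RGB masks are
    rejected; palette/binary modes are converted to greyscale first.
    """
    with Image.open(path) as im:
        if im.mode in ("RGB", "RGBA"):
            raise ValueError(f"{path}: masks must be single-channel, got mode {im.mode}")
        if im.mode not in ("L", "I", "I;16", "1"):
            im = im.convert("L")
        arr = np.asarray(im)
    if arr.dtype == bool:
        return arr.astype(np.uint8)
    half = np.iinfo(arr.dtype).max / 2.0 if np.issubdtype(arr.dtype, np.integer) else 0.5
    uniques = np.unique(arr)
    if len(uniques) > 2:
        warnings.warn(f"{path}: mask has {len(uniques)} distinct values; thresholding at {half:g}")
    return (arr > half).astype(np.uint8)


def write_mask(path, mask: np.ndarray) -> None:
    """Write a {0, 1} mask as an 8-bit {0, 255} PNG."""
    arr = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Image.fromarray(arr, mode="L").save(path)


def write_image(path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def load_manifest(path) -> pd.DataFrame:
    """Load a dataset manifest CSV and check that referenced files exist."""
    df = pd.read_csv(path)
    required = {"image", "od_mask", "oc_mask"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")
    base = Path(path).parent
    for col in ("image", "od_mask", "oc_mask"):
        for p in df[col]:
            if not (base / p).exists() and not Path(p).exists():
                raise FileNotFoundError(f"manifest references missing file: {p}")
    return df


def save_manifest(path, rows) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)


def load_configs(path):
    """Load (NetworkConfig, MMLMConfig) from a flat key-value YAML file.

    Keys matching NetworkConfig fields configure the architecture; keys
    matching MMLMConfig fields configure training; unknown keys error.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    net_fields = {f.name for f in dataclasses.fields(NetworkConfig)}
    train_fields = {f.name for f in dataclasses.fields(MMLMConfig)}
    net_kwargs, train_kwargs = {}, {}
    for key, value in raw.items():
        if key == "seed":  # one run seed drives both configs
            net_kwargs[key] = value
            train_kwargs[key] = value
        elif key in net_fields:
            net_kwargs[key] = value
        elif key in train_fields:
            train_kwargs[key] = value
        else:
            raise ValueError(f"unknown config key: {key}")
    if "input_side" not in net_kwargs:
        raise ValueError("config must set input_side")
    return NetworkConfig(**net_kwargs), MMLMConfig(**train_kwargs)


def save_configs(path, net_cfg: NetworkConfig, train_cfg: MMLMConfig) -> None:
    data = {**dataclasses.asdict(net_cfg), **dataclasses.asdict(train_cfg)}
    # 'seed' exists in both; the training seed wins on load via explicit key
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
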