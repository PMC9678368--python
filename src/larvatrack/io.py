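"""Frame/table readers and writers, YAML configuration, run manifests."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
import yaml
from imageio.v3 import imread


class FrameFormatError(ValueError):
    pass


def read_frames(path, strict: bool = True) -> np.ndarray:
    """Read a multi-page TIFF or a directory of numbered PNGs.

    Returns a (T, H, W) uint8 stack.  Mixed shapes raise; 16-bit input is
    rescaled with a warning in lax mode and rejected in strict mode.
    """
    p = Path(path)
    if p.is_dir():
        files = sorted(p.glob("*.png"))
        if not files:
            raise FrameFormatError(f"no PNG frames in {p}")
        frames = [imread(f) for f in files]
    else:
        frames = list(tifffile.imread(p))
        if np.ndim(frames[0]) == 0:  # single page
            frames = [np.asarray(tifffile.imread(p))]
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise FrameFormatError(f"mixed frame shapes: {shapes}")
    stack = np.stack(frames)
    if stack.dtype != np.uint8:
        if strict:
            raise FrameFormatError(f"expected 8-bit frames, got {stack.dtype}")
        import warnings
        warnings.warn(f"rescaling {stack.dtype} frames to 8 bit")
        stack = (stack.astype(float) / stack.max() * 255).astype(np.uint8)
    return stack


def write_frames(path, frames: np.ndarray) -> None:
    """Write a uint8 frame stack as a multi-page TIFF."""
    tifffile.imwrite(path, np.asarray(frames, dtype=np.uint8))


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    seed: int
    config: dict = field(default_factory=dict)
    input_paths: list[str] = field(default_factory=list)
    output_paths: list[str] = field(default_factory=list)
    version: str = ""
    timestamp: float = field(default_factory=time.time)

    @property
    def config_digest(self) -> str:
        return config_hash(self.config)

    def save(self, path) -> None:
        d = asdict(self)
        d["config_digest"] = self.config_digest
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, default=str)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        d.pop("config_digest", None)
        return cls(**d)
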