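"""From plate images or well readings to dRGB feature vectors.

The measurement object is an ``m x 4 x 3`` RGB matrix: per sample, the
mean well color of each of the four sensor channels.  Features are signed
response-minus-control differences (dRGB), flattened channel-major to
S1_R, S1_G, S1_B, ..., S4_B; that order is fixed and written into every
CSV header.  Differences are used unamplified for analysis — the 0-255
rescaling exists only for the color-difference display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .datasets import CHANNEL_NAMES, FEATURE_COLUMNS, N_CHANNELS, N_FEATURES


@dataclass
class RGBMatrix:
    """m x 4 x 3 array of mean well colors (samples x channels x R,G,B)."""

    values: np.ndarray
    channel_names: Sequence[str] = CHANNEL_NAMES

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1:] != (N_CHANNELS, 3):
            raise ValueError(f"values must be m x {N_CHANNELS} x 3, got {self.values.shape}")
        if self.values.min() < 0 or self.values.max() > 255:
            raise ValueError("RGB entries must lie within [0, 255]")
        if len(self.channel_names) != N_CHANNELS:
            raise ValueError(f"exactly {N_CHANNELS} channel names required")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass
class DeltaRGBFeatures:
    """m x 12 signed color differences (response minus control)."""

    values: np.ndarray
    column_names: Sequence[str] = FEATURE_COLUMNS

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_FEATURES:
            raise ValueError(f"values must be m x {N_FEATURES}")
        if np.abs(self.values).max() > 255:
            raise ValueError("dRGB entries must lie within [-255, 255]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.column_names))


@dataclass
class Well:
    """One well of the plate layout."""

    name: str  # e.g. "A1"
    role: str  # response | control | blank
    sample: str | None = None  # sample id (response wells)
    channel: str | None = None  # sensor channel S1..S4
    center: tuple[float, float] | None = None  # (x, y) pixel coordinates


@dataclass
class PlateLayout:
    """Well coordinates and roles; ROI disks default to 25 px diameter."""

    wells: list[Well] = field(default_factory=list)
    roi_diameter: float = 25.0

    @classmethod
    def from_yaml(cls, path) -> "PlateLayout":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        wells = [
            Well(
                name=w["name"],
                role=w["role"],
                sample=w.get("sample"),
                channel=w.get("channel"),
                center=tuple(w["center"]) if "center" in w else None,
            )
            for w in raw["wells"]
        ]
        return cls(wells=wells, roi_diameter=float(raw.get("roi_diameter", 25.0)))

    def to_yaml(self, path) -> None:
        raw = {
            "roi_diameter": self.roi_diameter,
            "wells": [
                {
                    k: v
                    for k, v in {
                        "name": w.name,
                        "role": w.role,
                        "sample": w.sample,
                        "channel": w.channel,
                        "center": list(w.center) if w.center else None,
                    }.items()
                    if v is not None
                }
                for w in self.wells
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as an H x W x 3 float array."""
    return np.asarray(Image.open(path).convert("RGB"), dtype=float)


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], diameter: float) -> np.ndarray:
    # pixels whose centers lie within Euclidean distance d/2 (inclusive)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = center
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= (diameter / 2.0) ** 2


def extract_well_rgb(image: np.ndarray, layout: PlateLayout, role: str = "response") -> RGBMatrix:
    """Mean RGB of the circular ROI at each well center, grouped per sample.

    Wells with the requested role are grouped by sample id and ordered by
    channel (S1..S4); each well's value is the unrounded arithmetic mean of
    the pixels inside the inclusive disk of ``layout.roi_diameter``.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must have exactly 3 color planes (RGB)")
    h, w = image.shape[:2]
    r = layout.roi_diameter / 2.0

    wells = [wl for wl in layout.wells if wl.role == role]
    if not wells:
        raise ValueError(f"layout contains no wells with role {role!r}")
    sample_ids = list(dict.fromkeys(wl.sample for wl in wells))
    by_key = {(wl.sample, wl.channel): wl for wl in wells}

    out = np.zeros((len(sample_ids), N_CHANNELS, 3))
    for i, sid in enumerate(sample_ids):
        for j, ch in enumerate(CHANNEL_NAMES):
            wl = by_key.get((sid, ch))
            if wl is None:
                raise ValueError(f"sample {sid!r} is missing channel {ch}")
            if wl.center is None:
                raise ValueError(f"well {wl.name!r} has no pixel center")
            cx, cy = wl.center
            if cx - r < -0.5 or cy - r < -0.5 or cx + r > w - 0.5 or cy + r > h - 0.5:
                raise ValueError(f"ROI of well {wl.name!r} extends outside the image")
            mask = _disk_mask((h, w), (cx, cy), layout.roi_diameter)
            out[i, j] = image[mask].mean(axis=0)
    return RGBMatrix(out)


def delta_rgb(response: RGBMatrix, control: RGBMatrix) -> DeltaRGBFeatures:
    """Signed response-minus-control differences, flattened to m x 12.

    The control is either row-matched (same m) or a single row broadcast
    to all samples (one control condition per plate).  No scaling is
    applied — the raw differences feed the models.
    """
    if list(response.channel_names) != list(control.channel_names):
        raise ValueError("response and control channel names differ")
    ctrl = control.values
    if ctrl.shape[0] == 1:
        ctrl = np.broadcast_to(ctrl, response.values.shape)
    elif ctrl.shape != response.values.shape:
        raise ValueError(
            f"control shape {control.values.shape} matches neither response "
            f"shape {response.values.shape} nor a single broadcastable row"
        )
    diff = response.values - ctrl
    return DeltaRGBFeatures(diff.reshape(response.n_samples, N_FEATURES))


def render_color_difference(features: DeltaRGBFeatures) -> np.ndarray:
    """Color-difference diagram: |dRGB| rescaled per column to 0-255.

    Visualization only; never feeds back into analysis.  A constant column
    (no dynamic range) renders as 0.  Returns an m x 4 x 3 uint8 array of
    display colors.
    """
    mag = np.abs(features.values.copy())
    lo, hi = mag.min(axis=0), mag.max(axis=0)
    span = hi - lo
    scaled = np.zeros_like(mag)
    nz = span > 0
    scaled[:, nz] = (mag[:, nz] - lo[nz]) / span[nz] * 255.0
    return scaled.reshape(-1, N_CHANNELS, 3).round().astype(np.uint8)


def aggregate_replicates(
    features: DeltaRGBFeatures, group_ids: Sequence
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group mean and sample standard deviation (n-1) of each feature.

    Groups of size 1 report a missing (NaN) standard deviation, not zero.
    """
    df = features.to_frame()
    if len(group_ids) != len(df):
        raise ValueError("every row needs a group id")
    grouped = df.groupby(pd.Series(list(group_ids), name="group"), sort=False)
    return grouped.mean(), grouped.std(ddof=1)
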