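"""Colony autolysis quantification from plate scans.

Plate images are converted from RGB to 8-bit gray (ITU-R 601 luma), pixels
are banded into lysed area and intact mycelium by gray level, and autolysis
is expressed as a percentage of either the colony area (lysis + mycelium,
the default) or the whole plate. The reference gray bands (lysis 1-112,
mycelium 107-255) overlap at 107-112; the default policy gives the overlap
to lysis so that the two masks partition gray levels 1-255. Gray 0 is
unassigned background.

A synthetic plate generator provides ground-truthed fixtures: a circular
colony with an inner lysed disc of a requested area fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

LYSIS_BAND = (1, 112)
MYCELIUM_BAND = (107, 255)


@dataclass(frozen=True)
class PlateMeasurement:
    """Pixel areas and percent autolysis of one plate image."""

    image_id: str
    lysis_pixels: int
    mycelium_pixels: int
    total_pixels: int
    percent_autolysis: float


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """8-bit luma (ITU-R 601: 0.299 R + 0.587 G + 0.114 B), rounded half-up."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected a 3-channel RGB image")
    luma = (0.299 * rgb[..., 0].astype(float)
            + 0.587 * rgb[..., 1].astype(float)
            + 0.114 * rgb[..., 2].astype(float))
    return np.floor(luma + 0.5).astype(np.uint8)


def segment(gray: np.ndarray,
            lysis_band: tuple[int, int] = LYSIS_BAND,
            mycelium_band: tuple[int, int] = MYCELIUM_BAND,
            overlap: str = "lysis") -> tuple[np.ndarray, np.ndarray]:
    """Band the gray image into (lysis mask, mycelium mask).

    Overlapping gray levels between the two bands go to the side named by
    ``overlap`` ('lysis' or 'mycelium'), keeping the masks disjoint. With the
    default bands and policy the effective split is lysis 1-112,
    mycelium 113-255.
    """
    for lo, hi in (lysis_band, mycelium_band):
        if not (0 <= lo <= hi <= 255):
            raise ValueError("bands must lie within 0-255")
    if overlap not in {"lysis", "mycelium"}:
        raise ValueError("overlap policy must be 'lysis' or 'mycelium'")
    l_lo, l_hi = lysis_band
    m_lo, m_hi = mycelium_band
    if overlap == "lysis":
        m_lo = max(m_lo, l_hi + 1)
    else:
        l_hi = min(l_hi, m_lo - 1)
    gray = np.asarray(gray)
    lysis = (gray >= l_lo) & (gray <= l_hi)
    mycelium = (gray >= m_lo) & (gray <= m_hi)
    return lysis, mycelium


def percent_autolysis(lysis_mask: np.ndarray, mycelium_mask: np.ndarray,
                      denominator: str = "colony") -> float:
    """100 * lysed pixels / denominator.

    ``colony`` divides by lysis + mycelium area (the default, matching the
    lysed-fraction-of-mycelium readout); ``plate`` divides by the full image.
    """
    if lysis_mask.shape != mycelium_mask.shape:
        raise ValueError("masks must have the same shape")
    lysis = int(lysis_mask.sum())
    mycelium = int(mycelium_mask.sum())
    if denominator == "colony":
        denom = lysis + mycelium
    elif denominator == "plate":
        denom = lysis_mask.size
    else:
        raise ValueError("denominator must be 'colony' or 'plate'")
    if denom == 0:
        raise ValueError("zero denominator: no assigned pixels")
    return 100.0 * lysis / denom


def measure_plate(image: np.ndarray | str | Path, image_id: str = "",
                  denominator: str = "colony", **segment_kwargs
                  ) -> PlateMeasurement:
    """Full measurement of one plate image (array, or PNG/TIFF path)."""
    if isinstance(image, (str, Path)):
        image_id = image_id or Path(image).stem
        image = np.asarray(Image.open(image).convert("RGB"))
    gray = to_grayscale(image) if image.ndim == 3 else np.asarray(image)
    lysis, myc = segment(gray, **segment_kwargs)
    return PlateMeasurement(
        image_id=image_id,
        lysis_pixels=int(lysis.sum()),
        mycelium_pixels=int(myc.sum()),
        total_pixels=gray.size,
        percent_autolysis=percent_autolysis(lysis, myc, denominator),
    )


def synth_plate(fraction_lysed: float, size: int = 512, seed: int = 0
                ) -> tuple[np.ndarray, dict[str, int]]:
    """Synthetic plate image with a planted lysed fraction, plus ground truth.

    A circular colony fills most of the frame; an inner concentric disc of
    the requested colony-area fraction is lysed. Gray values are drawn
    uniformly inside the respective default bands; the background is black
    (gray 0). Ground truth records the actual pixel areas.
    """
    if not 0.0 <= fraction_lysed <= 1.0:
        raise ValueError("fraction_lysed must be in [0, 1]")
    rng = np.random.default_rng(seed)
    radius = size * 0.42
    inner = radius * np.sqrt(fraction_lysed)
    yy, xx = np.mgrid[0:size, 0:size]
    dist2 = (yy - size / 2) ** 2 + (xx - size / 2) ** 2
    colony = dist2 <= radius ** 2
    # strict comparison keeps the exact centre out of a zero-area disc
    lysed = dist2 <= inner ** 2 if fraction_lysed > 0 else np.zeros_like(colony)
    mycelium = colony & ~lysed
    gray = np.zeros((size, size), dtype=np.uint8)
    gray[lysed] = rng.integers(40, 101, size=int(lysed.sum()))
    gray[mycelium] = rng.integers(150, 231, size=int(mycelium.sum()))
    rgb = np.repeat(gray[..., None], 3, axis=2)
    truth = {
        "lysis_pixels": int(lysed.sum()),
        "mycelium_pixels": int(mycelium.sum()),
        "total_pixels": size * size,
    }
    return rgb, truth
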