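"""Immunofluorescence field quantification.

For each channel of a multi-channel field two primary readouts are taken:
the stained area (pixels above a threshold, converted to µm² and to a
fraction of the field) and the stained intensity (mean over stained pixels;
a whole-field mean is available as an option).  Marker expression can be
normalized across channels per field (e.g. the nociceptive peptide CGRP by
the pan-neuronal marker TUBB3), and per-cell positivity can be scored
against a threshold given per-cell label masks.

No background subtraction or flat-field correction is applied; thresholds
are either fixed absolute values or per-channel Otsu, and the rule used is
recorded in every output row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gliakit.traces import Proportion

logger = logging.getLogger(__name__)


@dataclass
class FieldImage:
    """Named intensity channels of one microscope field."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 1.0
    field_id: str = "field"

    def __post_init__(self) -> None:
        shapes = {name: np.asarray(img).shape for name, img in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, img in self.channels.items():
            arr = np.asarray(img, dtype=float)
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} contains negative intensities")
            self.channels[name] = arr

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not present; available: {sorted(self.channels)}"
            ) from None


@dataclass(frozen=True)
class FieldQuant:
    """Stained-area and intensity record for one channel of one field."""

    field_id: str
    channel: str
    stained_area_um2: float
    area_fraction: float
    stained_intensity: float        # NaN when no pixel is stained
    whole_field_intensity: float
    threshold: float
    threshold_rule: str
    n_stained_px: int


def _resolve_threshold(img: np.ndarray, threshold_rule) -> tuple[float, str]:
    if threshold_rule == "otsu":
        from skimage.filters import threshold_otsu

        if np.ptp(img) == 0:
            # constant channel: nothing can stand out
            return float(img.flat[0]), "otsu"
        return float(threshold_otsu(img)), "otsu"
    value = float(threshold_rule)
    return value, f"fixed:{value:g}"


def quantify_channel(field: FieldImage, channel: str, threshold_rule) -> FieldQuant:
    """Stained area and intensity of one channel.

    ``threshold_rule`` is either a number (absolute intensity threshold) or
    the string ``"otsu"``.  Stained pixels are those strictly above the
    threshold.  When nothing is stained the area is 0 and the stained
    intensity is reported as NaN.
    """
    img = field[channel]
    threshold, rule = _resolve_threshold(img, threshold_rule)
    stained = img > threshold
    n = int(stained.sum())
    return FieldQuant(
        field_id=field.field_id,
        channel=channel,
        stained_area_um2=n * field.pixel_size_um**2,
        area_fraction=n / img.size,
        stained_intensity=float(img[stained].mean()) if n else float("nan"),
        whole_field_intensity=float(img.mean()),
        threshold=threshold,
        threshold_rule=rule,
        n_stained_px=n,
    )


def marker_ratio(
    field: FieldImage,
    numerator_channel: str,
    denominator_channel: str,
    threshold_rule="otsu",
    intensity: str = "stained",
) -> float:
    """Per-field intensity ratio of two markers (e.g. CGRP / TUBB3).

    Both channels are quantified with the same threshold rule; the ratio of
    their stained intensities (or whole-field means with
    ``intensity="whole_field"``) is returned.  Fields whose denominator has
    no signal cannot be normalized — they are excluded with a log entry and
    the ratio is NaN.
    """
    num = quantify_channel(field, numerator_channel, threshold_rule)
    den = quantify_channel(field, denominator_channel, threshold_rule)
    attr = "stained_intensity" if intensity == "stained" else "whole_field_intensity"
    num_v, den_v = getattr(num, attr), getattr(den, attr)
    if not np.isfinite(den_v) or den_v <= 0:
        logger.warning(
            "field %s: denominator channel %r has no signal; field excluded",
            field.field_id, denominator_channel,
        )
        return float("nan")
    return float(num_v / den_v)


def positive_proportion(
    field: FieldImage,
    cell_masks,
    channel: str,
    positivity_threshold: float,
) -> Proportion:
    """Fraction of cells whose mean channel intensity exceeds a threshold.

    ``cell_masks`` is either an integer label image (0 = background) or a
    list of boolean masks, one per cell.  Returns counts so the proportion
    can feed a chi-square comparison.
    """
    img = field[channel]
    if isinstance(cell_masks, np.ndarray) and cell_masks.dtype != bool and cell_masks.ndim == 2:
        labels = [cell_masks == lab for lab in np.unique(cell_masks) if lab != 0]
    else:
        labels = [np.asarray(m, dtype=bool) for m in cell_masks]
    if not labels:
        raise ValueError("no cell masks supplied")
    k = sum(1 for m in labels if img[m].mean() > positivity_threshold)
    return Proportion(k, len(labels))


def negative_control_threshold(control: FieldImage, channel: str, n_sd: float = 2.0) -> float:
    """Positivity threshold as mean + n_sd·SD of a negative-control field."""
    img = control[channel]
    return float(img.mean() + n_sd * img.std())


def quantify_field(field: FieldImage, threshold_rule, channels=None) -> pd.DataFrame:
    """Quantify several channels of one field into a tidy table."""
    names = channels or list(field.channels)
    rows = [quantify_channel(field, name, threshold_rule) for name in names]
    return pd.DataFrame([r.__dict__ for r in rows])
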