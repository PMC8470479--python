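"""Reading and writing the package's on-disk formats.

Traces travel either as long-format CSV tables (columns ``roi_id``,
``time_s``, ``F``) or as a single-channel TIFF stack with a companion
integer label image defining the ROIs (ROI trace = mean pixel value per
label per frame).  Masks and fields are TIFF; ground truth and summaries
are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from gliakit.protocols import PROTOCOLS, StimulusProtocol
from gliakit.synthetic import TraceGroundTruth
from gliakit.traces import TraceSet


def write_trace_csv(traces: TraceSet, path) -> None:
    traces.to_frame().to_csv(path, index=False)


def read_trace_csv(path, protocol: StimulusProtocol | str) -> TraceSet:
    """Load a long-format trace table into a :class:`TraceSet`."""
    if isinstance(protocol, str):
        protocol = PROTOCOLS[protocol]
    df = pd.read_csv(path)
    missing = {"roi_id", "time_s", "F"} - set(df.columns)
    if missing:
        raise ValueError(f"trace table {path} lacks columns {sorted(missing)}")
    wide = df.pivot(index="roi_id", columns="time_s", values="F").sort_index(axis=1)
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(f"ROIs with missing frames: {bad}")
    return TraceSet(
        roi_ids=wide.index.to_numpy(),
        times_s=wide.columns.to_numpy(dtype=float),
        F=wide.to_numpy(),
        protocol=protocol,
    )


def write_trace_tiff(traces: TraceSet, stack_path, labels_path=None, labels=None) -> None:
    """Write the recording as a TIFF stack (frames × H × W) plus ROI labels.

    Without an explicit label geometry each ROI becomes one pixel of a
    minimal image — enough to round-trip traces through the TIFF path.
    """
    import tifffile

    n_roi, n_t = traces.F.shape
    if labels is None:
        side = int(np.ceil(np.sqrt(n_roi)))
        labels = np.zeros((side, side), dtype=np.int32)
        labels.flat[:n_roi] = np.arange(1, n_roi + 1)
        stack = np.zeros((n_t, side, side), dtype=np.float32)
        for i in range(n_roi):
            stack[:, *np.unravel_index(i, (side, side))] = traces.F[i]
    else:
        labels = np.asarray(labels)
        stack = np.zeros((n_t, *labels.shape), dtype=np.float32)
        for i, roi in enumerate(np.unique(labels[labels > 0])):
            stack[:, labels == roi] = traces.F[i][:, None]
    tifffile.imwrite(stack_path, stack, photometric="minisblack")
    if labels_path is not None:
        tifffile.imwrite(labels_path, labels)


def read_trace_tiff(stack_path, labels_path, protocol: StimulusProtocol | str,
                    rate_hz: float = 1.0) -> TraceSet:
    """Extract per-ROI mean traces from a TIFF stack and a label image."""
    import tifffile

    if isinstance(protocol, str):
        protocol = PROTOCOLS[protocol]
    stack = tifffile.imread(stack_path).astype(float)
    labels = tifffile.imread(labels_path)
    if stack.shape[1:] != labels.shape:
        raise ValueError(
            f"label image {labels.shape} does not match frames {stack.shape[1:]}"
        )
    roi_ids = np.unique(labels[labels > 0])
    if len(roi_ids) == 0:
        raise ValueError("label image contains no ROIs")
    F = np.stack([stack[:, labels == roi].mean(axis=1) for roi in roi_ids])
    times = np.arange(stack.shape[0]) / rate_hz
    return TraceSet(roi_ids=roi_ids, times_s=times, F=F, protocol=protocol)


def write_ground_truth_json(truth: TraceGroundTruth, path) -> None:
    payload = {
        "event_times": [t.tolist() for t in truth.event_times],
        "event_amps": [a.tolist() for a in truth.event_amps],
        "responder": truth.responder.tolist(),
        "f0": truth.f0.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth_json(path) -> TraceGroundTruth:
    payload = json.loads(Path(path).read_text())
    return TraceGroundTruth(
        event_times=[np.asarray(t, dtype=float) for t in payload["event_times"]],
        event_amps=[np.asarray(a, dtype=float) for a in payload["event_amps"]],
        responder=np.asarray(payload["responder"], dtype=bool),
        f0=np.asarray(payload["f0"], dtype=float),
    )


def write_mask_tiff(mask: np.ndarray, path) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(mask).astype(np.uint8))


def read_mask_tiff(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path) > 0
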