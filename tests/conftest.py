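import numpy as np
import pytest

from gliakit.protocols import StimulusProtocol
from gliakit.traces import NormalizedTraceSet, TraceSet


@pytest.fixture
def drg_like_protocol():
    """Short protocol with the same layout as a depolarization recording."""
    from gliakit.protocols import StimulusEvent

    return StimulusProtocol(
        "mini", 120.0, (0.0, 100.0), (100.0, 120.0),
        (StimulusEvent(100.0, "KCl", 500.0, 20.0, 180.0),),
    )


@pytest.fixture
def make_traceset(drg_like_protocol):
    """Factory: TraceSet from a raw F matrix at 1 Hz."""

    def _make(F, protocol=None):
        F = np.atleast_2d(np.asarray(F, dtype=float))
        proto = protocol or drg_like_protocol
        if F.shape[1] != int(proto.total_duration_s):
            proto = StimulusProtocol(
                "adhoc", float(F.shape[1]), (0.0, float(F.shape[1])), None
            )
        return TraceSet(
            roi_ids=np.arange(F.shape[0]),
            times_s=np.arange(F.shape[1], dtype=float),
            F=F,
            protocol=proto,
        )

    return _make


@pytest.fixture
def make_norm():
    """Factory: NormalizedTraceSet directly from a ΔF/F₀ matrix at 1 Hz."""

    def _make(dff, baseline_end=None, evoked_end=None):
        dff = np.atleast_2d(np.asarray(dff, dtype=float))
        n_t = dff.shape[1]
        b_end = baseline_end if baseline_end is not None else n_t
        proto = StimulusProtocol(
            "adhoc", float(n_t), (0.0, float(b_end)),
            (float(b_end), float(evoked_end)) if evoked_end else None,
        )
        return NormalizedTraceSet(
            roi_ids=np.arange(dff.shape[0]),
            times_s=np.arange(n_t, dtype=float),
            dff=dff,
            f0=np.ones(dff.shape[0]),
            ddff=np.diff(dff, axis=1),
            protocol=proto,
        )

    return _make
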