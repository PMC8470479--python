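"""Stimulus protocols for time-lapse calcium recordings.

A protocol fixes the recording length, the window used both for the F₀
baseline and for spontaneous-activity analysis, the evoked-response window,
and the pharmacological stimulus applied between them.  Four presets cover
the assays this package was built around:

==================  ========  =================  ===============  =========================
preset              duration  baseline window    evoked window    stimulus
==================  ========  =================  ===============  =========================
``drg_rat``         350 s     0-300 s            300-350 s        KCl, 50 mM final
``mgc_rat``         700 s     0-500 s            500-700 s        ATP, 20 µM final
``drg_bovine``      110 s     0-100 s            100-110 s        KCl, 50 mM final
``microglia_bovine``200 s     0-100 s            100-200 s        ATP, 20 µM final
==================  ========  =================  ===============  =========================

Windows are half-open ``[start, end)`` in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field


def final_bath_concentration(stock: float, added_volume: float, bath_volume: float) -> float:
    """Concentration after adding ``added_volume`` of ``stock`` to a bath.

    Parameters
    ----------
    stock : concentration of the added solution (any unit).
    added_volume : volume added; must be > 0.
    bath_volume : volume already in the well; must be >= 0 (0 gives the
        undiluted limit, i.e. the stock concentration).

    Returns
    -------
    float
        ``stock * added_volume / (added_volume + bath_volume)`` in the unit
        of ``stock``.
    """
    if added_volume <= 0:
        raise ValueError(f"added_volume must be positive, got {added_volume}")
    if bath_volume < 0:
        raise ValueError(f"bath_volume must be non-negative, got {bath_volume}")
    return stock * added_volume / (added_volume + bath_volume)


@dataclass(frozen=True)
class StimulusEvent:
    """One pharmacological addition during a recording."""

    time_s: float
    agent: str                      # e.g. "KCl" or "ATP"
    stock_concentration: float      # in `unit`
    added_volume_ul: float
    bath_volume_ul: float
    unit: str = "mM"

    @property
    def final_concentration(self) -> float:
        return final_bath_concentration(
            self.stock_concentration, self.added_volume_ul, self.bath_volume_ul
        )


@dataclass(frozen=True)
class StimulusProtocol:
    """Recording layout: windows and stimuli for one protocol variant."""

    name: str
    total_duration_s: float
    baseline_window: tuple[float, float]
    evoked_window: tuple[float, float] | None = None
    stimuli: tuple[StimulusEvent, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        b0, b1 = self.baseline_window
        if not (0 <= b0 < b1 <= self.total_duration_s):
            raise ValueError(f"baseline_window {self.baseline_window} outside recording")
        if self.evoked_window is not None:
            e0, e1 = self.evoked_window
            if not (b1 <= e0 < e1 <= self.total_duration_s):
                raise ValueError(
                    f"evoked_window {self.evoked_window} must follow the baseline "
                    f"window and lie within the {self.total_duration_s}s recording"
                )

    @property
    def stimulus_agent(self) -> str | None:
        return self.stimuli[0].agent if self.stimuli else None


def _kcl(time_s: float, added_ul: float, bath_ul: float) -> StimulusEvent:
    return StimulusEvent(time_s, "KCl", 500.0, added_ul, bath_ul, unit="mM")


def _atp(time_s: float, added_ul: float, bath_ul: float) -> StimulusEvent:
    return StimulusEvent(time_s, "ATP", 200.0, added_ul, bath_ul, unit="uM")


#: Protocol presets keyed by name.  Rat DRG: 350 s at 1 Hz, KCl depolarization
#: at 300 s (20 µL of 500 mM into 180 µL, 50 mM final).  Rat mixed glia:
#: 700 s, ATP at 500 s (20 µL of 200 µM into 180 µL, 20 µM final).  The
#: bovine variants use the same arithmetic with shorter windows and smaller
#: well volumes (5 µL into 45 µL).
PROTOCOLS: dict[str, StimulusProtocol] = {
    "drg_rat": StimulusProtocol(
        "drg_rat", 350.0, (0.0, 300.0), (300.0, 350.0), (_kcl(300.0, 20.0, 180.0),)
    ),
    "mgc_rat": StimulusProtocol(
        "mgc_rat", 700.0, (0.0, 500.0), (500.0, 700.0), (_atp(500.0, 20.0, 180.0),)
    ),
    "drg_bovine": StimulusProtocol(
        "drg_bovine", 110.0, (0.0, 100.0), (100.0, 110.0), (_kcl(100.0, 5.0, 45.0),)
    ),
    "microglia_bovine": StimulusProtocol(
        "microglia_bovine", 200.0, (0.0, 100.0), (100.0, 200.0), (_atp(100.0, 5.0, 45.0),)
    ),
}


def get_protocol(name: str) -> StimulusProtocol:
    try:
        return PROTOCOLS[name]
    except KeyError:
        raise KeyError(f"unknown protocol {name!r}; available: {sorted(PROTOCOLS)}") from None
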