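"""Event-related skin-conductance response (SCR) extraction.

The autonomic statistic implemented here is the *event-related SCR*: for a
single stimulation, the maximum conductance within a fixed window after
stimulus offset, minus the conductance at the last sample strictly before
stimulus onset.  The difference ("delta", in μS) indexes the phasic
sympathetic response evoked by the stimulus; a trial counts as a response
when the delta reaches a minimum-amplitude criterion (default 0.05 μS, the
conventional electrodermal minimum).  Participants enter group analyses
only if they responded on at least one weak-intensity and at least one
strong-intensity trial.

No tonic/phasic decomposition or deconvolution is attempted: the statistic
is deliberately the literal peak-minus-baseline difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Window (s) after stimulus offset searched for the response peak.
DEFAULT_WINDOW_S = 10.0
#: Minimum peak-minus-baseline delta (μS) for a trial to count as a response.
DEFAULT_AMPLITUDE_CRITERION_US = 0.05

WEAK = "weak"
STRONG = "strong"
INTENSITIES = (WEAK, STRONG)


@dataclass(frozen=True)
class SkinConductanceTrace:
    """Uniformly sampled skin-conductance series.

    Parameters
    ----------
    time
        Sample times in seconds, strictly increasing.
    conductance
        Conductance in μS, one value per sample, all finite.
    """

    time: np.ndarray
    conductance: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        c = np.asarray(self.conductance, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "conductance", c)
        if t.ndim != 1 or c.ndim != 1 or t.shape != c.shape:
            raise ValueError("time and conductance must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValueError("a trace needs at least 2 samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("trace time must be strictly increasing")
        if not np.all(np.isfinite(c)):
            raise ValueError("trace conductance must be finite")

    @property
    def sampling_rate(self) -> float:
        """Nominal sampling rate (Hz) from the median sample spacing."""
        return 1.0 / float(np.median(np.diff(self.time)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "conductance_uS": self.conductance})


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulation: onset/offset in trace time, intensity label, current."""

    onset: float
    offset: float
    intensity_label: str = WEAK
    current: float = 1.0

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError(f"event offset ({self.offset}) must exceed onset ({self.onset})")
        if self.current <= 0:
            raise ValueError("event current must be positive")
        if self.intensity_label not in INTENSITIES:
            raise ValueError(f"unknown intensity label {self.intensity_label!r}")


@dataclass(frozen=True)
class EventRelatedSCR:
    """Per-trial event-related SCR measurements (all conductances in μS)."""

    pre_stimulus_value: float
    peak_value: float
    peak_latency: float  # seconds after stimulus offset
    delta: float
    responded: bool


@dataclass(frozen=True)
class ParticipantSCRSummary:
    participant_id: str
    mean_delta_weak: float
    mean_delta_strong: float
    mean_baseline_weak: float
    mean_baseline_strong: float
    included: bool


def read_trace_csv(path) -> SkinConductanceTrace:
    df = pd.read_csv(path)
    return SkinConductanceTrace(df["time_s"].to_numpy(), df["conductance_uS"].to_numpy())


def write_trace_csv(trace: SkinConductanceTrace, path) -> None:
    trace.to_frame().to_csv(path, index=False, float_format="%.6f")


def pre_stimulus_value(trace: SkinConductanceTrace, event: StimulusEvent) -> float:
    """Conductance at the last sample strictly before the stimulus onset.

    A point value (not a pre-window mean): the "value immediately before
    the stimulus onset".
    """
    idx = int(np.searchsorted(trace.time, event.onset, side="left")) - 1
    if idx < 0:
        raise ValueError(
            f"event with onset {event.onset} s starts before the first trace sample"
        )
    return float(trace.conductance[idx])


def extract_event_scr(
    trace: SkinConductanceTrace,
    event: StimulusEvent,
    window_s: float = DEFAULT_WINDOW_S,
    amplitude_criterion_uS: float = DEFAULT_AMPLITUDE_CRITERION_US,
    next_event_onset: float | None = None,
) -> EventRelatedSCR:
    """Extract the event-related SCR for one stimulation.

    The peak is the global maximum of the conductance over the half-open
    window ``(offset, offset + window_s]``; the delta is the peak minus the
    pre-onset value.  If the window overlaps the next event's onset the
    window is *not* truncated (the overlap is merely logged).

    Raises
    ------
    ValueError
        If the trace does not cover one sample before onset through
        ``offset + window_s``.
    """
    pre = pre_stimulus_value(trace, event)
    window_end = event.offset + window_s
    if trace.time[-1] < window_end:
        raise ValueError(
            f"trace ends at {trace.time[-1]:.3f} s but the response window for the "
            f"event at {event.onset:.3f} s extends to {window_end:.3f} s"
        )
    if next_event_onset is not None and next_event_onset < window_end:
        log.info(
            "response window for event at %.3f s overlaps next event onset %.3f s "
            "(window kept untruncated)", event.onset, next_event_onset,
        )
    mask = (trace.time > event.offset) & (trace.time <= window_end)
    idx = np.flatnonzero(mask)
    peak_rel = int(np.argmax(trace.conductance[idx]))
    peak_idx = idx[peak_rel]
    peak = float(trace.conductance[peak_idx])
    latency = float(trace.time[peak_idx] - event.offset)
    delta = peak - pre
    return EventRelatedSCR(
        pre_stimulus_value=pre,
        peak_value=peak,
        peak_latency=latency,
        delta=delta,
        responded=bool(delta >= amplitude_criterion_uS),
    )


def participant_inclusion(event_scrs: Mapping[str, Iterable[EventRelatedSCR]]) -> bool:
    """True iff at least one responded trial exists for weak AND for strong.

    ``event_scrs`` maps intensity label to that intensity's trials.  Both
    intensities must be present (possibly with zero responded trials).
    """
    for intensity in INTENSITIES:
        if intensity not in event_scrs:
            raise ValueError(f"missing intensity group {intensity!r}")
    return all(any(e.responded for e in event_scrs[i]) for i in INTENSITIES)


def summarize_scr(
    participant_id: str,
    event_scrs: Mapping[str, Sequence[EventRelatedSCR]],
) -> ParticipantSCRSummary:
    """Per-participant arithmetic means of delta and baseline per intensity."""
    for intensity in INTENSITIES:
        if not event_scrs.get(intensity):
            raise ValueError(
                f"participant {participant_id}: no trials for intensity {intensity!r}"
            )
    mean = lambda xs: float(np.mean(xs))  # noqa: E731
    return ParticipantSCRSummary(
        participant_id=participant_id,
        mean_delta_weak=mean([e.delta for e in event_scrs[WEAK]]),
        mean_delta_strong=mean([e.delta for e in event_scrs[STRONG]]),
        mean_baseline_weak=mean([e.pre_stimulus_value for e in event_scrs[WEAK]]),
        mean_baseline_strong=mean([e.pre_stimulus_value for e in event_scrs[STRONG]]),
        included=participant_inclusion(event_scrs),
    )
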