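"""Percent-GFP-positive gating of single-cell reporter fluorescence.

A promoter-GFP reporter strain is compared against a no-GFP control: the
gate threshold is the maximum fluorescence observed in the control, and an
event counts as GFP-positive when its signal is strictly above that
threshold.  Percent positive = 100 x (positive events) / (total events).
Gating the control against its own threshold therefore always yields 0%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FlowSample",
    "GateResult",
    "TrialSummary",
    "gate_threshold",
    "percent_positive",
    "summarize_trials",
]


@dataclass(frozen=True)
class FlowSample:
    """Event-level fluorescence for one acquired sample (single channel)."""

    sample_id: str
    strain: str
    events: np.ndarray
    is_control: bool = False

    def __post_init__(self) -> None:
        ev = np.asarray(self.events, dtype=float)
        if ev.size < 1:
            raise ValueError("a flow sample needs at least one event")
        if not np.all(np.isfinite(ev)):
            raise ValueError("fluorescence intensities must be finite")
        object.__setattr__(self, "events", ev)


@dataclass(frozen=True)
class GateResult:
    sample_id: str
    strain: str
    threshold: float
    percent_positive: float
    median_fluorescence: float
    n_events: int


def gate_threshold(control: FlowSample) -> float:
    """Gate threshold: the maximum fluorescence of the negative control."""
    if not control.is_control:
        raise ValueError(f"sample {control.sample_id!r} is not flagged as a control")
    return float(control.events.max())


def percent_positive(sample: FlowSample, threshold: float) -> GateResult:
    """Gate one sample: events strictly greater than ``threshold`` are
    positive.  The median is computed on all (linear-scale) events."""
    ev = sample.events
    pct = 100.0 * float(np.count_nonzero(ev > threshold)) / ev.size
    return GateResult(
        sample_id=sample.sample_id,
        strain=sample.strain,
        threshold=float(threshold),
        percent_positive=pct,
        median_fluorescence=float(np.median(ev)),
        n_events=int(ev.size),
    )


@dataclass(frozen=True)
class TrialSummary:
    """Across-trial mean and sample SD of the gated statistics for one strain."""

    strain: str
    n_trials: int
    mean_percent_positive: float
    sd_percent_positive: float
    mean_median_fluorescence: float
    sd_median_fluorescence: float


def summarize_trials(results: list[GateResult]) -> list[TrialSummary]:
    """Per-strain mean and sample SD of percent positive and of median
    fluorescence across trials.  A single trial reports SD 0 (n=1)."""
    if not results:
        raise ValueError("no gate results to summarize")
    by_strain: dict[str, list[GateResult]] = {}
    for r in results:
        by_strain.setdefault(r.strain, []).append(r)
    summaries = []
    for strain, rs in by_strain.items():
        pct = np.array([r.percent_positive for r in rs])
        med = np.array([r.median_fluorescence for r in rs])
        summaries.append(
            TrialSummary(
                strain=strain,
                n_trials=len(rs),
                mean_percent_positive=float(pct.mean()),
                sd_percent_positive=float(pct.std(ddof=1)) if pct.size > 1 else 0.0,
                mean_median_fluorescence=float(med.mean()),
                sd_median_fluorescence=float(med.std(ddof=1)) if med.size > 1 else 0.0,
            )
        )
    return summaries
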