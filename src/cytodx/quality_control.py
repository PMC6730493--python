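"""Event-level quality control.

Three independent filters, each of which only clears bits in the keep
mask and never alters intensity values:

* out-of-detection-range removal on untransformed fluorescence channels;
* a time-window anomaly filter that flags acquisition windows whose
  event rate or median signal deviates robustly from the run;
* consumption of manual pregate labels so that only live single cells
  enter the analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from cytodx.fcs_io import EventMatrix, is_scatter_channel, is_time_channel

logger = logging.getLogger(__name__)

#: pregate labels that mark events to discard
EXCLUDED_PREGATE_LABELS = frozenset({"debris", "doublet", "dead"})


@dataclass
class QCReport:
    n_input: int
    n_range_removed: int = 0
    n_anomaly_removed: int = 0
    n_pregate_removed: int = 0
    flagged_time_bins: list[int] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return (
            self.n_input
            - self.n_range_removed
            - self.n_anomaly_removed
            - self.n_pregate_removed
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _fluorescence_channels(E: EventMatrix) -> list[str]:
    return [
        ch
        for ch in E.channels
        if not is_scatter_channel(ch) and not is_time_channel(ch) and ch != "File"
    ]


def remove_out_of_range(E: EventMatrix) -> tuple[EventMatrix, QCReport]:
    """Drop events pinned at or beyond the detector limits.

    On untransformed data every fluorescence channel has a detection
    range (0, T); an event with any fluorescence value <= 0 or >= T is
    unreliable and removed.
    """
    out = E.copy()
    n_input = int(E.keep.sum())
    bad = np.zeros(E.n_events, dtype=bool)
    for ch in _fluorescence_channels(E):
        j = E.index(ch)
        if E.transformed[j]:
            raise ValueError("range filter requires untransformed values")
        x = E.values[:, j]
        T = float(E.ranges.get(ch, np.max(x[E.keep], initial=1.0)))
        bad |= (x <= 0) | (x >= T)
    removed = bad & E.keep
    out.keep[removed] = False
    return out, QCReport(n_input=n_input, n_range_removed=int(removed.sum()))


def time_anomaly_filter(
    E: EventMatrix,
    time_channel: str = "Time",
    n_bins: int = 100,
    mad_factor: float = 5.0,
) -> tuple[EventMatrix, QCReport]:
    """Flag acquisition windows with anomalous rate or signal level.

    Kept events are binned into ``n_bins`` equal-width bins over the time
    range.  A bin is flagged when its event count, or any channel's
    median signal, deviates from the across-bin median by more than
    ``mad_factor`` times the median absolute deviation of that statistic.
    All events in flagged bins are discarded.
    """
    if n_bins < 5:
        raise ValueError("n_bins must be at least 5")
    t = E.column(time_channel)
    kept = E.keep
    n_input = int(kept.sum())
    if n_input < n_bins:
        raise ValueError(f"{n_input} kept events cannot fill {n_bins} time bins")
    tk = t[kept]
    if np.any(np.diff(tk) < 0):
        raise ValueError("time channel must be monotone non-decreasing")
    edges = np.linspace(tk.min(), tk.max(), n_bins + 1)
    bin_of = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, n_bins - 1)

    def deviant(stat: np.ndarray) -> np.ndarray:
        med = np.median(stat)
        mad = np.median(np.abs(stat - med))
        if mad == 0:  # perfectly flat statistic: nothing robustly deviant
            return np.zeros(n_bins, dtype=bool)
        return np.abs(stat - med) > mad_factor * mad

    counts = np.bincount(bin_of[kept], minlength=n_bins).astype(float)
    flagged = deviant(counts)
    signal_channels = [
        ch for ch in E.channels if ch != time_channel and ch != "File"
    ]
    for ch in signal_channels:
        x = E.values[:, E.index(ch)]
        med_per_bin = np.full(n_bins, np.nan)
        for b in range(n_bins):
            sel = kept & (bin_of == b)
            if sel.any():
                med_per_bin[b] = np.median(x[sel])
        ok = np.isfinite(med_per_bin)
        dev = np.zeros(n_bins, dtype=bool)
        dev[ok] = deviant(med_per_bin[ok])
        flagged |= dev

    out = E.copy()
    removed = kept & flagged[bin_of]
    out.keep[removed] = False
    report = QCReport(
        n_input=n_input,
        n_anomaly_removed=int(removed.sum()),
        flagged_time_bins=[int(b) for b in np.nonzero(flagged)[0]],
    )
    return out, report


def apply_pregate(E: EventMatrix, labels) -> EventMatrix:
    """Keep only live single cells according to manual pregate labels.

    ``labels`` holds one entry per event; ``None``/empty, "debris",
    "doublet" and "dead" mark events to drop.  Unknown categories are
    kept and logged, so richer gating vocabularies pass through.
    """
    labels = list(labels)
    if len(labels) != E.n_events:
        raise ValueError(
            f"{len(labels)} labels for {E.n_events} events"
        )
    out = E.copy()
    unknown: set[str] = set()
    for i, lab in enumerate(labels):
        if lab is None or (isinstance(lab, float) and np.isnan(lab)) or lab == "":
            out.keep[i] = False
        elif str(lab).lower() in EXCLUDED_PREGATE_LABELS:
            out.keep[i] = False
        elif str(lab).lower() not in ("live_single", "live", "single"):
            unknown.add(str(lab))
    if unknown:
        logger.info("pregate labels kept as-is (unrecognized): %s", sorted(unknown))
    return out


def read_pregate_labels(path, n_events: int) -> list:
    """Read a two-column delimited file (0-based event index, label)."""
    labels: list = [None] * n_events
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            idx, lab = line.split(None, 1) if "\t" not in line else line.split("\t", 1)
            labels[int(idx)] = lab.strip()
    return labels
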