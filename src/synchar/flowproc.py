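"""Flow-cytometry preprocessing for genetic-part characterization.

Raw cytometry events are reduced to per-condition median fluorescences in
three steps:

1. **Density gating** on forward-scatter area vs height retains the densest
   95% of events, selecting intact single cells and discarding debris and
   aggregates.
2. **Replicate quality control**: a condition (one inducer concentration) is
   pooled only if every pairwise ratio of its replicates' median
   fluorescences is <= 8 and every replicate holds >= 1000 gated events;
   a ratio violation discards the whole condition, since the dose-response
   curvature can be recovered from neighboring conditions without bias.
3. **RPU conversion**: raw fluorescence is rescaled to relative promoter
   units against an autofluorescence control and a reference-promoter
   (J23101) control via

       gamma = ([GFP] - [GFP]_0) / ([GFP] * ([GFP]_RPU - [GFP]_0))

   where [GFP] is the sample median; multiplying every event by gamma puts
   the sample median at ([GFP] - [GFP]_0) / ([GFP]_RPU - [GFP]_0) RPU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical channel names used internally
FSC_AREA, FSC_HEIGHT, FLUOR = "fsc_area", "fsc_height", "fluorescence"


class ChannelConfigError(KeyError):
    """A mapped channel is absent from the input."""


class GatingError(ValueError):
    """Density gating is not applicable (too few events, degenerate scatter)."""


class ReplicateDataError(ValueError):
    """Replicate medians unusable (non-positive)."""


class CalibrationError(ValueError):
    """RPU calibration controls are inconsistent."""


class ConditionDiscardedError(RuntimeError):
    """Operation requested on a condition that failed quality control."""


@dataclass
class EventTable:
    """Per-event scatter and fluorescence measurements for one sample."""

    data: pd.DataFrame  # columns fsc_area, fsc_height, fluorescence
    sample: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        for col in (FSC_AREA, FSC_HEIGHT, FLUOR):
            if col not in self.data.columns:
                raise ChannelConfigError(f"event table is missing channel {col!r}")
        if len(self.data) < 1:
            raise ValueError("event table must contain at least one event")
        if not np.all(np.isfinite(self.data[[FSC_AREA, FSC_HEIGHT, FLUOR]].to_numpy())):
            raise ValueError("event table contains non-finite channel values")

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def median_fluorescence(self) -> float:
        return float(self.data[FLUOR].median())

    def subset(self, mask: np.ndarray) -> "EventTable":
        return EventTable(self.data.loc[mask].reset_index(drop=True), self.sample, self.replicate)


@dataclass
class GateResult:
    mask: np.ndarray  # boolean retention mask over the input events
    retained_fraction: float
    target_fraction: float
    n_bins_used: int
    density_threshold: float

    def __post_init__(self) -> None:
        assert abs(self.retained_fraction - float(np.mean(self.mask))) < 1e-12


@dataclass
class ConditionReplicates:
    """All replicates measured for one experimental condition."""

    condition: str
    replicates: list[EventTable]

    @property
    def medians(self) -> list[float]:
        return [r.median_fluorescence for r in self.replicates]

    @property
    def counts(self) -> list[int]:
        return [r.n_events for r in self.replicates]


@dataclass
class QCDecision:
    condition: str
    keep: bool
    kept_replicates: list[int]
    reasons: list[str] = field(default_factory=list)
    medians: list[float] = field(default_factory=list)
    counts: list[int] = field(default_factory=list)


@dataclass
class RpuCalibration:
    """Autofluorescence and reference-promoter medians defining the RPU scale."""

    auto_median: float
    ref_median: float

    def __post_init__(self) -> None:
        if not self.ref_median > self.auto_median:
            raise CalibrationError(
                "reference median must exceed autofluorescence median"
            )


def read_events(
    path: str | Path,
    channel_map: dict[str, str],
    sample: str = "",
    replicate: str = "",
) -> EventTable:
    """Load a CSV event table, mapping instrument channel names to the three
    canonical channels.

    ``channel_map`` maps the canonical names (``fsc_area``, ``fsc_height``,
    ``fluorescence``) to the column names in the file, e.g.
    ``{"fsc_area": "FSC-A", "fsc_height": "FSC-H", "fluorescence": "FL1-A"}``.
    """
    df = pd.read_csv(path)
    for canon in (FSC_AREA, FSC_HEIGHT, FLUOR):
        src = channel_map.get(canon, canon)
        if src not in df.columns:
            raise ChannelConfigError(
                f"channel {src!r} (mapped to {canon!r}) not found in {path}"
            )
    renamed = df.rename(columns={channel_map.get(c, c): c for c in (FSC_AREA, FSC_HEIGHT, FLUOR)})
    return EventTable(renamed[[FSC_AREA, FSC_HEIGHT, FLUOR]], sample, replicate)


def write_events(table: EventTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def density_gate(
    events: EventTable,
    retain_fraction: float = 0.95,
    bins: int = 128,
) -> GateResult:
    """Retain the densest ``retain_fraction`` of events in scatter space.

    Events are binned on a ``bins`` x ``bins`` 2-D histogram of
    log(forward-scatter area) vs log(forward-scatter height); bins are ranked
    by occupancy and whole bins are retained, densest first, until the target
    fraction is reached. Because whole bins are kept, the achieved fraction
    can overshoot the target by less than one bin's worth of events (under one
    percentage point in practice). Events with non-positive scatter values
    cannot be log-transformed and are dropped (never retained), with a logged
    count.
    """
    if not 0 < retain_fraction <= 1:
        raise ValueError("retain_fraction must be in (0, 1]")
    if events.n_events < 100:
        raise GatingError(
            f"density gating refused below 100 events (got {events.n_events})"
        )
    area = events.data[FSC_AREA].to_numpy(dtype=float)
    height = events.data[FSC_HEIGHT].to_numpy(dtype=float)
    valid = (area > 0) & (height > 0)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("density_gate: dropped %d events with non-positive scatter", n_dropped)
    la, lh = np.log(area[valid]), np.log(height[valid])
    if la.size < 100:
        raise GatingError("fewer than 100 events with positive scatter values")
    if np.ptp(la) == 0 or np.ptp(lh) == 0:
        raise GatingError("degenerate (constant) scatter channel")

    if retain_fraction == 1.0:
        mask = valid.copy()
        return GateResult(mask, float(mask.mean()), 1.0, bins * bins, 0.0)

    hist, xe, ye = np.histogram2d(la, lh, bins=bins)
    ix = np.clip(np.searchsorted(xe, la, side="right") - 1, 0, bins - 1)
    iy = np.clip(np.searchsorted(ye, lh, side="right") - 1, 0, bins - 1)
    flat_bin = ix * bins + iy
    counts = hist.ravel()
    order = np.argsort(-counts, kind="stable")  # densest first, deterministic ties
    target = retain_fraction * la.size
    cum = np.cumsum(counts[order])
    n_bins_used = int(np.searchsorted(cum, target) + 1)
    kept_bins = order[:n_bins_used]
    threshold = float(counts[kept_bins[-1]])
    keep_valid = np.isin(flat_bin, kept_bins)
    mask = np.zeros(events.n_events, dtype=bool)
    mask[np.flatnonzero(valid)] = keep_valid
    return GateResult(mask, float(mask.mean()), retain_fraction, n_bins_used, threshold)


def replicate_qc(
    cond: ConditionReplicates,
    max_ratio: float = 8.0,
    min_events: int = 1000,
) -> QCDecision:
    """Decide whether a condition's replicates may be pooled.

    Rules, applied to gated events: (1) replicates with fewer than
    ``min_events`` events are dropped individually; if fewer than two remain,
    the condition is discarded. (2) every pairwise ratio (larger/smaller) of
    the remaining replicates' median fluorescences must be <= ``max_ratio``;
    one violation discards the entire condition.
    """
    medians = cond.medians
    counts = cond.counts
    if any(m <= 0 for m in medians):
        raise ReplicateDataError(
            f"condition {cond.condition!r}: non-positive replicate median"
        )
    reasons: list[str] = []
    kept = [i for i, c in enumerate(counts) if c >= min_events]
    for i, c in enumerate(counts):
        if c < min_events:
            reasons.append(f"replicate {i} has {c} events (< {min_events})")
    if len(kept) < 2:
        reasons.append("fewer than 2 replicates with sufficient events")
        return QCDecision(cond.condition, False, [], reasons, medians, counts)
    kept_medians = [medians[i] for i in kept]
    worst = max(kept_medians) / min(kept_medians)
    if worst > max_ratio:
        reasons.append(
            f"max pairwise median ratio {worst:.3g} exceeds {max_ratio:g}; "
            "all replicates discarded"
        )
        return QCDecision(cond.condition, False, [], reasons, medians, counts)
    return QCDecision(cond.condition, True, kept, reasons, medians, counts)


def pool_replicates(
    cond: ConditionReplicates, decision: QCDecision | None = None
) -> EventTable:
    """Concatenate a condition's (QC-passing) replicates into one table."""
    if decision is None:
        decision = replicate_qc(cond)
    if not decision.keep:
        raise ConditionDiscardedError(
            f"condition {cond.condition!r} was discarded by QC: {decision.reasons}"
        )
    tables = [cond.replicates[i].data for i in decision.kept_replicates]
    merged = pd.concat(tables, ignore_index=True)
    return EventTable(merged, sample=cond.condition, replicate="pooled")


def rpu_convert(
    events: EventTable, auto_median: float, ref_median: float
) -> tuple[float, EventTable]:
    """Rescale a sample's fluorescence to relative promoter units.

    The conversion factor gamma is computed from this sample's median [GFP]
    against the autofluorescence control median [GFP]_0 and the reference
    promoter median [GFP]_RPU; every event is multiplied by gamma.
    """
    RpuCalibration(auto_median, ref_median)  # validates ref > auto
    sample_median = events.median_fluorescence
    if sample_median <= 0:
        raise ReplicateDataError("sample median must be positive for RPU conversion")
    gamma = (sample_median - auto_median) / (
        sample_median * (ref_median - auto_median)
    )
    rescaled = events.data.copy()
    rescaled[FLUOR] = rescaled[FLUOR] * gamma
    return gamma, EventTable(rescaled, events.sample, events.replicate)
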