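"""Event-level flow-cytometry handling: I/O, QC and co-culture demultiplexing.

Each screen well contains two co-cultured populations carrying the same
silencing reporter: the RFP(mCherry)-labelled knockout mutant and the
BFP-labelled wild-type reference.  Demultiplexing assigns every event to one
population from the log-ratio of the two constitutive marker channels; a
dead-band around the decision threshold leaves ambiguous events unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd

from . import fcs as _fcs

#: Canonical channel order: forward/side scatter plus the three fluorescence
#: channels (GFP 530/30, BFP 445/60, RFP/mCherry 615/30).
CHANNELS = ("FSC", "SSC", "GFP", "BFP", "RFP")

FILTER_BY_CHANNEL = {"GFP": "530/30", "BFP": "445/60", "RFP": "615/30"}


class MissingChannelError(KeyError):
    """A required cytometry channel is absent from the input."""


class DegenerateInputError(ValueError):
    """Input events carry no usable signal (e.g. all identical)."""


@dataclass(frozen=True)
class EventTable:
    """Immutable per-event channel intensities for one well."""

    well_id: str
    channels: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        chans = {}
        n = None
        for name in CHANNELS:
            if name not in self.channels:
                extra = f" ({FILTER_BY_CHANNEL[name]})" if name in FILTER_BY_CHANNEL else ""
                raise MissingChannelError(f"channel {name}{extra} missing from event data")
            arr = np.asarray(self.channels[name], dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"channel {name} must be 1-D")
            if n is None:
                n = arr.size
            elif arr.size != n:
                raise ValueError("all channel vectors must have the same length")
            if not np.isfinite(arr).all():
                raise ValueError(f"channel {name} contains non-finite intensities")
            if (arr < 0).any():
                raise ValueError(f"channel {name} contains negative intensities")
            arr = arr.copy()
            arr.setflags(write=False)
            chans[name] = arr
        if n == 0:
            raise ValueError("empty event set")
        object.__setattr__(self, "channels", MappingProxyType(chans))

    @property
    def n_events(self) -> int:
        return self.channels["GFP"].size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({k: self.channels[k] for k in CHANNELS})


def read_events(path, dialect: str = "tsv", *, channel_map: Mapping[str, str] | None = None,
                well_id: str | None = None) -> EventTable:
    """Load one well of events from a TSV (columns FSC,SSC,GFP,BFP,RFP) or FCS file.

    ``channel_map`` renames file channels to canonical names, e.g.
    ``{"FL1-A": "GFP"}``.  The load is lossless up to the file's own numeric
    precision (float32 for FCS).
    """
    wid = well_id if well_id is not None else str(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        if channel_map:
            df = df.rename(columns=dict(channel_map))
        return EventTable(well_id=wid, channels={c: df[c].to_numpy() for c in df.columns
                                                 if c in CHANNELS})
    if dialect == "fcs":
        names, data, _meta = _fcs.read_fcs(path)
        if channel_map:
            names = [dict(channel_map).get(n, n) for n in names]
        chans = {n: data[:, i].astype(float) for i, n in enumerate(names) if n in CHANNELS}
        return EventTable(well_id=wid, channels=chans)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_events(table: EventTable, path, dialect: str = "tsv") -> None:
    """Write one well as TSV (exact) or FCS 3.1 (float32)."""
    if dialect == "tsv":
        # %.17g guarantees binary64 round-trip through text
        table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif dialect == "fcs":
        _fcs.write_fcs(path, {c: table.channels[c] for c in CHANNELS})
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


@dataclass(frozen=True)
class DemuxResult:
    """Partition of a well's events into mutant / reference / unassigned."""

    mutant_indices: np.ndarray
    reference_indices: np.ndarray
    unassigned_indices: np.ndarray

    @property
    def n_mutant(self) -> int:
        return self.mutant_indices.size

    @property
    def n_reference(self) -> int:
        return self.reference_indices.size

    @property
    def n_total(self) -> int:
        return self.n_mutant + self.n_reference + self.unassigned_indices.size

    def assignment(self) -> np.ndarray:
        """Per-event labels: 'mutant', 'reference' or 'unassigned'."""
        out = np.full(self.n_total, "unassigned", dtype=object)
        out[self.mutant_indices] = "mutant"
        out[self.reference_indices] = "reference"
        return out


def marker_log_ratio(events: EventTable) -> np.ndarray:
    """log10(RFP+1) - log10(BFP+1); positive means mutant-like.

    The +1 pseudocount keeps zero intensities finite.
    """
    return np.log10(events.channels["RFP"] + 1.0) - np.log10(events.channels["BFP"] + 1.0)


def demultiplex(events: EventTable, method: str = "log_ratio_threshold", *,
                threshold: float = 0.0, dead_band: float = 0.3,
                min_events: int = 100, min_posterior: float = 0.95) -> DemuxResult:
    """Assign each event to the mutant (RFP) or reference (BFP) population.

    Default method thresholds the marker log-ratio at ``threshold`` with a
    symmetric ``dead_band`` (in decades) of unassigned events.  The
    ``two_gaussian`` method instead fits a two-component Gaussian mixture on
    the ratio and assigns by posterior, leaving events below
    ``min_posterior`` unassigned.  Both are deterministic given their
    configuration.
    """
    if events.n_events < min_events:
        raise DegenerateInputError(
            f"need at least {min_events} events, got {events.n_events}")
    ratio = marker_log_ratio(events)
    if np.ptp(ratio) == 0.0:
        raise DegenerateInputError("degenerate well: all events have identical marker ratio")

    if method == "log_ratio_threshold":
        mut = ratio > threshold + dead_band
        ref = ratio < threshold - dead_band
    elif method == "two_gaussian":
        from sklearn.mixture import GaussianMixture

        gm = GaussianMixture(n_components=2, random_state=0, n_init=1)
        x = ratio.reshape(-1, 1)
        gm.fit(x)
        post = gm.predict_proba(x)
        mut_comp = int(np.argmax(gm.means_.ravel()))
        confident = post.max(axis=1) >= min_posterior
        labels = post.argmax(axis=1)
        mut = confident & (labels == mut_comp)
        ref = confident & (labels != mut_comp)
    else:
        raise ValueError(f"unknown demultiplexing method {method!r}")

    idx = np.arange(events.n_events)
    return DemuxResult(
        mutant_indices=idx[mut],
        reference_indices=idx[ref],
        unassigned_indices=idx[~(mut | ref)],
    )


@dataclass(frozen=True)
class WellQc:
    """Well-level QC verdict with machine-readable failure reasons."""

    n_total: int
    passed: bool
    reasons: tuple[str, ...]


def well_qc(demux: DemuxResult, min_per_population: int = 1000, *,
            events: EventTable | None = None, saturation_limit: float | None = None,
            max_saturated_fraction: float = 0.01,
            imbalance_fraction: float = 0.05) -> WellQc:
    """QC a demultiplexed well.

    Fails with ``too_few_events`` when either population is below
    ``min_per_population``, ``population_imbalance`` when one population makes
    up less than ``imbalance_fraction`` of assigned events, and
    ``saturated_channel`` when more than ``max_saturated_fraction`` of events
    sit at/above ``saturation_limit`` in any channel (only checked when both
    ``events`` and ``saturation_limit`` are given).
    """
    reasons: list[str] = []
    n_mut, n_ref = demux.n_mutant, demux.n_reference
    if min(n_mut, n_ref) < min_per_population:
        reasons.append("too_few_events")
    assigned = n_mut + n_ref
    if assigned == 0 or min(n_mut, n_ref) / assigned < imbalance_fraction:
        reasons.append("population_imbalance")
    if events is not None and saturation_limit is not None:
        for name in CHANNELS:
            frac = float(np.mean(events.channels[name] >= saturation_limit))
            if frac > max_saturated_fraction:
                reasons.append("saturated_channel")
                break
    return WellQc(n_total=demux.n_total, passed=not reasons, reasons=tuple(reasons))
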