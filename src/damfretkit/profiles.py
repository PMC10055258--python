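"""Binned DAmFRET profiles, monomer-control FRET gates, and fgate.

A DAmFRET histogram divides per-cell expression (acceptor intensity, p.d.u.)
into 64 logarithmically spaced bins over a fixed global range chosen wide
enough to accommodate every data set (default 10**0.5 to 10**4.5 p.d.u.).
A per-bin FRET-positive gate is the 99th percentile of AmFRET in each bin of
a monomer-only (mEos3 alone) control; cells above the gate are counted as
containing assemblies.  ``fgate`` is the gross fraction of cells above the
gate across all bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_RANGE",
    "N_BINS",
    "BinnedProfile",
    "bin_events",
    "fret_positive_gate",
    "fraction_assembled",
]

DEFAULT_RANGE = (10.0**0.5, 10.0**4.5)
N_BINS = 64


@dataclass
class BinnedProfile:
    """Per-bin summaries of one well's DAmFRET distribution.

    Bins are left-closed/right-open on the log axis; the top bin is
    right-closed.  Events outside the global range are tallied in the
    overflow counters and excluded from the bins.
    """

    bin_edges: np.ndarray  # length n_bins + 1, expression (p.d.u.)
    counts: np.ndarray  # ints, length n_bins
    median_amfret: np.ndarray  # NaN for empty bins
    mean_amfret: np.ndarray
    q99_amfret: np.ndarray
    overflow_low: int
    overflow_high: int
    # per-event arrays (in-range events only) kept for downstream statistics
    bin_index: np.ndarray = field(repr=False)
    amfret: np.ndarray = field(repr=False)
    expression: np.ndarray = field(repr=False)

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def bin_centers(self) -> np.ndarray:
        """Geometric bin centers (p.d.u.)."""
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())


def _extract(events) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(events, pd.DataFrame):
        sub = events
        if "gate_all" in sub.columns:
            sub = sub[sub["gate_all"]]
        if "amfret_valid" in sub.columns:
            sub = sub[sub["amfret_valid"]]
        return sub["acceptor"].to_numpy(float), sub["amfret"].to_numpy(float)
    expression, amfret = events
    return np.asarray(expression, float), np.asarray(amfret, float)


def bin_events(
    events,
    expr_range: tuple[float, float] = DEFAULT_RANGE,
    n_bins: int = N_BINS,
) -> BinnedProfile:
    """Bin gated events into log-spaced expression bins.

    ``events`` is either a gated event table (rows failing ``gate_all`` or
    ``amfret_valid`` are ignored) or an ``(expression, amfret)`` array pair.
    """
    lo, hi = expr_range
    if lo <= 0 or hi <= lo:
        raise ValueError("expression range must satisfy 0 < lo < hi")
    expression, amfret = _extract(events)

    edges = np.geomspace(lo, hi, n_bins + 1)
    log_edges = np.log10(edges)
    logx = np.log10(np.maximum(expression, 1e-300))
    # left-closed bins; top edge inclusive
    idx = np.floor(
        (logx - log_edges[0]) / (log_edges[-1] - log_edges[0]) * n_bins
    ).astype(int)
    idx[np.isclose(logx, log_edges[-1])] = n_bins - 1  # top bin right-closed
    in_range = (idx >= 0) & (idx < n_bins)
    overflow_low = int(np.sum(idx < 0))
    overflow_high = int(np.sum(idx >= n_bins))

    idx_in = idx[in_range]
    am_in = amfret[in_range]
    expr_in = expression[in_range]

    counts = np.bincount(idx_in, minlength=n_bins)
    med = np.full(n_bins, np.nan)
    mean = np.full(n_bins, np.nan)
    q99 = np.full(n_bins, np.nan)
    order = np.argsort(idx_in, kind="stable")
    sorted_idx = idx_in[order]
    sorted_am = am_in[order]
    starts = np.searchsorted(sorted_idx, np.arange(n_bins), side="left")
    ends = np.searchsorted(sorted_idx, np.arange(n_bins), side="right")
    for b in range(n_bins):
        if ends[b] > starts[b]:
            vals = sorted_am[starts[b] : ends[b]]
            med[b] = np.median(vals)
            mean[b] = np.mean(vals)
            q99[b] = np.percentile(vals, 99)
    return BinnedProfile(
        bin_edges=edges,
        counts=counts,
        median_amfret=med,
        mean_amfret=mean,
        q99_amfret=q99,
        overflow_low=overflow_low,
        overflow_high=overflow_high,
        bin_index=idx_in,
        amfret=am_in,
        expression=expr_in,
    )


def fret_positive_gate(control: BinnedProfile, min_cells: int = 20) -> np.ndarray:
    """Per-bin upper gate from a monomer-only control profile.

    The gate in each bin is the 99th percentile of the control AmFRET
    distribution in that bin; bins with fewer than ``min_cells`` control
    cells inherit the gate of the nearest adequately populated bin.
    """
    q99 = control.q99_amfret.copy()
    ok = control.counts >= min_cells
    if not ok.any():
        raise ValueError("control profile has no adequately populated bins")
    good = np.flatnonzero(ok)
    for b in np.flatnonzero(~ok):
        q99[b] = q99[good[np.argmin(np.abs(good - b))]]
    return q99


def fraction_assembled(
    sample: BinnedProfile, gate: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-bin fraction of cells above the FRET-positive gate, and fgate.

    The per-bin fraction is above-gate count / bin count (NaN for empty
    bins); fgate is the gross fraction of above-gate cells over all in-range
    cells.
    """
    gate = np.asarray(gate, float)
    if gate.shape != (sample.n_bins,):
        raise ValueError("gate must provide one value per bin")
    above = sample.amfret > gate[sample.bin_index]
    above_counts = np.bincount(
        sample.bin_index, weights=above.astype(float), minlength=sample.n_bins
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = np.where(sample.counts > 0, above_counts / sample.counts, np.nan)
    total = sample.counts.sum()
    fgate = float(above_counts.sum() / total) if total else float("nan")
    return fractions, fgate
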