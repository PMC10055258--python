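"""Event-level transforms, gating and well QC for DAmFRET cytometry data.

An event table is a :class:`pandas.DataFrame` with one row per cell and the
canonical channel columns ``fsc_a, fsc_h, fsc_w, ssc_a, donor, autofluor,
acceptor, fret`` in procedure-defined units (p.d.u.).  Instrument channel
names (``FS00.A``, ``SS02.A``, ``FL03.A``, ``FL17.A``, ...) are accepted as
aliases by :func:`read_events`.  Gating never deletes rows: each gate adds a
boolean flag column and ``gate_all`` is their intersection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib.path import Path as _MplPath
from scipy.optimize import brentq

__all__ = [
    "CHANNEL_ALIASES",
    "REQUIRED_CHANNELS",
    "LogicleParams",
    "logicle_transform",
    "logicle_inverse",
    "asinh_transform",
    "Gate",
    "GateConfig",
    "default_gates",
    "apply_gates",
    "compute_amfret",
    "WellQC",
    "well_qc",
    "instance_retention_filter",
    "read_events",
    "write_events",
]

CHANNEL_ALIASES = {
    "FS00.A": "fsc_a",
    "FS00.H": "fsc_h",
    "FS00.W": "fsc_w",
    "SS02.A": "ssc_a",
    "FL03.A": "donor",
    "FL17.A": "autofluor",
}

REQUIRED_CHANNELS = (
    "fsc_a",
    "fsc_h",
    "fsc_w",
    "ssc_a",
    "donor",
    "autofluor",
    "acceptor",
    "fret",
)


def read_events(path) -> pd.DataFrame:
    """Read a per-well event table from CSV (or Parquet by extension).

    Instrument channel aliases are renamed to the canonical schema; the
    presence of all required channels is enforced.
    """
    path = str(path)
    if path.endswith(".parquet"):
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path)
    df = df.rename(columns=CHANNEL_ALIASES)
    missing = [c for c in REQUIRED_CHANNELS if c not in df.columns]
    if missing:
        raise ValueError(f"event table {path} missing channels: {missing}")
    return df


def write_events(events: pd.DataFrame, path) -> None:
    path = str(path)
    if path.endswith(".parquet"):
        events.to_parquet(path, index=False)
    else:
        events.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# logicle transform (standard biexponential definition, Newton inversion)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogicleParams:
    """Parameters of the logicle display transform.

    T : top of scale (maximum expected data value, p.d.u.)
    M : total display width in decades
    W : width of the quasi-linear region around zero, in decades
    A : additional negative decades below the linear region
    """

    T: float = 262144.0
    M: float = 4.5
    W: float = 0.5
    A: float = 0.0

    def __post_init__(self):
        if self.T <= 0 or self.M <= 0:
            raise ValueError("logicle requires T > 0 and M > 0")
        if not (0 <= self.W < self.M / 2):
            raise ValueError("logicle requires 0 <= W < M/2")
        if self.A < 0 or self.A > self.W:
            raise ValueError("logicle requires 0 <= A <= W")


def _biexp_coeffs(p: LogicleParams):
    """Coefficients (a, b, c, d, f, x1) of the biexponential
    B(y) = a*exp(b*y) - c*exp(-d*y) - f with B(x1) = 0 and B(1) = T."""
    b = (p.M + p.A) * np.log(10.0)
    w = p.W / (p.M + p.A)
    x2 = p.A / (p.M + p.A)
    x1 = x2 + w
    x0 = x2 + 2 * w
    if w == 0:
        d = b
    else:
        # d solves w = 2 ln(b/d) / (b + d), 0 < d < b
        d = brentq(lambda dd: w * (b + dd) - 2 * np.log(b / dd), 1e-12, b)
    c_a = np.exp(x0 * (b + d))
    f_a = np.exp(b * x1) - c_a * np.exp(-d * x1)
    a = p.T / ((np.exp(b) - c_a * np.exp(-d)) - f_a)
    return a, b, a * c_a, d, a * f_a, x1


def logicle_inverse(y, params: LogicleParams = LogicleParams()):
    """Biexponential: map display coordinates y (fraction of scale, data zero
    at the linearization point) back to intensities."""
    a, b, c, d, f, _ = _biexp_coeffs(params)
    y = np.asarray(y, dtype=float)
    return a * np.exp(b * y) - c * np.exp(-d * y) - f


def logicle_transform(values, params: LogicleParams = LogicleParams()):
    """Logicle transform of intensities.

    Returns display coordinates on [0, 1] for data in [B(0), T] (values
    outside extrapolate smoothly); strictly monotone with an exact inverse
    (:func:`logicle_inverse`).  Inversion of the biexponential is by Newton
    iteration from an interpolated starting point.
    """
    a, b, c, d, f, _ = _biexp_coeffs(params)
    x = np.asarray(values, dtype=float)
    # interpolated start from a dense grid, then Newton polish
    grid_y = np.linspace(-0.5, 1.5, 4097)
    grid_x = a * np.exp(b * grid_y) - c * np.exp(-d * grid_y) - f
    y = np.interp(x, grid_x, grid_y)
    for _ in range(60):
        fy = a * np.exp(b * y) - c * np.exp(-d * y) - f - x
        dfy = a * b * np.exp(b * y) + c * d * np.exp(-d * y)
        step = fy / dfy
        y = y - step
        if np.max(np.abs(step)) < 1e-13:
            break
    return y if np.ndim(values) else float(y)


def asinh_transform(values, cofactor: float = 150.0):
    """Inverse hyperbolic sine transform, the common simpler alternative to
    the logicle for display gating."""
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    return np.arcsinh(np.asarray(values, dtype=float) / cofactor)


# ---------------------------------------------------------------------------
# gating
# ---------------------------------------------------------------------------


@dataclass
class Gate:
    """A 2-D gate: rectangle (bounds) or polygon in (x_channel, y_channel).

    Either ``x_bounds``/``y_bounds`` (rectangle) or ``polygon`` (N x 2 vertex
    array, closed implicitly) describes the accepted region.
    """

    name: str
    x_channel: str
    y_channel: str
    x_bounds: tuple[float, float] | None = None
    y_bounds: tuple[float, float] | None = None
    polygon: np.ndarray | None = None

    def member_mask(self, events: pd.DataFrame) -> np.ndarray:
        for ch in (self.x_channel, self.y_channel):
            if ch not in events.columns:
                raise KeyError(f"gate {self.name!r}: channel {ch!r} missing")
        x = events[self.x_channel].to_numpy(float)
        y = events[self.y_channel].to_numpy(float)
        if self.polygon is not None:
            poly = np.asarray(self.polygon, dtype=float)
            if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
                raise ValueError(f"gate {self.name!r}: degenerate polygon")
            return _MplPath(poly).contains_points(np.column_stack([x, y]))
        mask = np.ones(len(x), dtype=bool)
        if self.x_bounds is not None:
            mask &= (x >= self.x_bounds[0]) & (x <= self.x_bounds[1])
        if self.y_bounds is not None:
            mask &= (y >= self.y_bounds[0]) & (y <= self.y_bounds[1])
        return mask


def default_gates() -> list[Gate]:
    """Rectangular defaults on the synthetic channel scales: scatter
    (fsc_a vs ssc_a), singlets (fsc_h vs fsc_w), expression (donor vs
    autofluorescence)."""
    return [
        Gate("scatter", "fsc_a", "ssc_a", x_bounds=(1e4, 2e5), y_bounds=(2e3, 2e5)),
        Gate("singlet", "fsc_h", "fsc_w", x_bounds=(0, np.inf), y_bounds=(0, 100.0)),
        Gate("expression", "donor", "autofluor", x_bounds=(1.0, np.inf), y_bounds=(0, 200.0)),
    ]


@dataclass
class GateConfig:
    gates: list[Gate] = field(default_factory=default_gates)
    logicle: LogicleParams = field(default_factory=LogicleParams)


def apply_gates(events: pd.DataFrame, cfg: GateConfig | None = None) -> pd.DataFrame:
    """Flag events by each gate; adds ``gate_<name>`` columns and ``gate_all``.

    Rows are never removed; the analysis subset is ``events[events.gate_all]``.
    Idempotent: reapplying the same config rewrites identical flags.
    """
    cfg = cfg or GateConfig()
    out = events.copy()
    all_mask = np.ones(len(out), dtype=bool)
    for gate in cfg.gates:
        m = gate.member_mask(out)
        out[f"gate_{gate.name}"] = m
        all_mask &= m
    out["gate_all"] = all_mask
    return out


def compute_amfret(events: pd.DataFrame, acceptor_floor: float = 0.0) -> pd.DataFrame:
    """AmFRET = FRET intensity / acceptor intensity, per cell.

    Rows with acceptor <= ``acceptor_floor`` are flagged (``amfret_valid``)
    rather than divided; their AmFRET is NaN.
    """
    if "acceptor" not in events.columns:
        raise KeyError("acceptor channel missing")
    out = events.copy()
    acc = out["acceptor"].to_numpy(float)
    valid = acc > acceptor_floor
    amfret = np.full(len(out), np.nan)
    np.divide(out["fret"].to_numpy(float), acc, out=amfret, where=valid)
    out["amfret"] = amfret
    out["amfret_valid"] = valid
    return out


# ---------------------------------------------------------------------------
# well QC and screen-level retention
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WellQC:
    n_events: int
    mean_acceptor: float
    passed: bool
    reasons: tuple[str, ...]


def well_qc(
    events: pd.DataFrame,
    min_events: int = 2500,
    min_acceptor: float = 3.5,
) -> WellQC:
    """Screen QC on the gated subset: a well passes with at least
    ``min_events`` expressing cells and mean acceptor intensity of at least
    ``min_acceptor`` p.d.u. (boundaries inclusive: the failing conditions are
    "fewer than" / "less than")."""
    sub = events[events["gate_all"]] if "gate_all" in events.columns else events
    n = len(sub)
    mean_acc = float(sub["acceptor"].mean()) if n else float("nan")
    reasons = []
    if n < min_events:
        reasons.append("n_events")
    if not (mean_acc >= min_acceptor):
        reasons.append("mean_acceptor")
    return WellQC(n, mean_acc, not reasons, tuple(reasons))


def instance_retention_filter(
    original_counts: dict,
    retained_counts: dict,
    min_fraction: float = 0.25,
) -> set:
    """Drop a DFD or seed entirely when fewer than ``min_fraction`` of its
    original wells survive QC (boundary inclusive: exactly 25% is retained).

    Returns the set of retained identifiers.
    """
    kept = set()
    for key, orig in original_counts.items():
        if orig <= 0:
            raise ValueError(f"zero original instances for {key!r}")
        if retained_counts.get(key, 0) / orig >= min_fraction:
            kept.add(key)
    return kept
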