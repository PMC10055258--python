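"""Discontinuous vs continuous classification of DAmFRET profiles.

A nucleation-limited (two-state) protein leaves a population of cells
unassembled well above the concentration where assembly becomes favourable,
so the AmFRET distribution is bimodal inside the concentration window where
cells stochastically convert.  The classifier locates that window and tests
the AmFRET values inside it for unimodality:

1. bin log-expression with Scott's rule and keep bins passing a density
   cutoff (>= 20 cells, count/IQR density >= 500, <= 25% Tukey outliers);
2. fit a "spline": per-bin median AmFRET, denoised with a zero-phase
   second-order-section low-pass filter and interpolated cubically onto a
   fixed grid; bootstrap the cells 100 times and average;
3. locate the transition point (max first derivative of the spline) and the
   transition range (second-derivative extrema before/after it), reporting
   bootstrap medians;
4. run Hartigan's dip test on AmFRET within the transition range:
   p < 0.05 -> discontinuous, otherwise continuous;
5. subtype continuous profiles as low / high / low-to-high by comparing the
   spline minimum and ending value against a reference AmFRET level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, sosfiltfilt

from .dip import dip_statistic, dip_pvalue

__all__ = [
    "ContinuityAbstention",
    "SplineProfile",
    "TransitionSummary",
    "ContinuityResult",
    "scott_bins",
    "density_filter",
    "fit_spline_profile",
    "transition_metrics",
    "classify_continuity",
    "classify_continuous_subtype",
    "majority_classification",
    "classify_well",
]

GRID_SIZE = 256


class ContinuityAbstention(Exception):
    """Raised when a well cannot be classified (reason in ``args[0]``)."""


def scott_bins(values: np.ndarray) -> np.ndarray:
    """Histogram bin edges by Scott's rule: width 3.49 * sd * n**(-1/3).

    ``values`` are log10 expression; the bin count is ceil(range / width).
    """
    v = np.asarray(values, float)
    n = v.size
    if n < 2:
        raise ValueError("Scott's rule requires n >= 2")
    sd = float(np.std(v, ddof=1))
    if sd == 0:
        raise ValueError("Scott's rule undefined for constant data")
    width = 3.49 * sd * n ** (-1.0 / 3.0)
    span = float(v.max() - v.min())
    n_bins = max(1, int(np.ceil(span / width)))
    return np.linspace(v.min(), v.max(), n_bins + 1)


def _tukey_outlier_fraction(vals: np.ndarray) -> float:
    q1, q3 = np.percentile(vals, [25, 75])
    iqr = q3 - q1
    out = (vals < q1 - 1.5 * iqr) | (vals > q3 + 1.5 * iqr)
    return float(out.mean())


def density_filter(
    amfret_by_bin: list[np.ndarray],
    min_cells: int = 20,
    min_density: float = 500.0,
    max_outlier_fraction: float = 0.25,
) -> tuple[np.ndarray, list[str]]:
    """Eligibility of each bin for the spline fit.

    Eligible iff count >= ``min_cells``, density = count / IQR(AmFRET)
    >= ``min_density`` (IQR of 0 gives infinite density), and the Tukey-fence
    outlier fraction is at most ``max_outlier_fraction``.
    """
    mask = np.zeros(len(amfret_by_bin), dtype=bool)
    reasons = []
    for b, vals in enumerate(amfret_by_bin):
        n = len(vals)
        if n < min_cells:
            reasons.append("too_few_cells")
            continue
        q1, q3 = np.percentile(vals, [25, 75])
        iqr = q3 - q1
        density = np.inf if iqr == 0 else n / iqr
        if density < min_density:
            reasons.append("low_density")
            continue
        if _tukey_outlier_fraction(vals) > max_outlier_fraction:
            reasons.append("outlier_heavy")
            continue
        mask[b] = True
        reasons.append("eligible")
    return mask, reasons


@dataclass
class SplineProfile:
    """Bootstrapped denoised median-AmFRET profile on a fixed grid."""

    bin_edges: np.ndarray  # Scott-rule edges on log10 expression
    bin_centers: np.ndarray  # eligible bin centers only (log10)
    median_amfret: np.ndarray  # eligible bins, original sample
    eligible: np.ndarray  # full-length mask
    reasons: list[str]
    grid: np.ndarray  # log10 expression, GRID_SIZE points
    spline: np.ndarray  # bootstrap mean on grid
    replicate_splines: np.ndarray  # (n_boot, GRID_SIZE)


def _denoise(medians: np.ndarray, cutoff: float, order: int) -> np.ndarray:
    sos = butter(order, cutoff, output="sos")
    padlen = min(len(medians) - 1, 3 * (2 * len(sos) + 1))
    return sosfiltfilt(sos, medians, padlen=padlen)


def fit_spline_profile(
    log_expr: np.ndarray,
    amfret: np.ndarray,
    n_boot: int = 100,
    rng_seed: int = 0,
    filter_cutoff: float = 0.2,
    filter_order: int = 2,
    min_cells: int = 20,
    min_density: float = 500.0,
    max_outlier_fraction: float = 0.25,
) -> SplineProfile:
    """Bootstrap the denoised median-AmFRET spline of one well.

    Each replicate resamples cells with replacement (realised as multinomial
    bin counts with i.i.d. within-bin draws, which is distributionally the
    same), takes per-eligible-bin medians, low-pass filters them forward and
    backward, and interpolates cubically onto a common 256-point grid; the
    reported spline is the pointwise mean of replicates.

    Raises :class:`ContinuityAbstention` with fewer than 4 eligible bins.
    """
    log_expr = np.asarray(log_expr, float)
    amfret = np.asarray(amfret, float)
    edges = scott_bins(log_expr)
    n_bins = len(edges) - 1
    idx = np.clip(np.searchsorted(edges, log_expr, side="right") - 1, 0, n_bins - 1)
    by_bin = [amfret[idx == b] for b in range(n_bins)]
    eligible, reasons = density_filter(
        by_bin, min_cells, min_density, max_outlier_fraction
    )
    elig_idx = np.flatnonzero(eligible)
    if len(elig_idx) < 4:
        raise ContinuityAbstention(
            f"only {len(elig_idx)} of {n_bins} bins pass the density cutoff"
        )
    centers = 0.5 * (edges[:-1] + edges[1:])[elig_idx]
    base_medians = np.array([np.median(by_bin[b]) for b in elig_idx])

    rng = np.random.default_rng(rng_seed)
    counts = np.array([len(by_bin[b]) for b in range(n_bins)], dtype=float)
    pvals = counts / counts.sum()
    grid = np.linspace(centers[0], centers[-1], GRID_SIZE)
    reps = np.empty((max(n_boot, 1), GRID_SIZE))
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    for r in range(n_boot):
        boot_counts = rng.multinomial(int(counts.sum()), pvals)
        med = base_medians.copy()
        for j, b in enumerate(elig_idx):
            m = boot_counts[b]
            if m > 0:
                draw = by_bin[b][rng.integers(0, len(by_bin[b]), m)]
                med[j] = np.median(draw)
        smoothed = _denoise(med, filter_cutoff, filter_order)
        reps[r] = CubicSpline(centers, smoothed)(grid)
    return SplineProfile(
        bin_edges=edges,
        bin_centers=centers,
        median_amfret=base_medians,
        eligible=eligible,
        reasons=reasons,
        grid=grid,
        spline=reps[:n_boot].mean(axis=0),
        replicate_splines=reps[:n_boot],
    )


@dataclass
class TransitionSummary:
    """Bootstrap-median transition landmarks (log10 expression)."""

    transition_point: float
    transition_start: float
    transition_end: float
    point_sd: float
    start_sd: float
    end_sd: float
    degenerate: bool


def transition_metrics(profile: SplineProfile, flat_tol: float = 0.02) -> TransitionSummary:
    """Transition point and range from spline derivatives.

    Per replicate: the transition point is the grid point of maximum first
    derivative; the start is the maximum of the second derivative at or
    before it, the end the minimum of the second derivative at or after it
    (argmax/argmin ties resolved leftmost).  Medians across replicates are
    reported.  A spline whose total rise is below ``flat_tol`` AmFRET units
    is flagged degenerate (no transition).
    """
    grid = profile.grid
    if len(grid) < 4:
        raise ValueError("spline grid too short for derivatives")
    pts, starts, ends = [], [], []
    for s in profile.replicate_splines:
        d1 = np.gradient(s, grid)
        d2 = np.gradient(d1, grid)
        tp = int(np.argmax(d1))
        st = int(np.argmax(d2[: tp + 1]))
        en = tp + int(np.argmin(d2[tp:]))
        pts.append(grid[tp])
        starts.append(grid[st])
        ends.append(grid[en])
    degenerate = float(profile.spline.max() - profile.spline.min()) < flat_tol
    return TransitionSummary(
        transition_point=float(np.median(pts)),
        transition_start=float(np.median(starts)),
        transition_end=float(np.median(ends)),
        point_sd=float(np.std(pts)),
        start_sd=float(np.std(starts)),
        end_sd=float(np.std(ends)),
        degenerate=degenerate,
    )


def classify_continuity(dip_p: float, alpha: float = 0.05) -> str:
    """"discontinuous" for p < alpha, "continuous" otherwise (equality is
    continuous: the rejection region is strictly below the cutoff)."""
    if not np.isfinite(dip_p):
        raise ValueError("dip p-value undefined")
    return "discontinuous" if dip_p < alpha else "continuous"


def classify_continuous_subtype(
    spline: np.ndarray, reference_amfret: float
) -> str:
    """Subtype a continuous profile by its spline minimum and ending value.

    Both below the reference -> "low"; both at/above -> "high"; minimum
    below with ending above -> "low_to_high".  The remaining combination
    (minimum above, ending below) cannot arise from a minimum but is flagged
    "anomalous" for completeness.
    """
    if reference_amfret is None or not np.isfinite(reference_amfret):
        raise ValueError("reference AmFRET level required for subtyping")
    mn = float(np.min(spline))
    end = float(spline[-1])
    below_min = mn < reference_amfret
    below_end = end < reference_amfret
    if below_min and below_end:
        return "low"
    if not below_min and not below_end:
        return "high"
    if below_min and not below_end:
        return "low_to_high"
    return "anomalous"


def majority_classification(labels) -> str:
    """Modal label across replicate wells; ties are "unresolved" (flagged
    for manual review rather than silently broken)."""
    labels = list(labels)
    if not labels:
        raise ValueError("no replicate labels")
    uniq, counts = np.unique(labels, return_counts=True)
    top = counts.max()
    winners = uniq[counts == top]
    return str(winners[0]) if len(winners) == 1 else "unresolved"


@dataclass
class ContinuityResult:
    """Full classification of one well."""

    profile: SplineProfile | None
    transition: TransitionSummary | None
    dip_stat: float
    dip_p: float
    n_window: int
    label: str  # discontinuous | continuous | abstained
    subtype: str  # low | high | low_to_high | anomalous | none
    reason: str = ""


def classify_well(
    log_expr,
    amfret,
    reference_amfret: float = 0.1,
    n_boot: int = 100,
    rng_seed: int = 0,
    alpha: float = 0.05,
    n_null: int = 2000,
    max_dip_cells: int = 2000,
    **spline_kw,
) -> ContinuityResult:
    """End-to-end continuity classification of one well.

    AmFRET values of cells whose log10 expression lies within the bootstrap
    transition range are dip-tested (subsampled to ``max_dip_cells`` for the
    null calibration to be shared across wells).  Degenerate (flat) splines
    are continuous by construction and subtyped directly.
    """
    log_expr = np.asarray(log_expr, float)
    amfret = np.asarray(amfret, float)
    try:
        profile = fit_spline_profile(
            log_expr, amfret, n_boot=n_boot, rng_seed=rng_seed, **spline_kw
        )
    except ContinuityAbstention as exc:
        return ContinuityResult(
            None, None, np.nan, np.nan, 0, "abstained", "none", str(exc)
        )
    summary = transition_metrics(profile)
    if summary.degenerate:
        subtype = classify_continuous_subtype(profile.spline, reference_amfret)
        return ContinuityResult(
            profile, summary, np.nan, 1.0, 0, "continuous", subtype, "flat_profile"
        )
    window = (log_expr >= summary.transition_start) & (
        log_expr <= summary.transition_end
    )
    vals = amfret[window]
    if len(vals) < 4:
        return ContinuityResult(
            profile, summary, np.nan, np.nan, len(vals),
            "abstained", "none", "too_few_cells_in_transition_range",
        )
    if len(vals) > max_dip_cells:
        sub_rng = np.random.default_rng(rng_seed + 1)
        vals = vals[sub_rng.choice(len(vals), max_dip_cells, replace=False)]
    dip = dip_statistic(vals)
    p = dip_pvalue(dip, len(vals), n_null=n_null)
    label = classify_continuity(p, alpha=alpha)
    subtype = (
        classify_continuous_subtype(profile.spline, reference_amfret)
        if label == "continuous"
        else "none"
    )
    return ContinuityResult(profile, summary, dip, p, len(vals), label, subtype)
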