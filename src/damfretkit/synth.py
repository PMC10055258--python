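"""Synthetic DAmFRET data with known ground truth.

Generates per-cell event tables, screen-scale well collections, and
synthetic microscopy objects that reproduce the statistical structure of
DAmFRET experiments so every downstream stage can be exercised without
instrument data:

- per-cell expression is log-normal over ~4 decades of p.d.u. (log10
  expression ~ Normal(2.5, 0.7), inside the default 10**0.5..10**4.5 global
  histogram range);
- a one-state protein has AmFRET ~ Normal(0, noise_sd) (or around its
  plateau for a constitutive assembler);
- a continuous assembler follows the stretched-exponential mean curve
  Amp*(1 - exp(-ln2 (c/C50)**a)) with Gaussian noise;
- a nucleation-limited (discontinuous) protein assembles stochastically:
  each cell is FRET-positive with a log-logistic probability of its
  concentration, rising 5% -> 95% over ``nucleation_width`` decades around
  C50, giving a bimodal AmFRET mixture inside that window;
- a seeded well has no nucleation barrier: every cell above
  C50/seed_fold_reduction is assembled;
- batch effects shift the measured expression axis by a per-batch log10
  offset, which downstream standardization must absorb.

Scatter, donor and autofluorescence channels are filled so that >= 90% of
events pass the default gates; a small doublet population (high FSC width)
is planted for the singlet gate to remove.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .weibull import weibull_eval

__all__ = [
    "PhenotypeSpec",
    "SimulatedWell",
    "simulate_events",
    "simulate_well",
    "make_screen_matrix",
    "simulate_screen",
    "ObjectSpec",
    "make_object_descriptors",
    "render_objects",
    "save_well",
]

BEHAVIORS = (
    "one_state_low",
    "one_state_high",
    "continuous_low_to_high",
    "discontinuous",
)

EXPR_LOG10_MEAN = 2.5
EXPR_LOG10_SD = 0.7
DOUBLET_FRACTION = 0.02


@dataclass(frozen=True)
class PhenotypeSpec:
    """Ground-truth phenotype of one simulated well.

    ``true_c50`` is in linear p.d.u.; ``nucleation_width`` is the number of
    decades over which the assembled fraction rises from ~5% to ~95% for a
    discontinuous protein; ``seed_fold_reduction`` is the factor by which a
    cognate seed lowers C50.
    """

    behavior: str = "discontinuous"
    true_c50: float = 1000.0
    true_amp: float = 0.3
    true_a: float = 2.0
    nucleation_width: float = 0.5
    seeded: bool = False
    seed_fold_reduction: float = 4.0
    noise_sd: float = 0.05
    batch_shift: float = 0.0

    def __post_init__(self):
        if self.behavior not in BEHAVIORS:
            raise ValueError(f"unknown behavior {self.behavior!r}")
        if self.true_amp <= 0:
            raise ValueError("true_amp must be positive")
        if self.true_c50 <= 0:
            raise ValueError("true_c50 must be positive")
        if self.nucleation_width <= 0:
            raise ValueError("nucleation_width must be positive")
        if self.seed_fold_reduction < 1:
            raise ValueError("seed_fold_reduction must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _assembly_probability(log_c: np.ndarray, spec: PhenotypeSpec) -> np.ndarray:
    """Log-logistic nucleation probability: 5% -> 95% over nucleation_width
    decades centered on C50."""
    steep = 2.0 * np.log10(19.0) / spec.nucleation_width
    return 1.0 / (1.0 + 10.0 ** (-steep * (log_c - np.log10(spec.true_c50))))


def simulate_events(
    spec: PhenotypeSpec,
    n_cells: int,
    rng_seed: int,
    expr_log10_mean: float = EXPR_LOG10_MEAN,
    expr_log10_sd: float = EXPR_LOG10_SD,
) -> pd.DataFrame:
    """Simulate one well's event table (canonical channel schema).

    Bit-reproducible for a fixed seed.  The acceptor channel is the
    expression proxy; FRET is AmFRET * acceptor so that downstream
    ``compute_amfret`` recovers the simulated AmFRET exactly.  The expression
    distribution can be shifted per well (``expr_log10_mean``) to emulate
    induction variability.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(rng_seed)
    log_c = rng.normal(expr_log10_mean, expr_log10_sd, n_cells)
    conc = 10.0**log_c

    if spec.behavior == "one_state_low":
        mean_amfret = np.zeros(n_cells)
    elif spec.behavior == "one_state_high":
        mean_amfret = np.full(n_cells, spec.true_amp)
    elif spec.behavior == "continuous_low_to_high":
        mean_amfret = weibull_eval(conc, spec.true_amp, spec.true_c50, spec.true_a)
    else:  # discontinuous
        if spec.seeded:
            assembled = conc > spec.true_c50 / spec.seed_fold_reduction
        else:
            assembled = rng.uniform(size=n_cells) < _assembly_probability(log_c, spec)
        mean_amfret = np.where(assembled, spec.true_amp, 0.0)

    amfret = mean_amfret + rng.normal(0.0, spec.noise_sd, n_cells)
    acceptor = 10.0 ** (log_c + spec.batch_shift)

    # scatter/donor/autofluorescence: a singlet cluster inside the default
    # gates plus a small doublet population at doubled area / high width
    doublet = rng.uniform(size=n_cells) < DOUBLET_FRACTION
    fsc_a = rng.normal(5e4, 8e3, n_cells) * np.where(doublet, 2.0, 1.0)
    ssc_a = rng.normal(3e4, 6e3, n_cells)
    fsc_h = fsc_a * (1.0 + rng.normal(0, 0.03, n_cells))
    fsc_w = np.where(
        doublet, rng.normal(140.0, 8.0, n_cells), rng.normal(70.0, 6.0, n_cells)
    )
    donor = 0.6 * acceptor * 10.0 ** rng.normal(0, 0.05, n_cells)
    autofluor = 10.0 ** rng.normal(1.0, 0.25, n_cells)

    return pd.DataFrame(
        {
            "fsc_a": fsc_a,
            "fsc_h": fsc_h,
            "fsc_w": fsc_w,
            "ssc_a": ssc_a,
            "donor": donor,
            "autofluor": autofluor,
            "acceptor": acceptor,
            "fret": amfret * acceptor,
        }
    )


@dataclass
class SimulatedWell:
    events: pd.DataFrame
    truth: PhenotypeSpec
    well_id: str
    dfd_id: str
    seed_id: str
    batch: str
    is_negative_control: bool = False


def simulate_well(
    spec: PhenotypeSpec,
    n_cells: int,
    rng_seed: int,
    well_id: str = "well-001",
    dfd_id: str = "DFD-01",
    seed_id: str = "null-01",
    batch: str = "batch-1",
    is_negative_control: bool = False,
    expr_log10_mean: float = EXPR_LOG10_MEAN,
) -> SimulatedWell:
    return SimulatedWell(
        events=simulate_events(spec, n_cells, rng_seed, expr_log10_mean),
        truth=spec,
        well_id=well_id,
        dfd_id=dfd_id,
        seed_id=seed_id,
        batch=batch,
        is_negative_control=is_negative_control,
    )


def make_screen_matrix(
    n_dfds: int = 10,
    n_seeds: int = 12,
    frac_positive: float = 0.05,
    n_negative_controls: int = 2,
    rng_seed: int = 0,
    seed_fold_reduction: float = 4.0,
) -> tuple[list[tuple[str, str, PhenotypeSpec]], pd.DataFrame]:
    """All-pairs screen design with planted nucleating interactions.

    Every DFD is discontinuous with its own C50 and amplitude; the first
    ``n_negative_controls`` seeds of each DFD are null seeds.  A fraction
    ``frac_positive`` of the seedable (non-control) pairs is planted as true
    positives (``seeded=True``); null seeds cannot be positive by
    construction.  Returns the (dfd, seed, spec) matrix and a truth table.
    """
    if n_seeds <= n_negative_controls:
        raise ValueError("need more seeds than negative controls")
    rng = np.random.default_rng(rng_seed)
    dfds = [f"DFD-{i + 1:02d}" for i in range(n_dfds)]
    seeds = [f"null-{j + 1:02d}" for j in range(n_negative_controls)] + [
        f"seed-{j + 1:02d}" for j in range(n_seeds - n_negative_controls)
    ]
    base = {
        d: PhenotypeSpec(
            behavior="discontinuous",
            true_c50=10.0 ** rng.uniform(2.9, 3.4),
            true_amp=rng.uniform(0.25, 0.4),
            nucleation_width=0.5,
            seed_fold_reduction=seed_fold_reduction,
        )
        for d in dfds
    }
    candidates = [(d, s) for d in dfds for s in seeds if not s.startswith("null")]
    n_pos = int(round(frac_positive * len(candidates)))
    pos_idx = rng.choice(len(candidates), size=n_pos, replace=False)
    positives = {candidates[i] for i in pos_idx}
    matrix, rows = [], []
    for d in dfds:
        for s in seeds:
            seeded = (d, s) in positives
            spec = PhenotypeSpec(**{**asdict(base[d]), "seeded": seeded})
            matrix.append((d, s, spec))
            rows.append(
                {
                    "dfd": d,
                    "seed": s,
                    "is_positive": seeded,
                    "is_negative_control": s.startswith("null"),
                    "true_c50": spec.true_c50,
                }
            )
    if not matrix:
        raise ValueError("empty screen matrix")
    return matrix, pd.DataFrame(rows)


def simulate_screen(
    matrix: list[tuple[str, str, PhenotypeSpec]],
    reps: int = 1,
    rng_seed: int = 0,
    n_cells: int = 10000,
    batch_shift_sd: float = 0.05,
    well_c50_jitter_sd: float = 0.05,
    well_amp_jitter_sd: float = 0.05,
    well_expr_jitter_sd: float = 0.05,
) -> list[SimulatedWell]:
    """Simulate every (DFD, seed) pair of a screen, ``reps`` times.

    Each replicate is one experimental batch with its own expression-axis
    shift; wells within a batch share it.  Independent per-well biological
    variability is applied on top of each pair's phenotype: the realised C50
    is jittered by ``well_c50_jitter_sd`` decades, the amplitude by a
    ``well_amp_jitter_sd`` relative factor, and the expression induction
    level by ``well_expr_jitter_sd`` decades (which moves the assembled
    fraction but not the saturation concentration), emulating day-to-day
    culture and instrument variation between wells of the same strain.
    Well seeds are derived from ``rng_seed`` so the whole screen is
    reproducible.
    """
    if not matrix:
        raise ValueError("empty screen matrix")
    rng = np.random.default_rng(rng_seed)
    wells = []
    for rep in range(reps):
        batch = f"batch-{rep + 1}"
        shift = rng.normal(0.0, batch_shift_sd)
        for d, s, spec in matrix:
            spec_b = PhenotypeSpec(
                **{
                    **asdict(spec),
                    "batch_shift": shift,
                    "true_c50": spec.true_c50
                    * 10.0 ** rng.normal(0.0, well_c50_jitter_sd),
                    "true_amp": spec.true_amp
                    * (1.0 + rng.normal(0.0, well_amp_jitter_sd)),
                }
            )
            wells.append(
                simulate_well(
                    spec_b,
                    n_cells=n_cells,
                    rng_seed=int(rng.integers(0, 2**31 - 1)),
                    well_id=f"{d}_{s}_{batch}",
                    dfd_id=d,
                    seed_id=s,
                    batch=batch,
                    is_negative_control=s.startswith("null"),
                    expr_log10_mean=EXPR_LOG10_MEAN
                    + rng.normal(0.0, well_expr_jitter_sd),
                )
            )
    return wells


def save_well(well: SimulatedWell, directory) -> None:
    """Write the event table (CSV) with its ground truth (JSON) beside it."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    well.events.to_csv(d / f"{well.well_id}.csv", index=False)
    truth = asdict(well.truth)
    truth.update(
        well_id=well.well_id,
        dfd_id=well.dfd_id,
        seed_id=well.seed_id,
        batch=well.batch,
        is_negative_control=well.is_negative_control,
    )
    (d / f"{well.well_id}.truth.json").write_text(json.dumps(truth, indent=2))


# ---------------------------------------------------------------------------
# synthetic microscopy objects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ObjectSpec:
    """One synthetic object: "diffuse" (low-contrast filled ellipse of
    near-unit aspect ratio), "punctate" (compact high-contrast Gaussian
    spot), or "fibrillar" (elongated high-contrast ridge with intensity
    fading toward the ends)."""

    cls: str
    size: float  # radius / sigma / half-length in px, by class
    intensity: float  # peak intensity above background
    aspect: float = 1.05  # diffuse ellipses only
    angle: float = 0.0  # fibrils only, radians


def make_object_descriptors(
    n_per_class: int, rng_seed: int = 0
) -> list[ObjectSpec]:
    rng = np.random.default_rng(rng_seed)
    descs = []
    for _ in range(n_per_class):
        descs.append(
            ObjectSpec(
                "diffuse",
                size=rng.uniform(8, 11),
                intensity=rng.uniform(1300, 1700),
                aspect=rng.uniform(1.0, 1.1),
            )
        )
        descs.append(
            ObjectSpec("punctate", size=rng.uniform(1.8, 2.4), intensity=rng.uniform(9000, 12000))
        )
        descs.append(
            ObjectSpec(
                "fibrillar",
                size=rng.uniform(12, 16),
                intensity=rng.uniform(8000, 11000),
                angle=rng.uniform(0, np.pi),
            )
        )
    return descs


def render_objects(
    descriptors: list[ObjectSpec],
    image_shape: tuple[int, int] = (320, 320),
    background: float = 100.0,
    noise_sd: float = 4.0,
    rng_seed: int = 0,
) -> tuple[np.ndarray, list[dict]]:
    """Render non-overlapping objects onto a noisy background.

    Objects are placed on a shuffled grid of cells large enough that no two
    can touch; asking for more objects than grid slots raises (overlap
    beyond tolerance).  Returns a 16-bit image and the truth labels (class
    and center per object).
    """
    rng = np.random.default_rng(rng_seed)
    h, w = image_shape
    # placement grid sized to the largest object so no two can touch
    cell = max(24, int(np.ceil(2 * max((d.size for d in descriptors), default=0) + 12)))
    slots = [
        (r * cell + cell // 2, c * cell + cell // 2)
        for r in range((h - cell // 2) // cell)
        for c in range((w - cell // 2) // cell)
    ]
    if len(descriptors) > len(slots):
        raise ValueError(
            f"{len(descriptors)} objects cannot be placed without overlap "
            f"in a {h}x{w} image ({len(slots)} slots)"
        )
    for d in descriptors:
        if 2 * d.size + 6 > cell:
            raise ValueError(f"object too large for overlap-free placement: {d}")
    order = rng.permutation(len(slots))[: len(descriptors)]
    img = np.full((h, w), background, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    truth = []
    for d, slot in zip(descriptors, order):
        cy, cx = slots[slot]
        cy += rng.uniform(-4, 4)
        cx += rng.uniform(-4, 4)
        dy, dx = yy - cy, xx - cx
        if d.cls == "diffuse":
            a = d.size * np.sqrt(d.aspect)
            b = d.size / np.sqrt(d.aspect)
            inside = (dx / a) ** 2 + (dy / b) ** 2 <= 1.0
            texture = 1.0 + rng.normal(0, 0.02, inside.sum())
            img[inside] += d.intensity * texture
        elif d.cls == "punctate":
            r2 = dx**2 + dy**2
            img += d.intensity * np.exp(-r2 / (2 * d.size**2))
        elif d.cls == "fibrillar":
            ux, uy = np.cos(d.angle), np.sin(d.angle)
            s = dx * ux + dy * uy  # along the fibril
            t = -dx * uy + dy * ux  # across
            s_clip = np.clip(s, -d.size, d.size)
            dist2 = (s - s_clip) ** 2 + t**2
            axial = 0.25 + 0.75 * np.cos(np.pi * s_clip / (2 * d.size)) ** 2
            img += d.intensity * axial * np.exp(-dist2 / (2 * 1.2**2))
        else:
            raise ValueError(f"unknown object class {d.cls!r}")
        truth.append({"cls": d.cls, "center": (float(cy), float(cx))})
    img += rng.normal(0, noise_sd, img.shape)
    return np.clip(img, 0, 65535).astype(np.uint16), truth
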