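"""Synthetic data generators with known ground truth.

Every downstream stage of the toolkit (granule quantification, exchange-kinetics
fitting, qPCR and array decay analysis) is exercised against data produced here,
so each generator records the exact ground truth it planted:

* :func:`gen_granule_field` — fluorescence fields of elliptical cells containing
  Gaussian granule spots, with a label mask and a per-granule truth table.
* :func:`gen_stress_timecourse` — fields over a stress time course in which the
  probability that a cell contains granules and the mean granule-area fraction
  follow per-condition logistic curves (rapid assembly in controls, delayed and
  strongly reduced assembly under the triple TIA1/TIAR/G3BP1 knockdown).
* :func:`gen_frap_trace` / :func:`gen_conversion_trace` — first-order exchange
  traces for bleach-recovery and photo-conversion experiments, including
  acquisition bleaching and an unbleached reference trace.
* :func:`gen_ct_table` / :func:`gen_decay_matrix` / :func:`gen_steady_state_matrix`
  — actinomycin-D chase measurements as qPCR Ct tables and array-like intensity
  matrices with per-probe detection p-values.

All randomness flows through the integer seed carried by each parameter
object; an identical parameter object gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

LN2 = math.log(2.0)
#: half-maximum radius of an isotropic Gaussian spot = HALF_MAX_FACTOR * sigma
HALF_MAX_FACTOR = math.sqrt(2.0 * LN2)
#: spots are truncated at this many sigma
TRUNCATION_SIGMA = 3.0


class PlacementError(RuntimeError):
    """Cells or granules could not be placed within the attempt budget."""


class ParameterError(ValueError):
    """A requested generative target is unreachable with the given parameters."""


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _child_seed(seed, *keys: int) -> np.random.Generator:
    """Deterministic named substream: independent streams per (seed, keys)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, keys)]))


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one synthetic microscopy field.

    ``granule_radius`` is the half-maximum radius of the Gaussian spot in
    pixels; the planted "area" ground truth is the number of pixels at or above
    half of the spot's peak amplitude.
    """

    image_shape: tuple[int, int] = (256, 256)
    n_cells: int = 4
    cell_axes: tuple[tuple[float, float], tuple[float, float]] = ((22.0, 34.0), (16.0, 26.0))
    granules_per_cell: tuple[int, int] = (2, 4)
    granule_radius: tuple[float, float] = (2.0, 3.5)
    granule_amplitude: tuple[float, float] = (80.0, 160.0)
    background_level: float = 20.0
    poisson_scale: float = 0.0
    gaussian_sd: float = 2.0
    sg_positive_prob: float = 1.0
    seed: int = 0
    max_attempts: int = 2000

    def validate(self) -> None:
        if min(self.image_shape) <= 0:
            raise ParameterError("image_shape must be positive")
        if not 0.0 <= self.sg_positive_prob <= 1.0:
            raise ParameterError("sg_positive_prob must be in [0, 1]")
        if self.granule_radius[0] < 1.0:
            raise ParameterError("granule_radius must be >= 1 px")
        if self.granules_per_cell[0] < 0 or self.granules_per_cell[0] > self.granules_per_cell[1]:
            raise ParameterError("granules_per_cell must be a nonnegative (lo, hi) range")


@dataclass
class GranuleField:
    """An image plus its cell label mask and (for synthetic fields) ground truth.

    ``truth`` has one row per planted granule (cell_id, granule_id, row, col,
    radius_px, sigma, amplitude, area_px); ``cell_truth`` one row per cell
    (cell_id, sg_positive, target_area_fraction, realized_area_fraction).
    """

    image: np.ndarray
    cell_mask: np.ndarray
    truth: pd.DataFrame | None = None
    cell_truth: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.image.shape != self.cell_mask.shape:
            raise ValueError("image and cell_mask shapes differ")


_TRUTH_COLUMNS = ["cell_id", "granule_id", "row", "col", "radius_px", "sigma", "amplitude", "area_px"]


def _place_cells(spec: FieldSpec, rng: np.random.Generator) -> tuple[np.ndarray, list[dict]]:
    """Place non-overlapping ellipses fully inside the image; returns label mask."""
    h, w = spec.image_shape
    mask = np.zeros((h, w), dtype=np.uint16)
    placed: list[dict] = []
    (a_lo, a_hi), (b_lo, b_hi) = spec.cell_axes
    for cid in range(1, spec.n_cells + 1):
        for _ in range(spec.max_attempts):
            a = rng.uniform(a_lo, a_hi)
            b = rng.uniform(b_lo, b_hi)
            theta = rng.uniform(0.0, math.pi)
            r_bound = max(a, b)
            if 2 * r_bound + 4 >= min(h, w):
                raise ParameterError("cell axes too large for image")
            cy = rng.uniform(r_bound + 2, h - r_bound - 3)
            cx = rng.uniform(r_bound + 2, w - r_bound - 3)
            # bounding-circle separation check (conservative, fast)
            ok = all(
                math.hypot(cy - p["cy"], cx - p["cx"]) > r_bound + p["r_bound"] + 3
                for p in placed
            )
            if not ok:
                continue
            yy, xx = np.mgrid[0:h, 0:w]
            ct, st = math.cos(theta), math.sin(theta)
            u = (yy - cy) * ct + (xx - cx) * st
            v = -(yy - cy) * st + (xx - cx) * ct
            inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            mask[inside] = cid
            placed.append({"cy": cy, "cx": cx, "a": a, "b": b, "theta": theta, "r_bound": r_bound})
            break
        else:
            raise PlacementError(f"could not place cell {cid} in {spec.max_attempts} attempts")
    return mask, placed


def _granule_centers(cell: dict, radii: Sequence[float], rng: np.random.Generator,
                     max_attempts: int) -> list[tuple[float, float]]:
    """Sample granule centres inside the (shrunken) ellipse, pairwise well separated."""
    centers: list[tuple[float, float, float]] = []
    ct, st = math.cos(cell["theta"]), math.sin(cell["theta"])
    for r in radii:
        # keep the half-max disk inside the cell; pairwise separation of
        # 2 * (r_i + r_j) keeps half-max regions disjoint with a wide margin,
        # so planted spots never merge at the detection level
        margin = r + 2.0
        a_eff, b_eff = cell["a"] - margin, cell["b"] - margin
        if a_eff <= 1.0 or b_eff <= 1.0:
            raise ParameterError("granule radius too large for cell geometry")
        for _ in range(max_attempts):
            # uniform in the shrunken ellipse via rejection from the bounding box
            u = rng.uniform(-a_eff, a_eff)
            v = rng.uniform(-b_eff, b_eff)
            if (u / a_eff) ** 2 + (v / b_eff) ** 2 > 1.0:
                continue
            gy = cell["cy"] + u * ct - v * st
            gx = cell["cx"] + u * st + v * ct
            sep_ok = all(
                math.hypot(gy - py, gx - px) > 2.0 * (r + pr)
                for (py, px, pr) in centers
            )
            if sep_ok:
                centers.append((gy, gx, r))
                break
        else:
            raise PlacementError("could not place granule without overlap")
    return [(gy, gx) for gy, gx, _ in centers]


def _best_effort_centers(cell: dict, radii: np.ndarray, rng: np.random.Generator,
                         max_attempts: int, min_granules: int
                         ) -> tuple[list[tuple[float, float]], np.ndarray]:
    """Place as many of the requested granules as geometry allows (>= min)."""
    radii = np.asarray(radii, dtype=float)
    while True:
        try:
            return _granule_centers(cell, radii, rng, max_attempts), radii
        except PlacementError:
            if len(radii) <= min_granules:
                raise
            radii = radii[:-1]


def _render_spot(image: np.ndarray, gy: float, gx: float, sigma: float, amplitude: float) -> int:
    """Add a truncated Gaussian spot in place; returns planted half-max pixel area."""
    h, w = image.shape
    r_trunc = TRUNCATION_SIGMA * sigma
    r0, r1 = max(0, int(gy - r_trunc) - 1), min(h, int(gy + r_trunc) + 2)
    c0, c1 = max(0, int(gx - r_trunc) - 1), min(w, int(gx + r_trunc) + 2)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d2 = (yy - gy) ** 2 + (xx - gx) ** 2
    spot = amplitude * np.exp(-d2 / (2.0 * sigma ** 2))
    spot[d2 > r_trunc ** 2] = 0.0
    image[r0:r1, c0:c1] += spot
    return int(np.count_nonzero(spot >= amplitude / 2.0))


def _apply_noise(image: np.ndarray, spec: FieldSpec, rng: np.random.Generator) -> np.ndarray:
    out = image
    if spec.poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) / spec.poisson_scale) * spec.poisson_scale
        out = out.astype(float)
    if spec.gaussian_sd > 0:
        out = out + rng.normal(0.0, spec.gaussian_sd, size=out.shape)
    return out


def gen_granule_field(spec: FieldSpec, *, rng: np.random.Generator | None = None,
                      metadata: dict | None = None) -> GranuleField:
    """Generate one field: background + per-granule Gaussian spots + noise.

    Granule count per SG-positive cell is uniform over ``spec.granules_per_cell``
    (inclusive); each cell is SG-positive with ``spec.sg_positive_prob``.
    """
    spec.validate()
    if rng is None:
        rng = _rng(spec.seed)
    mask, cells = _place_cells(spec, rng)
    image = np.full(spec.image_shape, float(spec.background_level))
    rows = []
    cell_rows = []
    for cid, cell in enumerate(cells, start=1):
        positive = rng.random() < spec.sg_positive_prob
        n = int(rng.integers(spec.granules_per_cell[0], spec.granules_per_cell[1] + 1)) if positive else 0
        radii = rng.uniform(spec.granule_radius[0], spec.granule_radius[1], size=n)
        amps = rng.uniform(spec.granule_amplitude[0], spec.granule_amplitude[1], size=n)
        centers = _granule_centers(cell, radii, rng, spec.max_attempts)
        area_sum = 0
        for gid, ((gy, gx), r, amp) in enumerate(zip(centers, radii, amps)):
            sigma = r / HALF_MAX_FACTOR
            area = _render_spot(image, gy, gx, sigma, amp)
            area_sum += area
            rows.append((cid, gid, gy, gx, r, sigma, amp, area))
        cell_px = int(np.count_nonzero(mask == cid))
        cell_rows.append((cid, n > 0, np.nan, area_sum / cell_px if cell_px else 0.0))
    image = _apply_noise(image, spec, rng)
    truth = pd.DataFrame(rows, columns=_TRUTH_COLUMNS)
    cell_truth = pd.DataFrame(
        cell_rows, columns=["cell_id", "sg_positive", "target_area_fraction", "realized_area_fraction"]
    )
    return GranuleField(image=image, cell_mask=mask, truth=truth, cell_truth=cell_truth,
                        metadata=metadata or {})


# ---------------------------------------------------------------------------
# stress time course
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticCurve:
    """plateau / (1 + exp(-(t - t50)/tau)); a delayed saturating response."""

    plateau: float
    t50: float
    tau: float

    def __call__(self, t: float) -> float:
        return self.plateau / (1.0 + math.exp(-(t - self.t50) / self.tau))


@dataclass(frozen=True)
class TimecourseSpec:
    """Per-condition SG assembly kinetics over a stress time course.

    Defaults emulate the reported behaviour of arsenate-stressed cells: controls
    are ~80% SG-positive by 30 min, while the triple TIA1/TIAR/G3BP1 knockdown
    (siSG) reaches only ~20% of control positivity after 2 h, with a matching
    reduction of the mean granule-area fraction.
    """

    times: tuple[float, ...] = (30.0, 60.0, 90.0, 120.0)
    assembly: Mapping[str, LogisticCurve] = field(default_factory=lambda: {
        "siC": LogisticCurve(plateau=0.80, t50=10.0, tau=4.0),
        "siSG": LogisticCurve(plateau=0.17, t50=60.0, tau=20.0),
    })
    area_fraction: Mapping[str, LogisticCurve] = field(default_factory=lambda: {
        "siC": LogisticCurve(plateau=0.030, t50=15.0, tau=8.0),
        "siSG": LogisticCurve(plateau=0.012, t50=60.0, tau=20.0),
    })
    n_fields_per_point: int = 4
    seed: int = 0
    max_granules_per_cell: int = 60

    def validate(self) -> None:
        if any(t < 0 for t in self.times) or list(self.times) != sorted(set(self.times)):
            raise ParameterError("times must be nonnegative and strictly increasing")
        for curve in self.assembly.values():
            if not 0.0 <= curve.plateau <= 1.0:
                raise ParameterError("assembly plateau must be in [0, 1]")
        if set(self.assembly) != set(self.area_fraction):
            raise ParameterError("assembly and area_fraction must cover the same conditions")


def _timecourse_field(fspec: FieldSpec, p_positive: float, mean_fraction: float,
                      tspec: TimecourseSpec, rng: np.random.Generator,
                      metadata: dict) -> GranuleField:
    mask, cells = _place_cells(fspec, rng)
    image = np.full(fspec.image_shape, float(fspec.background_level))
    r_lo, r_hi = fspec.granule_radius
    mean_granule_area = math.pi * ((r_lo + r_hi) / 2.0) ** 2
    rows, cell_rows = [], []
    for cid, cell in enumerate(cells, start=1):
        cell_px = int(np.count_nonzero(mask == cid))
        positive = rng.random() < p_positive
        target = 0.0
        n = 0
        if positive and mean_fraction > 0:
            # per-cell burden scatters around the condition mean
            target = mean_fraction * rng.lognormal(mean=0.0, sigma=0.25)
            n = max(2, int(round(target * cell_px / mean_granule_area)))
            if n > tspec.max_granules_per_cell:
                raise ParameterError(
                    f"area fraction {target:.3f} needs {n} granules; unreachable with "
                    f"radius range {fspec.granule_radius}"
                )
        radii = rng.uniform(r_lo, r_hi, size=n)
        amps = rng.uniform(*fspec.granule_amplitude, size=n)
        if n > 0:
            centers, radii = _best_effort_centers(cell, radii, rng, fspec.max_attempts,
                                                  min_granules=min(2, n))
            amps = amps[:len(radii)]
        else:
            centers = []
        area_sum = 0
        for gid, ((gy, gx), r, amp) in enumerate(zip(centers, radii, amps)):
            sigma = r / HALF_MAX_FACTOR
            area = _render_spot(image, gy, gx, sigma, amp)
            area_sum += area
            rows.append((cid, gid, gy, gx, r, sigma, amp, area))
        cell_rows.append((cid, positive and n > 0, target, area_sum / cell_px if cell_px else 0.0))
    image = _apply_noise(image, fspec, rng)
    return GranuleField(
        image=image, cell_mask=mask,
        truth=pd.DataFrame(rows, columns=_TRUTH_COLUMNS),
        cell_truth=pd.DataFrame(cell_rows, columns=["cell_id", "sg_positive",
                                                    "target_area_fraction", "realized_area_fraction"]),
        metadata=metadata,
    )


def gen_stress_timecourse(tspec: TimecourseSpec, fspec: FieldSpec
                          ) -> dict[tuple[str, float, int], GranuleField]:
    """Generate fields over (condition, time, field index) with logistic assembly.

    Per cell, SG positivity is Bernoulli with the condition's assembly-curve value
    and, if positive, the granule load realizes the condition's mean area-fraction
    curve (log-normal per-cell scatter, CV ~25%).
    """
    tspec.validate()
    fspec.validate()
    out: dict[tuple[str, float, int], GranuleField] = {}
    for ci, cond in enumerate(sorted(tspec.assembly)):
        for ti, t in enumerate(tspec.times):
            p = tspec.assembly[cond](t)
            f = tspec.area_fraction[cond](t)
            for fi in range(tspec.n_fields_per_point):
                rng = _child_seed(tspec.seed, ci, ti, fi)
                meta = {"condition": cond, "time": t, "field": fi}
                out[(cond, t, fi)] = _timecourse_field(fspec, p, f, tspec, rng, meta)
    return out


# ---------------------------------------------------------------------------
# exchange kinetics (FRAP / photo-conversion)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticTruth:
    """Ground truth for one first-order exchange experiment.

    Acquisition: ``n_pre`` frames before the event and ``n_post`` after, at
    ``frame_interval`` seconds (default 0.3 s, 5 pre; 100 post for FRAP, 300
    for photo-conversion). ``acquisition_bleach_rate`` dims ROI and reference
    alike, so reference-based normalization is exact by construction.
    """

    k_exchange: float
    immobile_fraction: float
    bleach_depth: float = 0.8
    acquisition_bleach_rate: float = 0.0
    frame_interval: float = 0.3
    n_pre: int = 5
    n_post: int = 100
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.k_exchange < 0:
            raise ParameterError("k_exchange must be >= 0")
        if not 0.0 <= self.immobile_fraction <= 1.0:
            raise ParameterError("immobile_fraction must be in [0, 1]")
        if self.frame_interval <= 0:
            raise ParameterError("frame_interval must be > 0")
        if self.n_pre < 1:
            raise ParameterError("n_pre must be >= 1")

    @property
    def t_half(self) -> float:
        return LN2 / self.k_exchange


#: the two dynamics classes of SG-associated proteins: rapidly exchanged
#: assembly factors (TIA1/TIAR/G3BP1-like) vs stably associated cargo RBPs
#: (IGF2BP1/YB1/HUR-like). Half-lives 2.5 s and 17 s are midpoints of the
#: observed ~2-3 s / ~15-20 s ranges; the stable immobile fraction 0.65 is the
#: midpoint of ~60-70%. The transient immobile fraction is insignificant (no
#: range is reported), and a value of 0 is the only one consistent with the
#: observed near-total 30-s clearance of converted transient-class protein.
CLASS_PRESETS = {
    "transient": {"t_half": 2.5, "immobile_fraction": 0.0},
    "stable": {"t_half": 17.0, "immobile_fraction": 0.65},
}


def preset_truth(class_label: str, kind: str = "frap", *, noise_sd: float = 0.0,
                 seed: int = 0, acquisition_bleach_rate: float = 0.0) -> KineticTruth:
    """KineticTruth for one of the two protein-dynamics class presets."""
    p = CLASS_PRESETS[class_label]
    return KineticTruth(
        k_exchange=LN2 / p["t_half"],
        immobile_fraction=p["immobile_fraction"],
        n_post=100 if kind == "frap" else 300,
        noise_sd=noise_sd,
        seed=seed,
        acquisition_bleach_rate=acquisition_bleach_rate,
    )


@dataclass
class ExchangeTrace:
    """A time-stamped fluorescence trace around a bleach/conversion event.

    ``times`` are seconds relative to the event (negative = pre-event); the
    first ``n_pre`` samples are pre-event. ``reference_intensity`` is an
    unbleached region recorded under the same acquisition bleaching.
    """

    times: np.ndarray
    roi_intensity: np.ndarray
    reference_intensity: np.ndarray | None
    n_pre: int
    kind: str = "frap"            # {"frap", "conversion"}
    channel: str = "green"        # {"green", "red"}
    roi_location: str = "SG"      # {"SG", "cytoplasm"}
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.roi_intensity = np.asarray(self.roi_intensity, dtype=float)
        if self.reference_intensity is not None:
            self.reference_intensity = np.asarray(self.reference_intensity, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.n_pre < 1:
            raise ValueError("n_pre must be >= 1")

    @property
    def post_times(self) -> np.ndarray:
        return self.times[self.n_pre:]

    @property
    def post_values(self) -> np.ndarray:
        return self.roi_intensity[self.n_pre:]

    @property
    def pre_values(self) -> np.ndarray:
        return self.roi_intensity[:self.n_pre]


@dataclass
class ConversionTracePair:
    """Red (converted) and green (unconverted) channels of one conversion event."""

    red: ExchangeTrace
    green: ExchangeTrace


def _acquisition_times(truth: KineticTruth) -> np.ndarray:
    dt = truth.frame_interval
    pre = np.arange(-truth.n_pre, 0) * dt
    post = np.arange(truth.n_post) * dt
    return np.concatenate([pre, post])


def frap_model(t: np.ndarray, k: float, f_inf: float, f_bleach: float) -> np.ndarray:
    """Mono-exponential recovery F(t) = F_inf - (F_inf - F_bleach) exp(-k t)."""
    return f_inf - (f_inf - f_bleach) * np.exp(-k * np.asarray(t, dtype=float))


def conversion_model(t: np.ndarray, k: float, r_plat: float, r0: float) -> np.ndarray:
    """Mono-exponential loss R(t) = R_plat + (R0 - R_plat) exp(-k t)."""
    return r_plat + (r0 - r_plat) * np.exp(-k * np.asarray(t, dtype=float))


def gen_frap_trace(truth: KineticTruth) -> ExchangeTrace:
    """Simulate a FRAP trace under balanced first-order exchange.

    Pre-event plateau 1, instantaneous drop by ``bleach_depth`` at t = 0, then
    recovery toward F_inf = F_bleach + (1 - immobile_fraction) * bleach_depth.
    """
    truth.validate()
    rng = _rng(truth.seed)
    t = _acquisition_times(truth)
    f_bleach = 1.0 - truth.bleach_depth
    f_inf = f_bleach + (1.0 - truth.immobile_fraction) * truth.bleach_depth
    model = np.ones_like(t)
    post = t >= 0
    model[post] = frap_model(t[post], truth.k_exchange, f_inf, f_bleach)
    decay = np.exp(-truth.acquisition_bleach_rate * (t - t[0]))
    roi = model * decay
    ref = decay.copy()
    if truth.noise_sd > 0:
        roi = roi + rng.normal(0.0, truth.noise_sd, size=t.shape)
        ref = ref + rng.normal(0.0, truth.noise_sd, size=t.shape)
    return ExchangeTrace(times=t, roi_intensity=roi, reference_intensity=ref,
                         n_pre=truth.n_pre, kind="frap", channel="green")


def gen_conversion_trace(truth: KineticTruth) -> ConversionTracePair:
    """Simulate a photo-conversion event (green-to-red within one granule).

    The red channel starts at R0 = 1 at t = 0 and relaxes toward
    R_plat = immobile_fraction as converted molecules exit; the green channel
    is emitted as the complementary recovery (R + G = 1 before noise).
    """
    truth.validate()
    rng = _rng(truth.seed)
    t = _acquisition_times(truth)
    post = t >= 0
    red_model = np.zeros_like(t)
    red_model[post] = conversion_model(t[post], truth.k_exchange, truth.immobile_fraction, 1.0)
    green_model = np.ones_like(t)
    green_model[post] = 1.0 - red_model[post]
    decay = np.exp(-truth.acquisition_bleach_rate * (t - t[0]))
    ref = decay.copy()
    red = red_model * decay
    green = green_model * decay
    if truth.noise_sd > 0:
        red = red + rng.normal(0.0, truth.noise_sd, size=t.shape)
        green = green + rng.normal(0.0, truth.noise_sd, size=t.shape)
        ref = ref + rng.normal(0.0, truth.noise_sd, size=t.shape)
    red_tr = ExchangeTrace(times=t, roi_intensity=red, reference_intensity=ref,
                           n_pre=truth.n_pre, kind="conversion", channel="red")
    green_tr = ExchangeTrace(times=t.copy(), roi_intensity=green, reference_intensity=ref.copy(),
                             n_pre=truth.n_pre, kind="conversion", channel="green")
    return ConversionTracePair(red=red_tr, green=green_tr)


# ---------------------------------------------------------------------------
# mRNA decay (qPCR and array)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecayTruth:
    """Ground truth for an ActD-chase decay experiment.

    Per-transcript decay is exponential with log-normally distributed half-life
    (minutes). ``condition_effect`` multiplies the decay rate in every
    non-reference condition (scalar, or one value per transcript); 1.0 means
    decay is identical across conditions — the null under which slope
    correlation between conditions should be high.
    """

    n_transcripts: int = 2000
    half_life_log_mean: float = math.log(60.0)
    half_life_log_sd: float = 0.5
    condition_effect: float | np.ndarray = 1.0
    baseline_log_mean: float = math.log(500.0)
    baseline_log_sd: float = 1.0
    reliable_fraction: float = 0.85
    times: tuple[float, ...] = (0.0, 30.0, 60.0, 120.0)
    conditions: tuple[str, ...] = ("siC", "siSG")
    replicates_per_point: int = 2
    ct_noise_sd: float = 0.15
    array_log_noise_sd: float = 0.10
    array_background: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_transcripts < 1:
            raise ParameterError("n_transcripts must be >= 1")
        if any(t < 0 for t in self.times) or list(self.times) != sorted(set(self.times)):
            raise ParameterError("times must be nonnegative and strictly increasing")
        if not 0.0 <= self.reliable_fraction <= 1.0:
            raise ParameterError("reliable_fraction must be in [0, 1]")


def _draw_half_lives(truth: DecayTruth, rng: np.random.Generator) -> np.ndarray:
    return rng.lognormal(truth.half_life_log_mean, truth.half_life_log_sd, size=truth.n_transcripts)


def _condition_rates(truth: DecayTruth, half_lives: np.ndarray) -> dict[str, np.ndarray]:
    lam = LN2 / half_lives
    effect = np.broadcast_to(np.asarray(truth.condition_effect, dtype=float),
                             (truth.n_transcripts,))
    rates = {}
    for i, cond in enumerate(truth.conditions):
        rates[cond] = lam if i == 0 else lam * effect
    return rates


def gen_ct_table(truth: DecayTruth, reference_gene: str = "RPLP0",
                 half_lives: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Generate a qPCR Ct table (gene, condition, time, replicate, ct).

    Ct rises by exactly one cycle per half-life: Ct(t) = Ct0 + log2(e)*lambda*t,
    so 2^-dCt reproduces exponential decay. The reference gene does not decay.
    ``half_lives`` (gene -> minutes; use ``inf`` for stable) overrides the drawn
    distribution; otherwise genes are named G000, G001, ...
    """
    truth.validate()
    rng = _rng(truth.seed)
    if half_lives is None:
        hl = _draw_half_lives(truth, rng)
        genes = {f"G{i:03d}": hl[i] for i in range(truth.n_transcripts)}
    else:
        genes = dict(half_lives)
    genes[reference_gene] = math.inf
    effect = float(np.asarray(truth.condition_effect, dtype=float).reshape(-1)[0]) \
        if np.ndim(truth.condition_effect) else float(truth.condition_effect)
    rows = []
    for gene, h in genes.items():
        ct0 = rng.uniform(18.0, 28.0)
        lam = 0.0 if math.isinf(h) else LN2 / h
        for ci, cond in enumerate(truth.conditions):
            lam_c = lam if (ci == 0 or gene == reference_gene) else lam * effect
            for t in truth.times:
                for rep in range(truth.replicates_per_point):
                    noise = rng.normal(0.0, truth.ct_noise_sd) if truth.ct_noise_sd > 0 else 0.0
                    ct = ct0 + math.log2(math.e) * lam_c * t + noise
                    rows.append((gene, cond, t, rep, ct))
    return pd.DataFrame(rows, columns=["gene", "condition", "time", "replicate", "ct"])


@dataclass
class ExpressionMatrix:
    """Non-log intensities (transcripts x samples) with detection p-values.

    ``sample_meta`` is indexed by sample id with at least columns
    (condition, time, replicate); steady-state designs add a boolean ``stress``.
    """

    intensities: pd.DataFrame
    detection_p: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.intensities.columns) != list(self.detection_p.columns):
            raise ValueError("intensities and detection_p must share columns")
        missing = set(self.intensities.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"sample_meta missing samples: {sorted(missing)}")


def _ols_slope_on_grid(times: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Closed-form OLS slope of y (n_transcripts x n_times) against times."""
    t = np.asarray(times, dtype=float)
    tc = t - t.mean()
    return (y - y.mean(axis=1, keepdims=True)) @ tc / (tc @ tc)


def gen_decay_matrix(truth: DecayTruth) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate an ActD-chase intensity matrix plus ground-truth decay slopes.

    Intensities decline as baseline*exp(-lambda*t), distorted by multiplicative
    log-normal noise and an additive per-sample background. A
    (1 - reliable_fraction) subset of probes is "absent": zero signal, high
    detection p-values. Ground truth is the OLS slope of the noiseless,
    background-free curve over the sampled time grid, per condition.
    """
    truth.validate()
    rng = _rng(truth.seed)
    n = truth.n_transcripts
    transcripts = [f"T{i:04d}" for i in range(n)]
    half_lives = _draw_half_lives(truth, rng)
    baselines = rng.lognormal(truth.baseline_log_mean, truth.baseline_log_sd, size=n)
    reliable = rng.random(n) < truth.reliable_fraction
    baselines = np.where(reliable, baselines, 0.0)
    rates = _condition_rates(truth, half_lives)
    times = np.asarray(truth.times, dtype=float)

    cols, intens, detect = [], [], []
    truth_rows = []
    for cond, lam in rates.items():
        clean = baselines[:, None] * np.exp(-np.outer(lam, times))
        slopes = _ols_slope_on_grid(times, clean)
        for i, tr in enumerate(transcripts):
            truth_rows.append((tr, cond, slopes[i], half_lives[i], baselines[i], bool(reliable[i])))
        for ti, t in enumerate(times):
            for rep in range(truth.replicates_per_point):
                col = f"{cond}_t{int(t)}_r{rep}"
                cols.append(col)
                signal = clean[:, ti]
                if truth.array_log_noise_sd > 0:
                    signal = signal * rng.lognormal(0.0, truth.array_log_noise_sd, size=n)
                bg = truth.array_background
                if bg > 0:
                    signal = signal + bg + rng.normal(0.0, 0.02 * bg, size=n)
                intens.append(signal)
                p = np.where(reliable, rng.uniform(0.0, 5e-4, size=n), rng.uniform(0.02, 1.0, size=n))
                detect.append(p)
    intensities = pd.DataFrame(np.column_stack(intens), index=transcripts, columns=cols)
    detection_p = pd.DataFrame(np.column_stack(detect), index=transcripts, columns=cols)
    meta_rows = []
    for col in cols:
        cond, t_str, r_str = col.rsplit("_", 2)
        meta_rows.append((col, cond, float(t_str[1:]), int(r_str[1:])))
    meta = pd.DataFrame(meta_rows, columns=["sample", "condition", "time", "replicate"]
                        ).set_index("sample")
    truth_slopes = pd.DataFrame(
        truth_rows, columns=["transcript", "condition", "slope", "half_life", "baseline", "reliable"]
    )
    return ExpressionMatrix(intensities, detection_p, meta), truth_slopes


def gen_steady_state_matrix(truth: DecayTruth, *, knockdown: str = "siSG",
                            control: str = "siC", frac_any: float = 0.045,
                            frac_stress_down: float = 0.012, frac_stress_up: float = 0.012,
                            ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate a {control, knockdown} x {no-stress, stress} steady-state design.

    Most transcripts are unchanged by the knockdown; planted subsets carry
    >=2-fold effects: ``frac_stress_down``/``frac_stress_up`` move only under
    stress (the "red"/"blue" classes of the fold-change scatter) and
    ``frac_any`` move in both states (generic >=2-fold hits). Returns the matrix
    and a per-transcript truth table with the planted log2 ratios and class.
    """
    truth.validate()
    rng = _rng(truth.seed)
    n = truth.n_transcripts
    transcripts = [f"T{i:04d}" for i in range(n)]
    baselines = rng.lognormal(truth.baseline_log_mean, truth.baseline_log_sd, size=n)
    labels = np.array(["none"] * n, dtype=object)
    x = np.zeros(n)   # log2 knockdown/control, no stress
    y = np.zeros(n)   # log2 knockdown/control, stress
    idx = rng.permutation(n)
    n_any = int(round(frac_any * n))
    n_rd = int(round(frac_stress_down * n))
    n_bu = int(round(frac_stress_up * n))
    sel_any, sel_rd, sel_bu = idx[:n_any], idx[n_any:n_any + n_rd], idx[n_any + n_rd:n_any + n_rd + n_bu]
    sign = rng.choice([-1.0, 1.0], size=n_any)
    x[sel_any] = sign * rng.uniform(1.2, 2.5, size=n_any)
    y[sel_any] = sign * rng.uniform(1.2, 2.5, size=n_any)
    labels[sel_any] = "green"
    y[sel_rd] = -rng.uniform(1.2, 2.5, size=n_rd)
    labels[sel_rd] = "red"
    y[sel_bu] = rng.uniform(1.2, 2.5, size=n_bu)
    labels[sel_bu] = "blue"
    # mild null scatter for the unchanged majority
    null = labels == "none"
    x[null] = rng.normal(0.0, 0.15, size=null.sum())
    y[null] = rng.normal(0.0, 0.15, size=null.sum())

    cols, intens, detect, meta_rows = [], [], [], []
    for cond, log2r in ((control, None), (knockdown, (x, y))):
        for stress, ratios in (("no", x), ("yes", y)):
            factor = np.ones(n) if log2r is None else 2.0 ** ratios
            for rep in range(truth.replicates_per_point):
                col = f"{cond}_{'stress' if stress == 'yes' else 'nostress'}_r{rep}"
                cols.append(col)
                signal = baselines * factor
                if truth.array_log_noise_sd > 0:
                    signal = signal * rng.lognormal(0.0, truth.array_log_noise_sd, size=n)
                intens.append(signal)
                detect.append(rng.uniform(0.0, 5e-4, size=n))
                meta_rows.append((col, cond, 0.0, rep, stress == "yes"))
    intensities = pd.DataFrame(np.column_stack(intens), index=transcripts, columns=cols)
    detection_p = pd.DataFrame(np.column_stack(detect), index=transcripts, columns=cols)
    meta = pd.DataFrame(meta_rows, columns=["sample", "condition", "time", "replicate", "stress"]
                        ).set_index("sample")
    planted = pd.DataFrame({"transcript": transcripts, "log2_nostress": x,
                            "log2_stress": y, "planted_class": labels})
    return ExpressionMatrix(intensities, detection_p, meta), planted
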