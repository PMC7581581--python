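"""Synthetic ground-truthed cohorts for the background-adaptation assay.

Real assay data consist of stage-graded chromatophore counts and segment
photographs for shrimp observed on a white and then a black substrate,
across exposure times, trials and nominal drug doses.  This module emulates
that design so every downstream stage (scoring, image quantification,
statistics) can be tested against known ground truth:

* **Design tables** — one specimen per trial x dose x replicate, observed at
  every exposure time on both backgrounds (repeated measure).
* **Stage counts** — an ordered-category (probit-style) latent model: each
  specimen-observation has a latent dispersion level built from additive
  background / time / trial / dose effects, a persistent specimen random
  effect and observation noise; each of its N ~ Poisson(lambda) cells adds
  independent cell noise and is graded 1-5 by four fixed cutpoints.
* **Segment images** — an 8-bit bright elliptical ROI on a neutral canvas,
  with each chromatophore drawn as a dark disk of radius
  ``radius_base + radius_per_stage * stage`` (soft 2-px rim), so that dark
  pixel area tracks stage dispersion and every blob's position, stage and
  radius are recorded as ground truth.

The default effect model is calibrated analytically so the white-background
mean coefficient is ~45 with a +20% relative shift on black — the
background effect size the assay is designed around.  All randomness flows
through one explicitly passed :class:`numpy.random.Generator`; identical
seeds give bit-identical tables and images.

Coordinates are 0-based, row-major, origin at the top-left pixel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .scoring import DEFAULT_RADIUS_BASE, DEFAULT_RADIUS_PER_STAGE, STAGES, StageCounts

logger = logging.getLogger(__name__)

EXPOSURE_TIMES = ("1h", "1d", "1wk")
BACKGROUNDS = ("white", "black")
CONCENTRATIONS_NG_PER_L = (0, 10, 100, 1000)


# ---------------------------------------------------------------------------
# Cohort design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortDesign:
    """Factorial layout of one assay campaign.

    Each specimen belongs to one trial and one dose group and is observed at
    every exposure time on both backgrounds (white first, then black).
    """

    trials: tuple = (1, 2, 3)
    concentrations: tuple = CONCENTRATIONS_NG_PER_L
    exposure_times: tuple = EXPOSURE_TIMES
    backgrounds: tuple = BACKGROUNDS
    replicates_per_treatment: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_treatment < 1:
            raise ValueError("replicates_per_treatment must be >= 1")
        if tuple(self.backgrounds) != BACKGROUNDS:
            raise ValueError(f"backgrounds must be {BACKGROUNDS} in white-then-black order")
        for name, levels in (
            ("trials", self.trials),
            ("concentrations", self.concentrations),
            ("exposure_times", self.exposure_times),
        ):
            if len(levels) == 0 or len(set(levels)) != len(levels):
                raise ValueError(f"{name} must be a nonempty list of unique levels")

    @property
    def n_specimens(self) -> int:
        return len(self.trials) * len(self.concentrations) * self.replicates_per_treatment

    @property
    def n_observations(self) -> int:
        return self.n_specimens * len(self.exposure_times) * len(self.backgrounds)


def sample_design(design: CohortDesign) -> pd.DataFrame:
    """Expand a :class:`CohortDesign` into the observation-level table.

    Returns one row per specimen x exposure time x background with columns
    ``specimen_id, trial, concentration_ng_per_L, exposure_time, background,
    observation_id``.  Specimen IDs are stable across their repeated
    measures, and the row order is deterministic.
    """
    rows = []
    for trial in design.trials:
        for conc in design.concentrations:
            for rep in range(1, design.replicates_per_treatment + 1):
                sid = f"T{trial}-C{conc:04d}-R{rep:02d}"
                for time in design.exposure_times:
                    for bg in design.backgrounds:
                        rows.append(
                            {
                                "specimen_id": sid,
                                "trial": trial,
                                "concentration_ng_per_L": conc,
                                "exposure_time": time,
                                "background": bg,
                                "observation_id": f"{sid}-{time}-{bg}",
                            }
                        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Latent ordered-category stage model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectModel:
    """Generator parameters for the latent dispersion model.

    The latent level of one observation is
    ``mu0 + beta_background(bg) + beta_time(t) + beta_trial(tr) +
    beta_concentration(c) + specimen effect + obs noise``; each cell adds
    N(0, sigma_cell) and is graded ``1 + #{cutpoints below}``.  The beta
    dictionaries map factor levels to additive latent shifts (missing level
    -> error; the white background is the implicit zero reference for the
    scalar ``beta_background``).
    """

    mu0: float = 0.0
    beta_background: float = 0.0
    beta_time: dict = field(default_factory=dict)
    beta_trial: dict = field(default_factory=dict)
    beta_concentration: dict = field(default_factory=dict)
    sigma_specimen: float = 0.3
    sigma_obs: float = 0.15
    sigma_cell: float = 0.6
    cutpoints: tuple = (-1.5, -0.5, 0.5, 1.5)
    lambda_count: float = 40.0
    min_count: int = 10

    def __post_init__(self) -> None:
        cp = tuple(float(c) for c in self.cutpoints)
        if len(cp) != 4 or any(b <= a for a, b in zip(cp, cp[1:])):
            raise ValueError(f"cutpoints must be 4 strictly increasing thresholds, got {cp}")
        for name in ("sigma_specimen", "sigma_obs", "sigma_cell"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.lambda_count <= 0:
            raise ValueError("lambda_count must be > 0")

    @property
    def sigma_total(self) -> float:
        """SD of a single cell's latent value around the fixed-effect mean."""
        return math.sqrt(self.sigma_specimen**2 + self.sigma_obs**2 + self.sigma_cell**2)

    def latent_mean(self, background: str, exposure_time=None, trial=None, concentration=None) -> float:
        """Fixed-effect latent level for one combination of covariates."""
        if background not in BACKGROUNDS:
            raise ValueError(f"unknown background level {background!r}")
        latent = self.mu0 + (self.beta_background if background == "black" else 0.0)
        for value, beta, name in (
            (exposure_time, self.beta_time, "exposure_time"),
            (trial, self.beta_trial, "trial"),
            (concentration, self.beta_concentration, "concentration"),
        ):
            if value is None:
                continue
            if beta and value not in beta:
                raise ValueError(f"unknown {name} level {value!r} (model has {sorted(beta)})")
            latent += beta.get(value, 0.0)
        return latent


def stage_probabilities(latent_mean: float, cutpoints, sigma: float) -> np.ndarray:
    """Analytic stage-occupancy probabilities of the ordered-probit model.

    ``p_k = Phi((tau_k - m)/sigma) - Phi((tau_{k-1} - m)/sigma)`` with
    ``tau_0 = -inf`` and ``tau_5 = +inf``.  With ``sigma = 0`` the mass
    collapses onto the single stage whose cutpoint interval contains ``m``.
    """
    taus = np.asarray(cutpoints, dtype=float)
    if sigma == 0.0:
        stage = 1 + int(np.searchsorted(taus, latent_mean))
        probs = np.zeros(5)
        probs[stage - 1] = 1.0
        return probs
    cdf = norm.cdf((taus - latent_mean) / sigma)
    return np.diff(np.concatenate([[0.0], cdf, [1.0]]))


def expected_stage(latent_mean: float, cutpoints, sigma: float) -> float:
    """Analytic mean stage ``sum_k k p_k`` at a given latent mean."""
    return float(np.dot(STAGES, stage_probabilities(latent_mean, cutpoints, sigma)))


def calibrate_effect_model(
    white_mean_coefficient: float = 45.0,
    relative_black_shift: float = 0.20,
    **overrides,
) -> EffectModel:
    """Build an :class:`EffectModel` whose marginal means hit stated targets.

    Solves (by root finding on the analytic ordered-probit mean stage, with
    the full cell-level latent SD) for ``mu0`` such that the cohort mean
    coefficient on white is ``white_mean_coefficient``, and for
    ``beta_background`` such that the black-background mean is
    ``(1 + relative_black_shift)`` times the white mean.  Remaining fields
    take their defaults unless overridden.
    """
    base = EffectModel(**overrides)
    sigma = base.sigma_total
    taus = base.cutpoints

    def solve(target_coeff: float) -> float:
        target = target_coeff / 20.0
        if not 1.0 < target < 5.0:
            raise ValueError(f"target coefficient {target_coeff} outside attainable (20, 100)")
        return brentq(lambda m: expected_stage(m, taus, sigma) - target, -50.0, 50.0, xtol=1e-10)

    mu0 = solve(white_mean_coefficient)
    mu_black = solve(white_mean_coefficient * (1.0 + relative_black_shift))
    return replace(base, mu0=mu0, beta_background=mu_black - mu0)


def default_effect_model() -> EffectModel:
    """The documented default generator: white mean ~45, black +20%, null drug."""
    return calibrate_effect_model(45.0, 0.20)


def sample_stage_counts(
    covariates: dict,
    model: EffectModel,
    rng: np.random.Generator,
    specimen_effect: float | None = None,
) -> StageCounts:
    """Draw one observation's stage counts from the latent model.

    ``covariates`` must contain ``background`` and may contain
    ``exposure_time``, ``trial`` and ``concentration`` (levels must exist in
    the model's beta maps when those maps are nonempty).  The specimen
    random effect can be passed explicitly so repeated measures of one
    animal share it; if omitted a fresh one is drawn.
    """
    latent = model.latent_mean(
        covariates["background"],
        covariates.get("exposure_time"),
        covariates.get("trial"),
        covariates.get("concentration"),
    )
    if specimen_effect is None:
        specimen_effect = rng.normal(0.0, model.sigma_specimen) if model.sigma_specimen > 0 else 0.0
    latent += specimen_effect
    if model.sigma_obs > 0:
        latent += rng.normal(0.0, model.sigma_obs)
    n_cells = int(rng.poisson(model.lambda_count))
    while n_cells < model.min_count:
        n_cells = int(rng.poisson(model.lambda_count))
    cell_noise = rng.normal(0.0, model.sigma_cell, size=n_cells) if model.sigma_cell > 0 else np.zeros(n_cells)
    cell_latent = latent + cell_noise
    stages = 1 + np.searchsorted(np.asarray(model.cutpoints), cell_latent)
    counts = np.bincount(stages, minlength=6)[1:6]
    return StageCounts(*(int(c) for c in counts))


# ---------------------------------------------------------------------------
# Segment image rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromatophoreTruth:
    """Ground truth for one rendered chromatophore."""

    center: tuple  # (row, col), 0-based
    stage: int
    radius: float
    intensity_drop: int = 180

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be in 1..5, got {self.stage}")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")


@dataclass(frozen=True)
class RenderParams:
    """Geometry and photometry of the synthetic segment image."""

    canvas: tuple = (512, 512)  # (height, width)
    roi_center: tuple = (256.0, 256.0)  # (row, col)
    roi_semi_axes: tuple = (85.0, 140.0)  # (row semi-axis, col semi-axis)
    background_intensity: int = 230
    canvas_intensity: int = 110
    background_noise_sd: float = 5.0
    radius_base: float = DEFAULT_RADIUS_BASE
    radius_per_stage: float = DEFAULT_RADIUS_PER_STAGE
    intensity_drop: int = 180
    edge_width: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.canvas) < 64:
            raise ValueError("canvas dimensions must be >= 64")
        if not 0 <= self.background_intensity <= 255:
            raise ValueError("background_intensity must be in [0, 255]")

    def stage_radius(self, stage: int) -> float:
        return self.radius_base + self.radius_per_stage * stage

    def roi_mask(self) -> np.ndarray:
        rr, cc = np.mgrid[0 : self.canvas[0], 0 : self.canvas[1]]
        cy, cx = self.roi_center
        a, b = self.roi_semi_axes
        return ((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2 <= 1.0

    def inside_roi(self, center: tuple, margin: float = 0.0) -> bool:
        cy, cx = self.roi_center
        a, b = self.roi_semi_axes
        am, bm = a - margin, b - margin
        if am <= 0 or bm <= 0:
            return False
        return ((center[0] - cy) / am) ** 2 + ((center[1] - cx) / bm) ** 2 <= 1.0


def place_chromatophores(
    counts: StageCounts,
    params: RenderParams,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> list[ChromatophoreTruth]:
    """Sample non-overlapping ground-truth positions for a set of stage counts.

    Centres are drawn uniformly over the ROI ellipse eroded so the full disk
    (plus rim) fits inside.  Candidates overlapping an accepted disk are
    rejected and redrawn; after ``max_tries`` failures the candidate is
    accepted with overlap and a warning is logged (dense stage-5 segments
    can exceed the packing limit).  Largest disks are placed first.
    """
    stages = [k for k in reversed(STAGES) for _ in range(int(counts.as_array()[k - 1]))]
    cy, cx = params.roi_center
    a, b = params.roi_semi_axes
    placed: list[ChromatophoreTruth] = []
    for stage in stages:
        radius = params.stage_radius(stage)
        margin = radius + params.edge_width / 2.0
        if a - margin <= 0 or b - margin <= 0:
            raise ValueError(f"ROI semi-axes {params.roi_semi_axes} too small for stage-{stage} disk")
        for attempt in range(max_tries):
            # uniform over the eroded ellipse via the unit-disk transform
            u = math.sqrt(rng.uniform())
            theta = rng.uniform(0.0, 2.0 * math.pi)
            row = cy + u * (a - margin) * math.sin(theta)
            col = cx + u * (b - margin) * math.cos(theta)
            ok = all(
                math.hypot(row - t.center[0], col - t.center[1]) >= radius + t.radius + 1.0
                for t in placed
            )
            if ok:
                break
        else:
            logger.warning("could not place stage-%d disk without overlap after %d tries", stage, max_tries)
        placed.append(
            ChromatophoreTruth(center=(row, col), stage=stage, radius=radius, intensity_drop=params.intensity_drop)
        )
    return placed


def render_segment_image(
    truths: list[ChromatophoreTruth],
    params: RenderParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Render an 8-bit segment image and its ROI mask from ground truth.

    The ROI ellipse is bright (``background_intensity`` plus Gaussian noise)
    on a darker neutral canvas.  Each chromatophore subtracts up to
    ``intensity_drop`` grey levels inside its disk, with a linear soft rim
    of ``edge_width`` pixels centred on the nominal radius, so the
    thresholded dark area closely matches ``pi * radius**2``.  Overlapping
    disks combine by maximum darkness, not additively.

    Returns ``(pixels uint8, roi_mask bool)``.

    Raises
    ------
    ValueError
        If any truth centre lies outside the ROI.
    """
    height, width = params.canvas
    roi = params.roi_mask()
    for t in truths:
        if not params.inside_roi(t.center):
            raise ValueError(f"chromatophore at {t.center} lies outside the ROI")
    base = np.full((height, width), float(params.canvas_intensity))
    base[roi] = float(params.background_intensity)
    if params.background_noise_sd > 0:
        base += rng.normal(0.0, params.background_noise_sd, size=base.shape)
    darkness = np.zeros_like(base)
    half_edge = params.edge_width / 2.0
    for t in truths:
        row, col = t.center
        reach = int(math.ceil(t.radius + half_edge)) + 1
        r0, r1 = max(0, int(row) - reach), min(height, int(row) + reach + 1)
        c0, c1 = max(0, int(col) - reach), min(width, int(col) + reach + 1)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        dist = np.hypot(rr - row, cc - col)
        profile = np.clip((t.radius + half_edge - dist) / params.edge_width, 0.0, 1.0)
        patch = darkness[r0:r1, c0:c1]
        np.maximum(patch, t.intensity_drop * profile, out=patch)
    pixels = np.clip(np.rint(base - darkness), 0, 255).astype(np.uint8)
    return pixels, roi


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class CohortBundle:
    """In-memory synthetic dataset: table plus optional per-observation images.

    ``table`` carries the design covariates and ground-truth stage counts;
    ``images`` maps observation_id to ``(pixels, roi_mask)``; ``truths``
    maps observation_id to the rendered chromatophore ground-truth list.
    """

    table: pd.DataFrame
    images: dict = field(default_factory=dict)
    truths: dict = field(default_factory=dict)


def generate_cohort(
    design: CohortDesign,
    effect_model: EffectModel | None = None,
    render_params: RenderParams | None = None,
    render: bool = False,
) -> CohortBundle:
    """Generate a full synthetic cohort (tables, and optionally images).

    Stage counts are drawn for every observation with a persistent random
    effect per specimen.  With ``render=True`` (or explicit
    ``render_params``) each observation also gets a rendered segment image,
    ROI mask and chromatophore ground-truth list.  The whole bundle is a
    deterministic function of ``design.seed``.
    """
    if effect_model is None:
        effect_model = default_effect_model()
    if render and render_params is None:
        render_params = RenderParams()
    rng = np.random.default_rng(design.seed)
    table = sample_design(design)
    specimen_effects = {
        sid: (rng.normal(0.0, effect_model.sigma_specimen) if effect_model.sigma_specimen > 0 else 0.0)
        for sid in table["specimen_id"].unique()
    }
    bundle = CohortBundle(table=table)
    count_cols: list[dict] = []
    for _, row in table.iterrows():
        counts = sample_stage_counts(
            {
                "background": row["background"],
                "exposure_time": row["exposure_time"],
                "trial": row["trial"],
                "concentration": row["concentration_ng_per_L"],
            },
            effect_model,
            rng,
            specimen_effect=specimen_effects[row["specimen_id"]],
        )
        count_cols.append(
            {"n1": counts.n1, "n2": counts.n2, "n3": counts.n3, "n4": counts.n4, "n5": counts.n5, "Tc": counts.tc}
        )
        if render_params is not None:
            truths = place_chromatophores(counts, render_params, rng)
            pixels, roi = render_segment_image(truths, render_params, rng)
            bundle.images[row["observation_id"]] = (pixels, roi)
            bundle.truths[row["observation_id"]] = truths
    bundle.table = pd.concat([table, pd.DataFrame(count_cols)], axis=1)
    return bundle


def dispersion_sweep(
    n_specimens: int,
    seed: int,
    effect_model: EffectModel | None = None,
    render_params: RenderParams | None = None,
    latent_range: tuple = (-2.5, 2.5),
) -> CohortBundle:
    """A validation cohort whose specimens span the full dispersion range.

    Each specimen's latent mean is drawn uniformly over ``latent_range``
    (covering stage-1-dominated through stage-5-dominated segments), its
    stage counts sampled, and its segment image rendered.  Used to check
    that image-derived percent cover tracks the coefficient across the whole
    scale, as the assay's white/black contrasts only probe the middle of it.
    """
    if effect_model is None:
        effect_model = default_effect_model()
    if render_params is None:
        render_params = RenderParams()
    rng = np.random.default_rng(seed)
    rows = []
    bundle = CohortBundle(table=pd.DataFrame())
    for i in range(n_specimens):
        sid = f"SWEEP-{i:03d}"
        latent = rng.uniform(*latent_range)
        model_i = replace(effect_model, mu0=latent, beta_background=0.0)
        counts = sample_stage_counts({"background": "white"}, model_i, rng, specimen_effect=0.0)
        truths = place_chromatophores(counts, render_params, rng)
        pixels, roi = render_segment_image(truths, render_params, rng)
        rows.append(
            {
                "specimen_id": sid,
                "observation_id": sid,
                "latent_mean": latent,
                "n1": counts.n1, "n2": counts.n2, "n3": counts.n3,
                "n4": counts.n4, "n5": counts.n5, "Tc": counts.tc,
            }
        )
        bundle.images[sid] = (pixels, roi)
        bundle.truths[sid] = truths
    bundle.table = pd.DataFrame(rows)
    return bundle
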