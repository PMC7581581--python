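"""Chromatophore dispersion scoring.

A specimen's colour state is summarised by the chromatophore coefficient:
every pigment cell in the reference abdominal segment is graded on the
ordinal dispersion scale 1 (small, fully concentrated pigment) to 5 (large,
fully dilated pigment), and the coefficient is the stage-weighted proportion

    C = sum_k (n_k / Tc) * 20 * k,   k = 1..5,

where ``n_k`` is the number of cells at stage k and ``Tc = sum n_k`` the
total cell count.  Equivalently ``C = 20 * (mean stage)``, so the score is
standardised for the number of chromatophores a specimen happens to carry
and ranges from 20 (every cell fully concentrated, a very light animal) to
100 (every cell fully dilated, a very dark animal).

The module also provides an automated grader that recovers per-stage counts
from a segmented binary image by classifying connected components into
stages by area, inverting the radius-per-stage map used by the synthetic
renderer.  It stands in for the human scorer so that image pipelines can be
exercised end to end.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

logger = logging.getLogger(__name__)

STAGES = (1, 2, 3, 4, 5)

#: Default radius model of the synthetic renderer: radius = BASE + PER_STAGE * stage.
DEFAULT_RADIUS_BASE = 2.0
DEFAULT_RADIUS_PER_STAGE = 1.5


@dataclass(frozen=True)
class StageCounts:
    """Per-specimen counts of chromatophores at dispersion stages 1-5.

    ``tc`` is the total number of graded cells and must equal the sum of the
    per-stage counts; it is filled in automatically when omitted.
    """

    n1: int
    n2: int
    n3: int
    n4: int
    n5: int
    tc: int = field(default=-1)

    def __post_init__(self) -> None:
        counts = (self.n1, self.n2, self.n3, self.n4, self.n5)
        for k, n in zip(STAGES, counts):
            if int(n) != n or n < 0:
                raise ValueError(f"stage-{k} count must be a nonnegative integer, got {n!r}")
        total = int(sum(counts))
        if self.tc == -1:
            object.__setattr__(self, "tc", total)
        elif self.tc != total:
            raise ValueError(f"Tc={self.tc} does not match sum of stage counts {total}")

    def as_array(self) -> np.ndarray:
        return np.array([self.n1, self.n2, self.n3, self.n4, self.n5], dtype=int)


@dataclass(frozen=True)
class CoefficientResult:
    """Chromatophore coefficient with its per-stage additive contributions."""

    value: float
    per_stage_contributions: tuple[float, float, float, float, float]


def chromatophore_coefficient(counts: StageCounts) -> CoefficientResult:
    """Compute the chromatophore coefficient from stage counts.

    Parameters
    ----------
    counts
        Validated stage counts with ``tc >= 1``.

    Returns
    -------
    CoefficientResult
        ``value`` in [20, 100]; ``per_stage_contributions[k-1]`` is the
        additive term ``(n_k / Tc) * 20 * k``.

    Raises
    ------
    ValueError
        If no chromatophores were graded (``Tc == 0``).
    """
    if counts.tc == 0:
        raise ValueError("no chromatophores graded (Tc = 0); coefficient undefined")
    n = counts.as_array()
    contributions = n / counts.tc * 20.0 * np.array(STAGES, dtype=float)
    value = float(contributions.sum())
    return CoefficientResult(value=value, per_stage_contributions=tuple(float(c) for c in contributions))


def stage_area_bins(
    radius_base: float = DEFAULT_RADIUS_BASE,
    radius_per_stage: float = DEFAULT_RADIUS_PER_STAGE,
) -> np.ndarray:
    """Area bin edges separating consecutive stages for the automated grader.

    A stage-k chromatophore renders as a dark disk of radius
    ``radius_base + radius_per_stage * k`` and hence area ~ pi r_k^2.  The
    four returned edges are the midpoints between consecutive stage areas;
    a component of area A is stage ``1 + #{edges below A}``.
    """
    areas = np.array([math.pi * (radius_base + radius_per_stage * k) ** 2 for k in STAGES])
    return (areas[:-1] + areas[1:]) / 2.0


def grade_chromatophores(
    binary: np.ndarray,
    radius_base: float = DEFAULT_RADIUS_BASE,
    radius_per_stage: float = DEFAULT_RADIUS_PER_STAGE,
    min_area_fraction: float = 0.5,
) -> StageCounts:
    """Grade segmented chromatophores into dispersion stages by area.

    Each connected component (8-connectivity) of the binary mask is assigned
    a stage by comparing its pixel area against :func:`stage_area_bins`.
    Components larger than any single stage-5 disk (touching or merged
    cells) are assigned stage 5 by their combined area and flagged in the
    log; the grader does not attempt to split them.  Components smaller
    than ``min_area_fraction`` of the stage-1 disk area are discarded as
    speckle (no real cell can be that small).

    Parameters
    ----------
    binary
        Boolean (or 0/1) 2-D mask of dark chromatophore pixels.

    Returns
    -------
    StageCounts
        Histogram of component stages.  May have ``tc == 0`` for an empty
        mask; the coefficient computation rejects that downstream.
    """
    binary = np.asarray(binary).astype(bool)
    if binary.ndim != 2:
        raise ValueError(f"binary mask must be 2-D, got shape {binary.shape}")
    edges = stage_area_bins(radius_base, radius_per_stage)
    min_area = min_area_fraction * math.pi * (radius_base + radius_per_stage * STAGES[0]) ** 2
    max_single_area = math.pi * (radius_base + radius_per_stage * STAGES[-1]) ** 2
    labels = measure.label(binary, connectivity=2)
    counts = [0, 0, 0, 0, 0]
    for region in measure.regionprops(labels):
        area = region.area
        if area < min_area:
            continue
        stage = 1 + int(np.searchsorted(edges, area, side="right"))
        if area > 1.3 * max_single_area:
            logger.warning(
                "component of area %d px exceeds any single-cell area; "
                "likely merged cells, graded as stage %d by combined area",
                area,
                stage,
            )
        counts[stage - 1] += 1
    return StageCounts(*counts)
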