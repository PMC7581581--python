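"""Blinding, file formats, run configuration and the end-to-end pipeline.

File conventions
----------------
* Specimen tables are plain CSV with one row per observation and columns
  ``specimen_id, trial, concentration_ng_per_L, exposure_time, background,
  n1..n5, Tc`` (plus any derived columns such as ``coefficient`` and
  ``percent_dark``).
* Images are 8-bit single-channel PNG; ROI masks are binary PNG of
  identical dimensions (0 = outside, 255 = inside).  Pixel coordinates are
  0-based, row-major, origin top-left.
* Ground-truth chromatophore lists are JSON, one file per image.
* Run configuration is JSON or YAML mirroring the CohortDesign /
  EffectModel / RenderParams fields plus quantification and stats options.

Blinding copies (never moves) images under shuffled zero-padded numeric
names so the scorer cannot infer treatment group, and writes the key to a
clearly separated file that must never sit in the analysis input directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import image_quant, scoring, stats, synthetic

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "specimen_id",
    "trial",
    "concentration_ng_per_L",
    "exposure_time",
    "background",
    "n1",
    "n2",
    "n3",
    "n4",
    "n5",
    "Tc",
)
COUNT_COLUMNS = ("n1", "n2", "n3", "n4", "n5", "Tc")


# ---------------------------------------------------------------------------
# Specimen tables
# ---------------------------------------------------------------------------

def validate_specimen_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the specimen-table schema; returns the table with int counts."""
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"specimen table missing required column {col!r}")
    table = table.copy()
    for col in COUNT_COLUMNS:
        values = table[col]
        as_float = pd.to_numeric(values, errors="coerce")
        if as_float.isna().any() or not np.allclose(as_float, np.round(as_float)):
            raise ValueError(f"column {col!r} must contain integer counts")
        if (as_float < 0).any():
            raise ValueError(f"column {col!r} contains negative counts")
        table[col] = as_float.astype(int)
    totals = table[["n1", "n2", "n3", "n4", "n5"]].sum(axis=1)
    if not (totals == table["Tc"]).all():
        bad = table.index[totals != table["Tc"]].tolist()
        raise ValueError(f"Tc does not equal the stage-count sum at rows {bad}")
    return table


def write_specimen_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    validate_specimen_table(table)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_specimen_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"specimen table not found: {path}")
    return validate_specimen_table(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Images, masks, truths
# ---------------------------------------------------------------------------

def write_image(pixels: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.asarray(pixels, dtype=np.uint8))
    return path


def read_image(path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path)))


def write_mask(mask: np.ndarray, path) -> Path:
    return write_image(np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8), path)


def read_mask(path) -> np.ndarray:
    return read_image(path) > 127


def write_truths(truths, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = [
        {
            "center_row": t.center[0],
            "center_col": t.center[1],
            "stage": t.stage,
            "radius": t.radius,
            "intensity_drop": t.intensity_drop,
        }
        for t in truths
    ]
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_truths(path) -> list:
    payload = json.loads(Path(path).read_text())
    return [
        synthetic.ChromatophoreTruth(
            center=(t["center_row"], t["center_col"]),
            stage=t["stage"],
            radius=t["radius"],
            intensity_drop=t["intensity_drop"],
        )
        for t in payload
    ]


def write_bundle(bundle: synthetic.CohortBundle, out_dir) -> Path:
    """Write a generated cohort as a directory bundle (CSV + PNGs + JSON)."""
    out_dir = Path(out_dir)
    write_specimen_table(bundle.table, out_dir / "specimens.csv")
    for obs_id, (pixels, roi) in bundle.images.items():
        write_image(pixels, out_dir / "images" / f"{obs_id}.png")
        write_mask(roi, out_dir / "masks" / f"{obs_id}.png")
    for obs_id, truths in bundle.truths.items():
        write_truths(truths, out_dir / "truths" / f"{obs_id}.json")
    return out_dir


# ---------------------------------------------------------------------------
# Blinding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlindingKey:
    """Bijection from observation ids to shuffled integer labels 1..N."""

    mapping: dict
    seed: int
    created: str

    def label(self, obs_id: str) -> int:
        return self.mapping[obs_id]

    def unblind(self, label: int) -> str:
        inverse = {v: k for k, v in self.mapping.items()}
        return inverse[label]


def make_blinding_key(observation_ids, seed: int) -> BlindingKey:
    """Assign a random permutation of 1..N to the observation ids."""
    ids = list(observation_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("observation ids must be unique")
    labels = np.arange(1, len(ids) + 1)
    np.random.default_rng(seed).shuffle(labels)
    mapping = {obs: int(lab) for obs, lab in zip(ids, labels)}
    return BlindingKey(mapping=mapping, seed=seed, created=datetime.now(timezone.utc).isoformat())


def write_blinding_key(key: BlindingKey, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(
        {"observation_id": list(key.mapping), "blinded_label": list(key.mapping.values())}
    )
    frame.attrs = {}
    with open(path, "w") as fh:
        fh.write(f"# blinding key; seed={key.seed}; created={key.created}\n")
        frame.to_csv(fh, index=False)
    return path


def read_blinding_key(path) -> BlindingKey:
    path = Path(path)
    header = path.read_text().splitlines()[0]
    seed = int(header.split("seed=")[1].split(";")[0])
    created = header.split("created=")[1].strip()
    frame = pd.read_csv(path, comment="#")
    mapping = dict(zip(frame["observation_id"], frame["blinded_label"].astype(int)))
    return BlindingKey(mapping=mapping, seed=seed, created=created)


def blind_images(image_dir, blinded_dir, key_path, seed: int) -> BlindingKey:
    """Copy every image in ``image_dir`` under a blinded numeric name.

    Blinded copies go to ``blinded_dir`` as ``0007.png`` etc.; the key is
    written to ``key_path``, which must lie outside ``blinded_dir`` so the
    scorer never sees it.  Source files are copied, never moved.
    """
    image_dir, blinded_dir, key_path = Path(image_dir), Path(blinded_dir), Path(key_path)
    files = sorted(p for p in image_dir.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff"))
    if not files:
        raise ValueError(f"no images found in {image_dir}")
    if blinded_dir in key_path.parents or key_path.parent == blinded_dir:
        raise ValueError("blinding key must not be written into the blinded image directory")
    key = make_blinding_key([p.stem for p in files], seed)
    width = len(str(len(files)))
    blinded_dir.mkdir(parents=True, exist_ok=True)
    for p in files:
        label = key.label(p.stem)
        shutil.copy2(p, blinded_dir / f"{label:0{width}d}{p.suffix}")
    write_blinding_key(key, key_path)
    logger.info("blinded %d images from %s into %s", len(files), image_dir, blinded_dir)
    return key


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything one end-to-end run needs, loadable from JSON/YAML."""

    out_dir: str = "chromassay_run"
    seed: int = 0
    design: dict = field(default_factory=dict)
    effect_model: dict = field(default_factory=dict)
    render: dict = field(default_factory=dict)
    white_mean_coefficient: float = 45.0
    relative_black_shift: float = 0.20
    median_radius: int = 2
    threshold: float | None = None
    min_contrast: int = image_quant.DEFAULT_MIN_CONTRAST
    alpha: float = stats.ALPHA
    image_dir: str | None = None  # ingest mode: pre-existing images instead of rendering

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        text = path.read_text()
        payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def build_design(self) -> synthetic.CohortDesign:
        payload = dict(self.design)
        payload.setdefault("seed", self.seed)
        for key in ("trials", "concentrations", "exposure_times", "backgrounds"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return synthetic.CohortDesign(**payload)

    def build_effect_model(self) -> synthetic.EffectModel:
        return synthetic.calibrate_effect_model(
            self.white_mean_coefficient, self.relative_black_shift, **self.effect_model
        )

    def build_render_params(self) -> synthetic.RenderParams:
        payload = dict(self.render)
        for key in ("canvas", "roi_center", "roi_semi_axes"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return synthetic.RenderParams(**payload)

    def validate(self) -> None:
        if self.image_dir is not None and not Path(self.image_dir).is_dir():
            raise ValueError(f"image directory does not exist: {self.image_dir}")


# ---------------------------------------------------------------------------
# Derived-column helpers
# ---------------------------------------------------------------------------

def score_table(table: pd.DataFrame) -> pd.DataFrame:
    """Add the chromatophore coefficient column computed from stage counts."""
    table = validate_specimen_table(table)
    coeffs = [
        scoring.chromatophore_coefficient(
            scoring.StageCounts(r.n1, r.n2, r.n3, r.n4, r.n5)
        ).value
        for r in table.itertuples()
    ]
    table["coefficient"] = coeffs
    return table


def quantify_directory(
    image_dir,
    mask_dir,
    median_radius: int = 2,
    threshold: float | None = None,
    min_contrast: int = image_quant.DEFAULT_MIN_CONTRAST,
) -> pd.DataFrame:
    """Run the percent-darkness recipe on every image/mask pair in a directory.

    Masks are matched to images by file stem.  Returns a table with columns
    ``observation_id, threshold_used, percent_dark``.
    """
    image_dir, mask_dir = Path(image_dir), Path(mask_dir)
    rows = []
    for img_path in sorted(image_dir.glob("*.png")):
        mask_path = mask_dir / img_path.name
        if not mask_path.exists():
            raise FileNotFoundError(f"no ROI mask for {img_path.name} in {mask_dir}")
        cover = image_quant.quantify_image(
            read_image(img_path),
            read_mask(mask_path),
            median_radius=median_radius,
            threshold=threshold,
            min_contrast=min_contrast,
        )
        rows.append(
            {
                "observation_id": img_path.stem,
                "threshold_used": cover.threshold_used,
                "percent_dark": cover.percent_dark,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Report serialisation
# ---------------------------------------------------------------------------

def report_to_dict(report: stats.AnalysisReport) -> dict:
    """JSON-serialisable view of an :class:`~chromassay.stats.AnalysisReport`."""
    return {
        "alpha": report.alpha,
        "anovas": {resp: tab.to_dict(orient="records") for resp, tab in report.anovas.items()},
        "posthocs": {
            f"{resp}::{factor}": tab.to_dict(orient="records")
            for (resp, factor), tab in report.posthocs.items()
        },
        "correlations": {
            label: dataclasses.asdict(res) for label, res in report.correlations.items()
        },
        "trial_subsets": {
            f"{resp}::without_trial_{trial}": tab.to_dict(orient="records")
            for (resp, trial), tab in report.trial_subsets.items()
        },
        "background_shift": report.background_shift,
    }


def write_report(report: stats.AnalysisReport, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report_to_dict(report), indent=1, default=str))
    return path


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> stats.AnalysisReport:
    """Full assay pipeline: generate -> blind -> quantify -> score -> analyse.

    Stages, each logged with its parameters:

    1. generate the synthetic cohort (tables + rendered images) from the
       config seed, and write it under ``out_dir/data``;
    2. blind the images into ``out_dir/blinded`` with the key kept apart
       under ``out_dir/blinding``;
    3. run the percent-darkness recipe on the *blinded* copies, then map
       the measurements back to observations through the key;
    4. score the stage counts into chromatophore coefficients;
    5. run the statistical battery and write the scored table and the
       JSON results bundle under ``out_dir/results``.

    Rerunning with the same config is bit-identical at every stage.
    """
    config.validate()
    out = Path(config.out_dir)
    design = config.build_design()
    model = config.build_effect_model()
    render_params = config.build_render_params()
    logger.info("stage generate: %d specimens, seed=%d", design.n_specimens, design.seed)
    bundle = synthetic.generate_cohort(design, model, render_params)
    data_dir = write_bundle(bundle, out / "data")

    logger.info("stage blind: seed=%d", config.seed + 1)
    key = blind_images(
        data_dir / "images",
        out / "blinded" / "images",
        out / "blinding" / "key.csv",
        seed=config.seed + 1,
    )
    # the scorer sees only blinded names; masks are copied alongside under the
    # same blinded labels so quantification itself runs blind too
    width = len(str(len(key.mapping)))
    blinded_masks = out / "blinded" / "masks"
    blinded_masks.mkdir(parents=True, exist_ok=True)
    for obs_id, label in key.mapping.items():
        shutil.copy2(data_dir / "masks" / f"{obs_id}.png", blinded_masks / f"{label:0{width}d}.png")

    logger.info("stage quantify: median_radius=%d threshold=%s", config.median_radius, config.threshold)
    measured = quantify_directory(
        out / "blinded" / "images",
        out / "blinded" / "masks",
        median_radius=config.median_radius,
        threshold=config.threshold,
        min_contrast=config.min_contrast,
    )
    measured["observation_id"] = [key.unblind(int(stem)) for stem in measured["observation_id"]]

    logger.info("stage score: %d observations", len(bundle.table))
    scored = score_table(bundle.table)
    scored = scored.merge(measured, on="observation_id", how="left", validate="1:1")

    logger.info("stage analyze: alpha=%.3f", config.alpha)
    report = stats.analyze_dataset(scored, alpha=config.alpha)
    write_specimen_table(scored, out / "results" / "scored_specimens.csv")
    write_report(report, out / "results" / "results.json")
    logger.info("pipeline complete: results under %s", out / "results")
    return report
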