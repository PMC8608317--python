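"""End-to-end orchestration: scene -> filter -> boundaries -> HVS -> statistics.

A :class:`PipelineConfig` gathers every knob of the chain plus a master
seed; all stochastic steps (subject sampling, response simulation,
presentation order) derive their seeds deterministically from it, so a
fixed config reproduces every output byte for byte.  Renders are cached per
unique scene spec within a run — the factorial design's two repetitions and
all simulated subjects share the same 125 rendered images, as in the
experiment, while the low-vision filtering step is per subject.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .boundaries import detect_luminance_boundaries
from .exceptions import InvalidInputError
from .filtering import FilterConfig, apply_lowvision_filter
from .scene import SceneRender, SceneSpec, enumerate_design, render_scene
from .scoring import ScoringParams, match_visibility
from .stats import bin_trials, fit_logistic, fits_table, simulate_observer
from .vision import CSFTemplate, VisionParams, build_csf

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CannyConfig:
    sigma: float = 1.0
    low_frac: float = 0.1
    high_frac: float = 0.2


@dataclass(frozen=True)
class GroupSpec:
    """A simulated observer group.

    Clinical means/SDs parameterize per-subject sampling; ``true_slope`` /
    ``true_intercept`` / ``guess_floor`` parameterize the response model
    P(correct) = g + (1-g) * logistic(A * HVS + B).  Defaults for the
    moderate and severe groups mirror the blur-goggle conditions
    (moderate: VA 1.2 +- 0.085, CS 0.68; severe: VA 1.62 +- 0.028, CS 0.60,
    inferred from acuity) with group slopes 3.02 and 1.54; the guessing
    floor is chance in the five-alternative task (0.2).
    """

    name: str
    n_subjects: int
    acuity_mean: float
    acuity_sd: float
    cs_mean: float | None
    cs_sd: float
    true_slope: float
    true_intercept: float
    guess_floor: float = 0.2


DEFAULT_GROUPS = (
    GroupSpec("moderate", 7, 1.20, 0.085, 0.68, 0.10, 3.02, -1.5),
    GroupSpec("severe", 7, 1.62, 0.028, None, 0.0, 1.54, -2.0),
)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs, plus the master seed."""

    vision: VisionParams = field(
        default_factory=lambda: VisionParams(acuity=1.2, contrast_sensitivity=0.68)
    )
    csf_template: CSFTemplate = field(default_factory=CSFTemplate)
    filter: FilterConfig = field(default_factory=FilterConfig)
    canny: CannyConfig = field(default_factory=CannyConfig)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    scene: SceneSpec = field(default_factory=SceneSpec)
    groups: tuple = DEFAULT_GROUPS
    roi_label: str = "whole-step"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        for key, klass in (
            ("vision", VisionParams),
            ("csf_template", CSFTemplate),
            ("filter", FilterConfig),
            ("canny", CannyConfig),
            ("scoring", ScoringParams),
        ):
            if key in data and isinstance(data[key], dict):
                data[key] = klass(**data[key])
        if "scene" in data and isinstance(data["scene"], dict):
            scene = dict(data["scene"])
            if "image_size" in scene:
                scene["image_size"] = tuple(scene["image_size"])
            data["scene"] = SceneSpec(**scene)
        if "groups" in data:
            data["groups"] = tuple(
                GroupSpec(**g) if isinstance(g, dict) else g for g in data["groups"]
            )
        return cls(**data)

    def config_hash(self) -> str:
        """Short stable hash of the full configuration, embedded in outputs."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def scene_hvs(
    render: SceneRender, vision: VisionParams, config: PipelineConfig
) -> dict:
    """Filter a rendered scene for one observer and score every ROI.

    Returns a mapping ROI label -> HVS.
    """
    csf = build_csf(vision, config.csf_template)
    filtered = apply_lowvision_filter(render.luminance, csf, config.filter)
    boundaries = detect_luminance_boundaries(
        filtered,
        sigma=config.canny.sigma,
        low_frac=config.canny.low_frac,
        high_frac=config.canny.high_frac,
        reference=render.luminance,
    )
    result = match_visibility(
        render.geometry_edges, boundaries, render.rois, render.luminance.ppd, config.scoring
    )
    return result.hvs


def run_hvs(config: PipelineConfig, scenes=None) -> pd.DataFrame:
    """Score a list of scenes for the configured observer.

    ``scenes`` may be SceneSpec instances, pre-rendered SceneRender objects,
    or None for the 125 unique scenes of the factorial design.  Returns one
    row per scene and ROI: scene id, ROI label, HVS, geometry pixel count,
    and the config hash.
    """
    if scenes is None:
        scenes = sorted(
            {t.spec for t in enumerate_design(config.scene)},
            key=lambda s: (s.target, s.lighting, s.viewpoint),
        )
    chash = config.config_hash()
    rows = []
    for scene in scenes:
        render = scene if isinstance(scene, SceneRender) else render_scene(scene)
        spec = render.spec
        hvs = scene_hvs(render, config.vision, config)
        scene_id = f"{spec.target}|{spec.lighting}|{spec.viewpoint}"
        for label, value in hvs.items():
            n_geom = int(
                np.count_nonzero(render.geometry_edges.mask & render.rois[label].mask)
            )
            rows.append(
                {
                    "scene": scene_id,
                    "target": spec.target,
                    "lighting": spec.lighting,
                    "viewpoint": spec.viewpoint,
                    "roi": label,
                    "hvs": value,
                    "n_geometry_pixels": n_geom,
                    "config_hash": chash,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ValidationReport:
    """Outputs of a simulated validation experiment."""

    trials: pd.DataFrame
    subject_fits: pd.DataFrame
    group_fits: pd.DataFrame
    bins: dict
    config_hash: str


def run_validation_experiment(config: PipelineConfig) -> ValidationReport:
    """Simulate the full validation experiment and fit its statistics.

    Renders the factorial design once, computes per-trial HVS for every
    simulated subject (each subject's clinical parameters drawn around the
    group means), simulates responses through the guessing-floor logistic
    observer, then fits per-subject and pooled accuracy-vs-HVS models and
    tabulates trial counts in 0.1-wide HVS bins per group.
    """
    master = np.random.SeedSequence(config.seed)
    trials_design = enumerate_design(config.scene)
    unique_specs = sorted(
        {t.spec for t in trials_design}, key=lambda s: (s.target, s.lighting, s.viewpoint)
    )
    logger.info("rendering %d unique scenes", len(unique_specs))
    renders = {s: render_scene(s) for s in unique_specs}

    all_trials = []
    subject_fits = {}
    subject_group = {}
    group_frames = {}
    for group, group_seed in zip(config.groups, master.spawn(len(config.groups))):
        subj_seeds = group_seed.spawn(group.n_subjects)
        frames = []
        for i, sseed in enumerate(subj_seeds):
            rng = np.random.default_rng(sseed)
            acuity = float(rng.normal(group.acuity_mean, group.acuity_sd))
            if group.cs_mean is None:
                vision = VisionParams.from_acuity(acuity)
            else:
                cs = max(0.01, float(rng.normal(group.cs_mean, group.cs_sd)))
                vision = VisionParams(acuity=acuity, contrast_sensitivity=cs)
            per_scene = {
                spec: scene_hvs(render, vision, config)[config.roi_label]
                for spec, render in renders.items()
            }
            subject = f"{group.name[0].upper()}{i + 1}"
            x = np.array([per_scene[t.spec] for t in trials_design])
            frame = simulate_observer(
                x,
                group.true_slope,
                group.true_intercept,
                group.guess_floor,
                seed=rng,
                subject=subject,
                group=group.name,
            )
            frame["target"] = [t.spec.target for t in trials_design]
            frame["lighting"] = [t.spec.lighting for t in trials_design]
            frame["viewpoint"] = [t.spec.viewpoint for t in trials_design]
            frame["repetition"] = [t.repetition for t in trials_design]
            frame["acuity"] = vision.acuity
            frame["cs"] = vision.contrast_sensitivity
            frames.append(frame)
            subject_fits[subject] = fit_logistic(frame)
            subject_group[subject] = group.name
        group_frames[group.name] = pd.concat(frames, ignore_index=True)
        all_trials.append(group_frames[group.name])

    trials = pd.concat(all_trials, ignore_index=True)
    group_fits = {}
    bins = {}
    for name, frame in group_frames.items():
        group_fits[name] = fit_logistic(frame)
        bins[name] = bin_trials(frame)
    subj_table = fits_table(subject_fits)
    subj_table.insert(1, "group", subj_table["subject"].map(subject_group))
    group_table = fits_table(group_fits)
    group_table = group_table.rename(columns={"subject": "group"})
    chash = config.config_hash()
    for df in (trials, subj_table, group_table):
        df["config_hash"] = chash
    return ValidationReport(
        trials=trials,
        subject_fits=subj_table,
        group_fits=group_table,
        bins=bins,
        config_hash=chash,
    )


def presentation_order(n_trials: int, seed: int) -> np.ndarray:
    """Randomized presentation order for a trial list (explicit seed)."""
    if n_trials < 1:
        raise InvalidInputError("n_trials must be >= 1")
    return np.random.default_rng(seed).permutation(n_trials)
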