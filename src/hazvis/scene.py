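"""Synthetic walkway/step stimuli with ground-truth geometric edges.

The stimulus family is a 30 ft walkway, 4 ft wide, with one of five targets
ten feet ahead of the viewer: a flat continuation, or a step up or down of
7 inches (big) or 1 inch (small).  Five lighting arrangements and five
viewpoints give the 5 × 5 × 5 factorial design; with two repetitions the
full design has 250 trials.

Scenes are rendered by per-pixel ray casting of the piecewise-planar
walkway model through a pinhole camera, with direct Lambertian shading from
a single (optionally coned) point light plus an ambient term.  This is a
deliberately simplified photometric model: it preserves the structural
contrast relations of the stimulus family (which surfaces are lit, where
the step edges gain or lose contrast across lighting variants) without
global illumination.  Alongside the luminance image the renderer emits the
projected ground-truth geometric edges (depth/orientation discontinuities,
independent of lighting) and named region-of-interest masks derived from
the projected step footprint.

World coordinates are inches: x to the viewer's right, y up, z forward;
the step riser lies at z = target_distance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .boundaries import EdgeMap
from .exceptions import ConfigurationError, InvalidInputError
from .filtering import LuminanceImage

TARGETS = ("flat", "big-step-up", "big-step-down", "small-step-up", "small-step-down")
LIGHTINGS = ("overhead", "far-panel", "near-panel", "spotlight-1", "spotlight-2")
VIEWPOINTS = ("center", "pivot-left", "pivot-right", "rotate-down", "rotate-up")

# surface ids in the rendered id map
SKY, NEAR_FLOOR, SIDE_GROUND, RISER, FAR_FLOOR, BACK_WALL = 0, 1, 2, 3, 4, 5

_REFLECTANCE = {
    SKY: 0.0,
    NEAR_FLOOR: 0.45,
    SIDE_GROUND: 0.18,
    RISER: 0.45,
    FAR_FLOOR: 0.45,
    BACK_WALL: 0.30,
}


def visual_angle(extent: float, distance: float) -> float:
    """Full visual angle (degrees) subtended by a frontal extent.

    Uses the exact full-angle form ``2 * atan(extent / (2 * distance))``.

    Examples
    --------
    A 7-inch step height at 10 ft (120 in) subtends about 3.3°; the 48-inch
    step width subtends about 23°.
    """
    if distance <= 0:
        raise InvalidInputError("distance must be > 0")
    if extent < 0:
        raise InvalidInputError("extent must be >= 0")
    return math.degrees(2.0 * math.atan2(extent / 2.0, distance))


@dataclass(frozen=True)
class SceneSpec:
    """One stimulus: target x lighting x viewpoint plus scene dimensions.

    Dimensions are inches; angles degrees.  Defaults reproduce the stimulus
    family: 30 ft walkway, 4 ft wide, target 10 ft ahead, 7 in / 1 in steps,
    5 ft eye height.
    """

    target: str = "flat"
    lighting: str = "overhead"
    viewpoint: str = "center"
    walkway_length: float = 360.0
    walkway_width: float = 48.0
    big_step: float = 7.0
    small_step: float = 1.0
    target_distance: float = 120.0
    eye_height: float = 60.0
    image_size: tuple[int, int] = (512, 512)
    ppd: float = 20.0
    base_pitch: float = -20.0  # camera pitch needed to frame a target 10 ft ahead
    pivot_angle: float = 15.0  # eye orbit about the target for pivot-left/right
    rotate_angle: float = 5.0  # pitch offset for rotate-down/up
    roi_dilation_deg: float = 0.2
    corner_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise InvalidInputError(f"target must be one of {TARGETS}, got {self.target!r}")
        if self.lighting not in LIGHTINGS:
            raise InvalidInputError(f"lighting must be one of {LIGHTINGS}")
        if self.viewpoint not in VIEWPOINTS:
            raise InvalidInputError(f"viewpoint must be one of {VIEWPOINTS}")
        for name in (
            "walkway_length",
            "walkway_width",
            "big_step",
            "small_step",
            "target_distance",
            "eye_height",
            "ppd",
        ):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")
        if min(self.image_size) < 8:
            raise InvalidInputError("image_size too small")

    @property
    def step_height(self) -> float:
        """Signed step height in inches (positive = up, 0 = flat)."""
        return {
            "flat": 0.0,
            "big-step-up": self.big_step,
            "big-step-down": -self.big_step,
            "small-step-up": self.small_step,
            "small-step-down": -self.small_step,
        }[self.target]


@dataclass(frozen=True)
class ROIMask:
    """A binary region-of-interest mask over the scene grid."""

    mask: np.ndarray
    label: str

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask).astype(bool)
        if mask.ndim != 2:
            raise InvalidInputError("ROI mask must be 2-D")
        object.__setattr__(self, "mask", mask)

    @property
    def n_pixels(self) -> int:
        return int(np.count_nonzero(self.mask))


@dataclass(frozen=True)
class TrialStimulus:
    """One trial of the factorial design: a scene plus a repetition index."""

    spec: SceneSpec
    repetition: int = 1

    def __post_init__(self) -> None:
        if self.repetition not in (1, 2):
            raise InvalidInputError("repetition must be 1 or 2")


@dataclass(frozen=True)
class SceneRender:
    """Rendered scene: luminance, ground-truth edges, ROI masks."""

    luminance: LuminanceImage
    geometry_edges: EdgeMap
    rois: dict
    spec: SceneSpec
    surface_id: np.ndarray = None
    depth: np.ndarray = None


@dataclass(frozen=True)
class _Light:
    position: tuple[float, float, float]
    intensity: float
    ambient: float = 30.0  # ambient illuminance, lux-like
    aim: tuple[float, float, float] | None = None  # spotlight target point
    cone_cos: float = 0.85  # cos of the cone half-angle (spotlights)


def _light_for(spec: SceneSpec) -> _Light:
    z0 = spec.target_distance
    return {
        "overhead": _Light((0.0, 108.0, z0), 2.2e7),
        "far-panel": _Light((0.0, 80.0, z0 + 180.0), 2.2e7),
        "near-panel": _Light((0.0, 80.0, 20.0), 1.8e7),
        "spotlight-1": _Light((-50.0, 45.0, 40.0), 2.5e7, aim=(0.0, 0.0, z0)),
        "spotlight-2": _Light((55.0, 50.0, z0 + 90.0), 2.5e7, aim=(0.0, 0.0, z0)),
    }[spec.lighting]


def _camera_pose(spec: SceneSpec) -> tuple[np.ndarray, float, float]:
    """Eye position, yaw (deg, about world y) and pitch (deg) for a viewpoint."""
    z0 = spec.target_distance
    eye = np.array([0.0, spec.eye_height, 0.0])
    yaw = 0.0
    pitch = spec.base_pitch
    if spec.viewpoint in ("pivot-left", "pivot-right"):
        a = math.radians(spec.pivot_angle)
        if spec.viewpoint == "pivot-right":
            a = -a
        # orbit the eye about the vertical axis through the target center,
        # keeping the camera aimed at the step
        eye = np.array([-z0 * math.sin(a), spec.eye_height, z0 - z0 * math.cos(a)])
        yaw = math.degrees(a)
    elif spec.viewpoint == "rotate-down":
        pitch -= spec.rotate_angle
    elif spec.viewpoint == "rotate-up":
        pitch += spec.rotate_angle
    return eye, yaw, pitch


def _rotation(yaw_deg: float, pitch_deg: float) -> np.ndarray:
    """Camera-to-world rotation: pitch about camera x, then yaw about y."""
    cy, sy = math.cos(math.radians(yaw_deg)), math.sin(math.radians(yaw_deg))
    cp, sp = math.cos(math.radians(pitch_deg)), math.sin(math.radians(pitch_deg))
    ry = np.array([[cy, 0.0, sy], [0.0, 1.0, 0.0], [-sy, 0.0, cy]])
    rx = np.array([[1.0, 0.0, 0.0], [0.0, cp, sp], [0.0, -sp, cp]])
    return ry @ rx


def _focal_px(ppd: float) -> float:
    """Pinhole focal length in pixels giving ``ppd`` pixels/degree on-axis."""
    return ppd * 180.0 / math.pi


def project_points(points: np.ndarray, spec: SceneSpec) -> np.ndarray:
    """Project world points (N, 3) to (row, col) pixel coordinates (N, 2).

    Points behind the camera get NaN coordinates.
    """
    eye, yaw, pitch = _camera_pose(spec)
    rot = _rotation(yaw, pitch)
    v = (np.atleast_2d(points) - eye) @ rot  # world -> camera
    h, w = spec.image_size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    f = _focal_px(spec.ppd)
    with np.errstate(divide="ignore", invalid="ignore"):
        col = cx + f * v[:, 0] / v[:, 2]
        row = cy - f * v[:, 1] / v[:, 2]
    bad = v[:, 2] <= 0
    row[bad] = np.nan
    col[bad] = np.nan
    return np.stack([row, col], axis=1)


def _ray_directions(spec: SceneSpec) -> np.ndarray:
    h, w = spec.image_size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    f = _focal_px(spec.ppd)
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    d = np.stack(
        [(cols - cx) / f, -(rows - cy) / f, np.ones((h, w))],
        axis=-1,
    )
    eye, yaw, pitch = _camera_pose(spec)
    d = d @ _rotation(yaw, pitch).T
    return d / np.linalg.norm(d, axis=-1, keepdims=True)


def _cast_rays(spec: SceneSpec):
    """Intersect all pixel rays with the walkway model.

    Returns (surface_id, depth, hit point, normal) grids.
    """
    eye, _, _ = _camera_pose(spec)
    d = _ray_directions(spec)
    h_img, w_img = spec.image_size
    half = spec.walkway_width / 2.0
    z_step = spec.target_distance
    z_end = spec.walkway_length
    step = spec.step_height

    t_best = np.full((h_img, w_img), np.inf)
    sid = np.full((h_img, w_img), SKY, dtype=np.int8)
    normal = np.zeros((h_img, w_img, 3))

    def consider(t, valid, surface, n_vec):
        hit = valid & (t > 1e-6) & (t < t_best)
        t_best[hit] = t[hit]
        sid[hit] = surface
        normal[hit] = n_vec

    dx, dy, dz = d[..., 0], d[..., 1], d[..., 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        # ground plane y = 0: near walkway, side ground, far walkway if flat
        t = (0.0 - eye[1]) / dy
        px = eye[0] + t * dx
        pz = eye[2] + t * dz
        on_plane = (dy < 0) & (pz >= 0) & (pz <= z_end)
        near = on_plane & (np.abs(px) <= half) & (pz <= z_step)
        side = on_plane & (np.abs(px) > half)
        consider(t, near, NEAR_FLOOR, (0.0, 1.0, 0.0))
        consider(t, side, SIDE_GROUND, (0.0, 1.0, 0.0))
        if step == 0.0:
            far_flat = on_plane & (np.abs(px) <= half) & (pz > z_step)
            consider(t, far_flat, NEAR_FLOOR, (0.0, 1.0, 0.0))
        else:
            # far walkway floor at y = step
            t2 = (step - eye[1]) / dy
            px2 = eye[0] + t2 * dx
            pz2 = eye[2] + t2 * dz
            far = (dy < 0) & (np.abs(px2) <= half) & (pz2 >= z_step) & (pz2 <= z_end)
            consider(t2, far, FAR_FLOOR, (0.0, 1.0, 0.0))
        if step > 0.0:
            # riser face at z = z_step, facing the viewer
            t3 = (z_step - eye[2]) / dz
            px3 = eye[0] + t3 * dx
            py3 = eye[1] + t3 * dy
            riser = (dz > 0) & (np.abs(px3) <= half) & (py3 >= 0) & (py3 <= step)
            consider(t3, riser, RISER, (0.0, 0.0, -1.0))
        # back wall at z = walkway_length
        t4 = (z_end - eye[2]) / dz
        py4 = eye[1] + t4 * dy
        wall = (dz > 0) & (py4 >= min(0.0, step) - 1e-9)
        consider(t4, wall, BACK_WALL, (0.0, 0.0, -1.0))

    point = eye + t_best[..., None] * d
    point[~np.isfinite(t_best)] = np.nan
    return sid, t_best, point, normal


def _shade(sid, point, normal, light: _Light) -> np.ndarray:
    """Direct Lambertian luminance (cd/m²) under one point light + ambient."""
    rho = np.zeros(sid.shape)
    for s, r in _REFLECTANCE.items():
        rho[sid == s] = r
    lpos = np.asarray(light.position)
    to_light = lpos - point
    r2 = np.sum(to_light**2, axis=-1)
    r2 = np.maximum(r2, 1e-6)
    ldir = to_light / np.sqrt(r2)[..., None]
    cos_inc = np.sum(ldir * normal, axis=-1)
    cos_inc = np.clip(cos_inc, 0.0, None)
    illuminance = light.intensity * cos_inc / r2
    if light.aim is not None:
        aim_dir = np.asarray(light.aim) - lpos
        aim_dir = aim_dir / np.linalg.norm(aim_dir)
        cos_spot = np.sum(-ldir * aim_dir, axis=-1)
        cone = np.clip((cos_spot - light.cone_cos) / (1.0 - light.cone_cos), 0.0, 1.0)
        illuminance = illuminance * cone
    lum = rho * (illuminance + light.ambient) / math.pi
    lum[sid == SKY] = 1.0  # dim featureless background
    return np.nan_to_num(lum, nan=1.0, posinf=0.0, neginf=0.0)


def _geometry_edges_from_ids(sid: np.ndarray, depth: np.ndarray) -> np.ndarray:
    """1-pixel edges where the surface id changes, marked on the nearer side."""
    edges = np.zeros(sid.shape, dtype=bool)
    # horizontal neighbours
    diff = sid[:, :-1] != sid[:, 1:]
    left_nearer = depth[:, :-1] <= depth[:, 1:]
    edges[:, :-1] |= diff & left_nearer
    edges[:, 1:] |= diff & ~left_nearer
    # vertical neighbours
    diff = sid[:-1, :] != sid[1:, :]
    top_nearer = depth[:-1, :] <= depth[1:, :]
    edges[:-1, :] |= diff & top_nearer
    edges[1:, :] |= diff & ~top_nearer
    edges[sid == SKY] = False
    return edges


def _step_edge_mask(sid: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Geometry-edge pixels that belong to the step discontinuity."""
    near_riser = ndi.binary_dilation(np.isin(sid, (RISER,)), iterations=1)
    near_far = ndi.binary_dilation(sid == FAR_FLOOR, iterations=1)
    near_near = ndi.binary_dilation(sid == NEAR_FLOOR, iterations=1)
    step_up = edges & near_riser
    step_down = edges & near_far & near_near  # near/far floor adjacency
    return step_up | step_down


def _rasterize_step_line(spec: SceneSpec) -> np.ndarray:
    """Pixels of the projected step line (used when no step discontinuity
    exists, i.e. the flat target)."""
    half = spec.walkway_width / 2.0
    xs = np.linspace(-half, half, 4 * max(spec.image_size))
    pts = np.stack([xs, np.zeros_like(xs), np.full_like(xs, spec.target_distance)], axis=1)
    rc = project_points(pts, spec)
    mask = np.zeros(spec.image_size, dtype=bool)
    ok = np.isfinite(rc).all(axis=1)
    rows = np.round(rc[ok, 0]).astype(int)
    cols = np.round(rc[ok, 1]).astype(int)
    inb = (rows >= 0) & (rows < spec.image_size[0]) & (cols >= 0) & (cols < spec.image_size[1])
    mask[rows[inb], cols[inb]] = True
    return mask


def _dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    if radius <= 0 or not mask.any():
        return mask.copy()
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    structure = (yy**2 + xx**2) <= radius**2
    return ndi.binary_dilation(mask, structure=structure)


def _build_rois(spec: SceneSpec, sid, point, edges) -> dict:
    """Named ROI masks from the projected step footprint.

    ``whole-step``: the dilated step discontinuity (or, for the flat target,
    the dilated projected line where the step would be — so every trial of
    the design has a scoreable region).  ``corners``: the outer
    ``corner_fraction`` of the step width per side; ``central-edge``: the
    rest.  ``walkway``: all geometry edges, dilated.
    """
    radius = max(1, int(round(spec.roi_dilation_deg * spec.ppd)))
    step_pixels = _step_edge_mask(sid, edges)
    if not step_pixels.any():
        step_pixels = _rasterize_step_line(spec)
    half = spec.walkway_width / 2.0
    frac = np.clip((point[..., 0] + half) / spec.walkway_width, 0.0, 1.0)
    frac = np.nan_to_num(frac, nan=0.5)
    corner = step_pixels & ((frac <= spec.corner_fraction) | (frac >= 1 - spec.corner_fraction))
    central = step_pixels & ~corner
    return {
        "whole-step": ROIMask(_dilate(step_pixels, radius), "whole-step"),
        "corners": ROIMask(_dilate(corner, radius), "corners"),
        "central-edge": ROIMask(_dilate(central, radius), "central-edge"),
        "walkway": ROIMask(_dilate(edges, radius), "walkway"),
    }


def render_scene(spec: SceneSpec) -> SceneRender:
    """Render one stimulus: luminance, geometric edges, and ROI masks.

    Raises a configuration error if the target's projected location falls
    outside the field of view.
    """
    target_pt = np.array([[0.0, max(spec.step_height, 0.0) / 2.0, spec.target_distance]])
    rc = project_points(target_pt, spec)[0]
    h, w = spec.image_size
    if not (np.isfinite(rc).all() and 0 <= rc[0] < h and 0 <= rc[1] < w):
        raise ConfigurationError(
            f"target projects to {tuple(np.round(rc, 1))}, outside the {spec.image_size} image"
        )
    sid, depth, point, normal = _cast_rays(spec)
    lum = _shade(sid, point, normal, _light_for(spec))
    edges = _geometry_edges_from_ids(sid, depth)
    rois = _build_rois(spec, sid, point, edges)
    luminance = LuminanceImage(lum, spec.ppd, "synthetic")
    geometry = EdgeMap(
        edges,
        "geometry",
        {"target": spec.target, "viewpoint": spec.viewpoint},
    )
    return SceneRender(
        luminance=luminance,
        geometry_edges=geometry,
        rois=rois,
        spec=spec,
        surface_id=sid,
        depth=depth,
    )


def step_geometry_mask(render: SceneRender) -> np.ndarray:
    """Step-discontinuity geometry pixels of a render (empty for flat)."""
    return _step_edge_mask(render.surface_id, render.geometry_edges.mask)


def enumerate_design(
    base: SceneSpec | None = None,
    targets: tuple = TARGETS,
    lightings: tuple = LIGHTINGS,
    viewpoints: tuple = VIEWPOINTS,
    n_reps: int = 2,
) -> list[TrialStimulus]:
    """Full factorial crossing of target x lighting x viewpoint x repetition.

    Deterministic ordering (targets outermost, repetitions innermost);
    presentation-order randomization is applied downstream with an explicit
    seed.  Defaults give the 5*5*5*2 = 250-trial design.
    """
    if n_reps < 1:
        raise InvalidInputError("n_reps must be >= 1")
    base = base or SceneSpec()
    trials = []
    for tgt, light, view in itertools.product(targets, lightings, viewpoints):
        spec = replace(base, target=tgt, lighting=light, viewpoint=view)
        for rep in range(1, n_reps + 1):
            trials.append(TrialStimulus(spec=spec, repetition=rep))
    return trials
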