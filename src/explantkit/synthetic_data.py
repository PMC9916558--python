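"""Ground-truthed synthetic data: explant micrographs, DAB sections, tables.

Three generators emulate the three data modalities of an explant outgrowth
study so that every downstream stage is testable without microscopy data:

* :func:`generate_explant_image` draws a two-channel 16-bit micrograph
  (nuclear + neuronal-marker channel) of an explant body with radiating,
  branching neurites, and returns the exact geometry as ground truth;
* :func:`generate_section_image` draws an RGB brightfield section with a
  controllable DAB-positive area fraction and mean stain intensity;
* :func:`generate_study_table` draws explant-level outcome tables whose
  group medians, litter structure and outcome correlations emulate the
  statistical shape of a real study (log-normal outcomes, medians as the
  location parameter, zero-effect covariates).

Every generator is a pure function of its spec (which includes the seed):
the same spec yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.draw import polygon2mask
from skimage.morphology import dilation, disk

from ._color import ir_to_rgb, pixel_ir
from .records import TURNS, ExplantRecord

__all__ = [
    "BodySpec",
    "DirectionSpec",
    "ExplantImageSpec",
    "OutgrowthGroundTruth",
    "SectionImageSpec",
    "StudyGroup",
    "StudySpec",
    "generate_outgrowth_geometry",
    "generate_explant_image",
    "generate_section_image",
    "generate_study_table",
    "dissect_ear",
]


# ---------------------------------------------------------------------------
# explant image


@dataclass(frozen=True)
class BodySpec:
    """Explant body shape: an ellipse or a wedge (annular sector), placed at
    the image center. The area is given in µm²; a freshly cut explant is a
    few hundred µm across."""

    kind: str = "ellipse"  # ellipse | wedge
    area_um2: float = 40_000.0
    aspect: float = 1.6  # ellipse: major/minor axis ratio
    wedge_span_deg: float = 120.0
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("ellipse", "wedge"):
            raise ValueError("body kind must be 'ellipse' or 'wedge'")
        if self.area_um2 <= 0:
            raise ValueError("body area must be > 0")


@dataclass(frozen=True)
class DirectionSpec:
    """Distribution of neurite growth bearings (0° = image up, clockwise).

    ``uniform`` draws bearings uniformly on [0°, 360°); ``von_mises``
    concentrates them around ``mu_deg`` with concentration ``kappa``;
    ``spaced`` places start points at near-regular angular spacing (small
    jitter), which keeps neurites well separated for ground-truth work.
    """

    kind: str = "uniform"  # uniform | von_mises | spaced
    mu_deg: float = 0.0
    kappa: float = 2.0
    spacing_jitter_deg: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "von_mises", "spaced"):
            raise ValueError("direction kind must be uniform, von_mises or spaced")


@dataclass(frozen=True)
class ExplantImageSpec:
    image_shape: tuple[int, int] = (2048, 2048)
    pixel_size_um: float = 0.5
    body: BodySpec = field(default_factory=BodySpec)
    n_start_points: int = 12
    neurites_per_start: tuple[int, int] = (2, 5)  # inclusive uniform range
    branch_probability: float = 0.15  # per 50 µm of growth
    length_median_um: float = 316.0
    length_sigma: float = 0.45  # log-scale sd
    direction: DirectionSpec = field(default_factory=DirectionSpec)
    step_um: float = 5.0
    heading_jitter_deg: float = 4.0  # per growth step
    branch_angle_deg: tuple[float, float] = (20.0, 45.0)
    neurite_width_px: int = 3
    signal_level: int = 20000
    background_level: int = 1000
    noise_sd: float = 200.0
    poisson_noise: bool = False
    fasciculation: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.n_start_points < 0:
            raise ValueError("n_start_points must be >= 0")
        if not 0.0 <= self.branch_probability <= 1.0:
            raise ValueError("branch_probability must be in [0, 1]")
        if self.length_median_um <= 0:
            raise ValueError("length_median_um must be > 0")
        if self.neurites_per_start[0] < 1 or self.neurites_per_start[1] < self.neurites_per_start[0]:
            raise ValueError("neurites_per_start must be an increasing range with low >= 1")


@dataclass
class OutgrowthGroundTruth:
    """Exact geometry of one synthetic explant, in pixel coordinates
    (row, col), plus per-ending root-to-tip lengths in µm."""

    body_polygon: np.ndarray
    start_points: np.ndarray  # (s, 2)
    neurite_paths: list[np.ndarray]  # polylines; shared trunks appear once
    endings: np.ndarray  # (e, 2)
    branch_points: np.ndarray  # (b, 2)
    lengths_um: np.ndarray  # (e,)
    total_length_um: float
    pixel_size_um: float
    body_mask: Optional[np.ndarray] = None
    neurite_mask: Optional[np.ndarray] = None

    @property
    def n_endings(self) -> int:
        return len(self.endings)


def _bearing_to_dir(bearing_deg: np.ndarray | float) -> np.ndarray:
    """Unit (row, col) step for an image bearing (0° up, clockwise)."""
    rad = np.radians(bearing_deg)
    return np.stack([-np.cos(rad), np.sin(rad)], axis=-1)


def _body_polygon(spec: ExplantImageSpec) -> np.ndarray:
    h, w = spec.image_shape
    center = np.array([h / 2.0, w / 2.0])
    area_px = spec.body.area_um2 / spec.pixel_size_um**2
    rot = np.radians(spec.body.rotation_deg)
    if spec.body.kind == "ellipse":
        b = np.sqrt(area_px / (np.pi * spec.body.aspect))
        a = spec.body.aspect * b
        t = np.linspace(0.0, 2.0 * np.pi, 181)[:-1]
        rr = a * np.cos(t)
        cc = b * np.sin(t)
    else:  # wedge: annular sector, outer radius 2x inner
        span = np.radians(spec.body.wedge_span_deg)
        r_in = np.sqrt(2.0 * area_px / (3.0 * span))
        r_out = 2.0 * r_in
        t = np.linspace(-span / 2.0, span / 2.0, 90)
        rr = np.concatenate([r_out * np.cos(t), r_in * np.cos(t[::-1])])
        cc = np.concatenate([r_out * np.sin(t), r_in * np.sin(t[::-1])])
    rr_rot = rr * np.cos(rot) - cc * np.sin(rot)
    cc_rot = rr * np.sin(rot) + cc * np.cos(rot)
    poly = center + np.stack([rr_rot, cc_rot], axis=1)
    if poly.min() < 0 or poly[:, 0].max() >= h or poly[:, 1].max() >= w:
        raise ValueError(
            "body polygon exceeds image bounds; enlarge image_shape or shrink body area"
        )
    return poly


def _boundary_point(poly: np.ndarray, center: np.ndarray, bearing_deg: float) -> np.ndarray:
    """Intersection of the ray from the centroid at ``bearing_deg`` with the
    body outline (nearest outline vertex by bearing)."""
    rel = poly - center
    ang = np.degrees(np.arctan2(rel[:, 1], -rel[:, 0])) % 360.0
    diff = np.abs((ang - bearing_deg + 180.0) % 360.0 - 180.0)
    return poly[np.argmin(diff)]


def _start_bearings(spec: ExplantImageSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_start_points
    d = spec.direction
    if n == 0:
        return np.empty(0)
    if d.kind == "uniform":
        return rng.uniform(0.0, 360.0, size=n)
    if d.kind == "von_mises":
        return (d.mu_deg + np.degrees(rng.vonmises(0.0, d.kappa, size=n))) % 360.0
    base = np.linspace(0.0, 360.0, n, endpoint=False)
    return (base + rng.uniform(0.0, 360.0 / n) + rng.normal(0.0, d.spacing_jitter_deg, n)) % 360.0


def _draw_length(spec: ExplantImageSpec, rng: np.random.Generator) -> float:
    return float(np.exp(rng.normal(np.log(spec.length_median_um), spec.length_sigma)))


def generate_outgrowth_geometry(spec: ExplantImageSpec) -> OutgrowthGroundTruth:
    """Grow the neurite geometry without rasterizing it.

    Neurites are polylines grown from body-boundary start points in steps
    of ``step_um`` with per-step Gaussian heading jitter. The root-to-tip
    target length of each terminal path is drawn from the log-normal
    length distribution; a branch event (Bernoulli per step, probability
    ``branch_probability`` per 50 µm of growth) spawns a child path whose
    root-to-tip length is drawn afresh (kept only if it exceeds the length
    already grown). Growth stops at the image margin, in which case the
    realized (shorter) length enters the ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    center = np.array([h / 2.0, w / 2.0])
    poly = _body_polygon(spec)
    margin = 4.0

    step_px = spec.step_um / spec.pixel_size_um
    paths: list[np.ndarray] = []
    path_lengths_um: list[float] = []
    endings: list[np.ndarray] = []
    lengths: list[float] = []
    branch_pts: list[np.ndarray] = []
    starts: list[np.ndarray] = []

    bearings = _start_bearings(spec, rng)
    for bearing in bearings:
        p0 = _boundary_point(poly, center, bearing)
        starts.append(p0)
        k = int(rng.integers(spec.neurites_per_start[0], spec.neurites_per_start[1] + 1))
        base_point, base_dist = p0, 0.0
        if spec.fasciculation and k > 1:
            # shared trunk: siblings branch off a common initial segment
            trunk_target = float(rng.uniform(20.0, 60.0))
            pts, grown, _ = _grow_path(
                spec, rng, p0, bearing, trunk_target, step_px, (h, w), margin
            )
            if grown > 0:
                paths.append(pts)
                path_lengths_um.append(grown)
                base_point, base_dist = pts[-1], grown
                branch_pts.append(pts[-1])
        # stack of (point, heading, base_dist, remaining_target, depth)
        stack = []
        for _ in range(k):
            heading = bearing + rng.normal(0.0, 10.0)
            target = max(5.0, _draw_length(spec, rng) - base_dist)
            stack.append((base_point, heading, base_dist, target, 0))
        while stack:
            pt, heading, base, target, depth = stack.pop()
            pts, grown, events = _grow_path(
                spec, rng, pt, heading, target, step_px, (h, w), margin, rng_branch=depth < 3
            )
            if grown <= 0:
                continue
            paths.append(pts)
            path_lengths_um.append(grown)
            endings.append(pts[-1])
            lengths.append(base + grown)
            for frac_dist, b_pt, b_heading in events:
                child_total = _draw_length(spec, rng)
                child_base = base + frac_dist
                if child_total - child_base < 10.0:
                    continue
                branch_pts.append(b_pt)
                stack.append((b_pt, b_heading, child_base, child_total - child_base, depth + 1))

    def _arr(lst, width=2):
        return np.array(lst, dtype=float).reshape(-1, width)

    return OutgrowthGroundTruth(
        body_polygon=poly,
        start_points=_arr(starts),
        neurite_paths=paths,
        endings=_arr(endings),
        branch_points=_arr(branch_pts),
        lengths_um=np.array(lengths, dtype=float),
        total_length_um=float(np.sum(path_lengths_um)),
        pixel_size_um=spec.pixel_size_um,
    )


def _grow_path(
    spec: ExplantImageSpec,
    rng: np.random.Generator,
    p0: np.ndarray,
    heading: float,
    target_um: float,
    step_px: float,
    shape: tuple[int, int],
    margin: float,
    rng_branch: bool = True,
):
    """Grow one polyline; returns (points, grown_um, branch_events) with
    branch events as (distance_from_path_root_um, point, child_heading)."""
    h, w = shape
    pts = [np.asarray(p0, dtype=float)]
    grown = 0.0
    events = []
    p_branch_per_step = spec.branch_probability * spec.step_um / 50.0
    p = np.asarray(p0, dtype=float)
    while grown < target_um - 1e-9:
        step_um = min(spec.step_um, target_um - grown)
        heading = heading + rng.normal(0.0, spec.heading_jitter_deg)
        p = p + _bearing_to_dir(heading) * step_um / spec.pixel_size_um
        if not (margin <= p[0] < h - margin and margin <= p[1] < w - margin):
            break
        pts.append(p)
        grown += step_um
        if rng_branch and spec.branch_probability > 0 and rng.random() < p_branch_per_step:
            delta = rng.uniform(*spec.branch_angle_deg) * rng.choice([-1.0, 1.0])
            events.append((grown, p.copy(), heading + delta))
    if len(pts) < 2:
        return np.empty((0, 2)), 0.0, []
    return np.array(pts), grown, events


def rasterize_paths(
    paths: list[np.ndarray], shape: tuple[int, int], width_px: int
) -> np.ndarray:
    """Binary raster of polylines at the given stroke width."""
    lines = np.zeros(shape, dtype=bool)
    h, w = shape
    for pts in paths:
        ij = np.clip(np.rint(pts).astype(int), [0, 0], [h - 1, w - 1])
        for (r0, c0), (r1, c1) in zip(ij[:-1], ij[1:]):
            rr, cc = draw_line(r0, c0, r1, c1)
            lines[rr, cc] = True
    if width_px > 1:
        lines = dilation(lines, disk(width_px // 2))
    return lines


def generate_explant_image(
    spec: ExplantImageSpec,
) -> tuple[np.ndarray, OutgrowthGroundTruth]:
    """Render a two-channel 16-bit explant micrograph plus ground truth.

    Channel 0 emulates the nuclear stain (speckled nuclei inside the
    body), channel 1 the neuronal marker (body plus neurites). The ground
    truth carries the rasterized body and neurite masks alongside the
    vector geometry.
    """
    gt = generate_outgrowth_geometry(spec)
    rng = np.random.default_rng(spec.seed + 1)  # rendering noise stream
    h, w = spec.image_shape

    body_mask = polygon2mask((h, w), gt.body_polygon)
    neurite_mask = rasterize_paths(gt.neurite_paths, (h, w), spec.neurite_width_px)

    tuj = np.full((h, w), float(spec.background_level))
    tuj[body_mask | neurite_mask] = float(spec.signal_level)

    dapi = np.full((h, w), float(spec.background_level))
    body_px = int(body_mask.sum())
    n_nuclei = max(1, body_px // 150)
    rows, cols = np.nonzero(body_mask)
    if len(rows):
        pick = rng.integers(0, len(rows), size=n_nuclei)
        radii = rng.integers(2, 5, size=n_nuclei)
        for idx, rad in zip(pick, radii):
            rr, cc = draw_disk((rows[idx], cols[idx]), rad, shape=(h, w))
            dapi[rr, cc] = float(spec.signal_level)

    img = np.stack([dapi, tuj])
    if spec.poisson_noise:
        img = rng.poisson(img).astype(float)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0, 65535).astype(np.uint16)

    gt.body_mask = body_mask
    gt.neurite_mask = neurite_mask
    return img, gt


# ---------------------------------------------------------------------------
# DAB section image


@dataclass(frozen=True)
class SectionImageSpec:
    image_shape: tuple[int, int] = (512, 512)
    roi_polygon: Optional[np.ndarray] = None  # default: centered rectangle
    exclusion_polygons: tuple[np.ndarray, ...] = ()
    positive_fraction: float = 0.3
    target_ir: float = 148.0
    background_shade: tuple[int, int, int] = (245, 243, 240)
    stain_shade_jitter: float = 6.0
    blob_scale_px: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in [0, 1]")
        if not 0.0 <= self.target_ir <= 255.0:
            raise ValueError("target_ir must be in [0, 255]")

    def roi(self) -> np.ndarray:
        if self.roi_polygon is not None:
            return np.asarray(self.roi_polygon, dtype=float)
        h, w = self.image_shape
        return np.array(
            [[h * 0.15, w * 0.15], [h * 0.15, w * 0.85], [h * 0.85, w * 0.85], [h * 0.85, w * 0.15]]
        )


def generate_section_image(
    spec: SectionImageSpec,
) -> tuple[np.ndarray, np.ndarray, Optional[float]]:
    """Render an RGB DAB section; returns (rgb, positive mask, realized IR).

    Positive pixels form smooth blobs covering ``positive_fraction`` of
    the ROI (threshold of a Gaussian random field at the matching
    quantile) and are painted in the brown shade whose IR equals
    ``target_ir``, with per-pixel Gaussian shade jitter. The realized mean
    IR is recomputed from the emitted image and mask; with an empty mask
    it is None.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    roi_mask = polygon2mask((h, w), spec.roi())
    for poly in spec.exclusion_polygons:
        roi_mask &= ~polygon2mask((h, w), np.asarray(poly, dtype=float))
    n_roi = int(roi_mask.sum())
    if n_roi == 0 and spec.positive_fraction > 0:
        raise ValueError("positive_fraction > 0 requires a nonempty ROI")

    mask = np.zeros((h, w), dtype=bool)
    if spec.positive_fraction > 0 and n_roi:
        field = gaussian_filter(rng.standard_normal((h, w)), spec.blob_scale_px)
        vals = field[roi_mask]
        thr = np.quantile(vals, 1.0 - spec.positive_fraction)
        mask = roi_mask & (field >= thr)

    rgb = np.empty((h, w, 3), dtype=float)
    rgb[:] = np.asarray(spec.background_shade, dtype=float)
    if mask.any():
        color = ir_to_rgb(spec.target_ir)
        stained = np.tile(color, (int(mask.sum()), 1))
        if spec.stain_shade_jitter > 0:
            stained = stained + rng.normal(0.0, spec.stain_shade_jitter, stained.shape)
        rgb[mask] = stained
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    realized = float(pixel_ir(rgb[mask].astype(float)).mean()) if mask.any() else None
    return rgb, mask, realized


# ---------------------------------------------------------------------------
# study tables


@dataclass(frozen=True)
class StudyGroup:
    treatment: str
    turn: str
    n: int
    median_endings: float
    median_length_um: float
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.turn not in TURNS:
            raise ValueError(f"turn must be one of {TURNS}")
        if self.n < 1:
            raise ValueError("group n must be >= 1")
        if self.median_endings <= 0 or self.median_length_um <= 0:
            raise ValueError("group medians must be > 0")


@dataclass(frozen=True)
class StudySpec:
    """Design of a synthetic explant study.

    Outcomes are log-normal with the group median as location parameter.
    A latent per-explant "vigor" couples the number of endings and the
    median length (rank correlation ~0.7 at the defaults, matching the
    correlation structure of real outgrowth data); total length and
    branch-point counts are derived from the endings count and are hence
    almost perfectly correlated with it. Litter effects are shared
    log-scale shifts within a litter; plate effects (for in-plate-control
    designs) are shared within a plate. Covariates (sex, side, age,
    weight) are generated with zero effect on outcomes.
    """

    groups: tuple[StudyGroup, ...]
    endings_sigma: float = 0.55
    length_sigma: float = 0.35
    outcome_corr: float = 0.7
    litter_sd: float = 0.12
    explants_per_litter: int = 36
    plate_sd: float = 0.0
    wells_per_plate: int = 24
    design: str = "nt"  # nt | es
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [(g.treatment, g.turn) for g in self.groups]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate (treatment, turn) group labels")
        if self.design not in ("nt", "es"):
            raise ValueError("design must be 'nt' or 'es'")


def generate_study_table(spec: StudySpec) -> pd.DataFrame:
    """Draw one explant-level table (one row per explant).

    Litters are assigned by a random permutation over all records, so each
    group samples from the shared litter pool (as in the real design, where
    one mouse contributes explants to many wells). For the 'es' design,
    plates host equal numbers of unstimulated-control and stimulated wells
    (half the plate each) and a shared per-plate log-effect of sd
    ``plate_sd`` multiplies all outcomes on the plate — the variance
    component that in-plate normalization exists to remove.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = sum(g.n for g in spec.groups)
    half = max(1, spec.wells_per_plate // 2)

    # litter pool shared across groups
    litter_of = rng.permutation(n_total) // spec.explants_per_litter
    n_litters = int(litter_of.max()) + 1 if n_total else 0
    litter_effects = rng.normal(0.0, spec.litter_sd, size=max(n_litters, 1))

    # expand group membership, then assign plates/wells
    membership = [g for g in spec.groups for _ in range(g.n)]
    plates = np.empty(n_total, dtype=int)
    wells = np.empty(n_total, dtype=int)
    if spec.design == "es":
        is_ctrl = np.array([g.is_control for g in membership])
        for flag, offset in ((True, 0), (False, half)):
            pos = np.flatnonzero(is_ctrl == flag)
            plates[pos] = np.arange(len(pos)) // half
            wells[pos] = offset + np.arange(len(pos)) % half
    else:
        plates[:] = np.arange(n_total) // spec.wells_per_plate
        wells[:] = np.arange(n_total) % spec.wells_per_plate
    n_plates = int(plates.max()) + 1 if n_total else 0
    plate_effects = (
        rng.normal(0.0, spec.plate_sd, size=max(n_plates, 1))
        if spec.plate_sd
        else np.zeros(max(n_plates, 1))
    )

    rho = spec.outcome_corr
    rows = []
    for idx, group in enumerate(membership):
        u_lit = litter_effects[litter_of[idx]]
        u_plate = plate_effects[plates[idx]]
        z = rng.standard_normal()
        w1 = rng.standard_normal()
        w2 = rng.standard_normal()
        log_e = (
            np.log(group.median_endings)
            + u_lit
            + u_plate
            + spec.endings_sigma * (rho * z + np.sqrt(1 - rho**2) * w1)
        )
        log_l = (
            np.log(group.median_length_um)
            + 0.6 * u_lit
            + 0.6 * u_plate
            + spec.length_sigma * (rho * z + np.sqrt(1 - rho**2) * w2)
        )
        n_endings = max(1, int(np.rint(np.exp(log_e))))
        med_len = float(np.exp(log_l))
        total_len = n_endings * med_len * float(np.exp(rng.normal(0.1, 0.10)))
        n_branch = max(0, int(np.rint(n_endings * np.exp(rng.normal(np.log(0.85), 0.12)))))
        n_starts = max(1, int(np.rint(n_endings * np.exp(rng.normal(np.log(0.22), 0.25)))))
        longest = med_len * float(np.exp(abs(rng.normal(0.45, 0.15))))
        weight = float(np.clip(rng.normal(3.8, 0.35), 2.5, None))
        # projected area: mild positive link to vigor, mild negative to weight
        log_area = np.log(60_000.0) + 0.25 * (
            0.35 * z
            - 0.25 * (weight - 3.8) / 0.35
            + np.sqrt(1 - 0.35**2 - 0.25**2) * rng.standard_normal()
        )
        rows.append(
            {
                "explant_id": f"e{idx:05d}",
                "treatment": group.treatment,
                "turn": group.turn,
                "is_control": group.is_control,
                "plate": f"p{plates[idx]:03d}",
                "well": f"w{wells[idx]:02d}",
                "litter": f"L{litter_of[idx]:03d}",
                "sex": rng.choice(["female", "male"]),
                "side": rng.choice(["left", "right"]),
                "age": rng.choice(["P6", "P7"]),
                "weight_g": weight,
                "n_endings": n_endings,
                "median_length_um": med_len,
                "longest_um": longest,
                "n_branch_points": n_branch,
                "n_start_points": n_starts,
                "total_length_um": total_len,
                "projected_area_um2": float(np.exp(log_area)),
            }
        )
    return pd.DataFrame(rows)


def dissect_ear(
    seed: Optional[int] = None,
    side: str = "right",
    mouse_id: str = "m000",
    age: str = "P6",
) -> list[ExplantRecord]:
    """The dissection scheme: one ear yields six explant stubs, two per
    cochlear turn (the spiral ganglion is split into three half-turns,
    each halved again). Deterministic; the seed only labels the RNG stream
    for callers composing larger designs."""
    del seed  # the split is fixed by the protocol
    records = []
    i = 0
    for turn in TURNS:
        for _ in range(2):
            records.append(
                ExplantRecord(
                    id=f"{mouse_id}-{side}-{turn}-{i % 2}",
                    turn=turn,
                    side=side,
                    age=age,
                )
            )
            i += 1
    return records
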