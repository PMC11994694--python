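"""Synthetic field and scene generation.

Everything the real pipeline would get from a field campaign is generated
here so the rest of the package is testable on a desk: plot scene images with
known seed point locations, fisheye video collections with timestamps and
plot-interval tables, and field layouts combining genotype effects with a
smooth environmental trend.

Scenes are deliberately stylised — seeds are shaded ellipses over a
Perlin-style textured background, with foreground clutter standing in for
foliage — but they reproduce the properties that matter to the downstream
code: annotations mark only clearly visible foreground seeds (a seed is
annotated iff at least half of its pixels are unoccluded), background-plot
seeds are rendered but never annotated, and per-plot seed counts tie to the
simulated plot yields through a fixed seeds-per-MT/ha factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage

from .fieldstats import FieldLayout
from .optics import CameraIntrinsics, apply_fisheye, distort_points
from .plotframes import Frame, SampledPlotImages
from .points import PointSet


class PlacementError(ValueError):
    """The requested seeds cannot be placed in the given image size."""


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------

#: A seed is annotated iff at least this fraction of its pixels is visible
#: (unoccluded and not overdrawn by a later seed).
VISIBILITY_THRESHOLD = 0.5


@dataclass(frozen=True)
class SceneSpec:
    """Specification of one synthetic plot scene.

    ``n_background_seeds`` are rendered dimmer and blurred, standing in for
    the background plot visible between rows; they must never be annotated.
    ``occlusion_fraction`` is the fraction of foreground seeds that receive a
    foliage occluder drawn over them.
    """

    n_foreground_seeds: int = 40
    n_background_seeds: int = 15
    seed_radius_px: tuple[float, float] = (3.0, 6.0)
    occlusion_fraction: float = 0.0
    image_size: tuple[int, int] = (1000, 1000)  # (width, height)
    eccentricity: float = 0.6
    background_texture_seed: int = 0
    #: minimum center separation between foreground seeds, as a multiple of
    #: the maximum seed radius; keeps seed-on-seed overdraw below the
    #: visibility threshold so only explicit occluders hide seeds
    min_separation_factor: float = 1.4

    def __post_init__(self) -> None:
        if self.n_foreground_seeds < 0 or self.n_background_seeds < 0:
            raise ValueError("seed counts must be non-negative")
        if not 0 <= self.occlusion_fraction <= 1:
            raise ValueError("occlusion_fraction must be in [0, 1]")
        lo, hi = self.seed_radius_px
        if not 0 < lo <= hi:
            raise ValueError("seed_radius_px must be a positive (low, high) range")


@dataclass
class SceneRender:
    """Full output of a scene render, including the masks that define the
    annotation ground truth (used by visibility-rule checks)."""

    image: np.ndarray  # (H, W, 3) float in [0, 1]
    points: PointSet  # annotated foreground seed centers
    fg_centers: np.ndarray  # all foreground centers, annotated or not
    seed_pixels: list[np.ndarray]  # per-seed flat indices of its own ellipse
    top_label: np.ndarray  # (H, W) int: 1-based index of topmost seed, 0 none
    occluder_mask: np.ndarray  # (H, W) bool
    annotated: np.ndarray  # per-seed bool
    visible_fraction: np.ndarray  # per-seed fraction of own pixels visible


def _ellipse_mask(w: int, h: int, cx: float, cy: float, a: float, b: float,
                  phi: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pixel indices and normalized radius of an ellipse, clipped to image."""
    rmax = max(a, b)
    x0, x1 = max(0, int(cx - rmax - 1)), min(w, int(cx + rmax + 2))
    y0, y1 = max(0, int(cy - rmax - 1)), min(h, int(cy + rmax + 2))
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx, dy = xs - cx, ys - cy
    u = (dx * np.cos(phi) + dy * np.sin(phi)) / a
    v = (-dx * np.sin(phi) + dy * np.cos(phi)) / b
    d2 = u * u + v * v
    inside = d2 <= 1.0
    return ys[inside], xs[inside], d2[inside]


def _perlin_style_texture(w: int, h: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth multi-octave noise in [0, 1]."""
    tex = np.zeros((h, w))
    for sigma, amp in ((12.0, 1.0), (4.0, 0.5), (1.5, 0.25)):
        tex += amp * ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma)
    lo, hi = tex.min(), tex.max()
    return (tex - lo) / (hi - lo + 1e-12)


def render_scene(spec: SceneSpec, rng_seed: int) -> SceneRender:
    """Render one scene and its annotation ground truth.

    Foreground seeds are drawn in order (later seeds overdraw earlier ones);
    a seed's visible fraction is the share of its own ellipse pixels still on
    top and unoccluded at the end, and it is annotated iff that fraction
    reaches :data:`VISIBILITY_THRESHOLD`.
    """
    w, h = spec.image_size
    r_lo, r_hi = spec.seed_radius_px
    mean_area = np.pi * ((r_lo + r_hi) / 2) ** 2
    if spec.n_foreground_seeds * mean_area > 0.5 * w * h:
        raise PlacementError(
            f"image_size {spec.image_size} too small to place "
            f"{spec.n_foreground_seeds} seeds of radius {spec.seed_radius_px}"
        )
    rng = np.random.default_rng(rng_seed)
    tex_rng = np.random.default_rng(spec.background_texture_seed)

    tex = _perlin_style_texture(w, h, tex_rng)
    base = np.array([0.35, 0.30, 0.22])  # dry-canopy brown
    image = base[None, None, :] * (0.6 + 0.8 * tex[..., None])

    # background-plot seeds: dim, blurred, never annotated
    if spec.n_background_seeds:
        bg = np.zeros((h, w))
        for _ in range(spec.n_background_seeds):
            cx, cy = rng.uniform(0, w), rng.uniform(0, h)
            r = rng.uniform(r_lo, r_hi)
            a, b = r, r * (1 - spec.eccentricity * rng.uniform(0.3, 1.0))
            ys, xs, d2 = _ellipse_mask(w, h, cx, cy, a, b, rng.uniform(0, np.pi))
            bg[ys, xs] = np.maximum(bg[ys, xs], 1 - 0.5 * d2)
        bg = ndimage.gaussian_filter(bg, 1.5)
        tint = np.array([0.55, 0.50, 0.35])
        image = image * (1 - 0.35 * bg[..., None]) + 0.35 * bg[..., None] * tint

    margin = r_hi + 1
    top_label = np.zeros((h, w), dtype=np.int32)
    seed_pixels: list[np.ndarray] = []
    centers = np.empty((spec.n_foreground_seeds, 2))
    seed_color = np.array([0.85, 0.78, 0.45])  # pale yellow seed
    min_sep2 = (spec.min_separation_factor * r_hi) ** 2
    for i in range(spec.n_foreground_seeds):
        for _attempt in range(200):
            cx = rng.uniform(margin, w - margin) if w > 2 * margin else w / 2
            cy = rng.uniform(margin, h - margin) if h > 2 * margin else h / 2
            if i == 0 or np.min(
                (centers[:i, 0] - cx) ** 2 + (centers[:i, 1] - cy) ** 2
            ) >= min_sep2:
                break
        else:
            raise PlacementError(
                f"could not place seed {i + 1} of {spec.n_foreground_seeds} in "
                f"image_size {spec.image_size} with minimum separation "
                f"{spec.min_separation_factor} x r_max = "
                f"{spec.min_separation_factor * r_hi:.1f} px"
            )
        centers[i] = (cx, cy)
        r = rng.uniform(r_lo, r_hi)
        a, b = r, max(1.0, r * (1 - spec.eccentricity * rng.uniform(0.2, 0.8)))
        ys, xs, d2 = _ellipse_mask(w, h, cx, cy, a, b, rng.uniform(0, np.pi))
        shade = np.clip(1.0 - 0.55 * d2, 0.0, 1.0)
        image[ys, xs] = seed_color[None, :] * shade[:, None] + \
            image[ys, xs] * (1 - shade[:, None]) * 0.2
        top_label[ys, xs] = i + 1
        seed_pixels.append(np.ravel_multi_index((ys, xs), (h, w)))

    # foliage occluders over a chosen fraction of the foreground seeds
    occluder_mask = np.zeros((h, w), dtype=bool)
    n_occluded = int(round(spec.occlusion_fraction * spec.n_foreground_seeds))
    occluded_ids = rng.choice(spec.n_foreground_seeds, size=n_occluded,
                              replace=False) if n_occluded else []
    leaf_color = np.array([0.25, 0.28, 0.15])
    for i in occluded_ids:
        cx, cy = centers[i]
        r = rng.uniform(r_lo, r_hi)
        # offset so that coverage of the seed varies around the 50% rule
        off = rng.uniform(0.2, 1.4) * r
        ang = rng.uniform(0, 2 * np.pi)
        ys, xs, d2 = _ellipse_mask(
            w, h, cx + off * np.cos(ang), cy + off * np.sin(ang),
            1.6 * r, 1.1 * r, rng.uniform(0, np.pi),
        )
        occluder_mask[ys, xs] = True
        image[ys, xs] = leaf_color[None, :] * (1 - 0.3 * d2[:, None]) + \
            image[ys, xs] * 0.15

    visible_fraction = np.zeros(spec.n_foreground_seeds)
    occ_flat = occluder_mask.ravel()
    top_flat = top_label.ravel()
    for i, pix in enumerate(seed_pixels):
        if len(pix) == 0:
            continue
        visible = (top_flat[pix] == i + 1) & ~occ_flat[pix]
        visible_fraction[i] = visible.sum() / len(pix)
    annotated = visible_fraction >= VISIBILITY_THRESHOLD

    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    points = PointSet(xy=centers[annotated] if spec.n_foreground_seeds else
                      np.empty((0, 2)))
    return SceneRender(
        image=image, points=points, fg_centers=centers,
        seed_pixels=seed_pixels, top_label=top_label,
        occluder_mask=occluder_mask, annotated=annotated,
        visible_fraction=visible_fraction,
    )


def render_plot_image(spec: SceneSpec, rng_seed: int) -> tuple[np.ndarray, PointSet]:
    """Render a scene; return the image and the annotated seed points."""
    render = render_scene(spec, rng_seed)
    return render.image, render.points


# ---------------------------------------------------------------------------
# field simulation
# ---------------------------------------------------------------------------


def linear_gaussian_trend(
    slope_range: float = 0.04,
    slope_pass: float = 0.03,
    bump_amp: float = 0.5,
    bump_center: tuple[float, float] | None = None,
    bump_sigma: float = 3.0,
) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Default smooth spatial trend: separable linear slope plus one Gaussian
    bump (in MT/ha), exercising both the global regression slope and the
    local moving means of the adjustment."""

    def trend(r: np.ndarray, p: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        p = np.asarray(p, dtype=float)
        if bump_center is None:
            cr, cp = r.mean(), p.mean()
        else:
            cr, cp = bump_center
        d2 = (r - cr) ** 2 + (p - cp) ** 2
        return slope_range * r + slope_pass * p + bump_amp * np.exp(
            -d2 / (2 * bump_sigma**2)
        )

    return trend


@dataclass
class FieldSpec:
    """Specification of a synthetic trial field.

    ``genotype_effects`` are per-entry yields in MT/ha around which the
    spatial trend and plot noise vary; entries are tiled over the
    ``n_ranges x n_passes`` grid and shuffled, so an entry recurs roughly
    ``n_plots / n_entries`` times (its replications).
    ``seeds_per_MT`` converts plot yield to the image-proxy seed count (the
    seeds visible across a plot's sampled images, not a census).
    """

    n_ranges: int = 10
    n_passes: int = 10
    genotype_effects: np.ndarray = field(
        default_factory=lambda: np.linspace(2.0, 4.5, 25)
    )
    spatial_trend: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None
    noise_sd: float = 0.15
    seeds_per_MT: float = 300.0
    rng_seed: int = 0
    clip_min: float = 0.05

    def __post_init__(self) -> None:
        self.genotype_effects = np.asarray(self.genotype_effects, dtype=float)
        if self.n_ranges < 1 or self.n_passes < 1:
            raise ValueError("field must have at least one range and pass")
        if len(self.genotype_effects) < 1:
            raise ValueError("need at least one genotype effect")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def simulate_field(spec: FieldSpec) -> FieldLayout:
    """Simulate per-plot true yields and seed counts on the field grid.

    true_yield = genotype_effect(entry) + spatial_trend(range, pass) + noise;
    true_seed_count = round(true_yield * seeds_per_MT). Non-positive yields
    are clipped to ``clip_min`` with a warning. Reproducible from
    ``rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n_plots = spec.n_ranges * spec.n_passes
    n_entries = len(spec.genotype_effects)
    entries = np.tile(np.arange(n_entries), n_plots // n_entries + 1)[:n_plots]
    rng.shuffle(entries)
    rr, pp = np.meshgrid(
        np.arange(1, spec.n_ranges + 1), np.arange(1, spec.n_passes + 1),
        indexing="ij",
    )
    rr, pp = rr.ravel(), pp.ravel()
    trend = (
        spec.spatial_trend(rr, pp)
        if spec.spatial_trend is not None
        else np.zeros(n_plots)
    )
    noise = rng.normal(0.0, spec.noise_sd, n_plots) if spec.noise_sd else np.zeros(n_plots)
    true_yield = spec.genotype_effects[entries] + trend + noise
    if (true_yield <= 0).any():
        n_bad = int((true_yield <= 0).sum())
        warnings.warn(f"clipped {n_bad} non-positive plot yields to {spec.clip_min}",
                      stacklevel=2)
        true_yield = np.maximum(true_yield, spec.clip_min)
    df = pd.DataFrame(
        {
            "range": rr,
            "pass": pp,
            "entry": entries,
            "genotype_effect": spec.genotype_effects[entries],
            "true_yield": true_yield,
            "true_seed_count": np.round(true_yield * spec.seeds_per_MT).astype(int),
        }
    )
    return FieldLayout(df)


# ---------------------------------------------------------------------------
# collection simulation
# ---------------------------------------------------------------------------


@dataclass
class FrameRecord:
    """One simulated video frame with its generation ground truth."""

    timestamp: float
    image: np.ndarray | None
    true_points: PointSet
    plot_id: tuple[int, int]
    row: int  # 1 or 2
    side: str  # 'A' or 'B'


@dataclass
class CollectionSim:
    """A simulated serpentine collection: per-(row, side) frame sequences over
    a shared plot-interval table."""

    frames: list[FrameRecord]
    intervals: pd.DataFrame  # range, pass, start_s, stop_s


def simulate_collection(
    layout: FieldLayout,
    intr: CameraIntrinsics,
    frames_per_plot: int = 10,
    robot_speed_mps: float = 1.0,
    plot_length_m: float = 2.13,
    alley_length_m: float = 0.91,
    seeds_per_frame_scale: float = 1 / 20,
    scene_template: SceneSpec | None = None,
    render_frames: bool = True,
    rng_seed: int = 0,
) -> CollectionSim:
    """Simulate fisheye frame sequences and the plot-interval table.

    For every plot, four sequences (rows 1-2 x sides A-B) of
    ``frames_per_plot`` frames are emitted, evenly spaced inside the plot's
    time interval (constant robot speed: interval length =
    plot_length / speed). Frame images are scenes rendered at the camera's
    native size with forward fisheye distortion applied; each frame's ground
    truth points are in distorted-frame coordinates. With
    ``render_frames=False`` only timestamps and empty images are produced
    (enough for assignment/sampling work).
    """
    if frames_per_plot < 8:
        raise ValueError("frames_per_plot must be >= 8 for splitter sampling")
    plot_dur = plot_length_m / robot_speed_mps
    alley_dur = alley_length_m / robot_speed_mps
    w, h = intr.native_size
    template = scene_template or SceneSpec(image_size=(w, h))
    if template.image_size != (w, h):
        template = replace(template, image_size=(w, h))
    rng = np.random.default_rng(rng_seed)

    # serpentine order: ranges ascending on odd passes, descending on even
    plots = layout.df.sort_values(["pass", "range"]).reset_index(drop=True)
    order = []
    for p, grp in plots.groupby("pass", sort=True):
        idx = grp.sort_values("range", ascending=(int(p) % 2 == 1)).index
        order.extend(idx.tolist())

    intervals_rows = []
    frames: list[FrameRecord] = []
    t = 0.0
    for i in order:
        row_ = plots.loc[i]
        plot_id = (int(row_["range"]), int(row_["pass"]))
        start, stop = t, t + plot_dur
        intervals_rows.append(
            {"range": plot_id[0], "pass": plot_id[1], "start_s": start, "stop_s": stop}
        )
        count = int(row_.get("true_seed_count", 0))
        for row in (1, 2):
            for side in ("A", "B"):
                for j in range(frames_per_plot):
                    ts = start + (j + 0.5) * plot_dur / frames_per_plot
                    if render_frames:
                        n_fg = int(rng.poisson(max(count * seeds_per_frame_scale, 0)))
                        spec = replace(template, n_foreground_seeds=n_fg)
                        scene = render_scene(spec, int(rng.integers(2**31)))
                        img = apply_fisheye(scene.image, intr)
                        pts = PointSet(xy=distort_points(scene.points.xy, intr)
                                       if len(scene.points) else np.empty((0, 2)))
                    else:
                        img, pts = None, PointSet.empty()
                    frames.append(
                        FrameRecord(timestamp=ts, image=img, true_points=pts,
                                    plot_id=plot_id, row=row, side=side)
                    )
        t = stop + alley_dur
    intervals = pd.DataFrame(intervals_rows)
    return CollectionSim(frames=frames, intervals=intervals)


# ---------------------------------------------------------------------------
# direct per-plot sampled-image generation (working-crop resolution)
# ---------------------------------------------------------------------------


def render_plot_samples(
    layout: FieldLayout,
    image_size: tuple[int, int] = (64, 64),
    n_images: int = 20,
    scene_template: SceneSpec | None = None,
    rng_seed: int = 0,
) -> dict[tuple[int, int], SampledPlotImages]:
    """Generate each plot's sampled-image set directly at working-crop
    resolution, splitting the plot's seed count multinomially across the
    images (bypassing the video/optics path; used for model training)."""
    template = scene_template or SceneSpec(image_size=image_size)
    if template.image_size != image_size:
        template = replace(template, image_size=image_size)
    rng = np.random.default_rng(rng_seed)
    out: dict[tuple[int, int], SampledPlotImages] = {}
    per_side = n_images // 2
    for _, row in layout.df.iterrows():
        plot_id = (int(row["range"]), int(row["pass"]))
        count = int(row["true_seed_count"])
        split = rng.multinomial(count, np.full(n_images, 1 / n_images))
        sides: dict[str, list[Frame]] = {"A": [], "B": []}
        for k in range(n_images):
            spec = replace(template, n_foreground_seeds=int(split[k]))
            img, _ = render_plot_image(spec, int(rng.integers(2**31)))
            side = "A" if k < per_side else "B"
            sides[side].append(Frame(timestamp=float(k), image=img))
        out[plot_id] = SampledPlotImages(plot_id=plot_id, sides=sides)
    return out


def render_annotated_corpus(
    n_images: int,
    scene_template: SceneSpec | None = None,
    count_range: tuple[int, int] = (5, 60),
    rng_seed: int = 0,
) -> list[tuple[np.ndarray, PointSet]]:
    """Generate an annotated training corpus of single scenes with varying
    seed density (the synthetic analogue of an annotated image dataset)."""
    template = scene_template or SceneSpec(image_size=(64, 64))
    rng = np.random.default_rng(rng_seed)
    corpus = []
    for i in range(n_images):
        n = int(rng.integers(count_range[0], count_range[1] + 1))
        spec = replace(template, n_foreground_seeds=n,
                       background_texture_seed=int(rng.integers(2**31)))
        img, pts = render_plot_image(spec, int(rng.integers(2**31)))
        pts.image_id = f"scene_{i:05d}"
        corpus.append((img, pts))
    return corpus
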