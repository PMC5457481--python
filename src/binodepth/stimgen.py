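"""Stimulus synthesis: random-dot stereograms, disparity step edges,
wallpaper and half-occlusion (da Vinci) displays, and naturalistic stereo
pairs rendered from synthetic textured scenes with a patch-extraction
pipeline.

Sign convention (package-wide): positive disparity means "far" and is
applied as a rightward shift of the right-eye feature, i.e.
``right(x) = left(x - d)``.  Intensities live in [-1, 1]: bright, dark and
mid-gray pixels are +1, -1 and 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "StereoPair",
    "RDSConfig",
    "StepEdgeConfig",
    "SceneSpec",
    "PatchSet",
    "make_rds",
    "make_step_edge",
    "polarity_controls",
    "render_stereo_from_depth",
    "synth_scene",
    "extract_patches",
    "make_wallpaper",
    "make_davinci",
    "to_png",
    "to_anaglyph_png",
]

PolarityMode = Literal["mixed", "bright", "dark"]


@dataclass
class StereoPair:
    """Two co-registered gray-scale images in [-1, 1].

    ``disparity`` optionally carries the ground-truth horizontal disparity
    (pixels, left-eye frame, positive = far); ``interp_mask`` marks pixels
    filled by interpolation during rendering; ``occlusion_mask`` marks
    monocular (one-eye-only) pixels.
    """

    left: np.ndarray
    right: np.ndarray
    disparity: Optional[np.ndarray] = None
    interp_mask: Optional[np.ndarray] = None
    occlusion_mask: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.shape != self.right.shape:
            raise ValueError("left and right images must have the same shape")
        for name in ("disparity", "interp_mask", "occlusion_mask"):
            m = getattr(self, name)
            if m is not None and np.asarray(m).shape != self.left.shape:
                raise ValueError(f"{name} must match the image shape")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.left.shape


@dataclass(frozen=True)
class RDSConfig:
    """Random-dot stereogram parameters (dots on a mid-gray background)."""

    size: tuple[int, int] = (100, 100)
    dot_size: int = 1
    density: float = 0.5
    polarity: PolarityMode = "mixed"
    disparity: int = 0
    correlated: bool = True
    background: float = 0.0
    anticorrelate_eye: Literal["left", "right"] = "right"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.density <= 1.0):
            raise ValueError(f"density must be in (0, 1], got {self.density}")
        if self.dot_size < 1:
            raise ValueError("dot size must be >= 1 pixel")


def _dot_values(rng: np.random.Generator, n: int, polarity: PolarityMode) -> np.ndarray:
    if polarity == "mixed":
        return rng.choice([-1.0, 1.0], size=n)
    if polarity == "bright":
        return np.ones(n)
    if polarity == "dark":
        return -np.ones(n)
    raise ValueError(f"unknown polarity mode: {polarity}")


def make_rds(config: RDSConfig, rng: Optional[np.random.Generator] = None) -> StereoPair:
    """Generate a random-dot stereogram.

    Dots are drawn on a field wider than the image by |disparity|, and the
    two eyes see horizontally offset crops of it, so every column of both
    images is a binocularly matched sample (no wrap-around or unmatched
    border strip).  In anticorrelated mode the dot contrast is inverted in
    the configured eye (right by default); background pixels are
    unaffected.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h, w = config.size
    d = int(config.disparity)
    wide = w + abs(d)
    field = np.full((h, wide), config.background)

    if config.dot_size == 1:
        mask = rng.random((h, wide)) < config.density
        vals = _dot_values(rng, int(mask.sum()), config.polarity)
        field[mask] = vals
    else:
        n_dots = int(round(config.density * h * wide / config.dot_size**2))
        ys = rng.integers(0, h, n_dots)
        xs = rng.integers(0, wide, n_dots)
        vals = _dot_values(rng, n_dots, config.polarity)
        for y, x, v in zip(ys, xs, vals):
            yy = (np.arange(config.dot_size) + y) % h
            xx = (np.arange(config.dot_size) + x) % wide
            field[np.ix_(yy, xx)] = v

    # right(x) = left(x - d): positive disparity shifts right-eye
    # features rightward (far)
    if d >= 0:
        left = field[:, d : d + w].copy()
        right = field[:, :w].copy()
    else:
        left = field[:, :w].copy()
        right = field[:, -d : -d + w].copy()
    if not config.correlated:
        if config.anticorrelate_eye == "right":
            right = np.where(right != config.background, -right, right)
        else:
            left = np.where(left != config.background, -left, left)

    disp = np.full((h, w), float(config.disparity))
    return StereoPair(left, right, disparity=disp, meta={"config": config})


@dataclass(frozen=True)
class StepEdgeConfig:
    """Disparity step-edge stereogram: two half-fields of dots at +-step/2
    pixels of disparity plus per-dot Gaussian disparity noise; dots never
    overlap."""

    size: tuple[int, int] = (240, 240)
    dot_size: int = 8
    density: float = 0.15
    step: float = 2.0
    noise_sd: float = 8.0
    polarity: PolarityMode = "mixed"
    near_side: Literal["left", "right"] = "left"
    background: float = 0.0
    max_retries: int = 200
    seed: Optional[int] = None


def make_step_edge(
    config: StepEdgeConfig, rng: Optional[np.random.Generator] = None
) -> StereoPair:
    """Generate a step-edge random-dot stereogram.

    Each dot's disparity is +-step/2 according to the half of the image it
    falls in, plus Gaussian noise (rounded to integer pixels).  Dots are
    placed by rejection sampling so that no two dots overlap in either eye.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h, w = config.size
    ds = config.dot_size
    n_dots = int(round(config.density * h * w / ds**2))

    left = np.full((h, w), config.background)
    right = np.full((h, w), config.background)
    disp_map = np.zeros((h, w))
    occupied_l = np.zeros((h, w), dtype=bool)
    occupied_r = np.zeros((h, w), dtype=bool)

    near_sign = -1.0  # near = negative disparity
    placed = 0
    attempts = 0
    max_attempts = config.max_retries * n_dots
    while placed < n_dots:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n_dots} non-overlapping dots "
                f"(placed {placed} after {attempts} attempts)"
            )
        attempts += 1
        y = int(rng.integers(0, h - ds))
        x = int(rng.integers(0, w - ds))
        on_near = (x + ds / 2 < w / 2) == (config.near_side == "left")
        d_signal = (near_sign if on_near else -near_sign) * config.step / 2.0
        d = int(round(d_signal + rng.normal(0.0, config.noise_sd)))
        xr = x + d
        if xr < 0 or xr + ds > w:
            continue
        if occupied_l[y : y + ds, x : x + ds].any():
            continue
        if occupied_r[y : y + ds, xr : xr + ds].any():
            continue
        v = float(_dot_values(rng, 1, config.polarity)[0])
        left[y : y + ds, x : x + ds] = v
        right[y : y + ds, xr : xr + ds] = v
        disp_map[y : y + ds, x : x + ds] = d
        occupied_l[y : y + ds, x : x + ds] = True
        occupied_r[y : y + ds, xr : xr + ds] = True
        placed += 1

    true_disp = np.where(
        (np.arange(w)[None, :] < w / 2) == (config.near_side == "left"),
        near_sign * config.step / 2.0,
        -near_sign * config.step / 2.0,
    ) * np.ones((h, 1))
    return StereoPair(
        left,
        right,
        disparity=disp_map,
        meta={"config": config, "signal_disparity": true_disp},
    )


def polarity_controls(
    pair: StereoPair,
    mode: Literal["dc-removed", "range-matched", "range-matched-after-dc"],
    target_range: float = 2.0,
) -> StereoPair:
    """Low-level covariate controls applied per image.

    - ``dc-removed``: subtract each image's mean luminance.
    - ``range-matched``: affinely map each image's [min, max] onto a
      symmetric interval of the target peak-to-trough range (default 2,
      i.e. [-1, +1]).
    - ``range-matched-after-dc``: remove the DC first, then range-match.
    """

    def _dc(img: np.ndarray) -> np.ndarray:
        return img - img.mean()

    def _range(img: np.ndarray) -> np.ndarray:
        lo, hi = img.min(), img.max()
        if hi - lo < 1e-12:
            return np.zeros_like(img)
        return (img - (hi + lo) / 2.0) * (target_range / (hi - lo))

    if mode == "dc-removed":
        fn = _dc
    elif mode == "range-matched":
        fn = _range
    elif mode == "range-matched-after-dc":
        fn = lambda img: _range(_dc(img))  # noqa: E731
    else:
        raise ValueError(f"unknown control mode: {mode}")
    return StereoPair(
        fn(pair.left),
        fn(pair.right),
        disparity=pair.disparity,
        interp_mask=pair.interp_mask,
        occlusion_mask=pair.occlusion_mask,
        meta={**pair.meta, "control": mode},
    )


def render_stereo_from_depth(
    texture: np.ndarray,
    depth: np.ndarray,
    max_shift: int = 10,
    normalize_depth: bool = True,
) -> StereoPair:
    """Render a stereo pair by per-pixel horizontal shifts of a texture.

    The left eye sees the texture unchanged; each pixel is shifted
    rightward in the right-eye image by its disparity (depth scaled so the
    maximum |depth| maps to ``max_shift`` pixels, rounded to integers).
    Where shifted pixels collide, the nearer surface (smaller signed
    disparity) wins; disoccluded pixels are filled by linear interpolation
    along the row and flagged in ``interp_mask``.
    """
    texture = np.asarray(texture, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if texture.shape != depth.shape:
        raise ValueError("texture and depth map must be co-registered")
    if not np.all(np.isfinite(depth)):
        raise ValueError("depth map contains non-finite values")

    if normalize_depth:
        dmax = np.abs(depth).max()
        disp = depth / dmax * max_shift if dmax > 0 else np.zeros_like(depth)
    else:
        disp = np.clip(depth, -max_shift, max_shift)
    disp_int = np.rint(disp).astype(int)

    h, w = texture.shape
    right = np.zeros((h, w))
    filled = np.zeros((h, w), dtype=bool)
    # paint far-to-near so that nearer surfaces overwrite farther ones
    for row in range(h):
        order = np.argsort(-disp_int[row], kind="stable")
        src = np.arange(w)[order]
        tgt = src + disp_int[row][order]
        ok = (tgt >= 0) & (tgt < w)
        right[row, tgt[ok]] = texture[row, src[ok]]
        filled[row, tgt[ok]] = True
        holes = ~filled[row]
        if holes.any():
            good = np.flatnonzero(filled[row])
            if len(good) >= 2:
                right[row, holes] = np.interp(np.flatnonzero(holes), good, right[row, good])
            elif len(good) == 1:
                right[row, holes] = right[row, good[0]]
    return StereoPair(
        texture,
        right,
        disparity=disp_int.astype(float),
        interp_mask=~filled,
        meta={"max_shift": max_shift},
    )


@dataclass(frozen=True)
class SceneSpec:
    """Synthetic textured scene with a piecewise-smooth depth map.

    The texture has a naturalistic power-law amplitude spectrum
    (|A(f)| ~ f^spectral_slope).  The depth map is piecewise constant over
    ``n_surfaces`` random (Voronoi) regions whose depths are drawn from
    ``depth_levels`` (abstract units in [-1, 1]; rendering shifts pixels by
    depth * ``max_shift``, so the defaults place surfaces on one near and
    one far plane at -+2 px of disparity -- the discrete near/far
    disparities the depth-discrimination task is trained on).
    """

    size: tuple[int, int] = (160, 160)
    spectral_slope: float = -1.0
    contrast: float = 0.35  # texture s.d. as a fraction of the half-range
    n_surfaces: int = 4
    depth_levels: Sequence[float] = (-0.2, 0.2)
    max_shift: int = 10
    seed: Optional[int] = None


def synth_scene(
    spec: SceneSpec, rng: Optional[np.random.Generator] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Generate (texture, depth map) for a synthetic scene.

    The texture is in [-1, 1] gray levels with mean ~0; the depth map holds
    signed values from ``spec.depth_levels`` (negative = near).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    h, w = spec.size

    noise = rng.standard_normal((h, w))
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0
    amp = f**spec.spectral_slope
    amp[0, 0] = 0.0
    texture = np.fft.ifft2(np.fft.fft2(noise) * amp).real
    texture = texture / texture.std() * spec.contrast
    texture = np.clip(texture, -1.0, 1.0)

    seeds_y = rng.integers(0, h, spec.n_surfaces)
    seeds_x = rng.integers(0, w, spec.n_surfaces)
    levels = rng.choice(spec.depth_levels, size=spec.n_surfaces)
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    d2 = (yy[..., None] - seeds_y) ** 2 + (xx[..., None] - seeds_x) ** 2
    depth = levels[np.argmin(d2, axis=-1)]
    return texture, depth


@dataclass
class PatchSet:
    """A labelled set of stereo patches (near = 0, far = 1)."""

    left: np.ndarray  # (n, patch, patch)
    right: np.ndarray
    labels: np.ndarray  # (n,) int, 0 = near, 1 = far

    def __len__(self) -> int:
        return len(self.labels)


def extract_patches(
    pairs: Sequence[StereoPair],
    patch: int = 30,
    sd_threshold: float = 20.0,
    max_interp: float = 0.05,
    split: tuple[float, float, float] = (70.0, 15.0, 15.0),
    min_abs_disparity: float = 1.0,
    seed: Optional[int] = None,
) -> tuple[PatchSet, PatchSet, PatchSet]:
    """Cut labelled train/validation/test patches from rendered pairs.

    Non-overlapping ``patch`` x ``patch`` tiles are excluded when (i) the
    pixel-intensity s.d. is below ``sd_threshold`` gray levels (0-255
    scale, i.e. sd_threshold/127.5 in [-1, 1] units), (ii) more than
    ``max_interp`` of the pixels were filled by interpolation, or (iii) the
    ground-truth disparity is not a consistent near/far signal (mixed signs
    or mean |disparity| < ``min_abs_disparity`` px).  Survivors are split
    into disjoint train/validation/test sets at the given percentages.
    """
    rng = np.random.default_rng(seed)
    sd_thr = sd_threshold / 127.5
    lefts, rights, labels = [], [], []
    for pair in pairs:
        if pair.disparity is None:
            raise ValueError("pairs must carry ground-truth disparity maps")
        interp = (
            pair.interp_mask
            if pair.interp_mask is not None
            else np.zeros(pair.shape, dtype=bool)
        )
        h, w = pair.shape
        for y in range(0, h - patch + 1, patch):
            for x in range(0, w - patch + 1, patch):
                sl = (slice(y, y + patch), slice(x, x + patch))
                if pair.left[sl].std() < sd_thr:
                    continue
                if interp[sl].mean() > max_interp:
                    continue
                d = pair.disparity[sl]
                mean_d = d.mean()
                if abs(mean_d) < min_abs_disparity:
                    continue
                signs = np.sign(d[d != 0])
                if signs.size == 0 or signs.min() != signs.max():
                    continue
                lefts.append(pair.left[sl])
                rights.append(pair.right[sl])
                labels.append(1 if mean_d > 0 else 0)

    n = len(labels)
    fr = np.asarray(split, dtype=float)
    fr = fr / fr.sum()
    n_train = int(round(n * fr[0]))
    n_val = int(round(n * fr[1]))
    if n_train < 1 or n_val < 1 or n - n_train - n_val < 1:
        raise RuntimeError(
            f"only {n} patches survived filtering; not enough for the "
            f"requested {split} split"
        )
    left_arr = np.stack(lefts)
    right_arr = np.stack(rights)
    label_arr = np.asarray(labels, dtype=int)
    order = rng.permutation(n)
    sets = []
    for idx in (order[:n_train], order[n_train : n_train + n_val], order[n_train + n_val :]):
        sets.append(PatchSet(left_arr[idx], right_arr[idx], label_arr[idx]))
    return tuple(sets)


def make_wallpaper(
    period: int = 8,
    bg_luminance: float = 0.0,
    size: tuple[int, int] = (120, 160),
    center_width: int = 64,
    center_height: int = 60,
    duty_cycle: float = 0.5,
    bright: float = 1.0,
    dark: float = -1.0,
) -> StereoPair:
    """Periodic vertical-stripe ("wallpaper") display.

    The central region carries a vertical square-wave grating that is
    identical in the two eyes, so matches at lags 0, +-period, ... are all
    geometrically valid.  The surrounding background luminance is the only
    free parameter distinguishing bias variants.
    """
    if period < 2:
        raise ValueError("period must be >= 2 pixels")
    h, w = size
    img = np.full((h, w), bg_luminance)
    y0 = (h - center_height) // 2
    x0 = (w - center_width) // 2
    xs = np.arange(center_width)
    stripes = np.where((xs % period) < duty_cycle * period, bright, dark)
    img[y0 : y0 + center_height, x0 : x0 + center_width] = stripes[None, :]
    return StereoPair(
        img.copy(),
        img.copy(),
        meta={
            "kind": "wallpaper",
            "period": period,
            "bg_luminance": bg_luminance,
            "center": (y0, x0, center_height, center_width),
        },
    )


def make_davinci(
    size: tuple[int, int] = (120, 160),
    target_width: int = 60,
    target_height: int = 60,
    flank_width: int = 6,
    flank_luminance: float = -1.0,
    bg_luminance: float = 0.0,
    target_density: float = 0.5,
    seed: Optional[int] = None,
) -> StereoPair:
    """Half-occlusion (da Vinci) display: a zero-disparity dot-textured
    target with monocular flanks at its vertical edges.

    The flank adjoining the target's left edge is visible only in the left
    eye; the flank at the right edge only in the right eye, emulating the
    half-occlusions produced by an occluder in front of a background. The
    occlusion mask marks the monocular flank pixels.
    """
    if flank_width < 1:
        raise ValueError("flank width must be >= 1 pixel")
    rng = np.random.default_rng(seed)
    h, w = size
    left = np.full((h, w), bg_luminance)
    right = np.full((h, w), bg_luminance)
    y0 = (h - target_height) // 2
    x0 = (w - target_width) // 2

    texture = np.full((target_height, target_width), bg_luminance)
    mask = rng.random(texture.shape) < target_density
    texture[mask] = rng.choice([-1.0, 1.0], size=int(mask.sum()))
    left[y0 : y0 + target_height, x0 : x0 + target_width] = texture
    right[y0 : y0 + target_height, x0 : x0 + target_width] = texture

    occl = np.zeros((h, w), dtype=bool)
    lf = (slice(y0, y0 + target_height), slice(x0 - flank_width, x0))
    rf = (slice(y0, y0 + target_height), slice(x0 + target_width, x0 + target_width + flank_width))
    left[lf] = flank_luminance
    right[rf] = flank_luminance
    occl[lf] = True
    occl[rf] = True
    return StereoPair(
        left,
        right,
        occlusion_mask=occl,
        meta={"kind": "davinci", "target": (y0, x0, target_height, target_width)},
    )


def _to_uint8(img: np.ndarray) -> np.ndarray:
    return np.clip((np.asarray(img) + 1.0) * 127.5, 0, 255).astype(np.uint8)


def to_png(pair: StereoPair, prefix: str, side_by_side: bool = True) -> list[str]:
    """Export a stereo pair to PNG: one file per eye, plus an optional
    side-by-side image for cross-eyed fusion (right eye on the left)."""
    import imageio.v3 as iio

    paths = [f"{prefix}_left.png", f"{prefix}_right.png"]
    iio.imwrite(paths[0], _to_uint8(pair.left))
    iio.imwrite(paths[1], _to_uint8(pair.right))
    if side_by_side:
        gap = np.zeros((pair.shape[0], 8), dtype=np.uint8)
        sbs = np.hstack([_to_uint8(pair.right), gap, _to_uint8(pair.left)])
        paths.append(f"{prefix}_sbs.png")
        iio.imwrite(paths[-1], sbs)
    return paths


def to_anaglyph_png(pair: StereoPair, path: str) -> str:
    """Export a red/green anaglyph (left eye in the red channel)."""
    import imageio.v3 as iio

    rgb = np.zeros((*pair.shape, 3), dtype=np.uint8)
    rgb[..., 0] = _to_uint8(pair.left)
    rgb[..., 1] = _to_uint8(pair.right)
    iio.imwrite(path, rgb)
    return path
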