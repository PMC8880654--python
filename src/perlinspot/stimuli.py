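"""Perlin-noise stimulus synthesis for spot-the-difference experiments.

Generates square gradient-noise images with physical (cm) calibration,
screens out directionally biased samples, embeds low-contrast Gaussian
luminance targets, and describes the four presentation formats
(horizontal, vertical, sequential with 200 ms ISI, sequential with no ISI).

All geometry is expressed in centimetres with the origin at the top-left
corner, x rightward and y downward.  Pixel (i, j) covers the square
[j/s, (j+1)/s) x [i/s, (i+1)/s) cm for scale s px/cm, and is sampled at
its centre ((j+0.5)/s, (i+0.5)/s).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_SIDE_CM = 8.7
DEFAULT_SCALE_PX_PER_CM = 40.0
DEFAULT_GRID_CELLS = 3
DEFAULT_SIGMA_CM = 0.35
DEFAULT_STRENGTHS = (40, 50, 60)
DEFAULT_MARGIN_CM = 1.0
DEFAULT_ANISOTROPY_THRESHOLD = 2.5
MEAN_LUMINANCE = 128

FORMAT_NAMES = ("horizontal", "vertical", "seq_isi200", "seq_isi0")


class StimulusError(Exception):
    """Base class for stimulus-generation failures."""


class InsufficientStimuliError(StimulusError):
    """Raised when artifact screening rejects every candidate image."""


def visual_angle_deg(size_cm: float, distance_cm: float = 60.0) -> float:
    """Visual angle (degrees) subtended by ``size_cm`` at ``distance_cm``.

    At the study's 60 cm viewing distance, 1 cm on screen subtends ~0.95
    degrees, i.e. approximately 1 degree of visual angle.
    """
    if size_cm < 0 or distance_cm <= 0:
        raise ValueError("size must be >= 0 and distance > 0")
    return float(np.degrees(2.0 * np.arctan(size_cm / (2.0 * distance_cm))))


# ---------------------------------------------------------------------------
# gradient lattice and noise field


@dataclass(frozen=True)
class GradientLattice:
    """Random unit gradient vectors at the corners of a square cell grid.

    ``angles`` has shape (grid_cells+1, grid_cells+1), indexed [row, col]
    with rows running down the image.  Gradients are (cos a, sin a), hence
    unit norm by construction.
    """

    grid_cells: int
    angles: np.ndarray
    seed: int

    @property
    def gradients(self) -> tuple[np.ndarray, np.ndarray]:
        return np.cos(self.angles), np.sin(self.angles)


def make_gradient_lattice(seed: int, grid_cells: int = DEFAULT_GRID_CELLS) -> GradientLattice:
    """Draw a (grid_cells+1)^2 lattice of uniform-random gradient angles."""
    if grid_cells < 1:
        raise ValueError(f"grid_cells must be >= 1, got {grid_cells}")
    rng = np.random.default_rng(seed)
    angles = rng.uniform(0.0, 2.0 * np.pi, size=(grid_cells + 1, grid_cells + 1))
    return GradientLattice(grid_cells=grid_cells, angles=angles, seed=int(seed))


def _fade(t: np.ndarray) -> np.ndarray:
    # classic cubic ease curve 3t^2 - 2t^3
    return t * t * (3.0 - 2.0 * t)


def perlin_noise(lattice: GradientLattice, x_cm, y_cm, side_cm: float) -> np.ndarray:
    """Evaluate the raw gradient-noise field at coordinates (cm).

    Offsets from the cell corners are measured in lattice-cell units, so
    the field's amplitude is independent of the physical cell size.
    Vanishes exactly at every lattice corner.
    """
    cell = side_cm / lattice.grid_cells
    u = np.asarray(x_cm, dtype=float) / cell
    v = np.asarray(y_cm, dtype=float) / cell
    i0 = np.clip(np.floor(u).astype(int), 0, lattice.grid_cells - 1)
    j0 = np.clip(np.floor(v).astype(int), 0, lattice.grid_cells - 1)
    fx = u - i0
    fy = v - j0
    gx, gy = lattice.gradients

    def corner(dj, di):
        return gx[j0 + dj, i0 + di] * (fx - di) + gy[j0 + dj, i0 + di] * (fy - dj)

    n00 = corner(0, 0)
    n01 = corner(0, 1)
    n10 = corner(1, 0)
    n11 = corner(1, 1)
    su = _fade(fx)
    sv = _fade(fy)
    nx0 = n00 + su * (n01 - n00)
    nx1 = n10 + su * (n11 - n10)
    return nx0 + sv * (nx1 - nx0)


@dataclass(eq=False)
class PerlinImage:
    """An 8-bit grayscale noise field with physical calibration.

    ``gain`` is the per-image luminance scaling 127/max|noise| applied
    about the mean level 128, so the raw field can be re-evaluated and
    mapped to luminance at arbitrary coordinates.
    """

    pixels: np.ndarray
    side_cm: float
    scale_px_per_cm: float
    lattice_seed: int
    grid_cells: int = DEFAULT_GRID_CELLS
    gain: float = float("nan")
    noise_mean: float = 0.0
    anisotropy: float | None = None

    @property
    def side_px(self) -> int:
        return self.pixels.shape[0]

    def pixel_centers_cm(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) meshgrid of pixel-centre coordinates in cm."""
        n = self.side_px
        c = (np.arange(n) + 0.5) / self.scale_px_per_cm
        return np.meshgrid(c, c)

    def luminance_at(self, x_cm: float, y_cm: float) -> float:
        """Continuous luminance (before 8-bit rounding) at a point."""
        lattice = make_gradient_lattice(self.lattice_seed, self.grid_cells)
        n = perlin_noise(lattice, x_cm, y_cm, self.side_cm)
        return float(MEAN_LUMINANCE + self.gain * (n - self.noise_mean))


def perlin_noise_image(
    lattice: GradientLattice,
    side_cm: float = DEFAULT_SIDE_CM,
    scale_px_per_cm: float = DEFAULT_SCALE_PX_PER_CM,
) -> PerlinImage:
    """Render a lattice to an 8-bit image of side round(side_cm * scale) px.

    The sampled noise field is centred on its per-image mean (with only a
    3x3 cell grid the raw field's spatial mean fluctuates appreciably
    between seeds) and mapped symmetrically about luminance 128 with gain
    g = 127 / max|n - mean|, so every image has mean luminance 128 and
    uses the full 8-bit range; rounded and clamped to [0, 255].
    """
    if side_cm <= 0 or scale_px_per_cm <= 0:
        raise ValueError("side_cm and scale_px_per_cm must be positive")
    n_px = int(round(side_cm * scale_px_per_cm))
    coords = (np.arange(n_px) + 0.5) / scale_px_per_cm
    x, y = np.meshgrid(coords, coords)
    noise = perlin_noise(lattice, x, y, side_cm)
    noise_mean = float(noise.mean())
    centred = noise - noise_mean
    peak = float(np.max(np.abs(centred)))
    if peak == 0.0:
        raise StimulusError(f"degenerate lattice (seed {lattice.seed}): flat noise field")
    gain = 127.0 / peak
    pixels = np.clip(np.rint(MEAN_LUMINANCE + gain * centred), 0, 255).astype(np.uint8)
    return PerlinImage(
        pixels=pixels,
        side_cm=side_cm,
        scale_px_per_cm=scale_px_per_cm,
        lattice_seed=lattice.seed,
        grid_cells=lattice.grid_cells,
        gain=gain,
        noise_mean=noise_mean,
    )


# ---------------------------------------------------------------------------
# directional-artifact screening


def anisotropy_score(image: PerlinImage | np.ndarray, n_orientation_bins: int = 8) -> float:
    """Orientation-energy concentration of the 2-D power spectrum.

    The DC-excluded power spectrum is summed into ``n_orientation_bins``
    orientation bins over [0, pi); the score is max bin energy over mean
    bin energy, >= 1 with equality only for perfectly isotropic energy.
    Oriented structure (e.g. a grating) concentrates energy into one bin
    and scores close to n_orientation_bins.
    """
    pixels = image.pixels if isinstance(image, PerlinImage) else np.asarray(image)
    if pixels.ndim != 2 or pixels.shape[0] != pixels.shape[1]:
        raise ValueError(f"expected a square 2-D image, got shape {pixels.shape}")
    data = pixels.astype(float)
    power = np.abs(np.fft.fft2(data - data.mean())) ** 2
    h, w = power.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    theta = np.mod(np.arctan2(fy, fx), np.pi)
    bins = np.minimum((theta / (np.pi / n_orientation_bins)).astype(int), n_orientation_bins - 1)
    mask = np.ones_like(power, dtype=bool)
    mask[0, 0] = False  # exclude DC
    energy = np.bincount(bins[mask].ravel(), weights=power[mask].ravel(), minlength=n_orientation_bins)
    total = energy.sum()
    if total == 0:
        return 1.0
    return float(energy.max() / (total / n_orientation_bins))


def screen_artifacts(
    images: Sequence[PerlinImage],
    threshold: float = DEFAULT_ANISOTROPY_THRESHOLD,
    n_orientation_bins: int = 8,
) -> list[PerlinImage]:
    """Keep images whose anisotropy score is below ``threshold``.

    Automated surrogate for by-eye rejection of images with directional
    artifacts.  Rejected seeds are logged.  Scores are stored on the
    returned images.
    """
    if not images:
        raise ValueError("screen_artifacts requires a nonempty image list")
    kept = []
    for img in images:
        score = anisotropy_score(img, n_orientation_bins=n_orientation_bins)
        img.anisotropy = score
        if score < threshold:
            kept.append(img)
        else:
            logger.info(
                "rejected lattice seed %d: anisotropy %.3f >= %.3f",
                img.lattice_seed, score, threshold,
            )
    if not kept:
        raise InsufficientStimuliError(
            f"all {len(images)} candidate images rejected at anisotropy threshold "
            f"{threshold}; widen the seed range or raise the threshold"
        )
    return kept


# ---------------------------------------------------------------------------
# Gaussian targets


@dataclass(frozen=True)
class TargetSpec:
    """A 2-D Gaussian luminance deviation embedded in a noise image.

    ``polarity`` is +1 (bright target) when the base image is darker than
    the mean luminance 128 at the target centre, else -1.
    """

    center_x_cm: float
    center_y_cm: float
    sigma_cm: float = DEFAULT_SIGMA_CM
    amplitude: int = 50
    polarity: int = 1


@dataclass(eq=False)
class StimulusPair:
    """One identical image pair differing only by an embedded target."""

    pair_id: str
    base: PerlinImage
    with_target: PerlinImage
    target: TargetSpec
    strength: int
    clamped_pixels: int = 0


def embed_target(
    image: PerlinImage,
    strength: int,
    rng: np.random.Generator,
    *,
    sigma_cm: float = DEFAULT_SIGMA_CM,
    margin_cm: float = DEFAULT_MARGIN_CM,
    allowed_strengths: Sequence[int] | None = DEFAULT_STRENGTHS,
    pair_id: str = "pair",
) -> StimulusPair:
    """Embed a randomly placed Gaussian target, returning the stimulus pair.

    The centre is uniform over the image with ``margin_cm`` clearance from
    every edge (so the 1 cm scoring region lies fully inside).  Contrast
    polarity follows the base luminance at the centre pixel: positive when
    below 128, negative otherwise.  The per-pixel increment is
    polarity * round(strength * exp(-d^2 / (2 sigma^2))) with d in cm; the
    result is clamped to [0, 255] and the clamped-pixel count recorded.
    """
    if allowed_strengths is not None and strength not in allowed_strengths:
        raise ValueError(f"strength {strength} not in allowed set {tuple(allowed_strengths)}")
    side = image.side_cm
    if side < 2 * margin_cm:
        raise ValueError(f"image side {side} cm leaves no room for margin {margin_cm} cm")
    cx = rng.uniform(margin_cm, side - margin_cm)
    cy = rng.uniform(margin_cm, side - margin_cm)

    s = image.scale_px_per_cm
    ci = min(int(cy * s), image.side_px - 1)
    cj = min(int(cx * s), image.side_px - 1)
    polarity = 1 if image.pixels[ci, cj] < MEAN_LUMINANCE else -1

    x, y = image.pixel_centers_cm()
    d2 = (x - cx) ** 2 + (y - cy) ** 2
    increment = np.rint(strength * np.exp(-d2 / (2.0 * sigma_cm**2))).astype(int)
    raw = image.pixels.astype(int) + polarity * increment
    clipped = np.clip(raw, 0, 255)
    clamped = int(np.count_nonzero(raw != clipped))

    target = TargetSpec(
        center_x_cm=float(cx), center_y_cm=float(cy),
        sigma_cm=sigma_cm, amplitude=int(strength), polarity=polarity,
    )
    with_target = PerlinImage(
        pixels=clipped.astype(np.uint8),
        side_cm=image.side_cm,
        scale_px_per_cm=image.scale_px_per_cm,
        lattice_seed=image.lattice_seed,
        grid_cells=image.grid_cells,
        gain=image.gain,
        noise_mean=image.noise_mean,
        anisotropy=image.anisotropy,
    )
    return StimulusPair(
        pair_id=pair_id, base=image, with_target=with_target,
        target=target, strength=int(strength), clamped_pixels=clamped,
    )


def build_stimulus_set(
    n_pairs: int = 30,
    strengths: Sequence[int] = DEFAULT_STRENGTHS,
    seed: int = 0,
    *,
    side_cm: float = DEFAULT_SIDE_CM,
    scale_px_per_cm: float = DEFAULT_SCALE_PX_PER_CM,
    grid_cells: int = DEFAULT_GRID_CELLS,
    sigma_cm: float = DEFAULT_SIGMA_CM,
    margin_cm: float = DEFAULT_MARGIN_CM,
    screening_threshold: float = DEFAULT_ANISOTROPY_THRESHOLD,
    max_candidates: int = 10_000,
) -> list[StimulusPair]:
    """Generate a screened, target-embedded stimulus set.

    Candidate lattices use sequential child seeds derived from ``seed``;
    candidates failing the anisotropy screen are discarded and generation
    continues until n_pairs / len(strengths) pairs exist per strength.
    Fully reproducible: the same seed yields byte-identical pixels.
    """
    strengths = tuple(strengths)
    if n_pairs % len(strengths) != 0:
        raise ValueError(f"n_pairs={n_pairs} not divisible by {len(strengths)} strengths")
    per_strength = n_pairs // len(strengths)
    target_rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(1,)))

    pairs: list[StimulusPair] = []
    quota = {s: per_strength for s in strengths}
    k = 0
    while len(pairs) < n_pairs:
        if k >= max_candidates:
            raise InsufficientStimuliError(
                f"exhausted {max_candidates} candidate seeds with "
                f"{len(pairs)}/{n_pairs} pairs built"
            )
        lattice_seed = (int(seed) * 1_000_003 + k) % (2**31)
        k += 1
        lattice = make_gradient_lattice(lattice_seed, grid_cells)
        img = perlin_noise_image(lattice, side_cm, scale_px_per_cm)
        score = anisotropy_score(img)
        img.anisotropy = score
        if score >= screening_threshold:
            logger.info("rejected lattice seed %d: anisotropy %.3f", lattice_seed, score)
            continue
        strength = strengths[len(pairs) % len(strengths)]
        if quota[strength] == 0:  # round-robin slot already full, find next open
            strength = next(s for s in strengths if quota[s] > 0)
        quota[strength] -= 1
        pair = embed_target(
            img, strength, target_rng,
            sigma_cm=sigma_cm, margin_cm=margin_cm,
            allowed_strengths=strengths,
            pair_id=f"pair{len(pairs):03d}",
        )
        pairs.append(pair)
    return pairs


# ---------------------------------------------------------------------------
# presentation formats


@dataclass(frozen=True)
class PresentationFormat:
    """One of the four ways an image pair is shown to the observer.

    Spatial formats (horizontal, vertical) show both images at once with a
    3 cm gap; sequential formats alternate the two images at the same
    location in 400 ms frames with an inter-stimulus blank of 200 or 0 ms.
    ``remaining_image`` names the image left on screen for target marking
    after the detection response.
    """

    name: str
    separation_cm: float | None = None
    frame_ms: float | None = None
    isi_ms: float | None = None
    time_limit_s: float = 30.0
    remaining_image: str = "last_shown"

    def __post_init__(self):
        if self.name not in FORMAT_NAMES:
            raise ValueError(f"unknown format {self.name!r}; expected one of {FORMAT_NAMES}")
        if self.is_spatial:
            if self.frame_ms is not None or self.isi_ms is not None:
                raise ValueError("spatial formats must not set frame/ISI timing")
            if self.separation_cm is None:
                raise ValueError("spatial formats require separation_cm")
        else:
            if self.separation_cm is not None:
                raise ValueError("sequential formats must not set separation_cm")
            if self.frame_ms is None or self.isi_ms is None:
                raise ValueError("sequential formats require frame_ms and isi_ms")

    @property
    def is_spatial(self) -> bool:
        return self.name in ("horizontal", "vertical")


def standard_formats() -> dict[str, PresentationFormat]:
    """The four study presentation formats with their published timing."""
    return {
        "horizontal": PresentationFormat("horizontal", separation_cm=3.0, remaining_image="right"),
        "vertical": PresentationFormat("vertical", separation_cm=3.0, remaining_image="top"),
        "seq_isi200": PresentationFormat("seq_isi200", frame_ms=400.0, isi_ms=200.0),
        "seq_isi0": PresentationFormat("seq_isi0", frame_ms=400.0, isi_ms=0.0),
    }


@dataclass
class PresentationPlan:
    """Declarative description of how a pair is laid out or scheduled."""

    pair_id: str
    format_name: str
    canvas_cm: tuple[float, float] | None = None
    slots: list[tuple[str, str, tuple[float, float]]] = field(default_factory=list)
    frames: list[tuple[str, float]] = field(default_factory=list)
    remaining_image: str = "last_shown"


def render_presentation(pair: StimulusPair, fmt: PresentationFormat) -> PresentationPlan:
    """Lay out a spatial composite or build a sequential frame schedule.

    Spatial plans give a canvas size (cm) and the top-left offsets of both
    images; sequential plans give an ordered (image, duration_ms) schedule
    alternating the two images, with blanks of isi_ms between frames,
    repeating until the 30 s search limit is filled.
    """
    side = pair.base.side_cm
    plan = PresentationPlan(pair_id=pair.pair_id, format_name=fmt.name,
                            remaining_image=fmt.remaining_image)
    base_id = f"{pair.pair_id}_base"
    target_id = f"{pair.pair_id}_target"
    if fmt.is_spatial:
        sep = fmt.separation_cm
        if fmt.name == "horizontal":
            plan.canvas_cm = (2 * side + sep, side)
            plan.slots = [("left", base_id, (0.0, 0.0)), ("right", target_id, (side + sep, 0.0))]
        else:
            plan.canvas_cm = (side, 2 * side + sep)
            plan.slots = [("top", base_id, (0.0, 0.0)), ("bottom", target_id, (0.0, side + sep))]
    else:
        limit_ms = fmt.time_limit_s * 1000.0
        t = 0.0
        frames: list[tuple[str, float]] = []
        images = (base_id, target_id)
        i = 0
        while t < limit_ms:
            dur = min(fmt.frame_ms, limit_ms - t)
            frames.append((images[i % 2], dur))
            t += dur
            if fmt.isi_ms > 0 and t < limit_ms:
                blank = min(fmt.isi_ms, limit_ms - t)
                frames.append(("blank", blank))
                t += blank
            i += 1
        plan.frames = frames
    return plan
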