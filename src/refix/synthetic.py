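"""Seeded synthetic scanpath cohorts with known ground truth.

The generator emulates the statistical structure every analysis stage
assumes: fixation locations drawn from a blob-shaped priority map with
a tunable exploitation weight, an oculomotor baseline with a forward
bias (von Mises direction about the previous saccade direction, gamma
amplitudes), injected 1-back and 2-back return saccades at known rates,
fixation durations generated from the piecewise-linear saccadic-
momentum model with Gaussian noise, and an additive duration bonus at
return locations on both visits.  Everything flows from one master
seed through named substreams, so regeneration is exact, and a ground-
truth sidecar records every injected return together with all
generative parameters.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from refix.core import Trajectory

logger = logging.getLogger(__name__)


@dataclass
class Blob:
    """One component of the generative priority map (and image layout)."""

    x: float
    y: float
    sigma: float = 1.5
    weight: float = 1.0
    contrast: float = 0.4   # luminance amplitude in the rendered image


def _default_blobs() -> list[Blob]:
    # a central-bias blob plus four peripheral hotspots
    return [Blob(0.0, 0.0, 2.0, 2.0, 0.5),
            Blob(-6.0, 3.5, 1.5, 1.0, 0.4),
            Blob(6.0, 3.5, 1.5, 1.0, 0.4),
            Blob(-6.0, -3.5, 1.5, 1.0, 0.4),
            Blob(6.0, -3.5, 1.5, 1.0, 0.4)]


@dataclass
class CohortSpec:
    """Generative parameters of a synthetic cohort.

    Durations follow the momentum model
    b0 + s1*min(dphi, c) + s2*max(dphi-c, 0) + u*min(da, 0) + o*max(da, 0)
    plus Gaussian noise, with ``return_bonus_ms`` added at return
    locations (both visits).  Trajectory lengths are 3 plus a negative
    binomial draw.  Non-return saccades target a priority-map draw with
    probability ``exploitation_weight`` and otherwise make an
    oculomotor move (von Mises direction around the previous direction
    with concentration ``forward_bias_kappa``, gamma amplitude).
    """

    n_subjects: int = 12
    n_images: int = 8
    trials_per_image: int = 1
    # trajectory length: 3 + NegativeBinomial(r, p) fixations
    length_nb_r: float = 5.0
    length_nb_p: float = 5.0 / 17.0       # mean length 3 + 12 = 15
    screen_extent: tuple[float, float, float, float] = (-12.0, 12.0, -9.0, 9.0)
    # momentum-model parameters (ms, ms/degree, degrees)
    beta0: float = 200.0
    s1: float = 0.383
    s2: float = 0.002
    c: float = 117.0
    u: float = 0.39
    o: float = -2.75
    noise_sd: float = 50.0
    # return injection
    p_return_1back: float = 0.02
    p_return_2back: float = 0.01
    return_jitter: float = 1.0            # radius (deg) of the uniform jitter disc
    #: duration bonus at return locations, applied at both visits of
    #: every realized 1-/2-back revisit (whether injected or arising by
    #: chance): return locations demand extra processing time
    return_bonus_ms: float = 40.0
    bonus_region_radius: float = 2.0      # revisit-detection radius (deg)
    #: exponent of the salience weighting of return injection: a
    #: candidate return is accepted with probability (f/f_max)**bias,
    #: f the blob-mixture density at the n-back location, so returns
    #: preferentially exploit salient locations (0 disables)
    return_salience_bias: float = 1.0
    # fixation selection
    blobs: list[Blob] = field(default_factory=_default_blobs)
    exploitation_weight: float = 0.6
    forward_bias_kappa: float = 0.8
    amplitude_shape: float = 3.0          # gamma shape; mean = shape * scale
    amplitude_scale: float = 2.0
    #: relative between-subject spread of the oculomotor tendencies
    #: (kappa, amplitude scale, exploitation weight); real observers differ
    subject_jitter: float = 0.2
    #: per-image displacement (sd, degrees) of the blob centers, so that
    #: different images carry different salient layouts while sharing
    #: the same global statistics
    image_blob_jitter: float = 1.5
    min_duration_ms: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_return_1back", "p_return_2back",
                     "exploitation_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_return_1back + self.p_return_2back > 1.0:
            raise ValueError("return injection probabilities exceed 1")
        if self.noise_sd < 0 or self.return_jitter < 0:
            raise ValueError("noise and jitter must be non-negative")
        x0, x1, y0, y1 = self.screen_extent
        if x1 <= x0 or y1 <= y0:
            raise ValueError("screen extent is empty")
        w = sum(b.weight for b in self.blobs)
        if self.blobs and w <= 0:
            raise ValueError("blob weights must sum to a positive value")


@dataclass
class Cohort:
    """Generated cohort: trajectories, tidy table, ground-truth sidecar."""

    spec: CohortSpec
    trajectories: list[Trajectory]
    table: pd.DataFrame
    ground_truth: dict

    def dataset_of(self) -> dict[str, str]:
        """Subject -> dataset label (subjects split into two halves)."""
        subjects = sorted({t.subject for t in self.trajectories})
        half = (len(subjects) + 1) // 2
        return {s: ("A" if k < half else "B")
                for k, s in enumerate(subjects)}


def _draw_priority(spec: CohortSpec, rng: np.random.Generator
                   ) -> tuple[float, float]:
    x0, x1, y0, y1 = spec.screen_extent
    if not spec.blobs:
        return rng.uniform(x0, x1), rng.uniform(y0, y1)
    weights = np.array([b.weight for b in spec.blobs], dtype=float)
    weights /= weights.sum()
    for _ in range(100):
        b = spec.blobs[rng.choice(len(spec.blobs), p=weights)]
        x = rng.normal(b.x, b.sigma)
        y = rng.normal(b.y, b.sigma)
        if x0 <= x <= x1 and y0 <= y <= y1:
            return float(x), float(y)
    return rng.uniform(x0, x1), rng.uniform(y0, y1)


def _draw_uniform(spec: CohortSpec, rng: np.random.Generator
                  ) -> tuple[float, float]:
    x0, x1, y0, y1 = spec.screen_extent
    return float(rng.uniform(x0, x1)), float(rng.uniform(y0, y1))


def _jitter_disc(radius: float, rng: np.random.Generator
                 ) -> tuple[float, float]:
    r = radius * np.sqrt(rng.random())
    theta = rng.uniform(0.0, 2.0 * np.pi)
    return float(r * np.cos(theta)), float(r * np.sin(theta))


def _momentum_move(x: float, y: float, prev_dir: float, spec: CohortSpec,
                   rng: np.random.Generator) -> tuple[float, float]:
    """Oculomotor baseline saccade with forward bias, kept on screen."""
    x0, x1, y0, y1 = spec.screen_extent
    for _ in range(50):
        if spec.forward_bias_kappa > 0:
            direction = rng.vonmises(np.radians(prev_dir),
                                     spec.forward_bias_kappa)
        else:
            direction = rng.uniform(-np.pi, np.pi)
        amp = rng.gamma(spec.amplitude_shape, spec.amplitude_scale)
        nx, ny = x + amp * np.cos(direction), y + amp * np.sin(direction)
        if x0 <= nx <= x1 and y0 <= ny <= y1:
            return float(nx), float(ny)
    return _draw_uniform(spec, rng)


def _blob_density(x: float, y: float, spec: CohortSpec) -> float:
    if not spec.blobs:
        return 1.0
    total = 0.0
    for b in spec.blobs:
        total += (b.weight / (2 * np.pi * b.sigma ** 2)
                  * np.exp(-((x - b.x) ** 2 + (y - b.y) ** 2)
                           / (2 * b.sigma ** 2)))
    return total


def _blob_density_max(spec: CohortSpec) -> float:
    if not spec.blobs:
        return 1.0
    return max(_blob_density(b.x, b.y, spec) for b in spec.blobs)


def _piecewise_duration(dphi: float, da: float, spec: CohortSpec) -> float:
    return (spec.beta0 + spec.s1 * min(dphi, spec.c)
            + spec.s2 * max(dphi - spec.c, 0.0)
            + spec.u * min(da, 0.0) + spec.o * max(da, 0.0))


def _turning(x: np.ndarray, y: np.ndarray, j: int) -> tuple[float, float]:
    """(dphi, da) of outgoing vs incoming saccade at interior fixation j."""
    v1 = np.array([x[j] - x[j - 1], y[j] - y[j - 1]])
    v2 = np.array([x[j + 1] - x[j], y[j + 1] - y[j]])
    a1, a2 = np.hypot(*v1), np.hypot(*v2)
    if a1 == 0 or a2 == 0:
        return 0.0, float(a2 - a1)
    dot = float(v1 @ v2)
    cross = float(v1[0] * v2[1] - v1[1] * v2[0])
    return float(np.degrees(abs(np.arctan2(cross, dot)))), float(a2 - a1)


def image_blob_layouts(spec: CohortSpec, seed: int) -> dict[str, list[Blob]]:
    """Per-image blob layouts: the cohort's base blobs displaced per image.

    Derived deterministically from the seed (independent substream), so
    :func:`generate_cohort` and :func:`generate_images` agree on the
    layouts when called with the same seed.  Displaced centers are
    clipped to the screen.
    """
    rng = np.random.default_rng([seed, 104729])
    x0, x1, y0, y1 = spec.screen_extent
    layouts: dict[str, list[Blob]] = {}
    for ii in range(spec.n_images):
        blobs = []
        for b in spec.blobs:
            bx = float(np.clip(b.x + spec.image_blob_jitter
                               * rng.standard_normal(), x0, x1))
            by = float(np.clip(b.y + spec.image_blob_jitter
                               * rng.standard_normal(), y0, y1))
            blobs.append(Blob(bx, by, b.sigma, b.weight, b.contrast))
        layouts[f"img{ii:03d}"] = blobs
    return layouts


def generate_cohort(spec: CohortSpec | None = None,
                    seed: int | None = None) -> Cohort:
    """Generate a full synthetic cohort from the spec (deterministic per seed)."""
    spec = spec or CohortSpec()
    spec.validate()
    used_seed = int(spec.seed if seed is None else seed)
    master = np.random.default_rng(used_seed)
    layouts = image_blob_layouts(spec, used_seed)
    trajectories: list[Trajectory] = []
    injected: list[dict] = []
    rows = []
    for si in range(spec.n_subjects):
        subject = f"s{si:03d}"
        rng = np.random.default_rng(master.integers(2 ** 31))
        jit = spec.subject_jitter
        subj_spec = dataclasses.replace(
            spec,
            forward_bias_kappa=max(
                spec.forward_bias_kappa * (1 + jit * rng.standard_normal()), 0.0),
            amplitude_scale=max(
                spec.amplitude_scale * (1 + jit * rng.standard_normal()), 0.1),
            exploitation_weight=float(np.clip(
                spec.exploitation_weight * (1 + jit * rng.standard_normal()),
                0.0, 1.0)))
        for ii in range(spec.n_images):
            image = f"img{ii:03d}"
            img_spec = dataclasses.replace(subj_spec, blobs=layouts[image])
            for ti in range(spec.trials_per_image):
                trial = f"t{ti:02d}"
                L = 3 + int(rng.negative_binomial(spec.length_nb_r,
                                                  spec.length_nb_p))
                x = np.empty(L)
                y = np.empty(L)
                events = []
                for i in range(L):
                    if i < 2:
                        if rng.random() < spec.exploitation_weight:
                            x[i], y[i] = _draw_priority(img_spec, rng)
                        else:
                            x[i], y[i] = _draw_uniform(img_spec, rng)
                        continue
                    roll = rng.random()
                    if roll < spec.p_return_1back:
                        nback = 1
                    elif roll < spec.p_return_1back + spec.p_return_2back \
                            and i >= 3:
                        nback = 2
                    else:
                        nback = 0
                    if nback and spec.return_salience_bias > 0:
                        # returns exploit salient spots: accept the
                        # candidate in proportion to local priority
                        tgt = i - 1 - nback
                        w = (_blob_density(x[tgt], y[tgt], img_spec)
                             / _blob_density_max(img_spec)
                             ) ** spec.return_salience_bias
                        if rng.random() >= w:
                            nback = 0
                    if nback:
                        jx, jy = _jitter_disc(spec.return_jitter, rng)
                        tgt = i - 1 - nback
                        x[i], y[i] = x[tgt] + jx, y[tgt] + jy
                        events.append({"subject": subject, "image": image,
                                       "trial": trial, "fix_index": i,
                                       "nback": nback,
                                       "first_visit": tgt})
                    elif rng.random() < spec.exploitation_weight:
                        x[i], y[i] = _draw_priority(img_spec, rng)
                    else:
                        prev_dir = np.degrees(np.arctan2(y[i - 1] - y[i - 2],
                                                         x[i - 1] - x[i - 2]))
                        x[i], y[i] = _momentum_move(x[i - 1], y[i - 1],
                                                    prev_dir, img_spec, rng)
                model_dur = np.full(L, spec.beta0)
                for j in range(1, L - 1):
                    dphi, da = _turning(x, y, j)
                    model_dur[j] = _piecewise_duration(dphi, da, spec)
                bonus = np.zeros(L)
                bonused: set[tuple[int, int]] = set()
                for i in range(2, L):
                    for nb in (1, 2):
                        j = i - 1 - nb
                        if j < 0:
                            continue
                        if (np.hypot(x[i] - x[j], y[i] - y[j])
                                < spec.bonus_region_radius):
                            bonused.add((j, i))
                for j, i in bonused:
                    bonus[i] += spec.return_bonus_ms
                    bonus[j] += spec.return_bonus_ms
                dur = model_dur + bonus + rng.normal(0.0, spec.noise_sd, L)
                dur = np.maximum(dur, spec.min_duration_ms)
                trajectories.append(Trajectory(subject, image, trial,
                                               x.copy(), y.copy(), dur))
                injected.extend(events)
                for i in range(L):
                    rows.append((subject, image, trial, i, x[i], y[i],
                                 dur[i], model_dur[i]))
    table = pd.DataFrame(rows, columns=["subject", "image", "trial",
                                        "fix_index", "x", "y", "duration",
                                        "model_duration"])
    params = dataclasses.asdict(spec)
    params["blobs"] = [dataclasses.asdict(b) for b in spec.blobs]
    ground_truth = {
        "parameters": params,
        "seed": used_seed,
        "injected_returns": injected,
        "n_fixations": int(len(table)),
    }
    return Cohort(spec, trajectories, table, ground_truth)


def generate_momentum_observations(n: int, spec: CohortSpec | None = None,
                                   seed: int | None = None
                                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (dphi, da, duration) triples directly from the momentum model.

    Angle differences are uniform on [0, 180] degrees and amplitude
    differences uniform on [-8, 8]; durations are the piecewise model
    plus Gaussian noise.  Used for parameter-recovery studies where the
    generative truth must be exactly the regression model.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    dphi = rng.uniform(0.0, 180.0, n)
    da = rng.uniform(-8.0, 8.0, n)
    mean = np.array([_piecewise_duration(p, a, spec)
                     for p, a in zip(dphi, da)])
    dur = mean + rng.normal(0.0, spec.noise_sd, n)
    return dphi, da, dur


def generate_images(spec: CohortSpec | None = None,
                    pixels_per_degree: float = 12.0,
                    seed: int | None = None,
                    link_to_priority: bool = True) -> dict[str, np.ndarray]:
    """Render one RGB raster per image id: Gaussian blobs on gray ground.

    With ``link_to_priority`` the blob centers coincide with the
    priority-map components, so fixations sampled from the map land on
    high-contrast image structure; contrast amplitudes vary slightly
    between images (seeded).  Zero blobs yield a constant image.
    """
    spec = spec or CohortSpec()
    used_seed = int(spec.seed if seed is None else seed)
    rng = np.random.default_rng(used_seed)
    layouts = image_blob_layouts(spec, used_seed)
    x0, x1, y0, y1 = spec.screen_extent
    w = int(round((x1 - x0) * pixels_per_degree))
    h = int(round((y1 - y0) * pixels_per_degree))
    # pixel grid in degrees: x rightward, y upward (row 0 is the top)
    xs = x0 + (np.arange(w) + 0.5) / pixels_per_degree
    ys = y1 - (np.arange(h) + 0.5) / pixels_per_degree
    gx, gy = np.meshgrid(xs, ys)
    images: dict[str, np.ndarray] = {}
    for ii in range(spec.n_images):
        blobs = layouts[f"img{ii:03d}"] if link_to_priority else []
        lum = np.full((h, w), 0.5)
        for b in blobs:
            amp = b.contrast * rng.uniform(0.8, 1.2)
            lum += amp * np.exp(-((gx - b.x) ** 2 + (gy - b.y) ** 2)
                                / (2 * b.sigma ** 2))
        lum = np.clip(lum, 0.0, 1.0)
        img = np.repeat(lum[..., None], 3, axis=2)
        images[f"img{ii:03d}"] = (img * 255).astype(np.uint8)
    return images


def save_images(images: dict[str, np.ndarray], directory) -> list:
    """Write rendered images as PNGs named after their image ids."""
    import pathlib

    import imageio.v3 as iio

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for image_id, img in images.items():
        path = directory / f"{image_id}.png"
        iio.imwrite(path, img)
        paths.append(path)
    return paths


def degrees_to_pixels(x: np.ndarray, y: np.ndarray,
                      spec: CohortSpec, pixels_per_degree: float = 12.0
                      ) -> np.ndarray:
    """Map screen-centered degree coordinates to (col, row) pixels of
    the rendered synthetic images (linear mapping, y flips downward)."""
    x0, x1, y0, y1 = spec.screen_extent
    col = (np.asarray(x) - x0) * pixels_per_degree - 0.5
    row = (y1 - np.asarray(y)) * pixels_per_degree - 0.5
    return np.column_stack([col, row])
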