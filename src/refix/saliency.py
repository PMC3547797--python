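"""Bottom-up image feature bank and fixated-vs-control AUC analysis.

The core feature bank crosses four color channels (luminance,
saturation, red/green, blue/yellow) with three spatial scales of a
Gaussian pyramid and three filters (Gaussian smoothing, local contrast,
texture contrast), giving 36 maps.  Local contrast of a map F is
sqrt(max(0, G*F^2 - (G*F)^2)) with a Gaussian kernel G — a smoothed
local standard deviation; texture contrast applies the same operator
twice.  Additional features (phase congruency, intrinsic
dimensionality, interactions) can be contributed through the plugin
registry; all downstream machinery is agnostic to the roster.

Feature quality is scored as the AUC separating feature values at
fixated locations from values at control locations drawn from fixations
on *other* images, which matches the spatial bias of gaze without using
truly fixated pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter
from skimage.transform import pyramid_reduce, resize
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

CHANNELS = ("luminance", "saturation", "red_green", "blue_yellow")
FILTERS = ("smooth", "local_contrast", "texture_contrast")

#: plugin registry: name -> callable(image: float array HxWx3) -> list[FeatureMap]
FEATURE_PLUGINS: dict[str, Callable] = {}


def register_feature_plugin(name: str, fn: Callable) -> None:
    """Register an additional feature-map generator (e.g. phase congruency)."""
    FEATURE_PLUGINS[name] = fn


@dataclass
class FeatureMap:
    name: str
    scale: int
    filter: str
    data: np.ndarray
    zscored: bool = False
    degenerate: bool = False


def color_channels(image: np.ndarray) -> dict[str, np.ndarray]:
    """Split an RGB image into the four opponent/intensity channels.

    luminance = mean(R, G, B); red/green = R - G;
    blue/yellow = B - (R + G)/2; saturation = max - min.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    if img.max() > 1.0:
        img = img / 255.0
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    return {
        "luminance": (r + g + b) / 3.0,
        "saturation": img.max(axis=2) - img.min(axis=2),
        "red_green": r - g,
        "blue_yellow": b - (r + g) / 2.0,
    }


def local_contrast(channel: np.ndarray, sigma: float) -> np.ndarray:
    """Smoothed local standard deviation sqrt(max(0, G*F^2 - (G*F)^2)).

    Convolutions use reflective padding.
    """
    m = gaussian_filter(channel, sigma, mode="reflect")
    m2 = gaussian_filter(channel ** 2, sigma, mode="reflect")
    return np.sqrt(np.maximum(m2 - m ** 2, 0.0))


def zscore_map(data: np.ndarray, tol: float = 1e-12
               ) -> tuple[np.ndarray, bool]:
    """Z-score a map over all pixels; constant maps become all-zero.

    Returns (map, degenerate_flag).  Idempotent for non-degenerate maps.
    """
    sd = data.std()
    if sd < tol:
        return np.zeros_like(data), True
    return (data - data.mean()) / sd, False


def compute_feature_bank(image: np.ndarray, scales: int = 3,
                         sigma_smooth: float = 10.0,
                         sigma_contrast: float = 5.0,
                         pixels_per_degree: float | None = None,
                         plugins: Sequence[str] | None = None
                         ) -> list[FeatureMap]:
    """Compute the 36-map core feature bank (plus any requested plugins).

    Sigmas are in pixels of the finest scale; when ``pixels_per_degree``
    is given they default to 1 degree (smoothing) and 0.5 degrees
    (contrast kernel).  Scale ``s`` downsamples by ``2**s`` through a
    Gaussian pyramid and the sigmas shrink with the image so each map
    measures the same physical neighborhood; coarse maps are upsampled
    back to image resolution for lookup.  Every map is z-scored per
    image.
    """
    channels = color_channels(image)
    if pixels_per_degree is not None:
        sigma_smooth = 1.0 * pixels_per_degree
        sigma_contrast = 0.5 * pixels_per_degree
    shape = image.shape[:2]
    out: list[FeatureMap] = []
    for name in CHANNELS:
        level = channels[name]
        for s in range(scales):
            if s > 0:
                level = pyramid_reduce(level, downscale=2, channel_axis=None)
            ss = sigma_smooth / 2 ** s
            sc = sigma_contrast / 2 ** s
            if int(4 * max(ss, sc)) + 1 > min(level.shape):
                raise ValueError(
                    f"filter kernel exceeds image size at scale {s}: "
                    f"sigma {max(ss, sc):.1f}px vs image {level.shape}")
            maps = {
                "smooth": gaussian_filter(level, ss, mode="reflect"),
                "local_contrast": local_contrast(level, sc),
            }
            maps["texture_contrast"] = local_contrast(
                maps["local_contrast"], sc)
            for filt in FILTERS:
                data = maps[filt]
                if data.shape != shape:
                    data = resize(data, shape, order=1, mode="reflect",
                                  anti_aliasing=False)
                data, degenerate = zscore_map(data)
                out.append(FeatureMap(name=f"{name}_{filt}_s{s}", scale=s,
                                      filter=filt, data=data, zscored=True,
                                      degenerate=degenerate))
    for pname in (plugins if plugins is not None else FEATURE_PLUGINS):
        for fm in FEATURE_PLUGINS[pname](np.asarray(image, dtype=float)):
            data, degenerate = zscore_map(fm.data)
            out.append(FeatureMap(fm.name, fm.scale, fm.filter, data,
                                  zscored=True, degenerate=degenerate))
    return out


def save_feature_map(fm: FeatureMap, path) -> None:
    """Export a map as a flat float32 raster with a JSON sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    fm.data.astype(np.float32).tofile(path)
    sidecar = {"name": fm.name, "scale": fm.scale, "filter": fm.filter,
               "shape": list(fm.data.shape), "dtype": "float32",
               "zscored": fm.zscored, "degenerate": fm.degenerate}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_feature_map(path) -> FeatureMap:
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.fromfile(path, dtype=np.float32).reshape(meta["shape"])
    return FeatureMap(meta["name"], meta["scale"], meta["filter"],
                      data.astype(float), meta["zscored"], meta["degenerate"])


def lookup(feature: FeatureMap | np.ndarray, xy_px: np.ndarray) -> np.ndarray:
    """Feature values at pixel coordinates (nearest pixel, no interpolation).

    ``xy_px`` is (n, 2) as (column, row) pixel positions; coordinates
    are clipped to the raster.
    """
    data = feature.data if isinstance(feature, FeatureMap) else feature
    xy = np.atleast_2d(np.asarray(xy_px, dtype=float))
    col = np.clip(np.rint(xy[:, 0]).astype(int), 0, data.shape[1] - 1)
    row = np.clip(np.rint(xy[:, 1]).astype(int), 0, data.shape[0] - 1)
    return data[row, col]


def sample_controls(target_image: str,
                    fixations_by_image: dict[str, np.ndarray], n: int,
                    seed: int | None = None) -> np.ndarray:
    """Control locations for an image: fixations made on *other* images.

    Draws ``n`` locations with replacement from the pooled fixations on
    all images except the target, preserving the corpus' spatial bias.
    """
    pools = [np.atleast_2d(v) for k, v in fixations_by_image.items()
             if k != target_image and len(v)]
    if not pools:
        raise ValueError("need fixations on at least one other image")
    pool = np.vstack(pools)
    rng = np.random.default_rng(seed)
    if n == 0:
        return np.empty((0, pool.shape[1]))
    return pool[rng.integers(0, len(pool), size=n)]


def auc_mann_whitney(positives: np.ndarray, controls: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U statistic; ties count 0.5."""
    pos = np.asarray(positives, dtype=float)
    ctl = np.asarray(controls, dtype=float)
    if len(pos) == 0 or len(ctl) == 0:
        raise ValueError("both groups must be non-empty")
    u = stats.mannwhitneyu(pos, ctl, alternative="two-sided").statistic
    return float(u / (len(pos) * len(ctl)))


@dataclass
class AucResult:
    feature: str
    auc: float
    ci_low: float
    ci_high: float
    repeats: np.ndarray = field(repr=False, default=None)
    degenerate: bool = False


def feature_auc(positive_values: np.ndarray, control_values: np.ndarray,
                n_repeats: int = 150, n_per_draw: int = 1000,
                n_boot: int = 2000, seed: int | None = None,
                feature: str = "") -> AucResult:
    """AUC of a feature for separating fixated from control locations.

    Each of ``n_repeats`` repeats subsamples ``n_per_draw`` values per
    group (without replacement when the pool allows) and computes the
    Mann-Whitney AUC; the point estimate is the mean over repeats and
    the CI a percentile bootstrap over the repeat values.
    """
    pos = np.asarray(positive_values, dtype=float)
    ctl = np.asarray(control_values, dtype=float)
    if len(pos) == 0 or len(ctl) == 0:
        raise ValueError("value samples must be non-empty")
    if np.ptp(pos) == 0 and np.ptp(ctl) == 0 and pos[0] == ctl[0]:
        return AucResult(feature, 0.5, 0.5, 0.5,
                         np.full(n_repeats, 0.5), degenerate=True)
    rng = np.random.default_rng(seed)

    def draw(pool: np.ndarray) -> np.ndarray:
        if len(pool) >= n_per_draw:
            return rng.choice(pool, size=n_per_draw, replace=False)
        return rng.choice(pool, size=n_per_draw, replace=True)

    repeats = np.array([auc_mann_whitney(draw(pos), draw(ctl))
                        for _ in range(n_repeats)])
    idx = rng.integers(0, n_repeats, size=(n_boot, n_repeats))
    boot = repeats[idx].mean(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return AucResult(feature, float(repeats.mean()), float(lo), float(hi),
                     repeats)


@dataclass
class SaliencyModelResult:
    """Leave-one-subject-out evaluation of a linear saliency combination."""

    model: str                       # "RS" or "FIX"
    auc_return: float                # mean over folds, return locations vs controls
    auc_fixation: float              # mean over folds, normal fixations vs controls
    fold_aucs: pd.DataFrame          # per held-out subject
    weights: np.ndarray              # mean weight vector over folds


def fit_saliency_model(positives_by_subject: dict[str, np.ndarray],
                       controls_by_subject: dict[str, np.ndarray],
                       eval_return_by_subject: dict[str, np.ndarray],
                       eval_fix_by_subject: dict[str, np.ndarray],
                       l2: float = 0.0, model: str = "",
                       max_iter: int = 1000) -> SaliencyModelResult:
    """Logistic saliency combination with leave-one-subject-out CV.

    For each held-out subject a logistic regression is trained on the
    remaining subjects' positive samples (rows of z-scored feature
    values) against their control samples; the learned score is then
    evaluated on the held-out subject as two AUCs: return locations vs
    controls and normal fixations vs controls.  The regression is
    unregularized by default; a small L2 penalty may be supplied for
    separable folds (logged).
    """
    subjects = sorted(set(positives_by_subject) & set(controls_by_subject))
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    rows, weight_list = [], []
    for held in subjects:
        train_pos = [positives_by_subject[s] for s in subjects
                     if s != held and len(positives_by_subject[s])]
        train_ctl = [controls_by_subject[s] for s in subjects if s != held]
        if not train_pos:
            logger.warning("fold %s skipped: no positive training samples", held)
            continue
        X = np.vstack(train_pos + train_ctl)
        y = np.concatenate([np.ones(sum(len(p) for p in train_pos)),
                            np.zeros(sum(len(c) for c in train_ctl))])
        if l2 > 0:
            logger.info("fold %s: using L2 penalty %g", held, l2)
            clf = LogisticRegression(C=1.0 / l2, max_iter=max_iter)
        else:
            clf = LogisticRegression(C=np.inf, max_iter=max_iter)
        clf.fit(X, y)
        w = clf.coef_.ravel()
        ctl_scores = controls_by_subject[held] @ w
        fold = {"subject": held}
        for label, samples in (("return", eval_return_by_subject.get(held)),
                               ("fixation", eval_fix_by_subject.get(held))):
            if samples is None or len(samples) == 0:
                fold[f"auc_{label}"] = np.nan
                continue
            scores = samples @ w
            yy = np.concatenate([np.ones(len(scores)), np.zeros(len(ctl_scores))])
            fold[f"auc_{label}"] = roc_auc_score(
                yy, np.concatenate([scores, ctl_scores]))
        rows.append(fold)
        weight_list.append(w)
    if not rows:
        raise ValueError("all folds were skipped")
    folds = pd.DataFrame(rows).set_index("subject")
    return SaliencyModelResult(
        model=model,
        auc_return=float(folds["auc_return"].mean()),
        auc_fixation=float(folds["auc_fixation"].mean()),
        fold_aucs=folds, weights=np.mean(weight_list, axis=0))


def rs_fix_model_comparison(return_by_subject: dict[str, np.ndarray],
                            fix_by_subject: dict[str, np.ndarray],
                            controls_by_subject: dict[str, np.ndarray],
                            l2: float = 0.0) -> pd.DataFrame:
    """The 2x2 of saliency models: RS/FIX training x return/fixation eval."""
    rs = fit_saliency_model(return_by_subject, controls_by_subject,
                            return_by_subject, fix_by_subject,
                            l2=l2, model="RS")
    fix = fit_saliency_model(fix_by_subject, controls_by_subject,
                             return_by_subject, fix_by_subject,
                             l2=l2, model="FIX")
    return pd.DataFrame(
        {"auc_return": [rs.auc_return, fix.auc_return],
         "auc_fixation": [rs.auc_fixation, fix.auc_fixation]},
        index=["RS", "FIX"])


@dataclass
class AucPatternFit:
    slope: float
    intercept: float
    r2: float
    t_slope_vs_1: float
    p_slope_vs_1: float


def auc_pattern_regression(auc_fixation: np.ndarray, auc_return: np.ndarray
                           ) -> AucPatternFit:
    """OLS of return-location AUC on fixation AUC across features.

    A slope above 1 in this orientation means predictive features
    (AUC > 0.5) predict return locations even better, and
    anti-predictive features are more anti-predictive there (the
    pattern of feature contributions is amplified, not reshuffled, at
    return locations).  The slope is tested against 1.0 with a
    two-sided t-test (df = n - 2).
    """
    x = np.asarray(auc_fixation, dtype=float)
    y = np.asarray(auc_return, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 features")
    fit = stats.linregress(x, y)
    if fit.stderr == 0:
        t = np.inf if fit.slope != 1.0 else 0.0
        p = 0.0 if fit.slope != 1.0 else 1.0
    else:
        t = (fit.slope - 1.0) / fit.stderr
        p = 2.0 * stats.t.sf(abs(t), df=len(x) - 2)
    return AucPatternFit(slope=float(fit.slope), intercept=float(fit.intercept),
                         r2=float(fit.rvalue ** 2), t_slope_vs_1=float(t),
                         p_slope_vs_1=float(p))
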