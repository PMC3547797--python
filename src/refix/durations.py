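"""Fixation-duration models.

The saccadic-momentum regression predicts the duration of fixation B in
a triplet A -> B -> C from the turning angle ``dphi`` and the amplitude
difference ``da`` between the incoming (A->B) and outgoing (B->C)
saccades:

    d(dphi, da) = b0 + s1*min(dphi, c) + s2*max(dphi - c, 0)
                     + u*min(da, 0) + o*max(da, 0)

The angle term is piecewise linear with a free critical angle ``c``
(the breakpoint) and the amplitude term changes slope at ``da = 0``
(undershoot slope ``u``, overshoot slope ``o``).  The model is
continuous at both breakpoints by construction.  The rival "inhibitory
hill" model instead predicts B's duration from the distance between A
and C through a Gaussian kernel centered on A:

    d_B = intercept + k * exp(-||C - A||^2 / (2 sigma^2))

Both are fitted by least squares, the breakpoint and kernel width by
profiling over a grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from refix.core import Trajectory, compute_saccades, pair_deltas

logger = logging.getLogger(__name__)


def momentum_observations(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Per-fixation (dphi, da, duration) triples for the duration models.

    One row per interior fixation B of every A -> B -> C triplet, with
    the coordinates of A, B and C retained for the hill model.
    """
    rows = []
    for t in trajectories:
        for d in pair_deltas(t, nback=1):
            j = d.saccade_index  # outgoing saccade B -> C; B has index j
            rows.append((t.subject, t.image, t.trial, j, d.dphi, d.da,
                         t.duration[j],
                         t.x[j - 1], t.y[j - 1], t.x[j], t.y[j],
                         t.x[j + 1], t.y[j + 1]))
    return pd.DataFrame(rows, columns=[
        "subject", "image", "trial", "fix_index", "dphi", "da", "duration",
        "ax", "ay", "bx", "by", "cx", "cy"])


@dataclass
class PiecewiseFit:
    """Fitted saccadic-momentum breakpoint regression."""

    beta0: float
    s1: float
    s2: float
    c: float
    u: float
    o: float
    r2: float
    sse: float
    residuals: np.ndarray
    c_identifiable: bool = True

    def predict(self, dphi, da) -> np.ndarray:
        dphi = np.asarray(dphi, dtype=float)
        da = np.asarray(da, dtype=float)
        return (self.beta0
                + self.s1 * np.minimum(dphi, self.c)
                + self.s2 * np.maximum(dphi - self.c, 0.0)
                + self.u * np.minimum(da, 0.0)
                + self.o * np.maximum(da, 0.0))


def _design(dphi: np.ndarray, da: np.ndarray, c: float) -> np.ndarray:
    return np.column_stack([
        np.ones_like(dphi),
        np.minimum(dphi, c),
        np.maximum(dphi - c, 0.0),
        np.minimum(da, 0.0),
        np.maximum(da, 0.0),
    ])


def _solve(dphi, da, dur, c):
    X = _design(dphi, da, c)
    beta, _, _, _ = np.linalg.lstsq(X, dur, rcond=None)
    resid = dur - X @ beta
    return beta, float(resid @ resid), resid


def fit_piecewise(dphi: np.ndarray, da: np.ndarray, duration: np.ndarray,
                  c_grid: np.ndarray | None = None,
                  min_observations: int = 20) -> PiecewiseFit:
    """Fit the breakpoint regression; the critical angle is profiled.

    For each candidate ``c`` (1-degree grid from 10 to 170 by default)
    the remaining parameters have a closed-form least-squares solution;
    the SSE-minimizing ``c`` is refined by bounded scalar minimization
    within +/- 1 degree.  When the breakpoint does not improve on a
    single-slope fit the returned ``c_identifiable`` flag is False.
    """
    dphi = np.asarray(dphi, dtype=float)
    da = np.asarray(da, dtype=float)
    dur = np.asarray(duration, dtype=float)
    if len(dphi) < min_observations:
        raise ValueError(f"need at least {min_observations} observations, "
                         f"got {len(dphi)}")
    if np.ptp(dphi) == 0:
        raise ValueError("degenerate design: all angle differences are equal")
    if c_grid is None:
        c_grid = np.arange(10.0, 170.0 + 0.5, 1.0)
    sses = np.array([_solve(dphi, da, dur, c)[1] for c in c_grid])
    k = int(np.argmin(sses))  # argmin ties break toward the smaller c
    lo = c_grid[max(k - 1, 0)]
    hi = c_grid[min(k + 1, len(c_grid) - 1)]
    res = optimize.minimize_scalar(lambda c: _solve(dphi, da, dur, c)[1],
                                   bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-6})
    c_best = float(res.x)
    beta, sse, resid = _solve(dphi, da, dur, c_best)
    if sse > res.fun:
        c_best = float(c_grid[k])
        beta, sse, resid = _solve(dphi, da, dur, c_best)

    # identifiability: a single angle slope (no break) fitting as well
    # as the profiled breakpoint means c is not determined by the data
    Xlin = np.column_stack([np.ones_like(dphi), dphi,
                            np.minimum(da, 0.0), np.maximum(da, 0.0)])
    blin, _, _, _ = np.linalg.lstsq(Xlin, dur, rcond=None)
    rlin = dur - Xlin @ blin
    sse_lin = float(rlin @ rlin)
    sst = float(np.sum((dur - dur.mean()) ** 2))
    scale = sst if sst > 0 else max(sse_lin, 1.0)
    identifiable = (sse_lin - sse) / scale > 1e-9
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    return PiecewiseFit(beta0=float(beta[0]), s1=float(beta[1]),
                        s2=float(beta[2]), c=c_best, u=float(beta[3]),
                        o=float(beta[4]), r2=float(r2), sse=sse,
                        residuals=resid, c_identifiable=bool(identifiable))


def fit_piecewise_per_subject(obs: pd.DataFrame, **kwargs
                              ) -> dict[str, PiecewiseFit]:
    """Fit the momentum model separately for each subject.

    ``obs`` is the frame from :func:`momentum_observations`; subjects
    with too few observations are skipped with a warning.
    """
    fits: dict[str, PiecewiseFit] = {}
    for s, g in obs.groupby("subject"):
        try:
            fits[s] = fit_piecewise(g["dphi"].to_numpy(), g["da"].to_numpy(),
                                    g["duration"].to_numpy(), **kwargs)
        except ValueError as err:
            logger.warning("subject %s: momentum fit skipped (%s)", s, err)
    return fits


@dataclass
class HillFit:
    """Fitted Gaussian inhibitory-hill model."""

    intercept: float
    k: float
    sigma: float
    r2: float
    sse: float
    residuals: np.ndarray


def fit_hill(dist_ac: np.ndarray, duration: np.ndarray,
             sigma_grid: np.ndarray | None = None) -> HillFit:
    """Fit the inhibitory-hill model by profiling the hill width.

    ``dist_ac`` is the distance between fixations A and C of each
    triplet.  For every sigma on the grid the intercept and hill height
    are linear least squares; the best sigma minimizes the SSE.  The
    reported ``r2`` is the variance explained on the provided response
    (which may itself be a residual series).
    """
    if sigma_grid is None:
        sigma_grid = np.arange(0.25, 8.0 + 0.125, 0.25)
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if sigma_grid.size == 0:
        raise ValueError("sigma grid must be non-empty")
    d = np.asarray(dist_ac, dtype=float)
    y = np.asarray(duration, dtype=float)
    best = None
    for sigma in sigma_grid:
        X = np.column_stack([np.ones_like(d), np.exp(-d ** 2 / (2 * sigma ** 2))])
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sse = float(resid @ resid)
        if best is None or sse < best[0]:
            best = (sse, sigma, beta, resid)
    sse, sigma, beta, resid = best
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    return HillFit(intercept=float(beta[0]), k=float(beta[1]),
                   sigma=float(sigma), r2=float(r2), sse=sse, residuals=resid)


@dataclass
class DurationMap:
    """Binned mean fixation durations over (dphi, da) cells."""

    dphi_edges: np.ndarray
    da_edges: np.ndarray
    mean: np.ndarray    # (n_dphi, n_da), NaN where empty
    count: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    @property
    def global_mean(self) -> float:
        m = self.count > 0
        return float(np.sum(self.mean[m] * self.count[m]) / self.count[m].sum())


def binned_duration_map(dphi: np.ndarray, da: np.ndarray,
                        duration: np.ndarray, dphi_bin: float = 30.0,
                        da_bin: float = 2.0,
                        da_range: tuple[float, float] | None = None
                        ) -> DurationMap:
    """Mean duration per (dphi, da) cell with normal-approximation CIs.

    Default binning is 30 degrees by 2 degrees; pass 1.0/1.0 for the
    fine-grained map.  Empty cells are NaN.
    """
    if dphi_bin <= 0 or da_bin <= 0:
        raise ValueError("bin widths must be positive")
    dphi = np.asarray(dphi, dtype=float)
    da = np.asarray(da, dtype=float)
    dur = np.asarray(duration, dtype=float)
    dphi_edges = np.arange(0.0, 180.0 + dphi_bin / 2, dphi_bin)
    if da_range is None:
        da_range = (np.floor(da.min() / da_bin) * da_bin,
                    np.ceil(da.max() / da_bin) * da_bin)
    da_edges = np.arange(da_range[0], da_range[1] + da_bin / 2, da_bin)
    mean, _, _, _ = stats.binned_statistic_2d(
        dphi, da, dur, statistic="mean", bins=[dphi_edges, da_edges])
    count, _, _, _ = stats.binned_statistic_2d(
        dphi, da, dur, statistic="count", bins=[dphi_edges, da_edges])
    sd, _, _, _ = stats.binned_statistic_2d(
        dphi, da, dur, statistic="std", bins=[dphi_edges, da_edges])
    with np.errstate(invalid="ignore", divide="ignore"):
        half = 1.96 * sd / np.sqrt(count)
    return DurationMap(dphi_edges, da_edges, mean, count.astype(int),
                       mean - half, mean + half)


def residual_null_band(residuals: np.ndarray, counts: np.ndarray,
                       n_boot: int = 2000, seed: int | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Sampling-density-dependent null band for residual cell means.

    Under the null that residuals carry no (dphi, da) structure, the
    mean of a cell with n observations is distributed like the mean of
    n draws from the pooled residual distribution.  Returns the 2.5 and
    97.5 percentile surfaces for the given per-cell counts (cells with
    zero observations are NaN); bands widen where sampling is sparse.
    """
    rng = np.random.default_rng(seed)
    pool = np.asarray(residuals, dtype=float)
    counts = np.asarray(counts)
    lo = np.full(counts.shape, np.nan)
    hi = np.full(counts.shape, np.nan)
    for idx in np.ndindex(counts.shape):
        n = int(counts[idx])
        if n == 0:
            continue
        draws = rng.choice(pool, size=(n_boot, n), replace=True).mean(axis=1)
        lo[idx], hi[idx] = np.percentile(draws, [2.5, 97.5])
    return lo, hi


def find_return_event(traj: Trajectory,
                      nback: int | Sequence[int] | None = 1,
                      radius: float = 2.0) -> tuple[int, int] | None:
    """First return event under the region criterion.

    Returns (first_visit_index, second_visit_index) for the earliest
    fixation i that lands strictly within ``radius`` of fixation
    ``i - 1 - n`` for one of the requested look-back depths ``n`` (an
    int or a sequence of ints).  With ``nback=None`` any earlier
    fixation j <= i - 2 qualifies and the nearest one is taken.  None
    when the trajectory contains no return.
    """
    x, y = traj.x, traj.y
    nbacks = ((nback,) if isinstance(nback, (int, np.integer))
              else nback)
    for i in range(2, len(traj)):
        if nbacks is not None:
            for n in nbacks:
                j = i - 1 - n
                if j < 0:
                    continue
                if np.hypot(x[i] - x[j], y[i] - y[j]) < radius:
                    return j, i
        else:
            d = np.hypot(x[i] - x[:i - 1], y[i] - y[:i - 1])
            if np.any(d < radius):
                return int(np.argmin(d)), i
    return None


@dataclass
class AlignedDurationCurve:
    """Mean durations around the aligned (return) fixation.

    Curves are means over subjects of per-subject trial means; CIs are
    percentile bootstraps over subjects.  ``tests`` holds the
    per-dataset paired t-test at the out-location (the fixation the
    return saccade departs from), Bonferroni-corrected.
    """

    offsets: np.ndarray
    rs_mean: np.ndarray
    rs_ci: np.ndarray      # (2, n_offsets)
    control_mean: np.ndarray
    control_ci: np.ndarray
    per_subject_rs: pd.DataFrame       # subject x offset
    per_subject_control: pd.DataFrame
    tests: pd.DataFrame | None = None


def _subject_offset_means(values_by_trial: list[tuple[np.ndarray, int]],
                          offsets: np.ndarray) -> np.ndarray:
    """Mean of per-trial values at each offset relative to the align index."""
    acc = np.zeros(len(offsets))
    cnt = np.zeros(len(offsets))
    for vals, align in values_by_trial:
        for k, off in enumerate(offsets):
            pos = align + off
            if 0 <= pos < len(vals) and np.isfinite(vals[pos]):
                acc[k] += vals[pos]
                cnt[k] += 1
    with np.errstate(invalid="ignore"):
        return np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)


def align_rs_trials(trajectories: Sequence[Trajectory], nback: int = 1,
                    return_region_radius: float = 2.0,
                    use_corrected: bool = False,
                    offsets: Sequence[int] = range(-3, 4),
                    test_offset: int = -1, n_boot: int = 2000,
                    seed: int | None = None,
                    dataset_of: dict[str, str] | None = None
                    ) -> AlignedDurationCurve:
    """Align return-saccade trials on the revisit and compare to controls.

    Trials containing an n-back return (region criterion) are aligned on
    the second visit of the return location.  Control trials (no return)
    of the same subject are aligned at a position drawn from the
    subject's empirical distribution of return positions given
    trajectory length (nearest available length when unmatched).  With
    ``use_corrected`` the per-subject piecewise-momentum residuals
    replace raw durations, so any spatially specific slowing survives
    the correction while saccadic momentum itself is removed.
    """
    offsets = np.asarray(list(offsets), dtype=int)
    rng = np.random.default_rng(seed)
    by_subject: dict[str, dict] = {}
    for t in trajectories:
        by_subject.setdefault(t.subject, {"rs": [], "ctrl": []})
        ev = find_return_event(t, nback=nback, radius=return_region_radius)
        if ev is not None:
            by_subject[t.subject]["rs"].append((t, ev[1]))
        else:
            by_subject[t.subject]["ctrl"].append(t)

    fits = None
    if use_corrected:
        fits = fit_piecewise_per_subject(momentum_observations(trajectories))

    def trial_values(t: Trajectory) -> np.ndarray:
        if not use_corrected:
            return t.duration.astype(float)
        fit = fits.get(t.subject)
        vals = np.full(len(t), np.nan)
        if fit is None:
            return vals
        for d in pair_deltas(t, nback=1):
            j = d.saccade_index
            vals[j] = t.duration[j] - float(fit.predict(d.dphi, d.da))
        return vals

    rs_rows, ctrl_rows, subjects = [], [], []
    for s, rec in sorted(by_subject.items()):
        if not rec["rs"]:
            logger.warning("subject %s has no return-saccade trials; skipped", s)
            continue
        # empirical P(return position | trajectory length)
        pos_by_len: dict[int, list[int]] = {}
        for t, align in rec["rs"]:
            pos_by_len.setdefault(len(t), []).append(align)
        rs_vals = [(trial_values(t), align) for t, align in rec["rs"]]
        ctrl_vals = []
        lens = np.array(sorted(pos_by_len))
        for t in rec["ctrl"]:
            L = lens[np.argmin(np.abs(lens - len(t)))]
            align = int(rng.choice(pos_by_len[int(L)]))
            align = min(align, len(t) - 1)
            ctrl_vals.append((trial_values(t), align))
        if not ctrl_vals:
            logger.warning("subject %s has no control trials; skipped", s)
            continue
        subjects.append(s)
        rs_rows.append(_subject_offset_means(rs_vals, offsets))
        ctrl_rows.append(_subject_offset_means(ctrl_vals, offsets))

    if not subjects:
        raise ValueError("no subject contributed both RS and control trials")
    rs = pd.DataFrame(rs_rows, index=subjects, columns=offsets)
    ctrl = pd.DataFrame(ctrl_rows, index=subjects, columns=offsets)

    def boot_ci(frame: pd.DataFrame) -> np.ndarray:
        arr = frame.to_numpy()
        idx = rng.integers(0, len(arr), size=(n_boot, len(arr)))
        means = np.nanmean(arr[idx], axis=1)
        return np.nanpercentile(means, [2.5, 97.5], axis=0)

    tests = None
    if dataset_of is not None:
        groups = {}
        for s in subjects:
            groups.setdefault(dataset_of.get(s, "all"), []).append(s)
        rows = []
        for ds, members in sorted(groups.items()):
            a = rs.loc[members, test_offset].to_numpy()
            b = ctrl.loc[members, test_offset].to_numpy()
            m = np.isfinite(a) & np.isfinite(b)
            if m.sum() < 2:
                continue
            t_stat, p = stats.ttest_rel(a[m], b[m])
            rows.append((ds, int(m.sum()), float(np.mean(a[m] - b[m])),
                         float(t_stat), float(p)))
        tests = pd.DataFrame(rows, columns=["dataset", "n_subjects",
                                            "mean_difference", "t", "p"])
        if len(tests):
            tests["p_bonferroni"] = np.minimum(tests["p"] * len(tests), 1.0)

    return AlignedDurationCurve(
        offsets=offsets,
        rs_mean=np.nanmean(rs.to_numpy(), axis=0),
        rs_ci=boot_ci(rs),
        control_mean=np.nanmean(ctrl.to_numpy(), axis=0),
        control_ci=boot_ci(ctrl),
        per_subject_rs=rs, per_subject_control=ctrl, tests=tests)
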