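"""Empirical priority maps and the multinomial scanpath likelihood.

The priority map for one (subject, image) is a fixation-density map
built from all *other* subjects' trials on that image that contain no
return saccade, blurred with a Gaussian of 1 degree full width at half
maximum and normalized to unit mass.  Interpreting the map cells as
multinomial event probabilities, a trajectory is scored by the
probability of its cell-count vector; the order of fixations is
deliberately irrelevant.

For a trajectory A-B-A-C-...-F-G whose third fixation revisits A, the
*return trajectory* keeps the revisit but drops the final fixation
(A-B-A-C-...-F) while the *exploration trajectory* drops the revisit
and keeps the final fixation (A-B-C-...-F-G).  Both have the same
number of fixations, so their log-likelihood difference isolates the
value of exploiting a seen location versus exploring a new one; the
return trajectory wins exactly when the map value at the return cell is
more than twice the value at the last-fixation cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import gammaln

from refix.core import Trajectory
from refix.durations import find_return_event

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class PriorityMap:
    """Normalized 2-D fixation-density map over the image area.

    ``p`` has shape (n_x, n_y) following the histogram2d convention;
    probabilities are non-negative and sum to 1 within 1e-9.
    ``provenance`` records which (subject, trial) pairs contributed.
    """

    p: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    provenance: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.p < 0):
            raise ValueError("cell probabilities must be non-negative")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("cell probabilities must sum to 1")

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        ix = int(np.clip(np.digitize(x, self.x_edges) - 1, 0,
                         self.p.shape[0] - 1))
        iy = int(np.clip(np.digitize(y, self.y_edges) - 1, 0,
                         self.p.shape[1] - 1))
        return ix, iy

    def value_at(self, x: float, y: float) -> float:
        return float(self.p[self.cell_index(x, y)])

    def counts(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Per-cell fixation counts for a set of locations (clipped to grid)."""
        c = np.zeros(self.p.shape, dtype=int)
        for xi, yi in zip(np.atleast_1d(x), np.atleast_1d(y)):
            c[self.cell_index(float(xi), float(yi))] += 1
        return c

    @classmethod
    def uniform_like(cls, other: "PriorityMap") -> "PriorityMap":
        p = np.full(other.p.shape, 1.0 / other.p.size)
        return cls(p, other.x_edges, other.y_edges, [("flat", "prior")])

    def save(self, path) -> None:
        """Export as a flat float64 raster with a JSON sidecar."""
        import json
        from pathlib import Path

        path = Path(path)
        self.p.astype(np.float64).tofile(path)
        sidecar = {"shape": list(self.p.shape), "dtype": "float64",
                   "x_edges": self.x_edges.tolist(),
                   "y_edges": self.y_edges.tolist(),
                   "provenance": [list(pr) for pr in self.provenance]}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar))

    @classmethod
    def load(cls, path) -> "PriorityMap":
        import json
        from pathlib import Path

        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        p = np.fromfile(path, dtype=np.float64).reshape(meta["shape"])
        return cls(p, np.asarray(meta["x_edges"]),
                   np.asarray(meta["y_edges"]),
                   [tuple(pr) for pr in meta["provenance"]])


def density_map(points: np.ndarray, extent: tuple[float, float, float, float],
                resolution: float = 0.25, fwhm: float = 1.0,
                provenance: list[tuple[str, str]] | None = None
                ) -> PriorityMap:
    """Histogram of fixation locations, Gaussian-blurred and normalized.

    ``extent`` is (x_min, x_max, y_min, y_max) in degrees; ``resolution``
    the cell size.  The blur uses sigma = fwhm / (2 sqrt(2 ln 2)).  Near
    the border the kernel is truncated and renormalized so the total
    mass stays inside the grid, and the map is finally rescaled to sum
    exactly to 1.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) == 0:
        raise ValueError("need at least one contributing fixation")
    x_edges = np.arange(extent[0], extent[1] + resolution / 2, resolution)
    y_edges = np.arange(extent[2], extent[3] + resolution / 2, resolution)
    hist, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=[x_edges, y_edges])
    sigma_cells = (fwhm * FWHM_TO_SIGMA) / resolution
    blurred = gaussian_filter(hist, sigma_cells, mode="constant")
    norm = gaussian_filter(np.ones_like(hist), sigma_cells, mode="constant")
    blurred = blurred / norm
    p = blurred / blurred.sum()
    return PriorityMap(p, x_edges, y_edges, provenance or [])


def build_priority_map(trajectories: Sequence[Trajectory], for_subject: str,
                       image: str, fwhm: float = 1.0,
                       resolution: float = 0.25,
                       extent: tuple[float, float, float, float] | None = None,
                       return_region_radius: float = 2.0,
                       nbacks: tuple[int, ...] = (1, 2)) -> PriorityMap:
    """Priority map for one (subject, image) with proper exclusions.

    Contributing fixations come from trials of *other* subjects on the
    same image that contain no 1- or 2-back return saccade (region
    criterion); the contributing (subject, trial) pairs are recorded
    as provenance.
    """
    pts, prov = [], []
    for t in trajectories:
        if t.image != image or t.subject == for_subject:
            continue
        if find_return_event(t, nback=nbacks, radius=return_region_radius):
            continue
        pts.append(np.column_stack([t.x, t.y]))
        prov.append((t.subject, t.trial))
    if not pts:
        raise ValueError(f"no contributing fixations for subject "
                         f"{for_subject!r} on image {image!r}")
    points = np.vstack(pts)
    if extent is None:
        pad = 2.0
        extent = (points[:, 0].min() - pad, points[:, 0].max() + pad,
                  points[:, 1].min() - pad, points[:, 1].max() + pad)
    return density_map(points, extent, resolution, fwhm, prov)


def multinomial_log_probability(counts: np.ndarray, pmap: PriorityMap | np.ndarray,
                                with_coefficient: bool = True) -> float:
    """Log-probability of a cell-count vector under the priority map.

    log[n!/prod c_i!] + sum c_i log p_i via log-gamma.  Occupied cells
    with zero probability give -inf (with a log message);
    ``with_coefficient=False`` drops the multinomial coefficient.
    """
    p = pmap.p if isinstance(pmap, PriorityMap) else np.asarray(pmap, float)
    c = np.asarray(counts)
    if p.shape != c.shape:
        raise ValueError(f"shape mismatch: counts {c.shape} vs map {p.shape}")
    if not np.all(c == np.floor(c)) or np.any(c < 0):
        raise ValueError("counts must be non-negative integers")
    c = c.astype(int)
    occupied = c > 0
    if np.any(p[occupied] == 0):
        logger.info("occupied cell with zero probability: log-probability -inf")
        return float("-inf")
    n = int(c.sum())
    logp = float(np.sum(c[occupied] * np.log(p[occupied])))
    if with_coefficient:
        logp += float(gammaln(n + 1) - gammaln(c[occupied] + 1).sum())
    return logp


@dataclass
class ReturnExploreResult:
    subject: str
    image: str
    trial: str
    first_visit: int
    second_visit: int
    delta_loglik: float    # logP(return trajectory) - logP(exploration trajectory)
    p_return: float        # map value at the return cell
    p_last: float          # map value at the last-fixation cell


def return_vs_explore(traj: Trajectory, pmap: PriorityMap,
                      return_region_radius: float = 2.0,
                      with_coefficient: bool = True,
                      nbacks: tuple[int, ...] = (1, 2)
                      ) -> ReturnExploreResult | None:
    """Likelihood advantage of keeping the revisit over one more new fixation.

    Uses the first return event of the trajectory (later ones are
    logged and ignored).  The two visits of the return location count
    as the same multinomial event: the revisit is tallied in the cell
    of the first visit, so the comparison is between fixating the
    return location twice versus adding one new location, regardless
    of the grid resolution relative to the return-region radius.
    Returns None, with the reason logged, when the trajectory has no
    return or no fixation after the second visit.
    """
    ev = find_return_event(traj, nback=nbacks, radius=return_region_radius)
    if ev is None:
        logger.info("trajectory %s/%s/%s skipped: no return event",
                    traj.subject, traj.image, traj.trial)
        return None
    j, i = ev
    if i >= len(traj) - 1:
        logger.info("trajectory %s/%s/%s skipped: no fixation after the "
                    "second visit", traj.subject, traj.image, traj.trial)
        return None
    x = traj.x.copy()
    y = traj.y.copy()
    x[i], y[i] = x[j], y[j]                 # revisit counts at the return cell
    cell_r = pmap.cell_index(x[j], y[j])
    cell_l = pmap.cell_index(x[-1], y[-1])
    p_r = float(pmap.p[cell_r])
    p_l = float(pmap.p[cell_l])
    if cell_r == cell_l:
        delta = 0.0                         # the two trajectories coincide
    elif p_r == 0.0 or p_l == 0.0:
        delta = float("-inf") if p_r == 0.0 else float("inf")
        logger.info("trajectory %s/%s/%s: unsupported return or last cell",
                    traj.subject, traj.image, traj.trial)
    else:
        # the two trajectories share every other fixation, so all common
        # terms of the multinomial log-probabilities cancel exactly
        counts = pmap.counts(x, y)
        c_r, c_l = counts[cell_r], counts[cell_l]
        delta = np.log(p_r) - np.log(p_l)
        if with_coefficient:
            delta += np.log(c_l) - np.log(c_r)
    return ReturnExploreResult(
        traj.subject, traj.image, traj.trial, j, i,
        delta_loglik=float(delta),
        p_return=p_r, p_last=p_l)


def delta_shortcut(p_return: float, p_last: float) -> float:
    """Closed form of the likelihood difference for the canonical case.

    When the return cell holds exactly the two visits and the last
    fixation sits alone in its own cell, the full multinomial
    difference reduces to log p_r - log(2 p_l); the sign flips exactly
    at p_r / p_l = 2.
    """
    return float(np.log(p_return) - np.log(2.0 * p_last))


@dataclass
class ForagingSummary:
    deltas: pd.DataFrame            # one row per eligible trajectory
    per_dataset: pd.DataFrame       # mean delta + bootstrap CI per dataset x map type
    anova: pd.DataFrame | None      # two-way ANOVA (dataset x map type)


def foraging_summary(trajectories: Sequence[Trajectory],
                     dataset_of: dict[str, str] | None = None,
                     fwhm: float = 1.0, resolution: float = 0.25,
                     extent: tuple[float, float, float, float] | None = None,
                     return_region_radius: float = 2.0,
                     with_coefficient: bool = True,
                     n_boot: int = 2000, seed: int | None = None
                     ) -> ForagingSummary:
    """Mean likelihood advantage of return saccades, per dataset and map type.

    Every eligible trajectory is scored under its empirical priority
    map and under a flat prior of the same geometry.  Per dataset and
    map type the mean delta log-likelihood is reported with a
    percentile-bootstrap CI over per-subject means; with at least two
    datasets a two-way ANOVA (dataset x map type) tests whether the
    empirical map changes the advantage.
    """
    rng = np.random.default_rng(seed)
    dataset_of = dataset_of or {}
    map_cache: dict[tuple[str, str], PriorityMap] = {}
    rows = []
    for t in trajectories:
        key = (t.subject, t.image)
        if key not in map_cache:
            try:
                map_cache[key] = build_priority_map(
                    trajectories, t.subject, t.image, fwhm, resolution,
                    extent, return_region_radius)
            except ValueError as err:
                logger.warning("map for %s skipped: %s", key, err)
                map_cache[key] = None
        pmap = map_cache[key]
        if pmap is None:
            continue
        for map_type, m in (("empirical", pmap),
                            ("flat", PriorityMap.uniform_like(pmap))):
            res = return_vs_explore(t, m, return_region_radius,
                                    with_coefficient)
            if res is None:
                break
            rows.append((dataset_of.get(t.subject, "all"), map_type,
                         t.subject, t.image, t.trial, res.delta_loglik))
    deltas = pd.DataFrame(rows, columns=["dataset", "map_type", "subject",
                                         "image", "trial", "delta"])
    deltas["delta"] = deltas["delta"].astype(float)
    n_nonfinite = int((~np.isfinite(deltas["delta"])).sum())
    if n_nonfinite:
        # trajectories visiting cells the contributing observers never
        # approached have -inf likelihood under the empirical map
        logger.warning("excluding %d non-finite delta(s) from the summary",
                       n_nonfinite)
        deltas = deltas[np.isfinite(deltas["delta"])]
    summary_rows = []
    for (ds, mt), g in deltas.groupby(["dataset", "map_type"]):
        subj_means = g.groupby("subject")["delta"].mean().to_numpy()
        mean = float(subj_means.mean())
        if len(subj_means) > 1:
            idx = rng.integers(0, len(subj_means), size=(n_boot, len(subj_means)))
            boot = subj_means[idx].mean(axis=1)
            lo, hi = np.percentile(boot, [2.5, 97.5])
        else:
            lo = hi = mean
        summary_rows.append((ds, mt, mean, float(lo), float(hi),
                             int(len(g)), len(subj_means)))
    per_dataset = pd.DataFrame(summary_rows, columns=[
        "dataset", "map_type", "mean_delta", "ci_low", "ci_high",
        "n_trajectories", "n_subjects"])
    anova = None
    if (deltas["dataset"].nunique() >= 2
            and deltas["map_type"].nunique() >= 2):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        try:
            model = ols("delta ~ C(dataset) * C(map_type)",
                        data=deltas).fit()
            anova = sm.stats.anova_lm(model, typ=2)
        except ValueError as err:
            logger.warning("ANOVA skipped (degenerate design: %s)", err)
    else:
        logger.info("single dataset: ANOVA skipped")
    return ForagingSummary(deltas, per_dataset, anova)


def priority_at_locations(trajectories: Sequence[Trajectory],
                          fwhm: float = 1.0, resolution: float = 0.25,
                          extent: tuple[float, float, float, float] | None = None,
                          return_region_radius: float = 2.0,
                          n_boot: int = 2000, seed: int | None = None
                          ) -> pd.DataFrame:
    """Mean priority-map value at return locations vs their neighbors.

    For every trajectory with a return event, the map value at the
    second visit is compared with the values at the fixations
    immediately before and after it.  Per-subject means are paired; the
    returned frame holds the mean differences and bootstrap CIs.
    """
    rng = np.random.default_rng(seed)
    map_cache: dict[tuple[str, str], PriorityMap] = {}
    rows = []
    for t in trajectories:
        ev = find_return_event(t, nback=(1, 2), radius=return_region_radius)
        if ev is None:
            continue
        _, i = ev
        key = (t.subject, t.image)
        if key not in map_cache:
            try:
                map_cache[key] = build_priority_map(
                    trajectories, t.subject, t.image, fwhm, resolution,
                    extent, return_region_radius)
            except ValueError:
                map_cache[key] = None
        pmap = map_cache[key]
        if pmap is None:
            continue
        at_return = pmap.value_at(t.x[i], t.y[i])
        neighbors = [pmap.value_at(t.x[k], t.y[k])
                     for k in (i - 1, i + 1) if 0 <= k < len(t)]
        rows.append((t.subject, at_return, float(np.mean(neighbors))))
    df = pd.DataFrame(rows, columns=["subject", "at_return", "at_neighbors"])
    per_subject = df.groupby("subject").mean()
    diff = (per_subject["at_return"] - per_subject["at_neighbors"]).to_numpy()
    if len(diff) > 1:
        idx = rng.integers(0, len(diff), size=(n_boot, len(diff)))
        boot = diff[idx].mean(axis=1)
        lo, hi = np.percentile(boot, [2.5, 97.5])
    else:
        lo = hi = diff.mean() if len(diff) else np.nan
    return pd.DataFrame({
        "mean_at_return": [per_subject["at_return"].mean()],
        "mean_at_neighbors": [per_subject["at_neighbors"].mean()],
        "mean_difference": [float(diff.mean()) if len(diff) else np.nan],
        "ci_low": [float(lo)], "ci_high": [float(hi)],
        "n_subjects": [len(per_subject)]})
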