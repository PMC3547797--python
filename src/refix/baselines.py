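"""Null models for return-saccade frequency.

Two baselines are provided.  The *shuffled* baseline permutes the order
of a subject's saccades while preserving the amplitude/direction
marginals exactly, destroying all sequential dependencies.  The
*conditional Markov simulator* estimates, per subject, the distribution
P(da, dphi | a_prev) of amplitude and turning-angle differences between
consecutive saccades given the previous amplitude, and regenerates
trajectories from it; the simulator reproduces all pairwise (1-back)
dependencies but cannot produce structure that spans three or more
saccades, which makes it the appropriate null for 2-back returns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import rel_entr

from refix.core import (
    PairDelta,
    Trajectory,
    classify_forward,
    classify_return,
    compute_saccades,
    pair_deltas,
)

logger = logging.getLogger(__name__)


def _rebuild_trajectory(amp: np.ndarray, direction: np.ndarray, subject: str,
                        image: str, trial: str,
                        duration_ms: float = 250.0) -> Trajectory:
    """Chain saccades (amplitude, direction) into fixation coordinates.

    The pseudo-trajectory starts at the origin; fixation durations carry
    no information in the null models and are set to a constant.
    """
    rad = np.radians(direction)
    dx = amp * np.cos(rad)
    dy = amp * np.sin(rad)
    x = np.concatenate([[0.0], np.cumsum(dx)])
    y = np.concatenate([[0.0], np.cumsum(dy)])
    return Trajectory(subject, image, trial, x, y,
                      np.full(len(x), duration_ms))


def _pooled_saccades(trajectories: Sequence[Trajectory]
                     ) -> dict[str, tuple[np.ndarray, np.ndarray, list[int]]]:
    """Per subject: pooled (amplitudes, directions, per-trajectory saccade counts)."""
    pools: dict[str, tuple[list, list, list]] = {}
    for t in trajectories:
        sacc = compute_saccades(t)
        amps, dirs, lens = pools.setdefault(t.subject, ([], [], []))
        amps.extend(s.amplitude for s in sacc)
        dirs.extend(s.direction for s in sacc)
        lens.append(len(sacc))
    return {s: (np.array(a), np.array(d), l) for s, (a, d, l) in pools.items()}


@dataclass
class ShuffledBaseline:
    """Result of the order-shuffled null model."""

    return_fractions: pd.DataFrame   # shuffle x subject
    forward_fractions: pd.DataFrame  # shuffle x subject
    trajectories: list[Trajectory]   # pseudo-trajectories of the last shuffle

    @property
    def mean_return_fraction(self) -> pd.Series:
        return self.return_fractions.mean(axis=0)

    @property
    def mean_forward_fraction(self) -> pd.Series:
        return self.forward_fractions.mean(axis=0)


def shuffled_baseline(trajectories: Sequence[Trajectory], nback: int = 1,
                      n_shuffles: int = 1, seed: int | None = None,
                      return_criterion: Callable[[PairDelta], bool] = classify_return,
                      forward_criterion: Callable[[PairDelta], bool] = classify_forward,
                      ) -> ShuffledBaseline:
    """Order-shuffled null model for n-back return/forward fractions.

    Each subject's pooled saccade list is permuted and reassembled into
    pseudo-trajectories with the original saccade counts; pair deltas
    are recomputed on the shuffled order.  Amplitude and direction
    marginals are preserved exactly (a permutation of the multiset).
    """
    rng = np.random.default_rng(seed)
    pools = _pooled_saccades(trajectories)
    for s, (amp, _, _) in pools.items():
        if len(amp) < 2:
            raise ValueError(f"subject {s} has fewer than 2 saccades")
    ret_rows, fwd_rows = [], []
    last: list[Trajectory] = []
    for k in range(n_shuffles):
        ret_row, fwd_row = {}, {}
        last = []
        for s, (amp, direction, lens) in pools.items():
            perm = rng.permutation(len(amp))
            a, d = amp[perm], direction[perm]
            n_hit = n_fwd = n_tot = 0
            pos = 0
            for j, ln in enumerate(lens):
                traj = _rebuild_trajectory(a[pos:pos + ln], d[pos:pos + ln],
                                           s, "shuffled", str(j))
                pos += ln
                for delta in pair_deltas(traj, nback):
                    n_tot += 1
                    n_hit += return_criterion(delta)
                    n_fwd += forward_criterion(delta)
                last.append(traj)
            ret_row[s] = n_hit / n_tot if n_tot else np.nan
            fwd_row[s] = n_fwd / n_tot if n_tot else np.nan
        ret_rows.append(ret_row)
        fwd_rows.append(fwd_row)
    return ShuffledBaseline(pd.DataFrame(ret_rows), pd.DataFrame(fwd_rows), last)


@dataclass
class ConditionalSaccadeDistribution:
    """Per-subject binned estimate of P(da, dphi | a_prev).

    ``hist[i]`` is the normalized 2-D histogram over (da, dphi) for
    conditioning amplitude bin ``i``; bins without data are flagged in
    ``empty`` and are never sampled from directly (the nearest populated
    bin substitutes, with a log message).  First saccades of each trial
    are stored as an empirical (amplitude, direction) sample.
    """

    subject: str
    amp_edges: np.ndarray
    da_edges: np.ndarray
    dphi_edges: np.ndarray
    hist: np.ndarray           # (n_amp_bins, n_da, n_dphi), rows sum to 1
    counts: np.ndarray         # raw counts, same shape
    empty: np.ndarray          # (n_amp_bins,) bool
    first_saccades: np.ndarray = field(default=None)  # (n, 2): amp, direction

    def __post_init__(self) -> None:
        populated = ~self.empty
        sums = self.hist[populated].sum(axis=(1, 2))
        if populated.any() and not np.allclose(sums, 1.0):
            raise ValueError("conditional histograms must sum to 1")

    def conditioning_bin(self, a_prev: float) -> int:
        i = int(np.digitize(a_prev, self.amp_edges) - 1)
        i = min(max(i, 0), len(self.amp_edges) - 2)
        if self.empty[i]:
            populated = np.flatnonzero(~self.empty)
            j = populated[np.argmin(np.abs(populated - i))]
            logger.info("subject %s: conditioning bin %d empty, "
                        "falling back to nearest populated bin %d",
                        self.subject, i, j)
            i = int(j)
        return i

    def sample(self, a_prev: float, rng: np.random.Generator
               ) -> tuple[float, float]:
        """Draw (da, dphi), uniform within the sampled histogram cell."""
        i = self.conditioning_bin(a_prev)
        flat = self.hist[i].ravel()
        cell = rng.choice(flat.size, p=flat)
        ida, idphi = np.unravel_index(cell, self.hist[i].shape)
        da = rng.uniform(self.da_edges[ida], self.da_edges[ida + 1])
        dphi = rng.uniform(self.dphi_edges[idphi], self.dphi_edges[idphi + 1])
        return float(da), float(dphi)

    def sample_first(self, rng: np.random.Generator) -> tuple[float, float]:
        k = rng.integers(len(self.first_saccades))
        amp, direction = self.first_saccades[k]
        return float(amp), float(direction)

    def to_json(self) -> dict:
        """Portable JSON representation (bin edges, histograms, counts)."""
        return {
            "subject": self.subject,
            "amp_edges": self.amp_edges.tolist(),
            "da_edges": self.da_edges.tolist(),
            "dphi_edges": self.dphi_edges.tolist(),
            "hist": self.hist.tolist(),
            "counts": self.counts.tolist(),
            "empty": self.empty.tolist(),
            "first_saccades": self.first_saccades.tolist(),
        }

    @classmethod
    def from_json(cls, data: dict) -> "ConditionalSaccadeDistribution":
        return cls(subject=data["subject"],
                   amp_edges=np.asarray(data["amp_edges"], dtype=float),
                   da_edges=np.asarray(data["da_edges"], dtype=float),
                   dphi_edges=np.asarray(data["dphi_edges"], dtype=float),
                   hist=np.asarray(data["hist"], dtype=float),
                   counts=np.asarray(data["counts"], dtype=float),
                   empty=np.asarray(data["empty"], dtype=bool),
                   first_saccades=np.asarray(data["first_saccades"],
                                             dtype=float))


def _edges(lo: float, hi: float, width: float) -> np.ndarray:
    lo = np.floor(lo / width) * width
    hi = np.ceil(hi / width) * width
    if hi <= lo:
        hi = lo + width
    return np.arange(lo, hi + width / 2, width)


def estimate_conditional(trajectories: Sequence[Trajectory],
                         amp_bin_width: float = 1.0,
                         dphi_bin_width: float = 3.0,
                         da_bin_width: float = 1.0,
                         ) -> dict[str, ConditionalSaccadeDistribution]:
    """Estimate P(da, dphi | a_prev) separately for every subject.

    Bin widths default to 1 degree for the conditioning amplitude and
    the amplitude difference and 3 degrees for the turning angle.
    """
    by_subject: dict[str, dict] = {}
    for t in trajectories:
        rec = by_subject.setdefault(t.subject, {"a_prev": [], "da": [],
                                                "dphi": [], "first": []})
        sacc = compute_saccades(t)
        if sacc:
            rec["first"].append((sacc[0].amplitude, sacc[0].direction))
        amps = {s.source: s for s in sacc}
        for d in pair_deltas(t, nback=1):
            prev = amps.get(d.saccade_index - 1)
            if prev is None:
                continue
            rec["a_prev"].append(prev.amplitude)
            rec["da"].append(d.da)
            rec["dphi"].append(d.dphi)
    out: dict[str, ConditionalSaccadeDistribution] = {}
    for s, rec in by_subject.items():
        a_prev = np.asarray(rec["a_prev"], dtype=float)
        da = np.asarray(rec["da"], dtype=float)
        dphi = np.asarray(rec["dphi"], dtype=float)
        if len(a_prev) == 0:
            logger.warning("subject %s has no saccade pairs; skipped", s)
            continue
        amp_edges = _edges(0.0, a_prev.max(), amp_bin_width)
        da_edges = _edges(da.min(), da.max(), da_bin_width)
        dphi_edges = _edges(0.0, 180.0, dphi_bin_width)
        counts, _ = np.histogramdd(
            np.column_stack([a_prev, da, dphi]),
            bins=[amp_edges, da_edges, dphi_edges])
        totals = counts.sum(axis=(1, 2))
        empty = totals == 0
        hist = np.zeros_like(counts)
        hist[~empty] = counts[~empty] / totals[~empty, None, None]
        out[s] = ConditionalSaccadeDistribution(
            subject=s, amp_edges=amp_edges, da_edges=da_edges,
            dphi_edges=dphi_edges, hist=hist, counts=counts, empty=empty,
            first_saccades=np.array(rec["first"], dtype=float))
    return out


def simulate_trajectories(dist: ConditionalSaccadeDistribution,
                          lengths: Sequence[int], seed: int | None = None,
                          max_rejects: int = 200) -> list[Trajectory]:
    """Regenerate trajectories from the conditional Markov model.

    ``lengths`` are fixation counts of the trajectories to produce (the
    empirical length multiset).  Each trajectory starts from a draw of
    the subject's first-saccade distribution, then repeatedly samples
    (da, dphi) given the current amplitude; the next amplitude is
    ``a + da`` (non-positive draws rejected and redrawn) and the next
    direction is the current one rotated by dphi with a uniformly random
    sign.  Trajectories exceeding the rejection cap are aborted.
    """
    rng = np.random.default_rng(seed)
    out: list[Trajectory] = []
    for j, n_fix in enumerate(lengths):
        if n_fix < 2:
            raise ValueError("trajectory lengths must be >= 2 fixations")
        amp, direction = dist.sample_first(rng)
        amps, dirs = [amp], [direction]
        aborted = False
        while len(amps) < n_fix - 1:
            for attempt in range(max_rejects + 1):
                da, dphi = dist.sample(amps[-1], rng)
                new_amp = amps[-1] + da
                if new_amp > 0:
                    break
                logger.debug("rejected non-positive amplitude %.3f", new_amp)
            else:
                logger.warning("subject %s: aborting simulated trajectory %d "
                               "after %d rejected draws", dist.subject, j,
                               max_rejects)
                aborted = True
                break
            sign = 1.0 if rng.random() < 0.5 else -1.0
            dirs.append((dirs[-1] + sign * dphi) % 360.0)
            amps.append(new_amp)
        if aborted:
            continue
        out.append(_rebuild_trajectory(np.array(amps), np.array(dirs),
                                       dist.subject, "simulated", str(j)))
    return out


def kl_divergence(p_hist: np.ndarray, q_hist: np.ndarray,
                  epsilon: float = 1e-9) -> float:
    """Kullback-Leibler divergence sum p log(p/q), natural log.

    Both histograms are regularized by ``epsilon`` and renormalized
    before the divergence is taken, so empty bins never produce
    infinities.  Zero iff the regularized histograms are identical.
    """
    p = np.asarray(p_hist, dtype=float)
    q = np.asarray(q_hist, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"histogram shapes differ: {p.shape} vs {q.shape}")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    p = p + epsilon
    q = q + epsilon
    p = p / p.sum()
    q = q / q.sum()
    return float(rel_entr(p, q).sum())


def delta_histogram(trajectories: Sequence[Trajectory], nback: int = 1,
                    da_edges: np.ndarray | None = None,
                    dphi_edges: np.ndarray | None = None
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D histogram of (da, dphi) pair deltas pooled over trajectories.

    Returns (counts, da_edges, dphi_edges); used for KL comparisons of
    subjects against each other and against their simulated saccades.
    """
    da, dphi = [], []
    for t in trajectories:
        for d in pair_deltas(t, nback):
            da.append(d.da)
            dphi.append(d.dphi)
    if da_edges is None:
        da_edges = np.arange(-30.0, 30.0 + 0.5, 1.0)
    if dphi_edges is None:
        dphi_edges = np.arange(0.0, 180.0 + 1.5, 3.0)
    counts, _, _ = np.histogram2d(np.asarray(da), np.asarray(dphi),
                                  bins=[da_edges, dphi_edges])
    return counts, da_edges, dphi_edges


@dataclass
class BaselineComparison:
    """Per-subject empirical vs baseline fractions with a bootstrap CI."""

    empirical: pd.Series
    baseline: pd.Series
    difference: pd.Series
    mean_difference: float
    ci_low: float
    ci_high: float
    significant: bool

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mean_difference <= self.ci_high):
            raise ValueError("bootstrap CI must bracket the mean difference")


def compare_to_baseline(empirical: pd.Series, baseline: pd.Series,
                        n_boot: int = 2000, seed: int | None = None
                        ) -> BaselineComparison:
    """Percentile-bootstrap CI of the mean per-subject difference.

    Subjects are the resampling unit; significance means the 95% CI
    excludes zero.
    """
    empirical, baseline = empirical.align(baseline, join="inner")
    mask = empirical.notna() & baseline.notna()
    empirical, baseline = empirical[mask], baseline[mask]
    if len(empirical) < 2:
        raise ValueError("need at least 2 subjects with paired values")
    diff = empirical - baseline
    rng = np.random.default_rng(seed)
    vals = diff.to_numpy()
    idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
    boot_means = vals[idx].mean(axis=1)
    lo, hi = np.percentile(boot_means, [2.5, 97.5])
    mean = float(vals.mean())
    lo = min(float(lo), mean)
    hi = max(float(hi), mean)
    return BaselineComparison(empirical, baseline, diff, mean, lo, hi,
                              significant=not (lo <= 0.0 <= hi))
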