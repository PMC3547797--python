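"""Fixation-table readers/writers, screen geometry, and the pipeline driver."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from refix.core import Trajectory

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject", "image", "trial", "fix_index", "duration")


@dataclass(frozen=True)
class GeometryConfig:
    """Display geometry for exact pixel <-> degree conversion.

    Degrees are screen-centered visual angle computed with the exact
    arctangent (no small-angle approximation); x is rightward and y
    upward, while pixel rows grow downward from the top-left corner.
    """

    screen_width_mm: float
    screen_height_mm: float
    screen_width_px: int
    screen_height_px: int
    viewing_distance_mm: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")

    @property
    def mm_per_px(self) -> tuple[float, float]:
        return (self.screen_width_mm / self.screen_width_px,
                self.screen_height_mm / self.screen_height_px)

    def px_to_deg(self, px_x, px_y) -> tuple[np.ndarray, np.ndarray]:
        mx, my = self.mm_per_px
        dx_mm = (np.asarray(px_x, float) - self.screen_width_px / 2.0) * mx
        dy_mm = (self.screen_height_px / 2.0 - np.asarray(px_y, float)) * my
        return (np.degrees(np.arctan2(dx_mm, self.viewing_distance_mm)),
                np.degrees(np.arctan2(dy_mm, self.viewing_distance_mm)))

    def deg_to_px(self, x_deg, y_deg) -> tuple[np.ndarray, np.ndarray]:
        mx, my = self.mm_per_px
        dx_mm = np.tan(np.radians(np.asarray(x_deg, float))) * self.viewing_distance_mm
        dy_mm = np.tan(np.radians(np.asarray(y_deg, float))) * self.viewing_distance_mm
        return (dx_mm / mx + self.screen_width_px / 2.0,
                self.screen_height_px / 2.0 - dy_mm / my)

    @property
    def pixels_per_degree(self) -> float:
        """Pixels per degree at screen center (mean of both axes)."""
        mx, my = self.mm_per_px
        mm = np.tan(np.radians(1.0)) * self.viewing_distance_mm
        return float((mm / mx + mm / my) / 2.0)


class FixationTableError(ValueError):
    """Malformed fixation table; the message names the offending lines."""


def read_fixation_table(path: str | Path,
                        geometry: GeometryConfig | None = None,
                        sep: str | None = None) -> list[Trajectory]:
    """Read a fixation CSV/TSV into trajectories grouped by (subject, image, trial).

    Required columns: subject, image, trial, fix_index, duration plus
    either (x, y) in degrees or (px_x, px_y) in pixels; pixel input
    needs a geometry for the conversion.  Line numbers in error
    messages refer to the file including its header.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    has_deg = {"x", "y"}.issubset(df.columns)
    has_px = {"px_x", "px_y"}.issubset(df.columns)
    if not has_deg and not has_px:
        missing.append("x/y or px_x/px_y")
    if missing:
        raise FixationTableError(f"missing required columns: {missing}")
    if has_px and not has_deg:
        if geometry is None:
            raise FixationTableError(
                "pixel coordinates given but no geometry config supplied")
        x, y = geometry.px_to_deg(_numeric(df, "px_x", path),
                                  _numeric(df, "px_y", path))
        df = df.assign(x=x, y=y)
    for col in ("fix_index", "x", "y", "duration"):
        df[col] = _numeric(df, col, path)
    bad = df.index[df["duration"] <= 0]
    if len(bad):
        raise FixationTableError(
            f"non-positive duration at line(s) {[int(i) + 2 for i in bad[:5]]}")
    dup = df.duplicated(subset=["subject", "image", "trial", "fix_index"])
    if dup.any():
        lines = [int(i) + 2 for i in df.index[dup][:5]]
        raise FixationTableError(f"duplicate (trial, fix_index) at line(s) {lines}")
    out: list[Trajectory] = []
    for (s, im, tr), g in df.groupby(["subject", "image", "trial"], sort=True):
        g = g.sort_values("fix_index")
        idx = g["fix_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise FixationTableError(
                f"fixation indices of {s}/{im}/{tr} are not consecutive from 0")
        out.append(Trajectory(str(s), str(im), str(tr), g["x"].to_numpy(),
                              g["y"].to_numpy(), g["duration"].to_numpy()))
    return out


def _numeric(df: pd.DataFrame, col: str, path: Path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[vals.isna() & df[col].notna()]
    if len(bad) or vals.isna().any():
        lines = [int(i) + 2 for i in (bad if len(bad) else df.index[vals.isna()])[:5]]
        raise FixationTableError(
            f"non-numeric or missing values in column {col!r} "
            f"of {path.name} at line(s) {lines}")
    return vals.to_numpy(dtype=float)


def write_fixation_table(trajectories: Sequence[Trajectory],
                         path: str | Path) -> None:
    """Write trajectories in the standard fixation-table CSV schema."""
    rows = []
    for t in trajectories:
        for i in range(len(t)):
            rows.append((t.subject, t.image, t.trial, i,
                         t.x[i], t.y[i], t.duration[i]))
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    pd.DataFrame(rows, columns=["subject", "image", "trial", "fix_index",
                                "x", "y", "duration"]).to_csv(
        path, index=False, sep=sep)


DEFAULT_CONFIG = {
    "seed": 0,
    "stages": ["simulate", "returns", "baseline", "durations", "foraging"],
    "input_table": None,       # path to a fixation CSV; None -> synthetic
    "cohort": {},              # CohortSpec overrides for the synthetic stage
    "nbacks": [1, 2],
    "return_region_radius": 2.0,
    "n_boot": 2000,
    "foraging": {"resolution": 0.5, "fwhm": 1.0},
}

STAGE_ORDER = ["simulate", "returns", "baseline", "durations", "saliency",
               "foraging"]


def load_config(path: str | Path | None = None, **overrides) -> dict:
    """Layered configuration: defaults < file < keyword overrides."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        with open(path) as fh:
            cfg.update(yaml.safe_load(fh) or {})
    cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute the selected analysis stages and write results + summary.

    Stages run in the fixed order simulate -> returns -> baseline ->
    durations -> saliency -> foraging; requesting a stage whose inputs
    are unavailable (e.g. saliency without images) is reported before
    execution.  The summary JSON carries the seed and a config hash so
    any number in it can be traced to the configuration that produced
    it.  Reruns with the same config are identical.
    """
    from refix import baselines, core, durations, foraging, synthetic

    cfg = config if isinstance(config, dict) else load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGE_ORDER if s in cfg["stages"]]
    unknown = set(cfg["stages"]) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    if cfg["input_table"] is None and "simulate" not in stages and stages:
        raise ValueError("no input table configured and 'simulate' not "
                         "among the stages")
    seed = int(cfg["seed"])
    summary: dict = {"seed": seed, "config_hash": config_hash(cfg),
                     "stages": stages}

    cohort = None
    if cfg["input_table"] is not None:
        trajectories = read_fixation_table(cfg["input_table"])
    else:
        spec = synthetic.CohortSpec(**cfg.get("cohort", {}), seed=seed)
        cohort = synthetic.generate_cohort(spec)
        trajectories = cohort.trajectories
        if "simulate" in stages:
            write_fixation_table(trajectories, out / "fixations.csv")
            with open(out / "ground_truth.json", "w") as fh:
                json.dump(cohort.ground_truth, fh, indent=1, default=str)
            summary["n_fixations"] = cohort.ground_truth["n_fixations"]

    if "returns" in stages:
        rows = {}
        for nb in cfg["nbacks"]:
            frac, pooled = core.count_returns(trajectories, nback=nb)
            frac.to_csv(out / f"return_fractions_{nb}back.csv")
            rows[f"{nb}back"] = {"pooled": pooled,
                                 "per_subject_mean": float(frac.mean())}
        summary["return_fractions"] = rows

    if "baseline" in stages:
        base = {}
        shuf = baselines.shuffled_baseline(trajectories, nback=1,
                                           seed=seed + 1)
        emp1, _ = core.count_returns(trajectories, nback=1)
        cmp1 = baselines.compare_to_baseline(emp1, shuf.mean_return_fraction,
                                             n_boot=cfg["n_boot"],
                                             seed=seed + 2)
        base["1back_vs_shuffled"] = {
            "mean_difference": cmp1.mean_difference,
            "ci": [cmp1.ci_low, cmp1.ci_high],
            "significant": cmp1.significant}
        dists = baselines.estimate_conditional(trajectories)
        sim = []
        for s, dist in dists.items():
            lengths = [len(t) for t in trajectories if t.subject == s]
            sim.extend(baselines.simulate_trajectories(dist, lengths,
                                                       seed=seed + 3))
        for nb in cfg["nbacks"]:
            emp, _ = core.count_returns(trajectories, nback=nb)
            simfrac, _ = core.count_returns(sim, nback=nb)
            cmp_ = baselines.compare_to_baseline(emp, simfrac,
                                                 n_boot=cfg["n_boot"],
                                                 seed=seed + 4)
            base[f"{nb}back_vs_simulated"] = {
                "mean_difference": cmp_.mean_difference,
                "ci": [cmp_.ci_low, cmp_.ci_high],
                "significant": cmp_.significant}
        summary["baselines"] = base

    if "durations" in stages:
        obs = durations.momentum_observations(trajectories)
        fit = durations.fit_piecewise(obs["dphi"].to_numpy(),
                                      obs["da"].to_numpy(),
                                      obs["duration"].to_numpy())
        hill = durations.fit_hill(
            np.hypot(obs["cx"] - obs["ax"], obs["cy"] - obs["ay"]).to_numpy(),
            obs["duration"].to_numpy())
        summary["durations"] = {
            "piecewise": {"beta0": fit.beta0, "s1": fit.s1, "s2": fit.s2,
                          "c": fit.c, "u": fit.u, "o": fit.o, "r2": fit.r2},
            "hill": {"intercept": hill.intercept, "k": hill.k,
                     "sigma": hill.sigma, "r2": hill.r2}}
        with open(out / "duration_fits.json", "w") as fh:
            json.dump(summary["durations"], fh, indent=1)
        dmap = durations.binned_duration_map(obs["dphi"], obs["da"],
                                             obs["duration"])
        pd.DataFrame(dmap.mean).to_csv(out / "duration_map.csv")

    if "saliency" in stages:
        if cohort is None:
            raise ValueError("saliency stage needs synthetic images; "
                             "external image corpora are supplied through "
                             "the library API")
        from refix import saliency as sal
        ppd = cfg.get("pixels_per_degree", 12.0)
        images = synthetic.generate_images(cohort.spec, ppd, seed=seed)
        bank = {im: sal.compute_feature_bank(img, pixels_per_degree=ppd)
                for im, img in images.items()}
        fix_by_image = {
            im: synthetic.degrees_to_pixels(
                np.concatenate([t.x for t in trajectories if t.image == im]),
                np.concatenate([t.y for t in trajectories if t.image == im]),
                cohort.spec, ppd)
            for im in images}
        aucs = []
        feat_names = [fm.name for fm in next(iter(bank.values()))]
        for fi, name in enumerate(feat_names):
            pos_vals, ctl_vals = [], []
            for im in images:
                fm = bank[im][fi]
                pos_vals.append(sal.lookup(fm, fix_by_image[im]))
                ctl = sal.sample_controls(im, fix_by_image,
                                          len(fix_by_image[im]),
                                          seed=seed + 5 + fi)
                ctl_vals.append(sal.lookup(fm, ctl))
            res = sal.feature_auc(np.concatenate(pos_vals),
                                  np.concatenate(ctl_vals),
                                  n_repeats=30, n_boot=cfg["n_boot"],
                                  seed=seed + 6 + fi, feature=name)
            aucs.append((name, res.auc, res.ci_low, res.ci_high))
        pd.DataFrame(aucs, columns=["feature", "auc", "ci_low", "ci_high"]
                     ).to_csv(out / "feature_auc.csv", index=False)
        summary["saliency"] = {"n_features": len(aucs),
                               "mean_auc": float(np.mean([a[1] for a in aucs]))}

    if "foraging" in stages:
        fcfg = cfg["foraging"]
        ds = cohort.dataset_of() if cohort is not None else None
        extent = (tuple(cohort.spec.screen_extent) if cohort is not None
                  else fcfg.get("extent"))
        summ = foraging.foraging_summary(
            trajectories, dataset_of=ds, fwhm=fcfg["fwhm"],
            resolution=fcfg["resolution"], extent=extent,
            return_region_radius=cfg["return_region_radius"],
            n_boot=cfg["n_boot"], seed=seed + 7)
        summ.per_dataset.to_csv(out / "foraging_summary.csv", index=False)
        emp = summ.per_dataset.query("map_type == 'empirical'")
        flat = summ.per_dataset.query("map_type == 'flat'")
        summary["foraging"] = {
            "mean_delta_empirical": float(emp["mean_delta"].mean()),
            "mean_delta_flat": float(flat["mean_delta"].mean()),
            "n_trajectories": int(
                (summ.deltas["map_type"] == "empirical").sum())}

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    logger.info("pipeline finished: %s", out / "summary.json")
    return summary
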