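"""End-to-end orchestration: simulate → calibrate → chronology →
envmetrics → analyze, as restartable stages over plain files.

Every stage reads and writes files in the run directory, so any stage can be
rerun or tested in isolation; the resolved configuration (with the seed) is
echoed into the run directory and hashed, and completed stages are skipped on
rerun if the configuration is unchanged.  A stage failure aborts with the
stage name; partial outputs are left in place for inspection.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import densitometry as dns
from . import env_metrics as em
from . import growth_stats as gs
from . import io as cio
from . import study
from .synthetic import BandingSpec, gen_core_image

log = logging.getLogger(__name__)

STAGES = ("simulate", "calibrate", "chronology", "envmetrics", "analyze")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (all defaults serialisable)."""

    seed: int = 0
    years: tuple = (1998, 2016)
    subset: str = "interannual"          # or "spatial"
    n_image_cores: int = 2               # cores rendered through the CT path
    collection_date: str = "2017-05-01"
    banding: dict = field(default_factory=lambda: {
        "double_band_prob": 0.0, "grey_noise_sd": 20.0,
        "cross_section_mm": 6.0})
    densitometry: dict = field(default_factory=lambda: {
        "window_mm": 5.0, "step_um": 50.0, "smooth_window": 5,
        "min_prominence": 0.02, "min_separation_um": 2000.0,
        "merge_rel_threshold": 0.6})
    analysis: dict = field(default_factory=lambda: {
        "baseline": (1998, 2012), "exclude_years": (2013, 2016),
        "make_figures": True})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key: {k}")
            current = getattr(cfg, k)
            if isinstance(current, dict) and isinstance(v, dict):
                current.update(v)
            elif k in ("years",):
                setattr(cfg, k, tuple(v))
            else:
                setattr(cfg, k, v)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["years"] = list(self.years)
        d["analysis"] = {k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in self.analysis.items()}
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _manifest(outdir: Path) -> dict:
    p = outdir / "manifest.json"
    return json.loads(p.read_text()) if p.exists() else {}


def _mark_done(outdir: Path, stage: str, digest: str) -> None:
    m = _manifest(outdir)
    m[stage] = digest
    (outdir / "manifest.json").write_text(json.dumps(m, indent=2))


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Run (or resume) the full pipeline into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "run_config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    digest = config.digest()
    done = _manifest(outdir)
    state: dict = {}
    for stage in STAGES:
        fn = globals()[f"_stage_{stage}"]
        if done.get(stage) == digest:
            log.info("stage %s up to date, skipping", stage)
            continue
        log.info("running stage %s", stage)
        try:
            fn(config, outdir, state)
        except Exception as exc:       # noqa: BLE001 - rewrap with stage name
            raise PipelineError(stage, exc) from exc
        _mark_done(outdir, stage, digest)
    return outdir


# --------------------------------------------------------------------- stages

def _stage_simulate(cfg: RunConfig, outdir: Path, state: dict) -> None:
    s = study.generate_study(cfg.seed, subset=cfg.subset, years=cfg.years)
    envdir = outdir / "env"
    envdir.mkdir(exist_ok=True)
    for loc, env in s["env"].items():
        cio.write_env_csv(env, envdir / f"{loc.replace(' ', '_')}.csv")
    cio.write_growth_csv(s["growth"], outdir / "growth_true.csv")
    bspec = BandingSpec(**cfg.banding)
    coredir = outdir / "cores"
    coredir.mkdir(exist_ok=True)
    image_cores = sorted(s["growth"]["core_id"].unique())[: cfg.n_image_cores]
    ss = np.random.SeedSequence(cfg.seed).spawn(len(image_cores) + 10)
    truth_boundaries = {}
    for i, core in enumerate(image_cores):
        sub = (s["growth"][s["growth"].core_id == core]
               .sort_values("year", ascending=False))
        result = gen_core_image(sub["extension_cm"].to_numpy(), bspec, ss[i])
        stem = core.replace(" ", "_")
        cio.write_core_tiff(result.image, coredir / f"{stem}.tiff",
                            result.voxel_pitch_um, {"core_id": core})
        cio.write_core_tiff(result.standard_image, coredir / f"{stem}_standard.tiff",
                            result.voxel_pitch_um, {"core_id": core})
        greys = [float(result.standard_image[r].mean())
                 for r in result.standard_regions]
        cio.write_standard_csv(result.insert_density, greys,
                               coredir / f"{stem}_standard.csv")
        truth_boundaries[core] = result.boundaries_um.tolist()
    (outdir / "image_truth.json").write_text(json.dumps(
        {"image_cores": list(image_cores), "boundaries_um": truth_boundaries}))
    state["study"] = s


def _stage_calibrate(cfg: RunConfig, outdir: Path, state: dict) -> None:
    curves = {}
    for csv in sorted((outdir / "cores").glob("*_standard.csv")):
        std = cio.read_standard_csv(csv)
        curve = dns.fit_calibration(std)
        curves[csv.stem.replace("_standard", "")] = {
            "slope": curve.slope, "intercept": curve.intercept,
            "r_squared": curve.r_squared}
    (outdir / "calibration.json").write_text(json.dumps(curves, indent=2))


def _stage_chronology(cfg: RunConfig, outdir: Path, state: dict) -> None:
    curves = json.loads((outdir / "calibration.json").read_text())
    info = json.loads((outdir / "image_truth.json").read_text())
    truth = cio.read_growth_csv(outdir / "growth_true.csv")
    d = cfg.densitometry
    rows = []
    for core in info["image_cores"]:
        stem = core.replace(" ", "_")
        image, meta = cio.read_core_tiff(outdir / "cores" / f"{stem}.tiff")
        c = curves[stem]
        curve = dns.CalibrationCurve(c["slope"], c["intercept"], c["r_squared"])
        profile = dns.extract_profile(
            image, curve, window_mm=d["window_mm"], step_um=d["step_um"],
            voxel_pitch_um=meta["voxel_pitch_um"])
        maxima = dns.detect_density_maxima(
            profile, smooth_window=d["smooth_window"],
            min_prominence=d["min_prominence"],
            min_separation_um=d["min_separation_um"])
        chron = dns.build_chronology(maxima, cfg.collection_date, profile)
        if cfg.banding.get("double_band_prob", 0) > 0:
            chron = dns.merge_double_bands(
                chron, rel_threshold=d["merge_rel_threshold"])
        chron.to_csv(outdir / "cores" / f"{stem}_chronology.csv", core_id=core)
        loc = truth.loc[truth.core_id == core, "location_id"].iloc[0]
        for _, r in chron.table.iterrows():
            rows.append({"core_id": core, "location_id": loc,
                         "year": int(r["year"]),
                         "extension_cm": r["extension_cm"],
                         "density_g_cm3": r["density_g_cm3"],
                         "calcification_g_cm2yr": r["calcification_g_cm2yr"],
                         "source": "ct"})
    observed = pd.DataFrame(rows)
    rest = truth[~truth.core_id.isin(info["image_cores"])].copy()
    rest["source"] = "simulated"
    observed = pd.concat([observed, rest[["core_id", "location_id", "year",
                                          "extension_cm", "source"]]],
                         ignore_index=True)
    observed = observed[observed["year"].between(*cfg.years)]
    cio.write_growth_csv(observed, outdir / "growth_observed.csv")


def _stage_envmetrics(cfg: RunConfig, outdir: Path, state: dict) -> None:
    rows = []
    for csv in sorted((outdir / "env").glob("*.csv")):
        loc = csv.stem.replace("_", " ")
        env = cio.read_env_csv(csv)
        kd = em.annual_mean(env, "kd490").set_index("year")["mean"]
        sst = em.annual_mean(env, "sst").set_index("year")["mean"]
        summer = em.summer_mean_sst(env).set_index("year")["mean"]
        clim = em.sst_climatology(env, cfg.years)
        ts = em.compute_dhw(env, clim)
        dhw = em.annual_max_dhw(ts).set_index("year")["max_dhw"]
        for y in range(cfg.years[0], cfg.years[1] + 1):
            rows.append({"location_id": loc, "year": y,
                         "kd490": kd.get(y, np.nan),
                         "sst": sst.get(y, np.nan),
                         "sst_summer": summer.get(y, np.nan),
                         "max_dhw": dhw.get(y, np.nan),
                         "events_ge4": em.count_stress_events(
                             ts, 4.0, bin_interval=(y, y))})
    annual = pd.DataFrame(rows)
    annual.to_csv(outdir / "env_annual.csv", index=False)
    binned = []
    for loc, sub in annual.groupby("location_id"):
        b = em.five_year_bin(sub.drop(columns="location_id"),
                             {"max_dhw": "max", "events_ge4": "sum"})
        b.insert(0, "location_id", loc)
        binned.append(b)
    pd.concat(binned, ignore_index=True).to_csv(outdir / "env_binned.csv",
                                                index=False)


def _bin_label(year: int) -> str:
    for b0, b1 in em.FIVE_YEAR_BINS:
        if b0 <= year <= b1:
            return f"{b0}-{b1}"
    raise ValueError(f"year {year} outside bins")


def _stage_analyze(cfg: RunConfig, outdir: Path, state: dict) -> None:
    growth = cio.read_growth_csv(outdir / "growth_observed.csv")
    annual_env = pd.read_csv(outdir / "env_annual.csv")
    data = growth.merge(annual_env, on=["location_id", "year"], how="left")
    report: dict = {}

    glm_annual = gs.fit_glm(data, "extension_cm", "kd490", name="annual pooled")
    ex0, ex1 = cfg.analysis["exclude_years"]
    loc_means = (data[~data.year.between(ex0, ex1)]
                 .groupby("location_id")[["extension_cm", "kd490"]]
                 .mean().reset_index())
    report["glm_annual"] = _fit_report(glm_annual)
    if len(loc_means) > 3:
        report["glm_location"] = _fit_report(
            gs.fit_glm(loc_means, "extension_cm", "kd490", name="location means"))

    data["bin"] = [_bin_label(y) for y in data["year"]]
    rm = gs.rm_anova_tukey(data, subject="core_id", within="bin",
                           value="extension_cm")
    rm.anova.to_csv(outdir / "rm_anova.csv", index=False)
    rm.tukey.to_csv(outdir / "tukey.csv", index=False)
    report["rm_anova"] = {"F": rm.F, "p": rm.p,
                          "n_subjects": rm.n_subjects,
                          "excluded": rm.excluded_subjects}

    rel, excluded = gs.relative_extension(
        growth, baseline=tuple(cfg.analysis["baseline"]),
        full_period=cfg.years)
    comp = gs.composite(rel, by="all")
    comp.to_csv(outdir / "composite_relative.csv", index=False)
    report["relative_excluded_cores"] = excluded

    if data["core_id"].nunique() >= 2:
        candidates = [
            ("kd490",), ("sst",), ("kd490", "sst_summer"),
            ("kd490", "max_dhw"), ("sst_summer", "max_dhw"),
            ("kd490", "sst_summer", "max_dhw"),
        ]
        fits = []
        for fixed in candidates:
            spec = gs.ModelSpec(response="extension_cm", fixed=fixed,
                                random=("location", "core"), ar1=True)
            fits.append(gs.fit_mixed_model(data.dropna(subset=["max_dhw"]), spec))
        ranked = gs.model_selection_aic(fits)
        ranked.to_csv(outdir / "model_selection.csv", index=False)
        best = fits[int(np.argmin([f.aic for f in fits]))]
        report["mixed_best"] = {
            "fixed": list(best.spec.fixed),
            "coefficients": best.params.to_dict(),
            "rho": best.rho, "aic": best.aic, "r_squared": best.r_squared}

    (outdir / "fit_report.json").write_text(json.dumps(report, indent=2))
    if cfg.analysis.get("make_figures", True):
        _figures(outdir, data, comp, annual_env)


def _fit_report(fit: gs.ModelFit) -> dict:
    return {"params": fit.params.to_dict(), "pvalues": fit.pvalues.to_dict(),
            "r_squared": fit.r_squared, "n": fit.nobs}


def _figures(outdir: Path, data: pd.DataFrame, comp: pd.DataFrame,
             annual_env: pd.DataFrame) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    core_means = data.groupby("core_id")[["extension_cm", "kd490"]].mean()
    ax.scatter(core_means["kd490"], core_means["extension_cm"])
    fit = gs.fit_glm(core_means.reset_index(), "extension_cm", "kd490")
    xs = np.linspace(core_means["kd490"].min(), core_means["kd490"].max(), 50)
    ax.plot(xs, fit.params["intercept"] + fit.params["kd490"] * xs, "k-")
    ax.set_xlabel("K$_{d}$490 (m$^{-1}$)")
    ax.set_ylabel("linear extension (cm/yr)")
    fig.tight_layout()
    fig.savefig(outdir / "fig_extension_vs_turbidity.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    binned = data.groupby(["bin"])["extension_cm"].agg(["mean", "sem"])
    ax.bar(binned.index, binned["mean"], yerr=binned["sem"], color="tan")
    ax.set_ylabel("linear extension (cm/yr)")
    fig.tight_layout()
    fig.savefig(outdir / "fig_binned_extension.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 4))
    dhw_max = annual_env.groupby("year")["max_dhw"].max()
    ax2 = ax.twinx()
    ax2.bar(dhw_max.index, dhw_max.to_numpy(), color="0.8", width=0.6,
            label="max DHW")
    ax2.set_ylabel("DHW (°C-weeks)")
    ax.errorbar(comp["year"], comp["relative_extension"], yerr=comp["se"],
                color="k", marker="o", label="composite")
    ax.axhline(0, color="0.5", lw=0.5)
    ax.set_ylabel("relative extension (%)")
    ax.set_zorder(ax2.get_zorder() + 1)
    ax.patch.set_visible(False)
    fig.tight_layout()
    fig.savefig(outdir / "fig_composite_dhw.png", dpi=120)
    plt.close(fig)
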