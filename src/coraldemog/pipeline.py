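"""End-to-end pipeline: simulate -> env -> sizes -> changes -> models.

Every stage writes tidy CSV under a single run directory, and a JSON manifest
records the seed, package/library versions, SHA-256 digests of stage inputs
and any warnings raised, so a rerun at the same seed is verifiably identical.
Stage seeds are derived deterministically from the single mandatory top-level
seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from copy import deepcopy
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml
from scipy.special import logit

from . import bayes_models as bm
from . import change_metrics as cm
from . import env_metrics as em
from . import size_structure as ss
from . import synth

__all__ = ["DEMO_CONFIG", "STAGES", "load_config", "validate_config", "run_pipeline"]

logger = logging.getLogger("coraldemog")

STAGES = ("simulate", "env", "sizes", "changes", "models")

# Bundled demonstration configuration. Survey design mirrors the study region:
# two inshore and two offshore sites, austral-spring visits in 2010/2012/2018/
# 2019 plus April and October 2016 (the bleaching year), three belt transects
# per site. Size targets are the published genus-level summaries; abundances,
# habitat contrasts (offshore ~1 °C warmer, inshore higher Chl-a, Pocillopora
# more abundant offshore, Turbinaria inshore) are scaled-down but realistic.
DEMO_CONFIG: dict = {
    "seed": 20160401,
    "run_dir": "runs/demo",
    "include_partially_captured": True,
    "n_boot": 1000,
    "mcmc": {"chains": 3, "iterations": 1500, "warmup": 300, "thin": 5},
    "generator": {
        "sites": {
            "Northwest Solitary": "inshore",
            "Southwest Solitary": "inshore",
            "North Solitary": "offshore",
            "South Solitary": "offshore",
        },
        "surveys": [[2010, 10], [2012, 10], [2016, 4], [2016, 10], [2018, 10], [2019, 10]],
        "transects": 3,
        "partial_capture_rate": 0.107,
        "taxa": {
            "Pocillopora": {
                "mean_area": 66.42, "cv_log": 0.51, "skew_log": -0.03,
                "inshore_mean_factor": 1.3, "offshore_mean_factor": 0.85,
                "n_inshore": 60, "n_offshore": 130,
                "bleach_rate": 0.806, "bleach_slope": 0.35,
                "pm_rate_unbleached": 0.0183, "pm_bleached_boost": 1.14,
                "pm_slope": 0.25,
            },
            "Turbinaria": {
                "mean_area": 708.47, "cv_log": 0.31, "skew_log": -0.29,
                "inshore_mean_factor": 1.3, "offshore_mean_factor": 0.85,
                "n_inshore": 60, "n_offshore": 25,
                "bleach_rate": 0.653, "bleach_slope": 0.5,
                "pm_rate_unbleached": 0.0183, "pm_bleached_boost": 1.14,
                "pm_slope": 0.0,
            },
            "Acropora": {
                "mean_area": 180.0, "cv_log": 0.42, "skew_log": 0.05,
                "inshore_mean_factor": 1.3, "offshore_mean_factor": 0.85,
                "n_inshore": 40, "n_offshore": 40,
                "bleach_rate": 0.069, "bleach_slope": 0.0,
                "pm_rate_unbleached": 0.0183, "pm_bleached_boost": 1.14,
                "pm_slope": 0.3,
            },
        },
        "env": {
            "start": "2008-01-01",
            "end": "2019-12-31",
            "inshore": {
                "baseline_sst": 21.0, "seasonal_amplitude": 3.2, "sst_noise_sd": 0.3,
                "chla_baseline": 0.9, "chla_seasonal_amplitude": 0.25,
                "chla_noise_sd": 0.08,
                "anomaly_events": [
                    ["2012-06-15", 70, -1.8],
                    ["2016-02-01", 80, 1.6],
                ],
                "gap_spec": [["2013-03-01", 12], ["2017-08-10", 8]],
            },
            "offshore": {
                "baseline_sst": 22.0, "seasonal_amplitude": 3.2, "sst_noise_sd": 0.3,
                "chla_baseline": 0.45, "chla_seasonal_amplitude": 0.12,
                "chla_noise_sd": 0.05,
                "anomaly_events": [
                    ["2012-06-15", 70, -1.0],
                    ["2016-02-01", 80, 2.2],
                ],
                "gap_spec": [["2011-05-01", 10], ["2018-01-20", 15]],
            },
        },
    },
}


def load_config(path: str | Path) -> dict:
    """Read a YAML pipeline config and validate it."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    """Fill defaults and enforce the schema; the seed is mandatory."""
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a mapping")
    if "seed" not in cfg:
        raise ValueError("pipeline config must set a seed")
    out = deepcopy(DEMO_CONFIG)
    out.update(deepcopy(cfg))
    if "mcmc" in cfg:
        out["mcmc"] = {**DEMO_CONFIG["mcmc"], **cfg["mcmc"]}
    gen = out["generator"]
    for key in ("sites", "surveys", "taxa", "env"):
        if key not in gen:
            raise ValueError(f"generator config missing {key!r}")
    return out


def _stage_seed(seed: int, k: int) -> int:
    return int((seed * 1000003 + 7919 * (k + 1)) % (2**31 - 1))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _build_generator(cfg: dict):
    gen = cfg["generator"]
    size_models: dict[tuple[str, str], synth.TaxonSizeModel] = {}
    condition_models: dict[str, synth.ConditionModel] = {}
    for genus, t in gen["taxa"].items():
        for habitat, factor_key, n_key in (
            ("inshore", "inshore_mean_factor", "n_inshore"),
            ("offshore", "offshore_mean_factor", "n_offshore"),
        ):
            size_models[(genus, habitat)] = synth.solve_size_params(
                t["mean_area"] * t.get(factor_key, 1.0),
                t["cv_log"],
                t["skew_log"],
                taxon=genus,
                habitat=habitat,
                n_per_stratum=int(t[n_key]),
            )
        center = float(
            np.mean([size_models[(genus, h)].mean_log for h in ("inshore", "offshore")])
        )
        condition_models[genus] = synth.ConditionModel(
            bleach_intercept=float(logit(t["bleach_rate"])),
            bleach_slope=float(t.get("bleach_slope", 0.0)),
            pm_intercept=float(logit(t["pm_rate_unbleached"])),
            pm_slope=float(t.get("pm_slope", 0.0)),
            pm_bleached_boost=float(t.get("pm_bleached_boost", 0.0)),
            partial_capture_rate=float(gen.get("partial_capture_rate", 0.107)),
            logarea_center=center,
        )
    design = synth.SurveyDesign(
        sites=dict(gen["sites"]),
        surveys=[tuple(s) for s in gen["surveys"]],
        transects=int(gen.get("transects", 3)),
    )
    return size_models, condition_models, design


def _stage_simulate(cfg: dict, run_dir: Path) -> None:
    size_models, condition_models, design = _build_generator(cfg)
    table = synth.generate_colony_table(
        size_models, condition_models, design, seed=_stage_seed(cfg["seed"], 0)
    )
    table.to_csv(run_dir / "colonies.csv", index=False)
    env_cfg = cfg["generator"]["env"]
    sst_rows, chla_rows = [], []
    for i, (site, habitat) in enumerate(sorted(cfg["generator"]["sites"].items())):
        hc = env_cfg[habitat]
        model = synth.EnvModel(
            baseline_sst=hc["baseline_sst"],
            seasonal_amplitude=hc["seasonal_amplitude"],
            anomaly_events=[tuple(e) for e in hc.get("anomaly_events", [])],
            chla_baseline=hc["chla_baseline"],
            chla_seasonal_amplitude=hc["chla_seasonal_amplitude"],
            gap_spec=[tuple(g) for g in hc.get("gap_spec", [])],
            sst_noise_sd=hc.get("sst_noise_sd", 0.0),
            chla_noise_sd=hc.get("chla_noise_sd", 0.0),
        )
        sst, chla = synth.generate_daily_env(
            model, env_cfg["start"], env_cfg["end"],
            seed=_stage_seed(cfg["seed"], 100 + i), site=site,
        )
        sst_rows.append(pd.DataFrame({"site": site, "date": sst.index, "value": sst.values}))
        chla_rows.append(pd.DataFrame({"site": site, "date": chla.index, "value": chla.values}))
    pd.concat(sst_rows).to_csv(run_dir / "sst.csv", index=False)
    pd.concat(chla_rows).to_csv(run_dir / "chla.csv", index=False)


def _stage_env(cfg: dict, run_dir: Path) -> None:
    sst_by_site = em.read_daily_csv(run_dir / "sst.csv")
    chla_by_site = em.read_daily_csv(run_dir / "chla.csv")
    stress_rows, annual_rows = [], []
    for site, sst in sst_by_site.items():
        clim = em.compute_climatology(sst)
        stress = em.build_stress_series(sst, clim)
        chla = em.gap_fill_linear(chla_by_site[site])
        annual_rows.append(em.annual_summaries(sst, chla, stress))
        sf = stress.frame.reset_index(names="date")
        sf.insert(0, "site", site)
        stress_rows.append(sf)
    pd.concat(stress_rows).to_csv(run_dir / "stress.csv", index=False)
    pd.concat(annual_rows).to_csv(run_dir / "env_annual.csv", index=False)


def _stage_sizes(cfg: dict, run_dir: Path) -> None:
    raw = pd.read_csv(run_dir / "colonies.csv")
    table = ss.preprocess(raw, cfg["include_partially_captured"])
    schemes = ss.build_schemes(table)
    classified = ss.assign_size_classes(table, schemes)
    classified.to_csv(run_dir / "colonies_classified.csv", index=False)
    ss.summarize_sizes(classified).to_csv(run_dir / "size_summaries.csv", index=False)

    ks_rows = []
    genera = sorted(classified["genus"].unique())
    for i, ga in enumerate(genera):  # among taxa, pooled sites/years
        for gb in genera[i + 1 :]:
            res = ss.ks_compare(
                classified.loc[classified["genus"] == ga, "log_area"],
                classified.loc[classified["genus"] == gb, "log_area"],
            )
            ks_rows.append({"comparison": f"{ga} vs {gb}", "genus": "", **vars(res)})
    for genus in genera:  # inshore vs offshore within taxa
        sub = classified[classified["genus"] == genus]
        res = ss.ks_compare(
            sub.loc[sub["shelf"] == "inshore", "log_area"],
            sub.loc[sub["shelf"] == "offshore", "log_area"],
        )
        ks_rows.append({"comparison": "inshore vs offshore", "genus": genus, **vars(res)})
        for pa, pb in cm.DEFAULT_PERIOD_PAIRS:  # periods within taxa x habitat
            for shelf in ("inshore", "offshore"):
                cell = sub[sub["shelf"] == shelf]
                a = cell.loc[cell["period"] == pa, "log_area"]
                b = cell.loc[cell["period"] == pb, "log_area"]
                if len(a) and len(b):
                    res = ss.ks_compare(a, b)
                    ks_rows.append(
                        {"comparison": f"{shelf} {pa} vs {pb}", "genus": genus,
                         **vars(res)}
                    )
    pd.DataFrame(ks_rows).to_csv(run_dir / "ks_tests.csv", index=False)


def _stage_changes(cfg: dict, run_dir: Path) -> None:
    table = pd.read_csv(run_dir / "colonies_classified.csv")
    schemes = ss.build_schemes(table)
    changes = cm.bootstrap_changes(
        table, schemes, n_boot=int(cfg["n_boot"]), seed=_stage_seed(cfg["seed"], 2)
    )
    changes.to_csv(run_dir / "changes.csv", index=False)


def _stage_models(cfg: dict, run_dir: Path) -> None:
    table = pd.read_csv(run_dir / "colonies_classified.csv")
    mcfg = cfg["mcmc"]
    settings = bm.MCMCSettings(
        chains=mcfg["chains"], iterations=mcfg["iterations"],
        warmup=mcfg["warmup"], thin=mcfg["thin"],
        seed=_stage_seed(cfg["seed"], 3),
    )
    summaries = []

    def record(fit: bm.FitResult) -> None:
        s = fit.summary()
        s.insert(0, "model", fit.spec.name)
        s["bayes_r2"] = fit.bayes_r2
        s["looic"] = fit.looic
        summaries.append(s)

    table = table.rename(columns={"log_area": "logArea"})
    bleach_fit = bm.fit_glm(
        bm.ModelSpec("bleached", ("logArea", "genus"), (("logArea", "genus"),),
                     "bernoulli_logit"),
        table, settings,
    )
    record(bleach_fit)
    pm_fit = bm.fit_glm(
        bm.ModelSpec("partial_mortality", ("bleached",), (), "bernoulli_logit"),
        table, settings,
    )
    record(pm_fit)
    pd.concat(summaries).to_csv(run_dir / "model_params.csv", index=False)

    # environmental correlates of small-coral abundance, per genus
    table = table.rename(columns={"logArea": "log_area"})
    env_annual = pd.read_csv(run_dir / "env_annual.csv")
    comp_rows = []
    screen = None
    for genus in sorted(table["genus"].unique()):
        joined = bm.small_coral_table(table, env_annual, genus)
        screen = bm.collinearity_screen(
            joined[list(bm._ENV_PREDICTORS)], r_threshold=0.8
        )
        specs = bm.small_coral_model_set(screen.retained)
        _, comparison = bm.fit_model_set(specs, joined, settings, force=True)
        t = comparison.table()
        t.insert(0, "genus", genus)
        comp_rows.append(t)
    pd.concat(comp_rows).to_csv(run_dir / "model_comparison.csv", index=False)
    if screen is not None:
        screen.correlations.to_csv(run_dir / "env_correlations.csv")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "env": _stage_env,
    "sizes": _stage_sizes,
    "changes": _stage_changes,
    "models": _stage_models,
}

_STAGE_INPUTS = {
    "simulate": [],
    "env": ["sst.csv", "chla.csv"],
    "sizes": ["colonies.csv"],
    "changes": ["colonies_classified.csv"],
    "models": ["colonies_classified.csv", "env_annual.csv"],
}


def run_pipeline(cfg: dict, stages: tuple[str, ...] = STAGES) -> Path:
    """Execute the requested stages in order, writing outputs and a manifest.

    Any stage failure leaves partial outputs in place, records the failure in
    the manifest, and re-raises.
    """
    cfg = validate_config(cfg)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    run_dir = Path(cfg["run_dir"])
    run_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(run_dir / "run.log")
    logger.addHandler(handler)
    manifest: dict = {
        "seed": cfg["seed"],
        "stages": [],
        "versions": {
            "coraldemog": _package_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "input_digests": {},
        "warnings": [],
    }
    try:
        for stage in [s for s in STAGES if s in stages]:
            logger.info("running stage %s", stage)
            for dep in _STAGE_INPUTS[stage]:
                path = run_dir / dep
                if not path.exists():
                    raise FileNotFoundError(
                        f"stage {stage!r} requires {dep} (run earlier stages first)"
                    )
                manifest["input_digests"][dep] = _digest(path)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                _STAGE_FUNCS[stage](cfg, run_dir)
            for w in caught:
                msg = f"{stage}: {w.message}"
                logger.warning(msg)
                manifest["warnings"].append(msg)
            manifest["stages"].append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = repr(exc)
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        logger.removeHandler(handler)
        raise
    manifest["output_digests"] = {
        p.name: _digest(p) for p in sorted(run_dir.glob("*.csv"))
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.removeHandler(handler)
    return run_dir


def _package_version() -> str:
    from . import __version__

    return __version__
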