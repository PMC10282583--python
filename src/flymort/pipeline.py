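"""End-to-end pipeline: records -> KM + rank tests -> model selection -> bands.

Runs the full demographic analysis on one records file (or a freshly simulated
cohort): Kaplan-Meier curves per group, the two stratified Gehan-Breslow
comparisons (treatment stratified by sex, sex stratified by treatment), AIC
model selection over the candidate hazard models, marginal and conditional
curves, and the four log-mortality difference bands (treatment within each
sex, sex within each treatment).  Every run writes a manifest recording the
input checksum, configuration hash, seeds, package versions and per-stage
wall time.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .contrasts import bootstrap_refits, difference_band, marginal_hazard, observable_grid
from .hazgam import CANDIDATE_SPECS, fit_hazard_model, predict_log_hazard, select_model
from .ioutils import read_config, read_records_csv, sha256_file, sha256_obj, write_json
from .lifetable import build_lifetable
from .survnp import gehan_breslow_stratified, km_fit, km_frame
from .synth import SEXES, TREATMENTS, CohortDesign, GompertzFrailtyParams, simulate_cohort

#: the four headline comparisons: (stratum A, stratum B) as (sex, treatment)
DEFAULT_PAIRS = (
    (("female", "rapamycin"), ("female", "control")),
    (("male", "rapamycin"), ("male", "control")),
    (("female", "control"), ("male", "control")),
    (("female", "rapamycin"), ("male", "rapamycin")),
)


@dataclass
class PipelineConfig:
    records: str | None = None  # input CSV; None -> simulate
    out_dir: str = "flymort_out"
    bin_width: float = 3.0
    model_spec: str = "full"
    select: bool = True
    basis_k: int = 10
    n_boot: int = 1000
    alpha: float = 0.05
    seed: int = 0
    flavor: str = "marginal"
    rank_test_method: str = "asymptotic"
    # generator settings, used only when records is None
    n_isolines: int = 14
    n_per_group: int = 90
    censor_prob_per_check: float = 0.002
    max_age: float = 150.0

    def __post_init__(self) -> None:
        if self.n_boot < 200:
            raise ValueError("n_boot must be >= 200")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.flavor not in ("marginal", "conditional"):
            raise ValueError("flavor must be 'marginal' or 'conditional'")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.seed is None:
            raise ValueError("a seed is mandatory (bootstrap and simulation)")

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        cfg = read_config(path)
        cfg.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**cfg)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to out_dir)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": sha256_obj(asdict(config)),
        "versions": {"flymort": __version__, "numpy": np.__version__, "pandas": pd.__version__},
        "stages": {},
        "outputs": {},
    }
    rng = np.random.default_rng(config.seed)
    seeds = {name: int(rng.integers(2**31 - 1)) for name in ("simulate", "ranktest", "bootstrap")}
    manifest["seeds"] = seeds

    def stage(name):
        t0 = time.perf_counter()

        def done():
            manifest["stages"][name] = round(time.perf_counter() - t0, 3)

        return done

    fin = stage("records")
    if config.records is None:
        design = CohortDesign(
            n_isolines=config.n_isolines,
            n_per_group=config.n_per_group,
            censor_prob_per_check=config.censor_prob_per_check,
            max_age=config.max_age,
            seed=seeds["simulate"],
        )
        cohort = simulate_cohort(design, GompertzFrailtyParams())
        records = cohort.to_frame()
        rec_path = out / "records.csv"
        records.to_csv(rec_path, index=False)
    else:
        rec_path = Path(config.records)
        records = read_records_csv(rec_path)
    manifest["input_checksum"] = sha256_file(rec_path)
    fin()

    fin = stage("lifetable")
    lt = build_lifetable(records, bin_width=config.bin_width)
    lt.to_csv(out / "lifetable.csv")
    manifest["outputs"]["lifetable"] = "lifetable.csv"
    fin()

    fin = stage("survnp")
    curves = km_fit(records, ["sex", "treatment"])
    km_frame(curves).to_csv(out / "km_curves.csv", index=False)
    tests = {
        "treatment|sex": gehan_breslow_stratified(
            records, compare="treatment", strata="sex",
            method=config.rank_test_method, seed=seeds["ranktest"],
        ),
        "sex|treatment": gehan_breslow_stratified(
            records, compare="sex", strata="treatment",
            method=config.rank_test_method, seed=seeds["ranktest"],
        ),
    }
    manifest["rank_tests"] = {
        k: {"statistic": r.statistic, "p_value": r.p_value, "method": r.method}
        for k, r in tests.items()
    }
    fin()

    fin = stage("hazgam")
    if config.select:
        fits = select_model(lt, list(CANDIDATE_SPECS.values()))
        fit = fits[0]
        manifest["model_selection"] = [
            {"spec": f.spec.name, "aic": f.aic, "edf": f.edf, "delta_aic": f.delta_aic}
            for f in fits
        ]
    else:
        fit = fit_hazard_model(lt, config.model_spec)
    manifest["selected_model"] = {
        "spec": fit.spec.name,
        "aic": fit.aic,
        "edf": fit.edf,
        "lambdas": fit.lambdas,
    }
    write_json(
        {
            "spec": fit.spec.name,
            "coefficients": fit.coef,
            "lambdas": fit.lambdas,
            "edf": fit.edf,
            "aic": fit.aic,
            "knots": fit.basis.knots,
        },
        out / "fit.json",
    )
    rows = []
    for s in SEXES:
        for t in TREATMENTS:
            if (s, t) not in fit.design.stratum_age_range:
                continue
            grid = observable_grid(fit, (s, t))
            cond = predict_log_hazard(fit, grid, s, t)
            marg = marginal_hazard(fit, s, t, grid)
            for c in (cond, marg):
                for a, lm in zip(c.ages, c.log_mu):
                    rows.append({"stratum": c.stratum, "age": a, "log_mu": lm, "flavor": c.flavor})
    pd.DataFrame(rows).to_csv(out / "hazard_curves.csv", index=False)
    fin()

    fin = stage("contrasts")
    boot = bootstrap_refits(records, fit, n_boot=config.n_boot, seed=seeds["bootstrap"])
    manifest["bands"] = []
    for a, b in DEFAULT_PAIRS:
        band = difference_band(fit, boot, a, b, flavor=config.flavor, alpha=config.alpha)
        name = f"band_{band.label_a}_vs_{band.label_b}".replace(":", "-")
        pd.DataFrame(
            {
                "age": band.ages,
                "delta": band.delta,
                "lo": band.lower,
                "hi": band.upper,
                "significant": (band.lower > 0) | (band.upper < 0),
            }
        ).to_csv(out / f"{name}.csv", index=False)
        manifest["bands"].append(
            {
                "a": band.label_a,
                "b": band.label_b,
                "flavor": band.flavor,
                "file": f"{name}.csv",
                "significant_windows": [list(wdw) for wdw in band.significant_windows],
            }
        )
    fin()

    manifest["n_rank_tests"] = len(tests)
    manifest["n_bands"] = len(manifest["bands"])
    manifest["manifest_hash"] = sha256_obj(
        {k: manifest[k] for k in ("config_hash", "input_checksum", "seeds")}
    )
    write_json(manifest, out / "manifest.json")
    return manifest
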