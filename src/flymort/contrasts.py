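"""Marginal vs conditional mortality, difference curves and bootstrap bands.

The fitted model gives each isoline its own predicted hazard.  The *marginal*
(population) hazard at age x averages those per-isoline hazards weighted by
each isoline's surviving fraction,

    mu_bar(x) = sum_i w_i(x) mu_i(x),   w_i(x) = S_i(x) / sum_j S_j(x),

with S_i the survivorship implied by mu_i (trapezoidal cumulation).  Frailer
isolines die out first, so the marginal curve decelerates relative to the
*conditional* curve (isoline effects zeroed) — the frailty-heterogeneity
signature.  Differences of two curves of the same flavor get pointwise
percentile confidence bands from design-preserving bootstrap refits
(individuals resampled with replacement within each isoline x sex x treatment
cell; smoothing parameters frozen at the original fit's values), and the
maximal age windows where a band excludes zero are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .curves import DifferenceBand, HazardCurve, significant_windows
from .hazgam import HazardModelFit, predict_log_hazard
from .lifetable import records_frame
from .synth import EVENT_DEATH


def marginal_hazard(
    fit: HazardModelFit, sex: str, treatment: str, ages: np.ndarray | None = None
) -> HazardCurve:
    """Survivor-weighted marginal hazard for one sex x treatment stratum.

    Weights start uniform at age zero; survivorship is integrated from 0 with
    a constant-hazard back-extension from the first grid age.  For a model
    without isoline effects the marginal curve equals the conditional one.
    """
    if ages is None:
        ages = observable_grid(fit, (sex, treatment))
    ages = np.asarray(ages, dtype=float)
    log_mu = _marginal_log_mu(fit, fit.coef, sex, treatment, ages)
    return HazardCurve(ages, log_mu, "marginal", f"{sex}:{treatment}")


def survivor_weighted_marginal(ages: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Marginal log hazard from per-isoline log hazards on a grid.

    ``eta`` has one row per isoline (log mu_i at each age).  Survivorship per
    isoline is integrated by the trapezoid rule with a constant-hazard
    back-extension on [0, ages[0]]; weights are the normalized surviving
    fractions, so the result is a convex combination of the mu_i at every age.
    """
    ages = np.asarray(ages, dtype=float)
    eta = np.atleast_2d(np.asarray(eta, dtype=float))
    if np.any(np.abs(np.diff(eta, axis=1)) > 2.0):
        warnings.warn(
            "adjacent log-hazard jump exceeds 2; grid may be too coarse for "
            "stable survivorship integration",
            stacklevel=2,
        )
    mu = np.exp(eta)
    h = np.concatenate(
        [mu[:, :1] * ages[0], 0.5 * (mu[:, 1:] + mu[:, :-1]) * np.diff(ages)], axis=1
    ).cumsum(axis=1)
    log_s = -h
    log_w = log_s - _logsumexp0(log_s)
    return _logsumexp0(log_w + eta)


def _marginal_log_mu(
    fit: HazardModelFit, coef: np.ndarray, sex: str, treatment: str, ages: np.ndarray,
    pred_rows: np.ndarray | None = None,
) -> np.ndarray:
    if fit.spec.isoline_effects == "none":
        Xp = fit.design.prediction_matrix(ages, sex, treatment)
        return Xp @ coef
    if pred_rows is None:
        pred_rows = _per_isoline_matrix(fit, sex, treatment, ages)
    m = len(fit.design.isolines)
    eta = (pred_rows @ coef).reshape(m, len(ages))
    return survivor_weighted_marginal(ages, eta)


def _logsumexp0(a: np.ndarray) -> np.ndarray:
    m = a.max(axis=0)
    return m + np.log(np.exp(a - m).sum(axis=0))


def _per_isoline_matrix(
    fit: HazardModelFit, sex: str, treatment: str, ages: np.ndarray
) -> np.ndarray:
    """Stacked prediction matrix for all isolines: shape (m * n_ages, p)."""
    rows = [
        fit.design.prediction_matrix(ages, sex, treatment, isoline=iso)
        for iso in fit.design.isolines
    ]
    return np.vstack(rows)


def observable_grid(
    fit: HazardModelFit,
    *strata: tuple[str, str],
) -> np.ndarray:
    """Life-table bin midpoints observable in every requested stratum."""
    d = fit.design
    lo = max(d.stratum_age_range[s][0] for s in strata)
    hi = min(d.stratum_age_range[s][1] for s in strata)
    if hi < lo:
        raise ValueError(f"strata {strata} have non-overlapping age ranges")
    mids = np.unique(d.x)
    return mids[(mids >= lo - 1e-9) & (mids <= hi + 1e-9)]


@dataclass
class BootstrapFits:
    """Coefficient vectors from design-preserving bootstrap refits."""

    base_fit: HazardModelFit
    coefs: np.ndarray  # (n_successful, p)
    n_requested: int
    n_failed: int
    seed: int | None
    unit: str

    def __len__(self) -> int:
        return self.coefs.shape[0]


def bootstrap_refits(
    records,
    fit: HazardModelFit,
    n_boot: int = 1000,
    seed: int | None = None,
    unit: str = "individual",
    reselect_lambda: bool = False,
) -> BootstrapFits:
    """Bootstrap the fitted model by resampling records and refitting.

    ``unit="individual"`` resamples flies with replacement within each
    isoline x sex x treatment cell (design-preserving); ``unit="isoline"`` is
    the cluster alternative, resampling whole isolines with replacement.
    Smoothing parameters stay frozen at the original fit's values unless
    ``reselect_lambda`` is set (slow).  Replicates whose refit does not
    converge are skipped and counted; more than 10% failures aborts.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200 for percentile bands")
    if unit not in ("individual", "isoline"):
        raise ValueError(f"unknown resampling unit {unit!r}")
    df = records_frame(records)
    d = fit.design
    w = d.bin_width

    # map each fly to its life-table design rows: exposure and death
    # contributions become two sparse fly -> row matrices, so a bootstrap
    # replicate is a single sparse matvec with the resample counts
    row_key: dict[tuple, int] = {}
    iso_arr = np.array([list(d.isolines)[c] for c in d.iso_code])
    for r in range(len(d.x)):
        b = int(round((d.x[r] - w / 2.0) / w))
        row_key[(iso_arr[r], d.sex[r], d.trt[r], b)] = r

    ages = df["observed_age"].to_numpy(dtype=float)
    is_death = (df["event"] == EVENT_DEATH).to_numpy()
    k = np.ceil(ages / w - 1e-9).astype(int)
    residual = ages - (k - 1) * w
    n_flies = len(df)
    e_rows, e_cols, e_vals = [], [], []
    d_rows, d_cols = [], []
    for f in range(n_flies):
        key0 = (df["isoline"].iat[f], df["sex"].iat[f], df["treatment"].iat[f])
        for b in range(k[f]):
            r = row_key.get((*key0, b))
            if r is None:  # bin absent from the original table (zero exposure)
                continue
            e_rows.append(f)
            e_cols.append(r)
            e_vals.append(w if b < k[f] - 1 else residual[f])
        if is_death[f]:
            r = row_key.get((*key0, k[f] - 1))
            if r is not None:
                d_rows.append(f)
                d_cols.append(r)
    n_rows = len(d.x)
    M_E = sp.csr_matrix((e_vals, (e_rows, e_cols)), shape=(n_flies, n_rows))
    M_D = sp.csr_matrix(
        (np.ones(len(d_rows)), (d_rows, d_cols)), shape=(n_flies, n_rows)
    )

    cell_codes, cells = _cell_codes(df)
    cell_members = [np.flatnonzero(cell_codes == c) for c in range(len(cells))]
    iso_of_fly = df["isoline"].to_numpy()

    rng = np.random.default_rng(seed)
    coefs = []
    n_failed = 0
    for _ in range(n_boot):
        counts = np.zeros(n_flies)
        if unit == "individual":
            for members in cell_members:
                picks = rng.integers(0, len(members), size=len(members))
                counts[members] += np.bincount(picks, minlength=len(members))
        else:
            drawn = rng.choice(d.isolines, size=len(d.isolines), replace=True)
            mult = {iso: 0 for iso in d.isolines}
            for iso in drawn:
                mult[iso] += 1
            counts = np.array([mult[i] for i in iso_of_fly], dtype=float)
        D_rep = M_D.T @ counts
        E_rep = M_E.T @ counts
        if reselect_lambda:
            from .hazgam import fit_hazard_model
            from .lifetable import LifeTable
            import pandas as pd

            mask = E_rep > 0
            t = pd.DataFrame(
                {
                    "isoline": iso_arr[mask],
                    "sex": d.sex[mask],
                    "treatment": d.trt[mask],
                    "age_bin_start": d.x[mask] - w / 2.0,
                    "D": D_rep[mask].astype(int),
                    "E": E_rep[mask],
                }
            )
            try:
                refit = fit_hazard_model(
                    LifeTable(t.sort_values(
                        ["isoline", "sex", "treatment", "age_bin_start"]
                    ).reset_index(drop=True), w),
                    fit.spec, basis=fit.basis,
                )
                coefs.append(refit.coef)
            except Exception:
                n_failed += 1
            continue
        beta, ok = fit.refit_response(D_rep, E_rep)
        if ok:
            coefs.append(beta)
        else:
            n_failed += 1
    if n_failed > 0.1 * n_boot:
        raise RuntimeError(
            f"bootstrap aborted: {n_failed}/{n_boot} replicates failed to converge"
        )
    return BootstrapFits(fit, np.array(coefs), n_boot, n_failed, seed, unit)


def _cell_codes(df):
    import pandas as pd

    key = df["isoline"].astype(str) + "\x1f" + df["sex"] + "\x1f" + df["treatment"]
    codes, cells = pd.factorize(key)
    return codes, cells


def difference_band(
    fit: HazardModelFit,
    boot: BootstrapFits,
    stratum_a: tuple[str, str],
    stratum_b: tuple[str, str],
    flavor: str = "marginal",
    ages: np.ndarray | None = None,
    alpha: float = 0.05,
) -> DifferenceBand:
    """Pointwise bootstrap percentile band for log mu_A(x) - log mu_B(x).

    The point estimate comes from the original fit; at each grid age the
    bounds are the empirical alpha/2 and 1-alpha/2 quantiles of the bootstrap
    differences.  The grid is restricted to ages observable in both strata.
    """
    if flavor not in ("marginal", "conditional"):
        raise ValueError("flavor must be 'marginal' or 'conditional'")
    if len(boot) < 200:
        raise RuntimeError(
            f"only {len(boot)} successful bootstrap refits; need at least 200"
        )
    if ages is None:
        ages = observable_grid(fit, stratum_a, stratum_b)
    ages = np.asarray(ages, dtype=float)

    def delta_for(coef: np.ndarray, pa, pb) -> np.ndarray:
        if flavor == "conditional":
            return pa @ coef - pb @ coef
        return (
            _marginal_log_mu(fit, coef, *stratum_a, ages, pred_rows=pa)
            - _marginal_log_mu(fit, coef, *stratum_b, ages, pred_rows=pb)
        )

    if flavor == "conditional":
        pa = fit.design.prediction_matrix(ages, *stratum_a)
        pb = fit.design.prediction_matrix(ages, *stratum_b)
    elif fit.spec.isoline_effects == "none":
        pa = pb = None
    else:
        pa = _per_isoline_matrix(fit, *stratum_a, ages)
        pb = _per_isoline_matrix(fit, *stratum_b, ages)

    delta = delta_for(fit.coef, pa, pb)
    sims = np.empty((len(boot), len(ages)))
    for i, coef in enumerate(boot.coefs):
        sims[i] = delta_for(coef, pa, pb)
    lower = np.quantile(sims, alpha / 2.0, axis=0)
    upper = np.quantile(sims, 1.0 - alpha / 2.0, axis=0)
    # percentile bands from finite resamples need not cover the point
    # estimate; clamp so the band always contains it (degenerate-width safe)
    lower = np.minimum(lower, delta)
    upper = np.maximum(upper, delta)
    wins = significant_windows(ages, delta, lower, upper)
    return DifferenceBand(
        ages, delta, lower, upper, alpha, flavor,
        ":".join(stratum_a), ":".join(stratum_b), len(boot), wins,
    )
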