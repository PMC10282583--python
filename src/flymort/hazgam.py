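"""Penalized-spline Poisson models of log mortality.

The response is the binned death count D with offset log E (exposure in
fly-days), so the linear predictor is the log mortality rate.  The predictor
combines parametric sex/treatment terms, cubic P-spline smooths of age (one
per group, per the chosen smooth structure) and, optionally, per-isoline
random smooth deviations ("factor smooths"): every isoline gets its own
B-spline deviation curve, all sharing one smoothing parameter and constrained
to sum to zero across isolines at each basis coefficient, so the fixed part
remains the average line and the deviations behave as random effects (the
factor-smooth penalty includes the basis null space, hence deviations shrink
to exactly zero as their lambda grows).

Fitting is penalized IRLS; smoothing parameters minimize the conditional
AIC = -2 loglik + 2 EDF over a log-spaced grid with coordinate-descent
refinement, where EDF is the trace of the influence matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, null_space
from scipy.special import gammaln

from .curves import HazardCurve
from .lifetable import LifeTable
from .synth import SEXES, TREATMENTS

SMOOTH_STRUCTURES = ("shared", "sex", "treatment", "sex:treatment")
ISOLINE_EFFECTS = ("none", "intercept", "factor_smooth")
FIXED_TERMS = ("sex", "treatment", "sex:treatment")


@dataclass(frozen=True)
class SmoothBasis:
    """Cubic B-spline basis with a difference penalty (P-spline)."""

    knots: np.ndarray
    k: int
    degree: int = 3
    penalty_order: int = 2

    @classmethod
    def from_range(
        cls, lo: float, hi: float, k: int = 10, degree: int = 3, penalty_order: int = 2
    ) -> "SmoothBasis":
        if k <= degree + 1:
            raise ValueError("basis dimension k must exceed degree + 1")
        if hi <= lo:
            raise ValueError("empty age range")
        # uniform knots extended beyond the domain (Eilers-Marx construction):
        # Greville abscissae stay equally spaced, so the difference-penalty
        # null space is exactly {constant, linear in age} over [lo, hi]
        h = (hi - lo) / (k - degree)
        knots = lo + h * (np.arange(k + degree + 1) - degree)
        return cls(knots=knots, k=k, degree=degree, penalty_order=penalty_order)

    @property
    def lo(self) -> float:
        return float(self.knots[self.degree])

    @property
    def hi(self) -> float:
        return float(self.knots[-self.degree - 1])

    def design(self, x: np.ndarray) -> np.ndarray:
        """Basis matrix B(x); rows sum to one (partition of unity)."""
        x = np.asarray(x, dtype=float)
        if x.size and (x.min() < self.lo - 1e-9 or x.max() > self.hi + 1e-9):
            raise ValueError(
                f"ages outside the fitted range [{self.lo:.3g}, {self.hi:.3g}]; "
                "no extrapolation policy"
            )
        xc = np.clip(x, self.lo, self.hi)
        return BSpline.design_matrix(xc, self.knots, self.degree).toarray()

    def penalty(self) -> np.ndarray:
        """P = D'D for the difference operator of the configured order."""
        d = np.diff(np.eye(self.k), n=self.penalty_order, axis=0)
        return d.T @ d

    def penalty_nullspace(self) -> np.ndarray:
        """Orthonormal basis of null(P): polynomial coefficient directions."""
        return null_space(self.penalty())


@dataclass(frozen=True)
class HazardModelSpec:
    """Which fixed terms, smooth structure and isoline effects to include."""

    name: str
    fixed_terms: tuple[str, ...] = FIXED_TERMS
    smooth_by: str = "sex:treatment"
    isoline_effects: str = "factor_smooth"

    def __post_init__(self) -> None:
        bad = [t for t in self.fixed_terms if t not in FIXED_TERMS]
        if bad:
            raise ValueError(f"unknown fixed terms {bad}")
        if self.smooth_by not in SMOOTH_STRUCTURES:
            raise ValueError(f"smooth_by must be one of {SMOOTH_STRUCTURES}")
        if self.isoline_effects not in ISOLINE_EFFECTS:
            raise ValueError(f"isoline_effects must be one of {ISOLINE_EFFECTS}")


#: the candidate set used for model selection; "full" carries all four
#: parametric/structural terms (sex, treatment, interaction, group smooths)
#: plus isoline factor smooths
CANDIDATE_SPECS: dict[str, HazardModelSpec] = {
    "full": HazardModelSpec("full"),
    "shared_smooth": HazardModelSpec("shared_smooth", smooth_by="shared"),
    "sex_smooth": HazardModelSpec("sex_smooth", smooth_by="sex"),
    "treatment_smooth": HazardModelSpec("treatment_smooth", smooth_by="treatment"),
    "no_sex": HazardModelSpec("no_sex", fixed_terms=("treatment",), smooth_by="treatment"),
    "no_treatment": HazardModelSpec("no_treatment", fixed_terms=("sex",), smooth_by="sex"),
    "no_isoline": HazardModelSpec("no_isoline", isoline_effects="none"),
    "isoline_intercept": HazardModelSpec("isoline_intercept", isoline_effects="intercept"),
}


class ModelDesign:
    """Design matrix, penalty blocks and prediction machinery for one spec."""

    def __init__(self, lifetable: LifeTable, spec: HazardModelSpec, basis: SmoothBasis):
        t = lifetable.table
        if t["D"].sum() <= 0:
            raise ValueError("life table contains no deaths; nothing to fit")
        self.spec = spec
        self.basis = basis
        self.bin_width = lifetable.bin_width
        self.x = t["age_bin_start"].to_numpy(dtype=float) + lifetable.bin_width / 2.0
        self.D = t["D"].to_numpy(dtype=float)
        self.E = t["E"].to_numpy(dtype=float)
        self.sex = t["sex"].to_numpy()
        self.trt = t["treatment"].to_numpy()
        self.isolines = tuple(sorted(t["isoline"].unique()))
        iso_index = {iso: i for i, iso in enumerate(self.isolines)}
        self.iso_code = np.array([iso_index[i] for i in t["isoline"]])

        # observable age range per sex:treatment stratum (for contrast grids)
        self.stratum_age_range: dict[tuple[str, str], tuple[float, float]] = {}
        for s in SEXES:
            for tr in TREATMENTS:
                m = (self.sex == s) & (self.trt == tr)
                if m.any():
                    self.stratum_age_range[(s, tr)] = (
                        float(self.x[m].min()),
                        float(self.x[m].max()),
                    )

        n = len(self.x)
        B = basis.design(self.x)
        P = basis.penalty()

        cols: list[np.ndarray] = [np.ones((n, 1))]
        self.fixed_names = ["intercept"]
        male = (self.sex == "male").astype(float)
        rapa = (self.trt == TREATMENTS[1]).astype(float)
        if "sex" in spec.fixed_terms:
            cols.append(male[:, None])
            self.fixed_names.append("sex[male]")
        if "treatment" in spec.fixed_terms:
            cols.append(rapa[:, None])
            self.fixed_names.append(f"treatment[{TREATMENTS[1]}]")
        if "sex:treatment" in spec.fixed_terms:
            if not {"sex", "treatment"} <= set(spec.fixed_terms):
                raise ValueError("interaction requires both main effects")
            cols.append((male * rapa)[:, None])
            self.fixed_names.append("sex:treatment")
        p0 = sum(c.shape[1] for c in cols)

        # centered group smooths: B Z per level, with 1'BZ = 0 over the
        # level's rows so the parametric terms stay identifiable
        self.blocks: list[tuple[str, slice, np.ndarray]] = []  # (name, slice, penalty)
        self.smooth_Z: dict[str, np.ndarray] = {}
        offset = p0
        for level in self._smooth_levels():
            mask = self._level_mask(level)
            if not mask.any():
                raise ValueError(f"no life-table rows for smooth group {level!r}")
            Bm = B * mask[:, None]
            s = Bm.sum(axis=0)[None, :]
            Z = null_space(s)
            self.smooth_Z[level] = Z
            cols.append(Bm @ Z)
            sl = slice(offset, offset + Z.shape[1])
            self.blocks.append((f"s({level})", sl, Z.T @ P @ Z))
            offset += Z.shape[1]

        m = len(self.isolines)
        self.iso_contrast = None
        if spec.isoline_effects != "none" and m < 2:
            raise ValueError("isoline effects need at least two isolines")
        if spec.isoline_effects == "intercept":
            C = _sum_to_zero_contrast(m)
            self.iso_contrast = C
            cols.append(C[self.iso_code, :])
            sl = slice(offset, offset + m - 1)
            self.blocks.append(("isoline", sl, C.T @ C))
            offset += m - 1
        elif spec.isoline_effects == "factor_smooth":
            C = _sum_to_zero_contrast(m)
            self.iso_contrast = C
            # row = kron(C[iso], B(x)); penalty = (C'C) x (P + null-space ridge)
            Xi = (C[self.iso_code][:, :, None] * B[:, None, :]).reshape(n, (m - 1) * basis.k)
            cols.append(Xi)
            U0 = basis.penalty_nullspace()
            P_fs = P + U0 @ U0.T
            sl = slice(offset, offset + (m - 1) * basis.k)
            self.blocks.append(("isoline_fs", sl, np.kron(C.T @ C, P_fs)))
            offset += (m - 1) * basis.k

        self.X = np.hstack(cols)
        self.p = self.X.shape[1]

    def _smooth_levels(self) -> list[str]:
        by = self.spec.smooth_by
        if by == "shared":
            return ["all"]
        if by == "sex":
            return [s for s in SEXES if (self.sex == s).any()]
        if by == "treatment":
            return [t for t in TREATMENTS if (self.trt == t).any()]
        return [
            f"{s}:{t}"
            for s in SEXES
            for t in TREATMENTS
            if ((self.sex == s) & (self.trt == t)).any()
        ]

    def _level_mask(self, level: str) -> np.ndarray:
        by = self.spec.smooth_by
        if by == "shared":
            return np.ones(len(self.x), dtype=bool)
        if by == "sex":
            return self.sex == level
        if by == "treatment":
            return self.trt == level
        s, t = level.split(":")
        return (self.sex == s) & (self.trt == t)

    def smooth_level_for(self, sex: str, treatment: str) -> str:
        by = self.spec.smooth_by
        if by == "shared":
            return "all"
        if by == "sex":
            return sex
        if by == "treatment":
            return treatment
        return f"{sex}:{treatment}"

    def penalty_total(self, lambdas: dict[str, float]) -> np.ndarray:
        S = np.zeros((self.p, self.p))
        for name, sl, Sb in self.blocks:
            S[sl, sl] += lambdas[name] * Sb
        return S

    def prediction_matrix(
        self, ages: np.ndarray, sex: str, treatment: str, isoline: str | None = None
    ) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        if sex not in SEXES or treatment not in TREATMENTS:
            raise ValueError(f"unknown stratum {sex!r}/{treatment!r}")
        n = len(ages)
        Xp = np.zeros((n, self.p))
        j = 0
        Xp[:, j] = 1.0
        j += 1
        if "sex" in self.spec.fixed_terms:
            Xp[:, j] = 1.0 if sex == "male" else 0.0
            j += 1
        if "treatment" in self.spec.fixed_terms:
            Xp[:, j] = 1.0 if treatment == TREATMENTS[1] else 0.0
            j += 1
        if "sex:treatment" in self.spec.fixed_terms:
            Xp[:, j] = 1.0 if (sex == "male" and treatment == TREATMENTS[1]) else 0.0
            j += 1
        Bp = self.basis.design(ages)
        level = self.smooth_level_for(sex, treatment)
        for name, sl, _ in self.blocks:
            if name == f"s({level})":
                Xp[:, sl] = Bp @ self.smooth_Z[level]
            elif name == "isoline" and isoline is not None:
                Xp[:, sl] = self.iso_contrast[self.isolines.index(isoline)]
            elif name == "isoline_fs" and isoline is not None:
                c = self.iso_contrast[self.isolines.index(isoline)]
                Xp[:, sl] = (c[:, None] * Bp[:, None, :]).reshape(n, -1)
        return Xp


def _sum_to_zero_contrast(m: int) -> np.ndarray:
    """(m, m-1) contrast whose full coefficient rows sum to zero."""
    C = np.vstack([np.eye(m - 1), -np.ones((1, m - 1))])
    return C


@dataclass
class HazardModelFit:
    """One fitted penalized Poisson hazard model."""

    spec: HazardModelSpec
    basis: SmoothBasis
    design: ModelDesign
    coef: np.ndarray
    lambdas: dict[str, float]
    edf: float
    loglik: float
    aic: float
    n_iter: int
    grad_norm: float
    converged: bool
    delta_aic: float = field(default=float("nan"))

    def fitted_rate(self) -> np.ndarray:
        """Fitted mortality rate per life-table row."""
        return np.exp(self.design.X @ self.coef)

    def refit_response(
        self, D: np.ndarray, E: np.ndarray, max_iter: int = 150
    ) -> tuple[np.ndarray, bool]:
        """Refit coefficients for new (D, E) on the same design with the same
        lambdas (the bootstrap fast path).  Rows with E = 0 are masked out."""
        d = self.design
        S = d.penalty_total(self.lambdas)
        mask = E > 0
        off = np.where(mask, np.log(np.where(mask, E, 1.0)), 0.0)
        res = _pirls(d.X[mask], D[mask], off[mask], S, self.coef.copy(), max_iter=max_iter)
        if not res.converged:  # retry once from a flat start
            beta0 = np.zeros(d.p)
            beta0[0] = math.log(max(D[mask].sum(), 0.5) / E[mask].sum())
            res = _pirls(d.X[mask], D[mask], off[mask], S, beta0, max_iter=2 * max_iter)
        return res.beta, res.converged


@dataclass
class _PirlsResult:
    beta: np.ndarray
    converged: bool
    n_iter: int
    grad_norm: float
    edf: float
    loglik: float


def _pirls(
    X: np.ndarray,
    y: np.ndarray,
    off: np.ndarray,
    S: np.ndarray,
    beta: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> _PirlsResult:
    """Penalized IRLS for Poisson log-link with offset, with step halving."""
    scale = max(1.0, float(y.sum()))

    def penalized_ll(b: np.ndarray) -> float:
        eta = X @ b + off
        return float(y @ eta - np.exp(np.clip(eta, -700, 60)).sum() - 0.5 * b @ S @ b)

    ll_old = penalized_ll(beta)
    converged = False
    gn = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta + off
        mu = np.exp(np.clip(eta, -700, 60))
        g = X.T @ (y - mu) - S @ beta
        gn = float(np.max(np.abs(g)))
        if gn < tol * scale:
            converged = True
            break
        W = np.maximum(mu, 1e-12)
        z = (eta - off) + (y - mu) / W
        XtW = X.T * W
        A = XtW @ X + S
        try:
            c = cho_factor(A, lower=True)
        except np.linalg.LinAlgError:
            A = A + 1e-8 * np.eye(A.shape[0]) * max(1.0, np.trace(A) / A.shape[0])
            c = cho_factor(A, lower=True)
        beta_new = cho_solve(c, XtW @ z)
        ll_new = penalized_ll(beta_new)
        halvings = 0
        while ll_new < ll_old - 1e-10 and halvings < 30:
            beta_new = 0.5 * (beta + beta_new)
            ll_new = penalized_ll(beta_new)
            halvings += 1
        step = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        ll_old = ll_new
        if step < 1e-11 * (1.0 + float(np.max(np.abs(beta)))):
            # stationary to machine precision (huge-lambda regime, where the
            # penalized gradient cannot be driven further down in floats)
            converged = True
            break

    # influence-matrix trace and unpenalized log-likelihood at the optimum
    eta = X @ beta + off
    mu = np.exp(np.clip(eta, -700, 60))
    W = np.maximum(mu, 1e-12)
    XtW = X.T * W
    A = XtW @ X + S
    try:
        c = cho_factor(A, lower=True)
    except np.linalg.LinAlgError:
        A = A + 1e-8 * np.eye(A.shape[0]) * max(1.0, np.trace(A) / A.shape[0])
        c = cho_factor(A, lower=True)
    edf = float(np.trace(cho_solve(c, XtW @ X)))
    loglik = float(y @ eta - mu.sum() - gammaln(y + 1.0).sum())
    return _PirlsResult(beta, converged, it, gn, edf, loglik)


class FitError(RuntimeError):
    """Non-convergence, reported with the lambda path walked so far."""


def fit_hazard_model(
    lifetable: LifeTable,
    spec: HazardModelSpec | str,
    basis: SmoothBasis | None = None,
    lambdas: dict[str, float] | float | None = None,
    share_smooth_lambda: bool = True,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> HazardModelFit:
    """Fit one penalized Poisson hazard model.

    If ``lambdas`` is given (a mapping block-name -> lambda, or one scalar for
    all blocks) a single penalized fit is performed; otherwise smoothing
    parameters are selected by minimizing AIC via coordinate descent over a
    log-spaced grid with one local refinement sweep.  With
    ``share_smooth_lambda`` (default) the group age-smooths share a single
    smoothing parameter; the isoline block always has its own.
    """
    if isinstance(spec, str):
        spec = CANDIDATE_SPECS[spec]
    if basis is None:
        t = lifetable.table
        mids = t["age_bin_start"].to_numpy(dtype=float) + lifetable.bin_width / 2.0
        basis = SmoothBasis.from_range(float(mids.min()), float(mids.max()))
    design = ModelDesign(lifetable, spec, basis)
    y, E = design.D, design.E
    off = np.log(E)
    beta0 = np.zeros(design.p)
    beta0[0] = math.log(max(y.sum(), 0.5) / E.sum())
    block_names = [b[0] for b in design.blocks]

    def run(lam: dict[str, float], beta_start: np.ndarray) -> tuple[_PirlsResult, float]:
        res = _pirls(design.X, y, off, design.penalty_total(lam), beta_start.copy(),
                     tol=tol, max_iter=max_iter)
        return res, -2.0 * res.loglik + 2.0 * res.edf

    if lambdas is not None:
        if not isinstance(lambdas, dict):
            lambdas = {name: float(lambdas) for name in block_names}
        missing = [n for n in block_names if n not in lambdas]
        if missing:
            raise ValueError(f"lambdas missing for blocks {missing}")
        res, aic = run(lambdas, beta0)
        if not res.converged:
            raise FitError(
                f"PIRLS did not converge for spec {spec.name!r} at fixed lambdas "
                f"{lambdas} (grad norm {res.grad_norm:.3g})"
            )
        return HazardModelFit(spec, basis, design, res.beta, dict(lambdas),
                              res.edf, res.loglik, aic, res.n_iter, res.grad_norm, True)

    if not block_names:  # pure GLM, nothing to select
        res, aic = run({}, beta0)
        return HazardModelFit(spec, basis, design, res.beta, {}, res.edf,
                              res.loglik, aic, res.n_iter, res.grad_norm, res.converged)

    # coordinate groups: smooth blocks optionally tied, isoline block separate
    groups: list[list[str]] = []
    smooth_names = [n for n in block_names if n.startswith("s(")]
    iso_names = [n for n in block_names if not n.startswith("s(")]
    if smooth_names:
        groups.extend([smooth_names] if share_smooth_lambda else [[n] for n in smooth_names])
    groups.extend([[n] for n in iso_names])

    lam = {name: 1.0 for name in block_names}
    beta = beta0
    path: list[tuple[dict[str, float], float]] = []
    grid = 10.0 ** np.linspace(-3.0, 7.0, 11)
    best_res, best_aic = run(lam, beta)
    path.append((dict(lam), best_aic))
    beta = best_res.beta
    for sweep_grid in (grid, None):  # coarse sweep, then local refinement
        for grp in groups:
            values = (
                sweep_grid
                if sweep_grid is not None
                else lam[grp[0]] * 10.0 ** np.array([-0.5, -0.25, 0.25, 0.5])
            )
            for v in values:
                trial = dict(lam)
                for name in grp:
                    trial[name] = float(v)
                res, aic = run(trial, beta)
                path.append((trial, aic))
                if res.converged and aic < best_aic - 1e-10:
                    best_aic, best_res, lam = aic, res, trial
                    beta = res.beta
    if not best_res.converged:
        raise FitError(
            f"no converged fit for spec {spec.name!r}; lambda path: "
            + "; ".join(f"{l} -> AIC {a:.2f}" for l, a in path[-5:])
        )
    return HazardModelFit(spec, basis, design, best_res.beta, dict(lam), best_res.edf,
                          best_res.loglik, best_aic, best_res.n_iter,
                          best_res.grad_norm, True)


def select_model(
    lifetable: LifeTable,
    candidate_specs: list[HazardModelSpec | str] | None = None,
    basis: SmoothBasis | None = None,
    **fit_kwargs,
) -> list[HazardModelFit]:
    """Fit candidates and rank by AIC (ascending); ties go to fewer EDF.

    Non-converged candidates are excluded with a warning.  The returned fits
    carry ``delta_aic`` relative to the winner.
    """
    if candidate_specs is None:
        candidate_specs = list(CANDIDATE_SPECS.values())
    if len(candidate_specs) < 2:
        raise ValueError("need at least two candidate specs")
    fits: list[HazardModelFit] = []
    for sp in candidate_specs:
        name = sp if isinstance(sp, str) else sp.name
        try:
            fits.append(fit_hazard_model(lifetable, sp, basis=basis, **fit_kwargs))
        except FitError as e:
            warnings.warn(f"candidate {name!r} excluded: {e}", stacklevel=2)
    if not fits:
        raise FitError("no candidate converged")
    fits.sort(key=lambda f: (round(f.aic / 1e-6) * 1e-6, f.edf))
    best = fits[0].aic
    return [replace(f, delta_aic=f.aic - best) for f in fits]


def predict_log_hazard(
    fit: HazardModelFit,
    ages: np.ndarray,
    sex: str,
    treatment: str,
    isoline_mode: str = "conditional_zero",
):
    """Predicted log mortality on an age grid within the fitted range.

    ``conditional_zero`` zeroes the isoline terms (the model keeps them; the
    prediction does not) and returns one conditional curve; ``per_isoline``
    returns a dict of curves, one per isoline, including its deviation smooth.
    """
    ages = np.asarray(ages, dtype=float)
    stratum = f"{sex}:{treatment}"
    if isoline_mode == "conditional_zero":
        Xp = fit.design.prediction_matrix(ages, sex, treatment, isoline=None)
        return HazardCurve(ages, Xp @ fit.coef, "conditional", stratum)
    if isoline_mode == "per_isoline":
        out = {}
        for iso in fit.design.isolines:
            Xp = fit.design.prediction_matrix(ages, sex, treatment, isoline=iso)
            out[iso] = HazardCurve(ages, Xp @ fit.coef, "per_isoline", stratum, isoline=iso)
        return out
    raise ValueError(f"unknown isoline_mode {isoline_mode!r}")
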