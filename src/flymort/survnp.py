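"""Nonparametric survival description and testing.

Kaplan-Meier product-limit survivorship per group, and a stratified
Gehan-Breslow (generalized Wilcoxon) two-sample test whose null distribution
comes from permuting group labels within strata: exact enumeration when the
total number of label arrangements is small, seeded Monte-Carlo otherwise,
with an asymptotic normal approximation (tie-corrected permutation variance)
as the fast alternative.  The Gehan statistic weights early deaths by the
number at risk, which makes the test sensitive to early survivorship
differences and robust to non-proportional hazards and crossing curves.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lifetable import records_frame
from .synth import EVENT_DEATH

EXACT_ENUMERATION_LIMIT = 1_000_000


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survivorship for one group.

    ``times`` are the distinct death ages; ``n_risk`` and ``deaths`` the
    at-risk and death counts there; ``survival`` the right-continuous step
    estimate S(t).  Censored flies tied with deaths at t are still at risk at
    t (deaths are processed first).
    """

    group: str
    times: np.ndarray
    n_risk: np.ndarray
    deaths: np.ndarray
    survival: np.ndarray
    n_total: int

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """S(t) as a right-continuous step function, S(t) = 1 before the first death."""
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:
            return np.ones_like(t)
        idx = np.searchsorted(self.times, t, side="right") - 1
        return np.where(idx >= 0, self.survival[np.maximum(idx, 0)], 1.0)


def _km_single(ages: np.ndarray, deaths: np.ndarray, group: str) -> KMCurve:
    order = np.argsort(ages, kind="mergesort")
    ages, deaths = ages[order], deaths[order]
    n = len(ages)
    event_times = np.unique(ages[deaths])
    n_risk = np.empty(len(event_times), dtype=int)
    d = np.empty(len(event_times), dtype=int)
    for j, t in enumerate(event_times):
        n_risk[j] = int(np.sum(ages >= t))
        d[j] = int(np.sum(deaths & (ages == t)))
    surv = np.cumprod(1.0 - d / n_risk)
    return KMCurve(group, event_times.astype(float), n_risk, d, surv, n)


def km_fit(records, group_by: list[str] | str | None = None) -> dict[str, KMCurve]:
    """Kaplan-Meier estimate per group (group label = joined factor levels)."""
    df = records_frame(records)
    if group_by is None:
        group_by = []
    elif isinstance(group_by, str):
        group_by = [group_by]
    ages = df["observed_age"].to_numpy(dtype=float)
    is_death = (df["event"] == EVENT_DEATH).to_numpy()
    if len(df) == 0:
        raise ValueError("no records to fit")
    if not group_by:
        return {"all": _km_single(ages, is_death, "all")}
    out: dict[str, KMCurve] = {}
    for key, sub in df.groupby(group_by, observed=True, sort=True):
        label = key if isinstance(key, str) else ":".join(map(str, key))
        if len(sub) == 0:
            raise ValueError(f"empty group {label!r}")
        ii = sub.index.to_numpy()
        out[label] = _km_single(ages[ii], is_death[ii], label)
    if not out:
        raise ValueError("no groups found")
    return out


def km_frame(curves: dict[str, KMCurve]) -> pd.DataFrame:
    rows = []
    for label, c in curves.items():
        for t, s, nr, d in zip(c.times, c.survival, c.n_risk, c.deaths):
            rows.append({"group": label, "time": t, "S": s, "n_risk": nr, "d": d})
    return pd.DataFrame(rows, columns=["group", "time", "S", "n_risk", "d"])


def gehan_scores(ages: np.ndarray, is_death: np.ndarray) -> np.ndarray:
    """Gehan scores u_i = #{j : i outlives j} - #{j : j outlives i}.

    A death at t outlives the deaths strictly before t and is outlived by the
    deaths strictly after t and by every observation censored at or after t
    (censored-at-t was still alive when the death occurred).  A censoring at c
    outlives the deaths at or before c; nothing is known to outlive it.  Ties
    among deaths score zero against each other (mid-rank convention).
    """
    ages = np.asarray(ages, dtype=float)
    is_death = np.asarray(is_death, dtype=bool)
    death_t = np.sort(ages[is_death])
    cens_t = np.sort(ages[~is_death])
    n_death_lt = np.searchsorted(death_t, ages, side="left")
    n_death_le = np.searchsorted(death_t, ages, side="right")
    n_death_gt = len(death_t) - n_death_le
    n_cens_ge = len(cens_t) - np.searchsorted(cens_t, ages, side="left")
    return np.where(
        is_death, n_death_lt - n_death_gt - n_cens_ge, n_death_le
    ).astype(float)


@dataclass(frozen=True)
class RankTestResult:
    statistic: float  # standardized (permutation-variance) statistic
    p_value: float
    method: str  # asymptotic | monte_carlo | exact
    n_permutations: int | None
    strata: tuple[str, ...]
    raw_statistic: float


def gehan_breslow_stratified(
    records,
    compare: str,
    strata: str | list[str] | None = None,
    method: str = "asymptotic",
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> RankTestResult:
    """Stratified two-sample Gehan-Breslow test with a permutation null.

    Gehan scores are computed within each stratum; the statistic is the sum of
    the first group's scores across strata (stratum score sums are zero by
    antisymmetry, so no centring is needed).  ``method``:

    - ``"exact"``: full enumeration of within-stratum label arrangements when
      their total count is at most 10^6 (falls back to Monte-Carlo above).
    - ``"mc"``: seeded within-stratum label permutation; p = (1+k)/(1+m).
    - ``"asymptotic"``: normal approximation with the exact permutation
      variance (tie-corrected via the realized scores).

    Two-sided p throughout.
    """
    df = records_frame(records)
    if compare not in df.columns:
        raise ValueError(f"unknown compare factor {compare!r}")
    levels = sorted(df[compare].unique())
    if len(levels) != 2:
        raise ValueError(f"compare factor {compare!r} must have exactly 2 levels, got {levels}")
    if strata is None:
        strata = []
    elif isinstance(strata, str):
        strata = [strata]
    if strata:
        stratum_key = df[strata[0]].astype(str)
        for s in strata[1:]:
            stratum_key = stratum_key + ":" + df[s].astype(str)
    else:
        stratum_key = pd.Series(["all"] * len(df))

    ages = df["observed_age"].to_numpy(dtype=float)
    is_death = (df["event"] == EVENT_DEATH).to_numpy()
    in_a = (df[compare] == levels[0]).to_numpy()

    per_stratum: list[tuple[np.ndarray, int]] = []  # (scores, n_in_group_a)
    stat = 0.0
    var = 0.0
    names: list[str] = []
    for name, idx in stratum_key.groupby(stratum_key).groups.items():
        ii = np.asarray(idx)
        a_mask = in_a[ii]
        n_s, n_a = len(ii), int(a_mask.sum())
        if n_a == 0 or n_a == n_s:
            raise ValueError(f"stratum {name!r} lacks one of the compare levels")
        u = gehan_scores(ages[ii], is_death[ii])
        per_stratum.append((u, n_a))
        names.append(str(name))
        stat += float(u[a_mask].sum())
        n_b = n_s - n_a
        var += n_a * n_b / (n_s * (n_s - 1.0)) * float((u**2).sum())

    z = stat / math.sqrt(var) if var > 0 else 0.0

    if method == "asymptotic":
        from scipy.stats import norm

        p = min(1.0, 2.0 * float(norm.sf(abs(z)))) if var > 0 else 1.0
        return RankTestResult(z, p, "asymptotic", None, tuple(names), stat)

    if method == "exact":
        total = 1.0
        for u, n_a in per_stratum:
            total *= math.comb(len(u), n_a)
            if total > EXACT_ENUMERATION_LIMIT:
                break
        if total <= EXACT_ENUMERATION_LIMIT:
            dist = np.array([0.0])
            for u, n_a in per_stratum:
                sums = np.array(
                    [sum(c) for c in itertools.combinations(u, n_a)], dtype=float
                )
                dist = (dist[:, None] + sums[None, :]).ravel()
            k = int(np.sum(np.abs(dist) >= abs(stat) - 1e-9))
            return RankTestResult(
                z, k / len(dist), "exact", len(dist), tuple(names), stat
            )
        method = "mc"  # too many arrangements; fall through

    if method != "mc":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    m = n_permutations
    sims = np.zeros(m)
    for u, n_a in per_stratum:
        n_s = len(u)
        # rank the first n_a slots of random keys: a uniform random subset
        keys = rng.random((m, n_s))
        take = np.argpartition(keys, n_a - 1, axis=1)[:, :n_a]
        sims += np.take_along_axis(np.broadcast_to(u, (m, n_s)), take, axis=1).sum(axis=1)
    k = int(np.sum(np.abs(sims) >= abs(stat) - 1e-9))
    p = (1 + k) / (1 + m)
    return RankTestResult(z, p, "monte_carlo", m, tuple(names), stat)
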