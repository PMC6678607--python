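"""Systemic inflammation markers and the statistics linking them to local
tumor immunity.

Blood-count ratios (PLR = platelets/lymphocytes, NLR = neutrophils/
lymphocytes) are related to immuno-cluster membership and signature scores
through crude and age-adjusted odds ratios (2x2 tables and binomial /
multinomial logistic regression with Wald 95% CIs), Spearman correlation,
Kruskal-Wallis rank tests, exact k x 2 Fisher tests, Kaplan-Meier 5-year
disease-free survival with log-rank comparison, and the quadrant scatter
classification of score versus time-to-event.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort_io import CBCRecord, ValidationError, cbc_to_frame

__all__ = [
    "InflammationMarkers",
    "ContingencyTable2x2",
    "AssociationResult",
    "compute_ratios",
    "odds_ratio_2x2",
    "binomial_logistic",
    "multinomial_logistic",
    "spearman",
    "kruskal_wallis",
    "fisher_exact_kx2",
    "km_dfs",
    "quadrant_classify",
]

Z975 = stats.norm.ppf(0.975)


@dataclasses.dataclass
class InflammationMarkers:
    """Per-sample systemic ratios with the raw counts carried through."""

    table: pd.DataFrame  # columns: neutrophils, lymphocytes, platelets, plr, nlr

    @property
    def plr(self) -> pd.Series:
        return self.table["plr"]

    @property
    def nlr(self) -> pd.Series:
        return self.table["nlr"]


@dataclasses.dataclass
class ContingencyTable2x2:
    """Exposure rows x outcome columns: a,b = exposed outcome+/-,
    c,d = unexposed outcome+/-."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for f in ("a", "b", "c", "d"):
            v = getattr(self, f)
            if v < 0 or v != int(v):
                raise ValidationError(f"cell {f} must be a nonnegative integer")

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)


@dataclasses.dataclass
class AssociationResult:
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    scaling: str = "per-unit"
    adjustment: str = "crude"
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValidationError(
                f"CI ({self.ci_low}, {self.ci_high}) does not bracket "
                f"estimate {self.estimate}"
            )


def compute_ratios(cbc: list[CBCRecord] | pd.DataFrame) -> InflammationMarkers:
    """PLR and NLR from absolute blood counts (lymphocytes must be > 0)."""
    df = cbc_to_frame(cbc) if isinstance(cbc, list) else cbc.copy()
    if (df["lymphocytes"] <= 0).any():
        bad = df.index[df["lymphocytes"] <= 0].tolist()
        raise ValidationError(f"nonpositive lymphocyte count for {bad[:5]}")
    df["plr"] = df["platelets"] / df["lymphocytes"]
    df["nlr"] = df["neutrophils"] / df["lymphocytes"]
    return InflammationMarkers(table=df)


def odds_ratio_2x2(
    t: ContingencyTable2x2, haldane: bool = False, label: str = ""
) -> AssociationResult:
    """Crude odds ratio (a*d)/(b*c) with Wald 95% CI and two-sided Wald p.

    A zero cell makes the OR undefined; ``haldane=True`` applies the
    Haldane-Anscombe +0.5 correction instead of raising.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if t.has_zero_cell:
        if not haldane:
            raise ValidationError(
                "odds_ratio_2x2: zero cell, OR undefined (set haldane=True to "
                "apply the +0.5 correction)"
            )
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    p = 2 * stats.norm.sf(abs(log_or) / se)
    return AssociationResult(
        estimate=math.exp(log_or),
        ci_low=math.exp(log_or - Z975 * se),
        ci_high=math.exp(log_or + Z975 * se),
        p_value=float(p),
        label=label,
    )


def _check_separation(X: np.ndarray, y: np.ndarray, names: list[str]) -> None:
    for j, name in enumerate(names):
        x = X[:, j]
        if len(np.unique(y)) < 2:
            raise ValidationError("binomial_logistic: outcome is constant")
        if x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min():
            raise ValidationError(
                f"binomial_logistic: perfect separation on covariate {name!r}"
            )


def binomial_logistic(
    X: pd.DataFrame | np.ndarray,
    y,
    unit_scales: dict[str, float] | None = None,
    adjustment: str = "crude",
) -> list[AssociationResult]:
    """Binomial logistic regression (maximum likelihood via IRLS) returning
    one OR + Wald 95% CI per covariate.

    ``unit_scales`` maps a covariate name to the per-how-many-units scale of
    its reported OR (e.g. 10 for PLR); default 1 for every covariate.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValidationError("binomial_logistic: X and y lengths differ")
    if X.shape[0] <= X.shape[1]:
        raise ValidationError("binomial_logistic: need n > number of covariates")
    names = [str(c) for c in X.columns]
    _check_separation(X.to_numpy(dtype=float), y, names)
    model = sm.GLM(y, sm.add_constant(X.astype(float)), family=sm.families.Binomial())
    fit = model.fit(maxiter=100)
    if not fit.converged:
        raise ValidationError(
            f"binomial_logistic: IRLS did not converge in 100 iterations "
            f"(deviance {fit.deviance:.4g})"
        )
    scales = unit_scales or {}
    out = []
    for name in names:
        s = scales.get(name, 1.0)
        beta = fit.params[name] * s
        se = fit.bse[name] * s
        out.append(AssociationResult(
            estimate=math.exp(beta),
            ci_low=math.exp(beta - Z975 * se),
            ci_high=math.exp(beta + Z975 * se),
            p_value=float(fit.pvalues[name]),
            scaling=f"per-{s:g}-unit",
            adjustment=adjustment,
            label=name,
        ))
    return out


def multinomial_logistic(
    x,
    labels,
    ref: str = "ImA",
    unit_scale: float = 1.0,
    age=None,
    age_cut: float = 50.0,
) -> dict[str, AssociationResult]:
    """Baseline-category multinomial logistic fit of cluster membership on a
    continuous marker; ORs per ``unit_scale`` units for each non-reference
    cluster versus ``ref``, with Wald 95% CIs.

    ``age`` (years) adds a binary >= ``age_cut`` adjustment term.
    """
    x = pd.Series(x, dtype=float).reset_index(drop=True)
    labels = pd.Series(labels).astype(str).reset_index(drop=True)
    classes = sorted(labels.unique())
    if ref not in classes:
        raise ValidationError(f"multinomial_logistic: reference class {ref!r} empty")
    if len(classes) < 3:
        raise ValidationError("multinomial_logistic: need >= 3 classes present")
    ordered = [ref] + [c for c in classes if c != ref]
    codes = labels.map({c: i for i, c in enumerate(ordered)}).to_numpy()
    design = pd.DataFrame({"marker": x / unit_scale})
    adjustment = "crude"
    if age is not None:
        design["age_ge_cut"] = (
            pd.Series(age, dtype=float).reset_index(drop=True) >= age_cut
        ).astype(float)
        adjustment = "age-adjusted"
    fit = sm.MNLogit(codes, sm.add_constant(design)).fit(disp=False, maxiter=200)
    out: dict[str, AssociationResult] = {}
    for j, cls in enumerate(ordered[1:]):
        beta = float(fit.params.iloc[:, j]["marker"])
        se = float(fit.bse.iloc[:, j]["marker"])
        out[cls] = AssociationResult(
            estimate=math.exp(beta),
            ci_low=math.exp(beta - Z975 * se),
            ci_high=math.exp(beta + Z975 * se),
            p_value=float(fit.pvalues.iloc[:, j]["marker"]),
            scaling=f"per-{unit_scale:g}-unit",
            adjustment=adjustment,
            label=f"{cls} vs {ref}",
        )
    return out


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (rho, two-sided p)."""
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and two-sided p across groups."""
    if any(len(g) == 0 for g in groups):
        raise ValidationError("kruskal_wallis: empty group")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if all(np.array_equal(arrays[0], a) for a in arrays[1:]):
        return 0.0, 1.0
    res = stats.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


def fisher_exact_kx2(table) -> float:
    """Exact two-sided Fisher test p for a k x 2 contingency table.

    Enumerates all tables with the observed margins and sums the conditional
    (multivariate hypergeometric) probabilities of tables at most as probable
    as the observed one — the standard generalization of the 2x2 test.
    Suitable for the small cohort sizes this pipeline targets.
    """
    T = np.asarray(table, dtype=int)
    if T.ndim != 2 or T.shape[1] != 2 or np.any(T < 0):
        raise ValidationError("fisher_exact_kx2: need a k x 2 nonnegative table")
    row_sums = T.sum(axis=1)
    if np.any(row_sums == 0):
        raise ValidationError("fisher_exact_kx2: empty group (zero row margin)")
    col0 = int(T[:, 0].sum())

    def log_binom(n, k):
        return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)

    denom = log_binom(int(row_sums.sum()), col0)

    def table_logp(cells0) -> float:
        return sum(log_binom(r, c) for r, c in zip(row_sums, cells0)) - denom

    obs_logp = table_logp(T[:, 0])
    total = 0.0
    ranges = [range(min(int(r), col0) + 1) for r in row_sums]
    for cells in itertools.product(*ranges[:-1]):
        last = col0 - sum(cells)
        if 0 <= last <= row_sums[-1]:
            lp = table_logp(list(cells) + [last])
            if lp <= obs_logp + 1e-9:
                total += math.exp(lp)
    return float(min(total, 1.0))


def km_dfs(
    times,
    events,
    groups=None,
    horizon_days: float = 5 * 365.0,
):
    """Kaplan-Meier disease-free-survival estimate(s) up to ``horizon_days``
    plus a log-rank test across groups.

    Returns (fitters, logrank_p): ``fitters`` maps group name to a fitted
    lifelines KaplanMeierFitter; ``logrank_p`` is None without groups.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.any(times < 0):
        raise ValidationError("km_dfs: negative follow-up time")
    capped_t = np.minimum(times, horizon_days)
    capped_e = np.where(times <= horizon_days, events, 0)
    fitters = {}
    if groups is None:
        kmf = KaplanMeierFitter()
        kmf.fit(capped_t, capped_e, label="all")
        return {"all": kmf}, None
    groups = pd.Series(groups).astype(str).to_numpy()
    for g in np.unique(groups):
        kmf = KaplanMeierFitter()
        mask = groups == g
        kmf.fit(capped_t[mask], capped_e[mask], label=str(g))
        fitters[str(g)] = kmf
    lr = multivariate_logrank_test(capped_t, groups, capped_e)
    return fitters, float(lr.p_value)


def quadrant_classify(x, y, x_cut: float, y_cut: float) -> pd.Series:
    """Quadrant of each (x, y) point around the cuts: Q2 = high-x/high-y,
    Q4 = high-x/low-y, Q1 = low-x/high-y, Q3 = low-x/low-y; boundary values
    go to the low side."""
    if not (np.isfinite(x_cut) and np.isfinite(y_cut)):
        raise ValidationError("quadrant_classify: cuts must be finite")
    x = pd.Series(x, dtype=float)
    y = pd.Series(y, dtype=float).set_axis(x.index)
    hx, hy = x > x_cut, y > y_cut
    out = np.where(hx & hy, "Q2",
          np.where(hx & ~hy, "Q4",
          np.where(~hx & hy, "Q1", "Q3")))
    return pd.Series(out, index=x.index, name="quadrant")
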