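"""Inferential layer: Welch tests, random-intercept mixed model, Pearson.

Group comparisons use the Welch (unequal-variance) two-sample t-test
with the Satterthwaite degrees-of-freedom approximation.  Because the
comparisons often have to be reproduced from *printed* summaries (mean,
dispersion, n) rather than raw data, the summary-statistics route is
the primitive and the raw-data route delegates to it.  The dispersion
kind (SD vs SEM) is an explicit input: published "+/-" values are not
always labelled consistently, so the caller states the interpretation
instead of the code guessing one.

Clustered per-object data (many vessels per animal) are handled by a
random-intercept linear mixed model, y_ij = b0 + b1*group + u_i + e_ij,
fitted by REML.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "WelchResult",
    "MixedModelResult",
    "welch_from_summary",
    "welch_from_data",
    "mixed_model",
    "pearson",
    "reproduce_group_table",
    "round_half_away",
]


@dataclass(frozen=True)
class GroupSummary:
    """Printed-table description of one group: n, mean and dispersion."""

    name: str
    n: int
    mean: float
    dispersion: float
    kind: str = "SEM"           # "SD" or "SEM"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.name!r}: need n >= 2, got {self.n}")
        if self.dispersion < 0:
            raise ValueError(f"group {self.name!r}: dispersion must be >= 0")
        if self.kind not in ("SD", "SEM"):
            raise ValueError(f"dispersion kind must be 'SD' or 'SEM', got {self.kind!r}")

    @property
    def sem(self) -> float:
        return self.dispersion if self.kind == "SEM" else self.dispersion / math.sqrt(self.n)


@dataclass(frozen=True)
class WelchResult:
    difference: float           # group1 mean - group2 mean
    se: float
    df: float                   # Welch-Satterthwaite degrees of freedom
    t: float
    p: float                    # two-sided
    ci_low: float
    ci_high: float
    level: float = 0.95


def welch_from_summary(g1: GroupSummary, g2: GroupSummary,
                       level: float = 0.95) -> WelchResult:
    """Welch two-sample t-test from group summaries.

    SE_diff = sqrt(SEM1^2 + SEM2^2); df by Welch-Satterthwaite;
    two-sided p from the t distribution; CI = diff +/- t_crit * SE_diff.
    """
    v1, v2 = g1.sem ** 2, g2.sem ** 2
    se = math.sqrt(v1 + v2)
    if se == 0:
        raise ValueError("both groups have zero dispersion; Welch t is undefined")
    df = (v1 + v2) ** 2 / (v1 ** 2 / (g1.n - 1) + v2 ** 2 / (g2.n - 1))
    diff = g1.mean - g2.mean
    t = diff / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    tcrit = float(sps.t.ppf(0.5 * (1.0 + level), df))
    return WelchResult(difference=diff, se=se, df=df, t=t, p=p,
                       ci_low=diff - tcrit * se, ci_high=diff + tcrit * se,
                       level=level)


def welch_from_data(x, y, level: float = 0.95,
                    names: tuple[str, str] = ("x", "y")) -> WelchResult:
    """Welch test from raw samples; summarises then delegates."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least two observations")
    g1 = GroupSummary(names[0], int(x.size), float(x.mean()),
                      float(x.std(ddof=1)), kind="SD")
    g2 = GroupSummary(names[1], int(y.size), float(y.mean()),
                      float(y.std(ddof=1)), kind="SD")
    return welch_from_summary(g1, g2, level=level)


@dataclass(frozen=True)
class MixedModelResult:
    beta: float                 # fixed group effect
    se: float
    p: float
    var_between: float          # between-animal (random intercept) variance
    var_resid: float


def _reml_profile(lam: float, y: np.ndarray, X: np.ndarray,
                  codes: np.ndarray, n_groups: int):
    """GLS quantities at a fixed variance ratio lam = var_u / var_e.

    With V0 = I + lam * Z Z' block-diagonal by cluster, the Woodbury
    identity gives V0^-1 a = a - lam/(1 + lam n_i) * J a per cluster,
    so everything reduces to per-cluster sums.
    """
    n, p = X.shape
    n_i = np.bincount(codes, minlength=n_groups).astype(float)
    w = lam / (1.0 + lam * n_i)                       # per-cluster shrinkage
    Xs = np.stack([np.bincount(codes, weights=X[:, j], minlength=n_groups)
                   for j in range(p)], axis=1)        # cluster column sums
    ys = np.bincount(codes, weights=y, minlength=n_groups)
    XtViX = X.T @ X - (Xs * w[:, None]).T @ Xs
    XtViy = X.T @ y - Xs.T @ (w * ys)
    ytViy = y @ y - np.sum(w * ys ** 2)
    beta = np.linalg.solve(XtViX, XtViy)
    rtVir = float(ytViy - beta @ XtViy)
    sign, logdet_X = np.linalg.slogdet(XtViX)
    logdet_V = float(np.sum(np.log1p(lam * n_i)))
    neg2ll = (n - p) * math.log(max(rtVir, 1e-300)) + logdet_V + logdet_X
    return neg2ll, beta, rtVir, XtViX


def mixed_model(observations: pd.DataFrame, value: str = "value",
                animal: str = "animal", genotype: str = "genotype",
                reference: str | None = None) -> MixedModelResult:
    """Random-intercept model for per-object data clustered by animal.

    Fits y_ij = b0 + b1 * I[genotype != reference] + u_i + e_ij by
    restricted maximum likelihood, profiling the single variance ratio
    lam = var_u / var_e (the boundary lam = 0 is examined explicitly,
    so zero between-animal variance degrades gracefully to OLS).
    Reports the genotype effect b1 with its Wald SE and two-sided
    normal p plus the variance components.  ``reference`` defaults to
    the first genotype in sorted order; at least two animals per
    genotype are required.
    """
    from scipy import optimize

    df = observations[[value, animal, genotype]].dropna()
    levels = sorted(df[genotype].unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two genotypes, got {levels}")
    ref = reference if reference is not None else levels[0]
    if ref not in levels:
        raise ValueError(f"reference {ref!r} not among genotypes {levels}")
    per_group = df.groupby(genotype)[animal].nunique()
    low = per_group[per_group < 2]
    if len(low):
        raise ValueError(
            f"need >= 2 animals per genotype; got {per_group.to_dict()}")

    y = df[value].to_numpy(dtype=float)
    g = (df[genotype] != ref).to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(g), g])
    codes, uniques = pd.factorize(df[animal])
    n_groups = len(uniques)

    obj = lambda t: _reml_profile(math.exp(t), y, X, codes, n_groups)[0]
    res = optimize.minimize_scalar(obj, bounds=(-14.0, 14.0), method="bounded")
    lam = math.exp(res.x)
    if _reml_profile(0.0, y, X, codes, n_groups)[0] <= res.fun:
        lam = 0.0
    _, beta, rtVir, XtViX = _reml_profile(lam, y, X, codes, n_groups)
    n, p = X.shape
    var_e = rtVir / (n - p)
    cov_beta = var_e * np.linalg.inv(XtViX)
    se = float(math.sqrt(cov_beta[1, 1]))
    z = beta[1] / se
    return MixedModelResult(beta=float(beta[1]), se=se,
                            p=2.0 * float(sps.norm.sf(abs(z))),
                            var_between=lam * var_e, var_resid=var_e)


def pearson(x, y) -> tuple[float, float, int]:
    """Pearson product-moment correlation with its two-sided p and df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), int(x.size - 2)


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (printed-table convention)."""
    scale = 10 ** decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def reproduce_group_table(rows: list[tuple[str, GroupSummary, GroupSummary]],
                          level: float = 0.95) -> pd.DataFrame:
    """Recompute a published comparison table from its printed summaries.

    Each row pairs the control and mutant summaries for one dependent
    variable; the difference is control mean minus mutant mean.  Outputs
    both full precision and values rounded half-away-from-zero to one
    decimal for side-by-side comparison with the printed table.
    """
    out = []
    for name, ctrl, mut in rows:
        w = welch_from_summary(ctrl, mut, level=level)
        out.append({
            "variable": name,
            "control_mean": ctrl.mean, "mutant_mean": mut.mean,
            "difference": w.difference, "se": w.se, "df": w.df,
            "t": w.t, "p": w.p, "l95": w.ci_low, "u95": w.ci_high,
            "difference_1dp": round_half_away(w.difference),
            "se_1dp": round_half_away(w.se),
            "l95_1dp": round_half_away(w.ci_low),
            "u95_1dp": round_half_away(w.ci_high),
        })
    return pd.DataFrame(out)
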