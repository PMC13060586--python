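"""Bioassay endpoints and the statistical comparison workflow.

Implements the full analysis chain applied to cone-assay outcomes and
total-movement data:

* knockdown (60 min) and mortality (24 h) rates pooled per swatch, with the
  WHO-convention control correction (Abbott);
* Welch's unequal-variance t test on group summaries, with
  Welch–Satterthwaite degrees of freedom;
* Cohen's d on the pooled (n−1-weighted) SD, with the t-multiplier CI
  ``d ± t_{1−α/2, n−2} · sqrt((na+nb)/(na·nb) + d²/(2(na+nb)))``;
* t-based confidence intervals for group means;
* Levene's test (classical mean-centred form);
* two-way factorial ANOVA with Type-III sums of squares under sum-to-zero
  contrasts, partial eta², Shapiro–Wilk residual normality, estimated
  marginal means (unweighted over the other factor's levels) and
  Tukey-adjusted pairwise contrasts, emmeans-style.

Group comparisons operate on :class:`GroupSummary` (n, mean, sample SD), so
printed summary tables can be analysed directly without raw data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "AssayOutcome",
    "WelchResult",
    "EffectSize",
    "LeveneResult",
    "AnovaReport",
    "AbbottResult",
    "EndpointRates",
    "endpoint_rates",
    "abbott_adjust",
    "welch_t",
    "cohens_d",
    "ci_mean",
    "levene_test",
    "two_way_anova",
]


# ---------------------------------------------------------------------------
# summaries and endpoints


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics of one comparison arm (sample SD, n−1)."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("GroupSummary needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @classmethod
    def from_values(cls, label: str, values) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        return cls(label=label, n=len(v), mean=float(v.mean()), sd=float(v.std(ddof=1)))


@dataclass(frozen=True)
class AssayOutcome:
    """One cone-assay replicate outcome (5 mosquitoes per cone)."""

    swatch_id: str
    replicate_id: str
    n_exposed: int
    n_kd_60min: int
    n_dead_24h: int
    arm: str  # "treated" | "control"
    strain: str = ""
    net: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.n_kd_60min <= self.n_exposed):
            raise ValueError("n_kd_60min outside [0, n_exposed]")
        if not (0 <= self.n_dead_24h <= self.n_exposed):
            raise ValueError("n_dead_24h outside [0, n_exposed]")
        if self.arm not in ("treated", "control"):
            raise ValueError("arm must be 'treated' or 'control'")


@dataclass(frozen=True)
class EndpointRates:
    per_swatch: pd.DataFrame
    per_arm: pd.DataFrame


def endpoint_rates(outcomes: list[AssayOutcome]) -> EndpointRates:
    """Pool replicate outcomes into per-swatch and per-arm KD%/mortality%.

    With the standard design (5 replicates x 5 exposed) each swatch pools
    25 mosquitoes.  Replicates with n_exposed != 5 are flagged, not
    rejected.
    """
    if not outcomes:
        raise ValueError("no outcomes supplied")
    df = pd.DataFrame([o.__dict__ for o in outcomes])
    rows = []
    for swatch, grp in df.groupby("swatch_id", sort=False):
        n_total = int(grp["n_exposed"].sum())
        rows.append(
            {
                "swatch_id": swatch,
                "arm": grp["arm"].iloc[0],
                "n_replicates": len(grp),
                "n_exposed": n_total,
                "kd_pct": 100.0 * grp["n_kd_60min"].sum() / n_total,
                "mortality_pct": 100.0 * grp["n_dead_24h"].sum() / n_total,
                "nonstandard_exposure": bool((grp["n_exposed"] != 5).any()),
            }
        )
    per_swatch = pd.DataFrame(rows)
    arm_rows = []
    for arm, grp in df.groupby("arm", sort=False):
        n_total = int(grp["n_exposed"].sum())
        arm_rows.append(
            {
                "arm": arm,
                "n_exposed": n_total,
                "kd_pct": 100.0 * grp["n_kd_60min"].sum() / n_total,
                "mortality_pct": 100.0 * grp["n_dead_24h"].sum() / n_total,
            }
        )
    return EndpointRates(per_swatch=per_swatch, per_arm=pd.DataFrame(arm_rows))


@dataclass(frozen=True)
class AbbottResult:
    adjusted_pct: float
    applied: bool  # formula actually applied (control in (5, 20])
    valid: bool  # False when control mortality > 20% voids the assay


def abbott_adjust(treated_pct: float, control_pct: float) -> AbbottResult:
    """Control-mortality correction, WHO convention.

    ``adjusted = 100 (treated − control) / (100 − control)``, floored at 0.
    Applied only when control mortality is in (5%, 20%]; at or below 5% the
    treated rate is reported unadjusted; above 20% the assay is invalid.
    """
    if not (0.0 <= control_pct < 100.0):
        raise ValueError("control_pct must be in [0, 100)")
    if not (0.0 <= treated_pct <= 100.0):
        raise ValueError("treated_pct must be in [0, 100]")
    if control_pct > 20.0:
        return AbbottResult(adjusted_pct=math.nan, applied=False, valid=False)
    if control_pct <= 5.0:
        return AbbottResult(adjusted_pct=treated_pct, applied=False, valid=True)
    adj = 100.0 * (treated_pct - control_pct) / (100.0 - control_pct)
    return AbbottResult(adjusted_pct=max(adj, 0.0), applied=True, valid=True)


# ---------------------------------------------------------------------------
# two-group comparisons from summaries


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    mean_diff: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    a: GroupSummary
    b: GroupSummary


def ci_mean(summary: GroupSummary, level: float = 0.95) -> tuple[float, float]:
    """t-based confidence interval for a group mean."""
    tcrit = sps.t.ppf(0.5 + level / 2.0, summary.n - 1)
    half = tcrit * summary.sd / math.sqrt(summary.n)
    return (summary.mean - half, summary.mean + half)


def welch_t(a: GroupSummary, b: GroupSummary) -> WelchResult:
    """Welch's unequal-variance t test from group summaries.

    ``t = (ma − mb) / sqrt(sa²/na + sb²/nb)`` with Welch–Satterthwaite
    degrees of freedom and a two-sided p-value.
    """
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    se2 = va + vb
    if se2 == 0.0:
        raise ValueError("both groups have zero variance; t undefined")
    t = (a.mean - b.mean) / math.sqrt(se2)
    df = se2**2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(
        t=t,
        df=df,
        p=p,
        mean_diff=a.mean - b.mean,
        ci_a=ci_mean(a),
        ci_b=ci_mean(b),
        a=a,
        b=b,
    )


@dataclass(frozen=True)
class EffectSize:
    d: float
    ci_lo: float
    ci_hi: float


def cohens_d(a: GroupSummary, b: GroupSummary, level: float = 0.95) -> EffectSize:
    """Cohen's d on the pooled (n−1-weighted) SD with a t-multiplier CI."""
    na, nb = a.n, b.n
    sp2 = ((na - 1) * a.sd**2 + (nb - 1) * b.sd**2) / (na + nb - 2)
    if sp2 == 0.0:
        raise ValueError("pooled SD is zero; d undefined")
    d = (a.mean - b.mean) / math.sqrt(sp2)
    se = math.sqrt((na + nb) / (na * nb) + d**2 / (2.0 * (na + nb)))
    tcrit = sps.t.ppf(0.5 + level / 2.0, na + nb - 2)
    return EffectSize(d=d, ci_lo=d - tcrit * se, ci_hi=d + tcrit * se)


# ---------------------------------------------------------------------------
# variance homogeneity


@dataclass(frozen=True)
class LeveneResult:
    F: float
    df_between: int
    df_within: int
    p: float


def levene_test(groups: list) -> LeveneResult:
    """Levene's test with classical mean centering.

    One-way ANOVA on absolute deviations from the group means.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(g) < 2 for g in arrays):
        raise ValueError("need >= 2 groups of >= 2 values each")
    if all(np.ptp(g) == 0 for g in arrays):
        raise ValueError("all groups constant; deviations are identically zero")
    F, p = sps.levene(*arrays, center="mean")
    k = len(arrays)
    n = sum(len(g) for g in arrays)
    return LeveneResult(F=float(F), df_between=k - 1, df_within=n - k, p=float(p))


# ---------------------------------------------------------------------------
# factorial ANOVA with estimated marginal means


@dataclass
class AnovaReport:
    """Two-way factorial ANOVA report.

    ``effects`` has one row per model term with SS, df, F, p and partial
    eta²; ``emmeans`` and ``contrasts`` are keyed by factor name (plus
    ``"<factor_b> | <factor_a>"`` for simple-effect contrasts); Tukey
    adjustment uses the studentized range over each contrast family.
    """

    effects: pd.DataFrame
    shapiro_w: float
    shapiro_p: float
    emmeans: dict[str, pd.DataFrame] = field(default_factory=dict)
    contrasts: dict[str, pd.DataFrame] = field(default_factory=dict)
    df_resid: float = 0.0
    residuals: np.ndarray | None = None

    def format_text(self) -> str:
        """Human-readable report: effects, marginal means, contrasts."""
        lines = ["Two-way ANOVA (Type-III SS, sum-to-zero contrasts)", ""]
        eff = self.effects.copy()
        eff["p"] = eff["p"].map(lambda v: f"{v:.4f}")
        lines.append(eff.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        lines.append("")
        lines.append(
            f"Shapiro-Wilk on residuals: W = {self.shapiro_w:.5f}, "
            f"p = {self.shapiro_p:.4f}"
        )
        for factor, emm in self.emmeans.items():
            lines += ["", f"Estimated marginal means: {factor}"]
            lines.append(emm.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        for family, con in self.contrasts.items():
            lines += ["", f"Tukey-adjusted contrasts: {family}"]
            con = con.copy()
            con["p_tukey"] = con["p_tukey"].map(lambda v: f"{v:.4f}")
            lines.append(con.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)


def _tukey_p(tstat: float, n_means: int, df: float) -> float:
    if n_means < 2:
        return math.nan
    return float(sps.studentized_range.sf(abs(tstat) * math.sqrt(2.0), n_means, df))


def _emmeans_rows(cell_X, cells, factor, params, cov, df_resid, level=0.95):
    levels = list(dict.fromkeys(cells[factor]))
    tcrit = sps.t.ppf(0.5 + level / 2.0, df_resid)
    L_rows = {}
    rows = []
    for lev in levels:
        sel = np.asarray(cells[factor] == lev)
        L = cell_X[sel].mean(axis=0)
        L_rows[lev] = L
        est = float(L @ params)
        se = float(np.sqrt(L @ cov @ L))
        rows.append(
            {
                "level": lev,
                "emmean": est,
                "se": se,
                "df": df_resid,
                "ci_lo": est - tcrit * se,
                "ci_hi": est + tcrit * se,
            }
        )
    return pd.DataFrame(rows), L_rows


def _pairwise(L_rows, params, cov, df_resid, family_size=None):
    levels = list(L_rows)
    k = family_size if family_size is not None else len(levels)
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            L = L_rows[levels[i]] - L_rows[levels[j]]
            est = float(L @ params)
            se = float(np.sqrt(L @ cov @ L))
            t = est / se
            rows.append(
                {
                    "contrast": f"{levels[i]} - {levels[j]}",
                    "estimate": est,
                    "se": se,
                    "t": t,
                    "p_tukey": _tukey_p(t, k, df_resid),
                }
            )
    return pd.DataFrame(rows)


def two_way_anova(
    data: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
) -> AnovaReport:
    """Two-way crossed ANOVA with Type-III SS and emmeans-style follow-up.

    Fits ``response ~ A * B`` under sum-to-zero contrasts (so Type-III sums
    of squares are meaningful for unbalanced data and marginal means are
    unweighted over the other factor's levels), tests residual normality
    with Shapiro–Wilk, and computes estimated marginal means with
    Tukey-adjusted pairwise contrasts for each factor and for ``B`` within
    each level of ``A``.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = data[[response, factor_a, factor_b]].copy()
    cell_n = df.groupby([factor_a, factor_b], observed=True).size().unstack()
    if cell_n.isna().any().any() or (cell_n < 2).any().any():
        raise ValueError(
            "every factor-level cell needs >= 2 observations; "
            f"cell counts:\n{cell_n.fillna(0).astype(int)}"
        )

    formula = f"{response} ~ C({factor_a}, Sum) * C({factor_b}, Sum)"
    model = smf.ols(formula, data=df).fit()
    tab = anova_lm(model, typ=3)
    ss_res = float(tab.loc["Residual", "sum_sq"])

    name_a, name_b = f"C({factor_a}, Sum)", f"C({factor_b}, Sum)"
    pretty = {
        name_a: factor_a,
        name_b: factor_b,
        f"{name_a}:{name_b}": f"{factor_a}:{factor_b}",
    }
    rows = []
    for term, label in pretty.items():
        ss = float(tab.loc[term, "sum_sq"])
        rows.append(
            {
                "effect": label,
                "ss": ss,
                "df": float(tab.loc[term, "df"]),
                "F": float(tab.loc[term, "F"]),
                "p": float(tab.loc[term, "PR(>F)"]),
                "partial_eta2": ss / (ss + ss_res),
            }
        )
    effects = pd.DataFrame(rows)

    resid = np.asarray(model.resid)
    sw = sps.shapiro(resid)

    # estimated marginal means on the model scale
    from patsy import build_design_matrices

    levels_a = list(dict.fromkeys(df[factor_a]))
    levels_b = list(dict.fromkeys(df[factor_b]))
    cells = pd.DataFrame(
        [(la, lb) for la in levels_a for lb in levels_b],
        columns=[factor_a, factor_b],
    )
    design_info = model.model.data.design_info
    cell_X = np.asarray(build_design_matrices([design_info], cells)[0])
    params = np.asarray(model.params)
    cov = np.asarray(model.cov_params())
    df_resid = float(model.df_resid)

    emmeans: dict[str, pd.DataFrame] = {}
    contrasts: dict[str, pd.DataFrame] = {}
    for factor in (factor_a, factor_b):
        emm, L_rows = _emmeans_rows(cell_X, cells, factor, params, cov, df_resid)
        emmeans[factor] = emm
        contrasts[factor] = _pairwise(L_rows, params, cov, df_resid)

    # simple effects: B within each level of A (Tukey family = levels of B)
    for la in levels_a:
        sub = np.asarray(cells[factor_a] == la)
        L_rows = {
            lb: cell_X[sub & np.asarray(cells[factor_b] == lb)].mean(axis=0)
            for lb in levels_b
        }
        contrasts[f"{factor_b} | {factor_a}={la}"] = _pairwise(
            L_rows, params, cov, df_resid, family_size=len(levels_b)
        )

    return AnovaReport(
        effects=effects,
        shapiro_w=float(sw.statistic),
        shapiro_p=float(sw.pvalue),
        emmeans=emmeans,
        contrasts=contrasts,
        df_resid=df_resid,
        residuals=resid,
    )
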