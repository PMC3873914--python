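"""Group-level statistics for the reference-region normalization analysis.

Implements the statistical framework of the study design: one-way ANOVA per
region, Dunnett's many-to-one post hoc comparisons against the control
group, Cohen's d effect sizes, coefficients of variation as the measure of
inter-subject intensity variability, a two-way random-effects variance
decomposition (diagnosis group vs normalization method), and an
age-covaried ANCOVA for volumetric comparisons.

Dunnett's family-wise adjusted p values are computed by deterministic
Gaussian quadrature of the k-variate t rectangle probability, using the
classical factorization of the comparison statistics into a shared control
normal deviate and the pooled variance chi factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from numpy.polynomial.legendre import leggauss
from scipy import stats
from scipy.special import ndtr

from .exceptions import AnalysisError
from .roi_norm import RegionMapping

__all__ = [
    "one_way_anova",
    "dunnett_test",
    "cohens_d",
    "coefficient_of_variation",
    "VarianceComponents",
    "variance_components",
    "AncovaResult",
    "ancova_volume",
    "compare_all",
]


# ---------------------------------------------------------------------------
# elementary statistics


def _check_groups(values_by_group: Mapping[str, np.ndarray], min_per_group: int = 2) -> None:
    if len(values_by_group) < 2:
        raise AnalysisError("need at least two groups")
    for name, vals in values_by_group.items():
        if len(vals) < min_per_group:
            raise AnalysisError(f"group {name!r} has fewer than {min_per_group} observations")


def one_way_anova(values: np.ndarray, groups: Sequence) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p value.

    Between/within mean-square ratio with (g - 1, n - g) degrees of freedom.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    by_group = {g: values[groups == g] for g in pd.unique(groups)}
    _check_groups(by_group)
    f, p = stats.f_oneway(*by_group.values())
    return float(f), float(p)


def cohens_d(patient: np.ndarray, control: np.ndarray) -> float:
    """Standardized mean difference (patient mean - control mean) / pooled SD."""
    x = np.asarray(patient, dtype=float)
    y = np.asarray(control, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise AnalysisError("both groups need at least two observations")
    nx, ny = len(x), len(y)
    pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2))
    if pooled == 0:
        warnings.warn("zero pooled SD: Cohen's d undefined", stacklevel=2)
        return float("nan")
    return float((x.mean() - y.mean()) / pooled)


def coefficient_of_variation(values: np.ndarray) -> float:
    """100 * sample SD / mean, in percent; undefined (NaN) for zero mean."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    m = values.mean()
    if m == 0:
        warnings.warn("zero mean: CV undefined", stacklevel=2)
        return float("nan")
    if len(values) < 2:
        return 0.0
    return float(100.0 * values.std(ddof=1) / m)


# ---------------------------------------------------------------------------
# Dunnett's test


@lru_cache(maxsize=64)
def _quad_nodes(df: int, n_z: int, n_u: int):
    """Cached quadrature nodes: standard-normal (Gauss-Hermite) and the
    chi factor S/sigma (Gauss-Legendre on the probability transform)."""
    zh, wh = hermgauss(n_z)
    z = np.sqrt(2.0) * zh
    wz = wh / np.sqrt(np.pi)
    ql, wl = leggauss(n_u)
    q = 0.5 * (ql + 1.0)
    wq = 0.5 * wl
    u = np.sqrt(stats.chi2.ppf(q, df) / df)
    return z, wz, u, wq


def _dunnett_family_prob(
    t: np.ndarray,
    n_treat: np.ndarray,
    n_control: int,
    df: int,
    sides: int = 2,
    n_z: int = 64,
    n_u: int = 64,
) -> np.ndarray:
    """P(max_j |T_j| <= t) (or max T_j for one-sided) under the null.

    T_j = (mean_j - mean_0) / (S * sqrt(1/n_j + 1/n_0)) with the pooled S.
    Conditional on the control deviate Z0 and the chi factor U = S/sigma the
    T_j are independent, so the rectangle probability reduces to a double
    quadrature: Gauss-Hermite over Z0 and Gauss-Legendre over the
    probability transform of U.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    n_treat = np.asarray(n_treat, dtype=float)
    z, wz, u, wq = _quad_nodes(int(df), n_z, n_u)

    c = np.sqrt(1.0 / n_treat + 1.0 / n_control)  # (k,)
    rootn = np.sqrt(n_treat)
    center = rootn[:, None] * (z[None, :] / np.sqrt(n_control))  # (k, nz)
    half = rootn[:, None, None, None] * t[None, :, None, None] * u[None, None, None, :] * c[:, None, None, None]
    # shapes: center (k, 1, nz, 1); half (k, nt, 1, nu)
    upper = center[:, None, :, None] + half
    if sides == 2:
        lower = center[:, None, :, None] - half
        probs = ndtr(upper) - ndtr(lower)
    elif sides == 1:
        probs = ndtr(upper)
    else:
        raise AnalysisError("sides must be 1 or 2")
    inner = probs.prod(axis=0)  # (nt, nz, nu)
    return np.einsum("tzu,z,u->t", inner, wz, wq)


def dunnett_test(
    treatments: Mapping[str, np.ndarray],
    control: np.ndarray,
    sides: int = 2,
) -> dict[str, float]:
    """Dunnett's many-to-one comparisons; family-wise adjusted p values.

    Pools the error variance over the control and all treatment groups;
    adjusted p for comparison i is 1 - P(max_j |T_j| <= |t_i|) under the
    joint null of the k-variate t with correlations induced by the shared
    control mean.  Returns {treatment name: adjusted p}.
    """
    if len(treatments) == 0:
        raise AnalysisError("Dunnett's test needs at least one treatment group")
    control = np.asarray(control, dtype=float)
    by_group = {"__control__": control, **{k: np.asarray(v, float) for k, v in treatments.items()}}
    _check_groups(by_group)
    names = list(treatments)
    n0 = len(control)
    n_i = np.array([len(by_group[g]) for g in names])
    n_tot = n0 + n_i.sum()
    df = int(n_tot - (len(names) + 1))
    sse = sum(np.sum((v - v.mean()) ** 2) for v in by_group.values())
    mse = sse / df
    if mse == 0:
        warnings.warn("zero pooled variance: Dunnett statistics undefined", stacklevel=2)
        return {g: float("nan") for g in names}
    tstat = np.array(
        [(by_group[g].mean() - control.mean()) / np.sqrt(mse * (1.0 / len(by_group[g]) + 1.0 / n0)) for g in names]
    )
    crit = np.abs(tstat) if sides == 2 else tstat
    probs = _dunnett_family_prob(crit, n_i, n0, df, sides=sides)
    p_adj = np.clip(1.0 - probs, 0.0, 1.0)
    return dict(zip(names, (float(p) for p in p_adj)))


# ---------------------------------------------------------------------------
# variance components


@dataclass(frozen=True)
class VarianceComponents:
    """Two-way random-effects variance decomposition."""

    var_diagnosis: float
    var_normalization: float
    var_residual: float

    @property
    def total(self) -> float:
        return self.var_diagnosis + self.var_normalization + self.var_residual

    @property
    def proportions(self) -> dict[str, float]:
        tot = self.total
        if tot == 0:
            # degenerate all-identical data: components are all zero
            return {"diagnosis": 0.0, "normalization": 0.0, "residual": 1.0}
        return {
            "diagnosis": self.var_diagnosis / tot,
            "normalization": self.var_normalization / tot,
            "residual": self.var_residual / tot,
        }


def _factor_ss(values: np.ndarray, factor: np.ndarray):
    """One factor's sum of squares, df and its EMS coefficient for the
    variance component (method of moments, additive model)."""
    levels = pd.unique(factor)
    n = len(values)
    grand = values.sum()
    ss = 0.0
    msq = 0.0
    for lv in levels:
        sel = factor == lv
        m = sel.sum()
        ss += values[sel].sum() ** 2 / m
        msq += m * m
    ss -= grand**2 / n
    coef = n - msq / n
    return float(ss), len(levels) - 1, float(coef)


def variance_components(
    data: pd.DataFrame,
    value_col: str = "value",
    diagnosis_col: str = "diagnosis",
    normalization_col: str = "normalization",
) -> VarianceComponents:
    """Method-of-moments variance components from the two-way
    random-effects ANOVA expected mean squares (additive model, both
    factors random); negative estimates are truncated to zero.

    The layout must be crossed: every subject (nested in diagnosis)
    contributes one value under each normalization, so each factor's
    marginal totals are free of the other factor's effects.
    """
    values = data[value_col].to_numpy(dtype=float)
    diag = data[diagnosis_col].to_numpy()
    norm = data[normalization_col].to_numpy()
    n = len(values)
    if n < 4:
        raise AnalysisError("too few observations for variance components")

    ss_tot = float(((values - values.mean()) ** 2).sum())
    out = {}
    used_df = 0
    ss_used = 0.0
    parts = {}
    for name, factor in (("diagnosis", diag), ("normalization", norm)):
        if len(pd.unique(factor)) < 2:
            warnings.warn(f"factor {name} has a single level: component set to 0", stacklevel=2)
            parts[name] = None
            continue
        ss, df, coef = _factor_ss(values, factor)
        parts[name] = (ss, df, coef)
        used_df += df
        ss_used += ss

    df_e = (n - 1) - used_df
    ss_e = max(ss_tot - ss_used, 0.0)
    var_e = ss_e / df_e if df_e > 0 else 0.0

    for name, part in parts.items():
        if part is None:
            out[name] = 0.0
            continue
        ss, df, coef = part
        ms = ss / df
        out[name] = max((ms - var_e) * df / coef, 0.0) if coef > 0 else 0.0

    return VarianceComponents(
        var_diagnosis=out.get("diagnosis", 0.0),
        var_normalization=out.get("normalization", 0.0),
        var_residual=var_e,
    )


# ---------------------------------------------------------------------------
# ANCOVA (age-covaried volume comparison)


@dataclass
class AncovaResult:
    f: float
    p: float
    dunnett_p: dict[str, float]
    used_covariate: bool


def ancova_volume(
    volumes: np.ndarray,
    groups: Sequence,
    ages: np.ndarray,
    control: str = "control",
    sides: int = 2,
) -> AncovaResult:
    """Group effect on volume adjusting for age.

    Fits volume = intercept + group indicators + age by OLS, tests the
    group effect with the extra-sum-of-squares F against the age-only
    model, and compares age-adjusted group means to the control with
    Dunnett-type family-wise adjustment using the model residual MSE.
    Falls back to the plain one-way ANOVA when age carries no information
    (constant or collinear).
    """
    volumes = np.asarray(volumes, dtype=float)
    ages = np.asarray(ages, dtype=float)
    groups = np.asarray(groups)
    if not (len(volumes) == len(groups) == len(ages)):
        raise AnalysisError("volumes, groups and ages must be aligned")
    names = [g for g in pd.unique(groups) if g != control]
    if control not in groups:
        raise AnalysisError(f"control group {control!r} absent")

    if np.ptp(ages) == 0:
        warnings.warn("constant age: falling back to one-way ANOVA", stacklevel=2)
        f, p = one_way_anova(volumes, groups)
        dp = dunnett_test({g: volumes[groups == g] for g in names}, volumes[groups == control], sides=sides)
        return AncovaResult(f, p, dp, used_covariate=False)

    n = len(volumes)
    agec = ages - ages.mean()
    dummies = np.stack([(groups == g).astype(float) for g in names], axis=1)
    x_full = np.column_stack([np.ones(n), dummies, agec])
    x_red = np.column_stack([np.ones(n), agec])

    beta, *_ = np.linalg.lstsq(x_full, volumes, rcond=None)
    resid = volumes - x_full @ beta
    sse_full = float(resid @ resid)
    df_full = n - x_full.shape[1]
    beta_r, *_ = np.linalg.lstsq(x_red, volumes, rcond=None)
    sse_red = float((volumes - x_red @ beta_r) @ (volumes - x_red @ beta_r))

    k = len(names)
    if df_full <= 0:
        raise AnalysisError("not enough observations for the ANCOVA model")
    f = ((sse_red - sse_full) / k) / (sse_full / df_full)
    p = float(stats.f.sf(f, k, df_full))

    mse = sse_full / df_full
    xtx_inv = np.linalg.pinv(x_full.T @ x_full)
    n_i = np.array([(groups == g).sum() for g in names])
    n0 = int((groups == control).sum())
    tstats = np.array(
        [beta[1 + j] / np.sqrt(mse * xtx_inv[1 + j, 1 + j]) for j in range(k)]
    )
    crit = np.abs(tstats) if sides == 2 else tstats
    probs = _dunnett_family_prob(crit, n_i, n0, df_full, sides=sides)
    dp = dict(zip(names, np.clip(1.0 - probs, 0.0, 1.0).astype(float)))
    return AncovaResult(float(f), p, dp, used_covariate=True)


# ---------------------------------------------------------------------------
# full report


def _reference_series(table: pd.DataFrame, which: str, mapping: RegionMapping) -> np.ndarray:
    if which == "cer":
        return table["cerebellum"].to_numpy(float)
    if which == "wm":
        return table["wm"].to_numpy(float)
    lobe_means = [
        table[[f"{lobe}_{h}" for h in mapping.hemispheres]].astype(float).mean(axis=1)
        for lobe in mapping.lobes
    ]
    return pd.concat(lobe_means, axis=1).mean(axis=1).to_numpy()


def compare_all(
    tables: Mapping[str, pd.DataFrame],
    mapping: RegionMapping,
    control: str = "control",
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Run the full normalization comparison on one cohort.

    ``tables`` maps normalization name ("absolute" plus any of "cer", "wm",
    "cgm") to an ROI table on the same cohort.  Emits:

    * ``bias_check`` — per reference region: absolute mean, SD and CV per
      group plus the ANOVA F/p testing for a disease bias in the reference;
    * ``group_comparisons`` — per (region, normalization): ANOVA, Dunnett p
      versus control, Cohen's d, and the gated significance flag (Dunnett is
      interpreted only when the ANOVA is significant at ``alpha``);
    * ``cv_table`` — coefficient of variation per lobe (hemispheres pooled,
      all groups pooled) for the absolute data and each normalization;
    * ``variance_components`` — per region, the share of variance across
      the normalized tables attributable to diagnosis group, normalization
      method and residual.
    """
    if "absolute" not in tables:
        raise AnalysisError('tables must include the "absolute" ROI table')
    ref_ids = sorted(tables["absolute"]["subject_id"])
    for name, tab in tables.items():
        if sorted(tab["subject_id"]) != ref_ids:
            raise AnalysisError(f"cohort mismatch between 'absolute' and {name!r} tables")

    absolute = tables["absolute"]
    groups = absolute["group"].to_numpy()
    group_names = list(pd.unique(groups))
    if control not in group_names:
        raise AnalysisError(f"control group {control!r} absent from cohort")
    patient_groups = [g for g in group_names if g != control]
    regions = mapping.lobe_regions()

    # (a) reference-region bias check on absolute values
    bias_rows = []
    for ref in ("cgm", "cer", "wm"):
        vals = _reference_series(absolute, ref, mapping)
        row = {"reference": ref}
        for g in group_names:
            gv = vals[groups == g]
            row[f"mean_{g}"] = gv.mean()
            row[f"sd_{g}"] = gv.std(ddof=1)
            row[f"cv_{g}"] = coefficient_of_variation(gv)
        row["anova_F"], row["anova_p"] = one_way_anova(vals, groups)
        bias_rows.append(row)
    bias_check = pd.DataFrame(bias_rows)

    # (b) per-region group comparisons under each normalization
    comp_rows = []
    norm_order = [n for n in ("absolute", "cer", "wm", "cgm") if n in tables]
    for norm in norm_order:
        tab = tables[norm].sort_values("subject_id")
        tgroups = tab["group"].to_numpy()
        for region in regions:
            vals = tab[region].to_numpy(float)
            row = {"region": region, "normalization": norm}
            for g in group_names:
                gv = vals[tgroups == g]
                row[f"mean_{g}"] = gv.mean()
                row[f"sd_{g}"] = gv.std(ddof=1)
            row["anova_F"], row["anova_p"] = one_way_anova(vals, tgroups)
            dp = dunnett_test(
                {g: vals[tgroups == g] for g in patient_groups},
                vals[tgroups == control],
            )
            for g in patient_groups:
                row[f"p_{g}"] = dp[g]
                row[f"d_{g}"] = cohens_d(vals[tgroups == g], vals[tgroups == control])
                row[f"significant_{g}"] = bool((row["anova_p"] < alpha) and (dp[g] < alpha))
            comp_rows.append(row)
    group_comparisons = pd.DataFrame(comp_rows)

    # (c) CV per lobe (bilateral pooled, groups pooled)
    cv_rows = []
    for lobe in mapping.lobes:
        row = {"lobe": lobe}
        for norm in norm_order:
            tab = tables[norm]
            pooled = np.concatenate(
                [tab[f"{lobe}_{h}"].to_numpy(float) for h in mapping.hemispheres]
            )
            row[f"cv_{norm}"] = coefficient_of_variation(pooled)
        cv_rows.append(row)
    cv_table = pd.DataFrame(cv_rows)

    # (d) variance components over the normalized tables
    vc_rows = []
    norm_only = [n for n in norm_order if n != "absolute"]
    if len(norm_only) >= 2:
        for region in regions:
            frames = []
            for norm in norm_only:
                tab = tables[norm]
                frames.append(
                    pd.DataFrame(
                        {"value": tab[region].to_numpy(float), "diagnosis": tab["group"], "normalization": norm}
                    )
                )
            long = pd.concat(frames, ignore_index=True)
            vc = variance_components(long)
            props = vc.proportions
            vc_rows.append(
                {
                    "region": region,
                    "var_diagnosis": vc.var_diagnosis,
                    "var_normalization": vc.var_normalization,
                    "var_residual": vc.var_residual,
                    "prop_diagnosis": props["diagnosis"],
                    "prop_normalization": props["normalization"],
                    "prop_residual": props["residual"],
                }
            )
    variance_table = pd.DataFrame(vc_rows)

    return {
        "bias_check": bias_check,
        "group_comparisons": group_comparisons,
        "cv_table": cv_table,
        "variance_components": variance_table,
    }
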