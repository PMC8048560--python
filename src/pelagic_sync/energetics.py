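"""Fish energetics: energy density, total energy, and annual models.

Juvenile herring energy density (kJ g^-1 wet mass) is estimated from
proximate composition as

    ED = 0.103 * C:N + 32.6 * (dry mass / wet mass) - 2.902

with C:N the carbon-to-nitrogen atomic ratio; total energy is ED times
body mass on an explicitly stated basis (wet for herring, dry for
sand lance calorimetry).  Annual energy levels are estimated either by
one-way ANOVA with Tukey HSD grouping letters, or — for unbalanced
designs — by a linear mixed model on log total energy with a fixed
year effect and a random intercept for site nested in year, reporting
back-transformed least-squares means with 95% CIs and marginal /
conditional R².
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger(__name__)

ED_CN_COEF = 0.103
ED_DRYWET_COEF = 32.6
ED_INTERCEPT = -2.902

HERRING_LENGTH_RANGE = (55.0, 115.0)  # fork length, mm

__all__ = [
    "herring_energy_density",
    "total_energy",
    "filter_herring_lengths",
    "annual_group_comparison",
    "annual_energy_model",
    "mean_comparison_ttest",
    "AnnualEnergyEstimate",
]


def herring_energy_density(cn_atomic_ratio, dry_wet):
    """Energy density (kJ g^-1 wet mass) from C:N ratio and dry/wet mass
    ratio.  Vectorized; non-positive results are returned as NaN with a
    warning (they indicate a data error upstream)."""
    cn = np.asarray(cn_atomic_ratio, dtype=float)
    dw = np.asarray(dry_wet, dtype=float)
    if np.any(cn <= 0):
        raise ValueError("C:N atomic ratio must be positive")
    if np.any((dw <= 0) | (dw > 1)):
        raise ValueError("dry/wet ratio must lie in (0, 1]")
    ed = ED_CN_COEF * cn + ED_DRYWET_COEF * dw + ED_INTERCEPT
    bad = ed <= 0
    if np.any(bad):
        logger.warning("%d records with non-positive energy density flagged NaN", int(np.sum(bad)))
        ed = np.where(bad, np.nan, ed)
    return ed if ed.ndim else float(ed)


def total_energy(ed, mass, basis: str):
    """Total energy (kJ) = energy density × body mass.

    ``basis`` must be ``"wet"`` or ``"dry"`` and must match the basis of
    both ED and mass — requiring it prevents silent unit mixing between
    the wet-mass (herring C:N) and dry-mass (calorimetry) conventions.
    """
    if basis not in ("wet", "dry"):
        raise ValueError("basis must be 'wet' or 'dry'")
    ed = np.asarray(ed, dtype=float)
    mass = np.asarray(mass, dtype=float)
    if np.any(mass <= 0):
        raise ValueError("mass must be positive")
    te = ed * mass
    return te if te.ndim else float(te)


def filter_herring_lengths(
    records: pd.DataFrame, length_col: str = "fork_length_mm"
) -> pd.DataFrame:
    """Keep records inside the 55–115 mm juvenile fork-length window;
    out-of-range records are logged, never silently dropped."""
    lo, hi = HERRING_LENGTH_RANGE
    ok = records[length_col].between(lo, hi)
    n_out = int((~ok).sum())
    if n_out:
        logger.info("%d records outside %.0f–%.0f mm excluded", n_out, lo, hi)
    return records[ok]


def _tukey_letters(groups: list, reject: np.ndarray, pairs: list[tuple]) -> dict:
    """Compact letter display: groups not significantly different share
    a letter.  Greedy insertion over ascending group means."""
    differ = {frozenset(p) for p, r in zip(pairs, reject) if r}
    letters: dict = {g: "" for g in groups}
    clusters: list[set] = []
    for g in groups:
        placed = False
        for cl in clusters:
            if all(frozenset((g, h)) not in differ for h in cl):
                cl.add(g)
                placed = True
        if not placed:
            clusters.append({g})
    # second pass: try to absorb each group into later clusters too
    for g in groups:
        for cl in clusters:
            if g not in cl and all(frozenset((g, h)) not in differ for h in cl):
                cl.add(g)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for i, cl in enumerate(clusters):
        for g in cl:
            letters[g] += alphabet[i]
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def annual_group_comparison(
    records: pd.DataFrame, value_col: str = "total_energy_kj", year_col: str = "year",
    alpha: float = 0.05,
) -> dict:
    """One-way ANOVA of a response across years with Tukey HSD letters.

    Years with a single record are dropped with a warning.  Returns a
    dict with ``F, p, r2, df_between, df_within, tukey`` (a frame of
    pairwise comparisons) and ``letters`` mapping year → letter group.
    """
    counts = records.groupby(year_col)[value_col].count()
    singletons = counts[counts < 2].index
    if len(singletons):
        logger.warning("years with n=1 dropped: %s", list(singletons))
        records = records[~records[year_col].isin(singletons)]
    years = sorted(records[year_col].unique())
    if len(years) < 2:
        raise ValueError("need >= 2 years with >= 2 records each")
    groups = [records.loc[records[year_col] == y, value_col].to_numpy() for y in years]
    f_stat, p = stats.f_oneway(*groups)
    grand = records[value_col].mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_total = float(((records[value_col] - grand) ** 2).sum())
    r2 = ss_between / ss_total if ss_total > 0 else np.nan

    tk = pairwise_tukeyhsd(
        records[value_col].to_numpy(), records[year_col].astype(str).to_numpy(), alpha=alpha
    )
    tukey_df = pd.DataFrame(
        tk.summary().data[1:], columns=tk.summary().data[0]
    )
    pairs = [
        (row[0], row[1]) for row in tk.summary().data[1:]
    ]
    letters = _tukey_letters([str(y) for y in years], np.asarray(tk.reject), pairs)
    return {
        "F": float(f_stat),
        "p": float(p),
        "r2": float(r2),
        "df_between": len(years) - 1,
        "df_within": len(records) - len(years),
        "tukey": tukey_df,
        "letters": letters,
    }


@dataclass
class AnnualEnergyEstimate:
    year: int
    ls_mean_total_energy: float  # kJ, back-transformed
    ci_lo: float
    ci_hi: float
    n: int
    model_r2_marginal: float
    model_r2_conditional: float
    random_effect_dropped: bool = False


def annual_energy_model(
    records: pd.DataFrame,
    value_col: str = "total_energy_kj",
    year_col: str = "year",
    site_col: str = "site",
) -> list[AnnualEnergyEstimate]:
    """Mixed model for annual energy: log(TE) ~ year + (1 | site-in-year).

    Fit by REML.  Least-squares means per year are back-transformed by
    exponentiation (no bias correction), with normal-theory 95% CIs
    transformed the same way.  Marginal R² (fixed effects only) and
    conditional R² (fixed + random) follow the variance-components
    decomposition var_f / (var_f + var_re + var_resid).  A singular
    random-effect variance triggers a refit without the random term,
    flagged on the output.
    """
    df = records.copy()
    if np.any(df[value_col] <= 0):
        raise ValueError("total energy must be positive for the log model")
    df["_logte"] = np.log(df[value_col].astype(float))
    df["_year"] = df[year_col].astype(int)
    df["_grp"] = df[year_col].astype(str) + ":" + df[site_col].astype(str)

    dropped = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm("_logte ~ C(_year)", df, groups=df["_grp"])
        try:
            fit = md.fit(reml=True)
            re_var = float(fit.cov_re.iloc[0, 0])
            singular = not np.isfinite(re_var) or re_var < 1e-10
        except Exception:
            singular = True
            fit = None
    if singular:
        logger.warning("singular random-effect variance; refitting fixed-effects only")
        dropped = True
        fit = smf.ols("_logte ~ C(_year)", df).fit()
        re_var = 0.0
        resid_var = float(fit.scale)
        params = fit.params
        cov = fit.cov_params()
    else:
        resid_var = float(fit.scale)
        params = fit.fe_params
        cov = fit.cov_params().loc[params.index, params.index]

    years = sorted(df["_year"].unique())
    # fixed-effect design rows for each year's LS mean (treatment coding)
    names = list(params.index)
    Xrows = {}
    for y in years:
        row = np.zeros(len(names))
        row[names.index("Intercept")] = 1.0
        nm = f"C(_year)[T.{y}]"
        if nm in names:
            row[names.index(nm)] = 1.0
        Xrows[y] = row
    # fixed-effect predictions for all observations, for variance decomposition
    obs_rows = np.stack([Xrows[y] for y in df["_year"]])
    fixed_pred = obs_rows @ params.to_numpy()
    var_f = float(np.var(fixed_pred, ddof=0))
    denom = var_f + re_var + resid_var
    r2_marg = var_f / denom
    r2_cond = (var_f + re_var) / denom

    out = []
    for y in years:
        row = Xrows[y]
        est = float(row @ params.to_numpy())
        se = float(np.sqrt(row @ cov.to_numpy() @ row))
        lo, hi = est - 1.96 * se, est + 1.96 * se
        out.append(
            AnnualEnergyEstimate(
                year=int(y),
                ls_mean_total_energy=float(np.exp(est)),
                ci_lo=float(np.exp(lo)),
                ci_hi=float(np.exp(hi)),
                n=int((df["_year"] == y).sum()),
                model_r2_marginal=r2_marg,
                model_r2_conditional=r2_cond,
                random_effect_dropped=dropped,
            )
        )
    return out


def mean_comparison_ttest(
    group_a: np.ndarray, group_b: np.ndarray, pooled: bool = False
) -> tuple[float, float, float]:
    """Two-sample t-test on lengths (Welch by default).

    Returns ``(t, df, p)``; ``pooled=True`` gives the equal-variance
    test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 in each group")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=pooled)
    return float(res.statistic), float(res.df), float(res.pvalue)
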