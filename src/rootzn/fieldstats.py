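"""Group summaries, ANOVA-protected LSD, correlations, and density folds."""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import RootznError

__all__ = [
    "LsdResult",
    "group_summary",
    "anova_lsd",
    "pearson_matrix",
    "density_folds",
    "percent_fine_roots",
    "significance_code",
]


@dataclass(frozen=True)
class LsdResult:
    """One-way ANOVA with Fisher-protected LSD pairwise comparisons.

    ``pairwise_significant`` is empty whenever the ANOVA F-test is not
    significant at alpha (the protection step); ``lsd_05`` is the least
    significant difference for the (harmonic-mean) per-group sample size.
    """

    timepoint: float | None
    f_stat: float
    f_pvalue: float
    lsd_05: float
    alpha: float
    pairwise_significant: frozenset[tuple[str, str]] = field(default_factory=frozenset)
    protected: bool = True


def group_summary(df: pd.DataFrame, by: list[str], values: list[str]) -> pd.DataFrame:
    """Mean ± SE and n per cell, tidy long format.

    Empty cells simply do not appear (missing, never zero); NaN observations
    are dropped per trait.
    """
    records = []
    for keys, cell in df.groupby(by, dropna=False, observed=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        for trait in values:
            x = cell[trait].dropna().to_numpy(dtype=float)
            if x.size == 0:
                continue
            se = float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
            records.append(
                dict(zip(by, keys))
                | {"trait": trait, "mean": float(x.mean()), "se": se, "n": int(x.size)}
            )
    return pd.DataFrame.from_records(records)


def anova_lsd(
    values,
    groups,
    alpha: float = 0.05,
    timepoint: float | None = None,
) -> LsdResult:
    """One-way ANOVA by group with protected-LSD pairwise flags.

    The pairwise comparisons are only performed when the F-test is
    significant at *alpha*; otherwise the significant set is empty and the
    result is marked protected.  Unbalanced designs use the exact pairwise
    LSD ``t·sqrt(MSE·(1/ni + 1/nj))``; the reported ``lsd_05`` uses the
    harmonic-mean group size.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if v.shape != g.shape:
        raise ValueError("values and groups must align")
    labels = [str(x) for x in pd.unique(g)]
    if len(labels) < 2:
        raise RootznError("need at least 2 groups for ANOVA")
    cells = {lab: v[g == lab] for lab in labels}
    ns = {lab: len(x) for lab, x in cells.items()}
    if min(ns.values()) < 2:
        raise RootznError("need at least 2 replicates per group")
    n_total = len(v)
    k = len(labels)
    df_err = n_total - k
    if df_err <= 0:
        raise RootznError("zero error degrees of freedom")

    grand = v.mean()
    ss_between = sum(len(x) * (x.mean() - grand) ** 2 for x in cells.values())
    ss_within = sum(((x - x.mean()) ** 2).sum() for x in cells.values())
    ms_between = ss_between / (k - 1)
    mse = ss_within / df_err

    if mse == 0:
        # all replicates identical within groups; F is undefined at equal
        # means and infinite otherwise
        if ss_between == 0:
            f_stat, f_pvalue = float("nan"), 1.0
        else:
            f_stat, f_pvalue = float("inf"), 0.0
    else:
        f_stat = ms_between / mse
        f_pvalue = float(stats.f.sf(f_stat, k - 1, df_err))

    t_crit = float(stats.t.ppf(1 - alpha / 2, df_err))
    n_harm = k / sum(1.0 / n for n in ns.values())
    lsd = t_crit * np.sqrt(2.0 * mse / n_harm)

    significant: set[tuple[str, str]] = set()
    f_significant = f_pvalue <= alpha
    if f_significant:
        for a, b in itertools.combinations(labels, 2):
            lsd_ab = t_crit * np.sqrt(mse * (1.0 / ns[a] + 1.0 / ns[b]))
            if abs(cells[a].mean() - cells[b].mean()) > lsd_ab:
                significant.add(tuple(sorted((a, b))))

    return LsdResult(
        timepoint=timepoint,
        f_stat=float(f_stat),
        f_pvalue=f_pvalue,
        lsd_05=float(lsd),
        alpha=alpha,
        pairwise_significant=frozenset(significant),
        protected=not f_significant,
    )


def significance_code(p: float) -> str:
    """ns / * / ** annotation at the 0.05 and 0.01 levels."""
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def pearson_matrix(df: pd.DataFrame, min_rows: int = 3) -> pd.DataFrame:
    """Pairwise Pearson correlations; zero-variance traits give NaN entries."""
    num = df.select_dtypes(include=[np.number])
    if len(num.dropna()) < min_rows:
        raise RootznError(f"need at least {min_rows} complete rows")
    zero_var = [c for c in num.columns if num[c].dropna().nunique() <= 1]
    if zero_var:
        warnings.warn(
            f"zero-variance traits, correlations undefined: {zero_var}", stacklevel=2
        )
    corr = num.corr(method="pearson", min_periods=min_rows)
    np.fill_diagonal(corr.values, 1.0)
    for c in zero_var:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
        corr.loc[c, c] = np.nan
    return corr


def density_folds(
    df: pd.DataFrame,
    uptake_col: str = "net_zn_uptake_ug",
    root_dw_col: str = "root_dw_mg",
) -> pd.DataFrame:
    """Per-plant and per-hill fold-changes across planting densities.

    Folds are relative to single-plant hills; the root-efficiency fold
    (uptake per unit root dry weight) is the ratio of the uptake fold to
    the root-DW fold.  ``*_display`` columns round to the nearest integer
    as the published narration does.
    """
    if "hill_density" not in df.columns:
        raise RootznError("density data must carry a hill_density column")
    means = (
        df.groupby("hill_density")[[uptake_col, root_dw_col]].mean().sort_index()
    )
    if 1 not in means.index:
        raise RootznError("baseline density 1 missing; folds undefined")
    base_u = means.loc[1, uptake_col]
    base_r = means.loc[1, root_dw_col]
    if base_u == 0 or base_r == 0:
        raise RootznError("baseline mean is zero; folds undefined")
    out = pd.DataFrame(index=means.index)
    out["uptake_per_plant"] = means[uptake_col]
    out["root_dw_per_plant"] = means[root_dw_col]
    out["uptake_per_hill"] = means[uptake_col] * means.index
    out["uptake_fold"] = means[uptake_col] / base_u
    out["root_dw_fold"] = means[root_dw_col] / base_r
    out["efficiency_fold"] = out["uptake_fold"] / out["root_dw_fold"]
    for col in ("uptake_fold", "root_dw_fold", "efficiency_fold"):
        out[col + "_display"] = out[col].round().astype(int)
    return out


def percent_fine_roots(fine, mid, coarse):
    """Fraction of root length in the fine (<0.15 mm) diameter class.

    Vectorized; zero total length yields NaN with a warning.
    """
    fine = np.asarray(fine, dtype=float)
    mid = np.asarray(mid, dtype=float)
    coarse = np.asarray(coarse, dtype=float)
    total = fine + mid + coarse
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(total > 0, fine / total, np.nan)
    if np.any(total <= 0):
        warnings.warn("zero total root length: fraction undefined", stacklevel=2)
    return float(frac) if frac.ndim == 0 else frac
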