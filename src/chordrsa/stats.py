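"""Group-level inference: repeated-measures ANCOVA with a subject-level
covariate, covariate-adjusted contrasts with Bonferroni control,
one-sample t tests against zero, and Freedman-Lane permutation p values.

The mixed ANCOVA uses the classical univariate split-plot formulation.
Within-subject effects are tested on orthonormal contrast scores of the
cell means: for each within effect the per-subject score vectors are
regressed on group (sum-coded) and the de-meaned covariate, and the
effect / error sums of squares come from Type-III model comparisons in
that stratum.  The covariate therefore consumes one denominator degree
of freedom in every stratum (SPSS/JASP rmANCOVA convention); with
``covariate=None`` the procedure reduces exactly to the repeated-
measures ANOVA.  No sphericity correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert


# ---------------------------------------------------------------- helpers

def _sum_code(groups: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Sum-to-zero (deviation) coding; returns (N, g-1) matrix."""
    levels = sorted(groups.unique())
    g = len(levels)
    X = np.zeros((len(groups), g - 1))
    for j, lev in enumerate(levels[:-1]):
        X[:, j] = (groups == lev).astype(float) - (groups == levels[-1]).astype(float)
    return X, levels


def _rss(X: np.ndarray, Y: np.ndarray) -> float:
    """Residual sum of squares of OLS of (possibly multi-column) Y on X."""
    if X.shape[1] == 0:
        return float((Y**2).sum())
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ beta
    return float((R**2).sum())


# ---------------------------------------------------------------- results

@dataclass
class AncovaFit:
    effects: pd.DataFrame  # effect, F, df1, df2, p, pes
    group_levels: list[str]
    subject_means: pd.DataFrame  # subject, group, covariate?, mean_dv
    dv: str
    covariate: str | None
    between: str = "group"

    def effect(self, name: str) -> pd.Series:
        sub = self.effects[self.effects["effect"] == name]
        if sub.empty:
            raise KeyError(f"no effect named {name!r}; have {list(self.effects['effect'])}")
        return sub.iloc[0]


def format_effect(row: pd.Series) -> str:
    """Pretty-print one effect in `F(df1, df2) = ...; p = ...; eta_p = ...` style."""
    return (
        f"F({row['df1']:.0f}, {row['df2']:.0f}) = {row['F']:.2f}; "
        f"p = {row['p']:.3f}; eta_p = {row['pes']:.2f}"
    )


# ---------------------------------------------------------------- rmANCOVA

def rm_ancova(
    table: pd.DataFrame,
    dv: str,
    subject: str = "subject",
    between: str = "group",
    within: list[str] | None = None,
    covariate: str | None = None,
) -> AncovaFit:
    """Mixed-design ANCOVA: one between-subject factor, 0-2 within-
    subject factors, and an optional subject-level covariate entered
    additively (de-meaned internally).

    Returns all main effects and interactions with F, dfs, p and
    partial eta squared (SS_effect / (SS_effect + SS_error), per
    stratum).  Requires a balanced within design (every subject has
    every cell exactly once); raises naming offending subjects.
    """
    within = list(within or [])
    df = table.copy()
    if df[dv].std() == 0:
        raise ValueError("dependent variable has zero variance")

    # subject-level attributes must be constant per subject
    subj_info = df.groupby(subject, observed=True).agg(
        {between: "nunique", **({covariate: "nunique"} if covariate else {})}
    )
    if (subj_info[between] > 1).any():
        bad = list(subj_info.index[subj_info[between] > 1])
        raise ValueError(f"subjects in more than one group: {bad}")

    if within:
        cells = df.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean", observed=True)
        counts = df.pivot_table(index=subject, columns=within, values=dv, aggfunc="size", observed=True)
        bad = list(cells.index[cells.isna().any(axis=1) | counts.isna().any(axis=1)])
        if bad:
            raise ValueError(f"unbalanced within-subject design; offending subjects: {bad}")
        level_sets = [sorted(df[w].unique()) for w in within]
        # order columns canonically
        if len(within) == 1:
            cells = cells[level_sets[0]]
        else:
            cells = cells[pd.MultiIndex.from_product(level_sets)]
        Y = cells.to_numpy(dtype=float)  # (N, prod levels)
    else:
        cells = df.groupby(subject, observed=True)[dv].mean().to_frame("m")
        level_sets = []
        Y = cells.to_numpy(dtype=float)

    subj_order = cells.index
    per_subj = df.drop_duplicates(subject).set_index(subject).loc[subj_order]
    groups = per_subj[between]
    G, levels = _sum_code(groups)
    g = len(levels)
    N = len(subj_order)
    cov_cols = 0
    if covariate is not None:
        a = per_subj[covariate].to_numpy(dtype=float)
        a = (a - a.mean()).reshape(-1, 1)
        cov_cols = 1
    else:
        a = np.zeros((N, 0))

    ones = np.ones((N, 1))
    X_full = np.hstack([ones, G, a])
    if N - g - cov_cols <= 0:
        raise ValueError("not enough subjects for the model")

    rows = []

    def add_stratum(Z: np.ndarray, suffix: str) -> None:
        """Test intercept (within main effect), group, covariate in the
        stratum whose responses are the contrast scores Z (N x q)."""
        q = Z.shape[1]
        rss_full = _rss(X_full, Z)
        df_err = q * (N - g - cov_cols)
        terms = []
        if suffix:  # within stratum: intercept tests the within main effect
            terms.append((suffix, [0], q))
            terms.append((f"{between}:{suffix}", list(range(1, g)), q * (g - 1)))
            if covariate is not None:
                terms.append((f"{covariate}:{suffix}", [g], q))
        else:  # between stratum
            terms.append((between, list(range(1, g)), g - 1))
            if covariate is not None:
                terms.append((covariate, [g], 1))
        for name, cols, df1 in terms:
            keep = [j for j in range(X_full.shape[1]) if j not in cols]
            ss_eff = _rss(X_full[:, keep], Z) - rss_full
            F = (ss_eff / df1) / (rss_full / df_err)
            p = float(sps.f.sf(F, df1, df_err))
            rows.append(
                {
                    "effect": name,
                    "F": float(F),
                    "df1": df1,
                    "df2": df_err,
                    "p": p,
                    "pes": float(ss_eff / (ss_eff + rss_full)),
                }
            )

    # between stratum: subject means
    add_stratum(Y.mean(axis=1, keepdims=True), "")

    # within strata: orthonormal contrast scores per effect
    if within:
        contrast_per_factor = [np.asarray(helmert(len(ls)), dtype=float) for ls in level_sets]
        eye_per_factor = [np.full((1, len(ls)), 1.0 / np.sqrt(len(ls))) for ls in level_sets]
        n_fac = len(within)
        for r in range(1, n_fac + 1):
            for idx in combinations(range(n_fac), r):
                mats = [
                    contrast_per_factor[i] if i in idx else eye_per_factor[i]
                    for i in range(n_fac)
                ]
                C = mats[0]
                for m in mats[1:]:
                    C = np.kron(C, m)
                name = ":".join(within[i] for i in idx)
                add_stratum(Y @ C.T, name)

    effects = pd.DataFrame(rows)
    subject_means = pd.DataFrame(
        {
            "subject": subj_order,
            between: groups.to_numpy(),
            "mean_dv": Y.mean(axis=1),
        }
    )
    if covariate is not None:
        subject_means[covariate] = per_subj[covariate].to_numpy(dtype=float)
    return AncovaFit(
        effects=effects,
        group_levels=levels,
        subject_means=subject_means,
        dv=dv,
        covariate=covariate,
        between=between,
    )


# ---------------------------------------------------------------- contrasts

def bonferroni_alpha(n_comparisons: int, alpha: float = 0.05) -> float:
    """Adjusted significance level alpha / k."""
    if n_comparisons < 1:
        raise ValueError("need at least one comparison")
    return alpha / n_comparisons


def adjusted_contrasts(
    fit: AncovaFit,
    pairs: list[tuple[str, str]] | None = None,
    correction: str = "bonferroni",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Covariate-adjusted group-mean differences from the between-
    subject stratum: estimate, SE, t, df, raw p and (per the reporting
    convention) the Bonferroni-adjusted alpha alongside, rather than
    adjusted p values."""
    sm = fit.subject_means
    levels = fit.group_levels
    if pairs is None:
        pairs = list(combinations(levels, 2))
    for a, b in pairs:
        if a not in levels or b not in levels:
            raise KeyError(f"unknown group level in pair ({a}, {b})")

    y = sm["mean_dv"].to_numpy(dtype=float)
    G = np.zeros((len(sm), len(levels)))
    for j, lev in enumerate(levels):
        G[:, j] = (sm[fit.between] == lev).astype(float)
    X = G
    if fit.covariate is not None:
        cov = sm[fit.covariate].to_numpy(dtype=float)
        X = np.hstack([G, (cov - cov.mean()).reshape(-1, 1)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_err = len(y) - X.shape[1]
    if df_err <= 0:
        raise ValueError("not enough subjects for contrasts")
    s2 = float(resid @ resid) / df_err
    XtX_inv = np.linalg.pinv(X.T @ X)

    if correction == "bonferroni":
        adj_alpha = bonferroni_alpha(len(pairs), alpha)
    elif correction == "none":
        adj_alpha = alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")

    rows = []
    for a, b in pairs:
        ell = np.zeros(X.shape[1])
        ell[levels.index(a)] = 1.0
        ell[levels.index(b)] = -1.0
        est = float(ell @ beta)
        se = float(np.sqrt(s2 * ell @ XtX_inv @ ell))
        t = est / se
        p = float(2 * sps.t.sf(abs(t), df_err))
        rows.append(
            {
                "contrast": f"{a} - {b}",
                "estimate": est,
                "se": se,
                "t": t,
                "df": df_err,
                "p": p,
                "adjusted_alpha": adj_alpha,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- t tests

def one_sample_vs_zero(values) -> tuple[float, int, float]:
    """Two-tailed one-sample t test against zero: (t, df, p)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if x.std(ddof=1) == 0:
        raise ValueError("zero variance")
    res = sps.ttest_1samp(x, 0.0)
    return float(res.statistic), int(x.size - 1), float(res.pvalue)


# ------------------------------------------------- Freedman-Lane permutation

@dataclass
class PermutationResult:
    f_obs: float
    p: float
    n_perm: int
    df1: int
    df2: int
    f_perm: np.ndarray = field(repr=False, default=None)


def _design_columns(table: pd.DataFrame, names: list[str]) -> np.ndarray:
    cols = []
    for name in names:
        col = table[name]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            X, _ = _sum_code(col)
            cols.append(X)
        else:
            cols.append(col.to_numpy(dtype=float).reshape(-1, 1))
    if not cols:
        return np.zeros((len(table), 0))
    return np.hstack(cols)


def freedman_lane_permutation(
    table: pd.DataFrame,
    dv: str,
    effect: str,
    nuisance: list[str] | None = None,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> PermutationResult:
    """Freedman-Lane permutation p value for ``effect`` in a fixed-
    effects linear model with nuisance covariates.

    Algorithm: fit the nuisance-only model (intercept + nuisance),
    permute its residuals, add back the nuisance fit, recompute the
    effect's F on every permuted dataset;
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = table[dv].to_numpy(dtype=float)
    n = len(y)
    Xe = _design_columns(table, [effect])
    Xn = np.hstack([np.ones((n, 1)), _design_columns(table, list(nuisance or []))])
    Xf = np.hstack([Xn, Xe])
    q = Xe.shape[1]
    df2 = n - np.linalg.matrix_rank(Xf)
    if df2 <= 0:
        raise ValueError("no residual degrees of freedom")

    # projection-based RSS for speed over many permutations
    Qn, _ = np.linalg.qr(Xn)
    Qf, _ = np.linalg.qr(Xf)

    def f_stat(Y: np.ndarray) -> np.ndarray:
        tot = (Y**2).sum(axis=0)
        rss_n = tot - ((Qn.T @ Y) ** 2).sum(axis=0)
        rss_f = tot - ((Qf.T @ Y) ** 2).sum(axis=0)
        return ((rss_n - rss_f) / q) / (rss_f / df2)

    f_obs = float(f_stat(y.reshape(-1, 1))[0])

    fitted = Qn @ (Qn.T @ y)
    resid = y - fitted
    perms = np.empty((n, n_perm))
    for b in range(n_perm):
        perms[:, b] = resid[rng.permutation(n)]
    Ystar = fitted.reshape(-1, 1) + perms
    f_perm = f_stat(Ystar)
    p = float((1 + np.sum(f_perm >= f_obs)) / (1 + n_perm))
    return PermutationResult(f_obs=f_obs, p=p, n_perm=n_perm, df1=q, df2=df2, f_perm=f_perm)
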