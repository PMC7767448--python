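"""Repeated-measures ANOVA with Greenhouse-Geisser correction, and Kendall
tau correlation tables.

The ANOVA is the classical univariate mixed design: any number of crossed
within-subject factors, an optional between-subject factor, subjects nested
in groups, balanced complete data (one observation per subject per within
cell).  Each within effect is evaluated through an orthonormal contrast of
the within-cell means; the error stratum is the effect-by-subject
interaction.  Sphericity is handled by the Greenhouse-Geisser epsilon
computed from the contrast-space error covariance, with the usual floor of
1/df; effects with a single numerator df have epsilon 1 by construction.
Effect size is partial eta squared, SS_effect / (SS_effect + SS_error).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert

__all__ = ["DesignError", "AnovaResult", "CorrelationResult",
           "rm_anova_gg", "kendall_tau_matrix"]


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class AnovaResult:
    """Per-effect F, dfs, p, partial eta squared, and GG-corrected values.

    ``table`` is indexed by effect name with columns F, df1, df2, p,
    partial_eta_sq, gg_epsilon, df1_gg, df2_gg, p_gg.  For effects with one
    numerator df the corrected values equal the uncorrected ones.
    """

    table: pd.DataFrame

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]


@dataclass(frozen=True)
class CorrelationResult:
    """Kendall tau-b per (variable, psychometric) pair with two-sided p."""

    table: pd.DataFrame


def _orth_contrast(levels: int) -> np.ndarray:
    """levels x (levels-1) orthonormal columns orthogonal to the mean."""
    return helmert(levels, full=False).T


def _pivot_balanced(data, dv, within, subject):
    levels = {f: list(pd.unique(np.sort(data[f].unique()))) for f in within}
    cells = list(itertools.product(*(levels[f] for f in within)))
    subjects = list(pd.unique(np.sort(data[subject].unique())))
    idx = data.set_index([subject] + within)[dv]
    if idx.index.has_duplicates:
        dup = idx.index[idx.index.duplicated()][0]
        raise DesignError(f"more than one observation in cell {dup}")
    Y = np.empty((len(subjects), len(cells)))
    for i, s in enumerate(subjects):
        for j, c in enumerate(cells):
            key = (s,) + c
            try:
                Y[i, j] = idx.loc[key]
            except KeyError:
                raise DesignError(f"missing cell: subject {s!r}, "
                                  + ", ".join(f"{f}={v!r}" for f, v in zip(within, c)))
    if not np.isfinite(Y).all():
        raise DesignError("design contains non-finite values")
    return Y, subjects, levels, cells


def rm_anova_gg(data: pd.DataFrame, dv: str, within, subject: str,
                between: str | None = None) -> AnovaResult:
    """Univariate mixed repeated-measures ANOVA with GG correction.

    Parameters
    ----------
    data : long-format DataFrame, one row per subject per within-cell.
    dv : name of the dependent-variable column.
    within : list of within-subject factor columns.
    subject : subject id column.
    between : optional between-subject factor column (constant per subject).

    Returns
    -------
    AnovaResult with one row per effect: each within subset, its interaction
    with the between factor, and the between main effect.
    """
    within = list(within)
    if not within:
        raise DesignError("need at least one within factor")
    Y, subjects, levels, _ = _pivot_balanced(data, dv, within, subject)
    N = len(subjects)

    if between is not None:
        per_subj = data.groupby(subject)[between].nunique()
        if (per_subj > 1).any():
            bad = per_subj[per_subj > 1].index[0]
            raise DesignError(f"subject {bad!r} appears in several {between} levels")
        grp_of = data.drop_duplicates(subject).set_index(subject)[between]
        grp_levels = list(pd.unique(np.sort(grp_of.unique())))
        g = len(grp_levels)
        X = np.zeros((N, g))
        for i, s in enumerate(subjects):
            X[i, grp_levels.index(grp_of.loc[s])] = 1.0
    else:
        g = 1
        X = np.ones((N, 1))
    if N <= g:
        raise DesignError("need more subjects than groups")

    XtX_inv = np.linalg.inv(X.T @ X)
    proj = X @ XtX_inv @ X.T

    def _ols(Z):
        B = XtX_inv @ X.T @ Z
        E = Z - proj @ Z
        return B, E

    rows = []

    def add_row(name, ss_eff, df1, ss_err, df2, eps, q):
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        F = ms_eff / ms_err if ms_err > 0 else np.inf
        p = float(sps.f.sf(F, df1, df2))
        df1_gg, df2_gg = df1 * eps, df2 * eps
        p_gg = float(sps.f.sf(F, df1_gg, df2_gg)) if q > 1 else p
        rows.append({
            "effect": name, "F": F, "df1": df1, "df2": df2, "p": p,
            "partial_eta_sq": ss_eff / (ss_eff + ss_err) if ss_eff + ss_err > 0 else 0.0,
            "gg_epsilon": eps, "df1_gg": df1_gg, "df2_gg": df2_gg, "p_gg": p_gg,
        })

    # between main effect (on within-cell means)
    if between is not None:
        p_cells = Y.shape[1]
        Z = Y @ (np.ones((p_cells, 1)) / np.sqrt(p_cells))
        B, E = _ols(Z)
        Cb = _orth_contrast(g)
        mid = np.linalg.inv(Cb.T @ XtX_inv @ Cb)
        ss_b = float(np.sum((Cb.T @ B) * (mid @ (Cb.T @ B))))
        ss_e = float(np.sum(E ** 2))
        add_row(between, ss_b, g - 1, ss_e, N - g, 1.0, 1)

    # within effects and their between interactions
    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(within, r):
            M = np.ones((1, 1))
            for f in within:
                L = len(levels[f])
                Mf = _orth_contrast(L) if f in combo else np.ones((L, 1)) / np.sqrt(L)
                M = np.kron(M, Mf)
            q = M.shape[1]
            Z = Y @ M
            B, E = _ols(Z)
            S = E.T @ E
            ss_err = float(np.trace(S))
            df_err = q * (N - g)
            tr, tr2 = float(np.trace(S)), float(np.trace(S @ S))
            eps = 1.0 if q == 1 or tr2 == 0 else min(1.0, max(tr * tr / (q * tr2), 1.0 / q))
            name = " * ".join(combo)
            # within main effect: unweighted grand mean over groups
            c = np.full((g, 1), 1.0 / g)
            denom = float((c.T @ XtX_inv @ c).item())
            val = (c.T @ B).ravel()
            ss_eff = float(np.sum(val ** 2) / denom)
            add_row(name, ss_eff, q, ss_err, df_err, eps, q)
            if between is not None:
                Cb = _orth_contrast(g)
                mid = np.linalg.inv(Cb.T @ XtX_inv @ Cb)
                ss_int = float(np.sum((Cb.T @ B) * (mid @ (Cb.T @ B))))
                add_row(f"{name} * {between}", ss_int, q * (g - 1), ss_err, df_err, eps, q)

    table = pd.DataFrame(rows).set_index("effect")
    return AnovaResult(table=table)


def kendall_tau_matrix(weights: pd.DataFrame, psychometrics: pd.DataFrame,
                       fdr: bool = False) -> CorrelationResult:
    """Kendall tau-b between each weight variable and each psychometric.

    Rows are aligned on the participant index; constant variables yield an
    ``undefined`` flag rather than a silent zero.  With ``fdr=True`` a
    Benjamini-Hochberg adjusted p column is appended (off by default).
    """
    common = weights.index.intersection(psychometrics.index)
    if len(common) < 3:
        raise DesignError("need at least 3 aligned participants")
    w = weights.loc[common]
    p = psychometrics.loc[common]
    num_p = p.select_dtypes(include=[np.number])
    rows = []
    for wv in w.columns:
        if not np.issubdtype(w[wv].dtype, np.number):
            continue
        for pv in num_p.columns:
            x, y = w[wv].to_numpy(float), num_p[pv].to_numpy(float)
            undefined = np.allclose(x, x[0]) or np.allclose(y, y[0])
            if undefined:
                tau, pval = np.nan, np.nan
            else:
                res = sps.kendalltau(x, y, variant="b")
                tau, pval = float(res.statistic), float(res.pvalue)
            rows.append({"weight_var": wv, "psych_var": pv, "tau": tau,
                         "p": pval, "n": len(common), "undefined": undefined})
    table = pd.DataFrame(rows)
    if fdr:
        ok = table["p"].notna()
        adj = np.full(len(table), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = sps.false_discovery_control(table.loc[ok, "p"], method="bh")
        table["p_fdr_bh"] = adj
    return CorrelationResult(table=table)
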