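"""Univariate mixed (split-plot) ANOVA for balanced repeated-measures designs.

Supports any number of fully-crossed within-subject factors and one
optional between-subjects grouping factor, on a complete balanced design
(every subject measured in every within cell; group sizes may differ).

The implementation follows the classical multivariate-transform approach:
for every within effect an orthonormal contrast basis (Kronecker product of
per-factor Helmert bases) maps the subject x cell response matrix onto
contrast variables; univariate sums of squares are traces over those
variables, with the effect's own stratum error (effect x subject within
group).  Hypothesis sums of squares use unweighted (Type III) group means,
so unequal group sizes do not bias within-effect tests.

Sphericity is handled with the Greenhouse-Geisser epsilon-hat estimated
from the pooled within-group covariance of the contrast variables; the
adjusted degrees of freedom are ``eps * df``.  Strata with a single
contrast variable (two-level factors) have eps = 1 by construction.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = ["rm_anova_gg", "bonferroni_posthoc", "DesignError"]


class DesignError(ValueError):
    """Raised when the design is incomplete or malformed."""


def _pivot(data: pd.DataFrame, dv: str, within: list[str], subject: str):
    """Subject x within-cell wide matrix, cells in full-product order."""
    if within:
        levels = [sorted(data[w].unique()) for w in within]
        if len(within) == 1:
            cells = pd.Index(levels[0], name=within[0])
        else:
            cells = pd.MultiIndex.from_product(levels, names=within)
        wide = data.pivot_table(index=subject, columns=within, values=dv,
                                aggfunc="mean")
        wide = wide.reindex(columns=cells)
        if wide.isna().any().any():
            i, j = np.argwhere(wide.isna().to_numpy())[0]
            raise DesignError(
                f"missing cell: subject {wide.index[i]!r}, "
                f"condition {wide.columns[j]!r}")
        return wide, levels
    grouped = data.groupby(subject)[dv].mean().to_frame("value")
    return grouped, []


def _helmert_full(n: int) -> np.ndarray:
    h = linalg.helmert(n, full=True)
    # scipy returns the orthonormal matrix whose first row is 1/sqrt(n)
    return h


def _effect_matrix(bases: list[np.ndarray], members: tuple[int, ...]) -> np.ndarray:
    m = np.ones((1, 1))
    for i, b in enumerate(bases):
        block = b[1:] if i in members else b[:1]
        m = np.kron(m, block)
    return m


def _group_hypothesis_ss(gmeans: np.ndarray, sizes: np.ndarray) -> float:
    """Type III SS for equality of group means (columns summed)."""
    G = len(sizes)
    L = _helmert_full(G)[1:]  # (G-1) x G contrasts among groups
    A = (L * (1.0 / sizes)) @ L.T
    B = L @ gmeans
    return float(np.trace(B.T @ np.linalg.solve(A, B)))


def _effect_hypothesis_ss(gmeans: np.ndarray, sizes: np.ndarray) -> float:
    """Type III SS for the (unweighted) grand mean being zero."""
    G = len(sizes)
    mu = gmeans.mean(axis=0)
    return float(G * G / np.sum(1.0 / sizes) * np.sum(mu ** 2))


def _gg_epsilon(resid: np.ndarray, df_resid: int) -> float:
    p = resid.shape[1]
    if p <= 1:
        return 1.0
    s = resid.T @ resid / df_resid
    tr = np.trace(s)
    denom = p * np.trace(s @ s)
    if denom <= 0:
        return 1.0
    return float(np.clip(tr * tr / denom, 1.0 / p, 1.0))


def _f_and_p(ss_h, df_h, ss_e, df_e, eps=1.0):
    if ss_e <= 0:
        if ss_h <= 0:
            return 0.0, 1.0, 1.0
        return math.inf, 0.0, 0.0
    f = (ss_h / df_h) / (ss_e / df_e)
    p_unc = float(stats.f.sf(f, df_h, df_e))
    p_adj = float(stats.f.sf(f, eps * df_h, eps * df_e))
    return f, p_unc, p_adj


def rm_anova_gg(data: pd.DataFrame, dv: str, within: list[str] | None = None,
                between: str | None = None,
                subject: str = "subject") -> pd.DataFrame:
    """Within-between ANOVA table with Greenhouse-Geisser adjustment.

    Parameters
    ----------
    data : tidy DataFrame with one observation per subject x within cell
        (replicates within a cell are averaged).
    dv : response column.
    within : within-subject factor columns (fully crossed).
    between : optional between-subjects factor column (constant per subject).
    subject : subject identifier column.

    Returns
    -------
    DataFrame with one row per effect: F, unadjusted and
    epsilon-hat-adjusted degrees of freedom, unadjusted and adjusted
    p-values, epsilon, and partial eta squared.  ``p_adj`` equals ``p_unc``
    whenever the stratum has a single contrast variable.
    """
    within = list(within or [])
    if not within and between is None:
        raise DesignError("at least one within or between factor required")
    wide, levels = _pivot(data, dv, within, subject)
    y = wide.to_numpy(dtype=float)
    n_subj = y.shape[0]

    if between is not None:
        gmap = data.groupby(subject)[between].agg(lambda s: s.unique())
        if any(len(u) != 1 for u in gmap):
            raise DesignError(f"{between!r} varies within a subject")
        groups = gmap.reindex(wide.index).map(lambda u: u[0])
        glevels = sorted(groups.unique())
        gidx = [np.flatnonzero((groups == g).to_numpy()) for g in glevels]
        sizes = np.array([len(ix) for ix in gidx], dtype=float)
        if np.any(sizes < 2):
            raise DesignError("each group needs at least 2 subjects")
    else:
        glevels = ["_all"]
        gidx = [np.arange(n_subj)]
        sizes = np.array([float(n_subj)])
    n_groups = len(glevels)
    df_sub_err = n_subj - n_groups

    bases = [_helmert_full(len(lv)) for lv in levels]
    rows = []

    def _stratum(z: np.ndarray):
        gmeans = np.vstack([z[ix].mean(axis=0) for ix in gidx])
        resid = z.copy()
        for g, ix in enumerate(gidx):
            resid[ix] -= gmeans[g]
        ss_err = float(np.sum(resid ** 2))
        eps = _gg_epsilon(resid, df_sub_err)
        return gmeans, ss_err, eps

    # between-subjects stratum
    m0 = _effect_matrix(bases, ()) if within else np.ones((1, 1))
    z0 = y @ m0.T if within else y
    gmeans0, ss_err0, _ = _stratum(z0)
    if between is not None:
        ss_g = _group_hypothesis_ss(gmeans0, sizes)
        f, p_unc, _ = _f_and_p(ss_g, n_groups - 1, ss_err0, df_sub_err)
        rows.append({"effect": between, "df1": n_groups - 1.0,
                     "df2": float(df_sub_err), "eps": 1.0,
                     "df1_adj": n_groups - 1.0, "df2_adj": float(df_sub_err),
                     "F": f, "p_unc": p_unc, "p_adj": p_unc,
                     "partial_eta_sq": _peta(ss_g, ss_err0)})

    # within strata, smallest interactions first
    for size in range(1, len(within) + 1):
        for members in itertools.combinations(range(len(within)), size):
            m = _effect_matrix(bases, members)
            p_dim = m.shape[0]
            z = y @ m.T
            gmeans, ss_err, eps = _stratum(z)
            df_err = float(p_dim * df_sub_err) if between is not None \
                else float(p_dim * (n_subj - 1))
            name = " * ".join(within[i] for i in members)

            ss_h = _effect_hypothesis_ss(gmeans, sizes)
            f, p_unc, p_adj = _f_and_p(ss_h, p_dim, ss_err, df_err, eps)
            rows.append({"effect": name, "df1": float(p_dim), "df2": df_err,
                         "eps": eps, "df1_adj": eps * p_dim,
                         "df2_adj": eps * df_err, "F": f, "p_unc": p_unc,
                         "p_adj": p_adj, "partial_eta_sq": _peta(ss_h, ss_err)})
            if between is not None:
                ss_i = _group_hypothesis_ss(gmeans, sizes)
                df_i = float(p_dim * (n_groups - 1))
                f, p_unc, p_adj = _f_and_p(ss_i, df_i, ss_err, df_err, eps)
                rows.append({"effect": f"{name} * {between}",
                             "df1": df_i, "df2": df_err, "eps": eps,
                             "df1_adj": eps * df_i, "df2_adj": eps * df_err,
                             "F": f, "p_unc": p_unc, "p_adj": p_adj,
                             "partial_eta_sq": _peta(ss_i, ss_err)})

    return pd.DataFrame(rows)


def _peta(ss_h, ss_e):
    if ss_h + ss_e <= 0:
        return 0.0
    return float(ss_h / (ss_h + ss_e))


def bonferroni_posthoc(data: pd.DataFrame, dv: str, factor: str,
                       within: list[str] | None = None,
                       between: str | None = None,
                       subject: str = "subject") -> pd.DataFrame:
    """Bonferroni-adjusted pairwise contrasts for one factor.

    Each pair of levels is tested with the same mixed ANOVA restricted to
    those two levels (averaging the response over any other within
    factors), and the raw p-value is multiplied by the number of pairwise
    comparisons (capped at 1).
    """
    within = list(within or [])
    levels = sorted(data[factor].unique())
    if len(levels) < 2:
        raise DesignError(f"factor {factor!r} needs at least 2 levels")
    pairs = list(itertools.combinations(levels, 2))
    k = len(pairs)
    rows = []
    for a, b in pairs:
        sub = data[data[factor].isin([a, b])]
        if factor == between:
            table = rm_anova_gg(sub, dv, within=[], between=between,
                                subject=subject)
            row = table[table["effect"] == between].iloc[0]
        else:
            table = rm_anova_gg(sub, dv, within=[factor], between=between,
                                subject=subject)
            row = table[table["effect"] == factor].iloc[0]
        rows.append({"level_a": a, "level_b": b, "F": row["F"],
                     "df1": row["df1"], "df2": row["df2"],
                     "p_unc": row["p_unc"],
                     "p_bonf": min(1.0, row["p_unc"] * k),
                     "n_comparisons": k})
    return pd.DataFrame(rows)
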