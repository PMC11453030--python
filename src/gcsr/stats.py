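"""Polynomial-trend repeated-measures statistics.

The within-subject factor (frequency bins, or demographic scales) is
decomposed into orthonormal polynomial contrasts.  For each polynomial order
j, every subject's profile is reduced to a single trend score (the dot product
with the order-j contrast vector) and a between-subjects factorial ANOVA is
run on the scores: the intercept test is the "frequency (order j)" effect and
each between-subjects term tests its interaction with that trend.  Type-III
sums of squares with sum-to-zero coding are used so unbalanced cells (e.g.
4/4/5/5) reproduce conventional statistics-package output; with 18 subjects in
a 2x2 design every denominator df is 14.

``gg_anova`` gives the omnibus multi-df within-subject F with the
Greenhouse-Geisser sphericity correction: the repeated measures are projected
onto the k-1 orthonormal contrasts, sums of squares are pooled across
contrasts, and epsilon is computed from the pooled residual covariance of the
projected data, clamped to [1/(k-1), 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DesignTable",
    "EffectResult",
    "TrendAnovaResult",
    "orth_poly",
    "trend_anova",
    "gg_anova",
    "run_study_analyses",
    "format_anova_table",
]


def orth_poly(k_levels: int) -> np.ndarray:
    """Orthonormal polynomial contrast vectors for k equally spaced levels.

    Returns a (k-1, k) matrix; row j-1 is the degree-j trend (linear,
    quadratic, ...), unit length, orthogonal to all lower orders and summing
    to zero.  Built by Gram-Schmidt on the Vandermonde basis with one
    re-orthogonalisation pass for stability at high order.
    """
    k = int(k_levels)
    if k < 2:
        raise ValueError("need at least 2 levels")
    x = np.arange(k, dtype=float) - (k - 1) / 2.0
    V = np.vander(x, k, increasing=True)  # columns 1, x, x^2, ...
    Q = np.empty_like(V)
    for j in range(k):
        v = V[:, j].copy()
        for _ in range(2):  # classical GS with re-orthogonalisation
            for i in range(j):
                v -= (Q[:, i] @ v) * Q[:, i]
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError("degenerate basis")
        Q[:, j] = v / norm
    P = Q[:, 1:].T
    # sign convention: positive weight on the highest level
    for row in P:
        if row[-1] < 0:
            row *= -1
    return P


@dataclass
class DesignTable:
    """One row per subject: between-subject factor levels plus an ordered
    within-subject measurement profile (e.g. GCSR over frequency bins)."""

    subject_ids: list[str]
    between: pd.DataFrame  # one column per between factor, categorical levels
    y: np.ndarray  # n_subjects x k_levels
    level_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.subject_ids)
        if self.y.shape[0] != n or len(self.between) != n:
            raise ValueError("row count mismatch between ids, factors and y")
        if self.y.shape[1] < 2:
            raise ValueError("need at least 2 within-subject levels")
        for col in self.between.columns:
            counts = self.between[col].value_counts()
            if (counts == 0).any():
                raise ValueError(f"empty level in between factor {col}")

    @property
    def k(self) -> int:
        return self.y.shape[1]

    @property
    def n(self) -> int:
        return self.y.shape[0]

    def cell_index(self) -> pd.Series:
        """Between-cell label per subject (all factors combined)."""
        if self.between.shape[1] == 0:
            return pd.Series(["all"] * self.n)
        return self.between.astype(str).agg("|".join, axis=1)


@dataclass
class EffectResult:
    effect: str  # e.g. "frequency", "diagnosis x frequency"
    order: int | None  # polynomial order, None for omnibus within effects
    F: float
    df1: float
    df2: float
    p: float
    epsilon: float | None = None
    note: str = ""

    def as_dict(self) -> dict:
        d = {
            "effect": self.effect,
            "order": self.order,
            "F": None if not np.isfinite(self.F) else round(float(self.F), 6),
            "df1": round(float(self.df1), 4),
            "df2": round(float(self.df2), 4),
            "p": None if not np.isfinite(self.p) else round(float(self.p), 6),
        }
        if self.epsilon is not None:
            d["epsilon"] = round(float(self.epsilon), 4)
        if self.note:
            d["note"] = self.note
        return d


@dataclass
class TrendAnovaResult:
    effects: list[EffectResult]

    def get(self, effect: str, order: int | None = None) -> EffectResult:
        for e in self.effects:
            if e.effect == effect and e.order == order:
                return e
        raise KeyError((effect, order))

    def as_records(self) -> list[dict]:
        return [e.as_dict() for e in self.effects]


def _between_design_matrix(between: pd.DataFrame) -> tuple[np.ndarray, list[tuple[str, list[int]]]]:
    """Sum-to-zero coded design matrix for up to two 2+-level between factors,
    with all interactions.  Returns (X, terms) where terms maps each named
    effect (incl. 'intercept') to its column indices in X."""
    n = len(between)
    cols: list[np.ndarray] = [np.ones(n)]
    terms: list[tuple[str, list[int]]] = [("intercept", [0])]
    factor_cols: dict[str, list[int]] = {}
    for name in between.columns:
        levels = sorted(between[name].astype(str).unique())
        if len(levels) < 2:
            raise ValueError(f"between factor {name} needs >= 2 levels")
        idxs = []
        for lev in levels[:-1]:
            c = np.where(between[name].astype(str) == lev, 1.0, 0.0)
            c -= np.where(between[name].astype(str) == levels[-1], 1.0, 0.0)
            idxs.append(len(cols))
            cols.append(c)
        terms.append((name, idxs))
        factor_cols[name] = idxs
    names = list(between.columns)
    if len(names) == 2:
        a, b = names
        idxs = []
        for ia in factor_cols[a]:
            for ib in factor_cols[b]:
                idxs.append(len(cols))
                cols.append(cols[ia] * cols[ib])
        terms.append((f"{a} x {b}", idxs))
    elif len(names) > 2:
        raise NotImplementedError("at most two between-subject factors supported")
    X = np.column_stack(cols)
    return X, terms


def _type3_anova(X: np.ndarray, terms: list[tuple[str, list[int]]], y: np.ndarray):
    """Type-III F tests for every term of a sum-coded linear model.

    Returns list of (term_name, ss, df1, F, p) plus (ss_resid, df_resid).
    With sum-to-zero coding and all interactions present, dropping a term's
    columns yields the type-III sum of squares.
    """
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    df_res = n - p
    out = []
    for name, idxs in terms:
        keep = [i for i in range(p) if i not in idxs]
        Xr = X[:, keep]
        br, *_ = np.linalg.lstsq(Xr, y, rcond=None)
        rr = y - Xr @ br
        ss_term = float(rr @ rr) - ss_res
        df1 = len(idxs)
        out.append((name, max(ss_term, 0.0), df1))
    return out, ss_res, df_res


def _score_anova(between: pd.DataFrame, scores: np.ndarray, order: int) -> list[EffectResult]:
    X, terms = _between_design_matrix(between)
    term_ss, ss_res, df_res = _type3_anova(X, terms, scores)
    # relative tolerance: sums of squares this small are numerical residue
    tol = 1e-12 * max(1.0, float(scores @ scores))
    results = []
    for name, ss, df1 in term_ss:
        label = "frequency" if name == "intercept" else f"{name} x frequency"
        if ss_res <= tol or df_res <= 0:
            if ss <= tol:
                results.append(EffectResult(label, order, 0.0, df1, df_res, 1.0,
                                            note="degenerate: zero trend variance"))
            else:
                results.append(EffectResult(label, order, np.inf, df1, df_res, 0.0,
                                            note="zero residual variance"))
            continue
        F = (ss / df1) / (ss_res / df_res)
        pval = float(sps.f.sf(F, df1, df_res))
        results.append(EffectResult(label, order, float(F), df1, df_res, pval))
    return results


def trend_anova(
    table: DesignTable,
    orders: Sequence[int] | None = None,
) -> TrendAnovaResult:
    """Orthogonal-polynomial trend decomposition of the within factor.

    For each order j, subjects' profiles are projected onto the order-j
    contrast and a type-III between-subjects factorial ANOVA is run on the
    scores.  ``orders`` defaults to 1..k-1.
    """
    k = table.k
    if k < 3:
        raise ValueError("need at least 3 within levels for trend analysis")
    P = orth_poly(k)
    if orders is None:
        orders = range(1, k)
    effects: list[EffectResult] = []
    for j in orders:
        if not 1 <= j <= k - 1:
            raise ValueError(f"order {j} out of range 1..{k - 1}")
        scores = table.y @ P[j - 1]
        effects.extend(_score_anova(table.between, scores, j))
    return TrendAnovaResult(effects)


def gg_anova(table: DesignTable) -> TrendAnovaResult:
    """Omnibus within-subject effects with Greenhouse-Geisser correction.

    Projects the k repeated measures onto k-1 orthonormal contrasts, pools
    sums of squares over contrasts for the within main effect, its
    interactions with the between factors, and the within error, and corrects
    all dfs by the GG epsilon estimated from the pooled residual covariance.
    """
    k, n = table.k, table.n
    P = orth_poly(k)  # (k-1, k) orthonormal
    Z = table.y @ P.T  # n x (k-1)
    X, terms = _between_design_matrix(table.between)
    g = X.shape[1]  # number of between-model parameters = number of cells

    # pooled SS per term across the k-1 contrast variables
    ss_by_term = {name: 0.0 for name, _ in terms}
    df1_by_term = {name: len(idxs) for name, idxs in terms}
    ss_err = 0.0
    resid_cols = []
    for j in range(k - 1):
        term_ss, ss_res, df_res = _type3_anova(X, terms, Z[:, j])
        for name, ss, _ in term_ss:
            ss_by_term[name] += ss
        ss_err += ss_res
        beta, *_ = np.linalg.lstsq(X, Z[:, j], rcond=None)
        resid_cols.append(Z[:, j] - X @ beta)
    df_err = (k - 1) * (n - g)

    R = np.column_stack(resid_cols)  # n x (k-1) residual projections
    S = (R.T @ R) / (n - g)  # pooled covariance of contrast variables
    tr = np.trace(S)
    denom = (k - 1) * float(np.sum(S * S))
    if denom <= 0 or not np.isfinite(denom):
        warnings.warn("singular covariance; epsilon set to its lower bound")
        eps = 1.0 / (k - 1)
    else:
        eps = float(tr * tr / denom)
    eps = float(np.clip(eps, 1.0 / (k - 1), 1.0))

    effects = []
    ms_err = ss_err / df_err if df_err > 0 else np.nan
    for name, _ in terms:
        df1 = df1_by_term[name] * (k - 1)
        label = "within" if name == "intercept" else f"{name} x within"
        ss = ss_by_term[name]
        if not np.isfinite(ms_err) or ms_err == 0:
            effects.append(EffectResult(label, None, 0.0, df1 * eps, df_err * eps, 1.0,
                                        epsilon=eps, note="degenerate"))
            continue
        F = (ss / df1) / ms_err
        df1_c = eps * df1
        df2_c = eps * df_err
        pval = float(sps.f.sf(F, df1_c, df2_c))
        effects.append(EffectResult(label, None, float(F), df1_c, df2_c, pval, epsilon=eps))
    return TrendAnovaResult(effects)


# ---------------------------------------------------------------------------
# the two study analyses

ANXIETY_GROUPS = ("GAD_TR", "GAD_NOT", "SAD_TR", "SAD_NOT")
DEPRESSION_GROUPS = ("MDD_TR", "GMD_NOT")


def _freq_columns(gcsr_df: pd.DataFrame, lo: int, hi: int) -> list[str]:
    cols = []
    for f in range(lo, hi + 1):
        name = f"{f}Hz"
        if name not in gcsr_df.columns:
            raise ValueError(f"GCSR table missing column {name}")
        cols.append(name)
    return cols


def run_study_analyses(gcsr_df: pd.DataFrame, metadata: pd.DataFrame) -> dict:
    """Run the two study analyses on a cohort GCSR table.

    Analysis 1 ("anxiety_2x2"): GAD/SAD x TR/non-TR over 2-13 Hz (12 bins,
    polynomial orders 1-11).  Analysis 2 ("depression_tr"): TR-MDD vs
    non-TR comorbid GAD+MDD as a single between factor over 2-10 Hz (9 bins,
    orders 1-8).  ``metadata`` needs columns subject_id and group; subjects in
    neither analysis are listed and skipped with a warning.
    """
    meta = metadata.set_index("subject_id")
    known = set(ANXIETY_GROUPS) | set(DEPRESSION_GROUPS)
    stray = [
        str(s) for s in gcsr_df.index
        if s not in meta.index or meta.loc[s, "group"] not in known
    ]
    if stray:
        warnings.warn(f"subjects outside both analyses skipped: {stray}")

    report: dict = {"analyses": {}, "skipped_subjects": stray}

    anx_ids = [s for s in gcsr_df.index if s in meta.index
               and meta.loc[s, "group"] in ANXIETY_GROUPS]
    if anx_ids:
        cols = _freq_columns(gcsr_df, 2, 13)
        groups = meta.loc[anx_ids, "group"]
        between = pd.DataFrame({
            "diagnosis": [g.split("_")[0] for g in groups],
            "resistance": [g.split("_")[1] for g in groups],
        })
        table = DesignTable(list(anx_ids), between, gcsr_df.loc[anx_ids, cols].to_numpy(),
                            level_labels=cols)
        report["analyses"]["anxiety_2x2"] = {
            "subjects": len(anx_ids),
            "freq_range_hz": [2, 13],
            "effects": trend_anova(table).as_records(),
        }

    dep_ids = [s for s in gcsr_df.index if s in meta.index
               and meta.loc[s, "group"] in DEPRESSION_GROUPS]
    if dep_ids:
        cols = _freq_columns(gcsr_df, 2, 10)
        groups = meta.loc[dep_ids, "group"]
        between = pd.DataFrame({
            "resistance": [g.split("_")[1] for g in groups],
        })
        table = DesignTable(list(dep_ids), between, gcsr_df.loc[dep_ids, cols].to_numpy(),
                            level_labels=cols)
        report["analyses"]["depression_tr"] = {
            "subjects": len(dep_ids),
            "freq_range_hz": [2, 10],
            "effects": trend_anova(table).as_records(),
        }
    return report


def format_anova_table(report: dict) -> str:
    """Human-readable ANOVA table for a run_study_analyses report."""
    lines = []
    for name, ana in report.get("analyses", {}).items():
        lo, hi = ana["freq_range_hz"]
        lines.append(f"=== {name} (n={ana['subjects']}, {lo}-{hi} Hz) ===")
        lines.append(f"{'effect':<40}{'order':>6}{'F':>10}{'df':>12}{'p':>9}")
        for e in ana["effects"]:
            order = "" if e["order"] is None else str(e["order"])
            F = "nan" if e["F"] is None else f"{e['F']:.3f}"
            p = "nan" if e["p"] is None else f"{e['p']:.3f}"
            df = f"({e['df1']:g}, {e['df2']:g})"
            lines.append(f"{e['effect']:<40}{order:>6}{F:>10}{df:>12}{p:>9}")
        lines.append("")
    return "\n".join(lines)
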