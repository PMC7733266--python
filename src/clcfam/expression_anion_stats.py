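"""Relative-expression and anion-content statistics.

Fold changes from Ct tables by the 2^-ddCt method, classical one-way
ANOVA with Tukey HSD pairwise tests summarized as a compact letter
display, treatment-vs-control fold ratios, and a Pearson correlation
matrix with significance stars.

Technical replicates are averaged before any biological-replicate
statistic; ANOVA/Tukey run independently per (variable, tissue) panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtTable",
    "MeasurementTable",
    "FoldChange",
    "AnovaResult",
    "StatResult",
    "CorrelationMatrix",
    "read_ct_table",
    "read_measurement_table",
    "ddct_fold_change",
    "one_way_anova",
    "tukey_hsd",
    "compact_letter_display",
    "group_stats",
    "fold_vs_control",
    "correlation_matrix",
    "panel_stats",
    "write_stat_table",
    "write_correlation_matrix",
]

CT_COLUMNS = ["gene", "tissue", "treatment_mM", "biorep", "techrep", "ct"]
MEASUREMENT_COLUMNS = ["tissue", "treatment_mM", "rep", "variable", "value"]


@dataclass
class CtTable:
    """qPCR Ct values with a designated reference gene and calibrator level."""

    data: pd.DataFrame
    reference_gene: str
    calibrator: float = 0.0

    def __post_init__(self) -> None:
        missing = set(CT_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing column(s) {sorted(missing)}")
        if not np.isfinite(self.data["ct"]).all() or (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be finite and positive")
        if self.reference_gene not in set(self.data["gene"]):
            raise ValueError(f"reference gene {self.reference_gene!r} absent from table")


@dataclass
class MeasurementTable:
    """Long-format measurements (anion contents, dry weights, ...)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(MEASUREMENT_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"measurement table missing column(s) {sorted(missing)}")


def read_ct_table(
    path: str | Path, reference_gene: str, calibrator: float = 0.0, sep: str | None = None
) -> CtTable:
    df = pd.read_csv(path, sep=sep, engine="python")
    return CtTable(data=df, reference_gene=reference_gene, calibrator=calibrator)


def read_measurement_table(path: str | Path, sep: str | None = None) -> MeasurementTable:
    return MeasurementTable(data=pd.read_csv(path, sep=sep, engine="python"))


# ---------------------------------------------------------------------------
# 2^-ddCt
# ---------------------------------------------------------------------------

@dataclass
class FoldChange:
    gene: str
    tissue: str
    treatment: float
    fold: float
    per_replicate_folds: list[float]

    @property
    def se(self) -> float:
        folds = np.asarray(self.per_replicate_folds)
        if folds.size < 2:
            return float("nan")
        return float(folds.std(ddof=1) / math.sqrt(folds.size))


def _mean_dct(ct: CtTable, gene: str, tissue: str, treatment: float) -> pd.Series:
    """Per-biological-replicate dCt (target minus reference), technical
    replicates averaged first."""
    df = ct.data
    sel = (df["tissue"] == tissue) & (df["treatment_mM"] == treatment)
    target = df[sel & (df["gene"] == gene)].groupby("biorep")["ct"].mean()
    ref = df[sel & (df["gene"] == ct.reference_gene)].groupby("biorep")["ct"].mean()
    if target.empty:
        raise ValueError(f"no Ct rows for gene={gene!r}, tissue={tissue!r}, "
                         f"treatment={treatment!r}")
    if ref.empty or not set(target.index) <= set(ref.index):
        raise ValueError(
            f"missing reference-gene rows for tissue={tissue!r}, "
            f"treatment={treatment!r} (reference {ct.reference_gene!r})"
        )
    return target - ref.loc[target.index]


def ddct_fold_change(
    ct: CtTable, gene: str, tissue: str, treatment: float
) -> FoldChange:
    """2^-ddCt fold change of a gene/tissue/treatment cell vs the calibrator."""
    dct_treat = _mean_dct(ct, gene, tissue, treatment)
    dct_cal = _mean_dct(ct, gene, tissue, ct.calibrator)
    ddct = dct_treat.mean() - dct_cal.mean()
    per_rep = [float(2.0 ** -(d - dct_cal.mean())) for d in dct_treat]
    return FoldChange(
        gene=gene,
        tissue=tissue,
        treatment=treatment,
        fold=float(2.0 ** -ddct),
        per_replicate_folds=per_rep,
    )


# ---------------------------------------------------------------------------
# ANOVA, Tukey HSD, compact letters
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    p_below_eps: bool = False


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical (non-Welch) one-way ANOVA."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrs):
        raise ValueError("every group needs at least 2 values")
    k = len(arrs)
    n = sum(a.size for a in arrs)
    grand = np.concatenate(arrs).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    dfb, dfw = k - 1, n - k
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(0.0, 1.0, dfb, dfw)
        # unequal means with zero within-group variance
        return AnovaResult(math.inf, 0.0, dfb, dfw, p_below_eps=True)
    f = (ssb / dfb) / (ssw / dfw)
    p = float(stats.f.sf(f, dfb, dfw))
    return AnovaResult(float(f), p, dfb, dfw)


def tukey_hsd(
    groups: Sequence[Sequence[float]], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Tukey HSD pairwise tests.

    Returns ``(significant, p_values)``: a symmetric boolean matrix of
    pairwise significance at family-wise ``alpha`` and the matching
    p-value matrix.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    # degenerate zero-variance case: scipy emits nan p-values
    pooled_var = np.concatenate([a - a.mean() for a in arrs]).var()
    if pooled_var == 0.0:
        k = len(arrs)
        p = np.ones((k, k))
        sig = np.zeros((k, k), dtype=bool)
        for i in range(k):
            for j in range(k):
                if i != j and arrs[i].mean() != arrs[j].mean():
                    p[i, j] = 0.0
                    sig[i, j] = True
        return sig, p
    res = stats.tukey_hsd(*arrs)
    p = np.asarray(res.pvalue)
    np.fill_diagonal(p, 1.0)
    return p < alpha, p


def compact_letter_display(significant: np.ndarray) -> list[str]:
    """Insert-and-absorb compact letter display.

    ``significant`` is a symmetric boolean matrix; groups sharing a
    letter in the output are not significantly different.  Letters are
    assigned in group order.
    """
    significant = np.asarray(significant, dtype=bool)
    k = significant.shape[0]
    if significant.shape != (k, k):
        raise ValueError("significance matrix must be square")
    if (significant != significant.T).any():
        raise ValueError("significance matrix must be symmetric")
    columns: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not significant[i, j]:
                continue
            for col in [c for c in columns if i in c and j in c]:
                columns.remove(col)
                columns.append(col - {i})
                columns.append(col - {j})
            # absorb: drop columns contained in another
            columns = [
                c
                for idx, c in enumerate(columns)
                if c
                and not any(
                    c < other or (c == other and idx2 < idx)
                    for idx2, other in enumerate(columns)
                    if idx2 != idx
                )
            ]
    # order columns by their smallest member, assign letters
    columns.sort(key=lambda c: (min(c), sorted(c)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = ["" for _ in range(k)]
    for li, col in enumerate(columns):
        ch = alphabet[li % len(alphabet)] * (1 + li // len(alphabet))
        for g in sorted(col):
            letters[g] += ch
    return letters


@dataclass
class StatResult:
    """Per-panel group statistics with post-hoc letters."""

    group_labels: list[str]
    means: list[float]
    ses: list[float]
    anova: AnovaResult
    tukey_p: np.ndarray
    letters: list[str]
    alpha: float = 0.05
    fold_vs_control: list[float] | None = None


def group_stats(groups: Sequence[Sequence[float]]) -> tuple[list[float], list[float]]:
    means, ses = [], []
    for g in groups:
        a = np.asarray(g, dtype=float)
        means.append(float(a.mean()))
        ses.append(float(a.std(ddof=1) / math.sqrt(a.size)) if a.size > 1 else float("nan"))
    return means, ses


def fold_vs_control(
    meas: MeasurementTable,
    variable: str,
    tissue: str,
    treatment: float,
    control: float = 0.0,
    convention: str = "ratio",
) -> float:
    """mean(treatment) / mean(control) for one variable/tissue panel.

    ``convention="ratio"`` reports the plain ratio ("increased N times"
    means ratio = N); ``convention="increment"`` reports ratio - 1
    (the alternative reading where "increased N times" means ratio = N+1).
    """
    df = meas.data
    sel = (df["variable"] == variable) & (df["tissue"] == tissue)
    m_t = df[sel & (df["treatment_mM"] == treatment)]["value"].mean()
    m_c = df[sel & (df["treatment_mM"] == control)]["value"].mean()
    if not np.isfinite(m_c) or m_c == 0:
        raise ValueError(
            f"control mean is zero or missing for variable={variable!r}, tissue={tissue!r}"
        )
    ratio = float(m_t / m_c)
    if convention == "ratio":
        return ratio
    if convention == "increment":
        return ratio - 1.0
    raise ValueError("convention must be 'ratio' or 'increment'")


def panel_stats(
    meas: MeasurementTable,
    variable: str,
    tissue: str,
    alpha: float = 0.05,
    control: float = 0.0,
) -> StatResult:
    """ANOVA + Tukey letters for one (variable, tissue) panel, groups
    ordered by treatment level."""
    df = meas.data
    sel = (df["variable"] == variable) & (df["tissue"] == tissue)
    sub = df[sel]
    if sub.empty:
        raise ValueError(f"no rows for variable={variable!r}, tissue={tissue!r}")
    levels = sorted(sub["treatment_mM"].unique())
    groups = [sub[sub["treatment_mM"] == lv]["value"].to_numpy() for lv in levels]
    anova = one_way_anova(groups)
    sig, p = tukey_hsd(groups, alpha=alpha)
    letters = compact_letter_display(sig)
    means, ses = group_stats(groups)
    folds = None
    if control in levels:
        ctrl_mean = means[levels.index(control)]
        if ctrl_mean != 0:
            folds = [m / ctrl_mean for m in means]
    return StatResult(
        group_labels=[str(lv) for lv in levels],
        means=means,
        ses=ses,
        anova=anova,
        tukey_p=p,
        letters=letters,
        alpha=alpha,
        fold_vs_control=folds,
    )


# ---------------------------------------------------------------------------
# Correlation matrix
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    variables: list[str]
    r: np.ndarray
    p: np.ndarray

    def star(self, i: int, j: int) -> str:
        if i == j:
            return ""
        if self.p[i, j] < 0.01:
            return "**"
        if self.p[i, j] < 0.05:
            return "*"
        return ""


def correlation_matrix(samples: pd.DataFrame) -> CorrelationMatrix:
    """Pearson correlations with two-sided p-values over an aligned
    per-sample table (columns = variables, rows = samples)."""
    variables = list(samples.columns)
    n = len(samples)
    if n < 3:
        raise ValueError("need at least 3 paired samples")
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = stats.pearsonr(samples.iloc[:, i], samples.iloc[:, j])
            r[i, j] = r[j, i] = float(res.statistic)
            p[i, j] = p[j, i] = float(res.pvalue)
    return CorrelationMatrix(variables=variables, r=r, p=p)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_stat_table(
    results: dict[tuple[str, str], StatResult], path: str | Path, sep: str = "\t"
) -> None:
    """Write per-panel group stats; one row per (variable, tissue, group)."""
    cols = ["variable", "tissue", "group", "mean", "se", "letter",
            "fold_vs_control", "F", "p"]
    with open(path, "w") as fh:
        fh.write(sep.join(cols) + "\n")
        for (variable, tissue), res in results.items():
            for i, label in enumerate(res.group_labels):
                fold = (
                    f"{res.fold_vs_control[i]:.4g}" if res.fold_vs_control else ""
                )
                fh.write(
                    sep.join(
                        [
                            variable,
                            tissue,
                            label,
                            f"{res.means[i]:.6g}",
                            f"{res.ses[i]:.6g}",
                            res.letters[i],
                            fold,
                            f"{res.anova.f_statistic:.6g}",
                            f"{res.anova.p_value:.6g}",
                        ]
                    )
                    + "\n"
                )


def write_correlation_matrix(
    corr: CorrelationMatrix, path: str | Path, sep: str = "\t"
) -> None:
    """Write both square (r) and long (r, p, stars) forms."""
    with open(path, "w") as fh:
        fh.write(sep.join(["variable"] + corr.variables) + "\n")
        for i, v in enumerate(corr.variables):
            fh.write(
                sep.join([v] + [f"{corr.r[i, j]:.4f}" for j in range(len(corr.variables))])
                + "\n"
            )
        fh.write("\n")
        fh.write(sep.join(["var_a", "var_b", "r", "p", "stars"]) + "\n")
        for i in range(len(corr.variables)):
            for j in range(i + 1, len(corr.variables)):
                fh.write(
                    sep.join(
                        [
                            corr.variables[i],
                            corr.variables[j],
                            f"{corr.r[i, j]:.4f}",
                            f"{corr.p[i, j]:.6g}",
                            corr.star(i, j),
                        ]
                    )
                    + "\n"
                )
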