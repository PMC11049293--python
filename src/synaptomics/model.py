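"""Protein-level factorial statistics.

Each protein's log2 quantities are fitted to a two-way fixed-effects model

    y ~ genotype + treatment + genotype:treatment

with type-II sums of squares. Complete balanced data (the common case after
the missing-value filter) use closed-form contrast arithmetic, vectorized
across proteins; proteins with missing cells fall back to a per-protein
OLS fit. Pairwise contrasts can also be computed directly from printed
summary statistics (cell mean, SEM, n), which reproduces published
two-sample p-values without the raw data.

The π score, log2FC x (−log10 p), ranks proteins by a blend of effect
size and statistical significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfigurationError, Design, QuantMatrix
from .quant import bh_adjust

EFFECTS = ("genotype", "treatment", "interaction")


def filter_missing(matrix: QuantMatrix, max_missing: int = 1) -> tuple[QuantMatrix, dict]:
    """Drop proteins quantified in too few samples.

    Retains proteins with at most ``max_missing`` missing cells. Returns
    the filtered matrix and a dict with ``n_input``, ``n_retained``,
    ``n_dropped``.
    """
    miss = matrix.missing_per_protein()
    keep = miss <= max_missing
    out = QuantMatrix(matrix.data.loc[keep])
    return out, {
        "n_input": len(miss),
        "n_retained": int(keep.sum()),
        "n_dropped": int((~keep).sum()),
    }


def _anova_balanced_complete(data: np.ndarray, g: np.ndarray, t: np.ndarray) -> pd.DataFrame:
    """Closed-form 2x2 ANOVA for complete data, balanced cells, vectorized.

    For a balanced 2x2 layout with n observations per cell the three
    effect sums of squares are n*dA^2, n*dB^2 and n*i^2/4 where dA, dB are
    the differences of factor-level means and i the interaction contrast
    m11 - m12 - m21 + m22; each has 1 df against the within-cell residual.
    """
    n_prot = data.shape[0]
    cells = {}
    ns = {}
    for gi in (0, 1):
        for ti in (0, 1):
            mask = (g == gi) & (t == ti)
            cells[(gi, ti)] = data[:, mask]
            ns[(gi, ti)] = mask.sum()
    n = ns[(0, 0)]
    means = {k: v.mean(axis=1) for k, v in cells.items()}
    d_g = (means[(1, 0)] + means[(1, 1)]) / 2 - (means[(0, 0)] + means[(0, 1)]) / 2
    d_t = (means[(0, 1)] + means[(1, 1)]) / 2 - (means[(0, 0)] + means[(1, 0)]) / 2
    inter = means[(0, 0)] - means[(0, 1)] - means[(1, 0)] + means[(1, 1)]
    ss = {
        "genotype": n * d_g**2,
        "treatment": n * d_t**2,
        "interaction": n * inter**2 / 4.0,
    }
    sse = np.zeros(n_prot)
    for k, block in cells.items():
        sse += ((block - means[k][:, None]) ** 2).sum(axis=1)
    df_resid = data.shape[1] - 4
    mse = sse / df_resid
    out = {}
    zero_var = mse <= 0
    for eff in EFFECTS:
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(zero_var, np.nan, ss[eff] / mse)
        p = np.where(zero_var, 1.0, stats.f.sf(f, 1, df_resid))
        out[f"F_{eff}"] = f
        out[f"p_{eff}"] = p
    res = pd.DataFrame(out)
    res["df_resid"] = df_resid
    res["zero_variance"] = zero_var
    return res


def _anova_typeii_single(y: np.ndarray, g: np.ndarray, t: np.ndarray) -> dict:
    """Type-II two-way ANOVA for one protein with missing cells (OLS)."""
    import statsmodels.api as sm
    from statsmodels.stats.anova import anova_lm

    ok = ~np.isnan(y)
    yy, gg, tt = y[ok], g[ok], t[ok]
    # every cell needs >=2 observations for an estimable interaction + residual
    for gi in (0, 1):
        for ti in (0, 1):
            if ((gg == gi) & (tt == ti)).sum() < 2:
                return {"inestimable": True}
    df = pd.DataFrame({"y": yy, "g": gg.astype(str), "t": tt.astype(str)})
    if np.allclose(yy, yy[0]):
        return {
            "F_genotype": np.nan, "p_genotype": 1.0,
            "F_treatment": np.nan, "p_treatment": 1.0,
            "F_interaction": np.nan, "p_interaction": 1.0,
            "df_resid": len(yy) - 4, "zero_variance": True, "inestimable": False,
        }
    fit = sm.OLS.from_formula("y ~ C(g) * C(t)", df).fit()
    tab = anova_lm(fit, typ=2)
    row = {
        "F_genotype": tab.loc["C(g)", "F"],
        "p_genotype": tab.loc["C(g)", "PR(>F)"],
        "F_treatment": tab.loc["C(t)", "F"],
        "p_treatment": tab.loc["C(t)", "PR(>F)"],
        "F_interaction": tab.loc["C(g):C(t)", "F"],
        "p_interaction": tab.loc["C(g):C(t)", "PR(>F)"],
        "df_resid": int(tab.loc["Residual", "df"]),
        "zero_variance": False,
        "inestimable": False,
    }
    return row


def fit_factorial_anova(matrix: QuantMatrix, design: Design) -> pd.DataFrame:
    """Per-protein two-way ANOVA (genotype x treatment, type II).

    Returns a DataFrame indexed by protein with F, p and BH q per effect
    (q computed within each effect family separately), cell means and SEMs,
    residual df, and flags for zero-variance and inestimable proteins
    (those with an empty or singleton design cell after missingness).
    """
    samples = [s for s in design.samples if s in matrix.samples]
    if len(samples) != len(design.samples):
        missing = set(design.samples) - set(matrix.samples)
        raise ConfigurationError(f"matrix lacks design samples: {sorted(missing)}")
    data = matrix.data[samples].to_numpy(dtype=float)
    g = (design.table.loc[samples, "genotype"] == "trisomic").to_numpy().astype(int)
    t = (design.table.loc[samples, "treatment"] == "fluoxetine").to_numpy().astype(int)

    groups = design.groups.loc[samples]
    balanced = len(set(groups.value_counts())) == 1
    complete = ~np.isnan(data).any(axis=1)

    records = pd.DataFrame(index=matrix.proteins)
    parts = []
    if balanced and complete.any():
        fast = _anova_balanced_complete(data[complete], g, t)
        fast.index = matrix.proteins[complete]
        fast["inestimable"] = False
        parts.append(fast)
    slow_mask = ~complete if balanced else np.ones(len(matrix.proteins), dtype=bool)
    for i in np.nonzero(slow_mask)[0]:
        row = _anova_typeii_single(data[i], g, t)
        if row.get("inestimable"):
            row = {"inestimable": True, "zero_variance": False, "df_resid": np.nan}
            for eff in EFFECTS:
                row[f"F_{eff}"] = np.nan
                row[f"p_{eff}"] = np.nan
        parts.append(pd.DataFrame([row], index=[matrix.proteins[i]]))
    stats_df = pd.concat(parts).loc[matrix.proteins]

    # cell means and SEMs for downstream contrasts
    for code in ("EW", "EF", "TW", "TF"):
        cols = [s for s in design.samples_in(code) if s in samples]
        block = matrix.data[cols]
        stats_df[f"mean_{code}"] = block.mean(axis=1)
        stats_df[f"sem_{code}"] = block.sem(axis=1, ddof=1)
        stats_df[f"n_{code}"] = block.notna().sum(axis=1)

    for eff in EFFECTS:
        stats_df[f"q_{eff}"] = bh_adjust(stats_df[f"p_{eff}"].to_numpy())
    return stats_df


@dataclass
class ContrastResult:
    protein: str
    group_a: str
    group_b: str
    log2fc: float
    t: float
    df: float
    p: float
    pi: float


def group_contrast(
    mean_a: float,
    sem_a: float,
    n_a: int,
    mean_b: float,
    sem_b: float,
    n_b: int,
    group_a: str = "a",
    group_b: str = "b",
    protein: str = "",
) -> ContrastResult:
    """Two-sample t-test from summary statistics (mean, SEM, n).

    Equal group sizes use the pooled test with SE_diff =
    sqrt(SEM_a^2 + SEM_b^2) and df = 2n − 2 (this is exactly the pooled
    two-sample t when n_a == n_b). Unequal sizes use Welch–Satterthwaite
    df. The fold change is mean_b − mean_a (log2 scale).
    """
    if n_a < 2 or n_b < 2:
        raise ConfigurationError("need n >= 2 per group")
    if sem_a < 0 or sem_b < 0:
        raise ConfigurationError("SEMs must be non-negative")
    diff = mean_b - mean_a
    se = np.sqrt(sem_a**2 + sem_b**2)
    if se == 0:
        if diff == 0:
            return ContrastResult(protein, group_a, group_b, 0.0, 0.0, n_a + n_b - 2, 1.0, 0.0)
        raise ConfigurationError("zero SEM in both groups with unequal means")
    if n_a == n_b:
        df = 2 * n_a - 2
    else:
        va, vb = sem_a**2, sem_b**2
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    tval = diff / se
    p = 2.0 * stats.t.sf(abs(tval), df)
    return ContrastResult(
        protein, group_a, group_b, float(diff), float(tval), float(df), float(p),
        pi_score(diff, p) if p > 0 else np.nan,
    )


def group_contrast_from_data(
    matrix: QuantMatrix, design: Design, group_a: str, group_b: str
) -> pd.DataFrame:
    """Per-protein contrast between two design cells from the raw matrix.

    Computes each group's mean and SEM from the data and delegates to
    :func:`group_contrast`, so raw-data and summary-statistics routes agree
    exactly for equal n.
    """
    rows = []
    a_cols = list(design.samples_in(group_a))
    b_cols = list(design.samples_in(group_b))
    for prot in matrix.proteins:
        a = matrix.data.loc[prot, a_cols].dropna()
        b = matrix.data.loc[prot, b_cols].dropna()
        if len(a) < 2 or len(b) < 2:
            continue
        res = group_contrast(
            a.mean(), a.sem(), len(a), b.mean(), b.sem(), len(b),
            group_a, group_b, prot,
        )
        rows.append(res.__dict__)
    out = pd.DataFrame(rows).set_index("protein") if rows else pd.DataFrame()
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["pi"] = [pi_score(fc, max(p, 1e-300)) for fc, p in zip(out["log2fc"], out["p"])]
    return out


def pi_score(log2fc: float, p: float) -> float:
    """π = log2FC x (−log10 p): effect size weighted by significance."""
    if not 0 < p <= 1:
        raise ConfigurationError(f"p must be in (0, 1], got {p}")
    return float(log2fc * -np.log10(p))


def select_interaction(stats_df: pd.DataFrame, alpha: float = 0.05) -> pd.Index:
    """Proteins with interaction p strictly below ``alpha``, ordered by p."""
    p = stats_df["p_interaction"]
    hits = stats_df.index[p < alpha]
    return hits[np.argsort(p[hits].to_numpy(), kind="stable")]
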