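"""Interaction-protein heatmap machinery.

Selected proteins are standard-scaled per row (mean 0, variance 1,
population convention), hierarchically clustered with Pearson-correlation
distance (d = 1 − r, pairwise-complete) under Ward.D2 agglomeration, and
the tree is cut at its first branch point into two clusters. The cluster
containing proteins that are lower in trisomic-fluoxetine than in
trisomic-water samples is labelled "cut1", matching the published heatmap
orientation; "cut2" holds the mirror pattern.

Plot-data exports (heatmap in leaf order, PC score ellipses, per-protein
boxplot summaries) are plain tables, ready for any plotting frontend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import chi2

from .containers import ConfigurationError, Design, QuantMatrix


@dataclass
class Dendrogram:
    """Ward.D2 merge tree over proteins."""

    linkage: np.ndarray  # scipy linkage matrix (n-1 x 4)
    leaves: pd.Index  # protein ids, positionally matching linkage indices
    method: str = "ward.D2"

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> pd.Index:
        order = hierarchy.leaves_list(self.linkage)
        return self.leaves[order]


def standard_scale(matrix: QuantMatrix) -> QuantMatrix:
    """Scale each protein to mean 0, variance 1 (population variance).

    Missing cells propagate; proteins with fewer than 2 observed values or
    zero variance are rejected by name.
    """
    vals = matrix.values().copy()
    obs = ~np.isnan(vals)
    n_obs = obs.sum(axis=1)
    if (n_obs < 2).any():
        bad = matrix.proteins[n_obs < 2][0]
        raise ConfigurationError(f"protein {bad!r} has fewer than 2 observed values")
    mean = np.nanmean(vals, axis=1)
    sd = np.sqrt(np.nanmean((vals - mean[:, None]) ** 2, axis=1))
    if (sd == 0).any():
        bad = matrix.proteins[sd == 0][0]
        raise ConfigurationError(f"protein {bad!r} has zero variance")
    scaled = (vals - mean[:, None]) / sd[:, None]
    return QuantMatrix(pd.DataFrame(scaled, index=matrix.proteins, columns=matrix.samples))


def correlation_distance(matrix: QuantMatrix) -> np.ndarray:
    """Condensed 1 − Pearson-r distances, pairwise-complete over missing."""
    df = matrix.data.T  # samples x proteins; pandas corr is pairwise-complete
    corr = df.corr(min_periods=3)
    if corr.isna().any().any():
        i, j = np.argwhere(corr.isna().to_numpy())[0]
        raise ConfigurationError(
            f"correlation undefined between {corr.index[i]!r} and {corr.columns[j]!r}"
        )
    d = 1.0 - corr.to_numpy()
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)  # enforce exact symmetry
    return squareform(d, checks=False)


def correlation_ward_tree(matrix: QuantMatrix) -> Dendrogram:
    """Ward.D2 tree on 1 − r distances.

    scipy's "ward" linkage on a precomputed condensed distance matrix runs
    the Lance–Williams recursion on squared dissimilarities and reports
    square-root heights — the ward.D2 convention. Merge order ties are
    resolved deterministically by scipy's lowest-index rule.
    """
    if matrix.shape[0] < 2:
        raise ConfigurationError("need at least 2 proteins to cluster")
    dist = correlation_distance(matrix)
    linkage = hierarchy.linkage(dist, method="ward")
    return Dendrogram(linkage, matrix.proteins)


def cut_first_branch(
    tree: Dendrogram,
    scaled: QuantMatrix | None = None,
    design: Design | None = None,
) -> pd.Series:
    """Cut at the root's first branch point into two clusters.

    With a scaled matrix and design supplied, "cut1" is oriented as the
    cluster whose mean scaled trisomic-fluoxetine (TF) value minus mean
    scaled trisomic-water (TW) value is negative — proteins lower under
    fluoxetine in the trisomic background — and "cut2" the other.
    Without them, labels follow scipy's cluster numbering.
    """
    if len(tree.leaves) < 2:
        raise ConfigurationError("cannot cut a single-leaf tree")
    labels = hierarchy.fcluster(tree.linkage, t=2, criterion="maxclust")
    assign = pd.Series(
        np.where(labels == 1, "cut1", "cut2"), index=tree.leaves, name="cluster"
    )
    if scaled is not None and design is not None:
        tf = list(design.samples_in("TF"))
        tw = list(design.samples_in("TW"))
        deltas = {}
        for cut in ("cut1", "cut2"):
            block = scaled.data.loc[assign[assign == cut].index]
            deltas[cut] = float(
                np.nanmean(block[tf].to_numpy()) - np.nanmean(block[tw].to_numpy())
            )
        if deltas["cut1"] > deltas["cut2"]:
            assign = assign.map({"cut1": "cut2", "cut2": "cut1"})
    return assign


def confidence_ellipse(points: np.ndarray, level: float = 0.95) -> dict:
    """Bivariate-normal confidence ellipse parameters for one group's scores.

    Returns center, semi-axis lengths (sqrt of eigenvalue x chi2 quantile,
    2 df) and orientation in radians. Degenerate (zero-variance) point sets
    are flagged.
    """
    pts = np.asarray(points, dtype=float)
    center = pts.mean(axis=0)
    if len(pts) < 3:
        return {"center": center.tolist(), "degenerate": True}
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    if np.any(evals <= 1e-12):
        return {"center": center.tolist(), "degenerate": True}
    scale = chi2.ppf(level, df=2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    return {
        "center": center.tolist(),
        "semi_axes": np.sqrt(evals * scale).tolist(),
        "angle_rad": float(np.arctan2(evecs[1, 0], evecs[0, 0])),
        "degenerate": False,
    }


def boxplot_summary(matrix: QuantMatrix, design: Design) -> pd.DataFrame:
    """Five-number summaries per protein per design group.

    Quartiles use linear interpolation; whiskers extend to the most extreme
    observation within 1.5 IQR of the box (Tukey convention).
    """
    rows = []
    for code in ("EW", "EF", "TW", "TF"):
        cols = list(design.samples_in(code))
        block = matrix.data[cols]
        for prot in matrix.proteins:
            vals = block.loc[prot].dropna().to_numpy()
            if len(vals) == 0:
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            lo = vals[vals >= q1 - 1.5 * iqr].min()
            hi = vals[vals <= q3 + 1.5 * iqr].max()
            rows.append(
                {"protein": prot, "group": code, "whisker_low": lo, "q1": q1,
                 "median": med, "q3": q3, "whisker_high": hi, "n": len(vals)}
            )
    return pd.DataFrame(rows)


def export_plot_data(
    scaled: QuantMatrix,
    tree: Dendrogram,
    assignment: pd.Series,
    pc_scores: pd.DataFrame | None = None,
    design: Design | None = None,
    raw_matrix: QuantMatrix | None = None,
    score_components: tuple = ("PC3", "PC4"),
) -> dict:
    """Assemble plot-ready bundles: heatmap, score ellipses, boxplots.

    The heatmap table is in dendrogram leaf order with the cluster label as
    a column; columns stay in design order (samples are not clustered).
    """
    order = tree.leaf_order()
    heatmap = scaled.data.loc[order].copy()
    heatmap.insert(0, "cluster", assignment.loc[order])
    bundle = {"heatmap": heatmap}
    if pc_scores is not None and design is not None:
        cols = [c for c in score_components if c in pc_scores.columns]
        scores = pc_scores[cols].copy()
        scores["group"] = design.groups.loc[scores.index]
        ellipses = {
            code: confidence_ellipse(
                scores.loc[scores["group"] == code, cols].to_numpy()
            )
            for code in ("EW", "EF", "TW", "TF")
        }
        bundle["scores"] = scores
        bundle["ellipses"] = ellipses
    if raw_matrix is not None and design is not None:
        bundle["boxplots"] = boxplot_summary(raw_matrix, design)
    return bundle
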