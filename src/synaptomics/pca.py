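"""PCA of the protein x sample matrix with design-association testing.

Samples are the observations (16 of them) and proteins the variables;
each protein is mean-centered (no unit-variance scaling). Components are
extracted by NIPALS, which tolerates missing cells by restricting every
regression step to observed entries; on complete data it agrees with the
SVD solution component by component, up to sign.

Each retained component's sample scores are then fitted to the 2x2
genotype x treatment ANOVA, and a randomization scheme (sample-label
permutation by default, optional cell-wise shuffle) estimates the FDR of
the observed component-effect associations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ConfigurationError, Design, QuantMatrix

NIPALS_TOL = 1e-9
NIPALS_MAX_ITER = 500
DEFAULT_N_COMPONENTS = 7
DEFAULT_VARIANCE_TARGET = 0.76


@dataclass
class PCModel:
    """Loadings (protein x comp), scores (sample x comp), variance fractions."""

    loadings: pd.DataFrame
    scores: pd.DataFrame
    variance_fraction: np.ndarray
    n_components: int

    @property
    def r2x(self) -> float:
        """Cumulative proportion of (centered) variance explained."""
        return float(self.variance_fraction.sum())


def _nipals(X: np.ndarray, n_components: int, tol: float, max_iter: int):
    """NIPALS with missing-data support. X: samples x variables, centered."""
    Xw = X.copy()
    obs = ~np.isnan(Xw)
    Xz = np.where(obs, Xw, 0.0)
    ss_total = np.nansum(Xw**2)
    n, p = Xw.shape
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    varfrac = np.zeros(n_components)
    ss_prev = ss_total
    for k in range(n_components):
        # deterministic start: the variable (protein) with maximal variance
        col_var = np.nanvar(np.where(obs, Xw, np.nan), axis=0)
        j0 = int(np.nanargmax(col_var))
        t = np.where(obs[:, j0], Xw[:, j0], 0.0)
        if np.allclose(t, 0):
            t = np.ones(n)
        for _ in range(max_iter):
            # loadings: per-variable regression of X on t over observed cells
            denom_p = (obs * (t**2)[:, None]).sum(axis=0)
            denom_p[denom_p == 0] = np.finfo(float).eps
            pv = (Xz * t[:, None]).sum(axis=0) / denom_p
            pv /= np.linalg.norm(pv)
            denom_t = (obs * (pv**2)[None, :]).sum(axis=1)
            denom_t[denom_t == 0] = np.finfo(float).eps
            t_new = (Xz * pv[None, :]).sum(axis=1) / denom_t
            if np.linalg.norm(t_new - t) < tol * max(np.linalg.norm(t_new), 1.0):
                t = t_new
                break
            t = t_new
        # sign convention: largest-|loading| entry positive
        sign = np.sign(pv[np.argmax(np.abs(pv))]) or 1.0
        pv, t = pv * sign, t * sign
        T[:, k], P[:, k] = t, pv
        Xw = Xw - np.where(obs, np.outer(t, pv), 0.0)
        Xz = np.where(obs, Xw, 0.0)
        ss_now = np.nansum(Xw**2)
        varfrac[k] = (ss_prev - ss_now) / ss_total if ss_total > 0 else 0.0
        ss_prev = ss_now
    return T, P, varfrac


def fit_pca(
    matrix: QuantMatrix,
    n_components: int = DEFAULT_N_COMPONENTS,
    variance_target: float | None = None,
    tol: float = NIPALS_TOL,
    max_iter: int = NIPALS_MAX_ITER,
) -> PCModel:
    """Mean-center each protein and extract components by NIPALS.

    ``n_components`` caps the extraction; with ``variance_target`` set,
    extraction stops at the first component count whose cumulative
    variance fraction reaches the target (still capped by matrix rank).
    All-missing proteins are rejected — filter first.
    """
    data = matrix.data.to_numpy(dtype=float)
    n_prot, n_samp = data.shape
    if n_prot < 2 or n_samp < 2:
        raise ConfigurationError("need at least 2 proteins and 2 samples")
    if np.isnan(data).all(axis=1).any():
        bad = matrix.proteins[np.isnan(data).all(axis=1)][0]
        raise ConfigurationError(f"protein {bad!r} has no observed values; filter first")

    X = data.T  # samples x proteins
    center = np.nanmean(X, axis=0)
    Xc = X - center[None, :]
    max_rank = min(n_samp - 1, n_prot)
    k = min(n_components, max_rank)
    T, P, varfrac = _nipals(Xc, k, tol, max_iter)
    if variance_target is not None:
        cum = np.cumsum(varfrac)
        k_keep = int(np.searchsorted(cum, variance_target) + 1)
        k_keep = min(k_keep, k)
        T, P, varfrac = T[:, :k_keep], P[:, :k_keep], varfrac[:k_keep]
        k = k_keep
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCModel(
        loadings=pd.DataFrame(P, index=matrix.proteins, columns=comp_names),
        scores=pd.DataFrame(T, index=matrix.samples, columns=comp_names),
        variance_fraction=varfrac,
        n_components=k,
    )


def test_pc_design(model: PCModel, design: Design, alpha: float = 0.05) -> pd.DataFrame:
    """Two-way ANOVA of each component's sample scores on the design.

    Returns one row per component with p-values for genotype, treatment
    and their interaction, plus significance flags at ``alpha``.
    Zero-variance (degenerate) score vectors are flagged and given p = 1.
    """
    from .model import fit_factorial_anova

    scores = model.scores.loc[design.samples]
    score_matrix = QuantMatrix(scores.T)
    res = fit_factorial_anova(score_matrix, design)
    out = pd.DataFrame(
        {
            "p_genotype": res["p_genotype"],
            "p_treatment": res["p_treatment"],
            "p_interaction": res["p_interaction"],
            "degenerate": res["zero_variance"],
        },
        index=model.scores.columns,
    )
    for eff in ("genotype", "treatment", "interaction"):
        out[f"significant_{eff}"] = out[f"p_{eff}"] < alpha
    return out


@dataclass
class RandomizationResult:
    """Observed per-component tests plus randomization FDR estimates."""

    tests: pd.DataFrame
    fdr_pairs: float  # denominator = significant component-effect pairs
    fdr_components: float  # denominator = components with any significant effect
    n_observed_pairs: int
    n_observed_components: int
    null_mean_pairs: float
    null_mean_components: float
    p_exceedance: float
    no_discoveries: bool
    n_rand: int


def _randomize(matrix: QuantMatrix, rng: np.random.Generator, scheme: str) -> QuantMatrix:
    vals = matrix.values()
    if scheme == "labels":
        perm = rng.permutation(vals.shape[1])
        new = vals[:, perm]
    elif scheme == "cells":
        flat = vals.flatten()
        rng.shuffle(flat)
        new = flat.reshape(vals.shape)
    else:
        raise ConfigurationError(f"unknown randomization scheme {scheme!r}")
    return QuantMatrix(pd.DataFrame(new, index=matrix.proteins, columns=matrix.samples))


def randomization_fdr(
    matrix: QuantMatrix,
    design: Design,
    n_components: int = DEFAULT_N_COMPONENTS,
    n_rand: int = 200,
    alpha: float = 0.05,
    fdr_alpha: float = 0.01,
    seed: int = 0,
    scheme: str = "labels",
) -> RandomizationResult:
    """Estimate the FDR of PC-design associations by randomization.

    Fits PCA + per-component design ANOVA on the observed matrix, then on
    ``n_rand`` randomized matrices (column/sample labels permuted by
    default; ``scheme="cells"`` shuffles all cells). The FDR estimate is
    the plug-in ratio: mean significant count under randomization divided
    by the observed significant count, clamped to [0, 1]; reported both
    with component-effect pairs and with components as the counting unit.

    ``alpha`` drives the per-component significance flags; ``fdr_alpha``
    is the stricter cutoff used when counting discoveries for the ratio.
    The two are separate because the plug-in estimator's floor is the
    counting cutoff itself (times a small permutation-vs-F distortion):
    under label permutation each component-effect pair, structured or not,
    clears a cutoff a with probability close to a, so E[null count]/R can
    never drop meaningfully below a once every pair is discovered. A
    counting cutoff well below the p-values of genuinely associated
    components is what lets a real association show a small FDR.
    ``p_exceedance`` — the fraction of randomizations with at least as
    many discoveries as observed — is reported alongside as a scale-free
    summary of the same comparison.
    """
    if n_rand < 20:
        raise ConfigurationError("need n_rand >= 20 for a stable estimate")
    rng = np.random.default_rng(seed)

    def counts(tests: pd.DataFrame) -> tuple[int, int]:
        p = tests[["p_genotype", "p_treatment", "p_interaction"]].to_numpy()
        sig = p < fdr_alpha
        return int(sig.sum()), int(sig.any(axis=1).sum())

    model = fit_pca(matrix, n_components=n_components)
    tests = test_pc_design(model, design, alpha=alpha)
    obs_pairs, obs_comps = counts(tests)

    null_pairs = np.zeros(n_rand)
    null_comps = np.zeros(n_rand)
    for r in range(n_rand):
        rand_m = _randomize(matrix, rng, scheme)
        mdl = fit_pca(rand_m, n_components=n_components)
        null_pairs[r], null_comps[r] = counts(test_pc_design(mdl, design, alpha=alpha))

    def ratio(null_mean: float, observed: int) -> float:
        if observed == 0:
            return 0.0
        return float(min(null_mean / observed, 1.0))

    return RandomizationResult(
        tests=tests,
        fdr_pairs=ratio(null_pairs.mean(), obs_pairs),
        fdr_components=ratio(null_comps.mean(), obs_comps),
        n_observed_pairs=obs_pairs,
        n_observed_components=obs_comps,
        null_mean_pairs=float(null_pairs.mean()),
        null_mean_components=float(null_comps.mean()),
        p_exceedance=float((null_pairs >= max(obs_pairs, 1)).mean()),
        no_discoveries=obs_pairs == 0,
        n_rand=n_rand,
    )
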