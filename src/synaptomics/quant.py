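"""Spectrum-level reporter-ion processing.

Order of operations mirrors a standard isobaric-label workflow:

1. :func:`impurity_correct` — invert the lot-specific isotope purity matrix
   so each channel reads only its own label's signal.
2. :func:`iterative_normalize` — alternately remove per-sample and
   per-spectrum median offsets in log2 space until convergence.
3. :func:`preprocess_spectra` — log2 transform, prune spectra matched to
   multiple proteins, attach intensity weights.
4. :func:`rollup_proteins` — weighted median of each protein's spectra per
   sample, yielding the protein x sample log2 matrix.
5. :func:`permutation_de` — two-group permutation test with BH control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import ConfigurationError, QuantMatrix, SpectrumTable

# Spectra whose total intensity falls at or below this quantile of the
# distribution get the strongest down-weighting (see intensity_weights).
WEIGHT_PIVOT_QUANTILE = 0.10
NORMALIZE_TOL = 1e-8
NORMALIZE_MAX_ITER = 100
#: Exhaustive label enumeration is used when the number of distinct group
#: splits is at most this; otherwise Monte-Carlo with the given draw count.
EXHAUSTIVE_SPLIT_CAP = 20_000
MC_PERMUTATIONS = 10_000


@dataclass
class PurityMatrix:
    """Square channel x channel signal-fraction matrix.

    ``matrix[i, j]`` is the fraction of label *j*'s true signal observed in
    channel *i*. Columns may sum to less than 1 (signal lost outside the
    monitored window) but never more.
    """

    channels: list
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        k = len(self.channels)
        if m.shape != (k, k):
            raise ConfigurationError(
                f"purity matrix shape {m.shape} does not match {k} channels"
            )
        if (m.sum(axis=0) > 1 + 1e-9).any():
            raise ConfigurationError("purity matrix column sums exceed 1")
        if (np.diag(m) <= 0).any():
            raise ConfigurationError("purity matrix has non-positive diagonal")
        self.matrix = m

    @classmethod
    def identity(cls, channels) -> "PurityMatrix":
        return cls(list(channels), np.eye(len(channels)))

    @classmethod
    def from_impurity_table(cls, table: pd.DataFrame) -> "PurityMatrix":
        """Expand a per-channel impurity table into the square matrix.

        ``table`` is indexed by channel with columns ``minus2, minus1,
        plus1, plus2`` giving the percentage of that label's signal leaking
        into the channel 2 below / 1 below / 1 above / 2 above. The diagonal
        is 100 minus the printed leakages; leakage off either end of the
        channel list is lost signal.
        """
        channels = list(table.index)
        k = len(channels)
        m = np.zeros((k, k))
        offsets = {"minus2": -2, "minus1": -1, "plus1": 1, "plus2": 2}
        for j, ch in enumerate(channels):
            row = table.loc[ch]
            total_leak = 0.0
            for col, off in offsets.items():
                pct = float(row.get(col, 0.0) or 0.0)
                total_leak += pct
                i = j + off
                if 0 <= i < k:
                    m[i, j] = pct / 100.0
            m[j, j] = (100.0 - total_leak) / 100.0
        return cls(channels, m)

    def is_identity(self) -> bool:
        return np.allclose(self.matrix, np.eye(len(self.channels)))


def impurity_correct(
    spectra: SpectrumTable, purity: PurityMatrix
) -> tuple[SpectrumTable, pd.Series]:
    """Invert channel cross-talk: solve ``purity @ x = observed`` per spectrum.

    Negative solutions (possible with noisy data) are clamped to zero;
    the returned Series counts clamped channels per spectrum.

    Raises on singular purity matrices and channel mismatches.
    """
    if list(spectra.channels) != list(purity.channels):
        raise ConfigurationError("spectrum channels do not match purity matrix channels")
    if spectra.log2:
        raise ConfigurationError("impurity correction operates on raw intensities")
    obs = spectra.intensities.to_numpy(dtype=float)
    if np.linalg.matrix_rank(purity.matrix) < len(purity.channels):
        raise ConfigurationError("purity matrix is singular; cannot correct")
    filled = np.nan_to_num(obs, nan=0.0)
    corrected = np.linalg.solve(purity.matrix, filled.T).T
    clamped = (corrected < 0).sum(axis=1)
    corrected = np.clip(corrected, 0.0, None)
    corrected[np.isnan(obs)] = np.nan
    out = spectra.copy()
    out.intensities = pd.DataFrame(
        corrected, index=spectra.intensities.index, columns=spectra.intensities.columns
    )
    return out, pd.Series(clamped, index=spectra.intensities.index, name="n_clamped")


def iterative_normalize(
    spectra: SpectrumTable,
    tol: float = NORMALIZE_TOL,
    max_iter: int = NORMALIZE_MAX_ITER,
) -> tuple[SpectrumTable, int]:
    """Alternately remove per-sample and per-spectrum median offsets.

    Works in the log2 domain regardless of the table's current scale and
    returns a table on the same scale as the input. Iterates until the
    largest absolute adjustment in a full sweep drops below ``tol``.
    Returns the normalized table and the number of sweeps performed.
    """
    vals = spectra.intensities.to_numpy(dtype=float).copy()
    if not spectra.log2:
        if np.nanmin(vals) <= 0:
            raise ConfigurationError("non-positive intensities; cannot log-normalize")
        work = np.log2(vals)
    else:
        work = vals
    if np.isnan(work).all(axis=0).any():
        bad = spectra.intensities.columns[np.isnan(work).all(axis=0)][0]
        raise ConfigurationError(f"sample channel {bad!r} has no observed intensities")
    if np.isnan(work).all(axis=1).any():
        bad = spectra.intensities.index[np.isnan(work).all(axis=1)][0]
        raise ConfigurationError(f"spectrum {bad!r} has no observed intensities")

    n_iter = 0
    for _ in range(max_iter):
        n_iter += 1
        col_med = np.nanmedian(work, axis=0)
        col_adj = col_med - np.median(col_med)
        work -= col_adj[None, :]
        row_med = np.nanmedian(work, axis=1)
        row_adj = row_med - np.median(row_med)
        work -= row_adj[:, None]
        if max(np.abs(col_adj).max(), np.abs(row_adj).max()) < tol:
            break

    out = spectra.copy()
    result = work if spectra.log2 else np.power(2.0, work)
    out.intensities = pd.DataFrame(
        result, index=spectra.intensities.index, columns=spectra.intensities.columns
    )
    return out, n_iter


def intensity_weights(total_intensity: np.ndarray) -> np.ndarray:
    """Adaptive intensity weights: ``w = I / (I + c)``.

    ``c`` is the 10th percentile of spectrum total intensities, so the
    dimmest spectra — whose reporter ratios are noisiest — are down-weighted
    while bright spectra approach weight 1. Monotone non-decreasing in
    total intensity, always in (0, 1).
    """
    total = np.asarray(total_intensity, dtype=float)
    pivot = np.percentile(total, WEIGHT_PIVOT_QUANTILE * 100)
    pivot = max(pivot, np.finfo(float).tiny)
    return total / (total + pivot)


def preprocess_spectra(
    spectra: SpectrumTable, weight_fn=intensity_weights
) -> tuple[SpectrumTable, dict]:
    """Log2 transform, prune multi-protein spectra, attach weights.

    Zero or negative intensities cannot be log-transformed; they become
    missing and are counted. Returns the processed table plus a dict of
    counts: ``n_input``, ``n_pruned_shared``, ``n_retained``,
    ``n_nonpositive_cells``.
    """
    if spectra.log2:
        raise ConfigurationError("spectra already log2-transformed")
    vals = spectra.intensities.to_numpy(dtype=float).copy()
    nonpos = (vals <= 0) & ~np.isnan(vals)
    vals[nonpos] = np.nan
    shared = spectra.protein_ids.map(len) > 1
    keep = ~shared.to_numpy()

    with np.errstate(invalid="ignore"):
        logged = np.log2(vals[keep])
    totals = np.nansum(vals[keep], axis=1)
    weights = weight_fn(totals)

    index = spectra.intensities.index[keep]
    out = SpectrumTable(
        pd.DataFrame(logged, index=index, columns=spectra.intensities.columns),
        spectra.protein_ids[keep],
        dict(spectra.sample_map),
        log2=True,
        weights=pd.Series(weights, index=index, name="weight"),
    )
    counts = {
        "n_input": spectra.n_spectra,
        "n_pruned_shared": int(shared.sum()),
        "n_retained": int(keep.sum()),
        "n_nonpositive_cells": int(nonpos.sum()),
    }
    return out, counts


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Smallest value whose cumulative weight reaches half the total.

    Ties break toward the lower value. Equal weights reduce to the lower
    median for even counts.
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    cum = np.cumsum(w)
    half = cum[-1] / 2.0
    idx = int(np.searchsorted(cum, half, side="left"))
    return float(v[idx])


def rollup_proteins(spectra: SpectrumTable) -> tuple[QuantMatrix, pd.Series]:
    """Weighted-median rollup of spectra to a protein x sample matrix.

    Requires a preprocessed table (log2, single-protein assignments,
    weights attached). Entries with no observed spectra stay missing.
    Returns the matrix and per-protein spectrum counts.
    """
    if not spectra.log2:
        raise ConfigurationError("rollup requires log2-transformed spectra")
    if (spectra.protein_ids.map(len) > 1).any():
        raise ConfigurationError("rollup requires single-protein spectra (prune first)")
    weights = (
        spectra.weights
        if spectra.weights is not None
        else pd.Series(1.0, index=spectra.intensities.index)
    )
    samples = [spectra.sample_map[ch] for ch in spectra.channels]
    if len(spectra.intensities) == 0:
        return QuantMatrix(pd.DataFrame(columns=samples)), pd.Series(dtype=int)

    protein = spectra.protein_ids.map(lambda ids: ids[0])
    rows: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    vals = spectra.intensities.to_numpy(dtype=float)
    w_all = weights.to_numpy(dtype=float)
    for prot, idx in protein.groupby(protein).groups.items():
        loc = spectra.intensities.index.get_indexer(idx)
        block = vals[loc]
        w = w_all[loc]
        row = np.full(block.shape[1], np.nan)
        for j in range(block.shape[1]):
            ok = ~np.isnan(block[:, j])
            if ok.any():
                row[j] = weighted_median(block[ok, j], w[ok])
        rows[prot] = row
        counts[prot] = len(loc)
    order = sorted(rows)
    data = pd.DataFrame(
        np.vstack([rows[p] for p in order]), index=pd.Index(order, name="protein"),
        columns=samples,
    )
    return QuantMatrix(data), pd.Series(counts, name="n_spectra").loc[order]


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (NaN-tolerant)."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _group_splits(n_a: int, n_b: int, cap: int, n_mc: int, rng: np.random.Generator):
    """Yield boolean masks assigning n_a of (n_a+n_b) samples to group A."""
    from itertools import combinations
    from math import comb

    n = n_a + n_b
    n_splits = comb(n, n_a)
    if n_splits <= cap:
        for combo in combinations(range(n), n_a):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            yield mask
    else:
        for _ in range(n_mc):
            perm = rng.permutation(n)
            mask = np.zeros(n, dtype=bool)
            mask[perm[:n_a]] = True
            yield mask


def permutation_de(
    matrix: QuantMatrix,
    design,
    group_a: str,
    group_b: str,
    n_perm: int = MC_PERMUTATIONS,
    alpha: float = 0.05,
    seed: int = 0,
    exhaustive_cap: int = EXHAUSTIVE_SPLIT_CAP,
) -> pd.DataFrame:
    """Two-group permutation test on the difference of group means.

    Label splits are enumerated exhaustively when their number is at most
    ``exhaustive_cap`` (p = fraction of splits with |statistic| at least
    the observed; granularity 1/n_splits, minimum 2/n_splits by symmetry),
    otherwise ``n_perm`` Monte-Carlo draws with the add-one convention.
    BH q-values are computed across proteins; decisions are reported both
    at unadjusted ``alpha`` and at BH q < ``alpha``.
    """
    from math import comb

    a_samples = design.samples_in(group_a)
    b_samples = design.samples_in(group_b)
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ConfigurationError("each group needs at least 2 samples")
    missing = [s for s in list(a_samples) + list(b_samples) if s not in matrix.samples]
    if missing:
        raise ConfigurationError(f"design samples absent from matrix: {missing}")

    data = matrix.data[list(a_samples) + list(b_samples)].to_numpy(dtype=float)
    n_a, n_b = len(a_samples), len(b_samples)
    exhaustive = comb(n_a + n_b, n_a) <= exhaustive_cap
    rng = np.random.default_rng(seed)

    mean_a = np.nanmean(data[:, :n_a], axis=1)
    mean_b = np.nanmean(data[:, n_a:], axis=1)
    observed = mean_b - mean_a

    exceed = np.zeros(len(observed))
    n_splits = 0
    for mask in _group_splits(n_a, n_b, exhaustive_cap, n_perm, rng):
        n_splits += 1
        pa = np.nanmean(data[:, mask], axis=1)
        pb = np.nanmean(data[:, ~mask], axis=1)
        exceed += np.abs(pb - pa) >= np.abs(observed) - 1e-12
    if exhaustive:
        p = exceed / n_splits
    else:
        p = (1.0 + exceed) / (1.0 + n_splits)
    p = np.clip(p, 0.0, 1.0)
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": observed,
            "p": p,
            "q": q,
            "significant_nominal": p < alpha,
            "significant_bh": q < alpha,
        },
        index=matrix.proteins,
    )
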