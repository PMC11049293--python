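"""Synthetic data with the statistical structure the analysis assumes.

Emulates a 16-channel isobaric-label experiment on a balanced 2x2
genotype x treatment design (4 mice per cell): per-protein baselines,
planted genotype / treatment main effects, planted "rescue"-patterned
interactions, log-normal intensity noise (additive Gaussian in log2 space),
spectrum-level replication with channel cross-talk, spectrum-to-protein
ambiguity, and sporadic missingness. Ground truth records which proteins
carry which effects so recovery can be scored.

Interaction proteins split evenly between two mirror-image patterns:
"rescue-down" (depressed in trisomic-water, restored by fluoxetine) and
"rescue-up" (elevated in trisomic-water, suppressed by fluoxetine).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import (
    ConfigurationError,
    Design,
    GeneSetCollection,
    QuantMatrix,
    SpectrumTable,
)
from .quant import PurityMatrix

#: Default TMTpro-16plex-style channel names.
DEFAULT_CHANNELS = [
    "126", "127N", "127C", "128N", "128C", "129N", "129C", "130N",
    "130C", "131N", "131C", "132N", "132C", "133N", "133C", "134N",
]


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults emulate the study scale.

    Effects are in log2 units. ``spectra_per_protein`` is the mean of a
    shifted-Poisson count (minimum 1). ``mnar`` switches missingness from
    completely-at-random to intensity-dependent (dimmer cells more likely
    missing).
    """

    n_proteins: int = 2554
    n_per_group: int = 4
    frac_interaction: float = 0.05
    effect_size_log2: float = 1.0
    main_effect_log2: float = 0.5
    frac_main_genotype: float = 0.05
    frac_main_treatment: float = 0.05
    sigma_log2: float = 0.25
    baseline_log2_range: tuple = (8.0, 14.0)
    spectra_per_protein: float = 4.0
    spectrum_sigma_log2: float = 0.3
    frac_shared_spectra: float = 0.02
    missing_rate: float = 0.0
    mnar: bool = False
    use_reference_names: bool = True
    seed: int = 0
    channels: list = field(default_factory=lambda: list(DEFAULT_CHANNELS))

    def __post_init__(self) -> None:
        for name in ("frac_interaction", "frac_main_genotype", "frac_main_treatment",
                     "frac_shared_spectra", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.missing_rate >= 1:
            raise ConfigurationError("missing_rate must be < 1")
        if self.n_proteins <= 0 or self.n_per_group < 2:
            raise ConfigurationError("need n_proteins > 0 and n_per_group >= 2")
        for name in ("effect_size_log2", "main_effect_log2", "sigma_log2"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")
        if len(self.channels) != 4 * self.n_per_group:
            # plex must cover the design; regenerate generic channel names
            self.channels = [f"ch{i:02d}" for i in range(4 * self.n_per_group)]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted-effect labels and true cell means per protein."""

    interaction_true: pd.Series
    main_genotype_true: pd.Series
    main_treatment_true: pd.Series
    rescue_direction: pd.Series  # "down"|"up"|"" per protein
    cell_means: pd.DataFrame  # protein x (EW, EF, TW, TF), log2
    enriched_sets: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "interaction_true": self.interaction_true.astype(bool).to_dict(),
            "main_genotype_true": self.main_genotype_true.astype(bool).to_dict(),
            "main_treatment_true": self.main_treatment_true.astype(bool).to_dict(),
            "rescue_direction": self.rescue_direction.to_dict(),
            "cell_means": {p: self.cell_means.loc[p].to_dict() for p in self.cell_means.index},
            "enriched_sets": dict(self.enriched_sets),
        }


def _plant_cell_means(config: SimulationConfig, rng: np.random.Generator):
    n = config.n_proteins
    proteins = pd.Index([f"P{i:04d}" for i in range(n)], name="protein")
    lo, hi = config.baseline_log2_range
    baseline = rng.uniform(lo, hi, n)

    inter = np.zeros(n, dtype=bool)
    n_int = int(round(config.frac_interaction * n))
    inter[rng.choice(n, n_int, replace=False)] = True
    direction = np.where(inter, np.where(rng.random(n) < 0.5, "down", "up"), "")

    main_g = np.zeros(n, dtype=bool)
    main_g[rng.choice(n, int(round(config.frac_main_genotype * n)), replace=False)] = True
    main_t = np.zeros(n, dtype=bool)
    main_t[rng.choice(n, int(round(config.frac_main_treatment * n)), replace=False)] = True

    cm = pd.DataFrame(
        {c: baseline.copy() for c in ("EW", "EF", "TW", "TF")}, index=proteins
    )
    g_sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    t_sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    cm.loc[main_g, "TW"] += (g_sign * config.main_effect_log2)[main_g]
    cm.loc[main_g, "TF"] += (g_sign * config.main_effect_log2)[main_g]
    cm.loc[main_t, "EF"] += (t_sign * config.main_effect_log2)[main_t]
    cm.loc[main_t, "TF"] += (t_sign * config.main_effect_log2)[main_t]
    # rescue pattern: TW shifted away from EW, TF pulled back to baseline
    delta = config.effect_size_log2
    down = inter & (direction == "down")
    up = inter & (direction == "up")
    cm.loc[down, "TW"] -= delta
    cm.loc[up, "TW"] += delta

    truth = GroundTruth(
        interaction_true=pd.Series(inter, index=proteins),
        main_genotype_true=pd.Series(main_g, index=proteins),
        main_treatment_true=pd.Series(main_t, index=proteins),
        rescue_direction=pd.Series(direction, index=proteins),
        cell_means=cm,
    )
    if config.use_reference_names:
        _apply_reference_names(truth)
    return truth.cell_means.index, truth.cell_means, truth


def _apply_reference_names(truth: GroundTruth) -> None:
    """Rename some simulated proteins after published markers/table proteins.

    Table proteins (known rescue directions) take over interaction-true
    proteins with the matching planted direction, best-effort while the
    direction pools last; the risk-marker panel takes over null proteins.
    Deterministic: pools are consumed in index order.
    """
    from .io import default_direction_expectations, default_markers

    index = truth.cell_means.index
    rename: dict[str, str] = {}
    pools = {
        "down": list(index[(truth.rescue_direction == "down").to_numpy()]),
        "up": list(index[(truth.rescue_direction == "up").to_numpy()]),
    }
    expectations = default_direction_expectations()
    for prot, row in expectations.iterrows():
        want = "down" if row["tw_vs_ew"] == "down" else "up"
        if pools[want]:
            rename[pools[want].pop(0)] = prot
    null_pool = [
        p for p in index
        if not truth.interaction_true[p] and not truth.main_genotype_true[p]
        and not truth.main_treatment_true[p] and p not in rename
    ]
    for marker in default_markers():
        if marker in expectations.index or not null_pool:
            continue  # already named via the direction table
        rename[null_pool.pop(0)] = marker

    new_index = pd.Index([rename.get(p, p) for p in index], name=index.name)
    for attr in ("interaction_true", "main_genotype_true", "main_treatment_true",
                 "rescue_direction"):
        getattr(truth, attr).index = new_index
    truth.cell_means.index = new_index


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[SpectrumTable, QuantMatrix, GroundTruth, Design]:
    """Generate a matched spectrum table, protein matrix and ground truth.

    The protein-level matrix is cell mean + N(0, sigma^2) per sample; each
    protein's spectra scatter around its per-sample value with an extra
    spectrum-level offset, so the per-protein median of log2 spectrum
    intensities tracks the matrix entry. A fraction of spectra is assigned
    to two proteins (ambiguity the preprocessing prunes). Missingness, if
    requested, is injected into the protein matrix.
    """
    rng = np.random.default_rng(config.seed)
    proteins, cm, truth = _plant_cell_means(config, rng)
    design = Design.balanced(config.n_per_group, channels=config.channels)
    groups = design.groups

    true_sample = cm[groups.to_numpy()].to_numpy()  # protein x sample
    noise = rng.normal(0.0, config.sigma_log2, true_sample.shape)
    matrix_vals = true_sample + noise
    matrix = QuantMatrix(
        pd.DataFrame(matrix_vals, index=proteins, columns=design.samples)
    )

    # spectrum level: counts ~ 1 + Poisson(mean-1), offsets shared across channels
    lam = max(config.spectra_per_protein - 1.0, 0.0)
    counts = 1 + rng.poisson(lam, config.n_proteins)
    prot_idx = np.repeat(np.arange(config.n_proteins), counts)
    n_spec = len(prot_idx)
    offsets = rng.normal(0.0, config.spectrum_sigma_log2, n_spec)
    spec_vals = matrix_vals[prot_idx] + offsets[:, None]
    intens = np.power(2.0, spec_vals)

    spectrum_ids = pd.Index([f"S{i:06d}" for i in range(n_spec)], name="spectrum_id")
    assignments = [(proteins[i],) for i in prot_idx]
    n_shared = int(round(config.frac_shared_spectra * n_spec))
    if n_shared and config.n_proteins > 1:
        for s in rng.choice(n_spec, n_shared, replace=False):
            other = rng.integers(config.n_proteins)
            if proteins[other] not in assignments[s]:
                assignments[s] = assignments[s] + (proteins[other],)
    sample_map = dict(zip(config.channels, design.samples))
    channel_cols = pd.Index(config.channels)
    spectra = SpectrumTable(
        pd.DataFrame(intens, index=spectrum_ids, columns=channel_cols),
        pd.Series(assignments, index=spectrum_ids, name="protein_ids"),
        sample_map,
    )

    if config.missing_rate > 0:
        matrix = inject_missingness(
            matrix, config.missing_rate, seed=int(rng.integers(2**31)), mnar=config.mnar
        )
    return spectra, matrix, truth, design


def mix_impurities(spectra: SpectrumTable, purity: PurityMatrix) -> SpectrumTable:
    """Forward model of channel cross-talk: observed = purity @ true.

    The exact inverse of :func:`synaptomics.quant.impurity_correct` for any
    full-rank purity matrix.
    """
    if list(spectra.channels) != list(purity.channels):
        raise ConfigurationError("spectrum channels do not match purity matrix channels")
    if spectra.log2:
        raise ConfigurationError("impurity mixing operates on raw intensities")
    true = spectra.intensities.to_numpy(dtype=float)
    mixed = (purity.matrix @ np.nan_to_num(true, nan=0.0).T).T
    mixed[np.isnan(true)] = np.nan
    out = spectra.copy()
    out.intensities = pd.DataFrame(
        mixed, index=spectra.intensities.index, columns=spectra.intensities.columns
    )
    return out


def simulate_gene_sets(
    truth: GroundTruth,
    n_sets: int = 20,
    size_range: tuple = (10, 80),
    enrichment_spec: dict | None = None,
    enrichment_purity: float = 0.9,
    seed: int = 0,
) -> GeneSetCollection:
    """Random gene sets over the simulated protein universe.

    ``enrichment_spec`` maps set names to a truth flag
    (``interaction_true`` / ``main_genotype_true`` / ``main_treatment_true``);
    those sets draw ``enrichment_purity`` of their members from flagged
    proteins. All other sets are uniform draws. Records the planted-
    enrichment labels on the returned truth object.
    """
    rng = np.random.default_rng(seed)
    universe = truth.interaction_true.index
    lo, hi = size_range
    if lo < 2 or hi > len(universe):
        raise ConfigurationError("size_range outside [2, n_proteins]")
    enrichment_spec = enrichment_spec or {}
    unknown = set(enrichment_spec.values()) - {
        "interaction_true", "main_genotype_true", "main_treatment_true"
    }
    if unknown:
        raise ConfigurationError(f"unknown truth flags in enrichment spec: {unknown}")

    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    names = list(enrichment_spec) + [
        f"RANDOM_SET_{i:03d}" for i in range(n_sets - len(enrichment_spec))
    ]
    for name in names:
        size = int(rng.integers(lo, hi + 1))
        if name in enrichment_spec:
            flag = getattr(truth, enrichment_spec[name])
            pool_true = universe[flag.to_numpy()]
            if enrichment_spec[name] == "interaction_true" and len(pool_true):
                # pathways move coherently: draw from one rescue direction,
                # else the set straddles both tails of a signed ranking and
                # carries no enrichment signal
                dirs = truth.rescue_direction.loc[pool_true]
                n_down = int((dirs == "down").sum())
                majority = "down" if n_down >= len(pool_true) - n_down else "up"
                pool_true = pool_true[(dirs == majority).to_numpy()]
            pool_false = universe[~flag.to_numpy()]
            n_true = min(int(round(enrichment_purity * size)), len(pool_true))
            members = list(rng.choice(pool_true, n_true, replace=False))
            members += list(rng.choice(pool_false, size - n_true, replace=False))
            descriptions[name] = f"planted:{enrichment_spec[name]}"
            truth.enriched_sets[name] = enrichment_spec[name]
        else:
            members = list(rng.choice(universe, size, replace=False))
            descriptions[name] = "uniform"
        sets[name] = frozenset(members)
    return GeneSetCollection(sets, descriptions)


def inject_missingness(
    matrix: QuantMatrix, rate: float, seed: int = 0, mnar: bool = False
) -> QuantMatrix:
    """Set cells missing with probability ``rate``.

    MCAR by default. With ``mnar=True`` the per-cell probability scales
    with how dim the cell is relative to the matrix (rank-based), keeping
    the overall expected rate equal to ``rate``.
    """
    if not 0 <= rate < 1:
        raise ConfigurationError("rate must be in [0, 1)")
    if rate == 0:
        return matrix.copy()
    rng = np.random.default_rng(seed)
    vals = matrix.values().copy()
    if mnar:
        flat = vals.flatten()
        ranks = stats_rankdata_desc(flat)
        prob = 2.0 * rate * ranks / len(flat)
        mask = rng.random(len(flat)) < prob
        mask = mask.reshape(vals.shape)
    else:
        mask = rng.random(vals.shape) < rate
    vals[mask] = np.nan
    return QuantMatrix(pd.DataFrame(vals, index=matrix.proteins, columns=matrix.samples))


def stats_rankdata_desc(x: np.ndarray) -> np.ndarray:
    """Rank with 1 = brightest ... n = dimmest (dim cells at high rank)."""
    from scipy.stats import rankdata

    return len(x) + 1 - rankdata(x, method="average")
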