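"""Preranked gene-set enrichment analysis.

Proteins are ranked by a chosen metric — a principal-component loading, or
the signed significance score (−log10 p) x log2FC from a contrast — and
each gene set is scored with the classic weighted Kolmogorov–Smirnov
running sum: hits step up in proportion to |metric|^w, misses step down by
1/(N − N_hits). The enrichment score (ES) is the signed maximum deviation
of the running sum. Significance comes from gene-label permutations (random
sets of matched size): NES = ES / mean |null ES| of the same sign, with an
add-one permutation p-value and BH adjustment across sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ConfigurationError, GeneSetCollection
from .quant import bh_adjust

DEFAULT_WEIGHT = 1.0
DEFAULT_N_PERM = 1000
MIN_SET_SIZE = 5


@dataclass
class RankedList:
    """Protein identifiers ordered by a descending ranking metric."""

    metric: pd.Series  # index: protein, values: metric, sorted descending
    source: str = ""

    def __post_init__(self) -> None:
        if self.metric.index.has_duplicates:
            raise ConfigurationError("duplicate proteins in ranked list")
        if not np.isfinite(self.metric.to_numpy()).all():
            raise ConfigurationError("non-finite ranking metric values")
        vals = self.metric.to_numpy()
        if (np.diff(vals) > 0).any():
            raise ConfigurationError("ranked list not in descending order")

    @property
    def proteins(self) -> pd.Index:
        return self.metric.index

    def __len__(self) -> int:
        return len(self.metric)


def rank_proteins(
    values: pd.Series, source: str = "", drop_missing: bool = True
) -> tuple[RankedList, int]:
    """Sort a protein -> metric mapping into a RankedList.

    Descending by metric; ties broken by protein identifier (lexicographic),
    so the order is deterministic. Missing metrics are excluded and counted.
    """
    n_missing = int(values.isna().sum())
    if n_missing and not drop_missing:
        raise ConfigurationError("missing metric values present")
    v = values.dropna()
    order = sorted(v.index, key=lambda prot: (-v[prot], str(prot)))
    return RankedList(v.loc[order], source=source), n_missing


def enrichment_score(
    ranked: RankedList, gene_set, weight_exponent: float = DEFAULT_WEIGHT
) -> tuple[float, np.ndarray]:
    """Weighted-KS enrichment score and the full running-sum profile.

    Hits add |metric|^w normalized over in-set hits; misses subtract
    1/(N − N_hits). ES is the running sum's most extreme value (signed).
    """
    members = frozenset(gene_set) & frozenset(ranked.proteins)
    n = len(ranked)
    n_hits = len(members)
    if n_hits == 0:
        raise ConfigurationError("gene set does not intersect the ranked universe")
    if n_hits == n:
        raise ConfigurationError("gene set covers the whole universe; miss step undefined")
    is_hit = ranked.proteins.isin(members)
    return _es_from_mask(ranked.metric.to_numpy(), is_hit, weight_exponent)


def _es_from_mask(metric: np.ndarray, is_hit: np.ndarray, w: float):
    n = len(metric)
    n_hits = int(is_hit.sum())
    hit_w = np.abs(metric[is_hit]) ** w
    denom = hit_w.sum()
    steps = np.where(is_hit, 0.0, -1.0 / (n - n_hits))
    if denom > 0:
        steps[is_hit] = np.abs(metric[is_hit]) ** w / denom
    else:  # all hit metrics zero: fall back to equal hit steps
        steps[is_hit] = 1.0 / n_hits
    running = np.cumsum(steps)
    # extremum = earliest point within float tolerance of the max deviation,
    # so exact ties (e.g. +x early vs -x late) resolve deterministically
    deviation = np.abs(running)
    idx = int(np.argmax(deviation >= deviation.max() - 1e-12))
    return float(running[idx]), running


def gsea(
    ranked: RankedList,
    collection: GeneSetCollection,
    n_perm: int = DEFAULT_N_PERM,
    weight_exponent: float = DEFAULT_WEIGHT,
    seed: int = 0,
    min_size: int = MIN_SET_SIZE,
) -> pd.DataFrame:
    """Score every set in a collection; permutation NES, p and BH q.

    Null ES values come from random gene sets of matched size drawn from
    the ranked universe (gene-label permutation). Sets intersecting the
    universe in fewer than ``min_size`` proteins are skipped and reported
    with NaN scores. Results are sorted by NES, descending.
    """
    if n_perm < 100:
        raise ConfigurationError("need n_perm >= 100")
    rng = np.random.default_rng(seed)
    metric = ranked.metric.to_numpy()
    n = len(ranked)
    prot_pos = {p: i for i, p in enumerate(ranked.proteins)}

    rows = []
    # share one null ensemble per distinct effective set size
    null_cache: dict[int, np.ndarray] = {}
    for name, members in collection:
        inset = [prot_pos[p] for p in members if p in prot_pos]
        k = len(inset)
        if k < min_size or k >= n:
            rows.append(
                {"name": name, "size": k, "ES": np.nan, "NES": np.nan,
                 "p": np.nan, "q": np.nan, "skipped": True,
                 "no_same_sign_null": False, "leading_edge": ""}
            )
            continue
        mask = np.zeros(n, dtype=bool)
        mask[inset] = True
        es, running = _es_from_mask(metric, mask, weight_exponent)

        if k not in null_cache:
            null = np.empty(n_perm)
            for b in range(n_perm):
                null_mask = np.zeros(n, dtype=bool)
                null_mask[rng.choice(n, k, replace=False)] = True
                null[b], _ = _es_from_mask(metric, null_mask, weight_exponent)
            null_cache[k] = null
        null = null_cache[k]

        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if len(same_sign) == 0:
            nes = np.nan
            p = 1.0 / (n_perm + 1)
            flagged = True
        else:
            nes = es / np.abs(same_sign).mean()
            p = (1.0 + (np.abs(same_sign) >= abs(es)).sum()) / (1.0 + len(same_sign))
            flagged = False

        # leading edge: hits at or before the running-sum extremum
        peak = int(np.argmax(np.abs(running)))
        if es >= 0:
            le_idx = [i for i in inset if i <= peak]
        else:
            le_idx = [i for i in inset if i > peak]
        leading = ";".join(str(ranked.proteins[i]) for i in sorted(le_idx))
        rows.append(
            {"name": name, "size": k, "ES": es, "NES": nes, "p": p,
             "q": np.nan, "skipped": False, "no_same_sign_null": flagged,
             "leading_edge": leading}
        )
    out = pd.DataFrame(rows).set_index("name")
    tested = ~out["skipped"]
    out.loc[tested, "q"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    return out.sort_values("NES", ascending=False)
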