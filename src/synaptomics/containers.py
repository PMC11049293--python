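"""Shared in-memory containers for the pipeline.

The central analysis object is :class:`QuantMatrix`, a protein x sample table
of log2 quantities with missing values, annotated by a :class:`Design` that
maps each sample to one cell of the 2x2 genotype x treatment layout.
Spectrum-level data (the raw quantification substrate) live in
:class:`SpectrumTable`; gene sets for enrichment in
:class:`GeneSetCollection`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPES = ("euploid", "trisomic")
TREATMENTS = ("water", "fluoxetine")

#: Canonical group codes for the four design cells.
GROUP_CODES = {
    ("euploid", "water"): "EW",
    ("euploid", "fluoxetine"): "EF",
    ("trisomic", "water"): "TW",
    ("trisomic", "fluoxetine"): "TF",
}


class ConfigurationError(ValueError):
    """Invalid configuration or malformed input."""


@dataclass
class Design:
    """Sample sheet: maps each sample to its genotype and treatment.

    Parameters
    ----------
    table : pd.DataFrame
        Indexed by sample_id, with columns ``genotype`` in
        {euploid, trisomic} and ``treatment`` in {water, fluoxetine}.
        May carry an optional ``channel`` column tying each sample to a
        reporter channel.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"genotype", "treatment"} - set(self.table.columns)
        if missing:
            raise ConfigurationError(f"design table missing columns: {sorted(missing)}")
        bad_g = set(self.table["genotype"]) - set(GENOTYPES)
        bad_t = set(self.table["treatment"]) - set(TREATMENTS)
        if bad_g or bad_t:
            raise ConfigurationError(
                f"unknown factor levels: genotype={sorted(bad_g)} treatment={sorted(bad_t)}"
            )
        if self.table.index.has_duplicates:
            raise ConfigurationError("duplicate sample ids in design")
        groups = self.groups
        empty = [g for g in GROUP_CODES.values() if (groups == g).sum() == 0]
        if empty:
            raise ConfigurationError(f"empty design cells: {empty}")

    @property
    def samples(self) -> pd.Index:
        return self.table.index

    @property
    def groups(self) -> pd.Series:
        """Per-sample group code (EW/EF/TW/TF)."""
        return pd.Series(
            [
                GROUP_CODES[(g, t)]
                for g, t in zip(self.table["genotype"], self.table["treatment"])
            ],
            index=self.table.index,
            name="group",
        )

    def samples_in(self, group: str) -> pd.Index:
        if group not in GROUP_CODES.values():
            raise ConfigurationError(f"unknown group label {group!r}")
        return self.table.index[self.groups == group]

    def n_per_group(self) -> dict[str, int]:
        return self.groups.value_counts().to_dict()

    @classmethod
    def balanced(cls, n_per_group: int = 4, channels: list[str] | None = None) -> "Design":
        """Balanced 2x2 design with ``n_per_group`` samples per cell.

        Sample ids are ``<code><i>`` (EW1..EW4, EF1..., TW..., TF...), in the
        fixed cell order EW, EF, TW, TF.
        """
        rows = []
        for (g, t), code in GROUP_CODES.items():
            for i in range(1, n_per_group + 1):
                rows.append((f"{code}{i}", g, t))
        table = pd.DataFrame(rows, columns=["sample_id", "genotype", "treatment"])
        table = table.set_index("sample_id")
        if channels is not None:
            if len(channels) != len(table):
                raise ConfigurationError("channel list does not match sample count")
            table["channel"] = channels
        return cls(table)


@dataclass
class QuantMatrix:
    """Protein x sample matrix of log2 quantities; NaN marks missing."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ConfigurationError(f"duplicate protein ids: {dup}")
        vals = self.data.to_numpy(dtype=float, copy=False)
        if np.isinf(vals).any():
            raise ConfigurationError("non-finite (infinite) quantities present")

    @property
    def proteins(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def missing_per_protein(self) -> pd.Series:
        return self.data.isna().sum(axis=1)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(self.data.copy())

    def subset(self, proteins) -> "QuantMatrix":
        return QuantMatrix(self.data.loc[proteins])


@dataclass
class SpectrumTable:
    """Spectrum-level reporter-ion intensities with protein assignments.

    ``intensities`` is spectrum x channel (non-negative, NaN = missing);
    ``protein_ids`` maps each spectrum to one or more proteins;
    ``sample_map`` ties each channel to exactly one sample id.
    ``log2`` records whether intensities are already log2-transformed.
    """

    intensities: pd.DataFrame
    protein_ids: pd.Series  # spectrum_id -> tuple[str, ...]
    sample_map: dict[str, str]
    log2: bool = False
    weights: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.protein_ids.index):
            raise ConfigurationError("intensities and protein_ids indices differ")
        unmapped = set(self.intensities.columns) - set(self.sample_map)
        if unmapped:
            raise ConfigurationError(f"channels without sample mapping: {sorted(unmapped)}")
        if not self.log2:
            vals = self.intensities.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ConfigurationError("negative raw intensities")

    @property
    def channels(self) -> pd.Index:
        return self.intensities.columns

    @property
    def n_spectra(self) -> int:
        return len(self.intensities)

    def copy(self) -> "SpectrumTable":
        return SpectrumTable(
            self.intensities.copy(),
            self.protein_ids.copy(),
            dict(self.sample_map),
            self.log2,
            None if self.weights is None else self.weights.copy(),
        )


@dataclass
class GeneSetCollection:
    """Named gene sets with free-text descriptions (GMT semantics)."""

    sets: dict[str, frozenset]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) < 1:
                raise ConfigurationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def sizes(self) -> dict[str, int]:
        return {name: len(m) for name, m in self.sets.items()}
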