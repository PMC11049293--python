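"""Readers, writers and reporting helpers.

Exchange formats are deliberately plain: TSV for matrices, spectra and
stats tables; GMT for gene sets; CSV for the sample sheet and per-channel
impurity percentages; JSON for ground truth and provenance. Every reader
validates and names the offending row or column on error, and write→read
round-trips are lossless.

Also houses two small biology-facing reports: marker presence (a panel of
Down-syndrome-related risk proteins expected in the synaptic proteome)
and direction concordance against published up/down expectations for the
trisomic-water vs euploid-water and trisomic-fluoxetine vs trisomic-water
contrasts.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

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


# ---------------------------------------------------------------- matrices

def write_quant_tsv(matrix: QuantMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="protein", na_rep="NA")


def read_quant_tsv(path) -> QuantMatrix:
    df = pd.read_csv(path, sep="\t", index_col="protein", na_values=["NA"],
                     float_precision="round_trip")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ConfigurationError(f"{path}: duplicate protein rows: {dup}")
    return QuantMatrix(df.astype(float))


# ------------------------------------------------------------ sample sheet

def write_sample_sheet(design: Design, path) -> None:
    out = design.table.copy()
    out.to_csv(path, index_label="sample_id")


def read_sample_sheet(path) -> Design:
    df = pd.read_csv(path, index_col="sample_id", dtype=str)
    try:
        return Design(df)
    except ConfigurationError as err:
        raise ConfigurationError(f"{path}: {err}") from err


# ----------------------------------------------------------------- spectra

def write_spectra_tsv(spectra: SpectrumTable, path) -> None:
    out = spectra.intensities.copy()
    out.insert(0, "protein_ids", spectra.protein_ids.map(";".join))
    out.to_csv(path, sep="\t", index_label="spectrum_id", na_rep="NA")


def read_spectra_tsv(path, sample_map: dict, log2: bool = False) -> SpectrumTable:
    df = pd.read_csv(path, sep="\t", index_col="spectrum_id", na_values=["NA"],
                     float_precision="round_trip")
    if "protein_ids" not in df.columns:
        raise ConfigurationError(f"{path}: missing protein_ids column")
    proteins = df.pop("protein_ids").map(lambda s: tuple(str(s).split(";")))
    return SpectrumTable(df.astype(float), proteins, dict(sample_map), log2=log2)


# ------------------------------------------------------------------ purity

def read_impurity_csv(path) -> PurityMatrix:
    """Per-channel impurity percentages (columns minus2,minus1,plus1,plus2)."""
    df = pd.read_csv(path, index_col=0)
    df.columns = [c.strip() for c in df.columns]
    return PurityMatrix.from_impurity_table(df)


# -------------------------------------------------------------------- GMT

def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ConfigurationError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 member"
                )
            name, desc, *members = parts
            if name in sets:
                raise ConfigurationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(members)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


# ------------------------------------------------------------------- JSON

def write_ground_truth(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.ndarray, pd.Index)):
        return list(x)
    if isinstance(x, (pd.Series,)):
        return x.to_dict()
    raise TypeError(f"not JSON-serializable: {type(x)}")


# ------------------------------------------------------- built-in fixtures

def _data_path(name: str) -> Path:
    return Path(resources.files("synaptomics").joinpath("data", name))


def default_markers() -> list[str]:
    """Down-syndrome-related risk proteins expected in the synaptic proteome."""
    return pd.read_csv(_data_path("ds_risk_markers.tsv"), sep="\t")["marker"].tolist()


def default_direction_expectations() -> pd.DataFrame:
    """Published up/down expectations for the two rescue contrasts."""
    return pd.read_csv(_data_path("rescue_directions.tsv"), sep="\t").set_index("protein")


# ----------------------------------------------------------------- reports

def marker_presence(
    matrix: QuantMatrix, design: Design | None = None, markers: list[str] | None = None
) -> pd.DataFrame:
    """Presence check for a marker panel, with per-group means if present."""
    if markers is None:
        markers = default_markers()
    rows = []
    for m in markers:
        present = m in matrix.proteins
        row = {"marker": m, "present": present}
        if present and design is not None:
            for code in ("EW", "EF", "TW", "TF"):
                cols = list(design.samples_in(code))
                row[f"mean_{code}"] = float(matrix.data.loc[m, cols].mean())
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["present"], index=pd.Index([], name="marker"))
    return pd.DataFrame(rows).set_index("marker")


def direction_concordance(
    contrast_tw_ew: pd.DataFrame,
    contrast_tf_tw: pd.DataFrame,
    expectations: pd.DataFrame | None = None,
) -> dict:
    """Sign agreement of estimated fold changes with expected directions.

    ``expectations`` has one row per protein with columns ``tw_vs_ew`` and
    ``tf_vs_tw``, each "up" or "down". Proteins absent from a contrast
    table are counted as untested. Returns per-protein detail plus overall
    concordance fraction (concordant / tested comparisons); with no
    applicable expectations the fraction is reported as None.
    """
    if expectations is None:
        expectations = default_direction_expectations()
    detail = []
    n_tested = n_concordant = n_untested = 0
    for prot, row in expectations.iterrows():
        for contrast, col in ((contrast_tw_ew, "tw_vs_ew"), (contrast_tf_tw, "tf_vs_tw")):
            expected = row[col]
            if expected not in ("up", "down"):
                raise ConfigurationError(f"{prot}: bad direction {expected!r}")
            if len(contrast) == 0 or prot not in contrast.index:
                detail.append({"protein": prot, "contrast": col, "status": "untested"})
                n_untested += 1
                continue
            fc = contrast.loc[prot, "log2fc"]
            observed = "up" if fc > 0 else ("down" if fc < 0 else "flat")
            ok = observed == expected
            n_tested += 1
            n_concordant += ok
            detail.append(
                {"protein": prot, "contrast": col, "expected": expected,
                 "observed": observed, "log2fc": float(fc), "status": "concordant" if ok else "discordant"}
            )
    return {
        "detail": pd.DataFrame(detail),
        "n_tested": n_tested,
        "n_concordant": n_concordant,
        "n_untested": n_untested,
        "concordance": (n_concordant / n_tested) if n_tested else None,
    }
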