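"""Reading, writing and harmonizing cytokine panels; model serialization.

File dialect: delimiter auto-detected from the extension (``.tsv`` → tab,
``.csv`` → comma, anything else → tab); UTF-8; ``NA`` or an empty cell is a
missing value.  Panel tables carry samples as rows, analytes as columns,
with the sample id in the first column.  Fitted models are stored as JSON
with an explicit schema version.
"""

from __future__ import annotations

import json
import warnings
from importlib import resources
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .panel import AnalyteMap, CytokinePanel, PanelError
from .pls import PLSModel

__all__ = [
    "read_panel",
    "write_panel",
    "harmonize",
    "serialize_model",
    "deserialize_model",
    "read_analyte_map",
    "default_human_mouse_map",
    "load_patient_roster",
    "load_control_roster",
    "cohort_counts",
    "ModelFormatError",
]

_NA_VALUES = ["NA", ""]


class ModelFormatError(ValueError):
    """Raised when a serialized model file is malformed."""


def _sep(path: Union[str, Path]) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _read_table(path: Union[str, Path], **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep(path), index_col=0, na_values=_NA_VALUES,
                       keep_default_na=False, encoding="utf-8", **kw)


def read_panel(table_path: Union[str, Path], metadata_path: Union[str, Path]) -> CytokinePanel:
    """Read a concentration table and its metadata into a validated panel.

    Raises :class:`PanelError` on duplicate sample ids, a metadata row
    missing for any sample, or negative concentrations.
    """
    conc = _read_table(table_path)
    conc.index = conc.index.astype(str)
    meta = _read_table(metadata_path, dtype={})
    meta.index = meta.index.astype(str)
    if meta.index.has_duplicates:
        dupes = meta.index[meta.index.duplicated()].unique().tolist()
        raise PanelError(f"duplicate sample ids in metadata: {dupes}")
    try:
        conc = conc.astype(float)
    except ValueError as exc:
        raise PanelError(f"non-numeric concentration value: {exc}") from exc
    return CytokinePanel(conc, meta)


def write_panel(panel: CytokinePanel, table_path: Union[str, Path],
                metadata_path: Union[str, Path]) -> None:
    """Write a panel back to delimited text (inverse of :func:`read_panel`)."""
    panel.concentrations.to_csv(table_path, sep=_sep(table_path), na_rep="NA",
                                index_label="sample")
    panel.metadata.to_csv(metadata_path, sep=_sep(metadata_path), na_rep="NA",
                          index_label="sample")


def read_analyte_map(path: Union[str, Path]) -> AnalyteMap:
    """Read a two-column delimited name map (side A, side B)."""
    df = pd.read_csv(path, sep=_sep(path), encoding="utf-8")
    if df.shape[1] < 2:
        raise PanelError("analyte map needs two columns")
    return AnalyteMap(list(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str))))


def harmonize(panel_a: CytokinePanel, panel_b: CytokinePanel,
              amap: AnalyteMap) -> tuple[CytokinePanel, CytokinePanel]:
    """Restrict two panels to their mapped (shared) analytes.

    Both returned panels keep their own analyte names but carry columns in
    the map's order, so column *k* of one panel corresponds to column *k* of
    the other.  Sample rows are untouched.
    """
    if len(amap) == 0:
        raise PanelError("analyte map is empty: no shared analytes")
    resolved = amap.resolve(panel_a, panel_b)
    names_a = [a for a, _ in resolved]
    names_b = [b for _, b in resolved]
    return panel_a.subset_analytes(names_a), panel_b.subset_analytes(names_b)


# -- model (de)serialization ----------------------------------------------

_SCHEMA_VERSION = 1

_ARRAY_FIELDS = ("weights", "x_loadings", "y_loadings", "x_rotations",
                 "scores_raw", "rotation", "x_mean", "x_sd")
_SCALAR_FIELDS = ("n_components", "y_mean", "case_label")
_LIST_FIELDS = ("analyte_names", "sample_ids")


def serialize_model(model: PLSModel, path: Union[str, Path]) -> Path:
    """Write a fitted model to JSON; returns the path written."""
    payload: dict = {"schema_version": _SCHEMA_VERSION}
    for f in _ARRAY_FIELDS:
        payload[f] = np.asarray(getattr(model, f)).tolist()
    for f in _SCALAR_FIELDS:
        payload[f] = getattr(model, f)
    for f in _LIST_FIELDS:
        payload[f] = list(getattr(model, f))
    enc = model.y_encoding
    payload["y_encoding"] = enc if isinstance(enc, str) else {str(k): float(v) for k, v in enc.items()}
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
    return path


def deserialize_model(path: Union[str, Path]) -> PLSModel:
    """Read a model written by :func:`serialize_model`.

    Raises :class:`ModelFormatError` naming the offending field when the
    file is truncated or missing a field.
    """
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"model file is not valid JSON: {exc}") from exc
    if not isinstance(payload, dict):
        raise ModelFormatError("model file does not contain a JSON object")
    if payload.get("schema_version") != _SCHEMA_VERSION:
        raise ModelFormatError(f"unsupported schema_version: {payload.get('schema_version')!r}")
    kw = {}
    for f in _ARRAY_FIELDS + _SCALAR_FIELDS + _LIST_FIELDS + ("y_encoding",):
        if f not in payload:
            raise ModelFormatError(f"model file missing field: {f!r}")
        kw[f] = payload[f]
    for f in _ARRAY_FIELDS:
        kw[f] = np.asarray(kw[f], dtype=float)
    return PLSModel(**kw)


# -- bundled fixtures ------------------------------------------------------

def _data_path(name: str):
    return resources.files("cytosig.data").joinpath(name)


def load_patient_roster() -> pd.DataFrame:
    """Clinical/genotype roster of the study's 18 patients (15 typical, 3 mild)."""
    with resources.as_file(_data_path("table1_roster.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype=str)


def load_control_roster() -> pd.DataFrame:
    """Synthetic stand-in roster for the 19 recruited familial controls.

    The control roster was never published; this fixture reproduces the
    documented counts (11 F / 8 M) and the single exclusion (a control who
    underwent a surgical procedure in the week before sample collection).
    """
    with resources.as_file(_data_path("controls_roster_synthetic.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype=str)


def default_human_mouse_map() -> AnalyteMap:
    """Human ↔ mouse analyte-name map covering commonly shared analytes.

    Only a partial map (names discussed across both panels, e.g. the GRO
    class mapping human GRO to mouse KC); users supply full kit maps.
    """
    with resources.as_file(_data_path("human_mouse_map.tsv")) as p:
        return read_analyte_map(p)


def cohort_counts() -> dict[str, int]:
    """Counts of the analyzed human cohorts derived from the bundled rosters.

    Controls are counted after applying the recorded exclusion.
    """
    patients = load_patient_roster()
    controls = load_control_roster()
    phen = patients["phenotype"].str.strip().str.casefold()
    analyzed_controls = controls[controls["excluded"].str.strip().str.casefold() == "no"]
    return {
        "n_patients": int(len(patients)),
        "n_typical": int((phen == "typical").sum()),
        "n_mild": int((phen == "mild").sum()),
        "n_controls_recruited": int(len(controls)),
        "n_controls_analyzed": int(len(analyzed_controls)),
    }
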