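"""Core data containers for multiplexed cytokine panels.

A :class:`CytokinePanel` couples a samples × analytes concentration matrix
(pg/mL, missing values allowed) with per-sample metadata (group label,
species, compartment, sex, age, optional clinical scores).  All analysis
modules consume and return this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["CytokinePanel", "AnalyteMap", "PanelError"]


class PanelError(ValueError):
    """Raised when a panel or analyte map violates its invariants."""


#: metadata columns every panel is expected to carry (extra columns allowed)
CORE_METADATA = ("group_label", "species", "compartment", "sex", "age")


@dataclass
class CytokinePanel:
    """Samples × analytes concentration matrix plus per-sample metadata.

    Parameters
    ----------
    concentrations
        DataFrame indexed by sample id, one column per analyte, values in
        pg/mL.  ``NaN`` encodes a missing (e.g. out-of-range) measurement.
    metadata
        DataFrame indexed by sample id covering every sample in
        ``concentrations``.  Reordered to match the concentration rows.
    """

    concentrations: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        conc = self.concentrations
        if conc.index.has_duplicates:
            dupes = conc.index[conc.index.duplicated()].unique().tolist()
            raise PanelError(f"duplicate sample ids: {dupes}")
        if conc.columns.has_duplicates:
            dupes = conc.columns[conc.columns.duplicated()].unique().tolist()
            raise PanelError(f"duplicate analyte names: {dupes}")
        vals = conc.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] < 0):
            bad = conc.columns[(conc < 0).any(axis=0)].tolist()
            raise PanelError(f"negative concentrations in analytes: {bad}")
        missing = conc.index.difference(self.metadata.index)
        if len(missing) > 0:
            raise PanelError(f"metadata missing for samples: {missing.tolist()}")
        # align metadata rows to the concentration row order
        self.metadata = self.metadata.loc[conc.index]
        self.concentrations = conc.astype(float)

    # -- accessors ---------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.concentrations.index]

    @property
    def analyte_names(self) -> list[str]:
        return [str(a) for a in self.concentrations.columns]

    @property
    def n_samples(self) -> int:
        return self.concentrations.shape[0]

    @property
    def n_analytes(self) -> int:
        return self.concentrations.shape[1]

    @property
    def values(self) -> np.ndarray:
        """Concentration matrix as a float array (NaN = missing)."""
        return self.concentrations.to_numpy(dtype=float)

    def groups(self, column: str = "group_label") -> np.ndarray:
        if column not in self.metadata.columns:
            raise PanelError(f"metadata column not found: {column!r}")
        return self.metadata[column].to_numpy()

    # -- subsetting --------------------------------------------------------
    def subset_analytes(self, names: Sequence[str]) -> "CytokinePanel":
        """Restrict to ``names`` in the given order (exact match)."""
        missing = [n for n in names if n not in self.concentrations.columns]
        if missing:
            raise PanelError(f"analytes not in panel: {missing}")
        return CytokinePanel(self.concentrations.loc[:, list(names)], self.metadata.copy())

    def subset_samples(self, ids: Sequence[str]) -> "CytokinePanel":
        missing = [s for s in ids if s not in self.concentrations.index]
        if missing:
            raise PanelError(f"samples not in panel: {missing}")
        idx = list(ids)
        return CytokinePanel(self.concentrations.loc[idx], self.metadata.loc[idx])

    def drop_samples(self, ids: Iterable[str]) -> "CytokinePanel":
        drop = set(ids)
        keep = [s for s in self.concentrations.index if s not in drop]
        return self.subset_samples(keep)

    def copy(self) -> "CytokinePanel":
        return CytokinePanel(self.concentrations.copy(), self.metadata.copy())


def _norm(name: str) -> str:
    return str(name).strip().casefold()


@dataclass
class AnalyteMap:
    """Pairs of analyte names harmonizing two panels (e.g. human ↔ mouse).

    Each side must be duplicate-free; matching against panel columns is
    case-insensitive after whitespace trimming.
    """

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        a_side = [_norm(a) for a, _ in self.pairs]
        b_side = [_norm(b) for _, b in self.pairs]
        for side, names in (("A", a_side), ("B", b_side)):
            seen, dupes = set(), []
            for n in names:
                if n in seen:
                    dupes.append(n)
                seen.add(n)
            if dupes:
                raise PanelError(f"duplicate names on side {side} of analyte map: {dupes}")

    def __len__(self) -> int:
        return len(self.pairs)

    def reversed(self) -> "AnalyteMap":
        return AnalyteMap([(b, a) for a, b in self.pairs])

    @staticmethod
    def identity(names: Sequence[str]) -> "AnalyteMap":
        return AnalyteMap([(n, n) for n in names])

    def resolve(self, panel_a: CytokinePanel, panel_b: CytokinePanel) -> list[tuple[str, str]]:
        """Map each pair onto the panels' actual column names.

        Raises :class:`PanelError` naming any mapped analyte absent from its
        panel.
        """
        lut_a = {_norm(c): c for c in panel_a.analyte_names}
        lut_b = {_norm(c): c for c in panel_b.analyte_names}
        resolved = []
        for a, b in self.pairs:
            ka, kb = _norm(a), _norm(b)
            if ka not in lut_a:
                raise PanelError(f"mapped analyte {a!r} not found in panel A")
            if kb not in lut_b:
                raise PanelError(f"mapped analyte {b!r} not found in panel B")
            resolved.append((lut_a[ka], lut_b[kb]))
        return resolved
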