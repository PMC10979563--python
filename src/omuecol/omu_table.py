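"""Data model and I/O for OMU (operational metagenomic unit) tables.

An OMU table is an abundance matrix with OMUs as rows and samples as
columns.  OMUs live at one of four levels:

* ``MG``   — metagenomic gene, the atomic unit;
* ``MF``   — metagenome function (set of MGs annotated to one function);
* ``MP``   — metagenome pathway (set of MGs annotated to one pathway);
* ``MFGC`` — metagenome functional gene cluster (set of MGs sharing an
  identical *combination* of functions/pathways).

Tables come in two modes: ``type2`` keeps read abundances, ``type1``
records only presence/absence (entries in {0, 1}).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from pathlib import Path
from typing import Iterable, Mapping
import warnings

import numpy as np
import pandas as pd

LEVELS = ("MG", "MFGC", "MF", "MP")
MODES = ("type1", "type2")


@dataclass
class OmuTable:
    """Abundance matrix of OMUs (rows) by samples (columns).

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative abundances; index = OMU ids, columns = sample ids.
    level : str
        One of ``MG``, ``MFGC``, ``MF``, ``MP``.
    mode : str
        ``type2`` (abundance) or ``type1`` (presence/absence).
    """

    counts: pd.DataFrame
    level: str = "MG"
    mode: str = "type2"

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}; expected one of {LEVELS}")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate OMU ids: {dups}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("non-numeric entries in OMU table")
        if np.any(values < 0):
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative entry at OMU {self.counts.index[r]!r}, "
                f"sample {self.counts.columns[c]!r}"
            )
        if self.mode == "type1" and not np.isin(values, (0, 1)).all():
            raise ValueError("type1 table must contain only 0/1 entries")

    # -- basic views ---------------------------------------------------

    @property
    def omu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_omu(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def S(self) -> int:
        """Number of OMU rows (the species count of similarity formulas)."""
        return self.counts.shape[0]

    def values(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)

    def copy(self) -> "OmuTable":
        return OmuTable(self.counts.copy(), level=self.level, mode=self.mode)

    # -- I/O -----------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="omu_id")


def read_omu_table(
    path: str | Path,
    orientation: str = "rows-are-omus",
    level: str = "MG",
    mode: str = "type2",
    sep: str | None = None,
) -> OmuTable:
    """Read a delimited OMU table (header row, first column = ids).

    ``orientation="rows-are-samples"`` transposes the file so the returned
    table is always rows-are-OMUs.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "rows-are-samples":
        df = df.T
    elif orientation != "rows-are-omus":
        raise ValueError(f"unknown orientation {orientation!r}")
    bad = df.map(lambda v: not isinstance(v, (int, float, np.number)))
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    return OmuTable(df.astype(float), level=level, mode=mode)


def to_type1(table: OmuTable) -> OmuTable:
    """Presence/absence transform: entry > 0 becomes 1."""
    binary = (table.counts > 0).astype(float)
    return OmuTable(binary, level=table.level, mode="type1")


def relative_abundance(table: OmuTable) -> pd.DataFrame:
    """Per-column normalized view; all-zero columns stay zero (warned)."""
    totals = table.counts.sum(axis=0)
    zero_cols = totals[totals == 0].index.tolist()
    if zero_cols:
        warnings.warn(f"all-zero sample columns left as zeros: {zero_cols}")
    safe = totals.replace(0, 1.0)
    return table.counts / safe


# -- annotation & aggregation ------------------------------------------


@dataclass
class AnnotationMap:
    """Many-to-one (or many-to-many) map from MG id to MF/MP labels."""

    mg_to_labels: dict[str, frozenset[str]]
    label_space: str = "custom"

    def __post_init__(self) -> None:
        self.mg_to_labels = {
            mg: frozenset(labels) for mg, labels in self.mg_to_labels.items()
        }
        empty = [mg for mg, labels in self.mg_to_labels.items() if not labels]
        if empty:
            raise ValueError(f"MG ids with no labels: {empty}")

    @property
    def labels(self) -> list[str]:
        out: set[str] = set()
        for labels in self.mg_to_labels.values():
            out |= labels
        return sorted(out)

    @classmethod
    def from_tsv(cls, path: str | Path, label_space: str = "custom") -> "AnnotationMap":
        """Read a two-column TSV: MG id, comma-separated labels."""
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
        mapping = {
            str(row.iloc[0]): frozenset(str(row.iloc[1]).split(","))
            for _, row in df.iterrows()
        }
        return cls(mapping, label_space=label_space)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (mg, ",".join(sorted(labels)))
            for mg, labels in sorted(self.mg_to_labels.items())
        ]
        pd.DataFrame(rows, columns=["mg_id", "labels"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class TreatmentDesign:
    """Sample id -> treatment label (e.g. healthy / diseased)."""

    labels: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TreatmentDesign":
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))

    def samples_for(self, label: str) -> list[str]:
        return [s for s, t in self.labels.items() if t == label]


def subset_by_treatment(
    table: OmuTable, design: TreatmentDesign, label: str
) -> OmuTable:
    """Columns of one treatment, preserving row order."""
    keep = [s for s in table.sample_ids if design.labels.get(s) == label]
    if not keep:
        raise ValueError(f"no samples with treatment {label!r}")
    return OmuTable(table.counts[keep], level=table.level, mode=table.mode)


def aggregate_to_mf(
    table: OmuTable,
    ann: AnnotationMap,
    level: str = "MF",
    on_unannotated: str = "error",
) -> OmuTable:
    """Aggregate an MG-level table to MF (or MP) rows.

    Each output row is one label; a multi-label MG contributes its full
    abundance to every label it maps to.  type2 rows are sums, type1 rows
    are logical ORs of member presences.
    """
    if table.level != "MG":
        raise ValueError("aggregation requires an MG-level table")
    if level not in {"MF", "MP"}:
        raise ValueError("target level must be MF or MP")
    missing = [mg for mg in table.omu_ids if mg not in ann.mg_to_labels]
    if missing:
        if on_unannotated == "error":
            raise ValueError(f"MG ids missing from annotation: {missing}")
        if on_unannotated != "drop":
            raise ValueError(f"unknown unannotated policy {on_unannotated!r}")
    members: dict[str, list[str]] = {}
    for mg in table.omu_ids:
        for label in ann.mg_to_labels.get(mg, ()):  # drop policy skips missing
            members.setdefault(label, []).append(mg)
    rows = {}
    for label in sorted(members):
        block = table.counts.loc[members[label]]
        rows[label] = block.sum(axis=0)
    out = pd.DataFrame(rows).T
    out.columns = table.sample_ids
    if table.mode == "type1":
        out = (out > 0).astype(float)
    return OmuTable(out, level=level, mode=table.mode)


def derive_mfgc(ann: AnnotationMap) -> dict[str, str]:
    """Map each MG to its MFGC signature (its exact label combination).

    MGs with identical label sets share one MFGC; the signature is the
    sorted labels joined by ``"|"``.
    """
    return {
        mg: "|".join(sorted(labels)) for mg, labels in ann.mg_to_labels.items()
    }


def aggregate_to_mfgc(
    table: OmuTable, ann: AnnotationMap, on_unannotated: str = "error"
) -> OmuTable:
    """Aggregate an MG-level table to MFGC rows (one row per label-combination)."""
    if table.level != "MG":
        raise ValueError("aggregation requires an MG-level table")
    signature = derive_mfgc(ann)
    missing = [mg for mg in table.omu_ids if mg not in signature]
    if missing:
        if on_unannotated == "error":
            raise ValueError(f"MG ids missing from annotation: {missing}")
        if on_unannotated != "drop":
            raise ValueError(f"unknown unannotated policy {on_unannotated!r}")
    members: dict[str, list[str]] = {}
    for mg in table.omu_ids:
        if mg in signature:
            members.setdefault(signature[mg], []).append(mg)
    rows = {sig: table.counts.loc[m].sum(axis=0) for sig, m in sorted(members.items())}
    out = pd.DataFrame(rows).T
    out.columns = table.sample_ids
    if table.mode == "type1":
        out = (out > 0).astype(float)
    return OmuTable(out, level="MFGC", mode=table.mode)


def count_possible_mfgc(m: int) -> int:
    """Number of possible multi-function MFGCs over ``m`` functions.

    Counts the label combinations of size >= 2:
    sum_{k=2..m} C(m, k) = 2^m - m - 1.
    """
    if m < 2:
        raise ValueError("need at least 2 MF labels")
    return sum(comb(m, k) for k in range(2, m + 1))
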