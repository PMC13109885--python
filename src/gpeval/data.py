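"""Core in-memory containers shared by every pipeline stage.

The package moves three objects through the pipeline: a :class:`Pedigree`
(sire/dam links over ordered animal records), a :class:`GenotypeMatrix`
(individuals x markers dosage matrix plus a marker map), and a phenotype
table, which is a plain :class:`pandas.DataFrame` with an ``id`` column,
one column per trait, a ``batch`` factor and optional covariate columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN_PARENT = "0"

__all__ = ["Pedigree", "GenotypeMatrix", "UNKNOWN_PARENT"]


@dataclass
class Pedigree:
    """Ordered animal records with parent links.

    ``table`` has columns ``id``, ``sire``, ``dam``, ``generation``; the
    unknown-parent sentinel is ``"0"``.  Records must be topologically
    ordered (parents before offspring), which :meth:`validate` enforces.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"id", "sire", "dam", "generation"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"pedigree table missing columns: {sorted(missing)}")
        for col in ("id", "sire", "dam"):
            self.table[col] = self.table[col].astype(str)
        self.table = self.table.reset_index(drop=True)
        self.validate()

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    @property
    def n(self) -> int:
        return len(self.table)

    def index_of(self) -> dict[str, int]:
        return {i: k for k, i in enumerate(self.table["id"])}

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Sire and dam row indices, -1 for unknown parents."""
        idx = self.index_of()
        sire = np.array([idx.get(s, -1) for s in self.table["sire"]], dtype=np.int64)
        dam = np.array([idx.get(d, -1) for d in self.table["dam"]], dtype=np.int64)
        return sire, dam

    def validate(self) -> None:
        ids = self.table["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicated animal id in pedigree: {dup!r}")
        idx = self.index_of()
        for row, (i, s, d) in enumerate(
            zip(self.table["id"], self.table["sire"], self.table["dam"])
        ):
            for parent in (s, d):
                if parent == UNKNOWN_PARENT:
                    continue
                if parent == i:
                    raise ValueError(f"animal {i!r} is its own parent (pedigree cycle)")
                j = idx.get(parent)
                if j is not None and j >= row:
                    raise ValueError(
                        "pedigree is not topologically ordered: parent "
                        f"{parent!r} listed at or after offspring {i!r}"
                    )

    def subset_index(self, ids: list[str]) -> np.ndarray:
        idx = self.index_of()
        out = []
        for i in ids:
            if i not in idx:
                raise KeyError(f"id {i!r} not in pedigree")
            out.append(idx[i])
        return np.asarray(out, dtype=np.int64)


@dataclass
class GenotypeMatrix:
    """Dosage matrix with marker map.

    ``dosages`` is float64 with values in {0, 1, 2} and NaN for missing.
    ``markers`` has columns ``marker``, ``chrom``, ``pos`` (1-based bp),
    ``a1``, ``a2``; dosage counts copies of ``a1``.  Positions must be
    nondecreasing within each chromosome.
    """

    dosages: np.ndarray
    ids: list[str] = field(default_factory=list)
    markers: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D individuals x markers array")
        n, m = self.dosages.shape
        if len(self.ids) != n:
            raise ValueError(f"{len(self.ids)} ids for {n} dosage rows")
        if len(self.markers) != m:
            raise ValueError(f"{len(self.markers)} marker records for {m} columns")
        if len(set(self.ids)) != n:
            raise ValueError("individual ids are not unique")
        self.markers = self.markers.reset_index(drop=True)
        self.markers["chrom"] = self.markers["chrom"].astype(str)
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions decrease within chromosome {chrom}")
        # fractional values allowed so mean-imputed matrices stay valid
        valid = np.isnan(self.dosages) | (
            (self.dosages >= 0.0) & (self.dosages <= 2.0)
        )
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(
                f"invalid dosage {self.dosages[tuple(bad)]} at row {bad[0]}, column {bad[1]}"
            )

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def allele_freqs(self) -> np.ndarray:
        """Frequency of the counted (a1) allele, from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def impute_mean(self) -> "GenotypeMatrix":
        """Replace missing dosages by the per-marker mean dosage."""
        if not np.isnan(self.dosages).any():
            return self
        filled = self.dosages.copy()
        col_mean = np.nanmean(filled, axis=0)
        nan_r, nan_c = np.where(np.isnan(filled))
        filled[nan_r, nan_c] = col_mean[nan_c]
        return GenotypeMatrix(filled, list(self.ids), self.markers.copy())

    def subset(self, individuals=None, markers=None) -> "GenotypeMatrix":
        """Row/column subset by individual ids and/or marker column indices."""
        dos = self.dosages
        ids = list(self.ids)
        if individuals is not None:
            pos = {i: k for k, i in enumerate(self.ids)}
            rows = [pos[i] for i in individuals]
            dos = dos[rows, :]
            ids = list(individuals)
        markers_df = self.markers
        if markers is not None:
            cols = np.asarray(markers, dtype=np.int64)
            dos = dos[:, cols]
            markers_df = self.markers.iloc[cols]
        return GenotypeMatrix(dos.copy(), ids, markers_df.copy())
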