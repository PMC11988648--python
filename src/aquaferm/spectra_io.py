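"""Containers and CSV I/O for NIR spectra and reference tables.

The universal in-memory currency of the package is :class:`SpectraSet`:
an absorbance matrix (one row per recorded scan, one column per wavelength
in nm) together with per-row metadata identifying the biological sample
(``sample_id``), starter culture (``BL``, ``LS``, ``MC`` or the shared
unfermented ``JUICE`` group), fermentation time in hours, replicate and
consecutive-scan index.

On disk a SpectraSet is a single wide CSV: the five metadata columns
followed by one column per wavelength, headed by the numeric nm value.
A leading ``#`` comment line records the schema version.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import SchemaError

META_COLUMNS = ("sample_id", "culture", "time_h", "replicate", "scan")

SPECTRA_SCHEMA = "aquaferm/spectra-wide/1"
REFERENCE_SCHEMA = "aquaferm/reference-long/1"

BASELINE_CULTURE = "JUICE"


@dataclass
class WavelengthRange:
    """Closed wavelength interval in nm."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise SchemaError(f"invalid wavelength range: low={self.low} >= high={self.high}")


@dataclass
class SpectraSet:
    """Absorbance matrix plus per-scan metadata.

    Parameters
    ----------
    wavelengths : (p,) array of strictly increasing nm values.
    absorbance : (n, p) array, absorbance units.
    meta : DataFrame with columns ``sample_id, culture, time_h, replicate, scan``
        (extra columns are carried along untouched).
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim == 1:
            self.absorbance = self.absorbance[None, :]
        self.meta = self.meta.reset_index(drop=True)
        self.validate()

    # -- schema -----------------------------------------------------------
    def validate(self) -> None:
        if self.wavelengths.ndim != 1:
            raise SchemaError("wavelengths must be one-dimensional")
        if self.wavelengths.size == 0:
            raise SchemaError("empty wavelength grid")
        d = np.diff(self.wavelengths)
        if np.any(d <= 0):
            raise SchemaError("wavelengths must be strictly increasing with no duplicates")
        n, p = self.absorbance.shape
        if p != self.wavelengths.size:
            raise SchemaError(f"absorbance has {p} columns for {self.wavelengths.size} wavelengths")
        if len(self.meta) != n:
            raise SchemaError(f"meta has {len(self.meta)} rows for {n} spectra")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise SchemaError(f"metadata columns missing: {missing}")
        key = self.meta[["sample_id", "replicate", "scan"]]
        if key.duplicated().any():
            raise SchemaError("(sample_id, replicate, scan) rows are not unique")
        # scans of one (sample_id, replicate) must be contiguous in row order
        block = self.meta["sample_id"].astype(str) + "/" + self.meta["replicate"].astype(str)
        codes, _ = pd.factorize(block)
        change = np.flatnonzero(np.diff(codes) != 0)
        seen_after = set()
        prev = codes[0] if len(codes) else None
        for i in change:
            seen_after.add(codes[i])
            if codes[i + 1] in seen_after:
                raise SchemaError("scans of one (sample_id, replicate) block are not contiguous")

    # -- basics -----------------------------------------------------------
    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.absorbance.shape[1]

    def copy(self) -> "SpectraSet":
        return SpectraSet(self.wavelengths.copy(), self.absorbance.copy(), self.meta.copy())

    def with_absorbance(
        self,
        absorbance: np.ndarray,
        wavelengths: np.ndarray | None = None,
        meta: pd.DataFrame | None = None,
    ) -> "SpectraSet":
        """Copy of this set with the matrix (and optionally grid/meta) replaced."""
        return SpectraSet(
            self.wavelengths.copy() if wavelengths is None else np.asarray(wavelengths, float),
            np.asarray(absorbance, float),
            self.meta.copy() if meta is None else meta,
        )

    def canonical_order(self) -> "SpectraSet":
        """Rows sorted by (culture, time_h, replicate, scan) — the reproducible layout."""
        order = self.meta.sort_values(
            ["culture", "time_h", "replicate", "scan"], kind="mergesort"
        ).index.to_numpy()
        return SpectraSet(
            self.wavelengths.copy(),
            self.absorbance[order],
            self.meta.iloc[order].reset_index(drop=True),
        )

    # -- subsetting -------------------------------------------------------
    def subset(
        self,
        culture: str | None = None,
        times: Iterable[float] | None = None,
        wavelength_range: WavelengthRange | tuple[float, float] | None = None,
        include_baseline: bool = True,
    ) -> "SpectraSet":
        """Row/column slice by metadata and wavelength range.

        A per-strain subset (``culture=...``) keeps the shared unfermented
        ``JUICE`` group unless ``include_baseline=False``.
        """
        mask = np.ones(self.n_spectra, dtype=bool)
        if culture is not None:
            cm = self.meta["culture"].to_numpy() == culture
            if include_baseline:
                cm |= self.meta["culture"].to_numpy() == BASELINE_CULTURE
            mask &= cm
        if times is not None:
            mask &= self.meta["time_h"].isin(list(times)).to_numpy()
        if not mask.any():
            raise SchemaError("subset selects no rows")
        wl = self.wavelengths
        cols = np.ones(wl.size, dtype=bool)
        if wavelength_range is not None:
            if isinstance(wavelength_range, tuple):
                wavelength_range = WavelengthRange(*wavelength_range)
            cols = (wl >= wavelength_range.low) & (wl <= wavelength_range.high)
            if not cols.any():
                raise SchemaError(
                    f"wavelength range [{wavelength_range.low}, {wavelength_range.high}] "
                    "does not overlap the grid"
                )
        return SpectraSet(
            wl[cols], self.absorbance[mask][:, cols], self.meta.loc[mask].reset_index(drop=True)
        )

    # -- serialization ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        values = pd.DataFrame(
            self.absorbance, columns=[_format_nm(w) for w in self.wavelengths]
        )
        return pd.concat([self.meta.loc[:, list(META_COLUMNS)], values], axis=1)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SpectraSet":
        missing = [c for c in META_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"metadata columns missing: {missing}")
        wl_cols = [c for c in frame.columns if c not in META_COLUMNS]
        try:
            wl = np.array([float(c) for c in wl_cols])
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"non-numeric wavelength column header: {exc}") from exc
        if np.unique(wl).size != wl.size:
            raise SchemaError("duplicated wavelength columns")
        order = np.argsort(wl)
        X = frame[wl_cols].to_numpy(dtype=float)[:, order]
        meta = frame[list(META_COLUMNS)].copy()
        meta["time_h"] = meta["time_h"].astype(float)
        meta["replicate"] = meta["replicate"].astype(int)
        meta["scan"] = meta["scan"].astype(int)
        return cls(wl[order], X, meta).canonical_order()

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# schema: {SPECTRA_SCHEMA}\n")
            self.to_frame().to_csv(fh, index=False, lineterminator="\n")
        return path

    @classmethod
    def read_csv(cls, path: str | Path) -> "SpectraSet":
        with open(path) as fh:
            header = ""
            for line in fh:
                if not line.startswith("#"):
                    header = line.rstrip("\n")
                    break
        names = header.split(",")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicated columns in {path}: {dupes}")
        frame = pd.read_csv(path, comment="#")
        if frame.shape[1] <= len(META_COLUMNS):
            raise SchemaError(f"{path}: no wavelength columns found")
        return cls.from_frame(frame)


def _format_nm(w: float) -> str:
    """Wavelength column header: shortest exact decimal for the nm value."""
    return format(float(w), "g")


def read_spectra(path: str | Path) -> SpectraSet:
    """Read a wide spectra CSV into a validated :class:`SpectraSet`."""
    return SpectraSet.read_csv(path)


def write_spectra(spectra: SpectraSet, path: str | Path) -> Path:
    return spectra.write_csv(path)


def subset(
    spectra: SpectraSet,
    culture: str | None = None,
    times: Iterable[float] | None = None,
    wavelength_range: WavelengthRange | tuple[float, float] | None = None,
    include_baseline: bool = True,
) -> SpectraSet:
    """Functional form of :meth:`SpectraSet.subset`."""
    return spectra.subset(culture, times, wavelength_range, include_baseline)


# ---------------------------------------------------------------------------
# Reference table (per-sample pH and log10 CFU/mL)
# ---------------------------------------------------------------------------

REFERENCE_COLUMNS = ("sample_id", "culture", "time_h", "replicate", "pH", "logcfu")


def validate_reference(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REFERENCE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"reference columns missing: {missing}")
    if table[["culture", "time_h", "replicate"]].duplicated().any():
        raise SchemaError("reference has duplicate (culture, time_h, replicate) rows")
    if (table["logcfu"] < 0).any():
        raise SchemaError("logcfu must be non-negative")
    return table.reset_index(drop=True)


def write_reference(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# schema: {REFERENCE_SCHEMA}\n")
        validate_reference(table).to_csv(fh, index=False, lineterminator="\n")
    return path


def read_reference(path: str | Path) -> pd.DataFrame:
    return validate_reference(pd.read_csv(path, comment="#"))
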