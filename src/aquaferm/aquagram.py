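"""Aquagrams: normalized water-band absorbance at the 12 water matrix
coordinates (WAMACs) of the 1300-1600 nm first overtone of water.

An aquagram displays, for each sample group (here culture x fermentation
time), the group-averaged absorbance at each WAMAC after pretreatment,
standardized across the displayed groups: ``(A_g - mu) / sigma`` per
coordinate.  A difference aquagram subtracts the baseline (0 h) group so
fermentation-induced changes in the water spectral pattern read directly
off the radar axes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import AquafermError, DegenerateSpectrumError

#: Conventional nominal WAMAC wavelengths (nm), C1..C12.
WAMAC_WAVELENGTHS = (
    1342.0, 1364.0, 1374.0, 1384.0, 1412.0, 1426.0,
    1440.0, 1452.0, 1462.0, 1476.0, 1488.0, 1512.0,
)
WAMAC_LABELS = tuple(f"C{i}" for i in range(1, 13))

_SPAN = (1300.0, 1600.0)


@dataclass(frozen=True)
class WamacSet:
    """The 12 aquagram coordinates: labels, nominal nm, optional band ranges."""

    labels: tuple = WAMAC_LABELS
    wavelengths: tuple = WAMAC_WAVELENGTHS
    ranges: tuple | None = None  # optional (low, high) per coordinate

    def __post_init__(self) -> None:
        if len(self.labels) != 12 or len(self.wavelengths) != 12:
            raise AquafermError("a WAMAC set has exactly 12 coordinates")
        wl = np.asarray(self.wavelengths, float)
        if np.any(np.diff(wl) <= 0):
            raise AquafermError("WAMAC wavelengths must be strictly increasing")
        if wl[0] < _SPAN[0] or wl[-1] > _SPAN[1]:
            raise AquafermError(f"WAMACs must lie within {_SPAN} nm")
        if self.ranges is not None and len(self.ranges) != 12:
            raise AquafermError("ranges, if given, must have 12 entries")

    def resolve(self, grid: np.ndarray, band_mean: bool = False) -> list:
        """Column indices on ``grid`` for each coordinate.

        Nearest single grid point by default; with ``band_mean`` (and
        ranges present) all grid points inside each coordinate's band.
        """
        grid = np.asarray(grid, float)
        out = []
        for i, w in enumerate(self.wavelengths):
            if w < grid[0] or w > grid[-1]:
                raise AquafermError(f"coordinate {self.labels[i]} ({w} nm) outside grid span")
            if band_mean and self.ranges is not None:
                lo, hi = self.ranges[i]
                idx = np.flatnonzero((grid >= lo) & (grid <= hi))
                if idx.size == 0:
                    raise AquafermError(f"band {self.labels[i]} [{lo}, {hi}] misses the grid")
            else:
                idx = np.array([int(np.argmin(np.abs(grid - w)))])
            out.append(idx)
        return out


def wamac_coordinates(overrides: Sequence[float] | Mapping[str, float] | None = None) -> WamacSet:
    """Default WAMAC registry, or one with overridden nominal wavelengths."""
    if overrides is None:
        return WamacSet()
    if isinstance(overrides, Mapping):
        wl = list(WAMAC_WAVELENGTHS)
        for label, w in overrides.items():
            if label not in WAMAC_LABELS:
                raise AquafermError(f"unknown WAMAC label {label!r}")
            wl[WAMAC_LABELS.index(label)] = float(w)
        return WamacSet(wavelengths=tuple(wl))
    return WamacSet(wavelengths=tuple(float(w) for w in overrides))


def compute_aquagram(
    spectra,
    wamacs: WamacSet | None = None,
    pretreatment="default",
    by: Sequence[str] = ("culture", "time_h"),
    band_mean: bool = False,
) -> pd.DataFrame:
    """Group-averaged, across-group-standardized absorbance at the WAMACs.

    Steps: (1) pretreat (default: 21-point smoothing then SNV; pass
    ``None`` to skip, or any :class:`~aquaferm.preprocess.PretreatmentSpec`);
    (2) average spectra per display group (``by``); (3) per coordinate,
    standardize across the displayed groups: ``(A_g - mu) / sigma``.

    Returns a DataFrame indexed by group with columns C1..C12.
    """
    from .preprocess import PretreatmentSpec, average_by  # local to avoid cycle

    wamacs = wamacs or WamacSet()
    if pretreatment == "default":
        pretreatment = PretreatmentSpec.from_list([{"savgol": {"window": 21}}, "snv"])
    if pretreatment is not None:
        spectra = pretreatment.apply(spectra)
    avg = average_by(spectra, list(by))
    if avg.n_spectra < 2:
        raise AquafermError("an aquagram needs at least two display groups")
    cols = wamacs.resolve(avg.wavelengths, band_mean=band_mean)
    A = np.column_stack([avg.absorbance[:, idx].mean(axis=1) for idx in cols])
    mu = A.mean(axis=0)
    sd = A.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [wamacs.labels[i] for i in zero]
        raise DegenerateSpectrumError(f"zero across-group spread at coordinates {names}")
    values = (A - mu) / sd
    index = pd.Index(
        ["_".join(str(avg.meta.loc[i, k]) for k in by) for i in range(avg.n_spectra)],
        name="group",
    )
    return pd.DataFrame(values, index=index, columns=list(wamacs.labels))


def difference_aquagram(values: pd.DataFrame, baseline_group: str) -> pd.DataFrame:
    """Subtract the baseline group's coordinates from every group."""
    if baseline_group not in values.index:
        raise AquafermError(f"baseline group {baseline_group!r} not in aquagram")
    return values - values.loc[baseline_group]


def export_radar(values: pd.DataFrame, csv_path: str | Path, png_path: str | Path | None = None):
    """Write the aquagram table as CSV and optionally render the radar plot.

    Axis order is C1..C12 clockwise from the top.  The CSV is written with
    a fixed float format so re-export is byte-identical.
    """
    if values.empty:
        raise AquafermError("empty aquagram values")
    csv_path = Path(csv_path)
    values.to_csv(csv_path, float_format="%.10g", lineterminator="\n")
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        n = values.shape[1]
        # clockwise from the top
        theta = np.pi / 2 - 2 * np.pi * np.arange(n + 1) / n
        fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
        for group, row in values.iterrows():
            vals = np.r_[row.to_numpy(), row.to_numpy()[:1]]
            ax.plot(theta, vals, label=str(group))
        ax.set_xticks(theta[:-1])
        ax.set_xticklabels(values.columns)
        ax.set_title("Aquagram")
        ax.legend(loc="upper right", bbox_to_anchor=(1.3, 1.1), fontsize=8)
        fig.savefig(png_path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return csv_path
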