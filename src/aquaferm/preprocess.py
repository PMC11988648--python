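"""Spectral pretreatments: cropping, Savitzky-Golay smoothing/derivatives,
polynomial detrending, SNV, MSC, group averaging and difference spectra.

Two surfaces are provided:

* scikit-learn transformers (:class:`SavitzkyGolay`, :class:`Detrend`,
  :class:`SNV`, :class:`MSC`) that map plain ``(n, p)`` arrays and compose
  in ``sklearn.pipeline.Pipeline``;
* thin module functions operating on :class:`~aquaferm.spectra_io.SpectraSet`
  that preserve metadata, plus :class:`PretreatmentSpec`, the serializable
  ordered recipe used by the run configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import AquafermError, DegenerateSpectrumError
from .spectra_io import META_COLUMNS, BASELINE_CULTURE, SpectraSet, WavelengthRange


def _check_window(window: int, polyorder: int, n_points: int) -> None:
    if window % 2 == 0:
        raise AquafermError(f"window must be odd, got {window}")
    if window <= polyorder:
        raise AquafermError(f"window ({window}) must exceed polyorder ({polyorder})")
    if window > n_points:
        raise AquafermError(f"window ({window}) exceeds spectrum length ({n_points})")


class SavitzkyGolay(TransformerMixin, BaseEstimator):
    """Savitzky-Golay local-polynomial smoothing or derivative.

    ``deriv=0`` smooths; ``deriv=1|2`` returns the derivative scaled by the
    grid step ``delta`` (units per nm).  Edges are handled by evaluating the
    terminal polynomial fits (``mode='interp'``), so the grid is unchanged.
    """

    def __init__(self, window: int = 21, polyorder: int = 2, deriv: int = 0, delta: float = 1.0):
        self.window = window
        self.polyorder = polyorder
        self.deriv = deriv
        self.delta = delta

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        if self.deriv not in (0, 1, 2):
            raise AquafermError(f"derivative order must be 0, 1 or 2, got {self.deriv}")
        _check_window(self.window, self.polyorder, X.shape[-1])
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, float))
        _check_window(self.window, self.polyorder, X.shape[1])
        return savgol_filter(
            X,
            window_length=self.window,
            polyorder=self.polyorder,
            deriv=self.deriv,
            delta=self.delta,
            axis=1,
            mode="interp",
        )


class Detrend(TransformerMixin, BaseEstimator):
    """Subtract each spectrum's own least-squares polynomial in wavelength."""

    def __init__(self, degree: int = 2):
        self.degree = degree

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        if self.degree < 0 or self.degree >= X.shape[-1]:
            raise AquafermError(f"degree {self.degree} invalid for {X.shape[-1]} points")
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, float))
        if self.degree < 0 or self.degree >= X.shape[1]:
            raise AquafermError(f"degree {self.degree} invalid for {X.shape[1]} points")
        # same projector for every row: I - V (V^T V)^-1 V^T on a normalized axis
        u = np.linspace(-1.0, 1.0, X.shape[1])
        V = np.vander(u, self.degree + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(V, X.T, rcond=None)
        return X - (V @ coef).T


class SNV(TransformerMixin, BaseEstimator):
    """Standard normal variate: per spectrum subtract mean, divide by sd (n-1)."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, float))
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        bad = np.flatnonzero(sd.ravel() == 0)
        if bad.size:
            raise DegenerateSpectrumError(f"constant spectrum rows (SNV undefined): {bad.tolist()}")
        return (X - mu) / sd


class MSC(TransformerMixin, BaseEstimator):
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is regressed as ``x ~ a + b * reference`` and corrected
    to ``(x - a) / b``.  The default reference is the column mean of the set
    the transformer was fitted on.
    """

    def __init__(self, reference: np.ndarray | None = None):
        self.reference = reference

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, float))
        if self.reference is not None:
            ref = np.asarray(self.reference, float)
        else:
            if X.shape[0] < 2:
                raise AquafermError("MSC needs >= 2 spectra to form a mean reference")
            ref = X.mean(axis=0)
        if np.std(ref) == 0:
            raise DegenerateSpectrumError("MSC reference spectrum is constant")
        self.reference_ = ref
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, float))
        ref = self.reference_
        rc = ref - ref.mean()
        xc = X - X.mean(axis=1, keepdims=True)
        b = (xc @ rc) / (rc @ rc)
        if np.any(b == 0):
            bad = np.flatnonzero(b == 0).tolist()
            raise DegenerateSpectrumError(f"MSC slope zero (orthogonal to reference): rows {bad}")
        a = X.mean(axis=1) - b * ref.mean()
        return (X - a[:, None]) / b[:, None]


# ---------------------------------------------------------------------------
# SpectraSet-level operations
# ---------------------------------------------------------------------------


def crop(spectra: SpectraSet, wavelength_range: WavelengthRange | tuple[float, float]) -> SpectraSet:
    """Keep wavelengths in the closed interval [low, high]."""
    return spectra.subset(wavelength_range=wavelength_range)


def savgol_smooth(spectra: SpectraSet, window: int, polyorder: int = 2) -> SpectraSet:
    t = SavitzkyGolay(window=window, polyorder=polyorder)
    return spectra.with_absorbance(t.fit(spectra.absorbance).transform(spectra.absorbance))


def detrend(spectra: SpectraSet, degree: int = 2) -> SpectraSet:
    t = Detrend(degree=degree)
    return spectra.with_absorbance(t.fit(spectra.absorbance).transform(spectra.absorbance))


def snv(spectra: SpectraSet) -> SpectraSet:
    return spectra.with_absorbance(SNV().fit(spectra.absorbance).transform(spectra.absorbance))


def msc(spectra: SpectraSet, reference: np.ndarray | None = None) -> SpectraSet:
    t = MSC(reference=reference)
    return spectra.with_absorbance(t.fit(spectra.absorbance).transform(spectra.absorbance))


def derivative(spectra: SpectraSet, order: int, window: int, polyorder: int = 2) -> SpectraSet:
    """Savitzky-Golay derivative in per-nm units of the active grid."""
    if order not in (1, 2):
        raise AquafermError(f"derivative order must be 1 or 2, got {order}")
    step = float(np.median(np.diff(spectra.wavelengths)))
    t = SavitzkyGolay(window=window, polyorder=polyorder, deriv=order, delta=step)
    return spectra.with_absorbance(t.fit(spectra.absorbance).transform(spectra.absorbance))


def average_by(spectra: SpectraSet, keys: Sequence[str]) -> SpectraSet:
    """Mean spectrum per combination of metadata keys.

    Replicate/scan structure is collapsed; the key columns are retained and
    ``sample_id`` becomes the joined key string.
    """
    keys = list(keys)
    if not keys:
        raise AquafermError("average_by needs at least one metadata key")
    unknown = [k for k in keys if k not in spectra.meta.columns]
    if unknown:
        raise AquafermError(f"unknown metadata keys: {unknown}")
    meta = spectra.meta.reset_index(drop=True)
    grouped = meta.groupby(keys, sort=True)
    rows, recs = [], []
    for name, idx in grouped.indices.items():
        name_t = name if isinstance(name, tuple) else (name,)
        rows.append(spectra.absorbance[np.sort(idx)].mean(axis=0))
        rec = {k: v for k, v in zip(keys, name_t)}
        rec["sample_id"] = "_".join(str(v) for v in name_t)
        rec.setdefault("culture", meta.loc[idx[0], "culture"] if "culture" in keys else "ALL")
        rec.setdefault("time_h", meta.loc[idx[0], "time_h"] if "time_h" in keys else -1.0)
        rec["replicate"], rec["scan"] = 0, 0
        recs.append(rec)
    new_meta = pd.DataFrame(recs)[list(META_COLUMNS)]
    return SpectraSet(spectra.wavelengths.copy(), np.vstack(rows), new_meta).canonical_order()


def difference_spectra(spectra: SpectraSet, baseline_time: float = 0.0) -> SpectraSet:
    """Per-culture averaged spectra minus that culture's averaged baseline.

    Spectra are first averaged per (culture, time_h); then, for each culture,
    the baseline-time average (the shared unfermented JUICE group when the
    culture has no own baseline) is subtracted from every time point.  The
    baseline rows are kept as all-zero spectra.
    """
    avg = average_by(spectra, ["culture", "time_h"])
    meta = avg.meta
    base_rows = {
        c: i
        for i, (c, t) in enumerate(zip(meta["culture"], meta["time_h"]))
        if float(t) == float(baseline_time)
    }
    shared = base_rows.get(BASELINE_CULTURE)
    X = np.empty_like(avg.absorbance)
    for i, c in enumerate(meta["culture"]):
        j = base_rows.get(c, shared)
        if j is None:
            raise AquafermError(f"no {baseline_time} h baseline group for culture {c!r}")
        X[i] = avg.absorbance[i] - avg.absorbance[j]
    return avg.with_absorbance(X)


# ---------------------------------------------------------------------------
# Ordered pretreatment recipes
# ---------------------------------------------------------------------------

_STEP_NAMES = ("crop", "savgol", "detrend", "msc", "snv", "derivative")


@dataclass
class PretreatmentSpec:
    """Ordered list of pretreatment steps, e.g. from a YAML config.

    Steps are ``(name, kwargs)`` pairs with names drawn from
    ``crop, savgol(window, polyorder), detrend(degree), msc, snv,
    derivative(order, window, polyorder)``.  At most one of msc/snv is
    allowed (they are alternative scatter corrections).
    """

    steps: list

    @classmethod
    def from_list(cls, raw: Iterable) -> "PretreatmentSpec":
        steps = []
        for item in raw:
            if isinstance(item, str):
                steps.append((item, {}))
            elif isinstance(item, dict) and len(item) == 1:
                ((name, kwargs),) = item.items()
                steps.append((name, dict(kwargs or {})))
            elif isinstance(item, (tuple, list)) and len(item) == 2:
                steps.append((item[0], dict(item[1])))
            else:
                raise AquafermError(f"unparseable pretreatment step: {item!r}")
        spec = cls(steps)
        spec.validate()
        return spec

    def validate(self) -> None:
        scatter = 0
        for name, kwargs in self.steps:
            if name not in _STEP_NAMES:
                raise AquafermError(f"unknown pretreatment step: {name!r}")
            if name in ("msc", "snv"):
                scatter += 1
            if name in ("savgol", "derivative"):
                window = int(kwargs.get("window", 21))
                polyorder = int(kwargs.get("polyorder", 2))
                if window % 2 == 0 or window <= polyorder:
                    raise AquafermError(f"{name}: window must be odd and > polyorder")
            if name == "derivative" and int(kwargs.get("order", 1)) not in (1, 2):
                raise AquafermError("derivative order must be 1 or 2")
        if scatter > 1:
            raise AquafermError("at most one of msc/snv may appear in a pretreatment")

    def to_list(self) -> list:
        return [{name: kwargs} if kwargs else name for name, kwargs in self.steps]

    def apply(self, spectra: SpectraSet) -> SpectraSet:
        out = spectra
        for name, kwargs in self.steps:
            if name == "crop":
                out = crop(out, (kwargs["low"], kwargs["high"]))
            elif name == "savgol":
                out = savgol_smooth(out, int(kwargs.get("window", 21)), int(kwargs.get("polyorder", 2)))
            elif name == "detrend":
                out = detrend(out, int(kwargs.get("degree", 2)))
            elif name == "msc":
                out = msc(out)
            elif name == "snv":
                out = snv(out)
            elif name == "derivative":
                out = derivative(
                    out,
                    int(kwargs.get("order", 1)),
                    int(kwargs.get("window", 21)),
                    int(kwargs.get("polyorder", 2)),
                )
        return out
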