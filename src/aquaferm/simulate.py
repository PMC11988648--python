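"""Synthetic probiotic-fermentation NIR experiment generator.

Emulates the measurement campaign the analysis modules expect: a blended
fruit juice inoculated with *Bifidobacterium longum* (BL), *Lactobacillus
salivarius* (LS) or their 1:1 mixed culture (MC), sampled at 0/4/8/16/24 h
in three replicates and scanned three consecutive times in 1 mm
transmission over 1300-1600 nm.  With the default design that is
13 sample groups (3 cultures x 4 fermented times + one shared unfermented
JUICE group) x 3 replicates x 3 scans = 117 spectra.

Ground truth per replicate is a pH trajectory (exponential decay from
6.5 toward ~4.0) and a strain-specific log10 CFU/mL growth curve.  Each
spectrum is a broad water first-overtone baseline plus Gaussian bands at
the 12 water matrix coordinates whose amplitudes are affine in
(pH, log10 CFU), plus a multiplicative-scatter term that grows with cell
density (turbidity), plus replicate-level (biological) and scan-level
(instrumental) noise.  Everything is driven by one integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aquagram import WAMAC_WAVELENGTHS
from .exceptions import AquafermError, SchemaError
from .spectra_io import BASELINE_CULTURE, SpectraSet, validate_reference

DEFAULT_CULTURES = ("BL", "LS", "MC")
DEFAULT_TIMES_H = (0.0, 4.0, 8.0, 16.0, 24.0)

#: Per-pH-unit (below pH0) coupling of each water-band amplitude.  Bands up
#: to 1452 nm gain absorbance as acidification proceeds; bands above 1462 nm
#: (more strongly hydrogen-bonded water) lose absorbance.
DEFAULT_BAND_PH_COEFF = (
    0.004, 0.005, 0.005, 0.006,  # 1342, 1364, 1374, 1384
    0.021, 0.017, 0.022, 0.010,  # 1412, 1426, 1440, 1452
    -0.006, -0.008, -0.008, -0.010,  # 1462, 1476, 1488, 1512
)

#: Per-log10-CFU-unit (above the inoculum level 7.0) band coupling.
DEFAULT_BAND_CFU_COEFF = (
    0.001, 0.002, 0.002, 0.001,
    0.004, 0.003, 0.002, 0.001,
    -0.002, -0.002, -0.003, -0.004,
)

LOG10_INOCULUM = 7.0


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExperimentDesign:
    """Enumeration of sample groups and scan rows of one campaign."""

    cultures: tuple[str, ...] = DEFAULT_CULTURES
    times_h: tuple[float, ...] = DEFAULT_TIMES_H
    n_replicates: int = 3
    n_scans: int = 3
    shared_baseline: bool = True

    def __post_init__(self) -> None:
        if not self.cultures or not self.times_h:
            raise AquafermError("cultures and times_h must be non-empty")
        if len(set(self.times_h)) != len(self.times_h):
            raise AquafermError(f"duplicate sampling times: {self.times_h}")
        if self.n_replicates < 1 or self.n_scans < 1:
            raise AquafermError("replicate and scan counts must be >= 1")
        if self.shared_baseline and 0.0 not in [float(t) for t in self.times_h]:
            raise AquafermError("shared_baseline requires a 0 h sampling time")

    def sample_groups(self) -> pd.DataFrame:
        """One row per biological sample group: (sample_id, culture, time_h)."""
        rows: list[tuple[str, str, float]] = []
        if self.shared_baseline:
            rows.append((_sample_id(BASELINE_CULTURE, 0.0), BASELINE_CULTURE, 0.0))
            times = [float(t) for t in self.times_h if float(t) != 0.0]
        else:
            times = [float(t) for t in self.times_h]
        for culture in self.cultures:
            for t in times:
                rows.append((_sample_id(culture, t), culture, t))
        frame = pd.DataFrame(rows, columns=["sample_id", "culture", "time_h"])
        return frame.sort_values(["culture", "time_h"], kind="mergesort").reset_index(drop=True)

    def scan_rows(self) -> pd.DataFrame:
        """One row per recorded scan, in canonical (culture, time, rep, scan) order."""
        groups = self.sample_groups()
        reps = np.arange(1, self.n_replicates + 1)
        scans = np.arange(1, self.n_scans + 1)
        out = groups.loc[groups.index.repeat(self.n_replicates * self.n_scans)].reset_index(
            drop=True
        )
        out["replicate"] = np.tile(np.repeat(reps, self.n_scans), len(groups))
        out["scan"] = np.tile(scans, len(groups) * self.n_replicates)
        return out[["sample_id", "culture", "time_h", "replicate", "scan"]]

    @property
    def n_groups(self) -> int:
        return len(self.sample_groups())

    @property
    def n_rows(self) -> int:
        return self.n_groups * self.n_replicates * self.n_scans


def _sample_id(culture: str, time_h: float) -> str:
    return f"{culture}_{int(round(time_h)):02d}h"


def simulate_design(
    cultures: Sequence[str] = DEFAULT_CULTURES,
    times_h: Sequence[float] = DEFAULT_TIMES_H,
    n_replicates: int = 3,
    n_scans: int = 3,
    shared_baseline: bool = True,
) -> ExperimentDesign:
    """Build and validate an :class:`ExperimentDesign`."""
    return ExperimentDesign(
        tuple(cultures), tuple(float(t) for t in times_h), n_replicates, n_scans, shared_baseline
    )


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


def _default_ph_end() -> dict:
    return {"BL": 4.0, "LS": 4.0, "MC": 4.0}


def _default_k_ph() -> dict:
    # BL and MC acidify fast and flatten out after 16 h; LS keeps moving
    # between every pair of sampling points.
    return {"BL": 0.20, "LS": 0.12, "MC": 0.22}


def _default_growth() -> dict:
    return {
        "BL": {
            "kind": "logistic",
            "log0": LOG10_INOCULUM,
            "plateau": 9.0,
            "rate": 0.5,
            "midpoint": 6.0,
        },
        "LS": {
            "kind": "peak_decline",
            "log0": LOG10_INOCULUM,
            "peak": math.log10(2e9),
            "peak_time": 8.0,
            "decline_rate": 0.15,
        },
        "MC": {
            "kind": "lag_logistic_decline",
            "log0": LOG10_INOCULUM,
            "plateau": 9.2,
            "rate": 0.7,
            "midpoint": 8.0,
            "decline_start": 16.0,
            "decline_rate": 0.10,
        },
    }


@dataclass
class SimParams:
    """All free parameters of the generator (absorbance units unless noted)."""

    wavelength_start: float = 1300.0
    wavelength_end: float = 1600.0
    wavelength_step: float = 0.5

    ph0: float = 6.5
    ph_end: dict = field(default_factory=_default_ph_end)
    k_ph: dict = field(default_factory=_default_k_ph)  # 1/h
    growth: dict = field(default_factory=_default_growth)

    band_centers: tuple = WAMAC_WAVELENGTHS  # nm
    band_sigma: float | tuple = 9.0  # nm
    band_amp0: float | tuple = 0.0
    band_ph_coeff: tuple = DEFAULT_BAND_PH_COEFF  # per pH unit below ph0
    band_cfu_coeff: tuple = DEFAULT_BAND_CFU_COEFF  # per log10 unit above 7

    baseline_amp: float = 1.10
    baseline_center: float = 1445.0  # nm, water first-overtone hump
    baseline_sigma: float = 45.0  # nm
    baseline_offset: float = 0.25

    scatter_offset_per_logcfu: float = 0.010  # turbidity baseline lift
    scatter_slope_per_logcfu: float = 2e-5  # per nm tilt

    replicate_band_sd: float = 5e-4  # biological band-amplitude noise
    replicate_offset_sd: float = 5e-4
    scan_noise_sd: float = 1e-4  # iid per wavelength
    scan_offset_sd: float = 2e-4
    scan_slope_sd: float = 2e-6  # per nm

    ph_noise_sd: float = 0.02  # replicate-level pH variation
    logcfu_noise_sd: float = 0.15  # replicate-level plate-count variation

    seed: int = 42

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.wavelength_step <= 0:
            raise AquafermError("wavelength_step must be > 0")
        if self.wavelength_end <= self.wavelength_start:
            raise AquafermError("wavelength_end must exceed wavelength_start")
        for name in (
            "replicate_band_sd",
            "replicate_offset_sd",
            "scan_noise_sd",
            "scan_offset_sd",
            "scan_slope_sd",
            "ph_noise_sd",
            "logcfu_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise AquafermError(f"{name} must be >= 0")
        for culture, k in self.k_ph.items():
            if k < 0:
                raise AquafermError(f"negative pH decay rate for {culture}")
            if self.ph_end.get(culture, self.ph0) > self.ph0:
                raise AquafermError(f"ph_end > ph0 for {culture}")
        nb = len(self.band_centers)
        for name in ("band_ph_coeff", "band_cfu_coeff"):
            if len(getattr(self, name)) != nb:
                raise AquafermError(f"{name} must have {nb} entries")

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(round((self.wavelength_end - self.wavelength_start) / self.wavelength_step)) + 1
        return self.wavelength_start + self.wavelength_step * np.arange(n)

    def band_sigmas(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.band_sigma, float), (len(self.band_centers),))

    def band_amp0s(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.band_amp0, float), (len(self.band_centers),))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band_centers"] = list(self.band_centers)
        return d

    def noiseless(self) -> "SimParams":
        """Copy with every noise standard deviation set to zero."""
        d = self.to_dict()
        for name in (
            "replicate_band_sd",
            "replicate_offset_sd",
            "scan_noise_sd",
            "scan_offset_sd",
            "scan_slope_sd",
            "ph_noise_sd",
            "logcfu_noise_sd",
        ):
            d[name] = 0.0
        d["band_centers"] = tuple(d["band_centers"])
        d["band_ph_coeff"] = tuple(d["band_ph_coeff"])
        d["band_cfu_coeff"] = tuple(d["band_cfu_coeff"])
        return SimParams(**d)


# ---------------------------------------------------------------------------
# Reference trajectories
# ---------------------------------------------------------------------------


def ph_curve(t: np.ndarray | float, ph0: float, ph_end: float, k: float) -> np.ndarray | float:
    """Exponential acidification: pH(t) = pH_end + (pH0 - pH_end) e^{-kt}."""
    return ph_end + (ph0 - ph_end) * np.exp(-k * np.asarray(t, float))


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return 3 * u**2 - 2 * u**3


def growth_curve(t: np.ndarray | float, spec: Mapping) -> np.ndarray:
    """Noiseless log10 CFU/mL at time t for one per-culture curve family.

    All families pass through ``log0`` at t=0.  ``logistic`` rises into a
    stationary plateau; ``peak_decline`` rises smoothly to a peak then
    declines linearly; ``lag_logistic_decline`` adds a late linear decline
    to the logistic shape.
    """
    t = np.asarray(t, float)
    kind = spec["kind"]
    log0 = float(spec["log0"])
    if kind == "constant":
        return np.full_like(t, log0)
    if kind == "logistic":
        return _normalized_logistic(t, log0, spec["plateau"], spec["rate"], spec["midpoint"])
    if kind == "peak_decline":
        peak, t_peak, d = float(spec["peak"]), float(spec["peak_time"]), float(spec["decline_rate"])
        if d < 0:
            raise AquafermError("negative decline_rate")
        rise = log0 + (peak - log0) * _smoothstep(t / t_peak)
        fall = peak - d * (t - t_peak)
        return np.maximum(np.where(t <= t_peak, rise, fall), 0.0)
    if kind == "lag_logistic_decline":
        base = _normalized_logistic(t, log0, spec["plateau"], spec["rate"], spec["midpoint"])
        d, t0 = float(spec["decline_rate"]), float(spec["decline_start"])
        if d < 0:
            raise AquafermError("negative decline_rate")
        return np.maximum(base - d * np.maximum(t - t0, 0.0), 0.0)
    raise AquafermError(f"unknown growth curve kind: {kind!r}")


def _normalized_logistic(
    t: np.ndarray, log0: float, plateau: float, rate: float, midpoint: float
) -> np.ndarray:
    if rate < 0:
        raise AquafermError("negative growth rate")
    s = 1.0 / (1.0 + np.exp(-rate * (t - midpoint)))
    s0 = 1.0 / (1.0 + np.exp(rate * midpoint))
    return log0 + (plateau - log0) * (s - s0) / (1.0 - s0)


def simulate_reference(design: ExperimentDesign, params: SimParams) -> pd.DataFrame:
    """Per-replicate ground-truth pH and log10 CFU/mL table.

    Replicate noise reflects true flask-to-flask variation: the spectra are
    generated from these same noisy values, so the reference and the optical
    signal are coherent.
    """
    rng = np.random.default_rng([int(params.seed), 1])
    groups = design.sample_groups()
    rows = []
    for _, g in groups.iterrows():
        culture, t = g["culture"], float(g["time_h"])
        if culture == BASELINE_CULTURE:
            ph_true = params.ph0
            cfu_true = LOG10_INOCULUM
        else:
            ph_true = float(
                ph_curve(t, params.ph0, params.ph_end[culture], params.k_ph[culture])
            )
            cfu_true = float(growth_curve(t, params.growth[culture]))
        for rep in range(1, design.n_replicates + 1):
            ph = ph_true + rng.normal(0.0, params.ph_noise_sd) if params.ph_noise_sd else ph_true
            cfu = cfu_true + (
                rng.normal(0.0, params.logcfu_noise_sd) if params.logcfu_noise_sd else 0.0
            )
            rows.append((g["sample_id"], culture, t, rep, ph, max(cfu, 0.0)))
    table = pd.DataFrame(
        rows, columns=["sample_id", "culture", "time_h", "replicate", "pH", "logcfu"]
    )
    return validate_reference(table)


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------


def _gaussians(wavelengths: np.ndarray, centers: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """(n_bands, p) unit-height Gaussian profiles."""
    return np.exp(-0.5 * ((wavelengths[None, :] - centers[:, None]) / sigmas[:, None]) ** 2)


def baseline_spectrum(params: SimParams) -> np.ndarray:
    """Unfermented-juice absorbance: broad water hump plus a flat offset."""
    wl = params.wavelengths
    hump = params.baseline_amp * np.exp(
        -0.5 * ((wl - params.baseline_center) / params.baseline_sigma) ** 2
    )
    return hump + params.baseline_offset


def band_amplitudes(reference: pd.DataFrame, params: SimParams) -> np.ndarray:
    """Noiseless band amplitudes (n_reference_rows, n_bands) from (pH, logcfu)."""
    dph = params.ph0 - reference["pH"].to_numpy(float)
    dcfu = reference["logcfu"].to_numpy(float) - LOG10_INOCULUM
    a0 = params.band_amp0s()
    cph = np.asarray(params.band_ph_coeff, float)
    ccfu = np.asarray(params.band_cfu_coeff, float)
    return a0[None, :] + dph[:, None] * cph[None, :] + dcfu[:, None] * ccfu[None, :]


def generating_factor_profiles(params: SimParams) -> dict:
    """Partial derivatives of the noiseless spectrum wrt pH and log10 CFU.

    Returns ``{"wavelengths", "d_ph", "d_logcfu"}``; used by tests and
    reports to compare fitted regression vectors against the generating
    spectral directions.
    """
    wl = params.wavelengths
    G = _gaussians(wl, np.asarray(params.band_centers, float), params.band_sigmas())
    d_ph = -np.asarray(params.band_ph_coeff, float) @ G  # amplitude ~ (ph0 - pH)
    mid = 0.5 * (wl[0] + wl[-1])
    d_cfu = (
        np.asarray(params.band_cfu_coeff, float) @ G
        + params.scatter_offset_per_logcfu
        + params.scatter_slope_per_logcfu * (wl - mid)
    )
    return {"wavelengths": wl, "d_ph": d_ph, "d_logcfu": d_cfu}


def simulate_spectra(
    design: ExperimentDesign, reference: pd.DataFrame, params: SimParams
) -> SpectraSet:
    """Render the absorbance matrix for every scan row of the design.

    ``A(lambda) = baseline + sum_k a_k G_k + scatter(lambda) + noise`` with
    band amplitudes affine in (pH, log10 CFU), scatter offset/slope linear in
    log10 CFU (turbidity), replicate noise shared by all scans of one
    replicate, and independent per-scan noise.  Fully determined by
    ``params.seed``.
    """
    reference = validate_reference(reference)
    rng = np.random.default_rng([int(params.seed), 2])
    wl = params.wavelengths
    mid = 0.5 * (wl[0] + wl[-1])
    G = _gaussians(wl, np.asarray(params.band_centers, float), params.band_sigmas())
    base = baseline_spectrum(params)

    ref_key = {
        (r["culture"], float(r["time_h"]), int(r["replicate"])): (r["pH"], r["logcfu"])
        for _, r in reference.iterrows()
    }
    rows = design.scan_rows()
    missing = [
        k
        for k in rows[["culture", "time_h", "replicate"]].drop_duplicates().itertuples(index=False)
        if (k[0], float(k[1]), int(k[2])) not in ref_key
    ]
    if missing:
        raise SchemaError(f"reference rows missing for: {missing[:5]}")

    nb = len(params.band_centers)
    X = np.empty((len(rows), wl.size))
    rep_noise: dict[tuple, tuple[np.ndarray, float]] = {}
    for i, r in rows.iterrows():
        key = (r["sample_id"], int(r["replicate"]))
        if key not in rep_noise:
            band_eps = rng.normal(0.0, params.replicate_band_sd, nb) if params.replicate_band_sd else np.zeros(nb)
            off_eps = rng.normal(0.0, params.replicate_offset_sd) if params.replicate_offset_sd else 0.0
            rep_noise[key] = (band_eps, off_eps)
        band_eps, off_eps = rep_noise[key]
        ph, cfu = ref_key[(r["culture"], float(r["time_h"]), int(r["replicate"]))]
        amps = (
            params.band_amp0s()
            + (params.ph0 - ph) * np.asarray(params.band_ph_coeff, float)
            + (cfu - LOG10_INOCULUM) * np.asarray(params.band_cfu_coeff, float)
            + band_eps
        )
        slope = params.scatter_slope_per_logcfu * (cfu - LOG10_INOCULUM)
        offset = params.scatter_offset_per_logcfu * (cfu - LOG10_INOCULUM) + off_eps
        if params.scan_slope_sd:
            slope += rng.normal(0.0, params.scan_slope_sd)
        if params.scan_offset_sd:
            offset += rng.normal(0.0, params.scan_offset_sd)
        spec = base + amps @ G + slope * (wl - mid) + offset
        if params.scan_noise_sd:
            spec = spec + rng.normal(0.0, params.scan_noise_sd, wl.size)
        X[i] = spec
    return SpectraSet(wl, X, rows)


def simulate_experiment(
    design: ExperimentDesign | None = None, params: SimParams | None = None
) -> tuple[SpectraSet, pd.DataFrame]:
    """Design + reference + spectra in one call (defaults reproduce the campaign)."""
    design = design or simulate_design()
    params = params or SimParams()
    reference = simulate_reference(design, params)
    return simulate_spectra(design, reference, params), reference
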