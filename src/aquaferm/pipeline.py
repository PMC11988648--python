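"""End-to-end orchestration: simulate -> pretreat -> classify / regress /
aquagram, with every artifact written under one output directory and a
manifest tying them to the configuration and seed.

The named pretreatment presets mirror the best-model treatments of the
underlying campaign: 35-point smoothing + detrending for difference
spectra, 43-point smoothing + detrending for the global PCA, per-strain
LDA treatments (21-point smoothing for BL, detrending for LS, MSC for MC),
per-strain pH PLSR treatments (detrending for BL, SNV for LS and MC),
21-point smoothing + MSC for the averaged cell-count PLSR, and 21-point
smoothing + SNV for the aquagrams.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .aquagram import compute_aquagram, difference_aquagram, export_radar, wamac_coordinates
from .chemometrics import (
    evaluate_plsr,
    fit_pca,
    make_fold_plan,
    pca_lda_classify,
    regression_vector_peaks,
    select_nrlvs,
    select_nrpcs,
    top_loading_wavelengths,
)
from .exceptions import ConfigError
from .preprocess import PretreatmentSpec, average_by, difference_spectra
from .simulate import SimParams, simulate_design, simulate_reference, simulate_spectra
from .spectra_io import write_reference

DEFAULT_PRESETS: dict[str, list] = {
    "difference": [{"savgol": {"window": 35}}, "detrend"],
    "pca_global": [{"savgol": {"window": 43}}, "detrend"],
    "lda_bl": [{"savgol": {"window": 21}}],
    "lda_ls": ["detrend"],
    "lda_mc": ["msc"],
    "plsr_ph_bl": ["detrend"],
    "plsr_ph_ls": ["snv"],
    "plsr_ph_mc": ["snv"],
    "plsr_cellcount": [{"savgol": {"window": 21}}, "msc"],
    "aquagram": [{"savgol": {"window": 21}}, "snv"],
}

STRAINS = ("BL", "LS", "MC")


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    sim: SimParams = field(default_factory=SimParams)
    presets: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_PRESETS.items()})
    max_pcs: int = 30
    max_lv: int = 10
    out_dir: str = "runs/default"
    seed: int | None = None  # overrides sim.seed when given

    def __post_init__(self) -> None:
        if self.seed is not None:
            self.sim.seed = int(self.seed)

    def preset(self, name: str) -> PretreatmentSpec:
        if name not in self.presets:
            raise ConfigError(f"pretreatment preset {name!r} is not defined")
        return PretreatmentSpec.from_list(self.presets[name])

    def to_dict(self) -> dict:
        return {
            "sim": self.sim.to_dict(),
            "presets": self.presets,
            "max_pcs": self.max_pcs,
            "max_lv": self.max_lv,
            "out_dir": self.out_dir,
            "seed": self.sim.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sim_d = dict(d.get("sim", {}))
        for key in ("band_centers", "band_ph_coeff", "band_cfu_coeff"):
            if key in sim_d:
                sim_d[key] = tuple(sim_d[key])
        return cls(
            sim=SimParams(**sim_d),
            presets=d.get("presets", {k: list(v) for k, v in DEFAULT_PRESETS.items()}),
            max_pcs=int(d.get("max_pcs", 30)),
            max_lv=int(d.get("max_lv", 10)),
            out_dir=d.get("out_dir", "runs/default"),
            seed=d.get("seed"),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(obj, path: Path) -> Path:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    metrics: dict = {}

    def record(path: Path) -> Path:
        files.append(str(path.relative_to(out)))
        return path

    # -- stage: simulate --------------------------------------------------
    design = simulate_design()
    reference = simulate_reference(design, config.sim)
    spectra = simulate_spectra(design, reference, config.sim)
    record(spectra.write_csv(out / "spectra.csv"))
    record(write_reference(reference, out / "reference.csv"))
    record(_write_json(config.sim.to_dict(), out / "sim_params.json"))
    metrics["simulate"] = {"n_spectra": spectra.n_spectra, "n_groups": design.n_groups}

    # -- stage: difference spectra ---------------------------------------
    diff = difference_spectra(config.preset("difference").apply(spectra))
    record(diff.write_csv(out / "difference_spectra.csv"))

    # -- stage: global PCA ------------------------------------------------
    pca_in = config.preset("pca_global").apply(spectra)
    pca = fit_pca(pca_in, max_pcs=10)
    metrics["pca_global"] = {
        "explained_variance_ratio": pca.explained_variance_ratio.tolist(),
        "pc1_pc2_percent": 100.0 * float(pca.explained_variance_ratio[:2].sum()),
        "top_wavelengths_pc1": top_loading_wavelengths(pca, 1, k=2),
        "top_wavelengths_pc2": top_loading_wavelengths(pca, 2, k=2),
    }
    record(_write_json(metrics["pca_global"], out / "pca_global.json"))

    # -- stage: per-strain PCA-LDA ---------------------------------------
    metrics["lda"] = {}
    for strain in STRAINS:
        sub = config.preset(f"lda_{strain.lower()}").apply(spectra.subset(culture=strain))
        plan = make_fold_plan(sub)
        labels = sub.meta["time_h"].to_numpy()
        nrpcs, table = select_nrpcs(sub, labels, plan, max_pcs=config.max_pcs)
        result = pca_lda_classify(sub, labels, nrpcs, plan)
        report = {
            "strain": strain,
            "nrpcs": result.nrpcs,
            "train_accuracy": result.train_accuracy,
            "cv_accuracy": result.cv_accuracy,
            "confusion": result.confusion.to_numpy().tolist(),
            "classes": [float(c) for c in result.classes],
            "candidate_table": table.to_dict(orient="list"),
        }
        metrics["lda"][strain] = {k: report[k] for k in ("nrpcs", "train_accuracy", "cv_accuracy")}
        record(_write_json(report, out / f"lda_{strain}.json"))

    # -- stage: per-strain pH PLSR ---------------------------------------
    metrics["plsr_ph"] = {}
    for strain in STRAINS:
        sub = config.preset(f"plsr_ph_{strain.lower()}").apply(spectra.subset(culture=strain))
        plan = make_fold_plan(sub)
        ref_key = reference.set_index(["culture", "time_h", "replicate"])["pH"]
        y = np.array(
            [
                ref_key.loc[(c, t, r)]
                for c, t, r in zip(sub.meta["culture"], sub.meta["time_h"], sub.meta["replicate"])
            ]
        )
        nrlv, curve = select_nrlvs(sub, y, plan, max_lv=config.max_lv)
        model = evaluate_plsr(sub, y, nrlv, plan)
        report = {
            "strain": strain,
            "target": "pH",
            "nrlv": model.nrlv,
            "r2c": model.r2c,
            "rmsec": model.rmsec,
            "r2cv": model.r2cv,
            "rmsecv": model.rmsecv,
            "rmsecv_curve": curve.to_dict(orient="list"),
            "peak_wavelengths": regression_vector_peaks(model, k=6),
        }
        metrics["plsr_ph"][strain] = {k: report[k] for k in ("nrlv", "r2c", "rmsec", "r2cv", "rmsecv")}
        record(_write_json(report, out / f"plsr_ph_{strain}.json"))

    # -- stage: averaged cell-count PLSR ---------------------------------
    pre = config.preset("plsr_cellcount").apply(spectra.subset(times=[4, 8, 16, 24]))
    avg = average_by(pre, ["culture", "time_h"])
    ref_mean = reference.groupby(["culture", "time_h"])["logcfu"].mean()
    y = np.array([ref_mean.loc[(c, t)] for c, t in zip(avg.meta["culture"], avg.meta["time_h"])])
    plan = _stratified_folds(avg.meta["culture"].to_numpy(), n_folds=3, seed=config.sim.seed)
    nrlv, curve = select_nrlvs(avg, y, plan, max_lv=min(config.max_lv, 6))
    model = evaluate_plsr(avg, y, nrlv, plan)
    metrics["plsr_cellcount"] = {
        "n_averaged": avg.n_spectra,
        "nrlv": model.nrlv,
        "r2c": model.r2c,
        "rmsec": model.rmsec,
        "r2cv": model.r2cv,
        "rmsecv": model.rmsecv,
        "fold_plan_note": "three-fold over averaged rows, stratified by culture, seeded",
    }
    record(
        _write_json(
            {**metrics["plsr_cellcount"], "rmsecv_curve": curve.to_dict(orient="list"),
             "peak_wavelengths": regression_vector_peaks(model, k=6)},
            out / "plsr_cellcount.json",
        )
    )

    # -- stage: aquagrams -------------------------------------------------
    wamacs = wamac_coordinates()
    aquagram_preset = config.preset("aquagram")
    for strain in STRAINS:
        sub = spectra.subset(culture=strain)
        values = compute_aquagram(sub, wamacs, pretreatment=aquagram_preset, by=("time_h",))
        baseline = values.index[[float(str(i)) == 0.0 for i in values.index]][0]
        diff_vals = difference_aquagram(values, baseline)
        record(export_radar(diff_vals, out / f"aquagram_{strain}.csv", out / f"aquagram_{strain}.png"))
        files.append(f"aquagram_{strain}.png")

    manifest = {
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.sim.seed,
        "versions": {"aquaferm": __version__, "numpy": np.__version__},
        "n_models": {"lda": len(metrics["lda"]), "plsr_ph": len(metrics["plsr_ph"]),
                     "plsr_cellcount": 1, "aquagram": len(STRAINS)},
        "metrics": metrics,
        "files": sorted(files),
    }
    _write_json(manifest, out / "manifest.json")
    return manifest


def _stratified_folds(strata: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Seeded fold assignment spreading each stratum across folds."""
    rng = np.random.default_rng([int(seed), 3])
    plan = np.zeros(len(strata), dtype=int)
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            plan[i] = (j % n_folds) + 1
    return plan
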