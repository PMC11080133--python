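"""End-to-end pipeline: simulate -> baseline -> align -> filter -> calibrate
-> validate -> report.

The default configuration reproduces the study conditions end to end on
synthetic data: a five-level, three-analyte mixture design mapped onto the
validated linear ranges, DPV simulation with baseline drift, potential
jitter and noise, airPLS baseline correction, rigid icoshift alignment
with the shift estimated on the composition-stable entacapone peak region,
first-derivative SG filtering, pareto-scaled PLS with cross-validated
latent-variable selection, the complete validation suite (RMSECV / RMSEP /
REP%, CV-ANOVA, permutation test, leverage, Hotelling T2, standardized
residuals) and a three-replicate dosage-form assay emulation.

Every stage writes its intermediate matrix before the next begins; a run
directory is fully reproducible from its manifest (config, seeds, stage
hashes).  The preprocessing "ladder" refits the calibration at each
preprocessing state (raw, airPLS, airPLS+icoshift, +SG) to quantify what
each stage buys in external prediction error.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .align_icoshift import IcoshiftParams, build_target, icoshift_align
from .baseline_airpls import AirPLSParams, correct_set
from .design_calibration import (brereton_design, map_levels_to_concentrations,
                                 split_calibration_validation)
from .errors import ConfigurationError
from .filter_scale import SGParams, apply_sg
from .pls_core import (CVResult, PLSModel, cross_validate, model_to_json,
                       pls_fit, pls_predict, select_n_lv)
from .signal_core import (DEFAULT_GRID, ConcentrationTable, PotentialGrid,
                          VoltammogramSet, write_concentration_table,
                          write_voltammogram_set)
from .synthetic_dpv import (DEFAULT_ANALYTES, AnalytePeakSpec, ArtifactSpec,
                            default_artifacts, simulate)
from .validation_stats import (cv_anova, error_stats, hotelling_t2, leverages,
                               normal_probability_coords, permutation_test,
                               standardized_residuals)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "preprocess_stages",
    "reproduce_preprocessing_ladder",
    "STAGES",
]

STAGES = ("raw", "airpls", "airpls_icoshift", "sg")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs; round-trips through YAML/JSON."""

    grid: PotentialGrid = DEFAULT_GRID
    analytes: tuple[AnalytePeakSpec, ...] = DEFAULT_ANALYTES
    artifacts: ArtifactSpec | None = None   # None -> study-condition defaults
    airpls: AirPLSParams = AirPLSParams()
    # alignment: the shift of each trace is estimated on the entacapone
    # peak region (0.36-0.66 V) -- the one region whose shape does not
    # change with the mixing ratio -- against the most intense calibration
    # trace, and applied rigidly to the whole voltammogram.  A whole-trace
    # correlation is biased by the composition-dependent shape of the
    # LD/CD composite peak, and the mean of unaligned traces is broadened
    # by the very shifts being corrected.  max_shift of 10 points (0.05 V)
    # spans the realistic jitter range while preventing peak-swapping.
    icoshift: IcoshiftParams = IcoshiftParams(
        target_mode="max", max_shift=10, reference_window=(0.36, 0.66))
    sg: SGParams = SGParams()
    x_scaling: str = "pareto"
    n_levels: int = 5
    n_cal: int = 16
    n_val: int = 9
    max_lv: int = 12
    cv_scheme: str = "auto"      # "auto" | "loo" | "kfold:K"
    n_lv_override: int | None = None
    lv_tol: float = 0.02
    alpha: float = 0.05
    n_perm: int = 40
    run_permutation: bool = True
    run_ladder: bool = True
    seed: int = 0

    # deterministic per-stage seeds derived from the master seed
    @property
    def artifact_seed(self) -> int:
        return self.seed

    @property
    def split_seed(self) -> int:
        return self.seed + 1

    @property
    def cv_seed(self) -> int:
        return self.seed + 2

    @property
    def perm_seed(self) -> int:
        return self.seed + 3

    def resolved_scheme(self, n_train: int):
        if self.cv_scheme == "auto":
            return "loo" if n_train <= 20 else ("kfold", 7)
        if self.cv_scheme == "loo":
            return "loo"
        if self.cv_scheme.startswith("kfold:"):
            return ("kfold", int(self.cv_scheme.split(":", 1)[1]))
        raise ConfigurationError(f"unknown cv scheme {self.cv_scheme!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["analytes"] = [asdict(a) for a in self.analytes]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "grid" in d and isinstance(d["grid"], dict):
            d["grid"] = PotentialGrid(**d["grid"])
        if "analytes" in d:
            d["analytes"] = tuple(
                AnalytePeakSpec(**{**a, "linear_range": tuple(a["linear_range"])})
                for a in d["analytes"])
        if isinstance(d.get("icoshift"), dict) and d["icoshift"].get(
                "reference_window") is not None:
            d["icoshift"]["reference_window"] = tuple(
                d["icoshift"]["reference_window"])
        for key, typ in (("artifacts", ArtifactSpec), ("airpls", AirPLSParams),
                         ("icoshift", IcoshiftParams), ("sg", SGParams)):
            if isinstance(d.get(key), dict):
                d[key] = typ(**d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        try:
            p = Path(source)
            text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        except (OSError, ValueError):        # not a path: inline YAML text
            text = str(source)
        return cls.from_dict(yaml.safe_load(text))


def preprocess_stages(raw: VoltammogramSet, cal_ids: Sequence[str],
                      config: PipelineConfig) -> tuple[dict[str, np.ndarray],
                                                       np.ndarray]:
    """Matrices at the four preprocessing states, plus the icoshift table.

    Baseline correction and SG filtering are per-trace operations; the
    alignment target is built from the calibration rows only, so no
    information flows from validation samples into the preprocessing.
    """
    stages, shifts, _ = _preprocess_with_target(raw, cal_ids, config)
    return stages, shifts


def _preprocess_with_target(raw: VoltammogramSet, cal_ids: Sequence[str],
                            config: PipelineConfig):
    corrected = correct_set(raw, config.airpls)
    target = build_target(corrected.subset(list(cal_ids)),
                          config.icoshift.target_mode)
    aligned, shifts = icoshift_align(corrected, config.icoshift, target=target)
    filtered = apply_sg(aligned.matrix, config.sg, step=raw.grid.step)
    return ({"raw": raw.matrix, "airpls": corrected.matrix,
             "airpls_icoshift": aligned.matrix, "sg": filtered},
            shifts, target)


#: label claim of the marketed combination tablet (mg per tablet) and the
#: molar masses (g/mol) used to turn it into a molar ratio
TABLET_LABEL_MASSES = {"LD": 200.0, "CD": 50.0, "ENT": 200.0}
TABLET_MOLAR_MASSES = {"LD": 197.19, "CD": 226.23, "ENT": 305.29}


def tablet_concentrations(analytes: Sequence[AnalytePeakSpec],
                          masses: dict[str, float] | None = None,
                          molar_masses: dict[str, float] | None = None,
                          ) -> dict[str, float]:
    """Concentrations (mol/L) of a dosage-form assay sample.

    The fixed mass ratio of the tablet label claim is converted to a molar
    ratio and diluted so that every analyte lands inside its validated
    linear range (geometric midpoint of the feasible dilution interval).
    """
    masses = TABLET_LABEL_MASSES if masses is None else masses
    molar_masses = TABLET_MOLAR_MASSES if molar_masses is None else molar_masses
    ratio = {a.name: masses[a.name] / molar_masses[a.name] for a in analytes}
    t_lo = max(a.linear_range[0] / ratio[a.name] for a in analytes)
    t_hi = min(a.linear_range[1] / ratio[a.name] for a in analytes)
    if t_lo >= t_hi:
        raise ConfigurationError(
            "no dilution places every analyte inside its linear range"
        )
    t = float(np.sqrt(t_lo * t_hi))
    return {a.name: t * ratio[a.name] for a in analytes}


def _fit_and_validate(X_cal, Y_cal, X_val, Y_val, config: PipelineConfig,
                      ) -> tuple[PLSModel, CVResult, int, np.ndarray]:
    scheme = config.resolved_scheme(X_cal.shape[0])
    max_lv = min(config.max_lv, X_cal.shape[0] - 2, X_cal.shape[1])
    cv = cross_validate(X_cal, Y_cal, max_lv, scheme, config.cv_seed,
                        x_mode=config.x_scaling)
    n_lv = (config.n_lv_override if config.n_lv_override
            else select_n_lv(cv, config.lv_tol))
    model = pls_fit(X_cal, Y_cal, n_lv, x_mode=config.x_scaling)
    y_pred_val = pls_predict(model, X_val)
    return model, cv, n_lv, y_pred_val


@dataclass
class PipelineResult:
    config: PipelineConfig
    design: ConcentrationTable
    raw: VoltammogramSet
    stages: dict[str, np.ndarray]
    shifts: np.ndarray
    cal_ids: list[str]
    val_ids: list[str]
    model: PLSModel
    cv: CVResult
    n_lv: int
    predictions_val: ConcentrationTable
    report: dict
    ladder: pd.DataFrame | None
    outdir: Path | None = None


def _recoveries(pred: np.ndarray, nominal: np.ndarray) -> dict:
    with np.errstate(divide="ignore", invalid="ignore"):
        per_sample = 100.0 * pred / nominal
    return {
        "per_sample_mean": float(np.mean(per_sample)),
        "per_sample_sd": float(np.std(per_sample, ddof=1)),
        "pooled": float(100.0 * pred.sum() / nominal.sum()),
    }


def reproduce_preprocessing_ladder(config: PipelineConfig,
                                   stages: dict[str, np.ndarray] | None = None,
                                   design: ConcentrationTable | None = None,
                                   cal_ids: Sequence[str] | None = None,
                                   val_ids: Sequence[str] | None = None,
                                   ) -> pd.DataFrame:
    """RMSEP and REP% per analyte with the calibration refit at each
    preprocessing state (raw, airPLS, airPLS+icoshift, +SG)."""
    if stages is None:
        design, raw, cal_ids, val_ids = _generate_and_split(config)
        stages, _ = preprocess_stages(raw, cal_ids, config)
    cal_rows = [design.sample_ids.index(s) for s in cal_ids]
    val_rows = [design.sample_ids.index(s) for s in val_ids]
    Y_cal = design.values[cal_rows]
    Y_val = design.values[val_rows]
    records = []
    for stage in STAGES:
        X = stages[stage]
        _, _, n_lv, y_pred = _fit_and_validate(
            X[cal_rows], Y_cal, X[val_rows], Y_val, config)
        for a, name in enumerate(design.analytes):
            es = error_stats(y_pred[:, a], Y_val[:, a])
            records.append({"stage": stage, "analyte": name, "n_lv": n_lv,
                            "rmsep": es.rmse, "rep_percent": es.rep_percent})
    return pd.DataFrame.from_records(records)


def _generate_and_split(config: PipelineConfig, with_artifacts: bool = False):
    design_codes = brereton_design(config.n_levels, len(config.analytes))
    ranges = {a.name: a.linear_range for a in config.analytes}
    design = map_levels_to_concentrations(design_codes, ranges)
    artifacts = config.artifacts
    if artifacts is None:
        artifacts = default_artifacts(config.analytes, design, config.grid,
                                      seed=config.artifact_seed)
    raw, _ = simulate(design, config.analytes, artifacts, config.grid)
    cal_ids, val_ids = split_calibration_validation(
        design, config.n_cal, config.n_val, seed=config.split_seed)
    if with_artifacts:
        return design, raw, cal_ids, val_ids, artifacts
    return design, raw, cal_ids, val_ids


def run_pipeline(config: PipelineConfig = PipelineConfig(),
                 outdir: str | Path | None = None) -> PipelineResult:
    """Execute the full study workflow; optionally write a run directory.

    Deterministic given the config: the same config (and hence seeds)
    produces byte-identical reports.
    """
    design, raw, cal_ids, val_ids, artifacts = _generate_and_split(
        config, with_artifacts=True)
    stages, shifts, target = _preprocess_with_target(raw, cal_ids, config)

    cal_rows = [design.sample_ids.index(s) for s in cal_ids]
    val_rows = [design.sample_ids.index(s) for s in val_ids]
    X = stages["sg"]
    Y_cal, Y_val = design.values[cal_rows], design.values[val_rows]
    model, cv, n_lv, y_pred_val = _fit_and_validate(
        X[cal_rows], Y_cal, X[val_rows], Y_val, config)
    y_fit_cal = pls_predict(model, X[cal_rows])

    report: dict = {
        "package_version": _pkg_version,
        "seeds": {"master": config.seed, "artifacts": config.artifact_seed,
                  "split": config.split_seed, "cv": config.cv_seed,
                  "permutation": config.perm_seed},
        "split": {"calibration": cal_ids, "validation": val_ids},
        "cv_scheme": cv.scheme,
        "n_lv": n_lv,
        "rmsecv_curve": cv.rmsecv.tolist(),
        "analytes": {},
    }
    hx, hy = leverages(model)
    t2, t2_crit = hotelling_t2(model, config.alpha)
    report["diagnostics"] = {
        "leverage_x": hx.tolist(), "leverage_y": hy.tolist(),
        "hotelling_t2": t2.tolist(), "t2_critical": t2_crit,
        "t2_outliers": [cal_ids[i] for i in np.nonzero(t2 > t2_crit)[0]],
    }
    for a, name in enumerate(design.analytes):
        es_cal = error_stats(y_fit_cal[:, a], Y_cal[:, a])
        es_val = error_stats(y_pred_val[:, a], Y_val[:, a])
        rmsecv_a = float(cv.rmsecv[n_lv - 1, a])
        y = Y_cal[:, a]
        sd = y.std(ddof=1)
        y_scaled = (y - y.mean()) / sd
        cv_resid_scaled = (cv.predictions[n_lv - 1, :, a] - y) / sd
        anova = cv_anova(y_scaled, cv_resid_scaled)
        z, flags = standardized_residuals(y_pred_val[:, a], Y_val[:, a])
        qq_x, qq_y = normal_probability_coords(z)
        entry = {
            "rmsecv": rmsecv_a,
            "calibration": asdict(es_cal),
            "validation": asdict(es_val),
            "recovery": _recoveries(y_pred_val[:, a], Y_val[:, a]),
            "cv_anova": anova.as_dict(),
            "standardized_residuals": z.tolist(),
            "residual_outliers": [val_ids[i] for i in np.nonzero(flags)[0]],
            "normal_probability": {"theoretical": qq_x.tolist(),
                                   "sorted_z": qq_y.tolist()},
        }
        if config.run_permutation:
            perm = permutation_test(X[cal_rows], y, n_lv,
                                    n_perm=config.n_perm,
                                    seed=config.perm_seed,
                                    x_mode=config.x_scaling)
            entry["permutation"] = {
                "n_perm": perm.n_perm,
                "r2_intercept": perm.r2_intercept,
                "q2_intercept": perm.q2_intercept,
                "r2_original": perm.r2_original,
                "q2_original": perm.q2_original,
                "max_permuted_q2": float(perm.q2_values[1:].max()),
            }
        report["analytes"][name] = entry

    # dosage-form assay emulation: three replicate measurements of the
    # fixed-ratio tablet sample through the same preprocessing and model
    tab_conc = tablet_concentrations(config.analytes)
    n_rep = 3
    tab_table = ConcentrationTable(
        [f"tablet{r + 1}" for r in range(n_rep)], list(design.analytes),
        np.tile([tab_conc[nm] for nm in design.analytes], (n_rep, 1)))
    tab_raw, _ = simulate(tab_table, config.analytes,
                          replace(artifacts, seed=artifacts.seed + 1000),
                          config.grid)
    tab_corr = correct_set(tab_raw, config.airpls)
    tab_ali, _ = icoshift_align(tab_corr, config.icoshift, target=target)
    tab_X = apply_sg(tab_ali.matrix, config.sg, step=config.grid.step)
    tab_pred = pls_predict(model, tab_X)
    tab_rec = 100.0 * tab_pred / tab_table.values
    report["tablet_assay"] = {
        "nominal_mol_per_L": tab_conc,
        "n_replicates": n_rep,
        "recovery_mean": {nm: float(tab_rec[:, a].mean())
                          for a, nm in enumerate(design.analytes)},
        "recovery_sd": {nm: float(tab_rec[:, a].std(ddof=1))
                        for a, nm in enumerate(design.analytes)},
    }

    ladder = None
    if config.run_ladder:
        ladder = reproduce_preprocessing_ladder(config, stages, design,
                                                cal_ids, val_ids)
        report["preprocessing_ladder"] = ladder.to_dict(orient="records")

    predictions_val = ConcentrationTable(list(val_ids), list(design.analytes),
                                         np.maximum(y_pred_val, 0.0))
    result = PipelineResult(config, design, raw, stages, shifts,
                            list(cal_ids), list(val_ids), model, cv, n_lv,
                            predictions_val, report, ladder)
    if outdir is not None:
        result.outdir = _write_run(result, Path(outdir))
    return result


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_run(result: PipelineResult, outdir: Path) -> Path:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    grid = result.raw.grid
    cfg.to_yaml(outdir / "config.yaml")
    write_concentration_table(result.design, outdir / "design.csv")
    write_voltammogram_set(result.raw, outdir / "voltammograms_raw.csv")
    for stage in ("airpls", "airpls_icoshift", "sg"):
        write_voltammogram_set(result.raw.with_matrix(result.stages[stage]),
                               outdir / f"voltammograms_{stage}.csv")
    pd.DataFrame(result.shifts, index=result.raw.sample_ids).to_csv(
        outdir / "icoshift_shifts.csv", index_label="sample_id")
    model_to_json(result.model, outdir / "model.json")
    pd.DataFrame(result.cv.rmsecv,
                 index=np.arange(1, result.cv.max_lv + 1),
                 columns=result.design.analytes).to_csv(
        outdir / "rmsecv_curve.csv", index_label="n_lv")
    write_concentration_table(result.predictions_val,
                              outdir / "predictions_validation.csv")
    if result.ladder is not None:
        result.ladder.to_csv(outdir / "preprocessing_ladder.csv", index=False)
    (outdir / "validation_report.json").write_text(
        json.dumps(result.report, sort_keys=True, indent=1), encoding="utf-8")
    files = sorted(p.name for p in outdir.iterdir()
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "package_version": _pkg_version,
        "config": cfg.to_dict(),
        "seeds": result.report["seeds"],
        "stage_hashes": {name: _sha256(outdir / name) for name in files},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1), encoding="utf-8")
    return outdir
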