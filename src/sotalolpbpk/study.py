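"""End-to-end study pipeline: calibrate, simulate, synthesize, evaluate.

Mirrors the modeling workflow: the adult model is calibrated (permeability
to 90% oral bioavailability), adult IV and oral mean datasets are compared
against virtual-population mean curves, and the pediatric cohort is
compared against virtual-twin median curves, with Obs/Pred ratio summaries,
range classifications and MDPE/MDAPE per age group.

With the synthetic generator in closed-loop configuration (no residual
noise, identity truth perturbations, variability off, anthropometric
resampling off) the pipeline is an identity: every ratio is exactly 1 and
every error metric 0.  That property is the primary correctness check of
the plumbing; the statistical behavior under noise is exercised separately.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, nca, popsim, synthetic_data
from .absorption import AbsorptionSettings, CalibrationReport, calibrate_permeability
from .distribution import sotalol_parameters
from .evaluation import mdpe_mdape, percentage_errors, range_fraction, summaries_by_group
from .nca import ConcentrationTimeProfile, nca_metrics
from .popsim import VariabilitySpec, fixed_variability, alternative_variability
from .synthetic_data import SyntheticCohortSpec


@dataclass
class StudyConfig:
    """Every knob of the pipeline; round-trips losslessly through YAML."""

    variant: str = "variant_a"
    seed: int = 0
    target_bioavailability: float = 0.90
    variability: str = "default"        # default | alternative | fixed
    truth_perturbation: str = "default"  # default | identity
    residual_error_cv: float = 0.20
    group_sizes: dict = field(
        default_factory=lambda: dict(synthetic_data.DEFAULT_GROUP_SIZES))
    n_twins: int = 100
    resample_anthropometrics: bool = True
    include_adult_stage: bool = True
    adult_population_n: int = 100
    adult_max_datasets: int | None = None
    n_bootstrap: int = 10_000
    out_dir: str | None = None
    log_level: str = "INFO"

    def variability_spec(self) -> VariabilitySpec:
        return {"default": VariabilitySpec(),
                "alternative": alternative_variability(),
                "fixed": fixed_variability()}[self.variability]

    def truth_spec(self) -> VariabilitySpec:
        return (fixed_variability() if self.truth_perturbation == "identity"
                else VariabilitySpec())

    def cohort_spec(self) -> SyntheticCohortSpec:
        return SyntheticCohortSpec(
            group_sizes=dict(self.group_sizes),
            residual_error_cv=self.residual_error_cv,
            truth_perturbation=self.truth_spec())

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError("config file must hold a mapping")
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def closed_loop(self) -> "StudyConfig":
        """Copy configured as the exact closed loop (identity pipeline)."""
        return dataclasses.replace(
            self, variability="fixed", truth_perturbation="identity",
            residual_error_cv=0.0, resample_anthropometrics=False)


@dataclass
class StudyReport:
    config: StudyConfig
    calibration: CalibrationReport
    per_subject_ratios: pd.DataFrame
    group_summaries: pd.DataFrame
    error_metrics: pd.DataFrame
    adult_auc_range_fraction: float | None

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = (f"# config_hash={self.config.config_hash()} "
                  f"seed={self.config.seed}\n")
        for name, df in (("per_subject_ratios", self.per_subject_ratios),
                         ("group_summaries", self.group_summaries),
                         ("error_metrics", self.error_metrics)):
            path = out / f"{name}.csv"
            with open(path, "w") as fh:
                fh.write(header)
                df.to_csv(fh, index=False)
        (out / "calibration.txt").write_text(
            header + self.calibration.to_text())


def run_calibrate(config: StudyConfig) -> tuple[CalibrationReport, AbsorptionSettings]:
    """Calibrate permeability for the configured variant; optionally write report."""
    drug = sotalol_parameters(config.variant)
    report = calibrate_permeability(config.target_bioavailability, drug)
    settings = AbsorptionSettings().with_permeability(report.effective_permeability)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "calibration.txt").write_text(
            f"# config_hash={config.config_hash()} seed={config.seed}\n"
            + report.to_text())
    return report, settings


def _predicted_at(times, curve_times, curve) -> np.ndarray:
    return np.clip(np.interp(times, curve_times, curve), 0.0, None)


def run_full_study(config: StudyConfig) -> StudyReport:
    """Execute adult IV/oral and pediatric stages and evaluate predictions."""
    drug = sotalol_parameters(config.variant)
    report, ab = run_calibrate(config)
    var_spec = config.variability_spec()
    ss = np.random.SeedSequence(config.seed)
    rng_adult_obs, rng_adult_pred, rng_child, rng_obs, rng_twins, rng_boot = (
        np.random.default_rng(s) for s in ss.spawn(6))

    subject_ages: dict[str, float] = {}
    obs_metrics: dict[str, nca.NCAMetrics] = {}
    pred_metrics: dict[str, nca.NCAMetrics] = {}
    pe_rows: list[tuple[str, np.ndarray]] = []

    # ---- adult stage: mean observed datasets vs population mean curves ----
    adult_auc_ratios = None
    if config.include_adult_stage:
        descriptor = synthetic_data.default_adult_descriptor()
        datasets = synthetic_data.generate_adult_datasets(
            descriptor, drug=drug, absorption_settings=ab, spec=config.truth_spec(),
            residual_error_cv=config.residual_error_cv, seed=rng_adult_obs,
            resample_anthropometrics=config.resample_anthropometrics)
        if config.adult_max_datasets is not None:
            datasets = datasets[: config.adult_max_datasets]
        for arm, obs in datasets:
            pop = popsim.simulate_adult_population(
                arm, n=config.adult_population_n, spec=var_spec, drug=drug,
                absorption_settings=ab, seed=rng_adult_pred,
                resample_anthropometrics=config.resample_anthropometrics)
            pred_c = _predicted_at(obs.times, pop.times, pop.summary_mean)
            pred = ConcentrationTimeProfile(
                subject_id=obs.subject_id, times=obs.times,
                concentrations=pred_c, age=None)
            sid = obs.subject_id
            subject_ages[sid] = 30.0  # adult stratum
            obs_metrics[sid] = nca_metrics(obs)
            pred_metrics[sid] = nca_metrics(pred)
            pe, _ = percentage_errors(pop.times, pop.summary_mean, obs)
            pe_rows.append(("adults", pe))
        adult_auc_ratios = np.array(
            [obs_metrics[s].auc_last / pred_metrics[s].auc_last
             for s in subject_ages])

    # ---- pediatric stage: individual children vs virtual-twin medians ----
    cohort, truth = synthetic_data.generate_pediatric_cohort(
        config.cohort_spec(), rng_child)
    observed = synthetic_data.generate_observed_profiles(
        cohort, truth, drug=drug, absorption_settings=ab,
        spec=config.cohort_spec(), seed=rng_obs)
    obs_by_id = {p.subject_id: p for p in observed}
    for _, row in cohort.iterrows():
        rec = synthetic_data.child_record(row)
        twins = popsim.simulate_virtual_twins(
            rec, n=config.n_twins, spec=var_spec, drug=drug,
            absorption_settings=ab, seed=rng_twins,
            resample_anthropometrics=config.resample_anthropometrics)
        obs = obs_by_id[rec.subject_id]
        pred_c = _predicted_at(obs.times, twins.times, twins.summary_median)
        pred = ConcentrationTimeProfile(
            subject_id=rec.subject_id, times=obs.times,
            concentrations=pred_c, age=rec.age)
        subject_ages[rec.subject_id] = rec.age
        obs_metrics[rec.subject_id] = nca_metrics(obs)
        pred_metrics[rec.subject_id] = nca_metrics(pred)
        pe, _ = percentage_errors(twins.times, twins.summary_median, obs)
        pe_rows.append((evaluation.assign_age_group(rec.age), pe))

    # ---- evaluation tables ----
    group_summaries = summaries_by_group(
        subject_ages, obs_metrics, pred_metrics,
        n_bootstrap=config.n_bootstrap, seed=rng_boot)
    err_rows = []
    for label in evaluation.AGE_GROUP_LABELS:
        pes = [pe for g, pe in pe_rows if g == label]
        if not pes:
            continue
        pooled = np.concatenate(pes)
        m = mdpe_mdape(pooled, n_bootstrap=config.n_bootstrap, seed=rng_boot)
        err_rows.append({"age_group": label, "mdpe": m.mdpe, "mdape": m.mdape,
                         "mdpe_ci_low": m.mdpe_ci[0], "mdpe_ci_high": m.mdpe_ci[1],
                         "mdape_ci_low": m.mdape_ci[0],
                         "mdape_ci_high": m.mdape_ci[1],
                         "n_points": m.n_points})
    error_metrics = pd.DataFrame(err_rows)

    ratio_rows = []
    for sid in subject_ages:
        for param in ("auc_last", "cmax", "tmax", "ke"):
            o = getattr(obs_metrics[sid], param)
            p = getattr(pred_metrics[sid], param)
            if o is None or p is None or p <= 0:
                continue
            ratio_rows.append({
                "subject_id": sid,
                "age_group": evaluation.assign_age_group(subject_ages[sid]),
                "parameter": param, "observed": o, "predicted": p,
                "ratio": o / p})
    per_subject = pd.DataFrame(ratio_rows)

    result = StudyReport(
        config=config, calibration=report,
        per_subject_ratios=per_subject,
        group_summaries=group_summaries,
        error_metrics=error_metrics,
        adult_auc_range_fraction=(
            range_fraction(adult_auc_ratios) if adult_auc_ratios is not None
            and len(adult_auc_ratios) else None),
    )
    if config.out_dir:
        result.write(config.out_dir)
    return result
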