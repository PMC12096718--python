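"""File I/O and the end-to-end pipeline: generate -> fit -> metrics -> report.

CSV schemas (all times in decimal hours from loading-dose start, all
concentrations in mg/L, 0-based time origin):

patients.csv:     patient_id, drug, age_y, sex, weight_kg, height_cm,
                  creatinine_umol_L, sofa, trauma (0/1)
doses.csv:        patient_id, loading_mg, loading_duration_h,
                  maintenance_mg, maintenance_duration_h, tau_h, horizon_h
observations.csv: patient_id, time_h, conc_mg_L, role, blq (0/1)
truth.csv:        patient_id, eta_*, CL, V1, Q, V2 (simulation ground truth)

A NONMEM-style event table (ID, TIME, AMT, RATE, DV, EVID, MDV) is accepted
as an alternative dosing/observation dialect. Every output file starts with
a comment header line carrying the seed and a configuration hash, so a
re-run with identical settings reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, SyntheticPatient, generate_cohort
from .estimate import FitResult, Observation, ObservationSet, map_fit
from .exposure import DEFAULT_TARGETS, ExposureSummary, MICTarget, exposure_summary
from .pk import DosingRegimen, InfusionEvent, PopulationModel, default_model_path, load_population_model
from .renal import PatientCovariates, assess_renal_function
from .stats import cda_curves, roc_cutoff, summarize_cohort, wilcoxon_exact

__all__ = [
    "PatientRecord",
    "RunConfig",
    "write_cohort",
    "read_patient_data",
    "read_nonmem_table",
    "run_pipeline",
    "load_default_models",
]

logger = logging.getLogger(__name__)

_SEXES = {"male", "female"}
_DRUGS = {"meropenem", "piperacillin"}


@dataclass(frozen=True)
class PatientRecord:
    """One patient's inputs: covariates, regimen, observations."""

    covariates: PatientCovariates
    drug: str
    regimen: DosingRegimen
    observations: ObservationSet


@dataclass(frozen=True)
class RunConfig:
    """Pipeline run configuration; the seed is recorded in every output header."""

    output_dir: Path
    seed: int = 0
    model_paths: dict[str, Path] = field(default_factory=dict)
    targets: dict[str, MICTarget] = field(default_factory=lambda: dict(DEFAULT_TARGETS))
    cohort: Optional[CohortConfig] = None
    input_dir: Optional[Path] = None

    def config_hash(self) -> str:
        payload = {
            "seed": self.seed,
            "targets": {d: (t.mic, t.unbound_fraction, t.multiplier) for d, t in sorted(self.targets.items())},
            "cohort": None
            if self.cohort is None
            else {
                "n_meropenem": self.cohort.n_meropenem,
                "n_piperacillin": self.cohort.n_piperacillin,
                "seed": self.cohort.seed,
                "trough_jitter_sd": self.cohort.trough_jitter_sd,
                "arc_linkage_rho": self.cohort.arc_linkage_rho,
                "arc_fraction": self.cohort.arc_fraction,
            },
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def load_default_models() -> dict[str, PopulationModel]:
    """The packaged meropenem and piperacillin population models."""
    return {d: load_population_model(default_model_path(d)) for d in ("meropenem", "piperacillin")}


def _write_csv(df: pd.DataFrame, path: Path, seed: int, config_hash: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# firstdose v{__version__} seed={seed} config={config_hash}\n")
        df.to_csv(fh, index=False, float_format="%.17g")  # lossless float round trip


def _read_csv(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def write_cohort(patients: Sequence[SyntheticPatient], out_dir: Union[str, Path], seed: int, config_hash: str = "-") -> None:
    """Write patients/doses/observations/truth CSVs for a synthetic cohort."""
    out = Path(out_dir)
    pats, doses, obs_rows, truth = [], [], [], []
    for p in patients:
        c = p.covariates
        pats.append(
            dict(
                patient_id=c.patient_id,
                drug=p.drug,
                age_y=c.age,
                sex=c.sex,
                weight_kg=c.weight,
                height_cm=c.height,
                creatinine_umol_L=c.serum_creatinine,
                sofa=c.sofa,
                trauma=int(c.trauma_admission),
            )
        )
        r = p.regimen
        doses.append(
            dict(
                patient_id=c.patient_id,
                loading_mg=r.loading.amount,
                loading_duration_h=r.loading.duration,
                maintenance_mg=r.maintenance_amount,
                maintenance_duration_h=r.maintenance_duration,
                tau_h=r.tau,
                horizon_h=r.horizon,
            )
        )
        for o in p.observations:
            obs_rows.append(
                dict(patient_id=c.patient_id, time_h=o.time, conc_mg_L=o.concentration, role=o.role, blq=int(o.blq))
            )
        row = dict(patient_id=c.patient_id)
        row.update({f"eta_{k}": v for k, v in p.true_eta.items()})
        tp = p.true_parameters
        row.update(CL=tp.CL, V1=tp.V1, Q=tp.Q, V2=tp.V2)
        truth.append(row)
    _write_csv(pd.DataFrame(pats), out / "patients.csv", seed, config_hash)
    _write_csv(pd.DataFrame(doses), out / "doses.csv", seed, config_hash)
    _write_csv(pd.DataFrame(obs_rows), out / "observations.csv", seed, config_hash)
    _write_csv(pd.DataFrame(truth), out / "truth.csv", seed, config_hash)


def _validation_error(table: str, rows: list[int], message: str) -> ValueError:
    return ValueError(f"{table}: {message} (rows {rows})")


def read_patient_data(
    patients_csv: Union[str, Path],
    doses_csv: Union[str, Path],
    observations_csv: Optional[Union[str, Path]] = None,
) -> list[PatientRecord]:
    """Read and validate the CSV dialect into patient records.

    Row-level validation failures raise with the offending 0-based row
    indices of the source table.
    """
    pats = _read_csv(patients_csv)
    doses = _read_csv(doses_csv)
    obs = _read_csv(observations_csv) if observations_csv is not None else pd.DataFrame(
        columns=["patient_id", "time_h", "conc_mg_L", "role", "blq"]
    )

    bad = [i for i, d in enumerate(pats["drug"]) if d not in _DRUGS]
    if bad:
        raise _validation_error("patients", bad, "unknown drug label")
    bad = [i for i, s in enumerate(pats["sex"]) if s not in _SEXES]
    if bad:
        raise _validation_error("patients", bad, "sex must be male/female")
    for col in ("age_y", "weight_kg", "height_cm", "creatinine_umol_L"):
        bad = [int(i) for i in np.flatnonzero(~(pats[col] > 0))]
        if bad:
            raise _validation_error("patients", bad, f"{col} must be > 0")
    bad = [int(i) for i in np.flatnonzero(~(obs["conc_mg_L"] > 0) & ~(obs["blq"].astype(bool)))]
    if bad:
        raise _validation_error("observations", bad, "non-BLQ concentration must be > 0")
    bad = [int(i) for i in np.flatnonzero(obs["time_h"] < 0)]
    if bad:
        raise _validation_error("observations", bad, "time_h must be >= 0")

    doses_by_id = doses.set_index("patient_id")
    records = []
    for _, row in pats.iterrows():
        pid = row["patient_id"]
        cov = PatientCovariates(
            patient_id=str(pid),
            age=float(row["age_y"]),
            sex=str(row["sex"]),
            weight=float(row["weight_kg"]),
            height=float(row["height_cm"]),
            serum_creatinine=float(row["creatinine_umol_L"]),
            sofa=int(row.get("sofa", 0)),
            trauma_admission=bool(int(row.get("trauma", 0))),
        )
        if pid not in doses_by_id.index:
            raise ValueError(f"doses: no dosing row for patient {pid!r}")
        d = doses_by_id.loc[pid]
        regimen = DosingRegimen(
            drug=str(row["drug"]),
            loading=InfusionEvent(start=0.0, duration=float(d["loading_duration_h"]), amount=float(d["loading_mg"])),
            maintenance_amount=float(d["maintenance_mg"]),
            tau=float(d["tau_h"]),
            maintenance_duration=float(d["maintenance_duration_h"]),
            horizon=float(d.get("horizon_h", 24.0)),
        )
        sub = obs[obs["patient_id"] == pid].sort_values("time_h")
        oset = ObservationSet(
            tuple(
                Observation(float(o["time_h"]), float(o["conc_mg_L"]), str(o["role"]), bool(int(o["blq"])))
                for _, o in sub.iterrows()
            )
        )
        records.append(PatientRecord(covariates=cov, drug=str(row["drug"]), regimen=regimen, observations=oset))
    return records


def read_nonmem_table(path: Union[str, Path], drug: str, tau: float) -> tuple[DosingRegimen, ObservationSet]:
    """Parse a one-subject NONMEM-style event table into a regimen and observations.

    Columns: ID, TIME, AMT, RATE, DV, EVID, MDV. Dose records (EVID = 1)
    carry AMT (mg) and RATE (mg/h), giving duration = AMT/RATE; observation
    records (EVID = 0, MDV = 0) carry DV (mg/L). The loading dose is the
    dose record at TIME 0; the maintenance amount comes from the second
    dose record. Only the regimen skeleton (loading + repeating maintenance
    every `tau`) is reconstructed.
    """
    df = _read_csv(path)
    df.columns = [c.upper() for c in df.columns]
    ids = df["ID"].unique()
    if len(ids) != 1:
        raise ValueError(f"expected a single-subject table, got IDs {list(ids)}")
    dose_rows = df[df["EVID"] == 1].sort_values("TIME")
    if len(dose_rows) < 2:
        raise ValueError("event table must contain at least loading and one maintenance dose")
    loading_row = dose_rows.iloc[0]
    if float(loading_row["TIME"]) != 0.0:
        raise ValueError("loading dose must start at TIME 0")
    maint_row = dose_rows.iloc[1]
    loading = InfusionEvent(
        start=0.0, duration=float(loading_row["AMT"]) / float(loading_row["RATE"]), amount=float(loading_row["AMT"])
    )
    regimen = DosingRegimen(
        drug=drug,
        loading=loading,
        maintenance_amount=float(maint_row["AMT"]),
        tau=tau,
        maintenance_duration=float(maint_row["AMT"]) / float(maint_row["RATE"]),
    )
    obs_rows = df[(df["EVID"] == 0) & (df["MDV"] == 0)].sort_values("TIME")
    roles = {0: "post_loading_cmax", 1: "end_infusion"}
    observations = []
    for j, (_, o) in enumerate(obs_rows.iterrows()):
        role = roles.get(j, "trough")
        observations.append(Observation(float(o["TIME"]), float(o["DV"]), role))
    return regimen, ObservationSet(tuple(observations))


def _fit_patient(rec: PatientRecord, pop: PopulationModel) -> tuple[FitResult, ExposureSummary, dict]:
    ra = assess_renal_function(rec.covariates)
    fit = map_fit(rec.observations, pop, cov=rec.covariates, crcl=ra.crcl, regimen=rec.regimen)
    target = DEFAULT_TARGETS[rec.drug]
    summ = exposure_summary(fit.individual, rec.regimen, target, obs=rec.observations)
    r = rec.regimen
    row = dict(
        patient_id=rec.covariates.patient_id,
        drug=rec.drug,
        age=rec.covariates.age,
        weight=rec.covariates.weight,
        height=rec.covariates.height,
        serum_creatinine=rec.covariates.serum_creatinine,
        relative_egfr=ra.relative_egfr,
        crcl=ra.crcl,
        arc=ra.arc,
        suspected_arc=ra.suspected_arc,
        egfr_group=ra.egfr_group,
        regimen=f"{r.loading.amount / 1000:g}g+{r.maintenance_amount / 1000:g}g q{r.tau:g}h",
        CL=fit.individual.CL,
        V1=fit.individual.V1,
        Q=fit.individual.Q,
        V2=fit.individual.V2,
        objective=fit.objective,
        converged=fit.converged,
        cmax_observed=summ.cmax_observed,
        cmin_observed=summ.cmin_observed,
        cmin_predicted=summ.cmin_predicted_at_tau,
        # free trough over MIC: unbound fraction times total Cmin / MIC
        fcmin_mic_observed=None
        if summ.cmin_observed is None
        else summ.cmin_observed * target.unbound_fraction / target.mic,
        fcmin_mic_predicted=summ.cmin_predicted_at_tau * target.unbound_fraction / target.mic,
        ft_above_interval=summ.ft_above_interval,
        ft_above_24h=summ.ft_above_24h,
        ft_above_4xmic_interval=summ.ft_above_4xmic_interval,
        attained_100=summ.attained_100,
        attained_50=summ.attained_50,
        attained_100_observed=summ.attained_100_observed,
        cmin_cmax_ratio=summ.cmin_cmax_ratio,
        terminal_half_life=summ.terminal_half_life,
        discordant=summ.discordant,
    )
    for name, val in fit.eta.items():
        row[f"eta_{name}"] = val
    return fit, summ, row


def run_pipeline(config: RunConfig, models: Optional[dict[str, PopulationModel]] = None) -> dict[str, pd.DataFrame]:
    """Execute the full analysis and write the report bundle.

    Either generates a synthetic cohort (config.cohort set) or reads CSVs
    from config.input_dir. Writes exposure.csv, cohort_summary.csv,
    comparisons.csv, roc.csv and run.log under config.output_dir. Returns
    the main tables. Non-converged fits are counted, logged, and excluded
    from model-based summaries.
    """
    t_start = time.time()
    if models is None:
        models = load_default_models()
        for drug, path in config.model_paths.items():
            models[drug] = load_population_model(path)

    if config.cohort is not None:
        patients = generate_cohort(config.cohort, models)
        write_cohort(patients, config.output_dir / "cohort", config.seed, config.config_hash())
        records = [
            PatientRecord(covariates=p.covariates, drug=p.drug, regimen=p.regimen, observations=p.observations)
            for p in patients
        ]
    elif config.input_dir is not None:
        d = Path(config.input_dir)
        records = read_patient_data(d / "patients.csv", d / "doses.csv", d / "observations.csv")
    else:
        raise ValueError("RunConfig needs either a cohort config or an input directory")

    rows = []
    n_nonconverged = 0
    for rec in records:
        _, _, row = _fit_patient(rec, models[rec.drug])
        if not row["converged"]:
            n_nonconverged += 1
        rows.append(row)
    report = pd.DataFrame(rows)
    usable = report[report["converged"]].copy()
    if n_nonconverged:
        logger.warning("%d non-converged fit(s) excluded from model-based summaries", n_nonconverged)

    chash = config.config_hash()
    out = Path(config.output_dir)
    _write_csv(report, out / "exposure.csv", config.seed, chash)

    summary = summarize_cohort(usable)
    _write_csv(summary["attainment"], out / "cohort_summary.csv", config.seed, chash)

    comp_rows, roc_rows = [], []
    for drug, grp in usable.groupby("drug"):
        hi = grp[grp["egfr_group"] == "above_90"]["cmin_observed"].dropna()
        lo = grp[grp["egfr_group"] == "at_or_below_90"]["cmin_observed"].dropna()
        if len(hi) and len(lo):
            c = wilcoxon_exact(lo, hi, label_x=f"{drug} eGFR<=90", label_y=f"{drug} eGFR>90")
            comp_rows.append(_comparison_row(drug, "cmin_by_egfr", c))
        sub = grp.dropna(subset=["cmin_cmax_ratio"])
        arc_mask = sub["suspected_arc"].astype(bool)
        if 0 < arc_mask.sum() < len(sub):
            c = wilcoxon_exact(
                sub.loc[arc_mask, "cmin_cmax_ratio"],
                sub.loc[~arc_mask, "cmin_cmax_ratio"],
                label_x=f"{drug} ARC",
                label_y=f"{drug} non-ARC",
            )
            comp_rows.append(_comparison_row(drug, "ratio_by_arc", c))
            if sub["cmin_cmax_ratio"].nunique() > 1:
                roc = roc_cutoff(sub["cmin_cmax_ratio"], arc_mask)
                _, cda_cut = cda_curves(sub["cmin_cmax_ratio"], arc_mask)
                roc_rows.append(
                    dict(
                        drug=drug,
                        cutoff=roc.cutoff,
                        sensitivity=roc.sensitivity,
                        specificity=roc.specificity,
                        youden_j=roc.youden_j,
                        cda_cutoff=cda_cut,
                    )
                )
    comparisons = pd.DataFrame(comp_rows)
    roc_df = pd.DataFrame(roc_rows)
    _write_csv(comparisons, out / "comparisons.csv", config.seed, chash)
    _write_csv(roc_df, out / "roc.csv", config.seed, chash)

    with open(out / "run.log", "w") as fh:
        fh.write(f"firstdose v{__version__}\nseed={config.seed}\nconfig={chash}\n")
        fh.write(f"n_patients={len(records)}\nn_nonconverged={n_nonconverged}\n")
        fh.write(f"elapsed_s={time.time() - t_start:.1f}\n")
        for row in rows:
            fh.write(f"patient {row['patient_id']}: converged={row['converged']} objective={row['objective']:.4f}\n")

    return {"exposure": report, "comparisons": comparisons, "roc": roc_df, **summary}


def _comparison_row(drug: str, quantity: str, c) -> dict:
    return dict(
        drug=drug,
        quantity=quantity,
        group_x=c.label_x,
        group_y=c.label_y,
        n_x=c.n_x,
        n_y=c.n_y,
        median_x=c.median_x,
        median_y=c.median_y,
        p_value=c.p_value,
        shift=c.shift_estimate,
        ci_low=c.ci_low,
        ci_high=c.ci_high,
    )
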