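"""Synthetic PBMC-assay cohorts with a controllable outcome link.

The generator emulates the statistical skeleton the analysis pipeline
assumes, so every stage is testable without patient data:

* per-analyte concentrations are log-normal on the pg/mL scale;
* S. pyogenes induction multiplies the unstimulated level by an
  analyte-specific fold change (times log-normal noise);
* each biologic multiplies the induced level by a per-analyte effect
  (< 1 = suppression), again with noise;
* clinical response is tied to the realized ex vivo suppression of a
  target index (default IFN-g/IL-13) through a Gaussian copula whose
  latent correlation r = 2 sin(pi * rho_s / 6) is calibrated so the
  rank correlation between the index's reduction rate and the PASI
  rate approaches ``target_rho``;
* concentrations below the per-analyte lower limit of quantification
  are emitted as below-range (censored) measurements.

Everything is reproducible from a single seed. The copula calibration
is exact for continuous latent pairs and approximate once censoring or
heavy ties intervene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats

import yaml

from .indices import parse_index
from .model import (
    Analyte,
    AssayMeasurement,
    BiologicCourse,
    Censor,
    CohortDataset,
    Condition,
    ConditionKind,
    PatientRecord,
    TROUGH_UG_ML,
    parse_analyte,
)

__all__ = ["SimulationConfig", "ConfigurationError", "simulate_cohort", "censor_lloq"]


class ConfigurationError(ValueError):
    """An internally inconsistent or infeasible simulation configuration."""


def _default_log_means():
    # unstimulated medians (pg/mL): exp of these values
    return {
        "IFN-g": math.log(5.0),
        "IL-13": math.log(0.42),
        "IL-4": math.log(2.7),
        "IL-17A": math.log(5.0),
        "IL-6": math.log(20.0),
    }


def _default_log_sds():
    return {"IFN-g": 1.0, "IL-13": 0.9, "IL-4": 0.9, "IL-17A": 1.0, "IL-6": 1.0}


def _default_induction():
    # fold induction by heat-inactivated S. pyogenes
    return {"IFN-g": 20.0, "IL-13": 4.0, "IL-4": 3.0, "IL-17A": 10.0, "IL-6": 50.0}


def _default_effects():
    # per-biologic multiplicative effect on induced levels, by mechanism class
    tnf = {"IFN-g": 0.85, "IL-17A": 0.9, "IL-13": 1.05, "IL-4": 1.05, "IL-6": 0.9}
    il1223 = {"IFN-g": 0.8, "IL-17A": 0.8, "IL-13": 1.1, "IL-4": 1.05, "IL-6": 0.95}
    il17 = {"IFN-g": 0.9, "IL-17A": 0.6, "IL-13": 1.05, "IL-4": 1.0, "IL-6": 0.9}
    il23 = {"IFN-g": 0.85, "IL-17A": 0.75, "IL-13": 1.05, "IL-4": 1.0, "IL-6": 0.95}
    return {
        "ada": dict(tnf), "gol": dict(tnf), "cer": dict(tnf),
        "ust": dict(il1223),
        "ixe": dict(il17), "sec": dict(il17),
        "gus": dict(il23), "ris": dict(il23),
    }


def _default_lloq():
    # chosen so a few percent of IL-4 stimulated draws fall below range
    return {"IFN-g": 0.05, "IL-13": 0.05, "IL-4": 1.0, "IL-17A": 0.05, "IL-6": 0.05}


@dataclass
class SimulationConfig:
    """Full parameterization of a synthetic cohort.

    Defaults mirror the study conditions: 20 patients, mostly two (some
    three) biologic courses each, stimulated concentration scales in the
    ranges the assay reports, mild biologic effects, and a target rank
    correlation of 0.5 between the IFN-g/IL-13 reduction rate and the
    PASI rate — the magnitude of the headline association.
    """

    n_patients: int = 20
    biologics_per_patient: dict[int, float] = field(
        default_factory=lambda: {2: 0.8, 3: 0.2}
    )
    analyte_log_means: dict[str, float] = field(default_factory=_default_log_means)
    analyte_log_sds: dict[str, float] = field(default_factory=_default_log_sds)
    induction_multipliers: dict[str, float] = field(default_factory=_default_induction)
    biologic_effects: dict[str, dict[str, float]] = field(default_factory=_default_effects)
    noise_sd: float = 0.15  # log-scale sd of induction/treatment noise
    target_rho: float = 0.5
    target_index: str = "IFN-g/IL-13"
    lloq: dict[str, float] = field(default_factory=_default_lloq)
    pasi_baseline_range: tuple[float, float] = (3.0, 40.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        probs = np.array(list(self.biologics_per_patient.values()), dtype=float)
        if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigurationError("biologics_per_patient must be a probability distribution")
        if any(k < 1 for k in self.biologics_per_patient):
            raise ConfigurationError("biologics_per_patient counts must be >= 1")
        if not abs(self.target_rho) <= 1.0:
            raise ConfigurationError(f"|target_rho| must be <= 1, got {self.target_rho}")
        for name, m in {**self.induction_multipliers}.items():
            if m <= 0:
                raise ConfigurationError(f"induction multiplier for {name} must be > 0")
        for bio, eff in self.biologic_effects.items():
            for name, m in eff.items():
                if m <= 0:
                    raise ConfigurationError(f"effect {bio}/{name} must be > 0")
        if any(v < 0 for v in self.lloq.values()):
            raise ConfigurationError("lloq must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        lo, hi = self.pasi_baseline_range
        if not (0 < lo <= hi <= 72.0 / 1.1):
            raise ConfigurationError("pasi_baseline_range must fit inside the PASI scale")
        parse_index(self.target_index)
        for name in self.analyte_log_means:
            parse_analyte(name)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        cfg = cls()
        for k, v in d.items():
            if not hasattr(cfg, k):
                raise ConfigurationError(f"unknown simulation option {k!r}")
            if k == "biologics_per_patient":
                v = {int(kk): float(vv) for kk, vv in v.items()}
            if k == "pasi_baseline_range":
                v = tuple(float(x) for x in v)
            setattr(cfg, k, v)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def censor_lloq(ds: CohortDataset, lloq) -> CohortDataset:
    """Censor every measurement strictly below its analyte's limit.

    *lloq* is a scalar limit or an analyte->limit mapping (pg/mL);
    analytes without a limit are untouched, as are already-censored
    measurements. Raising the limit can only increase the censored count.
    """
    if not isinstance(lloq, dict):
        lloq = {a.value: float(lloq) for a in Analyte}
    limits = {parse_analyte(k): float(v) for k, v in lloq.items()}
    new_assays = []
    for m in ds.assays:
        lim = limits.get(m.analyte)
        if (
            lim is not None
            and m.censor == Censor.OBSERVED
            and m.concentration is not None
            and m.concentration < lim
        ):
            m = replace(m, concentration=None, censor=Censor.BELOW_RANGE)
        new_assays.append(m)
    return CohortDataset(ds.patients, ds.courses, tuple(new_assays))


def _effect(cfg: SimulationConfig, biologic: str, analyte: str) -> float:
    return cfg.biologic_effects.get(biologic, {}).get(analyte, 1.0)


def simulate_cohort(cfg: Optional[SimulationConfig] = None) -> CohortDataset:
    """Draw one synthetic cohort; identical seeds give identical datasets."""
    cfg = cfg or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    analytes = list(cfg.analyte_log_means)
    target = parse_index(cfg.target_index)
    for a in target.analytes():
        if a.value not in cfg.analyte_log_means:
            raise ConfigurationError(
                f"target index {cfg.target_index!r} references unsimulated analyte {a.value!r}"
            )

    counts = sorted(cfg.biologics_per_patient)
    probs = [cfg.biologics_per_patient[k] for k in counts]

    patients, courses, assays = [], [], []
    course_info = []  # (patient_id, biologic, induced panel, treated panel)
    for i in range(cfg.n_patients):
        pid = f"S{i + 1:03d}"
        patients.append(
            PatientRecord(
                patient_id=pid,
                age=int(rng.integers(20, 66)),
                sex="M" if rng.random() < 0.5 else "F",
                has_pso=True,
                has_psa=bool(rng.random() < 0.5),
            )
        )
        control = {
            a: float(rng.lognormal(cfg.analyte_log_means[a], cfg.analyte_log_sds[a]))
            for a in analytes
        }
        induced = {
            a: control[a]
            * cfg.induction_multipliers.get(a, 1.0)
            * float(rng.lognormal(0.0, cfg.noise_sd))
            for a in analytes
        }
        n_bio = int(rng.choice(counts, p=probs))
        n_bio = min(n_bio, len(TROUGH_UG_ML))
        bios = sorted(rng.choice(list(TROUGH_UG_ML), size=n_bio, replace=False))
        for a in analytes:
            an = parse_analyte(a)
            assays.append(
                AssayMeasurement(pid, Condition(ConditionKind.CONTROL), an, control[a])
            )
            assays.append(
                AssayMeasurement(pid, Condition(ConditionKind.INDUCED), an, induced[a])
            )
        for bio in bios:
            treated = {
                a: induced[a] * _effect(cfg, bio, a) * float(rng.lognormal(0.0, cfg.noise_sd))
                for a in analytes
            }
            dose = TROUGH_UG_ML[bio][-1]
            cond = Condition(ConditionKind.INDUCED_PLUS_BIOLOGIC, bio, dose)
            for a in analytes:
                assays.append(AssayMeasurement(pid, cond, parse_analyte(a), treated[a]))
            course_info.append((pid, bio, induced, treated))

    # realized ex vivo suppression of the target index per course
    def idx_value(panel):
        if target.denominator is None:
            return panel[target.numerator.value]
        return panel[target.numerator.value] / panel[target.denominator.value]

    rates = np.array(
        [
            (idx_value(tr) - idx_value(ind)) / idx_value(ind)
            for (_, _, ind, tr) in course_info
        ]
    )
    if np.ptp(rates) == 0 and cfg.target_rho != 0 and len(rates) > 1:
        raise ConfigurationError(
            "target_rho != 0 is infeasible: the configured effects and noise "
            "produce identical index changes for every course"
        )

    # Gaussian copula between realized suppression and clinical response
    n = len(course_info)
    r_latent = 2.0 * math.sin(math.pi * cfg.target_rho / 6.0)
    u = stats.norm.ppf((stats.rankdata(rates) - 0.5) / n)
    z = r_latent * u + math.sqrt(max(0.0, 1.0 - r_latent**2)) * rng.standard_normal(n)
    # monotone map latent -> PASI rate in (-1, 0.1]: most courses improve
    # strongly, a small tail worsens, mimicking clinical response spreads
    pasi_rate = -1.0 + 1.1 * stats.norm.cdf(z) ** 2

    lo, hi = cfg.pasi_baseline_range
    per_patient_order: dict[str, int] = {}
    for k, (pid, bio, _, _) in enumerate(course_info):
        before = round(float(rng.uniform(lo, hi)), 1)
        after = round(min(max(before * (1.0 + pasi_rate[k]), 0.0), 72.0), 1)
        order = per_patient_order.get(pid, 0) + 1
        per_patient_order[pid] = order
        courses.append(
            BiologicCourse(
                patient_id=pid,
                biologic=bio,
                order_index=order,
                pasi_before=before,
                pasi_after=after,
                months_to_outcome=float(rng.integers(6, 31)),
                tested_before_start=False,
            )
        )

    ds = CohortDataset(tuple(patients), tuple(courses), tuple(assays))
    ds = censor_lloq(ds, cfg.lloq)
    return ds.require_valid()
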