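"""Synthetic study cohorts for estimation experiments.

Emulates the clinical study this package models: 59 septic ICU patients on
the standard regimen (400 mg q12h for 3 doses, then 400 mg q24h) with sparse
therapeutic-drug-monitoring sampling — troughs immediately before the 3rd,
4th, 5th and 6th doses, plus one extra sample assigned in thirds (end of the
5th infusion / 1 h after the start of the 5th infusion / 1 h before the 6th
dose). Covariates are drawn to match the reported cohort: GFR stratified
over five renal-function classes, weight with median 65 kg on 35-90 kg,
age 28-92 y, 62.7% male, and a panel of distractor laboratory covariates
spanning the reported ranges (sampled independently — they carry no signal
and exist to exercise covariate screening).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pk import DoseEvent, conc_batch
from .population import PopulationModel, apply_residual, sample_individual

__all__ = [
    "LOQ_MG_L",
    "Observation",
    "SubjectRecord",
    "Dataset",
    "sample_covariates",
    "standard_design",
    "generate_dataset",
]

LOQ_MG_L = 3.125  # assay lower limit of quantification

# GFR strata: (lower, upper) bounds in mL/min/1.73 m^2 and cohort fractions.
GFR_STRATA = [(90.0, 124.0), (60.0, 90.0), (30.0, 60.0), (15.0, 30.0), (11.0, 15.0)]
GFR_STRATA_PROBS = [0.237, 0.339, 0.237, 0.085, 0.102]

# Distractor covariates: (low, high) spans of the reported cohort; sampled
# log-uniformly (heavily right-skewed labs) or uniformly, independent of PK.
_DISTRACTOR_RANGES = {
    "ALT": (4.0, 993.0, "log"),
    "AST": (11.0, 2390.0, "log"),
    "TBIL": (5.5, 244.0, "log"),
    "DBIL": (0.6, 141.0, "log"),
    "TP": (33.5, 71.0, "lin"),
    "ALB": (15.5, 39.4, "lin"),
    "WBC": (2.39, 25.9, "lin"),
    "SCR": (28.4, 429.0, "log"),
    "BUN": (1.09, 81.6, "log"),
    "HT": (1.33, 1.80, "lin"),
}

_WEIGHT_MEDIAN = 65.0
_WEIGHT_LOG_SD = 0.18
_WEIGHT_BOUNDS = (35.0, 90.0)


@dataclass(frozen=True)
class Observation:
    time: float       # h from first dose
    conc: float       # mg/L
    blq: bool = False  # below the limit of quantification


@dataclass
class SubjectRecord:
    id: int
    covariates: dict[str, float]
    doses: list[DoseEvent] = field(default_factory=list)
    observations: list[Observation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.doses and self.observations:
            first = min(d.start for d in self.doses)
            for o in self.observations:
                if o.time < first:
                    raise ValueError(
                        f"subject {self.id}: observation at {o.time} h precedes the first dose"
                    )


@dataclass
class Dataset:
    subjects: list[SubjectRecord]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return sum(len(s.observations) for s in self.subjects)

    def without_blq(self) -> "Dataset":
        """Copy with below-LOQ observations dropped (default estimation input)."""
        subs = [
            SubjectRecord(
                id=s.id,
                covariates=dict(s.covariates),
                doses=list(s.doses),
                observations=[o for o in s.observations if not o.blq],
            )
            for s in self.subjects
        ]
        return Dataset(subjects=subs, provenance=dict(self.provenance))


def sample_covariates(n: int, rng: np.random.Generator) -> list[dict[str, float]]:
    """Draw n covariate records matching the study cohort's distributions."""
    if n < 0:
        raise ValueError("n must be >= 0")
    records: list[dict[str, float]] = []
    if n == 0:
        return records
    strata = rng.choice(len(GFR_STRATA), size=n, p=GFR_STRATA_PROBS)
    for i in range(n):
        lo, hi = GFR_STRATA[strata[i]]
        gfr = rng.uniform(lo, hi)
        # truncated log-normal weight, median 65 kg
        while True:
            wt = _WEIGHT_MEDIAN * np.exp(rng.normal(0.0, _WEIGHT_LOG_SD))
            if _WEIGHT_BOUNDS[0] <= wt <= _WEIGHT_BOUNDS[1]:
                break
        rec = {
            "GFR": float(gfr),
            "WT": float(wt),
            "AGE": float(rng.integers(28, 93)),
            "SEX": float(rng.random() < 0.627),  # 1 = male
        }
        for name, (lo_, hi_, scale) in _DISTRACTOR_RANGES.items():
            if scale == "log":
                rec[name] = float(np.exp(rng.uniform(np.log(lo_), np.log(hi_))))
            else:
                rec[name] = float(rng.uniform(lo_, hi_))
        rec["BMI"] = rec["WT"] / rec["HT"] ** 2
        records.append(rec)
    return records


def standard_design(
    arm: int = 0,
    infusion_duration_h: float = 1.0,
    dose_mg: float = 400.0,
    horizon_h: float = 96.0,
) -> tuple[list[DoseEvent], list[float]]:
    """The study's standard regimen and sparse sampling schedule.

    Doses: 400 mg at 0, 12, 24 h (q12h x3) then q24h (48, 72, 96 h, ...).
    Samples: troughs immediately before the 3rd-6th doses (24, 48, 72, 96 h)
    plus one extra sample by arm: 0 — end of the 5th infusion; 1 — 1 h after
    the start of the 5th infusion; 2 — 1 h before the 6th dose (95 h).
    """
    doses = [DoseEvent(t, dose_mg, infusion_duration_h) for t in (0.0, 12.0, 24.0)]
    t = 48.0
    while t <= horizon_h:
        doses.append(DoseEvent(t, dose_mg, infusion_duration_h))
        t += 24.0
    troughs = [24.0, 48.0, 72.0, 96.0]
    extra = {
        0: 72.0 + infusion_duration_h,
        1: 73.0,
        2: 95.0,
    }[arm % 3]
    times = sorted(set(troughs + [extra]))
    return doses, times


def generate_dataset(
    n: int,
    true_model: PopulationModel,
    rng: np.random.Generator,
    missing_rate: float = 0.156,
    infusion_duration_h: float = 1.0,
    loq: float = LOQ_MG_L,
) -> Dataset:
    """Forward-simulate an estimation-ready cohort from a known model.

    Each subject gets covariates, the standard design (extra-sample arm
    assigned cyclically in thirds), individual parameters with IIV, and
    observed concentrations with proportional residual error (negative draws
    truncated to zero on write-out). Observations are independently thinned
    at ``missing_rate`` (default tuned to ~249 kept samples for n = 59) and
    flagged below ``loq``.
    """
    covs = sample_covariates(n, rng)
    subjects = []
    for i, cov in enumerate(covs):
        doses, times = standard_design(arm=i % 3, infusion_duration_h=infusion_duration_h)
        ind = sample_individual(true_model, cov, rng)
        starts = np.array([d.start for d in doses])
        amts = np.array([d.amount for d in doses])
        durs = np.array([d.duration for d in doses])
        pred = conc_batch(ind.params.as_array()[None, :], np.array(times), starts, amts, durs)[0]
        obs_conc = apply_residual(pred, true_model.residual, rng, truncate=True)
        keep = rng.random(len(times)) >= missing_rate
        observations = [
            Observation(time=t, conc=float(c), blq=bool(c < loq))
            for t, c, k in zip(times, np.atleast_1d(obs_conc), keep)
            if k
        ]
        subjects.append(
            SubjectRecord(id=i + 1, covariates=cov, doses=doses, observations=observations)
        )
    prov = {
        "generator": "teicopk.cohort.generate_dataset",
        "n_subjects": n,
        "missing_rate": missing_rate,
        "infusion_duration_h": infusion_duration_h,
        "loq": loq,
        "true_model": true_model.to_dict(),
    }
    return Dataset(subjects=subjects, provenance=prov)
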