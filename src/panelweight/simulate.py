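"""Synthetic two-year EHR encounter streams with planted utilization archetypes.

No public primary-care empanelment dataset carries the encounter detail this
pipeline needs, so the generator emulates one: a mixture of utilization
archetypes, each defined by expected annual counts over the encounter
categories, a typical active-medication burden, and a demographic profile.
The default archetypes mirror the published training-set profiles of an
academic health system's empaneled adults — an inactive group plus seven
phenotypes ranging from minimally active (under one PCP visit a year) to
high outliers (over thirty a year).

Year-2 rates are coupled to year-1 realised counts through a persistence
parameter rho: ``rate2 = (1 - rho) * base_rate + rho * year1_count``, so
heavy users stay heavy and the next-year prediction task is non-trivial.

Truth labels (which archetype generated each patient) are carried for test
harnesses only; the pipeline never sees them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig, Window
from .features import CATEGORIES

PAYER_LEVELS = ["commercial", "medicare", "medicaid", "other"]

DEFAULT_SPECIALTY_MIX = {
    "cardiology": 0.25,
    "dermatology": 0.20,
    "gastroenterology": 0.20,
    "endocrinology": 0.15,
    "orthopedics": 0.20,
}


@dataclass
class ArchetypeSpec:
    """One planted utilization archetype.

    ``rates`` maps encounter category -> expected annual count.  Categories
    not listed default to zero.  ``payer_probs`` is (commercial,
    medicare, medicaid, other) and must sum to 1.
    """

    name: str
    rates: dict
    med_count_mean: float = 0.0
    year2_correlation: float = 0.6
    mixture_weight: float = 1.0
    age_mean: float = 52.0
    age_sd: float = 18.0
    male_fraction: float = 0.38
    payer_probs: tuple = (0.60, 0.23, 0.15, 0.02)
    #: Categories whose counts are Bernoulli(min(rate, 1)) rather than
    #: Poisson — for underdispersed profiles (mean 0.7, SD 0.5) that a
    #: Poisson law cannot produce.
    bernoulli_categories: tuple = ()

    def __post_init__(self) -> None:
        unknown = set(self.rates) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown encounter categories: {sorted(unknown)}")
        for cat, rate in self.rates.items():
            if rate < 0:
                raise ValueError(f"negative rate for {cat!r}: {rate}")
        if not 0.0 <= self.year2_correlation <= 1.0:
            raise ValueError("year2_correlation must be in [0, 1]")
        if self.mixture_weight < 0:
            raise ValueError("mixture_weight must be non-negative")

    def rate_vector(self) -> np.ndarray:
        return np.array([self.rates.get(c, 0.0) for c in CATEGORIES])


def _payer_split(medicare_medicaid: float, commercial: float, other: float) -> tuple:
    # The published tables pool Medicare with Medicaid; split 60/40 so the
    # four-level payer scheme has both levels populated.
    return (commercial, 0.6 * medicare_medicaid, 0.4 * medicare_medicaid, other)


def default_archetypes() -> list[ArchetypeSpec]:
    """Archetypes mirroring the published training-set phenotype profiles.

    Mixture weights are the published group sizes over the 24,324-patient
    training set; per-category rates, medication means, age and payer mixes
    follow the published per-phenotype tables.
    """
    # name, weight, rates per category, med mean, age mean/sd, male frac,
    # (commercial, medicare+medicaid, other)
    rows = [
        ("inactive", 3986, dict(no_show=0.1), 0.0, 41.9, 17.3, 0.389,
         (0.687, 0.268, 0.045)),
        ("A", 5343, dict(pcp_visit=0.7, no_show=0.2, urgent_care=0.1,
                         telephone=0.4, specialty_visit=1.0,
                         radiology_procedure=0.4, message_to_patient=0.7,
                         message_from_patient=0.9),
         2.3, 47.7, 14.7, 0.385, (0.799, 0.186, 0.020)),
        ("B", 6991, dict(pcp_visit=2.6, no_show=0.5, urgent_care=0.2,
                         telephone=1.7, ed_visit=0.2, specialty_visit=1.0,
                         radiology_procedure=0.6, message_to_patient=2.3,
                         message_from_patient=2.8),
         5.0, 53.7, 16.8, 0.383, (0.622, 0.364, 0.010)),
        ("C", 3000, dict(pcp_visit=2.1, no_show=0.6, urgent_care=0.2,
                         telephone=1.4, ed_visit=0.2, specialty_visit=5.5,
                         infusion=0.1, transfusion=0.1,
                         radiology_procedure=1.2, message_to_patient=4.0,
                         message_from_patient=5.0),
         5.5, 56.6, 16.4, 0.361, (0.577, 0.415, 0.010)),
        ("D", 2452, dict(pcp_visit=2.9, no_show=1.4, urgent_care=0.2,
                         telephone=2.3, ed_visit=0.3, emergent_hosp=0.1,
                         elective_hosp=0.1, specialty_visit=14.0,
                         infusion=0.7, transfusion=0.4,
                         radiology_procedure=2.2, message_to_patient=6.8,
                         message_from_patient=8.9),
         8.1, 59.9, 17.3, 0.376, (0.454, 0.540, 0.010)),
        ("E", 2082, dict(pcp_visit=7.0, no_show=1.8, urgent_care=0.2,
                         telephone=5.9, ed_visit=0.5, emergent_hosp=0.2,
                         specialty_visit=4.4, infusion=0.1,
                         radiology_procedure=1.5, message_to_patient=3.4,
                         message_from_patient=4.4),
         11.0, 65.1, 16.8, 0.344, (0.207, 0.782, 0.010)),
        ("F", 430, dict(pcp_visit=11.5, no_show=4.3, urgent_care=0.5,
                        telephone=19.4, ed_visit=1.6, emergent_hosp=0.9,
                        elective_hosp=0.1, specialty_visit=11.5,
                        infusion=0.1, transfusion=0.5,
                        radiology_procedure=2.7, message_to_patient=5.6,
                        message_from_patient=8.1),
         15.7, 67.4, 16.3, 0.367, (0.060, 0.930, 0.010)),
        ("G", 40, dict(pcp_visit=33.2, no_show=6.2, urgent_care=1.2,
                       telephone=18.5, ed_visit=1.8, emergent_hosp=0.9,
                       specialty_visit=7.6, transfusion=0.2,
                       radiology_procedure=2.5, message_to_patient=5.0,
                       message_from_patient=8.6),
         16.2, 60.5, 14.4, 0.200, (0.080, 0.920, 0.000)),
    ]
    total = sum(r[1] for r in rows)
    return [
        ArchetypeSpec(
            name=name,
            rates=rates,
            med_count_mean=med,
            mixture_weight=weight / total,
            age_mean=age_mean,
            age_sd=age_sd,
            male_fraction=male,
            payer_probs=_payer_split(mm, comm, other),
            # A's published PCP profile (mean 0.7, SD 0.5) is underdispersed
            bernoulli_categories=("pcp_visit",) if name == "A" else (),
        )
        for name, weight, rates, med, age_mean, age_sd, male, (comm, mm, other)
        in rows
    ]


@dataclass
class SyntheticPopulation:
    """Roster, two-year encounter stream, and planted truth labels."""

    patients: pd.DataFrame
    encounters: pd.DataFrame
    truth: pd.Series
    windows: tuple = ()
    seed: int | None = None

    def to_csv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.encounters.to_csv(outdir / "encounters.csv", index=False)
        self.patients.to_csv(outdir / "patients.csv", index=False)


def planted_labels(pop: SyntheticPopulation) -> pd.Series:
    """Ground-truth archetype per patient (test harness use only)."""
    return pop.truth


def generate_population(
    archetypes: list[ArchetypeSpec] | None = None,
    n_patients: int = 1000,
    seed: int = 0,
    config: PipelineConfig | None = None,
    dispersion: float | None = None,
    n_clinics: int = 4,
    n_providers: int = 24,
    provider_mix_strength: float = 0.8,
    specialty_mix: dict | None = None,
    missing_sex_rate: float = 1e-4,
    constant_meds_per_year: bool = False,
) -> SyntheticPopulation:
    """Generate a two-year synthetic encounter stream.

    Parameters
    ----------
    archetypes
        Mixture components; defaults to :func:`default_archetypes`.
    n_patients
        Roster size.
    seed
        Seeds every random draw; identical inputs give byte-identical output.
    dispersion
        If set, counts are negative-binomial via a gamma-Poisson mixture with
        this dispersion (variance = mean + dispersion * mean^2); default
        pure Poisson.
    provider_mix_strength
        Providers are given a complexity tilt so clinic case-mix varies
        (emulating e.g. a geriatric clinic); 0 gives uniform assignment.
    constant_meds_per_year
        Draw one medication count per patient-year instead of per visit.
    """
    if archetypes is None:
        archetypes = default_archetypes()
    if not archetypes:
        raise ValueError("archetype list is empty")
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    config = config or PipelineConfig()
    specialty_mix = specialty_mix or DEFAULT_SPECIALTY_MIX

    rng = np.random.default_rng(seed)
    n_arch = len(archetypes)
    weights = np.array([a.mixture_weight for a in archetypes], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("mixture weights must have positive sum")
    weights = weights / weights.sum()

    arch_idx = rng.choice(n_arch, size=n_patients, p=weights)
    rate_matrix = np.stack([a.rate_vector() for a in archetypes])  # arch x cat
    rho = np.array([a.year2_correlation for a in archetypes])[arch_idx]
    base = rate_matrix[arch_idx]  # n x cat

    bern_mask = np.zeros_like(base, dtype=bool)
    for j, cat in enumerate(CATEGORIES):
        in_cat = np.array(
            [cat in archetypes[i].bernoulli_categories for i in range(n_arch)]
        )
        bern_mask[:, j] = in_cat[arch_idx]

    counts1 = _draw_counts(rng, base, dispersion, bern_mask)
    lam2 = (1.0 - rho[:, None]) * base + rho[:, None] * counts1
    counts2 = _draw_counts(rng, lam2, dispersion, bern_mask)

    patients = _draw_demographics(
        rng, archetypes, arch_idx, n_patients, n_clinics, n_providers,
        provider_mix_strength, missing_sex_rate,
    )

    frames = []
    for counts, window in ((counts1, config.year1), (counts2, config.year2)):
        frames.append(
            _expand_encounters(
                rng, counts, window, patients["patient_id"].to_numpy(),
                arch_idx, archetypes, specialty_mix, constant_meds_per_year,
            )
        )
    encounters = pd.concat(frames, ignore_index=True)

    truth = pd.Series(
        [archetypes[i].name for i in arch_idx],
        index=pd.Index(patients["patient_id"], name="patient_id"),
        name="archetype",
    )
    return SyntheticPopulation(
        patients=patients,
        encounters=encounters,
        truth=truth,
        windows=(config.year1, config.year2),
        seed=seed,
    )


def _draw_counts(
    rng, lam: np.ndarray, dispersion: float | None,
    bernoulli_mask: np.ndarray | None = None,
) -> np.ndarray:
    if dispersion is None:
        counts = rng.poisson(lam)
    else:
        shape = 1.0 / dispersion
        mix = rng.gamma(shape, 1.0, size=lam.shape) / shape
        counts = rng.poisson(lam * mix)
    if bernoulli_mask is not None and bernoulli_mask.any():
        bern = (rng.random(lam.shape) < np.clip(lam, 0.0, 1.0)).astype(counts.dtype)
        counts = np.where(bernoulli_mask, bern, counts)
    return counts


def _draw_demographics(
    rng, archetypes, arch_idx, n, n_clinics, n_providers, tilt_strength,
    missing_sex_rate,
) -> pd.DataFrame:
    width = len(str(n))
    pids = np.array([f"pt{str(i).zfill(width)}" for i in range(n)])

    age_mean = np.array([a.age_mean for a in archetypes])[arch_idx]
    age_sd = np.array([a.age_sd for a in archetypes])[arch_idx]
    age = np.clip(rng.normal(age_mean, age_sd), 18, 115).round().astype(int)

    male_frac = np.array([a.male_fraction for a in archetypes])[arch_idx]
    sex = np.where(rng.random(n) < male_frac, "M", "F")
    sex = np.where(rng.random(n) < missing_sex_rate, "", sex)

    payer_probs = np.stack([a.payer_probs for a in archetypes])[arch_idx]
    payer_probs = payer_probs / payer_probs.sum(axis=1, keepdims=True)
    u = rng.random(n)
    payer_idx = (u[:, None] > payer_probs.cumsum(axis=1)).sum(axis=1)
    payer = np.array(PAYER_LEVELS)[payer_idx]

    # Providers get a complexity tilt so panels differ in case mix: the
    # heavier a patient's archetype, the more it favours high-tilt providers.
    tilt = np.linspace(-1.0, 1.0, n_providers) * tilt_strength
    pcp_rates = np.array([a.rates.get("pcp_visit", 0.0) for a in archetypes])
    z = (pcp_rates - pcp_rates.mean()) / (pcp_rates.std() or 1.0)
    logits = z[arch_idx][:, None] * tilt[None, :]
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(n)
    prov_idx = (u[:, None] > probs.cumsum(axis=1)).sum(axis=1)
    provider = np.array([f"prov{str(i).zfill(2)}" for i in range(n_providers)])[prov_idx]
    clinic = np.array([f"clinic{i % n_clinics + 1}" for i in range(n_providers)])[prov_idx]

    return pd.DataFrame(
        {
            "patient_id": pids,
            "age": age,
            "sex": sex,
            "payer": payer,
            "clinic": clinic,
            "provider": provider,
        }
    )


def _expand_encounters(
    rng, counts, window: Window, pids, arch_idx, archetypes, specialty_mix,
    constant_meds,
) -> pd.DataFrame:
    n, n_cat = counts.shape
    flat = counts.ravel()
    cell = np.repeat(np.arange(n * n_cat), flat)
    patient_row = cell // n_cat
    cat_code = cell % n_cat
    total = cell.size

    dates = pd.Timestamp(window.start) + pd.to_timedelta(
        rng.integers(0, window.days, size=total), unit="D"
    )
    categories = np.array(CATEGORIES)[cat_code]

    med_count = np.full(total, np.nan)
    pcp_mask = categories == "pcp_visit"
    if pcp_mask.any():
        med_means = np.array([a.med_count_mean for a in archetypes])
        if constant_meds:
            per_patient = rng.poisson(med_means[arch_idx])
            med_count[pcp_mask] = per_patient[patient_row[pcp_mask]]
        else:
            med_count[pcp_mask] = rng.poisson(
                med_means[arch_idx][patient_row[pcp_mask]]
            )

    specialty = np.full(total, "", dtype=object)
    spec_mask = categories == "specialty_visit"
    if spec_mask.any():
        names = list(specialty_mix)
        probs = np.array([specialty_mix[s] for s in names], dtype=float)
        probs /= probs.sum()
        specialty[spec_mask] = rng.choice(names, size=spec_mask.sum(), p=probs)

    msg_direction = np.full(total, "", dtype=object)
    msg_direction[categories == "message_to_patient"] = "to_patient"
    msg_direction[categories == "message_from_patient"] = "from_patient"

    return pd.DataFrame(
        {
            "patient_id": pids[patient_row],
            "category": categories,
            "date": pd.DatetimeIndex(dates).strftime("%Y-%m-%d"),
            "specialty": specialty,
            "med_count": med_count,
            "msg_direction": msg_direction,
        }
    )
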