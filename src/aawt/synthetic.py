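"""Synthetic multi-study cohorts with the model's exact generative structure.

Emulates the study designs found in the thickness literature: several
cohorts measured at different contact pressures (0-25 kPa), a subset of
patients contributing more than one sample (which is what separates
inter- from intra-patient variability), and some studies available only as
mean +/- SD of non-contact (zero-pressure) measurements.  The generator
implements the hierarchical model exactly -- mu_i ~ N(mu_pop, sigma_pop),
T_ij ~ LN(mu_i, sigma_pat), t_ij = lambda_r(c, k, p) T_ij -- so every stage
of the pipeline can be tested against known truth without any real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constitutive import HGOParams, invert_pressure
from .hierarchical import PopulationParams, ThicknessSample
from .summary_likelihood import SummaryStatStudy

__all__ = ["StudyDesign", "CohortDesign", "generate_cohort", "six_study_design"]


@dataclass(frozen=True)
class StudyDesign:
    """Design of one study: measurement pressure, cohort size and whether the
    study publishes raw samples or only summary statistics."""

    label: str
    pressure_kpa: float
    n_patients: int
    n_samples: int
    summary_only: bool = False

    def __post_init__(self) -> None:
        if self.pressure_kpa < 0:
            raise ValueError("pressure must be non-negative")
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        if self.n_samples < self.n_patients:
            raise ValueError("need at least one sample per patient")
        if self.summary_only and self.pressure_kpa != 0:
            raise ValueError(
                "summary-only studies are non-contact (pressure 0) by design"
            )


@dataclass(frozen=True)
class CohortDesign:
    """A multi-study design plus the generating ground truth."""

    studies: tuple[StudyDesign, ...]
    material: HGOParams
    population: PopulationParams
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.studies:
            raise ValueError("design needs at least one study")
        labels = [s.label for s in self.studies]
        if len(set(labels)) != len(labels):
            raise ValueError("study labels must be unique")


def _allocate_samples(
    n_patients: int, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample counts per patient: everyone gets one, the surplus is spread
    geometrically so most patients stay singletons (as in real cohorts,
    where roughly 40% of patients contribute a second sample)."""
    counts = np.ones(n_patients, dtype=int)
    extra = n_samples - n_patients
    while extra > 0:
        i = int(rng.integers(n_patients))
        counts[i] += 1
        extra -= 1
    return counts


def generate_cohort(
    design: CohortDesign,
) -> tuple[list[ThicknessSample], list[SummaryStatStudy], dict]:
    """Draw a full synthetic cohort from the generative model.

    Returns raw samples (deformed thicknesses at each study's pressure),
    summary statistics (undeformed, for summary-only studies; raw values are
    discarded), and a truth record holding every generating parameter and
    the latent undeformed thicknesses.
    """
    rng = np.random.default_rng(design.seed)
    pop = design.population
    mat = design.material
    lam_cache: dict[float, float] = {0.0: 1.0}

    samples: list[ThicknessSample] = []
    summaries: list[SummaryStatStudy] = []
    truth: dict = {
        "mu_pop": pop.mu_pop,
        "sigma_pop": pop.sigma_pop,
        "sigma_pat": pop.sigma_pat,
        "c": mat.c,
        "k": mat.k,
        "k2": mat.k2,
        "phi": mat.phi,
        "seed": design.seed,
        "lambda_r": {},
        "latent_T": {},
    }

    for st in design.studies:
        p = st.pressure_kpa
        if p not in lam_cache:
            lam_cache[p] = invert_pressure(mat, p)
        lam = lam_cache[p]
        truth["lambda_r"][st.label] = lam
        counts = _allocate_samples(st.n_patients, st.n_samples, rng)
        mu_i = pop.mu_pop + pop.sigma_pop * rng.standard_normal(st.n_patients)
        study_T = []
        for ip, (m_i, n_i) in enumerate(zip(mu_i, counts)):
            T = np.exp(m_i + pop.sigma_pat * rng.standard_normal(n_i))
            study_T.extend(T.tolist())
            if not st.summary_only:
                for js, Tij in enumerate(T):
                    samples.append(
                        ThicknessSample(
                            study_id=st.label,
                            patient_id=f"{st.label}-P{ip:04d}",
                            sample_id=f"{st.label}-P{ip:04d}-S{js}",
                            t=float(lam * Tij),
                            p=p,
                        )
                    )
        truth["latent_T"][st.label] = study_T
        if st.summary_only:
            arr = np.array(study_T)
            summaries.append(
                SummaryStatStudy(
                    M=float(arr.mean()),
                    S=float(arr.std(ddof=1)),
                    N=int(arr.size),
                    label=st.label,
                )
            )
    return samples, summaries, truth


def six_study_design(
    mu_pop: float = 0.85,
    sigma_pop: float = 0.26,
    sigma_pat: float = 0.18,
    c: float = 5.0,
    k: float = 20.0,
    seed: int = 0,
) -> CohortDesign:
    """The canonical six-study benchmark design.

    Mirrors the designs of the published thickness cohorts: four raw
    studies at contact pressures 0, 25, 16 and 1 kPa with 39, 251, 90 and
    92 samples, and two non-contact studies reduced to summary statistics
    (N = 34 and N = 90).  Defaults put the population truth at the
    literature-scale values (mu_pop = 0.85, sigma_pop = 0.26,
    sigma_pat = 0.18) with mid-range material stiffness.
    """
    studies = (
        StudyDesign("laser-A", 0.0, 25, 39),
        StudyDesign("summary-A", 0.0, 34, 34, summary_only=True),
        StudyDesign("micrometer-B", 25.0, 113, 251),
        StudyDesign("summary-B", 0.0, 90, 90, summary_only=True),
        StudyDesign("gauge-uniaxial", 16.0, 45, 90),
        StudyDesign("gauge-biaxial", 1.0, 75, 92),
    )
    return CohortDesign(
        studies=studies,
        material=HGOParams(c=c, k=k),
        population=PopulationParams(mu_pop, sigma_pop, sigma_pat),
        seed=seed,
    )
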