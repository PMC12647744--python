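"""Synthetic inputs with the statistical structure the analyses assume.

Patient-level trial data and the single-cell matrices are not publicly
redistributable, so every analysis stage is exercised on generated data
with known ground truth:

* Bernoulli response/toxicity outcome streams under configurable true
  rates, for the sequential monitor and the OC simulator;
* lesion timelines with known responder / hyperprogressor / stable
  labels, matching the input schema of the RECIST classifier;
* right-censored exponential event times for the survival endpoints;
* count-like expression where tumor-cell profiles are convex mixtures
  of a tumor archetype and a myeloid archetype with a
  condition-dependent mixing weight alpha — the "myeloid mimicry"
  structure the similarity panel is designed to detect.

All generators are bit-reproducible given their seed.  The realized
trial's printed aggregates (10 treated, 0 confirmed responses, 1 TOX,
infusion counts) are packaged as a fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData

from .monitor import PatientOutcome, TrialState
from .recist import LESION_COLUMNS

__all__ = [
    "TrialSimConfig",
    "LesionSimConfig",
    "SurvivalSimConfig",
    "ExpressionSimConfig",
    "generate_trial_outcomes",
    "generate_lesion_cohort",
    "generate_survival",
    "generate_expression",
    "fixture_trial_aggregates",
]

#: organ vocabulary for metastatic sites
ORGANS = ("lung", "liver", "bone", "node", "kidney")


@dataclass(frozen=True)
class TrialSimConfig:
    true_orr: float
    true_tox: float
    n_max: int = 30
    cohort_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.true_orr <= 1 and 0 <= self.true_tox <= 1):
            raise ValueError("rates must lie in [0, 1]")


def generate_trial_outcomes(config: TrialSimConfig) -> list[PatientOutcome]:
    """Independent Bernoulli response and TOX draws per patient."""
    rng = np.random.default_rng(config.seed)
    resp = rng.random(config.n_max) < config.true_orr
    tox = rng.random(config.n_max) < config.true_tox
    return [PatientOutcome(bool(r), bool(t)) for r, t in zip(resp, tox)]


@dataclass(frozen=True)
class LesionSimConfig:
    """Cohort of lesion timelines with known phenotype labels.

    Phenotypes: ``responder`` (SLD shrinks >= 30% by week 12, confirmed),
    ``hyperprogressor`` (PD within 8 weeks with the burden increases the
    definition requires) and ``stable`` (SLD stays within +/- 19% of
    baseline).  Hyperprogressors alternate between the >= 40% growth
    phenotype and the >= 20% growth-plus-new-lesions-in-two-organs
    phenotype.  ``noise_sd`` adds lognormal measurement wiggle; the
    default 0 keeps trajectories exactly on their phenotype so generator
    labels are an exact oracle for the classifier.
    """

    n_patients: int = 10
    fraction_responders: float = 0.0
    fraction_hyperprogressors: float = 0.5
    baseline_sld_range: tuple[float, float] = (40.0, 120.0)
    assessment_weeks: tuple[float, ...] = (0.0, 6.0, 12.0)
    lesions_per_patient: int = 2
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fraction_responders + self.fraction_hyperprogressors > 1:
            raise ValueError("phenotype fractions must sum to <= 1")
        if self.assessment_weeks[0] != 0:
            raise ValueError("first assessment week must be 0 (baseline)")


def generate_lesion_cohort(
    config: LesionSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lesion measurement table plus a ground-truth label table.

    Returns ``(lesions, labels)`` where ``lesions`` satisfies the RECIST
    input schema exactly and ``labels`` has columns ``patient_id,
    phenotype``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    n_resp = round(n * config.fraction_responders)
    n_hyper = round(n * config.fraction_hyperprogressors)
    phenotypes = (
        ["responder"] * n_resp
        + ["hyperprogressor"] * n_hyper
        + ["stable"] * (n - n_resp - n_hyper)
    )

    rows: list[dict] = []
    labels: list[dict] = []
    lo, hi = config.baseline_sld_range
    for i, phen in enumerate(phenotypes):
        pid = f"SYN{i + 1:03d}"
        labels.append({"patient_id": pid, "phenotype": phen})
        baseline = rng.uniform(lo, hi)
        # split baseline SLD across target lesions
        weights = rng.dirichlet(np.full(config.lesions_per_patient, 5.0))
        organs = rng.choice(ORGANS, size=config.lesions_per_patient, replace=True)

        hyper_via_new_lesions = phen == "hyperprogressor" and i % 2 == 1
        for week in config.assessment_weeks:
            factor = _sld_factor(phen, week, hyper_via_new_lesions)
            for j in range(config.lesions_per_patient):
                diam = baseline * weights[j] * factor
                if config.noise_sd > 0 and week > 0:
                    diam *= rng.lognormal(0.0, config.noise_sd)
                rows.append(
                    {
                        "patient_id": pid,
                        "week": week,
                        "lesion_id": f"{pid}-T{j + 1}",
                        "organ": organs[j],
                        "longest_diameter_mm": round(diam, 2),
                        "is_target": True,
                        "is_new": False,
                    }
                )
            if hyper_via_new_lesions and 0 < week <= 8:
                # new non-target lesions in two distinct organs
                new_organs = [o for o in ORGANS if o not in set(organs)][:2]
                for k, organ in enumerate(new_organs):
                    rows.append(
                        {
                            "patient_id": pid,
                            "week": week,
                            "lesion_id": f"{pid}-N{k + 1}",
                            "organ": organ,
                            "longest_diameter_mm": 15.0,
                            "is_target": False,
                            "is_new": True,
                        }
                    )

    lesions = pd.DataFrame(rows, columns=LESION_COLUMNS)
    return lesions, pd.DataFrame(labels)


def _sld_factor(phenotype: str, week: float, via_new_lesions: bool) -> float:
    """Multiplicative SLD trajectory relative to baseline."""
    if week == 0:
        return 1.0
    if phenotype == "responder":
        # PR depth reached at the first follow-up and confirmed later
        return 0.65 if week <= 6 else 0.60
    if phenotype == "hyperprogressor":
        if via_new_lesions:
            return 1.25 if week <= 8 else 1.40  # criterion ii: +25% early
        return 1.50 if week <= 8 else 1.80  # criterion i: +50% early
    return 1.10  # stable: within +/- 19%


@dataclass(frozen=True)
class SurvivalSimConfig:
    n_patients: int = 100
    event_rate: float = 0.5  # exponential hazard per month
    censor_rate: float = 0.0  # 0 disables censoring
    seed: int = 0

    def __post_init__(self) -> None:
        if self.event_rate <= 0:
            raise ValueError("event_rate must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be non-negative")


def generate_survival(config: SurvivalSimConfig) -> pd.DataFrame:
    """Exponential event times with independent exponential censoring.

    Returns columns ``patient_id, time_months, event``.
    """
    rng = np.random.default_rng(config.seed)
    t_event = rng.exponential(1.0 / config.event_rate, config.n_patients)
    if config.censor_rate > 0:
        t_cens = rng.exponential(1.0 / config.censor_rate, config.n_patients)
    else:
        t_cens = np.full(config.n_patients, np.inf)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    return pd.DataFrame(
        {
            "patient_id": [f"SYN{i + 1:03d}" for i in range(config.n_patients)],
            "time_months": time,
            "event": event,
        }
    )


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Two-archetype expression model with condition-dependent mixing.

    Tumor cells express ``(1 - alpha) * T + alpha * M`` where T and M
    are tumor and myeloid archetype programs and alpha is the myeloid
    mixing weight of the condition; myeloid cells express M.  A
    designated subset of genes carries an elevated between-archetype
    difference (the truth HVG set).  Counts are gamma-Poisson
    (negative-binomial-like) at the stated dispersion, then
    library-size normalized; ``dispersion <= 0`` produces noiseless
    expected profiles.
    """

    n_genes: int = 2000
    n_hvg_truth: int = 100
    n_tumor_cells: int = 200
    n_myeloid_cells: int = 200
    mixing_alpha_baseline: float = 0.1
    mixing_alpha_post: float = 0.4
    dispersion: float = 0.1
    marker_log_fold_mean: float = 2.2
    marker_log_fold_sd: float = 0.3
    library_size: int = 2000
    target_sum: float = 1e4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.mixing_alpha_baseline <= 1
                and 0 <= self.mixing_alpha_post <= 1):
            raise ValueError("mixing weights must lie in [0, 1]")
        if min(self.n_genes, self.n_tumor_cells, self.n_myeloid_cells) < 1:
            raise ValueError("counts must be >= 1")
        if self.n_hvg_truth > self.n_genes:
            raise ValueError("n_hvg_truth cannot exceed n_genes")


def generate_expression(
    config: ExpressionSimConfig,
) -> tuple[AnnData, dict]:
    """Cells x genes AnnData plus ground truth.

    The AnnData carries library-size-normalized expression with obs
    columns ``compartment`` (tumor/myeloid) and ``condition``
    (baseline/postNI).  Truth dict keys: ``hvg_genes`` (the designated
    variable set), ``alphas`` per condition, ``archetypes``.
    """
    rng = np.random.default_rng(config.seed)
    g = config.n_genes

    # log-normal base program shared by both archetypes
    base = rng.lognormal(mean=0.0, sigma=1.0, size=g)
    tumor_arch = base.copy()
    myeloid_arch = base.copy()
    # designated marker genes are drawn from the expressed (upper) half of
    # baseline abundance — lineage markers are not rare transcripts
    eligible = np.where(base >= np.median(base))[0]
    if config.n_hvg_truth > eligible.size:
        eligible = np.arange(g)
    hvg_idx = rng.choice(eligible, size=config.n_hvg_truth, replace=False)
    # elevated between-archetype difference on the designated genes:
    # opposite fold changes in the two programs
    effect = rng.lognormal(
        mean=config.marker_log_fold_mean,
        sigma=config.marker_log_fold_sd,
        size=config.n_hvg_truth,
    )
    half = config.n_hvg_truth // 2
    tumor_arch[hvg_idx[:half]] *= effect[:half]
    myeloid_arch[hvg_idx[half:]] *= effect[half:]

    tumor_arch /= tumor_arch.sum()
    myeloid_arch /= myeloid_arch.sum()

    alphas = {
        "baseline": config.mixing_alpha_baseline,
        "postNI": config.mixing_alpha_post,
    }
    blocks, compartments, conditions = [], [], []
    for cond, alpha in alphas.items():
        tumor_mean = (1 - alpha) * tumor_arch + alpha * myeloid_arch
        for comp, mean_profile, n_cells in (
            ("tumor", tumor_mean, config.n_tumor_cells),
            ("myeloid", myeloid_arch, config.n_myeloid_cells),
        ):
            mu = mean_profile * config.library_size
            counts = _gamma_poisson(rng, mu, config.dispersion,
                                    n_cells=n_cells)
            blocks.append(counts)
            compartments += [comp] * n_cells
            conditions += [cond] * n_cells

    counts = np.vstack(blocks)
    # library-size normalization to a common target sum
    libs = counts.sum(axis=1, keepdims=True)
    libs[libs == 0] = 1.0
    norm = counts / libs * config.target_sum

    obs = pd.DataFrame(
        {"compartment": compartments, "condition": conditions},
        index=[f"cell{i + 1:05d}" for i in range(norm.shape[0])],
    )
    var = pd.DataFrame(index=[f"gene{i + 1:05d}" for i in range(g)])
    adata = AnnData(X=norm, obs=obs, var=var)
    truth = {
        "hvg_genes": [var.index[i] for i in sorted(hvg_idx)],
        "alphas": alphas,
        "archetypes": {"tumor": tumor_arch, "myeloid": myeloid_arch},
    }
    return adata, truth


def _gamma_poisson(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float, n_cells: int
) -> np.ndarray:
    """Gamma-Poisson counts with Var = mu + dispersion * mu^2.

    ``dispersion <= 0`` returns the expected profile itself (noiseless
    limit).
    """
    if dispersion <= 0:
        return np.tile(mu, (n_cells, 1))
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.tile(mu, (n_cells, 1)) / shape)
    return rng.poisson(lam).astype(float)


def fixture_trial_aggregates() -> tuple[TrialState, list[int]]:
    """The realized trial's printed aggregates.

    10 treated and evaluable patients, 0 confirmed responses (the single
    PR was unconfirmed and counts as a non-responder for monitoring),
    1 extreme-toxicity event; the per-patient infusion counts have
    median 2 (range 1-6), with 7 of 10 patients receiving 2 infusions
    and one each receiving 1, 4 and 6.
    """
    state = TrialState(n_treated=10, r_responses=0, q_nonresponders=10, t_tox=1)
    infusions = [1, 2, 2, 2, 2, 2, 2, 2, 4, 6]
    return state, infusions
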