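"""Study-scale simulation experiments.

Each function reproduces one quantitative claim of the analysis under
the study conditions the pipeline emulates, end to end: generate the
synthetic inputs, run the estimator, measure the result. They are used
by the acceptance tests and the reproduction script; problem sizes are
parameters so tests can run scaled-down versions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .clinical import fit_cox, fit_cox_ag
from .discovery import EnhancedSequenceDiscovery
from .hla import HLACarrierClassifier
from .io import SampleMeta
from .simulate import (
    ALLELE_A,
    ClinicalConfig,
    CohortSpec,
    GeneratorConfig,
    build_pool,
    gen_repertoire,
    simulate_cohorts,
    simulate_trial,
)

logger = logging.getLogger(__name__)

__all__ = [
    "hla_imputation_auroc",
    "ag_interaction_recovery",
    "first_event_interaction_recovery",
    "discovery_recovery",
    "COMBIRX_RECURRENT_GROUPS",
    "NATIONMS_FIRST_EVENT_GROUPS",
]

#: arm-by-class-I-carrier allocation of the three-arm trial relapse
#: analysis (IFN, GA, IFN+GA; second number = carriers)
COMBIRX_RECURRENT_GROUPS = [("IFN", 168, 56), ("GA", 172, 60), ("GA+IFN", 353, 95)]

#: two-group one-year first-relapse cohort (IFN, GA; second number = carriers)
NATIONMS_FIRST_EVENT_GROUPS = [("IFN", 239, 74), ("GA", 96, 32)]

_AG_COVARIATES = [
    "age", "sex_m", "disease_duration", "ga", "gaifn", "a03", "dr15",
    "ga_x_a03", "gaifn_x_a03", "ga_x_dr15", "gaifn_x_dr15",
]
_FE_COVARIATES = [
    "age", "sex_m", "disease_duration", "ga", "a03", "dr15", "ga_x_a03", "ga_x_dr15",
]


def hla_imputation_auroc(
    seed: int,
    n_seeds: int = 10,
    n_subjects: int = 600,
    n_train: int = 480,
    pool_size: int = 60_000,
    mean_unique: int = 3000,
    carrier_frac: float = 0.4,
    n_feature_keys: int = 100,
    feature_carrier_presence: float = 0.30,
    feature_background_presence: float = 0.015,
) -> float:
    """Mean holdout AUROC of the two-covariate HLA imputation model.

    Per replicate: simulate labelled repertoires drawing ~``mean_unique``
    clonotypes per sample from a shared pool, with ``n_feature_keys``
    allele-marker clonotypes elevated in carriers; train with
    stratified 5-fold CV on ``n_train`` subjects; score AUROC on the
    held-out remainder.
    """
    cfg = GeneratorConfig(
        cohorts=(CohortSpec("holdout", 0, n_subjects, 0.0, 0.0, 0.0),),
        mean_unique=mean_unique,
        pool_size=pool_size,
        background_presence=(mean_unique - 0.5 * (feature_carrier_presence
                             + feature_background_presence) * n_feature_keys) / pool_size,
        n_planted_a=0, n_planted_b=0, n_planted_other=0,
        n_feature_keys=n_feature_keys,
        feature_carrier_presence=feature_carrier_presence,
        feature_background_presence=feature_background_presence,
    )
    aucs = []
    for child in np.random.SeedSequence(seed).spawn(n_seeds):
        rng = np.random.default_rng(child)
        pool = build_pool(cfg, rng)
        reps, labels = [], []
        for i in range(n_subjects):
            carrier = bool(rng.random() < carrier_frac)
            meta = SampleMeta(
                sample_id=f"s{i:04d}", subject_id=f"p{i:04d}", cohort_id="sim",
                ga_exposed=False,
                hla_genotype=frozenset({ALLELE_A}) if carrier else frozenset(),
            )
            reps.append(gen_repertoire(meta, pool, cfg, rng))
            labels.append(carrier)
        y = np.array(labels)
        clf = HLACarrierClassifier(allele=ALLELE_A, random_state=0).fit(
            reps[:n_train], y[:n_train]
        )
        proba = clf.predict_proba(reps[n_train:])[:, 1]
        auc = roc_auc_score(y[n_train:], proba)
        logger.info("imputation replicate: holdout AUROC %.4f", auc)
        aucs.append(auc)
        del reps
    return float(np.mean(aucs))


@dataclass
class InteractionRecovery:
    geometric_mean_hr: float
    n_replicates: int
    n_separated: int  # replicates with a monotone likelihood, excluded


def _geo_mean_interaction(
    seed: int,
    n_reps: int,
    groups,
    clinical: ClinicalConfig,
    term: str,
    covariates,
    recurrent: bool,
) -> InteractionRecovery:
    logs = []
    n_sep = 0
    for child in np.random.SeedSequence(seed).spawn(n_reps):
        rng = np.random.default_rng(child)
        data = simulate_trial(groups, clinical, rng)
        if recurrent:
            df = data["recurrent"].merge(data["subjects"], on="subject_id")
            fit = fit_cox_ag(
                df, "start", "stop", "event", covariates,
                cluster_col="subject_id", scale_columns=("age", "disease_duration"),
            )
        else:
            df = data["first_event"].merge(data["subjects"], on="subject_id")
            fit = fit_cox(
                df, "time", "event", covariates, scale_columns=("age", "disease_duration")
            )
        if term in fit.separated_terms:
            n_sep += 1
            continue
        logs.append(np.log(fit.hr(term)))
    return InteractionRecovery(
        geometric_mean_hr=float(np.exp(np.mean(logs))),
        n_replicates=len(logs),
        n_separated=n_sep,
    )


def ag_interaction_recovery(seed: int, n_reps: int = 50) -> InteractionRecovery:
    """Recover the combination-arm treatment-by-HLA interaction HR with
    the Andersen-Gill recurrent-event model at three-arm-trial scale.

    Relapses over 3 years at baseline intensity 0.3 events/year; the
    interaction HRs are planted at 0.67 (IFN+GA arm) and 0.66 (GA arm);
    the IFN+GA x carrier estimate is summarized as a geometric mean.
    """
    clinical = ClinicalConfig(
        followup_years=3.0, baseline_hazard=0.3, hr_ga_x_a03=0.66, hr_gaifn_x_a03=0.67
    )
    return _geo_mean_interaction(
        seed, n_reps, COMBIRX_RECURRENT_GROUPS, clinical, "gaifn_x_a03",
        _AG_COVARIATES, recurrent=True,
    )


def first_event_interaction_recovery(seed: int, n_reps: int = 50) -> InteractionRecovery:
    """Recover the planted GA-by-carrier interaction HR 0.37 with a
    time-to-first-relapse Cox fit at two-group one-year scale.

    First-relapse intensity 0.7 events/year before covariate effects,
    chosen so the fitted interaction's standard error (~0.4 on the log
    scale) matches the precision of a 335-subject one-year design;
    administrative censoring at one year. Replicates whose partial
    likelihood is monotone in the interaction (no events in a cell) are
    excluded and counted.
    """
    clinical = ClinicalConfig(
        baseline_hazard=0.7, censor_years=1.0, hr_ga_x_a03=0.37, hr_gaifn_x_a03=1.0
    )
    return _geo_mean_interaction(
        seed, n_reps, NATIONMS_FIRST_EVENT_GROUPS, clinical, "ga_x_a03",
        _FE_COVARIATES, recurrent=False,
    )


@dataclass
class DiscoveryRecovery:
    sensitivity: float  # planted clonotypes recovered / planted
    false_discovery_rate: float  # unplanted / discovered clonotypes
    n_discovered: int


def discovery_recovery(
    seed: int,
    n_seeds: int = 5,
    mean_unique: int = 300,
    pool_size: int = 2000,
    hla_restricted: bool = False,
) -> DiscoveryRecovery:
    """Sensitivity/FDR of replicated ES discovery on planted truth.

    Three case/control cohorts at the discovery splits (58/211, 75/234,
    71/978); 105 planted clonotypes present at 0.30 in exposed cases vs
    0.02 background, the contrast the per-clonotype Fisher test sees.
    With ``hla_restricted=True`` the planted set instead follows the
    pipeline's default carrier-conditioned design (65/35/5 keys raised
    to 0.30 only in exposed carriers of their allele), which dilutes
    the per-case contrast by the carrier frequency. Pooled over
    ``n_seeds`` generations.
    """
    n_found = n_planted = n_disc = n_false = 0
    planted_kw = {} if hla_restricted else {
        "n_planted_a": 0, "n_planted_b": 0, "n_planted_other": 105,
    }
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_seeds)):
        cfg = GeneratorConfig(
            mean_unique=mean_unique,
            pool_size=pool_size,
            seed=int(child.generate_state(1)[0] % (2**31)),
            **planted_kw,
        )
        cohorts, pool = simulate_cohorts(cfg)
        reps, y, cohort = [], [], []
        for name, (rr, mm) in cohorts.items():
            reps.extend(rr)
            y.extend(m.ga_exposed for m in mm)
            cohort.extend([name] * len(rr))
        disc = EnhancedSequenceDiscovery(min_presence=3).fit(
            reps, np.array(y), cohort=np.array(cohort)
        )
        planted = set(pool.planted_ga)
        found = {es.target for es in disc.keys_}
        n_found += len(found & planted)
        n_planted += len(planted)
        n_disc += len(found)
        n_false += len(found - planted)
        logger.info(
            "discovery replicate %d: %d/%d planted, %d false",
            i, len(found & planted), len(planted), len(found - planted),
        )
        del reps, cohorts
    return DiscoveryRecovery(
        sensitivity=n_found / n_planted,
        false_discovery_rate=n_false / n_disc if n_disc else 0.0,
        n_discovered=n_disc,
    )
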