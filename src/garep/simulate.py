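"""Synthetic multi-cohort TRB repertoire, genotype, and outcome generator.

Emulates the statistical structure the analysis pipeline assumes, so
every downstream stage can be exercised and power-tested without access
to patient-level data:

* carrier-level HLA genotypes for two linked alleles drawn from a 2x2
  carrier distribution with a configurable carrier-level normalized D';
* per-sample repertoires with negative-binomial unique-rearrangement
  counts and discrete power-law (Zipf) clone sizes, drawing public
  clonotypes from a shared pool; planted treatment-associated
  clonotypes appear at an elevated probability only in exposed carriers
  of their restricting allele (with a multiplicative synergy when the
  second allele is co-carried), and planted allele-marker clonotypes
  appear at carrier-elevated probability regardless of exposure;
* longitudinal baseline/treated repertoire pairs in which a configured
  number of new nucleotide rearrangements enters the treated sample's
  top-100 by template count;
* clinical outcomes: recurrent relapse times from a multiplicative-
  intensity Poisson process with treatment-by-HLA interaction hazard
  ratios, first-event times with administrative censoring, and
  continuous outcomes from linear models with Gaussian noise.

All generation is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Repertoire, SampleMeta, SequenceKey

__all__ = [
    "ALLELE_A",
    "ALLELE_B",
    "CohortSpec",
    "ClinicalConfig",
    "GeneratorConfig",
    "KeyPool",
    "assign_genotypes",
    "build_pool",
    "gen_repertoire",
    "gen_longitudinal_pair",
    "simulate_cohorts",
    "simulate_trial",
    "gen_clinical",
]

ALLELE_A = "A*03:01"
ALLELE_B = "DRB1*15:01"

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"), dtype="U1")
_NT = np.array(list("ACGT"), dtype="U1")

_V_GENES = [
    "TRBV02", "TRBV04-01", "TRBV05-01", "TRBV05-04", "TRBV05-06", "TRBV06-01",
    "TRBV06-05", "TRBV07-02", "TRBV07-09", "TRBV09", "TRBV10-03", "TRBV11-02",
    "TRBV12-03", "TRBV14", "TRBV15", "TRBV18", "TRBV19", "TRBV20-01",
    "TRBV24-01", "TRBV25-01", "TRBV27", "TRBV28", "TRBV29-01", "TRBV30",
]
_J_GENES = [
    "TRBJ01-01", "TRBJ01-02", "TRBJ01-05", "TRBJ02-01", "TRBJ02-02",
    "TRBJ02-03", "TRBJ02-05", "TRBJ02-07",
]


@dataclass(frozen=True)
class CohortSpec:
    """One case/control discovery cohort with its carrier structure.

    Default cohort sizes and carrier frequencies emulate the three
    discovery cohorts (combined NationMS/Muenster, ACP, FinBB) at their
    published case/control splits and per-cohort carrier tables.
    """

    name: str
    n_cases: int
    n_controls: int
    freq_a: float = 0.31  # carrier frequency of the class I allele
    freq_b: float = 0.48  # carrier frequency of the class II allele
    dprime: float = 0.31  # carrier-level normalized D'

    @property
    def n(self) -> int:
        return self.n_cases + self.n_controls


def _default_cohorts() -> list[CohortSpec]:
    return [
        CohortSpec("NationMS-Muenster", 58, 211, 125 / 405, 193 / 405, 0.31),
        CohortSpec("ACP", 75, 234, 101 / 309, 136 / 309, 0.27),
        CohortSpec("FinBB", 71, 978, 515 / 1049, 489 / 1049, 0.10),
    ]


@dataclass(frozen=True)
class ClinicalConfig:
    """Parameters of the outcome-generating models.

    Hazard ratios multiply a constant baseline relapse intensity
    (events/year); the default interaction values are the planted
    truths recovered by the model-fitting layer. Continuous outcomes
    follow a linear model with Gaussian noise.
    """

    followup_years: float = 3.0
    baseline_hazard: float = 0.3  # relapse events / year
    censor_years: float = 1.0  # administrative censoring for first-event data
    hr_ga: float = 1.0  # GA-arm main effect
    hr_gaifn: float = 1.0  # GA+IFN-arm main effect
    hr_a03: float = 1.0
    hr_dr15: float = 1.0
    hr_ga_x_a03: float = 0.66
    hr_gaifn_x_a03: float = 0.67
    hr_ga_x_dr15: float = 1.0
    hr_gaifn_x_dr15: float = 1.0
    frailty_sd: float = 0.0  # lognormal subject frailty (within-subject correlation)
    beta_edss_ga_x_a03: float = -0.34  # linear-model interaction on delta-EDSS/year
    edss_noise_sd: float = 1.0
    msss_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.followup_years <= 0 or self.censor_years <= 0:
            raise ValueError("follow-up and censoring horizons must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full configuration of the synthetic study.

    Occurrence probabilities follow the planted-effect design: every
    public-pool clonotype appears with ``background_presence``; planted
    treatment-associated clonotypes rise to ``exposed_carrier_presence``
    in exposed carriers of their allele (times ``synergy`` when the
    other allele is co-carried, for the class I set); allele-marker
    clonotypes used by HLA imputation rise from
    ``feature_background_presence`` to ``feature_carrier_presence`` in
    carriers regardless of exposure.
    """

    cohorts: tuple[CohortSpec, ...] = field(default_factory=lambda: tuple(_default_cohorts()))
    mean_unique: int = 3000  # mean unique productive rearrangements per sample
    size_dispersion: float = 10.0  # negative-binomial dispersion (larger = tighter)
    clone_exponent: float = 2.0  # discrete power-law exponent for clone sizes
    pool_size: int = 5000  # background public pool
    n_planted_a: int = 65
    n_planted_b: int = 35
    n_planted_other: int = 5
    background_presence: float = 0.02
    exposed_carrier_presence: float = 0.30
    synergy: float = 1.5
    n_feature_keys: int = 100  # allele-marker clonotypes per allele
    feature_carrier_presence: float = 0.30
    feature_background_presence: float = 0.015
    nonproductive_fraction: float = 0.10
    n_expansions: int = 12  # planted new top-100 rearrangements per treated sample
    top_k: int = 100
    clinical: ClinicalConfig = field(default_factory=ClinicalConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.background_presence,
            self.exposed_carrier_presence,
            self.feature_carrier_presence,
            self.feature_background_presence,
        ):
            if not 0 <= p <= 1:
                raise ValueError("occurrence probabilities must be in [0, 1]")
        for c in self.cohorts:
            _carrier_cells(c.freq_a, c.freq_b, c.dprime)  # feasibility
        if min(self.n_planted_a, self.n_planted_b, self.n_planted_other) < 0:
            raise ValueError("planted key counts must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# genotypes


def _carrier_cells(freq_a: float, freq_b: float, dprime: float) -> np.ndarray:
    """Joint carrier-cell probabilities (AB, Ab, aB, ab) implied by
    marginal carrier frequencies and a nonnegative carrier-level D'."""
    if not (0 <= freq_a <= 1 and 0 <= freq_b <= 1 and 0 <= dprime <= 1):
        raise ValueError("freq_a, freq_b, dprime must be in [0, 1]")
    dmax = min(freq_a * (1 - freq_b), (1 - freq_a) * freq_b)
    p_ab = freq_a * freq_b + dprime * dmax
    cells = np.array(
        [p_ab, freq_a - p_ab, freq_b - p_ab, 1 - freq_a - freq_b + p_ab]
    )
    if (cells < -1e-12).any():
        raise ValueError(
            f"infeasible carrier distribution: freq_a={freq_a}, freq_b={freq_b}, "
            f"dprime={dprime}"
        )
    return np.clip(cells, 0, 1)


def assign_genotypes(
    n: int,
    freq_a: float,
    freq_b: float,
    dprime: float,
    seed: int | np.random.Generator = 0,
) -> list[tuple[bool, bool]]:
    """Draw per-subject carrier pairs (carries A, carries B) from the 2x2
    carrier distribution implied by the marginals and carrier-level D'."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cells = _carrier_cells(freq_a, freq_b, dprime)
    draw = rng.choice(4, size=n, p=cells / cells.sum())
    a = np.isin(draw, (0, 1))
    b = np.isin(draw, (0, 2))
    return list(zip(a.tolist(), b.tolist()))


# ---------------------------------------------------------------------------
# sequence pool


@dataclass(frozen=True)
class KeyPool:
    """The shared public clonotype pool with its planted subsets."""

    background: tuple[SequenceKey, ...]
    planted_a: tuple[SequenceKey, ...]  # treatment-associated, class I restricted
    planted_b: tuple[SequenceKey, ...]  # treatment-associated, class II restricted
    planted_other: tuple[SequenceKey, ...]  # treatment-associated, no HLA background
    features: dict[str, tuple[SequenceKey, ...]]  # allele -> marker clonotypes

    @property
    def planted_ga(self) -> tuple[SequenceKey, ...]:
        return self.planted_a + self.planted_b + self.planted_other

    def all_keys(self) -> list[SequenceKey]:
        keys = list(self.background) + list(self.planted_ga)
        for f in self.features.values():
            keys.extend(f)
        return keys


def _random_junctions(rng: np.random.Generator, n: int, lo: int = 10, hi: int = 16) -> list[str]:
    """Random CDR3-like junctions: C + random interior + F."""
    lengths = rng.integers(lo, hi + 1, size=n)
    return [
        "C" + "".join(_AA[rng.integers(0, len(_AA), size=L - 2)]) + "F" for L in lengths
    ]


def _random_keys(
    rng: np.random.Generator, n: int, taken: set[SequenceKey], v_bias: float = 0.0
) -> list[SequenceKey]:
    """n distinct clonotype keys not colliding with ``taken``; with
    probability ``v_bias`` the V gene is TRBV05-06 (the skew observed in
    public treatment-associated clonotypes)."""
    keys: list[SequenceKey] = []
    while len(keys) < n:
        m = n - len(keys)
        juncs = _random_junctions(rng, m)
        vs = [
            "TRBV05-06" if rng.random() < v_bias else _V_GENES[rng.integers(len(_V_GENES))]
            for _ in range(m)
        ]
        js = [_J_GENES[rng.integers(len(_J_GENES))] for _ in range(m)]
        for j, v, jg in zip(juncs, vs, js):
            k = SequenceKey(j, v, jg)
            if k not in taken:
                taken.add(k)
                keys.append(k)
    return keys


def build_pool(config: GeneratorConfig, seed: int | np.random.Generator) -> KeyPool:
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    taken: set[SequenceKey] = set()
    background = tuple(_random_keys(rng, config.pool_size, taken))
    planted_a = tuple(_random_keys(rng, config.n_planted_a, taken, v_bias=0.6))
    planted_b = tuple(_random_keys(rng, config.n_planted_b, taken, v_bias=0.6))
    planted_other = tuple(_random_keys(rng, config.n_planted_other, taken))
    features = {
        ALLELE_A: tuple(_random_keys(rng, config.n_feature_keys, taken)),
        ALLELE_B: tuple(_random_keys(rng, config.n_feature_keys, taken)),
    }
    return KeyPool(background, planted_a, planted_b, planted_other, features)


# ---------------------------------------------------------------------------
# repertoires


def _random_strings(rng: np.random.Generator, alphabet: np.ndarray, n: int, length: int) -> np.ndarray:
    idx = rng.integers(0, len(alphabet), size=(n, length))
    return alphabet[idx].view(f"U{length}").ravel()


def _unique_nt(rng: np.random.Generator, n: int, length: int = 48) -> np.ndarray:
    seqs = _random_strings(rng, _NT, n, length)
    while len(np.unique(seqs)) < n:  # astronomically rare
        seqs = np.unique(seqs)
        seqs = np.concatenate([seqs, _random_strings(rng, _NT, n - len(seqs), length)])
    return seqs


def _presence_probs(meta: SampleMeta, pool: KeyPool, config: GeneratorConfig) -> np.ndarray:
    """Per-pool-key inclusion probability for one sample."""
    a = bool(meta.carries(ALLELE_A))
    b = bool(meta.carries(ALLELE_B))
    exposed = meta.ga_exposed
    p_exp = config.exposed_carrier_presence
    probs = [np.full(len(pool.background), config.background_presence)]
    p_a = p_exp * (config.synergy if b else 1.0) if (exposed and a) else config.background_presence
    probs.append(np.full(len(pool.planted_a), min(p_a, 1.0)))
    p_b = p_exp if (exposed and b) else config.background_presence
    probs.append(np.full(len(pool.planted_b), p_b))
    p_o = p_exp if exposed else config.background_presence
    probs.append(np.full(len(pool.planted_other), p_o))
    for allele in pool.features:
        carrier = bool(meta.carries(allele))
        p_f = config.feature_carrier_presence if carrier else config.feature_background_presence
        probs.append(np.full(len(pool.features[allele]), p_f))
    return np.concatenate(probs)


def _clone_sizes(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    return np.minimum(rng.zipf(exponent, size=n), 100_000).astype(np.int64)


def gen_repertoire(
    meta: SampleMeta,
    pool: KeyPool,
    config: GeneratorConfig,
    seed: int | np.random.Generator,
    timepoint: str = "single",
) -> Repertoire:
    """One sample's repertoire under the planted-effect occurrence model.

    Every included public-pool clonotype is realized as one nucleotide
    rearrangement (distinct random nucleotide sequences per sample);
    private clonotypes fill the repertoire up to a negative-binomial
    unique-rearrangement count; clone sizes are Zipf-distributed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    all_keys = pool.all_keys()
    if not all_keys:
        raise ValueError("empty public pool")
    probs = _presence_probs(meta, pool, config)
    include = rng.random(len(probs)) < probs
    public = [all_keys[i] for i in np.flatnonzero(include)]

    # negative binomial with mean m and dispersion k: p = k/(k+m)
    k = config.size_dispersion
    m = config.mean_unique
    n_unique = int(rng.negative_binomial(k, k / (k + m)))
    n_unique = max(n_unique, len(public), 1)
    n_private = n_unique - len(public)

    juncs = list(_random_junctions(rng, n_private))
    vs = [_V_GENES[i] for i in rng.integers(0, len(_V_GENES), size=n_private)]
    js = [_J_GENES[i] for i in rng.integers(0, len(_J_GENES), size=n_private)]
    junction = [k.junction_aa for k in public] + juncs
    v_gene = [k.v_gene for k in public] + vs
    j_gene = [k.j_gene for k in public] + js

    n_nonprod = int(round(config.nonproductive_fraction * n_unique))
    n_rows = n_unique + n_nonprod
    df = pd.DataFrame(
        {
            "nucleotide_seq": _unique_nt(rng, n_rows),
            "junction_aa": junction + [""] * n_nonprod,
            "v_gene": v_gene + [""] * n_nonprod,
            "j_gene": j_gene + [""] * n_nonprod,
            "templates": _clone_sizes(rng, n_rows, config.clone_exponent),
            "productive": [True] * n_unique + [False] * n_nonprod,
        }
    )
    return Repertoire(
        sample_id=meta.sample_id,
        subject_id=meta.subject_id,
        timepoint=timepoint,
        rearrangements=df,
    )


def gen_longitudinal_pair(
    meta: SampleMeta,
    pool: KeyPool,
    config: GeneratorConfig,
    seed: int | np.random.Generator,
) -> tuple[Repertoire, Repertoire]:
    """Baseline/treated repertoire pair for one exposed subject.

    The baseline sample is generated pre-exposure. The treated sample
    keeps every baseline rearrangement (with jittered template counts),
    adds newly arriving public clonotypes at template counts below the
    top-``top_k`` boundary, and plants exactly ``n_expansions`` new
    nucleotide rearrangements ranked inside the top ``top_k`` — these
    expansion clonotypes are drawn from the planted treatment-associated
    keys of the subject's carried allele background when possible.
    """
    if not meta.ga_exposed:
        raise ValueError("longitudinal pairs are generated for exposed subjects")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    import dataclasses

    baseline_meta = dataclasses.replace(meta, ga_exposed=False, treatment_arm="none")
    baseline = gen_repertoire(baseline_meta, pool, config, rng, timepoint="baseline")

    base = baseline.rearrangements.copy()
    jitter = np.exp(rng.normal(0.0, 0.2, size=len(base)))
    base["templates"] = np.maximum(1, np.round(base["templates"] * jitter)).astype(np.int64)

    # tie-safe template bounds around the top-k boundary of the
    # persisting repertoire: expansions get counts above the (k-m)th
    # largest persisted template (so at most k-m persisted rows can
    # outrank them); arrivals stay strictly below the kth largest (so at
    # least k+m rows outrank them)
    m = config.n_expansions
    top = np.sort(base["templates"].to_numpy())[::-1]
    k = config.top_k
    t_hi = int(top[max(k - m - 1, 0)]) if len(top) >= k - m and len(top) > 0 else 0
    t_low = int(top[k - 1]) if len(top) >= k else 0

    present = set(
        zip(base["junction_aa"], base["v_gene"], base["j_gene"])
    )
    # newly arriving public clonotypes under the exposed occurrence model,
    # kept strictly below the top-k boundary; in repertoires too small or
    # too flat to have a sub-top-k stratum they are omitted
    all_keys = pool.all_keys()
    probs = _presence_probs(meta, pool, config)
    include = rng.random(len(probs)) < probs
    arrivals = [
        all_keys[i]
        for i in np.flatnonzero(include)
        if tuple(all_keys[i]) not in present
    ]
    if t_low >= 2:
        arrival_templates = np.minimum(
            _clone_sizes(rng, len(arrivals), config.clone_exponent), t_low - 1
        )
    else:
        arrivals = []
        arrival_templates = np.empty(0, dtype=np.int64)

    # planted expansions: prefer treatment-associated keys of the carried
    # background that are absent from baseline and not already arriving
    carried: list[SequenceKey] = []
    if meta.carries(ALLELE_A):
        carried += list(pool.planted_a)
    if meta.carries(ALLELE_B):
        carried += list(pool.planted_b)
    used = present | {tuple(k) for k in arrivals}
    candidates = [k for k in carried if tuple(k) not in used]
    order = rng.permutation(len(candidates))
    expansion_keys: list[SequenceKey] = [candidates[i] for i in order[: config.n_expansions]]
    n_extra = config.n_expansions - len(expansion_keys)
    if n_extra > 0:
        taken = {SequenceKey(*t) for t in used} | set(expansion_keys)
        expansion_keys += _random_keys(rng, n_extra, taken)
    expansion_templates = t_hi + rng.integers(1, 50, size=len(expansion_keys))

    new_keys = arrivals + expansion_keys
    new_templates = np.concatenate([arrival_templates, expansion_templates]).astype(np.int64)
    existing_nt = set(base["nucleotide_seq"])
    nt = []
    while len(nt) < len(new_keys):
        for s in _unique_nt(rng, len(new_keys) - len(nt)):
            if s not in existing_nt:
                existing_nt.add(s)
                nt.append(s)
    new_df = pd.DataFrame(
        {
            "nucleotide_seq": nt,
            "junction_aa": [k.junction_aa for k in new_keys],
            "v_gene": [k.v_gene for k in new_keys],
            "j_gene": [k.j_gene for k in new_keys],
            "templates": new_templates,
            "productive": True,
        }
    )
    treated_df = pd.concat([base, new_df], ignore_index=True)
    treated = Repertoire(
        sample_id=f"{meta.sample_id}-treated",
        subject_id=meta.subject_id,
        timepoint="treated",
        rearrangements=treated_df,
    )
    baseline.sample_id = f"{meta.sample_id}-baseline"
    return baseline, treated


# ---------------------------------------------------------------------------
# cohorts


def _cohort_metas(
    spec: CohortSpec, rng: np.random.Generator
) -> list[SampleMeta]:
    genos = assign_genotypes(spec.n, spec.freq_a, spec.freq_b, spec.dprime, rng)
    metas = []
    for i, (a, b) in enumerate(genos):
        case = i < spec.n_cases
        alleles = set()
        if a:
            alleles.add(ALLELE_A)
        if b:
            alleles.add(ALLELE_B)
        metas.append(
            SampleMeta(
                sample_id=f"{spec.name}-s{i:04d}",
                subject_id=f"{spec.name}-p{i:04d}",
                cohort_id=spec.name,
                ga_exposed=case,
                treatment_arm="GA" if case else "none",
                hla_genotype=frozenset(alleles),
                age=round(float(np.clip(rng.normal(38, 10), 18, 70)), 1),
                sex="f" if rng.random() < 0.72 else "m",
                disease_duration=round(float(rng.exponential(5)), 1),
            )
        )
    return metas


def simulate_cohorts(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[dict[str, tuple[list[Repertoire], list[SampleMeta]]], KeyPool]:
    """Generate every configured cohort; returns {name: (reps, metas)}
    plus the pool carrying the planted ground truth."""
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    pool_seed, *cohort_seeds = root.spawn(1 + len(config.cohorts))
    pool = build_pool(config, np.random.default_rng(pool_seed))
    out = {}
    for spec, cseed in zip(config.cohorts, cohort_seeds):
        rng = np.random.default_rng(cseed)
        metas = _cohort_metas(spec, rng)
        reps = [
            gen_repertoire(m, pool, config, np.random.default_rng(s))
            for m, s in zip(metas, cseed.spawn(len(metas)))
        ]
        out[spec.name] = (reps, metas)
    return out, pool


# ---------------------------------------------------------------------------
# clinical outcomes


def simulate_trial(
    groups: Sequence[tuple[str, int, int]],
    clinical: ClinicalConfig,
    seed: int | np.random.Generator,
    freq_b_given_a: float = 0.65,
    freq_b_given_nota: float = 0.38,
) -> dict[str, pd.DataFrame]:
    """Simulate a treatment trial from explicit (arm, n, n_a03) groups.

    ``groups`` fixes the arm-by-class-I-allele allocation (as printed in
    trial tables); the class II allele is drawn conditionally on the
    class I carrier state so the two alleles show realistic linkage.
    Returns the subject covariate table and the recurrent-event,
    first-event, and continuous-outcome tables from
    :func:`gen_clinical`.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows = []
    sid = 0
    for arm, n, n_a03 in groups:
        if n_a03 > n:
            raise ValueError(f"group {arm}: n_a03 > n")
        for i in range(n):
            a03 = i < n_a03
            dr15 = rng.random() < (freq_b_given_a if a03 else freq_b_given_nota)
            rows.append(
                {
                    "subject_id": f"t{sid:04d}",
                    "arm": arm,
                    "a03": a03,
                    "dr15": dr15,
                    "age": float(np.clip(rng.normal(38, 10), 18, 70)),
                    "sex_m": rng.random() < 0.28,
                    "disease_duration": float(rng.exponential(5)),
                }
            )
            sid += 1
    subjects = pd.DataFrame(rows)
    return gen_clinical(subjects, clinical, rng)


def _log_hr_design(subjects: pd.DataFrame, clinical: ClinicalConfig) -> np.ndarray:
    ga = (subjects["arm"] == "GA").to_numpy()
    gaifn = (subjects["arm"] == "GA+IFN").to_numpy()
    a03 = subjects["a03"].to_numpy(dtype=bool)
    dr15 = subjects["dr15"].to_numpy(dtype=bool)
    log_hr = (
        np.log(clinical.hr_ga) * ga
        + np.log(clinical.hr_gaifn) * gaifn
        + np.log(clinical.hr_a03) * a03
        + np.log(clinical.hr_dr15) * dr15
        + np.log(clinical.hr_ga_x_a03) * (ga & a03)
        + np.log(clinical.hr_gaifn_x_a03) * (gaifn & a03)
        + np.log(clinical.hr_ga_x_dr15) * (ga & dr15)
        + np.log(clinical.hr_gaifn_x_dr15) * (gaifn & dr15)
    )
    return log_hr


def gen_clinical(
    subjects: pd.DataFrame,
    clinical: ClinicalConfig,
    seed: int | np.random.Generator,
) -> dict[str, pd.DataFrame]:
    """Outcome tables for a subject covariate table.

    ``subjects`` needs columns subject_id, arm (GA | IFN | GA+IFN),
    a03, dr15, age, sex_m, disease_duration. Returns:

    * ``subjects`` — the input with treatment/interaction indicator columns;
    * ``recurrent`` — counting-process rows (start, stop, event] per subject;
    * ``first_event`` — first relapse time with administrative censoring;
    * ``continuous`` — delta-EDSS/year and MSSS from the linear model.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    required = {"subject_id", "arm", "a03", "dr15", "age", "sex_m", "disease_duration"}
    missing = required - set(subjects.columns)
    if missing:
        raise ValueError(f"subject table missing columns {sorted(missing)}")

    subjects = subjects.copy()
    subjects["ga"] = (subjects["arm"] == "GA").astype(int)
    subjects["gaifn"] = (subjects["arm"] == "GA+IFN").astype(int)
    for t in ("ga", "gaifn"):
        subjects[f"{t}_x_a03"] = subjects[t] * subjects["a03"].astype(int)
        subjects[f"{t}_x_dr15"] = subjects[t] * subjects["dr15"].astype(int)

    log_hr = _log_hr_design(subjects, clinical)
    if clinical.frailty_sd > 0:
        log_hr = log_hr + rng.normal(0.0, clinical.frailty_sd, size=len(subjects))
    rate = clinical.baseline_hazard * np.exp(log_hr)

    T = clinical.followup_years
    rec_rows, first_rows = [], []
    for sid, lam in zip(subjects["subject_id"], rate):
        n_ev = rng.poisson(lam * T)
        times = np.sort(rng.uniform(0, T, size=n_ev))
        start = 0.0
        for t in times:
            if t <= start:  # guard against zero-length intervals
                continue
            rec_rows.append({"subject_id": sid, "start": start, "stop": t, "event": 1})
            start = t
        if start < T:
            rec_rows.append({"subject_id": sid, "start": start, "stop": T, "event": 0})
        # first event with administrative censoring
        c = clinical.censor_years
        if n_ev and times[0] <= c:
            first_rows.append({"subject_id": sid, "time": times[0], "event": 1})
        else:
            first_rows.append({"subject_id": sid, "time": c, "event": 0})

    ga_x_a03 = subjects["ga_x_a03"].to_numpy() + subjects["gaifn_x_a03"].to_numpy()
    edss = clinical.beta_edss_ga_x_a03 * ga_x_a03 + rng.normal(
        0, clinical.edss_noise_sd, size=len(subjects)
    )
    msss = 5.0 + clinical.beta_edss_ga_x_a03 * ga_x_a03 + rng.normal(
        0, clinical.msss_noise_sd, size=len(subjects)
    )
    continuous = pd.DataFrame(
        {"subject_id": subjects["subject_id"], "delta_edss": edss, "msss": msss}
    )
    return {
        "subjects": subjects,
        "recurrent": pd.DataFrame(rec_rows),
        "first_event": pd.DataFrame(first_rows),
        "continuous": continuous,
    }
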