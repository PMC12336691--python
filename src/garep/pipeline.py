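"""Pipeline orchestration: simulate -> discover -> map-hla -> score ->
classify -> model, driven by one YAML config and one seed.

The global seed is fanned out to per-stage child seeds with
``numpy.random.SeedSequence.spawn`` in a fixed order, so each stage is
a pure function of (config, seed) and can be re-run standalone with the
same child seed. A run manifest records the config hash, the seed, and
per-stage outputs with row counts and content hashes; identical
config+seed runs reproduce byte-identical stage outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import fit_cox, fit_cox_ag, fit_linear_interaction
from .discovery import EnhancedSequenceDiscovery
from .exposure import predict_exposure
from .hla import HLACarrierClassifier, assign_hla, merge_labels
from .io import SequenceKey, write_metadata, write_repertoire
from .motifs import MotifKey
from .simulate import (
    ALLELE_A,
    ALLELE_B,
    ClinicalConfig,
    CohortSpec,
    GeneratorConfig,
    simulate_cohorts,
    simulate_trial,
)
from .stats import score_pattern_table

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "validate_config", "run_all", "DEFAULT_TRIAL_GROUPS"]

#: arm-by-class-I-carrier allocation used by the demo `model` stage
#: (a three-arm trial plus a two-arm first-event cohort)
DEFAULT_TRIAL_GROUPS = {
    "recurrent": [("IFN", 168, 56), ("GA", 172, 60), ("GA+IFN", 353, 95)],
    "first_event": [("IFN", 239, 74), ("GA", 96, 32)],
}

_KNOWN_SECTIONS = {"seed", "generator", "discovery", "hla", "clinical", "trial"}


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, outputs: dict[str, Path], counts: dict[str, int], dt: float) -> None:
        self.stages.append(
            {
                "stage": name,
                "outputs": {k: str(v) for k, v in outputs.items()},
                "output_sha256": {k: _sha256(v) for k, v in outputs.items()},
                "rows": counts,
                "seconds": round(dt, 3),
            }
        )

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_config(config_path: str | Path) -> tuple[dict, list[str]]:
    """Parse and validate the YAML config; returns (resolved config
    dict, list of warnings). Schema violations raise ValueError with an
    itemized report; unknown top-level keys warn but do not fail."""
    raw = yaml.safe_load(Path(config_path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    warnings = [f"unknown config key {k!r} ignored" for k in raw if k not in _KNOWN_SECTIONS]

    problems: list[str] = []
    resolved: dict = {}
    if "seed" not in raw:
        warnings.append("seed missing; default 0 filled in")
    resolved["seed"] = int(raw.get("seed", 0))

    gen_kwargs = dict(raw.get("generator", {}))
    cohort_specs = gen_kwargs.pop("cohorts", None)
    clinical_kwargs = dict(raw.get("clinical", {}))
    try:
        clinical = ClinicalConfig(**clinical_kwargs)
    except (TypeError, ValueError) as e:
        problems.append(f"clinical: {e}")
        clinical = ClinicalConfig()
    try:
        if cohort_specs is not None:
            gen_kwargs["cohorts"] = tuple(CohortSpec(**c) for c in cohort_specs)
        generator = GeneratorConfig(
            **gen_kwargs, clinical=clinical, seed=resolved["seed"]
        )
    except (TypeError, ValueError) as e:
        problems.append(f"generator: {e}")
        generator = None
    resolved["generator"] = generator
    resolved["clinical"] = clinical

    disc_kwargs = dict(raw.get("discovery", {}))
    resolved["discovery"] = disc_kwargs
    if generator is not None:
        n_cohorts = len(generator.cohorts)
        min_rep = int(disc_kwargs.get("min_replicated_cohorts", 2))
        if min_rep > n_cohorts:
            problems.append(
                f"discovery: min_replicated_cohorts={min_rep} exceeds "
                f"{n_cohorts} configured cohort(s)"
            )
    resolved["hla"] = dict(raw.get("hla", {}))
    resolved["trial"] = raw.get("trial", DEFAULT_TRIAL_GROUPS)
    if problems:
        raise ValueError("invalid config:\n  - " + "\n  - ".join(problems))
    return resolved, warnings


def _key_to_json(k: SequenceKey | MotifKey) -> dict:
    if isinstance(k, MotifKey):
        return {
            "kind": "motif",
            "pattern": k.pattern,
            "v_gene": k.v_gene,
            "j_gene": k.j_gene,
            "members": [list(m) for m in sorted(k.members)],
        }
    return {"kind": "key", "junction_aa": k.junction_aa, "v_gene": k.v_gene, "j_gene": k.j_gene}


def run_all(config_path: str | Path, seed: int | None, out_dir: str | Path) -> RunManifest:
    """Execute the full analytical sequence on a synthetic study."""
    config_path = Path(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    resolved, warnings = validate_config(config_path)
    for w in warnings:
        logger.warning(w)
    if seed is None:
        seed = resolved["seed"]
    gen: GeneratorConfig = resolved["generator"]
    manifest = RunManifest(
        config_hash=hashlib.sha256(config_path.read_bytes()).hexdigest(),
        seed=seed,
        version=__version__,
    )
    root = np.random.SeedSequence(seed)
    s_sim, s_hla, s_trial = root.spawn(3)

    def _stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    try:
        # ---- simulate -------------------------------------------------
        t0 = _stage("simulate")
        cohorts, pool = simulate_cohorts(gen, seed=int(s_sim.generate_state(1)[0] % (2**31)))
        sim_dir = out / "cohorts"
        outputs, counts = {}, {}
        all_reps, all_metas = [], []
        for name, (reps, metas) in cohorts.items():
            cdir = sim_dir / name
            cdir.mkdir(parents=True, exist_ok=True)
            for rep in reps:
                write_repertoire(rep, cdir / f"{rep.sample_id}.tsv")
            meta_path = sim_dir / f"{name}.metadata.csv"
            write_metadata(metas, meta_path)
            outputs[f"{name}.metadata"] = meta_path
            counts[name] = len(reps)
            all_reps.extend(reps)
            all_metas.extend(metas)
        truth_path = out / "planted_truth.json"
        truth_path.write_text(
            json.dumps(
                {
                    "planted_a": [list(k) for k in pool.planted_a],
                    "planted_b": [list(k) for k in pool.planted_b],
                    "planted_other": [list(k) for k in pool.planted_other],
                },
                indent=2,
            )
        )
        outputs["planted_truth"] = truth_path
        manifest.add("simulate", outputs, counts, time.perf_counter() - t0)

        # ---- discover -------------------------------------------------
        t0 = _stage("discover")
        y = np.array([m.ga_exposed for m in all_metas])
        cohort_labels = np.array([m.cohort_id for m in all_metas])
        disc = EnhancedSequenceDiscovery(min_presence=2, **resolved["discovery"])
        disc.fit(all_reps, y, cohort=cohort_labels)
        es_path = out / "enhanced_sequences.json"
        es_path.write_text(
            json.dumps(
                [
                    {
                        "target": _key_to_json(es.target),
                        "pvalues": es.pvalues,
                        "tables": {k: list(v) for k, v in es.tables.items()},
                        "replicated_cohorts": sorted(es.replicated_cohorts),
                    }
                    for es in disc.enhanced_sequences_
                ],
                indent=2,
            )
        )
        manifest.add(
            "discover",
            {"enhanced_sequences": es_path},
            {"keys": len(disc.keys_), "motifs": len(disc.motifs_)},
            time.perf_counter() - t0,
        )

        # ---- map-hla --------------------------------------------------
        t0 = _stage("map-hla")
        hla_rng = int(s_hla.generate_state(1)[0] % (2**31))
        typed = pd.DataFrame(
            {
                ALLELE_A: [m.carries(ALLELE_A) for m in all_metas],
                ALLELE_B: [m.carries(ALLELE_B) for m in all_metas],
            },
            index=[m.sample_id for m in all_metas],
        )
        imputed = {}
        models_json = {}
        for allele in (ALLELE_A, ALLELE_B):
            labels = typed[allele].astype(bool).to_numpy()
            clf = HLACarrierClassifier(
                allele=allele, random_state=hla_rng, **resolved["hla"]
            ).fit(all_reps, labels)
            imputed[allele] = clf.predict(all_reps)
            models_json[allele] = clf.to_json_dict()
        imputed_df = pd.DataFrame(imputed, index=typed.index)
        labels_df = merge_labels(typed, imputed_df)
        assignments = assign_hla(disc.enhanced_sequences_, all_reps, labels_df)
        hla_path = out / "hla_assignments.json"
        hla_path.write_text(
            json.dumps(
                {
                    "models": models_json,
                    "assignments": [
                        {
                            "target": _key_to_json(a.target),
                            "alleles": list(a.alleles),
                            "p_value": a.p_value,
                            "category": a.category,
                        }
                        for a in assignments
                    ],
                },
                indent=2,
            )
        )
        manifest.add(
            "map-hla",
            {"hla_assignments": hla_path},
            {"assignments": len(assignments)},
            time.perf_counter() - t0,
        )

        # ---- score ----------------------------------------------------
        t0 = _stage("score")
        patterns: dict[str, list] = {}
        for a, assignment in zip(assignments, disc.enhanced_sequences_):
            for allele in a.alleles:
                if a.category in ("assigned", "uncertain"):
                    patterns.setdefault(allele, []).append(assignment.target)
        if not patterns and disc.enhanced_sequences_:
            # discoveries exist but none HLA-assignable: score them pooled
            patterns = {"all_es": disc.pattern()}
        scores = (
            score_pattern_table(all_reps, patterns)
            if patterns
            else pd.DataFrame(
                columns=["sample_id", "pattern_id", "breadth", "depth",
                         "breadth_per_1e6", "n_matching"]
            )
        )
        scores_path = out / "pattern_scores.csv"
        scores.to_csv(scores_path, index=False)
        manifest.add(
            "score", {"pattern_scores": scores_path}, {"rows": len(scores)},
            time.perf_counter() - t0,
        )

        # ---- classify -------------------------------------------------
        t0 = _stage("classify")
        exposed = pd.Series(
            [m.ga_exposed for m in all_metas], index=[m.sample_id for m in all_metas]
        )
        roc_out = {}
        for allele, pat in patterns.items():
            sub = scores[scores["pattern_id"] == allele].set_index("sample_id")
            carrier = (
                labels_df[allele]
                if allele in labels_df.columns
                else pd.Series(True, index=sub.index)
            )
            try:
                rocs = predict_exposure(sub, exposed, carrier)
            except ValueError as e:
                roc_out[allele] = {"error": str(e)}
                continue
            roc_out[allele] = {
                scorer: {"auc": r.auc, "ci95": list(r.ci95), "n_pos": r.n_pos, "n_neg": r.n_neg}
                for scorer, r in rocs.items()
            }
        roc_path = out / "exposure_auc.json"
        roc_path.write_text(json.dumps(roc_out, indent=2))
        manifest.add(
            "classify", {"exposure_auc": roc_path}, {"strata": len(roc_out)},
            time.perf_counter() - t0,
        )

        # ---- model ----------------------------------------------------
        t0 = _stage("model")
        trial_seed = int(s_trial.generate_state(1)[0] % (2**31))
        groups = resolved["trial"]
        covs = [
            "age", "sex_m", "disease_duration", "ga", "gaifn",
            "a03", "dr15", "ga_x_a03", "gaifn_x_a03", "ga_x_dr15", "gaifn_x_dr15",
        ]
        fits = {}
        rec = simulate_trial(
            [tuple(g) for g in groups["recurrent"]], gen.clinical, trial_seed
        )
        rec_df = rec["recurrent"].merge(rec["subjects"], on="subject_id")
        use = [c for c in covs if rec_df[c].astype(float).nunique() > 1]
        ag = fit_cox_ag(
            rec_df, "start", "stop", "event", use, cluster_col="subject_id",
            scale_columns=("age", "disease_duration"),
        )
        fits["andersen_gill"] = ag.summary.to_dict(orient="index")

        fe = simulate_trial(
            [tuple(g) for g in groups["first_event"]], gen.clinical, trial_seed + 1
        )
        fe_df = fe["first_event"].merge(fe["subjects"], on="subject_id")
        use = [c for c in covs if fe_df[c].astype(float).nunique() > 1]
        cox = fit_cox(
            fe_df, "time", "event", use, scale_columns=("age", "disease_duration")
        )
        fits["cox_first_event"] = cox.summary.to_dict(orient="index")

        cont_df = fe["continuous"].merge(fe["subjects"], on="subject_id")
        use = [c for c in covs if cont_df[c].astype(float).nunique() > 1]
        lin = fit_linear_interaction(cont_df, "delta_edss", use)
        fits["linear_delta_edss"] = lin.summary.to_dict(orient="index")

        model_path = out / "model_fits.json"
        model_path.write_text(json.dumps(fits, indent=2, default=float))
        manifest.add(
            "model", {"model_fits": model_path},
            {"recurrent_rows": len(rec_df), "first_event_rows": len(fe_df)},
            time.perf_counter() - t0,
        )
    except Exception as e:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        stage = manifest.stages[-1]["stage"] if manifest.stages else "simulate"
        (failed / "FAILED.txt").write_text(f"pipeline failed after stage {stage}: {e}\n")
        raise

    manifest.write(out / "manifest.json")
    return manifest
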