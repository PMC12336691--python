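"""Enhanced-Sequence (ES) discovery.

The discovery step asks, for every public amino-acid clonotype, whether
its *presence* (at least one productive rearrangement with that exact
junction + V gene + J gene) is enriched among treatment-exposed cases
relative to controls, cohort by cohort, using a one-sided Fisher exact
test. Clonotypes below a per-cohort p-value threshold (default 0.001)
are Enhanced Sequences. Private responses sharing a public motif are
captured by one-wildcard expansion: for every ES and every interior
junction position a candidate motif is formed, its presence defined as
presence of ANY matching clonotype, and the motif retained when its
pooled-presence p-value is below a stricter threshold (default 1e-4)
AND strictly below the p-value of every individual member. Cohort
effects are controlled by requiring replication: an ES must meet its
rule in at least ``min_replicated_cohorts`` cohorts. No multiplicity
correction is applied by default (the stringent threshold plus
multi-cohort replication is the filter); Benjamini-Hochberg is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .io import Repertoire, SequenceKey
from .motifs import WILDCARD, MotifKey, matches_motif

__all__ = [
    "DiscoveryConfig",
    "EnhancedSequence",
    "fet_enrichment",
    "presence_matrix",
    "cohort_pvalues",
    "expand_wildcards",
    "replicate_filter",
    "hamming_clusters",
    "EnhancedSequenceDiscovery",
]


@dataclass(frozen=True)
class DiscoveryConfig:
    """Thresholds of the dual-filter discovery rule."""

    p_seq: float = 1e-3  # per-cohort threshold for exact clonotypes
    p_motif: float = 1e-4  # per-cohort threshold for one-wildcard motifs
    min_replicated_cohorts: int = 2
    interior_only: bool = True  # never wildcard the first/last residue
    fdr_mode: str | None = None  # None | "bh"

    def __post_init__(self) -> None:
        if not (0 < self.p_seq < 1 and 0 < self.p_motif < 1):
            raise ValueError("thresholds must be in (0, 1)")
        if self.min_replicated_cohorts < 1:
            raise ValueError("min_replicated_cohorts must be >= 1")


@dataclass
class EnhancedSequence:
    """A discovered clonotype or motif with its per-cohort evidence."""

    target: SequenceKey | MotifKey
    tables: dict[str, tuple[int, int, int, int]]  # cohort -> (a, b, c, d)
    pvalues: dict[str, float]
    replicated_cohorts: frozenset[str]
    combined_p: float | None = None  # motifs: min per-cohort motif p

    @property
    def is_motif(self) -> bool:
        return isinstance(self.target, MotifKey)


def fet_enrichment(
    cases_present: int, cases_absent: int, controls_present: int, controls_absent: int
) -> float:
    """One-sided Fisher exact p for enrichment in cases.

    The one-sided tail P[X >= cases_present] of the hypergeometric
    distribution with the table's fixed margins.
    """
    if min(cases_present, cases_absent, controls_present, controls_absent) < 0:
        raise ValueError("table counts must be nonnegative")
    n = cases_present + cases_absent + controls_present + controls_absent
    k = cases_present + controls_present
    return float(hypergeom.sf(cases_present - 1, n, k, cases_present + cases_absent))


def _fet_vector(a: np.ndarray, n_cases: int, c: np.ndarray, n_controls: int) -> np.ndarray:
    """Vectorized one-sided FET over presence counts a (cases), c (controls)."""
    n = n_cases + n_controls
    return hypergeom.sf(a - 1, n, a + c, n_cases)


def presence_matrix(reps: Sequence[Repertoire], min_samples: int = 1) -> pd.DataFrame:
    """Samples x clonotype boolean presence matrix.

    Entry (s, k) is True iff sample s has >= 1 productive rearrangement
    with exact clonotype key k; only keys present somewhere appear as
    columns (all-false columns cannot arise). ``min_samples`` drops
    clonotypes present in fewer samples (private singletons carry no
    case/control information and dominate the column count).
    """
    ids = [r.sample_id for r in reps]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_ids in cohort")
    key_sets = [r.productive_keys() for r in reps]
    if min_samples > 1:
        from collections import Counter

        counts: Counter = Counter()
        for ks in key_sets:
            counts.update(ks)
        keep = {k for k, c in counts.items() if c >= min_samples}
        key_sets = [ks & keep for ks in key_sets]
    all_keys = sorted(set().union(*key_sets)) if key_sets else []
    col_index = {k: j for j, k in enumerate(all_keys)}
    mat = np.zeros((len(reps), len(all_keys)), dtype=bool)
    for i, ks in enumerate(key_sets):
        for k in ks:
            mat[i, col_index[k]] = True
    return pd.DataFrame(mat, index=ids, columns=all_keys)


def cohort_pvalues(pres: pd.DataFrame, is_case: np.ndarray) -> pd.Series:
    """Per-clonotype one-sided FET p-values for one cohort."""
    is_case = np.asarray(is_case, dtype=bool)
    n_cases = int(is_case.sum())
    n_controls = int((~is_case).sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError("cohort must contain at least one case and one control")
    a = pres.values[is_case].sum(axis=0)
    c = pres.values[~is_case].sum(axis=0)
    return pd.Series(_fet_vector(a, n_cases, c, n_controls), index=pres.columns)


def _bh_mask(p: pd.Series, alpha: float) -> pd.Series:
    from statsmodels.stats.multitest import multipletests

    if len(p) == 0:
        return pd.Series(dtype=bool)
    rej, *_ = multipletests(p.values, alpha=alpha, method="fdr_bh")
    return pd.Series(rej, index=p.index)


@dataclass
class _CohortData:
    """Internal: one cohort's presence matrix, labels, and key p-values."""

    name: str
    pres: pd.DataFrame
    is_case: np.ndarray
    pvals: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pvals is None:
            self.pvals = cohort_pvalues(self.pres, self.is_case)
        # positional lookup: SequenceKey tuples confuse label-based
        # pandas column selection (tuples read as MultiIndex keys)
        self._col = {k: j for j, k in enumerate(self.pres.columns)}
        self._mat = self.pres.to_numpy()
        self._pvec = self.pvals.to_numpy()

    @property
    def n_cases(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.is_case).sum())

    def table(self, present: np.ndarray) -> tuple[int, int, int, int]:
        a = int(present[self.is_case].sum())
        c = int(present[~self.is_case].sum())
        return a, self.n_cases - a, c, self.n_controls - c

    def key_present(self, key: SequenceKey) -> np.ndarray:
        j = self._col.get(key)
        if j is None:
            return np.zeros(len(self.pres), dtype=bool)
        return self._mat[:, j]

    def key_p(self, key: SequenceKey) -> float:
        j = self._col.get(key)
        return 1.0 if j is None else float(self._pvec[j])

    def any_present(self, keys) -> np.ndarray:
        cols = [self._col[k] for k in keys if k in self._col]
        if not cols:
            return np.zeros(len(self.pres), dtype=bool)
        return self._mat[:, cols].any(axis=1)


def expand_wildcards(
    es_keys: Sequence[SequenceKey],
    cohorts: Sequence[_CohortData],
    config: DiscoveryConfig = DiscoveryConfig(),
) -> list[EnhancedSequence]:
    """One-wildcard motif expansion seeded from ES clonotypes.

    For each seed and wildcard position, the motif's members are every
    observed clonotype (any cohort) matching the pattern with the same
    V/J; motif presence in a sample is presence of any member. The
    motif passes in a cohort when its FET p is below ``p_motif`` AND
    strictly below the p-value of every individual member there.
    """
    # index observed keys by (v, j, junction length) across cohorts
    groups: dict[tuple[str, str, int], set[SequenceKey]] = {}
    for cd in cohorts:
        for k in cd.pres.columns:
            groups.setdefault((k.v_gene, k.j_gene, len(k.junction_aa)), set()).add(k)

    seen: set[tuple[str, str, str]] = set()
    out: list[EnhancedSequence] = []
    for seed in es_keys:
        aa = seed.junction_aa
        lo, hi = (1, len(aa) - 1) if config.interior_only else (0, len(aa))
        for pos in range(lo, hi):
            pattern = aa[:pos] + WILDCARD + aa[pos + 1 :]
            ident = (pattern, seed.v_gene, seed.j_gene)
            if ident in seen:
                continue
            seen.add(ident)
            members = frozenset(
                k
                for k in groups.get((seed.v_gene, seed.j_gene, len(aa)), ())
                if matches_motif(pattern, k.junction_aa)
            )
            if not members:
                continue
            motif = MotifKey(pattern, seed.v_gene, seed.j_gene, members)
            tables, pvals, passed = {}, {}, set()
            for cd in cohorts:
                present = cd.any_present(members)
                a, b, c, d = cd.table(present)
                p = fet_enrichment(a, b, c, d)
                tables[cd.name] = (a, b, c, d)
                pvals[cd.name] = p
                min_member_p = min(cd.key_p(k) for k in members)
                if p < config.p_motif and p < min_member_p:
                    passed.add(cd.name)
            if passed:
                out.append(
                    EnhancedSequence(
                        target=motif,
                        tables=tables,
                        pvalues=pvals,
                        replicated_cohorts=frozenset(passed),
                        combined_p=min(pvals[c] for c in passed),
                    )
                )
    return out


def replicate_filter(
    candidates: Sequence[EnhancedSequence], config: DiscoveryConfig = DiscoveryConfig()
) -> list[EnhancedSequence]:
    """Keep candidates meeting their rule in >= min_replicated_cohorts."""
    kept = [
        es for es in candidates if len(es.replicated_cohorts) >= config.min_replicated_cohorts
    ]
    kept.sort(key=lambda es: min(es.pvalues.values()))
    return kept


def hamming_clusters(
    keys: Sequence[SequenceKey], d: int = 1
) -> list[tuple[list[SequenceKey], str]]:
    """Single-linkage clusters of same-length junctions at Hamming <= d.

    Returns, per connected component, its member keys and a consensus
    string with a wildcard at every non-unanimous position. Keys of
    different junction lengths are never clustered.
    """
    if not keys:
        raise ValueError("keys must be nonempty")
    keys = list(keys)
    parent = list(range(len(keys)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            a, b = keys[i].junction_aa, keys[j].junction_aa
            if len(a) != len(b):
                continue
            if sum(x != y for x, y in zip(a, b)) <= d:
                union(i, j)

    comps: dict[int, list[SequenceKey]] = {}
    for i in range(len(keys)):
        comps.setdefault(find(i), []).append(keys[i])
    out = []
    for members in comps.values():
        seqs = [m.junction_aa for m in members]
        consensus = "".join(
            col[0] if len(set(col)) == 1 else WILDCARD for col in zip(*seqs)
        )
        out.append((sorted(members), consensus))
    out.sort(key=lambda t: (-len(t[0]), t[1]))
    return out


class EnhancedSequenceDiscovery(BaseEstimator):
    """Case/control Enhanced-Sequence discovery with replication.

    A scikit-learn-style estimator: ``fit`` takes repertoires, exposure
    labels, and cohort labels, and discovers the replicated set of
    exposure-associated clonotypes and one-wildcard motifs;
    ``transform`` scores repertoires for clonal breadth and depth
    against the discovered pattern.

    Parameters
    ----------
    p_seq, p_motif : float
        Per-cohort one-sided FET thresholds for exact clonotypes and
        for motifs.
    min_replicated_cohorts : int
        Minimum number of cohorts in which the rule must hold.
    interior_only : bool
        Restrict wildcards to interior junction positions (the
        conserved C...F flanks are never freed).
    expand_motifs : bool
        Whether to run the one-wildcard expansion at all.
    fdr_mode : None or "bh"
        Optional Benjamini-Hochberg gate per cohort on top of p_seq.

    Attributes
    ----------
    enhanced_sequences_ : list of EnhancedSequence
        Replicated discoveries (clonotypes and motifs).
    keys_, motifs_ : lists of the two kinds separately.
    cohort_names_ : tuple of cohort labels seen during fit.
    """

    def __init__(
        self,
        p_seq: float = 1e-3,
        p_motif: float = 1e-4,
        min_replicated_cohorts: int = 2,
        interior_only: bool = True,
        expand_motifs: bool = True,
        fdr_mode: str | None = None,
        min_presence: int = 1,
    ):
        self.p_seq = p_seq
        self.p_motif = p_motif
        self.min_replicated_cohorts = min_replicated_cohorts
        self.interior_only = interior_only
        self.expand_motifs = expand_motifs
        self.fdr_mode = fdr_mode
        self.min_presence = min_presence

    def _config(self) -> DiscoveryConfig:
        return DiscoveryConfig(
            p_seq=self.p_seq,
            p_motif=self.p_motif,
            min_replicated_cohorts=self.min_replicated_cohorts,
            interior_only=self.interior_only,
            fdr_mode=self.fdr_mode,
        )

    def fit(self, X: Sequence[Repertoire], y, cohort=None):
        """Discover the replicated ES set.

        Parameters
        ----------
        X : sequence of Repertoire
        y : array-like of bool, exposure (case) status per sample
        cohort : array-like of cohort labels per sample (required when
            more than one cohort is present; defaults to a single cohort)
        """
        config = self._config()
        y = np.asarray(y, dtype=bool)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        cohort = (
            np.asarray(cohort) if cohort is not None else np.repeat("cohort0", len(y))
        )
        names = list(dict.fromkeys(cohort.tolist()))
        if len(names) < config.min_replicated_cohorts:
            raise ValueError(
                f"{len(names)} cohort(s) < min_replicated_cohorts="
                f"{config.min_replicated_cohorts}"
            )
        cohorts = []
        for name in names:
            idx = np.flatnonzero(cohort == name)
            cohorts.append(
                _CohortData(
                    name=str(name),
                    pres=presence_matrix([X[i] for i in idx], min_samples=self.min_presence),
                    is_case=y[idx],
                )
            )

        # per-cohort significant clonotypes, then replication over cohorts
        sig_sets = []
        for cd in cohorts:
            sig = cd.pvals < config.p_seq
            if config.fdr_mode == "bh":
                sig &= _bh_mask(cd.pvals, config.p_seq)
            sig_sets.append(set(cd.pvals.index[sig]))
        es_union = sorted(set().union(*sig_sets))

        key_candidates = []
        for key in es_union:
            tables, pvals, passed = {}, {}, set()
            for cd, sig in zip(cohorts, sig_sets):
                present = cd.key_present(key)
                tables[cd.name] = cd.table(present)
                pvals[cd.name] = cd.key_p(key)
                if key in sig:
                    passed.add(cd.name)
            key_candidates.append(
                EnhancedSequence(
                    target=key,
                    tables=tables,
                    pvalues=pvals,
                    replicated_cohorts=frozenset(passed),
                )
            )

        motif_candidates = (
            expand_wildcards(es_union, cohorts, config) if self.expand_motifs else []
        )

        self.cohort_names_ = tuple(names)
        self.keys_ = replicate_filter(key_candidates, config)
        self.motifs_ = replicate_filter(motif_candidates, config)
        self.enhanced_sequences_ = self.keys_ + self.motifs_
        return self

    def pattern(self) -> list[SequenceKey | MotifKey]:
        check_is_fitted(self, "enhanced_sequences_")
        return [es.target for es in self.enhanced_sequences_]

    def transform(self, X: Sequence[Repertoire]) -> pd.DataFrame:
        """Breadth/depth of each repertoire against the discovered pattern."""
        from .stats import score_pattern

        check_is_fitted(self, "enhanced_sequences_")
        pattern = self.pattern()
        rows = []
        for rep in X:
            s = score_pattern(rep, pattern, pattern_id="enhanced_sequences")
            rows.append({"sample_id": s.sample_id, "breadth": s.breadth, "depth": s.depth})
        return pd.DataFrame(rows).set_index("sample_id")
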