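"""Per-sample repertoire statistics: clonality, expansion calls, and
pattern breadth/depth scoring.

Productive clonality is 1 minus the normalized Shannon entropy of the
productive rearrangement frequency distribution: 0 for a perfectly even
repertoire, 1 for a monoclonal one. An *expansion* is a nucleotide-level
rearrangement absent from the baseline sample but ranked in the top-K
(default 100) most prevalent rearrangements of the post-treatment
sample. Pattern *breadth* is the fraction of unique productive
rearrangements matching a sequence pattern; *depth* is the fraction of
productive templates carried by those matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import Repertoire, SequenceKey
from .motifs import MotifKey

__all__ = [
    "PatternScore",
    "ExpansionCall",
    "productive_clonality",
    "detect_expansions",
    "score_pattern",
    "score_pattern_table",
]


@dataclass(frozen=True)
class PatternScore:
    """Clonal breadth and depth of one sample against one pattern."""

    sample_id: str
    pattern_id: str
    breadth: float  # unique matching rearrangements / R_unique
    depth: float  # matching templates / T_total
    n_matching: int

    @property
    def breadth_per_1e6(self) -> float:
        """Breadth per 10^6 unique rearrangements (plotting scale)."""
        return self.breadth * 1e6


@dataclass(frozen=True)
class ExpansionCall:
    nucleotide_seq: str
    treated_rank: int
    treated_templates: int


def productive_clonality(rep: Repertoire) -> float:
    """1 - H/ln(R_unique) over productive rearrangement frequencies.

    Returns 1.0 for a single-rearrangement repertoire (the monoclonal
    convention, since normalized entropy is undefined at R_unique = 1).
    """
    r = rep.r_unique
    if r == 0:
        raise ValueError(f"sample {rep.sample_id}: clonality undefined on empty productive set")
    if r == 1:
        return 1.0
    t = rep.productive["templates"].to_numpy(dtype=float)
    f = t / t.sum()
    h = -np.sum(f * np.log(f))
    return float(1.0 - h / np.log(r))


def detect_expansions(
    baseline: Repertoire,
    treated: Repertoire,
    k: int = 100,
    include_nonproductive: bool = True,
) -> list[ExpansionCall]:
    """Nucleotide rearrangements new since baseline and in the treated
    sample's top-``k`` by template count.

    Ranking is by descending templates with ties broken by lexicographic
    nucleotide sequence; exactly the first ``k`` rows are eligible, so
    the call set is independent of input row order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = treated.rearrangements
    if not include_nonproductive:
        df = df[df["productive"]]
    ranked = df.sort_values(
        ["templates", "nucleotide_seq"], ascending=[False, True], kind="mergesort"
    ).head(k)
    baseline_seqs = set(baseline.rearrangements["nucleotide_seq"])
    calls = []
    for rank, (seq, templ) in enumerate(
        zip(ranked["nucleotide_seq"], ranked["templates"]), start=1
    ):
        if seq not in baseline_seqs:
            calls.append(ExpansionCall(seq, rank, int(templ)))
    return calls


def _match_mask(rep: Repertoire, pattern: Iterable[SequenceKey | MotifKey]) -> pd.Series:
    """Boolean mask over the productive rows: row's clonotype hits the pattern."""
    exact: set[SequenceKey] = set()
    motifs: dict[tuple[str, str, int], list[MotifKey]] = {}
    n_elements = 0
    for el in pattern:
        n_elements += 1
        if isinstance(el, MotifKey):
            motifs.setdefault((el.v_gene, el.j_gene, len(el.pattern)), []).append(el)
        else:
            exact.add(SequenceKey(*el))
    if n_elements == 0:
        raise ValueError("empty pattern")
    prod = rep.productive
    keys = list(zip(prod["junction_aa"], prod["v_gene"], prod["j_gene"]))
    mask = np.zeros(len(keys), dtype=bool)
    for i, (aa, v, j) in enumerate(keys):
        if (aa, v, j) in exact:
            mask[i] = True
            continue
        for mot in motifs.get((v, j, len(aa)), ()):
            if mot.matches(SequenceKey(aa, v, j)):
                mask[i] = True
                break
    return pd.Series(mask, index=prod.index)


def score_pattern(
    rep: Repertoire,
    pattern: Iterable[SequenceKey | MotifKey],
    pattern_id: str = "pattern",
) -> PatternScore:
    """Clonal breadth and depth of ``rep`` against a set of clonotype
    keys and/or one-wildcard motifs.

    Breadth counts unique matching productive rearrangements over
    R_unique (several nucleotide variants of one clonotype each count);
    depth sums their templates over T_total.
    """
    r, t = rep.r_unique, rep.t_total
    if r == 0:
        return PatternScore(rep.sample_id, pattern_id, 0.0, 0.0, 0)
    mask = _match_mask(rep, pattern)
    n_match = int(mask.sum())
    t_match = int(rep.productive.loc[mask, "templates"].sum())
    return PatternScore(rep.sample_id, pattern_id, n_match / r, t_match / t, n_match)


def score_pattern_table(
    reps: Sequence[Repertoire],
    patterns: dict[str, Iterable[SequenceKey | MotifKey]],
) -> pd.DataFrame:
    """Score every repertoire against every named pattern; tidy table."""
    rows = []
    for rep in reps:
        for pid, pattern in patterns.items():
            s = score_pattern(rep, list(pattern), pattern_id=pid)
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "pattern_id": s.pattern_id,
                    "breadth": s.breadth,
                    "depth": s.depth,
                    "breadth_per_1e6": s.breadth_per_1e6,
                    "n_matching": s.n_matching,
                }
            )
    return pd.DataFrame(rows)
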