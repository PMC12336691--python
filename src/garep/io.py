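"""Domain types and I/O for TRB repertoires and cohort metadata.

The unit of all repertoire statistics is the *rearrangement*: one unique
nucleotide-level V(D)J recombination product with an absolute template
count. A repertoire is one sample's table of rearrangements; several
nucleotide rearrangements may encode the same amino-acid clonotype
(``SequenceKey``). Repertoires are held as pandas DataFrames (one row
per rearrangement) for vectorized downstream statistics.

Supported on-disk formats: the AIRR Community Rearrangement TSV (columns
``sequence``, ``junction_aa``, ``v_call``, ``j_call``,
``duplicate_count``, ``productive``) and an immunoSEQ-like TSV dialect
(``nucleotide``, ``aminoAcid``, ``count``, ``vGeneName``, ``jGeneName``,
``sequenceStatus``). Gene calls are canonicalized on read so that
cross-dialect comparisons are at gene resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .genes import canonical_gene

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "Rearrangement",
    "SequenceKey",
    "Repertoire",
    "SampleMeta",
    "read_repertoire",
    "write_repertoire",
    "read_metadata",
    "write_metadata",
    "read_cohort",
]

#: canonical in-memory column order of a repertoire table
REARRANGEMENT_COLUMNS = [
    "nucleotide_seq",
    "junction_aa",
    "v_gene",
    "j_gene",
    "templates",
    "productive",
]

_AIRR_COLUMNS = {
    "nucleotide_seq": "sequence",
    "junction_aa": "junction_aa",
    "v_gene": "v_call",
    "j_gene": "j_call",
    "templates": "duplicate_count",
    "productive": "productive",
}

_IMMUNOSEQ_COLUMNS = {
    "nucleotide_seq": "nucleotide",
    "junction_aa": "aminoAcid",
    "v_gene": "vGeneName",
    "j_gene": "jGeneName",
    "templates": "count",
    "productive": "sequenceStatus",
}


class FormatError(ValueError):
    """A repertoire or metadata file does not conform to its dialect."""


class SequenceKey(NamedTuple):
    """Amino-acid clonotype identity: CDR3 junction + V gene + J gene."""

    junction_aa: str
    v_gene: str
    j_gene: str

    def __str__(self) -> str:  # e.g. CASSSHGGEQYF+TRBV05-06+TRBJ02-07
        return f"{self.junction_aa}+{self.v_gene}+{self.j_gene}"


@dataclass(frozen=True)
class Rearrangement:
    """One unique nucleotide rearrangement with its template count."""

    nucleotide_seq: str
    junction_aa: str
    v_gene: str
    j_gene: str
    templates: int
    productive: bool

    def key(self) -> SequenceKey:
        return SequenceKey(self.junction_aa, self.v_gene, self.j_gene)


@dataclass
class Repertoire:
    """One sample's rearrangement table.

    ``R_unique`` (unique productive nucleotide rearrangements) and
    ``T_total`` (their summed templates) are the denominators of every
    breadth/depth statistic; they are always recomputed from the rows,
    never trusted from input.
    """

    sample_id: str
    subject_id: str
    timepoint: str  # baseline | treated | single
    rearrangements: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.rearrangements
        missing = [c for c in REARRANGEMENT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"repertoire table missing column(s): {missing}")
        df = df[REARRANGEMENT_COLUMNS].reset_index(drop=True)
        df = df.astype(
            {
                "nucleotide_seq": str,
                "junction_aa": str,
                "v_gene": str,
                "j_gene": str,
                "templates": np.int64,
                "productive": bool,
            }
        )
        self.rearrangements = df
        if len(df) and df["nucleotide_seq"].duplicated().any():
            raise FormatError(
                f"sample {self.sample_id}: duplicate nucleotide_seq rows "
                "(merge templates before constructing a Repertoire)"
            )
        if len(df) and (df["templates"] < 1).any():
            raise FormatError(f"sample {self.sample_id}: template counts must be >= 1")
        prod = df[df["productive"]]
        if len(prod):
            bad = prod["junction_aa"].eq("") | prod["v_gene"].eq("") | prod["j_gene"].eq("")
            if bad.any():
                raise FormatError(
                    f"sample {self.sample_id}: productive rows with empty "
                    "junction_aa/v_gene/j_gene"
                )

    @property
    def productive(self) -> pd.DataFrame:
        """View of the productive rows only."""
        return self.rearrangements[self.rearrangements["productive"]]

    @property
    def r_unique(self) -> int:
        """Number of unique productive nucleotide rearrangements."""
        return int(self.productive["nucleotide_seq"].nunique())

    @property
    def t_total(self) -> int:
        """Sum of templates over unique productive rearrangements."""
        return int(self.productive["templates"].sum())

    def productive_keys(self) -> set[SequenceKey]:
        """Set of amino-acid clonotype keys present in the productive rows."""
        prod = self.productive
        return {
            SequenceKey(j, v, g)
            for j, v, g in zip(prod["junction_aa"], prod["v_gene"], prod["j_gene"])
        }

    def __len__(self) -> int:
        return len(self.rearrangements)


@dataclass
class SampleMeta:
    """Per-sample cohort metadata.

    ``hla_genotype`` is a set of carried allele names, or ``None`` when
    the genotype is unknown (distinct from an empty set, which asserts
    that none of the panel alleles are carried). Optional per-cohort
    clinical scalars and event streams live in ``outcomes``.
    """

    sample_id: str
    subject_id: str
    cohort_id: str
    ga_exposed: bool
    treatment_arm: str = "none"  # GA | IFN | GA+IFN | none
    hla_genotype: frozenset[str] | None = None
    age: float = np.nan
    sex: str = ""  # f | m
    disease_duration: float = np.nan
    timepoint: str = "single"
    outcomes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arm_ga = self.treatment_arm in ("GA", "GA+IFN")
        if self.treatment_arm != "none" and self.ga_exposed != arm_ga:
            raise ValueError(
                f"sample {self.sample_id}: ga_exposed={self.ga_exposed} inconsistent "
                f"with treatment_arm={self.treatment_arm}"
            )

    def carries(self, allele: str) -> bool | None:
        if self.hla_genotype is None:
            return None
        return allele in self.hla_genotype


def _coerce_productive(values: pd.Series, dialect: str) -> pd.Series:
    if dialect == "immunoseq":
        return values.astype(str).str.strip().str.lower().eq("in")
    s = values.astype(str).str.strip().str.upper()
    return s.isin(("T", "TRUE", "1"))


def read_repertoire(
    path: str | Path,
    dialect: str = "airr",
    sample_id: str | None = None,
    subject_id: str | None = None,
    timepoint: str = "single",
) -> Repertoire:
    """Read one rearrangement TSV into a :class:`Repertoire`.

    Gene calls are canonicalized (allele suffix stripped, numbers
    zero-padded); rows sharing a nucleotide sequence are merged with
    summed templates (logged); non-productive rows are retained but
    excluded from ``R_unique``/``T_total`` by the Repertoire accessors.
    """
    path = Path(path)
    if dialect in ("airr",):
        colmap = _AIRR_COLUMNS
    elif dialect in ("immunoseq", "immunoseq-like"):
        colmap = _IMMUNOSEQ_COLUMNS
        dialect = "immunoseq"
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [src for src in colmap.values() if src not in raw.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    df = pd.DataFrame({dst: raw[src] for dst, src in colmap.items()})
    df["templates"] = pd.to_numeric(df["templates"], errors="raise").astype(np.int64)
    df["productive"] = _coerce_productive(df["productive"], dialect)
    for col in ("v_gene", "j_gene"):
        df[col] = df[col].map(canonical_gene)
    if df["nucleotide_seq"].duplicated().any():
        n = int(df["nucleotide_seq"].duplicated().sum())
        logger.warning("%s: %d duplicate nucleotide rows merged (templates summed)", path.name, n)
        df = (
            df.groupby("nucleotide_seq", as_index=False, sort=False)
            .agg(
                junction_aa=("junction_aa", "first"),
                v_gene=("v_gene", "first"),
                j_gene=("j_gene", "first"),
                templates=("templates", "sum"),
                productive=("productive", "first"),
            )
        )
    return Repertoire(
        sample_id=sample_id or path.stem,
        subject_id=subject_id or (sample_id or path.stem),
        timepoint=timepoint,
        rearrangements=df,
    )


def write_repertoire(rep: Repertoire, path: str | Path) -> None:
    """Write a repertoire as an AIRR Rearrangement TSV (round-trip exact)."""
    df = rep.rearrangements
    out = pd.DataFrame(
        {
            "sequence": df["nucleotide_seq"],
            "junction_aa": df["junction_aa"],
            "v_call": df["v_gene"],
            "j_call": df["j_gene"],
            "duplicate_count": df["templates"],
            "productive": np.where(df["productive"], "T", "F"),
        }
    )
    out.to_csv(path, sep="\t", index=False)


_META_FIELDS = [
    "sample_id",
    "subject_id",
    "cohort_id",
    "timepoint",
    "ga_exposed",
    "treatment_arm",
    "hla_genotype",
    "age",
    "sex",
    "disease_duration",
]


def write_metadata(metas: Iterable[SampleMeta], path: str | Path) -> None:
    """Write cohort metadata CSV; genotype as ';'-joined alleles.

    Unknown genotypes are written as the literal ``unknown``; a known
    all-negative genotype is written as ``-``.
    """
    rows = []
    for m in metas:
        if m.hla_genotype is None:
            geno = "unknown"
        elif not m.hla_genotype:
            geno = "-"
        else:
            geno = ";".join(sorted(m.hla_genotype))
        row = {
            "sample_id": m.sample_id,
            "subject_id": m.subject_id,
            "cohort_id": m.cohort_id,
            "timepoint": m.timepoint,
            "ga_exposed": m.ga_exposed,
            "treatment_arm": m.treatment_arm,
            "hla_genotype": geno,
            "age": m.age,
            "sex": m.sex,
            "disease_duration": m.disease_duration,
        }
        row.update(m.outcomes)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_metadata(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, dtype={"sample_id": str, "subject_id": str})
    missing = [c for c in _META_FIELDS if c not in df.columns]
    if missing:
        raise FormatError(f"{Path(path).name}: missing metadata column(s) {missing}")
    extra = [c for c in df.columns if c not in _META_FIELDS]
    metas = []
    for _, r in df.iterrows():
        geno_raw = r["hla_genotype"]
        if pd.isna(geno_raw) or str(geno_raw).strip().lower() in ("", "unknown", "nan"):
            geno: frozenset[str] | None = None
        elif str(geno_raw).strip() == "-":
            geno = frozenset()
        else:
            geno = frozenset(a for a in str(geno_raw).split(";") if a)
        metas.append(
            SampleMeta(
                sample_id=str(r["sample_id"]),
                subject_id=str(r["subject_id"]),
                cohort_id=str(r["cohort_id"]),
                ga_exposed=bool(r["ga_exposed"]),
                treatment_arm=str(r["treatment_arm"]),
                hla_genotype=geno,
                age=float(r["age"]),
                sex=str(r["sex"]),
                disease_duration=float(r["disease_duration"]),
                timepoint=str(r["timepoint"]),
                outcomes={c: r[c] for c in extra if not pd.isna(r[c])},
            )
        )
    return metas


def read_cohort(
    metadata_path: str | Path, repertoire_dir: str | Path, dialect: str = "airr"
) -> tuple[list[Repertoire], list[SampleMeta]]:
    """Read a cohort: metadata CSV plus one repertoire TSV per sample.

    Repertoire files are resolved as ``<repertoire_dir>/<sample_id>.tsv``;
    every metadata row must resolve. Extra files in the directory are
    reported in a log warning, missing ones are an error.
    """
    repertoire_dir = Path(repertoire_dir)
    metas = read_metadata(metadata_path)
    missing = [m.sample_id for m in metas if not (repertoire_dir / f"{m.sample_id}.tsv").exists()]
    if missing:
        raise FileNotFoundError(
            f"no repertoire file for sample_id(s): {', '.join(sorted(missing))}"
        )
    known = {m.sample_id for m in metas}
    extra = [p.stem for p in repertoire_dir.glob("*.tsv") if p.stem not in known]
    if extra:
        logger.warning("%d repertoire file(s) not referenced by metadata: %s",
                       len(extra), ", ".join(sorted(extra)[:10]))
    reps = [
        read_repertoire(
            repertoire_dir / f"{m.sample_id}.tsv",
            dialect=dialect,
            sample_id=m.sample_id,
            subject_id=m.subject_id,
            timepoint=m.timepoint,
        )
        for m in metas
    ]
    return reps, metas
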