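"""Variant domain types: keys, per-child records, and the cohort table.

Only autosomal biallelic SNVs are modeled: a variant is identified by
(chromosome, 1-based position, ref base, alt base). A :class:`VariantTable`
holds one row per candidate dnSNV per child, with the child's cohort label
(``proband`` or ``sibling``), optional genomic-compartment tag, optional
population minor allele frequency, and any number of continuous
prioritization-score columns.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

AUTOSOMES = tuple(str(i) for i in range(1, 23))
BASES = ("A", "C", "G", "T")
COHORTS = ("proband", "sibling")
COMPARTMENTS = ("coding", "intronic", "intergenic", "utr3", "utr5")

#: Columns every variant table carries, in canonical order. Any additional
#: column is treated as a score column.
CORE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "child_id",
    "family_id",
    "cohort",
    "compartment",
    "maf",
]


def normalize_chrom(chrom: str) -> str | None:
    """Strip a ``chr`` prefix and return the autosome name, or None.

    Non-autosomal contigs (X, Y, MT, alt scaffolds) return None so callers
    can drop them with a logged count.
    """
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    return c if c in AUTOSOMES else None


@functools.total_ordering
@dataclass(frozen=True)
class VariantKey:
    """Identity of an autosomal biallelic SNV.

    Keys are totally ordered by (numeric chromosome, position, ref, alt)
    so that output tables have a deterministic row order.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.chrom not in AUTOSOMES:
            raise ValueError(f"chrom must be an autosome '1'..'22', got {self.chrom!r}")
        if self.pos < 1:
            raise ValueError(f"pos is 1-based and must be >= 1, got {self.pos}")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"ref/alt must be single bases, got {self.ref!r}/{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError("alt must differ from ref")

    @property
    def sort_key(self) -> tuple[int, int, str, str]:
        return (int(self.chrom), self.pos, self.ref, self.alt)

    def __lt__(self, other: "VariantKey") -> bool:
        return self.sort_key < other.sort_key

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class VariantRecord:
    """One candidate dnSNV carried by one child."""

    key: VariantKey
    child_id: str
    family_id: str
    cohort: str
    compartment: str | None = None
    maf: float | None = None  # None means "no reference-panel frequency available"
    scores: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"cohort must be one of {COHORTS}, got {self.cohort!r}")
        if self.compartment is not None and self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise ValueError(f"maf must be in [0, 1], got {self.maf}")


class VariantTable:
    """Ordered collection of per-child dnSNV records backed by a DataFrame.

    Rows are sorted by variant key then child id; duplicate
    (key, child) pairs are rejected. ``maf`` uses NaN for "missing", which
    is a distinct state from 0. Score columns are any columns beyond
    :data:`CORE_COLUMNS`.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in CORE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        df = df.copy()
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        df["maf"] = df["maf"].astype(float)
        bad_cohort = set(df["cohort"].unique()) - set(COHORTS)
        if bad_cohort:
            raise ValueError(f"unknown cohort labels: {sorted(bad_cohort)}")
        order = np.lexsort(
            (df["child_id"], df["alt"], df["ref"], df["pos"], df["chrom"].astype(int))
        )
        df = df.iloc[order].reset_index(drop=True)
        dup = df.duplicated(subset=["chrom", "pos", "ref", "alt", "child_id"])
        if dup.any():
            raise ValueError(f"{int(dup.sum())} duplicate (variant, child) pairs")
        self.df = df

    # -- construction ----------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[VariantRecord]) -> "VariantTable":
        rows = []
        score_names: set[str] = set()
        recs = list(records)
        for r in recs:
            score_names.update(r.scores)
        for r in recs:
            row = {
                "chrom": r.key.chrom,
                "pos": r.key.pos,
                "ref": r.key.ref,
                "alt": r.key.alt,
                "child_id": r.child_id,
                "family_id": r.family_id,
                "cohort": r.cohort,
                "compartment": r.compartment,
                "maf": np.nan if r.maf is None else r.maf,
            }
            for s in score_names:
                row[s] = r.scores.get(s, np.nan)
            rows.append(row)
        cols = CORE_COLUMNS + sorted(score_names)
        return cls(pd.DataFrame(rows, columns=cols))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "VariantTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False, na_rep="NA")

    # -- accessors -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def score_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in CORE_COLUMNS]

    @property
    def n_proband(self) -> int:
        return int((self.df["cohort"] == "proband").sum())

    @property
    def n_sibling(self) -> int:
        return int((self.df["cohort"] == "sibling").sum())

    @property
    def is_proband(self) -> np.ndarray:
        return (self.df["cohort"] == "proband").to_numpy()

    def keys(self) -> list[VariantKey]:
        return [
            VariantKey(c, int(p), r, a)
            for c, p, r, a in zip(self.df["chrom"], self.df["pos"], self.df["ref"], self.df["alt"])
        ]

    def records(self) -> list[VariantRecord]:
        score_cols = self.score_columns
        out = []
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            maf = d["maf"]
            out.append(
                VariantRecord(
                    key=VariantKey(d["chrom"], int(d["pos"]), d["ref"], d["alt"]),
                    child_id=d["child_id"],
                    family_id=d["family_id"],
                    cohort=d["cohort"],
                    compartment=None if pd.isna(d["compartment"]) else d["compartment"],
                    maf=None if pd.isna(maf) else float(maf),
                    scores={s: d[s] for s in score_cols if not pd.isna(d[s])},
                )
            )
        return out

    def cohort_scores(self, column: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (proband, sibling) score vectors, NaNs dropped."""
        if column not in self.df.columns:
            raise KeyError(f"no score column {column!r}")
        s = self.df[column]
        mask = ~s.isna()
        p = s[mask & (self.df["cohort"] == "proband")].to_numpy(dtype=float)
        q = s[mask & (self.df["cohort"] == "sibling")].to_numpy(dtype=float)
        return p, q
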