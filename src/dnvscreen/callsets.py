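"""Call-set algebra for cross-study dnSNV comparison.

A :class:`CallSet` is a named study's set of variant identities. Published
cross-study sets usually lack child identifiers, so the default identity
mode matches on (chrom, pos, ref, alt) alone; (variant, child) matching is
available for within-cohort comparisons. Intersection / union / disjoint
operations and exclusive membership-pattern (UpSet) counts are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Hashable, Iterable, Sequence

from dnvscreen.variants import VariantKey, VariantTable

IDENTITY_MODES = ("key", "key_child")


@dataclass(frozen=True)
class CallSet:
    study_name: str
    keys: frozenset = field(default_factory=frozenset)
    identity_mode: str = "key"

    def __post_init__(self) -> None:
        if self.identity_mode not in IDENTITY_MODES:
            raise ValueError(f"identity_mode must be one of {IDENTITY_MODES}")
        object.__setattr__(self, "keys", frozenset(self.keys))

    def __len__(self) -> int:
        return len(self.keys)

    @classmethod
    def from_table(
        cls, table: VariantTable, study_name: str, identity_mode: str = "key"
    ) -> "CallSet":
        ks: Iterable[Hashable]
        if identity_mode == "key":
            ks = table.keys()
        else:
            ks = list(zip(table.keys(), table.df["child_id"]))
        return cls(study_name, frozenset(ks), identity_mode)

    @classmethod
    def from_tsv(cls, path: str | Path, study_name: str | None = None) -> "CallSet":
        """Read a call set from a TSV with chrom/pos/ref/alt columns."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        keys = frozenset(
            VariantKey(c, int(p), r, a)
            for c, p, r, a in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
        )
        return cls(study_name or Path(path).stem, keys, "key")

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        if self.identity_mode != "key":
            raise NotImplementedError("TSV export only for key identity mode")
        rows = sorted(self.keys)
        pd.DataFrame(
            {"chrom": [k.chrom for k in rows], "pos": [k.pos for k in rows],
             "ref": [k.ref for k in rows], "alt": [k.alt for k in rows]}
        ).to_csv(path, sep="\t", index=False)


def _check_modes(callsets: Sequence[CallSet]) -> None:
    modes = {c.identity_mode for c in callsets}
    if len(modes) > 1:
        raise ValueError(f"mixed call-set identity modes: {sorted(modes)}")


def callset_ops(a: CallSet, b: CallSet) -> dict[str, CallSet]:
    """Intersection, union, and the two disjoint (one-study-only) sets."""
    _check_modes([a, b])
    mode = a.identity_mode
    return {
        "intersection": CallSet(f"{a.study_name}&{b.study_name}", a.keys & b.keys, mode),
        "union": CallSet(f"{a.study_name}|{b.study_name}", a.keys | b.keys, mode),
        "disjoint_a": CallSet(f"{a.study_name}-{b.study_name}", a.keys - b.keys, mode),
        "disjoint_b": CallSet(f"{b.study_name}-{a.study_name}", b.keys - a.keys, mode),
    }


def upset_counts(callsets: Sequence[CallSet]) -> dict[tuple[str, ...], int]:
    """Exclusive membership-pattern counts across >=2 call sets.

    Keys are tuples of study names (in input order) forming each non-empty
    pattern; every variant in the union is counted under exactly one
    pattern, so per-study totals are recoverable by summing the patterns
    that contain the study.
    """
    if len(callsets) < 2:
        raise ValueError("need at least two call sets")
    _check_modes(callsets)
    names = [c.study_name for c in callsets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate study names")
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(range(len(names)), r):
            counts[tuple(names[i] for i in combo)] = 0
    membership: dict[Hashable, list[int]] = {}
    for i, cs in enumerate(callsets):
        for k in cs.keys:
            membership.setdefault(k, []).append(i)
    for pattern_idx in membership.values():
        pattern = tuple(names[i] for i in sorted(pattern_idx))
        counts[pattern] += 1
    return counts
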