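"""Genomic interval sets and point-overlap queries.

Intervals follow the BED convention: 0-based, half-open ``[start, end)``.
Variant positions are 1-based, so a variant at position ``p`` overlaps an
interval ``(start, end)`` iff ``start < p <= end``; that conversion happens
in exactly one place (:func:`overlap_membership` /
:meth:`IntervalSet.contains`), which keeps off-by-one drift out of the rest
of the pipeline.

Internally each chromosome's intervals are merged into a sorted,
non-overlapping list, so membership queries are a single binary search per
point and results do not depend on input interval order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from dnvscreen.variants import VariantTable, normalize_chrom

logger = logging.getLogger(__name__)

Interval = tuple[str, int, int]


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly-overlapping (start, end) half-open intervals."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class IntervalSet:
    """A named annotation category: merged intervals per chromosome."""

    name: str
    _starts: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _ends: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    n_raw: int = 0

    @classmethod
    def from_intervals(cls, name: str, intervals: Iterable[Interval]) -> "IntervalSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        n_raw = 0
        n_dropped = 0
        for chrom, start, end in intervals:
            n_raw += 1
            if end <= start:
                raise ValueError(f"interval end must exceed start, got ({chrom}, {start}, {end})")
            c = normalize_chrom(chrom)
            if c is None:
                n_dropped += 1
                continue
            by_chrom.setdefault(c, []).append((int(start), int(end)))
        if n_dropped:
            logger.info("%s: dropped %d non-autosomal intervals", name, n_dropped)
        obj = cls(name=name, n_raw=n_raw)
        for c, ivs in by_chrom.items():
            merged = merge_intervals(ivs)
            obj._starts[c] = np.array([s for s, _ in merged], dtype=np.int64)
            obj._ends[c] = np.array([e for _, e in merged], dtype=np.int64)
        return obj

    @property
    def n_intervals(self) -> int:
        return sum(len(v) for v in self._starts.values())

    def __len__(self) -> int:
        return self.n_intervals

    @property
    def total_bp(self) -> int:
        return int(sum((self._ends[c] - self._starts[c]).sum() for c in self._starts))

    def intervals(self) -> list[Interval]:
        out: list[Interval] = []
        for c in sorted(self._starts, key=int):
            out.extend((c, int(s), int(e)) for s, e in zip(self._starts[c], self._ends[c]))
        return out

    def contains(self, chroms: Sequence[str], positions: Sequence[int]) -> np.ndarray:
        """Vectorized point-in-set query for 1-based positions."""
        chroms = np.asarray(chroms, dtype=object)
        pos0 = np.asarray(positions, dtype=np.int64) - 1  # to 0-based
        hit = np.zeros(len(pos0), dtype=bool)
        for c in np.unique(chroms):
            starts = self._starts.get(str(c))
            if starts is None:
                continue
            ends = self._ends[str(c)]
            mask = chroms == c
            idx = np.searchsorted(starts, pos0[mask], side="right") - 1
            ok = idx >= 0
            ok[ok] &= pos0[mask][ok] < ends[idx[ok]]
            hit[mask] = ok
        return hit

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, s, e in self.intervals():
                fh.write(f"{chrom}\t{s}\t{e}\n")


def parse_bed(path: str | Path, name: str | None = None) -> IntervalSet:
    """Read a BED3+ file into a merged :class:`IntervalSet`.

    Raises ValueError (with the line number) on intervals where end <= start.
    """
    name = name or Path(path).stem
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end ({end}) <= start ({start})")
            intervals.append((chrom, start, end))
    out = IntervalSet.from_intervals(name, intervals)
    logger.info("%s: %d raw intervals, %d after merging", name, out.n_raw, out.n_intervals)
    return out


def promoter_intervals(
    tss: Iterable[tuple[str, int, str]], upstream: int = 1500, name: str = "promoters"
) -> IntervalSet:
    """Build promoter intervals as the ``upstream`` bp upstream of each TSS.

    ``tss`` yields (chrom, 1-based TSS position, strand). On the plus strand
    the promoter is the window just 5' of the TSS (lower coordinates); on the
    minus strand upstream means higher coordinates.
    """
    intervals: list[Interval] = []
    for chrom, pos, strand in tss:
        if strand == "+":
            start = max(0, pos - 1 - upstream)
            end = pos - 1
        elif strand == "-":
            start = pos
            end = pos + upstream
        else:
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        if end > start:
            intervals.append((chrom, start, end))
    return IntervalSet.from_intervals(name, intervals)


def overlap_membership(table: VariantTable, cat: IntervalSet) -> tuple[np.ndarray, int, int]:
    """Per-record category membership and per-cohort overlap counts.

    Returns ``(membership, k_p, k_s)`` where ``membership`` is a boolean
    array aligned to ``table.df`` and ``k_p``/``k_s`` count in-category
    dnSNVs for probands and siblings.
    """
    member = cat.contains(table.df["chrom"].to_numpy(), table.df["pos"].to_numpy())
    is_p = table.is_proband
    k_p = int(member[is_p].sum())
    k_s = int(member[~is_p].sum())
    return member, k_p, k_s
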