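"""Synthetic quad-family data with the statistical structure of a dnSNV study.

Real quad-cohort sequencing data of this kind is access-restricted, so the
generators here emulate its summary structure instead: per-child de novo
SNV counts are Poisson with means near 70 (probands) and 69 (siblings),
~98% of variants fall in intronic/intergenic compartments, annotation
categories overlap a configurable few percent of variants with an optional
relative proband excess g (proband in-category probability p2*(1+g) vs
sibling p2), continuous prioritization scores are uniform on [0,1] under
the null with an optional location shift in probands, and multi-study call
sets are derived from a shared truth set by independent per-study false
negatives and false positives.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dnvscreen.callsets import CallSet
from dnvscreen.intervals import IntervalSet
from dnvscreen.variants import BASES, CORE_COLUMNS, VariantKey, VariantTable

# Synthetic autosome map: 22 chromosomes of 10 Mb each. Coordinates are
# arbitrary (no real-genome correspondence); uniqueness of positions is all
# downstream stages rely on.
N_CHROMS = 22
CHROM_LEN = 10_000_000
GENOME_LEN = N_CHROMS * CHROM_LEN

DEFAULT_COMPARTMENT_PROBS = {
    "intronic": 0.55,
    "intergenic": 0.43,
    "coding": 0.012,
    "utr3": 0.005,
    "utr5": 0.003,
}

# Observed per-family dnSNV rates: cohort totals 134,969 / 131,896 over
# 1,917 quad families.
RATE_PROBAND = 134_969 / 1_917
RATE_SIBLING = 131_896 / 1_917


@dataclass
class CohortSimConfig:
    n_families: int = 1_917
    rate_proband: float = RATE_PROBAND
    rate_sibling: float = RATE_SIBLING
    compartment_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPARTMENT_PROBS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_proband <= 0 or self.rate_sibling <= 0:
            raise ValueError("rates must be positive")
        total = sum(self.compartment_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"compartment_probs must sum to 1, got {total}")


@dataclass
class CategorySimConfig:
    """In-category probabilities: sibling p2, proband p2*(1+g)."""

    baseline_prop: float = 0.05
    relative_excess: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_excess < -1:
            raise ValueError("relative_excess must be >= -1")
        if not (0.0 <= self.baseline_prop <= 1.0):
            raise ValueError("baseline_prop must be in [0, 1]")
        if self.proband_prop > 1.0:
            raise ValueError("p2*(1+g) exceeds 1")

    @property
    def proband_prop(self) -> float:
        return self.baseline_prop * (1.0 + self.relative_excess)


@dataclass
class ScoreSimConfig:
    """Uniform(0,1) null scores with a location shift in some probands.

    The default shift magnitude 0.01 mirrors the scale of mean-score
    differences reported for disease-impact-style scores; shifted values
    are clipped to [0, 1].
    """

    proband_shift: float = 0.01
    shift_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.shift_fraction <= 1.0):
            raise ValueError("shift_fraction must be in [0, 1]")


@dataclass
class StudySimConfig:
    n_studies: int = 4
    false_negative_rate: float = 0.10
    false_positive_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("false_negative_rate", "false_positive_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


def _unique_global_positions(rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw n distinct positions on the concatenated synthetic genome."""
    pos = np.unique(rng.integers(0, GENOME_LEN, size=int(n * 1.05) + 16))
    while len(pos) < n:
        extra = rng.integers(0, GENOME_LEN, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    return rng.permutation(pos)[:n]


def _split_global(gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    chrom = (gpos // CHROM_LEN + 1).astype(int).astype(str)
    pos = (gpos % CHROM_LEN + 1).astype(np.int64)
    return chrom, pos


def simulate_cohort(cfg: CohortSimConfig) -> VariantTable:
    """Generate a quad-cohort dnSNV table.

    Per-child counts are Poisson(rate); positions are unique uniform draws
    over the synthetic autosomes; ref/alt are random distinct bases;
    compartments are multinomial.
    """
    rng = np.random.default_rng(cfg.seed)
    counts_p = rng.poisson(cfg.rate_proband, cfg.n_families)
    counts_s = rng.poisson(cfg.rate_sibling, cfg.n_families)
    fam_ids = np.array([f"F{i:05d}" for i in range(cfg.n_families)])
    family = np.concatenate([np.repeat(fam_ids, counts_p), np.repeat(fam_ids, counts_s)])
    child = np.concatenate(
        [
            np.char.add(np.repeat(fam_ids, counts_p), ".p1"),
            np.char.add(np.repeat(fam_ids, counts_s), ".s1"),
        ]
    )
    cohort = np.concatenate(
        [np.repeat("proband", counts_p.sum()), np.repeat("sibling", counts_s.sum())]
    )
    n = len(cohort)
    chrom, pos = _split_global(_unique_global_positions(rng, n))
    ref_idx = rng.integers(0, 4, n)
    alt_idx = (ref_idx + rng.integers(1, 4, n)) % 4
    bases = np.array(BASES)
    comp_names = list(cfg.compartment_probs)
    comp = rng.choice(comp_names, size=n, p=[cfg.compartment_probs[c] for c in comp_names])
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref": bases[ref_idx],
            "alt": bases[alt_idx],
            "child_id": child,
            "family_id": family,
            "cohort": cohort,
            "compartment": comp,
            "maf": np.nan,
        },
        columns=CORE_COLUMNS,
    )
    return VariantTable(df)


def plant_category(
    table: VariantTable, cfg: CategorySimConfig
) -> tuple[IntervalSet, np.ndarray]:
    """Plant an annotation category with a known proband excess.

    Each sibling variant is in-category with probability p2 and each
    proband variant with probability p2*(1+g). The category is emitted as
    1-bp intervals at member positions so that interval overlap reproduces
    the planted membership exactly (cohort positions are unique).
    """
    rng = np.random.default_rng(cfg.seed)
    is_p = table.is_proband
    probs = np.where(is_p, cfg.proband_prop, cfg.baseline_prop)
    member = rng.random(len(table)) < probs
    ivs = [
        (c, int(p) - 1, int(p))
        for c, p in zip(table.df["chrom"][member], table.df["pos"][member])
    ]
    return IntervalSet.from_intervals("planted_category", ivs), member


def sample_overlap_counts(
    n_p: int, n_s: int, cfg: CategorySimConfig, rng: np.random.Generator
) -> tuple[int, int]:
    """Fast path: binomial in-category counts without materializing a table.

    Equivalent in distribution to plant_category followed by overlap
    counting; used for replicated calibration runs.
    """
    k_p = int(rng.binomial(n_p, cfg.proband_prop))
    k_s = int(rng.binomial(n_s, cfg.baseline_prop))
    return k_p, k_s


def simulate_scores(
    table: VariantTable, cfg: ScoreSimConfig, column: str = "score"
) -> np.ndarray:
    """Attach a synthetic prioritization-score column to ``table`` (in place).

    Sibling scores are Uniform(0,1); a fraction of proband scores get a
    location shift, clipped to [0,1]. Returns the score vector.
    """
    rng = np.random.default_rng(cfg.seed)
    scores = rng.random(len(table))
    is_p = table.is_proband
    shifted = is_p & (rng.random(len(table)) < cfg.shift_fraction)
    scores[shifted] = np.clip(scores[shifted] + cfg.proband_shift, 0.0, 1.0)
    table.df[column] = scores
    return scores


# ---------------------------------------------------------------------------
# Quad VCF fixtures with planted truth
# ---------------------------------------------------------------------------

#: Site classes understood by :func:`simulate_trio_genotypes` and the fate
#: each is expected to meet in the filter pipeline.
SITE_CLASSES = {
    "true_denovo": "retained",
    "inherited": "not_candidate",
    "low_gq": "removed_gq",
    "low_dp": "removed_dp",
    "high_af": "removed_ac_af",
    "high_maf": "removed_maf",
    "excluded": "removed_excluded",
    "recurrent": "removed_recurrent",
    "missing_gt": "ineligible",
}


@dataclass
class QuadSimResult:
    vcf_text: str
    ped_text: str
    truth: pd.DataFrame  # chrom,pos,ref,alt,family_id,cohort,site_class,expected_fate
    exclusion: IntervalSet
    maf_lookup: dict[tuple, float]

    def write(self, outdir: str | Path, prefix: str = "quads") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / f"{prefix}.vcf",
            "ped": outdir / f"{prefix}.ped",
            "truth": outdir / f"{prefix}.truth.tsv",
            "exclude": outdir / f"{prefix}.exclude.bed",
        }
        paths["vcf"].write_text(self.vcf_text)
        paths["ped"].write_text(self.ped_text)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        self.exclusion.to_bed(paths["exclude"])
        return paths


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AC,Number=A,Type=Integer,Description="Cohort alt allele count">
##INFO=<ID=AF,Number=A,Type=Float,Description="Cohort alt allele frequency">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def simulate_trio_genotypes(
    plant_spec: dict[str, int] | None = None,
    n_families: int = 8,
    seed: int = 0,
) -> QuadSimResult:
    """Emit a quad VCF + PED with per-site planted truth.

    ``plant_spec`` maps site classes (see :data:`SITE_CLASSES`) to counts.
    AC/AF are written to INFO emulating values computed on a much larger
    cohort, so a de novo singleton carries a tiny AF regardless of the
    number of families in the fixture. ``recurrent`` plants one variant in
    two children of different families (count = number of such pairs).
    """
    plant_spec = dict(plant_spec or {"true_denovo": 20, "inherited": 40, "low_gq": 5})
    unknown = set(plant_spec) - set(SITE_CLASSES)
    if unknown:
        raise ValueError(f"unknown site classes: {sorted(unknown)}")
    if n_families < 2:
        raise ValueError("need >= 2 families (recurrence spans families)")
    rng = np.random.default_rng(seed)

    fam_ids = [f"FAM{i:03d}" for i in range(n_families)]
    samples = []
    ped_lines = []
    for fid in fam_ids:
        mo, fa, p1, s1 = (f"{fid}.{r}" for r in ("mother", "father", "proband", "sibling"))
        samples += [mo, fa, p1, s1]
        ped_lines += [
            f"{fid}\t{fa}\t0\t0\t1\t1",
            f"{fid}\t{mo}\t0\t0\t2\t1",
            f"{fid}\t{p1}\t{fa}\t{mo}\t1\t2",
            f"{fid}\t{s1}\t{fa}\t{mo}\t2\t1",
        ]

    n_sites = sum(plant_spec.values()) + plant_spec.get("recurrent", 0)
    gpos = np.sort(_unique_global_positions(rng, n_sites))
    chroms, positions = _split_global(gpos)

    GOOD = (60, 30)  # GQ, DP for clean calls
    rows = []  # (chrom, pos, ref, alt, info, genotypes dict sample->(gt,gq,dp))
    truth_rows = []
    excl_intervals = []
    maf_lookup: dict[tuple, float] = {}
    site_i = 0

    def next_site() -> tuple[str, int, str, str]:
        nonlocal site_i
        c, p = chroms[site_i], int(positions[site_i])
        site_i += 1
        ref, alt = rng.choice(len(BASES), size=2, replace=False)
        return c, p, BASES[ref], BASES[alt]

    def denovo_genotypes(fid: str, cohort: str, gq_dp_override=None):
        gts = {s: ("0/0", *GOOD) for s in samples}
        child = f"{fid}.{'proband' if cohort == 'proband' else 'sibling'}"
        gts[child] = ("0/1", *GOOD)
        if gq_dp_override:
            member, gq, dp = gq_dp_override
            gts[f"{fid}.{member}"] = (gts[f"{fid}.{member}"][0], gq, dp)
        return gts

    def add(cls_name, chrom, pos, ref, alt, fid, cohort, gts, info="AC=1;AF=0.00001"):
        rows.append((chrom, pos, ref, alt, info, gts))
        truth_rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "family_id": fid,
                "cohort": cohort,
                "site_class": cls_name,
                "expected_fate": SITE_CLASSES[cls_name],
            }
        )

    for cls_name, count in plant_spec.items():
        for _ in range(count):
            fid = fam_ids[int(rng.integers(0, n_families))]
            cohort = "proband" if rng.random() < 0.5 else "sibling"
            chrom, pos, ref, alt = next_site()
            if cls_name == "true_denovo":
                add(cls_name, chrom, pos, ref, alt, fid, cohort, denovo_genotypes(fid, cohort))
            elif cls_name == "inherited":
                gts = denovo_genotypes(fid, cohort)
                parent = "mother" if rng.random() < 0.5 else "father"
                gts[f"{fid}.{parent}"] = ("0/1", *GOOD)
                add(cls_name, chrom, pos, ref, alt, fid, cohort, gts, info="AC=2;AF=0.0002")
            elif cls_name == "low_gq":
                member = ("mother", "father", "proband", "sibling")[int(rng.integers(0, 4))]
                gts = denovo_genotypes(fid, cohort, (member, 19, GOOD[1]))
                add(cls_name, chrom, pos, ref, alt, fid, cohort, gts)
            elif cls_name == "low_dp":
                member = ("mother", "father", "proband", "sibling")[int(rng.integers(0, 4))]
                gts = denovo_genotypes(fid, cohort, (member, GOOD[0], 9))
                add(cls_name, chrom, pos, ref, alt, fid, cohort, gts)
            elif cls_name == "high_af":
                add(
                    cls_name, chrom, pos, ref, alt, fid, cohort,
                    denovo_genotypes(fid, cohort), info="AC=6;AF=0.002",
                )
            elif cls_name == "high_maf":
                add(cls_name, chrom, pos, ref, alt, fid, cohort, denovo_genotypes(fid, cohort))
                maf_lookup[(chrom, pos, ref, alt)] = 0.01
            elif cls_name == "excluded":
                add(cls_name, chrom, pos, ref, alt, fid, cohort, denovo_genotypes(fid, cohort))
                excl_intervals.append((chrom, pos - 1, pos))
            elif cls_name == "missing_gt":
                gts = denovo_genotypes(fid, cohort)
                gts[f"{fid}.father"] = ("./.", *GOOD)
                add(cls_name, chrom, pos, ref, alt, fid, cohort, gts)
            elif cls_name == "recurrent":
                fid2 = fam_ids[(fam_ids.index(fid) + 1) % n_families]
                cohort2 = "proband" if rng.random() < 0.5 else "sibling"
                # same variant key, two carriers -> two separate VCF rows is
                # wrong; one row with both children carrying it
                gts = {s: ("0/0", *GOOD) for s in samples}
                gts[f"{fid}.{'proband' if cohort == 'proband' else 'sibling'}"] = ("0/1", *GOOD)
                gts[f"{fid2}.{'proband' if cohort2 == 'proband' else 'sibling'}"] = ("0/1", *GOOD)
                rows.append((chrom, pos, ref, alt, "AC=2;AF=0.00002", gts))
                for f, co in ((fid, cohort), (fid2, cohort2)):
                    truth_rows.append(
                        {
                            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                            "family_id": f, "cohort": co,
                            "site_class": cls_name,
                            "expected_fate": SITE_CLASSES[cls_name],
                        }
                    )

    rows.sort(key=lambda r: (int(r[0]), r[1]))
    lines = [_VCF_HEADER]
    for i in range(1, N_CHROMS + 1):
        lines.append(f"##contig=<ID={i},length={CHROM_LEN}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
    for chrom, pos, ref, alt, info, gts in rows:
        cols = [chrom, str(pos), ".", ref, alt, "100", "PASS", info, "GT:GQ:DP"]
        cols += [f"{g}:{gq}:{dp}" for g, gq, dp in (gts[s] for s in samples)]
        lines.append("\t".join(cols) + "\n")

    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "pos", "ref", "alt", "family_id", "cohort", "site_class", "expected_fate"],
    )
    exclusion = IntervalSet.from_intervals("excluded_regions", excl_intervals)
    return QuadSimResult("".join(lines), "\n".join(ped_lines) + "\n", truth, exclusion, maf_lookup)


def simulate_multistudy_callsets(truth: CallSet, cfg: StudySimConfig) -> list[CallSet]:
    """Derive per-study call sets from a truth set.

    Each study independently misses each true variant with the false
    negative rate and adds ``round(fp_rate * |truth|)`` spurious novel
    variants. Spurious variants are never shared between studies — an
    explicit independence assumption mirroring the idea that study-unique
    calls are enriched for errors.
    """
    if len(truth) == 0:
        raise ValueError("truth call set is empty")
    rng = np.random.default_rng(cfg.seed)
    true_keys = sorted(truth.keys)
    used = {(k.chrom, k.pos) for k in true_keys}
    out = []
    for s in range(cfg.n_studies):
        keep = rng.random(len(true_keys)) >= cfg.false_negative_rate
        keys = {k for k, kp in zip(true_keys, keep) if kp}
        n_fp = int(round(cfg.false_positive_rate * len(true_keys)))
        while n_fp > 0:
            gpos = int(rng.integers(0, GENOME_LEN))
            chrom, pos = str(gpos // CHROM_LEN + 1), gpos % CHROM_LEN + 1
            if (chrom, pos) in used:
                continue
            used.add((chrom, pos))
            ref, alt = (BASES[i] for i in rng.choice(len(BASES), size=2, replace=False))
            keys.add(VariantKey(chrom, int(pos), ref, alt))
            n_fp -= 1
        out.append(CallSet(f"study{s + 1}", frozenset(keys), truth.identity_mode))
    return out
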