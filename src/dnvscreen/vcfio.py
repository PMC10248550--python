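"""Reading quad-family genotypes from VCF + PLINK PED files.

The pipeline consumes a multi-sample VCF that has already been through
genotype refinement and quality recalibration upstream; this module only
extracts, for every site and every quad family, the per-member genotype
(alt-allele count), GQ and DP, together with site-level AC/AF. Sites that
are not biallelic SNVs are flagged rather than silently dropped so the
filter stage can account for them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from dnvscreen.variants import BASES, normalize_chrom

logger = logging.getLogger(__name__)

ROLES = ("mother", "father", "proband", "sibling")


@dataclass(frozen=True)
class QuadFamily:
    family_id: str
    mother: str
    father: str
    proband: str
    sibling: str

    def sample_of(self, role: str) -> str:
        return getattr(self, role)

    @property
    def samples(self) -> tuple[str, str, str, str]:
        return (self.mother, self.father, self.proband, self.sibling)


@dataclass
class MemberCall:
    """One sample's call at one site; ``alt_count`` is None when missing."""

    alt_count: int | None
    gq: int | None
    dp: int | None


@dataclass
class SiteGenotypes:
    """All four members' calls at one site for one family."""

    chrom: str
    pos: int
    ref: str
    alt: str
    family_id: str
    members: dict[str, MemberCall] = field(default_factory=dict)
    ac: int = 0
    af: float = 0.0
    biallelic_snv: bool = True

    @property
    def complete(self) -> bool:
        return all(
            r in self.members and self.members[r].alt_count is not None for r in ROLES
        )

    def min_gq(self) -> int | None:
        vals = [m.gq for m in self.members.values()]
        return None if any(v is None for v in vals) else min(vals)

    def min_dp(self) -> int | None:
        vals = [m.dp for m in self.members.values()]
        return None if any(v is None for v in vals) else min(vals)


def parse_ped(path: str | Path) -> list[QuadFamily]:
    """Parse a PLINK pedigree file into quad families.

    Expects the six standard whitespace-separated columns
    (FID, IID, father, mother, sex, phenotype); affected status 2 marks the
    proband, 1 the unaffected sibling. Each family must contribute two
    parents plus exactly one proband and one sibling.
    """
    parents_of: dict[str, tuple[str, str, str, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 PED columns")
            fid, iid, pat, mat, _sex, pheno = fields[:6]
            if pat != "0" and mat != "0":
                parents_of[iid] = (fid, pat, mat, int(pheno))
    families: dict[str, dict[str, str]] = {}
    for iid, (fid, pat, mat, pheno) in parents_of.items():
        fam = families.setdefault(fid, {"father": pat, "mother": mat})
        if pheno == 2:
            role = "proband"
        elif pheno == 1:
            role = "sibling"
        else:
            raise ValueError(f"child {iid}: phenotype must be 1 or 2, got {pheno}")
        if role in fam:
            raise ValueError(f"family {fid}: more than one {role}")
        fam[role] = iid
    quads = []
    for fid, fam in sorted(families.items()):
        missing = [r for r in ("proband", "sibling") if r not in fam]
        if missing:
            raise ValueError(f"family {fid}: missing {', '.join(missing)} child")
        quads.append(
            QuadFamily(fid, fam["mother"], fam["father"], fam["proband"], fam["sibling"])
        )
    return quads


def _alt_count(gt: tuple | None) -> int | None:
    if gt is None or any(a is None for a in gt):
        return None
    return sum(1 for a in gt if a == 1)


def parse_vcf_minimal(
    vcf_path: str | Path, families: list[QuadFamily]
) -> tuple[list[SiteGenotypes], dict[str, int]]:
    """Extract per-family genotype records from a multi-sample VCF.

    Returns (records, tally) where tally counts dropped/flagged sites:
    ``non_autosomal``, ``non_biallelic_snv``. AC/AF are taken from INFO
    when present, otherwise computed from the genotypes of all samples in
    the file. A PED sample absent from the VCF is a hard error.
    """
    vcf = pysam.VariantFile(str(vcf_path))
    vcf_samples = set(vcf.header.samples)
    for fam in families:
        for sample in fam.samples:
            if sample not in vcf_samples:
                raise ValueError(f"sample {sample!r} (family {fam.family_id}) not in VCF")

    records: list[SiteGenotypes] = []
    tally = {"non_autosomal": 0, "non_biallelic_snv": 0}
    n_samples = len(vcf.header.samples)
    for rec in vcf:
        chrom = normalize_chrom(rec.chrom)
        if chrom is None:
            tally["non_autosomal"] += 1
            continue
        alts = rec.alts or ()
        biallelic_snv = (
            len(alts) == 1
            and rec.ref in BASES
            and alts[0] in BASES
        )
        if not biallelic_snv:
            tally["non_biallelic_snv"] += 1
        alt = alts[0] if alts else "N"
        ac = rec.info.get("AC")
        af = rec.info.get("AF")
        if isinstance(ac, tuple):
            ac = ac[0]
        if isinstance(af, tuple):
            af = af[0]
        if ac is None or af is None:
            counts = [_alt_count(s.get("GT")) for s in rec.samples.values()]
            ac = sum(c for c in counts if c is not None)
            n_called = sum(1 for c in counts if c is not None)
            af = ac / (2 * n_called) if n_called else 0.0
        for fam in families:
            members = {}
            for role in ROLES:
                try:
                    s = rec.samples[fam.sample_of(role)]
                except Exception as exc:  # malformed genotype entry
                    raise ValueError(
                        f"{vcf_path}: malformed genotype at {rec.chrom}:{rec.pos} "
                        f"sample {fam.sample_of(role)}"
                    ) from exc
                members[role] = MemberCall(
                    alt_count=_alt_count(s.get("GT")),
                    gq=s.get("GQ"),
                    dp=s.get("DP"),
                )
            records.append(
                SiteGenotypes(
                    chrom=chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=str(alt),
                    family_id=fam.family_id,
                    members=members,
                    ac=int(ac),
                    af=float(af),
                    biallelic_snv=biallelic_snv,
                )
            )
    if tally["non_autosomal"] or tally["non_biallelic_snv"]:
        logger.info(
            "dropped %d non-autosomal sites; flagged %d non-biallelic-SNV sites (%d samples)",
            tally["non_autosomal"], tally["non_biallelic_snv"], n_samples,
        )
    return records, tally
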