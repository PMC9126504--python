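"""Somatic and germline variant containers, readers, and hard filters.

Somatic calls arrive as a VCF plus a VEP-style tabular annotation companion
(columns CHROM, POS, REF, ALT, Feature, Consequence, SYMBOL, Protein_position,
Amino_acids, optionally DownstreamProtein for frameshifts). Somatic retention
requires a clean FILTER column, variant allele fraction strictly above 5% and
tumor depth strictly above 5 reads. Germline calls are hard-filtered on the
GATK site metrics QD/FS/MQ/SOR with class-specific thresholds (SNPs:
QD < 2.0, FS > 60.0, MQ < 40.0, SOR > 3.0; indels: QD < 2.0, FS > 200.0,
MQ < 40.0, SOR > 5.0 — a variant failing any one is removed).

Multi-allelic VCF records are split into biallelic variants before filtering,
so downstream identity matching is per-allele. Coordinates are 1-based (VCF
convention); protein positions are 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = (
    "CHROM",
    "POS",
    "REF",
    "ALT",
    "Feature",
    "Consequence",
    "SYMBOL",
    "Protein_position",
    "Amino_acids",
)

#: normalized consequence classes
MISSENSE = "missense"
INFRAME_INDEL = "inframe_indel"
FRAMESHIFT = "frameshift"
STOP_GAIN = "stop_gain"
OTHER = "other"

PROTEIN_ALTERING = frozenset({MISSENSE, INFRAME_INDEL, FRAMESHIFT})

_CONSEQUENCE_MAP = {
    "missense_variant": MISSENSE,
    "missense": MISSENSE,
    "inframe_insertion": INFRAME_INDEL,
    "inframe_deletion": INFRAME_INDEL,
    "inframe_indel": INFRAME_INDEL,
    "frameshift_variant": FRAMESHIFT,
    "frameshift": FRAMESHIFT,
    "stop_gained": STOP_GAIN,
    "stop_gain": STOP_GAIN,
}


def normalize_consequence(raw: str) -> str:
    """Map a VEP consequence term onto the internal five-class scheme.

    Compound terms (``"missense_variant&splice_region_variant"``) take the
    first recognized component. Unrecognized terms (synonymous, stop_loss,
    UTR, ...) become ``"other"`` and are excluded from epitope generation.
    """
    for part in str(raw).replace(",", "&").split("&"):
        hit = _CONSEQUENCE_MAP.get(part.strip())
        if hit is not None:
            return hit
    return OTHER


@dataclass(frozen=True, order=True)
class VariantIdentity:
    """What makes two variants 'the same antigen': the altered protein sequence.

    Equality is an exact match on gene symbol, protein position (string so
    indel ranges like ``"10-12"`` compare literally) and the REF/ALT amino
    acid string. Genomic coordinates deliberately do not participate.
    """

    gene: str
    protein_position: str
    amino_acids: str

    def __str__(self) -> str:
        return f"{self.gene}:{self.protein_position}:{self.amino_acids}"


@dataclass
class SomaticVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    filter_status: frozenset[str] = frozenset()
    vaf: float | None = None
    depth: int | None = None
    gene: str | None = None
    transcript: str | None = None
    consequence: str = OTHER
    protein_position: str | None = None
    amino_acids: str | None = None
    downstream_seq: str = ""

    def __post_init__(self) -> None:
        if self.vaf is not None and not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must be in [0,1], got {self.vaf}")
        if self.depth is not None and self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")
        self.protein_position = (
            None if self.protein_position is None else str(self.protein_position)
        )

    @property
    def identity(self) -> VariantIdentity | None:
        if self.gene is None or self.protein_position is None or self.amino_acids is None:
            return None
        return VariantIdentity(self.gene, self.protein_position, self.amino_acids)

    @property
    def is_protein_altering(self) -> bool:
        return self.consequence in PROTEIN_ALTERING


@dataclass
class GermlineVariant:
    locus_id: tuple[str, int, str, str]
    qd: float | None = None
    fs: float | None = None
    mq: float | None = None
    sor: float | None = None
    per_sample_genotype: dict[str, str] = field(default_factory=dict)
    gene: str | None = None
    transcript: str | None = None
    consequence: str = OTHER
    protein_position: str | None = None
    amino_acids: str | None = None
    downstream_seq: str = ""

    def __post_init__(self) -> None:
        self.protein_position = (
            None if self.protein_position is None else str(self.protein_position)
        )

    @property
    def variant_class(self) -> str:
        _, _, ref, alt = self.locus_id
        return "SNP" if len(ref) == 1 and len(alt) == 1 else "indel"

    @property
    def identity(self) -> VariantIdentity | None:
        if self.gene is None or self.protein_position is None or self.amino_acids is None:
            return None
        return VariantIdentity(self.gene, self.protein_position, self.amino_acids)

    @property
    def is_protein_altering(self) -> bool:
        return self.consequence in PROTEIN_ALTERING


@dataclass(frozen=True)
class GermlineFilterParams:
    """GATK-style hard-filter thresholds, per variant class."""

    snp_qd_min: float = 2.0
    snp_fs_max: float = 60.0
    snp_mq_min: float = 40.0
    snp_sor_max: float = 3.0
    indel_qd_min: float = 2.0
    indel_fs_max: float = 200.0
    indel_mq_min: float = 40.0
    indel_sor_max: float = 5.0

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")


def _load_annotation(annotation_path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(annotation_path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation file {annotation_path} lacks columns {missing}")
    return df


def _genotype_str(gt: tuple | None) -> str:
    if gt is None or any(a is None for a in gt):
        return "missing"
    alleles = sorted(int(a) for a in gt)
    return "/".join(str(a) for a in alleles)


def read_somatic(
    vcf_path: str | Path,
    annotation_path: str | Path,
    tumor_sample: str | None = None,
) -> list[SomaticVariant]:
    """Read a somatic VCF and its annotation companion into variants.

    One variant is produced per (VCF allele, annotation transcript row) pair;
    VCF records with no annotation row get consequence ``"other"`` (and are
    excluded later by :func:`select_protein_altering`). Annotation rows with
    no matching VCF record are skipped with a warning.

    VAF is taken as alt_depth / (ref_depth + alt_depth) from the tumor
    sample's AD field; depth is the sample DP (total depth), falling back to
    sum(AD).
    """
    ann = _load_annotation(annotation_path)
    has_downstream = "DownstreamProtein" in ann.columns
    ann_by_key: dict[tuple[str, str, str, str], list[dict]] = {}
    for row in ann.to_dict("records"):
        key = (row["CHROM"], row["POS"], row["REF"], row["ALT"])
        ann_by_key.setdefault(key, []).append(row)

    variants: list[SomaticVariant] = []
    seen_keys: set[tuple[str, str, str, str]] = set()
    with pysam.VariantFile(str(vcf_path)) as vf:
        samples = list(vf.header.samples)
        if tumor_sample is None:
            tumor_sample = samples[-1] if samples else None
        for rec in vf:
            filt = frozenset(rec.filter.keys()) or frozenset({"PASS"})
            for alt_index, alt in enumerate(rec.alts or ()):
                vaf, depth = _vaf_depth(rec, tumor_sample, alt_index)
                key = (rec.chrom, str(rec.pos), rec.ref, alt)
                seen_keys.add(key)
                rows = ann_by_key.get(key)
                base = SomaticVariant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    filter_status=filt,
                    vaf=vaf,
                    depth=depth,
                )
                if not rows:
                    variants.append(base)
                    continue
                for row in rows:
                    variants.append(
                        replace(
                            base,
                            gene=row["SYMBOL"] or None,
                            transcript=row["Feature"] or None,
                            consequence=normalize_consequence(row["Consequence"]),
                            protein_position=row["Protein_position"] or None,
                            amino_acids=row["Amino_acids"] or None,
                            downstream_seq=row["DownstreamProtein"] if has_downstream else "",
                        )
                    )
    orphans = set(ann_by_key) - seen_keys
    for key in sorted(orphans):
        logger.warning("annotation row %s has no matching VCF record; skipped", key)
    return variants


def _vaf_depth(rec, tumor_sample: str | None, alt_index: int) -> tuple[float | None, int | None]:
    if tumor_sample is None:
        return None, None
    try:
        sample = rec.samples[tumor_sample]
    except KeyError:
        return None, None
    ad = sample.get("AD")
    depth = sample.get("DP")
    vaf = None
    if ad is not None and None not in ad:
        ref_d = ad[0]
        alt_d = ad[alt_index + 1] if len(ad) > alt_index + 1 else None
        if alt_d is not None and (ref_d + alt_d) > 0:
            vaf = alt_d / (ref_d + alt_d)
        if depth is None:
            depth = sum(ad)
    return vaf, (None if depth is None else int(depth))


def filter_somatic(
    variants: Iterable[SomaticVariant],
    vaf_min: float = 0.05,
    depth_min: int = 5,
) -> list[SomaticVariant]:
    """Keep variants with a clean FILTER, VAF > vaf_min and depth > depth_min.

    All three predicates are strict: a VAF of exactly 5% or a depth of exactly
    5 reads fails. A record flagged by any caller filter is removed. Missing
    VAF or depth counts as failing (logged). Order is preserved.
    """
    kept: list[SomaticVariant] = []
    for v in variants:
        if not v.filter_status <= {"PASS"}:
            continue
        if v.vaf is None or v.depth is None:
            logger.info("variant %s:%d %s>%s lacks vaf/depth; removed", v.chrom, v.pos, v.ref, v.alt)
            continue
        if v.vaf > vaf_min and v.depth > depth_min:
            kept.append(v)
    return kept


def select_protein_altering(variants: Iterable[SomaticVariant]) -> list[SomaticVariant]:
    """Keep missense, in-frame indel and frameshift variants.

    Stop-gain (and everything normalized to "other", including stop-loss and
    synonymous calls) is dropped: a truncation produces no novel
    strong-binding sequence in this framework.
    """
    return [v for v in variants if v.is_protein_altering]


def filter_germline(
    variants: Iterable[GermlineVariant],
    params: GermlineFilterParams = GermlineFilterParams(),
) -> list[GermlineVariant]:
    """Apply class-specific QD/FS/MQ/SOR hard filters.

    A SNP is removed iff QD < 2.0 or FS > 60.0 or MQ < 40.0 or SOR > 3.0;
    an indel iff QD < 2.0 or FS > 200.0 or MQ < 40.0 or SOR > 5.0 (defaults).
    Boundary values survive (the inequalities are strict). A missing metric
    fails the variant (logged).
    """
    kept: list[GermlineVariant] = []
    for v in variants:
        metrics = (v.qd, v.fs, v.mq, v.sor)
        if any(m is None for m in metrics):
            logger.info("germline %s lacks QD/FS/MQ/SOR; removed", v.locus_id)
            continue
        if v.variant_class == "SNP":
            fails = (
                v.qd < params.snp_qd_min
                or v.fs > params.snp_fs_max
                or v.mq < params.snp_mq_min
                or v.sor > params.snp_sor_max
            )
        else:
            fails = (
                v.qd < params.indel_qd_min
                or v.fs > params.indel_fs_max
                or v.mq < params.indel_mq_min
                or v.sor > params.indel_sor_max
            )
        if not fails:
            kept.append(v)
    return kept


def read_germline(
    vcf_path: str | Path,
    annotation_path: str | Path | None = None,
) -> list[GermlineVariant]:
    """Read a multi-sample germline VCF (QD/FS/MQ/SOR in INFO, GT per sample).

    Protein annotations, when available, come from a companion TSV in the same
    format as the somatic annotation file. Only the first annotation row per
    site is used (germline panels here are one-transcript-per-locus).
    """
    ann_by_key: dict[tuple[str, str, str, str], dict] = {}
    has_downstream = False
    if annotation_path is not None:
        ann = _load_annotation(annotation_path)
        has_downstream = "DownstreamProtein" in ann.columns
        for row in ann.to_dict("records"):
            key = (row["CHROM"], row["POS"], row["REF"], row["ALT"])
            ann_by_key.setdefault(key, row)

    out: list[GermlineVariant] = []
    with pysam.VariantFile(str(vcf_path)) as vf:
        sample_names = list(vf.header.samples)
        for rec in vf:
            for alt in rec.alts or ():
                genotypes = {
                    name: _genotype_str(rec.samples[name].get("GT"))
                    for name in sample_names
                }
                info = rec.info
                gv = GermlineVariant(
                    locus_id=(rec.chrom, rec.pos, rec.ref, alt),
                    qd=_info_float(info, "QD"),
                    fs=_info_float(info, "FS"),
                    mq=_info_float(info, "MQ"),
                    sor=_info_float(info, "SOR"),
                    per_sample_genotype=genotypes,
                )
                row = ann_by_key.get((rec.chrom, str(rec.pos), rec.ref, alt))
                if row is not None:
                    gv.gene = row["SYMBOL"] or None
                    gv.transcript = row["Feature"] or None
                    gv.consequence = normalize_consequence(row["Consequence"])
                    gv.protein_position = row["Protein_position"] or None
                    gv.amino_acids = row["Amino_acids"] or None
                    gv.downstream_seq = row["DownstreamProtein"] if has_downstream else ""
                out.append(gv)
    return out


def _info_float(info: Mapping, key: str) -> float | None:
    try:
        value = info[key]
    except KeyError:
        return None
    if isinstance(value, (tuple, list)):
        value = value[0] if value else None
    return None if value is None else float(value)


def write_filtered_tsv(variants: Sequence[SomaticVariant], path: str | Path) -> None:
    """Dump filtered somatic variants as a TSV audit table."""
    rows = [
        {
            "CHROM": v.chrom,
            "POS": v.pos,
            "REF": v.ref,
            "ALT": v.alt,
            "Feature": v.transcript or "",
            "Consequence": v.consequence,
            "SYMBOL": v.gene or "",
            "Protein_position": v.protein_position or "",
            "Amino_acids": v.amino_acids or "",
            "vaf": "" if v.vaf is None else f"{v.vaf:.6g}",
            "depth": "" if v.depth is None else v.depth,
            "kept_reason": "pass_vaf_depth_filter",
        }
        for v in variants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
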