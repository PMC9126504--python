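"""Synthetic tumor cohorts with the statistical structure the trial analysis assumes.

Real inputs to this kind of analysis are cancer-type-matched patient cohorts
(somatic variants, germline genotypes, HLA class I types, expression); those
live behind controlled access. This module generates cohorts with the same
*structure* so every downstream stage is exercisable end to end:

* HLA haplotypes drawn per locus i.i.d. from an allele-frequency table
  (homozygosity allowed; linkage between loci is not modeled).
* Recurrent driver variants, each carried independently with a configured
  cohort prevalence (the BRAF V600E / KRAS G12D-G12V pattern).
* Private passenger variants, Poisson-distributed per tumor, missense by
  default with a configurable frameshift fraction.
* A biallelic, linkage-free germline polymorphism panel with genotypes drawn
  under Hardy-Weinberg from the population allele frequency.
* Zero-inflated log-normal FPKM expression per gene.

A single seeded pseudo-random stream is threaded through all draws in a
fixed, documented order (per patient: HLA, drivers, passengers, germline,
expression), so a (spec, seed) pair always yields a byte-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .binding_model import AMINO_ACIDS
from .hla import LOCI, HLAAllele, Haplotype
from .variant_io import (
    FRAMESHIFT,
    GermlineVariant,
    MISSENSE,
    SomaticVariant,
    filter_germline,
    filter_somatic,
    read_germline,
    read_somatic,
    select_protein_altering,
)

__all__ = [
    "HLAAllele",
    "Haplotype",
    "DriverSpec",
    "GermlinePanelLocus",
    "ExpressionModel",
    "CohortSpec",
    "PatientSample",
    "generate_hla",
    "generate_cohort",
    "load_cohort_spec",
    "write_cohort",
    "read_cohort",
]


class CohortSpecError(ValueError):
    """The cohort specification violates an invariant."""


@dataclass(frozen=True)
class DriverSpec:
    """A recurrent missense driver carried at a given cohort prevalence."""

    gene: str
    ref_aa: str
    position: int
    alt_aa: str
    prevalence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise CohortSpecError(f"prevalence must be in [0,1], got {self.prevalence}")

    @property
    def protein_change(self) -> tuple[str, int, str]:
        return (self.ref_aa, self.position, self.alt_aa)


@dataclass(frozen=True)
class GermlinePanelLocus:
    """One biallelic germline polymorphism with its protein annotation.

    Site-level quality metrics (QD/FS/MQ/SOR) are part of the panel so the
    germline hard filter is exercisable; the defaults pass all thresholds.
    """

    locus_id: tuple[str, int, str, str]
    frequency: float
    gene: str
    consequence: str = "missense_variant"
    protein_position: int = 1
    amino_acids: str = ""
    downstream_seq: str = ""
    qd: float = 20.0
    fs: float = 5.0
    mq: float = 60.0
    sor: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise CohortSpecError(f"allele frequency must be in [0,1], got {self.frequency}")


@dataclass(frozen=True)
class ExpressionModel:
    """Zero-inflated log-normal FPKM: zero with prob zero_fraction, else LogN."""

    log_mean: float
    log_sd: float
    zero_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.zero_fraction <= 1.0:
            raise CohortSpecError(f"zero_fraction must be in [0,1], got {self.zero_fraction}")
        if self.log_sd < 0:
            raise CohortSpecError(f"log_sd must be >= 0, got {self.log_sd}")


@dataclass
class CohortSpec:
    n_individuals: int
    hla_frequencies: dict[str, list[tuple[str, float]]]
    drivers: list[DriverSpec] = field(default_factory=list)
    passenger_rate: float = 0.0
    frameshift_fraction: float = 0.0
    somatic_fail_fraction: float = 0.0
    germline_panel: list[GermlinePanelLocus] = field(default_factory=list)
    expression_model: dict[str, ExpressionModel] = field(default_factory=dict)
    protein_db: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise CohortSpecError("n_individuals must be positive")
        if self.passenger_rate < 0:
            raise CohortSpecError("passenger_rate must be >= 0")
        for frac in (self.frameshift_fraction, self.somatic_fail_fraction):
            if not 0.0 <= frac <= 1.0:
                raise CohortSpecError(f"fractions must be in [0,1], got {frac}")
        for locus in LOCI:
            entries = self.hla_frequencies.get(locus)
            if not entries:
                raise CohortSpecError(f"empty HLA frequency table for locus {locus}")
            total = sum(f for _, f in entries)
            if abs(total - 1.0) > 1e-9:
                raise CohortSpecError(
                    f"locus {locus} frequencies sum to {total!r}, expected 1"
                )
            for name, _ in entries:
                allele = HLAAllele(name)
                if allele.locus != locus:
                    raise CohortSpecError(f"allele {name} listed under locus {locus}")
        for d in self.drivers:
            seq = self.protein_db.get(d.gene)
            if seq is None:
                raise CohortSpecError(f"driver gene {d.gene!r} not in protein_db")
            if not 1 <= d.position <= len(seq):
                raise CohortSpecError(
                    f"driver {d.gene} position {d.position} outside protein (len {len(seq)})"
                )
            if seq[d.position - 1] != d.ref_aa:
                raise CohortSpecError(
                    f"driver {d.gene} expects {d.ref_aa} at {d.position}, protein has "
                    f"{seq[d.position - 1]}"
                )
        for locus in self.germline_panel:
            if locus.gene not in self.protein_db:
                raise CohortSpecError(f"germline panel gene {locus.gene!r} not in protein_db")
        for gene in self.protein_db:
            if gene not in self.expression_model and "default" not in self.expression_model:
                raise CohortSpecError(
                    f"no expression model for gene {gene!r} and no 'default' entry"
                )

    def expression_for(self, gene: str) -> ExpressionModel:
        return self.expression_model.get(gene, self.expression_model["default"])


@dataclass
class PatientSample:
    """One tumor: HLA haplotype, somatic variants, germline genotypes, expression."""

    sample_id: str
    haplotype: Haplotype
    somatic_variants: list[SomaticVariant] = field(default_factory=list)
    germline_genotypes: dict[tuple[str, int, str, str], str] = field(default_factory=dict)
    expression: dict[str, float] = field(default_factory=dict)


def generate_hla(
    hla_frequencies: Mapping[str, Sequence[tuple[str, float]]],
    rng: np.random.Generator,
) -> Haplotype:
    """Two independent draws per locus (A, B, C order) from the frequency table."""
    alleles: list[HLAAllele] = []
    for locus in LOCI:
        entries = hla_frequencies.get(locus)
        if not entries:
            raise CohortSpecError(f"empty HLA frequency table for locus {locus}")
        names = [name for name, _ in entries]
        probs = np.asarray([f for _, f in entries], dtype=float)
        probs = probs / probs.sum()
        for _ in range(2):
            idx = int(rng.choice(len(names), p=probs))
            alleles.append(HLAAllele(names[idx]))
    return Haplotype(tuple(alleles))


def _gene_layout(protein_db: Mapping[str, str]) -> dict[str, tuple[str, int]]:
    """Deterministic fake genomic layout: each gene gets a 1 Mb slot on chr1."""
    return {
        gene: ("1", (i + 1) * 1_000_000)
        for i, gene in enumerate(sorted(protein_db))
    }


_ALT_NT = {"A": "C", "C": "G", "G": "T", "T": "A"}


def _draw_vaf_depth(rng: np.random.Generator) -> tuple[float, int]:
    depth = int(rng.integers(30, 200))
    floor_alt = int(0.05 * depth)
    target = rng.uniform(0.10, 0.60)
    alt_d = max(floor_alt + 1, int(round(target * depth)))
    return alt_d / depth, depth


def _somatic_failure(v: SomaticVariant, rng: np.random.Generator) -> SomaticVariant:
    """Mutate a clean variant so it fails exactly one somatic filter."""
    mode = int(rng.integers(3))
    if mode == 0:
        v.filter_status = frozenset({"clustered_events"})
    elif mode == 1:
        depth = v.depth or 100
        v.vaf = int(0.05 * depth) / depth  # <= 5%
    else:
        v.depth = int(rng.integers(0, 6))  # <= 5 reads
    return v


def _passenger(
    spec: CohortSpec,
    layout: Mapping[str, tuple[str, int]],
    genes: Sequence[str],
    rng: np.random.Generator,
) -> SomaticVariant:
    gene = genes[int(rng.integers(len(genes)))]
    seq = spec.protein_db[gene]
    position = int(rng.integers(1, len(seq) + 1))
    chrom, base = layout[gene]
    vaf, depth = _draw_vaf_depth(rng)
    if rng.random() < spec.frameshift_fraction:
        tail_len = int(rng.integers(15, 60))
        tail = "".join(rng.choice(list(AMINO_ACIDS), size=tail_len))
        ref_aa = seq[position - 1]
        return SomaticVariant(
            chrom=chrom,
            pos=base + 3 * position,
            ref="AT",
            alt="A",
            filter_status=frozenset({"PASS"}),
            vaf=vaf,
            depth=depth,
            gene=gene,
            transcript=f"TX_{gene}",
            consequence=FRAMESHIFT,
            protein_position=str(position),
            amino_acids=f"{ref_aa}/{tail[:6]}fs",
            downstream_seq=tail,
        )
    ref_aa = seq[position - 1]
    others = [aa for aa in AMINO_ACIDS if aa != ref_aa]
    alt_aa = others[int(rng.integers(len(others)))]
    return SomaticVariant(
        chrom=chrom,
        pos=base + 3 * position,
        ref="A",
        alt="CGT"[AMINO_ACIDS.index(alt_aa) % 3],
        filter_status=frozenset({"PASS"}),
        vaf=vaf,
        depth=depth,
        gene=gene,
        transcript=f"TX_{gene}",
        consequence=MISSENSE,
        protein_position=str(position),
        amino_acids=f"{ref_aa}/{alt_aa}",
    )


def generate_cohort(spec: CohortSpec, seed: int) -> list[PatientSample]:
    """Generate ``spec.n_individuals`` patient samples, reproducibly.

    Deterministic for a fixed (spec, seed). Per patient, draws happen in the
    order HLA, drivers, passengers, germline genotypes, expression, all from
    one :class:`numpy.random.Generator` seeded with ``seed``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    layout = _gene_layout(spec.protein_db)
    genes = sorted(spec.protein_db)
    samples: list[PatientSample] = []
    for i in range(spec.n_individuals):
        sample_id = f"S{i:05d}"
        haplotype = generate_hla(spec.hla_frequencies, rng)

        variants: list[SomaticVariant] = []
        used: set[tuple[int, str]] = set()
        for d in spec.drivers:
            if rng.random() < d.prevalence:
                chrom, base = layout[d.gene]
                vaf, depth = _draw_vaf_depth(rng)
                v = SomaticVariant(
                    chrom=chrom,
                    pos=base + 3 * d.position,
                    ref="A",
                    alt="CGT"[AMINO_ACIDS.index(d.alt_aa) % 3],
                    filter_status=frozenset({"PASS"}),
                    vaf=vaf,
                    depth=depth,
                    gene=d.gene,
                    transcript=f"TX_{d.gene}",
                    consequence=MISSENSE,
                    protein_position=str(d.position),
                    amino_acids=f"{d.ref_aa}/{d.alt_aa}",
                )
                variants.append(v)
                used.add((v.pos, v.alt))
        n_passengers = int(rng.poisson(spec.passenger_rate))
        for _ in range(n_passengers):
            v = _passenger(spec, layout, genes, rng)
            if (v.pos, v.alt) in used:  # collision with an existing variant
                continue
            used.add((v.pos, v.alt))
            variants.append(v)
        if spec.somatic_fail_fraction > 0:
            for v in variants:
                if rng.random() < spec.somatic_fail_fraction:
                    _somatic_failure(v, rng)

        genotypes: dict[tuple[str, int, str, str], str] = {}
        for locus in spec.germline_panel:
            q = locus.frequency
            u = rng.random()
            if u < q * q:
                gt = "1/1"
            elif u < q * q + 2 * q * (1 - q):
                gt = "0/1"
            else:
                gt = "0/0"
            genotypes[locus.locus_id] = gt

        expression: dict[str, float] = {}
        for gene in genes:
            model = spec.expression_for(gene)
            if rng.random() < model.zero_fraction:
                expression[gene] = 0.0
            else:
                expression[gene] = float(rng.lognormal(model.log_mean, model.log_sd))

        samples.append(
            PatientSample(
                sample_id=sample_id,
                haplotype=haplotype,
                somatic_variants=variants,
                germline_genotypes=genotypes,
                expression=expression,
            )
        )
    return samples


# ---------------------------------------------------------------------------
# config file
# ---------------------------------------------------------------------------

def load_cohort_spec(path: str | Path) -> CohortSpec:
    """Read a CohortSpec from YAML (keys named exactly as the dataclass fields).

    ``protein_db`` may be given inline (gene -> sequence) or via a
    ``protein_fasta`` path (relative paths resolve against the config file).
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    protein_db = dict(raw.get("protein_db") or {})
    if "protein_fasta" in raw:
        fasta = Path(raw["protein_fasta"])
        if not fasta.is_absolute():
            fasta = path.parent / fasta
        for rec in SeqIO.parse(str(fasta), "fasta"):
            protein_db[rec.id] = str(rec.seq)
    drivers = [
        DriverSpec(
            gene=d["gene"],
            ref_aa=d["protein_change"][0],
            position=int(d["protein_change"][1]),
            alt_aa=d["protein_change"][2],
            prevalence=float(d["prevalence"]),
        )
        for d in raw.get("drivers") or []
    ]
    panel = [
        GermlinePanelLocus(
            locus_id=(str(g["locus_id"][0]), int(g["locus_id"][1]), g["locus_id"][2], g["locus_id"][3]),
            frequency=float(g["frequency"]),
            gene=g["gene"],
            consequence=g.get("consequence", "missense_variant"),
            protein_position=int(g.get("protein_position", 1)),
            amino_acids=g.get("amino_acids", ""),
            downstream_seq=g.get("downstream_seq", ""),
            qd=float(g.get("qd", 20.0)),
            fs=float(g.get("fs", 5.0)),
            mq=float(g.get("mq", 60.0)),
            sor=float(g.get("sor", 1.0)),
        )
        for g in raw.get("germline_panel") or []
    ]
    expression = {
        gene: ExpressionModel(float(m[0]), float(m[1]), float(m[2]))
        for gene, m in (raw.get("expression_model") or {}).items()
    }
    hla = {
        locus: [(name, float(freq)) for name, freq in entries]
        for locus, entries in (raw.get("hla_frequencies") or {}).items()
    }
    spec = CohortSpec(
        n_individuals=int(raw["n_individuals"]),
        hla_frequencies=hla,
        drivers=drivers,
        passenger_rate=float(raw.get("passenger_rate", 0.0)),
        frameshift_fraction=float(raw.get("frameshift_fraction", 0.0)),
        somatic_fail_fraction=float(raw.get("somatic_fail_fraction", 0.0)),
        germline_panel=panel,
        expression_model=expression,
        protein_db=protein_db,
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# cohort serialization
# ---------------------------------------------------------------------------

_CONSEQUENCE_OUT = {
    MISSENSE: "missense_variant",
    FRAMESHIFT: "frameshift_variant",
    "inframe_indel": "inframe_insertion",
    "stop_gain": "stop_gained",
    "other": "synonymous_variant",
}


def _vcf_header(contigs: Mapping[str, int], samples: Sequence[str], germline: bool) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.filters.add("clustered_events", None, None, "Clustered somatic events")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if germline:
        for key in ("QD", "FS", "MQ", "SOR"):
            header.info.add(key, 1, "Float", f"{key} site metric")
    else:
        header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
        header.formats.add("DP", 1, "Integer", "Total read depth")
    for s in samples:
        header.add_sample(s)
    return header


def _contig_table(spec: CohortSpec) -> dict[str, int]:
    contigs = {"1": (len(spec.protein_db) + 2) * 1_000_000}
    for locus in spec.germline_panel:
        chrom = locus.locus_id[0]
        end = locus.locus_id[1] + 1000
        contigs[chrom] = max(contigs.get(chrom, 0), end)
    return contigs


def _annotation_row(v) -> dict:
    return {
        "CHROM": v.chrom if hasattr(v, "chrom") else v.locus_id[0],
        "POS": v.pos if hasattr(v, "pos") else v.locus_id[1],
        "REF": v.ref if hasattr(v, "ref") else v.locus_id[2],
        "ALT": v.alt if hasattr(v, "alt") else v.locus_id[3],
        "Feature": v.transcript or "",
        "Consequence": _CONSEQUENCE_OUT.get(v.consequence, v.consequence),
        "SYMBOL": v.gene or "",
        "Protein_position": v.protein_position or "",
        "Amino_acids": v.amino_acids or "",
        "DownstreamProtein": v.downstream_seq or "",
    }


def write_cohort(samples: Sequence[PatientSample], spec: CohortSpec, outdir: str | Path) -> Path:
    """Serialize a cohort to plain-text files.

    Layout: ``proteins.fasta``, ``hla_types.tsv``, per-sample
    ``somatic/<id>.vcf`` + ``somatic/<id>.annotation.tsv`` and
    ``expression/<id>.tsv``, plus a multi-sample ``germline.vcf`` with its
    ``germline.annotation.tsv``. Output is deterministic (sorted keys, no
    timestamps), so identical cohorts serialize byte-identically.
    """
    outdir = Path(outdir)
    (outdir / "somatic").mkdir(parents=True, exist_ok=True)
    (outdir / "expression").mkdir(parents=True, exist_ok=True)
    contigs = _contig_table(spec)

    records = [
        SeqRecord(Seq(seq), id=gene, description="")
        for gene, seq in sorted(spec.protein_db.items())
    ]
    SeqIO.write(records, str(outdir / "proteins.fasta"), "fasta")

    hla_rows = [
        {"sample_id": s.sample_id, **{f"allele{i+1}": a.name for i, a in enumerate(s.haplotype.alleles)}}
        for s in samples
    ]
    pd.DataFrame(hla_rows).to_csv(outdir / "hla_types.tsv", sep="\t", index=False)

    for s in samples:
        vcf_path = outdir / "somatic" / f"{s.sample_id}.vcf"
        header = _vcf_header(contigs, ["TUMOR"], germline=False)
        with pysam.VariantFile(str(vcf_path), "w", header=header) as vf:
            for v in sorted(s.somatic_variants, key=lambda v: (v.chrom, v.pos, v.alt)):
                rec = vf.new_record(
                    contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
                )
                for f in sorted(v.filter_status):
                    rec.filter.add(f)
                depth = v.depth if v.depth is not None else 0
                alt_d = int(round((v.vaf or 0.0) * depth))
                rec.samples["TUMOR"]["GT"] = (0, 1)
                rec.samples["TUMOR"]["AD"] = (depth - alt_d, alt_d)
                rec.samples["TUMOR"]["DP"] = depth
                vf.write(rec)
        ann = pd.DataFrame(
            [_annotation_row(v) for v in sorted(s.somatic_variants, key=lambda v: (v.chrom, v.pos, v.alt))],
            columns=["CHROM", "POS", "REF", "ALT", "Feature", "Consequence", "SYMBOL",
                     "Protein_position", "Amino_acids", "DownstreamProtein"],
        )
        ann.to_csv(outdir / "somatic" / f"{s.sample_id}.annotation.tsv", sep="\t", index=False)

        expr = pd.DataFrame(
            sorted(s.expression.items()), columns=["gene", "FPKM"]
        )
        expr.to_csv(outdir / "expression" / f"{s.sample_id}.tsv", sep="\t", index=False)

    if spec.germline_panel:
        sample_ids = [s.sample_id for s in samples]
        header = _vcf_header(contigs, sample_ids, germline=True)
        gt_map = {"0/0": (0, 0), "0/1": (0, 1), "1/1": (1, 1)}
        with pysam.VariantFile(str(outdir / "germline.vcf"), "w", header=header) as vf:
            for locus in sorted(spec.germline_panel, key=lambda l: l.locus_id):
                chrom, pos, ref, alt = locus.locus_id
                rec = vf.new_record(contig=chrom, start=pos - 1, alleles=(ref, alt))
                rec.info["QD"] = locus.qd
                rec.info["FS"] = locus.fs
                rec.info["MQ"] = locus.mq
                rec.info["SOR"] = locus.sor
                for s in samples:
                    gt = s.germline_genotypes.get(locus.locus_id, "0/0")
                    rec.samples[s.sample_id]["GT"] = gt_map[gt]
                vf.write(rec)
        rows = []
        for locus in sorted(spec.germline_panel, key=lambda l: l.locus_id):
            rows.append(
                {
                    "CHROM": locus.locus_id[0],
                    "POS": locus.locus_id[1],
                    "REF": locus.locus_id[2],
                    "ALT": locus.locus_id[3],
                    "Feature": f"TX_{locus.gene}",
                    "Consequence": locus.consequence,
                    "SYMBOL": locus.gene,
                    "Protein_position": locus.protein_position,
                    "Amino_acids": locus.amino_acids,
                    "DownstreamProtein": locus.downstream_seq,
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "germline.annotation.tsv", sep="\t", index=False)
    return outdir


def read_cohort(
    cohort_dir: str | Path,
    apply_filters: bool = True,
) -> tuple[list[PatientSample], dict[str, str], list[GermlineVariant]]:
    """Load a serialized cohort back into memory.

    With ``apply_filters`` (default) somatic variants pass through the
    FILTER/VAF/depth and protein-altering filters and germline variants
    through the QD/FS/MQ/SOR hard filter, so the result is trial-ready.
    Returns (samples, protein_db, germline_variants).
    """
    cohort_dir = Path(cohort_dir)
    protein_db = {
        rec.id: str(rec.seq)
        for rec in SeqIO.parse(str(cohort_dir / "proteins.fasta"), "fasta")
    }
    hla = pd.read_csv(cohort_dir / "hla_types.tsv", sep="\t", dtype=str)

    germline_variants: list[GermlineVariant] = []
    germline_vcf = cohort_dir / "germline.vcf"
    if germline_vcf.exists():
        germline_variants = read_germline(
            germline_vcf, cohort_dir / "germline.annotation.tsv"
        )
        if apply_filters:
            germline_variants = filter_germline(germline_variants)

    samples: list[PatientSample] = []
    for row in hla.to_dict("records"):
        sid = row["sample_id"]
        haplotype = Haplotype(
            tuple(HLAAllele(row[f"allele{i+1}"]) for i in range(6))
        )
        variants = read_somatic(
            cohort_dir / "somatic" / f"{sid}.vcf",
            cohort_dir / "somatic" / f"{sid}.annotation.tsv",
        )
        if apply_filters:
            variants = select_protein_altering(filter_somatic(variants))
        expr_df = pd.read_csv(cohort_dir / "expression" / f"{sid}.tsv", sep="\t")
        expression = dict(zip(expr_df["gene"], expr_df["FPKM"].astype(float)))
        genotypes = {
            gv.locus_id: gv.per_sample_genotype.get(sid, "missing")
            for gv in germline_variants
        }
        samples.append(
            PatientSample(
                sample_id=sid,
                haplotype=haplotype,
                somatic_variants=variants,
                germline_genotypes=genotypes,
                expression=expression,
            )
        )
    return samples, protein_db, germline_variants
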