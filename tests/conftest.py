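import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from allovax import (
    CohortSpec,
    DriverSpec,
    ExpressionModel,
    GermlinePanelLocus,
    Haplotype,
    HLAAllele,
    PatientSample,
    SomaticVariant,
)

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

AA = "ACDEFGHIKLMNPQRSTVWY"

# 30-aa toy proteins used throughout
PROTEIN_DB = {
    "GENEA": "MKTVLQRAGDSEWFYHCNIPMKTVLQRAGD",
    "GENEB": "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL",
    "TAA1": "MSLLTEVETPIRNEWGCRCNDSSDPLVVAA",
}


def make_haplotype(*names: str) -> Haplotype:
    return Haplotype(tuple(HLAAllele(n) for n in names))


HAPLO_1 = make_haplotype(
    "HLA-A*01:01", "HLA-A*02:01", "HLA-B*07:02", "HLA-B*08:01",
    "HLA-C*07:01", "HLA-C*07:02",
)
HAPLO_2 = make_haplotype(
    "HLA-A*03:01", "HLA-A*03:01", "HLA-B*15:01", "HLA-B*15:01",
    "HLA-C*04:01", "HLA-C*04:01",
)


def make_missense(gene: str, position: int, alt_aa: str, sample_suffix: int = 0) -> SomaticVariant:
    seq = PROTEIN_DB[gene]
    return SomaticVariant(
        chrom="1",
        pos=1000 * (1 + sorted(PROTEIN_DB).index(gene)) + 3 * position,
        ref="A",
        alt="C",
        filter_status=frozenset({"PASS"}),
        vaf=0.3,
        depth=100,
        gene=gene,
        transcript=f"TX_{gene}",
        consequence="missense",
        protein_position=str(position),
        amino_acids=f"{seq[position - 1]}/{alt_aa}",
    )


def make_patient(
    sample_id: str,
    haplotype: Haplotype = HAPLO_1,
    variants=(),
    genotypes=None,
    expression=None,
) -> PatientSample:
    return PatientSample(
        sample_id=sample_id,
        haplotype=haplotype,
        somatic_variants=list(variants),
        germline_genotypes=dict(genotypes or {}),
        expression=dict(expression or {"GENEA": 5.0, "GENEB": 1.0, "TAA1": 10.0}),
    )


class ConstantPredictor:
    """Plugin returning one IC50 for every (peptide, allele) pair."""

    def __init__(self, ic50: float = 100.0, name: str = "const"):
        self.ic50 = ic50
        self.name = name
        self.calls = 0

    def predict(self, peptide, allele):
        self.calls += 1
        return self.ic50


class PeptideSetPredictor:
    """Plugin strong (100 nM) only for listed (peptide, allele name) pairs."""

    def __init__(self, strong_pairs, name: str = "setpred"):
        self.strong_pairs = set(strong_pairs)
        self.name = name
        self.calls = 0

    def predict(self, peptide, allele):
        self.calls += 1
        return 100.0 if (peptide, allele.name) in self.strong_pairs else 50000.0


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cohort_spec() -> CohortSpec:
    """A cohort spec with every feature turned on, small enough for tests."""
    return CohortSpec(
        n_individuals=40,
        hla_frequencies={
            "A": [("HLA-A*01:01", 0.55), ("HLA-A*02:01", 0.45)],
            "B": [("HLA-B*07:02", 0.6), ("HLA-B*08:01", 0.4)],
            "C": [("HLA-C*07:01", 0.7), ("HLA-C*07:02", 0.3)],
        },
        drivers=[DriverSpec("GENEA", PROTEIN_DB["GENEA"][9], 10, "E", 0.4)],
        passenger_rate=3.0,
        frameshift_fraction=0.15,
        germline_panel=[
            GermlinePanelLocus(
                locus_id=("2", 5000 + 10 * i, "A", "G"),
                frequency=0.1 + 0.08 * i,
                gene="GENEB",
                protein_position=3 + 3 * i,
                amino_acids=f"{PROTEIN_DB['GENEB'][2 + 3 * i]}/{'RKDE'[i % 4]}",
            )
            for i in range(8)
        ],
        expression_model={
            "default": ExpressionModel(1.0, 1.0, 0.2),
            "TAA1": ExpressionModel(2.5, 0.5, 0.0),
        },
        protein_db=dict(PROTEIN_DB),
    )


# ---------------------------------------------------------------------------
# 12-record somatic filter fixture: 3 non-PASS, 2 low-VAF, 2 low-depth, 5 clean
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=10000000>
##FILTER=<ID=clustered_events,Description="Clustered events">
##FILTER=<ID=germline_risk,Description="Germline risk">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR
"""

# (pos, filter, ref_depth, alt_depth, dp) — designed pass/fail pattern
TWELVE_RECORDS = [
    (100, "PASS", 90, 10, 100),   # clean
    (200, "PASS", 80, 20, 100),   # clean
    (300, "PASS", 70, 30, 100),   # clean
    (400, "PASS", 60, 40, 100),   # clean
    (500, "PASS", 50, 50, 100),   # clean
    (600, "clustered_events", 50, 50, 100),  # non-PASS
    (700, "germline_risk", 50, 50, 100),     # non-PASS
    (800, "clustered_events;germline_risk", 50, 50, 100),  # non-PASS
    (900, "PASS", 95, 5, 100),    # VAF exactly 0.05 -> removed (strict >)
    (1000, "PASS", 97, 3, 100),   # VAF 0.03 -> removed
    (1100, "PASS", 4, 1, 5),      # depth exactly 5 -> removed (strict >)
    (1200, "PASS", 2, 1, 3),      # depth 3 -> removed
]
TWELVE_RECORD_SURVIVORS = 5


@pytest.fixture
def twelve_record_fixture(tmp_path):
    """Write the 12-record somatic VCF + annotation TSV; returns the paths."""
    lines = []
    for pos, filt, ref_d, alt_d, dp in TWELVE_RECORDS:
        lines.append(
            f"1\t{pos}\t.\tA\tC\t.\t{filt}\t.\tGT:AD:DP\t0/1:{ref_d},{alt_d}:{dp}"
        )
    vcf = tmp_path / "somatic.vcf"
    vcf.write_text(_VCF_HEADER + "\n".join(lines) + "\n")

    ann_lines = ["\t".join(
        ["CHROM", "POS", "REF", "ALT", "Feature", "Consequence", "SYMBOL",
         "Protein_position", "Amino_acids"]
    )]
    for i, (pos, *_rest) in enumerate(TWELVE_RECORDS, start=1):
        ref_aa = PROTEIN_DB["GENEA"][i - 1]
        ann_lines.append(
            f"1\t{pos}\tA\tC\tTX_GENEA\tmissense_variant\tGENEA\t{i}\t{ref_aa}/E"
        )
    ann = tmp_path / "somatic.annotation.tsv"
    ann.write_text("\n".join(ann_lines) + "\n")
    return vcf, ann
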