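"""Simulated allogeneic-vaccine trials: pooling, sharing, and antigen counts.

One trial draws 33 tumors without replacement from a cohort, designates a
random 3 as the pooled vaccine and the remaining 30 as hypothetical
patients, and quantifies per patient:

* **shared neoantigens** — somatic variant identities (exact altered
  amino-acid match) present in both vaccine pool and patient that yield at
  least one strong-binding peptide (median IC50 < 500 nM);
* **tumor-associated antigens (TAAs)** — strong-binding 9-mers from
  full-length TAA proteins, counted only when the patient expresses the gene
  above the median of its nonzero FPKM values, with overlapping strong
  binders collapsed;
* **alloantigens** — germline polymorphisms carried by at least one vaccine
  sample but absent from the patient, counted at the variant level with
  strong-binder tallies.

Each quantity is evaluated under two presentation models. *Lysate-based*:
vaccine material is cross-presented by the patient's own cells, so binding
is scored against the patient's HLA alleles. *Cell-based*: intact vaccine
cells present directly, so vaccine-cell HLA alleles constrain presentation;
for neoantigens and TAAs the cell-based sets are, by construction, subsets
of the lysate-based sets, while the two alloantigen tallies are independent.

The whole simulation is deterministic for a fixed (cohort, config): the
master seed spawns one child random stream per trial iteration, so results
do not depend on execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np

from .binding_model import BindingCache, Predictor, is_strong_binder
from .hla import Haplotype, HLAAllele
from .peptide_engine import (
    apply_protein_change,
    collapse_starts,
    epitope_windows,
    scan_protein,
)
from .synthetic_cohort import PatientSample
from .variant_io import GermlineVariant, VariantIdentity

logger = logging.getLogger(__name__)


class SharingMode(str, Enum):
    LYSATE = "lysate"
    CELL = "cell"


@dataclass(frozen=True)
class TrialConfig:
    """Every numeric rule of the analysis in one place."""

    n_total: int = 33
    n_vaccine: int = 3
    n_patients: int = 30
    n_iterations: int = 10
    ic50_threshold: float = 500.0
    vaf_min: float = 0.05
    depth_min: int = 5
    epitope_lengths: tuple[int, ...] = (9,)
    taa_length: int = 9
    collapse_min_shared: int = 4
    frameshift_limit: int = 500
    expression_percentile: float = 50.0
    seed: int = 0
    cell_mode_neoantigen_rule: str = "both_contexts"  # or "shared_allele"
    vaccine_hla_scope: str = "carriers_only"  # or "union"

    def __post_init__(self) -> None:
        if self.n_vaccine + self.n_patients != self.n_total:
            raise ValueError(
                f"n_vaccine + n_patients must equal n_total "
                f"({self.n_vaccine}+{self.n_patients} != {self.n_total})"
            )
        for name in ("ic50_threshold", "vaf_min", "depth_min", "taa_length",
                     "collapse_min_shared", "frameshift_limit"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cell_mode_neoantigen_rule not in ("both_contexts", "shared_allele"):
            raise ValueError(f"unknown cell_mode_neoantigen_rule {self.cell_mode_neoantigen_rule!r}")
        if self.vaccine_hla_scope not in ("carriers_only", "union"):
            raise ValueError(f"unknown vaccine_hla_scope {self.vaccine_hla_scope!r}")


@dataclass
class VaccinePool:
    """Three samples merged into one vaccine."""

    sample_ids: tuple[str, ...]
    variant_identities: frozenset[VariantIdentity]
    per_variant_carriers: dict[VariantIdentity, tuple[str, ...]]
    representative_variants: dict[VariantIdentity, object]
    haplotypes: dict[str, Haplotype]
    germline_alt_presence: dict[tuple, frozenset[str]]

    @property
    def hla_union(self) -> frozenset[HLAAllele]:
        out: set[HLAAllele] = set()
        for h in self.haplotypes.values():
            out |= h.allele_set
        return frozenset(out)

    def scope_alleles(self, identity: VariantIdentity, scope: str) -> frozenset[HLAAllele]:
        """Vaccine-side alleles relevant to an identity under a scope rule."""
        if scope == "union":
            return self.hla_union
        out: set[HLAAllele] = set()
        for sid in self.per_variant_carriers.get(identity, ()):
            out |= self.haplotypes[sid].allele_set
        return frozenset(out)


@dataclass
class PatientTrialResult:
    patient_id: str
    shared_neoantigens: dict[str, frozenset[VariantIdentity]]
    neoantigen_total: int = 0
    taa_count: dict[str, int] = field(default_factory=lambda: {"lysate": 0, "cell": 0})
    allo_pav_count: int = 0
    allo_strong_count: dict[str, int] = field(default_factory=lambda: {"lysate": 0, "cell": 0})


@dataclass
class TrialResult:
    iteration: int
    vaccine_sample_ids: tuple[str, ...]
    patients: list[PatientTrialResult]


class AntigenScorer:
    """Memoized bridge from variants and TAA genes to strong-binder calls.

    Caches, in increasing granularity: per-variant-identity epitope peptides,
    per (peptide, allele, algorithm) IC50s, per (identity, allele) and per
    (TAA gene, allele) strong-binder outcomes. The (variant, allele) cache is
    what makes repeated trials over one cohort cheap: common variants and
    alleles recur across patients and iterations.
    """

    def __init__(
        self,
        protein_db: Mapping[str, str],
        algorithms: Sequence[Predictor],
        config: TrialConfig,
        cache: BindingCache | None = None,
    ):
        self.protein_db = dict(protein_db)
        self.algorithms = list(algorithms)
        self.config = config
        self.cache = cache if cache is not None else BindingCache()
        self._peptides: dict[VariantIdentity, tuple[str, ...]] = {}
        self._variant_strong: dict[tuple[VariantIdentity, str], bool] = {}
        self._taa_starts: dict[tuple[str, str], frozenset[int]] = {}

    def _protein(self, gene: str) -> str:
        try:
            return self.protein_db[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} absent from the protein database") from None

    def variant_peptides(self, variant) -> tuple[str, ...]:
        identity = variant.identity
        if identity not in self._peptides:
            mut = apply_protein_change(
                self._protein(variant.gene), variant, self.config.frameshift_limit
            )
            peptides: dict[str, None] = {}
            for k in self.config.epitope_lengths:
                for w in epitope_windows(mut, k):
                    peptides[w.peptide] = None
            self._peptides[identity] = tuple(peptides)
        return self._peptides[identity]

    def strong_on_allele(self, variant, allele: HLAAllele) -> bool:
        key = (variant.identity, allele.name)
        if key not in self._variant_strong:
            threshold = self.config.ic50_threshold
            hit = False
            for peptide in self.variant_peptides(variant):
                m = self.cache.median(peptide, allele, self.algorithms)
                if m is not None and is_strong_binder(m, threshold):
                    hit = True
                    break
            self._variant_strong[key] = hit
        return self._variant_strong[key]

    def variant_strong(self, variant, alleles: Iterable[HLAAllele]) -> bool:
        return any(self.strong_on_allele(variant, a) for a in sorted(set(alleles)))

    def taa_strong_starts(self, gene: str, alleles: Iterable[HLAAllele]) -> list[int]:
        """Union of strong-binder 9-mer start positions over an allele set."""
        starts: set[int] = set()
        for allele in sorted(set(alleles)):
            key = (gene, allele.name)
            if key not in self._taa_starts:
                threshold = self.config.ic50_threshold
                hits = []
                for w in scan_protein(self._protein(gene), self.config.taa_length, gene):
                    m = self.cache.median(w.peptide, allele, self.algorithms)
                    if m is not None and is_strong_binder(m, threshold):
                        hits.append(w.start)
                self._taa_starts[key] = frozenset(hits)
            starts |= self._taa_starts[key]
        return sorted(starts)


def simulate_trial(
    cohort: Sequence[PatientSample],
    config: TrialConfig,
    rng: np.random.Generator,
) -> tuple[list[PatientSample], list[PatientSample]]:
    """Draw one trial: n_total distinct samples, randomly split 3 / 30.

    Sampling is without replacement within a trial; successive calls with
    the same generator give independent trials, so samples may recur across
    iterations.
    """
    if len(cohort) < config.n_total:
        raise ValueError(
            f"cohort of {len(cohort)} is smaller than n_total={config.n_total}"
        )
    chosen = rng.choice(len(cohort), size=config.n_total, replace=False)
    picked = [cohort[int(i)] for i in chosen]
    # the draw order of rng.choice is already uniformly random, so the first
    # n_vaccine of a permuted draw form a uniform random subset
    perm = rng.permutation(config.n_total)
    vaccine = [picked[int(i)] for i in perm[: config.n_vaccine]]
    patients = [picked[int(i)] for i in perm[config.n_vaccine :]]
    return vaccine, patients


def pool_vaccine(samples: Sequence[PatientSample]) -> VaccinePool:
    """Merge the vaccine samples' somatic variants into one deduplicated list.

    Assumes the samples' variants are already filtered (clean FILTER, VAF,
    depth, protein-altering). Records which samples carry each identity, the
    HLA haplotype of each sample, and which samples carry the alt allele at
    each germline locus.
    """
    identities: dict[VariantIdentity, list[str]] = {}
    representatives: dict[VariantIdentity, object] = {}
    germline: dict[tuple, set[str]] = {}
    for s in samples:
        seen_here: set[VariantIdentity] = set()
        for v in s.somatic_variants:
            identity = v.identity
            if identity is None or identity in seen_here:
                continue
            seen_here.add(identity)
            identities.setdefault(identity, []).append(s.sample_id)
            representatives.setdefault(identity, v)
        for locus_id, gt in s.germline_genotypes.items():
            if gt in ("0/1", "1/1"):
                germline.setdefault(locus_id, set()).add(s.sample_id)
    return VaccinePool(
        sample_ids=tuple(s.sample_id for s in samples),
        variant_identities=frozenset(identities),
        per_variant_carriers={k: tuple(v) for k, v in identities.items()},
        representative_variants=representatives,
        haplotypes={s.sample_id: s.haplotype for s in samples},
        germline_alt_presence={k: frozenset(v) for k, v in germline.items()},
    )


def count_neoantigens(patient: PatientSample, scorer: AntigenScorer) -> int:
    """Distinct variant identities with >=1 strong-binding peptide on >=1
    patient allele; multiple registers or lengths per variant count once."""
    alleles = patient.haplotype.allele_set
    strong: set[VariantIdentity] = set()
    for v in patient.somatic_variants:
        identity = v.identity
        if identity is None or identity in strong:
            continue
        if scorer.variant_strong(v, alleles):
            strong.add(identity)
    return len(strong)


def shared_neoantigens(
    pool: VaccinePool,
    patient: PatientSample,
    mode: SharingMode,
    scorer: AntigenScorer,
) -> frozenset[VariantIdentity]:
    """Variant identities shared between pool and patient that bind strongly.

    Lysate: the shared variant must produce a strong binder on at least one
    patient allele. Cell: additionally strong in the vaccine context —
    under ``both_contexts`` on at least one vaccine-scope allele, under
    ``shared_allele`` on at least one allele carried by both patient and
    vaccine scope. Either cell rule yields a subset of the lysate set.
    """
    cfg = scorer.config
    patient_vars = {v.identity: v for v in patient.somatic_variants if v.identity}
    p_alleles = patient.haplotype.allele_set
    out: set[VariantIdentity] = set()
    for identity in pool.variant_identities & set(patient_vars):
        v = patient_vars[identity]
        if not scorer.variant_strong(v, p_alleles):
            continue
        if mode == SharingMode.LYSATE:
            out.add(identity)
            continue
        scope = pool.scope_alleles(identity, cfg.vaccine_hla_scope)
        if cfg.cell_mode_neoantigen_rule == "both_contexts":
            if scorer.variant_strong(v, scope):
                out.add(identity)
        else:
            common = p_alleles & scope
            if common and scorer.variant_strong(v, common):
                out.add(identity)
    return frozenset(out)


def expression_gate(
    expression: Mapping[str, float],
    gene: str,
    percentile: float = 50.0,
) -> bool:
    """True iff the gene's FPKM exceeds the percentile of nonzero FPKMs.

    The default 50th percentile is the median of the nonzero multiset, and
    the comparison is strict ("expressed above"), so a gene sitting exactly
    on the median does not pass. An absent gene is not expressed (logged).
    """
    if not expression:
        raise ValueError("expression table is empty")
    value = expression.get(gene)
    if value is None:
        logger.info("gene %s absent from expression table; gated off", gene)
        return False
    nonzero = [x for x in expression.values() if x > 0]
    if not nonzero:
        return False
    if percentile == 50.0:
        cutoff = float(median(nonzero))
    else:
        cutoff = float(np.percentile(nonzero, percentile))
    return value > cutoff


def taa_count(
    taa_genes: Sequence[str],
    patient: PatientSample,
    pool: VaccinePool,
    mode: SharingMode,
    scorer: AntigenScorer,
) -> int:
    """Collapsed count of strong-binding TAA 9-mers the patient can present.

    Vaccine samples are assumed to express every TAA gene robustly; the
    patient must express the gene above the nonzero-median gate. Lysate mode
    scores against the patient's alleles; cell mode against alleles shared
    by patient and vaccine (HLA union over the three samples). Overlapping
    strong binders (>= 4 of 9 shared residues) count once.
    """
    cfg = scorer.config
    if mode == SharingMode.LYSATE:
        alleles: frozenset[HLAAllele] = patient.haplotype.allele_set
    else:
        alleles = patient.haplotype.allele_set & pool.hla_union
    total = 0
    for gene in taa_genes:
        if gene not in scorer.protein_db:
            raise KeyError(f"TAA gene {gene!r} absent from the protein database")
        if not expression_gate(patient.expression, gene, cfg.expression_percentile):
            continue
        if not alleles:
            continue
        starts = scorer.taa_strong_starts(gene, alleles)
        total += len(collapse_starts(starts, cfg.taa_length, cfg.collapse_min_shared))
    return total


def alloantigen_variants(
    pool: VaccinePool,
    patient: PatientSample,
    germline_variants: Sequence[GermlineVariant],
) -> list[GermlineVariant]:
    """Germline variants foreign to the patient but carried by the vaccine.

    A locus qualifies when at least one vaccine sample's genotype contains
    the alt allele (0/1 or 1/1) and the patient's genotype lacks it (0/0).
    A missing patient genotype skips the locus (logged).
    """
    out: list[GermlineVariant] = []
    for gv in germline_variants:
        carriers = pool.germline_alt_presence.get(gv.locus_id, frozenset())
        if not carriers:
            continue
        gt = patient.germline_genotypes.get(gv.locus_id, "missing")
        if gt == "missing":
            logger.info("patient %s has no genotype at %s; skipped", patient.sample_id, gv.locus_id)
            continue
        if gt == "0/0":
            out.append(gv)
    return out


@dataclass(frozen=True)
class AlloCounts:
    pav_count: int
    strong_lysate: int
    strong_cell: int


def allo_counts(
    allo_variants: Sequence[GermlineVariant],
    patient: PatientSample,
    pool: VaccinePool,
    scorer: AntigenScorer,
) -> AlloCounts:
    """Variant-level alloantigen tallies.

    ``pav_count`` is the number of distinct foreign protein-altering variant
    identities. ``strong_lysate`` counts those with a strong binder on a
    patient allele (cross-presentation); ``strong_cell`` those with a strong
    binder on a vaccine allele (direct presentation, HLA union over the
    vaccine samples). The two strong tallies are asymmetric by definition and
    are not nested.
    """
    p_alleles = patient.haplotype.allele_set
    v_alleles = pool.hla_union
    seen: set[VariantIdentity] = set()
    pav = strong_lys = strong_cell = 0
    for gv in allo_variants:
        identity = gv.identity
        if identity is None or not gv.is_protein_altering or identity in seen:
            continue
        seen.add(identity)
        pav += 1
        if scorer.variant_strong(gv, p_alleles):
            strong_lys += 1
        if scorer.variant_strong(gv, v_alleles):
            strong_cell += 1
    return AlloCounts(pav, strong_lys, strong_cell)


def run_trials(
    cohort: Sequence[PatientSample],
    config: TrialConfig,
    protein_db: Mapping[str, str],
    algorithms: Sequence[Predictor],
    germline_variants: Sequence[GermlineVariant] = (),
    taa_genes: Sequence[str] = (),
    scorer: AntigenScorer | None = None,
) -> list[TrialResult]:
    """Run ``config.n_iterations`` independent trials over one cohort.

    Each iteration draws from its own child stream of the master seed
    (spawned by iteration index), so results are reproducible and
    independent of execution order.
    """
    if scorer is None:
        scorer = AntigenScorer(protein_db, algorithms, config)
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(config.n_iterations)
    results: list[TrialResult] = []
    for iteration, child in enumerate(children):
        rng = np.random.default_rng(child)
        vaccine, patients = simulate_trial(cohort, config, rng)
        pool = pool_vaccine(vaccine)
        patient_results: list[PatientTrialResult] = []
        for patient in patients:
            shared = {
                SharingMode.LYSATE.value: shared_neoantigens(pool, patient, SharingMode.LYSATE, scorer),
                SharingMode.CELL.value: shared_neoantigens(pool, patient, SharingMode.CELL, scorer),
            }
            result = PatientTrialResult(
                patient_id=patient.sample_id,
                shared_neoantigens=shared,
                neoantigen_total=count_neoantigens(patient, scorer),
            )
            if taa_genes:
                result.taa_count = {
                    SharingMode.LYSATE.value: taa_count(taa_genes, patient, pool, SharingMode.LYSATE, scorer),
                    SharingMode.CELL.value: taa_count(taa_genes, patient, pool, SharingMode.CELL, scorer),
                }
            if germline_variants:
                foreign = alloantigen_variants(pool, patient, germline_variants)
                counts = allo_counts(foreign, patient, pool, scorer)
                result.allo_pav_count = counts.pav_count
                result.allo_strong_count = {
                    SharingMode.LYSATE.value: counts.strong_lysate,
                    SharingMode.CELL.value: counts.strong_cell,
                }
            patient_results.append(result)
        results.append(
            TrialResult(
                iteration=iteration,
                vaccine_sample_ids=pool.sample_ids,
                patients=patient_results,
            )
        )
    return results
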