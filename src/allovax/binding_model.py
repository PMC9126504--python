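"""Pluggable MHC class I binding prediction.

Real epitope pipelines run an ensemble of external binding predictors
(NetMHC-family networks, scoring matrices, ...) and aggregate them with the
median IC50 over the algorithms applicable to each peptide:HLA pair; a
peptide is a strong binder when that median is strictly below 500 nM. This
module implements those semantics behind a small plugin contract so any
external predictor can be adapted, and ships two deterministic predictors:

* :class:`LookupPredictor` — an explicit (peptide, allele) -> IC50 table,
  for exact tests and for wiring known answers into simulations.
* :class:`PositionWeightPredictor` — a per-allele anchor-residue weight
  matrix; the summed score s maps to IC50 = 50000 * exp(-s), clamped to
  [1, 50000] nM, so IC50 is strictly decreasing in s.

A peptide length an algorithm does not support yields "not applicable"
(``None``) and simply drops that algorithm from the median. Because antigen
analyses revisit the same peptide:allele pairs many times (common germline
polymorphisms recur across patients and simulated trials), predictions run
through a (peptide, allele, algorithm) cache.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median
from typing import Iterable, Mapping, Protocol, Sequence, runtime_checkable

import numpy as np

from .hla import HLAAllele

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

IC50_CEILING = 50000.0
IC50_FLOOR = 1.0
STRONG_BINDER_NM = 500.0


@runtime_checkable
class Predictor(Protocol):
    """Plugin contract: return IC50 in nM, or None when not applicable."""

    name: str

    def predict(self, peptide: str, allele: HLAAllele) -> float | None: ...


@dataclass(frozen=True)
class BindingPrediction:
    peptide: str
    allele: HLAAllele
    algorithm: str
    ic50: float | None

    def __post_init__(self) -> None:
        if self.ic50 is not None and self.ic50 <= 0:
            raise ValueError(f"ic50 must be positive, got {self.ic50}")


class LookupPredictor:
    """Table-backed predictor: exact (peptide, allele name) -> IC50 nM.

    Pairs absent from the table are not applicable. ``calls`` counts
    invocations so caching behavior is testable.
    """

    def __init__(self, table: Mapping[tuple[str, str], float], name: str = "lookup"):
        self.name = name
        self.table = dict(table)
        self.calls = 0

    def predict(self, peptide: str, allele: HLAAllele) -> float | None:
        self.calls += 1
        return self.table.get((peptide, allele.name))

    @classmethod
    def from_tsv(cls, path: str | Path, name: str = "lookup") -> "LookupPredictor":
        table: dict[tuple[str, str], float] = {}
        with open(path) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                table[(row["peptide"], row["allele"])] = float(row["ic50_nM"])
        return cls(table, name=name)


class PositionWeightPredictor:
    """Anchor-residue scoring: IC50 = 50000 * exp(-s), clamped to [1, 50000].

    ``weights`` maps allele name -> position (1-based) -> residue -> score.
    The total score s sums the matched weights over peptide positions, so a
    higher anchor score means a (strictly) lower IC50 until the floor.
    Peptides outside ``supported_lengths`` are not applicable; alleles
    without a weight table score 0 (ceiling IC50).
    """

    def __init__(
        self,
        weights: Mapping[str, Mapping[int, Mapping[str, float]]],
        name: str = "pwm",
        supported_lengths: Sequence[int] = (8, 9, 10, 11),
    ):
        self.name = name
        self.weights = {a: {int(p): dict(res) for p, res in tab.items()} for a, tab in weights.items()}
        self.supported_lengths = frozenset(supported_lengths)
        self.calls = 0

    def score(self, peptide: str, allele: HLAAllele) -> float:
        table = self.weights.get(allele.name, {})
        return sum(
            table.get(i, {}).get(aa, 0.0) for i, aa in enumerate(peptide, start=1)
        )

    def predict(self, peptide: str, allele: HLAAllele) -> float | None:
        self.calls += 1
        if len(peptide) not in self.supported_lengths:
            return None
        s = self.score(peptide, allele)
        return float(np.clip(IC50_CEILING * np.exp(-s), IC50_FLOOR, IC50_CEILING))


def toy_ensemble(
    alleles: Iterable[HLAAllele],
    n_algorithms: int = 3,
    seed: int = 0,
    anchor_positions: Sequence[int] = (2, 9),
) -> list[PositionWeightPredictor]:
    """Deterministic ensemble of position-weight predictors.

    Each allele gets one base anchor table shared by the ensemble, and each
    algorithm perturbs it with its own jitter — mirroring real binding
    predictors, which agree broadly but differ in detail, so the median over
    the ensemble is non-degenerate. Base weights are uniform on (0, 3) per
    residue at each anchor, putting roughly a tenth of random 9-mer:allele
    pairs below the 500 nM strong-binder line. Reproducible for a fixed
    (alleles, n_algorithms, seed).
    """
    rng = np.random.default_rng(seed)
    allele_list = sorted(set(alleles))
    base: dict[str, dict[int, dict[str, float]]] = {}
    for allele in allele_list:
        base[allele.name] = {
            pos: {aa: float(rng.uniform(0.0, 3.0)) for aa in AMINO_ACIDS}
            for pos in anchor_positions
        }
    out = []
    for i in range(n_algorithms):
        weights = {
            allele: {
                pos: {
                    aa: max(0.0, w + float(rng.normal(0.0, 0.35)))
                    for aa, w in tab.items()
                }
                for pos, tab in per_pos.items()
            }
            for allele, per_pos in base.items()
        }
        out.append(PositionWeightPredictor(weights, name=f"pwm{i}"))
    return out


def median_ic50(
    peptide: str,
    allele: HLAAllele,
    algorithms: Sequence[Predictor],
) -> float | None:
    """Median IC50 over the algorithms applicable to this peptide:HLA pair.

    An even count takes the mean of the two middle values. Returns None when
    no algorithm applies (the candidate is skipped upstream).
    """
    values = [v for alg in algorithms if (v := alg.predict(peptide, allele)) is not None]
    if not values:
        return None
    return float(median(values))


def is_strong_binder(ic50: float, threshold: float = STRONG_BINDER_NM) -> bool:
    """True iff IC50 is strictly below the threshold (exactly 500 nM is weak)."""
    return ic50 < threshold


class BindingCache:
    """(peptide, allele, algorithm) -> IC50 cache, persistable as a flat TSV."""

    def __init__(self) -> None:
        self._store: dict[tuple[str, str, str], float | None] = {}

    def __len__(self) -> int:
        return len(self._store)

    def predict(self, peptide: str, allele: HLAAllele, algorithm: Predictor) -> float | None:
        key = (peptide, allele.name, algorithm.name)
        if key not in self._store:
            self._store[key] = algorithm.predict(peptide, allele)
        return self._store[key]

    def median(self, peptide: str, allele: HLAAllele, algorithms: Sequence[Predictor]) -> float | None:
        values = [
            v
            for alg in algorithms
            if (v := self.predict(peptide, allele, alg)) is not None
        ]
        if not values:
            return None
        return float(median(values))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["peptide", "allele", "algorithm", "ic50_nM"])
            for (pep, allele, alg), ic50 in sorted(self._store.items()):
                writer.writerow([pep, allele, alg, "NA" if ic50 is None else f"{ic50:.6g}"])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BindingCache":
        cache = cls()
        with open(path) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                ic50 = None if row["ic50_nM"] == "NA" else float(row["ic50_nM"])
                cache._store[(row["peptide"], row["allele"], row["algorithm"])] = ic50
        return cache


def cached_batch_predict(
    pairs: Iterable[tuple[str, HLAAllele]],
    algorithms: Sequence[Predictor],
    cache: BindingCache | None = None,
) -> dict[tuple[str, str], float | None]:
    """Median IC50 for each unique (peptide, allele) pair, computed once.

    Repeated pairs are served from the cache, so each underlying algorithm is
    invoked at most once per unique pair; results are identical with the
    cache on or off.
    """
    cache = cache if cache is not None else BindingCache()
    out: dict[tuple[str, str], float | None] = {}
    for peptide, allele in pairs:
        key = (peptide, allele.name)
        if key not in out:
            out[key] = cache.median(peptide, allele, algorithms)
    return out


@dataclass
class EpitopeCandidate:
    """A peptide window scored against a set of alleles."""

    peptide: str
    per_allele_median_ic50: dict[HLAAllele, float] = field(default_factory=dict)

    @property
    def best_allele(self) -> HLAAllele | None:
        if not self.per_allele_median_ic50:
            return None
        return min(self.per_allele_median_ic50, key=lambda a: (self.per_allele_median_ic50[a], a.name))

    @property
    def best_ic50(self) -> float | None:
        if not self.per_allele_median_ic50:
            return None
        return min(self.per_allele_median_ic50.values())

    def is_strong(self, threshold: float = STRONG_BINDER_NM) -> bool:
        best = self.best_ic50
        return best is not None and is_strong_binder(best, threshold)


def evaluate_peptide(
    peptide: str,
    alleles: Iterable[HLAAllele],
    algorithms: Sequence[Predictor],
    cache: BindingCache | None = None,
) -> EpitopeCandidate:
    """Score one peptide against each allele (median over applicable algorithms)."""
    cache = cache if cache is not None else BindingCache()
    medians = {}
    for allele in sorted(set(alleles)):
        m = cache.median(peptide, allele, algorithms)
        if m is not None:
            medians[allele] = m
    return EpitopeCandidate(peptide, medians)
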