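"""Summary statistics and figure-ready tables for simulated trials.

Percentages follow the reporting convention of the analysis: one decimal,
round half up, with whole numbers rendered without the decimal ("6%" rather
than "6.0%"). Counts pool all iterations (one row per simulated patient).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import pandas as pd

from .trial_engine import TrialResult

MODES = ("lysate", "cell")


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half-up to ``decimals`` places (0.05 -> 0.1, unlike banker's)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def pct_with_any_shared(n_with: int, n_total: int) -> float:
    """Percent of patients with >=1 shared antigen, half-up to 1 decimal."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_with <= n_total:
        raise ValueError(f"n_with={n_with} outside [0, {n_total}]")
    return round_half_up(100.0 * n_with / n_total, 1)


def identity_fraction(identity_count: int, base: int) -> float:
    """Percent of shared antigens attributable to one identity (1 decimal)."""
    if base <= 0:
        raise ValueError("base must be positive")
    return round_half_up(100.0 * identity_count / base, 1)


def format_percent(value: float) -> str:
    """Render a percentage: '24.3%', but whole numbers as '6%'."""
    if value == int(value):
        return f"{int(value)}%"
    return f"{value}%"


@dataclass
class CohortSummary:
    """Pooled per-mode summary over all iterations of a simulated trial set."""

    n_patients_total: int
    n_with_any_shared: dict[str, int]
    pct_with_any_shared: dict[str, float]
    shared_identity_frequency: dict[str, dict[str, int]]
    count_distribution: dict[str, dict[int, int]]

    def total_shared_instances(self, mode: str) -> int:
        return sum(count * n for count, n in self.count_distribution[mode].items())

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_patients_total": self.n_patients_total,
            "n_with_any_shared": self.n_with_any_shared,
            "pct_with_any_shared": self.pct_with_any_shared,
            "shared_identity_frequency": {
                mode: dict(sorted(table.items())) for mode, table in self.shared_identity_frequency.items()
            },
            "count_distribution": {
                mode: {str(k): v for k, v in sorted(table.items())}
                for mode, table in self.count_distribution.items()
            },
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CohortSummary":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        raw = json.loads(text)
        return cls(
            n_patients_total=raw["n_patients_total"],
            n_with_any_shared=dict(raw["n_with_any_shared"]),
            pct_with_any_shared=dict(raw["pct_with_any_shared"]),
            shared_identity_frequency={
                mode: dict(table) for mode, table in raw["shared_identity_frequency"].items()
            },
            count_distribution={
                mode: {int(k): v for k, v in table.items()}
                for mode, table in raw["count_distribution"].items()
            },
        )


def summarize(results: Sequence[TrialResult]) -> CohortSummary:
    """Pool iterations into per-mode distributions and identity frequencies.

    Deterministic and invariant to iteration or patient order: patients are
    pooled, identity frequencies count patients (not peptide instances).
    """
    if not results:
        raise ValueError("no trial results to summarize")
    n_total = 0
    n_with = {mode: 0 for mode in MODES}
    identity_freq: dict[str, dict[str, int]] = {mode: {} for mode in MODES}
    distribution: dict[str, dict[int, int]] = {mode: {} for mode in MODES}
    for result in results:
        for patient in result.patients:
            n_total += 1
            for mode in MODES:
                shared = patient.shared_neoantigens.get(mode, frozenset())
                count = len(shared)
                distribution[mode][count] = distribution[mode].get(count, 0) + 1
                if count:
                    n_with[mode] += 1
                for identity in shared:
                    key = str(identity)
                    identity_freq[mode][key] = identity_freq[mode].get(key, 0) + 1
    return CohortSummary(
        n_patients_total=n_total,
        n_with_any_shared=n_with,
        pct_with_any_shared={m: pct_with_any_shared(n_with[m], n_total) for m in MODES},
        shared_identity_frequency=identity_freq,
        count_distribution=distribution,
    )


def results_to_table(results: Sequence[TrialResult]) -> pd.DataFrame:
    """One row per (iteration, patient): the per-patient TSV export."""
    rows = []
    for result in results:
        for p in result.patients:
            lys = p.shared_neoantigens.get("lysate", frozenset())
            cell = p.shared_neoantigens.get("cell", frozenset())
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "iteration": result.iteration,
                    "neo_total": p.neoantigen_total,
                    "shared_neo_lysate": len(lys),
                    "shared_neo_cell": len(cell),
                    "shared_identities": ";".join(sorted(str(i) for i in lys)),
                    "taa_lysate": p.taa_count.get("lysate", 0),
                    "taa_cell": p.taa_count.get("cell", 0),
                    "allo_pav": p.allo_pav_count,
                    "allo_lysate": p.allo_strong_count.get("lysate", 0),
                    "allo_cell": p.allo_strong_count.get("cell", 0),
                }
            )
    return pd.DataFrame(rows)


def write_identity_table(summary: CohortSummary, path: str | Path) -> None:
    """Identity-by-mode patient-count matrix (heatmap-ready long TSV)."""
    rows = []
    for mode in MODES:
        for identity, count in sorted(summary.shared_identity_frequency[mode].items()):
            rows.append({"mode": mode, "identity": identity, "n_patients": count})
    pd.DataFrame(rows, columns=["mode", "identity", "n_patients"]).to_csv(
        path, sep="\t", index=False
    )
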