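"""Mutant protein construction and epitope peptide enumeration.

Given a protein-altering variant and the reference protein, this module
builds the mutant sequence, enumerates candidate epitope k-mers that overlap
the altered residues (neoantigens), scans full-length proteins for every
possible 9-mer (tumor-associated antigens), and collapses runs of
overlapping strong binders so each antigenic region is counted once.

Conventions: sequences are uppercase one-letter amino acids, positions are
1-based, and frameshift products are truncated to fewer than 500 novel
residues downstream of the variant (configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .variant_io import FRAMESHIFT, INFRAME_INDEL, MISSENSE, VariantIdentity

logger = logging.getLogger(__name__)


class ProteinChangeError(ValueError):
    """The annotated protein change is inconsistent with the reference protein."""


@dataclass(frozen=True)
class MutantProtein:
    """A mutated protein sequence plus which residues are novel."""

    sequence: str
    altered_positions: frozenset[int]
    source_identity: VariantIdentity | None = None

    def __post_init__(self) -> None:
        bad = [p for p in self.altered_positions if not 1 <= p <= len(self.sequence)]
        if bad:
            raise ValueError(f"altered positions {bad} outside sequence of length {len(self.sequence)}")


@dataclass(frozen=True)
class PeptideWindow:
    """A k-mer cut from a source protein, 1-based start."""

    peptide: str
    start: int
    source: VariantIdentity | str | None = None


def _parse_position(protein_position: str) -> int:
    """Return the (start) protein position from a "12" or "10-12" annotation."""
    head = str(protein_position).split("-")[0]
    return int(head)


def apply_protein_change(
    protein: str,
    variant,
    frameshift_limit: int = 500,
) -> MutantProtein:
    """Build the mutant protein implied by a protein-altering variant.

    * missense: single substitution; altered = {position}.
    * in-frame indel (``Amino_acids`` like ``"K/KQL"`` or ``"KQL/K"``): the
      reference segment is replaced by the alternate segment; for insertions
      the altered set is the novel residues, for deletions it is the junction
      residue.
    * frameshift: the prefix up to position-1 plus the annotated downstream
      peptide, truncated so the novel tail is shorter than ``frameshift_limit``
      residues; every tail residue is altered.

    Raises :class:`ProteinChangeError` if the annotated reference amino acids
    disagree with the protein, or a frameshift lacks a downstream sequence.
    """
    pos = _parse_position(variant.protein_position)
    aa = variant.amino_acids or ""
    if variant.consequence == FRAMESHIFT:
        if not variant.downstream_seq:
            raise ProteinChangeError(
                f"frameshift at {variant.gene}:{pos} has no downstream sequence"
            )
        if not 1 <= pos <= len(protein):
            raise ProteinChangeError(f"position {pos} outside protein of length {len(protein)}")
        tail = variant.downstream_seq[: frameshift_limit - 1]
        seq = protein[: pos - 1] + tail
        altered = frozenset(range(pos, pos + len(tail)))
        return MutantProtein(seq, altered, variant.identity)

    if "/" not in aa:
        raise ProteinChangeError(f"cannot parse Amino_acids {aa!r} for {variant.gene}:{pos}")
    ref_part, alt_part = aa.split("/", 1)
    ref_part = "" if ref_part == "-" else ref_part
    alt_part = "" if alt_part == "-" else alt_part

    end = pos - 1 + len(ref_part)
    if end > len(protein) or pos < 1:
        raise ProteinChangeError(f"position {pos} outside protein of length {len(protein)}")
    observed = protein[pos - 1 : end]
    if observed != ref_part:
        raise ProteinChangeError(
            f"reference mismatch at {variant.gene}:{pos}: annotation says "
            f"{ref_part!r}, protein has {observed!r}"
        )

    seq = protein[: pos - 1] + alt_part + protein[end:]
    if variant.consequence == MISSENSE:
        altered = frozenset({pos})
    elif variant.consequence == INFRAME_INDEL:
        if len(alt_part) > len(ref_part):  # insertion: the inserted residues
            common = 0
            while (
                common < len(ref_part)
                and common < len(alt_part)
                and ref_part[common] == alt_part[common]
            ):
                common += 1
            altered = frozenset(range(pos + common, pos + len(alt_part)))
        else:  # deletion: the junction residue
            junction = min(max(pos, 1), len(seq)) if seq else 1
            altered = frozenset({junction}) if seq else frozenset()
    else:
        raise ProteinChangeError(
            f"consequence {variant.consequence!r} does not produce a mutant protein"
        )
    return MutantProtein(seq, altered, variant.identity)


def epitope_windows(mut: MutantProtein, length: int = 9) -> list[PeptideWindow]:
    """All k-mers of the mutant that contain at least one altered residue.

    Returned in N-to-C order. A sequence shorter than ``length`` yields an
    empty list (logged).
    """
    if not 8 <= length <= 11:
        raise ValueError(f"epitope length must be 8-11, got {length}")
    seq = mut.sequence
    if len(seq) < length:
        logger.info("mutant of length %d shorter than k=%d; no windows", len(seq), length)
        return []
    out = []
    for start in range(1, len(seq) - length + 2):
        span = range(start, start + length)
        if any(p in mut.altered_positions for p in span):
            out.append(PeptideWindow(seq[start - 1 : start - 1 + length], start, mut.source_identity))
    return out


def scan_protein(protein: str, length: int = 9, source: str | None = None) -> list[PeptideWindow]:
    """Every possible k-mer of a full-length protein, in N-to-C order."""
    if len(protein) < length:
        logger.info("protein of length %d shorter than k=%d; no windows", len(protein), length)
        return []
    return [
        PeptideWindow(protein[start - 1 : start - 1 + length], start, source)
        for start in range(1, len(protein) - length + 2)
    ]


def shared_residues(start_a: int, start_b: int, length: int) -> int:
    """Number of residues two equal-length windows share: max(0, k - |j - i|)."""
    return max(0, length - abs(start_b - start_a))


def collapse_starts(starts, length: int = 9, min_shared_residues: int = 4) -> list[int]:
    """Greedy left-to-right collapse of overlapping window start positions.

    A window is kept iff it shares fewer than ``min_shared_residues`` residues
    with the last kept window; 4 of 9 residues (44.4% > 44%) triggers a
    collapse under the defaults. Keeping the N-terminal-most window of each
    overlapping run is deterministic and, for this chain constraint, keeps
    the maximum possible number of windows.
    """
    kept: list[int] = []
    for start in sorted(starts):
        if not kept or shared_residues(kept[-1], start, length) < min_shared_residues:
            kept.append(start)
    return kept


def collapse_overlapping(
    strong_windows: list[PeptideWindow],
    length: int = 9,
    min_shared_residues: int = 4,
) -> list[PeptideWindow]:
    """Collapse overlapping strong-binder windows; returns the kept windows.

    All windows must come from the same protein and share one k (mixed
    lengths are an error). The kept count is ``len(result)``.
    """
    for w in strong_windows:
        if len(w.peptide) != length:
            raise ValueError(
                f"window {w.peptide!r} has length {len(w.peptide)}, expected {length}"
            )
    by_start = {w.start: w for w in strong_windows}
    kept_starts = collapse_starts(by_start.keys(), length, min_shared_residues)
    return [by_start[s] for s in kept_starts]
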