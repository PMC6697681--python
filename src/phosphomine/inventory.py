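"""Sequence deduplication and the Ppm fusion-architecture inventory.

After homolog retrieval, identical protein sequences (the same protein
deposited for many genomes) are collapsed to one representative. Each
non-redundant Ppm is then classified by its fused partner domains:
stand-alone, fused to the MobA-like NTP transferase (PF12804), fused to
the cytidylyltransferase-like domain (PF01467), fused to both ("triple"
fusion), or fused only to something else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .domains import DomainHit

__all__ = [
    "FusionCategory",
    "FusionClassification",
    "InventorySummary",
    "deduplicate_sequences",
    "classify_fusion",
    "summarize_inventory",
]

PPM_ACCESSION = "PF13714"
NTP_TRANSF_3 = "PF12804"
CTP_TRANSF_LIKE = "PF01467"


class FusionCategory(str, Enum):
    ALONE = "ALONE"
    NTP_TRANSF_3 = "NTP_TRANSF_3"
    CTP_TRANSF_LIKE = "CTP_TRANSF_LIKE"
    TRIPLE = "TRIPLE"
    OTHER = "OTHER"


@dataclass(frozen=True)
class FusionClassification:
    protein_id: str
    has_motif: bool
    category: FusionCategory
    partner_accessions: frozenset[str]


@dataclass(frozen=True)
class Deduplication:
    """Result of exact-sequence deduplication.

    ``representatives`` maps representative id -> sequence;
    ``duplicate_map`` maps every input id to its representative (identity
    for representatives themselves).
    """

    representatives: dict[str, str]
    duplicate_map: dict[str, str]

    @property
    def n_nonredundant(self) -> int:
        return len(self.representatives)


def deduplicate_sequences(proteins: Mapping[str, str]) -> Deduplication:
    """Collapse identical residue strings (case-insensitive exact match).

    The representative of each distinct sequence is the first-seen protein
    when ids are scanned in sorted order, which makes the choice
    deterministic regardless of input ordering. Empty sequences are
    rejected.
    """
    reps: dict[str, str] = {}
    by_seq: dict[str, str] = {}
    dup_map: dict[str, str] = {}
    for pid in sorted(proteins):
        seq = proteins[pid]
        if not seq:
            raise ValueError(f"empty sequence for protein {pid!r}")
        key = seq.upper()
        rep = by_seq.get(key)
        if rep is None:
            by_seq[key] = pid
            reps[pid] = seq
            rep = pid
        dup_map[pid] = rep
    return Deduplication(representatives=reps, duplicate_map=dup_map)


def classify_fusion(
    protein_id: str,
    resolved_hits: Sequence[DomainHit],
    has_motif: bool = True,
    *,
    ppm_accession: str = PPM_ACCESSION,
    named_partners_take_precedence: bool = True,
) -> FusionClassification:
    """Classify one Ppm protein's fusion architecture.

    ``resolved_hits`` must already be coverage/GA-filtered and
    overlap-resolved, and must include a hit to the Ppm family itself.
    Partner accessions are every non-Ppm accession among the hits. By
    default a protein carrying a named partner (PF12804/PF01467) plus an
    unrelated extra domain is binned by the named partner; with
    ``named_partners_take_precedence=False`` any unrelated extra forces
    OTHER.
    """
    accessions = {h.pfam_accession for h in resolved_hits if h.protein_id == protein_id}
    if ppm_accession not in accessions:
        raise ValueError(f"protein {protein_id!r} has no {ppm_accession} hit")
    partners = frozenset(accessions - {ppm_accession})
    named = partners & {NTP_TRANSF_3, CTP_TRANSF_LIKE}
    extras = partners - named
    if not partners:
        category = FusionCategory.ALONE
    elif named and (named_partners_take_precedence or not extras):
        if named == {NTP_TRANSF_3, CTP_TRANSF_LIKE}:
            category = FusionCategory.TRIPLE
        elif named == {NTP_TRANSF_3}:
            category = FusionCategory.NTP_TRANSF_3
        else:
            category = FusionCategory.CTP_TRANSF_LIKE
    else:
        category = FusionCategory.OTHER
    return FusionClassification(
        protein_id=protein_id,
        has_motif=has_motif,
        category=category,
        partner_accessions=partners,
    )


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero to ``decimals`` places (59.46 -> 59.5)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class InventorySummary:
    """Funnel counts and fusion-category shares of the Ppm inventory.

    Percentages use the motif-positive non-redundant Ppm count as
    denominator (the "all Ppm proteins" of the pie chart);
    ``pct_fused_nonredundant`` alone uses the pre-motif non-redundant
    count. When ``n_motif`` is 0 the percentage maps are empty (undefined,
    not zero).
    """

    n_total_pf13714: int
    n_nonredundant: int
    n_fused: int
    n_motif: int
    n_motif_fused: int
    per_category_counts: dict[str, int] = field(default_factory=dict)
    per_category_pct: dict[str, float] = field(default_factory=dict)
    per_category_pct_unrounded: dict[str, float] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        """Presumed non-Ppm sequences removed by the motif filter."""
        return self.n_nonredundant - self.n_motif

    @property
    def n_removed_fused(self) -> int:
        """Fusion proteins among the motif-removed sequences."""
        return self.n_fused - self.n_motif_fused

    @property
    def pct_fused_nonredundant(self) -> float | None:
        """Fused share of all non-redundant family matches (pre-motif)."""
        if self.n_nonredundant == 0:
            return None
        return round_half_up(100.0 * self.n_fused / self.n_nonredundant)

    @property
    def pct_motif_fused(self) -> float | None:
        """Fused share among motif-positive Ppm proteins."""
        if self.n_motif == 0:
            return None
        return round_half_up(100.0 * self.n_motif_fused / self.n_motif)

    @property
    def pct_motif_alone(self) -> float | None:
        """Stand-alone share among motif-positive Ppm proteins."""
        if self.n_motif == 0:
            return None
        return round_half_up(100.0 * (self.n_motif - self.n_motif_fused) / self.n_motif)

    def pct_of(self, count: int) -> float | None:
        """Share of ``count`` proteins among motif-positive Ppm, 1-decimal."""
        if self.n_motif == 0:
            return None
        return round_half_up(100.0 * count / self.n_motif)

    def to_dict(self) -> dict:
        d = {
            "n_total_pf13714": self.n_total_pf13714,
            "n_nonredundant": self.n_nonredundant,
            "n_fused": self.n_fused,
            "n_motif": self.n_motif,
            "n_motif_fused": self.n_motif_fused,
            "n_removed": self.n_removed,
            "n_removed_fused": self.n_removed_fused,
            "pct_fused_nonredundant": self.pct_fused_nonredundant,
            "pct_motif_fused": self.pct_motif_fused,
            "per_category_counts": dict(self.per_category_counts),
            "per_category_pct": dict(self.per_category_pct),
            "per_category_pct_unrounded": dict(self.per_category_pct_unrounded),
        }
        return d


def summarize_inventory(
    classifications: Iterable[FusionClassification],
    n_total_pf13714: int | None = None,
    n_nonredundant: int | None = None,
    n_fused: int | None = None,
) -> InventorySummary:
    """Aggregate per-protein classifications into the inventory summary.

    ``classifications`` covers the motif-positive, non-redundant Ppm
    proteins. The pre-motif funnel counts (total family matches,
    non-redundant count, fused count) are supplied by the caller because
    they are measured before the motif filter; they default to the values
    implied by the classification list alone.
    """
    cls = list(classifications)
    n_motif = len(cls)
    n_motif_fused = sum(1 for c in cls if c.category is not FusionCategory.ALONE)
    counts = {cat.value: 0 for cat in FusionCategory}
    for c in cls:
        counts[c.category.value] += 1
    pct: dict[str, float] = {}
    pct_raw: dict[str, float] = {}
    if n_motif > 0:
        for cat, n in counts.items():
            raw = 100.0 * n / n_motif
            pct_raw[cat] = raw
            pct[cat] = round_half_up(raw)
    return InventorySummary(
        n_total_pf13714=n_total_pf13714 if n_total_pf13714 is not None else n_motif,
        n_nonredundant=n_nonredundant if n_nonredundant is not None else n_motif,
        n_fused=n_fused if n_fused is not None else n_motif_fused,
        n_motif=n_motif,
        n_motif_fused=n_motif_fused,
        per_category_counts=counts,
        per_category_pct=pct,
        per_category_pct_unrounded=pct_raw,
    )
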