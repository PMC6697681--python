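"""Parsing and quality filtering of per-domain profile-HMM hits.

Consumes HMMER3 ``--domtblout`` tables (the per-domain tabular output of
``hmmscan``/``hmmsearch``) and applies the hit-quality rules used when
retrieving phosphoenolpyruvate mutase (Ppm, Pfam PF13714) and
nucleotidyltransferase homologs from genome databases:

* membership at the Pfam gathering (GA) threshold,
* >= 60% coverage of the HMM by the aligned region, and
* greedy highest-score resolution of overlapping domains on one protein.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "DomainHit",
    "parse_domtblout",
    "coverage",
    "filter_hits",
    "resolve_overlaps",
]

#: Number of whitespace-delimited fields in a domtblout row before the
#: free-text target description.
_N_FIXED_FIELDS = 22

_ACCESSION_RE = re.compile(r"^(PF\d{5})(\.\d+)?$")


@dataclass(frozen=True)
class DomainHit:
    """One per-domain match of a profile HMM against a protein.

    Coordinates are 1-based inclusive, following HMMER conventions:
    ``hmm_from``/``hmm_to`` index columns of the profile (of length
    ``model_length``) and ``ali_from``/``ali_to`` index residues of the
    protein. ``bit_score`` is the full-sequence score, ``domain_bit_score``
    the score of this domain alone. ``meets_ga`` records whether the hit
    passes the family's curated gathering threshold; searches run with
    ``--cut_ga`` emit only passing rows, so parsers default it to True
    unless an explicit GA table says otherwise.
    """

    protein_id: str
    pfam_accession: str
    model_length: int
    hmm_from: int
    hmm_to: int
    ali_from: int
    ali_to: int
    bit_score: float
    domain_bit_score: float
    evalue: float
    meets_ga: bool = True
    description: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.hmm_from <= self.hmm_to <= self.model_length):
            raise ValueError(
                f"invalid model coordinates {self.hmm_from}..{self.hmm_to} "
                f"for model of length {self.model_length}"
            )
        if not (1 <= self.ali_from <= self.ali_to):
            raise ValueError(
                f"invalid alignment coordinates {self.ali_from}..{self.ali_to}"
            )


class DomtbloutParseError(ValueError):
    """Raised for malformed domtblout rows; carries the 1-based line number."""


def strip_accession_version(accession: str) -> str:
    """Normalize a Pfam accession by dropping the trailing version (``PF13714.7``)."""
    m = _ACCESSION_RE.match(accession)
    return m.group(1) if m else accession


def parse_domtblout(
    text: str,
    *,
    ga_table: Mapping[str, float] | None = None,
) -> list[DomainHit]:
    """Parse HMMER3 per-domain tabular output into :class:`DomainHit` records.

    Expects the ``hmmscan --domtblout`` dialect: the *target* is the HMM
    (so column 3 is the model length) and the *query* is the protein.
    Lines starting with ``#`` are comments. Each data row must have at
    least 23 whitespace-delimited tokens; the 23rd onward is the free-text
    description, preserved verbatim.

    Parameters
    ----------
    text:
        Full table text.
    ga_table:
        Optional map from (version-stripped) Pfam accession to a gathering
        bit-score threshold applied to the full-sequence score. When absent
        every row is assumed to come from a GA-thresholded search and
        ``meets_ga`` is True.
    """
    hits: list[DomainHit] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split(None, _N_FIXED_FIELDS)
        if len(parts) < _N_FIXED_FIELDS + 1:
            raise DomtbloutParseError(
                f"line {lineno}: expected at least 23 fields, got {len(parts)}"
            )
        try:
            model_length = int(parts[2])
            evalue = float(parts[6])
            bit_score = float(parts[7])
            domain_bit_score = float(parts[13])
            hmm_from, hmm_to = int(parts[15]), int(parts[16])
            ali_from, ali_to = int(parts[17]), int(parts[18])
        except ValueError as exc:
            raise DomtbloutParseError(f"line {lineno}: {exc}") from exc
        accession = strip_accession_version(parts[1])
        meets_ga = True
        if ga_table is not None:
            threshold = ga_table.get(accession)
            meets_ga = threshold is None or bit_score >= threshold
        try:
            hit = DomainHit(
                protein_id=parts[3],
                pfam_accession=accession,
                model_length=model_length,
                hmm_from=hmm_from,
                hmm_to=hmm_to,
                ali_from=ali_from,
                ali_to=ali_to,
                bit_score=bit_score,
                domain_bit_score=domain_bit_score,
                evalue=evalue,
                meets_ga=meets_ga,
                description=parts[22].strip(),
            )
        except ValueError as exc:
            raise DomtbloutParseError(f"line {lineno}: {exc}") from exc
        hits.append(hit)
    return hits


def coverage(hit: DomainHit) -> float:
    """Fraction of the HMM covered by the aligned region.

    The denominator is the model length, not the protein length: the
    filtering rule demands alignment *to the HMM*.
    """
    return (hit.hmm_to - hit.hmm_from + 1) / hit.model_length


def filter_hits(
    hits: Iterable[DomainHit],
    min_coverage: float = 0.6,
    require_ga: bool = True,
) -> list[DomainHit]:
    """Keep hits with coverage >= ``min_coverage`` (inclusive) that pass GA.

    Order-stable and idempotent; the default 0.6 reproduces the ">= 60%
    alignment to the HMM" retrieval rule.
    """
    return [
        h
        for h in hits
        if coverage(h) >= min_coverage and (not require_ga or h.meets_ga)
    ]


def _overlap_length(a: DomainHit, b: DomainHit) -> int:
    return min(a.ali_to, b.ali_to) - max(a.ali_from, b.ali_from) + 1


def resolve_overlaps(
    hits: Sequence[DomainHit],
    max_overlap: int = 0,
) -> list[DomainHit]:
    """Resolve overlapping domains on one protein, best score first.

    Greedy selection by descending per-domain bit score (ties: smaller
    ``ali_from``, then input order): a hit is kept iff its protein-coordinate
    interval shares at most ``max_overlap`` residues with every hit already
    kept. With the default tolerance of 0 any shared residue is a conflict,
    so kept intervals are pairwise disjoint. Output preserves input order.
    """
    if not hits:
        return []
    protein_ids = {h.protein_id for h in hits}
    if len(protein_ids) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(protein_ids)}")
    order = sorted(
        range(len(hits)),
        key=lambda i: (-hits[i].domain_bit_score, hits[i].ali_from, i),
    )
    kept: list[int] = []
    for i in order:
        if all(_overlap_length(hits[i], hits[j]) <= max_overlap for j in kept):
            kept.append(i)
    return [hits[i] for i in sorted(kept)]


def resolve_overlaps_per_protein(
    hits: Iterable[DomainHit],
    max_overlap: int = 0,
) -> dict[str, list[DomainHit]]:
    """Group hits by protein and resolve overlaps within each group."""
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    return {
        pid: resolve_overlaps(group, max_overlap=max_overlap)
        for pid, group in by_protein.items()
    }
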