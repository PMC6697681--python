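"""Catalytic-motif scanning for phosphoenolpyruvate mutase (Ppm).

Ppm shares the isocitrate lyase fold (Pfam PF13714) with several enzymes
that do not form C-P bonds. Bona fide PEP mutases carry the conserved
catalytic motif EDKXXXXXNS; scanning for it separates true Ppm sequences
from other family members.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

__all__ = ["MotifMatch", "MotifSplit", "find_ppm_motif", "split_by_motif", "DEFAULT_MOTIF"]

#: Default pattern: anchors E,D,K then five arbitrary residues then N,S.
DEFAULT_MOTIF = "EDKx{5}NS"

# 20 standard residues; 'X' (ambiguous) is accepted in queries but only
# matches wildcard positions, never a literal anchor.
_STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_VALID_SEQ_RE = re.compile(f"^[{_STANDARD_AA}X]*$")
_PATTERN_TOKEN_RE = re.compile(f"([{_STANDARD_AA}])|x\\{{(\\d+)\\}}|x")


@dataclass(frozen=True)
class MotifMatch:
    """One motif occurrence: 1-based ``start`` of the first anchor residue."""

    protein_id: str
    start: int
    matched_span: str


@dataclass(frozen=True)
class MotifSplit:
    """Partition of candidate proteins into motif-positive and removed sets."""

    ppm_ids: tuple[str, ...]
    removed_ids: tuple[str, ...]

    @property
    def n_ppm(self) -> int:
        return len(self.ppm_ids)

    @property
    def n_removed(self) -> int:
        return len(self.removed_ids)


def compile_motif(pattern: str = DEFAULT_MOTIF) -> "re.Pattern[str]":
    """Compile a restricted motif pattern into an overlap-aware regex.

    The pattern language is: an uppercase letter is a literal anchor residue;
    ``x`` (optionally ``x{n}``) is a run of wildcard positions matching any
    residue including 'X'. Anchors intentionally do not match 'X' — an
    ambiguous residue must not create a motif call.
    """
    pos = 0
    body = []
    for m in _PATTERN_TOKEN_RE.finditer(pattern):
        if m.start() != pos:
            raise ValueError(f"unparseable motif pattern at {pattern[pos:]!r}")
        pos = m.end()
        if m.group(1):
            body.append(re.escape(m.group(1)))
        else:
            n = int(m.group(2)) if m.group(2) else 1
            body.append(f"[{_STANDARD_AA}X]{{{n}}}")
    if pos != len(pattern):
        raise ValueError(f"unparseable motif pattern at {pattern[pos:]!r}")
    # Lookahead so overlapping occurrences are all reported.
    return re.compile(f"(?=({''.join(body)}))")


_DEFAULT_COMPILED = compile_motif(DEFAULT_MOTIF)


def find_ppm_motif(
    sequence: str,
    protein_id: str = "",
    pattern: str = DEFAULT_MOTIF,
) -> list[MotifMatch]:
    """Return every (possibly overlapping) motif occurrence in ``sequence``.

    Raises ``ValueError`` on characters outside the 20-residue alphabet
    plus 'X'. Matching is case-insensitive; positions are 1-based.
    """
    seq = sequence.upper()
    if not _VALID_SEQ_RE.match(seq):
        bad = sorted(set(seq) - set(_STANDARD_AA + "X"))
        raise ValueError(f"non-amino-acid characters in sequence: {bad}")
    rx = _DEFAULT_COMPILED if pattern == DEFAULT_MOTIF else compile_motif(pattern)
    return [
        MotifMatch(protein_id=protein_id, start=m.start() + 1, matched_span=m.group(1))
        for m in rx.finditer(seq)
    ]


def split_by_motif(
    proteins: Mapping[str, str],
    pattern: str = DEFAULT_MOTIF,
) -> MotifSplit:
    """Partition PF13714-matching proteins by presence of the Ppm motif.

    ``proteins`` maps protein id to residue sequence; every entry is assumed
    to already carry a filter-surviving PF13714 hit. Motif-positive proteins
    are presumed genuine PEP mutases; the remainder are removed as other
    isocitrate-lyase-family members. Output order follows input order, so
    ``len(ppm_ids) + len(removed_ids) == len(proteins)``.
    """
    ppm: list[str] = []
    removed: list[str] = []
    for pid, seq in proteins.items():
        (ppm if find_ppm_motif(seq, pid, pattern) else removed).append(pid)
    return MotifSplit(ppm_ids=tuple(ppm), removed_ids=tuple(removed))
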