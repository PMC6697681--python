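"""Gene-neighborhood distances between *ppm* and nucleotidyltransferase genes.

Functionally related bacterial genes tend to cluster on the chromosome, so
the distance (in genes) between a PEP mutase gene and the nearest
nucleotidyltransferase gene measures their biosynthetic association. Genes
are indexed by their ordinal position along a replicon (ascending start
coordinate); distance is the absolute index difference, with 0 reserved for
domains fused within a single gene. Per genome only the single closest
ppm-nucleotidyltransferase pair is tabulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

__all__ = [
    "Role",
    "GeneLocus",
    "DistanceDistribution",
    "pair_distance",
    "nearest_distance_per_genome",
    "build_distribution",
]


class Role(str, Enum):
    PPM = "PPM"
    NTF = "NTF"


class DifferentRepliconsError(ValueError):
    """Distance between loci on different replicons is undefined, not 0."""


@dataclass(frozen=True)
class GeneLocus:
    """A gene's position in a genome plus its pipeline-assigned roles.

    ``gene_index`` is the 0-based ordinal along the replicon by ascending
    start coordinate. A fusion protein (Ppm with a nucleotidyltransferase
    domain on the same polypeptide) carries both roles.
    """

    genome_id: str
    replicon_id: str
    gene_index: int
    protein_id: str
    roles: frozenset[str]

    def has_role(self, role: Role) -> bool:
        return role.value in self.roles


def pair_distance(
    a: GeneLocus,
    b: GeneLocus,
    *,
    circular: bool = False,
    n_genes: int | None = None,
) -> int:
    """Gene-index distance between two loci on the same replicon.

    The same gene (a fusion) gives 0. On circular replicons (requires
    ``n_genes``) the shorter arc is used. Loci on different replicons raise
    :class:`DifferentRepliconsError`.
    """
    if a.replicon_id != b.replicon_id or a.genome_id != b.genome_id:
        raise DifferentRepliconsError(
            f"loci on different replicons: {a.replicon_id!r} vs {b.replicon_id!r}"
        )
    d = abs(a.gene_index - b.gene_index)
    if circular:
        if n_genes is None:
            raise ValueError("circular distance requires n_genes")
        d = min(d, n_genes - d)
    return d


def nearest_distance_per_genome(
    loci: Iterable[GeneLocus],
    *,
    circular: bool = False,
    replicon_sizes: dict[str, int] | None = None,
) -> tuple[str, int] | None:
    """Closest PPM-NTF gene distance in one genome, or None.

    Considers every PPM x NTF pair sharing a replicon; a locus carrying
    both roles is a fusion and immediately yields 0. Genomes lacking either
    role contribute no record. When multiple ppm or nucleotidyltransferase
    genes are present only the minimum distance is tabulated.
    """
    loci = list(loci)
    if not loci:
        return None
    genome_ids = {l.genome_id for l in loci}
    if len(genome_ids) > 1:
        raise ValueError(f"loci span multiple genomes: {sorted(genome_ids)}")
    genome_id = genome_ids.pop()
    best: int | None = None
    for locus in loci:
        if locus.has_role(Role.PPM) and locus.has_role(Role.NTF):
            return (genome_id, 0)
    ppm = [l for l in loci if l.has_role(Role.PPM)]
    ntf = [l for l in loci if l.has_role(Role.NTF)]
    for p in ppm:
        for n in ntf:
            if p.replicon_id != n.replicon_id:
                continue
            size = (replicon_sizes or {}).get(p.replicon_id)
            d = pair_distance(p, n, circular=circular, n_genes=size)
            if best is None or d < best:
                best = d
    return None if best is None else (genome_id, best)


@dataclass(frozen=True)
class DistanceDistribution:
    """Distribution of per-genome nearest ppm-nucleotidyltransferase distances."""

    records: tuple[tuple[str, int], ...]
    histogram: dict[int, int] = field(default_factory=dict)
    cumulative_fraction: dict[int, float] = field(default_factory=dict)

    @property
    def n_genomes(self) -> int:
        return len(self.records)

    @property
    def fraction_at_zero(self) -> float | None:
        if not self.records:
            return None
        return self.histogram.get(0, 0) / self.n_genomes

    def fraction_within(self, k: int) -> float | None:
        """Fraction of genomes whose nearest distance is <= k genes."""
        if not self.records:
            return None
        return sum(n for d, n in self.histogram.items() if d <= k) / self.n_genomes

    def log10_counts(self) -> dict[int, float]:
        return {d: math.log10(n) for d, n in sorted(self.histogram.items())}


def build_distribution(records: Iterable[tuple[str, int]]) -> DistanceDistribution:
    """Histogram + cumulative fraction over nearest-distance records."""
    recs = tuple(records)
    hist: dict[int, int] = {}
    for _, d in recs:
        if d < 0:
            raise ValueError(f"negative distance {d}")
        hist[d] = hist.get(d, 0) + 1
    cum: dict[int, float] = {}
    total = len(recs)
    running = 0
    for d in sorted(hist):
        running += hist[d]
        cum[d] = running / total
    return DistanceDistribution(records=recs, histogram=hist, cumulative_fraction=cum)
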