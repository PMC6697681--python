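"""Shared fixtures: random domain hits and a varied synthetic genome suite."""

from __future__ import annotations

import numpy as np
import pytest

from phosphomine.domains import DomainHit
from phosphomine.synthetic import (
    GenomeSpec,
    PlantedNtf,
    PlantedPpm,
    RepliconSpec,
    generate_suite,
)


def random_hit(rng: np.random.Generator, protein_id: str = "p1") -> DomainHit:
    model_length = int(rng.integers(50, 300))
    hmm_from = int(rng.integers(1, model_length))
    hmm_to = int(rng.integers(hmm_from, model_length + 1))
    ali_from = int(rng.integers(1, 400))
    ali_to = ali_from + int(rng.integers(0, 200))
    return DomainHit(
        protein_id=protein_id,
        pfam_accession=f"PF{int(rng.integers(0, 99999)):05d}",
        model_length=model_length,
        hmm_from=hmm_from,
        hmm_to=hmm_to,
        ali_from=ali_from,
        ali_to=ali_to,
        bit_score=float(rng.uniform(10, 300)),
        domain_bit_score=float(rng.uniform(10, 300)),
        evalue=float(10 ** rng.uniform(-60, -2)),
        meets_ga=bool(rng.random() < 0.8),
    )


@pytest.fixture
def hit_rng() -> np.random.Generator:
    return np.random.default_rng(20240817)


def make_suite_specs(seed: int = 11) -> list[GenomeSpec]:
    """20 genomes exercising every planted feature.

    Covers: each fusion category, motif-negative family members, a
    below-coverage-threshold negative control, separate
    nucleotidyltransferases at distances 1-6, exact duplicates, a
    two-replicon genome, and genomes lacking either gene role.
    """
    specs: list[GenomeSpec] = []
    P, N = PlantedPpm, PlantedNtf
    both = frozenset({"PF12804", "PF01467"})
    ntp = frozenset({"PF12804"})
    ctp = frozenset({"PF01467"})

    def g(i: int, replicons, ppm=(), ntf=(), dup=()) -> GenomeSpec:
        return GenomeSpec(
            genome_id=f"G{i:03d}",
            replicons=replicons,
            planted_ppm=tuple(ppm),
            planted_ntf_distances=tuple(ntf),
            duplicate_groups=tuple(dup),
            seed=seed * 1000 + i,
        )

    chr20 = (RepliconSpec("chr", 20),)
    specs.append(g(0, chr20, ppm=[P("chr", 5)]))                       # ALONE
    specs.append(g(1, chr20, ppm=[P("chr", 5, fusion_partners=ntp)]))  # NTP fusion
    specs.append(g(2, chr20, ppm=[P("chr", 5, fusion_partners=ctp)]))  # CTP fusion
    specs.append(g(3, chr20, ppm=[P("chr", 5, fusion_partners=both)])) # TRIPLE
    specs.append(g(4, chr20, ppm=[P("chr", 5, has_motif=False)]))      # motif-negative
    specs.append(g(5, chr20, ppm=[P("chr", 5, coverage=0.5)]))         # below 60% cov
    for i, d in enumerate((1, 2, 3, 4, 5, 6), start=6):                # distances 1..6
        specs.append(g(i, chr20, ppm=[P("chr", 8)], ntf=[N("chr", 8, d)]))
    # fused ppm plus a separate NTF two genes away: nearest must stay 0
    specs.append(g(12, chr20, ppm=[P("chr", 8, fusion_partners=ntp)],
                  ntf=[N("chr", 8, 2)]))
    # two ppm genes, identical sequences via a duplicate group
    specs.append(
        g(13, (RepliconSpec("chr", 25),),
          ppm=[P("chr", 3), P("chr", 15)],
          dup=[frozenset({"G013|chr|g00003", "G013|chr|g00015"})])
    )
    # two replicons; ppm and NTF on different replicons (no distance record)
    specs.append(
        g(14, (RepliconSpec("c1", 12), RepliconSpec("c2", 12)),
          ppm=[P("c1", 4)], ntf=[N("c1", 4, 0)])
    )
    specs.append(
        g(15, (RepliconSpec("c1", 12), RepliconSpec("c2", 12)),
          ppm=[P("c1", 4)])
    )
    # distance realized on the minus side (index would overflow on plus side)
    specs.append(g(16, chr20, ppm=[P("chr", 18)], ntf=[N("chr", 18, 5)]))
    # motif-negative but fused: still an NTF gene for its genome
    specs.append(g(17, chr20, ppm=[P("chr", 5, has_motif=False, fusion_partners=ctp),
                                   P("chr", 10)]))
    specs.append(g(18, chr20))                                         # background only
    specs.append(g(19, chr20, ppm=[P("chr", 2), P("chr", 9)],
                  ntf=[N("chr", 9, 4)]))
    return specs


@pytest.fixture(scope="session")
def synthetic_suite():
    return generate_suite(make_suite_specs())
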