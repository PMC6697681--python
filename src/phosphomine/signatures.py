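"""Genome dereplication by trinucleotide DNA signatures.

A genome's trinucleotide signature — the relative frequencies of the 64
overlapping 3-mers counted on both strands — is a coarse, alignment-free
compositional fingerprint that is far more similar within a species than
between species. Greedy leader clustering of signatures at a small distance
cutoff (delta = 0.03 on a x100-scaled mean absolute difference) reduces a
redundant genome collection to roughly one representative per species.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SignatureVector",
    "trinucleotide_signature",
    "signature_distance",
    "dereplicate",
    "TRINUCLEOTIDES",
]

#: The 64 trinucleotides in lexicographic order (AAA ... TTT).
TRINUCLEOTIDES: tuple[str, ...] = tuple(
    "".join(p) for p in product("ACGT", repeat=3)
)
_TRI_INDEX = {t: i for i, t in enumerate(TRINUCLEOTIDES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Base -> code; non-ACGT bases get a sentinel that poisons any window
# containing them.
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i


@dataclass(frozen=True)
class SignatureVector:
    """64-component trinucleotide relative-frequency vector of one genome.

    Frequencies sum to 1 and are invariant under reverse-complementing the
    input because both strands are counted.
    """

    genome_id: str
    freqs: np.ndarray
    total_length: int = 0

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", freqs)
        if freqs.shape != (64,):
            raise ValueError("signature must have 64 components")
        if np.any(freqs < 0) or abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("signature components must be a probability vector")


def _count_trinucleotides(seq: str, counts: np.ndarray) -> int:
    """Add overlapping 3-mer counts of ``seq`` into ``counts``; returns #windows."""
    if len(seq) < 3:
        return 0
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    a, b, c = codes[:-2], codes[1:-1], codes[2:]
    valid = (a >= 0) & (b >= 0) & (c >= 0)
    idx = (a[valid] * 16 + b[valid] * 4 + c[valid]).astype(np.int64)
    if idx.size:
        counts += np.bincount(idx, minlength=64)
    return int(idx.size)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def trinucleotide_signature(
    sequences: str | Sequence[str],
    genome_id: str = "",
) -> SignatureVector:
    """Both-strand trinucleotide signature of a genome.

    ``sequences`` is one nucleotide string or a list of replicon strings.
    Every overlapping 3-mer of each record and of its reverse complement is
    counted; windows containing a non-ACGT character are skipped. Raises
    ``ValueError`` if no valid window exists.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    counts = np.zeros(64, dtype=np.int64)
    n_windows = 0
    total_length = 0
    for seq in sequences:
        total_length += len(seq)
        n_windows += _count_trinucleotides(seq, counts)
        n_windows += _count_trinucleotides(reverse_complement(seq.upper()), counts)
    if n_windows == 0:
        raise ValueError("no valid trinucleotide window in input")
    return SignatureVector(
        genome_id=genome_id,
        freqs=counts / counts.sum(),
        total_length=total_length,
    )


def signature_distance(
    a: SignatureVector,
    b: SignatureVector,
    scale: float = 100.0,
) -> float:
    """Scaled mean absolute difference between two signatures.

    ``scale * mean_i |a_i - b_i|``; with the default x100 scaling the
    species-level cutoff is delta = 0.03.
    """
    return float(scale * np.mean(np.abs(a.freqs - b.freqs)))


def dereplicate(
    genomes: Iterable[SignatureVector],
    delta: float = 0.03,
    scale: float = 100.0,
) -> list[str]:
    """Greedy leader clustering: one representative genome per species-like group.

    Genomes are visited in order of descending total length, ties broken by
    genome_id; each joins the first existing representative within ``delta``
    (scaled distance), else founds a new one. Returns representative
    genome_ids in founding order; every non-representative is within
    ``delta`` of its representative by construction.
    """
    sigs = sorted(genomes, key=lambda s: (-s.total_length, s.genome_id))
    if not sigs:
        raise ValueError("no genomes to dereplicate")
    reps: list[SignatureVector] = []
    for sig in sigs:
        if not any(signature_distance(sig, r, scale) <= delta for r in reps):
            reps.append(sig)
    return [r.genome_id for r in reps]


def assign_to_representatives(
    genomes: Sequence[SignatureVector],
    delta: float = 0.03,
    scale: float = 100.0,
) -> dict[str, str]:
    """Map every genome_id to its representative under the greedy rule."""
    sigs = sorted(genomes, key=lambda s: (-s.total_length, s.genome_id))
    reps: list[SignatureVector] = []
    assignment: dict[str, str] = {}
    for sig in sigs:
        home = next(
            (r for r in reps if signature_distance(sig, r, scale) <= delta), None
        )
        if home is None:
            reps.append(sig)
            home = sig
        assignment[sig.genome_id] = home.genome_id
    return assignment
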