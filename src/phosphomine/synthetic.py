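"""Synthetic genomes with planted phosphonate-cluster ground truth.

Every downstream stage of the mining pipeline (hit filtering, motif
scanning, fusion inventory, gene-distance statistics, signature
dereplication, kinetics fitting) is testable against known truth by
generating genomes here instead of downloading a reference database. A
:class:`GenomeSpec` plants Ppm-like proteins with or without the catalytic
EDKXXXXXNS motif, fusion architectures (PF13714 alone, +PF12804, +PF01467,
or triple), separate nucleotidyltransferase genes at exact gene distances,
exact-duplicate protein sequences, and per-genome nucleotide composition.

Background protein sequences are i.i.d. uniform over the 20 amino acids, so
an accidental motif occurrence has probability on the order of (1/20)^5 per
window and the planted motif flags are effectively exact (the generator
additionally rejection-samples to make them exact). Nucleotide composition
is drawn per genome from a Dirichlet so that unrelated genomes carry
distinct trinucleotide signatures, as unrelated species do; point-mutated
copies of one genome emulate within-species replicates.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .inventory import FusionCategory, NTP_TRANSF_3, CTP_TRANSF_LIKE, PPM_ACCESSION
from .kinetics import substrate_inhibition_rate
from .motif import find_ppm_motif

__all__ = [
    "RepliconSpec",
    "PlantedPpm",
    "PlantedNtf",
    "GenomeSpec",
    "BundleTruth",
    "SyntheticBundle",
    "generate_bundle",
    "generate_suite",
    "mutate_genome",
    "random_genome_sequence",
    "generate_kinetic_dataset",
]

_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)
_NT = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Model lengths used for emitted profile-HMM hit rows.
MODEL_LENGTHS: dict[str, int] = {
    PPM_ACCESSION: 250,
    NTP_TRANSF_3: 180,
    CTP_TRANSF_LIKE: 160,
}

_GENE_SPAN = 1000          # bp of genome allocated per gene ordinal
_GENE_LEN = 900            # bp of annotated CDS per gene
_LINKER = 10               # residues between fused domain segments
_BACKGROUND_PROTEIN_LEN = 250


@dataclass(frozen=True)
class RepliconSpec:
    replicon_id: str
    n_genes: int
    circular: bool = False


@dataclass(frozen=True)
class PlantedPpm:
    """A Ppm-like gene to plant: motif status, fusion partners, hit coverage.

    ``fusion_partners`` is a subset of {PF12804, PF01467}. ``coverage`` sets
    the emitted PF13714 hit's model coverage; values below the 0.6 filter
    threshold create negative controls that the pipeline must drop.
    """

    replicon_id: str
    gene_index: int
    has_motif: bool = True
    fusion_partners: frozenset[str] = frozenset()
    coverage: float = 0.9

    def __post_init__(self) -> None:
        bad = set(self.fusion_partners) - {NTP_TRANSF_3, CTP_TRANSF_LIKE}
        if bad:
            raise ValueError(f"unsupported fusion partners: {sorted(bad)}")
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must be in (0, 1]")


@dataclass(frozen=True)
class PlantedNtf:
    """A nucleotidyltransferase planted at an exact gene distance from a Ppm.

    Distance 0 is realized as a fusion partner on the Ppm protein itself,
    never as a separate gene.
    """

    replicon_id: str
    ppm_gene_index: int
    distance: int
    accession: str = NTP_TRANSF_3

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be non-negative")
        if self.accession not in {NTP_TRANSF_3, CTP_TRANSF_LIKE}:
            raise ValueError(f"unsupported accession {self.accession!r}")


@dataclass(frozen=True)
class GenomeSpec:
    genome_id: str
    replicons: tuple[RepliconSpec, ...]
    planted_ppm: tuple[PlantedPpm, ...] = ()
    planted_ntf_distances: tuple[PlantedNtf, ...] = ()
    duplicate_groups: tuple[frozenset[str], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "replicons", tuple(self.replicons))
        object.__setattr__(self, "planted_ppm", tuple(self.planted_ppm))
        object.__setattr__(
            self, "planted_ntf_distances", tuple(self.planted_ntf_distances)
        )
        object.__setattr__(
            self,
            "duplicate_groups",
            tuple(frozenset(g) for g in self.duplicate_groups),
        )


@dataclass
class BundleTruth:
    """Exact description of everything planted in one emitted bundle."""

    genome_id: str
    ppm_proteins: dict[str, dict]          # pid -> has_motif/partners/category/coverage
    ntf_proteins: list[str]                # separate nucleotidyltransferase genes
    nearest_distance: int | None           # pipeline-visible nearest ppm<->NTF distance
    duplicate_map: dict[str, str]          # every protein -> representative
    n_proteins: int
    n_distinct_sequences: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class SyntheticBundle:
    proteins_fasta: str
    gene_table_gff3: str
    domain_hits_domtblout: str
    genome_fasta: str
    truth: BundleTruth


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return _AA[rng.integers(0, 20, size=length)].tobytes().decode("ascii")


def _protein_without_motif(rng: np.random.Generator, length: int) -> str:
    # Accidental motifs are ~(1/20)^5-rare; rejection makes the flag exact.
    while True:
        seq = _random_protein(rng, length)
        if not find_ppm_motif(seq):
            return seq


def _plant_motif(rng: np.random.Generator, seq: str, lo: int, hi: int) -> str:
    """Overwrite a seeded interior position in [lo, hi) with the Ppm motif."""
    pos = int(rng.integers(lo, hi - 10))
    motif = "EDK" + _random_protein(rng, 5) + "NS"
    return seq[:pos] + motif + seq[pos + 10 :]


def random_genome_sequence(
    length: int,
    seed: int,
    base_probs: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Random nucleotide sequence; composition drawn from a Dirichlet if unset."""
    if rng is None:
        rng = np.random.default_rng(seed)
    if base_probs is None:
        base_probs = rng.dirichlet([10.0, 10.0, 10.0, 10.0])
    p = np.asarray(base_probs, dtype=float)
    p = p / p.sum()
    return _NT[rng.choice(4, size=length, p=p)].tobytes().decode("ascii")


def mutate_genome(genome_seq: str, substitution_rate: float, seed: int) -> str:
    """Independently substitute each position with the given probability.

    Substitutions are drawn from the three bases other than the original, so
    rate 1 changes every position. Length is preserved; non-ACGT input is
    rejected.
    """
    if not 0 <= substitution_rate <= 1:
        raise ValueError("substitution rate must be in [0, 1]")
    arr = np.frombuffer(genome_seq.encode("ascii"), dtype=np.uint8).copy()
    if not np.isin(arr, _NT).all():
        raise ValueError("genome sequence contains non-ACGT characters")
    rng = np.random.default_rng(seed)
    mask = rng.random(arr.size) < substitution_rate
    n = int(mask.sum())
    if n:
        # index of each base in ACGT, shifted by 1..3 mod 4: never the original
        idx = np.searchsorted(_NT, arr[mask])
        arr[mask] = _NT[(idx + rng.integers(1, 4, size=n)) % 4]
    return arr.tobytes().decode("ascii")


def _category_for(partners: frozenset[str]) -> str:
    if not partners:
        return FusionCategory.ALONE.value
    if partners == {NTP_TRANSF_3, CTP_TRANSF_LIKE}:
        return FusionCategory.TRIPLE.value
    if partners == {NTP_TRANSF_3}:
        return FusionCategory.NTP_TRANSF_3.value
    return FusionCategory.CTP_TRANSF_LIKE.value


def _domtblout_row(
    model_name: str,
    accession: str,
    model_length: int,
    protein_id: str,
    protein_len: int,
    score: float,
    hmm_from: int,
    hmm_to: int,
    ali_from: int,
    ali_to: int,
    dom_idx: int,
    n_dom: int,
) -> str:
    evalue = 10.0 ** -(score / 4.0)
    fields = [
        model_name, f"{accession}.1", str(model_length),
        protein_id, "-", str(protein_len),
        f"{evalue:.1e}", f"{score:.1f}", "0.1",
        str(dom_idx), str(n_dom),
        f"{evalue:.1e}", f"{evalue:.1e}", f"{score:.1f}", "0.1",
        str(hmm_from), str(hmm_to),
        str(ali_from), str(ali_to),
        str(max(1, ali_from - 2)), str(ali_to + 2),
        "0.95", "synthetic planted domain",
    ]
    return " ".join(fields)


def _nearest_planted_distance(
    spec: GenomeSpec,
    partners_by_locus: Mapping[tuple[str, int], frozenset[str]],
    ntf_positions: Sequence[tuple[str, int]],
) -> int | None:
    """Closest pipeline-visible ppm<->NTF distance implied by the plant layout."""
    sizes = {r.replicon_id: r.n_genes for r in spec.replicons}
    circ = {r.replicon_id: r.circular for r in spec.replicons}
    # PPM role survives the pipeline only with the motif and >= 60% coverage.
    ppm_loci = [
        (p.replicon_id, p.gene_index)
        for p in spec.planted_ppm
        if p.has_motif and p.coverage >= 0.6
    ]
    # NTF role: separate planted genes plus any fused Ppm (motif or not).
    ntf_loci = list(ntf_positions) + [
        loc for loc, partners in partners_by_locus.items() if partners
    ]
    best: int | None = None
    for rep_p, i in ppm_loci:
        for rep_n, j in ntf_loci:
            if rep_p != rep_n:
                continue
            d = abs(i - j)
            if circ[rep_p]:
                d = min(d, sizes[rep_p] - d)
            if best is None or d < best:
                best = d
    return best


def generate_bundle(spec: GenomeSpec) -> SyntheticBundle:
    """Emit FASTA/GFF3/domtblout text realizing ``spec`` exactly, with truth.

    One protein per gene; Ppm-like proteins contain the literal motif iff
    ``has_motif``; the hit table carries a PF13714 row per planted Ppm at
    its requested model coverage plus one row per fusion partner on
    non-overlapping alignment coordinates; planted gene distances are
    realized exactly. Index collisions between planted genes are rejected.
    Generation is deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = {r.replicon_id: r.n_genes for r in spec.replicons}
    if len(sizes) != len(spec.replicons):
        raise ValueError("duplicate replicon ids")

    # --- validate planted ppm loci and fold distance-0 plants into fusions
    partners_by_locus: dict[tuple[str, int], frozenset[str]] = {}
    ppm_by_locus: dict[tuple[str, int], PlantedPpm] = {}
    for p in spec.planted_ppm:
        if p.replicon_id not in sizes:
            raise ValueError(f"unknown replicon {p.replicon_id!r}")
        if not 0 <= p.gene_index < sizes[p.replicon_id]:
            raise ValueError(f"gene index {p.gene_index} out of range")
        loc = (p.replicon_id, p.gene_index)
        if loc in ppm_by_locus:
            raise ValueError(f"two planted genes collide at {loc}")
        ppm_by_locus[loc] = p
        partners_by_locus[loc] = p.fusion_partners

    ntf_positions: list[tuple[str, int]] = []
    ntf_accessions: dict[tuple[str, int], str] = {}
    occupied = set(ppm_by_locus)
    for plant in spec.planted_ntf_distances:
        loc = (plant.replicon_id, plant.ppm_gene_index)
        if loc not in ppm_by_locus:
            raise ValueError(f"no planted ppm at {loc} to anchor a distance")
        if plant.distance == 0:
            partners_by_locus[loc] = partners_by_locus[loc] | {plant.accession}
            continue
        n_genes = sizes[plant.replicon_id]
        candidates = [
            plant.ppm_gene_index + plant.distance,
            plant.ppm_gene_index - plant.distance,
        ]
        target = next(
            (
                (plant.replicon_id, c)
                for c in candidates
                if 0 <= c < n_genes and (plant.replicon_id, c) not in occupied
            ),
            None,
        )
        if target is None:
            raise ValueError(
                f"cannot realize distance {plant.distance} from ppm at {loc}: "
                "index collision or out of range"
            )
        occupied.add(target)
        ntf_positions.append(target)
        ntf_accessions[target] = plant.accession

    # --- proteins, gene table, hit rows
    proteins: dict[str, str] = {}
    gff_rows: list[str] = []
    hit_rows: list[str] = []
    truth_ppm: dict[str, dict] = {}
    truth_ntf: list[str] = []

    def protein_id(replicon_id: str, idx: int) -> str:
        return f"{spec.genome_id}|{replicon_id}|g{idx:05d}"

    for rep in spec.replicons:
        for idx in range(rep.n_genes):
            pid = protein_id(rep.replicon_id, idx)
            loc = (rep.replicon_id, idx)
            if loc in ppm_by_locus:
                planted = ppm_by_locus[loc]
                partners = sorted(partners_by_locus[loc])
                ppm_len = MODEL_LENGTHS[PPM_ACCESSION]
                segments = [(PPM_ACCESSION, 1, ppm_len, planted.coverage)]
                offset = ppm_len + _LINKER
                for acc in partners:
                    seg_len = MODEL_LENGTHS[acc]
                    segments.append((acc, offset + 1, offset + seg_len, 1.0))
                    offset += seg_len + _LINKER
                total_len = offset - _LINKER
                seq = _protein_without_motif(rng, total_len)
                if planted.has_motif:
                    seq = _plant_motif(rng, seq, 10, ppm_len - 10)
                proteins[pid] = seq
                n_dom = len(segments)
                for k, (acc, ali_from, ali_to, cov) in enumerate(segments, start=1):
                    model_len = MODEL_LENGTHS[acc]
                    hmm_to = max(1, round(cov * model_len))
                    score = float(rng.uniform(150.0, 250.0))
                    hit_rows.append(
                        _domtblout_row(
                            acc, acc, model_len, pid, total_len, score,
                            1, hmm_to, ali_from, ali_to, k, n_dom,
                        )
                    )
                truth_ppm[pid] = {
                    "has_motif": planted.has_motif,
                    "partners": partners,
                    "category": _category_for(frozenset(partners)),
                    "coverage": planted.coverage,
                    "gene_index": idx,
                    "replicon_id": rep.replicon_id,
                }
            elif loc in ntf_accessions:
                acc = ntf_accessions[loc]
                seg_len = MODEL_LENGTHS[acc]
                seq = _protein_without_motif(rng, seg_len)
                proteins[pid] = seq
                score = float(rng.uniform(100.0, 200.0))
                hit_rows.append(
                    _domtblout_row(
                        acc, acc, seg_len, pid, seg_len, score,
                        1, seg_len, 1, seg_len, 1, 1,
                    )
                )
                truth_ntf.append(pid)
            else:
                proteins[pid] = _protein_without_motif(
                    rng, _BACKGROUND_PROTEIN_LEN
                )
            start = idx * _GENE_SPAN + 101
            gff_rows.append(
                "\t".join(
                    [
                        f"{spec.genome_id}|{rep.replicon_id}",
                        "phosphomine_synth",
                        "CDS",
                        str(start),
                        str(start + _GENE_LEN - 1),
                        ".",
                        "+",
                        "0",
                        f"ID={pid};genome_id={spec.genome_id}",
                    ]
                )
            )

    # --- exact duplicates
    all_ids = set(proteins)
    for group in spec.duplicate_groups:
        unknown = group - all_ids
        if unknown:
            raise ValueError(f"duplicate group references unknown ids {sorted(unknown)}")
        members = sorted(group)
        ppm_members = [m for m in members if m in truth_ppm]
        if ppm_members and len(ppm_members) != len(members):
            raise ValueError(
                "a duplicate group must not mix Ppm-like and background proteins"
            )
        if ppm_members:
            keys = {
                (truth_ppm[m]["has_motif"], tuple(truth_ppm[m]["partners"]))
                for m in ppm_members
            }
            if len(keys) > 1:
                raise ValueError(
                    "duplicate-group Ppm members must share motif and fusion status"
                )
        for m in members[1:]:
            proteins[m] = proteins[members[0]]

    dedup_rep: dict[str, str] = {}
    by_seq: dict[str, str] = {}
    for pid in sorted(proteins):
        rep_id = by_seq.setdefault(proteins[pid], pid)
        dedup_rep[pid] = rep_id

    # --- genome nucleotide sequence, one record per replicon
    genome_records = []
    for rep in spec.replicons:
        length = rep.n_genes * _GENE_SPAN + 200
        seq = random_genome_sequence(length, 0, rng=rng)
        genome_records.append(
            SeqRecord(
                Seq(seq),
                id=f"{spec.genome_id}|{rep.replicon_id}",
                description=f"synthetic replicon circular={rep.circular}",
            )
        )

    protein_records = [
        SeqRecord(Seq(seq), id=pid, description="synthetic protein")
        for pid, seq in proteins.items()
    ]
    proteins_fasta = io.StringIO()
    SeqIO.write(protein_records, proteins_fasta, "fasta")
    genome_fasta = io.StringIO()
    SeqIO.write(genome_records, genome_fasta, "fasta")

    gff3 = "##gff-version 3\n" + "\n".join(gff_rows) + "\n"
    domtblout = (
        "# --- synthetic per-domain hits ---\n"
        + "\n".join(hit_rows)
        + ("\n" if hit_rows else "")
    )

    truth = BundleTruth(
        genome_id=spec.genome_id,
        ppm_proteins=truth_ppm,
        ntf_proteins=truth_ntf,
        nearest_distance=_nearest_planted_distance(
            spec, partners_by_locus, ntf_positions
        ),
        duplicate_map=dedup_rep,
        n_proteins=len(proteins),
        n_distinct_sequences=len(by_seq),
    )
    return SyntheticBundle(
        proteins_fasta=proteins_fasta.getvalue(),
        gene_table_gff3=gff3,
        domain_hits_domtblout=domtblout,
        genome_fasta=genome_fasta.getvalue(),
        truth=truth,
    )


@dataclass
class SyntheticSuite:
    """Concatenation of several bundles plus their per-genome truths."""

    proteins_fasta: str
    gene_table_gff3: str
    domain_hits_domtblout: str
    genome_fasta: str
    truths: dict[str, BundleTruth]


def generate_suite(specs: Iterable[GenomeSpec]) -> SyntheticSuite:
    """Generate and concatenate one bundle per spec (distinct genome_ids)."""
    bundles = [generate_bundle(s) for s in specs]
    ids = [b.truth.genome_id for b in bundles]
    if len(set(ids)) != len(ids):
        raise ValueError("genome ids must be unique across a suite")
    gff_bodies = [
        b.gene_table_gff3.removeprefix("##gff-version 3\n") for b in bundles
    ]
    # keep hit-table comments to the top: some downstream parsers treat an
    # inline comment line as end-of-records
    hit_bodies = [
        "".join(
            line
            for line in b.domain_hits_domtblout.splitlines(keepends=True)
            if not line.startswith("#")
        )
        for b in bundles
    ]
    return SyntheticSuite(
        proteins_fasta="".join(b.proteins_fasta for b in bundles),
        gene_table_gff3="##gff-version 3\n" + "".join(gff_bodies),
        domain_hits_domtblout="# --- synthetic per-domain hits ---\n"
        + "".join(hit_bodies),
        genome_fasta="".join(b.genome_fasta for b in bundles),
        truths={b.truth.genome_id: b.truth for b in bundles},
    )


def generate_kinetic_dataset(
    kcat: float,
    KM: float,
    KS: float,
    E0: float,
    S_grid: Sequence[float],
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Initial-rate table from the substrate-inhibition law with noise.

    ``v(S) = kcat*E0*S / (KM + S*(1 + S/KS))`` with multiplicative Gaussian
    noise of relative standard deviation ``noise_sd``; ``KS = inf`` gives
    pure Michaelis-Menten. S and KM/KS in mM, E0 in M, velocities in M/s.
    Negative noisy velocities are clamped to 0 and flagged in the
    ``clamped`` column.
    """
    if kcat <= 0 or KM <= 0 or KS <= 0 or E0 <= 0:
        raise ValueError("kcat, KM, KS and E0 must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    S = np.asarray(list(S_grid), dtype=float)
    if S.size == 0:
        raise ValueError("S_grid must be non-empty")
    v = substrate_inhibition_rate(S, kcat, KM, KS, E0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v * (1.0 + noise_sd * rng.standard_normal(S.size))
    clamped = v < 0
    v = np.where(clamped, 0.0, v)
    return pd.DataFrame({"S": S, "v": v, "clamped": clamped})
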