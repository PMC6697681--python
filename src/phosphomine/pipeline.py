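"""End-to-end orchestration of the phosphonate gene-cluster mining pipeline.

Stage order mirrors the published analysis: dereplicate genomes by
trinucleotide signature -> filter per-domain HMM hits (GA + coverage) and
resolve overlaps -> split PF13714 matches by the Ppm catalytic motif ->
deduplicate sequences -> fusion inventory -> ppm<->nucleotidyltransferase
gene distances -> distance distribution. Every stage writes a TSV and the
run emits one JSON summary plus a log recording each filtering decision
count, so the retrieval funnel can be reconstructed from the log alone.
"""

from __future__ import annotations

import io
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .domains import (
    coverage,
    filter_hits,
    parse_domtblout,
    resolve_overlaps_per_protein,
)
from .inventory import (
    CTP_TRANSF_LIKE,
    NTP_TRANSF_3,
    PPM_ACCESSION,
    classify_fusion,
    deduplicate_sequences,
    summarize_inventory,
)
from .motif import DEFAULT_MOTIF, split_by_motif
from .neighborhood import (
    DistanceDistribution,
    GeneLocus,
    Role,
    build_distribution,
    nearest_distance_per_genome,
)
from .signatures import dereplicate, trinucleotide_signature

logger = logging.getLogger("phosphomine")

_ACCESSION_SHAPE = re.compile(r"^PF\d{5}$")


@dataclass
class PipelineConfig:
    """Inputs, thresholds and accession sets for one pipeline run.

    Defaults encode the published retrieval rules: 60% model coverage,
    species-level signature cutoff delta = 0.03, nucleotidyltransferase
    roles from PF12804/PF01467, and the EDKXXXXXNS Ppm motif.
    """

    proteins: str | Path | None = None
    gff: str | Path | None = None
    domtblout: str | Path | None = None
    genomes: str | Path | None = None
    kinetics_tables: tuple[str, ...] = ()
    output_dir: str | Path = "phosphomine_out"

    min_coverage: float = 0.6
    require_ga: bool = True
    delta: float = 0.03
    within_k: int = 5
    circular: bool = False

    ppm_accession: str = PPM_ACCESSION
    ntf_accessions: tuple[str, ...] = (NTP_TRANSF_3, CTP_TRANSF_LIKE)
    motif_pattern: str = DEFAULT_MOTIF
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.min_coverage <= 1.0:
            raise ValueError(f"min_coverage {self.min_coverage} outside [0, 1]")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.within_k < 0:
            raise ValueError("within_k must be non-negative")
        for acc in (self.ppm_accession, *self.ntf_accessions):
            if not _ACCESSION_SHAPE.match(acc):
                raise ValueError(f"accession {acc!r} does not look like PFxxxxx")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("ntf_accessions", "kinetics_tables"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def _genome_of(record_id: str) -> str:
    """Genome id from a ``genome|replicon`` FASTA/GFF identifier."""
    return record_id.split("|", 1)[0]


def read_protein_fasta(text: str) -> dict[str, str]:
    return {
        rec.id: str(rec.seq)
        for rec in SeqIO.parse(io.StringIO(text), "fasta")
    }


def read_gene_table(text: str) -> pd.DataFrame:
    """Parse GFF3 gene rows into a table with 0-based gene ordinal indices.

    Gene order within each replicon is assigned by ascending start
    coordinate (strand ignored). Requires an ``ID=`` attribute per row.
    """
    names = [
        "seqid", "source", "type", "start", "end",
        "score", "strand", "frame", "attributes",
    ]
    df = pd.read_csv(
        io.StringIO(text), sep="\t", comment="#", header=None, names=names
    )
    df["protein_id"] = df["attributes"].str.extract(r"ID=([^;]+)")
    if df["protein_id"].isna().any():
        raise ValueError("GFF3 row without an ID attribute")
    df["genome_id"] = df["seqid"].map(_genome_of)
    df["replicon_id"] = df["seqid"]
    df = df.sort_values(["replicon_id", "start"], kind="stable")
    df["gene_index"] = df.groupby("replicon_id").cumcount()
    return df.reset_index(drop=True)


def build_loci(
    gene_table: pd.DataFrame,
    ppm_ids: set[str],
    ntf_ids: set[str],
) -> dict[str, list[GeneLocus]]:
    """Gene loci with PPM/NTF roles, grouped by genome."""
    by_genome: dict[str, list[GeneLocus]] = {}
    for row in gene_table.itertuples(index=False):
        roles = set()
        if row.protein_id in ppm_ids:
            roles.add(Role.PPM.value)
        if row.protein_id in ntf_ids:
            roles.add(Role.NTF.value)
        if not roles:
            continue
        by_genome.setdefault(row.genome_id, []).append(
            GeneLocus(
                genome_id=row.genome_id,
                replicon_id=row.replicon_id,
                gene_index=int(row.gene_index),
                protein_id=row.protein_id,
                roles=frozenset(roles),
            )
        )
    return by_genome


@dataclass
class PipelineResult:
    representatives: list[str]
    summary: dict
    inventory: pd.DataFrame
    distances: pd.DataFrame
    distribution: DistanceDistribution
    filtered_hits: pd.DataFrame


def run_pipeline_from_texts(
    proteins_fasta: str,
    gene_table_gff3: str,
    domtblout_text: str,
    genome_fasta: str,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run every genomic stage on in-memory inputs; see module docstring."""
    cfg = config or PipelineConfig()
    cfg.validate()

    # Stage 1: genome dereplication by trinucleotide signature.
    replicons_by_genome: dict[str, list[str]] = {}
    for rec in SeqIO.parse(io.StringIO(genome_fasta), "fasta"):
        replicons_by_genome.setdefault(_genome_of(rec.id), []).append(str(rec.seq))
    signatures = [
        trinucleotide_signature(seqs, genome_id=gid)
        for gid, seqs in sorted(replicons_by_genome.items())
    ]
    representatives = dereplicate(signatures, delta=cfg.delta)
    rep_set = set(representatives)
    logger.info(
        "dereplication: %d genomes in, %d representatives out",
        len(signatures), len(representatives),
    )

    # Stage 2: hit-quality filters and overlap resolution.
    hits = parse_domtblout(domtblout_text)
    kept = filter_hits(hits, min_coverage=cfg.min_coverage, require_ga=cfg.require_ga)
    kept = [h for h in kept if _genome_of(h.protein_id) in rep_set]
    logger.info("hit filter: %d hits in, %d kept", len(hits), len(kept))
    resolved = resolve_overlaps_per_protein(kept)

    # Stage 3: PF13714 matches, dedup, motif split.
    proteins = read_protein_fasta(proteins_fasta)
    pf13714_ids = {
        pid
        for pid, phits in resolved.items()
        if any(h.pfam_accession == cfg.ppm_accession for h in phits)
    }
    candidates = {pid: proteins[pid] for pid in sorted(pf13714_ids)}
    dedup = deduplicate_sequences(candidates) if candidates else None
    nonredundant = dedup.representatives if dedup else {}
    logger.info(
        "dedup: %d PF13714 matches, %d non-redundant",
        len(candidates), len(nonredundant),
    )
    split = split_by_motif(nonredundant, pattern=cfg.motif_pattern)
    logger.info(
        "motif split: %d Ppm, %d removed", split.n_ppm, split.n_removed
    )

    # Stage 4: fusion inventory over motif-positive non-redundant Ppm.
    ppm_ids = set(split.ppm_ids)
    n_fused_nonredundant = sum(
        1
        for pid in nonredundant
        if len({h.pfam_accession for h in resolved[pid]} - {cfg.ppm_accession}) > 0
    )
    classifications = [
        classify_fusion(pid, resolved[pid], has_motif=True,
                        ppm_accession=cfg.ppm_accession)
        for pid in sorted(ppm_ids)
    ]
    summary_obj = summarize_inventory(
        classifications,
        n_total_pf13714=len(candidates),
        n_nonredundant=len(nonredundant),
        n_fused=n_fused_nonredundant,
    )
    inventory_df = pd.DataFrame(
        [
            {
                "protein_id": c.protein_id,
                "has_motif": c.has_motif,
                "category": c.category.value,
                "partner_accessions": ",".join(sorted(c.partner_accessions)),
            }
            for c in classifications
        ]
    )

    # Stage 5: gene distances on representative genomes. The PPM role uses
    # every motif-positive pipeline-surviving protein (not only dedup
    # representatives: distance is a per-genome property).
    motif_positive_all = set(split.ppm_ids)
    if dedup:
        motif_positive_all = {
            pid
            for pid, rep in dedup.duplicate_map.items()
            if rep in ppm_ids
        }
    ntf_ids = {
        pid
        for pid, phits in resolved.items()
        if any(h.pfam_accession in cfg.ntf_accessions for h in phits)
    }
    gene_table = read_gene_table(gene_table_gff3)
    gene_table = gene_table[gene_table["genome_id"].isin(rep_set)]
    loci_by_genome = build_loci(gene_table, motif_positive_all, ntf_ids)
    records = []
    for gid in sorted(loci_by_genome):
        rec = nearest_distance_per_genome(loci_by_genome[gid], circular=cfg.circular,
                                          replicon_sizes=None if not cfg.circular else
                                          gene_table.groupby("replicon_id")["gene_index"]
                                          .max().add(1).to_dict())
        if rec is not None:
            records.append(rec)
    distribution = build_distribution(records)
    logger.info(
        "distances: %d genomes with a ppm<->NTF pair", distribution.n_genomes
    )

    summary = {
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": {
            "min_coverage": cfg.min_coverage,
            "require_ga": cfg.require_ga,
            "delta": cfg.delta,
            "within_k": cfg.within_k,
        },
        "n_genomes_in": len(signatures),
        "n_representatives": len(representatives),
        "inventory": summary_obj.to_dict(),
        "distances": {
            "n_genomes": distribution.n_genomes,
            "fraction_at_zero": distribution.fraction_at_zero,
            f"fraction_within_{cfg.within_k}": distribution.fraction_within(
                cfg.within_k
            ),
            "histogram": {str(k): v for k, v in sorted(distribution.histogram.items())},
        },
    }
    filtered_df = pd.DataFrame(
        [
            {
                "protein_id": h.protein_id,
                "pfam_accession": h.pfam_accession,
                "coverage": coverage(h),
                "domain_bit_score": h.domain_bit_score,
                "ali_from": h.ali_from,
                "ali_to": h.ali_to,
            }
            for phits in resolved.values()
            for h in phits
        ]
    )
    distances_df = pd.DataFrame(records, columns=["genome_id", "distance"])
    return PipelineResult(
        representatives=representatives,
        summary=summary,
        inventory=inventory_df,
        distances=distances_df,
        distribution=distribution,
        filtered_hits=filtered_df,
    )


def make_figure_tables(distribution: DistanceDistribution) -> pd.DataFrame:
    """Plot-ready distance table: count, log10 count, cumulative fraction.

    One row per observed distance (zero-count distances omitted), the form
    used for a log-count + cumulative-fraction distance figure.
    """
    if not distribution.records:
        raise ValueError("empty distribution")
    rows = []
    logs = distribution.log10_counts()
    for d in sorted(distribution.histogram):
        rows.append(
            {
                "distance": d,
                "count": distribution.histogram[d],
                "log10_count": logs[d],
                "cumulative_fraction": distribution.cumulative_fraction[d],
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based entry point: read config paths, run, write artifacts."""
    config.validate()
    for attr in ("proteins", "gff", "domtblout", "genomes"):
        if getattr(config, attr) is None:
            raise ValueError(f"config path {attr!r} is required")
    result = run_pipeline_from_texts(
        Path(config.proteins).read_text(),
        Path(config.gff).read_text(),
        Path(config.domtblout).read_text(),
        Path(config.genomes).read_text(),
        config,
    )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "summary.json").write_text(
        json.dumps(result.summary, indent=2, sort_keys=True) + "\n"
    )
    pd.DataFrame({"genome_id": result.representatives}).to_csv(
        out / "representatives.tsv", sep="\t", index=False
    )
    result.filtered_hits.to_csv(out / "filtered_hits.tsv", sep="\t", index=False)
    result.inventory.to_csv(out / "inventory.tsv", sep="\t", index=False)
    result.distances.to_csv(out / "distances.tsv", sep="\t", index=False)
    if result.distribution.records:
        make_figure_tables(result.distribution).to_csv(
            out / "distance_histogram.tsv", sep="\t", index=False
        )
    return result
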