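"""The synthetic-genome generator: determinism, planted truth, mutation."""

from __future__ import annotations

import math

import numpy as np
import pytest

from phosphomine.domains import parse_domtblout
from phosphomine.pipeline import read_gene_table, read_protein_fasta
from phosphomine.synthetic import (
    GenomeSpec,
    PlantedNtf,
    PlantedPpm,
    RepliconSpec,
    generate_bundle,
    generate_kinetic_dataset,
    mutate_genome,
    random_genome_sequence,
)
from test_motif import brute_force_motif_positions


def simple_spec(**kw) -> GenomeSpec:
    defaults = dict(
        genome_id="gT",
        replicons=(RepliconSpec("chr", 10),),
        planted_ppm=(PlantedPpm("chr", 3, has_motif=True),),
        planted_ntf_distances=(PlantedNtf("chr", 3, 2),),
        seed=5,
    )
    defaults.update(kw)
    return GenomeSpec(**defaults)


class TestGenerateBundle:
    def test_one_pair_at_planted_distance(self):
        bundle = generate_bundle(simple_spec())
        assert bundle.truth.nearest_distance == 2
        assert len(bundle.truth.ntf_proteins) == 1

    def test_one_protein_per_gene(self):
        bundle = generate_bundle(simple_spec())
        proteins = read_protein_fasta(bundle.proteins_fasta)
        genes = read_gene_table(bundle.gene_table_gff3)
        assert len(proteins) == 10
        assert set(genes["protein_id"]) == set(proteins)
        assert sorted(genes["gene_index"]) == list(range(10))

    def test_motifless_protein_has_no_motif_by_brute_force(self):
        spec = simple_spec(
            planted_ppm=(PlantedPpm("chr", 3, has_motif=False),),
            planted_ntf_distances=(),
        )
        bundle = generate_bundle(spec)
        proteins = read_protein_fasta(bundle.proteins_fasta)
        (ppm_id,) = bundle.truth.ppm_proteins
        assert brute_force_motif_positions(proteins[ppm_id]) == []

    def test_motif_positive_protein_contains_motif(self):
        bundle = generate_bundle(simple_spec())
        proteins = read_protein_fasta(bundle.proteins_fasta)
        (ppm_id,) = bundle.truth.ppm_proteins
        assert brute_force_motif_positions(proteins[ppm_id]) != []

    def test_deterministic_given_seed(self):
        a, b = generate_bundle(simple_spec()), generate_bundle(simple_spec())
        assert a.proteins_fasta == b.proteins_fasta
        assert a.gene_table_gff3 == b.gene_table_gff3
        assert a.domain_hits_domtblout == b.domain_hits_domtblout
        assert a.genome_fasta == b.genome_fasta

    def test_distinct_seeds_differ(self):
        a = generate_bundle(simple_spec(seed=5))
        b = generate_bundle(simple_spec(seed=6))
        assert a.proteins_fasta != b.proteins_fasta

    def test_fusion_rows_non_overlapping_coordinates(self):
        spec = simple_spec(
            planted_ppm=(
                PlantedPpm("chr", 3, fusion_partners=frozenset({"PF12804", "PF01467"})),
            ),
            planted_ntf_distances=(),
        )
        hits = parse_domtblout(generate_bundle(spec).domain_hits_domtblout)
        assert len(hits) == 3
        intervals = sorted((h.ali_from, h.ali_to) for h in hits)
        for (a1, a2), (b1, b2) in zip(intervals, intervals[1:]):
            assert a2 < b1

    def test_distance_zero_realized_as_fusion_not_gene(self):
        spec = simple_spec(planted_ntf_distances=(PlantedNtf("chr", 3, 0),))
        bundle = generate_bundle(spec)
        assert bundle.truth.ntf_proteins == []
        (rec,) = bundle.truth.ppm_proteins.values()
        assert "PF12804" in rec["partners"]
        assert bundle.truth.nearest_distance == 0

    def test_index_collision_rejected(self):
        spec = simple_spec(
            planted_ppm=(
                PlantedPpm("chr", 1), PlantedPpm("chr", 3), PlantedPpm("chr", 5),
            ),
            planted_ntf_distances=(PlantedNtf("chr", 3, 2),),
        )
        with pytest.raises(ValueError, match="collision|out of range"):
            generate_bundle(spec)

    def test_out_of_range_index_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            generate_bundle(simple_spec(planted_ppm=(PlantedPpm("chr", 10),)))

    def test_duplicate_groups_receive_identical_sequences(self):
        spec = GenomeSpec(
            genome_id="gD",
            replicons=(RepliconSpec("chr", 8),),
            duplicate_groups=(frozenset({"gD|chr|g00001", "gD|chr|g00004"}),),
            seed=2,
        )
        bundle = generate_bundle(spec)
        proteins = read_protein_fasta(bundle.proteins_fasta)
        assert proteins["gD|chr|g00001"] == proteins["gD|chr|g00004"]
        assert bundle.truth.n_distinct_sequences == 7

    def test_truth_counts_describe_emitted_files(self, synthetic_suite):
        proteins = read_protein_fasta(synthetic_suite.proteins_fasta)
        n_truth = sum(t.n_proteins for t in synthetic_suite.truths.values())
        assert len(proteins) == n_truth


class TestMutateGenome:
    def test_rate_zero_identity(self):
        seq = random_genome_sequence(2000, seed=1)
        assert mutate_genome(seq, 0.0, seed=2) == seq

    def test_rate_one_changes_every_base(self):
        assert "A" not in mutate_genome("AAAA", 1.0, seed=3)
        mutated = mutate_genome("ACGTACGT" * 50, 1.0, seed=4)
        assert all(a != b for a, b in zip("ACGTACGT" * 50, mutated))

    def test_length_preserved_and_alphabet_closed(self):
        seq = random_genome_sequence(5000, seed=5)
        out = mutate_genome(seq, 0.3, seed=6)
        assert len(out) == len(seq)
        assert set(out) <= set("ACGT")

    def test_substitution_count_within_binomial_bound(self):
        n, rate = 100_000, 0.05
        seq = random_genome_sequence(n, seed=7)
        out = mutate_genome(seq, rate, seed=8)
        observed = sum(a != b for a, b in zip(seq, out))
        sd = math.sqrt(n * rate * (1 - rate))
        assert abs(observed - n * rate) < 3 * sd

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            mutate_genome("ACGTN", 0.1, seed=9)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            mutate_genome("ACGT", 1.5, seed=0)


class TestKineticDataset:
    def test_noise_free_is_deterministic_formula(self):
        df = generate_kinetic_dataset(1.0, 1.0, 4.0, 1e-7, [0.5, 1, 2, 4], 0.0, 0)
        expected = [1e-7 * s / (1 + s * (1 + s / 4.0)) for s in (0.5, 1, 2, 4)]
        np.testing.assert_allclose(df["v"], expected, rtol=1e-12)
        assert not df["clamped"].any()

    def test_seeded_noise_reproducible(self):
        a = generate_kinetic_dataset(1.0, 1.0, math.inf, 1e-7, [1, 2, 3], 0.1, 42)
        b = generate_kinetic_dataset(1.0, 1.0, math.inf, 1e-7, [1, 2, 3], 0.1, 42)
        assert a.equals(b)

    def test_negative_draws_clamped_and_flagged(self):
        df = generate_kinetic_dataset(1.0, 1.0, math.inf, 1e-7, [1.0] * 500, 3.0, 0)
        assert df["clamped"].any()
        assert (df["v"] >= 0).all()
        assert (df.loc[df["clamped"], "v"] == 0).all()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_kinetic_dataset(-1.0, 1.0, math.inf, 1e-7, [1.0], 0.0, 0)
        with pytest.raises(ValueError, match="non-empty"):
            generate_kinetic_dataset(1.0, 1.0, math.inf, 1e-7, [], 0.0, 0)
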