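"""Domain-hit parsing, coverage/GA filtering, and overlap resolution."""

from __future__ import annotations

import numpy as np
import pytest

from phosphomine.domains import (
    DomainHit,
    DomtbloutParseError,
    coverage,
    filter_hits,
    parse_domtblout,
    resolve_overlaps,
)

from conftest import random_hit

# One hand-constructed domtblout row: hmm coords 5..90 of a 100-column model,
# alignment 12..101 of a 350-residue protein, domain score 83.2.
FIXTURE_ROW = (
    "PEP_mutase PF13714.7 100 WP_000001.1 - 350 "
    "1.2e-40 160.5 0.3 1 2 2.0e-41 3.1e-38 83.2 0.2 "
    "5 90 12 101 10 105 0.93 phosphoenolpyruvate mutase"
)


class TestParseDomtblout:
    def test_comment_only_file_gives_empty_list(self):
        text = "# target name ...\n#\n# comments only\n"
        assert parse_domtblout(text) == []

    def test_hand_parsed_fixture_row(self):
        (hit,) = parse_domtblout(FIXTURE_ROW + "\n")
        assert hit.protein_id == "WP_000001.1"
        assert hit.pfam_accession == "PF13714"  # version stripped
        assert hit.model_length == 100
        assert (hit.hmm_from, hit.hmm_to) == (5, 90)
        assert (hit.ali_from, hit.ali_to) == (12, 101)
        assert hit.bit_score == pytest.approx(160.5)
        assert hit.domain_bit_score == pytest.approx(83.2)
        assert hit.evalue == pytest.approx(1.2e-40)
        assert hit.description == "phosphoenolpyruvate mutase"

    def test_short_row_raises_with_line_number(self):
        text = "# header\nPEP_mutase PF13714.7 100 WP_1 - 350 1e-40 160 0.3\n"
        with pytest.raises(DomtbloutParseError, match="line 2"):
            parse_domtblout(text)

    def test_non_numeric_coordinate_raises(self):
        bad = FIXTURE_ROW.replace(" 5 90 ", " five 90 ")
        with pytest.raises(DomtbloutParseError, match="line 1"):
            parse_domtblout(bad)

    def test_ga_table_marks_subthreshold_hits(self):
        hits = parse_domtblout(FIXTURE_ROW, ga_table={"PF13714": 200.0})
        assert hits[0].meets_ga is False
        hits = parse_domtblout(FIXTURE_ROW, ga_table={"PF13714": 100.0})
        assert hits[0].meets_ga is True

    def test_planted_rows_round_trip_count(self, synthetic_suite):
        hits = parse_domtblout(synthetic_suite.domain_hits_domtblout)
        n_expected = sum(
            len(t.ppm_proteins[p]["partners"]) + 1
            for t in synthetic_suite.truths.values()
            for p in t.ppm_proteins
        ) + sum(len(t.ntf_proteins) for t in synthetic_suite.truths.values())
        assert len(hits) == n_expected

    def test_biopython_agrees_on_generated_table(self, synthetic_suite):
        """Independent oracle: Bio.SearchIO's hmmscan domtab parser."""
        import io

        from Bio import SearchIO

        ours = parse_domtblout(synthetic_suite.domain_hits_domtblout)
        theirs = [
            (qr.id, hit.id, hsp.hit_start + 1, hsp.hit_end)
            for qr in SearchIO.parse(
                io.StringIO(synthetic_suite.domain_hits_domtblout),
                "hmmscan3-domtab",
            )
            for hit in qr
            for hsp in hit.hsps
        ]
        mine = [(h.protein_id, h.pfam_accession, h.hmm_from, h.hmm_to) for h in ours]
        # SearchIO keys hits by target name (here equal to the accession stem)
        assert sorted(mine) == sorted(theirs)


class TestCoverageAndFilter:
    @pytest.mark.parametrize(
        "hmm_from,hmm_to,model_length,expected",
        [(1, 100, 100, 1.0), (21, 80, 100, 0.60), (1, 59, 100, 0.59)],
    )
    def test_coverage_arithmetic(self, hmm_from, hmm_to, model_length, expected):
        hit = DomainHit(
            protein_id="p", pfam_accession="PF00001", model_length=model_length,
            hmm_from=hmm_from, hmm_to=hmm_to, ali_from=1, ali_to=60,
            bit_score=50.0, domain_bit_score=50.0, evalue=1e-10,
        )
        assert coverage(hit) == pytest.approx(expected)

    def test_exact_60_percent_is_kept_and_59_removed(self):
        def hit(hmm_to):
            return DomainHit(
                protein_id="p", pfam_accession="PF00001", model_length=100,
                hmm_from=1, hmm_to=hmm_to, ali_from=1, ali_to=60,
                bit_score=50.0, domain_bit_score=50.0, evalue=1e-10,
            )
        assert filter_hits([hit(60)]) == [hit(60)]   # inclusive bound
        assert filter_hits([hit(59)]) == []

    def test_ga_failures_removed_only_when_required(self):
        hit = DomainHit(
            protein_id="p", pfam_accession="PF00001", model_length=100,
            hmm_from=1, hmm_to=100, ali_from=1, ali_to=100,
            bit_score=50.0, domain_bit_score=50.0, evalue=1e-10, meets_ga=False,
        )
        assert filter_hits([hit]) == []
        assert filter_hits([hit], require_ga=False) == [hit]

    def test_matches_brute_force_predicate_scan(self, hit_rng):
        hits = [random_hit(hit_rng) for _ in range(50)]
        expected = [
            h
            for h in hits
            if (h.hmm_to - h.hmm_from + 1) / h.model_length >= 0.6 and h.meets_ga
        ]
        assert filter_hits(hits) == expected

    def test_idempotent_and_subset(self, hit_rng):
        hits = [random_hit(hit_rng) for _ in range(50)]
        once = filter_hits(hits)
        assert filter_hits(once) == once
        assert all(h in hits for h in once)

    def test_raising_coverage_is_monotone(self, hit_rng):
        hits = [random_hit(hit_rng) for _ in range(100)]
        counts = [
            len(filter_hits(hits, min_coverage=c))
            for c in np.linspace(0.0, 1.0, 11)
        ]
        assert counts == sorted(counts, reverse=True)


def _brute_force_greedy(hits, max_overlap=0):
    """Independent re-implementation of the published rule: repeatedly take
    the highest-scoring remaining hit that overlaps no already-kept hit."""
    remaining = sorted(
        range(len(hits)),
        key=lambda i: (-hits[i].domain_bit_score, hits[i].ali_from, i),
    )
    kept = []
    for i in remaining:
        ok = True
        for j in kept:
            shared = min(hits[i].ali_to, hits[j].ali_to) - max(
                hits[i].ali_from, hits[j].ali_from
            ) + 1
            if shared > max_overlap:
                ok = False
                break
        if ok:
            kept.append(i)
    return [hits[i] for i in sorted(kept)]


class TestResolveOverlaps:
    def _hit(self, ali_from, ali_to, score, acc="PF00001"):
        return DomainHit(
            protein_id="p", pfam_accession=acc, model_length=100,
            hmm_from=1, hmm_to=100, ali_from=ali_from, ali_to=ali_to,
            bit_score=score, domain_bit_score=score, evalue=1e-10,
        )

    def test_higher_score_wins_on_overlap(self):
        a, b = self._hit(1, 100, 80.0), self._hit(50, 150, 40.0)
        assert resolve_overlaps([a, b]) == [a]

    def test_disjoint_hits_both_kept(self):
        a, b = self._hit(1, 100, 80.0), self._hit(101, 150, 40.0)
        assert resolve_overlaps([a, b]) == [a, b]

    def test_mixed_proteins_rejected(self):
        a = self._hit(1, 100, 80.0)
        b = DomainHit(
            protein_id="q", pfam_accession="PF00002", model_length=100,
            hmm_from=1, hmm_to=100, ali_from=1, ali_to=50,
            bit_score=10.0, domain_bit_score=10.0, evalue=1e-5,
        )
        with pytest.raises(ValueError, match="multiple proteins"):
            resolve_overlaps([a, b])

    def test_equals_brute_force_oracle_on_random_intervals(self, hit_rng):
        for _ in range(100):
            n = int(hit_rng.integers(1, 21))
            hits = [random_hit(hit_rng) for _ in range(n)]
            assert resolve_overlaps(hits) == _brute_force_greedy(hits)

    def test_output_pairwise_disjoint_and_dominates_single_hits(self, hit_rng):
        for _ in range(50):
            hits = [random_hit(hit_rng) for _ in range(15)]
            kept = resolve_overlaps(hits)
            for i, a in enumerate(kept):
                for b in kept[i + 1:]:
                    assert min(a.ali_to, b.ali_to) < max(a.ali_from, b.ali_from)
            total = sum(h.domain_bit_score for h in kept)
            assert total >= max(h.domain_bit_score for h in hits) - 1e-9

    def test_max_overlap_tolerance(self):
        a, b = self._hit(1, 100, 80.0), self._hit(100, 150, 40.0)  # share 1 residue
        assert resolve_overlaps([a, b]) == [a]
        assert resolve_overlaps([a, b], max_overlap=1) == [a, b]
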