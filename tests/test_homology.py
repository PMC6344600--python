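import random

import pytest
from Bio.Align import substitution_matrices

from eetscan.homology import (
    KNOWN_PCC_FAMILIES, ROLE_BY_FAMILY, load_references, local_align,
    read_hits_table, search_all, search_references,
)
from eetscan.io_model import ProteinRecord, ValidationError
from oracles import gotoh_local_score

AA = "ARNDCQEGHILKMFPSTWYV"


class TestLocalAlign:
    def test_self_alignment_scores_diagonal_sum(self, params):
        rng = random.Random(1)
        seq = "".join(rng.choices(AA, k=20))
        matrix = substitution_matrices.load("BLOSUM62")
        hit = local_align(seq, seq, params)
        assert hit.identity == 1.0
        assert hit.query_coverage == 1.0 and hit.reference_coverage == 1.0
        assert hit.score == sum(matrix[a, a] for a in seq)

    def test_all_negative_pairs_floor_at_zero(self, params):
        hit = local_align("AAAA", "WWWW", params)
        assert hit.score == 0.0
        assert hit.query_interval == (0, 0) and hit.blocks == ()

    def test_empty_sequence_rejected(self, params):
        with pytest.raises(ValidationError):
            local_align("", "MKV", params)

    def test_score_is_symmetric(self, params):
        rng = random.Random(2)
        for _ in range(20):
            a = "".join(rng.choices(AA, k=rng.randint(10, 50)))
            b = "".join(rng.choices(AA, k=rng.randint(10, 50)))
            assert local_align(a, b, params).score == local_align(b, a, params).score

    def test_matches_dynamic_programming_oracle(self, params):
        rng = random.Random(3)
        matrix = substitution_matrices.load("BLOSUM62")
        for _ in range(40):
            a = "".join(rng.choices(AA, k=rng.randint(5, 60)))
            b = "".join(rng.choices(AA, k=rng.randint(5, 60)))
            expected = gotoh_local_score(a, b, matrix, 11.0, 1.0)
            assert local_align(a, b, params).score == expected

    def test_point_mutations_track_identity(self, params):
        rng = random.Random(4)
        for _ in range(50):
            ref = "".join(rng.choices(AA, k=300))
            chars = list(ref)
            for i in rng.sample(range(300), 60):  # 20% substitutions
                chars[i] = rng.choice([c for c in AA if c != chars[i]])
            hit = local_align("".join(chars), ref, params)
            assert 0.75 <= hit.identity <= 0.85


class TestReferences:
    def test_bundled_set_covers_all_families(self, refs):
        families = {r.family for r in refs}
        assert families == set(ROLE_BY_FAMILY)
        for r in refs:
            assert r.role == ROLE_BY_FAMILY[r.family]
            assert r.source_tag.startswith("synthetic:")

    def test_families_are_mutually_non_homologous(self, refs, params):
        h = params["homology"]
        for i, a in enumerate(refs):
            for b in refs[i + 1:]:
                hit = local_align(a.sequence, b.sequence, params)
                assert not (
                    hit.identity >= h["min_identity"]
                    and hit.query_coverage >= h["min_query_cov"]
                ), (a.family, b.family)


class TestSearch:
    def test_identical_reference_scores_full_identity(self, refs, params):
        cyc2 = next(r for r in refs if r.family == "Cyc2")
        hits = search_references(ProteinRecord("q", cyc2.sequence), refs, params)
        assert hits["cyc2"].family == "Cyc2" and hits["cyc2"].identity == 1.0

    def test_mutated_homolog_recovers_family_and_role(self, refs, params):
        rng = random.Random(5)
        mtra = next(r for r in refs if r.family == "MtrA")
        chars = list(mtra.sequence)
        for i in rng.sample(range(len(chars)), int(0.25 * len(chars))):
            chars[i] = rng.choice([c for c in AA if c not in (chars[i], "C", "H")])
        hits = search_references(ProteinRecord("q", "".join(chars)), refs, params)
        hit = hits["periplasmic_MHC"]
        assert hit.family == "MtrA" and hit.family in KNOWN_PCC_FAMILIES
        assert hit.identity >= 0.6

    def test_shuffled_sequences_rarely_hit(self, refs, params):
        rng = random.Random(6)
        mtra = next(r for r in refs if r.family == "MtrA")
        false_hits = 0
        for _ in range(40):
            shuffled = list(mtra.sequence)
            rng.shuffle(shuffled)
            if search_references(ProteinRecord("q", "".join(shuffled)), refs, params):
                false_hits += 1
        assert false_hits <= 4  # empirical null: >=95% of shuffles score nothing

    def test_raising_identity_threshold_never_adds_hits(self, refs, params):
        import copy

        rng = random.Random(7)
        mtra = next(r for r in refs if r.family == "MtrA")
        chars = list(mtra.sequence)
        for i in rng.sample(range(len(chars)), int(0.5 * len(chars))):
            chars[i] = rng.choice([c for c in AA if c != chars[i]])
        protein = ProteinRecord("q", "".join(chars))
        loose = search_references(protein, refs, params)
        strict_params = copy.deepcopy(params)
        strict_params["homology"]["min_identity"] = 0.6
        strict = search_references(protein, refs, strict_params)
        assert set(strict) <= set(loose)

    def test_precomputed_hit_table_replaces_search(self, tmp_path, refs, params):
        table = tmp_path / "hits.tsv"
        table.write_text(
            "query_id\tfamily\tidentity\tquery_coverage\tscore\n"
            "p1\tMtrB\t0.45\t0.8\t250\n"
            "p1\tCyc2\t0.10\t0.9\t40\n"   # below identity threshold: dropped
            "p2\tOmcS\t0.55\t0.7\t300\n"
        )
        proteins = [ProteinRecord("p1", "MKV" * 30), ProteinRecord("p2", "MKL" * 30)]
        hits = search_all(proteins, refs, params, precomputed=read_hits_table(table))
        assert hits["p1"]["porin"].family == "MtrB"
        assert "cyc2" not in hits["p1"]
        assert hits["p2"]["outer_surface_MHC"].query_interval == (0, 90)

    def test_unknown_family_in_hit_table_rejected(self, tmp_path):
        table = tmp_path / "hits.tsv"
        table.write_text(
            "query_id\tfamily\tidentity\tquery_coverage\tscore\np1\tNope\t0.5\t0.8\t100\n"
        )
        with pytest.raises(ValidationError, match="Nope"):
            read_hits_table(table)
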