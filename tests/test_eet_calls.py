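import random

import pytest

from eetscan.config import default_params
from eetscan.eet_calls import (
    call_cyc2, call_outer_surface_mhcs, detect_pcc_clusters,
)
from eetscan.homology import ROLE_BY_FAMILY, AlignmentHit
from eetscan.io_model import GeneFeature, ProteinRecord
from eetscan.localization import LocalizationCall
from eetscan.motif_scan import HemeScan, classify_mhc


def feat(gid, contig, rank, strand="+"):
    return GeneFeature(gid, contig, rank * 1000, rank * 1000 + 900, strand, rank)


def mhc(gid, hemes, params):
    return classify_mhc(HemeScan(gid, tuple(range(0, hemes * 6, 6))), params)


def loc(gid, compartment, signal):
    return LocalizationCall(gid, compartment, signal, "annotation")


def hit(family, qid="q", interval=(0, 100)):
    return AlignmentHit(qid, family, ROLE_BY_FAMILY[family], 200.0, 0.6, 0.8, 0.8, interval)


@pytest.fixture
def params():
    return default_params()


class TestPCCDetection:
    def _scenario(self, params, ranks=(0, 1), porin_family="porin_other",
                  mhc_family=None, max_gap=None):
        p = dict(params)
        if max_gap is not None:
            p = default_params()
            p["pcc"]["max_gene_gap"] = max_gap
        features = [feat("porin1", "c1", ranks[0]), feat("mhc1", "c1", ranks[1])]
        for r in range(max(ranks) + 1):
            if r not in ranks:
                features.append(feat(f"fill{r}", "c1", r))
        mhc_calls = {"mhc1": mhc("mhc1", 8, p)}
        locs = {"mhc1": loc("mhc1", "periplasmic", True),
                "porin1": loc("porin1", "outer_membrane", False)}
        hits = {"porin1": {"porin": hit(porin_family, "porin1")}}
        if mhc_family:
            hits["mhc1"] = {ROLE_BY_FAMILY[mhc_family]: hit(mhc_family, "mhc1")}
        return detect_pcc_clusters(features, mhc_calls, locs, hits, p)

    def test_adjacent_pair_without_family_hits_is_novel(self, params):
        clusters = self._scenario(params)
        assert len(clusters) == 1
        c = clusters[0]
        assert c.cluster_type == "novel_organization"
        assert c.members() == ("porin1", "mhc1")
        assert c.periplasmic_heme_count == 8

    def test_known_family_pair_is_typed_and_labelled(self, params):
        clusters = self._scenario(params, porin_family="MtrB", mhc_family="MtrA")
        assert clusters[0].cluster_type == "known_family"
        assert clusters[0].family == "MtrAB-like"

    def test_genes_on_different_contigs_never_cluster(self, params):
        features = [feat("porin1", "c1", 0), feat("mhc1", "c2", 0)]
        clusters = detect_pcc_clusters(
            features,
            {"mhc1": mhc("mhc1", 8, params)},
            {"mhc1": loc("mhc1", "periplasmic", True)},
            {"porin1": {"porin": hit("porin_other", "porin1")}},
            params,
        )
        assert clusters == []

    def test_gap_window_respected_and_monotone(self, params):
        far = self._scenario(params, ranks=(0, 3))
        assert far == []
        widened = self._scenario(params, ranks=(0, 3), max_gap=2)
        assert len(widened) == 1  # enlarging the window only adds clusters

    def test_mhc_without_signal_peptide_never_joins(self, params):
        features = [feat("porin1", "c1", 0), feat("mhc1", "c1", 1)]
        clusters = detect_pcc_clusters(
            features,
            {"mhc1": mhc("mhc1", 8, params)},
            {"mhc1": loc("mhc1", "cytoplasmic", False)},
            {"porin1": {"porin": hit("porin_other", "porin1")}},
            params,
        )
        assert clusters == []

    def test_extracellular_member_joins_triplet(self, params):
        features = [feat("porin1", "c1", 0), feat("mhc1", "c1", 1), feat("ext1", "c1", 2)]
        mhc_calls = {"mhc1": mhc("mhc1", 10, params), "ext1": mhc("ext1", 10, params)}
        locs = {
            "mhc1": loc("mhc1", "periplasmic", True),
            "ext1": loc("ext1", "extracellular", True),
        }
        hits = {
            "porin1": {"porin": hit("MtrB", "porin1")},
            "mhc1": {"periplasmic_MHC": hit("MtrA", "mhc1")},
            "ext1": {"extracellular_MHC": hit("MtrC", "ext1")},
        }
        clusters = detect_pcc_clusters(features, mhc_calls, locs, hits, params)
        assert len(clusters) == 1
        assert clusters[0].members() == ("porin1", "mhc1", "ext1")
        assert clusters[0].cluster_type == "known_family"

    def test_each_gene_joins_at_most_one_cluster(self, params):
        # two porins flanking one MHC: leftmost porin wins
        features = [feat("porinA", "c1", 0), feat("mhc1", "c1", 1), feat("porinB", "c1", 2)]
        clusters = detect_pcc_clusters(
            features,
            {"mhc1": mhc("mhc1", 8, params)},
            {"mhc1": loc("mhc1", "periplasmic", True)},
            {
                "porinA": {"porin": hit("porin_other", "porinA")},
                "porinB": {"porin": hit("porin_other", "porinB")},
            },
            params,
        )
        assert len(clusters) == 1
        assert clusters[0].porin_gene == "porinA"


class TestOuterSurface:
    def test_compartment_filter_and_cluster_exclusivity(self, params):
        mhc_calls = {
            "om": mhc("om", 12, params),
            "cyto": mhc("cyto", 6, params),
            "inpcc": mhc("inpcc", 12, params),
        }
        locs = {
            "om": loc("om", "outer_membrane", True),
            "cyto": loc("cyto", "cytoplasmic", False),
            "inpcc": loc("inpcc", "extracellular", True),
        }

        class FakeCluster:
            def members(self):
                return ("porinX", "inpcc")

        calls = call_outer_surface_mhcs(mhc_calls, locs, [FakeCluster()])
        assert [c.gene_id for c in calls] == ["om"]
        assert calls[0].call_class == "outer_surface_mhc"

    def test_cell_wall_mhcs_are_called(self, params):
        calls = call_outer_surface_mhcs(
            {"cw": mhc("cw", 15, params)}, {"cw": loc("cw", "cell_wall", True)}, []
        )
        assert [c.gene_id for c in calls] == ["cw"]


class TestCyc2:
    def _call(self, params, n_motifs=1, motif_pos=25, length=300, interval=(0, 300),
              with_hit=True):
        seq_positions = tuple(motif_pos + i * 80 for i in range(n_motifs))
        proteins = [ProteinRecord("p", "A" * length)]
        scans = {"p": HemeScan("p", seq_positions)}
        hits = {"p": {"cyc2": hit("Cyc2", "p", interval)}} if with_hit else {}
        return call_cyc2(proteins, scans, hits, params)

    def test_archetypal_cyc2_is_called(self, params):
        calls = self._call(params)
        assert len(calls) == 1 and calls[0].call_class == "cyc2"

    def test_two_heme_motifs_disqualify(self, params):
        assert self._call(params, n_motifs=2) == []

    def test_motif_outside_n_terminal_window_disqualifies(self, params):
        assert self._call(params, motif_pos=100) == []

    def test_homology_evidence_is_required(self, params):
        assert self._call(params, with_hit=False) == []

    def test_hit_must_cover_c_terminal_half(self, params):
        assert self._call(params, interval=(0, 120)) == []

    def test_length_bounds(self, params):
        assert self._call(params, length=100, interval=(0, 100)) == []
        assert self._call(params, length=900, interval=(0, 900)) == []


class TestCallSetProperties:
    def test_call_classes_partition_genes(self, default_result):
        result, _ = default_result
        by_class = {}
        for c in result.calls:
            by_class.setdefault(c.call_class, set()).add(c.gene_id)
        classes = list(by_class.values())
        for i, a in enumerate(classes):
            for b in classes[i + 1:]:
                assert not (a & b)

    def test_input_order_does_not_change_calls(self, small_bundle, refs):
        from eetscan.pipeline import analyze_metagenome

        data, _, _ = small_bundle
        res1 = analyze_metagenome(data, refs=refs)
        rng = random.Random(0)
        shuffled = data.__class__(
            metagenome_id=data.metagenome_id,
            proteins=rng.sample(data.proteins, len(data.proteins)),
            features=rng.sample(data.features, len(data.features)),
            coverage=data.coverage,
            mags=data.mags,
            housekeeping=data.housekeeping,
            localization_annotations=data.localization_annotations,
        )
        res2 = analyze_metagenome(shuffled, refs=refs)
        assert res1.calls_df.equals(res2.calls_df)
        assert res1.calls == res2.calls
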