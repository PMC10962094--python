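"""The 54-slot genomic feature registry, extractors and normalization."""

import math

import numpy as np
import pandas as pd
import pytest

from m6aconserve.features import (
    ConservedSiteIndex,
    TranscriptomeStats,
    apply_minmax,
    compute_transcriptome_stats,
    default_registry,
    distance_features,
    featurize,
    fit_minmax,
    gene_level_features,
    structure_features,
    topology_features,
    track_features,
)
from m6aconserve.encoders import SequenceWindow
from m6aconserve.sites import GenomicSite
from m6aconserve.tracks import ConservationTrack, IntervalTrack, TrackSet
from m6aconserve.transcripts import TranscriptModel


def site(pos, strand="+", sid="s1", chrom="chr1"):
    return GenomicSite(site_id=sid, chrom=chrom, position=pos, strand=strand)


@pytest.fixture
def two_exon_model():
    # exons [100,200) + [300,750); CDS spans transcript coords [50, 450)
    model = TranscriptModel(
        gene_id="g", transcript_id="t", chrom="chr1", strand="+",
        exons=[(100, 200), (300, 750)],
    )
    g0, g1 = model.transcript_to_genomic(50), model.transcript_to_genomic(449)
    return TranscriptModel(
        gene_id="g", transcript_id="t", chrom="chr1", strand="+",
        exons=[(100, 200), (300, 750)],
        cds=[(g0, 200), (300, g1 + 1)],
    )


class TestRegistry:
    def test_exactly_54_slots(self):
        assert len(default_registry()) == 54

    def test_exactly_15_region_dummies(self):
        dummies = [s for s in default_registry() if s.group == "dummy"]
        assert len(dummies) == 15
        assert [s.slot for s in dummies] == list(range(1, 16))

    def test_group_layout(self):
        counts = {}
        for s in default_registry():
            counts[s.group] = counts.get(s.group, 0) + 1
        assert counts == {
            "dummy": 15, "rel_pos": 4, "region_len": 8, "distance": 4,
            "conservation": 2, "structure": 2, "regulator": 8,
            "gene_prop": 5, "gc_z": 3, "omics": 3,
        }

    def test_names_unique(self):
        names = [s.name for s in default_registry()]
        assert len(set(names)) == 54


class TestTopology:
    def test_long_exon_flag(self, two_exon_model):
        # exon [300,750) is 450 bp > 400
        vec = topology_features(site(400), two_exon_model)
        names = [s.name for s in default_registry()]
        assert vec[names.index("dummy_long_exon400")] == 1
        assert vec[names.index("dummy_exon")] == 1

    def test_short_exon_not_flagged(self, two_exon_model):
        vec = topology_features(site(150), two_exon_model)
        assert vec[7] == 0  # first exon is 100 bp

    def test_intron_site_flags(self, two_exon_model):
        vec = topology_features(site(250), two_exon_model)
        assert vec[4] == 1  # intron flag
        assert vec[0] == vec[1] == vec[2] == vec[3] == 0
        assert np.all(vec[15:18] == 0)  # no UTR/CDS relative position
        assert vec[18] > 0  # transcript-span position still defined

    def test_full_transcript_relative_position(self):
        model = TranscriptModel(
            gene_id="g", transcript_id="t", chrom="chr1", strand="+",
            exons=[(100, 200), (300, 450)],
        )
        vec = topology_features(site(150), model)
        assert vec[18] == pytest.approx(50 / 250)

    def test_unassigned_site_is_all_zero(self):
        assert np.all(topology_features(site(5), None) == 0)

    def test_dummies_are_binary_and_relpos_in_unit_interval(self, two_exon_model):
        for pos in (110, 150, 250, 320, 700, 749):
            vec = topology_features(site(pos), two_exon_model)
            assert set(vec[:15]) <= {0.0, 1.0}
            assert np.all((vec[15:19] >= 0) & (vec[15:19] <= 1))
            assert np.all(vec[19:] >= 0)

    def test_strand_symmetry_under_mirroring(self, two_exon_model):
        """Mirroring the coordinate system and flipping strand leaves
        every topology feature unchanged."""
        L = 1000
        mirrored = TranscriptModel(
            gene_id="g", transcript_id="t", chrom="chr1", strand="-",
            exons=[(L - b, L - a) for a, b in two_exon_model.exons],
            cds=[(L - b, L - a) for a, b in two_exon_model.cds],
        )
        for pos in (110, 150, 250, 320, 700):
            fwd = topology_features(site(pos), two_exon_model)
            rev = topology_features(site(L - 1 - pos, strand="-"), mirrored)
            assert fwd == pytest.approx(rev)


class TestDistances:
    def test_splice_junction_distances_worked_example(self):
        model = TranscriptModel(
            gene_id="g", transcript_id="t", chrom="chr1", strand="+",
            exons=[(100, 200), (300, 450)],
        )
        vec = distance_features(site(150), model, None)
        assert vec[0] == pytest.approx(math.log2(1 + 50))
        assert vec[1] == pytest.approx(math.log2(1 + 49))

    def test_single_exon_transcript_has_no_junction_distances(self):
        model = TranscriptModel(
            gene_id="g", transcript_id="t", chrom="chr1", strand="+",
            exons=[(100, 400)],
        )
        vec = distance_features(site(150), model, None)
        assert vec[0] == 0 and vec[1] == 0

    def test_nearest_conserved_site_linear_scan(self):
        index = ConservedSiteIndex([
            site(1000, sid="c1"), site(5000, sid="c2")
        ])
        vec = distance_features(site(1100, sid="q"), None, index)
        assert vec[2] == pytest.approx(math.log2(1 + 100))
        assert vec[3] == 1.0  # 100 < 2000

    def test_query_site_excludes_itself(self):
        index = ConservedSiteIndex([site(1000, sid="self")])
        vec = distance_features(site(1000, sid="self"), None, index)
        assert vec[2] == 0 and vec[3] == 0

    def test_far_site_not_flagged_near(self):
        index = ConservedSiteIndex([site(10_000, sid="c")])
        vec = distance_features(site(1000, sid="q"), None, index)
        assert vec[3] == 0.0


class TestTracks:
    def test_constant_conservation_over_window(self, tmp_path):
        bg = tmp_path / "cons.bedGraph"
        bg.write_text("chr1\t0\t10000\t0.8\n")
        tracks = TrackSet(conservation=ConservationTrack.from_bedgraph(bg))
        cons, reg, omics = track_features(site(500), 20, tracks)
        assert cons[0] == pytest.approx(0.8)
        assert cons[1] == pytest.approx(0.8)

    def test_uncovered_window_positions_count_as_zero(self, tmp_path):
        bg = tmp_path / "cons.bedGraph"
        # cover only the site base within a 5-base window
        bg.write_text("chr1\t500\t501\t1.0\n")
        tracks = TrackSet(conservation=ConservationTrack.from_bedgraph(bg))
        cons, _, _ = track_features(site(500), 2, tracks)
        assert cons[0] == 1.0
        assert cons[1] == pytest.approx(1 / 5)

    def test_interval_overlap_sets_slot(self, tmp_path):
        bed = tmp_path / "reg.bed"
        bed.write_text("chr1\t490\t510\n")
        tracks = TrackSet(regulators=[IntervalTrack.from_bed(bed)])
        _, reg, _ = track_features(site(500), 20, tracks)
        assert reg[0] == 1.0 and np.all(reg[1:] == 0)

    def test_no_tracks_configured_yields_zeros(self):
        cons, reg, omics = track_features(site(500), 20, None)
        assert not cons.any() and not reg.any() and not omics.any()


class TestStructureFeatures:
    def test_unpairable_window(self):
        w = SequenceWindow(site_id="s", bases="AAAAAAAAA")
        vec = structure_features(w)
        assert vec[0] == 0.0 and vec[1] == 1.0

    def test_hairpin_pairing_fraction(self):
        w = SequenceWindow(site_id="s", bases="GGGGAAACCCC")
        vec = structure_features(w)
        assert vec[0] == pytest.approx(8 / 11)

    def test_supplied_dotbracket_overrides_fold(self):
        w = SequenceWindow(site_id="s", bases="GGGAAACCC")
        vec = structure_features(w, dotbracket=".........")
        assert vec[0] == 0.0 and vec[1] == 1.0

    def test_n_window_zeroed(self):
        w = SequenceWindow(site_id="s", bases="GGNGAAACC")
        assert np.all(structure_features(w) == 0)


class TestGeneLevel:
    def test_z_score_of_host_transcript_gc(self):
        # transcripts with GC 0.4 / 0.5 / 0.6; host is the 0.6 one
        genome = {"chr1": "ATGCGCATAT" + "ATGCGCGTAT" + "ATGCGCGCAT"}
        models = {
            f"g{i}": TranscriptModel(
                gene_id=f"g{i}", transcript_id=f"t{i}", chrom="chr1",
                strand="+", exons=[(10 * i, 10 * i + 10)],
            )
            for i in range(3)
        }
        stats = compute_transcriptome_stats(models, genome)
        assert stats.tx_gc_mean == pytest.approx(0.5)
        assert stats.tx_gc_sd == pytest.approx(0.1)
        w = SequenceWindow(site_id="s", bases="AUAUA")  # GC 0 -> big negative z
        vec = gene_level_features(site(25), models["g2"], stats, genome, w)
        assert vec[7] == pytest.approx(1.0)  # (0.6 - 0.5) / 0.1

    def test_single_exon_single_isoform_log_counts_are_zero(self):
        genome = {"chr1": "A" * 100}
        model = TranscriptModel(gene_id="g", transcript_id="t", chrom="chr1",
                                strand="+", exons=[(10, 60)])
        stats = TranscriptomeStats(0.5, 0.1, 0.5, 0.1)
        w = SequenceWindow(site_id="s", bases="AUAUA")
        vec = gene_level_features(site(20), model, stats, genome, w)
        assert vec[0] == 0.0 and vec[1] == 0.0  # log2(1)

    def test_zero_sd_yields_zero_z(self):
        genome = {"chr1": "A" * 100}
        model = TranscriptModel(gene_id="g", transcript_id="t", chrom="chr1",
                                strand="+", exons=[(10, 60)])
        stats = TranscriptomeStats(0.5, 0.0, 0.5, 0.0)
        w = SequenceWindow(site_id="s", bases="GCGCG")
        vec = gene_level_features(site(20), model, stats, genome, w)
        assert vec[5] == 0.0 and vec[7] == 0.0


class TestFeaturize:
    def test_combined_vector_has_218_columns(self, small_dataset):
        assert small_dataset.features.shape[1] == 4 * 41 + 54

    def test_genomic_only_has_54_columns(self, small_bundle):
        from m6aconserve.pipeline import FeatureConfig, prepare_dataset

        data = prepare_dataset(
            small_bundle.genome_fa, small_bundle.gtf, small_bundle.sites_bed,
            small_bundle.profiles_tsv, seed=11,
            feature_config=FeatureConfig(sequence_strategy="none"),
        )
        assert data.features.shape[1] == 54

    def test_empty_site_list_gives_empty_frame(self):
        out = featurize([], {}, {"chr1": "ACGT" * 100})
        assert out.empty

    def test_permuting_sites_permutes_rows_only(self, small_bundle):
        from m6aconserve.pipeline import open_genome
        from m6aconserve.sites import read_sites_bed
        from m6aconserve.transcripts import build_transcript_models

        genome = open_genome(small_bundle.genome_fa)
        models = build_transcript_models(small_bundle.gtf)
        sites = read_sites_bed(small_bundle.sites_bed)[:12]
        a = featurize(sites, models, genome)
        b = featurize(list(reversed(sites)), models, genome)
        pd.testing.assert_frame_equal(a, b.loc[a.index])

    def test_registry_must_have_54_slots(self, small_bundle):
        with pytest.raises(ValueError, match="54"):
            featurize([], {}, {"chr1": "ACGT"}, registry=default_registry()[:10])

    def test_slot_ranges_on_real_matrix(self, small_dataset):
        feats = small_dataset.features
        names = [s.name for s in default_registry()]
        dummies = feats[[n for n in names if n.startswith("dummy_")]]
        assert dummies.isin([0.0, 1.0]).all().all()
        relpos = feats[[n for n in names if n.startswith("relpos_")]]
        assert ((relpos >= 0) & (relpos <= 1)).all().all()
        lengths = feats[[n for n in names if n.startswith(("len_", "dist_"))]]
        assert (lengths >= 0).all().all()


class TestMinMax:
    def test_direct_formula(self):
        train = pd.DataFrame({"f": [2.0, 4.0, 6.0]})
        scaler = fit_minmax(train)
        out = apply_minmax(scaler, train)
        assert out["f"].tolist() == [0.0, 0.5, 1.0]

    def test_constant_feature_maps_to_zero(self):
        train = pd.DataFrame({"f": [3.0, 3.0, 3.0]})
        out = apply_minmax(fit_minmax(train), train)
        assert out["f"].tolist() == [0.0, 0.0, 0.0]

    def test_out_of_range_test_values_clamp(self):
        scaler = fit_minmax(pd.DataFrame({"f": [2.0, 6.0]}))
        out = apply_minmax(scaler, pd.DataFrame({"f": [8.0, 0.0]}))
        assert out["f"].tolist() == [1.0, 0.0]

    def test_unfitted_scaler_rejected(self):
        from sklearn.exceptions import NotFittedError
        from sklearn.preprocessing import MinMaxScaler

        with pytest.raises(NotFittedError):
            apply_minmax(MinMaxScaler(clip=True),
                         pd.DataFrame({"f": [1.0]}))

    def test_column_mismatch_rejected(self):
        scaler = fit_minmax(pd.DataFrame({"f": [1.0, 2.0]}))
        with pytest.raises(ValueError, match="columns"):
            apply_minmax(scaler, pd.DataFrame({"g": [1.0]}))
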