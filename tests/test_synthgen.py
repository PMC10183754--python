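"""Generator contracts: determinism, Poisson statistics, exact read/UMI truth."""

import numpy as np
import pandas as pd
import pytest

from specklesplice import splicejx
from specklesplice.synthgen import (
    PlacementError,
    SceneSpec,
    UMIProfile,
    generate_fish_scene,
    generate_junction_reads,
    generate_umi_matrix,
)

from conftest import small_scene_spec


class TestFishScene:
    def test_empty_scene_has_no_cells_and_noise_only_dapi(self):
        spec = small_scene_spec(n_cells=0, image_height_px=256, image_width_px=256)
        bundle, truth = generate_fish_scene(spec)
        assert truth.n_cells == 0
        assert truth.counts_frame().empty
        dapi = bundle.channels["DAPI"]
        # pure read-out noise: no pixel anywhere near the nucleus amplitude
        assert dapi.max() < spec.dapi_amplitude / 10

    def test_poisson_spot_counts_match_rate(self):
        spec = SceneSpec(n_cells=100, channel_rates={"KCC2": 20.0}, seed=7)
        _, truth = generate_fish_scene(spec)
        counts = [c.count("KCC2") for c in truth.cells]
        se = np.sqrt(20.0 / 100)
        assert abs(np.mean(counts) - 20.0) < 3 * se

    def test_noiseless_spots_peak_at_ground_truth_positions(self):
        from skimage.feature import peak_local_max

        spec = small_scene_spec(
            n_cells=1,
            image_height_px=400,
            image_width_px=400,
            channel_rates={"KCC2": 3.0},
            noise_sd=0.0,
            seed=1,
        )
        bundle, truth = generate_fish_scene(spec)
        true_coords = truth.cells[0].spots["KCC2"]
        assert len(true_coords) > 0
        peaks = peak_local_max(
            bundle.channels["KCC2"], min_distance=2, threshold_abs=100.0
        )
        assert len(peaks) == len(true_coords)
        for tr, tc in true_coords:
            nearest = np.min(np.hypot(peaks[:, 0] - tr, peaks[:, 1] - tc))
            assert nearest <= 1.0

    def test_identical_spec_and_seed_bit_identical(self):
        spec = small_scene_spec(seed=3)
        b1, t1 = generate_fish_scene(spec)
        b2, t2 = generate_fish_scene(spec)
        for ch in b1.channels:
            np.testing.assert_array_equal(b1.channels[ch], b2.channels[ch])
        pd.testing.assert_frame_equal(t1.counts_frame(), t2.counts_frame())

    def test_ground_truth_spots_inside_image_and_counts_consistent(self, small_scene):
        spec, _, truth = small_scene
        for cell in truth.cells:
            for ch, coords in cell.spots.items():
                assert cell.count(ch) == len(coords)
                if len(coords):
                    assert coords[:, 0].min() >= 0
                    assert coords[:, 0].max() < spec.image_height_px
                    assert coords[:, 1].min() >= 0
                    assert coords[:, 1].max() < spec.image_width_px

    def test_impossible_packing_raises_placement_error(self):
        spec = small_scene_spec(
            n_cells=30, image_height_px=300, image_width_px=300
        )
        with pytest.raises(PlacementError, match="spacing"):
            generate_fish_scene(spec)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            small_scene_spec(channel_rates={"KCC2": -1.0}).validate()


class TestJunctionReads:
    FIG_COUNTS = [((200, 400), 44), ((200, 300), 14)]

    @pytest.mark.parametrize("emit", ["sam", "tsv"])
    def test_round_trip_recovers_counts_exactly(self, tmp_path, emit):
        suffix = ".sam" if emit == "sam" else ".tsv"
        path = tmp_path / f"jx{suffix}"
        generate_junction_reads(self.FIG_COUNTS, path, emit=emit)
        df = splicejx.extract_junctions(path)
        recovered = {
            (int(r.intron_start), int(r.intron_end)): int(r.n_reads)
            for r in df.itertuples()
        }
        assert recovered == {(200, 400): 44, (200, 300): 14}

    @pytest.mark.parametrize("emit", ["sam", "tsv"])
    def test_empty_input_gives_valid_empty_file(self, tmp_path, emit):
        suffix = ".sam" if emit == "sam" else ".tsv"
        path = tmp_path / f"empty{suffix}"
        generate_junction_reads([], path, emit=emit)
        assert splicejx.extract_junctions(path).empty

    def test_sam_cigar_gap_spans_exactly_the_intron(self, tmp_path):
        import pysam

        path = tmp_path / "one.sam"
        generate_junction_reads([((200, 400), 1)], path, emit="sam", flank_len=50)
        with pysam.AlignmentFile(str(path)) as fh:
            reads = list(fh.fetch(until_eof=True))
        assert len(reads) == 1
        (read,) = reads
        assert read.reference_start == 150
        ops = read.cigartuples
        assert ops == [(0, 50), (3, 200), (0, 50)]  # 50M 200N 50M

    def test_invalid_intervals_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_junction_reads([((400, 400), 3)], tmp_path / "bad.tsv", emit="tsv")
        with pytest.raises(ValueError):
            generate_junction_reads([((100, 200), -1)], tmp_path / "bad.tsv", emit="tsv")


class TestUMIMatrix:
    def test_zero_mean_gene_yields_zero_counts(self):
        profiles = {
            "only": UMIProfile(n_cells=1, gene_means={"Slc12a2": 0.0}, total_umi_mean=1000)
        }
        matrix, genes, ann = generate_umi_matrix(profiles, seed=0)
        assert matrix[genes.index("Slc12a2"), 0] == 0

    def test_type_specific_rates_order_downstream_expression(self):
        from specklesplice import scharmonize

        profiles = {
            "OL": UMIProfile(500, {"Slc12a2": 5.0}, 10_000),
            "neuron": UMIProfile(500, {"Slc12a2": 0.5}, 10_000),
        }
        matrix, genes, ann = generate_umi_matrix(profiles, seed=3)
        records = scharmonize.expression_records(matrix, genes, ann, "Slc12a2")
        means = records.groupby("cell_type")["ln_tpm1"].mean()
        assert means["OL"] > means["neuron"]

    def test_determinism(self):
        profiles = {"t": UMIProfile(40, {"g": 2.0}, 500)}
        m1, _, _ = generate_umi_matrix(profiles, seed=9)
        m2, _, _ = generate_umi_matrix(profiles, seed=9)
        assert (m1 != m2).nnz == 0

    def test_empty_profile_map_rejected(self):
        with pytest.raises(ValueError):
            generate_umi_matrix({}, seed=0)

    def test_realized_means_near_spec(self):
        profiles = {"t": UMIProfile(400, {"g": 5.0}, 2_000)}
        matrix, genes, _ = generate_umi_matrix(profiles, seed=5)
        realized = matrix[genes.index("g")].toarray().mean()
        assert abs(realized - 5.0) < 4 * np.sqrt(5.0 / 400)
        totals = np.asarray(matrix.sum(axis=0)).ravel()
        assert abs(totals.mean() - 2_000) < 4 * np.sqrt(2_000 / 400)
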