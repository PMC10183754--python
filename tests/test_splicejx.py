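"""Junction extraction, template classification and variant fractions."""

import numpy as np
import pandas as pd
import pysam
import pytest

from specklesplice.splicejx import (
    ExonModel,
    VariantFractions,
    classify_junctions,
    compute_variant_fractions,
    extract_junctions,
    read_star_sj_tab,
    variant_fractions_by_sample,
)
from specklesplice.synthgen import generate_junction_reads


@pytest.fixture()
def toy_model():
    # cassette exon of 48 nt (16 codons) flanked by two constitutive exons
    return ExonModel(
        chrom="chr18",
        strand="+",
        exons=((100, 200), (300, 348), (400, 500)),
        focal_index=1,
    )


def make_sam(tmp_path, reads):
    """reads: list of (pos, cigar string). Returns the SAM path."""
    path = tmp_path / "reads.sam"
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr18", "LN": 10_000}]}
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for i, (pos, cigar) in enumerate(reads):
            a = pysam.AlignedSegment(fh.header)
            a.query_name = f"r{i}"
            a.reference_id = 0
            a.reference_start = pos
            a.cigarstring = cigar
            a.query_sequence = "A" * a.infer_query_length()
            a.mapping_quality = 60
            fh.write(a)
    return path


class TestExtraction:
    def test_single_gap_cigar_walk(self, tmp_path):
        path = make_sam(tmp_path, [(100, "20M100N20M")])
        df = extract_junctions(path)
        assert df.to_dict("records") == [
            {"chrom": "chr18", "intron_start": 120, "intron_end": 220, "n_reads": 1}
        ]

    def test_ungapped_read_contributes_nothing(self, tmp_path):
        path = make_sam(tmp_path, [(100, "40M")])
        assert extract_junctions(path).empty

    def test_two_gap_read_counts_both_junctions(self, tmp_path):
        path = make_sam(tmp_path, [(1000, "10M50N10M60N10M")])
        df = extract_junctions(path)
        got = {(r.intron_start, r.intron_end) for r in df.itertuples()}
        assert got == {(1010, 1060), (1070, 1130)}
        assert (df["n_reads"] == 1).all()

    def test_deletions_and_insertions_shift_gap_correctly(self, tmp_path):
        # 10M 2D 5M 100N 10M with 3I: D consumes reference, I does not
        path = make_sam(tmp_path, [(500, "10M2D3I5M100N10M")])
        df = extract_junctions(path)
        assert (df["intron_start"].iloc[0], df["intron_end"].iloc[0]) == (517, 617)

    def test_region_filter(self, tmp_path):
        path = make_sam(tmp_path, [(100, "20M100N20M"), (2000, "20M50N20M")])
        df = extract_junctions(path, region=("chr18", 0, 1000))
        assert len(df) == 1
        assert df["intron_start"].iloc[0] == 120

    def test_counts_aggregate_per_interval(self, tmp_path):
        path = make_sam(tmp_path, [(100, "20M100N20M")] * 5)
        df = extract_junctions(path)
        assert len(df) == 1
        assert df["n_reads"].iloc[0] == 5

    def test_star_sj_tab_coordinates_converted(self, tmp_path):
        sj = tmp_path / "SJ.out.tab"
        # STAR: intron first/last base 1-based closed -> (200, 400) half-open
        sj.write_text("chr18\t201\t400\t1\t1\t1\t44\t3\t25\n")
        df = read_star_sj_tab(sj)
        assert (df["intron_start"].iloc[0], df["intron_end"].iloc[0]) == (200, 400)
        assert df["n_reads"].iloc[0] == 44


class TestClassification:
    def test_templates(self, toy_model):
        df = pd.DataFrame(
            {
                "chrom": ["chr18"] * 4,
                "intron_start": [200, 200, 348, 150],
                "intron_end": [400, 300, 400, 450],
                "n_reads": [4, 3, 2, 1],
            }
        )
        out = classify_junctions(df, toy_model)
        assert list(out["jx_class"]) == ["skip", "include_5p", "include_3p", "other"]

    def test_wrong_chromosome_is_other(self, toy_model):
        df = pd.DataFrame(
            {"chrom": ["chr1"], "intron_start": [200], "intron_end": [400], "n_reads": [1]}
        )
        assert classify_junctions(df, toy_model)["jx_class"].iloc[0] == "other"

    def test_classification_conserves_reads(self, toy_model, tmp_path):
        counts = [((200, 400), 44), ((200, 300), 14), ((348, 400), 14), ((150, 450), 7)]
        path = generate_junction_reads(counts, tmp_path / "jx.sam", emit="sam")
        out = classify_junctions(extract_junctions(path), toy_model)
        assert out["n_reads"].sum() == sum(n for _, n in counts)

    def test_focal_exon_length_is_sixteen_codons(self, toy_model):
        assert toy_model.focal_length == 48

    def test_model_validation(self):
        with pytest.raises(ValueError):
            ExonModel("chr18", "+", ((100, 200), (300, 348)), focal_index=1)
        with pytest.raises(ValueError):
            ExonModel("chr18", "+", ((100, 200), (150, 348), (400, 500)), 1)

    def test_bed_round_trip(self, toy_model, tmp_path):
        bed = tmp_path / "model.bed"
        lines = [
            f"chr18\t{s}\t{e}\texon{i}\t0\t+" for i, (s, e) in enumerate(toy_model.exons)
        ]
        bed.write_text("\n".join(lines) + "\n")
        loaded = ExonModel.from_bed(bed, focal_index=1)
        assert loaded.exons == toy_model.exons
        assert loaded.skip_template == toy_model.skip_template


class TestVariantFractions:
    @pytest.mark.parametrize(
        "n_skip,n_include,pa,pb",
        [
            (44, 14, 24, 76),   # neuron pooled evidence
            (116, 291, 71, 29),  # oligodendrocyte pooled evidence
            (2, 64, 97, 3),     # astrocyte pooled evidence
        ],
    )
    def test_percentages_from_counts(self, n_skip, n_include, pa, pb):
        vf = VariantFractions(n_skip=n_skip, n_include=n_include)
        assert (vf.percent_a, vf.percent_b) == (pa, pb)
        assert vf.frac_a + vf.frac_b == pytest.approx(1.0)
        assert vf.percent_a + vf.percent_b == 100

    def test_five_prime_and_mean_agree_with_equal_flanks(self, toy_model, tmp_path):
        counts = [((200, 400), 10), ((200, 300), 6), ((348, 400), 6)]
        path = generate_junction_reads(counts, tmp_path / "jx.tsv", emit="tsv")
        jx = classify_junctions(extract_junctions(path), toy_model)
        five = compute_variant_fractions(jx, "five_prime")
        mean = compute_variant_fractions(jx, "mean")
        assert five == mean
        both = compute_variant_fractions(jx, "sum")
        assert both.n_include == 12

    def test_zero_evidence_warns_and_returns_none(self, toy_model):
        df = pd.DataFrame(
            {"chrom": ["chr18"], "intron_start": [150], "intron_end": [450],
             "n_reads": [5], "jx_class": ["other"]}
        )
        with pytest.warns(UserWarning):
            assert compute_variant_fractions(df) is None

    def test_per_sample_and_pooled_table(self, toy_model, tmp_path):
        frames = {}
        for name, (skip, inc) in {"N1": (30, 10), "N2": (14, 4)}.items():
            counts = [((200, 400), skip), ((200, 300), inc), ((348, 400), inc)]
            path = generate_junction_reads(counts, tmp_path / f"{name}.tsv", emit="tsv")
            frames[name] = classify_junctions(extract_junctions(path), toy_model)
        table = variant_fractions_by_sample(frames)
        pooled = table.set_index("sample_id").loc["pooled"]
        assert pooled["n_skip"] == 44
        assert pooled["n_include"] == 14
        assert pooled["percent_b"] == 76
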