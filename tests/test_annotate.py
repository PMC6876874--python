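"""Region classification and per-class digestion metrics."""

import numpy as np
import pytest

from redigest import (
    FragmentSet,
    RefractoryRegion,
    RegionSet,
    classify_regions,
    fragment_length_per_class,
    get_panel,
    observed_fragment_lengths,
    read_bed,
    scan_genome,
    site_density_per_class,
)
from redigest.annotate import read_template_intervals
from redigest.simulate import random_sequence


def track(name, *intervals):
    rs = RegionSet(name)
    for chrom, s, e, *label in intervals:
        rs.add(chrom, s, e, label[0] if label else None)
    rs.sort()
    return rs


class TestClassifyRegions:
    def test_multi_label_any_overlap(self):
        regions = [RefractoryRegion("c", 0, 2000)]
        tracks = {
            "gap": track("gap", ("c", 500, 600)),
            "repeat": track("repeat", ("c", 1500, 1600)),
            "blacklist": track("blacklist", ("c", 5000, 6000)),
        }
        summary = classify_regions(regions, tracks)
        assert regions[0].labels == {"gap", "repeat"}
        assert summary.per_label == {"gap": 1, "repeat": 1, "blacklist": 0}
        assert summary.unique == 0

    def test_no_overlap_counts_as_unique(self):
        regions = [RefractoryRegion("c", 0, 2000)]
        summary = classify_regions(regions, {"gap": track("gap", ("c", 3000, 4000))})
        assert summary.unique == 1 and regions[0].labels == set()

    def test_single_bp_overlap_counts(self):
        regions = [RefractoryRegion("c", 0, 2000)]
        summary = classify_regions(regions, {"gap": track("gap", ("c", 1999, 2050))})
        assert summary.per_label["gap"] == 1

    def test_half_open_abutting_does_not_count(self):
        regions = [RefractoryRegion("c", 0, 2000)]
        summary = classify_regions(regions, {"gap": track("gap", ("c", 2000, 2100))})
        assert summary.unique == 1

    def test_empty_track_set_errors(self):
        with pytest.raises(ValueError, match="tracks"):
            classify_regions([RefractoryRegion("c", 0, 10)], {})

    def test_missing_chromosome_warns(self, caplog):
        regions = [RefractoryRegion("cX", 0, 10)]
        with caplog.at_level("WARNING"):
            classify_regions(regions, {"gap": track("gap", ("c1", 0, 5))})
        assert "cX" in caplog.text

    def test_brute_force_overlap_oracle(self, rng):
        # randomized fixture vs all-pairs intersection
        for _ in range(10):
            regions = [
                RefractoryRegion("c", int(s), int(s) + int(l))
                for s, l in zip(
                    rng.integers(0, 50_000, 200), rng.integers(1, 3000, 200)
                )
            ]
            tracks = {}
            for name in ("gap", "blacklist", "repeat"):
                ivs = [
                    ("c", int(s), int(s) + int(l))
                    for s, l in zip(
                        rng.integers(0, 50_000, 100), rng.integers(1, 2000, 100)
                    )
                ]
                tracks[name] = track(name, *ivs)
            summary = classify_regions(regions, tracks)
            truth_labels = []
            for r in regions:
                labels = {
                    name
                    for name, t in tracks.items()
                    if any(
                        r.start < e and s < r.end
                        for _, ivlist in t.intervals.items()
                        for s, e, _ in ivlist
                    )
                }
                truth_labels.append(labels)
            assert [r.labels for r in regions] == truth_labels
            assert summary.unique == sum(1 for l in truth_labels if not l)
            for name in tracks:
                assert summary.per_label[name] == sum(
                    1 for l in truth_labels if name in l
                )
            # label-count arithmetic: unique + labelled = total
            assert summary.unique + sum(1 for l in truth_labels if l) == summary.total
            assert sum(summary.per_label.values()) >= summary.total - summary.unique


class TestSiteDensity:
    def test_arithmetic(self):
        index = scan_genome(
            {"c": "AGCT" * 2 + "T" * 2008}, get_panel(["AluI"])
        )
        states = track("s", ("c", 0, 2000, "left"))
        df = site_density_per_class(index, states).set_index("class")
        assert df.loc["left", "n_sites"] == 2
        assert df.loc["left", "sites_per_kb"] == 1.0

    def test_zero_site_class(self):
        index = scan_genome({"c": "T" * 1000}, get_panel(["AluI"]))
        df = site_density_per_class(index, track("s", ("c", 0, 1000, "x")))
        assert df.loc[0, "sites_per_kb"] == 0.0

    def test_density_matches_analytic_oracle(self, rng):
        n = 1_000_000
        seq = random_sequence(rng, n)
        index = scan_genome({"c": seq}, get_panel(["AluI"]))
        df = site_density_per_class(index, track("s", ("c", 0, n, "all")))
        p = 0.25 ** 4
        se = 1000 * np.sqrt(n * p * (1 - p)) / n
        assert abs(df.loc[0, "sites_per_kb"] - 1000 * p) < 3 * se

    def test_merging_invariance(self):
        index = scan_genome({"c": "T" * 10 + "AGCT" + "T" * 86}, get_panel(["AluI"]))
        overlapping = track("s", ("c", 0, 60, "x"), ("c", 40, 100, "x"))
        merged = track("s", ("c", 0, 100, "x"))
        a = site_density_per_class(index, overlapping)
        b = site_density_per_class(index, merged)
        assert a.equals(b)

    def test_exclusions(self):
        index = scan_genome({"c": "T" * 100}, get_panel(["AluI"]))
        states = track("s", ("c", 0, 50, "14"), ("c", 50, 100, "1"))
        df = site_density_per_class(index, states, excluded_labels=["14"])
        assert df["class"].tolist() == ["1"]
        with pytest.raises(ValueError, match="exclusions"):
            site_density_per_class(index, states, excluded_labels=["1", "14"])


class TestFragmentLengthPerClass:
    def test_midpoint_assignment(self, toy_track):
        fs = FragmentSet.from_sites({"chr1": 3000}, {"chr1": [100, 300]})
        # fragments [0,100) mid 50, [100,300) mid 200, [300,3000) mid 1650
        df = fragment_length_per_class(fs, toy_track).set_index("class")
        assert df.loc["S1", "n_fragments"] == 2
        assert df.loc["S1", "mean_bp"] == 150.0
        # S2 contains the midpoint of the big fragment
        assert df.loc["S2", "n_fragments"] == 1
        assert df.loc["S2", "median_bp"] == 2700.0

    def test_enclosing_fragment_convention_for_empty_class(self, toy_track):
        fs = FragmentSet.from_sites({"chr1": 3000}, {"chr1": []})
        # single 3000 bp fragment, midpoint 1500 -> only S2 gets it directly;
        # S1 and S3 fall back to the enclosing fragment's length
        df = fragment_length_per_class(fs, toy_track).set_index("class")
        assert df.loc["S1", "median_bp"] == 3000.0
        assert df.loc["S3", "median_bp"] == 3000.0

    def test_partition_counts(self, rng):
        # classes partitioning the chromosome see every fragment exactly once
        n = 30_000
        sites = np.unique(rng.integers(1, n, 300)).tolist()
        fs = FragmentSet.from_sites({"chr1": n}, {"chr1": sites})
        states = track(
            "s", ("chr1", 0, 10_000, "a"), ("chr1", 10_000, 21_000, "b"),
            ("chr1", 21_000, n, "c")
        )
        df = fragment_length_per_class(fs, states)
        assert df["n_fragments"].sum() == fs.n_fragments()


class TestObservedLengths:
    def test_median_by_midpoint(self, toy_track):
        templates = [("chr1", 100, 200), ("chr1", 300, 500), ("chr1", 1200, 1300)]
        df = observed_fragment_lengths(templates, toy_track).set_index("class")
        assert df.loc["S1", "median_bp"] == 150.0
        assert df.loc["S2", "n_templates"] == 1

    def test_straddling_template_assigned_by_midpoint_only(self, toy_track):
        # template spans S1/S2 boundary; midpoint 990 is in S1
        df = observed_fragment_lengths([("chr1", 960, 1020)], toy_track)
        by = df.set_index("class")
        assert by.loc["S1", "n_templates"] == 1
        assert by.loc["S2", "n_templates"] == 0

    def test_bedpe_reader_outermost_coordinates(self, tmp_path):
        path = tmp_path / "frags.bedpe"
        path.write_text(
            "chr1\t100\t150\tchr1\t250\t300\n"  # template [100,300)
            "chr1\t10\t60\tchr2\t100\t150\n"    # interchromosomal -> malformed
            "chr1\t400\t450\tchr1\t500\t550\n"
        )
        with pytest.raises(ValueError, match="malformed"):
            read_template_intervals(path)
        templates, bad = read_template_intervals(path, max_malformed_fraction=0.5)
        assert bad == 1
        assert templates == [("chr1", 100, 300), ("chr1", 400, 550)]

    def test_bed_reader(self, tmp_path):
        path = tmp_path / "frags.bed"
        path.write_text("chr1\t100\t250\tt1\t0\t+\nchr1\t400\t500\tt2\t0\t-\n")
        templates, bad = read_template_intervals(path)
        assert bad == 0
        assert templates == [("chr1", 100, 250), ("chr1", 400, 500)]


class TestBedIO:
    def test_read_bed_with_labels_and_normalization(self, tmp_path):
        path = tmp_path / "states.bed"
        path.write_text(
            "track name=states\nchr1\t0\t100\t1_Active\nchr1\t100\t200\t14_Repeat\n"
        )
        rs = read_bed(path, "states", use_name_column=True, normalize_chroms=True)
        assert rs.labels() == ["14_Repeat", "1_Active"]
        assert set(rs.intervals) == {"1"}

    def test_read_bed_errors(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t100\n")
        with pytest.raises(ValueError, match="3 BED columns"):
            read_bed(path)

    def test_class_length_merges_overlaps(self):
        rs = track("t", ("c", 0, 100), ("c", 50, 150))
        assert rs.class_length() == 150
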