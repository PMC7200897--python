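import numpy as np
import pytest

from exofold import (
    BindingProfile,
    GenomeLayout,
    Read1,
    SimConfig,
    TrimmedRead,
    background_normalize,
    combine_strands,
    coverage_by_strand,
    deduplicate,
    extract_read1,
    merge_replicates,
    read_wig,
    simulate_signal,
    trim_reads,
    write_wig,
)


def tiny_profile(values, normalized=False):
    layout = GenomeLayout({"chr1": len(values)})
    return BindingProfile(layout, {"chr1": np.asarray(values, float)},
                          normalized=normalized)


class TestCoverage:
    def test_single_plus_read(self, mini_layout):
        fwd, rev = coverage_by_strand(
            [TrimmedRead("chr1", "+", 100, 119)], mini_layout
        )
        v = fwd.values["chr1"]
        assert v[100:119].sum() == 19 and v.sum() == 19
        assert rev.values["chr1"].sum() == 0

    def test_overlap_adds(self, mini_layout):
        fwd, _ = coverage_by_strand(
            [TrimmedRead("chr1", "+", 100, 119), TrimmedRead("chr1", "+", 110, 129)],
            mini_layout,
        )
        v = fwd.values["chr1"]
        assert (v[110:119] == 2).all()
        assert (v[100:110] == 1).all() and (v[119:129] == 1).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_base_membership_oracle(self, mini_layout, seed):
        rng = np.random.default_rng(seed)
        starts = rng.integers(0, 9_900, size=1_000)
        widths = rng.integers(1, 60, size=1_000)
        ends = np.minimum(starts + widths, 10_000)
        strands = np.where(rng.integers(0, 2, size=1_000), "+", "-")
        reads = [
            TrimmedRead("chr1", s, int(a), int(b))
            for s, a, b in zip(strands, starts, ends)
        ]
        fwd, rev = coverage_by_strand(reads, mini_layout)
        pos = np.arange(10_000)
        for cov, strand in ((fwd, "+"), (rev, "-")):
            mask = strands == strand
            oracle = (
                (starts[mask][:, None] <= pos) & (pos < ends[mask][:, None])
            ).sum(axis=0)
            np.testing.assert_array_equal(cov.values["chr1"], oracle)

    def test_read_outside_layout(self, mini_layout):
        with pytest.raises(ValueError):
            coverage_by_strand([TrimmedRead("chr1", "+", 9_990, 10_010)], mini_layout)
        with pytest.raises(ValueError):
            coverage_by_strand([TrimmedRead("chrZ", "+", 0, 10)], mini_layout)


class TestCombineStrands:
    def test_definition(self):
        layout = GenomeLayout({"chr1": 3})
        from exofold import StrandCoverage

        f = StrandCoverage(layout, "+", {"chr1": np.array([0.0, 2.0, 3.0])})
        r = StrandCoverage(layout, "-", {"chr1": np.array([1.0, 0.0, 3.0])})
        prof = combine_strands(f, r)
        np.testing.assert_array_equal(prof.values["chr1"], [0, 0, 6])
        assert not prof.normalized

    def test_zero_strand_zeroes_profile(self, mini_layout):
        fwd, rev = coverage_by_strand(
            [TrimmedRead("chr1", "+", 0, 50)], mini_layout
        )
        prof = combine_strands(fwd, rev)
        assert prof.values["chr1"].sum() == 0

    def test_bounded_by_sum_and_zero_where_either_zero(self, mini_layout):
        rng = np.random.default_rng(2)
        reads = [
            TrimmedRead("chr1", "+" if rng.integers(2) else "-",
                        int(s), int(s) + 19)
            for s in rng.integers(0, 9_900, size=400)
        ]
        fwd, rev = coverage_by_strand(reads, mini_layout)
        prof = combine_strands(fwd, rev)
        f, r, v = fwd.values["chr1"], rev.values["chr1"], prof.values["chr1"]
        assert (v <= f + r).all()
        assert (v[(f == 0) | (r == 0)] == 0).all()
        both = (f > 0) & (r > 0)
        np.testing.assert_array_equal(v[both], (f + r)[both])

    def test_overlap_interval_from_planted_borders(self, clean_sim):
        """With jitterless borders at center +/- 9 and trim 19, the profile
        is nonzero exactly on [center-9, center+10)."""
        config, sim = clean_sim
        trimmed = trim_reads(extract_read1(sim.pairs), 19, config.layout)
        fwd, rev = coverage_by_strand(trimmed, config.layout)
        prof = combine_strands(fwd, rev)
        for _, s in sim.sites.iterrows():
            v = prof.values[s.chrom]
            (nz,) = np.nonzero(v)
            site_nz = nz[(nz > s.center - 100) & (nz < s.center + 100)]
            np.testing.assert_array_equal(
                site_nz, np.arange(s.center - 9, s.center + 10)
            )

    def test_layout_mismatch(self):
        from exofold import StrandCoverage

        a = StrandCoverage(GenomeLayout({"chr1": 3}), "+", {"chr1": np.zeros(3)})
        b = StrandCoverage(GenomeLayout({"chr1": 4}), "-", {"chr1": np.zeros(4)})
        with pytest.raises(ValueError):
            combine_strands(a, b)


class TestNormalization:
    def test_mean_becomes_one(self):
        prof = background_normalize(tiny_profile([2, 4, 6]))
        assert prof.background_mean == pytest.approx(4.0)
        assert prof.genome_mean() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(prof.values["chr1"], [0.5, 1.0, 1.5])

    def test_all_zero_warns_and_passes_through(self):
        with pytest.warns(UserWarning, match="all zero"):
            prof = background_normalize(tiny_profile([0, 0, 0]))
        assert prof.normalized and prof.values["chr1"].sum() == 0

    def test_scale_invariance(self):
        base = tiny_profile([0, 1, 5, 0, 2])
        scaled = tiny_profile(np.array([0, 1, 5, 0, 2]) * 7.3)
        np.testing.assert_allclose(
            background_normalize(base).values["chr1"],
            background_normalize(scaled).values["chr1"],
        )

    def test_library_size_difference_vanishes(self, layout):
        """Two replicates that differ only in depth normalize to the
        same genome mean of 1."""
        config = SimConfig(layout=layout, site_positions=[("chr1", 50_000)],
                           reads_per_site=100, seed=4)
        deep = SimConfig(layout=layout, site_positions=[("chr1", 50_000)],
                         reads_per_site=200, seed=5)
        for cfg in (config, deep):
            sim = simulate_signal(cfg)
            kept, _ = deduplicate(sim.pairs)
            trimmed = trim_reads(extract_read1(kept), 19, layout)
            prof = background_normalize(
                combine_strands(*coverage_by_strand(trimmed, layout))
            )
            assert prof.genome_mean() == pytest.approx(1.0, abs=1e-9)

    def test_double_normalization_rejected(self):
        prof = background_normalize(tiny_profile([1, 2, 3]))
        with pytest.raises(ValueError):
            background_normalize(prof)


class TestMergeReplicates:
    def test_pointwise_mean(self):
        a = tiny_profile([0, 2, 4], normalized=True)
        b = tiny_profile([2, 2, 0], normalized=True)
        np.testing.assert_array_equal(
            merge_replicates([a, b]).values["chr1"], [1, 2, 2]
        )

    def test_single_and_identical_replicates_are_identity(self):
        a = tiny_profile([0, 1, 3], normalized=True)
        np.testing.assert_array_equal(
            merge_replicates([a]).values["chr1"], a.values["chr1"]
        )
        np.testing.assert_array_equal(
            merge_replicates([a, a, a]).values["chr1"], a.values["chr1"]
        )

    def test_permutation_invariance(self):
        profs = [tiny_profile(np.arange(5) * k, normalized=True) for k in (1, 2, 5)]
        forward = merge_replicates(profs).values["chr1"]
        backward = merge_replicates(profs[::-1]).values["chr1"]
        np.testing.assert_array_equal(forward, backward)

    def test_unnormalized_input_rejected(self):
        a = tiny_profile([1, 2, 3], normalized=True)
        b = tiny_profile([1, 2, 3], normalized=False)
        with pytest.raises(ValueError):
            merge_replicates([a, b])


class TestWiggle:
    def test_one_based_shift(self, tmp_path):
        prof = tiny_profile(np.zeros(200), normalized=True)
        prof.values["chr1"][101] = 2.5
        path = tmp_path / "t.wig"
        write_wig(prof, path)
        lines = path.read_text().splitlines()
        assert "variableStep chrom=chr1 span=1" in lines
        assert "102\t2.5" in lines

    def test_empty_profile_is_headers_only(self, tmp_path):
        prof = tiny_profile(np.zeros(50), normalized=True)
        path = tmp_path / "t.wig"
        write_wig(prof, path)
        data_lines = [
            l for l in path.read_text().splitlines()
            if not (l.startswith("track") or l.startswith("variableStep"))
        ]
        assert data_lines == []

    @pytest.mark.parametrize("seed", range(5))
    def test_sparse_round_trip(self, tmp_path, layout, seed):
        rng = np.random.default_rng(seed)
        prof = BindingProfile(
            layout,
            {c: np.zeros(layout[c]) for c in layout},
            normalized=True,
        )
        for chrom in layout:
            idx = rng.choice(layout[chrom], size=300, replace=False)
            prof.values[chrom][idx] = rng.gamma(2.0, 3.0, size=300)
        path = tmp_path / "rt.wig"
        write_wig(prof, path)
        back = read_wig(path, layout)
        for chrom in layout:
            np.testing.assert_allclose(
                back.values[chrom], prof.values[chrom], rtol=1e-6
            )

    def test_malformed_line_reports_line_number(self, tmp_path, layout):
        path = tmp_path / "bad.wig"
        path.write_text("variableStep chrom=chr1 span=1\n5\tnot_a_number\n")
        with pytest.raises(ValueError, match=":2"):
            read_wig(path, layout)

    def test_data_before_header_is_an_error(self, tmp_path, layout):
        path = tmp_path / "bad.wig"
        path.write_text("5\t1.0\n")
        with pytest.raises(ValueError, match="variableStep"):
            read_wig(path, layout)


class TestArgmax:
    @pytest.mark.parametrize("seed", range(3))
    def test_planted_site_center_recovered(self, layout, seed):
        config = SimConfig(
            layout=layout,
            site_positions=[("chr1", 60_000)],
            footprint_bp=19,
            reads_per_site=150,
            border_jitter_sd=1.5,
            background_fraction=0.0,
            seed=seed,
        )
        sim = simulate_signal(config)
        trimmed = trim_reads(extract_read1(sim.pairs), 19, layout)
        prof = combine_strands(*coverage_by_strand(trimmed, layout))
        chrom, pos = prof.argmax()
        assert chrom == "chr1" and abs(pos - 60_000) <= 2
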