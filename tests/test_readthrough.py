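import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hibernaseq.core import CoverageTrack, GeneModel, InputError, make_design, TranscribedSegment
from hibernaseq.readthrough import (
    InsufficientDataError,
    FilterError,
    compute_tpm,
    compute_tts_extension,
    delta_days_below_threshold,
    elongation_rate,
    extension_table,
    mean_extension_difference,
    metagene_profile,
    quantify_gene_bodies,
    revise_annotation,
    round_to_sig_figs,
    tts_offset_distribution,
)
from hibernaseq.segmentation import call_transcribed_segments, pool_state_coverage
from hibernaseq.simulate import SimConfig, build_genome, simulate_nascent


def seg(start, end, strand="+", state="LT", chrom="chr1"):
    return TranscribedSegment(chrom, start, end, strand, state, 1.0)


def gene(start, end, strand="+", gid="g1", chrom="chr1"):
    return GeneModel(gene_id=gid, chrom=chrom, start=start, end=end, strand=strand)


class TestTtsExtension:
    def test_segment_ending_at_tts_gives_zero(self):
        rec = compute_tts_extension(gene(1000, 5000), [seg(1000, 5000)], "LT")
        assert rec is not None and rec.extension == 0

    def test_plus_strand_arithmetic(self):
        rec = compute_tts_extension(gene(1000, 5000), [seg(3000, 7500)], "LT")
        assert rec.extension == 2500

    def test_minus_strand_flip(self):
        # mirror of the plus case: TTS = start = 4000, segment reaches 1800
        rec = compute_tts_extension(gene(4000, 9000, "-"), [seg(1800, 6000, "-")], "LT")
        assert rec.extension == 2200

    def test_no_overlap_is_ineligible(self):
        assert compute_tts_extension(gene(1000, 5000), [seg(5500, 7000)], "LT") is None

    def test_wrong_strand_ineligible(self):
        assert compute_tts_extension(gene(1000, 5000), [seg(3000, 7500, "-")], "LT") is None


class TestOffsetDistribution:
    def test_all_segments_end_at_tts_spike_at_zero(self):
        genes = [gene(1000, 5000, gid="g1"), gene(8000, 9000, gid="g2")]
        by_state = {
            s: [seg(1000, 5000, state=s), seg(8000, 9000, state=s)] for s in ("ET", "LT")
        }
        hists, edges, used = tts_offset_distribution(genes, by_state, window=2000, bin_width=100)
        zero_bin = np.searchsorted(edges, 0, side="right") - 1
        for state in ("ET", "LT"):
            assert hists[state][zero_bin] == 2
            assert hists[state].sum() == 2
        assert used == ["g1", "g2"]

    def test_modes_match_truth(self, det_config, det_genome, det_design, det_tracks):
        _, genes, _ = det_genome
        by_state = {}
        for state in ("Ent", "ET", "LT"):
            pooled = pool_state_coverage(
                [det_tracks[f"{state}_{i}"] for i in (1, 2, 3)]
            )
            by_state[state] = call_transcribed_segments(
                pooled, state, method="threshold", smooth_window=1, threshold=0.5, max_gap=0
            )
        hists, edges, used = tts_offset_distribution(genes, by_state, window=5000, bin_width=100)
        assert len(used) == len(genes)
        for state, ext in (("Ent", 300), ("ET", 600), ("LT", 2500)):
            mode_bin = int(np.argmax(hists[state]))
            assert edges[mode_bin] <= ext < edges[mode_bin + 1]

    def test_gene_missing_in_one_state_excluded_everywhere(self):
        genes = [gene(1000, 5000, gid="g1"), gene(8000, 9000, gid="g2")]
        by_state = {
            "ET": [seg(1000, 5000, state="ET"), seg(8000, 9000, state="ET")],
            "LT": [seg(1000, 5000, state="LT")],  # g2 missing
        }
        hists, _, used = tts_offset_distribution(genes, by_state)
        assert used == ["g1"]
        assert hists["ET"].sum() == 1

    def test_requires_two_states(self):
        with pytest.raises(InputError):
            tts_offset_distribution([gene(0, 10)], {"LT": []})


class TestMeanExtensionDifference:
    def _records(self, values, state):
        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(len(values))],
             "state": state, "extension": values}
        )

    def test_identical_records_zero(self):
        a = self._records([100, 200, 300], "ET")
        delta, se = mean_extension_difference(a, a.assign(state="LT"))
        assert delta == 0.0 and se == 0.0

    def test_simple_arithmetic(self):
        a = self._records([100, 200], "ET")
        b = self._records([400, 500], "LT")
        delta, _ = mean_extension_difference(a, b)
        assert delta == pytest.approx(300.0)

    def test_too_few_common_genes(self):
        a = self._records([100], "ET")
        b = self._records([400], "LT")
        with pytest.raises(InsufficientDataError):
            mean_extension_difference(a, b)

    def test_recovery_within_three_se(self):
        rng = np.random.default_rng(42)
        n = 500
        ids = [f"g{i}" for i in range(n)]
        ext_et = rng.uniform(550, 650, n).round()
        ext_lt = ext_et + rng.uniform(1850, 1950, n).round()
        a = pd.DataFrame({"gene_id": ids, "state": "ET", "extension": ext_et})
        b = pd.DataFrame({"gene_id": ids, "state": "LT", "extension": ext_lt})
        delta, se = mean_extension_difference(a, b, seed=1)
        assert abs(delta - 1900) <= 3 * max(se, 1.0)


class TestElongationRate:
    def test_paper_rounding_two_kb_five_days(self):
        out = elongation_rate(2000, 5)
        assert out["rate_kb_per_min"] == pytest.approx(2 / (5 * 1440), rel=1e-12)
        assert out["rounded_1sf"] == 0.0003

    def test_zero_distance(self):
        assert elongation_rate(0, 5)["rate_kb_per_min"] == 0.0

    def test_direct_arithmetic(self):
        out = elongation_rate(1890, 7.3)
        assert out["rate_kb_per_min"] == pytest.approx(1.89 / (7.3 * 1440), rel=1e-12)
        assert out["rounded_1sf"] == 0.0002

    def test_nonpositive_days_error(self):
        with pytest.raises(InputError):
            elongation_rate(1000, 0)

    @given(
        nt=st.floats(1, 1e6), days=st.floats(0.01, 1000),
        k=st.floats(0.1, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_linear_in_nt_inverse_in_days(self, nt, days, k):
        base = elongation_rate(nt, days)["rate_kb_per_min"]
        assert elongation_rate(nt * k, days)["rate_kb_per_min"] == pytest.approx(base * k)
        assert elongation_rate(nt, days * k)["rate_kb_per_min"] == pytest.approx(base / k)


class TestDeltaDays:
    def _design(self, et, lt):
        rows = [{"sample": f"ET_{i}", "state": "ET", "sex": "F", "days_below_8": v}
                for i, v in enumerate(et)]
        rows += [{"sample": f"LT_{i}", "state": "LT", "sex": "F", "days_below_8": v}
                 for i, v in enumerate(lt)]
        return pd.DataFrame(rows)

    def test_printed_value(self):
        assert delta_days_below_threshold(self._design([1.0], [8.3]), "ET", "LT") == pytest.approx(7.3)

    def test_identical_designs_zero(self):
        d = self._design([2.0, 3.0], [2.0, 3.0])
        assert delta_days_below_threshold(d, "ET", "LT") == 0.0

    def test_hand_computed_means(self):
        d = self._design([0.5, 1.5, 1.0], [7.0, 8.0, 9.0])
        assert delta_days_below_threshold(d, "ET", "LT") == pytest.approx(8.0 - 1.0)

    def test_missing_metadata_error(self):
        d = self._design([np.nan], [8.0])
        with pytest.raises(InputError):
            delta_days_below_threshold(d, "ET", "LT")


class TestReviseAnnotation:
    def test_no_extension_trim_only(self):
        genes = [gene(1000, 5000, gid="a"), gene(8000, 9000, "-", gid="b")]
        bodies, dropped = revise_annotation(genes, [])
        assert [(b.name, b.start, b.end) for b in bodies] == [("a", 1500, 5000), ("b", 8000, 8500)]
        assert dropped == []

    def test_substitution_plus_trim(self):
        bodies, _ = revise_annotation([gene(1000, 5000)], [seg(1200, 8000)])
        assert (bodies[0].start, bodies[0].end) == (1500, 8000)

    def test_tandem_merge_joins_names(self):
        genes = [gene(1000, 5000, gid="geneA"), gene(6000, 9000, gid="geneB")]
        # extension of geneA reaches into geneB
        bodies, _ = revise_annotation(genes, [seg(1000, 7000)])
        assert len(bodies) == 1
        assert bodies[0].name == "geneA:geneB"
        assert not bodies[0].de_eligible
        assert (bodies[0].start, bodies[0].end) == (1500, 9000)

    def test_short_body_dropped_and_logged(self):
        bodies, dropped = revise_annotation([gene(1000, 1520)], [])
        assert bodies == [] and dropped == ["g1"]

    def test_bodies_never_overlap_and_names_conserved(self, rng):
        genes = []
        pos = 0
        for i in range(30):
            pos += int(rng.integers(100, 2000))
            length = int(rng.integers(600, 3000))
            genes.append(gene(pos, pos + length, gid=f"g{i}"))
            pos += length
        segs = [seg(g.start, g.end + int(rng.integers(0, 3000))) for g in genes]
        bodies, dropped = revise_annotation(genes, segs)
        names = [m for b in bodies for m in b.members] + [
            m for d in dropped for m in d.split(":")
        ]
        assert sorted(names) == sorted(g.gene_id for g in genes)
        by_strand = sorted((b.start, b.end) for b in bodies)
        for (s1, e1), (s2, e2) in zip(by_strand, by_strand[1:]):
            assert e1 <= s2


class TestQuantifyAndTpm:
    def test_zero_coverage_zero_row(self):
        bodies, _ = revise_annotation([gene(1000, 5000)], [])
        track = CoverageTrack({"chr1": 10_000})
        counts = quantify_gene_bodies(bodies, {"s1": track})
        assert (counts.to_numpy() == 0).all()

    def test_constant_coverage_times_length(self):
        bodies, _ = revise_annotation([gene(1000, 2500)], [])  # trimmed to 1000 nt
        track = CoverageTrack({"chr1": 10_000})
        track.get("chr1", "+")[:] = 2.0
        counts = quantify_gene_bodies(bodies, {"s1": track})
        assert counts.iloc[0, 0] == pytest.approx(2000.0)

    def test_random_track_basewise_oracle(self, rng):
        genes = [gene(1000, 4000, gid="a"), gene(5000, 8000, "-", gid="b")]
        bodies, _ = revise_annotation(genes, [])
        track = CoverageTrack({"chr1": 10_000})
        track.get("chr1", "+")[:] = rng.poisson(3, 10_000)
        track.get("chr1", "-")[:] = rng.poisson(1, 10_000)
        counts = quantify_gene_bodies(bodies, {"s1": track})
        for b in bodies:
            expected = track.get(b.chrom, b.strand)[b.start : b.end].sum()
            assert counts.loc[b.name, "s1"] == pytest.approx(expected)

    def test_single_gene_tpm_1e6(self):
        counts = pd.DataFrame({"s1": [50.0]}, index=["a"])
        tpm = compute_tpm(counts, pd.Series({"a": 2000}))
        assert tpm.iloc[0, 0] == pytest.approx(1e6)

    def test_length_normalization_ratio(self):
        counts = pd.DataFrame({"s1": [100.0, 100.0]}, index=["a", "b"])
        tpm = compute_tpm(counts, pd.Series({"a": 1000, "b": 2000}))
        assert tpm.loc["a", "s1"] / tpm.loc["b", "s1"] == pytest.approx(2.0)

    def test_column_sums_1e6(self, rng):
        counts = pd.DataFrame(
            rng.poisson(100, (20, 4)).astype(float),
            index=[f"g{i}" for i in range(20)],
            columns=list("abcd"),
        )
        tpm = compute_tpm(counts, pd.Series(rng.integers(500, 5000, 20), index=counts.index))
        assert np.allclose(tpm.sum(axis=0), 1e6, atol=1e-6)

    def test_zero_column_warns(self):
        counts = pd.DataFrame({"s1": [0.0, 0.0]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="all-zero"):
            tpm = compute_tpm(counts, pd.Series({"a": 1000, "b": 2000}))
        assert (tpm["s1"] == 0).all()


def _uniform_gene_setup(strand="+"):
    """One gene with uniform coverage ending exactly at the TTS."""
    g = gene(4000, 8000, strand=strand, gid="g1")
    track = CoverageTrack({"chr1": 20_000})
    track.get("chr1", strand)[4000:8000] = 4.0
    design = pd.DataFrame(
        [{"sample": f"s{i}", "state": "SA", "sex": "F"} for i in range(3)]
    )
    tracks = {f"s{i}": track.copy() for i in range(3)}
    return g, tracks, design


class TestMetagene:
    def test_uniform_gene_steps_to_zero_at_tts(self):
        g, tracks, design = _uniform_gene_setup("+")
        profiles = metagene_profile(tracks, design, [g], anchor="TTS",
                                    window=(-1000, 2000), bin_width=50)
        vals = profiles["SA"].values
        # bins before the TTS are at the plateau (scaled 1), after are 0
        assert np.allclose(vals[:20], 1.0)
        assert np.allclose(vals[20:], 0.0)

    def test_minus_strand_profile_identical(self):
        gp, tp, design = _uniform_gene_setup("+")
        gm, tm, _ = _uniform_gene_setup("-")
        p = metagene_profile(tp, design, [gp], window=(-1000, 2000), bin_width=50)
        m = metagene_profile(tm, design, [gm], window=(-1000, 2000), bin_width=50)
        assert np.allclose(p["SA"].values, m["SA"].values)

    def test_scale_invariance_per_sample(self):
        g, tracks, design = _uniform_gene_setup("+")
        scaled = {k: t.copy() for k, t in tracks.items()}
        scaled["s0"].get("chr1", "+")[:] *= 7.0
        p1 = metagene_profile(tracks, design, [g], window=(-1000, 2000), bin_width=50)
        p2 = metagene_profile(scaled, design, [g], window=(-1000, 2000), bin_width=50)
        assert np.allclose(p1["SA"].values, p2["SA"].values)

    def test_values_bounded(self, det_config, det_genome, det_design, det_tracks):
        _, genes, _ = det_genome
        profiles = metagene_profile(det_tracks, det_design, genes,
                                    window=(-1000, 3000), bin_width=50)
        for p in profiles.values():
            assert (p.values >= 0).all() and (p.values <= 1).all()

    def test_lt_readthrough_persists_vs_sa(self, det_config, det_genome, det_design, det_tracks):
        _, genes, _ = det_genome
        profiles = metagene_profile(det_tracks, det_design, genes,
                                    window=(-1000, 3000), bin_width=50)
        edges = np.arange(-1000, 3000, 50)
        at_2400 = np.searchsorted(edges, 2400, side="right") - 1
        at_600 = np.searchsorted(edges, 600, side="right") - 1
        # the decaying LT tail is still visible at +2.4 kb (relative to the
        # 3'-peak-normalized maximum) while SA signal is gone by +0.6 kb
        assert profiles["LT"].values[at_2400] > 0.03
        assert profiles["SA"].values[at_600] < 0.01

    def test_no_passing_genes_raises_with_counts(self):
        g, tracks, design = _uniform_gene_setup("+")
        empty = {k: CoverageTrack({"chr1": 20_000}) for k in tracks}
        with pytest.raises(FilterError, match="bins"):
            metagene_profile(empty, design, [g], window=(-1000, 2000), bin_width=50)

    def test_n_run_filter(self):
        g, tracks, design = _uniform_gene_setup("+")
        seqs = {"chr1": "A" * 9000 + "N" * 30 + "A" * 10_970}
        with pytest.raises(FilterError, match="n_run"):
            metagene_profile(tracks, design, [g], window=(-1000, 2000), bin_width=50,
                             sequences=seqs)
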