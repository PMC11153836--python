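import numpy as np
import pytest

from _oracles import random_variant
from ismkit.mutator import fuse_breakend, incorporate
from ismkit.predictor import ToyCGPredictor
from ismkit.reference_genome import ArmTable, load_fasta
from ismkit.scoring import (
    DEFAULT_AUGMENTATION,
    DEFAULT_METRICS,
    METRICS,
    AlignedMapPair,
    AugmentationSpec,
    ScoringError,
    _bnd_half_pairs,
    _defined_ut,
    aligned_pair,
    augment_scores,
    disruption_track,
    mask_align,
    predict_pair,
    score,
    score_bnd,
    write_scores,
)
from ismkit.variant_io import BreakendMate, Variant

NAN = float("nan")


@pytest.fixture(scope="module")
def pred16():
    """512 bp windows, 32 bp bins, no cropping -> 16-bin maps."""
    return ToyCGPredictor(512, 32, 0)


def _sym_masked(rng, m=8):
    v = rng.normal(size=(m, m))
    v = (v + v.T) / 2
    idx = np.arange(m)
    v[np.abs(idx[:, None] - idx[None, :]) < 2] = NAN
    return v


class TestRegistry:
    def test_exactly_thirteen_metrics(self):
        assert len(METRICS) == 13

    def test_defaults_are_mse_and_spearman(self):
        assert DEFAULT_METRICS == ["mse", "spearman"]
        assert set(DEFAULT_METRICS) <= set(METRICS)

    def test_polarity_metadata(self):
        assert METRICS["mse"].higher_is_more_disruptive
        assert not METRICS["spearman"].higher_is_more_disruptive

    def test_unknown_metric_rejected(self):
        pair = AlignedMapPair(np.ones((3, 3)), np.ones((3, 3)), [], 32)
        with pytest.raises(ScoringError):
            score(pair, "rmsd")


class TestScoreIdentities:
    def test_identical_maps(self):
        rng = np.random.default_rng(4)
        v = _sym_masked(rng)
        pair = AlignedMapPair(v.copy(), v.copy(), [], 32)
        assert score(pair, "mse") == 0.0
        assert score(pair, "spearman") == pytest.approx(1.0)
        assert score(pair, "mae") == 0.0
        assert score(pair, "l2") == 0.0

    def test_hand_computed_masked_example(self):
        ref = np.array([[NAN, NAN, 1], [NAN, NAN, 2], [1, 2, NAN]])
        alt = np.array([[NAN, NAN, 2], [NAN, NAN, 4], [2, 4, NAN]])
        pair = AlignedMapPair(ref, alt, [], 32)
        # defined upper-triangle entries: (0,2) and (1,2)
        assert score(pair, "mse") == pytest.approx(((1 - 2) ** 2 + (2 - 4) ** 2) / 2)

    def test_bounds_on_random_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pair = AlignedMapPair(_sym_masked(rng), _sym_masked(rng), [], 32)
            assert score(pair, "mse") >= 0
            assert -1 <= score(pair, "spearman") <= 1
            assert score(pair, "max_abs") >= score(pair, "mae") >= 0

    def test_transpose_invariance(self):
        rng = np.random.default_rng(6)
        r, a = _sym_masked(rng), _sym_masked(rng)
        p1 = AlignedMapPair(r, a, [], 32)
        p2 = AlignedMapPair(r.T.copy(), a.T.copy(), [], 32, variant_bin=p1.variant_bin)
        for m in METRICS:
            v1, v2 = score(p1, m), score(p2, m)
            assert v1 == pytest.approx(v2, nan_ok=True)

    def test_all_masked_pair_rejected(self):
        nanmat = np.full((3, 3), NAN)
        pair = AlignedMapPair(nanmat, nanmat, [], 32)
        with pytest.raises(ScoringError):
            score(pair, "mse")


class TestMaskAlign:
    def test_snp_no_removal(self, genome, arms, pred16):
        v = random_variant(np.random.default_rng(0), "chrA", 10000, 512, genome)
        base = genome.fetch("chrA", 5000, 5001)
        v = Variant("s", "chrA", 5000, 5001, base, "A" if base != "A" else "G",
                    "SNP", 0)
        pair = incorporate(v, 512, 0, False, genome, arms)
        ref_maps, alt_map = predict_pair(pair, pred16)
        aligned = mask_align(ref_maps[0], alt_map, pair)
        assert aligned.m == 16
        assert aligned.removed_bins == []

    def test_masking_conservation_random_spans(self, genome, arms, pred16):
        """Aligned dimension = 16 - (# bins overlapping the variant), for
        randomized DEL and DUP spans."""
        rng = np.random.default_rng(7)
        for _ in range(40):
            sv_type = rng.choice(["DEL", "DUP"])
            span = int(rng.integers(10, 340))
            s = int(rng.integers(1000, 9000 - span))
            v = Variant(
                "m", "chrA", s, s + span, None, f"<{sv_type}>", sv_type,
                -span if sv_type == "DEL" else span,
            )
            pair = incorporate(v, 512, 0, False, genome, arms)
            ref_maps, alt_map = predict_pair(pair, pred16)
            aligned = mask_align(ref_maps[0], alt_map, pair)
            if sv_type == "DEL":
                lo, hi = ref_maps[0].variant_rel
            else:
                lo, hi = alt_map.variant_rel
                lo = lo + (hi - lo) // 2  # second copy only
            overlap = sum(
                1 for k in range(16)
                if max(lo, k * 32) < min(hi, (k + 1) * 32)
            )
            assert aligned.m == 16 - overlap

    def test_bin_aligned_del_three_bins(self, genome, arms, pred16):
        # 96 bp deletion; shift 16 makes the variant fall on bin boundaries
        v = Variant("d3", "chrA", 4608, 4704, None, "<DEL>", "DEL", -96)
        pair = incorporate(v, 512, 16, False, genome, arms)
        ref_maps, alt_map = predict_pair(pair, pred16)
        aligned = mask_align(ref_maps[0], alt_map, pair)
        assert aligned.m == 13

    def test_identical_flanks_agree_when_fully_aligned(self, genome, arms, pred16):
        # 128 bp = 4 bins; flank extension 64 bp = 2 bins: exact alignment
        for sv_type in ("DEL", "DUP"):
            v = Variant(
                "fa", "chrA", 4608, 4736, None, f"<{sv_type}>", sv_type,
                -128 if sv_type == "DEL" else 128,
            )
            pair = incorporate(v, 512, 0, False, genome, arms)
            aligned = aligned_pair(pair, pred16)
            assert aligned.m == 12
            d = np.abs(aligned.ref_values - aligned.alt_values)
            # homologous flanks split at the first internally-removed bin
            # (the variant bins of the map that contained them)
            split = min(aligned.removed_bins[0][1])
            left, right = slice(0, split), slice(split, 12)
            assert np.nanmax(d[left, left]) == 0.0
            assert np.nanmax(d[right, right]) == 0.0
            # entries straddling the variant carry the disruption signal
            assert np.nanmax(d[left, right]) > 0.0

    def test_bin_size_mismatch_rejected(self, pred16):
        from ismkit.predictor import toy_predict

        a = toy_predict("A" * 512, 32, 0)
        b = toy_predict("A" * 512, 64, 0)
        v = Variant("x", "c", 0, 1, "A", "G", "SNP", 0)
        with pytest.raises(ScoringError):
            mask_align(a, b, v)


class TestDisruptionTrack:
    def test_identical_maps_zero_track(self):
        rng = np.random.default_rng(8)
        v = _sym_masked(rng)
        pair = AlignedMapPair(v.copy(), v.copy(), [], 32)
        assert np.all(disruption_track(pair).values == 0)

    def test_localized_edit_peaks_at_edited_bin(self, genome, arms, pred16):
        # inversion reversing CG content inside a single bin region leaves
        # that bin's count intact; use an indel that rewrites one bin instead
        s = 5000 - 5000 % 32  # bin-aligned start
        ref = genome.fetch("chrA", s, s + 32)
        alt = "CG" * 16
        v = Variant("loc", "chrA", s, s + 32, ref, alt, "INDEL", 0)
        # +16 bp shift aligns the 32 bp edit with a single bin of the window
        pair = incorporate(v, 512, 16, False, genome, arms)
        aligned = aligned_pair(pair, pred16)
        track = disruption_track(aligned).values
        k = int(np.argmax(track))
        assert track[k] > 0
        # locality: map differences live in row/column k only, so every
        # other row's track value comes solely from its column-k entry
        d2 = (aligned.ref_values - aligned.alt_values) ** 2
        for i in range(aligned.m):
            if i == k:
                continue
            n_def = np.isfinite(aligned.ref_values[i]).sum()
            expected = (d2[i, k] / n_def) if np.isfinite(d2[i, k]) else 0.0
            assert track[i] == pytest.approx(expected)
            assert track[i] < track[k]

    def test_weighted_track_mean_equals_mse_identity(self):
        rng = np.random.default_rng(9)
        pair = AlignedMapPair(_sym_masked(rng), _sym_masked(rng), [], 32)
        track = disruption_track(pair).values
        both = np.isfinite(pair.ref_values)
        counts = both.sum(axis=1)
        total = float((track * counts).sum())
        r, a = _defined_ut(pair)
        assert total == pytest.approx(2 * ((r - a) ** 2).sum())


class TestAugmentation:
    def _snp(self, genome):
        base = genome.fetch("chrA", 5210, 5211)
        return Variant("aug", "chrA", 5210, 5211, base,
                       "A" if base != "A" else "G", "SNP", 0)

    def test_default_spec_members(self):
        assert DEFAULT_AUGMENTATION.augmentations == [
            (0, False), (-1, False), (1, False), (0, True),
        ]

    def test_single_member_equals_unaugmented(self, genome, arms, pred16):
        v = self._snp(genome)
        rec = augment_scores(
            v, AugmentationSpec([(0, False)]), ["mse"], 512, pred16, genome, arms
        )
        assert rec.values["mse"] == rec.per_augmentation[0]["mse"]

    def test_mean_contract_default_spec(self, genome, arms, pred16):
        v = Variant("augdel", "chrA", 5100, 5200, None, "<DEL>", "DEL", -100)
        rec = augment_scores(
            v, DEFAULT_AUGMENTATION, ["mse", "spearman"], 512, pred16,
            genome, arms,
        )
        assert len(rec.per_augmentation) == 4
        for m in ("mse", "spearman"):
            assert rec.values[m] == pytest.approx(
                np.mean([a[m] for a in rec.per_augmentation])
            )

    def test_duplicated_augmentation_idempotent_mean(self, genome, arms, pred16):
        v = self._snp(genome)
        one = augment_scores(
            v, AugmentationSpec([(0, False)]), ["mse"], 512, pred16, genome, arms
        )
        two = augment_scores(
            v, AugmentationSpec([(0, False), (0, False)]), ["mse"], 512,
            pred16, genome, arms,
        )
        assert one.values["mse"] == pytest.approx(two.values["mse"])

    def test_empty_spec_rejected(self):
        with pytest.raises(ScoringError):
            AugmentationSpec([])


class TestBreakendScoring:
    def test_degenerate_self_join_scores_zero(self, genome, arms, pred16):
        # t[p[ to the immediately following base reconstitutes the reference
        t = genome.fetch("chrA", 5000, 5001)
        v = Variant(
            "sj", "chrA", 5000, 5001, t, "x", "BND", 0,
            BreakendMate("chrA", 5001, "t[p[", ""),
        )
        rec = score_bnd(v, 512, pred16, genome, arms, ["mse", "spearman"])
        assert rec.values["mse"] == 0.0
        assert rec.values["spearman"] == pytest.approx(1.0)

    def test_defined_entry_accounting(self, genome, arms, pred16):
        t = genome.fetch("chrA", 5000, 5001)
        v = Variant(
            "acct", "chrA", 5000, 5001, t, "x", "BND", 0,
            BreakendMate("chrB", 3000, "t]p]", ""),
        )
        pair = fuse_breakend(v, 512, 0, genome, arms)
        halves = _bnd_half_pairs(pair, pred16)
        m = 16
        jb = pair.alt_rel_pos // 32  # 8
        left_bins, right_bins = jb, m - jb
        # excluded inter-flank quadrant
        assert left_bins * right_bins == jb * (m - jb)
        for half, nbins in zip(halves, (left_bins, right_bins)):
            r, _ = _defined_ut(half)
            # defined UT entries within an n-bin block with a 2-wide diagonal mask
            expected = nbins * (nbins - 1) // 2 - (nbins - 1)
            assert r.size == expected

    def test_junction_breaking_flank_scores_nonzero(self, genome, arms, pred16):
        t = genome.fetch("chrA", 5000, 5001)
        v = Variant(
            "bx", "chrA", 5000, 5001, t, "x", "BND", 0,
            BreakendMate("chrB", 3000, "[p[t", ""),
        )
        rec = score_bnd(v, 512, pred16, genome, arms, ["mse"])
        # flank content matches the oriented REF windows by construction, so
        # the strictly local toy predictor sees no intra-flank change
        assert rec.values["mse"] == pytest.approx(0.0)


class TestMonotonicity:
    def test_deleting_more_cg_content_never_decreases_mse(self, tmp_path, arms):
        """Constructed family: an otherwise CG-free chromosome with a CG-dense
        core; progressively larger deletions of the core."""
        core = "CG" * 160  # 320 bp CG block
        chrom = "A" * 2000 + core + "A" * 2000
        p = tmp_path / "mono.fa"
        p.write_text(">c\n" + chrom + "\n")
        g = load_fasta(p)
        a = ArmTable.whole_chromosomes(g)
        pred = ToyCGPredictor(512, 32, 0)
        scores = []
        for d in (64, 128, 192, 256):
            v = Variant(f"d{d}", "c", 2000, 2000 + d, None, "<DEL>", "DEL", -d)
            pair = incorporate(v, 512, 0, False, g, a)
            scores.append(score(aligned_pair(pair, pred), "mse"))
        assert all(b >= a_ for a_, b in zip(scores, scores[1:]))
        assert scores[-1] > 0


class TestWriteScores:
    def test_empty_records_header_only(self, tmp_path):
        p = write_scores([], tmp_path / "s.tsv", metrics=["mse", "spearman"])
        assert p.read_text() == "variant_id\tmse\tspearman\n"

    def test_shape_and_round_trip(self, tmp_path, genome, arms, pred16):
        import pandas as pd

        v = Variant("w", "chrA", 5100, 5200, None, "<INV>", "INV", 0)
        rec = augment_scores(
            v, DEFAULT_AUGMENTATION, list(METRICS), 512, pred16, genome, arms
        )
        p = write_scores([rec], tmp_path / "s.tsv", metrics=list(METRICS),
                         include_augmentations=True)
        df = pd.read_csv(p, sep="\t")
        assert df.shape == (1, 1 + 13 + 13 * 4)
        for m in METRICS:
            assert df.loc[0, m] == pytest.approx(rec.values[m], abs=1e-9)
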