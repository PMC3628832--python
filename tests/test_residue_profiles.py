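"""Per-residue profiling: window means, FoldIndex, binarization, runs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_protein
from idpcohort import ProteinRecord
from idpcohort.dataset_io import STANDARD_AA
from idpcohort.residue_profiles import (CHBoundaryParams, DisorderMask,
                                        ResidueScale, ScoreProfile,
                                        WindowSpec, binarize,
                                        disorder_content, foldindex_profile,
                                        import_score_profile, load_scale,
                                        long_disordered_regions,
                                        windowed_profile)


def brute_force_window_means(seq, scale, width):
    """Independent oracle: explicit loop over clipped windows."""
    n = len(seq)
    half = width // 2
    vals = [scale.values.get(c) for c in seq]
    present = [v is not None for v in vals]
    known = [v for v in vals if v is not None]
    global_mean = sum(known) / len(known)
    out = []
    for i in range(n):
        if n < width:
            window = list(range(n))
        else:
            window = range(max(0, i - half), min(n, i + half + 1))
        w = [vals[j] for j in window if present[j]]
        out.append(sum(w) / len(w) if w else global_mean)
    return np.array(out)


class TestWindowedProfile:
    def test_homopolymer_constant(self):
        scale = load_scale("topidp")
        rec = ProteinRecord("P1", "polyA", "A" * 60)
        prof = windowed_profile(rec, scale)
        assert np.allclose(prof.scores, scale.values["A"])

    def test_short_sequence_whole_mean(self):
        scale = load_scale("topidp")
        rec = ProteinRecord("P1", "short", "MKLVAEDRPW")
        prof = windowed_profile(rec, scale, WindowSpec(21))
        expected = np.mean([scale.values[c] for c in rec.sequence])
        assert np.allclose(prof.scores, expected)

    def test_matches_brute_force(self, rng):
        scale = load_scale("topidp")
        rec = random_protein(rng, 40)
        prof = windowed_profile(rec, scale, WindowSpec(5))
        assert np.allclose(prof.scores,
                           brute_force_window_means(rec.sequence, scale, 5))

    def test_brute_force_many_random(self, rng):
        scale = load_scale("kyte_doolittle")
        for width in (3, 7, 21):
            for _ in range(40):
                n = int(rng.integers(1, 80))
                rec = random_protein(rng, n)
                prof = windowed_profile(rec, scale, WindowSpec(width))
                oracle = brute_force_window_means(rec.sequence, scale, width)
                assert np.allclose(prof.scores, oracle)

    def test_ambiguity_codes_excluded(self):
        scale = load_scale("topidp")
        rec = ProteinRecord("P1", "amb", "AXA")
        prof = windowed_profile(rec, scale, WindowSpec(3))
        assert np.allclose(prof.scores, scale.values["A"])

    def test_missing_residue_rejected(self):
        incomplete = dict.fromkeys(STANDARD_AA[:-1], 0.0)
        with pytest.raises(ValueError, match="missing"):
            ResidueScale("broken", incomplete)

    def test_translation_equivariance(self, rng):
        scale = load_scale("topidp")
        core = "".join(rng.choice(list(STANDARD_AA), size=30))
        a = windowed_profile(ProteinRecord("A", "a", "W" * 10 + core + "W" * 10),
                             scale, WindowSpec(5)).scores
        b = windowed_profile(ProteinRecord("B", "b", "P" * 12 + core + "P" * 12),
                             scale, WindowSpec(5)).scores
        # interior window means depend only on the local context
        assert np.allclose(a[12:38], b[14:40])


class TestFoldIndex:
    def test_poly_e_window_value(self):
        # <H> = 1/9, |<R>| = 1 -> raw = 2.785/9 - 1 - 1.151
        rec = ProteinRecord("P1", "polyE", "E" * 41)
        prof, mask = foldindex_profile(rec)
        expected_raw = 2.785 * (1.0 / 9.0) - 1.0 - 1.151
        assert np.allclose(-prof.scores, expected_raw)
        assert mask.labels.all()  # disordered everywhere

    def test_poly_i_window_value(self):
        rec = ProteinRecord("P1", "polyI", "I" * 41)
        prof, mask = foldindex_profile(rec)
        assert np.allclose(-prof.scores, 2.785 * 1.0 - 0.0 - 1.151)
        assert not mask.labels.any()

    def test_charge_symmetry_cancels(self):
        rec = ProteinRecord("P1", "kkdd", "KKDD")
        prof, _ = foldindex_profile(rec, window=WindowSpec(5))
        params = CHBoundaryParams()
        h = params.hydropathy_scale.values
        mean_h = (2 * h["K"] + 2 * h["D"]) / 4
        assert np.allclose(-prof.scores,
                           params.slope * mean_h - 0.0 - params.intercept)

    def test_profile_uncalibrated(self):
        prof, _ = foldindex_profile(ProteinRecord("P1", "x", "MKWV" * 10))
        assert not prof.calibrated


class TestImportScoreProfile:
    def test_parses_plain_layout(self, tmp_path):
        path = tmp_path / "scores.txt"
        path.write_text("# comment\n1 M 0.10\n2 K 0.90\n\n3 L 0.50\n4 V 0.00\n")
        prof = import_score_profile(path, 4)
        assert prof.calibrated
        assert np.allclose(prof.scores, [0.10, 0.90, 0.50, 0.00])

    def test_length_mismatch_names_both(self, tmp_path):
        path = tmp_path / "scores.txt"
        path.write_text("".join(f"{i} A 0.5\n" for i in range(1, 101)))
        with pytest.raises(ValueError, match="100.*101"):
            import_score_profile(path, 101)

    def test_out_of_range_score_names_line(self, tmp_path):
        path = tmp_path / "scores.txt"
        path.write_text("1 M 0.5\n2 K 1.5\n")
        with pytest.raises(ValueError, match=":2"):
            import_score_profile(path, 2)

    def test_all_at_threshold_valid(self, tmp_path):
        path = tmp_path / "scores.txt"
        path.write_text("1 M 0.5\n2 K 0.5\n")
        prof = import_score_profile(path, 2)
        assert binarize(prof).labels.all()


class TestBinarize:
    def test_threshold_inclusive(self):
        prof = ScoreProfile("P1", "x", [0.4, 0.5, 0.6], calibrated=True)
        assert binarize(prof, 0.5).labels.tolist() == [False, True, True]

    def test_all_zero(self):
        prof = ScoreProfile("P1", "x", [0.0] * 5, calibrated=True)
        assert not binarize(prof).labels.any()

    def test_uncalibrated_rejected(self):
        prof = ScoreProfile("P1", "x", [1.5, -2.0], calibrated=False)
        with pytest.raises(ValueError, match="calibrated"):
            binarize(prof)

    def test_elementwise_oracle(self, rng):
        scores = rng.random(200)
        prof = ScoreProfile("P1", "x", scores, calibrated=True)
        mask = binarize(prof, 0.5)
        assert mask.labels.tolist() == [s >= 0.5 for s in scores]

    def test_monotone_in_threshold(self, rng):
        scores = rng.random(500)
        prof = ScoreProfile("P1", "x", scores, calibrated=True)
        contents = [disorder_content(binarize(prof, t))
                    for t in (0.9, 0.7, 0.5, 0.3, 0.1)]
        assert contents == sorted(contents)


class TestDisorderContent:
    def test_half(self):
        m = DisorderMask("P1", [True, True, False, False], 0.5)
        assert disorder_content(m) == 0.5

    def test_all_true(self):
        assert disorder_content(DisorderMask("P1", [True] * 7, 0.5)) == 1.0

    def test_planted_fraction_exact(self):
        labels = np.zeros(1000, dtype=bool)
        labels[:300] = True
        prof = ScoreProfile("P1", "x", labels.astype(float), calibrated=True)
        assert disorder_content(binarize(prof)) == 0.3


def rle_regions(labels, min_len):
    """Independent run-length-encoding oracle."""
    out, start = [], None
    for i, lab in enumerate(list(labels) + [False]):
        if lab and start is None:
            start = i
        elif not lab and start is not None:
            if i - start >= min_len:
                out.append((start + 1, i))
            start = None
    return out


class TestLongDisorderedRegions:
    def test_run_of_35(self):
        labels = [False] * 10 + [True] * 35 + [False] * 10
        regions = long_disordered_regions(DisorderMask("P", labels, 0.5))
        assert [(r.start, r.end) for r in regions] == [(11, 45)]

    def test_run_of_29_excluded(self):
        labels = [False] + [True] * 29 + [False]
        assert long_disordered_regions(DisorderMask("P", labels, 0.5)) == []

    def test_matches_rle_oracle(self, rng):
        for _ in range(100):
            labels = rng.random(int(rng.integers(1, 300))) < 0.7
            mask = DisorderMask("P", labels, 0.5)
            for min_len in (1, 5, 30):
                got = [(r.start, r.end)
                       for r in long_disordered_regions(mask, min_len)]
                assert got == rle_regions(labels, min_len)

    def test_regions_disjoint_and_long_enough(self, rng):
        labels = rng.random(2000) < 0.9
        regions = long_disordered_regions(DisorderMask("P", labels, 0.5), 10)
        for r in regions:
            assert r.end - r.start + 1 >= 10
        for a, b in zip(regions, regions[1:]):
            assert b.start > a.end + 1  # separated by >= 1 ordered residue

    def test_min_len_validation(self):
        with pytest.raises(ValueError):
            long_disordered_regions(DisorderMask("P", [True], 0.5), 0)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.text(alphabet=STANDARD_AA, min_size=1, max_size=120),
       st.sampled_from([3, 5, 21]))
def test_window_mean_bounded_by_scale(seq, width):
    scale = load_scale("topidp")
    prof = windowed_profile(ProteinRecord("P", "p", seq), scale,
                            WindowSpec(width))
    lo, hi = min(scale.values.values()), max(scale.values.values())
    assert np.all(prof.scores >= lo - 1e-12)
    assert np.all(prof.scores <= hi + 1e-12)
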