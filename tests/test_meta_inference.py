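"""Reverse-inference machinery: term database, masks, posterior maps,
chi-square z, peaks, ROI averaging, evidence scores and term ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from accumaint import meta_inference as mi
from accumaint._porter import porter_stem
from accumaint.statmap import StatMap, mni_grid
from accumaint.synthetic_data import corpus_from_json, corpus_to_json


@pytest.fixture
def small_grid():
    return StatMap(np.zeros((10, 10, 10)), origin_mm=(-18.0, -18.0, -18.0), spacing_mm=(4.0, 4.0, 4.0))


class TestStemmerAndTermDb:
    @pytest.mark.parametrize(
        "a,b",
        [("decisions", "decision"), ("memories", "memory"), ("running", "run"),
         ("responses", "response"), ("activations", "activation"), ("attending", "attend")],
    )
    def test_inflected_forms_share_stem(self, a, b):
        assert porter_stem(a) == porter_stem(b)

    def test_occurrence_after_stemming(self):
        texts = {i: "We studied rapid decisions under uncertainty." for i in range(1, 16)}
        db = mi.build_term_db(texts, ["decision", "memory"], min_articles=15)
        assert db.term_counts == {"decision": 15}

    def test_below_threshold_dropped(self):
        texts = {i: "working memory load" if i <= 14 else "motor control" for i in range(1, 31)}
        db = mi.build_term_db(texts, ["memory", "motor"], min_articles=15)
        assert "memory" not in db.term_counts  # 14 articles < 15
        assert "motor" in db.term_counts

    def test_excluded_terms_never_appear(self):
        texts = {i: "pictures of faces and houses shown to viewers" for i in range(1, 21)}
        db = mi.build_term_db(
            texts, ["picture", "face", "faces", "house", "attention"], min_articles=1
        )
        assert db.term_counts == {}

    def test_prefix_pattern_is_literal(self):
        # "face*" excludes "face"/"faces" but not "facial" (no shared prefix)
        texts = {i: "facial features of faces" for i in range(1, 16)}
        db = mi.build_term_db(texts, ["face", "facial"], min_articles=15)
        assert db.term_counts == {"facial": 15}

    def test_two_word_terms_match_after_stopword_removal(self):
        # matching runs on the stop-word-filtered token stream, so a term
        # split only by stop words still counts as consecutive
        texts = {1: "a working memory task", 2: "working through memory lists", 3: "memory working backwards"}
        db = mi.build_term_db(texts, ["working memory"], min_articles=1)
        assert db.articles[1] == {"working memory"}
        assert db.articles[2] == {"working memory"}
        assert db.articles[3] == set()

    def test_empty_term_list_rejected(self):
        with pytest.raises(ValueError):
            mi.build_term_db({1: "text"}, [], min_articles=1)


class TestMergeFoci:
    def test_disjoint_union(self):
        merged = mi.merge_foci({1: [[0, 0, 0]]}, {2: [[1, 1, 1]]})
        assert set(merged) == {1, 2}

    def test_shared_id_deduplicates_exact_focus(self):
        merged = mi.merge_foci({1: [[0.0, 0.0, 0.0]]}, {1: [[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]]})
        assert merged[1] == [[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]]

    def test_set_arithmetic_counts(self):
        a = {i: [] for i in range(750)}
        b = {i: [] for i in range(650, 900)}
        assert len(mi.merge_foci(a, b)) == 900


class TestActivationMasks:
    def test_within_radius_active(self, small_grid):
        masks = mi.activation_masks({1: [[0.0, 0.0, 0.0]]}, small_grid, radius_mm=10)
        vox = small_grid.world_to_voxel((0.0, 0.0, 8.0))
        flat = np.ravel_multi_index(vox, small_grid.shape)
        assert flat in masks.active[1]

    def test_beyond_radius_inactive(self, small_grid):
        masks = mi.activation_masks({1: [[0.0, 0.0, 0.0]]}, small_grid, radius_mm=10)
        vox = small_grid.world_to_voxel((0.0, 0.0, 12.0))
        flat = np.ravel_multi_index(vox, small_grid.shape)
        assert flat not in masks.active[1]

    def test_article_without_foci_empty(self, small_grid):
        masks = mi.activation_masks({1: []}, small_grid)
        assert masks.active[1].size == 0

    def test_outside_grid_warns_and_ignores(self, small_grid):
        with pytest.warns(UserWarning, match="outside grid"):
            masks = mi.activation_masks({1: [[500.0, 0.0, 0.0]]}, small_grid, radius_mm=5)
        assert masks.active[1].size == 0


def brute_force_posterior(term, articles, active, voxel, prior):
    """Direct Bayes from raw article counts at one voxel."""
    w = [a for a in articles if term in articles[a]]
    wo = [a for a in articles if term not in articles[a]]
    p_a_t = np.mean([voxel in active[a] for a in w])
    p_a_nt = np.mean([voxel in active[a] for a in wo])
    denom = p_a_t * prior + p_a_nt * (1 - prior)
    return np.nan if denom == 0 else p_a_t * prior / denom


class TestTermPosterior:
    @pytest.fixture
    def toy_masks(self, small_grid, rng):
        articles = {i: ({"decision"} if i % 2 else set()) for i in range(1, 101)}
        foci = {}
        for i in articles:
            pts = []
            if "decision" in articles[i]:
                if rng.random() < 0.8:
                    pts.append([0.0, 0.0, 0.0])
            elif rng.random() < 0.1:
                pts.append([0.0, 0.0, 0.0])
            if rng.random() < 0.5:
                pts.append(list(rng.uniform(-16, 16, 3)))
            foci[i] = pts
        db = mi.TermDatabase.from_annotations(articles)
        return db, mi.activation_masks(foci, small_grid, radius_mm=6)

    def test_matches_brute_force_everywhere(self, toy_masks):
        db, masks = toy_masks
        pmap = mi.term_posterior_map("decision", db, masks, prior=0.5)
        active_sets = {a: set(v.tolist()) for a, v in masks.active.items()}
        flat = pmap.data.reshape(-1)
        for voxel in range(0, flat.size, 37):  # stride over the toy grid
            expected = brute_force_posterior("decision", db.articles, active_sets, voxel, 0.5)
            if np.isnan(expected):
                assert np.isnan(flat[voxel])
            else:
                assert flat[voxel] == pytest.approx(expected)

    def test_known_fractions(self):
        """0.8 with-term vs 0.1 without-term activation at prior 0.5."""
        articles = {i: ({"t"} if i < 10 else set()) for i in range(20)}
        grid = StatMap(np.zeros((1, 1, 1)), (0, 0, 0), (2, 2, 2))
        active = {i: (np.array([0]) if (i < 8 or i in (10, 11)) else np.empty(0, dtype=int)) for i in range(20)}
        masks = mi.ActivationMasks(grid=grid, active=active, radius_mm=10)
        db = mi.TermDatabase.from_annotations(articles)
        pmap = mi.term_posterior_map("t", db, masks, prior=0.5)
        assert pmap.data[0, 0, 0] == pytest.approx(0.8 * 0.5 / (0.8 * 0.5 + 0.2 * 0.5))

    def test_equal_fractions_give_prior_half(self, toy_masks):
        db, _ = toy_masks
        grid = StatMap(np.zeros((1, 1, 1)), (0, 0, 0), (2, 2, 2))
        active = {a: np.array([0]) for a in db.articles}
        masks = mi.ActivationMasks(grid=grid, active=active, radius_mm=10)
        pmap = mi.term_posterior_map("decision", db, masks, prior=0.5)
        assert pmap.data[0, 0, 0] == pytest.approx(0.5)

    def test_prior_one_saturates(self, toy_masks):
        db, masks = toy_masks
        pmap = mi.term_posterior_map("decision", db, masks, prior=1.0)
        vals = pmap.data[~np.isnan(pmap.data)]
        assert np.all((vals == 1.0) | (vals == 0.0))

    def test_monotone_in_activation_fraction(self):
        for p_t in (0.2, 0.4, 0.6, 0.8):
            post = p_t * 0.5 / (p_t * 0.5 + 0.1 * 0.5)
            post_next = (p_t + 0.1) * 0.5 / ((p_t + 0.1) * 0.5 + 0.1 * 0.5)
            assert post_next > post

    def test_unknown_term_rejected(self, toy_masks):
        db, masks = toy_masks
        with pytest.raises(KeyError):
            mi.term_posterior_map("nonexistent", db, masks)


class TestPosteriorZ:
    def make_masks(self, n_t_act, n_t_inact, n_nt_act, n_nt_inact):
        n = n_t_act + n_t_inact + n_nt_act + n_nt_inact
        articles, active = {}, {}
        k = 0
        for count, has_term, is_act in (
            (n_t_act, True, True), (n_t_inact, True, False),
            (n_nt_act, False, True), (n_nt_inact, False, False),
        ):
            for _ in range(count):
                articles[k] = {"t"} if has_term else set()
                active[k] = np.array([0]) if is_act else np.empty(0, dtype=int)
                k += 1
        grid = StatMap(np.zeros((1, 1, 1)), (0, 0, 0), (2, 2, 2))
        db = mi.TermDatabase.from_annotations(articles)
        return db, mi.ActivationMasks(grid=grid, active=active, radius_mm=10)

    def test_matches_scipy_chi2(self):
        table = [[16, 4], [8, 72]]
        db, masks = self.make_masks(16, 4, 8, 72)
        zmap = mi.term_posterior_z("t", db, masks)
        chi2 = stats.chi2_contingency(table, correction=False).statistic
        assert zmap.data[0, 0, 0] == pytest.approx(np.sqrt(chi2))
        assert zmap.data[0, 0, 0] > 0  # with-term fraction is higher

    def test_independent_margins_zero(self):
        db, masks = self.make_masks(10, 10, 30, 30)
        zmap = mi.term_posterior_z("t", db, masks)
        assert zmap.data[0, 0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_negative_association_signed(self):
        db, masks = self.make_masks(2, 18, 30, 10)
        assert mi.term_posterior_z("t", db, masks).data[0, 0, 0] < 0

    def test_degenerate_margin_missing(self):
        db, masks = self.make_masks(0, 20, 0, 60)  # nothing active anywhere
        assert np.isnan(mi.term_posterior_z("t", db, masks).data[0, 0, 0])


def gaussian_bump(grid, center, height, width=8.0):
    c = grid.voxel_centers()
    d2 = np.sum((c - np.asarray(center, dtype=float)) ** 2, axis=-1)
    return height * np.exp(-d2 / (2 * width**2))


class TestLocalMaxima:
    def test_two_separated_bumps(self):
        grid = mni_grid(4.0, box=((-40, 40), (-40, 40), (-40, 40)))
        grid.data[:] = gaussian_bump(grid, (-20, 0, 0), 4.0) + gaussian_bump(grid, (20, 0, 0), 3.5)
        peaks = mi.local_maxima(grid, z_thresh=2.3, min_distance_mm=30)
        assert len(peaks) == 2
        assert peaks[0].z > peaks[1].z

    def test_close_bumps_suppressed(self):
        grid = mni_grid(4.0, box=((-40, 40), (-40, 40), (-40, 40)))
        grid.data[:] = gaussian_bump(grid, (-4, 0, 0), 4.0) + gaussian_bump(grid, (6, 0, 0), 3.5)
        peaks = mi.local_maxima(grid, z_thresh=2.3, min_distance_mm=30)
        assert len(peaks) == 1

    def test_subthreshold_empty(self):
        grid = mni_grid(8.0, box=((-40, 40), (-40, 40), (-40, 40)))
        grid.data[:] = 1.0
        assert mi.local_maxima(grid, z_thresh=2.3) == []


class TestRoiWeightedZ:
    def grid_pair(self, post_values, contrast_values):
        grid = StatMap(np.zeros((len(post_values), 1, 1)), (0, 0, 0), (2, 2, 2))
        post = grid.like(np.asarray(post_values, dtype=float).reshape(-1, 1, 1))
        contrast = grid.like(np.asarray(contrast_values, dtype=float).reshape(-1, 1, 1))
        return post, contrast

    def test_constant_posterior_any_weights(self):
        post, contrast = self.grid_pair([2.5, 2.5, 2.5], [5.0, 1.0, 0.2])
        assert mi.roi_weighted_posterior_z((2, 0, 0), post, contrast, radius_mm=50) == pytest.approx(2.5)

    def test_weighted_arithmetic(self):
        post, contrast = self.grid_pair([2.0, 6.0], [3.0, 1.0])
        assert mi.roi_weighted_posterior_z((1, 0, 0), post, contrast, radius_mm=50) == pytest.approx(3.0)

    def test_negative_weights_clamped(self):
        post, contrast = self.grid_pair([2.0, 6.0, 100.0], [3.0, 1.0, -5.0])
        # the negative-contrast voxel gets zero weight
        assert mi.roi_weighted_posterior_z((1, 0, 0), post, contrast, radius_mm=50) == pytest.approx(3.0)

    def test_missing_posterior_renormalized(self):
        post, contrast = self.grid_pair([2.0, np.nan, 6.0], [3.0, 4.0, 1.0])
        assert mi.roi_weighted_posterior_z((1, 0, 0), post, contrast, radius_mm=50) == pytest.approx(3.0)

    def test_all_missing_rejected(self):
        post, contrast = self.grid_pair([np.nan, np.nan], [1.0, 1.0])
        with pytest.raises(ValueError):
            mi.roi_weighted_posterior_z((0, 0, 0), post, contrast, radius_mm=50)


class TestEvidenceAndTopTerms:
    def rows(self, entries):
        return pd.DataFrame(
            [
                {"contrast": "c", "cluster": cl, "term": t, "evidence_score": s,
                 "peak_x": 0, "peak_y": 0, "peak_z": 0, "peak_z_value": 1.0, "roi_post_z": s}
                for t, s, cl in entries
            ]
        )

    def test_peak_times_roi_product(self):
        assert 4.07 * 2.0 == pytest.approx(8.14)

    def test_term_deduped_to_best_peak(self):
        rows = self.rows([("a", 5.0, 1), ("a", 9.0, 2), ("b", 3.0, 1)])
        assert mi.top_terms(rows, k=8) == ["a", "b"]
        assert rows.sort_values("evidence_score", ascending=False).drop_duplicates("term")[
            "evidence_score"
        ].tolist() == [9.0, 3.0]

    def test_fewer_terms_than_k(self):
        rows = self.rows([("a", 5.0, 1), ("b", 3.0, 2), ("c", 1.0, 1)])
        assert mi.top_terms(rows, k=8) == ["a", "b", "c"]

    def test_single_cluster_limits_to_three(self):
        rows = self.rows([(t, s, 1) for t, s in zip("abcdef", [9, 8, 7, 6, 5, 4])])
        assert mi.top_terms(rows, k=8, per_cluster_k=3) == ["a", "b", "c"]

    def test_empty_rows_rejected(self):
        with pytest.raises(ValueError):
            mi.top_terms(pd.DataFrame())

    def test_score_homogeneity(self, toy_corpus):
        _, terms, foci, planted = toy_corpus
        grid = mni_grid(8.0, box=((-30, 50), (-30, 50), (-30, 50)))
        masks = mi.activation_masks(foci, grid, radius_mm=10)
        db = mi.TermDatabase.from_annotations(terms, min_articles=15)
        contrast = grid.like(gaussian_bump(grid, planted["decision"]["center_mm"], 4.0, 12.0))
        double = grid.like(2 * contrast.data)
        r1 = mi.evidence_scores(contrast, db, masks)
        r2 = mi.evidence_scores(double, db, masks)
        merged = r1.merge(r2, on=["term", "peak_x", "peak_y", "peak_z"], suffixes=("_1", "_2"))
        assert len(merged) > 0
        assert np.allclose(merged["evidence_score_2"], 2 * merged["evidence_score_1"])

    def test_pipeline_deterministic(self, toy_corpus):
        _, terms, foci, planted = toy_corpus
        grid = mni_grid(8.0, box=((-30, 50), (-30, 50), (-30, 50)))
        masks = mi.activation_masks(foci, grid, radius_mm=10)
        db = mi.TermDatabase.from_annotations(terms, min_articles=15)
        contrast = grid.like(gaussian_bump(grid, planted["decision"]["center_mm"], 4.0, 12.0))
        a = mi.evidence_scores(contrast, db, masks)
        b = mi.evidence_scores(contrast, db, masks)
        pd.testing.assert_frame_equal(a, b)


class TestStatMapIO:
    def test_csv_round_trip_exact(self, rng, tmp_path):
        m = StatMap(rng.normal(size=(5, 4, 3)), (-10, -8, -6), (2, 2, 2))
        m.to_csv(tmp_path / "m.csv")
        back = StatMap.from_csv(tmp_path / "m.csv")
        assert np.array_equal(back.data, m.data)
        assert back.origin_mm == m.origin_mm
        assert back.spacing_mm == m.spacing_mm

    def test_nifti_round_trip(self, rng, tmp_path):
        pytest.importorskip("nibabel")
        m = StatMap(rng.normal(size=(5, 4, 3)), (-10.0, -8.0, -6.0), (2.0, 2.0, 2.0))
        m.to_nifti(tmp_path / "m.nii")
        back = StatMap.from_nifti(tmp_path / "m.nii")
        assert np.allclose(back.data, m.data)
        assert back.origin_mm == m.origin_mm

    def test_corpus_json_round_trip(self, toy_corpus):
        _, terms, foci, _ = toy_corpus
        back_terms, back_foci = corpus_from_json(corpus_to_json(terms, foci))
        assert back_terms == terms
        assert back_foci == foci
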