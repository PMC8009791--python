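"""Rank-sum score, severity index, cut-offs and both cranial indices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cranioquant as cq
from cranioquant.curve import curve_from_extrema, outline_to_curve
from cranioquant.features import CurveFeatures, derive_features, extract_features
from cranioquant.severity import (
    SeverityError,
    ci_curve,
    ci_traditional,
    ci_traditional_from_outline,
    classify_severity,
    severity_components,
    severity_index,
    ucsq_score,
)


def _features(F, O, R, L):
    return CurveFeatures(
        F=F, O=O, R=R, L=L, XF=np.pi, XO=0.0, XR=3 * np.pi / 2, XL=np.pi / 2,
        **derive_features(F, O, R, L),
    )


class TestRankScore:
    def test_two_subjects_narrower_longer_scores_higher(self):
        a = _features(F=1.25, O=1.28, R=0.74, L=0.74)  # narrower, more elongated
        b = _features(F=1.12, O=1.15, R=0.86, L=0.86)
        ranking = ucsq_score([a, b], subject_ids=["A", "B"])
        assert ranking.scores[0] == 4.0
        assert ranking.scores[1] == 2.0

    def test_cohort_of_21_mean_is_22(self, cohort_features):
        ranking = ucsq_score(cohort_features)
        assert len({round(w, 9) for w in ranking.widths}) == 21  # untied
        assert ranking.mean_score == pytest.approx(22.0, abs=1e-12)
        assert ranking.scores.min() >= 2.0
        assert ranking.scores.max() <= 42.0

    def test_tied_widths_share_average_rank(self):
        feats = [
            _features(1.2, 1.25, 0.80, 0.80),
            _features(1.18, 1.22, 0.80, 0.80),  # same width as above
            _features(1.10, 1.12, 0.90, 0.90),
        ]
        ranking = ucsq_score(feats)
        assert ranking.ranks_width.sum() == pytest.approx(6.0)
        assert ranking.ranks_width[0] == ranking.ranks_width[1] == 2.5
        assert ranking.ranks_width[2] == 1.0

    def test_single_subject_rejected(self):
        with pytest.raises(SeverityError):
            ucsq_score([_features(1.2, 1.25, 0.8, 0.8)])

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(
        st.lists(
            st.tuples(
                st.floats(1.05, 1.4), st.floats(1.05, 1.4),
                st.floats(0.6, 0.95), st.floats(0.6, 0.95),
            ),
            min_size=2, max_size=15,
        )
    )
    def test_rank_sums_conserved(self, rows):
        feats = [_features(F, O, R, L) for F, O, R, L in rows]
        ranking = ucsq_score(feats)
        n = len(rows)
        assert ranking.ranks_width.sum() == pytest.approx(n * (n + 1) / 2)
        assert ranking.ranks_peaks.sum() == pytest.approx(n * (n + 1) / 2)
        assert ranking.mean_score == pytest.approx(n + 1)


class TestSeverityIndex:
    def test_cohort_mean_extrema(self):
        value, cls = severity_index(_features(F=1.18, O=1.24, R=0.79, L=0.79))
        assert value == pytest.approx(0.29, abs=1e-12)
        assert cls == "moderate"
        comps = severity_components(_features(F=1.18, O=1.24, R=0.79, L=0.79))
        assert comps["occiput"] == pytest.approx(0.14, abs=1e-12)
        assert comps["forehead"] == pytest.approx(0.03, abs=1e-12)
        assert comps["width"] == pytest.approx(0.12, abs=1e-12)

    def test_control_reference_scores_zero_mild(self):
        value, cls = severity_index(_features(F=1.15, O=1.10, R=0.85, L=0.85))
        assert value == pytest.approx(0.0, abs=1e-12)
        assert cls == "mild"

    @pytest.mark.parametrize(
        "value,expected",
        [(0.1999, "mild"), (0.20, "moderate"), (0.3499, "moderate"),
         (0.35, "severe"), (-0.1, "mild"), (0.60, "severe")],
    )
    def test_classification_boundaries(self, value, expected):
        assert classify_severity(value) == expected

    def test_width_dial_strictly_decreases_severity(self):
        vals = []
        for width in np.linspace(105, 135, 5):
            spec = cq.PhantomSpec(base_length_mm=160, base_width_mm=width,
                                  occipital_bulge=0.05, frontal_bossing=0.04)
            f = extract_features(outline_to_curve(cq.make_outline(spec)))
            vals.append(severity_index(f)[0])
        assert np.all(np.diff(vals) < 0)


class TestCranialIndex:
    def test_traditional_arithmetic(self):
        assert ci_traditional(100, 125) == pytest.approx(80.0)
        assert ci_traditional(100, 100) == pytest.approx(100.0)

    def test_traditional_rejects_nonpositive(self):
        with pytest.raises(SeverityError):
            ci_traditional(0, 100)

    def test_traditional_from_ellipse_outline(self, ellipse_spec):
        out = cq.make_outline(ellipse_spec)
        assert ci_traditional_from_outline(out) == pytest.approx(62.5, rel=0.005)

    def test_curve_index_from_cohort_extrema(self):
        assert ci_curve(_features(1.18, 1.24, 0.79, 0.79)) == pytest.approx(
            100 * 1.58 / 2.42, abs=1e-9
        )
        assert round(ci_curve(_features(1.18, 1.24, 0.79, 0.79)), 2) == 65.29

    def test_curve_index_of_circle_is_100(self):
        assert ci_curve(_features(1.0, 1.0, 1.0, 1.0)) == pytest.approx(100.0)

    def test_curve_index_underestimates_traditional_on_peaked_heads(self):
        """With peaks at the anteroposterior extremes, the curve-based
        index sits below the extent-based one."""
        for spec in cq.make_cohort(5, seed=3, severity_range=(0.5, 1.0)):
            out = cq.make_outline(spec)
            f = extract_features(outline_to_curve(out))
            assert ci_curve(f) < ci_traditional_from_outline(out)

    def test_two_indices_track_across_sweep(self):
        """Across a 50-phantom sweep spanning roughly CI 55-80 the two
        cranial indices correlate strongly."""
        trad, curv = [], []
        for spec in cq.make_cohort(50, seed=4, severity_range=(0.0, 1.0)):
            out = cq.make_outline(spec)
            f = extract_features(outline_to_curve(out))
            trad.append(ci_traditional_from_outline(out))
            curv.append(ci_curve(f))
        assert min(trad) < 62 and max(trad) > 78  # sweep covers the range
        res = cq.pearson(trad, curv)
        assert res.r > 0.9


def test_severity_monotone_in_combined_severity_dial():
    """Combined narrowing + bossing sweep: severity index strictly rises,
    curve cranial index strictly falls."""
    sev, ci = [], []
    for s in np.linspace(0.2, 1.0, 5):
        spec = cq.PhantomSpec(
            base_length_mm=150 + 28 * s, base_width_mm=128 - 22 * s,
            frontal_bossing=0.035 * s, occipital_bulge=0.05 * s,
            temporal_narrowing=0.04 * s,
        )
        f = extract_features(outline_to_curve(cq.make_outline(spec)))
        sev.append(severity_index(f)[0])
        ci.append(ci_curve(f))
    assert np.all(np.diff(sev) > 0)
    assert np.all(np.diff(ci) < 0)


def test_evaluate_bundles_layers(scapho_curve, scapho_spec):
    from cranioquant.severity import evaluate

    out = cq.make_outline(scapho_spec)
    f = extract_features(scapho_curve)
    res = evaluate(f, outline=out)
    assert res.severity_class == classify_severity(res.severity_index)
    assert 0 < res.ci_curve < 200 and 0 < res.ci_traditional < 200
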