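"""Neutral-loss annotation, seven-type classification, library identification."""

import itertools

import pytest

from protostane.annotate import (
    DEFAULT_LOSS_VOCABULARY,
    FeatureRecord,
    FragmentPeak,
    annotate_losses,
    annotate_run,
    classify_type,
    fragment_tolerance,
    identify,
    uv_class,
)
from protostane.simulate import SimConfig, simulate_qtof_features

# Printed fragment values whose own loss arithmetic is off by >10 mDa
# (typos in the transcribed table); they cannot round-trip and are excluded.
ANOMALOUS_FRAGMENTS = {
    (1, 451.3416),
    (5, 415.2650),
    (5, 379.3427),
    (11, 415.2652),
    (15, 495.3598),
    (15, 435.3592),
    (20, 451.3321),
    (22, 437.2426),
}


def _chain_composition(losses):
    total: dict[str, int] = {}
    for loss in losses:
        for elem, n in loss.composition.counts:
            total[elem] = total.get(elem, 0) + n
    return total


def _label_composition(labels):
    from protostane.annotate import DEFAULT_LOSS_VOCABULARY

    by_label = {l.label: l for l in DEFAULT_LOSS_VOCABULARY}
    total: dict[str, int] = {}
    for lab in labels:
        for elem, n in by_label[lab].composition.counts:
            total[elem] = total.get(elem, 0) + n
    return total


class TestAnnotateLosses:
    def test_single_losses_water_and_acetic_acid(self):
        anns = annotate_losses(529.3522, [FragmentPeak(511.3424), FragmentPeak(469.3313)])
        assert [l.label for l in anns[0].loss_chain] == ["H2O"]
        assert [l.label for l in anns[1].loss_chain] == ["HAc"]

    def test_fragment_at_precursor_gets_empty_chain(self):
        (ann,) = annotate_losses(529.3522, [FragmentPeak(529.3522)])
        assert ann.matched and ann.loss_chain == () and ann.ppm == 0.0
        assert ann.label == "[M+H]+"

    def test_empty_vocabulary_rejected(self):
        with pytest.raises(ValueError):
            annotate_losses(500.0, [FragmentPeak(450.0)], losses=())

    def test_unexplainable_fragment_left_unassigned(self):
        (ann,) = annotate_losses(500.0, [FragmentPeak(470.0)])
        assert not ann.matched and ann.label == "unassigned"

    def test_chain_search_equals_brute_force_oracle(self):
        """All instances with <= 6 vocabulary losses and depth <= 3."""
        import random

        rng = random.Random(13958)
        vocab = DEFAULT_LOSS_VOCABULARY[:6]
        for _ in range(150):
            precursor = rng.uniform(300.0, 600.0)
            # half the fragments are true chain products, half are random
            if rng.random() < 0.5:
                chain = [rng.choice(vocab) for _ in range(rng.randint(1, 3))]
                frag = precursor - sum(l.mass for l in chain)
                frag *= 1 + rng.uniform(-8e-6, 8e-6)
            else:
                frag = rng.uniform(100.0, precursor)
            if frag <= 0:
                continue
            (got,) = annotate_losses(precursor, [FragmentPeak(frag)], vocab, max_depth=3)
            expected = self._oracle(precursor, frag, vocab, 3)
            if expected is None:
                assert not got.matched
            else:
                assert got.matched
                assert len(got.loss_chain) == expected[0]
                assert abs(got.ppm) == pytest.approx(expected[1], abs=1e-6)
                assert tuple(l.label for l in got.loss_chain) == expected[2]

    @staticmethod
    def _oracle(precursor, frag, vocab, depth):
        from protostane.chem import MONOISOTOPIC_MASS

        def combo_mass(combo):
            total: dict[str, int] = {}
            for loss in combo:
                for elem, n in loss.composition.counts:
                    total[elem] = total.get(elem, 0) + n
            return sum(MONOISOTOPIC_MASS[e] * n for e, n in sorted(total.items()))

        tol = fragment_tolerance(frag)
        best = None
        for d in range(0, depth + 1):
            for combo in itertools.product(vocab, repeat=d):
                exp = precursor - combo_mass(combo)
                if exp <= 0 or abs(frag - exp) > tol:
                    continue
                ppm = (frag - exp) / exp * 1e6
                labels = tuple(sorted(l.label for l in combo))
                key = (d, abs(ppm), labels)
                if best is None or key < best:
                    best = key
        return best

    def test_packaged_fragments_round_trip_to_printed_losses(self, library):
        """Every consistent printed fragment is explained by a chain whose
        summed elemental composition equals the printed loss labels'.

        Chains that are exactly mass-degenerate (e.g. C4H8O + H2O vs
        C4H10O2) count as matches; the known typo values and the entry with
        the inconsistent precursor are excluded.
        """
        for entry in library:
            if entry.mz_anomalous:
                continue
            anns = annotate_losses(
                entry.reported_precursor_mz,
                [FragmentPeak(mz) for mz in entry.expected_fragments],
            )
            for mz, printed, ann in zip(entry.expected_fragments, entry.expected_losses, anns):
                if (entry.peak, mz) in ANOMALOUS_FRAGMENTS:
                    continue
                assert ann.matched, f"peak {entry.peak} fragment {mz} unannotated"
                assert len(ann.loss_chain) <= 4
                assert _chain_composition(ann.loss_chain) == _label_composition(printed)


class TestClassifyType:
    def test_uv_binning(self):
        assert uv_class(287.0) == "287-band"
        assert uv_class(243.0) == "245-band"
        assert uv_class(None) == "none"
        assert uv_class(210.0) == "none"

    def test_conjugated_skeleton_with_287_band_is_type_i(self):
        feat = FeatureRecord(25.91, 469.3315, (FragmentPeak(397.2745),), uv_lambda_max=287)
        assert classify_type(feat) == "I"

    def test_skeleton_ion_383_without_uv_is_type_iii(self):
        feat = FeatureRecord(49.06, 515.3739, (FragmentPeak(383.2983),))
        assert classify_type(feat) == "III"

    def test_no_fragments_is_unclassified(self):
        assert classify_type(FeatureRecord(10.0, 500.0)) is None

    def test_shared_ion_with_wrong_uv_is_unclassified(self):
        # the I/II skeleton ion without any UV band matches neither rule
        feat = FeatureRecord(20.0, 505.0, (FragmentPeak(397.2745),))
        assert classify_type(feat) is None

    def test_packaged_records_reproduce_reported_grouping(self, library, packaged_features):
        expected = {
            "I": {6, 14, 20},
            "II": {1, 2, 3, 5, 11},
            "III": {16, 17, 18, 21, 22, 23},
            "IV": {9, 10, 15},
            "V": {24, 25},
            "VI": {4, 8, 12, 19},
            "VII": {7, 13},
        }
        got: dict[str, set] = {}
        for entry, feat in zip(library, packaged_features):
            got.setdefault(classify_type(feat), set()).add(entry.peak)
        assert got == expected

    def test_invariant_to_fragment_order_and_intensity(self, packaged_features):
        for feat in packaged_features:
            scaled = FeatureRecord(
                feat.retention_time,
                feat.precursor_mz,
                tuple(FragmentPeak(p.mz, p.intensity * 731.0) for p in reversed(feat.fragments)),
                feat.uv_lambda_max,
            )
            assert classify_type(scaled) == classify_type(feat)


class TestIdentify:
    def test_standard_confirmed_compound_matches(self, library):
        feat = FeatureRecord(
            25.91, 469.3315, (FragmentPeak(451.3216), FragmentPeak(397.2745)), uv_lambda_max=287
        )
        res = identify(feat, library)
        assert res.mode == "standard-match"
        assert res.matched_entry.name == "alisol L"

    def test_compound_without_standard_is_tentative(self, library):
        feat = FeatureRecord(
            19.72,
            489.3562,
            (FragmentPeak(471.3471), FragmentPeak(453.3367), FragmentPeak(399.2896)),
            uv_lambda_max=245,
        )
        res = identify(feat, library)
        assert res.mode == "tentative"
        assert str(res.assigned_formula) == "C30H48O5"
        assert res.assigned_type == "VII"

    def test_feature_far_from_everything_is_unidentified(self, library):
        # m/z chosen so that no CHO formula sits within 5 ppm
        feat = FeatureRecord(99.0, 470.0000)
        res = identify(feat, library)
        assert res.mode == "unidentified"

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            identify(FeatureRecord(1.0, 500.0), [])


class TestAnnotateRun:
    def test_packaged_run_summary(self, library, packaged_features):
        report = annotate_run(packaged_features, library)
        assert report.n_features == 25
        assert report.n_identified == 25
        assert report.n_standard_matches == 21
        assert report.type_tally == {
            "I": 3, "II": 5, "III": 6, "IV": 3, "V": 2, "VI": 4, "VII": 2,
        }

    def test_empty_input_empty_report(self, library):
        report = annotate_run([], library)
        assert report.n_features == 0 and report.summary()["n_identified"] == 0

    def test_simulated_features_recovered(self, library):
        """At 2 ppm MS1 noise the run names >= 95% of compounds correctly."""
        ok = total = 0
        for seed in range(20):
            feats, truth = simulate_qtof_features(library, SimConfig(seed=seed))
            report = annotate_run(feats, library)
            for res, true_name in zip(report.results, truth.feature_compounds):
                total += 1
                ok += res.matched_entry is not None and res.matched_entry.name == true_name
        assert ok / total >= 0.95
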