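import warnings

import numpy as np
import pandas as pd
import pytest

from metaphylo.simulate import SimulationConfig, emit_flank_counts
from metaphylo.tiers import (CharacterMatrix, apply_tier3_filters,
                             call_presence, estimate_background_noise,
                             promote_tier4)


def _obs(rows):
    return pd.DataFrame(rows, columns=["patient", "sample", "snv_id",
                                       "ref_reads", "alt_reads"])


def _cell(sample, snv, depth, vaf):
    alt = int(round(depth * vaf))
    return dict(patient="X", sample=sample, snv_id=snv,
                ref_reads=depth - alt, alt_reads=alt)


class TestBackgroundNoise:
    def test_clean_positions_give_zero_noise(self):
        table = pd.DataFrame(dict(substitution_class=["CG>TA"] * 10,
                                  depth=[2000] * 10, nonref_reads=[0] * 10))
        est, max_mean = estimate_background_noise(table)
        assert est["CG>TA"].mean_background == 0.0
        assert est["CG>TA"].sd_background == 0.0
        assert max_mean == 0.0

    def test_position_above_ten_percent_is_excluded(self):
        clean = [dict(substitution_class="CG>TA", depth=1000, nonref_reads=5)
                 for _ in range(20)]
        spike = [dict(substitution_class="CG>TA", depth=1000, nonref_reads=120)]
        est_clean, _ = estimate_background_noise(pd.DataFrame(clean))
        est_spiked, _ = estimate_background_noise(pd.DataFrame(clean + spike))
        assert est_spiked["CG>TA"].mean_background == \
            est_clean["CG>TA"].mean_background
        assert est_spiked["CG>TA"].n_positions == 20

    def test_fully_excluded_class_is_absent_not_zero(self):
        table = pd.DataFrame(dict(substitution_class=["AT>CG"] * 3,
                                  depth=[100] * 3, nonref_reads=[50] * 3))
        est, max_mean = estimate_background_noise(table)
        assert "AT>CG" not in est
        assert np.isnan(max_mean)

    def test_planted_class_error_recovered_from_simulation(self):
        cfg = SimulationConfig(seed=17, depth_mean=4000)
        table = emit_flank_counts(cfg, n_positions=10000,
                                  class_error={c: 0.005 for c in
                                               ("AT>CG", "AT>GC", "AT>TA",
                                                "CG>AT", "CG>GC", "CG>TA")})
        est, max_mean = estimate_background_noise(table)
        for cls, e in est.items():
            assert abs(e.mean_background - 0.005) < 0.001
        assert abs(max_mean - 0.005) < 0.001


class TestPresenceCall:
    @pytest.mark.parametrize("vaf, expected", [
        (0.0, False), (0.029, False), (0.03, True), (0.031, True), (0.5, True),
    ])
    def test_three_percent_cutoff_boundary(self, vaf, expected):
        assert call_presence(vaf) is expected

    def test_vectorised_call(self):
        out = call_presence(np.array([0.0, 0.03, 0.1]))
        assert out.tolist() == [False, True, True]

    def test_invalid_vaf_rejected(self):
        with pytest.raises(ValueError):
            call_presence(1.5)


class TestTier3Filters:
    def test_clean_deep_matrix_keeps_everything(self):
        rows = [_cell(s, f"v{i}", 5000, 0.5)
                for s in ("A", "B", "C") for i in range(4)]
        m = apply_tier3_filters(_obs(rows))
        assert m.calls.shape == (3, 4)
        assert (m.calls == 1.0).all().all()

    def test_low_coverage_sample_dropped(self):
        rows = []
        for i in range(10):
            for s in ("A", "B", "C"):
                depth = 1000 if (s == "C" and i < 6) else 5000
                rows.append(_cell(s, f"v{i}", depth, 0.5))
        m = apply_tier3_filters(_obs(rows))
        assert "C" not in m.samples
        assert set(m.samples) == {"A", "B"}

    def test_boundary_depth_is_missing(self):
        # coverage must exceed 1,500x: a cell at exactly 1,500 is missing
        rows = [_cell(s, f"v{i}", 5000, 0.5)
                for s in ("A", "B", "C") for i in range(4)]
        rows = [r for r in rows if not (r["sample"] == "C"
                                        and r["snv_id"] == "v1")]
        rows += [_cell("C", "v1", 1500, 0.5)]
        m = apply_tier3_filters(_obs(rows), max_snv_missing=1)
        assert np.isnan(m.calls.loc["C", "v1"])

    def test_snv_with_two_missing_cells_dropped(self):
        rows = []
        for s in ("A", "B", "C", "D"):
            for i in range(5):
                rows.append(_cell(s, f"good{i}", 5000, 0.5))
            depth = 1200 if s in ("A", "B") else 5000
            rows.append(_cell(s, "holey", depth, 0.5))
        m = apply_tier3_filters(_obs(rows))
        assert "holey" not in m.snvs
        assert len(m.snvs) == 5

    def test_snv_absent_everywhere_dropped(self):
        rows = []
        for s in ("A", "B", "C"):
            rows.append(_cell(s, "real", 5000, 0.4))
            rows.append(_cell(s, "noise", 5000, 0.02))
        m = apply_tier3_filters(_obs(rows))
        assert m.snvs == ["real"]

    def test_sample_with_too_few_present_snvs_dropped(self):
        rows = []
        for i in range(10):
            for s in ("A", "B", "C"):
                vaf = 0.5 if s != "C" else (0.5 if i < 2 else 0.0)
                rows.append(_cell(s, f"v{i}", 5000, vaf))
        m = apply_tier3_filters(_obs(rows))
        assert "C" not in m.samples

    def test_empty_result_warns(self):
        rows = [_cell(s, "v0", 5000, 0.0) for s in ("A", "B", "C")]
        with pytest.warns(UserWarning, match="empty"):
            m = apply_tier3_filters(_obs(rows))
        assert m.is_empty

    def test_filters_are_idempotent(self, reversion_patient):
        _, _, counts = reversion_patient
        m1 = apply_tier3_filters(counts)
        # feed the retained cells back through the filter chain
        keep = counts["sample"].isin(m1.samples) & counts["snv_id"].isin(m1.snvs)
        m2 = apply_tier3_filters(counts[keep])
        pd.testing.assert_frame_equal(m1.calls.sort_index(axis=1),
                                      m2.calls.sort_index(axis=1))

    def test_raising_min_depth_never_retains_more(self, reversion_patient):
        _, _, counts = reversion_patient
        sizes = []
        for depth in (1000, 1500, 2500, 3500):
            m = apply_tier3_filters(counts, min_depth=depth)
            sizes.append((len(m.samples), len(m.snvs)))
        for (s1, v1), (s2, v2) in zip(sizes, sizes[1:]):
            assert s2 <= s1 and v2 <= v1

    def test_noise_free_matrix_equals_planted_truth(self, clean_patient):
        cfg, truth, counts = clean_patient
        m = apply_tier3_filters(counts)
        informative = [c for c in truth.presence.columns
                       if truth.presence[c].any()]
        assert sorted(m.snvs) == sorted(informative)
        expected = truth.presence.loc[m.samples, sorted(m.snvs)].astype(float)
        got = m.calls[sorted(m.snvs)]
        pd.testing.assert_frame_equal(got, expected, check_names=False)


class TestTier4Promotion:
    @pytest.mark.parametrize("ccf, tier", [(0.29, 3), (0.30, 4), (0.31, 4),
                                           (1.0, 4)])
    def test_thirty_percent_boundary(self, ccf, tier):
        m = CharacterMatrix(pd.DataFrame([[1.0]], index=["A"], columns=["v"]))
        out = promote_tier4(m, {"A": ccf})
        assert out.sample_tier["A"] == tier

    def test_missing_ccf_warns_and_stays_tier3(self):
        m = CharacterMatrix(pd.DataFrame([[1.0], [1.0]], index=["A", "B"],
                                         columns=["v"]))
        with pytest.warns(UserWarning, match="no CCF"):
            out = promote_tier4(m, {"A": 0.9})
        assert out.sample_tier == {"A": 4, "B": 3}


def test_matrix_tsv_round_trip(tmp_path):
    calls = pd.DataFrame([[1.0, 0.0, np.nan], [0.0, 1.0, 1.0]],
                         index=["A", "B"], columns=["v1", "v2", "v3"])
    m = promote_tier4(CharacterMatrix(calls), {"A": 0.9, "B": 0.2})
    path = tmp_path / "matrix.tsv"
    m.to_tsv(path)
    back = CharacterMatrix.from_tsv(path)
    pd.testing.assert_frame_equal(back.calls, m.calls)
    assert back.sample_tier == m.sample_tier
    assert back.tier == m.tier


def test_outgroup_row_is_all_absent():
    m = CharacterMatrix(pd.DataFrame([[1.0, 0.0]], index=["A"],
                                     columns=["v1", "v2"]))
    out = m.with_outgroup()
    assert (out.calls.loc["N"] == 0.0).all()
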