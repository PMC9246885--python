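"""Replicate aggregation, control subtraction, ratio estimators, profiles."""

import numpy as np
import pandas as pd
import pytest

from rnarray.design import DesignTable, TemplateSpec, make_control, make_template
from rnarray.quant import (
    DegenerateNormalizationError,
    MissingReferenceError,
    UndefinedRatioError,
    aggregate,
    background_correct_normalize,
    conversion_efficiency,
    degradation_residual,
    positional_profile,
)
from rnarray.scansim import Arm, ScanTable, SimParams, simulate_scan
from rnarray.design import da_walk_series

from conftest import GREEN


def _scan(values_by_probe, channel=532):
    rows = []
    i = 0
    for pid, values in values_by_probe.items():
        for v in values:
            rows.append({"row": i // 100, "col": i % 100, "probe_id": pid,
                         "channel": channel, "F": float(v), "B": 0.0})
            i += 1
    return ScanTable(pd.DataFrame(rows))


class TestAggregate:
    def test_mean_and_sd(self):
        stats = aggregate(_scan({"p": [10, 20, 30]}))
        assert stats.loc["p", "mean"] == 20.0
        assert stats.loc["p", "sd"] == pytest.approx(10.0)
        assert stats.loc["p", "n_excluded"] == 0

    def test_dust_rule_excludes_planted_outliers(self):
        rng = np.random.default_rng(2)
        base = rng.normal(1000, 100, size=83)
        values = np.concatenate([base, [100_000.0, 95_000.0]])  # dust at ~100x
        stats = aggregate(_scan({"p": values}), exclude="mad")
        assert stats.loc["p", "n_excluded"] == 2
        assert stats.loc["p", "n_replicates"] == 85
        assert stats.loc["p", "mean"] == pytest.approx(base.mean(), rel=0.01)

    def test_rule_off_by_default(self):
        values = list(np.full(84, 100.0)) + [100_000.0]
        stats = aggregate(_scan({"p": values}))
        assert stats.loc["p", "n_excluded"] == 0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        values = rng.normal(500, 50, size=24)
        a = aggregate(_scan({"p": values}))
        b = aggregate(_scan({"p": rng.permutation(values)}))
        assert a.loc["p", "mean"] == pytest.approx(b.loc["p", "mean"])
        assert a.loc["p", "sd"] == pytest.approx(b.loc["p", "sd"])

    def test_missing_probe_reported(self):
        design = DesignTable([make_template(GREEN, 5, probe_id="absent")])
        stats = aggregate(_scan({"p": [1.0]}), design)
        assert stats.attrs["missing_probes"] == ["absent"]
        assert "absent" not in stats.index


class TestBackgroundCorrectNormalize:
    def test_subtract_and_normalize(self):
        out = background_correct_normalize(
            {"a": 100.0, "b": 80.0}, {"ca": 20.0, "cb": 20.0}, {"a": "ca", "b": "cb"}
        )
        assert out.loc["a", "corrected"] == 80.0
        assert out.loc["b", "corrected"] == 60.0
        assert out.loc["a", "normalized"] == 1.0
        assert out.loc["b", "normalized"] == 0.75

    def test_floor_at_zero(self):
        out = background_correct_normalize(
            {"a": 10.0, "b": 100.0}, {"c": 50.0}, {"a": "c", "b": "c"}
        )
        assert out.loc["a", "corrected"] == 0.0

    def test_shift_invariance(self):
        base = background_correct_normalize({"a": 100.0}, {"c": 20.0}, {"a": "c"})
        shifted = background_correct_normalize({"a": 400.0}, {"c": 320.0}, {"a": "c"})
        assert base.loc["a", "corrected"] == shifted.loc["a", "corrected"]

    def test_degenerate_normalization(self):
        with pytest.raises(DegenerateNormalizationError):
            background_correct_normalize({"a": 10.0}, {"c": 50.0}, {"a": "c"})

    def test_normalization_idempotence(self):
        out = background_correct_normalize(
            {"a": 100.0, "b": 80.0}, {"ca": 20.0, "cb": 20.0}, {"a": "ca", "b": "cb"}
        )
        again = background_correct_normalize(
            out["normalized"].to_dict(), {"ca": 0.0, "cb": 0.0}, {"a": "ca", "b": "cb"}
        )
        assert np.allclose(again["normalized"], out["normalized"])


class TestRatioEstimators:
    def test_simple_percentage(self):
        rep = conversion_efficiency(
            _scan({"r": [20.0] * 4}), _scan({"d": [100.0] * 4}), {"r": "d"}, n_boot=50
        )
        assert rep.summary.ratio == pytest.approx(20.0)

    def test_identical_tables_give_100pct(self):
        scan = _scan({"p": [50.0, 60.0, 70.0]})
        rep = conversion_efficiency(scan, scan, {"p": "p"}, n_boot=50)
        assert rep.summary.ratio == pytest.approx(100.0)

    def test_zero_denominator_raises(self):
        with pytest.raises(UndefinedRatioError):
            conversion_efficiency(
                _scan({"r": [1.0] * 3}), _scan({"d": [0.0] * 3}), {"r": "d"}, n_boot=10
            )

    def test_buffer_as_treated_gives_unity_residual(self):
        scan = _scan({"p": [25.0, 30.0, 35.0]})
        rep = degradation_residual(scan, scan, {"p": "p"}, n_boot=50)
        assert rep.summary.ratio == pytest.approx(1.0)

    def test_treated_over_buffer_fraction(self):
        rep = degradation_residual(
            _scan({"p": [25.0] * 4}), _scan({"p": [100.0] * 4}), {"p": "p"}, n_boot=50
        )
        assert rep.summary.ratio == pytest.approx(0.25)


class TestRecovery:
    def test_efficiency_recovered_within_bootstrap_ci(self, paired_design, pairing):
        """Simulated scans at e=0.20 recover 20% within the bootstrap CI
        (nominal 95% coverage over 20 fixed simulation seeds)."""
        layout = paired_design.randomized_layout(seed=11)
        covered = 0
        estimates = []
        for s in range(20):
            scans = simulate_scan(
                layout,
                paired_design,
                SimParams(seed=100 + s, efficiency=0.20, cv=0.2),
                [Arm("treated"), Arm("untreated", converted=False)],
            )
            rep = conversion_efficiency(
                scans["treated"], scans["untreated"], pairing,
                n_boot=400, seed=3, background_probe="bgdark",
            )
            estimates.append(rep.summary.ratio)
            covered += rep.summary.ci_low <= 20.0 <= rep.summary.ci_high
        assert covered >= 16  # binomial slack around 95% nominal coverage
        assert np.mean(estimates) == pytest.approx(20.0, abs=0.5)

    @pytest.mark.parametrize("arm_name, residual", [("t2h", 0.5), ("t6h", 0.22)])
    def test_degradation_residual_recovered(self, paired_design, arm_name, residual):
        layout = paired_design.randomized_layout(seed=11)
        scans = simulate_scan(
            layout,
            paired_design,
            SimParams(seed=9, cv=0.2),
            [Arm("t2h", residual=0.5), Arm("t6h", residual=0.22), Arm("buffer")],
        )
        rep = degradation_residual(
            scans[arm_name], scans["buffer"],
            {f"c{i}": f"c{i}" for i in range(4)},
            n_boot=400, seed=3, background_probe="bgdark",
        )
        assert rep.summary.ci_low <= residual <= rep.summary.ci_high

    def test_bias_shrinks_with_replicates(self, pairing):
        """Ratio estimates tighten around truth as replicate counts grow."""
        from rnarray.design import make_control, make_template

        errors = []
        for n in (8, 24, 62, 85):
            design = DesignTable(
                [make_template(GREEN, 5, probe_id="t0"), make_control(GREEN, 5, probe_id="c0")],
                replicate_count=n,
            )
            layout = design.randomized_layout(seed=5)
            ratios = []
            for s in range(8):
                scans = simulate_scan(
                    layout, design,
                    SimParams(seed=50 + s, efficiency=0.20, cv=0.2, background=0.0),
                    [Arm("treated"), Arm("untreated", converted=False)],
                )
                rep = conversion_efficiency(
                    scans["treated"], scans["untreated"], {"t0": "c0"}, n_boot=10, seed=1
                )
                ratios.append(rep.summary.ratio)
            errors.append(abs(np.mean(ratios) - 20.0))
        assert errors[-1] < errors[0] + 0.5  # no blow-up; converging scatter
        assert errors[-1] < 1.0


@pytest.fixture(scope="module")
def walk():
    return da_walk_series()


class TestPositionalProfile:
    def test_noise_free_plateau_is_exact(self, walk):
        layout = walk.randomized_layout(seed=3, n_rows=60, n_cols=60)
        scans = simulate_scan(layout, walk, SimParams(seed=5, mode="cy3_utp", cv=0.0))
        prof = positional_profile(scans["default"], walk)
        assert prof.final_window_mean == pytest.approx(0.70, abs=1e-9)
        # relative intensity at position 1 is unity by construction
        rel1 = prof.profile.loc[prof.profile["position"] == 1, "relative"].iloc[0]
        assert rel1 == 1.0

    def test_flat_profile_when_no_decay(self, walk):
        layout = walk.randomized_layout(seed=3, n_rows=60, n_cols=60)
        params = SimParams(seed=5, mode="cy3_utp", cv=0.0, decay=1.0, plateau=0.0)
        scans = simulate_scan(layout, walk, params)
        prof = positional_profile(scans["default"], walk)
        assert np.allclose(prof.profile["relative"], 1.0)

    def test_noisy_plateau_recovered_within_3se(self, walk):
        layout = walk.randomized_layout(seed=3, n_rows=60, n_cols=60)
        scans = simulate_scan(layout, walk, SimParams(seed=17, mode="cy3_utp", cv=0.2))
        prof = positional_profile(scans["default"], walk)
        # SE of the plateau statistic: cv/sqrt(85) per variant mean, 7 variants
        se = 0.70 * 0.2 / np.sqrt(85) / np.sqrt(7) * np.sqrt(2)
        assert abs(prof.final_window_mean - 0.70) < 3 * max(se, 0.01)

    def test_missing_position1_raises(self, walk):
        layout = walk.randomized_layout(seed=3, n_rows=60, n_cols=60)
        scans = simulate_scan(layout, walk, SimParams(seed=5, mode="cy3_utp", cv=0.0))
        frame = scans["default"].frame
        pruned = ScanTable(frame[frame["probe_id"] != "daA_pos01"])
        with pytest.raises(MissingReferenceError):
            positional_profile(pruned, walk)

    def test_pipeline_determinism(self, walk):
        layout = walk.randomized_layout(seed=3, n_rows=60, n_cols=60)
        out = []
        for _ in range(2):
            scans = simulate_scan(layout, walk, SimParams(seed=23, mode="cy3_utp", cv=0.2))
            prof = positional_profile(scans["default"], walk)
            out.append(prof.profile.to_csv())
        assert out[0] == out[1]
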