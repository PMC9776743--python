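"""Hierarchical gating: thresholds, pre-gates, and deconvolution."""

import numpy as np
import pandas as pd
import pytest

from fgbkit import (
    MeasurementModel,
    classify_caar,
    classify_fluor,
    deconvolute,
    fit_thresholds,
    generate_events,
    pregate,
)
from fgbkit.gating import (
    UNASSIGNED_FLUOR,
    VECTOR_NEGATIVE,
    GateThresholds,
    ThresholdWarning,
    _mixture_threshold,
)
from fgbkit.registry import CHANNELS, CaarPermutation, FluorCombo


def synthetic_channel_frame(rng, n=5000, neg=2.0, pos=4.0, sd=0.3):
    """Half-negative/half-positive log-normal intensities on every channel."""
    data = {}
    for ch in ("FSC-A", "FSC-H"):
        data[ch] = 10 ** rng.normal(5.0, 0.1, n)
    data["SSC-A"] = 10 ** rng.normal(4.5, 0.15, n)
    data["DAPI"] = 10 ** rng.normal(2.0, sd, n)
    for ch in CHANNELS:
        state = rng.random(n) < 0.5
        data[ch] = 10 ** rng.normal(np.where(state, pos, neg), sd)
    return pd.DataFrame(data)


class TestFitThresholds:
    def test_mixture_threshold_at_equal_posterior(self):
        """For components N(2, .3) and N(4, .3), the cutoff sits near 3."""
        rng = np.random.default_rng(0)
        log_values = np.concatenate(
            [rng.normal(2.0, 0.3, 4000), rng.normal(4.0, 0.3, 4000)]
        )
        cut = _mixture_threshold(log_values, seed=0)
        assert 2.6 < cut < 3.4

    def test_percentile_method_definition(self, registry, default_model):
        rng = np.random.default_rng(1)
        control = synthetic_channel_frame(rng)
        # all-negative control on hmAG3
        control["hmAG3"] = 10 ** rng.normal(2.0, 0.3, len(control))
        events = synthetic_channel_frame(rng)
        thr = fit_thresholds(events, method="percentile", controls=control, percentile=99.9)
        below = (np.log10(control["hmAG3"]) <= thr.marker_cutoffs["hmAG3"]).mean()
        assert below >= 0.999

    def test_log_scale_equivariance(self):
        """Scaling intensities by 10 shifts every log cutoff by exactly 1."""
        rng = np.random.default_rng(2)
        events = synthetic_channel_frame(rng)
        thr = fit_thresholds(events, seed=0)
        thr10 = fit_thresholds(events * 10.0, seed=0)
        for ch in CHANNELS:
            assert thr10.marker_cutoffs[ch] == pytest.approx(
                thr.marker_cutoffs[ch] + 1.0, abs=0.02
            )

    def test_unimodal_marker_falls_back_with_warning(self, registry, equal_mix, default_model):
        events = generate_events(equal_mix, 5000, default_model, registry, seed=4)
        with pytest.warns(ThresholdWarning):
            thr = fit_thresholds(events, seed=0)
        # EGFRt is bright on every code: unimodal, resolved by the pooled cutoff
        assert thr.method["EGFRt"].endswith("pooled_fallback")
        assert 2.5 < thr.marker_cutoffs["EGFRt"] < 3.5

    def test_valley_method(self):
        rng = np.random.default_rng(3)
        events = synthetic_channel_frame(rng)
        thr = fit_thresholds(events, method="valley", seed=0)
        assert 2.5 < thr.marker_cutoffs["YFP"] < 3.5

    def test_too_few_events_for_mixture(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            fit_thresholds(synthetic_channel_frame(rng, n=100), method="mixture2")

    def test_thresholds_roundtrip_json(self, fitted_thresholds, tmp_path):
        path = tmp_path / "thr.json"
        fitted_thresholds.to_json(path)
        restored = GateThresholds.from_json(path)
        assert restored.marker_cutoffs == fitted_thresholds.marker_cutoffs
        assert restored.dapi_max == fitted_thresholds.dapi_max


class TestPregate:
    def test_clean_sample_fully_survives(self, registry, equal_mix, default_model, fitted_thresholds):
        events = generate_events(equal_mix, 10_000, default_model, registry, seed=5)
        survivors, tally = pregate(events, fitted_thresholds)
        assert tally["survivors"] >= 0.99 * len(events)

    def test_dead_gate_removes_expected_share(self, registry, equal_mix, fitted_thresholds):
        model = MeasurementModel(dead_fraction=0.1)
        n = 20_000
        events = generate_events(equal_mix, n, model, registry, seed=6)
        _, tally = pregate(events, fitted_thresholds)
        sd = np.sqrt(n * 0.1 * 0.9)
        assert abs(tally["dead"] - 0.1 * n) < 5 * sd

    def test_tallies_partition_events(self, registry, equal_mix, fitted_thresholds):
        model = MeasurementModel(debris_fraction=0.05, doublet_fraction=0.05, dead_fraction=0.05)
        events = generate_events(equal_mix, 10_000, model, registry, seed=7)
        survivors, tally = pregate(events, fitted_thresholds)
        assert tally["debris"] + tally["doublet"] + tally["dead"] + len(survivors) == len(events)

    def test_contamination_recovered_per_gate(self, registry, equal_mix, fitted_thresholds):
        model = MeasurementModel(debris_fraction=0.08, doublet_fraction=0.05, dead_fraction=0.06)
        n = 30_000
        events = generate_events(equal_mix, n, model, registry, seed=8)
        _, tally = pregate(events, fitted_thresholds)
        for gate, frac in (("debris", 0.08), ("doublet", 0.05), ("dead", 0.06)):
            sd = np.sqrt(n * frac * (1 - frac))
            assert abs(tally[gate] - frac * n) < 6 * sd, gate


def event_row(thresholds, **log_levels):
    """One event with stated log10 levels (default: mid-positive scatter,
    negative everything else)."""
    base = {"FSC-A": 5.0, "FSC-H": 5.0, "SSC-A": 4.5, "DAPI": 2.0}
    base.update({ch: 2.0 for ch in CHANNELS})
    base.update(log_levels)
    return pd.Series({ch: 10.0**v for ch, v in base.items()})


class TestBooleanClassifiers:
    @pytest.mark.parametrize(
        "bright, expected",
        [
            (("hmAG3",), FluorCombo.HMAG3),
            (("YFP", "mChEY"), FluorCombo.YFP_MCHEY),
            (("YFP", "hmAG3"), FluorCombo.YFP_HMAG3),
            ((), UNASSIGNED_FLUOR),
            (("hmAG3", "YFP", "mChEY"), UNASSIGNED_FLUOR),
        ],
    )
    def test_fluor_patterns(self, fitted_thresholds, bright, expected):
        event = event_row(fitted_thresholds, **{ch: 4.0 for ch in bright})
        assert classify_fluor(event, fitted_thresholds) == expected

    def test_caar_enumeration_bijective(self, fitted_thresholds):
        seen = set()
        for ha in (False, True):
            for cmyc in (False, True):
                for thy in (False, True):
                    levels = {"EGFRt": 4.0}
                    if ha:
                        levels["HA"] = 4.0
                    if cmyc:
                        levels["cMyc"] = 4.0
                    if thy:
                        levels["Thy1.1"] = 4.0
                    call = classify_caar(event_row(fitted_thresholds, **levels), fitted_thresholds)
                    assert call == CaarPermutation(ha, cmyc, thy)
                    seen.add(call)
        assert len(seen) == 8

    def test_egfrt_negative_never_gets_caar_call(self, fitted_thresholds):
        event = event_row(fitted_thresholds, HA=4.0, cMyc=4.0)
        assert classify_caar(event, fitted_thresholds) == VECTOR_NEGATIVE


def boolean_signature_oracle(events, thresholds, registry):
    """Independent per-event classifier: threshold all 7 marker channels and
    look the boolean vector up in the expected-signature map."""
    sig_to_id = {code.signature(): str(code.bc_id) for code in registry}
    labels = []
    for _, row in events.iterrows():
        log_fsc = np.log10(row["FSC-A"])
        if log_fsc <= thresholds.fsc_a_min:
            labels.append("debris")
            continue
        ratio = row["FSC-A"] / row["FSC-H"]
        if abs(ratio - thresholds.singlet_ratio) > thresholds.singlet_tolerance * thresholds.singlet_ratio:
            labels.append("doublet")
            continue
        if np.log10(row["DAPI"]) > thresholds.dapi_max:
            labels.append("dead")
            continue
        bools = tuple(
            np.log10(row[ch]) > thresholds.marker_cutoffs[ch] for ch in CHANNELS
        )
        if not bools[-1]:
            labels.append(VECTOR_NEGATIVE)
            continue
        labels.append(sig_to_id.get(bools, UNASSIGNED_FLUOR))
    return pd.Series(labels, index=events.index)


class TestDeconvolution:
    def test_noiseless_events_assigned_perfectly(self, registry, fitted_thresholds):
        """Intensities pinned at the component means classify without error."""
        rows = []
        for code in registry:
            levels = {
                ch: 4.0 if positive else 2.0
                for ch, positive in zip(CHANNELS, code.signature())
            }
            rows.append(event_row(fitted_thresholds, **levels))
        events = pd.DataFrame(rows).reset_index(drop=True)
        events["truth"] = [str(c.bc_id) for c in registry]
        assignment = deconvolute(events, fitted_thresholds, registry)
        assert assignment.accuracy == 1.0
        assert (assignment.labels.to_numpy() == events["truth"].to_numpy()).all()

    def test_equals_boolean_signature_oracle(self, registry, equal_mix, fitted_thresholds):
        model = MeasurementModel(
            debris_fraction=0.03, doublet_fraction=0.03, dead_fraction=0.03, dim_fraction=0.02
        )
        events = generate_events(equal_mix * 0.95, 10_000, model, registry, seed=9)
        assignment = deconvolute(events, fitted_thresholds, registry)
        oracle = boolean_signature_oracle(events, fitted_thresholds, registry)
        assert (assignment.labels.to_numpy() == oracle.to_numpy()).all()

    def test_every_event_gets_exactly_one_label(self, registry, equal_mix, fitted_thresholds, default_model):
        events = generate_events(equal_mix, 5000, default_model, registry, seed=10)
        assignment = deconvolute(events, fitted_thresholds, registry)
        assert len(assignment.labels) == len(events)
        assert assignment.labels.notna().all()

    def test_fraction_estimator_unbiased(self, registry, equal_mix, fitted_thresholds, default_model):
        n = 100_000
        events = generate_events(equal_mix, n, default_model, registry, seed=12)
        assignment = deconvolute(events, fitted_thresholds, registry)
        p = 1 / 48
        sd = np.sqrt(p * (1 - p) / assignment.counts.sum())
        assert (np.abs(assignment.fractions - p) < 5 * sd).all()
        assert assignment.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_accuracy_degrades_with_shrinking_separation(self, registry, equal_mix):
        accuracies = []
        for pos in (4.0, 3.2, 2.8):
            model = MeasurementModel(pos_logmean=pos)
            events = generate_events(equal_mix, 20_000, model, registry, seed=13)
            thr = fit_thresholds(events, seed=0)
            accuracies.append(deconvolute(events, thr, registry).accuracy)
        assert accuracies[0] > accuracies[1] > accuracies[2]
        assert accuracies[0] >= 0.99

    def test_dim_events_leave_the_coded_gate(self, registry, equal_mix, fitted_thresholds):
        """Variegated (dim) cells fall below the positive cutoffs and are
        mostly read as vector-negative or unassigned, not as codes."""
        model = MeasurementModel(dim_fraction=0.3, dim_logmean=2.2)
        events = generate_events(equal_mix, 20_000, model, registry, seed=14)
        assignment = deconvolute(events, fitted_thresholds, registry)
        coded = assignment.labels.str.fullmatch(r"\d+").mean()
        assert coded < 0.8
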