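"""Synthetic-cohort generator: ground truth, effects, signals, recovery."""

import numpy as np
import pandas as pd
import pytest

from histoptm import abundance as ab
from histoptm import io, marks, pipeline, xic
from histoptm import simulate as sim
from histoptm.constants import ARG10_DELTA
from histoptm.library import PeptideLibrary, mz as _mz


class TestProfiles:
    def test_baseline_sums_to_100_per_family(self, default_library):
        prof = sim.expand_baseline(default_library)
        fam = pd.Series(
            {f.form_id: f.family_id for f in default_library}
        )
        sums = prof.groupby(fam).sum()
        assert np.allclose(sums, 100.0)

    def test_fold_change_one_leaves_profiles_identical(self, default_library):
        cfg = sim.CohortConfig(
            fold_changes={"total_H3K14ac": 1.0}, seed=1
        )
        truth = sim.generate_cohort(cfg, default_library)
        pd.testing.assert_series_equal(
            truth.profiles["tumor"], truth.profiles["normal"]
        )

    def test_fold_change_closed_form_renormalization(self, default_library):
        # baseline mark at 40%: halving its members gives 20 raw, family 80,
        # hence 25% after renormalization
        members = marks.builtin_marks()["total_H3K14ac"].members
        baseline = {
            "H3_9-17": {m: 8.0 for m in members}  # mark = 40%
        }
        prof = sim.expand_baseline(default_library, baseline)
        out = sim.apply_fold_changes(
            prof, {"total_H3K14ac": 0.5}, default_library
        )
        assert out[list(members)].sum() == pytest.approx(25.0)

    def test_nonpositive_fold_change_rejected(self, default_library):
        prof = sim.expand_baseline(default_library)
        with pytest.raises(ValueError):
            sim.apply_fold_changes(prof, {"total_H3K14ac": 0.0}, default_library)

    def test_true_ra_sums_to_100(self, noisy_cohort):
        sums = noisy_cohort.true_ra.groupby(["group", "channel", "family_id"])[
            "true_ra"
        ].sum()
        assert np.allclose(sums, 100.0)


class TestDeterminism:
    def test_same_seed_bitwise_identical(self, default_library):
        cfg = sim.CohortConfig(seed=42)
        t1 = sim.generate_cohort(cfg, default_library)
        t2 = sim.generate_cohort(cfg, default_library)
        pd.testing.assert_frame_equal(t1.auc, t2.auc)
        pd.testing.assert_frame_equal(t1.metadata, t2.metadata)

    def test_different_seed_differs(self, default_library):
        t1 = sim.generate_cohort(sim.CohortConfig(seed=1), default_library)
        t2 = sim.generate_cohort(sim.CohortConfig(seed=2), default_library)
        assert not np.allclose(t1.auc["auc"], t2.auc["auc"])


class TestPeaks:
    @pytest.fixture(scope="class")
    def peaks(self, noise_free_truth, default_library):
        return sim.simulate_peaks(noise_free_truth, default_library)

    def test_heavy_offset_per_charge(self, noise_free_truth, default_library):
        form = default_library["H3_9-17:K9me3"]
        for z in (2, 3):
            assert _mz(form, z, "heavy") - _mz(form, z, "light") == (
                pytest.approx(form.n_arg * ARG10_DELTA / z, abs=1e-9)
            )

    def test_missing_form_absent_from_peaks(
        self, noise_free_truth, default_library
    ):
        truth = noise_free_truth
        drop = "H3_73-83:K79ac"
        pruned = sim.GroundTruth(
            truth.metadata, truth.true_ra,
            truth.auc[truth.auc["form_id"] != drop],
            truth.rt_expected, truth.profiles, truth.config,
        )
        peaks = sim.simulate_peaks(pruned, default_library)
        form = default_library[drop]
        for z in (2, 3):
            target = _mz(form, z, "light")
            near = np.abs(peaks["mz"] - target) / target * 1e6 <= 10
            apex = truth.rt_expected[drop]
            in_window = np.abs(peaks["rt"] - apex) < 0.2
            assert not (near & in_window).any()

    def test_family_restriction(self, noise_free_truth, default_library):
        peaks = sim.simulate_peaks(
            noise_free_truth, default_library,
            sim.PeakShapeConfig(families=("H3_9-17",)),
        )
        # all peaks lie in the 9-17 elution neighborhood
        rts = list(noise_free_truth.rt_expected.values())
        fam_forms = [
            f.form_id for f in default_library.family_forms("H3_9-17")
        ]
        lo = min(noise_free_truth.rt_expected[f] for f in fam_forms) - 1
        hi = max(noise_free_truth.rt_expected[f] for f in fam_forms) + 1
        assert peaks["rt"].between(lo, hi).all()

    def test_mz_jitter_stays_within_ppm(self, noise_free_truth, default_library):
        shape = sim.PeakShapeConfig(mz_jitter_ppm=3.0, families=("H3_3-8",))
        peaks = sim.simulate_peaks(
            noise_free_truth, default_library, shape,
            rng=np.random.default_rng(0),
        )
        targets = np.array(
            sorted(
                {_mz(f, z, ch) for f in default_library.family_forms("H3_3-8")
                 for z in (2, 3) for ch in ("light", "heavy")}
            )
        )
        nearest = targets[
            np.argmin(np.abs(peaks["mz"].to_numpy()[:, None] - targets), axis=1)
        ]
        ppm = np.abs(peaks["mz"].to_numpy() - nearest) / nearest * 1e6
        assert ppm.max() <= 3.0 + 1e-6


class TestCoelution:
    def test_unresolvable_spacing_warns_and_flags_isobars(
        self, default_library
    ):
        cfg = sim.CohortConfig(
            groups={"normal": 1}, fold_changes={}, noise_sd=0.0,
            sample_scale_sd=0.0, ki67=None, rt_spacing=0.05, seed=4,
        )
        truth = sim.generate_cohort(cfg, default_library)
        with pytest.warns(UserWarning, match="resolvable"):
            peaks = sim.simulate_peaks(
                truth, default_library,
                sim.PeakShapeConfig(families=("H3_9-17",)),
            )
        q = xic.quantify_run(
            io.spectra_from_frame(peaks), default_library,
            xic.QuantConfig(rt_window=0.4), truth.rt_expected,
        )
        # isobaric placements (e.g. K9me1/K14un vs K9un/K14me1) now co-elute:
        # their areas are withheld and the set is flagged
        flagged = q[q["flag"] == xic.UNRESOLVED]
        assert {"H3_9-17:K9me1", "H3_9-17:K14me1"} <= set(flagged["form_id"])
        assert flagged["auc"].isna().all()


class TestStorageMask:
    def test_ffpe_exclusions_drop_light_only(self, default_library):
        cfg = sim.CohortConfig(
            groups={"normal": 2}, fold_changes={}, ki67=None,
            storage="FFPE", seed=6,
        )
        truth = sim.generate_cohort(cfg, default_library)
        masked = sim.apply_storage_mask(
            truth, {"FFPE": ["H3_9-17:K9ac", "H3_3-8:K4me3"]}
        )
        gone = masked.auc[masked.auc["form_id"] == "H3_9-17:K9ac"]
        assert (gone["channel"] == "heavy").all() and len(gone) == 2
        # frozen samples would be untouched
        untouched = sim.apply_storage_mask(
            truth, {"frozen": ["H3_9-17:K9ac"]}
        )
        assert len(untouched.auc) == len(truth.auc)


class TestKi67:
    def test_correlation_matches_configured_link(self, default_library):
        cfg = sim.CohortConfig(
            groups={"normal": 150}, fold_changes={}, seed=9,
            ki67=sim.Ki67Config(r=0.6, linked_mark="total_H3K9me3"),
        )
        truth = sim.generate_cohort(cfg, default_library)
        res = pipeline.cohort_mark_analysis(
            truth, group_a="normal", group_b="normal"
        )
        mark = np.log2(
            res["mark_ratios"]["total_H3K9me3"].reindex(truth.metadata.index)
        )
        r = np.corrcoef(mark, truth.metadata["ki67"])[0, 1]
        assert abs(r - 0.6) < 0.15


class TestEndToEndRecovery:
    def test_noise_free_pipeline_recovers_mark_fold_change(
        self, noise_free_truth, default_library
    ):
        truth = noise_free_truth
        peaks = sim.simulate_peaks(truth, default_library)
        cfg = xic.QuantConfig(rt_window=0.4)
        auc_tables = []
        for run in truth.metadata["sample_id"]:
            spectra = io.spectra_from_frame(peaks[peaks["run_id"] == run])
            auc_tables.append(
                xic.quantify_run(spectra, default_library, cfg, truth.rt_expected)
            )
        measured = pd.concat(auc_tables, ignore_index=True)
        res = pipeline.cohort_mark_analysis(truth, auc_df=measured)
        est = pipeline.estimate_mark_fold_change(
            res["mark_ratios"], truth.metadata["group"], "total_H3K14ac"
        )
        reg = marks.builtin_marks()["total_H3K14ac"]
        true_fc = sim.true_mark_ratio(truth, reg, "tumor") / (
            sim.true_mark_ratio(truth, reg, "normal")
        )
        assert est == pytest.approx(true_fc, rel=0.05)

    def test_noise_free_form_ratios_match_truth_exactly(self, default_library):
        cfg = sim.CohortConfig(
            groups={"normal": 2}, fold_changes={}, noise_sd=0.0,
            sample_scale_sd=0.0, ki67=None, seed=3,
        )
        truth = sim.generate_cohort(cfg, default_library)
        tables = pipeline.auc_to_ratios(truth.auc)
        # generator light/heavy %RA are both the baseline, so every ratio is 1
        assert np.allclose(tables["ratios"].to_numpy(), 1.0)
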