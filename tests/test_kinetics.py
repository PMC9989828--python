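"""Exponential transfer-kinetics fitting: exact self-consistency, agreement
with a brute-force SSE grid search, the rate-concordance filter, manual-style
average rates, and cohort summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from ldtransfer.kinetics import (
    AcceptorTransferModel,
    DonorTransferModel,
    TransferEventModel,
    TransferEvent,
    acceptor_volume,
    average_transfer_rate,
    detect_events,
    donor_volume,
    filter_multi_transfer,
    fit_events,
    summarize_cohort,
    volume_from_diameters,
)
from ldtransfer.synthetic import simulate_event_traces


def grid_search_donor(times, volumes, tmax, vd0_range=(5, 15), rd_range=(0.005, 0.05), n=200):
    """Independent SSE oracle: dense grid over (Vd0, Rd)."""
    vd0 = np.linspace(*vd0_range, n)
    rd = np.linspace(*rd_range, n)
    dt = np.asarray(times) - tmax
    model = vd0[:, None, None] * (1.0 - np.exp(rd[None, :, None] * dt[None, None, :]))
    sse = ((model - np.asarray(volumes)[None, None, :]) ** 2).sum(axis=2)
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    return vd0[i], rd[j], (vd0[1] - vd0[0], rd[1] - rd[0])


class TestFitting:
    def test_noiseless_donor_recovery(self):
        t = np.arange(0.0, 581.0, 20.0)
        v = donor_volume(t, 10.0, 0.02, 600.0)
        res = DonorTransferModel(t, v, 600.0).fit()
        assert res.converged
        assert res.Vd0 == pytest.approx(10.0, rel=1e-6)
        assert res.Rd == pytest.approx(0.02, rel=1e-6)
        assert res.sse < 1e-12

    def test_noiseless_acceptor_recovery(self):
        t = np.arange(0.0, 581.0, 20.0)
        v = acceptor_volume(t, 20.0, 30.0, 0.02, 600.0)
        res = AcceptorTransferModel(t, v, 600.0).fit()
        assert res.converged
        assert res.Va0 == pytest.approx(20.0, rel=1e-6)
        assert res.Vamax == pytest.approx(30.0, rel=1e-6)
        assert res.Ra == pytest.approx(0.02, rel=1e-6)

    def test_noisy_fit_matches_grid_oracle(self, rng):
        """The optimiser lands within one grid cell of a 200x200 brute-force
        SSE minimiser on noisy traces."""
        t = np.arange(0.0, 581.0, 20.0)
        clean = donor_volume(t, 10.0, 0.02, 600.0)
        for _ in range(3):
            v = np.clip(clean + rng.normal(0, 0.2, clean.shape), 0, None)
            res = DonorTransferModel(t, v, 600.0).fit()
            vd0_g, rd_g, (cell_v, cell_r) = grid_search_donor(t, v, 600.0)
            assert abs(res.Vd0 - vd0_g) <= cell_v
            assert abs(res.Rd - rd_g) <= cell_r

    def test_constant_trace_flagged(self):
        t = np.arange(0.0, 581.0, 20.0)
        res = DonorTransferModel(t, np.full_like(t, 5.0), 600.0).fit()
        assert not res.converged
        assert res.message

    def test_flat_acceptor_degenerate(self):
        t = np.arange(0.0, 581.0, 20.0)
        res = AcceptorTransferModel(t, np.full_like(t, 20.0), 600.0).fit()
        assert not res.converged

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            DonorTransferModel([0, 20, 40], [3, 2, 1], 60.0)
        # samples at/after tmax do not count
        with pytest.raises(ValueError, match="at least 4"):
            DonorTransferModel([0, 20, 40, 60, 80], [3, 2, 1, 0, 0], 60.0)

    def test_negative_volumes_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            DonorTransferModel([0, 20, 40, 60], [3, 2, -1, 1], 100.0)

    def test_fitted_model_identities(self, rng):
        """Fitted donor curve vanishes at tmax, decreases strictly, and its
        shrinkage speed grows toward completion."""
        t = np.arange(0.0, 581.0, 20.0)
        v = np.clip(donor_volume(t, 8.0, 0.015, 600.0) + rng.normal(0, 0.1, t.shape), 0, None)
        res = DonorTransferModel(t, v, 600.0).fit()
        assert donor_volume(600.0, res.Vd0, res.Rd, 600.0) == pytest.approx(0.0, abs=1e-12)
        fine = np.linspace(0, 599.0, 500)
        curve = donor_volume(fine, res.Vd0, res.Rd, 600.0)
        assert np.all(np.diff(curve) < 0)
        speed = -np.diff(curve)
        assert np.all(np.diff(speed) > 0)

    def test_summary_mentions_parameters(self):
        t = np.arange(0.0, 581.0, 20.0)
        res = DonorTransferModel(t, donor_volume(t, 10.0, 0.02, 600.0), 600.0).fit()
        s = res.summary()
        assert "Vd0" in s and "Rd" in s and "SSE" in s


class TestFilter:
    @pytest.mark.parametrize(
        "rd, ra, metric, passes",
        [
            (0.01, 0.01, 0.0, True),
            (0.001, 0.1, 2.0 / 3.0, False),
            (0.022, 0.02, 0.024969, True),
        ],
    )
    def test_metric_values(self, rd, ra, metric, passes):
        res = filter_multi_transfer(rd, ra)
        assert res.metric == pytest.approx(metric, abs=1e-5)
        assert res.passes is passes

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            filter_multi_transfer(0.0, 0.01)

    def test_near_unity_rd_undefined(self):
        res = filter_multi_transfer(1.0, 0.01)
        assert not res.passes
        assert np.isnan(res.metric)
        assert "log10" in res.reason

    @settings(derandomize=True, max_examples=50)
    @given(rd=st.floats(1e-4, 0.5), ra=st.floats(1e-4, 0.5))
    def test_matches_direct_formula(self, rd, ra):
        res = filter_multi_transfer(rd, ra)
        expected = abs(np.log10(ra) / np.log10(rd) - 1.0)
        assert res.metric == pytest.approx(expected, rel=1e-12)
        assert res.passes == (expected < 0.4)

    @settings(derandomize=True, max_examples=25)
    @given(r=st.floats(1e-4, 0.5))
    def test_identical_rates_always_pass(self, r):
        res = filter_multi_transfer(r, r)
        assert res.metric == 0.0 and res.passes


class TestRatesAndSummaries:
    def test_average_rate_examples(self):
        assert average_transfer_rate([0, 3600], [10.0, 0.0]) == pytest.approx(10.0)
        assert average_transfer_rate([0, 500], [5.0, 5.0]) == 0.0

    def test_average_rate_matches_model_endpoints(self):
        t = np.arange(0.0, 601.0, 20.0)
        v = donor_volume(t, 10.0, 0.02, 600.0)
        expected = (v[0] - v[-1]) / 600.0 * 3600.0
        assert average_transfer_rate(t, v) == pytest.approx(expected)

    def test_average_rate_rejects_degenerate_window(self):
        with pytest.raises(ValueError):
            average_transfer_rate([100.0], [5.0])
        with pytest.raises(ValueError):
            average_transfer_rate([100.0, 100.0], [5.0, 4.0])

    @pytest.mark.parametrize(
        "diams, expected",
        [
            ([2.0], 4.1887902),
            ([1.8, 2.2], 4.1887902),
            ([1.0, 1.0, 1.0], 0.5235988),
        ],
    )
    def test_volume_from_diameters(self, diams, expected):
        assert volume_from_diameters(diams) == pytest.approx(expected, rel=1e-6)

    def test_volume_from_diameters_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            volume_from_diameters([2.0, -1.0])

    def test_cohort_summary_basics(self):
        df = pd.DataFrame({"average_rate_um3_per_h": [1, 2, 3, 4, 5],
                           "Rd_per_s": [0.01] * 5})
        out = summarize_cohort(df)
        assert out.average_rate_um3_per_h_median.iloc[0] == 3
        assert out.average_rate_um3_per_h_iqr.iloc[0] == 2.0
        single = summarize_cohort(df.iloc[:1])
        assert single.average_rate_um3_per_h_iqr.iloc[0] == 0.0
        assert summarize_cohort(pd.DataFrame()).empty

    def test_cohort_median_within_resampling_ci(self, rng):
        """Median of a 50-event fitted cohort falls inside a bootstrap CI of
        the generating distribution's median."""
        traces, truth = simulate_event_traces(50, rng=11)
        fitted = []
        for eid, g in traces.groupby("event_id"):
            res = DonorTransferModel(g.time_s, g.donor_volume_um3, g.tmax_s.iloc[0]).fit()
            fitted.append(res.Rd)
        out = summarize_cohort(pd.DataFrame({"Rd_per_s": fitted}),
                               value_columns=("Rd_per_s",))
        boot = np.median(
            rng.choice(truth.Rd.to_numpy(), size=(2000, len(truth)), replace=True), axis=1
        )
        lo, hi = np.percentile(boot, [0.5, 99.5])
        assert lo <= out.Rd_per_s_median.iloc[0] <= hi


class TestEventAssembly:
    @staticmethod
    def _tables(n_frames=12, merge=True, extra_contact=False):
        rows, dt = [], 20.0
        for f in range(n_frames):
            t = f * dt
            rows.append({"frame": f, "time_s": t, "track_id": 0,
                         "volume_um3": 8.0 + 4.0 * np.exp(0.02 * (t - 200.0)),
                         "label": 1})
            if f < n_frames - 2:
                rows.append({"frame": f, "time_s": t, "track_id": 1,
                             "volume_um3": max(4.0 * (1 - np.exp(0.02 * (t - 200.0))), 0.01),
                             "label": 2})
            if extra_contact:
                rows.append({"frame": f, "time_s": t, "track_id": 2,
                             "volume_um3": 6.0, "label": 3})
        tracks = pd.DataFrame(rows)
        summary = pd.DataFrame([
            {"track_id": 0, "birth_frame": 0, "death_frame": n_frames - 1,
             "n_detections": n_frames, "merged_into": np.nan, "merge_frame": np.nan},
            {"track_id": 1, "birth_frame": 0, "death_frame": n_frames - 3,
             "n_detections": n_frames - 2,
             "merged_into": 0.0 if merge else np.nan,
             "merge_frame": float(n_frames - 2) if merge else np.nan},
        ])
        contacts = []
        for f in range(1, n_frames):
            contacts.append({"frame": f, "track_a": 0, "track_b": 1, "in_contact": True})
            if extra_contact:
                contacts.append({"frame": f, "track_a": 1, "track_b": 2, "in_contact": True})
        return tracks, summary, pd.DataFrame(contacts)

    def test_single_merge_yields_one_event(self):
        events = detect_events(*self._tables())
        assert len(events) == 1
        ev = events[0]
        assert ev.donor_track_id == 1 and ev.acceptor_track_id == 0
        assert ev.tmax == pytest.approx(200.0)
        assert not ev.multi_acceptor

    def test_no_merge_no_event(self):
        events = detect_events(*self._tables(merge=False))
        assert events == []

    def test_multi_acceptor_flagged_and_excluded(self):
        events = detect_events(*self._tables(extra_contact=True))
        assert len(events) == 1
        assert events[0].multi_acceptor
        table = fit_events(events)
        assert not table.passes_filter.iloc[0]

    def test_event_model_summary_and_row(self):
        ev = detect_events(*self._tables())[0]
        res = TransferEventModel(ev).fit()
        row = res.row()
        assert row["Rd_per_s"] == pytest.approx(0.02, rel=0.05)
        assert row["Ra_per_s"] == pytest.approx(0.02, rel=0.05)
        assert res.passes_filter
        assert "filter" in res.summary()

    def test_event_time_ordering_enforced(self):
        with pytest.raises(ValueError):
            TransferEvent(
                donor_track_id=0, acceptor_track_id=1, t_contact=300.0, tmax=200.0,
                donor_times=np.array([0.0]), donor_volumes=np.array([1.0]),
                acceptor_times=np.array([0.0]), acceptor_volumes=np.array([1.0]),
            )


class TestCohortProperties:
    def test_size_dependence_recovered(self, rng):
        """When generation imposes a pressure-like rule Rd ~ Vd0^(-1/3),
        fitted rates decrease with donor start volume (Spearman rho < 0)."""
        rows_rd, rows_v = [], []
        dt = 20.0
        for _ in range(60):
            vd0 = float(np.exp(rng.uniform(np.log(1.0), np.log(30.0))))
            rd = 0.012 / vd0 ** (1 / 3) * float(np.exp(rng.normal(0, 0.15)))
            n = int(np.clip(round(4.0 / rd / dt), 8, 80))
            t = np.arange(n) * dt
            tmax = n * dt
            v = donor_volume(t, vd0, rd, tmax)
            v = np.clip(v * (1 + 0.05 * rng.standard_normal(n)), 0, None)
            res = DonorTransferModel(t, v, tmax).fit()
            if res.converged:
                rows_rd.append(res.Rd)
                rows_v.append(res.Vd0)
        rho, p = spearmanr(rows_v, rows_rd)
        assert rho < 0
        assert p < 0.01
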