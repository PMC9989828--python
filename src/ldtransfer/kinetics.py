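"""Exponential kinetics of LD-to-LD neutral-lipid transfer.

A transfer event is the merging of two droplet tracks at completion time
``tmax``: the donor is the droplet whose volume vanishes at ``tmax``, the
acceptor the one that survives. Donor and acceptor volumes follow

    Vd(t) = Vd0 (1 - exp(Rd (t - tmax)))
    Va(t) = Va0 + (Vamax - Va0) exp(Ra (t - tmax))

so transfer starts slowly and accelerates toward completion. ``tmax`` is
known from event detection; the five free parameters (Vd0, Rd) and
(Va0, Vamax, Ra) are recovered by nonlinear least squares, independently
for the two droplets. Because a droplet engaged in a single transfer must
show matching rate constants on both sides, events with
``|log10(Ra)/log10(Rd) - 1| >= 0.4`` are excluded as likely multi-transfer
participants.

The fitting API follows the Model/Results convention: build a
:class:`DonorTransferModel` / :class:`AcceptorTransferModel` (or a paired
:class:`TransferEventModel`) from data, call ``.fit()``, read estimates,
standard errors and diagnostics off the returned results object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "donor_volume",
    "acceptor_volume",
    "DonorTransferModel",
    "AcceptorTransferModel",
    "TransferEventModel",
    "DonorFitResults",
    "AcceptorFitResults",
    "TransferEvent",
    "FilterResult",
    "detect_events",
    "fit_events",
    "filter_multi_transfer",
    "average_transfer_rate",
    "volume_from_diameters",
    "summarize_cohort",
]

RD_BOUNDS = (1e-6, 1.0)  # 1/s; physiological rates are 1e-3..1e-1
FILTER_THRESHOLD = 0.4
LOG10_RD_EPS = 0.05  # |log10 Rd| below this makes the filter ratio ill-posed


# ---------------------------------------------------------------------------
# model functions
# ---------------------------------------------------------------------------


def donor_volume(t, vd0: float, rd: float, tmax: float):
    """Donor volume Vd(t) = Vd0 (1 - exp(Rd (t - tmax))); zero at tmax."""
    t = np.asarray(t, dtype=float)
    return vd0 * (1.0 - np.exp(rd * (t - tmax)))


def acceptor_volume(t, va0: float, vamax: float, ra: float, tmax: float):
    """Acceptor volume Va(t) = Va0 + (Vamax - Va0) exp(Ra (t - tmax)).

    Note the model runs backward in time from completion: at ``t = tmax``
    the exponential equals 1 and Va = Vamax; far before completion it
    decays toward Va0.
    """
    t = np.asarray(t, dtype=float)
    return va0 + (vamax - va0) * np.exp(ra * (t - tmax))


# ---------------------------------------------------------------------------
# results objects
# ---------------------------------------------------------------------------


class _FitResultsBase:
    """Shared plumbing: residuals, SSE, standard errors, summary table."""

    param_names: tuple[str, ...] = ()

    def __init__(self, model, params, converged, message=""):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.converged = bool(converged)
        self.message = message
        self.fittedvalues = model.predict(self.params)
        self.resid = model.volumes - self.fittedvalues
        self.sse = float(np.sum(self.resid**2))
        self.bse = self._standard_errors()

    def _standard_errors(self) -> np.ndarray:
        n, p = self.model.nobs, len(self.params)
        if n <= p:
            return np.full(p, np.nan)
        jac = self.model.jacobian(self.params)
        jtj = jac.T @ jac
        try:
            cov = np.linalg.inv(jtj) * self.sse / (n - p)
            return np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            return np.full(p, np.nan)

    def summary(self) -> str:
        lines = [
            f"{type(self).__name__}",
            f"  n obs      : {self.model.nobs}",
            f"  tmax (s)   : {self.model.tmax:g}",
            f"  SSE (µm⁶)  : {self.sse:.6g}",
            f"  converged  : {self.converged}" + (f" ({self.message})" if self.message else ""),
        ]
        for name, val, se in zip(self.param_names, self.params, self.bse):
            lines.append(f"  {name:<10} : {val:.6g} (se {se:.3g})")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<{type(self).__name__} converged={self.converged} sse={self.sse:.4g}>"


class DonorFitResults(_FitResultsBase):
    """(Vd0, Rd) estimates for one donor trace."""

    param_names = ("Vd0 (µm³)", "Rd (1/s)")

    @property
    def Vd0(self) -> float:
        return float(self.params[0])

    @property
    def Rd(self) -> float:
        return float(self.params[1])


class AcceptorFitResults(_FitResultsBase):
    """(Va0, Vamax, Ra) estimates for one acceptor trace."""

    param_names = ("Va0 (µm³)", "Vamax (µm³)", "Ra (1/s)")

    @property
    def Va0(self) -> float:
        return float(self.params[0])

    @property
    def Vamax(self) -> float:
        return float(self.params[1])

    @property
    def Ra(self) -> float:
        return float(self.params[2])


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


class _TransferModelBase:
    """Volume-trace model with fixed completion time tmax."""

    def __init__(self, times: Sequence[float], volumes: Sequence[float], tmax: float):
        times = np.asarray(times, dtype=float)
        volumes = np.asarray(volumes, dtype=float)
        if times.shape != volumes.shape or times.ndim != 1:
            raise ValueError("times and volumes must be matching 1-D arrays")
        if np.any(volumes < 0):
            raise ValueError("volumes must be non-negative")
        keep = times < tmax
        if keep.sum() < 4:
            raise ValueError(
                f"need at least 4 samples before tmax, got {int(keep.sum())}"
            )
        self.times = times[keep]
        self.volumes = volumes[keep]
        self.tmax = float(tmax)
        self.dt = self.times - self.tmax  # all negative

    @property
    def nobs(self) -> int:
        return self.times.size


class DonorTransferModel(_TransferModelBase):
    """Exponential shrinkage of a donor droplet up to completion.

    Parameters
    ----------
    times, volumes
        Observation times (s) and measured volumes (µm³). Samples at or
        after ``tmax`` are dropped (the donor no longer exists there).
    tmax
        Completion time (s), fixed from event detection.

    Examples
    --------
    >>> t = np.arange(0, 580, 20.0)
    >>> v = donor_volume(t, 10.0, 0.02, 600.0)
    >>> res = DonorTransferModel(t, v, tmax=600.0).fit()
    >>> round(res.Vd0, 6), round(res.Rd, 6)
    (10.0, 0.02)
    """

    def predict(self, params) -> np.ndarray:
        vd0, rd = params
        return donor_volume(self.times, vd0, rd, self.tmax)

    def jacobian(self, params) -> np.ndarray:
        vd0, rd = params
        e = np.exp(rd * self.dt)
        return np.column_stack([1.0 - e, -vd0 * self.dt * e])

    def _start_params(self) -> tuple[float, float]:
        vd0_init = float(self.volumes[0]) if self.volumes[0] > 0 else float(
            np.max(self.volumes)
        )
        if vd0_init <= 0:
            return 1.0, 0.01
        # log-linear: log(1 - V/Vd0) = Rd (t - tmax)
        frac = 1.0 - self.volumes / vd0_init
        ok = frac > 1e-6
        if ok.sum() >= 2:
            slope = np.polyfit(self.dt[ok], np.log(frac[ok]), 1)[0]
            rd_init = float(np.clip(slope, *RD_BOUNDS))
        else:
            rd_init = 0.01
        return vd0_init, rd_init

    def fit(self) -> DonorFitResults:
        x0 = np.asarray(self._start_params())
        lb = np.array([1e-12, RD_BOUNDS[0]])
        ub = np.array([np.inf, RD_BOUNDS[1]])
        sol = least_squares(
            lambda p: self.predict(p) - self.volumes,
            np.clip(x0, lb, ub),
            jac=lambda p: self.jacobian(p),
            bounds=(lb, ub),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        at_bound = sol.x[1] <= RD_BOUNDS[0] * 2 or sol.x[1] >= RD_BOUNDS[1]
        vmax = float(self.volumes.max())
        head = float(np.mean(self.volumes[:3]))
        tail = float(np.mean(self.volumes[-3:]))
        no_decline = vmax <= 0 or (head - tail) / vmax < 0.02
        msg = "" if sol.success else sol.message
        if at_bound:
            msg = f"Rd pinned at bound ({sol.x[1]:.2g}/s); trace likely not a transfer"
        elif no_decline:
            msg = "no donor shrinkage in observation window; Rd unidentified"
        return DonorFitResults(self, sol.x, sol.success and not (at_bound or no_decline), msg)


class AcceptorTransferModel(_TransferModelBase):
    """Exponential growth of an acceptor droplet toward its final volume."""

    def predict(self, params) -> np.ndarray:
        va0, vamax, ra = params
        return acceptor_volume(self.times, va0, vamax, ra, self.tmax)

    def jacobian(self, params) -> np.ndarray:
        va0, vamax, ra = params
        e = np.exp(ra * self.dt)
        return np.column_stack([1.0 - e, e, (vamax - va0) * self.dt * e])

    def _start_params(self) -> tuple[float, float, float]:
        va0_init = float(self.volumes[0])
        vamax_init = float(np.max(self.volumes[-3:]))
        if vamax_init <= va0_init:
            vamax_init = va0_init * 1.1 + 1e-6
        gain = (self.volumes - va0_init) / (vamax_init - va0_init)
        ok = gain > 1e-6
        if ok.sum() >= 2:
            slope = np.polyfit(self.dt[ok], np.log(gain[ok]), 1)[0]
            ra_init = float(np.clip(slope, *RD_BOUNDS))
        else:
            ra_init = 0.01
        return va0_init, vamax_init, ra_init

    def fit(self) -> AcceptorFitResults:
        x0 = np.asarray(self._start_params())
        lb = np.array([1e-12, 1e-12, RD_BOUNDS[0]])
        ub = np.array([np.inf, np.inf, RD_BOUNDS[1]])
        sol = least_squares(
            lambda p: self.predict(p) - self.volumes,
            np.clip(x0, lb, ub),
            jac=lambda p: self.jacobian(p),
            bounds=(lb, ub),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        va0, vamax, ra = sol.x
        degenerate = vamax - va0 <= 1e-9 or ra <= RD_BOUNDS[0] * 2 or ra >= RD_BOUNDS[1]
        msg = "" if sol.success else sol.message
        if degenerate:
            msg = "flat acceptor trace or Ra pinned at bound"
        return AcceptorFitResults(self, sol.x, sol.success and not degenerate, msg)


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------


@dataclass
class TransferEvent:
    """A donor/acceptor track pair with its contact window.

    ``donor_times/volumes`` and ``acceptor_times/volumes`` hold the traces
    inside the event window (first in-contact frame at which the donor has
    begun shrinking, through the last frame before ``tmax``).
    """

    donor_track_id: int
    acceptor_track_id: int
    t_contact: float
    tmax: float
    donor_times: np.ndarray
    donor_volumes: np.ndarray
    acceptor_times: np.ndarray
    acceptor_volumes: np.ndarray
    multi_acceptor: bool = False
    contact_frames: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        if self.t_contact > self.tmax:
            raise ValueError("t_contact must not exceed tmax")


class FilterResult(NamedTuple):
    metric: float
    passes: bool
    reason: str


def filter_multi_transfer(
    rd: float, ra: float, threshold: float = FILTER_THRESHOLD, eps: float = LOG10_RD_EPS
) -> FilterResult:
    """Rate-concordance filter excluding likely multiple-transfer events.

    The metric is ``|log10(Ra)/log10(Rd) - 1|``; an event passes when it is
    below ``threshold`` (default 0.4). When ``|log10(Rd)| <= eps`` the
    ratio is ill-posed and the event is excluded with a reason (never the
    case at physiological rates, which sit well below 1/s).
    """
    if rd <= 0 or ra <= 0:
        raise ValueError("rates must be positive")
    log_rd = math.log10(rd)
    if abs(log_rd) <= eps:
        return FilterResult(float("nan"), False, f"|log10(Rd)|={abs(log_rd):.3g} <= {eps}")
    metric = abs(math.log10(ra) / log_rd - 1.0)
    return FilterResult(metric, metric < threshold, "")


def average_transfer_rate(times_s: Sequence[float], volumes: Sequence[float]) -> float:
    """Net donor shrinkage rate over a window, in µm³/h.

    ``(V_start - V_end) / (t_end - t_start)``, positive when the donor
    loses volume — the averaged rate plotted per event in manual analyses.
    """
    t = np.asarray(times_s, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two samples")
    span = t[-1] - t[0]
    if span <= 0:
        raise ValueError("zero-length window")
    return float((v[0] - v[-1]) / span * 3600.0)


def volume_from_diameters(diameters_um: Sequence[float]) -> float:
    """Sphere volume (µm³) from the mean of measured diameters (µm)."""
    d = np.asarray(diameters_um, dtype=float)
    if d.size == 0 or np.any(d <= 0):
        raise ValueError("need at least one positive diameter")
    return float(math.pi / 6.0 * float(d.mean()) ** 3)


def detect_events(
    tracks: pd.DataFrame,
    track_summary: pd.DataFrame,
    contacts: pd.DataFrame,
    *,
    shrink_fraction: float = 0.98,
) -> list[TransferEvent]:
    """Assemble transfer events from tracking output.

    An event is a track that merges into a surviving track: the vanishing
    track is the donor, ``tmax`` the time of the merged frame. The event
    window opens at the first in-contact frame where the donor volume has
    dropped below ``shrink_fraction`` x its pre-contact median ("engaged in
    active transfer"). A donor in contact with more than one partner during
    the window is flagged ``multi_acceptor`` (excluded from rate cohorts).

    Parameters take the ``tracks``/``track summary``/``contacts`` tables of
    :mod:`ldtransfer.detection`; tracks must carry ``time_s`` per frame.
    """
    events: list[TransferEvent] = []
    merged = track_summary.dropna(subset=["merged_into"])
    frame_time = tracks.drop_duplicates("frame").set_index("frame")["time_s"]
    for _, row in merged.iterrows():
        donor_id = int(row["track_id"])
        acceptor_id = int(row["merged_into"])
        merge_frame = int(row["merge_frame"])
        if merge_frame not in frame_time.index:
            continue
        tmax = float(frame_time.loc[merge_frame])
        donor_tr = tracks[tracks["track_id"] == donor_id].sort_values("frame")
        accept_tr = tracks[tracks["track_id"] == acceptor_id].sort_values("frame")
        if accept_tr["frame"].max() < merge_frame:
            continue  # vanished into nothing that survives: not an event
        pair_contacts = contacts[
            (contacts["in_contact"])
            & (
                ((contacts["track_a"] == donor_id) & (contacts["track_b"] == acceptor_id))
                | ((contacts["track_a"] == acceptor_id) & (contacts["track_b"] == donor_id))
            )
        ]
        if pair_contacts.empty:
            continue
        contact_frames = np.sort(pair_contacts["frame"].unique())
        t_contact = float(frame_time.loc[contact_frames[0]])

        pre = donor_tr[donor_tr["frame"] < contact_frames[0]]["volume_um3"]
        pre_median = float(pre.median()) if len(pre) else float(
            donor_tr["volume_um3"].iloc[0]
        )
        in_window = donor_tr["frame"].isin(contact_frames) & (
            donor_tr["volume_um3"] < shrink_fraction * pre_median
        )
        if in_window.any():
            start_frame = int(donor_tr.loc[in_window, "frame"].iloc[0])
        else:
            start_frame = int(contact_frames[0])

        dsel = donor_tr[(donor_tr["frame"] >= start_frame) & (donor_tr["frame"] < merge_frame)]
        asel = accept_tr[(accept_tr["frame"] >= start_frame) & (accept_tr["frame"] < merge_frame)]

        partners = contacts[
            (contacts["in_contact"])
            & (contacts["frame"].isin(contact_frames))
            & ((contacts["track_a"] == donor_id) | (contacts["track_b"] == donor_id))
        ]
        others = set(partners["track_a"]).union(partners["track_b"]) - {donor_id}
        multi = len(others) > 1

        events.append(
            TransferEvent(
                donor_track_id=donor_id,
                acceptor_track_id=acceptor_id,
                t_contact=t_contact,
                tmax=tmax,
                donor_times=dsel["time_s"].to_numpy(),
                donor_volumes=dsel["volume_um3"].to_numpy(),
                acceptor_times=asel["time_s"].to_numpy(),
                acceptor_volumes=asel["volume_um3"].to_numpy(),
                multi_acceptor=multi,
                contact_frames=contact_frames,
            )
        )
    return events


class TransferEventModel:
    """Joint view of one event: donor and acceptor fits plus the filter.

    ``fit()`` fits both sides independently (five free parameters in
    total — Vd0, Rd, Va0, Vamax, Ra — with tmax fixed) and returns a
    :class:`TransferEventResults`.
    """

    def __init__(self, event: TransferEvent):
        self.event = event

    def fit(self) -> "TransferEventResults":
        ev = self.event
        donor = DonorTransferModel(ev.donor_times, ev.donor_volumes, ev.tmax).fit()
        acceptor = AcceptorTransferModel(
            ev.acceptor_times, ev.acceptor_volumes, ev.tmax
        ).fit()
        return TransferEventResults(self, donor, acceptor)


class TransferEventResults:
    def __init__(self, model: TransferEventModel, donor: DonorFitResults,
                 acceptor: AcceptorFitResults):
        self.model = model
        self.donor = donor
        self.acceptor = acceptor
        if donor.converged and acceptor.converged:
            self.filter = filter_multi_transfer(donor.Rd, acceptor.Ra)
        else:
            self.filter = FilterResult(float("nan"), False, "fit did not converge")
        ev = model.event
        self.average_rate = average_transfer_rate(ev.donor_times, ev.donor_volumes)

    @property
    def passes_filter(self) -> bool:
        return self.filter.passes and not self.model.event.multi_acceptor

    def summary(self) -> str:
        ev = self.model.event
        head = (
            f"TransferEvent donor={ev.donor_track_id} acceptor={ev.acceptor_track_id} "
            f"t_contact={ev.t_contact:g}s tmax={ev.tmax:g}s"
            + (" [multi-acceptor]" if ev.multi_acceptor else "")
        )
        filt = (
            f"filter |log10Ra/log10Rd - 1| = {self.filter.metric:.4g} -> "
            f"{'pass' if self.passes_filter else 'excluded'}"
            + (f" ({self.filter.reason})" if self.filter.reason else "")
        )
        rate = f"average rate = {self.average_rate:.4g} µm³/h"
        return "\n".join([head, self.donor.summary(), self.acceptor.summary(), filt, rate])

    def row(self) -> dict:
        """One events-table row (the events.csv schema)."""
        ev = self.model.event
        return {
            "donor_track_id": ev.donor_track_id,
            "acceptor_track_id": ev.acceptor_track_id,
            "t_contact_s": ev.t_contact,
            "tmax_s": ev.tmax,
            "Vd0_um3": self.donor.Vd0,
            "Rd_per_s": self.donor.Rd,
            "Va0_um3": self.acceptor.Va0,
            "Vamax_um3": self.acceptor.Vamax,
            "Ra_per_s": self.acceptor.Ra,
            "donor_sse": self.donor.sse,
            "acceptor_sse": self.acceptor.sse,
            "donor_converged": self.donor.converged,
            "acceptor_converged": self.acceptor.converged,
            "filter_metric": self.filter.metric,
            "passes_filter": self.passes_filter,
            "multi_acceptor": ev.multi_acceptor,
            "average_rate_um3_per_h": self.average_rate,
        }


def fit_events(events: Sequence[TransferEvent]) -> pd.DataFrame:
    """Fit every event and return the events table (one row per event).

    Events whose traces are too short to fit (fewer than 4 pre-tmax
    samples on either side) are skipped.
    """
    rows = []
    for ev in events:
        try:
            rows.append(TransferEventModel(ev).fit().row())
        except ValueError:
            continue
    return pd.DataFrame(rows)


def summarize_cohort(
    events: pd.DataFrame,
    value_columns: Sequence[str] = ("average_rate_um3_per_h", "Rd_per_s"),
    by: str | None = None,
) -> pd.DataFrame:
    """Median, IQR (Q3 - Q1, linear-interpolation quantiles) and n per group."""
    if events.empty:
        return pd.DataFrame()
    groups = events.groupby(by) if by is not None else [("all", events)]
    rows = []
    for name, g in groups:
        row: dict = {"group": name, "n": len(g)}
        for col in value_columns:
            vals = g[col].dropna().to_numpy()
            if vals.size == 0:
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            row[f"{col}_median"] = med
            row[f"{col}_iqr"] = q3 - q1
        rows.append(row)
    return pd.DataFrame(rows)
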