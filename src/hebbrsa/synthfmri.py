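"""Synthetic BOLD generator matched to the Hebb-repetition analysis assumptions.

Each subject's session is rendered run by run at TR 1.37 s.  Every trial
phase (encoding / delay / probe) evokes a multivoxel pattern that is a
mixture of a fixed sequence-specific template and fresh trial noise,

    pattern = amp_phase * (s * template(seq) + sqrt(1 - s^2) * fresh),

with mixing weight s = w(run) for repeat trials (the pattern-stabilization
schedule, non-decreasing over runs) and s = ``novel_structure_gain`` for
novel trials.  Patterns are convolved with a canonical double-gamma HRF at
the event onsets/durations and summed with polynomial drift, shared smooth
nuisance components with random voxel loadings, and AR(1) voxel noise.  The
drift basis and component time series are returned as a "known" nuisance
table, standing in for the polynomial + component confound regressors of a
preprocessed dataset.

Behavioral responses are drawn per trial with delay-dependent accuracy
(defaults follow the observed proportions correct: .63/.57/.50 at 3/6/9 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import lfilter
from scipy.stats import gamma as gamma_dist

from .exceptions import InvalidInputError, InvalidParameterError
from .stimgen import ExperimentDesign, design_to_events

HRF_PEAK_S = 6.0
HRF_UNDERSHOOT_S = 16.0
HRF_RATIO = 6.0
HRF_LEN_S = 32.0
_HI_DT = 0.1


def _double_gamma(t):
    # unit-scale gamma densities with modes at the stated peak/undershoot times
    return (gamma_dist.pdf(t, HRF_PEAK_S + 1.0)
            - gamma_dist.pdf(t, HRF_UNDERSHOOT_S + 1.0) / HRF_RATIO)


@lru_cache(maxsize=8)
def _hrf_peak() -> float:
    return float(_double_gamma(np.arange(0.0, HRF_LEN_S, 0.01)).max())


def hrf(t) -> np.ndarray:
    """Canonical double-gamma HRF (peak 6 s, undershoot 16 s, ratio 6), unit peak."""
    t = np.asarray(t, dtype=float)
    return np.where(t >= 0, _double_gamma(t) / _hrf_peak(), 0.0)


@lru_cache(maxsize=8)
def _hrf_kernel(dt: float) -> np.ndarray:
    kern = hrf(np.arange(0.0, HRF_LEN_S, dt))
    kern.flags.writeable = False
    return kern


def convolve_events(events: pd.DataFrame, tr_s: float, n_timepoints: int,
                    dt: float = _HI_DT) -> np.ndarray:
    """HRF regressor for a set of events, sampled at the TR grid.

    Each event contributes a boxcar of its duration (a zero-duration event is
    treated as a single high-resolution impulse), scaled by an optional
    ``amplitude`` column, convolved with the canonical HRF.
    """
    reg_hi_len = int(np.ceil(n_timepoints * tr_s / dt)) + 1
    box = np.zeros(reg_hi_len)
    if len(events):
        if (events["duration"].to_numpy(dtype=float) < 0).any():
            raise InvalidInputError("event durations must be non-negative")
        amps = events["amplitude"].to_numpy(dtype=float) if "amplitude" in events else np.ones(len(events))
        for onset, dur, amp in zip(events["onset"], events["duration"], amps):
            i0 = int(round(onset / dt))
            i1 = max(i0 + 1, int(round((onset + dur) / dt)))
            if i0 < reg_hi_len:
                box[i0:min(i1, reg_hi_len)] += amp
    sig = np.convolve(box, _hrf_kernel(dt))[:reg_hi_len]
    idx = np.round(np.arange(n_timepoints) * tr_s / dt).astype(int)
    return sig[idx]


def event_regressors(events: pd.DataFrame, tr_s: float, n_timepoints: int,
                     dt: float = _HI_DT, unit_peak: bool = True) -> np.ndarray:
    """One HRF regressor per event row (timepoints x events).

    With ``unit_peak`` each column is scaled to peak 1, so a unit event
    amplitude means a unit peak response regardless of event duration; this
    convention is used by the simulator, the trial design matrices, and the
    phase GLM alike.
    """
    onsets = events["onset"].to_numpy(dtype=float)
    durs = events["duration"].to_numpy(dtype=float)
    amps = (events["amplitude"].to_numpy(dtype=float)
            if "amplitude" in events else np.ones(len(events)))
    if (durs < 0).any():
        raise InvalidInputError("event durations must be non-negative")
    reg_hi_len = int(np.ceil(n_timepoints * tr_s / dt)) + 1
    kern = _hrf_kernel(dt)
    idx = np.round(np.arange(n_timepoints) * tr_s / dt).astype(int)
    out = np.empty((n_timepoints, len(events)))
    for k, (onset, dur, amp) in enumerate(zip(onsets, durs, amps)):
        box = np.zeros(reg_hi_len)
        i0 = int(round(onset / dt))
        i1 = max(i0 + 1, int(round((onset + dur) / dt)))
        if i0 < reg_hi_len:
            box[i0:min(i1, reg_hi_len)] = amp
        r = np.convolve(box, kern)[:reg_hi_len][idx]
        peak = r.max()
        out[:, k] = r / peak if (unit_peak and peak > 0) else r
    return out


DEFAULT_AMP_PHASE = {"encoding": 0.5, "delay": 0.2, "probe": 0.08}
DEFAULT_P_CORRECT = {3.0: 0.63, 6.0: 0.57, 9.0: 0.50}
DEFAULT_ROIS = ("PSL-like", "STG-like", "PMd-like", "control")


@dataclass
class SimParams:
    """Generative settings for one simulated cohort.

    ``stabilization`` gives the repeat-trial template weight per run; if
    None, a linear schedule from ``w_start`` to ``w_end`` over the design's
    runs is used.  Amplitudes are in noise-SD units of a single voxel;
    ``mean_activation`` adds a uniform evoked offset across voxels so ROIs
    also show univariate phase activity (pattern correlations are invariant
    to it).
    """

    n_subjects: int = 23
    rois: tuple[str, ...] = DEFAULT_ROIS
    n_voxels_per_roi: int = 24
    tr_s: float = 1.37
    noise_sd: float = 1.0
    ar1_rho: float = 0.3
    drift_poly_degree: int = 5
    n_noise_components: int = 5
    drift_sd: float = 1.0
    component_sd: float = 1.0
    amp_phase: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_AMP_PHASE))
    roi_phase_gain: Mapping[str, Mapping[str, float]] | None = None
    stabilization: tuple[float, ...] | None = None
    w_start: float = 0.2
    w_end: float = 0.8
    novel_structure_gain: float = 0.0
    mean_activation: float = 1.0
    p_correct: Mapping[float, float] = field(default_factory=lambda: dict(DEFAULT_P_CORRECT))
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.ar1_rho < 1:
            raise InvalidParameterError("ar1_rho must be in [0, 1)")
        if any(a < 0 for a in self.amp_phase.values()):
            raise InvalidParameterError("phase amplitudes must be >= 0")
        sched = self.stabilization
        if sched is not None:
            arr = np.asarray(sched, dtype=float)
            if (arr < 0).any() or (arr > 1).any() or (np.diff(arr) < 0).any():
                raise InvalidParameterError("stabilization must be non-decreasing in [0, 1]")

    @property
    def n_voxels(self) -> int:
        return self.n_voxels_per_roi * len(self.rois)

    def w(self, run: int, n_runs: int) -> float:
        """Template mixing weight for repeat trials in 1-indexed ``run``."""
        if self.stabilization is not None:
            return float(self.stabilization[run - 1])
        if n_runs == 1:
            return self.w_end
        return self.w_start + (self.w_end - self.w_start) * (run - 1) / (n_runs - 1)

    def gain(self, roi: str, phase: str) -> float:
        if self.roi_phase_gain is None:
            return 1.0
        return float(self.roi_phase_gain.get(roi, {}).get(phase, 1.0))


@dataclass
class BOLDRun:
    """One run of simulated data: voxels x timepoints plus its nuisance table."""

    data: np.ndarray
    tr_s: float
    run: int
    roi_labels: tuple[str, ...]
    nuisance: pd.DataFrame
    truth: dict

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


def _ar1_noise(rng, n_t, n_v, rho, sd):
    if sd == 0:
        return np.zeros((n_t, n_v))
    innov = rng.standard_normal((n_t, n_v)) * sd * np.sqrt(1.0 - rho ** 2)
    innov[0] /= np.sqrt(1.0 - rho ** 2)          # stationary start
    return lfilter([1.0], [1.0, -rho], innov, axis=0)


def simulate_subject(
    design: ExperimentDesign,
    params: SimParams,
    subject: int = 0,
) -> tuple[list[BOLDRun], pd.DataFrame]:
    """Simulate all runs and the behavioral table for one subject."""
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), int(subject)]))
    events = design_to_events(design)
    n_v = params.n_voxels
    roi_labels = tuple(r for r in params.rois for _ in range(params.n_voxels_per_roi))
    roi_slices = {
        r: slice(i * params.n_voxels_per_roi, (i + 1) * params.n_voxels_per_roi)
        for i, r in enumerate(params.rois)
    }

    templates: dict[str, np.ndarray] = {}

    def template(seq_id):
        if seq_id not in templates:
            templates[seq_id] = rng.standard_normal(n_v)
        return templates[seq_id]

    runs: list[BOLDRun] = []
    for run_idx in range(1, design.n_runs + 1):
        ev = events[events["run"] == run_idx].reset_index(drop=True)
        end = (ev["onset"] + ev["duration"]).max()
        n_t = int(np.ceil((end + 20.0) / params.tr_s))

        # unit-peak per event so amp_phase is the peak response amplitude,
        # independent of event duration (3 s encoding vs up to 9 s delay)
        regs = event_regressors(ev, params.tr_s, n_t)

        patterns = np.empty((len(ev), n_v))
        weights = []
        for k, row in ev.iterrows():
            s = (
                params.w(run_idx, design.n_runs)
                if row["seq_type"] == "repeat"
                else params.novel_structure_gain
            )
            fresh = rng.standard_normal(n_v)
            pat = s * template(row["seq_id"]) + np.sqrt(max(0.0, 1.0 - s ** 2)) * fresh
            pat = pat + params.mean_activation
            amp = np.empty(n_v)
            for roi, sl in roi_slices.items():
                amp[sl] = params.amp_phase[row["trial_type"]] * params.gain(roi, row["trial_type"])
            patterns[k] = amp * pat
            weights.append(
                dict(run=run_idx, trial=row["trial"], phase=row["trial_type"],
                     seq_id=row["seq_id"], s=s)
            )
        signal = regs @ patterns

        x = np.linspace(-1.0, 1.0, n_t)
        poly = np.polynomial.legendre.legvander(x, params.drift_poly_degree)
        drift = poly @ (rng.standard_normal((params.drift_poly_degree + 1, n_v)) * params.drift_sd)

        comps = gaussian_filter1d(
            rng.standard_normal((n_t, params.n_noise_components)), sigma=4.0, axis=0
        )
        comps /= comps.std(axis=0, keepdims=True)
        comp_sig = comps @ (rng.standard_normal((params.n_noise_components, n_v)) * params.component_sd)

        noise = _ar1_noise(rng, n_t, n_v, params.ar1_rho, params.noise_sd)

        nuisance = pd.DataFrame(
            np.hstack([poly, comps]),
            columns=[f"poly{d}" for d in range(params.drift_poly_degree + 1)]
            + [f"comp{c + 1}" for c in range(params.n_noise_components)],
        )
        runs.append(
            BOLDRun(
                data=(signal + drift + comp_sig + noise).T,
                tr_s=params.tr_s, run=run_idx, roi_labels=roi_labels,
                nuisance=nuisance,
                truth={"templates": dict(templates), "weights": pd.DataFrame(weights)},
            )
        )

    behav_rows = []
    for tr in design.trials:
        p = params.p_correct[float(tr.delay_s)]
        correct = bool(rng.random() < p)
        response = tr.probe_type if correct else (
            "mismatch" if tr.probe_type == "match" else "match"
        )
        behav_rows.append(
            dict(subject=subject, run=tr.run, trial=tr.trial, seq_type=tr.seq_type,
                 probe_type=tr.probe_type, delay_s=tr.delay_s,
                 response=response, correct=correct)
        )
    return runs, pd.DataFrame(behav_rows)
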