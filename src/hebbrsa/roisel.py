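"""Univariate phase GLM per ROI and FDR-based conjunction grouping.

Encoding, delay, and probe phases are modeled with duration-matched
boxcar x HRF regressors (encoding and delay split by sequence type, probe
further split by probe type), together with the nuisance matrix.  Voxelwise
least-squares betas are averaged within each ROI; one-sample t-tests across
subjects per (ROI, phase) are Benjamini–Hochberg adjusted within phase, and
ROIs are grouped by the conjunction of their encoding/delay significance:

    auditory          p_fdr(encoding) < alpha and p_fdr(delay) >= alpha
    auditory+memory   p_fdr(encoding) < alpha and p_fdr(delay) <  alpha
    memory            p_fdr(encoding) >= alpha and p_fdr(delay) < alpha
    none              otherwise

The boundary value p_fdr == alpha falls on the not-significant side.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import InvalidInputError, SingularDesignError
from .stimgen import PHASES
from .synthfmri import BOLDRun, event_regressors

GROUPS = ("auditory", "auditory+memory", "memory", "none")


@dataclass(frozen=True)
class ROIPhaseStat:
    roi: str
    phase: str
    mean_beta: float
    t_stat: float
    p_value: float
    p_fdr: float | None = None


def _phase_regressor_spec(events: pd.DataFrame):
    """(name, row-mask) pairs: enc/delay by seq_type, probe by seq x probe type."""
    specs = []
    for st in ("repeat", "novel"):
        for ph in ("encoding", "delay"):
            specs.append((f"{ph}_{st}",
                          (events["trial_type"] == ph) & (events["seq_type"] == st)))
        for pt in ("match", "mismatch"):
            specs.append((f"probe_{st}_{pt}",
                          (events["trial_type"] == "probe")
                          & (events["seq_type"] == st)
                          & (events["probe_type"] == pt)))
    return specs


def phase_glm(bold: BOLDRun, events: pd.DataFrame,
              nuisance: pd.DataFrame | None = None) -> pd.DataFrame:
    """Voxelwise phase GLM, averaged to per-ROI mean betas per phase.

    Returns a tidy frame (roi, phase, mean_beta) where the phase beta
    collapses across the sequence-type (and probe-type) split regressors.
    """
    ev = events[events["run"] == bold.run]
    if ev.empty:
        raise InvalidInputError(f"no events for run {bold.run}")
    nuis = bold.nuisance if nuisance is None else nuisance
    n_t = bold.n_timepoints
    names, cols = [], []
    for name, mask in _phase_regressor_spec(ev):
        if mask.any():
            names.append(name)
            cols.append(event_regressors(ev[mask], bold.tr_s, n_t).sum(axis=1))
    X = np.column_stack(cols + [nuis.to_numpy(dtype=float)])
    all_names = names + list(nuis.columns)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = np.corrcoef(X.T)
        bad = sorted({
            all_names[a] for a in range(len(all_names))
            for b in range(a + 1, len(all_names))
            if abs(corr[a, b]) > 0.999
        })
        raise SingularDesignError(
            f"singular phase-GLM design (rank {rank} < {X.shape[1]}); "
            f"near-collinear columns: {bad or all_names}", columns=bad or all_names
        )
    coef, *_ = np.linalg.lstsq(X, bold.data.T, rcond=None)
    beta = pd.DataFrame(coef[: len(names)].T, columns=names)
    beta["roi"] = list(bold.roi_labels)
    roi_mean = beta.groupby("roi").mean()
    rows = []
    for roi, r in roi_mean.iterrows():
        for phase in PHASES:
            sel = [n for n in names if n.startswith(phase)]
            rows.append(dict(roi=roi, phase=phase, mean_beta=float(r[sel].mean())))
    return pd.DataFrame(rows)


def one_sample_t(values) -> tuple[float, float]:
    """One-sample t vs 0 with two-sided p; zero variance flags an infinite t."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InvalidInputError("need at least 2 observations")
    if np.allclose(x.std(ddof=1), 0.0):
        warnings.warn("zero variance in one-sample t-test; returning infinite t")
        if np.allclose(x.mean(), 0.0):
            return 0.0, 1.0
        return float(np.sign(x.mean()) * np.inf), 0.0
    res = stats.ttest_1samp(x, 0.0)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise InvalidInputError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def roi_phase_stats(subject_betas: pd.DataFrame,
                    phases=("encoding", "delay")) -> pd.DataFrame:
    """Group-level one-sample tests per (roi, phase) with BH-FDR within phase.

    ``subject_betas``: long frame (subject, roi, phase, mean_beta) from
    per-subject ``phase_glm`` output.
    """
    rows = []
    for phase in phases:
        sub = subject_betas[subject_betas["phase"] == phase]
        stats_rows = []
        for roi, grp in sub.groupby("roi"):
            t, p = one_sample_t(grp["mean_beta"])
            stats_rows.append(dict(roi=roi, phase=phase,
                                   mean_beta=float(grp["mean_beta"].mean()),
                                   t_stat=t, p_value=p))
        dfp = pd.DataFrame(stats_rows)
        dfp["p_fdr"] = bh_fdr(dfp["p_value"].clip(lower=np.nextafter(0, 1)))
        rows.append(dfp)
    return pd.concat(rows, ignore_index=True)


def conjunction_groups(stats_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Assign each ROI to auditory / auditory+memory / memory / none."""
    wide = stats_table.pivot(index="roi", columns="phase", values="p_fdr")
    for ph in ("encoding", "delay"):
        if ph not in wide or wide[ph].isna().any():
            raise InvalidInputError(f"missing FDR-adjusted p-values for phase {ph!r}")
    enc = wide["encoding"] < alpha
    dly = wide["delay"] < alpha
    group = np.select(
        [enc & ~dly, enc & dly, ~enc & dly],
        ["auditory", "auditory+memory", "memory"],
        default="none",
    )
    return pd.DataFrame({"roi": wide.index, "group": group}).reset_index(drop=True)
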