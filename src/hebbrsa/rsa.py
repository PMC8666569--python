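"""Representational similarity analysis over single-trial beta patterns.

Neural RDMs use correlation distance (1 - Pearson) between trial patterns;
the RSA effect is the Spearman rank correlation between the lower triangles
of a model RDM (tone-sequence EMDs) and a neural RDM.  A positive effect
means trials with more similar sequences evoke more similar patterns.
Contrasting the repeat-trial effect against the novel-trial effect isolates
repetition-driven pattern structure from generic sequence-similarity coding,
and recomputing the effects per run traces the learning trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .exceptions import InvalidInputError, UndefinedStatisticError
from .seqdist import GroundMetric, DEFAULT_METRIC, ModelRDM, build_model_rdm
from .singletrial import TrialBetas, build_trial_design, denoise, pls_betas
from .stimgen import ExperimentDesign, PHASES, design_to_events
from .synthfmri import BOLDRun

EFFECT_COLUMNS = ["subject", "roi", "phase", "seq_type", "run", "value"]


@dataclass(frozen=True)
class NeuralRDM:
    """Correlation-distance matrix over trial patterns; entries in [0, 2]."""

    matrix: np.ndarray
    trial_ids: tuple[str, ...]
    roi: str | None = None
    phase: str | None = None


@dataclass(frozen=True)
class RSAEffect:
    """Model–neural association for one (subject, roi, phase, seq_type, run) cell."""

    value: float
    subject: int | None = None
    roi: str | None = None
    phase: str | None = None
    seq_type: str | None = None
    run: int | str = "pooled"
    n_pairs: int = 0


def neural_rdm(betas: TrialBetas, method: str = "correlation") -> NeuralRDM:
    """Trial-by-trial pattern dissimilarity from a trials x voxels beta matrix.

    Zero-variance patterns get missing entries and are excluded downstream.
    """
    B = np.asarray(betas.betas, dtype=float)
    if B.shape[0] < 2 or B.shape[1] < 2:
        raise InvalidInputError("need >= 2 trials and >= 2 voxels")
    if method == "correlation":
        sd = B.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            D = 1.0 - np.corrcoef(B)
        D[sd == 0, :] = np.nan
        D[:, sd == 0] = np.nan
    elif method == "euclidean":
        diff = B[:, None, :] - B[None, :, :]
        D = np.sqrt((diff ** 2).sum(axis=-1))
    else:
        raise InvalidInputError(f"unknown dissimilarity method {method!r}")
    np.fill_diagonal(D, 0.0)
    return NeuralRDM(D, betas.trial_ids, roi=betas.roi, phase=betas.phase)


def rsa_effect(model: ModelRDM, neural: NeuralRDM, **labels) -> RSAEffect:
    """Spearman correlation between lower triangles of model and neural RDMs.

    Missing neural cells are pairwise-excluded; fewer than 3 valid pairs is
    an undefined statistic.
    """
    if tuple(model.trial_ids) != tuple(neural.trial_ids):
        raise InvalidInputError("model and neural RDM trial_ids do not match")
    i, j = np.tril_indices(len(model.trial_ids), k=-1)
    m = model.matrix[i, j]
    n = neural.matrix[i, j]
    ok = np.isfinite(m) & np.isfinite(n)
    if ok.sum() < 3:
        raise UndefinedStatisticError("fewer than 3 valid RDM cell pairs")
    rho = spearmanr(m[ok], n[ok]).statistic
    return RSAEffect(value=float(rho), n_pairs=int(ok.sum()),
                     phase=neural.phase, roi=neural.roi, **labels)


def effects_to_frame(effects) -> pd.DataFrame:
    rows = [
        dict(subject=e.subject, roi=e.roi, phase=e.phase, seq_type=e.seq_type,
             run=e.run, value=e.value)
        for e in effects
    ]
    return pd.DataFrame(rows, columns=EFFECT_COLUMNS)


def repeat_novel_contrast(effects: pd.DataFrame) -> pd.DataFrame:
    """value(repeat) - value(novel), matched on subject/roi/phase/run.

    Unmatched cells come back with a missing contrast so they can be
    reported rather than silently dropped.
    """
    df = effects if isinstance(effects, pd.DataFrame) else effects_to_frame(effects)
    keys = ["subject", "roi", "phase", "run"]
    wide = df.pivot_table(index=keys, columns="seq_type", values="value",
                          aggfunc="mean", dropna=False).reset_index()
    for col in ("repeat", "novel"):
        if col not in wide:
            wide[col] = np.nan
    wide["contrast"] = wide["repeat"] - wide["novel"]
    return wide


# ---------------------------------------------------------------------------
# subject-level pipeline
# ---------------------------------------------------------------------------

def _run_betas(design: ExperimentDesign, bold: BOLDRun, phases,
               n_components: int) -> dict[str, TrialBetas]:
    """Denoise one run and estimate trial betas for each requested phase."""
    events = design_to_events(design)
    ev = events[events["run"] == bold.run]
    resid = denoise(bold, bold.nuisance)
    out = {}
    for phase in phases:
        X = build_trial_design(ev, phase, bold.tr_s, bold.n_timepoints)
        out[phase] = pls_betas(X, resid, n_components, run=bold.run)
    return out


def _subset_betas(betas_by_run: dict[int, TrialBetas], design: ExperimentDesign,
                  seq_type: str, runs, roi_mask=None) -> TrialBetas:
    """Stack the trials of one sequence type (within ``runs``) across runs."""
    wanted = {
        (t.run, t.trial) for t in design.trials
        if t.seq_type == seq_type and t.run in set(runs)
    }
    blocks, ids = [], []
    for r in sorted(set(runs)):
        tb = betas_by_run[r]
        keep = [
            k for k, tid in enumerate(tb.trial_ids)
            if (r, int(tid.split("-trial")[1])) in wanted
        ]
        B = tb.betas[keep]
        if roi_mask is not None:
            B = B[:, roi_mask]
        blocks.append(B)
        ids.extend(tb.trial_ids[k] for k in keep)
    first = betas_by_run[sorted(set(runs))[0]]
    return TrialBetas(np.vstack(blocks), tuple(ids), first.phase)


def subject_rsa_effects(
    design: ExperimentDesign,
    bold_runs: list[BOLDRun],
    subject: int | None = None,
    roi: str | list[str] | None = None,
    phases=PHASES,
    metric: GroundMetric = DEFAULT_METRIC,
    n_components: int = 5,
    per_run: bool = True,
) -> pd.DataFrame:
    """Full within-subject pipeline: betas -> RDMs -> pooled and per-run effects.

    ``roi`` restricts the voxel set to one ROI label or a list of labels
    (None = all voxels as a single pattern); betas are estimated once and
    shared across ROIs.  Returns a long-format effects table (subject, roi,
    phase, seq_type, run, value) with run = "pooled" rows and, if requested,
    one row per run.
    """
    labels = np.asarray(bold_runs[0].roi_labels)
    if roi is None:
        roi_masks = {None: None}
    else:
        roi_list = [roi] if isinstance(roi, str) else list(roi)
        roi_masks = {r: labels == r for r in roi_list}
        for r, mask in roi_masks.items():
            if not mask.any():
                raise InvalidInputError(f"no voxels labelled {r!r}")
    all_runs = [b.run for b in bold_runs]
    betas = {phase: {} for phase in phases}
    for bold in bold_runs:
        for phase, tb in _run_betas(design, bold, phases, n_components).items():
            betas[phase][bold.run] = tb

    model_cache = {
        (seq_type, rkey): build_model_rdm(design, seq_type, runs=rsel, metric=metric)
        for seq_type in ("repeat", "novel")
        for rkey, rsel in [("pooled", all_runs)] + ([(r, [r]) for r in all_runs] if per_run else [])
    }

    effects = []
    for phase in phases:
        for seq_type in ("repeat", "novel"):
            for roi_name, roi_mask in roi_masks.items():
                pooled_b = _subset_betas(betas[phase], design, seq_type, all_runs, roi_mask)
                eff = rsa_effect(model_cache[(seq_type, "pooled")], neural_rdm(pooled_b))
                effects.append(RSAEffect(eff.value, subject, roi_name, phase,
                                         seq_type, "pooled", eff.n_pairs))
                if per_run:
                    for r in all_runs:
                        b_r = _subset_betas(betas[phase], design, seq_type, [r], roi_mask)
                        try:
                            e = rsa_effect(model_cache[(seq_type, r)], neural_rdm(b_r))
                        except UndefinedStatisticError:
                            continue
                        effects.append(RSAEffect(e.value, subject, roi_name, phase,
                                                 seq_type, r, e.n_pairs))
    return effects_to_frame(effects)


def per_run_trajectory(effects: pd.DataFrame) -> pd.DataFrame:
    """Per-run effect series (drops pooled rows), ready for run-slope models."""
    df = effects if isinstance(effects, pd.DataFrame) else effects_to_frame(effects)
    out = df[df["run"] != "pooled"].copy()
    out["run"] = out["run"].astype(int)
    return out.sort_values(["subject", "roi", "phase", "seq_type", "run"]).reset_index(drop=True)
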