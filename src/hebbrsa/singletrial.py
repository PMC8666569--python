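"""Single-trial activity estimation: denoise -> per-trial design -> PLS betas.

The estimator follows a beta-series logic with latent-component
regularization.  For one run and one trial phase:

1. the voxel time series are residualized against the known nuisance matrix
   (polynomial drift basis plus shared noise components);
2. a design matrix X holds one HRF-convolved regressor per trial of the
   target phase, plus a "fixed effect" column equal to the row-wise sum of
   the trial columns (this common-activation column absorbs the shared
   evoked response and regularizes the trialwise estimates);
3. for every voxel, the denoised series y is regressed on X by univariate
   partial least squares (PLS1) with a small number of components, and the
   trial-column coefficients are kept as that voxel's single-trial betas.

PLS1 coefficients are computed by projecting the least-squares problem onto
the Krylov subspace span{X'y, (X'X)X'y, ...} — the classical equivalence of
PLS1 with conjugate-gradient iterations on the normal equations — which
yields coefficients identical to NIPALS/SIMPLS at the same component count
and reduces to OLS when the component count reaches the problem's grade.
X columns are mean-centered (not variance-scaled) and y is centered per
voxel, so betas keep the units of the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .synthfmri import BOLDRun, event_regressors

DEFAULT_N_COMPONENTS = 5


@dataclass(frozen=True)
class TrialDesignMatrix:
    """Per-trial HRF regressors plus the row-sum fixed-effect column (last)."""

    X: np.ndarray                  # timepoints x (n_trials + 1)
    trial_ids: tuple[str, ...]
    phase: str
    has_fixed_effect: bool = True

    @property
    def n_trials(self) -> int:
        return len(self.trial_ids)


@dataclass
class TrialBetas:
    """Trials x voxels single-trial activity estimates for one run and phase."""

    betas: np.ndarray
    trial_ids: tuple[str, ...]
    phase: str
    run: int | None = None
    roi: str | None = None
    meta: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.betas, index=list(self.trial_ids))


def _as_timeseries(data) -> np.ndarray:
    """Accept a BOLDRun (voxels x time) or an array (time x voxels)."""
    if isinstance(data, BOLDRun):
        return data.data.T
    return np.asarray(data, dtype=float)


def denoise(data, nuisance) -> np.ndarray:
    """Residualize each voxel's series against the nuisance column space.

    Returns a timepoints x voxels array of least-squares residuals; a rank
    deficient nuisance matrix triggers a warning and a pseudoinverse
    projection.
    """
    Y = _as_timeseries(data)
    N = nuisance.to_numpy(dtype=float) if isinstance(nuisance, pd.DataFrame) else np.asarray(nuisance, dtype=float)
    if N.shape[0] != Y.shape[0]:
        raise InvalidInputError(
            f"nuisance rows ({N.shape[0]}) != timepoints ({Y.shape[0]})"
        )
    if np.linalg.matrix_rank(N) < N.shape[1]:
        warnings.warn("rank-deficient nuisance matrix; using pseudoinverse projection")
    coef, *_ = np.linalg.lstsq(N, Y, rcond=None)
    return Y - N @ coef


def build_trial_design(events: pd.DataFrame, phase: str, tr_s: float,
                       n_timepoints: int,
                       include_fixed_effect: bool = True) -> TrialDesignMatrix:
    """One HRF-convolved regressor per trial of ``phase`` + row-sum column.

    Columns are unit-peak normalized, so a beta is the trial's peak response
    amplitude irrespective of the event duration (delay trials vary 3-9 s).
    """
    ev = events[events["trial_type"] == phase]
    if ev.empty:
        raise InvalidInputError(f"no events of phase {phase!r}")
    if ev.duplicated(subset=["run", "trial"]).any():
        raise InvalidInputError("duplicate trial events for the requested phase")
    ids = [
        f"run{int(r):02d}-trial{int(t):02d}"
        for r, t in zip(ev["run"], ev["trial"])
    ]
    X = event_regressors(ev, tr_s, n_timepoints)
    if include_fixed_effect:
        X = np.column_stack([X, X.sum(axis=1)])
    return TrialDesignMatrix(X, tuple(ids), phase, include_fixed_effect)


def _pls1_coef(Xc: np.ndarray, yc: np.ndarray, n_components: int) -> np.ndarray:
    """PLS1 regression coefficients via an orthonormal Krylov basis.

    Builds span{s, As, ..., A^(k-1)s} with s = X'y, A = X'X (Lanczos-style
    re-orthogonalization) and solves the least-squares problem restricted to
    that subspace.  Terminates early when the Krylov space saturates, at
    which point the coefficients equal the (minimum-norm) OLS solution.
    """
    s = Xc.T @ yc
    A = Xc.T @ Xc
    scale = np.linalg.norm(s)
    if scale == 0:
        return np.zeros(Xc.shape[1])
    basis = []
    v = s.copy()
    for _ in range(n_components):
        for b in basis:                       # full re-orthogonalization
            v = v - (b @ v) * b
        for b in basis:
            v = v - (b @ v) * b
        nv = np.linalg.norm(v)
        if nv <= 1e-12 * scale:
            break
        v = v / nv
        basis.append(v)
        v = A @ v
    Q = np.column_stack(basis)
    M = Q.T @ A @ Q
    rhs = Q.T @ s
    coef, *_ = np.linalg.lstsq(M, rhs, rcond=None)
    return Q @ coef


def pls_betas(design: TrialDesignMatrix, Y: np.ndarray,
              n_components: int = DEFAULT_N_COMPONENTS, *,
              run: int | None = None, roi: str | None = None) -> TrialBetas:
    """Per-voxel PLS1 betas for the trial columns of ``design``.

    ``Y`` is the denoised timepoints x voxels array.  The fixed-effect
    coefficient is retained in ``meta['fixed_effect_beta']`` but excluded
    from the returned patterns.  ``n_components`` above rank(X) is clipped
    with a warning.
    """
    X = design.X
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.ndim == 2 and Y.shape[0] != X.shape[0]:
        if Y.shape[1] == X.shape[0]:
            Y = Y.T
        else:
            raise InvalidInputError("Y timepoints do not match the design matrix")
    if n_components < 1:
        raise InvalidInputError("n_components must be >= 1")
    rank = np.linalg.matrix_rank(X)
    if n_components > rank:
        warnings.warn(f"n_components={n_components} > rank(X)={rank}; clipping")
        n_components = rank
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    coefs = np.empty((X.shape[1], Y.shape[1]))
    for v in range(Y.shape[1]):
        coefs[:, v] = _pls1_coef(Xc, Yc[:, v], n_components)
    return TrialBetas(
        betas=coefs[:-1] if design.has_fixed_effect else coefs,
        trial_ids=design.trial_ids,
        phase=design.phase,
        run=run,
        roi=roi,
        meta={
            "n_components": n_components,
            "fixed_effect_beta": coefs[-1].copy() if design.has_fixed_effect else None,
            "denoising": "nuisance-projected Y (design not denoised)",
        },
    )
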