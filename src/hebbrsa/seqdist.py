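"""Earth Mover's Distance between tone sequences and model RDM assembly.

A nine-tone sequence is treated as a discrete distribution placing mass 1/9
at each (serial position, pitch) coordinate.  The EMD between two sequences
is the minimal cost of transporting one distribution onto the other under a
ground cost that charges for moving a tone across serial positions and for
exchanging it against a tone of different pitch — it is "costlier" to move
tones with different frequencies across larger serial distances.  With equal
unit masses the balanced transportation problem reduces exactly to an
assignment problem, which is solved to optimality (Hungarian algorithm).

Model RDMs are the pairwise EMDs over the study sequences of the repeat (or
novel) trials of a design; identical-sequence trial pairs have dissimilarity
exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .exceptions import InvalidInputError
from .stimgen import DEFAULT_BASE_HZ, DEFAULT_STEP_RATIO, ExperimentDesign, ToneSequence

PITCH_SCALES = ("pool-steps", "semitones", "log-hz")


@dataclass(frozen=True)
class GroundMetric:
    """Per-unit transport costs over the (serial position, pitch) plane.

    ``pitch_scale`` fixes the pitch unit: ``pool-steps`` counts multiplicative
    steps of the generating ladder (log_step(f/base)), ``semitones`` is
    12*log2, ``log-hz`` is the natural log of frequency.
    """

    position_weight: float = 1.0
    pitch_weight: float = 1.0
    pitch_scale: str = "pool-steps"
    base_hz: float = DEFAULT_BASE_HZ
    step_ratio: float = DEFAULT_STEP_RATIO

    def __post_init__(self):
        if self.position_weight < 0 or self.pitch_weight < 0:
            raise InvalidInputError("ground-metric weights must be >= 0")
        if self.position_weight == 0 and self.pitch_weight == 0:
            raise InvalidInputError("at least one ground-metric weight must be positive")
        if self.pitch_scale not in PITCH_SCALES:
            raise InvalidInputError(f"pitch_scale must be one of {PITCH_SCALES}")

    def pitch_values(self, freqs_hz) -> np.ndarray:
        f = np.asarray(freqs_hz, dtype=float)
        if self.pitch_scale == "pool-steps":
            return np.log(f / self.base_hz) / np.log(self.step_ratio)
        if self.pitch_scale == "semitones":
            return 12.0 * np.log2(f / self.base_hz)
        return np.log(f)


DEFAULT_METRIC = GroundMetric()


@dataclass(frozen=True)
class ModelRDM:
    """Square symmetric trial-by-trial dissimilarity matrix in EMD units."""

    matrix: np.ndarray
    trial_ids: tuple[str, ...]
    kind: str                      # "repeat" | "novel"

    def __post_init__(self):
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.trial_ids):
            raise InvalidInputError("RDM matrix/trial_ids shape mismatch")

    def to_csv(self, path) -> None:
        pd.DataFrame(self.matrix, index=list(self.trial_ids),
                     columns=list(self.trial_ids)).to_csv(path)

    def to_long(self) -> pd.DataFrame:
        i, j = np.triu_indices(len(self.trial_ids), k=1)
        return pd.DataFrame(
            {
                "trial_i": [self.trial_ids[a] for a in i],
                "trial_j": [self.trial_ids[b] for b in j],
                "dissimilarity": self.matrix[i, j],
            }
        )


def sequence_emd(
    a: ToneSequence,
    b: ToneSequence,
    metric: GroundMetric = DEFAULT_METRIC,
) -> float:
    """Exact EMD between two equal-length tone sequences.

    Ground cost between tone i of ``a`` and tone j of ``b``:
    ``position_weight*|i - j| + pitch_weight*|pitch_a(i) - pitch_b(j)|``;
    each tone carries mass 1/n.  Symmetric, and 0 iff the sequences agree.
    """
    if len(a) != len(b):
        raise InvalidInputError("sequences must have equal length")
    n = len(a)
    pa = metric.pitch_values(a.freqs_hz)
    pb = metric.pitch_values(b.freqs_hz)
    pos = np.arange(n, dtype=float)
    cost = (
        metric.position_weight * np.abs(pos[:, None] - pos[None, :])
        + metric.pitch_weight * np.abs(pa[:, None] - pb[None, :])
    )
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum() / n)


def build_model_rdm(
    design: ExperimentDesign,
    subset: str,
    runs=None,
    metric: GroundMetric = DEFAULT_METRIC,
    phase_replication: int = 1,
) -> ModelRDM:
    """Pairwise EMD RDM over the study sequences of one trial subset.

    ``subset`` selects repeat or novel trials (optionally restricted to
    ``runs``), ordered as in the session.  ``phase_replication`` > 1 tiles
    the trial set block-wise so the RDM lines up with per-phase beta stacks.
    """
    if subset not in ("repeat", "novel"):
        raise InvalidInputError("subset must be 'repeat' or 'novel'")
    trials = [
        t for t in design.trials
        if t.seq_type == subset and (runs is None or t.run in set(runs))
    ]
    if not trials:
        raise InvalidInputError(f"no {subset} trials in the requested runs")
    seqs = [t.study_seq for t in trials] * phase_replication
    ids = [
        f"run{t.run:02d}-trial{t.trial:02d}" + (f"-p{p}" if phase_replication > 1 else "")
        for p in range(phase_replication)
        for t in trials
    ]
    n = len(seqs)
    mat = np.zeros((n, n))
    # cache on sequence identity: repeated sequences share EMD values
    cache: dict[tuple, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            key = (seqs[i].freqs_hz, seqs[j].freqs_hz)
            if key not in cache:
                d = sequence_emd(seqs[i], seqs[j], metric)
                cache[key] = d
                cache[(key[1], key[0])] = d
            mat[i, j] = mat[j, i] = cache[key]
    return ModelRDM(mat, tuple(ids), subset)
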