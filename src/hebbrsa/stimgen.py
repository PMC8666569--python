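"""Stimulus and experiment-design generation for the Hebb-repetition tone task.

A session presents nine-tone sequences drawn from a geometric frequency
ladder (300–2600 Hz in 30% proportional steps).  Three covertly repeating
sequences (S1, S2, S3) are intermixed with novel sequences; on every trial a
study sequence is followed, after a 3/6/9 s silent delay, by a probe that is
either identical ("match") or differs by one adjacent transposition
("mismatch").  The default session is 8 runs x 18 trials = 144 trials with
36 trials per sequence-type x probe-type cell and each repeating sequence
studied 24 times, the same repeating sequence never occurring on two
successive trials.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import (
    DesignInfeasibleError,
    InvalidParameterError,
    NoValidProbeError,
)

DEFAULT_BASE_HZ = 300.0
DEFAULT_STEP_RATIO = 1.3
DEFAULT_MAX_HZ = 2600.0
SEQ_LEN = 9
TONE_DUR_S = 0.200
GAP_S = 0.150
ENCODING_DUR_S = 3.0
PROBE_DUR_S = 3.0
DELAYS_S = (3.0, 6.0, 9.0)
ITI_RANGE_S = (4.0, 10.0)
PHASES = ("encoding", "delay", "probe")

EVENT_COLUMNS = [
    "onset", "duration", "trial_type", "run", "trial",
    "seq_id", "seq_type", "probe_type", "delay_s",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TonePool:
    """Maximal geometric ladder of pure-tone frequencies within [base, max]."""

    frequencies: tuple[float, ...]
    base_hz: float
    step_ratio: float
    max_hz: float

    def __len__(self) -> int:
        return len(self.frequencies)


@dataclass(frozen=True)
class ToneSequence:
    """Ordered nine-tone stimulus; tones of ``tone_dur_s`` separated by silent gaps."""

    freqs_hz: tuple[float, ...]
    tone_dur_s: float = TONE_DUR_S
    gap_s: float = GAP_S
    seq_id: str = ""

    def __len__(self) -> int:
        return len(self.freqs_hz)

    @property
    def total_dur_s(self) -> float:
        n = len(self.freqs_hz)
        return n * self.tone_dur_s + (n - 1) * self.gap_s


@dataclass(frozen=True)
class TrialSpec:
    run: int
    trial: int
    seq_type: str            # "repeat" | "novel"
    probe_type: str          # "match" | "mismatch"
    delay_s: float
    study_seq: ToneSequence
    probe_seq: ToneSequence
    onset_s: float
    iti_s: float

    @property
    def condition(self) -> str:
        return f"{self.seq_type}-{self.probe_type}-{int(self.delay_s)}s"


@dataclass(frozen=True)
class ExperimentDesign:
    trials: tuple[TrialSpec, ...]
    repeating_seqs: tuple[ToneSequence, ToneSequence, ToneSequence]
    n_runs: int
    trials_per_run: int
    seed: int


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_tone_pool(
    base_hz: float = DEFAULT_BASE_HZ,
    step_ratio: float = DEFAULT_STEP_RATIO,
    max_hz: float = DEFAULT_MAX_HZ,
) -> TonePool:
    """Build the maximal geometric frequency ladder within ``[base_hz, max_hz]``.

    Frequencies are ``base_hz * step_ratio**k`` for k = 0, 1, ... while the
    value stays at or below ``max_hz``.  Defaults give the 9-tone pool
    spanning 300–2600 Hz in proportional 30% increments.
    """
    if base_hz <= 0 or max_hz <= 0:
        raise InvalidParameterError("frequencies must be positive")
    if step_ratio <= 1:
        raise InvalidParameterError("step_ratio must exceed 1")
    if max_hz < base_hz:
        raise InvalidParameterError("max_hz must be >= base_hz")
    freqs = [base_hz]
    while freqs[-1] * step_ratio <= max_hz:
        freqs.append(freqs[-1] * step_ratio)
    return TonePool(tuple(freqs), base_hz, step_ratio, max_hz)


def make_sequence(
    pool: TonePool,
    rng_seed: int | np.random.Generator,
    policy: str = "permutation",
    seq_id: str = "",
) -> ToneSequence:
    """Draw a nine-tone sequence from ``pool`` ("pseudorandom shuffle").

    ``permutation`` (default) shuffles nine distinct pool tones, so adjacent
    transposition probes are always well defined; ``with_replacement`` samples
    nine tones independently.
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    if policy == "permutation":
        if len(pool) < SEQ_LEN:
            raise InvalidParameterError(
                f"permutation policy needs >= {SEQ_LEN} pool tones, got {len(pool)}"
            )
        freqs = rng.permutation(np.asarray(pool.frequencies))[:SEQ_LEN]
    elif policy == "with_replacement":
        freqs = rng.choice(np.asarray(pool.frequencies), size=SEQ_LEN, replace=True)
    else:
        raise InvalidParameterError(f"unknown policy {policy!r}")
    return ToneSequence(tuple(float(f) for f in freqs), seq_id=seq_id)


def transpose_probe(
    seq: ToneSequence,
    position: int | None = None,
    rng_seed: int | np.random.Generator | None = None,
) -> ToneSequence:
    """Swap two adjacent tones, keeping the multiset of frequencies.

    ``position`` indexes the left element of the swapped pair; if omitted it
    is drawn uniformly from positions whose two adjacent tones differ.
    """
    freqs = list(seq.freqs_hz)
    n = len(freqs)
    if position is None:
        valid = [i for i in range(n - 1) if freqs[i] != freqs[i + 1]]
        if not valid:
            raise NoValidProbeError("all adjacent tone pairs are equal")
        rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
        position = int(rng.choice(valid))
    if not 0 <= position <= n - 2:
        raise InvalidParameterError(f"position must be in [0, {n - 2}]")
    freqs[position], freqs[position + 1] = freqs[position + 1], freqs[position]
    return replace(seq, freqs_hz=tuple(freqs))


def _order_labels(rng: np.random.Generator, n_runs: int, trials_per_run: int,
                  max_tries: int = 2000) -> list[list[str]]:
    """Per-run shuffles of [S1 S2 S3]x3 + novel x9 with no adjacent equal
    repeating labels, enforced across run boundaries too."""
    reps = trials_per_run // 2
    per_seq, rem = divmod(reps, 3)
    rep_labels = [f"S{i + 1}" for i in range(3) for _ in range(per_seq)]
    rep_labels += [f"S{i + 1}" for i in range(rem)]
    base = rep_labels + ["novel"] * (trials_per_run - reps)
    runs: list[list[str]] = []
    prev_last = None
    for _ in range(n_runs):
        for attempt in itertools.count():
            if attempt >= max_tries:
                raise DesignInfeasibleError(
                    "could not order repeating sequences without back-to-back repeats"
                )
            order = list(rng.permutation(base))
            ok = all(
                order[i] != order[i + 1] or order[i] == "novel"
                for i in range(len(order) - 1)
            )
            if ok and (prev_last == "novel" or order[0] != prev_last):
                break
        runs.append(order)
        prev_last = order[-1]
    return runs


def build_design(
    n_runs: int = 8,
    trials_per_run: int = 18,
    rng_seed: int = 0,
    iti_range_s: tuple[float, float] = ITI_RANGE_S,
    delays_s: tuple[float, ...] = DELAYS_S,
) -> ExperimentDesign:
    """Generate the full constrained Hebb-repetition session design.

    Each run holds equal numbers of repeat and novel trials; repeats cycle
    through S1/S2/S3; probe type and delay are balanced within every
    sequence-type x probe-type cell; ITIs are uniform on ``iti_range_s``.
    """
    n_trials = n_runs * trials_per_run
    n_rep = n_trials // 2
    per_cell = n_trials // 4                      # per seq_type x probe_type
    n_delays = len(delays_s)
    if (
        trials_per_run % 2
        or (trials_per_run // 2) % 3
        or per_cell % n_delays
        or (n_rep // 3) % 2
    ):
        raise InvalidParameterError(
            "trial counts cannot balance seq_type x probe_type x delay cells"
        )
    rng = np.random.default_rng(rng_seed)
    pool = build_tone_pool()

    # distinct repeating sequences
    reps: list[ToneSequence] = []
    while len(reps) < 3:
        cand = make_sequence(pool, rng, seq_id=f"S{len(reps) + 1}")
        if all(cand.freqs_hz != r.freqs_hz for r in reps):
            reps.append(cand)
    rep_seqs = {s.seq_id: s for s in reps}

    # per repeating sequence: balanced (probe_type, delay) slates
    per_seq_combo = (n_rep // 3) // (2 * n_delays)
    slates = {}
    for sid in rep_seqs:
        combos = [
            (pt, d)
            for pt in ("match", "mismatch")
            for d in delays_s
            for _ in range(per_seq_combo)
        ]
        rng.shuffle(combos)
        slates[sid] = combos
    novel_combos = [
        (pt, d)
        for pt in ("match", "mismatch")
        for d in delays_s
        for _ in range(per_cell // n_delays)
    ]
    rng.shuffle(novel_combos)

    label_runs = _order_labels(rng, n_runs, trials_per_run)

    used = {s.freqs_hz for s in reps}
    trials: list[TrialSpec] = []
    novel_k = 0
    for run_idx, labels in enumerate(label_runs, start=1):
        t = 0.0
        for trial_idx, lab in enumerate(labels, start=1):
            if lab == "novel":
                probe_type, delay = novel_combos.pop()
                while True:
                    novel_k += 1
                    study = make_sequence(pool, rng, seq_id=f"novel-{novel_k}")
                    if study.freqs_hz not in used:
                        used.add(study.freqs_hz)
                        break
                seq_type = "novel"
            else:
                probe_type, delay = slates[lab].pop()
                study = rep_seqs[lab]
                seq_type = "repeat"
            probe = study if probe_type == "match" else transpose_probe(study, rng_seed=rng)
            iti = round(float(rng.uniform(*iti_range_s)), 3)
            trials.append(
                TrialSpec(
                    run=run_idx, trial=trial_idx, seq_type=seq_type,
                    probe_type=probe_type, delay_s=float(delay),
                    study_seq=study, probe_seq=probe,
                    onset_s=round(t, 3), iti_s=iti,
                )
            )
            t += ENCODING_DUR_S + delay + PROBE_DUR_S + iti
    return ExperimentDesign(tuple(trials), tuple(reps), n_runs, trials_per_run, int(rng_seed))


def design_to_events(design: ExperimentDesign) -> pd.DataFrame:
    """Expand a design into a BIDS-style events table, one row per trial phase."""
    rows = []
    for tr in design.trials:
        onsets = (
            tr.onset_s,
            tr.onset_s + ENCODING_DUR_S,
            tr.onset_s + ENCODING_DUR_S + tr.delay_s,
        )
        durs = (ENCODING_DUR_S, tr.delay_s, PROBE_DUR_S)
        for phase, onset, dur in zip(PHASES, onsets, durs):
            rows.append(
                dict(
                    onset=round(onset, 3), duration=dur, trial_type=phase,
                    run=tr.run, trial=tr.trial, seq_id=tr.study_seq.seq_id,
                    seq_type=tr.seq_type, probe_type=tr.probe_type,
                    delay_s=tr.delay_s,
                )
            )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events(events: pd.DataFrame, path) -> None:
    """Write an events table as UTF-8 TSV, onsets in seconds with 3 decimals."""
    out = events.copy()
    for col in ("onset", "duration", "delay_s"):
        out[col] = out[col].map(lambda v: f"{v:.3f}")
    out.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")


def read_events(path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    return events[EVENT_COLUMNS]
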