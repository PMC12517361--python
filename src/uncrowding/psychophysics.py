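"""PEST staircase, simulated observers, and cumulative-Gaussian fitting.

The staircase follows the classical sequential-testing rules: at each
offset level a Wald test against 75% correct decides when to move, steps
halve at reversals, repeat once in the same direction, then double (with
the usual post-reversal exception). Offsets start at 800'' and are hard
capped at 1,600''. Thresholds are estimated post hoc by a binomial
maximum-likelihood fit of a cumulative Gaussian on log offset, with the
75%-correct point reported in arcsec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

START_OFFSET_ARCSEC = 800.0
MAX_OFFSET_ARCSEC = 1600.0
MIN_STEP_ARCSEC = 5.0
INITIAL_STEP_ARCSEC = 400.0
TARGET_P = 0.75
WALD_LIMIT = 1.0
DEFAULT_LAPSE = 0.02
GUESS_RATE = 0.5


def generate_direction_sequence(n_trials: int, rng: np.random.Generator) -> list[str]:
    """Random left/right sequence with runs of at most four.

    Directions are drawn independently except that a fifth repeat is forced
    to the other side, keeping the sequence balanced in expectation.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    out: list[str] = []
    run = 0
    for _ in range(n_trials):
        if run >= 4:
            d = "left" if out[-1] == "right" else "right"
        else:
            d = "right" if rng.random() < 0.5 else "left"
        if out and d == out[-1]:
            run += 1
        else:
            run = 1
        out.append(d)
    return out


@dataclass(frozen=True)
class StaircaseState:
    """PEST bookkeeping: current level, step size, and Wald counters."""

    current_offset_arcsec: float = START_OFFSET_ARCSEC
    step_arcsec: float = INITIAL_STEP_ARCSEC
    start_offset: float = START_OFFSET_ARCSEC
    max_offset: float = MAX_OFFSET_ARCSEC
    min_step: float = MIN_STEP_ARCSEC
    target_p: float = TARGET_P
    wald_limit: float = WALD_LIMIT
    n_at_level: int = 0
    correct_at_level: int = 0
    last_direction: int = 0  # sign of the last level change (+1 = larger offset)
    steps_in_direction: int = 0
    last_step_doubled: bool = False
    record_history: bool = True  # disable for very long simulated sessions
    history: tuple[tuple[float, bool], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (0 < self.current_offset_arcsec <= self.max_offset):
            raise ValueError("presented offset must lie in (0, max_offset]")


def pest_update(state: StaircaseState, response_correct: bool) -> StaircaseState:
    """Record one response and move the level when the Wald test triggers.

    Excess correct responses (beyond target_p per trial, by at least the
    Wald deviation limit) drive the offset down; excess errors drive it up.
    Step sizing follows the classical rules: halve on reversal, same size
    for the second step in a direction, then double, except that after a
    reversal that followed a doubled step the doubling is deferred one step.
    """
    n = state.n_at_level + 1
    c = state.correct_at_level + int(response_correct)
    history = state.history
    if state.record_history:
        history = history + ((state.current_offset_arcsec, bool(response_correct)),)
    expected = state.target_p * n
    move = 0
    if c - expected >= state.wald_limit:
        move = -1  # too easy: decrease offset
    elif expected - c >= state.wald_limit:
        move = +1  # too hard: increase offset
    if move == 0:
        return replace(
            state, n_at_level=n, correct_at_level=c, history=history
        )
    if state.last_direction == 0:
        step = state.step_arcsec
        steps_in_dir = 1
        doubled = False
    elif move == state.last_direction:
        k = state.steps_in_direction + 1
        if k <= 2:
            step = state.step_arcsec
            doubled = False
        elif k == 3 and state.last_step_doubled:
            # post-reversal exception: wait one extra step before doubling
            step = state.step_arcsec
            doubled = False
        else:
            step = state.step_arcsec * 2.0
            doubled = True
        steps_in_dir = k
    else:
        step = max(state.step_arcsec / 2.0, state.min_step)
        steps_in_dir = 1
        doubled = state.last_step_doubled  # remembered for the exception rule
    new_offset = min(
        state.max_offset, max(state.min_step, state.current_offset_arcsec + move * step)
    )
    return replace(
        state,
        current_offset_arcsec=new_offset,
        step_arcsec=step,
        n_at_level=0,
        correct_at_level=0,
        last_direction=move,
        steps_in_direction=steps_in_dir,
        last_step_doubled=doubled,
        history=history,
    )


@dataclass(frozen=True)
class SimulatedObserver:
    """2AFC observer: P(correct | offset) follows a cumulative Gaussian in
    log offset between the guess rate and 1 - lapse/2."""

    mu_log: float
    sigma_log: float
    lapse: float = DEFAULT_LAPSE

    def p_correct(self, offset_arcsec: float) -> float:
        if offset_arcsec <= 0:
            raise ValueError("offset must be positive")
        z = (math.log(offset_arcsec) - self.mu_log) / self.sigma_log
        return GUESS_RATE + (1.0 - GUESS_RATE - self.lapse / 2.0) * stats.norm.cdf(z)

    @property
    def true_threshold(self) -> float:
        """Offset at which p_correct equals 0.75 exactly."""
        q = (TARGET_P - GUESS_RATE) / (1.0 - GUESS_RATE - self.lapse / 2.0)
        return math.exp(self.mu_log + self.sigma_log * stats.norm.ppf(q))


def simulate_block(
    observer: SimulatedObserver,
    rng: np.random.Generator,
    n_trials: int = 80,
    state: StaircaseState | None = None,
):
    """One 80-trial block driven by the PEST staircase.

    Returns (trial table, final staircase state); passing the returned
    state into another call continues the staircase across blocks, giving
    the standard 160 trials per condition over two blocks.
    """
    import pandas as pd

    state = state or StaircaseState()
    directions = generate_direction_sequence(n_trials, rng)
    rows = []
    for i, direction in enumerate(directions):
        offset = state.current_offset_arcsec
        correct = bool(rng.random() < observer.p_correct(offset))
        rows.append((i, direction, offset, correct))
        state = pest_update(state, correct)
    table = pd.DataFrame(rows, columns=["trial", "direction", "offset_arcsec", "response"])
    return table, state


@dataclass(frozen=True)
class PsychometricFit:
    """Cumulative-Gaussian fit on log offset with 75%-correct threshold."""

    mu_log: float
    sigma_log: float
    threshold_arcsec: float
    converged: bool
    n_trials: int


def _nll(params, log_x, k, n, lapse):
    mu, log_sigma = params
    sigma = math.exp(log_sigma)
    p = GUESS_RATE + (1.0 - GUESS_RATE - lapse / 2.0) * stats.norm.cdf(
        (log_x - mu) / sigma
    )
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return -(k * np.log(p) + (n - k) * np.log(1 - p)).sum()


def fit_psychometric(table, lapse: float = DEFAULT_LAPSE) -> PsychometricFit:
    """Binomial MLE of the psychometric function from a trial table.

    The table needs ``offset_arcsec`` and boolean ``response`` columns.
    Degenerate data (all correct, all incorrect, or a fitted threshold at
    or beyond the 1,600'' staircase cap) are flagged non-converged with the
    threshold censored at the cap.
    """
    grouped = table.groupby("offset_arcsec")["response"].agg(["sum", "count"])
    if len(grouped) < 2:
        raise ValueError("need at least two distinct offsets to fit")
    log_x = np.log(grouped.index.to_numpy(dtype=float))
    k = grouped["sum"].to_numpy(dtype=float)
    n = grouped["count"].to_numpy(dtype=float)
    n_total = int(n.sum())
    if k.sum() == 0 or k.sum() == n.sum():
        return PsychometricFit(math.nan, math.nan, MAX_OFFSET_ARCSEC, False, n_total)
    frac = k.sum() / n.sum()
    mu0 = float(np.average(log_x, weights=n)) + (0.5 if frac < TARGET_P else 0.0)
    best = None
    for log_s0 in (math.log(0.1), math.log(0.3), math.log(1.0)):
        res = optimize.minimize(
            _nll,
            x0=[mu0, log_s0],
            args=(log_x, k, n, lapse),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    mu, log_sigma = best.x
    sigma = math.exp(log_sigma)
    q = (TARGET_P - GUESS_RATE) / (1.0 - GUESS_RATE - lapse / 2.0)
    threshold = math.exp(mu + sigma * stats.norm.ppf(q))
    converged = bool(best.success) and threshold <= MAX_OFFSET_ARCSEC
    if threshold > MAX_OFFSET_ARCSEC:
        threshold = MAX_OFFSET_ARCSEC
    return PsychometricFit(float(mu), float(sigma), float(threshold), converged, n_total)


def evidence_to_threshold(
    evidence: float,
    rng: np.random.Generator,
    alpha: float = math.log(900.0),
    beta: float = 3.0,
    sigma_log: float = 0.25,
    lapse: float = DEFAULT_LAPSE,
    n_blocks: int = 2,
    n_trials_per_block: int = 80,
) -> PsychometricFit:
    """Predicted threshold for a condition with the given model evidence.

    The link places the observer's psychometric location at
    mu_log = alpha - beta * evidence (beta > 0), so larger evidence means a
    lower threshold; the full pipeline simulates the staircase blocks and
    fits the psychometric function post hoc.
    """
    if beta < 0:
        raise ValueError("the evidence->threshold link must be non-increasing")
    observer = SimulatedObserver(alpha - beta * evidence, sigma_log, lapse)
    tables, state = [], None
    for b in range(n_blocks):
        table, state = simulate_block(observer, rng, n_trials_per_block, state)
        tables.append(table)
    import pandas as pd

    return fit_psychometric(pd.concat(tables, ignore_index=True), lapse)
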