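"""Runs-theory significance for contiguous detection failures.

If per-interval detection errors occur independently with probability
``p``, the expected frequency of a maximal run of exactly ``n``
successive failures at a given position is ``F = p**n * (1-p)**2`` (a
convenient approximation from the theory of runs; the two boundary
factors require the run to be delimited by successes).  Over ``N``
assayed intervals the expected number of such chance runs in one track
is ``E = N * F``.  A run is treated as evidence of a real deletion or
duplication when ``E`` falls below a significance threshold such as
0.05: fewer than one in twenty tracks would show such a run by chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RunStatParams",
    "run_frequency",
    "expected_runs",
    "min_significant_run",
    "estimate_p",
]

DEFAULT_ALPHA_LEVELS = (0.05, 0.01)


@dataclass(frozen=True)
class RunStatParams:
    """Chance-flag probability and track size for one line and flag mode."""

    p: float
    n_intervals: int
    alpha_levels: tuple[float, ...] = DEFAULT_ALPHA_LEVELS

    def __post_init__(self) -> None:
        if not 0 <= self.p < 1:
            raise ValueError(f"p must be in [0, 1), got {self.p}")
        if self.n_intervals < 1:
            raise ValueError("n_intervals must be >= 1")
        if any(not 0 < a < 1 for a in self.alpha_levels):
            raise ValueError("alpha levels must be in (0, 1)")


def _check_n(n) -> int:
    if n != int(n) or n < 1:
        raise ValueError(f"run length must be a positive integer, got {n!r}")
    return int(n)


def run_frequency(p: float, n: int) -> float:
    """Chance frequency of a maximal run of exactly ``n`` flags: p**n (1-p)**2."""
    n = _check_n(n)
    if not 0 <= p <= 1:
        raise ValueError(f"p must be in [0, 1], got {p}")
    return p**n * (1 - p) ** 2


def expected_runs(params: RunStatParams, n: int) -> float:
    """Expected number of chance maximal runs of length ``n`` in one track."""
    return params.n_intervals * run_frequency(params.p, n)


def min_significant_run(params: RunStatParams, alpha: float) -> int:
    """Smallest run length whose chance expectation is <= ``alpha``.

    This is the method's detection floor in intervals: shorter runs are
    indistinguishable from random error.  With ``p = 0`` a single flag
    suffices.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if params.p == 0:
        return 1
    for n in range(1, params.n_intervals + 1):
        if expected_runs(params, n) <= alpha:
            return n
    raise ValueError(
        f"no run length up to N={params.n_intervals} reaches "
        f"significance at alpha={alpha} with p={params.p}"
    )


def estimate_p(flag_track: np.ndarray, accepted_runs=()) -> float:
    """Per-interval error rate from flags outside accepted runs.

    Errors are assumed uniform over the track, so the rate is estimated
    from intervals not covered by an accepted (believed-real) run:
    ``p = flags outside accepted runs / intervals outside accepted
    runs``.  ``accepted_runs`` are ``(start, stop)`` half-open index
    spans into the track.
    """
    flags = np.asarray(flag_track, dtype=bool)
    if flags.ndim != 1 or flags.size == 0:
        raise ValueError("flag_track must be a non-empty 1-D boolean vector")
    outside = np.ones(flags.size, dtype=bool)
    for start, stop in accepted_runs:
        outside[int(start): int(stop)] = False
    denom = int(outside.sum())
    if denom == 0:
        raise ValueError("accepted runs cover the whole track; p is undefined")
    return float(flags[outside].sum() / denom)
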