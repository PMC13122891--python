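"""Population-level arithmetic: genome saturation and detection limits.

If each screened family deletes, on average, a fraction ``f`` of the
genome and deletions are placed independently and uniformly, the chance
that a given locus is deleted in at least one of ``M`` families is
``P = 1 - (1 - f)**M``.  The screen's detection floor in bp is the
minimum significant run length from the runs model times the window
size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .runs import RunStatParams, min_significant_run

__all__ = [
    "SaturationModel",
    "per_family_fraction",
    "hit_probability",
    "families_needed",
    "detection_limit_bp",
    "detection_rate",
]


def per_family_fraction(deleted_bp: float, genome_bp: float, n_families: int) -> float:
    """Average deleted genome fraction per screened family."""
    if deleted_bp < 0 or genome_bp <= 0 or n_families <= 0:
        raise ValueError("inputs must be positive (deleted_bp may be zero)")
    if deleted_bp > genome_bp * n_families:
        raise ValueError("deleted_bp exceeds genome_bp * n_families")
    return deleted_bp / (genome_bp * n_families)


def hit_probability(f: float, M: int) -> float:
    """P(locus deleted in >= 1 of M families) = 1 - (1 - f)**M."""
    if not 0 <= f <= 1:
        raise ValueError(f"f must be in [0, 1], got {f}")
    if M < 1:
        raise ValueError("M must be >= 1")
    return 1.0 - (1.0 - f) ** M


def families_needed(f: float, target_P: float) -> int:
    """Smallest M with hit_probability(f, M) >= target_P."""
    if not 0 < f < 1:
        raise ValueError(f"f must be in (0, 1), got {f}")
    if not 0 < target_P < 1:
        raise ValueError(f"target_P must be in (0, 1), got {target_P}")
    m = max(1, int(math.ceil(math.log(1.0 - target_P) / math.log(1.0 - f))))
    # the closed form can land one off at floating-point boundaries
    while hit_probability(f, m) < target_P:
        m += 1
    while m > 1 and hit_probability(f, m - 1) >= target_P:
        m -= 1
    return m


def detection_limit_bp(params: RunStatParams, alpha: float, window_size: int = 10_000) -> int:
    """Minimum reliably detectable event size: n_min windows * window size."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    return min_significant_run(params, alpha) * window_size


def detection_rate(n_detected: int, n_total: int) -> float:
    """Fraction of confirmed mutant lineages in which a deletion was found."""
    if n_total <= 0 or not 0 <= n_detected <= n_total:
        raise ValueError("need 0 <= n_detected <= n_total with n_total > 0")
    return n_detected / n_total


@dataclass
class SaturationModel:
    """Hit-probability arithmetic for a mutagenized population.

    ``deleted_bp`` is the union of unique deleted sequence over the
    ``n_families`` screened; ``M`` is the size of the full population
    the screen extrapolates to.  The model assumes deletions are placed
    independently and uniformly across families.
    """

    deleted_bp: float
    genome_bp: float
    n_families: int
    M: int

    @property
    def f(self) -> float:
        return per_family_fraction(self.deleted_bp, self.genome_bp, self.n_families)

    @property
    def screened_fraction(self) -> float:
        """Fraction of the genome covered by deletions in the screened sample."""
        return min(1.0, self.deleted_bp / self.genome_bp)

    def hit_probability(self) -> float:
        return hit_probability(self.f, self.M)

    def report(self) -> dict:
        p = self.hit_probability()
        return {
            "deleted_bp": self.deleted_bp,
            "genome_bp": self.genome_bp,
            "n_families_screened": self.n_families,
            "screened_genome_fraction": self.screened_fraction,
            "per_family_fraction": self.f,
            "population_families": self.M,
            "hit_probability": p,
            "hit_probability_percent": round(100.0 * p),
            "assumes": "independent uniform deletion placement across families",
        }
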