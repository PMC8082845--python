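"""Crossover-rate arithmetic conditioned on karyotype structure.

Acrocentric autosomes are effectively single-armed, so under the
one-obligatory-crossover-per-arm model the minimum crossover count per
cell depends on how many autosomes are acrocentric.  The rat karyotype
(20 autosomes, 8 acrocentric) and the mouse karyotype (19 autosomes, all
acrocentric) are provided as constants.  Sex chromosomes are excluded
throughout: rates concern autosomal crossover nodules.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import UndefinedFractionError

__all__ = [
    "Karyotype",
    "RAT_KARYOTYPE",
    "MOUSE_KARYOTYPE",
    "per_autosome_rate",
    "min_crossovers_per_cell",
]


@dataclass(frozen=True)
class Karyotype:
    n_autosomes: int
    n_acrocentric: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_acrocentric <= self.n_autosomes:
            raise ValueError(
                f"need 0 <= acrocentric ({self.n_acrocentric}) "
                f"<= autosomes ({self.n_autosomes})"
            )

    @property
    def n_arms(self) -> int:
        """Acrocentric autosomes contribute one arm, metacentric two."""
        return self.n_acrocentric + 2 * (self.n_autosomes - self.n_acrocentric)


RAT_KARYOTYPE = Karyotype(n_autosomes=20, n_acrocentric=8)
MOUSE_KARYOTYPE = Karyotype(n_autosomes=19, n_acrocentric=19)


def per_autosome_rate(mean_nodules_per_cell: float, k: Karyotype) -> float:
    """Mean crossover nodules per autosome (e.g. 27.4 / 20 = 1.37)."""
    if k.n_autosomes == 0:
        raise UndefinedFractionError("karyotype with zero autosomes")
    if mean_nodules_per_cell < 0:
        raise ValueError("negative nodule count")
    return mean_nodules_per_cell / k.n_autosomes


def min_crossovers_per_cell(k: Karyotype, per_arm_minimum: int = 1) -> int:
    """Minimum nodules per cell under an obligatory per-arm crossover."""
    if per_arm_minimum < 0:
        raise ValueError("per_arm_minimum must be >= 0")
    return per_arm_minimum * k.n_arms
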