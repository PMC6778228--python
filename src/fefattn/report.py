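"""Report formatting and derived summary quantities."""

from __future__ import annotations


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Cell-count percentage as printed in reports, e.g. 68/86 -> 79.1."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0 or numerator > denominator:
        raise ValueError("numerator must be in [0, denominator]")
    return round(100.0 * numerator / denominator, decimals)


def chance_hit_rate(n_dimming_epochs: int = 3, decimals: int = 2) -> float:
    """Chance probability of responding at the correct dimming epoch when
    guessing uniformly among the epochs (3 epochs -> 0.33)."""
    if n_dimming_epochs < 1:
        raise ValueError("need >= 1 dimming epoch")
    return round(1.0 / n_dimming_epochs, decimals)


def joint_fraction_percent(p_a: float, p_b: float, decimals: int = 2) -> float:
    """Expected percentage of a population in the intersection of two
    independent subclasses, e.g. 25% inhibitory x 25% PV -> 6.25%."""
    if not (0 <= p_a <= 1 and 0 <= p_b <= 1):
        raise ValueError("proportions must be in [0, 1]")
    return round(100.0 * p_a * p_b, decimals)
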