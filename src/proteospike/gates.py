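"""Boolean-gate characterization of the per-character response table.

Mean amplitudes and mean periods are min-max normalized to [0, 1] across the
26 characters, then thresholded (strict inequalities) at T_A and T_P:

    AND_i  = (A_i > T_A) and (P_i > T_P)
    OR_i   = (A_i > T_A) or  (P_i > T_P)
    NOT_i  = (A_i < T_A) or  (P_i < T_P)     (combined, see below)
    NAND_i = not AND_i
    NOR_i  = not OR_i

The characterization defines separate NOT gates for amplitude and period but
reports a single NOT row satisfied by all 26 characters ("small magnitude or
brief duration"); the disjunctive combination with the default thresholds
T_A = T_P = 1.0 reproduces that row exactly, whereas a conjunction would
exclude the characters whose normalized amplitude or period is exactly 1.
``not_mode="both"`` switches to the conjunction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import LABELS, ProfileTable

__all__ = ["GATES", "GateTable", "min_max_normalize", "evaluate_gates", "gates_from_profiles"]

GATES = ("AND", "OR", "NOT", "NAND", "NOR")


@dataclass(frozen=True)
class GateTable:
    """Per-gate boolean vectors over the 26 characters."""

    t_amplitude: float
    t_period: float
    vectors: dict[str, np.ndarray]
    labels: tuple[str, ...] = LABELS

    def count(self, gate: str) -> int:
        return int(self.vectors[gate].sum())

    @property
    def counts(self) -> dict[str, int]:
        return {g: self.count(g) for g in GATES}

    def characters(self, gate: str) -> list[str]:
        return [lab for lab, on in zip(self.labels, self.vectors[gate]) if on]


def min_max_normalize(values) -> np.ndarray:
    """Affine rescale so the minimum maps to 0 and the maximum to 1."""
    x = np.asarray(values, float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("degenerate range: all values are equal")
    return (x - lo) / (hi - lo)


def evaluate_gates(
    amplitude_norm,
    period_norm,
    t_amplitude: float = 1.0,
    t_period: float = 1.0,
    not_mode: str = "either",
) -> GateTable:
    """Evaluate the five gates on normalized amplitude/period vectors."""
    a = np.asarray(amplitude_norm, float)
    p = np.asarray(period_norm, float)
    if a.shape != p.shape or a.shape != (len(LABELS),):
        raise ValueError(
            f"expected two vectors of length {len(LABELS)}, got {a.shape} and {p.shape}"
        )
    if not_mode not in ("either", "both"):
        raise ValueError(f"not_mode must be 'either' or 'both', got {not_mode!r}")
    gate_and = (a > t_amplitude) & (p > t_period)
    gate_or = (a > t_amplitude) | (p > t_period)
    not_a, not_p = a < t_amplitude, p < t_period
    gate_not = (not_a | not_p) if not_mode == "either" else (not_a & not_p)
    vectors = {
        "AND": gate_and,
        "OR": gate_or,
        "NOT": gate_not,
        "NAND": ~gate_and,
        "NOR": ~gate_or,
    }
    return GateTable(t_amplitude=t_amplitude, t_period=t_period, vectors=vectors)


def gates_from_profiles(
    profiles: ProfileTable,
    t_amplitude: float = 1.0,
    t_period: float = 1.0,
    not_mode: str = "either",
) -> GateTable:
    """Normalize a profile table's mean amplitudes/periods and evaluate gates."""
    return evaluate_gates(
        min_max_normalize(profiles.amplitude_means()),
        min_max_normalize(profiles.period_means()),
        t_amplitude=t_amplitude,
        t_period=t_period,
        not_mode=not_mode,
    )
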