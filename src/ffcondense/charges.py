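"""Charge equilibration: partial charges from electronegativity and hardness.

Atomic charges minimize the second-order per-atom expansion of the
electrostatic energy, E(q) = sum_i (e_i q_i + s_i/2 q_i^2), subject to the
total-charge constraint sum_i q_i = Q.  Electronegativity e_i = dE/dq_i
quantifies an atom's appetite for negative charge; hardness s_i = d^2E/dq_i^2
its resistance to gaining or losing charge.  With all s_i > 0 the problem is
strictly convex and the Lagrange-multiplier solution is closed-form:

    q_i = (lambda - e_i) / s_i,
    lambda = (Q + sum_j e_j / s_j) / (sum_j 1 / s_j).

The e and s values are inputs (typically predicted upstream per atom);
this module does not predict them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ModelError

__all__ = ["ChargeModelInput", "equilibrate_charges"]


@dataclass
class ChargeModelInput:
    """Per-atom electronegativity e (kJ mol^-1 e^-1), hardness s
    (kJ mol^-1 e^-2) and total molecular charge Q (e)."""

    e: np.ndarray
    s: np.ndarray
    Q: float = 0.0

    def __post_init__(self) -> None:
        self.e = np.asarray(self.e, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.e.shape != self.s.shape or self.e.ndim != 1 or self.e.size == 0:
            raise ModelError("e and s must be equal-length 1-D arrays")
        if not (np.all(np.isfinite(self.e)) and np.all(np.isfinite(self.s))):
            raise ModelError("e and s must be finite")
        if np.any(self.s <= 0.0):
            raise ModelError("hardness must be strictly positive (convexity)")


def equilibrate_charges(inp: ChargeModelInput) -> np.ndarray:
    """Closed-form constrained minimizer; returns per-atom charges (e) with
    sum(q) = Q to machine precision."""
    inv_s = 1.0 / inp.s
    lam = (inp.Q + float(np.sum(inp.e * inv_s))) / float(np.sum(inv_s))
    q = (lam - inp.e) * inv_s
    # absorb the last rounding crumb so the constraint holds exactly
    q[-1] += inp.Q - float(np.sum(q))
    return q
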