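"""Conformer geometry optimization on the molecular potential energy surface.

L-BFGS is the workhorse; if it terminates without meeting the gradient
tolerance (line-search failure or iteration cap), BFGS is restarted from the
best point seen so far and the result is flagged ``bfgs_fallback``.  The
optimizer is deterministic: a fixed input produces an identical iterate
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .energy import ParameterSet, analytic_gradient, total_energy
from .errors import ModelError
from .topology import Conformer, InternalCoordinateIndex

__all__ = ["OptimizeOptions", "OptimizationResult", "minimize"]


@dataclass
class OptimizeOptions:
    """Convergence: gradient infinity-norm <= gtol (kJ mol^-1 A^-1) or
    relative energy change <= ftol_rel; at most maxiter iterations."""

    gtol: float = 1e-5
    ftol_rel: float = 1e-10
    maxiter: int = 2000
    lbfgs_memory: int = 10
    trace: bool = False


@dataclass
class OptimizationResult:
    conformer: Conformer
    energy: float
    iterations: int
    converged: bool
    algorithm: str  # "lbfgs" or "bfgs_fallback"
    grad_inf_norm: float
    energy_trace: list[float] = field(default_factory=list)


def minimize(
    conf0: Conformer,
    ps: ParameterSet,
    internals: InternalCoordinateIndex,
    opts: OptimizeOptions | None = None,
) -> OptimizationResult:
    """Minimize the total energy over Cartesian coordinates.

    The final energy never exceeds the initial one (the best-seen point is
    returned even on failure); an unconverged run returns a flagged result
    rather than raising.
    """
    if opts is None:
        opts = OptimizeOptions()
    n = conf0.n_atoms
    x0 = conf0.coords.ravel().copy()

    best = {"e": np.inf, "x": x0.copy()}

    def fun(x):
        c = Conformer(x.reshape(n, 3))
        e, _ = total_energy(c, ps, internals)
        g = analytic_gradient(c, ps, internals)
        if e < best["e"]:
            best["e"] = e
            best["x"] = x.copy()
        return e, g.ravel()

    e0, _ = fun(x0)
    if not np.isfinite(e0):
        raise ModelError("non-finite energy at the starting conformer")

    trace: list[float] = [e0] if opts.trace else []

    def callback(xk):
        if opts.trace:
            c = Conformer(xk.reshape(n, 3))
            e, _ = total_energy(c, ps, internals)
            trace.append(e)

    res = _scipy_minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        callback=callback if opts.trace else None,
        options={
            "maxiter": opts.maxiter,
            "maxcor": opts.lbfgs_memory,
            "ftol": opts.ftol_rel,
            "gtol": opts.gtol,
            "maxls": 50,
        },
    )
    algorithm = "lbfgs"
    x, e = res.x, float(res.fun)
    nit = int(res.nit)
    ginf = float(np.max(np.abs(fun(x)[1])))
    converged = _met(e, e0, ginf, opts)

    if not converged:
        # fallback: full-memory BFGS from the best point seen so far
        res2 = _scipy_minimize(
            fun,
            best["x"].copy(),
            jac=True,
            method="BFGS",
            callback=callback if opts.trace else None,
            options={"maxiter": opts.maxiter, "gtol": opts.gtol},
        )
        algorithm = "bfgs_fallback"
        x2, e2 = res2.x, float(res2.fun)
        if e2 <= e:
            x, e = x2, e2
        nit += int(res2.nit)
        ginf = float(np.max(np.abs(fun(x)[1])))
        converged = _met(e, e0, ginf, opts)

    if best["e"] < e:
        x, e = best["x"], best["e"]
        ginf = float(np.max(np.abs(fun(x)[1])))
        converged = _met(e, e0, ginf, opts)

    return OptimizationResult(
        conformer=Conformer(x.reshape(n, 3)),
        energy=e,
        iterations=nit,
        converged=converged,
        algorithm=algorithm,
        grad_inf_norm=ginf,
        energy_trace=trace,
    )


def _met(e: float, e0: float, ginf: float, opts: OptimizeOptions) -> bool:
    # converged means the gradient tolerance is met; ftol_rel only controls
    # when the line search gives up, so a flat-but-steep endpoint is not
    # reported as converged
    return ginf <= opts.gtol
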