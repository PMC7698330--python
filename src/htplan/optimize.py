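"""Excitation optimization: maximize the tumor-to-healthy SAR ratio.

The objective SARvol(tumor)/SARvol(healthy) is a generalized Rayleigh
quotient A^H H_t A / A^H H_h A in the complex excitation vector, so the
exact maximizer is the principal generalized eigenvector of (H_t, H_h) and
the maximal ratio is the principal generalized eigenvalue.  The ratio is
invariant to a global amplitude scale and a global phase, so the solution
is reported with the total power rescaled to the prescribed budget and the
last antenna's phase gauged to zero.  A seeded derivative-free global
search over (P, ϕ) cross-checks that no better feasible excitation exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .sar import ExcitationVector, SarQuadraticForm, sar_vol

__all__ = [
    "OptimizationProblem",
    "sar_ratio",
    "optimal_excitation",
    "stochastic_refine",
]


@dataclass
class OptimizationProblem:
    """Tumor/healthy SAR quadratic forms plus the power constraint."""

    H_tumor: SarQuadraticForm
    H_healthy: SarQuadraticForm
    total_power: float = 8.0
    regularization: float = 1e-12
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.H_tumor.n_antennas != self.H_healthy.n_antennas:
            raise ValueError("form sizes differ")
        if not self.total_power > 0:
            raise ValueError("total_power must be positive")

    @property
    def n_antennas(self) -> int:
        return self.H_tumor.n_antennas


def sar_ratio(excitation: ExcitationVector, problem: OptimizationProblem) -> float:
    """SARvol(tumor) / SARvol(healthy) for one excitation (dimensionless)."""
    den = sar_vol(problem.H_healthy, excitation)
    if den == 0:
        raise ZeroDivisionError("zero healthy-region SAR in ratio")
    return sar_vol(problem.H_tumor, excitation) / den


def _to_excitation(A: np.ndarray, total_power: float) -> ExcitationVector:
    A = np.asarray(A, dtype=complex)
    p = np.abs(A) ** 2
    s = p.sum()
    if s == 0:
        raise ValueError("zero excitation")
    A = A * np.sqrt(total_power / s)
    return ExcitationVector.from_amplitudes(A, reference_last=True)


def optimal_excitation(
    problem: OptimizationProblem,
) -> tuple[ExcitationVector, float]:
    """Exact maximizer of the SAR ratio under the total-power budget.

    Solves the Hermitian generalized eigenproblem H_t v = λ H_h v; the
    principal eigenvector, rescaled to Σ P_i = total_power and phase-gauged
    to the last antenna, is the optimal excitation and λ_max the achieved
    ratio.  A singular healthy-region form is ridge-regularized (scaled by
    its largest diagonal entry) before failing.
    """
    Ht = problem.H_tumor.H
    Hh = problem.H_healthy.H
    try:
        w, v = linalg.eigh(Ht, Hh)
    except linalg.LinAlgError:
        ridge = problem.regularization * max(np.abs(np.diag(Hh)).max(), 1e-300)
        try:
            w, v = linalg.eigh(Ht, Hh + ridge * np.eye(Hh.shape[0]))
        except linalg.LinAlgError as exc:
            raise linalg.LinAlgError(
                "healthy-region form is singular even after regularization"
            ) from exc
    A = v[:, np.argmax(w)]
    exc = _to_excitation(A, problem.total_power)
    return exc, sar_ratio(exc, problem)


def stochastic_refine(
    problem: OptimizationProblem,
    start: ExcitationVector,
    seed: int = 0,
    maxiter: int = 150,
    popsize: int = 16,
) -> tuple[ExcitationVector, float]:
    """Seeded derivative-free search over powers and phases.

    Differential evolution over (P_1..P_N, ϕ_1..ϕ_{N-1}) with the last
    phase gauged to zero; the power budget is enforced by rescaling (the
    ratio is scale-invariant, so this loses nothing).  Returns whichever of
    the refined point and ``start`` scores better — never worse than the
    start.
    """
    n = problem.n_antennas
    start_ratio = sar_ratio(start, problem)

    def unpack(x):
        p = np.clip(x[:n], 0.0, None)
        ph = np.concatenate([x[n:], [0.0]])
        if p.sum() == 0:
            p = np.ones(n)
        A = np.sqrt(p) * np.exp(1j * np.deg2rad(ph))
        return A

    def neg_ratio(x):
        A = unpack(x)
        den = np.real(A.conj() @ problem.H_healthy.H @ A)
        if den <= 0:
            return np.inf
        return -np.real(A.conj() @ problem.H_tumor.H @ A) / den

    bounds = [(0.0, problem.total_power)] * n + [(-180.0, 180.0)] * (n - 1)
    x0 = np.concatenate([np.asarray(start.powers),
                         np.asarray(start.phases_deg[:-1])])
    res = optimize.differential_evolution(
        neg_ratio,
        bounds,
        x0=x0,
        seed=seed,
        maxiter=maxiter,
        popsize=popsize,
        tol=1e-10,
        polish=True,
    )
    cand = _to_excitation(unpack(res.x), problem.total_power)
    cand_ratio = sar_ratio(cand, problem)
    if cand_ratio > start_ratio:
        return cand, cand_ratio
    return start, start_ratio
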