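"""Equilibrium theory of linked purifying selection.

This module implements the quantitative-genetic view of background
selection due to Santiago & Caballero (SC16): polygenic additive fitness
variance ``V_A`` spread along the genome inflates the variance of
stochastic allele-frequency change, reducing the *fitness-effective*
population size ``N_f`` below the drift-effective size ``N``.  For a
conserved segment receiving deleterious mutations at diploid rate
``U = 2*mu*L`` with heterozygous cost ``s`` (``2s`` in homozygotes,
multiplicative across sites), the equilibrium is the joint solution of

    N_f = N * exp(-V_A * Q^2 / 2)                 (population size)
    R   = 2*N_f*U*s / (exp(4*N_f*s) - 1)          (substitution rate)
    V_A = (U - 2*R) * s                           (fitness variance)

where ``Q^2`` is the cumulative autocorrelation ("inflation") factor of
the fitness background a neutral allele is linked to, and ``R`` is the
per-lineage substitution rate (neutral limit ``U/2``, i.e. Kimura's
fixation probability times the ``N*U`` new mutations per generation), so
``V_A >= 0`` holds for every deleterious mutation.  Classic background
selection is the strong-selection special case ``R = 0``.

All selection coefficients are stored positive (the heterozygote cost);
all ``exp(x)-1`` expressions go through ``expm1`` and reduction-map
exponents are handled in log space.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SegmentSelectionInput",
    "PopulationContext",
    "Equilibrium",
    "GridAxes",
    "q_flank",
    "q2_segment",
    "fixation_rate",
    "lineage_fixation_rate",
    "va_equilibrium",
    "classic_b_exponent",
    "solve_equilibrium",
    "solve_equilibrium_grid",
    "solve_rescaled_equilibrium",
]


class TheoryDomainError(ValueError):
    """Raised when inputs leave the domain of validity of a formula."""


class ConvergenceError(RuntimeError):
    """Solver failed to converge; carries the last iterate and residual."""

    def __init__(self, message, last=None, residual=None):
        super().__init__(message)
        self.last = last
        self.residual = residual


@dataclass(frozen=True)
class SegmentSelectionInput:
    """Selection regime of one conserved segment.

    Parameters
    ----------
    U : float
        Diploid deleterious mutation rate per generation for the whole
        segment, ``U = 2*mu*L`` (dimensionless, per generation).
    s : float
        Heterozygous selection cost per mutation (positive = deleterious).
    M : float
        Total internal map length of the segment in Morgans,
        ``M = r_bp * L``.
    L : int
        Segment length in basepairs.
    mu : float
        Per-basepair per-generation deleterious mutation rate.
    """

    U: float
    s: float
    M: float
    L: int
    mu: float

    def __post_init__(self):
        if self.U < 0:
            raise ValueError(f"U must be >= 0, got {self.U}")
        if not 0 <= self.s <= 1:
            raise ValueError(f"s must be in [0, 1], got {self.s}")
        if self.M < 0:
            raise ValueError(f"M must be >= 0, got {self.M}")
        if self.L < 1:
            raise ValueError(f"L must be >= 1, got {self.L}")
        if not math.isclose(self.U, 2.0 * self.mu * self.L, rel_tol=1e-6, abs_tol=1e-300):
            raise ValueError(
                f"U = 2*mu*L violated: U={self.U}, 2*mu*L={2 * self.mu * self.L}"
            )

    @classmethod
    def from_rates(cls, mu: float, s: float, L: int, r_bp: float = 0.0) -> "SegmentSelectionInput":
        return cls(U=2.0 * mu * L, s=s, M=r_bp * L, L=L, mu=mu)


@dataclass(frozen=True)
class PopulationContext:
    """Drift-effective population size, with optional local rescaling.

    ``rescale`` multiplies ``N`` (local fitness-effective size ``B(x)*N``)
    when re-solving equilibria under the selective-interference
    approximation.
    """

    N: float
    rescale: float = 1.0

    def __post_init__(self):
        if self.N < 2:
            raise ValueError(f"N must be >= 2, got {self.N}")
        if not 0 < self.rescale <= 1:
            raise ValueError(f"rescale must be in (0, 1], got {self.rescale}")

    @property
    def effective_N(self) -> float:
        return self.N * self.rescale


@dataclass(frozen=True)
class Equilibrium:
    """Solved segment equilibrium: (N_f, R, V_A).

    ``R`` is the per-lineage substitution rate (neutral limit ``U/2``);
    downstream reporting always uses the fraction ``R / (U/2)`` of the
    neutral rate, which is invariant to the rate convention.
    """

    Nf: float
    R: float
    VA: float

    def rate_fraction(self, U: float) -> float:
        """R as a fraction of the neutral rate U/2 for the same segment."""
        return 1.0 if U == 0 else self.R / (0.5 * U)


@dataclass(frozen=True)
class GridAxes:
    """Log10-spaced grids of selection coefficients and per-bp mutation rates."""

    s_values: np.ndarray
    m_values: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.s_values, dtype=float)
        m = np.asarray(self.m_values, dtype=float)
        if s.ndim != 1 or m.ndim != 1:
            raise ValueError("grid axes must be 1-D")
        if not (np.all(np.diff(s) > 0) and np.all(np.diff(m) > 0)):
            raise ValueError("grid axes must be strictly increasing")
        object.__setattr__(self, "s_values", s)
        object.__setattr__(self, "m_values", m)

    @classmethod
    def default(cls) -> "GridAxes":
        """Default grid: s in 10^-8..10^-2, m in 10^-11..10^-7 (decades)."""
        return cls(np.logspace(-8, -2, 7), np.logspace(-11, -7, 5))

    @classmethod
    def strong(cls) -> "GridAxes":
        """Strong-selection grid extending up to s = 10^-1."""
        return cls(np.logspace(-8, -1, 8), np.logspace(-11, -7, 5))

    @property
    def shape(self):
        return (len(self.m_values), len(self.s_values))


def q_flank(kappa, r):
    """Cumulative autocorrelation multiplier for a flanking neutral site.

    ``Q = 1 + sum_{t>=1} [(1-r)(1-kappa)]^t = 1 / (kappa + r*(1-kappa))``
    where ``kappa`` is the per-generation decay rate of the associated
    fitness variance and ``r`` the recombination fraction to the segment.
    ``Q >= 1``, with equality iff ``kappa = 1``.
    """
    kappa = np.asarray(kappa, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(kappa < 0) or np.any(kappa > 1):
        raise TheoryDomainError("kappa must be in (0, 1]")
    if np.any(r < 0) or np.any(r > 0.5):
        raise TheoryDomainError("r must be in [0, 0.5]")
    denom = kappa + r * (1.0 - kappa)
    if np.any(denom <= 0):
        raise TheoryDomainError(
            "divergent autocorrelation series: kappa = 0 with r = 0"
        )
    out = 1.0 / denom
    return float(out) if out.ndim == 0 else out


def _decay_z(s, M, drift=0.0):
    # Within-segment retention factor: associated variance decays each
    # generation by selection (s), internal recombination (M), and -- when
    # a population size is in play -- pair coalescence (1/(2N)), which
    # truncates the autocorrelation sum at the coalescent time scale.
    return 1.0 - s - M - drift


def q2_segment(seg: SegmentSelectionInput, drift: float = 0.0) -> float:
    """Within-segment inflation factor ``Q^2``.

    ``Q^2 = 2 / [(1-Z)(2-(2-M)Z)]`` with retention ``Z = 1 - s - M``
    (minus an optional coalescent-decay term ``drift = 1/(2N)``, used by
    the equilibrium solver so the neutral limit ``N_f -> N`` holds even
    at ``M = 0``).  With ``drift = 0`` and ``M = 0`` this reduces to
    ``1/s^2 = q_flank(s, 0)**2``.
    """
    Z = _decay_z(seg.s, seg.M, drift)
    if Z >= 1.0:
        raise TheoryDomainError(
            f"degenerate decay Z={Z} >= 1 for (U={seg.U}, s={seg.s}, M={seg.M})"
        )
    denom = (1.0 - Z) * (2.0 - (2.0 - seg.M) * Z)
    if denom <= 0:
        raise TheoryDomainError(
            f"non-positive Q^2 denominator for (U={seg.U}, s={seg.s}, M={seg.M})"
        )
    return 2.0 / denom


# exp argument beyond which 4*Nf*U*s/expm1(4*Nf*s) underflows to 0
_EXP_OVERFLOW = 700.0


def fixation_rate(Nf, U, s):
    """Deleterious substitution rate ``R = 4*Nf*U*s / (exp(4*Nf*s) - 1)``.

    Continuous at ``s = 0`` via the limit ``R -> U`` (Kimura's fixation
    probability at neutrality); strictly decreasing in ``s``; overflow of
    the exponential returns 0 (the ratio underflows), never NaN.
    """
    Nf = np.asarray(Nf, dtype=float)
    U = np.asarray(U, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(Nf <= 0) or np.any(U < 0) or np.any(s < 0):
        raise TheoryDomainError("require Nf > 0, U >= 0, s >= 0")
    x = 4.0 * Nf * s
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        out = np.where(
            x == 0.0,
            U,
            np.where(
                x > _EXP_OVERFLOW,
                0.0,
                U * x / np.expm1(np.minimum(x, _EXP_OVERFLOW)),
            ),
        )
    return float(out) if out.ndim == 0 else out


def va_equilibrium(U, R, s, warn: bool = True, rtol: float = 1e-9):
    """Equilibrium additive fitness variance ``V_A = (U - 2R) * s``, floored at 0.

    ``R > U/2`` violates the deleterious-fixation convention (fixation
    probability above neutral); such values are clamped to 0 with a
    warning when beyond tolerance.
    """
    U = np.asarray(U, dtype=float)
    R = np.asarray(R, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(U < 0) or np.any(s < 0) or np.any(R < 0):
        raise TheoryDomainError("require U >= 0, s >= 0, R >= 0")
    va = (U - 2.0 * R) * s
    if warn and np.any(va < -rtol * np.maximum(U * s, 1e-300)):
        warnings.warn(
            "R > U/2: fixation rate above the deleterious convention; "
            "V_A clamped to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    out = np.maximum(va, 0.0)
    return float(out) if out.ndim == 0 else out


def classic_b_exponent(mu, L, s, r):
    """Classic-BGS contribution of one segment to ``-log B``.

    ``mu*L*s / (s + r*(1-s))^2``, the mutation-selection-balance special
    case (``R = 0``): identical to ``0.5 * (2*mu*L*s) * q_flank(s, r)**2``.
    """
    mu = np.asarray(mu, dtype=float)
    L = np.asarray(L, dtype=float)
    s = np.asarray(s, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(s <= 0):
        raise TheoryDomainError("classic model undefined at s = 0")
    if np.any(r < 0) or np.any(r > 0.5):
        raise TheoryDomainError("r must be in [0, 0.5]")
    out = mu * L * s / (s + r * (1.0 - s)) ** 2
    return float(out) if out.ndim == 0 else out


def lineage_fixation_rate(Nf, U, s):
    """Per-lineage deleterious substitution rate, ``fixation_rate / 2``.

    With the diploid segment rate ``U = 2*mu*L``, the population sees
    ``N*U`` new mutations per generation; Kimura's fixation probability
    for a heterozygous cost ``s`` gives ``R = 2*Nf*U*s / (exp(4*Nf*s)-1)``
    with neutral limit ``U/2 = mu*L`` (one genome copy's mutation rate).
    This is the rate that balances the fitness-variance equation:
    ``R <= U/2`` always, so ``V_A = (U - 2R)s >= 0`` for every
    deleterious mutation, and its weak-selection limit recovers the
    neutral drift genic variance ``2*N*U*s^2``.
    """
    return 0.5 * fixation_rate(Nf, U, s)


def _nf_update(Nf, N, U, s, Q2, va_form):
    """One substitution of the rate equation into the size equation.

    Scalar-math hot path: equivalent to composing
    ``lineage_fixation_rate`` and ``va_equilibrium`` but without array
    wrapping, since the solver calls it thousands of times per grid.
    """
    x = 4.0 * Nf * s
    if x == 0.0:
        R2 = U  # twice the per-lineage rate at neutrality (2R = U)
    elif x > _EXP_OVERFLOW:
        R2 = 0.0
    else:
        R2 = U * x / math.expm1(x)
    if va_form == "U-2R":
        va = max((U - R2) * s, 0.0)
    elif va_form == "U-R":
        va = max((U - 0.5 * R2) * s, 0.0)
    else:  # pragma: no cover - guarded upstream
        raise ValueError(f"unknown va_form {va_form!r}")
    # exponent is bounded: va*Q2/2 <= U*s*Q2/2
    return N * math.exp(-0.5 * va * Q2)


def solve_equilibrium(
    seg: SegmentSelectionInput,
    pop: PopulationContext,
    tol: float = 1e-10,
    max_iter: int = 500,
    va_form: str = "U-2R",
    method: str = "auto",
) -> Equilibrium:
    """Jointly solve the fitness-effective size / substitution rate system.

    After substituting the substitution-rate equation into the size
    equation the system is one-dimensional in ``N_f``; the right-hand side
    is non-increasing in ``N_f`` so the fixed point is unique.  A damped
    fixed-point iteration is tried first, with a guaranteed fallback to
    bracketed root-finding on ``log N_f`` in ``[log 1, log N]``.

    Parameters
    ----------
    va_form : {"U-2R", "U-R"}
        Variance law used in the exponent.  ``"U-2R"`` is the equilibrium
        fitness-variance equation the maps are built from; ``"U-R"`` is
        the alternative form exposed for comparison.
    method : {"auto", "fixed-point", "bisect"}
        ``auto`` tries fixed-point and falls back to bracketing on
        oscillation or non-convergence.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    N = pop.effective_N
    U, s = seg.U, seg.s
    Q2 = q2_segment(seg, drift=1.0 / (2.0 * N))

    def finish(Nf):
        R = lineage_fixation_rate(Nf, U, s)
        if va_form == "U-2R":
            va = va_equilibrium(U, R, s, warn=False)
        else:
            va = max((U - R) * s, 0.0)
        return Equilibrium(Nf=float(Nf), R=float(R), VA=float(va))

    if s == 0 or U == 0:
        return finish(N)

    if method in ("auto", "fixed-point"):
        Nf = N
        damp = 0.5
        prev_delta = None
        for _ in range(max_iter):
            target = _nf_update(Nf, N, U, s, Q2, va_form)
            new = damp * Nf + (1.0 - damp) * target
            delta = abs(new - Nf) / N
            if prev_delta is not None and delta > prev_delta * 1.5:
                break  # oscillation: fall back to bracketing
            prev_delta = delta
            Nf = new
            if delta < tol:
                return finish(Nf)
        if method == "fixed-point":
            raise ConvergenceError(
                f"fixed-point iteration did not converge after {max_iter} "
                "iterations; use bracketed bisection",
                last=Nf,
                residual=prev_delta,
            )

    # Bracketed root finding on x = log Nf: g(x) = x - log(rhs(e^x)).
    from scipy.optimize import brentq

    def g(x):
        return x - math.log(_nf_update(math.exp(x), N, U, s, Q2, va_form))

    lo, hi = math.log(1e-6), math.log(N)
    if g(hi) <= 0:  # rhs(N) >= N: no reduction at all
        return finish(N)
    x = brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=max_iter)
    return finish(math.exp(x))


def solve_equilibrium_grid(
    L: int,
    M: float,
    pop: PopulationContext,
    grid: GridAxes,
    tol: float = 1e-10,
    va_form: str = "U-2R",
):
    """Solve the segment equilibrium over an (m, s) grid.

    Returns three arrays ``(Nf, R, VA)`` of shape
    ``(len(m_values), len(s_values))``; cell ``(i, j)`` is solved with
    ``U = 2 * m_i * L`` and selection coefficient ``s_j``.
    """
    nm, ns = grid.shape
    Nf = np.empty((nm, ns))
    R = np.empty((nm, ns))
    VA = np.empty((nm, ns))
    for i, m in enumerate(grid.m_values):
        for j, s in enumerate(grid.s_values):
            seg = SegmentSelectionInput(U=2.0 * m * L, s=s, M=M, L=L, mu=m)
            try:
                eq = solve_equilibrium(seg, pop, tol=tol, va_form=va_form)
            except (TheoryDomainError, ConvergenceError) as err:
                raise type(err)(
                    f"grid cell (m={m:g}, s={s:g}): {err}"
                ) from err
            Nf[i, j] = eq.Nf
            R[i, j] = eq.R
            VA[i, j] = eq.VA
    return Nf, R, VA


def solve_rescaled_equilibrium(
    seg: SegmentSelectionInput,
    pop: PopulationContext,
    tol: float = 1e-8,
    max_rounds: int = 200,
    va_form: str = "U-2R",
) -> tuple:
    """Self-consistent locally rescaled equilibrium for one segment.

    Selective interference makes a segment experience a local
    fitness-effective population size ``B * N`` rather than ``N``; this
    iterates drift size ``N_k = B_k * N`` and reduction
    ``B_{k+1} = Nf(N_k) / N_k`` to a fixed point (damped).  Away from the
    nearly-neutral domain (2Ns ~ 1) the result coincides with
    :func:`solve_equilibrium`.  Returns ``(Equilibrium, B)`` with ``B``
    the reduction relative to the unrescaled neutral baseline.
    """
    B = 1.0
    eq = solve_equilibrium(seg, pop, va_form=va_form)
    for _ in range(max_rounds):
        p = PopulationContext(N=pop.N, rescale=min(1.0, pop.rescale * B))
        eq = solve_equilibrium(seg, p, va_form=va_form)
        B_new = eq.Nf / p.effective_N
        if abs(B_new - B) < tol:
            return eq, float(B_new)
        B = 0.5 * B + 0.5 * B_new
    return eq, float(B)
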