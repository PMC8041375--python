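"""Free-energy estimation from non-equilibrium work samples.

A single alchemical "leg" (e.g. mutating a residue in the folded protein)
yields two sets of work values: forward work for the WT→mutant
transformation and reverse work for the mutant→WT transformation, each
recorded as the work done on the system in that leg's own direction.
From these the free-energy difference ΔG of the transformation is
estimated by

* the Bennett acceptance ratio (BAR) — the statistically optimal two-sided
  estimator, solved here as a bracketed root of the self-consistency
  condition;
* the Crooks Gaussian intersection (CGI) — the crossing point of Normal
  densities fitted to the forward and negated-reverse work;
* the Jarzynski exponential average — a one-sided estimator used as a
  bracketing sanity check.

All energies are in kJ/mol; temperatures in kelvin.  Standard errors come
from a seeded bootstrap over work samples (:func:`bootstrap_error`).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

from .errors import EstimationError, OverlapError

__all__ = [
    "KB",
    "DEFAULT_TEMPERATURE",
    "FreeEnergyEstimate",
    "WorkSet",
    "estimate_bar",
    "estimate_cgi",
    "estimate_jarzynski",
    "bootstrap_error",
]

#: Boltzmann constant in kJ/(mol·K).
KB = 0.008314462618

#: Default simulation temperature in kelvin.
DEFAULT_TEMPERATURE = 298.15


@dataclass(frozen=True)
class FreeEnergyEstimate:
    """A free-energy value with a 1-standard-error uncertainty, in kJ/mol.

    ``method`` records how the value was obtained (``bar``, ``cgi``,
    ``jarzynski``, ``path``, ``propagated`` or ``input`` for externally
    supplied numbers).  ``offset_relative`` marks ΔΔG values computed
    without an unfolded-state leg: they share an unknown per-mutation
    constant that cancels in any nonadditivity.
    """

    value: float
    uncertainty: float = 0.0
    method: str = "input"
    offset_relative: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError(f"non-finite free energy value: {self.value}")
        if not (self.uncertainty >= 0.0):
            raise ValueError(f"uncertainty must be >= 0, got {self.uncertainty}")

    def __str__(self) -> str:
        return f"{self.value:.3f} ± {self.uncertainty:.3f} kJ/mol [{self.method}]"


class WorkSet:
    """Forward/reverse non-equilibrium work samples at a temperature.

    Parameters
    ----------
    forward_work
        Work values (kJ/mol) of the forward (WT→mutant) transformation.
    reverse_work
        Work values (kJ/mol) of the reverse (mutant→WT) transformation,
        stored as the work of that reverse process itself.  Estimators
        negate internally where needed.
    temperature
        Absolute temperature in kelvin; must be positive.
    """

    def __init__(self, forward_work=(), reverse_work=(), temperature: float = DEFAULT_TEMPERATURE):
        self.forward_work = np.atleast_1d(np.asarray(forward_work, dtype=float))
        self.reverse_work = np.atleast_1d(np.asarray(reverse_work, dtype=float))
        if self.forward_work.size == 0 and self.reverse_work.size == 0:
            raise ValueError("at least one direction must contain work samples")
        if not temperature > 0:
            raise ValueError(f"temperature must be positive, got {temperature}")
        if not (np.all(np.isfinite(self.forward_work)) and np.all(np.isfinite(self.reverse_work))):
            raise ValueError("work values must be finite")
        self.temperature = float(temperature)

    @property
    def kt(self) -> float:
        """Thermal energy kT in kJ/mol."""
        return KB * self.temperature

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/kT in mol/kJ."""
        return 1.0 / self.kt

    def swapped(self) -> "WorkSet":
        """Return the WorkSet with forward and reverse roles exchanged."""
        return WorkSet(self.reverse_work, self.forward_work, self.temperature)

    def __repr__(self) -> str:
        return (
            f"WorkSet(n_forward={self.forward_work.size}, "
            f"n_reverse={self.reverse_work.size}, T={self.temperature} K)"
        )


def _bar_value(forward: np.ndarray, reverse: np.ndarray, kt: float) -> float:
    """Solve the Bennett self-consistency condition for ΔG.

    Finds the ΔG at which

        Σ_f f(β(W_i − ΔG) + M)  =  Σ_r f(β(W'_j + ΔG) − M),

    with f the Fermi function 1/(1+e^x) and M = ln(n_f/n_r).  The
    left-hand side grows and the right-hand side falls monotonically in
    ΔG, so the root is unique; it is bracketed inside
    [min − 10σ, max + 10σ] of the pooled work values (forward and negated
    reverse) and refined to 1e-8 kJ/mol.
    """
    beta = 1.0 / kt
    n_f, n_r = forward.size, reverse.size
    m = np.log(n_f / n_r)

    def residual(dg: float) -> float:
        lhs = expit(-(beta * (forward - dg) + m)).sum()
        rhs = expit(-(beta * (reverse + dg) - m)).sum()
        return lhs - rhs

    neg_rev = -reverse
    # Disjoint supports leave the residual numerically flat in the gap, so a
    # root finder would "converge" to an arbitrary point; fail instead.
    if forward.min() > neg_rev.max() or neg_rev.min() > forward.max():
        raise OverlapError(
            "forward and negated-reverse work samples occupy disjoint ranges "
            f"([{forward.min():.3g}, {forward.max():.3g}] vs "
            f"[{neg_rev.min():.3g}, {neg_rev.max():.3g}] kJ/mol); "
            "BAR is undefined without overlap"
        )
    pooled = np.concatenate([forward, neg_rev])
    spread = pooled.std()
    pad = 10.0 * spread if spread > 0 else 1.0
    lo, hi = pooled.min() - pad, pooled.max() + pad
    if residual(lo) > 0 or residual(hi) < 0:
        raise OverlapError(
            "forward and reverse work distributions do not bracket a BAR root "
            f"within [{lo:.3g}, {hi:.3g}] kJ/mol (insufficient overlap)"
        )
    return float(brentq(residual, lo, hi, xtol=1e-8))


def _cgi_value(forward: np.ndarray, reverse: np.ndarray, kt: float) -> float:
    """Crossing point of Normal fits to forward and negated-reverse work.

    With equal fitted variances the crossing is the midpoint of the means;
    otherwise the quadratic from equating the two Normal log-densities is
    solved and the root lying between the means is returned.
    """
    neg_rev = -reverse
    mu1, s1 = forward.mean(), forward.std(ddof=1)
    mu2, s2 = neg_rev.mean(), neg_rev.std(ddof=1)

    if np.isclose(mu1, mu2, rtol=0.0, atol=1e-12):
        return float(0.5 * (mu1 + mu2))
    if np.isclose(s1, s2, rtol=1e-12, atol=1e-12):
        return float(0.5 * (mu1 + mu2))
    if s1 <= 0 or s2 <= 0:
        raise EstimationError(
            "CGI requires positive variance in both directions "
            f"(got sd_forward={s1:.4g}, sd_neg_reverse={s2:.4g})"
        )
    # (x-mu1)^2/s1^2 - (x-mu2)^2/s2^2 + 2 ln(s1/s2) = 0
    a = 1.0 / s1**2 - 1.0 / s2**2
    b = -2.0 * (mu1 / s1**2 - mu2 / s2**2)
    c = mu1**2 / s1**2 - mu2**2 / s2**2 + 2.0 * np.log(s1 / s2)
    roots = np.roots([a, b, c])
    real = roots[np.abs(roots.imag) < 1e-9].real
    lo, hi = sorted((mu1, mu2))
    tol = 1e-9 * (1.0 + hi - lo)
    inside = [r for r in real if lo - tol <= r <= hi + tol]
    if not inside:
        raise EstimationError(
            f"no Gaussian intersection between the fitted means "
            f"({mu1:.4g} and {mu2:.4g}; sds {s1:.4g}, {s2:.4g})"
        )
    mid = 0.5 * (mu1 + mu2)
    return float(min(inside, key=lambda r: abs(r - mid)))


def _jarzynski_value(work: np.ndarray, kt: float, direction: str) -> float:
    """One-sided exponential-average estimate, log-sum-exp stabilised.

    The forward estimate is −kT ln⟨e^{−βW}⟩ over forward work; for the
    reverse direction the same average over reverse work estimates the
    free energy of the reverse process, so its sign is flipped.
    """
    val = -kt * (logsumexp(-work / kt) - np.log(work.size))
    return float(val if direction == "forward" else -val)


_POINT_ESTIMATORS = {
    "bar": _bar_value,
    "cgi": _cgi_value,
    "jarzynski": lambda f, r, kt: _jarzynski_value(f, kt, "forward"),
    "jarzynski_forward": lambda f, r, kt: _jarzynski_value(f, kt, "forward"),
    "jarzynski_reverse": lambda f, r, kt: _jarzynski_value(r, kt, "reverse"),
}


def bootstrap_error(
    work: WorkSet,
    estimator: str = "bar",
    n_boot: int = 100,
    seed: int = 0,
) -> float:
    """Bootstrap standard error of a point estimator over work resamples.

    Each of the ``n_boot`` iterations draws, with replacement and
    independently within each non-empty direction, first a forward index
    vector then a reverse index vector from a PCG64 generator seeded with
    ``seed``, and re-evaluates the estimator.  The returned value is the
    sample standard deviation (n−1) of the successful re-estimates.

    Raises :class:`EstimationError` if the estimator fails on more than
    half of the resamples.
    """
    if n_boot < 2:
        raise ValueError(f"n_boot must be >= 2, got {n_boot}")
    try:
        point = _POINT_ESTIMATORS[estimator]
    except KeyError:
        raise ValueError(f"unknown estimator tag {estimator!r}") from None
    rng = np.random.default_rng(seed)
    fwd, rev, kt = work.forward_work, work.reverse_work, work.kt
    values = []
    failures = 0
    for _ in range(n_boot):
        f = fwd[rng.integers(0, fwd.size, fwd.size)] if fwd.size else fwd
        r = rev[rng.integers(0, rev.size, rev.size)] if rev.size else rev
        try:
            values.append(point(f, r, kt))
        except EstimationError:
            failures += 1
    if failures > n_boot // 2:
        raise EstimationError(
            f"estimator {estimator!r} failed on {failures}/{n_boot} bootstrap resamples"
        )
    return float(np.std(values, ddof=1))


def _require_samples(work: WorkSet, n_min: int, directions=("forward", "reverse")) -> None:
    counts = {"forward": work.forward_work.size, "reverse": work.reverse_work.size}
    for d in directions:
        if counts[d] < n_min:
            raise ValueError(f"need at least {n_min} {d} work samples, got {counts[d]}")


def estimate_bar(work: WorkSet, n_boot: int = 100, seed: int = 0) -> FreeEnergyEstimate:
    """Bennett-acceptance-ratio estimate of ΔG from a WorkSet.

    Requires at least two samples in each direction.  The uncertainty is
    the bootstrap standard error (``n_boot`` resamples); pass ``n_boot=0``
    to skip the bootstrap and report zero uncertainty.
    """
    _require_samples(work, 2)
    value = _bar_value(work.forward_work, work.reverse_work, work.kt)
    unc = bootstrap_error(work, "bar", n_boot, seed) if n_boot else 0.0
    return FreeEnergyEstimate(value, unc, "bar")


def estimate_cgi(work: WorkSet, n_boot: int = 100, seed: int = 0) -> FreeEnergyEstimate:
    """Crooks-Gaussian-intersection estimate of ΔG from a WorkSet.

    Requires at least three samples per direction so both variances are
    defined.  Uncertainty as in :func:`estimate_bar`.
    """
    _require_samples(work, 3)
    value = _cgi_value(work.forward_work, work.reverse_work, work.kt)
    unc = bootstrap_error(work, "cgi", n_boot, seed) if n_boot else 0.0
    return FreeEnergyEstimate(value, unc, "cgi")


def estimate_jarzynski(
    work: WorkSet, direction: str = "forward", n_boot: int = 100, seed: int = 0
) -> FreeEnergyEstimate:
    """One-sided Jarzynski estimate of ΔG from the chosen direction."""
    if direction not in ("forward", "reverse"):
        raise ValueError(f"direction must be 'forward' or 'reverse', got {direction!r}")
    _require_samples(work, 1, (direction,))
    samples = work.forward_work if direction == "forward" else work.reverse_work
    value = _jarzynski_value(samples, work.kt, direction)
    unc = bootstrap_error(work, f"jarzynski_{direction}", n_boot, seed) if n_boot else 0.0
    return FreeEnergyEstimate(value, unc, "jarzynski")
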