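"""Calculation-versus-experiment benchmark statistics.

Summarises paired calculated/experimental free-energy values (kJ/mol) by
the average unsigned error (AUE), the Pearson correlation coefficient,
an ordinary least-squares regression of calculated on experimental
values, and the fraction of points within a chemical-accuracy band
(default ±1 kcal/mol = 4.184 kJ/mol).  ``stratify_by_distance`` repeats
the comparison within inter-residue distance bins to check whether
accuracy degrades for spatially distant mutation pairs.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import BenchmarkError

__all__ = [
    "KCAL_BAND",
    "BenchmarkReport",
    "DistanceStratum",
    "StratifiedBenchmark",
    "compare",
    "stratify_by_distance",
]

#: ±1 kcal/mol in kJ/mol, the conventional chemical-accuracy band.
KCAL_BAND = 4.184


@dataclass(frozen=True)
class BenchmarkReport:
    """Agreement statistics between calculated and experimental values.

    ``pearson_r``, ``slope`` and ``intercept`` are ``None`` when the
    statistic is undefined (zero variance in one of the vectors); this is
    a typed "undefined", deliberately not NaN, so downstream code must
    handle it explicitly rather than propagate it silently.
    """

    n: int
    aue: float
    pearson_r: Optional[float]
    slope: Optional[float]
    intercept: Optional[float]
    frac_within_band: float
    band: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_within_band <= 1.0):
            raise ValueError("frac_within_band must lie in [0, 1]")
        if self.aue < 0:
            raise ValueError("aue must be >= 0")
        if self.pearson_r is not None and not (-1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12):
            raise ValueError("pearson_r must lie in [-1, 1]")

    def to_dict(self) -> dict:
        def _enc(x):
            return "undefined" if x is None else x

        return {
            "n": self.n,
            "aue_kJmol": self.aue,
            "pearson_r": _enc(self.pearson_r),
            "slope": _enc(self.slope),
            "intercept_kJmol": _enc(self.intercept),
            "frac_within_band": self.frac_within_band,
            "band_kJmol": self.band,
        }


def compare(calc: Sequence[float], exp: Sequence[float], band: float = KCAL_BAND) -> BenchmarkReport:
    """Compare paired calculated and experimental values.

    AUE = mean |calc − exp|; the regression is ordinary least squares of
    the calculated values (y) on the experimental values (x);
    ``frac_within_band`` is the fraction of pairs with |calc − exp| ≤ band.
    """
    calc = np.asarray(calc, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if calc.shape != exp.shape or calc.ndim != 1:
        raise BenchmarkError(
            f"calc and exp must be equal-length 1-d vectors, got {calc.shape} and {exp.shape}"
        )
    if calc.size < 2:
        raise BenchmarkError(f"need at least 2 paired values, got {calc.size}")
    if not band > 0:
        raise BenchmarkError(f"band must be positive, got {band}")

    diff = calc - exp
    aue = float(np.abs(diff).mean())
    frac = float((np.abs(diff) <= band).mean())

    pearson_r = slope = intercept = None
    if np.ptp(exp) > 0:
        fit = stats.linregress(exp, calc)
        slope, intercept = float(fit.slope), float(fit.intercept)
        if np.ptp(calc) > 0:
            pearson_r = float(fit.rvalue)
    return BenchmarkReport(
        n=int(calc.size),
        aue=aue,
        pearson_r=pearson_r,
        slope=slope,
        intercept=intercept,
        frac_within_band=frac,
        band=band,
    )


@dataclass(frozen=True)
class DistanceStratum:
    """One distance bin [lo, hi) with its member pairs and, when the bin
    holds at least two pairs, a BenchmarkReport (else ``None`` and
    ``insufficient`` is True)."""

    lo: float
    hi: float
    pairs: Tuple[str, ...]
    report: Optional[BenchmarkReport]

    @property
    def n(self) -> int:
        return len(self.pairs)

    @property
    def insufficient(self) -> bool:
        return self.report is None


@dataclass(frozen=True)
class StratifiedBenchmark:
    """Distance-stratified comparison: one stratum per bin plus the ids of
    pairs falling outside the binning range."""

    strata: Tuple[DistanceStratum, ...]
    unassigned: Tuple[str, ...]


def stratify_by_distance(
    results: Sequence[Tuple[str, float, float]],
    distances: Dict[str, float],
    edges: Sequence[float],
    band: float = KCAL_BAND,
) -> StratifiedBenchmark:
    """Per-distance-bin benchmark of (pair id, calculated, experimental) rows.

    ``edges`` are strictly increasing bin boundaries in Å; pairs are
    assigned to half-open bins [e_i, e_{i+1}).  A pair without a distance
    is an error; a pair outside the binning range is reported in
    ``unassigned``.  Bins with fewer than two pairs are flagged
    insufficient rather than failing.
    """
    edges = list(map(float, edges))
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise BenchmarkError(f"bin edges must be strictly increasing, got {edges}")

    binned: List[List[Tuple[str, float, float]]] = [[] for _ in range(len(edges) - 1)]
    unassigned: List[str] = []
    for pair_id, calc, exp in results:
        if pair_id not in distances:
            raise BenchmarkError(f"no distance provided for pair {pair_id!r}")
        d = distances[pair_id]
        idx = np.searchsorted(edges, d, side="right") - 1
        if 0 <= idx < len(binned) and d < edges[-1]:
            binned[idx].append((pair_id, calc, exp))
        else:
            unassigned.append(pair_id)

    strata = []
    for i, members in enumerate(binned):
        ids = tuple(m[0] for m in members)
        report = None
        if len(members) >= 2:
            report = compare([m[1] for m in members], [m[2] for m in members], band=band)
        strata.append(DistanceStratum(lo=edges[i], hi=edges[i + 1], pairs=ids, report=report))
    return StratifiedBenchmark(strata=tuple(strata), unassigned=tuple(unassigned))
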