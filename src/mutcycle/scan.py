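"""Positional scans of third-site effects on a coupled mutation pair.

For a fixed pair (A, B) — e.g. L37A+G79S in staphylococcal nuclease — a
scan substitutes every amino acid at an external third position, computes
the pair coupling δ_C^AB in each mutant background via the triple-mutant
box, and summarises the position by the mean unsigned nonadditivity with
its standard error.  ``classify_change`` labels how a given third mutation
reshapes the coupling (erased / retained / amplified / inverted /
emergent), the vocabulary used to describe scan outcomes such as the
coupling-erasing N118D substitution.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import cycles
from .cycles import AMINO_ACIDS, CouplingResult, DDGTable, MutationSpec
from .errors import MissingEdgeError, ScanError

__all__ = ["ScanSummary", "positional_scan", "classify_change", "CATEGORIES"]

#: Possible outcomes of ``classify_change``.
CATEGORIES = ("erased", "retained", "amplified", "inverted", "emergent")


@dataclass(frozen=True)
class ScanSummary:
    """Result of scanning one external position against a fixed pair.

    ``per_substitution`` maps the substituted residue (one-letter) to the
    triple-box coupling δ_C^AB; substitutions whose table edges were
    missing are listed in ``missing`` and excluded from the averages.
    ``mean_abs_delta`` is the mean of |δ| over the scanned substitutions
    and ``std_error`` its standard error (sample SD / √n).
    """

    pair: Tuple[MutationSpec, MutationSpec]
    position: int
    chain: str
    wt_res: str
    per_substitution: Dict[str, CouplingResult]
    missing: Tuple[str, ...]
    mean_abs_delta: float
    std_error: float

    def __post_init__(self) -> None:
        if not self.per_substitution:
            raise ScanError("scan summary requires at least one computed substitution")
        if self.mean_abs_delta < 0:
            raise ValueError("mean_abs_delta must be >= 0")


def positional_scan(
    table: DDGTable,
    a: MutationSpec,
    b: MutationSpec,
    position: int,
    wt_res: str,
    substitutions: Optional[Sequence[str]] = None,
    chain: str = "",
) -> ScanSummary:
    """Scan third-site substitutions at ``position`` against the pair (A, B).

    Parameters
    ----------
    table
        ΔΔG table covering the triple-box edges for each substitution.
    a, b
        The fixed mutation pair whose coupling is probed.
    position, wt_res, chain
        The external site to scan and its wild-type residue.
    substitutions
        Residues to substitute; defaults to the 19 non-wild-type canonical
        amino acids.  The wild-type identity substitution is always
        excluded.

    Substitutions whose required edges are absent from the table are
    recorded as missing rather than aborting the scan; the scan fails only
    if no substitution can be computed at all.
    """
    if substitutions is None:
        substitutions = [res for res in AMINO_ACIDS if res != wt_res]
    else:
        substitutions = [res for res in substitutions if res != wt_res]
    if not substitutions:
        raise ScanError(f"no substitutions to scan at position {position}")

    per_sub: Dict[str, CouplingResult] = {}
    missing: List[str] = []
    for res in substitutions:
        c = MutationSpec(position=position, wt_res=wt_res, mut_res=res, chain=chain)
        try:
            per_sub[res] = cycles.triple_box(table, a, b, c)
        except MissingEdgeError:
            missing.append(res)
    if not per_sub:
        raise ScanError(
            f"no substitution at position {position} had complete table coverage "
            f"(missing: {', '.join(missing)})"
        )

    abs_deltas = np.array([abs(r.delta) for r in per_sub.values()])
    mean_abs = float(abs_deltas.mean())
    if abs_deltas.size > 1:
        std_error = float(abs_deltas.std(ddof=1) / np.sqrt(abs_deltas.size))
    else:
        std_error = 0.0
    return ScanSummary(
        pair=(a, b),
        position=position,
        chain=chain,
        wt_res=wt_res,
        per_substitution=per_sub,
        missing=tuple(missing),
        mean_abs_delta=mean_abs,
        std_error=std_error,
    )


def classify_change(
    delta_ref: Union[CouplingResult, float],
    delta_new: Union[CouplingResult, float],
    additive_threshold: float = 1.0,
) -> str:
    """Label how a coupling changed between two backgrounds.

    With t = ``additive_threshold`` (kJ/mol, the magnitude below which a
    coupling counts as additive):

    * ``erased``    — |δ_new| < t ≤ |δ_ref|: a real coupling vanished;
    * ``emergent``  — |δ_ref| < t ≤ |δ_new|: a coupling appeared;
    * ``inverted``  — both above t with opposite signs;
    * ``amplified`` — both above t, same sign, |δ_new| > |δ_ref| + t;
    * ``retained``  — anything else.

    The branches are checked in that order, so exactly one label applies
    to any input.
    """
    if not additive_threshold > 0:
        raise ValueError(f"additive_threshold must be positive, got {additive_threshold}")
    d_ref = delta_ref.delta if isinstance(delta_ref, CouplingResult) else float(delta_ref)
    d_new = delta_new.delta if isinstance(delta_new, CouplingResult) else float(delta_new)
    t = additive_threshold
    if abs(d_new) < t <= abs(d_ref):
        return "erased"
    if abs(d_ref) < t <= abs(d_new):
        return "emergent"
    if abs(d_ref) >= t and abs(d_new) >= t and np.sign(d_ref) != np.sign(d_new):
        return "inverted"
    if np.sign(d_ref) == np.sign(d_new) and abs(d_new) > abs(d_ref) + t:
        return "amplified"
    return "retained"
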