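"""Thermodynamic-cycle algebra for mutational free energies.

The central objects are mutation-set *states* (the wild type is the empty
set; ``{L37A}``, ``{L37A, G79S}``, ... are mutants) and a
:class:`DDGTable` holding ΔΔG edges between a reference state and a
strictly larger target state.  On top of the table this module provides

* ``nonadditivity`` — the double-mutant-cycle coupling
  δ_ref^AB = ΔΔG_ref^{AB} − ΔΔG_ref^{A} − ΔΔG_ref^{B}; δ = 0 means the
  two mutations act additively, δ ≠ 0 means they are thermodynamically
  coupled;
* ``compose_path`` — ΔΔG between any two connected states by summing
  table edges along a deterministic shortest chain, with a consistency
  report over all alternative chains (free energy is a state function, so
  all chains must agree on a consistent table);
* ``triple_box`` — the coupling δ_C^AB of a pair evaluated in the
  background of a third mutation C, computable either directly from
  C-referenced edges or by the exact decomposition
  δ_C^AB = δ_WT^AB + ΔΔG_AB^{ABC} + ΔΔG_WT^{C} − ΔΔG_A^{AC} − ΔΔG_B^{BC}.

Uncertainties are combined in quadrature under the assumption of
independent legs.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import DuplicateEdgeError, MissingEdgeError, NoPathError
from .estimators import FreeEnergyEstimate

__all__ = [
    "AMINO_ACIDS",
    "MutationSpec",
    "MutationSet",
    "WT",
    "DDGTable",
    "CouplingResult",
    "PathResult",
    "ddg_from_legs",
    "nonadditivity",
    "compose_path",
    "triple_box",
    "propagate",
    "is_correlated",
]

#: Canonical one-letter amino-acid alphabet.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Formal side-chain charges at neutral pH; histidine treated as neutral.
_CHARGE = {"D": -1, "E": -1, "K": +1, "R": +1}

_CODE_RE = re.compile(r"^(?:(?P<chain>[A-Za-z0-9]+):)?(?P<wt>[A-Z])(?P<pos>-?\d+)(?P<mut>[A-Z])$")


@dataclass(frozen=True)
class MutationSpec:
    """A single point mutation, e.g. ``L37A`` (wild-type L, position 37,
    mutant A).  ``chain`` may be left empty for single-chain proteins;
    positions follow PDB numbering."""

    position: int
    wt_res: str
    mut_res: str
    chain: str = ""

    def __post_init__(self) -> None:
        if self.wt_res not in AMINO_ACIDS:
            raise ValueError(f"unknown wild-type residue {self.wt_res!r}")
        if self.mut_res not in AMINO_ACIDS:
            raise ValueError(f"unknown mutant residue {self.mut_res!r}")
        if self.wt_res == self.mut_res:
            raise ValueError(f"wild-type and mutant residue are both {self.wt_res!r}")

    @property
    def site(self) -> Tuple[str, int]:
        """The (chain, position) this mutation occupies."""
        return (self.chain, self.position)

    @property
    def code(self) -> str:
        """Compact label such as ``L37A`` or ``B:L37A``."""
        prefix = f"{self.chain}:" if self.chain else ""
        return f"{prefix}{self.wt_res}{self.position}{self.mut_res}"

    @property
    def is_charge_changing(self) -> bool:
        """True when the substitution alters the formal side-chain charge
        (D/E negative, K/R positive, H neutral), e.g. N118D."""
        return _CHARGE.get(self.wt_res, 0) != _CHARGE.get(self.mut_res, 0)

    @classmethod
    def from_code(cls, code: str) -> "MutationSpec":
        """Parse ``L37A`` or ``A:L37A`` into a MutationSpec."""
        m = _CODE_RE.match(code.strip())
        if m is None:
            raise ValueError(f"malformed mutation code {code!r} (expected e.g. 'L37A')")
        return cls(
            position=int(m.group("pos")),
            wt_res=m.group("wt"),
            mut_res=m.group("mut"),
            chain=m.group("chain") or "",
        )

    @property
    def sort_key(self) -> Tuple[str, int, str]:
        return (self.chain, self.position, self.mut_res)

    def __str__(self) -> str:
        return self.code


class MutationSet:
    """An unordered set of point mutations defining a protein state.

    The empty set is the wild type.  At most one mutation may occupy a
    given (chain, position).  Instances are immutable and hashable, so
    they serve as DDGTable keys; the canonical ``label`` joins the
    mutation codes with ``+`` in (chain, position) order, the wild type
    rendering as the empty string.
    """

    __slots__ = ("_specs",)

    def __init__(self, mutations: Iterable[MutationSpec] = ()):
        specs = frozenset(mutations)
        sites = [m.site for m in specs]
        if len(set(sites)) != len(sites):
            dupes = sorted({s for s in sites if sites.count(s) > 1})
            raise ValueError(f"multiple mutations at the same site(s): {dupes}")
        object.__setattr__(self, "_specs", specs)

    @classmethod
    def from_code(cls, label: str) -> "MutationSet":
        """Parse a '+'-joined label (``\"\"`` = wild type) into a state."""
        label = label.strip()
        if not label:
            return cls()
        return cls(MutationSpec.from_code(part) for part in label.split("+"))

    @property
    def mutations(self) -> frozenset:
        return self._specs

    @property
    def label(self) -> str:
        return "+".join(m.code for m in self)

    def add(self, *mutations: MutationSpec) -> "MutationSet":
        """Return a new state with the extra mutations introduced."""
        return MutationSet(self._specs | set(mutations))

    def issubset(self, other: "MutationSet") -> bool:
        return self._specs <= other._specs

    def __or__(self, other: "MutationSet") -> "MutationSet":
        return MutationSet(self._specs | other._specs)

    def __contains__(self, spec: MutationSpec) -> bool:
        return spec in self._specs

    def __iter__(self) -> Iterator[MutationSpec]:
        return iter(sorted(self._specs, key=lambda m: m.sort_key))

    def __len__(self) -> int:
        return len(self._specs)

    def __eq__(self, other) -> bool:
        return isinstance(other, MutationSet) and self._specs == other._specs

    def __hash__(self) -> int:
        return hash(self._specs)

    def __repr__(self) -> str:
        return f"MutationSet({self.label or 'WT'})"


#: The wild-type state (no mutations).
WT = MutationSet()


def _state_name(state: MutationSet) -> str:
    return state.label or "WT"


class DDGTable:
    """Map (reference state, target state) → ΔΔG estimate, kJ/mol.

    Every entry is one mutational free-energy difference
    ΔΔG_reference^target with the target a strict superset of the
    reference; duplicate keys are rejected.
    """

    def __init__(self):
        self._edges: Dict[Tuple[MutationSet, MutationSet], FreeEnergyEstimate] = {}

    def add(self, reference: MutationSet, target: MutationSet, estimate: FreeEnergyEstimate) -> None:
        if not (reference.issubset(target) and reference != target):
            raise ValueError(
                f"target {_state_name(target)} must strictly contain "
                f"reference {_state_name(reference)}"
            )
        key = (reference, target)
        if key in self._edges:
            raise DuplicateEdgeError(
                f"duplicate ΔΔG entry {_state_name(reference)} -> {_state_name(target)}"
            )
        self._edges[key] = estimate

    def get(self, reference: MutationSet, target: MutationSet) -> Optional[FreeEnergyEstimate]:
        return self._edges.get((reference, target))

    def require(self, reference: MutationSet, target: MutationSet) -> FreeEnergyEstimate:
        est = self.get(reference, target)
        if est is None:
            raise MissingEdgeError(
                f"missing ΔΔG entry ({_state_name(reference)}, {_state_name(target)})"
            )
        return est

    def edges(self) -> Iterator[Tuple[MutationSet, MutationSet, FreeEnergyEstimate]]:
        """Iterate edges in deterministic (reference label, target label) order."""
        for (ref, tgt) in sorted(self._edges, key=lambda k: (k[0].label, k[1].label)):
            yield ref, tgt, self._edges[(ref, tgt)]

    def states(self) -> list:
        seen = {s for key in self._edges for s in key}
        return sorted(seen, key=lambda s: (len(s), s.label))

    def __len__(self) -> int:
        return len(self._edges)

    def __contains__(self, key: Tuple[MutationSet, MutationSet]) -> bool:
        return key in self._edges

    @classmethod
    def from_state_energies(
        cls,
        energies: Mapping[MutationSet, float],
        edges: Optional[Iterable[Tuple[MutationSet, MutationSet]]] = None,
        uncertainty: float = 0.0,
        method: str = "input",
    ) -> "DDGTable":
        """Build a thermodynamically consistent table from per-state free
        energies: each edge value is G(target) − G(reference).

        With ``edges=None`` every strict-subset pair among the given states
        becomes an edge (convenient for small consistency fixtures).
        """
        table = cls()
        if edges is None:
            states = list(energies)
            edges = [
                (r, t)
                for r in states
                for t in states
                if r != t and r.issubset(t)
            ]
        for ref, tgt in edges:
            value = energies[tgt] - energies[ref]
            table.add(ref, tgt, FreeEnergyEstimate(value, uncertainty, method))
        return table


@dataclass(frozen=True)
class CouplingResult:
    """A nonadditivity δ (kJ/mol) for a mutation pair at a reference state.

    ``breakdown`` names the ΔΔG terms that entered the computation so the
    dominant contribution can be traced."""

    pair: Tuple[MutationSpec, MutationSpec]
    reference: MutationSet
    delta: float
    uncertainty: float
    breakdown: Optional[Dict[str, FreeEnergyEstimate]] = None

    def __post_init__(self) -> None:
        if not (self.uncertainty >= 0.0):
            raise ValueError(f"uncertainty must be >= 0, got {self.uncertainty}")

    def __str__(self) -> str:
        a, b = self.pair
        return (
            f"delta_{_state_name(self.reference)}^{a.code}+{b.code} = "
            f"{self.delta:.3f} ± {self.uncertainty:.3f} kJ/mol"
        )


@dataclass(frozen=True)
class PathResult:
    """A composed ΔΔG between two states plus pathway diagnostics.

    ``max_discrepancy`` is the largest difference between the summed
    values of any two chains connecting the states (0 when only one chain
    exists); on a thermodynamically consistent table it vanishes.  It is
    ``None`` when the diagnostic enumeration was skipped."""

    estimate: FreeEnergyEstimate
    states: Tuple[MutationSet, ...]
    n_paths: Optional[int]
    max_discrepancy: Optional[float]


def propagate(
    components: Sequence[FreeEnergyEstimate], signs: Optional[Sequence[int]] = None
) -> FreeEnergyEstimate:
    """Signed sum of estimates with quadrature error propagation.

    Legs are assumed independent, so the combined standard error is the
    square root of the sum of squared component uncertainties.
    """
    if signs is None:
        signs = [1] * len(components)
    if len(signs) != len(components):
        raise ValueError(
            f"{len(components)} components but {len(signs)} signs"
        )
    value = sum(s * c.value for s, c in zip(signs, components))
    unc = float(np.sqrt(sum(c.uncertainty**2 for c in components)))
    offset = any(c.offset_relative for c in components)
    return FreeEnergyEstimate(value, unc, "propagated", offset_relative=offset)


def ddg_from_legs(
    dg_folded: FreeEnergyEstimate,
    dg_unfolded: Optional[FreeEnergyEstimate] = None,
) -> FreeEnergyEstimate:
    """ΔΔG of unfolding from the folded- and unfolded-state alchemical legs.

    ΔΔG = ΔG_folded − ΔG_unfolded, errors in quadrature.  When the
    unfolded leg is omitted the mutations are assumed additive in the
    unfolded state, so the unfolded contribution is a per-mutation
    constant that cancels from every double-mutant-cycle δ; the returned
    estimate is then flagged ``offset_relative``.
    """
    if dg_unfolded is None:
        return FreeEnergyEstimate(
            dg_folded.value, dg_folded.uncertainty, dg_folded.method, offset_relative=True
        )
    value = dg_folded.value - dg_unfolded.value
    unc = float(np.hypot(dg_folded.uncertainty, dg_unfolded.uncertainty))
    return FreeEnergyEstimate(value, unc, dg_folded.method)


def _neighbors(table: DDGTable):
    adj: Dict[MutationSet, list] = {}
    for ref, tgt, est in table.edges():
        key = (ref, tgt)
        adj.setdefault(ref, []).append((tgt, +1, est, key))
        adj.setdefault(tgt, []).append((ref, -1, est, key))
    for lst in adj.values():
        lst.sort(key=lambda item: _state_name(item[0]))
    return adj


def _all_simple_paths(adj, source, target, max_paths=5000):
    """Enumerate simple chains source→target as lists of (sign, est) with
    their state sequences; capped at ``max_paths``."""
    paths = []
    stack = [(source, [source], [])]
    while stack and len(paths) < max_paths:
        node, visited, legs = stack.pop()
        for nxt, sign, est, _key in reversed(adj.get(node, [])):
            if nxt in visited:
                continue
            if nxt == target:
                paths.append((visited + [nxt], legs + [(sign, est)]))
                if len(paths) >= max_paths:
                    break
            else:
                stack.append((nxt, visited + [nxt], legs + [(sign, est)]))
    return paths


def _shortest_chain(adj, reference, target):
    """Breadth-first shortest chain; among equal-length chains the one
    whose state-label sequence is lexicographically smallest is kept.
    Returns (states, legs) with legs = [(sign, est, edge_key), ...]."""
    # best[node] = lexicographically minimal label-tuple path at min depth
    best = {reference: ((_state_name(reference),), [reference], [])}
    frontier = [reference]
    while frontier:
        if target in best:
            return best[target][1], best[target][2]
        nxt_best = {}
        for node in sorted(frontier, key=_state_name):
            labels, states, legs = best[node]
            for neigh, sign, est, key in adj.get(node, []):
                if neigh in best:  # reached at an earlier level
                    continue
                cand = (
                    labels + (_state_name(neigh),),
                    states + [neigh],
                    legs + [(sign, est, key)],
                )
                if neigh not in nxt_best or cand[0] < nxt_best[neigh][0]:
                    nxt_best[neigh] = cand
        best.update(nxt_best)
        frontier = list(nxt_best)
    return None


def compose_path(
    table: DDGTable,
    reference: MutationSet,
    target: MutationSet,
    diagnostics: bool = True,
) -> PathResult:
    """ΔΔG_reference^target composed from a chain of table edges.

    Edges may be traversed against their stored direction (sign flipped).
    Among all chains the shortest is used, ties broken by the
    lexicographic order of the chain's state labels.  Because free energy
    is a state function every chain must agree on a consistent table;
    with ``diagnostics=True`` all simple chains (capped at 5000) are
    enumerated and ``max_discrepancy`` reports the worst disagreement.
    """
    if reference == target:
        return PathResult(FreeEnergyEstimate(0.0, 0.0, "path"), (reference,), 1, 0.0)
    adj = _neighbors(table)
    if reference not in adj or target not in adj:
        missing = reference if reference not in adj else target
        raise NoPathError(f"state {_state_name(missing)} does not appear in the table")
    found = _shortest_chain(adj, reference, target)
    if found is None:
        raise NoPathError(
            f"no chain of edges connects {_state_name(reference)} to {_state_name(target)}"
        )
    states, legs = found

    if len(legs) == 1 and legs[0][0] == +1:
        est = legs[0][1]  # direct edge: pass through unchanged
    else:
        value = sum(sign * e.value for sign, e, _k in legs)
        unc = float(np.sqrt(sum(e.uncertainty**2 for _, e, _k in legs)))
        offset = any(e.offset_relative for _, e, _k in legs)
        est = FreeEnergyEstimate(value, unc, "path", offset_relative=offset)

    n_paths = max_discrepancy = None
    if diagnostics:
        paths = _all_simple_paths(adj, reference, target)
        sums = [sum(sign * e.value for sign, e in p_legs) for _, p_legs in paths]
        n_paths = len(paths)
        max_discrepancy = float(max(sums) - min(sums)) if len(sums) > 1 else 0.0
    return PathResult(est, tuple(states), n_paths, max_discrepancy)


def _term_edges(table: DDGTable, reference: MutationSet, target: MutationSet, adj=None):
    """Resolve ΔΔG_reference^target to signed table edges.

    Returns a list of (edge_key, sign, estimate): a single entry for a
    direct edge, otherwise the legs of the shortest composing chain.
    Failure names the missing (reference, target) key.
    """
    est = table.get(reference, target)
    if est is not None:
        return [((reference, target), +1, est)]
    if adj is None:
        adj = _neighbors(table)
    found = None
    if reference in adj and target in adj:
        found = _shortest_chain(adj, reference, target)
    if found is None:
        raise MissingEdgeError(
            f"missing ΔΔG entry ({_state_name(reference)}, {_state_name(target)}) "
            "and no composable path"
        )
    return [(key, sign, e) for sign, e, key in found[1]]


def _combine_edge_terms(edge_terms) -> FreeEnergyEstimate:
    """Signed sum over table edges with net-coefficient quadrature.

    An edge contributing to several ΔΔG terms enters the uncertainty with
    its *net* coefficient, so shared legs that cancel in value carry no
    spurious uncertainty; distinct edges are assumed independent.
    """
    agg: Dict[tuple, list] = {}
    for key, sign, est in edge_terms:
        if key in agg:
            agg[key][0] += sign
        else:
            agg[key] = [float(sign), est]
    value = sum(coeff * est.value for coeff, est in agg.values())
    unc = float(np.sqrt(sum((coeff * est.uncertainty) ** 2 for coeff, est in agg.values())))
    offset = any(est.offset_relative for coeff, est in agg.values() if coeff != 0)
    return FreeEnergyEstimate(value, unc, "propagated", offset_relative=offset)


def _resolve_ddg(table: DDGTable, reference: MutationSet, target: MutationSet) -> FreeEnergyEstimate:
    """Direct edge if present, else a composed path; failure names the key."""
    legs = _term_edges(table, reference, target)
    if len(legs) == 1 and legs[0][1] == +1:
        return legs[0][2]
    return _combine_edge_terms(legs)


def _check_pair(a: MutationSpec, b: MutationSpec, reference: MutationSet) -> None:
    if a.site == b.site:
        raise ValueError(f"pair mutations {a.code} and {b.code} occupy the same site")
    occupied = {m.site for m in reference.mutations}
    for spec in (a, b):
        if spec.site in occupied:
            raise ValueError(
                f"mutation {spec.code} clashes with the reference state "
                f"{_state_name(reference)}"
            )


def _nonadditivity_terms(table, a, b, reference, adj=None):
    """Edge terms and per-term breakdown for δ_ref^AB."""
    terms = []
    breakdown = {}
    for name, target, sign in (
        ("ddg_ab", reference.add(a, b), +1),
        ("ddg_a", reference.add(a), -1),
        ("ddg_b", reference.add(b), -1),
    ):
        legs = _term_edges(table, reference, target, adj=adj)
        if len(legs) == 1 and legs[0][1] == +1:
            breakdown[name] = legs[0][2]
        else:
            breakdown[name] = _combine_edge_terms(legs)
        terms.extend((key, sign * leg_sign, est) for key, leg_sign, est in legs)
    return terms, breakdown


def nonadditivity(
    table: DDGTable,
    a: MutationSpec,
    b: MutationSpec,
    reference: MutationSet = WT,
) -> CouplingResult:
    """Double-mutant-cycle nonadditivity δ_ref^AB.

    δ_ref^AB = ΔΔG_ref^{ref+AB} − ΔΔG_ref^{ref+A} − ΔΔG_ref^{ref+B},
    with the three terms taken from direct edges where available and
    composed from chains of edges otherwise.  δ = 0 means A and B act
    additively at this reference; δ ≠ 0 means they are thermodynamically
    coupled.

    Uncertainty is combined in quadrature over the *unique* table edges
    involved, each weighted by its net coefficient, so an edge shared
    between terms (e.g. a composing leg that cancels against a single-
    mutation term) does not contribute twice.
    """
    _check_pair(a, b, reference)
    adj = _neighbors(table)
    terms, breakdown = _nonadditivity_terms(table, a, b, reference, adj=adj)
    combined = _combine_edge_terms(terms)
    return CouplingResult(
        pair=(a, b),
        reference=reference,
        delta=combined.value,
        uncertainty=combined.uncertainty,
        breakdown=breakdown,
    )


def triple_box(
    table: DDGTable,
    a: MutationSpec,
    b: MutationSpec,
    c: MutationSpec,
    form: str = "auto",
) -> CouplingResult:
    """Coupling of the pair (A, B) in the background of a third mutation C.

    Two algebraically identical routes exist (both follow from free
    energy being a state function):

    * ``direct`` — the double-mutant cycle re-referenced to C:
      δ_C^AB = ΔΔG_C^{ABC} − ΔΔG_C^{AC} − ΔΔG_C^{BC};
    * ``decomposition`` — the wild-type coupling corrected by the four
      single C-introduction legs:
      δ_C^AB = δ_WT^AB + ΔΔG_AB^{ABC} + ΔΔG_WT^{C} − ΔΔG_A^{AC} − ΔΔG_B^{BC}.

    ``form='auto'`` tries the direct route first and falls back to the
    decomposition when C-referenced edges are absent.
    """
    if form not in ("auto", "direct", "decomposition"):
        raise ValueError(f"unknown form {form!r}")
    _check_pair(a, b, WT)
    if c.site in (a.site, b.site):
        raise ValueError(f"third mutation {c.code} occupies a pair site")

    if form in ("auto", "direct"):
        try:
            return nonadditivity(table, a, b, reference=MutationSet([c]))
        except MissingEdgeError:
            if form == "direct":
                raise

    state_a, state_b = MutationSet([a]), MutationSet([b])
    state_ab = MutationSet([a, b])
    adj = _neighbors(table)
    nonadd_terms, _ = _nonadditivity_terms(table, a, b, WT, adj=adj)
    breakdown = {"delta_wt_ab": _combine_edge_terms(nonadd_terms)}
    terms = list(nonadd_terms)
    for name, ref, tgt, sign in (
        ("ddg_ab_abc", state_ab, state_ab.add(c), +1),
        ("ddg_wt_c", WT, MutationSet([c]), +1),
        ("ddg_a_ac", state_a, state_a.add(c), -1),
        ("ddg_b_bc", state_b, state_b.add(c), -1),
    ):
        legs = _term_edges(table, ref, tgt, adj=adj)
        if len(legs) == 1 and legs[0][1] == +1:
            breakdown[name] = legs[0][2]
        else:
            breakdown[name] = _combine_edge_terms(legs)
        terms.extend((key, sign * leg_sign, est) for key, leg_sign, est in legs)
    combined = _combine_edge_terms(terms)
    return CouplingResult(
        pair=(a, b),
        reference=MutationSet([c]),
        delta=combined.value,
        uncertainty=combined.uncertainty,
        breakdown=breakdown,
    )


def is_correlated(
    coupling: CouplingResult,
    base_threshold: float = 1.0,
    sigma_factor: float = 2.0,
) -> bool:
    """Call a pair correlated when |δ| clears both an absolute floor and a
    multiple of its own uncertainty: |δ| > max(base, sigma_factor·u)."""
    return abs(coupling.delta) > max(base_threshold, sigma_factor * coupling.uncertainty)
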