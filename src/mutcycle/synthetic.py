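"""Synthetic free-energy landscapes and Crooks-consistent work samples.

Stands in for the molecular-dynamics stage of the pipeline so that every
analysis step can be exercised against a known ground truth.  The
landscape model assigns each mutation-set state a free energy

    G(S) = Σ singles  +  Σ pair couplings fully inside S
                      +  Σ triangular terms whose pair and third mutation
                          are all present in S,

with G(WT) = 0.  A pair coupling c plants a double-mutant-cycle
nonadditivity δ_WT^AB = c; a triangular term t for (pair, C) shifts the
coupling seen in the C background to δ_C^AB = c + t — the planted
analogue of a third-site mutation erasing (t = −c), amplifying or
inverting a pair coupling.

Work samples are drawn from the unique per-direction Normal family that
satisfies the Crooks fluctuation theorem exactly:
forward ~ N(ΔG + βσ²/2, σ²), reverse ~ N(−ΔG + βσ²/2, σ²), so that
P_f(W)/P_r(−W) = exp(β(W − ΔG)).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .cycles import AMINO_ACIDS, WT, DDGTable, MutationSet, MutationSpec
from .estimators import DEFAULT_TEMPERATURE, KB, FreeEnergyEstimate, WorkSet

__all__ = [
    "Site",
    "LandscapeModel",
    "generate_landscape",
    "emit_ddg_table",
    "generate_work_samples",
    "pair_states",
    "triple_states",
]

PairKey = FrozenSet[MutationSpec]
TriangleKey = Tuple[PairKey, MutationSpec]

# Default effect-size ranges (kJ/mol).  Singles span typical stability
# changes of point mutations; couplings span up to the ~10 kJ/mol scale of
# the strongest experimentally observed pair nonadditivities.
SINGLE_RANGE = (-8.0, 8.0)
COUPLING_RANGE = (-10.0, 10.0)
TRIANGULAR_RANGE = (-10.0, 10.0)


@dataclass(frozen=True)
class Site:
    """A mutable position: wild-type residue and allowed substitutions."""

    position: int
    wt_res: str
    substitutions: Tuple[str, ...]
    chain: str = ""

    def spec(self, mut_res: str) -> MutationSpec:
        return MutationSpec(
            position=self.position, wt_res=self.wt_res, mut_res=mut_res, chain=self.chain
        )


@dataclass
class LandscapeModel:
    """Ground-truth additive-plus-couplings free-energy landscape."""

    sites: List[Site]
    singles: Dict[MutationSpec, float]
    pair_couplings: Dict[PairKey, float]
    triangular_terms: Dict[TriangleKey, float]
    seed: int = 0

    def energy(self, state: MutationSet) -> float:
        """Free energy of a mutation-set state relative to G(WT) = 0."""
        members = state.mutations
        g = sum(self.singles[m] for m in members)
        for pair, c in self.pair_couplings.items():
            if pair <= members:
                g += c
        for (pair, third), t in self.triangular_terms.items():
            if pair <= members and third in members:
                g += t
        return float(g)

    def ddg(self, reference: MutationSet, target: MutationSet) -> float:
        """Exact ΔΔG_reference^target."""
        return self.energy(target) - self.energy(reference)

    def delta(self, a: MutationSpec, b: MutationSpec, reference: MutationSet = WT) -> float:
        """Exact ground-truth nonadditivity δ_ref^AB from the G function."""
        return (
            self.energy(reference.add(a, b))
            - self.energy(reference.add(a))
            - self.energy(reference.add(b))
            + self.energy(reference)
        )

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "sites": [
                {
                    "position": s.position,
                    "wt_res": s.wt_res,
                    "substitutions": list(s.substitutions),
                    "chain": s.chain,
                }
                for s in self.sites
            ],
            "singles": {m.code: v for m, v in sorted(self.singles.items(), key=lambda kv: kv[0].code)},
            "pair_couplings": {
                "|".join(sorted(m.code for m in pair)): c
                for pair, c in sorted(
                    self.pair_couplings.items(),
                    key=lambda kv: sorted(m.code for m in kv[0]),
                )
            },
            "triangular_terms": {
                "|".join(sorted(m.code for m in pair)) + "|" + third.code: t
                for (pair, third), t in sorted(
                    self.triangular_terms.items(),
                    key=lambda kv: (sorted(m.code for m in kv[0][0]), kv[0][1].code),
                )
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    @classmethod
    def from_dict(cls, data: dict) -> "LandscapeModel":
        sites = [
            Site(
                position=s["position"],
                wt_res=s["wt_res"],
                substitutions=tuple(s["substitutions"]),
                chain=s.get("chain", ""),
            )
            for s in data["sites"]
        ]
        singles = {MutationSpec.from_code(k): v for k, v in data["singles"].items()}
        pairs = {
            frozenset(MutationSpec.from_code(p) for p in key.split("|")): v
            for key, v in data["pair_couplings"].items()
        }
        triangles = {}
        for key, v in data["triangular_terms"].items():
            a, b, c = (MutationSpec.from_code(p) for p in key.split("|"))
            triangles[(frozenset((a, b)), c)] = v
        return cls(
            sites=sites,
            singles=singles,
            pair_couplings=pairs,
            triangular_terms=triangles,
            seed=data.get("seed", 0),
        )

    @classmethod
    def from_json(cls, text: str) -> "LandscapeModel":
        return cls.from_dict(json.loads(text))


def generate_landscape(
    n_sites: int,
    n_pair_couplings: int,
    n_triangular: int,
    single_range: Tuple[float, float] = SINGLE_RANGE,
    coupling_range: Tuple[float, float] = COUPLING_RANGE,
    triangular_range: Tuple[float, float] = TRIANGULAR_RANGE,
    substitutions_per_site: int = 1,
    seed: int = 0,
) -> LandscapeModel:
    """Draw a reproducible landscape with planted couplings.

    Sites occupy positions 1..n_sites with random wild-type residues and
    ``substitutions_per_site`` random allowed substitutions each (pass 19
    for the full non-wild-type alphabet).  ``n_pair_couplings`` distinct
    cross-site mutation pairs receive couplings drawn from
    ``coupling_range``; ``n_triangular`` triangular terms attach a
    third-site mutation to one of the planted pairs.  Counts that cannot
    be realised raise ``ValueError``.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if not 1 <= substitutions_per_site <= 19:
        raise ValueError("substitutions_per_site must be in 1..19")
    if n_triangular > 0 and n_pair_couplings < 1:
        raise ValueError("triangular terms require at least one pair coupling")
    if n_triangular > 0 and n_sites < 3:
        raise ValueError("triangular terms require at least 3 sites")
    if n_pair_couplings > 0 and n_sites < 2:
        raise ValueError("pair couplings require at least 2 sites")

    rng = np.random.default_rng(seed)
    sites: List[Site] = []
    for pos in range(1, n_sites + 1):
        wt = AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS))]
        others = [r for r in AMINO_ACIDS if r != wt]
        subs = tuple(
            sorted(str(r) for r in rng.choice(others, size=substitutions_per_site, replace=False))
        )
        sites.append(Site(position=pos, wt_res=wt, substitutions=subs))

    specs_by_site = [[site.spec(r) for r in site.substitutions] for site in sites]
    all_specs = [spec for specs in specs_by_site for spec in specs]
    singles = {
        spec: float(rng.uniform(*single_range)) for spec in all_specs
    }

    cross_pairs = [
        frozenset((s1, s2))
        for i, specs1 in enumerate(specs_by_site)
        for specs2 in specs_by_site[i + 1 :]
        for s1 in specs1
        for s2 in specs2
    ]
    if n_pair_couplings > len(cross_pairs):
        raise ValueError(
            f"requested {n_pair_couplings} pair couplings but only "
            f"{len(cross_pairs)} cross-site pairs exist"
        )
    chosen_idx = rng.choice(len(cross_pairs), size=n_pair_couplings, replace=False)
    pair_couplings = {
        cross_pairs[i]: float(rng.uniform(*coupling_range)) for i in sorted(chosen_idx)
    }

    triangular: Dict[TriangleKey, float] = {}
    if n_triangular:
        pair_list = list(pair_couplings)
        candidates = []
        for pair in pair_list:
            pair_sites = {m.site for m in pair}
            for spec in all_specs:
                if spec.site not in pair_sites:
                    candidates.append((pair, spec))
        if n_triangular > len(candidates):
            raise ValueError(
                f"requested {n_triangular} triangular terms but only "
                f"{len(candidates)} (pair, third) combinations exist"
            )
        tri_idx = rng.choice(len(candidates), size=n_triangular, replace=False)
        for i in sorted(tri_idx):
            triangular[candidates[i]] = float(rng.uniform(*triangular_range))

    return LandscapeModel(
        sites=sites,
        singles=singles,
        pair_couplings=pair_couplings,
        triangular_terms=triangular,
        seed=seed,
    )


def pair_states(a: MutationSpec, b: MutationSpec) -> List[Tuple[MutationSet, MutationSet]]:
    """The four single-introduction edges of the double-mutant cycle
    (WT→A, WT→B, A→AB, B→AB)."""
    sa, sb = MutationSet([a]), MutationSet([b])
    sab = MutationSet([a, b])
    return [(WT, sa), (WT, sb), (sa, sab), (sb, sab)]


def triple_states(
    a: MutationSpec, b: MutationSpec, c: MutationSpec
) -> List[Tuple[MutationSet, MutationSet]]:
    """The twelve single-introduction edges of the triple-mutant box over
    the states WT, A, B, C, AB, AC, BC, ABC."""
    edges = []
    specs = (a, b, c)
    for mask in range(8):
        members = [s for i, s in enumerate(specs) if mask & (1 << i)]
        ref = MutationSet(members)
        for i, s in enumerate(specs):
            if not mask & (1 << i):
                edges.append((ref, ref.add(s)))
    return edges


def emit_ddg_table(
    model: LandscapeModel,
    pairs: Sequence[Tuple[MutationSpec, MutationSpec]] = (),
    triples: Sequence[Tuple[MutationSpec, MutationSpec, MutationSpec]] = (),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DDGTable:
    """Emit a ΔΔG table of exact G differences plus Gaussian noise.

    For each requested pair the four double-mutant-cycle edges are
    produced, for each requested triple the twelve triple-box edges;
    shared edges are emitted once.  Every edge value is the exact ground
    truth plus independent N(0, noise_sd²) noise, with the reported
    uncertainty set to ``noise_sd``.  Deterministic for a given seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    wanted: Dict[Tuple[str, str], Tuple[MutationSet, MutationSet]] = {}
    for a, b in pairs:
        for ref, tgt in pair_states(a, b):
            wanted[(ref.label, tgt.label)] = (ref, tgt)
    for a, b, c in triples:
        for ref, tgt in triple_states(a, b, c):
            wanted[(ref.label, tgt.label)] = (ref, tgt)
    if not wanted:
        raise ValueError("no pairs or triples requested")

    rng = np.random.default_rng(seed)
    table = DDGTable()
    for key in sorted(wanted):
        ref, tgt = wanted[key]
        value = model.ddg(ref, tgt) + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
        table.add(ref, tgt, FreeEnergyEstimate(value, noise_sd, "input"))
    return table


def generate_work_samples(
    true_dg: float,
    sigma: float,
    n_forward: int,
    n_reverse: int,
    temperature: float = DEFAULT_TEMPERATURE,
    seed: int = 0,
) -> WorkSet:
    """Draw Crooks-consistent Gaussian work samples for a planted ΔG.

    Forward work ~ N(ΔG + βσ²/2, σ²) and reverse work
    ~ N(−ΔG + βσ²/2, σ²), the dissipated work βσ²/2 appearing
    symmetrically in both directions; this family satisfies
    P_f(W)/P_r(−W) = exp(β(W − ΔG)) exactly.  With σ = 0 all samples are
    the deterministic work values ±ΔG.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n_forward < 1 or n_reverse < 1:
        raise ValueError("need at least one sample per direction")
    beta = 1.0 / (KB * temperature)
    rng = np.random.default_rng(seed)
    dissipation = 0.5 * beta * sigma**2
    forward = rng.normal(true_dg + dissipation, sigma, size=n_forward)
    reverse = rng.normal(-true_dg + dissipation, sigma, size=n_reverse)
    return WorkSet(forward, reverse, temperature)
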