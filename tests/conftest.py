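"""Shared fixtures: toy PDB text and random consistent ΔΔG tables."""
import numpy as np
import pytest

from mutcycle.cycles import DDGTable, MutationSet, MutationSpec, WT


def atom_line(
    serial,
    name,
    resname,
    chain,
    resseq,
    x,
    y,
    z,
    occ=1.0,
    element=None,
    altloc=" ",
    icode=" ",
    record="ATOM",
):
    """Format one fixed-column PDB ATOM/HETATM record."""
    if element is None:
        element = name[0]
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record:<6s}{serial:5d} {name_field}{altloc}{resname:>3s} {chain}"
        f"{resseq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture
def two_residue_pdb():
    """Two single-heavy-atom glycines 5 Å apart (3-4-5 triangle)."""
    lines = [
        atom_line(1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0, element="C"),
        atom_line(2, "CA", "GLY", "A", 2, 3.0, 4.0, 0.0, element="C"),
        "END",
    ]
    return "\n".join(lines) + "\n"


def make_specs(*codes):
    return tuple(MutationSpec.from_code(c) for c in codes)


@pytest.fixture
def abc_specs():
    """The worked trio from the staphylococcal-nuclease study."""
    return make_specs("L37A", "G79S", "N118D")


def random_consistent_table(rng, specs, uncertainty=0.0):
    """A table over the 8 triple-box states with random per-state free
    energies; every strict-subset pair becomes an edge, so all pathway
    identities hold exactly.  Returns (table, energies dict)."""
    a, b, c = specs
    states = []
    for mask in range(8):
        members = [s for i, s in enumerate((a, b, c)) if mask & (1 << i)]
        states.append(MutationSet(members))
    energies = {s: (0.0 if s == WT else float(rng.uniform(-10, 10))) for s in states}
    table = DDGTable.from_state_energies(energies, uncertainty=uncertainty)
    return table, energies


@pytest.fixture
def consistent_table(abc_specs):
    rng = np.random.default_rng(20240917)
    table, energies = random_consistent_table(rng, abc_specs)
    return table, energies, abc_specs
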