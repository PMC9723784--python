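"""Minimal SMILES parsing into validated molecular graphs.

The compounds of interest — lignin-derived aromatics (vanillate, benzoate,
catechol, muconate ...) and plastic-derived monomers and plasticizers
(terephthalic acid, phthalates, hydroxyalkanoates ...) — are small,
single-component organic molecules.  This module therefore supports a
practical SMILES subset sufficient for them: the organic-subset elements
B, C, N, O, P, S, F, Cl, Br, I; aromatic lowercase atoms; branches; ring
closures (digits and ``%nn``); bond symbols ``- = # :``; bracket atoms with
charge and explicit hydrogen counts.  Stereo markers (``/ \\ @``) and
isotope labels are accepted and discarded, because the downstream
similarity analysis is 2-D fingerprint based.  Wildcards and
multi-component input are rejected (a largest-component mode keeps the
biggest fragment on request).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

__all__ = [
    "Atom",
    "Bond",
    "Molecule",
    "SmilesError",
    "parse_smiles",
    "kekule_aromatize",
    "validate_molecule",
]

#: Elements accepted by the parser.
SUPPORTED_ELEMENTS = frozenset(
    {"B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"}
)

#: Elements that may be written lowercase (aromatic) in SMILES.
AROMATIC_ELEMENTS = frozenset({"B", "C", "N", "O", "P", "S"})

#: Default valences per element; multivalent elements list every allowed
#: value, smallest first (the smallest feasible one is used for implicit H).
DEFAULT_VALENCES: dict[str, tuple[int, ...]] = {
    "B": (3,),
    "C": (4,),
    "N": (3,),
    "O": (2,),
    "P": (3, 5),
    "S": (2, 4, 6),
    "F": (1,),
    "Cl": (1,),
    "Br": (1,),
    "I": (1,),
}

#: Numeric bond orders used for valence accounting; an aromatic bond
#: contributes 1.5 and the per-atom total is rounded (ties toward zero,
#: which keeps ring-fusion carbons at valence 4).
BOND_ORDER_VALUE = {"single": 1.0, "double": 2.0, "triple": 3.0, "aromatic": 1.5}

BOND_SYMBOL_TO_ORDER = {"-": "single", "=": "double", "#": "triple", ":": "aromatic"}


class SmilesError(ValueError):
    """Raised for any unparseable or chemically invalid SMILES input."""


@dataclass(frozen=True)
class Atom:
    """One heavy atom of a molecular graph.

    ``explicit_h`` is the hydrogen count written in a bracket atom (``None``
    for organic-subset atoms); ``implicit_h`` is the hydrogen count actually
    carried, computed from default valences when not explicit.
    """

    index: int
    element: str
    aromatic: bool = False
    formal_charge: int = 0
    explicit_h: int | None = None
    implicit_h: int = 0


@dataclass(frozen=True)
class Bond:
    """Undirected bond between atom indices ``a`` and ``b``."""

    a: int
    b: int
    order: str  # single | double | triple | aromatic

    def key(self) -> tuple[int, int]:
        return (self.a, self.b) if self.a < self.b else (self.b, self.a)


@dataclass
class Molecule:
    """A connected molecular graph parsed from one SMILES string."""

    name: str
    smiles: str
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.atoms)

    def adjacency(self) -> dict[int, list[tuple[int, Bond]]]:
        """Neighbor lists: atom index -> [(neighbor index, bond), ...]."""
        adj: dict[int, list[tuple[int, Bond]]] = {a.index: [] for a in self.atoms}
        for b in self.bonds:
            adj[b.a].append((b.b, b))
            adj[b.b].append((b.a, b))
        return adj


# --------------------------------------------------------------------------
# tokenizer

_BRACKET_RE = re.compile(
    r"""\[
        (?P<isotope>\d+)?
        (?P<symbol>Cl|Br|[BCNOPSFI]|[bcnops])
        (?P<chiral>@{1,2})?
        (?P<hcount>H\d*)?
        (?P<charge>\+{1,2}|-{1,2}|[+-]\d+)?
    \]""",
    re.VERBOSE,
)


def _parse_bracket(token: str) -> tuple[str, bool, int, int]:
    """Return (element, aromatic, charge, explicit_h) for a bracket atom."""
    m = _BRACKET_RE.fullmatch(token)
    if m is None:
        raise SmilesError(f"unsupported bracket atom {token!r}")
    sym = m.group("symbol")
    aromatic = sym.islower()
    element = sym.capitalize() if aromatic else sym
    if element not in SUPPORTED_ELEMENTS:
        raise SmilesError(f"unsupported atom symbol {sym!r}")
    h = m.group("hcount")
    explicit_h = 0 if h is None else (1 if h == "H" else int(h[1:]))
    c = m.group("charge")
    if c is None:
        charge = 0
    elif c in ("+", "++", "-", "--"):
        charge = len(c) * (1 if c[0] == "+" else -1)
    else:
        charge = int(c)
    return element, aromatic, charge, explicit_h


# --------------------------------------------------------------------------
# parser


def parse_smiles(s: str, name: str = "", largest_component: bool = False) -> Molecule:
    """Parse a SMILES string into a validated :class:`Molecule`.

    Atoms appear in left-to-right source order.  Stereo bond markers and
    tetrahedral tags are ignored; isotope labels are ignored.  Multi-component
    input (``.``) is an error unless ``largest_component`` is set, in which
    case the fragment with the most atoms is kept.

    Raises :class:`SmilesError` on unsupported symbols, unpaired ring
    closures, unbalanced parentheses, or valence violations.
    """
    if not s or not s.strip():
        raise SmilesError("empty SMILES string")
    s = s.strip()
    if "." in s:
        if not largest_component:
            raise SmilesError(
                f"multi-component SMILES {s!r}: '.' not supported "
                "(enable largest-component mode to keep the biggest fragment)"
            )
        parts = [p for p in s.split(".") if p]
        mols = [parse_smiles(p, name) for p in parts]
        best = max(mols, key=len)
        best.smiles = s
        return best

    atoms: list[Atom] = []
    raw_h: list[int | None] = []  # explicit H or None per atom
    bonds: dict[tuple[int, int], Bond] = {}
    ring_open: dict[int, tuple[int, str | None]] = {}
    prev_stack: list[int | None] = []
    prev: int | None = None
    pending_bond: str | None = None

    def add_bond(i: int, j: int, symbol: str | None) -> None:
        if i == j:
            raise SmilesError("self-bond")
        if symbol is not None:
            order = BOND_SYMBOL_TO_ORDER[symbol]
        elif atoms[i].aromatic and atoms[j].aromatic:
            order = "aromatic"
        else:
            order = "single"
        b = Bond(i, j, order)
        if b.key() in bonds:
            raise SmilesError(f"duplicate bond between atoms {i} and {j}")
        bonds[b.key()] = b

    def add_atom(element: str, aromatic: bool, charge: int, explicit_h: int | None) -> None:
        nonlocal prev, pending_bond
        if aromatic and element not in AROMATIC_ELEMENTS:
            raise SmilesError(f"element {element} cannot be aromatic")
        idx = len(atoms)
        atoms.append(Atom(idx, element, aromatic, charge, explicit_h))
        raw_h.append(explicit_h)
        if prev is not None:
            add_bond(prev, idx, pending_bond)
        pending_bond = None
        prev = idx

    i = 0
    n = len(s)
    while i < n:
        ch = s[i]
        if ch == "[":
            j = s.find("]", i)
            if j < 0:
                raise SmilesError("unterminated bracket atom")
            add_atom(*_parse_bracket(s[i : j + 1]))
            i = j + 1
        elif ch in ("/", "\\"):
            # stereo bond marker: treat as an unspecified (single) bond
            i += 1
        elif ch in BOND_SYMBOL_TO_ORDER:
            if pending_bond is not None:
                raise SmilesError(f"two consecutive bond symbols at position {i}")
            pending_bond = ch
            i += 1
        elif ch == "(":
            if prev is None:
                raise SmilesError("branch before any atom")
            prev_stack.append(prev)
            i += 1
        elif ch == ")":
            if not prev_stack:
                raise SmilesError("unbalanced parentheses: ')' without '('")
            prev = prev_stack.pop()
            i += 1
        elif ch.isdigit() or ch == "%":
            if ch == "%":
                if i + 2 >= n or not s[i + 1 : i + 3].isdigit():
                    raise SmilesError("'%' ring closure needs two digits")
                num = int(s[i + 1 : i + 3])
                i += 3
            else:
                num = int(ch)
                i += 1
            if prev is None:
                raise SmilesError("ring closure before any atom")
            if num in ring_open:
                j_atom, sym0 = ring_open.pop(num)
                if sym0 is not None and pending_bond is not None and sym0 != pending_bond:
                    raise SmilesError(f"conflicting bond symbols on ring closure {num}")
                add_bond(j_atom, prev, sym0 or pending_bond)
            else:
                ring_open[num] = (prev, pending_bond)
            pending_bond = None
        elif ch == "*":
            raise SmilesError("wildcard atom '*' not supported")
        else:
            two = s[i : i + 2]
            if two in ("Cl", "Br"):
                add_atom(two, False, 0, None)
                i += 2
            elif ch in "BCNOPSFI":
                add_atom(ch, False, 0, None)
                i += 1
            elif ch in "bcnops":
                add_atom(ch.upper(), True, 0, None)
                i += 1
            else:
                raise SmilesError(f"unsupported symbol {ch!r} at position {i}")

    if prev_stack:
        raise SmilesError("unbalanced parentheses: unclosed '('")
    if ring_open:
        raise SmilesError(f"unpaired ring closure digit(s): {sorted(ring_open)}")
    if pending_bond is not None:
        raise SmilesError("dangling bond symbol at end of input")
    if not atoms:
        raise SmilesError("no atoms parsed")

    mol = Molecule(name=name, smiles=s, atoms=atoms, bonds=list(bonds.values()))
    _assign_implicit_h(mol)
    problems = validate_molecule(mol)
    if problems:
        raise SmilesError(f"invalid molecule {name or s!r}: " + "; ".join(problems))
    return mol


# --------------------------------------------------------------------------
# valence / implicit hydrogens


def _rounded_bond_sum(mol: Molecule, idx: int) -> int:
    atom = mol.atoms[idx]
    # lone-pair-donating aromatic heteroatoms (furan o, thiophene s,
    # pyrrole [nH]) have two sigma ring bonds: count their aromatic bonds
    # as order 1, otherwise furan/pyrrole would fail the valence check
    lone_pair_donor = atom.aromatic and (
        atom.element in ("O", "S")
        or (atom.element == "N" and (atom.explicit_h or 0) > 0)
    )
    total = 0.0
    for b in mol.bonds:
        if idx in (b.a, b.b):
            if b.order == "aromatic" and lone_pair_donor:
                total += 1.0
            else:
                total += BOND_ORDER_VALUE[b.order]
    # ties (x.5 from aromatic bonds) round down: a ring-fusion aromatic
    # carbon with three aromatic bonds (4.5) is tetravalent
    return math.ceil(total - 0.5)


def _allowed_valences(atom: Atom) -> tuple[int, ...]:
    # a formal charge shifts every allowed valence by its sign
    return tuple(v + atom.formal_charge for v in DEFAULT_VALENCES[atom.element])


def _assign_implicit_h(mol: Molecule) -> None:
    for atom in mol.atoms:
        bond_sum = _rounded_bond_sum(mol, atom.index)
        if atom.explicit_h is not None:
            h = atom.explicit_h
        else:
            h = 0
            for v in _allowed_valences(atom):
                if v >= bond_sum:
                    h = v - bond_sum
                    break
        mol.atoms[atom.index] = replace(atom, implicit_h=h)


def validate_molecule(m: Molecule) -> list[str]:
    """Check structural invariants; return a list of violations (empty = valid).

    Reported problems: bond endpoints outside the atom list, self-bonds,
    duplicate bonds, a disconnected graph, and valence violations (bond-order
    sum plus hydrogens not an allowed valence for the element and charge).
    Never mutates its argument.
    """
    problems: list[str] = []
    n = len(m.atoms)
    for i, atom in enumerate(m.atoms):
        if atom.index != i:
            problems.append(f"atom {i} carries index {atom.index}")
        if atom.element not in SUPPORTED_ELEMENTS:
            problems.append(f"atom {i}: unsupported element {atom.element!r}")
    seen: set[tuple[int, int]] = set()
    for b in m.bonds:
        if not (0 <= b.a < n and 0 <= b.b < n):
            problems.append(f"bond ({b.a},{b.b}) references a missing atom")
            continue
        if b.a == b.b:
            problems.append(f"self-bond on atom {b.a}")
        if b.key() in seen:
            problems.append(f"duplicate bond {b.key()}")
        seen.add(b.key())
    if problems:
        return problems

    # connectivity
    if n > 1:
        adj = m.adjacency()
        stack, visited = [0], {0}
        while stack:
            for j, _ in adj[stack.pop()]:
                if j not in visited:
                    visited.add(j)
                    stack.append(j)
        if len(visited) != n:
            problems.append(
                f"disconnected graph: {n - len(visited)} atom(s) unreachable"
            )

    # valence
    for atom in m.atoms:
        total = _rounded_bond_sum(m, atom.index) + atom.implicit_h
        if total not in _allowed_valences(atom):
            problems.append(
                f"valence violation on atom {atom.index} ({atom.element}"
                f"{atom.formal_charge:+d}): total {total} not in "
                f"{_allowed_valences(atom)}"
            )
    return problems


# --------------------------------------------------------------------------
# aromatization


def kekule_aromatize(m: Molecule) -> Molecule:
    """Relabel Kekulé-spelled benzene rings as aromatic.

    Every 6-membered all-carbon ring whose ring bonds alternate
    single/double is rewritten with aromatic atoms and bonds, so that
    ``C1=CC=CC=C1`` and ``c1ccccc1`` fingerprint identically.  Rings not
    matching the pattern (including already-aromatic ones) are left
    untouched; the operation is idempotent.  No general Hückel perception
    is attempted.
    """
    bond_by_key = {b.key(): b for b in m.bonds}
    adj: dict[int, list[int]] = {a.index: [] for a in m.atoms}
    for b in m.bonds:
        adj[b.a].append(b.b)
        adj[b.b].append(b.a)

    aromatic_atoms: set[int] = set()
    aromatic_bonds: set[tuple[int, int]] = set()
    for ring in _six_rings(adj):
        if not all(m.atoms[i].element == "C" for i in ring):
            continue
        ring_bonds = [
            bond_by_key[(min(ring[k], ring[(k + 1) % 6]), max(ring[k], ring[(k + 1) % 6]))]
            for k in range(6)
        ]
        orders = [b.order for b in ring_bonds]
        if set(orders) != {"single", "double"}:
            continue
        if all(orders[k] != orders[(k + 1) % 6] for k in range(6)):
            aromatic_atoms.update(ring)
            aromatic_bonds.update(b.key() for b in ring_bonds)

    if not aromatic_atoms:
        return m

    new_atoms = [
        replace(a, aromatic=True) if a.index in aromatic_atoms else a
        for a in m.atoms
    ]
    new_bonds = [
        replace(b, order="aromatic") if b.key() in aromatic_bonds else b
        for b in m.bonds
    ]
    out = Molecule(name=m.name, smiles=m.smiles, atoms=new_atoms, bonds=new_bonds)
    _assign_implicit_h(out)
    return out


def _six_rings(adj: dict[int, list[int]]) -> list[list[int]]:
    """Enumerate distinct simple cycles of exactly 6 atoms."""
    rings: list[list[int]] = []
    seen: set[frozenset[int]] = set()
    for start in sorted(adj):
        stack: list[list[int]] = [[start]]
        while stack:
            path = stack.pop()
            last = path[-1]
            for nxt in adj[last]:
                if nxt == start and len(path) == 6:
                    key = frozenset(path)
                    if key not in seen:
                        seen.add(key)
                        rings.append(path)
                elif nxt not in path and len(path) < 6 and nxt > start:
                    stack.append(path + [nxt])
    return rings
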