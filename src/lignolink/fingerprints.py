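"""Molecular fingerprints as fixed-length bit sets.

Two self-contained schemes are fully specified here so similarity values
are reproducible bit-for-bit on any platform:

``path``
    Daylight-style topological fingerprint: every simple linear path of
    1..``max_path_len`` bonds is serialized canonically and hashed to one
    bit (no per-feature folding).
``morgan``
    ECFP-style circular fingerprint: per-atom invariants are iteratively
    rehashed from neighbor environments up to ``radius``; every identifier
    from every round sets a bit (no duplicate-environment suppression —
    collisions only reduce resolution).

Two adapter schemes delegate to RDKit when it is installed:

``toolkit_default``
    RDKit's default topological (path/subtree) fingerprint.
``maccs``
    RDKit's 166-bit MACCS structural keys.  This is the literature-
    compatibility scheme: it reproduces similarity values reported for
    lignin/plastic compound pairs (e.g. monomethyl phthalate vs vanillate
    near 70%).

All hashing in the self-contained schemes uses FNV-1a 64-bit over the
UTF-8 feature string, so any independent implementation of the same rules
is bit-compatible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chem_core import Molecule

__all__ = [
    "FingerprintConfig",
    "Fingerprint",
    "FingerprintError",
    "fnv1a64",
    "enumerate_paths",
    "path_fingerprint",
    "morgan_fingerprint",
    "compute_fingerprint",
    "write_fingerprints_tsv",
]

SCHEMES = ("path", "morgan", "toolkit_default", "maccs")

_BOND_TOKEN = {"single": "-", "double": "=", "triple": "#", "aromatic": ":"}


class FingerprintError(ValueError):
    """Raised for invalid fingerprint configurations or inputs."""


@dataclass(frozen=True)
class FingerprintConfig:
    """Parameters that fully determine a fingerprint.

    ``n_bits`` is the bit-vector length (a power of two is conventional but
    any positive value works).  ``max_path_len`` applies to the path scheme,
    ``radius`` to the morgan scheme; parameters of inactive schemes are
    ignored.  ``maccs`` has a fixed key count and ignores ``n_bits``.
    """

    scheme: str = "path"
    n_bits: int = 2048
    max_path_len: int = 7
    radius: int = 2
    hash_name: str = "fnv1a64"

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise FingerprintError(
                f"unknown scheme {self.scheme!r}; choose from {SCHEMES}"
            )
        if self.n_bits < 1:
            raise FingerprintError("n_bits must be positive")
        if not 1 <= self.max_path_len <= 7:
            raise FingerprintError("max_path_len must be in 1..7")
        if self.radius < 0:
            raise FingerprintError("radius must be non-negative")
        if self.hash_name != "fnv1a64":
            raise FingerprintError("only the fnv1a64 hash is defined")


@dataclass(frozen=True)
class Fingerprint:
    bits: frozenset[int]
    config: FingerprintConfig
    molecule_name: str = ""

    def __post_init__(self) -> None:
        n = 167 if self.config.scheme == "maccs" else self.config.n_bits
        if any(not 0 <= b < n for b in self.bits):
            raise FingerprintError("bit index out of range")


# --------------------------------------------------------------------------
# stable hash

_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3


def fnv1a64(data: str | bytes) -> int:
    """FNV-1a 64-bit hash of a string (UTF-8) or byte sequence."""
    if isinstance(data, str):
        data = data.encode("utf-8")
    h = _FNV_OFFSET
    for byte in data:
        h ^= byte
        h = (h * _FNV_PRIME) & 0xFFFFFFFFFFFFFFFF
    return h


# --------------------------------------------------------------------------
# path scheme


def _atom_token(mol: Molecule, idx: int) -> str:
    a = mol.atoms[idx]
    tok = a.element.lower() if a.aromatic else a.element
    if a.formal_charge > 0:
        tok += f"+{a.formal_charge}"
    elif a.formal_charge < 0:
        tok += f"-{-a.formal_charge}"
    return tok


def enumerate_paths(mol: Molecule, max_path_len: int) -> set[str]:
    """Distinct canonical strings of all simple paths of 1..max_path_len bonds.

    Each path is serialized in both directions as alternating atom and bond
    tokens; the lexicographically smaller string represents the path.
    """
    if max_path_len < 1:
        raise FingerprintError("max_path_len must be >= 1")
    adj = mol.adjacency()
    out: set[str] = set()

    def extend(path: list[int], tokens: list[str]) -> None:
        if len(path) >= 2:
            forward = "".join(tokens)
            backward = "".join(reversed(tokens))
            out.add(min(forward, backward))
        if len(path) - 1 >= max_path_len:
            return
        for nxt, bond in adj[path[-1]]:
            if nxt in path:
                continue
            extend(
                path + [nxt],
                tokens + [_BOND_TOKEN[bond.order], _atom_token(mol, nxt)],
            )

    for a in mol.atoms:
        extend([a.index], [_atom_token(mol, a.index)])
    return out


def path_fingerprint(mol: Molecule, cfg: FingerprintConfig) -> Fingerprint:
    """Hash every distinct canonical path to one bit."""
    if cfg.scheme != "path":
        raise FingerprintError(f"config scheme is {cfg.scheme!r}, not 'path'")
    if len(mol.atoms) == 0:
        raise FingerprintError("cannot fingerprint an empty molecule")
    paths = enumerate_paths(mol, cfg.max_path_len)
    if not paths:
        # a single atom has no >=1-bond path; an empty fingerprint would make
        # every Tanimoto zero and silently poison similarity matrices
        raise FingerprintError(
            f"molecule {mol.name or mol.smiles!r} has no paths of >=1 bond "
            "(single atom); the path scheme cannot fingerprint it"
        )
    bits = frozenset(fnv1a64(p) % cfg.n_bits for p in paths)
    return Fingerprint(bits=bits, config=cfg, molecule_name=mol.name)


# --------------------------------------------------------------------------
# morgan scheme


def morgan_fingerprint(mol: Molecule, cfg: FingerprintConfig) -> Fingerprint:
    """ECFP-style circular fingerprint.

    Round-0 atom identifiers hash (element, degree, formal charge, aromatic
    flag, implicit H count); each later round rehashes an atom's previous
    identifier together with the sorted (bond token, neighbor previous
    identifier) pairs.  Identifiers from every round set bits.
    """
    if cfg.scheme != "morgan":
        raise FingerprintError(f"config scheme is {cfg.scheme!r}, not 'morgan'")
    if len(mol.atoms) == 0:
        raise FingerprintError("cannot fingerprint an empty molecule")
    adj = mol.adjacency()
    ids = {
        a.index: fnv1a64(
            f"{a.element}|{len(adj[a.index])}|{a.formal_charge}|"
            f"{int(a.aromatic)}|{a.implicit_h}"
        )
        for a in mol.atoms
    }
    all_ids = set(ids.values())
    for _ in range(cfg.radius):
        nxt: dict[int, int] = {}
        for a in mol.atoms:
            env = sorted(
                (_BOND_TOKEN[bond.order], ids[nb]) for nb, bond in adj[a.index]
            )
            payload = str(ids[a.index]) + "".join(f"|{t}{i}" for t, i in env)
            nxt[a.index] = fnv1a64(payload)
        ids = nxt
        all_ids.update(ids.values())
    bits = frozenset(i % cfg.n_bits for i in all_ids)
    return Fingerprint(bits=bits, config=cfg, molecule_name=mol.name)


# --------------------------------------------------------------------------
# dispatch + toolkit adapters


def compute_fingerprint(mol: Molecule, cfg: FingerprintConfig) -> Fingerprint:
    """Compute a fingerprint under any configured scheme.

    The ``toolkit_default`` and ``maccs`` schemes delegate to RDKit (parsing
    the molecule's source SMILES) and raise a capability error when RDKit is
    not installed.
    """
    if cfg.scheme == "path":
        return path_fingerprint(mol, cfg)
    if cfg.scheme == "morgan":
        return morgan_fingerprint(mol, cfg)
    if cfg.scheme in ("toolkit_default", "maccs"):
        return _rdkit_fingerprint(mol, cfg)
    raise FingerprintError(f"unknown scheme {cfg.scheme!r}")


def _rdkit_fingerprint(mol: Molecule, cfg: FingerprintConfig) -> Fingerprint:
    try:
        from rdkit import Chem
        from rdkit.Chem import MACCSkeys
        from rdkit.Chem.rdmolops import RDKFingerprint
    except ImportError as exc:  # pragma: no cover - rdkit present in CI env
        raise FingerprintError(
            f"scheme {cfg.scheme!r} requires the RDKit toolkit, which is not "
            "installed; use the self-contained 'path' or 'morgan' schemes"
        ) from exc
    rd = Chem.MolFromSmiles(mol.smiles)
    if rd is None:
        raise FingerprintError(
            f"RDKit could not parse SMILES {mol.smiles!r} ({mol.name})"
        )
    if cfg.scheme == "maccs":
        bv = MACCSkeys.GenMACCSKeys(rd)
    else:
        bv = RDKFingerprint(rd, fpSize=cfg.n_bits)
    bits = frozenset(bv.GetOnBits())
    return Fingerprint(bits=bits, config=cfg, molecule_name=mol.name)


# --------------------------------------------------------------------------
# export


def write_fingerprints_tsv(fps: list[Fingerprint], path) -> None:
    """Write fingerprints as TSV: molecule_name, n_bits, sorted bit indices."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("molecule_name\tn_bits\tbits\n")
        for fp in fps:
            n = 167 if fp.config.scheme == "maccs" else fp.config.n_bits
            fh.write(
                f"{fp.molecule_name}\t{n}\t"
                + ",".join(str(b) for b in sorted(fp.bits))
                + "\n"
            )
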