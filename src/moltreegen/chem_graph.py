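"""Molecular graphs as fixed-size feature maps, and valence-safe stepwise construction.

Molecules are represented two ways:

* :class:`MolecularGraph` — a padded ``max_atoms x D_node`` node-feature matrix
  plus a symmetric ``max_atoms x max_atoms x D_edge`` edge-feature tensor, the
  fixed-size "feature maps" consumed and produced by the graph auto-encoder.
* :class:`BuildState` — a mutable partial molecule (atoms, bonds, rings) used
  by the tree search, which only ever admits bond additions that keep every
  atom within its maximum valence, so any reachable state assembles into a
  sanitizable molecule.

Hydrogens are implicit throughout; stereochemistry and isotopes are stripped
during canonicalization (the generator never places stereo bonds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")


class InvalidStructureError(ValueError):
    """A structure string failed to parse or sanitize."""


class CapacityError(ValueError):
    """A molecule exceeds max_atoms or uses an element outside the vocabulary."""


class ConfigurationError(ValueError):
    """Inconsistent configuration (unknown element, bad format, ...)."""


#: Maximum bond-order sum per element at formal charge 0.
MAX_VALENCE = {
    "C": 4, "N": 3, "O": 2, "F": 1, "P": 5, "S": 6, "Cl": 1, "Br": 1, "I": 1,
}

#: Bond-order contribution of each bond type (aromatic counts 1.5).
BOND_ORDER = {"single": 1.0, "double": 2.0, "triple": 3.0, "aromatic": 1.5}

_RDKIT_BOND = {
    "single": Chem.BondType.SINGLE,
    "double": Chem.BondType.DOUBLE,
    "triple": Chem.BondType.TRIPLE,
    "aromatic": Chem.BondType.AROMATIC,
}
_BOND_NAME = {v: k for k, v in _RDKIT_BOND.items()}

_HYBRIDIZATIONS = (
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
)


@dataclass(frozen=True)
class FeatureConfig:
    """Featurization vocabulary and fixed feature-map geometry.

    Node features are the concatenation of: one-hot element over
    ``allowed_elements``, one-hot heavy-atom degree (0-5), formal charge,
    aromatic flag, and one-hot hybridization (sp / sp2 / sp3 / other).
    Edge features are a one-hot over ``bond_types``.
    """

    allowed_elements: tuple = ("C", "N", "O", "F", "P", "S", "Cl", "Br", "I")
    bond_types: tuple = ("single", "double", "triple", "aromatic")
    max_atoms: int = 38
    max_degree: int = 5

    def __post_init__(self):
        if self.max_atoms < 1:
            raise ConfigurationError("max_atoms must be >= 1")
        for vocab, name in ((self.allowed_elements, "allowed_elements"),
                            (self.bond_types, "bond_types")):
            if not vocab or len(set(vocab)) != len(vocab):
                raise ConfigurationError(f"{name} must be non-empty and duplicate-free")
        for el in self.allowed_elements:
            if el not in MAX_VALENCE:
                raise ConfigurationError(f"no valence entry for element {el!r}")

    @property
    def node_feature_spec(self):
        return (
            ("element", len(self.allowed_elements)),
            ("degree", self.max_degree + 1),
            ("formal_charge", 1),
            ("aromatic", 1),
            ("hybridization", 4),
        )

    @property
    def edge_feature_spec(self):
        return (("bond_type", len(self.bond_types)),)

    @property
    def n_node_features(self) -> int:
        return sum(d for _, d in self.node_feature_spec)

    @property
    def n_edge_features(self) -> int:
        return sum(d for _, d in self.edge_feature_spec)

    def element_index(self, symbol: str) -> int:
        try:
            return self.allowed_elements.index(symbol)
        except ValueError:
            raise CapacityError(f"element {symbol!r} not in vocabulary") from None

    def to_dict(self) -> dict:
        return {
            "allowed_elements": list(self.allowed_elements),
            "bond_types": list(self.bond_types),
            "max_atoms": int(self.max_atoms),
            "max_degree": int(self.max_degree),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls(
            allowed_elements=tuple(d["allowed_elements"]),
            bond_types=tuple(d["bond_types"]),
            max_atoms=int(d["max_atoms"]),
            max_degree=int(d.get("max_degree", 5)),
        )


@dataclass
class MolecularGraph:
    """Fixed-size feature maps for one molecule (padded beyond ``n_atoms``)."""

    node_features: np.ndarray   # (max_atoms, D_node)
    edge_features: np.ndarray   # (max_atoms, max_atoms, D_edge), symmetric
    n_atoms: int
    source: str                 # canonical SMILES

    def validate(self, config: FeatureConfig) -> None:
        na, dn = self.node_features.shape
        if na != config.max_atoms or dn != config.n_node_features:
            raise ConfigurationError("node feature shape does not match config")
        if self.edge_features.shape != (na, na, config.n_edge_features):
            raise ConfigurationError("edge feature shape does not match config")
        if not np.array_equal(self.edge_features,
                              self.edge_features.transpose(1, 0, 2)):
            raise ConfigurationError("edge feature tensor is not symmetric")
        if self.edge_features[np.arange(na), np.arange(na)].any():
            raise ConfigurationError("self-edges present")
        n = self.n_atoms
        if self.node_features[n:].any() or self.edge_features[n:].any() \
                or self.edge_features[:, n:].any():
            raise ConfigurationError("padding region is not zero")

    @property
    def adjacency(self) -> np.ndarray:
        """Binary edge-existence matrix (any bond type)."""
        return (self.edge_features.sum(axis=2) > 0).astype(float)


def canonicalize(smiles: str) -> str:
    """Canonical SMILES with stereochemistry and isotopes stripped."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidStructureError(f"cannot parse {smiles!r}")
    return _canonicalize_mol(mol)


def _canonicalize_mol(mol: Chem.Mol) -> str:
    Chem.RemoveStereochemistry(mol)
    for atom in mol.GetAtoms():
        atom.SetIsotope(0)
    return Chem.MolToSmiles(mol, isomericSmiles=False)


def _canonical_order_mol(smiles: str) -> Chem.Mol:
    """Parse and renumber atoms by RDKit's canonical ranking (seedless, deterministic)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidStructureError(f"cannot parse {smiles!r}")
    Chem.RemoveStereochemistry(mol)
    order = np.argsort(list(Chem.CanonicalRankAtoms(mol))).tolist()
    return Chem.RenumberAtoms(mol, [int(i) for i in order])


def smiles_to_graph(smiles: str, config: FeatureConfig) -> MolecularGraph:
    """Convert a SMILES string into padded node/edge feature maps.

    Raises :class:`InvalidStructureError` on parse failure and
    :class:`CapacityError` when the molecule is too large or contains an
    element outside the vocabulary (callers may skip such records).
    """
    mol = _canonical_order_mol(smiles)
    n = mol.GetNumAtoms()
    if n > config.max_atoms:
        raise CapacityError(f"{n} heavy atoms exceeds max_atoms={config.max_atoms}")

    node = np.zeros((config.max_atoms, config.n_node_features))
    edge = np.zeros((config.max_atoms, config.max_atoms, config.n_edge_features))

    n_el = len(config.allowed_elements)
    n_deg = config.max_degree + 1
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        node[i, config.element_index(atom.GetSymbol())] = 1.0
        deg = min(atom.GetDegree(), config.max_degree)
        node[i, n_el + deg] = 1.0
        node[i, n_el + n_deg] = float(atom.GetFormalCharge())
        node[i, n_el + n_deg + 1] = float(atom.GetIsAromatic())
        hyb = atom.GetHybridization()
        h = _HYBRIDIZATIONS.index(hyb) if hyb in _HYBRIDIZATIONS else 3
        node[i, n_el + n_deg + 2 + h] = 1.0

    for bond in mol.GetBonds():
        name = _BOND_NAME.get(bond.GetBondType())
        if name is None or name not in config.bond_types:
            raise CapacityError(f"bond type {bond.GetBondType()} not in vocabulary")
        k = config.bond_types.index(name)
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edge[i, j, k] = edge[j, i, k] = 1.0

    return MolecularGraph(node, edge, n, _canonicalize_mol(mol))


@dataclass
class BuildState:
    """A partial molecule under construction: atom slots, bonds, and ring sizes.

    ``atoms`` maps occupied feature-map slots to element symbols; ``bonds``
    holds ``(slot_i, slot_j, bond_type)`` triples with ``slot_i < slot_j``.
    """

    atoms: dict = field(default_factory=dict)            # slot -> element
    bonds: list = field(default_factory=list)            # (i, j, bond_type)
    ring_sizes: list = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def bond_order_sum(self, slot: int) -> float:
        return sum(BOND_ORDER[t] for i, j, t in self.bonds if slot in (i, j))

    def has_bond(self, i: int, j: int) -> bool:
        a, b = min(i, j), max(i, j)
        return any((x, y) == (a, b) for x, y, _ in self.bonds)

    def copy(self) -> "BuildState":
        return BuildState(dict(self.atoms), list(self.bonds), list(self.ring_sizes))

    def add_atom(self, slot: int, element: str) -> None:
        if slot in self.atoms:
            raise ValueError(f"slot {slot} already occupied")
        self.atoms[slot] = element

    def add_bond(self, i: int, j: int, bond_type: str) -> None:
        if i not in self.atoms or j not in self.atoms:
            raise ValueError("bond references a missing atom")
        if i == j or self.has_bond(i, j):
            raise ValueError("self-bond or duplicate bond")
        closing = self._path_length(i, j)
        self.bonds.append((min(i, j), max(i, j), bond_type))
        if closing is not None:
            self.ring_sizes.append(closing + 1)

    def _path_length(self, i: int, j: int):
        """Shortest bond-path length between i and j, or None if disconnected."""
        adj = {}
        for a, b, _ in self.bonds:
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
        frontier, seen, depth = [i], {i}, 0
        while frontier:
            depth += 1
            nxt = []
            for u in frontier:
                for v in adj.get(u, ()):
                    if v == j:
                        return depth
                    if v not in seen:
                        seen.add(v)
                        nxt.append(v)
            frontier = nxt
        return None


def valence_ok(state: BuildState, atom_slot: int, bond_type: str) -> bool:
    """True iff one more ``bond_type`` bond keeps the atom within its max valence."""
    if atom_slot not in state.atoms:
        raise ConfigurationError(f"slot {atom_slot} not in state")
    element = state.atoms[atom_slot]
    if element not in MAX_VALENCE:
        raise ConfigurationError(f"unknown element {element!r}")
    return state.bond_order_sum(atom_slot) + BOND_ORDER[bond_type] \
        <= MAX_VALENCE[element]


def assemble_molecule(state: BuildState) -> str:
    """Realize a BuildState as a canonical SMILES (implicit H fills valence).

    Sanitization failure here signals a construction bug: it is unreachable
    when every addition was gated by :func:`valence_ok`.
    """
    rw = Chem.RWMol()
    slot_to_idx = {}
    for slot in sorted(state.atoms):
        atom = Chem.Atom(state.atoms[slot])
        slot_to_idx[slot] = rw.AddAtom(atom)
    aromatic_slots = set()
    for i, j, t in state.bonds:
        rw.AddBond(slot_to_idx[i], slot_to_idx[j], _RDKIT_BOND[t])
        if t == "aromatic":
            aromatic_slots.update((i, j))
    for slot in aromatic_slots:
        rw.GetAtomWithIdx(slot_to_idx[slot]).SetIsAromatic(True)
        for b in rw.GetAtomWithIdx(slot_to_idx[slot]).GetBonds():
            if b.GetBondType() == Chem.BondType.AROMATIC:
                b.SetIsAromatic(True)
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - unreachable with valence gating
        raise InvalidStructureError(f"assembled state does not sanitize: {exc}")
    return _canonicalize_mol(mol)


def state_from_smiles(smiles: str, config: FeatureConfig | None = None) -> BuildState:
    """BuildState for a complete molecule, slots in canonical atom order."""
    mol = _canonical_order_mol(smiles)
    state = BuildState()
    for atom in mol.GetAtoms():
        state.add_atom(atom.GetIdx(), atom.GetSymbol())
    for bond in mol.GetBonds():
        state.add_bond(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(),
                       _BOND_NAME[bond.GetBondType()])
    return state


def read_molecule_file(path, fmt: str = "smiles"):
    """Read molecules from a SMILES (one per line) or SDF file.

    Returns ``(canonical_smiles_list, n_skipped)``; unparseable records are
    counted, never fatal. Unknown formats raise :class:`ConfigurationError`.
    """
    mols, skipped = [], 0
    if fmt == "smiles":
        with open(path) as fh:
            for line in fh:
                token = line.split()
                if not token:
                    continue
                try:
                    mols.append(canonicalize(token[0]))
                except InvalidStructureError:
                    skipped += 1
    elif fmt == "sdf":
        for mol in Chem.SDMolSupplier(str(path), sanitize=True):
            if mol is None:
                skipped += 1
            else:
                mols.append(_canonicalize_mol(mol))
    else:
        raise ConfigurationError(f"unknown format {fmt!r}")
    return mols, skipped


def write_smiles_file(path, smiles_list) -> None:
    with open(path, "w") as fh:
        for s in smiles_list:
            fh.write(s + "\n")
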