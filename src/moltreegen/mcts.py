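"""Monte Carlo tree search over decoded feature maps.

Molecules are grown atom-by-atom: the decoder's edge-existence probability
map defines which atom-atom connections are candidate construction moves
(probability >= ``edge_threshold``, inclusive), and the node feature map
provides per-slot atom-type distributions. Each search iteration performs
the classic four phases:

1. *Selection* — descend from the root, at each level taking the child with
   the smallest confidence-bound value ``s/n - c * sqrt(ln N / n)``
   (rewards are minimized, so the exploration term is subtracted; unvisited
   children score ``-inf`` and are therefore tried first, ties broken by
   lowest child index).
2. *Expansion* — create one child per admissible (candidate edge, bond type)
   action; the added atom's element is drawn stochastically from the node
   feature map. Every child is valence-checked; children that close a ring
   larger than ``max_ring_size`` are created but filter-flagged.
3. *Simulation* — complete the partial molecule with uniformly random
   admissible actions (rollout) and score it with the active reward.
4. *Update* — back up the effective reward along the path: rewards of
   filter-flagged molecules are multiplied by ``filter_penalty_factor``
   (making those branches unattractive under minimization), and with the
   aromatic force-cycle mode on, molecules containing an aromatic ring have
   their reward reduced by ``aromatic_bonus`` (floored at 0) so they are
   preferred during selection.

After the configured number of iterations on one feature map, the
best-scoring (lowest-reward) unflagged molecule observed at each heavy-atom
count >= ``minimum_depth`` is emitted, and the search moves to the next map.

Two chemical-realism filters flag molecules: rings larger than 7 atoms, and
a steric-strain score above ``strain_cutoff`` computed from the angle
deviations of a force-field-relaxed 3D geometry.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields

import networkx as nx
import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem
from sklearn.base import BaseEstimator

from .chem_graph import (
    BOND_ORDER,
    MAX_VALENCE,
    BuildState,
    FeatureConfig,
    assemble_molecule,
    valence_ok,
)
from .rewards import RewardSpec, largest_ring_size
from .vgae import DecodedFeatureMap, GraphVAE

logger = logging.getLogger(__name__)

#: elements that can sit in an aromatic ring seed
AROMATIC_CAPABLE = ("C", "N", "O", "S")

#: bond types the stepwise builder may place (aromatic bonds only via seeding)
GROWTH_BONDS = ("single", "double", "triple")

_IDEAL_ANGLE = {
    Chem.HybridizationType.SP: 180.0,
    Chem.HybridizationType.SP2: 120.0,
    Chem.HybridizationType.SP3: 109.471,
}


@dataclass
class MCTSConfig:
    """Search hyperparameters.

    ``minimum_depth`` is a floor on the heavy-atom count of emitted
    molecules; reference settings are 21 for distribution-learning
    benchmarking, 17 for QED optimization and 6 for penalized-logP
    optimization. ``rollout_depth`` caps the heavy-atom count reached during
    simulation (the feature map's ``max_atoms`` when None).
    """

    c: float = 1.5                       # exploration coefficient
    edge_threshold: float = 0.10         # candidate-edge probability cutoff
    iterations: int = 8000               # searches per feature map
    minimum_depth: int = 17
    aromatic_force: bool = True
    aromatic_ring_sizes: tuple = (5, 6)
    aromatic_bonus: float = 0.5
    aromatic_bonus_additive: bool = False  # raw "+0.5 to the reward" variant
    filter_penalty_factor: float = 10.0
    max_ring_size: int = 7
    rollout_depth: int | None = None
    strain_filter: bool = True
    strain_cutoff: float = 0.82
    seed: int = 0

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("c must be > 0")
        if not 0.0 <= self.edge_threshold <= 1.0:
            raise ValueError("edge_threshold must be in [0,1]")
        if self.iterations < 1 or self.minimum_depth < 1:
            raise ValueError("iterations and minimum_depth must be >= 1")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) if f.name != "aromatic_ring_sizes"
                else list(self.aromatic_ring_sizes) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "MCTSConfig":
        d = dict(d)
        if "aromatic_ring_sizes" in d:
            d["aromatic_ring_sizes"] = tuple(d["aromatic_ring_sizes"])
        return cls(**d)


class SearchNode:
    """One node of the search tree: a partial molecule with statistics.

    ``s`` is the cumulative backed-up score, ``n`` the visit count; the
    parent's visit count plays the role of ``N`` in the selection rule.
    ``children is None`` marks a not-yet-expanded node; ``[]`` a terminal
    one. Child states are materialized lazily from the parent state plus
    the stored action, which keeps wide trees affordable.
    """

    __slots__ = ("state", "parent", "s", "n", "depth", "children",
                 "filter_flag", "action")

    def __init__(self, state, parent=None, action=None, filter_flag=False):
        self.state = state
        self.parent = parent
        self.action = action
        self.s = 0.0
        self.n = 0
        self.depth = 0 if parent is None else parent.depth + 1
        self.children = None
        self.filter_flag = filter_flag


def _apply_action(state: BuildState, action):
    """Apply an action tuple in place; returns the closed ring size or None."""
    kind = action[0]
    if kind == "atom":
        _, slot, element = action
        state.add_atom(slot, element)
        return None
    if kind == "grow":
        _, i, j, bt, element = action
        target = j if j not in state.atoms else i
        state.add_atom(target, element)
        state.add_bond(i, j, bt)
        return None
    _, i, j, bt = action  # "close"
    before = len(state.ring_sizes)
    state.add_bond(i, j, bt)
    return state.ring_sizes[-1] if len(state.ring_sizes) > before else None


def _materialize(node: SearchNode, config: MCTSConfig, store: bool = True):
    """State of a lazily created node; sets the ring filter flag on closures."""
    if node.state is not None:
        return node.state
    state = node.parent.state.copy()
    ring = _apply_action(state, node.action)
    if ring is not None and ring > config.max_ring_size:
        node.filter_flag = True
    if store:
        node.state = state
    return state


def ucb_value(node: SearchNode, c: float, N: int) -> float:
    """Selection value; smaller is more attractive. Unvisited nodes get -inf."""
    if node.n == 0:
        return -math.inf
    return node.s / node.n - c * math.sqrt(math.log(N) / node.n)


def select(root: SearchNode, config: MCTSConfig) -> SearchNode:
    """Descend by minimal selection value until an expandable/terminal node."""
    node = root
    while node.children:
        N = max(node.n, 1)
        node = min(enumerate(node.children),
                   key=lambda item: (ucb_value(item[1], config.c, N), item[0]))[1]
    return node


def _path_to_root(node: SearchNode):
    path = []
    while node is not None:
        path.append(node)
        node = node.parent
    return path[::-1]


# ---------------------------------------------------------------------------
# candidate actions
# ---------------------------------------------------------------------------

def candidate_edges(fm: DecodedFeatureMap, state: BuildState,
                    threshold: float,
                    feature_config: FeatureConfig | None = None):
    """Candidate construction edges for a partial molecule.

    Returns ``(slot_i, slot_j, bond_types)`` triples for every feature-map
    edge with probability >= threshold (inclusive) that either connects a
    placed atom to an unplaced slot or closes a ring between two placed,
    not-yet-bonded atoms. Bond types are restricted to those keeping the
    placed endpoint(s) within valence.
    """
    out = []
    prob = fm.edge_prob
    m = prob.shape[0]
    for i in range(m):
        for j in range(i + 1, m):
            if prob[i, j] < threshold:
                continue
            pi, pj = i in state.atoms, j in state.atoms
            if pi and pj:
                if state.has_bond(i, j):
                    continue
                bts = [bt for bt in GROWTH_BONDS
                       if valence_ok(state, i, bt) and valence_ok(state, j, bt)]
            elif pi or pj:
                placed = i if pi else j
                bts = [bt for bt in GROWTH_BONDS if valence_ok(state, placed, bt)]
            else:
                continue
            if bts:
                out.append((i, j, bts))
    return out


class _MapContext:
    """Per-feature-map caches for the hot search path.

    Holds the thresholded pair arrays, per-slot element distributions
    conditioned on the minimum valence an element must support, and the
    slots eligible to receive the first atom. The vectorized candidate
    enumeration here matches :func:`candidate_edges` exactly.
    """

    def __init__(self, fm: DecodedFeatureMap, feature_config: FeatureConfig,
                 config: MCTSConfig):
        self.fm = fm
        self.feature_config = feature_config
        self.config = config
        prob = fm.edge_prob
        mask = np.triu(prob >= config.edge_threshold, 1)
        ii, jj = np.nonzero(mask)
        self.ii, self.jj = ii, jj
        self.first_slots = sorted(set(ii.tolist()) | set(jj.tolist()))
        self._elem = {}

    def element_sample(self, slot: int, order: float, rng):
        """Element for a new atom at ``slot`` that must support ``order``."""
        key = (slot, order)
        if key not in self._elem:
            elements = self.feature_config.allowed_elements
            scores = self.fm.node_map[slot, :len(elements)]
            feas = np.array([MAX_VALENCE[e] >= order for e in elements])
            if not feas.any():
                self._elem[key] = None
            else:
                x = np.where(feas, scores - scores[feas].max(), -np.inf)
                p = np.exp(x)
                self._elem[key] = (elements, np.cumsum(p / p.sum()))
        cached = self._elem[key]
        if cached is None:
            return None
        elements, cum = cached
        return elements[min(np.searchsorted(cum, rng.random()), len(elements) - 1)]


class _StateArrays:
    """Incremental valence/placement bookkeeping mirroring a BuildState."""

    __slots__ = ("placed", "cap", "bonded")

    def __init__(self, state: BuildState, m: int):
        self.placed = np.zeros(m, dtype=bool)
        self.cap = np.zeros(m)                      # remaining bond-order capacity
        self.bonded = np.zeros((m, m), dtype=bool)
        for slot, el in state.atoms.items():
            self.placed[slot] = True
            self.cap[slot] = MAX_VALENCE[el]
        for i, j, bt in state.bonds:
            self.bonded[i, j] = self.bonded[j, i] = True
            self.cap[i] -= BOND_ORDER[bt]
            self.cap[j] -= BOND_ORDER[bt]

    def place(self, slot: int, element: str):
        self.placed[slot] = True
        self.cap[slot] = MAX_VALENCE[element]

    def bond(self, i: int, j: int, bt: str):
        self.bonded[i, j] = self.bonded[j, i] = True
        self.cap[i] -= BOND_ORDER[bt]
        self.cap[j] -= BOND_ORDER[bt]


def _action_masks(ctx: _MapContext, arrs: _StateArrays):
    """Admissible (pair, bond-order) masks; mirrors candidate_edges."""
    ii, jj = ctx.ii, ctx.jj
    pi, pj = arrs.placed[ii], arrs.placed[jj]
    ext = pi ^ pj
    clo = pi & pj & ~arrs.bonded[ii, jj]
    cap_i, cap_j = arrs.cap[ii], arrs.cap[jj]
    cap_placed = np.where(pi, cap_i, cap_j)
    masks = {}
    for bt in GROWTH_BONDS:
        o = BOND_ORDER[bt]
        masks[bt] = (ext & (cap_placed >= o)) | (clo & (cap_i >= o) & (cap_j >= o))
    return masks


def expand(node: SearchNode, candidates, fm: DecodedFeatureMap,
           feature_config: FeatureConfig, config: MCTSConfig, rng,
           ctx: _MapContext | None = None) -> list:
    """Create the children of a selected node.

    One child per admissible (edge, bond type) action; for edges reaching an
    unplaced slot the element of the new atom is drawn stochastically from
    the node feature map. Ring closures larger than ``max_ring_size`` are
    flagged (lazily, on materialization). With no admissible action the node
    becomes terminal (``children = []``).
    """
    ctx = ctx or _MapContext(fm, feature_config, config)
    children = []
    if node.state.n_atoms == 0:
        for slot in ctx.first_slots:
            element = ctx.element_sample(slot, 1.0, rng)
            if element is None:
                continue
            st = node.state.copy()
            st.add_atom(slot, element)
            children.append(SearchNode(st, parent=node,
                                       action=("atom", slot, element)))
    else:
        atoms = node.state.atoms
        for i, j, bond_types in candidates:
            extension = (i not in atoms) or (j not in atoms)
            for bt in bond_types:
                if extension:
                    new_slot = j if j not in atoms else i
                    element = ctx.element_sample(new_slot, BOND_ORDER[bt], rng)
                    if element is None:
                        continue
                    action = ("grow", i, j, bt, element)
                else:
                    action = ("close", i, j, bt)
                children.append(SearchNode(None, parent=node, action=action,
                                           filter_flag=node.filter_flag))
    node.children = children
    return children


def _candidates_from_masks(ctx, masks):
    triples = []
    any_mask = masks["single"] | masks["double"] | masks["triple"]
    for k in np.nonzero(any_mask)[0]:
        bts = [bt for bt in GROWTH_BONDS if masks[bt][k]]
        triples.append((int(ctx.ii[k]), int(ctx.jj[k]), bts))
    return triples


def rollout(state: BuildState, fm: DecodedFeatureMap, config: MCTSConfig,
            rng, feature_config: FeatureConfig | None = None,
            reward_spec: RewardSpec | None = None,
            ctx: _MapContext | None = None):
    """Complete a partial molecule by uniformly random admissible actions.

    Returns ``(smiles, reward, ring_flag)``; the molecule always sanitizes
    because every action is valence-gated. A terminal input returns itself;
    an empty state with no candidate edges returns ``(None, None, False)``.
    """
    feature_config = feature_config or FeatureConfig()
    reward_spec = reward_spec or RewardSpec("qed")
    ctx = ctx or _MapContext(fm, feature_config, config)
    st = state.copy()
    cap = config.rollout_depth or feature_config.max_atoms
    ring_flag = False
    if st.n_atoms == 0:
        if not ctx.first_slots:
            return None, None, False
        slot = ctx.first_slots[rng.integers(len(ctx.first_slots))]
        element = ctx.element_sample(slot, 1.0, rng)
        if element is None:
            return None, None, False
        st.add_atom(slot, element)
    arrs = _StateArrays(st, feature_config.max_atoms)
    while True:
        masks = _action_masks(ctx, arrs)
        flat = np.concatenate([masks[bt] for bt in GROWTH_BONDS])
        choices = np.nonzero(flat)[0]
        if choices.size == 0:
            break
        pick = int(choices[rng.integers(choices.size)])
        bt = GROWTH_BONDS[pick // len(ctx.ii)]
        k = pick % len(ctx.ii)
        i, j = int(ctx.ii[k]), int(ctx.jj[k])
        if arrs.placed[i] and arrs.placed[j]:
            ring = _apply_action(st, ("close", i, j, bt))
            if ring is not None and ring > config.max_ring_size:
                ring_flag = True
            arrs.bond(i, j, bt)
        else:
            if st.n_atoms >= cap:
                break
            new_slot = j if not arrs.placed[j] else i
            element = ctx.element_sample(new_slot, BOND_ORDER[bt], rng)
            if element is None:
                break
            _apply_action(st, ("grow", i, j, bt, element))
            arrs.place(new_slot, element)
            arrs.bond(i, j, bt)
    if st.n_atoms == 0:
        return None, None, False
    smiles = assemble_molecule(st)
    return smiles, reward_spec.reward(smiles), ring_flag


def update(path, reward: float, config: MCTSConfig,
           flagged: bool = False, aromatic: bool = False) -> None:
    """Back the effective reward up a root-to-leaf path.

    The raw reward is multiplied by ``filter_penalty_factor`` when a realism
    filter fired, then reduced by ``aromatic_bonus`` (floored at 0) for
    aromatic-containing molecules when the aromatic force-cycle mode is on.
    """
    eff = reward * (config.filter_penalty_factor if flagged else 1.0)
    if config.aromatic_force and aromatic:
        if config.aromatic_bonus_additive:
            eff = eff - config.aromatic_bonus
        else:
            eff = max(0.0, eff - config.aromatic_bonus)
    for node in path:
        node.n += 1
        node.s += eff


# ---------------------------------------------------------------------------
# realism filters
# ---------------------------------------------------------------------------

_strain_cache: dict = {}


def strain_score(smiles: str) -> float | None:
    """Steric-strain score of a force-field-relaxed 3D geometry.

    Mean absolute deviation of all bond angles from the ideal angle of the
    central atom's hybridization, in units of 20 degrees, so an ideal
    geometry scores 0 and cubane (19.5 degree deviations at every carbon)
    scores just below 1. Returns None when no conformer can be embedded.
    """
    if smiles in _strain_cache:
        return _strain_cache[smiles]
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    mol = Chem.AddHs(mol)
    # the score is defined on a force-field-relaxed geometry, so molecules
    # outside MMFF94 coverage cannot be assessed (and embedding them is
    # pathologically slow); report them as unscorable
    if not AllChem.MMFFHasAllMoleculeParams(mol):
        _strain_cache[smiles] = None
        return None
    params = AllChem.ETKDGv3()
    params.randomSeed = 0xF00D
    params.useRandomCoords = True
    params.maxIterations = 20
    score = None
    try:
        embedded = AllChem.EmbedMolecule(mol, params) == 0
    except Exception:
        embedded = False
    if embedded:
        try:
            AllChem.MMFFOptimizeMolecule(mol, maxIters=200)
        except Exception:
            pass
        conf = mol.GetConformer()
        devs = []
        from rdkit.Chem import rdMolTransforms
        for atom in mol.GetAtoms():
            if atom.GetAtomicNum() == 1:
                continue
            ideal = _IDEAL_ANGLE.get(atom.GetHybridization())
            if ideal is None:
                continue
            nbrs = [n.GetIdx() for n in atom.GetNeighbors()]
            for a in range(len(nbrs)):
                for b in range(a + 1, len(nbrs)):
                    angle = rdMolTransforms.GetAngleDeg(
                        conf, nbrs[a], atom.GetIdx(), nbrs[b])
                    devs.append(abs(angle - ideal))
        if devs:
            score = float(np.mean(devs) / 20.0)
    else:
        logger.warning("conformer embedding failed for %s; strain flag off", smiles)
    _strain_cache[smiles] = score
    return score


def detect_filters(smiles: str, config: MCTSConfig | None = None) -> dict:
    """Realism-filter flags for a complete molecule.

    ``oversized_ring`` fires for any ring with more than 7 atoms (or the
    configured ``max_ring_size``); ``steric_strain`` fires when the strain
    score exceeds the cutoff (default 0.82). Embedding failures leave the
    strain flag off with a logged warning.
    """
    config = config or MCTSConfig()
    flags = {"oversized_ring": largest_ring_size(smiles) > config.max_ring_size,
             "steric_strain": False}
    if config.strain_filter:
        s = strain_score(smiles)
        flags["steric_strain"] = s is not None and s > config.strain_cutoff
    return flags


_aromatic_cache: dict = {}


def _has_aromatic_ring(smiles: str) -> bool:
    if smiles not in _aromatic_cache:
        mol = Chem.MolFromSmiles(smiles)
        _aromatic_cache[smiles] = bool(
            mol and any(b.GetIsAromatic() for b in mol.GetBonds()))
    return _aromatic_cache[smiles]


# ---------------------------------------------------------------------------
# aromatic seeding
# ---------------------------------------------------------------------------

def aromatic_seed(fm: DecodedFeatureMap, config: MCTSConfig,
                  feature_config: FeatureConfig | None = None) -> BuildState:
    """Seed the search with an aromatic ring if the edge map supports one.

    Looks for a simple cycle of an allowed size (5 or 6) among the
    above-threshold edges; if several exist the one with the largest summed
    edge probability wins. A 6-cycle seeds an all-carbon aromatic ring; a
    5-cycle seeds a furan-like ring with one oxygen at the slot scoring
    highest for oxygen. Returns an empty state when no cycle is available.
    """
    feature_config = feature_config or FeatureConfig()
    prob = fm.edge_prob
    mask = prob >= config.edge_threshold
    np.fill_diagonal(mask, False)
    ii, jj = np.nonzero(np.triu(mask))
    pairs = sorted(zip(ii.tolist(), jj.tolist()),
                   key=lambda e: (-prob[e[0], e[1]], e))
    # cycle search is restricted to the strongest edges so that dense maps
    # (e.g. from a barely trained decoder) stay tractable
    g = nx.Graph()
    g.add_edges_from(pairs[:60])
    best_cycle, best_weight = None, -1.0
    max_size = max(config.aromatic_ring_sizes)
    n_seen = 0
    for cycle in nx.simple_cycles(g, length_bound=max_size):
        n_seen += 1
        if n_seen > 20000:
            break
        if len(cycle) not in config.aromatic_ring_sizes:
            continue
        w = sum(prob[cycle[k], cycle[(k + 1) % len(cycle)]]
                for k in range(len(cycle)))
        key = tuple(sorted(cycle))
        if w > best_weight or (w == best_weight and key < tuple(sorted(best_cycle))):
            best_cycle, best_weight = cycle, w
    state = BuildState()
    if best_cycle is None:
        return state
    size = len(best_cycle)
    elements = ["C"] * size
    if size == 5 and "O" in feature_config.allowed_elements:
        o_idx = int(np.argmax([fm.node_map[s, feature_config.element_index("O")]
                               for s in best_cycle]))
        elements[o_idx] = "O"
    for slot, el in zip(best_cycle, elements):
        state.add_atom(slot, el)
    for k in range(size):
        state.add_bond(best_cycle[k], best_cycle[(k + 1) % size], "aromatic")
    return state


# ---------------------------------------------------------------------------
# full search
# ---------------------------------------------------------------------------

def search_feature_map(fm: DecodedFeatureMap, feature_config: FeatureConfig,
                       reward_spec: RewardSpec, config: MCTSConfig, rng):
    """Run ``config.iterations`` searches on one feature map.

    Returns ``(root, best)`` where ``best`` maps heavy-atom count to the
    lowest-reward unflagged molecule observed at that size:
    ``{depth: (reward, smiles)}``.
    """
    ctx = _MapContext(fm, feature_config, config)
    root_state = (aromatic_seed(fm, config, feature_config)
                  if config.aromatic_force else BuildState())
    root = SearchNode(root_state)
    best: dict = {}

    def record(smiles, reward, flagged):
        if smiles is None or flagged:
            return
        mol_n = Chem.MolFromSmiles(smiles).GetNumAtoms()
        if mol_n not in best or reward < best[mol_n][0]:
            best[mol_n] = (reward, smiles)

    for _ in range(config.iterations):
        leaf = select(root, config)
        sim_node = leaf
        if leaf.children is None:  # expandable
            _materialize(leaf, config)
            masks = _action_masks(ctx, _StateArrays(leaf.state,
                                                    feature_config.max_atoms))
            cands = _candidates_from_masks(ctx, masks)
            children = expand(leaf, cands, fm, feature_config, config, rng,
                              ctx=ctx)
            if children:
                sim_node = children[0]  # all unvisited: lowest-index tie-break
        sim_state = _materialize(sim_node, config, store=False) \
            if sim_node.state is None else sim_node.state
        smiles, reward, ring_flag = rollout(
            sim_state, fm, config, rng, feature_config, reward_spec, ctx=ctx)
        if smiles is None:
            update(_path_to_root(sim_node), 1.0, config)  # dead map: worst reward
            continue
        # ring sizes were checked at closure time, so only the strain filter
        # needs the assembled molecule; already-flagged molecules skip it
        flagged = sim_node.filter_flag or ring_flag
        if not flagged and config.strain_filter:
            s = strain_score(smiles)
            flagged = s is not None and s > config.strain_cutoff
        aromatic = _has_aromatic_ring(smiles) if config.aromatic_force else False
        update(_path_to_root(sim_node), reward, config,
               flagged=flagged, aromatic=aromatic)
        record(smiles, reward, flagged)
    return root, best


def generate(model: GraphVAE, reward_spec: RewardSpec, config: MCTSConfig,
             n_feature_maps: int, seed: int = 0) -> pd.DataFrame:
    """Generate molecules from ``n_feature_maps`` prior samples.

    For each feature map (latent drawn from N(0, I) and decoded), runs the
    configured number of search iterations and emits the best molecule per
    heavy-atom count for every count >= ``minimum_depth``. Returns a
    DataFrame with columns ``feature_map, depth, smiles, reward, property``;
    the whole run is reproducible under ``seed``.
    """
    rows = []
    seeds = np.random.SeedSequence(seed).spawn(n_feature_maps)
    for idx in range(n_feature_maps):
        rng = np.random.default_rng(seeds[idx])
        z = rng.standard_normal(model.latent_dim)
        fm = model.decode(z)
        _, best = search_feature_map(fm, model.feature_config_, reward_spec,
                                     config, rng)
        emitted = {d: v for d, v in best.items() if d >= config.minimum_depth}
        if not emitted:
            logger.info("feature map %d yielded no molecule at depth >= %d",
                        idx, config.minimum_depth)
        for depth in sorted(emitted):
            reward, smiles = emitted[depth]
            rows.append({"feature_map": idx, "depth": depth, "smiles": smiles,
                         "reward": reward,
                         "property": reward_spec.property_value(smiles)})
    return pd.DataFrame(rows, columns=["feature_map", "depth", "smiles",
                                       "reward", "property"])


def random_rollouts(model: GraphVAE, reward_spec: RewardSpec,
                    config: MCTSConfig, n_feature_maps: int,
                    seed: int = 0) -> pd.DataFrame:
    """Tree-free baseline: pure random rollouts from the same feature maps.

    Uses the same per-map seed stream as :func:`generate` so the comparison
    is paired; each map contributes ``config.iterations`` rollout molecules.
    """
    rows = []
    seeds = np.random.SeedSequence(seed).spawn(n_feature_maps)
    for idx in range(n_feature_maps):
        rng = np.random.default_rng(seeds[idx])
        z = rng.standard_normal(model.latent_dim)
        fm = model.decode(z)
        ctx = _MapContext(fm, model.feature_config_, config)
        root_state = (aromatic_seed(fm, config, model.feature_config_)
                      if config.aromatic_force else BuildState())
        for _ in range(config.iterations):
            smiles, reward, _flag = rollout(root_state, fm, config, rng,
                                            model.feature_config_, reward_spec,
                                            ctx=ctx)
            if smiles is None:
                continue
            rows.append({"feature_map": idx, "smiles": smiles, "reward": reward,
                         "property": reward_spec.property_value(smiles)})
    return pd.DataFrame(rows, columns=["feature_map", "smiles", "reward",
                                       "property"])


class MoleculeGenerator(BaseEstimator):
    """End-to-end generator with a scikit-learn estimator interface.

    ``fit`` trains the graph auto-encoder on a molecule corpus; ``sample``
    decodes prior draws and runs the tree search, returning the emitted
    molecules as a DataFrame. Estimator parameters mirror
    :class:`~moltreegen.vgae.GraphVAE` and :class:`MCTSConfig`.
    """

    def __init__(self, objective="qed", normalize=None, latent_dim=64,
                 hidden_dim=128, learning_rate=0.001, batch_size=64,
                 epochs=50, iterations=8000, edge_threshold=0.10, c=1.5,
                 minimum_depth=17, aromatic_force=True,
                 filter_penalty_factor=10.0, strain_filter=True,
                 strain_cutoff=0.82, max_ring_size=7, feature_config=None,
                 seed=0):
        self.objective = objective
        self.normalize = normalize
        self.latent_dim = latent_dim
        self.hidden_dim = hidden_dim
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.iterations = iterations
        self.edge_threshold = edge_threshold
        self.c = c
        self.minimum_depth = minimum_depth
        self.aromatic_force = aromatic_force
        self.filter_penalty_factor = filter_penalty_factor
        self.strain_filter = strain_filter
        self.strain_cutoff = strain_cutoff
        self.max_ring_size = max_ring_size
        self.feature_config = feature_config
        self.seed = seed

    def _mcts_config(self) -> MCTSConfig:
        return MCTSConfig(
            c=self.c, edge_threshold=self.edge_threshold,
            iterations=self.iterations, minimum_depth=self.minimum_depth,
            aromatic_force=self.aromatic_force,
            filter_penalty_factor=self.filter_penalty_factor,
            strain_filter=self.strain_filter, strain_cutoff=self.strain_cutoff,
            max_ring_size=self.max_ring_size, seed=self.seed)

    def fit(self, X, y=None):
        self.vgae_ = GraphVAE(
            latent_dim=self.latent_dim, hidden_dim=self.hidden_dim,
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            epochs=self.epochs, feature_config=self.feature_config,
            seed=self.seed)
        self.vgae_.fit(X)
        self.reward_spec_ = RewardSpec(self.objective, normalize=self.normalize)
        return self

    def sample(self, n_feature_maps: int = 1, seed: int | None = None
               ) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "vgae_")
        return generate(self.vgae_, self.reward_spec_, self._mcts_config(),
                        n_feature_maps, seed=self.seed if seed is None else seed)
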