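"""Tree-search mechanics: selection, expansion, rollout, backup, filters."""

import math

import numpy as np
import pytest
from rdkit import Chem

from moltreegen import FeatureConfig, MCTSConfig, RewardSpec
from moltreegen.chem_graph import BuildState
from moltreegen.mcts import (
    SearchNode,
    aromatic_seed,
    candidate_edges,
    detect_filters,
    expand,
    generate,
    random_rollouts,
    rollout,
    search_feature_map,
    select,
    strain_score,
    ucb_value,
    update,
    _MapContext,
    _action_masks,
    _StateArrays,
    _candidates_from_masks,
)

from conftest import toy_feature_map


def _node(s, n, parent=None):
    node = SearchNode(BuildState(), parent=parent)
    node.s, node.n = s, n
    return node


class TestUcbValue:
    def test_unvisited_is_minus_infinity(self):
        assert ucb_value(_node(0, 0), 1.5, 10) == -math.inf

    def test_arithmetic_oracle(self):
        # s=0.5, n=1, N=2, c=1.5 -> 0.5 - 1.5*sqrt(ln 2) (hand computation)
        assert ucb_value(_node(0.5, 1), 1.5, 2) == pytest.approx(
            -0.7488319167365465)

    def test_exploration_term_vanishes(self):
        """Holding the mean fixed, the value rises toward s/n as n grows."""
        values = [ucb_value(_node(0.4 * n, n), 1.5, 10**6)
                  for n in (10, 10**3, 10**5)]
        assert values == sorted(values)
        assert values[-1] == pytest.approx(0.4, abs=0.05)


class TestSelect:
    def test_all_unvisited_takes_first_child(self):
        root = _node(0, 1)
        root.children = [_node(0, 0) for _ in range(3)]
        for ch in root.children:
            ch.parent = root
        assert select(root, MCTSConfig()) is root.children[0]

    def test_matches_exhaustive_argmin_on_three_level_tree(self):
        config = MCTSConfig()
        root = _node(0, 30)
        stats = [[(1.0, 5), (0.4, 8), (0.9, 4)],
                 [(0.2, 3), (0.8, 2)]]
        root.children = [_node(s * n, n, root) for s, n in stats[0]]
        mid = root.children[1]
        mid.children = [_node(s * n, n, mid) for s, n in stats[1]]

        # brute force: explicit argmin at each level
        level1 = [s - config.c * math.sqrt(math.log(30) / n) for s, n in stats[0]]
        assert int(np.argmin(level1)) == 1
        level2 = [s - config.c * math.sqrt(math.log(8) / n) for s, n in stats[1]]
        expected = mid.children[int(np.argmin(level2))]
        assert select(root, config) is expected

    def test_depth_equals_path_length(self):
        root = _node(0, 2)
        child = SearchNode(BuildState(), parent=root)
        grand = SearchNode(BuildState(), parent=child)
        assert (root.depth, child.depth, grand.depth) == (0, 1, 2)


class TestCandidateEdges:
    def test_all_below_threshold(self, config):
        fm = toy_feature_map({(0, 1): 0.05, (1, 2): 0.09})
        state = BuildState()
        state.add_atom(0, "C")
        assert candidate_edges(fm, state, 0.10, config) == []

    def test_threshold_is_inclusive(self, config):
        fm = toy_feature_map({(0, 1): 0.10})
        state = BuildState()
        state.add_atom(0, "C")
        cands = candidate_edges(fm, state, 0.10, config)
        assert [(i, j) for i, j, _ in cands] == [(0, 1)]

    def test_matches_brute_force_enumeration(self, config, chain_map):
        """Count equals direct enumeration over the probability matrix."""
        state = BuildState()
        state.add_atom(0, "C")
        state.add_atom(1, "C")
        state.add_bond(0, 1, "single")
        cands = candidate_edges(chain_map, state, 0.10, config)
        expected = []
        prob = chain_map.edge_prob
        for i in range(5):
            for j in range(i + 1, 5):
                if prob[i, j] < 0.10:
                    continue
                placed = [k in state.atoms for k in (i, j)]
                if all(placed) and not state.has_bond(i, j):
                    expected.append((i, j))
                elif any(placed) and not all(placed):
                    expected.append((i, j))
        assert [(i, j) for i, j, _ in cands] == expected

    def test_vectorized_path_agrees(self, config, chain_map):
        state = BuildState()
        state.add_atom(1, "C")
        ctx = _MapContext(chain_map, config, MCTSConfig(edge_threshold=0.10))
        masks = _action_masks(ctx, _StateArrays(state, config.max_atoms))
        fast = _candidates_from_masks(ctx, masks)
        slow = candidate_edges(chain_map, state, 0.10, config)
        assert fast == slow

    def test_no_self_loops_or_unplaced_pairs(self, config, chain_map):
        state = BuildState()
        state.add_atom(0, "C")
        for i, j, _ in candidate_edges(chain_map, state, 0.10, config):
            assert i != j
            assert (i in state.atoms) or (j in state.atoms)


class TestExpand:
    def test_children_satisfy_invariants(self, config, chain_map):
        from moltreegen.mcts import _materialize
        cfg = MCTSConfig()
        rng = np.random.default_rng(0)
        root = SearchNode(BuildState())
        root.state.add_atom(0, "C")
        cands = candidate_edges(chain_map, root.state, 0.10, config)
        children = expand(root, cands, chain_map, config, cfg, rng)
        assert children
        for ch in children:
            st = _materialize(ch, cfg)
            assert ch.depth == root.depth + 1
            for slot, el in st.atoms.items():
                from moltreegen.chem_graph import MAX_VALENCE
                assert st.bond_order_sum(slot) <= MAX_VALENCE[el]

    def test_terminal_when_no_candidates(self, config):
        fm = toy_feature_map({})
        cfg = MCTSConfig()
        node = SearchNode(BuildState())
        node.state.add_atom(0, "C")
        children = expand(node, [], fm, config, cfg, np.random.default_rng(0))
        assert children == []
        assert node.children == []

    def test_first_atom_expansion(self, config, chain_map):
        cfg = MCTSConfig()
        root = SearchNode(BuildState())
        children = expand(root, [], chain_map, config, cfg,
                          np.random.default_rng(0))
        assert {ch.action[1] for ch in children} == {0, 1, 2, 3, 4}


class TestRollout:
    def test_terminal_state_returns_itself(self, config):
        fm = toy_feature_map({})  # no candidate edges at all
        state = BuildState()
        state.add_atom(0, "C")
        smiles, reward, flag = rollout(state, fm, MCTSConfig(),
                                       np.random.default_rng(0), config,
                                       RewardSpec("qed"))
        assert smiles == "C"
        assert not flag

    def test_seeded_trajectories_identical(self, config, chain_map):
        state = BuildState()
        state.add_atom(0, "C")
        out = [rollout(state, chain_map, MCTSConfig(),
                       np.random.default_rng(42), config, RewardSpec("qed"))
               for _ in range(2)]
        assert out[0] == out[1]

    def test_molecules_always_sanitize(self, config, chain_map):
        state = BuildState()
        state.add_atom(0, "C")
        for seed in range(25):
            smiles, _, _ = rollout(state, chain_map, MCTSConfig(),
                                   np.random.default_rng(seed), config,
                                   RewardSpec("qed"))
            assert Chem.MolFromSmiles(smiles) is not None

    def test_respects_rollout_depth_cap(self, config, chain_map):
        state = BuildState()
        state.add_atom(0, "C")
        cfg = MCTSConfig(rollout_depth=3)
        for seed in range(10):
            smiles, _, _ = rollout(state, chain_map, cfg,
                                   np.random.default_rng(seed), config,
                                   RewardSpec("qed"))
            assert Chem.MolFromSmiles(smiles).GetNumAtoms() <= 3


class TestUpdate:
    def _path(self, k=3):
        nodes = [SearchNode(BuildState())]
        for _ in range(k - 1):
            nodes.append(SearchNode(BuildState(), parent=nodes[-1]))
        return nodes

    def test_single_update_on_fresh_path(self):
        path = self._path()
        update(path, 0.3, MCTSConfig(aromatic_force=False))
        assert all(n.n == 1 and n.s == pytest.approx(0.3) for n in path)

    def test_flagged_reward_scaled_tenfold(self):
        plain, flagged = self._path(), self._path()
        cfg = MCTSConfig(aromatic_force=False)
        update(plain, 0.07, cfg, flagged=False)
        update(flagged, 0.07, cfg, flagged=True)
        assert flagged[0].s == pytest.approx(10 * plain[0].s)

    def test_aromatic_bonus_floored_at_zero(self):
        path = self._path()
        update(path, 0.2, MCTSConfig(aromatic_force=True), aromatic=True)
        assert path[0].s == 0.0  # max(0, 0.2 - 0.5)

    def test_visit_conservation_through_search(self, tiny_model, config):
        cfg = MCTSConfig(iterations=40, minimum_depth=2, strain_filter=False,
                         seed=0)
        fm = tiny_model.decode(tiny_model.sample_prior(seed=3))
        root, _ = search_feature_map(fm, config, RewardSpec("qed"), cfg,
                                     np.random.default_rng(0))
        assert root.n == 40
        assert root.n == sum(ch.n for ch in root.children) + \
            (0 if root.children else 40)


class TestBanditBehavior:
    def _two_arm_visits(self, rewards, flags, iterations=200):
        """Select/update loop with deterministic arm rewards."""
        cfg = MCTSConfig(aromatic_force=False)
        root = SearchNode(BuildState())
        root.children = [SearchNode(BuildState(), parent=root),
                         SearchNode(BuildState(), parent=root)]
        for _ in range(iterations):
            leaf = select(root, cfg)
            arm = root.children.index(leaf)
            update([root, leaf], rewards[arm], cfg, flagged=flags[arm])
        return [ch.n for ch in root.children]

    def test_visits_concentrate_on_lower_mean_reward(self):
        """Matches the exact two-arm bandit optimum (lower reward wins)."""
        visits = self._two_arm_visits([0.8, 0.2], [False, False])
        assert visits[1] / sum(visits) > 0.6

    def test_filter_penalty_suppresses_flagged_twin(self):
        visits = self._two_arm_visits([0.1, 0.1], [True, False])
        assert visits[0] < visits[1]


class TestFilters:
    def test_cyclooctane_oversized_ring(self):
        flags = detect_filters("C1CCCCCCC1")
        assert flags["oversized_ring"]

    def test_benzene_clean(self):
        flags = detect_filters("c1ccccc1")
        assert not flags["oversized_ring"]
        assert not flags["steric_strain"]

    def test_cubane_strained(self):
        # strain oracle: cubane's sp3 angles deviate ~19.5 deg -> score ~0.88
        flags = detect_filters("C12C3C4C1C5C2C3C45")
        assert flags["steric_strain"]

    def test_strain_score_zero_for_benzene(self):
        assert strain_score("c1ccccc1") == pytest.approx(0.0, abs=0.05)


class TestAromaticSeed:
    def test_six_cycle_seeds_benzene_like_ring(self, config):
        ring = {(i, (i + 1) % 6): 0.9 for i in range(6)}
        fm = toy_feature_map(ring, n_slots=8)
        state = aromatic_seed(fm, MCTSConfig(), config)
        assert state.n_atoms == 6
        from moltreegen.chem_graph import assemble_molecule
        assert assemble_molecule(state) == "c1ccccc1"

    def test_no_cycle_returns_empty_state(self, config, chain_map):
        state = aromatic_seed(chain_map, MCTSConfig(), config)
        assert state.n_atoms == 0

    def test_seeded_ring_size_always_allowed(self, config, tiny_model):
        cfg = MCTSConfig()
        for s in range(6):
            fm = tiny_model.decode(tiny_model.sample_prior(seed=s))
            state = aromatic_seed(fm, cfg, config)
            if state.ring_sizes:
                assert state.ring_sizes[0] in {5, 6}

    def test_five_cycle_seeds_furan_like_ring(self, config):
        ring = {(i, (i + 1) % 5): 0.9 for i in range(5)}
        fm = toy_feature_map(ring, n_slots=6)
        state = aromatic_seed(fm, MCTSConfig(), config)
        assert state.n_atoms == 5
        assert sorted(state.atoms.values()) == ["C", "C", "C", "C", "O"]


class TestGenerate:
    def test_emitted_molecules_sanitize_and_respect_depth(self, tiny_model):
        cfg = MCTSConfig(iterations=30, minimum_depth=4, strain_filter=False,
                         seed=0)
        table = generate(tiny_model, RewardSpec("qed"), cfg, 3, seed=5)
        for _, row in table.iterrows():
            mol = Chem.MolFromSmiles(row["smiles"])
            assert mol is not None
            assert mol.GetNumAtoms() >= 4
            assert mol.GetNumAtoms() == row["depth"]

    def test_equal_seeds_identical_output(self, tiny_model):
        cfg = MCTSConfig(iterations=25, minimum_depth=3, strain_filter=False,
                         seed=0)
        a = generate(tiny_model, RewardSpec("qed"), cfg, 2, seed=11)
        b = generate(tiny_model, RewardSpec("qed"), cfg, 2, seed=11)
        assert a.equals(b)

    def test_aromatic_force_raises_aromatic_fraction(self, tiny_model):
        """Paired comparison over 20 feature maps, same seeds."""
        def frac_aromatic(force):
            cfg = MCTSConfig(iterations=25, minimum_depth=3,
                             aromatic_force=force, strain_filter=False, seed=0)
            table = generate(tiny_model, RewardSpec("qed"), cfg, 20, seed=3)
            if table.empty:
                return 0.0
            flags = [any(b.GetIsAromatic()
                         for b in Chem.MolFromSmiles(s).GetBonds())
                     for s in table["smiles"]]
            return float(np.mean(flags))
        assert frac_aromatic(True) >= frac_aromatic(False)

    def test_random_rollout_baseline_is_paired(self, tiny_model):
        cfg = MCTSConfig(iterations=10, minimum_depth=3, strain_filter=False,
                         seed=0)
        table = random_rollouts(tiny_model, RewardSpec("qed"), cfg, 2, seed=4)
        assert set(table["feature_map"]) <= {0, 1}
        assert all(Chem.MolFromSmiles(s) is not None for s in table["smiles"])


class TestMCTSConfig:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            MCTSConfig(c=0)
        with pytest.raises(ValueError):
            MCTSConfig(edge_threshold=1.5)
        with pytest.raises(ValueError):
            MCTSConfig(iterations=0)

    def test_reference_defaults(self):
        cfg = MCTSConfig()
        assert cfg.c == 1.5
        assert cfg.edge_threshold == 0.10
        assert cfg.iterations == 8000
        assert cfg.filter_penalty_factor == 10.0
        assert cfg.aromatic_bonus == 0.5
        assert cfg.max_ring_size == 7
        assert cfg.strain_cutoff == 0.82

    def test_dict_round_trip(self):
        cfg = MCTSConfig(iterations=123, aromatic_ring_sizes=(5,))
        assert MCTSConfig.from_dict(cfg.to_dict()) == cfg
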