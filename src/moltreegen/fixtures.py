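"""Seeded fixture-molecule generation.

Stands in for large public training corpora in tests and desk-scale runs:
small, valid, drug-like molecules are enumerated by combinatorial
decoration of scaffold templates (benzene, pyridine, furan, cyclohexane,
linear and branched alkanes) with common substituents (halogens, hydroxyl,
amine, carbonyl-bearing groups, methyl, ...). Enumeration order is fixed,
so a seed fully determines the returned subset; every output sanitizes,
is at most 20 heavy atoms, and canonical forms are pairwise distinct.
"""

from __future__ import annotations

import itertools

import numpy as np

from .chem_graph import CapacityError, canonicalize

#: scaffold templates with one or two substitution points
MONO_TEMPLATES = (
    "c1ccc({0})cc1",        # benzene
    "c1ccc({0})nc1",        # pyridine
    "c1ccc({0})o1",         # furan
    "C1CCC({0})CC1",        # cyclohexane
    "CCC({0})CC",           # pentane, 3-substituted
    "CC(C)C({0})C",         # branched alkane
)
DI_TEMPLATES = (
    "c1cc({0})ccc1{1}",     # benzene, para
    "c1cc({0})cc({1})c1",   # benzene, meta
    "CC({0})CC({1})C",      # branched alkane
    "C1CC({0})CCC1{1}",     # cyclohexane, 1,3
)

#: substituent fragments (as written inside a SMILES branch)
SUBSTITUENTS = (
    "F", "Cl", "Br", "I", "O", "N", "C", "CC",
    "C=O", "C(=O)O", "C(=O)C", "OC", "C#N", "CO", "N(C)C", "S",
)


def _enumerate_all():
    """All decorated scaffolds in fixed order, canonical and de-duplicated."""
    seen, ordered = set(), []
    raw = itertools.chain(
        (t.format(s) for t in MONO_TEMPLATES for s in SUBSTITUENTS),
        (t.format(a, b) for t in DI_TEMPLATES
         for a in SUBSTITUENTS for b in SUBSTITUENTS),
    )
    for smi in raw:
        can = canonicalize(smi)
        if can not in seen:
            seen.add(can)
            ordered.append(can)
    return ordered


def make_fixture_set(n: int, seed: int = 0) -> list:
    """Deterministically pick ``n`` distinct fixture molecules.

    Raises :class:`CapacityError` when ``n`` exceeds the enumerable space,
    stating the maximum available.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pool = _enumerate_all()
    if n > len(pool):
        raise CapacityError(
            f"only {len(pool)} distinct fixture molecules are enumerable")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    return [pool[i] for i in order[:n]]
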