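"""Property scores and the [0,1] minimization rewards that drive the tree search.

Two built-in objectives, both framed so that *lower reward is better*
(the search selects the node with the smallest confidence-bound value):

* ``qed``   — reward = 1 - QED(m), QED being the quantitative estimate of
  drug-likeness in [0,1].
* ``plogp`` — reward = 1 - sigmoid(penalized logP(m)), where
  penalized logP = logP(m) - SA(m) - RingPenalty(m), with
  RingPenalty = max(0, largest ring size - 6). An alternative variant
  z-score-normalizes each term by drug-like-corpus statistics
  (``normalize="zinc"``).

SA is the Ertl-Schuffenhauer synthetic-accessibility score in [1, 10]
(fragment contributions plus complexity penalties), taken from the RDKit
contrib implementation with its pinned fragment-score table.
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, QED, RDConfig
from scipy.special import expit

from .chem_graph import InvalidStructureError

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib module)

#: Drug-like corpus statistics for the z-score-normalized penalized-logP
#: variant (the JT-VAE lineage convention on the ZINC drug-like subset).
ZINC_NORMALIZATION = {
    "logp": (2.4570953396190123, 1.434324401111988),
    "sa": (3.0525811293166134, 0.8335207024513095),
    "ring": (0.0485696876403053, 0.2860212110245455),
}


def _mol(smiles_or_mol):
    if isinstance(smiles_or_mol, Chem.Mol):
        return smiles_or_mol
    mol = Chem.MolFromSmiles(smiles_or_mol)
    if mol is None:
        raise InvalidStructureError(f"cannot parse {smiles_or_mol!r}")
    return mol


def sa_score(mol) -> float:
    """Ertl-Schuffenhauer synthetic-accessibility score, clamped to [1, 10]."""
    return float(np.clip(sascorer.calculateScore(_mol(mol)), 1.0, 10.0))


def qed(mol) -> float:
    return float(QED.qed(_mol(mol)))


def logp(mol) -> float:
    return float(Crippen.MolLogP(_mol(mol)))


def largest_ring_size(mol) -> int:
    m = _mol(mol)  # keep the Mol alive while its RingInfo is used
    rings = m.GetRingInfo().AtomRings()
    return max((len(r) for r in rings), default=0)


def ring_penalty(mol) -> float:
    """max(0, largest ring size - 6); exactly 0 for acyclic molecules."""
    return float(max(0, largest_ring_size(mol) - 6))


def penalized_logp(mol, normalize: str | None = None) -> float:
    """logP - SA - RingPenalty (optionally z-score normalized per term)."""
    m = _mol(mol)
    lp, sa, rp = logp(m), sa_score(m), ring_penalty(m)
    if normalize is None:
        return lp - sa - rp
    if normalize == "zinc":
        (lm, ls), (sm, ss), (rm, rs) = (ZINC_NORMALIZATION[k]
                                        for k in ("logp", "sa", "ring"))
        return (lp - lm) / ls - (sa - sm) / ss - (rp - rm) / rs
    raise ValueError(f"unknown normalization {normalize!r}")


def scale_penalized_logp(x: float) -> float:
    """Logistic squashing of penalized logP to (0,1); strictly increasing."""
    return float(expit(x))


def qed_reward(mol) -> float:
    """1 - QED; in [0,1], lower is more drug-like."""
    return 1.0 - qed(mol)


def plogp_reward(mol, normalize: str | None = None) -> float:
    """1 - sigmoid(penalized logP); in (0,1), lower is better."""
    return 1.0 - scale_penalized_logp(penalized_logp(mol, normalize=normalize))


@dataclass
class PropertyScores:
    qed: float
    logp: float
    sa_score: float
    ring_penalty: float
    penalized_logp: float
    scaled_penalized_logp: float

    @classmethod
    def compute(cls, mol) -> "PropertyScores":
        m = _mol(mol)
        plp = penalized_logp(m)
        return cls(qed=qed(m), logp=logp(m), sa_score=sa_score(m),
                   ring_penalty=ring_penalty(m), penalized_logp=plp,
                   scaled_penalized_logp=scale_penalized_logp(plp))


@dataclass
class RewardSpec:
    """Which property is optimized and how it maps to a [0,1] reward.

    ``objective`` is ``"qed"``, ``"plogp"`` or ``"custom"``; custom objectives
    supply their own callable mapping a SMILES to a reward in [0,1]. The
    direction is always minimization: lower reward = better molecule.
    """

    objective: str = "qed"
    normalize: str | None = None          # plogp variant switch
    custom_fn: object = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if self.objective not in ("qed", "plogp", "custom"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.objective == "custom" and not callable(self.custom_fn):
            raise ValueError("custom objective requires a callable custom_fn")

    def reward(self, smiles: str) -> float:
        """Reward for a complete molecule; cached by structure string."""
        if smiles in self._cache:
            return self._cache[smiles]
        if self.objective == "qed":
            r = qed_reward(smiles)
        elif self.objective == "plogp":
            r = plogp_reward(smiles, normalize=self.normalize)
        else:
            r = float(self.custom_fn(smiles))
        self._cache[smiles] = r
        return r

    def property_value(self, smiles: str) -> float:
        """The optimized property on its natural scale (higher = better)."""
        if self.objective == "qed":
            return qed(smiles)
        if self.objective == "plogp":
            return scale_penalized_logp(
                penalized_logp(smiles, normalize=self.normalize))
        return 1.0 - self.reward(smiles)


def property_table(smiles_list) -> "pandas.DataFrame":
    """Per-molecule property scores as a DataFrame (CSV-exportable)."""
    import pandas as pd

    rows = []
    for s in smiles_list:
        ps = PropertyScores.compute(s)
        rows.append({"smiles": s, **ps.__dict__})
    return pd.DataFrame(rows)
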