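"""Distribution-learning metrics, statistical tests, drug-likeness filters,
and chemical-space projection for generated molecule sets.

The headline metrics follow the standard distribution-learning benchmark
definitions: validity (fraction of structures that parse and sanitize),
uniqueness (distinct canonical forms among the valid ones), novelty
(fraction of unique valid molecules absent from the reference corpus), and
a KL-divergence score — the mean of ``exp(-KL)`` between reference and
generated histograms over a panel of physicochemical descriptors, so 1
means the generated set reproduces the reference property distributions.
An optional Fréchet ChemNet Distance adapter is used only when an external
scorer package is importable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, GraphDescriptors, Lipinski
from rdkit import DataStructs
from scipy import stats

from .chem_graph import ConfigurationError
from .rewards import largest_ring_size, logp, sa_score

logger = logging.getLogger(__name__)

_SMOOTH = 1e-10


@dataclass
class BenchmarkReport:
    """Distribution-learning scores for a generated set vs a reference set."""

    validity: float
    uniqueness: float
    novelty: float
    kl_divergence_score: float | None
    fcd_score: float | None
    n_generated: int
    n_valid: int
    n_unique: int
    n_novel: int

    def __post_init__(self):
        if not (self.n_novel <= self.n_unique <= self.n_valid
                <= self.n_generated):
            raise ValueError("count monotonicity violated")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _valid_canonical(smiles_list):
    out = []
    for s in smiles_list:
        mol = Chem.MolFromSmiles(s)
        if mol is not None:
            Chem.RemoveStereochemistry(mol)
            out.append(Chem.MolToSmiles(mol, isomericSmiles=False))
    return out


# ---------------------------------------------------------------------------
# KL-divergence descriptor score
# ---------------------------------------------------------------------------

#: (name, callable, discrete?) descriptor panel
DESCRIPTOR_PANEL = (
    ("molecular_weight", Descriptors.MolWt, False),
    ("logp", Crippen.MolLogP, False),
    ("bertz_complexity", GraphDescriptors.BertzCT, False),
    ("tpsa", Descriptors.TPSA, False),
    ("num_h_donors", Lipinski.NumHDonors, True),
    ("num_h_acceptors", Lipinski.NumHAcceptors, True),
    ("num_rotatable_bonds", Lipinski.NumRotatableBonds, True),
    ("num_aliphatic_rings", Lipinski.NumAliphaticRings, True),
    ("num_aromatic_rings", Lipinski.NumAromaticRings, True),
)


def histogram_kl(p_counts, q_counts) -> float:
    """KL(P||Q) between two aligned histograms, with smoothing on both."""
    p = np.asarray(p_counts, dtype=float) + _SMOOTH
    q = np.asarray(q_counts, dtype=float) + _SMOOTH
    return float(stats.entropy(p / p.sum(), q / q.sum()))


def continuous_kl(reference, generated, grid_points: int = 1000) -> float:
    """KL between kernel-density estimates evaluated on a shared grid.

    Falls back to shared-bin histograms when a sample is degenerate
    (single-valued), so no division by zero can occur.
    """
    ref = np.asarray(reference, dtype=float)
    gen = np.asarray(generated, dtype=float)
    lo = min(ref.min(), gen.min())
    hi = max(ref.max(), gen.max())
    if hi == lo:
        return 0.0
    grid = np.linspace(lo, hi, grid_points)
    try:
        p = stats.gaussian_kde(ref)(grid)
        q = stats.gaussian_kde(gen)(grid)
    except (np.linalg.LinAlgError, ValueError):
        bins = np.linspace(lo, hi, 41)
        p, _ = np.histogram(ref, bins=bins)
        q, _ = np.histogram(gen, bins=bins)
    return histogram_kl(p, q)


def discrete_kl(reference, generated) -> float:
    """KL between integer-valued descriptor histograms on shared bins."""
    ref = np.asarray(reference, dtype=int)
    gen = np.asarray(generated, dtype=int)
    lo = min(ref.min(), gen.min())
    hi = max(ref.max(), gen.max())
    bins = np.arange(lo, hi + 2) - 0.5
    p, _ = np.histogram(ref, bins=bins)
    q, _ = np.histogram(gen, bins=bins)
    return histogram_kl(p, q)


def _internal_similarities(smiles_list, max_mols: int = 500):
    """Max Tanimoto similarity of each molecule to the rest of its own set."""
    subset = smiles_list[:max_mols]
    fps = [AllChem.GetMorganFingerprintAsBitVect(Chem.MolFromSmiles(s), 2, 2048)
           for s in subset]
    sims = []
    for i, fp in enumerate(fps):
        others = fps[:i] + fps[i + 1:]
        if not others:
            continue
        sims.append(max(DataStructs.BulkTanimotoSimilarity(fp, others)))
    return np.asarray(sims)


def kl_score(generated, reference, panel=DESCRIPTOR_PANEL,
             include_similarity: bool = True) -> float:
    """Mean of exp(-KL) over the descriptor panel; in (0, 1], 1 = identical.

    Both sets must contribute at least 10 valid molecules.
    """
    gen = _valid_canonical(list(generated))
    ref = _valid_canonical(list(reference))
    if len(gen) < 10 or len(ref) < 10:
        raise ConfigurationError("kl_score needs >= 10 valid molecules per set")
    gen_mols = [Chem.MolFromSmiles(s) for s in gen]
    ref_mols = [Chem.MolFromSmiles(s) for s in ref]
    kls = []
    for _name, fn, discrete in panel:
        gv = [fn(m) for m in gen_mols]
        rv = [fn(m) for m in ref_mols]
        kls.append(discrete_kl(rv, gv) if discrete else continuous_kl(rv, gv))
    if include_similarity:
        kls.append(continuous_kl(_internal_similarities(ref),
                                 _internal_similarities(gen)))
    return float(np.mean(np.exp(-np.asarray(kls))))


def _fcd_score(generated, reference):
    """Fréchet ChemNet Distance via an external scorer, if installed."""
    try:
        import fcd  # type: ignore
    except ImportError:
        return None
    try:  # pragma: no cover - exercised only with the optional dependency
        model = fcd.load_ref_model()
        act_g = fcd.get_predictions(model, generated)
        act_r = fcd.get_predictions(model, reference)
        d = fcd.calculate_frechet_distance(
            act_g.mean(0), np.cov(act_g.T), act_r.mean(0), np.cov(act_r.T))
        return float(np.exp(-0.2 * d))
    except Exception as exc:
        logger.warning("FCD adapter failed: %s", exc)
        return None


def distribution_benchmark(generated, reference) -> BenchmarkReport:
    """Validity / uniqueness / novelty / KL score for a generated set."""
    generated = list(generated)
    reference = list(reference)
    if not generated or not reference:
        raise ConfigurationError("generated and reference sets must be non-empty")
    valid = _valid_canonical(generated)
    unique = sorted(set(valid))
    ref_canonical = set(_valid_canonical(reference))
    novel = [s for s in unique if s not in ref_canonical]
    kl = None
    if len(valid) >= 10 and len(ref_canonical) >= 10:
        kl = kl_score(valid, sorted(ref_canonical))
    return BenchmarkReport(
        validity=len(valid) / len(generated),
        uniqueness=len(unique) / len(valid) if valid else 0.0,
        novelty=len(novel) / len(unique) if unique else 0.0,
        kl_divergence_score=kl,
        fcd_score=_fcd_score(valid, list(ref_canonical)) if valid else None,
        n_generated=len(generated), n_valid=len(valid),
        n_unique=len(unique), n_novel=len(novel))


# ---------------------------------------------------------------------------
# statistical comparison
# ---------------------------------------------------------------------------

def mann_whitney_bonferroni(sample_a, sample_b, n_comparisons: int = 1,
                            subsample_size: int | None = None,
                            seed: int = 0):
    """Two-sided Mann-Whitney U test with Bonferroni correction.

    Small tie-free samples use the exact null distribution; larger or tied
    samples use the normal approximation with tie correction (scipy's
    ``method="auto"``). ``subsample_size`` draws seeded random subsamples
    first (the reference protocol compares 500-molecule subsamples of
    3,000-molecule sets). Returns ``(U, p_raw, p_adjusted)`` with
    ``p_adjusted = min(1, p_raw * n_comparisons)``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ConfigurationError("samples must be non-empty")
    if subsample_size is not None:
        rng = np.random.default_rng(seed)
        if a.size > subsample_size:
            a = rng.choice(a, subsample_size, replace=False)
        if b.size > subsample_size:
            b = rng.choice(b, subsample_size, replace=False)
    if np.ptp(np.concatenate([a, b])) == 0:
        warnings.warn("all observations tied; p-value set to 1")
        return a.size * b.size / 2.0, 1.0, 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    p_adj = min(1.0, float(res.pvalue) * n_comparisons)
    return float(res.statistic), float(res.pvalue), p_adj


# ---------------------------------------------------------------------------
# drug-likeness filtering
# ---------------------------------------------------------------------------

def _passes_lipinski(mol) -> bool:
    return (Descriptors.MolWt(mol) <= 500 and Crippen.MolLogP(mol) <= 5
            and Lipinski.NumHDonors(mol) <= 5
            and Lipinski.NumHAcceptors(mol) <= 10)


def druglike_filter(smiles_list, strain_cutoff: float = 0.82):
    """Keep molecules passing all drug-likeness rules.

    Rules: Lipinski's rule of five; synthetic-accessibility score <= 5;
    steric strain below the cutoff; logP <= 5; largest ring <= 6 atoms.
    Returns ``(survivors, failure_counts)`` where ``failure_counts`` tallies
    per-rule failures (one molecule may fail several rules).
    """
    from .mcts import strain_score  # local import to avoid a cycle

    failures = {"lipinski": 0, "sa_score": 0, "steric_strain": 0,
                "logp": 0, "ring_size": 0}
    survivors = []
    for s in smiles_list:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            raise ConfigurationError(f"cannot parse {s!r}")
        ok = True
        if not _passes_lipinski(mol):
            failures["lipinski"] += 1
            ok = False
        if sa_score(mol) > 5:
            failures["sa_score"] += 1
            ok = False
        strain = strain_score(s)
        if strain is not None and strain >= strain_cutoff:
            failures["steric_strain"] += 1
            ok = False
        if logp(mol) > 5:
            failures["logp"] += 1
            ok = False
        if largest_ring_size(mol) > 6:
            failures["ring_size"] += 1
            ok = False
        if ok:
            survivors.append(s)
    return survivors, failures


# ---------------------------------------------------------------------------
# chemical-space projection
# ---------------------------------------------------------------------------

def fingerprint_matrix(smiles_list, radius: int = 2, n_bits: int = 2048
                       ) -> np.ndarray:
    """Circular (ECFP-style) fingerprints of diameter ``2*radius`` as 0/1 rows."""
    rows = []
    for s in smiles_list:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            raise ConfigurationError(f"cannot parse {s!r}")
        fp = AllChem.GetMorganFingerprintAsBitVect(mol, radius, nBits=n_bits)
        arr = np.zeros(n_bits, dtype=np.uint8)
        DataStructs.ConvertToNumpyArray(fp, arr)
        rows.append(arr)
    return np.asarray(rows)


def chemical_space_map(smiles_list, seed: int = 0) -> np.ndarray:
    """2-D embedding of 2048-bit diameter-4 circular fingerprints via UMAP."""
    smiles_list = list(smiles_list)
    if len(smiles_list) < 5:
        raise ConfigurationError("need at least 5 molecules to embed")
    import umap

    fps = fingerprint_matrix(smiles_list)
    n_neighbors = min(15, len(smiles_list) - 1)
    if n_neighbors < 15:
        logger.warning("reducing n_neighbors to %d for %d molecules",
                       n_neighbors, len(smiles_list))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                            random_state=seed, metric="jaccard")
        coords = reducer.fit_transform(fps)
    return np.asarray(coords, dtype=float)
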