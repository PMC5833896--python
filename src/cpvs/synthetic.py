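"""Synthetic molecule libraries and a surrogate docking oracle.

The generator stands in for a real screening library plus docking engine so
the whole pipeline can be exercised without downloads or licensed software.
It emulates two things the method relies on:

* a library of small organic molecules as valence-respecting heavy-atom
  graphs (random growth, optional branches and ring closures);
* a docking-score distribution that is right-skewed — most molecules fit a
  receptor poorly, a few fit well — and partially predictable from the
  molecules' signature features, so the learner has real signal to find.

Scores are built from a latent linear function of signature counts pushed
through a bounded right-skew transform plus id-keyed Gaussian noise, so
the same molecule always gets the same score regardless of query order and
of whether it is scored by the iterative screen or the exhaustive
baseline.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.special import ndtr

from .errors import LibrarySpecError
from .molecules import Atom, Bond, MoleculeGraph, MoleculeLibrary
from .signatures import (SignatureVocabulary, build_vocabulary,
                         molecule_signature_counts, signature_matrix)

#: Valences used during generation: neutral organic chemistry only, so every
#: generated molecule survives a round trip through standard toolkits.
GROWTH_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1}


@dataclass
class LibrarySpec:
    """Recipe for a random molecule library."""

    n_molecules: int = 1000
    atom_count_range: tuple[int, int] = (4, 20)   # uniform, inclusive
    element_weights: dict[str, float] = field(default_factory=lambda: {
        "C": 0.70, "N": 0.12, "O": 0.12, "S": 0.03, "F": 0.015, "Cl": 0.015})
    branch_probability: float = 0.3
    ring_closure_probability: float = 0.3
    double_bond_probability: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.atom_count_range
        if not 1 <= lo <= hi:
            raise LibrarySpecError(f"bad atom count range {self.atom_count_range}")
        unknown = set(self.element_weights) - set(GROWTH_VALENCE)
        if unknown:
            raise LibrarySpecError(f"elements without growth valence: {unknown}")
        if hi > 2 and all(GROWTH_VALENCE[e] < 2
                          for e, w in self.element_weights.items() if w > 0):
            raise LibrarySpecError(
                "all weighted elements are monovalent; cannot grow chains")


def _grow_molecule(rng: np.random.Generator, spec: LibrarySpec,
                   mol_id: str) -> MoleculeGraph:
    lo, hi = spec.atom_count_range
    n_atoms = int(rng.integers(lo, hi + 1))
    elements = list(spec.element_weights)
    weights = np.array([spec.element_weights[e] for e in elements], dtype=float)
    weights /= weights.sum()
    multivalent = [i for i, e in enumerate(elements) if GROWTH_VALENCE[e] >= 2]
    w_multi = weights[multivalent] / weights[multivalent].sum()

    def pick_element(require_multivalent: bool) -> str:
        if require_multivalent:
            return elements[multivalent[rng.choice(len(multivalent), p=w_multi)]]
        return elements[rng.choice(len(elements), p=weights)]

    symbols = [pick_element(require_multivalent=n_atoms > 1)]
    free = [GROWTH_VALENCE[symbols[0]]]
    bonds: list[Bond] = []

    for k in range(1, n_atoms):
        open_atoms = [i for i, f in enumerate(free) if f > 0]
        if not open_atoms:
            raise LibrarySpecError(f"{mol_id}: growth dead-ended at {k} atoms")
        if rng.random() < spec.branch_probability:
            anchor = int(open_atoms[rng.integers(len(open_atoms))])
        else:
            anchor = int(open_atoms[-1])  # chain growth from newest open atom
        remaining = n_atoms - k - 1
        # a non-final atom must leave at least one open slot behind
        total_free = sum(free)
        for _ in range(30):
            el = pick_element(require_multivalent=False)
            order = 1
            if (spec.double_bond_probability > rng.random()
                    and free[anchor] >= 2 and GROWTH_VALENCE[el] >= 2):
                order = 2
            if remaining == 0 or (total_free - order) + (GROWTH_VALENCE[el] - order) >= 1:
                break
        else:
            el, order = "C", 1
        symbols.append(el)
        bonds.append(Bond(anchor, k, order))
        free[anchor] -= order
        free.append(GROWTH_VALENCE[el] - order)

    # optionally close one small ring between non-adjacent open atoms
    if n_atoms >= 3 and rng.random() < spec.ring_closure_probability:
        adjacent = {(min(b.a, b.b), max(b.a, b.b)) for b in bonds}
        open_atoms = [i for i, f in enumerate(free) if f > 0]
        dist = _bfs_distances(n_atoms, bonds)
        candidates = [
            (i, j) for ii, i in enumerate(open_atoms)
            for j in open_atoms[ii + 1:]
            if (i, j) not in adjacent and 2 <= dist[i][j] <= 6
        ]
        if candidates:
            i, j = candidates[rng.integers(len(candidates))]
            bonds.append(Bond(i, j, 1))
            free[i] -= 1
            free[j] -= 1

    atoms = [Atom(index=i, element=el) for i, el in enumerate(symbols)]
    return MoleculeGraph(id=mol_id, atoms=atoms, bonds=bonds)


def _bfs_distances(n: int, bonds: Sequence[Bond]) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in range(n)]
    for b in bonds:
        adj[b.a].append(b.b)
        adj[b.b].append(b.a)
    big = n + 1
    dist = [[big] * n for _ in range(n)]
    for start in range(n):
        dist[start][start] = 0
        queue = [start]
        while queue:
            nxt = []
            for u in queue:
                for v in adj[u]:
                    if dist[start][v] > dist[start][u] + 1:
                        dist[start][v] = dist[start][u] + 1
                        nxt.append(v)
            queue = nxt
    return dist


def generate_library(spec: LibrarySpec) -> MoleculeLibrary:
    """Grow ``spec.n_molecules`` random valence-legal molecules.

    Deterministic per seed; ids are ``syn%06d`` in generation order.
    """
    rng = np.random.default_rng(spec.seed)
    molecules = [_grow_molecule(rng, spec, f"syn{i:06d}")
                 for i in range(spec.n_molecules)]
    return MoleculeLibrary(molecules, source=f"synthetic(seed={spec.seed})")


# ---------------------------------------------------------------------------
# Surrogate docking oracle
# ---------------------------------------------------------------------------

@dataclass
class SurrogateSpec:
    """Statistical recipe for the surrogate docking-score function.

    The noise-free score is ``scale * Phi(z)**skew_exponent`` where z is
    the standardized latent and Phi the standard normal CDF: a bounded,
    strongly right-skewed map (mass piles up near zero, only the best
    latents approach ``scale``) whose histogram occupancy is stable in the
    sample size — an unbounded transform of a normal-tailed latent would
    let a single sample maximum stretch the equal-width bins until the top
    bins are empty. Larger ``skew_exponent`` = heavier skew.
    ``noise_sd_factor`` scales the id-keyed Gaussian noise relative to the
    standard deviation of the noise-free scores. Signal signatures are
    drawn uniformly from the part of the vocabulary present in at least
    ``min_support_fraction`` of the library: random-graph vocabularies are
    dominated by near-unique signatures, and a latent built on those is a
    point mass at zero with a few wild outliers rather than a plausibly
    shaped binding propensity.
    """

    n_signal_signatures: int = 50
    weight_sd: float = 1.0
    noise_sd_factor: float = 0.5
    skew_exponent: float = 10.0
    scale: float = 10.0
    min_support_fraction: float = 0.01


class SurrogateOracle:
    """Deterministic docking-score surrogate over signature features.

    ``score = max(0, scale * Phi(z)**skew_exponent + noise)`` where z is a
    standardized linear combination of the molecule's signature counts
    (weights drawn once over a random subset of the library vocabulary)
    and the noise is keyed by (seed, molecule id), never by call order.
    """

    def __init__(self, library: MoleculeLibrary,
                 spec: SurrogateSpec | None = None,
                 seed: int = 0,
                 features: tuple[SignatureVocabulary, sparse.csr_matrix] | None = None):
        self.spec = spec or SurrogateSpec()
        self.seed = int(seed)
        if features is None:
            vocab = build_vocabulary(library).freeze()
            X = signature_matrix(library, vocab)
        else:
            vocab, X = features
        rng = np.random.default_rng([self.seed, 1])
        support = np.asarray((X > 0).sum(axis=0)).ravel()
        min_support = self.spec.min_support_fraction * X.shape[0]
        eligible = np.flatnonzero(support >= min_support)
        if eligible.size == 0:
            eligible = np.arange(len(vocab))
        n_signal = min(self.spec.n_signal_signatures, eligible.size)
        if n_signal == 0:
            raise LibrarySpecError("library vocabulary is empty")
        cols = eligible[rng.choice(eligible.size, size=n_signal, replace=False)]
        w = rng.normal(0.0, self.spec.weight_sd, size=n_signal)
        texts = vocab.texts()
        self._signal_weights = {texts[c]: w[k] for k, c in enumerate(cols)}

        raw = np.asarray(X[:, cols] @ w).ravel()
        self._z_mean = float(raw.mean())
        self._z_sd = float(raw.std())
        if self._z_sd == 0.0:
            raise LibrarySpecError(
                "surrogate latent score is constant over the library")
        z = (raw - self._z_mean) / self._z_sd
        signal = self._transform(z)
        self.noise_sd = self.spec.noise_sd_factor * float(signal.std())
        self._z_cache = dict(zip(library.ids(), z))

    def _transform(self, z):
        """Bounded right-skew map from latent to noise-free score."""
        return self.spec.scale * ndtr(z) ** self.spec.skew_exponent

    # -- latent ------------------------------------------------------------

    def latent(self, molecule: MoleculeGraph) -> float:
        """Standardized latent binding propensity z of a molecule."""
        z = self._z_cache.get(molecule.id)
        if z is not None:
            return float(z)
        counts = molecule_signature_counts(molecule).counts
        raw = sum(self._signal_weights.get(t, 0.0) * c for t, c in counts.items())
        return (raw - self._z_mean) / self._z_sd

    def _noise(self, mol_id: str) -> float:
        key = zlib.crc32(mol_id.encode("utf-8"))
        rng = np.random.default_rng([self.seed, 2, key])
        return float(rng.normal(0.0, self.noise_sd))

    # -- DockingOracle contract --------------------------------------------

    def score(self, molecule: MoleculeGraph) -> float:
        s = float(self._transform(self.latent(molecule))) + self._noise(molecule.id)
        return max(s, 0.0)

    def score_batch(self, molecules: Sequence[MoleculeGraph]) -> list[float]:
        return [self.score(m) for m in molecules]


def make_surrogate_oracle(library: MoleculeLibrary,
                          spec: SurrogateSpec | None = None,
                          seed: int = 0,
                          features=None) -> SurrogateOracle:
    """Build a deterministic surrogate docking oracle for ``library``."""
    return SurrogateOracle(library, spec=spec, seed=seed, features=features)


# ---------------------------------------------------------------------------
# Exchangeable benchmark for conformal validity checks
# ---------------------------------------------------------------------------

@dataclass
class CPBenchmark:
    """Two-Gaussian-class data split into proper-training/calibration/test."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_cal: np.ndarray
    y_cal: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray


def generate_cp_benchmark(n_train: int, n_cal: int, n_test: int,
                          dim: int,
                          class_balance: float = 0.5,
                          separation: float = 1.0,
                          seed: int = 0) -> CPBenchmark:
    """Exchangeable two-class Gaussian data.

    Class-conditional features are unit-variance Gaussians whose means
    differ by ``separation`` standard deviations along the first axis;
    labels are i.i.d. Bernoulli(``class_balance``), so train, calibration
    and test splits are exchangeable by construction.
    """
    rng = np.random.default_rng(seed)

    def draw(n: int):
        y = (rng.random(n) < class_balance).astype(int)
        X = rng.standard_normal((n, dim))
        X[:, 0] += separation * y
        return X, y

    X_train, y_train = draw(n_train)
    X_cal, y_cal = draw(n_cal)
    X_test, y_test = draw(n_test)
    return CPBenchmark(X_train, y_train, X_cal, y_cal, X_test, y_test)
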