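"""The iterative conformal-prediction virtual screening (CPVS) loop.

The idea: dock only a small sample of the library, learn which structural
features predict a poor docking score, and confidently discard ('prune')
molecules predicted low-scoring so they are never docked at all. Concretely:

1. featurize the whole library once (signature counts, heights 1-3); keep
   two views of it — the shrinking candidate pool *Ds* and the full
   universe *DsComplete*;
2. dock an initial random sample (``ds_init``) drawn from the pool;
3. label all docked-so-far scores via a fresh 10-bin histogram and the
   bin-combination scheme; train a mondrian ICP (linear SVM scorer) on the
   labeled set with a stratified calibration split;
4. predict conformal sets for the ENTIRE universe; remove every molecule
   predicted exactly {0} from the pool — those are never docked;
5. compute efficiency = fraction of singleton sets over the universe; if
   it is below threshold, dock another ``ds_incr`` sample from the pool
   and repeat from (3);
6. once efficient (or out of iterations/pool), dock every remaining pool
   molecule whose current prediction set is exactly {1} and stop.

Evaluation compares against an exhaustive screen: what fraction of the
exhaustive run's top-N molecules did the iterative run also dock, and what
fraction of the library was docked at all.
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from . import cp
from .errors import ConfigError, DegenerateDataError, InsufficientClassError
from .labeling import BinScheme, assign_labels, histogram_scores
from .molecules import MoleculeGraph, MoleculeLibrary
from .signatures import SignatureVocabulary, build_vocabulary, signature_matrix

logger = logging.getLogger(__name__)


class DockingOracle(Protocol):
    """Anything that deterministically scores molecules (higher = better)."""

    def score(self, molecule: MoleculeGraph) -> float: ...

    def score_batch(self, molecules: Sequence[MoleculeGraph]) -> list[float]: ...


@dataclass
class ScreeningConfig:
    """All tunables of one CPVS run.

    Defaults are desk-scale: a 100x shrink of the full-scale operating
    point (initial sample 200 000 -> 2 000, increment 100 000 -> 1 000)
    with the same significance level, efficiency threshold, bin scheme,
    calibration fraction and signature heights.
    """

    ds_init: int = 2000
    ds_incr: int = 1000
    epsilon: float = 0.2
    efficiency_threshold: float = 0.8
    bin_scheme: str = "1_5"
    n_bins: int = 10
    calibration_fraction: float = 0.1
    h_min: int = 1
    h_max: int = 3
    max_iterations: int = 25
    seed: int = 0
    score_higher_is_better: bool = True
    dock_uncertain_at_end: bool = False
    max_opt_iterations: int = 50
    reg: float = 1e-2

    def __post_init__(self) -> None:
        if not self.ds_init >= self.ds_incr > 0:
            raise ConfigError("need ds_init >= ds_incr > 0")
        if not 0.0 <= self.efficiency_threshold < 1.0:
            raise ConfigError("efficiency_threshold must be in [0, 1)")
        if not 0.0 < self.epsilon < 1.0:
            raise ConfigError("epsilon must be in (0, 1)")
        if not 0.0 < self.calibration_fraction < 1.0:
            raise ConfigError("calibration_fraction must be in (0, 1)")
        if self.max_iterations < 1:
            raise ConfigError("max_iterations must be >= 1")
        self.scheme  # validates

    @property
    def scheme(self) -> BinScheme:
        return BinScheme.parse(self.bin_scheme)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScreeningConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ScreeningResult:
    """Outcome of one CPVS run."""

    docked: dict[str, float]                 # id -> score (higher = better)
    iteration_docked: dict[str, int]         # final-stage docks get n_iterations + 1
    n_iterations: int
    efficiency_history: list[float]
    set_tallies: list[dict[str, int]]        # per iteration: counts of {0},{1},{0,1},{}
    pruned: frozenset[str]
    final_sets: dict[str, str]               # id -> "{0}" | "{1}" | "{0,1}" | "{}"
    universe_size: int
    pruned_history: list[int] = field(default_factory=list)   # newly pruned per iteration
    pool_history: list[int] = field(default_factory=list)     # pool size after pruning
    model: cp.ICPClassifier | None = None

    @property
    def fraction_docked(self) -> float:
        """Percentage of the universe that was docked."""
        return 100.0 * len(self.docked) / self.universe_size


SET_NAMES = {frozenset(): "{}", frozenset({0}): "{0}",
             frozenset({1}): "{1}", frozenset({0, 1}): "{0,1}"}


def run_cpvs(library: MoleculeLibrary,
             oracle: DockingOracle,
             config: ScreeningConfig,
             output_dir: str | Path | None = None,
             features: tuple[SignatureVocabulary, sparse.csr_matrix] | None = None,
             ) -> ScreeningResult:
    """Run the full iterative screen; see the module docstring for stages.

    ``features`` optionally supplies a precomputed ``(vocabulary, matrix)``
    pair (rows aligned with library order) to avoid re-featurizing when
    several runs share one library. All randomness derives from
    ``config.seed``.
    """
    if len(library) == 0:
        raise DegenerateDataError("empty library")
    if config.ds_init > len(library):
        raise ConfigError(f"ds_init={config.ds_init} exceeds library size "
                          f"{len(library)}")

    ids = library.ids()
    if features is None:
        vocab = build_vocabulary(library, config.h_min, config.h_max).freeze()
        X = signature_matrix(library, vocab, config.h_min, config.h_max)
    else:
        vocab, X = features
    n = len(ids)
    row_of = {mol_id: i for i, mol_id in enumerate(ids)}
    mol_of = {m.id: m for m in library}

    in_pool = np.ones(n, dtype=bool)
    pruned = np.zeros(n, dtype=bool)
    docked: dict[str, float] = {}
    iteration_docked: dict[str, int] = {}

    sample_rng = np.random.default_rng([config.seed, 10])
    sign = 1.0 if config.score_higher_is_better else -1.0

    def dock(indices: np.ndarray, iteration: int) -> None:
        mols = [mol_of[ids[i]] for i in indices]
        scores = oracle.score_batch(mols)
        for i, s in zip(indices, scores):
            docked[ids[i]] = sign * float(s)
            iteration_docked[ids[i]] = iteration
        in_pool[indices] = False

    def draw(k: int) -> np.ndarray:
        candidates = np.flatnonzero(in_pool)
        return sample_rng.choice(candidates, size=k, replace=False)

    dock(draw(config.ds_init), iteration=1)

    efficiency_history: list[float] = []
    set_tallies: list[dict[str, int]] = []
    pruned_history: list[int] = []
    pool_history: list[int] = []
    model: cp.ICPClassifier | None = None
    in0 = in1 = None
    iteration = 1

    while True:
        hist = histogram_scores(list(docked.values()), n_bins=config.n_bins)
        labels = _label_with_fallback(docked, hist, config.scheme)
        labeled_ids = list(labels)
        y = np.array([labels[i] for i in labeled_ids])
        X_train = X[[row_of[i] for i in labeled_ids]]

        split_seed = np.random.SeedSequence([config.seed, 20, iteration])
        train_idx, cal_idx = cp.split_calibration(
            y, config.calibration_fraction, seed=split_seed)
        scorer = cp.train_underlying(
            X_train[train_idx], y[train_idx], seed=config.seed,
            max_opt_iterations=config.max_opt_iterations, reg=config.reg)
        model = cp.ICPClassifier.from_calibration(
            scorer, X_train[cal_idx], y[cal_idx], epsilon=config.epsilon)

        # predict on the whole universe
        p0, p1 = model.p_values(X)
        in0 = p0 > config.epsilon
        in1 = p1 > config.epsilon
        only0 = in0 & ~in1
        only1 = in1 & ~in0
        eff = float((only0 | only1).mean())
        efficiency_history.append(eff)
        tally = {"{0}": int(only0.sum()), "{1}": int(only1.sum()),
                 "{0,1}": int((in0 & in1).sum()),
                 "{}": int((~in0 & ~in1).sum())}
        set_tallies.append(tally)

        newly_pruned = in_pool & only0
        pruned |= newly_pruned
        in_pool &= ~only0
        n_pool = int(in_pool.sum())
        pruned_history.append(int(newly_pruned.sum()))
        pool_history.append(n_pool)
        logger.info("iteration %d: efficiency=%.3f pruned=%d pool=%d sets=%s",
                    iteration, eff, int(newly_pruned.sum()), n_pool, tally)

        if eff >= config.efficiency_threshold:
            break
        if iteration >= config.max_iterations:
            warnings.warn(
                f"stopping at max_iterations={config.max_iterations} with "
                f"efficiency {eff:.3f} below threshold", stacklevel=2)
            break
        if n_pool < config.ds_incr:
            warnings.warn(
                f"candidate pool ({n_pool}) smaller than ds_incr "
                f"({config.ds_incr}); stopping early", stacklevel=2)
            break
        iteration += 1
        dock(draw(config.ds_incr), iteration=iteration)

    # final stage: dock remaining predicted high-scorers
    final_mask = in_pool & (in1 & ~in0)
    if config.dock_uncertain_at_end:
        final_mask = in_pool & ~(in0 & ~in1)
    if final_mask.any():
        dock(np.flatnonzero(final_mask), iteration=iteration + 1)

    final_sets = {
        ids[i]: SET_NAMES[frozenset(
            ([0] if in0[i] else []) + ([1] if in1[i] else []))]
        for i in range(n)}

    result = ScreeningResult(
        docked=docked,
        iteration_docked=iteration_docked,
        n_iterations=iteration,
        efficiency_history=efficiency_history,
        set_tallies=set_tallies,
        pruned=frozenset(ids[i] for i in np.flatnonzero(pruned)),
        final_sets=final_sets,
        universe_size=n,
        pruned_history=pruned_history,
        pool_history=pool_history,
        model=model)
    if output_dir is not None:
        write_result(result, output_dir)
    return result


def _label_with_fallback(docked: Mapping[str, float], hist, scheme: BinScheme
                         ) -> dict[str, int]:
    """Label scores; if a class is unusably small, widen the scheme once.

    'Unusably small' means fewer than two examples: such a class cannot be
    split into proper-training and calibration parts. Widening moves the
    offending boundary one bin toward the other (class 0 short: raise
    low_max; class 1 short: lower high_min) while keeping low_max < high_min.
    """
    assignment = assign_labels(docked, hist, scheme)
    counts = {lab: sum(1 for v in assignment.labels.values() if v == lab)
              for lab in (0, 1)}
    if min(counts.values()) >= 2:
        return assignment.labels

    widened = scheme
    if counts[0] < 2 and scheme.low_max + 1 < scheme.high_min:
        widened = BinScheme(scheme.low_max + 1, scheme.high_min)
    elif counts[1] < 2 and scheme.high_min - 1 > scheme.low_max:
        widened = BinScheme(scheme.low_max, scheme.high_min - 1)
    if widened != scheme:
        warnings.warn(f"class counts {counts} under scheme {scheme}; "
                      f"widened once to {widened}", stacklevel=2)
        assignment = assign_labels(docked, hist, widened)
        counts = {lab: sum(1 for v in assignment.labels.values() if v == lab)
                  for lab in (0, 1)}
    if min(counts.values()) < 2:
        raise DegenerateDataError(
            f"class counts {counts} still unusable after widening {scheme} "
            f"to {widened}")
    return assignment.labels


# ---------------------------------------------------------------------------
# Baseline and evaluation
# ---------------------------------------------------------------------------

def exhaustive_screen(library: MoleculeLibrary,
                      oracle: DockingOracle) -> dict[str, float]:
    """Dock every molecule once; the ground-truth baseline."""
    scores = oracle.score_batch(list(library))
    return {m.id: float(s) for m, s in zip(library, scores)}


def top_n_accuracy(result: "ScreeningResult | Mapping[str, float]",
                   exhaustive: Mapping[str, float],
                   n: int = 30) -> float:
    """Fraction of the exhaustive top-n that the screen also docked.

    Ties at the cutoff are broken by lexicographic id, so the top-n set is
    deterministic.
    """
    if n > len(exhaustive):
        raise ValueError(f"n={n} exceeds baseline size {len(exhaustive)}")
    docked = result.docked if isinstance(result, ScreeningResult) else result
    top = sorted(exhaustive.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    return sum(1 for mol_id, _ in top if mol_id in docked) / n


def fraction_docked(result: ScreeningResult,
                    universe_size: int | None = None) -> tuple[float, float]:
    """(percent docked, percent reduction) relative to the universe."""
    size = universe_size if universe_size is not None else result.universe_size
    pct = 100.0 * len(result.docked) / size
    return pct, 100.0 - pct


# ---------------------------------------------------------------------------
# Run outputs
# ---------------------------------------------------------------------------

def write_result(result: ScreeningResult, output_dir: str | Path,
                 baseline: Mapping[str, float] | None = None,
                 top_n: int = 30) -> None:
    """Write result.csv, efficiency.csv and summary.txt into ``output_dir``."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = sorted(result.docked)
    pd.DataFrame({
        "id": rows,
        "score": [result.docked[i] for i in rows],
        "iteration_docked": [result.iteration_docked[i] for i in rows],
    }).to_csv(out / "result.csv", index=False)

    tally_cols = {"{0}": "n_low", "{1}": "n_high",
                  "{0,1}": "n_both", "{}": "n_empty"}
    eff_rows = []
    for it, (eff, tally, n_pruned, n_pool) in enumerate(
            zip(result.efficiency_history, result.set_tallies,
                result.pruned_history, result.pool_history), start=1):
        eff_rows.append({"iteration": it, "efficiency": eff,
                         "n_pruned": n_pruned, "n_pool": n_pool,
                         **{tally_cols[k]: v for k, v in tally.items()}})
    pd.DataFrame(eff_rows).to_csv(out / "efficiency.csv", index=False)

    pct, reduction = fraction_docked(result)
    lines = [
        f"universe_size: {result.universe_size}",
        f"n_docked: {len(result.docked)}",
        f"n_pruned: {len(result.pruned)}",
        f"n_iterations: {result.n_iterations}",
        f"final_efficiency: {result.efficiency_history[-1]:.4f}",
        f"fraction_docked_pct: {pct:.2f}",
        f"reduction_pct: {reduction:.2f}",
    ]
    if baseline is not None:
        lines.append(f"top_{top_n}_accuracy: "
                     f"{top_n_accuracy(result, baseline, top_n):.4f}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# External docking command adapter
# ---------------------------------------------------------------------------

class ExternalCommandOracle:
    """Adapter that shells out to a user-supplied docking command.

    The command template receives ``{input}`` (a batch SDF written by the
    adapter) and ``{output}`` (a CSV path the command must produce with
    ``id,score`` columns, no header required). Scores are cached by
    molecule id, so each molecule is scored at most once per run.
    """

    def __init__(self, command_template: str):
        if "{input}" not in command_template or "{output}" not in command_template:
            raise ConfigError(
                "command template must contain {input} and {output}")
        self.command_template = command_template
        self._cache: dict[str, float] = {}

    def score(self, molecule: MoleculeGraph) -> float:
        return self.score_batch([molecule])[0]

    def score_batch(self, molecules: Sequence[MoleculeGraph]) -> list[float]:
        from .molecules import write_sdf

        missing = [m for m in molecules if m.id not in self._cache]
        if missing:
            with tempfile.TemporaryDirectory(prefix="cpvs-dock-") as tmp:
                sdf = Path(tmp) / "batch.sdf"
                csv_out = Path(tmp) / "scores.csv"
                write_sdf(missing, sdf)
                cmd = self.command_template.format(input=sdf, output=csv_out)
                proc = subprocess.run(cmd, shell=True, capture_output=True,
                                      text=True)
                if proc.returncode != 0:
                    raise RuntimeError(
                        f"docking command failed ({proc.returncode}): "
                        f"{proc.stderr.strip()[:500]}")
                for line in csv_out.read_text().splitlines():
                    line = line.strip()
                    if not line or line.lower().startswith("id,"):
                        continue
                    mol_id, score = line.split(",")[:2]
                    self._cache[mol_id.strip()] = float(score)
            still = [m.id for m in missing if m.id not in self._cache]
            if still:
                raise RuntimeError(f"docking command returned no score for "
                                   f"{still[:5]}...")
        return [self._cache[m.id] for m in molecules]
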