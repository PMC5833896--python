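import filecmp

import numpy as np
import pytest

from cpvs import (LibrarySpec, ScreeningConfig, exhaustive_screen,
                  fraction_docked, generate_library, make_surrogate_oracle,
                  run_cpvs, top_n_accuracy)
from cpvs.errors import ConfigError
from cpvs.screening import ExternalCommandOracle, write_result


@pytest.fixture(scope="module")
def lib3k():
    return generate_library(LibrarySpec(n_molecules=3000, seed=21))


@pytest.fixture(scope="module")
def oracle3k(lib3k):
    return make_surrogate_oracle(lib3k, seed=7)


@pytest.fixture(scope="module")
def run3k(lib3k, oracle3k, quiet_module):
    cfg = ScreeningConfig(ds_init=1000, ds_incr=500, seed=7)
    return run_cpvs(lib3k, oracle3k, cfg)


@pytest.fixture(scope="module")
def quiet_module():
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


def test_config_validation():
    with pytest.raises(ConfigError):
        ScreeningConfig(ds_init=100, ds_incr=200)
    with pytest.raises(ConfigError):
        ScreeningConfig(efficiency_threshold=1.0)
    with pytest.raises(ConfigError):
        ScreeningConfig(bin_scheme="5_2")
    with pytest.raises(ConfigError):
        ScreeningConfig.from_dict({"ds_init": 100, "ds_incr": 50,
                                   "not_a_key": 1})


def test_zero_threshold_runs_loop_exactly_once(lib3k, oracle3k, quiet):
    cfg = ScreeningConfig(ds_init=1000, ds_incr=500, efficiency_threshold=0.0,
                          seed=1)
    res = run_cpvs(lib3k, oracle3k, cfg)
    assert res.n_iterations == 1
    assert len(res.efficiency_history) == 1
    # initial sample plus final {1} docking only
    n_final_high = sum(1 for i, s in res.final_sets.items()
                       if s == "{1}" and i not in res.pruned)
    assert len(res.docked) <= 1000 + n_final_high


def test_run_set_algebra(lib3k, run3k):
    res = run3k
    docked = set(res.docked)
    pruned = set(res.pruned)
    universe = set(lib3k.ids())
    # conservation: docked, pruned, untouched partition the universe
    assert docked <= universe and pruned <= universe
    assert not docked & pruned  # no pruned molecule was ever docked
    assert docked | pruned | (universe - docked - pruned) == universe
    # the initial sample is part of the docked set
    assert sum(1 for it in res.iteration_docked.values() if it == 1) == 1000


def test_budget_invariant(run3k):
    res = run3k
    n_final_high = sum(1 for i, s in res.final_sets.items() if s == "{1}")
    assert len(res.docked) <= (1000 + (res.n_iterations - 1) * 500
                               + n_final_high)


def test_fraction_docked_arithmetic(run3k):
    pct, reduction = fraction_docked(run3k)
    assert pct == pytest.approx(100.0 * len(run3k.docked) / 3000)
    assert reduction == pytest.approx(100.0 - pct)
    assert 0.0 < pct <= 100.0


def test_exhaustive_screen_covers_and_agrees(lib3k, oracle3k, run3k):
    scores = exhaustive_screen(lib3k, oracle3k)
    assert len(scores) == len(lib3k)
    for mol_id, s in run3k.docked.items():
        assert scores[mol_id] == s  # oracle determinism across runs
    assert exhaustive_screen(
        generate_library(LibrarySpec(n_molecules=0)), oracle3k) == {}


def test_top_n_accuracy_arithmetic():
    exhaustive = {"a": 9.0, "b": 8.0, "c": 7.0, "d": 1.0}
    assert top_n_accuracy({"a": 9.0, "b": 8.0}, exhaustive, n=3) == pytest.approx(2 / 3)
    assert top_n_accuracy(exhaustive, exhaustive, n=3) == 1.0
    assert top_n_accuracy({"d": 1.0}, exhaustive, n=3) == 0.0
    with pytest.raises(ValueError):
        top_n_accuracy({}, exhaustive, n=5)
    # ties at the cutoff break by id
    tied = {"a": 5.0, "b": 5.0, "c": 5.0}
    assert top_n_accuracy({"a": 5.0, "b": 5.0}, tied, n=2) == 1.0


def test_score_orientation_flag(lib3k, oracle3k, quiet):
    """A lower-is-better engine, negated on ingest, docks the same set."""

    class NegatedOracle:
        def score(self, m):
            return -oracle3k.score(m)

        def score_batch(self, ms):
            return [-s for s in oracle3k.score_batch(ms)]

    cfg = ScreeningConfig(ds_init=1000, ds_incr=500, seed=7)
    res_pos = run_cpvs(lib3k, oracle3k, cfg)
    cfg_neg = ScreeningConfig(ds_init=1000, ds_incr=500, seed=7,
                              score_higher_is_better=False)
    res_neg = run_cpvs(lib3k, NegatedOracle(), cfg_neg)
    assert res_neg.docked == res_pos.docked
    assert res_neg.efficiency_history == res_pos.efficiency_history


def test_reproducible_outputs_byte_identical(lib3k, oracle3k, tmp_path, quiet):
    cfg = ScreeningConfig(ds_init=1000, ds_incr=500, seed=5)
    run_cpvs(lib3k, oracle3k, cfg, output_dir=tmp_path / "a")
    run_cpvs(lib3k, oracle3k, cfg, output_dir=tmp_path / "b")
    for name in ("result.csv", "efficiency.csv", "summary.txt"):
        assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                           shallow=False), name


def test_write_result_includes_baseline_metrics(run3k, lib3k, oracle3k,
                                                tmp_path):
    baseline = exhaustive_screen(lib3k, oracle3k)
    write_result(run3k, tmp_path, baseline=baseline, top_n=30)
    summary = (tmp_path / "summary.txt").read_text()
    assert "top_30_accuracy" in summary
    eff_csv = (tmp_path / "efficiency.csv").read_text()
    assert eff_csv.startswith("iteration,efficiency,n_pruned,n_pool")


def test_ds_init_larger_than_library_rejected(lib3k, oracle3k):
    with pytest.raises(ConfigError):
        run_cpvs(lib3k, oracle3k, ScreeningConfig(ds_init=5000, ds_incr=100))


def test_external_command_oracle(tmp_path):
    """Round-trip through the shell adapter with a scorer script that
    counts atoms per SDF record."""
    lib = generate_library(LibrarySpec(n_molecules=12, seed=2))
    script = tmp_path / "fake_dock.py"
    script.write_text('''
import sys
from rdkit import Chem
inp, out = sys.argv[1], sys.argv[2]
with open(out, "w") as fh:
    for mol in Chem.SDMolSupplier(inp, sanitize=False):
        fh.write(mol.GetProp("_Name") + "," + str(mol.GetNumAtoms()) + "\\n")
''')
    import sys
    oracle = ExternalCommandOracle(
        f"{sys.executable} {script} {{input}} {{output}}")
    scores = oracle.score_batch(list(lib))
    assert scores == [float(g.n_atoms) for g in lib]
    # cached: second call must not re-invoke the command
    script.write_text("raise SystemExit(1)\n")
    assert oracle.score(lib[0]) == float(lib[0].n_atoms)

    with pytest.raises(ConfigError):
        ExternalCommandOracle("docker run no-placeholders")
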