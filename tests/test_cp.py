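import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cpvs import (ICPClassifier, LinearScorer, efficiency, error_rate,
                  generate_cp_benchmark, nonconformity, p_value,
                  split_calibration, train_underlying)
from cpvs.cp import PredictionSet, singleton_accuracy
from cpvs.errors import DegenerateDataError, InsufficientClassError

from _oracles import brute_force_p_value


# ---------------------------------------------------------------------------
# Calibration split
# ---------------------------------------------------------------------------

def test_split_is_stratified_and_deterministic():
    y = np.array([0] * 50 + [1] * 50)
    train, cal = split_calibration(y, fraction=0.1, seed=4)
    assert len(cal) == 10 and len(train) == 90
    assert (y[cal] == 0).sum() == 5 and (y[cal] == 1).sum() == 5
    train2, cal2 = split_calibration(y, fraction=0.1, seed=4)
    assert np.array_equal(cal, cal2) and np.array_equal(train, train2)
    assert not set(cal) & set(train)


def test_split_small_balanced_set():
    y = np.array([0, 0, 1, 1])
    train, cal = split_calibration(y, fraction=0.5, seed=0)
    assert (y[cal] == 0).sum() == 1 and (y[cal] == 1).sum() == 1


def test_split_rejects_tiny_class():
    with pytest.raises(InsufficientClassError):
        split_calibration(np.array([0, 0, 0, 1]), fraction=0.2, seed=0)


# ---------------------------------------------------------------------------
# Underlying scorer
# ---------------------------------------------------------------------------

def test_separable_toy_signs():
    X = np.array([[1.0], [-1.0]])
    y = np.array([1, 0])
    scorer = train_underlying(X, y)
    d = scorer.decision(X)
    assert d[0] > 0 > d[1]


def test_duplicating_training_set_changes_nothing():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(40, 3))
    y = (X[:, 0] > 0).astype(int)
    a = train_underlying(X, y)
    b = train_underlying(np.vstack([X, X]), np.concatenate([y, y]))
    assert np.allclose(a.weights, b.weights, atol=1e-6)
    assert np.isclose(a.intercept, b.intercept, atol=1e-6)


def test_gaussian_training_accuracy():
    """Two Gaussian classes 2 sigma apart: training accuracy approaches the
    Bayes accuracy Phi(1) ~ 0.84 (it cannot reach far beyond it)."""
    bench = generate_cp_benchmark(500, 10, 10, dim=5, separation=2.0, seed=11)
    scorer = train_underlying(bench.X_train, bench.y_train)
    acc = ((scorer.decision(bench.X_train) > 0).astype(int)
           == bench.y_train).mean()
    assert acc >= 0.8


# ---------------------------------------------------------------------------
# Nonconformity and p-values
# ---------------------------------------------------------------------------

def test_nonconformity_is_signed_decision():
    assert nonconformity(2.0, 1) == -2.0
    assert nonconformity(2.0, 0) == +2.0
    assert nonconformity(0.0, 0) == nonconformity(0.0, 1) == 0.0


def test_p_value_worked_examples():
    alphas = np.array([1.0, 2.0, 3.0])
    assert p_value(2.5, alphas) == pytest.approx(0.5)     # (1+1)/4
    assert p_value(0.5, alphas) == 1.0                    # below all
    assert p_value(9.0, alphas) == pytest.approx(0.25)    # above all: 1/(n+1)
    with pytest.raises(DegenerateDataError):
        p_value(1.0, np.array([]))


@settings(derandomize=True, max_examples=300)
@given(
    alphas=st.lists(st.integers(-5, 5).map(lambda v: v / 2.0),
                    min_size=1, max_size=50),
    alpha_new=st.integers(-6, 6).map(lambda v: v / 2.0),
)
def test_p_value_matches_rank_oracle(alphas, alpha_new):
    """Tie-heavy random lists: searchsorted path == plain counting."""
    assert p_value(alpha_new, np.array(alphas)) == pytest.approx(
        brute_force_p_value(alpha_new, alphas))


@settings(derandomize=True, max_examples=100)
@given(alphas=st.lists(st.floats(-3, 3), min_size=1, max_size=30),
       a=st.floats(-4, 4), b=st.floats(-4, 4))
def test_p_value_monotone_and_bounded(alphas, a, b):
    arr = np.array(alphas)
    lo, hi = min(a, b), max(a, b)
    assert p_value(hi, arr) <= p_value(lo, arr)
    p = p_value(a, arr)
    assert 1 / (arr.size + 1) <= p <= 1.0


# ---------------------------------------------------------------------------
# Prediction sets
# ---------------------------------------------------------------------------

def icp_with(alphas_0, alphas_1, epsilon):
    scorer = LinearScorer(weights=np.array([1.0]), intercept=0.0)
    return ICPClassifier(scorer=scorer, alphas_0=np.asarray(alphas_0, float),
                         alphas_1=np.asarray(alphas_1, float), epsilon=epsilon)


@pytest.mark.parametrize("epsilon,expected", [
    (0.2, {0}), (0.05, {0, 1}), (0.6, set()),
])
def test_predict_set_inclusion_rule(epsilon, expected):
    # nine calibration alphas per class => p-values land on k/10 grid;
    # x = 0.5 gives alpha_0 = 0.5 (4 alphas >= it, p0 = 0.5) and
    # alpha_1 = -0.5 (no alphas >= it, p1 = 0.1)
    icp = icp_with([0.0, 0.1, 0.2, 0.3, 0.4, 0.6, 0.7, 0.8, 0.9],
                   -1.0 - np.linspace(0.0, 0.8, 9), epsilon)
    ps = icp.predict_set(np.array([0.5]))
    assert (ps.p0, ps.p1) == (0.5, 0.1)
    assert set(ps.labels) == expected


def test_sets_nested_as_epsilon_decreases(rng):
    alphas_0 = rng.normal(size=21)
    alphas_1 = rng.normal(size=17)
    X = rng.normal(size=(200, 1))
    previous = None
    for eps in (0.4, 0.2, 0.1, 0.05):
        sets = icp_with(alphas_0, alphas_1, eps).predict(X)
        if previous is not None:
            for small, big in zip(previous, sets):
                assert small.labels <= big.labels
        previous = sets


def test_efficiency_and_error_rate_metrics():
    mk = lambda labels: PredictionSet(frozenset(labels), 0.5, 0.5)
    sets = [mk({0}), mk({1}), mk({0, 1}), mk(set())]
    assert efficiency(sets) == 0.5
    assert efficiency([mk({0})] * 3) == 1.0
    with pytest.raises(DegenerateDataError):
        efficiency([])

    rates = error_rate(sets, [0, 1, 0, 1])
    assert rates.overall == 0.25          # only the empty set errs
    assert rates.per_class == {0: 0.0, 1: 0.5}
    assert error_rate([mk({0})], [1]).overall == 1.0
    assert singleton_accuracy(sets, [0, 0, 0, 1]) == 0.5


def test_export_predictions_csv(tmp_path):
    from cpvs.cp import export_predictions_csv
    sets = [PredictionSet(frozenset({0}), 0.5, 0.1),
            PredictionSet(frozenset({0, 1}), 0.5, 0.3)]
    path = tmp_path / "preds.csv"
    export_predictions_csv(["a", "b"], sets, path)
    lines = path.read_text().splitlines()
    assert lines[0] == "id,p0,p1,set"
    assert lines[1] == 'a,0.5,0.1,"{0}"'
    assert lines[2] == 'b,0.5,0.3,"{0,1}"'


def test_model_save_load_round_trip(tmp_path, rng):
    icp = icp_with(rng.normal(size=9), rng.normal(size=7), 0.2)
    path = tmp_path / "model.npz"
    icp.save(path)
    back = ICPClassifier.load(path)
    X = rng.normal(size=(20, 1))
    p0a, p1a = icp.p_values(X)
    p0b, p1b = back.p_values(X)
    assert np.allclose(p0a, p0b) and np.allclose(p1a, p1b)


def test_validity_quick_single_seed():
    """One-seed sanity check of per-class validity at the operating point."""
    bench = generate_cp_benchmark(2000, 500, 2000, dim=10, separation=1.0,
                                  seed=3)
    scorer = train_underlying(bench.X_train, bench.y_train)
    icp = ICPClassifier.from_calibration(scorer, bench.X_cal, bench.y_cal,
                                         epsilon=0.2)
    rates = error_rate(icp.predict(bench.X_test), bench.y_test)
    for label, rate in rates.per_class.items():
        n = (bench.y_test == label).sum()
        assert rate <= 0.2 + 3 * np.sqrt(0.2 * 0.8 / n)
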