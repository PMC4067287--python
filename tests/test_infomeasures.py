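"""Unit and property tests for the plug-in information measures."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from telag.infomeasures import (
    DiscreteSeries,
    EmpiricalJoint,
    conditional_entropy,
    conditional_mutual_information,
    directionality_index,
    effective_rate_of_change,
    empirical_joint,
    entropy,
    lag_scan,
    mutual_information,
    te_from_joint,
    transfer_entropy,
)


def series(vals, M=2):
    return DiscreteSeries(np.array(vals), M)


def joint_from_table(table):
    t = np.asarray(table, dtype=float)
    return EmpiricalJoint(tuple((i, 0) for i in range(t.ndim)), t, 0)


# ---------------------------------------------------------------- oracles


def entropy_bruteforce(table):
    """Direct −Σ p log2 p over all cells."""
    return -sum(p * np.log2(p) for p in np.asarray(table).ravel() if p > 0)


def cmi_bruteforce(t):
    """Direct triple sum of p(x,y,z) log2[ p(x,y|z) / (p(x|z) p(y|z)) ]."""
    t = np.asarray(t, dtype=float)
    pz = t.sum(axis=(0, 1))
    pxz = t.sum(axis=1)
    pyz = t.sum(axis=0)
    out = 0.0
    for x in range(t.shape[0]):
        for y in range(t.shape[1]):
            for z in range(t.shape[2]):
                p = t[x, y, z]
                if p > 0:
                    out += p * np.log2(p * pz[z] / (pxz[x, z] * pyz[y, z]))
    return out


def te_bruteforce(source, target, lag):
    """TE by explicit counting and direct summation on the 3-tuple table."""
    x, y = source.values, target.values
    n = len(y)
    counts = {}
    for t in range(max(0, lag - 1), n - 1):
        key = (y[t + 1], y[t], x[t + 1 - lag])
        counts[key] = counts.get(key, 0) + 1
    total = sum(counts.values())
    Mt, Ms = target.alphabet_size, source.alphabet_size
    table = np.zeros((Mt, Mt, Ms))
    for k, v in counts.items():
        table[k] = v / total
    return cmi_bruteforce(np.transpose(table, (0, 2, 1)))


# ---------------------------------------------------------- empirical_joint


def test_joint_identity_series_mass_on_diagonal():
    x = series([0, 1, 0, 1, 1])
    j = empirical_joint([x, x], [0, 0])
    assert j.table[0, 1] == 0 and j.table[1, 0] == 0
    assert j.table[0, 0] + j.table[1, 1] == pytest.approx(1.0)


def test_joint_anticorrelated_series():
    x = series([0, 1, 0, 1])
    y = series([1, 0, 1, 0])
    j = empirical_joint([x, y], [0, 0])
    assert j.table[0, 1] == pytest.approx(0.5)
    assert j.table[1, 0] == pytest.approx(0.5)


def test_joint_time_shift_hand_count():
    x = series([0, 0, 1, 1])
    j = empirical_joint([x, x], [0, 1])
    # pairs (x_t, x_{t+1}): (0,0), (0,1), (1,1)
    assert j.total_count == 3
    assert j.table[0, 0] == pytest.approx(1 / 3)
    assert j.table[0, 1] == pytest.approx(1 / 3)
    assert j.table[1, 1] == pytest.approx(1 / 3)
    assert j.table[1, 0] == 0.0


def test_joint_errors():
    x, y = series([0, 1, 0]), series([0, 1, 0, 1])
    with pytest.raises(ValueError, match="length"):
        empirical_joint([x, y], [0, 0])
    with pytest.raises(ValueError, match="overlap"):
        empirical_joint([x, x], [0, 5])


# ------------------------------------------------------------------ entropy


@pytest.mark.parametrize(
    "table,expected",
    [([0.5, 0.5], 1.0), ([1.0, 0.0], 0.0), ([0.25] * 4, 2.0)],
)
def test_entropy_known_values(table, expected):
    assert entropy(joint_from_table(table)) == pytest.approx(expected, abs=1e-12)


def test_unnormalized_table_rejected():
    with pytest.raises(ValueError, match="normalized"):
        joint_from_table([0.5, 0.4])


def test_conditional_entropy_deterministic_and_independent():
    # Y = X uniform binary
    assert conditional_entropy(joint_from_table([[0.5, 0], [0, 0.5]])) == pytest.approx(
        0.0, abs=1e-12
    )
    # Y independent uniform binary
    assert conditional_entropy(
        joint_from_table([[0.25, 0.25], [0.25, 0.25]])
    ) == pytest.approx(1.0, abs=1e-12)


def test_conditional_entropy_matches_direct_summation():
    # joint over (y, x): {(0,0):1/2, (1,0):1/4, (1,1):1/4}
    t = np.array([[0.5, 0.0], [0.25, 0.25]])
    got = conditional_entropy(joint_from_table(t))
    # oracle: chain rule from direct entropies
    want = entropy_bruteforce(t) - entropy_bruteforce(t.sum(axis=0))
    assert got == pytest.approx(want, abs=1e-12)
    # and the explicit conditional form −Σ p(y,x) log2 p(y|x)
    px = t.sum(axis=0)
    direct = -sum(
        t[y, x] * np.log2(t[y, x] / px[x])
        for y in range(2)
        for x in range(2)
        if t[y, x] > 0
    )
    assert got == pytest.approx(direct, abs=1e-12)


def test_mutual_information_known_values():
    assert mutual_information(joint_from_table([[0.5, 0], [0, 0.5]])) == pytest.approx(
        1.0, abs=1e-12
    )
    assert mutual_information(
        joint_from_table(np.outer([0.3, 0.7], [0.6, 0.4]))
    ) == pytest.approx(0.0, abs=1e-12)
    # binary symmetric relation, flip prob 0.25: I = 1 − H_b(0.25)
    t = np.array([[0.375, 0.125], [0.125, 0.375]])
    hb = -(0.25 * np.log2(0.25) + 0.75 * np.log2(0.75))
    assert mutual_information(joint_from_table(t)) == pytest.approx(1 - hb, abs=1e-9)
    assert mutual_information(joint_from_table(t)) == pytest.approx(0.188722, abs=1e-6)


def test_cmi_vacuous_and_degenerate_conditioning(rng):
    txy = rng.dirichlet(np.ones(4)).reshape(2, 2)
    # Z constant: I(X;Y|Z) = I(X;Y)
    t = txy[:, :, None]
    assert conditional_mutual_information(joint_from_table(t)) == pytest.approx(
        mutual_information(joint_from_table(txy)), abs=1e-12
    )
    # X = Z: no information left
    txz = np.zeros((2, 2, 2))
    for x in range(2):
        for y in range(2):
            txz[x, y, x] = txy[x, y]
    assert conditional_mutual_information(joint_from_table(txz)) == pytest.approx(
        0.0, abs=1e-12
    )


def test_cmi_matches_bruteforce_on_random_tables(rng):
    for _ in range(20):
        t = rng.dirichlet(np.ones(8)).reshape(2, 2, 2)
        got = conditional_mutual_information(joint_from_table(t))
        assert got == pytest.approx(cmi_bruteforce(t), abs=1e-12)


# ----------------------------------------------------------- transfer entropy


def test_self_te_at_lag_one_is_exactly_zero(rng):
    x = series(rng.integers(0, 2, 500))
    assert transfer_entropy(x, x, 1).value == 0.0


def test_te_copy_with_delay_is_one_bit(rng):
    n = 100_000
    x = rng.integers(0, 2, n)
    y = np.empty(n, dtype=np.int64)
    y[0] = 0
    y[1:] = x[:-1]  # y_{t+1} = x_t
    te = transfer_entropy(series(x), series(y), 1)
    assert te.value == pytest.approx(1.0, abs=0.01)
    assert te.n_effective == n - 1


def test_te_independent_series_is_pure_small_bias(rng):
    n = 1_000_000
    x = series(rng.integers(0, 2, n))
    y = series(rng.integers(0, 2, n))
    assert transfer_entropy(x, y, 1).value <= 0.001


def test_te_errors(rng):
    x = series(rng.integers(0, 2, 50))
    with pytest.raises(ValueError, match="lag"):
        transfer_entropy(x, x, 0)
    with pytest.raises(ValueError, match="window"):
        transfer_entropy(x, x, 45)


def test_te_n_effective_contract(rng):
    x = series(rng.integers(0, 2, 200))
    y = series(rng.integers(0, 2, 200))
    for tau in (1, 2, 5):
        assert transfer_entropy(x, y, tau).n_effective == 200 - max(1, tau)


def test_lag_scan_constant_target_all_zero(rng):
    x = series(rng.integers(0, 2, 300))
    y = series(np.zeros(300, dtype=np.int64))
    scan = lag_scan(x, y, 5)
    assert all(r.value == 0.0 for r in scan.results)
    assert scan.argmax_lag == 1  # tie broken at smallest lag


def test_erc_known_values():
    assert effective_rate_of_change(series([0, 0, 0, 0])) == 0.0
    assert effective_rate_of_change(series([0, 1, 0, 1, 0])) == 1.0
    assert effective_rate_of_change(series([0, 0, 1, 1])) == pytest.approx(1 / 3)


def test_directionality_identical_series_and_frozen_target(rng):
    x = series(rng.integers(0, 2, 400))
    assert directionality_index(x, x, 2) == 0.0
    frozen = series(np.zeros(400, dtype=np.int64))
    assert np.isnan(directionality_index(x, frozen, 1))


# ----------------------------------------------------------- property tests

dist_st = st.lists(
    st.integers(min_value=0, max_value=20), min_size=4, max_size=4
).filter(lambda w: sum(w) > 0)


@given(dist_st)
def test_chain_rule_on_arbitrary_tables(weights):
    t = np.array(weights, dtype=float).reshape(2, 2)
    t /= t.sum()
    j = joint_from_table(t)
    h_xy = entropy_bruteforce(t)
    h_x = entropy_bruteforce(t.sum(axis=0))
    assert conditional_entropy(j) == pytest.approx(h_xy - h_x, abs=1e-12)
    assert conditional_entropy(j) >= -1e-12


@given(dist_st)
def test_mi_symmetry_and_nonnegativity(weights):
    t = np.array(weights, dtype=float).reshape(2, 2)
    t /= t.sum()
    a = mutual_information(joint_from_table(t))
    b = mutual_information(joint_from_table(t.T))
    assert a == pytest.approx(b, abs=1e-12)
    assert a >= -1e-12


series_pair_st = st.tuples(
    st.integers(min_value=0, max_value=2**30),
    st.integers(min_value=2, max_value=4),
    st.integers(min_value=12, max_value=50),
    st.integers(min_value=1, max_value=3),
)


@given(series_pair_st)
def test_te_formulations_agree_and_match_bruteforce(args):
    """CMI-form and log-ratio-form TE are algebraically identical, and both
    equal a direct-summation oracle on small random series."""
    seed, M, n, tau = args
    r = np.random.default_rng(seed)
    x = DiscreteSeries(r.integers(0, M, n), M)
    y = DiscreteSeries(r.integers(0, M, n), M)
    a = transfer_entropy(x, y, tau, min_window=5, method="log-ratio").value
    b = transfer_entropy(x, y, tau, min_window=5, method="cmi").value
    assert a == pytest.approx(b, abs=1e-12)
    assert a >= 0.0
    assert a == pytest.approx(te_bruteforce(x, y, tau), abs=1e-12)


@given(st.integers(min_value=0, max_value=2**30))
def test_measures_match_bruteforce_on_empirical_tables(seed):
    r = np.random.default_rng(seed)
    M = int(r.integers(2, 5))
    n = int(r.integers(10, 51))
    x = DiscreteSeries(r.integers(0, M, n), M)
    y = DiscreteSeries(r.integers(0, M, n), M)
    j2 = empirical_joint([x, y], [0, 0])
    assert mutual_information(j2) == pytest.approx(
        entropy_bruteforce(j2.table.sum(axis=1))
        + entropy_bruteforce(j2.table.sum(axis=0))
        - entropy_bruteforce(j2.table),
        abs=1e-12,
    )
    z = DiscreteSeries(r.integers(0, M, n), M)
    j3 = empirical_joint([x, y, z], [0, 0, 0])
    assert conditional_mutual_information(j3) == pytest.approx(
        cmi_bruteforce(j3.table), abs=1e-12
    )


def test_te_from_joint_rejects_wrong_arity():
    with pytest.raises(ValueError):
        te_from_joint(np.ones((2, 2)) / 4)
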