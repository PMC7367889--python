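"""GOF bootstrap test, accuracy, KS, D'Hondt allocation, cross-validation."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from edith.calibration import ChainSettings, TaxonReads
from edith.evaluation import (
    accuracy_vs_reference,
    cross_validate,
    dhondt_allocation,
    edna_presence_rule,
    gof_test,
    gof_test_sites,
    ks_two_sample,
    stratified_subsample,
)
from edith.synthetic import (
    place_sites,
    simulate_reads,
    synthetic_covariates,
    synthetic_network,
)
from edith.forward import ModelParams


# -- goodness of fit ------------------------------------------------------


def test_gof_p_value_bounds():
    rng = np.random.default_rng(0)
    for _ in range(5):
        trip = rng.integers(0, 30, size=3)
        H = 500
        p = gof_test(trip, 4.0, H=H, seed=int(rng.integers(1000)))
        assert 1 / (1 + H) <= p <= 1.0


def test_gof_degenerate_site_is_consistent():
    # all replicates equal to the predicted mean -> s_j = 0 -> p = 1
    assert gof_test(np.array([2.0, 2.0, 2.0]), 2.0, H=100, seed=0) == 1.0


def test_gof_matches_independent_reimplementation():
    """Dual route: plain-loop implementation of the statistic on the same
    bootstrap draws reproduces the vectorized p-value exactly."""
    trip = np.array([0, 7, 1])
    n_hat = 2.3
    H, seed = 400, 13
    ours = gof_test(trip, n_hat, H=H, seed=seed)

    rng = np.random.default_rng(seed)
    draws = rng.geometric(1 / (1 + n_hat), size=(H, 3)) - 1
    s_obs = np.sqrt(sum((x - n_hat) ** 2 for x in trip))
    r_obs = sorted((x - n_hat) / s_obs for x in trip)
    boot_resid = []
    for h in range(H):
        s_h = np.sqrt(sum((x - n_hat) ** 2 for x in draws[h]))
        if s_h == 0:
            boot_resid.append([0.0, 0.0, 0.0])
        else:
            boot_resid.append(sorted((x - n_hat) / s_h for x in draws[h]))
    r50 = [float(np.median([boot_resid[h][o] for h in range(H)]))
           for o in range(3)]
    d_obs = sum((r_obs[o] - r50[o]) ** 2 for o in range(3))
    exceed = sum(
        1 for h in range(H)
        if sum((boot_resid[h][o] - r50[o]) ** 2 for o in range(3)) >= d_obs
    )
    assert ours == pytest.approx((1 + exceed) / (1 + H), abs=1e-15)


def test_gof_null_rejection_rate_quick():
    """Data generated from the hypothesized geometric law should rarely be
    rejected (quick version at reduced scale)."""
    rng = np.random.default_rng(99)
    n_sites, H = 250, 400
    n_hat = np.exp(rng.uniform(np.log(0.5), np.log(50), size=n_sites))
    counts = rng.geometric(1 / (1 + n_hat[:, None]), size=(n_sites, 3)) - 1
    reads = TaxonReads([f"s{j}" for j in range(n_sites)], counts)
    gof = gof_test_sites(reads, n_hat, H=H, seed=1)
    rate = 1 - gof.fraction_not_rejected
    assert 0.0 <= rate <= 0.12


def test_gof_detects_gross_misfit():
    trip = np.array([500, 480, 510])  # far from a mean-1 geometric law
    assert gof_test(trip, 1.0, H=2000, seed=3) < 0.05


# -- accuracy -------------------------------------------------------------


def test_perfect_agreement():
    v = np.array([True, False, True, True])
    cc = accuracy_vs_reference(v, v)
    assert cc.accuracy == 1.0 and cc.FP == cc.FN == 0


def test_all_false_positives():
    cc = accuracy_vs_reference(np.ones(5, bool), np.zeros(5, bool))
    assert cc.accuracy == 0.0
    assert cc.accuracy_fp_ok == 1.0


def test_hand_built_confusion_table():
    model = np.array([1, 1, 0, 0, 1, 0, 1, 0, 1, 0], bool)
    ref = np.array([1, 0, 0, 1, 1, 0, 0, 0, 1, 1], bool)
    cc = accuracy_vs_reference(model, ref)
    assert (cc.TP, cc.TN, cc.FP, cc.FN) == (3, 3, 2, 2)
    assert cc.accuracy == pytest.approx(0.6)
    assert cc.accuracy + (cc.FP + cc.FN) / cc.total == pytest.approx(1.0)


def test_mismatched_site_sets_rejected():
    with pytest.raises(ValueError):
        accuracy_vs_reference(np.ones(3, bool), np.ones(4, bool))


@pytest.mark.parametrize(
    "triplet, present",
    [((5, 0, 0), False), ((1, 1, 0), True), ((0, 0, 0), False),
     ((2, 3, 4), True)],
)
def test_edna_presence_rule(triplet, present):
    assert edna_presence_rule(np.array(triplet)) is present


# -- Kolmogorov-Smirnov ---------------------------------------------------


def test_ks_identical_samples():
    x = np.array([1.0, 2.0, 3.0])
    D, p = ks_two_sample(x, x)
    assert D == 0.0 and p == pytest.approx(1.0)


def test_ks_disjoint_supports():
    D, _ = ks_two_sample([1, 2, 3], [10, 11, 12])
    assert D == 1.0


def test_ks_matches_ecdf_enumeration():
    x, y = np.array([1.0, 2, 3]), np.array([1.0, 2, 3, 4])
    D, _ = ks_two_sample(x, y)
    grid = np.concatenate([x, y])
    gaps = [abs((x <= t).mean() - (y <= t).mean()) for t in grid]
    assert D == pytest.approx(max(gaps))


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_ks_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=12)
    y = rng.normal(0.5, 1.5, size=9)
    D1, _ = ks_two_sample(x, y)
    D2, _ = ks_two_sample(np.exp(x), np.exp(y))
    assert D1 == pytest.approx(D2)


def test_ks_empty_sample_rejected():
    with pytest.raises(ValueError):
        ks_two_sample([], [1.0])


# -- D'Hondt allocation ---------------------------------------------------


def test_dhondt_exact_proportionality():
    assert dhondt_allocation([20, 10], 3).tolist() == [2, 1]


def test_dhondt_matches_quotient_table():
    counts, n = [7, 5, 3], 4
    alloc = dhondt_allocation(counts, n)
    # brute force: all quotients, top n
    quots = sorted(
        ((c / k, c, -s) for s, c in enumerate(counts) for k in range(1, n + 1)),
        reverse=True,
    )[:n]
    manual = np.zeros(3, dtype=int)
    for _, c, negs in quots:
        manual[-negs] += 1
    assert alloc.tolist() == manual.tolist()


def test_dhondt_zero_seats():
    assert dhondt_allocation([3, 2], 0).tolist() == [0, 0]


def test_dhondt_all_zero_rejected():
    with pytest.raises(ValueError):
        dhondt_allocation([0, 0], 2)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    st.lists(st.integers(0, 40), min_size=1, max_size=6).filter(
        lambda c: sum(c) > 0),
    st.integers(0, 30),
)
def test_dhondt_allocations_sum_to_total(counts, n):
    assert dhondt_allocation(counts, n).sum() == n


# -- stratified subsampling -----------------------------------------------


@pytest.mark.parametrize("fraction, n_cal", [(0.8, 49), (0.6, 37), (0.4, 25)])
def test_subset_sizes_on_61_sites(fraction, n_cal):
    rng = np.random.default_rng(8)
    sites = [f"s{j}" for j in range(61)]
    orders = rng.choice([1, 2, 3, 4], size=61, p=[0.35, 0.3, 0.2, 0.15])
    calib, valid = stratified_subsample(sites, orders, fraction, seed=2)
    assert len(calib) == n_cal
    assert len(valid) == 61 - n_cal
    assert set(calib) | set(valid) == set(sites)


def test_subsample_keeps_order_proportions():
    sites = [f"s{j}" for j in range(60)]
    orders = np.repeat([1, 2, 3], [30, 20, 10])
    calib, _ = stratified_subsample(sites, orders, 0.5, seed=0)
    calib_orders = orders[[int(s[1:]) for s in calib]]
    assert (np.bincount(calib_orders, minlength=4)[1:] == [15, 10, 5]).all()


def test_subsample_is_seed_deterministic():
    sites = [f"s{j}" for j in range(30)]
    orders = np.ones(30, dtype=int)
    a = stratified_subsample(sites, orders, 0.7, seed=5)
    b = stratified_subsample(sites, orders, 0.7, seed=5)
    assert a == b


# -- cross-validation -----------------------------------------------------


@pytest.fixture(scope="module")
def tiny_crossval():
    rng = np.random.default_rng(31)
    net = synthetic_network(30, seed=int(rng.integers(2**31 - 1)))
    X = synthetic_covariates(net, 2, seed=int(rng.integers(2**31 - 1)))
    sites = place_sites(net, 12, seed=int(rng.integers(2**31 - 1)))
    reads = {}
    for t, beta in (("taxA", [1.5, 0.0]), ("taxB", [0.0, -1.5])):
        reads[t] = simulate_reads(
            net, X, ModelParams(np.array(beta), 2e-4, 5400.0), sites,
            seed=int(rng.integers(2**31 - 1)), taxon=t)
    orders = {s: int(net.strahler[net.index(s)]) for s in sites}
    result = cross_validate(
        net, X, reads, orders,
        fractions=(0.75, 1.0), n_reps=1,
        settings=ChainSettings(n_burn=300, n_keep=600),
        H=200, seed=5,
    )
    return result


def test_degenerate_full_fraction_has_zero_loss(tiny_crossval):
    full = tiny_crossval.per_simulation.query("fraction == 1.0")
    assert (full["loss_gof_all"] == 0).all()
    assert (full["loss_gof_calibration"] == 0).all()


def test_loss_weighted_average_identity(tiny_crossval):
    rows = tiny_crossval.per_simulation.query("fraction < 1.0")
    for _, row in rows.iterrows():
        n_c, n_v = row["n_calibration"], row["n_validation"]
        weighted = (n_c * row["loss_gof_calibration"]
                    + n_v * row["loss_gof_validation"]) / (n_c + n_v)
        assert row["loss_gof_all"] == pytest.approx(weighted, abs=1e-9)


def test_crossval_reports_every_group_and_taxon(tiny_crossval):
    sim = tiny_crossval.per_simulation
    assert set(sim["group"]) == {"AS1", "AS2"}
    assert set(sim["taxon"]) == {"taxA", "taxB"}
    assert set(tiny_crossval.per_group["group"]) == {"AS1", "AS2"}
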