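import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from segmatch import (
    Monomer,
    SynthSpec,
    chisq_two_proportions,
    compare_all,
    make_fec,
    make_genome,
    mann_whitney_u,
    sweep_lengths,
)
from segmatch.group_stats import compare_sweep


def exact_mw_pvalue(x, y):
    """Exact two-sided p by enumerating all rank assignments (no ties)."""
    pooled = sorted(x + y)
    n = len(x)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in x) - n * (n + 1) / 2
    m = len(y)
    us = []
    for idx in combinations(range(1, n + m + 1), n):
        us.append(sum(idx) - n * (n + 1) / 2)
    mean_u = n * m / 2
    extreme = sum(1 for u in us if abs(u - mean_u) >= abs(u_obs - mean_u))
    return extreme / len(us)


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        u, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_exact_enumeration_small_samples(self):
        u, p = mann_whitney_u([1, 2, 3], [101, 102, 103])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 * (1/20) over C(6,3) arrangements
        assert p == pytest.approx(exact_mw_pvalue([1, 2, 3], [101, 102, 103]))

    def test_swap_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=12), rng.normal(1.0, 1.0, size=9)
        _, p1 = mann_whitney_u(x, y)
        _, p2 = mann_whitney_u(y, x)
        assert p1 == pytest.approx(p2)

    def test_empty_sampling_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_agrees_with_reference_on_random_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            n, m = rng.integers(9, 25, size=2)
            x = rng.normal(size=n)
            y = rng.normal(size=m)
            u, p = mann_whitney_u(x, y)
            ref = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=False
            )
            assert abs(u - ref.statistic) < 1e-8
            assert abs(p - ref.pvalue) < 1e-6

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(2)
        hits = 0
        reps = 4000
        for _ in range(reps):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            hits += mann_whitney_u(x, y)[1] < 0.05
        rate = hits / reps
        se = math.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3.5 * se


class TestChisq:
    def test_equal_proportions_zero_statistic(self):
        s, p = chisq_two_proportions(3, 10, 6, 20)
        assert s == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        # oracle: sum (O-E)^2 / E over four cells
        k1, n1, k2, n2 = 30, 100, 10, 100
        obs = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        want = ((obs - exp) ** 2 / exp).sum()
        s, p = chisq_two_proportions(k1, n1, k2, n2)
        assert s == pytest.approx(want)
        assert p == pytest.approx(stats.chi2.sf(want, 1))

    def test_group_swap_invariance(self):
        s1, p1 = chisq_two_proportions(12, 40, 25, 60)
        s2, p2 = chisq_two_proportions(25, 60, 12, 40)
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)

    def test_zero_group_rejected(self):
        with pytest.raises(ValueError):
            chisq_two_proportions(0, 0, 1, 10)

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(3)
        hits = 0
        reps = 4000
        for _ in range(reps):
            k1 = rng.binomial(80, 0.3)
            k2 = rng.binomial(80, 0.3)
            hits += chisq_two_proportions(k1, 80, k2, 80)[1] < 0.05
        rate = hits / reps
        se = math.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3.5 * se


@pytest.fixture(scope="module")
def two_strain_sweep():
    spec = SynthSpec(
        n_sections=10,
        section_length=3000,
        monomers=(Monomer(sections=(1, 4, 7), copy_number=5, length=100),),
        lambda0=1.0,
        lambda1=10.0,
        seed=31,
    )
    _, ss, truth = make_genome(spec)
    fecs = {
        "coupled": make_fec(truth, seed=32, strain="coupled"),
    }
    # null strain: same marginal rates but decoupled from the sequence
    null_truth = type(truth)(
        labels=truth.labels,
        planted={l: set() for l in truth.labels},
        shared=np.zeros_like(truth.shared),
        lam=np.full_like(truth.lam, truth.lam[np.triu_indices(10, 1)].mean()),
        monomer_seqs=[],
    )
    np.fill_diagonal(null_truth.lam, 0)
    fecs["null"] = make_fec(null_truth, seed=33, strain="null")
    return sweep_lengths(ss, fecs, L_list=(10, 20), filters=(False,))


class TestCompareAll:
    def test_row_count_matches_design(self, two_strain_sweep):
        table = compare_sweep(two_strain_sweep, ref_L=20)
        # factors: strain (2 types x 2 L), type (2 strains x 2 L),
        # L vs ref (2 strains x 2 types); two tests per contrast
        assert len(table) == 2 * (4 + 4 + 4)
        assert set(table["test"]) == {"mannwhitney_R", "chisq_P"}

    def test_identical_conditions_not_compared(self, two_strain_sweep):
        table = compare_sweep(two_strain_sweep, ref_L=20)
        assert (table["level_a"] != table["level_b"]).all()

    def test_dispatcher(self, two_strain_sweep):
        assert len(compare_all(two_strain_sweep, ref_L=20)) > 0

    def test_planted_strain_differs_in_specific_significance(self):
        """Sequence-coupled contacts vs decoupled contacts: the specific-P
        contrast at the planted L must come out significant."""
        spec = SynthSpec(
            n_sections=20,
            section_length=5000,
            monomers=(Monomer(sections=(1, 4, 7, 10, 13, 16), copy_number=5, length=150),),
            lambda0=1.0,
            lambda1=12.0,
            seed=41,
        )
        _, ss, truth = make_genome(spec)
        null_lam = np.full_like(truth.lam, 1.0)
        np.fill_diagonal(null_lam, 0)
        null_truth = type(truth)(
            labels=truth.labels,
            planted={l: set() for l in truth.labels},
            shared=np.zeros_like(truth.shared),
            lam=null_lam,
        )
        fecs = {
            "coupled": make_fec(truth, seed=42, strain="coupled"),
            "null": make_fec(null_truth, seed=43, strain="null"),
        }
        sweep = sweep_lengths(ss, fecs, L_list=(15,), filters=(False,))
        table = compare_sweep(sweep, ref_L=15)
        row = table[
            (table["factor"] == "strain")
            & (table["type"] == "specific")
            & (table["test"] == "chisq_P")
        ]
        assert len(row) == 1
        assert bool(row["significant"].iloc[0])
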