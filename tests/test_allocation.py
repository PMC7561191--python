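"""The seeding allocator: seeds, windows, distance scores, conversion."""

import numpy as np
import pytest

from landseed.allocation import (
    NoEligibleSeed,
    PatchWindow,
    SeedingConfig,
    allocate_all,
    allocate_county,
    annular_distance,
    build_patch_window,
    convert_patch,
    distance_modify,
    select_seed,
)
from landseed.grid import (
    ClassCode,
    CountyPartition,
    LandUseGrid,
    QuotaLedger,
    TransitionKey,
    build_quota_ledgers,
)
from landseed.probability import TransitionProbabilityStack
from landseed.synthetic import (
    LandscapeRecipe,
    generate_landscape,
    generate_quotas,
    random_probability_stack,
)

D, F, A, W, O = (ClassCode.DEVELOPED, ClassCode.FOREST, ClassCode.AGRICULTURE,
                 ClassCode.WATER, ClassCode.OTHER)
FD, AD, AF = TransitionKey(F, D), TransitionKey(A, D), TransitionKey(A, F)


class TestAnnularDistance:
    @pytest.mark.parametrize("a,b,d", [
        ((0, 0), (0, 0), 0),
        ((0, 0), (2, 1), 2),
        ((3, 3), (1, 5), 2),
    ])
    def test_examples(self, a, b, d):
        assert annular_distance(a, b) == d

    def test_matches_max_abs_on_random_pairs(self):
        rng = np.random.default_rng(0)
        pts = rng.integers(-50, 50, size=(1000, 4))
        for r1, c1, r2, c2 in pts:
            assert annular_distance((r1, c1), (r2, c2)) == max(
                abs(r1 - r2), abs(c1 - c2))


class TestSelectSeed:
    def _surface(self):
        gen = np.zeros((10, 10))
        eligible = np.zeros((10, 10), dtype=bool)
        rng = np.random.default_rng(1)
        cells = [(i, j) for i in range(10) for j in range(10)]
        rng.shuffle(cells)
        for (i, j) in cells[:50]:
            eligible[i, j] = True
            gen[i, j] = rng.uniform(0.1, 0.9)
        return gen, eligible

    def test_contagious_limit_unique_argmax(self):
        gen, eligible = self._surface()
        gen[3, 4] = 0.99
        eligible[3, 4] = True
        rng = np.random.default_rng(0)
        for _ in range(200):
            cell, p = select_seed(gen, eligible, n=10_000, rng=rng)
            assert cell == (3, 4) and p == 0.99

    def test_random_limit_uniform(self):
        """n = 1 makes seed positions uniform over eligible cells."""
        gen, eligible = self._surface()
        rng = np.random.default_rng(5)
        counts = {}
        for _ in range(5000):
            cell, _ = select_seed(gen, eligible, n=1, rng=rng)
            counts[cell] = counts.get(cell, 0) + 1
        observed = np.array([counts.get(tuple(c), 0)
                             for c in np.argwhere(eligible)])
        from scipy import stats
        chi2 = ((observed - 100.0) ** 2 / 100.0).sum()
        p = stats.chi2.sf(chi2, df=observed.size - 1)
        assert p > 0.001

    def test_tie_break_uniform(self):
        gen = np.zeros((2, 5))
        gen[0, 0] = gen[1, 4] = 0.9
        gen[0, 2] = 0.5
        eligible = gen > 0
        rng = np.random.default_rng(11)
        hits = 0
        trials = 10_000
        for _ in range(trials):
            cell, _ = select_seed(gen, eligible, n=3, rng=rng)
            hits += cell == (0, 0)
        assert abs(hits / trials - 0.5) <= 0.02

    def test_no_eligible_raises(self):
        with pytest.raises(NoEligibleSeed):
            select_seed(np.zeros((3, 3)), np.zeros((3, 3), bool), 5,
                        np.random.default_rng(0))


class TestPatchWindow:
    def _grid(self, n=9):
        return LandUseGrid(np.full((n, n), int(F)))

    def test_k1_singleton(self):
        grid = self._grid()
        gen = np.full(grid.shape, 0.5)
        w = build_patch_window((4, 4), 1, np.ones(grid.shape, bool), grid, gen, D)
        assert w.radius == 0
        assert list(zip(w.rows, w.cols)) == [(4, 4)]
        assert w.n_candidates == 1

    def test_k5_interior_25_cells(self):
        grid = self._grid()
        gen = np.full(grid.shape, 0.5)
        w = build_patch_window((4, 4), 5, np.ones(grid.shape, bool), grid, gen, D)
        assert w.radius == 2 and len(w.rows) == 25

    def test_clipped_to_county_matches_brute_force(self):
        grid = self._grid()
        county = np.zeros(grid.shape, bool)
        county[:, :4] = True  # seed one cell from the county edge
        gen = np.full(grid.shape, 0.5)
        seed = (4, 2)
        w = build_patch_window(seed, 5, county, grid, gen, D)
        expected = {
            (i, j)
            for i in range(9) for j in range(9)
            if county[i, j] and max(abs(i - seed[0]), abs(j - seed[1])) <= 2
        }
        assert set(zip(w.rows.tolist(), w.cols.tolist())) == expected

    def test_candidate_flags(self):
        values = np.full((3, 3), int(F))
        values[0, 0] = int(D)     # never a candidate
        values[0, 1] = int(W)     # never a candidate
        values[0, 2] = int(A)
        grid = LandUseGrid(values)
        gen = np.full((3, 3), 0.4)
        gen[1, 0] = 0.0           # zero probability -> not a candidate
        w = build_patch_window((1, 1), 3, np.ones((3, 3), bool), grid, gen, D)
        flags = {(r, c): bool(f)
                 for r, c, f in zip(w.rows, w.cols, w.candidate)}
        assert not flags[(0, 0)] and not flags[(0, 1)] and not flags[(1, 0)]
        assert flags[(0, 2)] and flags[(1, 1)] and flags[(2, 2)]

    def test_even_k_rejected(self):
        grid = self._grid()
        with pytest.raises(ValueError):
            build_patch_window((4, 4), 4, np.ones(grid.shape, bool), grid,
                               np.zeros(grid.shape), D)


def _window(probs, dists, radius):
    n = len(probs)
    return PatchWindow(
        seed=(0, 0), radius=radius,
        rows=np.zeros(n, dtype=int), cols=np.arange(n),
        distances=np.asarray(dists), candidate=np.ones(n, dtype=bool),
        probabilities=np.asarray(probs, dtype=float),
    )


class TestDistanceModify:
    def test_flat_probabilities(self):
        """With sigma = 0 and r = 2, the cell at distance 1 scores
        0.5 + (1 - 1/2)(1 - 0) = 1.0 and the rim cell stays at 0.5."""
        w = _window([0.5, 0.5, 0.5], [0, 1, 2], radius=2)
        scores = distance_modify(w)
        np.testing.assert_allclose(scores, [1.5, 1.0, 0.5])

    def test_rim_cell_unchanged(self):
        for r in (1, 2, 5):
            w = _window([0.3, 0.7], [r, r], radius=r)
            np.testing.assert_allclose(distance_modify(w), [0.3, 0.7])

    @pytest.mark.parametrize("sigma", [0.0, 0.1, 0.3])
    def test_center_rim_spread_is_one_minus_sigma(self, sigma):
        """Score difference between a center and a rim cell sharing the same
        probability equals exactly (1 - sigma)."""
        c = sigma * np.sqrt(2.0)  # two extra values at +-c give pop. SD sigma
        probs = [0.5, 0.5, 0.5 + c, 0.5 - c]
        w = _window(probs, [0, 3, 1, 2], radius=3)
        scores = distance_modify(w)
        assert np.std(w.probabilities) == pytest.approx(sigma)
        assert scores[0] - scores[1] == pytest.approx(1.0 - sigma)

    def test_r0_leaves_probabilities(self):
        w = _window([0.42], [0], radius=0)
        np.testing.assert_allclose(distance_modify(w), [0.42])

    def test_single_candidate_uses_sigma_zero(self):
        w = _window([0.4], [0], radius=2)
        np.testing.assert_allclose(distance_modify(w), [0.4 + 1.0])


def _conversion_fixture(values, quotas, gen_value=0.5):
    grid = LandUseGrid(values)
    stack = TransitionProbabilityStack(grid.shape)
    for key in stack.probs:
        stack.probs[key][values == key.donor] = gen_value / 3
    ledger = QuotaLedger(1, quotas)
    return grid, stack, ledger


class TestConvertPatch:
    def test_k_highest_scores_converted(self):
        values = np.full((5, 5), int(F))
        grid, stack, ledger = _conversion_fixture(values, {FD: 100})
        gen = stack.generalized[D]
        w = build_patch_window((2, 2), 5, np.ones((5, 5), bool), grid, gen, D)
        scores = distance_modify(w)
        converted = convert_patch(w, scores, 3, ledger, D, grid, stack)
        assert len(converted) == 3
        # seed first (distance 0 maximizes the modifier), then nearest
        assert converted[0] == (2, 2)
        assert all(annular_distance((2, 2), c) <= 1 for c in converted)

    def test_quota_limits_conversion(self):
        values = np.full((5, 5), int(F))
        grid, stack, ledger = _conversion_fixture(values, {FD: 2})
        gen = stack.generalized[D]
        w = build_patch_window((2, 2), 9, np.ones((5, 5), bool), grid, gen, D)
        converted = convert_patch(w, distance_modify(w), 9, ledger, D,
                                  grid, stack)
        assert len(converted) == 2
        assert ledger.remaining[FD] == 0

    def test_mixed_donor_skips_spent_quota(self):
        """Forest quota 0, Agriculture quota 5: only agriculture candidates
        convert, up to k = 4."""
        values = np.full((5, 5), int(F))
        values[:, 3:] = int(A)
        grid, stack, ledger = _conversion_fixture(values, {FD: 0, AD: 5})
        gen = stack.generalized[D]
        w = build_patch_window((2, 2), 5, np.ones((5, 5), bool), grid, gen, D)
        converted = convert_patch(w, distance_modify(w), 4, ledger, D,
                                  grid, stack)
        assert len(converted) == 4
        assert all(values[r, c] == int(A) for r, c in converted)
        assert ledger.remaining[AD] == 1 and ledger.converted(FD) == 0

    def test_converted_cells_zeroed_and_relabelled(self):
        values = np.full((3, 3), int(F))
        grid, stack, ledger = _conversion_fixture(values, {FD: 9})
        gen = stack.generalized[D]
        w = build_patch_window((1, 1), 3, np.ones((3, 3), bool), grid, gen, D)
        converted = convert_patch(w, distance_modify(w), 5, ledger, D,
                                  grid, stack)
        for r, c in converted:
            assert grid.values[r, c] == int(D)
            for arr in stack.probs.values():
                assert arr[r, c] == 0.0

    def test_rank_shift_invariance(self):
        """Adding a constant to all candidate probabilities shifts every
        score equally (the SD is unchanged), so the converted set is
        identical."""
        rng = np.random.default_rng(6)
        base_probs = rng.uniform(0.1, 0.5, size=25)

        def run(shift):
            values = np.full((5, 5), int(F))
            grid = LandUseGrid(values)
            stack = TransitionProbabilityStack(grid.shape)
            stack.probs[FD][:, :] = (base_probs + shift).reshape(5, 5)
            ledger = QuotaLedger(1, {FD: 100})
            gen = stack.generalized[D]
            w = build_patch_window((2, 2), 5, np.ones((5, 5), bool), grid,
                                   gen, D)
            return set(convert_patch(w, distance_modify(w), 7, ledger, D,
                                     grid, stack))

        assert run(0.0) == run(0.3) == run(0.45)


def _county_fixture(n_forest=60, shape=(12, 12), quota=None, prob=0.5):
    rng = np.random.default_rng(0)
    values = np.full(shape, int(O))
    cells = [(i, j) for i in range(shape[0]) for j in range(shape[1])]
    rng.shuffle(cells)
    for (i, j) in cells[:n_forest]:
        values[i, j] = int(F)
    grid = LandUseGrid(values)
    stack = TransitionProbabilityStack(grid.shape)
    stack.probs[FD][values == int(F)] = prob
    ledger = QuotaLedger(1, quota or {FD: 50})
    return grid, stack, ledger


class TestAllocateCounty:
    def test_zero_quota_identity(self):
        grid, stack, _ = _county_fixture()
        before = grid.values.copy()
        ledger = QuotaLedger(1, {})
        allocate_county(grid, np.ones(grid.shape, bool), stack, ledger, {},
                        SeedingConfig(sample_size=8, rng_seed=0),
                        np.random.default_rng(0))
        np.testing.assert_array_equal(grid.values, before)

    def test_exact_quota_met(self):
        grid, stack, ledger = _county_fixture(n_forest=80, quota={FD: 50})
        t1 = grid.values.copy()
        report = allocate_county(grid, np.ones(grid.shape, bool), stack,
                                 ledger, {},
                                 SeedingConfig(sample_size=8, rng_seed=1),
                                 np.random.default_rng(1))
        changed = grid.values != t1
        assert int(changed.sum()) == 50
        assert np.all(t1[changed] == int(F))
        assert np.all(grid.values[changed] == int(D))
        assert report.converted[FD] == 50 and report.shortfall[FD] == 0

    def test_shortfall_when_supply_runs_out(self):
        grid, stack, ledger = _county_fixture(n_forest=30, quota={FD: 50})
        report = allocate_county(grid, np.ones(grid.shape, bool), stack,
                                 ledger, {},
                                 SeedingConfig(sample_size=4, rng_seed=2),
                                 np.random.default_rng(2))
        assert report.converted[FD] == 30
        assert report.shortfall[FD] == 20
        assert report.converted[FD] + report.shortfall[FD] == report.initial[FD]


@pytest.fixture(scope="module")
def allocation_problem():
    recipe = LandscapeRecipe(shape=(80, 80), county_layout=(2, 2),
                             clumpiness=0.8, seed=13)
    grid, counties, _ = generate_landscape(recipe)
    quotas = generate_quotas(grid, counties, 0.05)
    stack = random_probability_stack(grid, np.random.default_rng(17))
    return grid, counties, quotas, stack


class TestAllocateAll:
    def test_quota_only_in_one_county(self, allocation_problem):
        grid, counties, quotas, stack = allocation_problem
        sub = quotas[quotas.county == 1]
        ledgers = build_quota_ledgers(sub)
        for c in counties.county_ids[1:]:
            ledgers[c] = QuotaLedger(c, {})
        t2, _ = allocate_all(grid, counties, stack, ledgers, {},
                             SeedingConfig(sample_size=16, rng_seed=3))
        outside = ~counties.mask(1)
        np.testing.assert_array_equal(t2.values[outside],
                                      grid.values[outside])
        assert np.any(t2.values[counties.mask(1)]
                      != grid.values[counties.mask(1)])

    def test_deterministic_and_order_independent(self, allocation_problem):
        grid, counties, quotas, stack = allocation_problem
        config = SeedingConfig(sample_size=16, rng_seed=4)
        runs = []
        for order in ([1, 2, 3, 4], [4, 2, 1, 3], None):
            ledgers = build_quota_ledgers(quotas)
            t2, _ = allocate_all(grid, counties, stack, ledgers, {},
                                 config, county_order=order)
            runs.append(t2.values)
        np.testing.assert_array_equal(runs[0], runs[1])
        np.testing.assert_array_equal(runs[0], runs[2])

    def test_ledger_audit(self, allocation_problem):
        """Per key: conversions recorded in the grid, the ledger and the
        report all agree, and converted + shortfall = initial."""
        grid, counties, quotas, stack = allocation_problem
        ledgers = build_quota_ledgers(quotas)
        t2, reports = allocate_all(grid, counties, stack, ledgers, {},
                                   SeedingConfig(sample_size=16, rng_seed=5))
        for county, report in reports.items():
            cmask = counties.mask(county)
            for key, initial in report.initial.items():
                grid_conv = int(np.sum(cmask & (grid.values == key.donor)
                                       & (t2.values == key.target)))
                assert grid_conv == report.converted[key]
                assert report.converted[key] + report.shortfall[key] == initial

    def test_irreversibility(self, allocation_problem):
        grid, counties, quotas, stack = allocation_problem
        ledgers = build_quota_ledgers(quotas)
        t2, _ = allocate_all(grid, counties, stack, ledgers, {},
                             SeedingConfig(sample_size=16, rng_seed=6))
        for frozen in (D, W):
            assert np.all(t2.values[grid.values == frozen] == frozen)

    def test_missing_ledger_raises(self, allocation_problem):
        grid, counties, quotas, stack = allocation_problem
        ledgers = build_quota_ledgers(quotas[quotas.county == 1])
        with pytest.raises(ValueError, match="ledger"):
            allocate_all(grid, counties, stack, ledgers, {},
                         SeedingConfig(sample_size=8, rng_seed=0))
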