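import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from shapeatlas import (
    BinaryVolume,
    EvalRecord,
    ProbabilityVolume,
    VolumeGrid,
    best_threshold_eval,
    compare_methods,
    dice,
    hausdorff,
    iprob,
    jaccard,
    leave_one_out,
    ncf_atlas,
    threshold_atlas,
)
from shapeatlas.errors import DomainError, PairingError, UndefinedMeasureError
from shapeatlas.evaluation import (
    ATLAS_METHODS,
    REGISTRATION_MODELS,
    LeaveOneOutConfig,
    holm_adjust,
    method_label,
)
from shapeatlas.registration import RegistrationOptions

from conftest import ball_volume, random_binary


def brute_hausdorff(a, b):
    pa = a.grid.index_grid_physical().reshape(-1, 3)[a.occupancy.reshape(-1) > 0]
    pb = b.grid.index_grid_physical().reshape(-1, 3)[b.occupancy.reshape(-1) > 0]
    d = cdist(pa, pb)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


class TestBinaryMeasures:
    def test_dice_identical(self, unit_grid):
        v = ball_volume(unit_grid, 4.0)
        assert dice(v, v) == 1.0
        assert jaccard(v, v) == 1.0
        assert hausdorff(v, v) == 0.0

    def test_dice_disjoint(self, unit_grid):
        a = ball_volume(unit_grid, 2.0, center=(3, 3, 3))
        b = ball_volume(unit_grid, 2.0, center=(12, 12, 12))
        assert dice(a, b) == 0.0

    def test_counted_example(self):
        grid = VolumeGrid((10, 1, 1), (1, 1, 1))
        a = np.zeros(grid.dims, dtype=np.uint8)
        b = np.zeros(grid.dims, dtype=np.uint8)
        a[:4] = 1          # |A| = 4
        b[1:7] = 1         # |B| = 6, |A&B| = 3
        av, bv = BinaryVolume(grid, a), BinaryVolume(grid, b)
        assert dice(av, bv) == pytest.approx(0.6)
        assert jaccard(av, bv) == pytest.approx(3 / 7)

    def test_jaccard_dice_identity(self, unit_grid):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = random_binary(unit_grid, rng)
            b = random_binary(unit_grid, rng)
            d = dice(a, b)
            j = jaccard(a, b)
            assert j == pytest.approx(d / (2 - d), abs=1e-12)
            assert j <= d + 1e-12

    def test_empty_pair_undefined(self, unit_grid):
        empty = BinaryVolume(unit_grid, np.zeros(unit_grid.dims, dtype=np.uint8))
        with pytest.raises(UndefinedMeasureError):
            dice(empty, empty)
        with pytest.raises(UndefinedMeasureError):
            hausdorff(empty, ball_volume(unit_grid, 3.0))

    def test_two_point_hausdorff(self):
        grid = VolumeGrid((8, 1, 1), (1, 1, 1))
        a = np.zeros(grid.dims, dtype=np.uint8)
        b = np.zeros(grid.dims, dtype=np.uint8)
        a[2] = 1
        b[5] = 1
        assert hausdorff(BinaryVolume(grid, a), BinaryVolume(grid, b)) == 3.0

    def test_hausdorff_matches_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            dims = tuple(rng.integers(3, 11, size=3))
            grid = VolumeGrid(dims, tuple(rng.uniform(0.8, 2.0, size=3)))
            a = random_binary(grid, rng, p=0.2)
            b = random_binary(grid, rng, p=0.2)
            assert hausdorff(a, b) == pytest.approx(brute_hausdorff(a, b), abs=1e-6)

    def test_hausdorff_metric_properties(self, unit_grid):
        rng = np.random.default_rng(6)
        for _ in range(10):
            a, b, c = (random_binary(unit_grid, rng, p=0.15) for _ in range(3))
            assert hausdorff(a, b) == pytest.approx(hausdorff(b, a), abs=1e-9)
            assert hausdorff(a, c) <= hausdorff(a, b) + hausdorff(b, c) + 1e-9

    def test_one_minus_jaccard_triangle(self, unit_grid):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a, b, c = (random_binary(unit_grid, rng, p=0.3) for _ in range(3))
            dab = 1 - jaccard(a, b)
            dbc = 1 - jaccard(b, c)
            dac = 1 - jaccard(a, c)
            assert dac <= dab + dbc + 1e-12


class TestIProb:
    def test_indicator_gives_one(self, unit_grid):
        s = ball_volume(unit_grid, 4.0)
        p = ProbabilityVolume(unit_grid, s.occupancy.astype(np.float32))
        assert iprob(p, s) == 1.0

    def test_uniform_half_gives_zero(self, unit_grid):
        s = ball_volume(unit_grid, 4.0)
        p = ProbabilityVolume(unit_grid, np.full(unit_grid.dims, 0.5))
        assert iprob(p, s) == pytest.approx(0.0, abs=1e-7)

    def test_complement_indicator_gives_minus_one(self, unit_grid):
        s = ball_volume(unit_grid, 4.0)
        p = ProbabilityVolume(unit_grid, 1.0 - s.occupancy.astype(np.float32))
        assert iprob(p, s) == -1.0

    def test_antisymmetry_under_complement(self, unit_grid):
        rng = np.random.default_rng(8)
        s = ball_volume(unit_grid, 5.0)
        for _ in range(5):
            p = ProbabilityVolume(unit_grid, rng.random(unit_grid.dims))
            q = ProbabilityVolume(unit_grid, 1.0 - p.prob)
            assert iprob(p, s) + iprob(q, s) == pytest.approx(0.0, abs=1e-6)

    def test_degenerate_shape_rejected(self, unit_grid):
        p = ProbabilityVolume(unit_grid, np.zeros(unit_grid.dims))
        empty = BinaryVolume(unit_grid, np.zeros(unit_grid.dims, dtype=np.uint8))
        full = BinaryVolume(unit_grid, np.ones(unit_grid.dims, dtype=np.uint8))
        with pytest.raises(UndefinedMeasureError):
            iprob(p, empty)
        with pytest.raises(UndefinedMeasureError):
            iprob(p, full)


class TestBestThreshold:
    def test_indicator_truth(self, unit_grid):
        truth = ball_volume(unit_grid, 4.0)
        p = ProbabilityVolume(unit_grid, truth.occupancy.astype(np.float32))
        best = best_threshold_eval(p, truth)
        assert best["dice"] == 1.0
        assert best["hausdorff"] == 0.0
        assert best["thresholds"]["dice"] == 0.0  # lowest tie wins

    def test_two_shape_ncf_matches_enumeration(self, unit_grid):
        a = ball_volume(unit_grid, 4.0, center=(6, 7, 7))
        b = ball_volume(unit_grid, 4.0, center=(9, 8, 8))
        p = ncf_atlas([a, b])
        best = best_threshold_eval(p, a)
        by_hand = max(
            dice(threshold_atlas(p, t), a) for t in np.arange(0.0, 1.0, 0.1)
        )
        assert best["dice"] == pytest.approx(by_hand)
        # threshold 0 binarizes to the union
        union = threshold_atlas(p, 0.0)
        assert np.array_equal(
            union.occupancy, (a.occupancy | b.occupancy)
        )

    def test_all_degenerate(self, unit_grid):
        p = ProbabilityVolume(unit_grid, np.zeros(unit_grid.dims))
        truth = ball_volume(unit_grid, 3.0)
        with pytest.raises(UndefinedMeasureError):
            best_threshold_eval(p, truth)


class TestEvalRecord:
    def test_jaccard_cannot_exceed_dice(self):
        with pytest.raises(DomainError):
            EvalRecord("c", "NCF+R", dice=0.5, jaccard=0.7, hausdorff=1.0)


def _fake_records(n_cases=6, seed=0, delta=0.0):
    """Records for all 12 method labels with controllable mean offsets."""
    rng = np.random.default_rng(seed)
    records = []
    labels = [
        method_label(a, r) for a in ATLAS_METHODS for r in REGISTRATION_MODELS
    ]
    for i, label in enumerate(labels):
        sta = label.startswith("STA")
        for c in range(n_cases):
            d = float(np.clip(0.7 + delta * i + rng.normal(0, 0.02), 0.05, 0.99))
            records.append(
                EvalRecord(
                    f"case{c}", label, dice=d, jaccard=d / (2 - d),
                    hausdorff=10 - delta * i + rng.normal(0, 0.5),
                    iprob=None if sta else d - 0.1,
                )
            )
    return records


class TestCompareMethods:
    def test_twelve_labels_and_66_tests(self):
        table = compare_methods(_fake_records())
        assert len(table.summary) == 12
        assert table.n_tests == 66
        assert len(list(itertools.combinations(range(12), 2))) == 66

    def test_identical_values_give_p_one(self, unit_grid):
        records = []
        for label in ("NCF+R", "NCF+TRS"):
            for c in range(5):
                records.append(
                    EvalRecord(f"case{c}", label, 0.8, 0.8 / 1.2, 5.0, 0.5)
                )
        table = compare_methods(records)
        assert table.pvalues["dice"].loc["NCF+R", "NCF+TRS"] == 1.0
        assert not table.significant["dice"].loc["NCF+R", "NCF+TRS"]
        assert table.winners["dice"].loc["NCF+R", "NCF+TRS"] == ""

    def test_paired_t_matches_closed_form(self):
        x = np.array([0.70, 0.72, 0.68, 0.75])
        y = np.array([0.60, 0.66, 0.64, 0.65])
        records = []
        for c, (a, b) in enumerate(zip(x, y)):
            records.append(EvalRecord(f"case{c}", "NCF+R", a, a / (2 - a), 1.0, 0.1))
            records.append(EvalRecord(f"case{c}", "GLM+R", b, b / (2 - b), 1.0, 0.1))
        table = compare_methods(records, adjust="none")
        diff = x - y
        t_expected = diff.mean() / (diff.std(ddof=1) / np.sqrt(len(diff)))
        from scipy import stats

        p_expected = 2 * stats.t.sf(abs(t_expected), len(diff) - 1)
        assert table.pvalues["dice"].loc["NCF+R", "GLM+R"] == pytest.approx(
            p_expected, abs=1e-10
        )

    def test_iprob_tests_exclude_sta(self):
        table = compare_methods(_fake_records())
        mat = table.pvalues["iprob"]
        assert np.isnan(mat.loc["STA+R", "NCF+R"])
        assert not np.isnan(mat.loc["GLM+R", "NCF+R"])

    def test_unpaired_cases_rejected(self):
        records = [
            EvalRecord("c0", "NCF+R", 0.8, 0.7, 1.0, 0.1),
            EvalRecord("c1", "NCF+R", 0.8, 0.7, 1.0, 0.1),
            EvalRecord("c0", "GLM+R", 0.8, 0.7, 1.0, 0.1),
            EvalRecord("cX", "GLM+R", 0.8, 0.7, 1.0, 0.1),
        ]
        with pytest.raises(PairingError):
            compare_methods(records)

    def test_holm_adjustment(self):
        p = [0.01, 0.04, 0.03, 0.005]
        adj = holm_adjust(p)
        # step-down by hand: sorted p (0.005, 0.01, 0.03, 0.04) * (4,3,2,1)
        assert adj[3] == pytest.approx(0.02)
        assert adj[0] == pytest.approx(0.03)
        assert adj[2] == pytest.approx(0.06)
        assert adj[1] == pytest.approx(0.06)  # monotonicity enforcement
        assert (holm_adjust([0.5] * 10) <= 1.0).all()


FAST_LOO = LeaveOneOutConfig(
    reg_opts=RegistrationOptions(xtol=1e-2, ftol=5e-3, maxiter=10)
)


class TestLeaveOneOut:
    def test_degenerate_patients(self):
        grid = VolumeGrid((24, 24, 24), (1.5, 1.5, 1.5))
        v = ball_volume(grid, 9.0)
        sample = [("p1", v), ("p2", v), ("p3", v)]
        records = leave_one_out(sample, "NCF", "rigid", FAST_LOO)
        assert len(records) == 3
        for r in records:
            assert r.dice == 1.0
            assert r.jaccard == 1.0
            assert r.hausdorff == 0.0
            assert r.iprob >= 0.99

    def test_heldout_patient_excluded(self, monkeypatch):
        grid = VolumeGrid((24, 24, 24), (1.5, 1.5, 1.5))
        v = ball_volume(grid, 9.0)
        sample = [("p1", v), ("p1", v), ("p2", v), ("p3", v)]
        seen = []
        import shapeatlas.evaluation as ev

        orig = ev._build_atlas

        def spy(aligned, method, cfg):
            seen.append(len(aligned))
            return orig(aligned, method, cfg)

        monkeypatch.setattr(ev, "_build_atlas", spy)
        leave_one_out(sample, "NCF", "rigid", FAST_LOO)
        # p1 has two explorations: both p1 folds train on 2 shapes only
        assert seen == [2, 2, 3, 3]

    def test_too_few_patients(self, unit_grid):
        v = ball_volume(unit_grid, 4.0)
        with pytest.raises(DomainError):
            leave_one_out([("p1", v), ("p2", v)], "NCF", "rigid", FAST_LOO)


@pytest.mark.parametrize("atlas_method", ATLAS_METHODS)
@pytest.mark.parametrize("reg_model", list(REGISTRATION_MODELS))
def test_degenerate_harness_all_combinations(atlas_method, reg_model):
    """Every method combination approaches its ideal score on a population
    of identical shapes (exact for NCF; the GLM is eps-clamped and the STA
    reconstruction is approximate by design)."""
    grid = VolumeGrid((24, 24, 24), (1.5, 1.5, 1.5))
    v = ball_volume(grid, 9.0)
    sample = [("p1", v), ("p2", v), ("p3", v)]
    records = leave_one_out(sample, atlas_method, reg_model, FAST_LOO)
    assert len(records) == 3
    for r in records:
        if atlas_method == "NCF":
            assert r.dice == 1.0
            assert r.hausdorff == 0.0
            assert r.iprob >= 0.98
        elif atlas_method == "GLM":
            assert r.dice >= 0.97
            assert r.hausdorff <= 2 * max(grid.spacing)
            assert r.iprob >= 0.95
        else:  # STA: binary reconstruction, no iprob/threshold
            assert r.dice >= 0.9
            assert r.iprob is None
            assert r.threshold_used is None
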