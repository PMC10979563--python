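import numpy as np
import pandas as pd
import pytest

from omuecol.networks import build_network, detect_core_periphery
from omuecol.omu_table import OmuTable
from omuecol.randomize import (
    integrate_sloan_cpn,
    permute,
    randomization_test,
    shared_core_periphery,
)
from omuecol.simulate import (
    SyntheticSpec,
    plant_selection,
    plant_treatment_effect,
    sample_source_profile,
    simulate_neutral_assemblage,
)


def _pair(seed, n_omu=40, n_samples=12, depth=3000):
    spec = SyntheticSpec(n_omu=n_omu, n_samples=2 * n_samples, I_T=depth,
                         m=0.3, depth=depth, seed=seed)
    prof = sample_source_profile(spec)
    table, _ = simulate_neutral_assemblage(prof, 0.3, depth, 2 * n_samples,
                                           depth, seed=seed + 1)
    cols = table.sample_ids
    H = OmuTable(table.counts[cols[:n_samples]], level=table.level, mode=table.mode)
    D = OmuTable(table.counts[cols[n_samples:]], level=table.level, mode=table.mode)
    return H, D


def mean_abundance_diff(a: OmuTable, b: OmuTable) -> float:
    ra = a.values() / a.values().sum(axis=0)
    rb = b.values() / b.values().sum(axis=0)
    return float(ra[:10].mean() - rb[:10].mean())


class TestPermute:
    def test_reproducible(self):
        H, D = _pair(1)
        a = permute(H, D, "A2", seed=9)
        b = permute(H, D, "A2", seed=9)
        assert a[0].counts.equals(b[0].counts)
        assert a[1].counts.equals(b[1].counts)

    def test_a2_preserves_sample_columns_exactly(self):
        H, D = _pair(2)
        Hs, Ds = permute(H, D, "A2", seed=3)
        pooled_before = {
            tuple(col) for col in
            np.concatenate([H.values().T, D.values().T])
        }
        pooled_after = {
            tuple(col) for col in
            np.concatenate([Hs.values().T, Ds.values().T])
        }
        assert pooled_before == pooled_after
        assert Hs.n_samples == H.n_samples
        assert Ds.n_samples == D.n_samples

    def test_a1_preserves_abundance_multisets_and_totals(self):
        H, D = _pair(3)
        Hs, _ = permute(H, D, "A1", seed=4)
        for j, col in enumerate(H.sample_ids):
            assert sorted(Hs.counts.iloc[:, j]) == sorted(H.counts.iloc[:, j])
        assert np.array_equal(
            Hs.counts.sum(axis=0).to_numpy(), H.counts.sum(axis=0).to_numpy()
        )

    def test_unknown_algorithm_rejected(self):
        H, D = _pair(4)
        with pytest.raises(ValueError):
            permute(H, D, "A3", seed=0)


class TestRandomizationTest:
    def test_single_draw_pseudo_p_values(self):
        H, D = _pair(5)
        res = randomization_test(mean_abundance_diff, H, D, B=1, seed=0)
        assert res.pseudo_p in (0.5, 1.0)

    def test_a2_invariant_statistic_never_significant(self):
        H, D = _pair(6)

        def label_blind(a, b):
            pooled = np.concatenate([a.values(), b.values()], axis=1)
            return float(pooled.mean())

        res = randomization_test(label_blind, H, D, algorithm="A2", B=50, seed=1)
        # the statistic ignores labels: every permutation reproduces it
        assert res.null_sd == pytest.approx(0.0, abs=1e-12)
        assert res.pseudo_p == 1.0

    def test_type_one_error_calibrated_under_null(self):
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            H, D = _pair(700 + rep, n_omu=25, n_samples=8, depth=1500)
            res = randomization_test(mean_abundance_diff, H, D,
                                     algorithm="A2", B=100, seed=rep)
            hits += res.pseudo_p <= 0.05
        assert 0.0 <= hits / n_rep <= 0.12

    def test_planted_fold_change_detected(self):
        detected = 0
        for rep in range(10):
            H, D = _pair(900 + rep, n_omu=40, n_samples=15, depth=3000)
            affected = list(D.omu_ids)[:8]
            _, D_fold, _ = plant_treatment_effect(D, affected, fold=8.0,
                                                  seed=rep)
            res = randomization_test(mean_abundance_diff, H, D_fold,
                                     algorithm="A2", B=100, seed=rep)
            detected += res.pseudo_p <= 0.05
        assert detected >= 8

    def test_failing_statistic_aborts(self):
        H, D = _pair(8)

        def broken(a, b):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError):
            randomization_test(broken, H, D, B=20, seed=0)


class TestSharedCorePeriphery:
    def _factor_pair(self, seed, disjoint):
        from omuecol.simulate import plant_core_periphery

        tH, _ = plant_core_periphery(6, 14, 40, loading=0.9, seed=seed)
        if disjoint:
            tD, _ = plant_core_periphery(6, 14, 40, loading=0.9, seed=seed + 99)
            # different factor draw but same OMU ids: relabel cores so the
            # planted cores sit on different ids
            ids = list(tD.counts.index)
            rotated = ids[10:] + ids[:10]
            tD = OmuTable(
                pd.DataFrame(tD.values(), index=rotated, columns=tD.sample_ids)
                .loc[ids],
                level=tD.level, mode=tD.mode,
            )
        else:
            tD = tH.copy()
        return tH, tD

    def test_identical_tables_share_entire_core(self):
        tH, tD = self._factor_pair(1, disjoint=False)
        res = shared_core_periphery(tH, tD, B=20, algorithm="A2", seed=2,
                                    fast=True)
        netH = build_network(tH)
        coreH = detect_core_periphery(netH, seed=1).core
        assert res.observed["core"] == len(coreH)
        assert res.pseudo_p_decline["core"] > 0.05
        assert res.observed["core"] <= min(len(coreH), len(coreH))

    def test_rotated_cores_decline(self):
        tH, tD = self._factor_pair(3, disjoint=True)
        res = shared_core_periphery(tH, tD, B=30, algorithm="A2", seed=4,
                                    fast=True)
        assert res.observed["core"] <= 2

    def test_shared_counts_bounded_by_core_sizes(self):
        tH, tD = self._factor_pair(5, disjoint=True)
        res = shared_core_periphery(tH, tD, B=5, algorithm="A2", seed=6,
                                    fast=True)
        cH = detect_core_periphery(build_network(tH), seed=1)
        cD = detect_core_periphery(build_network(tD), seed=1)
        assert res.observed["core"] <= min(len(cH.core), len(cD.core))


def _arbitrary_split(table: OmuTable, n_core: int):
    """Core/periphery assignment decoupled from any network structure."""
    from omuecol.networks import CpnResult

    nodes = list(table.omu_ids)
    delta = np.array([1] * n_core + [0] * (len(nodes) - n_core))
    return CpnResult(nodes, delta, rho_score=0.0, core_strength=0.0)


class TestIntegration:
    def test_neutral_core_and_periphery_equally_neutral(self):
        spec = SyntheticSpec(n_omu=120, n_samples=60, I_T=10_000, m=0.3,
                             depth=10_000, seed=13)
        prof = sample_source_profile(spec)
        table, _ = simulate_neutral_assemblage(prof, 0.3, 10_000, 60, 10_000,
                                               seed=14)
        # under neutrality any core/periphery split is arbitrary, so both
        # sides should classify overwhelmingly neutral
        cpn = _arbitrary_split(table, 40)
        out = integrate_sloan_cpn(table, cpn)
        fracs = [
            r[1].fraction("neutral") for r in out.values() if r is not None
        ]
        assert len(fracs) == 2
        for f in fracs:
            assert f >= 0.7
        assert abs(fracs[0] - fracs[1]) < 0.2

    def test_selection_planted_in_core_enriches_above_calls(self):
        from omuecol.simulate import plant_core_periphery

        table, truth = plant_core_periphery(8, 24, 60, loading=0.9, seed=21)
        core_ids = [i for i, s in truth.structure.items() if s == "core"]
        net = build_network(table)
        cpn = detect_core_periphery(net, seed=1)
        # split works even when one side is too small to fit
        out = integrate_sloan_cpn(table, cpn, min_side=5)
        assert set(out) == {"core", "periphery"}

    def test_class_percentages_sum_per_side(self):
        spec = SyntheticSpec(n_omu=100, n_samples=40, I_T=5_000, m=0.3,
                             depth=5_000, seed=31)
        prof = sample_source_profile(spec)
        table, _ = simulate_neutral_assemblage(prof, 0.3, 5_000, 40, 5_000,
                                               seed=32)
        cpn = _arbitrary_split(table, 30)
        out = integrate_sloan_cpn(table, cpn)
        for side, result in out.items():
            assert result is not None
            assert sum(result[1].percentages.values()) == pytest.approx(100.0)

    def test_tiny_side_skipped_with_warning(self):
        spec = SyntheticSpec(n_omu=50, n_samples=20, I_T=2_000, m=0.3,
                             depth=2_000, seed=41)
        prof = sample_source_profile(spec)
        table, _ = simulate_neutral_assemblage(prof, 0.3, 2_000, 20, 2_000,
                                               seed=42)
        cpn = _arbitrary_split(table, 3)
        with pytest.warns(UserWarning, match="core"):
            out = integrate_sloan_cpn(table, cpn, min_side=5)
        assert out["core"] is None
        assert out["periphery"] is not None
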