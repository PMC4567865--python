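"""Hierarchical two-way germination model: recovery, contrasts, letters."""

import numpy as np
import pandas as pd
import pytest

from isopop import (
    GerminationDataset,
    SimulationConfig,
    fit_germination,
    letter_groups,
    marginal_contrasts,
    simulate_germination,
)
from isopop.germination import Contrast


def dataset_from_counts(counts_by_cell, sown=10):
    rows = []
    for (treat, region), counts in counts_by_cell.items():
        for i, y in enumerate(counts):
            rows.append(
                {"dish_id": f"{treat}|{region}|{i}", "treatment": treat,
                 "region": region, "germinated": y, "sown": sown}
            )
    return GerminationDataset(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def null_fit():
    cfg = SimulationConfig(
        germination_modes=((0.5, 0.5),) * 4, germination_concentration=30.0, seed=21
    )
    data = simulate_germination(cfg)
    return fit_germination(data, seed=22, chains=2, draws=2500, warmup=600)


@pytest.fixture(scope="session")
def effect_fit():
    """One treatment generated 0.3 lower than the rest (kappa = 50)."""
    cfg = SimulationConfig(
        germination_modes=((0.6, 0.6), (0.3, 0.3), (0.6, 0.6), (0.6, 0.6)),
        germination_concentration=50.0,
        seed=31,
    )
    data = simulate_germination(cfg)
    return (
        fit_germination(data, seed=32, chains=2, draws=3000, warmup=800),
        data,
    )


class TestDatasetValidation:
    def test_count_bounds(self):
        with pytest.raises(ValueError, match="germinated"):
            dataset_from_counts({("a", "r1"): [11, 2], ("a", "r2"): [1, 2],
                                 ("b", "r1"): [1, 2], ("b", "r2"): [1, 2]})

    def test_missing_cell_rejected_at_fit(self):
        data = dataset_from_counts({
            ("a", "r1"): [1, 2], ("a", "r2"): [1, 2], ("b", "r1"): [1, 2],
        })
        with pytest.raises(ValueError, match="cell"):
            fit_germination(data, draws=10, warmup=10)

    def test_boundary_data_flagged(self):
        data = dataset_from_counts({
            (t, r): [0, 0, 0] for t in ("a", "b") for r in ("r1", "r2")
        })
        post = fit_germination(data, seed=1, chains=2, draws=300, warmup=200)
        assert any("boundary" in w for w in post.warnings)


class TestFit:
    def test_null_data_rarely_yields_credible_contrasts(self):
        """With all cells generated equal, credible contrasts stay near the
        nominal false-positive rate across replicate datasets."""
        credible = total = 0
        for rep in range(6):
            cfg = SimulationConfig(
                germination_modes=((0.5, 0.5),) * 4,
                germination_concentration=30.0,
                seed=700 + rep,
            )
            post = fit_germination(
                simulate_germination(cfg), seed=800 + rep,
                chains=2, draws=1500, warmup=500,
            )
            for factor in ("treatment", "region"):
                for c in marginal_contrasts(post, factor):
                    credible += c.credible
                    total += 1
        assert total == 42
        assert credible / total <= 0.15

    def test_designed_effect_detected(self, effect_fit):
        post, _ = effect_fit
        low = "22HD-light"  # second default treatment carries the 0.3 deficit
        for c in marginal_contrasts(post, "treatment"):
            if low in c.pair:
                assert c.credible
            else:
                assert not c.credible

    def test_cell_mode_recovery(self, effect_fit):
        post, _ = effect_fit
        truth = np.array(((0.6, 0.6), (0.3, 0.3), (0.6, 0.6), (0.6, 0.6)))
        est = post.cell_theta.mean(axis=(0, 1))
        assert np.abs(est - truth).mean() < 0.07

    def test_sum_to_zero_for_every_retained_draw(self, null_fit):
        assert np.allclose(null_fit.treatment_deflections.sum(axis=2), 0, atol=1e-10)
        assert np.allclose(null_fit.region_deflections.sum(axis=2), 0, atol=1e-10)
        assert np.allclose(
            null_fit.interaction_deflections.sum(axis=2), 0, atol=1e-10
        )
        assert np.allclose(
            null_fit.interaction_deflections.sum(axis=3), 0, atol=1e-10
        )
        assert (null_fit.concentration > 2).all()
        assert ((null_fit.cell_theta > 0) & (null_fit.cell_theta < 1)).all()

    def test_shrinkage_toward_pooled_mean(self):
        """A single deviant cell is shrunk from its empirical proportion
        toward the pooled one (hierarchical pooling of the interaction)."""
        cfg = SimulationConfig(
            germination_modes=((0.85, 0.5), (0.5, 0.5), (0.5, 0.5), (0.5, 0.5)),
            germination_concentration=100.0,
            seed=51,
        )
        data = simulate_germination(cfg)
        post = fit_germination(data, seed=52, chains=2, draws=2000, warmup=600)
        df = data.records
        pooled = df["germinated"].sum() / df["sown"].sum()
        cell = df[(df["treatment"] == "14HD-light") & (df["region"] == "R1")]
        cell_emp = cell["germinated"].sum() / cell["sown"].sum()
        est = post.cell_theta[:, :, 0, 0].mean()
        # posterior pulled from the cell proportion toward the pooled one
        assert abs(est - pooled) < abs(cell_emp - pooled)
        assert np.sign(est - pooled) == np.sign(cell_emp - pooled)

    def test_more_seeds_narrow_every_cell_hdi(self):
        from isopop.bayes import hdi

        widths = {}
        for sown in (10, 100):
            cfg = SimulationConfig(
                germination_modes=((0.55, 0.45), (0.5, 0.5), (0.45, 0.55), (0.5, 0.5)),
                germination_concentration=200.0,
                seeds_per_dish=sown,
                seed=41,
            )
            post = fit_germination(
                simulate_germination(cfg), seed=42, chains=2, draws=2000, warmup=600
            )
            w = np.empty((4, 2))
            for tj in range(4):
                for rj in range(2):
                    lo, hi = hdi(post.cell_theta[:, :, tj, rj].reshape(-1), 0.95)
                    w[tj, rj] = hi - lo
            widths[sown] = w
        assert (widths[100] < widths[10]).all()

    def test_region_contrast_equals_mean_cell_difference(self, null_fit):
        (contrast,) = marginal_contrasts(null_fit, "region")
        cells = null_fit.cell_theta
        expected = (cells[:, :, :, 0] - cells[:, :, :, 1]).mean(axis=2).reshape(-1)
        assert np.allclose(contrast.draws, expected, atol=1e-12)

    def test_unknown_factor(self, null_fit):
        with pytest.raises(ValueError, match="unknown factor"):
            marginal_contrasts(null_fit, "dish")


def fake_contrast(a, b, credible):
    draws = np.full(200, 0.2 if credible else 0.0)
    return Contrast((a, b), draws, 0.1 if credible else -0.1, 0.3 if credible else 0.1,
                    credible, float(draws.mean()))


class TestLetterGroups:
    def test_no_credible_differences(self):
        contrasts = [fake_contrast(a, b, False)
                     for a, b in [("A", "B"), ("A", "C"), ("B", "C")]]
        assert letter_groups(contrasts) == {"A": "a", "B": "a", "C": "a"}

    def test_one_level_distinct(self):
        contrasts = [
            fake_contrast("A", "B", True),
            fake_contrast("A", "C", True),
            fake_contrast("B", "C", False),
        ]
        letters = letter_groups(contrasts)
        assert letters["A"] == "a"
        assert letters["B"] == letters["C"] == "b"

    def test_chain_pattern(self):
        # A != C while A = B and B = C: the classic a / ab / b display
        contrasts = [
            fake_contrast("A", "B", False),
            fake_contrast("A", "C", True),
            fake_contrast("B", "C", False),
        ]
        assert letter_groups(contrasts) == {"A": "a", "B": "ab", "C": "b"}

    def test_requires_all_pairs(self):
        with pytest.raises(ValueError, match="all pairwise"):
            letter_groups(
                [fake_contrast("A", "B", False), fake_contrast("B", "C", False)]
            )
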