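"""Efficiency-corrected qPCR ratios and the fixed-reallocation randomization test."""

import math

import numpy as np
import pandas as pd
import pytest

import supersage.qpcr as qpcr
from supersage.qpcr import (
    ExpressionRatio,
    QpcrAssay,
    RelativeExpression,
    concordance_check,
    efficiency_from_slope,
    rest_randomization_test,
    rest_ratio,
    signed_mrgel,
)
from supersage.simulate import simulate_ct_tables


def _ct_table(gene_means: dict, n_bio: int = 3, n_tech: int = 3) -> pd.DataFrame:
    """Noise-free Ct table; gene_means maps gene -> (control Ct, treatment Ct)."""
    rows = []
    for gene, (mc, mt) in gene_means.items():
        for group, mu in (("control", mc), ("treatment", mt)):
            for b in range(1, n_bio + 1):
                for t in range(1, n_tech + 1):
                    rows.append(
                        {"gene": gene, "group": group, "bio_rep": b, "tech_rep": t, "ct": mu}
                    )
    return pd.DataFrame(rows)


E1 = {g: QpcrAssay(g, 1.0) for g in ("target", "ref1", "ref2")}


class TestEfficiency:
    def test_perfect_doubling_slope(self):
        # slope = -1/log10(2): one cycle per two-fold dilution
        assert efficiency_from_slope(-1 / math.log10(2)) == pytest.approx(1.0, abs=1e-4)

    def test_printed_formula_value(self):
        assert efficiency_from_slope(-3.6) == pytest.approx(0.8957, abs=5e-4)

    def test_positive_slope_rejected(self):
        with pytest.raises(ValueError):
            efficiency_from_slope(1.0)

    def test_atypical_efficiency_warns(self):
        with pytest.warns(UserWarning):
            efficiency_from_slope(-10.0)


class TestRestRatio:
    def test_identical_groups_ratio_one(self):
        ct = _ct_table({"target": (20, 20), "ref1": (18, 18)})
        assert rest_ratio(ct, "target", ["ref1"], E1) == pytest.approx(1.0)

    def test_target_drop_one_cycle_doubles(self):
        ct = _ct_table({"target": (20, 19), "ref1": (18, 18)})
        assert rest_ratio(ct, "target", ["ref1"], E1) == pytest.approx(2.0)

    def test_reference_drop_halves(self):
        ct = _ct_table({"target": (20, 20), "ref1": (18, 17), "ref2": (18, 17)})
        assert rest_ratio(ct, "target", ["ref1", "ref2"], E1) == pytest.approx(0.5)

    def test_shift_invariance(self):
        ct = _ct_table({"target": (20, 18.5), "ref1": (18, 17.8)})
        shifted = ct.assign(ct=ct["ct"] + 3.7)
        assert rest_ratio(ct, "target", ["ref1"], E1) == pytest.approx(
            rest_ratio(shifted, "target", ["ref1"], E1)
        )

    def test_classic_ddct_equivalence(self):
        # single reference, both efficiencies 1: ratio = 2^-(ddCt)
        ct = _ct_table({"target": (21.0, 19.2), "ref1": (17.0, 16.6)})
        ddct = (19.2 - 21.0) - (16.6 - 17.0)
        assert rest_ratio(ct, "target", ["ref1"], E1) == pytest.approx(2.0 ** (-ddct))

    def test_efficiency_correction(self):
        # E = 0.8 for target: a 1-cycle drop gives a 1.8-fold ratio
        assays = {"target": QpcrAssay("target", 0.8), "ref1": QpcrAssay("ref1", 1.0)}
        ct = _ct_table({"target": (20, 19), "ref1": (18, 18)})
        assert rest_ratio(ct, "target", ["ref1"], assays) == pytest.approx(1.8)

    def test_missing_group_rejected(self):
        ct = _ct_table({"target": (20, 19), "ref1": (18, 18)})
        with pytest.raises(ValueError):
            rest_ratio(ct[ct["group"] == "control"], "target", ["ref1"], E1)


class TestRandomization:
    def test_total_separation_three_vs_three(self):
        # only the observed allocation and its mirror are as extreme:
        # p = 2 / C(6,3) = 0.1
        rng = np.random.default_rng(0)
        ct = _ct_table({"target": (20, 16), "ref1": (18, 18)})
        ct["ct"] = ct["ct"] + rng.normal(0, 0.01, len(ct))
        p = rest_randomization_test(ct, "target", ["ref1"], E1, seed=0)
        assert p == pytest.approx(2 / 20)

    def test_label_swap_keeps_p(self):
        rng = np.random.default_rng(1)
        ct = _ct_table({"target": (20, 18.4), "ref1": (18, 18)})
        ct["ct"] = ct["ct"] + rng.normal(0, 0.2, len(ct))
        swapped = ct.assign(
            group=ct["group"].map({"control": "treatment", "treatment": "control"})
        )
        r = rest_ratio(ct, "target", ["ref1"], E1)
        r_swapped = rest_ratio(swapped, "target", ["ref1"], E1)
        assert r_swapped == pytest.approx(1 / r)
        p = rest_randomization_test(ct, "target", ["ref1"], E1, seed=2)
        p_swapped = rest_randomization_test(swapped, "target", ["ref1"], E1, seed=2)
        assert p == pytest.approx(p_swapped)  # exhaustive: exactly equal

    def test_null_calibration(self):
        # 4v4 replicates so achievable p-values go below 0.05 (min 2/70)
        rng = np.random.default_rng(42)
        n_sig = 0
        n_sim = 200
        for _ in range(n_sim):
            ct = _ct_table({"target": (20, 20), "ref1": (18, 18)}, n_bio=4, n_tech=1)
            ct["ct"] = ct["ct"] + rng.normal(0, 0.3, len(ct))
            p = rest_randomization_test(ct, "target", ["ref1"], E1, seed=0)
            n_sig += p < 0.05
        assert n_sig / n_sim <= 0.08

    def test_monte_carlo_agrees_with_exhaustive(self, monkeypatch):
        rng = np.random.default_rng(3)
        ct = _ct_table({"target": (20, 18.7), "ref1": (18, 18)}, n_bio=4, n_tech=1)
        ct["ct"] = ct["ct"] + rng.normal(0, 0.4, len(ct))
        p_exh = rest_randomization_test(ct, "target", ["ref1"], E1)
        monkeypatch.setattr(qpcr, "EXHAUSTIVE_LIMIT", 0)
        p_mc = rest_randomization_test(
            ct, "target", ["ref1"], E1, permutations=2000, seed=5
        )
        se = math.sqrt(p_exh * (1 - p_exh) / 2000)
        assert abs(p_mc - p_exh) < 4 * se + 1e-3

    def test_too_few_replicates_rejected(self):
        ct = _ct_table({"target": (20, 19), "ref1": (18, 18)}, n_bio=1)
        with pytest.raises(ValueError):
            rest_randomization_test(ct, "target", ["ref1"], E1)


class TestModelObject:
    def test_fit_returns_ratio_and_call(self):
        rng = np.random.default_rng(4)
        ct = _ct_table({"target": (21, 18), "ref1": (18, 18)})
        ct["ct"] = ct["ct"] + rng.normal(0, 0.05, len(ct))
        res = RelativeExpression(ct, "target", ["ref1"], E1, group_label="T1").fit(seed=0)
        assert res.ratio == pytest.approx(8.0, rel=0.1)
        assert res.call in ("up", "n.s.")  # p floor is 0.1 with 3v3 replicates
        assert 0 <= res.p_value <= 1


class TestRecoveryFromSimulatedCt:
    def test_median_recovered_ratio(self):
        recovered = []
        for seed in range(60):
            ct, _ = simulate_ct_tables({"target": 2.5}, noise_sd=0.1, seed=seed)
            assays = {g: QpcrAssay(g, 1.0) for g in ("target", "actin", "rna18S")}
            recovered.append(rest_ratio(ct, "target", ["actin", "rna18S"], assays))
        assert 2.2 <= float(np.median(recovered)) <= 2.8

    def test_reference_only_shift_compensated(self):
        ct = _ct_table({"target": (20, 20), "ref1": (18, 17), "ref2": (18, 18)})
        r = rest_ratio(ct, "target", ["ref1", "ref2"], E1)
        assert r == pytest.approx(1 / math.sqrt(2))


class TestConcordance:
    def _ratio(self, ratio, p):
        return ExpressionRatio("g", "T1", ratio, p)

    def test_agreement_one_timepoint(self):
        assert concordance_check("UR", [self._ratio(1.1, 0.4), self._ratio(2.0, 0.01)])

    def test_all_ns_disagrees(self):
        assert not concordance_check("UR", [self._ratio(2.0, 0.2)])

    def test_wrong_direction_disagrees(self):
        assert not concordance_check("DR", [self._ratio(2.0, 0.01)])

    def test_signed_report_convention(self):
        assert signed_mrgel(2.0) == 2.0
        assert signed_mrgel(0.5) == pytest.approx(-2.0)
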