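"""CSC, tAI, CAI, demand, SDR and the cross-condition comparisons."""

import numpy as np
import pandas as pd
import pytest

from trnadapt._codes import SENSE_CODONS, SYNONYMOUS_FAMILIES, wc_anticodon
from trnadapt.codons import codon_count_matrix, normalized_frequencies
from trnadapt.optimality import (
    classify_codons,
    codon_demand,
    codon_tai,
    cohens_d,
    compute_cai,
    compute_csc,
    compute_sdr,
    differential_tai_csc,
    gene_tai,
    geneset_halflife_summary,
    tai_csc_effect,
    wc_abundance_map,
)


def full_pool(value=100.0):
    """Every sense codon's WC anticodon at a constant abundance."""
    return {wc_anticodon(c): value for c in SENSE_CODONS}


class TestCSC:
    def freq_frame(self, col, values, n=None):
        n = n or len(values)
        base = pd.DataFrame(
            0.0, index=[f"g{i}" for i in range(n)], columns=list(SENSE_CODONS)
        )
        base[col] = values
        return base

    def test_perfect_linear_relation_gives_one(self):
        freqs = self.freq_frame("AAA", [0.1, 0.2, 0.3, 0.4, 0.5])
        hl = pd.Series([1.0, 2, 3, 4, 5], index=freqs.index)
        assert compute_csc(freqs, hl)["AAA"] == pytest.approx(1.0)

    def test_constant_frequency_column_is_missing(self):
        freqs = self.freq_frame("AAA", [0.1, 0.2, 0.3])
        freqs["CCC"] = 0.5
        hl = pd.Series([1.0, 2, 3], index=freqs.index)
        csc = compute_csc(freqs, hl)
        assert np.isnan(csc["CCC"]) and not np.isnan(csc["AAA"])

    def test_constant_half_life_errors(self):
        freqs = self.freq_frame("AAA", [0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="constant"):
            compute_csc(freqs, pd.Series([2.0, 2, 2], index=freqs.index))

    def test_matches_direct_pearson_formula(self, rng):
        freqs = pd.DataFrame(
            rng.dirichlet(np.ones(61), size=15), columns=list(SENSE_CODONS),
            index=[f"g{i}" for i in range(15)],
        )
        hl = pd.Series(rng.uniform(1, 10, 15), index=freqs.index)
        csc = compute_csc(freqs, hl)
        for codon in rng.choice(SENSE_CODONS, 8, replace=False):
            x, y = freqs[codon], hl
            want = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
                ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
            )
            assert csc[codon] == pytest.approx(want, abs=1e-12)

    def test_invariances(self, rng):
        freqs = pd.DataFrame(
            rng.dirichlet(np.ones(61), size=12), columns=list(SENSE_CODONS),
            index=[f"g{i}" for i in range(12)],
        )
        hl = pd.Series(rng.uniform(1, 10, 12), index=freqs.index)
        base = compute_csc(freqs, hl)
        perm = freqs.sample(frac=1, random_state=1)
        pd.testing.assert_series_equal(base, compute_csc(perm, hl))
        pd.testing.assert_series_equal(
            base, compute_csc(freqs, hl + 7.0), atol=1e-12
        )
        assert base.abs().max() <= 1.0 + 1e-12


class TestClassifyCodons:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.01, "optimal"),
            (0.009, "neutral"),
            (-0.009, "neutral"),
            (-0.01, "non_optimal"),
            (0.5, "optimal"),
            (-0.5, "non_optimal"),
            (0.0, "neutral"),
        ],
    )
    def test_boundaries(self, value, expected):
        assert classify_codons(pd.Series({"AAA": value}))["AAA"] == expected

    def test_nan_propagates(self):
        out = classify_codons(pd.Series({"AAA": np.nan}))
        assert pd.isna(out["AAA"])


class TestCodonTai:
    def test_single_codon_family_is_one(self):
        w, tai = codon_tai(full_pool())
        assert tai["ATG"] == 1.0 and tai["TGG"] == 1.0

    def test_phe_toy_wobble_weights(self):
        w, tai = codon_tai({"GAA": 100.0}, codons=["TTT"])
        assert w["TTC"] == pytest.approx(100.0)
        assert w["TTT"] == pytest.approx(59.0)  # (1 - 0.41) x 100
        assert tai["TTC"] == 1.0
        assert tai["TTT"] == pytest.approx(0.59)

    def test_scale_invariance(self):
        pool = {wc_anticodon(c): v for c, v in
                zip(SENSE_CODONS, np.linspace(10, 700, 61))}
        _, tai1 = codon_tai(pool)
        _, tai10 = codon_tai({k: 10 * v for k, v in pool.items()})
        pd.testing.assert_series_equal(tai1, tai10)

    def test_one_codon_per_family_attains_one(self):
        pool = {wc_anticodon(c): v for c, v in
                zip(SENSE_CODONS, np.linspace(10, 700, 61))}
        _, tai = codon_tai(pool)
        for family in SYNONYMOUS_FAMILIES.values():
            assert tai[list(family)].max() == pytest.approx(1.0)

    def test_empty_family_errors(self):
        pool = full_pool()
        # remove all anticodons that can read any Phe codon
        for ac in ("GAA", "AAA"):
            pool.pop(ac, None)
        with pytest.raises(ValueError, match="Phe"):
            codon_tai(pool)

    def test_met_restricted_to_watson_crick(self):
        # a TAT (Ile) anticodon must not contribute to ATG by U:G wobble
        w_with, _ = codon_tai({"CAT": 50.0, "TAT": 1000.0}, codons=["ATG"])
        assert w_with["ATG"] == pytest.approx(50.0)


class TestGeneTai:
    def test_all_ones(self):
        counts = pd.Series({"AAA": 5, "TTT": 3}).reindex(SENSE_CODONS, fill_value=0)
        tai = pd.Series(1.0, index=list(SENSE_CODONS))
        assert gene_tai(counts, tai) == pytest.approx(1.0)

    def test_two_position_geometric_mean(self):
        counts = pd.Series(0, index=list(SENSE_CODONS))
        counts["AAA"], counts["CCC"] = 1, 1
        tai = pd.Series(1.0, index=list(SENSE_CODONS))
        tai["CCC"] = 0.25
        assert gene_tai(counts, tai) == pytest.approx(0.5)

    def test_matches_product_then_root_oracle(self, rng):
        codons = rng.choice(SENSE_CODONS, 50)
        counts = pd.Series(0, index=list(SENSE_CODONS))
        for c in codons:
            counts[c] += 1
        tai = pd.Series(rng.uniform(0.05, 1.0, 61), index=list(SENSE_CODONS))
        oracle = np.prod([tai[c] for c in codons]) ** (1 / 50)
        assert gene_tai(counts, tai) == pytest.approx(oracle, abs=1e-12)

    def test_zero_tai_strict_errors_lenient_floors(self):
        counts = pd.Series(0, index=list(SENSE_CODONS))
        counts["AAA"], counts["CCC"] = 1, 1
        tai = pd.Series(1.0, index=list(SENSE_CODONS))
        tai["CCC"] = 0.0
        with pytest.raises(ValueError):
            gene_tai(counts, tai)
        lenient = gene_tai(counts, tai, zero_policy="floor")
        assert 0 < lenient <= 1.0

    def test_geometric_never_exceeds_arithmetic(self, rng):
        counts = pd.Series(rng.integers(0, 5, 61), index=list(SENSE_CODONS))
        counts["AAA"] += 1
        tai = pd.Series(rng.uniform(0.1, 1.0, 61), index=list(SENSE_CODONS))
        geo = gene_tai(counts, tai)
        arith = float((tai * counts).sum() / counts.sum())
        assert geo <= arith + 1e-12


class TestCAI:
    def reference(self):
        ref = pd.Series(0.0, index=list(SENSE_CODONS))
        ref["TTT"], ref["TTC"] = 75, 25
        # give every other family one used codon so w is defined
        for family in SYNONYMOUS_FAMILIES.values():
            if ref[list(family)].sum() == 0:
                ref[family[0]] = 10
        return ref

    def test_rscu_toy_value(self):
        counts = pd.Series(0, index=list(SENSE_CODONS))
        counts["TTC"] = 1
        assert compute_cai(counts.rename("g"), self.reference()) == pytest.approx(1 / 3)

    def test_best_codon_usage_gives_one(self):
        counts = pd.Series(0, index=list(SENSE_CODONS))
        counts["TTT"] = 4  # family-maximal reference codon
        counts["ATG"] = 2  # excluded single-codon family
        assert compute_cai(counts.rename("g"), self.reference()) == pytest.approx(1.0)

    def test_duplication_invariance(self, rng):
        body = "".join(rng.choice(SENSE_CODONS, 40))
        counts = codon_count_matrix({"g": body, "gg": body + body})
        ref = self.reference()
        cai = compute_cai(counts, ref)
        assert cai["g"] == pytest.approx(cai["gg"], abs=1e-12)

    def test_cai_is_one_iff_only_family_maximal_codons(self, rng):
        ref = self.reference()
        best = {
            fam: max(fam_codons, key=lambda c: ref[c])
            for fam, fam_codons in SYNONYMOUS_FAMILIES.items()
            if len(fam_codons) > 1
        }
        counts = pd.Series(0, index=list(SENSE_CODONS))
        for c in best.values():
            counts[c] = 2
        assert compute_cai(counts.rename("g"), ref) == pytest.approx(1.0)
        counts["TTC"] = 1  # one sub-maximal codon
        assert compute_cai(counts.rename("g"), ref) < 1.0


class TestDemandAndSDR:
    def freqs(self, rng, n=10):
        return pd.DataFrame(
            rng.dirichlet(np.ones(61), size=n),
            columns=list(SENSE_CODONS),
            index=[f"g{i}" for i in range(n)],
        )

    def test_single_gene_demand_is_its_frequency_row(self, rng):
        freqs = self.freqs(rng, 1)
        demand = codon_demand(freqs, pd.Series({"g0": 1.0}))
        assert np.allclose(demand, freqs.loc["g0"], atol=1e-12)

    def test_equal_expression_demand_is_mean(self, rng):
        freqs = self.freqs(rng, 2)
        demand = codon_demand(freqs, pd.Series({"g0": 3.0, "g1": 3.0}))
        assert np.allclose(demand, freqs.mean(axis=0), atol=1e-12)

    def test_matches_weighted_average_oracle(self, rng):
        freqs = self.freqs(rng, 10)
        expr = pd.Series(rng.uniform(1, 50, 10), index=freqs.index)
        demand = codon_demand(freqs, expr)
        oracle = np.zeros(61)
        for g in freqs.index:
            oracle += expr[g] * freqs.loc[g].to_numpy()
        oracle /= oracle.sum()
        assert np.allclose(demand, oracle, atol=1e-12)

    def test_all_zero_expression_errors(self, rng):
        freqs = self.freqs(rng, 3)
        with pytest.raises(ValueError, match="zero"):
            codon_demand(freqs, pd.Series(0.0, index=freqs.index))

    def test_uniform_case_gives_constant_sdr_and_zero_delta(self, rng):
        tai = pd.Series(1.0, index=list(SENSE_CODONS))
        demand = pd.Series(1 / 61, index=list(SENSE_CODONS))
        counts = codon_count_matrix(
            {f"g{i}": "".join(rng.choice(SENSE_CODONS, 30)) for i in range(4)}
        )
        sdr_c, sdr = compute_sdr(tai, demand, counts)
        assert np.allclose(sdr_c, 61.0)
        assert np.allclose(sdr, sdr.iloc[0])
        # identical conditions -> delta SDR exactly 0
        _, sdr2 = compute_sdr(tai, demand, counts)
        assert np.allclose(sdr - sdr2, 0.0)

    def test_zero_demand_for_occurring_codon_errors(self):
        tai = pd.Series(1.0, index=list(SENSE_CODONS))
        demand = pd.Series(1 / 61, index=list(SENSE_CODONS))
        demand["AAA"] = 0.0
        counts = codon_count_matrix({"g": "AAACCC"})
        with pytest.raises(ValueError, match="AAA"):
            compute_sdr(tai, demand, counts)

    def test_sdr_scale_invariance_via_normalized_demand(self, rng):
        freqs = self.freqs(rng, 6)
        expr = pd.Series(rng.uniform(1, 9, 6), index=freqs.index)
        pool = {wc_anticodon(c): v for c, v in
                zip(SENSE_CODONS, np.linspace(10, 700, 61))}
        _, tai = codon_tai(pool)
        _, tai_scaled = codon_tai({k: 3.7 * v for k, v in pool.items()})
        demand = codon_demand(freqs, expr)
        demand_scaled = codon_demand(freqs, expr * 1000.0)
        counts = (freqs * 300).round().astype(int)
        _, sdr_a = compute_sdr(tai, demand, counts, zero_policy="floor")
        _, sdr_b = compute_sdr(
            tai_scaled, demand_scaled, counts, zero_policy="floor"
        )
        assert np.allclose(sdr_a, sdr_b, rtol=1e-9)


class TestWCAbundanceMap:
    def test_reverse_complement_lookup(self):
        out = wc_abundance_map({"GAA": 123.0})
        assert out["TTC"] == 123.0

    def test_absent_trna_gives_zero(self):
        out = wc_abundance_map({})
        assert (out == 0).all()

    def test_full_map_matches_hand_table(self):
        pool = {wc_anticodon(c): float(i) for i, c in enumerate(SENSE_CODONS)}
        out = wc_abundance_map(pool)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for i, codon in enumerate(SENSE_CODONS):
            hand = "".join(comp[b] for b in reversed(codon))
            assert out[codon] == pool[hand] == float(i)


class TestEffectSizes:
    def test_identical_groups_give_zero_effect(self):
        tai = pd.Series(
            [0.5, 0.5, 0.6, 0.5, 0.5, 0.6], index=list("abcdef")
        )
        csc = pd.Series([0.1, 0.2, 0.3, -0.1, -0.2, -0.3], index=list("abcdef"))
        out = tai_csc_effect(tai, csc)
        assert out["cohens_d"] == pytest.approx(0.0)
        assert out["p_value"] == pytest.approx(1.0)

    def test_degenerate_zero_sd_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            cohens_d(np.array([1.0, 1, 1]), np.array([0.0, 0, 0]))

    def test_planted_shift_matches_formula_oracle(self, rng):
        g1 = rng.normal(1.0, 1.0, 6)
        g2 = rng.normal(0.0, 1.0, 6)
        tai = pd.Series(np.concatenate([g1, g2]))
        csc = pd.Series([0.2] * 6 + [-0.2] * 6)
        got = tai_csc_effect(tai, csc)["cohens_d"]
        sp = np.sqrt((5 * g1.var(ddof=1) + 5 * g2.var(ddof=1)) / 10)
        assert got == pytest.approx((g1.mean() - g2.mean()) / sp, abs=1e-12)

    def test_class_grouping_excludes_neutral(self):
        tai = pd.Series([1.0, 0.9, 0.2, 0.1, 0.5, 0.6])
        csc = pd.Series([0.05, 0.02, -0.05, -0.02, 0.005, -0.005])
        out = tai_csc_effect(tai, csc, grouping="class")
        assert out["n_stabilizing"] == 2 and out["n_destabilizing"] == 2


class TestDifferentialTaiCsc:
    def build(self, tai_a, tai_b, cls_a, cls_b):
        idx = ["X"]
        return differential_tai_csc(
            pd.Series(tai_a, idx), pd.Series(tai_b, idx),
            pd.Series(cls_a, idx), pd.Series(cls_b, idx),
        )

    def test_concordant_shift(self):
        out = self.build([0.5], [0.75], ["neutral"], ["optimal"])
        assert out.loc["X", "category"] == "concordant"

    def test_below_threshold_is_csc_only(self):
        out = self.build([0.5], [0.6], ["optimal"], ["neutral"])
        assert out.loc["X", "category"] == "csc_only"

    def test_identical_conditions_no_difference(self):
        out = self.build([0.5], [0.5], ["optimal"], ["optimal"])
        assert out.loc["X", "category"] == "no_difference"

    def test_tai_only(self):
        out = self.build([0.2], [0.9], ["neutral"], ["neutral"])
        assert out.loc["X", "category"] == "tai_only"

    def test_opposite_directions_flagged_discordant(self):
        out = self.build([0.9], [0.2], ["neutral"], ["optimal"])
        assert out.loc["X", "category"] == "discordant"


class TestGenesetHalflifeSummary:
    def test_two_gene_hand_arithmetic(self):
        hl = {"nb": pd.Series({"a": 2.0, "b": 4.0})}
        out = geneset_halflife_summary(["a", "b"], hl)
        assert out.loc["nb", "mean"] == 3.0
        assert out.loc["nb", "sem"] == pytest.approx(1.0)
        assert out.loc["nb", "n"] == 2

    def test_single_gene_sem_missing(self):
        out = geneset_halflife_summary(["a"], {"nb": pd.Series({"a": 5.0})})
        assert out.loc["nb", "mean"] == 5.0
        assert np.isnan(out.loc["nb", "sem"])

    def test_matches_formula_oracle(self, rng):
        vals = rng.uniform(1, 12, 30)
        hl = {"c": pd.Series(vals, index=[f"g{i}" for i in range(30)])}
        out = geneset_halflife_summary([f"g{i}" for i in range(30)], hl)
        assert out.loc["c", "mean"] == pytest.approx(vals.mean())
        assert out.loc["c", "sem"] == pytest.approx(
            vals.std(ddof=1) / np.sqrt(30)
        )

    def test_empty_intersection_errors(self):
        with pytest.raises(ValueError, match="coverage"):
            geneset_halflife_summary(["zz"], {"nb": pd.Series({"a": 1.0})})
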