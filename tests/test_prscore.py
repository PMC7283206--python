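"""C+T core: allele harmonization decision table, LD, greedy clumping vs an
independent oracle, the PRS equation vs a double-loop oracle, and the
threshold-scan contract."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from prsoverlap import assoc, prscore, synthdata
from prsoverlap.prscore import PruneConfig
from prsoverlap.synthdata import SimulationConfig
from conftest import make_genotypes


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive)
# ---------------------------------------------------------------------------

def prs_oracle(dosage, betas, m_rows):
    """Literal per-sample, per-SNP evaluation of PRS_j = sum S_i G_ij / M_j."""
    n = dosage.shape[0]
    scores = np.full(n, np.nan)
    m_out = np.zeros(n, dtype=int)
    for j in range(n):
        num = 0.0
        m = 0
        for i in m_rows:
            gij = dosage[j, i]
            if np.isnan(gij):
                continue
            num += betas[i] * gij
            m += 2
        m_out[j] = m
        if m > 0:
            scores[j] = num / m
    return scores, m_out


def clump_oracle(harm, g, r2_threshold=0.1, window_bp=250_000):
    """Independent greedy clump: explicit sort, pairwise r2 via ld_r2."""
    rows = sorted(
        range(len(harm)),
        key=lambda i: (harm["p"].iat[i], harm["pos"].iat[i], harm["snp_id"].iat[i]),
    )
    removed = set()
    retained = []
    for k in rows:
        if k in removed:
            continue
        retained.append(k)
        for j in rows:
            if j == k or j in removed or j in retained:
                continue
            if harm["chrom"].iat[j] != harm["chrom"].iat[k]:
                continue
            if abs(harm["pos"].iat[j] - harm["pos"].iat[k]) > window_bp:
                continue
            try:
                r2 = prscore.ld_r2(g, int(harm["col"].iat[k]), int(harm["col"].iat[j]))
            except ValueError:
                continue
            if r2 > r2_threshold:
                removed.add(j)
    return retained


def _harm_frame(g, betas=None, pvals=None):
    m = g.n_snps
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        {
            "col": np.arange(m),
            "snp_id": g.snps["id"],
            "chrom": g.snps["chrom"],
            "pos": g.snps["pos"],
            "beta": betas if betas is not None else rng.normal(size=m),
            "p": pvals if pvals is not None else rng.random(m),
        }
    )


def _random_instance(rng, n_snps=None, with_missing=True, n_samples=20):
    m = n_snps or int(rng.integers(5, 26))
    base = rng.choice([0.0, 1.0, 2.0], size=(n_samples, m), p=[0.45, 0.35, 0.2])
    if rng.random() < 0.5:  # duplicated columns create r2 = 1 pairs
        i, j = rng.integers(m, size=2)
        base[:, i] = base[:, j]
    if with_missing:
        mask = rng.random(base.shape) < 0.1
        base[mask] = np.nan
    positions = np.sort(rng.choice(np.arange(1, 900_000, 1000), size=m, replace=False))
    g = make_genotypes(base, positions=positions)
    harm = _harm_frame(g, betas=rng.normal(size=m), pvals=rng.random(m))
    return g, harm


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

class TestHarmonize:
    def _inputs(self, ea, oa, beta=0.3):
        ss = pd.DataFrame(
            {"snp_id": ["snp1"], "chrom": ["1"], "pos": [1], "effect_allele": [ea],
             "other_allele": [oa], "beta": [beta], "p": [0.01]}
        )
        g = make_genotypes(np.array([[0.0], [1.0], [2.0]]))  # a1=A, a2=G
        return ss, g

    @pytest.mark.parametrize(
        "ea,oa,expected_sign",
        [
            ("A", "G", +1),   # direct match, effect allele is the counted allele
            ("G", "A", -1),   # allele swap
            ("T", "C", +1),   # reverse complement of (A, G)
            ("C", "T", -1),   # reverse complement + swap
        ],
    )
    def test_allele_decision_table(self, ea, oa, expected_sign):
        ss, g = self._inputs(ea, oa)
        harm = prscore.harmonize(ss, g, strict_palindromic=True)
        assert harm["beta"].iat[0] == pytest.approx(expected_sign * 0.3)

    def test_palindromic_dropped_in_strict_mode(self):
        ss = pd.DataFrame(
            {"snp_id": ["snp1", "snp2"], "chrom": ["1", "1"], "pos": [1, 2],
             "effect_allele": ["A", "A"], "other_allele": ["T", "G"],
             "beta": [0.3, 0.2], "p": [0.01, 0.02]}
        )
        g = make_genotypes(np.array([[0.0, 1.0], [1.0, 2.0]]))
        harm = prscore.harmonize(ss, g, strict_palindromic=True)
        assert harm["snp_id"].tolist() == ["snp2"]
        assert harm.attrs["drops"]["palindromic"] == 1

    def test_mismatched_alleles_dropped(self):
        ss, g = self._inputs("C", "G")  # neither direct nor strand-flip match
        with pytest.raises(ValueError, match="zero SNPs matched"):
            prscore.harmonize(ss, g)

    def test_unmatched_ids_counted(self):
        ss, g = self._inputs("A", "G")
        ss["snp_id"] = ["absent"]
        with pytest.raises(ValueError, match="zero SNPs matched"):
            prscore.harmonize(ss, g)


class TestLdR2:
    def test_self_and_duplicate_are_one(self, rng):
        d = rng.choice([0.0, 1, 2], size=(50, 2))
        d[:, 1] = d[:, 0]
        g = make_genotypes(d)
        assert prscore.ld_r2(g, 0, 0) == pytest.approx(1.0)
        assert prscore.ld_r2(g, 0, 1) == pytest.approx(1.0)

    def test_independent_snps_low_r2(self):
        g = synthdata.simulate_genotypes(
            SimulationConfig(n_snps=2, block_size=1, rho=0.0, seed=2), 5000)
        assert prscore.ld_r2(g, 0, 1) < 0.01

    def test_monomorphic_rejected(self):
        g = make_genotypes(np.column_stack([np.ones(20), np.tile([0.0, 1], 10)]))
        with pytest.raises(ValueError, match="variance"):
            prscore.ld_r2(g, 0, 1)


class TestClump:
    def test_perfect_ld_retains_smallest_p(self):
        col = np.tile([0.0, 1, 2, 1, 0], 10)
        g = make_genotypes(np.column_stack([col, col, col]),
                           positions=[1000, 2000, 3000])
        harm = _harm_frame(g, pvals=np.array([1e-8, 1e-4, 1e-2]))
        kept = prscore.clump(harm, g)
        assert harm["snp_id"].iloc[kept].tolist() == ["snp1"]

    def test_window_rule_keeps_distant_snps(self):
        col = np.tile([0.0, 1, 2, 1, 0], 10)
        g = make_genotypes(np.column_stack([col, col]), positions=[1, 300_001])
        harm = _harm_frame(g, pvals=np.array([1e-8, 1e-2]))
        kept = prscore.clump(harm, g)
        assert len(kept) == 2  # r2 = 1 but beyond the 250 kb window

    def test_unlinked_snps_all_retained(self):
        g = synthdata.simulate_genotypes(
            SimulationConfig(n_snps=8, block_size=1, rho=0.0, seed=3), 2000)
        harm = _harm_frame(g)
        kept = prscore.clump(harm, g)
        assert len(kept) == 8

    def test_matches_independent_oracle_and_constraint(self, rng):
        for _ in range(40):
            g, harm = _random_instance(rng)
            kept = sorted(prscore.clump(harm, g).tolist())
            assert kept == sorted(clump_oracle(harm, g))
            for a in kept:
                for b in kept:
                    if a >= b or harm["chrom"].iat[a] != harm["chrom"].iat[b]:
                        continue
                    if abs(harm["pos"].iat[a] - harm["pos"].iat[b]) > 250_000:
                        continue
                    try:
                        assert prscore.ld_r2(g, a, b) <= 0.1
                    except ValueError:
                        pass

    def test_position_prune_mode_differs_by_order(self):
        col = np.tile([0.0, 1, 2, 1, 0], 10)
        g = make_genotypes(np.column_stack([col, col]), positions=[1000, 2000])
        harm = _harm_frame(g, pvals=np.array([1e-2, 1e-8]))
        by_p = prscore.clump(harm, g, PruneConfig(mode="clump_by_p"))
        by_pos = prscore.clump(harm, g, PruneConfig(mode="position_prune"))
        assert harm["snp_id"].iloc[by_p].tolist() == ["snp2"]
        assert harm["snp_id"].iloc[by_pos].tolist() == ["snp1"]

    def test_empty_input_rejected(self):
        g = make_genotypes(np.zeros((5, 1)))
        with pytest.raises(ValueError, match="empty"):
            prscore.clump(_harm_frame(g).iloc[:0], g)


class TestComputePrs:
    def test_hand_example(self):
        g = make_genotypes(np.array([[0.0, 1.0, 2.0]]))
        harm = _harm_frame(g, betas=np.array([0.5, -0.2, 0.1]))
        prs = prscore.compute_prs(g, harm, [0, 1, 2])
        assert prs.score[0] == pytest.approx(0.0)
        assert prs.m_alleles[0] == 6

    def test_unit_effects_saturate_at_one(self):
        g = make_genotypes(np.full((4, 7), 2.0))
        harm = _harm_frame(g, betas=np.ones(7))
        prs = prscore.compute_prs(g, harm, np.arange(7))
        np.testing.assert_allclose(prs.score, 1.0)

    def test_missing_snp_shrinks_m(self):
        d = np.array([[1.0, np.nan], [1.0, 2.0]])
        g = make_genotypes(d)
        harm = _harm_frame(g, betas=np.array([0.5, 0.25]))
        prs = prscore.compute_prs(g, harm, [0, 1])
        assert prs.m_alleles.tolist() == [2, 4]
        assert prs.score[0] == pytest.approx(0.5 / 2)
        assert prs.score[1] == pytest.approx((0.5 + 0.5) / 4)

    def test_all_missing_sample_gets_nan(self):
        d = np.array([[np.nan], [2.0]])
        g = make_genotypes(d)
        harm = _harm_frame(g, betas=np.array([1.0]))
        prs = prscore.compute_prs(g, harm, [0])
        assert np.isnan(prs.score[0]) and prs.score[1] == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(25):
            g, harm = _random_instance(rng, n_snps=50)
            included = np.sort(rng.choice(50, size=int(rng.integers(1, 51)), replace=False))
            prs = prscore.compute_prs(g, harm, included)
            exp_scores, exp_m = prs_oracle(g.dosage, harm["beta"].to_numpy(), included)
            np.testing.assert_array_equal(prs.m_alleles, exp_m)
            np.testing.assert_array_equal(np.isnan(prs.score), np.isnan(exp_scores))
            np.testing.assert_allclose(prs.score[~np.isnan(prs.score)],
                                       exp_scores[~np.isnan(exp_scores)], rtol=1e-12)

    def test_empty_included_rejected(self):
        g = make_genotypes(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="empty"):
            prscore.compute_prs(g, _harm_frame(g), [])


class TestThresholdGrid:
    def test_printed_start_and_increment(self):
        grid = prscore.threshold_grid()
        np.testing.assert_allclose(grid[:3], [0.0001, 0.00015, 0.0002])

    def test_grid_length_closed_form(self):
        assert len(prscore.threshold_grid(1e-4, 5e-5, 0.5)) == 9999

    def test_stop_equal_start_single_threshold(self):
        grid = prscore.threshold_grid(0.01, 0.005, 0.01)
        np.testing.assert_allclose(grid, [0.01])

    @given(st.integers(1, 500))
    def test_monotone_and_bounded(self, k):
        grid = prscore.threshold_grid(1e-3, 7e-4, 1e-3 + k * 7e-4)
        assert (np.diff(grid) > 0).all()
        assert len(grid) == k + 1

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            prscore.threshold_grid(0, 1e-5, 0.5)
        with pytest.raises(ValueError):
            prscore.threshold_grid(1e-4, 5e-5, 1e-5)


class TestScan:
    @pytest.fixture(scope="class")
    def scan_setup(self):
        cfg = SimulationConfig(n_snps=300, block_size=10, rho=0.6, n_base=500,
                               n_target=300, causal_fraction=0.05, shared_fraction=1.0,
                               h2_base=0.5, h2_target=0.5, seed=21)
        co = synthdata.simulate_cohorts(cfg)
        ss = assoc.gwas(co.base, co.pheno_base)
        harm = prscore.harmonize(ss, co.target, strict_palindromic=False)
        clumped = prscore.clump(harm, co.target)
        scan = prscore.scan_clumped(harm, clumped, co.target, co.pheno_target)
        return co, harm, clumped, scan

    def test_snp_count_monotone_in_threshold(self, scan_setup):
        _, _, _, scan = scan_setup
        assert (np.diff(scan.n_snps) >= 0).all()

    def test_best_maximizes_r2(self, scan_setup):
        _, _, _, scan = scan_setup
        finite = np.nan_to_num(scan.r2, nan=-1.0)
        assert scan.r2[scan.best_index] == finite.max()
        assert scan.best_index == int(np.argmax(finite))  # ties -> smallest threshold

    def test_scan_agrees_with_direct_association(self, scan_setup):
        co, harm, clumped, scan = scan_setup
        t = scan.best_threshold
        sub = harm.iloc[clumped]
        included = clumped[np.flatnonzero((sub["p"] < t).to_numpy())]
        prs = prscore.compute_prs(co.target, harm, included, threshold=t)
        res = assoc.prs_association(prs, co.pheno_target)
        assert res.r2_nagelkerke == pytest.approx(scan.best_r2, abs=1e-9)
        assert res.p_value == pytest.approx(scan.best_p, abs=1e-9)

    def test_rescaled_effects_preserve_association(self, scan_setup):
        # positive rescaling of all weights rescales every score identically,
        # so the logistic association is unchanged (an additive shift of the
        # weights is NOT association-preserving: it adds c * mean dosage,
        # which varies by sample)
        co, harm, clumped, _ = scan_setup
        included = clumped[:20]
        prs_a = prscore.compute_prs(co.target, harm, included)
        scaled = harm.copy()
        scaled["beta"] = scaled["beta"] * 3.5
        prs_b = prscore.compute_prs(co.target, scaled, included)
        np.testing.assert_allclose(prs_b.score, 3.5 * prs_a.score, rtol=1e-12)
        ra = assoc.prs_association(prs_a, co.pheno_target)
        rb = assoc.prs_association(prs_b, co.pheno_target)
        assert ra.r2_nagelkerke == pytest.approx(rb.r2_nagelkerke, abs=1e-6)
        assert ra.p_value == pytest.approx(rb.p_value, abs=1e-6)

    def test_all_source_p_above_grid_rejected(self):
        g = make_genotypes(np.tile([0.0, 1, 2, 1], (20, 2)).T.reshape(20, -1)[:, :2])
        harm = _harm_frame(g, pvals=np.array([0.9, 0.95]))
        phen = pd.DataFrame({"sample_id": g.sample_ids,
                             "status": ["case", "control"] * 10})
        with pytest.raises(ValueError, match="no threshold"):
            prscore.scan_clumped(harm, np.array([0, 1]), g, phen,
                                 grid=np.array([1e-4, 2e-4]))

    def test_signal_below_grid_start_makes_first_threshold_best(self):
        rng = np.random.default_rng(8)
        causal = rng.choice([0.0, 1, 2], size=200, p=[0.25, 0.5, 0.25])
        noise = rng.choice([0.0, 1, 2], size=(200, 2), p=[0.25, 0.5, 0.25])
        g = make_genotypes(np.column_stack([causal, noise]),
                           positions=[1, 300_000, 600_000])
        status = np.where(causal + rng.normal(0, 0.8, 200) > 1, "case", "control")
        phen = pd.DataFrame({"sample_id": g.sample_ids, "status": status})
        harm = _harm_frame(g, betas=np.array([1.0, 0.0, 0.0]),
                           pvals=np.array([1e-6, 0.4, 0.6]))
        scan = prscore.scan_clumped(harm, np.arange(3), g, phen)
        assert scan.best_index == 0
        assert scan.best_n_snps == 1
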