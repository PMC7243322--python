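"""QC filters: missingness, exact HWE, ambiguity, Ts/Tv, relatedness,
LD pruning, polarization and DAF."""

import numpy as np
import pytest
from scipy.special import gammaln

from adaptscan.panel import ANC_ALT, ANC_REF, ANC_UNKNOWN, MISSING
from adaptscan.qc import (
    assign_ancestral,
    daf_filter,
    derived_freq,
    filter_missingness,
    hwe_exact_test,
    hwe_filter,
    kinship_filter,
    ld_prune,
    pairwise_relatedness,
    remove_ambiguous,
    tstv_ratio,
)

from conftest import build_panel, random_panel


# -- independent HWE oracle: log-space enumeration -----------------------------

def hwe_oracle_distribution(n, nA):
    """Exact conditional P(het = h | n, nA) via log-gamma arithmetic."""
    hs, logps = [], []
    for h in range(nA % 2, min(nA, 2 * n - nA) + 1, 2):
        aa = (nA - h) // 2
        bb = n - aa - h
        if aa < 0 or bb < 0:
            continue
        lp = (
            gammaln(n + 1)
            - gammaln(aa + 1)
            - gammaln(h + 1)
            - gammaln(bb + 1)
            + h * np.log(2.0)
        )
        hs.append(h)
        logps.append(lp)
    logps = np.array(logps)
    p = np.exp(logps - logps.max())
    return dict(zip(hs, p / p.sum()))


def hwe_oracle_p(n_AA, n_Aa, n_aa):
    n = n_AA + n_Aa + n_aa
    nA = 2 * n_AA + n_Aa
    if nA == 0 or nA == 2 * n:
        return 1.0
    dist = hwe_oracle_distribution(n, nA)
    p_obs = dist[n_Aa]
    return sum(p for p in dist.values() if p <= p_obs * (1 + 1e-12))


class TestHweExactTest:
    def test_monomorphic_returns_one(self):
        assert hwe_exact_test(100, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 37) == 1.0

    def test_all_heterozygotes_matches_enumeration(self):
        assert hwe_exact_test(0, 100, 0) == pytest.approx(
            hwe_oracle_p(0, 100, 0), rel=1e-9
        )

    def test_random_configurations_match_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 51))
            nAA = int(rng.integers(0, n + 1))
            nAa = int(rng.integers(0, n - nAA + 1))
            naa = n - nAA - nAa
            assert hwe_exact_test(nAA, nAa, naa) == pytest.approx(
                hwe_oracle_p(nAA, nAa, naa), rel=1e-9
            ), (nAA, nAa, naa)

    def test_distribution_sums_to_one(self):
        # exact conditional probabilities over all compatible het counts
        for n in range(1, 51, 7):
            for nA in range(1, 2 * n, 5):
                dist = hwe_oracle_distribution(n, nA)
                assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)

    def test_pvalues_superuniform_under_h0(self, rng):
        # 2,000 HWE-conforming sites; discreteness makes p super-uniform
        n = 40
        ps = []
        for _ in range(2000):
            p_allele = rng.uniform(0.1, 0.9)
            g = rng.binomial(1, p_allele, 2 * n).reshape(n, 2).sum(axis=1)
            ps.append(
                hwe_exact_test(int((g == 2).sum()), int((g == 1).sum()), int((g == 0).sum()))
            )
        ps = np.array(ps)
        for alpha in (0.01, 0.05, 0.1):
            assert (ps <= alpha).mean() <= alpha + 0.015

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 0, 5)
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)


class TestSiteFilters:
    def test_missingness_boundary_is_strictly_greater(self):
        H = np.zeros((40, 3), dtype=np.int8)
        H[1::2, :] = 1  # keep sites polymorphic
        H[:2, 0] = MISSING  # 2/40 = 5% exactly -> retained
        H[:3, 1] = MISSING  # 7.5% -> removed
        panel = build_panel(H)
        out, removed = filter_missingness(panel, 0.05)
        assert removed == 1
        assert out.n_sites == 2

    def test_zero_threshold_keeps_complete_sites_only(self):
        H = np.zeros((4, 2), dtype=np.int8)
        H[0, 0] = 1
        H[1, 1] = MISSING
        out, removed = filter_missingness(build_panel(H), 0.0)
        assert removed == 1 and out.n_sites == 1

    def test_ambiguous_pairs_removed(self):
        pairs = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("A", "G"), ("C", "T")]
        H = np.tile(np.array([[0], [1]], dtype=np.int8), (1, len(pairs)))
        panel = build_panel(H)
        panel.ref_allele = np.array([p[0] for p in pairs], dtype=object)
        panel.alt_allele = np.array([p[1] for p in pairs], dtype=object)
        out, removed = remove_ambiguous(panel)
        assert removed == 4
        assert list(out.ref_allele) == ["A", "C"]

    def test_tstv_examples(self, rng):
        panel = random_panel(rng, n_hap=4, n_sites=3)
        panel.ref_allele = np.array(["A", "C", "A"], dtype=object)
        panel.alt_allele = np.array(["G", "T", "C"], dtype=object)
        assert tstv_ratio(panel) == pytest.approx(2.0)
        panel.alt_allele = np.array(["G", "T", "G"], dtype=object)
        assert np.isnan(tstv_ratio(panel))  # no transversions

    def test_tstv_random_matches_direct_count(self, rng):
        panel = random_panel(rng, n_hap=4, n_sites=60)
        nucs = np.array(["A", "C", "G", "T"])
        ref = nucs[rng.integers(0, 4, 60)]
        alt = np.array([rng.choice([n for n in nucs if n != r]) for r in ref])
        panel.ref_allele = ref.astype(object)
        panel.alt_allele = alt.astype(object)
        ts = sum((r, a) in {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")} for r, a in zip(ref, alt))
        tv = 60 - ts
        if tv:
            assert tstv_ratio(panel) == pytest.approx(ts / tv)


class TestHweFilter:
    def test_bonferroni_threshold_arithmetic(self, rng):
        panel = random_panel(rng, n_hap=40, n_sites=50)
        out, threshold, removed = hwe_filter(panel, alpha=0.05)
        assert threshold == pytest.approx(0.05 / 50)

    def test_conforming_panel_no_removals(self, rng):
        n = 50
        cols = []
        for _ in range(200):
            p = rng.uniform(0.2, 0.8)
            cols.append((rng.random(2 * n) < p).astype(np.int8))
        panel = build_panel(np.array(cols).T)
        out, _, removed = hwe_filter(panel)
        assert removed == 0

    def test_all_heterozygote_site_removed(self, rng):
        panel = random_panel(rng, n_hap=400, n_sites=30)
        panel.H[0::2, 0] = 0
        panel.H[1::2, 0] = 1  # every genotype heterozygous at site 0
        out, threshold, removed = hwe_filter(panel)
        assert removed >= 1
        assert panel.pos[0] not in out.pos


class TestRelatedness:
    def test_duplicate_sample_detected_and_removed(self, rng):
        panel = random_panel(rng, n_hap=30, n_sites=400)
        H = np.vstack([panel.H, panel.H[:2]])
        panel = build_panel(H, pos=panel.pos, ancestral=panel.ancestral)
        rel = pairwise_relatedness(panel)
        assert rel[0, panel.n_samples - 1] > 0.9
        assert np.allclose(rel, rel.T)
        assert np.all(np.diag(rel) == 1.0)
        filtered, removed, pairs = kinship_filter(panel, 0.125)
        assert len(removed) >= 1
        assert any({a, b} == {"s000", f"s{panel.n_samples-1:03d}"} for a, b, _ in pairs)

    def test_unrelated_mean_near_zero(self, rng):
        # independent sites: the moments estimator is unbiased
        n, S = 24, 1000
        p = rng.uniform(0.1, 0.9, S)
        H = (rng.random((2 * n, S)) < p).astype(np.int8)
        rel = pairwise_relatedness(build_panel(H))
        vals = rel[np.triu_indices(n, 1)]
        se = vals.std() / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * max(se, 1e-3)

    def test_parent_offspring_half(self, rng):
        S = 2000
        p = rng.uniform(0.2, 0.8, S)
        par = (rng.random((4, S)) < p).astype(np.int8)  # two parents
        child = np.vstack(
            [
                par[rng.integers(0, 2, S), np.arange(S)],
                par[2 + rng.integers(0, 2, S), np.arange(S)],
            ]
        )
        others = (rng.random((2 * 12, S)) < p).astype(np.int8)
        panel = build_panel(np.vstack([par, child, others]))
        rel = pairwise_relatedness(panel)
        assert rel[0, 2] == pytest.approx(0.5, abs=0.08)
        assert rel[1, 2] == pytest.approx(0.5, abs=0.08)
        assert abs(rel[0, 1]) < 0.1  # the two parents are unrelated


def _audit_ld(panel, r2_max=0.2, window=50, step=5):
    """Brute-force window audit of the pruning postcondition."""
    G = panel.genotypes().astype(float)
    S = panel.n_sites
    for w0 in range(0, max(S - 1, 1), step):
        win = list(range(w0, min(w0 + window, S)))
        for i in range(len(win)):
            for j in range(i + 1, len(win)):
                a, b = G[:, win[i]], G[:, win[j]]
                if a.var() == 0 or b.var() == 0:
                    continue
                r = np.corrcoef(a, b)[0, 1]
                if r * r > r2_max + 1e-12:
                    return False
    return True


class TestLdPrune:
    def test_perfectly_correlated_triplet_keeps_one(self, rng):
        col = (rng.random(20) < 0.5).astype(np.int8)
        H = np.column_stack([col, col, col, 1 - col])
        panel = build_panel(H)
        out, removed = ld_prune(panel)
        assert out.n_sites == 1
        assert removed == 3  # the complement is also perfectly correlated

    def test_independent_sites_mostly_retained(self, rng):
        n, S = 60, 120
        H = (rng.random((2 * n, S)) < rng.uniform(0.2, 0.8, S)).astype(np.int8)
        out, removed = ld_prune(build_panel(H))
        assert removed <= S * 0.08

    def test_postcondition_audit_random_panels(self, rng):
        for _ in range(5):
            n = int(rng.integers(10, 25))
            S = int(rng.integers(40, 120))
            # correlated blocks to force pruning activity
            base = (rng.random((2 * n, S // 4)) < 0.5).astype(np.int8)
            noise = (rng.random((2 * n, S)) < 0.5).astype(np.int8)
            H = noise.copy()
            for j in range(S // 4):
                H[:, 4 * j] = base[:, j]
                flip = rng.random(2 * n) < 0.05
                H[:, 4 * j + 1] = np.where(flip, 1 - base[:, j], base[:, j])
            out, _ = ld_prune(build_panel(H))
            assert _audit_ld(out)


class TestPolarization:
    @pytest.mark.parametrize(
        "outgroups,expected",
        [
            (["A", "A", "A"], ANC_REF),
            (["G", "G", "G"], ANC_ALT),
            (["A", "G", "A"], ANC_UNKNOWN),
            (["C", "C", "C"], ANC_UNKNOWN),  # third allele
            (["A"], ANC_REF),
        ],
    )
    def test_conservation_rule(self, outgroups, expected):
        assert assign_ancestral("A", "G", outgroups) == expected

    def test_empty_outgroups_raise(self):
        with pytest.raises(ValueError):
            assign_ancestral("A", "G", [])

    def test_daf_boundary_semantics(self):
        H = np.zeros((40, 3), dtype=np.int8)
        H[:8, 0] = 1  # DAF 0.2 -> kept
        H[:7, 1] = 1  # DAF 0.175 -> removed
        H[:20, 2] = 1  # unpolarized -> excluded
        panel = build_panel(H)
        panel.ancestral[2] = ANC_UNKNOWN
        track = derived_freq(panel, "pop1")
        assert track.daf[0] == pytest.approx(0.2)
        mask = daf_filter(track, 0.2)
        assert list(mask) == [True, False, False]

    def test_daf_counts_non_ancestral_allele(self):
        H = np.zeros((10, 1), dtype=np.int8)
        H[:4, 0] = 1
        panel = build_panel(H)
        panel.ancestral[0] = ANC_ALT  # derived allele is now the ref
        track = derived_freq(panel, "pop1")
        assert track.daf[0] == pytest.approx(0.6)


class TestRunQcBookkeeping:
    def test_removed_counts_reconcile(self, rng):
        from adaptscan.qc import run_qc

        panel = random_panel(rng, n_hap=40, n_sites=120, p_missing=0.02)
        # plant one heavy-missingness site and one ambiguous site
        panel.H[: int(40 * 0.2), 0] = -1
        panel.ref_allele[1], panel.alt_allele[1] = "A", "T"
        out, rep = run_qc(panel)
        assert rep.n_input_sites == 120
        assert (
            rep.n_input_sites
            - rep.removed_missingness
            - rep.removed_ambiguous
            - rep.removed_hwe
            == rep.n_output_sites
        )
        assert rep.removed_missingness >= 1
        assert rep.removed_ambiguous >= 1
        assert rep.n_output_sites == out.n_sites
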