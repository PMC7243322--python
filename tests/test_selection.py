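"""Selection statistics: DIND and nSL against brute-force oracles,
DAF-bin standardization, site classification and the balancing CLR."""

import numpy as np
import pytest
from scipy.stats import kstest

from adaptscan.panel import ANC_ALT, ANC_REF, ANC_UNKNOWN
from adaptscan.selection import (
    SiteClassTable,
    balancing_clr,
    classify_sites,
    default_alpha_grid,
    dind_score,
    filter_shared,
    nsl_score,
    scan_genome,
    standardize_by_daf,
)
from adaptscan.simulate import OutgroupTable

from conftest import build_panel, random_panel


# -- brute-force oracles -------------------------------------------------------

def dind_oracle(H, anc, focal, window):
    """Explicit O(n^2 * w) pairwise-difference DIND."""
    n, S = H.shape
    derived = 1 - anc
    poly = [
        j
        for j in range(S)
        if 0 < H[:, j].sum() < n
    ]
    k = poly.index(focal)
    win = poly[max(k - window, 0) : k] + poly[k + 1 : k + 1 + window]
    dm = H[:, focal] == derived[focal]
    def class_pi(rows):
        idx = np.flatnonzero(rows)
        if len(idx) < 2:
            return float("nan")
        tot = cnt = 0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                tot += sum(H[idx[a], j] != H[idx[b], j] for j in win)
                cnt += 1
        return tot / cnt
    return class_pi(~dm), class_pi(dm)


def nsl_oracle(H, anc, focal, max_extend):
    """Direct per-pair identity-run scan around the focal site."""
    n, S = H.shape
    derived = 1 - anc
    poly = [j for j in range(S) if 0 < H[:, j].sum() < n]
    k = poly.index(focal)
    Hs = H[:, poly]
    def run_len(i, j):
        left = 0
        while k - left - 1 >= 0 and Hs[i, k - left - 1] == Hs[j, k - left - 1]:
            left += 1
        right = 0
        while k + right + 1 < len(poly) and Hs[i, k + right + 1] == Hs[j, k + right + 1]:
            right += 1
        return min(left, max_extend) + min(right, max_extend) + 1
    dm = H[:, focal] == derived[focal]
    sl_d, nd = 0.0, 0
    sl_a, na = 0.0, 0
    for i in range(n):
        for j in range(i + 1, n):
            if dm[i] and dm[j]:
                sl_d += run_len(i, j)
                nd += 1
            elif not dm[i] and not dm[j]:
                sl_a += run_len(i, j)
                na += 1
    if nd == 0 or na == 0:
        return float("nan")
    return np.log((sl_a / na) / (sl_d / nd))


def _eligible_sites(panel, pop="pop1", min_frac=0.25):
    n = len(panel.haplotype_rows(pop))
    der = panel.derived_code()
    out = []
    for j in range(panel.n_sites):
        c = (panel.H[:, j] == der[j]).sum()
        if 2 <= c <= n - 2:
            out.append(j)
    return out


class TestDindOracle:
    def test_random_panels_match_brute_force(self, rng):
        for _ in range(25):
            panel = random_panel(rng, n_hap=2 * int(rng.integers(4, 8)), n_sites=30)
            anc = panel.ancestral
            sites = _eligible_sites(panel)
            if not sites:
                continue
            focal = sites[rng.integers(0, len(sites))]
            w = int(rng.integers(3, 10))
            ipa, ipd, raw, flag = dind_score(panel, "pop1", focal, w)
            o_a, o_d = dind_oracle(panel.H, anc, focal, w)
            if flag in ("ok", "ipid_zero", "no_diversity"):
                assert ipa == pytest.approx(o_a, abs=1e-12)
                assert ipd == pytest.approx(o_d, abs=1e-12)

    def test_symmetric_classes_give_ratio_one(self):
        # derived and ancestral carriers have identical window haplotypes
        block = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.int8)
        H = np.zeros((8, 3), dtype=np.int8)
        H[:4, 0] = 1  # focal: first four haplotypes derived
        H[:4, 1:] = block[:, :2]
        H[4:, 1:] = block[:, :2]
        panel = build_panel(H)
        ipa, ipd, raw, flag = dind_score(panel, "pop1", 0, 5)
        assert flag == "ok"
        assert raw == pytest.approx(1.0)

    def test_zero_derived_diversity_capped_and_flagged(self):
        H = np.zeros((8, 5), dtype=np.int8)
        H[:4, 2] = 1  # derived carriers...
        H[4:, [0, 1, 3, 4]] = np.array([[1, 0, 1, 0], [0, 1, 0, 1], [1, 1, 0, 0], [0, 0, 1, 1]], dtype=np.int8)
        panel = build_panel(H)
        ipa, ipd, raw, flag = dind_score(panel, "pop1", 2, 5)
        assert ipd == 0 and ipa > 0
        assert np.isinf(raw) and flag == "ipid_zero"

    def test_small_class_invalid(self, rng):
        panel = random_panel(rng, n_hap=10, n_sites=10)
        j = 0
        panel.H[:, j] = 0
        panel.H[0, j] = 1  # single derived copy
        panel.ancestral[j] = ANC_REF
        *_, flag = dind_score(panel, "pop1", j, 5)
        assert flag == "class_too_small"


class TestNslOracle:
    def test_random_panels_match_brute_force(self, rng):
        checked = 0
        while checked < 50:
            panel = random_panel(rng, n_hap=2 * int(rng.integers(4, 7)), n_sites=40)
            sites = _eligible_sites(panel)
            if not sites:
                continue
            focal = sites[rng.integers(0, len(sites))]
            m = int(rng.integers(3, 4500))
            raw, flag = nsl_score(panel, "pop1", focal, m)
            expected = nsl_oracle(panel.H, panel.ancestral, focal, m)
            if flag == "ok":
                assert raw == pytest.approx(expected, abs=1e-12)
                checked += 1

    def test_equal_run_lengths_give_zero(self):
        # classes with mirror-image haplotype structure
        H = np.array(
            [
                [1, 1, 0, 1, 0],
                [1, 1, 0, 1, 0],
                [0, 0, 1, 0, 1],
                [0, 0, 1, 0, 1],
            ],
            dtype=np.int8,
        )
        panel = build_panel(H)
        raw, flag = nsl_score(panel, "pop1", 2, 4500)
        assert flag == "ok"
        assert raw == pytest.approx(0.0)

    def test_duplicating_derived_haplotype_decreases_nsl(self, rng):
        # growing derived-class homogeneity makes runs longer: nSL drops
        base = random_panel(rng, n_hap=12, n_sites=40)
        sites = _eligible_sites(base)
        focal = sites[len(sites) // 2]
        der = base.derived_code()[focal]
        carrier = int(np.flatnonzero(base.H[:, focal] == der)[0])
        prev = None
        H = base.H.copy()
        for k in range(3):
            others = [i for i in range(H.shape[0]) if H[i, focal] == der and i != carrier]
            H[others[0]] = H[carrier]  # overwrite another derived with the carrier
            panel = build_panel(H.copy(), ancestral=base.ancestral)
            raw, flag = nsl_score(panel, "pop1", focal, 4500)
            if flag != "ok":
                break
            if prev is not None:
                assert raw <= prev + 1e-12
            prev = raw

    def test_row_permutation_invariance(self, rng):
        panel = random_panel(rng, n_hap=12, n_sites=30)
        sites = _eligible_sites(panel)
        focal = sites[0]
        raw1, _ = nsl_score(panel, "pop1", focal, 4500)
        perm = rng.permutation(6)  # permute samples (pairs of rows)
        rows = np.empty(12, dtype=int)
        rows[0::2] = perm * 2
        rows[1::2] = perm * 2 + 1
        panel2 = build_panel(panel.H[rows], ancestral=panel.ancestral)
        raw2, _ = nsl_score(panel2, "pop1", focal, 4500)
        assert raw1 == pytest.approx(raw2)

    def test_allele_label_swap_invariance(self, rng):
        panel = random_panel(rng, n_hap=12, n_sites=30)
        sites = _eligible_sites(panel)
        focal = sites[0]
        raw1, _ = nsl_score(panel, "pop1", focal, 4500)
        ipa1, ipd1, d1, _ = dind_score(panel, "pop1", focal, 8)
        flipped = build_panel(
            (1 - panel.H).astype(np.int8), ancestral=(1 - panel.ancestral)
        )
        raw2, _ = nsl_score(flipped, "pop1", focal, 4500)
        ipa2, ipd2, d2, _ = dind_score(flipped, "pop1", focal, 8)
        assert raw1 == pytest.approx(raw2)
        assert (ipa1, ipd1) == (ipa2, ipd2)


class TestStandardize:
    def test_constant_bin_invalid(self):
        raw = np.ones(30)
        dafs = np.full(30, 0.5)
        z, bins, valid = standardize_by_daf(raw, dafs, bin_min=5)
        assert not valid.any()

    def test_two_bin_mixture_pools_to_standard_normal(self, rng):
        n = 4000
        daf = np.concatenate([rng.uniform(0.2, 0.4, n // 2), rng.uniform(0.6, 0.8, n // 2)])
        raw = np.where(daf < 0.5, rng.normal(5, 2, n), rng.normal(-1, 0.5, n))
        z, bins, valid = standardize_by_daf(raw, daf, bin_width=0.025, bin_min=20)
        stat = kstest(z[valid], "norm")
        assert stat.pvalue > 0.01

    def test_bin_boundary_lower_closed(self):
        raw = np.arange(100, dtype=float)
        daf = np.full(100, 0.25)  # exactly on a 0.025 bin edge
        z, bins, valid = standardize_by_daf(raw, daf, bin_min=5)
        assert len(np.unique(bins[valid])) == 1
        # 0.25 belongs to [0.25, 0.275): bin index 2 from min_daf=0.2
        assert np.unique(bins[valid])[0] == 2


def _mk_table(rng, n=300, p0=0.5):
    pos = np.sort(rng.choice(10**6, n, replace=False))
    poly = rng.random(n) < p0
    cm = pos * 1e-6 * 1.0  # 1 cM/Mb
    return SiteClassTable("pop1", pos, poly, cm, float(poly.mean()))


class TestBalancingClr:
    def test_nested_grid_gives_zero(self, rng):
        t = _mk_table(rng)
        focal = int(t.pos[len(t.pos) // 2])
        T = balancing_clr(t, focal, alpha_grid=np.array([t.p0]))
        assert T == 0.0

    def test_non_negative_on_random_tables(self, rng):
        for _ in range(20):
            t = _mk_table(rng, n=int(rng.integers(50, 400)), p0=rng.uniform(0.2, 0.8))
            focal = int(t.pos[len(t.pos) // 2])
            assert balancing_clr(t, focal) >= 0.0

    def test_matches_dense_grid_oracle(self, rng):
        # independent implementation of the same grid maximization
        for _ in range(20):
            t = _mk_table(rng, n=150, p0=rng.uniform(0.3, 0.7))
            k = len(t.pos) // 2
            focal = int(t.pos[k])
            flank = list(range(max(k - 100, 0), k)) + list(
                range(k + 1, min(k + 101, len(t.pos)))
            )
            y = t.is_polymorphic[flank].astype(float)
            d = np.abs(t.cM[flank] - t.cM[k]) / 100.0
            p0 = t.p0
            ll0 = np.sum(y * np.log(p0) + (1 - y) * np.log(1 - p0))
            best = -np.inf
            for delta in (1e-5, 1e-4, 1e-3):
                for a in default_alpha_grid(p0):
                    pr = np.clip(np.exp(-d / delta) * a + (1 - np.exp(-d / delta)) * p0, 1e-12, 1 - 1e-12)
                    ll = np.sum(y * np.log(pr) + (1 - y) * np.log(1 - pr))
                    best = max(best, ll)
            expected = max(2 * (best - ll0), 0.0)
            assert balancing_clr(t, focal) == pytest.approx(expected, rel=1e-9)

    def test_reflection_invariance(self, rng):
        t = _mk_table(rng, n=201)
        k = 100
        focal = int(t.pos[k])
        T1 = balancing_clr(t, focal)
        # reflect positions (and classes) around the focal site
        pos2 = np.sort(2 * t.pos[k] - t.pos)[::-1] * -1 + 2 * t.pos[k]
        order = np.argsort(2 * t.pos[k] - t.pos)
        t2 = SiteClassTable(
            "pop1",
            np.sort(2 * t.pos[k] - t.pos),
            t.is_polymorphic[order],
            np.sort(t.cM[k] * 2 - t.cM),
            t.p0,
        )
        T2 = balancing_clr(t2, focal)
        assert T1 == pytest.approx(T2, rel=1e-9)

    def test_degenerate_background_raises(self, rng):
        t = _mk_table(rng)
        t.p0 = 1.0
        with pytest.raises(ValueError):
            balancing_clr(t, int(t.pos[50]))

    def test_null_calibration_small_t(self, rng):
        # i.i.d. Bernoulli(p0) flanks: T should be small most of the time
        ts = []
        for _ in range(100):
            t = _mk_table(rng, n=250, p0=0.5)
            ts.append(balancing_clr(t, int(t.pos[125])))
        q95 = np.quantile(ts, 0.95)
        assert q95 < 15.0  # chi2-ish null scale, far below sweep-region values


class TestClassifySites:
    def _panel_with_outgroup(self):
        H = np.zeros((8, 3), dtype=np.int8)
        H[:, 0] = 1          # fixed derived (ancestral = ref "A")
        H[:4, 1] = 1         # polymorphic
        # site 2: fixed ancestral
        gmap = np.array([0.1, 0.2, 0.3])
        panel = build_panel(H, gmap_cM=gmap)
        out = OutgroupTable(
            pos=panel.pos.copy(),
            outgroup_allele=np.array(["A", "A", "A"], dtype=object),
            ingroup_allele=np.array(["A", "A", "A"], dtype=object),
            is_panel_site=np.ones(3, bool),
        )
        return panel, out

    def test_three_way_classification(self):
        panel, out = self._panel_with_outgroup()
        table = classify_sites(panel, "pop1", out)
        # fixed derived G vs outgroup A -> substitution; DAF 0.5 -> polymorphic;
        # fixed ancestral equal to outgroup -> excluded
        assert len(table.pos) == 2
        assert list(table.is_polymorphic) == [False, True]
        assert table.n_excluded == 1
        assert table.p0 == pytest.approx(0.5)

    def test_extra_outgroup_sites_enter_substitution_class(self):
        panel, out = self._panel_with_outgroup()
        out2 = OutgroupTable(
            pos=np.append(out.pos, 350),
            outgroup_allele=np.append(out.outgroup_allele, "T"),
            ingroup_allele=np.append(out.ingroup_allele, "C"),
            is_panel_site=np.append(out.is_panel_site, False),
        )
        table = classify_sites(panel, "pop1", out2)
        assert 350 in table.pos
        assert not table.is_polymorphic[list(table.pos).index(350)]


class TestScanGenome:
    def test_neutral_tail_fraction(self, rng):
        # standardized scores on a neutral-ish random panel: ~4.6% beyond |2|
        panel = random_panel(rng, n_hap=60, n_sites=3000)
        track = scan_genome(panel, "pop1", "nSL", standardize=True, bin_min=20)
        z = track.z[track.valid]
        frac = np.mean(np.abs(z) > 2)
        assert 0.01 < frac < 0.10

    def test_determinism(self, rng):
        panel = random_panel(rng, n_hap=20, n_sites=200)
        t1 = scan_genome(panel, "pop1", "DIND")
        t2 = scan_genome(panel, "pop1", "DIND")
        assert np.array_equal(t1.raw, t2.raw, equal_nan=True)
        assert np.array_equal(t1.z, t2.z, equal_nan=True)

    def test_unknown_statistic_rejected(self, rng):
        with pytest.raises(ValueError):
            scan_genome(random_panel(rng), "pop1", "iHS")


class _Res:
    def __init__(self, pathway_id, genes, significant=True):
        self.pathway_id = pathway_id
        self.genes = list(genes)
        self.significant = significant


class TestFilterShared:
    def test_identical_subnetwork_removed(self):
        t = [_Res("P1", ["a", "b", "c"])]
        r = [[_Res("P1", ["a", "b", "c"])]]
        kept, dropped = filter_shared(t, r)
        assert kept == [] and len(dropped) == 1

    def test_disjoint_gene_sets_retained(self):
        t = [_Res("P1", ["a", "b", "c"])]
        r = [[_Res("P1", ["x", "y", "z"])]]
        kept, dropped = filter_shared(t, r)
        assert len(kept) == 1 and dropped == []

    def test_jaccard_boundary_inclusive(self):
        # overlap 2, union 4 -> jaccard exactly 0.5 -> removed
        t = [_Res("P1", ["a", "b", "c"])]
        r = [[_Res("P1", ["a", "b", "d"])]]
        kept, dropped = filter_shared(t, r, jaccard_max=0.5)
        assert kept == [] and len(dropped) == 1

    def test_non_significant_reference_ignored(self):
        t = [_Res("P1", ["a", "b", "c"])]
        r = [[_Res("P1", ["a", "b", "c"], significant=False)]]
        kept, _ = filter_shared(t, r)
        assert len(kept) == 1

    def test_different_pathway_ignored(self):
        t = [_Res("P1", ["a", "b", "c"])]
        r = [[_Res("P2", ["a", "b", "c"])]]
        kept, _ = filter_shared(t, r)
        assert len(kept) == 1
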