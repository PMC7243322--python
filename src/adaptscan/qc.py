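"""Variant and sample quality control, polarization and derived-allele
frequencies.

Implements the curation filters that gate the selection scans: per-site
missingness, an exact Hardy-Weinberg test with Bonferroni correction,
removal of strand-ambiguous (A/T, C/G) SNVs, Ts/Tv bookkeeping,
method-of-moments IBD relatedness with greedy sample removal, sliding-window
LD pruning on genotype dosages, outgroup-based ancestral-allele assignment
and the derived-allele-frequency (DAF) machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .panel import ANC_ALT, ANC_REF, ANC_UNKNOWN, MISSING, HaplotypePanel

log = logging.getLogger(__name__)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class QCReport:
    """Bookkeeping for a QC pass; removed counts sum to input - output."""

    n_input_sites: int = 0
    n_output_sites: int = 0
    removed_missingness: int = 0
    removed_hwe: int = 0
    removed_ambiguous: int = 0
    hwe_threshold: float | None = None
    hwe_n_tested: int = 0
    tstv: float | None = None
    removed_samples: list[str] = field(default_factory=list)
    kinship_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input_sites": self.n_input_sites,
            "n_output_sites": self.n_output_sites,
            "removed_missingness": self.removed_missingness,
            "removed_hwe": self.removed_hwe,
            "removed_ambiguous": self.removed_ambiguous,
            "hwe_threshold": self.hwe_threshold,
            "hwe_n_tested": self.hwe_n_tested,
            "tstv": self.tstv,
            "removed_samples": self.removed_samples,
            "kinship_pairs": [list(p) for p in self.kinship_pairs],
        }


# -- per-site filters ----------------------------------------------------------

def filter_missingness(
    panel: HaplotypePanel, max_frac: float = 0.05
) -> tuple[HaplotypePanel, int]:
    """Drop sites with a missing-haplotype fraction strictly above
    ``max_frac`` (the rule removes "more than" the threshold, so a site at
    exactly the boundary is retained)."""
    frac = (panel.H == MISSING).mean(axis=0)
    keep = frac <= max_frac
    return panel.take_sites(keep), int((~keep).sum())


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test (conditional on allele counts).

    Enumerates every heterozygote count compatible with the observed allele
    counts, computes the exact conditional probability of each
    configuration, and returns the summed probability of all configurations
    no more probable than the observed one (the "prob" aggregation).  All
    arithmetic is in exact integers, so ties are handled exactly.
    """
    if min(n_AA, n_Aa, n_aa) < 0 or n_AA + n_Aa + n_aa < 1:
        raise ValueError("genotype counts must be non-negative with total >= 1")
    n = n_AA + n_Aa + n_aa
    nA = 2 * n_AA + n_Aa
    if nA == 0 or nA == 2 * n:
        return 1.0
    # conditional weights: P(het = h) proportional to
    # n! / (nAA! h! naa!) * 2^h  with nAA = (nA - h)/2, naa = n - nAA - h
    import math

    h_max = min(nA, 2 * n - nA)
    weights: dict[int, int] = {}
    for h in range(nA % 2, h_max + 1, 2):  # h must share parity with nA
        aa = (nA - h) // 2
        bb = n - aa - h
        if aa < 0 or bb < 0:
            continue
        w = (
            math.factorial(n)
            // (math.factorial(aa) * math.factorial(h) * math.factorial(bb))
        ) * (2**h)
        weights[h] = w
    w_obs = weights[n_Aa]
    total = sum(weights.values())
    p_num = sum(w for w in weights.values() if w <= w_obs)
    return p_num / total


def hwe_filter(
    panel: HaplotypePanel, alpha: float = 0.05
) -> tuple[HaplotypePanel, float, int]:
    """Remove sites out of Hardy-Weinberg equilibrium at the Bonferroni
    threshold alpha / n_tested (n_tested = polymorphic sites with at least
    one complete genotype)."""
    G = panel.genotypes()
    pvals = np.ones(panel.n_sites)
    tested = np.zeros(panel.n_sites, dtype=bool)
    for j in range(panel.n_sites):
        g = G[:, j]
        g = g[g != MISSING]
        if g.size == 0:
            continue
        n_aa = int((g == 0).sum())
        n_het = int((g == 1).sum())
        n_AA = int((g == 2).sum())
        nA = 2 * n_AA + n_het
        if nA == 0 or nA == 2 * g.size:
            continue  # monomorphic: not tested
        tested[j] = True
        pvals[j] = hwe_exact_test(n_AA, n_het, n_aa)
    n_tested = int(tested.sum())
    threshold = alpha / n_tested if n_tested else 0.0
    keep = ~(tested & (pvals < threshold))
    return panel.take_sites(keep), threshold, int((~keep).sum())


def remove_ambiguous(panel: HaplotypePanel) -> tuple[HaplotypePanel, int]:
    """Drop strand-ambiguous A/T and C/G substitutions."""
    amb = np.array(
        [
            (str(r), str(a)) in _AMBIGUOUS
            for r, a in zip(panel.ref_allele, panel.alt_allele)
        ]
    )
    return panel.take_sites(~amb), int(amb.sum())


def tstv_ratio(panel: HaplotypePanel) -> float:
    """Transition/transversion ratio over the panel's sites.

    Returns NaN (flagged undefined) when there are no transversions.
    """
    ts = sum(
        (str(r), str(a)) in _TRANSITIONS
        for r, a in zip(panel.ref_allele, panel.alt_allele)
    )
    tv = panel.n_sites - ts
    if tv == 0:
        log.warning("tstv_ratio: no transversions; ratio undefined")
        return float("nan")
    return ts / tv


# -- relatedness ---------------------------------------------------------------

def pairwise_relatedness(panel: HaplotypePanel) -> np.ndarray:
    """Method-of-moments IBD sharing (PI-HAT-style) for every sample pair.

    From identity-by-state counts and panel allele counts, estimates
    P(IBD=0), P(IBD=1), P(IBD=2) per pair and returns the matrix of
    relatedness coefficients P1/2 + P2.  The diagonal is 1.

    The expected IBS-class probabilities conditional on IBD state use
    without-replacement (hypergeometric) draws from the sample allele pool,
    the finite-sample correction that keeps the estimator unbiased at small
    sample sizes.
    """
    G = panel.genotypes().astype(np.float64)
    G[G == MISSING] = np.nan
    n_samp, S = G.shape
    if n_samp < 2:
        raise ValueError("need at least 2 samples")
    X = 2.0 * np.nansum(G == 2, axis=0) + np.nansum(G == 1, axis=0)  # ALT alleles
    T = 2.0 * np.sum(np.isfinite(G), axis=0)
    Y = T - X
    informative = (X > 0) & (Y > 0) & (T >= 4)
    if informative.sum() < 50:
        log.warning(
            "pairwise_relatedness: only %d informative sites; estimates noisy",
            int(informative.sum()),
        )
    Gi = G[:, informative]
    X, Y, T = X[informative], Y[informative], T[informative]

    P4 = T * (T - 1) * (T - 2) * (T - 3)
    P3 = T * (T - 1) * (T - 2)
    e0_ibs0 = 2 * X * (X - 1) * Y * (Y - 1) / P4
    e0_ibs1 = (
        4 * X * (X - 1) * (X - 2) * Y + 4 * Y * (Y - 1) * (Y - 2) * X
    ) / P4
    e0_ibs2 = (
        X * (X - 1) * (X - 2) * (X - 3)
        + Y * (Y - 1) * (Y - 2) * (Y - 3)
        + 4 * X * (X - 1) * Y * (Y - 1)
    ) / P4
    e1_ibs1 = (2 * X * (X - 1) * Y + 2 * Y * (Y - 1) * X) / P3
    e1_ibs2 = (
        X * (X - 1) * (X - 2)
        + Y * (Y - 1) * (Y - 2)
        + X * Y * (Y - 1)
        + Y * X * (X - 1)
    ) / P3

    out = np.eye(n_samp)
    for i in range(n_samp):
        for j in range(i + 1, n_samp):
            gi, gj = Gi[i], Gi[j]
            ok = ~(np.isnan(gi) | np.isnan(gj))
            diff = np.abs(gi[ok] - gj[ok])
            n_ibs0 = float((diff == 2).sum())
            n_ibs1 = float((diff == 1).sum())
            n_ibs2 = float((diff == 0).sum())
            s0 = e0_ibs0[ok].sum()
            P0 = n_ibs0 / s0 if s0 > 0 else 0.0
            s11 = e1_ibs1[ok].sum()
            P1 = (n_ibs1 - P0 * e0_ibs1[ok].sum()) / s11 if s11 > 0 else 0.0
            P2 = (n_ibs2 - P0 * e0_ibs2[ok].sum() - P1 * e1_ibs2[ok].sum()) / max(
                ok.sum(), 1
            )
            # no lower clamping: truncating negative moment estimates at
            # zero would bias the coefficient upward on short panels
            pihat = P1 / 2.0 + P2
            out[i, j] = out[j, i] = min(pihat, 1.0)
    return out


def kinship_filter(
    panel: HaplotypePanel, max_coeff: float = 0.125
) -> tuple[HaplotypePanel, list[str], list[tuple[str, str, float]]]:
    """Drop one member of every pair with relatedness >= ``max_coeff``.

    Within a flagged pair the member with more missing data is removed
    (ties: the later sample in panel order).  Returns the filtered panel,
    the removed sample ids and the offending pairs.
    """
    rel = pairwise_relatedness(panel)
    miss = (panel.genotypes() == MISSING).sum(axis=1)
    n = panel.n_samples
    removed: set[int] = set()
    pairs: list[tuple[str, str, float]] = []
    while True:
        worst = None
        for i in range(n):
            if i in removed:
                continue
            for j in range(i + 1, n):
                if j in removed:
                    continue
                if rel[i, j] >= max_coeff and (
                    worst is None or rel[i, j] > worst[2]
                ):
                    worst = (i, j, rel[i, j])
        if worst is None:
            break
        i, j, c = worst
        pairs.append((panel.sample_ids[i], panel.sample_ids[j], float(c)))
        drop = j if miss[j] >= miss[i] else i
        removed.add(drop)
    keep_ids = [s for k, s in enumerate(panel.sample_ids) if k not in removed]
    removed_ids = [panel.sample_ids[k] for k in sorted(removed)]
    return panel.take_samples(keep_ids), removed_ids, pairs


# -- LD pruning ----------------------------------------------------------------

def _dosage_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    ok = (g1 != MISSING) & (g2 != MISSING)
    if ok.sum() < 2:
        return 0.0
    a = g1[ok].astype(np.float64)
    b = g2[ok].astype(np.float64)
    va = a.var()
    vb = b.var()
    if va == 0 or vb == 0:
        return 0.0
    c = ((a - a.mean()) * (b - b.mean())).mean()
    return float(c * c / (va * vb))


def ld_prune(
    panel: HaplotypePanel,
    r2_max: float = 0.2,
    window: int = 50,
    step: int = 5,
) -> tuple[HaplotypePanel, int]:
    """Greedy sliding-window LD pruning on genotype dosages.

    Windows of ``window`` retained SNVs advance by ``step``; within a
    window, for every pair with squared Pearson correlation > ``r2_max``
    the later site is removed.  Passes repeat until no retained pair inside
    any window position exceeds the threshold.
    """
    G = panel.genotypes()
    keep = np.ones(panel.n_sites, dtype=bool)
    changed = True
    while changed:
        changed = False
        idx = np.flatnonzero(keep)
        for w0 in range(0, max(len(idx) - 1, 0), step):
            win = idx[w0 : w0 + window]
            win = win[keep[win]]
            if len(win) < 2:
                continue
            block = G[:, win]
            if not (block == MISSING).any():
                x = block.astype(np.float64)
                sd = x.std(axis=0)
                ok_var = sd > 0
                r2 = np.zeros((len(win), len(win)))
                if ok_var.sum() >= 2:
                    with np.errstate(invalid="ignore"):
                        c = np.corrcoef(x[:, ok_var], rowvar=False) ** 2
                    sub = np.ix_(ok_var, ok_var)
                    r2[sub] = np.nan_to_num(c)
                for a_i in range(len(win)):
                    if not keep[win[a_i]]:
                        continue
                    for b_i in range(a_i + 1, len(win)):
                        if keep[win[b_i]] and r2[a_i, b_i] > r2_max:
                            keep[win[b_i]] = False
                            changed = True
            else:
                for a_i in range(len(win)):
                    if not keep[win[a_i]]:
                        continue
                    for b_i in range(a_i + 1, len(win)):
                        if not keep[win[b_i]]:
                            continue
                        if _dosage_r2(G[:, win[a_i]], G[:, win[b_i]]) > r2_max:
                            keep[win[b_i]] = False
                            changed = True
            if len(idx) <= window:
                break
    return panel.take_sites(keep), int((~keep).sum())


# -- polarization and DAF ------------------------------------------------------

def assign_ancestral(
    site_ref: str, site_alt: str, outgroup_alleles: list[str]
) -> int:
    """Conservative polarization: the ancestral state is assigned only when
    every outgroup allele agrees and matches ref or alt; any disagreement,
    gap or third allele leaves the site unpolarized.

    Returns ANC_REF, ANC_ALT or ANC_UNKNOWN.
    """
    if not outgroup_alleles:
        raise ValueError("need at least one outgroup allele")
    alleles = {str(a).upper() for a in outgroup_alleles}
    if len(alleles) != 1:
        return ANC_UNKNOWN
    a = alleles.pop()
    if a == str(site_ref).upper():
        return ANC_REF
    if a == str(site_alt).upper():
        return ANC_ALT
    return ANC_UNKNOWN


def polarize_panel(
    panel: HaplotypePanel, outgroup_columns: list[np.ndarray]
) -> HaplotypePanel:
    """Re-assign panel.ancestral from per-site outgroup allele vectors."""
    anc = np.empty(panel.n_sites, dtype=np.int8)
    for j in range(panel.n_sites):
        anc[j] = assign_ancestral(
            panel.ref_allele[j],
            panel.alt_allele[j],
            [col[j] for col in outgroup_columns],
        )
    out = panel.take_sites(np.arange(panel.n_sites))
    out.ancestral = anc
    return out


@dataclass
class DAFTrack:
    """Per-site derived allele frequency in one population."""

    pop: str
    pos: np.ndarray
    daf: np.ndarray  # NaN where unpolarized
    polarized: np.ndarray


def derived_freq(panel: HaplotypePanel, pop: str) -> DAFTrack:
    """Derived-allele frequency among the population's non-missing
    haplotypes; NaN at unpolarized sites."""
    rows = panel.haplotype_rows(pop)
    H = panel.H[rows]
    derived = panel.derived_code()
    daf = np.full(panel.n_sites, np.nan)
    polarized = derived >= 0
    for j in np.flatnonzero(polarized):
        col = H[:, j]
        ok = col != MISSING
        if ok.sum() == 0:
            polarized[j] = False
            continue
        daf[j] = float((col[ok] == derived[j]).mean())
    return DAFTrack(pop, panel.pos.copy(), daf, polarized)


def daf_filter(track: DAFTrack, min_daf: float = 0.2) -> np.ndarray:
    """Mask of sites passing the DAF cut: polarized and DAF >= min_daf
    (the rule removes sites with frequency strictly below the cut)."""
    with np.errstate(invalid="ignore"):
        return track.polarized & (track.daf >= min_daf)


# -- composite QC pass ---------------------------------------------------------

def run_qc(
    panel: HaplotypePanel,
    max_missing: float = 0.05,
    hwe_alpha: float = 0.05,
    kinship_max: float = 0.125,
    ld_r2: float = 0.2,
    ld_window: int = 50,
    ld_step: int = 5,
    drop_ambiguous: bool = True,
) -> tuple[HaplotypePanel, QCReport]:
    """The full curation pass: missingness, ambiguity, HWE, relatedness
    (estimated on an LD-pruned copy), in that order."""
    rep = QCReport(n_input_sites=panel.n_sites)
    panel, rep.removed_missingness = filter_missingness(panel, max_missing)
    if drop_ambiguous:
        panel, rep.removed_ambiguous = remove_ambiguous(panel)
    panel, rep.hwe_threshold, rep.removed_hwe = hwe_filter(panel, hwe_alpha)
    rep.hwe_n_tested = (
        int(round(hwe_alpha / rep.hwe_threshold)) if rep.hwe_threshold else 0
    )
    rep.tstv = tstv_ratio(panel) if panel.n_sites else None
    if panel.n_samples >= 2 and panel.n_sites >= 50:
        # relatedness is estimated within each population on LD-pruned
        # sites: the moments estimator assumes homogeneous frequencies, and
        # pooling structured populations would flag unrelated pairs
        pruned, _ = ld_prune(panel, ld_r2, ld_window, ld_step)
        for pop in panel.populations:
            ids = [
                s for s, p in zip(panel.sample_ids, panel.pop_labels) if p == pop
            ]
            if len(ids) < 2:
                continue
            sub = pruned.take_samples(ids)
            filtered, removed_ids, pairs = kinship_filter(sub, kinship_max)
            rep.removed_samples.extend(removed_ids)
            rep.kinship_pairs.extend(pairs)
        if rep.removed_samples:
            drop = set(rep.removed_samples)
            panel = panel.take_samples(
                [s for s in panel.sample_ids if s not in drop]
            )
    rep.n_output_sites = panel.n_sites
    return panel, rep
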