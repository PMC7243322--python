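"""Haplotype-based selection statistics and genome scanning.

Three statistics are implemented:

* **DIND** - derived intra-allelic nucleotide diversity: the ratio
  iπA/iπD of mean pairwise differences among ancestral-allele versus
  derived-allele carrying haplotypes around a focal SNV.  A derived allele
  swept quickly to intermediate/high frequency sits on near-identical
  haplotypes, so iπD collapses and the ratio grows.
* **nSL** - number of segregating sites by length: ln(SL_A/SL_D), where
  SL_C is the mean, over haplotype pairs within allele class C at the focal
  site, of the length (in consecutive polymorphic loci, truncated at
  ``max_extend`` per side) of the maximal identity run containing the focal
  site.  Long shared derived haplotypes push nSL negative.
* **BAL** - a composite-likelihood balancing-selection statistic over
  polymorphism/substitution site classes relative to an outgroup: under the
  alternative, the probability that a site is polymorphic is
  w(d)·α + (1−w(d))·p0 with w(d) = exp(−d/δ) in genetic distance d, and
  T = 2(max ℓ1 − ℓ0) over an (α, δ) grid nesting the background α = p0.

Raw DIND and nSL scores are standardized within derived-allele-frequency
bins, the field-standard treatment of frequency-dependent statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .panel import MISSING, HaplotypePanel
from .simulate import OutgroupTable

log = logging.getLogger(__name__)

STATISTICS = ("DIND", "nSL", "BAL")


@dataclass
class ScoreTrack:
    """Per-site selection statistic for one population."""

    stat: str
    pop: str
    pos: np.ndarray
    daf: np.ndarray
    raw: np.ndarray
    z: np.ndarray
    bin_id: np.ndarray
    valid: np.ndarray
    reason: np.ndarray  # short reason code per site; "ok" where valid

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "pos": self.pos,
                "daf": self.daf,
                "raw": self.raw,
                "z": self.z,
                "bin": self.bin_id,
                "valid": self.valid,
                "reason": self.reason,
            }
        )


@dataclass
class SiteClassTable:
    """Polymorphism/substitution classification relative to an outgroup."""

    pop: str
    pos: np.ndarray
    is_polymorphic: np.ndarray
    cM: np.ndarray
    p0: float
    n_excluded: int = 0


class _PopView:
    """Complete-data, polarized view of one population's haplotypes."""

    def __init__(self, panel: HaplotypePanel, pop: str):
        self.rows = panel.haplotype_rows(pop)
        self.Hp = panel.H[self.rows]
        self.n = len(self.rows)
        self.complete = ~(self.Hp == MISSING).any(axis=0)
        cnt = np.where(self.complete, self.Hp.clip(0).sum(axis=0), -1)
        self.poly = self.complete & (cnt > 0) & (cnt < self.n)
        self.der = panel.derived_code()
        # derived indicator (defined only where polarized & complete)
        self.D = self.Hp == self.der[None, :]
        self.n_D = np.where(self.complete & (self.der >= 0), self.D.sum(axis=0), -1)
        with np.errstate(invalid="ignore"):
            self.daf = np.where(self.n_D >= 0, self.n_D / self.n, np.nan)
        self.poly_idx = np.flatnonzero(self.poly)
        self.pos = panel.pos


def _class_pi(Hw: np.ndarray, members: np.ndarray) -> float:
    """Mean pairwise difference count among ``members`` over window sites."""
    nc = int(members.sum())
    if nc < 2:
        return float("nan")
    c = Hw[members].sum(axis=0, dtype=np.int64)
    pairs_diff = (c * (nc - c)).sum()
    return float(pairs_diff) / (nc * (nc - 1) / 2)


def dind_score(
    panel: HaplotypePanel,
    pop: str,
    focal_site: int,
    window_snvs: int = 50,
) -> tuple[float, float, float, str]:
    """DIND at one focal site.

    Returns (i_pi_A, i_pi_D, raw, flag); raw is +inf with flag
    "ipid_zero" when the derived class carries no diversity, and NaN with
    an explanatory flag when the site is ineligible.
    """
    v = _PopView(panel, pop)
    return _dind_at(v, focal_site, window_snvs)


def _dind_at(
    v: _PopView, focal: int, window_snvs: int
) -> tuple[float, float, float, str]:
    if not v.complete[focal]:
        return np.nan, np.nan, np.nan, "missing_data"
    if v.der[focal] < 0:
        return np.nan, np.nan, np.nan, "unpolarized"
    if not v.poly[focal]:
        return np.nan, np.nan, np.nan, "monomorphic"
    n_D = int(v.n_D[focal])
    if n_D < 2 or v.n - n_D < 2:
        return np.nan, np.nan, np.nan, "class_too_small"
    k = int(np.searchsorted(v.poly_idx, focal))
    left = v.poly_idx[max(k - window_snvs, 0) : k]
    right = v.poly_idx[k + 1 : k + 1 + window_snvs]
    win = np.concatenate([left, right])
    if win.size == 0:
        return np.nan, np.nan, np.nan, "no_window_sites"
    Hw = v.Hp[:, win]
    dm = v.D[:, focal]
    i_pi_D = _class_pi(Hw, dm)
    i_pi_A = _class_pi(Hw, ~dm)
    if i_pi_D == 0.0 and i_pi_A == 0.0:
        return i_pi_A, i_pi_D, np.nan, "no_diversity"
    if i_pi_D == 0.0:
        return i_pi_A, i_pi_D, np.inf, "ipid_zero"
    return i_pi_A, i_pi_D, i_pi_A / i_pi_D, "ok"


def nsl_score(
    panel: HaplotypePanel,
    pop: str,
    focal_site: int,
    max_extend: int = 4500,
) -> tuple[float, str]:
    """nSL at one focal site: ln(SL_A / SL_D).  Identity runs are measured
    in consecutive polymorphic sites of the population, truncated to at
    most ``max_extend`` sites on each side of the focal site."""
    v = _PopView(panel, pop)
    raw, valid, reason = _nsl_all(v, max_extend, only_sites=[focal_site])
    j = int(np.flatnonzero(v.poly_idx == focal_site)[0]) if v.poly[focal_site] else -1
    if j < 0:
        return np.nan, "monomorphic"
    return float(raw[j]), str(reason[j])


def _nsl_all(
    v: _PopView, max_extend: int, only_sites=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """nSL raw scores at every polymorphic site of the population view.

    Returns (raw, valid, reason) arrays over v.poly_idx positions.
    Accumulates, pair by pair, the truncated identity-run length around
    every site into derived-pair and ancestral-pair sums.
    """
    P = len(v.poly_idx)
    Hseq = v.Hp[:, v.poly_idx]
    Dseq = v.D[:, v.poly_idx]
    idx = np.arange(P)
    sum_D = np.zeros(P)
    cnt_D = np.zeros(P, dtype=np.int64)
    sum_A = np.zeros(P)
    cnt_A = np.zeros(P, dtype=np.int64)
    n = v.n
    for i in range(n):
        hi = Hseq[i]
        di = Dseq[i]
        for j in range(i + 1, n):
            eq = hi == Hseq[j]
            neq = ~eq
            if neq.any():
                lf = np.maximum.accumulate(np.where(neq, idx, -1))
                nfrev = np.minimum.accumulate(np.where(neq, idx, P)[::-1])[::-1]
                left = idx - (lf + 1)
                right = nfrev - 1 - idx
            else:
                left = idx.copy()
                right = P - 1 - idx
            sl = (
                np.minimum(left, max_extend)
                + np.minimum(right, max_extend)
                + 1
            )
            bothD = di & Dseq[j] & eq
            bothA = (~di) & (~Dseq[j]) & eq
            sum_D[bothD] += sl[bothD]
            cnt_D[bothD] += 1
            sum_A[bothA] += sl[bothA]
            cnt_A[bothA] += 1
    raw = np.full(P, np.nan)
    reason = np.full(P, "class_too_small", dtype=object)
    der_ok = v.der[v.poly_idx] >= 0
    reason[~der_ok] = "unpolarized"
    valid = (cnt_D > 0) & (cnt_A > 0) & der_ok
    with np.errstate(divide="ignore", invalid="ignore"):
        raw[valid] = np.log(
            (sum_A[valid] / cnt_A[valid]) / (sum_D[valid] / cnt_D[valid])
        )
    reason[valid] = "ok"
    return raw, valid, reason


# -- DAF-bin standardization ---------------------------------------------------

def standardize_by_daf(
    raw: np.ndarray,
    dafs: np.ndarray,
    bin_width: float = 0.025,
    bin_min: int = 20,
    min_daf: float = 0.2,
    log_transform: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Within-DAF-bin z-scores.

    Bins partition [min_daf, 1) lower-closed/upper-open; bins with fewer
    than ``bin_min`` valid sites are merged with their nearest neighbour.
    Returns (z, bin_id, valid); sites in a zero-variance bin are invalid.
    """
    raw = np.asarray(raw, dtype=np.float64)
    x = np.log(raw) if log_transform else raw.copy()
    ok = np.isfinite(x) & np.isfinite(dafs)
    edges = np.arange(min_daf, 1.0 + bin_width / 2, bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    nb = len(edges) - 1
    bin_id = np.full(len(x), -1, dtype=np.int64)
    bin_id[ok] = np.clip(
        np.searchsorted(edges, dafs[ok], side="right") - 1, 0, nb - 1
    )
    # merge under-filled bins with their nearest occupied neighbour until
    # every occupied bin reaches bin_min (or only one bin remains)
    eff_bin = bin_id.copy()
    while True:
        occupied, counts = np.unique(eff_bin[eff_bin >= 0], return_counts=True)
        small = occupied[counts < bin_min]
        if small.size == 0 or occupied.size <= 1:
            break
        b = small[np.argmin(counts[counts < bin_min])]
        others = occupied[occupied != b]
        target = others[np.argmin(np.abs(others - b))]
        eff_bin[eff_bin == b] = target
    z = np.full(len(x), np.nan)
    valid = np.zeros(len(x), dtype=bool)
    for b in np.unique(eff_bin[eff_bin >= 0]):
        m = eff_bin == b
        mu = x[m].mean()
        sd = x[m].std(ddof=0)
        if sd > 0:
            z[m] = (x[m] - mu) / sd
            valid[m] = True
    return z, eff_bin, valid


def reference_standardize(
    raw: np.ndarray,
    dafs: np.ndarray,
    ref_raw: np.ndarray,
    ref_dafs: np.ndarray,
    bin_width: float = 0.05,
    min_daf: float = 0.2,
    bin_min: int = 10,
    log_transform: bool = False,
) -> np.ndarray:
    """DAF-bin z-scores calibrated against a reference score distribution.

    Within-population standardization assumes the statistic's genome-wide
    distribution is essentially neutral; on a short chromosome a sweep can
    fill its own frequency bin and normalize itself away.  Here the bin
    means and SDs come from reference scores (e.g. the same scan in
    populations without the signal), so a target population's outliers
    stay outliers.  Bins with fewer than ``bin_min`` reference sites give
    NaN.
    """
    x = np.log(np.asarray(raw, float)) if log_transform else np.asarray(raw, float)
    rx = np.log(np.asarray(ref_raw, float)) if log_transform else np.asarray(ref_raw, float)
    with np.errstate(invalid="ignore"):
        ok = np.isfinite(x) & np.isfinite(dafs)
        rok = np.isfinite(rx) & np.isfinite(ref_dafs)
    z = np.full(len(x), np.nan)
    for lo in np.arange(min_daf, 1.0, bin_width):
        hi = lo + bin_width
        mt = ok & (dafs >= lo) & (dafs < hi)
        mr = rok & (ref_dafs >= lo) & (ref_dafs < hi)
        if mt.any() and mr.sum() >= bin_min:
            sd = rx[mr].std(ddof=0)
            if sd > 0:
                z[mt] = (x[mt] - rx[mr].mean()) / sd
    return z


# -- site classification and balancing-selection CLR ---------------------------

def classify_sites(
    panel: HaplotypePanel, pop: str, outgroup: OutgroupTable
) -> SiteClassTable:
    """Classify every informative site as within-population polymorphism or
    between-species substitution relative to the outgroup.

    Sites monomorphic in the population and equal to the outgroup allele
    carry no information and are excluded; the outgroup table's extra
    (monomorphic-in-panel) substitution sites enter the substitution class.
    """
    if panel.gmap_cM is None:
        raise ValueError("panel needs an attached genetic map")
    v = _PopView(panel, pop)
    lut = outgroup.lookup()
    pos_list: list[int] = []
    poly_list: list[bool] = []
    cm_list: list[float] = []
    n_excl = 0
    for j in range(panel.n_sites):
        p = int(panel.pos[j])
        if p not in lut:
            continue
        if v.poly[j]:
            pos_list.append(p)
            poly_list.append(True)
            cm_list.append(float(panel.gmap_cM[j]))
            continue
        col = v.Hp[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            continue
        allele = str(panel.alt_allele[j] if col[0] == 1 else panel.ref_allele[j])
        if allele != lut[p]:
            pos_list.append(p)
            poly_list.append(False)
            cm_list.append(float(panel.gmap_cM[j]))
        else:
            n_excl += 1
    extra = ~outgroup.is_panel_site
    if extra.any():
        xpos = outgroup.pos[extra]
        subst = outgroup.outgroup_allele[extra] != outgroup.ingroup_allele[extra]
        xcm = np.interp(
            xpos.astype(float), panel.pos.astype(float), panel.gmap_cM
        )
        for p, is_sub, cm in zip(xpos, subst, xcm):
            if is_sub:
                pos_list.append(int(p))
                poly_list.append(False)
                cm_list.append(float(cm))
            else:
                n_excl += 1
    if not pos_list:
        raise ValueError("no informative sites for classification")
    pos = np.array(pos_list, dtype=np.int64)
    order = np.argsort(pos, kind="stable")
    is_poly = np.array(poly_list, dtype=bool)[order]
    cm = np.array(cm_list)[order]
    p0 = float(is_poly.mean())
    return SiteClassTable(pop, pos[order], is_poly, cm, p0, n_excl)


def default_alpha_grid(p0: float, k: int = 10) -> np.ndarray:
    """α grid {p0 + j·(1−p0)/k, j=0..k−1}; includes α = p0 so the null is
    nested and T >= 0 by construction."""
    return p0 + np.arange(k) * (1.0 - p0) / k


DEFAULT_DELTA_GRID = (1e-5, 1e-4, 1e-3)  # Morgans


def balancing_clr(
    table: SiteClassTable,
    focal_pos: int,
    flank_sites: int = 100,
    alpha_grid: np.ndarray | None = None,
    delta_grid=DEFAULT_DELTA_GRID,
) -> float:
    """Composite-likelihood ratio T for balancing selection at ``focal_pos``.

    Over the ``flank_sites`` informative sites nearest the focal position on
    each side (focal excluded), contrasts the locally elevated polymorphism
    model P(poly at distance d) = w(d)·α + (1−w(d))·p0, w(d) = exp(−d/δ),
    maximized over the (α, δ) grid, against the background model P = p0.
    """
    p0 = table.p0
    if p0 <= 0.0 or p0 >= 1.0:
        raise ValueError("degenerate background polymorphic fraction p0")
    if alpha_grid is None:
        alpha_grid = default_alpha_grid(p0)
    k = int(np.searchsorted(table.pos, focal_pos))
    if k >= len(table.pos) or table.pos[k] != focal_pos:
        raise ValueError(f"focal position {focal_pos} not an informative site")
    left = np.arange(max(k - flank_sites, 0), k)
    right = np.arange(k + 1, min(k + 1 + flank_sites, len(table.pos)))
    flank = np.concatenate([left, right])
    if flank.size < 10:
        raise ValueError("fewer than 10 informative flank sites")
    y = table.is_polymorphic[flank].astype(np.float64)
    d = np.abs(table.cM[flank] - table.cM[k]) / 100.0  # Morgans
    ll0 = float(
        (y * np.log(p0) + (1.0 - y) * np.log(1.0 - p0)).sum()
    )
    best = -np.inf
    for delta in delta_grid:
        w = np.exp(-d / delta)
        for a in alpha_grid:
            if a == p0:  # nested null: exactly the background model
                ll = ll0
            else:
                prob = np.clip(w * a + (1.0 - w) * p0, 1e-12, 1.0 - 1e-12)
                ll = float((y * np.log(prob) + (1.0 - y) * np.log(1.0 - prob)).sum())
            if ll > best:
                best = ll
    return max(2.0 * (best - ll0), 0.0)


# -- genome scanning -----------------------------------------------------------

def scan_genome(
    panel: HaplotypePanel,
    pop: str,
    statistic: str,
    min_daf: float = 0.2,
    dind_window: int = 50,
    nsl_max_extend: int = 4500,
    bal_flank: int = 100,
    bal_stride: int = 1,
    outgroup: OutgroupTable | None = None,
    standardize: bool = True,
    bin_width: float = 0.025,
    bin_min: int = 20,
) -> ScoreTrack:
    """Apply one statistic at every eligible focal site and standardize.

    DIND and nSL run at polarized, complete-data polymorphic sites with
    DAF >= ``min_daf`` and both allele classes of size >= 2; DIND is
    log-transformed before DAF-bin standardization and its infinite
    (zero-derived-diversity) scores are capped at the largest finite score
    of the scan.  BAL runs at every polymorphic site at ``bal_stride`` and
    reports the raw T in both raw and z slots.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    S = panel.n_sites
    raw = np.full(S, np.nan)
    z = np.full(S, np.nan)
    bin_id = np.full(S, -1, dtype=np.int64)
    valid = np.zeros(S, dtype=bool)
    reason = np.full(S, "ineligible", dtype=object)
    v = _PopView(panel, pop)
    daf = v.daf.copy()

    if statistic == "BAL":
        if outgroup is None:
            raise ValueError("BAL scan requires an outgroup table")
        table = classify_sites(panel, pop, outgroup)
        tpos = set(table.pos[table.is_polymorphic].tolist())
        targets = [
            j
            for j in np.flatnonzero(v.poly)[::bal_stride]
            if int(panel.pos[j]) in tpos
        ]
        for j in targets:
            try:
                raw[j] = balancing_clr(table, int(panel.pos[j]), bal_flank)
                valid[j] = True
                reason[j] = "ok"
            except ValueError as e:
                reason[j] = "clr_error"
        z[valid] = raw[valid]
        if not valid.any():
            log.warning("BAL scan: zero eligible sites")
        return ScoreTrack("BAL", pop, panel.pos.copy(), daf, raw, z, bin_id, valid, reason)

    with np.errstate(invalid="ignore"):
        eligible = (
            v.poly
            & (v.der >= 0)
            & (daf >= min_daf)
            & (v.n_D >= 2)
            & (v.n - v.n_D >= 2)
        )
    if statistic == "DIND":
        flags = np.full(S, "", dtype=object)
        for j in np.flatnonzero(eligible):
            _, _, r, fl = _dind_at(v, j, dind_window)
            raw[j] = r
            flags[j] = fl
        finite = np.isfinite(raw)
        if np.isinf(raw).any():
            cap = raw[finite].max() if finite.any() else 1.0
            raw[np.isinf(raw)] = cap
        ok = ~np.isnan(raw)
        # zero ratios cannot be log-transformed: floor at the smallest
        # positive finite score (rank-preserving, mirrors the +inf cap)
        if ok.any():
            pos_min = raw[ok & (raw > 0)].min() if (ok & (raw > 0)).any() else 1.0
            raw[ok & (raw == 0.0)] = pos_min
        valid[ok] = True
        reason[ok] = flags[ok]
        reason[eligible & ~ok] = flags[eligible & ~ok]
        xform = True
    else:  # nSL
        nraw, nvalid, nreason = _nsl_all(v, nsl_max_extend)
        sel = v.poly_idx
        raw[sel] = nraw
        keep = eligible[sel] & nvalid
        valid[sel] = keep
        reason[sel] = np.where(keep, nreason, "ineligible")
        xform = False

    if not valid.any():
        log.warning("%s scan for %s: zero eligible sites", statistic, pop)
        return ScoreTrack(statistic, pop, panel.pos.copy(), daf, raw, z, bin_id, valid, reason)

    if standardize:
        zs, bins, zvalid = standardize_by_daf(
            np.where(valid, raw, np.nan),
            np.where(valid, daf, np.nan),
            bin_width=bin_width,
            bin_min=bin_min,
            min_daf=min_daf,
            log_transform=xform,
        )
        z[:] = zs
        bin_id[:] = bins
        newly_invalid = valid & ~zvalid
        valid &= zvalid
        reason[newly_invalid] = "sd_zero"
    else:
        z[valid] = raw[valid]
    return ScoreTrack(statistic, pop, panel.pos.copy(), daf, raw, z, bin_id, valid, reason)


# -- cross-population shared-signal filtering ----------------------------------

def filter_shared(
    target_results: list,
    reference_results: list[list],
    mode: str = "network",
    jaccard_max: float = 0.5,
) -> tuple[list, list[tuple]]:
    """Remove target subnetwork signals replicated in reference populations.

    In "network" mode a significant target subnetwork is dropped when any
    reference population has a significant subnetwork in the same pathway
    whose gene set overlaps with Jaccard >= ``jaccard_max``.  Results carry
    ``pathway_id``, ``genes`` and ``significant`` attributes.  Returns the
    retained results and a log of (dropped_result, matching_reference).
    """
    if mode not in ("network", "gene"):
        raise ValueError(f"unknown filter mode {mode!r}")
    kept = []
    dropped: list[tuple] = []
    for res in target_results:
        if not getattr(res, "significant", False):
            kept.append(res)
            continue
        hit = None
        tg = set(res.genes)
        for ref_list in reference_results:
            for ref in ref_list:
                if not getattr(ref, "significant", False):
                    continue
                if ref.pathway_id != res.pathway_id:
                    continue
                rg = set(ref.genes)
                denom = len(tg | rg)
                jac = len(tg & rg) / denom if denom else 0.0
                if mode == "gene":
                    jac = len(tg & rg) / len(tg) if tg else 0.0
                if jac >= jaccard_max:
                    hit = ref
                    break
            if hit is not None:
                break
        if hit is None:
            kept.append(res)
        else:
            dropped.append((res, hit))
    return kept, dropped
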