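"""Outgroup f3 shared-drift estimation, residual contrasts and Hudson Fst.

f3(O; A, B) = E[(o - a)(o - b)] measures the shared genetic drift of A and
B relative to an outgroup O.  The per-site term carries the finite-sample
correction h_o/n_o (h_o = o(1-o)·n_o/(n_o-1)) for the population appearing
twice, so the statistic has expectation zero when O, A and B are samples of
one panmictic population.  Standard errors come from a weighted delete-one
block jackknife over contiguous genomic blocks.

The residual contrast replicates a two-cluster design: outgroup-f3 scores
of two focal clusters against a series of reference groups are differenced
per group, and groups whose residual exceeds 1 or 2 standard deviations of
the residual distribution are classified (2 SD counting as significant).

Fst uses the Hudson ratio-of-sums estimator, with significance from
permutation of individuals' population labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .panel import MISSING, HaplotypePanel

log = logging.getLogger(__name__)


@dataclass
class FreqTable:
    """Per-population counted-allele (ALT-orientation) frequencies."""

    pos: np.ndarray
    chrom: np.ndarray
    freqs: dict[str, np.ndarray]  # pop -> ALT allele frequency (NaN: no data)
    counts: dict[str, np.ndarray]  # pop -> haplotypes with data

    def populations(self) -> list[str]:
        return list(self.freqs)


@dataclass
class F3Result:
    outgroup: str
    a: str
    b: str
    estimate: float
    se: float
    n_blocks: int
    n_sites: int

    @property
    def z(self) -> float:
        return self.estimate / self.se if self.se > 0 else float("nan")


@dataclass
class ResidualTable:
    """Per-group f3 residual contrast between two focal clusters."""

    groups: list[str]
    f3_first: np.ndarray
    f3_second: np.ndarray
    residual: np.ndarray
    mean: float
    sd: float
    classes: list[str]  # "none", "+1SD", "-1SD", "+2SD", "-2SD"

    def significant(self) -> list[str]:
        return [g for g, c in zip(self.groups, self.classes) if c.endswith("2SD")]


def allele_freqs(
    panel: HaplotypePanel,
    pops: list[str] | None = None,
    sites: np.ndarray | None = None,
) -> FreqTable:
    """ALT-allele frequency and haplotype count per population per site.

    Missing haplotypes are dropped per population (listwise within pop); a
    site with no data in a population carries NaN frequency and count 0.
    """
    if pops is None:
        pops = panel.populations
    if sites is None:
        sites = np.arange(panel.n_sites)
    freqs: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    for pop in pops:
        rows = panel.haplotype_rows(pop)  # raises for absent population
        Hp = panel.H[rows][:, sites]
        ok = Hp != MISSING
        n = ok.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n > 0, (Hp == 1).sum(axis=0) / np.maximum(n, 1), np.nan)
        freqs[pop] = f
        counts[pop] = n
    return FreqTable(panel.pos[sites].copy(), panel.chrom[sites].copy(), freqs, counts)


def _f3_site_terms(
    freqs: FreqTable, O: str, A: str, B: str
) -> tuple[np.ndarray, np.ndarray]:
    o, a, b = freqs.freqs[O], freqs.freqs[A], freqs.freqs[B]
    n_o = freqs.counts[O].astype(np.float64)
    ok = (
        np.isfinite(o)
        & np.isfinite(a)
        & np.isfinite(b)
        & (n_o >= 2)
    )
    oo, aa, bb, nn = o[ok], a[ok], b[ok], n_o[ok]
    h_o = oo * (1.0 - oo) * nn / (nn - 1.0)
    term = (oo - aa) * (oo - bb) - h_o / nn
    return term, ok


def outgroup_f3(
    freqs: FreqTable,
    O: str,
    A: str,
    B: str,
    block_size_bp: float = 5e6,
    n_blocks: int | None = None,
) -> F3Result:
    """f3(O; A, B) with weighted delete-one block-jackknife SE.

    Blocks are contiguous position windows of ``block_size_bp`` (or, when
    ``n_blocks`` is given, the site range split into that many equal-width
    position blocks, convenient for short simulated chromosomes).
    """
    term, ok = _f3_site_terms(freqs, O, A, B)
    if term.size == 0:
        raise ValueError("no usable sites for f3")
    o = freqs.freqs[O][ok]
    if np.all((o == 0) | (o == 1)):
        raise ValueError("outgroup monomorphic at every usable site")
    pos = freqs.pos[ok].astype(np.float64)
    if n_blocks is not None:
        edges = np.linspace(pos.min(), pos.max() + 1.0, n_blocks + 1)
    else:
        edges = np.arange(pos.min(), pos.max() + block_size_bp, block_size_bp)
    block = np.clip(np.searchsorted(edges, pos, side="right") - 1, 0, len(edges) - 2)
    ids, sizes = np.unique(block, return_counts=True)
    g = len(ids)
    est = float(term.mean())
    if g < 2:
        raise ValueError("need at least 2 non-empty jackknife blocks")
    n = term.size
    total = term.sum()
    theta_minus = np.empty(g)
    for k, bid in enumerate(ids):
        m = block == bid
        theta_minus[k] = (total - term[m].sum()) / (n - sizes[k])
    # weighted delete-one jackknife (Busing et al. 1999)
    h = n / sizes.astype(np.float64)
    theta_J = g * est - float(((1.0 - 1.0 / h) * theta_minus).sum())
    tau = h * est - (h - 1.0) * theta_minus
    var = float((((tau - theta_J) ** 2) / (h - 1.0)).sum()) / g
    return F3Result(O, A, B, est, float(np.sqrt(max(var, 0.0))), g, int(n))


def f3_residual_contrast(
    f3_first: list[F3Result] | np.ndarray,
    f3_second: list[F3Result] | np.ndarray,
    groups: list[str],
) -> ResidualTable:
    """Per-group residual r_k = f3_first(k) - f3_second(k), classified
    against the empirical mean and SD of the residual distribution
    (strictly greater than k·SD; the 2 SD class is the significant one)."""
    a = np.array(
        [r.estimate if isinstance(r, F3Result) else float(r) for r in f3_first]
    )
    b = np.array(
        [r.estimate if isinstance(r, F3Result) else float(r) for r in f3_second]
    )
    if len(a) != len(groups) or len(b) != len(groups):
        raise ValueError("f3 lists and groups must have equal length")
    if len(groups) < 3:
        raise ValueError("need at least 3 groups for a residual SD")
    r = a - b
    mean = float(r.mean())
    sd = float(r.std(ddof=0))
    classes = []
    for x in r:
        dev = x - mean
        if sd > 0 and abs(dev) > 2 * sd:
            classes.append("+2SD" if dev > 0 else "-2SD")
        elif sd > 0 and abs(dev) > sd:
            classes.append("+1SD" if dev > 0 else "-1SD")
        else:
            classes.append("none")
    return ResidualTable(list(groups), a, b, r, mean, sd, classes)


def hudson_fst(freqs: FreqTable, A: str, B: str) -> float:
    """Hudson ratio-of-sums Fst estimator from allele frequencies."""
    pa, pb = freqs.freqs[A], freqs.freqs[B]
    na = freqs.counts[A].astype(np.float64)
    nb = freqs.counts[B].astype(np.float64)
    ok = np.isfinite(pa) & np.isfinite(pb) & (na >= 2) & (nb >= 2)
    pa, pb, na, nb = pa[ok], pb[ok], na[ok], nb[ok]
    num = (
        (pa - pb) ** 2
        - pa * (1 - pa) / (na - 1)
        - pb * (1 - pb) / (nb - 1)
    )
    den = pa * (1 - pb) + pb * (1 - pa)
    d = den.sum()
    if d == 0:
        return float("nan")
    return float(num.sum() / d)


def fst_permutation_p(
    panel: HaplotypePanel,
    A: str,
    B: str,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation p-value for Hudson Fst between populations A and B.

    Individuals' population labels are permuted within the A+B sample;
    p = (1 + #{perm Fst >= observed}) / (n_perm + 1).
    Returns (observed Fst, p).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    members = [i for i, p in enumerate(panel.pop_labels) if p in (A, B)]
    labels = np.array([panel.pop_labels[i] for i in members])
    nA = int((labels == A).sum())
    G = panel.genotypes()[members].astype(np.float64)
    G[G == MISSING] = np.nan

    def fst_of(mask_a: np.ndarray) -> float:
        fa, na = _freq_count(G[mask_a])
        fb, nb = _freq_count(G[~mask_a])
        ok = np.isfinite(fa) & np.isfinite(fb) & (na >= 2) & (nb >= 2)
        fa, fb, na2, nb2 = fa[ok], fb[ok], na[ok], nb[ok]
        num = (
            (fa - fb) ** 2
            - fa * (1 - fa) / (na2 - 1)
            - fb * (1 - fb) / (nb2 - 1)
        )
        den = fa * (1 - fb) + fb * (1 - fa)
        d = den.sum()
        return float(num.sum() / d) if d else float("nan")

    obs = fst_of(labels == A)
    count = 0
    idx = np.arange(len(members))
    for _ in range(n_perm):
        rng.shuffle(idx)
        mask = np.zeros(len(members), dtype=bool)
        mask[idx[:nA]] = True
        if fst_of(mask) >= obs:
            count += 1
    return obs, (1 + count) / (n_perm + 1)


def _freq_count(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = 2.0 * np.isfinite(G).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.nansum(G, axis=0) / n
    return f, n
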