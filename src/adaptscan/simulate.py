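"""Forward Wright-Fisher simulator producing phased panels with ground truth.

The generator emulates the sampling design the analyses assume: two
descendant populations (``pop1``, ``pop2``) diverged from a common ancestor
(optionally exchanging migrants), one or two outer reference populations
split earlier (``ref1``, ``ref2``), phased diploid haplotypes with known
ancestral alleles, localized hard sweeps and overdominant (balanced) loci,
and an outgroup sequence at deep divergence for polarization and
substitution calling.

The simulation is a discrete-generation diploid Wright-Fisher model with
Poisson recombination and infinite-sites Poisson mutation.  Because forward
simulation at realistic human effective sizes is not desk-scale, the
configuration carries natural-unit parameters plus an explicit rescaling
factor ``scale``: the engine runs with N/scale individuals, mu*scale and
r*scale per-bp rates, s*scale selection coefficients, m*scale migration and
generations/scale, preserving the population-scaled compound parameters
(4*N*mu, 4*N*r, 2*N*s, 4*N*m, T/N) that the statistics respond to.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .panel import ANC_ALT, ANC_REF, ANC_UNKNOWN, GeneticMap, GeneAnnotation, HaplotypePanel, PathwayGraph

log = logging.getLogger(__name__)

_NUC = np.array(["A", "C", "G", "T"])
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ["C", "T"],
    "G": ["C", "T"],
    "C": ["A", "G"],
    "T": ["A", "G"],
}


@dataclass
class SelectionEvent:
    """One selected locus.

    ``s`` is the natural-unit selection coefficient: for ``mode="sweep"``
    genotype fitnesses are 1, 1+s/2, 1+s (additive); for
    ``mode="balanced"`` it is the overdominance strength, with homozygote
    fitnesses calibrated so the deterministic equilibrium frequency of the
    derived allele equals ``eq_freq``.  ``start_gen`` counts generations
    before sampling (natural units); ``pop`` is the population carrying the
    selected mutation ("pop1", "pop2" or "ancestral").
    """

    pos: int
    mode: str = "sweep"  # "sweep" | "balanced"
    s: float = 0.05
    eq_freq: float = 0.5
    start_gen: int = 0
    pop: str = "ancestral"

    def __post_init__(self) -> None:
        if self.mode not in ("sweep", "balanced"):
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if self.pop not in ("pop1", "pop2", "ancestral"):
            raise ValueError(f"unknown target population {self.pop!r}")
        if not 0.0 < self.eq_freq < 1.0:
            raise ValueError("eq_freq must lie in (0, 1)")


@dataclass
class SimConfig:
    """Simulation parameters in natural units plus the rescaling factor.

    Defaults emulate a two-cluster human design: mutation rate 1.25e-8 per
    bp per generation, a recent two-way split (~310 generations, i.e. ~9 ky
    at 29 y/generation), an outer reference split ~5x older, and diploid
    sizes of 10,000 rescaled by ``scale=100`` to 100 individuals.
    """

    L: int = 500_000
    mu: float = 1.25e-8
    r: float = 1.0e-8
    N_anc: int = 10_000
    N1: int = 10_000
    N2: int = 10_000
    N_ref: int = 10_000
    g_split: int = 310
    g_ref_split: int = 1550
    m: float = 0.0
    n_ref_pops: int = 1
    growth_factor: float = 10.0
    growth_start_gen: int = 300
    selection: list[SelectionEvent] = field(default_factory=list)
    n_sample: int | dict[str, int] = 20
    seed: int = 0
    scale: float = 100.0
    burnin_factor: float = 10.0
    tstv: float = 2.071
    p_ref_derived: float = 0.25
    anc_unknown_frac: float = 0.0
    retry_cap: int = 100

    # -- scaled accessors -------------------------------------------------
    def _scaled_size(self, n: int) -> int:
        return max(2, int(round(n / self.scale)))

    @property
    def Na_s(self) -> int:
        return self._scaled_size(self.N_anc)

    @property
    def N1_s(self) -> int:
        return self._scaled_size(self.N1)

    @property
    def N2_s(self) -> int:
        return self._scaled_size(self.N2)

    @property
    def Nref_s(self) -> int:
        return self._scaled_size(self.N_ref)

    @property
    def mu_s(self) -> float:
        return self.mu * self.scale

    @property
    def r_s(self) -> float:
        return self.r * self.scale

    @property
    def m_s(self) -> float:
        return min(self.m * self.scale, 0.49)

    @property
    def g_split_s(self) -> int:
        return int(round(self.g_split / self.scale))

    @property
    def g_ref_split_s(self) -> int:
        return max(int(round(self.g_ref_split / self.scale)), self.g_split_s)

    def s_eff(self, s: float) -> float:
        return s * self.scale

    def validate(self) -> None:
        if self.g_ref_split < self.g_split:
            raise ValueError("g_ref_split must be >= g_split")
        if not 0.0 <= self.m < 0.5:
            raise ValueError("migration fraction m must lie in [0, 0.5)")
        if self.n_ref_pops not in (0, 1, 2):
            raise ValueError("n_ref_pops must be 0, 1 or 2")
        for n in (self.N_anc, self.N1, self.N2):
            if n < 2:
                raise ValueError("population sizes must be >= 2")
        for ev in self.selection:
            if not 1 <= ev.pos <= self.L:
                raise ValueError(f"selected position {ev.pos} outside [1, L]")

    def sample_sizes(self) -> dict[str, int]:
        pops = ["pop1", "pop2"] + [f"ref{i + 1}" for i in range(self.n_ref_pops)]
        if isinstance(self.n_sample, dict):
            return {p: int(self.n_sample.get(p, 0)) for p in pops}
        return {p: int(self.n_sample) for p in pops}


@dataclass
class SelectedSiteTruth:
    pos: int
    mode: str
    s: float
    eq_freq: float
    pop: str
    seeded_gen: int  # scaled generations before present at (re)seeding
    n_reseeds: int = 0
    lost: bool = False
    final_freq: dict[str, float] = field(default_factory=dict)
    sample_freq: dict[str, float] = field(default_factory=dict)

    @property
    def fixed(self) -> bool:
        return bool(self.final_freq) and all(
            f >= 1.0 for f in self.final_freq.values()
        )


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated panel."""

    selected: list[SelectedSiteTruth]
    g_split_scaled: int
    g_ref_split_scaled: int
    scale: float
    seed: int
    n_background_fixed: int = 0
    module_genes: list[str] = field(default_factory=list)
    module_pathway: str | None = None


def _take_columns(H: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Column subset via contiguous-run slice copies (fast for int8 C-order
    matrices where a fancy take would gather column-by-column)."""
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        return np.empty((H.shape[0], 0), dtype=H.dtype)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    parts = [H[:, idx[s] : idx[e] + 1] for s, e in zip(starts, ends)]
    return parts[0].copy() if len(parts) == 1 else np.concatenate(parts, axis=1)


class _Engine:
    """Internal mutable simulation state (scaled units throughout)."""

    def __init__(self, cfg: SimConfig):
        cfg.validate()
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.L = cfg.L
        self.muL = cfg.mu_s * cfg.L
        self.rL = cfg.r_s * cfg.L
        # columns: currently segregating derived mutations
        self.H = np.zeros((2 * cfg.Na_s, 0), dtype=np.int8)
        self.pos_arr = np.empty(0, dtype=np.int64)
        self.blocks: dict[str, tuple[int, int]] = {"anc": (0, cfg.Na_s)}
        self.occupied: set[int] = {ev.pos for ev in cfg.selection}
        self.fixed_pos: list[int] = []
        self.truth: dict[int, SelectedSiteTruth] = {}
        self.active: list[SelectionEvent] = []

    # -- helpers ----------------------------------------------------------
    def _block_rows(self, name: str) -> tuple[int, int]:
        s0, n = self.blocks[name]
        return 2 * s0, 2 * (s0 + n)

    def _event_targets(self, ev: SelectionEvent, block: str) -> bool:
        if ev.pop == "ancestral":
            return block in ("anc", "pop1", "pop2")
        return block == ev.pop

    def _col_of(self, pos: int) -> int:
        hits = np.flatnonzero(self.pos_arr == pos)
        return int(hits[0]) if hits.size else -1

    def _fitness(self, block: str) -> np.ndarray | None:
        evs = [e for e in self.active if self._event_targets(e, block)]
        if not evs:
            return None
        r0, r1 = self._block_rows(block)
        n = (r1 - r0) // 2
        w = np.ones(n)
        any_seg = False
        for ev in evs:
            col = self._col_of(ev.pos)
            if col < 0:
                continue
            any_seg = True
            g = (
                self.H[r0:r1:2, col].astype(np.float64)
                + self.H[r0 + 1 : r1 : 2, col]
            )
            se = self.cfg.s_eff(ev.s)
            if ev.mode == "sweep":
                w *= 1.0 + se * g / 2.0
            else:  # overdominance with equilibrium at eq_freq
                s_dd = se * (1.0 - ev.eq_freq)
                s_aa = se * ev.eq_freq
                w *= np.where(g == 2, 1.0 - s_dd, np.where(g == 1, 1.0, 1.0 - s_aa))
        if not any_seg:
            return None
        return np.clip(w, 1e-9, None)

    # -- one generation ---------------------------------------------------
    def reproduce(self, offspring_spec: list[tuple[str, int, str]]) -> None:
        """Produce the next generation.

        ``offspring_spec`` lists (new_block_name, n_diploids, parent_block).
        """
        par_a: list[np.ndarray] = []
        par_b: list[np.ndarray] = []
        new_blocks: dict[str, tuple[int, int]] = {}
        row = 0
        for name, n, src in offspring_spec:
            s0, ns = self.blocks[src]
            w = self._fitness(src)
            if w is None:
                pidx = self.rng.integers(0, ns, 2 * n)
            else:
                pidx = self.rng.choice(ns, size=2 * n, p=w / w.sum())
            base = 2 * (s0 + pidx)
            start = self.rng.integers(0, 2, 2 * n)
            par_a.append(base + start)
            par_b.append(base + 1 - start)
            new_blocks[name] = (row, n)
            row += n
        A = np.concatenate(par_a)
        B = np.concatenate(par_b)
        out = self.H[A].copy()
        S = self.H.shape[1]
        if S:
            # pos_arr is kept sorted, so each crossover splits the columns
            # at a searchsorted index and alternate segments copy from the
            # homologous haplotype via cheap slice assignments
            ncx = self.rng.poisson(self.rL, len(A))
            for g in np.flatnonzero(ncx):
                bp = np.sort(self.rng.uniform(1.0, self.L + 1.0, ncx[g]))
                cuts = np.searchsorted(self.pos_arr, bp)
                src = self.H[B[g]]
                for i in range(0, len(cuts), 2):
                    j1 = cuts[i]
                    j2 = cuts[i + 1] if i + 1 < len(cuts) else S
                    out[g, j1:j2] = src[j1:j2]
        self.H = out
        self.blocks = new_blocks

    def migrate(self) -> None:
        cfg = self.cfg
        if cfg.m_s <= 0 or "pop1" not in self.blocks or "pop2" not in self.blocks:
            return
        n1 = self.blocks["pop1"][1]
        n2 = self.blocks["pop2"][1]
        k = self.rng.binomial(min(n1, n2), cfg.m_s)
        if k == 0:
            return
        i1 = self.rng.choice(n1, k, replace=False)
        i2 = self.rng.choice(n2, k, replace=False)
        r1 = 2 * (self.blocks["pop1"][0] + i1)
        r2 = 2 * (self.blocks["pop2"][0] + i2)
        rows1 = np.concatenate([r1, r1 + 1])
        rows2 = np.concatenate([r2, r2 + 1])
        tmp = self.H[rows1].copy()
        self.H[rows1] = self.H[rows2]
        self.H[rows2] = tmp

    def mutate_and_prune(self) -> None:
        """Drop lost/fixed columns, add this generation's new mutations and
        restore the sorted-by-position column invariant in one rebuild."""
        G = self.H.shape[0]
        n_new = self.rng.poisson(self.muL * G)
        carriers = self.rng.integers(0, G, n_new) if n_new else None
        newpos = np.empty(n_new, dtype=np.int64)
        for i in range(n_new):
            while True:
                p = int(self.rng.integers(1, self.L + 1))
                if p not in self.occupied:
                    break
            self.occupied.add(p)
            newpos[i] = p

        keep = None
        if self.pos_arr.size:
            cnt = self.H.sum(axis=0, dtype=np.int64)
            fixed = cnt == G
            lost = cnt == 0
            if fixed.any():
                self.fixed_pos.extend(int(p) for p in self.pos_arr[fixed])
            if lost.any():
                sel_positions = {ev.pos for ev in self.cfg.selection}
                for p in self.pos_arr[lost]:
                    if int(p) not in sel_positions:  # selected stay reserved
                        self.occupied.discard(int(p))
            keep = ~(fixed | lost)

        if n_new:
            order_new = np.argsort(newpos, kind="stable")
            newpos = newpos[order_new]
            cols = np.zeros((G, n_new), dtype=np.int8)
            cols[carriers[order_new], np.arange(n_new)] = 1
            if keep is not None and not keep.all():
                base = _take_columns(self.H, keep)
                basep = self.pos_arr[keep]
            else:
                base, basep = self.H, self.pos_arr
            # merge the sorted new columns into the sorted base by slices
            ins = np.searchsorted(basep, newpos)
            parts: list[np.ndarray] = []
            prev = 0
            for k in range(n_new):
                parts.append(base[:, prev : ins[k]])
                parts.append(cols[:, k : k + 1])
                prev = ins[k]
            parts.append(base[:, prev:])
            self.H = np.concatenate(parts, axis=1)
            self.pos_arr = np.insert(basep, ins, newpos)
        elif keep is not None and not keep.all():
            self.H = _take_columns(self.H, keep)
            self.pos_arr = self.pos_arr[keep]

    def seed_event(self, ev: SelectionEvent, gens_left: int, reseed: bool = False) -> None:
        """Introduce (or re-introduce) the selected mutation as a single copy."""
        if ev.pop in self.blocks:
            block = ev.pop
        elif ev.pop == "ancestral":
            if "anc" in self.blocks:
                block = "anc"
            else:
                block = "pop1" if self.rng.integers(0, 2) == 0 else "pop2"
        else:  # target population does not exist yet: seed into the ancestor
            block = "anc"
        r0, r1 = self._block_rows(block)
        if ev.mode == "balanced" and not reseed:
            # a balanced polymorphism is modelled as already established:
            # seed at the deterministic equilibrium frequency (a single
            # copy would usually be lost before overdominance can hold it)
            k = max(1, int(round(ev.eq_freq * (r1 - r0))))
            rows = r0 + self.rng.choice(r1 - r0, size=k, replace=False)
        else:
            rows = np.array([int(self.rng.integers(r0, r1))])
        col = self._col_of(ev.pos)
        if col < 0:  # insert keeping columns sorted by position
            j = int(np.searchsorted(self.pos_arr, ev.pos))
            newcol = np.zeros((self.H.shape[0], 1), dtype=np.int8)
            self.H = np.concatenate(
                [self.H[:, :j], newcol, self.H[:, j:]], axis=1
            )
            self.pos_arr = np.insert(self.pos_arr, j, ev.pos)
            col = j
        self.H[rows, col] = 1
        t = self.truth.setdefault(
            ev.pos,
            SelectedSiteTruth(
                ev.pos, ev.mode, ev.s, ev.eq_freq, ev.pop, seeded_gen=gens_left
            ),
        )
        if reseed:
            t.n_reseeds += 1
            t.seeded_gen = gens_left
        if ev not in self.active:
            self.active.append(ev)

    def check_retries(self, gens_left: int) -> None:
        fixed = set(self.fixed_pos)
        for ev in self.active:
            if self._col_of(ev.pos) >= 0 or ev.pos in fixed:
                continue  # still segregating, or fixed (a success, not a loss)
            t = self.truth[ev.pos]
            if ev.mode == "sweep" and t.n_reseeds < self.cfg.retry_cap and gens_left > 0:
                self.seed_event(ev, gens_left, reseed=True)
            else:
                t.lost = True

    def pop_frequencies(self, pos: int) -> dict[str, float]:
        col = self._col_of(pos)
        out = {}
        for name in self.blocks:
            r0, r1 = self._block_rows(name)
            out[name] = (
                float(self.H[r0:r1, col].mean()) if col >= 0 else
                (1.0 if pos in self.fixed_pos else 0.0)
            )
        return out


def simulate_panel(config: SimConfig) -> tuple[HaplotypePanel, SimTruth]:
    """Run the forward simulation and emit a sampled phased panel + truth.

    The emitted panel contains every site carrying a derived allele among
    the sampled haplotypes (including sites fixed derived in the sample,
    which a variant caller would report against the ancestral-like
    reference) on chromosome "1", with truth-known ancestral alleles and a
    constant-rate genetic map matching the simulated recombination rate.
    """
    eng = _Engine(config)
    cfg = config
    burnin = int(round(cfg.burnin_factor * cfg.Na_s))
    total = burnin + cfg.g_ref_split_s
    ref_names = [f"ref{i + 1}" for i in range(cfg.n_ref_pops)]

    def seed_time(ev: SelectionEvent) -> int:
        t = int(round(ev.start_gen / cfg.scale))
        if ev.pop in ("pop1", "pop2"):
            t = min(t, cfg.g_split_s)
        return min(t, total)

    schedule: dict[int, list[SelectionEvent]] = {}
    for ev in cfg.selection:
        schedule.setdefault(seed_time(ev), []).append(ev)

    # recent population growth (human-like late expansion); keeping close
    # relatives rare in the sampled generation despite the rescaled size
    growth_s = int(round(cfg.growth_start_gen / cfg.scale))

    def gsize(n: int, gens_left: int) -> int:
        if cfg.growth_factor > 1.0 and 0 < growth_s >= gens_left:
            return int(round(n * cfg.growth_factor))
        return n

    for gens_left in range(total, 0, -1):
        for ev in schedule.get(gens_left, ()):
            eng.seed_event(ev, gens_left)
        # population restructuring happens when crossing the split times
        if gens_left == cfg.g_ref_split_s and ref_names and "anc" in eng.blocks:
            spec = [("anc", gsize(cfg.Na_s, gens_left), "anc")] + [
                (r, gsize(cfg.Nref_s, gens_left), "anc") for r in ref_names
            ]
        elif gens_left == cfg.g_split_s and "anc" in eng.blocks:
            spec = [
                ("pop1", gsize(cfg.N1_s, gens_left), "anc"),
                ("pop2", gsize(cfg.N2_s, gens_left), "anc"),
            ] + [
                (r, gsize(cfg.Nref_s, gens_left), r)
                for r in ref_names
                if r in eng.blocks
            ]
        elif gens_left == growth_s and cfg.growth_factor > 1.0:
            spec = [
                (b, int(round(n * cfg.growth_factor)), b)
                for b, (s0, n) in eng.blocks.items()
            ]
        else:
            spec = [(b, n, b) for b, (s0, n) in eng.blocks.items()]
        eng.reproduce(spec)
        eng.migrate()
        eng.mutate_and_prune()
        eng.check_retries(gens_left - 1)
    if "anc" in eng.blocks:  # g_split == 0: split at the sampling instant
        spec = [
            ("pop1", gsize(cfg.N1_s, 0), "anc"),
            ("pop2", gsize(cfg.N2_s, 0), "anc"),
        ] + [(r, eng.blocks[r][1], r) for r in ref_names if r in eng.blocks]
        eng.reproduce(spec)
        eng.mutate_and_prune()
        eng.check_retries(0)

    # record whole-population final frequencies for selected sites
    for pos, t in eng.truth.items():
        t.final_freq = eng.pop_frequencies(pos)

    # -- sample diploids and emit the panel -------------------------------
    rng = eng.rng
    sizes = cfg.sample_sizes()
    sample_rows: list[np.ndarray] = []
    sample_ids: list[str] = []
    pop_labels: list[str] = []
    for name in ["pop1", "pop2", *ref_names]:
        want = sizes.get(name, 0)
        if want <= 0:
            continue
        s0, n = eng.blocks[name]
        if want > n:
            raise ValueError(f"n_sample for {name} exceeds population size {n}")
        chosen = np.sort(rng.choice(n, size=want, replace=False))
        for i in chosen:
            base = 2 * (s0 + i)
            sample_rows.append(np.array([base, base + 1]))
        sample_ids.extend(f"{name}_{k:03d}" for k in range(want))
        pop_labels.extend([name] * want)
    rows = np.concatenate(sample_rows) if sample_rows else np.empty(0, dtype=int)
    Hs = eng.H[rows]

    cnt = Hs.sum(axis=0, dtype=np.int64)
    keep = cnt > 0
    Hs = Hs[:, keep]
    pos_seg = eng.pos_arr[keep]
    # sites fixed derived population-wide during the run: all-derived columns
    fixed_arr = np.array(sorted(set(eng.fixed_pos)), dtype=np.int64)
    all_pos = np.concatenate([pos_seg, fixed_arr])
    Hall = np.concatenate(
        [Hs, np.ones((Hs.shape[0], len(fixed_arr)), dtype=np.int8)], axis=1
    )
    order = np.argsort(all_pos, kind="stable")
    all_pos = all_pos[order]
    Hall = Hall[:, order]

    for pos, t in eng.truth.items():
        col = np.flatnonzero(all_pos == pos)
        if col.size:
            for name in ["pop1", "pop2", *ref_names]:
                if sizes.get(name, 0) <= 0:
                    continue
                mask = np.array([p == name for p in pop_labels]).repeat(2)
                t.sample_freq[name] = float(Hall[mask, col[0]].mean())

    # nucleotide assignment: ancestral uniform, derived transition-biased
    S = len(all_pos)
    anc_nuc = _NUC[rng.integers(0, 4, S)]
    p_ts = cfg.tstv / (1.0 + cfg.tstv)
    der_nuc = np.empty(S, dtype=object)
    is_ts = rng.random(S) < p_ts
    for j in range(S):
        a = anc_nuc[j]
        der_nuc[j] = (
            _TRANSITION[a] if is_ts[j] else _TRANSVERSIONS[a][rng.integers(0, 2)]
        )

    flip = rng.random(S) < cfg.p_ref_derived  # reference carries the derived allele
    ref = np.where(flip, der_nuc, anc_nuc).astype(object)
    alt = np.where(flip, anc_nuc, der_nuc).astype(object)
    Hout = np.where(flip[None, :], 1 - Hall, Hall).astype(np.int8)
    ancestral = np.where(flip, ANC_ALT, ANC_REF).astype(np.int8)
    if cfg.anc_unknown_frac > 0:
        unk = rng.random(S) < cfg.anc_unknown_frac
        ancestral[unk] = ANC_UNKNOWN

    panel = HaplotypePanel(
        chrom=np.array(["1"] * S, dtype=object),
        pos=all_pos,
        ref_allele=ref,
        alt_allele=alt,
        H=Hout,
        sample_ids=sample_ids,
        pop_labels=pop_labels,
        ancestral=ancestral,
    )
    panel.attach_genetic_map(
        GeneticMap.uniform("1", cfg.L, cfg.r_s * 100.0)
    )
    panel.validate()
    truth = SimTruth(
        selected=list(eng.truth.values()),
        g_split_scaled=cfg.g_split_s,
        g_ref_split_scaled=cfg.g_ref_split_s,
        scale=cfg.scale,
        seed=cfg.seed,
        n_background_fixed=len(fixed_arr),
    )
    for t in truth.selected:
        if t.pos not in set(all_pos.tolist()) and not t.fixed:
            t.lost = True
    return panel, truth


# -- outgroup ------------------------------------------------------------------

@dataclass
class OutgroupTable:
    """Per-site outgroup alleles for polarization and substitution calling.

    Contains one row per panel site plus additional rows for sites that are
    monomorphic in the panel but substituted on the outgroup lineage.
    ``ingroup_allele`` is the (monomorphic/ancestral) ingroup nucleotide.
    """

    pos: np.ndarray
    outgroup_allele: np.ndarray
    ingroup_allele: np.ndarray
    is_panel_site: np.ndarray

    def to_tsv(self, path: str) -> str:
        with open(path, "w") as fh:
            fh.write("pos\toutgroup_allele\tingroup_allele\tin_panel\n")
            for p, o, i, b in zip(
                self.pos, self.outgroup_allele, self.ingroup_allele, self.is_panel_site
            ):
                fh.write(f"{p}\t{o}\t{i}\t{int(b)}\n")
        return path

    @classmethod
    def from_tsv(cls, path: str) -> "OutgroupTable":
        pos, og, ig, ip = [], [], [], []
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                f = line.rstrip("\n").split("\t")
                pos.append(int(f[0]))
                og.append(f[1])
                ig.append(f[2])
                ip.append(bool(int(f[3])))
        return cls(
            np.array(pos, dtype=np.int64),
            np.array(og, dtype=object),
            np.array(ig, dtype=object),
            np.array(ip, dtype=bool),
        )

    def lookup(self) -> dict[int, str]:
        return {int(p): str(a) for p, a in zip(self.pos, self.outgroup_allele)}


def generate_outgroup(
    panel: HaplotypePanel,
    t_div_years: float = 6.0e6,
    mu: float = 1.25e-8,
    gen_years: float = 29.0,
    seed: int = 0,
    L: int | None = None,
) -> OutgroupTable:
    """Simulate an outgroup sequence on a lineage of ``t_div_years`` years.

    Each panel site carries the panel's ancestral allele in the outgroup,
    substituted with probability 1 - exp(-mu * t_div_years / gen_years)
    (single-lineage Poisson substitution).  Additional substitution sites,
    monomorphic in the panel, are emitted at the same per-bp rate; the
    balancing-selection scan needs them as its substitution class.
    """
    rng = np.random.default_rng(seed)
    if np.any(panel.ancestral == ANC_UNKNOWN):
        raise ValueError("generate_outgroup requires known ancestral alleles")
    if L is None:
        L = int(panel.pos.max()) + 1 if panel.n_sites else 0
    t_gen = t_div_years / gen_years
    p_sub = 1.0 - math.exp(-mu * t_gen)

    anc_nuc = np.where(
        panel.ancestral == ANC_REF, panel.ref_allele, panel.alt_allele
    ).astype(object)
    out_nuc = anc_nuc.copy()
    hit = rng.random(panel.n_sites) < p_sub
    for j in np.flatnonzero(hit):
        out_nuc[j] = _mutate_nucleotide(str(anc_nuc[j]), rng)

    n_extra = rng.poisson(L * p_sub) if L > 0 else 0
    taken = set(int(p) for p in panel.pos)
    extra_pos = np.empty(n_extra, dtype=np.int64)
    for i in range(n_extra):
        while True:
            p = int(rng.integers(1, max(L, 2)))
            if p not in taken:
                break
        taken.add(p)
        extra_pos[i] = p
    extra_pos.sort()
    extra_in = _NUC[rng.integers(0, 4, n_extra)].astype(object)
    extra_out = np.array(
        [_mutate_nucleotide(str(a), rng) for a in extra_in], dtype=object
    )

    pos = np.concatenate([panel.pos, extra_pos])
    og = np.concatenate([out_nuc, extra_out])
    ig = np.concatenate([anc_nuc, extra_in])
    is_panel = np.concatenate(
        [np.ones(panel.n_sites, bool), np.zeros(n_extra, bool)]
    )
    order = np.argsort(pos, kind="stable")
    return OutgroupTable(pos[order], og[order], ig[order], is_panel[order])


def _mutate_nucleotide(a: str, rng: np.random.Generator, tstv: float = 2.071) -> str:
    if rng.random() < tstv / (1.0 + tstv):
        return _TRANSITION[a]
    return _TRANSVERSIONS[a][rng.integers(0, 2)]


# -- annotation and pathways ---------------------------------------------------

def generate_annotation(
    panel: HaplotypePanel,
    gene_len_bp: int = 10_000,
    gap_bp: int = 5_000,
    L: int | None = None,
) -> list[GeneAnnotation]:
    """Tile genes [k*(len+gap), k*(len+gap)+len) along the chromosome."""
    if gene_len_bp <= 0 or gap_bp <= 0:
        raise ValueError("gene_len_bp and gap_bp must be positive")
    if L is None:
        L = int(panel.pos.max()) if panel.n_sites else 0
    if L < gene_len_bp:
        log.warning("sequence length %d shorter than one gene; no genes", L)
        return []
    chrom = str(panel.chrom[0]) if panel.n_sites else "1"
    genes = []
    k = 0
    while True:
        start = k * (gene_len_bp + gap_bp)
        end = start + gene_len_bp
        if end > L:
            break
        genes.append(GeneAnnotation(f"g{k + 1:04d}", chrom, start, end))
        k += 1
    return genes


def generate_pathways(
    genes: list[GeneAnnotation],
    n_pathways: int = 10,
    size_range: tuple[int, int] = (8, 15),
    p_edge: float = 0.15,
    injected_module: list[str] | None = None,
    seed: int = 0,
) -> tuple[list[PathwayGraph], dict]:
    """Random pathway graphs: spanning tree + extra edges (connected by
    construction).  If ``injected_module`` lists gene ids, the first pathway
    contains them as a connected subgraph (recorded in the returned truth).
    """
    rng = np.random.default_rng(seed)
    ids = [g.gene_id for g in genes]
    if size_range[0] < 2 or size_range[1] > len(ids):
        raise ValueError("size_range incompatible with number of genes")
    truth = {"module_pathway": None, "module_genes": []}
    out: list[PathwayGraph] = []
    for pi in range(n_pathways):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        module: list[str] = []
        if pi == 0 and injected_module:
            module = list(injected_module)
            if len(set(module) - set(ids)):
                raise ValueError("injected module genes missing from annotation")
            size = max(size, len(module))
            rest_pool = [g for g in ids if g not in module]
            rest = list(
                rng.choice(rest_pool, size=size - len(module), replace=False)
            )
            members = module + rest
            truth["module_pathway"] = f"P{pi + 1:03d}"
            truth["module_genes"] = module
        else:
            members = list(rng.choice(ids, size=size, replace=False))
        # random spanning tree; module genes occupy the first positions and
        # are wired as a path, so the injected module is a connected chain
        # rather than a high-degree hub; remaining nodes attach uniformly
        edges: set[tuple[str, str]] = set()
        for i in range(1, len(members)):
            j = i - 1 if module and i < len(module) else int(rng.integers(0, i))
            a, b = members[j], members[i]
            edges.add((a, b) if a < b else (b, a))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.random() < p_edge:
                    a, b = members[i], members[j]
                    edges.add((a, b) if a < b else (b, a))
        out.append(PathwayGraph(f"P{pi + 1:03d}", members, sorted(edges)))
    return out, truth
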