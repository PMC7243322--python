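"""Core in-memory containers for phased haplotype panels and genomic annotation.

The :class:`HaplotypePanel` is the single exchange object of the package: a
phased 0/1 haplotype matrix over biallelic SNVs together with per-site
metadata (alleles, ancestral state, genetic-map position) and per-sample
population labels.  All scan, QC and f-statistic operations consume and
return panels or thin views derived from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

MISSING = -1  # sentinel for a missing haplotype allele in H

# ancestral-state codes, per site
ANC_REF = 0
ANC_ALT = 1
ANC_UNKNOWN = -1

_AUTOSOMES = {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}


def is_autosome(chrom: str) -> bool:
    return chrom in _AUTOSOMES


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotype panel.

    Attributes
    ----------
    chrom : array of str, per site
    pos : array of int, 1-based bp coordinates (VCF convention)
    ref_allele, alt_allele : arrays of single-letter nucleotides per site
    H : int8 matrix of shape (2 * n_samples, n_sites); 0 = ref, 1 = alt,
        -1 = missing.  Haplotype rows 2k and 2k+1 belong to sample k.
    sample_ids : ordered sample identifiers
    pop_labels : population label per sample
    ancestral : int8 per site; 0 = ref ancestral, 1 = alt ancestral,
        -1 = unknown
    gmap_cM : float per site, genetic position in centimorgans (may be NaN
        when no map was attached)
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    H: np.ndarray
    sample_ids: list[str]
    pop_labels: list[str]
    ancestral: np.ndarray
    gmap_cM: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        self.H = np.asarray(self.H, dtype=np.int8)
        self.ancestral = np.asarray(self.ancestral, dtype=np.int8)
        if self.gmap_cM is not None:
            self.gmap_cM = np.asarray(self.gmap_cM, dtype=np.float64)

    # -- basic dimensions -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.H.shape[1]

    @property
    def n_haplotypes(self) -> int:
        return self.H.shape[0]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pop_labels:
            seen.setdefault(p)
        return list(seen)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        """Check the panel invariants; raise ``ValueError`` on violation."""
        if self.H.ndim != 2:
            raise ValueError("H must be 2-D")
        if self.H.shape[0] % 2 != 0:
            raise ValueError("H must have an even number of haplotype rows")
        if self.H.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("H rows must equal 2 * n_samples")
        if len(self.pop_labels) != len(self.sample_ids):
            raise ValueError("pop_labels must match sample_ids")
        n = self.n_sites
        for name, arr in (
            ("chrom", self.chrom),
            ("pos", self.pos),
            ("ref_allele", self.ref_allele),
            ("alt_allele", self.alt_allele),
            ("ancestral", self.ancestral),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != n_sites {n}")
        for c in np.unique(self.chrom.astype(str)):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"pos not strictly increasing on {c}")
            if self.gmap_cM is not None:
                g = self.gmap_cM[self.chrom == c]
                g = g[~np.isnan(g)]
                if np.any(np.diff(g) < 0):
                    raise ValueError(f"gmap_cM decreasing on {c}")
        bad = ~np.isin(self.H, (0, 1, MISSING))
        if bad.any():
            raise ValueError("H entries must be 0, 1 or missing (-1)")

    # -- views ------------------------------------------------------------
    def haplotype_rows(self, pop: str) -> np.ndarray:
        """Row indices in ``H`` of all haplotypes of population ``pop``."""
        idx = [i for i, p in enumerate(self.pop_labels) if p == pop]
        if not idx:
            raise KeyError(f"population {pop!r} not present in panel")
        rows = np.empty(2 * len(idx), dtype=np.intp)
        rows[0::2] = np.asarray(idx) * 2
        rows[1::2] = np.asarray(idx) * 2 + 1
        return rows

    def genotypes(self) -> np.ndarray:
        """Diploid dosage matrix (n_samples x n_sites); missing = -1."""
        a = self.H[0::2]
        b = self.H[1::2]
        g = (a + b).astype(np.int8)
        g[(a == MISSING) | (b == MISSING)] = MISSING
        return g

    def take_sites(self, mask_or_index: np.ndarray) -> "HaplotypePanel":
        """New panel restricted to the given site mask / index array."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref_allele=self.ref_allele[idx],
            alt_allele=self.alt_allele[idx],
            H=self.H[:, idx],
            ancestral=self.ancestral[idx],
            gmap_cM=None if self.gmap_cM is None else self.gmap_cM[idx],
        )

    def take_samples(self, keep: Sequence[str]) -> "HaplotypePanel":
        keep_set = set(keep)
        idx = [i for i, s in enumerate(self.sample_ids) if s in keep_set]
        rows = np.empty(2 * len(idx), dtype=np.intp)
        rows[0::2] = np.asarray(idx) * 2
        rows[1::2] = np.asarray(idx) * 2 + 1
        return replace(
            self,
            H=self.H[rows],
            sample_ids=[self.sample_ids[i] for i in idx],
            pop_labels=[self.pop_labels[i] for i in idx],
        )

    def derived_code(self) -> np.ndarray:
        """Per-site code (0/1) of the derived allele; -1 where unpolarized."""
        d = np.full(self.n_sites, -1, dtype=np.int8)
        d[self.ancestral == ANC_REF] = 1
        d[self.ancestral == ANC_ALT] = 0
        return d

    def attach_genetic_map(self, gmap: "GeneticMap") -> None:
        cm = np.empty(self.n_sites, dtype=np.float64)
        for c in np.unique(self.chrom.astype(str)):
            m = self.chrom == c
            cm[m] = gmap.interpolate(c, self.pos[m])
        self.gmap_cM = cm


@dataclass
class GeneticMap:
    """Piecewise-linear genetic map: per chromosome, anchors (bp, cM).

    Interpolation is linear between anchors and constant beyond the ends.
    """

    anchors: dict[str, tuple[np.ndarray, np.ndarray]]  # chrom -> (bp, cM)

    def __post_init__(self) -> None:
        for c, (bp, cm) in self.anchors.items():
            bp = np.asarray(bp, dtype=np.float64)
            cm = np.asarray(cm, dtype=np.float64)
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"map bp not increasing on {c}")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"map cM decreasing on {c}")
            self.anchors[c] = (bp, cm)

    def interpolate(self, chrom: str, bp) -> np.ndarray:
        if chrom not in self.anchors:
            raise KeyError(f"chromosome {chrom!r} not in genetic map")
        xs, ys = self.anchors[chrom]
        return np.interp(np.asarray(bp, dtype=np.float64), xs, ys)

    @classmethod
    def uniform(cls, chrom: str, length_bp: int, cm_per_bp: float) -> "GeneticMap":
        """Constant-rate map over [0, length_bp]."""
        bp = np.array([0.0, float(length_bp)])
        return cls({chrom: (bp, bp * cm_per_bp)})


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene body in 0-based half-open BED coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )


@dataclass
class PathwayGraph:
    """An undirected gene graph for one pathway.

    Edges must connect member genes; isolated members are retained.
    """

    pathway_id: str
    genes: list[str]
    edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        members = set(self.genes)
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"{self.pathway_id}: self-loop on {a}")
            for g in (a, b):
                if g not in members:
                    raise ValueError(
                        f"pathway {self.pathway_id}: edge gene {g} is not a member"
                    )

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.genes)
        g.add_edges_from(self.edges)
        return g
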