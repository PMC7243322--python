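"""Readers and writers for the standard formats the pipeline touches.

VCF 4.x is the canonical interchange format for haplotype panels (phased GT,
ancestral allele in INFO/AA).  Genetic maps are 4-column TSV
(chrom, id, cM, bp), gene bodies are BED (0-based half-open, name in
column 4), and pathways are GMT gene sets plus a TSV edge list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from cyvcf2 import VCF
import pysam

from .panel import (
    ANC_ALT,
    ANC_REF,
    ANC_UNKNOWN,
    MISSING,
    GeneAnnotation,
    GeneticMap,
    HaplotypePanel,
    PathwayGraph,
    is_autosome,
)

log = logging.getLogger(__name__)

_NUCS = {"A", "C", "G", "T"}


@dataclass
class VcfReadReport:
    """Bookkeeping for records skipped while reading a VCF."""

    n_kept: int = 0
    n_non_autosomal: int = 0
    n_non_biallelic_snv: int = 0
    n_unphased_tolerated: int = 0


def read_pop_map(path: str) -> dict[str, str]:
    """Read a two-column TSV of (sample_id, population label)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"pop map line has <2 columns: {line!r}")
            out[fields[0]] = fields[1]
    return out


def read_vcf(
    path: str,
    pop_map: str | dict[str, str],
    allow_unphased: bool = False,
) -> tuple[HaplotypePanel, VcfReadReport]:
    """Read phased biallelic SNVs from a VCF into a :class:`HaplotypePanel`.

    Non-autosomal records are dropped (autosome restriction), non-biallelic
    or non-SNV records are skipped with a logged count.  The ancestral
    allele is taken from INFO/AA when present and matching ref or alt;
    otherwise the site is left unpolarized.

    Parameters
    ----------
    pop_map : path to a (sample, population) TSV, or an in-memory dict.
    allow_unphased : treat "/" genotypes as phased, with a logged warning.
    """
    pops = read_pop_map(pop_map) if isinstance(pop_map, str) else dict(pop_map)
    vcf = VCF(path, gts012=False)
    samples = list(vcf.samples)
    for s in samples:
        if s not in pops:
            raise ValueError(f"sample {s!r} missing from population map")
    report = VcfReadReport()

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    ancs: list[int] = []
    cols: list[np.ndarray] = []

    n = len(samples)
    for var in vcf:
        if not is_autosome(var.CHROM):
            report.n_non_autosomal += 1
            continue
        if (
            len(var.ALT) != 1
            or var.REF not in _NUCS
            or var.ALT[0] not in _NUCS
        ):
            report.n_non_biallelic_snv += 1
            continue
        gts = var.genotypes  # [a0, a1, phased] per sample
        col = np.empty(2 * n, dtype=np.int8)
        for k, gt in enumerate(gts):
            a0, a1, phased = gt[0], gt[1], gt[-1]
            if not phased and a0 >= 0 and a1 >= 0:
                if not allow_unphased:
                    raise ValueError(
                        f"unphased genotype for sample {samples[k]} at "
                        f"{var.CHROM}:{var.POS}; pass allow_unphased=True to accept"
                    )
                report.n_unphased_tolerated += 1
            col[2 * k] = a0 if a0 >= 0 else MISSING
            col[2 * k + 1] = a1 if a1 >= 0 else MISSING
        aa = var.INFO.get("AA")
        if aa is not None:
            aa = str(aa).upper()
        if aa == var.REF:
            anc = ANC_REF
        elif aa == var.ALT[0]:
            anc = ANC_ALT
        else:
            anc = ANC_UNKNOWN
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        ancs.append(anc)
        cols.append(col)
        report.n_kept += 1

    if report.n_non_autosomal or report.n_non_biallelic_snv:
        log.info(
            "read_vcf(%s): dropped %d non-autosomal and %d non-biallelic-SNV records",
            path,
            report.n_non_autosomal,
            report.n_non_biallelic_snv,
        )
    if report.n_unphased_tolerated:
        log.warning(
            "read_vcf(%s): treated %d unphased genotypes as phased",
            path,
            report.n_unphased_tolerated,
        )

    H = (
        np.stack(cols, axis=1)
        if cols
        else np.empty((2 * n, 0), dtype=np.int8)
    )
    panel = HaplotypePanel(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref_allele=np.array(refs, dtype=object),
        alt_allele=np.array(alts, dtype=object),
        H=H,
        sample_ids=samples,
        pop_labels=[pops[s] for s in samples],
        ancestral=np.array(ancs, dtype=np.int8),
    )
    panel.validate()
    return panel, report


def write_vcf(panel: HaplotypePanel, path: str) -> str:
    """Write a panel as an uncompressed VCF (phased GT, INFO/AA).

    Round trip: ``read_vcf(write_vcf(p))`` reproduces H, pos, alleles and
    ancestral annotation exactly.  Missing alleles are written as ".".
    """
    header = pysam.VariantHeader()
    header.add_meta(
        "INFO",
        items=[
            ("ID", "AA"),
            ("Number", "1"),
            ("Type", "String"),
            ("Description", "Ancestral allele"),
        ],
    )
    header.add_meta(
        "FORMAT",
        items=[
            ("ID", "GT"),
            ("Number", "1"),
            ("Type", "String"),
            ("Description", "Genotype"),
        ],
    )
    chrom_order: list[str] = []
    for c in panel.chrom.astype(str):
        if c not in chrom_order:
            chrom_order.append(c)
    for c in chrom_order or ["1"]:
        length = int(panel.pos[panel.chrom == c].max()) + 1 if len(panel.pos) else 2
        header.contigs.add(c, length=length)
    for s in panel.sample_ids:
        header.add_sample(s)

    with pysam.VariantFile(path, "w", header=header) as out:
        for j in range(panel.n_sites):
            rec = out.new_record(
                contig=str(panel.chrom[j]),
                start=int(panel.pos[j]) - 1,
                stop=int(panel.pos[j]),
                alleles=(str(panel.ref_allele[j]), str(panel.alt_allele[j])),
            )
            if panel.ancestral[j] == ANC_REF:
                rec.info["AA"] = str(panel.ref_allele[j])
            elif panel.ancestral[j] == ANC_ALT:
                rec.info["AA"] = str(panel.alt_allele[j])
            for k, s in enumerate(panel.sample_ids):
                a = panel.H[2 * k, j]
                b = panel.H[2 * k + 1, j]
                rec.samples[s]["GT"] = (
                    None if a == MISSING else int(a),
                    None if b == MISSING else int(b),
                )
                rec.samples[s].phased = True
            out.write(rec)
    return path


# -- genetic map --------------------------------------------------------------

def read_genetic_map(path: str) -> GeneticMap:
    """Read a 4-column TSV genetic map: chrom, id, cM, bp."""
    anchors: dict[str, tuple[list[float], list[float]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 columns")
            chrom, _mid, cm, bp = f[0], f[1], float(f[2]), float(f[3])
            anchors.setdefault(chrom, ([], []))
            anchors[chrom][0].append(bp)
            anchors[chrom][1].append(cm)
    return GeneticMap(
        {c: (np.asarray(bp), np.asarray(cm)) for c, (bp, cm) in anchors.items()}
    )


def write_genetic_map(gmap: GeneticMap, path: str) -> str:
    with open(path, "w") as fh:
        for c, (bp, cm) in gmap.anchors.items():
            for i, (b, m) in enumerate(zip(bp, cm)):
                fh.write(f"{c}\t{c}_{i}\t{m:.10g}\t{b:.10g}\n")
    return path


# -- genes (BED) --------------------------------------------------------------

def read_genes_bed(path: str) -> list[GeneAnnotation]:
    """Read BED3+ with the gene name in column 4; coordinates kept 0-based
    half-open as given.  Duplicate gene names or start >= end are errors."""
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 4:
                raise ValueError(f"{path}:{ln}: BED line needs >= 4 columns")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            if start >= end:
                raise ValueError(f"{path}:{ln}: start {start} >= end {end}")
            if name in seen:
                raise ValueError(f"{path}:{ln}: duplicate gene name {name!r}")
            seen.add(name)
            genes.append(GeneAnnotation(name, chrom, start, end))
    return genes


def write_genes_bed(genes: list[GeneAnnotation], path: str) -> str:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\n")
    return path


# -- pathways (GMT + edge TSV) ------------------------------------------------

def read_pathways(gmt_path: str, edges_path: str) -> list[PathwayGraph]:
    """Read pathway definitions: a GMT file (pathway, description, genes...)
    and a TSV edge list (pathway, gene_a, gene_b).

    Every edge endpoint must belong to its pathway's GMT gene set; member
    genes without edges are retained as isolates.
    """
    members: dict[str, list[str]] = {}
    with open(gmt_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"GMT row for {f[0]!r} lists no genes")
            members[f[0]] = f[2:]
    edges: dict[str, list[tuple[str, str]]] = {p: [] for p in members}
    with open(edges_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{edges_path}:{ln}: expected 3 columns")
            pid, a, b = f[0], f[1], f[2]
            if pid not in members:
                raise ValueError(f"{edges_path}:{ln}: unknown pathway {pid!r}")
            for g in (a, b):
                if g not in members[pid]:
                    raise ValueError(
                        f"pathway {pid}: edge gene {g} is not a GMT member"
                    )
            edges[pid].append((a, b))
    return [PathwayGraph(pid, members[pid], edges[pid]) for pid in members]


def write_pathways(
    pathways: list[PathwayGraph], gmt_path: str, edges_path: str
) -> tuple[str, str]:
    with open(gmt_path, "w") as gf, open(edges_path, "w") as ef:
        for p in pathways:
            gf.write("\t".join([p.pathway_id, "na", *p.genes]) + "\n")
            for a, b in p.edges:
                ef.write(f"{p.pathway_id}\t{a}\t{b}\n")
    return gmt_path, edges_path
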