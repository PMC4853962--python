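"""Genotype / annotation / phenotype I/O, marker filtering, and GO SNP-set construction.

The central container is :class:`GenotypeMatrix`: an inbred-line panel coded as
minor-allele counts (0/1/2; fully inbred lines carry only 0 and 2).  Markers are
kept in genome order (a fixed chromosome-arm order, then position) because the
circular-rotation permutation test downstream relies on physical ordering.

SNP-sets are built by annotating markers to genes within a +/- 5 kb window and
grouping genes by GO term; sets are retained only if they contain more than ten
genes and at least 200 markers.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Default concatenation order of Drosophila chromosome arms.  Any fixed order
#: is valid for the rotation test; this one is used throughout the package.
CHROM_ORDER: tuple[str, ...] = ("2L", "2R", "3L", "3R", "X", "4")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Lines x markers minor-allele-count matrix with genomic coordinates.

    Attributes
    ----------
    line_ids : list of str
        Row labels (one inbred line per row).
    marker_ids : ndarray of str
        Column labels, genome ordered.
    chrom, pos : ndarray
        Per-marker chromosome arm and 1-based position.
    A : ndarray, shape (n_lines, n_markers)
        Allele counts in {0, 1, 2}, counting the minor allele.
    """

    line_ids: list[str]
    marker_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    A: np.ndarray
    chrom_order: tuple[str, ...] = CHROM_ORDER

    @property
    def n_lines(self) -> int:
        return self.A.shape[0]

    @property
    def n_markers(self) -> int:
        return self.A.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Per-marker minor allele frequency in the current line sample."""
        f = self.A.mean(axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    def _chrom_rank(self) -> np.ndarray:
        order = {c: i for i, c in enumerate(self.chrom_order)}
        extras = sorted(set(map(str, self.chrom)) - set(self.chrom_order))
        order.update({c: len(self.chrom_order) + i for i, c in enumerate(extras)})
        return np.array([order[str(c)] for c in self.chrom])

    def genome_sorted(self) -> "GenotypeMatrix":
        """Return a copy with markers sorted by (chromosome order, position)."""
        key = np.lexsort((self.pos, self._chrom_rank()))
        if np.array_equal(key, np.arange(self.n_markers)):
            return self
        log.info("genotypes were not genome sorted; sorting %d markers", self.n_markers)
        return replace(
            self,
            marker_ids=self.marker_ids[key],
            chrom=self.chrom[key],
            pos=self.pos[key],
            A=self.A[:, key],
        )

    def subset_lines(self, keep: Sequence[str]) -> "GenotypeMatrix":
        """Restrict to a subset of lines (MAF is always recomputed lazily)."""
        idx = [self.line_ids.index(l) for l in keep]
        return replace(self, line_ids=list(keep), A=self.A[idx])

    def orient_minor(self) -> "GenotypeMatrix":
        """Flip allele coding of columns whose coded-allele frequency exceeds 0.5."""
        f = self.A.mean(axis=0) / 2.0
        flip = f > 0.5
        if flip.any():
            A = self.A.copy()
            A[:, flip] = 2 - A[:, flip]
            log.info("re-oriented %d markers to minor-allele coding", int(flip.sum()))
            return replace(self, A=A)
        return self


@dataclass(frozen=True)
class SNPSet:
    """One GO term's SNP-set: member genes and the union of their markers."""

    go_id: str
    go_class: str
    genes: tuple[str, ...]
    markers: np.ndarray  # unique, genome-ordered column indices into A

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_markers(self) -> int:
        return len(self.markers)


@dataclass
class SNPSetCatalog:
    """GO id -> SNPSet mapping plus a record of the filters that produced it."""

    sets: dict[str, SNPSet]
    filters: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, go_id: str) -> SNPSet:
        return self.sets[go_id]

    def by_class(self, go_class: str) -> "SNPSetCatalog":
        sub = {k: v for k, v in self.sets.items() if v.go_class == go_class}
        return SNPSetCatalog(sub, dict(self.filters))

    def classes(self) -> list[str]:
        return sorted({s.go_class for s in self})


# ---------------------------------------------------------------------------
# genotype readers / writers
# ---------------------------------------------------------------------------

def load_genotypes(path: str | Path, fmt: str | None = None,
                   marker_map: str | Path | None = None) -> GenotypeMatrix:
    """Load genotypes from VCF or TSV, re-orient to minor allele, genome-sort.

    Parameters
    ----------
    path : file path.  ``fmt`` is inferred from the suffix when omitted
        (``.vcf``/``.vcf.gz`` -> VCF, else TSV).
    marker_map : sidecar TSV (marker_id, chrom, pos) required for the TSV format.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if ".vcf" in path.suffixes or path.suffix == ".vcf" else "tsv"
    if fmt == "vcf":
        g = _load_vcf(path)
    elif fmt == "tsv":
        if marker_map is None:
            raise ValueError("TSV genotypes require a marker_map sidecar file")
        g = _load_tsv(path, marker_map)
    else:
        raise ValueError(f"unknown genotype format: {fmt!r}")
    return g.orient_minor().genome_sorted()


def _load_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, poss, ids, cols = [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            log.warning("skipping multiallelic record %s:%d", var.CHROM, var.POS)
            continue
        counts = np.array([a + b for a, b, *_ in var.genotypes], dtype=float)
        if (counts < 0).any():
            raise ValueError(f"missing genotype call at {var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        cols.append(counts)
    if n_skipped:
        log.warning("skipped %d multiallelic records", n_skipped)
    if not cols:
        raise ValueError(f"no biallelic records found in {path}")
    A = np.column_stack(cols)
    return GenotypeMatrix(samples, np.array(ids, dtype=object),
                          np.array(chroms, dtype=object),
                          np.array(poss, dtype=np.int64), A)


def _load_tsv(path: Path, marker_map: str | Path) -> GenotypeMatrix:
    mat = pd.read_csv(path, sep="\t", index_col=0)
    mm = pd.read_csv(marker_map, sep="\t", dtype={"chrom": str})
    mm = mm.set_index("marker_id").loc[mat.columns]
    return GenotypeMatrix(
        list(mat.index.astype(str)),
        np.array(mat.columns, dtype=object),
        mm["chrom"].to_numpy(dtype=object),
        mm["pos"].to_numpy(dtype=np.int64),
        mat.to_numpy(dtype=float),
    )


def write_genotypes_tsv(g: GenotypeMatrix, path: str | Path,
                        marker_map: str | Path) -> None:
    """Write a lines x markers TSV plus the (marker_id, chrom, pos) sidecar."""
    df = pd.DataFrame(g.A, index=pd.Index(g.line_ids, name="line_id"),
                      columns=g.marker_ids)
    df.to_csv(path, sep="\t")
    pd.DataFrame({"marker_id": g.marker_ids, "chrom": g.chrom, "pos": g.pos}
                 ).to_csv(marker_map, sep="\t", index=False)


_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal GT-only VCF; the ALT allele is the coded (minor) allele."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=pathblup\n")
        for c in dict.fromkeys(map(str, g.chrom)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.line_ids) + "\n")
        for j in range(g.n_markers):
            gts = "\t".join(_GT[int(round(g.A[i, j]))] for i in range(g.n_lines))
            fh.write(f"{g.chrom[j]}\t{g.pos[j]}\t{g.marker_ids[j]}\tA\tT\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# marker filtering
# ---------------------------------------------------------------------------

def filter_markers(g: GenotypeMatrix, maf_min: float = 0.05) -> GenotypeMatrix:
    """Drop monomorphic markers and markers with MAF <= ``maf_min``.

    Monomorphic columns (zero variance in the current line sample) are always
    removed; they arise naturally when analysing a subset of a larger panel.
    Markers are kept only if their sample MAF is strictly greater than
    ``maf_min``.  Filtering is idempotent.
    """
    mono = np.ptp(g.A, axis=0) == 0
    p = g.maf
    keep = (~mono) & (p > maf_min)
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("filter_markers: removed %d of %d markers (%d monomorphic, maf_min=%g)",
                 n_drop, g.n_markers, int(mono.sum()), maf_min)
    if not keep.any():
        raise ValueError("all markers removed by filtering")
    return replace(g, marker_ids=g.marker_ids[keep], chrom=g.chrom[keep],
                   pos=g.pos[keep], A=g.A[:, keep])


# ---------------------------------------------------------------------------
# gene / GO annotation
# ---------------------------------------------------------------------------

def load_genes_bed(path: str | Path) -> pd.DataFrame:
    """Read genes from BED (0-based half-open) into 1-based inclusive coordinates."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "gene_id"],
                     usecols=[0, 1, 2, 3], dtype={0: str})
    out = pd.DataFrame({"gene_id": df["gene_id"].astype(str), "chrom": df["chrom"],
                        "start": df["start"].astype(int) + 1,
                        "end": df["end"].astype(int)})
    _check_gene_table(out)
    return out


def load_genes_gff3(path: str | Path, feature: str = "gene") -> pd.DataFrame:
    """Read gene intervals from GFF3 (already 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "source", "type", "start", "end",
                            "score", "strand", "phase", "attributes"],
                     dtype={0: str})
    df = df[df["type"] == feature]
    ids = df["attributes"].str.extract(r"ID=([^;]+)")[0]
    out = pd.DataFrame({"gene_id": ids.astype(str), "chrom": df["chrom"],
                        "start": df["start"].astype(int),
                        "end": df["end"].astype(int)}).reset_index(drop=True)
    _check_gene_table(out)
    return out


def write_genes_bed(genes: pd.DataFrame, path: str | Path) -> None:
    pd.DataFrame({"chrom": genes["chrom"], "start": genes["start"] - 1,
                  "end": genes["end"], "gene_id": genes["gene_id"]}
                 ).to_csv(path, sep="\t", header=False, index=False)


def _check_gene_table(genes: pd.DataFrame) -> None:
    if (genes["start"] > genes["end"]).any():
        bad = genes.loc[genes["start"] > genes["end"], "gene_id"].tolist()
        raise ValueError(f"gene intervals with start > end: {bad}")
    if genes["gene_id"].duplicated().any():
        dup = genes.loc[genes["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids: {dup}")


def load_go_table(path: str | Path) -> pd.DataFrame:
    """Read the 3-column gene->GO membership TSV (gene_id, go_id, go_class)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "go_id", "go_class"}
    if not required.issubset(df.columns):
        raise ValueError(f"GO table must have columns {sorted(required)}")
    return df


def load_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"line_id": str})


# ---------------------------------------------------------------------------
# SNP -> gene -> GO set construction
# ---------------------------------------------------------------------------

def map_snps_to_genes(g: GenotypeMatrix, genes: pd.DataFrame,
                      window_bp: int = 5000) -> dict[str, np.ndarray]:
    """Assign markers to genes within ``window_bp`` of the gene span (inclusive).

    A marker is assigned to a gene iff
    ``gene.start - window_bp <= pos <= gene.end + window_bp``; a marker inside
    two overlapping windows is assigned to both genes.  Returns
    ``gene_id -> genome-ordered marker column indices`` (possibly empty).
    """
    missing = sorted(set(genes["chrom"].astype(str)) - set(map(str, g.chrom)))
    if missing:
        raise ValueError(
            f"gene chromosomes absent from genotype data: {missing}")
    out: dict[str, np.ndarray] = {}
    idx_all = np.arange(g.n_markers)
    for chrom, sub in genes.groupby("chrom", sort=False):
        on = np.asarray(g.chrom) == chrom
        pos = g.pos[on]
        gidx = idx_all[on]
        order = np.argsort(pos, kind="stable")
        pos, gidx = pos[order], gidx[order]
        lo = np.searchsorted(pos, sub["start"].to_numpy() - window_bp, side="left")
        hi = np.searchsorted(pos, sub["end"].to_numpy() + window_bp, side="right")
        for gene_id, a, b in zip(sub["gene_id"], lo, hi):
            out[str(gene_id)] = np.sort(gidx[a:b])
    return out


def build_snpsets(gene_map: Mapping[str, np.ndarray], go_table: pd.DataFrame,
                  min_genes: int = 11, min_markers: int = 200) -> SNPSetCatalog:
    """Group genes by GO term and take the union of member-gene markers.

    A marker mapping to several member genes is counted once.  Sets are
    retained only if they have at least ``min_genes`` member genes (i.e. more
    than ten under the default) and at least ``min_markers`` unique markers.
    GO rows referencing genes absent from ``gene_map`` are ignored with a log
    message.  Raises if no set survives.
    """
    unknown = sorted(set(go_table["gene_id"]) - set(gene_map))
    if unknown:
        log.warning("build_snpsets: ignoring %d unknown gene ids (e.g. %s)",
                    len(unknown), unknown[:5])
    sets: dict[str, SNPSet] = {}
    dropped = {"genes": 0, "markers": 0}
    for go_id in sorted(go_table["go_id"].unique()):
        rows = go_table[go_table["go_id"] == go_id]
        go_class = str(rows["go_class"].iloc[0])
        members = tuple(sorted(set(rows["gene_id"]) & set(gene_map)))
        if len(members) < min_genes:
            dropped["genes"] += 1
            log.debug("dropping %s: %d genes < %d", go_id, len(members), min_genes)
            continue
        markers = np.unique(np.concatenate(
            [gene_map[m] for m in members] or [np.array([], dtype=int)]))
        if len(markers) < min_markers:
            dropped["markers"] += 1
            log.debug("dropping %s: %d markers < %d", go_id, len(markers), min_markers)
            continue
        sets[go_id] = SNPSet(go_id, go_class, members, markers.astype(int))
    if not sets:
        raise ValueError("no SNP-set survived the gene/marker thresholds")
    per_class = pd.Series([s.go_class for s in sets.values()]).value_counts().to_dict()
    log.info("build_snpsets: kept %d sets %s; dropped %d (gene count), %d (marker count)",
             len(sets), per_class, dropped["genes"], dropped["markers"])
    return SNPSetCatalog(sets, {"min_genes": min_genes, "min_markers": min_markers,
                                "dropped": dropped, "per_class": per_class})
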