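"""Gene annotation loading and SNP-to-gene cascade mapping.

Mapping is a two-stage cascade: a SNP inside an annotated coding (CDS)
interval maps directly to that gene ("coding_direct", distance 0); any
other SNP maps to the nearest gene whose strand-aware window -- 2 kb
upstream of the transcription start through 0.5 kb downstream of the
gene end -- contains it ("proximal", with the bp distance to the gene
span; 0 when the SNP lies inside the span, e.g. an intron).  Ties at
equal distance return every tied gene.  The 10 kb gene-window selector
used for seeded analyses is strand-agnostic on both sides.

Coordinates are 1-based inclusive internally; BED input is converted
from 0-based half-open at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

UPSTREAM_BP = 2000
DOWNSTREAM_BP = 500


@dataclass(frozen=True)
class GeneModel:
    """A gene interval with strand and coding sub-intervals (1-based inclusive)."""

    gene_id: str
    name: str
    chromosome: str
    strand: str
    start: int
    end: int
    coding_intervals: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.start > self.end or self.start < 1:
            raise ValidationError(f"gene {self.gene_id}: bad span [{self.start}, {self.end}]")
        for lo, hi in self.coding_intervals:
            if not (self.start <= lo <= hi <= self.end):
                raise ValidationError(
                    f"gene {self.gene_id}: coding interval [{lo}, {hi}] outside span"
                )

    def contains_coding(self, pos: int) -> bool:
        return any(lo <= pos <= hi for lo, hi in self.coding_intervals)

    def span_distance(self, pos: int) -> int:
        """bp distance from a position to the gene span (0 inside)."""
        if pos < self.start:
            return self.start - pos
        if pos > self.end:
            return pos - self.end
        return 0

    def proximal_window(self, upstream: int = UPSTREAM_BP, downstream: int = DOWNSTREAM_BP) -> tuple[int, int]:
        """Strand-aware promoter-to-tail window [lo, hi] including the gene body."""
        if self.strand == "+":
            return (self.start - upstream, self.end + downstream)
        return (self.start - downstream, self.end + upstream)


@dataclass(frozen=True)
class MappingResult:
    snp_id: str
    genes: tuple[tuple[str, str, int], ...]  # (gene_id, class, distance)


def load_annotation(path: str | Path, format: str = "gff3") -> list[GeneModel]:
    """Read gene models from GFF3 (with CDS children) or BED.

    For BED, 12-column entries use the block fields as coding intervals;
    entries with fewer columns treat the whole span as coding.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "gff3":
        return _load_gff3(path)
    if format == "bed":
        return _load_bed(path)
    raise ValueError(f"unknown annotation format {format!r}")


def _load_gff3(path: Path) -> list[GeneModel]:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:
        raise FormatError(f"cannot parse GFF3 {path}: {exc}") from exc
    genes = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        coding = tuple(
            sorted(
                (cds.start, cds.end)
                for cds in db.children(gene, featuretype="CDS", order_by="start")
            )
        )
        name = gene.attributes.get("Name", [gene.id])[0]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                name=name,
                chromosome=gene.seqid,
                strand=gene.strand,
                start=gene.start,
                end=gene.end,
                coding_intervals=coding,
            )
        )
    return genes


def _load_bed(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: BED needs >= 6 columns for strand")
            try:
                chrom = parts[0]
                start = int(parts[1]) + 1  # 0-based half-open -> 1-based inclusive
                end = int(parts[2])
                name = parts[3]
                strand = parts[5]
                if len(parts) >= 12:
                    n_blocks = int(parts[9])
                    sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                    starts = [int(x) for x in parts[11].rstrip(",").split(",")]
                    if len(sizes) != n_blocks or len(starts) != n_blocks:
                        raise ValueError("block count mismatch")
                    coding = tuple(
                        (start + off, start + off + size - 1)
                        for off, size in zip(starts, sizes)
                    )
                else:
                    coding = ((start, end),)
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed BED record: {exc}") from exc
            genes.append(
                GeneModel(
                    gene_id=name,
                    name=name,
                    chromosome=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    coding_intervals=coding,
                )
            )
    return genes


def write_bed(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models as 12-column BED (coding intervals as blocks)."""
    with open(path, "w") as fh:
        for g in genes:
            blocks = g.coding_intervals or ((g.start, g.end),)
            sizes = ",".join(str(hi - lo + 1) for lo, hi in blocks)
            starts = ",".join(str(lo - g.start) for lo, _ in blocks)
            fh.write(
                f"{g.chromosome}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start - 1}\t{g.end}\t0\t{len(blocks)}\t{sizes}\t{starts}\n"
            )


def cascade_map(
    chromosome: str,
    position: int,
    genes: list[GeneModel],
    snp_id: str = "",
    upstream: int = UPSTREAM_BP,
    downstream: int = DOWNSTREAM_BP,
) -> MappingResult:
    """Map one SNP position to gene(s) by the coding-then-proximal cascade."""
    if position < 1:
        raise ValidationError("SNP position must be 1-based positive")
    on_chrom = [g for g in genes if g.chromosome == chromosome]
    if not on_chrom:
        logger.warning("SNP %s: chromosome %s absent from annotation", snp_id or position, chromosome)
        return MappingResult(snp_id, ())
    coding_hits = tuple(
        (g.gene_id, "coding_direct", 0)
        for g in on_chrom
        if g.contains_coding(position)
    )
    if coding_hits:
        return MappingResult(snp_id, coding_hits)
    in_window = []
    for g in on_chrom:
        lo, hi = g.proximal_window(upstream, downstream)
        if lo <= position <= hi:
            in_window.append((g.span_distance(position), g.gene_id))
    if not in_window:
        return MappingResult(snp_id, ())
    best = min(d for d, _ in in_window)
    hits = tuple(
        (gid, "proximal", d) for d, gid in sorted(in_window) if d == best
    )
    return MappingResult(snp_id, hits)


def map_snps(matrix_snp_map: pd.DataFrame, genes: list[GeneModel]) -> list[MappingResult]:
    """Cascade-map every SNP of a matrix's snp_map."""
    return [
        cascade_map(str(rec["chrom"]), int(rec["pos"]), genes, snp_id=str(snp_id))
        for snp_id, rec in matrix_snp_map.iterrows()
    ]


def snps_near_genes(
    matrix_snp_map: pd.DataFrame, genes: list[GeneModel], window_bp: int = 10_000
) -> list[str]:
    """SNP ids within ``window_bp`` of any gene span, both sides, strand-agnostic.

    Boundaries are inclusive (a SNP exactly ``window_bp`` beyond a span end
    is selected).  The result is deduplicated and keeps snp_map order.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    chroms = matrix_snp_map["chrom"].astype(str).to_numpy()
    pos = matrix_snp_map["pos"].to_numpy()
    selected = np.zeros(len(matrix_snp_map), dtype=bool)
    for g in genes:
        selected |= (
            (chroms == g.chromosome)
            & (pos >= g.start - window_bp)
            & (pos <= g.end + window_bp)
        )
    return [str(s) for s in matrix_snp_map.index[selected]]


def write_mapping(results: list[MappingResult], path) -> None:
    rows = [
        {"snp_id": r.snp_id, "gene_id": gid, "class": cls, "distance": dist}
        for r in results
        for gid, cls, dist in r.genes
    ]
    pd.DataFrame(rows, columns=["snp_id", "gene_id", "class", "distance"]).to_csv(
        path, sep="\t", index=False
    )
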