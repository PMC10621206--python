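"""Genotype matrices: loading, validation, QC and linkage checks.

The central container is :class:`GenotypeMatrix`, a dense samples x SNPs
matrix of genotype *states*.  A state is the number of copies of the minor
allele an individual carries at a SNP: 0 (homozygous major / wild type),
1 (heterozygous) or 2 (homozygous minor).  Missing genotypes are encoded
with the sentinel :data:`MISSING` (-1) and are never imputed; every
downstream analysis defines its own exclusion rule for them.

The minor allele is determined empirically from the loaded cohort.  When
the alternate-allele frequency is exactly 0.5 the alternate allele is kept
as the minor allele so that the orientation is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyResultError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Sentinel state for a missing genotype call.
MISSING: int = -1

_VALID_STATES = frozenset({0, 1, 2, MISSING})

#: Columns of the per-SNP map carried by every :class:`GenotypeMatrix`.
SNP_MAP_COLUMNS = ("chrom", "pos", "ref", "alt", "minor_is_alt")


@dataclass
class GenotypeMatrix:
    """Dense samples x SNPs genotype state matrix with a per-SNP map.

    Parameters
    ----------
    sample_ids:
        Ordered, unique sample identifiers (rows of ``states``).
    snp_ids:
        Ordered, unique SNP identifiers (columns of ``states``).
    states:
        ``int8`` array of shape ``(n_samples, n_snps)`` with values in
        ``{0, 1, 2, MISSING}``; the integer is the minor-allele count.
    snp_map:
        DataFrame indexed by SNP id with columns ``chrom``, ``pos``
        (1-based bp), ``ref``, ``alt`` and ``minor_is_alt``.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    states: np.ndarray
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        self.validate()
        self._snp_pos = {s: i for i, s in enumerate(self.snp_ids)}

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check structural invariants; raise :class:`ValidationError` on failure."""
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValidationError("duplicate SNP ids")
        if self.states.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValidationError(
                f"states shape {self.states.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        bad = set(np.unique(self.states)) - _VALID_STATES
        if bad:
            raise ValidationError(f"invalid genotype states {sorted(bad)}")
        if list(self.snp_map.index) != list(self.snp_ids):
            raise ValidationError("snp_map index does not match snp_ids")
        missing_cols = set(SNP_MAP_COLUMNS) - set(self.snp_map.columns)
        if missing_cols:
            raise ValidationError(f"snp_map missing columns {sorted(missing_cols)}")
        if (self.snp_map["pos"] <= 0).any():
            raise ValidationError("SNP positions must be positive 1-based integers")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_index(self, snp_id: str) -> int:
        try:
            return self._snp_pos[snp_id]
        except KeyError:
            raise KeyError(f"unknown SNP id {snp_id!r}") from None

    def column(self, snp_id: str) -> np.ndarray:
        """State vector (over all samples) for one SNP."""
        return self.states[:, self.snp_index(snp_id)]

    def subset(
        self,
        samples: list[str] | np.ndarray | None = None,
        snps: list[str] | np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given samples/SNPs (order kept)."""
        sample_ids = list(self.sample_ids)
        snp_ids = list(self.snp_ids)
        states = self.states
        if samples is not None:
            idx = [self.sample_ids.index(s) if isinstance(s, str) else int(s) for s in samples]
            sample_ids = [self.sample_ids[i] for i in idx]
            states = states[idx, :]
        if snps is not None:
            jdx = [self._snp_pos[s] if isinstance(s, str) else int(s) for s in snps]
            snp_ids = [self.snp_ids[j] for j in jdx]
            states = states[:, jdx]
        return GenotypeMatrix(sample_ids, snp_ids, states.copy(), self.snp_map.loc[snp_ids])

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.snp_ids == other.snp_ids
            and np.array_equal(self.states, other.states)
            and self.snp_map[list(SNP_MAP_COLUMNS)].equals(other.snp_map[list(SNP_MAP_COLUMNS)])
        )


def _placeholder_map(snp_ids: list[str]) -> pd.DataFrame:
    """Synthesize a minimal SNP map when a table comes without one."""
    return pd.DataFrame(
        {
            "chrom": ["un"] * len(snp_ids),
            "pos": np.arange(1, len(snp_ids) + 1, dtype=np.int64),
            "ref": ["A"] * len(snp_ids),
            "alt": ["B"] * len(snp_ids),
            "minor_is_alt": [True] * len(snp_ids),
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )


# ----------------------------------------------------------------------
# Loading / writing
# ----------------------------------------------------------------------

def load_genotypes(path: str | Path, format: str = "table", map_path: str | Path | None = None) -> GenotypeMatrix:
    """Load a genotype matrix from a VCF or a tab-separated table.

    ``format='table'`` expects a TSV with a header row of SNP ids, a first
    column of sample ids and cell values in {0, 1, 2, NA}.  An optional
    ``map_path`` TSV (columns snp_id, chrom, pos, ref, alt[, minor_is_alt])
    supplies coordinates; without it a placeholder map is synthesized.

    ``format='vcf'`` reads GT fields from a VCF 4.x file (phase ignored);
    multi-allelic records are skipped with a warning.  States are oriented
    to count the empirically minor allele.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "table":
        return _load_table(path, map_path)
    if format == "vcf":
        return _load_vcf(path)
    raise ValueError(f"unknown format {format!r}")


def _load_table(path: Path, map_path: str | Path | None) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse genotype table {path}: {exc}") from exc
    snp_ids = [str(c) for c in df.columns]
    sample_ids = [str(s) for s in df.index]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError(f"duplicate sample ids in {path}")
    if len(set(snp_ids)) != len(snp_ids):
        raise ValidationError(f"duplicate SNP ids in {path}")
    states = np.full(df.shape, MISSING, dtype=np.int8)
    arr = df.to_numpy()
    for val, code in (("0", 0), ("1", 1), ("2", 2)):
        states[arr == val] = code
    unexpected = ~np.isin(arr, ["0", "1", "2", "NA"]) & ~pd.isna(arr)
    if unexpected.any():
        i, j = np.argwhere(unexpected)[0]
        raise FormatError(
            f"unparseable genotype {arr[i, j]!r} at line {i + 2}, column {snp_ids[j]} of {path}"
        )
    if map_path is None:
        default = path.with_name(path.name + ".map")
        map_path = default if default.exists() else None
    if map_path is not None:
        snp_map = pd.read_csv(map_path, sep="\t", index_col=0)
        snp_map.index = snp_map.index.astype(str)
        snp_map["chrom"] = snp_map["chrom"].astype(str)
        snp_map["pos"] = snp_map["pos"].astype(np.int64)
        if "minor_is_alt" not in snp_map.columns:
            snp_map["minor_is_alt"] = True
        snp_map = snp_map.loc[snp_ids]
    else:
        logger.warning("no SNP map for %s; synthesizing placeholder coordinates", path)
        snp_map = _placeholder_map(snp_ids)
    return GenotypeMatrix(sample_ids, snp_ids, states, snp_map)


def _load_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:
        raise FormatError(f"cannot open VCF {path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError(f"duplicate sample ids in {path}")
    snp_ids: list[str] = []
    rows = []
    columns: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping multi-allelic record %s:%s", var.CHROM, var.POS)
            continue
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        # gts012: 0/1/2 = alt-allele count, 3 = unknown
        alt_counts = np.asarray(var.gt_types, dtype=np.int8)
        alt_counts[alt_counts == 3] = MISSING
        snp_ids.append(snp_id)
        rows.append((var.CHROM, int(var.POS), var.REF, var.ALT[0]))
        columns.append(alt_counts)
    if len(set(snp_ids)) != len(snp_ids):
        raise ValidationError(f"duplicate SNP ids in {path}")
    states = np.column_stack(columns) if columns else np.empty((len(sample_ids), 0), dtype=np.int8)
    minor_is_alt = np.ones(len(snp_ids), dtype=bool)
    for j in range(states.shape[1]):
        col = states[:, j]
        ok = col != MISSING
        if ok.any():
            f_alt = col[ok].mean() / 2.0
            if f_alt > 0.5:  # ties keep alt as minor
                col[ok] = 2 - col[ok]
                minor_is_alt[j] = False
    snp_map = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt"], index=pd.Index(snp_ids, name="snp_id")
    )
    snp_map["minor_is_alt"] = minor_is_alt
    return GenotypeMatrix(sample_ids, snp_ids, states, snp_map)


def write_genotype_table(matrix: GenotypeMatrix, path: str | Path, map_path: str | Path | None = None) -> None:
    """Write the matrix as a TSV (samples as rows, ``NA`` for missing) plus a map file."""
    path = Path(path)
    df = pd.DataFrame(
        matrix.states.astype(object), index=matrix.sample_ids, columns=matrix.snp_ids
    )
    df[matrix.states == MISSING] = "NA"
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")
    if map_path is None:
        map_path = path.with_name(path.name + ".map")
    matrix.snp_map.to_csv(map_path, sep="\t", index_label="snp_id")


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 file with GT fields only."""
    path = Path(path)
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.sample_ids) + "\n")
        order = np.lexsort(
            (matrix.snp_map["pos"].to_numpy(), matrix.snp_map["chrom"].astype(str).to_numpy())
        )
        for j in order:
            rec = matrix.snp_map.iloc[j]
            col = matrix.states[:, j]
            # states count the minor allele; GT is written in ref/alt space
            alt_counts = col if rec["minor_is_alt"] else np.where(col == MISSING, MISSING, 2 - col)
            gts = "\t".join(gt_codes[int(c)] for c in alt_counts)
            fh.write(
                f"{rec['chrom']}\t{int(rec['pos'])}\t{matrix.snp_ids[j]}\t"
                f"{rec['ref']}\t{rec['alt']}\t.\t.\t.\tGT\t{gts}\n"
            )


# ----------------------------------------------------------------------
# QC
# ----------------------------------------------------------------------

def compute_maf(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP minor-allele frequency and call rate.

    MAF is computed over non-missing genotypes only:
    ``f = (het + 2 * hom_minor) / (2 * n_nonmissing)`` and ``maf = min(f, 1 - f)``.
    A SNP with no calls gets ``maf = NaN`` (never 0) and ``call_rate = 0``.
    """
    states = matrix.states
    nonmiss = states != MISSING
    n_called = nonmiss.sum(axis=0)
    counts = np.where(nonmiss, states, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = counts / (2.0 * n_called)
    maf = np.minimum(f, 1.0 - f)
    maf[n_called == 0] = np.nan
    call_rate = n_called / matrix.n_samples if matrix.n_samples else n_called * 0.0
    return pd.DataFrame(
        {"maf": maf, "call_rate": call_rate}, index=pd.Index(matrix.snp_ids, name="snp_id")
    )


def apply_qc(
    matrix: GenotypeMatrix,
    maf_min: float = 0.05,
    snp_call_min: float = 0.98,
    sample_call_min: float = 0.95,
) -> tuple[GenotypeMatrix, dict]:
    """Filter samples then SNPs; return the filtered matrix and a QC report.

    Samples with call rate below ``sample_call_min`` are removed first, then
    SNPs with ``maf < maf_min`` (a SNP at exactly the boundary is retained)
    or call rate below ``snp_call_min`` are removed, with MAF computed on the
    retained samples so every surviving SNP satisfies the MAF floor.
    """
    for name, value in (("maf_min", maf_min), ("snp_call_min", snp_call_min), ("sample_call_min", sample_call_min)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {value}")
    logger.info(
        "QC thresholds: maf_min=%s snp_call_min=%s sample_call_min=%s",
        maf_min, snp_call_min, sample_call_min,
    )
    nonmiss = matrix.states != MISSING
    sample_call = nonmiss.mean(axis=1) if matrix.n_snps else np.ones(matrix.n_samples)
    keep_samples = sample_call >= sample_call_min
    trimmed = matrix.subset(samples=np.flatnonzero(keep_samples)) if not keep_samples.all() else matrix

    qc = compute_maf(trimmed)
    maf_ok = (qc["maf"] >= maf_min).fillna(False).to_numpy()
    call_ok = (qc["call_rate"] >= snp_call_min).to_numpy()
    keep_snps = maf_ok & call_ok
    report = {
        "n_samples_in": matrix.n_samples,
        "n_snps_in": matrix.n_snps,
        "samples_removed_call_rate": int((~keep_samples).sum()),
        "snps_removed_maf": int((~maf_ok).sum()),
        "snps_removed_call_rate": int((maf_ok & ~call_ok).sum()),
        "n_samples_out": int(keep_samples.sum()),
        "n_snps_out": int(keep_snps.sum()),
        "thresholds": {
            "maf_min": maf_min,
            "snp_call_min": snp_call_min,
            "sample_call_min": sample_call_min,
        },
    }
    if report["n_snps_out"] == 0:
        raise EmptyResultError(
            "all SNPs removed by QC; review maf_min/snp_call_min thresholds"
        )
    if keep_snps.all() and keep_samples.all():
        return matrix, report
    out = trimmed.subset(snps=np.flatnonzero(keep_snps))
    logger.info("QC kept %d/%d samples and %d/%d SNPs",
                report["n_samples_out"], report["n_samples_in"],
                report["n_snps_out"], report["n_snps_in"])
    return out, report


def pairwise_r2(matrix: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation of two SNPs' state vectors.

    Computed over jointly non-missing samples; returns NaN when either
    vector has zero variance (the linkage statistic is then undefined).
    """
    a = matrix.column(snp_a).astype(float)
    b = matrix.column(snp_b).astype(float)
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        raise ValidationError("need at least 2 jointly non-missing samples for r^2")
    a, b = a[ok], b[ok]
    if a.std() == 0.0 or b.std() == 0.0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
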