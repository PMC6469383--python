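"""Genotype, phenotype and group-structure I/O plus per-SNP quality control.

Genotypes are biallelic dosages (count of the A1 allele, 0/1/2) held dense with
NaN marking missing calls.  Supported on-disk formats: PLINK v1 binary triples
(.bed/.bim/.fam, SNP-major 2-bit encoding) and a plain TSV dosage matrix
(header row = SNP ids, first column = sample ids, ``NA`` = missing).  Gene
group structure is either read from a two-column TSV or derived from a gene
annotation with a buffer region around each gene body.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeData",
    "PhenotypeVector",
    "GroupStructure",
    "QCReport",
    "read_genotypes",
    "write_genotypes",
    "read_phenotype",
    "read_groups",
    "write_groups",
    "qc_filter",
    "map_snps_to_genes",
    "read_gene_annotation",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # PLINK v1, SNP-major

# 2-bit PLINK codes -> dosage of A1: 00 hom A1, 01 missing, 10 het, 11 hom A2
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


@dataclass
class GenotypeData:
    """Dense dosage matrix with sample/SNP metadata.

    dosages : float array (m samples x p SNPs), values in {0, 1, 2} or NaN.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        m, p = self.dosages.shape
        if len(self.sample_ids) != m:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.snp_ids) != p or len(self.chrom) != p or len(self.pos) != p:
            raise ValueError("SNP metadata length does not match dosage columns")
        if len(set(self.snp_ids)) != p:
            raise ValueError("snp_ids must be unique")
        if p and self.pos.min() < 1:
            raise ValueError("positions are 1-based and must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def subset_snps(self, index: np.ndarray) -> "GenotypeData":
        index = np.asarray(index)
        return GenotypeData(
            self.dosages[:, index],
            self.sample_ids,
            [self.snp_ids[i] for i in np.atleast_1d(index)],
            self.chrom[index],
            self.pos[index],
        )

    def subset_samples(self, index: np.ndarray) -> "GenotypeData":
        index = np.asarray(index)
        return GenotypeData(
            self.dosages[index],
            [self.sample_ids[i] for i in index],
            self.snp_ids,
            self.chrom,
            self.pos,
        )


@dataclass
class PhenotypeVector:
    """Quantitative phenotype aligned to a genotype panel (no missing values)."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.sample_ids):
            raise ValueError("phenotype values must be a vector aligned to sample_ids")
        if np.isnan(self.values).any():
            raise ValueError("phenotype contains missing values after alignment")

    def align_to(self, genotypes: GenotypeData) -> tuple["PhenotypeVector", GenotypeData]:
        """Intersect samples with a genotype panel; drops (with a warning) the rest."""
        pheno_idx = {s: i for i, s in enumerate(self.sample_ids)}
        keep = [i for i, s in enumerate(genotypes.sample_ids) if s in pheno_idx]
        dropped_g = genotypes.n_samples - len(keep)
        dropped_p = len(self.sample_ids) - len(keep)
        if not keep:
            raise ValueError("no samples shared between phenotype and genotypes")
        if dropped_g or dropped_p:
            warnings.warn(
                f"sample alignment dropped {dropped_g} genotype-only and "
                f"{dropped_p} phenotype-only samples"
            )
        g = genotypes.subset_samples(np.array(keep))
        values = np.array([self.values[pheno_idx[s]] for s in g.sample_ids])
        return PhenotypeVector(values, list(g.sample_ids)), g


class GroupStructure:
    """Non-overlapping partition of SNPs into ordered groups (genes).

    ``assignments[j]`` is the integer group index of SNP ``j``; ``group_ids``
    orders the groups.  Every SNP belongs to exactly one group and no group is
    empty.
    """

    def __init__(self, group_ids: list[str], assignments: np.ndarray):
        self.group_ids = list(group_ids)
        self.assignments = np.asarray(assignments, dtype=np.int64)
        if self.assignments.ndim != 1:
            raise ValueError("assignments must be one-dimensional")
        if len(self.assignments) == 0:
            raise ValueError("empty group structure")
        if self.assignments.min() < 0 or self.assignments.max() >= len(self.group_ids):
            raise ValueError("assignment index out of range")
        self.sizes = np.bincount(self.assignments, minlength=len(self.group_ids))
        if (self.sizes == 0).any():
            raise ValueError("empty groups are not allowed")
        # member index arrays, in SNP order, one per group
        order = np.argsort(self.assignments, kind="stable")
        bounds = np.cumsum(self.sizes)
        self.members = [order[s:e] for s, e in zip(np.r_[0, bounds[:-1]], bounds)]

    @property
    def n_groups(self) -> int:
        return len(self.group_ids)

    @property
    def n_snps(self) -> int:
        return len(self.assignments)

    @classmethod
    def from_mapping(cls, snp_ids: list[str], mapping: dict[str, str]) -> "GroupStructure":
        missing = [s for s in snp_ids if s not in mapping]
        if missing:
            raise ValueError(f"SNPs without group assignment: {missing[:5]}...")
        group_ids = sorted(set(mapping.values()))
        gidx = {g: i for i, g in enumerate(group_ids)}
        return cls(group_ids, np.array([gidx[mapping[s]] for s in snp_ids]))

    def group_of(self, snp_index: int) -> str:
        return self.group_ids[self.assignments[snp_index]]


@dataclass
class QCReport:
    """Per-filter removal counts with first-failing-rule attribution."""

    n_input: int
    n_removed_maf: int
    n_removed_missing: int
    n_removed_hwe: int
    n_kept: int
    maf: np.ndarray = field(repr=False)
    missing_rate: np.ndarray = field(repr=False)
    hwe_p: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        total = self.n_removed_maf + self.n_removed_missing + self.n_removed_hwe + self.n_kept
        if total != self.n_input:
            raise ValueError("QC attribution does not sum to the input count")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str = "tsv") -> GenotypeData:
    """Read a genotype panel from PLINK v1 binary or a TSV dosage matrix."""
    if format == "tsv":
        return _read_tsv(Path(path))
    if format == "plink":
        return _read_plink(Path(path))
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(g: GenotypeData, path: str | Path, format: str = "tsv") -> None:
    if format == "tsv":
        df = pd.DataFrame(g.dosages, index=g.sample_ids, columns=g.snp_ids)
        df.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")
    elif format == "plink":
        _write_plink(g, Path(path))
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def _read_tsv(path: Path) -> GenotypeData:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    dos = df.to_numpy(dtype=float)
    valid = np.isnan(dos) | np.isin(dos, (0.0, 1.0, 2.0))
    if not valid.all():
        raise ValueError("TSV dosages must be 0, 1, 2 or NA")
    p = df.shape[1]
    return GenotypeData(
        dos,
        [str(s) for s in df.index],
        [str(s) for s in df.columns],
        np.array(["0"] * p, dtype=object),
        np.arange(1, p + 1),
    )


def _read_plink(prefix: Path) -> GenotypeData:
    prefix = Path(str(prefix).removesuffix(".bed"))
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FileNotFoundError(f"PLINK file set incomplete: {f} missing")
    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"], dtype={"chrom": str},
    )
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None, usecols=[0, 1], names=["fid", "iid"], dtype=str)
    raw = np.fromfile(bed, dtype=np.uint8)
    if len(raw) < 3 or bytes(raw[:3]) != _BED_MAGIC:
        raise ValueError(f"{bed}: not a SNP-major PLINK v1 .bed file (bad magic bytes)")
    m, p = len(fam_df), len(bim_df)
    bytes_per_snp = (m + 3) // 4
    body = raw[3:]
    if len(body) != bytes_per_snp * p:
        raise ValueError(
            f"{bed}: payload of {len(body)} bytes inconsistent with "
            f"{m} samples x {p} SNPs from .fam/.bim"
        )
    blocks = body.reshape(p, bytes_per_snp)
    # unpack 2-bit fields, sample-fastest within a byte (LSB first)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (blocks[:, :, None] >> shifts) & 0b11  # (p, bytes, 4)
    codes = codes.reshape(p, -1)[:, :m]
    dosages = _CODE_TO_DOSAGE[codes].T  # (m, p)
    return GenotypeData(
        dosages,
        list(fam_df["iid"]),
        list(bim_df["snp_id"].astype(str)),
        bim_df["chrom"].to_numpy(dtype=object),
        bim_df["pos"].to_numpy(dtype=np.int64),
    )


def _write_plink(g: GenotypeData, prefix: Path) -> None:
    prefix = Path(str(prefix).removesuffix(".bed"))
    m, p = g.dosages.shape
    dos = g.dosages
    codes = np.full((p, m), 0b01, dtype=np.uint8)  # missing
    dt = dos.T
    codes[dt == 2.0] = 0b00
    codes[dt == 1.0] = 0b10
    codes[dt == 0.0] = 0b11
    pad = (-m) % 4
    if pad:
        codes = np.hstack([codes, np.full((p, pad), 0b01, dtype=np.uint8)])
    packed = (
        codes[:, 0::4]
        | (codes[:, 1::4] << 2)
        | (codes[:, 2::4] << 4)
        | (codes[:, 3::4] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j in range(p):
            fh.write(f"{g.chrom[j]}\t{g.snp_ids[j]}\t0\t{g.pos[j]}\tA\tB\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in g.sample_ids:
            fh.write(f"{s}\t{s}\t0\t0\t0\t-9\n")


def read_phenotype(path: str | Path, genotypes: GenotypeData | None = None) -> PhenotypeVector:
    """Read a two-column (sample_id, value) TSV; optionally validate ids."""
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    if df.shape[1] != 2:
        raise ValueError("phenotype file must have exactly two columns")
    ids = [str(s) for s in df.iloc[:, 0]]
    pheno = PhenotypeVector(df.iloc[:, 1].to_numpy(dtype=float), ids)
    if genotypes is not None:
        pheno, _ = pheno.align_to(genotypes)
    return pheno


def read_groups(
    path: str | Path, genotypes: GenotypeData, ignore_missing: bool = False
) -> GroupStructure:
    """Read a (snp_id, group_id) TSV and validate it against a genotype panel.

    ``ignore_missing`` tolerates entries for SNPs absent from the panel (e.g.
    removed by QC after the group file was written); by default they are an
    error.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] != 2:
        raise ValueError("group file must have exactly two columns")
    dup = df[df.duplicated(subset=df.columns[0], keep=False)]
    if not dup.empty:
        uniq = dup.groupby(df.columns[0])[df.columns[1]].nunique()
        if (uniq > 1).any():
            raise ValueError(
                "overlapping groups are unsupported; duplicate SNPs with "
                f"conflicting groups: {list(uniq[uniq > 1].index)[:5]}"
            )
        df = df.drop_duplicates()
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    unknown = sorted(set(mapping) - set(genotypes.snp_ids))
    if unknown:
        if not ignore_missing:
            raise ValueError(f"group file lists SNPs absent from the panel: {unknown[:5]}")
        for s in unknown:
            del mapping[s]
    return GroupStructure.from_mapping(genotypes.snp_ids, mapping)


def write_groups(groups: GroupStructure, snp_ids: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\tgroup_id\n")
        for s, a in zip(snp_ids, groups.assignments):
            fh.write(f"{s}\t{groups.group_ids[a]}\n")


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def _hwe_chi2_p(dosages: np.ndarray) -> float:
    """One-df chi-square goodness-of-fit of genotype counts to HWE proportions."""
    obs = np.array([
        np.sum(dosages == 0.0),
        np.sum(dosages == 1.0),
        np.sum(dosages == 2.0),
    ], dtype=float)
    n = obs.sum()
    if n == 0:
        return np.nan
    q = (2 * obs[2] + obs[1]) / (2 * n)  # A1 frequency
    exp = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
    if q in (0.0, 1.0):
        return 1.0  # monomorphic: fits HWE trivially
    stat = np.sum((obs - exp) ** 2 / exp)
    return float(stats.chi2.sf(stat, df=1))


def qc_filter(
    g: GenotypeData,
    maf_min: float = 0.05,
    miss_max: float = 0.05,
    hwe_p_min: float = 1e-4,
) -> tuple[GenotypeData, QCReport]:
    """Apply standard per-SNP GWAS QC: MAF, missing rate, HWE.

    A SNP failing several rules is attributed to the first failing one, in the
    order MAF -> missingness -> HWE, so the report counts are deterministic.
    """
    if g.n_snps == 0:
        raise ValueError("empty genotype panel")
    dos = g.dosages
    miss = np.isnan(dos)
    n_obs = (~miss).sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(dos, axis=0) / (2 * np.maximum(n_obs, 1))
    freq[n_obs == 0] = np.nan
    maf = np.minimum(freq, 1 - freq)
    missing_rate = miss.mean(axis=0)
    hwe_p = np.array([_hwe_chi2_p(dos[:, j]) for j in range(g.n_snps)])

    fail_maf = ~(maf >= maf_min)  # NaN MAF (all-missing SNP) fails here
    fail_miss = missing_rate > miss_max
    fail_hwe = hwe_p < hwe_p_min

    removed_maf = fail_maf
    removed_miss = fail_miss & ~removed_maf
    removed_hwe = fail_hwe & ~removed_maf & ~removed_miss
    keep = ~(removed_maf | removed_miss | removed_hwe)
    if not keep.any():
        raise ValueError("QC removed every SNP; no panel left")
    report = QCReport(
        n_input=g.n_snps,
        n_removed_maf=int(removed_maf.sum()),
        n_removed_missing=int(removed_miss.sum()),
        n_removed_hwe=int(removed_hwe.sum()),
        n_kept=int(keep.sum()),
        maf=maf,
        missing_rate=missing_rate,
        hwe_p=hwe_p,
    )
    return g.subset_snps(np.where(keep)[0]), report


# ---------------------------------------------------------------------------
# gene-based grouping
# ---------------------------------------------------------------------------

def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read gene intervals from GFF3 or a 4-column (chrom, start, end, gene_id) table.

    Coordinates are 1-based inclusive (GFF convention) in both cases.
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                gid = attrs.get("ID") or attrs.get("gene_id") or attrs.get("Name")
                rows.append((f[0], int(f[3]), int(f[4]), gid))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])
    else:
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "gene_id"],
            dtype={"chrom": str, "gene_id": str}, comment="#",
        )
    if df.empty:
        raise ValueError(f"no gene intervals found in {path}")
    return df


def map_snps_to_genes(
    g: GenotypeData,
    annotation: pd.DataFrame,
    buffer_bp: int = 10_000,
) -> GroupStructure:
    """Assign each SNP to the gene whose buffered interval contains it.

    A SNP at position ``pos`` joins gene ``(chrom, start, end)`` iff
    ``start - buffer_bp <= pos <= end + buffer_bp`` on the same chromosome
    (boundaries inclusive, 1-based coordinates).  A SNP inside several buffered
    genes goes to the one whose gene body is nearest (ties to the
    lexicographically smallest gene id).  SNPs outside every buffered gene
    become singleton groups so the SNP panel is never shrunk by grouping.
    """
    if annotation is None or len(annotation) == 0:
        raise ValueError("empty gene annotation")
    ann = annotation.copy()
    ann["chrom"] = ann["chrom"].astype(str)
    snp_chroms = set(str(c) for c in g.chrom)
    unmatched = sorted(snp_chroms - set(ann["chrom"]))
    if unmatched:
        warnings.warn(f"chromosomes with no annotated genes: {unmatched}")
    mapping: dict[str, str] = {}
    by_chrom = {c: sub for c, sub in ann.groupby("chrom")}
    for j, snp in enumerate(g.snp_ids):
        sub = by_chrom.get(str(g.chrom[j]))
        gene = None
        if sub is not None:
            pos = g.pos[j]
            hit = sub[(sub["start"] - buffer_bp <= pos) & (pos <= sub["end"] + buffer_bp)]
            if len(hit):
                # distance to the gene body itself (0 when inside it)
                dist = np.maximum(hit["start"] - pos, 0) + np.maximum(pos - hit["end"], 0)
                hit = hit.assign(_dist=dist).sort_values(["_dist", "gene_id"])
                gene = str(hit.iloc[0]["gene_id"])
        mapping[snp] = gene if gene is not None else f"snp:{snp}"
    return GroupStructure.from_mapping(g.snp_ids, mapping)
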