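"""Genotype/pedigree/phenotype I/O, marker QC, LD pruning and PCs.

Two genotype dialects are supported: PLINK text ``.ped``/``.map``
(space-delimited, ``0 0`` missing genotype) and a TSV dosage dialect
(individuals x markers with a marker-id header, accompanied by a marker
map TSV).  Dosages count copies of the a1 allele; on PLINK read, a1 is
the lexicographically smaller of the two alleles observed at a marker,
and the writer normalizes to the same convention so write -> read
round-trips are lossless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, Pedigree

__all__ = [
    "QCReport",
    "read_plink",
    "write_plink",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_pedigree_csv",
    "write_pedigree_csv",
    "read_phenotypes_tsv",
    "write_phenotypes_tsv",
    "read_dataset",
    "write_dataset",
    "qc_filter",
    "hwe_exact_p",
    "ld_prune",
    "compute_pcs",
]

MISSING_ALLELE = "0"
UNPLACED_CHROM = "0"  # reserved label for markers without a physical position


class ParseError(ValueError):
    """Raised with file and line context when an input file is malformed."""


# ---------------------------------------------------------------------------
# readers / writers


def write_plink(geno: GenotypeMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    mk = geno.markers
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, r in mk.iterrows():
            fh.write(f"{r['chrom']} {r['marker']} 0 {int(r['pos'])}\n")
    a1 = mk["a1"].to_numpy(dtype=object)
    a2 = mk["a2"].to_numpy(dtype=object)
    swap = a1 > a2  # normalize so dosage counts the lexicographically smaller allele
    lo = np.where(swap, a2, a1)
    hi = np.where(swap, a1, a2)
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, iid in enumerate(geno.ids):
            dos = geno.dosages[i]
            fields = [iid, iid, "0", "0", "0", "-9"]
            for j in range(geno.n_markers):
                d = dos[j]
                if np.isnan(d):
                    fields.extend((MISSING_ALLELE, MISSING_ALLELE))
                    continue
                d = int(round(d if not swap[j] else 2 - d))
                if d == 2:
                    fields.extend((lo[j], lo[j]))
                elif d == 1:
                    fields.extend((lo[j], hi[j]))
                else:
                    fields.extend((hi[j], hi[j]))
            fh.write(" ".join(fields) + "\n")


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    markers = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ParseError(f"{map_path}:{ln}: expected 4 columns, got {len(parts)}")
            chrom, mid, _cm, pos = parts
            markers.append((mid, chrom, int(pos)))
    m = len(markers)
    ids: list[str] = []
    raw: list[list[str]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m} fields for {m} markers, got {len(parts)}"
                )
            iid = parts[1]
            if iid in ids:
                raise ParseError(f"{ped_path}:{ln}: duplicated individual id {iid!r}")
            ids.append(iid)
            raw.append(parts[6:])
    n = len(ids)
    alle = np.array(raw, dtype=object).reshape(n, m, 2) if n else np.empty((0, m, 2), dtype=object)
    dosages = np.full((n, m), np.nan)
    a1_out, a2_out = [], []
    for j in range(m):
        col = alle[:, j, :]
        obs = sorted({a for a in col.ravel() if a != MISSING_ALLELE})
        if len(obs) > 2:
            raise ParseError(f"{ped_path}: marker {markers[j][0]} has >2 alleles: {obs}")
        if len(obs) == 0:
            a1, a2 = "N", "N"
        elif len(obs) == 1:
            a1, a2 = obs[0], obs[0]
        else:
            a1, a2 = obs
        a1_out.append(a1)
        a2_out.append(a2)
        missing = (col[:, 0] == MISSING_ALLELE) | (col[:, 1] == MISSING_ALLELE)
        partial = (col[:, 0] == MISSING_ALLELE) != (col[:, 1] == MISSING_ALLELE)
        if partial.any():
            raise ParseError(
                f"{ped_path}: marker {markers[j][0]}: half-missing genotype call"
            )
        dosages[:, j] = (col[:, 0] == a1).astype(float) + (col[:, 1] == a1).astype(float)
        dosages[missing, j] = np.nan
    mk = pd.DataFrame(markers, columns=["marker", "chrom", "pos"])
    mk["a1"] = a1_out
    mk["a2"] = a2_out
    return GenotypeMatrix(dosages, ids, mk)


def write_dosage_tsv(geno: GenotypeMatrix, dosage_path: str | Path, map_path: str | Path) -> None:
    df = pd.DataFrame(geno.dosages, columns=geno.markers["marker"])
    df.insert(0, "id", geno.ids)
    df.to_csv(dosage_path, sep="\t", index=False, na_rep="NA")
    geno.markers.to_csv(map_path, sep="\t", index=False)


def read_dosage_tsv(dosage_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(dosage_path, sep="\t", dtype={"id": str})
    if "id" not in df.columns:
        raise ParseError(f"{dosage_path}: missing 'id' column")
    if df["id"].duplicated().any():
        raise ParseError(f"{dosage_path}: duplicated individual ids")
    mk = pd.read_csv(map_path, sep="\t", dtype={"marker": str, "chrom": str, "a1": str, "a2": str})
    if list(df.columns[1:]) != list(mk["marker"]):
        raise ParseError(f"{dosage_path}: marker columns disagree with map {map_path}")
    dosages = df.iloc[:, 1:].to_numpy(dtype=float)
    return GenotypeMatrix(dosages, df["id"].tolist(), mk)


def write_pedigree_csv(ped: Pedigree, path: str | Path) -> None:
    ped.table.to_csv(path, index=False)


def read_pedigree_csv(path: str | Path) -> Pedigree:
    df = pd.read_csv(path, dtype={"id": str, "sire": str, "dam": str})
    return Pedigree(df)


def write_phenotypes_tsv(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"id": str, "batch": str})


def write_dataset(
    outdir: str | Path,
    geno: GenotypeMatrix,
    ped: Pedigree,
    pheno: pd.DataFrame,
    dialect: str = "tsv",
) -> dict[str, Path]:
    """Write the three pipeline inputs into one directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": outdir / "pedigree.csv",
        "phenotypes": outdir / "phenotypes.tsv",
    }
    write_pedigree_csv(ped, paths["pedigree"])
    write_phenotypes_tsv(pheno, paths["phenotypes"])
    if dialect == "tsv":
        paths["dosages"] = outdir / "dosages.tsv"
        paths["markers"] = outdir / "markers.tsv"
        write_dosage_tsv(geno, paths["dosages"], paths["markers"])
    elif dialect == "plink":
        paths["plink"] = outdir / "genotypes"
        write_plink(geno, paths["plink"])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return paths


def read_dataset(indir: str | Path, dialect: str = "tsv") -> tuple[GenotypeMatrix, Pedigree, pd.DataFrame]:
    indir = Path(indir)
    ped = read_pedigree_csv(indir / "pedigree.csv")
    pheno = read_phenotypes_tsv(indir / "phenotypes.tsv")
    if dialect == "tsv":
        geno = read_dosage_tsv(indir / "dosages.tsv", indir / "markers.tsv")
    elif dialect == "plink":
        geno = read_plink(indir / "genotypes")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return geno, ped, pheno


# ---------------------------------------------------------------------------
# marker QC


@dataclass
class QCReport:
    removed_snp_call_rate: list[str] = field(default_factory=list)
    removed_maf: list[str] = field(default_factory=list)
    removed_hwe: list[str] = field(default_factory=list)
    removed_unplaced: list[str] = field(default_factory=list)
    removed_individuals: list[str] = field(default_factory=list)
    n_snps_in: int = 0
    n_snps_out: int = 0
    n_individuals_in: int = 0
    n_individuals_out: int = 0

    def summary(self) -> str:
        return (
            f"SNPs {self.n_snps_in} -> {self.n_snps_out} "
            f"(call rate {len(self.removed_snp_call_rate)}, MAF {len(self.removed_maf)}, "
            f"HWE {len(self.removed_hwe)}, unplaced {len(self.removed_unplaced)}); "
            f"individuals {self.n_individuals_in} -> {self.n_individuals_out} "
            f"({len(self.removed_individuals)} removed)"
        )


def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg test P-value.

    Sums the probabilities of all heterozygote counts (conditional on
    allele counts) no more likely than the observed one, following the
    standard exact-test recurrence on heterozygote counts.
    """
    if min(n_het, n_hom1, n_hom2) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_rare = n_het + 2 * min(n_hom1, n_hom2)
    # heterozygote counts share the parity of the rare-allele count
    mid = n_rare * (2 * n - n_rare) // (2 * n)
    if mid % 2 != n_rare % 2:
        mid += 1
    probs = {mid: 1.0}
    # downward recurrence: het -> het - 2
    het = mid
    rare_hom = (n_rare - het) // 2
    common_hom = n - het - rare_hom
    p = 1.0
    while het >= 2:
        p *= het * (het - 1) / (4.0 * (rare_hom + 1) * (common_hom + 1))
        het -= 2
        rare_hom += 1
        common_hom += 1
        probs[het] = p
    # upward recurrence: het -> het + 2
    het = mid
    rare_hom = (n_rare - het) // 2
    common_hom = n - het - rare_hom
    p = 1.0
    while het <= n_rare - 2 and rare_hom >= 1 and common_hom >= 1:
        p *= 4.0 * rare_hom * common_hom / ((het + 2.0) * (het + 1.0))
        het += 2
        rare_hom -= 1
        common_hom -= 1
        probs[het] = p
    total = sum(probs.values())
    obs = probs.get(n_het)
    if obs is None:  # impossible configuration for these allele counts
        return 0.0
    return min(1.0, sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / total)


def qc_filter(
    geno: GenotypeMatrix,
    snp_call_rate: float = 0.98,
    maf: float = 0.05,
    hwe_p: float = 1e-6,
    ind_call_rate: float = 0.95,
) -> tuple[GenotypeMatrix, QCReport]:
    """Marker and individual QC, rules applied in a fixed order.

    (1) SNP call rate < ``snp_call_rate`` removed; (2) MAF strictly below
    ``maf`` removed; (3) exact Hardy-Weinberg P < ``hwe_p`` removed;
    (4) individuals with call rate < ``ind_call_rate`` removed;
    (5) markers on the unplaced chromosome label removed.  A marker
    removed by an earlier rule is not re-tested by later rules.
    """
    if geno.n_markers == 0 or geno.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    report = QCReport(
        n_snps_in=geno.n_markers, n_individuals_in=geno.n_individuals
    )
    dos = geno.dosages
    names = geno.markers["marker"].to_numpy()
    alive = np.ones(geno.n_markers, dtype=bool)

    called = ~np.isnan(dos)
    call_rate = called.mean(axis=0)
    drop = call_rate < snp_call_rate
    report.removed_snp_call_rate = list(names[drop])
    alive &= ~drop

    with np.errstate(invalid="ignore"):
        p = np.nanmean(dos, axis=0) / 2.0
    maf_vec = np.minimum(p, 1.0 - p)
    drop = alive & (maf_vec < maf)
    report.removed_maf = list(names[drop])
    alive &= ~drop

    hwe_drop = np.zeros(geno.n_markers, dtype=bool)
    for j in np.flatnonzero(alive):
        col = dos[called[:, j], j]
        n_hom2 = int((col == 0).sum())
        n_het = int((col == 1).sum())
        n_hom1 = int((col == 2).sum())
        if hwe_exact_p(n_het, n_hom1, n_hom2) < hwe_p:
            hwe_drop[j] = True
    report.removed_hwe = list(names[hwe_drop])
    alive &= ~hwe_drop

    ind_rate = called[:, alive].mean(axis=1) if alive.any() else np.ones(geno.n_individuals)
    ind_keep = ind_rate >= ind_call_rate
    report.removed_individuals = [i for i, k in zip(geno.ids, ind_keep) if not k]

    unplaced = alive & (geno.markers["chrom"].to_numpy() == UNPLACED_CHROM)
    report.removed_unplaced = list(names[unplaced])
    alive &= ~unplaced

    if not alive.any():
        raise ValueError("empty panel: all SNPs removed by QC")
    kept_ids = [i for i, k in zip(geno.ids, ind_keep) if k]
    if not kept_ids:
        raise ValueError("all individuals removed by QC")
    out = geno.subset(individuals=kept_ids, markers=np.flatnonzero(alive))
    report.n_snps_out = out.n_markers
    report.n_individuals_out = out.n_individuals
    return out, report


# ---------------------------------------------------------------------------
# LD pruning


def ld_prune(
    geno: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_threshold: float = 0.2,
) -> np.ndarray:
    """Greedy windowed pairwise pruning (``--indep-pairwise`` semantics).

    Slides a ``window_snps`` window along the map in steps of
    ``step_snps``; whenever a surviving pair within the window has
    squared dosage correlation above the threshold, the member with the
    lower MAF is removed (ties: the later map position).  Returns the
    retained marker column indices.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2_threshold must lie in (0, 1]")
    dos = geno.impute_mean().dosages
    m = geno.n_markers
    p = dos.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    sd = dos.std(axis=0)
    centered = dos - dos.mean(axis=0)
    alive = np.ones(m, dtype=bool)
    starts = range(0, max(1, m - 1), step_snps)
    for start in starts:
        end = min(m, start + window_snps)
        idx = np.flatnonzero(alive[start:end]) + start
        if len(idx) < 2:
            if end >= m:
                break
            continue
        block = centered[:, idx]
        bsd = sd[idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (block.T @ block) / dos.shape[0]
            corr /= np.outer(bsd, bsd)
        r2 = np.nan_to_num(corr**2, nan=0.0)
        local_alive = np.ones(len(idx), dtype=bool)
        for a in range(len(idx)):
            if not local_alive[a]:
                continue
            for b in range(a + 1, len(idx)):
                if not local_alive[b]:
                    continue
                if r2[a, b] > r2_threshold:
                    ja, jb = idx[a], idx[b]
                    # lower MAF goes; ties remove the later map position
                    if maf[ja] < maf[jb]:
                        victim_local, victim = a, ja
                    else:
                        victim_local, victim = b, jb
                    alive[victim] = False
                    local_alive[victim_local] = False
                    if victim_local == a:
                        break
        if end >= m:
            break
    return np.flatnonzero(alive)


# ---------------------------------------------------------------------------
# principal components


def compute_pcs(geno: GenotypeMatrix, k: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Leading PCs of the genomic relationship structure.

    Eigendecomposes the VanRaden-centered genotype covariance (the G
    matrix built from the observed allele frequencies); returns per-
    individual scores scaled by sqrt(eigenvalue) and the fractions of
    variance explained.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n = geno.n_individuals
    if k >= min(n, geno.n_markers):
        raise ValueError(f"k={k} must be < min(n_individuals, n_markers)")
    from .kinship import g_matrix

    G = g_matrix(geno.impute_mean()).values
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    total = vals.sum()
    frac = vals[:k] / total if total > 0 else np.zeros(k)
    scores = vecs[:, :k] * np.sqrt(vals[:k])
    df = pd.DataFrame(scores, columns=[f"pc{i + 1}" for i in range(k)])
    df.insert(0, "id", geno.ids)
    return df, frac
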