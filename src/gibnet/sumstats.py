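"""GWAS summary-statistics I/O, harmonisation, and filtering.

Summary statistics are the only data level the pipeline touches: per-SNP
effect sizes (``beta``), standard errors, Z-scores, p-values, allele
frequencies, imputation quality and sample sizes for each trait.  This module
reads whitespace/tab-delimited files into :class:`SumStatsTable`, aligns them
to an allele/frequency reference (``munge``), splits them by chromosome
parity for the exploratory/confirmatory factor-analysis stages, and reads the
per-chromosome LD-score tables used by LD score regression.

Conventions
-----------
* positions are 1-based, chromosomes restricted to autosomes 1-22;
* allele frequencies are folded to the minor allele, i.e. ``maf`` in (0, 0.5];
* strand-ambiguous SNPs (A/T, C/G) are removed unconditionally during munging;
* missing values are written as ``NA`` and parsed from ``NA``, ``.`` or empty.
"""

from __future__ import annotations

import dataclasses
import glob as _glob
import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats


class SumStatsError(ValueError):
    """Fatal configuration or data error in summary-statistics handling."""


#: canonical in-memory column names
CANONICAL_COLUMNS = (
    "snp_id", "chrom", "pos", "a1", "a2", "maf",
    "beta", "se", "z", "n", "info", "pval",
)

#: canonical -> on-disk header used by :func:`write_sumstats`
OUTPUT_HEADER = {
    "snp_id": "SNP", "chrom": "CHR", "pos": "BP", "a1": "A1", "a2": "A2",
    "maf": "MAF", "beta": "BETA", "se": "SE", "z": "Z", "pval": "P",
    "n": "N", "info": "INFO",
}

DEFAULT_COLUMN_MAP = {
    "snp_id": "SNP", "chrom": "CHR", "pos": "BP", "a1": "A1", "a2": "A2",
    "maf": "MAF", "beta": "BETA", "se": "SE", "z": "Z", "pval": "P",
    "n": "N", "info": "INFO",
}

NA_VALUES = ["NA", "na", ".", ""]
VALID_ALLELES = frozenset("ACGT")
AMBIGUOUS_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

_NUMERIC_COLS = ("chrom", "pos", "maf", "beta", "se", "z", "n", "info", "pval")


@dataclasses.dataclass
class SumStatsTable:
    """Per-SNP association records for one trait on a shared variant universe.

    ``df`` holds the canonical columns of :data:`CANONICAL_COLUMNS` (absent
    optional columns are filled with NaN), is unique on ``snp_id`` and sorted
    by ``(chrom, pos)``.  ``provenance`` is a free-text audit trail of every
    filter applied, with removal counts.
    """

    trait_name: str
    df: pd.DataFrame
    provenance: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.df
        for col in CANONICAL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df = df.loc[:, list(CANONICAL_COLUMNS)]
        if df["snp_id"].duplicated().any():
            n0 = len(df)
            df = df.drop_duplicates("snp_id", keep="first")
            self.provenance.append(f"dropped {n0 - len(df)} duplicate snp_id rows")
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        self.df = df

    @property
    def n_snps(self) -> int:
        return len(self.df)

    def note(self, msg: str) -> None:
        self.provenance.append(msg)

    def copy(self) -> "SumStatsTable":
        return SumStatsTable(self.trait_name, self.df.copy(), list(self.provenance))


def read_sumstats(
    path: str | os.PathLike,
    column_map: Mapping[str, str] | None = None,
    trait_name: str | None = None,
    n_default: float | None = None,
) -> SumStatsTable:
    """Read a whitespace/tab-delimited summary-statistics file.

    ``column_map`` maps canonical names (:data:`CANONICAL_COLUMNS`) to the
    file's header names; unmapped canonical columns fall back to the standard
    header (SNP/CHR/BP/A1/A2/MAF/BETA/SE/Z/P/N/INFO).  The file must provide
    ``snp_id``, ``a1``, ``a2``, either (``beta``, ``se``) or ``z``, and ``n``
    (or a constant ``n_default``).  ``z`` is computed as beta/se when absent;
    rows with unparseable values are dropped and counted in the provenance.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise SumStatsError(f"summary-statistics file not found: {path}")
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=r"\s+", na_values=NA_VALUES, keep_default_na=True)
    if raw.empty:
        raise SumStatsError(f"empty summary-statistics file: {path}")

    df = pd.DataFrame(index=raw.index)
    for canon, header in cmap.items():
        if header in raw.columns:
            df[canon] = raw[header]

    for col in ("snp_id", "a1", "a2"):
        if col not in df.columns:
            raise SumStatsError(f"missing required column '{col}' (mapped to {cmap[col]!r}) in {path}")
    has_beta_se = "beta" in df.columns and "se" in df.columns
    if not has_beta_se and "z" not in df.columns:
        raise SumStatsError(f"need either (beta, se) or z columns in {path}")
    if "n" not in df.columns:
        if n_default is None:
            raise SumStatsError(f"missing required column 'n' in {path} and no constant N supplied")
        df["n"] = float(n_default)

    prov: list[str] = [f"read {len(df)} rows from {path}"]
    n_total = len(df)

    for col in _NUMERIC_COLS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    df["a1"] = df["a1"].astype(str).str.upper()
    df["a2"] = df["a2"].astype(str).str.upper()

    bad = df["snp_id"].isna() | ~df["a1"].isin(VALID_ALLELES) | ~df["a2"].isin(VALID_ALLELES)
    bad |= df["a1"] == df["a2"]
    if "pos" in df.columns:
        bad |= df["pos"].notna() & (df["pos"] <= 0)
    if "chrom" in df.columns:
        bad |= df["chrom"].notna() & ~df["chrom"].isin(range(1, 23))
    if has_beta_se:
        bad |= df["beta"].isna() | df["se"].isna() | (df["se"] <= 0)
    else:
        bad |= df["z"].isna()
    bad |= df["n"].isna() | (df["n"] <= 0)
    df = df.loc[~bad].copy()
    prov.append(f"dropped {int(bad.sum())} unparseable/invalid rows of {n_total}")

    if df.empty:
        raise SumStatsError(f"no valid rows left after parsing {path}")

    # fold allele frequency to the minor allele
    if "maf" in df.columns:
        f = df["maf"].to_numpy(dtype=float)
        folded = np.where(f > 0.5, 1.0 - f, f)
        if np.any(f > 0.5):
            prov.append(f"folded {int(np.sum(f > 0.5))} frequencies > 0.5 to minor-allele scale")
        folded[(folded <= 0) | (folded > 0.5)] = np.nan
        df["maf"] = folded

    if has_beta_se:
        z = df["beta"] / df["se"]
        if "z" in df.columns:
            df["z"] = df["z"].fillna(z)
        else:
            df["z"] = z
    if "pval" not in df.columns or df["pval"].isna().all():
        df["pval"] = 2.0 * _stats.norm.sf(np.abs(df["z"]))

    name = trait_name or os.path.splitext(os.path.basename(path))[0]
    return SumStatsTable(name, df, prov)


def munge(
    table: SumStatsTable,
    ref: SumStatsTable | pd.DataFrame,
    info_min: float = 0.6,
    maf_min: float = 0.01,
) -> SumStatsTable:
    """Harmonize a table to an allele/frequency reference panel.

    Removal classes, each counted in the provenance: SNPs absent from the
    reference; ``info <= info_min``; reference minor-allele frequency
    ``<= maf_min``; strand-ambiguous SNPs (A/T, C/G); SNPs whose alleles match
    the reference in neither orientation.  SNPs whose a1/a2 are swapped
    relative to the reference have ``z`` and ``beta`` sign-flipped and their
    alleles re-oriented.  The output ``maf`` is the reference panel frequency.
    Idempotent against the same reference.
    """
    rdf = ref.df if isinstance(ref, SumStatsTable) else ref
    rdf = rdf.loc[:, ["snp_id", "a1", "a2", "maf"]].rename(
        columns={"a1": "ref_a1", "a2": "ref_a2", "maf": "ref_maf"}
    )
    rmaf = rdf["ref_maf"].to_numpy(dtype=float)
    rdf = rdf.assign(ref_maf=np.where(rmaf > 0.5, 1.0 - rmaf, rmaf))

    df = table.df.merge(rdf, on="snp_id", how="left")
    counts: dict[str, int] = {}

    miss = df["ref_a1"].isna()
    counts["missing_from_reference"] = int(miss.sum())
    df = df.loc[~miss]

    lowinfo = df["info"].notna() & (df["info"] <= info_min)
    counts[f"info<={info_min}"] = int(lowinfo.sum())
    df = df.loc[~lowinfo]

    lowmaf = df["ref_maf"] <= maf_min
    counts[f"ref_maf<={maf_min}"] = int(lowmaf.sum())
    df = df.loc[~lowmaf]

    ambig = pd.Series(
        [(x, y) in AMBIGUOUS_PAIRS for x, y in zip(df["a1"], df["a2"])], index=df.index
    )
    counts["strand_ambiguous"] = int(ambig.sum())
    df = df.loc[~ambig]

    same = (df["a1"] == df["ref_a1"]) & (df["a2"] == df["ref_a2"])
    swap = (df["a1"] == df["ref_a2"]) & (df["a2"] == df["ref_a1"])
    counts["allele_mismatch"] = int((~same & ~swap).sum())
    df = df.loc[same | swap].copy()
    swap = swap.loc[df.index]

    df.loc[swap, "z"] = -df.loc[swap, "z"]
    df.loc[swap, "beta"] = -df.loc[swap, "beta"]
    df.loc[swap, ["a1", "a2"]] = df.loc[swap, ["ref_a1", "ref_a2"]].to_numpy()
    df["maf"] = df["ref_maf"]
    n_flipped = int(swap.sum())
    df = df.drop(columns=["ref_a1", "ref_a2", "ref_maf"])

    if df.empty:
        raise SumStatsError(
            f"no SNPs survive munging of {table.trait_name!r}; removal counts: {counts}"
        )
    prov = list(table.provenance)
    prov.append(
        "munge(info_min=%g, maf_min=%g): kept %d of %d; flipped %d; removed %s"
        % (info_min, maf_min, len(df), table.n_snps, n_flipped, counts)
    )
    return SumStatsTable(table.trait_name, df.reset_index(drop=True), prov)


def select_chromosome_parity(table: SumStatsTable, parity: str) -> SumStatsTable:
    """Keep SNPs on odd, even, or all autosomes (``parity`` in odd|even|all)."""
    if parity not in ("odd", "even", "all"):
        raise SumStatsError(f"parity must be odd|even|all, got {parity!r}")
    if parity == "all":
        return table.copy()
    keep = (table.df["chrom"] % 2 == 1) if parity == "odd" else (table.df["chrom"] % 2 == 0)
    out = table.df.loc[keep].reset_index(drop=True)
    prov = list(table.provenance)
    prov.append(f"parity={parity}: kept {len(out)} of {table.n_snps} SNPs")
    if out.empty:
        prov.append(f"warning: no SNPs on {parity} chromosomes")
    return SumStatsTable(table.trait_name, out, prov)


def write_sumstats(table: SumStatsTable, path: str | os.PathLike) -> str:
    """Write tab-delimited summary statistics (header SNP CHR BP A1 A2 MAF
    BETA SE Z P N INFO, missing values as NA).  Round-trips losslessly
    through :func:`read_sumstats`."""
    if table.n_snps == 0:
        raise SumStatsError("refusing to write an empty summary-statistics table")
    out = table.df.rename(columns=OUTPUT_HEADER)[list(OUTPUT_HEADER.values())]
    out.to_csv(path, sep="\t", index=False, na_rep="NA")
    return os.fspath(path)


# ---------------------------------------------------------------------------
# LD-score tables


@dataclasses.dataclass
class LDScoreTable:
    """Per-SNP LD scores plus the reference SNP count M.

    ``df`` has columns snp_id, chrom, pos, ell (the LD score: the sum of r^2
    between the SNP and its neighbours, so ell >= 1).  ``m`` is the total
    number of reference SNPs on the heritability scale, summed over
    chromosomes.
    """

    df: pd.DataFrame
    m: float

    def __post_init__(self) -> None:
        if self.m < len(self.df):
            raise SumStatsError(
                f"LD-score M ({self.m}) smaller than the number of rows ({len(self.df)})"
            )
        self.df = self.df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    @property
    def n_snps(self) -> int:
        return len(self.df)


def _m_companion(path: str) -> str:
    return path[: -len(".ldscore")] + ".M" if path.endswith(".ldscore") else path + ".M"


def read_ldscores(paths: Sequence[str] | str) -> LDScoreTable:
    """Read per-chromosome LD-score files (header CHR SNP BP L2); each file
    has a companion single-number ``.M`` file; M is summed over files.

    ``paths`` may be a glob pattern or an explicit list of ``.ldscore`` paths.
    """
    if isinstance(paths, str):
        paths = sorted(_glob.glob(paths))
    if not paths:
        raise SumStatsError("no LD-score files found")
    frames = []
    m_total = 0.0
    for p in paths:
        d = pd.read_csv(p, sep=r"\s+", na_values=NA_VALUES)
        for col in ("CHR", "SNP", "BP", "L2"):
            if col not in d.columns:
                raise SumStatsError(f"LD-score file {p} lacks required column {col}")
        frames.append(
            d.rename(columns={"CHR": "chrom", "SNP": "snp_id", "BP": "pos", "L2": "ell"})[
                ["snp_id", "chrom", "pos", "ell"]
            ]
        )
        with open(_m_companion(p)) as fh:
            m_total += float(fh.read().strip())
    df = pd.concat(frames, ignore_index=True)
    n0 = len(df)
    df = df.loc[df["ell"] >= 0.9].reset_index(drop=True)  # a SNP is in LD with itself
    if len(df) < n0:
        pass  # silently drop malformed rows; they cannot enter the regression
    return LDScoreTable(df, m_total)


def write_ldscores(ld: LDScoreTable, directory: str | os.PathLike, prefix: str = "ld") -> list[str]:
    """Write one ``{prefix}.{chrom}.ldscore`` + ``.M`` pair per chromosome."""
    os.makedirs(directory, exist_ok=True)
    paths = []
    per_chrom_m = ld.m / max(ld.df["chrom"].nunique(), 1)
    for chrom, grp in ld.df.groupby("chrom", sort=True):
        p = os.path.join(os.fspath(directory), f"{prefix}.{int(chrom)}.ldscore")
        out = grp.rename(columns={"chrom": "CHR", "snp_id": "SNP", "pos": "BP", "ell": "L2"})
        out[["CHR", "SNP", "BP", "L2"]].to_csv(p, sep="\t", index=False)
        with open(_m_companion(p), "w") as fh:
            fh.write(f"{per_chrom_m!r}\n")
        paths.append(p)
    return paths
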