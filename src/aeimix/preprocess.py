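"""Data preparation for allele-count tables.

Implements the first two pipeline stages: ratio-preserving library-size
adjustment, raw-count SNP filtering, gene-unit coverage averaging, trimming
of the most extreme units, and stratification of SNPs by coverage class and
genic region.  Tables are plain pandas DataFrames with the column schema
below; a "sample" is one (subject, tissue) library.

Input TSV schema (UTF-8, tab-delimited):
    subject  tissue  gene  snp  region  ref_count  var_count

Region tokens are case-insensitive and normalised to the canonical labels
``utr3, utr5, exon, intron, upstream, downstream, intergenic``.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "MODELED_REGIONS",
    "normalize_region",
    "read_counts_table",
    "write_table",
    "round_half_away",
    "adjust_library_size",
    "filter_snps",
    "compute_unit_averages",
    "trim_top_units",
    "stratify_by_region",
]

REQUIRED_COLUMNS = ["subject", "tissue", "gene", "snp", "region", "ref_count", "var_count"]

#: regions modelled with their own folded-Skellam fit; upstream/downstream
#: SNPs are carried through but reported separately, intergenic is filtered.
MODELED_REGIONS = ("utr3", "utr5", "exon", "intron")

_REGION_TOKENS = {
    "3utr": "utr3",
    "utr3": "utr3",
    "3'utr": "utr3",
    "5utr": "utr5",
    "utr5": "utr5",
    "5'utr": "utr5",
    "exonic": "exon",
    "exon": "exon",
    "intronic": "intron",
    "intron": "intron",
    "intergenic": "intergenic",
    "upstream": "upstream",
    "downstream": "downstream",
}

# a SNP annotated with several regions takes the highest-priority label
_REGION_PRIORITY = ("utr3", "utr5", "exon", "intron", "upstream", "downstream", "intergenic")


def normalize_region(token: str) -> str:
    """Map a raw region annotation to its canonical label.

    Multi-label annotations (separated by ``;`` or ``,``) resolve by the
    priority utr3 > utr5 > exon > intron > upstream > downstream >
    intergenic.
    """
    parts = [p.strip().lower() for p in str(token).replace(",", ";").split(";") if p.strip()]
    labels = []
    for part in parts:
        if part not in _REGION_TOKENS:
            raise ValueError(f"unknown region annotation: {token!r}")
        labels.append(_REGION_TOKENS[part])
    if not labels:
        raise ValueError("empty region annotation")
    return min(labels, key=_REGION_PRIORITY.index)


def read_counts_table(path) -> pd.DataFrame:
    """Read a per-SNP allele count TSV and validate/normalise it."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={c: str for c in ("subject", "tissue", "gene", "snp", "region")},
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"counts table is missing columns: {missing}")
    df = df[list(df.columns)].copy()
    df["region"] = df["region"].map(normalize_region)
    for col in ("ref_count", "var_count"):
        df[col] = pd.to_numeric(df[col])
        if (df[col] < 0).any():
            raise ValueError(f"negative values in {col}")
        df[col] = df[col].astype(np.int64)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table as TSV with stable float formatting (reproducible)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def round_half_away(x):
    """Round half away from zero (symmetric, unlike banker's rounding)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def _sample_key(df: pd.DataFrame) -> pd.Series:
    return df["subject"].astype(str) + "\x1f" + df["tissue"].astype(str)


def adjust_library_size(
    table: pd.DataFrame,
    library_totals: Mapping | pd.Series | None = None,
) -> pd.DataFrame:
    """Scale each sample's counts to the median library size.

    Every (ref, var) pair is multiplied by ``median(total) / total(sample)``
    so coverage is comparable across samples while the within-pair ratio is
    untouched.  ``library_totals`` maps ``(subject, tissue)`` to the sample's
    total read count; by default the total is the sum of ref + var over the
    sample's rows in ``table`` (override when true library sizes are known).

    Adds columns ``ref_adj, var_adj, scale, sum_adj, diff_adj, abs_diff``;
    ``abs_diff`` is the rounded (half away from zero) absolute adjusted
    difference used as folded-Skellam support, ``diff_adj`` keeps the signed
    real difference.
    """
    df = table.copy()
    key = _sample_key(df)
    if library_totals is None:
        totals = (df["ref_count"] + df["var_count"]).groupby(key).sum()
    else:
        if isinstance(library_totals, pd.Series):
            mapping = {
                (str(k[0]) + "\x1f" + str(k[1]) if isinstance(k, tuple) else str(k)): v
                for k, v in library_totals.items()
            }
        else:
            mapping = {
                (str(k[0]) + "\x1f" + str(k[1]) if isinstance(k, tuple) else str(k)): v
                for k, v in dict(library_totals).items()
            }
        totals = pd.Series(mapping)
    sample_keys = pd.Index(key.unique())
    absent = [k for k in sample_keys if k not in totals.index]
    if absent:
        names = ", ".join(k.replace("\x1f", "/") for k in absent[:5])
        raise ValueError(f"missing library total for sample(s): {names}")
    totals = totals.loc[sample_keys].astype(float)
    bad = totals[totals <= 0]
    if len(bad):
        names = ", ".join(str(k).replace("\x1f", "/") for k in bad.index[:5])
        raise ValueError(f"non-positive library total for sample(s): {names}")
    median_total = float(np.median(totals.to_numpy()))
    scale = (median_total / totals).reindex(key).to_numpy()
    df["scale"] = scale
    df["ref_adj"] = df["ref_count"].to_numpy() * scale
    df["var_adj"] = df["var_count"].to_numpy() * scale
    df["sum_adj"] = df["ref_adj"] + df["var_adj"]
    df["diff_adj"] = df["ref_adj"] - df["var_adj"]
    df["abs_diff"] = round_half_away(np.abs(df["diff_adj"])).astype(np.int64)
    return df


def filter_snps(
    table: pd.DataFrame,
    min_low_allele: int = 3,
    exclude_regions: Iterable[str] = ("intergenic",),
) -> pd.DataFrame:
    """Keep SNPs with min(R, V) >= ``min_low_allele`` (raw counts) outside
    the excluded regions."""
    excluded = {normalize_region(r) for r in exclude_regions}
    low = np.minimum(table["ref_count"], table["var_count"])
    mask = (low >= min_low_allele) & ~table["region"].isin(excluded)
    out = table[mask].copy()
    if out.empty:
        warnings.warn("no SNPs survive filtering", stacklevel=2)
    return out


def compute_unit_averages(adjusted: pd.DataFrame) -> pd.DataFrame:
    """Average adjusted coverage within each (subject, tissue, gene) unit.

    The same gene observed in two tissues forms two distinct units.  Returns
    one row per unit with ``mean_total`` (mean of sum_adj over its SNPs) and
    ``n_snps``.
    """
    if adjusted.empty:
        raise ValueError("adjusted table is empty")
    grouped = adjusted.groupby(["subject", "tissue", "gene"], sort=True)["sum_adj"]
    units = grouped.agg(mean_total="mean", n_snps="size").reset_index()
    units["n_snps"] = units["n_snps"].astype(np.int64)
    return units


def trim_top_units(units: pd.DataFrame, fraction: float = 0.001):
    """Drop the ``ceil(fraction * N)`` units with the largest mean coverage.

    Returns ``(kept, removed)``.  Ties break deterministically by
    (mean_total desc, subject, tissue, gene).
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    n_remove = math.ceil(fraction * len(units)) if fraction > 0 else 0
    ordered = units.sort_values(
        ["mean_total", "subject", "tissue", "gene"],
        ascending=[False, True, True, True],
        kind="mergesort",
    )
    removed = ordered.iloc[:n_remove]
    kept = units.loc[~units.index.isin(removed.index)]
    return kept.copy(), removed.copy()


def stratify_by_region(adjusted: pd.DataFrame, unit_labels: pd.DataFrame):
    """Partition SNPs into (coverage component, region) strata.

    ``unit_labels`` has columns subject, tissue, gene, component.  Only the
    four modelled regions form strata; upstream/downstream SNPs are returned
    separately (second element).  Every retained SNP's unit must be
    labelled.
    """
    merged = adjusted.merge(unit_labels, on=["subject", "tissue", "gene"], how="left")
    if merged["component"].isna().any():
        bad = merged[merged["component"].isna()].iloc[0]
        raise ValueError(
            "unlabelled unit for SNP "
            f"{bad['snp']} ({bad['subject']}/{bad['tissue']}/{bad['gene']})"
        )
    merged["component"] = merged["component"].astype(int)
    modeled = merged[merged["region"].isin(MODELED_REGIONS)]
    excluded = merged[~merged["region"].isin(MODELED_REGIONS)].copy()
    strata = {
        (comp, region): sub.copy()
        for (comp, region), sub in modeled.groupby(["component", "region"], sort=True)
    }
    return strata, excluded
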