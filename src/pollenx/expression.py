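"""Normalization, differential expression and expression-threshold calls.

Counts from each RNA-seq dataset are normalized two ways, as in the study
design this package models: reads per million (RPM, against the sample's
total library size) drive the threshold calls — pollen-expressed (PEX,
mean RPM > 1), highly expressed (hPEX, > 10), present (>= 0.05) and
pollen-specific (PSX: PEX in pollen, < 1 RPM in every sporophytic
dataset) — while the differential-expression test uses median-of-ratios
size factors and a per-locus negative-binomial Wald test. A locus is
heat-stress responsive (DEX) at |log2 fold change| >= 1 and
Benjamini–Hochberg adjusted p < 0.05.

The Wald test here is deliberately minimal: a shared method-of-moments
dispersion per locus, no fold-change shrinkage, no outlier refitting and
no independent filtering.  It implements the same decision rule as the
mainstream NB frameworks while staying self-contained and unit-testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SAMPLE_COLUMNS = ["dataset", "sample", "condition", "replicate", "library_size"]

CONTROL, TREATED = "control", "HS"


@dataclass
class ExpressionStudy:
    """Locus x sample count matrix plus its sample sheet.

    ``samples`` rows describe the columns of ``counts`` (keyed by the
    ``sample`` column); an optional ``tissue`` column tags each dataset as
    ``pollen`` or ``sporophyte`` for the specificity calls.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample sheet lacks columns {missing}")
        self.samples = self.samples.set_index("sample", drop=False) if (
            self.samples.index.name != "sample"
        ) else self.samples
        unknown = [s for s in self.counts.columns if s not in self.samples.index]
        if unknown:
            raise ValueError(f"count columns without sample-sheet rows: {unknown}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        lib = self.samples.loc[self.counts.columns, "library_size"].astype(float)
        over = self.counts.sum(axis=0) > lib
        if over.any():
            bad = list(self.counts.columns[over])
            raise ValueError(
                f"assigned counts exceed library size for samples {bad}"
            )

    @property
    def datasets(self) -> list[str]:
        return list(dict.fromkeys(self.samples.dataset))

    def dataset_samples(self, dataset: str) -> pd.DataFrame:
        return self.samples[self.samples.dataset == dataset]

    def subset(self, dataset: str) -> "ExpressionStudy":
        sheet = self.dataset_samples(dataset)
        return ExpressionStudy(self.counts[list(sheet["sample"])].copy(), sheet.copy())

    def pollen_datasets(self) -> list[str]:
        if "tissue" in self.samples.columns:
            return [
                d for d in self.datasets
                if (self.dataset_samples(d).tissue == "pollen").all()
            ]
        return self.datasets

    def sporophytic_datasets(self) -> list[str]:
        return [d for d in self.datasets if d not in self.pollen_datasets()]


# ---------------------------------------------------------------- normalization

def rpm_normalize(study: ExpressionStudy) -> pd.DataFrame:
    """Reads per million against each sample's total library size.

    The denominator is the library total from the sample sheet, not the
    column sum of assigned reads.
    """
    lib = study.samples.loc[study.counts.columns, "library_size"].astype(float)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"non-positive library size for samples {bad}")
    return study.counts.div(lib, axis=1) * 1e6


def filter_low_counts(study: ExpressionStudy, min_count: int = 10) -> ExpressionStudy:
    """Drop loci with fewer than ``min_count`` reads in every sample."""
    keep = (study.counts >= min_count).any(axis=1)
    return ExpressionStudy(study.counts.loc[keep].copy(), study.samples.copy())


def median_ratio_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq normalization).

    factor_j = median over reference loci of count_ij / geomean_i, where
    the reference loci are those with positive counts in every sample.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no locus with positive counts in all samples; median-ratio "
            "factors are undefined (consider a pseudo-reference fallback)"
        )
    log_mat = np.log(mat[positive])
    log_geomean = log_mat.mean(axis=1)
    factors = np.exp(np.median(log_mat - log_geomean[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def condition_mean_rpm(study: ExpressionStudy) -> pd.DataFrame:
    """Arithmetic mean RPM over replicates per (dataset, condition)."""
    rpm = rpm_normalize(study)
    key = pd.MultiIndex.from_frame(
        study.samples.loc[rpm.columns, ["dataset", "condition"]]
    )
    out = rpm.T.groupby(key).mean().T
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["dataset", "condition"])
    return out


# ---------------------------------------------------------------- DE test

@dataclass
class DEResult:
    """Per-dataset differential-expression table (HS vs control)."""

    dataset: str
    table: pd.DataFrame  # columns: lfc, se, wald_p, padj, mean_norm_control, mean_norm_hs, undefined, dex
    size_factors: pd.Series = field(repr=False, default=None)

    def dex_loci(self) -> set[str]:
        return set(self.table.index[self.table.dex])


def nb_wald_test(
    study: ExpressionStudy,
    dataset: str | None = None,
    min_count: int = 10,
    lfc_min: float = 1.0,
    padj_max: float = 0.05,
    dispersion_floor: float = 1e-8,
    pool_dispersion: bool = True,
) -> DEResult:
    """Negative-binomial Wald test of heat stress vs control for one dataset.

    Counts are low-count filtered and scaled by median-of-ratios size
    factors.  Dispersion is estimated by method of moments on the
    normalized counts; with ``pool_dispersion`` (the default) the median
    over loci is shared by all loci, which stabilizes the standard error
    enough for a normal reference at typical replicate numbers (per-locus
    moment estimates from 3 replicates are far too noisy).  Everything is
    floored at ``dispersion_floor``.  The log2 fold change uses a
    pseudo-count of 1/2 on the normalized condition means, its standard
    error comes from the delta method under the NB mean-variance relation,
    and the two-sided p value from the normal reference.  BH adjustment
    runs over the loci actually tested; loci with all-zero counts in both
    conditions carry an ``undefined`` flag and are excluded from the
    adjustment.
    """
    sub = study.subset(dataset) if dataset is not None else study
    dataset = dataset or "/".join(sub.datasets)
    sheet = sub.samples
    for cond in (CONTROL, TREATED):
        if (sheet.condition == cond).sum() < 2:
            raise ValueError(f"{dataset}: need >= 2 replicates in condition {cond!r}")

    filtered = filter_low_counts(sub, min_count=min_count)
    sf = median_ratio_size_factors(filtered.counts)
    norm = filtered.counts / sf

    ctl_cols = list(sheet["sample"][sheet.condition == CONTROL])
    hs_cols = list(sheet["sample"][sheet.condition == TREATED])
    m1 = norm[ctl_cols].mean(axis=1).to_numpy()
    m2 = norm[hs_cols].mean(axis=1).to_numpy()
    v1 = norm[ctl_cols].var(axis=1, ddof=1).to_numpy()
    v2 = norm[hs_cols].var(axis=1, ddof=1).to_numpy()
    n1, n2 = len(ctl_cols), len(hs_cols)

    with np.errstate(divide="ignore", invalid="ignore"):
        a1 = np.where(m1 > 0, (v1 - m1) / m1**2, np.nan)
        a2 = np.where(m2 > 0, (v2 - m2) / m2**2, np.nan)
    alpha = np.nanmean(np.vstack([a1, a2]), axis=0)
    if pool_dispersion and np.isfinite(alpha).any():
        pooled = float(np.nanmedian(alpha))
        alpha = np.full_like(m1, max(pooled, dispersion_floor))
    else:
        alpha = np.where(np.isnan(alpha), dispersion_floor, alpha)
        alpha = np.maximum(alpha, dispersion_floor)

    var_mean1 = (m1 + alpha * m1**2) / n1
    var_mean2 = (m2 + alpha * m2**2) / n2
    ln2sq = np.log(2.0) ** 2
    lfc = np.log2(m2 + 0.5) - np.log2(m1 + 0.5)
    se = np.sqrt(
        var_mean1 / ((m1 + 0.5) ** 2 * ln2sq) + var_mean2 / ((m2 + 0.5) ** 2 * ln2sq)
    )

    undefined = (m1 == 0) & (m2 == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(lfc == 0, 0.0, lfc / se)
    p = np.where(undefined, np.nan, 2.0 * stats.norm.sf(np.abs(z)))
    p = np.where(np.isnan(p) & ~undefined, 1.0, p)

    padj = np.full_like(p, np.nan)
    tested = ~undefined
    if tested.any():
        padj[tested] = multipletests(p[tested], method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "lfc": np.where(undefined, np.nan, lfc),
            "se": se,
            "wald_p": p,
            "padj": padj,
            "mean_norm_control": m1,
            "mean_norm_hs": m2,
            "undefined": undefined,
        },
        index=filtered.counts.index,
    )
    table["dex"] = call_dex(table.lfc, table.padj, lfc_min=lfc_min, padj_max=padj_max)
    return DEResult(dataset=dataset, table=table, size_factors=sf)


def call_dex(
    lfc: pd.Series | np.ndarray | float,
    padj: pd.Series | np.ndarray | float,
    lfc_min: float = 1.0,
    padj_max: float = 0.05,
):
    """Differential-expression flag: |LFC| >= 1 and adjusted p < 0.05."""
    lfc_arr = np.asarray(lfc, dtype=float)
    padj_arr = np.asarray(padj, dtype=float)
    with np.errstate(invalid="ignore"):
        flag = (np.abs(lfc_arr) >= lfc_min) & (padj_arr < padj_max)
    flag = np.where(np.isnan(lfc_arr) | np.isnan(padj_arr), False, flag)
    if isinstance(lfc, pd.Series):
        return pd.Series(flag, index=lfc.index, name="dex")
    if np.isscalar(lfc) or flag.ndim == 0:
        return bool(flag)
    return flag


# ---------------------------------------------------------------- specificity

@dataclass
class SpecificityCall:
    """Threshold-based expression flags per locus."""

    table: pd.DataFrame  # per-locus: pex_<ds>, hpex_<ds>, present_<ds>, pex, hpex, psx


def call_specificity(
    mean_rpm: pd.DataFrame,
    pollen_datasets: list[str],
    sporophytic_datasets: list[str],
    rpm_pex: float = 1.0,
    rpm_hpex: float = 10.0,
    rpm_present: float = 0.05,
) -> SpecificityCall:
    """PEX/hPEX/present/PSX flags from condition-mean RPM values.

    ``mean_rpm`` has a (dataset, condition) column MultiIndex.  A locus is
    PEX for a pollen dataset when its mean RPM exceeds ``rpm_pex`` in at
    least one condition (and hPEX analogously at ``rpm_hpex``); it is
    present in a dataset at mean RPM >= ``rpm_present``; it is
    pollen-specific (PSX) when PEX in at least one pollen dataset and
    below ``rpm_pex`` in every condition of every sporophytic dataset.
    """
    out = pd.DataFrame(index=mean_rpm.index)
    for ds in list(pollen_datasets) + list(sporophytic_datasets):
        block = mean_rpm[ds]
        out[f"present_{ds}"] = (block >= rpm_present).any(axis=1)
        if ds in pollen_datasets:
            out[f"pex_{ds}"] = (block > rpm_pex).any(axis=1)
            out[f"hpex_{ds}"] = (block > rpm_hpex).any(axis=1)
    pex_cols = [f"pex_{ds}" for ds in pollen_datasets]
    out["pex"] = out[pex_cols].any(axis=1) if pex_cols else False
    hpex_cols = [f"hpex_{ds}" for ds in pollen_datasets]
    out["hpex"] = out[hpex_cols].any(axis=1) if hpex_cols else False
    if sporophytic_datasets:
        sporo = pd.concat([mean_rpm[ds] for ds in sporophytic_datasets], axis=1)
        quiet = (sporo < rpm_pex).all(axis=1)
    else:
        quiet = pd.Series(True, index=mean_rpm.index)
    out["psx"] = out["pex"] & quiet
    return SpecificityCall(table=out)
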