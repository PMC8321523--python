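"""Count-table analytics for barcoded knockout-library selections.

Covers control-design (median-of-ratios) normalization, per-design
enrichment/depletion calls across replicate populations with
growth-control filtering, and the diversity / between-population
heterogeneity metrics (retained-design fraction, frequency distributions,
pairwise Pearson correlations, top-hit tallies).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError
from .smallstats import bh_adjust

__all__ = [
    "BarcodeCountTable",
    "EnrichmentResult",
    "DiversityResult",
    "HeterogeneityResult",
    "normalize_counts",
    "log2_fold_change",
    "replicate_log2fc",
    "enrichment_test",
    "filter_growth_confounded",
    "diversity_metrics",
    "heterogeneity_metrics",
    "variant_top_tally",
    "LOST_MUTANT_THRESHOLD",
]

#: Raw-read threshold below which a design counts as lost after selection.
LOST_MUTANT_THRESHOLD = 3


@dataclass
class BarcodeCountTable:
    """Designs x samples integer read counts plus metadata.

    ``counts`` is indexed by design_id with one column per sample_id;
    ``design_meta`` carries ``is_control`` (and an optional ``group``
    label); ``sample_meta`` carries ``replicate``, ``bottleneck``,
    ``timepoint`` in {before, after} and ``arm`` in
    {selection, growth-control}.
    """

    counts: pd.DataFrame
    design_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise InvalidParameterError("read counts must be nonnegative")
        if not self.counts.index.equals(self.design_meta.index):
            raise InvalidParameterError("counts and design_meta indices differ")
        if set(self.counts.columns) != set(self.sample_meta.index):
            raise InvalidParameterError("counts columns and sample_meta index differ")
        if "is_control" not in self.design_meta.columns:
            raise InvalidParameterError("design_meta needs an is_control column")
        for col in ("replicate", "timepoint"):
            if col not in self.sample_meta.columns:
                raise InvalidParameterError(f"sample_meta needs a {col} column")

    def samples(self, timepoint: str | None = None) -> list[str]:
        meta = self.sample_meta
        if timepoint is not None:
            meta = meta[meta["timepoint"] == timepoint]
        return list(meta.index)

    def to_long(self) -> pd.DataFrame:
        """Long TSV-ready form: design_id, sample_id, replicate, timepoint, count, is_control."""
        long = (
            self.counts.rename_axis(index="design_id", columns="sample_id")
            .stack()
            .rename("count")
            .reset_index()
        )
        long = long.merge(
            self.sample_meta[["replicate", "timepoint"]].rename_axis("sample_id").reset_index(),
            on="sample_id",
        )
        long = long.merge(
            self.design_meta[["is_control"]].rename_axis("design_id").reset_index(),
            on="design_id",
        )
        cols = ["design_id", "sample_id", "replicate", "timepoint", "count", "is_control"]
        return long[cols].sort_values(["sample_id", "design_id"]).reset_index(drop=True)

    @classmethod
    def from_long(cls, long: pd.DataFrame, sample_meta: pd.DataFrame | None = None):
        required = {"design_id", "sample_id", "replicate", "timepoint", "count", "is_control"}
        missing = required - set(long.columns)
        if missing:
            raise InvalidParameterError(f"long table missing columns: {sorted(missing)}")
        counts = (
            long.pivot(index="design_id", columns="sample_id", values="count")
            .fillna(0)
            .astype(np.int64)
        )
        design_meta = (
            long[["design_id", "is_control"]].drop_duplicates().set_index("design_id")
        ).loc[counts.index]
        if sample_meta is None:
            sample_meta = (
                long[["sample_id", "replicate", "timepoint"]]
                .drop_duplicates()
                .set_index("sample_id")
            )
        return cls(counts=counts, design_meta=design_meta, sample_meta=sample_meta)


@dataclass(frozen=True)
class EnrichmentResult:
    design_id: str
    log2fc: float
    p: float
    padj: float
    call: str  # enriched / depleted / none
    growth_confounded: bool = False


def normalize_counts(table: BarcodeCountTable) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios normalization restricted to inert control designs.

    The size factor of sample j is the median over control designs c of
    ``count[c, j] / geomean(count[c, :])``. Controls that are zero in every
    sample are dropped with a warning. Zeros elsewhere are handled
    poscounts-style: the geometric mean of a control is taken over its
    positive counts only, and a control contributes to a sample's median
    only where its count is positive; a sample with no positive control
    counts is an error. Returns (normalized counts, size factors).
    """
    controls = table.design_meta.index[table.design_meta["is_control"].astype(bool)]
    if len(controls) == 0:
        raise InvalidParameterError("no control designs present")
    ctrl = table.counts.loc[controls].astype(float)
    all_zero = ctrl.sum(axis=1) == 0
    if all_zero.any():
        warnings.warn(
            f"dropping {int(all_zero.sum())} control design(s) with all-zero counts",
            UserWarning,
        )
        ctrl = ctrl[~all_zero]
    if ctrl.empty:
        raise InvalidParameterError("no usable control designs for normalization")
    with np.errstate(divide="ignore"):
        logs = np.log(ctrl.where(ctrl > 0))
    geomean = np.exp(logs.mean(axis=1, skipna=True))
    ratios = ctrl.where(ctrl > 0).div(geomean, axis=0)
    size_factors = ratios.median(axis=0, skipna=True)
    if size_factors.isna().any():
        bad = list(size_factors.index[size_factors.isna()])
        raise InvalidParameterError(
            f"no positive control counts in sample(s) {bad}: size factor undefined"
        )
    # rescale to geometric mean 1 so re-normalizing is the identity
    size_factors = size_factors / np.exp(np.log(size_factors).mean())
    size_factors.name = "size_factor"
    normalized = table.counts.div(size_factors, axis=1)
    return normalized, size_factors


def log2_fold_change(before, after, pseudocount: float = 0.5):
    """Per-design log2((after + ps) / (before + ps)); default ps = 0.5."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise InvalidParameterError("before/after must be matched")
    if np.any(before < 0) or np.any(after < 0):
        raise InvalidParameterError("counts must be nonnegative")
    if pseudocount <= 0:
        raise InvalidParameterError("pseudocount must be > 0")
    return np.log2(after + pseudocount) - np.log2(before + pseudocount)


def replicate_log2fc(
    table: BarcodeCountTable,
    normalized: pd.DataFrame | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Designs x replicates matrix of log2 fold-changes (after vs before).

    Uses control-normalized counts when ``normalized`` is given, raw counts
    otherwise. Every replicate must have exactly one before and one after
    sample.
    """
    counts = normalized if normalized is not None else table.counts
    meta = table.sample_meta
    cols = {}
    for rep, g in meta.groupby("replicate"):
        before = g.index[g["timepoint"] == "before"]
        after = g.index[g["timepoint"] == "after"]
        if len(before) != 1 or len(after) != 1:
            raise InvalidParameterError(
                f"replicate {rep!r} needs exactly one before and one after sample"
            )
        cols[rep] = log2_fold_change(
            counts[before[0]].to_numpy(), counts[after[0]].to_numpy(), pseudocount
        )
    return pd.DataFrame(cols, index=counts.index)


def _one_sample_p(values: np.ndarray) -> float:
    """Two-sided p of mean == 0; sign-flip fallback for zero variance."""
    if np.ptp(values) == 0:
        if values[0] == 0:
            return 1.0
        # sign-flip permutation: |mean| matched only when all signs agree
        return min(1.0, 2.0 ** (1 - len(values)))
    return float(stats.ttest_1samp(values, popmean=0.0).pvalue)


def enrichment_test(log2fc: pd.DataFrame, alpha: float = 0.05) -> list[EnrichmentResult]:
    """Per-design one-sample t-test of replicate log2 fold-changes vs 0.

    BH adjustment across designs; a design is called enriched/depleted by
    the sign of its mean when the adjusted p falls below ``alpha``.
    Requires >= 3 replicates. Zero-variance designs fall back to an exact
    sign-flip permutation p-value.
    """
    if log2fc.shape[1] < 3:
        raise InvalidParameterError("need >= 3 replicate populations")
    if not 0.0 < alpha < 1.0:
        raise InvalidParameterError("alpha must be in (0, 1)")
    values = log2fc.to_numpy()
    means = values.mean(axis=1)
    pvals = np.array([_one_sample_p(row) for row in values])
    padj = bh_adjust(pvals)
    results = []
    for gid, m, p, pa in zip(log2fc.index, means, pvals, padj):
        if pa < alpha and m != 0:
            call = "enriched" if m > 0 else "depleted"
        else:
            call = "none"
        results.append(EnrichmentResult(str(gid), float(m), float(p), float(pa), call))
    return results


def filter_growth_confounded(
    selection: list[EnrichmentResult], control: list[EnrichmentResult]
) -> list[EnrichmentResult]:
    """Void calls for designs that are also significant in the growth-only arm.

    Designs with a non-``none`` call in the control experiment keep their
    statistics but get ``growth_confounded=True`` and ``call="none"`` —
    their enrichment may reflect a growth effect, not altered tolerance.
    """
    sel_ids = {r.design_id for r in selection}
    ctl_ids = {r.design_id for r in control}
    if sel_ids != ctl_ids:
        raise InvalidParameterError("selection and control cover different design sets")
    confounded = {r.design_id for r in control if r.call != "none"}
    out = []
    for r in selection:
        if r.design_id in confounded:
            out.append(
                EnrichmentResult(r.design_id, r.log2fc, r.p, r.padj, "none", True)
            )
        else:
            out.append(r)
    return out


@dataclass
class DiversityResult:
    """Per-population diversity after selection."""

    retained: pd.Series  # fraction of designs with raw count >= threshold
    frequencies: pd.DataFrame  # design frequency per after-selection sample
    log10_freq_hist: dict[str, tuple[np.ndarray, np.ndarray]] = field(repr=False, default_factory=dict)
    threshold: int = LOST_MUTANT_THRESHOLD


def diversity_metrics(
    table: BarcodeCountTable,
    threshold: int = LOST_MUTANT_THRESHOLD,
    n_bins: int = 30,
) -> DiversityResult:
    """Retained-design fraction and frequency distributions after selection.

    A design is retained in a population when its raw read count after
    selection is >= ``threshold`` (lost-mutant rule). Frequencies are raw
    counts normalized per sample; the histogram is over log10 frequencies
    of designs with nonzero counts.
    """
    after = table.samples("after")
    if not after:
        raise InvalidParameterError("no after-selection samples present")
    raw = table.counts[after]
    totals = raw.sum(axis=0)
    empty = totals == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} after-selection sample(s) empty: retained undefined",
            UserWarning,
        )
    retained = (raw >= threshold).sum(axis=0) / len(raw.index)
    retained[empty] = np.nan
    retained.name = "retained_fraction"
    freqs = raw.div(totals.where(~empty), axis=1)
    hists = {}
    for s in after:
        nz = freqs[s][freqs[s] > 0]
        if len(nz):
            hists[s] = np.histogram(np.log10(nz), bins=n_bins)
    return DiversityResult(
        retained=retained, frequencies=freqs, log10_freq_hist=hists, threshold=threshold
    )


@dataclass
class HeterogeneityResult:
    """Between-population heterogeneity across replicate populations."""

    pearson: pd.DataFrame  # pairwise r on raw after-selection counts
    mean_r: float
    top_tally: pd.Series  # design/variant -> number of populations it tops
    ties: list[str] = field(default_factory=list)


def heterogeneity_metrics(
    table: BarcodeCountTable,
    pseudocount: float = 0.5,
    log_counts: bool = False,
) -> HeterogeneityResult:
    """Pairwise Pearson correlations and the top-hit tally across replicates.

    Correlations are computed on raw after-selection read counts (the
    ``log_counts`` flag switches to log2(count + pseudocount); off by
    default). The tally records, per population, the design with the
    largest absolute log2 fold-change; ties break to the smallest design id
    and are flagged.
    """
    after = table.samples("after")
    if len(after) < 2:
        raise InvalidParameterError("need >= 2 replicate populations")
    mat = table.counts[after].astype(float)
    if log_counts:
        mat = np.log2(mat + pseudocount)
    cols = list(mat.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            a, b = mat[cols[i]].to_numpy(), mat[cols[j]].to_numpy()
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                warnings.warn(
                    f"constant count vector: correlation undefined for ({cols[i]}, {cols[j]})",
                    UserWarning,
                )
                r.iloc[i, j] = r.iloc[j, i] = np.nan
                continue
            r.iloc[i, j] = r.iloc[j, i] = float(np.corrcoef(a, b)[0, 1])
    off = r.to_numpy()[~np.eye(len(cols), dtype=bool)]
    mean_r = float(np.nanmean(off)) if np.any(np.isfinite(off)) else math.nan

    lfc = replicate_log2fc(table, pseudocount=pseudocount)
    tally: dict[str, int] = {}
    ties = []
    for rep in lfc.columns:
        scores = lfc[rep].abs()
        best = scores.max()
        winners = sorted(scores.index[scores == best])
        if len(winners) > 1:
            ties.append(str(rep))
        top = str(winners[0])
        tally[top] = tally.get(top, 0) + 1
    tally_s = pd.Series(tally, dtype=int).sort_values(ascending=False)
    tally_s.name = "n_populations_topped"
    return HeterogeneityResult(pearson=r, mean_r=mean_r, top_tally=tally_s, ties=ties)


def variant_top_tally(variants: pd.DataFrame, by: str = "operon") -> pd.Series:
    """Tally of which variant/gene/operon attains the top frequency per population.

    ``variants`` is a long table with columns population_id, variant_id,
    gene, operon, frequency. Ties break to the smallest label.
    """
    required = {"population_id", "variant_id", "frequency"}
    if not required <= set(variants.columns):
        raise InvalidParameterError(f"variant table needs columns {sorted(required)}")
    if by not in variants.columns:
        raise InvalidParameterError(f"unknown grouping column {by!r}")
    if ((variants["frequency"] < 0) | (variants["frequency"] > 1)).any():
        raise InvalidParameterError("variant frequencies must lie in [0, 1]")
    tally: dict[str, int] = {}
    for _, g in variants.groupby("population_id"):
        best = g["frequency"].max()
        winners = sorted(g.loc[g["frequency"] == best, by].astype(str))
        tally[winners[0]] = tally.get(winners[0], 0) + 1
    out = pd.Series(tally, dtype=int).sort_values(ascending=False)
    out.name = "n_populations_topped"
    return out
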