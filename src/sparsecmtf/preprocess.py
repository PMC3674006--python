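"""Block assembly, transformation, scaling and weighting.

The analysis couples three blocks through a shared subject mode:

* a three-way tensor of repeated paraclinical biomarkers
  (subjects x biomarkers x timepoints, with an observation mask),
* a baseline matrix of onset characteristics (subjects x variables),
* a genotype matrix of additive risk-allele counts (subjects x SNPs,
  with a mask for failed genotyping).

Before joint factorization, each biomarker-by-time column and each
baseline/gene column is centered and scaled to unit sample variance over
its observed entries, and each block receives a weight equal to the
inverse of its observed sum of squares so that no block dominates the
joint loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MultiBlockDataset",
    "assemble_tensor",
    "flatten_tensor",
    "transform_and_scale",
    "weight_blocks",
    "DataError",
]

DEFAULT_TIME_GRID = (1, 3, 6, 12)


class DataError(ValueError):
    """Raised for malformed or inconsistent input tables."""


@dataclass
class MultiBlockDataset:
    """The three coupled data blocks sharing a subject mode.

    Attributes
    ----------
    tensor : (n, J, K) float array
        Biomarker block; unobserved cells hold 0 and are masked out.
    tensor_mask : (n, J, K) bool array
        True where observed.
    baseline : (n, M) float array
    gene : (n, P) float array
    gene_mask : (n, P) bool array
    subjects, biomarkers, times, baseline_vars, snps
        Axis labels. ``times`` are months since diagnosis.
    block_weights : (3,) float array or None
        Tensor / baseline / gene weights used in the joint loss.
    standardized : bool
        Whether :func:`transform_and_scale` has been applied.
    """

    tensor: np.ndarray
    tensor_mask: np.ndarray
    baseline: np.ndarray
    gene: np.ndarray
    gene_mask: np.ndarray
    subjects: list = field(default_factory=list)
    biomarkers: list = field(default_factory=list)
    times: list = field(default_factory=lambda: list(DEFAULT_TIME_GRID))
    baseline_vars: list = field(default_factory=list)
    snps: list = field(default_factory=list)
    block_weights: np.ndarray | None = None
    standardized: bool = False

    def __post_init__(self):
        self.tensor = np.asarray(self.tensor, dtype=float)
        self.tensor_mask = np.asarray(self.tensor_mask, dtype=bool)
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.gene = np.asarray(self.gene, dtype=float)
        self.gene_mask = np.asarray(self.gene_mask, dtype=bool)
        if self.tensor.shape != self.tensor_mask.shape:
            raise DataError("tensor and tensor_mask shapes differ")
        if self.gene.shape != self.gene_mask.shape:
            raise DataError("gene and gene_mask shapes differ")
        n = self.tensor.shape[0]
        if self.baseline.shape[0] != n or self.gene.shape[0] != n:
            raise DataError("blocks disagree on the number of subjects")
        if not self.subjects:
            self.subjects = [f"S{i:03d}" for i in range(n)]
        if not self.biomarkers:
            self.biomarkers = [f"bm{j:02d}" for j in range(self.tensor.shape[1])]
        if not self.baseline_vars:
            self.baseline_vars = [f"bl{m:02d}" for m in range(self.baseline.shape[1])]
        if not self.snps:
            self.snps = [f"snp{p:02d}" for p in range(self.gene.shape[1])]

    @property
    def n_subjects(self) -> int:
        return self.tensor.shape[0]

    @property
    def shape(self) -> tuple:
        return (
            self.tensor.shape,
            self.baseline.shape,
            self.gene.shape,
        )

    def subset_subjects(self, idx) -> "MultiBlockDataset":
        """Row-subset every block (used by split-half validation)."""
        idx = np.asarray(idx)
        return replace(
            self,
            tensor=self.tensor[idx],
            tensor_mask=self.tensor_mask[idx],
            baseline=self.baseline[idx],
            gene=self.gene[idx],
            gene_mask=self.gene_mask[idx],
            subjects=[self.subjects[i] for i in idx],
            block_weights=None,
        )


# ---------------------------------------------------------------------------
# tensor assembly from long tables
# ---------------------------------------------------------------------------

def assemble_tensor(
    long_table: pd.DataFrame,
    subjects=None,
    variables=None,
    times=DEFAULT_TIME_GRID,
):
    """Pivot a long table (subject, variable, time, value) into a 3-way array.

    Parameters
    ----------
    long_table : DataFrame with columns subject_id, variable, time_months, value
        Column names are fixed; extra columns are ignored.
    subjects, variables : optional explicit label orders.
        Default: order of first appearance.
    times : the declared visit grid in months.

    Returns
    -------
    (tensor, mask) : zero-filled float array and boolean observation mask.

    Raises
    ------
    DataError
        On duplicate (subject, variable, time) cells, unknown labels, or a
        subject with zero observations.
    """
    required = {"subject_id", "variable", "time_months", "value"}
    missing = required - set(long_table.columns)
    if missing:
        raise DataError(f"long table lacks columns: {sorted(missing)}")
    tab = long_table
    times = list(times)
    bad_t = set(tab["time_months"]) - set(times)
    if bad_t:
        raise DataError(f"time values outside the declared grid: {sorted(bad_t)}")
    if subjects is None:
        subjects = list(pd.unique(tab["subject_id"]))
    if variables is None:
        variables = list(pd.unique(tab["variable"]))
    bad_v = set(tab["variable"]) - set(variables)
    if bad_v:
        raise DataError(f"unknown variables: {sorted(bad_v)}")
    bad_s = set(tab["subject_id"]) - set(subjects)
    if bad_s:
        raise DataError(f"unknown subjects: {sorted(bad_s)}")

    dup = tab.duplicated(subset=["subject_id", "variable", "time_months"])
    if dup.any():
        first = tab.loc[dup.idxmax()]
        raise DataError(
            "duplicate cell: subject=%s variable=%s time=%s"
            % (first["subject_id"], first["variable"], first["time_months"])
        )

    si = pd.Categorical(tab["subject_id"], categories=subjects).codes
    vi = pd.Categorical(tab["variable"], categories=variables).codes
    ti = pd.Categorical(tab["time_months"], categories=times).codes
    shape = (len(subjects), len(variables), len(times))
    tensor = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    tensor[si, vi, ti] = tab["value"].to_numpy(dtype=float)
    mask[si, vi, ti] = True

    empty = ~mask.any(axis=(1, 2))
    if empty.any():
        names = [subjects[i] for i in np.flatnonzero(empty)]
        raise DataError(f"subjects with zero observations: {names}")
    return tensor, mask


def flatten_tensor(ds: MultiBlockDataset) -> pd.DataFrame:
    """Inverse of :func:`assemble_tensor`: observed cells as a long table."""
    i, j, k = np.nonzero(ds.tensor_mask)
    return pd.DataFrame(
        {
            "subject_id": [ds.subjects[a] for a in i],
            "variable": [ds.biomarkers[a] for a in j],
            "time_months": [ds.times[a] for a in k],
            "value": ds.tensor[i, j, k],
        }
    )


# ---------------------------------------------------------------------------
# transformation and scaling
# ---------------------------------------------------------------------------

def _standardize_columns(x: np.ndarray, mask: np.ndarray):
    """Center/scale each column of a 2-D array over observed entries (ddof=1).

    Returns (standardized array, keep flags); constant or <2-observation
    columns are flagged for dropping.
    """
    x = np.where(mask, x, 0.0)
    cnt = mask.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = x.sum(axis=0) / cnt
        cen = np.where(mask, x - mean, 0.0)
        var = (cen**2).sum(axis=0) / (cnt - 1)
    keep = (cnt >= 2) & (var > 1e-12)
    sd = np.sqrt(np.where(keep, var, 1.0))
    out = np.where(mask, cen / sd, 0.0)
    return out, keep


def transform_and_scale(
    ds: MultiBlockDataset, log_vars=()
) -> MultiBlockDataset:
    """Log-transform designated biomarkers, then standardize every column.

    Each biomarker-by-time column of the tensor, each baseline column and
    each SNP column is centered and scaled to unit sample variance over its
    observed entries. Constant columns are dropped (baseline/gene) or fully
    masked (tensor) with a warning. Idempotent up to numerical tolerance.

    Parameters
    ----------
    log_vars : iterable of biomarker names to analyse on log scale.

    Raises
    ------
    DataError
        If a log-designated variable has a non-positive observed value.
    """
    tensor = ds.tensor.copy()
    tmask = ds.tensor_mask.copy()
    log_vars = set(log_vars)
    unknown = log_vars - set(ds.biomarkers)
    if unknown:
        raise DataError(f"log_vars not in biomarker labels: {sorted(unknown)}")
    for j, name in enumerate(ds.biomarkers):
        if name in log_vars:
            vals = tensor[:, j, :]
            bad = tmask[:, j, :] & (vals <= 0)
            if bad.any():
                i, k = np.argwhere(bad)[0]
                raise DataError(
                    f"non-positive value for log variable {name!r}: "
                    f"subject={ds.subjects[i]} time={ds.times[k]}"
                )
            tensor[:, j, :] = np.where(tmask[:, j, :], np.log(vals), 0.0)

    n, J, K = tensor.shape
    flat = tensor.reshape(n, J * K)
    fmask = tmask.reshape(n, J * K)
    flat_std, keep = _standardize_columns(flat, fmask)
    if not keep.all():
        for c in np.flatnonzero(~keep):
            j, k = divmod(c, K)
            warnings.warn(
                f"constant/empty tensor column ({ds.biomarkers[j]}, "
                f"t={ds.times[k]}) masked out",
                stacklevel=2,
            )
            fmask[:, c] = False
            flat_std[:, c] = 0.0
    tensor = flat_std.reshape(n, J, K)
    tmask = fmask.reshape(n, J, K)
    if not tmask.any(axis=(1, 2)).all():
        raise DataError("a subject lost all tensor observations in scaling")

    bmask = np.ones_like(ds.baseline, dtype=bool)
    baseline, bkeep = _standardize_columns(ds.baseline, bmask)
    if not bkeep.all():
        for c in np.flatnonzero(~bkeep):
            warnings.warn(
                f"constant baseline column {ds.baseline_vars[c]!r} dropped",
                stacklevel=2,
            )
    baseline = baseline[:, bkeep]
    baseline_vars = [v for v, k in zip(ds.baseline_vars, bkeep) if k]

    gene, gkeep = _standardize_columns(ds.gene, ds.gene_mask)
    gmask = ds.gene_mask.copy()
    if not gkeep.all():
        for c in np.flatnonzero(~gkeep):
            warnings.warn(
                f"constant SNP column {ds.snps[c]!r} dropped", stacklevel=2
            )
    gene = gene[:, gkeep]
    gmask = gmask[:, gkeep]
    snps = [s for s, k in zip(ds.snps, gkeep) if k]

    return replace(
        ds,
        tensor=tensor,
        tensor_mask=tmask,
        baseline=baseline,
        baseline_vars=baseline_vars,
        gene=np.where(gmask, gene, 0.0),
        gene_mask=gmask,
        snps=snps,
        block_weights=None,
        standardized=True,
    )


def weight_blocks(ds: MultiBlockDataset) -> MultiBlockDataset:
    """Attach block weights 1 / (observed sum of squares) per block.

    With these weights each block contributes exactly 1 to the joint loss of
    the zero model, so no block dominates the fit by sheer size.
    """
    ss = np.array(
        [
            float((ds.tensor[ds.tensor_mask] ** 2).sum()),
            float((ds.baseline**2).sum()),
            float((ds.gene[ds.gene_mask] ** 2).sum()),
        ]
    )
    if (ss <= 0).any():
        which = ["tensor", "baseline", "gene"][int(np.argmax(ss <= 0))]
        raise DataError(f"block {which!r} has zero observed sum of squares")
    return replace(ds, block_weights=1.0 / ss)


def prepare(ds: MultiBlockDataset, log_vars=()) -> MultiBlockDataset:
    """Convenience: transform_and_scale followed by weight_blocks."""
    return weight_blocks(transform_and_scale(ds, log_vars=log_vars))
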