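"""Internal and external validation of coupled factor models.

Three procedures mirror how multi-block latent factor analyses are
defended in practice:

* **Pattern-to-pattern permutation testing** — for one component, the
  absolute Pearson correlation between two blocks' subject scores is
  compared against a null built by permuting the subject rows of one
  block. Because the loading structure of the permuted block is refit for
  every draw (a cheap closed-form regression), the null statistic
  undergoes the same adaptive fitting as the observed one, which keeps
  the test calibrated under an independent-blocks null.
* **Split-half consistency** — subjects are randomly halved, independent
  models are fitted on the halves, components are matched (optimal
  assignment on Tucker congruence) and the matched congruence is compared
  against a null of congruences from models fit on column-permuted data.
* **Gene-selection homogeneity** — the sparse gene supports selected in
  the two halves are tested for association by Fisher's exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import fisher_exact

from .cmtf import CMTFModel, align_components, cmtf_fit
from .preprocess import MultiBlockDataset, transform_and_scale, weight_blocks

__all__ = [
    "congruence_coefficient",
    "ComponentMatch",
    "match_components",
    "block_scores",
    "PermutationResult",
    "permutation_association_test",
    "SplitHalfResult",
    "split_half_once",
    "split_half_consistency",
    "gene_selection_homogeneity",
]

_MODE_ATTRS = (("biomarker", "B"), ("time", "C"), ("baseline", "D"), ("gene", "E"))


def congruence_coefficient(u, v) -> float:
    """Tucker congruence: cosine of the angle between two loading vectors."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("congruence is undefined for a zero vector")
    return float(u @ v / (nu * nv))


@dataclass
class ComponentMatch:
    """Optimal pairing of two models' components."""

    permutation: np.ndarray  # column r of model1 matches permutation[r] of model2
    signs: np.ndarray  # sign applied to model2's matched column
    overall: np.ndarray  # |congruence| on concatenated non-subject modes
    mode_congruence: dict  # mode -> signed congruence per matched pair


def _mode_matrices(model: CMTFModel):
    out = {}
    for mode, attr in _MODE_ATTRS:
        m = getattr(model, attr)
        if m is not None:
            out[mode] = m
    return out


def _unit_cols(m):
    nrm = np.linalg.norm(m, axis=0, keepdims=True)
    return m / np.where(nrm == 0, 1.0, nrm)


def _match_on_modes(model1: CMTFModel, model2: CMTFModel, modes=None):
    """Assignment of model2 columns to model1 columns on a subset of modes."""
    m1, m2 = _mode_matrices(model1), _mode_matrices(model2)
    use = set(m1) & set(m2) if modes is None else set(modes)
    qs = {}
    for mode in use:
        if m1[mode].shape[0] != m2[mode].shape[0]:
            raise ValueError(f"mode {mode!r} dimensions differ")
        qs[mode] = _unit_cols(m1[mode]).T @ _unit_cols(m2[mode])
    qavg = np.mean([np.abs(q) for q in qs.values()], axis=0)
    rows, cols = linear_sum_assignment(-qavg)
    perm = np.empty(model1.rank, dtype=int)
    perm[rows] = cols
    return perm, qs, qavg


def match_components(model1: CMTFModel, model2: CMTFModel) -> ComponentMatch:
    """Pair the components of two fitted models.

    Maximizes, over one-to-one pairings, the total absolute congruence
    averaged across the non-subject modes. Each mode's congruence enters
    through its absolute value, because a CP component's per-mode sign is
    a gauge: flipping a loading vector together with the subject scores
    leaves the model unchanged, so two equivalent fits may disagree in
    sign mode by mode. Invariant to column permutation and sign flips of
    either model.

    The reported ``signs`` follow the biomarker mode (the convention
    mode); ``mode_congruence`` holds the raw signed congruence per mode at
    the matched pairs.
    """
    if model1.rank != model2.rank:
        raise ValueError("models have different ranks")
    m1, m2 = _mode_matrices(model1), _mode_matrices(model2)
    if set(m1) != set(m2):
        raise ValueError("models have different mode sets")
    perm, qs, qavg = _match_on_modes(model1, model2)
    overall = qavg[np.arange(model1.rank), perm]
    signs = np.sign(qs["biomarker"][np.arange(model1.rank), perm])
    signs[signs == 0] = 1.0
    mode_con = {
        mode: q[np.arange(model1.rank), perm] for mode, q in qs.items()
    }
    return ComponentMatch(
        permutation=perm, signs=signs, overall=overall, mode_congruence=mode_con
    )


# ---------------------------------------------------------------------------
# per-block subject scores
# ---------------------------------------------------------------------------

def _rowwise_lstsq(data, mask, design):
    """Min-norm least-squares scores per subject row on observed entries.

    Zero design columns (fully shrunk components) yield zero scores; rows
    with no observations yield NaN.
    """
    n = data.shape[0]
    R = design.shape[1]
    out = np.full((n, R), np.nan)
    full = mask.all()
    if full:
        sol, *_ = np.linalg.lstsq(design, data.T, rcond=None)
        return sol.T
    for i in range(n):
        m = mask[i]
        if not m.any():
            continue
        sol, *_ = np.linalg.lstsq(design[m], data[i, m], rcond=None)
        out[i] = sol
    return out


def block_scores(model: CMTFModel, dataset: MultiBlockDataset, block: str):
    """Block-specific subject scores: LS projection onto the block's loadings.

    For the tensor the design is the Khatri-Rao structure of B and C; for
    the matrix blocks it is D (with baseline gains) or E (with gene
    gains). Subjects with no observations in the block get NaN rows.
    """
    if block == "tensor":
        n, J, K = dataset.tensor.shape
        design = (model.B[:, None, :] * model.C[None, :, :]).reshape(J * K, -1)
        data = dataset.tensor.reshape(n, J * K)
        mask = dataset.tensor_mask.reshape(n, J * K)
        return _rowwise_lstsq(data, mask, design)
    if block == "baseline":
        g = model.baseline_gains if model.baseline_gains is not None else 1.0
        design = model.D * g
        mask = np.ones_like(dataset.baseline, dtype=bool)
        return _rowwise_lstsq(dataset.baseline, mask, design)
    if block == "gene":
        g = model.gene_gains if model.gene_gains is not None else 1.0
        design = model.E * g
        return _rowwise_lstsq(dataset.gene, dataset.gene_mask, design)
    raise ValueError(f"unknown block {block!r}")


# ---------------------------------------------------------------------------
# permutation association test
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    component: int
    block_pair: tuple
    statistic: float
    null_stats: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    method: str


def _abs_corr(x, y):
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 complete subject pairs")
    x, y = x[ok], y[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(abs(np.corrcoef(x, y)[0, 1]))


def _block_data(dataset: MultiBlockDataset, block: str):
    if block == "tensor":
        n = dataset.tensor.shape[0]
        return (
            dataset.tensor.reshape(n, -1),
            dataset.tensor_mask.reshape(n, -1),
        )
    if block == "baseline":
        return dataset.baseline, np.ones_like(dataset.baseline, dtype=bool)
    if block == "gene":
        return dataset.gene, dataset.gene_mask
    raise ValueError(f"unknown block {block!r}")


def _refit_scores(data, mask, anchor):
    """Refit the block's loading matrix on ``anchor`` scores, then project.

    Column-wise masked regression of the block on the anchor scores gives
    fresh loadings; row-wise masked LS on those loadings gives the
    block's subject scores. Both steps are closed-form, so they can be
    repeated for every permutation draw.
    """
    R = anchor.shape[1]
    md = np.where(mask, data, 0.0)
    if mask.all():
        G = anchor.T @ anchor
        L = np.linalg.lstsq(G, (md.T @ anchor).T, rcond=None)[0].T
    else:
        AA = anchor[:, :, None] * anchor[:, None, :]
        G = np.einsum("ip,irs->prs", mask, AA)
        h = md.T @ anchor
        L = np.empty((data.shape[1], R))
        for p in range(data.shape[1]):
            L[p] = np.linalg.lstsq(G[p], h[p], rcond=None)[0]
    return _rowwise_lstsq(data, mask, L)


def _loo_anchor_model(dataset, model, tested_block, seed, n_starts, max_iter, tol):
    """Refit the model with the tested block's weight set to zero.

    The resulting factors are a function of the untested blocks only, so
    subject scores derived from them are independent of the tested block
    under the no-association null — the property that makes the row
    permutation of the tested block an exact null.
    """
    from dataclasses import replace

    from .cmtf import align_components as _align
    from .cmtf import cmtf_fit as _fit
    from .preprocess import weight_blocks as _wb

    ds = dataset if dataset.block_weights is not None else _wb(dataset)
    w = np.array(ds.block_weights, dtype=float)
    w[{"tensor": 0, "baseline": 1, "gene": 2}[tested_block]] = 0.0
    ds0 = replace(ds, block_weights=w)
    anchor = _fit(
        ds0, rank=model.rank, lam=model.lam, n_starts=n_starts,
        tol=tol, max_iter=max_iter, seed=seed,
    )
    return _align(anchor, ds0)


_TESTED_MODES = {"tensor": ("biomarker", "time"), "baseline": ("baseline",), "gene": ("gene",)}


def permutation_association_test(
    dataset: MultiBlockDataset,
    model: CMTFModel,
    block_pair=("tensor", "baseline"),
    component: int = 0,
    n_perm: int = 9999,
    seed: int = 0,
    method: str = "loo",
    n_starts: int = 2,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> PermutationResult:
    """Pattern-to-pattern association between two blocks for one component.

    The observed statistic is the absolute Pearson correlation between the
    two blocks' subject scores for the component. The null is built by
    permuting the subject rows of the second block and recomputing the
    statistic; p = (1 + #{null >= observed}) / (1 + n_perm).

    Methods
    -------
    "loo" (default)
        Anchor scores come from a refit of the model with the tested
        block's weight set to zero, so they depend only on the untested
        blocks; the tested block's loadings are refit by closed-form
        regression on the anchor for the observed data and for every
        permutation draw. Exact permutation validity under an
        independent-blocks null, at the cost of one extra model fit.
    "refit"
        Anchor scores from the supplied joint model; tested-block
        loadings refit per draw. Cheaper, but the joint fit leaks the
        observed pairing into the anchor, inflating type-I error.
    "model"
        Both score sets projected onto the supplied model's own loadings,
        null by permuting the projected scores. Cheapest and most
        anti-conservative; kept for comparison.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    b1, b2 = block_pair
    if b1 == b2:
        raise ValueError("block pair must name two different blocks")
    if b2 == "tensor":
        b1, b2 = b2, b1  # permute the matrix block; the statistic is symmetric
    rng = np.random.default_rng(seed)
    data2, mask2 = _block_data(dataset, b2)

    if method == "model":
        s1 = block_scores(model, dataset, b1)[:, component]
        s2 = block_scores(model, dataset, b2)[:, component]
        obs = _abs_corr(s1, s2)
        null = np.empty(n_perm)
        for b in range(n_perm):
            null[b] = _abs_corr(s1, s2[rng.permutation(len(s2))])
    elif method in ("refit", "loo"):
        if method == "loo":
            fit_seed = int(rng.integers(2**31 - 1))
            anchor_model = _loo_anchor_model(
                dataset, model, b2, fit_seed, n_starts, max_iter, tol
            )
            # name the anchor component by matching to the reference model
            # on the modes the tested block does not touch
            modes = [
                m
                for m in dict(_MODE_ATTRS)
                if getattr(model, dict(_MODE_ATTRS)[m]) is not None
                and m not in _TESTED_MODES[b2]
            ]
            perm_map, _, _ = _match_on_modes(model, anchor_model, modes=modes)
            comp = int(perm_map[component])
            anchor = block_scores(anchor_model, dataset, b1)
        else:
            comp = component
            anchor = block_scores(model, dataset, b1)
        keep = np.isfinite(anchor).all(axis=1)
        if keep.sum() < 3:
            raise ValueError("fewer than 3 complete subject pairs")
        anchor = np.where(keep[:, None], anchor, 0.0)
        s1 = anchor[:, comp]
        s2 = _refit_scores(data2, mask2, anchor)[:, comp]
        obs = _abs_corr(s1, s2)
        null = np.empty(n_perm)
        for b in range(n_perm):
            p = rng.permutation(data2.shape[0])
            s2p = _refit_scores(data2[p], mask2[p], anchor)[:, comp]
            null[b] = _abs_corr(s1, s2p)
    else:
        raise ValueError(f"unknown method {method!r}")

    pval = (1.0 + float((null >= obs).sum())) / (1.0 + n_perm)
    return PermutationResult(
        component=component,
        block_pair=(b1, b2),
        statistic=obs,
        null_stats=null,
        p_value=pval,
        n_perm=n_perm,
        seed=seed,
        method=method,
    )


# ---------------------------------------------------------------------------
# split-half consistency
# ---------------------------------------------------------------------------

@dataclass
class SplitHalfResult:
    per_split: list = field(default_factory=list)
    median_congruence: pd.DataFrame | None = None
    worst_p: pd.DataFrame | None = None
    n_splits: int = 0
    seed: int = 0


def _prepare_half(ds_half: MultiBlockDataset, full: MultiBlockDataset):
    """Standardize a subject half, re-inserting any dropped columns as zeros
    so the two halves' loading matrices stay dimension-compatible."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = transform_and_scale(ds_half)
    if out.baseline_vars != full.baseline_vars:
        M = len(full.baseline_vars)
        bl = np.zeros((out.n_subjects, M))
        for j, name in enumerate(full.baseline_vars):
            if name in out.baseline_vars:
                bl[:, j] = out.baseline[:, out.baseline_vars.index(name)]
        out.baseline = bl
        out.baseline_vars = list(full.baseline_vars)
    if out.snps != full.snps:
        P = len(full.snps)
        gn = np.zeros((out.n_subjects, P))
        gm = np.zeros((out.n_subjects, P), dtype=bool)
        for j, name in enumerate(full.snps):
            if name in out.snps:
                k = out.snps.index(name)
                gn[:, j] = out.gene[:, k]
                gm[:, j] = out.gene_mask[:, k]
        out.gene = gn
        out.gene_mask = gm
        out.snps = list(full.snps)
    return weight_blocks(out)


def _fit_half(ds_half, full, rank, lam, seed, n_starts, max_iter, tol):
    prepped = _prepare_half(ds_half, full)
    model = cmtf_fit(
        prepped, rank=rank, lam=lam, n_starts=n_starts,
        tol=tol, max_iter=max_iter, seed=seed,
    )
    return align_components(model, prepped)


def _column_permuted(ds: MultiBlockDataset, rng) -> MultiBlockDataset:
    """Destroy within- and cross-block subject linkage: every variable
    column gets its own independent subject permutation."""
    n, J, K = ds.tensor.shape
    tensor = ds.tensor.copy()
    tmask = ds.tensor_mask.copy()
    for j in range(J):
        for k in range(K):
            p = rng.permutation(n)
            tensor[:, j, k] = tensor[p, j, k]
            tmask[:, j, k] = tmask[p, j, k]
    # a subject may lose all observations; give it back one random cell
    empty = ~tmask.any(axis=(1, 2))
    for i in np.flatnonzero(empty):
        j, k = rng.integers(J), rng.integers(K)
        tmask[i, j, k] = True
    baseline = ds.baseline.copy()
    for m in range(baseline.shape[1]):
        baseline[:, m] = baseline[rng.permutation(n), m]
    gene = ds.gene.copy()
    gmask = ds.gene_mask.copy()
    for p_ in range(gene.shape[1]):
        perm = rng.permutation(n)
        gene[:, p_] = gene[perm, p_]
        gmask[:, p_] = gmask[perm, p_]
    from dataclasses import replace

    return replace(
        ds, tensor=tensor, tensor_mask=tmask, baseline=baseline,
        gene=gene, gene_mask=gmask, block_weights=None,
    )


def split_half_once(
    dataset: MultiBlockDataset,
    idx1,
    idx2,
    rank: int = 2,
    lam: float = 0.0,
    seed: int = 0,
    n_null: int = 19,
    n_starts: int = 2,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> dict:
    """Fit independent models on two subject sets and compare their patterns.

    Returns a dict with matched per-mode congruences, consistency
    p-values (if ``n_null`` > 0) against a null of congruences from
    models fit on column-permuted data, and the gene supports selected in
    each half.
    """
    rng = np.random.default_rng(seed)
    ds1 = dataset.subset_subjects(np.asarray(idx1))
    ds2 = dataset.subset_subjects(np.asarray(idx2))
    fit_seed = int(rng.integers(2**31 - 1))
    m1 = _fit_half(ds1, dataset, rank, lam, fit_seed, n_starts, max_iter, tol)
    m2 = _fit_half(ds2, dataset, rank, lam, fit_seed, n_starts, max_iter, tol)
    match = match_components(m1, m2)

    null_con = {mode: [] for mode in match.mode_congruence}
    for _ in range(n_null):
        ds2n = _column_permuted(ds2, rng)
        null_seed = int(rng.integers(2**31 - 1))
        mn = _fit_half(ds2n, dataset, rank, lam, null_seed, n_starts, max_iter, tol)
        nmatch = match_components(m1, mn)
        for mode, vals in nmatch.mode_congruence.items():
            null_con[mode].append(np.abs(vals))

    pvals = {}
    for mode, vals in match.mode_congruence.items():
        if n_null > 0:
            nulls = np.array(null_con[mode])  # (n_null, R)
            obs = np.abs(vals)
            pvals[mode] = (1.0 + (nulls >= obs[None, :]).sum(axis=0)) / (1.0 + n_null)
        else:
            pvals[mode] = np.full(len(vals), np.nan)

    sel1 = [
        set(np.flatnonzero(m1.E[:, r] != 0)) for r in range(rank)
    ]
    sel2 = [
        set(np.flatnonzero(m2.E[:, match.permutation[r]] != 0)) for r in range(rank)
    ]
    return {
        "congruence": match.mode_congruence,
        "p_values": pvals,
        "gene_support_1": sel1,
        "gene_support_2": sel2,
        "models": (m1, m2),
        "match": match,
        "seed": seed,
    }


def split_half_consistency(
    dataset: MultiBlockDataset,
    rank: int = 2,
    lam: float = 0.0,
    n_splits: int = 20,
    seed: int = 0,
    n_null: int = 19,
    n_starts: int = 2,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> SplitHalfResult:
    """Repeated random split-half validation, aggregated.

    Subjects are randomly split into two (near-)equal halves ``n_splits``
    times; each split is analysed with :func:`split_half_once`. Summaries
    are the median matched congruence and the worst-case p-value per mode
    and component. Deterministic given ``seed``.
    """
    n = dataset.n_subjects
    if n < 8:
        raise ValueError("need >= 8 subjects for split-half validation")
    rng = np.random.default_rng(seed)
    per_split = []
    for s in range(n_splits):
        perm = rng.permutation(n)
        half = (n + 1) // 2
        rec = split_half_once(
            dataset, np.sort(perm[:half]), np.sort(perm[half:]),
            rank=rank, lam=lam, seed=int(rng.integers(2**31 - 1)),
            n_null=n_null, n_starts=n_starts, max_iter=max_iter, tol=tol,
        )
        rec.pop("models")
        per_split.append(rec)

    modes = list(per_split[0]["congruence"].keys())
    med = pd.DataFrame(
        {
            mode: np.median(
                np.abs([rec["congruence"][mode] for rec in per_split]), axis=0
            )
            for mode in modes
        }
    )
    worst = pd.DataFrame(
        {
            mode: np.max([rec["p_values"][mode] for rec in per_split], axis=0)
            for mode in modes
        }
    )
    return SplitHalfResult(
        per_split=per_split,
        median_congruence=med,
        worst_p=worst,
        n_splits=n_splits,
        seed=seed,
    )


def gene_selection_homogeneity(selected1, selected2, universe):
    """Agreement of two gene selections by Fisher's exact test.

    Builds the 2x2 table (selected/not in half 1 x half 2) over the SNP
    universe and returns (odds_ratio, p_value). Degenerate tables (e.g.
    both halves select everything) give p = 1 by convention.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty SNP universe")
    s1, s2 = set(selected1), set(selected2)
    if not s1 <= universe or not s2 <= universe:
        raise ValueError("selections must be subsets of the universe")
    a = len(s1 & s2)
    b = len(s1 - s2)
    c = len(s2 - s1)
    d = len(universe - s1 - s2)
    odds, p = fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds), float(p)
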