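"""Masked CP decomposition and sparse coupled matrix-tensor factorization.

The model couples a subjects x biomarkers x timepoints tensor X with a
baseline matrix Y (subjects x M) and a genotype matrix Z (subjects x P)
through a shared subject score matrix A:

    X ~ [[A, B, C]]        (CP / PARAFAC structure)
    Y ~ A D'
    Z ~ A E'

fitted by block-coordinate (alternating) least squares on observed
entries only, minimizing

    F = w1 |Wx o (X - [[A,B,C]])|^2 + w2 |Y - A D'|^2 + w3 |Wz o (Z - A E')|^2
        + lambda (|B|_1 + |D|_1 + |E|_1) + rho (|A|^2 + |C|^2)

The L1 penalty on the variable modes (biomarkers, baseline, genes) sets
small loadings exactly to zero via coordinate-wise soft-thresholding, so
each component reflects only a subset of variables. The small ridge on
the unpenalized modes (rho proportional to lambda) pins the scale
indeterminacy that would otherwise let the subject mode absorb the
penalty. The time mode C is never sparsified: patterns over the four
visits stay dense.

Every sweep minimizes each block of coordinates exactly (or descends, for
the penalized coordinate updates), so the penalized objective is
non-increasing across sweeps — an invariant the test-suite asserts on
every fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import MultiBlockDataset

__all__ = [
    "CMTFModel",
    "ComponentPattern",
    "cp_als",
    "cmtf_fit",
    "explained_variation",
    "align_components",
    "component_patterns",
    "select_lambda",
    "DEFAULT_LAMBDA_GRID",
]

#: log-spaced penalty grid searched by :func:`select_lambda`
DEFAULT_LAMBDA_GRID = tuple(np.logspace(-4, -1, 7))

_RIDGE_FRAC = 0.01  # rho = _RIDGE_FRAC * lambda


@dataclass
class CMTFModel:
    """Fitted factors of a (coupled) CP model.

    A holds subject scores (components in columns); B, C biomarker and
    time loadings; D, E baseline and gene loadings (None for tensor-only
    models). After :func:`align_components`, non-subject columns are
    unit-norm (or exactly zero), tensor scale lives in A, and
    ``baseline_gains`` / ``gene_gains`` carry each matrix block's
    per-component strength so reconstruction is unchanged.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray | None = None
    E: np.ndarray | None = None
    baseline_gains: np.ndarray | None = None
    gene_gains: np.ndarray | None = None
    rank: int = 0
    lam: float = 0.0
    ridge: float = 0.0
    block_weights: np.ndarray | None = None
    loss_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = False
    n_iter: int = 0
    seed: int | None = None

    def __post_init__(self):
        if self.rank == 0:
            self.rank = self.A.shape[1]

    @property
    def coupled(self) -> bool:
        return self.D is not None

    def tensor_hat(self) -> np.ndarray:
        return np.einsum("ir,jr,kr->ijk", self.A, self.B, self.C)

    def baseline_hat(self) -> np.ndarray:
        g = self.baseline_gains if self.baseline_gains is not None else 1.0
        return (self.A * g) @ self.D.T

    def gene_hat(self) -> np.ndarray:
        g = self.gene_gains if self.gene_gains is not None else 1.0
        return (self.A * g) @ self.E.T


class DimensionError(ValueError):
    pass


def _soft(x, t):
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def _thresh(lam, w):
    # a zero-weight block contributes no fit term; its penalized loadings
    # shrink all the way to zero
    return lam / (2 * w) if w > 0 else np.inf


def _solve_rows(G, h, ridge=0.0):
    """Solve (G_i + ridge I) x_i = h_i for every row i; G is (n,R,R) or (R,R)."""
    R = h.shape[1]
    eye = np.eye(R)
    if G.ndim == 2:
        G = G[None]
    try:
        return np.linalg.solve(G + ridge * eye, h[..., None])[..., 0]
    except np.linalg.LinAlgError:
        return np.linalg.solve(G + (ridge + 1e-10) * eye, h[..., None])[..., 0]


# ---------------------------------------------------------------------------
# gram/rhs builders (masked with full-mask fast paths)
# ---------------------------------------------------------------------------

def _tensor_grams_mode0(X, W, full, B, C):
    """Per-subject gram and rhs for the A update from the tensor block."""
    if full:
        G = (B.T @ B) * (C.T @ C)  # (R,R), shared
        h = np.einsum("ijk,jr,kr->ir", X, B, C)
        return G, h
    BB = B[:, :, None] * B[:, None, :]
    CC = C[:, :, None] * C[:, None, :]
    G = np.einsum("ijk,jrs,krs->irs", W, BB, CC)
    h = np.einsum("ijk,jr,kr->ir", X, B, C)
    return G, h


def _tensor_grams_mode1(X, W, full, A, C):
    if full:
        G = (A.T @ A) * (C.T @ C)
        h = np.einsum("ijk,ir,kr->jr", X, A, C)
        return G, h
    AA = A[:, :, None] * A[:, None, :]
    CC = C[:, :, None] * C[:, None, :]
    G = np.einsum("ijk,irs,krs->jrs", W, AA, CC)
    h = np.einsum("ijk,ir,kr->jr", X, A, C)
    return G, h


def _tensor_grams_mode2(X, W, full, A, B):
    if full:
        G = (A.T @ A) * (B.T @ B)
        h = np.einsum("ijk,ir,jr->kr", X, A, B)
        return G, h
    AA = A[:, :, None] * A[:, None, :]
    BB = B[:, :, None] * B[:, None, :]
    G = np.einsum("ijk,irs,jrs->krs", W, AA, BB)
    h = np.einsum("ijk,ir,jr->kr", X, A, B)
    return G, h


def _matrix_grams_cols(Z, Wz, full, A):
    """Gram/rhs for loading-matrix update (rows of D or E)."""
    if full:
        return A.T @ A, Z.T @ A
    AA = A[:, :, None] * A[:, None, :]
    G = np.einsum("ip,irs->prs", Wz, AA)
    h = Z.T @ A
    return G, h


def _cd_sparse_rows(M, G, h, thresh, sweeps=50, tol=1e-12):
    """Exact cyclic coordinate descent for rows of a penalized loading matrix.

    Minimizes per row m:  m' G m - 2 h' m + (2*thresh) |m|_1  (up to the
    fit-term weight folded into ``thresh``); every coordinate update is an
    exact 1-D minimization, hence descent.
    """
    R = M.shape[1]
    shared = G.ndim == 2
    for _ in range(sweeps):
        delta = 0.0
        for r in range(R):
            if shared:
                Grr = np.full(M.shape[0], G[r, r])
                off = M @ G[:, r] - M[:, r] * G[r, r]
            else:
                Grr = G[:, r, r]
                off = np.einsum("ps,ps->p", G[:, r, :], M) - M[:, r] * Grr
            num = h[:, r] - off
            with np.errstate(invalid="ignore", divide="ignore"):
                new = np.where(Grr > 1e-300, _soft(num, thresh) / np.where(Grr > 1e-300, Grr, 1.0), 0.0)
            delta = max(delta, float(np.max(np.abs(new - M[:, r]), initial=0.0)))
            M[:, r] = new
        if delta < tol:
            break
    return M


# ---------------------------------------------------------------------------
# the ALS engine
# ---------------------------------------------------------------------------

def _penalized_loss(X, Wx, fullx, Y, Z, Wz, fullz, w, A, B, C, D, E, lam, rho):
    Xhat = np.einsum("ir,jr,kr->ijk", A, B, C)
    res = X - Xhat if fullx else np.where(Wx, X - Xhat, 0.0)
    loss = w[0] * float((res**2).sum())
    if Y is not None:
        loss += w[1] * float(((Y - A @ D.T) ** 2).sum())
        rz = Z - A @ E.T if fullz else np.where(Wz, Z - A @ E.T, 0.0)
        loss += w[2] * float((rz**2).sum())
        loss += lam * (np.abs(B).sum() + np.abs(D).sum() + np.abs(E).sum())
    else:
        loss += lam * np.abs(B).sum()
    loss += rho * (float((A**2).sum()) + float((C**2).sum()))
    return loss


def _als_single(
    X, Wx, Y, Z, Wz, w, rank, lam, rho, init, tol, max_iter, cd_sweeps=30
):
    fullx = bool(Wx.all())
    fullz = bool(Wz.all()) if Wz is not None else True
    Xz = X if fullx else np.where(Wx, X, 0.0)
    Zz = None
    if Y is not None:
        Zz = Z if fullz else np.where(Wz, Z, 0.0)
    A, B, C, D, E = (m.copy() if m is not None else None for m in init)
    coupled = Y is not None

    trace = []
    prev = np.inf
    converged = False
    for it in range(max_iter):
        # --- A (subject scores; exact ridge LS per subject) -------------
        Gt, ht = _tensor_grams_mode0(Xz, Wx, fullx, B, C)
        if coupled:
            Gy = D.T @ D
            hy = Y @ D
            if fullz:
                Gz_a = E.T @ E
            else:  # per-subject gram over that subject's observed SNPs
                EE = E[:, :, None] * E[:, None, :]
                Gz_a = np.einsum("ip,prs->irs", Wz, EE)
            hz_a = Zz @ E
            G = w[0] * Gt + w[1] * Gy + w[2] * Gz_a
            h = w[0] * ht + w[1] * hy + w[2] * hz_a
        else:
            G = w[0] * Gt
            h = w[0] * ht
        A = _solve_rows(G, h, ridge=rho)

        # --- B (biomarker loadings; L1 coordinate descent) --------------
        Gb, hb = _tensor_grams_mode1(Xz, Wx, fullx, A, C)
        if lam > 0:
            B = _cd_sparse_rows(B, Gb, hb, thresh=_thresh(lam, w[0]), sweeps=cd_sweeps)
        else:
            B = _solve_rows(Gb, hb, ridge=0.0)

        # --- C (time loadings; dense ridge LS) ---------------------------
        Gc, hc = _tensor_grams_mode2(Xz, Wx, fullx, A, B)
        C = _solve_rows(w[0] * Gc, w[0] * hc, ridge=rho)

        if coupled:
            # --- D (baseline loadings; L1) -------------------------------
            Gd, hd = A.T @ A, Y.T @ A
            if lam > 0:
                D = _cd_sparse_rows(D, Gd, hd, thresh=_thresh(lam, w[1]), sweeps=cd_sweeps)
            else:
                D = _solve_rows(Gd, hd)
            # --- E (gene loadings; L1, masked) ---------------------------
            Ge, he = _matrix_grams_cols(Zz, Wz, fullz, A)
            if lam > 0:
                E = _cd_sparse_rows(E, Ge, he, thresh=_thresh(lam, w[2]), sweeps=cd_sweeps)
            else:
                E = _solve_rows(Ge, he)

        loss = _penalized_loss(
            X, Wx, fullx, Y, Zz, Wz, fullz, w, A, B, C, D, E, lam, rho
        )
        trace.append(loss)
        if np.isfinite(prev) and prev - loss <= tol * max(prev, 1e-30):
            converged = True
            break
        prev = loss
    return A, B, C, D, E, np.array(trace), converged


def _spectral_init(Xz, rank, rng):
    """Initialize B, C from singular vectors of the zero-filled unfoldings."""
    n, J, K = Xz.shape
    u2, _, _ = np.linalg.svd(np.moveaxis(Xz, 1, 0).reshape(J, n * K), full_matrices=False)
    u3, _, _ = np.linalg.svd(np.moveaxis(Xz, 2, 0).reshape(K, n * J), full_matrices=False)
    B = u2[:, :rank].copy()
    C = u3[:, :rank].copy()
    if B.shape[1] < rank:  # degenerate, pad randomly
        B = np.hstack([B, rng.standard_normal((J, rank - B.shape[1]))])
    if C.shape[1] < rank:
        C = np.hstack([C, rng.standard_normal((K, rank - C.shape[1]))])
    return B, C


def _unit_columns(M):
    nrm = np.linalg.norm(M, axis=0, keepdims=True)
    return M / np.where(nrm == 0, 1.0, nrm)


def _check_rank(rank, dims):
    if rank < 1:
        raise DimensionError("rank must be >= 1")
    for name, d in dims.items():
        if rank > d:
            raise DimensionError(f"rank {rank} exceeds mode {name} (={d})")


def _multi_start(
    X, Wx, Y, Z, Wz, w, rank, lam, n_starts, tol, max_iter, seed
):
    if not Wx.any(axis=(1, 2)).all():
        raise ValueError("every subject needs >= 1 observed tensor entry")
    rho = _RIDGE_FRAC * lam
    rng = np.random.default_rng(seed)
    n, J, K = X.shape
    Xz = np.where(Wx, X, 0.0)
    best = None
    for s in range(n_starts):
        if s == 0:
            B0, C0 = _spectral_init(Xz, rank, rng)
        else:
            B0 = _unit_columns(rng.standard_normal((J, rank)))
            C0 = _unit_columns(rng.standard_normal((K, rank)))
        A0 = np.zeros((n, rank))
        D0 = np.zeros((Y.shape[1], rank)) if Y is not None else None
        E0 = np.zeros((Z.shape[1], rank)) if Y is not None else None
        out = _als_single(
            X, Wx, Y, Z, Wz, w, rank, lam, rho,
            (A0, B0, C0, D0, E0), tol, max_iter,
        )
        if best is None or out[5][-1] < best[5][-1]:
            best = out
    A, B, C, D, E, trace, converged = best
    return CMTFModel(
        A=A, B=B, C=C, D=D, E=E, rank=rank, lam=lam, ridge=rho,
        block_weights=np.asarray(w, dtype=float), loss_trace=trace,
        converged=converged, n_iter=len(trace), seed=seed,
    )


def cp_als(
    tensor,
    mask=None,
    rank: int = 2,
    n_starts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
) -> CMTFModel:
    """Masked CP/PARAFAC decomposition by alternating least squares.

    Fits ``tensor ~ [[A, B, C]]`` on observed entries only, returning the
    best of ``n_starts`` runs (one spectral-initialized, the rest random)
    by final loss. Deterministic given ``seed``.
    """
    X = np.asarray(tensor, dtype=float)
    if X.ndim != 3:
        raise DimensionError("tensor must be 3-way")
    W = np.ones(X.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    n, J, K = X.shape
    _check_rank(rank, {"subjects": n, "biomarkers": J, "timepoints": K})
    return _multi_start(
        X, W, None, None, None, (1.0, 0.0, 0.0), rank, 0.0,
        n_starts, tol, max_iter, seed,
    )


def cmtf_fit(
    dataset: MultiBlockDataset,
    rank: int = 2,
    lam: float = 0.0,
    n_starts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
) -> CMTFModel:
    """Sparse coupled matrix-tensor factorization of a weighted dataset.

    Minimizes the weighted sum of masked squared reconstruction errors of
    the three blocks over shared subject scores A and mode loadings
    B, C, D, E, with an L1 penalty ``lam`` on the variable modes (B, D, E)
    that sets small loadings exactly to zero.

    The dataset should be standardized and weighted (see
    :func:`sparsecmtf.preprocess.prepare`); if block weights are absent,
    equal-contribution weights are computed on the fly.
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    ds = dataset
    if ds.block_weights is None:
        from .preprocess import weight_blocks

        ds = weight_blocks(ds)
    n, J, K = ds.tensor.shape
    _check_rank(
        rank,
        {
            "subjects": n,
            "biomarkers": J,
            "timepoints": K,
            "baseline": ds.baseline.shape[1],
            "genes": ds.gene.shape[1],
        },
    )
    return _multi_start(
        ds.tensor, ds.tensor_mask, ds.baseline, ds.gene, ds.gene_mask,
        tuple(ds.block_weights), rank, lam, n_starts, tol, max_iter, seed,
    )


# ---------------------------------------------------------------------------
# explained variation, alignment, patterns
# ---------------------------------------------------------------------------

def _block_res_tot(model: CMTFModel, ds, block: str):
    if block == "tensor":
        if isinstance(ds, np.ndarray):
            X, W = ds, np.ones(ds.shape, dtype=bool)
        elif isinstance(ds, tuple):
            X, W = ds
        else:
            X, W = ds.tensor, ds.tensor_mask
        if X.shape != model.tensor_hat().shape:
            raise ValueError("tensor dimensions do not match the model")
        res = np.where(W, X - model.tensor_hat(), 0.0)
        tot = np.where(W, X, 0.0)
        return float((res**2).sum()), float((tot**2).sum())
    if not model.coupled:
        raise ValueError(f"model has no {block!r} block")
    if block == "baseline":
        if ds.baseline.shape != (model.A.shape[0], model.D.shape[0]):
            raise ValueError("baseline dimensions do not match the model")
        res = ds.baseline - model.baseline_hat()
        return float((res**2).sum()), float((ds.baseline**2).sum())
    if block == "gene":
        if ds.gene.shape != (model.A.shape[0], model.E.shape[0]):
            raise ValueError("gene dimensions do not match the model")
        res = np.where(ds.gene_mask, ds.gene - model.gene_hat(), 0.0)
        tot = np.where(ds.gene_mask, ds.gene, 0.0)
        return float((res**2).sum()), float((tot**2).sum())
    raise ValueError(f"unknown block {block!r}")


def explained_variation(model: CMTFModel, dataset, block: str = "tensor") -> float:
    """Percent of observed-entry variation explained for the named block.

    ``block`` in {"tensor", "baseline", "gene", "total"}; "total" combines
    the blocks with the model's weights.
    """
    if block == "total":
        w = model.block_weights if model.block_weights is not None else np.ones(3)
        names = ["tensor", "baseline", "gene"] if model.coupled else ["tensor"]
        res = tot = 0.0
        for b, wb in zip(names, w):
            r, t = _block_res_tot(model, dataset, b)
            res += wb * r
            tot += wb * t
        return 100.0 * (1.0 - res / tot)
    res, tot = _block_res_tot(model, dataset, block)
    return 100.0 * (1.0 - res / tot)


def _component_tensor_ev(model: CMTFModel, ds) -> np.ndarray:
    """Explained tensor variation (%) of each component used alone."""
    if isinstance(ds, np.ndarray):
        X, W = ds, np.ones(ds.shape, dtype=bool)
    elif isinstance(ds, tuple):
        X, W = ds
    else:
        X, W = ds.tensor, ds.tensor_mask
    tot = float((np.where(W, X, 0.0) ** 2).sum())
    out = np.empty(model.rank)
    for r in range(model.rank):
        hat = np.einsum(
            "i,j,k->ijk", model.A[:, r], model.B[:, r], model.C[:, r]
        )
        res = np.where(W, X - hat, 0.0)
        out[r] = 100.0 * (1.0 - float((res**2).sum()) / tot)
    return out


def align_components(model: CMTFModel, dataset=None) -> CMTFModel:
    """Resolve CP scale/sign/permutation indeterminacy.

    Normalizes B and C columns to unit norm (absorbing the tensor scale
    into A), normalizes D and E storing their per-component strengths in
    ``baseline_gains`` / ``gene_gains``, applies the sign convention (the
    largest-magnitude biomarker loading of each component is positive) and
    orders components by tensor-block explained variation (descending)
    when a dataset is supplied, else by tensor component scale.
    Reconstruction is unchanged to within 1e-10. Idempotent.
    """
    A = model.A.copy()
    B = model.B.copy()
    C = model.C.copy()
    D = model.D.copy() if model.D is not None else None
    E = model.E.copy() if model.E is not None else None
    gD = (
        model.baseline_gains.copy()
        if model.baseline_gains is not None
        else (np.ones(model.rank) if D is not None else None)
    )
    gE = (
        model.gene_gains.copy()
        if model.gene_gains is not None
        else (np.ones(model.rank) if E is not None else None)
    )
    R = model.rank
    for r in range(R):
        nb = np.linalg.norm(B[:, r])
        nc = np.linalg.norm(C[:, r])
        sb = nb if nb > 0 else 1.0
        sc = nc if nc > 0 else 1.0
        B[:, r] /= sb
        C[:, r] /= sc
        A[:, r] *= sb * sc
        if D is not None:
            nd = np.linalg.norm(D[:, r]) * abs(gD[r])
            dvec = D[:, r] * gD[r]
            D[:, r] = dvec / nd if nd > 0 else 0.0
            gD[r] = nd / (sb * sc)
        if E is not None:
            ne = np.linalg.norm(E[:, r]) * abs(gE[r])
            evec = E[:, r] * gE[r]
            E[:, r] = evec / ne if ne > 0 else 0.0
            gE[r] = ne / (sb * sc)
        # sign conventions: largest-|.| biomarker loading positive (flip
        # shared with A so the tensor is intact; D/E flip along with A to
        # preserve the matrix blocks), then largest-|.| time loading
        # positive (flip shared between C and A, D/E again following A) —
        # pinning both modes removes the residual joint A/C sign gauge
        if nb > 0:
            jmax = int(np.argmax(np.abs(B[:, r])))
            if B[jmax, r] < 0:
                B[:, r] *= -1
                A[:, r] *= -1
                if D is not None:
                    D[:, r] *= -1
                if E is not None:
                    E[:, r] *= -1
        if nc > 0:
            kmax = int(np.argmax(np.abs(C[:, r])))
            if C[kmax, r] < 0:
                C[:, r] *= -1
                A[:, r] *= -1
                if D is not None:
                    D[:, r] *= -1
                if E is not None:
                    E[:, r] *= -1

    tmp = replace(model, A=A, B=B, C=C, D=D, E=E, baseline_gains=gD, gene_gains=gE)
    if dataset is not None:
        order = np.argsort(-_component_tensor_ev(tmp, dataset), kind="stable")
    else:
        order = np.argsort(-np.linalg.norm(A, axis=0), kind="stable")
    return replace(
        tmp,
        A=A[:, order],
        B=B[:, order],
        C=C[:, order],
        D=D[:, order] if D is not None else None,
        E=E[:, order] if E is not None else None,
        baseline_gains=gD[order] if gD is not None else None,
        gene_gains=gE[order] if gE is not None else None,
    )


@dataclass
class ComponentPattern:
    """One component's loadings across modes, after alignment."""

    index: int
    biomarker: pd.Series
    time: pd.Series
    baseline: pd.Series | None
    gene: pd.Series | None
    explained_variation: float

    def nonzero_gene_names(self) -> list:
        if self.gene is None:
            return []
        return list(self.gene.index[self.gene != 0.0])


def component_patterns(model: CMTFModel, dataset) -> list:
    """Extract per-component loading patterns from an aligned model."""
    ev = _component_tensor_ev(model, dataset)
    labels = dataset if isinstance(dataset, MultiBlockDataset) else None
    pats = []
    for r in range(model.rank):
        bm = pd.Series(
            model.B[:, r],
            index=labels.biomarkers if labels else range(model.B.shape[0]),
            name=f"component_{r + 1}",
        )
        tm = pd.Series(
            model.C[:, r],
            index=labels.times if labels else range(model.C.shape[0]),
        )
        bl = gn = None
        if model.coupled:
            gd = model.baseline_gains[r] if model.baseline_gains is not None else 1.0
            ge = model.gene_gains[r] if model.gene_gains is not None else 1.0
            bl = pd.Series(
                model.D[:, r] * np.sign(gd) if gd else model.D[:, r],
                index=labels.baseline_vars if labels else range(model.D.shape[0]),
            )
            gn = pd.Series(
                model.E[:, r] * np.sign(ge) if ge else model.E[:, r],
                index=labels.snps if labels else range(model.E.shape[0]),
            )
        pats.append(
            ComponentPattern(
                index=r,
                biomarker=bm,
                time=tm,
                baseline=bl,
                gene=gn,
                explained_variation=float(ev[r]),
            )
        )
    return pats


# ---------------------------------------------------------------------------
# penalty selection by split-half stability
# ---------------------------------------------------------------------------

def select_lambda(
    dataset: MultiBlockDataset,
    rank: int = 2,
    grid=DEFAULT_LAMBDA_GRID,
    n_splits: int = 3,
    seed: int = 0,
    n_starts: int = 2,
    max_iter: int = 200,
    tol: float = 1e-6,
    stability_tol: float = 0.05,
):
    """Choose the L1 penalty by split-half component stability.

    For each candidate penalty, subjects are randomly halved ``n_splits``
    times, a model is fitted on each half, components are matched, and the
    mean absolute congruence over the sparse variable modes is recorded.
    The largest penalty whose median stability is within
    ``stability_tol`` of the best over the grid is selected (favouring the
    sparsest model among equally stable ones).

    Returns (lam, table) where table is a DataFrame of per-penalty
    stability scores.
    """
    from .validation import match_components  # local import, avoids cycle

    rng = np.random.default_rng(seed)
    n = dataset.n_subjects
    splits = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        half = (n + 1) // 2
        splits.append((perm[:half], perm[half:]))

    rows = []
    for lam in grid:
        scores = []
        for idx1, idx2 in splits:
            sub_seed = int(rng.integers(2**31 - 1))
            stats = []
            models = []
            for idx in (idx1, idx2):
                half_ds = dataset.subset_subjects(np.sort(idx))
                from .preprocess import weight_blocks

                half_ds = weight_blocks(half_ds)
                models.append(
                    align_components(
                        cmtf_fit(
                            half_ds, rank=rank, lam=lam, n_starts=n_starts,
                            tol=tol, max_iter=max_iter, seed=sub_seed,
                        ),
                        half_ds,
                    )
                )
            match = match_components(models[0], models[1])
            for mode in ("biomarker", "baseline", "gene"):
                stats.append(np.abs(match.mode_congruence[mode]).mean())
            scores.append(float(np.mean(stats)))
        rows.append({"lam": float(lam), "stability": float(np.median(scores))})
    tab = pd.DataFrame(rows)
    best = tab["stability"].max()
    ok = tab[tab["stability"] >= best - stability_tol]
    lam = float(ok["lam"].max())
    return lam, tab
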