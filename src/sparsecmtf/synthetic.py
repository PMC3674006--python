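"""Synthetic coupled three-block cohorts with known latent structure.

The generator emulates the shape of a remission-phase T1D cohort: ~129
subjects with up to 20 paraclinical biomarkers measured 1, 3, 6 and 12
months after diagnosis (with entry-level missingness, every subject
keeping at least one measurement), ~10 baseline characteristics and 51
SNP genotypes coded 0/1/2 — all driven by a low-rank latent structure
shared across blocks through the subject mode, with sparse loadings in
the variable modes and Gaussian residual noise.

Ground truth is returned alongside the dataset so factor-recovery,
support-recovery and validation calibration are all testable without any
patient-level data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .preprocess import DEFAULT_TIME_GRID, MultiBlockDataset

__all__ = ["GroundTruth", "generate_cohort", "planted_cohort", "DimensionError"]


class DimensionError(ValueError):
    """Requested rank exceeds a mode dimension, or dims are inconsistent."""


@dataclass
class GroundTruth:
    """Generating factors and nuisance parameters of a synthetic cohort.

    Non-subject loading columns have unit Euclidean norm; sparse modes
    (biomarker, baseline, gene) contain exact zeros at the designated
    positions. Component strength lives in ``subject_scores``.
    """

    subject_scores: np.ndarray  # n x R
    biomarker_loadings: np.ndarray  # J x R
    time_loadings: np.ndarray  # K x R
    baseline_loadings: np.ndarray  # M x R
    gene_loadings: np.ndarray  # P x R
    noise_sd_per_block: tuple
    missing_rate: float
    seed: int

    @property
    def rank(self) -> int:
        return self.subject_scores.shape[1]

    def tensor_signal(self) -> np.ndarray:
        return np.einsum(
            "ir,jr,kr->ijk",
            self.subject_scores,
            self.biomarker_loadings,
            self.time_loadings,
        )

    def baseline_signal(self) -> np.ndarray:
        return self.subject_scores @ self.baseline_loadings.T

    def gene_signal(self) -> np.ndarray:
        return self.subject_scores @ self.gene_loadings.T

    def to_json(self) -> str:
        d = {
            "subject_scores": self.subject_scores.tolist(),
            "biomarker_loadings": self.biomarker_loadings.tolist(),
            "time_loadings": self.time_loadings.tolist(),
            "baseline_loadings": self.baseline_loadings.tolist(),
            "gene_loadings": self.gene_loadings.tolist(),
            "noise_sd_per_block": list(self.noise_sd_per_block),
            "missing_rate": self.missing_rate,
            "seed": self.seed,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "GroundTruth":
        d = json.loads(s)
        return cls(
            subject_scores=np.array(d["subject_scores"]),
            biomarker_loadings=np.array(d["biomarker_loadings"]),
            time_loadings=np.array(d["time_loadings"]),
            baseline_loadings=np.array(d["baseline_loadings"]),
            gene_loadings=np.array(d["gene_loadings"]),
            noise_sd_per_block=tuple(d["noise_sd_per_block"]),
            missing_rate=d["missing_rate"],
            seed=d["seed"],
        )


def _sparse_loadings(rng, dim, rank, zero_frac):
    """Unit-norm columns with an exact ``zero_frac`` fraction of zeros each."""
    x = rng.standard_normal((dim, rank))
    n_zero = int(round(zero_frac * dim))
    n_zero = min(n_zero, dim - 1)  # keep >=1 nonzero so unit norm exists
    for r in range(rank):
        if n_zero > 0:
            zero_idx = rng.choice(dim, size=n_zero, replace=False)
            x[zero_idx, r] = 0.0
    return x / np.linalg.norm(x, axis=0, keepdims=True)


def _orthonormal_columns(rng, dim, rank):
    q, r = np.linalg.qr(rng.standard_normal((dim, rank)))
    return q * np.sign(np.diag(r))


def _tensor_mask(rng, shape, missing_rate, max_retries=100):
    """Entry-level MCAR mask keeping >=1 observed entry per subject."""
    mask = rng.random(shape) >= missing_rate
    for i in range(shape[0]):
        tries = 0
        while not mask[i].any():
            mask[i] = rng.random(shape[1:]) >= missing_rate
            tries += 1
            if tries >= max_retries:
                raise ValueError(
                    f"missing_rate={missing_rate} leaves subject {i} empty "
                    f"after {max_retries} retries"
                )
    return mask


def generate_cohort(
    subjects: int = 129,
    biomarkers: int = 20,
    timepoints: int = 4,
    baseline_vars: int = 10,
    snps: int = 51,
    rank: int = 2,
    sparsity=(0.5, 0.3, 0.7),
    noise_sd=(0.3, 0.3, 0.3),
    missing_rate: float = 0.1,
    signal_strength: float = 1.0,
    seed: int = 0,
    discretize_genes: bool = True,
):
    """Generate a coupled three-block cohort and its ground truth.

    The tensor block is the rank-``rank`` CP sum of outer products of the
    subject scores with biomarker and time loadings plus Gaussian noise;
    entries are then deleted completely at random (each subject keeps at
    least one observation). Baseline and gene blocks are ``scores @
    loadings.T`` plus noise; the gene block is additionally discretized to
    genotype counts {0,1,2} by cutting each latent column at the tertiles
    of its exact marginal distribution.

    Parameters
    ----------
    sparsity : (biomarker, baseline, gene) fractions of exact-zero loadings
        per component in the sparse variable modes.
    noise_sd : per-block Gaussian residual standard deviations.
    signal_strength : multiplier on the subject scores; 0 gives a
        pure-noise cohort for null simulations.
    discretize_genes : if False the gene block stays continuous.

    Returns
    -------
    (MultiBlockDataset, GroundTruth); identical seeds give identical output.
    """
    dims = dict(
        subjects=subjects,
        biomarkers=biomarkers,
        timepoints=timepoints,
        baseline_vars=baseline_vars,
        snps=snps,
    )
    if rank < 1:
        raise DimensionError("rank must be >= 1")
    for name, d in dims.items():
        if d < rank:
            raise DimensionError(f"rank {rank} exceeds {name}={d}")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    noise_sd = tuple(float(s) for s in np.broadcast_to(noise_sd, (3,)))
    if any(s < 0 for s in noise_sd):
        raise ValueError("noise_sd must be nonnegative")
    sp_bm, sp_bl, sp_gn = np.broadcast_to(sparsity, (3,))

    rng = np.random.default_rng(seed)
    A = signal_strength * rng.standard_normal((subjects, rank))
    B = _sparse_loadings(rng, biomarkers, rank, sp_bm)
    C = _orthonormal_columns(rng, timepoints, rank)
    D = _sparse_loadings(rng, baseline_vars, rank, sp_bl)
    E = _sparse_loadings(rng, snps, rank, sp_gn)

    truth = GroundTruth(
        subject_scores=A,
        biomarker_loadings=B,
        time_loadings=C,
        baseline_loadings=D,
        gene_loadings=E,
        noise_sd_per_block=noise_sd,
        missing_rate=float(missing_rate),
        seed=int(seed),
    )

    tensor = truth.tensor_signal() + noise_sd[0] * rng.standard_normal(
        (subjects, biomarkers, timepoints)
    )
    tmask = _tensor_mask(rng, tensor.shape, missing_rate)
    tensor = np.where(tmask, tensor, 0.0)

    baseline = truth.baseline_signal() + noise_sd[1] * rng.standard_normal(
        (subjects, baseline_vars)
    )

    gene_latent = truth.gene_signal() + noise_sd[2] * rng.standard_normal(
        (subjects, snps)
    )
    if discretize_genes:
        # cut each latent column at the tertiles of its exact N(0, s_p^2)
        # marginal (scores ~ N(0, signal^2) i.i.d.), giving balanced 0/1/2
        # genotype counts monotone in the latent score
        var_p = (signal_strength**2) * (E**2).sum(axis=1) + noise_sd[2] ** 2
        sd_p = np.sqrt(np.maximum(var_p, 1e-30))
        lo = norm.ppf(1 / 3) * sd_p
        hi = norm.ppf(2 / 3) * sd_p
        gene = (gene_latent > lo).astype(float) + (gene_latent > hi)
    else:
        gene = gene_latent
    gmask = np.ones_like(gene, dtype=bool)

    times = list(DEFAULT_TIME_GRID)[:timepoints]
    if timepoints > len(DEFAULT_TIME_GRID):
        times = list(range(1, timepoints + 1))
    ds = MultiBlockDataset(
        tensor=tensor,
        tensor_mask=tmask,
        baseline=baseline,
        gene=gene,
        gene_mask=gmask,
        times=times,
    )
    return ds, truth


def planted_cohort(seed: int = 0, noise_sd=(0.2, 0.2, 0.2), missing_rate=0.05):
    """A cohort with a hand-planted, sign-interpretable leading component.

    Component 1 mimics a declining beta-cell-function pattern: a
    "cpeptide_like" biomarker loads positively and a "glucose_like"
    biomarker negatively on a monotonically declining time profile, the
    baseline "age_years" variable loads negatively (young age), and five
    designated risk SNPs carry positive gene loadings.  Component 2 is a
    weaker generic pattern on disjoint biomarkers.

    Returns (dataset, truth, planted) where ``planted`` names the planted
    features and their expected relative signs.
    """
    subjects, biomarkers, timepoints, baseline_vars, snps = 129, 20, 4, 10, 51
    rng = np.random.default_rng(seed)

    B = np.zeros((biomarkers, 2))
    B[0, 0] = 0.75  # cpeptide_like declines with the time profile
    B[1, 0] = -0.55  # glucose_like moves opposite
    B[2, 0] = 0.35
    B[3:6, 1] = [0.7, -0.5, 0.4]
    B /= np.linalg.norm(B, axis=0, keepdims=True)

    C = np.array(
        [
            [0.80, 0.55, 0.25, -0.15],  # declining profile
            [0.30, 0.45, 0.60, 0.58],  # late-rising profile
        ]
    ).T
    C /= np.linalg.norm(C, axis=0, keepdims=True)

    D = np.zeros((baseline_vars, 2))
    D[0, 0] = -0.70  # age_years: young age goes with the declining pattern
    D[1, 0] = 0.45  # symptom_duration
    D[2, 0] = 0.40  # dka
    D[4, 1] = 0.9
    D[5, 1] = -0.4
    D /= np.where(
        np.linalg.norm(D, axis=0, keepdims=True) == 0,
        1.0,
        np.linalg.norm(D, axis=0, keepdims=True),
    )

    E = np.zeros((snps, 2))
    planted_snps = [0, 1, 2, 3, 4]
    E[planted_snps, 0] = [0.55, 0.5, 0.45, 0.4, -0.35]
    E[10:14, 1] = [0.6, 0.5, -0.45, 0.4]
    E /= np.linalg.norm(E, axis=0, keepdims=True)

    A = rng.standard_normal((subjects, 2)) * np.array([1.6, 1.0])

    truth = GroundTruth(
        subject_scores=A,
        biomarker_loadings=B,
        time_loadings=C,
        baseline_loadings=D,
        gene_loadings=E,
        noise_sd_per_block=tuple(np.broadcast_to(noise_sd, (3,)).astype(float)),
        missing_rate=float(missing_rate),
        seed=int(seed),
    )

    noise_sd = truth.noise_sd_per_block
    tensor = truth.tensor_signal() + noise_sd[0] * rng.standard_normal(
        (subjects, biomarkers, timepoints)
    )
    tmask = _tensor_mask(rng, tensor.shape, missing_rate)
    tensor = np.where(tmask, tensor, 0.0)
    baseline = truth.baseline_signal() + noise_sd[1] * rng.standard_normal(
        (subjects, baseline_vars)
    )
    gene_latent = truth.gene_signal() + noise_sd[2] * rng.standard_normal(
        (subjects, snps)
    )
    var_p = (A.var(axis=0) @ (E**2).T) + noise_sd[2] ** 2
    sd_p = np.sqrt(var_p)
    gene = (gene_latent > norm.ppf(1 / 3) * sd_p).astype(float) + (
        gene_latent > norm.ppf(2 / 3) * sd_p
    )

    biomarker_names = ["cpeptide_like", "glucose_like"] + [
        f"bm{j:02d}" for j in range(2, biomarkers)
    ]
    baseline_names = ["age_years", "symptom_duration", "dka"] + [
        f"bl{m:02d}" for m in range(3, baseline_vars)
    ]
    snp_names = [f"rs{1000 + p}" for p in range(snps)]

    ds = MultiBlockDataset(
        tensor=tensor,
        tensor_mask=tmask,
        baseline=baseline,
        gene=gene,
        gene_mask=np.ones_like(gene, dtype=bool),
        biomarkers=biomarker_names,
        baseline_vars=baseline_names,
        snps=snp_names,
    )
    planted = {
        "component": 0,
        "biomarker_pair": ("cpeptide_like", "glucose_like"),  # opposite signs
        "baseline_negative_vs_cpeptide": "age_years",
        "planted_snps": [snp_names[p] for p in planted_snps],
        "snp_signs": {snp_names[p]: s for p, s in zip(planted_snps, [1, 1, 1, 1, -1])},
    }
    return ds, truth, planted
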