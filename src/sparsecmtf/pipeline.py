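"""End-to-end orchestration: load blocks, fit, validate, report.

The run directory a pipeline produces contains, as plain CSV/JSON:

* ``loadings.csv`` — tidy per-mode loading table (mode, label, component,
  value) of the aligned model,
* ``component_<r>.csv`` — one pattern table per component with
  zero loadings omitted,
* ``explained_variation.csv`` — per block and per component,
* ``permutation_tests.csv`` — pattern-to-pattern association p-values
  (biomarker block vs baseline, biomarker vs genes) per component,
* ``split_half.csv`` — matched-congruence and consistency-p summaries,
* ``model.json`` / ``run_info.json`` — the fitted factors and the full
  configuration/seed record.

All stages are deterministic given the configured seeds.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cmtf, validation
from .preprocess import (
    DataError,
    MultiBlockDataset,
    assemble_tensor,
    prepare,
)
from .synthetic import GroundTruth, generate_cohort

__all__ = [
    "RunConfig",
    "load_blocks",
    "run_pipeline",
    "write_cohort_csvs",
    "model_to_json",
    "model_from_json",
]


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    biomarker_csv: str
    baseline_csv: str
    genotype_csv: str
    out_dir: str
    rank: int = 2
    lam: float | str = 0.0  # a number, or "auto" for stability selection
    lambda_grid: tuple = cmtf.DEFAULT_LAMBDA_GRID
    log_vars: tuple = ()
    time_grid: tuple = (1, 3, 6, 12)
    n_starts: int = 10
    max_iter: int = 500
    tol: float = 1e-8
    seed: int = 0
    n_perm: int = 999
    n_splits: int = 10
    n_null: int = 19
    scan_ranks: tuple = ()

    def __post_init__(self):
        if self.rank < 1:
            raise ValueError("rank must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate_paths(self):
        for attr in ("biomarker_csv", "baseline_csv", "genotype_csv"):
            p = Path(getattr(self, attr))
            if not p.exists():
                raise FileNotFoundError(f"{attr}: no such file {p}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cohort_csvs(ds: MultiBlockDataset, out_dir, truth: GroundTruth | None = None):
    """Serialize a dataset (and optional ground truth) as the three CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .preprocess import flatten_tensor

    flatten_tensor(ds).to_csv(out / "biomarkers_long.csv", index=False)
    bl = pd.DataFrame(ds.baseline, columns=ds.baseline_vars)
    bl.insert(0, "subject_id", ds.subjects)
    bl.to_csv(out / "baseline.csv", index=False)
    gn = pd.DataFrame(
        np.where(ds.gene_mask, ds.gene, np.nan), columns=ds.snps
    )
    gn.insert(0, "subject_id", ds.subjects)
    gn.to_csv(out / "genotypes.csv", index=False)
    if truth is not None:
        (out / "ground_truth.json").write_text(truth.to_json())
    return out


def load_blocks(config: RunConfig) -> MultiBlockDataset:
    """Assemble a MultiBlockDataset from the three configured CSVs.

    The biomarker file is long format (subject_id, variable, time_months,
    value); baseline and genotype files are wide with a subject_id column.
    Subjects present in the tensor must appear in both matrices.
    """
    config.validate_paths()
    long_tab = pd.read_csv(config.biomarker_csv)
    tensor, mask = assemble_tensor(long_tab, times=config.time_grid)
    subjects = list(pd.unique(long_tab["subject_id"]))
    variables = list(pd.unique(long_tab["variable"]))

    bl = pd.read_csv(config.baseline_csv).set_index("subject_id")
    gn = pd.read_csv(config.genotype_csv).set_index("subject_id")
    for name, tab in (("baseline", bl), ("genotype", gn)):
        missing = set(subjects) - set(tab.index.astype(str)) - set(tab.index)
        if missing:
            raise DataError(f"{name} table lacks subjects: {sorted(missing)[:5]}")
    bl = bl.loc[subjects]
    gn = gn.loc[subjects]
    gene = gn.to_numpy(dtype=float)
    gmask = np.isfinite(gene)
    return MultiBlockDataset(
        tensor=tensor,
        tensor_mask=mask,
        baseline=bl.to_numpy(dtype=float),
        gene=np.where(gmask, gene, 0.0),
        gene_mask=gmask,
        subjects=subjects,
        biomarkers=variables,
        times=list(config.time_grid),
        baseline_vars=list(bl.columns),
        snps=list(gn.columns),
    )


def model_to_json(model: cmtf.CMTFModel) -> str:
    d = {}
    for k in ("A", "B", "C", "D", "E", "baseline_gains", "gene_gains"):
        v = getattr(model, k)
        d[k] = None if v is None else np.asarray(v).tolist()
    d.update(
        rank=model.rank,
        lam=model.lam,
        ridge=model.ridge,
        block_weights=None
        if model.block_weights is None
        else list(model.block_weights),
        loss_trace=list(model.loss_trace),
        converged=bool(model.converged),
        n_iter=model.n_iter,
        seed=model.seed,
    )
    return json.dumps(d)


def model_from_json(s: str) -> cmtf.CMTFModel:
    d = json.loads(s)
    arr = lambda v: None if v is None else np.array(v)
    return cmtf.CMTFModel(
        A=arr(d["A"]), B=arr(d["B"]), C=arr(d["C"]), D=arr(d["D"]), E=arr(d["E"]),
        baseline_gains=arr(d["baseline_gains"]), gene_gains=arr(d["gene_gains"]),
        rank=d["rank"], lam=d["lam"], ridge=d["ridge"],
        block_weights=arr(d["block_weights"]),
        loss_trace=np.array(d["loss_trace"]), converged=d["converged"],
        n_iter=d["n_iter"], seed=d["seed"],
    )


# ---------------------------------------------------------------------------
# reporting helpers
# ---------------------------------------------------------------------------

def _loadings_table(model, ds) -> pd.DataFrame:
    rows = []
    mode_info = [
        ("biomarker", model.B, ds.biomarkers, None),
        ("time", model.C, ds.times, None),
        ("baseline", model.D, ds.baseline_vars, model.baseline_gains),
        ("gene", model.E, ds.snps, model.gene_gains),
    ]
    for mode, mat, labels, gains in mode_info:
        if mat is None:
            continue
        for r in range(model.rank):
            for lab, val in zip(labels, mat[:, r]):
                rows.append(
                    {
                        "mode": mode,
                        "label": lab,
                        "component": r + 1,
                        "value": float(val),
                        "gain": float(gains[r]) if gains is not None else 1.0,
                    }
                )
    return pd.DataFrame(rows)


def _explained_table(model, ds) -> pd.DataFrame:
    rows = [
        {"scope": f"block:{b}", "explained_pct": cmtf.explained_variation(model, ds, b)}
        for b in ("tensor", "baseline", "gene", "total")
    ]
    for pat in cmtf.component_patterns(model, ds):
        rows.append(
            {
                "scope": f"component:{pat.index + 1}:tensor",
                "explained_pct": pat.explained_variation,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the report directory.

    Returns a dict of output paths plus the in-memory model and
    validation results. Raises before any computation if the configured
    input files are missing.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    raw = load_blocks(config)
    ds = prepare(raw, log_vars=config.log_vars)

    rng = np.random.default_rng(config.seed)
    fit_seed = int(rng.integers(2**31 - 1))
    val_seed = int(rng.integers(2**31 - 1))
    split_seed = int(rng.integers(2**31 - 1))

    lam = config.lam
    lambda_table = None
    if lam == "auto":
        lam, lambda_table = cmtf.select_lambda(
            ds, rank=config.rank, grid=config.lambda_grid,
            seed=int(rng.integers(2**31 - 1)),
        )
        lambda_table.to_csv(out / "lambda_selection.csv", index=False)
    lam = float(lam)

    model = cmtf.cmtf_fit(
        ds, rank=config.rank, lam=lam, n_starts=config.n_starts,
        tol=config.tol, max_iter=config.max_iter, seed=fit_seed,
    )
    model = cmtf.align_components(model, ds)

    _loadings_table(model, ds).to_csv(out / "loadings.csv", index=False)
    for pat in cmtf.component_patterns(model, ds):
        rows = []
        for mode, series in (
            ("biomarker", pat.biomarker),
            ("time", pat.time),
            ("baseline", pat.baseline),
            ("gene", pat.gene),
        ):
            if series is None:
                continue
            for lab, val in series.items():
                if mode in ("biomarker", "baseline", "gene") and val == 0.0:
                    continue  # zeroed loadings omitted from pattern tables
                rows.append({"mode": mode, "label": lab, "loading": float(val)})
        pd.DataFrame(rows).to_csv(
            out / f"component_{pat.index + 1}.csv", index=False
        )

    _explained_table(model, ds).to_csv(out / "explained_variation.csv", index=False)

    perm_rows = []
    for r in range(config.rank):
        for pair in (("tensor", "baseline"), ("tensor", "gene")):
            res = validation.permutation_association_test(
                ds, model, block_pair=pair, component=r,
                n_perm=config.n_perm, seed=val_seed,
            )
            perm_rows.append(
                {
                    "component": r + 1,
                    "blocks": "-".join(pair),
                    "abs_correlation": res.statistic,
                    "p_value": res.p_value,
                    "n_perm": res.n_perm,
                }
            )
    perm_tab = pd.DataFrame(perm_rows)
    perm_tab.to_csv(out / "permutation_tests.csv", index=False)

    split = validation.split_half_consistency(
        raw, rank=config.rank, lam=lam, n_splits=config.n_splits,
        seed=split_seed, n_null=config.n_null,
    )
    split_rows = []
    for mode in split.median_congruence.columns:
        for r in range(config.rank):
            split_rows.append(
                {
                    "mode": mode,
                    "component": r + 1,
                    "median_abs_congruence": float(
                        split.median_congruence[mode][r]
                    ),
                    "worst_p": float(split.worst_p[mode][r]),
                }
            )
    pd.DataFrame(split_rows).to_csv(out / "split_half.csv", index=False)

    scan_rows = []
    for rk in config.scan_ranks:
        m = cmtf.cmtf_fit(
            ds, rank=rk, lam=lam, n_starts=max(2, config.n_starts // 3),
            tol=config.tol, max_iter=config.max_iter, seed=fit_seed,
        )
        scan_rows.append(
            {
                "rank": rk,
                "tensor_explained_pct": cmtf.explained_variation(m, ds, "tensor"),
                "total_explained_pct": cmtf.explained_variation(m, ds, "total"),
            }
        )
    if scan_rows:
        pd.DataFrame(scan_rows).to_csv(out / "rank_scan.csv", index=False)

    (out / "model.json").write_text(model_to_json(model))
    info = asdict(config)
    info.update(
        lam_used=lam,
        fit_seed=fit_seed,
        val_seed=val_seed,
        split_seed=split_seed,
        n_subjects=ds.n_subjects,
        dims={
            "tensor": list(ds.tensor.shape),
            "baseline": list(ds.baseline.shape),
            "gene": list(ds.gene.shape),
        },
        tensor_observed_fraction=float(ds.tensor_mask.mean()),
        converged=bool(model.converged),
    )
    for k, v in list(info.items()):
        if isinstance(v, tuple):
            info[k] = list(v)
    (out / "run_info.json").write_text(json.dumps(info, indent=2, default=float))
    return {
        "out_dir": str(out),
        "model": model,
        "dataset": ds,
        "permutation": perm_tab,
        "split_half": split,
        "lam": lam,
    }


def simulate_to_dir(out_dir, seed=0, **kwargs):
    """Generate a synthetic cohort and write it as pipeline-ready CSVs."""
    ds, truth = generate_cohort(seed=seed, **kwargs)
    return write_cohort_csvs(ds, out_dir, truth)
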