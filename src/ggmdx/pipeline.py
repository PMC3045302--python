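"""End-to-end pipeline: pattern search -> precision fit -> contrast test.

Each stage reads its declared inputs from disk, writes its outputs, and is
skipped on re-runs if the output already exists (checkpointing).  The run
log records the settings, the seed, timings and the kmax/n ratio warning.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .core import residuals_under
from .inference import build_frame, modified_bonferroni, permutation_null
from .io import (read_design, read_expression, read_pattern, read_precision,
                 read_table_matrix, write_sparse_symmetric)
from .pattern import KMAX_SAMPLE_RATIO, default_kmax, find_pattern
from .precision import fit_precision

__all__ = ["RunConfig", "pipeline"]

log = logging.getLogger("ggmdx")


@dataclass
class RunConfig:
    expression: str
    design: str
    contrast: str
    outdir: str
    genes_in_rows: bool = False
    kmax: int | None = None
    criterion: str = "bic1.0"
    tol: float = 1e-6
    nperm: int = 1000
    seed: int = 0
    alpha_expected_fp: float = 8.0
    n_jobs: int = 1
    overwrite: bool = False

    def validate(self) -> None:
        for name in ("expression", "design", "contrast"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"{name} file not found: {path}")
        if self.seed is None:
            raise ValueError("a seed is mandatory for the permutation stage")


def pipeline(run: RunConfig) -> dict:
    """Run pattern -> fit -> test, returning the paths of the artifacts."""
    run.validate()
    out = Path(run.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    X = read_expression(run.expression, genes_in_rows=run.genes_in_rows)
    D = read_design(run.design)
    C = read_table_matrix(run.contrast)
    n = X.n_samples
    kmax = run.kmax if run.kmax is not None else default_kmax(n)
    log.info("ggmdx %s | n=%d p=%d kmax=%d (kmax/n=%.3f%s) seed=%d",
             __version__, n, X.n_genes, kmax, kmax / n,
             ", above the recommended 1/20" if kmax / n > KMAX_SAMPLE_RATIO else "",
             run.seed)

    pattern_path = out / "pattern.mtx"
    resid = residuals_under(X, D)
    if run.overwrite or not pattern_path.exists():
        _, N = find_pattern(resid.residuals, kmax, run.criterion,
                            n_jobs=run.n_jobs)
        write_sparse_symmetric(pattern_path, N)
        log.info("pattern stage done in %.1fs", time.time() - t0)
    else:
        log.info("pattern stage skipped (checkpoint %s exists)", pattern_path)
    N = read_pattern(pattern_path)

    precision_path = out / "precision.mtx"
    if run.overwrite or not precision_path.exists():
        t1 = time.time()
        S = resid.sample_cov.dense()
        K, report = fit_precision(S, N, tol=run.tol, n=n)
        write_sparse_symmetric(precision_path, K)
        with open(out / "fit_report.json", "w") as fh:
            json.dump(asdict(report), fh, indent=1)
        log.info("fit stage done in %.1fs (%d iterations, gap %.2e)",
                 time.time() - t1, report.iterations, report.max_edge_gap)
    else:
        log.info("fit stage skipped (checkpoint exists)")
    K = read_precision(precision_path)

    t2 = time.time()
    frame = build_frame(X, D, C)
    result = permutation_null(X, D, C, K, run.nperm, run.seed, frame=frame)
    mult = modified_bonferroni(result.pvalues_de, result.pvalues_dc,
                               alpha_expected_fp=run.alpha_expected_fp)
    _write_test_outputs(out, X, result, mult)
    log.info("test stage done in %.1fs (T=%.2f, p=%.4g)",
             time.time() - t2, result.T_obs, result.pvalue_T)
    return {
        "pattern": str(pattern_path),
        "precision": str(precision_path),
        "results": str(out / "gene_tests.tsv"),
        "summary": str(out / "test_summary.json"),
    }


def _write_test_outputs(out: Path, X, result, mult) -> None:
    import pandas as pd

    rej_de = np.zeros(X.n_genes, bool)
    rej_de[mult.rejected_de] = True
    rej_dc = np.zeros(X.n_genes, bool)
    rej_dc[mult.rejected_dc] = True
    df = pd.DataFrame({
        "gene": X.gene_ids,
        "gamma": result.gamma[0] if result.gamma.shape[0] == 1 else result.de_stat,
        "gamma_nb": result.gamma_nb[0] if result.gamma_nb.shape[0] == 1 else result.dc_stat,
        "component": result.components,
        "p_de": result.pvalues_de,
        "p_dc": result.pvalues_dc,
        "rejected_de": rej_de,
        "rejected_dc": rej_dc,
    })
    df.to_csv(out / "gene_tests.tsv", sep="\t", index=False)
    qs = [0.90, 0.95, 0.99, 0.99995]
    summary = {
        "T_obs": result.T_obs,
        "pvalue_T": result.pvalue_T,
        "n_perm": result.n_perm,
        "null_T_quantiles": {f"{100*q:g}%": float(np.quantile(result.null_T, q))
                             for q in qs},
        "multiplicity": {
            "alpha_expected_fp": mult.alpha_expected_fp,
            "m_tests": mult.m_tests,
            "threshold": mult.threshold,
            "n_rejected_de": int(len(mult.rejected_de)),
            "n_rejected_dc": int(len(mult.rejected_dc)),
        },
    }
    with open(out / "test_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
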