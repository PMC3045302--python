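"""On-disk fixture datasets with known truth for two-group tests.

Wraps the precision generator and MVN sampler, splits the samples into two
groups, and optionally injects a mean shift delta into selected genes of
group 1 so that the per-gene contrast truths are known: for the two-group
contrast C' = [1,-1]/sqrt(2), gamma0 = L' Q2' B_true, and the expected
neighbour-corrected value at gene i is gamma0_i - sum_j beta_ij gamma0_j.
With delta on a gene that has no neighbours the DC truth equals the DE
truth; a "smooth" effect (gamma0 proportional to a covariance column) makes
many genes differentially expressed while almost all stay DC-null.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import ExpressionMatrix
from .inference import build_frame, two_group_design
from .io import write_expression, write_sparse_symmetric
from .precision import conditional_regressions
from .simulate import SimConfig, generate_precision, sample_mvn

__all__ = ["make_fixture"]


def make_fixture(outdir, p: int, m: int, n: int, *, effect: float = 0.0,
                 n_effect_genes: int = 5, effect_mode: str = "sparse",
                 seed=0, q_per_row: float | None = None) -> dict:
    """Write expression/design/contrast/truth files; return the truth dict.

    ``effect`` = 0 gives a pure-null calibration dataset.  ``effect_mode``
    'sparse' adds delta to ``n_effect_genes`` random genes' means in group
    1; 'smooth' shifts group 1 along a covariance column scaled by
    ``effect``, which is DE-non-null at many genes but DC-null except at
    the seeding gene.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    cfg = SimConfig(p=p, n=n, q_per_row=q_per_row, target_median=m if q_per_row is None else None,
                    reps=1, seed=int(rng.integers(2**31 - 1)))
    model = generate_precision(cfg)
    data = sample_mvn(model.K_true, n, int(rng.integers(2**31 - 1)))

    n1 = n // 2
    labels = ["treatment"] * n1 + ["control"] * (n - n1)
    D, C = two_group_design(labels)

    delta = np.zeros(p)
    de_genes: list[int] = []
    if effect != 0.0:
        if effect_mode == "sparse":
            de_genes = sorted(rng.choice(p, size=min(n_effect_genes, p),
                                         replace=False).tolist())
            delta[de_genes] = effect
        elif effect_mode == "smooth":
            j = int(rng.integers(p))
            Sigma_col = np.linalg.solve(model.K_true.dense(),
                                        np.eye(p)[:, j])
            delta = effect * Sigma_col / np.abs(Sigma_col).max()
            de_genes = [j]
        else:
            raise ValueError(f"unknown effect_mode {effect_mode!r}")
        data[:n1] += delta

    X = ExpressionMatrix(data, sample_ids=[f"s{i}" for i in range(n)],
                         gene_ids=[f"g{j}" for j in range(p)])
    write_expression(outdir / "expression.tsv", X)
    np.savetxt(outdir / "design.tsv", D.values, fmt="%.1f", delimiter="\t")
    np.savetxt(outdir / "contrast.tsv", C, delimiter="\t")
    with open(outdir / "labels.tsv", "w") as fh:
        fh.write("sample\tgroup\n")
        for s, l in zip(X.sample_ids, labels):
            fh.write(f"{s}\t{l}\n")
    write_sparse_symmetric(outdir / "pattern_true.mtx", model.N_true)
    write_sparse_symmetric(outdir / "precision_true.mtx", model.K_true)

    # contrast-scale truths: gamma0 = L' Q2' B_true, DC mean per Eq-style
    # neighbour correction gamma0_i - sum_j beta_ij gamma0_j
    B_true = np.vstack([delta, np.zeros(p)])
    frame = build_frame(X, D, C)
    gamma0 = (frame.L.T @ (frame.Q[:, -1:].T @ B_true)).ravel()
    cr = conditional_regressions(model.K_true)
    gamma_nb0 = gamma0 - np.asarray(cr.beta @ gamma0).ravel()
    truth = {
        "p": p, "n": n, "n1": n1, "seed": seed, "effect": effect,
        "effect_mode": effect_mode, "de_genes": de_genes,
        "d_used": model.d_used, "q_used": model.q_used,
        "delta": delta.tolist(),
        "gamma0": gamma0.tolist(),
        "gamma_nb0": gamma_nb0.tolist(),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth
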