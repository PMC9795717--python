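"""Synthetic expression matrices and interaction-candidate tables.

The transcriptomic stage is screened on matrices with planted structure:
per cell type, background genes whose co/mono log2 fold change stays
well inside (-1, 1), plus differentially expressed genes planted in
clusters with distinct temporal fold-change templates.  Interaction
candidate tables carry three confidence scores per edge (database,
experimental, text-mining), with planted high-confidence cross-cell-type
edges and decoys that must be screened out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CELL_TYPES = ("EC", "MSC")

# temporal log2FC templates over (early, late) timepoints; extended
# cyclically if more timepoints are requested
UP_TEMPLATES = {
    "early": (2.6, 0.4),
    "late": (0.4, 2.6),
    "sustained": (2.2, 2.2),
}
DOWN_TEMPLATES = {
    "early": (-2.6, -0.4),
    "late": (-0.4, -2.6),
}


@dataclass
class ExpressionPhantomSpec:
    """Planted-DEG design for one synthetic RNA-seq style experiment."""

    n_background: int = 200
    up_clusters: dict[str, int] = field(
        default_factory=lambda: {"early": 20, "late": 20}
    )
    down_clusters: dict[str, int] = field(default_factory=lambda: {"early": 15})
    timepoints: tuple[int, ...] = (12, 24)
    fc_noise_sd: float = 0.15
    baseline_log_mean: float = 6.0
    baseline_log_sd: float = 1.5
    seed: int = 0


@dataclass
class ExpressionTruth:
    """Ground truth per cell type: DEG direction and planted cluster."""

    direction: dict[str, str]  # gene -> "up" | "down" | "none"
    cluster: dict[str, str]  # DEG gene -> template name


def _template_fc(name: str, direction: str, n_t: int) -> np.ndarray:
    base = UP_TEMPLATES[name] if direction == "up" else DOWN_TEMPLATES[name]
    return np.array([base[i % len(base)] for i in range(n_t)], dtype=float)


def make_expression_phantom(
    spec: ExpressionPhantomSpec, cell_type: str = "EC", gene_prefix: str | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, ExpressionTruth]:
    """Build (expression matrix, sample sheet, truth) for one cell type.

    The matrix is genes × samples of positive expression units; samples
    cover mono and co conditions at each timepoint.  Planted DEGs reach
    |log2FC| well above 1 at one or more timepoints; background genes
    stay inside ±0.8.
    """
    if cell_type not in CELL_TYPES:
        raise ValueError(f"cell_type must be one of {CELL_TYPES}")
    rng = np.random.default_rng(spec.seed)
    prefix = gene_prefix or f"{cell_type}G"
    n_t = len(spec.timepoints)

    genes, fcs = [], []
    direction: dict[str, str] = {}
    cluster: dict[str, str] = {}
    idx = 0
    for name, n in spec.up_clusters.items():
        tpl = _template_fc(name, "up", n_t)
        for _ in range(n):
            g = f"{prefix}{idx:04d}"
            genes.append(g)
            fcs.append(tpl + rng.normal(0, spec.fc_noise_sd, n_t))
            direction[g] = "up"
            cluster[g] = f"up-{name}"
            idx += 1
    for name, n in spec.down_clusters.items():
        tpl = _template_fc(name, "down", n_t)
        for _ in range(n):
            g = f"{prefix}{idx:04d}"
            genes.append(g)
            fcs.append(tpl + rng.normal(0, spec.fc_noise_sd, n_t))
            direction[g] = "down"
            cluster[g] = f"down-{name}"
            idx += 1
    for _ in range(spec.n_background):
        g = f"{prefix}{idx:04d}"
        genes.append(g)
        fcs.append(np.clip(rng.normal(0, 0.2, n_t), -0.8, 0.8))
        direction[g] = "none"
        idx += 1
    fcs = np.asarray(fcs)

    baseline = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, len(genes))
    cols, data = [], []
    for ti, t in enumerate(spec.timepoints):
        cols.append(f"{cell_type}_mono_{t}h")
        data.append(baseline)
        cols.append(f"{cell_type}_co_{t}h")
        data.append(baseline * 2.0 ** fcs[:, ti])
    expr = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    expr.index.name = "gene_id"

    sheet = pd.DataFrame(
        {
            "sample": cols,
            "cell_type": cell_type,
            "condition": [c.split("_")[1] for c in cols],
            "time_h": [int(c.split("_")[2].rstrip("h")) for c in cols],
        }
    )
    return expr, sheet, ExpressionTruth(direction=direction, cluster=cluster)


def make_ppi_candidates(
    ec_degs: list[str],
    msc_degs: list[str],
    n_true: int = 3,
    n_decoy: int = 20,
    shared_degs: list[str] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build a candidate interaction table with planted keepers.

    Returns ``(candidates, truth)``.  Keepers are cross-cell-type edges
    with all three confidence scores > 0.9 and no endpoint in
    ``shared_degs`` (genes differentially expressed in both cell types);
    decoys violate at least one of those conditions.
    """
    rng = np.random.default_rng(seed)
    shared = list(shared_degs or [])
    ec_pool = [g for g in ec_degs if g not in shared]
    msc_pool = [g for g in msc_degs if g not in shared]
    if len(ec_pool) < n_true or len(msc_pool) < n_true:
        raise ValueError("not enough exclusive DEGs to plant true edges")

    rows, keep = [], []
    ec_pick = rng.choice(ec_pool, size=n_true, replace=False)
    msc_pick = rng.choice(msc_pool, size=n_true, replace=False)
    for a, b in zip(ec_pick, msc_pick):
        rows.append((a, "EC", b, "MSC", *rng.uniform(0.91, 0.995, 3)))
        keep.append(True)

    for _ in range(n_decoy):
        mode = rng.integers(0, 3 if shared else 2)
        if mode == 0:  # low score on a random channel
            a, b = rng.choice(ec_pool), rng.choice(msc_pool)
            s = rng.uniform(0.91, 0.995, 3)
            s[rng.integers(0, 3)] = rng.uniform(0.2, 0.9)
            rows.append((a, "EC", b, "MSC", *s))
        elif mode == 1:  # same cell type
            a, b = rng.choice(ec_pool, size=2, replace=False)
            rows.append((a, "EC", b, "EC", *rng.uniform(0.91, 0.995, 3)))
        else:  # touches a gene regulated in both cell types
            a, b = rng.choice(shared), rng.choice(msc_pool)
            rows.append((a, "EC", b, "MSC", *rng.uniform(0.91, 0.995, 3)))
        keep.append(False)

    cand = pd.DataFrame(
        rows,
        columns=[
            "gene_a",
            "cell_type_a",
            "gene_b",
            "cell_type_b",
            "db_score",
            "exp_score",
            "text_score",
        ],
    )
    truth = cand.assign(keep=keep)
    return cand, truth
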