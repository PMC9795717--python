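"""Transcriptomic screening: DEGs, temporal clusters, interaction network.

Simulates co/mono expression matrices for both cell types with planted
temporal DEG clusters, calls |log2FC| > 1 DEGs, clusters their
z-normalized profiles (Ward on cosine distances, cut at the >0.6
within-cluster correlation rule), builds a candidate interaction table
— including a synthetic stand-in trio modelled on the BMP2→BMPR1A,
BMP4→BMPR1A and IL1B→IL1R1 ligand–receptor pairs — and screens it with
the strict all-three-scores > 0.9 cross-cell-type rule.

Writes DEG lists, cluster assignments (EC-U1 … MSC-D2 naming), the
retained network as TSV and GraphML, and per-cluster gene lists ready
for external GO-term annotation.
"""

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from angiocross.phantom import (
    ExpressionPhantomSpec,
    make_expression_phantom,
    make_ppi_candidates,
)
from angiocross.ppi import (
    call_degs,
    cluster_degs,
    filter_ppis,
    fold_changes,
    network_from_edges,
)

OUT = Path("results/ppi")
SEED = 20

# synthetic stand-ins for the angiogenic ligand-receptor axes; scores are
# generated, not retrieved from any interaction database
NAMED_TRIO = [
    ("BMP2_syn", "EC", "BMPR1A_syn", "MSC"),
    ("BMP4_syn", "EC", "BMPR1A_syn", "MSC"),
    ("IL1B_syn", "EC", "IL1R1_syn", "MSC"),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = ExpressionPhantomSpec(
        n_background=300,
        up_clusters={"early": 25, "late": 20, "sustained": 15},
        down_clusters={"early": 20, "late": 15},
        timepoints=(12, 24),
        seed=SEED,
    )
    degs, fcs = {}, {}
    deg_rows = []
    cluster_rows = []
    for ct in ("EC", "MSC"):
        expr, sheet, _ = make_expression_phantom(spec, ct)
        expr.to_csv(OUT / f"expression_{ct}.tsv", sep="\t")
        sheet.to_csv(OUT / f"samples_{ct}.tsv", sep="\t", index=False)
        fc = fold_changes(expr, sheet)[ct]
        fcs[ct] = fc
        d = call_degs(fc)
        degs[ct] = d
        for g, row in d.iterrows():
            deg_rows.append(
                {"cell_type": ct, "gene": g, "direction": row.direction}
            )
        for direction in ("up", "down"):
            sel = d[d.direction == direction].index
            if len(sel) < 2:
                continue
            cs = cluster_degs(fc.zprofile.loc[sel], ct, direction)
            print(
                f"{ct} {direction}: {len(sel)} DEGs -> {cs.k} clusters "
                f"({', '.join(sorted(cs.assignments.unique()))})"
            )
            for g, lab in cs.assignments.items():
                cluster_rows.append({"cell_type": ct, "gene": g, "cluster": lab})
    pd.DataFrame(deg_rows).to_csv(OUT / "degs.tsv", sep="\t", index=False)
    clusters = pd.DataFrame(cluster_rows)
    clusters.to_csv(OUT / "clusters.tsv", sep="\t", index=False)
    for lab, sub in clusters.groupby("cluster"):
        (OUT / f"cluster_{lab}_genes.txt").write_text("\n".join(sub.gene) + "\n")

    ec_degs = set(degs["EC"].index) | {g for g, _, _, _ in NAMED_TRIO}
    msc_degs = set(degs["MSC"].index) | {r for _, _, r, _ in NAMED_TRIO}
    cand, _ = make_ppi_candidates(
        sorted(ec_degs), sorted(msc_degs), n_true=3, n_decoy=25, seed=SEED + 1
    )
    import numpy as np

    rng = np.random.default_rng(SEED + 2)
    named = pd.DataFrame(
        [
            (a, cta, b, ctb, *rng.uniform(0.92, 0.99, 3))
            for a, cta, b, ctb in NAMED_TRIO
        ],
        columns=cand.columns,
    )
    cand = pd.concat([named, cand], ignore_index=True)
    cand.to_csv(OUT / "candidates.tsv", sep="\t", index=False)

    kept = filter_ppis(cand, ec_degs, msc_degs)
    kept.to_csv(OUT / "network.tsv", sep="\t", index=False)
    nx.write_graphml(network_from_edges(kept), OUT / "network.graphml")
    (OUT / "summary.json").write_text(
        json.dumps(
            {
                "n_degs": {ct: int(len(d)) for ct, d in degs.items()},
                "n_candidates": int(len(cand)),
                "n_retained": int(len(kept)),
                "retained_edges": [
                    f"{r.gene_a}->{r.gene_b}" for r in kept.itertuples()
                ],
            },
            indent=2,
        )
    )
    print(f"\nretained {len(kept)}/{len(cand)} candidate interactions:")
    for r in kept.itertuples():
        print(f"  {r.gene_a} ({r.cell_type_a}) — {r.gene_b} ({r.cell_type_b})")


if __name__ == "__main__":
    main()
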