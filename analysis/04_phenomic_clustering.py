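#!/usr/bin/env python
"""Phenomic PCA and two-way hierarchical clustering.

Aggregates the endpoint battery to a group-mean matrix, applies
unit-variance row scaling, computes SVD principal components with groups as
observations, clusters both axes (correlation distance, average linkage),
and exports the column dendrogram — the phenogram — as Newick for the
concordance step. Writes the scaled matrix, PCA scores, phenogram and a
clustered heatmap under results/.
"""

from pathlib import Path

import pandas as pd

from phenofish import phenomics, pipeline

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    tidy = pd.read_csv(ROOT / "endpoints.tsv", sep="\t")
    res = pipeline.phenomic_analysis(tidy)
    res["scaled"].to_csv(ROOT / "phenome_scaled.tsv", sep="\t")
    res["pca"]["scores"].to_csv(ROOT / "phenome_pca_scores.tsv", sep="\t")
    (ROOT / "phenogram.nwk").write_text(res["phenogram_newick"] + "\n")
    ve = res["pca"]["variance_explained_pct"]
    print("variance explained (%):",
          ", ".join(f"{c}={v:.1f}" for c, v in ve.items()))
    print("phenogram:", res["phenogram_newick"])
    two = phenomics.cut_clusters(res["column_clustering"], 2)
    print("2-cluster cut:", two)
    phenomics.heatmap_figure(res["scaled"], res["row_clustering"],
                             res["column_clustering"],
                             path=ROOT / "phenome_heatmap.png")
    print(f"heatmap -> {ROOT / 'phenome_heatmap.png'}")


if __name__ == "__main__":
    main()
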