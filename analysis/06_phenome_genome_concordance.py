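#!/usr/bin/env python
"""Compare the phenomic dendrogram with the nd2 gene tree.

Robinson-Foulds distance (raw and normalized by 2(n-3)) measures topological
agreement; cophenetic correlation compares the full leaf-pair distance
structure. Writes results/concordance.json.
"""

import json
from pathlib import Path

from phenofish import phylo

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    pheno = phylo.read_newick(ROOT / "phenogram.nwk")
    gene = phylo.read_newick(ROOT / "gene_tree.nwk")
    out = phylo.tree_concordance(pheno, gene)
    (ROOT / "concordance.json").write_text(json.dumps(out, indent=2))
    print(json.dumps(out, indent=2))
    n = len(list(pheno.tips()))
    if out["normalized_rf"] == 0:
        print(f"the phenogram and gene tree agree on every split ({n} taxa)")
    else:
        print(f"{out['robinson_foulds']} of {2 * (n - 3)} possible split "
              "differences between phenome and genome trees")


if __name__ == "__main__":
    main()
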