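#!/usr/bin/env python
"""Species comparisons for every behavioral endpoint.

Kruskal-Wallis omnibus tests with uncorrected pairwise Dunn tests and
figure-style compact letter displays for each endpoint; the time-binned
novel tank endpoints additionally get the mixed two-way ANOVA
(species x bin, Geisser-Greenhouse corrected) with uncorrected Fisher's LSD.
Also reports each group's coefficient of variation per endpoint as a
reproducibility summary. Writes results/statistics.tsv and
results/novel_tank_anova.tsv.
"""

from pathlib import Path

import pandas as pd

from phenofish import pipeline, stats
from phenofish.synthdata import load_study
from phenofish.zones import novel_tank_endpoints

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    tidy = pd.read_csv(ROOT / "endpoints.tsv", sep="\t")
    table = pipeline.endpoint_statistics(tidy)
    table.to_csv(ROOT / "statistics.tsv", sep="\t", index=False)
    n_sig = int((table["p"] < 0.05).sum())
    print(f"Kruskal-Wallis + Dunn on {len(table)} endpoints -> "
          f"{ROOT / 'statistics.tsv'}; {n_sig} significant at alpha=0.05")
    print(table.sort_values("p").head(10).to_string(index=False))

    # repeated-measures ANOVA over novel-tank bins (speed endpoint per bin)
    study = load_study(ROOT / "study")
    rows = []
    for (group, assay, session), traj in study["trajectories"].items():
        if assay != "novel_tank":
            continue
        per_bin = novel_tank_endpoints(traj, study["arena"])
        for _, r in per_bin.iterrows():
            if not r["bin_missing"]:
                rows.append({"subject": f"{group}_{session}", "group": group,
                             "bin": int(r["bin"]),
                             "value": r["average_speed_cm_s"]})
    d = pd.DataFrame(rows)
    res = stats.rm_anova_gg(d)
    res["anova"].to_csv(ROOT / "novel_tank_anova.tsv", sep="\t", index=False)
    print(f"\nnovel tank speed, mixed ANOVA (epsilon-hat = "
          f"{res['epsilon']:.3f}):")
    print(res["anova"].to_string(index=False))

    cv = (tidy.groupby(["endpoint", "group"])["value"]
          .apply(stats.coefficient_of_variation).rename("cv_pct")
          .reset_index())
    cv.to_csv(ROOT / "coefficients_of_variation.tsv", sep="\t", index=False)
    print("\nmedian CV (%) per group:")
    print(cv.groupby("group")["cv_pct"].median().round(1).to_string())


if __name__ == "__main__":
    main()
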