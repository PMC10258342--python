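"""Pattern analysis of the BLUP mean matrices.

Standardizes each accession x trait BLUP matrix, runs PCA for the
biplot (scores, loadings, percentage of variation per component) and
Ward hierarchical clustering, truncating at the study's group levels:
three groups for the first year, two for the second, three across
years.  Group trait means are reported in original units.
"""

from pathlib import Path

import pandas as pd

from seedtraits.pattern import pattern_analysis
from seedtraits.repeatability import build_blup_matrix
from seedtraits.trait_data import load_trait_table

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ds = load_trait_table(RESULTS / "trial.csv")
    for scope, year, k, name in (
        ("single_year", ds.years[0], 3, f"pattern_{ds.years[0]}"),
        ("single_year", ds.years[1], 2, f"pattern_{ds.years[1]}"),
        ("across_years", None, 3, "pattern_across"),
    ):
        bm = build_blup_matrix(ds, scope=scope, year=year).drop_constant()
        res = pattern_analysis(bm, k=k)
        res.scores.to_csv(RESULTS / f"{name}_scores.csv")
        res.loadings.to_csv(RESULTS / f"{name}_loadings.csv")
        pd.DataFrame(
            {"component": res.scores.columns, "pct_var": res.pct_var}
        ).to_csv(RESULTS / f"{name}_pctvar.csv", index=False)
        res.clusters.to_frame().to_csv(RESULTS / f"{name}_clusters.csv")
        res.group_means.to_csv(RESULTS / f"{name}_groupmeans.csv")
        sizes = res.group_means["n_accessions"].to_dict()
        print(f"{name}: PC1 {res.pct_var[0]:.2f}%, PC2 {res.pct_var[1]:.2f}% "
              f"of variation; k={k} group sizes {sizes}")


if __name__ == "__main__":
    main()
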