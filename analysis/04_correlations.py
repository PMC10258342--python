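"""Phenotypic correlations between traits, per year and across years.

Pearson correlations over the accession BLUP means with two-sided
t-test p-values and 0.05/0.01 significance stars.  Traits whose BLUP
column is constant (genotypic variance clamped to zero, total
shrinkage) carry no between-accession information and are dropped from
the correlation tables; the console output names them.
"""

from pathlib import Path

import pandas as pd

from seedtraits.association import phenotypic_correlation
from seedtraits.repeatability import build_blup_matrix
from seedtraits.trait_data import load_trait_table

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ds = load_trait_table(RESULTS / "trial.csv")
    for scope, year, name in (
        ("single_year", ds.years[0], f"corr_{ds.years[0]}"),
        ("single_year", ds.years[1], f"corr_{ds.years[1]}"),
        ("across_years", None, "corr_across"),
    ):
        bm = build_blup_matrix(ds, scope=scope, year=year)
        kept = bm.drop_constant()
        dropped = sorted(set(bm.traits) - set(kept.traits))
        cm = phenotypic_correlation(kept)
        cm.long().to_csv(RESULTS / f"{name}.csv", index=False)
        strong = cm.long().query("stars == '**'")
        note = f" (dropped constant: {', '.join(dropped)})" if dropped else ""
        print(f"{name}: {len(strong)} trait pairs significant at P<0.01"
              f"{note} -> {RESULTS / (name + '.csv')}")


if __name__ == "__main__":
    main()
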