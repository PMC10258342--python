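"""Accession-mean repeatability and BLUP-adjusted mean matrices.

Computes R1 per trait within each year and R2 across years from the
fitted variance components, and builds the accession x trait matrices of
BLUP-adjusted means (the across-years matrix is adjusted for
genotype-by-year interaction through the R2 shrinkage factor).
"""

from pathlib import Path

import pandas as pd

from seedtraits.repeatability import (
    build_blup_matrix,
    repeatability_across,
    repeatability_single,
)
from seedtraits.trait_data import load_trait_table, validate_design
from seedtraits.varcomp import fit_across_years, fit_single_year

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ds = load_trait_table(RESULTS / "trial.csv")
    design = validate_design(ds)

    rows = []
    for year in ds.years:
        for trait in ds.traits:
            vc = fit_single_year(ds, trait, year)
            try:
                r1 = repeatability_single(vc.sigma_g2, vc.sigma_e2, design.nr).value
            except ZeroDivisionError:
                r1 = float("nan")
            rows.append(dict(scope=f"R1_{year}", trait=trait, R=r1))
    for trait in ds.traits:
        vc = fit_across_years(ds, trait)
        r2 = repeatability_across(
            vc.sigma_g2, vc.sigma_gy2, vc.sigma_e2, design.nl, design.nr
        ).value
        rows.append(dict(scope="R2", trait=trait, R=r2))
    rep = pd.DataFrame(rows).pivot(index="trait", columns="scope", values="R")
    rep = rep.loc[list(ds.traits)]
    rep.to_csv(RESULTS / "repeatability.csv")
    r2 = rep["R2"]
    print(f"R2 ranges from {r2.min():.3f} ({r2.idxmin()}) to "
          f"{r2.max():.3f} ({r2.idxmax()}) -> {RESULTS / 'repeatability.csv'}")

    for scope, year, name in (
        ("single_year", ds.years[0], f"blup_{ds.years[0]}"),
        ("single_year", ds.years[1], f"blup_{ds.years[1]}"),
        ("across_years", None, "blup_across"),
    ):
        bm = build_blup_matrix(ds, scope=scope, year=year)
        bm.values.to_csv(RESULTS / f"{name}.csv")
        print(f"{name}: {bm.values.shape[0]} x {bm.values.shape[1]} matrix, "
              f"mean shrinkage {bm.shrinkage.mean():.3f}")


if __name__ == "__main__":
    main()
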