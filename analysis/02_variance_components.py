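"""Variance components and genotypic significance per trait.

Fits the single-year model for each year and the across-years mixed
model (year fixed; genotype and genotype-by-year random) for every
trait, runs the boundary-mixture REML likelihood-ratio test of genotypic
variation, and tabulates components with standard errors plus the
least significant difference between accession means.
"""

from pathlib import Path

import pandas as pd

from seedtraits.trait_data import load_trait_table, validate_design
from seedtraits.varcomp import fit_across_years, fit_single_year, lrt_genotype, lsd

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ds = load_trait_table(RESULTS / "trial.csv")
    design = validate_design(ds)

    for year in ds.years:
        rows = []
        for trait in ds.traits:
            vc = fit_single_year(ds, trait, year)
            t = lrt_genotype(ds, trait, model="single_year", year=year)
            rows.append(dict(
                trait=trait, sigma_g2=vc.sigma_g2, se_g=vc.se_g,
                sigma_e2=vc.sigma_e2, se_e=vc.se_e, truncated=vc.truncated,
                lr_stat=t.lr_stat, p_value=t.p_value, lsd_005=lsd(vc).lsd,
            ))
        out = RESULTS / f"varcomp_{year}.csv"
        pd.DataFrame(rows).to_csv(out, index=False)
        n_sig = sum(r["p_value"] < 0.05 for r in rows)
        print(f"{year}: {n_sig}/{len(rows)} traits with significant genotypic "
              f"variation (P<0.05) -> {out}")

    rows = []
    for trait in ds.traits:
        vc = fit_across_years(ds, trait)
        t = lrt_genotype(ds, trait, model="across_years")
        rows.append(dict(
            trait=trait, sigma_g2=vc.sigma_g2, se_g=vc.se_g,
            sigma_gy2=vc.sigma_gy2, se_gy=vc.se_gy,
            sigma_e2=vc.sigma_e2, se_e=vc.se_e,
            truncated=",".join(sorted(vc.truncated_components)),
            lr_stat=t.lr_stat, p_value=t.p_value, lsd_005=lsd(vc).lsd,
        ))
    out = RESULTS / "varcomp_across.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    n_sig = sum(r["p_value"] < 0.05 for r in rows)
    print(f"across years ({design.nl} years): {n_sig}/{len(rows)} traits "
          f"significant -> {out}")


if __name__ == "__main__":
    main()
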