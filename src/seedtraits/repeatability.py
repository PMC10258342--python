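"""Accession-mean repeatability and BLUP-adjusted accession means.

Repeatability of an accession mean is the fraction of the variance of
that mean attributable to genotype:

* within one year:   ``R1 = sigma_g2 / (sigma_g2 + sigma_e2 / nr)``
* across years:      ``R2 = sigma_g2 / (sigma_g2 + sigma_gy2 / nl
  + sigma_e2 / (nl nr))``

For the balanced random-intercept structure the BLUP of an accession
effect is a shrinkage of its raw mean deviation toward the grand mean,
and the shrinkage factor is *exactly* the matching repeatability.  The
across-years shrinkage therefore adjusts the accession means for
genotype-by-year interaction: interaction variance inflates the
denominator and pulls the predicted means closer together.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .trait_data import TraitDataset
from .varcomp import (
    VarCompAcross,
    VarCompSingle,
    fit_across_years,
    fit_single_year,
)

__all__ = [
    "RepeatabilityResult",
    "BlupMatrix",
    "repeatability_single",
    "repeatability_across",
    "blup_accession_means",
    "build_blup_matrix",
]


@dataclass(frozen=True)
class RepeatabilityResult:
    trait: str
    scope: str  # "single_year" | "across_years"
    value: float
    nl: int
    nr: int
    components: dict


@dataclass(frozen=True)
class BlupMatrix:
    """Accession x trait matrix of BLUP-adjusted means."""

    values: pd.DataFrame  # index: accessions, columns: traits
    grand_means: pd.Series
    shrinkage: pd.Series  # per-trait shrinkage factor in [0, 1]
    scope: str = "across_years"

    @property
    def accessions(self) -> tuple:
        return tuple(self.values.index)

    @property
    def traits(self) -> tuple:
        return tuple(self.values.columns)

    def drop_constant(self) -> "BlupMatrix":
        """Drop traits whose BLUP column is constant (fully shrunk because
        the genotypic variance estimate clamped to zero); correlations and
        standardization are undefined for them."""
        varying = [t for t in self.traits if self.values[t].std(ddof=1) > 0]
        return BlupMatrix(
            values=self.values[varying],
            grand_means=self.grand_means[varying],
            shrinkage=self.shrinkage[varying],
            scope=self.scope,
        )


def _check_nonneg(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")


def repeatability_single(
    sigma_g2: float, sigma_e2: float, nr: int, trait: str = ""
) -> RepeatabilityResult:
    """R1 = sigma_g2 / (sigma_g2 + sigma_e2 / nr)."""
    _check_nonneg(sigma_g2=sigma_g2, sigma_e2=sigma_e2)
    if nr < 1:
        raise ValueError("nr must be >= 1")
    denom = sigma_g2 + sigma_e2 / nr
    if denom == 0:
        raise ZeroDivisionError("repeatability undefined: all variances zero")
    return RepeatabilityResult(
        trait=trait,
        scope="single_year",
        value=sigma_g2 / denom,
        nl=1,
        nr=int(nr),
        components={"sigma_g2": sigma_g2, "sigma_e2": sigma_e2},
    )


def repeatability_across(
    sigma_g2: float,
    sigma_gy2: float,
    sigma_e2: float,
    nl: int,
    nr: int,
    trait: str = "",
) -> RepeatabilityResult:
    """R2 = sigma_g2 / (sigma_g2 + sigma_gy2 / nl + sigma_e2 / (nl nr))."""
    _check_nonneg(sigma_g2=sigma_g2, sigma_gy2=sigma_gy2, sigma_e2=sigma_e2)
    if nl < 1 or nr < 1:
        raise ValueError("nl and nr must be >= 1")
    denom = sigma_g2 + sigma_gy2 / nl + sigma_e2 / (nl * nr)
    if denom == 0:
        raise ZeroDivisionError("repeatability undefined: all variances zero")
    return RepeatabilityResult(
        trait=trait,
        scope="across_years",
        value=sigma_g2 / denom,
        nl=int(nl),
        nr=int(nr),
        components={
            "sigma_g2": sigma_g2,
            "sigma_gy2": sigma_gy2,
            "sigma_e2": sigma_e2,
        },
    )


def shrinkage_factor(vc: VarCompSingle | VarCompAcross, nl: int, nr: int) -> float:
    """BLUP shrinkage for a balanced design; equals R1 or R2 by identity."""
    if isinstance(vc, VarCompSingle):
        return repeatability_single(vc.sigma_g2, vc.sigma_e2, nr).value
    return repeatability_across(vc.sigma_g2, vc.sigma_gy2, vc.sigma_e2, nl, nr).value


def blup_accession_means(
    ds: TraitDataset,
    trait: str,
    vc: VarCompSingle | VarCompAcross,
) -> pd.Series:
    """One BLUP-adjusted mean per accession for a single trait.

    ``BLUP_i = mu_hat + lambda (ybar_i - ybar)`` where ``lambda`` is the
    repeatability of the accession mean computed from ``vc``.  If every
    component is zero the shrinkage target is the grand mean itself
    (``lambda = 0`` by convention).
    """
    year = vc.year if isinstance(vc, VarCompSingle) else None
    sub = ds.subset(trait=trait, year=year).records
    if isinstance(vc, VarCompAcross):
        yrs = set(pd.unique(sub["year"]))
        if yrs != set(vc.year_means):
            raise ValueError(
                f"variance components fitted on years {sorted(vc.year_means)} "
                f"but data cover {sorted(yrs)}"
            )
    counts = sub.groupby(["accession", "year"], sort=False)["value"].count()
    if counts.nunique() != 1:
        raise ValueError("BLUP closed form requires a balanced design")
    nr = int(counts.iloc[0])
    nl = sub["year"].nunique()
    try:
        lam = shrinkage_factor(vc, nl, nr)
    except ZeroDivisionError:
        lam = 0.0
    means = sub.groupby("accession", sort=False)["value"].mean()
    grand = float(sub["value"].mean())
    out = grand + lam * (means - grand)
    out.name = trait
    return out


def build_blup_matrix(
    ds: TraitDataset,
    scope: Literal["single_year", "across_years"] = "across_years",
    year: int | None = None,
) -> BlupMatrix:
    """Fit every trait under ``scope`` and assemble the accession x trait
    matrix of BLUP-adjusted means (trait order = dataset trait order)."""
    if scope == "single_year" and year is None:
        raise ValueError("single_year scope needs a year")
    if len(ds.accessions) < 2:
        raise ValueError("need at least 2 accessions for genotypic contrast")
    cols, grand, shrink, failures = {}, {}, {}, []
    for trait in ds.traits:
        try:
            if scope == "single_year":
                vc = fit_single_year(ds, trait, year)
            else:
                vc = fit_across_years(ds, trait)
            col = blup_accession_means(ds, trait, vc)
            cols[trait] = col
            sub = ds.subset(trait=trait, year=year if scope == "single_year" else None)
            grand[trait] = float(sub.records["value"].mean())
            counts = sub.records.groupby(["accession", "year"], sort=False)["value"].count()
            try:
                shrink[trait] = shrinkage_factor(
                    vc, sub.records["year"].nunique(), int(counts.iloc[0])
                )
            except ZeroDivisionError:
                shrink[trait] = 0.0
        except (ValueError, ZeroDivisionError) as exc:
            failures.append(f"{trait}: {exc}")
    if failures:
        raise ValueError("BLUP fits failed for trait(s): " + "; ".join(failures))
    values = pd.DataFrame(cols).loc[list(ds.accessions), list(ds.traits)]
    return BlupMatrix(
        values=values,
        grand_means=pd.Series(grand).loc[list(ds.traits)],
        shrinkage=pd.Series(shrink).loc[list(ds.traits)],
        scope=scope,
    )
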