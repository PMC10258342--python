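"""Phenotypic correlations, MANOVA cross-products and trait-environment
correlations.

Phenotypic correlations are Pearson correlations across accessions of the
BLUP-adjusted means, with two-sided p-values from the t transform
``t = r sqrt((n-2)/(1-r^2))`` on ``n-2`` degrees of freedom and
significance stars at 0.05 (*) and 0.01 (**).  No multiple-testing
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .repeatability import BlupMatrix
from .trait_data import SiteMetadata, TraitDataset

__all__ = [
    "CorrelationMatrix",
    "SscpDecomposition",
    "phenotypic_correlation",
    "sscp_strata",
    "env_correlation",
    "stars_from_p",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    labels: tuple
    r: pd.DataFrame
    p: pd.DataFrame
    n: int
    stars: pd.DataFrame

    def long(self) -> pd.DataFrame:
        """Lower-triangle pairs as a tidy (var1, var2, r, p, stars) table."""
        rows = []
        labs = list(self.labels)
        for i, a in enumerate(labs):
            for b in labs[:i]:
                rows.append(
                    (a, b, self.r.loc[a, b], self.p.loc[a, b], self.stars.loc[a, b])
                )
        return pd.DataFrame(rows, columns=["var1", "var2", "r", "p", "stars"])


@dataclass(frozen=True)
class SscpDecomposition:
    labels: tuple
    between: pd.DataFrame
    within: pd.DataFrame
    df_between: int
    df_within: int


def stars_from_p(p: float, thresholds: tuple[float, float] = (0.05, 0.01)) -> str:
    """Significance markers: '**' below the stricter threshold, '*' below
    the looser one, '' otherwise (pure function of p)."""
    loose, strict = max(thresholds), min(thresholds)
    if p < strict:
        return "**"
    if p < loose:
        return "*"
    return ""


def _corr_with_p(data: pd.DataFrame) -> CorrelationMatrix:
    n = len(data)
    if n < 3:
        raise ValueError(f"need at least 3 observations for correlation, got {n}")
    sds = data.std(ddof=1)
    constant = sds.index[sds == 0].tolist()
    if constant:
        raise ValueError(f"constant column(s): {', '.join(map(str, constant))}")
    r = data.corr(method="pearson")
    rv = r.to_numpy().copy()
    np.fill_diagonal(rv, 1.0)
    rv = np.clip(rv, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = rv * np.sqrt((n - 2) / np.clip(1 - rv**2, 1e-300, None))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    np.fill_diagonal(p, 0.0)
    labels = tuple(data.columns)
    rdf = pd.DataFrame(rv, index=labels, columns=labels)
    pdf = pd.DataFrame(p, index=labels, columns=labels)
    sdf = pdf.map(stars_from_p)
    for lab in labels:
        sdf.loc[lab, lab] = ""
    return CorrelationMatrix(labels=labels, r=rdf, p=pdf, n=n, stars=sdf)


def phenotypic_correlation(bm: BlupMatrix) -> CorrelationMatrix:
    """Pairwise trait correlations over the accession BLUP means."""
    return _corr_with_p(bm.values)


def sscp_strata(
    ds: TraitDataset,
    traits: list[str] | None = None,
    year: int | None = None,
) -> SscpDecomposition:
    """Between-accession and residual sums of cross-products (MANOVA strata).

    With several years present and no ``year`` filter, values are first
    adjusted for the year fixed effect (year means removed), so the
    between + within additivity holds on the adjusted total.
    """
    traits = list(traits or ds.traits)
    sub = ds.subset(year=year).records
    sub = sub[sub["trait"].isin(traits)]
    wide = sub.pivot_table(
        index=["accession", "year", "replicate"],
        columns="trait",
        values="value",
        aggfunc="first",
    )
    if wide.isna().any().any():
        bad = wide.columns[wide.isna().any()].tolist()
        raise ValueError(f"unequal record coverage across traits: {bad}")
    wide = wide[traits]
    counts = sub.groupby(["accession", "year"], sort=False)["trait"].count()
    if counts.nunique() != 1:
        raise ValueError("sscp_strata requires a balanced slice")
    years = wide.index.get_level_values("year")
    nl = years.nunique()
    nr = len(wide) // (wide.index.get_level_values("accession").nunique() * nl)
    # adjust for the year fixed effect
    adj = wide - wide.groupby(level="year").transform("mean") + wide.mean()
    acc_means = adj.groupby(level="accession", sort=False).mean()
    grand = adj.mean()
    dev = acc_means - grand
    between = nl * nr * dev.T @ dev
    total_dev = adj - grand
    total = total_dev.T @ total_dev
    within = total - between
    a = len(acc_means)
    df_between = a - 1
    df_within = len(wide) - 1 - (nl - 1) - (a - 1)
    labels = tuple(traits)
    return SscpDecomposition(
        labels=labels,
        between=between.loc[list(labels), list(labels)],
        within=within.loc[list(labels), list(labels)],
        df_between=df_between,
        df_within=df_within,
    )


def env_correlation(
    bm: BlupMatrix, meta: SiteMetadata, covariates: list[str] | None = None
) -> CorrelationMatrix:
    """Correlations between trait BLUP means and site covariates.

    Returns the joint correlation matrix over traits plus covariates so
    the usual symmetric conventions (unit diagonal, stars) apply; the
    trait x covariate block is the quantity of interest.
    """
    covariates = list(covariates or meta.covariates)
    missing = [a for a in bm.accessions if a not in meta.accessions]
    if missing:
        raise ValueError(f"accession(s) missing from metadata: {', '.join(missing)}")
    unknown = [c for c in covariates if c not in meta.covariates]
    if unknown:
        raise ValueError(f"unknown covariate(s): {', '.join(unknown)}")
    cov = meta.table.loc[list(bm.accessions), covariates]
    joint = pd.concat([bm.values, cov], axis=1)
    return _corr_with_p(joint)
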