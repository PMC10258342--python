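"""Variance components for balanced seed-trait trials.

Two models are supported, both with genotype (accession) random:

* single-year:  ``y_ik = mu + g_i + e_ik``
* across-years: ``y_ijk = mu + Y_j + g_i + (gY)_ij + e_ijk``

with year a *fixed* effect and genotype and genotype-by-year random.  On
balanced data the ANOVA strata are independent scaled chi-squares, so the
method-of-moments (expected-mean-squares) solution is also the REML
solution whenever it is interior; negative solutions are clamped at zero
and flagged.  An EM-type REML iteration handles the general (possibly
unbalanced) case and doubles as an internal cross-check of the closed
form.

Standard errors on the balanced path use the large-sample mean-square
variance ``Var(MS) = 2 MS^2 / df`` propagated through the linear
combinations; on the iterative path they come from the inverse expected
information at convergence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .trait_data import TraitDataset, validate_design

__all__ = [
    "VarCompSingle",
    "VarCompAcross",
    "GenotypicTest",
    "LsdResult",
    "UnbalancedError",
    "fit_single_year",
    "fit_across_years",
    "em_reml",
    "lrt_genotype",
    "lsd",
]


class UnbalancedError(ValueError):
    """Balanced-path estimator applied to an unbalanced slice."""


@dataclass(frozen=True)
class VarCompSingle:
    trait: str
    year: int
    sigma_g2: float
    sigma_e2: float
    se_g: float
    se_e: float
    ms_g: float
    ms_e: float
    df_g: int
    df_e: int
    truncated: bool
    loglik: float = float("nan")  # restricted log-likelihood at the estimate

    @property
    def nr(self) -> float:
        """Replication implied by the mean squares (balanced data only)."""
        if self.sigma_g2 > 0 and not self.truncated:
            return (self.ms_g - self.ms_e) / self.sigma_g2
        return float("nan")


@dataclass(frozen=True)
class VarCompAcross:
    trait: str
    sigma_g2: float
    sigma_gy2: float
    sigma_e2: float
    se_g: float
    se_gy: float
    se_e: float
    year_means: dict
    truncated_components: frozenset
    ms_g: float = float("nan")
    ms_gy: float = float("nan")
    ms_e: float = float("nan")
    df_g: int = 0
    df_gy: int = 0
    df_e: int = 0
    loglik: float = float("nan")


@dataclass(frozen=True)
class GenotypicTest:
    trait: str
    lr_stat: float
    p_value: float
    model: str


@dataclass(frozen=True)
class LsdResult:
    trait: str
    alpha: float
    lsd: float
    df: int
    n_eff: float


# ---------------------------------------------------------------------------
# balanced ANOVA strata


def _slice(ds: TraitDataset, trait: str, year: int | None) -> pd.DataFrame:
    sub = ds.subset(trait=trait, year=year)
    return sub.records


def _single_year_strata(df: pd.DataFrame):
    """(SS, df) for the residual and genotype strata of a one-way layout."""
    counts = df.groupby("accession", sort=False)["value"].count()
    if counts.nunique() != 1:
        raise UnbalancedError(
            "unequal replicate counts across accessions; use em_reml for "
            "unbalanced data"
        )
    nr = int(counts.iloc[0])
    a = len(counts)
    if a < 2:
        raise ValueError("need at least 2 accessions to estimate sigma_g2")
    if nr < 2:
        raise ValueError("need nr >= 2 replicates to estimate sigma_e2")
    y = df["value"].to_numpy()
    means = df.groupby("accession", sort=False)["value"].mean()
    grand = y.mean()
    ss_e = float(((df["value"] - df["accession"].map(means)) ** 2).sum())
    ss_g = float(nr * ((means - grand) ** 2).sum())
    return a, nr, (ss_e, a * (nr - 1)), (ss_g, a - 1)


def _across_years_strata(df: pd.DataFrame):
    """(SS, df) for residual, g x y and genotype strata, year fixed."""
    cell = df.groupby(["accession", "year"], sort=False)["value"]
    counts = cell.count()
    if counts.nunique() != 1:
        raise UnbalancedError("missing or unequal cells; use em_reml")
    accs = df["accession"].unique()
    yrs = df["year"].unique()
    a, nl = len(accs), len(yrs)
    if len(counts) != a * nl:
        raise UnbalancedError("missing accession x year cells; use em_reml")
    if nl < 2:
        raise ValueError("single year of data; use fit_single_year")
    if a < 2:
        raise ValueError("need at least 2 accessions")
    nr = int(counts.iloc[0])
    if nr < 2:
        raise ValueError("need nr >= 2 replicates")
    cm = cell.mean().unstack()  # accession x year cell means
    cm = cm.loc[accs, yrs]
    ss_e = float(
        ((df["value"] - df.set_index(["accession", "year"]).index.map(cell.mean())) ** 2).sum()
    )
    gm = cm.to_numpy()
    acc_mean = gm.mean(axis=1, keepdims=True)
    yr_mean = gm.mean(axis=0, keepdims=True)
    grand = gm.mean()
    inter = gm - acc_mean - yr_mean + grand
    ss_gy = float(nr * (inter**2).sum())
    ss_g = float(nl * nr * ((acc_mean - grand) ** 2).sum())
    year_means = {int(y): float(m) for y, m in zip(yrs, gm.mean(axis=0))}
    return (
        a,
        nl,
        nr,
        (ss_e, a * nl * (nr - 1)),
        (ss_gy, (a - 1) * (nl - 1)),
        (ss_g, a - 1),
        year_means,
    )


def fit_single_year(ds: TraitDataset, trait: str, year: int) -> VarCompSingle:
    """Expected-mean-squares variance components for one trait in one year.

    ``sigma_e2 = MS_e`` and ``sigma_g2 = (MS_g - MS_e) / nr``, clamped at
    zero with a ``truncated`` flag.  Identical for any record order.
    """
    df = _slice(ds, trait, year)
    a, nr, (ss_e, df_e), (ss_g, df_g) = _single_year_strata(df)
    ms_e = ss_e / df_e
    ms_g = ss_g / df_g
    sigma_e2 = ms_e
    sigma_g2 = (ms_g - ms_e) / nr
    truncated = sigma_g2 < 0
    sigma_g2 = max(sigma_g2, 0.0)
    se_e = float(np.sqrt(2 * ms_e**2 / df_e))
    se_g = float(np.sqrt(2 * ms_g**2 / df_g + 2 * ms_e**2 / df_e) / nr)
    lam = _pava([(ss_e, df_e), (ss_g, df_g)])
    return VarCompSingle(
        trait=trait,
        year=int(year),
        sigma_g2=float(sigma_g2),
        sigma_e2=float(sigma_e2),
        se_g=se_g,
        se_e=se_e,
        ms_g=float(ms_g),
        ms_e=float(ms_e),
        df_g=int(df_g),
        df_e=int(df_e),
        truncated=bool(truncated),
        loglik=-0.5 * _strata_nll([(ss_e, df_e), (ss_g, df_g)], lam),
    )


def fit_across_years(ds: TraitDataset, trait: str) -> VarCompAcross:
    """Variance components over years: genotype and g x y random, year fixed.

    Balanced-data solution: ``sigma_e2 = MS_e``,
    ``sigma_gy2 = (MS_gy - MS_e)/nr``, ``sigma_g2 = (MS_g - MS_gy)/(nl nr)``,
    each clamped at zero.
    """
    df = _slice(ds, trait, None)
    a, nl, nr, (ss_e, df_e), (ss_gy, df_gy), (ss_g, df_g), year_means = _across_years_strata(df)
    ms_e, ms_gy, ms_g = ss_e / df_e, ss_gy / df_gy, ss_g / df_g
    sigma_e2 = ms_e
    sigma_gy2 = (ms_gy - ms_e) / nr
    sigma_g2 = (ms_g - ms_gy) / (nl * nr)
    truncated = set()
    if sigma_gy2 < 0:
        truncated.add("sigma_gy2")
        sigma_gy2 = 0.0
    if sigma_g2 < 0:
        truncated.add("sigma_g2")
        sigma_g2 = 0.0
    se_e = float(np.sqrt(2 * ms_e**2 / df_e))
    se_gy = float(np.sqrt(2 * ms_gy**2 / df_gy + 2 * ms_e**2 / df_e) / nr)
    se_g = float(np.sqrt(2 * ms_g**2 / df_g + 2 * ms_gy**2 / df_gy) / (nl * nr))
    strata = [(ss_e, df_e), (ss_gy, df_gy), (ss_g, df_g)]
    lam = _pava(strata)
    return VarCompAcross(
        trait=trait,
        sigma_g2=float(sigma_g2),
        sigma_gy2=float(sigma_gy2),
        sigma_e2=float(sigma_e2),
        se_g=se_g,
        se_gy=se_gy,
        se_e=se_e,
        year_means=year_means,
        truncated_components=frozenset(truncated),
        ms_g=float(ms_g),
        ms_gy=float(ms_gy),
        ms_e=float(ms_e),
        df_g=int(df_g),
        df_gy=int(df_gy),
        df_e=int(df_e),
        loglik=-0.5 * _strata_nll(strata, lam),
    )


# ---------------------------------------------------------------------------
# restricted likelihood of balanced strata

# On balanced data the error contrasts decompose into independent strata
# with SS_k / lambda_k ~ chi^2_{df_k}, where the stratum variances are
# lambda_e = sigma_e2, lambda_gy = sigma_e2 + nr sigma_gy2,
# lambda_g = lambda_gy + nl nr sigma_g2 (single-year: lambda_g =
# sigma_e2 + nr sigma_g2).  Non-negative components mean the lambdas are
# non-decreasing, so the constrained REML maximum is an isotonic
# regression of the stratum mean squares (pool adjacent violators).


def _pava(strata: list[tuple[float, float]]) -> list[float]:
    """Isotonic (non-decreasing) REML solution for stratum variances."""
    blocks = [[ss, df] for ss, df in strata]  # mutable [SS, df] pools
    idx = [[i] for i in range(len(strata))]
    k = 0
    while k < len(blocks) - 1:
        lam_k = blocks[k][0] / blocks[k][1]
        lam_n = blocks[k + 1][0] / blocks[k + 1][1]
        if lam_n < lam_k:
            blocks[k][0] += blocks[k + 1][0]
            blocks[k][1] += blocks[k + 1][1]
            idx[k].extend(idx[k + 1])
            del blocks[k + 1], idx[k + 1]
            k = max(k - 1, 0)
        else:
            k += 1
    lam = [0.0] * len(strata)
    for block, members in zip(blocks, idx):
        for i in members:
            lam[i] = block[0] / block[1]
    return lam


def _strata_nll(strata: list[tuple[float, float]], lam: list[float]) -> float:
    """-2 x restricted log-likelihood (up to a constant).

    Degenerate strata (zero variance with zero sum of squares) carry no
    information and are skipped; they cancel in likelihood-ratio
    differences.
    """
    total = 0.0
    for (ss, df), l in zip(strata, lam):
        if l == 0.0:
            if ss == 0.0:
                continue
            return float("inf")
        total += df * np.log(l) + ss / l
    return float(total)


def lrt_genotype(
    ds: TraitDataset,
    trait: str,
    model: Literal["single_year", "across_years"] = "single_year",
    year: int | None = None,
) -> GenotypicTest:
    """REML likelihood-ratio test of H0: sigma_g2 = 0.

    The null puts the genotypic variance on the boundary of its parameter
    space, so the reference distribution is the mixture
    ``1/2 chi^2_0 + 1/2 chi^2_1``: ``p = 1/2 P(chi^2_1 >= LR)`` for
    ``LR > 0`` and ``p = 1`` at ``LR = 0``.  Both fits share the same
    fixed-effect structure, as a REML comparison requires.
    """
    if model == "single_year":
        if year is None:
            yrs = ds.subset(trait=trait).years
            if len(yrs) != 1:
                raise ValueError("single_year model needs an explicit year")
            year = yrs[0]
        df = _slice(ds, trait, year)
        _, _, s_e, s_g = _single_year_strata(df)
        strata = [s_e, s_g]
    elif model == "across_years":
        df = _slice(ds, trait, None)
        _, _, _, s_e, s_gy, s_g, _ = _across_years_strata(df)
        strata = [s_e, s_gy, s_g]
    else:
        raise ValueError(f"unknown model {model!r}")
    lam_full = _pava(strata)
    # reduced model: sigma_g2 = 0 merges the genotype stratum into its
    # neighbour (lambda_g = lambda_gy, or lambda_e in the one-way layout)
    merged = strata[:-2] + [
        (strata[-2][0] + strata[-1][0], strata[-2][1] + strata[-1][1])
    ]
    lam_merged = _pava(merged)
    lam_reduced = lam_merged + [lam_merged[-1]]
    lr = _strata_nll(strata, lam_reduced) - _strata_nll(strata, lam_full)
    lr = max(lr, 0.0)
    p = 1.0 if lr == 0.0 else 0.5 * float(stats.chi2.sf(lr, 1))
    return GenotypicTest(trait=trait, lr_stat=float(lr), p_value=p, model=model)


def lsd(
    vc: VarCompSingle | VarCompAcross,
    alpha: float = 0.05,
    n_eff: float | None = None,
) -> LsdResult:
    """Least significant difference between two accession means.

    ``lsd = t_{1-alpha/2, df_e} * sqrt(2 sigma_e2 / n_eff)``; by default
    ``n_eff`` is the replication of an accession mean: ``nr`` within a
    year and ``nl * nr`` across years.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n_eff is None:
        if isinstance(vc, VarCompSingle):
            # df_e = a (nr - 1), df_g = a - 1  =>  nr = df_e / (df_g + 1) + 1
            n_eff = vc.df_e / (vc.df_g + 1) + 1
        else:
            a = vc.df_g + 1
            nl = vc.df_gy // vc.df_g + 1
            n_eff = nl * (vc.df_e / (a * nl) + 1)
    t = float(stats.t.ppf(1 - alpha / 2, vc.df_e))
    val = 0.0 if vc.sigma_e2 == 0 else t * float(np.sqrt(2 * vc.sigma_e2 / n_eff))
    return LsdResult(trait=vc.trait, alpha=alpha, lsd=val, df=int(vc.df_e), n_eff=float(n_eff))


# ---------------------------------------------------------------------------
# EM-REML for the general case


def _design(df: pd.DataFrame, model: str):
    """Response, fixed-effect and random-effect design matrices."""
    y = df["value"].to_numpy(float)
    acc = pd.Categorical(df["accession"], categories=pd.unique(df["accession"]))
    Zg = pd.get_dummies(acc, dtype=float).to_numpy()
    if model == "single_year":
        X = np.ones((len(y), 1))
        return y, X, [Zg], ["sigma_g2"]
    yr = pd.Categorical(df["year"], categories=pd.unique(df["year"]))
    X = pd.get_dummies(yr, dtype=float).to_numpy()  # cell-means coding: year means
    cell = pd.Categorical(
        df["accession"].astype(str) + "\x1f" + df["year"].astype(str)
    )
    Zgy = pd.get_dummies(cell, dtype=float).to_numpy()
    return y, X, [Zg, Zgy], ["sigma_g2", "sigma_gy2"]


def _reml_loglik(y, X, Zs, comps, sigma_e2):
    n = len(y)
    V = sigma_e2 * np.eye(n)
    for s2, Z in zip(comps, Zs):
        V += s2 * (Z @ Z.T)
    Vinv = np.linalg.inv(V)
    XtVX = X.T @ Vinv @ X
    P = Vinv - Vinv @ X @ np.linalg.solve(XtVX, X.T @ Vinv)
    sign, logdetV = np.linalg.slogdet(V)
    sign2, logdetX = np.linalg.slogdet(XtVX)
    return -0.5 * (logdetV + logdetX + float(y @ P @ y)), P


def em_reml(
    ds: TraitDataset,
    trait: str,
    model: Literal["single_year", "across_years"] = "across_years",
    year: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 10000,
) -> VarCompSingle | VarCompAcross:
    """EM-type REML iteration for the random-effects model (year fixed).

    The EM update keeps every variance non-negative and the restricted
    log-likelihood non-decreasing.  Convergence is declared when every
    component moves by less than ``tol`` (relative to total variance)
    between successive iterations.  Initialisation is the
    method-of-moments solution clamped to a small positive floor, or a
    crude variance split when the data are unbalanced.

    On balanced data with an interior moment solution this agrees with
    :func:`fit_single_year` / :func:`fit_across_years` to high accuracy.
    """
    df = _slice(ds, trait, year if model == "single_year" else None)
    if model == "single_year" and year is None:
        yrs = pd.unique(df["year"])
        if len(yrs) != 1:
            raise ValueError("single_year model needs an explicit year")
    if df["accession"].nunique() < 2:
        raise ValueError("need at least 2 accessions")
    y, X, Zs, names = _design(df, model)
    n = len(y)
    if n - X.shape[1] - sum(Z.shape[1] for Z in Zs) + len(Zs) <= 0:
        pass  # rank bookkeeping is delicate for unbalanced data; rely on df check below
    rep_counts = df.groupby(["accession", "year"], sort=False)["value"].count()
    if (rep_counts < 2).all():
        raise ValueError("no cell with >= 2 replicates; sigma_e2 not estimable")

    total = float(np.var(y, ddof=1))
    if total == 0.0:
        zero = 0.0
        comps = [0.0] * len(Zs)
        return _package_em(ds, df, trait, model, year, comps, zero, names, [0.0] * (len(Zs) + 1), 0.0)
    floor = 1e-6 * total
    # moment-style start: within-cell variance for sigma_e2, rest split evenly
    within = df.groupby(["accession", "year"], sort=False)["value"].var(ddof=1)
    sigma_e2 = max(float(np.nanmean(within)), floor)
    rest = max(total - sigma_e2, floor)
    comps = [max(rest / len(Zs), floor)] * len(Zs)

    qs = [Z.shape[1] for Z in Zs]
    ll_prev = -np.inf
    traj = []
    for it in range(max_iter):
        ll, P = _reml_loglik(y, X, Zs, comps, sigma_e2)
        if ll < ll_prev - 1e-6:
            raise RuntimeError(
                f"restricted likelihood decreased at iteration {it}: {ll_prev} -> {ll}"
            )
        ll_prev = ll
        Py = P @ y
        new_comps = []
        for s2, Z, q in zip(comps, Zs, qs):
            ZtPy = Z.T @ Py
            trZPZ = float(np.einsum("ij,ji->", Z.T @ P, Z))
            new = s2 + (s2**2 / q) * (float(ZtPy @ ZtPy) - trZPZ)
            new_comps.append(max(new, 0.0))
        new_e = sigma_e2 + (sigma_e2**2 / n) * (float(Py @ Py) - float(np.trace(P)))
        new_e = max(new_e, 0.0)
        delta = max(
            max(abs(a - b) for a, b in zip(new_comps, comps)), abs(new_e - sigma_e2)
        )
        comps, sigma_e2 = new_comps, new_e
        traj.append((it, *comps, sigma_e2))
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"EM-REML did not converge in {max_iter} iterations; "
            f"last iterates: {traj[-3:]}"
        )
    ll, P = _reml_loglik(y, X, Zs, comps, sigma_e2)
    ses = _info_se(y, X, Zs, comps, sigma_e2, P)
    return _package_em(ds, df, trait, model, year, comps, sigma_e2, names, ses, ll)


def _info_se(y, X, Zs, comps, sigma_e2, P):
    """SEs from the inverse expected information at the REML estimate."""
    As = [Z @ Z.T for Z in Zs] + [np.eye(len(y))]
    m = len(As)
    info = np.zeros((m, m))
    PAs = [P @ A for A in As]
    for i in range(m):
        for j in range(i, m):
            info[i, j] = info[j, i] = 0.5 * float(np.einsum("ij,ji->", PAs[i], PAs[j]))
    try:
        cov = np.linalg.pinv(info)
        return list(np.sqrt(np.clip(np.diag(cov), 0, None)))
    except np.linalg.LinAlgError:
        return [float("nan")] * m


def _package_em(ds, df, trait, model, year, comps, sigma_e2, names, ses, ll):
    balanced_ms = {}
    try:
        if model == "single_year":
            _, nr, (ss_e, df_e), (ss_g, df_g) = _single_year_strata(df)
            balanced_ms = dict(ms_g=ss_g / df_g, ms_e=ss_e / df_e, df_g=df_g, df_e=df_e)
        else:
            _, nl, nr, (ss_e, df_e), (ss_gy, df_gy), (ss_g, df_g), _ = _across_years_strata(df)
            balanced_ms = dict(
                ms_g=ss_g / df_g, ms_gy=ss_gy / df_gy, ms_e=ss_e / df_e,
                df_g=df_g, df_gy=df_gy, df_e=df_e,
            )
    except (UnbalancedError, ValueError):
        n = len(df)
        balanced_ms = dict(df_e=max(n - df["accession"].nunique(), 1))
    if model == "single_year":
        yr = year if year is not None else int(df["year"].iloc[0])
        return VarCompSingle(
            trait=trait,
            year=int(yr),
            sigma_g2=float(comps[0]),
            sigma_e2=float(sigma_e2),
            se_g=float(ses[0]),
            se_e=float(ses[-1]),
            ms_g=float(balanced_ms.get("ms_g", np.nan)),
            ms_e=float(balanced_ms.get("ms_e", np.nan)),
            df_g=int(balanced_ms.get("df_g", df["accession"].nunique() - 1)),
            df_e=int(balanced_ms.get("df_e", 1)),
            truncated=bool(comps[0] == 0.0),
            loglik=float(ll),
        )
    year_means = {
        int(k): float(v) for k, v in df.groupby("year", sort=False)["value"].mean().items()
    }
    truncated = frozenset(
        name for name, c in zip(names, comps) if c == 0.0
    )
    return VarCompAcross(
        trait=trait,
        sigma_g2=float(comps[0]),
        sigma_gy2=float(comps[1]),
        sigma_e2=float(sigma_e2),
        se_g=float(ses[0]),
        se_gy=float(ses[1]),
        se_e=float(ses[-1]),
        year_means=year_means,
        truncated_components=truncated,
        ms_g=float(balanced_ms.get("ms_g", np.nan)),
        ms_gy=float(balanced_ms.get("ms_gy", np.nan)),
        ms_e=float(balanced_ms.get("ms_e", np.nan)),
        df_g=int(balanced_ms.get("df_g", df["accession"].nunique() - 1)),
        df_gy=int(balanced_ms.get("df_gy", 0)),
        df_e=int(balanced_ms.get("df_e", 1)),
        loglik=float(ll),
    )
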