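"""Synthetic seed-trait trials with the generative structure the analysis
assumes.

Observations follow ``y_ijkt = mu_t + Y_jt + g_it + (gY)_ijt + e_ijkt``
with genotype effects drawn accession-wise from a zero-mean multivariate
normal whose covariance is ``diag(s_g) rho diag(s_g)`` (``rho`` a genetic
correlation matrix), and independent normal interaction and residual
draws.  Year effects are fixed offsets summing to zero.  All randomness
flows from one integer seed through per-stratum substreams
(``numpy.random.SeedSequence.spawn``), so one seed gives one dataset,
bit for bit, and partial re-runs are reproducible.

The default configuration mirrors a 15-accession x 2-year x 3-replicate
trial of nine seed-morphology traits (perimeter, length, width,
width/length ratio, hilum length/width and their ratio, thickness and
100-seed weight), with trait means, variance components and a genetic
correlation structure typical of a high-altitude legume germplasm
collection.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .repeatability import repeatability_across
from .trait_data import TraitDataset
from .varcomp import fit_across_years

__all__ = [
    "TraitSpec",
    "SimConfig",
    "GeneticCorrelation",
    "RecoveryReport",
    "simulate_dataset",
    "simulate_grouped_dataset",
    "recovery_experiment",
    "reference_fixture",
    "default_sim_config",
    "default_genetic_correlation",
    "drop_records",
    "TRAIT_NAMES",
]

#: the nine seed traits, in table order
TRAIT_NAMES = ("Pe", "SL", "SW", "W/L", "HL", "HW", "HW/HL", "ST", "SY")

# trait-level summaries of the reference trial: grand means across years,
# per-year averages, and across-year variance components
_MU = (14.778, 4.522, 4.470, 0.989, 1.782, 1.297, 0.729, 3.652, 0.830)
_AVG_Y1 = (14.661, 4.453, 4.405, 0.990, 1.790, 1.295, 0.725, 3.594, 0.791)
_AVG_Y2 = (14.959, 4.592, 4.554, 0.992, 1.773, 1.307, 0.738, 3.730, 0.876)
_SIGMA_G2 = (0.055, 0.043, 0.072, 0.068, 0.180, 0.260, 0.016, 0.058, 0.099)
_SIGMA_E2 = (0.154, 0.016, 0.111, 0.042, 0.080, 0.450, 0.382, 0.004, 0.003)
_SIGMA_GY2 = (0.005, 0.005, 0.008, 0.046, 0.052, 0.069, 0.003, 0.004, 0.015)

# across-year phenotypic correlation pattern of the reference trial
# (lower triangle, trait order as TRAIT_NAMES); used as the target genetic
# correlation after projection to the nearest PSD correlation matrix
_RHO_LOWER = [
    [1.0],
    [0.954, 1.0],
    [0.907, 0.834, 1.0],
    [-0.081, -0.286, 0.289, 1.0],
    [0.466, 0.434, 0.467, 0.058, 1.0],
    [-0.053, -0.079, -0.215, -0.242, 0.299, 1.0],
    [-0.443, -0.436, -0.582, -0.259, -0.610, 0.572, 1.0],
    [0.599, 0.584, 0.755, 0.303, 0.312, -0.554, -0.735, 1.0],
    [0.562, 0.569, 0.717, 0.266, 0.452, -0.520, -0.832, 0.859, 1.0],
]


@dataclass(frozen=True)
class TraitSpec:
    """Generative parameters for one trait."""

    name: str
    mu: float
    sigma_g2: float
    sigma_gy2: float
    sigma_e2: float
    year_effects: tuple = ()  # per-year fixed offsets, summing to 0

    def __post_init__(self) -> None:
        for f in ("sigma_g2", "sigma_gy2", "sigma_e2"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")
        if self.year_effects and abs(sum(self.year_effects)) > 1e-9:
            raise ValueError("year_effects must sum to zero")


@dataclass(frozen=True)
class SimConfig:
    """Design and trait parameters of a simulated balanced trial."""

    n_accessions: int = 15
    years: tuple = (2014, 2019)
    nr: int = 3
    traits: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_accessions < 1 or self.nr < 1 or not self.years:
            raise ValueError("counts must be positive")
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise ValueError("trait names must be unique")
        for t in self.traits:
            if t.year_effects and len(t.year_effects) != len(self.years):
                raise ValueError(
                    f"trait {t.name!r}: {len(t.year_effects)} year effects for "
                    f"{len(self.years)} years"
                )


@dataclass(frozen=True)
class GeneticCorrelation:
    """Correlation matrix of accession genotype effects across traits."""

    traits: tuple
    rho: np.ndarray

    def __post_init__(self) -> None:
        rho = np.asarray(self.rho, float)
        if rho.shape != (len(self.traits),) * 2:
            raise ValueError("rho shape does not match trait list")
        if not np.allclose(rho, rho.T):
            raise ValueError("rho must be symmetric")
        if not np.allclose(np.diag(rho), 1.0):
            raise ValueError("rho must have unit diagonal")
        if np.linalg.eigvalsh(rho).min() < -1e-10:
            raise ValueError("rho is not positive semi-definite")
        object.__setattr__(self, "rho", rho)


@dataclass(frozen=True)
class RecoveryReport:
    """Aggregate of repeated simulate-and-refit experiments."""

    n_sims: int
    table: pd.DataFrame  # one row per trait, truth vs mean/sd of estimates
    n_failures: int = 0
    failures: tuple = ()


def _nearest_psd_corr(m: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Clip negative eigenvalues and rescale to unit diagonal."""
    w, v = np.linalg.eigh((m + m.T) / 2)
    w = np.clip(w, eps, None)
    out = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2


def default_sim_config(seed: int = 0) -> SimConfig:
    """Reference 15 x 2 x 3 trial for nine seed traits."""
    specs = []
    for i, name in enumerate(TRAIT_NAMES):
        y1 = _AVG_Y1[i] - (_AVG_Y1[i] + _AVG_Y2[i]) / 2
        specs.append(
            TraitSpec(
                name=name,
                mu=_MU[i],
                sigma_g2=_SIGMA_G2[i],
                sigma_gy2=_SIGMA_GY2[i],
                sigma_e2=_SIGMA_E2[i],
                year_effects=(y1, -y1),
            )
        )
    return SimConfig(n_accessions=15, years=(2014, 2019), nr=3, traits=tuple(specs), seed=seed)


def default_genetic_correlation() -> GeneticCorrelation:
    """PSD projection of the reference cross-trait correlation pattern."""
    p = len(TRAIT_NAMES)
    rho = np.eye(p)
    for i, row in enumerate(_RHO_LOWER):
        for j, v in enumerate(row):
            rho[i, j] = rho[j, i] = v
    return GeneticCorrelation(traits=TRAIT_NAMES, rho=_nearest_psd_corr(rho))


def _genotype_factor(cfg: SimConfig, gc: GeneticCorrelation | None) -> np.ndarray:
    """Matrix A with A A^T = diag(s_g) rho diag(s_g)."""
    sg = np.sqrt([t.sigma_g2 for t in cfg.traits])
    p = len(cfg.traits)
    if gc is None:
        return np.diag(sg)
    names = tuple(t.name for t in cfg.traits)
    if tuple(gc.traits) != names:
        raise ValueError(
            f"genetic correlation traits {gc.traits} do not match config traits {names}"
        )
    w, v = np.linalg.eigh(gc.rho)
    root = v @ np.diag(np.sqrt(np.clip(w, 0, None)))
    return np.diag(sg) @ root


def _simulate_values(cfg: SimConfig, gc: GeneticCorrelation | None, g_shift=None):
    a, nl, nr, p = cfg.n_accessions, len(cfg.years), cfg.nr, len(cfg.traits)
    ss = np.random.SeedSequence(cfg.seed)
    rng_g, rng_gy, rng_e = (np.random.default_rng(c) for c in ss.spawn(3))
    A = _genotype_factor(cfg, gc)
    g = rng_g.standard_normal((a, p)) @ A.T
    if g_shift is not None:
        g = g + g_shift
    sgy = np.sqrt([t.sigma_gy2 for t in cfg.traits])
    se = np.sqrt([t.sigma_e2 for t in cfg.traits])
    gy = rng_gy.standard_normal((a, nl, p)) * sgy
    e = rng_e.standard_normal((a, nl, nr, p)) * se
    mu = np.array([t.mu for t in cfg.traits])
    yeff = np.zeros((nl, p))
    for t_idx, t in enumerate(cfg.traits):
        if t.year_effects:
            yeff[:, t_idx] = t.year_effects
    y = (
        mu[None, None, None, :]
        + yeff[None, :, None, :]
        + g[:, None, None, :]
        + gy[:, :, None, :]
        + e
    )
    return y


def _to_dataset(cfg: SimConfig, y: np.ndarray) -> TraitDataset:
    a, nl, nr, p = y.shape
    accs = [f"A{i + 1:02d}" for i in range(a)]
    idx = pd.MultiIndex.from_product(
        [accs, list(cfg.years), range(1, nr + 1), [t.name for t in cfg.traits]],
        names=["accession", "year", "replicate", "trait"],
    )
    df = pd.DataFrame({"value": y.reshape(-1)}, index=idx).reset_index()
    return TraitDataset(df)


def simulate_dataset(cfg: SimConfig, gc: GeneticCorrelation | None = None) -> TraitDataset:
    """One balanced dataset under the random-effects model; deterministic
    in ``cfg.seed``."""
    return _to_dataset(cfg, _simulate_values(cfg, gc))


def simulate_grouped_dataset(
    cfg: SimConfig,
    k: int,
    separation: float,
    gc: GeneticCorrelation | None = None,
) -> tuple[TraitDataset, pd.Series]:
    """Dataset with ``k`` built-in accession groups.

    Group ``m`` shifts every genotype effect by ``m * separation * sd_t``
    where ``sd_t`` is the standard deviation of an accession mean under
    the trait's own components — so ``separation`` is the between-group
    distance in units of the within-group accession-mean spread.
    Accessions are assigned to groups round-robin.  Returns the dataset
    and the true group labels (1..k).
    """
    nl, nr = len(cfg.years), cfg.nr
    sd = np.array(
        [
            np.sqrt(t.sigma_g2 + t.sigma_gy2 / nl + t.sigma_e2 / (nl * nr))
            for t in cfg.traits
        ]
    )
    labels = np.arange(cfg.n_accessions) % k
    shift = labels[:, None] * separation * sd[None, :]
    ds = _to_dataset(cfg, _simulate_values(cfg, gc, g_shift=shift))
    truth = pd.Series(labels + 1, index=[f"A{i + 1:02d}" for i in range(cfg.n_accessions)])
    return ds, truth


def drop_records(ds: TraitDataset, frac: float, seed: int) -> TraitDataset:
    """Randomly delete a fraction of records (unbalanced-data fixture)."""
    if not 0 <= frac < 1:
        raise ValueError("frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = len(ds.records)
    keep = rng.permutation(n) >= int(round(frac * n))
    return TraitDataset(ds.records[keep].reset_index(drop=True))


def recovery_experiment(cfg: SimConfig, n_sims: int, seed: int) -> RecoveryReport:
    """Simulate ``n_sims`` datasets, refit the across-years model per trait
    and aggregate bias in the components and in the across-year
    repeatability R2.  Per-simulation fit failures are recorded; more than
    10% failures raises."""
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    nl, nr = len(cfg.years), cfg.nr
    children = np.random.SeedSequence(seed).spawn(n_sims)
    names = [t.name for t in cfg.traits]
    est = {name: {"sigma_g2": [], "sigma_gy2": [], "sigma_e2": [], "R2": []} for name in names}
    failures = []
    for i, child in enumerate(children):
        sim_seed = int(child.generate_state(1, dtype=np.uint32)[0] % 2**31)
        ds = simulate_dataset(dataclasses.replace(cfg, seed=sim_seed))
        for name in names:
            try:
                vc = fit_across_years(ds, name)
                r2 = repeatability_across(
                    vc.sigma_g2, vc.sigma_gy2, vc.sigma_e2, nl, nr
                ).value
            except (ValueError, ZeroDivisionError) as exc:
                failures.append(f"sim {i}, trait {name}: {exc}")
                continue
            est[name]["sigma_g2"].append(vc.sigma_g2)
            est[name]["sigma_gy2"].append(vc.sigma_gy2)
            est[name]["sigma_e2"].append(vc.sigma_e2)
            est[name]["R2"].append(r2)
    if len(failures) > 0.1 * n_sims * len(names):
        raise RuntimeError(f"{len(failures)} fit failures (> 10%): {failures[:5]}")
    rows = []
    for t in cfg.traits:
        true_r2 = repeatability_across(t.sigma_g2, t.sigma_gy2, t.sigma_e2, nl, nr).value
        e = est[t.name]
        rows.append(
            {
                "trait": t.name,
                "true_sigma_g2": t.sigma_g2,
                "mean_sigma_g2": float(np.mean(e["sigma_g2"])),
                "sd_sigma_g2": float(np.std(e["sigma_g2"], ddof=1)) if len(e["sigma_g2"]) > 1 else 0.0,
                "true_sigma_gy2": t.sigma_gy2,
                "mean_sigma_gy2": float(np.mean(e["sigma_gy2"])),
                "true_sigma_e2": t.sigma_e2,
                "mean_sigma_e2": float(np.mean(e["sigma_e2"])),
                "true_R2": true_r2,
                "mean_R2": float(np.mean(e["R2"])),
                "bias_sigma_g2": float(np.mean(e["sigma_g2"]) - t.sigma_g2),
                "bias_R2": float(np.mean(e["R2"]) - true_r2),
                "n_ok": len(e["R2"]),
            }
        )
    return RecoveryReport(
        n_sims=n_sims,
        table=pd.DataFrame(rows).set_index("trait"),
        n_failures=len(failures),
        failures=tuple(failures),
    )


def reference_fixture(seed: int = 0) -> TraitDataset:
    """Demo dataset shaped like the reference trial: 15 accessions x 2
    years x 3 replicates x 9 traits, with the reference trait means,
    variance components and genetic correlation structure."""
    return simulate_dataset(default_sim_config(seed), default_genetic_correlation())
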