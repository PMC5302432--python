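"""Synthetic multi-environment trials with known ground truth.

The yield generator is the generative twin of the AMMI decomposition:

    yield_ijr = μ + g_i + e_j + Z_ij + ε_ijr,   Z_ij = Σ_k λ_k α_ik γ_jk,

with genotype effects g, environment effects e drawn Gaussian and
re-centered to exact zero sum, and the interaction built from
orthonormal score vectors α_k, γ_jk (QR of Gaussian draws, orthogonal to
the constant vector) scaled by chosen singular values λ_k — so the
simulated interaction has *exactly* the stated low rank and magnitudes,
and every downstream estimator can be checked against stored truth.

Mineral concentrations follow the dilution relationship observed in real
grain: higher-yielding cells carry lower concentrations,

    C_mijr = base_m · (μ / E[yield_ij])^dilution_exponent · (1 + η),

with multiplicative noise η ~ N(0, conc_cv²) floored so concentrations
stay nonnegative. ``dilution_exponent = 0`` switches the coupling off.

:func:`worked_example_fixture` is different in kind: a fully
deterministic 19 × 3 × 2 dataset reverse-engineered from the published
genotype-level results of the Swedish organic trial in
:mod:`nutmet.reference`, used as an end-to-end worked example.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import METDataset, PlotRecord
from . import reference

__all__ = [
    "MineralSpec",
    "SimulationConfig",
    "SimulationTruth",
    "generate_met",
    "worked_example_fixture",
]


@dataclass(frozen=True)
class MineralSpec:
    """Generative parameters for one mineral's concentration."""

    base_conc: float  # mg/kg at the population mean yield
    dilution_exponent: float = 0.0  # ≥ 0; strength of yield–concentration coupling
    conc_cv: float = 0.0  # coefficient of variation of plot-level noise

    def __post_init__(self):
        if self.base_conc < 0 or self.dilution_exponent < 0 or self.conc_cv < 0:
            raise ValueError("mineral parameters must be nonnegative")


def _default_minerals() -> dict[str, MineralSpec]:
    # Population-mean wholemeal concentrations on the order of the organic
    # trial (Fe 43, Zn 36 mg/kg reported; Cu and Mg at their typical wheat
    # levels), with a moderate dilution coupling and 10% plot-level CV.
    return {
        "Fe": MineralSpec(43.0, 0.5, 0.10),
        "Zn": MineralSpec(36.0, 0.5, 0.10),
        "Cu": MineralSpec(5.0, 0.5, 0.10),
        "Mg": MineralSpec(1200.0, 0.5, 0.10),
    }


@dataclass
class SimulationConfig:
    """Study-scale defaults: 19 genotypes × 3 years × 2 replicates.

    Dispersions are on the kg·ha⁻¹ scale: genotype SD 800 (the published
    genotype means span ≈2000–5300 kg·ha⁻¹), year SD 400, plot error SD
    300, and a single interaction singular value of 600 giving the clearly
    significant, PC1-dominated G×E the trial reported.
    """

    n_genotypes: int = 19
    n_environments: int = 3
    n_replicates: int = 2
    mu_yield: float = 3959.0
    sigma_g: float = 800.0
    sigma_env: float = 400.0
    sigma_eps: float = 300.0
    interaction_lambdas: list[float] = field(default_factory=lambda: [600.0])
    minerals: dict[str, MineralSpec] = field(default_factory=_default_minerals)
    hulled_fraction: float = 4.0 / 19.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_genotypes, self.n_environments, self.n_replicates) < 1:
            raise ValueError("design dimensions must be positive")
        if any(l < 0 for l in self.interaction_lambdas):
            raise ValueError("interaction singular values must be nonnegative")
        if len(self.interaction_lambdas) > min(self.n_genotypes, self.n_environments) - 1:
            raise ValueError(
                "at most min(G, E) − 1 interaction components are identifiable"
            )
        if any(s < 0 for s in (self.sigma_g, self.sigma_env, self.sigma_eps)):
            raise ValueError("dispersions must be nonnegative")
        if not (0 <= self.hulled_fraction <= 1):
            raise ValueError("hulled_fraction must be in [0, 1]")
        if not self.minerals:
            raise ValueError("at least one mineral must be specified")


@dataclass
class SimulationTruth:
    """Everything the generator knows: effects, scores, and expectations."""

    genotype_effects: pd.Series  # g_i, exact zero sum
    environment_effects: pd.Series  # e_j, exact zero sum
    lambdas: np.ndarray
    alpha: pd.DataFrame  # genotype score vectors, orthonormal columns
    gamma: pd.DataFrame  # environment score vectors, orthonormal columns
    interaction: pd.DataFrame  # Z_ij, zero row/column sums
    cell_means: pd.DataFrame  # μ + g_i + e_j + Z_ij
    expected_concentrations: dict[str, pd.DataFrame]
    seed: int


def _orthonormal_scores(rng: np.random.Generator, dim: int, k: int) -> np.ndarray:
    """k orthonormal columns orthogonal to the constant vector (QR-based)."""
    draws = rng.standard_normal((dim, k))
    basis = np.column_stack([np.full(dim, 1.0 / np.sqrt(dim)), draws])
    q, r = np.linalg.qr(basis)
    # fix QR sign ambiguity for reproducibility across BLAS builds
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    q = q * signs
    return q[:, 1:k + 1]


def generate_met(config: SimulationConfig) -> tuple[METDataset, SimulationTruth]:
    """Draw one balanced trial; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    G, E, R = config.n_genotypes, config.n_environments, config.n_replicates
    genotypes = [f"G{i + 1:02d}" for i in range(G)]
    environments = [f"E{j + 1}" for j in range(E)]

    g = rng.normal(0.0, config.sigma_g, G) if config.sigma_g > 0 else np.zeros(G)
    g = g - g.mean()
    e = rng.normal(0.0, config.sigma_env, E) if config.sigma_env > 0 else np.zeros(E)
    e = e - e.mean()

    K = len(config.interaction_lambdas)
    lambdas = np.asarray(config.interaction_lambdas, dtype=float)
    if K:
        alpha = _orthonormal_scores(rng, G, K)
        gamma = _orthonormal_scores(rng, E, K)
        Z = (alpha * lambdas) @ gamma.T
    else:
        alpha = np.zeros((G, 0))
        gamma = np.zeros((E, 0))
        Z = np.zeros((G, E))

    cell = config.mu_yield + g[:, None] + e[None, :] + Z
    eps = (
        rng.normal(0.0, config.sigma_eps, (G, E, R))
        if config.sigma_eps > 0
        else np.zeros((G, E, R))
    )
    yields = np.maximum(cell[:, :, None] + eps, 0.0)

    # dilution: expected concentration scales with (μ / E[yield])^exponent
    ratio = config.mu_yield / np.maximum(cell, 1e-6 * config.mu_yield)
    expected_conc = {
        m: spec.base_conc * ratio**spec.dilution_exponent
        for m, spec in config.minerals.items()
    }
    conc = {}
    for m, spec in config.minerals.items():
        noise = (
            rng.normal(0.0, spec.conc_cv, (G, E, R))
            if spec.conc_cv > 0
            else np.zeros((G, E, R))
        )
        conc[m] = np.maximum(expected_conc[m][:, :, None] * (1.0 + noise), 0.0)

    n_hulled = int(np.ceil(config.hulled_fraction * G))
    groups = ["Spelt"] * n_hulled + ["Cultivar"] * (G - n_hulled)

    records = [
        PlotRecord(
            genotype_id=genotypes[i],
            genotype_group=groups[i],
            environment_id=environments[j],
            replicate=r + 1,
            yield_raw=float(yields[i, j, r]),
            concentrations={m: float(conc[m][i, j, r]) for m in config.minerals},
        )
        for i in range(G)
        for j in range(E)
        for r in range(R)
    ]
    data = METDataset(records, list(config.minerals), genotypes, environments)

    pcs = [f"PC{k + 1}" for k in range(K)]
    truth = SimulationTruth(
        genotype_effects=pd.Series(g, index=genotypes, name="g"),
        environment_effects=pd.Series(e, index=environments, name="e"),
        lambdas=lambdas,
        alpha=pd.DataFrame(alpha, index=genotypes, columns=pcs),
        gamma=pd.DataFrame(gamma, index=environments, columns=pcs),
        interaction=pd.DataFrame(Z, index=genotypes, columns=environments),
        cell_means=pd.DataFrame(cell, index=genotypes, columns=environments),
        expected_concentrations={
            m: pd.DataFrame(v, index=genotypes, columns=environments)
            for m, v in expected_conc.items()
        },
        seed=config.seed,
    )
    return data, truth


# Deterministic construction constants for the worked example: additive
# year offsets on the dehulled-yield scale (sum zero; the middle harvest
# year was the poor one) and the ±1% replicate spread.
_YEAR_OFFSETS = {"2012": 250.0, "2013": -400.0, "2014": 150.0}
_REP_SPREAD = 0.01

_DRI = {"Fe": 12.0, "Zn": 8.0, "Cu": 0.9, "Mg": 315.0}
_HULLED_GROUPS = {"Spelt", "Primitive"}
_DEHULL = 0.75
_YEAR_DAYS = 365.0


def worked_example_fixture() -> METDataset:
    """Deterministic 19 × 3 × 2 dataset matching the published trial means.

    Construction (no randomness):

    * each genotype's mean dehulled yield equals its published three-year
      mean; year offsets (+250, −400, +150 kg·ha⁻¹) add environment
      variation without disturbing genotype means; hulled genotypes are
      stored at raw (hulled) yield so the pipeline's dehulling correction
      reproduces the published values;
    * wholemeal concentrations are the published means for the six study
      genotypes and are back-solved from the published nutritional yields
      (C = NY·DRI·365 / yield) for the rest;
    * replicate pairs sit at yield × (1 ± 1%) with concentration
      × (1 ∓ 1%), giving nonzero replicate variance while keeping genotype
      mean yield and mean concentration exact (mean nutritional yield is
      exact up to the factor 1 − 10⁻⁴).
    """
    means = reference.genotype_means()
    study = reference.study_concentrations()
    minerals = list(reference.MINERALS)

    records = []
    for name, row in means.iterrows():
        hulled = row["group"] in _HULLED_GROUPS
        if name in study.index:
            conc = study.loc[name].to_dict()
        else:
            conc = {
                m: row[f"ny_{m}"] * _DRI[m] * _YEAR_DAYS / row["yield_kg_ha"]
                for m in minerals
            }
        for env, offset in _YEAR_OFFSETS.items():
            adj_cell = row["yield_kg_ha"] + offset
            raw_cell = adj_cell / _DEHULL if hulled else adj_cell
            for rep, sign in ((1, +1.0), (2, -1.0)):
                records.append(
                    PlotRecord(
                        genotype_id=str(name),
                        genotype_group=row["group"],
                        environment_id=env,
                        replicate=rep,
                        yield_raw=raw_cell * (1.0 + sign * _REP_SPREAD),
                        concentrations={
                            m: conc[m] * (1.0 - sign * _REP_SPREAD) for m in minerals
                        },
                    )
                )
    return METDataset(
        records,
        minerals,
        [str(g) for g in means.index],
        list(_YEAR_OFFSETS),
    )
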