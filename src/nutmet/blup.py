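"""Mixed-model genotypic values and harmonic-mean stability statistics.

Model (one trait): y_ijr = μ + E_j + g_i + (ge)_ij + ε_ijr with
environments E_j fixed, genotype effects g_i ~ N(0, σ²_g), interaction
(ge)_ij ~ N(0, σ²_ge) and plot error ε ~ N(0, σ²_ε), all independent.

Variance components come from ANOVA closed forms on balanced data
(σ̂²_ε = MS_err, σ̂²_ge = (MS_GE − MS_err)/r, σ̂²_g = (MS_G − MS_GE)/(r·e),
negatives truncated to zero) or from EM-REML otherwise. BLUPs of g and
(ge) solve Henderson's mixed-model equations; the predicted genotypic
value of genotype i in environment j is

    GV_ij = μ̂_j + BLUP(g_i) + BLUP((ge)_ij).

Three summary statistics rank genotypes simultaneously on level,
stability and adaptability:

    HMGV_i   = e / Σ_j 1/GV_ij              (harmonic mean, trait units)
    RPGV_i   = (1/e) Σ_j GV_ij / μ̂_j        (relative performance)
    HMRPGV_i = e / Σ_j μ̂_j / GV_ij          (harmonic mean of relatives)

The harmonic mean penalises environments where a genotype dips, so HMGV
rewards both level and stability; scaling by environment means μ̂_j makes
RPGV/HMRPGV dimensionless measures of adaptability. Genotypes are ranked
by HMRPGV descending.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import AnalysisConfig, METDataset
from .nutrition import trait_cell_means

__all__ = [
    "VarianceComponents",
    "GenotypicValueTable",
    "fit_random_genotype_model",
    "predict_genotypic_values",
    "hmgv_rpgv_hmrpgv",
]


@dataclass
class VarianceComponents:
    """Estimated variance components for one trait."""

    sigma2_g: float
    sigma2_ge: float
    sigma2_eps: float
    method: str  # "anova_closed_form" | "em_reml"
    converged: bool = True
    n_iterations: int = 0

    def __post_init__(self):
        for name in ("sigma2_g", "sigma2_ge", "sigma2_eps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class GenotypicValueTable:
    """Predicted genotypic values per environment plus stability statistics."""

    trait_name: str
    gv: pd.DataFrame  # genotype × environment predicted values
    env_means: pd.Series  # μ̂_j, observed environment means of cell means
    components: VarianceComponents
    stats: pd.DataFrame | None = field(default=None)  # HMGV/RPGV/HMRPGV/rank

    @property
    def nonpositive_genotypes(self) -> list[str]:
        """Genotypes with any GV ≤ 0, for which harmonic statistics fail."""
        bad = (self.gv <= 0).any(axis=1)
        return list(self.gv.index[bad])


def _trait_long(data: METDataset, trait: str, config: AnalysisConfig) -> pd.DataFrame:
    from .nutrition import plot_nutritional_yields

    if trait == "yield" or trait.startswith("ny_"):
        table = plot_nutritional_yields(data, config)
        col = "yield_adj" if trait == "yield" else trait
    elif trait in data.minerals:
        table = data.to_frame().rename(columns={f"conc_{trait}_mg_kg": "value"})
        col = "value"
    else:
        raise KeyError(f"unknown trait {trait!r}")
    return table[["genotype", "environment", "replicate", col]].rename(columns={col: "value"})


def _anova_components(long: pd.DataFrame, n_g: int, n_e: int, r: int) -> tuple[float, float, float]:
    y = long["value"].to_numpy(dtype=float)
    grand = y.mean()
    g_means = long.groupby("genotype", sort=False)["value"].mean()
    e_means = long.groupby("environment", sort=False)["value"].mean()
    cell = long.groupby(["genotype", "environment"], sort=False)["value"].mean()

    ms_g = r * n_e * float(np.sum((g_means - grand) ** 2)) / (n_g - 1)
    dev = cell.reset_index()
    dev["d"] = (
        dev["value"]
        - dev["genotype"].map(g_means)
        - dev["environment"].map(e_means)
        + grand
    )
    ms_ge = r * float(np.sum(dev["d"] ** 2)) / ((n_g - 1) * (n_e - 1))
    merged = long.merge(cell.rename("cell_mean"), left_on=["genotype", "environment"],
                        right_index=True)
    if r > 1:
        ms_err = float(np.sum((merged["value"] - merged["cell_mean"]) ** 2)) / (
            n_g * n_e * (r - 1)
        )
    else:
        ms_err = 0.0
    s2_eps = max(ms_err, 0.0)
    s2_ge = max((ms_ge - ms_err) / r, 0.0)
    s2_g = max((ms_g - ms_ge) / (r * n_e), 0.0)
    return s2_g, s2_ge, s2_eps


def _design(long: pd.DataFrame):
    """Fixed (env cell-mean) and random (genotype, G×E) design matrices."""
    genos = list(dict.fromkeys(long["genotype"]))
    envs = list(dict.fromkeys(long["environment"]))
    g_idx = long["genotype"].map({g: i for i, g in enumerate(genos)}).to_numpy()
    e_idx = long["environment"].map({e: j for j, e in enumerate(envs)}).to_numpy()
    n = len(long)
    X = np.zeros((n, len(envs)))
    X[np.arange(n), e_idx] = 1.0
    Zg = np.zeros((n, len(genos)))
    Zg[np.arange(n), g_idx] = 1.0
    Zge = np.zeros((n, len(genos) * len(envs)))
    Zge[np.arange(n), g_idx * len(envs) + e_idx] = 1.0
    return genos, envs, X, Zg, Zge


def _reml_loglik(y, X, Zs, sigmas, s2_eps) -> float:
    n = len(y)
    V = s2_eps * np.eye(n)
    for Z, s2 in zip(Zs, sigmas):
        if s2 > 0:
            V += s2 * (Z @ Z.T)
    L = np.linalg.cholesky(V)
    Vi_y = np.linalg.solve(V, y)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    resid = y - X @ beta
    quad = float(resid @ np.linalg.solve(V, resid))
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(L))))
    sign, logdet_X = np.linalg.slogdet(XtViX)
    return -0.5 * (logdet_V + logdet_X + quad)


def _em_reml(long: pd.DataFrame, init: tuple[float, float, float],
             tol: float = 1e-8, max_iter: int = 10_000):
    """EM-REML for the environment-fixed, genotype/G×E-random model.

    Deterministic initialisation at the method-of-moments (ANOVA) values;
    components constrained nonnegative by flooring at a tiny positive
    multiple of the phenotypic variance. Convergence requires both the
    relative log-likelihood change and the relative parameter change to
    fall below ``tol``.
    """
    y = long["value"].to_numpy(dtype=float)
    _, _, X, Zg, Zge = _design(long)
    n, p = X.shape[0], np.linalg.matrix_rank(X)
    scale = max(float(np.var(y)), 1e-12)
    floor = 1e-12 * scale

    Zs = [Zg, Zge]
    qs = [Zg.shape[1], Zge.shape[1]]
    sigmas = [max(init[0], floor), max(init[1], floor)]
    s2_eps = max(init[2], floor)

    ll_old = _reml_loglik(y, X, Zs, sigmas, s2_eps)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        V = s2_eps * np.eye(n)
        for Z, s2 in zip(Zs, sigmas):
            V += s2 * (Z @ Z.T)
        Vi = np.linalg.inv(V)
        Vi_X = Vi @ X
        P = Vi - Vi_X @ np.linalg.solve(X.T @ Vi_X, Vi_X.T)
        Py = P @ y

        new_sigmas = []
        for Z, s2, q in zip(Zs, sigmas, qs):
            ZtPy = Z.T @ Py
            tr = float(np.trace(Z.T @ P @ Z))
            s2_new = s2 + (s2**2 / q) * (float(ZtPy @ ZtPy) - tr)
            new_sigmas.append(max(s2_new, floor))
        s2_eps_new = s2_eps + (s2_eps**2 / (n - p)) * (float(Py @ Py) - float(np.trace(P)))
        s2_eps_new = max(s2_eps_new, floor)

        delta = max(
            abs(a - b) / max(abs(b), scale * 1e-6)
            for a, b in zip(new_sigmas + [s2_eps_new], sigmas + [s2_eps])
        )
        sigmas, s2_eps = new_sigmas, s2_eps_new
        ll = _reml_loglik(y, X, Zs, sigmas, s2_eps)
        if abs(ll - ll_old) / max(abs(ll_old), 1.0) < tol and delta < tol:
            converged = True
            break
        ll_old = ll

    out = [0.0 if s <= 2 * floor else s for s in sigmas]
    eps_out = 0.0 if s2_eps <= 2 * floor else s2_eps
    return out[0], out[1], eps_out, converged, it


def fit_random_genotype_model(data: METDataset, trait: str, config: AnalysisConfig,
                              method: str | None = None) -> VarianceComponents:
    """Estimate σ²_g, σ²_ge, σ²_ε for one trait.

    Balanced data defaults to exact ANOVA closed forms; unbalanced data
    (or ``method="em_reml"``) uses EM-REML started from the closed forms.
    """
    long = _trait_long(data, trait, config)
    genos = long["genotype"].nunique()
    envs = long["environment"].nunique()
    if genos < 2:
        raise ValueError("need at least 2 genotypes")
    if envs < 2:
        raise ValueError("G×E variance is inestimable with a single environment")
    counts = long.groupby(["genotype", "environment"], sort=False).size()
    if len(counts) < genos * envs:
        raise ValueError("incomplete genotype × environment layout")
    balanced = counts.nunique() == 1
    r = int(counts.iloc[0]) if balanced else 0

    init = _anova_components(long, genos, envs, r if balanced else 1) if balanced else None
    if method is None:
        method = "anova_closed_form" if balanced else "em_reml"
    if method == "anova_closed_form":
        if not balanced:
            raise ValueError("ANOVA closed forms require balanced data; use em_reml")
        s2_g, s2_ge, s2_eps = init
        return VarianceComponents(s2_g, s2_ge, s2_eps, method="anova_closed_form")
    if method != "em_reml":
        raise ValueError(f"unknown method {method!r}")
    if init is None:
        # method-of-moments start ignoring imbalance (cell means, pooled error)
        init = _anova_components(long, genos, envs, max(int(round(counts.mean())), 1))
    s2_g, s2_ge, s2_eps, converged, n_iter = _em_reml(long, init)
    if not converged:
        raise RuntimeError(
            f"EM-REML did not converge in {n_iter} iterations for trait {trait!r} "
            f"(last estimates g={s2_g:.6g}, ge={s2_ge:.6g}, eps={s2_eps:.6g})"
        )
    return VarianceComponents(s2_g, s2_ge, s2_eps, method="em_reml",
                              converged=converged, n_iterations=n_iter)


def predict_genotypic_values(vc: VarianceComponents, data: METDataset, trait: str,
                             config: AnalysisConfig) -> GenotypicValueTable:
    """BLUP genotypic values GV_ij from Henderson's mixed-model equations."""
    long = _trait_long(data, trait, config)
    genos, envs, X, Zg, Zge = _design(long)
    y = long["value"].to_numpy(dtype=float)
    n_g, n_e = len(genos), len(envs)

    blocks = [X]
    lambdas = []  # ridge penalty σ²_ε/σ²_k per random block
    if vc.sigma2_g > 0:
        blocks.append(Zg)
        lambdas.append(vc.sigma2_eps / vc.sigma2_g)
    if vc.sigma2_ge > 0:
        blocks.append(Zge)
        lambdas.append(vc.sigma2_eps / vc.sigma2_ge)
    W = np.hstack(blocks)
    C = W.T @ W
    offset = X.shape[1]
    for Z, lam in zip(blocks[1:], lambdas):
        q = Z.shape[1]
        C[offset:offset + q, offset:offset + q] += lam * np.eye(q)
        offset += q
    # σ²_ε = 0 with both variance ratios finite: λ = 0, plain least squares
    sol = np.linalg.lstsq(C, W.T @ y, rcond=None)[0]

    beta = sol[:X.shape[1]]
    pos = X.shape[1]
    u_g = np.zeros(n_g)
    u_ge = np.zeros(n_g * n_e)
    if vc.sigma2_g > 0:
        u_g = sol[pos:pos + n_g]
        pos += n_g
    if vc.sigma2_ge > 0:
        u_ge = sol[pos:pos + n_g * n_e]

    gv = pd.DataFrame(
        beta[None, :] + u_g[:, None] + u_ge.reshape(n_g, n_e),
        index=pd.Index(genos, name="genotype"),
        columns=pd.Index(envs, name="environment"),
    )
    env_means = trait_cell_means(data, trait, config).values.mean(axis=0)
    return GenotypicValueTable(
        trait_name=trait, gv=gv, env_means=env_means.reindex(envs), components=vc
    )


def hmgv_rpgv_hmrpgv(table: GenotypicValueTable) -> GenotypicValueTable:
    """Complete a genotypic-value table with HMGV, RPGV, HMRPGV and ranks."""
    bad = table.nonpositive_genotypes
    if bad:
        raise ValueError(
            f"harmonic statistics undefined: nonpositive genotypic values for {bad}"
        )
    gv = table.gv
    mu = table.env_means.reindex(gv.columns)
    if (mu <= 0).any():
        raise ValueError("environment means must be positive for RPGV/HMRPGV")
    e = gv.shape[1]
    hmgv = e / (1.0 / gv).sum(axis=1)
    rpgv = gv.div(mu, axis=1).mean(axis=1)
    hmrpgv = e / gv.rdiv(mu, axis=1).sum(axis=1)
    stats = pd.DataFrame({"HMGV": hmgv, "RPGV": rpgv, "HMRPGV": hmrpgv})
    order = stats.sort_values(
        by=["HMRPGV"], ascending=False, kind="mergesort"
    )
    order = order.reindex(
        sorted(order.index, key=lambda g: (-order.loc[g, "HMRPGV"], g))
    )
    stats["rank"] = pd.Series(
        np.arange(1, len(order) + 1), index=order.index
    )
    table.stats = stats
    return table
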