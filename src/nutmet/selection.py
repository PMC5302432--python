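"""Selection indexes and the combined "balanced genotype" ranking.

Elston's multiplicative index (EMI) scores a genotype as the product of
its trait exceedances over per-trait lowest acceptable limits (LALs),

    EMI_i = Π_t (x_it − LAL_t)   if every factor is positive, else 0;

a genotype at or below any limit is culled (score 0, flagged). The index
is parameter-free beyond the limits and rewards genotypes good in *all*
traits at once.

The desired-gains index (Pesek–Baker form) instead asks for a stated
response vector d: coefficients solve G b = d, where G is the genotypic
covariance matrix of the traits, so that selection on the score
b'x yields expected genetic gains proportional to d. A zero entry in d is
meaningful — it asks the index to hold that trait constant, usually with
a nonzero coefficient.

The combined ranking averages the rank positions a genotype attains
across all supplied component rankings (AMMI stability and BLUP-HMRPGV
per trait, EMI, BDGI); genotypes near the top of every list — the
"balanced" ones — surface first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import AnalysisConfig, METDataset

__all__ = [
    "IndexResult",
    "elston_index",
    "estimate_genotypic_covariance",
    "baker_desired_gains_index",
    "combined_balanced_ranking",
]


@dataclass
class IndexResult:
    """Scores, ranks and diagnostics for one selection index."""

    name: str
    scores: pd.Series  # per genotype
    ranks: pd.Series  # 1..n, best first
    flagged: pd.Series | None = None  # EMI: genotypes failing an LAL
    coefficients: pd.Series | None = None  # BDGI: b = G⁻¹ d
    expected_gains: pd.Series | None = None  # BDGI: G b (∝ d by construction)


def _rank_descending(scores: pd.Series) -> pd.Series:
    """Dense 1..n ranks, highest score first, ties lexicographic by genotype."""
    order = sorted(scores.index, key=lambda g: (-scores.loc[g], str(g)))
    return pd.Series(np.arange(1, len(order) + 1), index=order).reindex(scores.index)


def elston_index(trait_means: pd.DataFrame, lal: dict[str, float]) -> IndexResult:
    """Elston's multiplicative index over genotype trait means.

    ``trait_means`` is genotype × trait; ``lal`` maps each trait to its
    lowest acceptable limit. Genotypes with any trait at or below its
    limit score 0 and are flagged; they rank after all positive-score
    genotypes.
    """
    traits = list(lal)
    missing = [t for t in traits if t not in trait_means.columns]
    if missing:
        raise KeyError(f"trait means lack columns for {missing}")
    if trait_means[traits].isna().any().any():
        bad = trait_means[traits].isna().any(axis=1)
        raise ValueError(f"missing trait values for {list(trait_means.index[bad])}")
    exceed = trait_means[traits] - pd.Series(lal)
    positive = (exceed > 0).all(axis=1)
    scores = exceed.prod(axis=1).where(positive, 0.0)
    # flagged (zero) genotypes sort after every positive score; among
    # themselves order lexicographically via the common zero score
    ranks = _rank_descending(scores)
    return IndexResult(name="EMI", scores=scores, ranks=ranks, flagged=~positive)


def estimate_genotypic_covariance(data: METDataset, traits: list[str],
                                  config: AnalysisConfig) -> pd.DataFrame:
    """Genotypic covariance matrix G of the traits.

    Each trait's genotype main effects are predicted by BLUP (shrunken
    genotype effects from the environment-fixed mixed model) and G is the
    sample covariance of those predictions across genotypes — a stabler
    estimate than raw mean covariances in small trials.
    """
    from .blup import fit_random_genotype_model, predict_genotypic_values

    if len(traits) < 1:
        raise ValueError("need at least one trait")
    if len(data.genotypes) < 3:
        raise ValueError("genotypic covariance unreliable with fewer than 3 genotypes")
    blups = {}
    for t in traits:
        vc = fit_random_genotype_model(data, t, config)
        table = predict_genotypic_values(vc, data, t, config)
        # genotype main-effect value: average GV over environments
        blups[t] = table.gv.mean(axis=1)
    frame = pd.DataFrame(blups)
    return frame.cov()


def baker_desired_gains_index(trait_means: pd.DataFrame, G: pd.DataFrame,
                              desired_gains: dict[str, float],
                              ridge: float = 0.0,
                              cond_limit: float = 1e10) -> IndexResult:
    """Desired-gains index: b = G⁻¹d, score_i = b'x_i, rank descending.

    ``ridge`` adds λ·mean(diag G)·I before solving for ill-conditioned G
    (default 0 — fail instead, suggesting the ridge).
    """
    traits = list(desired_gains)
    missing = [t for t in traits if t not in trait_means.columns]
    if missing:
        raise KeyError(f"trait means lack columns for {missing}")
    Gm = G.loc[traits, traits].to_numpy(dtype=float)
    if ridge > 0:
        Gm = Gm + ridge * float(np.mean(np.diag(Gm))) * np.eye(len(traits))
    cond = np.linalg.cond(Gm)
    if not np.isfinite(cond) or cond > cond_limit:
        raise np.linalg.LinAlgError(
            f"genotypic covariance matrix is ill-conditioned (cond={cond:.3g}); "
            "consider the ridge option"
        )
    d = np.array([desired_gains[t] for t in traits], dtype=float)
    b = np.linalg.solve(Gm, d)
    coefficients = pd.Series(b, index=traits, name="b")
    scores = trait_means[traits].to_numpy(dtype=float) @ b
    scores = pd.Series(scores, index=trait_means.index, name="BDGI")
    ranks = _rank_descending(scores)
    expected = pd.Series(Gm @ b, index=traits, name="expected_gain")
    return IndexResult(name="BDGI", scores=scores, ranks=ranks,
                       coefficients=coefficients, expected_gains=expected)


def combined_balanced_ranking(component_ranks: dict[str, pd.Series]) -> pd.DataFrame:
    """Aggregate several 1..n rankings into the balanced-genotype ranking.

    ``component_ranks`` maps a component label (e.g. ``"ammi_ny_Fe"``,
    ``"blup_yield"``, ``"EMI"``) to a per-genotype rank Series. All series
    must cover the same genotypes. The aggregate is the mean rank, ties
    broken lexicographically; the result lists every component rank
    alongside ``mean_rank`` and the final ``rank``.
    """
    if not component_ranks:
        raise ValueError("no component rankings supplied")
    frame = pd.DataFrame(component_ranks)
    if frame.isna().any().any():
        bad = frame.index[frame.isna().any(axis=1)]
        raise ValueError(f"component rankings disagree on the genotype set: {list(bad)}")
    genos = set(frame.index)
    for name, s in component_ranks.items():
        if set(s.index) != genos:
            raise ValueError(f"component {name!r} covers a different genotype set")
    frame["mean_rank"] = frame.mean(axis=1)
    order = sorted(frame.index, key=lambda g: (frame.loc[g, "mean_rank"], str(g)))
    frame = frame.loc[order]
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame
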