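"""BLUP-uncertainty-propagated survival selection analysis.

For each trait and fate contrast (survived vs harvested = hunter
selection; survived vs predated = predator selection) one logistic
regression is fitted per retained posterior draw:

    logit P(survived_i) = a_j + g_j * u_ji

where u_ji is individual i's random-intercept value in draw j.  Iterating
over the full posterior of the BLUPs (2000 draws under the default MCMC
schedule) propagates behavioural-type uncertainty instead of conditioning
on point BLUPs.  The per-draw slopes are aggregated by their median,
equal-tailed 95% CrI and probability of direction — the empirical
distribution of point estimates, deliberately ignoring each GLM's own
standard error (a documented understatement of total uncertainty).

Risk traits are sign-flipped (x -1) before fitting so a positive log-odds
ratio reads as riskier individuals surviving more.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .hmodel import EffectSummary, PosteriorDraws, summarize_draw_vector
from .simulate import RISK_TRAITS, TRAITS

_FATE_OF_SOURCE = {"hunter": "harvested", "predator": "predated"}

IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100
_SEPARATION_BOUND = 50.0  # |slope| beyond this on a standardized axis => separation


@dataclass(frozen=True)
class FateContrast:
    """A survived-vs-mortality-source comparison within one population."""

    name: str  # "hunter" or "predator"
    population: str

    def __post_init__(self) -> None:
        if self.name not in _FATE_OF_SOURCE:
            raise ValueError("contrast name must be 'hunter' or 'predator'")

    @property
    def dead_fate(self) -> str:
        return _FATE_OF_SOURCE[self.name]


@dataclass
class SelectionResult:
    """Per-draw selection slopes for one trait x contrast, plus summary."""

    trait: str
    contrast: FateContrast
    slopes: np.ndarray  # one log-odds slope per retained draw (NaN = failed fit)
    summary: EffectSummary
    flipped: bool
    n_failed: int
    n_individuals: int


def subset_by_fate(profiles: pd.DataFrame, contrast: FateContrast) -> pd.DataFrame:
    """Binary outcome table: 1 survived, 0 the contrast's mortality fate.

    Individuals with the excluded fate are dropped, not recoded.
    """
    sub = profiles.loc[profiles["population"] == contrast.population]
    keep = sub.loc[sub["fate"].isin(["survived", contrast.dead_fate])]
    n_alive = int((keep["fate"] == "survived").sum())
    n_dead = len(keep) - n_alive
    if n_alive == 0 or n_dead == 0:
        raise ValueError(
            f"{contrast.population} {contrast.name} contrast has an empty group "
            f"(survived={n_alive}, {contrast.dead_fate}={n_dead}): model unidentifiable"
        )
    return pd.DataFrame(
        {
            "individual_id": keep["individual_id"].to_numpy(),
            "outcome": (keep["fate"] == "survived").astype(int).to_numpy(),
        }
    )


def blup_matrix(draws: PosteriorDraws, individual_ids) -> np.ndarray:
    """(retained draws x individuals) matrix of random-intercept draws.

    Column order matches ``individual_ids``; an individual absent from the
    fitted model raises.
    """
    index = {ind: j for j, ind in enumerate(draws.individual_ids)}
    missing = [i for i in individual_ids if i not in index]
    if missing:
        raise ValueError(f"individual(s) not in fitted model: {missing}")
    cols = [index[i] for i in individual_ids]
    return draws.u[:, cols]


def _logistic_slopes(x_rows: np.ndarray, y: np.ndarray):
    """Batched Newton/IRLS logistic fits of y ~ 1 + x for each row of x_rows.

    Returns (slopes, failed) where failed marks non-converged or separated
    fits (recorded as NaN).
    """
    J, n = x_rows.shape
    b0 = np.zeros(J)
    b1 = np.zeros(J)
    active = np.ones(J, dtype=bool)
    for _ in range(IRLS_MAX_ITER):
        eta = b0[:, None] + b1[:, None] * x_rows
        p = expit(eta)
        w = np.clip(p * (1.0 - p), 1e-12, None)
        r = y[None, :] - p
        g0 = r.sum(axis=1)
        g1 = (r * x_rows).sum(axis=1)
        h00 = w.sum(axis=1)
        h01 = (w * x_rows).sum(axis=1)
        h11 = (w * x_rows**2).sum(axis=1)
        det = np.clip(h00 * h11 - h01**2, 1e-300, None)
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        step = np.where(active, 1.0, 0.0)
        b0 = b0 + step * d0
        b1 = b1 + step * d1
        active = active & (np.maximum(np.abs(d0), np.abs(d1)) >= IRLS_TOL)
        if not active.any():
            break
    failed = active | ~np.isfinite(b1) | (np.abs(b1) > _SEPARATION_BOUND)
    slopes = np.where(failed, np.nan, b1)
    return slopes, failed


def iterate_glms(
    blups: np.ndarray,
    outcome: np.ndarray,
    flip: bool = False,
    trait: str = "",
    contrast: FateContrast | None = None,
    max_failed_frac: float = 0.05,
) -> SelectionResult:
    """One logistic regression per posterior draw; aggregate the slopes.

    Complete/quasi-complete separation in a draw leaves that draw's slope
    non-finite and is counted; more than ``max_failed_frac`` failures is a
    hard error.
    """
    blups = np.asarray(blups, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if blups.ndim != 2 or blups.shape[0] < 2:
        raise ValueError("need a (draws x individuals) matrix with >= 2 rows")
    if blups.shape[1] != len(y):
        raise ValueError("BLUP columns must match outcome length")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    x = -blups if flip else blups
    slopes, failed = _logistic_slopes(x, y)
    n_failed = int(failed.sum())
    if n_failed > max_failed_frac * len(slopes):
        raise RuntimeError(
            f"{n_failed}/{len(slopes)} per-draw GLMs failed (separation or "
            "non-convergence)"
        )
    ok = slopes[np.isfinite(slopes)]
    return SelectionResult(
        trait=trait,
        contrast=contrast if contrast is not None else FateContrast("hunter", ""),
        slopes=slopes,
        summary=summarize_draw_vector(ok),
        flipped=flip,
        n_failed=n_failed,
        n_individuals=blups.shape[1],
    )


def run_selection(
    draws_by_trait: dict[str, PosteriorDraws],
    profiles: pd.DataFrame,
    populations=("Georgia", "SouthCarolina"),
    sources=("hunter", "predator"),
    flip_risk: bool = True,
) -> list[SelectionResult]:
    """All trait x contrast x population selection fits.

    BLUPs come from the full-data fit; survival subsetting happens only in
    the GLM (refitting the behavioural model per fate subset is possible
    by passing subset-fitted draws).
    """
    results = []
    for trait in draws_by_trait:
        draws = draws_by_trait[trait]
        for pop in populations:
            for source in sources:
                contrast = FateContrast(source, pop)
                table = subset_by_fate(profiles, contrast)
                blups = blup_matrix(draws, table["individual_id"].tolist())
                flip = flip_risk and trait in RISK_TRAITS
                results.append(
                    iterate_glms(
                        blups,
                        table["outcome"].to_numpy(),
                        flip=flip,
                        trait=trait,
                        contrast=contrast,
                    )
                )
    return results


def selection_report(results: list[SelectionResult]) -> pd.DataFrame:
    """Tabulate selection results, one row per (trait, population, source)."""
    rows = []
    seen = set()
    for res in results:
        key = (res.trait, res.contrast.population, res.contrast.name)
        if key in seen:
            raise ValueError(f"duplicate selection result for {key}")
        seen.add(key)
        rows.append(
            {
                "trait": res.trait,
                "population": res.contrast.population,
                "mortality_source": res.contrast.name,
                "median_log_odds": res.summary.median,
                "ci_low": res.summary.ci_low,
                "ci_high": res.summary.ci_high,
                "pd_pct": res.summary.pd,
                "sign_convention": "flipped" if res.flipped else "unflipped",
                "n_individuals": res.n_individuals,
                "n_draws": len(res.slopes),
                "n_failed": res.n_failed,
            }
        )
    columns = [
        "trait", "population", "mortality_source", "median_log_odds",
        "ci_low", "ci_high", "pd_pct", "sign_convention",
        "n_individuals", "n_draws", "n_failed",
    ]
    return pd.DataFrame(rows, columns=columns)
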