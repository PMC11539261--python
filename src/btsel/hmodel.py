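"""Bayesian random-intercept model for repeated behavioural measures.

One univariate Gaussian mixed model is fitted per (standardized) trait:

    y_ij = x_ij' beta + u_i + e_ij,   u_i ~ N(0, V_ind),  e_ij ~ N(0, V_e)

with fixed effects for hunting stage (reference pre-hunt), study
population (reference Georgia) and their interaction, and a random
intercept u_i per individual — the individual's behavioural type.
Repeatability, the fraction of phenotypic variance attributable to
among-individual differences, is

    r = V_ind / (V_ind + V_e)

computed per posterior draw and summarised by its median and equal-tailed
95% credible interval.

Sampling is by a conjugate Gibbs sampler.  Priors are flat (improper) on
the fixed effects and half-Student-t(df 3, scale 2.5) on both standard
deviations, implemented through the Huang-Wand (2013) inverse-gamma
parameter expansion so every conditional update stays conjugate:

    sigma^2 | a ~ Inv-Gamma(nu/2, nu/a),  a ~ Inv-Gamma(1/2, 1/A^2)
    =>  sigma ~ half-t(nu, A)

The retained posterior draws carry the full vector of per-individual
intercepts (the "BLUP draws") so downstream selection analyses can
propagate behavioural-type uncertainty instead of using point BLUPs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg

STAGE_LEVELS = ("pre-hunt", "hunt", "post-hunt")
POPULATIONS = ("Georgia", "SouthCarolina")

FIXED_EFFECT_NAMES = (
    "intercept",
    "stage[hunt]",
    "stage[post-hunt]",
    "population[SouthCarolina]",
    "stage[hunt]:population[SouthCarolina]",
    "stage[post-hunt]:population[SouthCarolina]",
)


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class ModelSpec:
    """Configuration of one univariate trait model.

    The default MCMC schedule retains chains * (iterations - burnin) / thin
    = 2 * (15300 - 300) / 15 = 2000 draws.
    """

    response: str = "value"
    formula: str = "stage*population"  # or "1" (intercept only)
    iterations: int = 15_300
    burnin: int = 300
    thin: int = 15
    chains: int = 2
    seed: int = 0
    prior_df: float = 3.0
    prior_scale: float = 2.5
    rhat_threshold: float = 1.1
    fix_variances: tuple[float, float] | None = None  # (V_ind, V_e); testing aid

    def __post_init__(self) -> None:
        if self.formula not in ("stage*population", "stage", "1"):
            raise ValueError("formula must be 'stage*population', 'stage' or '1'")
        if (self.iterations - self.burnin) % self.thin != 0:
            raise ValueError("(iterations - burnin) must be divisible by thin")
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for R-hat")

    @property
    def n_retained(self) -> int:
        return self.chains * (self.iterations - self.burnin) // self.thin


@dataclass
class EffectSummary:
    """Posterior summary: median, equal-tailed 95% CrI, PD, optional ROPE (%)."""

    median: float
    ci_low: float
    ci_high: float
    pd: float
    rope: float | None = None

    def __post_init__(self) -> None:
        if not self.ci_low <= self.median <= self.ci_high:
            raise ValueError("summary quantiles out of order")


@dataclass
class PosteriorDraws:
    """Retained MCMC draws of a fitted trait model.

    ``u`` holds one column per modelled individual (the BLUP draws),
    ordered as ``individual_ids``.
    """

    beta: np.ndarray          # (n_draws, p)
    v_ind: np.ndarray         # (n_draws,)
    v_e: np.ndarray           # (n_draws,)
    u: np.ndarray             # (n_draws, q)
    chain: np.ndarray         # (n_draws,)
    draw: np.ndarray          # (n_draws,) within-chain index
    beta_names: tuple[str, ...]
    individual_ids: tuple[str, ...]
    spec: ModelSpec
    rhat: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    @property
    def n_draws(self) -> int:
        return len(self.v_ind)

    def repeatability_draws(self) -> np.ndarray:
        return self.v_ind / (self.v_ind + self.v_e)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (chain, draw, parameter, value) table."""
        blocks = []
        for j, name in enumerate(self.beta_names):
            blocks.append((f"beta:{name}", self.beta[:, j]))
        blocks.append(("v_ind", self.v_ind))
        blocks.append(("v_e", self.v_e))
        for j, ind in enumerate(self.individual_ids):
            blocks.append((f"u:{ind}", self.u[:, j]))
        frames = [
            pd.DataFrame(
                {"chain": self.chain, "draw": self.draw, "parameter": name, "value": v}
            )
            for name, v in blocks
        ]
        return pd.concat(frames, ignore_index=True)

    def save_csv(self, path) -> None:
        """Persist draws with a JSON metadata header line (# prefixed)."""
        meta = {
            "response": self.spec.response,
            "formula": self.spec.formula,
            "iterations": self.spec.iterations,
            "burnin": self.spec.burnin,
            "thin": self.spec.thin,
            "chains": self.spec.chains,
            "seed": self.spec.seed,
            "prior": f"half-t(df={self.spec.prior_df}, scale={self.spec.prior_scale})",
            "rhat": self.rhat,
            "converged": self.converged,
        }
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(meta, sort_keys=True) + "\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def load_csv(cls, path) -> "PosteriorDraws":
        with open(path) as fh:
            first = fh.readline()
            meta = json.loads(first.lstrip("#"))
            frame = pd.read_csv(fh)
        spec = ModelSpec(
            response=meta["response"],
            formula=meta["formula"],
            iterations=meta["iterations"],
            burnin=meta["burnin"],
            thin=meta["thin"],
            chains=meta["chains"],
            seed=meta["seed"],
        )
        wide = frame.pivot_table(
            index=["chain", "draw"], columns="parameter", values="value", sort=False
        ).reset_index()
        beta_names = [p[5:] for p in frame["parameter"].unique() if p.startswith("beta:")]
        ind_ids = [p[2:] for p in frame["parameter"].unique() if p.startswith("u:")]
        return cls(
            beta=wide[[f"beta:{n}" for n in beta_names]].to_numpy(),
            v_ind=wide["v_ind"].to_numpy(),
            v_e=wide["v_e"].to_numpy(),
            u=wide[[f"u:{i}" for i in ind_ids]].to_numpy(),
            chain=wide["chain"].to_numpy(),
            draw=wide["draw"].to_numpy(),
            beta_names=tuple(beta_names),
            individual_ids=tuple(ind_ids),
            spec=spec,
            rhat=meta.get("rhat", {}),
            converged=meta.get("converged", True),
        )


def design_matrix(data: pd.DataFrame, formula: str = "stage*population"):
    """Build the fixed-effect design matrix.

    Returns (X, names).  Raises a ``ValueError`` naming the aliased column
    if the design is rank deficient (e.g. a stage absent in one population).
    """
    n = len(data)
    if formula == "1":
        return np.ones((n, 1)), ("intercept",)
    stage = data["stage"].astype(str)
    unknown_stage = set(stage) - set(STAGE_LEVELS)
    if unknown_stage:
        raise ValueError(f"unknown stage levels: {sorted(unknown_stage)}")
    hunt = (stage == "hunt").to_numpy(float)
    post = (stage == "post-hunt").to_numpy(float)
    if formula == "stage":
        X = np.column_stack([np.ones(n), hunt, post])
        names = FIXED_EFFECT_NAMES[:3]
    else:
        pop = data["population"].astype(str)
        unknown_pop = set(pop) - set(POPULATIONS)
        if unknown_pop:
            raise ValueError(f"unknown populations: {sorted(unknown_pop)}")
        sc = (pop == "SouthCarolina").to_numpy(float)
        X = np.column_stack([np.ones(n), hunt, post, sc, hunt * sc, post * sc])
        names = FIXED_EFFECT_NAMES
    # pivoted QR exposes the first aliased column
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 1.0)
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        aliased = names[piv[rank]]
        raise ValueError(f"rank-deficient design: column '{aliased}' is aliased")
    return X, names


def _sample_inv_gamma(rng, shape, rate):
    return rate / rng.gamma(shape)


def _run_chain(y, X, group, q, spec: ModelSpec, rng, chain_idx):
    n, p = X.shape
    nu, A = spec.prior_df, spec.prior_scale
    XtX = X.T @ X
    Xty = X.T @ y
    # per-individual sums for the collapsed beta update
    SX = np.zeros((q, p))
    np.add.at(SX, group, X)
    Sy = np.bincount(group, weights=y, minlength=q)
    counts = np.bincount(group, minlength=q).astype(float)

    # initial values from simple moment splits
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    resid_var = max(float(np.var(y - X @ beta)), 1e-6)
    if spec.fix_variances is not None:
        v_ind, v_e = spec.fix_variances
    else:
        v_ind = resid_var / 2.0
        v_e = resid_var / 2.0
    u = np.zeros(q)
    a_ind = a_e = 1.0

    keep = (spec.iterations - spec.burnin) // spec.thin
    out_beta = np.empty((keep, p))
    out_vind = np.empty(keep)
    out_ve = np.empty(keep)
    out_u = np.empty((keep, q))
    k = 0
    for t in range(spec.iterations):
        # beta | variances (u integrated out: y ~ N(X beta, v_e I + v_ind ZZ'))
        kg = v_ind / (v_e * (v_e + counts * v_ind))
        A_mat = XtX / v_e - SX.T @ (kg[:, None] * SX)
        b_vec = Xty / v_e - SX.T @ (kg * Sy)
        Ra = linalg.cholesky(A_mat, lower=False)
        beta_hat = linalg.cho_solve((Ra, False), b_vec)
        z = rng.standard_normal(p)
        beta = beta_hat + linalg.solve_triangular(Ra, z, lower=False)

        # u | beta, variances
        resid = y - X @ beta
        s = np.bincount(group, weights=resid, minlength=q)
        prec = counts / v_e + 1.0 / v_ind
        u = s / v_e / prec + rng.standard_normal(q) / np.sqrt(prec)

        if spec.fix_variances is None:
            # half-t via parameter expansion: conjugate inverse-gamma steps
            v_ind = max(
                _sample_inv_gamma(rng, (nu + q) / 2.0, nu / a_ind + 0.5 * u @ u), 1e-12
            )
            a_ind = _sample_inv_gamma(rng, (nu + 1) / 2.0, nu / v_ind + 1.0 / A**2)
            ee = resid - u[group]
            v_e = max(
                _sample_inv_gamma(rng, (nu + n) / 2.0, nu / a_e + 0.5 * ee @ ee), 1e-12
            )
            a_e = _sample_inv_gamma(rng, (nu + 1) / 2.0, nu / v_e + 1.0 / A**2)

        if t >= spec.burnin and (t - spec.burnin) % spec.thin == spec.thin - 1:
            out_beta[k] = beta
            out_vind[k] = v_ind
            out_ve[k] = v_e
            out_u[k] = u
            k += 1
    assert k == keep
    return out_beta, out_vind, out_ve, out_u


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> PosteriorDraws:
    """Fit the random-intercept model by Gibbs sampling.

    ``data`` needs columns ``individual_id``, ``spec.response`` and — for
    the full formula — ``stage`` and ``population``.  Non-convergence
    (any split R-hat >= ``spec.rhat_threshold``) flags the result and
    emits a :class:`ConvergenceWarning`; it is never silently accepted.
    """
    if data[spec.response].isna().any():
        raise ValueError("response contains missing values")
    X, names = design_matrix(data, spec.formula)
    y = data[spec.response].to_numpy(float)
    ids, group = np.unique(data["individual_id"].astype(str), return_inverse=True)
    q = len(ids)
    if np.bincount(group).min() < 1:
        raise ValueError("every individual needs at least one observation")

    seeds = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    per_chain = (spec.iterations - spec.burnin) // spec.thin
    chunks = [
        _run_chain(y, X, group, q, spec, np.random.default_rng(s), c)
        for c, s in enumerate(seeds)
    ]
    beta = np.concatenate([c[0] for c in chunks])
    v_ind = np.concatenate([c[1] for c in chunks])
    v_e = np.concatenate([c[2] for c in chunks])
    u = np.concatenate([c[3] for c in chunks])
    chain = np.repeat(np.arange(spec.chains), per_chain)
    draw = np.tile(np.arange(per_chain), spec.chains)

    rhat: dict[str, float] = {}
    for j, name in enumerate(names):
        rhat[f"beta:{name}"] = split_rhat(beta[:, j].reshape(spec.chains, per_chain))
    if spec.fix_variances is None:
        rhat["v_ind"] = split_rhat(np.log(v_ind).reshape(spec.chains, per_chain))
        rhat["v_e"] = split_rhat(np.log(v_e).reshape(spec.chains, per_chain))
    converged = all(v < spec.rhat_threshold for v in rhat.values())
    if not converged:
        bad = {k: round(v, 3) for k, v in rhat.items() if v >= spec.rhat_threshold}
        warnings.warn(
            f"model for '{spec.response}' did not converge (R-hat >= "
            f"{spec.rhat_threshold}): {bad}",
            ConvergenceWarning,
            stacklevel=2,
        )
    return PosteriorDraws(
        beta=beta,
        v_ind=v_ind,
        v_e=v_e,
        u=u,
        chain=chain,
        draw=draw,
        beta_names=tuple(names),
        individual_ids=tuple(ids),
        spec=spec,
        rhat=rhat,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# posterior summaries


def repeatability_from_components(v_ind: float, v_e: float) -> float:
    """Point repeatability r = V_ind / (V_ind + V_e)."""
    if v_ind < 0 or v_e < 0 or v_ind + v_e == 0:
        raise ValueError("variance components must be non-negative and not both zero")
    return v_ind / (v_ind + v_e)


def probability_of_direction(draws) -> float:
    """Percent of draws sharing the sign of the posterior median (50-100).

    Draws at exactly zero count toward the median's sign.
    """
    v = np.asarray(draws, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 draws")
    med = np.median(v)
    if med >= 0:
        p = np.mean(v >= 0)
    else:
        p = np.mean(v <= 0)
    return float(100.0 * max(p, 0.5))


def rope_percent(draws, rope: tuple[float, float] = (-0.1, 0.1)) -> float:
    """Percent of draws inside the region of practical equivalence."""
    lo, hi = rope
    if not lo < hi:
        raise ValueError("ROPE lower bound must be below upper bound")
    v = np.asarray(draws, dtype=float)
    return float(100.0 * np.mean((v >= lo) & (v <= hi)))


def summarize_draw_vector(draws, rope: tuple[float, float] | None = None) -> EffectSummary:
    v = np.asarray(draws, dtype=float)
    lo, med, hi = np.quantile(v, [0.025, 0.5, 0.975])
    return EffectSummary(
        median=float(med),
        ci_low=float(lo),
        ci_high=float(hi),
        pd=probability_of_direction(v),
        rope=rope_percent(v, rope) if rope is not None else None,
    )


def repeatability(draws: PosteriorDraws) -> EffectSummary:
    """Median and 95% CrI of per-draw repeatability."""
    return summarize_draw_vector(draws.repeatability_draws())


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    ``chains`` has shape (n_chains, n_draws_per_chain).  Each chain is
    split in half; R-hat compares between- and within-half-chain variance.
    Constant chains return exactly 1.0.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 chains of draws")
    if x.shape[1] < 4:
        raise ValueError("need at least 4 draws per chain")
    half = x.shape[1] // 2
    splits = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, n = splits.shape
    within = splits.var(axis=1, ddof=1).mean()
    between = n * splits.mean(axis=1).var(ddof=1)
    if within == 0:
        return 1.0
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))


def summarize_effects(
    draws: PosteriorDraws, rope: tuple[float, float] = (-0.1, 0.1)
) -> pd.DataFrame:
    """Posterior summary table per trait model.

    One row per fixed effect (median, CrI, PD, ROPE), one per variance
    component (reported on the variance scale, with the SD scale in
    companion columns to keep both readings available), plus the
    repeatability row: 6 + 2 + 1 = 9 rows for the full formula.
    """
    rows = []
    for j, name in enumerate(draws.beta_names):
        s = summarize_draw_vector(draws.beta[:, j], rope)
        rows.append(
            {
                "term": name,
                "kind": "fixed",
                "median": s.median,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "pd_pct": s.pd,
                "rope_pct": s.rope,
            }
        )
    for name, v in [("individual (V_ind)", draws.v_ind), ("residual (V_e)", draws.v_e)]:
        s = summarize_draw_vector(v)
        sd = summarize_draw_vector(np.sqrt(v))
        rows.append(
            {
                "term": name,
                "kind": "variance",
                "median": s.median,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "pd_pct": s.pd,
                "rope_pct": None,
                "median_sd_scale": sd.median,
                "ci_low_sd_scale": sd.ci_low,
                "ci_high_sd_scale": sd.ci_high,
            }
        )
    s = repeatability(draws)
    rows.append(
        {
            "term": "repeatability",
            "kind": "repeatability",
            "median": s.median,
            "ci_low": s.ci_low,
            "ci_high": s.ci_high,
            "pd_pct": s.pd,
            "rope_pct": None,
        }
    )
    out = pd.DataFrame(rows)
    out.insert(0, "response", draws.spec.response)
    return out
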