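"""Multi-environment mixed model: REML variance components, BLUPs, dBLUPs.

Model for a plot observation of one trait:

    y = mu + clone + env (fixed) + rep(env) + block(rep, env)
        + clone x env + residual

with independent Gaussian random effects for clone, replication nested in
environment, block nested in replication, clone-by-environment interaction
and residual, each with its own variance.

Estimation is REML with the residual variance profiled out. The likelihood
is evaluated through Henderson's mixed-model equations: with variance ratios
``lambda_i = sigma2_i / sigma2_e`` the coefficient matrix is

    C = [[X'X, X'Z], [Z'X, Z'Z + diag(1/lambda_i)]]

and, writing r = y'y - [b; u]'[X'y; Z'y] for the solution [b; u],

    -2 l_R = (n - p) log(r / (n - p)) + sum_i q_i log lambda_i + log|C| + const.

The objective is minimised over log-ratios with a bounded Nelder-Mead
search; the cross-product blocks are formed once per fit, so each evaluation
costs one Cholesky factorisation. At the optimum, BLUPs are the random-
effect solutions and PEV_i = sigma2_e * (C^{-1})_{ii} on the clone block.
Reliability is 1 - PEV/sigma2_g; deregressed BLUPs divide the BLUP by its
reliability, with a floor below which the dBLUP is reported missing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .exceptions import ConfigurationError, DegenerateInputError

DEFAULT_TERMS = ("clone", "rep", "block", "gxe")
RELIABILITY_FLOOR = 0.05
_LOG_LAMBDA_BOUNDS = (-10.0, 10.0)

TERM_TO_COMPONENT = dict(
    clone="sigma2_g", rep="sigma2_r", block="sigma2_k", gxe="sigma2_ge"
)


@dataclass
class MixedModelFit:
    trait: str
    variance_components: dict
    fixed_effects: dict  # {"mu": float, "env": {env_id: effect}}
    clone_effects: pd.DataFrame  # clone_id, blup, pev, reliability, dblup
    converged: bool
    n_iterations: int
    reml_loglik: float
    terms: tuple


def _cholesky_inverse_diag(L: np.ndarray) -> np.ndarray:
    """Diagonal of C^{-1} from its lower Cholesky factor (LAPACK dpotri)."""
    inv_c, info = linalg.lapack.dpotri(L, lower=1)
    if info != 0:  # pragma: no cover
        inv_c = linalg.cho_solve((L, True), np.eye(L.shape[0]))
    return np.diag(inv_c).copy()


def _indicator(labels: pd.Series) -> tuple[np.ndarray, list]:
    codes, levels = pd.factorize(labels, sort=True)
    Z = np.zeros((len(labels), len(levels)))
    Z[np.arange(len(labels)), codes] = 1.0
    return Z, list(levels)


def _design(traits: pd.DataFrame, terms: tuple):
    """Fixed design (intercept + environment) and random-term indicators."""
    n = len(traits)
    env_codes, env_levels = pd.factorize(traits["env_id"], sort=True)
    X = [np.ones(n)]
    for j in range(1, len(env_levels)):  # treatment coding against env 1
        X.append((env_codes == j).astype(float))
    X = np.column_stack(X)

    n_envs = len(env_levels)
    active, Zs, levels = [], [], {}
    for term in terms:
        if term == "clone":
            lab = traits["clone_id"].astype(str)
        elif term == "rep":
            if n_envs * traits["rep_id"].nunique() < 2:
                continue
            lab = traits["env_id"].astype(str) + ":" + traits["rep_id"].astype(str)
        elif term == "block":
            lab = (
                traits["env_id"].astype(str)
                + ":" + traits["rep_id"].astype(str)
                + ":" + traits["block_id"].astype(str)
            )
            if lab.nunique() < 2:
                continue
        elif term == "gxe":
            if n_envs < 2:
                continue  # confounded with clone when only one environment
            lab = traits["clone_id"].astype(str) + ":" + traits["env_id"].astype(str)
        else:
            raise ConfigurationError(f"unknown model term {term!r}")
        Z, lev = _indicator(lab)
        if Z.shape[1] < 2:
            continue
        active.append(term)
        Zs.append(Z)
        levels[term] = lev
    if "clone" not in active:
        raise ConfigurationError("model must include the clone term")
    return X, env_levels, tuple(active), Zs, levels


def fit_mixed_model(
    traits: pd.DataFrame,
    trait_name: str,
    model_terms: tuple = DEFAULT_TERMS,
    reliability_floor: float = RELIABILITY_FLOOR,
    max_iterations: int = 2000,
) -> MixedModelFit:
    """REML fit of the multi-environment model for one trait.

    Terms whose factor has fewer than two levels (or, for the interaction,
    a single environment) are dropped automatically. Raises on singular
    designs; non-convergence is flagged on the returned fit, not silent.
    """
    if traits["clone_id"].nunique() < 2:
        raise ConfigurationError("need at least 2 clones")
    y = traits[trait_name].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        raise DegenerateInputError("response has zero variance")
    X, env_levels, terms, Zs, levels = _design(traits, model_terms)
    n, p = X.shape
    q_sizes = [Z.shape[1] for Z in Zs]
    q_total = sum(q_sizes)
    slices = []
    start = p
    for q in q_sizes:
        slices.append(slice(start, start + q))
        start += q

    # cross-products formed once
    M = np.column_stack([X] + Zs)
    C0 = M.T @ M
    rhs = M.T @ y
    yty = float(y @ y)
    if np.linalg.matrix_rank(X) < p:
        raise ConfigurationError("singular fixed-effects design")

    def assemble(log_lam: np.ndarray) -> np.ndarray:
        C = C0.copy()
        for sl, ll in zip(slices, log_lam):
            idx = np.arange(sl.start, sl.stop)
            C[idx, idx] += np.exp(-ll)
        return C

    def objective(log_lam: np.ndarray) -> float:
        C = assemble(log_lam)
        try:
            L = linalg.cholesky(C, lower=True)
        except linalg.LinAlgError:
            return np.inf
        sol = linalg.cho_solve((L, True), rhs)
        r = yty - float(sol @ rhs)
        if r <= 0:
            r = 1e-12
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        pen = float(sum(q * ll for q, ll in zip(q_sizes, log_lam)))
        return (n - p) * np.log(r / (n - p)) + pen + logdet

    x0 = np.zeros(len(Zs))
    res = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        bounds=[_LOG_LAMBDA_BOUNDS] * len(Zs),
        options=dict(maxiter=max_iterations, xatol=1e-5, fatol=1e-9),
    )
    if not res.success:
        warnings.warn(f"REML search did not converge: {res.message}")

    # EM polish: the Nelder-Mead objective is numerically flat near the
    # optimum; the EM-REML fixed point satisfies the score equations to
    # machine precision. Iterate sigma2_i <- (u'u + sigma2_e tr(Cinv_ii))/q_i
    # and sigma2_e <- r/(n - p) from the search optimum.
    log_lam = np.clip(res.x, *_LOG_LAMBDA_BOUNDS)
    lam = np.exp(log_lam)
    em_iters = 0
    for em_iters in range(1, 101):
        C = assemble(np.log(lam))
        L = linalg.cholesky(C, lower=True)
        sol = linalg.cho_solve((L, True), rhs)
        inv_diag = _cholesky_inverse_diag(L)
        r = max(yty - float(sol @ rhs), 1e-12)
        s2e_new = r / (n - p)
        lam_new = np.empty_like(lam)
        for i, (sl, q) in enumerate(zip(slices, q_sizes)):
            u = sol[sl]
            s2i = (float(u @ u) + s2e_new * float(inv_diag[sl].sum())) / q
            lam_new[i] = max(s2i / s2e_new, math.exp(_LOG_LAMBDA_BOUNDS[0]))
        lam_new = np.minimum(lam_new, math.exp(_LOG_LAMBDA_BOUNDS[1]))
        converged_em = np.allclose(lam_new, lam, rtol=1e-11, atol=1e-13)
        lam = lam_new
        if converged_em:
            break

    C = assemble(np.log(lam))
    L = linalg.cholesky(C, lower=True)
    sol = linalg.cho_solve((L, True), rhs)
    r = max(yty - float(sol @ rhs), 1e-12)
    sigma2_e = r / (n - p)
    components = {TERM_TO_COMPONENT[t]: float(l * sigma2_e) for t, l in zip(terms, lam)}
    components["sigma2_e"] = float(sigma2_e)
    for key in TERM_TO_COMPONENT.values():
        components.setdefault(key, 0.0)

    inv_diag = _cholesky_inverse_diag(L)
    clone_slice = slices[terms.index("clone")]
    blup = sol[clone_slice]
    pev = sigma2_e * inv_diag[clone_slice]
    sigma2_g = components["sigma2_g"]
    reliability = np.clip(1.0 - pev / sigma2_g, 0.0, 1.0) if sigma2_g > 0 else np.zeros_like(pev)
    dblup = deregress_values(blup, pev, sigma2_g, reliability_floor) if sigma2_g > 0 else np.full_like(blup, np.nan)

    fixed = {"mu": float(sol[0]), "env": {}}
    for j, env in enumerate(env_levels):
        fixed["env"][str(env)] = 0.0 if j == 0 else float(sol[j])

    clone_effects = pd.DataFrame(
        dict(
            clone_id=levels["clone"],
            blup=blup,
            pev=pev,
            reliability=reliability,
            dblup=dblup,
        )
    )
    return MixedModelFit(
        trait=trait_name,
        variance_components=components,
        fixed_effects=fixed,
        clone_effects=clone_effects,
        converged=bool(res.success),
        n_iterations=int(res.nit) + em_iters,
        reml_loglik=float(-0.5 * objective(np.log(lam))),
        terms=terms,
    )


def deregress_values(
    blup,
    pev,
    sigma2_g: float,
    reliability_floor: float = RELIABILITY_FLOOR,
) -> np.ndarray:
    """Deregress BLUPs: dBLUP_i = BLUP_i / (1 - PEV_i / sigma2_g).

    Requires sigma2_g > 0. Clones whose reliability falls at or below the
    floor get a missing dBLUP (a warning lists how many), avoiding exploding
    values when the BLUP carries almost no information.
    """
    blup = np.atleast_1d(np.asarray(blup, dtype=float))
    pev = np.atleast_1d(np.asarray(pev, dtype=float))
    if sigma2_g <= 0:
        raise DegenerateInputError("deregression undefined: sigma2_g must be > 0")
    reliability = 1.0 - pev / sigma2_g
    out = np.full_like(blup, np.nan)
    ok = reliability > reliability_floor
    out[ok] = blup[ok] / reliability[ok]
    if (~ok).any():
        warnings.warn(
            f"{int((~ok).sum())} clone(s) below the reliability floor "
            f"({reliability_floor}); their dBLUPs are missing"
        )
    return out


def deregress(fit: MixedModelFit, reliability_floor: float = RELIABILITY_FLOOR) -> pd.Series:
    """Per-clone dBLUPs from a fitted model, indexed by clone id."""
    sigma2_g = fit.variance_components.get("sigma2_g", 0.0)
    vals = deregress_values(
        fit.clone_effects["blup"].to_numpy(),
        fit.clone_effects["pev"].to_numpy(),
        sigma2_g,
        reliability_floor,
    )
    return pd.Series(vals, index=fit.clone_effects["clone_id"].to_numpy(), name="dblup")


def write_blups_csv(fit: MixedModelFit, path) -> None:
    out = fit.clone_effects.copy()
    out["trait"] = fit.trait
    out.to_csv(path, index=False)
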