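"""Study-level modelling: explanatory item response theory and composites.

The melodic-recall outcome (a similarity or proportion-correct score on
[0, 1]) is regressed on melodic item features with a per-participant
random intercept — an explanatory IRT formulation in which the random
intercepts are the participants' singing ability scores.  The module
wraps a REML mixed-model solver in a statsmodels-style
``TrialModel.fit() -> TrialModelResults`` pair and adds the
Nakagawa–Schielzeth R² decomposition, Horn's parallel analysis, and the
varimax-rotated PCA pipeline used to build composite long-note and
singing-accuracy scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "MODEL_SPECS",
    "TrialModel",
    "TrialModelResults",
    "fit_trial_model",
    "nakagawa_r2",
    "parallel_analysis",
    "varimax",
    "CompositeModel",
    "pca_composite",
]

# fixed-effect terms of the three published model specifications
MODEL_SPECS = {
    "combined": ["N", "step_cont_loc_var", "tonalness", "log_freq",
                 "melody_type_rhythmic", "arhythmic_x_d_entropy", "rhythmic_x_d_entropy"],
    "arhythmic": ["N", "step_cont_loc_var", "tonalness", "log_freq"],
    "rhythmic": ["N", "step_cont_loc_var", "log_freq", "d_entropy", "i_entropy"],
}


def _design_matrix(trials: pd.DataFrame, spec: str) -> pd.DataFrame:
    """Fixed-effects design matrix (without intercept) for a model spec.

    The combined spec derives the rhythmic indicator and the
    melody_type × d_entropy interaction columns from ``trial_type``.
    """
    terms = MODEL_SPECS[spec]
    X = pd.DataFrame(index=trials.index)
    if spec == "combined":
        is_rhythmic = (trials["trial_type"] == "rhythmic").astype(float)
        for t in terms:
            if t == "melody_type_rhythmic":
                X[t] = is_rhythmic
            elif t == "arhythmic_x_d_entropy":
                X[t] = (1.0 - is_rhythmic) * trials["d_entropy"]
            elif t == "rhythmic_x_d_entropy":
                X[t] = is_rhythmic * trials["d_entropy"]
            else:
                X[t] = trials[t].astype(float)
    else:
        for t in terms:
            X[t] = trials[t].astype(float)
    return X


@dataclass
class TrialModelResults:
    """Estimates and diagnostics of a fitted explanatory-IRT trial model."""

    spec: str
    params: pd.Series  # fixed effects incl. Intercept
    bse: pd.Series
    conf_int: pd.DataFrame
    var_fixed: float  # variance of the fixed-effect linear predictor
    var_random: float  # participant random-intercept variance
    var_resid: float
    abilities: pd.Series  # per-participant random intercepts (BLUPs)
    converged: bool
    n_obs: int
    n_participants: int

    @property
    def r2_marginal(self) -> float:
        return nakagawa_r2(self.var_fixed, self.var_random, self.var_resid)[0]

    @property
    def r2_conditional(self) -> float:
        return nakagawa_r2(self.var_fixed, self.var_random, self.var_resid)[1]

    def ability_scores(self) -> pd.DataFrame:
        """Participant ability table (random intercepts), one row per participant."""
        name = {"combined": "SAA_Ability",
                "arhythmic": "SAA_Ability_Arrhythmic",
                "rhythmic": "SAA_Ability_Rhythmic"}[self.spec]
        return pd.DataFrame({"participant_id": self.abilities.index, name: self.abilities.values})

    def summary(self) -> str:
        lines = [
            f"Explanatory IRT model ({self.spec}); n_obs={self.n_obs}, "
            f"participants={self.n_participants}, converged={self.converged}",
            f"R2 marginal={self.r2_marginal:.3f}  conditional={self.r2_conditional:.3f}",
            f"{'term':<24}{'beta':>10}{'SE':>10}{'2.5%':>10}{'97.5%':>10}",
        ]
        for t in self.params.index:
            lines.append(
                f"{t:<24}{self.params[t]:>10.3f}{self.bse[t]:>10.3f}"
                f"{self.conf_int.loc[t, 0]:>10.3f}{self.conf_int.loc[t, 1]:>10.3f}"
            )
        lines.append(
            f"variance components: fixed={self.var_fixed:.4f} "
            f"random={self.var_random:.4f} residual={self.var_resid:.4f}"
        )
        return "\n".join(lines)


class TrialModel:
    """Mixed-effects model of trial outcomes with participant random intercepts.

    ``spec`` selects the fixed-effect set: "combined" (both trial types,
    with a rhythmic-indicator main effect and melody_type × d_entropy
    interaction), "arhythmic", or "rhythmic".  Only first attempts are
    analysed by default, matching the study design.
    """

    def __init__(self, trials: pd.DataFrame, spec: str = "combined",
                 outcome: str = "outcome", first_attempt_only: bool = True):
        if spec not in MODEL_SPECS:
            raise ValueError(f"unknown model spec {spec!r}")
        df = trials.copy()
        if first_attempt_only and "attempt" in df.columns:
            df = df[df["attempt"] == 1]
        if spec in ("arhythmic", "rhythmic") and "trial_type" in df.columns:
            df = df[df["trial_type"] == spec]
        df = df.reset_index(drop=True)
        if df["participant_id"].nunique() < 2:
            raise ValueError("need at least 2 participants")
        self.spec = spec
        self.trials = df
        self.outcome = outcome
        self.exog = _design_matrix(df, spec)

    def fit(self) -> TrialModelResults:
        X = sm.add_constant(self.exog, prepend=True).rename(columns={"const": "Intercept"})
        y = self.trials[self.outcome].astype(float)
        groups = self.trials["participant_id"]
        model = MixedLM(endog=y, exog=X, groups=groups)
        fit = model.fit(reml=True)

        beta = fit.fe_params
        eta = X.values @ beta.values
        var_fixed = float(np.var(eta))
        var_random = float(fit.cov_re.iloc[0, 0])
        var_resid = float(fit.scale)
        re = pd.Series(
            {g: float(v.iloc[0]) for g, v in fit.random_effects.items()}
        ).sort_index()
        ci = fit.conf_int().loc[beta.index]
        ci.columns = [0, 1]
        return TrialModelResults(
            spec=self.spec,
            params=beta,
            bse=fit.bse_fe,
            conf_int=ci,
            var_fixed=var_fixed,
            var_random=var_random,
            var_resid=var_resid,
            abilities=re,
            converged=bool(fit.converged),
            n_obs=len(y),
            n_participants=groups.nunique(),
        )


def fit_trial_model(trials: pd.DataFrame, spec: str = "combined", **kwargs) -> TrialModelResults:
    """Convenience wrapper: build a :class:`TrialModel` and fit it."""
    return TrialModel(trials, spec=spec, **kwargs).fit()


def nakagawa_r2(var_fixed: float, var_random: float, var_resid: float) -> tuple[float, float]:
    """Nakagawa–Schielzeth marginal and conditional R² from variance components.

    R²m = s2f / (s2f + s2r + s2e); R²c = (s2f + s2r) / (s2f + s2r + s2e).
    """
    total = var_fixed + var_random + var_resid
    if total <= 0:
        raise ValueError("total variance must be positive")
    return var_fixed / total, (var_fixed + var_random) / total


def parallel_analysis(X, n_sims: int = 100, quantile: float = 0.95,
                      seed: int | None = None) -> int:
    """Horn's parallel analysis: components retained against a random baseline.

    Observed correlation-matrix eigenvalues are compared rank-by-rank with
    the ``quantile`` of eigenvalues from ``n_sims`` standard-normal
    datasets of the same shape; components are retained while the observed
    eigenvalue exceeds its baseline, stopping at the first failure.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if p < 3 or n < 20:
        raise ValueError("parallel analysis needs >= 3 variables and >= 20 rows")
    if np.any(np.std(X, axis=0) == 0):
        raise ValueError("constant column in input")
    obs = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
    rng = np.random.default_rng(seed)
    sims = np.empty((n_sims, p))
    for s in range(n_sims):
        Z = rng.standard_normal((n, p))
        sims[s] = np.sort(np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False)))[::-1]
    thresh = np.quantile(sims, quantile, axis=0)
    k = 0
    while k < p and obs[k] > thresh[k]:
        k += 1
    return k


def varimax(loadings: np.ndarray, max_iter: int = 500, tol: float = 1e-10) -> np.ndarray:
    """Varimax rotation of a loading matrix (orthogonal, unnormalised)."""
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L
    R = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        B = L @ R
        u, s, vt = np.linalg.svd(L.T @ (B**3 - B @ np.diag(np.sum(B**2, axis=0)) / p))
        R = u @ vt
        d = s.sum()
        if d_old != 0 and d / d_old < 1 + tol:
            break
        d_old = d
    return L @ R


@dataclass
class CompositeModel:
    """A (rotated) PCA composite: loadings, communalities and scoring weights."""

    variables: list
    loadings: pd.DataFrame  # variables x components
    communalities: pd.Series
    variance_explained: np.ndarray  # per-component share of total variance
    weights: pd.DataFrame  # regression-method scoring weights
    dropped: list


def pca_composite(
    X: pd.DataFrame,
    n_components: int,
    rotation: str = "varimax",
    drop_below_h2: float | None = None,
) -> tuple[CompositeModel, pd.DataFrame]:
    """Standardised PCA with optional varimax rotation and low-h² pruning.

    Variables whose communality falls below ``drop_below_h2`` are removed
    one at a time (lowest first) and the solution refitted, mirroring the
    composite-building procedure for the long-note (threshold .75) and
    melodic-accuracy (threshold .30) pipelines.  Component scores use the
    regression method: Z R⁻¹ Λ.  Returns the model and per-row scores.
    """
    if rotation not in ("varimax", "none"):
        raise ValueError("rotation must be 'varimax' or 'none'")
    df = pd.DataFrame(X).dropna(axis=0)
    dropped: list = []
    while True:
        cols = [c for c in df.columns if c not in dropped]
        if n_components > len(cols):
            raise ValueError("n_components exceeds the number of remaining variables")
        Z = (df[cols] - df[cols].mean()) / df[cols].std(ddof=1)
        R = np.corrcoef(Z.values, rowvar=False)
        eigval, eigvec = np.linalg.eigh(R)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        L = eigvec[:, :n_components] * np.sqrt(np.maximum(eigval[:n_components], 0.0))
        if rotation == "varimax" and n_components > 1:
            L = varimax(L)
        # deterministic sign: largest-|loading| entry of each component positive
        for j in range(L.shape[1]):
            i = np.argmax(np.abs(L[:, j]))
            if L[i, j] < 0:
                L[:, j] = -L[:, j]
        h2 = np.sum(L**2, axis=1)
        if drop_below_h2 is not None and np.min(h2) < drop_below_h2 and len(cols) > n_components:
            dropped.append(cols[int(np.argmin(h2))])
            continue
        break
    var_explained = np.sum(L**2, axis=0) / len(cols)
    W = np.linalg.solve(R, L)  # regression-method scoring weights
    scores = pd.DataFrame(Z.values @ W, index=df.index,
                          columns=[f"RC{j + 1}" for j in range(n_components)])
    model = CompositeModel(
        variables=cols,
        loadings=pd.DataFrame(L, index=cols, columns=scores.columns),
        communalities=pd.Series(h2, index=cols),
        variance_explained=var_explained,
        weights=pd.DataFrame(W, index=cols, columns=scores.columns),
        dropped=dropped,
    )
    return model, scores
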