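"""Bayesian Gaussian linear mixed model for logit-scale dermal absorption.

The response is the logit-transformed fraction of active substance absorbed.
Fixed effects are concentration status (reference: dilution) and formulation
type category (reference: organic solvent). Random effects:

* a random slope for substance within concentration status — each substance
  carries a pair of effects (one for its dilutions, one for its
  concentrates) drawn from a bivariate normal with covariance ``G``, so
  between-substance variation is estimated separately per status together
  with its correlation;
* a random intercept for study identity (between-study variation);
* a random intercept for the within-study grouping variable (replicates of
  the same applied concentration of the same substance in the same
  formulation type within the same study).

Inference is a blocked Gibbs sampler exploiting full conjugacy: one joint
multivariate-normal update for all location effects (fixed + random), an
inverse-Wishart update for ``G`` and scaled-inverse-chi-squared updates for
the scalar variances. Draw sequences are bit-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .dataset import FORMULATION_CATEGORIES, STATUSES
from .diagnostics import effective_sample_size, hpdi
from .preprocessing import PreparedDataset
from . import prediction as _prediction

__all__ = [
    "ModelParams",
    "PriorSpec",
    "DesignMatrices",
    "DermalAbsorptionLMM",
    "LMMResults",
    "PARAM_NAMES",
    "build_design",
]

#: Canonical posterior-column order: 5 fixed effects, 4 random-effect
#: variances, the substance-effect correlation, then the parameters not
#: reported in category-default tables (covariance, residual variance).
PARAM_NAMES = (
    "alpha",
    "beta_concentrate",
    "beta_other",
    "beta_solid",
    "beta_water_based",
    "var_substance_dilution",
    "var_substance_concentrate",
    "var_study",
    "var_within",
    "rho_substance",
    "cov_substance",
    "var_resid",
)

_FIXED_NAMES = PARAM_NAMES[:5]
# non-reference indicator columns, in fixed-effect order after the intercept
_CATEGORY_COLUMNS = ("other", "solid", "water_based")


@dataclass(frozen=True)
class ModelParams:
    """One full set of model parameters (a posterior draw, or generator truth)."""

    alpha: float
    beta_concentrate: float
    beta_other: float
    beta_solid: float
    beta_water_based: float
    var_substance_dilution: float
    var_substance_concentrate: float
    rho_substance: float
    var_study: float
    var_within: float
    var_resid: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "var_substance_dilution",
            "var_substance_concentrate",
            "var_study",
            "var_within",
            "var_resid",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not -1.0 < self.rho_substance < 1.0:
            raise ValueError("|rho_substance| must be < 1")

    @property
    def G(self) -> np.ndarray:
        """2x2 substance-effect covariance (dilution first, concentrate second)."""
        sd = np.sqrt(self.var_substance_dilution * self.var_substance_concentrate)
        c = self.rho_substance * sd
        return np.array(
            [
                [self.var_substance_dilution, c],
                [c, self.var_substance_concentrate],
            ]
        )

    @property
    def fixed_effects(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _FIXED_NAMES])

    def pseudo_draw(self) -> pd.DataFrame:
        """A one-row posterior table holding exactly these parameter values.

        Lets the prediction machinery run as a deterministic plug-in on
        point estimates (e.g. published posterior means).
        """
        cov = self.rho_substance * np.sqrt(
            self.var_substance_dilution * self.var_substance_concentrate
        )
        row = {n: getattr(self, n) for n in PARAM_NAMES if n != "cov_substance"}
        row["cov_substance"] = cov
        return pd.DataFrame([row], columns=list(PARAM_NAMES))


@dataclass(frozen=True)
class PriorSpec:
    """Weakly-informative proper priors (all conjugate).

    Fixed effects: independent N(mean, variance). Scalar variances: scaled
    inverse-chi-squared with ``variance_df`` degrees of freedom and unit
    scale by default. Substance covariance: inverse-Wishart with the
    smallest integer df giving a proper prior for a 2x2 matrix.
    """

    fixed_effect_mean: float = 0.0
    fixed_effect_variance: float = 1.0e4
    variance_scale: float = 1.0
    variance_df: float = 1.0
    G_scale: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 0.0), (0.0, 1.0))
    G_df: float = 3.0

    def __post_init__(self) -> None:
        if self.fixed_effect_variance <= 0 or self.variance_scale <= 0:
            raise ValueError("prior scales must be positive")
        if self.variance_df <= 0 or self.G_df < 2:
            raise ValueError("prior degrees of freedom too small for a proper prior")

    @property
    def G_scale_matrix(self) -> np.ndarray:
        S = np.asarray(self.G_scale, dtype=float)
        if S.shape != (2, 2) or not np.allclose(S, S.T):
            raise ValueError("G_scale must be a symmetric 2x2 matrix")
        return S


@dataclass
class DesignMatrices:
    """Index structures mapping rows of the modelling table to effect columns."""

    X: np.ndarray  # (n, 5) fixed-effect design
    substance_labels: list  # length S
    study_labels: list  # length J
    group_labels: list  # length K
    b_col: np.ndarray  # (n,) column into the 2S substance-by-status effects
    u_col: np.ndarray  # (n,) study column
    w_col: np.ndarray  # (n,) within-study group column
    y: np.ndarray  # (n,) logit response

    @property
    def n(self) -> int:
        return self.y.size


def build_design(dataset: PreparedDataset | pd.DataFrame) -> DesignMatrices:
    """Build fixed-effect indicators and random-effect incidence indices.

    Fixed-effect row: ``[1, I(concentrate), I(other), I(solid),
    I(water_based)]`` — dilution and organic solvent are the reference
    categories. Substance effects are indexed by (substance, status) pairs,
    dilution column first.
    """
    table = dataset.table if isinstance(dataset, PreparedDataset) else dataset
    status = table["status"].to_numpy()
    cat = table["formulation_category"].to_numpy()
    bad_status = set(status) - set(STATUSES)
    bad_cat = set(cat) - set(FORMULATION_CATEGORIES)
    if bad_status or bad_cat:
        raise ValueError(
            f"unseen category labels: {sorted(bad_status | bad_cat)}"
        )
    n = len(table)
    X = np.ones((n, 5))
    X[:, 1] = status == "concentrate"
    for j, c in enumerate(_CATEGORY_COLUMNS, start=2):
        X[:, j] = cat == c

    substances = sorted(set(table["substance"]))
    studies = sorted(set(table["study_id"]))
    groups = sorted(set(table["group_id"]))
    s_idx = {s: i for i, s in enumerate(substances)}
    j_idx = {s: i for i, s in enumerate(studies)}
    k_idx = {g: i for i, g in enumerate(groups)}

    sub = np.array([s_idx[s] for s in table["substance"]])
    is_conc = (status == "concentrate").astype(int)
    b_col = 2 * sub + is_conc  # dilution effect at 2s, concentrate at 2s+1
    u_col = np.array([j_idx[s] for s in table["study_id"]])
    w_col = np.array([k_idx[g] for g in table["group_id"]])
    y = table["y"].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite logit response in modelling table")
    return DesignMatrices(X, substances, studies, groups, b_col, u_col, w_col, y)


class DermalAbsorptionLMM:
    """Bayesian hierarchical model of logit dermal absorption.

    Parameters
    ----------
    data : PreparedDataset or DataFrame
        Logit-scale modelling table (see :class:`~dermabs.preprocessing.PreparedDataset`).
    priors : PriorSpec, optional
        Conjugate prior settings; defaults are weakly informative.
    include_random_effects : bool
        When False, fit only fixed effects + residual variance (ordinary
        Bayesian linear regression). Used for sampler diagnostics against
        the closed-form conjugate posterior.
    """

    def __init__(
        self,
        data: PreparedDataset | pd.DataFrame,
        priors: PriorSpec | None = None,
        *,
        include_random_effects: bool = True,
    ):
        self.data = data
        self.priors = priors or PriorSpec()
        self.include_random_effects = include_random_effects
        self.design = build_design(data)
        if self.design.n == 0:
            raise ValueError("empty modelling table")

    @classmethod
    def from_records(cls, records, definition=None, priors=None, **prep_kwargs):
        """Build the model straight from replicate records (runs preprocessing)."""
        from .preprocessing import prepare_dataset

        prepared = prepare_dataset(records, definition, **prep_kwargs)
        return cls(prepared, priors)

    # -- sampler ----------------------------------------------------------

    def _assemble(self):
        d = self.design
        n = d.n
        blocks = [sparse.csr_matrix(d.X)]
        self._S = len(d.substance_labels)
        self._J = len(d.study_labels)
        self._K = len(d.group_labels)
        if self.include_random_effects:
            rows = np.arange(n)
            ones = np.ones(n)
            Zb = sparse.csr_matrix((ones, (rows, d.b_col)), shape=(n, 2 * self._S))
            Zu = sparse.csr_matrix((ones, (rows, d.u_col)), shape=(n, self._J))
            Zw = sparse.csr_matrix((ones, (rows, d.w_col)), shape=(n, self._K))
            blocks += [Zb, Zu, Zw]
        W = sparse.hstack(blocks, format="csr")
        return W, np.asarray((W.T @ W).todense()), W.T @ d.y

    def fit(
        self,
        draws: int = 2000,
        burnin: int = 500,
        thin: int = 1,
        seed: int | None = None,
        start: ModelParams | None = None,
    ) -> "LMMResults":
        """Run the Gibbs sampler and return posterior draws with diagnostics.

        ``draws`` retained draws are collected after ``burnin`` iterations,
        keeping every ``thin``-th. Identical seeds give bit-identical draw
        sequences.
        """
        if draws < 1 or burnin < 0 or thin < 1:
            raise ValueError("need draws >= 1, burnin >= 0, thin >= 1")
        rng = np.random.default_rng(seed)
        pr = self.priors
        d = self.design
        n = d.n
        W, WtW, Wty = self._assemble()
        p = WtW.shape[0]
        use_re = self.include_random_effects
        S, J, K = self._S, self._J, self._K

        # parameter state
        if start is None:
            G = np.eye(2)
            var_study = var_within = var_resid = 1.0
        else:
            G = start.G
            var_study, var_within = start.var_study, start.var_within
            var_resid = start.var_resid
        theta = np.zeros(p)

        beta_prec = 1.0 / pr.fixed_effect_variance
        beta_prior_mean = np.full(5, pr.fixed_effect_mean)
        nu0, s0 = pr.variance_df, pr.variance_scale
        G0, nu_g0 = pr.G_scale_matrix, pr.G_df

        b_slice = slice(5, 5 + 2 * S) if use_re else slice(5, 5)
        u_slice = slice(5 + 2 * S, 5 + 2 * S + J) if use_re else slice(5, 5)
        w_slice = slice(5 + 2 * S + J, p) if use_re else slice(5, 5)

        out = np.empty((draws, len(PARAM_NAMES)))
        kept = 0
        total_iters = burnin + draws * thin
        col = {name: i for i, name in enumerate(PARAM_NAMES)}

        for it in range(total_iters):
            # --- joint location update: theta | variances, y ---
            Q = WtW / var_resid
            Q[:5, :5] += np.eye(5) * beta_prec
            r = Wty / var_resid
            r[:5] += beta_prec * beta_prior_mean
            if use_re:
                Ginv = np.linalg.inv(G)
                idx = np.arange(5, 5 + 2 * S, 2)
                Q[idx, idx] += Ginv[0, 0]
                Q[idx + 1, idx + 1] += Ginv[1, 1]
                Q[idx, idx + 1] += Ginv[0, 1]
                Q[idx + 1, idx] += Ginv[1, 0]
                ud = np.arange(5 + 2 * S, 5 + 2 * S + J)
                Q[ud, ud] += 1.0 / var_study
                wd = np.arange(5 + 2 * S + J, p)
                Q[wd, wd] += 1.0 / var_within
            try:
                L = np.linalg.cholesky(Q)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise RuntimeError(
                    "location precision matrix not positive definite"
                ) from exc
            mu = np.linalg.solve(L.T, np.linalg.solve(L, r))
            z = rng.standard_normal(p)
            theta = mu + np.linalg.solve(L.T, z)

            # --- residual variance ---
            resid = d.y - W @ theta
            sse = float(resid @ resid)
            var_resid = _inv_chi2(rng, nu0 + n, (nu0 * s0 + sse) / (nu0 + n))

            if use_re:
                # --- substance covariance G | b ---
                B = theta[b_slice].reshape(S, 2)
                scale = G0 + B.T @ B
                G = stats.invwishart.rvs(df=nu_g0 + S, scale=scale, random_state=rng)
                G = np.atleast_2d(G)
                if np.linalg.eigvalsh(G)[0] <= 0:  # pragma: no cover
                    raise RuntimeError("non-positive-definite substance covariance draw")
                # --- scalar variance components ---
                u = theta[u_slice]
                var_study = _inv_chi2(
                    rng, nu0 + J, (nu0 * s0 + float(u @ u)) / (nu0 + J)
                )
                w = theta[w_slice]
                var_within = _inv_chi2(
                    rng, nu0 + K, (nu0 * s0 + float(w @ w)) / (nu0 + K)
                )

            if it >= burnin and (it - burnin) % thin == 0:
                row = out[kept]
                row[:5] = theta[:5]
                if use_re:
                    sd, sc = G[0, 0], G[1, 1]
                    row[col["var_substance_dilution"]] = sd
                    row[col["var_substance_concentrate"]] = sc
                    row[col["var_study"]] = var_study
                    row[col["var_within"]] = var_within
                    row[col["cov_substance"]] = G[0, 1]
                    row[col["rho_substance"]] = G[0, 1] / np.sqrt(sd * sc)
                else:
                    for name in PARAM_NAMES[5:-1]:
                        row[col[name]] = 0.0
                row[col["var_resid"]] = var_resid
                kept += 1

        posterior = pd.DataFrame(out[:kept], columns=list(PARAM_NAMES))
        return LMMResults(
            model=self,
            posterior=posterior,
            seed=seed,
            chain_settings={"draws": draws, "burnin": burnin, "thin": thin},
        )


def _inv_chi2(rng: np.random.Generator, df: float, scale: float) -> float:
    """Draw from a scaled inverse-chi-squared(df, scale) distribution."""
    return df * scale / rng.chisquare(df)


@dataclass
class LMMResults:
    """Posterior draws plus summaries, predictions and diagnostics.

    ``posterior`` has one row per retained draw and one column per
    parameter (see :data:`PARAM_NAMES`); ``rho_substance`` and
    ``cov_substance`` are derived per draw from the covariance draw.
    """

    posterior: pd.DataFrame
    model: DermalAbsorptionLMM | None = None
    seed: int | None = None
    chain_settings: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return len(self.posterior)

    def ess(self, param: str) -> float:
        return effective_sample_size(self.posterior[param].to_numpy())

    def hpdi(self, param: str, mass: float = 0.95) -> tuple[float, float]:
        return hpdi(self.posterior[param].to_numpy(), mass)

    def summary(self, params: tuple[str, ...] = PARAM_NAMES[:10]) -> pd.DataFrame:
        """Posterior mean, 95% HPDI and effective sample size per parameter.

        Defaults to the ten parameters reported in category-default tables:
        the five fixed effects, the four random-effect variances and the
        substance-effect correlation.
        """
        rows = []
        for name in params:
            x = self.posterior[name].to_numpy()
            lo, hi = hpdi(x, 0.95) if x.size >= 20 else (np.nan, np.nan)
            try:
                ess = effective_sample_size(x)
            except ValueError:
                ess = np.nan
            rows.append(
                {
                    "parameter": name,
                    "mean": float(x.mean()),
                    "hpdi_2.5": lo,
                    "hpdi_97.5": hi,
                    "ess": ess,
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    # -- predictions (delegate to the prediction module) -------------------

    def predict_mean(self, status=None, category=None) -> np.ndarray:
        """Posterior draws of mean percent absorbed for one cell (reference
        categories fill whichever predictor is not given)."""
        return _prediction.mean_prediction(self.posterior, status=status, category=category)

    def predict_upper(
        self, status: str, category: str, variance_level: str = "substance+study+within"
    ) -> np.ndarray:
        """Posterior draws of the upper 95% limit of the 90% prediction interval."""
        return _prediction.pi_upper(self.posterior, status, category, variance_level)

    def prediction_table(self, round_percent: bool = True) -> pd.DataFrame:
        """Category-default table: 8 cells x 3 variance levels x {median, p95}."""
        return _prediction.prediction_table(self.posterior, round_percent=round_percent)

    def to_csv(self, path) -> None:
        self.posterior.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LMMResults":
        return cls(posterior=pd.read_csv(path))
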