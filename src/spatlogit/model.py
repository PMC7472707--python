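"""Survey-weighted Bayesian spatial logistic regression.

The model, for individual i in district j:

    y_ij ~ Bernoulli(p_ij),
    logit(p_ij) = Z_ij' beta + s(t_ij) + phi(t'_ij) + b_j + h_j,

with vague Normal(0, v) priors on beta, random-walk (RW1/RW2) priors on the
smooth age effects s and phi, an intrinsic CAR prior on the spatially
structured district effects b, an IID normal prior on the unstructured
district effects h, and priors on each precision tau (Gamma(1, 1e-5) by
default). Sampling weights w_ij enter as likelihood exponents
(pseudo-likelihood): the log-likelihood is sum_ij w_ij * log Bernoulli.

Inference is by Pólya-Gamma data augmentation Gibbs sampling: given
omega_ij ~ PG(w_ij, psi_ij) the conditional for all Gaussian blocks is a
joint multivariate normal with a sparse-structured precision, sampled exactly
under hard sum-to-zero constraints on the CAR effects and each centred
smooth (conditioning by kriging). Precisions with a Gamma prior have
conjugate updates; the other families (half-normal, half-Cauchy, half-t,
uniform, PC) are updated by slice sampling on log tau.

Usage::

    model = SpatialLogit.from_dataframe(df, spec, graph)
    res = model.fit(draws=500, warmup=300, chains=2, seed=1)
    res.summary()
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_solve, solve_triangular
from scipy.special import expit, log_expit

from .design import DesignBundle, ModelSpec, build_design
from .graphs import AdjacencyGraph, build_icar_precision
from .samplers import sample_polya_gamma, slice_sample

__all__ = [
    "SpatialLogit",
    "SpatialLogitResults",
    "PosteriorPrediction",
    "fit",
    "predict_probabilities",
    "pointwise_log_density",
]


def _indicator(index: np.ndarray, k: int) -> sp.csr_array:
    n = index.size
    return sp.csr_array((np.ones(n), (np.arange(n), index)), shape=(n, k))


@dataclass
class _VarComponent:
    """One variance component: a theta block penalised by tau * Q."""

    name: str  # e.g. "age_survey", "district_car", "district_iid"
    sl: slice
    Q: np.ndarray  # dense unit precision of the block
    rank: int  # rank of Q (exponent of tau in the GMRF density)
    constrained: bool  # hard sum-to-zero constraint on the block


class SpatialLogit:
    """Bayesian spatial logistic regression model (survey-weighted Bernoulli).

    Construct from a prepared :class:`DesignBundle` or directly from a
    DataFrame via :meth:`from_dataframe`.
    """

    def __init__(self, bundle: DesignBundle, spec: ModelSpec, graph: AdjacencyGraph):
        if spec.has_car and not graph.is_connected():
            raise ValueError("CAR random effects require a connected adjacency graph")
        self.bundle = bundle
        self.spec = spec
        self.graph = graph
        self._assemble()

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        spec: ModelSpec,
        graph: AdjacencyGraph,
        outcome: str = "outcome",
        district: str = "district",
        weight: str | None = "weight",
        normalize_weights: bool = True,
    ) -> "SpatialLogit":
        bundle = build_design(
            data, spec, graph,
            outcome=outcome, district=district, weight=weight,
            normalize_weights=normalize_weights,
        )
        return cls(bundle, spec, graph)

    # ------------------------------------------------------------------
    def _assemble(self) -> None:
        bundle, spec, graph = self.bundle, self.spec, self.graph
        n = bundle.n_obs
        blocks: dict[str, slice] = {}
        mats = [sp.csr_array(bundle.Z)]
        p = bundle.Z.shape[1]
        blocks["beta"] = slice(0, p)
        offset = p
        components: list[_VarComponent] = []
        names = list(bundle.z_names)

        for sm in bundle.smooths:
            k = sm.n_knots
            sl = slice(offset, offset + k)
            blocks[sm.name] = sl
            mats.append(_indicator(sm.index, k))
            components.append(
                _VarComponent(sm.name, sl, sm.precision.matrix.toarray(),
                              sm.precision.rank, constrained=True)
            )
            names += [f"{sm.name}[{knot:g}]" for knot in sm.knots]
            offset += k

        J = bundle.n_units
        if spec.has_car:
            sl = slice(offset, offset + J)
            blocks["b"] = sl
            mats.append(_indicator(bundle.district_index, J))
            icar = build_icar_precision(graph)
            components.append(
                _VarComponent("district_car", sl, icar.matrix.toarray(),
                              icar.rank, constrained=True)
            )
            names += [f"b[{u}]" for u in bundle.unit_ids]
            offset += J
        if spec.has_iid:
            sl = slice(offset, offset + J)
            blocks["h"] = sl
            mats.append(_indicator(bundle.district_index, J))
            components.append(
                _VarComponent("district_iid", sl, np.eye(J), J, constrained=False)
            )
            names += [f"h[{u}]" for u in bundle.unit_ids]
            offset += J

        self.X = sp.hstack(mats, format="csr")
        self.d = offset
        self.blocks = blocks
        self.components = components
        self.param_names = names
        # per-component column blocks for the interweaving step
        xc = self.X.tocsc()
        self._block_cols = {c.name: xc[:, c.sl].tocsr() for c in components}

        rows = []
        for comp in components:
            if comp.constrained:
                a = np.zeros(self.d)
                k = comp.sl.stop - comp.sl.start
                a[comp.sl] = 1.0 / np.sqrt(k)
                rows.append(a)
        self.A = np.array(rows) if rows else None

    # ------------------------------------------------------------------
    def fit(
        self,
        draws: int = 500,
        warmup: int = 300,
        chains: int = 2,
        seed: int = 0,
        pg_terms: int = 64,
        start_sigma: float = 0.5,
    ) -> "SpatialLogitResults":
        """Run the Pólya-Gamma Gibbs sampler.

        Parameters
        ----------
        draws, warmup : int
            Retained and discarded iterations per chain.
        chains : int
            Independent chains (run sequentially; seeded from ``seed``).
        seed : int
            Master seed; fixing it makes the draws bitwise reproducible.
        pg_terms : int
            Series truncation of the Pólya-Gamma sampler.
        """
        if draws < 1 or warmup < 0 or chains < 1:
            raise ValueError("draws >= 1, warmup >= 0, chains >= 1 required")
        seeds = np.random.SeedSequence(seed).spawn(chains)
        theta_ch, tau_ch = [], []
        for c in range(chains):
            th, ta = self._run_chain(draws, warmup, np.random.default_rng(seeds[c]),
                                     pg_terms, start_sigma)
            theta_ch.append(th)
            tau_ch.append(ta)
        theta = np.stack(theta_ch)  # (C, S, d)
        tau = np.stack(tau_ch)  # (C, S, k)
        return SpatialLogitResults(self, theta, tau, seed=seed, chains=chains)

    def _run_chain(self, draws, warmup, rng, pg_terms, start_sigma):
        X, d = self.X, self.d
        bundle = self.bundle
        y = bundle.y.astype(float)
        w = bundle.w
        kappa = w * (y - 0.5)
        r = X.T @ kappa
        A = self.A
        beta_sl = self.blocks["beta"]
        beta_prec = 1.0 / self.spec.priors.beta_variance
        prior = self.spec.priors.precision_prior

        theta = np.zeros(d)
        tau = np.full(len(self.components), 1.0 / start_sigma**2)
        theta_out = np.empty((draws, d))
        tau_out = np.empty((draws, max(1, len(self.components))))

        for it in range(warmup + draws):
            psi = X @ theta
            if not np.all(np.isfinite(psi)):
                bad = int(np.argwhere(~np.isfinite(psi))[0, 0])
                raise FloatingPointError(
                    f"non-finite linear predictor at record {bad}"
                )
            omega = sample_polya_gamma(w, psi, rng, n_terms=pg_terms)
            P = (X.T @ X.multiply(omega[:, None])).toarray()
            P[np.arange(beta_sl.start, beta_sl.stop),
              np.arange(beta_sl.start, beta_sl.stop)] += beta_prec
            for k, comp in enumerate(self.components):
                P[comp.sl, comp.sl] += tau[k] * comp.Q
            if A is not None:
                # extra precision along constrained directions; invariant on
                # the constraint subspace, keeps the Cholesky well-conditioned
                c_jit = np.mean(np.diag(P))
                P = P + c_jit * (A.T @ A)
            L = np.linalg.cholesky(P)
            mu = cho_solve((L, True), r)
            x = mu + solve_triangular(L.T, rng.standard_normal(d), lower=False)
            if A is not None:
                V = cho_solve((L, True), A.T)
                x = x - V @ np.linalg.solve(A @ V, A @ x)
            theta = x

            for k, comp in enumerate(self.components):
                block = theta[comp.sl]
                q = float(block @ (comp.Q @ block))
                if getattr(prior, "conjugate", False):
                    shape = prior.a1 + 0.5 * comp.rank
                    rate = prior.a2 + 0.5 * q
                    tau[k] = rng.gamma(shape, 1.0 / rate)
                else:
                    rank = comp.rank

                    def logdens(u, q=q, rank=rank):
                        sigma = np.exp(-0.5 * u)
                        lp = prior.log_density_sd(sigma)
                        if not np.isfinite(lp):
                            return -np.inf
                        return lp - 0.5 * u + 0.5 * rank * u - 0.5 * np.exp(u) * q

                    u0 = np.log(tau[k])
                    if not np.isfinite(logdens(u0)):
                        u0 = 0.0
                    tau[k] = np.exp(slice_sample(u0, logdens, rng))

            # Ancillarity-sufficiency interweaving: re-update each sigma in the
            # non-centred parameterisation (block = sigma * btilde, btilde a
            # priori independent of sigma). Breaks the small-sigma funnel the
            # centred Gibbs step is prone to when a variance is weakly
            # identified.
            psi = self.X @ theta
            for k, comp in enumerate(self.components):
                sigma_now = tau[k] ** -0.5
                btilde = theta[comp.sl] / sigma_now
                u_vec = self._block_cols[comp.name] @ btilde
                rest = psi - sigma_now * u_vec
                a_lin = float(kappa @ u_vec - (omega * rest) @ u_vec)
                b_quad = float((omega * u_vec) @ u_vec)

                def logdens_v(v, a=a_lin, b=b_quad):
                    s = np.exp(v)
                    lp = prior.log_density_sd(s)
                    if not np.isfinite(lp):
                        return -np.inf
                    return lp + v + a * s - 0.5 * b * s * s

                v_new = slice_sample(np.log(sigma_now), logdens_v, rng)
                sigma_new = np.exp(v_new)
                theta[comp.sl] = sigma_new * btilde
                tau[k] = sigma_new**-2.0
                psi = rest + sigma_new * u_vec

            if it >= warmup:
                theta_out[it - warmup] = theta
                if len(self.components):
                    tau_out[it - warmup, : len(self.components)] = tau
        return theta_out, tau_out[:, : max(1, len(self.components))]


@dataclass
class PosteriorPrediction:
    """Posterior predictive probabilities: per-record draws and summaries."""

    draws: np.ndarray  # (S_total, n)
    mean: np.ndarray  # (n,)
    sd: np.ndarray  # (n,)


class SpatialLogitResults:
    """Posterior draws, summaries and diagnostics for a fitted model.

    Draws are stored as ``theta`` (chains, draws, params) plus the precision
    draws; named views (``beta_draws``, ``b_draws`` ...) slice into it.
    """

    def __init__(self, model: SpatialLogit, theta, tau, seed: int, chains: int):
        self.model = model
        self.theta = theta
        self.tau = tau
        self.seed = seed
        self.chains = chains
        self.param_names = model.param_names
        self._diagnostics = None

    # -- draw access -------------------------------------------------------
    @property
    def n_draws(self) -> int:
        return self.theta.shape[0] * self.theta.shape[1]

    def block_draws(self, name: str) -> np.ndarray:
        """Draws for a named block, shape (chains, draws, block dim)."""
        return self.theta[:, :, self.model.blocks[name]]

    def flat(self, name: str) -> np.ndarray:
        d = self.block_draws(name)
        return d.reshape(-1, d.shape[-1])

    @property
    def beta_draws(self) -> np.ndarray:
        return self.flat("beta")

    @property
    def b_draws(self) -> np.ndarray | None:
        return self.flat("b") if "b" in self.model.blocks else None

    @property
    def h_draws(self) -> np.ndarray | None:
        return self.flat("h") if "h" in self.model.blocks else None

    def smooth_draws(self, name: str) -> np.ndarray:
        return self.flat(name)

    def sigma_draws(self, component: str) -> np.ndarray:
        """Flattened posterior draws of a standard deviation (sigma = tau^-1/2)."""
        for k, comp in enumerate(self.model.components):
            if comp.name == component:
                return self.tau[:, :, k].reshape(-1) ** -0.5
        raise KeyError(
            f"no variance component {component!r}; have "
            f"{[c.name for c in self.model.components]}"
        )

    @property
    def sigma_names(self) -> list[str]:
        return [c.name for c in self.model.components]

    # -- summaries ----------------------------------------------------------
    @property
    def params(self) -> pd.Series:
        """Posterior means of the regression coefficients."""
        return pd.Series(
            self.beta_draws.mean(axis=0),
            index=self.param_names[: self.model.blocks["beta"].stop],
        )

    def _all_named_draws(self) -> dict[str, np.ndarray]:
        out = {}
        for i, nm in enumerate(self.param_names):
            out[nm] = self.theta[:, :, i]
        for k, comp in enumerate(self.model.components):
            out[f"sigma[{comp.name}]"] = self.tau[:, :, k] ** -0.5
        return out

    def summary(self, round_to: int = 4) -> pd.DataFrame:
        """Posterior mean, sd, equal-tailed 95% interval, split-Rhat and ESS."""
        named = self._all_named_draws()
        diag = self.diagnostics()
        rows = []
        for nm, arr in named.items():
            flat = arr.reshape(-1)
            rows.append({
                "parameter": nm,
                "mean": flat.mean(),
                "sd": flat.std(ddof=1),
                "ci2.5": np.quantile(flat, 0.025),
                "ci97.5": np.quantile(flat, 0.975),
                "rhat": diag["rhat"].get(nm, np.nan),
                "ess": diag["ess"].get(nm, np.nan),
            })
        df = pd.DataFrame(rows).set_index("parameter")
        return df.round(round_to)

    def odds_ratios(self) -> pd.DataFrame:
        """exp(posterior mean) and exp(95% interval) for the fixed effects."""
        p = self.model.blocks["beta"].stop
        draws = self.beta_draws
        rows = []
        for i in range(p):
            nm = self.param_names[i]
            if nm == "intercept":
                continue
            d = draws[:, i]
            rows.append({
                "covariate": nm,
                "or": np.exp(d.mean()),
                "or2.5": np.exp(np.quantile(d, 0.025)),
                "or97.5": np.exp(np.quantile(d, 0.975)),
            })
        return pd.DataFrame(rows).set_index("covariate")

    def diagnostics(self) -> dict:
        """Split-chain Rhat and effective sample size per parameter."""
        if self._diagnostics is None:
            import arviz as az

            named = self._all_named_draws()
            rhat, ess = {}, {}
            for nm, arr in named.items():
                a = arr
                if a.shape[0] == 1:  # split the single chain for split-Rhat
                    half = a.shape[1] // 2
                    a = np.stack([a[0, :half], a[0, half: 2 * half]])
                if a.std() < 1e-12:
                    rhat[nm] = 1.0
                    ess[nm] = float(a.size)
                    continue
                rhat[nm] = float(az.rhat(az.convert_to_dataset(a))["x"].values)
                ess[nm] = float(az.ess(az.convert_to_dataset(arr))["x"].values)
            self._diagnostics = {
                "rhat": rhat,
                "ess": ess,
                "max_rhat": max(rhat.values()),
                "min_ess": min(ess.values()),
            }
        return self._diagnostics

    @property
    def converged(self) -> bool:
        return self.diagnostics()["max_rhat"] < 1.1

    # -- predictions and pointwise densities --------------------------------
    def linear_predictor_draws(self, bundle: DesignBundle | None = None) -> np.ndarray:
        """(S_total, n) draws of psi = X theta for this (or a matching) bundle."""
        model = self.model
        if bundle is None or bundle is model.bundle:
            X = model.X
        else:
            X = SpatialLogit(bundle, model.spec, model.graph).X
            if X.shape[1] != model.d:
                raise ValueError("design of the new bundle does not match the fit")
        theta_flat = self.theta.reshape(-1, model.d)
        return (X @ theta_flat.T).T

    def predict(self, bundle: DesignBundle | None = None) -> PosteriorPrediction:
        """Posterior predictive termination probabilities per record."""
        psi = self.linear_predictor_draws(bundle)
        p = expit(psi)
        sd = p.std(axis=0, ddof=1) if p.shape[0] > 1 else np.zeros(p.shape[1])
        return PosteriorPrediction(draws=p, mean=p.mean(axis=0), sd=sd)

    def pointwise_log_density(self) -> np.ndarray:
        """(S_total, n) matrix of weighted per-observation log densities.

        Entry (s, i) = w_i * log Bernoulli(y_i | p_i^(s)); these are the WAIC
        inputs under the survey-weighted pseudo-likelihood.
        """
        psi = self.linear_predictor_draws()
        y = self.model.bundle.y
        w = self.model.bundle.w
        ll = np.where(y[None, :] == 1, log_expit(psi), log_expit(-psi))
        return w[None, :] * ll

    def waic(self):
        from .selection import compute_waic

        return compute_waic(self.pointwise_log_density())

    # -- serialisation -------------------------------------------------------
    def save(self, outdir) -> dict:
        """Write draws (CSV, one column per parameter), summary CSV and JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        named = self._all_named_draws()
        draws_df = pd.DataFrame({nm: a.reshape(-1) for nm, a in named.items()})
        draws_path = outdir / "draws.csv"
        draws_df.to_csv(draws_path, index=False)
        summ = self.summary()
        summ_csv = outdir / "summary.csv"
        summ.to_csv(summ_csv)
        meta = {
            "seed": self.seed,
            "chains": self.chains,
            "draws_per_chain": int(self.theta.shape[1]),
            "max_rhat": self.diagnostics()["max_rhat"],
            "min_ess": self.diagnostics()["min_ess"],
            "random_structure": self.model.spec.random_structure,
            "parameters": {
                nm: {"mean": float(a.mean()), "sd": float(a.std(ddof=1))}
                for nm, a in named.items()
            },
        }
        summ_json = outdir / "summary.json"
        with open(summ_json, "w") as fh:
            json.dump(meta, fh, indent=1)
        return {"draws": str(draws_path), "summary_csv": str(summ_csv),
                "summary_json": str(summ_json)}


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------
def fit(
    bundle: DesignBundle,
    spec: ModelSpec,
    graph: AdjacencyGraph,
    draws: int = 500,
    warmup: int = 300,
    chains: int = 2,
    seed: int = 0,
    **kwargs,
) -> SpatialLogitResults:
    """Fit the spatial logistic model from a prepared design bundle."""
    return SpatialLogit(bundle, spec, graph).fit(
        draws=draws, warmup=warmup, chains=chains, seed=seed, **kwargs
    )


def predict_probabilities(
    results: SpatialLogitResults, bundle: DesignBundle | None = None
) -> PosteriorPrediction:
    return results.predict(bundle)


def pointwise_log_density(results: SpatialLogitResults) -> np.ndarray:
    return results.pointwise_log_density()
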