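"""Synthetic areal survey data with known ground truth.

Emulates the statistical structure of a nationally representative household
survey of ever-married women aged 15-49 over 64 districts: a binary
pregnancy-termination outcome driven by categorical socio-demographic
covariates, two nonlinearly acting age covariates (age at survey, age at
first cohabitation), an ICAR-distributed spatially structured district
effect, an IID unstructured district effect, and heterogeneous sampling
weights. Every draw is reproducible from its seed and the generating
parameters are returned alongside the records.

The default mixes and effect sizes mirror the published descriptive table
and fitted model of the motivating study: covariate level proportions at the
survey's observed frequencies, log-odds-ratio effects at the fitted CAR-model
values, sigma_b = 0.44, a rise-then-plateau effect of age at survey time
(plateau from 25) and a decline-then-plateau effect of age at first
cohabitation (plateau from 22), and an intercept calibrated so the overall
prevalence is near 19.4%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular
from scipy.special import expit

from .graphs import AdjacencyGraph, build_icar_precision, generate_lattice_graph

__all__ = [
    "TrueParameters",
    "SyntheticDataset",
    "default_true_parameters",
    "default_covariate_mix",
    "rise_then_plateau",
    "decline_then_plateau",
    "sample_icar_field",
    "simulate_survey",
]

# Covariate level proportions at the survey's printed frequencies
DEFAULT_COVARIATE_MIX: dict[str, dict[str, float]] = {
    "residence": {"rural": 0.654, "urban": 0.346},
    "occupation": {"not_working": 0.685, "working": 0.315},
    "wealth": {"poorest": 0.182, "poorer": 0.188, "middle": 0.203,
               "richer": 0.211, "richest": 0.216},
    "marital": {"married": 0.942, "separated": 0.013, "divorced": 0.010,
                "widowed": 0.035},
    "children": {"none": 0.100, "one": 0.222, "two": 0.264, "three": 0.186,
                 "four_plus": 0.227},
}

# Fixed-effect log odds ratios at the fitted CAR-model values
DEFAULT_BETA: dict[str, dict[str, float]] = {
    "residence": {"urban": np.log(1.09)},
    "occupation": {"working": np.log(1.19)},
    "wealth": {"poorer": np.log(1.08), "middle": np.log(1.18),
               "richer": np.log(1.19), "richest": np.log(1.26)},
    "marital": {"separated": np.log(0.50), "divorced": np.log(0.37),
                "widowed": np.log(0.41)},
    "children": {"one": np.log(0.99), "two": np.log(0.79),
                 "three": np.log(0.72), "four_plus": np.log(0.63)},
}

SURVEY_AGE_RANGE = (15.0, 49.0)
COHAB_AGE_RANGE = (10.0, 35.0)


def rise_then_plateau(t, slope: float = 0.12, knee: float = 25.0,
                      grid=SURVEY_AGE_RANGE):
    """Log-odds contribution rising linearly to a plateau at ``knee``.

    Centred to average zero over a uniform grid on ``grid`` so the intercept
    keeps the level (identifiability).
    """
    t = np.asarray(t, dtype=float)
    lo, hi = grid
    base = slope * (np.minimum(t, knee) - knee)
    # mean of base over U(lo, hi): only t < knee contributes
    offset = -slope * (knee - lo) ** 2 / (2.0 * (hi - lo))
    return base - offset


def decline_then_plateau(t, slope: float = 0.05, knee: float = 22.0,
                         grid=COHAB_AGE_RANGE):
    """Log-odds contribution declining linearly to a plateau at ``knee``; centred."""
    t = np.asarray(t, dtype=float)
    lo, hi = grid
    base = slope * (knee - np.minimum(t, knee))
    offset = slope * (knee - lo) ** 2 / (2.0 * (hi - lo))
    return base - offset


@dataclass
class TrueParameters:
    """Ground-truth generating parameters of a synthetic survey.

    ``beta`` maps covariate -> non-reference level -> log odds ratio; the
    smooth functions give the centred log-odds contribution of each age.
    """

    # calibrated so the default study conditions give ~19.4% overall prevalence
    intercept: float = -1.442
    beta: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_BETA.items()})
    smooth_age_survey: Callable = rise_then_plateau
    smooth_age_cohab: Callable = decline_then_plateau
    sigma_b: float = 0.44
    sigma_h: float = 0.0

    def __post_init__(self):
        if self.sigma_b < 0 or self.sigma_h < 0:
            raise ValueError("random-effect standard deviations must be non-negative")
        vals = [self.intercept, self.sigma_b, self.sigma_h]
        vals += [v for lev in self.beta.values() for v in lev.values()]
        if not np.all(np.isfinite(vals)):
            raise ValueError("true parameters must be finite")

    def to_dict(self, age_grid_step: float = 0.25) -> dict:
        gs = np.arange(SURVEY_AGE_RANGE[0], SURVEY_AGE_RANGE[1] + 1e-9, age_grid_step)
        gc = np.arange(COHAB_AGE_RANGE[0], COHAB_AGE_RANGE[1] + 1e-9, age_grid_step)
        return {
            "intercept": self.intercept,
            "beta": {c: {l: float(v) for l, v in lev.items()}
                     for c, lev in self.beta.items()},
            "sigma_b": self.sigma_b,
            "sigma_h": self.sigma_h,
            "smooth_age_survey": {"grid": gs.tolist(),
                                  "values": np.asarray(self.smooth_age_survey(gs)).tolist()},
            "smooth_age_cohab": {"grid": gc.tolist(),
                                 "values": np.asarray(self.smooth_age_cohab(gc)).tolist()},
        }


def default_true_parameters(**overrides) -> TrueParameters:
    """The study-condition defaults (printed-table mixes and fitted effects)."""
    return TrueParameters(**overrides)


def default_covariate_mix() -> dict[str, dict[str, float]]:
    return {k: dict(v) for k, v in DEFAULT_COVARIATE_MIX.items()}


@dataclass
class SyntheticDataset:
    """Individual records plus the truth that generated them."""

    data: pd.DataFrame
    truth: TrueParameters
    true_b: np.ndarray
    true_h: np.ndarray
    seed: int
    graph: AdjacencyGraph

    @property
    def n_obs(self) -> int:
        return len(self.data)

    def prevalence(self) -> float:
        return float(self.data["outcome"].mean())

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def truth_to_json(self, path) -> None:
        payload = self.truth.to_dict()
        payload["true_b"] = self.true_b.tolist()
        payload["true_h"] = self.true_h.tolist()
        payload["unit_ids"] = list(self.graph.unit_ids)
        payload["seed"] = self.seed
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def write(self, outdir, stem: str = "survey") -> dict:
        """Write records CSV, truth JSON sidecar and the graph edge list."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "dataset": str(outdir / f"{stem}.csv"),
            "truth": str(outdir / f"{stem}_truth.json"),
            "graph": str(outdir / f"{stem}_graph.csv"),
        }
        self.to_csv(paths["dataset"])
        self.truth_to_json(paths["truth"])
        self.graph.to_edge_csv(paths["graph"])
        return paths


def sample_icar_field(
    graph: AdjacencyGraph, sigma_b: float, seed=None
) -> np.ndarray:
    """Draw one ICAR field under the global sum-to-zero constraint.

    The intrinsic CAR density is proper only on the subspace orthogonal to the
    constant vector; we sample from N(0, K^-1) with K = Q + (1/J) 1 1' (a rank-
    one completion along the null space) and project out the mean, which gives
    exactly N(0, pinv(Q)) scaled by sigma_b. ``seed`` may be an int or a
    numpy Generator. Disconnected graphs are rejected.
    """
    if sigma_b < 0:
        raise ValueError("sigma_b must be non-negative")
    q = build_icar_precision(graph)  # raises on disconnected graphs
    J = graph.n_units
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal(J)
    if sigma_b == 0:
        return np.zeros(J)
    K = q.matrix.toarray() + np.ones((J, J)) / J
    U = cholesky(K, lower=False)  # K = U'U, so x = U^-1 z ~ N(0, K^-1)
    x = solve_triangular(U, z, lower=False)
    x = x - x.mean()
    return sigma_b * x


def _draw_ages(rng: np.random.Generator, n: int):
    """Cohabitation age on a quarter-year grid in [10, 35]; survey age adds a
    non-negative duration and is truncated to [15, 49]."""
    cohab = 10.0 + rng.gamma(4.3, 1.4, size=n)
    cohab = np.clip(cohab, *COHAB_AGE_RANGE)
    cohab = np.round(cohab * 4.0) / 4.0
    duration = rng.gamma(2.0, 7.3, size=n)
    survey = np.clip(cohab + duration, *SURVEY_AGE_RANGE)
    survey = np.round(survey * 4.0) / 4.0
    survey = np.maximum(survey, cohab)
    return survey, cohab


def _draw_weights(rng: np.random.Generator, district_index: np.ndarray,
                  J: int, scheme: str) -> np.ndarray:
    n = district_index.size
    if scheme == "uniform":
        return np.ones(n)
    if scheme != "stratified":
        raise ValueError("weight_scheme must be 'uniform' or 'stratified'")
    # district-level selection probability plus individual non-response noise;
    # weights are the inverse, clipped to [0.3, 3] and rescaled to mean 1
    log_pi = rng.normal(0.0, 0.45, size=J)[district_index] + rng.normal(0.0, 0.15, size=n)
    w = np.clip(np.exp(-log_pi), 0.3, 3.0)
    return w / w.mean()


def simulate_survey(
    graph: AdjacencyGraph | None = None,
    truth: TrueParameters | None = None,
    n_per_district: int = 278,
    covariate_mix: dict | None = None,
    weight_scheme: str = "stratified",
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a survey-style dataset from the spatial logistic model.

    Outcomes are Bernoulli with logit p = intercept + Z beta + s(age_survey)
    + phi(age_cohab) + b_j + h_j, where b is an ICAR field with conditional
    sd sigma_b, h is IID normal with sd sigma_h, and the true fields are
    stored for parameter-recovery checks.
    """
    if graph is None:
        graph = generate_lattice_graph(8, 8)
    if truth is None:
        truth = default_true_parameters()
    if covariate_mix is None:
        covariate_mix = default_covariate_mix()
    if not covariate_mix:
        raise ValueError("covariate_mix must not be empty")
    if n_per_district < 1:
        raise ValueError("n_per_district must be at least 1")
    for cov, mix in covariate_mix.items():
        tot = sum(mix.values())
        # printed survey percentages round to 0.1%, so allow slight slack;
        # probabilities are renormalised before drawing
        if not np.isclose(tot, 1.0, atol=5e-3):
            raise ValueError(f"covariate_mix[{cov!r}] sums to {tot}, not 1")

    rng = np.random.default_rng(seed)
    J = graph.n_units
    n = n_per_district * J
    district_index = np.repeat(np.arange(J), n_per_district)

    cols: dict[str, np.ndarray] = {}
    eta = np.full(n, truth.intercept)
    for cov, mix in covariate_mix.items():
        levels = list(mix.keys())
        probs = np.array([mix[l] for l in levels], dtype=float)
        draw = rng.choice(len(levels), size=n, p=probs / probs.sum())
        cols[cov] = np.array(levels, dtype=object)[draw]
        effects = np.array([truth.beta.get(cov, {}).get(l, 0.0) for l in levels])
        eta += effects[draw]

    age_survey, age_cohab = _draw_ages(rng, n)
    # centre each smooth over the realised ages: the fitted smooths carry a
    # sum-to-zero constraint, so the intercept owns the level either way
    s_vals = np.broadcast_to(np.asarray(truth.smooth_age_survey(age_survey),
                                        dtype=float), (n,))
    p_vals = np.broadcast_to(np.asarray(truth.smooth_age_cohab(age_cohab),
                                        dtype=float), (n,))
    eta += s_vals - s_vals.mean()
    eta += p_vals - p_vals.mean()

    true_b = sample_icar_field(graph, truth.sigma_b, rng)
    true_h = (rng.standard_normal(J) * truth.sigma_h if truth.sigma_h > 0
              else np.zeros(J))
    eta += true_b[district_index] + true_h[district_index]

    y = (rng.uniform(size=n) < expit(eta)).astype(np.int8)
    w = _draw_weights(rng, district_index, J, weight_scheme)

    data = pd.DataFrame({
        "outcome": y,
        **cols,
        "age_survey": age_survey,
        "age_cohab": age_cohab,
        "district": np.array(graph.unit_ids, dtype=object)[district_index],
        "weight": w,
    })
    return SyntheticDataset(data=data, truth=truth, true_b=true_b,
                            true_h=true_h, seed=seed, graph=graph)
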