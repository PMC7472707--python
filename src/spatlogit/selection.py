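"""Model comparison: WAIC, the covariance-structure ladder, backward covariate
selection, prior-sensitivity sweeps, and the linear-vs-RW1 coefficient report.

WAIC convention
---------------
``waic = -2 * (lppd - p_d)`` (deviance scale), with ``lppd`` the log pointwise
predictive density, ``lppd_i = log mean_s exp(ld_si)``, and the effective
number of parameters ``p_d_i = var_s(ld_si)`` (variance form). The pointwise
log densities are survey-weighted, so WAIC compares weighted pseudo-
likelihood fits. Smaller is better; candidates within 2 units of the best
are treated as fitting similarly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .design import ModelSpec, PriorSpec, build_design, make_precision_prior
from .graphs import AdjacencyGraph
from .model import SpatialLogit, SpatialLogitResults

__all__ = [
    "WAICResult",
    "SelectionReport",
    "compute_waic",
    "structure_ladder",
    "backward_select",
    "sensitivity_sweep",
    "linearity_comparison",
]

RHAT_WARN = 1.1


@dataclass(frozen=True)
class WAICResult:
    """Widely applicable information criterion on the deviance scale."""

    lppd: float
    p_d: float
    waic: float
    per_obs_lppd: np.ndarray = field(repr=False, default=None)
    per_obs_p_d: np.ndarray = field(repr=False, default=None)
    n_high_p_d: int = 0  # observations with p_d_i > 0.4 (unstable terms)


def compute_waic(pointwise: np.ndarray) -> WAICResult:
    """WAIC from an (S, n) matrix of per-draw, per-observation log densities."""
    pointwise = np.asarray(pointwise, dtype=float)
    if pointwise.ndim != 2 or pointwise.shape[0] < 2:
        raise ValueError("pointwise log-density matrix must be (S >= 2, n)")
    if not np.all(np.isfinite(pointwise)):
        raise ValueError("pointwise log densities contain non-finite entries")
    S = pointwise.shape[0]
    lppd_i = logsumexp(pointwise, axis=0) - np.log(S)
    p_d_i = pointwise.var(axis=0, ddof=1)
    lppd = float(lppd_i.sum())
    p_d = float(p_d_i.sum())
    return WAICResult(
        lppd=lppd,
        p_d=p_d,
        waic=-2.0 * (lppd - p_d),
        per_obs_lppd=lppd_i,
        per_obs_p_d=p_d_i,
        n_high_p_d=int((p_d_i > 0.4).sum()),
    )


@dataclass
class SelectionReport:
    """Candidates with their WAICs, the winner, and the decision trace."""

    candidates: list  # [(label, WAICResult)]
    best: str
    decision_trace: list
    fits: dict = field(default_factory=dict, repr=False)
    warnings: list = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"model": lab, "waic": w.waic, "p_d": w.p_d, "lppd": w.lppd,
             "delta_waic": w.waic - min(x.waic for _, x in self.candidates),
             "within_2": w.waic - min(x.waic for _, x in self.candidates) <= 2.0}
            for lab, w in self.candidates
        ]
        return pd.DataFrame(rows).set_index("model")


def _pick_best(candidates: list) -> str:
    """Minimal WAIC; ties within numerical noise broken by fewer effective params."""
    best_waic = min(w.waic for _, w in candidates)
    tied = [(lab, w) for lab, w in candidates if w.waic - best_waic < 1e-9]
    return min(tied, key=lambda lw: lw[1].p_d)[0]


def _fit_candidate(data, spec, graph, sampler, seed_seq, warnings):
    res = SpatialLogit.from_dataframe(data, spec, graph, **sampler.get("columns", {})).fit(
        draws=sampler.get("draws", 400),
        warmup=sampler.get("warmup", 300),
        chains=sampler.get("chains", 1),
        seed=int(seed_seq.generate_state(1)[0] % (2**31 - 1)),
        pg_terms=sampler.get("pg_terms", 64),
    )
    if not res.converged:
        warnings.append(
            f"{spec.random_structure}: max split-Rhat "
            f"{res.diagnostics()['max_rhat']:.3f} exceeds {RHAT_WARN}"
        )
    return res


def structure_ladder(
    data: pd.DataFrame,
    graph: AdjacencyGraph,
    spec: ModelSpec,
    sampler: dict | None = None,
    seed: int = 0,
    keep_fits: bool = False,
) -> SelectionReport:
    """Compare the four district-effect covariance structures by WAIC.

    Fits NO (no district effect), IID, CAR and CAR+IID variants of ``spec``
    with identical sampler settings and a seed schedule derived from one
    master seed, and ranks them by WAIC with the 2-unit similarity rule.
    """
    sampler = sampler or {}
    root = np.random.SeedSequence(seed)
    candidates, trace, fits, warnings = [], [], {}, []
    for structure, child in zip(("NO", "IID", "CAR", "CAR_IID"), root.spawn(4)):
        cand_spec = spec.with_structure(structure)
        try:
            res = _fit_candidate(data, cand_spec, graph, sampler, child, warnings)
        except Exception as exc:  # a failed member is reported, not fatal
            warnings.append(f"{structure}: fit failed ({exc})")
            trace.append({"model": structure, "status": "failed", "error": str(exc)})
            continue
        w = res.waic()
        candidates.append((structure, w))
        trace.append({"model": structure, "status": "ok", "waic": w.waic, "p_d": w.p_d})
        if keep_fits:
            fits[structure] = res
    if not candidates:
        raise RuntimeError("every candidate fit failed")
    best = _pick_best(candidates)
    best_waic = min(w.waic for _, w in candidates)
    for entry in trace:
        if entry["status"] == "ok":
            entry["delta_waic"] = entry["waic"] - best_waic
            entry["within_2_of_best"] = entry["delta_waic"] <= 2.0
    return SelectionReport(candidates, best, trace, fits, warnings)


def backward_select(
    data: pd.DataFrame,
    graph: AdjacencyGraph,
    spec: ModelSpec,
    sampler: dict | None = None,
    seed: int = 0,
    threshold: float = 2.0,
) -> SelectionReport:
    """Backward covariate elimination under the 2-unit WAIC rule.

    Starting from the full fixed-effect set, repeatedly drops the covariate
    whose removal most decreases WAIC, stopping when no removal decreases it
    by more than ``threshold``. The trace records every comparison.
    """
    if not spec.fixed_effects:
        raise ValueError("backward selection needs at least one fixed effect")
    sampler = sampler or {}
    root = np.random.SeedSequence(seed)

    def next_seed():
        return root.spawn(1)[0]

    warnings: list[str] = []
    trace: list[dict] = []
    current = spec
    res = _fit_candidate(data, current, graph, sampler, next_seed(), warnings)
    current_waic = res.waic()
    trace.append({"step": 0, "model": "full", "waic": current_waic.waic,
                  "covariates": [f.name for f in current.fixed_effects]})
    step = 0
    while len(current.fixed_effects) > 1:
        step += 1
        trials = []
        for eff in current.fixed_effects:
            cand = current.without_covariate(eff.name)
            r = _fit_candidate(data, cand, graph, sampler, next_seed(), warnings)
            w = r.waic()
            trials.append((eff.name, cand, w))
            trace.append({"step": step, "dropped": eff.name, "waic": w.waic,
                          "delta_vs_current": w.waic - current_waic.waic})
        name, cand, w = min(trials, key=lambda t: t[2].waic)
        if current_waic.waic - w.waic > threshold:
            current, current_waic = cand, w
            trace.append({"step": step, "decision": f"drop {name}",
                          "new_waic": w.waic})
        else:
            trace.append({"step": step, "decision": "stop",
                          "best_removal": name,
                          "improvement": current_waic.waic - w.waic})
            break
    label = "+".join(f.name for f in current.fixed_effects)
    report = SelectionReport([(label, current_waic)], label, trace, {}, warnings)
    report.selected_spec = current
    return report


def sensitivity_sweep(
    data: pd.DataFrame,
    graph: AdjacencyGraph,
    spec: ModelSpec,
    families: list | None = None,
    sampler: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Refit the model under alternative precision-prior families.

    ``families`` is a list of family names (``gamma``, ``half_normal``,
    ``half_cauchy``, ``half_t``, ``uniform``, ``pc``) or of
    ``(label, prior object)`` pairs. Returns one row per family per variance
    component: posterior mean and equal-tailed 95% interval of sigma, plus
    the model's WAIC — the stability analogue of a prior-sensitivity table.
    """
    if families is None:
        families = ["gamma", "half_normal", "half_cauchy", "half_t", "uniform", "pc"]
    sampler = sampler or {}
    root = np.random.SeedSequence(seed)
    rows = []
    for fam, child in zip(families, root.spawn(len(families))):
        if isinstance(fam, str):
            label, prior = fam, make_precision_prior(fam)
        else:
            label, prior = fam
        cand_spec = spec.with_priors(PriorSpec(
            beta_variance=spec.priors.beta_variance, precision_prior=prior))
        warnings: list[str] = []
        res = _fit_candidate(data, cand_spec, graph, sampler, child, warnings)
        w = res.waic()
        for comp in res.sigma_names:
            sig = res.sigma_draws(comp)
            rows.append({
                "family": label,
                "component": comp,
                "sigma_mean": sig.mean(),
                "sigma2.5": np.quantile(sig, 0.025),
                "sigma97.5": np.quantile(sig, 0.975),
                "waic": w.waic,
                "converged": res.converged,
            })
    return pd.DataFrame(rows)


def linearity_comparison(
    data: pd.DataFrame,
    graph: AdjacencyGraph,
    spec: ModelSpec,
    sampler: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fixed-effect odds ratios under RW-smooth vs linear age effects.

    Fits ``spec`` as given (nonlinear random-walk age effects) and its
    linearised counterpart, and returns a forest-plot-ready paired table: per
    fixed effect, OR = exp(posterior mean) with the equal-tailed 95% interval
    under both treatments, plus interval-overlap and sign-agreement flags.
    """
    sampler = sampler or {}
    root = np.random.SeedSequence(seed)
    s_non, s_lin = root.spawn(2)
    warnings: list[str] = []
    res_non = _fit_candidate(data, spec, graph, sampler, s_non, warnings)
    res_lin = _fit_candidate(data, spec.linearised(), graph, sampler, s_lin, warnings)
    or_non = res_non.odds_ratios()
    or_lin = res_lin.odds_ratios()
    shared = [c for c in or_non.index if c in or_lin.index]
    rows = []
    for cov in shared:
        a, b = or_non.loc[cov], or_lin.loc[cov]
        overlap = (a["or2.5"] <= b["or97.5"]) and (b["or2.5"] <= a["or97.5"])
        rows.append({
            "covariate": cov,
            "or_nonlinear": a["or"], "or_nonlinear2.5": a["or2.5"],
            "or_nonlinear97.5": a["or97.5"],
            "or_linear": b["or"], "or_linear2.5": b["or2.5"],
            "or_linear97.5": b["or97.5"],
            "intervals_overlap": overlap,
            "same_direction": (a["or"] - 1.0) * (b["or"] - 1.0) >= 0,
        })
    return pd.DataFrame(rows).set_index("covariate")
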