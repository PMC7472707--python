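"""Model specification and design construction.

Turns an individual-level survey table plus a :class:`ModelSpec` into the
concrete arrays the sampler consumes: a reference-cell-coded fixed-effects
matrix with an intercept, knot assignments for random-walk smooth terms,
district indices aligned with an :class:`~spatlogit.graphs.AdjacencyGraph`,
and mean-one-normalised sampling weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .graphs import AdjacencyGraph, PrecisionStructure, build_rw_precision

__all__ = [
    "FixedEffect",
    "SmoothTerm",
    "PriorSpec",
    "ModelSpec",
    "DesignBundle",
    "SmoothDesign",
    "assign_knots",
    "build_design",
    "PRIOR_FAMILIES",
    "make_precision_prior",
]

RANDOM_STRUCTURES = ("NO", "IID", "CAR", "CAR_IID")


# ---------------------------------------------------------------------------
# priors on the variance components
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class GammaPrecision:
    """Gamma(a1, a2) prior on the precision tau; conjugate in the Gibbs sweep.

    The defaults a1 = 1 (an exponential) and a2 = 1e-5 give the precision a
    large prior mean and variance, i.e. a vague prior.
    """

    a1: float = 1.0
    a2: float = 1e-5
    name: str = "gamma"
    conjugate: bool = True

    def log_density_sd(self, sigma: float) -> float:
        # induced density on sigma from Gamma(a1, a2) on tau = sigma^-2
        tau = sigma**-2.0
        return (self.a1 * np.log(self.a2) + (self.a1 - 1) * np.log(tau)
                - self.a2 * tau + np.log(2.0) - 3.0 * np.log(sigma))


@dataclass(frozen=True)
class HalfNormalSD:
    scale: float = 1.0
    name: str = "half_normal"
    conjugate: bool = False

    def log_density_sd(self, sigma: float) -> float:
        return -0.5 * (sigma / self.scale) ** 2


@dataclass(frozen=True)
class HalfCauchySD:
    scale: float = 1.0
    name: str = "half_cauchy"
    conjugate: bool = False

    def log_density_sd(self, sigma: float) -> float:
        return -np.log1p((sigma / self.scale) ** 2)


@dataclass(frozen=True)
class HalfTSD:
    df: float = 3.0
    scale: float = 1.0
    name: str = "half_t"
    conjugate: bool = False

    def log_density_sd(self, sigma: float) -> float:
        return -0.5 * (self.df + 1) * np.log1p((sigma / self.scale) ** 2 / self.df)


@dataclass(frozen=True)
class UniformSD:
    """Uniform prior on the standard deviation, sigma ~ U(0, upper)."""

    upper: float = 10.0
    name: str = "uniform"
    conjugate: bool = False

    def log_density_sd(self, sigma: float) -> float:
        return 0.0 if 0.0 < sigma < self.upper else -np.inf


@dataclass(frozen=True)
class PCPrecision:
    """Penalised-complexity prior: exponential on sigma with P(sigma > u) = alpha."""

    u: float = 1.0
    alpha: float = 0.01
    name: str = "pc"
    conjugate: bool = False

    @property
    def rate(self) -> float:
        return -np.log(self.alpha) / self.u

    def log_density_sd(self, sigma: float) -> float:
        return -self.rate * sigma


PRIOR_FAMILIES = {
    "gamma": GammaPrecision,
    "half_normal": HalfNormalSD,
    "half_cauchy": HalfCauchySD,
    "half_t": HalfTSD,
    "uniform": UniformSD,
    "pc": PCPrecision,
}


def make_precision_prior(family: str, **params):
    """Instantiate a precision-prior family by name (for configs and sweeps)."""
    try:
        cls = PRIOR_FAMILIES[family]
    except KeyError:
        raise ValueError(
            f"unknown precision-prior family {family!r}; "
            f"choose from {sorted(PRIOR_FAMILIES)}"
        ) from None
    return cls(**params)


@dataclass(frozen=True)
class PriorSpec:
    """Priors for the regression coefficients and the variance components.

    ``beta_variance`` is the variance of the vague Normal(0, v) prior on each
    fixed-effect coefficient (default 1e6). ``precision_prior`` applies to
    every precision (per-smooth tau_s, spatial tau_b, unstructured tau_h).
    """

    beta_variance: float = 1e6
    precision_prior: object = GammaPrecision()

    def __post_init__(self):
        if self.beta_variance <= 0:
            raise ValueError("beta_variance must be positive")

    def to_dict(self) -> dict:
        fam = self.precision_prior
        d = {"beta_variance": self.beta_variance, "family": fam.name}
        for key in ("a1", "a2", "scale", "df", "upper", "u", "alpha"):
            if hasattr(fam, key):
                d[key] = getattr(fam, key)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        d = dict(d)
        beta_variance = float(d.pop("beta_variance", 1e6))
        family = d.pop("family", "gamma")
        return cls(beta_variance=beta_variance,
                   precision_prior=make_precision_prior(family, **d))


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class FixedEffect:
    """A categorical covariate with a declared reference level.

    ``levels`` fixes the dummy-column order; when omitted the non-reference
    levels are sorted lexicographically (deterministic either way).
    """

    name: str
    reference: str
    levels: tuple | None = None


@dataclass(frozen=True)
class SmoothTerm:
    """A continuous covariate modelled as RW1 (order=1), RW2 (order=2), or 'linear'."""

    name: str
    order: object = 1  # 1 | 2 | "linear"

    def __post_init__(self):
        if self.order not in (1, 2, "linear"):
            raise ValueError("smooth order must be 1, 2 or 'linear'")


@dataclass(frozen=True)
class ModelSpec:
    fixed_effects: tuple
    smooth_terms: tuple = ()
    random_structure: str = "CAR"
    priors: PriorSpec = PriorSpec()
    bin_width: float = 1.0
    max_knots: int = 60

    def __post_init__(self):
        object.__setattr__(self, "fixed_effects", tuple(self.fixed_effects))
        object.__setattr__(self, "smooth_terms", tuple(self.smooth_terms))
        if self.random_structure not in RANDOM_STRUCTURES:
            raise ValueError(
                f"random_structure must be one of {RANDOM_STRUCTURES}, "
                f"got {self.random_structure!r}"
            )

    @property
    def has_car(self) -> bool:
        return self.random_structure in ("CAR", "CAR_IID")

    @property
    def has_iid(self) -> bool:
        return self.random_structure in ("IID", "CAR_IID")

    def with_structure(self, structure: str) -> "ModelSpec":
        return replace(self, random_structure=structure)

    def with_priors(self, priors: PriorSpec) -> "ModelSpec":
        return replace(self, priors=priors)

    def without_covariate(self, name: str) -> "ModelSpec":
        kept = tuple(f for f in self.fixed_effects if f.name != name)
        if len(kept) == len(self.fixed_effects):
            raise ValueError(f"no fixed effect named {name!r}")
        return replace(self, fixed_effects=kept)

    def linearised(self) -> "ModelSpec":
        """Same spec with every RW smooth replaced by a linear effect."""
        return replace(
            self,
            smooth_terms=tuple(SmoothTerm(t.name, "linear") for t in self.smooth_terms),
        )

    # -- config (de)serialisation ------------------------------------------
    def to_dict(self) -> dict:
        return {
            "fixed_effects": [
                {"name": f.name, "reference": f.reference,
                 **({"levels": list(f.levels)} if f.levels else {})}
                for f in self.fixed_effects
            ],
            "smooth_terms": [{"name": t.name, "order": t.order} for t in self.smooth_terms],
            "random_structure": self.random_structure,
            "priors": self.priors.to_dict(),
            "bin_width": self.bin_width,
            "max_knots": self.max_knots,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        fixed = d.get("fixed_effects", [])
        if isinstance(fixed, dict):  # shorthand {name: reference}
            fixed = [{"name": k, "reference": v} for k, v in fixed.items()]
        fe = tuple(
            FixedEffect(f["name"], f["reference"],
                        tuple(f["levels"]) if f.get("levels") else None)
            for f in fixed
        )
        st = tuple(SmoothTerm(t["name"], t.get("order", 1))
                   for t in d.get("smooth_terms", []))
        priors = PriorSpec.from_dict(d["priors"]) if "priors" in d else PriorSpec()
        return cls(
            fixed_effects=fe,
            smooth_terms=st,
            random_structure=d.get("random_structure", "CAR"),
            priors=priors,
            bin_width=float(d.get("bin_width", 1.0)),
            max_knots=int(d.get("max_knots", 60)),
        )


# ---------------------------------------------------------------------------
# knot assignment and the design bundle
# ---------------------------------------------------------------------------
def assign_knots(values, bin_width: float, max_knots: int = 60):
    """Bin a continuous covariate and map records to ranked knots.

    Values are floor-binned at ``bin_width`` (the ranked-value construction of
    the random-walk prior, with ties sharing a knot); if more than
    ``max_knots`` distinct bins result, the bin width is doubled until the
    count fits.

    Returns ``(knots, indices)`` with ``knots`` the sorted distinct bin
    locations and ``indices`` the per-record knot index.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot assign knots for an empty covariate")
    if not np.all(np.isfinite(values)):
        raise ValueError("knot covariate contains non-finite values")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    width = float(bin_width)
    while True:
        binned = np.floor(values / width) * width
        knots = np.unique(binned)
        if knots.size <= max_knots:
            break
        width *= 2.0
    indices = np.searchsorted(knots, binned)
    return knots, indices.astype(int)


@dataclass(frozen=True)
class SmoothDesign:
    """Knot layout and unit precision for one RW smooth term."""

    name: str
    order: int
    knots: np.ndarray
    index: np.ndarray  # per-record knot index
    precision: PrecisionStructure

    @property
    def n_knots(self) -> int:
        return self.knots.size

    @property
    def degenerate(self) -> bool:
        return self.n_knots < self.order + 1


@dataclass(frozen=True)
class DesignBundle:
    """Everything the sampler needs, in aligned arrays.

    ``Z`` carries the intercept, the dummy-coded fixed effects, and any
    centred *linear* age terms; RW smooths live in ``smooths`` as knot
    assignments; ``district_index`` maps records onto graph units; ``w`` is
    the weight vector (mean 1 when normalised).
    """

    y: np.ndarray
    Z: np.ndarray
    z_names: tuple
    smooths: tuple
    district_index: np.ndarray
    w: np.ndarray
    unit_ids: tuple
    n_excluded: int = 0

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)


def _dummy_columns(series: pd.Series, effect: FixedEffect):
    observed = list(pd.unique(series))
    if effect.levels is not None:
        declared = list(effect.levels)
        unseen = set(observed) - set(declared)
        if unseen:
            raise ValueError(
                f"covariate {effect.name!r} has categories {sorted(map(str, unseen))} "
                f"not in its declared levels"
            )
        levels = declared
    else:
        levels = sorted(map(str, observed))
        series = series.astype(str)
    if str(effect.reference) not in map(str, levels):
        raise ValueError(
            f"reference category {effect.reference!r} of {effect.name!r} "
            f"does not occur in the declared or observed levels"
        )
    cols, names = [], []
    for lev in levels:
        if str(lev) == str(effect.reference):
            continue
        cols.append((series.astype(str) == str(lev)).to_numpy(dtype=float))
        names.append(f"{effect.name}[{lev}]")
    return cols, names


def build_design(
    dataset: pd.DataFrame,
    spec: ModelSpec,
    graph: AdjacencyGraph,
    outcome: str = "outcome",
    district: str = "district",
    weight: str | None = "weight",
    normalize_weights: bool = True,
) -> DesignBundle:
    """Build the design bundle from an individual-level table.

    Records with missing values in any used column are dropped (listwise
    deletion) and the count is reported in ``n_excluded``. Reference-cell
    coding drops the declared reference level of each fixed effect; column
    order follows the spec order, then level order.
    """
    used = [outcome, district]
    used += [f.name for f in spec.fixed_effects]
    used += [t.name for t in spec.smooth_terms]
    if weight is not None and weight in dataset.columns:
        used.append(weight)
    missing_cols = [c for c in used if c not in dataset.columns]
    if missing_cols:
        raise ValueError(f"dataset is missing columns {missing_cols}")
    sub = dataset[used]
    keep = sub.notna().all(axis=1)
    n_excluded = int((~keep).sum())
    sub = sub.loc[keep].reset_index(drop=True)
    if len(sub) == 0:
        raise ValueError("no complete records after listwise deletion")

    y = sub[outcome].to_numpy()
    if not np.isin(y, [0, 1]).all():
        raise ValueError("outcome must be binary 0/1")
    y = y.astype(np.int8)

    n = len(sub)
    cols = [np.ones(n)]
    names = ["intercept"]
    for eff in spec.fixed_effects:
        c, nm = _dummy_columns(sub[eff.name], eff)
        cols += c
        names += nm

    smooths = []
    for term in spec.smooth_terms:
        vals = sub[term.name].to_numpy(dtype=float)
        if term.order == "linear":
            # centred so the intercept keeps the level
            cols.append(vals - vals.mean())
            names.append(term.name)
            continue
        knots, idx = assign_knots(vals, spec.bin_width, spec.max_knots)
        if knots.size < term.order + 1:
            raise ValueError(
                f"smooth term {term.name!r} is degenerate: only {knots.size} "
                f"distinct knot(s); model it as a fixed effect instead"
            )
        prec = build_rw_precision(knots.size, term.order)
        smooths.append(SmoothDesign(term.name, term.order, knots, idx, prec))

    Z = np.column_stack(cols)
    if not np.all(np.isfinite(Z)):
        bad = int(np.argwhere(~np.isfinite(Z))[0, 0])
        raise ValueError(f"non-finite design value at record {bad}")

    try:
        district_index = np.array(
            [graph.index_of(d) for d in sub[district]], dtype=int
        )
    except KeyError as exc:
        raise ValueError(
            f"district {exc.args[0]!r} does not appear in the adjacency graph"
        ) from None

    if weight is not None and weight in sub.columns:
        w = sub[weight].to_numpy(dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
        if normalize_weights:
            w = w / w.mean()
    else:
        w = np.ones(n)

    return DesignBundle(
        y=y,
        Z=Z,
        z_names=tuple(names),
        smooths=tuple(smooths),
        district_index=district_index,
        w=w,
        unit_ids=tuple(graph.unit_ids),
        n_excluded=n_excluded,
    )
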