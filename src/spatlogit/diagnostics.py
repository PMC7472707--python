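"""Descriptive summaries, multicollinearity screening and spatial risk maps.

* :func:`descriptive_table` — outcome-stratified frequency/percentage table
  for categorical covariates plus median/IQR rows for continuous ones.
* :func:`compute_gvif` — generalized variance inflation factors for
  (possibly multi-column) covariates, reported on the comparable
  GVIF^(1/(2 df)) scale with the sqrt(2.5) ≈ 1.58 rule-of-thumb cutoff.
* :func:`exceedance` / :func:`district_risk_map` — posterior exceedance
  probabilities q_j = P(exp(b_j) > 1) with elevated-district flags, and
  per-district summaries of the spatial effect and predicted probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignBundle
from .graphs import AdjacencyGraph
from .model import SpatialLogitResults

__all__ = [
    "descriptive_table",
    "GVIFReport",
    "compute_gvif",
    "DistrictRiskSummary",
    "exceedance",
    "district_risk_map",
]


def descriptive_table(
    data: pd.DataFrame,
    outcome: str = "outcome",
    categorical: list | None = None,
    continuous: list | None = None,
    weights: str | None = None,
) -> pd.DataFrame:
    """Outcome-stratified descriptive table (unweighted by default).

    For each categorical level: total frequency, column percent, and the
    frequency and row percent within each outcome stratum. For each
    continuous covariate: median and IQR overall and by outcome. Percentages
    are rounded to two decimals. Pass ``weights`` for a weighted variant.
    """
    if categorical is None:
        categorical = [c for c in data.columns
                       if c != outcome and not pd.api.types.is_numeric_dtype(data[c])]
    if continuous is None:
        continuous = [c for c in data.columns
                      if c not in categorical and c != outcome
                      and pd.api.types.is_numeric_dtype(data[c])
                      and data[c].nunique() > 10]
    w = data[weights].to_numpy(float) if weights else np.ones(len(data))
    y = data[outcome].to_numpy()
    rows = []
    for cov in categorical:
        col = data[cov]
        total_w = w.sum()
        for lev in sorted(col.dropna().unique(), key=str):
            mask = (col == lev).to_numpy()
            n_tot = w[mask].sum()
            n_yes = w[mask & (y == 1)].sum()
            n_no = w[mask & (y == 0)].sum()
            rows.append({
                "covariate": cov, "level": str(lev),
                "total": n_tot if weights else int(n_tot),
                "column_pct": round(100.0 * n_tot / total_w, 2),
                "yes": n_yes if weights else int(n_yes),
                "yes_row_pct": round(100.0 * n_yes / n_tot, 2) if n_tot else np.nan,
                "no": n_no if weights else int(n_no),
                "no_row_pct": round(100.0 * n_no / n_tot, 2) if n_tot else np.nan,
            })
    for cov in continuous:
        v = data[cov]
        for label, mask in (("overall", np.ones(len(data), bool)),
                            ("yes", y == 1), ("no", y == 0)):
            sub = v[mask]
            q1, med, q3 = sub.quantile([0.25, 0.5, 0.75])
            rows.append({
                "covariate": cov, "level": f"median/IQR ({label})",
                "total": int(mask.sum()), "column_pct": np.nan,
                "yes": round(med, 2), "yes_row_pct": np.nan,
                "no": round(q3 - q1, 2), "no_row_pct": np.nan,
            })
    out = pd.DataFrame(rows).set_index(["covariate", "level"])
    overall = pd.DataFrame([{
        "covariate": outcome, "level": "prevalence_pct",
        "total": int(len(data)),
        "column_pct": round(100.0 * (w * (y == 1)).sum() / w.sum(), 2),
        "yes": int((y == 1).sum()), "yes_row_pct": np.nan,
        "no": int((y == 0).sum()), "no_row_pct": np.nan,
    }]).set_index(["covariate", "level"])
    return pd.concat([overall, out])


# ---------------------------------------------------------------------------
@dataclass
class GVIFReport:
    """Per-covariate generalized variance inflation factors."""

    table: pd.DataFrame  # columns: gvif, df, adjusted
    threshold: float
    flagged: list
    collinear_sets: list = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def _design_columns(data: pd.DataFrame, covariates, references=None):
    """Dummy-code covariates (reference level dropped); continuous pass through."""
    references = references or {}
    groups, cols, names = [], [], []
    for cov in covariates:
        col = data[cov]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 10:
            groups.append((cov, 1))
            cols.append(col.to_numpy(float))
            names.append(cov)
            continue
        levels = sorted(col.dropna().unique(), key=str)
        ref = references.get(cov, levels[0])
        dummy_levels = [l for l in levels if str(l) != str(ref)]
        groups.append((cov, len(dummy_levels)))
        for lev in dummy_levels:
            cols.append((col == lev).to_numpy(float))
            names.append(f"{cov}[{lev}]")
    return np.column_stack(cols), groups, names


def compute_gvif(
    data: pd.DataFrame,
    covariates: list,
    references: dict | None = None,
    threshold: float = 1.58,
) -> GVIFReport:
    """GVIF per covariate from the correlation matrix of the dummy design.

    GVIF_c = det(R11) det(R22) / det(R), where R is the correlation matrix of
    all non-intercept design columns, R11 the block of covariate c's own
    columns and R22 the block of all the others. The comparable scale is
    GVIF^(1/(2 df)); values at or above ``threshold`` (default 1.58, i.e.
    sqrt(2.5)) are flagged. A rank-deficient design yields infinite GVIFs
    with the collinear covariates identified.
    """
    if len(covariates) < 2:
        raise ValueError("GVIF needs at least two covariates")
    X, groups, names = _design_columns(data, covariates, references)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        const = [names[i] for i in np.where(sd == 0)[0]]
        raise ValueError(f"constant design columns: {const}")
    R = np.corrcoef(X, rowvar=False)
    R = np.atleast_2d(R)
    sign, logdet_R = np.linalg.slogdet(R)
    singular = sign <= 0 or logdet_R < -40  # det below ~4e-18: numerically rank-deficient
    collinear_sets = []
    if singular:
        evals, evecs = np.linalg.eigh(R)
        v = np.abs(evecs[:, 0])
        involved_cols = [names[i] for i in np.where(v > 0.1)[0]]
        involved = sorted({c.split("[")[0] for c in involved_cols})
        collinear_sets.append(involved)

    rows = []
    start = 0
    for cov, df_c in groups:
        idx = np.arange(start, start + df_c)
        other = np.setdiff1d(np.arange(len(names)), idx)
        start += df_c
        if singular:
            gvif = np.inf
        else:
            s1, ld1 = np.linalg.slogdet(np.atleast_2d(R[np.ix_(idx, idx)]))
            s2, ld2 = np.linalg.slogdet(np.atleast_2d(R[np.ix_(other, other)]))
            gvif = float(np.exp(ld1 + ld2 - logdet_R)) if s1 > 0 and s2 > 0 else np.inf
        adjusted = gvif ** (1.0 / (2.0 * df_c)) if np.isfinite(gvif) else np.inf
        rows.append({"covariate": cov, "gvif": gvif, "df": df_c,
                     "adjusted": adjusted})
    table = pd.DataFrame(rows).set_index("covariate")
    flagged = list(table.index[table["adjusted"] >= threshold])
    return GVIFReport(table=table, threshold=threshold, flagged=flagged,
                      collinear_sets=collinear_sets)


# ---------------------------------------------------------------------------
@dataclass
class DistrictRiskSummary:
    """Per-district posterior risk summaries keyed by unit id."""

    table: pd.DataFrame  # index: unit id
    cutoff: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    def to_geojson(self, collection, id_property: str = "id"):
        """Join the summary columns onto a GeoJSON FeatureCollection's properties."""
        if isinstance(collection, (str, bytes)):
            with open(collection) as fh:
                collection = json.load(fh)
        out = json.loads(json.dumps(collection))  # deep copy
        for feat in out["features"]:
            uid = (feat.get("properties") or {}).get(id_property)
            if uid in self.table.index:
                rec = self.table.loc[uid]
                feat.setdefault("properties", {}).update(
                    {k: (None if pd.isna(v) else float(v)) if not isinstance(v, (bool, np.bool_)) else bool(v)
                     for k, v in rec.items()}
                )
        return out


def exceedance(results: SpatialLogitResults, cutoff: float = 0.90) -> DistrictRiskSummary:
    """Exceedance probabilities q_j = P(exp(b_j) > 1) = P(b_j > 0) per district.

    Districts with q_j strictly above ``cutoff`` are flagged as having
    significantly elevated residual risk. Requires a fit with CAR effects.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie in (0, 1)")
    b = results.b_draws
    if b is None:
        raise ValueError(
            "exceedance probabilities need spatially structured (CAR) effects; "
            f"this fit has random_structure={results.model.spec.random_structure!r}"
        )
    q = (b > 0).mean(axis=0)
    table = pd.DataFrame({
        "b_mean": b.mean(axis=0),
        "b_sd": b.std(axis=0, ddof=1),
        "q": q,
        "elevated": q > cutoff,
    }, index=pd.Index(results.model.bundle.unit_ids, name="district"))
    return DistrictRiskSummary(table=table, cutoff=cutoff)


def district_risk_map(
    results: SpatialLogitResults,
    bundle: DesignBundle | None = None,
    graph: AdjacencyGraph | None = None,
    cutoff: float = 0.90,
) -> DistrictRiskSummary:
    """Full district risk summary: spatial effect, exceedance, and the average
    and spread (over records) of the per-record posterior predictive means.

    Districts with no records keep their spatial-effect fields but have null
    probability fields.
    """
    summary = exceedance(results, cutoff=cutoff)
    bundle = bundle or results.model.bundle
    pred = results.predict(bundle if bundle is not results.model.bundle else None)
    idx = bundle.district_index
    J = len(summary.table)
    p_mean = np.full(J, np.nan)
    p_sd = np.full(J, np.nan)
    n_rec = np.bincount(idx, minlength=J)
    sums = np.bincount(idx, weights=pred.mean, minlength=J)
    with np.errstate(invalid="ignore"):
        means = np.where(n_rec > 0, sums / np.maximum(n_rec, 1), np.nan)
    sq = np.bincount(idx, weights=pred.mean**2, minlength=J)
    with np.errstate(invalid="ignore"):
        var = np.where(n_rec > 1,
                       (sq - n_rec * means**2) / np.maximum(n_rec - 1, 1), np.nan)
    p_mean[:] = means
    p_sd[:] = np.sqrt(np.maximum(var, 0.0))
    table = summary.table.copy()
    table["n_records"] = n_rec
    table["p_mean"] = p_mean
    table["p_sd"] = p_sd
    return DistrictRiskSummary(table=table, cutoff=cutoff)
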