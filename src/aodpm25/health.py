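"""Population exposure and IER premature-mortality attribution.

Relative risk follows the integrated exposure-response (IER) form

    RR(Cn) = 1                                           for Cn <= Cn_cf
    RR(Cn) = 1 + alpha * (1 - exp(-gamma (Cn - Cn_cf)^delta))  otherwise

with counterfactual concentration Cn_cf = 5.8 ug/m3 by default, below which
no excess risk is attributed.  Attributable deaths use the standard
attributable fraction (RR - 1)/RR:

    dM = BM * (RR - 1)/RR * Pop

evaluated at each of the baseline-mortality CI bounds (lo, mid, hi); RR
uncertainty is deliberately not propagated.  The shipped disease/age
parameters are illustrative placeholders with the right qualitative shape
(risk ceilings falling with age for IHD and stroke), not GBD estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["IERParams", "default_ier_params", "relative_risk", "relative_risk_lookup",
           "attributable_mortality", "population_weighted_pm25", "build_mortality_table",
           "aggregate_burden", "CNCF_DEFAULT"]

CNCF_DEFAULT = 5.8  # ug/m3


@dataclass(frozen=True)
class IERParams:
    """Parameters of one disease (and age group, where age-dependent)."""

    disease: str
    age_group: str      # "all" for age-independent curves
    alpha: float        # excess-risk ceiling (unitless, >= 0)
    gamma: float        # rate, per (ug/m3)^delta (>= 0)
    delta: float        # shape (> 0)
    cncf: float = CNCF_DEFAULT

    def __post_init__(self):
        if self.alpha < 0 or self.gamma < 0 or self.delta <= 0 or self.cncf < 0:
            raise ValueError("require alpha >= 0, gamma >= 0, delta > 0, cncf >= 0")


# Illustrative (synthetic, non-GBD) defaults: IHD and stroke ceilings decline
# with age; COPD and LNC are age-independent.
_AGE_GROUPS = ("25-34", "35-44", "45-54", "55-64", "65-74", "75+")
_IHD_ALPHA = (1.20, 1.00, 0.80, 0.60, 0.45, 0.30)
_STROKE_ALPHA = (1.30, 1.05, 0.80, 0.55, 0.40, 0.25)


def default_ier_params() -> list[IERParams]:
    out = []
    for age, a in zip(_AGE_GROUPS, _IHD_ALPHA):
        out.append(IERParams("IHD", age, a, 0.060, 0.55))
    for age, a in zip(_AGE_GROUPS, _STROKE_ALPHA):
        out.append(IERParams("stroke", age, a, 0.045, 0.60))
    out.append(IERParams("COPD", "all", 0.35, 0.015, 0.75))
    out.append(IERParams("LNC", "all", 0.40, 0.010, 0.80))
    return out


def relative_risk(cn: float, params: IERParams) -> float:
    """Parametric IER relative risk; RR = 1 at and below the counterfactual."""
    cn = float(cn)
    if cn < 0:
        raise ValueError("concentration must be non-negative")
    if cn <= params.cncf:
        return 1.0
    return 1.0 + params.alpha * (1.0 - np.exp(-params.gamma * (cn - params.cncf) ** params.delta))


def relative_risk_lookup(cn: float, table: pd.DataFrame) -> float:
    """RR by linear interpolation in a (cn, rr) lookup table, clamped at ends."""
    if cn < 0:
        raise ValueError("concentration must be non-negative")
    t = table.sort_values("cn")
    return float(np.interp(cn, t["cn"].to_numpy(), t["rr"].to_numpy()))


def lookup_from_params(params: IERParams, cns: np.ndarray) -> pd.DataFrame:
    """Tabulate the parametric curve at given knot concentrations."""
    return pd.DataFrame({"cn": cns, "rr": [relative_risk(c, params) for c in cns]})


def attributable_mortality(rr: float, bm: tuple[float, float, float], pop: float) -> tuple[float, float, float]:
    """dM = BM * (RR-1)/RR * Pop at each baseline-mortality CI bound."""
    if rr < 1.0:
        raise ValueError("RR must be >= 1")
    lo, mid, hi = bm
    if not (0.0 <= lo <= mid <= hi):
        raise ValueError("baseline mortality CI must satisfy 0 <= lo <= mid <= hi")
    if pop < 0:
        raise ValueError("population must be non-negative")
    af = (rr - 1.0) / rr
    return (lo * af * pop, mid * af * pop, hi * af * pop)


def population_weighted_pm25(pm25: np.ndarray, population: np.ndarray,
                             districts: np.ndarray) -> pd.DataFrame:
    """Per-district Cn = sum(pop * pm25) / sum(pop) over the district's cells.

    Zero-population districts fall back to the unweighted mean and are
    flagged.
    """
    pm25 = np.asarray(pm25, dtype=float)
    pop = np.asarray(population, dtype=float)
    if np.any(pop < 0):
        raise ValueError("population must be non-negative")
    rows = []
    for d in np.unique(districts):
        sel = districts == d
        w = pop[sel]
        v = pm25[sel]
        if w.sum() > 0:
            cn = float(np.sum(w * v) / w.sum())
            flag = "ok"
        else:
            cn = float(v.mean())
            flag = "zero-population"
        rows.append({"district": int(d), "cn": cn, "pop": float(w.sum()), "flag": flag})
    return pd.DataFrame(rows)


def build_mortality_table(district_cn: pd.DataFrame, health: pd.DataFrame,
                          params: list[IERParams] | None = None, year: int | None = None,
                          lookup: pd.DataFrame | None = None) -> pd.DataFrame:
    """District x disease x age mortality table (Eq.-by-Eq. assembly).

    ``health`` columns: district, age_group, disease, pop, bm_lo, bm_mid,
    bm_hi.  Parametric mode uses ``params``; lookup mode interpolates the
    (disease, age_group, cn, rr) ``lookup`` table.
    """
    params = params if params is not None else default_ier_params()
    pmap = {(p.disease, p.age_group): p for p in params}
    cn_map = dict(zip(district_cn["district"], district_cn["cn"]))
    rows = []
    for rec in health.itertuples(index=False):
        cn = cn_map[rec.district]
        if lookup is not None:
            sub = lookup[(lookup["disease"] == rec.disease)
                         & (lookup["age_group"].isin([rec.age_group, "all"]))]
            rr = relative_risk_lookup(cn, sub)
        else:
            p = pmap.get((rec.disease, rec.age_group)) or pmap.get((rec.disease, "all"))
            if p is None:
                raise KeyError(f"no IER parameters for {rec.disease}/{rec.age_group}")
            rr = relative_risk(cn, p)
        lo, mid, hi = attributable_mortality(rr, (rec.bm_lo, rec.bm_mid, rec.bm_hi), rec.pop)
        rows.append({"district": rec.district, "disease": rec.disease, "age_group": rec.age_group,
                     "year": year, "cn": cn, "rr": rr, "pop": rec.pop,
                     "bm_lo": rec.bm_lo, "bm_mid": rec.bm_mid, "bm_hi": rec.bm_hi,
                     "dm_lo": lo, "dm_mid": mid, "dm_hi": hi})
    return pd.DataFrame(rows)


def aggregate_burden(mortality: pd.DataFrame, total_override: float | None = None) -> dict:
    """Totals by disease and district, overall total, and disease shares.

    CI totals are sums of the per-row bounds (no independence assumption).
    ``total_override`` replaces the denominator used for the shares, for
    re-deriving published percentages from printed component totals.
    """
    cols = [c for c in ("dm_lo", "dm_mid", "dm_hi") if c in mortality]
    by_disease = mortality.groupby("disease")[cols].sum()
    overall = by_disease.sum()
    denom = total_override if total_override is not None else float(overall["dm_mid"])
    shares = 100.0 * by_disease["dm_mid"] / denom
    out = {"by_disease": by_disease, "overall": overall, "shares_pct": shares}
    if "district" in mortality:
        out["by_district"] = mortality.groupby("district")[cols].sum()
    if total_override is not None:
        out["total_used_for_shares"] = float(total_override)
    return out


def read_ier_csv(path) -> list[IERParams]:
    df = pd.read_csv(Path(path))
    return [IERParams(r.disease, r.age_group, r.alpha, r.gamma, r.delta,
                      getattr(r, "cncf", CNCF_DEFAULT)) for r in df.itertuples(index=False)]
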