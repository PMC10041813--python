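"""Three-step floating catchment area (3-SFCA) spatial accessibility.

The 3-SFCA computes, for every enumeration area (EA) i and transfusing
facility j with travel time T_ij below a catchment threshold T_max:

1. selection weights  G_ij = W_ij / sum_{j': T_ij' <= T_max} W_ij'  with the
   gaussian decay weight W_ij = f(T_ij) = exp(-T_ij^2 / beta) — the
   probability that population i seeks care at j given the alternatives;
2. supply-demand ratios  R_j = S_j / sum_{i: T_ij <= T_max} G_ij P_i W_ij,
   distributing the demand P_i over facilities by selection probability;
3. the spatial accessibility index  SPAI_i = sum_{T_ij <= T_max} G_ij R_j W_ij.

Because each EA's demand is split across facilities by G and weighted by W
consistently in steps 2 and 3, supply is conserved: the population-weighted
SPAI total equals the total supply of facilities with in-catchment demand.

The friction coefficient beta defaults to T_max^2 / ln(100): the decay
weight at the catchment edge is then exactly 0.01, a transparent calibration
of the "edge of reach" that is fully configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DecayParams",
    "decay_weight",
    "selection_weights",
    "supply_demand_ratio",
    "spai",
    "classify_spai",
    "aggregate_subcounty",
    "compare_marginalization",
    "FloatingCatchmentModel",
    "AccessibilityResults",
]

CLASS_LABELS = ("low", "moderate", "high")


@dataclass(frozen=True)
class DecayParams:
    """Gaussian decay parameters: friction beta (minutes^2) and catchment T_max (minutes)."""

    t_max: float = 60.0
    beta: float | None = None

    def __post_init__(self):
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        if self.beta is None:
            object.__setattr__(self, "beta", self.t_max**2 / np.log(100.0))
        if self.beta <= 0:
            raise ValueError("beta must be positive")


def decay_weight(t, params: DecayParams = DecayParams()):
    """Gaussian decay f(t) = exp(-t^2/beta), hard 0 beyond the catchment."""
    t = np.asarray(t, dtype=float)
    if np.any(t[np.isfinite(t)] < 0):
        raise ValueError("travel times must be non-negative")
    w = np.exp(-(t**2) / params.beta)
    w = np.where(np.isfinite(t) & (t <= params.t_max), w, 0.0)
    return w if w.ndim else float(w)


def selection_weights(T: pd.DataFrame, params: DecayParams = DecayParams()) -> pd.DataFrame:
    """Row-normalised selection probabilities G_ij over in-catchment facilities.

    EAs with no facility within T_max get an all-zero row (reported by the
    model as the no-access list rather than NaN).
    """
    W = decay_weight(T.to_numpy(float), params)
    rowsum = W.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        G = np.where(rowsum > 0, W / np.where(rowsum > 0, rowsum, 1.0), 0.0)
    return pd.DataFrame(G, index=T.index, columns=T.columns)


def supply_demand_ratio(
    G: pd.DataFrame, P: pd.Series, W: pd.DataFrame, S: pd.Series
) -> pd.Series:
    """Supply-demand ratio R_j = S_j / sum_i G_ij P_i W_ij.

    Facilities with zero weighted demand in their catchment get NaN
    (flagged undefined, excluded downstream) rather than a division by zero.
    """
    P = P.reindex(G.index)
    S = S.reindex(G.columns)
    if np.any(P.to_numpy(float) < 0):
        raise ValueError("EA populations must be non-negative")
    demand = (G.to_numpy(float) * W.to_numpy(float) * P.to_numpy(float)[:, None]).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(demand > 0, S.to_numpy(float) / np.where(demand > 0, demand, 1.0), np.nan)
    return pd.Series(R, index=G.columns, name="R")


def spai(G: pd.DataFrame, R: pd.Series, W: pd.DataFrame) -> pd.Series:
    """SPAI_i = sum_j G_ij R_j W_ij, skipping facilities with undefined R_j."""
    Rv = R.reindex(G.columns).to_numpy(float)
    Rv = np.where(np.isnan(Rv), 0.0, Rv)
    vals = (G.to_numpy(float) * W.to_numpy(float) * Rv[None, :]).sum(axis=1)
    return pd.Series(vals, index=G.index, name="spai")


def classify_spai(
    values: pd.Series,
    mode: str = "fixed",
    thresholds: tuple[float, float] = (0.5, 1.5),
) -> pd.Series:
    """Assign low / moderate / high accessibility classes.

    ``fixed`` mode uses the printed boundaries: SPAI <= 0.5 low,
    0.5 < SPAI <= 1.5 moderate, SPAI > 1.5 high. ``quantile`` mode collapses
    empirical quintiles to three classes by splitting at the 40th and 80th
    percentiles (bottom two quintiles low, middle two moderate, top high).
    """
    values = pd.Series(values)
    if values.empty:
        raise ValueError("no SPAI values to classify")
    if mode == "fixed":
        lo, hi = thresholds
    elif mode == "quantile":
        lo, hi = np.quantile(values.to_numpy(float), [0.4, 0.8])
        if lo == hi:
            warnings.warn("constant SPAI values: quantile classes collapse to 'moderate'")
            return pd.Series("moderate", index=values.index, name="class")
    else:
        raise ValueError(f"unknown classification mode {mode!r}")
    out = np.where(values <= lo, "low", np.where(values <= hi, "moderate", "high"))
    return pd.Series(out, index=values.index, name="class")


def aggregate_subcounty(
    spai_values: pd.Series,
    classes: pd.Series,
    subcounty_of_ea: pd.Series,
    populations: pd.Series,
) -> pd.DataFrame:
    """Mean SPAI and persons / % per accessibility class, per sub-county.

    Adds a county total row; per-row class percentages sum to 100 (rows with
    population) and the county persons equal the summed EA populations.
    """
    idx = spai_values.index
    missing = idx.difference(subcounty_of_ea.index)
    if len(missing):
        raise ValueError(f"EA(s) with no sub-county: {list(missing)[:5]}")
    sub = subcounty_of_ea.reindex(idx)
    pop = populations.reindex(idx).fillna(0.0)

    frames = []
    for sc, sel in idx.groupby(sub).items():
        p = pop.loc[sel]
        row = {"subcounty": sc, "mean_spai": float(spai_values.loc[sel].mean()), "persons": float(p.sum())}
        for lab in CLASS_LABELS:
            persons = float(p[classes.loc[sel] == lab].sum())
            row[f"persons_{lab}"] = persons
        frames.append(row)
    table = pd.DataFrame(frames).set_index("subcounty").sort_index()
    county = {
        "mean_spai": float(spai_values.mean()),
        "persons": float(pop.sum()),
        **{f"persons_{lab}": float(table[f"persons_{lab}"].sum()) for lab in CLASS_LABELS},
    }
    table.loc["county"] = county
    for lab in CLASS_LABELS:
        with np.errstate(invalid="ignore", divide="ignore"):
            table[f"pct_{lab}"] = np.where(
                table["persons"] > 0, 100.0 * table[f"persons_{lab}"] / table["persons"], 0.0
            )
    return table


def compare_marginalization(
    travel_time_marginalized: pd.Series, spai_low: pd.Series
) -> pd.DataFrame:
    """Compare the two marginalised-population definitions per sub-county.

    ``travel_time_marginalized`` holds persons beyond the 1-h catchment and
    ``spai_low`` persons in low-SPAI EAs. Reports both counts, their
    difference and their ratio (low-SPAI over travel-time, inf when only the
    SPAI definition flags anyone), with a county-wide row.
    """
    idx = travel_time_marginalized.index.union(spai_low.index)
    tt = travel_time_marginalized.reindex(idx).fillna(0.0)
    sp = spai_low.reindex(idx).fillna(0.0)
    out = pd.DataFrame({"travel_time_marginalized": tt, "spai_low": sp})
    out.loc["county"] = out.sum()
    out["difference"] = out["spai_low"] - out["travel_time_marginalized"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["ratio"] = np.where(
            out["travel_time_marginalized"] > 0,
            out["spai_low"] / out["travel_time_marginalized"],
            np.where(out["spai_low"] > 0, np.inf, np.nan),
        )
    return out


class FloatingCatchmentModel:
    """3-SFCA accessibility model for one county.

    Parameters
    ----------
    travel_time : DataFrame
        Minutes T_ij, EAs on the index, transfusing facilities on the
        columns; +inf marks unreachable pairs.
    population : Series
        Demand P_i per EA (persons), aligned with the matrix index.
    supply : Series
        Capacity S_j per facility (the analysis uses total inpatient
        admissions over the reporting window).
    decay : DecayParams
        Catchment threshold and gaussian friction coefficient.
    """

    def __init__(
        self,
        travel_time: pd.DataFrame,
        population: pd.Series,
        supply: pd.Series,
        decay: DecayParams = DecayParams(),
    ):
        self.travel_time = travel_time
        self.population = pd.Series(population).reindex(travel_time.index)
        self.supply = pd.Series(supply).reindex(travel_time.columns)
        if self.population.isna().any():
            raise ValueError("population missing for some EAs")
        if self.supply.isna().any():
            raise ValueError("supply missing for some facilities")
        self.decay = decay

    def fit(
        self, class_mode: str = "fixed", thresholds: tuple[float, float] = (0.5, 1.5)
    ) -> "AccessibilityResults":
        W = pd.DataFrame(
            decay_weight(self.travel_time.to_numpy(float), self.decay),
            index=self.travel_time.index,
            columns=self.travel_time.columns,
        )
        G = selection_weights(self.travel_time, self.decay)
        R = supply_demand_ratio(G, self.population, W, self.supply)
        values = spai(G, R, W)
        classes = classify_spai(values, mode=class_mode, thresholds=thresholds)
        return AccessibilityResults(
            model=self, W=W, G=G, R=R, spai=values, classes=classes,
            class_mode=class_mode, thresholds=thresholds,
        )


@dataclass
class AccessibilityResults:
    """Fitted 3-SFCA surfaces: intermediates, SPAI and class labels."""

    model: FloatingCatchmentModel
    W: pd.DataFrame
    G: pd.DataFrame
    R: pd.Series
    spai: pd.Series
    classes: pd.Series
    class_mode: str
    thresholds: tuple[float, float]

    @property
    def no_access(self) -> list:
        """EAs with no facility within the catchment threshold."""
        return list(self.G.index[(self.G.to_numpy() == 0).all(axis=1)])

    @property
    def undefined_supply(self) -> list:
        """Facilities with no weighted demand in catchment (R undefined)."""
        return list(self.R.index[self.R.isna()])

    def conservation_gap(self) -> float:
        """Relative gap between population-weighted SPAI and total supply."""
        lhs = float((self.model.population * self.spai).sum())
        rhs = float(self.model.supply[self.R.notna()].sum())
        return abs(lhs - rhs) / rhs if rhs else abs(lhs)

    def aggregate(self, subcounty_of_ea: pd.Series) -> pd.DataFrame:
        return aggregate_subcounty(
            self.spai, self.classes, subcounty_of_ea, self.model.population
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"spai": self.spai, "class": self.classes})

    def summary(self) -> str:
        counts = self.classes.value_counts().reindex(CLASS_LABELS, fill_value=0)
        lines = [
            "3-SFCA spatial accessibility",
            "=" * 42,
            f"EAs: {len(self.spai):>6d}    facilities: {len(self.R)}",
            f"T_max: {self.model.decay.t_max:.0f} min    beta: {self.model.decay.beta:.2f} min^2",
            f"SPAI range: {self.spai.min():.3f} - {self.spai.max():.3f}",
            f"classification ({self.class_mode}, thresholds {self.thresholds}):",
        ]
        for lab in CLASS_LABELS:
            lines.append(f"  {lab:<9s} {counts[lab]:>6d} EAs")
        if self.no_access:
            lines.append(f"no-access EAs: {len(self.no_access)}")
        if self.undefined_supply:
            lines.append(f"facilities with undefined R: {len(self.undefined_supply)}")
        lines.append(f"supply conservation gap: {self.conservation_gap():.2e}")
        return "\n".join(lines)
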