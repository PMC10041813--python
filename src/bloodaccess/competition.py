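"""Spatial competition between transfusing hospitals.

Each transfusing hospital i is characterised within its 1-hour travel-time
catchment by n_i, the number of low-level (level-3/4 but non-transfusing)
facilities it serves through referrals, and k_i, the number of alternative
transfusing hospitals competing with it. With the bed-share weight
W_i = beds_i / sum(beds), the Spatial Competition Index is

    SCI_i = (1/n_i) * sum_{l=1..n_i} (1/k) * W_i

In its printed form the summand does not vary with l, so the default
('collapsed') evaluation is SCI_i = W_i / max(k_i, 1), the monopoly case
k_i = 0 using divisor 1 by convention. A documented variant ('per_low_level')
evaluates k per low-level facility l — k_l = number of transfusing hospitals
within the threshold of l — which is the only reading under which the 1/n_i
average is meaningful; neither reading is asserted as canonical.

Level-2 facilities (dispensaries, not expected to provide emergency care)
are excluded throughout. Market share is each hospital's percentage of the
county blood-service volume under a configurable basis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "catchment_membership",
    "bed_weight",
    "sci",
    "market_share",
    "SpatialCompetitionModel",
    "CompetitionResults",
]


def catchment_membership(
    fac_tt: pd.DataFrame, facilities: pd.DataFrame, threshold: float = 60.0
) -> pd.DataFrame:
    """Counts (n_i, k_i) inside each transfusing facility's catchment.

    ``fac_tt`` holds travel times in minutes from every level-3/4 facility
    (rows) to every transfusing facility (columns, whose travel-time surface
    defines the catchment). A facility is a member when its time is within
    ``threshold``; the transfusing facility itself is excluded from k_i, and
    level-2 facilities must already be absent from the rows.
    """
    fac = facilities.set_index("id") if "id" in facilities else facilities
    if (fac.loc[fac_tt.index, "level"] < 3).any():
        raise ValueError("level-2 facilities must be excluded from catchment membership")
    transfusing = fac.loc[fac_tt.index, "transfusing"].astype(bool)
    inside = fac_tt.to_numpy(float) <= threshold
    rows = []
    for j, tj in enumerate(fac_tt.columns):
        members = fac_tt.index[inside[:, j]]
        k = int(transfusing.loc[members].sum()) - int(tj in members)
        n = int((~transfusing.loc[members]).sum())
        rows.append({"facility": tj, "n_low_level": n, "k_competing": k})
    return pd.DataFrame(rows).set_index("facility")


def bed_weight(beds: pd.Series) -> pd.Series:
    """Bed-share weights W_i = beds_i / total beds (sums to 1)."""
    beds = pd.Series(beds, dtype=float)
    total = beds.sum()
    if total <= 0:
        raise ValueError("total beds must be positive")
    if (beds < 0).any():
        raise ValueError("bed counts must be non-negative")
    return beds / total


def sci(
    n: pd.Series,
    k: pd.Series,
    W: pd.Series,
    variant: str = "collapsed",
    k_per_low_level: pd.DataFrame | None = None,
) -> pd.Series:
    """Spatial Competition Index per transfusing facility.

    ``collapsed``: SCI_i = W_i / max(k_i, 1) (constant summand cancels the
    1/n_i average; monopoly k_i = 0 uses divisor 1). ``per_low_level``:
    SCI_i = (1/n_i) * sum_l W_i / k_l with k_l the number of transfusing
    facilities reaching low-level facility l, supplied via
    ``k_per_low_level`` (rows: low-level facility, columns: facility i,
    NaN when l is outside i's catchment).
    """
    n = pd.Series(n).astype(int)
    k = pd.Series(k).astype(int)
    if (n < 0).any() or (k < 0).any():
        raise ValueError("catchment counts must be non-negative")
    if (n == 0).any():
        warnings.warn("facility with no low-level facilities in catchment (n=0)")
    if variant == "collapsed":
        return W / np.maximum(k, 1)
    if variant == "per_low_level":
        if k_per_low_level is None:
            raise ValueError("per_low_level variant needs the k_per_low_level matrix")
        out = {}
        for i in n.index:
            kl = k_per_low_level[i].dropna()
            out[i] = float((W[i] / np.maximum(kl, 1)).mean()) if len(kl) else W[i]
        return pd.Series(out, name="sci")
    raise ValueError(f"unknown SCI variant {variant!r}")


def market_share(units: pd.Series, basis: str = "transfused") -> pd.Series:
    """Percent share of county blood-service volume per facility.

    ``units`` may be a Series (single basis) or a DataFrame with
    ``units_received`` / ``units_transfused`` columns from which the basis
    ('received', 'transfused' or 'received+transfused') is assembled.
    """
    if isinstance(units, pd.DataFrame):
        if basis == "received":
            units = units["units_received"]
        elif basis == "transfused":
            units = units["units_transfused"]
        elif basis == "received+transfused":
            units = units["units_received"] + units["units_transfused"]
        else:
            raise ValueError(f"unknown market share basis {basis!r}")
    units = pd.Series(units, dtype=float)
    total = units.sum()
    if total <= 0:
        raise ValueError("total units must be positive")
    return 100.0 * units / total


class SpatialCompetitionModel:
    """Catchment-based competition model over the transfusing hospitals.

    Parameters
    ----------
    facilities : DataFrame
        Register with id, level, transfusing flag, beds and blood-unit
        columns; level-2 rows are dropped on entry.
    fac_tt : DataFrame
        Travel-time matrix (minutes) from each level-3/4 facility to each
        transfusing facility's surface, as produced by
        :func:`bloodaccess.traveltime.od_matrix` with facility locations as
        the "demand" points.
    threshold : float
        Catchment limit in minutes (1 h for emergency transfusion).
    """

    def __init__(
        self,
        facilities: pd.DataFrame,
        fac_tt: pd.DataFrame,
        threshold: float = 60.0,
        variant: str = "collapsed",
        share_basis: str = "transfused",
    ):
        fac = facilities.set_index("id") if "id" in facilities else facilities.copy()
        self.facilities = fac[fac["level"] >= 3]
        self.fac_tt = fac_tt.loc[fac_tt.index.intersection(self.facilities.index)]
        self.threshold = threshold
        self.variant = variant
        self.share_basis = share_basis

    def fit(self) -> "CompetitionResults":
        members = catchment_membership(self.fac_tt, self.facilities, self.threshold)
        trans = self.facilities[self.facilities["transfusing"].astype(bool)]
        W = bed_weight(trans["beds"]).reindex(members.index)
        k_ll = None
        if self.variant == "per_low_level":
            k_ll = self._k_per_low_level()
        sci_vals = sci(
            members["n_low_level"], members["k_competing"], W,
            variant=self.variant, k_per_low_level=k_ll,
        )
        shares = market_share(
            trans[["units_received", "units_transfused"]].reindex(members.index),
            basis=self.share_basis,
        )
        table = pd.DataFrame(
            {
                "beds": trans["beds"].reindex(members.index),
                "k_competing": members["k_competing"],
                "n_low_level": members["n_low_level"],
                "units_received": trans["units_received"].reindex(members.index),
                "units_transfused": trans["units_transfused"].reindex(members.index),
                "bed_weight": W,
                "market_share_pct": shares,
                "sci": sci_vals,
            }
        )
        return CompetitionResults(model=self, table=table)

    def _k_per_low_level(self) -> pd.DataFrame:
        """k_l per (low-level facility, transfusing facility) pair."""
        trans_flag = self.facilities.loc[self.fac_tt.index, "transfusing"].astype(bool)
        low = self.fac_tt.index[~trans_flag]
        inside = self.fac_tt.loc[low] <= self.threshold
        # k_l: transfusing facilities whose catchment contains l
        k_l = inside.sum(axis=1)
        out = pd.DataFrame(np.nan, index=low, columns=self.fac_tt.columns)
        for j in self.fac_tt.columns:
            sel = inside[j]
            out.loc[sel, j] = k_l[sel]
        return out


@dataclass
class CompetitionResults:
    """Per-hospital catchment composition, SCI and market share."""

    model: SpatialCompetitionModel
    table: pd.DataFrame

    @property
    def sci(self) -> pd.Series:
        return self.table["sci"]

    def summary(self) -> str:
        t = self.table.sort_values("sci", ascending=False)
        lines = [
            "Spatial competition between transfusing hospitals",
            "=" * 58,
            f"threshold: {self.model.threshold:.0f} min   variant: {self.model.variant}"
            f"   share basis: {self.model.share_basis}",
            f"{'facility':<14s} {'beds':>5s} {'k':>3s} {'n':>3s} {'share%':>7s} {'SCI':>7s}",
        ]
        for fid, row in t.iterrows():
            lines.append(
                f"{str(fid):<14s} {row['beds']:>5.0f} {row['k_competing']:>3.0f} "
                f"{row['n_low_level']:>3.0f} {row['market_share_pct']:>7.2f} {row['sci']:>7.3f}"
            )
        lines.append(
            f"sum of bed weights: {self.table['bed_weight'].sum():.6f}; "
            f"sum of market shares: {self.table['market_share_pct'].sum():.4f}"
        )
        return "\n".join(lines)
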