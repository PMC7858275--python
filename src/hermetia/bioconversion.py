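"""Larval growth and substrate-degradation indices from per-box mass budgets.

The seven classical feeding-trial indices are computed on a dry-matter basis
(growth rate on fresh mass, per larva):

* ``GR = (L_end - L_initial) / T``            growth rate, mg d-1
* ``SR = (I - R_residue) / I * 100``          substrate reduction, %
* ``CI = E / (T * A)``                        consumption index
* ``WRI = D / T * 100`` with ``D = (I - R_residue)/I``   waste reduction index
* ``AD = (E - R_egesta) / E * 100``           approximate digestibility, %
* ``ECI = B / E * 100``                       efficiency of conversion of ingested food, %
* ``ECD = B / (E - R_egesta) * 100``          efficiency of conversion of digested food, %

The symbol ``R`` is used for two different quantities in this family of
formulas: the *total* post-process residue (uneaten feed plus egesta) in SR
and WRI, and the *egesta* alone in AD and ECD.  :class:`MassBudget` therefore
carries both fields and each formula is bound to its own residue.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MassBudget",
    "BioconversionIndices",
    "EndpointSummary",
    "schedule_feedings",
    "build_mass_budget",
    "compute_indices",
    "endpoint_summary",
    "compare_groups",
    "GroupComparison",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MassBudget:
    """Per-box dry-mass accounting feeding all downstream indices.

    Masses in mg; ``T_days`` is the duration from diet introduction to the
    diet's termination day.  ``A_mean_biomass`` is the time-averaged live dry
    biomass of the box (trapezoidal over the observation days, the classical
    "mean weight during the feeding period").
    """

    I_offered_dry: float
    R_residue_dry: float
    E_ingested_dry: float
    R_egesta_dry: float
    B_gain_dry: float
    A_mean_biomass: float
    T_days: float
    L_initial_fresh: float
    L_end_fresh: float

    def __post_init__(self) -> None:
        for name in ("I_offered_dry", "R_residue_dry", "E_ingested_dry",
                     "R_egesta_dry", "A_mean_biomass"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.T_days <= 0:
            raise ValueError("T_days must be positive")
        if self.E_ingested_dry > self.I_offered_dry * (1 + 1e-9):
            raise ValueError("ingested mass exceeds offered mass")
        if self.R_egesta_dry > self.E_ingested_dry * (1 + 1e-9):
            raise ValueError("egesta exceeds ingested mass")

    @property
    def D_fraction(self) -> float:
        """Degraded fraction (I - R_residue) / I, the D of the waste reduction index."""
        if self.I_offered_dry == 0:
            return math.nan
        return (self.I_offered_dry - self.R_residue_dry) / self.I_offered_dry


@dataclass
class BioconversionIndices:
    """The seven Table-style indices; degenerate divisions are flagged, not raised."""

    GR: float
    SR: float
    CI: float
    WRI: float
    AD: float
    ECI: float
    ECD: float
    flags: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ("GR", "SR", "CI", "WRI", "AD", "ECI", "ECD")}


@dataclass
class EndpointSummary:
    """Per-diet endpoint biomass characterization (means +/- sd over boxes)."""

    table: pd.DataFrame  # index: diet; columns: <quantity>_mean, <quantity>_sd


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def schedule_feedings(start_day: int, end_day: int, interval_days: int) -> list[int]:
    """Feeding days ``start, start+interval, ... <= end``.

    A d0-to-d18 trial fed every second day yields ten feeding events.
    """
    if interval_days < 1:
        raise ValueError("interval_days must be >= 1")
    if end_day < start_day:
        raise ValueError("end_day must be >= start_day")
    return list(range(start_day, end_day + 1, interval_days))


def build_mass_budget(
    observations: pd.DataFrame,
    feeding_log: pd.DataFrame,
    residue_table: pd.DataFrame,
    box: str,
    *,
    end_day: int | None = None,
) -> MassBudget:
    """Assemble a per-box :class:`MassBudget` from trial tables.

    Parameters
    ----------
    observations
        Per-box rows with columns ``box, day, n_alive, n_pupae,
        mean_fresh_mg, mean_dry_mg`` (per-larva means).
    feeding_log
        Rows ``box, day, offered_fresh_mg, dry_frac`` — substrate offered per
        feeding event on a fresh basis with its dry-matter fraction.
    residue_table
        One row per box at the end day with ``residue_dry_mg`` (total
        residue: uneaten + egesta) and, when measured separately,
        ``egesta_dry_mg`` and ``uneaten_dry_mg``.  When egesta is absent,
        ingested mass is estimated as offered minus uneaten and egesta as
        residue minus uneaten; this convention is the best a mass balance can
        do without marker studies and is reported as a flag downstream.

    Notes
    -----
    ``A`` is the trapezoidal time-average of live dry biomass (alive larvae x
    per-larva dry mass) over ``[0, T]``; ``B`` is end dry biomass (live +
    pupated, at their end-day per-larva mass) minus initial dry biomass.
    """
    obs = observations.loc[observations["box"] == box].sort_values("day")
    if len(obs) < 2:
        raise ValueError(f"box {box!r}: need at least two observation days")
    feed = feeding_log.loc[feeding_log["box"] == box]
    res = residue_table.loc[residue_table["box"] == box]
    if res.empty:
        raise ValueError(f"box {box!r}: missing residue row")
    res = res.iloc[0]

    T = float(end_day if end_day is not None else obs["day"].max())
    if T <= 0:
        raise ValueError("zero trial duration")
    obs = obs.loc[obs["day"] <= T]

    I_offered = float((feed["offered_fresh_mg"] * feed["dry_frac"]).sum())
    R_residue = float(res["residue_dry_mg"])

    if "egesta_dry_mg" in res.index and not pd.isna(res["egesta_dry_mg"]):
        egesta = float(res["egesta_dry_mg"])
        uneaten = float(res.get("uneaten_dry_mg", R_residue - egesta))
        E_ingested = I_offered - uneaten
    else:
        uneaten = float(res.get("uneaten_dry_mg", 0.0))
        E_ingested = I_offered - uneaten
        egesta = max(R_residue - uneaten, 0.0)

    days = obs["day"].to_numpy(dtype=float)
    live_dry = (obs["n_alive"].to_numpy(dtype=float)
                * obs["mean_dry_mg"].to_numpy(dtype=float))
    if len(days) > 1:
        A = float(np.trapezoid(live_dry, days) / (days[-1] - days[0]))
    else:
        A = float(live_dry[0])

    first, last = obs.iloc[0], obs.iloc[-1]
    n0 = float(first["n_alive"]) + float(first.get("n_pupae", 0) or 0)
    initial_dry = n0 * float(first["mean_dry_mg"])
    pupae_dry_col = last.get("pupae_total_dry_mg")
    if pupae_dry_col is not None and not pd.isna(pupae_dry_col):
        pupated_dry = float(pupae_dry_col)
    else:
        pupated_dry = float(last.get("n_pupae", 0) or 0) * float(last["mean_dry_mg"])
    end_dry = float(last["n_alive"]) * float(last["mean_dry_mg"]) + pupated_dry
    B_gain = end_dry - initial_dry

    return MassBudget(
        I_offered_dry=I_offered,
        R_residue_dry=R_residue,
        E_ingested_dry=max(E_ingested, 0.0),
        R_egesta_dry=egesta,
        B_gain_dry=B_gain,
        A_mean_biomass=A,
        T_days=T,
        L_initial_fresh=float(first["mean_fresh_mg"]),
        L_end_fresh=float(last["mean_fresh_mg"]),
    )


def compute_indices(budget: MassBudget) -> BioconversionIndices:
    """Evaluate the seven indices on a budget; division-by-zero is flagged."""
    flags: dict[str, str] = {}

    def safe(num: float, den: float, name: str) -> float:
        if den == 0:
            flags[name] = "undefined: zero denominator"
            return math.nan
        return num / den

    I, Rr = budget.I_offered_dry, budget.R_residue_dry
    E, Re = budget.E_ingested_dry, budget.R_egesta_dry
    B, A, T = budget.B_gain_dry, budget.A_mean_biomass, budget.T_days

    GR = (budget.L_end_fresh - budget.L_initial_fresh) / T
    SR = safe(I - Rr, I, "SR") * 100
    CI = safe(E, T * A, "CI")
    D = safe(I - Rr, I, "WRI")
    WRI = D / T * 100
    AD = safe(E - Re, E, "AD") * 100
    ECI = safe(B, E, "ECI") * 100
    ECD = safe(B, E - Re, "ECD") * 100
    return BioconversionIndices(GR=GR, SR=SR, CI=CI, WRI=WRI, AD=AD,
                                ECI=ECI, ECD=ECD, flags=flags)


def endpoint_summary(observations: pd.DataFrame,
                     pupae_table: pd.DataFrame | None = None,
                     *,
                     end_day_per_diet: dict[str, int] | None = None) -> EndpointSummary:
    """Per-diet endpoint means +/- sd over boxes of larval (and pupal) biomass.

    Quantities per larva in g: fresh weight, dry weight, water content
    (fresh - dry), volatile solids; plus mortality %, developmental time and
    pupation rate.  Dry mass exceeding fresh mass is physically impossible
    and rejected.
    """
    if (observations["mean_dry_mg"] > observations["mean_fresh_mg"] + 1e-9).any():
        raise ValueError("dry mass exceeds fresh mass in observations")

    rows = {}
    for diet, sub in observations.groupby("diet"):
        end = (end_day_per_diet or {}).get(diet, sub["day"].max())
        endpoint = sub.loc[sub["day"] == end]
        per_box = endpoint.set_index("box")
        fresh = per_box["mean_fresh_mg"] / 1000.0
        dry = per_box["mean_dry_mg"] / 1000.0
        vs = per_box["mean_vs_mg"] / 1000.0 if "mean_vs_mg" in per_box else dry * np.nan
        start = sub.loc[sub["day"] == sub["day"].min()].set_index("box")
        n0 = start["n_alive"] + start.get("n_pupae", 0)
        mortality = (1 - (per_box["n_alive"] + per_box["n_pupae"]) / n0) * 100
        pupation = per_box["n_pupae"] / n0 * 100

        def ms(series: pd.Series) -> tuple[float, float]:
            vals = series.dropna()
            sd = float(vals.std(ddof=1)) if len(vals) >= 2 else math.nan
            return float(vals.mean()), sd

        row = {}
        for name, series in (("fresh_g", fresh), ("dry_g", dry),
                             ("water_g", fresh - dry), ("vs_g", vs),
                             ("mortality_pct", mortality),
                             ("pupation_rate_pct", pupation)):
            row[f"{name}_mean"], row[f"{name}_sd"] = ms(series)
        if pupae_table is not None and not pupae_table.loc[pupae_table["diet"] == diet].empty:
            pup = pupae_table.loc[pupae_table["diet"] == diet]
            row["pupa_fresh_g_mean"], row["pupa_fresh_g_sd"] = ms(pup["mean_fresh_mg"] / 1000.0)
            row["pupa_dry_g_mean"], row["pupa_dry_g_sd"] = ms(pup["mean_dry_mg"] / 1000.0)
            if "first_pupation_day" in pup:
                row["dev_time_days_mean"], row["dev_time_days_sd"] = ms(pup["first_pupation_day"])
        rows[diet] = row
    return EndpointSummary(table=pd.DataFrame.from_dict(rows, orient="index"))


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    method: str
    statistic: float
    p_value: float
    flags: dict[str, str] = field(default_factory=dict)
    pairwise: pd.DataFrame | None = None
    letters: dict[str, str] | None = None


def _tukey_letters(groups: list[str], sig_pairs: set[frozenset[str]]) -> dict[str, str]:
    """Compact letter display: groups sharing a letter are not significantly different.

    Insert-and-absorb: start with one letter set containing all groups, split
    on each significant pair, drop subsets, then assign letters in order.
    """
    sets: list[set[str]] = [set(groups)]
    for pair in sig_pairs:
        a, b = tuple(pair)
        new_sets = []
        for s in sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        # absorb subsets
        sets = [s for s in new_sets
                if not any(s < t for t in new_sets)]
        # dedupe
        uniq: list[set[str]] = []
        for s in sets:
            if s not in uniq:
                uniq.append(s)
        sets = uniq
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for letter, s in zip(alphabet, sorted(sets, key=lambda s: sorted(s))):
        for g in s:
            letters[g] += letter
    return letters


def compare_groups(values_by_group: dict[str, "np.ndarray | list[float]"],
                   method: str = "anova",
                   alpha: float = 0.05) -> GroupComparison:
    """One-way comparison of per-diet values.

    ``method`` is one of ``anova``, ``pairwise_t_bonferroni``, ``tukey_hsd``
    or ``bartlett``.  Constant data across all groups yields F = 0 and p = 1
    with a flag rather than an exception.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    names = list(groups)
    arrays = [groups[n] for n in names]
    flags: dict[str, str] = {}

    all_vals = np.concatenate(arrays)
    if np.ptp(all_vals) == 0:
        flags["constant"] = "all values identical; F undefined, reported as 0"
        if method in ("anova", "bartlett"):
            return GroupComparison(method, 0.0, 1.0, flags)

    if method == "anova":
        if any(len(a) < 2 for a in arrays):
            raise ValueError("anova requires >= 2 values per group")
        stat, p = stats.f_oneway(*arrays)
        return GroupComparison(method, float(stat), float(p), flags)

    if method == "bartlett":
        stat, p = stats.bartlett(*arrays)
        return GroupComparison(method, float(stat), float(p), flags)

    if method == "pairwise_t_bonferroni":
        rows = []
        pairs = list(itertools.combinations(names, 2))
        for a, b in pairs:
            if np.ptp(np.concatenate([groups[a], groups[b]])) == 0:
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(groups[a], groups[b])
            rows.append({"group1": a, "group2": b, "t": float(t),
                         "p_raw": float(p),
                         "p_adj": min(float(p) * len(pairs), 1.0)})
        table = pd.DataFrame(rows)
        best = table.loc[table["p_adj"].idxmin()]
        return GroupComparison(method, float(best["t"]), float(best["p_adj"]),
                               flags, pairwise=table)

    if method == "tukey_hsd":
        if any(len(a) < 2 for a in arrays):
            raise ValueError("tukey_hsd requires >= 2 values per group")
        if np.ptp(all_vals) == 0:
            letters = {n: "a" for n in names}
            return GroupComparison(method, 0.0, 1.0, flags, letters=letters)
        res = stats.tukey_hsd(*arrays)
        rows, sig_pairs = [], set()
        for i, j in itertools.combinations(range(len(names)), 2):
            p = float(res.pvalue[i, j])
            rows.append({"group1": names[i], "group2": names[j],
                         "statistic": float(res.statistic[i, j]), "p_adj": p})
            if p < alpha:
                sig_pairs.add(frozenset((names[i], names[j])))
        table = pd.DataFrame(rows)
        letters = _tukey_letters(names, sig_pairs)
        best = table.loc[table["p_adj"].idxmin()]
        return GroupComparison(method, float(best["statistic"]), float(best["p_adj"]),
                               flags, pairwise=table, letters=letters)

    raise ValueError(f"unknown method {method!r}")
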