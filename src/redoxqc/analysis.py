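"""Distribution summaries and carrier-compatibility analysis.

Answers the downstream biology questions: how the per-category potential
distributions compare (Welch's unequal-variance t-test between structural
subgroups), and which couples a physiological electron carrier — NAD(P) by
default — can run reversibly, given that metabolite concentrations can
offset a couple's effective potential by RT·ln(span)/(nF) around E'^m.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .thermo import CONSTANTS, PhysicalConstants, reversibility_window

__all__ = [
    "CarrierProfile",
    "NADP_PROFILE",
    "welch_t_test",
    "category_summary",
    "classify_vs_carrier",
    "subgroup_comparison",
    "round_to_5mv",
]


@dataclass(frozen=True)
class CarrierProfile:
    """Physiological potential range of an electron carrier.

    ``e_low``/``e_high`` bound the carrier's in-vivo potential (V), set by
    its standard potential and the physiological span of its reduced/
    oxidized concentration ratio; ``concentration_span`` is the fold-range
    of *metabolite* concentrations used when widening to the reversibility
    window.
    """

    name: str
    e_low: float
    e_high: float
    concentration_span: float = 1e4

    def __post_init__(self) -> None:
        if self.e_low > self.e_high:
            raise ValueError(f"{self.name}: e_low must not exceed e_high")
        if self.concentration_span < 1:
            raise ValueError(f"{self.name}: concentration_span must be >= 1")


#: NAD(P) in vivo: standard potential ~ -330 mV (pH 7, I 0.25 M) with
#: [NADPH]/[NADP] up to ~50 and [NADH]/[NAD] down to ~1/500, giving a
#: physiological range of -380 to -250 mV; metabolites span ~1 uM - 10 mM.
NADP_PROFILE = CarrierProfile("NAD(P)", e_low=-0.380, e_high=-0.250,
                              concentration_span=1e4)


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> dict[str, float]:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df.

    Both groups need >= 2 values; at least one group must have nonzero
    variance.  Returns the t statistic, effective degrees of freedom and the
    two-sided p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return {"t": 0.0, "df": float(a.size + b.size - 2), "p": 1.0}
        raise ValueError("both groups are constant; Welch test undefined")
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return {"t": float(t), "df": float(df), "p": float(p)}


def round_to_5mv(potential_v: float) -> float:
    """Display rounding of a potential to the nearest multiple of 5 mV (in mV)."""
    return 5.0 * round(potential_v * 1000.0 / 5.0)


def category_summary(
    potentials: Sequence[float],
) -> dict[str, float]:
    """Mean/median/n of a category's potentials, in mV.

    ``rounded_mean`` applies the nearest-5-mV display convention; all other
    entries are unrounded.
    """
    e = np.asarray(potentials, dtype=float)
    if e.size == 0:
        raise ValueError("category has no potential estimates")
    mean_v = float(e.mean())
    return {
        "mean_mv": mean_v * 1000.0,
        "median_mv": float(np.median(e)) * 1000.0,
        "n": int(e.size),
        "rounded_mean_mv": round_to_5mv(mean_v),
    }


def classify_vs_carrier(
    e_prime_m: float,
    carrier: CarrierProfile = NADP_PROFILE,
    n_electrons: int = 2,
    temperature: float = 298.15,
    constants: PhysicalConstants = CONSTANTS,
) -> str:
    """How a couple relates to a carrier: reversible or one-directional.

    Inside the carrier's reversibility window (closed interval) the carrier
    can drive the couple both ways.  Below the window the couple's potential
    is too low for the carrier to reduce it — the carrier can only oxidize
    the couple's reduced form ("oxidation_only", e.g. carbonyl -> acid for
    low-lying acid couples).  Above the window the reduced carrier can only
    reduce it ("reduction_only", e.g. hydroxycarbon -> hydrocarbon).
    """
    e_min, e_max = reversibility_window(
        carrier.e_low,
        carrier.e_high,
        carrier.concentration_span,
        n_electrons,
        temperature,
        constants=constants,
    )
    if e_prime_m < e_min:
        return "oxidation_only"
    if e_prime_m > e_max:
        return "reduction_only"
    return "reversible"


def subgroup_comparison(
    potentials: Mapping[str, float],
    labels: Mapping[str, str],
    correction: str | None = None,
) -> pd.DataFrame:
    """Pairwise subgroup mean differences with Welch p-values.

    ``potentials`` maps pair id -> E'^m (V); ``labels`` maps the same ids to
    a subgroup label along one axis (e.g. aldehyde/ketone).  Every estimate
    must be labelled.  Returns one row per unordered label pair with the
    mean difference in mV (group_a minus group_b) and the Welch two-sided
    p-value; ``correction="bh"`` optionally adds Benjamini-Hochberg adjusted
    p-values (raw p-values are the default reporting convention here).
    """
    missing = sorted(set(potentials) - set(labels))
    if missing:
        raise ValueError(f"unlabelled estimates: {', '.join(missing)}")
    groups: dict[str, list[float]] = {}
    for pid, e in potentials.items():
        groups.setdefault(labels[pid], []).append(e)
    names = sorted(groups)
    rows = []
    for i, ga in enumerate(names):
        for gb in names[i + 1 :]:
            res = welch_t_test(groups[ga], groups[gb])
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "n_a": len(groups[ga]),
                    "n_b": len(groups[gb]),
                    "delta_mean_mv": (
                        float(np.mean(groups[ga])) - float(np.mean(groups[gb]))
                    )
                    * 1000.0,
                    "welch_t": res["t"],
                    "welch_df": res["df"],
                    "p": res["p"],
                }
            )
    table = pd.DataFrame(rows)
    if correction == "bh" and not table.empty:
        p = table["p"].to_numpy()
        order = np.argsort(p)
        m = p.size
        adjusted = np.empty(m)
        running = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            rank = m - rank_from_end
            running = min(running, p[idx] * m / rank)
            adjusted[idx] = running
        table["p_adjusted"] = adjusted
    return table
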