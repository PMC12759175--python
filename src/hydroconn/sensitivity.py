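"""Robustness of RCI to uncertainty in expert-elicited passability values.

Barrier passabilities are expert judgments, so the indices are recomputed
under multiplicative perturbations of the default upstream/downstream values
(suitability held fixed) and compared with the baseline by Pearson
correlation of the per-reach RCI vectors and a paired two-sided Wilcoxon
signed-rank test. A "blocked upstream" scenario (dam pass_up forced to 0)
probes the restrictive extreme.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import PassabilityPolicy, rci
from .river_graph import RiverNetwork

__all__ = [
    "PerturbationScenario",
    "perturb_policy",
    "moderate_grid",
    "blocked_upstream_scenario",
    "default_grid",
    "sensitivity_grid",
]

PERTURBED_KINDS = ("anthropogenic", "waterfall")


@dataclass(frozen=True)
class PerturbationScenario:
    """Multiplicative factors applied to the default barrier passabilities."""

    label: str
    up_factor: float = 1.0
    down_factor: float = 1.0
    blocked_upstream: bool = False


def perturb_policy(
    policy: PassabilityPolicy, scenario: PerturbationScenario
) -> PassabilityPolicy:
    """Policy with perturbed barrier defaults, clipped to [0, 1].

    Only the anthropogenic/waterfall defaults move; confluences, explicit
    per-barrier values and the suitability layers are untouched.
    ``blocked_upstream`` then forces the anthropogenic upstream default to 0.
    """
    defaults = dict(policy.defaults)
    for kind in PERTURBED_KINDS:
        defaults[(kind, "up")] = float(
            np.clip(defaults[(kind, "up")] * scenario.up_factor, 0.0, 1.0)
        )
        defaults[(kind, "down")] = float(
            np.clip(defaults[(kind, "down")] * scenario.down_factor, 0.0, 1.0)
        )
    if scenario.blocked_upstream:
        defaults[("anthropogenic", "up")] = 0.0
    return replace(policy, defaults=defaults)


def moderate_grid(
    magnitudes: Iterable[float] = (0.10, 0.25),
) -> list[PerturbationScenario]:
    """The +/-10% and +/-25% grid over up, down and both directions."""
    out = []
    for m in magnitudes:
        pct = int(round(m * 100))
        for sign, tag in ((1.0 + m, f"+{pct}"), (1.0 - m, f"-{pct}")):
            out.append(PerturbationScenario(f"up{tag}", up_factor=sign))
            out.append(PerturbationScenario(f"down{tag}", down_factor=sign))
            out.append(
                PerturbationScenario(
                    f"both{tag}", up_factor=sign, down_factor=sign
                )
            )
    return out


def blocked_upstream_scenario() -> PerturbationScenario:
    return PerturbationScenario("blocked_upstream", blocked_upstream=True)


def default_grid() -> list[PerturbationScenario]:
    return moderate_grid() + [blocked_upstream_scenario()]


def sensitivity_grid(
    network: RiverNetwork,
    policy: PassabilityPolicy,
    scenarios: Iterable[PerturbationScenario],
    active: Optional[frozenset[str]] = None,
) -> pd.DataFrame:
    """Compare baseline RCI against each perturbation scenario.

    Returns one row per scenario with the Pearson r over reaches, the paired
    Wilcoxon signed-rank statistic and two-sided p-value (zero differences
    dropped), and a ``degenerate`` flag. All-zero differences give r = 1,
    p = 1; a constant RCI vector leaves r undefined (NaN) and is flagged.
    """
    if len(network) < 3:
        raise ValueError("need at least 3 reaches for a meaningful correlation")
    base = rci(network, policy, active=active)
    x = base.to_numpy(float)
    rows = []
    for sc in scenarios:
        pert = rci(network, perturb_policy(policy, sc), active=active)
        y = pert.reindex(base.index).to_numpy(float)
        diff = y - x
        degenerate = bool(np.all(diff == 0.0))
        if degenerate:
            r, stat, p = 1.0, np.nan, 1.0
        elif np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            degenerate = True
            r, stat, p = np.nan, np.nan, np.nan
        else:
            r = float(stats.pearsonr(x, y).statistic)
            nz = diff[diff != 0.0]
            if nz.size == 0:
                stat, p = np.nan, 1.0
            else:
                res = stats.wilcoxon(
                    nz, zero_method="wilcox", alternative="two-sided"
                )
                stat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "scenario": sc.label,
                "up_factor": sc.up_factor,
                "down_factor": sc.down_factor,
                "blocked_upstream": sc.blocked_upstream,
                "pearson_r": r,
                "wilcoxon_stat": stat,
                "p_value": p,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)
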