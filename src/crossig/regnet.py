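"""Upstream-regulator activation scoring on a signed regulator->target
network.

For a regulator with targets found in a signed differential-expression list,
the activation z-score is

    z = sum_t (edge_sign_t * observed_direction_t) / sqrt(n_overlap)

with unit edge weights, so |z| = sqrt(n) exactly when every target moves
consistently with the regulator being active. Regulators with z >= 2 are
called activated, z <= -2 inhibited, otherwise undetermined. A hypergeometric
upper-tail p quantifies target-set enrichment in the DE list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .io import RegulatorNetwork

logger = logging.getLogger("crossig")

ACTIVATION_THRESHOLD = 2.0


@dataclass
class RegulatorScore:
    regulator: str
    n_overlap: int
    z: float
    overlap_p: float
    state: str  # activated / inhibited / undetermined


def activation_z(
    regulator: str, network: RegulatorNetwork, de_list: dict[str, int]
) -> float:
    """Signed-consistency z-score for one regulator.

    ``de_list`` maps gene -> observed direction (+1 up, -1 down). Raises if
    the regulator has no target in the DE list.
    """
    targets = network.targets_of(regulator)
    hits = [(s, de_list[t]) for t, s in targets.items() if t in de_list]
    if not hits:
        raise ValueError(f"regulator {regulator!r} has no target in the DE list")
    score = sum(s * d for s, d in hits)
    return score / math.sqrt(len(hits))


def overlap_p(
    regulator: str,
    network: RegulatorNetwork,
    de_list: dict[str, int],
    universe_size: int,
) -> float:
    """Hypergeometric upper-tail probability of the observed target overlap.

    Universe of ``universe_size`` genes, of which ``len(de_list)`` are DE;
    the regulator's target set is the draw.
    """
    targets = network.targets_of(regulator)
    n_targets = len(targets)
    n_de = len(de_list)
    if universe_size < n_de or universe_size < n_targets:
        raise ValueError("universe smaller than DE list or target set")
    k = sum(1 for t in targets if t in de_list)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, universe_size, n_de, n_targets))


def score_regulators(
    network: RegulatorNetwork, de_list: dict[str, int], universe_size: int
) -> pd.DataFrame:
    """Score every regulator with >=1 target in the DE list.

    Regulators with zero overlap are skipped with a note. Returns a frame
    ordered by z descending.
    """
    rows = []
    for reg in network.regulators:
        targets = network.targets_of(reg)
        n = sum(1 for t in targets if t in de_list)
        if n == 0:
            logger.info("regulator %s skipped: no target in DE list", reg)
            continue
        z = activation_z(reg, network, de_list)
        p = overlap_p(reg, network, de_list, universe_size)
        if z >= ACTIVATION_THRESHOLD:
            state = "activated"
        elif z <= -ACTIVATION_THRESHOLD:
            state = "inhibited"
        else:
            state = "undetermined"
        rows.append((reg, n, z, p, state))
    df = pd.DataFrame(
        rows, columns=["regulator", "n_overlap", "z", "overlap_p", "state"]
    ).set_index("regulator")
    return df.sort_values("z", ascending=False)
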