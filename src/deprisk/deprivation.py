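"""SIMD quintiles and the three socioeconomic analysis groups.

The Scottish Index of Multiple Deprivation (2009 revision) scores areas from
0.94 (least deprived) to 89.89 (most deprived). Quintiles are defined on the
full Scottish population, quintile 1 being the *most* deprived fifth:

    SIMD >= 33.81          -> quintile 1
    20.98 <= SIMD < 33.81  -> quintile 2
    13.67 <= SIMD < 20.98  -> quintile 3
    7.94  <= SIMD < 13.67  -> quintile 4
    SIMD < 7.94            -> quintile 5

Analyses are stratified into group 1 (quintile 1, most deprived), group 2
(quintiles 2-4) and group 3 (quintile 5, least deprived). Missing SIMD
propagates to a missing group; it is never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_CUTOFFS = (7.94, 13.67, 20.98, 33.81)
DEFAULT_GROUP_MAP = {1: 1, 2: 2, 3: 2, 4: 2, 5: 3}


@dataclass(frozen=True)
class DeprivationConfig:
    cutoffs: tuple[float, float, float, float] = DEFAULT_CUTOFFS
    group_map: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_MAP))

    def __post_init__(self):
        if list(self.cutoffs) != sorted(self.cutoffs) or len(set(self.cutoffs)) != len(
            self.cutoffs
        ):
            raise ValueError("quintile cutoffs must be strictly increasing")
        if set(self.group_map) != {1, 2, 3, 4, 5}:
            raise ValueError("group mapping must cover quintiles 1-5")
        if not set(self.group_map.values()) <= {1, 2, 3}:
            raise ValueError("groups must be 1, 2 or 3")


def simd_quintile(score: float, config: DeprivationConfig | None = None) -> int:
    """Quintile 1-5 for a SIMD score; quintile 1 is the most deprived."""
    config = config or DeprivationConfig()
    if score is None or not np.isfinite(score):
        raise ValueError(f"SIMD score must be finite, got {score!r}")
    if score < 0:
        raise ValueError(f"SIMD score must be >= 0, got {score}")
    c = config.cutoffs
    # lower bound inclusive on the deprived side, as the cutoffs are printed
    if score >= c[3]:
        return 1
    if score >= c[2]:
        return 2
    if score >= c[1]:
        return 3
    if score >= c[0]:
        return 4
    return 5


def simd_group(score: float | None, config: DeprivationConfig | None = None) -> int | None:
    """Analysis group 1/2/3; missing score propagates to None."""
    config = config or DeprivationConfig()
    if score is None or (isinstance(score, float) and np.isnan(score)):
        return None
    return config.group_map[simd_quintile(score, config)]


def simd_groups(scores, config: DeprivationConfig | None = None) -> np.ndarray:
    """Vectorised :func:`simd_group`; NaN in -> NaN out."""
    config = config or DeprivationConfig()
    s = pd.to_numeric(pd.Series(scores), errors="coerce").to_numpy(dtype=float)
    if np.nanmin(s, initial=0.0) < 0:
        raise ValueError("SIMD scores must be >= 0")
    c = config.cutoffs
    quint = np.select(
        [s >= c[3], s >= c[2], s >= c[1], s >= c[0], s >= 0], [1, 2, 3, 4, 5],
        default=np.nan,
    )
    gmap = np.array([np.nan] + [config.group_map[q] for q in (1, 2, 3, 4, 5)])
    out = np.full(len(s), np.nan)
    ok = ~np.isnan(quint)
    out[ok] = gmap[quint[ok].astype(int)]
    return out
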