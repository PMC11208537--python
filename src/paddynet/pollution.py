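"""Heavy-metal pollution indices and Cd risk screening.

Two indices quantify pollution relative to regional background soil:

* contamination factor, ``CF = C_metal / C_background`` — single metal;
* pollution load index, ``PLI = (CF_1 * ... * CF_n)^(1/n)`` — the
  geometric mean of the CFs of the assessed metals.  ``PLI > 1``
  indicates pollution.

Cd risk screening follows the GB 15618-2018 pH-dependent screening
values for paddy soil: 0.3 mg/kg at pH <= 5.5 and 0.4 mg/kg at
5.5 < pH <= 6.5.  Above pH 6.5 the threshold is configuration-supplied
(default 0.6 mg/kg) and the result is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tables_io import (METALS, BackgroundTable, MetalTable,
                        SoilProfileTable)

#: GB 15618-2018 Cd risk screening value above pH 6.5 (mg/kg), flagged
CD_SCREEN_HIGH_PH_DEFAULT = 0.6


@dataclass
class PollutionResult:
    """Per-sample pollution assessment."""

    sample_id: str
    cf: dict[str, float]
    pli: float
    polluted: bool
    cd_exceeds_screen: bool
    cd_screen_extrapolated: bool = field(default=False)

    def __post_init__(self) -> None:
        assert all(v >= 0 for v in self.cf.values())
        assert self.pli >= 0
        assert self.polluted == (self.pli > 1.0)


def contamination_factor(concentration: float, background: float) -> float:
    """CF of one metal: measured concentration over regional background."""
    if not background > 0:
        raise ValueError(f"background must be > 0, got {background}")
    if concentration < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    return concentration / background


def pollution_load_index(cfs: Sequence[float]) -> float:
    """Geometric mean of contamination factors.

    Computed as ``exp(mean(log cf))`` for numerical stability; undefined
    (raises) when any CF is zero or negative.
    """
    cfs = np.asarray(cfs, dtype=float)
    if cfs.size == 0:
        raise ValueError("need at least one CF")
    if (cfs <= 0).any():
        raise ValueError("all CFs must be > 0 (geometric mean undefined at 0)")
    return float(np.exp(np.mean(np.log(cfs))))


def cd_risk_screen(ph: float, total_cd: float,
                   high_ph_threshold: float = CD_SCREEN_HIGH_PH_DEFAULT,
                   ) -> tuple[bool, bool]:
    """pH-dependent Cd screening; returns (exceeds, threshold_extrapolated).

    Strict inequality: a concentration exactly at the screening value
    does not exceed it.
    """
    if not 0 < ph < 14:
        raise ValueError(f"pH must be in (0, 14), got {ph}")
    extrapolated = False
    if ph <= 5.5:
        threshold = 0.3
    elif ph <= 6.5:
        threshold = 0.4
    else:
        threshold = high_ph_threshold
        extrapolated = True
    return total_cd > threshold, extrapolated


def assess_site(metals: dict[str, float], backgrounds: BackgroundTable,
                ph: float, sample_id: str = "",
                pli_metals: Iterable[str] = METALS) -> PollutionResult:
    """Assess one site: per-metal CF, four-metal PLI, Cd screening.

    ``metals`` maps metal -> total concentration (mg/kg); CF uses total,
    not DTPA-extractable, concentrations.
    """
    pli_metals = list(pli_metals)
    need = sorted(set(metals) | set(pli_metals))
    if not backgrounds.covers(need):
        missing = [m for m in need if m not in backgrounds.values]
        raise ValueError(f"backgrounds missing metal(s): {missing}")
    cf = {m: contamination_factor(metals[m], backgrounds[m]) for m in metals}
    pli = pollution_load_index([cf[m] for m in pli_metals])
    exceeds, extrapolated = cd_risk_screen(ph, metals["Cd"])
    return PollutionResult(sample_id=sample_id, cf=cf, pli=pli,
                           polluted=pli > 1.0, cd_exceeds_screen=exceeds,
                           cd_screen_extrapolated=extrapolated)


def assess_table(metals: MetalTable, backgrounds: BackgroundTable,
                 soil: SoilProfileTable) -> pd.DataFrame:
    """Assess every sample; soil supplies pH for the Cd screen.

    Returns a frame with columns ``CF_<metal>``, ``PLI``, ``polluted``,
    ``cd_exceeds_screen`` indexed by sample_id.
    """
    rows = []
    for sid in metals.sample_ids:
        res = assess_site(metals.row(sid), backgrounds,
                          ph=float(soil.data.loc[sid, "ph"]), sample_id=sid)
        row = {f"CF_{m}": res.cf[m] for m in metals.metals}
        row.update(PLI=res.pli, polluted=res.polluted,
                   cd_exceeds_screen=res.cd_exceeds_screen)
        rows.append(pd.Series(row, name=sid))
    out = pd.DataFrame(rows)
    out.index.name = "sample_id"
    return out
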