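"""Protein-composition statistics from SE-HPLC fraction areas.

From the raw absorbance areas of four fractions (F1 = HMW polymeric
protein, F2 = LMW glutenin polymers, F3 = gliadins, F4 = albumins/
globulins/hydrolysates) in the SDS-extractable (E) and SDS-unextractable
(U) sets, this module derives:

* absorbance-area percentages A% (per fraction, within each of the E, U
  and total T = E + U sets), which express protein *composition*
  independently of total protein content;
* the composition ratios: gliadin-to-glutenin Gli:Glu = F3 / (F1 + F2),
  HMW:LMW = F1 / F2 (E, U and T variants), and UPP:TPP = unextractable
  polymeric protein over total polymeric protein,
  U(F1 + F2) / [E(F1 + F2) + U(F1 + F2)].

Ratios are computed from raw areas (they are scale-invariant either way);
the A% values are what enters the trait tables for ANOVA.  F4 takes no
part in any ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import FractionAreaTable


def _set_frame(areas: FractionAreaTable, prefix: str) -> pd.DataFrame:
    cols = [f"{prefix}_F{i}" for i in range(1, 5)]
    return areas.data[cols].set_axis([f"F{i}" for i in range(1, 5)], axis=1)


def area_percent(areas: FractionAreaTable) -> pd.DataFrame:
    """A% per fraction within the E, U and T (= E + U) sets.

    Each set's four percentages sum to 100 per sample.  A sample with a
    zero total area in any set is rejected.
    """
    out = {}
    frames = {"E": _set_frame(areas, "E"), "U": _set_frame(areas, "U")}
    frames["T"] = frames["E"] + frames["U"]
    for prefix, frame in frames.items():
        total = frame.sum(axis=1)
        if (total <= 0).any():
            bad = list(total.index[total <= 0])[:5]
            raise ValueError(f"zero total {prefix} area for samples {bad}")
        for i in range(1, 5):
            out[f"{prefix}_F{i}"] = 100.0 * frame[f"F{i}"] / total
    return pd.DataFrame(out, index=areas.data.index)


def fraction_ratios(areas: FractionAreaTable,
                    gliadin: str = "total") -> pd.DataFrame:
    """Composition ratios from raw absorbance areas.

    ``gliadin`` selects whether Gli:Glu uses total (E + U, default) or
    extractable-only areas.  Zero denominators yield NaN and set the
    sample's ``flagged`` column.
    """
    e = _set_frame(areas, "E")
    u = _set_frame(areas, "U")
    t = e + u
    g = t if gliadin == "total" else e if gliadin == "extractable" else None
    if g is None:
        raise ValueError("gliadin must be 'total' or 'extractable'")

    def safe_div(num, den):
        den = den.replace(0.0, np.nan)
        return num / den

    out = pd.DataFrame(index=areas.data.index)
    out["T_Gli:Glu"] = safe_div(g["F3"], g["F1"] + g["F2"])
    for prefix, frame in (("E", e), ("U", u), ("T", t)):
        out[f"{prefix}_HMW:LMW"] = safe_div(frame["F1"], frame["F2"])
    upp = u["F1"] + u["F2"]
    tpp = t["F1"] + t["F2"]
    out["UPP:TPP"] = safe_div(upp, tpp)
    out["flagged"] = out.drop(columns="flagged", errors="ignore").isna().any(axis=1)
    return out


def trait_table(areas: FractionAreaTable,
                gliadin: str = "total") -> pd.DataFrame:
    """Per-sample composition traits in the layout of the trial tables:
    T_HMW, T_LMW, T_Gli (A% of total F1-F3), T_HMW:LMW, T_Gli:Glu, UPP:TPP.
    """
    pct = area_percent(areas)
    ratios = fraction_ratios(areas, gliadin=gliadin)
    return pd.DataFrame({
        "T_HMW": pct["T_F1"],
        "T_LMW": pct["T_F2"],
        "T_Gli": pct["T_F3"],
        "T_HMW:LMW": ratios["T_HMW:LMW"],
        "T_Gli:Glu": ratios["T_Gli:Glu"],
        "UPP:TPP": ratios["UPP:TPP"],
    })
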