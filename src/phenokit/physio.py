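"""Leaf water-status and oxidative-stress indices.

Implements the three indices as printed in the source protocol:

* relative water content  RWC = 100 * (FW - DW) / (TW - FW)  [%]
  (note the non-standard denominator TW - FW; the conventional
  TW - DW form is available as ``formula="standard"``)
* leaf succulence  S = FW / leaf area  [g cm^-2]
* MDA concentration  [umol L^-1] = 6.45 * OD532 - 0.56 * OD450,
  with an explicit volume-bookkeeping conversion to nmol per gram
  fresh weight using the extraction protocol volumes
  (3 mL TCA on 0.2 g tissue; 2 mL supernatant + 2 mL TBA = 4 mL assay).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "rwc",
    "succulence",
    "mda_concentration",
    "mda_per_gram",
    "index_series",
    "MDA_SLOPE_OD532",
    "MDA_SLOPE_OD450",
]

logger = logging.getLogger(__name__)

MDA_SLOPE_OD532 = 6.45
MDA_SLOPE_OD450 = -0.56

#: Extraction-protocol volume defaults (mL) and tissue mass (g).
PROTOCOL_EXTRACT_ML = 3.0
PROTOCOL_ALIQUOT_ML = 2.0
PROTOCOL_ASSAY_ML = 4.0
PROTOCOL_TISSUE_G = 0.2


def rwc(fw: float, dw: float, tw: float, formula: str = "printed") -> float:
    """Relative water content in percent.

    ``formula="printed"`` uses 100*(FW-DW)/(TW-FW) as in the protocol;
    ``"standard"`` uses the conventional 100*(FW-DW)/(TW-DW).
    A DW > FW input is physically inconsistent and yields a flagged
    (warned) negative result rather than an exception.
    """
    if formula not in ("printed", "standard"):
        raise ValueError(f"unknown RWC formula {formula!r}")
    denom = (tw - fw) if formula == "printed" else (tw - dw)
    if denom <= 0:
        raise ZeroDivisionError(
            f"RWC denominator non-positive (formula={formula}): "
            f"FW={fw}, DW={dw}, TW={tw}"
        )
    value = 100.0 * (fw - dw) / denom
    if dw > fw:
        warnings.warn(
            f"DW={dw} > FW={fw}: negative RWC {value:.3g}% returned", stacklevel=2
        )
    return value


def succulence(fw: float, leaf_area: float) -> float:
    """Leaf succulence, fresh weight per leaf area (g cm^-2)."""
    if leaf_area <= 0:
        raise ZeroDivisionError(f"leaf area must be positive, got {leaf_area}")
    return fw / leaf_area


def mda_concentration(od532: float, od450: float) -> float:
    """MDA concentration (umol L^-1) from the two-wavelength absorbances.

    Negative results are possible when OD450 dominates; they are returned
    with a warning, never clipped.
    """
    if od532 < 0 or od450 < 0:
        raise ValueError("absorbances must be >= 0")
    value = MDA_SLOPE_OD532 * od532 + MDA_SLOPE_OD450 * od450
    if value < 0:
        warnings.warn(
            f"negative MDA concentration {value:.4g} umol/L "
            f"(OD532={od532}, OD450={od450})", stacklevel=2
        )
    return value


def mda_per_gram(
    concentration: float,
    tissue_mass: float = PROTOCOL_TISSUE_G,
    extract_volume: float = PROTOCOL_EXTRACT_ML,
    aliquot_volume: float = PROTOCOL_ALIQUOT_ML,
    assay_volume: float = PROTOCOL_ASSAY_ML,
) -> float:
    """Convert an assay concentration (umol L^-1) to nmol per g fresh weight.

    nmol/g = conc * assay_volume[L] * (extract/aliquot) / tissue_mass * 1000.
    The dilution ratio extract/aliquot accounts for assaying only part of the
    extract; defaults are the extraction-protocol numbers (3, 2, 4 mL, 0.2 g).
    """
    if tissue_mass <= 0 or extract_volume <= 0 or aliquot_volume <= 0 or assay_volume <= 0:
        raise ValueError("volumes and tissue mass must be positive")
    if aliquot_volume > extract_volume:
        raise ValueError(
            f"aliquot ({aliquot_volume} mL) exceeds extract ({extract_volume} mL)"
        )
    assay_litres = assay_volume / 1000.0
    return concentration * assay_litres * (extract_volume / aliquot_volume) / tissue_mass * 1000.0


def _se(x: np.ndarray) -> float:
    x = np.asarray(x, float)
    if x.size < 2:
        return 0.0
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def index_series(samples: pd.DataFrame, rwc_formula: str = "printed") -> pd.DataFrame:
    """Per-day, per-group index table with mean, SE and replicate count.

    ``samples`` is a long table with columns ``day, group`` and, as available,
    ``fw_g, tw_g, dw_g, area_cm2, od532, od450, tissue_g``.  Each index is
    computed row-wise (per replicate) and then aggregated, so group means are
    means of replicate indices, not indices of mean inputs.  Rows missing the
    fields an index needs have that index omitted (logged), never NaN-filled.

    Returns a long table ``day, group, index, mean, se, n`` with index names
    ``rwc_pct``, ``succulence_g_cm2``, ``mda_nmol_g``.
    """
    df = samples.copy()
    values: list[dict] = []

    def per_row(row, fields, fn):
        if any(f not in row or pd.isna(row[f]) for f in fields):
            return None
        return fn(row)

    df["_rwc"] = df.apply(
        lambda r: per_row(r, ["fw_g", "dw_g", "tw_g"],
                          lambda r: rwc(r["fw_g"], r["dw_g"], r["tw_g"],
                                        formula=rwc_formula)),
        axis=1,
    )
    df["_succ"] = df.apply(
        lambda r: per_row(r, ["fw_g", "area_cm2"],
                          lambda r: succulence(r["fw_g"], r["area_cm2"])),
        axis=1,
    )

    def _mda(r):
        conc = mda_concentration(r["od532"], r["od450"])
        mass = r["tissue_g"] if "tissue_g" in r and not pd.isna(r["tissue_g"]) \
            else PROTOCOL_TISSUE_G
        return mda_per_gram(conc, tissue_mass=mass)

    df["_mda"] = df.apply(
        lambda r: per_row(r, ["od532", "od450"], _mda), axis=1
    )

    index_cols = {"rwc_pct": "_rwc", "succulence_g_cm2": "_succ",
                  "mda_nmol_g": "_mda"}
    for (day, group), sub in df.groupby(["day", "group"], sort=True):
        for name, col in index_cols.items():
            vals = sub[col].dropna().to_numpy(float)
            if vals.size == 0:
                logger.info("index %s omitted for day=%s group=%s (no usable rows)",
                            name, day, group)
                continue
            if vals.size < len(sub):
                logger.info("index %s for day=%s group=%s uses %d/%d replicates",
                            name, day, group, vals.size, len(sub))
            values.append({"day": day, "group": group, "index": name,
                           "mean": float(np.mean(vals)), "se": _se(vals),
                           "n": int(vals.size)})
    return pd.DataFrame(values, columns=["day", "group", "index", "mean", "se", "n"])
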