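"""Isotope and growth phenotype derivation.

Converts raw isotope-ratio measurements (delta notation) to atom percent,
computes atom percent excess (APE) over a pre-experiment baseline, and
derives the individual and tank-level feed-efficiency phenotypes:

* WG, RG       -- absolute and relative weight gain of a fish,
* FCR          -- tank feed conversion ratio, feed intake per unit gain,
* IFCR, IFER   -- individual isotope indicator ratios, ``FW * APE / (FW - IW)``
                  and its reciprocal, proxies for individual feed conversion
                  and feed efficiency.

After a period on a diet enriched in a heavy isotope, the atom percent
excess of a tissue is proportional to the fraction of its nutrients that
were newly deposited during the period; scaled by final weight it tracks
the mass of new nutrients, and per gram of gain it tracks feed spent per
gram grown.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "R_STD_N15_AIR",
    "R_STD_C13_VPDB",
    "IsotopeStandards",
    "ISOTOPE_KEYS",
    "TRAIT_OF_KEY",
    "delta_to_atom_percent",
    "atom_percent_to_delta",
    "atom_percent_excess",
    "estimate_baseline",
    "growth_traits",
    "filter_growth_outliers",
    "tank_fcr",
    "indicator_ratios",
    "dry_matter_intake",
    "tank_means",
    "derive_phenotypes",
]

#: Isotope ratio of atmospheric N2, the international reference for 15N/14N.
R_STD_N15_AIR = 0.003676
#: Isotope ratio of Vienna Pee Dee Belemnite, the reference for 13C/12C.
R_STD_C13_VPDB = 0.0112372

#: (tissue, isotope) keys measured by the protocol, with the conventional
#: trait abbreviations: A<tissue><element>, e.g. AMN = atom% 15N in muscle.
ISOTOPE_KEYS: tuple[tuple[str, str], ...] = (
    ("muscle", "c13"),
    ("muscle", "n15"),
    ("liver", "c13"),
    ("liver", "n15"),
    ("adipose", "c13"),
)

TRAIT_OF_KEY: dict[tuple[str, str], str] = {
    ("muscle", "c13"): "amc",
    ("muscle", "n15"): "amn",
    ("liver", "c13"): "alc",
    ("liver", "n15"): "aln",
    ("adipose", "c13"): "aac",
}

# Growth-based missingness thresholds (percent relative weight gain).
RG_LOW_THRESHOLD = 6.4
RG_HIGH_THRESHOLD = 49.0


@dataclasses.dataclass(frozen=True)
class IsotopeStandards:
    """Reference ratios and pre-experiment baseline atom% (IA%).

    ``baseline_mean``/``baseline_sd`` map trait abbreviations (amc, amn,
    alc, aln, aac) to the initial atom% of unexposed fish and its
    sampling SD.  The default baselines are the conventional natural
    abundances used for the indicator-ratio calculations: 0.370% for
    15N and 1.087% for 13C in every tissue (a per-tissue override is
    possible, e.g. 1.082 for adipose 13C).
    """

    r_n15: float = R_STD_N15_AIR
    r_c13: float = R_STD_C13_VPDB
    baseline_mean: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "amc": 1.087,
            "amn": 0.370,
            "alc": 1.087,
            "aln": 0.370,
            "aac": 1.087,
        }
    )
    baseline_sd: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "amc": 0.0005,
            "amn": 0.0001,
            "alc": 0.0007,
            "aln": 0.0003,
            "aac": 0.0003,
        }
    )

    def __post_init__(self) -> None:
        if self.r_n15 <= 0 or self.r_c13 <= 0:
            raise ValueError("standard isotope ratios must be strictly positive")
        for k, v in self.baseline_mean.items():
            if not 0.0 < v < 100.0:
                raise ValueError(f"baseline IA% for {k!r} outside (0, 100): {v}")

    def ratio_for(self, isotope: str) -> float:
        if isotope == "n15":
            return self.r_n15
        if isotope == "c13":
            return self.r_c13
        raise KeyError(f"unknown isotope {isotope!r}")


def delta_to_atom_percent(delta, standard_ratio: float):
    """Convert a delta value (per mil) to atom percent of the heavy isotope.

    ``atom% = (delta + 1000) / (delta + 1000 + 1000/R_std) * 100`` where
    ``R_std`` is the heavy/light ratio of the international standard
    (air for nitrogen, VPDB for carbon).  Strictly increasing in delta,
    with output in (0, 100) on the physical domain delta > -1000.
    """
    delta = np.asarray(delta, dtype=float)
    if standard_ratio <= 0:
        raise ValueError("standard_ratio must be strictly positive")
    if np.any(delta <= -1000.0):
        raise ValueError("delta <= -1000 per mil is nonphysical")
    out = (delta + 1000.0) / (delta + 1000.0 + 1000.0 / standard_ratio) * 100.0
    return float(out) if out.ndim == 0 else out


def atom_percent_to_delta(atom, standard_ratio: float):
    """Inverse of :func:`delta_to_atom_percent` (atom% in (0, 100))."""
    atom = np.asarray(atom, dtype=float)
    if standard_ratio <= 0:
        raise ValueError("standard_ratio must be strictly positive")
    if np.any((atom <= 0.0) | (atom >= 100.0)):
        raise ValueError("atom percent must lie strictly inside (0, 100)")
    out = (1000.0 / standard_ratio) * atom / (100.0 - atom) - 1000.0
    return float(out) if out.ndim == 0 else out


def atom_percent_excess(atom, ia: float):
    """Atom percent excess: measured atom% minus the baseline IA%."""
    atom_arr = np.asarray(atom, dtype=float)
    if not 0.0 < ia < 100.0:
        raise ValueError("baseline IA% must lie in (0, 100)")
    if np.any((atom_arr <= 0.0) | (atom_arr >= 100.0)):
        raise ValueError("atom percent must lie in (0, 100)")
    out = atom_arr - ia
    return float(out) if out.ndim == 0 else out


def estimate_baseline(samples: Sequence[float]) -> tuple[float, float]:
    """Mean and sample SD of baseline atom% from unexposed fish (n >= 2)."""
    arr = np.asarray(list(samples), dtype=float)
    if arr.size < 2:
        raise ValueError("baseline estimation requires at least two fish")
    return float(arr.mean()), float(arr.std(ddof=1))


def growth_traits(iw, fw):
    """Weight gain WG = FW - IW (g) and relative gain RG = WG/FW * 100 (%)."""
    iw = np.asarray(iw, dtype=float)
    fw = np.asarray(fw, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(iw[~np.isnan(iw)] <= 0) or np.any(fw[~np.isnan(fw)] <= 0):
            raise ValueError("weights must be strictly positive")
    wg = fw - iw
    rg = wg / fw * 100.0
    if wg.ndim == 0:
        return float(wg), float(rg)
    return wg, rg


def filter_growth_outliers(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Flag growth records as missing by reason code.

    A fish is excluded from the growth and FCR analyses when either weight
    is missing (``weight_missing``), when RG < 6.4% (``low_growth``,
    abnormal development) or when RG > 49% (``high_growth``, growth not
    matched by the isotope profile, i.e. a phenotyping error).  Both
    thresholds are strict; the rule is idempotent.  Returns the table with
    ``growth_missing`` / ``missing_reason`` columns and the per-reason
    counts.
    """
    out = records.copy()
    rg = out["rg"].to_numpy(dtype=float)
    weight_missing = out["iw"].isna().to_numpy() | out["fw"].isna().to_numpy()
    low = ~weight_missing & (rg < RG_LOW_THRESHOLD)
    high = ~weight_missing & (rg > RG_HIGH_THRESHOLD)
    reason = np.full(len(out), "", dtype=object)
    reason[weight_missing] = "weight_missing"
    reason[low] = "low_growth"
    reason[high] = "high_growth"
    out["growth_missing"] = weight_missing | low | high
    out["missing_reason"] = reason
    counts = {
        "weight_missing": int(weight_missing.sum()),
        "low_growth": int(low.sum()),
        "high_growth": int(high.sum()),
        "total_missing": int((weight_missing | low | high).sum()),
    }
    return out, counts


def tank_fcr(fi: float, member_wg: Iterable[float]) -> float:
    """Tank feed conversion ratio FI / sum(WG) over non-missing members."""
    wg = np.asarray([w for w in member_wg if not (w is None or np.isnan(w))], dtype=float)
    if fi < 0:
        raise ValueError("feed intake must be non-negative")
    total = float(wg.sum())
    if wg.size == 0 or total <= 0:
        raise ValueError("tank weight gain must be positive over non-missing members")
    return fi / total


def indicator_ratios(iw, fw, ape):
    """Isotope indicator ratio traits.

    ``IFCR = FW * APE / (FW - IW)`` is proportional to the mass of newly
    deposited nutrients per gram of body-weight gain; its reciprocal IFER
    is the efficiency analogue.  Returns NaN for both where FW == IW, and
    NaN IFER where APE == 0.
    """
    iw = np.asarray(iw, dtype=float)
    fw = np.asarray(fw, dtype=float)
    ape = np.asarray(ape, dtype=float)
    wg = fw - iw
    with np.errstate(divide="ignore", invalid="ignore"):
        ifcr = np.where(wg != 0.0, fw * ape / wg, np.nan)
        ifer = np.where((wg != 0.0) & (ape != 0.0), wg / (fw * ape), np.nan)
    if ifcr.ndim == 0:
        return float(ifcr), float(ifer)
    return ifcr, ifer


def dry_matter_intake(
    fed: float,
    waste_recovered: float,
    leaching_correction: float = 0.0,
    dm_fraction: float = 1.0,
) -> float:
    """Tank dry-matter feed intake from fed amount and recovered waste.

    Uneaten feed trapped on the outlet screen is corrected upward for
    leaching losses before subtraction: ``FI = (fed - waste/(1 - leach))
    * dm_fraction`` (g dry matter).
    """
    if fed < 0 or waste_recovered < 0:
        raise ValueError("fed and waste must be non-negative")
    if not 0.0 <= leaching_correction < 1.0:
        raise ValueError("leaching_correction must lie in [0, 1)")
    if not 0.0 < dm_fraction <= 1.0:
        raise ValueError("dm_fraction must lie in (0, 1]")
    corrected_waste = waste_recovered / (1.0 - leaching_correction)
    if corrected_waste > fed:
        raise ValueError("corrected waste exceeds fed feed")
    return (fed - corrected_waste) * dm_fraction


def tank_means(records: pd.DataFrame, trait: str, tank_col: str = "tank") -> pd.DataFrame:
    """Per-tank arithmetic means of a trait over non-missing members."""
    if trait not in records.columns:
        raise KeyError(f"trait column {trait!r} not present")
    grouped = records.groupby(tank_col)[trait]
    means = grouped.mean()
    counts = grouped.count()
    if (counts == 0).any():
        empty = counts.index[counts == 0].tolist()
        raise ValueError(f"tanks with no non-missing member for {trait!r}: {empty}")
    return pd.DataFrame({trait: means, "n": counts})


def derive_phenotypes(
    individuals: pd.DataFrame,
    tanks: pd.DataFrame,
    standards: IsotopeStandards | None = None,
    *,
    units: str = "atom",
    indicator_keys: Sequence[tuple[str, str]] = (("muscle", "n15"), ("muscle", "c13")),
    include_filtered_in_fcr: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Full phenotype derivation for an experiment.

    Parameters
    ----------
    individuals
        One row per fish with columns ``fish_id, family, tank, day, iw, fw``
        and one isotope column per measured key, named ``atom_<trait>`` or
        ``delta_<trait>`` depending on ``units`` (trait in amc, amn, alc,
        aln, aac).
    tanks
        One row per tank with ``tank, day, fi`` (g dry matter).
    units
        ``"atom"`` if isotope columns are already atom%, ``"delta"`` if
        they are per-mil delta values to be converted.
    indicator_keys
        (tissue, isotope) keys for which IFCR/IFER are computed; the
        default follows the standard protocol (muscle N and muscle C).
    include_filtered_in_fcr
        Sensitivity switch: include growth-flagged fish in the tank WG sum.

    Returns
    -------
    (individual table, tank table, filter counts)
        The individual table gains wg, rg, atom_*, ape_*, ifcr_*, ifer_*
        and missingness flags; the tank table gains sum_wg, fcr and the
        per-trait tank means used as regression covariates.
    """
    standards = standards or IsotopeStandards()
    ind = individuals.copy()

    with np.errstate(invalid="ignore"):
        wg, rg = growth_traits(ind["iw"].to_numpy(float), ind["fw"].to_numpy(float))
    ind["wg"], ind["rg"] = wg, rg
    ind, counts = filter_growth_outliers(ind)

    for (tissue, isotope) in ISOTOPE_KEYS:
        trait = TRAIT_OF_KEY[(tissue, isotope)]
        acol, dcol = f"atom_{trait}", f"delta_{trait}"
        if units == "delta" and dcol in ind.columns:
            vals = ind[dcol].to_numpy(float)
            ok = ~np.isnan(vals)
            atom = np.full_like(vals, np.nan)
            atom[ok] = delta_to_atom_percent(vals[ok], standards.ratio_for(isotope))
            ind[acol] = atom
        if acol not in ind.columns:
            continue
        ia = standards.baseline_mean[trait]
        sd = standards.baseline_sd.get(trait, 0.0)
        ape = ind[acol].to_numpy(float) - ia
        ind[f"ape_{trait}"] = ape
        # Slightly negative APE is measurement noise near baseline; far
        # below baseline it is an invalid record.
        ind[f"ape_{trait}_flag"] = np.select(
            [ape < -3.0 * sd, ape < 0.0], ["invalid", "negative_noise"], default=""
        )
        counts[f"ape_{trait}_invalid"] = int((ape < -3.0 * sd).sum())

    for (tissue, isotope) in indicator_keys:
        trait = TRAIT_OF_KEY[(tissue, isotope)]
        if f"ape_{trait}" not in ind.columns:
            raise KeyError(f"no isotope data for indicator key {(tissue, isotope)!r}")
        ifcr, ifer = indicator_ratios(
            ind["iw"].to_numpy(float), ind["fw"].to_numpy(float),
            ind[f"ape_{trait}"].to_numpy(float),
        )
        invalid = ind[f"ape_{trait}_flag"].to_numpy() == "invalid"
        ifcr = np.where(invalid, np.nan, ifcr)
        ifer = np.where(invalid, np.nan, ifer)
        ind[f"ifcr_{trait}"], ind[f"ifer_{trait}"] = ifcr, ifer

    tk = tanks.copy().set_index("tank", drop=False)
    usable = ind if include_filtered_in_fcr else ind[~ind["growth_missing"]]
    sum_wg = usable.groupby("tank")["wg"].sum()
    tk["sum_wg"] = sum_wg.reindex(tk.index)
    tk["fcr"] = [
        tank_fcr(fi, usable.loc[usable["tank"] == t, "wg"]) if t in sum_wg.index else np.nan
        for t, fi in zip(tk["tank"], tk["fi"])
    ]

    mean_traits = ["wg", "rg"] + [
        f"{p}_{TRAIT_OF_KEY[k]}" for k in ISOTOPE_KEYS for p in ("atom",)
        if f"atom_{TRAIT_OF_KEY[k]}" in ind.columns
    ] + [c for c in ind.columns if c.startswith(("ifcr_", "ifer_"))]
    for trait in mean_traits:
        source = usable if trait in ("wg", "rg") else ind[~ind["growth_missing"]]
        tm = tank_means(source.dropna(subset=[trait]), trait)
        colname = "mean_" + (trait[5:] if trait.startswith("atom_") else trait)
        tk[colname] = tm[trait].reindex(tk.index)

    return ind, tk.reset_index(drop=True), counts
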