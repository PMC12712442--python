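"""Trait-database curation: frost (LT50/LT0) and drought (P50) resistance.

Raw per-measurement tables are pandas DataFrames.  Frost tables require the
columns ``species, organ, method, value_C, date, lat, rate_C_per_h,
age_class`` (organ in {branch, bud, leaf}; method EL = electrolyte leakage,
yielding an LT50, or VS = visual scoring, yielding an LT0).  Drought tables
require ``species, organ, technique, curve_shape, p50_MPa, psi_tlp_MPa``
(organ in {stem, leaf}).

Curation proceeds by: midwinter filtering (maximum hardiness), freezing/
thawing-rate screening, per-(organ, method) averaging with a 6-level
priority selection for frost; curve-shape filtering, a 4-tier technique
priority and a turgor-loss-point consistency check for drought; and a
canonicalized full outer join into one row per species.  Every filter
returns a report dict so that input rows = output rows + dropped rows.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "SigmoidFit", "canonicalize_species",
    "filter_midwinter", "screen_rates", "fit_el_sigmoid",
    "curves_to_measurements", "select_frost_value",
    "filter_curve_shape", "select_p50_value", "tlp_consistency_filter",
    "merge_species_table", "curate_frost", "curate_drought",
    "MIDWINTER_WINDOW", "FROST_PRIORITY",
]

# middle of winter, per hemisphere (month numbers)
MIDWINTER_WINDOW: dict[str, frozenset[int]] = {
    "N": frozenset({12, 1, 2}),
    "S": frozenset({6, 7, 8}),
}

# selection priority: (method, organ) -> category 1..6
FROST_PRIORITY: dict[tuple[str, str], int] = {
    ("EL", "branch"): 1,
    ("EL", "bud"): 2,
    ("VS", "branch"): 3,
    ("VS", "bud"): 4,
    ("EL", "leaf"): 5,
    ("VS", "leaf"): 6,
}

P50_TIER1 = {"centrifuge", "optical", "microCT"}


def canonicalize_species(name: str) -> str:
    """Normalize a binomial: single spaces, genus capitalized, epithet lower."""
    parts = re.split(r"\s+", str(name).strip())
    if not parts or not parts[0]:
        raise ValueError(f"empty species name: {name!r}")
    genus = parts[0].capitalize()
    rest = [p.lower() for p in parts[1:]]
    return " ".join([genus] + rest)


def _canon_col(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["species"] = df["species"].map(canonicalize_species)
    return df


def _hemisphere(row: pd.Series) -> str | None:
    lat = row.get("lat")
    if lat is not None and pd.notna(lat):
        return "N" if float(lat) >= 0 else "S"
    hemi = row.get("hemisphere")
    if isinstance(hemi, str) and hemi in ("N", "S"):
        return hemi
    return None


def filter_midwinter(
    df: pd.DataFrame,
    window: dict[str, frozenset[int]] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Keep only measurements taken in the middle of winter.

    Hemisphere comes from the study latitude when present, else from a
    ``hemisphere`` column.  Rows with no usable date (or no hemisphere) are
    dropped and counted in the report.
    """
    window = window or MIDWINTER_WINDOW
    if any(len(m) == 0 for m in window.values()):
        raise ValueError("midwinter window must be nonempty per hemisphere")
    months = pd.to_datetime(df["date"], errors="coerce").dt.month
    hemis = df.apply(_hemisphere, axis=1)
    dateless = months.isna() | hemis.isna()
    in_window = pd.Series(
        [(not d) and (m in window[h])
         for d, m, h in zip(dateless, months, hemis)],
        index=df.index,
    )
    report = {
        "input_rows": int(len(df)),
        "dropped_no_date": int(dateless.sum()),
        "dropped_out_of_window": int(((~dateless) & (~in_window)).sum()),
        "kept_rows": int(in_window.sum()),
    }
    return df[in_window].copy(), report


def screen_rates(df: pd.DataFrame, lo: float = 0.2, hi: float = 9.0
                 ) -> tuple[pd.DataFrame, dict]:
    """Drop rows with freezing/thawing rates below ``lo`` or above ``hi``
    degC/h (boundaries inclusive-keep); rows with missing rate are retained
    and flagged in a ``rate_missing`` column."""
    if not lo < hi:
        raise ValueError("require lo < hi")
    rate = pd.to_numeric(df["rate_C_per_h"], errors="coerce")
    missing = rate.isna()
    bad = (~missing) & ((rate < lo) | (rate > hi))
    out = df[~bad].copy()
    out["rate_missing"] = missing[~bad].to_numpy()
    report = {
        "input_rows": int(len(df)),
        "dropped_rate_out_of_bounds": int(bad.sum()),
        "missing_rate_flagged": int(missing.sum()),
        "kept_rows": int(len(out)),
    }
    return out, report


@dataclass(frozen=True)
class SigmoidFit:
    """4-parameter logistic fit to an electrolyte-leakage curve."""

    lt50: float       # inflection temperature, degC
    baseline: float   # undamaged REL, %
    plateau: float    # fully damaged REL, %
    slope: float      # steepness, % per degC
    rss: float
    converged: bool


def _logistic(T, baseline, plateau, lt50, s):
    return baseline + (plateau - baseline) / (1.0 + np.exp(s * (T - lt50)))


def fit_el_sigmoid(temperatures, rel, min_span: float = 30.0) -> SigmoidFit:
    """Fit REL(T) = b + (p - b) / (1 + exp(s (T - lt50))) by least squares.

    Multi-start (5 starts seeded from data quantiles) robustified least
    squares; the inflection is the LT50.  Raises if fewer than 5 points,
    duplicate temperatures, or the REL span is below ``min_span`` percentage
    points (no damage transition observed; "flat curve").
    """
    T = np.asarray(temperatures, dtype=float)
    R = np.asarray(rel, dtype=float)
    if T.shape[0] != R.shape[0]:
        raise ValueError("temperatures and rel must have equal length")
    if T.shape[0] < 5:
        raise ValueError("need at least 5 points")
    if len(np.unique(T)) != len(T):
        raise ValueError("temperatures must be distinct")
    if np.any((R < 0) | (R > 100)):
        raise ValueError("rel values must lie in [0, 100]")
    if np.ptp(R) < min_span:
        raise ValueError(
            f"flat curve: REL span {np.ptp(R):.1f} < {min_span} points; "
            "no damage transition observed")

    lo, hi = float(np.min(R)), float(np.max(R))
    best = None
    for q in (0.2, 0.35, 0.5, 0.65, 0.8):
        lt50_0 = float(np.quantile(T, q))
        x0 = np.array([lo, hi, lt50_0, 0.5])
        try:
            res = least_squares(
                lambda p: _logistic(T, *p) - R, x0,
                bounds=([-np.inf, -np.inf, T.min() - 20.0, 1e-6],
                        [np.inf, np.inf, T.max() + 20.0, np.inf]),
                method="trf", max_nfev=2000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return SigmoidFit(np.nan, np.nan, np.nan, np.nan, np.inf, False)
    b, p, lt50, s = best.x
    if b > p:  # normalize orientation: baseline is the low-REL side
        b, p = p, b
    return SigmoidFit(float(lt50), float(b), float(p), float(s),
                      float(2.0 * best.cost), bool(best.success))


def curves_to_measurements(curves: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Fit every (species, sample_id) EL curve and emit frost measurement rows.

    ``curves`` is long-format with columns species, sample_id, temperature_C,
    rel_pct.  Curves that fail (flat, too few points) are counted, not fatal.
    Emitted rows have organ='branch', method='EL'.
    """
    rows, failed = [], 0
    for (sp, sid), grp in curves.groupby(["species", "sample_id"]):
        try:
            fit = fit_el_sigmoid(grp["temperature_C"], grp["rel_pct"])
        except ValueError:
            failed += 1
            continue
        if not fit.converged:
            failed += 1
            continue
        rows.append({"species": sp, "sample_id": sid, "organ": "branch",
                     "method": "EL", "value_C": fit.lt50})
    out = pd.DataFrame(rows, columns=["species", "sample_id", "organ",
                                      "method", "value_C"])
    return out, {"curves_fit": int(len(out)), "curves_failed": int(failed)}


def select_frost_value(df: pd.DataFrame) -> pd.DataFrame:
    """Per species: average within (organ, method) cells, then pick the cell
    with the best (lowest-numbered) priority.

    Returns a DataFrame ``species, lt50, lt50_category`` with exactly one row
    per species that has at least one recognized cell.
    """
    df = _canon_col(df)
    cells = (df.groupby(["species", "method", "organ"])["value_C"]
             .mean().reset_index())
    cells["category"] = [
        FROST_PRIORITY.get((m, o)) for m, o in zip(cells["method"], cells["organ"])
    ]
    cells = cells.dropna(subset=["category"])
    cells["category"] = cells["category"].astype(int)
    best = (cells.sort_values(["species", "category"], kind="mergesort")
            .groupby("species", sort=True).head(1))
    return (best.rename(columns={"value_C": "lt50", "category": "lt50_category"})
            [["species", "lt50", "lt50_category"]].reset_index(drop=True))


def filter_curve_shape(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Remove r-shaped vulnerability curves (open-vessel artifact); curves of
    unknown shape are retained with a ``shape_unknown`` flag."""
    shape = df["curve_shape"].astype(str)
    bad = shape == "r_shaped"
    out = df[~bad].copy()
    out["shape_unknown"] = (shape[~bad] == "unknown").to_numpy()
    report = {
        "input_rows": int(len(df)),
        "dropped_r_shaped": int(bad.sum()),
        "unknown_flagged": int((shape == "unknown").sum()),
        "kept_rows": int(len(out)),
    }
    return out, report


def select_p50_value(df: pd.DataFrame) -> pd.DataFrame:
    """Per-species P50 by technique priority.

    Tier 1: mean of stem values from centrifuge, optical and microCT;
    tier 2: mean stem bench-dehydration; tier 3: mean leaf values;
    tier 4: mean stem air-injection.  Also carries the species mean
    turgor-loss point (psi_tlp) for the downstream consistency filter.
    """
    df = _canon_col(df)
    rows = []
    for sp, grp in df.groupby("species", sort=True):
        stem = grp[grp["organ"] == "stem"]
        leaf = grp[grp["organ"] == "leaf"]
        tiers = [
            ("1", stem[stem["technique"].isin(P50_TIER1)]),
            ("2", stem[stem["technique"] == "bench_dehydration"]),
            ("3", leaf),
            ("4", stem[stem["technique"] == "air_injection"]),
        ]
        for tier, sel in tiers:
            if len(sel):
                tlp = pd.to_numeric(grp["psi_tlp_MPa"], errors="coerce").mean()
                rows.append({"species": sp,
                             "p50": float(sel["p50_MPa"].mean()),
                             "p50_source": f"tier{tier}",
                             "psi_tlp": float(tlp) if pd.notna(tlp) else np.nan})
                break
    return pd.DataFrame(rows, columns=["species", "p50", "p50_source", "psi_tlp"])


def tlp_consistency_filter(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Remove species whose P50 is higher (less negative) than their
    turgor-loss point; species without a psi_tlp are retained, flagged."""
    tlp = pd.to_numeric(df["psi_tlp"], errors="coerce")
    missing = tlp.isna()
    bad = (~missing) & (df["p50"] > tlp)
    out = df[~bad].copy()
    out["tlp_unchecked"] = missing[~bad].to_numpy()
    report = {
        "input_rows": int(len(df)),
        "dropped_p50_above_tlp": int(bad.sum()),
        "missing_tlp_flagged": int(missing.sum()),
        "kept_rows": int(len(out)),
    }
    return out, report


def _check_unique(df: pd.DataFrame, source: str) -> None:
    dup = df["species"][df["species"].duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate species in {source} input: {dup[:5]}")


def merge_species_table(
    frost: pd.DataFrame | None = None,
    drought: pd.DataFrame | None = None,
    other_traits: pd.DataFrame | None = None,
    climate: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full outer join of per-species tables on the canonical binomial.

    Raises on duplicate species within one source.  The report gives species
    counts per source and the frost-drought overlap.
    """
    sources = {"frost": frost, "drought": drought,
               "other_traits": other_traits, "climate": climate}
    merged = None
    report: dict = {"species_per_source": {}}
    for name, df in sources.items():
        if df is None:
            continue
        df = _canon_col(df)
        _check_unique(df, name)
        report["species_per_source"][name] = int(len(df))
        merged = df if merged is None else merged.merge(
            df, on="species", how="outer")
    if merged is None:
        raise ValueError("no input tables provided")
    if frost is not None and drought is not None:
        fs = set(_canon_col(frost)["species"])
        ds = set(_canon_col(drought)["species"])
        report["frost_drought_overlap"] = int(len(fs & ds))
    report["merged_species"] = int(len(merged))
    return merged.sort_values("species").reset_index(drop=True), report


def curate_frost(
    raw: pd.DataFrame,
    el_curves: pd.DataFrame | None = None,
    window: dict[str, frozenset[int]] | None = None,
    rate_lo: float = 0.2,
    rate_hi: float = 9.0,
) -> tuple[pd.DataFrame, dict]:
    """Full frost curation: midwinter filter -> rate screen -> (EL curve
    fits appended) -> per-species priority selection."""
    report: dict = {}
    df, report["midwinter"] = filter_midwinter(raw, window)
    df, report["rate_screen"] = screen_rates(df, rate_lo, rate_hi)
    if el_curves is not None and len(el_curves):
        fitted, report["el_curves"] = curves_to_measurements(el_curves)
        df = pd.concat([df, fitted], ignore_index=True)
    table = select_frost_value(df)
    report["species"] = int(len(table))
    report["genera"] = int(table["species"].str.split().str[0].nunique())
    report["category_counts"] = {
        int(k): int(v)
        for k, v in table["lt50_category"].value_counts().sort_index().items()
    }
    return table, report


def curate_drought(raw: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Full drought curation: curve-shape filter -> technique priority ->
    turgor-loss-point consistency filter."""
    report: dict = {}
    df, report["curve_shape"] = filter_curve_shape(raw)
    table = select_p50_value(df)
    table, report["tlp_filter"] = tlp_consistency_filter(table)
    report["species"] = int(len(table))
    return table.reset_index(drop=True), report
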