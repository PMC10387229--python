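"""Deterministic coding of intrinsic-capacity (IC) impairments and outcomes.

Six binary IC domain impairments are derived from raw measures with the
cut-points used throughout:

* locomotion    — walking speed < 0.8 m/s
* nutrition     — self-reported weight loss >= 4.5 kg in 3 months OR
                  mid-upper-arm circumference (MUAC) < 22 cm
* vision        — self-reported eyesight problems (incl. interviewer-identified
                  functional blindness, assumed pre-merged upstream)
* hearing       — self-reported hearing problems / deafness (same convention)
* cognition     — CSI-D COGSCORE < 29.5
* psychological — EURO-D depression symptom count > 3 (i.e. >= 4 of 12)

Outcomes:

* frailty (modified Fried phenotype) — >= 2 of 4 available components
  (weight loss, exhaustion, slow walk, low energy; grip strength unavailable)
* disability — WHODAS 2.0 score at or above a configurable threshold

Missingness is propagated, never coerced: a missing raw measure yields a
missing indicator.  The one deliberate asymmetry is the nutrition OR-rule:
a single confirmed criterion suffices for ``True`` even when the other
criterion is missing; the result is missing only when both are missing.
All columns use pandas' nullable ``boolean`` dtype.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "DOMAINS",
    "FRAILTY_COMPONENTS",
    "RAW_COLUMNS",
    "ValidationError",
    "code_impairments",
    "code_frailty",
    "code_disability",
    "read_raw_csv",
    "read_indicator_csv",
    "write_indicator_csv",
]

#: canonical domain order used everywhere downstream
DOMAINS = ("locomotion", "nutrition", "vision", "hearing", "cognition", "psychological")

FRAILTY_COMPONENTS = ("weight_loss", "exhaustion", "slow_walk", "low_energy")

#: column dictionary for raw-measure CSV tables
RAW_COLUMNS = {
    "walk_speed": "usual walking speed, m/s (timed 5 m walk)",
    "weight_loss": "self-reported weight loss >= 4.5 kg in last 3 months (0/1)",
    "muac": "mid-upper-arm circumference, cm",
    "vision_problem": "self-reported eyesight problems limiting activities (0/1)",
    "hearing_problem": "self-reported hearing problems or deafness (0/1)",
    "cogscore": "CSI-D COGSCORE (0-34)",
    "eurod": "EURO-D depression symptom count (0-12)",
    "exhaustion": "frailty component: exhaustion (0/1)",
    "low_energy": "frailty component: low energy expenditure (0/1)",
}

WALK_SPEED_CUT = 0.8  # m/s, strict <
MUAC_CUT = 22.0  # cm, strict <
COGSCORE_CUT = 29.5  # strict <
EUROD_CUT = 3  # strict >, i.e. >= 4 symptoms


class ValidationError(ValueError):
    """Raised when a raw measure violates its declared range."""


def _as_nullable_bool(s: pd.Series) -> pd.Series:
    """Coerce a 0/1/True/False column with NaN to pandas nullable boolean."""
    return s.astype("Float64").astype("boolean")


def _check_range(s: pd.Series, name: str, lo=None, hi=None, strict_lo: bool = False) -> None:
    if lo is not None:
        bad = (s <= lo) if strict_lo else (s < lo)
        bad = bad.fillna(False)
        if bad.any():
            rows = list(s.index[bad][:5])
            raise ValidationError(f"{name} out of range (must be {'>' if strict_lo else '>='} {lo}) at rows {rows}")
    if hi is not None:
        bad = (s > hi).fillna(False)
        if bad.any():
            rows = list(s.index[bad][:5])
            raise ValidationError(f"{name} out of range (must be <= {hi}) at rows {rows}")


def code_impairments(raw: pd.DataFrame) -> pd.DataFrame:
    """Code the six binary IC impairments from a raw-measure table.

    Parameters
    ----------
    raw : DataFrame with (a subset of) the columns in :data:`RAW_COLUMNS`.
        Missing values may be NaN/NA or, in CSV files, empty fields.

    Returns
    -------
    DataFrame indexed like ``raw`` with the six :data:`DOMAINS` columns,
    nullable boolean dtype.
    """
    out = pd.DataFrame(index=raw.index)

    walk = raw["walk_speed"].astype("Float64")
    _check_range(walk, "walk_speed", lo=0.0)
    out["locomotion"] = walk < WALK_SPEED_CUT

    wl = _as_nullable_bool(raw["weight_loss"])
    muac = raw["muac"].astype("Float64")
    _check_range(muac, "muac", lo=0.0, strict_lo=True)
    muac_low = muac < MUAC_CUT
    # OR with asymmetric missingness: one confirmed criterion suffices
    nutrition = wl | muac_low  # Kleene logic: True|NA -> True, False|NA -> NA
    out["nutrition"] = nutrition

    out["vision"] = _as_nullable_bool(raw["vision_problem"])
    out["hearing"] = _as_nullable_bool(raw["hearing_problem"])

    cog = raw["cogscore"].astype("Float64")
    out["cognition"] = cog < COGSCORE_CUT

    eurod = raw["eurod"].astype("Float64")
    _check_range(eurod, "eurod", lo=0, hi=12)
    out["psychological"] = eurod > EUROD_CUT

    return out.astype("boolean")


def code_frailty(components: pd.DataFrame) -> pd.Series:
    """Modified Fried phenotype: frail iff >= 2 of the 4 components present.

    Any missing component makes the result missing (never ``False``): with a
    component unknown the >= 2 criterion can neither be confirmed in general
    nor excluded.
    """
    comp = components[list(FRAILTY_COMPONENTS)].astype("Float64")
    n_true = comp.sum(axis=1)  # Float64 sum propagates NA
    frail = (n_true >= 2).astype("boolean")
    frail[comp.isna().any(axis=1)] = pd.NA
    return frail


def code_disability(whodas_score: pd.Series, threshold: float) -> pd.Series:
    """Disability: WHODAS 2.0 score at or above ``threshold`` (inclusive).

    The threshold is a configuration parameter; missing scores yield missing.
    """
    score = pd.Series(whodas_score).astype("Float64")
    return (score >= threshold).astype("boolean")


# ---------------------------------------------------------------------------
# CSV dialect: comma-separated, missing encoded as empty field, optional
# comment header lines starting with '#'.
# ---------------------------------------------------------------------------

def read_raw_csv(path) -> pd.DataFrame:
    """Read a raw-measure table (columns per :data:`RAW_COLUMNS`)."""
    return pd.read_csv(path, comment="#")


def indicator_columns(waves=(1, 2)) -> list[str]:
    return [f"{d}_w{t}" for t in waves for d in DOMAINS]


def read_indicator_csv(path) -> pd.DataFrame:
    """Read a two-wave indicator table (``<domain>_w1``/``_w2`` columns)."""
    df = pd.read_csv(path, comment="#")
    for c in indicator_columns():
        if c in df.columns:
            df[c] = _as_nullable_bool(df[c])
    return df


def write_indicator_csv(df: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    """Write indicators/outcomes; booleans as 0/1, missing as empty field."""
    out = df.copy()
    for c in out.columns:
        if str(out[c].dtype) == "boolean":
            out[c] = out[c].astype("Float64")
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        out.to_csv(fh, index=False)
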