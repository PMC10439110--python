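"""Classify environments against phage ion requirements.

For each (phage, ion) threshold and each environmental profile, an ion is
``permissive`` when its ambient concentration meets or exceeds the phage's
half-maximal requirement and ``limiting`` otherwise; limiting verdicts carry
the fold deficit (threshold / concentration).  The boundary convention is
inclusive: a concentration exactly at the EC50 is permissive, since the EC50
is a half-maximal point rather than a hard floor.
"""

from __future__ import annotations

import math

import pandas as pd

from .errors import SchemaError
from .ions import IonProfile

__all__ = ["classify_environment", "summarize_environments"]


def _threshold_items(thresholds) -> list[tuple[str, str, float]]:
    if isinstance(thresholds, pd.DataFrame):
        return [
            (str(r["phage"]), str(r["ion"]), float(r["threshold_mM"]))
            for _, r in thresholds.iterrows()
        ]
    return [(p, i, float(t)) for (p, i), t in thresholds.items()]


def classify_environment(profile: IonProfile, thresholds) -> pd.DataFrame:
    """Per-(phage, ion) verdicts for one environment.

    ``thresholds`` maps (phage, ion) -> mM (dict or a DataFrame with columns
    phage/ion/threshold_mM).  Only ions present in the profile are judged;
    the profile must contain at least one threshold ion.
    """
    items = _threshold_items(thresholds)
    if not items:
        raise SchemaError("thresholds table is empty")
    if not profile.concentrations:
        raise SchemaError(f"profile {profile.name!r} is empty")
    rows = []
    for phage, ion, thr in sorted(items):
        if ion not in profile.concentrations:
            continue
        conc = profile.concentrations[ion]
        permissive = conc >= thr
        rows.append(
            {
                "environment": profile.name,
                "category": profile.category,
                "phage": phage,
                "ion": ion,
                "conc_mM": conc,
                "threshold_mM": thr,
                "status": "permissive" if permissive else "limiting",
                "fold_deficit": math.nan if permissive
                else (thr / conc if conc > 0 else math.inf),
            }
        )
    if not rows:
        raise SchemaError(
            f"profile {profile.name!r} shares no ion with the thresholds table"
        )
    return pd.DataFrame(rows)


def summarize_environments(
    profiles: list[IonProfile], thresholds
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Verdicts plus per-environment and per-category summaries.

    Returns ``(verdicts, by_environment, by_category)``:

    * ``verdicts`` — all per-(environment, phage, ion) rows;
    * ``by_environment`` — one row per (environment, phage) with
      ``any_permissive_ion``; ordered by category then name;
    * ``by_category`` — fraction of environments in each category with at
      least one permissive ion for at least one phage.
    """
    if not profiles:
        raise SchemaError("need at least one profile")
    ordered = sorted(profiles, key=lambda p: (p.category, p.name))
    verdicts = pd.concat(
        [classify_environment(p, thresholds) for p in ordered], ignore_index=True
    )
    by_env = (
        verdicts.assign(permissive=verdicts["status"] == "permissive")
        .groupby(["category", "environment", "phage"], sort=True)["permissive"]
        .any()
        .rename("any_permissive_ion")
        .reset_index()
    )
    env_any = (
        by_env.groupby(["category", "environment"], sort=True)["any_permissive_ion"]
        .any()
        .reset_index()
    )
    by_cat = (
        env_any.groupby("category", sort=True)["any_permissive_ion"]
        .mean()
        .rename("fraction_permissive")
        .reset_index()
    )
    return verdicts, by_env, by_cat
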