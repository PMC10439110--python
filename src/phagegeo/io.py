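"""Plain-text readers and writers for the pipeline's tables.

Formats: plate assays as CSV, fits/thresholds/community/effect tables as
TSV, truth sidecars / profiles / capability flags as JSON.  All readers
return the same in-memory objects the generators produce, so real exports
in the same schema drop in unchanged.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd

from .community import CapabilityTable, TaxonCapability
from .dose_response import FourPLFit, ThresholdCall
from .errors import SchemaError
from .ions import IonProfile
from .synthetic import CurveTruth, PlateTruth

PLATE_COLUMNS = ["well", "ion", "salt_formula", "conc_mM", "phage", "replicate", "od600"]

__all__ = [
    "read_plate_csv", "write_plate_csv",
    "read_truth_json", "write_truth_json",
    "fits_to_frame", "write_fits_tsv", "read_thresholds_tsv",
    "read_profiles_json", "write_profiles_json",
    "read_community_tables", "write_community_tables",
    "read_capabilities_json", "write_capabilities_json",
]


def write_plate_csv(plate: pd.DataFrame, path) -> None:
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise SchemaError(f"plate table missing columns: {missing}")
    plate.to_csv(path, index=False)


def read_plate_csv(path) -> pd.DataFrame:
    plate = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return plate


def write_truth_json(truth: PlateTruth, path) -> None:
    payload = {
        "noise_sd": truth.noise_sd,
        "seed": truth.seed,
        "curves": {
            f"{ion}|{phage}": {
                "ec50": c.ec50, "hill": c.hill, "top": c.top, "bottom": c.bottom
            }
            for (ion, phage), c in sorted(truth.curves.items())
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth_json(path) -> PlateTruth:
    payload = json.loads(Path(path).read_text())
    curves = {
        tuple(key.split("|", 1)): CurveTruth(**params)
        for key, params in payload["curves"].items()
    }
    return PlateTruth(
        curves=curves, noise_sd=payload["noise_sd"], seed=payload["seed"]
    )


def fits_to_frame(
    fits: list[FourPLFit], calls: list[ThresholdCall] | None = None
) -> pd.DataFrame:
    cls = {}
    if calls:
        for call in calls:
            cls[(call.ion, call.ec50_fit.phage)] = call.classification
            cls.setdefault((call.ion, call.ic50_fit.phage), call.classification)
    rows = [
        {
            "ion": f.ion,
            "phage": f.phage,
            "half_max_mM": f.half_max,
            "ci_low": f.ci_low,
            "ci_high": f.ci_high,
            "hill": f.hill,
            "top": f.top,
            "bottom": f.bottom,
            "rss": f.rss,
            "converged": f.converged,
            "direction": f.direction,
            "no_inhibition": f.no_inhibition,
            "classification": cls.get((f.ion, f.phage), ""),
        }
        for f in sorted(fits, key=lambda f: (f.ion, f.phage))
    ]
    return pd.DataFrame(rows)


def write_fits_tsv(fits, calls, path) -> None:
    fits_to_frame(fits, calls).to_csv(path, sep="\t", index=False)


def read_thresholds_tsv(path) -> dict[tuple[str, str], float]:
    """Thresholds TSV (columns phage, ion, threshold_mM[, source]) as the
    mapping the classification and hot-spot modules consume."""
    tab = pd.read_csv(path, sep="\t")
    required = {"phage", "ion", "threshold_mM"}
    if not required <= set(tab.columns):
        raise SchemaError(f"{path}: need columns {sorted(required)}")
    return {
        (str(r["phage"]), str(r["ion"])): float(r["threshold_mM"])
        for _, r in tab.iterrows()
        if math.isfinite(float(r["threshold_mM"]))
    }


def write_profiles_json(profiles: list[IonProfile], path) -> None:
    payload = [
        {
            "name": p.name,
            "category": p.category,
            "concentrations_mM": p.concentrations,
            "charges": p.charges,
        }
        for p in profiles
    ]
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_profiles_json(path) -> list[IonProfile]:
    payload = json.loads(Path(path).read_text())
    return [
        IonProfile(
            name=entry["name"],
            category=entry.get("category", "uncategorized"),
            concentrations={k: float(v) for k, v in entry["concentrations_mM"].items()},
            charges={k: int(v) for k, v in entry["charges"].items()},
        )
        for entry in payload
    ]


def write_community_tables(
    community: pd.DataFrame, metadata: pd.DataFrame, community_path, metadata_path
) -> None:
    community.to_csv(community_path, sep="\t")
    metadata.to_csv(metadata_path, sep="\t")


def read_community_tables(community_path, metadata_path):
    community = pd.read_csv(community_path, sep="\t", index_col=0)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    required = {"carbon_source", "phage", "replicate", "ammonium_mM"}
    if not required <= set(metadata.columns):
        raise SchemaError(f"{metadata_path}: need columns {sorted(required)}")
    return community, metadata


def write_capabilities_json(caps: CapabilityTable, path) -> None:
    payload = {
        taxon: {
            "can_nitrate_to_nitrite": c.can_nitrate_to_nitrite,
            "can_nitrite_to_ammonium": c.can_nitrite_to_ammonium,
            "phage_targeted": c.phage_targeted,
        }
        for taxon, c in sorted(caps.taxa.items())
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_capabilities_json(path) -> CapabilityTable:
    payload = json.loads(Path(path).read_text())
    return CapabilityTable(
        taxa={taxon: TaxonCapability(**flags) for taxon, flags in payload.items()}
    )
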