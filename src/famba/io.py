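"""CSV schemas and writers binding the analysis stages together.

Profiles travel as a long-format table {matrix_label, fatty_acid,
percent} with a sidecar metadata table {matrix_label,
total_fa_content_mg_per_g_lipid, lipid_g_per_g_dm, dm_g_per_g}; tanks,
markers and per-FA digestibilities have flat one-row-per-record
schemas.  Output files carry a comment header block with the tool
version, the seed and a hash of the configuration so runs are
traceable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .fatty_acids import FAProfile
from .trial_metrics import TankRecord

__all__ = [
    "read_profiles",
    "write_profiles",
    "read_tanks",
    "write_tanks",
    "read_ad",
    "write_frame",
    "config_hash",
]


def read_profiles(profiles_csv, metadata_csv=None) -> dict[str, FAProfile]:
    """Read long-format composition CSV (+ optional sidecar metadata)."""
    long = pd.read_csv(profiles_csv, comment="#")
    meta = pd.read_csv(metadata_csv, comment="#").set_index("matrix_label") if metadata_csv else None
    out: dict[str, FAProfile] = {}
    for label, grp in long.groupby("matrix_label"):
        kwargs = {}
        if meta is not None and label in meta.index:
            row = meta.loc[label]
            kwargs = {
                "total_fa_content": _opt(row.get("total_fa_content_mg_per_g_lipid")),
                "lipid_content": _opt(row.get("lipid_g_per_g_dm")),
                "dry_matter": _opt(row.get("dm_g_per_g")),
            }
        out[label] = FAProfile(
            matrix_label=label,
            composition=dict(zip(grp["fatty_acid"], grp["percent"].astype(float))),
            **kwargs,
        )
    return out


def _opt(v):
    return None if v is None or pd.isna(v) else float(v)


def write_profiles(profiles: Mapping[str, FAProfile], profiles_csv, metadata_csv,
                   header: str = "") -> None:
    rows = [
        {"matrix_label": label, "fatty_acid": fa, "percent": pct}
        for label, p in profiles.items()
        for fa, pct in p.composition.items()
    ]
    meta = [
        {
            "matrix_label": label,
            "total_fa_content_mg_per_g_lipid": p.total_fa_content,
            "lipid_g_per_g_dm": p.lipid_content,
            "dm_g_per_g": p.dry_matter,
        }
        for label, p in profiles.items()
    ]
    write_frame(pd.DataFrame(rows), profiles_csv, header)
    write_frame(pd.DataFrame(meta), metadata_csv, header)


def read_tanks(tanks_csv, marker_csv=None) -> list[TankRecord]:
    """Read tanks.csv {tank_id, system_id, diet, n_fish, wi_g, wf_g,
    fi_g, days[, fl_cm]} and optional marker.csv {tank_id, analyte,
    diet_conc, faeces_conc}."""
    tanks = pd.read_csv(tanks_csv, comment="#")
    markers: dict[str, dict[str, tuple[float, float]]] = {}
    if marker_csv is not None:
        m = pd.read_csv(marker_csv, comment="#")
        for _, r in m.iterrows():
            markers.setdefault(str(r["tank_id"]), {})[r["analyte"]] = (
                float(r["diet_conc"]),
                float(r["faeces_conc"]),
            )
    out = []
    for _, r in tanks.iterrows():
        tid = str(r["tank_id"])
        out.append(
            TankRecord(
                tank_id=tid,
                diet=str(r["diet"]),
                system_id=str(r["system_id"]) if "system_id" in tanks.columns else None,
                n_fish=int(r["n_fish"]) if "n_fish" in tanks.columns and pd.notna(r.get("n_fish")) else None,
                wi_g=float(r["wi_g"]),
                wf_g=float(r["wf_g"]),
                fi_g=float(r["fi_g"]),
                days=int(r["days"]),
                fl_cm=float(r["fl_cm"]) if "fl_cm" in tanks.columns and pd.notna(r.get("fl_cm")) else None,
                marker=markers.get(tid, {}),
            )
        )
    return out


def write_tanks(tanks: Iterable[TankRecord], tanks_csv, marker_csv=None,
                header: str = "") -> None:
    rows, mrows = [], []
    for t in tanks:
        rows.append(
            {
                "tank_id": t.tank_id,
                "system_id": t.system_id,
                "diet": t.diet,
                "n_fish": t.n_fish,
                "wi_g": t.wi_g,
                "wf_g": t.wf_g,
                "fi_g": t.fi_g,
                "days": t.days,
                "fl_cm": t.fl_cm,
            }
        )
        for analyte, (dc, fc) in t.marker.items():
            mrows.append(
                {"tank_id": t.tank_id, "analyte": analyte, "diet_conc": dc, "faeces_conc": fc}
            )
    write_frame(pd.DataFrame(rows), tanks_csv, header)
    if marker_csv is not None:
        write_frame(pd.DataFrame(mrows), marker_csv, header)


def read_ad(ad_csv) -> dict[str, dict[str, float]]:
    """Read ad.csv {diet, fatty_acid, ad_percent} into nested maps."""
    df = pd.read_csv(ad_csv, comment="#")
    out: dict[str, dict[str, float]] = {}
    for _, r in df.iterrows():
        out.setdefault(str(r["diet"]), {})[str(r["fatty_acid"])] = float(r["ad_percent"])
    return out


def config_hash(config) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_frame(frame: pd.DataFrame, path, header: str = "") -> None:
    """Write a CSV with an optional '#'-comment header block."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        frame.to_csv(fh, index=not isinstance(frame.index, pd.RangeIndex))
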