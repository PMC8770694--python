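"""Landmark, tree and metadata I/O with cross-validation.

Two landmark dialects are supported: long-format CSV (columns specimen,
landmark, x, y, z, plus optional species/sex/scan_type) and the TPS
convention (LM3= blocks followed by coordinate triples and ID= lines).
Missing landmarks are coded as blank cells in CSV and as the conventional
-9999 triple in TPS; both are unified into a boolean ``missing_mask``.

Landmarks are numbered 1-based in every user-facing label or index and
0-based in arrays; converters sit at this boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .trees import read_tree, read_tree_string, prune_and_match, tip_labels  # noqa: F401

MISSING_TPS = -9999.0
SEX_LEVELS = ("male", "female", "unknown")
SCAN_LEVELS = ("surface", "ct")
DIET_LEVELS = ("browser", "grazer", "mixed", "frugivore")
SUBFAMILY_LEVELS = ("Bovinae", "Antilopinae")


class LandmarkFormatError(ValueError):
    """Malformed landmark file (inconsistent counts, bad TPS block...)."""


class DatasetValidationError(ValueError):
    """Cross-reference failures that cannot be reported as warnings."""


@dataclass
class LandmarkConfiguration:
    """One specimen's named 3D landmark set, in scanner units (mm)."""

    specimen_id: str
    species: str
    coords: np.ndarray  # (k, 3)
    landmark_labels: list[str]
    missing_mask: np.ndarray  # (k,) bool
    sex: str = "unknown"
    scan_type: str = "surface"
    estimated_landmarks: list[int] = field(default_factory=list)  # 1-based, provenance

    def __post_init__(self):
        self.coords = np.array(self.coords, dtype=float, copy=True)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (k, 3)")
        k = self.coords.shape[0]
        if k < 3:
            raise ValueError("need at least 3 landmarks")
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != (k,):
            raise ValueError("missing_mask length must equal landmark count")
        if len(self.landmark_labels) != k:
            raise ValueError("landmark_labels length must equal landmark count")
        if len(set(self.landmark_labels)) != k:
            raise ValueError("landmark_labels must be unique")
        if self.sex not in SEX_LEVELS:
            raise ValueError(f"sex must be one of {SEX_LEVELS}")
        if self.scan_type not in SCAN_LEVELS:
            raise ValueError(f"scan_type must be one of {SCAN_LEVELS}")
        # missing rows carry no finite values
        self.coords[self.missing_mask] = np.nan

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    @property
    def is_complete(self) -> bool:
        return not self.missing_mask.any()

    def landmark(self, number: int) -> np.ndarray:
        """Coordinates of 1-based landmark ``number``."""
        if not 1 <= number <= self.n_landmarks:
            raise IndexError(f"landmark {number} out of range 1..{self.n_landmarks}")
        return self.coords[number - 1]


def default_landmark_labels(k: int) -> list[str]:
    return [f"lm{str(i).zfill(2)}" for i in range(1, k + 1)]


# ---------------------------------------------------------------------------
# landmark readers / writers


def read_landmarks(path, dialect: str | None = None) -> list[LandmarkConfiguration]:
    """Read landmark configurations from a CSV or TPS file.

    ``dialect`` is inferred from the extension when omitted. All specimens
    must share one landmark count; duplicate specimen ids are rejected.
    """
    path = Path(path)
    if dialect is None:
        dialect = "tps" if path.suffix.lower() == ".tps" else "csv"
    if dialect == "csv":
        configs = _read_landmarks_csv(path)
    elif dialect == "tps":
        configs = _read_landmarks_tps(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    counts = {c.n_landmarks for c in configs}
    if len(counts) > 1:
        raise LandmarkFormatError(f"inconsistent landmark counts across specimens: {sorted(counts)}")
    ids = [c.specimen_id for c in configs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DatasetValidationError(f"duplicate specimen ids: {', '.join(dupes)}")
    return configs


def _read_landmarks_csv(path: Path) -> list[LandmarkConfiguration]:
    df = pd.read_csv(path, dtype={"specimen": str, "landmark": str})
    required = {"specimen", "landmark", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise LandmarkFormatError(f"CSV must have columns {sorted(required)}; got {list(df.columns)}")
    configs = []
    for spec_id, grp in df.groupby("specimen", sort=False):
        if grp["landmark"].duplicated().any():
            raise DatasetValidationError(
                f"duplicate specimen id or repeated landmarks: {spec_id}"
            )
        coords = grp[["x", "y", "z"]].to_numpy(dtype=float)
        mask = ~np.isfinite(coords).all(axis=1)
        labels = grp["landmark"].tolist()
        species = str(grp["species"].iloc[0]) if "species" in grp else "unknown"
        sex = str(grp["sex"].iloc[0]) if "sex" in grp else "unknown"
        scan = str(grp["scan_type"].iloc[0]) if "scan_type" in grp else "surface"
        configs.append(
            LandmarkConfiguration(
                specimen_id=str(spec_id), species=species, coords=coords,
                landmark_labels=labels, missing_mask=mask, sex=sex, scan_type=scan,
            )
        )
    return configs


def _read_landmarks_tps(path: Path) -> list[LandmarkConfiguration]:
    configs = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM3="):
            raise LandmarkFormatError(f"expected LM3= block at line {i + 1}, got {line!r}")
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise LandmarkFormatError(f"bad LM3 count at line {i + 1}") from exc
        i += 1
        coords = np.empty((k, 3))
        for j in range(k):
            parts = lines[i].split()
            if len(parts) != 3:
                raise LandmarkFormatError(f"expected 3 coordinates at line {i + 1}")
            coords[j] = [float(v) for v in parts]
            i += 1
        meta = {"ID": f"specimen{len(configs) + 1}", "SPECIES": "unknown",
                "SEX": "unknown", "SCANTYPE": "surface"}
        while i < len(lines) and lines[i].strip() and "=" in lines[i] and not lines[i].upper().startswith("LM3="):
            key, _, val = lines[i].partition("=")
            meta[key.strip().upper()] = val.strip()
            i += 1
        mask = np.all(coords == MISSING_TPS, axis=1)
        configs.append(
            LandmarkConfiguration(
                specimen_id=meta["ID"], species=meta["SPECIES"], coords=coords,
                landmark_labels=default_landmark_labels(k), missing_mask=mask,
                sex=meta["SEX"], scan_type=meta["SCANTYPE"],
            )
        )
    return configs


def write_landmarks(configs: list[LandmarkConfiguration], path, dialect: str | None = None) -> None:
    """Write configurations to CSV or TPS (coordinates at 6 decimals)."""
    path = Path(path)
    if dialect is None:
        dialect = "tps" if path.suffix.lower() == ".tps" else "csv"
    if dialect == "csv":
        rows = []
        for c in configs:
            for j in range(c.n_landmarks):
                x, y, z = c.coords[j]
                rows.append({
                    "specimen": c.specimen_id, "species": c.species,
                    "landmark": c.landmark_labels[j],
                    "x": "" if c.missing_mask[j] else f"{x:.6f}",
                    "y": "" if c.missing_mask[j] else f"{y:.6f}",
                    "z": "" if c.missing_mask[j] else f"{z:.6f}",
                    "sex": c.sex, "scan_type": c.scan_type,
                })
        pd.DataFrame(rows).to_csv(path, index=False)
    elif dialect == "tps":
        out = []
        for c in configs:
            out.append(f"LM3={c.n_landmarks}")
            for j in range(c.n_landmarks):
                if c.missing_mask[j]:
                    out.append(f"{MISSING_TPS:.6f} {MISSING_TPS:.6f} {MISSING_TPS:.6f}")
                else:
                    x, y, z = c.coords[j]
                    out.append(f"{x:.6f} {y:.6f} {z:.6f}")
            out.append(f"ID={c.specimen_id}")
            out.append(f"SPECIES={c.species}")
            out.append(f"SEX={c.sex}")
            out.append(f"SCANTYPE={c.scan_type}")
        Path(path).write_text("\n".join(out) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# species table


def read_species_table(path) -> pd.DataFrame:
    """Species-level trait table: tribe, subfamily, diet, hypsodonty, body mass."""
    df = pd.read_csv(path)
    return validate_species_table(df)


def validate_species_table(df: pd.DataFrame) -> pd.DataFrame:
    if "species" not in df.columns:
        raise DatasetValidationError("species table needs a 'species' column")
    if df["species"].duplicated().any():
        dupes = df.loc[df["species"].duplicated(), "species"].tolist()
        raise DatasetValidationError(f"duplicate species rows: {dupes}")
    if "diet" in df.columns:
        bad = set(df["diet"].dropna()) - set(DIET_LEVELS)
        if bad:
            raise DatasetValidationError(f"unknown diet categories: {sorted(bad)}")
    if "subfamily" in df.columns:
        bad = set(df["subfamily"].dropna()) - set(SUBFAMILY_LEVELS)
        if bad:
            raise DatasetValidationError(f"unknown subfamilies: {sorted(bad)}")
    if "hypsodonty" in df.columns and (df["hypsodonty"].dropna() < 0).any():
        raise DatasetValidationError("hypsodonty must be >= 0")
    return df


# ---------------------------------------------------------------------------
# dataset-level validation


@dataclass
class ValidationReport:
    issues: list[str]
    multi_specimen_species: dict[str, int]
    counts_by_sex: dict[str, int]
    counts_by_scan_type: dict[str, int]
    n_specimens: int
    n_species: int

    @property
    def ok(self) -> bool:
        return not self.issues

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.__dict__, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def validate_dataset(configs, species_table: pd.DataFrame | None = None, tree=None) -> ValidationReport:
    """Cross-check landmark configs against the species table and tree.

    Report-only: lists orphan species on either side, flags multi-specimen
    species (candidates for the random one-per-species subset) and tallies
    sex and scan-type composition.
    """
    issues: list[str] = []
    config_species = [c.species for c in configs]
    uniq = sorted(set(config_species))
    if species_table is not None:
        table_species = set(species_table["species"])
        for sp in uniq:
            if sp not in table_species:
                issues.append(f"species {sp} in landmark data but not in species table")
        for sp in sorted(table_species - set(uniq)):
            issues.append(f"species {sp} in species table but has no specimens")
    if tree is not None:
        tips = set(tip_labels(tree))
        for sp in uniq:
            if sp not in tips:
                issues.append(f"species {sp} in landmark data but not on tree")
    counts = pd.Series(config_species).value_counts()
    multi = {sp: int(n) for sp, n in counts.items() if n > 1}
    sex_counts = pd.Series([c.sex for c in configs]).value_counts().to_dict()
    scan_counts = pd.Series([c.scan_type for c in configs]).value_counts().to_dict()
    return ValidationReport(
        issues=issues,
        multi_specimen_species=dict(sorted(multi.items())),
        counts_by_sex={k: int(v) for k, v in sex_counts.items()},
        counts_by_scan_type={k: int(v) for k, v in scan_counts.items()},
        n_specimens=len(configs),
        n_species=len(uniq),
    )
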