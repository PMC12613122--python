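"""Metal-centered and condition descriptors, preprocessing, feature assembly.

The full feature table concatenates four blocks per complex — the 40
quantum-chemistry descriptors, 24 structure descriptors, 6 metal-centered
descriptors and 3 external-condition descriptors — next to the measured
singlet-oxygen quantum yield target.
"""

from __future__ import annotations

import difflib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .excited import QCD_COLUMNS, QCDRecord
from .structure import STRUCTURE_COLUMNS, StructureDescriptorRecord

__all__ = [
    "MetalDescriptorRecord",
    "ConditionDescriptorRecord",
    "SampleRecord",
    "FeatureTable",
    "METAL_COLUMNS",
    "CONDITION_COLUMNS",
    "ALL_DESCRIPTOR_COLUMNS",
    "metal_descriptors",
    "condition_descriptors",
    "known_solvents",
    "preprocess_dataset",
    "assemble_feature_table",
]

METAL_COLUMNS = ("cn", "cp", "mc", "cf", "cd", "cs")
CONDITION_COLUMNS = ("eps", "epsinf", "wl")
ALL_DESCRIPTOR_COLUMNS = tuple(QCD_COLUMNS) + STRUCTURE_COLUMNS + METAL_COLUMNS + CONDITION_COLUMNS

TARGET_COLUMN = "phi_delta"


def _load_json(name: str) -> dict:
    with resources.files("soqy.data").joinpath(name).open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class MetalDescriptorRecord:
    """Metal-centered descriptors: count, period, charge, free-atom f/d/s."""

    cn: int
    cp: int
    mc: int
    cf: int
    cd: int
    cs: int

    def as_dict(self) -> dict[str, int]:
        return {k: getattr(self, k) for k in METAL_COLUMNS}


@dataclass(frozen=True)
class ConditionDescriptorRecord:
    """Solvent dielectric constants and irradiation wavelength (nm)."""

    eps: float
    epsinf: float
    wl: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in CONDITION_COLUMNS}


def metal_descriptors(element: str, metal_charge: int = 0, metal_count: int = 1) -> MetalDescriptorRecord:
    """Descriptors of the metal center from the free neutral atom.

    Period and s/d/f electron counts come from the bundled ground-state
    configuration table (e.g. Ru, [Kr]4d7 5s1: cp=5, cs=1, cd=7, cf=0);
    charge and count are annotations passed through.
    """
    table = _load_json("metal_configurations.json")["elements"]
    if element not in table:
        raise KeyError(
            f"unknown metal {element!r}; supported: {', '.join(sorted(table))}"
        )
    cfg = table[element]
    return MetalDescriptorRecord(
        cn=int(metal_count), cp=cfg["period"], mc=int(metal_charge),
        cf=cfg["cf"], cd=cfg["cd"], cs=cfg["cs"],
    )


def known_solvents() -> list[str]:
    return sorted(_load_json("solvents.json")["solvents"])


def condition_descriptors(solvent: str, wavelength_nm: float) -> ConditionDescriptorRecord:
    """Dielectric constants of ``solvent`` plus the irradiation wavelength."""
    if wavelength_nm <= 0:
        raise ValueError(f"irradiation wavelength must be positive, got {wavelength_nm}")
    data = _load_json("solvents.json")
    key = solvent.strip().lower()
    key = data["aliases"].get(key, key)
    if key not in data["solvents"]:
        hint = difflib.get_close_matches(key, list(data["solvents"]) + list(data["aliases"]), n=1)
        extra = f"; did you mean {hint[0]!r}?" if hint else ""
        raise KeyError(f"unknown solvent {solvent!r}{extra}")
    s = data["solvents"][key]
    return ConditionDescriptorRecord(eps=s["eps"], epsinf=s["epsinf"], wl=float(wavelength_nm))


@dataclass(frozen=True)
class SampleRecord:
    """One complex: all four descriptor blocks plus the measured target."""

    identifier: str
    qcd: QCDRecord
    structure: StructureDescriptorRecord
    metal: MetalDescriptorRecord
    condition: ConditionDescriptorRecord
    phi_delta: float
    metal_element: str = ""
    source: str = "internal"

    def __post_init__(self) -> None:
        if not (0 < self.phi_delta <= 1):
            raise ValueError(
                f"{self.identifier}: phi_delta must be in (0, 1], got {self.phi_delta}"
            )

    def as_row(self) -> dict:
        row: dict = {"identifier": self.identifier}
        row.update(self.qcd.as_row())
        row.update(self.structure.as_dict())
        row.update(self.metal.as_dict())
        row.update(self.condition.as_dict())
        row[TARGET_COLUMN] = self.phi_delta
        row["metal_element"] = self.metal_element
        row["source"] = self.source
        return row


@dataclass
class FeatureTable:
    """Descriptor matrix + targets, with a block manifest for provenance."""

    frame: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    @property
    def descriptors(self) -> pd.DataFrame:
        return self.frame[list(ALL_DESCRIPTOR_COLUMNS)]

    @property
    def target(self) -> pd.Series:
        return self.frame[TARGET_COLUMN]

    def subset_metal(self, element: str) -> "FeatureTable":
        """Rows whose metal center is ``element`` (per-metal retraining)."""
        sub = self.frame[self.frame["metal_element"] == element].reset_index(drop=True)
        return FeatureTable(sub, dict(self.manifest))

    def to_csv(self, path: str | Path, manifest_path: str | Path | None = None) -> None:
        path = Path(path)
        self.frame.to_csv(path, index=False)
        mpath = Path(manifest_path) if manifest_path else path.with_suffix(".manifest.json")
        mpath.write_text(json.dumps(self.manifest, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path, manifest_path: str | Path | None = None) -> "FeatureTable":
        path = Path(path)
        frame = pd.read_csv(path)
        mpath = Path(manifest_path) if manifest_path else path.with_suffix(".manifest.json")
        manifest = json.loads(mpath.read_text()) if mpath.exists() else {}
        return cls(frame, manifest)


def default_manifest() -> dict:
    return {
        "blocks": {
            "qcd": list(QCD_COLUMNS),
            "structure": list(STRUCTURE_COLUMNS),
            "metal": list(METAL_COLUMNS),
            "condition": list(CONDITION_COLUMNS),
        },
        "target": TARGET_COLUMN,
        "metadata": ["identifier", "metal_element", "source"],
    }


def assemble_feature_table(samples: Iterable[SampleRecord]) -> FeatureTable:
    """One row per sample, fixed column order, block manifest alongside."""
    rows = [s.as_row() for s in samples]
    if not rows:
        raise ValueError("no samples to assemble")
    frame = pd.DataFrame(rows)
    ordered = ["identifier", *ALL_DESCRIPTOR_COLUMNS, TARGET_COLUMN, "metal_element", "source"]
    dupes = [c for c in frame.columns if list(frame.columns).count(c) > 1]
    if dupes:
        raise ValueError(f"column collision in feature table: {sorted(set(dupes))}")
    return FeatureTable(frame[ordered], default_manifest())


def preprocess_dataset(
    frame: pd.DataFrame,
    min_phi: float = 0.01,
    wavelength_ratio: float = 2.0,
    group_column: str = "identifier",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the dataset cleaning rules; returns (kept rows, exclusion log).

    Rows with a quantum yield below ``min_phi`` are removed.  Groups of rows
    for the same complex measured only at different irradiation wavelengths
    are removed entirely when their max/min quantum-yield ratio exceeds
    ``wavelength_ratio``.  The log lists every excluded row with its rule.
    """
    if TARGET_COLUMN not in frame.columns:
        raise ValueError(f"frame lacks the {TARGET_COLUMN!r} column")
    log: list[dict] = []
    keep = frame.copy().reset_index(drop=True)

    low = keep[TARGET_COLUMN] < min_phi
    for _, row in keep[low].iterrows():
        log.append({
            "identifier": row.get(group_column, "?"),
            "rule": f"below-{min_phi}",
            TARGET_COLUMN: row[TARGET_COLUMN],
        })
    keep = keep[~low]

    if "wl" in keep.columns and group_column in keep.columns:
        drop_groups = []
        for ident, grp in keep.groupby(group_column):
            if grp["wl"].nunique() > 1:
                ratio = grp[TARGET_COLUMN].max() / grp[TARGET_COLUMN].min()
                if ratio > wavelength_ratio:
                    drop_groups.append((ident, ratio))
        for ident, ratio in drop_groups:
            for _, row in keep[keep[group_column] == ident].iterrows():
                log.append({
                    "identifier": ident,
                    "rule": f"wavelength-ratio>{wavelength_ratio}",
                    TARGET_COLUMN: row[TARGET_COLUMN],
                })
            keep = keep[keep[group_column] != ident]

    keep = keep.sort_values(group_column if group_column in keep.columns else keep.columns[0])
    keep = keep.reset_index(drop=True)
    return keep, pd.DataFrame(log, columns=["identifier", "rule", TARGET_COLUMN])
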