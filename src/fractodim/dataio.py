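"""Dataset manifests and result I/O.

Supports two dataset layouts: the BreaKHIS-style folder convention
(``<class>/<subtype>/<patient>/<magnification>/<image>.png``, with
tolerant parsing of common variants) and a flat CSV manifest with columns
``path, magnification, label, subtype``.  Feature tables and experiment
reports round-trip through CSV/JSON; human-facing rates are written with
three decimals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .classify import (
    ALL_SUBTYPES,
    BENIGN_SUBTYPES,
    MAGNIFICATIONS,
    MALIGNANT_SUBTYPES,
    ClassificationReport,
    FDRecord,
)

logger = logging.getLogger("fractodim")

_SUBTYPE_ALIASES = {
    "adenosis": "A",
    "fibroadenoma": "F",
    "phyllodes_tumor": "PT",
    "phyllodes_tumour": "PT",
    "tubular_adenoma": "TA",
    "tubular_adenona": "TA",  # spelling found in circulating copies
    "ductal_carcinoma": "DC",
    "lobular_carcinoma": "LC",
    "mucinous_carcinoma": "MC",
    "papillary_carcinoma": "PC",
}


@dataclass
class DatasetManifest:
    """Image inventory plus tallies by magnification × class and subtype."""

    entries: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["path", "magnification", "label", "subtype"])

    def validate(self) -> None:
        """Check the additivity invariants of the tally tables."""
        df = self.to_frame()
        for _, row in df.iterrows():
            benign = row["subtype"] in BENIGN_SUBTYPES
            if benign != (row["label"] == "benign"):
                raise ValueError(
                    f"subtype/label mismatch at {row['path']}: "
                    f"{row['subtype']} vs {row['label']}"
                )
        by_mag = df.groupby("magnification").size()
        by_mag_label = df.groupby(["magnification", "label"]).size()
        for mag in by_mag.index:
            parts = sum(
                by_mag_label.get((mag, lab), 0) for lab in ("benign", "malignant")
            )
            if parts != by_mag[mag]:
                raise ValueError(f"tally mismatch at magnification {mag}")

    def counts(self) -> dict[str, pd.DataFrame]:
        """The three standard tally tables (totals, benign, malignant)."""
        df = self.to_frame()
        totals = (
            df.pivot_table(index="magnification", columns="label", aggfunc="size", fill_value=0)
            .reindex(columns=["benign", "malignant"], fill_value=0)
        )
        totals["total"] = totals.sum(axis=1)
        ben = df[df["label"] == "benign"].pivot_table(
            index="magnification", columns="subtype", aggfunc="size", fill_value=0
        ).reindex(columns=list(BENIGN_SUBTYPES), fill_value=0)
        ben["total"] = ben.sum(axis=1)
        mal = df[df["label"] == "malignant"].pivot_table(
            index="magnification", columns="subtype", aggfunc="size", fill_value=0
        ).reindex(columns=list(MALIGNANT_SUBTYPES), fill_value=0)
        mal["total"] = mal.sum(axis=1)
        return {"totals": totals, "benign": ben, "malignant": mal}


def _normalize_magnification(token: str) -> str | None:
    token = token.strip().lower().rstrip("x")
    if token.endswith("X"):
        token = token[:-1]
    if token in {"40", "100", "200", "400"}:
        return f"{token}x"
    return None


def _normalize_subtype(token: str) -> str | None:
    token = token.strip()
    if token.upper() in ALL_SUBTYPES:
        return token.upper()
    return _SUBTYPE_ALIASES.get(token.lower())


def scan_dataset(root: str | Path, layout: str = "breakhis") -> DatasetManifest:
    """Build a manifest from a dataset directory or flat CSV.

    ``layout="breakhis"`` walks the folder convention
    class/subtype/patient/magnification; unparseable paths are skipped
    with a logged warning.  ``layout="flat_csv"`` reads ``manifest.csv``
    under the root (or the root itself if it is a file).  Zero usable
    entries is an error.
    """
    root = Path(root)
    entries: list[dict] = []
    if layout == "flat_csv":
        csv_path = root if root.is_file() else root / "manifest.csv"
        if not csv_path.exists():
            raise FileNotFoundError(csv_path)
        df = pd.read_csv(csv_path)
        for i, row in df.iterrows():
            mag = _normalize_magnification(str(row["magnification"]))
            sub = _normalize_subtype(str(row["subtype"]))
            label = str(row["label"]).strip().lower()
            if mag is None or sub is None or label not in ("benign", "malignant"):
                logger.warning("skipping unparseable manifest row %d", i)
                continue
            entries.append(
                {"path": str(row["path"]), "magnification": mag, "label": label, "subtype": sub}
            )
    elif layout == "breakhis":
        if not root.is_dir():
            raise FileNotFoundError(root)
        for path in sorted(root.rglob("*.png")):
            parts = [p.lower() for p in path.relative_to(root).parts]
            label = next((p for p in parts if p in ("benign", "malignant")), None)
            mag = next(
                (m for m in (_normalize_magnification(p) for p in parts) if m), None
            )
            sub = next(
                (s for s in (_normalize_subtype(p) for p in path.relative_to(root).parts) if s),
                None,
            )
            if label is None or mag is None or sub is None:
                logger.warning("skipping unparseable path %s", path)
                continue
            entries.append(
                {"path": str(path), "magnification": mag, "label": label, "subtype": sub}
            )
    else:
        raise ValueError(f"unknown layout {layout!r}")
    if not entries:
        raise ValueError("no usable entries found")
    manifest = DatasetManifest(entries=entries)
    manifest.validate()
    return manifest


def summarize_manifest(manifest: DatasetManifest) -> dict[str, pd.DataFrame]:
    """Emit the three tally tables after re-asserting their consistency."""
    if not manifest.entries:
        raise ValueError("empty manifest")
    manifest.validate()
    tables = manifest.counts()
    grand = int(tables["totals"]["total"].sum())
    parts = int(tables["benign"]["total"].sum() + tables["malignant"]["total"].sum())
    if grand != parts:
        raise ValueError("inconsistent tallies: subtype totals != class totals")
    return tables


@dataclass
class RunConfig:
    """Resolved options for one pipeline run.

    Validated on construction and serialized next to every result file so
    a run can be reproduced from its outputs alone.
    """

    epsilons: list[int] = field(default_factory=lambda: [3, 4])
    binarize_method: str = "otsu"
    binarize_threshold: float | None = None
    edges_mode: str = "binary_boundary"
    edges_connectivity: int = 4
    fraction: float = 0.5
    seeds: list[int] = field(default_factory=lambda: [0])
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if len({int(e) for e in self.epsilons}) < 2:
            raise ValueError("config: need at least 2 distinct epsilons")
        if any(int(e) < 1 for e in self.epsilons):
            raise ValueError("config: epsilons must be >= 1")
        if self.binarize_method not in ("otsu", "fixed"):
            raise ValueError(f"config: unknown binarize method {self.binarize_method!r}")
        if self.binarize_method == "fixed" and not (
            self.binarize_threshold is not None and 0.0 <= self.binarize_threshold <= 1.0
        ):
            raise ValueError("config: fixed binarization needs threshold in [0, 1]")
        if self.edges_mode not in ("binary_boundary", "canny"):
            raise ValueError(f"config: unknown edges mode {self.edges_mode!r}")
        if self.edges_connectivity not in (4, 8):
            raise ValueError("config: connectivity must be 4 or 8")
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("config: fraction must lie in (0, 1)")
        if not self.seeds:
            raise ValueError("config: at least one seed required")


def load_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    unknown = set(raw) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"config: unknown keys {sorted(unknown)}")
    return RunConfig(**raw)


def save_run_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))


# ---------------------------------------------------------------------------
# feature tables and reports

_FD_COLUMNS = ["image_id", "magnification", "label", "subtype", "fd"]


def write_fd_csv(records: Sequence[FDRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "image_id": r.image_id,
                "magnification": r.magnification,
                "label": r.label,
                "subtype": r.subtype,
                "fd": repr(r.fd),  # repr round-trips float64 losslessly
            }
            for r in records
        ],
        columns=_FD_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_fd_csv(path: str | Path) -> list[FDRecord]:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _FD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fd CSV missing columns: {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            fd = float(row["fd"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed fd value at line {i + 2}") from exc
        records.append(
            FDRecord(
                image_id=row["image_id"],
                magnification=row["magnification"],
                label=row["label"],
                subtype=row["subtype"],
                fd=fd,
            )
        )
    return records


def write_report_json(report: ClassificationReport, path: str | Path, seed: int | None = None) -> None:
    payload = report.rounded()
    payload["confusion"] = report.confusion
    if seed is not None:
        payload["seed"] = seed
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a {0,1} mask as an 8-bit 0/255 PNG."""
    Image.fromarray((np.asarray(mask) * 255).astype(np.uint8)).save(path)


def read_image(path: str | Path) -> np.ndarray:
    """Load a raster (PNG/TIFF/JPEG) as a numpy array."""
    with Image.open(path) as im:
        return np.asarray(im)
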