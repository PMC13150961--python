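"""Desikan-Killiany cortical atlas registry, cortical-thickness table I/O, and
edge indexing.

The Desikan-Killiany (DK) parcellation divides each hemisphere into 34 gyral
regions, giving 68 cortical regions in total.  All downstream machinery in
this package indexes regions by a fixed, documented ordering: **all left
hemisphere regions first, then all right**, alphabetically by canonical
FreeSurfer label within each hemisphere.  Edge (region-pair) enumeration
supports two conventions:

``full_grid``
    all ordered pairs including the diagonal, ``68**2 = 4624`` entries —
    the count conventionally quoted for a full 68-region covariance matrix;
``unique_pairs``
    unordered off-diagonal pairs ``i < j``, ``68*67/2 = 2278`` entries —
    the set actually carrying distinct statistical tests, since covariance
    matrices are symmetric with a unit diagonal.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "AtlasRegistry",
    "CorticalThicknessTable",
    "EdgeIndex",
    "dk_atlas",
    "load_ct_table",
    "save_ct_table",
    "edge_enumeration",
    "export_network",
]

# Canonical FreeSurfer labels of the 34 DK regions per hemisphere, with the
# short codes used in this package's tabular reports.  The codes follow common
# usage in the cortical-thickness literature (ST = superior temporal,
# TrT = transverse temporal, LOrF = lateral orbitofrontal, ...); codes for
# regions that rarely appear abbreviated in print are our own, kept unique.
_DK_LABELS: list[tuple[str, str]] = [
    ("bankssts", "BSTS"),
    ("caudalanteriorcingulate", "CACg"),
    ("caudalmiddlefrontal", "CMF"),
    ("cuneus", "Cu"),
    ("entorhinal", "En"),
    ("frontalpole", "FPol"),
    ("fusiform", "Fu"),
    ("inferiorparietal", "IP"),
    ("inferiortemporal", "IT"),
    ("insula", "Ins"),
    ("isthmuscingulate", "IstCg"),
    ("lateraloccipital", "LO"),
    ("lateralorbitofrontal", "LOrF"),
    ("lingual", "Lg"),
    ("medialorbitofrontal", "MOrF"),
    ("middletemporal", "MT"),
    ("paracentral", "PaC"),
    ("parahippocampal", "PaH"),
    ("parsopercularis", "Op"),
    ("parsorbitalis", "Or"),
    ("parstriangularis", "Tr"),
    ("pericalcarine", "PerCa"),
    ("postcentral", "PoC"),
    ("posteriorcingulate", "PoCg"),
    ("precentral", "PreC"),
    ("precuneus", "PreCu"),
    ("rostralanteriorcingulate", "RACg"),
    ("rostralmiddlefrontal", "RoMF"),
    ("superiorfrontal", "SF"),
    ("superiorparietal", "SP"),
    ("superiortemporal", "ST"),
    ("supramarginal", "SM"),
    ("temporalpole", "TPol"),
    ("transversetemporal", "TrT"),
]

# Approximate MNI (mm) centroids of the DK regions, right-hemisphere
# convention (positive x); the left-hemisphere centroid mirrors x.  These are
# display coordinates for graph-viewer exports only, not analysis inputs.
_DK_CENTROIDS_RH: dict[str, tuple[float, float, float]] = {
    "bankssts": (54, -46, 10),
    "caudalanteriorcingulate": (5, 20, 28),
    "caudalmiddlefrontal": (36, 12, 48),
    "cuneus": (8, -80, 28),
    "entorhinal": (24, -8, -32),
    "frontalpole": (9, 62, -10),
    "fusiform": (36, -52, -20),
    "inferiorparietal": (44, -62, 32),
    "inferiortemporal": (50, -50, -20),
    "insula": (36, -4, 2),
    "isthmuscingulate": (8, -44, 22),
    "lateraloccipital": (30, -88, 10),
    "lateralorbitofrontal": (24, 30, -16),
    "lingual": (14, -68, -4),
    "medialorbitofrontal": (8, 36, -18),
    "middletemporal": (56, -30, -10),
    "paracentral": (8, -26, 58),
    "parahippocampal": (26, -36, -14),
    "parsopercularis": (48, 14, 14),
    "parsorbitalis": (44, 38, -10),
    "parstriangularis": (46, 30, 8),
    "pericalcarine": (12, -80, 8),
    "postcentral": (42, -26, 50),
    "posteriorcingulate": (6, -30, 40),
    "precentral": (38, -12, 50),
    "precuneus": (10, -58, 38),
    "rostralanteriorcingulate": (6, 36, 8),
    "rostralmiddlefrontal": (32, 42, 20),
    "superiorfrontal": (12, 26, 52),
    "superiorparietal": (24, -60, 52),
    "superiortemporal": (54, -18, 0),
    "supramarginal": (52, -40, 32),
    "temporalpole": (32, 12, -34),
    "transversetemporal": (46, -24, 10),
}

# Coarse lobar grouping used by the synthetic-cohort generator to build a
# block-structured base correlation (4 lobes x 2 hemispheres = 8 blocks).
# Cingulate and insular regions are folded into the nearest lobe.
DK_LOBE: dict[str, str] = {
    "bankssts": "temporal",
    "caudalanteriorcingulate": "frontal",
    "caudalmiddlefrontal": "frontal",
    "cuneus": "occipital",
    "entorhinal": "temporal",
    "frontalpole": "frontal",
    "fusiform": "temporal",
    "inferiorparietal": "parietal",
    "inferiortemporal": "temporal",
    "insula": "temporal",
    "isthmuscingulate": "parietal",
    "lateraloccipital": "occipital",
    "lateralorbitofrontal": "frontal",
    "lingual": "occipital",
    "medialorbitofrontal": "frontal",
    "middletemporal": "temporal",
    "paracentral": "frontal",
    "parahippocampal": "temporal",
    "parsopercularis": "frontal",
    "parsorbitalis": "frontal",
    "parstriangularis": "frontal",
    "pericalcarine": "occipital",
    "postcentral": "parietal",
    "posteriorcingulate": "parietal",
    "precentral": "frontal",
    "precuneus": "parietal",
    "rostralanteriorcingulate": "frontal",
    "rostralmiddlefrontal": "frontal",
    "superiorfrontal": "frontal",
    "superiorparietal": "parietal",
    "superiortemporal": "temporal",
    "supramarginal": "parietal",
    "temporalpole": "temporal",
    "transversetemporal": "temporal",
}


@dataclass(frozen=True)
class Region:
    region_id: int
    name: str
    abbreviation: str
    hemisphere: str  # "left" | "right"

    @property
    def column(self) -> str:
        """Header name of this region's thickness column (``lh_``/``rh_`` prefix)."""
        prefix = "lh" if self.hemisphere == "left" else "rh"
        return f"{prefix}_{self.name}"

    @property
    def short(self) -> str:
        """Display code, e.g. ``L TrT``."""
        return f"{'L' if self.hemisphere == 'left' else 'R'} {self.abbreviation}"


@dataclass(frozen=True)
class AtlasRegistry:
    """Fixed 68-region DK registry (left hemisphere first, alphabetical)."""

    regions: tuple[Region, ...]

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def columns(self) -> list[str]:
        return [r.column for r in self.regions]

    @property
    def short_names(self) -> list[str]:
        return [r.short for r in self.regions]

    def lookup(self, abbreviation: str, hemisphere: str) -> Region:
        for r in self.regions:
            if r.abbreviation == abbreviation and r.hemisphere == hemisphere:
                return r
        raise KeyError(f"no region with abbreviation {abbreviation!r} in {hemisphere} hemisphere")

    def by_name(self, name: str, hemisphere: str) -> Region:
        for r in self.regions:
            if r.name == name and r.hemisphere == hemisphere:
                return r
        raise KeyError(f"no region named {name!r} in {hemisphere} hemisphere")

    def from_short(self, short: str) -> Region:
        """Resolve a display code such as ``"L TrT"``."""
        hemi_code, abbrev = short.split(None, 1)
        hemisphere = {"L": "left", "R": "right"}[hemi_code]
        return self.lookup(abbrev, hemisphere)

    def centroid(self, region_id: int) -> tuple[float, float, float]:
        r = self.regions[region_id]
        x, y, z = _DK_CENTROIDS_RH[r.name]
        if r.hemisphere == "left":
            x = -x
        return (float(x), float(y), float(z))

    def lobes(self) -> list[str]:
        """Per-region block label, e.g. ``left-temporal`` (8 distinct values)."""
        return [f"{r.hemisphere}-{DK_LOBE[r.name]}" for r in self.regions]


def dk_atlas() -> AtlasRegistry:
    """Return the fixed 68-region Desikan-Killiany registry."""
    regions = []
    for hemisphere in ("left", "right"):
        for name, abbrev in _DK_LABELS:
            regions.append(Region(len(regions), name, abbrev, hemisphere))
    return AtlasRegistry(tuple(regions))


@dataclass
class CorticalThicknessTable:
    """Validated subjects x regions cortical-thickness table (mm).

    ``thickness`` columns follow the atlas ordering exactly.  ``weekly_hours``
    is NaN for subjects without a recorded value (e.g. non-gaming controls).
    """

    subject_ids: list[str]
    group: np.ndarray  # dtype=object / str, shape (n,)
    thickness: np.ndarray  # shape (n, 68), strictly positive, float64
    weekly_hours: np.ndarray | None
    atlas: AtlasRegistry

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        if len(set(self.subject_ids)) != n:
            dupes = sorted({s for s in self.subject_ids if self.subject_ids.count(s) > 1})
            raise ValueError(f"duplicate subject_id(s): {dupes}")
        self.thickness = np.asarray(self.thickness, dtype=float)
        if self.thickness.shape != (n, self.atlas.n_regions):
            raise ValueError(
                f"thickness shape {self.thickness.shape} does not match "
                f"{n} subjects x {self.atlas.n_regions} regions"
            )
        bad = np.argwhere(~np.isfinite(self.thickness) | (self.thickness <= 0))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"non-finite or nonpositive thickness for subject "
                f"{self.subject_ids[i]!r}, region {self.atlas.columns[j]!r}"
            )
        self.group = np.asarray(self.group, dtype=object)
        if self.group.shape != (n,):
            raise ValueError("every subject needs a group label")
        if self.weekly_hours is not None:
            self.weekly_hours = np.asarray(self.weekly_hours, dtype=float)
            if self.weekly_hours.shape != (n,):
                raise ValueError("weekly_hours length mismatch")
            with np.errstate(invalid="ignore"):
                if np.any(self.weekly_hours < 0):
                    raise ValueError("weekly_hours must be nonnegative")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def subset(self, mask: np.ndarray) -> "CorticalThicknessTable":
        idx = np.flatnonzero(np.asarray(mask))
        return CorticalThicknessTable(
            subject_ids=[self.subject_ids[i] for i in idx],
            group=self.group[idx],
            thickness=self.thickness[idx],
            weekly_hours=None if self.weekly_hours is None else self.weekly_hours[idx],
            atlas=self.atlas,
        )

    def by_group(self, label: str) -> "CorticalThicknessTable":
        return self.subset(self.group == label)

    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for g in self.group:
            if g not in seen:
                seen.append(g)
        return seen

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.thickness, columns=self.atlas.columns)
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "group", self.group)
        if self.weekly_hours is not None:
            df["weekly_hours"] = self.weekly_hours
        return df


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def load_ct_table(path: str | Path, atlas: AtlasRegistry | None = None) -> CorticalThicknessTable:
    """Read and validate a delimited cortical-thickness table.

    The header must name ``subject_id``, ``group`` and all 68 region columns
    (``lh_<label>`` / ``rh_<label>``); ``weekly_hours`` is optional.  Columns
    are reordered to atlas order.  The delimiter is inferred from the file
    extension (TSV for ``.tsv``/``.tab``, CSV otherwise).
    """
    atlas = atlas or dk_atlas()
    path = Path(path)
    df = pd.read_csv(
        path, sep=_delimiter_for(path), dtype={"subject_id": str},
        float_precision="round_trip",
    )
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    missing = [c for c in atlas.columns if c not in df.columns]
    if missing:
        raise ValueError(f"missing region column(s): {missing}")
    thick = np.empty((len(df), atlas.n_regions), dtype=float)
    for j, col in enumerate(atlas.columns):
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy()
        bad = np.flatnonzero(~np.isfinite(vals))
        if bad.size:
            sid = df["subject_id"].iloc[bad[0]]
            raise ValueError(f"non-numeric thickness for subject {sid!r}, region {col!r}")
        thick[:, j] = vals
    hours = None
    if "weekly_hours" in df.columns:
        hours = pd.to_numeric(df["weekly_hours"], errors="coerce").to_numpy(dtype=float)
    return CorticalThicknessTable(
        subject_ids=df["subject_id"].astype(str).tolist(),
        group=df["group"].to_numpy(dtype=object),
        thickness=thick,
        weekly_hours=hours,
        atlas=atlas,
    )


def save_ct_table(table: CorticalThicknessTable, path: str | Path) -> Path:
    path = Path(path)
    table.to_frame().to_csv(path, sep=_delimiter_for(path), index=False, float_format="%.17g")
    return path


class EdgeIndex:
    """Bijection between flat edge indices and region pairs.

    ``full_grid`` enumerates all ordered pairs ``(i, j)`` including the
    diagonal (row-major, ``R**2`` entries); ``unique_pairs`` enumerates
    unordered pairs ``i < j`` in upper-triangular row-major order
    (``R*(R-1)/2`` entries).
    """

    CONVENTIONS = ("full_grid", "unique_pairs")

    def __init__(self, n_regions: int, convention: str = "unique_pairs") -> None:
        if convention not in self.CONVENTIONS:
            raise ValueError(f"unknown edge convention {convention!r}")
        self.n_regions = int(n_regions)
        self.convention = convention
        if convention == "full_grid":
            self.n_edges = self.n_regions**2
        else:
            self.n_edges = self.n_regions * (self.n_regions - 1) // 2
            self._rows, self._cols = np.triu_indices(self.n_regions, k=1)

    def flatten(self, i: int, j: int) -> int:
        R = self.n_regions
        if not (0 <= i < R and 0 <= j < R):
            raise IndexError(f"region pair ({i}, {j}) out of range for {R} regions")
        if self.convention == "full_grid":
            return i * R + j
        if i == j:
            raise ValueError("unique_pairs excludes the diagonal")
        if i > j:
            i, j = j, i
        # count of pairs in rows above i, plus offset within row i
        return i * (2 * R - i - 1) // 2 + (j - i - 1)

    def unflatten(self, k: int) -> tuple[int, int]:
        if not 0 <= k < self.n_edges:
            raise IndexError(f"edge index {k} out of range")
        R = self.n_regions
        if self.convention == "full_grid":
            return divmod(k, R)
        return int(self._rows[k]), int(self._cols[k])

    def pairs(self) -> Iterator[tuple[int, int]]:
        for k in range(self.n_edges):
            yield self.unflatten(k)

    def extract(self, matrix: np.ndarray) -> np.ndarray:
        """Flatten a square region x region matrix into edge order."""
        matrix = np.asarray(matrix)
        if matrix.shape[-2:] != (self.n_regions, self.n_regions):
            raise ValueError("matrix dimension does not match the edge index")
        if self.convention == "full_grid":
            return matrix.reshape(*matrix.shape[:-2], -1)
        return matrix[..., self._rows, self._cols]

    def to_matrix(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Inverse of :meth:`extract` for ``unique_pairs`` (symmetric fill)."""
        values = np.asarray(values, dtype=float)
        R = self.n_regions
        if self.convention == "full_grid":
            return values.reshape(R, R)
        out = np.full((R, R), fill, dtype=float)
        out[self._rows, self._cols] = values
        out[self._cols, self._rows] = values
        return out


def edge_enumeration(atlas: AtlasRegistry, convention: str = "unique_pairs") -> EdgeIndex:
    return EdgeIndex(atlas.n_regions, convention)


def export_network(
    matrix: np.ndarray,
    atlas: AtlasRegistry,
    out_prefix: str | Path,
    format: str = "csv",
    node_sizes: Sequence[float] | None = None,
    node_colors: Sequence[float] | None = None,
) -> list[Path]:
    """Write a region x region matrix as CSV or BrainNet-Viewer-style files.

    ``csv`` writes ``<prefix>.csv`` with region display codes as header/index;
    values round-trip exactly through :func:`load_network_csv`.  ``brainnet``
    writes ``<prefix>.node`` (per region: ``x y z color size label``,
    whitespace-delimited, MNI display centroids) and ``<prefix>.edge``
    (R x R whitespace-delimited matrix).
    """
    matrix = np.asarray(matrix, dtype=float)
    R = atlas.n_regions
    if matrix.shape != (R, R):
        raise ValueError(f"matrix shape {matrix.shape} does not match the {R}-region atlas")
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if format == "csv":
        out = prefix.with_suffix(".csv")
        df = pd.DataFrame(matrix, index=atlas.short_names, columns=atlas.short_names)
        df.to_csv(out, float_format="%.17g")
        written.append(out)
    elif format == "brainnet":
        if node_sizes is None:
            node_sizes = np.abs(matrix).sum(axis=0)
        if node_colors is None:
            node_colors = np.ones(R)
        node_path = prefix.with_suffix(".node")
        with open(node_path, "w", newline="\n") as fh:
            for r in atlas.regions:
                x, y, z = atlas.centroid(r.region_id)
                label = f"{'L' if r.hemisphere == 'left' else 'R'}.{r.abbreviation}"
                fh.write(
                    f"{x:g}\t{y:g}\t{z:g}\t{node_colors[r.region_id]:g}"
                    f"\t{node_sizes[r.region_id]:g}\t{label}\n"
                )
        edge_path = prefix.with_suffix(".edge")
        np.savetxt(edge_path, matrix, fmt="%.10g", delimiter="\t")
        written.extend([node_path, edge_path])
    else:
        raise ValueError(f"unknown export format {format!r}")
    return written


def load_network_csv(path: str | Path) -> np.ndarray:
    """Read back a matrix written by :func:`export_network` (csv format)."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return df.to_numpy(dtype=float)
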