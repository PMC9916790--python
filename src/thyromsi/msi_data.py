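"""Core data model and readers/writers for MSI datacubes, ROI masks and tables.

An :class:`MSIDataset` is a collection of pixel positions on a 0-based,
row-major integer grid, each carrying one mass spectrum (ascending m/z axis,
non-negative intensities).  Continuous-mode data share a single m/z axis; the
per-pixel accessors hide whether the axis is shared.

Two on-disk dialects are supported:

* ``internal`` — one text file: a JSON header line followed by a TSV of
  ``pixel_x  pixel_y  mz  intensity`` rows.  Diffable and language-neutral.
* ``imzml`` — continuous-mode imzML via :mod:`pyimzml`.

ROI annotations (:class:`ROIMap`) are stored as character grids (one token per
pixel: ``N``/``H``/``T``/``.``) with a nodule-id grid and a nodule→mutation
side-car table.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, InvariantError, ParseError, ShapeError

NIFTP = "NIFTP"
HP = "HP"
THYP = "THYP"
UNANNOTATED = "UNANNOTATED"
REGION_LABELS = (NIFTP, HP, THYP)

RAS_MUTANT = "RAS_MUTANT"
RAS_WT = "RAS_WT"
UNKNOWN = "UNKNOWN"

#: single-character mask tokens <-> region labels
LABEL_TOKENS = {"N": NIFTP, "H": HP, "T": THYP, ".": UNANNOTATED}
TOKEN_OF_LABEL = {v: k for k, v in LABEL_TOKENS.items()}

DEFAULT_MZ_RANGE = (700.0, 3000.0)


@dataclass
class MSIDataset:
    """Per-pixel mass spectra over a 2-D grid.

    Parameters
    ----------
    pixels:
        ``(x, y)`` integer grid coordinates, 0-based, ``x`` = column.
    spectra:
        One ``(mz_values, intensities)`` pair per pixel.  ``mz_values`` must be
        strictly ascending and lie within ``mz_range``; both arrays are stored
        as 64-bit floats.  Pixels of a continuous-mode dataset may share one
        m/z array object.
    mz_range:
        Acquired mass window in Da (default 700–3000).
    mode:
        ``"profile"`` or ``"centroided"``.
    metadata:
        Free-form annotations (instrument, pixel size, provenance).
    """

    pixels: list[tuple[int, int]]
    spectra: list[tuple[np.ndarray, np.ndarray]]
    mz_range: tuple[float, float] = DEFAULT_MZ_RANGE
    mode: str = "profile"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = [(int(x), int(y)) for x, y in self.pixels]
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if len(self.pixels) != len(self.spectra):
            raise InvariantError(
                f"{len(self.pixels)} pixels but {len(self.spectra)} spectra"
            )
        if self.mode not in ("profile", "centroided"):
            raise InvariantError(f"unknown mode {self.mode!r}")
        lo, hi = self.mz_range
        if not lo < hi:
            raise InvariantError(f"empty mz_range {self.mz_range}")
        if len(set(self.pixels)) != len(self.pixels):
            raise InvariantError("duplicate pixel coordinates")
        checked_axes: set[int] = set()
        for (x, y), (mz, inten) in zip(self.pixels, self.spectra):
            if len(mz) != len(inten):
                raise InvariantError(
                    f"pixel ({x},{y}): {len(mz)} m/z values vs "
                    f"{len(inten)} intensities"
                )
            if np.any(inten < 0):
                raise InvariantError(f"pixel ({x},{y}): negative intensity")
            if id(mz) in checked_axes:  # shared continuous axis, already checked
                continue
            if len(mz) and (np.any(np.diff(mz) <= 0)):
                raise InvariantError(f"pixel ({x},{y}): m/z not strictly ascending")
            if len(mz) and (mz[0] < lo or mz[-1] > hi):
                raise InvariantError(
                    f"pixel ({x},{y}): m/z outside range {self.mz_range}"
                )
            checked_axes.add(id(mz))

    # -- convenience --------------------------------------------------------
    def __len__(self) -> int:
        return len(self.pixels)

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(height, width) of the bounding grid."""
        if not self.pixels:
            return (0, 0)
        xs = [p[0] for p in self.pixels]
        ys = [p[1] for p in self.pixels]
        return (max(ys) + 1, max(xs) + 1)

    def has_common_axis(self) -> bool:
        if not self.spectra:
            return True
        first = self.spectra[0][0]
        return all(
            s[0] is first or np.array_equal(s[0], first) for s in self.spectra
        )

    @property
    def common_mz(self) -> np.ndarray:
        if not self.has_common_axis():
            raise DataError("dataset pixels do not share one m/z axis")
        return self.spectra[0][0]

    def intensity_matrix(self) -> np.ndarray:
        """Pixels × m/z-points matrix (requires a shared axis)."""
        mz = self.common_mz
        out = np.empty((len(self.pixels), len(mz)))
        for i, (_, inten) in enumerate(self.spectra):
            out[i] = inten
        return out

    @classmethod
    def from_matrix(
        cls,
        pixels: Sequence[tuple[int, int]],
        mz: np.ndarray,
        intensities: np.ndarray,
        mz_range: tuple[float, float] | None = None,
        mode: str = "profile",
        metadata: dict | None = None,
    ) -> "MSIDataset":
        """Build a continuous-mode dataset from a pixels × points matrix.

        Rows of ``intensities`` become views, so the matrix is not copied.
        """
        mz = np.asarray(mz, dtype=np.float64)
        intensities = np.asarray(intensities, dtype=np.float64)
        if intensities.shape != (len(pixels), len(mz)):
            raise ShapeError(
                f"intensity matrix {intensities.shape} does not match "
                f"{len(pixels)} pixels x {len(mz)} m/z points"
            )
        if mz_range is None:
            mz_range = (float(mz[0]), float(mz[-1]))
        spectra = [(mz, intensities[i]) for i in range(len(pixels))]
        return cls(
            pixels=list(pixels),
            spectra=spectra,
            mz_range=mz_range,
            mode=mode,
            metadata=dict(metadata or {}),
        )


@dataclass
class ROIMap:
    """Pathologist region annotation companion to one :class:`MSIDataset`.

    ``label_grid`` / ``nodule_grid`` cover the full bounding grid;
    pixels absent from the dataset must stay ``UNANNOTATED`` / ``-1``.
    """

    label_grid: np.ndarray            # (h, w) array of region-label strings
    nodule_grid: np.ndarray           # (h, w) int array, -1 = no nodule
    mutation_status: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.label_grid = np.asarray(self.label_grid, dtype=object)
        self.nodule_grid = np.asarray(self.nodule_grid, dtype=int)
        if self.label_grid.shape != self.nodule_grid.shape:
            raise ShapeError(
                f"label grid {self.label_grid.shape} vs nodule grid "
                f"{self.nodule_grid.shape}"
            )
        bad = set(np.unique(self.label_grid)) - set(LABEL_TOKENS.values())
        if bad:
            raise InvariantError(f"unknown region labels {sorted(map(str, bad))}")
        misplaced = (self.nodule_grid >= 0) & ~np.isin(
            self.label_grid.astype(str), (NIFTP, HP)
        )
        if np.any(misplaced):
            y, x = np.argwhere(misplaced)[0]
            raise InvariantError(
                f"pixel ({x},{y}): nodule id set outside NIFTP/HP region"
            )
        for status in self.mutation_status.values():
            if status not in (RAS_MUTANT, RAS_WT, UNKNOWN):
                raise InvariantError(f"unknown mutation status {status!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_grid.shape

    def labels_for(self, ds: MSIDataset) -> np.ndarray:
        """Region label per dataset pixel, in dataset pixel order."""
        return np.array(
            [str(self.label_grid[y, x]) for x, y in ds.pixels], dtype=object
        )

    def nodules_for(self, ds: MSIDataset) -> np.ndarray:
        return np.array([int(self.nodule_grid[y, x]) for x, y in ds.pixels])

    def check_against(self, ds: MSIDataset) -> None:
        h, w = self.shape
        dh, dw = ds.grid_shape
        if (dh, dw) != (0, 0) and (h < dh or w < dw):
            raise ShapeError(f"ROI grid {h}x{w} smaller than dataset grid {dh}x{dw}")
        covered = np.zeros(self.shape, dtype=bool)
        for x, y in ds.pixels:
            covered[y, x] = True
        orphan = (self.label_grid.astype(str) != UNANNOTATED) & ~covered
        if np.any(orphan):
            y, x = np.argwhere(orphan)[0]
            raise InvariantError(
                f"pixel ({x},{y}) is annotated but absent from the dataset"
            )


# ---------------------------------------------------------------------------
# datacube I/O
# ---------------------------------------------------------------------------

def write_dataset(ds: MSIDataset, path: str, dialect: str = "internal") -> str:
    """Serialize ``ds``; returns the main file path written.

    ``internal`` writes a single text file; ``imzml`` writes continuous-mode
    ``path`` (+ the paired ``.ibd`` binary) and requires a shared m/z axis.
    """
    if dialect == "internal":
        return _write_internal(ds, path)
    if dialect == "imzml":
        return _write_imzml(ds, path)
    raise ParameterErrorDialect(dialect)


def read_dataset(path: str, dialect: str = "internal") -> MSIDataset:
    if dialect == "internal":
        return _read_internal(path)
    if dialect == "imzml":
        return _read_imzml(path)
    raise ParameterErrorDialect(dialect)


def ParameterErrorDialect(dialect: str) -> Exception:
    from .errors import ParameterError

    return ParameterError(f"unknown dialect {dialect!r}; use 'internal' or 'imzml'")


def _write_internal(ds: MSIDataset, path: str) -> str:
    header = {
        "format": "thyromsi-internal",
        "version": 1,
        "mz_range": list(ds.mz_range),
        "mode": ds.mode,
        "n_pixels": len(ds.pixels),
        "metadata": ds.metadata,
    }
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        fh.write("pixel_x\tpixel_y\tmz\tintensity\n")
        for (x, y), (mz, inten) in zip(ds.pixels, ds.spectra):
            for m, v in zip(mz, inten):
                fh.write(f"{x}\t{y}\t{float(m)!r}\t{float(v)!r}\n")
    return path


def _read_internal(path: str) -> MSIDataset:
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline()
        try:
            header = json.loads(header_line)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}:1: header is not valid JSON ({exc})") from exc
        if header.get("format") != "thyromsi-internal":
            raise ParseError(f"{path}:1: not a thyromsi internal-dialect file")
        column_line = fh.readline().rstrip("\n")
        if column_line.split("\t") != ["pixel_x", "pixel_y", "mz", "intensity"]:
            raise ParseError(f"{path}:2: unexpected column header {column_line!r}")
        per_pixel: dict[tuple[int, int], tuple[list, list]] = {}
        order: list[tuple[int, int]] = []
        for lineno, line in enumerate(fh, start=3):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            try:
                x, y = int(parts[0]), int(parts[1])
                m, v = float(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            key = (x, y)
            if key not in per_pixel:
                per_pixel[key] = ([], [])
                order.append(key)
            per_pixel[key][0].append(m)
            per_pixel[key][1].append(v)
    spectra = []
    shared: np.ndarray | None = None
    for key in order:
        mz = np.asarray(per_pixel[key][0], dtype=np.float64)
        if shared is not None and np.array_equal(mz, shared):
            mz = shared  # deduplicate continuous axes
        elif shared is None:
            shared = mz
        spectra.append((mz, np.asarray(per_pixel[key][1], dtype=np.float64)))
    return MSIDataset(
        pixels=order,
        spectra=spectra,
        mz_range=tuple(header["mz_range"]),
        mode=header.get("mode", "profile"),
        metadata=header.get("metadata", {}),
    )


def _write_imzml(ds: MSIDataset, path: str) -> str:
    from pyimzml.ImzMLWriter import ImzMLWriter

    if not ds.has_common_axis():
        raise DataError("imzML continuous mode requires a shared m/z axis")
    with ImzMLWriter(path, mode="continuous") as writer:
        for (x, y), (mz, inten) in zip(ds.pixels, ds.spectra):
            # imzML coordinates are 1-based
            writer.addSpectrum(mz, inten, (x + 1, y + 1, 1))
    return path


def _read_imzml(path: str) -> MSIDataset:
    from pyimzml.ImzMLParser import ImzMLParser

    try:
        parser = ImzMLParser(path)
    except Exception as exc:  # lxml/pyimzml raise various types
        raise ParseError(f"{path}: failed to parse imzML ({exc})") from exc
    pixels: list[tuple[int, int]] = []
    spectra: list[tuple[np.ndarray, np.ndarray]] = []
    shared: np.ndarray | None = None
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        mz = np.asarray(mz, dtype=np.float64)
        if shared is not None and np.array_equal(mz, shared):
            mz = shared
        elif shared is None:
            shared = mz
        pixels.append((int(x) - 1, int(y) - 1))
        spectra.append((mz, np.asarray(inten, dtype=np.float64)))
    lo = min((s[0][0] for s in spectra if len(s[0])), default=DEFAULT_MZ_RANGE[0])
    hi = max((s[0][-1] for s in spectra if len(s[0])), default=DEFAULT_MZ_RANGE[1])
    return MSIDataset(
        pixels=pixels,
        spectra=spectra,
        mz_range=(float(lo), float(hi)),
        mode="profile",
    )


# ---------------------------------------------------------------------------
# ROI map I/O
# ---------------------------------------------------------------------------

def write_roi_map(roi: ROIMap, prefix: str) -> list[str]:
    """Write ``{prefix}.labels.txt``, ``{prefix}.nodules.txt``,
    ``{prefix}.mutations.tsv``; returns the paths written."""
    h, w = roi.shape
    labels_path = f"{prefix}.labels.txt"
    nodules_path = f"{prefix}.nodules.txt"
    mut_path = f"{prefix}.mutations.tsv"
    with open(labels_path, "w", encoding="utf-8") as fh:
        for y in range(h):
            fh.write(
                "".join(TOKEN_OF_LABEL[str(roi.label_grid[y, x])] for x in range(w))
                + "\n"
            )
    with open(nodules_path, "w", encoding="utf-8") as fh:
        for y in range(h):
            row = []
            for x in range(w):
                nid = int(roi.nodule_grid[y, x])
                row.append("." if nid < 0 else np.base_repr(nid, 36))
            fh.write("".join(row) + "\n")
    with open(mut_path, "w", encoding="utf-8") as fh:
        fh.write("nodule_id\tras_status\n")
        for nid in sorted(roi.mutation_status):
            fh.write(f"{nid}\t{roi.mutation_status[nid]}\n")
    return [labels_path, nodules_path, mut_path]


def read_roi_map(prefix: str, ds: MSIDataset) -> ROIMap:
    """Read an ROI annotation and check it against its companion dataset."""
    labels_path = f"{prefix}.labels.txt"
    with open(labels_path, encoding="utf-8") as fh:
        rows = [line.rstrip("\n") for line in fh if line.rstrip("\n")]
    if not rows:
        raise ParseError(f"{labels_path}: empty mask")
    w = len(rows[0])
    if any(len(r) != w for r in rows):
        raise ShapeError(f"{labels_path}: ragged rows")
    h = len(rows)
    dh, dw = ds.grid_shape
    if (dh, dw) != (0, 0) and (h, w) != (dh, dw):
        raise ShapeError(
            f"{labels_path}: mask grid {h}x{w} does not match dataset grid {dh}x{dw}"
        )
    label_grid = np.empty((h, w), dtype=object)
    for y, row in enumerate(rows):
        for x, tok in enumerate(row):
            if tok not in LABEL_TOKENS:
                raise ParseError(
                    f"{labels_path}:{y + 1}: unknown label token {tok!r} at column {x}"
                )
            label_grid[y, x] = LABEL_TOKENS[tok]

    nodule_grid = np.full((h, w), -1, dtype=int)
    nodules_path = f"{prefix}.nodules.txt"
    if os.path.exists(nodules_path):
        with open(nodules_path, encoding="utf-8") as fh:
            nrows = [line.rstrip("\n") for line in fh if line.rstrip("\n")]
        if len(nrows) != h or any(len(r) != w for r in nrows):
            raise ShapeError(f"{nodules_path}: grid does not match {h}x{w} mask")
        for y, row in enumerate(nrows):
            for x, tok in enumerate(row):
                if tok == ".":
                    continue
                try:
                    nodule_grid[y, x] = int(tok, 36)
                except ValueError as exc:
                    raise ParseError(
                        f"{nodules_path}:{y + 1}: bad nodule token {tok!r}"
                    ) from exc

    mutation_status: dict[int, str] = {}
    mut_path = f"{prefix}.mutations.tsv"
    if os.path.exists(mut_path):
        table = pd.read_csv(mut_path, sep="\t")
        for _, row in table.iterrows():
            mutation_status[int(row["nodule_id"])] = str(row["ras_status"])

    roi = ROIMap(label_grid, nodule_grid, mutation_status)
    roi.check_against(ds)
    return roi


# ---------------------------------------------------------------------------
# cohort table
# ---------------------------------------------------------------------------

#: internal column name -> printed clinical-table column name
COHORT_COLUMNS = {
    "case_id": "Case No.",
    "patient_id": "Patient ID",
    "age": "Age",
    "sex": "Sex",
    "n_nodules": "No. Nodules",
    "diameter": "Diameter (cm)",
    "lobe": "Thyroid Lobe",
    "ras_status": "RAS",
    "other_mutations": "Others",
    "other_diseases": "Other Thyroid Diseases",
    "tsh": "TSH (uIU/mL)",
    "anti_tpo": "anti-TPO Ab (IU/mL)",
    "anti_tg": "anti-Tg Ab (IU/mL)",
}


def validate_cohort(table: pd.DataFrame) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise InvariantError(f"cohort table missing columns {missing}")
    if len(table) == 0:
        raise DataError("cohort table is empty")
    if (table["age"] <= 0).any():
        raise InvariantError("cohort table: non-positive age")
    if (table["diameter"] <= 0).any():
        raise InvariantError("cohort table: non-positive diameter")
    if not table["sex"].isin(["M", "F"]).all():
        raise InvariantError("cohort table: sex must be M or F")


def write_cohort(table: pd.DataFrame, path: str) -> str:
    validate_cohort(table)
    table.rename(columns=COHORT_COLUMNS).to_csv(path, index=False)
    return path


def read_cohort(path: str) -> pd.DataFrame:
    raw = pd.read_csv(path)
    inverse = {v: k for k, v in COHORT_COLUMNS.items()}
    table = raw.rename(columns=inverse)
    validate_cohort(table)
    return table
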