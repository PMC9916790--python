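"""Peptide mass arithmetic and ppm-tolerance matching of imaging features.

Imaging features carry no sequence information; an identity is transferred
from an LC–MS/MS run by mass proximity alone.  A feature is putatively
assigned every identification whose m/z lies strictly within the working
ppm tolerance (default 100 ppm), and is called *uniquely identified* when
all its candidates agree on one gene.

Masses are monoisotopic, singly protonated ([M+H]+) — the standard MALDI
assumption in this mass range.  FFPE chemistry modifications are handled as
explicit named mass shifts, not inferred from sequence context.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

from .errors import DataError, ParameterError

__all__ = [
    "PeptideID",
    "MatchResult",
    "NAMED_MODIFICATIONS",
    "peptide_mh",
    "ppm_error",
    "match_features",
    "read_id_table",
    "write_id_table",
]

_CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")

#: named variable-modification mass shifts (Da).  The FFPE formaldehyde
#: adduct shifts are nominal, configurable values.
NAMED_MODIFICATIONS: dict[str, float] = {
    "Oxidation(M)": 15.994915,
    "FFPE+12": 12.000,
    "FFPE+30": 30.011,
}


@dataclass(frozen=True)
class PeptideID:
    """One LC–MS/MS identification row."""

    sequence: str
    gene: str
    protein: str
    measured_mz: float
    theoretical_mz: float
    modifications: tuple[tuple[str, float], ...] = ()
    unique_for_protein: bool = True

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - _CANONICAL:
            raise DataError(
                f"peptide {self.sequence!r}: sequence must be non-empty "
                "uppercase canonical residues"
            )
        if self.theoretical_mz <= 18.01:
            raise DataError(
                f"peptide {self.sequence!r}: theoretical m/z "
                f"{self.theoretical_mz} not heavier than water"
            )


@dataclass
class MatchResult:
    """All identifications within tolerance of one imaging feature."""

    feature_mz: float
    candidates: list[tuple[PeptideID, float]]  # (id, signed ppm error)
    unique_gene: str | None

    def genes(self) -> set[str]:
        return {pid.gene for pid, _ in self.candidates}


def peptide_mh(
    sequence: str,
    modifications: Sequence[tuple[str, float]] | Sequence[str] = (),
) -> float:
    """Monoisotopic [M+H]+ m/z of a peptide.

    ``modifications`` may be ``(name, shift)`` pairs or bare names looked up
    in :data:`NAMED_MODIFICATIONS`.
    """
    if not sequence or set(sequence) - _CANONICAL:
        bad = sorted(set(sequence) - _CANONICAL) if sequence else "<empty>"
        raise DataError(f"invalid residue(s) {bad} in sequence {sequence!r}")
    mz = float(_pmass.calculate_mass(sequence=sequence, ion_type="M", charge=1))
    for mod in modifications:
        if isinstance(mod, str):
            if mod not in NAMED_MODIFICATIONS:
                raise ParameterError(f"unknown modification {mod!r}")
            mz += NAMED_MODIFICATIONS[mod]
        else:
            _name, shift = mod
            mz += float(shift)
    return mz


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error, parts per million.

    The second argument is always the denominator; swapping the arguments is
    only approximately antisymmetric.
    """
    if theoretical <= 0:
        raise ParameterError(f"theoretical m/z must be > 0, got {theoretical}")
    return (observed - theoretical) / theoretical * 1e6


def match_features(
    feature_mz: Sequence[float],
    ids: Sequence[PeptideID],
    tol_ppm: float = 100.0,
    against: str = "measured",
) -> list[MatchResult]:
    """Assign identifications to imaging features by strict ppm proximity.

    ``against`` selects which LC–MS/MS m/z to compare with (the published
    procedure compares the two *measured* values); that value is also the
    ppm denominator.  Candidate sets grow monotonically with ``tol_ppm``.
    """
    if tol_ppm <= 0:
        raise ParameterError(f"tol_ppm must be > 0, got {tol_ppm}")
    if against not in ("measured", "theoretical"):
        raise ParameterError(f"against must be 'measured' or 'theoretical'")
    if not ids:
        raise DataError("empty identification table")
    results: list[MatchResult] = []
    for fmz in feature_mz:
        candidates: list[tuple[PeptideID, float]] = []
        for pid in ids:
            ref = pid.measured_mz if against == "measured" else pid.theoretical_mz
            err = ppm_error(float(fmz), ref)
            if abs(err) < tol_ppm:
                candidates.append((pid, err))
        genes = {pid.gene for pid, _ in candidates}
        unique_gene = genes.pop() if len(genes) == 1 else None
        results.append(MatchResult(float(fmz), candidates, unique_gene))
    return results


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

_ID_COLUMNS = [
    "sequence", "gene", "protein", "measured_mz", "theoretical_mz",
    "mods", "unique",
]


def _format_mods(mods: tuple[tuple[str, float], ...]) -> str:
    return ";".join(f"{name}:{shift:+.6f}" for name, shift in mods)


def _parse_mods(text: str) -> tuple[tuple[str, float], ...]:
    if not text or text in ("-", "nan"):
        return ()
    out = []
    for item in text.split(";"):
        name, _, shift = item.partition(":")
        out.append((name, float(shift) if shift else NAMED_MODIFICATIONS[name]))
    return tuple(out)


def write_id_table(ids: Sequence[PeptideID], path: str) -> str:
    frame = pd.DataFrame(
        [
            {
                "sequence": p.sequence,
                "gene": p.gene,
                "protein": p.protein,
                "measured_mz": repr(p.measured_mz),
                "theoretical_mz": repr(p.theoretical_mz),
                "mods": _format_mods(p.modifications),
                "unique": int(p.unique_for_protein),
            }
            for p in ids
        ],
        columns=_ID_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_id_table(path: str) -> list[PeptideID]:
    frame = pd.read_csv(path, sep="\t", dtype={"mods": str}, keep_default_na=False)
    missing = [c for c in _ID_COLUMNS if c not in frame.columns]
    if missing:
        raise DataError(f"{path}: identification table missing columns {missing}")
    out = []
    for _, row in frame.iterrows():
        out.append(
            PeptideID(
                sequence=str(row["sequence"]),
                gene=str(row["gene"]),
                protein=str(row["protein"]),
                measured_mz=float(row["measured_mz"]),
                theoretical_mz=float(row["theoretical_mz"]),
                modifications=_parse_mods(str(row["mods"])),
                unique_for_protein=bool(int(row["unique"])),
            )
        )
    return out


def write_matches(matches: Sequence[MatchResult], path: str) -> str:
    rows = []
    for m in matches:
        for pid, err in m.candidates:
            rows.append(
                {
                    "feature_mz": m.feature_mz,
                    "gene": pid.gene,
                    "sequence": pid.sequence,
                    "ppm_error": err,
                    "unique_gene": m.unique_gene or "",
                }
            )
        if not m.candidates:
            rows.append(
                {"feature_mz": m.feature_mz, "gene": "", "sequence": "",
                 "ppm_error": float("nan"), "unique_gene": ""}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
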