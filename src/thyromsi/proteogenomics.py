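"""RAS-interactome signature reduction and signature-based nodule calls.

The proteogenomic step narrows the differential imaging features to genes
that physically interact with both RAS baits (NRAS and HRAS), keeps one
feature per gene ("one signal for each protein"), re-segments the NIFTP
pixels with 2-means on those signature features only, and calls each nodule
RAS-like or wild-type-like from its cluster composition.  Cluster
orientation is anchored on the PPIA feature, which is selectively more
intense in RAS-mutant nodules.  Cohort descriptive statistics distinguish
patient-level quantities (a bilateral case is one patient) from
nodule-level ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .identification import MatchResult
from .msi_data import ROIMap, NIFTP
from .preprocess import FeatureMatrix
from .segmentation import bisecting_kmeans
from .synthetic_msi import MIXED, RAS_LIKE, WT_LIKE

__all__ = [
    "Signature",
    "NoduleCall",
    "interactome_intersection",
    "reduce_signature",
    "classify_nodules",
    "cohort_summary",
]


@dataclass
class Signature:
    """One representative feature per uniquely identified common interactor."""

    entries: list[tuple[float, str]]              # (feature_mz, gene), mz-ascending
    provenance: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        genes = [g for _, g in self.entries]
        if len(set(genes)) != len(genes):
            raise DataError("signature contains two entries for one gene")
        self.entries = sorted(self.entries)

    @property
    def feature_mz(self) -> list[float]:
        return [mz for mz, _ in self.entries]

    @property
    def genes(self) -> list[str]:
        return [g for _, g in self.entries]

    def mz_of(self, gene: str) -> float:
        for mz, g in self.entries:
            if g == gene:
                return mz
        raise DataError(f"gene {gene!r} not in signature")

    def to_json_dict(self) -> dict:
        return {
            "entries": [{"mz": mz, "gene": g} for mz, g in self.entries],
            "provenance": {g: sorted(v) for g, v in self.provenance.items()},
        }


@dataclass
class NoduleCall:
    nodule_id: int
    cluster_fractions: dict[int, float]   # cluster id -> pixel fraction
    call: str                             # RAS_LIKE | WT_LIKE | MIXED
    n_pixels: int


def interactome_intersection(
    identified_genes: set[str],
    interactors: Mapping[str, set[str]],
) -> tuple[set[str], dict[str, int]]:
    """Common interactors of all baits among the identified proteins.

    Returns the intersection and Venn-diagram region counts over the sets
    {identified} ∪ {interactors of each bait}, keyed by ``&``-joined set
    names (exclusive regions, as a Venn diagram prints them).
    """
    if not interactors:
        raise ParameterError("at least one bait required")
    for bait, genes in interactors.items():
        if not genes:
            raise DataError(f"bait {bait!r} has an empty interactor set")
    sets: dict[str, set[str]] = {"identified": set(identified_genes)}
    sets.update({bait: set(genes) for bait, genes in interactors.items()})
    common = set(identified_genes)
    for genes in interactors.values():
        common &= genes

    venn: dict[str, int] = {}
    names = list(sets)
    universe = set().union(*sets.values())
    for r in range(1, len(names) + 1):
        for chosen in combinations(names, r):
            inside = set(universe)
            for name in chosen:
                inside &= sets[name]
            for name in names:
                if name not in chosen:
                    inside -= sets[name]
            venn["&".join(chosen)] = len(inside)
    return common, venn


def reduce_signature(
    matches: Sequence[MatchResult],
    common: set[str],
    feature_scores: Mapping[float, float] | None = None,
    per_gene_rule: str = "max_auc",
) -> Signature:
    """Collapse uniquely identified common-interactor matches to one
    feature per gene.

    ``per_gene_rule="max_auc"`` keeps the gene's most discriminative
    feature (score = |AUC - 0.5| from ``feature_scores``); ``"lowest_ppm"``
    keeps the best mass match.  Ties break to the lower m/z.  An empty
    result is valid (with a warning): the interactome simply contributes
    no signature.
    """
    if per_gene_rule not in ("max_auc", "lowest_ppm"):
        raise ParameterError(f"unknown per_gene_rule {per_gene_rule!r}")
    if per_gene_rule == "max_auc" and feature_scores is None:
        raise ParameterError("per_gene_rule 'max_auc' requires feature_scores")
    per_gene: dict[str, list[tuple[float, float]]] = {}  # gene -> [(mz, score)]
    provenance: dict[str, list[float]] = {}
    for m in matches:
        if m.unique_gene is None or m.unique_gene not in common:
            continue
        gene = m.unique_gene
        provenance.setdefault(gene, []).append(m.feature_mz)
        if per_gene_rule == "max_auc":
            score = abs(float(feature_scores.get(m.feature_mz, 0.5)) - 0.5)
        else:
            score = -min(abs(err) for _, err in m.candidates)
        per_gene.setdefault(gene, []).append((m.feature_mz, score))
    entries = []
    for gene, options in per_gene.items():
        best = max(options, key=lambda t: (t[1], -t[0]))  # ties -> lower m/z
        entries.append((best[0], gene))
    if not entries:
        warnings.warn("no uniquely identified common interactor matched; "
                      "signature is empty")
    return Signature(entries=entries, provenance=provenance)


def classify_nodules(
    fm: FeatureMatrix,
    signature: Signature,
    roi: ROIMap,
    k: int = 2,
    seed: int = 0,
    mixed_threshold: float = 0.7,
    anchor_gene: str = "PPIA",
    tol: float = 0.25,
) -> list[NoduleCall]:
    """2-means re-segmentation of NIFTP pixels on signature features only.

    The cluster with the higher mean intensity of the ``anchor_gene``
    feature (PPIA, selectively higher in RAS-mutant nodules) is oriented as
    RAS-like.  Each nodule is called from its pixel fractions: the dominant
    cluster if its fraction reaches ``mixed_threshold``, otherwise MIXED.
    A degenerate split (all pixels identical) yields MIXED calls and a
    warning.
    """
    if not signature.entries:
        raise DataError("signature is empty")
    if not 0.5 < mixed_threshold <= 1.0:
        raise ParameterError(
            f"mixed_threshold must be in (0.5, 1], got {mixed_threshold}"
        )
    labels = np.array(
        [str(roi.label_grid[y, x]) for x, y in fm.pixel_index], dtype=object
    )
    nodules = np.array([int(roi.nodule_grid[y, x]) for x, y in fm.pixel_index])
    rows = np.flatnonzero((labels == NIFTP) & (nodules >= 0))
    nodule_ids = sorted(int(n) for n in np.unique(nodules[rows]))
    if len(nodule_ids) < 2:
        raise DataError(f"need >= 2 NIFTP nodules, found {len(nodule_ids)}")
    cols = [fm.column_index(mz, tol) for mz in signature.feature_mz]
    sub = FeatureMatrix(
        feature_mz=fm.feature_mz[cols],
        values=fm.values[np.ix_(rows, cols)],
        pixel_index=[fm.pixel_index[i] for i in rows],
    )
    degenerate = bool(np.allclose(sub.values, sub.values[0]))
    if degenerate:
        warnings.warn("signature intensities are identical across NIFTP pixels; "
                      "split is degenerate, all calls MIXED")
        calls = []
        for nid in nodule_ids:
            n_pix = int(np.sum(nodules[rows] == nid))
            calls.append(NoduleCall(nid, {0: 1.0}, MIXED, n_pix))
        return calls
    seg = bisecting_kmeans(sub, k=k, seed=seed)
    leaf_ids = sorted(seg.leaves)

    # orient: leaf with higher mean anchor-gene intensity is the RAS-like pole
    anchor_col = sub.column_index(signature.mz_of(anchor_gene), tol)
    anchor_means = {
        leaf: float(sub.values[seg.assignment == leaf, anchor_col].mean())
        if np.any(seg.assignment == leaf) else -np.inf
        for leaf in leaf_ids
    }
    ras_leaf = max(anchor_means, key=anchor_means.get)

    calls: list[NoduleCall] = []
    sub_nodules = nodules[rows]
    for nid in nodule_ids:
        sel = sub_nodules == nid
        n_pix = int(sel.sum())
        fractions = {
            int(leaf): float(np.mean(seg.assignment[sel] == leaf))
            for leaf in leaf_ids
        }
        top_leaf = max(fractions, key=fractions.get)
        if fractions[top_leaf] < mixed_threshold:
            call = MIXED
        elif top_leaf == ras_leaf:
            call = RAS_LIKE
        else:
            call = WT_LIKE
        calls.append(NoduleCall(nid, fractions, call, n_pix))
    return calls


def cohort_summary(table: pd.DataFrame) -> dict:
    """Descriptive cohort statistics, patient-level and nodule-level.

    Patients are de-duplicated on ``patient_id`` (a bilateral case counts
    once for age/sex statistics); percentages are recomputed from raw
    counts.  Sample SD uses the n−1 denominator and is undefined (None) for
    a single patient.
    """
    from .msi_data import validate_cohort

    validate_cohort(table)
    patients = table.drop_duplicates(subset="patient_id")
    n_patients = len(patients)
    ages = patients["age"].astype(float)
    mean_age = float(ages.mean())
    sd_age = float(ages.std(ddof=1)) if n_patients > 1 else None
    n_female = int((patients["sex"] == "F").sum())

    n_nodules = len(table)
    ras = table["ras_status"].astype(str)
    mutant = ras != "WT"
    tallies = ras[mutant].value_counts().to_dict()
    diameters = table["diameter"].astype(float)
    return {
        "n_patients": n_patients,
        "n_nodules": n_nodules,
        "mean_age": mean_age,
        "sd_age": sd_age,
        "percent_female": round(100.0 * n_female / n_patients),
        "mean_diameter": float(diameters.mean()),
        "sd_diameter": float(diameters.std(ddof=1)) if n_nodules > 1 else None,
        "percent_ras_mutant": round(100.0 * int(mutant.sum()) / n_nodules),
        "mutation_tallies": {str(k): int(v) for k, v in sorted(tallies.items())},
    }
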