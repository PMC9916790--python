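"""Ground-truthed synthetic MALDI–MSI data emulating a thyroid-nodule study.

The generator plants a tryptic-peptide panel over an annotated tissue grid
with three region types — NIFTP nodules, a hyperplastic nodule (HP) and
surrounding thyroid parenchyma (THYP) — and produces, with known ground
truth, everything the downstream analysis consumes:

* a profile-mode datacube (Gaussian peaks + smooth baseline drift +
  per-pixel multiplicative TIC variation + additive noise, truncated at 0);
* the matching ROI map with nodule ids and planted RAS mutation classes;
* an LC–MS/MS-style identification table with ppm-jittered measured masses;
* per-bait interactor tables with a configured common-interactor core;
* a clinical cohort table reproducing the published 10-nodule series.

The default configuration encodes the study conditions the analysis is
validated against: a 30-peptide panel of which 8 are differential between
NIFTP and HP (four of them the RAS-interactome signature genes PPIA, ATP1A1,
CANX and BCAP31, elevated in RAS-mutant nodules), 9 NIFTP nodules (4 RAS, 4
wild-type, one 50/50 mixed core/rim), and instrument-like spectral parameters
(m/z 700–3000, 0.3 Da peak sigma, TIC coefficient of variation 0.2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigError
from .identification import PeptideID
from .msi_data import (
    HP,
    NIFTP,
    RAS_MUTANT,
    RAS_WT,
    THYP,
    UNANNOTATED,
    MSIDataset,
    ROIMap,
)

OVER = "OVER"
UNDER = "UNDER"
NULL = "NULL"

RAS_LIKE = "RAS_LIKE"
WT_LIKE = "WT_LIKE"
MIXED = "MIXED"

#: the four common NRAS/HRAS interactors that form the published signature
SIGNATURE_GENES = ("BCAP31", "CANX", "PPIA", "ATP1A1")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionSpec:
    """One annotated region.

    ``geometry`` is ``("rect", x0, y0, x1, y1)`` (inclusive corners),
    ``("disc", cx, cy, r)``, ``("annulus", cx, cy, r_in, r_out)`` or
    ``("rest",)`` — every grid pixel not claimed by another region.
    ``profile`` selects the intensity column of the peptide panel; NIFTP
    regions use their planted RAS class (``RAS_MUTANT``/``RAS_WT``) so a
    single nodule may be built from a core and a rim with divergent
    proteomic content.
    """

    label: str
    geometry: tuple
    nodule_id: int | None = None
    profile: str | None = None  # None -> the region label itself

    @property
    def profile_key(self) -> str:
        if self.label == NIFTP and self.profile:
            return f"{NIFTP}:{self.profile}"
        return self.label


@dataclass(frozen=True)
class PeptideSpec:
    """One planted tryptic peptide.

    ``region_intensity`` maps profile keys (``"HP"``, ``"THYP"``,
    ``"NIFTP:RAS_MUTANT"``, ``"NIFTP:RAS_WT"``) to the mean peak apex
    amplitude in that tissue context; absent keys mean absent peptide.
    """

    theoretical_mz: float
    gene: str
    region_intensity: Mapping[str, float]
    peak_sigma: float = 0.3  # Da, TOF-like at this mass range

    def amplitude(self, profile_key: str) -> float:
        return float(self.region_intensity.get(profile_key, 0.0))


@dataclass(frozen=True)
class SimulationConfig:
    grid: tuple[int, int]  # (width, height)
    regions: tuple[RegionSpec, ...]
    peptide_panel: tuple[PeptideSpec, ...]
    baseline: tuple[float, float] = (3.0, 400.0)  # (amplitude, length-scale Da)
    tic_variation: float = 0.2    # CV of the per-pixel multiplicative factor
    noise_sd: float = 1.0         # additive intensity noise
    mz_axis: tuple[float, float, float] = (700.0, 3000.0, 0.25)
    ppm_jitter: float = 50.0      # |measured - theoretical| bound, ppm
    nodule_classes: Mapping[int, str] = field(default_factory=dict)
    seed: int = 42

    def mz_grid(self) -> np.ndarray:
        lo, hi, step = self.mz_axis
        n = int(math.floor((hi - lo) / step)) + 1
        return lo + step * np.arange(n)

    def validate(self) -> None:
        w, h = self.grid
        if w <= 0 or h <= 0:
            raise ConfigError(f"empty grid {self.grid}")
        lo, hi, step = self.mz_axis
        if not (lo < hi and step > 0):
            raise ConfigError(f"bad mz_axis {self.mz_axis}")
        if self.tic_variation < 0 or self.noise_sd < 0 or self.ppm_jitter < 0:
            raise ConfigError("tic_variation, noise_sd and ppm_jitter must be >= 0")
        for pep in self.peptide_panel:
            if not lo <= pep.theoretical_mz <= hi:
                raise ConfigError(
                    f"peptide {pep.gene} m/z {pep.theoretical_mz} outside axis"
                )
            if pep.peak_sigma <= 0:
                raise ConfigError(f"peptide {pep.gene}: peak_sigma must be > 0")
        n_rest = sum(1 for r in self.regions if r.geometry[0] == "rest")
        if n_rest > 1:
            raise ConfigError("at most one 'rest' region allowed")
        for r in self.regions:
            if r.label not in (NIFTP, HP, THYP):
                raise ConfigError(f"unknown region label {r.label!r}")
        # explicit geometries must not overlap
        claimed = np.zeros((h, w), dtype=bool)
        for r in self.regions:
            if r.geometry[0] == "rest":
                continue
            mask = _rasterize(r.geometry, w, h)
            if np.any(claimed & mask):
                raise ConfigError(f"region {r} overlaps an earlier region")
            claimed |= mask


def _rasterize(geometry: tuple, w: int, h: int) -> np.ndarray:
    kind = geometry[0]
    yy, xx = np.mgrid[0:h, 0:w]
    if kind == "rect":
        _, x0, y0, x1, y1 = geometry
        return (xx >= x0) & (xx <= x1) & (yy >= y0) & (yy <= y1)
    if kind == "disc":
        _, cx, cy, r = geometry
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    if kind == "annulus":
        _, cx, cy, r_in, r_out = geometry
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        return (d2 > r_in**2) & (d2 <= r_out**2)
    if kind == "rest":
        return np.ones((h, w), dtype=bool)  # resolved by the caller
    raise ConfigError(f"unknown geometry kind {kind!r}")


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

def _panel() -> tuple[PeptideSpec, ...]:
    """30-peptide default panel; profiles are (NIFTP-RAS, NIFTP-WT, HP, THYP).

    The four configured totals are equal (940 per profile), so total ion
    current differences between regions are purely instrumental and TIC
    normalisation is exactly the right correction.
    """
    NR, NW = f"{NIFTP}:{RAS_MUTANT}", f"{NIFTP}:{RAS_WT}"

    def pep(mz: float, gene: str, nr: float, nw: float, hp: float, thyp: float):
        return PeptideSpec(mz, gene, {NR: nr, NW: nw, HP: hp, THYP: thyp})

    differential = [
        pep(815.39, "RBMX", 60, 60, 20, 20),
        pep(894.42, "PRDX1", 60, 60, 20, 20),
        pep(944.50, "BCAP31", 80, 40, 20, 20),
        pep(952.35, "SFPQ", 30, 30, 150, 20),
        pep(1002.40, "CANX", 80, 40, 20, 20),
        pep(1063.57, "HNRNPM", 30, 30, 150, 20),
        pep(1505.83, "PPIA", 80, 40, 20, 20),
        pep(1584.90, "ATP1A1", 80, 40, 20, 20),
    ]
    parenchyma = [  # stromal collagens, high in the surrounding parenchyma
        pep(836.48, "COL1A1", 20, 20, 20, 150),
        pep(868.39, "COL1A2", 20, 20, 20, 150),
    ]
    ras_down = [  # redistributed within NIFTP: down in RAS-mutant nodules
        pep(1198.70, "VIM", 20, 60, 40, 40),
        pep(1274.65, "ACTB", 20, 60, 40, 40),
        pep(1352.72, "GAPDH", 20, 60, 40, 40),
        pep(1436.55, "HNRNPA1", 20, 60, 40, 40),
    ]
    null_genes = [
        ("ALB", 731.42), ("HBB", 772.51), ("TG", 921.48), ("TPO", 1033.51),
        ("KRT8", 1105.58), ("KRT18", 1161.63), ("ANXA2", 1241.61),
        ("HSPA8", 1309.66), ("LDHA", 1399.69), ("ENO1", 1477.80),
        ("PKM", 1551.74), ("TUBB", 1675.84), ("EEF1A1", 1743.86),
        ("RPL7", 1832.91), ("MYH9", 1979.02), ("HIST1H2BK", 2211.10),
    ]
    nulls = [pep(mz, gene, 20, 20, 20, 20) for gene, mz in null_genes]
    return tuple(differential + parenchyma + ras_down + nulls)


def default_config(seed: int = 42) -> SimulationConfig:
    """The default simulated study: 60×40 grid, 9 NIFTP nodules, HP, THYP.

    Nodules 1–4 are planted RAS-mutant, 5–8 wild-type; nodule 9 is
    RAS-mutant by genotype but proteomically mixed — a RAS-like core under
    a wild-type-like rim of near-equal area, mirroring a bilateral/mixed
    clinical case.
    """
    regions = [RegionSpec(HP, ("rect", 4, 4, 55, 13))]
    for i, cx in enumerate([5, 12, 19, 26, 33, 40, 47, 54]):
        nid = i + 1
        profile = RAS_MUTANT if nid <= 4 else RAS_WT
        regions.append(
            RegionSpec(NIFTP, ("disc", cx, 33, 3.5), nodule_id=nid, profile=profile)
        )
    regions.append(  # mixed nodule: RAS-like core, WT-like rim
        RegionSpec(NIFTP, ("disc", 30, 20, 3.5), nodule_id=9, profile=RAS_MUTANT)
    )
    regions.append(
        RegionSpec(NIFTP, ("annulus", 30, 20, 3.5, 5.0), nodule_id=9, profile=RAS_WT)
    )
    regions.append(RegionSpec(THYP, ("rest",)))
    nodule_classes = {nid: (RAS_MUTANT if nid <= 4 else RAS_WT) for nid in range(1, 9)}
    nodule_classes[9] = RAS_MUTANT  # genotype; proteome is mixed
    return SimulationConfig(
        grid=(60, 40),
        regions=tuple(regions),
        peptide_panel=_panel(),
        nodule_classes=nodule_classes,
        seed=seed,
    )


def small_config(seed: int = 42) -> SimulationConfig:
    """A miniature cube (16×12 grid, m/z 700–1000) for I/O round-trips and
    quick smoke runs; same structure as the default, far fewer pixels."""
    NR, NW = f"{NIFTP}:{RAS_MUTANT}", f"{NIFTP}:{RAS_WT}"

    def pep(mz, gene, nr, nw, hp, thyp):
        return PeptideSpec(mz, gene, {NR: nr, NW: nw, HP: hp, THYP: thyp})

    panel = (
        pep(731.42, "ALB", 20, 20, 20, 20),
        pep(772.51, "HBB", 20, 20, 20, 20),
        pep(815.39, "RBMX", 60, 60, 20, 20),
        pep(836.48, "COL1A1", 20, 20, 20, 100),
        pep(894.42, "PRDX1", 60, 60, 20, 20),
        pep(921.48, "TG", 20, 20, 20, 20),
        pep(944.50, "BCAP31", 80, 40, 20, 20),
        pep(952.35, "SFPQ", 30, 30, 120, 20),
    )
    regions = (
        RegionSpec(HP, ("rect", 1, 1, 14, 4)),
        RegionSpec(NIFTP, ("disc", 4, 8, 2.2), nodule_id=1, profile=RAS_MUTANT),
        RegionSpec(NIFTP, ("disc", 11, 8, 2.2), nodule_id=2, profile=RAS_WT),
        RegionSpec(THYP, ("rest",)),
    )
    return SimulationConfig(
        grid=(16, 12),
        regions=regions,
        peptide_panel=panel,
        mz_axis=(700.0, 1000.0, 0.25),
        nodule_classes={1: RAS_MUTANT, 2: RAS_WT},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """What the generator planted, exposed for recovery tests."""

    config: SimulationConfig
    pixel_profile: np.ndarray        # profile key per dataset pixel (object)
    pixel_label: np.ndarray          # region label per dataset pixel
    nodule_classes: dict[int, str]   # planted genotype per NIFTP nodule
    expected_calls: dict[int, str]   # expected proteomic call per nodule

    @property
    def panel(self) -> tuple[PeptideSpec, ...]:
        return self.config.peptide_panel

    def snap_factor(self, pep: PeptideSpec) -> float:
        """Attenuation of the apex from sampling the Gaussian on the grid."""
        lo, _hi, step = self.config.mz_axis
        offset = (pep.theoretical_mz - lo) % step
        delta = min(offset, step - offset)
        return math.exp(-0.5 * (delta / pep.peak_sigma) ** 2)

    def expected_apex(self, pep: PeptideSpec, profile_key: str) -> float:
        return pep.amplitude(profile_key) * self.snap_factor(pep)

    def label_mean(self, pep: PeptideSpec, label: str) -> float:
        """Configured mean for a region label (unweighted over its profiles)."""
        keys = sorted({str(k) for k in self.pixel_profile[self.pixel_label == label]})
        if not keys:
            return 0.0
        return float(np.mean([pep.amplitude(k) for k in keys]))

    def differential_status(self, comparison: tuple[str, str]) -> dict[float, str]:
        """OVER/UNDER/NULL per planted m/z for (positive, reference) labels."""
        pos, ref = comparison
        out: dict[float, str] = {}
        for pep in self.panel:
            a, b = self.label_mean(pep, pos), self.label_mean(pep, ref)
            if math.isclose(a, b, rel_tol=1e-12, abs_tol=1e-12):
                out[pep.theoretical_mz] = NULL
            else:
                out[pep.theoretical_mz] = OVER if a > b else UNDER
        return out

    def population_auc(self, pep: PeptideSpec, comparison: tuple[str, str]) -> float:
        """P(positive-pixel intensity > reference-pixel intensity) under the
        additive-noise model, mixing the label's profiles by pixel count.

        Ignores TIC variation and baseline residuals; exact in the
        noise-only limit and a close approximation at the default settings.
        """
        pos, ref = comparison
        sd = self.config.noise_sd
        out = 0.0
        for key_a, w_a in self._profile_weights(pos).items():
            mu_a = self.expected_apex(pep, key_a)
            for key_b, w_b in self._profile_weights(ref).items():
                mu_b = self.expected_apex(pep, key_b)
                if sd == 0:
                    p = 0.5 if mu_a == mu_b else float(mu_a > mu_b)
                else:
                    p = float(norm.cdf((mu_a - mu_b) / (math.sqrt(2) * sd)))
                out += w_a * w_b * p
        return out

    def _profile_weights(self, label: str) -> dict[str, float]:
        keys = self.pixel_profile[self.pixel_label == label].astype(str)
        values, counts = np.unique(keys, return_counts=True)
        return {v: c / counts.sum() for v, c in zip(values, counts)}

    def to_json_dict(self) -> dict:
        per_pair = {}
        for pair in ((NIFTP, HP), (NIFTP, THYP), (HP, THYP)):
            per_pair[f"{pair[0]}:{pair[1]}"] = {
                f"{mz:.4f}": status
                for mz, status in self.differential_status(pair).items()
            }
        return {
            "panel": [
                {"mz": p.theoretical_mz, "gene": p.gene,
                 "region_intensity": dict(p.region_intensity)}
                for p in self.panel
            ],
            "differential": per_pair,
            "nodule_classes": {str(k): v for k, v in self.nodule_classes.items()},
            "expected_calls": {str(k): v for k, v in self.expected_calls.items()},
        }


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _resolve_regions(cfg: SimulationConfig):
    """Label, nodule and profile grids from the region specs."""
    w, h = cfg.grid
    label_grid = np.full((h, w), UNANNOTATED, dtype=object)
    nodule_grid = np.full((h, w), -1, dtype=int)
    profile_grid = np.full((h, w), "", dtype=object)
    rest_spec = None
    claimed = np.zeros((h, w), dtype=bool)
    for spec in cfg.regions:
        if spec.geometry[0] == "rest":
            rest_spec = spec
            continue
        mask = _rasterize(spec.geometry, w, h)
        label_grid[mask] = spec.label
        profile_grid[mask] = spec.profile_key
        if spec.nodule_id is not None:
            nodule_grid[mask] = spec.nodule_id
        claimed |= mask
    if rest_spec is not None:
        mask = ~claimed
        label_grid[mask] = rest_spec.label
        profile_grid[mask] = rest_spec.profile_key
    return label_grid, nodule_grid, profile_grid


def _baseline_curve(cfg: SimulationConfig, mz: np.ndarray) -> np.ndarray:
    amplitude, length_scale = cfg.baseline
    if amplitude == 0:
        return np.zeros_like(mz)
    lo = cfg.mz_axis[0]
    t = mz - lo
    decay = np.exp(-t / (3.0 * length_scale))
    osc = 1.2 + 0.5 * np.cos(2 * np.pi * t / length_scale) + 0.3 * np.cos(
        2 * np.pi * t / (2.25 * length_scale)
    )
    return amplitude * decay * osc / 2.0  # strictly positive by construction


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[MSIDataset, ROIMap, GroundTruth]:
    """Simulate one datacube plus its ROI annotation and ground truth.

    Each pixel spectrum is ``TIC_factor * (sum of Gaussian peaks + baseline
    + Gaussian noise)``, truncated at zero.  Byte-identical output under a
    fixed seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    w, h = cfg.grid
    mz = cfg.mz_grid()
    label_grid, nodule_grid, profile_grid = _resolve_regions(cfg)

    pixels = [(x, y) for y in range(h) for x in range(w)]  # row-major
    n_pix = len(pixels)
    profile_per_pixel = np.array(
        [str(profile_grid[y, x]) for x, y in pixels], dtype=object
    )
    label_per_pixel = np.array(
        [str(label_grid[y, x]) for x, y in pixels], dtype=object
    )

    # clean signal: peaks + baseline, assembled per profile key
    clean = np.tile(_baseline_curve(cfg, mz), (n_pix, 1))
    profile_keys = np.unique(profile_per_pixel.astype(str))
    lo, _hi, step = cfg.mz_axis
    for pep in cfg.peptide_panel:
        # +-8 sigma: the clipped tail is < 1.3e-14 of the apex
        half = int(math.ceil(8 * pep.peak_sigma / step))
        centre = int(round((pep.theoretical_mz - lo) / step))
        sl = slice(max(0, centre - half), min(len(mz), centre + half + 1))
        shape = np.exp(
            -0.5 * ((mz[sl] - pep.theoretical_mz) / pep.peak_sigma) ** 2
        )
        for key in profile_keys:
            amp = pep.amplitude(str(key))
            if amp == 0:
                continue
            rows = np.flatnonzero(profile_per_pixel.astype(str) == key)
            clean[np.ix_(rows, np.arange(sl.start, sl.stop))] += amp * shape

    # additive detector noise, then the per-pixel multiplicative TIC factor
    # (log-normal, mean 1).  The factor models per-pixel ablation/ionisation
    # efficiency and therefore scales the whole measured spectrum, noise
    # included — which is exactly the distortion TIC normalisation corrects.
    if cfg.noise_sd > 0:
        clean += rng.normal(0.0, cfg.noise_sd, size=clean.shape)
    if cfg.tic_variation > 0:
        sigma_ln = math.sqrt(math.log(1 + cfg.tic_variation**2))
        tic = rng.lognormal(mean=-0.5 * sigma_ln**2, sigma=sigma_ln, size=n_pix)
        clean *= tic[:, None]
    np.maximum(clean, 0.0, out=clean)

    ds = MSIDataset.from_matrix(
        pixels,
        mz,
        clean,
        mz_range=(cfg.mz_axis[0], cfg.mz_axis[1]),
        metadata={"simulated": True, "seed": cfg.seed},
    )
    roi = ROIMap(
        label_grid,
        nodule_grid,
        mutation_status=dict(cfg.nodule_classes),
    )
    expected_calls = _expected_calls(cfg, profile_grid, nodule_grid)
    truth = GroundTruth(
        config=cfg,
        pixel_profile=profile_per_pixel,
        pixel_label=label_per_pixel,
        nodule_classes=dict(cfg.nodule_classes),
        expected_calls=expected_calls,
    )
    return ds, roi, truth


def _expected_calls(cfg, profile_grid, nodule_grid, mixed_threshold=0.7):
    """Planted proteomic call per nodule from its profile composition."""
    calls: dict[int, str] = {}
    for nid in sorted(cfg.nodule_classes):
        mask = nodule_grid == nid
        if not np.any(mask):
            continue
        keys = profile_grid[mask].astype(str)
        frac_ras = float(np.mean(keys == f"{NIFTP}:{RAS_MUTANT}"))
        if frac_ras >= mixed_threshold:
            calls[nid] = RAS_LIKE
        elif frac_ras <= 1 - mixed_threshold:
            calls[nid] = WT_LIKE
        else:
            calls[nid] = MIXED
    return calls


# ---------------------------------------------------------------------------
# identification table
# ---------------------------------------------------------------------------

_RESIDUES = "ACDEFGHILMNPSTVWY"  # K/R reserved for the tryptic terminus
_MEAN_RESIDUE_MASS = 111.0


def _tryptic_sequence(rng: np.random.Generator, mz: float) -> str:
    n = max(2, int(round((mz - 19.0) / _MEAN_RESIDUE_MASS)))
    body = "".join(rng.choice(list(_RESIDUES), size=n - 1))
    terminus = "K" if rng.random() < 0.5 else "R"
    return body + terminus


#: extra same-gene peptides co-matching a signature feature, so that the
#: signature genes carry 7 identified peptides over 4 proteins
EXTRA_SIGNATURE_PEPTIDES = (
    ("BCAP31", 944.53),
    ("CANX", 1002.37),
    ("ATP1A1", 1584.95),
)


def simulate_id_table(
    cfg: SimulationConfig,
    include_extra_signature_peptides: bool = True,
) -> list[PeptideID]:
    """LC–MS/MS-style identifications for the planted panel.

    Measured m/z = theoretical × (1 + ε) with ε uniform within the
    configured ppm jitter.  Peptides whose theoretical m/z collide within
    that jitter window across different genes are flagged non-unique.
    """
    cfg.validate()
    rng = np.random.default_rng(_derive_seed(cfg.seed, "id_table"))
    entries: list[tuple[float, str]] = [
        (p.theoretical_mz, p.gene) for p in cfg.peptide_panel
    ]
    if include_extra_signature_peptides:
        entries += [(mz, gene) for gene, mz in EXTRA_SIGNATURE_PEPTIDES]

    rows: list[PeptideID] = []
    for theo, gene in entries:
        eps = rng.uniform(-cfg.ppm_jitter, cfg.ppm_jitter) * 1e-6
        measured = theo * (1 + eps)
        rows.append(
            PeptideID(
                sequence=_tryptic_sequence(rng, theo),
                gene=gene,
                protein=f"{gene}_HUMAN",
                measured_mz=measured,
                theoretical_mz=theo,
                modifications=(),
                unique_for_protein=True,
            )
        )
    # cross-gene m/z collisions (within jitter) make both rows non-unique
    for i, a in enumerate(rows):
        for b in rows[i + 1:]:
            if a.gene != b.gene and abs(a.theoretical_mz - b.theoretical_mz) <= (
                2e-6 * cfg.ppm_jitter * a.theoretical_mz
            ):
                rows[rows.index(a)] = _replace_unique(a, False)
                rows[rows.index(b)] = _replace_unique(b, False)
    return rows


def _replace_unique(pid: PeptideID, flag: bool) -> PeptideID:
    from dataclasses import replace

    return replace(pid, unique_for_protein=flag)


# ---------------------------------------------------------------------------
# interactome
# ---------------------------------------------------------------------------

def simulate_interactome(
    cfg: SimulationConfig,
    baits: Sequence[str] = ("NRAS", "HRAS"),
    common: Sequence[str] = SIGNATURE_GENES,
    n_decoys: int = 500,
) -> dict[str, set[str]]:
    """Per-bait interactor sets with a configured common core.

    Non-common panel genes are split disjointly between baits (so the
    across-bait intersection within the panel is exactly ``common``), and
    each bait is padded with synthetic decoy genes up to a realistic size.
    """
    if not baits:
        raise ConfigError("at least one bait required")
    rng = np.random.default_rng(_derive_seed(cfg.seed, "interactome"))
    panel_genes = [p.gene for p in cfg.peptide_panel]
    others = [g for g in panel_genes if g not in set(common)]
    rng.shuffle(others)
    per_bait_extra = len(others) // (len(baits) + 1)
    out: dict[str, set[str]] = {}
    for i, bait in enumerate(baits):
        share = others[i * per_bait_extra:(i + 1) * per_bait_extra]
        decoys = {
            f"DECOY{i}_{j:04d}" for j in range(n_decoys + 10 * i)
        }  # slight size asymmetry between baits, as in real databases
        out[bait] = set(common) | set(share) | decoys
    return out


def write_interactome(interactors: Mapping[str, set[str]], path: str) -> str:
    """Two-column (bait, interactor) TSV, IntAct-export-like."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("bait\tinteractor\n")
        for bait in sorted(interactors):
            for gene in sorted(interactors[bait]):
                fh.write(f"{bait}\t{gene}\n")
    return path


def read_interactome(path: str) -> dict[str, set[str]]:
    table = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for _, row in table.iterrows():
        out.setdefault(str(row["bait"]), set()).add(str(row["interactor"]))
    return out


# ---------------------------------------------------------------------------
# cohort fixture
# ---------------------------------------------------------------------------

def fixture_table1() -> pd.DataFrame:
    """The published 10-nodule clinical series (one bilateral patient).

    Cases 9 and 10 are the left and right nodules of a single patient and
    share a patient id; all other cases are one patient each.
    """
    rows = [
        # case, patient, age, sex, n_nodules, diam, lobe, ras, others, other diseases, tsh, tpo, tg
        (1, "P1", 65, "F", "3", 0.3, "Left", "NRAS Q61R",
         "PTCH1, RAD51B, SMARCA4", "Hurthle cell carcinoma - Right lobe", 1.9, 8.0, 11.0),
        (2, "P2", 52, "F", "2", 0.5, "Left", "HRAS A59T",
         "RICTOR, CHEK2, SLX4", "Multinodular goitre and C cell hyperplasia", 4.12, 10.0, 10.0),
        (3, "P3", 50, "F", "multiple", 1.3, "Right", "NRAS Q61R",
         "-", "PTC - Right lobe", 2.26, 9.0, 12.0),
        (4, "P4", 41, "F", "1", 5.5, "Right", "NRAS Q61R", "-", "-", 3.12, 7.0, 9.0),
        (5, "P5", 48, "M", "3", 3.0, "Right", "NRAS Q61R", "NOTCH2", "-", 0.6, 8.0, 11.0),
        (6, "P6", 61, "F", "1", 1.6, "Left", "WT", "NTRK1, FBXW7", "-", 1.5, 10.0, 12.0),
        (7, "P7", 58, "F", "1", 9.0, "Left", "WT",
         "MDM4, ESR1, CDKN2A, AXL", "microPTC - Right lobe", 1.16, 9.0, 11.0),
        (8, "P8", 53, "F", "multiple", 1.0, "Right", "WT",
         "SLX4, ATM, ARID1A, AXL", "Multinodular goitre", 4.4, 172.9, 2.83),
        (9, "P9", 56, "M", "2", 2.0, "Left", "HRAS Q61K", "SLX4", "-", 0.85, 5.0, 7.0),
        (10, "P9", 56, "M", "2", 2.0, "Right", "WT", "SLX4", "-", 0.85, 5.0, 7.0),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "case_id", "patient_id", "age", "sex", "n_nodules", "diameter",
            "lobe", "ras_status", "other_mutations", "other_diseases",
            "tsh", "anti_tpo", "anti_tg",
        ],
    )


def _derive_seed(root: int, stream: str) -> int:
    """Deterministic per-stream child seed below 2**31."""
    h = 0
    for ch in stream:
        h = (h * 131 + ord(ch)) % 1_000_003
    return (int(root) * 1_000_003 + h) % (2**31)
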