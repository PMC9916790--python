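"""End-to-end orchestration: simulate → preprocess → segment → discover →
identify → signature → classify → summarize, with a provenance manifest.

All stage parameters live in one :class:`PipelineConfig`; every source of
randomness derives deterministically from its root seed, so a rerun with
the same config produces identical artefacts (checksums included).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import yaml

from . import discovery as _discovery
from . import preprocess as _preprocess
from . import proteogenomics as _proteo
from . import segmentation as _segmentation
from . import synthetic_msi as _synth
from .errors import ConfigError
from .msi_data import NIFTP, HP, write_cohort, write_roi_map

logger = logging.getLogger("thyromsi")


@dataclass
class PipelineConfig:
    """Every tunable of every stage, with published-threshold defaults."""

    seed: int = 42
    outdir: str = "thyromsi-run"
    write_cube: bool = False          # full datacube artefacts are large
    cube_dialect: str = "internal"
    # preprocessing
    tophat_width: int = _preprocess.DEFAULT_TOPHAT_WIDTH
    tic_target: float | None = None
    snr_min: float = _preprocess.DEFAULT_SNR_MIN
    tol: float = _preprocess.DEFAULT_TOL
    denoise_radius: int = _preprocess.DEFAULT_DENOISE_RADIUS
    # segmentation
    k_tissue: int = 3
    k_niftp: int = 2
    # discovery
    comparison: tuple[str, str] = (NIFTP, HP)
    auc_min: float = _discovery.DEFAULT_AUC_MIN
    p_max: float = _discovery.DEFAULT_P_MAX
    # identification / signature
    tol_ppm: float = 100.0
    per_gene_rule: str = "max_auc"
    mixed_threshold: float = 0.7
    anchor_gene: str = "PPIA"
    # stage toggles
    stages: tuple[str, ...] = (
        "simulate", "preprocess", "segment", "discover",
        "identify", "signature", "classify", "summarize",
    )

    def validate(self) -> None:
        if not 0.5 < self.auc_min <= 1.0:
            raise ConfigError(f"auc_min must be in (0.5, 1], got {self.auc_min}")
        if not 0.0 < self.p_max <= 1.0:
            raise ConfigError(f"p_max must be in (0, 1], got {self.p_max}")
        if self.tol_ppm <= 0:
            raise ConfigError(f"tol_ppm must be > 0, got {self.tol_ppm}")
        if self.tol <= 0:
            raise ConfigError(f"tol must be > 0, got {self.tol}")
        if self.snr_min <= 0:
            raise ConfigError(f"snr_min must be > 0, got {self.snr_min}")
        if self.tophat_width % 2 == 0 or self.tophat_width < 3:
            raise ConfigError(
                f"tophat_width must be odd and >= 3, got {self.tophat_width}"
            )
        if self.denoise_radius < 0:
            raise ConfigError(f"denoise_radius must be >= 0")
        if self.k_tissue < 1 or self.k_niftp < 1:
            raise ConfigError("cluster counts must be >= 1")
        if not 0.5 < self.mixed_threshold <= 1.0:
            raise ConfigError(
                f"mixed_threshold must be in (0.5, 1], got {self.mixed_threshold}"
            )
        unknown = set(self.stages) - set(
            ("simulate", "preprocess", "segment", "discover", "identify",
             "signature", "classify", "summarize")
        )
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}")

    def stage_seed(self, stage: str) -> int:
        return _synth._derive_seed(self.seed, stage)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["comparison"] = list(self.comparison)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        d = dict(d)
        if "comparison" in d:
            d["comparison"] = tuple(d["comparison"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)


def _sha256(path: str) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _dump_json(obj: dict, path: str) -> str:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def run_all(cfg: PipelineConfig, sim_cfg: "_synth.SimulationConfig | None" = None) -> dict:
    """Run the configured stages on synthetic data; returns the manifest.

    Artefacts (tables, maps, JSON results, a manifest with SHA-256
    checksums and the full serialized config) are written under
    ``cfg.outdir``.  Raises with the failing stage named.
    """
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    if sim_cfg is None:
        sim_cfg = _synth.default_config(seed=cfg.stage_seed("simulate"))
    artefacts: list[str] = []
    state: dict = {"config": cfg}

    def emit(path: str) -> str:
        artefacts.append(path)
        return path

    def out(name: str) -> str:
        return os.path.join(cfg.outdir, name)

    stage_log: list[dict] = []
    for stage in cfg.stages:
        t0 = time.perf_counter()
        try:
            _STAGES[stage](cfg, sim_cfg, state, emit, out)
        except Exception:
            logger.exception("stage %s failed", stage)
            raise
        record = {
            "stage": stage,
            "seconds": round(time.perf_counter() - t0, 3),
            "seed": cfg.stage_seed(stage),
        }
        stage_log.append(record)
        logger.info("stage done %s", json.dumps(record, sort_keys=True))

    config_path = out("config.yaml")
    with open(config_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    emit(config_path)
    manifest = {
        "config": cfg.to_dict(),
        "stages": stage_log,
        "artefacts": [
            {"path": os.path.relpath(p, cfg.outdir), "sha256": _sha256(p)}
            for p in sorted(artefacts)
        ],
    }
    _dump_json(manifest, out("manifest.json"))
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg, sim_cfg, state, emit, out):
    ds, roi, truth = _synth.simulate_dataset(sim_cfg)
    state.update(ds=ds, roi=roi, truth=truth)
    if cfg.write_cube:
        from .msi_data import write_dataset

        emit(write_dataset(ds, out(f"cube.{cfg.cube_dialect}"), cfg.cube_dialect))
    for path in write_roi_map(roi, out("roi")):
        emit(path)
    _dump_json(truth.to_json_dict(), emit(out("ground_truth.json")))
    write_cohort(_synth.fixture_table1(), emit(out("cohort.csv")))


def _stage_preprocess(cfg, sim_cfg, state, emit, out):
    fm = _preprocess.preprocess_dataset(
        state["ds"],
        tophat_width=cfg.tophat_width,
        tic_target=cfg.tic_target,
        snr_min=cfg.snr_min,
        tol=cfg.tol,
        denoise_radius=cfg.denoise_radius,
    )
    state["fm"] = fm
    emit(fm.to_csv(out("features.csv")))


def _stage_segment(cfg, sim_cfg, state, emit, out):
    fm = state["fm"]
    seg = _segmentation.bisecting_kmeans(
        fm, k=cfg.k_tissue, seed=cfg.stage_seed("segment")
    )
    state["segmentation"] = seg
    _dump_json(seg.to_json_dict(), emit(out("segmentation.json")))
    import pandas as pd

    pd.DataFrame(
        {
            "pixel_x": [p[0] for p in fm.pixel_index],
            "pixel_y": [p[1] for p in fm.pixel_index],
            "cluster": seg.assignment,
        }
    ).to_csv(emit(out("assignment.csv")), index=False)
    _segmentation.render_map(
        seg.assignment, fm.pixel_index, kind="cluster",
        path=emit(out("cluster_map.png")),
    )


def _stage_discover(cfg, sim_cfg, state, emit, out):
    results = _discovery.discover(
        state["fm"], state["roi"], cfg.comparison,
        auc_min=cfg.auc_min, p_max=cfg.p_max,
    )
    state["discovery"] = results
    _discovery.results_frame(results).to_csv(emit(out("discovery.csv")), index=False)


def _stage_identify(cfg, sim_cfg, state, emit, out):
    from . import identification as _ident

    ids = _synth.simulate_id_table(sim_cfg)
    state["ids"] = ids
    _ident.write_id_table(ids, emit(out("identifications.tsv")))
    matches = _ident.match_features(
        state["fm"].feature_mz, ids, tol_ppm=cfg.tol_ppm
    )
    state["matches"] = matches
    _ident.write_matches(matches, emit(out("matches.tsv")))


def _stage_signature(cfg, sim_cfg, state, emit, out):
    interactors = _synth.simulate_interactome(sim_cfg)
    _synth.write_interactome(interactors, emit(out("interactome.tsv")))
    identified = {pid.gene for pid in state["ids"]}
    common, venn = _proteo.interactome_intersection(identified, interactors)
    _dump_json(
        {"common": sorted(common), "venn": venn}, emit(out("venn.json"))
    )
    scores = {r.feature_mz: r.auc for r in state["discovery"]}
    signature = _proteo.reduce_signature(
        state["matches"], common, feature_scores=scores,
        per_gene_rule=cfg.per_gene_rule,
    )
    state["signature"] = signature
    _dump_json(signature.to_json_dict(), emit(out("signature.json")))


def _stage_classify(cfg, sim_cfg, state, emit, out):
    calls = _proteo.classify_nodules(
        state["fm"], state["signature"], state["roi"],
        k=cfg.k_niftp, seed=cfg.stage_seed("classify"),
        mixed_threshold=cfg.mixed_threshold, anchor_gene=cfg.anchor_gene,
        tol=cfg.tol,
    )
    state["calls"] = calls
    import pandas as pd

    pd.DataFrame(
        [
            {
                "nodule_id": c.nodule_id,
                "call": c.call,
                "n_pixels": c.n_pixels,
                **{f"fraction_{k}": v for k, v in sorted(c.cluster_fractions.items())},
            }
            for c in calls
        ]
    ).to_csv(emit(out("nodule_calls.csv")), index=False)


def _stage_summarize(cfg, sim_cfg, state, emit, out):
    summary = _proteo.cohort_summary(_synth.fixture_table1())
    truth = state.get("truth")
    if truth is not None and "calls" in state:
        expected = truth.expected_calls
        calls = {c.nodule_id: c.call for c in state["calls"]}
        summary = {
            "cohort": summary,
            "nodule_calls_correct": sum(
                1 for nid, want in expected.items() if calls.get(nid) == want
            ),
            "nodule_calls_total": len(expected),
        }
    _dump_json(summary, emit(out("summary.json")))


_STAGES = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "segment": _stage_segment,
    "discover": _stage_discover,
    "identify": _stage_identify,
    "signature": _stage_signature,
    "classify": _stage_classify,
    "summarize": _stage_summarize,
}
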