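"""End-to-end orchestration: config, logging, and report generation.

``run_characterization`` executes the full breed-characterization chain —
QC, per-breed diversity, pairwise F_ST, Nei distances, PCA, LD pruning,
ROH detection, F_ROH, LD-based Ne — in a fixed declared order, and emits a
bundle of TSV/PHYLIP/NEXUS tables whose layout mirrors the standard
breed-report format (diversity table with Ho/He/F_IS/F_ROH/Ne columns,
F_ST matrix with per-breed means, F_ROH by length class, Ne trajectories,
PCA coordinates).  Every table carries the configuration hash, and
re-running with the same config and inputs reproduces byte-identical
files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genio import DataError, GenotypeMatrix, QCReport, ld_prune, qc_filter, read_plink, write_plink
from .diversity import diversity_table, fst_matrix, nei_distance, allele_frequencies, pca
from .roh import ROHParams, breed_froh, detect_roh, froh_table, segments_to_bed_frame
from .ne import DEFAULT_BIN_EDGES, MIN_PAIRS_PER_BIN, estimate_ne

logger = logging.getLogger(__name__)

_SCHEMA: dict[str, dict] = {
    "input": {"prefix": str, "sidecar": str},
    "qc": {"max_snp_missing": float, "max_sample_missing": float, "autosomes_only": bool},
    "prune": {"window_snps": int, "step_snps": int, "r2_threshold": float},
    "roh": {"alpha": float, "het": float, "l_min_snps": int, "max_gap_bp": int,
            "max_bp_per_snp": int, "min_length_bp": int},
    "ne": {"bin_edges": list, "max_pairs_per_bin": int, "min_pairs": int,
           "rate_cm_per_mb": float, "t_max": float},
    "pca": {"n_components": int},
    "seed": int,
    "out_dir": str,
    "breeds": list,
}


class ConfigError(DataError):
    """Configuration file fails schema validation."""


class StageError(DataError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    prefix: str
    sidecar: str | None = None
    breeds: list[str] | None = None
    qc: dict = field(default_factory=dict)
    prune: dict = field(default_factory=dict)
    roh: dict = field(default_factory=dict)
    ne: dict = field(default_factory=dict)
    pca: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "pramenka_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - set(_SCHEMA)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for section in ("input", "qc", "prune", "roh", "ne", "pca"):
            sub = raw.get(section) or {}
            if not isinstance(sub, dict):
                raise ConfigError(f"config section {section!r} must be a mapping")
            bad = set(sub) - set(_SCHEMA[section])
            if bad:
                raise ConfigError(f"unknown keys in section {section!r}: {sorted(bad)}")
        inp = raw.get("input") or {}
        if "prefix" not in inp:
            raise ConfigError("config requires input.prefix")
        return cls(
            prefix=str(inp["prefix"]),
            sidecar=inp.get("sidecar"),
            breeds=raw.get("breeds"),
            qc=raw.get("qc") or {},
            prune=raw.get("prune") or {},
            roh=raw.get("roh") or {},
            ne=raw.get("ne") or {},
            pca=raw.get("pca") or {},
            seed=int(raw.get("seed", 0)),
            out_dir=str(raw.get("out_dir", "pramenka_out")),
        )

    def to_dict(self) -> dict:
        return {
            "input": {"prefix": self.prefix, **({"sidecar": self.sidecar} if self.sidecar else {})},
            "breeds": self.breeds,
            "qc": self.qc, "prune": self.prune, "roh": self.roh,
            "ne": self.ne, "pca": self.pca,
            "seed": self.seed, "out_dir": self.out_dir,
        }

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    diversity: pd.DataFrame          # Ho/He/F_IS (+- SE), F_ROH>2Mb, current Ne
    fst: pd.DataFrame                # pairwise matrix with MFst column
    froh_classes: pd.DataFrame       # per-breed mean/SE by length class
    froh_individuals: pd.DataFrame
    roh_segments: pd.DataFrame       # BED-like, 0-based half-open
    ne_trajectories: pd.DataFrame    # per breed: generations, Ne, c, r2
    pca_coordinates: pd.DataFrame
    pca_variance: np.ndarray
    distances_phylip: str
    distances_nexus: str
    qc_report: QCReport
    pruned: GenotypeMatrix
    manifest: dict


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kw):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kw)
            except DataError as exc:
                raise StageError(name, exc) from exc
        return wrapper
    return deco


def run_characterization(cfg: RunConfig, data: GenotypeMatrix | None = None) -> ReportBundle:
    """Execute qc -> diversity -> fst -> distances -> pca -> prune -> roh ->
    froh -> ne and assemble the report bundle.

    ``data`` may be supplied directly (e.g. a simulated fixture); otherwise
    the PLINK prefix in the config is read.
    """
    if data is None:
        data = _stage("read")(read_plink)(cfg.prefix, cfg.sidecar)

    qc_data, qc_report = _stage("qc")(qc_filter)(data, **cfg.qc)
    qc_data = qc_data.sort_markers()
    breeds = cfg.breeds or qc_data.breeds()

    div = _stage("diversity")(diversity_table)(qc_data, breeds)
    fst = _stage("fst")(fst_matrix)(qc_data, breeds)
    freqs = allele_frequencies(qc_data, breeds)
    dist = _stage("distances")(nei_distance)(freqs)
    pca_res = _stage("pca")(pca)(qc_data, **cfg.pca)
    pruned = _stage("prune")(ld_prune)(qc_data, **cfg.prune)

    roh_params = _stage("roh")(ROHParams.from_data)(qc_data, **cfg.roh)
    froh_ind = _stage("roh")(froh_table)(qc_data, roh_params)
    froh_breed = _stage("froh")(breed_froh)(froh_ind)
    segments = []
    for i in range(qc_data.n_samples):
        segments.extend(
            detect_roh(qc_data.genotypes[i], qc_data.markers, roh_params,
                       sample_id=qc_data.samples["sample_id"].iat[i])
        )
    seg_frame = segments_to_bed_frame(segments)

    ne_rows = []
    ne_current: dict[str, float] = {}
    ne_kw = dict(cfg.ne)
    bin_edges = tuple(ne_kw.pop("bin_edges", DEFAULT_BIN_EDGES))
    min_pairs = int(ne_kw.pop("min_pairs", MIN_PAIRS_PER_BIN))
    for b in breeds:
        n_b = int((qc_data.samples["breed"] == b).sum())
        if n_b < 10:
            logger.warning("ne: breed %s has %d individuals (<10); skipped", b, n_b)
            ne_current[b] = float("nan")
            continue
        try:
            traj = _stage("ne")(estimate_ne)(
                qc_data, b, bin_edges=bin_edges, seed=cfg.seed,
                min_pairs=min_pairs, **ne_kw,
            )
        except StageError as exc:
            logger.warning("ne: breed %s unusable (%s); skipped", b, exc.cause)
            ne_current[b] = float("nan")
            continue
        ne_current[b] = traj.ne_current
        pts = traj.points.copy()
        pts.insert(0, "breed", b)
        ne_rows.append(pts)
    ne_traj = pd.concat(ne_rows, ignore_index=True) if ne_rows else pd.DataFrame(
        columns=["breed", "generations", "ne", "c_mid", "r2_mean", "n_pairs"]
    )

    # Table-1-layout diversity report
    froh_by_breed = froh_breed.set_index("breed")
    div = div.copy()
    div["froh_gt2_mean"] = [froh_by_breed.loc[b, "froh_total_mean"] for b in div["breed"]]
    div["froh_gt2_se"] = [froh_by_breed.loc[b, "froh_total_se"] for b in div["breed"]]
    div["ne_current"] = [ne_current[b] for b in div["breed"]]

    manifest = {
        "tool": "pramenka",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_samples_qc": qc_data.n_samples,
        "n_snps_qc": qc_data.n_snps,
        "n_snps_pruned": pruned.n_snps,
        "roh_l_min_snps": roh_params.l_min_snps,
        "breeds": ",".join(breeds),
    }
    return ReportBundle(
        diversity=div,
        fst=fst.to_frame(),
        froh_classes=froh_breed,
        froh_individuals=froh_ind,
        roh_segments=seg_frame,
        ne_trajectories=ne_traj,
        pca_coordinates=pca_res.coordinates,
        pca_variance=pca_res.variance_fraction,
        distances_phylip=dist.to_phylip(),
        distances_nexus=dist.to_nexus(),
        qc_report=qc_report,
        pruned=pruned,
        manifest=manifest,
    )


def _write_table(df: pd.DataFrame, path: Path, manifest: dict, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={manifest['config_hash']}\n")
        fh.write(f"# pramenka_version={manifest['version']} seed={manifest['seed']}\n")
        fh.write(df.to_csv(sep="\t", index=index, float_format="%.6g"))


def write_bundle(bundle: ReportBundle, out_dir: str | Path) -> Path:
    """Write every report artifact under ``out_dir``; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    m = bundle.manifest
    _write_table(bundle.diversity, out / "diversity_table.tsv", m)
    _write_table(bundle.fst, out / "fst_matrix.tsv", m, index=True)
    _write_table(bundle.froh_classes, out / "froh_by_breed.tsv", m)
    _write_table(bundle.froh_individuals, out / "froh_individuals.tsv", m)
    _write_table(bundle.ne_trajectories, out / "ne_trajectories.tsv", m)
    pca_df = bundle.pca_coordinates.copy()
    with open(out / "pca_coordinates.tsv", "w") as fh:
        fh.write(f"# config_hash={m['config_hash']}\n")
        fh.write("# variance_fraction_percent="
                 + ",".join(f"{v:.4f}" for v in bundle.pca_variance) + "\n")
        fh.write(pca_df.to_csv(sep="\t", index=True, float_format="%.6g"))
    with open(out / "roh_segments.bed.tsv", "w") as fh:
        fh.write("# coordinates: 0-based half-open\n")
        fh.write(f"# config_hash={m['config_hash']}\n")
        fh.write(bundle.roh_segments.to_csv(sep="\t", index=False))
    (out / "distances.phy").write_text(bundle.distances_phylip)
    (out / "distances.nex").write_text(bundle.distances_nexus)
    bundle.qc_report.to_tsv(out / "qc_report.tsv")
    write_plink(bundle.pruned, out / "pruned")
    with open(out / "manifest.json", "w") as fh:
        json.dump(m, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("report bundle written to %s", out)
    return out
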