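"""End-to-end orchestration: cohort → features → distances → embedding → separation.

A run evaluates every requested (feature kind, parameter) cell on the raw
and/or preprocessed path and collects one results row per cell: ensemble
mean ± SD of the group Jensen–Shannon distance and the mean subject-cluster
ratio ρ.  Feature kinds:

* ``op_dist``    — per-channel ordinal-pattern distributions, d_nm distance
* ``mi``         — ordinal-pattern mutual-information adjacency, Euclidean
* ``psd``        — per-channel (band-restricted) PSDs, d_nm distance
* ``coherence``  — band-averaged coherence adjacency, Euclidean

Parameters are time scales τ (ms) for the ordinal kinds and band names
("theta", "alpha", "beta", "gamma", "full") for the spectral kinds.  Every
sample point is one (subject, condition) cell of the cohort.  Runs are
deterministic given the master seed and write a manifest with checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import EEGDataset
from .divergences import ChannelFeatureVector, pairwise_distances
from .ordinal import OPConfig, encode_trialset, mi_adjacency, op_distribution
from .preprocessing import PreprocConfig, preprocess_trials
from .separation import cluster_ratio_rho, ensemble_jsd
from .spectral import BandDefinition, band_restrict, coherence_matrix, psd_average, trial_spectra
from .synth import CohortConfig, generate_cohort
from .tsne import TSNEConfig, tsne_ensemble

logger = logging.getLogger(__name__)

FEATURE_KINDS = ("op_dist", "mi", "psd", "coherence")


@dataclass
class PipelineConfig:
    """Full run configuration; defaults mirror the study-scale analysis."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    paths: tuple[str, ...] = ("raw", "preprocessed")
    feature_kinds: tuple[str, ...] = FEATURE_KINDS
    taus_ms: tuple[float, ...] = (15.0, 100.0)
    bands: tuple[str, ...] = ("theta", "alpha", "beta", "gamma", "full")
    op_w: int = 4
    perplexity: float = 30.0
    n_tsne_runs: int = 100
    tsne_iter: int = 1000
    gridsize: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.feature_kinds) - set(FEATURE_KINDS)
        if unknown:
            raise ValueError(f"unknown feature kinds: {unknown}")
        if set(self.paths) - {"raw", "preprocessed"}:
            raise ValueError("paths must be 'raw' and/or 'preprocessed'")

    @classmethod
    def scaled_down(cls, seed: int = 0) -> "PipelineConfig":
        """Small profile for smoke runs: 16 channels, short grids, 10 seeds."""
        cohort = CohortConfig(
            n_young=5, n_elderly=5, n_channels=16, n_trials_per_condition=10,
            conditions=("pre", "post"), seed=seed,
        )
        return cls(cohort=cohort, paths=("raw",), taus_ms=(15.0,),
                   bands=("theta", "alpha"), perplexity=5.0, n_tsne_runs=10,
                   tsne_iter=400, seed=seed)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f)
        cohort = CohortConfig(**raw.pop("cohort", {}))
        preproc = PreprocConfig(**raw.pop("preproc", {}))
        for key in ("paths", "feature_kinds", "taus_ms", "bands"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(cohort=cohort, preproc=preproc, **raw)


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    seed: int
    files: dict[str, str] = field(default_factory=dict)  # path -> sha256
    version: str = "0.1.0"

    def validate(self, root: Path) -> None:
        for rel, digest in self.files.items():
            p = root / rel
            if not p.exists():
                raise FileNotFoundError(f"manifest lists missing file {rel}")
            if _sha256(p) != digest:
                raise ValueError(f"checksum mismatch for {rel}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ------------------------------------------------------------------ features


def compute_feature_samples(dataset: EEGDataset, kind: str, param,
                            op_w: int = 4) -> tuple[list, list[dict]]:
    """One feature object + label dict per (subject, condition) cell."""
    samples, labels = [], []
    for ts in dataset:
        label = {"subject": ts.subject, "group": ts.group, "condition": ts.condition}
        if kind in ("op_dist", "mi"):
            cfg = OPConfig(w=op_w, tau_ms=float(param))
            if kind == "mi":
                samples.append(mi_adjacency(ts, cfg))
            else:
                idx = encode_trialset(ts, cfg)
                dists = [op_distribution(ch, w=op_w) for ch in idx]
                samples.append(ChannelFeatureVector.from_op_distributions(dists, meta=label))
        elif kind in ("psd", "coherence"):
            band = None if param in (None, "full") else BandDefinition.named(str(param))
            spectra = trial_spectra(ts)
            if kind == "coherence":
                samples.append(coherence_matrix(spectra, band=band))
            else:
                psd = psd_average(spectra)
                if band is not None:
                    psd = band_restrict(psd, band)
                samples.append(ChannelFeatureVector.from_psd(psd, meta=label))
        else:
            raise ValueError(f"unknown feature kind {kind!r}")
        labels.append(label)
    return samples, labels


def params_for_kind(cfg: PipelineConfig, kind: str) -> tuple:
    return cfg.taus_ms if kind in ("op_dist", "mi") else cfg.bands


def run_cell(dataset: EEGDataset, kind: str, param, cfg: PipelineConfig,
             path_name: str) -> dict:
    """Features → distances → t-SNE ensemble → separation for one cell."""
    samples, labels = compute_feature_samples(dataset, kind, param, op_w=cfg.op_w)
    D = pairwise_distances(samples, labels=labels)
    tcfg = TSNEConfig(perplexity=cfg.perplexity, n_iter=cfg.tsne_iter, seed=cfg.seed)
    embeddings = tsne_ensemble(D, tcfg, n_runs=cfg.n_tsne_runs)
    sep = ensemble_jsd(embeddings, gridsize=cfg.gridsize,
                       meta={"kind": kind, "param": param, "path": path_name})
    rhos = [np.mean(list(cluster_ratio_rho(emb).values())) for emb in embeddings]
    return {
        "feature": kind,
        "param": str(param),
        "path": path_name,
        "jsd_mean": sep.mean,
        "jsd_sd": sep.sd,
        "jsd_div_mean": sep.divergence_mean,
        "rho_mean": float(np.mean(rhos)),
        "n_runs": cfg.n_tsne_runs,
    }


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> RunManifest:
    """Execute all requested cells and write results table + manifest.

    A failing cell is logged and skipped; the other cells still run.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(cfg.cohort)
    datasets = {}
    if "raw" in cfg.paths:
        datasets["raw"] = cohort
    if "preprocessed" in cfg.paths:
        datasets["preprocessed"] = cohort.map_trials(
            lambda ts: preprocess_trials(ts, cfg.preproc)
        )
    rows = []
    for path_name, ds in datasets.items():
        for kind in cfg.feature_kinds:
            for param in params_for_kind(cfg, kind):
                try:
                    rows.append(run_cell(ds, kind, param, cfg, path_name))
                    logger.info("cell done: %s %s %s", path_name, kind, param)
                except Exception:
                    logger.exception("cell failed: %s %s %s", path_name, kind, param)
    results = pd.DataFrame(rows)
    results_path = outdir / "results.tsv"
    write_results(results, results_path)
    manifest = RunManifest(
        config=_config_dict(cfg), seed=cfg.seed,
        files={"results.tsv": _sha256(results_path)},
    )
    with open(outdir / "manifest.json", "w") as f:
        json.dump(dataclasses.asdict(manifest), f, indent=2, default=str)
    manifest.validate(outdir)
    return manifest


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return json.loads(json.dumps(d, default=str))


# ------------------------------------------------------------------ tables


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a results table as TSV (header always present)."""
    cols = ["feature", "param", "path", "jsd_mean", "jsd_sd",
            "jsd_div_mean", "rho_mean", "n_runs"]
    if results.empty:
        results = pd.DataFrame(columns=cols)
    results.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as e:
        raise ValueError(f"malformed results table {path}: {e}") from e


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read a delimited label table (subject, group, condition, ...)."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as e:
        raise ValueError(f"malformed label table {path}: {e}") from e
    missing = {"subject", "group", "condition"} - set(df.columns)
    if missing:
        raise ValueError(f"label table {path} lacks columns: {sorted(missing)}")
    return df


def write_labels(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
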