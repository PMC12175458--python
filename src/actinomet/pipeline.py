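"""Stage orchestration: each stage reads its predecessor's CSV outputs.

The stage order mirrors the screening workflow: simulate (or supply) the
aligned feature tables → cleanup (blank/medium subtraction, mode merge) →
dereplication → multivariate modelling → bioactivity correlation → report
bundle. Every stage appends a provenance record (config echo, seed,
versions, feature counts) to ``provenance.log`` in the output directory,
and all outputs are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import ConfigurationError
from .tabio import (
    read_bioactivity,
    read_compound_library,
    read_feature_table,
    write_bioactivity,
    write_compound_library,
    write_feature_table,
)
from . import bioassoc, chemometrics, derep, preprocess, synthdata

__all__ = [
    "PipelineConfig",
    "stage_simulate",
    "stage_preprocess",
    "stage_dereplicate",
    "stage_model",
    "stage_correlate",
    "stage_report",
    "run_all",
]


@dataclass
class PipelineConfig:
    """Flat configuration for the whole pipeline.

    Paths are resolved against ``outdir`` for stage outputs; defaults equal
    the workflow's published parameters (blank 1e4, medium 20x, 5 ppm,
    12 mm, alpha 0.05, top-15).
    """

    outdir: str = "results/pipeline"
    pi_table: str | None = None
    ni_table: str | None = None
    library: str | None = None
    bioactivity: str | None = None
    blank_threshold: float = 1e4
    media_fold: float = 20.0
    tolerance_ppm: float = 5.0
    include_sodium: bool = False
    zone_cutoff: float = 12.0
    n_comp: int = 3
    n_orth: int = 1
    cv_folds: int = 7
    alpha: float = 0.05
    k_top: int = 15
    n_decoys: int = 20
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Read a flat ``key = value`` text file (# comments allowed)."""
        kwargs = {}
        fields = {f: t for f, t in cls.__annotations__.items()}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(f"bad config line: {line!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ConfigurationError(f"unknown config key {key!r}")
            default = getattr(cls, key, None)
            if isinstance(default, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(default, int) and not isinstance(default, bool):
                kwargs[key] = int(value)
            elif isinstance(default, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def resolve(self, name: str) -> Path:
        return Path(self.outdir) / name


def _log(cfg: PipelineConfig, stage: str, **info) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    record = {
        "stage": stage,
        "seed": cfg.seed,
        "versions": {
            "actinomet": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": asdict(cfg),
        **info,
    }
    with open(out / "provenance.log", "a") as fh:
        fh.write(json.dumps(record, default=str) + "\n")


def _input(cfg: PipelineConfig, explicit: str | None, default_name: str) -> Path:
    path = Path(explicit) if explicit else cfg.resolve(default_name)
    if not path.exists():
        raise ConfigurationError(f"missing input file: {path}")
    return path


def stage_simulate(cfg: PipelineConfig) -> dict[str, Path]:
    """Generate a synthetic experiment and write all its input tables."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sc = synthdata.SynthConfig(seed=cfg.seed)
    pi, ni, bio, truth = synthdata.generate_experiment(sc)
    lib = synthdata.generate_library(truth, n_decoys=cfg.n_decoys, seed=cfg.seed + 1)
    paths = {
        "pi": out / "features_pi.csv",
        "ni": out / "features_ni.csv",
        "bioactivity": out / "bioactivity.csv",
        "library": out / "library.csv",
        "ground_truth": out / "ground_truth.csv",
    }
    write_feature_table(pi, paths["pi"])
    write_feature_table(ni, paths["ni"])
    write_bioactivity(bio, paths["bioactivity"])
    write_compound_library(lib, paths["library"])
    synthdata.write_ground_truth(truth, paths["ground_truth"])
    _log(cfg, "simulate", n_features={"pi": pi.n_features, "ni": ni.n_features},
         n_samples=len(pi.samples), library_size=len(lib))
    return paths


def stage_preprocess(cfg: PipelineConfig) -> Path:
    """Blank + medium filters per mode, then merge modes into one table."""
    params = preprocess.FilterParams(
        blank_threshold=cfg.blank_threshold, media_fold=cfg.media_fold
    )
    counts = {}
    cleaned = {}
    for mode, name, explicit in (
        ("positive", "features_pi.csv", cfg.pi_table),
        ("negative", "features_ni.csv", cfg.ni_table),
    ):
        ft = read_feature_table(_input(cfg, explicit, name), mode)
        counts[mode] = {"input": ft.n_features}
        ft = preprocess.subtract_blanks(ft, params)
        counts[mode]["after_blank"] = ft.n_features
        ft = preprocess.filter_media(ft, params)
        counts[mode]["after_medium"] = ft.n_features
        cleaned[mode] = ft
    merged = preprocess.merge_modes(cleaned["positive"], cleaned["negative"])
    out = cfg.resolve("features_merged.csv")
    write_feature_table(merged, out)
    summary = pd.DataFrame(counts).T
    summary.index.name = "mode"
    summary.to_csv(cfg.resolve("filter_report.csv"))
    _log(cfg, "preprocess", counts=counts, merged=merged.n_features)
    return out


def stage_dereplicate(cfg: PipelineConfig) -> Path:
    ft = read_feature_table(_input(cfg, None, "features_merged.csv"), "merged")
    lib = read_compound_library(_input(cfg, cfg.library, "library.csv"))
    hits = derep.annotate(ft, lib, tolerance=cfg.tolerance_ppm,
                          include_sodium=cfg.include_sodium)
    frame = derep.hits_frame(hits, ft)
    out = cfg.resolve("dereplication.csv")
    frame.to_csv(out, index=False)
    n_annotated = frame[frame["compound"] != "no hits"]["feature_id"].nunique()
    _log(cfg, "dereplicate", n_hits=len(hits), n_annotated=int(n_annotated))
    return out


def stage_model(cfg: PipelineConfig) -> dict[str, Path]:
    """PCA + Hotelling, PLS-DA (+VIP), OPLS-DA (+S-plot), RF ranking."""
    ft = read_feature_table(_input(cfg, None, "features_merged.csv"), "merged")
    bio_and_qc = ft.biological_samples + ft.qc_samples
    labels = [ft.sample_roles[s] if s in ft.biological_samples else "QC"
              for s in bio_and_qc]
    Xs_all = chemometrics.pareto_scale(ft.to_matrix(bio_and_qc))
    pca = chemometrics.fit_pca(Xs_all, n_comp=min(2, Xs_all.n_samples - 1))
    ellipse = chemometrics.hotelling_ellipse(pca, alpha=cfg.alpha)

    bio = ft.biological_samples
    bio_labels = [ft.sample_roles[s] for s in bio]
    Xs = chemometrics.pareto_scale(ft.to_matrix(bio))
    plsda = chemometrics.fit_plsda(Xs, bio_labels, n_comp=cfg.n_comp,
                                   cv_folds=cfg.cv_folds)
    vip = chemometrics.vip_scores(plsda)
    oplsda, splot = chemometrics.fit_oplsda(Xs, bio_labels, n_orth=cfg.n_orth,
                                            cv_folds=cfg.cv_folds)
    rf = chemometrics.rank_features_rf(Xs, bio_labels, k=cfg.k_top, seed=cfg.seed)

    paths = {}
    scores = pca.scores_frame()
    scores["label"] = labels
    scores["hotelling_t2"] = ellipse.t2
    scores["outlier"] = ellipse.outliers
    paths["pca_scores"] = cfg.resolve("pca_scores.csv")
    scores.to_csv(paths["pca_scores"])
    paths["pca_loadings"] = cfg.resolve("pca_loadings.csv")
    pca.loadings_frame().to_csv(paths["pca_loadings"])
    paths["plsda_scores"] = cfg.resolve("plsda_scores.csv")
    plsda.scores_frame().to_csv(paths["plsda_scores"])
    paths["vip"] = cfg.resolve("vip.csv")
    vip.to_csv(paths["vip"])
    paths["oplsda_scores"] = cfg.resolve("oplsda_scores.csv")
    oplsda.scores_frame().to_csv(paths["oplsda_scores"])
    paths["splot"] = cfg.resolve("splot.csv")
    splot.to_frame().to_csv(paths["splot"])
    paths["rf"] = cfg.resolve("rf_top.csv")
    rf.to_csv(paths["rf"], index=False)

    report = cfg.resolve("fit_report.txt")
    with open(report, "w") as fh:
        fh.write("PCA: R2X per component: "
                 + ", ".join(f"{v:.3f}" for v in pca.r2x_per_comp) + "\n")
        fh.write(f"PCA Hotelling outliers ({int(100 * (1 - cfg.alpha))}%): "
                 + ", ".join(ellipse.outlier_samples(pca.sample_names)) + "\n")
        fh.write(
            f"PLS-DA ({plsda.n_components} comp): R2X {plsda.R2X_cum:.3f} "
            f"R2Y {plsda.R2Y_cum:.3f} Q2 {plsda.Q2_cum:.3f}\n"
        )
        fh.write(
            f"OPLS-DA (1+{cfg.n_orth}): R2X {oplsda.R2X_cum:.3f} "
            f"R2Y {oplsda.R2Y_cum:.3f} Q2 {oplsda.Q2_cum:.3f}\n"
        )
    paths["fit_report"] = report
    _log(cfg, "model", plsda_r2y=plsda.R2Y_cum, plsda_q2=plsda.Q2_cum,
         oplsda_r2y=oplsda.R2Y_cum, oplsda_q2=oplsda.Q2_cum,
         pca_r2x=list(map(float, pca.r2x_per_comp)))
    return paths


def stage_correlate(cfg: PipelineConfig) -> Path:
    ft = read_feature_table(_input(cfg, None, "features_merged.csv"), "merged")
    bt = read_bioactivity(_input(cfg, cfg.bioactivity, "bioactivity.csv"))
    result = bioassoc.pearson_matrix(ft, bt, alpha=cfg.alpha)
    out = cfg.resolve("correlation_r.csv")
    result.r.to_csv(out)
    result.p.to_csv(cfg.resolve("correlation_p.csv"))
    _log(cfg, "correlate", n_features=int(result.r.shape[0]),
         n_activities=int(result.r.shape[1]))
    return out


def stage_report(cfg: PipelineConfig) -> dict[str, object]:
    ft = read_feature_table(_input(cfg, None, "features_merged.csv"), "merged")
    bt = read_bioactivity(_input(cfg, cfg.bioactivity, "bioactivity.csv"))
    hits = pd.read_csv(_input(cfg, None, "dereplication.csv"))
    vip = pd.read_csv(_input(cfg, None, "vip.csv"), index_col=0)["VIP"]
    splot_frame = pd.read_csv(_input(cfg, None, "splot.csv"), index_col=0)
    splot = chemometrics.SPlot(
        feature_names=list(splot_frame.index),
        p=splot_frame["p"].to_numpy(),
        pcorr=splot_frame["pcorr"].to_numpy(),
    )
    rf = pd.read_csv(_input(cfg, None, "rf_top.csv"))
    correlations = bioassoc.pearson_matrix(ft, bt, alpha=cfg.alpha)
    written = bioassoc.heatmap_report(
        ft, hits, {"vip": vip, "splot": splot, "rf": rf}, correlations,
        cfg.resolve("report"),
    )
    _log(cfg, "report", files=sorted(str(p) for p in written.values()))
    return written


def run_all(cfg: PipelineConfig) -> dict[str, object]:
    """Chain every stage on a simulated experiment; returns the report files."""
    stage_simulate(cfg)
    stage_preprocess(cfg)
    stage_dereplicate(cfg)
    stage_model(cfg)
    stage_correlate(cfg)
    return stage_report(cfg)
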