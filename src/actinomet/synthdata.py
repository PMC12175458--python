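"""Seeded synthetic LC-MS experiments with known ground truth.

The study design this generator emulates is a crude-extract screening
campaign: eight actinomycete isolate groups measured in triplicate in both
ionization modes, together with solvent blanks, uninoculated ISP-2 medium
controls and pooled QC injections (equal-parts mix of all biological
samples). Because no raw data exist to re-analyse, every downstream stage
is validated against experiments with *planted* structure:

* **background features** — present in blanks above the 1e4 blank-removal
  threshold and at medium-like levels in all samples, so the cleanup rules
  must remove them;
* **marker clusters** — features at >= ``marker_fold`` times their medium
  level in designated member groups (cluster 1 and cluster 2 split the
  non-outlier isolates, mirroring the loading-plot clusters of the real
  campaign), a subset of which sit at the exact adduct m/z of known
  library compounds (within ±2 ppm) so dereplication must recover them;
* **an outlier group** — private markers at 10x typical intensity give one
  isolate the "rich, unique chemistry" topology that places it outside the
  95% Hotelling ellipse;
* **bioactivity vectors** — inhibition zones and IC50s whose group-level
  variation follows designated marker clusters, so correlation analysis can
  recover the planted links.

Intensity noise is multiplicative log-normal (sigma on the log10 scale);
missing values are encoded as 0. Identical config + seed reproduces the
tables bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import load_reference_compounds
from .exceptions import ConfigurationError
from .formulas import M_MINUS_H, M_PLUS_H, adduct_mz
from .tabio import (
    MZ_MAX,
    MZ_MIN,
    ROLE_BLANK,
    ROLE_MEDIUM,
    ROLE_QC,
    BioactivityTable,
    CompoundLibrary,
    CompoundRecord,
    FeatureTable,
)

__all__ = ["SynthConfig", "GroundTruth", "generate_experiment", "generate_library",
           "write_ground_truth"]

#: Isolate labels of the campaign the generator mirrors.
DEFAULT_GROUPS = ("6", "10", "12", "35", "42", "43", "45", "48")

# loading-plot cluster structure: cluster1/cluster2 partition the regular
# isolates; cluster3 is private to the outlier group.
_CLUSTER1_GROUPS = ("6", "35", "45")
_CLUSTER2_GROUPS = ("12", "42", "43", "48")


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters of a synthetic experiment.

    Defaults mirror the emulated campaign: 8 isolate groups x 3 replicates,
    two ionization modes of 250 aligned features each, planted markers at
    50x their medium level (comfortably above the 20x retention rule) and
    log-normal multiplicative noise of 0.1 decades.
    """

    n_groups: int = 8
    replicates: int = 3
    n_features_per_mode: int = 250
    n_markers_per_cluster: int = 7
    n_background: int = 60
    n_blanks: int = 2
    n_media: int = 3
    n_qc: int = 4
    outlier_group: str = "10"
    marker_fold: float = 50.0
    noise_sigma: float = 0.1
    qc_sigma: float = 0.02
    dropout_rate: float = 0.02
    mz_range: tuple[float, float] = (MZ_MIN, MZ_MAX)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_groups, self.replicates, self.n_features_per_mode,
            self.n_markers_per_cluster, self.n_background, self.n_blanks,
            self.n_media, self.n_qc,
        )
        if any(c < 0 for c in counts):
            raise ConfigurationError("all counts must be >= 0")
        if self.n_groups < 1 or self.replicates < 1:
            raise ConfigurationError("need >= 1 group with >= 1 replicate")
        if self.marker_fold < 20:
            raise ConfigurationError("marker_fold must be >= 20 (the retention rule)")
        lo, hi = self.mz_range
        if not (MZ_MIN <= lo < hi <= MZ_MAX):
            raise ConfigurationError(f"mz_range must lie within [{MZ_MIN}, {MZ_MAX}]")
        needed = self.n_background // 2 + 3 * self.n_markers_per_cluster
        if self.n_features_per_mode < needed + 1:
            raise ConfigurationError(
                f"n_features_per_mode too small; need > {needed}"
            )

    @property
    def group_labels(self) -> tuple[str, ...]:
        if self.n_groups == len(DEFAULT_GROUPS):
            return DEFAULT_GROUPS
        return tuple(f"G{i + 1}" for i in range(self.n_groups))


@dataclass
class GroundTruth:
    """What was planted where, for test harnesses and recovery scoring."""

    marker_features: dict[str, list[str]]      # cluster -> feature ids
    background_features: list[str]
    noise_features: list[str]
    cluster_groups: dict[str, list[str]]       # cluster -> member group labels
    planted_matches: dict[str, str]            # feature id -> compound name
    planted_adducts: dict[str, str]            # feature id -> adduct name
    feature_mz: dict[str, float]               # every feature id -> m/z
    bioactivity_effect: dict[str, list[tuple[str, int]]]  # cluster -> [(column, sign)]

    @property
    def all_markers(self) -> list[str]:
        return [f for ids in self.marker_features.values() for f in ids]

    @property
    def contrast_markers(self) -> list[str]:
        """Markers of clusters that carry a planted bioactivity effect."""
        return [
            f
            for cluster, ids in self.marker_features.items()
            if self.bioactivity_effect.get(cluster)
            for f in ids
        ]

    def active_groups(self) -> list[str]:
        """Groups of the cluster planted with a positive zone effect."""
        for cluster, effects in self.bioactivity_effect.items():
            if any(col.startswith("zone:") and sign > 0 for col, sign in effects):
                return list(self.cluster_groups[cluster])
        return []


def _log10_normal(rng, loc, sigma, size):
    return 10.0 ** rng.normal(loc, sigma, size)


def _sample_names(cfg: SynthConfig) -> tuple[list[str], dict[str, str]]:
    names, roles = [], {}
    for i in range(cfg.n_blanks):
        s = f"Blank_{i + 1}"
        names.append(s)
        roles[s] = ROLE_BLANK
    for i in range(cfg.n_media):
        s = f"Medium_{i + 1}"
        names.append(s)
        roles[s] = ROLE_MEDIUM
    for g in cfg.group_labels:
        for r in range(cfg.replicates):
            s = f"Iso{g}_r{r + 1}"
            names.append(s)
            roles[s] = g
    for i in range(cfg.n_qc):
        s = f"QC_{i + 1}"
        names.append(s)
        roles[s] = ROLE_QC
    return names, roles


def _cluster_groups(cfg: SynthConfig) -> dict[str, list[str]]:
    labels = [g for g in cfg.group_labels if g != cfg.outlier_group]
    if cfg.group_labels == DEFAULT_GROUPS and cfg.outlier_group == "10":
        return {
            "cluster1": list(_CLUSTER1_GROUPS),
            "cluster2": list(_CLUSTER2_GROUPS),
            "cluster3": [cfg.outlier_group],
        }
    half = max(1, len(labels) // 2)
    out = {"cluster1": labels[:half], "cluster2": labels[half:]}
    if cfg.outlier_group in cfg.group_labels:
        out["cluster3"] = [cfg.outlier_group]
    return out


def generate_experiment(
    config: SynthConfig = SynthConfig(),
) -> tuple[FeatureTable, FeatureTable, BioactivityTable, GroundTruth]:
    """Generate one synthetic experiment: (PI table, NI table, bioactivity, truth)."""
    rng = np.random.default_rng(config.seed)
    samples, roles = _sample_names(config)
    clusters = _cluster_groups(config)
    lib = load_reference_compounds()
    # unique formulas in library order; the first name of each formula is
    # the canonical planted annotation
    seen: dict[str, str] = {}
    for rec in lib:
        seen.setdefault(rec.formula, rec.name)
    planted_pool = [(name, formula) for formula, name in seen.items()]

    tables = {}
    truth = GroundTruth(
        marker_features={c: [] for c in clusters},
        background_features=[],
        noise_features=[],
        cluster_groups=clusters,
        planted_matches={},
        planted_adducts={},
        feature_mz={},
        bioactivity_effect={
            "cluster1": [("ic50:HSF", -1)],
            "cluster2": [("zone:Enterococcus sp.", +1), ("ic50:MCF-7", -1)],
        },
    )
    # drop effects for clusters that do not exist (tiny configs)
    truth.bioactivity_effect = {
        c: eff for c, eff in truth.bioactivity_effect.items() if c in clusters
    }
    pool_iter = iter(planted_pool)

    bio_samples = [s for s in samples if roles[s] not in (ROLE_BLANK, ROLE_MEDIUM, ROLE_QC)]
    blank_samples = [s for s in samples if roles[s] == ROLE_BLANK]
    medium_samples = [s for s in samples if roles[s] == ROLE_MEDIUM]
    qc_samples = [s for s in samples if roles[s] == ROLE_QC]

    for mode, prefix, adduct in (
        ("positive", "P_", M_PLUS_H),
        ("negative", "N_", M_MINUS_H),
    ):
        n_feat = config.n_features_per_mode
        n_bg = config.n_background // 2 + (config.n_background % 2 if mode == "positive" else 0)
        inten = np.zeros((n_feat, len(samples)))
        mz = np.empty(n_feat)
        ids = [f"{prefix}{i + 1}" for i in range(n_feat)]
        col = {s: j for j, s in enumerate(samples)}
        lo, hi = config.mz_range
        row = 0

        # --- background features: loud in blanks and medium everywhere
        for _ in range(n_bg):
            inten[row, [col[s] for s in blank_samples]] = _log10_normal(
                rng, 5.0, config.noise_sigma, len(blank_samples))
            inten[row, [col[s] for s in medium_samples]] = _log10_normal(
                rng, 5.0, config.noise_sigma, len(medium_samples))
            inten[row, [col[s] for s in bio_samples]] = _log10_normal(
                rng, 5.0, config.noise_sigma, len(bio_samples))
            mz[row] = rng.uniform(lo, hi)
            truth.background_features.append(ids[row])
            row += 1

        # --- marker clusters
        # per-mode marker count: ~70% of each cluster in positive mode
        n_pos = int(np.ceil(0.7 * config.n_markers_per_cluster))
        n_here = n_pos if mode == "positive" else config.n_markers_per_cluster - n_pos
        for cluster, members in clusters.items():
            is_outlier = members == [config.outlier_group]
            level = 6.0 if is_outlier else 5.0   # outlier privates at 10x
            medium_level = np.log10(10.0**level / (2.0 * config.marker_fold))
            for _ in range(n_here):
                member_cols = [col[s] for s in bio_samples if roles[s] in members]
                other_cols = [col[s] for s in bio_samples if roles[s] not in members]
                inten[row, member_cols] = _log10_normal(
                    rng, level, config.noise_sigma, len(member_cols))
                inten[row, other_cols] = _log10_normal(
                    rng, 3.0, config.noise_sigma, len(other_cols))
                inten[row, [col[s] for s in medium_samples]] = _log10_normal(
                    rng, medium_level, config.noise_sigma, len(medium_samples))
                inten[row, [col[s] for s in blank_samples]] = _log10_normal(
                    rng, 2.0, config.noise_sigma, len(blank_samples))
                planted = next(pool_iter, None)
                if planted is not None:
                    name, formula = planted
                    theo = adduct_mz(
                        CompoundRecord(name=name, formula=formula).neutral_mass,
                        adduct,
                    )
                    if lo <= theo <= hi:
                        mz[row] = theo * (1.0 + rng.uniform(-2.0, 2.0) * 1e-6)
                        truth.planted_matches[ids[row]] = name
                        truth.planted_adducts[ids[row]] = adduct.name
                    else:
                        mz[row] = rng.uniform(lo, hi)
                else:
                    mz[row] = rng.uniform(lo, hi)
                truth.marker_features[cluster].append(ids[row])
                row += 1

        # --- unstructured (noise) features: consistent level, no class signal
        while row < n_feat:
            level = rng.uniform(3.5, 4.5)
            vals = _log10_normal(rng, level, config.noise_sigma, len(bio_samples))
            if config.dropout_rate > 0:
                vals[rng.random(len(vals)) < config.dropout_rate] = 0.0
            inten[row, [col[s] for s in bio_samples]] = vals
            inten[row, [col[s] for s in medium_samples]] = _log10_normal(
                rng, level - 1.9, config.noise_sigma, len(medium_samples))
            inten[row, [col[s] for s in blank_samples]] = _log10_normal(
                rng, 2.0, config.noise_sigma, len(blank_samples))
            mz[row] = rng.uniform(lo, hi)
            truth.noise_features.append(ids[row])
            row += 1

        # --- QC columns: equal-parts pool of all biological samples
        bio_cols = [col[s] for s in bio_samples]
        pooled = inten[:, bio_cols].mean(axis=1)
        for s in qc_samples:
            inten[:, col[s]] = pooled * _log10_normal(
                rng, 0.0, config.qc_sigma, n_feat)

        frame = pd.DataFrame(inten, index=pd.Index(ids, name="feature_id"),
                             columns=samples)
        tables[mode] = FeatureTable(
            intensities=frame,
            mz=pd.Series(mz, index=frame.index),
            rt=pd.Series(np.round(rng.uniform(0.5, 14.5, n_feat), 3),
                         index=frame.index),
            sample_roles=dict(roles),
            mode=mode,
        )
        truth.feature_mz.update(dict(zip(ids, mz)))

    bioactivity = _generate_bioactivity(rng, config, truth)
    return tables["positive"], tables["negative"], bioactivity, truth


def _generate_bioactivity(rng, cfg: SynthConfig, truth: GroundTruth) -> BioactivityTable:
    groups = list(cfg.group_labels)
    organisms = ["Enterococcus sp.", "Pseudomonas sp.", "Klebsiella sp."]
    cell_lines = ["MCF-7", "HSF"]
    zones = pd.DataFrame(
        rng.normal(8.0, 1.5, size=(len(groups), len(organisms))).clip(min=0.0),
        index=pd.Index(groups, name="group"), columns=organisms,
    )
    ic50 = pd.DataFrame(
        _log10_normal(rng, 1.9, 0.05, (len(groups), len(cell_lines))),
        index=zones.index, columns=cell_lines,
    )
    for cluster, effects in truth.bioactivity_effect.items():
        members = truth.cluster_groups.get(cluster, [])
        for column, sign in effects:
            kind, name = column.split(":", 1)
            for g in members:
                if kind == "zone" and sign > 0:
                    zones.loc[g, name] = rng.normal(16.0, 1.0)
                elif kind == "ic50" and sign < 0:
                    ic50.loc[g, name] = _log10_normal(rng, 1.4, 0.05, 1)[0]
    return BioactivityTable(zones=zones.clip(lower=0.0), ic50=ic50)


def generate_library(
    truth: GroundTruth, n_decoys: int = 20, seed: int = 0
) -> CompoundLibrary:
    """A dereplication library of the planted compounds plus mass decoys.

    Every planted (feature, compound) match has its formula in the library;
    decoy formulas are rejection-sampled until all of their adduct m/z
    values lie more than 20 ppm from every feature m/z in the experiment,
    so a 5 ppm search recovers exactly the planted annotations.
    """
    if n_decoys < 0:
        raise ConfigurationError("n_decoys must be >= 0")
    rng = np.random.default_rng(seed)
    reference = load_reference_compounds()
    planted_names = set(truth.planted_matches.values())
    records = [rec for rec in reference if rec.name in planted_names]
    all_mz = np.array(sorted(truth.feature_mz.values())) if truth.feature_mz else np.array([])

    def _far_enough(mz_val: float) -> bool:
        if not all_mz.size:
            return True
        return np.min(np.abs(all_mz - mz_val)) / mz_val * 1e6 > 20.0

    made = 0
    attempts = 0
    while made < n_decoys:
        attempts += 1
        if attempts > 10000 * max(1, n_decoys):
            raise ConfigurationError("could not place decoys away from all features")
        c = int(rng.integers(6, 41))
        h = int(rng.integers(max(4, c // 2), 2 * c + 3))
        n = int(rng.integers(0, 6))
        o = int(rng.integers(0, 9))
        formula = f"C{c}H{h}" + (f"N{n}" if n else "") + (f"O{o}" if o else "")
        rec = CompoundRecord(name=f"Decoy_{made + 1:03d}", formula=formula,
                             source="synthetic decoy", activity_note="none")
        mzs = [adduct_mz(rec.neutral_mass, M_PLUS_H),
               adduct_mz(rec.neutral_mass, M_MINUS_H)]
        if not (MZ_MIN <= mzs[1] and mzs[0] <= MZ_MAX):
            continue
        if all(_far_enough(m) for m in mzs):
            records.append(rec)
            made += 1
    return CompoundLibrary(records)


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Serialize the per-feature ground truth as CSV (+ effects as JSON header).

    One row per feature: category (marker/background/noise), cluster,
    planted compound and adduct, m/z. The bioactivity-effect map and the
    cluster membership are stored as JSON in commented header lines.
    """
    rows = []
    cluster_of = {
        f: c for c, ids in truth.marker_features.items() for f in ids
    }
    for fid, mz_val in truth.feature_mz.items():
        if fid in cluster_of:
            cat = "marker"
        elif fid in truth.background_features:
            cat = "background"
        else:
            cat = "noise"
        rows.append(
            {
                "feature_id": fid,
                "category": cat,
                "cluster": cluster_of.get(fid, ""),
                "planted_compound": truth.planted_matches.get(fid, ""),
                "planted_adduct": truth.planted_adducts.get(fid, ""),
                "mz": mz_val,
            }
        )
    header = {
        "cluster_groups": truth.cluster_groups,
        "bioactivity_effect": {
            c: [[col, sign] for col, sign in eff]
            for c, eff in truth.bioactivity_effect.items()
        },
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        pd.DataFrame(rows).to_csv(fh, index=False)
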