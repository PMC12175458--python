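"""Bioactivity handling and metabolite–bioactivity association.

Antimicrobial readouts are agar-diffusion inhibition zones; a zone of 12 mm
or larger counts as positive activity (inclusive threshold). Cytotoxicity is
summarised as the IC50 of a four-parameter logistic (4PL) dose–response
curve over the tested concentration series (128, 32, 8, 2, 0.5 µg/mL);
when viability never drops through 50% inside the tested range the IC50 is
"not reached" and reported as NA. Candidate marker metabolites are linked
to these readouts by a per-group Pearson correlation matrix over features
that survive a significance prefilter (one-way ANOVA across isolate groups
by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import ConfigurationError, DataError
from .tabio import BioactivityTable, FeatureTable

__all__ = [
    "DEFAULT_ZONE_CUTOFF",
    "DEFAULT_CONCENTRATIONS",
    "DoseResponse",
    "CorrelationResult",
    "classify_zones",
    "activity_counts",
    "fit_ic50",
    "compare_ic50",
    "anova_prefilter",
    "pearson_matrix",
    "heatmap_report",
]

DEFAULT_ZONE_CUTOFF = 12.0  # mm, inclusive
DEFAULT_CONCENTRATIONS = (128.0, 32.0, 8.0, 2.0, 0.5)  # µg/mL


def classify_zones(bt: BioactivityTable, cutoff: float = DEFAULT_ZONE_CUTOFF) -> pd.DataFrame:
    """One activity call per (group, organism); zones >= cutoff are active.

    Missing zones (NA) mean "no inhibition observed" and are inactive.
    """
    if (bt.zones.to_numpy(dtype=float) < 0).any():
        raise DataError("negative inhibition zone")
    rows = []
    for group in bt.zones.index:
        for organism in bt.zones.columns:
            zone = bt.zones.loc[group, organism]
            rows.append(
                {
                    "group": group,
                    "organism": organism,
                    "zone_mm": zone,
                    "active": bool(pd.notna(zone) and zone >= cutoff),
                }
            )
    return pd.DataFrame(rows)


def activity_counts(calls: pd.DataFrame) -> pd.Series:
    """Number of active groups per organism."""
    if calls.empty:
        raise ConfigurationError("no activity calls")
    counts = calls.groupby("organism", sort=False)["active"].sum().astype(int)
    counts.name = "n_active"
    return counts


# ---------------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------------


@dataclass
class DoseResponse:
    """A viability series over a concentration ladder (fractions of control)."""

    concentrations: np.ndarray = field(
        default_factory=lambda: np.asarray(DEFAULT_CONCENTRATIONS)
    )
    viability: np.ndarray = field(default_factory=lambda: np.array([]))
    ic50: float | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if (self.concentrations <= 0).any():
            raise DataError("concentrations must be strictly positive")
        if self.viability.size and (
            (self.viability < 0).any() or (self.viability > 1.2).any()
        ):
            raise DataError("viability must lie in [0, 1.2]")


def _four_pl(c, bottom, top, e, h):
    return bottom + (top - bottom) / (1.0 + (c / e) ** h)


def fit_ic50(dr: DoseResponse) -> float:
    """IC50 from a 4PL fit: the concentration where fitted viability is 0.5.

    Returns NaN ("not reached") when the fitted curve does not cross 50%
    viability inside the tested concentration range. A clearly non-monotone
    series triggers a warning but the fit is still attempted.
    """
    c = dr.concentrations
    v = dr.viability
    if len(c) < 4 or len(c) != len(v):
        raise ConfigurationError("need >= 4 matched concentration/viability points")
    order = np.argsort(c)
    c, v = c[order], v[order]
    # viability should fall as concentration rises
    if np.sum(np.diff(v) > 0.1) >= 2:
        warnings.warn("dose-response series is non-monotonic", stacklevel=2)
    if v.min() >= 0.5:
        return float("nan")
    p0 = (max(v.min(), 0.0), min(v.max(), 1.2), float(np.sqrt(c[0] * c[-1])), 1.0)
    bounds = ([0.0, 0.3, c[0] / 10.0, 0.1], [0.49, 1.2, c[-1] * 10.0, 10.0])
    try:
        params, _ = optimize.curve_fit(
            _four_pl, c, v, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError:
        return float("nan")
    bottom, top, e, h = params
    if not (bottom < 0.5 < top):
        return float("nan")
    c50 = e * ((top - 0.5) / (0.5 - bottom)) ** (1.0 / h)
    if not (c[0] <= c50 <= c[-1]):
        return float("nan")
    return float(c50)


def compare_ic50(a, b) -> tuple[float, float]:
    """Two-sided unpaired Student t-test between two sets of replicate IC50s."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ConfigurationError("need >= 2 replicates per side")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise DataError("both samples have zero variance; t-test undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# metabolite-bioactivity correlation
# ---------------------------------------------------------------------------


def anova_prefilter(ft: FeatureTable, alpha: float = 0.05) -> list[str]:
    """Features differing across isolate groups (one-way ANOVA, p < alpha)."""
    groups = ft.groups
    if len(groups) < 2:
        raise ConfigurationError("ANOVA prefilter requires >= 2 groups")
    by_group = {
        g: [s for s in ft.biological_samples if ft.sample_roles[s] == g]
        for g in groups
    }
    selected = []
    mat = ft.intensities
    for fid in ft.feature_ids:
        arrays = [mat.loc[fid, cols].to_numpy(dtype=float) for cols in by_group.values()]
        if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = stats.f_oneway(*arrays)
        if np.isfinite(p) and p < alpha:
            selected.append(fid)
    return selected


@dataclass
class CorrelationResult:
    """Feature × activity Pearson matrix with two-sided p-values."""

    r: pd.DataFrame
    p: pd.DataFrame
    alpha: float

    @property
    def mask(self) -> pd.DataFrame:
        return self.p < self.alpha


def pearson_matrix(
    features: FeatureTable,
    activities: BioactivityTable,
    alpha: float = 0.05,
    prefilter="anova",
) -> CorrelationResult:
    """Pearson r between group-mean feature intensities and activity readouts.

    ``prefilter`` selects the "significantly different" features: ``"anova"``
    (default, per-feature one-way ANOVA at p < 0.05), an explicit list of
    feature ids, a callable ``ft -> ids``, or ``None`` for all features.
    Pairs with fewer than 3 aligned groups (after dropping NA activity
    readouts) yield NaN.
    """
    if prefilter == "anova":
        ids = anova_prefilter(features, alpha=alpha)
    elif prefilter is None:
        ids = features.feature_ids
    elif callable(prefilter):
        ids = list(prefilter(features))
    else:
        ids = list(prefilter)
    means = features.group_means()[ids] if ids else features.group_means().iloc[:, :0]
    acts = activities.activity_columns()
    common = means.index.intersection(acts.index)
    if len(common) < 3:
        raise ConfigurationError(
            f"need >= 3 isolate groups shared between features and activities, got {len(common)}"
        )
    means = means.loc[common]
    acts = acts.loc[common]
    r = pd.DataFrame(index=ids, columns=acts.columns, dtype=float)
    p = pd.DataFrame(index=ids, columns=acts.columns, dtype=float)
    for col in acts.columns:
        y = acts[col]
        ok = y.notna()
        if ok.sum() < 3:
            continue
        yv = y[ok].to_numpy(dtype=float)
        for fid in ids:
            xv = means.loc[ok, fid].to_numpy(dtype=float)
            if np.ptp(xv) == 0 or np.ptp(yv) == 0:
                continue
            rr, pp = stats.pearsonr(xv, yv)
            r.loc[fid, col] = rr
            p.loc[fid, col] = pp
    return CorrelationResult(r=r, p=p, alpha=alpha)


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------


def _heatmap(frame: pd.DataFrame, path, title: str, vmin=None, vmax=None) -> None:
    fig, ax = plt.subplots(
        figsize=(max(4, 0.45 * frame.shape[1] + 2), max(3, 0.3 * frame.shape[0] + 1.5))
    )
    im = ax.imshow(frame.to_numpy(dtype=float), aspect="auto", cmap="RdBu_r",
                   vmin=vmin, vmax=vmax)
    ax.set_xticks(range(frame.shape[1]), [str(c) for c in frame.columns],
                  rotation=90, fontsize=7)
    ax.set_yticks(range(frame.shape[0]), [str(i) for i in frame.index], fontsize=7)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def heatmap_report(
    features: FeatureTable,
    hits: pd.DataFrame | None,
    models: dict | None,
    correlations: CorrelationResult | None,
    outdir,
) -> dict[str, object]:
    """Write the prioritization bundle: heat maps plus one merged CSV.

    ``models`` may carry ``"vip"`` (Series), ``"splot"`` (SPlot) and
    ``"rf"`` (the random-forest ranking frame); all are optional. The merged
    CSV joins, per selected feature: m/z, best annotation (compound + ppm),
    VIP, S-plot coordinates, RF rank and the activity correlations.
    Correlation heat maps use the red-positive / blue-negative convention.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    models = models or {}
    selected = list(correlations.r.index) if correlations is not None else []
    written: dict[str, object] = {}

    if not selected:
        warnings.warn("empty feature selection; writing empty report", stacklevel=2)
        empty = pd.DataFrame(columns=["feature_id"])
        empty.to_csv(outdir / "prioritization.csv", index=False)
        written["prioritization"] = outdir / "prioritization.csv"
        return written

    # per-group mean intensities, row standardized
    means = features.group_means()[selected].T  # features x groups
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=1).replace(0, 1.0)
    z = means.sub(mu, axis=0).div(sd, axis=0)
    _heatmap(z, outdir / "intensity_heatmap.png",
             "Row-standardized mean intensity per isolate group")
    written["intensity_heatmap"] = outdir / "intensity_heatmap.png"

    if correlations is not None:
        _heatmap(correlations.r, outdir / "correlation_heatmap.png",
                 "Pearson r (red +, blue -)", vmin=-1, vmax=1)
        written["correlation_heatmap"] = outdir / "correlation_heatmap.png"

    merged = pd.DataFrame(index=pd.Index(selected, name="feature_id"))
    merged["mz"] = features.mz.reindex(selected)
    if hits is not None and len(hits):
        best = (
            hits[hits["compound"] != "no hits"]
            .assign(abs_ppm=lambda d: d["ppm"].abs())
            .sort_values(["feature_id", "abs_ppm"])
            .groupby("feature_id")
            .first()
        )
        merged["compound"] = best["compound"].reindex(selected).fillna("no hits")
        merged["annotation_ppm"] = best["ppm"].reindex(selected)
    if "vip" in models:
        merged["VIP"] = models["vip"].reindex(selected)
    if "splot" in models:
        sp = models["splot"].to_frame()
        merged["splot_p"] = sp["p"].reindex(selected)
        merged["splot_pcorr"] = sp["pcorr"].reindex(selected)
    if "rf" in models:
        rf = models["rf"].set_index("feature_id")
        merged["rf_rank"] = rf["rank"].reindex(selected)
    if correlations is not None:
        merged = merged.join(correlations.r.add_prefix("r:"))
    merged.to_csv(outdir / "prioritization.csv")
    written["prioritization"] = outdir / "prioritization.csv"
    return written
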