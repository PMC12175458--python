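"""Feature-table cleanup: blank subtraction, medium subtraction, mode merging.

Crude-extract LC-MS profiles are dominated by ions that have nothing to do
with the producing organism: solvent/background ions that also show up in
blank injections, and metabolites of the ISP-2 growth medium itself. Two
per-feature rules remove them:

* **blank rule** — a feature is discarded when its intensity in any solvent
  blank exceeds 1e4 (strictly greater; a blank intensity of exactly 1e4 is
  kept);
* **medium rule** — a feature is kept only when its best biological signal
  is at least 20x its best medium signal (features absent from the medium
  are always kept).

Replicate blanks/media/samples are aggregated by **maximum**, the
conservative choice. Both rules are pure per-feature predicates, so they
are idempotent and commute with each other.

The module also trims and bins 1H NMR spectra (solvent-region exclusion,
fixed-width integration bins) so the same chemometric models can run on
NMR fingerprints.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, FormatError
from .tabio import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "FilterParams",
    "subtract_blanks",
    "filter_media",
    "merge_modes",
    "NMRSpectrum",
    "nmr_trim_bin",
]


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the two cleanup rules.

    blank_threshold:
        Intensity above which a blank signal disqualifies a feature
        (default 1e4).
    media_fold:
        Required sample/medium intensity ratio (default 20).
    """

    blank_threshold: float = 1e4
    media_fold: float = 20.0

    def __post_init__(self) -> None:
        if self.blank_threshold < 0:
            raise ConfigurationError("blank_threshold must be >= 0")
        if self.media_fold <= 1:
            raise ConfigurationError("media_fold must be > 1")


def subtract_blanks(ft: FeatureTable, params: FilterParams = FilterParams()) -> FeatureTable:
    """Remove every feature whose maximum blank intensity exceeds the threshold.

    The rule is strict ("higher than"): a feature whose blank maximum equals
    the threshold exactly is retained.
    """
    blanks = ft.blank_samples
    if not blanks:
        raise ConfigurationError("blank subtraction requires >= 1 blank sample")
    blank_max = ft.intensities[blanks].max(axis=1)
    keep = blank_max <= params.blank_threshold
    removed = int((~keep).sum())
    logger.info(
        "blank filter: removed %d of %d features (threshold %g)",
        removed, ft.n_features, params.blank_threshold,
    )
    return ft.subset(ft.intensities.index[keep])


def filter_media(ft: FeatureTable, params: FilterParams = FilterParams()) -> FeatureTable:
    """Keep features whose best biological signal is >= media_fold x the medium.

    A feature entirely absent from the medium (medium maximum of zero) is
    retained regardless of its sample intensity.
    """
    media = ft.medium_samples
    if not media:
        raise ConfigurationError("medium subtraction requires >= 1 medium sample")
    bio = ft.biological_samples
    if not bio:
        raise ConfigurationError("medium subtraction requires biological samples")
    medium_max = ft.intensities[media].max(axis=1)
    sample_max = ft.intensities[bio].max(axis=1)
    keep = (medium_max == 0) | (sample_max >= params.media_fold * medium_max)
    removed = int((~keep).sum())
    logger.info(
        "medium filter: removed %d of %d features (fold %g)",
        removed, ft.n_features, params.media_fold,
    )
    return ft.subset(ft.intensities.index[keep])


_MODE_PREFIX = {"positive": "P_", "negative": "N_"}


def _prefixed(ft: FeatureTable) -> FeatureTable:
    prefix = _MODE_PREFIX.get(ft.mode)
    if prefix is None:
        raise ConfigurationError(f"cannot merge a table with mode {ft.mode!r}")
    if all(str(i).startswith(prefix) for i in ft.intensities.index):
        return ft
    renamed = ft.subset(ft.feature_ids)
    new_ids = pd.Index(
        [i if str(i).startswith(prefix) else prefix + str(i) for i in renamed.intensities.index]
    )
    renamed.intensities.index = new_ids
    renamed.mz.index = new_ids
    renamed.rt.index = new_ids
    return renamed


def merge_modes(pi: FeatureTable, ni: FeatureTable) -> FeatureTable:
    """Row-concatenate the positive- and negative-mode tables.

    Feature ids are prefixed ``P_``/``N_`` so both modes coexist in one
    matrix; sample columns are aligned by name and must agree between modes.
    """
    pi_bio, ni_bio = set(pi.biological_samples), set(ni.biological_samples)
    if pi_bio != ni_bio:
        raise FormatError(
            f"biological sample sets differ between modes: {sorted(pi_bio ^ ni_bio)}"
        )
    if set(pi.samples) != set(ni.samples):
        raise FormatError(
            f"sample sets differ between modes: {sorted(set(pi.samples) ^ set(ni.samples))}"
        )
    p, n = _prefixed(pi), _prefixed(ni)
    order = p.samples
    overlap = p.intensities.index.intersection(n.intensities.index)
    if len(overlap):
        raise FormatError(f"feature ids collide across modes: {list(overlap[:5])}")
    roles = dict(p.sample_roles)
    if roles != n.sample_roles:
        raise FormatError("sample roles disagree between modes")
    return FeatureTable(
        intensities=pd.concat([p.intensities[order], n.intensities[order]]),
        mz=pd.concat([p.mz, n.mz]),
        rt=pd.concat([p.rt, n.rt]),
        sample_roles=roles,
        mode="merged",
    )


# ---------------------------------------------------------------------------
# 1H NMR trimming + binning
# ---------------------------------------------------------------------------

#: Default solvent exclusion windows (ppm) for extracts run in DMSO-d6:
#: residual water and the DMSO quintet.
DEFAULT_EXCLUSIONS = ((3.28, 3.40), (2.47, 2.53))


@dataclass
class NMRSpectrum:
    """A processed 1H spectrum: chemical-shift axis, amplitudes, exclusions."""

    chemical_shift: np.ndarray
    amplitude: np.ndarray
    exclusion_regions: tuple = DEFAULT_EXCLUSIONS
    bin_width: float = 0.04

    def __post_init__(self) -> None:
        self.chemical_shift = np.asarray(self.chemical_shift, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.chemical_shift.shape != self.amplitude.shape:
            raise FormatError("shift axis and amplitude must have the same length")
        d = np.diff(self.chemical_shift)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise FormatError("chemical-shift axis must be strictly monotone")
        if self.bin_width <= 0:
            raise ConfigurationError("bin_width must be > 0")


def nmr_trim_bin(sp: NMRSpectrum) -> pd.Series:
    """Zero solvent regions, then integrate the axis into fixed-width bins.

    Returns a Series of bin integrals (sums of amplitudes) indexed by bin
    centre, of length ``ceil(span / bin_width)``.
    """
    shift = sp.chemical_shift
    amp = sp.amplitude.copy()
    if shift[0] > shift[-1]:  # spectra are often stored high-field last
        shift, amp = shift[::-1], amp[::-1]
    lo, hi = shift[0], shift[-1]
    for a, b in sp.exclusion_regions:
        a, b = min(a, b), max(a, b)
        if a < lo - 1e-9 or b > hi + 1e-9:
            raise ConfigurationError(
                f"exclusion region ({a}, {b}) outside axis range [{lo}, {hi}]"
            )
        amp[(shift >= a) & (shift <= b)] = 0.0
    span = hi - lo
    n_bins = max(1, math.ceil(span / sp.bin_width - 1e-9))
    # small epsilon guards against floating-point jitter at bin boundaries
    idx = np.minimum(
        np.floor((shift - lo) / sp.bin_width + 1e-9), n_bins - 1
    ).astype(int)
    values = np.zeros(n_bins)
    np.add.at(values, idx, amp)
    centres = lo + (np.arange(n_bins) + 0.5) * sp.bin_width
    return pd.Series(values, index=np.round(centres, 6), name="intensity")
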