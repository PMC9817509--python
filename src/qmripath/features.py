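"""First-order histogram features of VOI-restricted parameter samples.

Twelve statistics per parameter and lesion: median, interquartile range,
the 10th/25th/75th/90th percentiles, skewness, kurtosis (Pearson
convention, normal = 3), mean, standard deviation, and the histogram
energy (sum of squared bin probabilities) and entropy (base-2 Shannon
entropy of the bin probabilities).  Moment and percentile statistics are
computed from the raw voxel values; only energy and entropy use the
fixed-width histogram, whose bin size is parameter-specific and shared
across lesions with bins anchored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Fixed histogram bin widths per parameter (Ktrans and kep in min^-1,
#: D in mm^2/s, ve and K unitless).
DEFAULT_BIN_SIZES = {
    "ktrans": 0.2,
    "kep": 0.5,
    "ve": 0.025,
    "d": 0.1e-3,
    "k": 0.1,
}

FEATURE_NAMES = (
    "median", "iqr", "p10", "p25", "p75", "p90",
    "skewness", "kurtosis", "mean", "std", "energy", "entropy",
)


@dataclass(frozen=True)
class BinSpec:
    """Histogram layout: per-parameter fixed bin width, bins anchored at
    the ``origin`` (0 by default, shared across patients)."""

    bin_sizes: dict = None
    origin: float = 0.0

    def __post_init__(self) -> None:
        sizes = dict(DEFAULT_BIN_SIZES if self.bin_sizes is None else self.bin_sizes)
        if any(w <= 0 for w in sizes.values()):
            raise ValueError("bin sizes must be positive")
        object.__setattr__(self, "bin_sizes", sizes)


@dataclass
class HistogramFeatures:
    median: float
    iqr: float
    p10: float
    p25: float
    p75: float
    p90: float
    skewness: float
    kurtosis: float
    mean: float
    std: float
    energy: float
    entropy: float
    n_values: int

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _bin_probabilities(values, bin_size, origin):
    lo = origin + np.floor((values.min() - origin) / bin_size) * bin_size
    n_bins = max(1, int(np.ceil((values.max() - lo) / bin_size)))
    if values.max() >= lo + n_bins * bin_size:  # max exactly on the top edge
        n_bins += 1
    edges = lo + bin_size * np.arange(n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    return counts / values.size


def compute_features(values, bin_size: float, origin: float = 0.0,
                     kurtosis_excess: bool = False) -> HistogramFeatures:
    """First-order feature vector of one parameter sample.

    ``values`` must contain at least two finite numbers.  A zero-variance
    sample gets NaN skewness/kurtosis sentinels (they are undefined), but
    keeps energy 1 and entropy 0.  ``kurtosis_excess`` switches kurtosis
    to the excess (normal = 0) convention.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least 2 finite values")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")

    p10, p25, p50, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    if v.max() > v.min():
        std = float(np.std(v, ddof=1))
        skew = float(sps.skew(v, bias=True))
        kurt = float(sps.kurtosis(v, fisher=kurtosis_excess, bias=True))
    else:  # point mass: dispersion is zero, shape moments undefined
        std = 0.0
        skew = kurt = np.nan

    p = _bin_probabilities(v, bin_size, origin)
    occupied = p[p > 0]
    energy = float(np.sum(occupied**2))
    entropy = max(float(-np.sum(occupied * np.log2(occupied))), 0.0)

    return HistogramFeatures(
        median=float(p50), iqr=float(p75 - p25), p10=float(p10), p25=float(p25),
        p75=float(p75), p90=float(p90), skewness=skew, kurtosis=kurt,
        mean=float(v.mean()), std=std, energy=energy, entropy=entropy,
        n_values=int(v.size),
    )


def feature_table(lesion_values: dict, spec: BinSpec | None = None) -> pd.DataFrame:
    """Per-lesion feature matrix.

    ``lesion_values`` maps lesion id -> {parameter -> 1D value sample or
    None}.  Each available parameter contributes its 12 features as
    ``<param>_<feature>`` columns plus an ``<param>_n`` count; parameters
    whose map is unavailable for a lesion (e.g. a failed DKI acquisition)
    leave their cells missing.
    """
    spec = spec or BinSpec()
    rows = {}
    for lesion_id, per_param in lesion_values.items():
        row = {}
        for param, vals in per_param.items():
            if param not in spec.bin_sizes:
                raise KeyError(f"no bin size configured for parameter {param!r}")
            if vals is None:
                continue
            feats = compute_features(vals, spec.bin_sizes[param], spec.origin)
            for name in FEATURE_NAMES:
                row[f"{param}_{name}"] = getattr(feats, name)
            row[f"{param}_n"] = feats.n_values
        rows[lesion_id] = row
    columns = []
    for param in spec.bin_sizes:
        columns += [f"{param}_{name}" for name in FEATURE_NAMES] + [f"{param}_n"]
    df = pd.DataFrame.from_dict(rows, orient="index")
    return df.reindex(columns=columns)
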