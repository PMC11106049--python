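"""Cross-condition LC/MS metabolite-profile bookkeeping.

Implements the feature-table processing used when comparing extracts from
one strain grown under several cultivation conditions (OSMAC designs):

* noise filtering — peaks below 1% relative area are discarded;
* polarity-zone summaries — peak counts and total areas per retention-time
  zone on a reversed-phase gradient (defaults: high polarity 9-21 min,
  middle 21-39 min, low > 39 min, plus a pre-gradient bucket);
* the samples x features matrix of relative areas, log10-transformed for
  heat-map display with a floor for absent features;
* PCA with explained-variance fractions and k-means condition clustering.

Peak tables travel as delimited text with columns
``sample,feature_id,rt_min,mz,area`` (``mz`` optional).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "Peak",
    "PeakTable",
    "ZoneConfig",
    "ProfileMatrix",
    "read_peak_tables",
    "write_peak_tables",
    "filter_noise",
    "zone_summary",
    "build_profile_matrix",
    "pca_profiles",
    "kmeans_profiles",
]

#: log10 relative area assigned to features absent from a sample
#: (pseudo relative area 1e-6).
LOG_FLOOR = -6.0


@dataclass(frozen=True)
class Peak:
    feature_id: str
    retention_time: float  # min
    area: float  # detector units
    mz: Optional[float] = None

    def __post_init__(self) -> None:
        if self.retention_time < 0:
            raise ValueError(f"retention time must be >= 0, got {self.retention_time}")
        if self.area < 0:
            raise ValueError(f"peak area must be >= 0, got {self.area}")


@dataclass(frozen=True)
class PeakTable:
    sample_id: str
    peaks: Sequence[Peak]

    def __post_init__(self) -> None:
        ids = [p.feature_id for p in self.peaks]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate feature ids in {self.sample_id}: {dup}")
        object.__setattr__(self, "peaks", tuple(self.peaks))

    @property
    def total_area(self) -> float:
        return float(sum(p.area for p in self.peaks))


@dataclass(frozen=True)
class ZoneConfig:
    """Retention-time cut points (min) splitting the gradient into polarity
    zones.  Peaks before the first boundary land in a pre-gradient bucket;
    zone intervals are half-open [lower, upper), the last zone open-ended."""

    boundaries: Tuple[float, ...] = (9.0, 21.0, 39.0)
    labels: Tuple[str, ...] = ("high_polarity", "middle_polarity", "low_polarity")
    pre_gradient_label: str = "pre_gradient"

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.boundaries)
        if any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise ValueError("zone boundaries must be strictly increasing")
        if len(self.labels) != len(b):
            raise ValueError("need one label per zone (boundary to next boundary / open end)")
        object.__setattr__(self, "boundaries", b)

    def zone_of(self, rt: float) -> str:
        if rt < self.boundaries[0]:
            return self.pre_gradient_label
        for i, label in enumerate(self.labels):
            upper = self.boundaries[i + 1] if i + 1 < len(self.boundaries) else float("inf")
            if self.boundaries[i] <= rt < upper:
                return label
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class ProfileMatrix:
    """Samples x features matrix of relative areas (rows sum to 1 over the
    features detected in each sample)."""

    relative_areas: pd.DataFrame  # index: samples, columns: features

    def log10(self, floor: float = LOG_FLOOR) -> pd.DataFrame:
        """Heat-map matrix: log10 of the relative areas with absent features
        (zero relative area) held at ``floor``."""
        vals = self.relative_areas.to_numpy(dtype=float)
        with np.errstate(divide="ignore"):
            logged = np.log10(vals)
        logged[~np.isfinite(logged)] = floor
        logged = np.maximum(logged, floor)
        return pd.DataFrame(logged, index=self.relative_areas.index,
                            columns=self.relative_areas.columns)

    @property
    def samples(self) -> List[str]:
        return list(self.relative_areas.index)


# -- I/O --------------------------------------------------------------------

def read_peak_tables(path: "str | Path") -> List[PeakTable]:
    """Read one or more samples from a delimited file with columns
    ``sample,feature_id,rt_min,mz,area`` (``mz`` may be blank/absent)."""
    df = pd.read_csv(path)
    required = {"sample", "feature_id", "rt_min", "area"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    tables = []
    for sample, grp in df.groupby("sample", sort=False):
        peaks = [
            Peak(
                feature_id=str(row.feature_id),
                retention_time=float(row.rt_min),
                area=float(row.area),
                mz=None if "mz" not in df.columns or pd.isna(row.mz) else float(row.mz),
            )
            for row in grp.itertuples()
        ]
        tables.append(PeakTable(str(sample), peaks))
    return tables


def write_peak_tables(tables: Sequence[PeakTable], path: "str | Path") -> None:
    rows = [
        {
            "sample": t.sample_id,
            "feature_id": p.feature_id,
            "rt_min": p.retention_time,
            "mz": p.mz,
            "area": p.area,
        }
        for t in tables
        for p in t.peaks
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# -- operations -------------------------------------------------------------

def filter_noise(table: PeakTable, threshold_percent: float = 1.0) -> PeakTable:
    """Remove peaks whose relative area is below ``threshold_percent``.

    Relative areas are computed against the pre-filter total, and the cut
    is strict: a peak at exactly the threshold is kept.
    """
    if not table.peaks:
        warnings.warn(f"peak table {table.sample_id!r} is empty", stacklevel=2)
        return table
    total = table.total_area
    if total <= 0:
        warnings.warn(f"peak table {table.sample_id!r} has zero total area", stacklevel=2)
        return replace(table, peaks=())
    kept = tuple(p for p in table.peaks if p.area / total * 100.0 >= threshold_percent)
    return replace(table, peaks=kept)


def zone_summary(table: PeakTable, zones: ZoneConfig = ZoneConfig()) -> pd.DataFrame:
    """Peak counts and total areas per polarity zone.

    Returns a DataFrame indexed by zone (pre-gradient bucket first) with
    columns ``n_peaks`` and ``total_area``; counts and areas over all zones
    sum to the whole-table values.
    """
    order = [zones.pre_gradient_label, *zones.labels]
    counts = {z: 0 for z in order}
    areas = {z: 0.0 for z in order}
    for p in table.peaks:
        z = zones.zone_of(p.retention_time)
        counts[z] += 1
        areas[z] += p.area
    return pd.DataFrame(
        {"n_peaks": [counts[z] for z in order],
         "total_area": [areas[z] for z in order]},
        index=pd.Index(order, name="zone"),
    )


def _match_features(
    tables: Sequence[PeakTable],
    rt_tolerance: float,
    mz_tolerance_ppm: float,
) -> List[Tuple[PeakTable, Dict[str, Peak]]]:
    """Assign each peak a cross-sample feature key.

    Peaks keep their own feature_id as key.  Peaks whose id is empty are
    matched to the nearest previously seen feature within the RT (and,
    when both have m/z, ppm) tolerance; unmatched ones open a new feature.
    Deterministic: samples and peaks are processed in input order and ties
    resolved by smallest RT distance, then feature key.
    """
    seen: Dict[str, Tuple[float, Optional[float]]] = {}
    out: List[Tuple[PeakTable, Dict[str, Peak]]] = []
    anon = 0
    for table in tables:
        keyed: Dict[str, Peak] = {}
        for p in table.peaks:
            if p.feature_id:
                key = p.feature_id
                seen.setdefault(key, (p.retention_time, p.mz))
            else:
                best_key, best_d = None, rt_tolerance
                for k, (rt, mz) in sorted(seen.items()):
                    d = abs(p.retention_time - rt)
                    if d > best_d:
                        continue
                    if p.mz is not None and mz is not None:
                        if abs(p.mz - mz) / mz * 1e6 > mz_tolerance_ppm:
                            continue
                    if best_key is None or d < best_d:
                        best_key, best_d = k, d
                if best_key is None:
                    anon += 1
                    best_key = f"feature_{anon:04d}"
                    seen[best_key] = (p.retention_time, p.mz)
                key = best_key
            if key in keyed:
                keyed[key] = max(keyed[key], p, key=lambda q: q.area)
            else:
                keyed[key] = p
        out.append((table, keyed))
    return out


def build_profile_matrix(
    tables: Sequence[PeakTable],
    align_tolerance: Tuple[float, float] = (0.2, 10.0),
) -> ProfileMatrix:
    """Relative-area matrix across samples.

    Features are matched across samples by ``feature_id`` where present,
    otherwise by RT/mz proximity within ``align_tolerance`` (RT minutes,
    m/z ppm).  Each cell is peak area divided by the sample's total area;
    features absent from a sample are 0 (and sit at the log floor after
    the log10 transform).
    """
    if len(tables) < 1:
        raise ValueError("need at least one peak table")
    rt_tol, ppm_tol = align_tolerance
    matched = _match_features(tables, rt_tol, ppm_tol)
    features: List[str] = []
    for _t, keyed in matched:
        for k in keyed:
            if k not in features:
                features.append(k)
    data = np.zeros((len(tables), len(features)))
    for i, (table, keyed) in enumerate(matched):
        total = sum(p.area for p in keyed.values())
        if total <= 0:
            warnings.warn(f"sample {table.sample_id!r} has zero total area", stacklevel=2)
            continue
        for j, feat in enumerate(features):
            if feat in keyed:
                data[i, j] = keyed[feat].area / total
    df = pd.DataFrame(data, index=[t.sample_id for t in tables], columns=features)
    return ProfileMatrix(df)


def pca_profiles(
    matrix: "ProfileMatrix | pd.DataFrame",
    n_components: int = 2,
    log_transform: bool = True,
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Principal-component scores of the samples and per-component
    explained-variance fractions.

    By default operates on the log10 heat-map matrix (mean-centered per
    feature by the decomposition; no unit-variance scaling).
    """
    df = matrix.log10() if isinstance(matrix, ProfileMatrix) and log_transform else (
        matrix.relative_areas if isinstance(matrix, ProfileMatrix) else matrix
    )
    n_samples, n_features = df.shape
    if n_components > min(n_samples - 1, n_features):
        raise ValueError(
            f"n_components={n_components} exceeds min(samples-1, features)="
            f"{min(n_samples - 1, n_features)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(df.to_numpy(dtype=float))
    cols = [f"PC{i+1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=df.index, columns=cols),
        pca.explained_variance_ratio_.copy(),
    )


def kmeans_profiles(
    data: "ProfileMatrix | pd.DataFrame | np.ndarray",
    k: int = 2,
    seed: int = 0,
) -> np.ndarray:
    """k-means cluster labels for the samples, deterministic for a seed.

    Accepts the profile matrix (clustered on its log10 transform), a
    DataFrame of scores, or a plain array.  Labels are canonicalized so
    cluster ids follow first occurrence (sample 0 is always cluster 0).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if isinstance(data, ProfileMatrix):
        X = data.log10().to_numpy(dtype=float)
    elif isinstance(data, pd.DataFrame):
        X = data.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of samples {X.shape[0]}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(X)
    mapping: Dict[int, int] = {}
    for lbl in raw:
        if lbl not in mapping:
            mapping[lbl] = len(mapping)
    return np.array([mapping[lbl] for lbl in raw])
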