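"""Edge-wise functional connectivity: region mean series, Pearson r, Fisher z.

Feature schemes
---------------
``loops``
    40 z values per hemisphere, one per edge of the individually mapped short
    (19) and long (21) loops.  Region pairs shared by both loops contribute a
    value to each loop's feature block.
``atlas``
    26 z values per hemisphere on whole (undivided) subcortical structures.
    When only subdivision series are available, a parent structure's series is
    the mean of its subdivisions' series — identical to averaging the voxels
    the subdivisions jointly cover.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .regions import LoopEdge, LoopManifest, RegionLabel, SUBCORTICAL

#: correlations are clipped to 1 - ARCTANH_EPS in magnitude so z stays finite
ARCTANH_EPS = 1e-7


class ConstantSeriesError(ValueError):
    pass


def mean_region_series(source, mask_or_region):
    """Mean time series of a region.

    Volume mode: ``source`` is a 4D array (x, y, z, t) and ``mask_or_region``
    a boolean/integer voxel mask — returns the voxel-mean series.  Matrix
    mode: ``source`` is a regions x time DataFrame and ``mask_or_region`` a
    region row key — returns the stored row.
    """
    if isinstance(source, pd.DataFrame):
        if mask_or_region not in source.index:
            raise KeyError(f"region {mask_or_region!r} not present in series matrix")
        return source.loc[mask_or_region].to_numpy(dtype=float)
    vol = np.asarray(source)
    mask = np.asarray(mask_or_region).astype(bool)
    if not mask.any():
        raise ValueError(f"empty mask for region {getattr(mask_or_region, 'name', '')!r}")
    return vol[mask].mean(axis=0)


def pearson_r(x, y) -> float:
    """Sample Pearson correlation of two equal-length series (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("series must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ConstantSeriesError("constant series")
    return float(np.corrcoef(x, y)[0, 1])


def fisher_z(r) -> float | np.ndarray:
    """Fisher r-to-z transform, clipped near +/-1 so the result is always finite."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("|r| > 1")
    z = np.arctanh(np.clip(r, -1 + ARCTANH_EPS, 1 - ARCTANH_EPS))
    return float(z) if z.ndim == 0 else z


def region_series_key(region: RegionLabel) -> str:
    return f"{region.hemisphere}:{region.name}"


def resolve_region_series(series: pd.DataFrame, region: RegionLabel) -> np.ndarray:
    """Series for a region; whole subcortical structures fall back to the mean
    of their subdivision rows when no dedicated row exists."""
    key = region_series_key(region)
    if key in series.index:
        return series.loc[key].to_numpy(dtype=float)
    if region.kind == "subcortical":
        prefix = f"{region.hemisphere}:{region.name}_"
        rows = [i for i in series.index if i.startswith(prefix)]
        if rows:
            return series.loc[rows].to_numpy(dtype=float).mean(axis=0)
    raise KeyError(f"no series for region {key}")


def fc_vector(series: pd.DataFrame, edges: list[LoopEdge]) -> pd.Series:
    """One subject's Fisher-z FC across ``edges`` from a regions x time matrix."""
    cache: dict[str, np.ndarray] = {}

    def get(region: RegionLabel) -> np.ndarray:
        key = region_series_key(region)
        if key not in cache:
            s = resolve_region_series(series, region)
            sd = s.std()
            if sd == 0:
                raise ConstantSeriesError(f"constant series for region {key}")
            cache[key] = (s - s.mean()) / sd
        return cache[key]

    n_t = series.shape[1]
    values = {}
    for e in edges:
        r = float(get(e.a) @ get(e.b)) / n_t
        values[e.key] = fisher_z(r)
    return pd.Series(values)


def extract_fc_vector(series_by_subject: dict[str, pd.DataFrame],
                      manifest: LoopManifest, scheme: str) -> pd.DataFrame:
    """Subjects x edges table of Fisher-z FC for one feature scheme.

    Rows follow the input subject order; columns are edge keys
    ``loop:hemisphere:regionA-regionB``.  Unresolvable regions (e.g. an empty
    subdivision) raise — downstream stages require complete cases.
    """
    edges = manifest.scheme_edges(scheme)
    rows = {sid: fc_vector(s, edges) for sid, s in series_by_subject.items()}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out = out[[e.key for e in edges]]
    out.index.name = "id"
    return out


def save_fc_table(fc: pd.DataFrame, path) -> None:
    fc.to_csv(path, sep="\t", float_format="%.10g")


def load_fc_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")
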