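"""Static resting-state network (RSN) connectivity.

Parcel-averaged time series, Pearson correlation matrices between regions,
and aggregation of region-pair correlations into within- and between-RSN
values (an n_rsn x n_rsn symmetric matrix).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Volume4D


@dataclass
class Parcellation:
    """Label volume (0 = background) plus a region table mapping each region
    id to a name and a resting-state network."""

    label_volume: np.ndarray
    region_table: pd.DataFrame  # columns: region_id, name, rsn_id, rsn_name

    def __post_init__(self) -> None:
        labels = np.unique(self.label_volume)
        labels = labels[labels > 0]
        known = set(self.region_table["region_id"].tolist())
        unknown = [int(l) for l in labels if int(l) not in known]
        if unknown:
            raise ValueError(f"labels missing from region table: {unknown}")

    @property
    def n_regions(self) -> int:
        return len(self.region_table)

    @property
    def n_rsn(self) -> int:
        return int(self.region_table["rsn_id"].nunique())

    @property
    def region_ids(self) -> np.ndarray:
        return self.region_table["region_id"].to_numpy()

    @classmethod
    def from_files(cls, label_nifti: str | Path, region_tsv: str | Path) -> "Parcellation":
        import nibabel as nib

        img = nib.load(str(label_nifti))
        return cls(
            label_volume=np.asarray(img.dataobj).astype(int),
            region_table=pd.read_csv(region_tsv, sep="\t"),
        )


@dataclass
class RsnMatrix:
    """Symmetric matrix of mean region-pair correlations per RSN pair."""

    values: np.ndarray
    rsn_ids: np.ndarray

    @property
    def n_rsn(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        names = [f"RSN{i}" for i in self.rsn_ids]
        return pd.DataFrame(self.values, index=names, columns=names)


def parcel_timeseries(
    vol: Volume4D, parc: Parcellation, keep_mask: np.ndarray | None = None
) -> np.ndarray:
    """Mean time series per region, restricted to kept frames.

    Returns a (n_kept_frames, n_regions) matrix; a region with no voxels
    yields a NaN column with a warning.
    """
    if parc.label_volume.shape != vol.data.shape[:3]:
        raise ValueError("parcellation grid does not match the volume")
    keep = np.ones(vol.n_frames, dtype=bool) if keep_mask is None else np.asarray(keep_mask, bool)
    out = np.full((int(keep.sum()), parc.n_regions), np.nan)
    for j, rid in enumerate(parc.region_ids):
        voxels = parc.label_volume == rid
        if not voxels.any():
            warnings.warn(f"region {rid} has no voxels; NaN column", RuntimeWarning, stacklevel=2)
            continue
        out[:, j] = vol.data[voxels][:, keep].mean(axis=0)
    return out


def fc_matrix(ts: np.ndarray) -> np.ndarray:
    """Pearson correlation between region time series (symmetric, unit
    diagonal). Zero-variance columns give NaN rows/columns with a warning."""
    ts = np.asarray(ts, dtype=float)
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 kept frames")
    bad = ts.std(axis=0) == 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} zero-variance region(s); NaN correlations", RuntimeWarning, stacklevel=2
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.corrcoef(ts, rowvar=False)
    fc[bad, :] = np.nan
    fc[:, bad] = np.nan
    np.fill_diagonal(fc, np.where(bad, np.nan, 1.0))
    return fc


def rsn_aggregate(fc: np.ndarray, parc: Parcellation, fisher_z: bool = False) -> RsnMatrix:
    """Average region-pair correlations into RSN blocks.

    Diagonal (within-RSN) blocks average off-diagonal pairs only, so unit
    self-correlations never inflate within-network connectivity. An RSN with
    a single region has no within pairs and yields NaN with a warning.
    With ``fisher_z`` the average is taken in Fisher-z space and mapped back.
    """
    fc = np.asarray(fc, dtype=float)
    if fc.shape[0] != parc.n_regions:
        raise ValueError("fc dimension does not match number of regions")
    vals = np.arctanh(np.clip(fc, -1 + 1e-12, 1 - 1e-12)) if fisher_z else fc
    rsn_ids = np.sort(parc.region_table["rsn_id"].unique())
    region_rsn = parc.region_table.set_index("region_id")["rsn_id"]
    membership = region_rsn.loc[parc.region_ids].to_numpy()
    n = len(rsn_ids)
    out = np.full((n, n), np.nan)
    for a_i, a in enumerate(rsn_ids):
        ia = np.flatnonzero(membership == a)
        for b_i, b in enumerate(rsn_ids[: a_i + 1]):
            ib = np.flatnonzero(membership == b)
            block = vals[np.ix_(ia, ib)]
            if a == b:
                if len(ia) < 2:
                    warnings.warn(
                        f"RSN {a} has a single region; within-RSN value undefined",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                    continue
                pairs = block[np.triu_indices(len(ia), 1)]
            else:
                pairs = block.ravel()
            m = np.nanmean(pairs)
            out[a_i, b_i] = out[b_i, a_i] = np.tanh(m) if fisher_z else m
    return RsnMatrix(values=out, rsn_ids=rsn_ids)
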