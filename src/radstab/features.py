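"""Radiomic feature extraction and feature-table handling.

Features are computed in 3D from the whole-tumour region of each MRI
sequence after fixed-bin-number discretisation: 18 first-order, 24
grey-level co-occurrence (GLCM), 16 grey-level run length (GLRLM), 16
grey-level size zone (GLSZM), 14 grey-level dependence (GLDM) and 5
neighbouring grey-tone difference (NGTDM) features per sequence, plus 12
shape features from the contrast-enhanced T1 mask — 384 features per image
set.  Conventions (13 unique 3D direction offsets at distance 1, symmetric
matrices, per-direction features averaged, 26-connectivity zones and
neighbourhoods) follow the common reference-implementation choices.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

SEQUENCES = ("T1W", "T2W", "FLAIR", "T1CE")
SHAPE_SEQUENCE = "T1CE"
BIN_COUNTS = (8, 32, 64, 128)

#: the 13 unique 3D direction offsets (half of the 26-neighbourhood)
DIRECTIONS_3D = [
    off
    for off in itertools.product((-1, 0, 1), repeat=3)
    if off > (0, 0, 0)
]

FAMILY_COUNTS = {
    "firstorder": 18, "glcm": 24, "glrlm": 16,
    "glszm": 16, "gldm": 14, "ngtdm": 5,
}
N_SHAPE = 12
N_FEATURES_TOTAL = sum(FAMILY_COUNTS.values()) * len(SEQUENCES) + N_SHAPE  # 384


# --------------------------------------------------------------------------
# feature table container

@dataclass
class FeatureTable:
    """Patients x named radiomic features.

    ``values`` is a DataFrame indexed by patient_id with feature-name
    columns following the schema ``{sequence}_{family}_{feature}_bin{N}``
    (shape features, which are bin-independent, omit the bin suffix).
    """

    values: pd.DataFrame

    def __post_init__(self):
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate feature names")

    @property
    def patient_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_patients(self) -> int:
        return len(self.values)

    def metadata(self) -> pd.DataFrame:
        """Parse feature names into (sequence, family, feature, bin_count)."""
        rows = []
        for name in self.values.columns:
            parts = name.split("_")
            seq, family = parts[0], parts[1]
            if parts[-1].startswith("bin") and parts[-1][3:].isdigit():
                bin_count: int | None = int(parts[-1][3:])
                feat = "_".join(parts[2:-1])
            else:
                bin_count = None
                feat = "_".join(parts[2:])
            rows.append((name, seq, family, feat, bin_count))
        return pd.DataFrame(
            rows, columns=["name", "sequence", "family", "feature", "bin_count"]
        ).set_index("name")

    def sequence_block(self, sequence: str) -> "FeatureTable":
        cols = [c for c in self.values.columns if c.split("_")[0] == sequence]
        return FeatureTable(self.values[cols].copy())

    def subset(self, patient_ids=None, feature_names=None) -> "FeatureTable":
        df = self.values
        if patient_ids is not None:
            df = df.loc[list(patient_ids)]
        if feature_names is not None:
            df = df[list(feature_names)]
        return FeatureTable(df.copy())

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="patient_id")

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        return cls(pd.read_csv(path, index_col="patient_id"))


# --------------------------------------------------------------------------
# discretisation

def discretise(volume: np.ndarray, mask: np.ndarray, bin_count: int) -> np.ndarray:
    """Map in-mask intensities to integer levels 1..bin_count.

    Equal-width bins span the in-mask intensity range, so the levels are
    invariant under affine transforms of the input.  The in-mask maximum
    maps to bin_count.  Out-of-mask voxels are set to 0.
    """
    if bin_count < 2:
        raise ValueError("bin_count must be >= 2")
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = np.asarray(volume, float)[mask]
    lo, hi = vals.min(), vals.max()
    out = np.zeros(volume.shape, dtype=np.int32)
    if hi == lo:
        warnings.warn("constant in-mask region: all voxels assigned level 1")
        out[mask] = 1
        return out
    levels = np.floor((vals - lo) / (hi - lo) * bin_count).astype(np.int32) + 1
    np.clip(levels, 1, bin_count, out=levels)
    out[mask] = levels
    return out


# --------------------------------------------------------------------------
# first order

def _firstorder(vals: np.ndarray, levels: np.ndarray, bin_count: int) -> dict:
    n = vals.size
    hist = np.bincount(levels, minlength=bin_count + 1)[1:]
    p = hist[hist > 0] / n
    mean = vals.mean()
    var = vals.var()  # population convention
    sd = np.sqrt(var)
    p10, p25, p50, p75, p90 = np.percentile(vals, [10, 25, 50, 75, 90])
    robust = vals[(vals >= p10) & (vals <= p90)]
    if var > 0:
        zc = (vals - mean) / sd
        skew = np.mean(zc**3)
        kurt = np.mean(zc**4)  # non-excess (Pearson) kurtosis
    else:
        skew, kurt = 0.0, 0.0
    return {
        "Energy": float(np.sum(vals**2)),
        "TotalEnergy": float(np.sum(vals**2)),  # 1 mm^3 voxels
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(vals.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(vals.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(vals.max() - vals.min()),
        "MeanAbsoluteDeviation": float(np.abs(vals - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt(np.mean(vals**2))),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Variance": float(var),
        "Uniformity": float((p**2).sum()),
    }


# --------------------------------------------------------------------------
# helpers for offset-based co-occurrence

def _offset_pairs(levels: np.ndarray, mask: np.ndarray, off) -> tuple[np.ndarray, np.ndarray]:
    """Level values of all in-mask voxel pairs separated by ``off``."""
    sl_a, sl_b = [], []
    for o in off:
        if o >= 0:
            sl_a.append(slice(None, levels.shape[len(sl_a)] - o if o else None))
            sl_b.append(slice(o, None))
        else:
            sl_a.append(slice(-o, None))
            sl_b.append(slice(None, o))
    a = levels[tuple(sl_a)]
    b = levels[tuple(sl_b)]
    m = mask[tuple(sl_a)] & mask[tuple(sl_b)]
    return a[m], b[m]


# --------------------------------------------------------------------------
# GLCM

def glcm_matrix(levels: np.ndarray, mask: np.ndarray, off, bin_count: int) -> np.ndarray:
    """Symmetric co-occurrence counts for one direction offset (distance 1)."""
    a, b = _offset_pairs(levels, mask, off)
    mat = np.bincount((a - 1) * bin_count + (b - 1),
                      minlength=bin_count * bin_count
                      ).reshape(bin_count, bin_count).astype(float)
    return mat + mat.T


def _glcm_features(P: np.ndarray) -> dict:
    eps = np.finfo(float).eps
    total = P.sum()
    if total == 0:
        return {k: 0.0 for k in _GLCM_NAMES}
    p = P / total
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = (i * px).sum()
    muy = (i * py).sum()
    sigx = np.sqrt(((i - mux) ** 2 * px).sum())
    sigy = np.sqrt(((i - muy) ** 2 * py).sum())
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = np.abs(ii - jj)
    # p_{x+y}: k = 2..2Ng ; p_{x-y}: k = 0..Ng-1
    pxy_sum = np.zeros(2 * ng - 1)
    np.add.at(pxy_sum, (ii + jj - 2).ravel(), p.ravel())
    pxy_diff = np.zeros(ng)
    np.add.at(pxy_diff, diff.ravel(), p.ravel())
    ks = np.arange(2, 2 * ng + 1)
    kd = np.arange(ng)
    da = (kd * pxy_diff).sum()
    hx = -(px[px > 0] * np.log2(px[px > 0])).sum()
    hy = -(py[py > 0] * np.log2(py[py > 0])).sum()
    hxy = -(p[p > 0] * np.log2(p[p > 0])).sum()
    pxpy = px[:, None] * py[None, :]
    hxy1 = -(p * np.log2(pxpy + eps)).sum()
    hxy2 = -(pxpy * np.log2(pxpy + eps)).sum()
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = np.sqrt(max(0.0, 1 - np.exp(-2 * (hxy2 - hxy))))
    # MCC: second-largest eigenvalue of Q
    with np.errstate(divide="ignore", invalid="ignore"):
        Q = np.where((px[:, None] > 0),
                     p @ (p / np.where(py[None, :] > 0, py[None, :], 1)).T, 0.0)
        Q = Q / np.where(px[:, None] > 0, px[:, None], 1)
    ev = np.sort(np.real(np.linalg.eigvals(Q)))
    mcc = np.sqrt(max(0.0, ev[-2])) if len(ev) > 1 else 1.0
    off_diag = diff > 0
    return {
        "Autocorrelation": float((ii * jj * p).sum()),
        "JointAverage": float(mux),
        "ClusterProminence": float((((ii + jj) - (mux + muy)) ** 4 * p).sum()),
        "ClusterShade": float((((ii + jj) - (mux + muy)) ** 3 * p).sum()),
        "ClusterTendency": float((((ii + jj) - (mux + muy)) ** 2 * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": float(
            ((ii * jj * p).sum() - mux * muy) / (sigx * sigy)
            if sigx > 0 and sigy > 0 else 1.0
        ),
        "DifferenceAverage": float(da),
        "DifferenceEntropy": float(
            -(pxy_diff[pxy_diff > 0] * np.log2(pxy_diff[pxy_diff > 0])).sum()
        ),
        "DifferenceVariance": float(((kd - da) ** 2 * pxy_diff).sum()),
        "Id": float((p / (1 + diff)).sum()),
        "Idm": float((p / (1 + diff**2)).sum()),
        "Idmn": float((p / (1 + diff**2 / ng**2)).sum()),
        "Idn": float((p / (1 + diff / ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": float(imc2),
        "InverseVariance": float((p[off_diag] / diff[off_diag] ** 2).sum()),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": float(hxy),
        "Mcc": float(mcc),
        "MaximumProbability": float(p.max()),
        "SumAverage": float((ks * pxy_sum).sum()),
        "SumEntropy": float(
            -(pxy_sum[pxy_sum > 0] * np.log2(pxy_sum[pxy_sum > 0])).sum()
        ),
        "SumSquares": float(((ii - mux) ** 2 * p).sum()),
    }


_GLCM_NAMES = list(_glcm_features(np.ones((2, 2))).keys())


# --------------------------------------------------------------------------
# GLRLM

def glrlm_matrix(levels: np.ndarray, mask: np.ndarray, off, bin_count: int,
                 max_len: int | None = None) -> np.ndarray:
    """Run-length counts R[g-1, l-1] along one direction."""
    if max_len is None:
        max_len = int(np.ceil(np.linalg.norm(levels.shape) / max(np.abs(off).max(), 1))) + 1
    shape = levels.shape
    inmask = mask
    coords = np.argwhere(inmask)
    lv = levels[inmask]
    off = np.asarray(off)
    # a voxel starts a run if its predecessor (v - off) is outside the mask
    # or carries a different level
    prev = coords - off
    ok = np.all((prev >= 0) & (prev < shape), axis=1)
    prev_same = np.zeros(len(coords), bool)
    pc = prev[ok]
    prev_same[ok] = inmask[pc[:, 0], pc[:, 1], pc[:, 2]] & (
        levels[pc[:, 0], pc[:, 1], pc[:, 2]] == lv[ok]
    )
    starts = coords[~prev_same]
    start_lv = lv[~prev_same]
    lengths = np.ones(len(starts), dtype=np.int64)
    alive = np.ones(len(starts), bool)
    k = 1
    while alive.any() and k <= max_len:
        nxt = starts[alive] + k * off
        inb = np.all((nxt >= 0) & (nxt < shape), axis=1)
        cont = np.zeros(inb.shape, bool)
        nb = nxt[inb]
        cont[inb] = inmask[nb[:, 0], nb[:, 1], nb[:, 2]] & (
            levels[nb[:, 0], nb[:, 1], nb[:, 2]] == start_lv[alive][inb]
        )
        idx = np.flatnonzero(alive)
        lengths[idx[cont]] += 1
        alive[idx[~cont]] = False
        k += 1
    L = int(lengths.max()) if len(lengths) else 1
    R = np.zeros((bin_count, L))
    np.add.at(R, (start_lv - 1, lengths - 1), 1.0)
    return R


def _rlm_features(R: np.ndarray, n_voxels: int) -> dict:
    nr = R.sum()
    if nr == 0:
        R = np.ones((1, 1))
        nr = 1.0
    g = np.arange(1, R.shape[0] + 1, dtype=float)
    l = np.arange(1, R.shape[1] + 1, dtype=float)
    pg = R.sum(axis=1)
    pl = R.sum(axis=0)
    p = R / nr
    mu_g = (g * pg / nr).sum()
    mu_l = (l * pl / nr).sum()
    pnz = p[p > 0]
    return {
        "ShortRunEmphasis": float((pl / l**2).sum() / nr),
        "LongRunEmphasis": float((pl * l**2).sum() / nr),
        "GrayLevelNonUniformity": float((pg**2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum() / nr**2),
        "RunLengthNonUniformity": float((pl**2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((pl**2).sum() / nr**2),
        "RunPercentage": float(nr / n_voxels),
        "GrayLevelVariance": float((((g - mu_g) ** 2) * pg / nr).sum()),
        "RunVariance": float((((l - mu_l) ** 2) * pl / nr).sum()),
        "RunEntropy": float(-(pnz * np.log2(pnz)).sum()),
        "LowGrayLevelRunEmphasis": float((pg / g**2).sum() / nr),
        "HighGrayLevelRunEmphasis": float((pg * g**2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float(
            (R / (g[:, None] ** 2 * l[None, :] ** 2)).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float(
            (R * g[:, None] ** 2 / l[None, :] ** 2).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float(
            (R * l[None, :] ** 2 / g[:, None] ** 2).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float(
            (R * g[:, None] ** 2 * l[None, :] ** 2).sum() / nr),
    }


# --------------------------------------------------------------------------
# GLSZM

_STRUCT_26 = np.ones((3, 3, 3), dtype=int)


def glszm_matrix(levels: np.ndarray, mask: np.ndarray, bin_count: int) -> np.ndarray:
    """Size-zone counts S[g-1, s-1]; zones are 26-connected same-level blobs."""
    sizes_by_level = []
    max_size = 1
    for gval in range(1, bin_count + 1):
        blob = mask & (levels == gval)
        if not blob.any():
            sizes_by_level.append(np.zeros(0, dtype=np.int64))
            continue
        lab, nlab = ndimage.label(blob, structure=_STRUCT_26)
        sizes = np.bincount(lab.ravel())[1:]
        sizes_by_level.append(sizes)
        max_size = max(max_size, int(sizes.max()))
    S = np.zeros((bin_count, max_size))
    for gi, sizes in enumerate(sizes_by_level):
        if sizes.size:
            np.add.at(S, (gi, sizes - 1), 1.0)
    return S


def _szm_features(S: np.ndarray, n_voxels: int) -> dict:
    base = _rlm_features(S, n_voxels)
    rename = {
        "ShortRunEmphasis": "SmallAreaEmphasis",
        "LongRunEmphasis": "LargeAreaEmphasis",
        "RunLengthNonUniformity": "SizeZoneNonUniformity",
        "RunLengthNonUniformityNormalized": "SizeZoneNonUniformityNormalized",
        "RunPercentage": "ZonePercentage",
        "RunVariance": "ZoneVariance",
        "RunEntropy": "ZoneEntropy",
        "LowGrayLevelRunEmphasis": "LowGrayLevelZoneEmphasis",
        "HighGrayLevelRunEmphasis": "HighGrayLevelZoneEmphasis",
        "ShortRunLowGrayLevelEmphasis": "SmallAreaLowGrayLevelEmphasis",
        "ShortRunHighGrayLevelEmphasis": "SmallAreaHighGrayLevelEmphasis",
        "LongRunLowGrayLevelEmphasis": "LargeAreaLowGrayLevelEmphasis",
        "LongRunHighGrayLevelEmphasis": "LargeAreaHighGrayLevelEmphasis",
    }
    return {rename.get(k, k): v for k, v in base.items()}


# --------------------------------------------------------------------------
# GLDM

def gldm_matrix(levels: np.ndarray, mask: np.ndarray, bin_count: int) -> np.ndarray:
    """Dependence counts D[g-1, j-1]; j = 1 + number of 26-neighbours with
    the same level (the centre voxel counts as its own dependency)."""
    dep = np.zeros(levels.shape, dtype=np.int32)
    for off in DIRECTIONS_3D:
        for sgn in (1, -1):
            o = tuple(sgn * np.asarray(off))
            sl_a, sl_b = [], []
            for ax, oo in enumerate(o):
                if oo >= 0:
                    sl_a.append(slice(None, levels.shape[ax] - oo if oo else None))
                    sl_b.append(slice(oo, None))
                else:
                    sl_a.append(slice(-oo, None))
                    sl_b.append(slice(None, oo))
            same = (
                mask[tuple(sl_a)] & mask[tuple(sl_b)]
                & (levels[tuple(sl_a)] == levels[tuple(sl_b)])
            )
            dep[tuple(sl_a)] += same
    j = dep[mask] + 1
    g = levels[mask]
    D = np.zeros((bin_count, int(j.max())))
    np.add.at(D, (g - 1, j - 1), 1.0)
    return D


def _gldm_features(D: np.ndarray) -> dict:
    nz = D.sum()
    g = np.arange(1, D.shape[0] + 1, dtype=float)
    j = np.arange(1, D.shape[1] + 1, dtype=float)
    pg = D.sum(axis=1)
    pj = D.sum(axis=0)
    p = D / nz
    mu_g = (g * pg / nz).sum()
    mu_j = (j * pj / nz).sum()
    pnz = p[p > 0]
    return {
        "SmallDependenceEmphasis": float((pj / j**2).sum() / nz),
        "LargeDependenceEmphasis": float((pj * j**2).sum() / nz),
        "GrayLevelNonUniformity": float((pg**2).sum() / nz),
        "DependenceNonUniformity": float((pj**2).sum() / nz),
        "DependenceNonUniformityNormalized": float((pj**2).sum() / nz**2),
        "GrayLevelVariance": float((((g - mu_g) ** 2) * pg / nz).sum()),
        "DependenceVariance": float((((j - mu_j) ** 2) * pj / nz).sum()),
        "DependenceEntropy": float(-(pnz * np.log2(pnz)).sum()),
        "LowGrayLevelEmphasis": float((pg / g**2).sum() / nz),
        "HighGrayLevelEmphasis": float((pg * g**2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float(
            (D / (g[:, None] ** 2 * j[None, :] ** 2)).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float(
            (D * g[:, None] ** 2 / j[None, :] ** 2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float(
            (D * j[None, :] ** 2 / g[:, None] ** 2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float(
            (D * g[:, None] ** 2 * j[None, :] ** 2).sum() / nz),
    }


# --------------------------------------------------------------------------
# NGTDM

def ngtdm_table(levels: np.ndarray, mask: np.ndarray, bin_count: int):
    """Per-level occurrence counts n_i and summed absolute differences s_i
    between each voxel and the mean of its in-mask 26-neighbourhood."""
    lv = np.where(mask, levels, 0).astype(float)
    msk = mask.astype(float)
    sum_nb = np.zeros(levels.shape)
    cnt_nb = np.zeros(levels.shape)
    for off in DIRECTIONS_3D:
        for sgn in (1, -1):
            o = tuple(sgn * np.asarray(off))
            sl_a, sl_b = [], []
            for ax, oo in enumerate(o):
                if oo >= 0:
                    sl_a.append(slice(None, levels.shape[ax] - oo if oo else None))
                    sl_b.append(slice(oo, None))
                else:
                    sl_a.append(slice(-oo, None))
                    sl_b.append(slice(None, oo))
            sum_nb[tuple(sl_a)] += lv[tuple(sl_b)]
            cnt_nb[tuple(sl_a)] += msk[tuple(sl_b)]
    valid = mask & (cnt_nb > 0)
    diffs = np.abs(levels[valid] - sum_nb[valid] / cnt_nb[valid])
    g = levels[valid]
    n_i = np.bincount(g, minlength=bin_count + 1)[1:].astype(float)
    s_i = np.zeros(bin_count)
    np.add.at(s_i, g - 1, diffs)
    return n_i, s_i


def _ngtdm_features(n_i: np.ndarray, s_i: np.ndarray) -> dict:
    N = n_i.sum()
    if N == 0:
        return {k: 0.0 for k in
                ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")}
    p_i = n_i / N
    i = np.arange(1, len(n_i) + 1, dtype=float)
    nz = p_i > 0
    ngp = int(nz.sum())
    coarse = 1.0 / (p_i * s_i).sum() if (p_i * s_i).sum() > 0 else 1e6
    ii = i[nz]
    pi = p_i[nz]
    si = s_i[nz]
    dmat = (ii[:, None] - ii[None, :]) ** 2
    if ngp > 1:
        contrast = (pi[:, None] * pi[None, :] * dmat).sum() \
            / (ngp * (ngp - 1)) * (s_i.sum() / N)
        denom_busy = np.abs(ii[:, None] * pi[:, None]
                            - ii[None, :] * pi[None, :]).sum()
        busy = (pi * si).sum() / denom_busy if denom_busy > 0 else 0.0
        cplx = (np.abs(ii[:, None] - ii[None, :])
                * (pi[:, None] * si[:, None] + pi[None, :] * si[None, :])
                / (pi[:, None] + pi[None, :])).sum() / N
        strength = ((pi[:, None] + pi[None, :]) * dmat).sum() / s_i.sum() \
            if s_i.sum() > 0 else 0.0
    else:
        contrast = busy = cplx = strength = 0.0
    return {
        "Coarseness": float(coarse),
        "Contrast": float(contrast),
        "Busyness": float(busy),
        "Complexity": float(cplx),
        "Strength": float(strength),
    }


# --------------------------------------------------------------------------
# shape (mask only; bin- and intensity-independent)

def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 10:
        try:
            points = points[ConvexHull(points).vertices]
        except Exception:  # degenerate (coplanar/collinear) point sets
            pass
    return float(pdist(points).max())


def shape_features(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> dict:
    """12 shape descriptors of a 3D binary mask (1 mm^3 voxels by default)."""
    from skimage.measure import marching_cubes, mesh_surface_area

    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    nvox = int(mask.sum())
    vox_vol = float(np.prod(spacing))
    voxel_volume = nvox * vox_vol
    padded = np.pad(mask.astype(float), 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=spacing)
    surface = float(mesh_surface_area(verts, faces))
    # mesh volume via divergence theorem over the closed surface
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    mesh_vol = float(abs(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0))
    coords = np.argwhere(mask) * np.asarray(spacing)
    max3d = _max_pairwise(coords)
    # maximum in-slice diameter over the first axis
    max2d = 0.0
    for z in np.unique(np.argwhere(mask)[:, 0]):
        pts = np.argwhere(mask[z]) * np.asarray(spacing[1:])
        max2d = max(max2d, _max_pairwise(pts))
    centred = coords - coords.mean(axis=0)
    if len(coords) > 1:
        ev = np.sort(np.linalg.eigvalsh(np.cov(centred.T)))[::-1]
        ev = np.clip(ev, 0, None)
    else:
        ev = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(ev)).tolist()
    sphericity = (36 * np.pi * voxel_volume**2) ** (1 / 3) / surface
    return {
        "MeshVolume": mesh_vol,
        "VoxelVolume": voxel_volume,
        "SurfaceArea": surface,
        "SurfaceVolumeRatio": surface / voxel_volume,
        "Sphericity": float(sphericity),
        "Maximum3DDiameter": max3d,
        "Maximum2DDiameterSlice": max2d,
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": float(np.sqrt(ev[1] / ev[0])) if ev[0] > 0 else 0.0,
        "Flatness": float(np.sqrt(ev[2] / ev[0])) if ev[0] > 0 else 0.0,
    }


# --------------------------------------------------------------------------
# per-image-set extraction

def _texture_and_firstorder(volume, mask, bin_count) -> dict:
    vals = np.asarray(volume, float)[mask]
    levels = discretise(volume, mask, bin_count)
    out = {}
    for name, val in _firstorder(vals, levels[mask], bin_count).items():
        out[("firstorder", name)] = val
    glcm_acc: dict[str, float] = {}
    rlm_acc: dict[str, float] = {}
    nvox = int(mask.sum())
    for off in DIRECTIONS_3D:
        for name, val in _glcm_features(glcm_matrix(levels, mask, off, bin_count)).items():
            glcm_acc[name] = glcm_acc.get(name, 0.0) + val
        for name, val in _rlm_features(
                glrlm_matrix(levels, mask, off, bin_count), nvox).items():
            rlm_acc[name] = rlm_acc.get(name, 0.0) + val
    nd = len(DIRECTIONS_3D)
    for name, val in glcm_acc.items():
        out[("glcm", name)] = val / nd
    for name, val in rlm_acc.items():
        out[("glrlm", name)] = val / nd
    for name, val in _szm_features(glszm_matrix(levels, mask, bin_count), nvox).items():
        out[("glszm", name)] = val
    for name, val in _gldm_features(gldm_matrix(levels, mask, bin_count)).items():
        out[("gldm", name)] = val
    for name, val in _ngtdm_features(*ngtdm_table(levels, mask, bin_count)).items():
        out[("ngtdm", name)] = val
    return out


def extract_features(volumes: dict, wtv_mask: np.ndarray, bin_count: int,
                     spacing=(1.0, 1.0, 1.0)) -> pd.Series:
    """Extract the full 384-feature vector for one patient.

    ``volumes`` maps sequence name (T1W, T2W, FLAIR, T1CE) to a 3D array on
    a common grid; intensity/texture features are computed per sequence from
    the whole-tumour mask, shape features from the mask alone (attributed to
    the contrast-enhanced T1 sequence).
    """
    wtv_mask = np.asarray(wtv_mask, bool)
    if not wtv_mask.any():
        raise ValueError("empty whole-tumour mask")
    missing = [s for s in SEQUENCES if s not in volumes]
    if missing:
        raise ValueError(f"missing sequences: {missing}")
    out = {}
    for seq in SEQUENCES:
        vol = np.asarray(volumes[seq], float)
        if vol.shape != wtv_mask.shape:
            raise ValueError("mask outside volume grid (shape mismatch)")
        for (family, name), val in _texture_and_firstorder(
                vol, wtv_mask, bin_count).items():
            out[f"{seq}_{family}_{name}_bin{bin_count}"] = val
    for name, val in shape_features(wtv_mask, spacing).items():
        out[f"{SHAPE_SEQUENCE}_shape_{name}"] = val
    s = pd.Series(out)
    assert len(s) == N_FEATURES_TOTAL
    return s


def extract_cohort(volume_sets, bin_count: int) -> FeatureTable:
    """Extract features for a list of VolumeSet objects into a FeatureTable."""
    rows = {}
    for vs in volume_sets:
        rows[vs.patient_id] = extract_features(vs.volumes, vs.masks["wtv"], bin_count)
    df = pd.DataFrame(rows).T
    df.index.name = "patient_id"
    return FeatureTable(df)


# --------------------------------------------------------------------------
# segmentation-robustness filter and mask agreement

def icc_2_1(a: np.ndarray, b: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Computed from the classical ANOVA decomposition with n subjects and
    k = 2 raters.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n = len(a)
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    Y = np.stack([a, b], axis=1)
    k = 2
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sse = ((Y - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return np.nan
    return float((msr - mse) / denom)


def icc_filter(table_a: FeatureTable, table_b: FeatureTable,
               threshold: float = 0.8) -> list[str]:
    """Retain features whose ICC(2,1) across two independent segmentations
    is at or above ``threshold``.  Features with undefined ICC (no
    between-patient variance) are removed and reported via a warning."""
    if list(table_a.patient_ids) != list(table_b.patient_ids):
        raise ValueError("patient sets differ between segmentations")
    if list(table_a.feature_names) != list(table_b.feature_names):
        raise ValueError("feature sets differ between segmentations")
    if table_a.n_patients < 3:
        raise ValueError("ICC needs at least 3 patients")
    retained = []
    dropped_undefined = []
    A = table_a.values
    B = table_b.values
    for name in table_a.feature_names:
        icc = icc_2_1(A[name].to_numpy(), B[name].to_numpy())
        if np.isnan(icc):
            dropped_undefined.append(name)
        elif icc >= threshold:
            retained.append(name)
    if dropped_undefined:
        warnings.warn(
            f"{len(dropped_undefined)} feature(s) had undefined ICC and were removed")
    return retained


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A^B|/(|A|+|B|); 1.0 if both empty."""
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    denom = a.sum() + b.sum()
    if denom == 0:
        warnings.warn("both masks empty; Dice defined as 1.0 by convention")
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
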