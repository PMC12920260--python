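"""Grad-CAM attribution for the 3D age regressor and regional statistics.

For a regression output, Grad-CAM weights each channel of a convolutional
block's activation maps by the spatial mean of the output's gradient with
respect to that channel, sums, rectifies, upsamples trilinearly to the
input grid and (by default) normalizes each subject's map by its maximum.
Regional mean activations are then correlated with Brain-PAD, optionally
partially (residualizing both variables on age, sex and scanner), with
Benjamini-Hochberg FDR adjustment within each family of regional tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .model import BrainAgeRegressor
from .phantom import PhantomConfig, REFERENCE_GRID

REGION_NAMES = ("whole_brain", "frontal", "temporal", "parietal", "occipital",
                "limbic", "primary_motor", "primary_sensory", "cerebellar")


@dataclass
class AttributionVolume:
    """Nonnegative, per-subject-normalized attribution map on the input grid."""

    data: np.ndarray
    subject_id: str = ""
    target_block: int = -1

    def __post_init__(self) -> None:
        if np.any(self.data < 0) or not np.all(np.isfinite(self.data)):
            raise ValueError("attribution map must be nonnegative and finite")


@dataclass
class RegionSet:
    """Named boolean masks on the model-input grid; whole_brain covers all."""

    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        wb = self.masks.get("whole_brain")
        if wb is None:
            raise ValueError("RegionSet requires a whole_brain mask")
        for name, m in self.masks.items():
            if m.dtype != bool:
                raise ValueError(f"mask {name!r} must be boolean")
            if not m.any():
                raise ValueError(f"mask {name!r} is empty")
            if name != "whole_brain" and np.any(m & ~wb):
                raise ValueError(f"mask {name!r} extends outside whole_brain")


def gradcam(model: BrainAgeRegressor, vol: np.ndarray, sex=None, scanner=None,
            target_block: int | None = None,
            normalize: str = "max") -> AttributionVolume:
    """Gradient-weighted class-activation map for one preprocessed volume.

    ``target_block`` is 1-based (the reference model uses its fourth of
    five blocks); ``None`` selects the penultimate block. ``normalize``
    is one of ``max`` (per-subject maximum, the default), ``sum``
    (sum-to-one) or ``none``.
    """
    if not hasattr(model, "model_"):
        raise ValueError("model is not fitted")
    net = model.model_
    n_blocks = len(net.blocks)
    if target_block is None:
        target_block = n_blocks - 1  # penultimate, 1-based
    if not (1 <= target_block <= n_blocks):
        raise ValueError(
            f"target_block {target_block} out of range 1..{n_blocks}")
    block0 = target_block - 1

    x = np.asarray(vol, dtype=np.float32)[None]
    sex_idx, sc_idx = model._encode(
        [sex] if sex is not None else None,
        [scanner] if scanner is not None else None, 1)
    net.forward(x, sex_idx, sc_idx, train=False, keep_activations=True)
    acts = net.block_activations[block0][0]  # (C, d, d, d)
    grad = net.backward(np.ones(1, dtype=np.float32), tap_block=block0)[0]
    for p in net.params():  # discard bookkeeping from the tap backward
        p.grad[...] = 0.0

    weights = grad.mean(axis=(1, 2, 3))
    cam = np.maximum((weights[:, None, None, None] * acts).sum(axis=0), 0.0)

    edge = x.shape[1]
    src = cam.shape[0]
    if src != edge:
        coords = np.linspace(0.0, src - 1.0, edge)
        grid = np.meshgrid(coords, coords, coords, indexing="ij")
        cam = ndimage.map_coordinates(cam, np.stack(grid), order=1,
                                      mode="nearest")
    if normalize == "max":
        peak = cam.max()
        if peak > 0:
            cam = cam / peak
    elif normalize == "sum":
        total = cam.sum()
        if total > 0:
            cam = cam / total
    elif normalize != "none":
        raise ValueError(f"unknown normalization {normalize!r}")
    return AttributionVolume(data=cam.astype(np.float32),
                             target_block=target_block)


def phantom_region_set(cfg: PhantomConfig, grid: int) -> RegionSet:
    """Geometric stand-in parcellation for the phantom head.

    Anatomical atlases do not apply to the synthetic head, so "lobes" are
    angular sectors of the shell (frontal anterior, occipital posterior,
    parietal superior, temporal lateral, motor/sensory narrow superior
    bands, cerebellar posterior-inferior) and "limbic" is the peri-
    ventricular band. Masks are built at the model-input grid from the
    reference (mid-age, sex-neutral) geometry.
    """
    scale_ref = grid / REFERENCE_GRID
    mid_age = 0.5 * (cfg.age_range[0] + cfg.age_range[1])
    decades = (mid_age - cfg.age_range[0]) / 10.0
    outer = cfg.outer_radius_frac * grid
    thickness = (cfg.shell_thickness0 - cfg.shell_thinning_rate * decades) * scale_ref
    ventricle = (cfg.ventricle_radius0 + cfg.ventricle_growth_rate * decades) * scale_ref

    c = (grid - 1) / 2.0
    ax = np.arange(grid) - c
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(X ** 2 + Y ** 2 + Z ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        ux, uy, uz = X / r, Y / r, Z / r
    ux[r == 0] = uy[r == 0] = uz[r == 0] = 0.0

    whole = r <= outer
    shell = whole & (r >= outer - 2.0 * thickness)
    masks = {
        "whole_brain": whole,
        "frontal": shell & (uy > 0.45),
        "occipital": shell & (uy < -0.45) & (uz > -0.2),
        "parietal": shell & (uz > 0.55) & (np.abs(uy) <= 0.45),
        "temporal": shell & (np.abs(ux) > 0.55) & (uz < 0.3),
        "limbic": whole & (r >= ventricle) & (r <= ventricle + 0.25 * outer),
        "primary_motor": shell & (uz > 0.35) & (uy > 0.05) & (uy <= 0.45),
        "primary_sensory": shell & (uz > 0.35) & (uy < -0.05) & (uy >= -0.45),
        "cerebellar": shell & (uz < -0.45) & (uy < -0.2),
    }
    return RegionSet(masks=masks)


def regional_means(attr: AttributionVolume, regions: RegionSet) -> dict[str, float]:
    """Arithmetic mean attribution inside each region mask."""
    out = {}
    for name, mask in regions.masks.items():
        if mask.shape != attr.data.shape:
            raise ValueError(
                f"mask {name!r} shape {mask.shape} != map {attr.data.shape}")
        out[name] = float(attr.data[mask].mean())
    return out


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ beta


def _pearson_t_p(r: float, n: int, k: int = 0) -> float:
    df = n - 2 - k
    if df <= 0 or abs(r) >= 1:
        return np.nan
    t = r * np.sqrt(df / (1.0 - r ** 2))
    return float(2 * stats.t.sf(abs(t), df))


def activation_pad_correlation(regional: pd.DataFrame, pads,
                               covariates: pd.DataFrame | None = None,
                               regions=None) -> pd.DataFrame:
    """Pearson (or partial) correlation of regional activation with Brain-PAD.

    ``regional`` has one column per region; ``covariates`` (optional)
    holds age (numeric) and/or sex/scanner (categorical, dummy-coded
    internally). Partial correlations are Pearson correlations of the
    residuals of both variables after linear adjustment. FDR adjustment
    (Benjamini-Hochberg) is applied across the returned family.
    """
    pads = np.asarray(pads, dtype=float)
    if regions is None:
        regions = list(regional.columns)
    n = pads.size
    partial = covariates is not None
    if partial:
        Z = [np.ones(n)]
        for col in covariates.columns:
            v = covariates[col]
            if pd.api.types.is_numeric_dtype(v):
                Z.append(np.asarray(v, dtype=float))
            else:
                Z.extend(pd.get_dummies(v, drop_first=True).to_numpy(float).T)
        Z = np.column_stack(Z)
        k = Z.shape[1] - 1
        if n < k + 4:
            raise ValueError(f"need n >= covariates + 4, got n={n}, k={k}")
        y = _residualize(pads, Z)
    else:
        if n < 4:
            raise ValueError(f"need n >= 4, got {n}")
        k = 0
        y = pads

    rows = []
    for region in regions:
        x = np.asarray(regional[region], dtype=float)
        if np.allclose(x, x[0]) or np.allclose(y, y[0]):
            rows.append({"region": region, "r": np.nan, "p": np.nan,
                         "partial": partial, "flag": "constant input"})
            continue
        if partial:
            x = _residualize(x, Z)
            r = float(stats.pearsonr(x, y)[0])
            p = _pearson_t_p(r, n, k)
        else:
            r, p = stats.pearsonr(x, y)
            r, p = float(r), float(p)
        rows.append({"region": region, "r": r, "p": p, "partial": partial,
                     "flag": ""})
    df = pd.DataFrame(rows)
    ok = df["p"].notna()
    df["p_fdr"] = np.nan
    if ok.any():
        df.loc[ok, "p_fdr"] = bh_fdr(df.loc[ok, "p"].to_numpy())
    return df


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
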