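"""Dataset-level quality metrics: SNR, angular CNR and SSE summaries.

SNR follows the background-ROI convention: per DW volume, mean tissue
signal divided by the noise SD estimated from an air region, averaged over
the shell's DW volumes,

    SNR_global = (1/NDIR) Σ_i meanSI(hippocampus, i) / σ(background, i).

Background magnitude noise is Rayleigh-distributed (no underlying signal),
so the raw background SD is converted to the Gaussian-equivalent noise
sigma by dividing by √(2 − π/2); the same estimate feeds the CNR map.

The angular CNR is defined here as the per-voxel SD of the signal across a
shell's DW volumes divided by the noise sigma — a measure of how much
direction-dependent (anisotropy-driven) contrast the shell generates above
the noise floor.  It deliberately quantifies the same notion as
eddy-QC-style CNR maps but is not numerically identical to any external
tool, so it is used for orderings, never absolute comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import DWIDataset, LABEL_CODES, GM_LAYERS

__all__ = [
    "QualityReport",
    "RAYLEIGH_SD_FACTOR",
    "estimate_noise_sigma",
    "snr_b0",
    "snr_global",
    "cnr_map",
    "cnr_voi",
    "sse_summary",
    "quality_report",
]

RAYLEIGH_SD_FACTOR = float(np.sqrt(2.0 - np.pi / 2.0))  # SD of |N+iN| with S=0, sigma=1


@dataclass(frozen=True)
class QualityReport:
    """Per-dataset quality summary (one animal, one reconstructed dataset)."""

    dataset_label: str
    snr_b0: float
    snr_global: float
    cnr_per_voi: dict[str, float] = field(default_factory=dict)
    sse_per_voi: dict[str, float] = field(default_factory=dict)


def _masks(dataset: DWIDataset) -> tuple[np.ndarray, np.ndarray]:
    tissue = np.isin(dataset.labelmap, [LABEL_CODES[n] for n in GM_LAYERS])
    background = dataset.labelmap == LABEL_CODES["background"]
    if not tissue.any():
        raise ValueError("empty hippocampal tissue mask")
    if not background.any():
        raise ValueError("empty background mask")
    return tissue, background


def estimate_noise_sigma(volumes: np.ndarray, background_mask: np.ndarray) -> np.ndarray:
    """Gaussian-equivalent noise sigma per volume from the air background."""
    bg = volumes[background_mask]  # (nbg, nvol)
    sd = bg.std(axis=0, ddof=1)
    return sd / RAYLEIGH_SD_FACTOR


def snr_b0(dataset: DWIDataset) -> float:
    """Mean hippocampal b=0 signal over the background-derived noise sigma."""
    tissue, background = _masks(dataset)
    b0 = dataset.scheme.b0_mask
    if not b0.any():
        raise ValueError("dataset has no b=0 volumes")
    sigma = estimate_noise_sigma(dataset.volumes, background)[b0]
    if np.any(sigma == 0):
        raise ValueError("zero noise floor in background")
    means = dataset.volumes[tissue][:, b0].mean(axis=0)
    return float(np.mean(means / sigma))


def snr_global(
    dataset: DWIDataset,
    tissue_mask: np.ndarray | None = None,
    background_mask: np.ndarray | None = None,
) -> float:
    """Average over DW volumes of tissue mean signal / per-volume noise sigma.

    b=0 volumes are excluded from the average (they feed :func:`snr_b0`).
    """
    if tissue_mask is None or background_mask is None:
        t, b = _masks(dataset)
        tissue_mask = t if tissue_mask is None else tissue_mask
        background_mask = b if background_mask is None else background_mask
    if not tissue_mask.any() or not background_mask.any():
        raise ValueError("empty mask")
    if np.any(tissue_mask & background_mask):
        raise ValueError("tissue and background masks overlap")
    dw = ~dataset.scheme.b0_mask
    if not dw.any():
        raise ValueError("dataset has no DW volumes")
    sigma = estimate_noise_sigma(dataset.volumes, background_mask)[dw]
    if np.any(sigma == 0):
        raise ValueError("zero noise floor in background")
    means = dataset.volumes[tissue_mask][:, dw].mean(axis=0)
    return float(np.mean(means / sigma))


def cnr_map(dataset: DWIDataset, noise_sd: float) -> np.ndarray:
    """Angular contrast map: SD across the shell's DW volumes / noise sigma."""
    dw = ~dataset.scheme.b0_mask
    if np.count_nonzero(dw) < 6:
        raise ValueError("CNR needs at least 6 DW volumes in the shell")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    return dataset.volumes[..., dw].std(axis=-1, ddof=1) / noise_sd


def cnr_voi(cmap: np.ndarray, mask: np.ndarray) -> float:
    if not mask.any():
        raise ValueError("empty VOI mask")
    return float(np.nanmean(cmap[mask]))


def sse_summary(sse_map: np.ndarray, voi_masks: dict[str, np.ndarray]) -> dict[str, float]:
    """Voxel-mean fit residue per VOI."""
    out = {}
    for name, mask in voi_masks.items():
        if not mask.any():
            raise ValueError(f"empty VOI mask {name!r}")
        out[name] = float(np.nanmean(sse_map[mask]))
    return out


def quality_report(
    dataset: DWIDataset, sse_map: np.ndarray | None = None, label: str | None = None
) -> QualityReport:
    """Full per-dataset QC bundle: SNRs, per-layer CNR and optional SSE."""
    tissue, background = _masks(dataset)
    sigma = float(np.mean(estimate_noise_sigma(dataset.volumes, background)))
    if sigma == 0:
        raise ValueError("zero noise floor in background")
    cmap = cnr_map(dataset, sigma)
    voi_masks = {
        name: dataset.labelmap == LABEL_CODES[name] for name in (*GM_LAYERS, "CC")
    }
    cnrs = {name: cnr_voi(cmap, m) for name, m in voi_masks.items()}
    cnrs["hippocampus"] = cnr_voi(cmap, tissue)
    sses = {}
    if sse_map is not None:
        sses = sse_summary(sse_map, {**voi_masks, "hippocampus": tissue})
    return QualityReport(
        dataset_label=label or dataset.meta.get("dataset_label", ""),
        snr_b0=snr_b0(dataset),
        snr_global=snr_global(dataset, tissue, background),
        cnr_per_voi=cnrs,
        sse_per_voi=sses,
    )
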