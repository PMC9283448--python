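"""Digital hippocampus phantom and seeded synthetic dMRI cohorts.

The phantom holds five tissue classes — three adjacent hippocampal
gray-matter bands (stratum radiatum SR, stratum lacunosum-moleculare SLM,
dentate-gyrus molecular layer ML), a corpus-callosum (CC) white-matter band
and air background — on an anisotropic voxel grid.  Each class carries an
axially-symmetric diffusion/kurtosis parameter set (D_ax, D_rad, K_ax,
K_rad, principal axis e₁) and the diffusion-weighted signal follows the
two-term cumulant decay

    S(b, g) = S0 · exp(−b̃·D(g) + b̃²·D(g)²·K(g)/6),   b̃ = b/1000,

with D(g) = D_rad + (D_ax−D_rad)(g·e₁)² and the same cos² interpolation for
K(g).  Diffusivities are in μm²·ms⁻¹ throughout (hence b̃ in ms·μm⁻²).

Gray-matter defaults are calibrated so that the per-layer *apparent*
directional diffusivities (ln(S0/S)/b̃, which decrease with b when K > 0)
reproduce published in vivo mouse hippocampus values at both b = 1000 and
b = 2700 s·mm⁻² shells.  An optional EAE (dendritic-loss) effect attenuates
the ML apparent diffusivities at the high shell only, so the lesion is
invisible at b = 1000 — the phenomenon the surrounding analysis pipeline is
designed to detect.

Noise is Rician: magnitude of the clean signal plus complex Gaussian noise,
with sigma set from the requested b=0 SNR.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .schemes import AcquisitionScheme, DirectionSet

__all__ = [
    "LABEL_CODES",
    "LayerParams",
    "CohortSpec",
    "DWIDataset",
    "build_label_map",
    "signal_model",
    "apparent_adc",
    "calibrate_from_two_shells",
    "default_layer_params",
    "eae_layer_params",
    "add_rician_noise",
    "simulate_cohort",
    "write_dataset",
    "read_dataset",
]

LABEL_CODES = {"background": 0, "SR": 1, "SLM": 2, "ML": 3, "CC": 4}
GM_LAYERS = ("SR", "SLM", "ML")

FREE_WATER_D = 3.2  # μm²·ms⁻¹ at 37 °C
K_MAX = 3.0


@dataclass(frozen=True)
class LayerParams:
    """Axially-symmetric tissue parameters for one phantom class."""

    name: str
    D_ax: float
    D_rad: float
    K_ax: float
    K_rad: float
    orientation: tuple[float, float, float] = (1.0, 0.0, 0.0)
    S0: float = 1000.0

    def __post_init__(self) -> None:
        if self.name not in LABEL_CODES:
            raise ValueError(f"unknown layer name {self.name!r}")
        if self.name == "background":
            if self.S0 != 0:
                raise ValueError("background must have S0 = 0")
            return
        if not 0 < self.D_rad <= self.D_ax <= FREE_WATER_D:
            raise ValueError(
                f"{self.name}: need 0 < D_rad <= D_ax <= {FREE_WATER_D}, "
                f"got D_ax={self.D_ax}, D_rad={self.D_rad}"
            )
        for k in (self.K_ax, self.K_rad):
            if not 0.0 <= k <= K_MAX:
                raise ValueError(f"{self.name}: kurtosis {k} outside [0, {K_MAX}]")
        n = np.linalg.norm(self.orientation)
        if abs(n - 1.0) > 1e-6:
            raise ValueError(f"{self.name}: orientation not unit-norm ({n})")


@dataclass(frozen=True)
class CohortSpec:
    """Study-design knobs for a simulated cohort.

    Defaults follow the post-QC study population (15 control, 16 EAE
    animals), 5% between-animal coefficient of variation on diffusivities
    and kurtoses, and a b=0 hippocampal SNR of 79.5.
    """

    n_control: int = 15
    n_eae: int = 16
    between_animal_cv: float = 0.05
    eae_attenuation: float = 0.033
    snr_b0: float = 79.5
    seed: int = 0
    shape: tuple[int, int, int] = (48, 48, 6)
    voxel_size: tuple[float, float, float] = (0.08, 0.08, 0.2)

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_eae < 0:
            raise ValueError("animal counts must be >= 0")
        if not (self.snr_b0 > 0 or np.isinf(self.snr_b0)):
            raise ValueError("snr_b0 must be > 0 (np.inf for noise-free)")


@dataclass
class DWIDataset:
    """One animal's 4D magnitude volumes plus scheme and label map."""

    volumes: np.ndarray  # (x, y, z, n_volumes)
    scheme: AcquisitionScheme
    labelmap: np.ndarray  # (x, y, z) int
    voxel_size: tuple[float, float, float] = (0.08, 0.08, 0.2)
    animal_id: str = ""
    group: str = "control"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.volumes.ndim != 4:
            raise ValueError(f"volumes must be 4D, got shape {self.volumes.shape}")
        if self.volumes.shape[-1] != len(self.scheme):
            raise ValueError(
                f"{self.volumes.shape[-1]} volumes but scheme has {len(self.scheme)}"
            )
        if self.labelmap.shape != self.volumes.shape[:3]:
            raise ValueError("labelmap shape must equal the spatial shape")
        if np.any(self.volumes < 0):
            raise ValueError("magnitude volumes must be non-negative")

    def subset(self, mask: np.ndarray, label: str = "") -> "DWIDataset":
        """Restrict to the volumes selected by a boolean mask over volumes."""
        return DWIDataset(
            self.volumes[..., mask],
            self.scheme.subset(mask),
            self.labelmap,
            self.voxel_size,
            self.animal_id,
            self.group,
            {**self.meta, "dataset_label": label} if label else dict(self.meta),
        )


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def build_label_map(
    shape: tuple[int, int, int] = (48, 48, 6),
    voxel_size: tuple[float, float, float] = (0.08, 0.08, 0.2),
) -> np.ndarray:
    """Integer label volume with three adjacent GM bands, a CC band and air.

    Bands run along x (their long axis) and are stacked along y, mimicking
    the laminar geometry of the dorsal hippocampus in coronal sections:
    CC above, then SR | SLM | ML in contact.  Each band spans all slices.
    """
    nx, ny, nz = shape
    if nz < 3:
        raise ValueError("need at least 3 slices")
    band = max(2, ny // 12)  # in-plane thickness per layer
    x0, x1 = max(1, nx // 8), nx - max(1, nx // 8)
    if (x1 - x0) * band * nz < 100:
        raise ValueError(f"shape {shape} too small for >=100 voxels per class")
    # vertical placement: CC separated from the GM stack by one background row
    y_cc = ny // 4
    y_sr = y_cc + band + 2
    labels = np.zeros(shape, dtype=np.int16)
    labels[x0:x1, y_cc : y_cc + band, :] = LABEL_CODES["CC"]
    labels[x0:x1, y_sr : y_sr + band, :] = LABEL_CODES["SR"]
    labels[x0:x1, y_sr + band : y_sr + 2 * band, :] = LABEL_CODES["SLM"]
    labels[x0:x1, y_sr + 2 * band : y_sr + 3 * band, :] = LABEL_CODES["ML"]
    if y_sr + 3 * band > ny:
        raise ValueError(f"shape {shape} too small to stack the layer bands")
    return labels


# ---------------------------------------------------------------------------
# Signal model and calibration
# ---------------------------------------------------------------------------


def _dir_params(params: LayerParams, g: np.ndarray) -> tuple[float, float]:
    c2 = float(np.dot(g, params.orientation)) ** 2
    D = params.D_rad + (params.D_ax - params.D_rad) * c2
    K = params.K_rad + (params.K_ax - params.K_rad) * c2
    return D, K


def signal_model(params: LayerParams, b: float, g: np.ndarray) -> float:
    """Cumulant (tensor + kurtosis) signal decay for one direction.

    With b̃ = b/1000 in ms·μm⁻²:  S = S0·exp(−b̃·D(g) + b̃²·D(g)²·K(g)/6).
    """
    if b < 0:
        raise ValueError("b must be >= 0")
    g = np.asarray(g, dtype=float)
    if abs(np.linalg.norm(g) - 1.0) > 1e-6:
        raise ValueError("g must be unit-norm")
    if b == 0:
        return params.S0
    D, K = _dir_params(params, g)
    bt = b / 1000.0
    return float(params.S0 * np.exp(-bt * D + bt**2 * D**2 * K / 6.0))


def apparent_adc(D: float, K: float, b: float) -> float:
    """Single-shell apparent diffusivity ln(S0/S)/b̃ = D − b̃·D²·K/6."""
    bt = b / 1000.0
    return D - bt * D**2 * K / 6.0


def calibrate_from_two_shells(
    adc_low: float,
    adc_high: float,
    b_low: float = 1000.0,
    b_high: float = 2700.0,
    allow_negative_k: bool = False,
) -> tuple[float, float]:
    """Invert two apparent diffusivities into intrinsic (D, K).

    Closed form from adc(b̃) = D − b̃·D²·K/6:
    D²K = 6(adc_low − adc_high)/(b̃_high − b̃_low);  D = adc_low + b̃_low·D²K/6;
    K = D²K/D².  K outside [0, 3] triggers a warning (values are returned
    unclipped).
    """
    if adc_high <= 0:
        raise ValueError("apparent diffusivities must be > 0")
    if b_high <= b_low:
        raise ValueError("b_high must exceed b_low")
    if adc_low < adc_high and not allow_negative_k:
        raise ValueError(
            f"adc_low ({adc_low}) < adc_high ({adc_high}) implies K < 0; "
            "pass allow_negative_k=True to force"
        )
    btl, bth = b_low / 1000.0, b_high / 1000.0
    d2k = 6.0 * (adc_low - adc_high) / (bth - btl)
    D = adc_low + btl * d2k / 6.0
    K = d2k / D**2
    if not 0.0 <= K <= K_MAX:
        warnings.warn(f"calibrated K = {K:.3f} outside [0, {K_MAX}]", stacklevel=2)
    return float(D), float(K)


# Published per-layer apparent directional diffusivities (μm²·ms⁻¹):
# (axial @ b=1000, axial @ b=2700, radial @ b=1000, radial @ b=2700),
# from the healthy-cohort 22-direction b=1000 and 43-direction b=2700 fits.
_GM_APPARENT = {
    "SR": (0.662, 0.530, 0.517, 0.432),
    "SLM": (0.683, 0.519, 0.518, 0.423),
    "ML": (0.676, 0.542, 0.466, 0.383),
}


def default_layer_params(s0: float = 1000.0) -> dict[str, LayerParams]:
    """Calibrated healthy-tissue parameter set for all five classes.

    GM layers are solved from the two-shell apparent axial/radial pairs;
    CC uses plausible rodent white-matter values (not calibrated to any
    printed table) chosen for high anisotropy and kurtosis.
    """
    out: dict[str, LayerParams] = {}
    for name, (ad_lo, ad_hi, rd_lo, rd_hi) in _GM_APPARENT.items():
        D_ax, K_ax = calibrate_from_two_shells(ad_lo, ad_hi)
        D_rad, K_rad = calibrate_from_two_shells(rd_lo, rd_hi)
        out[name] = LayerParams(name, D_ax, D_rad, K_ax, K_rad, S0=s0)
    out["CC"] = LayerParams("CC", 1.2, 0.35, 0.8, 1.8, S0=s0)
    out["background"] = LayerParams("background", 1.0, 1.0, 0.0, 0.0, S0=0.0)
    return out


def eae_layer_params(
    base: dict[str, LayerParams], attenuation: float = 0.033
) -> dict[str, LayerParams]:
    """EAE (dendritic-loss) variant: ML high-shell apparent ADCs shrink.

    The ML apparent axial and radial diffusivities at b = 2700 are both
    scaled by (1 − attenuation) while the b = 1000 apparent values are held
    fixed; (D, K) are re-solved from the shifted two-shell pairs.  Scaling
    both eigen-ADCs by the same factor leaves the apparent FA unchanged, so
    the lesion is visible to MD/AD/RD at the high shell only — not to FA and
    not to any b = 1000 metric.
    """
    ad_lo, ad_hi, rd_lo, rd_hi = _GM_APPARENT["ML"]
    ad_hi *= 1.0 - attenuation
    rd_hi *= 1.0 - attenuation
    D_ax, K_ax = calibrate_from_two_shells(ad_lo, ad_hi)
    D_rad, K_rad = calibrate_from_two_shells(rd_lo, rd_hi)
    ml = base["ML"]
    out = dict(base)
    out["ML"] = dataclasses.replace(ml, D_ax=D_ax, D_rad=D_rad, K_ax=K_ax, K_rad=K_rad)
    return out


# ---------------------------------------------------------------------------
# Noise
# ---------------------------------------------------------------------------


def add_rician_noise(
    clean_volumes: np.ndarray, sigma: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Magnitude of the clean signal plus complex Gaussian noise.

    Each voxel becomes sqrt((S + n₁)² + n₂²) with n₁, n₂ ~ N(0, sigma²)
    independent — the noise model of magnitude MR images.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, clean_volumes.shape)
    n2 = rng.normal(0.0, sigma, clean_volumes.shape)
    return np.sqrt((clean_volumes + n1) ** 2 + n2**2)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def _clean_volumes(
    labelmap: np.ndarray, scheme: AcquisitionScheme, params: dict[str, LayerParams]
) -> np.ndarray:
    """Noise-free 4D signal for one animal (piecewise-constant per class)."""
    nvol = len(scheme)
    out = np.zeros(labelmap.shape + (nvol,), dtype=float)
    for name, code in LABEL_CODES.items():
        if name == "background":
            continue
        mask = labelmap == code
        if not mask.any():
            continue
        p = params[name]
        sig = np.empty(nvol)
        for i, (b, g) in enumerate(zip(scheme.bvals, scheme.bvecs)):
            sig[i] = p.S0 if b == 0 else signal_model(p, b, g)
        out[mask, :] = sig
    return out


def _perturb(
    p: LayerParams, rng: np.random.Generator, cv: float, shared: float = 1.0
) -> LayerParams:
    """Multiplicative Gaussian between-animal variation on D's and K's.

    ``shared`` is an animal-level scale factor (drawn once per animal) that
    multiplies every parameter of every layer — a global physiological
    component; the per-parameter factors drawn here add independent jitter.
    The split is 0.8·cv shared / 0.6·cv independent so the total
    multiplicative sd stays cv.
    """
    if cv == 0:
        return p
    f = shared * rng.normal(1.0, 0.6 * cv, size=4)
    D_ax = p.D_ax * f[0]
    D_rad = min(p.D_rad * f[1], D_ax)  # preserve D_rad <= D_ax
    K_ax = float(np.clip(p.K_ax * f[2], 0.0, K_MAX))
    K_rad = float(np.clip(p.K_rad * f[3], 0.0, K_MAX))
    return dataclasses.replace(p, D_ax=D_ax, D_rad=D_rad, K_ax=K_ax, K_rad=K_rad)


def simulate_cohort(
    spec: CohortSpec,
    schemes: list[DirectionSet] | None = None,
    base_params: dict[str, LayerParams] | None = None,
    n_b0_per_shell: int = 2,
) -> tuple[list[DWIDataset], pd.DataFrame]:
    """Simulate a seeded control + EAE cohort over the digital phantom.

    ``schemes`` must contain the b=1000 and b=2700 shells (defaults: the
    jointly-optimised 22- and 43-direction electrostatic pair).  Both shells
    of one animal are generated from the same ground-truth parameters.
    Returns the datasets and a tidy ground-truth table (one row per animal ×
    layer, with intrinsic and apparent parameter values).
    """
    from .schemes import generate_multishell_set

    if schemes is None:
        schemes = list(generate_multishell_set(22, 43, seed=spec.seed))
    bvals = sorted({s.bvalue for s in schemes})
    if len(bvals) < 2:
        raise ValueError("simulate_cohort needs both shells (b=1000 and b=2700)")
    scheme = AcquisitionScheme.from_shells(schemes, n_b0_per_shell=n_b0_per_shell)
    labelmap = build_label_map(spec.shape, spec.voxel_size)

    base = base_params if base_params is not None else default_layer_params()
    eae_base = eae_layer_params(base, spec.eae_attenuation)

    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_control + spec.n_eae)

    tissue_s0 = np.mean([base[n].S0 for n in GM_LAYERS])
    sigma = None if np.isinf(spec.snr_b0) else tissue_s0 / spec.snr_b0

    datasets: list[DWIDataset] = []
    truth_rows: list[dict] = []
    groups = ["control"] * spec.n_control + ["EAE"] * spec.n_eae
    for idx, (group, child) in enumerate(zip(groups, children)):
        rng = np.random.default_rng(child)
        animal_id = f"{'ctl' if group == 'control' else 'eae'}{idx:02d}"
        template = base if group == "control" else eae_base
        shared = rng.normal(1.0, 0.8 * spec.between_animal_cv) if spec.between_animal_cv else 1.0
        params = {
            name: (
                _perturb(p, rng, spec.between_animal_cv, shared)
                if name != "background"
                else p
            )
            for name, p in template.items()
        }
        clean = _clean_volumes(labelmap, scheme, params)
        vols = clean if sigma is None else add_rician_noise(clean, sigma, rng)
        datasets.append(
            DWIDataset(
                vols,
                scheme,
                labelmap,
                spec.voxel_size,
                animal_id,
                group,
                meta={"seed": spec.seed, "sigma": sigma},
            )
        )
        for name in (*GM_LAYERS, "CC"):
            p = params[name]
            row = {
                "animal_id": animal_id,
                "group": group,
                "layer": name,
                "D_ax": p.D_ax,
                "D_rad": p.D_rad,
                "K_ax": p.K_ax,
                "K_rad": p.K_rad,
            }
            for b in bvals:
                row[f"adc_ax_b{b:.0f}"] = apparent_adc(p.D_ax, p.K_ax, b)
                row[f"adc_rad_b{b:.0f}"] = apparent_adc(p.D_rad, p.K_rad, b)
            truth_rows.append(row)
    return datasets, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Dataset I/O (NIfTI-1 + FSL bval/bvec + JSON sidecar)
# ---------------------------------------------------------------------------


def write_dataset(dataset: DWIDataset, directory: str | Path) -> None:
    """Persist one animal: dwi.nii.gz, labels.nii.gz, bval/bvec, sidecar.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*dataset.voxel_size, 1.0])
    nib.save(nib.Nifti1Image(dataset.volumes.astype(np.float64), affine), directory / "dwi.nii.gz")
    nib.save(
        nib.Nifti1Image(dataset.labelmap.astype(np.int16), affine), directory / "labels.nii.gz"
    )
    np.savetxt(directory / "dwi.bvec", dataset.scheme.bvecs.T, fmt="%.17g")
    np.savetxt(directory / "dwi.bval", dataset.scheme.bvals[None, :], fmt="%.17g")
    sidecar = {
        "animal_id": dataset.animal_id,
        "group": dataset.group,
        "voxel_size": list(dataset.voxel_size),
        **{k: v for k, v in dataset.meta.items() if _json_ok(v)},
    }
    (directory / "sidecar.json").write_text(json.dumps(sidecar, indent=2))


def _json_ok(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def read_dataset(directory: str | Path) -> DWIDataset:
    directory = Path(directory)
    bvec_path = directory / "dwi.bvec"
    if not bvec_path.exists():
        raise FileNotFoundError(f"missing bvec file: {bvec_path}")
    img = nib.load(directory / "dwi.nii.gz")
    labels = nib.load(directory / "labels.nii.gz")
    bvec = np.loadtxt(bvec_path, ndmin=2)
    bval = np.loadtxt(directory / "dwi.bval", ndmin=2).ravel()
    sidecar = json.loads((directory / "sidecar.json").read_text())
    voxel_size = tuple(sidecar.get("voxel_size", (0.08, 0.08, 0.2)))
    meta = {
        k: v for k, v in sidecar.items() if k not in {"animal_id", "group", "voxel_size"}
    }
    return DWIDataset(
        np.asarray(img.dataobj, dtype=float),
        AcquisitionScheme(bval, bvec.T),
        np.asarray(labels.dataobj).astype(np.int16),
        voxel_size,
        sidecar.get("animal_id", ""),
        sidecar.get("group", "control"),
        meta,
    )
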