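"""Voxel-wise diffusion tensor (DTI) and diffusion kurtosis (DKI) models.

Organised like statsmodels: a model object is built from data
(:class:`DiffusionTensorModel`, :class:`DiffusionKurtosisModel`, both with a
``from_dataset`` constructor) and ``fit()`` returns a results object
(:class:`DTIResults` / :class:`DKIResults`) carrying parameter maps, derived
metric maps, the fit residue and QC counters, with ``summary()`` and
``voi_means()`` accessors.

Both models are log-linear: for volume v with weighting b and direction g,

    ln S_v = ln S0 − b̃ gᵀDg                       (DTI)
    ln S_v = ln S0 − b̃ gᵀDg + (b̃²/6)·V(g)        (DKI)

with b̃ = b/1000 (ms·μm⁻²), D the diffusion tensor in μm²·ms⁻¹ and
V(g) = MD²·W(g) the kurtosis term (W the dimensionless kurtosis tensor).
Estimation is ordinary least squares on ln S followed by one (configurable)
re-weighting pass with weights equal to the squared predicted signals — the
standard WLS scheme for log-linearised diffusion models.  The DKI fit
additionally enforces 0 ≤ apparent kurtosis ≤ 3 along the measured
directions and the tensor eigen-axes, via constrained optimisation on the
voxels where the unconstrained solution violates the bounds.

The fit residue (SSE) is the per-voxel sum of squared residuals in
ln-signal space.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .phantom import DWIDataset, LABEL_CODES
from .schemes import AcquisitionScheme

__all__ = [
    "DiffusionTensorModel",
    "DTIResults",
    "DiffusionKurtosisModel",
    "DKIResults",
    "dti_design_matrix",
    "dki_design_matrix",
    "fit_dti",
    "fit_dki",
    "fa_from_eigenvalues",
    "metric_maps",
    "dki_signal",
]

_LN_FLOOR = np.finfo(float).tiny


def dti_design_matrix(scheme: AcquisitionScheme) -> np.ndarray:
    """(n_volumes × 7) design for the log-linear tensor model.

    Columns: −b̃gx², −b̃gy², −b̃gz², −2b̃gxgy, −2b̃gxgz, −2b̃gygz, 1 — the
    regression of ln S on the six unique tensor components and ln S0.
    """
    bt = scheme.bvals / 1000.0
    g = scheme.bvecs
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    X = np.column_stack(
        [
            -bt * gx**2,
            -bt * gy**2,
            -bt * gz**2,
            -2 * bt * gx * gy,
            -2 * bt * gx * gz,
            -2 * bt * gy * gz,
            np.ones_like(bt),
        ]
    )
    return X


# 15 unique kurtosis-tensor components: (indices, multiplicity)
_W_INDEX: list[tuple[tuple[int, int, int, int], int]] = []
for comb in itertools.combinations_with_replacement(range(3), 4):
    perms = set(itertools.permutations(comb))
    _W_INDEX.append((comb, len(perms)))
# order is deterministic: xxxx, xxxy, xxxz, xxyy, xxyz, xxzz, xyyy, xyyz, ...


def _w_monomials(g: np.ndarray) -> np.ndarray:
    """(n, 15) array of multiplicity-weighted quartic direction monomials."""
    cols = []
    for (i, j, k, l), mult in _W_INDEX:
        cols.append(mult * g[:, i] * g[:, j] * g[:, k] * g[:, l])
    return np.column_stack(cols)


def dki_design_matrix(scheme: AcquisitionScheme) -> np.ndarray:
    """(n_volumes × 22) design: 6 tensor + 15 kurtosis (V = MD²W) + ln S0."""
    bt = scheme.bvals / 1000.0
    Xd = dti_design_matrix(scheme)
    Xw = (bt**2 / 6.0)[:, None] * _w_monomials(scheme.bvecs)
    return np.column_stack([Xd[:, :6], Xw, Xd[:, 6]])


def fa_from_eigenvalues(l1, l2, l3):
    """Fractional anisotropy √(3/2)·√(Σ(λᵢ−λ̄)² / Σλᵢ²); 0 for zero tensors."""
    l1, l2, l3 = np.broadcast_arrays(*(np.asarray(x, dtype=float) for x in (l1, l2, l3)))
    lam = np.stack([l1, l2, l3], axis=-1)
    mean = lam.mean(axis=-1, keepdims=True)
    num = ((lam - mean) ** 2).sum(axis=-1)
    den = (lam**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    fa = np.where(den > 0, fa, 0.0)
    return float(fa) if fa.ndim == 0 else fa


def _tensor_from_components(d6: np.ndarray) -> np.ndarray:
    """(..., 6) [Dxx,Dyy,Dzz,Dxy,Dxz,Dyz] -> (..., 3, 3) symmetric tensors."""
    T = np.empty(d6.shape[:-1] + (3, 3))
    T[..., 0, 0] = d6[..., 0]
    T[..., 1, 1] = d6[..., 1]
    T[..., 2, 2] = d6[..., 2]
    T[..., 0, 1] = T[..., 1, 0] = d6[..., 3]
    T[..., 0, 2] = T[..., 2, 0] = d6[..., 4]
    T[..., 1, 2] = T[..., 2, 1] = d6[..., 5]
    return T


def _batched_wls(X: np.ndarray, Y: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Solve per-row weighted least squares: Y (n, v), W (n, v), X (v, p)."""
    A = np.einsum("vi,nv,vj->nij", X, W, X, optimize=True)
    rhs = np.einsum("vi,nv,nv->ni", X, W, Y, optimize=True)
    return np.linalg.solve(A, rhs[..., None])[..., 0]


def _log_signals(vols2d: np.ndarray) -> tuple[np.ndarray, int]:
    floored = int(np.count_nonzero(vols2d <= 0))
    return np.log(np.maximum(vols2d, _LN_FLOOR)), floored


@dataclass
class _ResultsBase:
    spatial_shape: tuple[int, ...]
    mask: np.ndarray  # (nvox_total,) bool over the flattened grid

    def _to_map(self, flat_vals: np.ndarray) -> np.ndarray:
        """Scatter per-fitted-voxel values back onto the grid (NaN elsewhere)."""
        extra = flat_vals.shape[1:]
        out = np.full((self.mask.size,) + extra, np.nan)
        out[self.mask] = flat_vals
        return out.reshape(self.spatial_shape + extra)


@dataclass
class DTIResults(_ResultsBase):
    """Per-voxel tensor estimates and derived metric maps.

    All diffusivities in μm²·ms⁻¹.  Invariants: MD = (λ1+λ2+λ3)/3 = (AD+2RD)/3,
    eigenvalues sorted descending, eigenvectors unit and mutually orthogonal.
    Negative eigenvalues are kept (not clamped); their per-fit fraction is
    reported in ``qc``.
    """

    s0: np.ndarray = None
    tensor: np.ndarray = None  # flat (n, 6)
    evals: np.ndarray = None  # flat (n, 3) descending
    evecs: np.ndarray = None  # flat (n, 3, 3), columns are V1,V2,V3
    fa: np.ndarray = None
    md: np.ndarray = None
    ad: np.ndarray = None
    rd: np.ndarray = None
    sse: np.ndarray = None
    qc: dict = field(default_factory=dict)

    _metric_names = ("FA", "MD", "AD", "RD", "SSE", "S0")

    def metric_maps(self) -> dict[str, np.ndarray]:
        return {
            "FA": self._to_map(self.fa),
            "MD": self._to_map(self.md),
            "AD": self._to_map(self.ad),
            "RD": self._to_map(self.rd),
            "SSE": self._to_map(self.sse),
            "S0": self._to_map(self.s0),
        }

    def voi_means(self, labelmap: np.ndarray, labels: dict[str, int] | None = None):
        from .analysis import voi_means_from_maps

        return voi_means_from_maps(self.metric_maps(), labelmap, labels)

    def summary(self) -> str:
        lines = [
            "Diffusion tensor fit (log-linear WLS)",
            f"  fitted voxels : {int(self.mask.sum())} / {self.mask.size}",
            f"  floored sigs  : {self.qc.get('floored_signals', 0)}",
            f"  neg-eig frac  : {self.qc.get('negative_eigenvalue_fraction', 0.0):.4f}",
            "  metric   mean     sd",
        ]
        for name, arr in (("FA", self.fa), ("MD", self.md), ("AD", self.ad), ("RD", self.rd), ("SSE", self.sse)):
            lines.append(f"  {name:<6} {np.nanmean(arr):8.4f} {np.nanstd(arr):8.4f}")
        return "\n".join(lines)


class DiffusionTensorModel:
    """Log-linear DTI model for one 4D dataset.

    Parameters
    ----------
    volumes : 4D magnitude array (x, y, z, n_volumes)
    scheme : per-volume b-values and directions (needs >= 7 volumes with at
        least one b=0)
    mask : optional boolean 3D array restricting the fit
    wls_iterations : number of predicted-signal re-weighting passes after the
        initial OLS (default 1; 0 gives plain OLS)
    """

    def __init__(
        self,
        volumes: np.ndarray,
        scheme: AcquisitionScheme,
        mask: np.ndarray | None = None,
        wls_iterations: int = 1,
    ):
        volumes = np.asarray(volumes, dtype=float)
        if volumes.ndim != 4:
            raise ValueError("volumes must be 4D")
        if len(scheme) != volumes.shape[-1]:
            raise ValueError("scheme length must equal number of volumes")
        if len(scheme) < 7:
            raise ValueError("DTI needs at least 7 volumes")
        if scheme.n_b0 < 1:
            raise ValueError("DTI needs at least one b=0 volume")
        self.volumes = volumes
        self.scheme = scheme
        self.spatial_shape = volumes.shape[:3]
        flat = volumes.reshape(-1, volumes.shape[-1])
        valid = np.any(flat > 0, axis=1)
        if mask is not None:
            valid &= np.asarray(mask, dtype=bool).ravel()
        self.mask_flat = valid
        self.wls_iterations = wls_iterations

    @classmethod
    def from_dataset(cls, dataset: DWIDataset, mask: np.ndarray | None = None, **kw):
        if mask is None:
            mask = dataset.labelmap > 0
        return cls(dataset.volumes, dataset.scheme, mask=mask, **kw)

    def fit(self) -> DTIResults:
        X = dti_design_matrix(self.scheme)
        flat = self.volumes.reshape(-1, self.volumes.shape[-1])[self.mask_flat]
        Y, floored = _log_signals(flat)
        beta = np.linalg.lstsq(X, Y.T, rcond=None)[0].T  # OLS
        for _ in range(self.wls_iterations):
            W = np.exp(2.0 * (beta @ X.T))  # squared predicted signals
            beta = _batched_wls(X, Y, W)
        resid = Y - beta @ X.T
        sse = np.einsum("nv,nv->n", resid, resid)
        tensors = _tensor_from_components(beta[:, :6])
        evals, evecs = np.linalg.eigh(tensors)
        evals = evals[:, ::-1]  # descending
        evecs = evecs[:, :, ::-1]
        md = evals.mean(axis=1)
        ad = evals[:, 0]
        rd = evals[:, 1:].mean(axis=1)
        fa = fa_from_eigenvalues(evals[:, 0], evals[:, 1], evals[:, 2])
        neg_frac = float(np.count_nonzero(evals[:, 2] < 0) / max(len(evals), 1))
        return DTIResults(
            spatial_shape=self.spatial_shape,
            mask=self.mask_flat,
            s0=np.exp(beta[:, 6]),
            tensor=beta[:, :6],
            evals=evals,
            evecs=evecs,
            fa=fa,
            md=md,
            ad=ad,
            rd=rd,
            sse=sse,
            qc={
                "floored_signals": floored,
                "negative_eigenvalue_fraction": neg_frac,
                "n_fitted": int(self.mask_flat.sum()),
            },
        )


def fit_dti(
    volumes: np.ndarray,
    scheme: AcquisitionScheme,
    mask: np.ndarray | None = None,
    wls_iterations: int = 1,
) -> DTIResults:
    """Functional wrapper over :class:`DiffusionTensorModel`."""
    return DiffusionTensorModel(volumes, scheme, mask, wls_iterations).fit()


# ---------------------------------------------------------------------------
# DKI
# ---------------------------------------------------------------------------


def _full_w_tensor(w15: np.ndarray) -> np.ndarray:
    """Expand (..., 15) unique components to full (..., 3, 3, 3, 3) tensors."""
    out = np.zeros(w15.shape[:-1] + (3, 3, 3, 3))
    for col, ((i, j, k, l), _) in enumerate(_W_INDEX):
        for p in set(itertools.permutations((i, j, k, l))):
            out[(...,) + p] = w15[..., col]
    return out


_ISO4 = np.zeros((3, 3, 3, 3))
for _i, _j, _k, _l in itertools.product(range(3), repeat=4):
    _ISO4[_i, _j, _k, _l] = (
        (_i == _j) * (_k == _l) + (_i == _k) * (_j == _l) + (_i == _l) * (_j == _k)
    ) / 3.0


def _apparent_kurtosis(d6: np.ndarray, v15: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    """K_app(g) = V(g)/D_app(g)² for rows of unit directions; (..., ndirs)."""
    mono = _w_monomials(dirs)  # (ndirs, 15)
    T = _tensor_from_components(d6)
    d_app = np.einsum("di,...ij,dj->...d", dirs, T, dirs)
    v_app = v15 @ mono.T
    with np.errstate(invalid="ignore", divide="ignore"):
        return v_app / np.maximum(d_app, 1e-12) ** 2


@dataclass
class DKIResults(_ResultsBase):
    """Constrained DKI fit: tensor pair and scalar kurtosis metrics.

    ``kt`` holds the dimensionless kurtosis tensor W (15 unique components);
    K metrics are apparent kurtoses (axial along V1, radial averaged over
    the V2–V3 plane, mean over the measured directions); MKT is the
    spherical mean of W(g); KFA its normalised anisotropy.
    """

    s0: np.ndarray = None
    tensor: np.ndarray = None  # (n, 6)
    kt: np.ndarray = None  # (n, 15) W components
    evals: np.ndarray = None
    evecs: np.ndarray = None
    fa: np.ndarray = None
    d_mean: np.ndarray = None
    d_ax: np.ndarray = None
    d_rad: np.ndarray = None
    k_ax: np.ndarray = None
    k_rad: np.ndarray = None
    k_mean: np.ndarray = None
    mkt: np.ndarray = None
    kfa: np.ndarray = None
    sse: np.ndarray = None
    qc: dict = field(default_factory=dict)

    def metric_maps(self) -> dict[str, np.ndarray]:
        return {
            "dki_FA": self._to_map(self.fa),
            "D_mean": self._to_map(self.d_mean),
            "D_ax": self._to_map(self.d_ax),
            "D_rad": self._to_map(self.d_rad),
            "K_ax": self._to_map(self.k_ax),
            "K_rad": self._to_map(self.k_rad),
            "K_mean": self._to_map(self.k_mean),
            "MKT": self._to_map(self.mkt),
            "KFA": self._to_map(self.kfa),
            "dki_SSE": self._to_map(self.sse),
        }

    def voi_means(self, labelmap: np.ndarray, labels: dict[str, int] | None = None):
        from .analysis import voi_means_from_maps

        return voi_means_from_maps(self.metric_maps(), labelmap, labels)

    def summary(self) -> str:
        lines = [
            "Diffusion kurtosis fit (constrained log-linear WLS)",
            f"  fitted voxels    : {int(self.mask.sum())} / {self.mask.size}",
            f"  constrained vox  : {self.qc.get('n_constrained', 0)}",
            "  metric   mean     sd",
        ]
        for name in ("fa", "d_mean", "d_ax", "d_rad", "k_ax", "k_rad", "k_mean", "mkt", "kfa"):
            arr = getattr(self, name)
            lines.append(f"  {name:<7} {np.nanmean(arr):8.4f} {np.nanstd(arr):8.4f}")
        return "\n".join(lines)


class DiffusionKurtosisModel:
    """Constrained log-linear DKI model; requires at least two nonzero shells.

    The apparent kurtosis is bounded to [k_min, k_max] (defaults 0 and 3)
    along every measured direction plus the three tensor eigen-axes, the
    linear-constraint construction recommended for kurtosis fitting.
    """

    def __init__(
        self,
        volumes: np.ndarray,
        scheme: AcquisitionScheme,
        mask: np.ndarray | None = None,
        k_min: float = 0.0,
        k_max: float = 3.0,
        wls_iterations: int = 1,
    ):
        volumes = np.asarray(volumes, dtype=float)
        shells = {float(b) for b in scheme.bvals if b > 0}
        if len(shells) < 2:
            raise ValueError("DKI requires >=2 shells")
        n_dw = int(np.count_nonzero(scheme.bvals > 0))
        if n_dw < 22:
            raise ValueError(f"DKI needs >= 22 DW volumes, got {n_dw}")
        if len(scheme) != volumes.shape[-1]:
            raise ValueError("scheme length must equal number of volumes")
        self.volumes = volumes
        self.scheme = scheme
        self.spatial_shape = volumes.shape[:3]
        flat = volumes.reshape(-1, volumes.shape[-1])
        valid = np.any(flat > 0, axis=1)
        if mask is not None:
            valid &= np.asarray(mask, dtype=bool).ravel()
        self.mask_flat = valid
        self.k_min = k_min
        self.k_max = k_max
        self.wls_iterations = wls_iterations

    @classmethod
    def from_dataset(cls, dataset: DWIDataset, mask: np.ndarray | None = None, **kw):
        if mask is None:
            mask = dataset.labelmap > 0
        return cls(dataset.volumes, dataset.scheme, mask=mask, **kw)

    # -- constrained solve on one voxel -----------------------------------
    def _constrain_voxel(
        self, X: np.ndarray, y: np.ndarray, w: np.ndarray, beta0: np.ndarray, dirs: np.ndarray
    ) -> np.ndarray:
        """Weighted LSQ with 0 ≤ K_app ≤ k_max and D_app ≥ 0 along ``dirs``.

        The kurtosis bounds are quadratic-over-linear in the parameters;
        SLSQP with analytic jacobians and mean-normalised weights solves the
        problem reliably at this size (22 parameters, ~3·n_dirs constraints).
        """
        gx, gy, gz = dirs[:, 0], dirs[:, 1], dirs[:, 2]
        Gd = np.zeros((len(dirs), 22))
        Gd[:, 0], Gd[:, 1], Gd[:, 2] = gx**2, gy**2, gz**2
        Gd[:, 3], Gd[:, 4], Gd[:, 5] = 2 * gx * gy, 2 * gx * gz, 2 * gy * gz
        Gv = np.zeros((len(dirs), 22))
        Gv[:, 6:21] = _w_monomials(dirs)
        wn = w / w.mean()

        def obj(b):
            r = X @ b - y
            return float(np.sum(wn * r * r))

        def grad(b):
            r = X @ b - y
            return 2.0 * (X.T @ (wn * r))

        k_min, k_max = self.k_min, self.k_max
        cons = [
            # K_app >= k_min  <=>  V(g) - k_min·D_app² >= 0
            {
                "type": "ineq",
                "fun": lambda b: Gv @ b - k_min * (Gd @ b) ** 2,
                "jac": lambda b: Gv - 2 * k_min * (Gd @ b)[:, None] * Gd,
            },
            # K_app <= k_max  <=>  k_max·D_app² - V(g) >= 0
            {
                "type": "ineq",
                "fun": lambda b: k_max * (Gd @ b) ** 2 - Gv @ b,
                "jac": lambda b: 2 * k_max * (Gd @ b)[:, None] * Gd - Gv,
            },
            # D_app >= 0
            {"type": "ineq", "fun": lambda b: Gd @ b, "jac": lambda b: Gd},
        ]
        res = minimize(
            obj, beta0, jac=grad, constraints=cons, method="SLSQP",
            options={"maxiter": 1000, "ftol": 1e-14},
        )
        return res.x if res.success or res.status == 8 else beta0

    def fit(self) -> DKIResults:
        X = dki_design_matrix(self.scheme)
        flat = self.volumes.reshape(-1, self.volumes.shape[-1])[self.mask_flat]
        Y, floored = _log_signals(flat)
        beta = np.linalg.lstsq(X, Y.T, rcond=None)[0].T
        W = np.ones_like(Y)
        for _ in range(self.wls_iterations):
            W = np.exp(2.0 * (beta @ X.T))
            beta = _batched_wls(X, Y, W)

        dw_dirs = self.scheme.bvecs[self.scheme.bvals > 0]
        # unique encoding axes (both shells may share directions)
        dirs = np.unique(np.round(dw_dirs, 12), axis=0)

        tensors = _tensor_from_components(beta[:, :6])
        evals, evecs = np.linalg.eigh(tensors)
        evals = evals[:, ::-1]
        evecs = evecs[:, :, ::-1]

        # constraint screening on measured directions + eigen-axes
        tol = 1e-9
        n_constrained = 0
        for n in range(len(beta)):
            vdirs = np.vstack([dirs, evecs[n].T])
            kapp = _apparent_kurtosis(beta[n, :6], beta[n, 6:21], vdirs)
            T = _tensor_from_components(beta[n, :6])
            dapp = np.einsum("di,ij,dj->d", vdirs, T, vdirs)
            if (
                np.any(kapp < self.k_min - 1e-6)
                or np.any(kapp > self.k_max + 1e-6)
                or np.any(dapp < -tol)
            ):
                beta[n] = self._constrain_voxel(X, Y[n], W[n], beta[n], vdirs)
                n_constrained += 1
        if n_constrained:
            tensors = _tensor_from_components(beta[:, :6])
            evals, evecs = np.linalg.eigh(tensors)
            evals = evals[:, ::-1]
            evecs = evecs[:, :, ::-1]

        resid = Y - beta @ X.T
        sse = np.einsum("nv,nv->n", resid, resid)

        md = evals.mean(axis=1)
        v15 = beta[:, 6:21]
        with np.errstate(invalid="ignore", divide="ignore"):
            w15 = v15 / np.maximum(md, 1e-12)[:, None] ** 2

        # scalar kurtosis metrics
        k_ax = np.empty(len(beta))
        k_rad = np.empty(len(beta))
        angles = np.linspace(0, np.pi, 8, endpoint=False)
        for n in range(len(beta)):
            v1, v2, v3 = evecs[n, :, 0], evecs[n, :, 1], evecs[n, :, 2]
            k_ax[n] = _apparent_kurtosis(beta[n, :6], v15[n], v1[None, :])[0]
            plane = np.array([np.cos(a) * v2 + np.sin(a) * v3 for a in angles])
            k_rad[n] = _apparent_kurtosis(beta[n, :6], v15[n], plane).mean()
        k_mean = _apparent_kurtosis(beta[:, :6], v15, dirs).mean(axis=1)

        # MKT: spherical mean of W(g) = (Wxxxx+Wyyyy+Wzzzz+2Wxxyy+2Wxxzz+2Wyyzz)/5
        idx = {comb: c for c, (comb, _) in enumerate(_W_INDEX)}
        mkt = (
            w15[:, idx[(0, 0, 0, 0)]]
            + w15[:, idx[(1, 1, 1, 1)]]
            + w15[:, idx[(2, 2, 2, 2)]]
            + 2 * w15[:, idx[(0, 0, 1, 1)]]
            + 2 * w15[:, idx[(0, 0, 2, 2)]]
            + 2 * w15[:, idx[(1, 1, 2, 2)]]
        ) / 5.0

        w_full = _full_w_tensor(w15)
        dev = w_full - mkt[:, None, None, None, None] * _ISO4
        num = np.sqrt(np.einsum("nijkl,nijkl->n", dev, dev))
        den = np.sqrt(np.einsum("nijkl,nijkl->n", w_full, w_full))
        with np.errstate(invalid="ignore", divide="ignore"):
            kfa = np.where(den > 1e-12, num / np.maximum(den, 1e-12), 0.0)
        kfa = np.clip(kfa, 0.0, 1.0)

        return DKIResults(
            spatial_shape=self.spatial_shape,
            mask=self.mask_flat,
            s0=np.exp(beta[:, 21]),
            tensor=beta[:, :6],
            kt=w15,
            evals=evals,
            evecs=evecs,
            fa=fa_from_eigenvalues(evals[:, 0], evals[:, 1], evals[:, 2]),
            d_mean=md,
            d_ax=evals[:, 0],
            d_rad=evals[:, 1:].mean(axis=1),
            k_ax=k_ax,
            k_rad=k_rad,
            k_mean=k_mean,
            mkt=mkt,
            kfa=kfa,
            sse=sse,
            qc={
                "floored_signals": floored,
                "n_constrained": n_constrained,
                "n_fitted": int(self.mask_flat.sum()),
            },
        )


def fit_dki(
    volumes: np.ndarray,
    scheme: AcquisitionScheme,
    mask: np.ndarray | None = None,
    k_min: float = 0.0,
    k_max: float = 3.0,
) -> DKIResults:
    """Functional wrapper over :class:`DiffusionKurtosisModel`."""
    return DiffusionKurtosisModel(volumes, scheme, mask, k_min, k_max).fit()


def metric_maps(fit: DTIResults | DKIResults) -> dict[str, np.ndarray]:
    """Named 3D maps aligned with the input grid (NaN outside the mask)."""
    return fit.metric_maps()


def dki_signal(
    s0: float, tensor6: np.ndarray, w15: np.ndarray, scheme: AcquisitionScheme
) -> np.ndarray:
    """Exact forward DKI signal for one voxel over a scheme.

    ``tensor6`` = [Dxx, Dyy, Dzz, Dxy, Dxz, Dyz] (μm²·ms⁻¹), ``w15`` the 15
    unique dimensionless kurtosis-tensor components in the same ordering the
    fit uses.  This is the generator counterpart of the DKI model: fitting
    its noise-free output recovers the tensors exactly.
    """
    X = dki_design_matrix(scheme)
    md = float(np.mean(tensor6[:3]))
    beta = np.concatenate([tensor6, md**2 * np.asarray(w15), [np.log(s0)]])
    return np.exp(X @ beta)
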