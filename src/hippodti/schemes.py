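"""Diffusion-encoding direction sets: generation, subsampling and angle QC.

A diffusion shell is described by a :class:`DirectionSet` (unit encoding
vectors plus one b-value).  The module provides

* the antipodally-symmetric angular metric used throughout
  (``d(u, v) = arccos|u·v|``, in degrees),
* the greedy neighbour-count subsampling procedure that derives reduced
  direction sets from an acquired shell (remove, one at a time, the vector
  with the most neighbours closer than a threshold, by default 30°),
* nearest-neighbour ("minimum") angle reports,
* electrostatic-repulsion generators for single shells and jointly
  optimised two-shell schemes, and
* FSL-dialect bval/bvec readers and writers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "DirectionSet",
    "AngleReport",
    "AcquisitionScheme",
    "angular_distance",
    "pairwise_angles",
    "neighbor_count",
    "subsample_directions",
    "min_angle_report",
    "generate_electrostatic_set",
    "generate_multishell_set",
    "read_directions",
    "write_directions",
]

_UNIT_TOL = 1e-6


def _check_unit(v: np.ndarray, name: str = "vector") -> None:
    n = float(np.linalg.norm(v))
    if abs(n - 1.0) > _UNIT_TOL:
        raise ValueError(f"{name} is not unit-norm (|{name}| = {n!r}): {np.asarray(v)!r}")


@dataclass(frozen=True)
class DirectionSet:
    """An ordered set of unit diffusion-encoding vectors sharing one b-value.

    b=0 reference volumes are *not* members; they are tracked by the
    acquisition scheme.
    """

    vectors: np.ndarray  # (N, 3)
    bvalue: float  # s·mm⁻²
    label: str = ""

    def __post_init__(self) -> None:
        vecs = np.asarray(self.vectors, dtype=float)
        if vecs.ndim != 2 or vecs.shape[1] != 3:
            raise ValueError(f"vectors must be (N, 3), got {vecs.shape}")
        object.__setattr__(self, "vectors", vecs)
        norms = np.linalg.norm(vecs, axis=1)
        bad = np.nonzero(np.abs(norms - 1.0) > _UNIT_TOL)[0]
        if bad.size:
            raise ValueError(
                f"non-unit vector(s) at index {bad.tolist()} in {self.label or 'set'}: "
                f"norms {norms[bad].tolist()}"
            )
        if self.bvalue <= 0:
            raise ValueError(f"bvalue must be > 0, got {self.bvalue}")
        # reject duplicate / antipodal duplicates
        if len(vecs) > 1:
            dots = np.abs(vecs @ vecs.T)
            np.fill_diagonal(dots, 0.0)
            if np.any(dots > 1.0 - _UNIT_TOL):
                i, j = np.unravel_index(int(np.argmax(dots)), dots.shape)
                raise ValueError(
                    f"vectors {i} and {j} are identical or antipodal within tolerance"
                )

    def __len__(self) -> int:
        return len(self.vectors)

    @property
    def ndir(self) -> int:
        return len(self.vectors)


@dataclass(frozen=True)
class AngleReport:
    """Nearest-neighbour angles (degrees) for every vector of a set."""

    per_vector_min_angle: np.ndarray
    mean_min_angle: float
    sd_min_angle: float
    label: str = ""


def angular_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Angle in degrees between two encoding axes, antipodally symmetric.

    ``d(u, v) = arccos(|u·v|)`` so that a vector and its antipode are at
    distance zero; the range is [0, 90].
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    _check_unit(u, "u")
    _check_unit(v, "v")
    c = min(1.0, abs(float(u @ v)))
    return float(np.degrees(np.arccos(c)))


def pairwise_angles(vectors: np.ndarray) -> np.ndarray:
    """(N, N) matrix of antipodally-symmetric angles in degrees (diagonal 0)."""
    vecs = np.asarray(vectors, dtype=float)
    dots = np.clip(np.abs(vecs @ vecs.T), 0.0, 1.0)
    ang = np.degrees(np.arccos(dots))
    np.fill_diagonal(ang, 0.0)
    return ang


def neighbor_count(dirset: DirectionSet, index: int, threshold: float = 30.0) -> int:
    """Number of *other* vectors strictly closer than ``threshold`` degrees."""
    n = dirset.ndir
    if not 0 <= index < n:
        raise IndexError(f"index {index} out of range for {n} vectors")
    if not 0.0 < threshold <= 90.0:
        raise ValueError(f"threshold must be in (0, 90], got {threshold}")
    ang = pairwise_angles(dirset.vectors)[index]
    mask = np.ones(n, dtype=bool)
    mask[index] = False
    return int(np.count_nonzero(ang[mask] < threshold))


def _min_angles(ang: np.ndarray) -> np.ndarray:
    a = ang.copy()
    np.fill_diagonal(a, np.inf)
    return a.min(axis=1)


def subsample_directions(
    dirset: DirectionSet, target_n: int, threshold: float = 30.0, label: str | None = None
) -> DirectionSet:
    """Greedy removal of crowded encoding vectors down to ``target_n``.

    Iteratively removes the vector with the largest number of neighbours at
    angular distance < ``threshold``; neighbour counts are recomputed after
    every removal.  Ties are broken by removing, among the most crowded
    vectors, the one with the smallest nearest-neighbour angle, then the
    lowest original index.  The survivors keep their original relative order.
    """
    n = dirset.ndir
    if not 1 <= target_n <= n:
        raise ValueError(f"target_n must be in [1, {n}], got {target_n}")
    keep = list(range(n))
    full_ang = pairwise_angles(dirset.vectors)
    while len(keep) > target_n:
        sub = full_ang[np.ix_(keep, keep)]
        counts = np.count_nonzero((sub < threshold) & (sub > 0.0), axis=1)
        # antipodal/identical duplicates are excluded at construction, so
        # sub > 0 off-diagonal except exact-0 pairs which cannot occur
        nn = _min_angles(sub)
        worst = counts.max()
        cand = np.nonzero(counts == worst)[0]
        cand = cand[nn[cand] == nn[cand].min()]
        keep.pop(int(cand[0]))
    new_label = label if label is not None else f"{dirset.label}->{target_n}Dir"
    return DirectionSet(dirset.vectors[keep], dirset.bvalue, new_label)


def min_angle_report(dirset: DirectionSet) -> AngleReport:
    """Per-vector nearest-neighbour angle with sample mean and SD (n−1)."""
    if dirset.ndir < 2:
        raise ValueError("min_angle_report requires at least 2 vectors")
    mins = _min_angles(pairwise_angles(dirset.vectors))
    return AngleReport(
        per_vector_min_angle=mins,
        mean_min_angle=float(mins.mean()),
        sd_min_angle=float(mins.std(ddof=1)),
        label=dirset.label,
    )


# ---------------------------------------------------------------------------
# Electrostatic-repulsion scheme generation
# ---------------------------------------------------------------------------


def _energy_and_grad(points: list[np.ndarray]) -> tuple[float, list[np.ndarray]]:
    """Antipodal 1/d² pair energy and its gradient for grouped point sets.

    ``points`` is a list of (n_i, 3) arrays; the energy is the sum over the
    per-group energies plus the energy of the union, each being
    Σ_{i<j} [1/|x_i−x_j|² + 1/|x_i+x_j|²].
    """

    def group_eg(x: np.ndarray) -> tuple[float, np.ndarray]:
        diff = x[:, None, :] - x[None, :, :]
        summ = x[:, None, :] + x[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        s2 = np.einsum("ijk,ijk->ij", summ, summ)
        np.fill_diagonal(d2, np.inf)
        np.fill_diagonal(s2, np.inf)
        e = 0.5 * float(np.sum(1.0 / d2) + np.sum(1.0 / s2))
        # dE/dx_i = Σ_j [-2(x_i-x_j)/d²² - 2(x_i+x_j)/s²²]
        g = -2.0 * np.einsum("ij,ijk->ik", 1.0 / d2**2, diff)
        g += -2.0 * np.einsum("ij,ijk->ik", 1.0 / s2**2, summ)
        return e, g

    sizes = [len(p) for p in points]
    total_e = 0.0
    grads = [np.zeros_like(p) for p in points]
    for i, p in enumerate(points):
        e, g = group_eg(p)
        total_e += e
        grads[i] += g
    if len(points) > 1:
        union = np.vstack(points)
        e, g = group_eg(union)
        total_e += e
        off = 0
        for i, s in enumerate(sizes):
            grads[i] += g[off : off + s]
            off += s
    return total_e, grads


class ElectrostaticConvergenceError(RuntimeError):
    """Raised when repulsion optimisation fails to converge; carries the energy."""

    def __init__(self, energy: float, max_iter: int):
        super().__init__(
            f"electrostatic repulsion did not converge after {max_iter} iterations "
            f"(last energy {energy:.6g})"
        )
        self.energy = energy


def _optimize_repulsion(
    groups: list[np.ndarray], tol_rad: float = 1e-8, max_iter: int = 50_000
) -> tuple[list[np.ndarray], float]:
    """Quasi-Newton descent then projected-gradient polish on the unit sphere.

    L-BFGS runs on unconstrained coordinates (energy evaluated on the
    normalised vectors, gradient mapped by the tangent projection); the
    polishing loop then iterates projected gradient steps until the largest
    per-iteration vector displacement drops below ``tol_rad``.
    """
    from scipy.optimize import minimize as _sp_minimize

    sizes = [len(p) for p in groups]

    def _split(y: np.ndarray) -> list[np.ndarray]:
        out, off = [], 0
        for s in sizes:
            out.append(y[off : off + 3 * s].reshape(s, 3))
            off += 3 * s
        return out

    def fun(y: np.ndarray):
        raw = _split(y)
        norms = [np.linalg.norm(r, axis=1, keepdims=True) for r in raw]
        pts = [r / n for r, n in zip(raw, norms)]
        e, grads = _energy_and_grad(pts)
        gy = []
        for r, n, p, g in zip(raw, norms, pts, grads):
            radial = np.einsum("ik,ik->i", g, p)[:, None] * p
            gy.append(((g - radial) / n).ravel())
        return e, np.concatenate(gy)

    y0 = np.concatenate([p.ravel() for p in groups])
    res = _sp_minimize(fun, y0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 20_000, "gtol": 1e-12, "ftol": 1e-16})
    pts = [p / np.linalg.norm(p, axis=1, keepdims=True) for p in _split(res.x)]
    energy, grads = _energy_and_grad(pts)
    step, step_max = 1e-4, 1e-3
    for _ in range(max_iter):
        # project gradient onto the tangent plane of each point
        tangent = []
        for p, g in zip(pts, grads):
            radial = np.einsum("ik,ik->i", g, p)[:, None] * p
            tangent.append(g - radial)
        gmax = max(float(np.abs(t).max()) for t in tangent)
        # backtracking line search on the projected step
        while True:
            new_pts = []
            for p, t in zip(pts, tangent):
                q = p - step * t
                new_pts.append(q / np.linalg.norm(q, axis=1, keepdims=True))
            new_energy, new_grads = _energy_and_grad(new_pts)
            if new_energy < energy or step < 1e-16:
                break
            step *= 0.5
        # chord length ≈ angle (rad) for small displacements; arccos of the
        # dot product cannot resolve angles below sqrt(machine eps)
        disp = max(
            float(np.linalg.norm(q - p, axis=1).max()) for p, q in zip(pts, new_pts)
        )
        pts, energy, grads = new_pts, new_energy, new_grads
        step = min(step * 1.2, step_max)
        if disp < tol_rad and gmax * step < 1e-10:
            return pts, energy
        if disp < tol_rad:
            return pts, energy
    raise ElectrostaticConvergenceError(energy, max_iter)


def generate_electrostatic_set(
    n: int,
    seed: int,
    bvalue: float = 1000.0,
    label: str | None = None,
    max_iter: int = 200_000,
) -> DirectionSet:
    """Uniform antipodally-symmetric shell via 1/d² electrostatic repulsion.

    Deterministic given ``seed``.  Converged when the largest per-iteration
    vector displacement falls below 1e-8 rad.
    """
    if n < 3:
        raise ValueError(f"n must be >= 3, got {n}")
    rng = np.random.default_rng(seed)
    start = rng.standard_normal((n, 3))
    pts, _ = _optimize_repulsion([start], max_iter=max_iter)
    return DirectionSet(pts[0], bvalue, label or f"ES{n}")


def generate_multishell_set(
    n_shell1: int,
    n_shell2: int,
    seed: int,
    bvalues: tuple[float, float] = (1000.0, 2700.0),
    labels: tuple[str, str] | None = None,
    max_iter: int = 200_000,
) -> tuple[DirectionSet, DirectionSet]:
    """Two shells jointly optimised for per-shell and combined coverage.

    The objective is the equal-weight sum of each shell's antipodal 1/d²
    energy and the energy of the pooled point set, mirroring schemes designed
    for both within-shell and whole-protocol angular uniformity.
    """
    if min(n_shell1, n_shell2) < 3:
        raise ValueError("each shell needs at least 3 directions")
    rng = np.random.default_rng(seed)
    starts = [rng.standard_normal((n_shell1, 3)), rng.standard_normal((n_shell2, 3))]
    pts, _ = _optimize_repulsion(starts, max_iter=max_iter)
    if labels is None:
        labels = (
            f"B{bvalues[0]:.0f}-{n_shell1}Dir",
            f"B{bvalues[1]:.0f}-{n_shell2}Dir",
        )
    return (
        DirectionSet(pts[0], bvalues[0], labels[0]),
        DirectionSet(pts[1], bvalues[1], labels[1]),
    )


# ---------------------------------------------------------------------------
# FSL bval / bvec I/O
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AcquisitionScheme:
    """Per-volume (b, direction) bookkeeping, including b=0 volumes.

    ``bvals`` has one entry per volume; rows of ``bvecs`` for b=0 volumes are
    zero vectors, as in the FSL dialect.
    """

    bvals: np.ndarray  # (N,)
    bvecs: np.ndarray  # (N, 3)

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.shape != (bvals.size, 3):
            raise ValueError(
                f"bvecs shape {bvecs.shape} inconsistent with {bvals.size} bvals"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def n_b0(self) -> int:
        return int(np.count_nonzero(self.b0_mask))

    def shells(self) -> list[DirectionSet]:
        """One DirectionSet per distinct nonzero b-value (order of appearance)."""
        out = []
        seen: list[float] = []
        for b in self.bvals:
            if b > 0 and b not in seen:
                seen.append(float(b))
        for b in seen:
            mask = self.bvals == b
            out.append(DirectionSet(self.bvecs[mask], b, f"B{b:.0f}-{mask.sum()}Dir"))
        return out

    def subset(self, mask: np.ndarray) -> "AcquisitionScheme":
        return AcquisitionScheme(self.bvals[mask], self.bvecs[mask])

    @staticmethod
    def from_shells(shells: list[DirectionSet], n_b0_per_shell: int = 2) -> "AcquisitionScheme":
        """Concatenate shells, each preceded by its b=0 reference volumes."""
        bvals: list[float] = []
        bvecs: list[np.ndarray] = []
        for s in shells:
            for _ in range(n_b0_per_shell):
                bvals.append(0.0)
                bvecs.append(np.zeros(3))
            bvals.extend([s.bvalue] * s.ndir)
            bvecs.extend(list(s.vectors))
        return AcquisitionScheme(np.array(bvals), np.array(bvecs))


def read_directions(bvec_path: str | Path, bval_path: str | Path) -> tuple[list[DirectionSet], int]:
    """Read FSL bvec (3×N) / bval (1×N) files.

    Returns one :class:`DirectionSet` per distinct nonzero b-value plus the
    number of b=0 columns.
    """
    bvec = np.loadtxt(bvec_path, ndmin=2)
    bval = np.loadtxt(bval_path, ndmin=2).ravel()
    if bvec.shape[0] != 3:
        raise ValueError(f"bvec file must have 3 rows, found {bvec.shape[0]}")
    if bvec.shape[1] != bval.size:
        raise ValueError(
            f"bvec has {bvec.shape[1]} columns but bval has {bval.size} entries"
        )
    scheme = AcquisitionScheme(bval, bvec.T)
    return scheme.shells(), scheme.n_b0


def write_directions(
    sets: list[DirectionSet],
    bvec_path: str | Path,
    bval_path: str | Path,
    n_b0: int = 0,
) -> None:
    """Write shells to FSL bvec/bval files, b=0 columns (zero vectors) first."""
    scheme = AcquisitionScheme.from_shells(sets, n_b0_per_shell=0)
    bvals = np.concatenate([np.zeros(n_b0), scheme.bvals])
    bvecs = np.vstack([np.zeros((n_b0, 3)), scheme.bvecs])
    np.savetxt(bvec_path, bvecs.T, fmt="%.17g")
    np.savetxt(bval_path, bvals[None, :], fmt="%.17g")
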