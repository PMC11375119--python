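"""The muscle-to-force null-space coordinate system and its reachable cone.

With 4 wrist muscles driving 2 force degrees of freedom, the kernel of the
pulling matrix H is 2-dimensional: the set of activation patterns producing
no net force.  The cursor coordinate used to visualise this null-space is

    n = R_c (N_tilde alpha - n0),       N_tilde = kappa N,

where the rows of N are an orthonormal basis of ker(H),
kappa = max(||h1||, ||h2||) scales null units to be commensurate with
newtons of force (||n_tilde|| = beta reads as "muscle effort similar to
beta N of force"), n0 is the resting offset, and R_c rotates the natural
co-contraction direction n_c onto the +X axis.

Because muscles only pull (alpha >= 0), the attainable set of null-space
coordinates is a planar cone, not the whole plane; membership is decided by
linear-program feasibility and the cone's extreme rays are exposed for
diagnostics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import null_space as _scipy_null_space
from scipy.optimize import linprog

from .preprocess import CHANNELS, EnvelopeRecording

#: Equality-constraint tolerance for cone feasibility, in scaled null units.
FEASIBILITY_TOL = 1e-7

_ORTHO_TOL = 1e-10


def nullspace_basis(H: np.ndarray) -> np.ndarray:
    """Orthonormal basis (2 rows) of the kernel of the pulling matrix.

    The SVD leaves the basis sign/rotation ambiguous; rows are canonicalised
    so that the entry of largest magnitude in each row is positive, making
    serialised models reproducible across runs.
    """
    H = np.asarray(H, dtype=float)
    if H.shape != (2, 4):
        raise ValueError(f"pulling matrix must be 2x4; got {H.shape}")
    if np.linalg.matrix_rank(H) < 2:
        raise np.linalg.LinAlgError("pulling matrix is not full row rank")
    N = _scipy_null_space(H).T  # (2, 4), orthonormal rows
    for i in range(2):
        j = int(np.argmax(np.abs(N[i])))
        if N[i, j] < 0:
            N[i] = -N[i]
    return N


def scale_basis(N: np.ndarray, H: np.ndarray) -> tuple[float, np.ndarray]:
    """Scaling kappa = max row norm of H, and the scaled basis kappa * N."""
    H = np.asarray(H, dtype=float)
    kappa = float(max(np.linalg.norm(H[0]), np.linalg.norm(H[1])))
    return kappa, kappa * np.asarray(N, dtype=float)


def estimate_offset(rest: EnvelopeRecording, N_scaled: np.ndarray,
                    window_s: float = 2.0) -> np.ndarray:
    """Rest offset n0 = N_tilde * mean resting envelope.

    Requires at least 2 s of rest recording after the filter warm-up.
    """
    usable = rest.n_samples / rest.fs - rest.warmup_s
    if usable < window_s:
        raise ValueError(f"rest recording must provide >= {window_s} s "
                         f"after warm-up; got {usable:.2f} s")
    return np.asarray(N_scaled) @ rest.mean_envelope(window_s)


def estimate_cocontraction(repetitions: Sequence[EnvelopeRecording],
                           N_scaled: np.ndarray, n0: np.ndarray,
                           window_s: float = 2.0,
                           min_norm: float = 1e-8) -> np.ndarray:
    """Mean natural co-contraction coordinate n_c over the 6 repetitions.

    Each repetition contributes the projection of its final-2-s mean
    envelope; the rest offset is subtracted from the average.
    """
    if len(repetitions) != 6:
        raise ValueError(f"expected 6 co-contraction repetitions, got {len(repetitions)}")
    N_scaled = np.asarray(N_scaled)
    coords = np.array([N_scaled @ rep.mean_envelope(window_s) for rep in repetitions])
    n_c = coords.mean(axis=0) - np.asarray(n0)
    if np.linalg.norm(n_c) < min_norm:
        raise ValueError("co-contraction coordinate is numerically zero; "
                         "rotation undefined")
    return n_c


def make_rotation(n_c: np.ndarray) -> np.ndarray:
    """Proper rotation R_c with R_c n_c = [||n_c||, 0]."""
    n_c = np.asarray(n_c, dtype=float)
    r = np.linalg.norm(n_c)
    if r == 0:
        raise ValueError("cannot orient a zero co-contraction vector")
    c, s = n_c[0] / r, n_c[1] / r
    return np.array([[c, s], [-s, c]])


@dataclass
class ReachableCone:
    """Extreme rays of the attainable null-space set, rotated frame.

    ``rays`` are unit vectors bounding {R_c N_tilde alpha : alpha >= 0};
    when the four muscle images positively span the plane the cone is the
    whole plane and ``contains_full_plane`` is set.
    """

    rays: np.ndarray                 # (k, 2), k in {1, 2}
    contains_full_plane: bool = False
    degenerate: bool = False         # all column images collinear


@dataclass
class NullspaceModel:
    """Complete null-space coordinate system for one session."""

    H: np.ndarray             # (2, 4) pulling matrix
    N: np.ndarray             # (2, 4) orthonormal kernel basis
    kappa: float              # scaling, N per envelope unit
    n0: np.ndarray            # (2,) rest offset, scaled null units
    n_c: np.ndarray           # (2,) natural co-contraction coordinate
    R_c: np.ndarray           # (2, 2) rotation aligning n_c with +X
    smvf: float | None = None

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        self.N = np.asarray(self.N, dtype=float)
        self.n0 = np.asarray(self.n0, dtype=float)
        self.n_c = np.asarray(self.n_c, dtype=float)
        self.R_c = np.asarray(self.R_c, dtype=float)
        if np.abs(self.N @ self.N.T - np.eye(2)).max() > _ORTHO_TOL:
            raise ValueError("N rows are not orthonormal")
        if np.abs(self.N @ self.H.T).max() > _ORTHO_TOL * max(1.0, np.abs(self.H).max()):
            raise ValueError("N is not orthogonal to the rows of H")

    @property
    def N_scaled(self) -> np.ndarray:
        return self.kappa * self.N

    def project(self, alpha: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Split activation into (force, rotated null coordinate).

        ``alpha`` may be a single 4-vector or an (n, 4) trajectory.
        Returns ``force = H alpha`` and ``n = R_c (N_tilde alpha - n0)``.
        """
        alpha = np.asarray(alpha, dtype=float)
        if not np.isfinite(alpha).all():
            raise ValueError("activation contains non-finite values")
        if (alpha < 0).any():
            raise ValueError("activation must be non-negative")
        force = alpha @ self.H.T
        null = (alpha @ self.N_scaled.T - self.n0) @ self.R_c.T
        return force, null

    def null_magnitude(self, alpha: np.ndarray) -> np.ndarray:
        """Offset-corrected null magnitude ||n_tilde - n0|| (cursor radius
        in the concurrent task).  Rotation preserves the norm, so this is
        also ||n||."""
        _, null = self.project(alpha)
        return np.linalg.norm(np.atleast_2d(null), axis=1)

    # -- reachable cone ----------------------------------------------------

    def cone_membership(self, target: np.ndarray,
                        required_force: np.ndarray | None = None,
                        return_witness: bool = False):
        """Is a rotated null-space target attainable with alpha >= 0?

        Decides feasibility of R_c (N_tilde alpha - n0) = target together
        with H alpha = required_force (zero force by default, the
        null-space-reaching constraint), over alpha >= 0, by linear
        programming.  Strict positivity is relaxed to the closure
        alpha >= 0, which is the numerically decidable version.
        """
        target = np.asarray(target, dtype=float)
        f_req = np.zeros(2) if required_force is None else np.asarray(required_force, dtype=float)
        # N_tilde alpha = R_c^T target + n0
        b_null = self.R_c.T @ target + self.n0
        A_eq = np.vstack([self.N_scaled, self.H])
        b_eq = np.concatenate([b_null, f_req])
        # scale rows to comparable magnitude for the solver
        scale = np.maximum(np.linalg.norm(A_eq, axis=1), 1.0)
        res = linprog(c=np.zeros(4), A_eq=A_eq / scale[:, None],
                      b_eq=b_eq / scale, bounds=[(0, None)] * 4,
                      method="highs")
        ok = bool(res.status == 0 and
                  np.abs(A_eq @ res.x - b_eq).max() <= FEASIBILITY_TOL * max(1.0, np.abs(b_eq).max()))
        if return_witness:
            return ok, (res.x if ok else None)
        return ok

    def cone_extreme_rays(self) -> ReachableCone:
        """Boundary of {R_c N_tilde alpha : alpha >= 0} in the plane.

        The image of the non-negative orthant under a linear map to the
        plane is the conical hull of the four column images; with the
        columns sorted by angle, the cone is bounded by the two columns
        adjacent to the largest angular gap, and is the full plane when
        every gap is below 180 degrees.
        """
        cols = (self.R_c @ self.N_scaled).T  # (4, 2) column images
        norms = np.linalg.norm(cols, axis=1)
        keep = cols[norms > 1e-12 * max(1.0, norms.max())]
        if keep.shape[0] == 0:
            raise ValueError("null-space map is zero")
        angles = np.arctan2(keep[:, 1], keep[:, 0])
        units = keep / np.linalg.norm(keep, axis=1)[:, None]
        order = np.argsort(angles)
        a_sorted = angles[order]
        gaps = np.diff(np.concatenate([a_sorted, [a_sorted[0] + 2 * np.pi]]))
        widest = int(np.argmax(gaps))
        if gaps[widest] < np.pi - 1e-12:
            return ReachableCone(rays=units[order], contains_full_plane=True)
        if np.isclose(gaps[widest], 2 * np.pi):
            # all collinear in a single direction
            return ReachableCone(rays=units[order][:1], degenerate=True)
        lo = units[order][(widest + 1) % len(a_sorted)]
        hi = units[order][widest]
        if np.allclose(lo, hi):
            return ReachableCone(rays=np.array([lo]), degenerate=True)
        return ReachableCone(rays=np.array([lo, hi]))

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "channel_order": list(CHANNELS),
            "H": self.H.tolist(),
            "N": self.N.tolist(),
            "kappa": self.kappa,
            "n0": self.n0.tolist(),
            "n_c": self.n_c.tolist(),
            "R_c": self.R_c.tolist(),
            "smvf": self.smvf,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "NullspaceModel":
        return cls(H=np.array(d["H"]), N=np.array(d["N"]), kappa=d["kappa"],
                   n0=np.array(d["n0"]), n_c=np.array(d["n_c"]),
                   R_c=np.array(d["R_c"]), smvf=d.get("smvf"))

    @classmethod
    def from_json(cls, path) -> "NullspaceModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_nullspace_model(H: np.ndarray, rest: EnvelopeRecording,
                          cocontraction_reps: Sequence[EnvelopeRecording],
                          smvf: float | None = None) -> NullspaceModel:
    """Assemble the full coordinate system from calibration recordings.

    Runs the whole chain: kernel basis, kappa scaling, rest offset,
    co-contraction averaging and the aligning rotation.  The basis row
    driving the first pre-rotation coordinate is flipped if needed so the
    co-contraction coordinate lands with a non-negative first component
    before rotation (serialisation reproducibility; R_c absorbs the rest).
    """
    N = nullspace_basis(H)
    kappa, N_scaled = scale_basis(N, H)
    n0 = estimate_offset(rest, N_scaled)
    n_c = estimate_cocontraction(cocontraction_reps, N_scaled, n0)
    if n_c[0] < 0:
        N = N.copy()
        N[0] = -N[0]
        N_scaled = kappa * N
        n0 = np.array([-n0[0], n0[1]])
        n_c = np.array([-n_c[0], n_c[1]])
    R_c = make_rotation(n_c)
    return NullspaceModel(H=np.asarray(H, dtype=float), N=N, kappa=kappa,
                          n0=n0, n_c=n_c, R_c=R_c, smvf=smvf)
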