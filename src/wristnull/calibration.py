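"""Force/EMG calibration: MVF, sMVF, and the pulling matrix H.

The pulling matrix is the linear map f = H alpha from the 4-channel EMG
envelope to 2-D isometric wrist force, estimated by ordinary least squares
over calibration holds.  No intercept is fitted: the model is strictly
f = H alpha, with a rest target anchoring the origin; any resting-envelope
bias is absorbed downstream by the null-space offset n0.

`EmgForceModel` / `EmgForceResults` follow the statsmodels Model/Results
convention: construct the model from data, `fit()` returns a results object
carrying estimates, diagnostics and a `summary()` table, and the null-space
coordinate system is built from the results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, TYPE_CHECKING

import numpy as np

from .preprocess import CHANNELS, EnvelopeRecording

if TYPE_CHECKING:  # pragma: no cover
    from .nullspace import NullspaceModel

#: Number of maximum-voluntary-force directions.
N_MVF_DIRECTIONS = 16

#: Fraction of sMVF used for calibration / task-space target radii.
TARGET_FORCE_FRAC = 0.2

#: Hold window averaged for each calibration point (s).
HOLD_WINDOW_S = 2.0


@dataclass
class MvfResult:
    """Maximum voluntary force per direction and the scaling sMVF.

    ``smvf`` is the minimum MVF across the 16 directions; it scales every
    force threshold and target radius in the experiment.
    """

    directions_deg: np.ndarray   # (16,)
    mvf: np.ndarray              # (16,) N
    smvf: float                  # N

    def __post_init__(self) -> None:
        self.directions_deg = np.asarray(self.directions_deg, dtype=float)
        self.mvf = np.asarray(self.mvf, dtype=float)
        if self.mvf.shape[0] != N_MVF_DIRECTIONS:
            raise ValueError("expected 16 MVF values")
        if (self.mvf <= 0).any():
            raise ValueError("MVF values must be positive")


@dataclass
class CalibrationPoint:
    """One calibration hold: target force, mean force and mean envelope.

    Averages are taken over the final 2 s hold window of the trial.
    """

    target_force: np.ndarray   # (2,) N
    mean_force: np.ndarray     # (2,) N
    mean_envelope: np.ndarray  # (4,)

    def __post_init__(self) -> None:
        self.target_force = np.asarray(self.target_force, dtype=float)
        self.mean_force = np.asarray(self.mean_force, dtype=float)
        self.mean_envelope = np.asarray(self.mean_envelope, dtype=float)


def mvf_direction_schedule() -> np.ndarray:
    """The 16 instructed MVF directions, degrees.

    The schedule starts at 180 deg (leftward, i.e. flexion-ward force) and
    progresses anticlockwise in 22.5 deg steps; 0 deg is +X (extension).
    """
    return (180.0 + 22.5 * np.arange(N_MVF_DIRECTIONS)) % 360.0


def compute_mvf(force_trace: np.ndarray, fs: float, *,
                direction_deg: float | None = None,
                projected: bool = False) -> float:
    """Maximum force over the final 2 s of a >= 4 s exertion trace.

    By default the magnitude of the 2-D force vector is used; with
    ``projected=True`` the component along the instructed direction is used
    instead (sensitivity analysis only).
    """
    force_trace = np.atleast_2d(np.asarray(force_trace, dtype=float))
    n = force_trace.shape[0]
    if n / fs < 4.0:
        raise ValueError(f"MVF trace must last >= 4 s; got {n / fs:.2f} s")
    tail = force_trace[-int(round(2.0 * fs)):]
    if projected:
        if direction_deg is None:
            raise ValueError("projected MVF needs the instructed direction")
        th = np.deg2rad(direction_deg)
        values = tail @ np.array([np.cos(th), np.sin(th)])
    else:
        values = np.linalg.norm(tail, axis=1)
    return float(values.max())


def compute_smvf(mvf_by_direction: Sequence[float]) -> float:
    """Scaling MVF: the minimum per-direction MVF across the 16 directions."""
    mvf = np.asarray(mvf_by_direction, dtype=float)
    if mvf.shape != (N_MVF_DIRECTIONS,):
        raise ValueError(f"expected {N_MVF_DIRECTIONS} MVF values, got {mvf.shape}")
    if (mvf <= 0).any():
        raise ValueError("MVF values must be positive")
    return float(mvf.min())


def make_calibration_targets(smvf: float) -> np.ndarray:
    """The 17 calibration target forces: rest plus a 16-point ring.

    Returns a (17, 2) array: row 0 is the rest target [0, 0] N, rows 1..16
    are evenly spaced anticlockwise from +X on the circle of radius
    0.2 * sMVF.
    """
    if smvf <= 0:
        raise ValueError("sMVF must be positive")
    ang = np.deg2rad(22.5 * np.arange(16))
    ring = TARGET_FORCE_FRAC * smvf * np.column_stack([np.cos(ang), np.sin(ang)])
    return np.vstack([np.zeros((1, 2)), ring])


def points_from_recordings(
    holds: Iterable[tuple[np.ndarray, EnvelopeRecording]],
    window_s: float = HOLD_WINDOW_S,
) -> list[CalibrationPoint]:
    """Average labelled hold recordings into calibration points."""
    pts = []
    for target, rec in holds:
        pts.append(CalibrationPoint(
            target_force=np.asarray(target, dtype=float),
            mean_force=rec.mean_force(window_s),
            mean_envelope=rec.mean_envelope(window_s),
        ))
    return pts


class EmgForceModel:
    """Linear EMG-envelope-to-force model f = H alpha.

    Parameters
    ----------
    force : (n, 2) array
        Mean force per calibration hold, N.
    envelope : (n, 4) array
        Mean EMG envelope per hold, channel order FCR, FCU, ECRL, ECU.
    smvf : float, optional
        Scaling MVF for the session; carried through to the results.
    """

    def __init__(self, force: np.ndarray, envelope: np.ndarray,
                 smvf: float | None = None):
        self.force = np.atleast_2d(np.asarray(force, dtype=float))
        self.envelope = np.atleast_2d(np.asarray(envelope, dtype=float))
        if self.force.shape[0] != self.envelope.shape[0]:
            raise ValueError("force and envelope row counts differ")
        if self.force.shape[1] != 2 or self.envelope.shape[1] != 4:
            raise ValueError("expected (n, 2) force and (n, 4) envelope")
        if self.force.shape[0] < 4:
            raise ValueError("need at least 4 calibration points")
        self.smvf = smvf

    @classmethod
    def from_points(cls, points: Sequence[CalibrationPoint],
                    smvf: float | None = None) -> "EmgForceModel":
        force = np.array([p.mean_force for p in points])
        env = np.array([p.mean_envelope for p in points])
        return cls(force, env, smvf=smvf)

    @classmethod
    def from_dataframe(cls, df, smvf: float | None = None) -> "EmgForceModel":
        """Build from a tidy table with columns force_x_n, force_y_n and
        env_fcr, env_fcu, env_ecrl, env_ecu."""
        force = df[["force_x_n", "force_y_n"]].to_numpy(dtype=float)
        env = df[["env_fcr", "env_fcu", "env_ecrl", "env_ecu"]].to_numpy(dtype=float)
        return cls(force, env, smvf=smvf)

    def fit(self) -> "EmgForceResults":
        """Ordinary least squares for H (no intercept).

        Raises on a rank-deficient envelope design, naming the collinear
        channels.
        """
        X = self.envelope
        rank = np.linalg.matrix_rank(X)
        if rank < 4:
            # channels loading on the design's null directions are collinear
            _, _, vt = np.linalg.svd(X, full_matrices=False)
            null_mask = np.abs(vt[rank:]).sum(axis=0) > 1e-12
            bad = [CHANNELS[i] for i in np.nonzero(null_mask)[0]]
            raise np.linalg.LinAlgError(
                f"envelope design is rank deficient (rank {rank}); "
                f"collinear channels: {', '.join(bad) or 'unknown'}")
        coef, _, _, _ = np.linalg.lstsq(X, self.force, rcond=None)
        H = coef.T  # (2, 4)
        fitted = X @ H.T
        residuals = self.force - fitted
        ssr = (residuals ** 2).sum(axis=0)
        sst = ((self.force - self.force.mean(axis=0)) ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(sst > 0, 1.0 - ssr / sst, np.nan)
        return EmgForceResults(self, H, r2, residuals)


class EmgForceResults:
    """OLS fit of the pulling matrix, with diagnostics.

    Attributes
    ----------
    pulling_matrix : (2, 4) array
        Rows h_1 (X axis) and h_2 (Y axis), N per envelope unit.
    r_squared : (2,) array
        Per-axis coefficient of determination (NaN if the axis had zero
        force variance).
    residuals : (n, 2) array
    """

    def __init__(self, model: EmgForceModel, H: np.ndarray,
                 r_squared: np.ndarray, residuals: np.ndarray):
        self.model = model
        self.pulling_matrix = H
        self.r_squared = r_squared
        self.residuals = residuals

    @property
    def smvf(self) -> float | None:
        return self.model.smvf

    @property
    def residual_norms(self) -> np.ndarray:
        return np.linalg.norm(self.residuals, axis=1)

    def nullspace(self, rest: EnvelopeRecording,
                  cocontraction_reps: Sequence[EnvelopeRecording]) -> "NullspaceModel":
        """Build the rotated, offset null-space coordinate system."""
        from .nullspace import build_nullspace_model
        return build_nullspace_model(self.pulling_matrix, rest,
                                     cocontraction_reps, smvf=self.smvf)

    def summary(self) -> str:
        H = self.pulling_matrix
        lines = [
            "EMG-to-force pulling matrix (OLS, no intercept)",
            "=" * 55,
            f"n calibration points: {self.model.force.shape[0]}",
            f"sMVF: {self.smvf:.3f} N" if self.smvf is not None else "sMVF: not set",
            "",
            "            " + "".join(f"{c:>10}" for c in CHANNELS),
            "h1 (X, N/u)" + "".join(f"{v:10.4f}" for v in H[0]),
            "h2 (Y, N/u)" + "".join(f"{v:10.4f}" for v in H[1]),
            "",
            f"R^2 (X): {self.r_squared[0]:.4f}   R^2 (Y): {self.r_squared[1]:.4f}",
            f"max |residual|: {np.abs(self.residuals).max():.4g} N",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "channel_order": list(CHANNELS),
            "pulling_matrix": self.pulling_matrix.tolist(),
            "r_squared": np.asarray(self.r_squared, dtype=float).tolist(),
            "smvf": self.smvf,
        }


def fit_pulling_matrix(points: Sequence[CalibrationPoint],
                       smvf: float | None = None) -> EmgForceResults:
    """Functional wrapper: OLS pulling-matrix fit from calibration points."""
    return EmgForceModel.from_points(points, smvf=smvf).fit()


def fit_quality(results: EmgForceResults) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis R^2 and per-point residual norms of a fit."""
    return results.r_squared, results.residual_norms
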