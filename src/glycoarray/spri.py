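"""SPR imaging: sensorgram extraction, concentric-ROI sweeps and Langmuir kinetics.

An SPRi acquisition is a time-stamped stack of reflectance images in pixel
intensity units. Protein binding to a glycan spot follows, to first order,
1:1 Langmuir kinetics: during association at analyte concentration C,

    R(t) = R_eq * (1 - exp(-(C*k_on + k_off) * t)),
    R_eq = R_max * C / (C + K_D),  K_D = k_off / k_on,

and after the association phase ends at t_a the response decays as
R(t_a) * exp(-k_off * (t - t_a)). ROI statistics use the same pixel-center
membership rule as the SIMS cube module so both modalities share one
coordinate convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .sims_cube import RoiSpec, roi_pixel_slices

__all__ = [
    "KineticParams",
    "SpriStack",
    "Sensorgram",
    "LangmuirFit",
    "langmuir_response",
    "langmuir_sensorgram",
    "read_stack",
    "write_stack",
    "roi_sensorgram",
    "concentric_rois",
    "response_at",
    "roi_sweep",
    "fit_langmuir",
    "estimate_koff",
]


@dataclass(frozen=True)
class KineticParams:
    """1:1 Langmuir binding parameters.

    k_on in 1/(M s), k_off in 1/s, r_max in pixel-intensity units at unit
    surface density, concentration in M, t_assoc_end in s (end of analyte
    injection).
    """

    k_on: float = 1.0e5
    k_off: float = 1.0e-3
    r_max: float = 100.0
    concentration: float = 1.0e-7
    t_assoc_end: float = 720.0

    def __post_init__(self) -> None:
        if self.k_on <= 0 or self.k_off <= 0 or self.r_max <= 0:
            raise ValueError("rates and r_max must be strictly positive")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if self.t_assoc_end <= 0:
            raise ValueError("t_assoc_end must be positive")

    @property
    def k_d(self) -> float:
        return self.k_off / self.k_on

    @property
    def k_obs(self) -> float:
        """Observed association rate C*k_on + k_off (1/s)."""
        return self.concentration * self.k_on + self.k_off

    @property
    def equilibrium_response(self) -> float:
        """Plateau response at unit density, R_max * C / (C + K_D)."""
        c = self.concentration
        return self.r_max * c / (c + self.k_d) if c > 0 else 0.0


def langmuir_response(
    kp: KineticParams, t: np.ndarray | float, density: float | np.ndarray = 1.0
) -> np.ndarray:
    """Noise-free 1:1 Langmuir response at time(s) t, scaled by local density."""
    t = np.asarray(t, dtype=float)
    t_assoc = np.minimum(t, kp.t_assoc_end)
    assoc = kp.equilibrium_response * (1.0 - np.exp(-kp.k_obs * t_assoc))
    decay = np.exp(-kp.k_off * np.maximum(t - kp.t_assoc_end, 0.0))
    return np.asarray(density) * assoc * decay


@dataclass
class SpriStack:
    """Time-ordered stack of reflectance frames sharing the SIMS pixel grid."""

    frames: np.ndarray  # (n_frames, rows, cols), pixel-intensity units
    t_seconds: np.ndarray
    pixel_um: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.t_seconds = np.asarray(self.t_seconds, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be n_frames x rows x cols")
        if len(self.t_seconds) != self.frames.shape[0]:
            raise ValueError("one timestamp per frame required")
        if len(self.t_seconds) == 0:
            raise ValueError("empty stack")
        if len(self.t_seconds) > 1 and np.any(np.diff(self.t_seconds) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be positive")

    @property
    def field_um(self) -> tuple[float, float]:
        _, rows, cols = self.frames.shape
        return (cols * self.pixel_um, rows * self.pixel_um)


def write_stack(stack: SpriStack, tiff_path: str | Path, times_csv: str | Path) -> None:
    """Write frames as multi-page 32-bit float TIFF plus a timestamps CSV."""
    import tifffile

    tifffile.imwrite(
        str(tiff_path), stack.frames.astype(np.float32), photometric="minisblack"
    )
    pd.DataFrame(
        {"frame_index": np.arange(len(stack.t_seconds)), "t_seconds": stack.t_seconds}
    ).to_csv(times_csv, index=False)


def read_stack(
    tiff_path: str | Path, times_csv: str | Path, pixel_um: float
) -> SpriStack:
    import tifffile

    frames = np.asarray(tifffile.imread(str(tiff_path)), dtype=float)
    if frames.ndim == 2:
        frames = frames[None, :, :]
    times = pd.read_csv(times_csv).sort_values("frame_index")["t_seconds"].to_numpy()
    return SpriStack(frames=frames, t_seconds=times, pixel_um=pixel_um)


@dataclass
class Sensorgram:
    """ROI response vs. time: spatial mean and sd over the ROI per time point."""

    t_seconds: np.ndarray
    response: np.ndarray
    response_sd: np.ndarray
    roi: RoiSpec | None = None

    def __post_init__(self) -> None:
        self.t_seconds = np.asarray(self.t_seconds, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        self.response_sd = np.asarray(self.response_sd, dtype=float)
        n = len(self.t_seconds)
        if len(self.response) != n or len(self.response_sd) != n:
            raise ValueError("t_seconds, response, response_sd must align")
        if np.any(self.response_sd < 0):
            raise ValueError("response_sd must be non-negative")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "t_seconds": self.t_seconds,
                "response": self.response,
                "response_sd": self.response_sd,
            }
        ).to_csv(path, index=False)


def langmuir_sensorgram(
    kp: KineticParams,
    times: Sequence[float],
    density: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Sensorgram:
    """Synthesize a single-ROI sensorgram directly from the Langmuir model."""
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("empty times")
    y = langmuir_response(kp, times, density)
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return Sensorgram(times, y, np.zeros_like(y))


def roi_sensorgram(
    stack: SpriStack, roi: RoiSpec, frame_average: int = 30
) -> Sensorgram:
    """Sensorgram over an ROI with consecutive-block frame averaging.

    Frames are grouped into consecutive blocks of `frame_average` (the final
    block may be shorter) and averaged into one image per block, emulating
    the instrument's n-image averaging; the response is the spatial mean over
    ROI pixels of each averaged image, the sd the spatial standard deviation,
    and the timestamp the block mean time.
    """
    n = stack.frames.shape[0]
    if not 1 <= frame_average <= n:
        raise ValueError("frame_average must be in [1, n_frames]")
    rs, cs = roi_pixel_slices(roi, stack.frames.shape[1:], stack.pixel_um, stack.origin)
    t_out, mean_out, sd_out = [], [], []
    for start in range(0, n, frame_average):
        block = stack.frames[start : start + frame_average, rs, cs]
        avg = block.mean(axis=0)
        pix = avg.ravel()
        t_out.append(stack.t_seconds[start : start + frame_average].mean())
        mean_out.append(pix.mean())
        sd_out.append(pix.std(ddof=1) if pix.size > 1 else 0.0)
    return Sensorgram(np.asarray(t_out), np.asarray(mean_out), np.asarray(sd_out), roi)


def concentric_rois(
    center_um: tuple[float, float],
    sizes_um: Sequence[float],
    field_um: tuple[float, float] | float | None = None,
) -> list[RoiSpec]:
    """Square ROIs of strictly increasing size sharing one center.

    If `field_um` is given (scalar for a square field), the largest ROI must
    fit inside the field; ROIs are never clipped.
    """
    sizes = np.asarray(sizes_um, dtype=float)
    if sizes.size == 0 or np.any(sizes <= 0):
        raise ValueError("sizes must be positive")
    if sizes.size > 1 and np.any(np.diff(sizes) <= 0):
        raise ValueError("sizes must be strictly increasing")
    cx, cy = center_um
    if field_um is not None:
        fx, fy = (field_um, field_um) if np.isscalar(field_um) else field_um
        half = sizes[-1] / 2
        if cx - half < 0 or cy - half < 0 or cx + half > fx or cy + half > fy:
            raise ValueError("largest ROI exceeds field")
    return [RoiSpec(cx - s / 2, cy - s / 2, s, s) for s in sizes]


def _value_at(t_seconds: np.ndarray, values: np.ndarray, t_s: float) -> float:
    if t_s < t_seconds[0] or t_s > t_seconds[-1]:
        raise ValueError("requested time outside sensorgram range")
    i = int(np.argmin(np.abs(t_seconds - t_s)))
    if abs(t_seconds[i] - t_s) <= 60.0:
        return float(values[i])
    return float(np.interp(t_s, t_seconds, values))


def response_at(sensorgram: Sensorgram, t_minutes: float = 11.0) -> float:
    """Response at the given readout time (minutes).

    Uses the nearest sampled time if it lies within 60 s, otherwise linear
    interpolation between the neighboring samples.
    """
    return _value_at(sensorgram.t_seconds, sensorgram.response, t_minutes * 60.0)


def roi_sweep(
    stack: SpriStack,
    center_um: tuple[float, float],
    sizes_um: Sequence[float],
    t_minutes: float = 11.0,
    frame_average: int = 30,
) -> pd.DataFrame:
    """Response and spatial variability at a readout time over nested ROIs.

    Returns a table with columns size_um, area_um2, mean, sd, norm_mean,
    where norm_mean is the mean response divided by the maximum mean across
    the sweep (the largest-response ROI reads 1).
    """
    rois = concentric_rois(center_um, sizes_um, stack.field_um)
    t_s = t_minutes * 60.0
    rows = []
    for size, roi in zip(np.asarray(sizes_um, dtype=float), rois):
        sg = roi_sensorgram(stack, roi, frame_average)
        rows.append(
            {
                "size_um": size,
                "area_um2": size * size,
                "mean": _value_at(sg.t_seconds, sg.response, t_s),
                "sd": _value_at(sg.t_seconds, sg.response_sd, t_s),
            }
        )
    table = pd.DataFrame(rows)
    table["norm_mean"] = table["mean"] / table["mean"].max()
    return table


# ---------------------------------------------------------------------------
# Langmuir fitting


@dataclass(frozen=True)
class LangmuirFit:
    """Result of a 1:1 Langmuir fit: estimates plus the residual norm."""

    params: KineticParams
    residual_norm: float
    n_starts_converged: int


def estimate_koff(sensorgram: Sensorgram, t_assoc_end: float) -> float:
    """k_off from a log-linear fit to the dissociation-phase decay.

    The dissociation of a 1:1 complex is a single exponential, so the slope
    of log(R) vs t over t > t_assoc_end is -k_off. Used to seed the full
    nonlinear fit; requires strictly positive responses after t_assoc_end.
    """
    mask = sensorgram.t_seconds > t_assoc_end
    t = sensorgram.t_seconds[mask]
    y = sensorgram.response[mask]
    if len(t) < 2:
        raise ValueError("need at least two dissociation-phase samples")
    if np.any(y <= 0):
        raise ValueError("dissociation responses must be positive for log fit")
    slope = np.polyfit(t, np.log(y), 1)[0]
    if slope >= 0:
        raise ValueError("dissociation phase does not decay")
    return -float(slope)


def _model_and_jac(theta: np.ndarray, t: np.ndarray, c: float, t_end: float):
    k_on, k_off, r_max = theta
    k = c * k_on + k_off
    amp = r_max * c * k_on / k
    d_amp = np.array([r_max * c * k_off / k**2, -r_max * c * k_on / k**2, c * k_on / k])

    ta = np.minimum(t, t_end)
    e = np.exp(-k * ta)
    g = 1.0 - e
    # association-phase value and gradient (evaluated at min(t, t_end))
    f_a = amp * g
    df_a = np.empty((len(t), 3))
    df_a[:, 0] = d_amp[0] * g + amp * ta * e * c
    df_a[:, 1] = d_amp[1] * g + amp * ta * e
    df_a[:, 2] = d_amp[2] * g

    dt = np.maximum(t - t_end, 0.0)
    decay = np.exp(-k_off * dt)
    f = f_a * decay
    jac = df_a * decay[:, None]
    jac[:, 1] += f_a * (-dt) * decay
    return f, jac


def fit_langmuir(
    sensorgram: Sensorgram,
    concentration: float,
    t_assoc_end: float,
) -> LangmuirFit:
    """Nonlinear least-squares fit of the 1:1 Langmuir model.

    Fits (k_on, k_off, R_max) in log-space with analytic gradients; five
    deterministic multi-starts scale the rate seeds over +/-2 decades around
    heuristic initial values (plateau for R_max*C/(C+K_D), the 63%-rise time
    for k_obs, and a log-linear dissociation slope for k_off when available).
    Raises if no start converges.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    t = sensorgram.t_seconds
    y = sensorgram.response
    if t[0] >= t_assoc_end or t[-1] <= t_assoc_end:
        raise ValueError("sensorgram must span association and some dissociation")

    plateau = max(float(np.max(y)), 1e-12)
    try:
        koff0 = estimate_koff(sensorgram, t_assoc_end)
    except ValueError:
        koff0 = 1e-3
    assoc = (t <= t_assoc_end) & (y > 0)
    rise = y[assoc] / plateau
    crossed = np.nonzero(rise >= 1 - np.exp(-1))[0]
    t63 = t[assoc][crossed[0]] if len(crossed) else t_assoc_end / 2
    kobs0 = 1.0 / max(t63, t[1] - t[0])
    kon0 = max((kobs0 - koff0) / concentration, koff0 / concentration * 1e-2)

    def residuals(phi):
        f, _ = _model_and_jac(np.exp(phi), t, concentration, t_assoc_end)
        return f - y

    def jacobian(phi):
        theta = np.exp(phi)
        _, j = _model_and_jac(theta, t, concentration, t_assoc_end)
        return j * theta[None, :]

    best = None
    n_ok = 0
    for scale in (1e-2, 1e-1, 1.0, 1e1, 1e2):
        kd = koff0 * scale / (kon0 * scale)
        rmax0 = plateau * (concentration + kd) / concentration
        phi0 = np.log([kon0 * scale, koff0 * scale, rmax0])
        try:
            res = least_squares(
                residuals, phi0, jac=jacobian, method="trf", max_nfev=400
            )
        except Exception:
            continue
        if not res.success:
            continue
        n_ok += 1
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError(
            "Langmuir fit failed to converge from all starts "
            f"(k_on0={kon0:.3g}, k_off0={koff0:.3g}, plateau={plateau:.3g})"
        )
    k_on, k_off, r_max = np.exp(best.x)
    params = KineticParams(
        k_on=k_on,
        k_off=k_off,
        r_max=r_max,
        concentration=concentration,
        t_assoc_end=t_assoc_end,
    )
    return LangmuirFit(
        params=params,
        residual_norm=float(np.linalg.norm(best.fun)),
        n_starts_converged=n_ok,
    )
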