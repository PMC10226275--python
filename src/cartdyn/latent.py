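"""Latent CAR T-cell trajectory reconstruction by delay embedding.

Only the cancer-cell series is densely observed; the CAR T-cell series
exists as two flow-cytometry endpoints.  Takens' theorem lets the missing
state be reconstructed from time-shifted copies of the observed one:

1. smooth the cancer series with a cubic smoothing spline;
2. pick the embedding delay ``tau`` at the first minimum of the
   time-delayed mutual information;
3. pick the embedding dimension ``m`` where the false-nearest-neighbour
   fraction becomes negligible;
4. stack the delayed series into a Hankel matrix, take its SVD, and read
   the latent coordinate off the second right-singular vector;
5. pin the latent series to the two measured CAR T endpoints with an
   affine map.

The reconstruction is only guaranteed up to a diffeomorphism of the true
hidden state, which is why downstream interpretation leans on model
*structure* rather than exact coefficient values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_smoothing_spline

__all__ = [
    "SmoothedSeries",
    "EmbeddingResult",
    "DegenerateEmbeddingError",
    "spline_smooth",
    "mutual_information",
    "select_delay",
    "false_nearest_neighbors",
    "select_dimension",
    "hankel_matrix",
    "extract_latent",
    "rescale_to_endpoints",
    "reconstruct_latent",
]


class DegenerateEmbeddingError(RuntimeError):
    """The series carries no usable second embedding coordinate."""


@dataclass
class SmoothedSeries:
    """A series smoothed on its original uniform grid."""

    times: np.ndarray
    values: np.ndarray
    lam: float | None = None      # spline penalty actually used (None = GCV)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class EmbeddingResult:
    """Everything produced by one well's latent reconstruction."""

    tau: int
    m: int
    hankel: np.ndarray
    latent_raw: np.ndarray
    latent_rescaled: np.ndarray | None = None
    mi_profile: dict[int, float] = field(default_factory=dict)
    fnn_profile: dict[int, float] = field(default_factory=dict)
    singular_values: np.ndarray | None = None


def spline_smooth(
    times: np.ndarray,
    values: np.ndarray,
    lam: float | None = None,
) -> SmoothedSeries:
    """Cubic smoothing spline resampled on the original grid.

    With ``lam=None`` the curvature penalty is chosen by generalized
    cross-validation.  The grid must be uniform (the downstream Hankel
    indexing assumes it).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 10:
        raise ValueError("need at least 10 points to smooth")
    steps = np.diff(times)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
        raise ValueError("time grid must be uniform; resample first")
    if np.ptp(values) == 0:
        # constant input: the GCV problem is degenerate, output is constant
        return SmoothedSeries(times, values.copy(), lam)
    spl = make_smoothing_spline(times, values, lam=lam)
    return SmoothedSeries(times, spl(times), lam)


def mutual_information(
    series: np.ndarray, tau: int, bins: int | None = None
) -> float:
    """Time-delayed mutual information I(tau), in nats.

    The range ``[min, max]`` of the series is split into ``bins`` equal
    partitions (default ``ceil(sqrt(N))``) and I(tau) is the mutual
    information between the pair distribution of ``x_i`` and ``x_{i+tau}``
    and the product of its marginals.  Nonnegative; ``tau=0`` returns the
    partition entropy.
    """
    x = np.asarray(series, dtype=float)
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if x.size < tau + 2:
        raise ValueError("series shorter than tau + 2")
    if bins is None:
        bins = int(np.ceil(np.sqrt(x.size)))
    if bins < 2:
        raise ValueError("need at least 2 partitions")
    a = x[: x.size - tau]
    b = x[tau:]
    edges = np.linspace(x.min(), x.max(), bins + 1)
    counts, _, _ = np.histogram2d(a, b, bins=[edges, edges])
    p = counts / counts.sum()
    ph = p.sum(axis=1)
    pk = p.sum(axis=0)
    mask = p > 0
    denom = np.outer(ph, pk)
    return float(np.sum(p[mask] * np.log(p[mask] / denom[mask])))


def select_delay(
    series: np.ndarray,
    max_delay: int = 48,
    bins: int | None = None,
) -> tuple[int, dict[int, float]]:
    """Embedding delay at the first local minimum of I(tau).

    Scans ``tau = 1..max_delay`` (12 h at 15-min sampling by default).  If
    the profile has no interior local minimum — typical for smooth,
    densely-sampled series where information decays monotonically — the
    global argmin over the window is returned with a warning.
    """
    x = np.asarray(series, dtype=float)
    max_delay = min(max_delay, x.size - 2)
    taus = np.arange(1, max_delay + 1)
    profile = {int(t): mutual_information(x, int(t), bins) for t in taus}
    vals = np.array([profile[int(t)] for t in taus])
    for i in range(1, len(vals) - 1):
        if vals[i] < vals[i - 1] and vals[i] < vals[i + 1]:
            return int(taus[i]), profile
    warnings.warn(
        "mutual information has no interior local minimum over the scan "
        "window; falling back to the global argmin",
        stacklevel=2,
    )
    return int(taus[np.argmin(vals)]), profile


def hankel_matrix(series: np.ndarray, tau: int, m: int) -> np.ndarray:
    """m-row Hankel matrix of time-shifted copies of the series.

    Row ``r`` (0-based), column ``c`` holds ``x(t_{c + r*tau})``; the matrix
    has ``N - (m-1)*tau`` columns.
    """
    x = np.asarray(series, dtype=float)
    if tau < 1 or m < 1:
        raise ValueError("tau and m must be positive integers")
    ncol = x.size - (m - 1) * tau
    if ncol < 1:
        raise ValueError("series too short for this (tau, m)")
    return np.vstack([x[r * tau : r * tau + ncol] for r in range(m)])


def false_nearest_neighbors(
    series: np.ndarray,
    tau: int,
    m: int,
    r_threshold: float = 10.0,
) -> float:
    """Fraction of false nearest neighbours in an m-dimensional embedding.

    For each delay vector ``p(i)`` the nearest neighbour ``p(j)`` closer
    than the series' standard deviation is found; the pair is false when
    the next-coordinate separation, normalized by the neighbour distance,

        R_i = |x(t_i + m*tau) - x(t_j + m*tau)| / ||p(i) - p(j)||

    exceeds ``r_threshold`` (10 works for most data sets).  Points with no
    admissible neighbour are skipped.
    """
    x = np.asarray(series, dtype=float)
    emb = hankel_matrix(x, tau, m)          # m x ncol
    ncol = emb.shape[1]
    usable = ncol - tau                      # need x(t_i + m*tau)
    if usable < 2:
        raise ValueError("series too short for FNN at this (tau, m)")
    pts = emb[:, :usable].T                  # usable x m
    nxt = x[m * tau : m * tau + usable]
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=2))
    np.fill_diagonal(dist, np.inf)
    limit = float(np.std(x))
    false = 0
    counted = 0
    for i in range(usable):
        j = int(np.argmin(dist[i]))
        dij = dist[i, j]
        if not np.isfinite(dij) or dij >= limit or dij == 0:
            continue
        counted += 1
        if abs(nxt[i] - nxt[j]) / dij > r_threshold:
            false += 1
    if counted == 0:
        return 0.0
    return false / counted


def select_dimension(
    series: np.ndarray,
    tau: int,
    max_dim: int = 6,
    threshold: float = 0.05,
    r_threshold: float = 10.0,
) -> tuple[int, dict[int, float]]:
    """Smallest embedding dimension with a negligible FNN fraction.

    "Negligible" defaults to below 5%.  Returns the selected ``m`` and the
    full profile; if no dimension passes, the argmin of the profile is
    returned with a warning.
    """
    profile: dict[int, float] = {}
    for m in range(1, max_dim + 1):
        profile[m] = false_nearest_neighbors(series, tau, m, r_threshold)
        if profile[m] < threshold:
            return m, profile
    warnings.warn(
        f"false-neighbor fraction stayed above {threshold:g} up to "
        f"m={max_dim}; returning the argmin",
        stacklevel=2,
    )
    best = min(profile, key=profile.get)
    return best, profile


def extract_latent(
    series: np.ndarray, tau: int = 1, m: int = 2
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Latent coordinate from the SVD of the Hankel matrix.

    With the published embedding (``tau=1``, ``m=2``) the Hankel matrix is
    the 2 x (N-1) stack of the series and its one-step shift; the SVD
    ``H = U S V*`` then yields the latent series as the second column of
    ``V``, assigned to the first ``N-1`` time points.

    Returns ``(latent_raw, singular_values, hankel)``.  A (near-)rank-one
    Hankel matrix — a constant series, or one equal to its own shift —
    has no second coordinate and raises :class:`DegenerateEmbeddingError`.
    """
    H = hankel_matrix(series, tau, m)
    U, s, Vt = np.linalg.svd(H, full_matrices=False)
    if s.size < 2 or s[1] <= s[0] * 1e-12:
        raise DegenerateEmbeddingError(
            "Hankel matrix is rank deficient; no latent coordinate"
        )
    return Vt[1], s, H


def rescale_to_endpoints(
    latent_raw: np.ndarray, y_init: float, y_final: float
) -> np.ndarray:
    """Affine map pinning the latent series to the measured endpoints.

    Solves ``a * v + b`` such that the first and last latent samples map to
    ``y_init`` and ``y_final``.  ``a`` may be negative — the SVD sign is
    arbitrary and the anchoring absorbs it.
    """
    v = np.asarray(latent_raw, dtype=float)
    if v.size < 2 or v[0] == v[-1]:
        raise DegenerateEmbeddingError(
            "latent endpoints coincide; cannot anchor the affine rescaling"
        )
    if y_init == y_final:
        raise DegenerateEmbeddingError(
            "measured endpoints coincide; the scale of the latent variable "
            "is undetermined"
        )
    a = (y_final - y_init) / (v[-1] - v[0])
    b = y_init - a * v[0]
    return a * v + b


def reconstruct_latent(
    times: np.ndarray,
    cancer: np.ndarray,
    y_init: float,
    y_final: float,
    tau: int | None = None,
    m: int | None = None,
    lam: float | None = None,
    max_delay: int = 48,
) -> EmbeddingResult:
    """Full per-well reconstruction: smooth, embed, extract, anchor.

    ``tau``/``m`` default to automatic selection (mutual-information first
    minimum; FNN < 5%).  The latent series is one sample shorter than the
    input; downstream stacking holds the final value for the last sample.
    """
    smooth = spline_smooth(times, cancer, lam=lam)
    x = smooth.values
    mi_profile: dict[int, float] = {}
    fnn_profile: dict[int, float] = {}
    if tau is None:
        tau, mi_profile = select_delay(x, max_delay=max_delay)
    if m is None:
        m, fnn_profile = select_dimension(x, tau)
    latent_raw, svals, H = extract_latent(x, tau, m)
    rescaled = rescale_to_endpoints(latent_raw, y_init, y_final)
    return EmbeddingResult(
        tau=tau,
        m=m,
        hankel=H,
        latent_raw=latent_raw,
        latent_rescaled=rescaled,
        mi_profile=mi_profile,
        fnn_profile=fnn_profile,
        singular_values=svals,
    )
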