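"""Egocentric hippocampal encoding analysis.

Pipeline, per recorded neuron:

1. restrict to qualifying epochs — host bat on the large net with at least
   3 conspecifics co-present — binned at 0.5 s; neurons need >= 600 s of
   qualifying time and >= 100 qualifying spikes to enter the analysis;
2. fit additive Poisson (log-link) encoding models with ridge-penalized
   IRLS: a baseline (intercept + own-position Gaussian grid) plus, per
   conspecific, a circular harmonic basis on the egocentric bearing, a
   B-spline basis on the distance, or a Gaussian grid on the conspecific's
   allocentric net position;
3. classify each neuron egocentric vs allocentric by DIC (deviance at the
   penalized fit + 2 x effective degrees of freedom), requiring
   |DIC difference| strictly greater than 10;
4. attribute the explained deviance of the full egocentric model across the
   2 x (number of conspecifics) angle/distance variables with exact Shapley
   values over all 2^n variable subsets;
5. extract empirical tuning curves (12 x 30 deg circular bins; 12 equal
   distance bins up to the net diagonal) for the top-attributed bats and
   run the population-level statistics (Shapley KS, Kuiper on preferred
   angles, chi-square on preferred distances, front/back signed-rank,
   Delta-Elo class chi-square, sex splits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.special import xlogy

from .angles import circular_mean_deg, egocentric_angle
from .dominance import DELTA_ELO_CLASS_EDGE, EloState
from .errors import (
    ConfigError,
    DataError,
    DegenerateCovariateError,
    FitError,
    InsufficientSampleError,
    ValidationError,
)
from .session_io import SpikeTrain, TrajectorySet
from .stats import (
    StatResult,
    chi2_counts,
    chi2_uniform,
    ks_two_sample,
    kuiper_two_sample,
    kuiper_uniform,
    wilcoxon,
)

MIN_QUALIFYING_SECONDS = 600.0
MIN_QUALIFYING_SPIKES = 100
DIC_MARGIN = 10.0
MAX_SHAPLEY_VARS = 14

CLASS_EGO = "egocentric"
CLASS_ALLO = "allocentric"
CLASS_NONE = "unclassified"


@dataclass(frozen=True)
class BasisConfig:
    """Bases and penalty of the encoding models.

    ``harmonic_order`` = 3 gives 6 circular columns (sin/cos of 1-3x the
    bearing) per conspecific angle; ``n_dist_splines`` cubic B-splines span
    distances [0, d_max]; own and allocentric positions use ``grid`` x
    ``grid`` Gaussian bumps over the large net.  ``ridge_lambda`` is the
    fixed L2 penalty on all non-intercept coefficients (columns are
    standardized so the penalty is scale-free).
    """

    bin_width: float = 0.5
    harmonic_order: int = 3
    n_dist_splines: int = 5
    grid: int = 3
    ridge_lambda: float = 1.0
    d_max: float | None = None  # default: large-net diagonal
    min_conspecifics: int = 3
    max_iter: int = 50
    tol: float = 1e-8


# ---------------------------------------------------------------------------
# Covariate frame
# ---------------------------------------------------------------------------


@dataclass
class CovariateFrame:
    """Binned sociospatial covariates for one host bat on the large net.

    Arrays are (n_bins,) or (n_bins, n_conspecifics): egocentric bearing
    ``theta`` (deg, [-180, 180), 0 = ahead, positive = left), distance
    ``dist`` (m), allocentric net-local position ``allo`` (m), and a
    presence mask.  Values are NaN where the conspecific is absent.
    """

    host: str
    conspecifics: list[str]
    bin_width: float
    bin_start_times: np.ndarray
    host_pos: np.ndarray  # (n, 2) net-local
    host_hd: np.ndarray  # (n,)
    theta: np.ndarray  # (n, m)
    dist: np.ndarray  # (n, m)
    allo: np.ndarray  # (n, m, 2)
    present: np.ndarray  # (n, m) bool
    net_diagonal: float

    @property
    def n_bins(self) -> int:
        return int(self.bin_start_times.size)

    @property
    def qualifying_duration(self) -> float:
        return self.n_bins * self.bin_width

    def count_spikes(self, spikes: SpikeTrain | np.ndarray) -> np.ndarray:
        """Spike counts within each (possibly non-contiguous) kept bin."""
        times = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes)
        counts = np.empty(self.n_bins, dtype=float)
        for i, t0 in enumerate(self.bin_start_times):
            counts[i] = np.count_nonzero(
                (times >= t0) & (times < t0 + self.bin_width)
            )
        return counts


def build_covariates(
    traj: TrajectorySet,
    host: str,
    *,
    config: BasisConfig = BasisConfig(),
) -> CovariateFrame:
    """Bin a session into qualifying analysis bins for one host bat.

    A bin qualifies when the host is on the large net with a defined head
    direction in every frame of the bin and at least ``min_conspecifics``
    conspecifics share the net throughout the bin.  Per bin, angles are
    circular means and positions/distances plain means over frames; a
    conspecific absent during any frame of a bin is masked out of that bin.
    """
    if host not in traj.positions:
        raise DataError(f"unknown host bat {host!r}")
    geom = traj.geometry
    net = geom.large_net
    dt = traj.frame_interval
    frames_per_bin = max(1, int(round(config.bin_width / dt)))
    n_full = traj.n_frames // frames_per_bin
    if n_full == 0:
        raise DataError("session shorter than one analysis bin")
    others = [lab for lab in traj.labels if lab != host]
    m = len(others)

    host_on = (traj.zone[host] == net.name) & ~np.isnan(traj.head_direction[host])
    on_net = np.stack([traj.zone[lab] == net.name for lab in others], axis=1)

    def bin_all(mask):  # all frames of each bin satisfy mask
        return mask[: n_full * frames_per_bin].reshape(n_full, frames_per_bin).all(axis=1)

    host_ok = bin_all(host_on)
    cons_present = np.stack([bin_all(on_net[:, j]) for j in range(m)], axis=1)
    enough = cons_present.sum(axis=1) >= config.min_conspecifics
    keep = host_ok & enough
    if not keep.any():
        raise DataError("no qualifying bins (host on large net with >= 3 others)")

    def bin_mean(x):
        return np.nanmean(
            x[: n_full * frames_per_bin].reshape(n_full, frames_per_bin, -1), axis=1
        )

    t0 = traj.frame_times[0]
    starts = t0 + np.arange(n_full) * frames_per_bin * dt
    hp_room = bin_mean(traj.positions[host][:, :2])
    hd_frames = traj.head_direction[host][: n_full * frames_per_bin].reshape(
        n_full, frames_per_bin
    )
    host_hd = circular_mean_deg(hd_frames, axis=1) % 360.0

    theta = np.full((n_full, m), np.nan)
    dist = np.full((n_full, m), np.nan)
    allo = np.full((n_full, m, 2), np.nan)
    for j, lab in enumerate(others):
        pos = bin_mean(traj.positions[lab][:, :2])
        ok = cons_present[:, j]
        allo[ok, j] = net.to_local(pos[ok])
        d = pos - hp_room
        dist[ok, j] = np.linalg.norm(d[ok], axis=1)
        theta[ok, j] = egocentric_angle(hp_room[ok], host_hd[ok], pos[ok])

    return CovariateFrame(
        host=host,
        conspecifics=others,
        bin_width=frames_per_bin * dt,
        bin_start_times=starts[keep],
        host_pos=net.to_local(hp_room[keep]),
        host_hd=host_hd[keep],
        theta=theta[keep],
        dist=dist[keep],
        allo=allo[keep],
        present=cons_present[keep],
        net_diagonal=net.diagonal,
    )


def inclusion_filter(
    spikes: SpikeTrain, frame: CovariateFrame
) -> tuple[bool, dict[str, float]]:
    """Apply the analysis inclusion rule (closed >= thresholds).

    A neuron is included iff its qualifying epoch duration is >= 600 s
    (10 min) and it fired >= 100 spikes within qualifying bins.
    """
    duration = frame.qualifying_duration
    n_spikes = int(frame.count_spikes(spikes).sum())
    ok = duration >= MIN_QUALIFYING_SECONDS and n_spikes >= MIN_QUALIFYING_SPIKES
    return ok, {"qualifying_seconds": duration, "qualifying_spikes": n_spikes}


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------


def _gaussian_grid(xy: np.ndarray, width: float, height: float, g: int) -> np.ndarray:
    """g x g Gaussian bumps tiling a [0, width] x [0, height] rectangle."""
    cx = (np.arange(g) + 0.5) * width / g
    cy = (np.arange(g) + 0.5) * height / g
    sx, sy = width / g, height / g
    cols = []
    for x0 in cx:
        for y0 in cy:
            cols.append(
                np.exp(
                    -((xy[:, 0] - x0) ** 2) / (2 * sx**2)
                    - ((xy[:, 1] - y0) ** 2) / (2 * sy**2)
                )
            )
    return np.column_stack(cols)


def _bspline_knots(pooled: np.ndarray, n_splines: int):
    """Cubic B-spline knot vector with boundary/internal knots on quantiles
    of the observed distances, so every basis function carries data."""
    k = 3
    n_inner = n_splines - k - 1
    qs = np.linspace(0.0, 1.0, n_inner + 2)
    pts = np.quantile(pooled, qs)
    lo, hi = pts[0], pts[-1]
    if hi - lo < 1e-6:
        raise DegenerateCovariateError("distances have no spread")
    inner = np.clip(pts[1:-1], lo + 1e-6, hi - 1e-6) if n_inner > 0 else []
    t = np.concatenate([[lo] * (k + 1), inner, [hi] * (k + 1)])
    return t, k, lo, hi


def _harmonics(theta_deg: np.ndarray, order: int) -> np.ndarray:
    rad = np.radians(theta_deg)
    cols = []
    for h in range(1, order + 1):
        cols.append(np.sin(h * rad))
        cols.append(np.cos(h * rad))
    return np.column_stack(cols)


class DesignBuilder:
    """Caches standardized basis blocks for one covariate frame.

    Variables are named ``("angle", bat)``, ``("dist", bat)`` and
    ``("allo", bat)``; the baseline (intercept + own-position grid) is
    always included.  Per-conspecific blocks are gated by presence: rows
    where the bat is absent are zero, mapping absence onto the baseline.
    """

    def __init__(self, frame: CovariateFrame, config: BasisConfig):
        self.frame = frame
        self.config = config
        self.d_max = config.d_max or frame.net_diagonal
        self._blocks: dict[tuple[str, str], np.ndarray] = {}
        self._dist_knots = None
        self._own = self._standardize(
            _gaussian_grid(frame.host_pos, 0.80, 0.40, config.grid), ("own", "")
        )

    def _standardize(self, X: np.ndarray, name) -> np.ndarray:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        if np.any(sd < 1e-12):
            raise DegenerateCovariateError(
                f"covariate {name} has a zero-variance column"
            )
        return (X - mu) / sd

    def block(self, var: tuple[str, str]) -> np.ndarray:
        if var in self._blocks:
            return self._blocks[var]
        kind, bat = var
        f = self.frame
        j = f.conspecifics.index(bat)
        pres = f.present[:, j]
        if kind == "angle":
            raw = np.zeros((f.n_bins, 2 * self.config.harmonic_order))
            raw[pres] = _harmonics(f.theta[pres, j], self.config.harmonic_order)
        elif kind == "dist":
            if self._dist_knots is None:
                pooled = self.frame.dist[self.frame.present]
                self._dist_knots = _bspline_knots(pooled, self.config.n_dist_splines)
            t, k, lo, hi = self._dist_knots
            d = np.clip(f.dist[pres, j], lo, hi - 1e-9)
            raw = np.zeros((f.n_bins, self.config.n_dist_splines))
            raw[pres] = BSpline.design_matrix(d, t, k).toarray()
        elif kind == "allo":
            raw = np.zeros((f.n_bins, self.config.grid**2))
            raw[pres] = _gaussian_grid(f.allo[pres, j], 0.80, 0.40, self.config.grid)
        else:
            raise ConfigError(f"unknown variable kind {kind!r}")
        X = self._standardize(raw, var)
        self._blocks[var] = X
        return X

    def design(self, subset) -> np.ndarray:
        """Full design matrix: intercept | own-position | subset blocks."""
        parts = [np.ones((self.frame.n_bins, 1)), self._own]
        for var in subset:
            parts.append(self.block(var))
        return np.column_stack(parts)


# ---------------------------------------------------------------------------
# Penalized Poisson fit
# ---------------------------------------------------------------------------


@dataclass
class EncodingFit:
    """One penalized Poisson fit: subset, coefficients, deviance, EDF, DIC."""

    subset: tuple
    beta: np.ndarray
    deviance: float
    edf: float
    dic: float
    converged: bool
    n_bins: int


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    return float(2.0 * np.sum(xlogy(y, y / mu) - (y - mu)))


def fit_encoding_model(
    frame: CovariateFrame,
    subset,
    counts: np.ndarray,
    *,
    config: BasisConfig = BasisConfig(),
    builder: DesignBuilder | None = None,
) -> EncodingFit:
    """Ridge-penalized Poisson regression of spike counts on basis expansions.

    Log-link with the bin width as exposure offset; Newton/IRLS maximizes
    ``loglik - lambda * |beta_penalized|^2``.  The effective degrees of
    freedom are the trace of the ridge influence matrix,
    ``tr[(X'WX + 2 lambda P)^-1 X'WX]``, and DIC = deviance + 2 EDF.
    """
    subset = tuple(subset)
    builder = builder or DesignBuilder(frame, config)
    X = builder.design(subset)
    y = np.asarray(counts, dtype=float)
    n, p = X.shape
    if n < p:
        raise FitError(
            f"too few bins ({n}) for the requested basis dimension ({p})"
        )
    # glmnet-style parameterization: the penalty is lambda per observation,
    # so a fixed lambda has the same shrinkage strength at any problem size
    lam = config.ridge_lambda * n
    pen = np.ones(p)
    pen[0] = 0.0  # intercept unpenalized
    offset = math.log(frame.bin_width)
    beta = np.zeros(p)
    beta[0] = math.log(max(y.mean(), 1e-3)) - offset

    def objective(b, mu):
        ll = float(np.sum(y * np.log(mu) - mu))
        return ll - lam * float(np.sum(pen * b * b))

    eta = X @ beta + offset
    mu = np.exp(np.clip(eta, -30, 30))
    obj = objective(beta, mu)
    converged = False
    for _ in range(config.max_iter):
        w = mu
        grad = X.T @ (y - mu) - 2.0 * lam * pen * beta
        H = (X * w[:, None]).T @ X
        H_pen = H + 2.0 * lam * np.diag(pen)
        try:
            step = np.linalg.solve(H_pen, grad)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular system for subset {subset}") from exc
        # backtracking line search on the penalized log-likelihood
        t_step = 1.0
        for _ in range(20):
            cand = beta + t_step * step
            eta = X @ cand + offset
            mu_c = np.exp(np.clip(eta, -30, 30))
            new_obj = objective(cand, mu_c)
            if new_obj >= obj - 1e-12:
                break
            t_step *= 0.5
        beta = beta + t_step * step
        mu = mu_c
        if abs(new_obj - obj) < config.tol * (abs(obj) + 1.0):
            obj = new_obj
            converged = True
            break
        obj = new_obj
    if not converged and config.max_iter > 0:
        raise FitError(
            f"IRLS did not converge after {config.max_iter} iterations "
            f"(subset {subset})"
        )
    w = mu
    H = (X * w[:, None]).T @ X
    H_pen = H + 2.0 * lam * np.diag(pen)
    edf = float(np.trace(np.linalg.solve(H_pen, H)))
    dev = _poisson_deviance(y, mu)
    return EncodingFit(subset, beta, dev, edf, dev + 2.0 * edf, converged, n)


# ---------------------------------------------------------------------------
# DIC model selection
# ---------------------------------------------------------------------------


@dataclass
class Classification:
    label: str
    delta_dic: float  # DIC_allo - DIC_ego (positive favours egocentric)
    fit_ego: EncodingFit | None
    fit_allo: EncodingFit | None
    reason: str = ""


def classify_neuron(
    frame: CovariateFrame,
    counts: np.ndarray,
    *,
    config: BasisConfig = BasisConfig(),
    builder: DesignBuilder | None = None,
) -> Classification:
    """Egocentric vs allocentric by DIC with a strict |dDIC| > 10 rule.

    The egocentric candidate holds every conspecific's bearing and distance
    bases; the allocentric candidate every conspecific's net-position grid;
    both share the intercept + own-position baseline.
    """
    builder = builder or DesignBuilder(frame, config)
    ego_subset = [(k, b) for b in frame.conspecifics for k in ("angle", "dist")]
    allo_subset = [("allo", b) for b in frame.conspecifics]
    try:
        fit_ego = fit_encoding_model(
            frame, ego_subset, counts, config=config, builder=builder
        )
        fit_allo = fit_encoding_model(
            frame, allo_subset, counts, config=config, builder=builder
        )
    except FitError as exc:
        return Classification(CLASS_NONE, float("nan"), None, None, str(exc))
    delta = fit_allo.dic - fit_ego.dic
    return Classification(dic_label(delta), delta, fit_ego, fit_allo)


def dic_label(delta_dic: float) -> str:
    """Map dDIC = DIC_allo - DIC_ego to a class label.

    The margin is strict: |dDIC| must exceed 10, so a difference of exactly
    10 stays unclassified.
    """
    if delta_dic > DIC_MARGIN:
        return CLASS_EGO
    if delta_dic < -DIC_MARGIN:
        return CLASS_ALLO
    return CLASS_NONE


# ---------------------------------------------------------------------------
# Shapley attribution
# ---------------------------------------------------------------------------


def shapley_from_values(values: dict[int, float], n: int) -> np.ndarray:
    """Exact Shapley values from a characteristic function over bitmasks.

    ``values[mask]`` is v(S) for the subset encoded by ``mask``; all 2^n
    masks must be present.  Uses the subset-weight form of the Shapley
    formula: phi_i = sum_S |S|! (n-|S|-1)! / n! [v(S+i) - v(S)].
    """
    fact = [math.factorial(i) for i in range(n + 1)]
    phi = np.zeros(n)
    for mask in range(1 << n):
        s = bin(mask).count("1")
        w = fact[s] * fact[n - s - 1] / fact[n]
        for i in range(n):
            if mask & (1 << i):
                continue
            phi[i] += w * (values[mask | (1 << i)] - values[mask])
    return phi


@dataclass
class ShapleyAttribution:
    """Explained-deviance Shapley attribution over angle/distance variables."""

    host: str
    variables: list[tuple[str, str]]
    phi: np.ndarray
    v_full: float
    v_empty: float
    top_angle_bat: str
    top_distance_bat: str

    def phi_of(self, kind: str, bat: str) -> float:
        return float(self.phi[self.variables.index((kind, bat))])


def shapley_attribution(
    frame: CovariateFrame,
    counts: np.ndarray,
    *,
    config: BasisConfig = BasisConfig(),
    builder: DesignBuilder | None = None,
) -> ShapleyAttribution:
    """Exhaustive Shapley attribution of explained deviance.

    The characteristic function of a variable subset S is the explained-
    deviance fraction of the model (baseline + S) relative to the baseline
    (intercept + own position): ``v(S) = max(0, 1 - dev(S)/dev(baseline))``.
    All 2^n subsets are fitted (n = 2 x conspecifics, capped at 14).
    """
    variables = [(k, b) for b in frame.conspecifics for k in ("angle", "dist")]
    n = len(variables)
    if n > MAX_SHAPLEY_VARS:
        raise ConfigError(
            f"{n} variables exceed the exhaustive-enumeration cap "
            f"({MAX_SHAPLEY_VARS}); reduce the conspecific set"
        )
    builder = builder or DesignBuilder(frame, config)
    base_dev = fit_encoding_model(
        frame, (), counts, config=config, builder=builder
    ).deviance
    values: dict[int, float] = {}
    for mask in range(1 << n):
        if mask == 0:
            values[0] = 0.0
            continue
        subset = [variables[i] for i in range(n) if mask & (1 << i)]
        dev = fit_encoding_model(
            frame, subset, counts, config=config, builder=builder
        ).deviance
        values[mask] = max(0.0, (base_dev - dev) / base_dev)
    phi = shapley_from_values(values, n)
    full = values[(1 << n) - 1]
    if abs(phi.sum() - full) > 1e-9:  # efficiency axiom, checked every run
        raise FitError(
            f"Shapley efficiency violated: sum(phi)={phi.sum()} vs v(full)={full}"
        )
    ang = {b: phi[variables.index(("angle", b))] for b in frame.conspecifics}
    dst = {b: phi[variables.index(("dist", b))] for b in frame.conspecifics}
    top_angle = max(sorted(ang), key=lambda b: ang[b])
    top_dist = max(sorted(dst), key=lambda b: dst[b])
    return ShapleyAttribution(
        frame.host, variables, phi, values[(1 << n) - 1], 0.0, top_angle, top_dist
    )


# ---------------------------------------------------------------------------
# Tuning curves
# ---------------------------------------------------------------------------


@dataclass
class TuningCurve:
    """Empirical binned firing-rate curve; preferred value = peak bin centre."""

    axis: str  # "angle" | "distance"
    bin_edges: np.ndarray
    rates: np.ndarray  # Hz, NaN for unvisited bins
    preferred: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def tuning_curve(
    frame: CovariateFrame,
    counts: np.ndarray,
    bat: str,
    axis: str,
    n_bins: int = 12,
) -> TuningCurve:
    """Empirical tuning to one conspecific's bearing or distance.

    Rate per bin = qualifying spikes / occupancy time; bins never visited
    get NaN and cannot be preferred.  The angle axis is circular (the first
    and last 30 deg bins are adjacent).
    """
    j = frame.conspecifics.index(bat)
    pres = frame.present[:, j]
    if axis == "angle":
        x = frame.theta[pres, j]
        edges = np.linspace(-180.0, 180.0, n_bins + 1)
    elif axis == "distance":
        x = frame.dist[pres, j]
        edges = np.linspace(0.0, frame.net_diagonal, n_bins + 1)
    else:
        raise ConfigError(f"unknown tuning axis {axis!r}")
    y = np.asarray(counts, float)[pres]
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    spikes = np.bincount(idx, weights=y, minlength=n_bins)
    occ = np.bincount(idx, minlength=n_bins) * frame.bin_width
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(occ > 0, spikes / occ, np.nan)
    peak = int(np.nanargmax(rates))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return TuningCurve(axis, edges, rates, float(centers[peak]))


# ---------------------------------------------------------------------------
# Population analysis
# ---------------------------------------------------------------------------


@dataclass
class NeuronSummary:
    """Per-neuron record feeding the population statistics."""

    neuron_id: str
    host: str
    label: str
    delta_dic: float
    top_angle_bat: str = ""
    top_distance_bat: str = ""
    phi_angle: float = float("nan")
    phi_distance: float = float("nan")
    preferred_angle: float = float("nan")
    preferred_distance: float = float("nan")


def summarize_neuron(
    neuron_id: str,
    frame: CovariateFrame,
    counts: np.ndarray,
    *,
    config: BasisConfig = BasisConfig(),
) -> NeuronSummary:
    """Classify one neuron and, if egocentric, attribute and extract tuning."""
    builder = DesignBuilder(frame, config)
    cls = classify_neuron(frame, counts, config=config, builder=builder)
    out = NeuronSummary(neuron_id, frame.host, cls.label, cls.delta_dic)
    if cls.label != CLASS_EGO:
        return out
    attr = shapley_attribution(frame, counts, config=config, builder=builder)
    out.top_angle_bat = attr.top_angle_bat
    out.top_distance_bat = attr.top_distance_bat
    out.phi_angle = attr.phi_of("angle", attr.top_angle_bat)
    out.phi_distance = attr.phi_of("dist", attr.top_distance_bat)
    out.preferred_angle = tuning_curve(
        frame, counts, attr.top_angle_bat, "angle"
    ).preferred
    out.preferred_distance = tuning_curve(
        frame, counts, attr.top_distance_bat, "distance"
    ).preferred
    return out


def delta_elo_class(delta: float) -> str:
    """Hierarchy class of a conspecific relative to the host by Delta-Elo."""
    if delta < -DELTA_ELO_CLASS_EDGE:
        return "lower"
    if delta > DELTA_ELO_CLASS_EDGE:
        return "higher"
    return "similar"


def tuning_and_population(
    summaries: list[NeuronSummary],
    elo: EloState,
    sexes: dict[str, str],
    *,
    d_max: float | None = None,
    min_population: int = 5,
) -> dict[str, object]:
    """Population statistics over egocentric neurons.

    Emits: KS of top-angle vs top-distance Shapley values; Kuiper test of
    preferred angles vs circular uniform; chi-square of preferred distances
    vs uniform over 12 bins; signed-rank front-vs-back test on
    (90 - |preferred angle|); Delta-Elo 3-class chi-squares for top-angle
    and top-distance bats; and sex splits (male vs female targets, same vs
    opposite sex) via two-sample Kuiper (angles) and KS (distances).
    With fewer than ``min_population`` egocentric neurons only the counts
    and class histograms are returned.
    """
    ego = [s for s in summaries if s.label == CLASS_EGO]
    report: dict[str, object] = {
        "n_total": len(summaries),
        "n_egocentric": len(ego),
        "n_allocentric": sum(s.label == CLASS_ALLO for s in summaries),
        "n_unclassified": sum(s.label == CLASS_NONE for s in summaries),
    }
    if not ego:
        raise DataError("no egocentric neurons in the population")
    classes_angle = [
        delta_elo_class(elo.ratings[s.top_angle_bat] - elo.ratings[s.host])
        for s in ego
    ]
    classes_dist = [
        delta_elo_class(elo.ratings[s.top_distance_bat] - elo.ratings[s.host])
        for s in ego
    ]
    order = ["lower", "similar", "higher"]
    report["delta_elo_hist_angle"] = {
        c: classes_angle.count(c) for c in order
    }
    report["delta_elo_hist_distance"] = {
        c: classes_dist.count(c) for c in order
    }
    pref_angles = np.array([s.preferred_angle for s in ego])
    pref_dists = np.array([s.preferred_distance for s in ego])
    report["preferred_angles"] = pref_angles
    report["preferred_distances"] = pref_dists
    report["front_fraction"] = float(np.mean(np.abs(pref_angles) < 90.0))
    if len(ego) < min_population:
        return report

    dmax = d_max or math.hypot(0.8, 0.4)

    def _try(fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except (InsufficientSampleError, ValidationError):
            return None

    report["shapley_ks"] = _try(
        ks_two_sample, [s.phi_angle for s in ego], [s.phi_distance for s in ego]
    )
    report["angle_kuiper"] = _try(kuiper_uniform, pref_angles)
    report["distance_chi2"] = _try(chi2_uniform, pref_dists, 12, (0.0, dmax))
    report["front_back_signed_rank"] = _try(_front_back_test, pref_angles)
    report["delta_elo_chi2_angle"] = chi2_counts(
        [classes_angle.count(c) for c in order]
    )
    report["delta_elo_chi2_distance"] = chi2_counts(
        [classes_dist.count(c) for c in order]
    )
    report.update(_sex_splits(ego, sexes))
    return report


def _front_back_test(pref_angles: np.ndarray) -> StatResult:
    """Signed-rank test of whether preferred angles favour the front.

    The paired quantity is (90 - |preferred angle|) degrees against zero:
    positive for front-hemicircle neurons, negative for back.
    """
    return wilcoxon(90.0 - np.abs(pref_angles), mode="signed_rank")


def _sex_splits(ego: list[NeuronSummary], sexes: dict[str, str]) -> dict:
    out: dict[str, object] = {}
    ang_m = [s.preferred_angle for s in ego if sexes[s.top_angle_bat] == "male"]
    ang_f = [s.preferred_angle for s in ego if sexes[s.top_angle_bat] == "female"]
    ang_same = [
        s.preferred_angle for s in ego if sexes[s.top_angle_bat] == sexes[s.host]
    ]
    ang_opp = [
        s.preferred_angle for s in ego if sexes[s.top_angle_bat] != sexes[s.host]
    ]
    d_m = [s.preferred_distance for s in ego if sexes[s.top_distance_bat] == "male"]
    d_f = [s.preferred_distance for s in ego if sexes[s.top_distance_bat] == "female"]
    d_same = [
        s.preferred_distance for s in ego if sexes[s.top_distance_bat] == sexes[s.host]
    ]
    d_opp = [
        s.preferred_distance for s in ego if sexes[s.top_distance_bat] != sexes[s.host]
    ]
    for key, (a, b, kind) in {
        "angle_male_vs_female": (ang_m, ang_f, "kuiper"),
        "angle_same_vs_opposite": (ang_same, ang_opp, "kuiper"),
        "distance_male_vs_female": (d_m, d_f, "ks"),
        "distance_same_vs_opposite": (d_same, d_opp, "ks"),
    }.items():
        if min(len(a), len(b)) < 5:
            out[key] = None
            continue
        out[key] = (
            kuiper_two_sample(a, b) if kind == "kuiper" else ks_two_sample(a, b)
        )
    return out
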