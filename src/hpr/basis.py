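"""Response-function basis sets for heart-period response modelling.

The canonical heart period response function (HPRF) describes the
CS+ minus CS− difference in heart period after a fear-conditioned
stimulus as a gamma density

    h(x) = A / (theta^k Gamma(k)) * (x - x0)^(k-1) * exp(-(x - x0)/theta)

with shape ``k``, scale ``theta`` (s), onset shift ``x0`` (s) and
amplitude ``A`` left free in the GLM. Four published parameter rows are
available by name (:data:`CANONICAL_PARAMS`); the combined-sample
optimized row is the default for new studies. The parameterisation is
strongly degenerate — very different (k, theta, x0) triplets yield
near-identical curves — so shapes, not parameters, should be compared.

Basis sets:

* ``G1`` — canonical HPRF only;
* ``G2`` — canonical + its analytic time derivative (absorbs
  between-subject peak-latency variation);
* ``G3`` — G2 + an early stimulus-processing response;
* ``S1`` — CS− baseline response + canonical (the canonical then
  reflects the CS+/CS− difference).

The early-response and CS− baseline components are not analytically
specified here; they ship as versioned synthetic stand-in fixtures
(``data/*_synthetic.tsv``) generated by :mod:`hpr.synthetic`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
from scipy import optimize
from scipy.stats import gamma as gamma_dist

from .exceptions import FitError, IllPosedError, InvalidParamsError, ValidationError

__all__ = [
    "GammaParams",
    "BasisFunction",
    "BasisSet",
    "GaussianInputParams",
    "CANONICAL_PARAMS",
    "DEFAULT_PARAMS_NAME",
    "gamma_rf",
    "derivative_rf",
    "make_basis_set",
    "fit_rf",
    "lock_to_us",
    "shift_basis",
    "reconstruct_input",
    "load_fixture",
]

#: epoch grid defaults shared with hp_series
DEFAULT_FS = 10.0
DEFAULT_DURATION = 11.0
#: SOA at which the canonical shape was derived (s)
REFERENCE_SOA = 3.5


@dataclass(frozen=True)
class GammaParams:
    """Gamma-density parameters of the canonical HPRF.

    ``k`` shape (dimensionless, > 1 for a unimodal response),
    ``theta`` scale (s), ``x0`` onset shift (s), ``A`` amplitude
    (ms·s; free in the GLM, kept at 1 for basis construction).
    """

    k: float
    theta: float
    x0: float
    A: float = 1.0

    def __post_init__(self) -> None:
        if self.k <= 1:
            raise InvalidParamsError(f"shape k must exceed 1, got {self.k}")
        if self.theta <= 0:
            raise InvalidParamsError(f"scale theta must be positive, got {self.theta}")

    @property
    def mode(self) -> float:
        """Closed-form peak latency x0 + (k-1)*theta (s after CS onset)."""
        return self.x0 + (self.k - 1.0) * self.theta


#: published parameter rows for the canonical HPRF, by dataset of origin
CANONICAL_PARAMS: dict[str, GammaParams] = {
    "dataset1": GammaParams(k=2.56e5, theta=2.26e-3, x0=-574.0),
    "dataset1_optimized": GammaParams(k=1.37e3, theta=3.11e-2, x0=-38.0),
    "dataset12": GammaParams(k=43.2, theta=0.196, x0=-3.47),
    "dataset12_optimized": GammaParams(k=48.5, theta=0.182, x0=-3.86),
}

#: combined-sample, filter-optimized row — recommended for new studies
DEFAULT_PARAMS_NAME = "dataset12_optimized"


@dataclass(frozen=True)
class BasisFunction:
    """A response-function component sampled on the epoch grid."""

    samples: np.ndarray
    kind: str  # canonical | derivative | early | cs_minus_baseline
    fs: float
    norm: float = 1.0  # peak-absolute-value scaling that was divided out
    params: GammaParams | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not np.all(np.isfinite(samples)):
            raise ValidationError("basis samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class BasisSet:
    """Ordered basis functions forming one of the models G1/G2/G3/S1."""

    functions: tuple[BasisFunction, ...]
    model_id: str
    lock: str = "cs"
    reference_soa: float = REFERENCE_SOA
    us_shift: float = 0.0  # applied shift (s) when lock == "us"

    @property
    def fs(self) -> float:
        return self.functions[0].fs

    @property
    def kinds(self) -> tuple[str, ...]:
        return tuple(f.kind for f in self.functions)


@dataclass(frozen=True)
class GaussianInputParams:
    """Gaussian autonomic-input estimate: centre mu (s after CS onset),
    width sigma (s), and gain."""

    mu: float
    sigma: float
    gain: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise InvalidParamsError("sigma must be positive")
        if self.mu < 0:
            raise InvalidParamsError("mu must be >= 0 (input cannot precede CS onset)")


def _grid(fs: float, duration: float) -> np.ndarray:
    return np.arange(int(round(duration * fs))) / fs


def _gamma_pdf(x: np.ndarray, p: GammaParams) -> np.ndarray:
    return p.A * gamma_dist.pdf(x, p.k, loc=p.x0, scale=p.theta)


def gamma_rf(
    params: GammaParams,
    fs: float = DEFAULT_FS,
    duration: float = DEFAULT_DURATION,
    normalize: bool = True,
) -> BasisFunction:
    """Sample the canonical gamma response function on the epoch grid.

    With ``normalize=True`` (default) the samples are divided by their
    peak absolute value, which is recorded in ``norm``; the GLM
    amplitude then scales inversely and fitted reconstructions are
    unchanged.

    Raises
    ------
    InvalidParamsError
        If the gamma mode x0 + (k-1)*theta lies outside (0, duration).
    """
    mode = params.mode
    if not (0.0 < mode < duration):
        raise InvalidParamsError(
            f"gamma mode {mode:.3f}s outside (0, {duration})s epoch window"
        )
    x = _grid(fs, duration)
    y = _gamma_pdf(x, params)
    norm = 1.0
    if normalize:
        norm = float(np.max(np.abs(y)))
        if norm == 0:
            raise InvalidParamsError("response function is identically zero on the grid")
        y = y / norm
    return BasisFunction(samples=y, kind="canonical", fs=fs, norm=norm, params=params)


def derivative_rf(canonical: BasisFunction) -> BasisFunction:
    """Analytic time derivative of a canonical gamma basis function.

    d/dx of the gamma density equals pdf(x) * ((k-1)/(x-x0) - 1/theta);
    computing it analytically keeps the component grid-independent.
    The result is peak-normalized.
    """
    if canonical.kind != "canonical" or canonical.params is None:
        raise ValidationError("derivative_rf needs a canonical basis function with params")
    p = canonical.params
    x = canonical.times
    pdf = _gamma_pdf(x, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = (p.k - 1.0) / (x - p.x0) - 1.0 / p.theta
    d = np.where(x > p.x0, pdf * np.where(np.isfinite(factor), factor, 0.0), 0.0)
    norm = float(np.max(np.abs(d)))
    if norm == 0:
        raise ValidationError("derivative is identically zero on the grid")
    return BasisFunction(samples=d / norm, kind="derivative", fs=canonical.fs, norm=norm, params=p)


# ---------------------------------------------------------------------------
# fixture components (early response, CS- baseline, brief-stimulus RF)
# ---------------------------------------------------------------------------


def load_fixture(kind: str, fs: float = DEFAULT_FS, duration: float = DEFAULT_DURATION) -> BasisFunction:
    """Load a shipped basis-component fixture, resampled to the epoch grid.

    ``kind`` is one of ``early``, ``cs_minus_baseline`` or
    ``brief_stimulus`` (the prior response function to brief stimuli
    used for autonomic-input reconstruction). All three are synthetic
    stand-ins generated by :func:`hpr.synthetic.fixture_curve`.
    """
    names = {
        "early": "early_response_synthetic.tsv",
        "cs_minus_baseline": "cs_minus_baseline_synthetic.tsv",
        "brief_stimulus": "brief_stimulus_rf_synthetic.tsv",
    }
    if kind not in names:
        raise ValidationError(f"unknown fixture kind {kind!r}")
    ref = resources.files("hpr.data").joinpath(names[kind])
    rows = [
        line.split("\t")
        for line in ref.read_text().strip().splitlines()
        if line and not line.startswith("time")
    ]
    t = np.array([float(r[0]) for r in rows])
    v = np.array([float(r[1]) for r in rows])
    x = _grid(fs, duration)
    y = np.interp(x, t, v, left=0.0, right=0.0)
    norm = float(np.max(np.abs(y))) or 1.0
    return BasisFunction(samples=y / norm, kind=kind if kind != "brief_stimulus" else "canonical",
                         fs=fs, norm=norm)


_MODEL_KINDS = {
    "G1": ("canonical",),
    "G2": ("canonical", "derivative"),
    "G3": ("canonical", "derivative", "early"),
    "S1": ("cs_minus_baseline", "canonical"),
}


def make_basis_set(
    model_id: str = "G2",
    lock: str = "cs",
    params: str | GammaParams = DEFAULT_PARAMS_NAME,
    fs: float = DEFAULT_FS,
    duration: float = DEFAULT_DURATION,
) -> BasisSet:
    """Construct one of the model basis sets G1, G2, G3 or S1."""
    if model_id not in _MODEL_KINDS:
        raise ValidationError(f"unknown model {model_id!r}; choose from {sorted(_MODEL_KINDS)}")
    if lock not in ("cs", "us"):
        raise ValidationError(f"lock must be 'cs' or 'us', got {lock!r}")
    gp = CANONICAL_PARAMS[params] if isinstance(params, str) else params
    canonical = gamma_rf(gp, fs=fs, duration=duration)
    parts: list[BasisFunction] = []
    for kind in _MODEL_KINDS[model_id]:
        if kind == "canonical":
            parts.append(canonical)
        elif kind == "derivative":
            parts.append(derivative_rf(canonical))
        else:
            parts.append(load_fixture(kind, fs=fs, duration=duration))
    return BasisSet(functions=tuple(parts), model_id=model_id, lock=lock)


def shift_basis(bf: BasisFunction, shift: float) -> BasisFunction:
    """Time-shift a basis function by ``shift`` seconds (zero-padded)."""
    x = bf.times
    shifted = np.interp(x - shift, x, bf.samples, left=0.0, right=0.0)
    return replace(bf, samples=shifted)


def lock_to_us(bset: BasisSet, trial_soa: float) -> BasisSet:
    """Re-lock a CS-locked basis set to the (anticipated) US onset.

    The response shape is unchanged — LTI time invariance — and merely
    shifted by ``trial_soa - reference_soa``, the amount by which the
    session's US time differs from the SOA at which the canonical
    shape was derived.
    """
    if bset.lock != "cs":
        raise ValidationError("lock_to_us expects a CS-locked basis set")
    shift = trial_soa - bset.reference_soa
    funcs = tuple(shift_basis(f, shift) for f in bset.functions)
    for f in bset.functions:
        if f.params is not None and f.params.mode + shift >= funcs[0].times[-1]:
            import warnings

            warnings.warn("US-locked shift pushes the response mode past the epoch end")
    return BasisSet(
        functions=funcs,
        model_id=bset.model_id,
        lock="us",
        reference_soa=bset.reference_soa,
        us_shift=shift,
    )


# ---------------------------------------------------------------------------
# gamma fit to an observed difference waveform
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RfFit:
    """Result of fitting the gamma HPRF to a difference waveform."""

    params: GammaParams
    rss: float
    degenerate: bool = False
    grid_rss: float = field(default=np.inf, repr=False)


def fit_rf(
    diff_waveform: np.ndarray,
    fs: float = DEFAULT_FS,
    duration: float = DEFAULT_DURATION,
) -> RfFit:
    """Least-squares fit of the gamma HPRF to a CS+ minus CS− waveform.

    The 4-parameter gamma fit is strongly degenerate in (k, theta, x0),
    so optimisation starts from the best point of a deterministic
    coarse grid over peak latency (3–7 s), response width (0.5–3 s SD)
    and shape, then refines with bounded least squares in
    (log k, log theta, x0, A). Recovery should be judged on mode,
    width and amplitude, not on raw parameters.

    Returns an :class:`RfFit`; an all-zero input yields
    ``degenerate=True`` with A = 0.
    """
    y = np.asarray(diff_waveform, dtype=float)
    x = _grid(fs, duration)
    if y.shape != x.shape:
        raise ValidationError(f"waveform length {y.size} does not match the {duration}s/{fs}Hz grid")
    peak = float(np.max(np.abs(y)))
    if peak == 0.0 or not np.isfinite(peak):
        return RfFit(
            params=GammaParams(k=40.0, theta=0.2, x0=-3.0, A=0.0),
            rss=float(y @ y),
            degenerate=True,
        )

    def shape_only(k: float, theta: float, x0: float) -> np.ndarray:
        return gamma_dist.pdf(x, k, loc=x0, scale=theta)

    # deterministic coarse grid initialisation
    best = None
    for mode in (3.0, 4.0, 5.0, 6.0, 7.0):
        for width in (0.5, 1.0, 1.5, 2.0, 3.0):
            for k in (5.0, 20.0, 60.0, 200.0):
                theta = width / np.sqrt(k)
                x0 = mode - (k - 1.0) * theta
                g = shape_only(k, theta, x0)
                gg = float(g @ g)
                if gg == 0:
                    continue
                a = float(g @ y) / gg
                rss = float(np.sum((y - a * g) ** 2))
                if best is None or rss < best[0]:
                    best = (rss, k, theta, x0, a)
    if best is None:
        raise FitError("no valid grid initialisation found")
    grid_rss, k0, th0, x00, a0 = best

    def residual(p: np.ndarray) -> np.ndarray:
        k, theta, x0, a = np.exp(p[0]), np.exp(p[1]), p[2], p[3]
        return a * shape_only(k, theta, x0) - y

    try:
        sol = optimize.least_squares(
            residual,
            x0=np.array([np.log(k0), np.log(th0), x00, a0]),
            bounds=(
                [np.log(1.01), np.log(1e-6), -1000.0, -np.inf],
                [np.log(1e7), np.log(100.0), 10.0, np.inf],
            ),
            method="trf",
        )
    except Exception as exc:  # pragma: no cover - scipy failure path
        raise FitError(f"gamma fit failed: {exc}") from exc
    rss_opt = float(2.0 * sol.cost)
    if rss_opt <= grid_rss:
        k, theta, x0, a = np.exp(sol.x[0]), np.exp(sol.x[1]), sol.x[2], sol.x[3]
    else:  # optimizer wandered; keep the grid optimum
        k, theta, x0, a, rss_opt = k0, th0, x00, a0, grid_rss
    return RfFit(
        params=GammaParams(k=float(k), theta=float(theta), x0=float(x0), A=float(a)),
        rss=rss_opt,
        degenerate=abs(a) < 1e-12 * peak,
        grid_rss=grid_rss,
    )


# ---------------------------------------------------------------------------
# autonomic input reconstruction
# ---------------------------------------------------------------------------


def _convolve_same_grid(g: np.ndarray, h: np.ndarray, dt: float) -> np.ndarray:
    """Discrete approximation of (g * h)(t) on g's grid."""
    return np.convolve(g, h)[: g.size] * dt


def reconstruct_input(
    observed_rf: BasisFunction,
    prior_rf: BasisFunction,
    mu_max: float = 11.0,
) -> GaussianInputParams:
    """Estimate the Gaussian autonomic input driving an observed response.

    Solves, by ordinary least squares, for (mu, sigma, gain) such that
    ``gaussian(mu, sigma, gain) * prior_rf`` (convolution) best matches
    ``observed_rf``. ``mu`` is constrained >= 0 so the input cannot
    precede the CS onset.
    """
    if observed_rf.fs != prior_rf.fs or observed_rf.samples.size != prior_rf.samples.size:
        raise ValidationError("observed and prior RFs must share one grid")
    h = prior_rf.samples
    y = observed_rf.samples
    if float(np.max(np.abs(h))) < 1e-12:
        raise IllPosedError("prior response function is ~0; deconvolution is ill-posed")
    x = observed_rf.times
    dt = 1.0 / observed_rf.fs

    def model(mu: float, sigma: float, gain: float) -> np.ndarray:
        g = gain * np.exp(-0.5 * ((x - mu) / sigma) ** 2)
        return _convolve_same_grid(g, h, dt)

    def residual(p: np.ndarray) -> np.ndarray:
        return model(p[0], p[1], p[2]) - y

    mu0 = max(float(x[np.argmax(np.abs(y))] - x[np.argmax(np.abs(h))]), 0.1)
    unit = _convolve_same_grid(np.exp(-0.5 * ((x - mu0) / 1.0) ** 2), h, dt)
    gain0 = float(unit @ y) / max(float(unit @ unit), 1e-30)
    sol = optimize.least_squares(
        residual,
        x0=np.array([mu0, 1.0, gain0]),
        bounds=([0.0, 1e-3, -np.inf], [mu_max, 10.0, np.inf]),
        method="trf",
    )
    return GaussianInputParams(mu=float(sol.x[0]), sigma=float(sol.x[1]), gain=float(sol.x[2]))
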