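"""Diffusion + dark-state model for FCS curves and its weighted fit.

The fitted model is the 3D Brownian-diffusion correlation with a single
dark-state (blinking) term,

    G(tau) = (1/N) [1 + T_ds/(1 - T_ds) exp(-tau/tau_ds)]
             sum_i alpha_i (1 + tau/tau_D,i)^-1 (1 + tau/(kappa^2 tau_D,i))^-1/2

with the structure parameter kappa fixed at 1 for the aperture
observation volume.  One species (i = 1) describes free diffusion; in the
presence of surface adhesion a second, slow species is added and its
relative amplitude alpha_slow is the sticking metric: absence of sticking
drives the fast amplitude toward 100% and the slow amplitude toward 0%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import lmfit
import numpy as np

from .correlate import CorrelationCurve

__all__ = [
    "FCSModelParams",
    "FCSFitResult",
    "FCSFitError",
    "eval_fcs_model",
    "fit_fcs",
    "sticking_fractions",
    "molecules_and_brightness",
]

KAPPA = 1.0  # axial/lateral aspect ratio of the observation volume; fixed

# physically plausible bounds bracketing the relevant time scales; the
# dark state is a fast microsecond-scale process (cis/triplet), so its
# term is confined there lest it absorb the diffusion decay
BOUNDS = {
    "N": (1e-6, 1e4),
    "T_ds": (0.0, 0.8),
    "tau_ds": (1e-7, 1e-5),
    "tau_d": (1e-6, 10.0),
    # the slow species models surface-adhesion dwells, which produce
    # spikes longer than 100 ms; keep it out of the diffusion regime
    "tau_d_slow": (1e-2, 10.0),
}


@dataclass
class FCSModelParams:
    """Parameters of the diffusion + blinking correlation model.

    ``species`` lists (amplitude fraction, diffusion time s) ordered
    fast to slow; fractions sum to 1.
    """

    N: float
    species: list[tuple[float, float]]
    T_ds: float = 0.0
    tau_ds: float = 1e-5
    kappa: float = KAPPA

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("N must be positive")
        if not 0.0 <= self.T_ds < 1.0:
            raise ValueError("T_ds must be in [0, 1)")
        if self.tau_ds <= 0:
            raise ValueError("tau_ds must be positive")
        if not self.species:
            raise ValueError("at least one species required")
        alphas = np.array([a for a, _ in self.species])
        taus = np.array([t for _, t in self.species])
        if np.any(alphas < 0) or not np.isclose(alphas.sum(), 1.0, atol=1e-8):
            raise ValueError("species fractions must be >= 0 and sum to 1")
        if np.any(taus <= 0) or np.any(np.diff(taus) <= 0):
            raise ValueError("diffusion times must be positive and strictly increasing")

    @property
    def n_species(self) -> int:
        return len(self.species)


def eval_fcs_model(tau, params: FCSModelParams):
    """Evaluate G(tau); accepts scalar or array lag times (s)."""
    tau = np.asarray(tau, float)
    if np.any(tau < 0):
        raise ValueError("lags must be >= 0")
    blink = 1.0
    if params.T_ds > 0:
        blink = 1.0 + params.T_ds / (1.0 - params.T_ds) * np.exp(-tau / params.tau_ds)
    diff = np.zeros_like(tau, dtype=float)
    for alpha, tau_d in params.species:
        diff = diff + alpha / (
            (1.0 + tau / tau_d) * np.sqrt(1.0 + tau / (params.kappa**2 * tau_d))
        )
    out = blink * diff / params.N
    return float(out) if out.ndim == 0 else out


@dataclass
class FCSFitResult:
    """Converged fit with derived molecule-number / sticking metrics."""

    params: FCSModelParams
    stderr: dict = field(default_factory=dict)
    redchi: float = float("nan")
    n_species: int = 1
    mean_rate: float = 0.0
    success: bool = True
    message: str = ""

    @property
    def molecule_number(self) -> float:
        return self.params.N

    @property
    def diffusion_time(self) -> float:
        """Diffusion time of the fast species (s)."""
        return self.params.species[0][1]

    @property
    def brightness(self) -> float:
        """Counts/s per molecule from the mean rate and fitted N."""
        return self.mean_rate / self.params.N

    @property
    def fast_fraction(self) -> float:
        return 100.0 * self.params.species[0][0]

    @property
    def slow_fraction(self) -> float:
        if self.params.n_species < 2:
            return 0.0
        return 100.0 * sum(a for a, _ in self.params.species[1:])

    def to_dict(self) -> dict:
        return {
            "N": self.params.N,
            "T_ds": self.params.T_ds,
            "tau_ds": self.params.tau_ds,
            "kappa": self.params.kappa,
            "species": [list(s) for s in self.params.species],
            "stderr": self.stderr,
            "redchi": self.redchi,
            "n_species": self.n_species,
            "mean_rate": self.mean_rate,
            "fast_fraction": self.fast_fraction,
            "slow_fraction": self.slow_fraction,
            "diffusion_time": self.diffusion_time,
            "brightness": self.brightness,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


class FCSFitError(RuntimeError):
    """Fit failed to converge; carries the best attempt for diagnostics."""

    def __init__(self, message: str, best: FCSFitResult | None = None):
        super().__init__(message)
        self.best = best


def _init_from_curve(curve: CorrelationCurve) -> tuple[float, float]:
    """(N0, tau_D0) from the amplitude and half-decay lag of the curve."""
    g0 = float(np.median(curve.g[: max(1, min(3, len(curve.g)))]))
    g0 = max(g0, 1e-4)
    n0 = 1.0 / g0
    half = g0 / 2.0
    below = np.nonzero(curve.g <= half)[0]
    tau0 = float(curve.lags[below[0]]) if len(below) else float(curve.lags[len(curve.lags) // 2])
    return n0, max(tau0, float(curve.lags[0]))


def _params_from_lmfit(p: lmfit.Parameters, n_species: int) -> FCSModelParams:
    if n_species == 1:
        species = [(1.0, p["tau_d1"].value)]
    else:
        a2 = p["alpha2"].value
        sp = [(1.0 - a2, p["tau_d1"].value), (a2, p["tau_d2"].value)]
        sp.sort(key=lambda s: s[1])
        species = sp
        # species closer than 1% in diffusion time collapse to one
        if species[1][1] / species[0][1] < 1.01:
            species = [(1.0, species[0][1])]
    return FCSModelParams(
        N=p["N"].value,
        species=species,
        T_ds=p["T_ds"].value,
        tau_ds=p["tau_ds"].value,
    )


def fit_fcs(
    curve: CorrelationCurve,
    n_species: int = 1,
    init: FCSModelParams | None = None,
    fit_blinking: bool = True,
    max_restarts: int = 5,
    restart_seed: int = 0,
) -> FCSFitResult:
    """Weighted least-squares fit of the correlation model (kappa fixed at 1).

    Uses the per-lag standard errors as weights (uniform where absent).
    On non-convergence the fit is retried from randomly perturbed starts
    up to ``max_restarts`` times; persistent failure raises
    :class:`FCSFitError` carrying the best attempt.
    """
    if n_species not in (1, 2):
        raise ValueError("n_species must be 1 or 2")
    lags = curve.lags
    if len(lags) < 8:
        raise ValueError("curve too short to fit")
    if lags[-1] / lags[0] < 100:
        raise ValueError("curve must span at least ~2-3 decades of lag")
    g = curve.g
    w = curve.weights.copy()
    good = w > 0
    if good.any():
        w[~good] = w[good].min()
        sigma = np.maximum(w, 1e-3 * np.abs(g).max())
    else:
        sigma = np.ones_like(g)

    n0, tau0 = _init_from_curve(curve)
    if init is not None:
        n0 = init.N
        tau0 = init.species[0][1]

    def make_params(rng: np.random.Generator | None) -> lmfit.Parameters:
        p = lmfit.Parameters()
        jit = (lambda: rng.uniform(0.6, 1.7)) if rng is not None else (lambda: 1.0)
        p.add("N", value=n0 * jit(), min=BOUNDS["N"][0], max=BOUNDS["N"][1])
        p.add(
            "T_ds",
            value=(init.T_ds if init is not None else 0.1),
            min=BOUNDS["T_ds"][0],
            max=BOUNDS["T_ds"][1],
            vary=fit_blinking,
        )
        p.add(
            "tau_ds",
            value=(init.tau_ds if init is not None else 3e-6) * jit(),
            min=BOUNDS["tau_ds"][0],
            max=BOUNDS["tau_ds"][1],
            vary=fit_blinking,
        )
        p.add("tau_d1", value=tau0 * jit(), min=BOUNDS["tau_d"][0], max=BOUNDS["tau_d"][1])
        if n_species == 2:
            if init is not None and init.n_species == 2:
                a2, t2 = init.species[1]
            else:
                a2, t2 = 0.15, max(200 * tau0, 0.05)
            lo, hi = BOUNDS["tau_d_slow"]
            p.add("alpha2", value=min(max(a2, 0.01), 0.9), min=0.0, max=1.0)
            p.add("tau_d2", value=min(max(t2 * jit(), lo * 2), hi / 2), min=lo, max=hi)
        return p

    def residual(p: lmfit.Parameters) -> np.ndarray:
        blink = 1.0 + p["T_ds"] / (1.0 - p["T_ds"]) * np.exp(-lags / p["tau_ds"])
        diff = 1.0 / ((1.0 + lags / p["tau_d1"]) * np.sqrt(1.0 + lags / p["tau_d1"]))
        if n_species == 2:
            d2 = 1.0 / ((1.0 + lags / p["tau_d2"]) * np.sqrt(1.0 + lags / p["tau_d2"]))
            diff = (1.0 - p["alpha2"]) * diff + p["alpha2"] * d2
        model = blink * diff / p["N"]
        return (model - g) / sigma

    best = None
    rng = np.random.default_rng(restart_seed)
    for attempt in range(max_restarts + 1):
        params = make_params(rng if attempt else None)
        try:
            res = lmfit.minimize(residual, params, method="leastsq", nan_policy="raise")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
        if res.success and np.isfinite(res.chisqr):
            break
    if best is None:
        raise FCSFitError("FCS fit failed on every restart")
    stderr = {
        k: (v.stderr if v.stderr is not None else float("nan"))
        for k, v in best.params.items()
    }
    result = FCSFitResult(
        params=_params_from_lmfit(best.params, n_species),
        stderr=stderr,
        redchi=best.redchi,
        n_species=n_species,
        mean_rate=curve.mean_rate,
        success=bool(best.success),
        message=str(best.message),
    )
    if not best.success:
        raise FCSFitError(f"FCS fit did not converge: {best.message}", best=result)
    return result


def sticking_fractions(fit: FCSFitResult) -> tuple[float, float]:
    """(fast %, slow %) amplitude fractions; (100, 0) for a 1-species fit.

    The slow percentage is the adhesion metric: around 20% for a sticky
    dye on an uncoated aperture, near 0 with an effective passivation.
    """
    return fit.fast_fraction, fit.slow_fraction


def molecules_and_brightness(fit: FCSFitResult, curve: CorrelationCurve) -> tuple[float, float]:
    """(N, counts/s per molecule) from the fit and the curve's mean rate."""
    if fit.params.N <= 0:
        raise ValueError("fit carries non-positive N")
    return fit.params.N, curve.mean_rate / fit.params.N
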