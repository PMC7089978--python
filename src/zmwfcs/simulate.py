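"""Synthetic TTTR photon streams from a nanoaperture diffusion model.

The generator emulates the statistical structure of single-molecule
fluorescence inside a zero-mode waveguide (ZMW): labelled DNA diffusing
through an attoliter evanescent detection volume (diffusion-limited
bursts), rare long surface-adsorption events producing fluorescence
spikes exceeding 100 ms, fast dark-state blinking, and excited-state
decays whose lifetime shortens for adsorbed molecules (metal quenching).

Model geometry
--------------
The aperture is a cylinder (diameter 110 nm, height 100 nm) with a
reflecting glass floor and reflecting metal side walls.  Detection weight
follows the evanescent excitation profile ``exp(-z / axial_decay_length)``
with a lateral top-hat across the aperture.  The simulated domain ends at
an exit plane two decay lengths above the aperture mouth, where the
detection weight has fallen below a percent: a molecule crossing the
plane upward is returned to the reservoir (deleted), and fresh molecules
enter through the plane as a Poisson flux at the equilibrium one-way
crossing rate of an ideal solution at the configured concentration
(grand-canonical boundary injection via a virtual slab above the plane).
This keeps the mean occupancy exactly at concentration x volume with
Poisson number statistics, and emulates the rapid three-dimensional
dilution above a real aperture: a molecule that escapes does not return
coherently.

Adsorption is a two-state phenomenological scheme: on each wall contact a
free molecule sticks with probability ``adsorption_prob_per_contact``;
adsorbed dwell times are exponential with mean ``adsorbed_dwell_mean``.
:func:`calibrate_adsorption` maps a target slow-component amplitude
fraction (the sticking metric reported by the FCS analysis) onto this
contact probability through the closed-form fluctuation-amplitude budget
of the free and adsorbed populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from numba import njit

from .photon_data import IRFModel, TTTRTrace

__all__ = [
    "SimulationConfig",
    "TrajectorySample",
    "simulate_trajectories",
    "generate_photon_stream",
    "simulate_experiment",
    "reference_intensity_trace",
    "number_density",
    "expected_molecules",
    "expected_count_rate",
    "expected_adsorbed_number",
    "expected_slow_fraction",
    "calibrate_adsorption",
    "NOMINAL_DIFFUSION_TIME",
    "NOMINAL_MOLECULE_NUMBER",
]

AVOGADRO = 6.02214076e23

#: Diffusion-time scale (s) and FCS-amplitude molecule number of the
#: default configuration, obtained by fitting the single-species
#: correlation model to the shot-noise-free detection-weighted occupancy
#: autocorrelation from :func:`reference_intensity_trace` (mean of five
#: 60 s realizations; see docs/methods.md).  The diffusion time scales
#: as 1/D at fixed geometry.
NOMINAL_DIFFUSION_TIME = 1.94e-4
NOMINAL_MOLECULE_NUMBER = 0.0377


def number_density(concentration_nM: float) -> float:
    """Molecules per nm^3 at a molar concentration given in nM."""
    return concentration_nM * 1e-9 * AVOGADRO / 1e24


@dataclass
class SimulationConfig:
    """Geometry, kinetics, photophysics and acquisition parameters.

    Lengths in nm, times in s unless suffixed otherwise; brightnesses in
    detected counts/s per molecule at the detection-profile maximum.
    """

    # geometry
    aperture_diameter: float = 110.0
    aperture_height: float = 100.0
    axial_decay_length: float = 30.0
    # transport / occupancy
    diffusion_coefficient: float = 30.0  # um^2/s (hindered in-pore mobility)
    concentration: float = 100.0  # nM
    n_molecules: int = 2  # closed-column (trajectory) mode only
    # photophysics
    brightness_free: float = 5e5
    brightness_adsorbed: float = 3.5e5
    dark_fraction: float = 0.15  # T_ds
    dark_lifetime: float = 2e-6  # tau_ds, s
    lifetime_free: float = 1.74  # ns (excited-state decay, in-aperture)
    lifetime_adsorbed: float = 0.8  # ns (metal-quenched)
    # adsorption kinetics
    adsorption_prob_per_contact: float = 0.0
    adsorbed_dwell_mean: float = 0.15  # s
    # acquisition
    irf: IRFModel = field(default_factory=lambda: IRFModel(fwhm_ps=110.0, center_ps=2500.0))
    sync_rate: float = 4e7
    duration: float = 60.0
    background_rate: float = 200.0  # counts/s, uniform microtimes
    rng_seed: int = 0
    # numerics
    max_rms_step: float = 5.0  # nm per axis; sets the fine time step
    time_step: float | None = None  # explicit override (required if D == 0)
    exit_margin: float = 60.0  # nm above the mouth where reservoir exchange occurs

    def __post_init__(self) -> None:
        if self.aperture_diameter <= 0 or self.aperture_height <= 0:
            raise ValueError("aperture dimensions must be positive")
        if self.axial_decay_length <= 0:
            raise ValueError("axial_decay_length must be positive")
        if self.diffusion_coefficient < 0:
            raise ValueError("diffusion_coefficient must be >= 0")
        if self.concentration <= 0 or self.n_molecules < 1:
            raise ValueError("need positive concentration and >= 1 molecule")
        if not 0.0 <= self.dark_fraction < 1.0:
            raise ValueError("dark_fraction must be in [0, 1)")
        if self.dark_lifetime <= 0 or self.adsorbed_dwell_mean <= 0:
            raise ValueError("kinetic time constants must be positive")
        if not 0.0 <= self.adsorption_prob_per_contact <= 1.0:
            raise ValueError("adsorption_prob_per_contact must be a probability")
        if self.duration <= 0 or self.sync_rate <= 0:
            raise ValueError("duration and sync_rate must be positive")
        if self.lifetime_free <= 0 or self.lifetime_adsorbed <= 0:
            raise ValueError("lifetimes must be positive")
        if self.time_step is not None and self.time_step <= 0:
            raise ValueError("time_step must be positive")
        if self.diffusion_coefficient == 0 and self.time_step is None:
            raise ValueError("time_step must be given explicitly when D == 0")

    # -- derived quantities --------------------------------------------
    @property
    def radius(self) -> float:
        return 0.5 * self.aperture_diameter

    @property
    def area(self) -> float:
        return math.pi * self.radius**2

    @property
    def diffusion_nm2_s(self) -> float:
        return self.diffusion_coefficient * 1e6

    @property
    def dt(self) -> float:
        """Fine integration step: RMS step per axis <= max_rms_step."""
        if self.time_step is not None:
            return self.time_step
        return self.max_rms_step**2 / (2.0 * self.diffusion_nm2_s)

    @property
    def step_sigma(self) -> float:
        """Per-axis RMS Brownian step (nm)."""
        return math.sqrt(2.0 * self.diffusion_nm2_s * self.dt)

    @property
    def density(self) -> float:
        """Number density in molecules / nm^3."""
        return number_density(self.concentration)

    @property
    def exit_plane(self) -> float:
        """Height of the reservoir-exchange plane (nm)."""
        return self.aperture_height + self.exit_margin

    @property
    def column_height(self) -> float:
        """Closed-column height (nm) holding n_molecules at concentration."""
        h = self.n_molecules / (self.density * self.area)
        if h < self.exit_plane:
            raise ValueError("concentration too high for n_molecules; increase n_molecules")
        return h

    @property
    def wall_area(self) -> float:
        """Adsorbing surface: aperture floor + side wall (nm^2)."""
        return self.area + 2.0 * math.pi * self.radius * self.aperture_height

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "irf"}
        if self.irf.fwhm_ps is not None:
            d["irf"] = {"fwhm_ps": self.irf.fwhm_ps, "center_ps": self.irf.center_ps}
        else:
            d["irf"] = {
                "channel_width": self.irf.histogram.channel_width,
                "counts": self.irf.histogram.counts.tolist(),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        irf = d.pop("irf", None)
        if irf is not None:
            if "fwhm_ps" in irf:
                d["irf"] = IRFModel(fwhm_ps=irf["fwhm_ps"], center_ps=irf.get("center_ps", 0.0))
            else:
                from .photon_data import TCSPCHistogram

                d["irf"] = IRFModel(
                    histogram=TCSPCHistogram(irf["channel_width"], np.asarray(irf["counts"]))
                )
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ----------------------------------------------------------------------
# Closed-form occupancy / amplitude budget
# ----------------------------------------------------------------------

def _profile_integrals(config: SimulationConfig) -> tuple[float, float]:
    """(integral of f, integral of f^2) over the simulated domain, nm^3."""
    d = config.axial_decay_length
    h = config.exit_plane
    v1 = config.area * d * (1.0 - math.exp(-h / d))
    v2 = config.area * 0.5 * d * (1.0 - math.exp(-2.0 * h / d))
    return v1, v2


def expected_molecules(config: SimulationConfig) -> float:
    """FCS-effective mean molecule number N = (C int f)^2 / (C int f^2)."""
    v1, v2 = _profile_integrals(config)
    return config.density * v1**2 / v2


def expected_count_rate(config: SimulationConfig, include_background: bool = True) -> float:
    """Expected detected count rate (counts/s)."""
    v1, _ = _profile_integrals(config)
    bright = 1.0 - config.dark_fraction
    rate = config.density * v1 * config.brightness_free * bright
    rate += (
        expected_adsorbed_number(config)
        * config.brightness_adsorbed
        * _wall_weight_moments(config)[0]
        * bright
    )
    if include_background:
        rate += config.background_rate
    return rate


def _wall_weight_moments(config: SimulationConfig) -> tuple[float, float]:
    """Mean of f and f^2 over the adsorbing surface (uniform contact flux)."""
    r, h, d = config.radius, config.aperture_height, config.axial_decay_length
    floor = config.area
    a = config.wall_area
    m1 = (floor + 2.0 * math.pi * r * d * (1.0 - math.exp(-h / d))) / a
    m2 = (floor + 2.0 * math.pi * r * 0.5 * d * (1.0 - math.exp(-2.0 * h / d))) / a
    return m1, m2


def _contact_rate(config: SimulationConfig) -> float:
    """Total wall-contact rate (contacts/s) of the free pool.

    For Brownian steps of per-axis RMS sigma, the one-way crossing flux
    through a plane is density * sigma / (sqrt(2 pi) dt) per unit area.
    """
    return (
        config.density
        * config.wall_area
        * config.step_sigma
        / (math.sqrt(2.0 * math.pi) * config.dt)
    )


def expected_adsorbed_number(config: SimulationConfig) -> float:
    """Steady-state mean number of adsorbed molecules."""
    return (
        config.adsorption_prob_per_contact
        * _contact_rate(config)
        * config.adsorbed_dwell_mean
    )


def expected_slow_fraction(config: SimulationConfig) -> float:
    """Amplitude fraction of the slow (adsorbed) component in the FCS fit.

    Fluctuation amplitudes add as (number) x (brightness x detection
    weight)^2 per population; the dark-state factor is common to both
    populations and cancels.
    """
    _, v2 = _profile_integrals(config)
    _, w2 = _wall_weight_moments(config)
    slow = expected_adsorbed_number(config) * config.brightness_adsorbed**2 * w2
    fast = config.density * v2 * config.brightness_free**2
    return slow / (slow + fast)


def calibrate_adsorption(config: SimulationConfig, slow_fraction: float) -> SimulationConfig:
    """Return a config whose contact probability targets a slow-amplitude fraction.

    ``slow_fraction`` is the expected relative amplitude of the slow FCS
    component (0.20 reproduces the heavy-sticking regime of an uncoated
    aperture; 0 disables adsorption).
    """
    if not 0.0 <= slow_fraction < 1.0:
        raise ValueError("slow_fraction must be in [0, 1)")
    if slow_fraction == 0.0:
        return replace(config, adsorption_prob_per_contact=0.0)
    _, v2 = _profile_integrals(config)
    _, w2 = _wall_weight_moments(config)
    n_ads = (
        slow_fraction
        / (1.0 - slow_fraction)
        * config.density
        * v2
        * config.brightness_free**2
        / (config.brightness_adsorbed**2 * w2)
    )
    p = n_ads / (_contact_rate(config) * config.adsorbed_dwell_mean)
    if p > 1.0:
        raise ValueError("target slow_fraction unreachable: contact probability > 1")
    return replace(config, adsorption_prob_per_contact=p)


# ----------------------------------------------------------------------
# Numba kernels
# ----------------------------------------------------------------------

_MAX_ACTIVE = 256


@njit(cache=True)
def _exchange_kernel(
    seed,
    n_steps,
    dt,
    sigma,
    radius,
    h_ap,
    z_exit,
    d_decay,
    lam_steps,
    init_mean,
    p_ads,
    p_des,
    p_bd,
    p_db,
    t_ds,
    rate_free,
    rate_ads,
    w_ads_scale,
    ph_time,
    ph_state,
    rec_weight,
    weight_stride,
    dwells,
):
    """Grand-canonical aperture simulation with boundary-flux injection.

    Molecules live in the cylinder 0 <= z <= z_exit; crossing the exit
    plane upward deletes them.  Entrants arrive as a Poisson process at
    the equilibrium one-way crossing rate (``lam_steps`` per step) with
    the overshoot depth distribution of Gaussian steps from a uniform
    half-space, sampled by stepping virtual molecules from a slab above
    the plane.  Steps with an empty aperture are skipped to the next
    arrival.  Returns (n_photons, n_dwells, truth[6]) where truth holds
    [int f dt free, int f^2 dt free, int f dt adsorbed, int f^2 dt
    adsorbed, adsorption events, adsorbed molecule-time].
    """
    np.random.seed(seed)
    cap = ph_time.shape[0]
    r2max = radius * radius
    xs = np.zeros(_MAX_ACTIVE)
    ys = np.zeros(_MAX_ACTIVE)
    zs = np.zeros(_MAX_ACTIVE)
    kin = np.zeros(_MAX_ACTIVE, np.int8)
    dark = np.zeros(_MAX_ACTIVE, np.int8)
    stick_t = np.zeros(_MAX_ACTIVE)
    n_act = 0
    # equilibrium initial population, uniform in the domain
    n0 = np.random.poisson(init_mean)
    for _ in range(min(n0, _MAX_ACTIVE - 1)):
        while True:
            x = np.random.uniform(-radius, radius)
            y = np.random.uniform(-radius, radius)
            if x * x + y * y <= r2max:
                break
        xs[n_act] = x
        ys[n_act] = y
        zs[n_act] = np.random.uniform(0.0, z_exit)
        kin[n_act] = 0
        dark[n_act] = 1 if np.random.random() < t_ds else 0
        n_act += 1
    count = 0
    n_dwell = 0
    truth = np.zeros(6)
    record_weight = weight_stride > 0
    step = 0
    next_inj = int(-math.log(np.random.random()) / lam_steps) if lam_steps > 0 else n_steps
    while step < n_steps:
        if n_act == 0:
            # empty aperture: nothing happens until the next arrival
            if next_inj >= n_steps:
                break
            step = next_inj
        while next_inj <= step:
            # entrant crosses the exit plane this step; sample the
            # overshoot depth by stepping a virtual molecule from the
            # uniform slab above the plane
            if n_act < _MAX_ACTIVE:
                while True:
                    z0 = np.random.uniform(0.0, 6.0 * sigma)
                    z1 = z0 + sigma * np.random.normal()
                    if z1 < 0.0:
                        break
                while True:
                    x = np.random.uniform(-radius, radius)
                    y = np.random.uniform(-radius, radius)
                    if x * x + y * y <= r2max:
                        break
                xs[n_act] = x
                ys[n_act] = y
                zs[n_act] = max(z_exit + z1, 0.0)
                kin[n_act] = 0
                dark[n_act] = 1 if np.random.random() < t_ds else 0
                stick_t[n_act] = 0.0
                n_act += 1
            next_inj += max(int(-math.log(np.random.random()) / lam_steps), 1) if lam_steps > 0 else n_steps
        # advance actives
        i = 0
        while i < n_act:
            if kin[i] == 1:
                # adsorbed: frozen at the wall, quenched emission, may desorb
                w = math.exp(-zs[i] / d_decay)
                truth[2] += w * dt
                truth[3] += w * w * dt
                truth[5] += dt
                stick_t[i] += dt
                if record_weight:
                    k = min(step // weight_stride, rec_weight.shape[0] - 1)
                    rec_weight[k] += w_ads_scale * w * dt
                if dark[i] == 0:
                    lam = rate_ads * w * dt
                    if lam > 0.0:
                        n = np.random.poisson(lam)
                        for _ in range(n):
                            if count < cap:
                                ph_time[count] = (step + np.random.random()) * dt
                                ph_state[count] = 1
                                count += 1
                    if np.random.random() < p_bd:
                        dark[i] = 1
                else:
                    if np.random.random() < p_db:
                        dark[i] = 0
                if np.random.random() < p_des:
                    kin[i] = 0
                    if n_dwell < dwells.shape[0]:
                        dwells[n_dwell] = stick_t[i]
                    n_dwell += 1
                    stick_t[i] = 0.0
                i += 1
                continue
            x = xs[i] + sigma * np.random.normal()
            y = ys[i] + sigma * np.random.normal()
            z = zs[i] + sigma * np.random.normal()
            if z > z_exit:
                # escape into the reservoir: remove (swap-delete)
                n_act -= 1
                xs[i] = xs[n_act]
                ys[i] = ys[n_act]
                zs[i] = zs[n_act]
                kin[i] = kin[n_act]
                dark[i] = dark[n_act]
                stick_t[i] = stick_t[n_act]
                continue
            adsorbed_now = False
            if z < 0.0:
                # floor contact
                if p_ads > 0.0 and np.random.random() < p_ads:
                    adsorbed_now = True
                    z = 0.0
                else:
                    z = -z
            r2 = x * x + y * y
            if r2 > r2max:
                r = math.sqrt(r2)
                if (not adsorbed_now) and z < h_ap and p_ads > 0.0 and np.random.random() < p_ads:
                    # side-wall contact below the film top
                    adsorbed_now = True
                    s = radius / r
                    x *= s
                    y *= s
                else:
                    rr = 2.0 * radius - r
                    if rr < 0.0:
                        rr = 0.0
                    s = rr / r
                    x *= s
                    y *= s
            if adsorbed_now:
                r2 = x * x + y * y
                if r2 > r2max:
                    s = radius / math.sqrt(r2)
                    x *= s
                    y *= s
                kin[i] = 1
                stick_t[i] = 0.0
                truth[4] += 1.0
            xs[i] = x
            ys[i] = y
            zs[i] = z
            w = math.exp(-z / d_decay)
            rate = rate_ads if adsorbed_now else rate_free
            if adsorbed_now:
                truth[2] += w * dt
                truth[3] += w * w * dt
                truth[5] += dt
            else:
                truth[0] += w * dt
                truth[1] += w * w * dt
            if record_weight:
                k = min(step // weight_stride, rec_weight.shape[0] - 1)
                rec_weight[k] += (w_ads_scale if adsorbed_now else 1.0) * w * dt
            if dark[i] == 0:
                lam = rate * w * dt
                if lam > 1e-12:
                    n = np.random.poisson(lam)
                    for _ in range(n):
                        if count < cap:
                            ph_time[count] = (step + np.random.random()) * dt
                            ph_state[count] = 1 if adsorbed_now else 0
                            count += 1
                if np.random.random() < p_bd:
                    dark[i] = 1
            else:
                if np.random.random() < p_db:
                    dark[i] = 0
            i += 1
        step += 1
    return count, n_dwell, truth


@njit(cache=True)
def _closed_kernel(
    seed,
    n_mol,
    n_steps,
    dt,
    sigma,
    radius,
    h_ap,
    h_box,
    d_decay,
    p_ads,
    p_des,
    p_bd,
    p_db,
    t_ds,
    init_pos,
    rec_pos,
    rec_kin,
    sample_stride,
    dwells,
):
    """Closed reflecting column with a fixed molecule count; records paths."""
    np.random.seed(seed)
    r2max = radius * radius
    n_dwell = 0
    for j in range(n_mol):
        if np.isnan(init_pos[j, 0]):
            z = np.random.uniform(0.0, h_box)
            while True:
                x = np.random.uniform(-radius, radius)
                y = np.random.uniform(-radius, radius)
                if x * x + y * y <= r2max:
                    break
        else:
            x = init_pos[j, 0]
            y = init_pos[j, 1]
            z = init_pos[j, 2]
        kin = 0
        t_stick = 0.0
        for step in range(n_steps):
            if step % sample_stride == 0:
                k = step // sample_stride
                rec_pos[j, k, 0] = x
                rec_pos[j, k, 1] = y
                rec_pos[j, k, 2] = z
                rec_kin[j, k] = kin
            if kin == 1:
                t_stick += dt
                if np.random.random() < p_des:
                    kin = 0
                    if n_dwell < dwells.shape[0]:
                        dwells[n_dwell] = t_stick
                    n_dwell += 1
                    t_stick = 0.0
                continue
            x += sigma * np.random.normal()
            y += sigma * np.random.normal()
            z += sigma * np.random.normal()
            adsorbed_now = False
            if z < 0.0:
                if p_ads > 0.0 and np.random.random() < p_ads:
                    adsorbed_now = True
                    z = 0.0
                else:
                    z = -z
            if z > h_box:
                z = 2.0 * h_box - z
            r2 = x * x + y * y
            if r2 > r2max:
                r = math.sqrt(r2)
                if (not adsorbed_now) and z < h_ap and p_ads > 0.0 and np.random.random() < p_ads:
                    adsorbed_now = True
                    s = radius / r
                    x *= s
                    y *= s
                else:
                    rr = 2.0 * radius - r
                    if rr < 0.0:
                        rr = 0.0
                    s = rr / r
                    x *= s
                    y *= s
            if adsorbed_now:
                r2 = x * x + y * y
                if r2 > r2max:
                    s = radius / math.sqrt(r2)
                    x *= s
                    y *= s
                kin = 1
                t_stick = 0.0
    return n_dwell


def _kernel_rates(config: SimulationConfig) -> tuple[float, float, float]:
    """Per-step probabilities (desorb, bright->dark, dark->bright)."""
    dt = config.dt
    p_des = 1.0 - math.exp(-dt / config.adsorbed_dwell_mean)
    k_db = 1.0 / config.dark_lifetime
    k_bd = config.dark_fraction / (1.0 - config.dark_fraction) * k_db
    return p_des, 1.0 - math.exp(-k_bd * dt), 1.0 - math.exp(-k_db * dt)


def _seeds(config: SimulationConfig) -> tuple[int, np.random.Generator]:
    ss = np.random.SeedSequence(config.rng_seed)
    kernel_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
    return kernel_seed, np.random.default_rng(ss.spawn(1)[0])


def _photon_capacity(config: SimulationConfig) -> int:
    v1, _ = _profile_integrals(config)
    free = config.density * v1 * config.brightness_free
    ads = expected_adsorbed_number(config) * config.brightness_adsorbed
    return int(8.0 * (free + ads) * config.duration + 2e5)


# ----------------------------------------------------------------------
# Public operations
# ----------------------------------------------------------------------

@dataclass
class TrajectorySample:
    """Decimated molecule paths: positions (nm) and kinetic states."""

    times: np.ndarray  # (n_samples,) s
    positions: np.ndarray  # (n_mol, n_samples, 3) nm
    kinetic: np.ndarray  # (n_mol, n_samples) 0 free / 1 adsorbed
    config: SimulationConfig

    @property
    def sample_interval(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else self.config.dt


def simulate_trajectories(
    config: SimulationConfig,
    sample_interval: float | None = None,
    initial_positions: np.ndarray | None = None,
    return_dwells: bool = False,
):
    """Integrate Brownian paths with adsorption in a closed column.

    A fixed set of ``n_molecules`` diffuses in a reflecting column whose
    height realizes the configured concentration; paths are recorded
    every ``sample_interval`` (default 100 fine steps).
    ``initial_positions`` (n_molecules x 3, nm) pins the starting
    positions; by default molecules start uniformly in the column.
    """
    dt = config.dt
    if dt <= 0:
        raise ValueError("time step must be positive")
    stride = max(1, int(round((sample_interval or 100 * dt) / dt)))
    n_steps = int(round(config.duration / dt))
    if n_steps < 1:
        raise ValueError("duration shorter than one time step")
    n_samples = (n_steps + stride - 1) // stride
    if n_samples * config.n_molecules > 5e7:
        raise ValueError("trajectory recording too large; increase sample_interval")
    init = np.full((config.n_molecules, 3), np.nan)
    if initial_positions is not None:
        init[:] = np.asarray(initial_positions, dtype=float)
    p_des, p_bd, p_db = _kernel_rates(config)
    kernel_seed, _ = _seeds(config)
    rec_pos = np.zeros((config.n_molecules, n_samples, 3))
    rec_kin = np.zeros((config.n_molecules, n_samples), np.int8)
    dwells = np.zeros(200000)
    n_dwell = _closed_kernel(
        kernel_seed,
        config.n_molecules,
        n_steps,
        dt,
        config.step_sigma,
        config.radius,
        config.aperture_height,
        config.column_height,
        config.axial_decay_length,
        config.adsorption_prob_per_contact,
        p_des,
        p_bd,
        p_db,
        config.dark_fraction,
        init,
        rec_pos,
        rec_kin,
        stride,
        dwells,
    )
    sample = TrajectorySample(
        times=dt * stride * np.arange(n_samples),
        positions=rec_pos,
        kinetic=rec_kin,
        config=config,
    )
    if return_dwells:
        return sample, dwells[: min(n_dwell, len(dwells))].copy()
    return sample


def _emitted_to_trace(
    times: np.ndarray, states: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> TTTRTrace:
    """Attach microtimes, merge background, and package as a TTTR trace."""
    n_bg = rng.poisson(config.background_rate * config.duration)
    bg_times = rng.uniform(0.0, config.duration, n_bg)
    all_times = np.concatenate([times, bg_times])
    all_states = np.concatenate([states, np.full(n_bg, 2, np.int8)])
    order = np.argsort(all_times, kind="stable")
    all_times = all_times[order]
    all_states = all_states[order]

    period_ps = 1e12 / config.sync_rate
    delays = np.empty(len(all_times))
    for state, tau_ns in ((0, config.lifetime_free), (1, config.lifetime_adsorbed)):
        m = all_states == state
        delays[m] = rng.exponential(tau_ns * 1e3, int(m.sum()))
    m = all_states == 2
    delays[m] = rng.uniform(0.0, period_ps, int(m.sum()))
    # reconvolve with the instrument response
    if config.irf.fwhm_ps is not None:
        jitter = rng.normal(0.0, config.irf.sigma_ps, len(delays))
        delays = delays + jitter + config.irf.center_ps
    else:
        hist = config.irf.histogram
        edges = hist.channel_width * np.arange(hist.n_channels + 1)
        p = hist.counts / hist.counts.sum()
        ch = rng.choice(hist.n_channels, size=len(delays), p=p)
        delays = delays + edges[ch] + rng.uniform(0, hist.channel_width, len(delays))
    micro = np.floor(np.mod(delays, period_ps)).astype(np.int64)
    macro = np.floor(all_times * config.sync_rate).astype(np.int64)
    meta = {"seed": int(config.rng_seed), "simulated": True}
    return TTTRTrace(
        macrotimes=macro,
        microtimes=micro,
        channels=np.zeros(len(macro), np.int16),
        sync_rate=config.sync_rate,
        duration=config.duration,
        metadata=meta,
    )


def generate_photon_stream(paths: TrajectorySample, config: SimulationConfig) -> TTTRTrace:
    """Emit photons from sampled trajectories.

    Emission is an inhomogeneous Poisson process with rate
    ``brightness(state) x exp(-z / axial_decay_length)`` gated by a
    two-state dark process realizing (T_ds, tau_ds); microtimes are drawn
    from the state's exponential decay and convolved with the IRF.  The
    path is treated as piecewise constant over the sample interval, so
    this route suits finely sampled paths; :func:`simulate_experiment`
    streams the same physics at full step resolution.
    """
    _, rng = _seeds(config)
    dt = paths.sample_interval
    n_mol, n_samples = paths.kinetic.shape
    z = paths.positions[:, :, 2]
    w = np.exp(-z / config.axial_decay_length)
    rate = np.where(paths.kinetic == 1, config.brightness_adsorbed, config.brightness_free) * w
    # two-state dark gating on the sample grid
    if config.dark_fraction > 0:
        k_db = 1.0 / config.dark_lifetime
        k_bd = config.dark_fraction / (1.0 - config.dark_fraction) * k_db
        p_bd = 1.0 - math.exp(-k_bd * dt)
        p_db = 1.0 - math.exp(-k_db * dt)
        dark = rng.random(n_mol) < config.dark_fraction
        bright = np.empty((n_mol, n_samples), bool)
        u = rng.random((n_mol, n_samples))
        for k in range(n_samples):
            bright[:, k] = ~dark
            flip_down = (~dark) & (u[:, k] < p_bd)
            flip_up = dark & (u[:, k] < p_db)
            dark = (dark | flip_down) & ~flip_up
        rate = rate * bright
    counts = rng.poisson(rate * dt)
    total = int(counts.sum())
    times = np.empty(total)
    states = np.empty(total, np.int8)
    pos = 0
    for j in range(n_mol):
        nz = np.nonzero(counts[j])[0]
        for k in nz:
            c = counts[j, k]
            times[pos : pos + c] = paths.times[k] + rng.uniform(0, dt, c)
            states[pos : pos + c] = paths.kinetic[j, k]
            pos += c
    return _emitted_to_trace(times, states, config, rng)


def _run_exchange(config: SimulationConfig, rec_weight: np.ndarray, weight_stride: int,
                  unit_brightness: bool = False):
    dt = config.dt
    n_steps = int(round(config.duration / dt))
    p_des, p_bd, p_db = _kernel_rates(config)
    kernel_seed, rng = _seeds(config)
    cap = _photon_capacity(config) if not unit_brightness else 1
    ph_time = np.zeros(cap)
    ph_state = np.zeros(cap, np.int8)
    dwells = np.zeros(100000)
    sigma = config.step_sigma
    # equilibrium one-way crossing flux through the exit plane, per step
    lam_steps = config.density * config.area * sigma / math.sqrt(2.0 * math.pi)
    init_mean = config.density * config.area * config.exit_plane
    rate_free = 0.0 if unit_brightness else config.brightness_free
    rate_ads = 0.0 if unit_brightness else config.brightness_adsorbed
    w_ads_scale = (
        config.brightness_adsorbed / config.brightness_free if config.brightness_free else 1.0
    )
    count, n_dwell, truth = _exchange_kernel(
        kernel_seed,
        n_steps,
        dt,
        sigma,
        config.radius,
        config.aperture_height,
        config.exit_plane,
        config.axial_decay_length,
        lam_steps,
        init_mean,
        config.adsorption_prob_per_contact,
        p_des,
        p_bd,
        p_db,
        config.dark_fraction,
        rate_free,
        rate_ads,
        w_ads_scale,
        ph_time,
        ph_state,
        rec_weight,
        weight_stride,
        dwells,
    )
    if count >= cap:
        raise RuntimeError(
            "photon buffer exhausted; the configuration emits far more photons "
            "than its steady-state estimate"
        )
    return ph_time[:count], ph_state[:count], n_dwell, truth, rng


def simulate_experiment(config: SimulationConfig, return_truth: bool = False):
    """Full synthetic acquisition: trajectories + photon stream, fused.

    Logically the composition of trajectory integration and photon
    emission; the trajectory is streamed internally at full step
    resolution instead of being materialized.  Deterministic under
    ``config.rng_seed``.
    """
    times, states, n_dwell, truth, rng = _run_exchange(config, np.zeros(1), -1)
    trace = _emitted_to_trace(times, states, config, rng)
    if not return_truth:
        return trace
    dur = config.duration
    truth_d = {
        "mean_weight_free": truth[0] / dur,
        "mean_weight2_free": truth[1] / dur,
        "mean_weight_adsorbed": truth[2] / dur,
        "mean_weight2_adsorbed": truth[3] / dur,
        "n_adsorption_events": int(truth[4]),
        "adsorbed_time": truth[5],
        "n_completed_dwells": n_dwell,
    }
    num = truth_d["mean_weight2_adsorbed"] * config.brightness_adsorbed**2
    den = num + truth_d["mean_weight2_free"] * config.brightness_free**2
    truth_d["realized_slow_fraction"] = num / den if den > 0 else 0.0
    return trace, truth_d


def reference_intensity_trace(config: SimulationConfig, bin_width: float = 4e-6) -> np.ndarray:
    """Shot-noise-free detection-weighted occupancy integrated per time bin.

    The independent truth signal for the diffusion-time scale: its
    autocorrelation is the ideal correlation function of the configured
    dynamics, free of photon statistics and correlator approximations.
    Adsorbed molecules contribute with the brightness ratio
    ``brightness_adsorbed / brightness_free``.
    """
    dt = config.dt
    stride = max(1, int(round(bin_width / dt)))
    n_steps = int(round(config.duration / dt))
    n_bins = (n_steps + stride - 1) // stride
    rec_weight = np.zeros(n_bins)
    _run_exchange(config, rec_weight, stride, unit_brightness=True)
    return rec_weight
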