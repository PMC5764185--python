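"""Synthetic bi-directional western blot scans with ground truth.

The generator renders, for every occupied microwell, a pair of Gaussian
protein bands: the cytoplasmic band "east" of the well and the nuclear band
"west", with the per-cell total signal split between the two by a
localization fraction.  The physics follows standard electrophoresis /
diffusion scaling:

* bands migrate ``drift_velocity * t_page`` from the well center, with a
  configurable cell-to-cell coefficient of variation of the migration
  distance mimicking field non-uniformity across the array;
* band standard deviation grows diffusively,
  ``sigma(t) = sqrt(sigma0^2 + 2 D t)``, with the injection dispersion
  absorbed into ``sigma0`` (default: well_diameter / 4);
* protein escaping the open microwell during lysis is modeled as a
  single-exponential diffusive loss ``1 - exp(-t_lysis / tau_loss)``.

Cell-to-cell expression variability is lognormal; the nuclear fraction is a
clipped normal (Beta optional).  Noise is additive Gaussian (scanner read
noise proxy).  Every simulation emits a truth table whose rows match the
rendered parameters exactly, so quantification can be scored against ground
truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from sc2wb.errors import ConfigError
from sc2wb.layout import ArrayLayout

__all__ = [
    "TransportParams",
    "TargetSpec",
    "SimulationTruth",
    "compartment_volume_pl",
    "diffusion_time",
    "band_sigma",
    "diffusive_loss",
    "simulate_array",
    "simulate_timecourse",
    "nfkb_pulse",
]


def compartment_volume_pl(length_um: float) -> float:
    """Volume (pL) of a spherical compartment of characteristic diameter l (um).

    (pi/6) l^3: the ~30 um cytoplasmic and ~15 um nuclear compartments give
    ~14 pL and ~2 pL, the volumes the assay samples per cell.
    """
    if length_um <= 0:
        raise ValueError(f"characteristic length must be positive, got {length_um}")
    return math.pi / 6.0 * length_um**3 * 1e-3


def diffusion_time(x: float, D: float) -> float:
    """Characteristic diffusion timescale tau = x^2 / (2 D), in seconds.

    ``x`` is the diffusion length (um) and ``D`` the species diffusivity
    (um^2/s).  For GFP (D = 88 um^2/s) over the 10 um from a lysed cell to the
    open top of the microwell this gives ~0.6 s, the scale that limits the
    usable lysis duration.
    """
    if x < 0:
        raise ValueError(f"diffusion length must be non-negative, got {x}")
    if D <= 0:
        raise ValueError(f"diffusivity must be positive, got {D}")
    return x * x / (2.0 * D)


def band_sigma(sigma0: float, D: float, t: float) -> float:
    """Diffusively broadened band s.d.: sqrt(sigma0^2 + 2 D t), in um."""
    if sigma0 < 0 or D < 0 or t < 0:
        raise ValueError("sigma0, D and t must all be non-negative")
    return math.sqrt(sigma0 * sigma0 + 2.0 * D * t)


def diffusive_loss(t_lysis: float, tau_loss: float) -> float:
    """Fraction of lysate lost from the open microwell during lysis.

    Single-exponential in lysis duration: ``1 - exp(-t_lysis/tau_loss)``,
    clamped to [0, 1).
    """
    if tau_loss <= 0:
        raise ValueError(f"tau_loss must be positive, got {tau_loss}")
    if t_lysis < 0:
        raise ValueError(f"t_lysis must be non-negative, got {t_lysis}")
    return min(1.0 - math.exp(-t_lysis / tau_loss), 1.0 - 1e-12)


@dataclass(frozen=True)
class TransportParams:
    """Electromigration and diffusion parameters of one simulated separation.

    Defaults reflect the standard assay conditions: 40 V/cm field, 17 s PAGE,
    25 s lysis, initial band s.d. 8 um (a quarter of the 32 um well
    diameter).  ``D`` is the *in-gel* diffusivity governing band broadening
    during PAGE; sieving in an 8%T polyacrylamide gel slows proteins well
    below their free-solution diffusivity (88 um^2/s for GFP, the value
    relevant to microwell transport).  The 15 um^2/s default yields band
    widths w = 4 sigma of ~96 um after a 17 s separation, i.e. a peak
    capacity of ~10 on a 1 mm axis, matching observed separations.
    ``drift_velocity`` is the apparent band velocity (mobility x field),
    chosen so a typical band migrates ~250 um, mid-lane of a 500 um
    half-separation.
    """

    D: float = 15.0  # um^2/s, in-gel
    E: float = 40.0  # V/cm
    drift_velocity: float = 250.0 / 17.0  # um/s
    t_lysis: float = 25.0  # s
    t_page: float = 17.0  # s
    sigma0: float = 8.0  # um

    def __post_init__(self) -> None:
        for name in ("D", "E", "drift_velocity", "t_lysis", "t_page", "sigma0"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"TransportParams.{name} must be strictly positive")

    @property
    def migration_um(self) -> float:
        return self.drift_velocity * self.t_page

    @property
    def sigma_um(self) -> float:
        return band_sigma(self.sigma0, self.D, self.t_page)


@dataclass(frozen=True)
class TargetSpec:
    """One protein target of the simulated panel.

    ``mean_auc`` is the population-mean total band area (AU*um); per-cell
    totals are lognormal with coefficient of variation ``expression_cv``.
    ``nuclear_fraction_mean``/``sd`` parameterize the clipped-normal per-cell
    nuclear split (sd=0 pins every cell to the mean).  ``migration_um``
    optionally overrides the transport-derived migration distance so several
    targets can share a detection channel at distinct positions.
    """

    name: str
    channel: str = "AF647"
    mean_auc: float = 5.0e5
    expression_cv: float = 0.4
    nuclear_fraction_mean: float = 0.5
    nuclear_fraction_sd: float = 0.11
    migration_um: float | None = None
    expected_compartment: str = "both"  # cytoplasmic | nuclear | both

    def __post_init__(self) -> None:
        if not 0.0 <= self.nuclear_fraction_mean <= 1.0:
            raise ConfigError("nuclear_fraction_mean must lie in [0, 1]")
        if self.mean_auc <= 0 or self.expression_cv < 0 or self.nuclear_fraction_sd < 0:
            raise ConfigError("mean_auc must be positive; CVs/sds non-negative")
        if self.expected_compartment not in ("cytoplasmic", "nuclear", "both"):
            raise ConfigError(
                f"expected_compartment must be cytoplasmic|nuclear|both, "
                f"got {self.expected_compartment!r}"
            )


@dataclass
class SimulationTruth:
    """Ground-truth generative parameters for one cell x target."""

    cell_id: int
    target: str
    channel: str
    true_total_auc: float
    true_nuclear_fraction: float
    true_center_east: float
    true_center_west: float
    true_sigma_east: float
    true_sigma_west: float
    loss_fraction: float
    seed: int

    def as_dict(self) -> dict:
        return asdict(self)


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and CV."""
    s2 = math.log1p(cv * cv)
    return math.log(mean) - 0.5 * s2, math.sqrt(s2)


def _draw_fraction(rng, mean: float, sd: float, n: int, model: str) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    if model == "normal":
        return np.clip(rng.normal(mean, sd, n), 0.0, 1.0)
    if model == "beta":
        # method-of-moments Beta with the same mean and sd
        m = min(max(mean, 1e-6), 1 - 1e-6)
        v = min(sd * sd, m * (1 - m) * 0.999)
        k = m * (1 - m) / v - 1.0
        return rng.beta(m * k, (1 - m) * k, n)
    raise ConfigError(f"fraction_model must be 'normal' or 'beta', got {model!r}")


def _render_band(
    image: np.ndarray,
    layout: ArrayLayout,
    well_center_px: tuple[float, float],
    center_um: float,
    sigma_um: float,
    auc: float,
) -> None:
    """Add one Gaussian band to ``image`` in place.

    The band is Gaussian along the axis and uniform across the well-diameter
    worth of transverse rows, scaled so the transverse-summed axial profile
    integrates (over um) to ``auc``.
    """
    if auc <= 0:
        return
    r, c = well_center_px
    half_w = layout.well_diameter / 2 / layout.pixel_size
    r0, r1 = int(round(r - half_w)), int(round(r + half_w))
    n_rows = max(r1 - r0, 1)
    cols = np.arange(image.shape[1], dtype=np.float64)
    u = (cols - c) * layout.pixel_size
    amplitude = auc / (sigma_um * math.sqrt(2.0 * math.pi))
    profile = amplitude * np.exp(-0.5 * ((u - center_um) / sigma_um) ** 2)
    image[r0:r1, :] += profile / n_rows


def simulate_array(
    layout: ArrayLayout,
    panel: Sequence[TargetSpec],
    transport: TransportParams | None = None,
    n_cells: int | None = None,
    noise_sd: float = 10.0,
    seed: int = 0,
    migration_cv: float = 6.4,
    tau_loss: float | None = None,
    fraction_model: str = "normal",
    well_residual_fraction: float = 0.0,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Simulate one array scan and its ground-truth table.

    Per cell and target: the total band area is lognormal
    (``mean_auc``, ``expression_cv``), split by a clipped-normal nuclear
    fraction; the east (cytoplasmic) and west (nuclear) Gaussian bands are
    rendered at ``+/- drift_velocity * t_page`` (per-cell migration perturbed
    with CV ``migration_cv`` percent) with diffusive s.d. from
    :func:`band_sigma`, scaled down by the diffusive loss fraction when
    ``tau_loss`` is given.  Additive Gaussian noise of s.d. ``noise_sd`` is
    applied per channel.  Identical seeds give identical output.

    Returns a dict of per-channel images and a truth DataFrame (one row per
    cell x target).
    """
    transport = transport or TransportParams()
    if n_cells is None:
        n_cells = layout.n_wells
    if n_cells > layout.n_wells:
        raise ConfigError(
            f"n_cells={n_cells} exceeds the {layout.n_wells} wells of the layout"
        )
    if migration_cv < 0 or noise_sd < 0:
        raise ConfigError("migration_cv and noise_sd must be non-negative")

    rng = np.random.default_rng(seed)
    shape = layout.image_shape()
    channels = []
    for t in panel:
        if t.channel not in channels:
            channels.append(t.channel)
    images = {ch: np.zeros(shape, dtype=np.float64) for ch in channels}

    loss = diffusive_loss(transport.t_lysis, tau_loss) if tau_loss else 0.0
    sigma = transport.sigma_um
    truths: list[SimulationTruth] = []
    for cell in range(n_cells):
        i, j = divmod(cell, layout.n_cols)
        well = layout.well_center_px(i, j)
        for target in panel:
            mu, s = _lognormal_params(target.mean_auc, max(target.expression_cv, 1e-12))
            total = float(rng.lognormal(mu, s))
            nuc = float(
                _draw_fraction(
                    rng, target.nuclear_fraction_mean, target.nuclear_fraction_sd, 1, fraction_model
                )[0]
            )
            base_m = target.migration_um if target.migration_um is not None else transport.migration_um
            m_east = base_m * (1.0 + migration_cv / 100.0 * rng.standard_normal())
            m_west = base_m * (1.0 + migration_cv / 100.0 * rng.standard_normal())
            east_sign = 1.0 if layout.east_positive else -1.0
            auc_east = total * (1.0 - nuc) * (1.0 - loss)
            auc_west = total * nuc * (1.0 - loss)
            img = images[target.channel]
            _render_band(img, layout, well, east_sign * m_east, sigma, auc_east)
            _render_band(img, layout, well, -east_sign * m_west, sigma, auc_west)
            if well_residual_fraction > 0:
                _render_band(
                    img, layout, well, 0.0, layout.well_diameter / 4,
                    well_residual_fraction * total,
                )
            truths.append(
                SimulationTruth(
                    cell_id=cell,
                    target=target.name,
                    channel=target.channel,
                    true_total_auc=total,
                    true_nuclear_fraction=nuc,
                    true_center_east=east_sign * m_east,
                    true_center_west=-east_sign * m_west,
                    true_sigma_east=sigma,
                    true_sigma_west=sigma,
                    loss_fraction=loss,
                    seed=seed,
                )
            )
    if noise_sd > 0:
        for ch in channels:
            images[ch] += rng.normal(0.0, noise_sd, shape)
    truth = pd.DataFrame(
        [t.as_dict() for t in truths], columns=[f.name for f in fields(SimulationTruth)]
    )
    return images, truth


def nfkb_pulse(
    peak_time: float = 60.0,
    width: float = 25.0,
    baseline: float = 0.15,
    amplitude: float = 0.45,
) -> Callable[[float], float]:
    """Unimodal nuclear-fraction time course for a translocation transient.

    A Gaussian pulse over the stimulation clock: nuclear fraction rises from
    ``baseline`` to ``baseline + amplitude`` at ``peak_time`` minutes and
    relaxes symmetrically, emulating stimulus-driven nuclear import followed
    by export.
    """

    def curve(t_min: float) -> float:
        return baseline + amplitude * math.exp(-0.5 * ((t_min - peak_time) / width) ** 2)

    return curve


def simulate_timecourse(
    layout: ArrayLayout,
    panel: Sequence[TargetSpec],
    timepoints: Sequence[float],
    nuclear_fraction_curve: Callable[[float], float],
    n_cells_per_timepoint: int,
    transport: TransportParams | None = None,
    seed: int = 0,
    **kwargs,
) -> dict[float, tuple[dict[str, np.ndarray], pd.DataFrame]]:
    """Simulate one array per stimulation timepoint.

    The panel's per-target ``nuclear_fraction_mean`` is replaced by
    ``nuclear_fraction_curve(t)`` at each timepoint; per-timepoint seeds are
    derived deterministically from ``seed``.  Returns an ordered mapping
    ``timepoint -> (images, truth)`` with a ``timepoint_min`` column added to
    each truth table.
    """
    if len(timepoints) == 0:
        raise ConfigError("timepoints must be non-empty")
    master = np.random.default_rng(seed)
    sub_seeds = master.integers(0, 2**31 - 1, size=len(timepoints))
    out: dict[float, tuple[dict[str, np.ndarray], pd.DataFrame]] = {}
    for tp, sub in zip(timepoints, sub_seeds):
        frac = float(np.clip(nuclear_fraction_curve(tp), 0.0, 1.0))
        panel_t = [
            TargetSpec(**{**asdict(t), "nuclear_fraction_mean": frac}) for t in panel
        ]
        images, truth = simulate_array(
            layout,
            panel_t,
            transport=transport,
            n_cells=n_cells_per_timepoint,
            seed=int(sub),
            **kwargs,
        )
        truth.insert(1, "timepoint_min", tp)
        out[tp] = (images, truth)
    return out
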